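"""Detection of C2H2 zinc-finger motifs and EAR repression motifs.

The C2H2 finger is matched with the classical geometry
``X2-Cys-X2,4-Cys-X12-His-X3,4,5-His`` expressed as the two regular
expressions ``.{2}C.{2}C.{12}H.{3,5}H`` and ``.{2}C.{4}C.{12}H.{3,5}H``
(one per Cys spacing).  Two matching modes are offered:

``published``
    Each pattern is scanned independently with Python ``re.finditer``
    semantics — leftmost, non-overlapping, greedy inter-His gap (the
    longest of 3–5 residues that completes a match at the anchor).  The
    two result sets are merged and sorted by start; where a Cys-gap-2
    call overlaps a Cys-gap-4 call, the gap-2 call is kept (C-X2-C is the
    canonical C2H2 geometry, and one physical finger should yield one
    call).

``exhaustive``
    Every window satisfying either pattern is reported, overlaps allowed.
    This mode is validated character by character, independently of the
    regex engine, and serves as the oracle superset for the published
    mode.

EAR (ERF-associated amphiphilic repression) sites are matched with the
two canonical patterns ``LxLxL`` and ``DLNxxP``; leftmost non-overlapping
occurrences per pattern, merged and sorted.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

from zfpkit.seq_io import ProteinRecord

__all__ = [
    "C2H2Motif",
    "EARSite",
    "scan_c2h2",
    "scan_ear",
    "attach_confirmation",
    "is_c2h2_window",
]

logger = logging.getLogger(__name__)

#: the two finger patterns, keyed by Cys gap
C2H2_PATTERNS: dict[int, re.Pattern] = {
    2: re.compile(r".{2}C.{2}C.{12}H.{3,5}H"),
    4: re.compile(r".{2}C.{4}C.{12}H.{3,5}H"),
}

#: canonical EAR motif classes
EAR_PATTERNS: dict[str, re.Pattern] = {
    "LxLxL": re.compile(r"L.L.L"),
    "DLNxxP": re.compile(r"DLN..P"),
}

CYS_GAPS = (2, 4)
HIS_GAPS = (3, 4, 5)


@dataclass(frozen=True)
class C2H2Motif:
    """One detected C2H2 finger (protein coordinates, 0-based half-open).

    ``core6`` is the six-residue string ending at the first His (the
    stretch that defines the Q/QM typing); ``inter_his`` is the
    ``his_gap``-long segment between the two His residues (the stretch
    that defines Q subgroups).
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    cys_gap: int
    his_gap: int
    core6: str
    inter_his: str
    mtype: str = "unassigned"
    subgroup: str = ""

    def __post_init__(self) -> None:
        expected = 18 + self.cys_gap + self.his_gap
        if self.end - self.start != expected or len(self.sequence) != expected:
            raise ValueError("motif span inconsistent with spacer geometry")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def first_his_offset(self) -> int:
        return 16 + self.cys_gap


@dataclass(frozen=True)
class EARSite:
    """One detected EAR repression-motif occurrence (0-based half-open)."""

    protein_id: str
    start: int
    end: int
    pattern_id: str
    matched: str

    def __post_init__(self) -> None:
        pat = EAR_PATTERNS[self.pattern_id]
        if pat.fullmatch(self.matched) is None:
            raise ValueError(f"{self.matched!r} does not satisfy {self.pattern_id}")


def is_c2h2_window(seq: str, start: int, cys_gap: int, his_gap: int) -> bool:
    """Character-by-character check that a window is a valid C2H2 finger.

    Independent of the regex engine on purpose: used by exhaustive mode and
    by tests as the validation oracle for published-mode calls.
    """
    length = 18 + cys_gap + his_gap
    if start < 0 or start + length > len(seq):
        return False
    c1 = start + 2
    c2 = c1 + 1 + cys_gap
    h1 = c2 + 1 + 12
    h2 = h1 + 1 + his_gap
    return seq[c1] == "C" and seq[c2] == "C" and seq[h1] == "H" and seq[h2] == "H"


def _motif_from_window(record: ProteinRecord, start: int, cys_gap: int, his_gap: int) -> C2H2Motif:
    length = 18 + cys_gap + his_gap
    end = start + length
    window = record.sequence[start:end]
    first_his = 16 + cys_gap
    return C2H2Motif(
        protein_id=record.id,
        start=start,
        end=end,
        sequence=window,
        cys_gap=cys_gap,
        his_gap=his_gap,
        core6=window[first_his - 5 : first_his + 1],
        inter_his=window[first_his + 1 : first_his + 1 + his_gap],
    )


def _overlaps(a: C2H2Motif, b: C2H2Motif) -> bool:
    return a.start < b.end and b.start < a.end


def scan_c2h2(
    record: ProteinRecord,
    mode: Literal["published", "exhaustive"] = "published",
    patterns: Mapping[int, re.Pattern] = C2H2_PATTERNS,
) -> list[C2H2Motif]:
    """Scan one protein for C2H2 fingers.

    Returns motifs sorted by start (ties: smaller Cys gap first), with
    ``mtype`` left ``unassigned``.  Published-mode output is guaranteed
    non-overlapping; exhaustive mode reports every satisfying window.
    """
    seq = record.sequence
    if mode == "exhaustive":
        out = []
        for start in range(len(seq)):
            for cys_gap in CYS_GAPS:
                for his_gap in HIS_GAPS:
                    if is_c2h2_window(seq, start, cys_gap, his_gap):
                        out.append(_motif_from_window(record, start, cys_gap, his_gap))
        out.sort(key=lambda m: (m.start, m.cys_gap, m.his_gap))
        return out
    if mode != "published":
        raise ValueError(f"unknown scan mode {mode!r}")

    per_gap: dict[int, list[C2H2Motif]] = {}
    for cys_gap, pattern in patterns.items():
        calls = []
        for m in pattern.finditer(seq):
            his_gap = (m.end() - m.start()) - 18 - cys_gap
            calls.append(_motif_from_window(record, m.start(), cys_gap, his_gap))
        per_gap[cys_gap] = calls
    # cross-pattern overlap resolution: keep the Cys-gap-2 call
    kept4 = [
        m4
        for m4 in per_gap.get(4, [])
        if not any(_overlaps(m4, m2) for m2 in per_gap.get(2, []))
    ]
    merged = sorted(per_gap.get(2, []) + kept4, key=lambda m: (m.start, m.cys_gap))
    return merged


def scan_ear(
    record: ProteinRecord,
    patterns: Mapping[str, re.Pattern] = EAR_PATTERNS,
) -> list[EARSite]:
    """Scan one protein for EAR repression sites.

    Each enabled pattern is evaluated independently (leftmost,
    non-overlapping within the pattern); results are merged and sorted by
    start, then pattern id.
    """
    sites = []
    for pattern_id, pattern in patterns.items():
        for m in pattern.finditer(record.sequence):
            sites.append(
                EARSite(
                    protein_id=record.id,
                    start=m.start(),
                    end=m.end(),
                    pattern_id=pattern_id,
                    matched=m.group(0),
                )
            )
    sites.sort(key=lambda s: (s.start, s.pattern_id))
    return sites


def attach_confirmation(
    calls: Mapping[str, Sequence[C2H2Motif]],
    keep_drop_list: Optional[Mapping[str, str]] = None,
) -> tuple[dict[str, list[C2H2Motif]], int]:
    """Apply an externally produced keep/drop confirmation list.

    The upstream study confirmed regex candidates against curated domain
    databases; that scan is not reproduced here — its verdict is ingested
    as a mapping ``protein id -> "keep" | "drop"``.  Absent list is the
    identity.  Returns ``(filtered_calls, n_dropped)``; ids in the list
    but not among the calls only raise a warning.
    """
    if keep_drop_list is None:
        return {pid: list(ms) for pid, ms in calls.items()}, 0
    unknown = [pid for pid in keep_drop_list if pid not in calls]
    if unknown:
        warnings.warn(f"{len(unknown)} keep/drop ids not among candidate calls")
    bad = {v for v in keep_drop_list.values()} - {"keep", "drop"}
    if bad:
        raise ValueError(f"keep/drop verdicts must be 'keep' or 'drop', got {sorted(bad)}")
    filtered = {
        pid: list(ms)
        for pid, ms in calls.items()
        if keep_drop_list.get(pid, "keep") != "drop"
    }
    n_dropped = len(calls) - len(filtered)
    logger.info("confirmation filter dropped %d of %d candidates", n_dropped, len(calls))
    return filtered, n_dropped
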