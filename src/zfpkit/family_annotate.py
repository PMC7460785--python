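"""Per-protein aggregation: finger counts, tandem arrays, EAR arrangements.

Zinc-finger proteins fall into natural classes by the number of fingers
they carry.  Within one protein, consecutive fingers joined by short
linkers (fewer than 11 residues between the end of one motif and the
start of the next) form tandem arrays.  For single-finger proteins the
relative order of the finger and any EAR repression sites defines an
arrangement class (the PALM1/RSD layout is finger first, EAR at the far
C-terminus).  An EAR lying inside a finger (as in the five-finger
repressor TRM1, whose fifth finger carries an LKLHLK) is flagged as an
overlap rather than entering the arrangement logic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from zfpkit.motif_scan import C2H2Motif, EARSite

__all__ = [
    "TandemArray",
    "ZFPAnnotation",
    "call_tandem_arrays",
    "classify_architecture",
    "family_summary",
    "FamilySummary",
    "render_architecture",
    "DEFAULT_TANDEM_THRESHOLD",
]

DEFAULT_TANDEM_THRESHOLD = 11

_COUNT_CLASS = {1: "single", 2: "two", 3: "three", 4: "four", 5: "five", 6: "six", 9: "nine"}


@dataclass(frozen=True)
class TandemArray:
    """A maximal run of fingers joined by sub-threshold linkers."""

    member_indices: tuple[int, ...]
    linker_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.member_indices) < 2:
            raise ValueError("a tandem array needs >= 2 members")
        if len(self.linker_lengths) != len(self.member_indices) - 1:
            raise ValueError("need exactly one linker per adjacent pair")

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class ZFPAnnotation:
    """Aggregate annotation of one zinc-finger protein."""

    protein_id: str
    protein_length: int
    motifs: list[C2H2Motif]
    ears: list[EARSite]
    finger_count: int
    count_class: str
    arrays: list[TandemArray]
    array_class: str  # has_tandem | no_tandem | single_finger
    ear_class: str  # no_EAR | one_EAR | multi_EAR
    arrangement: str
    ear_overlaps: list[EARSite] = field(default_factory=list)


def call_tandem_arrays(
    motifs: Sequence[C2H2Motif],
    threshold: int = DEFAULT_TANDEM_THRESHOLD,
) -> list[TandemArray]:
    """Find maximal tandem arrays among one protein's fingers.

    The linker is the number of residues strictly between the matched
    spans (``next.start - prev.end``); a run extends while each linker is
    ``< threshold``.  Singleton runs are not arrays.  Motifs must be
    sorted and non-overlapping (the published-mode scanner contract).
    """
    for a, b in zip(motifs, motifs[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping motifs at {a.start}-{a.end} / {b.start}-{b.end}: "
                "scanner contract violated"
            )
        if a.protein_id != b.protein_id:
            raise ValueError("motifs from different proteins")
    arrays: list[TandemArray] = []
    run = [0] if motifs else []
    linkers: list[int] = []
    for i in range(1, len(motifs)):
        linker = motifs[i].start - motifs[i - 1].end
        if linker < threshold:
            run.append(i)
            linkers.append(linker)
        else:
            if len(run) >= 2:
                arrays.append(TandemArray(tuple(run), tuple(linkers)))
            run, linkers = [i], []
    if len(run) >= 2:
        arrays.append(TandemArray(tuple(run), tuple(linkers)))
    return arrays


def _midpoint(start: int, end: int) -> float:
    return (start + end) / 2


def _single_finger_arrangement(motif: C2H2Motif, ears: Sequence[EARSite]) -> str:
    fm = _midpoint(motif.start, motif.end)
    sides = ["down" if _midpoint(e.start, e.end) > fm else "up" for e in ears]
    if len(ears) == 0:
        return "not_applicable"
    if len(ears) == 1:
        return "C2H2_then_EAR" if sides[0] == "down" else "EAR_then_C2H2"
    if len(ears) == 2:
        if set(sides) == {"up", "down"}:
            return "C2H2_between_EARs"
        return "EARs_flanking_other"
    return "mixed"


def classify_architecture(
    protein_id: str,
    protein_length: int,
    motifs: Sequence[C2H2Motif],
    ears: Sequence[EARSite],
    tandem_threshold: int = DEFAULT_TANDEM_THRESHOLD,
) -> ZFPAnnotation:
    """Build the full per-protein annotation from scanner output.

    EAR sites overlapping a finger are flagged (``ear_overlaps``) and
    excluded from the arrangement ordering but still counted in
    ``ear_class``.  Multi-finger proteins get an arrangement only when
    every EAR lies strictly to one side of every finger.
    """
    if not motifs:
        raise ValueError(f"{protein_id}: no motifs — not a ZFP")
    motifs = sorted(motifs, key=lambda m: m.start)
    ears = sorted(ears, key=lambda e: e.start)
    n = len(motifs)
    count_class = _COUNT_CLASS.get(n, f"other-{n}")

    overlapped = [
        e for e in ears if any(e.start < m.end and m.start < e.end for m in motifs)
    ]
    clear = [e for e in ears if e not in overlapped]

    arrays = call_tandem_arrays(motifs, tandem_threshold)
    if n == 1:
        array_class = "single_finger"
    else:
        array_class = "has_tandem" if arrays else "no_tandem"

    n_ears = len(ears)
    ear_class = "no_EAR" if n_ears == 0 else ("one_EAR" if n_ears == 1 else "multi_EAR")

    if n == 1:
        arrangement = _single_finger_arrangement(motifs[0], clear)
    else:
        if clear and all(e.start >= motifs[-1].end for e in clear):
            arrangement = "C2H2_then_EAR"
        elif clear and all(e.end <= motifs[0].start for e in clear):
            arrangement = "EAR_then_C2H2"
        else:
            arrangement = "not_applicable"

    return ZFPAnnotation(
        protein_id=protein_id,
        protein_length=protein_length,
        motifs=motifs,
        ears=ears,
        finger_count=n,
        count_class=count_class,
        arrays=arrays,
        array_class=array_class,
        ear_class=ear_class,
        arrangement=arrangement,
        ear_overlaps=overlapped,
    )


@dataclass
class FamilySummary:
    """Family-level tabulation of the annotation classes."""

    total: int
    count_class_counts: dict[str, int]
    single_ear_counts: dict[str, int]
    single_arrangements: dict[str, int]
    multi_tandem: int
    multi_no_tandem: int
    fraction_single: float


def family_summary(annotations: Iterable[ZFPAnnotation]) -> FamilySummary:
    """Tabulate count classes, EAR classes among single-finger proteins,
    and tandem vs non-tandem among multi-finger proteins."""
    anns = list(annotations)
    total = len(anns)
    count_class_counts = Counter(a.count_class for a in anns)
    singles = [a for a in anns if a.finger_count == 1]
    multis = [a for a in anns if a.finger_count > 1]
    return FamilySummary(
        total=total,
        count_class_counts=dict(count_class_counts),
        single_ear_counts=dict(Counter(a.ear_class for a in singles)),
        single_arrangements=dict(Counter(a.arrangement for a in singles)),
        multi_tandem=sum(1 for a in multis if a.array_class == "has_tandem"),
        multi_no_tandem=sum(1 for a in multis if a.array_class == "no_tandem"),
        fraction_single=(len(singles) / total) if total else 0.0,
    )


def render_architecture(annotation: ZFPAnnotation) -> dict:
    """Deterministic diagram description of one protein's architecture.

    Returns a JSON-serializable layout: the protein as a line of its
    length, one rectangle per feature with the conventional colours
    (black = C2H2 finger, red = EAR), features ordered by start then kind.
    Suitable for any plotting layer or SVG writer.
    """
    feats = [
        {"kind": "C2H2", "start": m.start, "end": m.end, "color": "black"}
        for m in annotation.motifs
    ] + [
        {"kind": "EAR", "start": e.start, "end": e.end, "color": "red"}
        for e in annotation.ears
    ]
    feats.sort(key=lambda f: (f["start"], f["kind"]))
    return {
        "protein_id": annotation.protein_id,
        "length": annotation.protein_length,
        "legend": {"C2H2": "black", "EAR": "red"},
        "features": feats,
    }
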