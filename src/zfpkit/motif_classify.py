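"""Typing of C2H2 motifs into the Q / QM / IDD / Z / C scheme.

The classifier works from two short strings the scanner extracts per
finger: ``core6`` — the six residues ending at the first His — and
``inter_his`` — the residues between the two His.  Rules, applied in
precedence order Q -> QM -> IDD -> Z -> C:

Q
    ``core6 == "QALGGH"`` (the plant-specific Q-type core).  Subgroups
    Q1–Q5 are consensus classes of the three inter-His residues
    (QNA / (K|R)AS / MR(R|K) / MN(I|V) / KR(C|S)); anything else, or an
    inter-His gap other than 3, is Q6.
QM
    "Q-modified": 1–2 mismatches (Hamming) from ``QALGG`` over the five
    pre-His core positions.  Subgroup label defaults to the mismatch
    signature (e.g. ``P1:R`` for RALGGH); an override table can be loaded
    from config.
IDD
    the INDETERMINATE-DOMAIN signature: a 23-residue finger starting with
    Phe whose sequence agrees with a reference per-position profile at
    >= ``idd_min_matches`` of 23 positions.
Z
    conserved cores outside the above: matched against a configurable
    core-signature table, or — when no table is supplied — found by
    deterministic single-linkage clustering of full motif strings.
C
    the residual class with no conserved core.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from zfpkit.motif_scan import C2H2Motif

__all__ = [
    "IDDProfile",
    "ClassifierRules",
    "build_idd_profile",
    "classify_motif",
    "classify_all",
    "ClassificationSummary",
    "default_rules",
    "load_rules",
    "DEFAULT_Q_SUBGROUPS",
    "SYNTHETIC_IDD_REFERENCE",
    "SYNTHETIC_Z_CORES",
]

Q_CORE = "QALGGH"

#: Q subgroup consensus classes of the three inter-His residues
DEFAULT_Q_SUBGROUPS: dict[str, frozenset[str]] = {
    "Q1": frozenset({"QNA"}),
    "Q2": frozenset({"KAS", "RAS"}),
    "Q3": frozenset({"MRR", "MRK"}),
    "Q4": frozenset({"MNI", "MNV"}),
    "Q5": frozenset({"KRC", "KRS"}),
}

# Synthetic stand-in reference set for the IDD-type signature.  The real
# signature is built from Arabidopsis INDETERMINATE-DOMAIN zinc fingers;
# absent those sequences this packaged set is a constructed surrogate with
# the same formal properties (23-mer, F at position 1, Cys at 3/6, His at
# 19/23, strong per-position conservation).  Real analyses should pass
# their own reference motifs to :func:`build_idd_profile`.
SYNTHETIC_IDD_REFERENCE: tuple[str, ...] = (
    "FYCELCGKTFSDPSTLRNHIKTH",
    "FYCELCGKGFSDPSTLRNHIKTH",
    "FYCELCGKTFSDQSTLRNHVKTH",
    "FYCEMCGKTFSDPSTLGNHIKSH",
    "FYCELCGKTFTDPSALRNHIKTH",
)

# Synthetic stand-in for the Z-type core-signature table (the study's own
# eight Z subgroups are defined in supplementary material not packaged
# here).  Each core is a core6 value: five conserved residues + the first
# His.  Override via the rules config to match a real table.
SYNTHETIC_Z_CORES: dict[str, frozenset[str]] = {
    "Z1": frozenset({"RKFANH"}),
    "Z2": frozenset({"SSDNVH"}),
    "Z3": frozenset({"TTGEPH"}),
    "Z4": frozenset({"MKNGFH"}),
    "Z5": frozenset({"WRDAEH"}),
    "Z6": frozenset({"IPKSSH"}),
    "Z7": frozenset({"VVEGTH"}),
    "Z8": frozenset({"NNQRFH"}),
}


@dataclass(frozen=True)
class IDDProfile:
    """Per-position consensus over aligned 23-mer reference motifs."""

    consensus: str
    frequencies: tuple[float, ...]
    invariant: tuple[bool, ...]
    n_references: int

    def matches(self, motif_23mer: str) -> int:
        """Number of positions agreeing with the consensus."""
        if len(motif_23mer) != len(self.consensus):
            raise ValueError("motif length differs from profile length")
        return sum(a == b for a, b in zip(motif_23mer, self.consensus))


def build_idd_profile(reference_motifs: Sequence[str]) -> IDDProfile:
    """Build a per-position majority profile from aligned 23-mers.

    Requires >= 2 references of identical length.  Positions where every
    reference agrees are flagged invariant.  Majority ties break
    alphabetically so the profile is deterministic.
    """
    if len(reference_motifs) < 2:
        raise ValueError("need at least two reference motifs")
    lengths = {len(s) for s in reference_motifs}
    if len(lengths) != 1:
        raise ValueError(f"reference motifs have mixed lengths {sorted(lengths)}")
    (length,) = lengths
    consensus = []
    freqs = []
    invariant = []
    n = len(reference_motifs)
    for pos in range(length):
        counts = Counter(s[pos] for s in reference_motifs)
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        consensus.append(best[0])
        freqs.append(best[1] / n)
        invariant.append(best[1] == n)
    return IDDProfile(
        consensus="".join(consensus),
        frequencies=tuple(freqs),
        invariant=tuple(invariant),
        n_references=n,
    )


@dataclass
class ClassifierRules:
    """Tunable rule tables for motif typing (see module docstring)."""

    q_core: str = Q_CORE
    q_subgroups: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_Q_SUBGROUPS)
    )
    qm_max_mismatch: int = 2
    idd_profile: Optional[IDDProfile] = None
    idd_min_matches: int = 16
    idd_require_first_f: bool = True
    z_subgroup_cores: Optional[Mapping[str, frozenset[str]]] = field(
        default_factory=lambda: dict(SYNTHETIC_Z_CORES)
    )
    qm_subgroup_overrides: Mapping[str, str] = field(default_factory=dict)
    z_cluster_min_size: int = 2
    z_cluster_min_identity: float = 0.60

    def __post_init__(self) -> None:
        if self.qm_max_mismatch < 1:
            raise ValueError("qm_max_mismatch must be >= 1")
        if not (0 < self.idd_min_matches <= 23):
            raise ValueError("idd_min_matches must be in 1..23")
        seen: dict[str, str] = {}
        for label, members in self.q_subgroups.items():
            for m in members:
                if m in seen:
                    raise ValueError(f"inter-His {m!r} in both {seen[m]} and {label}")
                seen[m] = label
        if self.idd_profile is None:
            self.idd_profile = build_idd_profile(SYNTHETIC_IDD_REFERENCE)


def default_rules() -> ClassifierRules:
    """The packaged default rule set."""
    return ClassifierRules()


def load_rules(path) -> ClassifierRules:
    """Load a ``classify:`` rules section from a YAML config file.

    Recognized keys mirror the :class:`ClassifierRules` fields;
    ``idd_reference_motifs`` (a list of 23-mers) builds the IDD profile.
    Unspecified keys keep their packaged defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    section = doc.get("classify", doc)
    kwargs = {}
    if "q_core" in section:
        kwargs["q_core"] = section["q_core"]
    if "q_subgroups" in section:
        kwargs["q_subgroups"] = {
            label: frozenset(members) for label, members in section["q_subgroups"].items()
        }
    for key in (
        "qm_max_mismatch",
        "idd_min_matches",
        "idd_require_first_f",
        "z_cluster_min_size",
        "z_cluster_min_identity",
    ):
        if key in section:
            kwargs[key] = section[key]
    if "idd_reference_motifs" in section:
        kwargs["idd_profile"] = build_idd_profile(section["idd_reference_motifs"])
    if "z_subgroup_cores" in section:
        kwargs["z_subgroup_cores"] = {
            label: frozenset(members)
            for label, members in section["z_subgroup_cores"].items()
        }
    if "qm_subgroup_overrides" in section:
        kwargs["qm_subgroup_overrides"] = dict(section["qm_subgroup_overrides"])
    return ClassifierRules(**kwargs)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _qm_signature(core6: str, q_core: str) -> str:
    """Mismatch signature over the five pre-His positions, e.g. 'P1:R'."""
    parts = [
        f"P{i + 1}:{core6[i]}" for i in range(5) if core6[i] != q_core[i]
    ]
    return "+".join(parts)


def classify_motif(motif: C2H2Motif, rules: ClassifierRules) -> C2H2Motif:
    """Assign ``mtype`` (and subgroup) to one motif; Z clustering excluded.

    The Z similarity-clustering fallback needs the whole motif set, so this
    single-motif entry point applies the core-table Z rule only; use
    :func:`classify_all` for the fallback path.
    """
    if motif.length < 23:
        raise RuntimeError("motif shorter than 23 violates the scanner invariant")
    core6 = motif.core6
    # Q: exact core
    if core6 == rules.q_core:
        subgroup = "Q6"
        if motif.his_gap == 3:
            for label, members in rules.q_subgroups.items():
                if motif.inter_his in members:
                    subgroup = label
                    break
        return replace(motif, mtype="Q", subgroup=subgroup)
    # QM: 1..max mismatches on the five pre-His positions
    if _hamming(core6[:5], rules.q_core[:5]) <= rules.qm_max_mismatch:
        sig = _qm_signature(core6, rules.q_core)
        subgroup = rules.qm_subgroup_overrides.get(sig, sig)
        return replace(motif, mtype="QM", subgroup=subgroup)
    # IDD: 23-mer starting with F, close to the reference profile
    if motif.length == 23 and (not rules.idd_require_first_f or motif.sequence[0] == "F"):
        if rules.idd_profile.matches(motif.sequence) >= rules.idd_min_matches:
            return replace(motif, mtype="IDD", subgroup="")
    # Z by core table (clustering fallback lives in classify_all)
    if rules.z_subgroup_cores:
        for label, cores in rules.z_subgroup_cores.items():
            if core6 in cores:
                return replace(motif, mtype="Z", subgroup=label)
        return replace(motif, mtype="C", subgroup="")
    return replace(motif, mtype="C", subgroup="")


def _pair_identity(a: str, b: str) -> float:
    """Fractional identity of two motif strings.

    Equal lengths compare position-wise; unequal lengths fall back to
    1 - edit_distance/max_len (motifs are <= 27 residues, so the small DP
    is cheap).
    """
    if len(a) == len(b):
        return sum(x == y for x, y in zip(a, b)) / len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return 1.0 - prev[-1] / max(len(a), len(b))


def _z_fallback_clusters(
    motifs: Sequence[C2H2Motif], rules: ClassifierRules
) -> dict[int, str]:
    """Single-linkage clusters over unassigned motifs; returns index -> label.

    Deterministic: union-find over all pairs at >= min identity; clusters of
    size >= min_size become Z, labelled ZC1, ZC2, ... ordered by smallest
    member protein id (ties: smallest start).
    """
    n = len(motifs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _pair_identity(motifs[i].sequence, motifs[j].sequence) >= rules.z_cluster_min_identity:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    clusters = [
        sorted(idx) for idx in groups.values() if len(idx) >= rules.z_cluster_min_size
    ]
    clusters.sort(key=lambda idx: min((motifs[i].protein_id, motifs[i].start) for i in idx))
    labels: dict[int, str] = {}
    for k, idx in enumerate(clusters, 1):
        for i in idx:
            labels[i] = f"ZC{k}"
    return labels


@dataclass
class ClassificationSummary:
    """Counts per type/subgroup plus per-type distinct-gene counts."""

    type_counts: dict[str, int]
    subgroup_counts: dict[str, dict[str, int]]
    gene_counts: dict[str, int]
    total: int

    def to_rows(self) -> list[tuple[str, str, int, int]]:
        """(type, subgroup, motif count, distinct genes) rows, stable order."""
        rows = []
        for mtype in ("Q", "QM", "IDD", "Z", "C"):
            rows.append((mtype, "*", self.type_counts.get(mtype, 0), self.gene_counts.get(mtype, 0)))
            for sub in sorted(self.subgroup_counts.get(mtype, {})):
                rows.append((mtype, sub, self.subgroup_counts[mtype][sub], -1))
        return rows


def classify_all(
    motifs: Iterable[C2H2Motif],
    rules: Optional[ClassifierRules] = None,
    gene_of: Optional[Mapping[str, str]] = None,
) -> tuple[list[C2H2Motif], ClassificationSummary]:
    """Classify every motif and tabulate the partition.

    ``gene_of`` optionally maps protein ids to gene ids for the distinct-
    gene counts (defaults to the protein id itself).  When the rules carry
    no Z core table, unassigned motifs are clustered (single linkage on
    full-string identity) and clusters of sufficient size become Z.
    """
    rules = rules or default_rules()
    motifs = list(motifs)
    typed = [classify_motif(m, rules) for m in motifs]
    if not rules.z_subgroup_cores:
        candidates = [i for i, m in enumerate(typed) if m.mtype == "C"]
        labels = _z_fallback_clusters([typed[i] for i in candidates], rules)
        for local_idx, label in labels.items():
            i = candidates[local_idx]
            typed[i] = replace(typed[i], mtype="Z", subgroup=label)
    type_counts: dict[str, int] = Counter(m.mtype for m in typed)
    subgroup_counts: dict[str, dict[str, int]] = defaultdict(Counter)
    genes: dict[str, set] = defaultdict(set)
    for m in typed:
        if m.subgroup:
            subgroup_counts[m.mtype][m.subgroup] += 1
        gene = gene_of.get(m.protein_id, m.protein_id) if gene_of else m.protein_id
        genes[m.mtype].add(gene)
    summary = ClassificationSummary(
        type_counts=dict(type_counts),
        subgroup_counts={k: dict(v) for k, v in subgroup_counts.items()},
        gene_counts={k: len(v) for k, v in genes.items()},
        total=len(typed),
    )
    return typed, summary
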