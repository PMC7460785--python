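"""Synthetic proteomes, gene orders and expression matrices with planted truth.

The generator emulates the conditions of a genome-wide C2H2
zinc-finger survey in a model legume genome: a proteome in which 272 candidate
proteins match the C2H2 regex (55 of them destined to fail external
confirmation, leaving 217), a separately supplied nine-finger TFIIIA
record that brings the confirmed family to 218 proteins / 337 motifs,
a representative motif-type composition (93 Q in subgroups Q1-Q6, 57 QM,
19 IDD, 41 Z in eight subgroups, 127 C), the finger-count distribution
(151 single, 38 double, 16 triple, 9 quadruple, one five-finger TRM1,
two six-finger, one nine-finger TFIIIA), the single-finger EAR layout
(74 none / 59 finger-then-EAR / 1 EAR-then-finger / 9 finger between two
EARs / 7 two EARs one side / 1 three EARs), tandem arrays with the
described linkers, a chromosome layout with 46 planted local-duplication
clusters of two to six genes (59 family genes on chr1), and an
expression atlas with three well-separated abundance tiers and 14
nodule-induced genes.

Cleanliness guarantee: decoy sequences, flanks and linkers are drawn
from an alphabet excluding C, H and L, and motif-internal wildcard
positions exclude C/H/L too, so the planted fingers and EAR sites are
provably the only pattern matches — scanning recovers the truth tables
exactly.  Every constructed finger is verified against the scanner and
classifier before acceptance (resampled up to a bound, then an error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from zfpkit.seq_io import GeneOrderIndex, ProteinRecord
from zfpkit.motif_scan import scan_c2h2, scan_ear
from zfpkit.motif_classify import ClassifierRules, default_rules

__all__ = [
    "MotifPlanEntry",
    "SyntheticSpec",
    "ProteomeTruth",
    "generate_proteome",
    "generate_gene_order",
    "generate_expression",
    "medicago_like_spec",
    "write_truth_fasta",
]

#: wildcard alphabet for flanks/linkers/motif X positions: no C, H or L,
#: so structural residues and planted EAR leucines are the only ones.
CLEAN_ALPHABET = "ADEFGIKMNPQRSTVWY"

_RESAMPLE_BOUND = 100


@dataclass(frozen=True)
class MotifPlanEntry:
    """One planted-motif class: type, subgroup, spacer geometry, count."""

    mtype: str
    subgroup: str = ""
    cys_gap: int = 2
    his_gap: int = 3
    core: Optional[str] = None  # core6 for QM/Z plants
    count: int = 1


def _default_motif_plan() -> list[MotifPlanEntry]:
    plan = [
        MotifPlanEntry("Q", "Q1", count=28),
        MotifPlanEntry("Q", "Q2", count=22),
        MotifPlanEntry("Q", "Q3", count=12),
        MotifPlanEntry("Q", "Q4", count=10),
        MotifPlanEntry("Q", "Q5", count=10),
        MotifPlanEntry("Q", "Q6", count=6),
        MotifPlanEntry("Q", "Q6", his_gap=4, count=3),
        MotifPlanEntry("Q", "Q6", his_gap=5, count=2),
    ]
    qm_cores = [
        ("RALGGH", 12), ("QGLGGH", 10), ("KALGGH", 8), ("QALEGH", 7),
        ("QTLGGH", 6), ("QASGGH", 5), ("RGLGGH", 4), ("QAMGAH", 3), ("TALGAH", 2),
    ]
    plan += [MotifPlanEntry("QM", core=c, count=n) for c, n in qm_cores]
    plan.append(MotifPlanEntry("IDD", count=19))
    z_sizes = {"Z1": 15, "Z2": 8, "Z3": 5, "Z4": 4, "Z5": 3, "Z6": 2, "Z7": 2, "Z8": 2}
    plan += [MotifPlanEntry("Z", sub, count=n) for sub, n in z_sizes.items()]
    # 127 C-type total; 14 are reserved for TFIIIA (9) and TRM1 (5)
    plan += [
        MotifPlanEntry("C", count=104),
        MotifPlanEntry("C", cys_gap=4, count=10),
        MotifPlanEntry("C", his_gap=4, count=6),
        MotifPlanEntry("C", his_gap=5, count=4),
        MotifPlanEntry("C", cys_gap=4, his_gap=4, count=3),
    ]
    return plan


def _default_array_plan() -> dict[int, list[tuple[int, ...]]]:
    # linker tuples for the proteins of each finger-count class that carry
    # tandem arrays; remaining proteins of the class get linkers >= 11
    return {
        2: [(0,), (5,), (10,)],
        3: [(10, 10), (10, 40)],
        4: [(10, 9, 65), (10, 9, 65), (10, 9, 65), (4, 6, 8), (2, 5, 7), (0, 3, 9)],
        6: [(1, 3, 5, 7, 9), (2, 4, 6, 8, 10)],
    }


@dataclass
class SyntheticSpec:
    """Generator configuration; the defaults define the reference scenario."""

    seed: int = 0
    motif_plan: list[MotifPlanEntry] = field(default_factory=_default_motif_plan)
    finger_count_plan: dict[int, int] = field(
        default_factory=lambda: {1: 151, 2: 38, 3: 16, 4: 9, 5: 1, 6: 2, 9: 1}
    )
    single_ear_plan: dict[str, int] = field(
        default_factory=lambda: {
            "none": 74,
            "one_downstream": 59,
            "one_upstream": 1,
            "two_between": 9,
            "two_same_side": 7,
            "three": 1,
        }
    )
    array_plan: dict[int, list[tuple[int, ...]]] = field(default_factory=_default_array_plan)
    include_tfiiia: bool = True
    include_trm1: bool = True
    tfiiia_linkers: tuple[int, ...] = (25, 7, 8, 30, 5, 6, 7, 8)
    trm1_linkers: tuple[int, ...] = (29, 30, 29, 65)
    n_false_candidates: int = 55
    n_decoys: int = 216
    n_variant_genes: int = 12
    decoy_length: tuple[int, int] = (80, 400)
    flank_alphabet: str = CLEAN_ALPHABET
    guarantee_clean: bool = True
    loose_linker: tuple[int, int] = (15, 60)
    # gene order
    chromosome_family_counts: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 59, "chr2": 25, "chr3": 24, "chr4": 35,
            "chr5": 22, "chr6": 3, "chr7": 36, "chr8": 14,
        }
    )
    cluster_sizes: list[int] = field(
        default_factory=lambda: [6, 5, 4, 4] + [3] * 4 + [2] * 38
    )
    duplication_window: int = 100
    # expression
    tissues: list[str] = field(
        default_factory=lambda: [
            "root", "stem", "leaf", "petiole", "flower", "pod", "seed", "nodule",
        ]
    )
    n_mapped_genes: int = 119
    tier_log2_means: tuple[float, float, float] = (2.0, 6.0, 10.0)
    tier_log2_sd: float = 0.4
    noise_log2_sd: float = 0.2
    induced_tissue: str = "nodule"
    induced_folds: list[float] = field(
        default_factory=lambda: [32, 24, 20, 16, 14, 12, 11, 10, 9, 8, 8, 7, 6, 6]
    )

    def __post_init__(self) -> None:
        if self.guarantee_clean:
            forbidden = set("CHL") & set(self.flank_alphabet)
            if forbidden:
                raise ValueError(
                    f"clean flank alphabet must exclude {sorted(forbidden)}"
                )
        for entry in self.motif_plan:
            if entry.count < 0:
                raise ValueError("motif counts must be >= 0")


def medicago_like_spec(seed: int = 0) -> SyntheticSpec:
    """The default reference scenario (see module docstring)."""
    return SyntheticSpec(seed=seed)


@dataclass
class ProteomeTruth:
    """Generated records plus the planted ground truth."""

    records: list[ProteinRecord]  # candidate proteome: family + false + variants + decoys
    tfiiia: Optional[ProteinRecord]
    motifs: pd.DataFrame  # protein_id,start,end,cys_gap,his_gap,mtype,subgroup,record_set
    ears: pd.DataFrame  # protein_id,start,end,pattern,record_set
    keep_drop: dict[str, str]
    family_ids: list[str]  # confirmed candidates (TFIIIA excluded)
    seed: int

    @property
    def all_family_ids(self) -> list[str]:
        ids = list(self.family_ids)
        if self.tfiiia is not None:
            ids.append(self.tfiiia.id)
        return ids


def _rand_res(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


_Q_INTER = {
    "Q1": ("QNA",),
    "Q2": ("KAS", "RAS"),
    "Q3": ("MRR", "MRK"),
    "Q4": ("MNI", "MNV"),
    "Q5": ("KRS",),  # the Cys variant of KR(C/S) would break the clean alphabet
}

_Z_CORE5 = {
    "Z1": "RKFAN", "Z2": "SSDNV", "Z3": "TTGEP", "Z4": "MKNGF",
    "Z5": "WRDAE", "Z6": "IPKSS", "Z7": "VVEGT", "Z8": "NNQRF",
}


def _build_finger(
    rng: np.random.Generator,
    entry: MotifPlanEntry,
    alphabet: str,
    rules: ClassifierRules,
    embed_ear: bool = False,
) -> tuple[str, Optional[int]]:
    """Construct one finger string for a plan entry; returns (string, ear_rel).

    ``ear_rel`` is the in-motif offset of an embedded LxLxL site when
    ``embed_ear`` is set (the TRM1 fifth-finger construction).
    """
    cg, hg = entry.cys_gap, entry.his_gap
    if entry.mtype == "IDD":
        base = list(rules.idd_profile.consensus)
        structural = {0, 2, 5, 18, 22}
        mutable = [i for i in range(23) if i not in structural]
        n_mut = int(rng.integers(0, 6))
        for pos in rng.choice(mutable, size=n_mut, replace=False):
            choices = [a for a in alphabet if a != base[pos]]
            base[pos] = choices[int(rng.integers(0, len(choices)))]
        return "".join(base), None
    # core5 (the five residues before the first His)
    if entry.mtype == "Q":
        core5 = rules.q_core[:5]
    elif entry.mtype in ("QM", "Z") and entry.core:
        core5 = entry.core[:5]
    elif entry.mtype == "Z":
        core5 = _Z_CORE5[entry.subgroup]
    else:  # C-type: random, validated against all other rules afterwards
        core5 = _rand_res(rng, alphabet, 5)
    # inter-His segment
    if entry.mtype == "Q" and entry.subgroup in _Q_INTER and hg == 3:
        options = _Q_INTER[entry.subgroup]
        inter = options[int(rng.integers(0, len(options)))]
    else:
        inter = _rand_res(rng, alphabet, hg)
    ear_rel = None
    if embed_ear:
        # 12-residue gap = rr + LKLHLK + rrrr; the extra H is harmless
        # (it can anchor no alternative window) and LKLHL is a real EAR
        gap12 = _rand_res(rng, alphabet, 2) + "LKLHLK" + _rand_res(rng, alphabet, 4)
        ear_rel = 3 + cg + 1 + 2  # offset of the embedded L within the finger
    else:
        gap12 = _rand_res(rng, alphabet, 7) + core5
    finger = (
        _rand_res(rng, alphabet, 2)
        + "C"
        + _rand_res(rng, alphabet, cg)
        + "C"
        + gap12
        + "H"
        + inter
        + "H"
    )
    return finger, ear_rel


def _finger_ok(finger: str, entry: MotifPlanEntry, rules: ClassifierRules, relaxed: bool) -> bool:
    """Verify a constructed finger against the scanner and classifier."""
    from zfpkit.motif_classify import classify_motif

    rec = ProteinRecord(id="_tmp", sequence=finger)
    found = scan_c2h2(rec, mode="exhaustive")
    if len(found) != 1:
        return False
    m = found[0]
    if m.start != 0 or m.cys_gap != entry.cys_gap or m.his_gap != entry.his_gap:
        return False
    typed = classify_motif(m, rules)
    if typed.mtype != entry.mtype:
        return False
    if not relaxed and entry.subgroup and typed.subgroup != entry.subgroup:
        return False
    # no accidental EAR sites besides a deliberately embedded one
    n_ears = len(scan_ear(rec))
    return n_ears == (1 if "LKLHL" in finger else 0)


def _make_finger(
    rng: np.random.Generator,
    entry: MotifPlanEntry,
    alphabet: str,
    rules: ClassifierRules,
    embed_ear: bool = False,
) -> tuple[str, Optional[int]]:
    for _ in range(_RESAMPLE_BOUND):
        finger, ear_rel = _build_finger(rng, entry, alphabet, rules, embed_ear)
        if _finger_ok(finger, entry, rules, relaxed=embed_ear):
            return finger, ear_rel
    raise RuntimeError(
        f"could not construct a {entry.mtype}/{entry.subgroup or '-'} finger "
        f"satisfying its classification rule in {_RESAMPLE_BOUND} attempts"
    )


def _ear_instance(rng: np.random.Generator, alphabet: str) -> str:
    # D/N are excluded from the wildcard slots: with flanks L-free, any
    # DLNxxP match would need an EAR leucine plus an adjacent D/N, so this
    # keeps planted LxLxL sites from spawning accidental DLNxxP overlaps
    choices = [a for a in alphabet if a not in "DN"]
    x1 = choices[int(rng.integers(0, len(choices)))]
    x2 = choices[int(rng.integers(0, len(choices)))]
    return f"L{x1}L{x2}L"


_EAR_LAYOUT = {
    "none": (0, 0),
    "one_downstream": (0, 1),
    "one_upstream": (1, 0),
    "two_between": (1, 1),
    "two_same_side": (0, 2),
    "three": (1, 2),
}


def _assemble_protein(
    rng: np.random.Generator,
    pid: str,
    fingers: Sequence[tuple[str, MotifPlanEntry, Optional[int]]],
    linkers: Sequence[int],
    ear_layout: str,
    alphabet: str,
) -> tuple[str, list[dict], list[dict]]:
    """Concatenate flanks, fingers, linkers and EAR sites into one protein."""
    n_up, n_down = _EAR_LAYOUT[ear_layout]
    n_term = int(rng.integers(14, 61))
    c_term = int(rng.integers(45 if n_down == 2 else 25, 121))
    ears: list[dict] = []

    head = list(_rand_res(rng, alphabet, n_term))
    if n_up:
        p = int(rng.integers(2, n_term - 7))
        head[p : p + 5] = _ear_instance(rng, alphabet)
        ears.append({"start": p, "end": p + 5, "pattern": "LxLxL"})

    body = []
    motifs: list[dict] = []
    cur = n_term
    for i, (finger, entry, ear_rel) in enumerate(fingers):
        motifs.append(
            {
                "start": cur,
                "end": cur + len(finger),
                "cys_gap": entry.cys_gap,
                "his_gap": entry.his_gap,
                "mtype": entry.mtype,
                "subgroup": entry.subgroup,
            }
        )
        if ear_rel is not None:
            ears.append({"start": cur + ear_rel, "end": cur + ear_rel + 5, "pattern": "LxLxL"})
        body.append(finger)
        cur += len(finger)
        if i < len(fingers) - 1:
            body.append(_rand_res(rng, alphabet, linkers[i]))
            cur += linkers[i]

    tail = list(_rand_res(rng, alphabet, c_term))
    if n_down == 1:
        q = int(rng.integers(max(2, c_term - 25), c_term - 6))
        tail[q : q + 5] = _ear_instance(rng, alphabet)
        ears.append({"start": cur + q, "end": cur + q + 5, "pattern": "LxLxL"})
    elif n_down == 2:
        q1 = int(rng.integers(2, c_term // 2 - 7))
        q2 = int(rng.integers(c_term // 2 + 2, c_term - 6))
        for q in (q1, q2):
            tail[q : q + 5] = _ear_instance(rng, alphabet)
            ears.append({"start": cur + q, "end": cur + q + 5, "pattern": "LxLxL"})

    sequence = "".join(head) + "".join(body) + "".join(tail)
    for m in motifs:
        m["protein_id"] = pid
    for e in ears:
        e["protein_id"] = pid
    ears.sort(key=lambda e: e["start"])
    return sequence, motifs, ears


def generate_proteome(spec: SyntheticSpec) -> ProteomeTruth:
    """Generate the candidate proteome and its planted truth tables.

    The returned ``records`` list is the scan input (confirmed family,
    false candidates, splice variants, decoys); the TFIIIA record — when
    enabled — is returned separately, mirroring a family member recovered
    outside the annotated proteome and appended after confirmation.
    """
    rng = np.random.default_rng([spec.seed, 1])
    rules = default_rules()
    alphabet = spec.flank_alphabet

    # expand the motif plan into individual entries
    pool: list[MotifPlanEntry] = []
    for entry in spec.motif_plan:
        pool += [
            MotifPlanEntry(entry.mtype, entry.subgroup, entry.cys_gap, entry.his_gap, entry.core)
            for _ in range(entry.count)
        ]

    # reserve C-type entries for the special records
    n_reserved = (9 if spec.include_tfiiia else 0) + (5 if spec.include_trm1 else 0)
    c_indices = [i for i, e in enumerate(pool) if e.mtype == "C"]
    if len(c_indices) < n_reserved:
        raise ValueError("motif plan has too few C-type motifs for TFIIIA/TRM1")
    reserved = [pool[i] for i in c_indices[:n_reserved]]
    pool = [e for i, e in enumerate(pool) if i not in set(c_indices[:n_reserved])]
    rng.shuffle(pool)  # type: ignore[arg-type]

    # build the list of regular protein definitions (finger counts)
    finger_counts: list[int] = []
    for n in sorted(spec.finger_count_plan):
        count = spec.finger_count_plan[n]
        if spec.include_trm1 and n == 5:
            count -= 1
        if spec.include_tfiiia and n == 9:
            count -= 1
        finger_counts += [n] * count
    if sum(finger_counts) != len(pool):
        raise ValueError(
            f"motif plan ({len(pool)} unreserved motifs) does not match the "
            f"finger-count plan ({sum(finger_counts)} finger slots)"
        )

    # EAR layouts for single-finger proteins
    layouts: list[str] = []
    for name, count in spec.single_ear_plan.items():
        layouts += [name] * count
    if len(layouts) != finger_counts.count(1):
        raise ValueError("single-finger EAR plan does not match the single-finger count")
    rng.shuffle(layouts)  # type: ignore[arg-type]

    # linker assignment per finger-count class
    class_seen: dict[int, int] = {}
    lo, hi = spec.loose_linker

    def _linkers_for(n: int) -> tuple[int, ...]:
        k = class_seen.get(n, 0)
        class_seen[n] = k + 1
        planned = spec.array_plan.get(n, [])
        if k < len(planned):
            return tuple(planned[k])
        return tuple(int(rng.integers(lo, hi + 1)) for _ in range(n - 1))

    records: list[ProteinRecord] = []
    motif_rows: list[dict] = []
    ear_rows: list[dict] = []
    keep_drop: dict[str, str] = {}
    family_ids: list[str] = []

    pool_iter = iter(pool)
    single_iter = iter(layouts)
    for idx, n in enumerate(finger_counts, 1):
        pid = f"ZFP{idx:03d}"
        entries = [next(pool_iter) for _ in range(n)]
        fingers = []
        for e in entries:
            f, rel = _make_finger(rng, e, alphabet, rules)
            fingers.append((f, e, rel))
        layout = next(single_iter) if n == 1 else "none"
        linkers = _linkers_for(n) if n > 1 else ()
        seq, motifs, ears = _assemble_protein(rng, pid, fingers, linkers, layout, alphabet)
        records.append(ProteinRecord(id=pid, sequence=seq))
        for m in motifs:
            m["record_set"] = "candidate"
        for e in ears:
            e["record_set"] = "candidate"
        motif_rows += motifs
        ear_rows += ears
        keep_drop[pid] = "keep"
        family_ids.append(pid)

    # TRM1: five C-type fingers, linkers as described, LKLHLK inside finger 5
    if spec.include_trm1:
        entries = reserved[:5]
        reserved = reserved[5:]
        fingers = []
        for i, e in enumerate(entries):
            f, rel = _make_finger(rng, e, alphabet, rules, embed_ear=(i == 4))
            fingers.append((f, e, rel))
        seq, motifs, ears = _assemble_protein(
            rng, "TRM1", fingers, spec.trm1_linkers, "none", alphabet
        )
        records.append(ProteinRecord(id="TRM1", sequence=seq))
        for m in motifs:
            m["record_set"] = "candidate"
        for e in ears:
            e["record_set"] = "candidate"
        motif_rows += motifs
        ear_rows += ears
        keep_drop["TRM1"] = "keep"
        family_ids.append("TRM1")

    # TFIIIA: nine C-type fingers, first isolated, arrays 2-4 and 5-9;
    # returned separately (it is appended after confirmation, not scanned
    # out of the candidate proteome)
    tfiiia = None
    if spec.include_tfiiia:
        entries = reserved[:9]
        fingers = []
        for e in entries:
            f, rel = _make_finger(rng, e, alphabet, rules)
            fingers.append((f, e, rel))
        seq, motifs, ears = _assemble_protein(
            rng, "TFIIIA", fingers, spec.tfiiia_linkers, "none", alphabet
        )
        tfiiia = ProteinRecord(id="TFIIIA", sequence=seq)
        for m in motifs:
            m["record_set"] = "tfiiia"
        for e in ears:
            e["record_set"] = "tfiiia"
        motif_rows += motifs
        ear_rows += ears

    # false candidates: real pattern matches that fail external confirmation
    fp_entry = MotifPlanEntry("C")
    for i in range(1, spec.n_false_candidates + 1):
        pid = f"FPC{i:03d}"
        f, _ = _make_finger(rng, fp_entry, alphabet, rules)
        seq, motifs, ears = _assemble_protein(
            rng, pid, [(f, fp_entry, None)], (), "none", alphabet
        )
        records.append(ProteinRecord(id=pid, sequence=seq))
        for m in motifs:
            m["record_set"] = "false_candidate"
        motif_rows += motifs
        keep_drop[pid] = "drop"

    # splice variants: truncated extra records collapsed away per-gene
    for pid in family_ids[: spec.n_variant_genes]:
        base = next(r for r in records if r.id == pid)
        cut = max(30, len(base.sequence) - 30)
        records.append(
            ProteinRecord(id=f"{pid}.2", sequence=base.sequence[:cut], variant_of=pid)
        )

    # motif-free decoys
    lo_d, hi_d = spec.decoy_length
    for i in range(1, spec.n_decoys + 1):
        length = int(rng.integers(lo_d, hi_d + 1))
        records.append(ProteinRecord(id=f"DECOY{i:04d}", sequence=_rand_res(rng, alphabet, length)))

    motifs_df = pd.DataFrame(
        motif_rows,
        columns=["protein_id", "start", "end", "cys_gap", "his_gap", "mtype", "subgroup", "record_set"],
    )
    ears_df = pd.DataFrame(
        ear_rows, columns=["protein_id", "start", "end", "pattern", "record_set"]
    )
    return ProteomeTruth(
        records=records,
        tfiiia=tfiiia,
        motifs=motifs_df,
        ears=ears_df,
        keep_drop=keep_drop,
        family_ids=family_ids,
        seed=spec.seed,
    )


def write_truth_fasta(truth: ProteomeTruth, path) -> None:
    """Write the candidate proteome (not TFIIIA) as FASTA, seed in headers."""
    with open(path, "w") as fh:
        for rec in truth.records:
            fh.write(f">{rec.id} synthetic seed={truth.seed}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def generate_gene_order(
    spec: SyntheticSpec, family_ids: Sequence[str]
) -> tuple[GeneOrderIndex, pd.DataFrame, list[tuple[str, tuple[str, ...]]]]:
    """Lay the family out on chromosomes with planted duplication clusters.

    Family genes are split across chromosomes per the configured counts;
    cluster members sit 1-3 gene models apart, and every cluster or
    singleton is separated from its neighbours by more than the
    duplication window of decoy gene models, so exactly the planted
    clusters are recoverable.  Returns (index, gene-order table, truth
    clusters).
    """
    rng = np.random.default_rng([spec.seed, 2])
    family = list(family_ids)
    counts = dict(spec.chromosome_family_counts)
    if sum(counts.values()) != len(family):
        raise ValueError(
            f"chromosome family counts sum to {sum(counts.values())}, "
            f"but there are {len(family)} family genes"
        )
    rng.shuffle(family)  # type: ignore[arg-type]
    per_chrom: dict[str, list[str]] = {}
    pos = 0
    for chrom in sorted(counts):
        per_chrom[chrom] = family[pos : pos + counts[chrom]]
        pos += counts[chrom]

    # place clusters on the chromosome with the most unclustered genes left
    remaining = {c: len(g) for c, g in per_chrom.items()}
    cluster_sizes = sorted(spec.cluster_sizes, reverse=True)
    chrom_clusters: dict[str, list[int]] = {c: [] for c in per_chrom}
    for size in cluster_sizes:
        if size < 2:
            raise ValueError("cluster sizes must be >= 2")
        chrom = max(remaining, key=lambda c: (remaining[c], c))
        if remaining[chrom] < size:
            raise ValueError("cluster plan exceeds the family genes available")
        chrom_clusters[chrom].append(size)
        remaining[chrom] -= size

    rows: list[tuple[str, str, int]] = []
    truth: list[tuple[str, tuple[str, ...]]] = []
    decoy_counter = 0
    window = spec.duplication_window
    for chrom in sorted(per_chrom):
        genes = list(per_chrom[chrom])
        items: list[tuple[str, ...]] = []
        for size in chrom_clusters[chrom]:
            items.append(tuple(genes[:size]))
            genes = genes[size:]
        items += [(g,) for g in genes]
        order = rng.permutation(len(items))
        bp = 1000
        for item_idx in order:
            item = items[item_idx]
            # separating decoy run, longer than the window
            for _ in range(window + 1 + int(rng.integers(0, 40))):
                decoy_counter += 1
                rows.append((f"GENE{decoy_counter:05d}", chrom, bp))
                bp += 2000
            placed = []
            for j, gene in enumerate(item):
                rows.append((gene, chrom, bp))
                placed.append(gene)
                bp += 2000
                if j < len(item) - 1:
                    for _ in range(int(rng.integers(0, 3))):  # 0-2 decoys inside
                        decoy_counter += 1
                        rows.append((f"GENE{decoy_counter:05d}", chrom, bp))
                        bp += 2000
            if len(item) >= 2:
                truth.append((chrom, tuple(placed)))
    truth.sort()
    table = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start"])
    index = GeneOrderIndex.from_rows(rows)
    return index, table, truth


def generate_expression(
    spec: SyntheticSpec, family_ids: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, str], dict[str, str], dict[str, float]]:
    """Probeset x tissue abundance matrix with planted tiers and inductions.

    Returns ``(matrix, probeset->gene map, truth tiers, truth induced)``.
    Tier truth is assigned by ranking the noise-free expected mean log2
    abundance (induction included) into equal thirds, so recovery errors
    reflect measurement noise only.
    """
    rng = np.random.default_rng([spec.seed, 3])
    if spec.n_mapped_genes > len(family_ids):
        raise ValueError("more mapped genes requested than family genes exist")
    mapped = sorted(
        str(g) for g in rng.choice(list(family_ids), size=spec.n_mapped_genes, replace=False)
    )
    mus = spec.tier_log2_means
    if min(np.diff(mus)) < 4 * spec.tier_log2_sd:
        warnings.warn("tier mean separation below 4 sd: tiers may overlap")
    order = rng.permutation(len(mapped))
    groups = np.array_split(order, 3)
    gene_mu: dict[str, float] = {}
    for tier_idx, group in enumerate(groups):
        for gi in group:
            gene_mu[mapped[gi]] = float(rng.normal(mus[tier_idx], spec.tier_log2_sd))

    induced_genes = sorted(
        str(g) for g in rng.choice(mapped, size=len(spec.induced_folds), replace=False)
    )
    truth_induced = dict(zip(induced_genes, sorted(spec.induced_folds, reverse=True)))

    tissues = list(spec.tissues)
    if spec.induced_tissue not in tissues:
        raise ValueError(f"induced tissue {spec.induced_tissue!r} not among tissues")
    values = {}
    for gene in mapped:
        log2v = gene_mu[gene] + rng.normal(0.0, spec.noise_log2_sd, size=len(tissues))
        raw = np.power(2.0, log2v)
        if gene in truth_induced:
            raw[tissues.index(spec.induced_tissue)] *= truth_induced[gene]
        values[gene] = raw

    # expected mean log2 (noise-free), induction included -> tier truth
    expected = {
        gene: gene_mu[gene]
        + (np.log2(truth_induced[gene]) / len(tissues) if gene in truth_induced else 0.0)
        for gene in mapped
    }
    ranked = sorted(mapped, key=lambda g: (expected[g], g))
    names = ("low", "medium", "high")
    truth_tiers: dict[str, str] = {}
    for tier_idx, chunk in enumerate(np.array_split(np.arange(len(ranked)), 3)):
        for i in chunk:
            truth_tiers[ranked[i]] = names[tier_idx]

    probe_rows = {}
    gene_map: dict[str, str] = {}
    for i, gene in enumerate(mapped, 1):
        probeset = f"Mtr.{i:05d}.1.S1_at"
        probe_rows[probeset] = values[gene]
        gene_map[probeset] = gene
    # a handful of genes get a second probeset (same signal, fresh noise)
    for i, gene in enumerate(mapped[:5], 1):
        probeset = f"Mtr.{i:05d}.2.S1_s_at"
        log2v = gene_mu[gene] + rng.normal(0.0, spec.noise_log2_sd, size=len(tissues))
        raw = np.power(2.0, log2v)
        if gene in truth_induced:
            raw[tissues.index(spec.induced_tissue)] *= truth_induced[gene]
        probe_rows[probeset] = raw
        gene_map[probeset] = gene
    matrix = pd.DataFrame.from_dict(probe_rows, orient="index", columns=tissues).sort_index()
    matrix.index.name = "probeset"
    return matrix, gene_map, truth_tiers, truth_induced
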