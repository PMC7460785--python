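"""Chromosomal distribution and local gene-duplication detection.

Local duplication is called on gene order alone: family genes on one
chromosome whose consecutive members lie within a fixed window of
adjacent gene models (default 100) are chained transitively into
clusters, so a cluster may span more than one window end to end.
Whole-genome-duplication pairs are not detected here — synteny scanning
is a separate tool's job — but externally computed pair lists are
ingested and checked for motif-architecture concordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from zfpkit.seq_io import GeneOrderIndex
from zfpkit.family_annotate import ZFPAnnotation

__all__ = [
    "DuplicationCluster",
    "WGDPair",
    "find_local_duplications",
    "chromosome_distribution",
    "plot_coordinates",
    "load_wgd_pairs",
    "DEFAULT_DUPLICATION_WINDOW",
]

DEFAULT_DUPLICATION_WINDOW = 100


@dataclass(frozen=True)
class DuplicationCluster:
    """A run of family genes within bounded gene-order gaps on one chromosome."""

    chromosome: str
    members: tuple[str, ...]  # gene ids ordered by rank
    rank_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a duplication cluster needs >= 2 members")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class WGDPair:
    """One whole-genome-duplication paralog pair (ingested, not detected)."""

    gene_a: str
    gene_b: str
    source: str = ""
    concordant: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a WGD pair needs two distinct genes")


def find_local_duplications(
    index: GeneOrderIndex,
    family_ids: Iterable[str],
    window: int = DEFAULT_DUPLICATION_WINDOW,
) -> list[DuplicationCluster]:
    """Chain family genes whose consecutive rank gaps are <= ``window``.

    Maximal chains of size >= 2 are reported, sorted by chromosome then
    rank.  Every family id must be present in the index.
    """
    family = sorted(set(family_ids))
    missing = [g for g in family if g not in index]
    if missing:
        raise KeyError(f"family ids missing from gene order: {missing[:10]}")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for gene in family:
        chrom, rank = index.rank_of(gene)
        by_chrom.setdefault(chrom, []).append((rank, gene))
    clusters: list[DuplicationCluster] = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        run: list[tuple[int, str]] = [entries[0]]
        for cur in entries[1:]:
            if cur[0] - run[-1][0] <= window:
                run.append(cur)
            else:
                if len(run) >= 2:
                    clusters.append(
                        DuplicationCluster(
                            chromosome=chrom,
                            members=tuple(g for _, g in run),
                            rank_span=(run[0][0], run[-1][0]),
                        )
                    )
                run = [cur]
        if len(run) >= 2:
            clusters.append(
                DuplicationCluster(
                    chromosome=chrom,
                    members=tuple(g for _, g in run),
                    rank_span=(run[0][0], run[-1][0]),
                )
            )
    return clusters


def chromosome_distribution(
    index: GeneOrderIndex, family_ids: Iterable[str]
) -> pd.DataFrame:
    """Per-chromosome family counts and fractions.

    Returns a DataFrame indexed by chromosome with ``count`` and
    ``fraction`` columns; fractions sum to 1 over the family.
    """
    family = sorted(set(family_ids))
    missing = [g for g in family if g not in index]
    if missing:
        raise KeyError(f"family ids missing from gene order: {missing[:10]}")
    counts: dict[str, int] = {}
    for gene in family:
        chrom, _ = index.rank_of(gene)
        counts[chrom] = counts.get(chrom, 0) + 1
    df = pd.DataFrame(
        {"count": pd.Series(counts, dtype=int)}
    ).sort_index()
    df["fraction"] = df["count"] / max(len(family), 1)
    return df


def plot_coordinates(index: GeneOrderIndex, family_ids: Iterable[str]) -> pd.DataFrame:
    """(chromosome, position, gene id) table for chromosome-map plotting."""
    rows = []
    for gene in sorted(set(family_ids)):
        chrom, pos = index.position_of(gene)
        rows.append((chrom, pos, gene))
    rows.sort()
    return pd.DataFrame(rows, columns=["chromosome", "position_bp", "gene_id"])


def _type_arrangement_string(ann: ZFPAnnotation) -> str:
    return "+".join(m.mtype for m in ann.motifs) + "|" + ann.arrangement


def load_wgd_pairs(
    path,
    family_ids: Iterable[str],
    annotations: Optional[Mapping[str, ZFPAnnotation]] = None,
) -> list[WGDPair]:
    """Read externally computed WGD paralog pairs from a two-column TSV.

    Pairs with members outside the family are filtered with a warning;
    malformed rows are rejected with a warning.  When annotations are
    supplied, each pair is checked for motif-architecture concordance
    (identical type string and arrangement).
    """
    family = set(family_ids)
    pairs: list[WGDPair] = []
    n_bad = n_filtered = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                n_bad += 1
                continue
            a, b = parts[0], parts[1]
            source = parts[2] if len(parts) > 2 else ""
            if a not in family or b not in family:
                n_filtered += 1
                continue
            concordant = None
            if annotations is not None and a in annotations and b in annotations:
                concordant = _type_arrangement_string(annotations[a]) == _type_arrangement_string(
                    annotations[b]
                )
            pairs.append(WGDPair(a, b, source, concordant))
    if n_bad:
        warnings.warn(f"{n_bad} malformed WGD pair rows rejected")
    if n_filtered:
        warnings.warn(f"{n_filtered} WGD pairs dropped (member outside family)")
    return pairs
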