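"""Expression tiering and tissue-specific induction flagging.

Works on a probeset x tissue abundance matrix (microarray-atlas style)
plus a gene <-> probeset map.  Genes are tiered (low/medium/high) by
mean log2 abundance with quantile (equal-count) cuts, and flagged as
induced in a target tissue set when the mean abundance there exceeds a
fold multiple of the mean elsewhere.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "log2_matrix",
    "collapse_probesets",
    "abundance_tiers",
    "tissue_induction",
    "read_expression_tsv",
    "read_gene_map",
]

_TIER_NAMES = {3: ("low", "medium", "high")}


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a probeset x tissue TSV (first column = probeset id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression matrix has negative values")
    return df


def read_gene_map(path) -> dict[str, str]:
    """Read a gene<TAB>probeset map; returns probeset -> gene."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, probeset = line.rstrip("\n").split("\t")[:2]
            if gene == "gene_id":
                continue
            out[probeset] = gene
    return out


def log2_matrix(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(value + pseudocount); negative input is an error."""
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(matrix + pseudocount)


def collapse_probesets(
    matrix: pd.DataFrame, gene_map: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probeset x tissue matrix to gene level (mean of probesets).

    Probesets absent from the map are dropped.
    """
    mapped = matrix.loc[[p for p in matrix.index if p in gene_map]].copy()
    mapped.index = [gene_map[p] for p in mapped.index]
    mapped.index.name = "gene_id"
    return mapped.groupby(level=0).mean().sort_index()


def abundance_tiers(log2_gene_matrix: pd.DataFrame, k: int = 3) -> tuple[pd.Series, list[float]]:
    """Split genes into ``k`` abundance tiers by mean log2 abundance.

    Quantile (equal-count) cuts: genes are ordered by (mean, gene id) —
    the id is the documented tie-break — and divided into ``k`` groups
    whose sizes differ by at most one.  Returns the tier label per gene
    (``low``/``medium``/``high`` for k=3, else ``tier1..k``) and the cut
    values (boundary means) for transparency.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(log2_gene_matrix) < k:
        raise ValueError(f"need at least {k} genes for {k} tiers")
    means = log2_gene_matrix.mean(axis=1)
    order = means.reset_index()
    order.columns = ["gene_id", "mean"]
    order = order.sort_values(["mean", "gene_id"], kind="stable")
    chunks = np.array_split(np.arange(len(order)), k)
    names = _TIER_NAMES.get(k, tuple(f"tier{i + 1}" for i in range(k)))
    labels = pd.Series(index=means.index, dtype=object, name="tier")
    cuts: list[float] = []
    for tier_idx, chunk in enumerate(chunks):
        genes = order.iloc[chunk]["gene_id"]
        labels.loc[genes] = names[tier_idx]
        if tier_idx < k - 1 and len(chunk):
            cuts.append(float(order.iloc[chunk[-1]]["mean"]))
    return labels, cuts


def tissue_induction(
    matrix: pd.DataFrame,
    target_tissues: Sequence[str],
    fold: float = 2.0,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Score and flag genes induced in a target tissue set.

    ``score = mean(target) / max(mean(non-target), floor + eps)``;
    flagged when ``score >= fold``.  Input is the (raw, non-log) gene x
    tissue matrix.  Result is sorted by descending score, ties by id.
    """
    unknown = [t for t in target_tissues if t not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown tissue labels: {unknown}")
    if not target_tissues:
        raise ValueError("target tissue set is empty")
    others = [c for c in matrix.columns if c not in set(target_tissues)]
    if not others:
        raise ValueError("no non-target tissues to compare against")
    eps = 1e-9
    mt = matrix[list(target_tissues)].mean(axis=1)
    mo = matrix[others].mean(axis=1)
    score = mt / np.maximum(mo, floor + eps)
    out = pd.DataFrame(
        {"score": score, "target_mean": mt, "other_mean": mo}
    )
    out["flagged"] = out["score"] >= fold
    out = out.sort_index().sort_values("score", ascending=False, kind="stable")
    return out
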