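"""Reading and writing the standard formats the pipeline touches.

Proteomes come in as amino-acid FASTA (optionally carrying splice-variant
suffixes on the identifiers), gene models as GFF3 or a simple TSV, and
annotations go out as a per-protein summary TSV plus a GFF3-style motif
feature file.  Internally all protein coordinates are 0-based half-open;
exported feature files are 1-based inclusive (GFF convention).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "GeneOrderIndex",
    "FormatError",
    "read_proteome",
    "read_gene_order",
    "write_annotations",
]

#: default recognizer for splice-variant suffixes: trailing ".<digits>"
VARIANT_SUFFIX_RE = re.compile(r"\.(\d+)$")

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    ``sequence`` is uppercase, stop-stripped, and restricted to the 20
    canonical residues plus ``X``.  ``variant_of`` carries the gene id when
    the record id bears a splice-variant suffix (``g1.2`` -> ``g1``).
    ``location`` is ``(chromosome, start_bp, end_bp, strand)`` when known.
    """

    id: str
    description: str = ""
    sequence: str = ""
    variant_of: Optional[str] = None
    location: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r} has non-amino-acid characters {sorted(bad)!r}"
            )
        if self.location is not None:
            _, start, end, _ = self.location
            if start > end:
                raise ValueError(f"record {self.id!r}: start > end in location")

    @property
    def gene_id(self) -> str:
        """Gene identifier with any splice-variant suffix removed."""
        return self.variant_of if self.variant_of is not None else self.id

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase a sequence and strip trailing stop characters ('*')."""
    return raw.upper().rstrip("*")


@dataclass
class GeneOrderIndex:
    """Per-chromosome gene order with dense ranks.

    ``order[chrom]`` is the list of ``(gene_id, start_bp)`` sorted by start
    (ties broken by id); a gene's rank is its index in that list.  Ranks are
    therefore consecutive integers ``0..n-1`` per chromosome.
    """

    order: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    _lookup: dict[str, tuple[str, int, int]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, int]]) -> "GeneOrderIndex":
        """Build the index from ``(gene_id, chromosome, start_bp)`` rows."""
        by_chrom: dict[str, list[tuple[str, int]]] = {}
        for gene_id, chrom, start in rows:
            by_chrom.setdefault(chrom, []).append((gene_id, start))
        index = cls()
        for chrom in sorted(by_chrom):
            entries = sorted(by_chrom[chrom], key=lambda e: (e[1], e[0]))
            index.order[chrom] = entries
            for rank, (gene_id, start) in enumerate(entries):
                if gene_id in index._lookup:
                    raise FormatError(f"gene id {gene_id!r} appears more than once")
                index._lookup[gene_id] = (chrom, rank, start)
        return index

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._lookup

    def __len__(self) -> int:
        return len(self._lookup)

    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chromosome, rank)`` for a gene."""
        chrom, rank, _ = self._lookup[gene_id]
        return chrom, rank

    def position_of(self, gene_id: str) -> tuple[str, int]:
        """Return ``(chromosome, start_bp)`` for a gene."""
        chrom, _, start = self._lookup[gene_id]
        return chrom, start

    @property
    def chromosomes(self) -> list[str]:
        return list(self.order)


def _split_variant(record_id: str, variant_re: re.Pattern = VARIANT_SUFFIX_RE):
    m = variant_re.search(record_id)
    if m:
        return record_id[: m.start()], m.group(0)
    return record_id, None


def read_proteome(
    path,
    variant_policy: Literal["longest_per_gene", "all"] = "longest_per_gene",
    variant_re: re.Pattern = VARIANT_SUFFIX_RE,
) -> list[ProteinRecord]:
    """Read a protein FASTA into normalized :class:`ProteinRecord` objects.

    Under ``longest_per_gene`` one record is kept per gene id — the longest
    sequence, ties broken by the lexicographically smallest variant suffix —
    so downstream family counts are per gene, matching how splice variants
    are customarily collapsed in gene-family surveys.
    """
    if variant_policy not in ("longest_per_gene", "all"):
        raise ValueError(f"unknown variant_policy {variant_policy!r}")
    seen_headers: set[str] = set()
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        if header in seen_headers:
            raise FormatError(f"duplicate identical header: {header!r}")
        seen_headers.add(header)
        gene, suffix = _split_variant(rec.id, variant_re)
        records.append(
            ProteinRecord(
                id=rec.id,
                description=rec.description,
                sequence=normalize_sequence(str(rec.seq)),
                variant_of=gene if suffix else None,
            )
        )
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if variant_policy == "all":
        return records
    best: dict[str, ProteinRecord] = {}
    for record in records:
        gene = record.gene_id
        incumbent = best.get(gene)
        if (
            incumbent is None
            or len(record) > len(incumbent)
            or (len(record) == len(incumbent) and record.id < incumbent.id)
        ):
            best[gene] = record
    return [best[g] for g in sorted(best)]


def read_gene_order(path) -> tuple[GeneOrderIndex, int]:
    """Read gene models from GFF3 or TSV into a :class:`GeneOrderIndex`.

    TSV columns: gene_id, chromosome, start[, end, strand] (header optional,
    detected by a non-numeric third column).  GFF3: rows of type ``gene``
    with an ``ID=`` attribute.  Returns ``(index, n_rejected_rows)``; rows
    missing a coordinate are rejected with a warning.
    """
    path = Path(path)
    rows: list[tuple[str, str, int]] = []
    rejected = 0
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        first_fields = first.rstrip("\n").split("\t")
        is_gff = first.startswith("##gff") or len(first_fields) >= 9
        if is_gff:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != "gene":
                    continue
                try:
                    start = int(parts[3])
                except ValueError:
                    rejected += 1
                    continue
                m = re.search(r"ID=([^;]+)", parts[8])
                if not m:
                    rejected += 1
                    continue
                rows.append((m.group(1), parts[0], start))
        else:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    rejected += 1
                    continue
                gene_id, chrom, start_s = parts[0], parts[1], parts[2]
                if gene_id in ("gene_id", "id"):  # header row
                    continue
                try:
                    start = int(start_s)
                except ValueError:
                    rejected += 1
                    continue
                rows.append((gene_id, chrom, start))
    if rejected:
        warnings.warn(f"{rejected} gene-order rows rejected (missing coordinate)")
    return GeneOrderIndex.from_rows(rows), rejected


_SUMMARY_COLUMNS = [
    "protein_id",
    "finger_count",
    "count_class",
    "type_string",
    "ear_count",
    "ear_class",
    "array_class",
    "arrangement",
]


def write_annotations(annotations, out_dir) -> tuple[Path, Path]:
    """Write per-protein summary TSV and a GFF3-style motif feature file.

    Feature coordinates are converted from the internal 0-based half-open
    convention to 1-based inclusive.  Row order is deterministic (protein id,
    then feature start), so re-running on the same input is byte-identical.
    Returns ``(summary_path, features_path)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary_path = out_dir / "zfp_summary.tsv"
    features_path = out_dir / "zfp_features.gff3"

    with open(summary_path, "w") as fh:
        fh.write("\t".join(_SUMMARY_COLUMNS) + "\n")
        for ann in sorted(annotations, key=lambda a: a.protein_id):
            type_string = "+".join(m.mtype for m in ann.motifs)
            fh.write(
                "\t".join(
                    [
                        ann.protein_id,
                        str(ann.finger_count),
                        ann.count_class,
                        type_string,
                        str(len(ann.ears)),
                        ann.ear_class,
                        ann.array_class,
                        ann.arrangement,
                    ]
                )
                + "\n"
            )

    with open(features_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in sorted(annotations, key=lambda a: a.protein_id):
            feats = [
                ("C2H2_motif", m.start, m.end, f"type={m.mtype};subgroup={m.subgroup or '.'}")
                for m in ann.motifs
            ] + [
                ("EAR_motif", e.start, e.end, f"pattern={e.pattern_id}")
                for e in ann.ears
            ]
            for kind, start, end, attrs in sorted(feats, key=lambda f: (f[1], f[0])):
                fh.write(
                    "\t".join(
                        [
                            ann.protein_id,
                            "zfpkit",
                            kind,
                            str(start + 1),  # 1-based inclusive
                            str(end),
                            ".",
                            ".",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    return summary_path, features_path


def read_motif_features(path) -> list[tuple[str, str, int, int]]:
    """Re-parse a feature file written by :func:`write_annotations`.

    Returns ``(protein_id, kind, start, end)`` tuples in internal 0-based
    half-open coordinates — the round-trip inverse of the export.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], parts[2], int(parts[3]) - 1, int(parts[4])))
    return out
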