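"""Intron-exon architecture and length statistics of gene cohorts.

Built for ortholog comparisons: how many exons/introns the family members
carry, and how gene, transcript and translation lengths distribute around
their medians. Skew is operationalized as sign(mean - median) per measure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from statistics import mean, median
from typing import Iterable, Sequence

from .sequence_io import GeneModel


@dataclass(frozen=True)
class GeneStructureRecord:
    """Exon counts and lengths of one gene."""

    gene_id: str
    species: str = ""
    n_exons: int = 0
    gene_length: int | None = None
    transcript_length: int | None = None
    translation_length: int | None = None
    flagged: bool = False  # inconsistent or incomplete, excluded from summaries

    @property
    def n_introns(self) -> int:
        return max(self.n_exons - 1, 0)


@dataclass
class StructureSummary:
    """Cohort-level exon-count table, medians and skew directions."""

    exon_count_freq: dict[int, int]
    modal_exon_count: int | None
    modal_fold: float | None  # modal class size / runner-up class size
    medians: dict[str, float | None]
    means: dict[str, float | None]
    skew: dict[str, int | None]  # sign(mean - median): -1, 0, +1
    n_records: int


def _record_from_gene_model(gene: GeneModel, species: str = "") -> GeneStructureRecord:
    return GeneStructureRecord(
        gene_id=gene.gene_id,
        species=species,
        n_exons=len(gene.exons),
        gene_length=gene.gene_length,
        transcript_length=gene.transcript_length,
        translation_length=gene.translation_length,
        flagged=not gene.exons,
    )


def collect_structures(
    source: Iterable[GeneModel] | str | Path,
    species: str = "",
) -> list[GeneStructureRecord]:
    """Build structure records from GeneModel objects or a metadata TSV.

    The TSV mirrors what ortholog databases export: columns gene_id, species,
    n_exons, gene_length, transcript_length, translation_length (missing
    values empty). Records with non-positive lengths or exon counts are
    flagged and excluded from summaries.
    """
    if isinstance(source, (str, Path)):
        records = []
        with open(source) as fh:
            reader = csv.DictReader(
                (line for line in fh if not line.startswith("#")), delimiter="\t"
            )
            for row in reader:
                def _int(key: str) -> int | None:
                    val = (row.get(key) or "").strip()
                    return int(val) if val else None

                n_exons = _int("n_exons") or 0
                lengths = [
                    _int("gene_length"),
                    _int("transcript_length"),
                    _int("translation_length"),
                ]
                flagged = n_exons < 1 or any(
                    v is not None and v <= 0 for v in lengths
                )
                records.append(
                    GeneStructureRecord(
                        gene_id=row["gene_id"],
                        species=row.get("species", "") or species,
                        n_exons=n_exons,
                        gene_length=lengths[0],
                        transcript_length=lengths[1],
                        translation_length=lengths[2],
                        flagged=flagged,
                    )
                )
        return records
    return [_record_from_gene_model(g, species=species) for g in source]


def _summarize_measure(values: list[float]) -> tuple[float | None, float | None, int | None]:
    if not values:
        return None, None, None
    med = float(median(values))
    mu = float(mean(values))
    delta = mu - med
    skew = 0 if delta == 0 else (1 if delta > 0 else -1)
    return med, mu, skew


def summarize_structures(
    records: Sequence[GeneStructureRecord],
    exclude_partial: bool = False,
    partial_max_length: int = 600,
) -> StructureSummary:
    """Cohort summary: modal exon class, its fold over the runner-up, medians.

    ``exclude_partial`` drops likely-partial entries (single exon and short
    gene length) from the length medians; by default they are included.
    """
    usable = [r for r in records if not r.flagged]
    if not usable:
        raise ValueError("no valid records to summarize")

    freq: dict[int, int] = {}
    for r in usable:
        freq[r.n_exons] = freq.get(r.n_exons, 0) + 1
    by_size = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    modal_exon_count = by_size[0][0]
    modal_fold = (by_size[0][1] / by_size[1][1]) if len(by_size) > 1 else None

    def _is_partial(r: GeneStructureRecord) -> bool:
        return (
            r.n_exons == 1
            and r.gene_length is not None
            and r.gene_length <= partial_max_length
        )

    length_pool = [
        r for r in usable if not (exclude_partial and _is_partial(r))
    ]
    medians: dict[str, float | None] = {}
    means: dict[str, float | None] = {}
    skew: dict[str, int | None] = {}
    for attr in ("gene_length", "transcript_length", "translation_length"):
        values = [
            float(getattr(r, attr))
            for r in length_pool
            if getattr(r, attr) is not None
        ]
        med, mu, sk = _summarize_measure(values)
        medians[attr], means[attr], skew[attr] = med, mu, sk

    return StructureSummary(
        exon_count_freq=freq,
        modal_exon_count=modal_exon_count,
        modal_fold=modal_fold,
        medians=medians,
        means=means,
        skew=skew,
        n_records=len(usable),
    )


def write_summary_tsv(summary: StructureSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#metric\tvalue\n")
        fh.write(f"n_records\t{summary.n_records}\n")
        fh.write(f"modal_exon_count\t{summary.modal_exon_count}\n")
        fold = "" if summary.modal_fold is None else f"{summary.modal_fold:.3f}"
        fh.write(f"modal_fold\t{fold}\n")
        for n, count in sorted(summary.exon_count_freq.items()):
            fh.write(f"exon_count_{n}\t{count}\n")
        for attr in ("gene_length", "transcript_length", "translation_length"):
            med = summary.medians[attr]
            fh.write(f"median_{attr}\t{'' if med is None else med}\n")
            sk = summary.skew[attr]
            fh.write(f"skew_{attr}\t{'' if sk is None else sk}\n")
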