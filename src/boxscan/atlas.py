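"""Comparative promoter annotation across promoter sets and ortholog families.

Promoters here follow the convention of 2000 bp immediately 5' of the ATG
start codon; hit coordinates are reported ATG-relative, with position -1 the
base immediately 5' of the A of ATG, so a hexamer starting at -6 abuts the
start codon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifs import MotifDefinition, MotifHit, StrandPolicy, default_registry, scan
from .sequence_io import PromoterRegion


@dataclass
class PromoterAnnotation:
    """Per-promoter motif hits in ATG-relative coordinates."""

    gene_id: str
    species: str
    length: int
    hits: list[MotifHit] = field(default_factory=list)  # positions ATG-relative
    truncated: bool = False
    too_short: bool = False
    motifs_scanned: tuple[str, ...] = ()

    def count(self, motif_name: str, strand: str | None = None) -> int:
        return sum(
            1
            for h in self.hits
            if h.motif_name == motif_name and (strand is None or h.strand == strand)
        )

    def counts_by_strand(self) -> dict[tuple[str, str], int]:
        return dict(Counter((h.motif_name, h.strand) for h in self.hits))


@dataclass
class CountDistribution:
    """Histogram of per-promoter motif counts with its mean."""

    motif_name: str
    histogram: dict[int, int]
    n_promoters: int

    @property
    def mean(self) -> float:
        total = sum(c * n for c, n in self.histogram.items())
        return total / self.n_promoters if self.n_promoters else 0.0

    def mark(self, focal_count: int) -> dict:
        """Place a focal gene's count against the distribution."""
        at_or_above = sum(n for c, n in self.histogram.items() if c >= focal_count)
        return {
            "focal_count": focal_count,
            "mean": self.mean,
            "fold_over_mean": focal_count / self.mean if self.mean > 0 else None,
            "n_promoters_at_or_above": at_or_above,
        }


def _as_records(
    promoters: Iterable,
) -> list[tuple[str, str, str, bool]]:
    """Normalize input to (gene_id, species, sequence, truncated) tuples."""
    records = []
    for p in promoters:
        if isinstance(p, PromoterRegion):
            records.append((p.gene_id, "", p.sequence, p.truncated))
        elif isinstance(p, tuple):
            if len(p) == 2:
                records.append((p[0], "", p[1], False))
            else:
                records.append((p[0], p[1], p[2], len(p) > 3 and p[3]))
        else:
            raise TypeError(f"cannot annotate {type(p).__name__}")
    return records


def annotate_promoter_set(
    promoters: Iterable,
    motifs: Sequence[MotifDefinition] | None = None,
    strands: StrandPolicy = "both",
) -> list[PromoterAnnotation]:
    """Annotate each promoter with all motif hits, ATG-relative.

    ``promoters`` may be PromoterRegion objects, (gene_id, sequence) pairs or
    (gene_id, species, sequence[, truncated]) tuples. Output is ordered by
    species then gene_id, so annotation is invariant under input reordering.
    Records shorter than the motif length are kept with zero hits and flagged.
    """
    if motifs is None:
        motifs = default_registry()
    annotations = []
    for gene_id, species, seq, truncated in _as_records(promoters):
        L = len(seq)
        ann = PromoterAnnotation(
            gene_id=gene_id,
            species=species,
            length=L,
            truncated=truncated,
            motifs_scanned=tuple(m.name for m in motifs),
        )
        min_k = min(m.k for m in motifs) if motifs else 0
        if L < min_k:
            ann.too_short = True
        else:
            for motif in motifs:
                for h in scan(seq, motif, strands):
                    ann.hits.append(
                        MotifHit(h.motif_name, h.position - L, h.strand, h.matched_word)
                    )
        ann.hits.sort(key=lambda h: (h.position, h.motif_name, h.strand))
        annotations.append(ann)
    annotations.sort(key=lambda a: (a.species, a.gene_id))
    return annotations


def annotate_promoter_fasta(
    path: str | Path,
    motifs: Sequence[MotifDefinition] | None = None,
    strands: StrandPolicy = "both",
) -> list[PromoterAnnotation]:
    """Annotate a promoter FASTA; record ids carry gene (and species) labels.

    A record id of the form ``species|gene`` splits into both fields;
    otherwise the whole id is the gene id.
    """
    from Bio import SeqIO

    promoters = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" in rec.id:
            species, gene = rec.id.split("|", 1)
        else:
            species, gene = "", rec.id
        truncated = "truncated" in rec.description
        promoters.append((gene, species, str(rec.seq).upper(), truncated))
    return annotate_promoter_set(promoters, motifs=motifs, strands=strands)


def count_distribution(
    annotations: Sequence[PromoterAnnotation],
    motif_name: str,
    include_truncated: bool = False,
) -> CountDistribution:
    """Histogram of per-promoter counts for one motif.

    Truncated promoters are excluded by default: their counts are not
    comparable at fixed window length.
    """
    if not annotations:
        raise ValueError("empty annotation set")
    known = {name for a in annotations for name in a.motifs_scanned}
    known |= {h.motif_name for a in annotations for h in a.hits}
    if motif_name not in known:
        raise KeyError(f"motif {motif_name!r} was never scanned")
    usable = [
        a for a in annotations if include_truncated or not (a.truncated or a.too_short)
    ]
    if not usable:
        raise ValueError("no untruncated promoters to summarize")
    counts = Counter(a.count(motif_name) for a in usable)
    return CountDistribution(
        motif_name=motif_name, histogram=dict(counts), n_promoters=len(usable)
    )


def family_track_table(
    annotations: Sequence[PromoterAnnotation],
    families: Mapping[str, Sequence[str]] | None = None,
    shared_fraction: float = 0.5,
) -> pd.DataFrame:
    """Side-by-side hit table for ortholog families.

    ``families`` maps family_id -> promoter gene_ids; when omitted all
    promoters form one family. Each hit is one row (family, species, gene,
    motif, ATG-relative position, strand); promoters without hits keep an
    empty row so the family roster stays complete. A ``shared`` column flags
    motifs present in at least ``shared_fraction`` of family members.
    """
    by_gene = {a.gene_id: a for a in annotations}
    if families is None:
        families = {"all": [a.gene_id for a in annotations]}
    rows = []
    for family_id, gene_ids in families.items():
        members = [by_gene[g] for g in gene_ids if g in by_gene]
        n_members = len(members)
        motif_presence: Counter[str] = Counter()
        for a in members:
            for name in {h.motif_name for h in a.hits}:
                motif_presence[name] += 1
        shared = {
            name
            for name, n in motif_presence.items()
            if n_members and n / n_members >= shared_fraction
        }
        for a in members:
            if not a.hits:
                rows.append(
                    {
                        "family": family_id,
                        "species": a.species,
                        "gene_id": a.gene_id,
                        "motif": None,
                        "position": None,
                        "strand": None,
                        "truncated": a.truncated,
                        "shared": None,
                    }
                )
            for h in a.hits:
                rows.append(
                    {
                        "family": family_id,
                        "species": a.species,
                        "gene_id": a.gene_id,
                        "motif": h.motif_name,
                        "position": h.position,
                        "strand": h.strand,
                        "truncated": a.truncated,
                        "shared": h.motif_name in shared,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "family", "species", "gene_id", "motif",
            "position", "strand", "truncated", "shared",
        ],
    )


def annotations_to_bed(
    annotations: Sequence[PromoterAnnotation], k: int = 6
) -> list[str]:
    """BED6 lines in promoter-local coordinates (0-based from the 5' end)."""
    lines = []
    for a in annotations:
        for h in a.hits:
            start = h.position + a.length  # back to 0-based local
            lines.append(
                f"{a.gene_id}\t{start}\t{start + k}\t{h.motif_name}\t0\t{h.strand}"
            )
    return lines


def read_family_file(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (family_id, promoter_record_id) -> family mapping."""
    families: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        family_id, gene_id = line.split("\t")[:2]
        families.setdefault(family_id, []).append(gene_id)
    return families
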