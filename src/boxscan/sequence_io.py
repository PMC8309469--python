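"""Genome/annotation input, promoter extraction, fragmentation and GC content.

Coordinate conventions: GFF3 input is 1-based inclusive; every internal
interval is 0-based half-open. Promoters are reported 5'->3' in gene
orientation and end at the base immediately 5' of the A of the ATG start
codon, so they include the 5'UTR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of a genome assembly; sequence is upper-case A/C/G/T/N."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: invalid bases {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Minimal protein-coding gene model.

    ``cds_start`` is the 1-based genomic coordinate of the first base of the
    start codon: the leftmost CDS base on the + strand, the rightmost on the
    - strand. ``exons`` are 1-based inclusive genomic intervals ordered
    5'->3' on the gene's strand.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    exons: tuple[tuple[int, int], ...] = ()
    transcript_length: int | None = None
    translation_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def gene_length(self) -> int | None:
        """Genomic span from first to last exon base, introns included."""
        if not self.exons:
            return None
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return max(ends) - min(starts) + 1


@dataclass(frozen=True)
class PromoterRegion:
    """Fixed-length upstream region of one gene, 5'->3' in gene orientation."""

    gene_id: str
    sequence: str
    requested_length: int
    contig_id: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    truncated: bool

    @property
    def actual_length(self) -> int:
        return len(self.sequence)

    @property
    def genomic_interval(self) -> tuple[str, int, int]:
        return (self.contig_id, self.start, self.end)


@dataclass(frozen=True)
class GenomeFragment:
    """Non-overlapping fixed-width genome window with its GC fraction."""

    contig_id: str
    start: int  # 0-based half-open
    end: int
    gc: float
    sequence: str = field(repr=False, default="")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return self.sequence.count("N") / len(self.sequence)


def read_genome(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA assembly into GenomeSequence records, order preserved.

    Sequences are upper-cased. An empty file yields an empty list with a
    warning rather than an error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(GenomeSequence(contig_id=rec.id, sequence=seq))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record {rec.id!r}: {exc}") from exc
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def _first_or_none(values: Iterable) -> object | None:
    for v in values:
        return v
    return None


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GFF3 annotation into GeneModel records.

    One record per protein-coding gene. When a gene has several transcripts
    the first-listed one is used. Genes without CDS features are skipped with
    a warning. Exons fall back to CDS segments when no exon features exist.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(
            db.children(gene, featuretype=("mRNA", "transcript"), order_by="start")
        )
        parent = _first_or_none(transcripts) or gene
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds:
            # fall back: CDS attached directly to the gene
            cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            logger.warning("gene %s has no CDS features; skipped", gene.id)
            continue
        exons = list(db.children(parent, featuretype="exon", order_by="start"))
        if not exons:
            exons = cds
        strand = gene.strand if gene.strand in "+-" else "+"
        if strand == "+":
            cds_start = min(f.start for f in cds)
            exon_ivs = tuple((f.start, f.end) for f in exons)
        else:
            cds_start = max(f.end for f in cds)
            exon_ivs = tuple(
                (f.start, f.end) for f in sorted(exons, key=lambda f: -f.end)
            )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=strand,
                cds_start=cds_start,
                exons=exon_ivs,
            )
        )
    return genes


def extract_promoter(
    genome: GenomeSequence, gene: GeneModel, length: int = 2000
) -> PromoterRegion:
    """Extract the ``length`` bp immediately upstream of the start codon.

    On the + strand the genomic interval is [cds_start-1-length, cds_start-1)
    (0-based half-open); on the - strand it is [cds_start, cds_start+length)
    reverse-complemented. Intervals are clipped at contig boundaries and the
    ``truncated`` flag records any clipping.
    """
    if gene.contig_id != genome.contig_id:
        raise ValueError(
            f"gene {gene.gene_id!r} is on contig {gene.contig_id!r}, "
            f"not {genome.contig_id!r}"
        )
    if length < 0:
        raise ValueError("promoter length must be non-negative")
    atg0 = gene.cds_start - 1  # 0-based position of the A of ATG
    if gene.strand == "+":
        start = max(0, atg0 - length)
        end = max(0, atg0)
        seq = genome.sequence[start:end]
    else:
        start = min(genome.length, atg0 + 1)
        end = min(genome.length, atg0 + 1 + length)
        seq = reverse_complement(genome.sequence[start:end])
    truncated = len(seq) < length
    if not seq:
        logger.warning(
            "gene %s has zero upstream bases on contig %s",
            gene.gene_id,
            genome.contig_id,
        )
    return PromoterRegion(
        gene_id=gene.gene_id,
        sequence=seq,
        requested_length=length,
        contig_id=genome.contig_id,
        start=start,
        end=end,
        strand=gene.strand,
        truncated=truncated,
    )


def gc_content(sequence: str) -> float:
    """GC fraction (#G+#C)/(#A+#C+#G+#T); N bases are excluded entirely."""
    if not sequence:
        raise ValueError("gc_content of an empty sequence is undefined")
    sequence = sequence.upper()
    gc = sequence.count("G") + sequence.count("C")
    at = sequence.count("A") + sequence.count("T")
    if gc + at == 0:
        raise ValueError("gc_content undefined: sequence contains only N")
    return gc / (gc + at)


def fragment_genome(
    genome: GenomeSequence, window: int = 2000
) -> list[GenomeFragment]:
    """Cut one contig into non-overlapping ``window``-bp fragments.

    Fragments start at contig offset 0; the trailing remainder shorter than
    ``window`` is discarded so every fragment has identical width.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    fragments = []
    n = genome.length // window
    for i in range(n):
        start = i * window
        end = start + window
        seq = genome.sequence[start:end]
        try:
            gc = gc_content(seq)
        except ValueError:
            gc = float("nan")  # all-N fragment; dropped by N-fraction filters
        fragments.append(
            GenomeFragment(
                contig_id=genome.contig_id, start=start, end=end, gc=gc, sequence=seq
            )
        )
    return fragments


def filter_fragments_by_gc(
    fragments: Sequence[GenomeFragment],
    center: float,
    tolerance: float = 0.02,
) -> list[GenomeFragment]:
    """Keep fragments with gc in [center-tolerance, center+tolerance].

    Both boundaries are inclusive: a 2% tolerance around 28.4% retains the
    closed range 26.4%..30.4%.
    """
    if not 0.0 <= center <= 1.0:
        raise ValueError("center must lie in [0, 1]")
    lo, hi = center - tolerance, center + tolerance
    return [f for f in fragments if lo <= f.gc <= hi]


def drop_n_rich_fragments(
    fragments: Sequence[GenomeFragment], max_n_fraction: float = 0.10
) -> list[GenomeFragment]:
    """Drop fragments whose N fraction exceeds ``max_n_fraction``.

    Assembly-gap-rich windows would bias composition estimates.
    """
    return [f for f in fragments if f.n_fraction <= max_n_fraction]


def write_promoter_fasta(
    promoters: Sequence[PromoterRegion], path: str | Path
) -> None:
    """Write promoters as FASTA, one record per gene."""
    with open(path, "w") as fh:
        for p in promoters:
            flag = " truncated" if p.truncated else ""
            fh.write(
                f">{p.gene_id} {p.contig_id}:{p.start}-{p.end}({p.strand}){flag}\n"
            )
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_fragment_table(
    fragments: Sequence[GenomeFragment], path: str | Path, header: str = ""
) -> None:
    """Write fragments as TSV: contig, start, end, gc."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("#contig\tstart\tend\tgc\n")
        for f in fragments:
            fh.write(f"{f.contig_id}\t{f.start}\t{f.end}\t{f.gc:.6f}\n")


def write_promoter_bed(
    promoters: Sequence[PromoterRegion], path: str | Path
) -> None:
    """Write promoter genomic intervals as BED6."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f"{p.contig_id}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}\n"
            )
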