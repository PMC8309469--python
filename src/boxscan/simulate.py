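"""Seeded synthetic genomes, promoters and annotations.

Generators reproduce the statistical structure the analysis assumes — iid
composition at a target GC (the study genome's 36%, or the 28.4% of an
AT-rich promoter), first-order Markov transition structure, and exact motif
words planted at known positions/strands — so every pipeline stage is
testable without downloads. All randomness flows from one integer seed
through numpy SeedSequence substreams (one per contig), so fixtures are
stable under contig addition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .background import BASES, CompositionModel
from .motifs import default_registry
from .sequence_io import GenomeSequence, reverse_complement

_BASE_ARRAY = np.frombuffer(BASES.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Declarative description of a synthetic genome fixture.

    ``planted_motifs`` entries are (motif_name, contig_index, position,
    strand); planted words overwrite the background (no insertion) so all
    other coordinates stay put.
    """

    mode: str = "iid_gc"  # or "markov"
    gc_target: float = 0.36
    model: CompositionModel | None = None
    length: int = 10_000
    n_contigs: int = 1
    seed: int = 0
    planted_motifs: tuple[tuple[str, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in {"iid_gc", "markov"}:
            raise ValueError("mode must be 'iid_gc' or 'markov'")
        if self.mode == "markov" and self.model is None:
            raise ValueError("markov mode needs a CompositionModel")
        # overlap check per contig
        k = 6
        by_contig: dict[int, list[int]] = {}
        for _, contig, pos, _ in self.planted_motifs:
            by_contig.setdefault(contig, []).append(pos)
        for contig, positions in by_contig.items():
            positions.sort()
            for a, b in zip(positions, positions[1:]):
                if b < a + k:
                    raise ValueError(
                        f"planted motifs overlap on contig {contig}: {a} and {b}"
                    )


def _contig_rng(seed: int, contig_index: int) -> np.random.Generator:
    child = np.random.SeedSequence(seed).spawn(contig_index + 1)[contig_index]
    return np.random.default_rng(child)


def generate_iid_genome(
    gc: float, length: int, seed: int, contig_id: str = "chr1", contig_index: int = 0
) -> GenomeSequence:
    """Bases drawn independently with p_G = p_C = gc/2, p_A = p_T = (1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    if length < 1:
        raise ValueError("length must be positive")
    rng = _contig_rng(seed, contig_index)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=probs)
    seq = _BASE_ARRAY[idx].tobytes().decode()
    return GenomeSequence(contig_id=contig_id, sequence=seq)


def generate_markov_genome(
    model: CompositionModel,
    length: int,
    seed: int,
    contig_id: str = "chr1",
    contig_index: int = 0,
) -> GenomeSequence:
    """First base from the mononucleotide vector, the rest from the chain."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = _contig_rng(seed, contig_index)
    # Vectorized chain walk: draw uniforms once, step through cumulative rows.
    cum_trans = np.cumsum(model.trans, axis=1)
    cum_trans[:, -1] = 1.0  # guard against float round-off
    u = rng.random(length)
    idx = np.empty(length, dtype=np.int64)
    idx[0] = int(np.searchsorted(np.cumsum(model.mono), u[0], side="right"))
    state = idx[0]
    for i in range(1, length):
        state = int(np.searchsorted(cum_trans[state], u[i], side="right"))
        idx[i] = state
    seq = _BASE_ARRAY[np.minimum(idx, 3)].tobytes().decode()
    return GenomeSequence(contig_id=contig_id, sequence=seq)


def plant_motifs(
    sequence: str,
    plants: Sequence[tuple[str, int, str]],
) -> str:
    """Overwrite exact words at the given positions.

    ``plants`` entries are (word, position, strand); reverse-strand plants
    write the reverse complement at the position. Plants must fit the
    sequence and not overlap one another.
    """
    occupied: list[tuple[int, int]] = []
    buf = list(sequence)
    for word, pos, strand in plants:
        word = word.upper()
        end = pos + len(word)
        if pos < 0 or end > len(sequence):
            raise ValueError(f"plant at {pos} does not fit the sequence")
        for s, e in occupied:
            if pos < e and s < end:
                raise ValueError(f"plants overlap at position {pos}")
        occupied.append((pos, end))
        written = reverse_complement(word) if strand in {"-", "reverse"} else word
        buf[pos:end] = written
    return "".join(buf)


def _resolve_variant(motif_name: str) -> str:
    """First exact variant (lexicographic) of a registry motif."""
    for m in default_registry():
        if m.name == motif_name:
            return sorted(m.variants)[0]
    raise KeyError(f"unknown motif {motif_name!r}")


def generate_genome_set(spec: SimulationSpec) -> list[GenomeSequence]:
    """Generate the contigs of a SimulationSpec, planting any motifs."""
    contigs = []
    for c in range(spec.n_contigs):
        cid = f"chr{c + 1}"
        if spec.mode == "iid_gc":
            g = generate_iid_genome(
                spec.gc_target, spec.length, spec.seed, contig_id=cid, contig_index=c
            )
        else:
            g = generate_markov_genome(
                spec.model, spec.length, spec.seed, contig_id=cid, contig_index=c
            )
        plants = [
            (_resolve_variant(name), pos, strand)
            for name, contig, pos, strand in spec.planted_motifs
            if contig == c
        ]
        if plants:
            g = GenomeSequence(cid, plant_motifs(g.sequence, plants))
        contigs.append(g)
    return contigs


@dataclass(frozen=True)
class FixtureGene:
    """Gene placement request for make_fixture: where the ATG sits."""

    gene_id: str
    contig_index: int
    cds_start: int  # 1-based first base of the start codon
    strand: str = "+"
    cds_length: int = 300
    n_exons: int = 1


def make_fixture(
    spec: SimulationSpec,
    genes: Sequence[FixtureGene],
    fasta_path: str | Path,
    gff_path: str | Path,
    promoter_length: int = 2000,
) -> list[GenomeSequence]:
    """Write a toy genome FASTA and GFF3 pair for end-to-end runs.

    Genes must leave ``promoter_length`` bp of upstream contig (downstream
    for - strand) so extracted promoters are untruncated. Regenerating from
    the same spec/seed yields byte-identical files.
    """
    contigs = generate_genome_set(spec)
    for gene in genes:
        contig = contigs[gene.contig_index]
        if gene.strand == "+":
            upstream = gene.cds_start - 1
            room = gene.cds_start - 1 + gene.cds_length <= contig.length
        else:
            upstream = contig.length - gene.cds_start
            room = gene.cds_start - gene.cds_length >= 0
        if upstream < promoter_length or not room:
            raise ValueError(
                f"contig too short for gene {gene.gene_id!r} "
                f"(needs {promoter_length} bp upstream plus the CDS)"
            )
    with open(fasta_path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.contig_id}\n")
            for i in range(0, contig.length, 60):
                fh.write(contig.sequence[i : i + 60] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in contigs:
            fh.write(f"##sequence-region {contig.contig_id} 1 {contig.length}\n")
        for gene in genes:
            contig = contigs[gene.contig_index]
            if gene.strand == "+":
                start = gene.cds_start
                end = gene.cds_start + gene.cds_length - 1
            else:
                start = gene.cds_start - gene.cds_length + 1
                end = gene.cds_start
            gid = gene.gene_id
            common = f"{contig.contig_id}\tboxscan_sim"
            fh.write(
                f"{common}\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{common}\tmRNA\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f"ID={gid}.1;Parent={gid}\n"
            )
            # split the CDS span into n_exons equal-ish exons with 50-bp introns
            n = max(gene.n_exons, 1)
            span = end - start + 1
            intron = 0 if n == 1 else min(50, max(0, (span - n) // max(n, 1) // 2))
            exon_total = span - intron * (n - 1)
            base = exon_total // n
            pos = start
            for i in range(n):
                w = base + (1 if i < exon_total % n else 0)
                ex_start, ex_end = pos, pos + w - 1
                fh.write(
                    f"{common}\texon\t{ex_start}\t{ex_end}\t.\t{gene.strand}\t.\t"
                    f"ID={gid}.1.exon{i + 1};Parent={gid}.1\n"
                )
                fh.write(
                    f"{common}\tCDS\t{ex_start}\t{ex_end}\t.\t{gene.strand}\t0\t"
                    f"ID={gid}.1.cds{i + 1};Parent={gid}.1\n"
                )
                pos = ex_end + 1 + intron
    return contigs
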