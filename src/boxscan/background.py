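"""First-order Markov null model for motif occurrence.

A sequence is treated as a first-order Markov chain: the first base is an
independent draw from the mononucleotide distribution and every following
base depends only on its predecessor through the 4x4 conditional transition
matrix. The chance of an exact word w = b1..bk per start position is then

    P(w) = p(b1) * prod_i p(b_{i+1} | b_i)

and a motif's per-position probability sums P(w) over its exact variants
(plus the reverse-complement variants under both-strand counting, except for
palindromes, whose forward and reverse occurrences coincide). Over a window
of L bases there are L - k + 1 start positions, so the expected count is
p_motif * (L - k + 1); linearity of expectation makes this exact even though
overlapping windows are dependent.

The module also carries the statsmodels-style model/results pair
(:class:`MotifEnrichment` / :class:`MotifEnrichmentResults`) that packages
composition estimation, expectation and observed-count comparison for a
collection of equal-length regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motifs import (
    MotifDefinition,
    StrandPolicy,
    default_registry,
    scan,
)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class CompositionModel:
    """Mononucleotide and first-order transition probabilities.

    ``mono[i]`` is p(base_i) and ``trans[i, j]`` is p(base_j | base_i) with
    bases ordered A, C, G, T. ``source`` labels the provenance
    (whole-genome, GC-stratified, custom); ``n_sites`` counts the bases used.
    ``degenerate`` flags bases never observed (their transition row is
    undefined and kept at zero).
    """

    mono: np.ndarray
    trans: np.ndarray
    source: str = "custom"
    n_sites: int = 0
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mono = np.asarray(self.mono, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        if self.mono.shape != (4,) or self.trans.shape != (4, 4):
            raise ValueError("mono must be length 4 and trans 4x4 (A,C,G,T order)")
        if (self.mono < 0).any() or (self.trans < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.mono.sum(), 1.0):
            raise ValueError("mono probabilities must sum to 1")
        for i, b in enumerate(BASES):
            row = self.trans[i].sum()
            if b not in self.degenerate and not np.isclose(row, 1.0):
                raise ValueError(f"transition row for {b} sums to {row}, not 1")

    @classmethod
    def from_gc(cls, gc: float, source: str | None = None) -> "CompositionModel":
        """Zero-order model at a target GC: every transition row equals mono.

        p(G) = p(C) = gc/2 and p(A) = p(T) = (1-gc)/2, the composition of an
        unstranded genome at that GC content.
        """
        if not 0.0 < gc < 1.0:
            raise ValueError("gc must lie strictly between 0 and 1")
        mono = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        trans = np.tile(mono, (4, 1))
        return cls(mono=mono, trans=trans, source=source or f"iid-gc{gc:.3f}")

    def p_base(self, b: str) -> float:
        return float(self.mono[_BASE_INDEX[b]])

    def p_transition(self, b1: str, b2: str) -> float:
        return float(self.trans[_BASE_INDEX[b1], _BASE_INDEX[b2]])

    @property
    def gc(self) -> float:
        return float(self.mono[1] + self.mono[2])

    def word_probability(self, word: str) -> float:
        """Chain probability of an exact word per start position."""
        p = self.p_base(word[0])
        for b1, b2 in zip(word, word[1:]):
            p *= self.p_transition(b1, b2)
        return p

    def to_table(self) -> str:
        """Serialize as a plain-text table with a provenance header."""
        lines = [f"#source={self.source}", f"#n_sites={self.n_sites}"]
        if self.degenerate:
            lines.append(f"#degenerate={','.join(self.degenerate)}")
        for i, b in enumerate(BASES):
            lines.append(f"mono\t{b}\t{self.mono[i]:.10g}")
        for i, b1 in enumerate(BASES):
            for j, b2 in enumerate(BASES):
                lines.append(f"trans\t{b1}{b2}\t{self.trans[i, j]:.10g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "CompositionModel":
        source, n_sites, degenerate = "custom", 0, ()
        mono = np.zeros(4)
        trans = np.zeros((4, 4))
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                if key == "source":
                    source = val
                elif key == "n_sites":
                    n_sites = int(val)
                elif key == "degenerate":
                    degenerate = tuple(val.split(",")) if val else ()
                continue
            kind, name, value = line.split("\t")
            if kind == "mono":
                mono[_BASE_INDEX[name]] = float(value)
            elif kind == "trans":
                trans[_BASE_INDEX[name[0]], _BASE_INDEX[name[1]]] = float(value)
        return cls(mono=mono, trans=trans, source=source, n_sites=n_sites,
                   degenerate=degenerate)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_table())

    @classmethod
    def load(cls, path: str | Path) -> "CompositionModel":
        return cls.from_table(Path(path).read_text())


def estimate_composition(
    sequences: Iterable[str], source: str = "custom"
) -> CompositionModel:
    """Estimate mono- and dinucleotide composition from a sequence collection.

    Mononucleotide probabilities come from base counts; transitions from
    adjacent-pair counts within each sequence — pairs never span sequence or
    fragment boundaries. Pairs (and bases) involving N are excluded. A base
    never observed keeps a zero probability and is flagged in the model.
    """
    mono_counts = np.zeros(4)
    pair_counts = np.zeros((4, 4))
    for seq in sequences:
        seq = seq.upper()
        for b in seq:
            idx = _BASE_INDEX.get(b)
            if idx is not None:
                mono_counts[idx] += 1
        for b1, b2 in zip(seq, seq[1:]):
            i, j = _BASE_INDEX.get(b1), _BASE_INDEX.get(b2)
            if i is not None and j is not None:
                pair_counts[i, j] += 1
    n_sites = int(mono_counts.sum())
    if n_sites < 2:
        raise ValueError("need at least 2 usable bases to estimate composition")
    mono = mono_counts / n_sites
    trans = np.zeros((4, 4))
    degenerate = []
    for i, b in enumerate(BASES):
        row_total = pair_counts[i].sum()
        if row_total > 0:
            trans[i] = pair_counts[i] / row_total
        else:
            degenerate.append(b)
    return CompositionModel(
        mono=mono,
        trans=trans,
        source=source,
        n_sites=n_sites,
        degenerate=tuple(degenerate),
    )


def motif_probability(
    motif: MotifDefinition,
    model: CompositionModel,
    strands: StrandPolicy = "both",
) -> float:
    """Per-start-position probability of the motif under the chain model.

    Sums the chain probability over the exact forward variants; under
    both-strand counting the reverse-complement variants are added unless the
    motif is palindromic (a palindrome's reverse occurrence is the same
    position, counted once).
    """
    p = sum(model.word_probability(w) for w in motif.variants)
    if strands == "both" and not motif.palindromic:
        p += sum(model.word_probability(w) for w in motif.reverse_variants)
    return p


def expected_count(p_motif: float, L: int, k: int = 6) -> float:
    """Expected motif occurrences in an L-bp window: p_motif * (L - k + 1).

    A 2000-bp window holds 1995 start positions for a hexamer, so a
    per-position chance of 0.105% gives 2.09 expected occurrences.
    """
    if not 0.0 <= p_motif <= 1.0:
        raise ValueError("p_motif must lie in [0, 1]")
    if L < k:
        raise ValueError(f"window length {L} is shorter than the motif ({k} bp)")
    return p_motif * (L - k + 1)


def enrichment(observed: float, expected: float) -> float:
    """Fold enrichment observed/expected; undefined when expected is 0."""
    if expected <= 0:
        raise ZeroDivisionError("enrichment undefined for expected <= 0")
    return observed / expected


@dataclass
class ExpectedCountReport:
    """Observed-vs-expected summary for one motif under one background model."""

    motif_name: str
    model_source: str
    per_position_probability: float
    window_length: int
    positions: int
    expected: float
    observed_mean: float | None = None
    n_regions: int | None = None
    enrichment_fold: float | None = None

    def as_dict(self) -> dict:
        return {
            "motif": self.motif_name,
            "model_source": self.model_source,
            "p_motif": self.per_position_probability,
            "L": self.window_length,
            "positions": self.positions,
            "expected": self.expected,
            "observed_mean": self.observed_mean,
            "n_regions": self.n_regions,
            "enrichment_fold": self.enrichment_fold,
        }


def observed_vs_expected_report(
    regions: Sequence[str],
    motifs: Sequence[MotifDefinition] | None = None,
    model: CompositionModel | None = None,
    strands: StrandPolicy = "both",
    window_length: int | None = None,
) -> list[ExpectedCountReport]:
    """Compare mean observed motif counts per region with the Markov expectation.

    One report row per motif: the mean observed count over ``regions``
    (equal-length windows such as genome fragments or promoters), the
    expectation from ``model`` (estimated from the regions themselves when
    not supplied) and the enrichment fold. Scanning and expectation use the
    same strand policy so the two are commensurable.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("no regions supplied")
    if motifs is None:
        motifs = default_registry()
    if model is None:
        model = estimate_composition(regions, source="regions")
    if window_length is None:
        window_length = len(regions[0])
    reports = []
    for motif in motifs:
        p = motif_probability(motif, model, strands)
        positions = window_length - motif.k + 1
        exp = expected_count(p, window_length, motif.k)
        counts = [len(scan(r, motif, strands)) for r in regions]
        obs_mean = float(np.mean(counts))
        fold = obs_mean / exp if exp > 0 else None
        reports.append(
            ExpectedCountReport(
                motif_name=motif.name,
                model_source=model.source,
                per_position_probability=p,
                window_length=window_length,
                positions=positions,
                expected=exp,
                observed_mean=obs_mean,
                n_regions=len(regions),
                enrichment_fold=fold,
            )
        )
    return reports


class MotifEnrichment:
    """Motif-occurrence model for a collection of equal-length regions.

    Parameters
    ----------
    regions : sequence of str
        Equal-length nucleotide windows (genome fragments or promoters).
    motifs : sequence of MotifDefinition, optional
        Defaults to the five-box registry.
    background : sequence of str, optional
        Sequences the composition is estimated from; defaults to the regions
        themselves. Pass genome fragments here to test promoters against a
        genomic background.
    strands : {"both", "forward_only"}
        Strand policy shared by scanning and expectation.
    """

    def __init__(
        self,
        regions: Sequence[str],
        motifs: Sequence[MotifDefinition] | None = None,
        background: Sequence[str] | None = None,
        strands: StrandPolicy = "both",
        source: str = "custom",
    ) -> None:
        self.regions = [r.upper() for r in regions]
        if not self.regions:
            raise ValueError("no regions supplied")
        lengths = {len(r) for r in self.regions}
        if len(lengths) != 1:
            raise ValueError("regions must share one length; filter truncated ones")
        self.window_length = lengths.pop()
        self.motifs = list(motifs) if motifs is not None else default_registry()
        self.background = list(background) if background is not None else None
        self.strands: StrandPolicy = strands
        self.source = source

    @classmethod
    def from_fasta(cls, path: str | Path, **kwargs) -> "MotifEnrichment":
        from Bio import SeqIO

        regions = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
        return cls(regions, **kwargs)

    def fit(self) -> "MotifEnrichmentResults":
        """Estimate the composition model and compare observed with expected."""
        bg = self.background if self.background is not None else self.regions
        model = estimate_composition(bg, source=self.source)
        reports = observed_vs_expected_report(
            self.regions,
            motifs=self.motifs,
            model=model,
            strands=self.strands,
            window_length=self.window_length,
        )
        return MotifEnrichmentResults(self, model, reports)


class MotifEnrichmentResults:
    """Fitted composition model plus per-motif observed/expected comparison."""

    def __init__(
        self,
        model_spec: MotifEnrichment,
        composition: CompositionModel,
        reports: list[ExpectedCountReport],
    ) -> None:
        self.model = model_spec
        self.composition = composition
        self.reports = reports

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.reports])

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Motif enrichment against first-order Markov background",
            f"  regions: {len(self.model.regions)} x {self.model.window_length} bp"
            f"  strands: {self.model.strands}",
            f"  background: {self.composition.source}"
            f"  (GC {self.composition.gc:.3f}, n={self.composition.n_sites})",
            "",
            f"{'motif':<8}{'p_motif':>12}{'expected':>10}"
            f"{'observed':>10}{'fold':>8}",
        ]
        for r in self.reports:
            fold = f"{r.enrichment_fold:.2f}" if r.enrichment_fold is not None else "NA"
            lines.append(
                f"{r.motif_name:<8}{r.per_position_probability:>12.3e}"
                f"{r.expected:>10.3f}{r.observed_mean:>10.3f}{fold:>8}"
            )
        return "\n".join(lines)

    def to_tsv(self, path: str | Path, header: str = "") -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(header)
        self.table.to_csv(path, sep="\t", index=False, mode="a")
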