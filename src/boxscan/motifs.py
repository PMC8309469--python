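"""Degenerate hexamer boxes and strand-aware exact-word scanning.

The default registry holds the five boxes used throughout: the WRKY-bound
W-box (T/C)TGAC(T/C) and the bZIP-targeted ACGT-core boxes A (TACGTA),
T (AACGTT), C (GACGTA) and G (CACGTA). A- and T-boxes are their own reverse
complements; for those, a position is reported once under the forward strand
even when both strands are scanned, so palindromes are never double-counted.
Every start position is tested, so overlapping occurrences are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Literal, Sequence

from .sequence_io import reverse_complement

# IUPAC subset sufficient for the five boxes
_IUPAC: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "Y": "CT",
    "R": "AG",
}

StrandPolicy = Literal["forward_only", "both"]


@dataclass(frozen=True)
class MotifDefinition:
    """A named degenerate pattern with its expanded exact variants."""

    name: str
    pattern: str
    variants: frozenset[str]
    palindromic: bool

    @property
    def k(self) -> int:
        return len(self.pattern)

    @property
    def reverse_variants(self) -> frozenset[str]:
        """Exact words that signal a reverse-strand occurrence."""
        return frozenset(reverse_complement(v) for v in self.variants)


@dataclass(frozen=True)
class MotifHit:
    """One exact-word occurrence on a scanned sequence.

    ``position`` is the 0-based start on the scanned sequence;
    ``matched_word`` is the word as it appears on the scanned strand (for
    reverse hits its reverse complement is a motif variant).
    """

    motif_name: str
    position: int
    strand: str  # "+" forward, "-" reverse
    matched_word: str


def compile_motif(name: str, pattern: str) -> MotifDefinition:
    """Expand a degenerate pattern (A/C/G/T/Y/R) into exact variants.

    Palindromy is detected by comparing the variant set with its reverse
    complement set.
    """
    pattern = pattern.upper()
    unsupported = set(pattern) - set(_IUPAC)
    if unsupported:
        raise ValueError(
            f"motif {name!r}: unsupported pattern symbols {sorted(unsupported)!r}"
        )
    variants = frozenset(
        "".join(word) for word in product(*(_IUPAC[c] for c in pattern))
    )
    palindromic = variants == frozenset(reverse_complement(v) for v in variants)
    return MotifDefinition(
        name=name, pattern=pattern, variants=variants, palindromic=palindromic
    )


DEFAULT_MOTIFS: tuple[tuple[str, str], ...] = (
    ("W-box", "YTGACY"),
    ("A-box", "TACGTA"),
    ("T-box", "AACGTT"),
    ("C-box", "GACGTA"),
    ("G-box", "CACGTA"),
)


def default_registry() -> list[MotifDefinition]:
    """The five-box registry."""
    return [compile_motif(name, pattern) for name, pattern in DEFAULT_MOTIFS]


def scan(
    sequence: str,
    motif: MotifDefinition,
    strands: StrandPolicy = "both",
) -> list[MotifHit]:
    """Locate every occurrence of ``motif`` on ``sequence``.

    Every start position 0..L-k is tested, so overlapping hits are all
    reported. With ``strands="both"`` a window whose reverse complement is a
    variant yields a reverse-strand hit; for palindromic motifs each position
    is reported at most once, on the forward strand. Windows containing N
    never match.
    """
    sequence = sequence.upper()
    k = motif.k
    hits: list[MotifHit] = []
    fwd = motif.variants
    rev = motif.reverse_variants if strands == "both" and not motif.palindromic else frozenset()
    for i in range(len(sequence) - k + 1):
        word = sequence[i : i + k]
        if word in fwd:
            hits.append(MotifHit(motif.name, i, "+", word))
        elif word in rev:
            hits.append(MotifHit(motif.name, i, "-", word))
    return hits


def count_in_region(
    sequence: str,
    motif: MotifDefinition,
    strands: StrandPolicy = "both",
    windows: Sequence[tuple[int, int]] | None = None,
    atg_relative: bool = False,
) -> dict:
    """Count motif occurrences, optionally within stated sub-intervals.

    Returns a dict with ``total``, ``forward`` and ``reverse`` counts plus a
    ``windows`` entry mapping each requested (lo, hi) interval to its count.
    With ``atg_relative=True`` the sequence is treated as a promoter ending
    immediately 5' of the ATG, window bounds are ATG-relative (e.g. (-1000, 0)
    for the kilobase next to the start codon) and a hit is assigned to a
    window when its start position falls in [lo, hi).
    """
    hits = scan(sequence, motif, strands)
    L = len(sequence)
    result = {
        "total": len(hits),
        "forward": sum(1 for h in hits if h.strand == "+"),
        "reverse": sum(1 for h in hits if h.strand == "-"),
        "windows": {},
    }
    if windows:
        for lo, hi in windows:
            if atg_relative:
                n = sum(1 for h in hits if lo <= h.position - L < hi)
            else:
                n = sum(1 for h in hits if lo <= h.position < hi)
            result["windows"][(lo, hi)] = n
    return result


def hits_to_bed(
    hits: Iterable[MotifHit],
    region_id: str,
    k: int | None = None,
) -> list[str]:
    """Render hits as BED6 lines on the scanned region's coordinates."""
    lines = []
    for h in hits:
        width = k if k is not None else len(h.matched_word)
        lines.append(
            f"{region_id}\t{h.position}\t{h.position + width}\t"
            f"{h.motif_name}\t0\t{h.strand}"
        )
    return lines
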