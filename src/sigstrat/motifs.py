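"""Canonical 96-motif vocabulary for single-base substitutions.

Every SNV is reported on the pyrimidine strand: a substitution whose
reference base is a purine is reverse-complemented together with its
flanking bases, so the six substitution classes are C>A, C>G, C>T,
T>A, T>C and T>G.  A motif is written ``5'[ref>alt]3'``, e.g. a C>T
in the sequence GCA is ``G[C>T]A``.

The canonical ordering is substitution-major (C>A, C>G, C>T, T>A,
T>C, T>G), then the 5' flank in A, C, G, T order, then the 3' flank
in A, C, G, T order — the ordering used by COSMIC SBS matrices, so
reference-signature files align row-wise without shuffling.
"""

from __future__ import annotations

from dataclasses import dataclass

BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifKey:
    """One of the 96 pyrimidine-normalized trinucleotide substitution motifs."""

    five_prime: str
    substitution: str  # e.g. "C>T", reference base always a pyrimidine
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"not a pyrimidine-strand substitution: {self.substitution!r}")
        if self.five_prime not in BASES or self.three_prime not in BASES:
            raise ValueError(f"invalid flanking base in motif {self!r}")

    def __str__(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        """Position of this motif in the canonical 96-motif order."""
        return (
            SUBSTITUTIONS.index(self.substitution) * 16
            + BASES.index(self.five_prime) * 4
            + BASES.index(self.three_prime)
        )


#: The 96 motifs in canonical order.
MOTIF_ORDER: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)

MOTIF_INDEX: dict[str, int] = {m: i for i, m in enumerate(MOTIF_ORDER)}


def parse_motif(label: str) -> MotifKey:
    """Parse a ``G[C>T]A``-style label into a :class:`MotifKey`."""
    if len(label) != 7 or label[1] != "[" or label[5] != "]":
        raise ValueError(f"malformed motif label: {label!r}")
    return MotifKey(five_prime=label[0], substitution=label[2:5], three_prime=label[6])


def motif_from_context(ref: str, alt: str, five: str, three: str) -> MotifKey:
    """Build the pyrimidine-strand motif for an SNV given its flanks.

    If ``ref`` is a purine, the substitution and both flanks are
    reverse-complemented so the reported reference base is a pyrimidine.
    """
    if ref in PURINES:
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return MotifKey(five_prime=five, substitution=f"{ref}>{alt}", three_prime=three)


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS
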