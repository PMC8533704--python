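"""Domain record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, replace

VARIANT_CLASSES = (
    "silent",
    "missense",
    "nonsense",
    "frameshift",
    "in_frame",
    "splice",
    "intronic",
    "TSS",
)

CONTEXT_FLANK = 20  # bases on each side of the variant position
CONTEXT_LEN = 2 * CONTEXT_FLANK + 1

_DNA = frozenset("ACGTN")


class RecordError(ValueError):
    """A variant record violating a structural invariant."""


@dataclass
class VariantRecord:
    """One somatic variant call with the metrics the filter cascade consumes.

    Coordinates are 1-based and fully closed (MAF convention); ``pos`` is
    the substituted base for SNVs and the first changed base for indels.
    ``context41`` is the 41-base reference window centred on ``pos``
    (20 bases each side), padded with ``N`` near chromosome ends.
    Deletions use ``alt_allele == "-"``; insertions use ``ref_allele == "-"``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str
    variant_class: str
    depth: int
    alt_fwd: int
    alt_rev: int
    ref_fwd: int
    ref_rev: int
    vaf: float
    phred_quality: float
    context41: str
    is_putative_germline: bool = False
    is_common_snp: bool = False
    is_multiallelic: bool = False

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        self.context41 = self.context41.upper()
        self.validate()

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
        )

    def validate(self) -> None:
        if self.pos < 1:
            raise RecordError(f"{self._id()}: pos must be >= 1, got {self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise RecordError(f"{self._id()}: unknown variant_class {self.variant_class!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise RecordError(f"{self._id()}: vaf {self.vaf} outside [0, 1]")
        if self.phred_quality < 0:
            raise RecordError(f"{self._id()}: negative phred_quality")
        if min(self.depth, self.alt_fwd, self.alt_rev, self.ref_fwd, self.ref_rev) < 0:
            raise RecordError(f"{self._id()}: negative read count")
        if self.alt_fwd + self.alt_rev > self.depth:
            raise RecordError(f"{self._id()}: alt strand counts exceed depth")
        if self.ref_fwd + self.ref_rev > self.depth:
            raise RecordError(f"{self._id()}: ref strand counts exceed depth")
        if len(self.context41) != CONTEXT_LEN:
            raise RecordError(
                f"{self._id()}: context41 has length {len(self.context41)}, expected {CONTEXT_LEN}"
            )
        if not set(self.context41) <= _DNA:
            raise RecordError(f"{self._id()}: context41 contains non-ACGTN characters")
        if self.is_snv:
            if self.ref_allele == self.alt_allele:
                raise RecordError(f"{self._id()}: ref and alt alleles are identical")
            mid = self.context41[CONTEXT_FLANK]
            if mid != self.ref_allele:
                raise RecordError(
                    f"{self._id()}: context41 middle base {mid!r} does not match ref "
                    f"allele {self.ref_allele!r}"
                )

    def _id(self) -> str:
        return f"{self.sample_id} {self.chrom}:{self.pos} {self.ref_allele}>{self.alt_allele}"

    def reverse_complemented(self) -> "VariantRecord":
        """The same variant reported on the opposite strand (test helper)."""
        from .motifs import revcomp

        return replace(
            self,
            ref_allele=revcomp(self.ref_allele) if self.ref_allele != "-" else "-",
            alt_allele=revcomp(self.alt_allele) if self.alt_allele != "-" else "-",
            context41=revcomp(self.context41),
        )
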