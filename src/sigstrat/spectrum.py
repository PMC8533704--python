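"""Per-sample 96-motif mutational spectra and substitution summaries.

A sample's spectrum counts its single-base substitutions over the 96
pyrimidine-normalized trinucleotide motifs (6 substitutions x 4 five-prime
x 4 three-prime flanks).  Non-SNV variants never enter spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import MOTIF_ORDER, MotifKey, is_transition, motif_from_context
from .records import CONTEXT_FLANK, RecordError, VariantRecord


@dataclass
class MutationalSpectrum:
    sample_id: str
    counts: np.ndarray  # 96 ints, canonical motif order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError(f"spectrum must have 96 entries, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def motif_of(record: VariantRecord) -> MotifKey | None:
    """The pyrimidine-strand motif of an SNV, or None for non-SNVs.

    Purine-reference substitutions are reverse-complemented together with
    their flanks, so e.g. a G>A with 5' T and 3' C maps to G[C>T]A.
    """
    if not record.is_snv:
        return None
    mid = record.context41[CONTEXT_FLANK]
    if mid != record.ref_allele:
        raise RecordError(
            f"{record.sample_id} {record.chrom}:{record.pos}: context middle base "
            f"{mid!r} does not match ref allele {record.ref_allele!r}"
        )
    five = record.context41[CONTEXT_FLANK - 1]
    three = record.context41[CONTEXT_FLANK + 1]
    if five == "N" or three == "N":
        return None  # context truncated at a chromosome end
    return motif_from_context(record.ref_allele, record.alt_allele, five, three)


def build_spectra(records: list[VariantRecord]) -> list[MutationalSpectrum]:
    """One spectrum per sample present in the input (SNVs only).

    Samples are returned in first-appearance order; a sample with only
    non-SNV variants gets an all-zero spectrum.
    """
    order: list[str] = []
    acc: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.sample_id not in acc:
            acc[rec.sample_id] = np.zeros(96, dtype=int)
            order.append(rec.sample_id)
        key = motif_of(rec)
        if key is not None:
            acc[rec.sample_id][key.index] += 1
    return [MutationalSpectrum(sample_id=s, counts=acc[s]) for s in order]


def spectra_matrix(spectra: list[MutationalSpectrum]) -> pd.DataFrame:
    """Spectra as a 96 x n_samples DataFrame (motifs as index)."""
    return pd.DataFrame(
        np.column_stack([s.counts for s in spectra]) if spectra else np.zeros((96, 0), int),
        index=list(MOTIF_ORDER),
        columns=[s.sample_id for s in spectra],
    )


def titv_summary(records: list[VariantRecord]) -> tuple[float, float]:
    """Fractions of transitions (A<->G, C<->T) and transversions among SNVs."""
    ti = tv = 0
    for rec in records:
        if not rec.is_snv:
            continue
        if is_transition(rec.ref_allele, rec.alt_allele):
            ti += 1
        else:
            tv += 1
    n = ti + tv
    if n == 0:
        raise ValueError("transition/transversion summary needs at least one SNV")
    return ti / n, tv / n


def class_tally(records: list[VariantRecord]) -> dict[str, int]:
    """Counts of records per variant class (all classes present as keys)."""
    from .records import VARIANT_CLASSES

    tally = {c: 0 for c in VARIANT_CLASSES}
    for rec in records:
        tally[rec.variant_class] += 1
    return tally
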