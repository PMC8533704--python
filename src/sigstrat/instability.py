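"""Tumor mutational load (TML) and microsatellite instability (MSI) calling.

TML is the number of somatic mutations per megabase of sufficiently
covered exonic sequence,

    TML = somatic_mutation_count * 10^6 / covered_exonic_bases,

classified high at 20 mutations/Mb or above.  MSI status comes from a
five-locus panel (BAT25, BAT26, D2S123, D5S346, D17S250): MSI-high with
three or more unstable loci, microsatellite-stable with none, and
indeterminate in between (the 1-2 locus zone has no defined call).
"""

from __future__ import annotations

from dataclasses import dataclass

MSI_PANEL = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")


@dataclass(frozen=True)
class TmlResult:
    sample_id: str
    somatic_mutation_count: int
    covered_exonic_bases: float
    tml: float  # mutations per megabase
    status: str  # "high" | "low"


@dataclass(frozen=True)
class MsiResult:
    sample_id: str
    locus_calls: dict  # locus -> "stable" | "unstable"
    n_unstable: int
    status: str  # "MSS" | "MSI-H" | "indeterminate"


def compute_tml(
    somatic_mutation_count: int,
    covered_exonic_bases: float,
    sample_id: str = "sample",
    threshold: float = 20.0,
) -> TmlResult:
    """Mutations per megabase with the high/low call (high iff TML >= threshold)."""
    if covered_exonic_bases <= 0:
        raise ValueError("covered_exonic_bases must be positive")
    if somatic_mutation_count < 0:
        raise ValueError("somatic_mutation_count must be non-negative")
    tml = somatic_mutation_count * 1e6 / covered_exonic_bases
    return TmlResult(
        sample_id=sample_id,
        somatic_mutation_count=somatic_mutation_count,
        covered_exonic_bases=covered_exonic_bases,
        tml=tml,
        status="high" if tml >= threshold else "low",
    )


def classify_msi(locus_calls: dict, sample_id: str = "sample") -> MsiResult:
    """MSI status from the five-locus panel; every panel locus must be called."""
    missing = [loc for loc in MSI_PANEL if loc not in locus_calls]
    if missing:
        raise ValueError(f"missing MSI locus call(s): {', '.join(missing)}")
    bad = {v for v in locus_calls.values()} - {"stable", "unstable"}
    if bad:
        raise ValueError(f"invalid locus call value(s): {sorted(bad)}")
    n_unstable = sum(1 for loc in MSI_PANEL if locus_calls[loc] == "unstable")
    if n_unstable >= 3:
        status = "MSI-H"
    elif n_unstable == 0:
        status = "MSS"
    else:
        status = "indeterminate"
    return MsiResult(
        sample_id=sample_id,
        locus_calls={loc: locus_calls[loc] for loc in MSI_PANEL},
        n_unstable=n_unstable,
        status=status,
    )
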