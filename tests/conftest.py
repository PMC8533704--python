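import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from sigstrat.records import VariantRecord
from sigstrat.synthetic_cohort import CohortSpec, generate_cohort, synthetic_reference_set


def make_record(**overrides) -> VariantRecord:
    """A clean, filter-passing SNV record with sensible defaults."""
    base = dict(
        sample_id="S001",
        chrom="chr1",
        pos=500_000,
        ref_allele="C",
        alt_allele="T",
        gene="GENE1",
        variant_class="missense",
        depth=800,
        alt_fwd=120,
        alt_rev=118,
        ref_fwd=280,
        ref_rev=282,
        vaf=0.2975,
        phred_quality=250.0,
        context41="ACGTACGTACGTACGTACGGCATGCATGCATGCATGCATGC"[:41],
    )
    base.update(overrides)
    if "context41" not in overrides and base["ref_allele"] in "ACGT" and len(base["ref_allele"]) == 1:
        ctx = list(base["context41"])
        ctx[20] = base["ref_allele"]
        base["context41"] = "".join(ctx)
    return VariantRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_cohort():
    """A small full-featured synthetic cohort shared across tests."""
    spec = CohortSpec(seed=7, n_samples=8, mutations_per_sample_mean=80.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_set():
    return synthetic_reference_set(seed=3)
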