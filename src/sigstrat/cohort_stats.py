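"""Mutation-defined subgrouping and cohort-level association statistics.

Samples are labelled by the status of two designated driver genes
(defaults ARID1A and PIK3CA): mutated in the first only, the second
only, both ("Double hit") or neither ("Undetermined").  Pairwise gene
co-occurrence / mutual exclusivity and binary associations (e.g. APOBEC
vs high TML) use the two-sided Fisher exact test on 2x2 presence tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import VariantRecord

#: Sentinel reported when the sample odds ratio is infinite.
ODDS_RATIO_CAP = float("inf")

NON_SILENT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "in_frame", "splice", "TSS"}
)


@dataclass(frozen=True)
class SubgroupLabel:
    sample_id: str
    label: str  # gene_a name | gene_b name | "Double hit" | "Undetermined"


@dataclass
class PairwiseResult:
    gene_a: str
    gene_b: str
    n_both: int
    n_only_a: int
    n_only_b: int
    n_neither: int
    odds_ratio: float
    p_value: float
    direction: str  # "co-occurring" | "mutually exclusive" | "none"

    @property
    def n_co_events(self) -> int:
        return self.n_both


def _mutated_samples(
    records: list[VariantRecord], qualifying_classes: frozenset
) -> dict[str, set]:
    """gene -> set of sample_ids with >=1 qualifying mutation."""
    out: dict[str, set] = {}
    for rec in records:
        if rec.variant_class in qualifying_classes:
            out.setdefault(rec.gene, set()).add(rec.sample_id)
    return out


def assign_subgroups(
    records: list[VariantRecord],
    gene_a: str = "ARID1A",
    gene_b: str = "PIK3CA",
    qualifying_classes: frozenset = NON_SILENT_CLASSES,
) -> list[SubgroupLabel]:
    """Exhaustive, mutually exclusive 4-way labelling of every sample.

    Silent variants never toggle membership (configurable via
    ``qualifying_classes``).
    """
    samples: list[str] = []
    seen = set()
    for rec in records:
        if rec.sample_id not in seen:
            seen.add(rec.sample_id)
            samples.append(rec.sample_id)
    mutated = _mutated_samples(records, qualifying_classes)
    in_a = mutated.get(gene_a, set())
    in_b = mutated.get(gene_b, set())
    labels = []
    for s in samples:
        if s in in_a and s in in_b:
            lab = "Double hit"
        elif s in in_a:
            lab = gene_a
        elif s in in_b:
            lab = gene_b
        else:
            lab = "Undetermined"
        labels.append(SubgroupLabel(sample_id=s, label=lab))
    return labels


def prevalence_table(
    records: list[VariantRecord],
    labels: list[SubgroupLabel] | None = None,
    qualifying_classes: frozenset = NON_SILENT_CLASSES,
) -> dict:
    """Per-gene mutation prevalence and subgroup counts.

    Returns a dict with ``gene_prevalence`` (DataFrame: gene, n_mutated,
    fraction), ``subgroup_counts`` (label -> (count, fraction)) and
    ``n_samples``.
    """
    sample_ids = {r.sample_id for r in records}
    n = len(sample_ids)
    mutated = _mutated_samples(records, qualifying_classes)
    gene_rows = [
        {"gene": g, "n_mutated": len(s), "prevalence": len(s) / n if n else 0.0}
        for g, s in sorted(mutated.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    out = {
        "n_samples": n,
        "gene_prevalence": pd.DataFrame(gene_rows, columns=["gene", "n_mutated", "prevalence"]),
    }
    if labels is not None:
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab.label] = counts.get(lab.label, 0) + 1
        out["subgroup_counts"] = {
            k: (v, v / n if n else 0.0) for k, v in counts.items()
        }
    return out


def union_cooccurrence(
    records: list[VariantRecord],
    gene_a: str = "ARID1A",
    gene_b: str = "PIK3CA",
    qualifying_classes: frozenset = NON_SILENT_CLASSES,
) -> dict:
    """Co-mutation of the two designated genes: |both|, |union| and their ratio."""
    mutated = _mutated_samples(records, qualifying_classes)
    a, b = mutated.get(gene_a, set()), mutated.get(gene_b, set())
    both, union = len(a & b), len(a | b)
    return {
        "n_both": both,
        "n_union": union,
        "ratio_both_over_union": both / union if union else float("nan"),
    }


def association_test(binary_a, binary_b) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 cross-tabulation of two flags.

    Returns (odds ratio, p-value); the odds ratio is the sample (conditional
    ML is not needed here) estimate, infinite when a discordant cell is empty.
    """
    a = np.asarray(binary_a, dtype=bool)
    b = np.asarray(binary_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"flag vectors differ in length: {a.shape} vs {b.shape}")
    table = [
        [int(np.sum(a & b)), int(np.sum(a & ~b))],
        [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def pairwise_interactions(
    records: list[VariantRecord],
    min_mutated_samples: int = 5,
    alpha: float = 0.05,
    qualifying_classes: frozenset = NON_SILENT_CLASSES,
    bh_correct: bool = False,
) -> list[PairwiseResult]:
    """Fisher exact co-occurrence / mutual-exclusivity screen over gene pairs.

    Genes mutated in fewer than ``min_mutated_samples`` samples are
    dropped.  Direction is "co-occurring" when the odds ratio exceeds 1
    and p falls below ``alpha`` (after optional Benjamini-Hochberg
    correction), "mutually exclusive" when the odds ratio is below 1 at
    the same level, else "none".
    """
    sample_ids = sorted({r.sample_id for r in records})
    n = len(sample_ids)
    mutated = _mutated_samples(records, qualifying_classes)
    genes = sorted(g for g, s in mutated.items() if len(s) >= min_mutated_samples)
    results: list[PairwiseResult] = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            sa, sb = mutated[ga], mutated[gb]
            both = len(sa & sb)
            only_a = len(sa) - both
            only_b = len(sb) - both
            neither = n - both - only_a - only_b
            odds, p = stats.fisher_exact(
                [[both, only_a], [only_b, neither]], alternative="two-sided"
            )
            results.append(
                PairwiseResult(
                    gene_a=ga,
                    gene_b=gb,
                    n_both=both,
                    n_only_a=only_a,
                    n_only_b=only_b,
                    n_neither=neither,
                    odds_ratio=float(odds),
                    p_value=float(p),
                    direction="none",
                )
            )
    pvals = np.array([r.p_value for r in results])
    if bh_correct and len(pvals):
        from scipy.stats import false_discovery_control

        adj = false_discovery_control(pvals, method="bh")
    else:
        adj = pvals
    for r, p in zip(results, adj):
        if p < alpha and r.odds_ratio > 1:
            r.direction = "co-occurring"
        elif p < alpha and r.odds_ratio < 1:
            r.direction = "mutually exclusive"
    return results


def interactions_frame(results: list[PairwiseResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in results],
            "gene_b": [r.gene_b for r in results],
            "n_both": [r.n_both for r in results],
            "n_only_a": [r.n_only_a for r in results],
            "n_only_b": [r.n_only_b for r in results],
            "n_neither": [r.n_neither for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )


def geneset_tally(
    records: list[VariantRecord],
    gene_sets: dict,
    qualifying_classes: frozenset = NON_SILENT_CLASSES,
) -> pd.DataFrame:
    """Fraction of samples with >=1 qualifying mutation in each gene set.

    ``gene_sets`` maps a set name to an iterable of gene symbols (e.g.
    parsed from a GMT file).
    """
    sample_ids = {r.sample_id for r in records}
    n = len(sample_ids)
    mutated = _mutated_samples(records, qualifying_classes)
    rows = []
    for name, genes in gene_sets.items():
        hit = set()
        for g in genes:
            hit |= mutated.get(g, set())
        rows.append({"gene_set": name, "n_samples": len(hit), "fraction": len(hit) / n if n else 0.0})
    return pd.DataFrame(rows, columns=["gene_set", "n_samples", "fraction"])


def read_gmt(path) -> dict:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
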