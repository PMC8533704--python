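"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) they check: the Fisher oracle enumerates the hypergeometric
distribution directly, the segmentation oracle enumerates every
partition, and the run-scanner oracle uses a regular expression.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] by exhaustive
    enumeration over all tables with the same margins, summing the
    probabilities of tables no more probable than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)

    def log_prob(x: int) -> float:
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1)
            - math.lgamma(c1 - x + 1)
            - math.lgamma(r2 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        # tables at most as probable as observed; the tiny slack admits
        # exact mirror-tables despite floating-point rounding
        if lp <= obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def best_segmentation_cost(x: np.ndarray, penalty: float, min_seg: int = 1) -> float:
    """Minimal penalized least-squares cost over *all* segmentations of x."""
    x = np.asarray(x, dtype=float)
    n = x.size
    best = math.inf
    positions = range(1, n)
    for r in range(0, n):
        for cuts in itertools.combinations(positions, r):
            bounds = [0, *cuts, n]
            if any(bounds[i + 1] - bounds[i] < min_seg for i in range(len(bounds) - 1)):
                continue
            cost = 0.0
            for i in range(len(bounds) - 1):
                seg = x[bounds[i] : bounds[i + 1]]
                cost += float(np.sum((seg - seg.mean()) ** 2)) + penalty
            best = min(best, cost)
    return best


_RUN_RE = re.compile(r"A{6,}|C{6,}|G{6,}|T{6,}")


def homopolymer_regex(context: str, window: int = 5) -> bool:
    centre = len(context) // 2
    return any(
        m.start() <= centre + window and m.end() - 1 >= centre - window
        for m in _RUN_RE.finditer(context)
    )


def count_spectrum(records) -> dict:
    """Naive per-motif dictionary count over SNVs (pyrimidine-normalized)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out: dict[tuple[str, str], int] = {}
    for rec in records:
        if not rec.is_snv:
            continue
        ref, alt = rec.ref_allele, rec.alt_allele
        five, three = rec.context41[19], rec.context41[21]
        if "N" in (five, three):
            continue
        if ref in "AG":
            ref, alt = comp[ref], comp[alt]
            five, three = comp[rec.context41[21]], comp[rec.context41[19]]
        motif = f"{five}[{ref}>{alt}]{three}"
        out[(rec.sample_id, motif)] = out.get((rec.sample_id, motif), 0) + 1
    return out
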