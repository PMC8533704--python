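"""Kataegis detection and APOBEC tCw enrichment scoring.

Kataegis: mutations are ordered along each chromosome, intermutation
distances (bp to the previous mutation) are computed, and the
log-distance series is segmented into regions of constant intermutation
distance by exact penalized least squares (dynamic programming).  A
segment is a kataegis focus when it spans six or more consecutive
mutations with a mean intermutation distance of at most 1000 bp.

APOBEC enrichment: for each sample, mutated cytosines (pyrimidine-
normalized, by default restricted to C>T and C>G, the deamination
outcomes) are tested for over-representation of the tCw context
(w = A or T) against the base composition of the 41-base windows
around those mutations:

    E = (mut_tcw * background_c) / (mut_c * background_tcw)

A sample is APOBEC-positive when E exceeds 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .motifs import revcomp
from .records import CONTEXT_FLANK, VariantRecord


@dataclass(frozen=True)
class RainfallPoint:
    sample_id: str
    chrom: str
    pos: int
    distance: float  # bp to the previous mutation on the chromosome; nan for the first


@dataclass
class KataegisSegment:
    sample_id: str  # "cohort" when mutations are pooled
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_distance: float
    is_kataegis: bool


@dataclass
class ApobecResult:
    sample_id: str
    mut_tcw: int
    mut_c: int
    background_tcw: int
    background_c: int
    enrichment: float  # nan when undefined
    is_positive: bool


@dataclass(frozen=True)
class KataegisConfig:
    penalty: float = 1.0  # per-segment penalty on the squared-log10 cost
    min_seg: int = 1  # minimum number of distances per segment
    min_mutations: int = 6
    max_mean_distance: float = 1000.0
    per_sample: bool = False  # default pools mutations across the cohort


def intermutation_distances(
    records: list[VariantRecord], pooled_label: str | None = "cohort"
) -> list[RainfallPoint]:
    """Rainfall points for a set of mutations, sorted by (chrom, pos).

    The distance of the first mutation on each chromosome is NaN; ties at
    the same position get distance 0.  When ``pooled_label`` is set the
    points carry that label instead of their sample of origin (cohort-wide
    ordering mixes samples).
    """
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos, r.sample_id))
    points: list[RainfallPoint] = []
    prev_chrom = None
    prev_pos = 0
    for rec in ordered:
        if rec.chrom != prev_chrom:
            dist = float("nan")
        else:
            dist = float(rec.pos - prev_pos)
        points.append(
            RainfallPoint(
                sample_id=pooled_label if pooled_label is not None else rec.sample_id,
                chrom=rec.chrom,
                pos=rec.pos,
                distance=dist,
            )
        )
        prev_chrom, prev_pos = rec.chrom, rec.pos
    return points


def _segment_costs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums enabling O(1) SSE of any contiguous slice."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def optimal_segmentation(x: np.ndarray, penalty: float, min_seg: int = 1) -> list[tuple[int, int]]:
    """Exact minimizer of  sum_segments [SSE(segment) + penalty]  by DP.

    Returns the list of (start, end) index pairs (inclusive, 0-based)
    partitioning ``x``.
    """
    if penalty <= 0:
        raise ValueError("segmentation penalty must be positive")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return []
    s1, s2 = _segment_costs(x)
    best = np.full(n + 1, np.inf)
    best[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        i = np.arange(0, j - min_seg + 1)
        if i.size == 0:
            continue
        lengths = j - i
        tot = s1[j] - s1[i]
        sse = (s2[j] - s2[i]) - tot * tot / lengths
        cost = best[i] + sse + penalty
        k = int(np.argmin(cost))
        best[j] = cost[k]
        back[j] = i[k]
    if not np.isfinite(best[n]):  # fewer points than min_seg: one segment
        return [(0, n - 1)]
    bounds: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j - 1))
        j = i
    return bounds[::-1]


def segment_distances(
    points: list[RainfallPoint], config: KataegisConfig | None = None
) -> list[KataegisSegment]:
    """Piecewise-constant segmentation of log10(distance + 1) per chromosome.

    Each returned segment is annotated with its mutation count, the
    arithmetic mean of the raw distances it covers, and the kataegis
    verdict (>= ``min_mutations`` mutations, mean distance <=
    ``max_mean_distance``).  A distance segment covering distances
    d_a..d_b spans the mutations a-1..b, so its mutation count is the
    number of distances plus one.
    """
    config = config or KataegisConfig()
    segments: list[KataegisSegment] = []
    by_key: dict[tuple[str, str], list[RainfallPoint]] = {}
    for p in points:
        by_key.setdefault((p.sample_id, p.chrom), []).append(p)
    for (sid, chrom), pts in by_key.items():
        pts = sorted(pts, key=lambda p: p.pos)
        if len(pts) < 2:
            continue
        dists = np.array([p.distance for p in pts[1:]], dtype=float)
        x = np.log10(dists + 1.0)
        for a, b in optimal_segmentation(x, config.penalty, config.min_seg):
            seg_d = dists[a : b + 1]
            n_mut = (b - a + 1) + 1
            mean_d = float(seg_d.mean())
            segments.append(
                KataegisSegment(
                    sample_id=sid,
                    chrom=chrom,
                    start=pts[a].pos,
                    end=pts[b + 1].pos,
                    n_mutations=n_mut,
                    mean_distance=mean_d,
                    is_kataegis=(
                        n_mut >= config.min_mutations and mean_d <= config.max_mean_distance
                    ),
                )
            )
    return segments


def call_kataegis(
    records: list[VariantRecord], config: KataegisConfig | None = None
) -> list[KataegisSegment]:
    """End-to-end kataegis calling; returns only the kataegis segments.

    Mutations are pooled across the cohort by default (per-sample mode via
    ``config.per_sample``).
    """
    config = config or KataegisConfig()
    if not records:
        return []
    points = intermutation_distances(
        records, pooled_label=None if config.per_sample else "cohort"
    )
    return [s for s in segment_distances(points, config) if s.is_kataegis]


# ---------------------------------------------------------------------------
# APOBEC enrichment
# ---------------------------------------------------------------------------

_W = frozenset("AT")


def apobec_positive(enrichment: float) -> bool:
    """The classification rule: positive iff the score strictly exceeds 2."""
    return bool(enrichment > 2.0) if np.isfinite(enrichment) else False


def _count_tcw(window: str) -> int:
    return sum(
        1
        for i in range(len(window) - 2)
        if window[i] == "T" and window[i + 1] == "C" and window[i + 2] in _W
    )


def apobec_enrichment(
    records: list[VariantRecord],
    sample_id: str | None = None,
    restrict_substitutions: bool = True,
) -> ApobecResult:
    """tCw enrichment score for one sample's mutations.

    Mutated cytosines are counted on the pyrimidine-normalized strand
    (guanine-reference records are reverse-complemented), by default
    restricted to C>T and C>G outcomes; ``restrict_substitutions=False``
    widens to all mutated cytosines.  Background c and tcw are tallied
    over the 41-base windows around the counted mutations, one tally per
    window occurrence (overlapping windows are not deduplicated).
    """
    if sample_id is None:
        ids = {r.sample_id for r in records}
        sample_id = ids.pop() if len(ids) == 1 else "pooled"
    mut_c = mut_tcw = bg_c = bg_tcw = 0
    for rec in records:
        if not rec.is_snv or rec.ref_allele not in "CG":
            continue
        if rec.ref_allele == "C":
            ctx, alt = rec.context41, rec.alt_allele
        else:
            ctx, alt = revcomp(rec.context41), revcomp(rec.alt_allele)
        if restrict_substitutions and alt not in "TG":  # keep C>T and C>G only
            continue
        mut_c += 1
        if ctx[CONTEXT_FLANK - 1] == "T" and ctx[CONTEXT_FLANK + 1] in _W:
            mut_tcw += 1
        bg_c += ctx.count("C")
        bg_tcw += _count_tcw(ctx)
    if mut_c == 0 or bg_tcw == 0:
        warnings.warn(
            f"{sample_id}: APOBEC enrichment undefined "
            f"(mut_c={mut_c}, background_tcw={bg_tcw})"
        )
        e = float("nan")
    else:
        e = (mut_tcw * bg_c) / (mut_c * bg_tcw)
    return ApobecResult(
        sample_id=sample_id,
        mut_tcw=mut_tcw,
        mut_c=mut_c,
        background_tcw=bg_tcw,
        background_c=bg_c,
        enrichment=e,
        is_positive=apobec_positive(e),
    )


def apobec_by_sample(
    records: list[VariantRecord], restrict_substitutions: bool = True
) -> list[ApobecResult]:
    order: list[str] = []
    groups: dict[str, list[VariantRecord]] = {}
    for rec in records:
        if rec.sample_id not in groups:
            groups[rec.sample_id] = []
            order.append(rec.sample_id)
        groups[rec.sample_id].append(rec)
    return [
        apobec_enrichment(groups[s], sample_id=s, restrict_substitutions=restrict_substitutions)
        for s in order
    ]


def plot_rainfall(points: list[RainfallPoint], ax=None):
    """Rainfall plot: mutation index vs log10 intermutation distance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    chroms = sorted({p.chrom for p in points})
    offset = 0
    for chrom in chroms:
        pts = [p for p in points if p.chrom == chrom]
        y = [p.distance for p in pts]
        ax.scatter(range(offset, offset + len(pts)), y, s=4, label=chrom)
        offset += len(pts)
    ax.set_yscale("log")
    ax.set_ylabel("intermutation distance (bp)")
    ax.set_xlabel("mutation index (ordered by chromosome, position)")
    ax.legend(fontsize=7)
    return ax
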