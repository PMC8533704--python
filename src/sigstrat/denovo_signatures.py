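"""De novo mutational-signature extraction by repeated NMF.

The motif-by-sample count matrix V (96 x n) is factorized as V ~ W H with
W >= 0 (signatures, columns normalized to sum 1) and H >= 0 (exposures),
using multiplicative updates that minimize the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ],

the variant appropriate for count data.  The number of signatures is
selected by consensus clustering over random restarts: each restart
assigns every sample to its maximal-exposure signature, the consensus
(co-assignment) matrix is averaged over restarts, and the cophenetic
correlation between consensus dissimilarities and their hierarchical
clustering measures how reproducible the decomposition is at each rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .io_formats import ReferenceSignatureSet
from .motifs import MOTIF_ORDER

_EPS = 1e-12


@dataclass
class NmfRun:
    """One converged factorization V ~ W H at a fixed rank."""

    rank: int
    W: np.ndarray  # 96 x k, columns sum to 1
    H: np.ndarray  # k x n
    objective: float  # generalized KL divergence at the solution
    seed: int | None = None


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    val = float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum())
    return val


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    W0: np.ndarray | None = None,
    H0: np.ndarray | None = None,
) -> NmfRun:
    """Multiplicative-update KL-NMF with random uniform initialization.

    Deterministic for a fixed seed.  Initial W entries are uniform(0, 1];
    initial H entries are uniform(0, 1] scaled by the data mean, so
    scaling V by c > 0 scales H by c and leaves W unchanged.  Explicit
    ``W0``/``H0`` override the random initialization.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)) or (V < 0).any():
        raise ValueError("V must be non-negative and finite")
    m, n = V.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank {k} outside 1..min({m}, {n})")
    zero_cols = np.where(V.sum(axis=0) == 0)[0]
    if zero_cols.size:
        raise ValueError(f"all-zero sample column(s) at index {zero_cols.tolist()}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(_EPS, 1.0, size=(m, k)) if W0 is None else np.asarray(W0, float).copy()
    H = (
        rng.uniform(_EPS, 1.0, size=(k, n)) * max(V.mean(), _EPS)
        if H0 is None
        else np.asarray(H0, float).copy()
    )
    prev_obj = None
    for it in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            obj = _kl_divergence(V, W @ H + _EPS)
            if prev_obj is not None and abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
                break
            prev_obj = obj
    scale = W.sum(axis=0)
    scale[scale == 0] = 1.0
    W = W / scale
    H = H * scale[:, None]
    obj = _kl_divergence(V, W @ H + _EPS)
    return NmfRun(rank=k, W=W, H=H, objective=obj, seed=seed)


def explained_variance(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """100 x (1 - ||V - WH||_F^2 / ||V||_F^2), clipped to [0, 100]."""
    V = np.asarray(V, dtype=float)
    denom = float(np.sum(V**2))
    if denom == 0:
        raise ValueError("explained variance undefined for an all-zero matrix")
    ev = 100.0 * (1.0 - float(np.sum((V - np.asarray(W) @ np.asarray(H)) ** 2)) / denom)
    return float(np.clip(ev, 0.0, 100.0))


def residual_sum_of_squares(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.sum((np.asarray(V, float) - np.asarray(W) @ np.asarray(H)) ** 2))


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity structure."""
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    dc = squareform(D, checks=False)
    if dc.size == 0:
        return 1.0
    if dc.max() < 1e-12:  # identical partition in every restart
        return 1.0
    Z = linkage(dc, method="average")
    with np.errstate(invalid="ignore"):
        c, _ = cophenet(Z, dc)
    return 1.0 if np.isnan(c) else float(c)


@dataclass
class RankSelection:
    """Per-rank stability statistics and the selected number of signatures."""

    ranks: list[int]
    cophenetic: dict  # rank -> coefficient (nan for rank 1)
    rss: dict  # rank -> RSS of the best restart
    explained_variance: dict  # rank -> percent for the best restart
    chosen_rank: int
    n_restarts: int
    best_runs: dict = field(repr=False, default_factory=dict)  # rank -> NmfRun
    consensus: dict = field(repr=False, default_factory=dict)  # rank -> n x n matrix

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.ranks:
            rows.append(
                {
                    "rank": k,
                    "cophenetic": self.cophenetic[k],
                    "rss": self.rss[k],
                    "explained_variance": self.explained_variance[k],
                    "chosen": k == self.chosen_rank,
                }
            )
        return pd.DataFrame(rows)


def select_rank(
    V: np.ndarray,
    rank_range: tuple[int, int] = (1, 4),
    n_restarts: int = 500,
    seed: int | None = None,
    stability_threshold: float = 0.95,
    rank_rule: str = "max_cophenetic",
    max_iter: int = 300,
    tol: float = 1e-5,
) -> RankSelection:
    """Run ``n_restarts`` factorizations per rank and select the number of
    signatures from consensus-clustering stability.

    Rank 1 is excluded from stability selection (its consensus matrix is
    all-ones by construction).  With ``rank_rule="max_cophenetic"`` (default)
    the chosen rank is the largest rank attaining the maximal cophenetic
    coefficient among ranks whose coefficient exceeds the stability
    threshold; ``"largest_stable"`` picks the largest rank above the
    threshold.  If no rank >= 2 is stable, rank 1 is returned with a warning.
    """
    if n_restarts < 10:
        raise ValueError("n_restarts must be at least 10")
    if rank_rule not in ("max_cophenetic", "largest_stable"):
        raise ValueError(f"unknown rank_rule {rank_rule!r}")
    V = np.asarray(V, dtype=float)
    lo, hi = rank_range
    ranks = list(range(max(lo, 1), hi + 1))
    n = V.shape[1]
    streams = np.random.SeedSequence(seed).spawn(len(ranks))
    coph: dict[int, float] = {}
    rss: dict[int, float] = {}
    ev: dict[int, float] = {}
    best_runs: dict[int, NmfRun] = {}
    consensus_by_rank: dict[int, np.ndarray] = {}
    for rank, ss in zip(ranks, streams):
        child_seeds = ss.generate_state(n_restarts)
        consensus = np.zeros((n, n))
        best: NmfRun | None = None
        for rseed in child_seeds:
            run = nmf_factorize(V, rank, seed=int(rseed % (2**31 - 1)), max_iter=max_iter, tol=tol)
            assign = run.H.argmax(axis=0)
            consensus += assign[:, None] == assign[None, :]
            if best is None or run.objective < best.objective:
                best = run
        consensus /= n_restarts
        consensus_by_rank[rank] = consensus
        best_runs[rank] = best
        coph[rank] = np.nan if rank == 1 else _cophenetic_coefficient(consensus)
        rss[rank] = residual_sum_of_squares(V, best.W, best.H)
        ev[rank] = explained_variance(V, best.W, best.H)
    stable = [k for k in ranks if k >= 2 and coph[k] > stability_threshold]
    if not stable:
        warnings.warn("no rank >= 2 is stable; falling back to a single signature")
        chosen = 1
    elif rank_rule == "largest_stable":
        chosen = max(stable)
    else:
        top = max(coph[k] for k in stable)
        chosen = max(k for k in stable if coph[k] >= top - 1e-6)
    return RankSelection(
        ranks=ranks,
        cophenetic=coph,
        rss=rss,
        explained_variance=ev,
        chosen_rank=chosen,
        n_restarts=n_restarts,
        best_runs=best_runs,
        consensus=consensus_by_rank,
    )


def match_to_reference(
    W: np.ndarray, refs: ReferenceSignatureSet, min_cosine: float = 0.6
) -> list[tuple[int, str | None, float]]:
    """Greedy one-to-one matching of extracted signatures to references.

    Returns (signature index, best reference name or None, cosine); a
    signature whose best available cosine falls below ``min_cosine`` is
    reported unmatched.
    """
    W = np.asarray(W, dtype=float)
    R = refs.matrix
    wn = np.linalg.norm(W, axis=0)
    rn = np.linalg.norm(R, axis=0)
    C = (W.T @ R) / np.outer(np.where(wn == 0, 1, wn), np.where(rn == 0, 1, rn))
    k, r = C.shape
    out: dict[int, tuple[str | None, float]] = {}
    free_sig = set(range(k))
    free_ref = set(range(r))
    while free_sig and free_ref:
        best = max(
            ((i, j) for i in free_sig for j in free_ref), key=lambda ij: C[ij[0], ij[1]]
        )
        i, j = best
        if C[i, j] < min_cosine:
            break
        out[i] = (refs.names[j], float(C[i, j]))
        free_sig.remove(i)
        free_ref.remove(j)
    for i in free_sig:
        j = int(np.argmax(C[i])) if r else 0
        out[i] = (None, float(C[i, j]) if r else 0.0)
    return [(i, out[i][0], out[i][1]) for i in range(k)]


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class MutationalSignatureModel:
    """De novo signature model over a 96 x n motif-count matrix.

    Parameters
    ----------
    spectra
        96 x n_samples array or DataFrame of motif counts in canonical
        order (e.g. the output of :func:`sigstrat.spectrum.spectra_matrix`).
    sample_ids
        Column labels; inferred from a DataFrame.
    """

    def __init__(self, spectra, sample_ids: list[str] | None = None):
        if isinstance(spectra, pd.DataFrame):
            self.sample_ids = [str(c) for c in spectra.columns]
            self.V = spectra.to_numpy(dtype=float)
        else:
            self.V = np.asarray(spectra, dtype=float)
            self.sample_ids = sample_ids or [f"sample{i+1}" for i in range(self.V.shape[1])]
        if self.V.shape[0] != 96:
            raise ValueError(f"expected 96 motif rows, got {self.V.shape[0]}")

    @classmethod
    def from_records(cls, records) -> "MutationalSignatureModel":
        from .spectrum import build_spectra, spectra_matrix

        return cls(spectra_matrix(build_spectra(records)))

    def fit(self, rank: int, seed: int | None = None, n_restarts: int = 1,
            max_iter: int = 500, tol: float = 1e-6) -> "SignatureResults":
        """Best-of-``n_restarts`` KL-NMF factorization at a fixed rank."""
        streams = np.random.SeedSequence(seed).generate_state(n_restarts)
        best: NmfRun | None = None
        for s in streams:
            run = nmf_factorize(self.V, rank, seed=int(s % (2**31 - 1)), max_iter=max_iter, tol=tol)
            if best is None or run.objective < best.objective:
                best = run
        return SignatureResults(model=self, run=best)

    def select_rank(self, rank_range=(1, 4), n_restarts: int = 500, seed: int | None = None,
                    **kwargs) -> RankSelection:
        return select_rank(self.V, rank_range=rank_range, n_restarts=n_restarts, seed=seed, **kwargs)


class SignatureResults:
    """A fitted de novo decomposition with its goodness-of-fit statistics."""

    def __init__(self, model: MutationalSignatureModel, run: NmfRun):
        self.model = model
        self.run = run
        self.W = run.W
        self.H = run.H
        self.rank = run.rank
        self.objective = run.objective
        self.rss = residual_sum_of_squares(model.V, run.W, run.H)
        self.explained_variance = explained_variance(model.V, run.W, run.H)

    @property
    def signature_names(self) -> list[str]:
        return [f"signature{i+1}" for i in range(self.rank)]

    def signatures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=list(MOTIF_ORDER), columns=self.signature_names)

    def exposures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.H, index=self.signature_names, columns=self.model.sample_ids)

    def match_references(self, refs: ReferenceSignatureSet, min_cosine: float = 0.6):
        return match_to_reference(self.W, refs, min_cosine=min_cosine)

    def summary(self) -> pd.DataFrame:
        expo = self.H.sum(axis=1)
        frac = expo / expo.sum() if expo.sum() > 0 else expo
        df = pd.DataFrame(
            {
                "signature": self.signature_names,
                "total_exposure": expo,
                "exposure_fraction": frac,
            }
        )
        df.attrs["rank"] = self.rank
        df.attrs["rss"] = self.rss
        df.attrs["explained_variance"] = self.explained_variance
        df.attrs["kl_objective"] = self.objective
        return df

    def plot_signatures(self, axes=None):
        """Bar plot of each signature over the 96 motifs (one axis per signature)."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(self.rank, 1, figsize=(12, 2.2 * self.rank), sharex=True)
        axes = np.atleast_1d(axes)
        colors = np.repeat(
            ["#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63", "#EBC6C4"], 16
        )
        for ax, name, col in zip(axes, self.signature_names, self.W.T):
            ax.bar(range(96), col, color=colors, width=0.8)
            ax.set_ylabel(name)
            ax.set_xlim(-1, 96)
        axes[-1].set_xticks(range(0, 96, 16))
        axes[-1].set_xticklabels([s for s in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")])
        return axes
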