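"""Supervised exposure fitting against a fixed reference signature set.

A 96-motif spectrum s is decomposed into non-negative exposures e of the
reference signatures R by non-negative least squares,
min ||s - R e||_2 s.t. e >= 0, the linear-combination-decomposition
convention used for COSMIC signature refitting.  Exposures below a
relative pruning threshold are zeroed and the fit re-solved on the
remaining support, guarding against signature bleed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import ReferenceSignatureSet
from .spectrum import MutationalSpectrum


class ExposureProfile:
    """Non-negative exposures of one unit (sample or subgroup)."""

    def __init__(self, unit: str, names: list[str], exposures: np.ndarray, residual: float):
        self.unit = unit
        self.names = list(names)
        self.exposures = np.asarray(exposures, dtype=float)
        self.residual = float(residual)

    @property
    def fractions(self) -> np.ndarray:
        total = self.exposures.sum()
        return self.exposures / total if total > 0 else self.exposures.copy()

    def as_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=self.names, name=self.unit)


def fit_exposures(
    spectrum,
    refs: ReferenceSignatureSet,
    unit: str = "sample",
    prune_fraction: float = 0.01,
) -> ExposureProfile:
    """NNLS decomposition of one 96-vector into reference exposures.

    ``spectrum`` may be a :class:`MutationalSpectrum` or a raw 96-vector.
    Exposures below ``prune_fraction`` of the total exposure are set to
    zero and the fit is re-solved on the surviving support (deterministic
    active-set solver).
    """
    if isinstance(spectrum, MutationalSpectrum):
        unit = spectrum.sample_id
        s = spectrum.counts.astype(float)
    else:
        s = np.asarray(spectrum, dtype=float)
    if s.shape != (96,):
        raise ValueError(f"spectrum must be a 96-vector, got shape {s.shape}")
    if (s < 0).any():
        raise ValueError("spectrum must be non-negative")
    if s.sum() == 0:
        raise ValueError("cannot fit an all-zero spectrum")
    R = refs.matrix
    e, res = nnls(R, s)
    total = e.sum()
    if total > 0 and prune_fraction > 0:
        support = e >= prune_fraction * total
        if support.any() and not support.all():
            e2 = np.zeros_like(e)
            sol, res = nnls(R[:, support], s)
            e2[support] = sol
            e = e2
        elif not support.any():
            e = np.zeros_like(e)
            res = float(np.linalg.norm(s))
    return ExposureProfile(unit=unit, names=refs.names, exposures=e, residual=res)


def subgroup_exposures(
    spectra: list[MutationalSpectrum],
    labels: dict,
    refs: ReferenceSignatureSet,
    prune_fraction: float = 0.01,
) -> tuple[list[ExposureProfile], list[ExposureProfile]]:
    """Pooled per-subgroup exposures plus per-sample profiles.

    ``labels`` maps every sample_id to its subgroup; spectra of a subgroup
    are summed and the pooled spectrum fitted.  Returns
    (subgroup profiles in first-appearance order, per-sample profiles).
    """
    missing = [s.sample_id for s in spectra if s.sample_id not in labels]
    if missing:
        raise ValueError(f"no subgroup label for sample(s): {missing[:5]}")
    order: list[str] = []
    pooled: dict[str, np.ndarray] = {}
    for sp in spectra:
        g = labels[sp.sample_id]
        if g not in pooled:
            pooled[g] = np.zeros(96, dtype=float)
            order.append(g)
        pooled[g] += sp.counts
    group_profiles = [
        fit_exposures(pooled[g], refs, unit=g, prune_fraction=prune_fraction) for g in order
    ]
    sample_profiles = [
        fit_exposures(sp, refs, prune_fraction=prune_fraction) for sp in spectra
    ]
    return group_profiles, sample_profiles


def exposures_frame(profiles: list[ExposureProfile], fractions: bool = False) -> pd.DataFrame:
    """Profiles as a signatures x units DataFrame."""
    if not profiles:
        return pd.DataFrame()
    data = {
        p.unit: (p.fractions if fractions else p.exposures) for p in profiles
    }
    return pd.DataFrame(data, index=profiles[0].names)


class ReferenceExposureModel:
    """Model object for supervised refitting against one reference set."""

    def __init__(self, refs: ReferenceSignatureSet, prune_fraction: float = 0.01):
        self.refs = refs
        self.prune_fraction = prune_fraction

    def fit(self, spectrum, unit: str = "sample") -> "ExposureResults":
        profile = fit_exposures(spectrum, self.refs, unit=unit, prune_fraction=self.prune_fraction)
        return ExposureResults(self, [profile], None)

    def fit_groups(self, spectra: list[MutationalSpectrum], labels: dict) -> "ExposureResults":
        groups, samples = subgroup_exposures(
            spectra, labels, self.refs, prune_fraction=self.prune_fraction
        )
        return ExposureResults(self, groups, samples)


class ExposureResults:
    def __init__(self, model, profiles, sample_profiles):
        self.model = model
        self.profiles = profiles
        self.sample_profiles = sample_profiles

    def summary(self, fractions: bool = True) -> pd.DataFrame:
        return exposures_frame(self.profiles, fractions=fractions)

    def plot(self, ax=None, fractions: bool = True):
        """Stacked bars of exposures per unit."""
        import matplotlib.pyplot as plt

        df = self.summary(fractions=fractions)
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 + 0.8 * df.shape[1], 4))
        bottom = np.zeros(df.shape[1])
        for name, row in df.iterrows():
            ax.bar(df.columns, row.values, bottom=bottom, label=name)
            bottom += row.values
        ax.set_ylabel("exposure fraction" if fractions else "exposure")
        ax.legend(fontsize=7, ncol=2)
        return ax
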