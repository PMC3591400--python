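"""Median normalisation and Z-statistic significance of protein log2 ratios.

Under a 1:1 light/heavy mixture the bulk (unregulated) proteome should
centre at log2 = 0; a global shift reflects imperfect pooling and is removed
by subtracting the per-fraction median.  Normalised ratios of null proteins
are modelled as Gaussian around 0 with scale sigma, estimated either as the
sample standard deviation (default) or the Gaussian-consistent MAD
(1.4826 x median absolute deviation, robust to a regulated minority).  Each
protein then gets a two-sided standard-normal p-value at
z = norm_log2 / sigma, and proteins with p < alpha are called significantly
regulated.

One-channel proteins (no detectable signal in one isotope channel) sit
beyond any measurable ratio: they are excluded from the median/sigma fit,
assigned p = 0 by convention (rendered "0.000"), and always called
significant.

:class:`RatioSignificanceModel` wraps this procedure in a fit/results pair;
the functional surface (:func:`normalize_median`, :func:`fit_scale`,
:func:`z_pvalues`, :func:`significant_set`) operates on the pipeline's
protein records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .evidence import OneChannel, ProteinQuant, Tier

__all__ = [
    "RatioDistribution",
    "RatioSignificanceModel",
    "RatioSignificanceResults",
    "normalize_median",
    "fit_scale",
    "z_pvalues",
    "apply_significance",
    "significant_set",
]

#: Gaussian-consistency factor for the MAD scale estimator.
MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class RatioDistribution:
    """Fitted location/scale of one fraction's protein log2-ratio distribution."""

    fraction: str
    n: int
    median: float
    sigma: float
    estimator: str


def normalize_median(values: Iterable[float]) -> tuple[np.ndarray, float]:
    """Centre finite log2 ratios on their median.

    Returns ``(values - median, median)``.  Requires at least 3 finite
    ratios; NaNs pass through untouched.
    """
    arr = np.asarray(list(values), dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 3:
        raise ValueError(
            f"median normalisation needs >= 3 finite ratios, got {finite.size}"
        )
    med = float(np.median(finite))
    return arr - med, med


def fit_scale(values: Iterable[float], estimator: str = "sd") -> float:
    """Scale of the (normalised) ratio distribution.

    ``sd``: sample standard deviation (ddof=1).  ``mad``: 1.4826 x median
    absolute deviation, consistent for the Gaussian sigma and insensitive to
    a regulated minority.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError("scale estimation needs >= 3 finite ratios")
    if estimator == "sd":
        sigma = float(np.std(arr, ddof=1))
    elif estimator == "mad":
        sigma = MAD_TO_SIGMA * float(np.median(np.abs(arr - np.median(arr))))
    else:
        raise ValueError(f"unknown scale estimator {estimator!r}")
    if sigma <= 0:
        raise ValueError("ratio distribution has zero spread; cannot test")
    return sigma


def z_pvalues(norm_values: Iterable[float], sigma: float) -> np.ndarray:
    """Two-sided standard-normal p-values: p = 2*(1 - Phi(|x| / sigma))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = np.asarray(list(norm_values), dtype=float)
    return 2.0 * _st.norm.sf(np.abs(arr) / sigma)


class RatioSignificanceModel:
    """Gaussian null model for a fraction's normalised protein log2 ratios.

    Parameters
    ----------
    ratios : array-like of float
        Protein-level log2(L/H) values (NaN allowed: excluded from the fit
        and returned with NaN p-values).
    fit_mask : array-like of bool, optional
        Subset used to estimate median and sigma (e.g. only unambiguous-tier
        proteins); p-values are still computed for every ratio.
    """

    def __init__(
        self,
        ratios,
        fraction: str = "",
        scale_estimator: str = "sd",
        fit_mask=None,
    ) -> None:
        self.ratios = np.asarray(ratios, dtype=float)
        self.fraction = fraction
        self.scale_estimator = scale_estimator
        if fit_mask is None:
            self.fit_mask = np.ones(self.ratios.shape, dtype=bool)
        else:
            self.fit_mask = np.asarray(fit_mask, dtype=bool)
            if self.fit_mask.shape != self.ratios.shape:
                raise ValueError("fit_mask must match ratios in shape")

    def fit(self) -> "RatioSignificanceResults":
        fit_values = self.ratios[self.fit_mask]
        _, median = normalize_median(fit_values)
        normalized = self.ratios - median
        sigma = fit_scale(fit_values - median, self.scale_estimator)
        pvalues = np.full_like(self.ratios, np.nan)
        finite = np.isfinite(normalized)
        pvalues[finite] = z_pvalues(normalized[finite], sigma)
        return RatioSignificanceResults(
            model=self,
            distribution=RatioDistribution(
                fraction=self.fraction,
                n=int(np.isfinite(fit_values).sum()),
                median=median,
                sigma=sigma,
                estimator=self.scale_estimator,
            ),
            normalized=normalized,
            pvalues=pvalues,
        )


@dataclass
class RatioSignificanceResults:
    """Fit results: normalised ratios, p-values, BH q-values, summary table."""

    model: RatioSignificanceModel
    distribution: RatioDistribution
    normalized: np.ndarray
    pvalues: np.ndarray

    @property
    def qvalues(self) -> np.ndarray:
        """Benjamini-Hochberg adjusted p-values (informational; the primary
        call thresholds the raw p-values)."""
        q = np.full_like(self.pvalues, np.nan)
        ok = np.isfinite(self.pvalues)
        if ok.any():
            q[ok] = multipletests(self.pvalues[ok], method="fdr_bh")[1]
        return q

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        return np.isfinite(self.pvalues) & (self.pvalues < alpha)

    def summary(self, alpha: float = 0.05) -> str:
        d = self.distribution
        lines = [
            "Ratio significance (Gaussian null, Z statistic)",
            f"  fraction:        {d.fraction or '-'}",
            f"  n (fit):         {d.n}",
            f"  median (log2):   {d.median:+.4f}  (subtracted)",
            f"  sigma ({d.estimator}):      {d.sigma:.4f}",
            f"  significant:     {int(self.significant_mask(alpha).sum())}"
            f" of {int(np.isfinite(self.pvalues).sum())} at p < {alpha:g}",
        ]
        return "\n".join(lines)


def apply_significance(
    quants: Sequence[ProteinQuant],
    fraction: str = "",
    scale_estimator: str = "sd",
    fit_tier: Tier | None = Tier.UNAMBIGUOUS,
) -> RatioDistribution:
    """Normalise and test a fraction's protein records in place.

    The median and sigma come from finite ratios of ``fit_tier`` proteins
    (all finite ratios when None); every record then receives norm_log2,
    p_value and q_value.  One-channel records keep their sentinel, get
    p = 0.0 and are excluded from the fit.
    """
    ratios = np.array(
        [math.nan if q.is_one_channel else q.log2_lh for q in quants], dtype=float
    )
    if fit_tier is None:
        mask = np.ones(len(quants), dtype=bool)
    else:
        mask = np.array([q.tier == fit_tier for q in quants], dtype=bool)
    results = RatioSignificanceModel(
        ratios, fraction=fraction, scale_estimator=scale_estimator,
        fit_mask=mask,
    ).fit()
    qvals = results.qvalues
    for i, q in enumerate(quants):
        if q.is_one_channel:
            q.norm_log2 = q.log2_lh
            q.p_value = 0.0
            q.q_value = 0.0
        else:
            q.norm_log2 = float(results.normalized[i])
            q.p_value = float(results.pvalues[i])
            q.q_value = float(qvals[i])
    return results.distribution


def significant_set(
    quants: Sequence[ProteinQuant],
    alpha: float = 0.05,
    require_tier: Tier | None = Tier.UNAMBIGUOUS,
) -> list[ProteinQuant]:
    """Proteins called significantly regulated: p < alpha (one-channel
    records are significant by convention), restricted to ``require_tier``.

    Ordered as in the report: over-expressed (positive normalised ratio or
    light-only) before lower-expressed, each sorted by |ratio| descending
    with one-channel sentinels first.
    """
    chosen = [
        q
        for q in quants
        if (require_tier is None or q.tier == require_tier)
        and (q.is_one_channel or (math.isfinite(q.p_value) and q.p_value < alpha))
    ]

    def key(q: ProteinQuant):
        over = q.norm_log2 is OneChannel.LIGHT_ONLY or (
            not q.is_one_channel and q.finite_norm > 0
        )
        mag = math.inf if q.is_one_channel else abs(q.finite_norm)
        return (0 if over else 1, 0 if q.is_one_channel else 1, -mag, q.accession)

    return sorted(chosen, key=key)
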