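"""Sides-by-individuals mixed ANOVA and the FA/ME index family.

The model behind everything here is the balanced two-way mixed ANOVA for
replicated bilateral measurements: sides (left/right, fixed, 2 levels) crossed
with individuals (random, J levels), M replicate measurements per cell.  Its
strata separate the four biological signals of interest:

* sides main effect      -> directional asymmetry (DA),
* individuals            -> between-individual size variation,
* sides x individuals    -> non-directional asymmetry (FA), variance ``sigma2_i``,
* replicates-within-cell -> measurement error (ME), variance ``sigma2_m``.

From the interaction and error mean squares the FA variance component is
``sigma2_i = (MS_interaction - MS_error) / M`` (clamped at zero), and the
index family follows:

* ``FA1  = mean(|R_i - L_i|)`` on side means,
* ``FA4a = sqrt(2/pi) * sqrt(var(R_i - L_i))``,
* ``FA10a = sqrt(2/pi) * sqrt(2 * sigma2_i)`` — the ME-corrected magnitude of
  FA, i.e. the expected mean absolute asymmetry had each side been measured
  without error,
* ``ME3% = 100 * sigma2_m / (sigma2_i + sigma2_m)`` — the share of the
  non-directional between-sides variance attributable to ME; repeatability is
  its complement.

``sqrt(2/pi) ~ 0.798`` converts the standard deviation of a centred normal to
its mean absolute value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import TraitMatrix

__all__ = [
    "HALF_NORMAL",
    "AnovaDecomposition",
    "VarianceComponents",
    "FAReport",
    "SidesByIndividualsANOVA",
    "side_means",
    "fit_sides_anova",
    "variance_components",
    "fa_indices",
]

#: E|X| / sd(X) for a centred normal: sqrt(2/pi).
HALF_NORMAL = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class AnovaDecomposition:
    """Mean squares of the balanced sides x individuals model."""

    ms_sides: float        # df = 1
    ms_individuals: float  # df = J - 1
    ms_interaction: float  # df = J - 1
    ms_error: float        # df = 2 J (M - 1)
    n_individuals: int
    n_replicates: int

    @property
    def df_interaction(self) -> int:
        return self.n_individuals - 1

    @property
    def df_error(self) -> int:
        return 2 * self.n_individuals * (self.n_replicates - 1)


@dataclass(frozen=True)
class VarianceComponents:
    """FA and ME variance components from the mixed-model mean squares."""

    sigma2_i: float  # non-directional between-sides (FA) component
    sigma2_m: float  # per-measurement error component
    clamped: bool    # raw sigma2_i estimate was negative and was set to 0


@dataclass(frozen=True)
class FAReport:
    """Per-trait asymmetry indices (mm) with the ME diagnostics."""

    fa1: float
    fa4a: float
    fa10a: float
    me3_percent: float   # NaN when sigma2_i + sigma2_m == 0
    repeatability: float  # 1 - me3_percent / 100
    n: int
    clamped: bool = False


def _as_array(tm) -> np.ndarray:
    if isinstance(tm, TraitMatrix):
        return tm.to_array()
    x = np.asarray(tm, dtype=float)
    if x.ndim != 3 or x.shape[1] != 2:
        raise ValueError("expected a TraitMatrix or (J, 2, M) array")
    if not np.isfinite(x).all():
        raise ValueError("measurements must be finite")
    return x


def side_means(tm) -> np.ndarray:
    """Per-individual side summaries.

    Returns a ``(J, 4)`` array of columns ``(Lbar_i, Rbar_i, d_i, s_i)`` with
    ``d_i = Rbar_i - Lbar_i`` (right minus left throughout) and
    ``s_i = (Rbar_i + Lbar_i) / 2``.
    """
    x = _as_array(tm)
    lbar = x[:, 0, :].mean(axis=1)
    rbar = x[:, 1, :].mean(axis=1)
    return np.column_stack([lbar, rbar, rbar - lbar, (rbar + lbar) / 2.0])


class SidesByIndividualsANOVA(BaseEstimator):
    """Balanced sides x individuals mixed ANOVA with the FA index family.

    A fit-only estimator in the scikit-learn idiom: ``fit`` takes one trait's
    balanced measurement block and exposes the decomposition, the variance
    components and the indices as fitted attributes.

    Parameters
    ----------
    clamp_negative : bool, default True
        Clamp a negative raw FA variance component at zero (flagged via
        ``clamped_``) instead of propagating it.

    Attributes
    ----------
    ms_sides_, ms_individuals_, ms_interaction_, ms_error_ : float
        Mean squares of the four strata.
    sigma2_i_, sigma2_m_ : float
        FA and ME variance components.
    fa1_, fa4a_, fa10a_, me3_percent_, repeatability_ : float
        Index family (see module docstring).
    n_individuals_, n_replicates_ : int
    clamped_ : bool
    """

    def __init__(self, clamp_negative: bool = True):
        self.clamp_negative = clamp_negative

    def fit(self, X, y=None):
        """Fit on a :class:`~flucasym.io.TraitMatrix` or ``(J, 2, M)`` array."""
        x = _as_array(X)
        j, _, m = x.shape
        if j < 2:
            raise ValueError("need at least 2 individuals")
        if m < 2:
            raise ValueError(
                "no replicate stratum: M = 1 leaves the error mean square undefined"
            )
        grand = x.mean()
        cell = x.mean(axis=2)              # (J, 2)
        ind = cell.mean(axis=1)            # (J,)
        side = cell.mean(axis=0)           # (2,)

        ss_sides = j * m * float(((side - grand) ** 2).sum())
        ss_ind = 2 * m * float(((ind - grand) ** 2).sum())
        resid = cell - ind[:, None] - side[None, :] + grand
        ss_inter = m * float((resid ** 2).sum())
        ss_err = float(((x - cell[:, :, None]) ** 2).sum())

        self.n_individuals_ = j
        self.n_replicates_ = m
        self.ss_total_ = float(((x - grand) ** 2).sum())
        self.ms_sides_ = ss_sides / 1.0
        self.ms_individuals_ = ss_ind / (j - 1)
        self.ms_interaction_ = ss_inter / (j - 1)
        self.ms_error_ = ss_err / (2 * j * (m - 1))

        raw = (self.ms_interaction_ - self.ms_error_) / m
        self.clamped_ = bool(raw < 0) and self.clamp_negative
        self.sigma2_i_ = max(0.0, raw) if self.clamp_negative else raw
        self.sigma2_m_ = self.ms_error_

        d = side_means(x)[:, 2]
        self.fa1_ = float(np.abs(d).mean())
        self.fa4a_ = HALF_NORMAL * math.sqrt(float(np.var(d, ddof=1)))
        self.fa10a_ = HALF_NORMAL * math.sqrt(2.0 * max(0.0, self.sigma2_i_))
        total = self.sigma2_i_ + self.sigma2_m_
        if total <= 0:
            warnings.warn(
                "sigma2_i + sigma2_m is zero: ME3 and repeatability undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            self.me3_percent_ = float("nan")
            self.repeatability_ = float("nan")
        else:
            self.me3_percent_ = 100.0 * self.sigma2_m_ / total
            self.repeatability_ = 1.0 - self.me3_percent_ / 100.0
        return self

    # -- views -------------------------------------------------------------

    def decomposition_(self) -> AnovaDecomposition:
        return AnovaDecomposition(
            ms_sides=self.ms_sides_,
            ms_individuals=self.ms_individuals_,
            ms_interaction=self.ms_interaction_,
            ms_error=self.ms_error_,
            n_individuals=self.n_individuals_,
            n_replicates=self.n_replicates_,
        )

    def components_(self) -> VarianceComponents:
        return VarianceComponents(
            sigma2_i=self.sigma2_i_, sigma2_m=self.sigma2_m_, clamped=self.clamped_
        )

    def report_(self) -> FAReport:
        return FAReport(
            fa1=self.fa1_,
            fa4a=self.fa4a_,
            fa10a=self.fa10a_,
            me3_percent=self.me3_percent_,
            repeatability=self.repeatability_,
            n=self.n_individuals_,
            clamped=self.clamped_,
        )


def fit_sides_anova(tm) -> AnovaDecomposition:
    """Mean squares of the sides x individuals model for one trait."""
    return SidesByIndividualsANOVA().fit(tm).decomposition_()


def variance_components(a: AnovaDecomposition) -> VarianceComponents:
    """FA and ME variance components from a decomposition.

    ``sigma2_i = max(0, (MS_interaction - MS_error) / M)`` (clamped negative
    estimates are flagged); ``sigma2_m = MS_error``.
    """
    raw = (a.ms_interaction - a.ms_error) / a.n_replicates
    return VarianceComponents(
        sigma2_i=max(0.0, raw), sigma2_m=a.ms_error, clamped=bool(raw < 0)
    )


def fa_indices(tm) -> FAReport:
    """FA1, FA4a, FA10a, ME3% and repeatability for one trait."""
    return SidesByIndividualsANOVA().fit(tm).report_()
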