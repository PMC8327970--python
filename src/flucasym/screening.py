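"""Confounder screening for FA analyses.

Before a fluctuating-asymmetry index is interpretable, each trait's signed
side difference ``d_i = Rbar_i - Lbar_i`` must be screened for the classical
confounders:

* **directional asymmetry (DA)** — a consistently larger side.  The primary
  flag here is a significant skew of ``d`` (D'Agostino standardized skewness
  test); the conventional mean-shift one-sample t test is computed alongside
  and can be made the flagging rule.
* **antisymmetry (AS)** — asymmetry of random side, producing a platykurtic
  or bimodal ``d`` distribution; flagged by a one-sided (platykurtic)
  Anscombe-Glynn kurtosis test.
* **trait-size dependency** — |d| growing with trait size, flagged by a
  Spearman rank correlation of ``|d_i|`` with the individual trait size
  ``s_i = (Rbar_i + Lbar_i)/2``.
* **aberrant individuals** — iterative two-sided Grubbs outlier test on
  ``d``; flagged indices are reported, removal is the caller's choice.

The moment tests need J >= 8; below that the screens are reported as
not-evaluable and the verdict is "clean" with a warning flag.

:func:`replicate_scan` supports the choice of how many replicate measurement
trials to keep: it recomputes the per-variable ME3 percentage over contiguous
replicate subsets and summarizes each subset across variables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .anova import SidesByIndividualsANOVA, side_means
from .io import TraitMatrix, build_trait_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult",
    "AsymmetryScreen",
    "grubbs_outliers",
    "screen_trait",
    "EliminationRules",
    "apply_elimination",
    "replicate_scan",
]

_MIN_J_MOMENTS = 8


@dataclass(frozen=True)
class ScreeningResult:
    """Screening statistics and verdict for one trait stratum."""

    trait_key: tuple
    n: int
    skewness: float
    skew_p: float
    excess_kurtosis: float
    kurtosis_p: float          # one-sided toward platykurtosis
    mean_d: float
    mean_d_t: float
    mean_d_p: float
    size_dependency_rho: float
    size_dependency_p: float
    outlier_indices: tuple[int, ...]
    verdict: str               # clean | DA | AS | size_dependent
    evaluable: bool = True     # False when J < 8 or d is constant


def platykurtosis_test(d: np.ndarray) -> tuple[float, float]:
    """One-sided (platykurtic) Anscombe-Glynn kurtosis test: (z, p).

    Uses the standardized kurtosis statistic of :func:`scipy.stats.kurtosistest`
    but takes the tail direction from the pre-transform standardized fourth
    moment: the Anscombe-Glynn cube-root transform changes branch for extremely
    platykurtic samples (e.g. well-separated bimodal data) and then reports a
    spuriously positive statistic.  p is the lower-tail normal probability, so
    small p means evidence of platykurtosis.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    z, _ = stats.kurtosistest(d)
    b2 = stats.kurtosis(d, fisher=False, bias=True)
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    x = (b2 - e_b2) / math.sqrt(var_b2)
    if x != 0 and np.sign(z) != np.sign(x):  # transform branch flipped
        z = math.copysign(abs(z), x)
    return float(z), float(stats.norm.cdf(z))


def grubbs_outliers(d: np.ndarray, alpha: float = 0.05) -> tuple[int, ...]:
    """Iterative two-sided Grubbs test; returns flagged indices into ``d``.

    At each pass the most extreme deviate is tested against the Grubbs
    critical value ``(N-1)/sqrt(N) * sqrt(t^2 / (N-2+t^2))`` with
    ``t = t_{1-alpha/(2N), N-2}``; a significant datum is set aside and the
    test repeats on the remainder until no datum is flagged or N < 3.
    The decision is location- and scale-invariant in ``d``.
    """
    d = np.asarray(d, dtype=float)
    active = list(range(d.size))
    flagged: list[int] = []
    while len(active) >= 3:
        sub = d[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        imax = int(np.argmax(dev))
        n = len(active)
        g = dev[imax] / sd
        t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
        if g > crit:
            flagged.append(active.pop(imax))
        else:
            break
    return tuple(sorted(flagged))


class AsymmetryScreen(BaseEstimator):
    """Confounder screen on per-individual side differences.

    Parameters
    ----------
    alpha : float, default 0.05
        Significance level shared by every screen.
    da_rule : {"skew", "t", "either"}, default "skew"
        Which statistic flags DA: the skewness test (the field's screening
        convention for replicated data), the mean-shift t test, or either.

    Attributes (after ``fit(d, s)``)
    --------------------------------
    skewness_, skew_p_, excess_kurtosis_, kurtosis_p_, mean_d_t_, mean_d_p_,
    size_rho_, size_p_ : float
    outlier_indices_ : tuple of int
    verdict_ : str
    evaluable_ : bool
    """

    def __init__(self, alpha: float = 0.05, da_rule: str = "skew"):
        self.alpha = alpha
        self.da_rule = da_rule

    def fit(self, d, s=None):
        """Screen side differences ``d`` (and trait sizes ``s``, if given)."""
        if self.da_rule not in ("skew", "t", "either"):
            raise ValueError(f"unknown da_rule: {self.da_rule!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        d = np.asarray(d, dtype=float)
        n = d.size
        nan = float("nan")
        self.n_ = n
        self.mean_d_ = float(d.mean()) if n else nan
        self.evaluable_ = n >= _MIN_J_MOMENTS and float(np.ptp(d)) > 0
        if not self.evaluable_:
            logger.warning(
                "screen not evaluable (J=%d%s): verdict clean-with-warning",
                n, ", constant d" if n and np.ptp(d) == 0 else "",
            )
            self.skewness_ = self.skew_p_ = nan
            self.excess_kurtosis_ = self.kurtosis_p_ = nan
            self.mean_d_t_ = self.mean_d_p_ = nan
            self.size_rho_ = self.size_p_ = nan
            self.outlier_indices_ = ()
            self.verdict_ = "clean"
            return self

        self.skewness_ = float(stats.skew(d, bias=False))
        _, self.skew_p_ = stats.skewtest(d)
        self.excess_kurtosis_ = float(stats.kurtosis(d, fisher=True, bias=False))
        _, self.kurtosis_p_ = platykurtosis_test(d)
        t, p = stats.ttest_1samp(d, 0.0)
        self.mean_d_t_, self.mean_d_p_ = float(t), float(p)
        if s is not None:
            s = np.asarray(s, dtype=float)
            rho, rho_p = stats.spearmanr(np.abs(d), s)
            self.size_rho_, self.size_p_ = float(rho), float(rho_p)
        else:
            self.size_rho_ = self.size_p_ = nan
        self.outlier_indices_ = grubbs_outliers(d, self.alpha)

        a = self.alpha
        da = {
            "skew": self.skew_p_ < a,
            "t": self.mean_d_p_ < a,
            "either": self.skew_p_ < a or self.mean_d_p_ < a,
        }[self.da_rule]
        antisym = self.kurtosis_p_ < a and self.excess_kurtosis_ < 0
        sized = (not math.isnan(self.size_p_)) and self.size_p_ < a
        if da:
            self.verdict_ = "DA"
        elif antisym:
            self.verdict_ = "AS"
        elif sized:
            self.verdict_ = "size_dependent"
        else:
            self.verdict_ = "clean"
        return self

    def result_(self, trait_key: tuple = ()) -> ScreeningResult:
        return ScreeningResult(
            trait_key=trait_key,
            n=self.n_,
            skewness=self.skewness_,
            skew_p=self.skew_p_,
            excess_kurtosis=self.excess_kurtosis_,
            kurtosis_p=self.kurtosis_p_,
            mean_d=self.mean_d_,
            mean_d_t=self.mean_d_t_,
            mean_d_p=self.mean_d_p_,
            size_dependency_rho=self.size_rho_,
            size_dependency_p=self.size_p_,
            outlier_indices=self.outlier_indices_,
            verdict=self.verdict_,
            evaluable=self.evaluable_,
        )


def screen_trait(tm: TraitMatrix, alpha: float = 0.05, da_rule: str = "skew") -> ScreeningResult:
    """Run the full confounder screen on one trait matrix."""
    sm = side_means(tm)
    screen = AsymmetryScreen(alpha=alpha, da_rule=da_rule).fit(sm[:, 2], sm[:, 3])
    key = tm.trait_key if isinstance(tm, TraitMatrix) else ()
    return screen.result_(trait_key=key)


@dataclass(frozen=True)
class EliminationRules:
    """Which screening verdicts eliminate a trait variable.

    The default alpha is deliberately stricter than the per-screen 0.05: an
    elimination pass over a full study roster runs on the order of a hundred
    screen tests, and a 0.05 rule would discard several clean variables by
    chance alone.  Eliminations should reflect overwhelming signals.
    """

    drop_da: bool = True
    drop_as: bool = True
    drop_size_dependent: bool = True
    alpha: float = 0.001
    da_rule: str = "either"


def apply_elimination(
    results: Mapping[tuple, ScreeningResult] | Iterable[ScreeningResult],
    rules: EliminationRules | None = None,
) -> tuple[list[tuple], pd.DataFrame]:
    """Apply elimination rules to screening results.

    Re-evaluates each screen's p-values at ``rules.alpha`` (verdict priority
    DA > AS > size dependency) and returns ``(retained_keys, ledger)`` where
    the ledger has one row per eliminated variable (``trait_key, reason,
    statistic, p``).  An empty retained list is legal and warned about.
    """
    rules = rules or EliminationRules()
    if isinstance(results, Mapping):
        items = list(results.values())
    else:
        items = list(results)
    retained: list[tuple] = []
    rows = []
    a = rules.alpha
    for r in items:
        reason = None
        if r.evaluable:
            da = {
                "skew": r.skew_p < a,
                "t": r.mean_d_p < a,
                "either": r.skew_p < a or r.mean_d_p < a,
            }[rules.da_rule]
            if rules.drop_da and da:
                stat = r.skew_p if r.skew_p < a else r.mean_d_p
                reason = ("DA", r.skewness if r.skew_p < a else r.mean_d_t, stat)
            elif rules.drop_as and r.kurtosis_p < a and r.excess_kurtosis < 0:
                reason = ("AS", r.excess_kurtosis, r.kurtosis_p)
            elif rules.drop_size_dependent and not math.isnan(r.size_dependency_p) \
                    and r.size_dependency_p < a:
                reason = ("size_dependent", r.size_dependency_rho, r.size_dependency_p)
        if reason is None:
            retained.append(r.trait_key)
        else:
            rows.append(
                {"trait_key": r.trait_key, "reason": reason[0],
                 "statistic": reason[1], "p": reason[2]}
            )
    if not retained:
        logger.warning("every trait was eliminated; retained list is empty")
    ledger = pd.DataFrame(rows, columns=["trait_key", "reason", "statistic", "p"])
    return retained, ledger


def _subset_range(subset) -> list[int]:
    if isinstance(subset, str):
        lo, _, hi = subset.replace("–", "-").partition("-")
        subset = range(int(lo), int(hi or lo) + 1)
    return sorted(int(r) for r in subset)


def replicate_scan(
    records: pd.DataFrame,
    subsets: Sequence,
) -> pd.DataFrame:
    """ME summary over contiguous replicate subsets.

    For each subset (a contiguous range, e.g. ``(1, 10)``, ``range(2, 6)`` or
    ``"2-5"``), trait matrices are rebuilt restricted to those replicate
    trials, per-variable ME3 percentages are computed, and the row reports

    * ``me3_pooled`` — ``100 * sum(sigma2_m) / sum(sigma2_i + sigma2_m)``
      across variables (components pooled before the ratio), and
    * ``mean, median, minimum, maximum, range`` of the per-variable ME3.

    Raises if a subset requests replicates absent from the data.
    """
    rows = []
    for subset in subsets:
        rng = _subset_range(subset if not isinstance(subset, tuple)
                            else range(subset[0], subset[1] + 1))
        label = f"{rng[0]}-{rng[-1]}"
        try:
            mats = build_trait_matrices(records, replicate_subset=rng)
        except ValueError as exc:
            raise ValueError(f"replicate subset {label}: {exc}") from exc
        me3 = []
        s2i_total = s2m_total = 0.0
        for tm in mats.values():
            if tm.n_replicates < 2:
                continue
            est = SidesByIndividualsANOVA().fit(tm)
            s2i_total += est.sigma2_i_
            s2m_total += est.sigma2_m_
            if not math.isnan(est.me3_percent_):
                me3.append(est.me3_percent_)
        me3 = np.asarray(me3, dtype=float)
        denom = s2i_total + s2m_total
        rows.append(
            {
                "subset": label,
                "me3_pooled": 100.0 * s2m_total / denom if denom > 0 else 0.0,
                "mean": me3.mean() if me3.size else 0.0,
                "median": float(np.median(me3)) if me3.size else 0.0,
                "minimum": me3.min() if me3.size else 0.0,
                "maximum": me3.max() if me3.size else 0.0,
                "range": float(np.ptp(me3)) if me3.size else 0.0,
                "n_variables": int(me3.size),
            }
        )
    return pd.DataFrame(rows)
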