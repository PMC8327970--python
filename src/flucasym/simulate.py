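"""Synthetic replicated bilateral measurement data with known structure.

The generative model mirrors the structure of a replicated dental-metric
study.  For individual ``i`` of a trait stratum:

* true trait size ``T_i ~ Normal(trait_mean, trait_sd^2)`` (mm),
* signed asymmetry ``A_i = da_offset + FA_i + AS_i`` with
  ``FA_i ~ Normal(0, sigma_fa_i^2)`` and, with probability ``as_prob``,
  an antisymmetric two-point term ``AS_i = +/- as_delta`` (fair sign),
* true sides ``R_i = T_i + A_i/2``, ``L_i = T_i - A_i/2``,
* observed replicate ``k`` adds independent ``Normal(0, sigma_me_k^2)``
  measurement noise per single reading,
* each (individual, side) cell is unmeasurable with ``missing_rate``.

``sigma_fa_i = sigma_fa * (T_i / trait_mean)**size_exponent`` lets trait-size
dependency of FA be planted (0 disables).  The closed-form variance of the
replicate-averaged side difference is
``var(d) = sigma_fa^2 + as_prob * as_delta^2 + 2 * mean(sigma_me^2) / M``.

Everything is reproducible: a dataset is a pure function of its config, and
a multi-trait study derives one independent substream per trait from a single
global seed, so any one trait can be regenerated alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import COLUMNS, TOOTH_ANATOMY, TraitMatrix

__all__ = [
    "SyntheticConfig",
    "STUDY_ROSTER",
    "simulate_trait_matrix",
    "simulate_dataset",
    "simulate_study",
    "make_study_configs",
]

#: the standard study roster: 2 sexes x 9 teeth x 2 metrics = 36 trait variables
STUDY_ROSTER: tuple[tuple[str, str, str], ...] = tuple(
    (sex, tooth, metric)
    for sex in ("female", "male")
    for tooth in sorted(TOOTH_ANATOMY)
    for metric in ("breadth", "length")
)


@dataclass(frozen=True)
class SyntheticConfig:
    """True generative parameters for one trait stratum.

    Defaults emulate a replicated baboon dental study: ~30 measurable
    individuals per trait, ten caliper replicates, crown dimensions around
    10 mm with ~10% between-individual size variation, an FA standard
    deviation of 0.03 mm (an FA10a near 0.034 mm, the scale of the published
    indices), 0.02 mm single-reading caliper noise, and no DA, antisymmetry
    or size dependency unless planted.
    """

    n_individuals: int = 30
    n_replicates: int = 10
    trait_mean: float = 10.0    # mm
    trait_sd: float = 1.0       # mm, between-individual size SD
    sigma_fa: float = 0.03      # mm, SD of the signed FA deviation
    da_offset: float = 0.0      # mm, mean of R - L
    as_delta: float = 0.0       # mm, half-separation of the antisymmetric mixture
    as_prob: float = 0.0        # mixture weight of the antisymmetric term
    sigma_me: float | tuple[float, ...] = 0.02  # mm per reading; scalar or per-trial
    size_exponent: float = 0.0  # FA scale grows as (T_i/trait_mean)**this
    missing_rate: float = 0.0   # P(an (individual, side) cell is unmeasurable)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2 or self.n_replicates < 1:
            raise ValueError("need n_individuals >= 2 and n_replicates >= 1")
        me = np.atleast_1d(np.asarray(self.sigma_me, dtype=float))
        if me.size not in (1, self.n_replicates):
            raise ValueError("sigma_me must be scalar or one value per replicate")
        if (me < 0).any() or self.trait_sd < 0 or self.sigma_fa < 0 or self.as_delta < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.as_prob <= 1:
            raise ValueError("as_prob must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def sigma_me_per_trial(self) -> np.ndarray:
        me = np.atleast_1d(np.asarray(self.sigma_me, dtype=float))
        return np.broadcast_to(me, (self.n_replicates,)).copy()

    def d_variance(self) -> float:
        """Closed-form variance of the replicate-averaged side difference."""
        me2 = float(np.mean(self.sigma_me_per_trial ** 2))
        return (
            self.sigma_fa ** 2
            + self.as_prob * self.as_delta ** 2
            + 2.0 * me2 / self.n_replicates
        )


def _rng_for(cfg: SyntheticConfig, trait_key=None, global_seed=None):
    if global_seed is None:
        return np.random.default_rng(np.random.SeedSequence(cfg.seed))
    tag = zlib.crc32("|".join(trait_key).encode()) if trait_key else 0
    return np.random.default_rng(np.random.SeedSequence(int(global_seed), spawn_key=(tag,)))


def _simulate_cells(cfg: SyntheticConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Observed (J, 2, M) block and (J, 2) missing-cell mask."""
    j, m = cfg.n_individuals, cfg.n_replicates
    t = rng.normal(cfg.trait_mean, cfg.trait_sd, size=j)
    scale = cfg.sigma_fa * np.power(np.maximum(t, 1e-9) / cfg.trait_mean, cfg.size_exponent)
    fa = rng.normal(0.0, 1.0, size=j) * scale
    has_as = rng.random(j) < cfg.as_prob
    signs = rng.choice([-1.0, 1.0], size=j)
    asym = cfg.da_offset + fa + np.where(has_as, signs * cfg.as_delta, 0.0)
    true_sides = np.stack([t - asym / 2.0, t + asym / 2.0], axis=1)  # (J, 2) L,R
    noise = rng.normal(0.0, 1.0, size=(j, 2, m)) * cfg.sigma_me_per_trial
    obs = true_sides[:, :, None] + noise
    missing = rng.random((j, 2)) < cfg.missing_rate
    return obs, missing


def simulate_trait_matrix(cfg: SyntheticConfig) -> TraitMatrix | None:
    """Simulate one trait and return the complete-case :class:`TraitMatrix`.

    Individuals with an unmeasurable side are dropped (complete case); returns
    None when fewer than two complete individuals remain.  Individual ids are
    ``i000, i001, ...`` in generation order.
    """
    rng = _rng_for(cfg)
    obs, missing = _simulate_cells(cfg, rng)
    keep = ~missing.any(axis=1)
    if keep.sum() < 2:
        return None
    ids = [f"i{i:03d}" for i in np.flatnonzero(keep)]
    return TraitMatrix(
        trait_key=("synthetic", "synthetic", "synthetic"),
        individuals=ids,
        left=obs[keep, 0, :],
        right=obs[keep, 1, :],
    )


def simulate_dataset(
    cfg: SyntheticConfig,
    sex: str = "female",
    tooth: str = "MXM1",
    metric: str = "length",
    _rng=None,
) -> pd.DataFrame:
    """Simulate one trait stratum as long-format measurement records.

    Output matches the canonical CSV schema; missing (individual, side) cells
    are simply absent.  Byte-identical for identical configs.
    """
    tooth = tooth.upper()
    if tooth not in TOOTH_ANATOMY:
        raise ValueError(f"unknown tooth code: {tooth!r}")
    arcade, tooth_class = TOOTH_ANATOMY[tooth]
    rng = _rng if _rng is not None else _rng_for(cfg)
    obs, missing = _simulate_cells(cfg, rng)
    j, m = cfg.n_individuals, cfg.n_replicates
    prefix = sex[0].upper()
    idx_i, idx_s = np.nonzero(~missing)
    rows = {
        "individual_id": np.repeat([f"{prefix}{i:03d}" for i in idx_i], m),
        "sex": sex,
        "tooth": tooth,
        "arcade": arcade,
        "tooth_class": tooth_class,
        "metric": metric,
        "side": np.repeat(np.where(idx_s == 0, "L", "R"), m),
        "replicate": np.tile(np.arange(1, m + 1), idx_i.size),
        "value_mm": obs[idx_i, idx_s, :].ravel(),
    }
    return pd.DataFrame(rows, columns=list(COLUMNS))


def simulate_study(
    configs: Mapping[tuple[str, str, str], SyntheticConfig]
    | Iterable[tuple[tuple[str, str, str], SyntheticConfig]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a multi-trait study from per-trait configs.

    ``configs`` maps ``(sex, tooth, metric)`` to a :class:`SyntheticConfig`
    (an iterable of pairs is accepted; duplicate keys are an error).  When
    ``seed`` is given it drives one deterministic, independent substream per
    trait key (the per-config seeds are ignored), so any trait can be
    regenerated in isolation from the same global seed.
    """
    if isinstance(configs, Mapping):
        pairs = list(configs.items())
    else:
        pairs = list(configs)
        keys = [k for k, _ in pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate trait keys in configs")
    frames = []
    for key, cfg in pairs:
        sex, tooth, metric = key
        rng = _rng_for(cfg, trait_key=key, global_seed=seed) if seed is not None else None
        frames.append(simulate_dataset(cfg, sex=sex, tooth=tooth, metric=metric, _rng=rng))
    return pd.concat(frames, ignore_index=True)


def make_study_configs(
    base: SyntheticConfig | None = None,
    overrides: Mapping[tuple[str, str, str], Mapping] | None = None,
    roster: Iterable[tuple[str, str, str]] = STUDY_ROSTER,
) -> dict[tuple[str, str, str], SyntheticConfig]:
    """Per-trait configs for a study roster, with per-trait field overrides.

    ``overrides`` maps trait keys to ``SyntheticConfig`` field replacements,
    e.g. ``{("male", "MNM1", "length"): {"da_offset": 0.5}}`` to plant DA.
    """
    base = base or SyntheticConfig()
    overrides = overrides or {}
    out = {}
    for key in roster:
        out[key] = replace(base, **overrides.get(key, {})) if key in overrides else base
    unknown = set(overrides) - set(out)
    if unknown:
        raise ValueError(f"overrides for traits not on the roster: {sorted(unknown)}")
    return out
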