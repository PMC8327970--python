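"""Data model and I/O for replicated bilateral measurements.

The canonical interchange format is a long (tidy) CSV, one row per single
caliper reading, with columns::

    individual_id,sex,tooth,arcade,tooth_class,metric,side,replicate,value_mm

Tooth codes combine arcade and tooth identity (``MN``/``MX`` + ``P3``, ``P4``,
``M1``, ``M2``, ``M3``); arcade and tooth class are redundant with the code and
are validated against it.  Values are crown dimensions in mm.

The substrate for all per-trait statistics is the :class:`TraitMatrix`: a
balanced J x 2 x M block (J individuals, left/right antimeres, M replicate
measurements) for one (sex, tooth, metric) stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "TOOTH_ANATOMY",
    "TraitMatrix",
    "ReadReport",
    "FormatError",
    "read_measurements",
    "write_measurements",
    "validate_measurements",
    "build_trait_matrices",
    "load_table2_fixture",
    "load_levene_reference",
]

#: Required columns of the long-format measurement CSV, in canonical order.
COLUMNS = (
    "individual_id",
    "sex",
    "tooth",
    "arcade",
    "tooth_class",
    "metric",
    "side",
    "replicate",
    "value_mm",
)

#: tooth code -> (arcade, tooth_class).  The mandibular third premolar is the
#: sectorial (canine-honing) tooth in cercopithecines and is not part of the
#: measurable roster.
TOOTH_ANATOMY: Mapping[str, tuple[str, str]] = {
    "MNP4": ("mandible", "premolar"),
    "MNM1": ("mandible", "molar"),
    "MNM2": ("mandible", "molar"),
    "MNM3": ("mandible", "molar"),
    "MXP3": ("maxilla", "premolar"),
    "MXP4": ("maxilla", "premolar"),
    "MXM1": ("maxilla", "molar"),
    "MXM2": ("maxilla", "molar"),
    "MXM3": ("maxilla", "molar"),
}

_SEXES = frozenset({"female", "male"})
_METRICS = frozenset({"length", "breadth"})
_SIDES = frozenset({"L", "R"})

#: unique key of a single reading
_KEY = ["individual_id", "tooth", "metric", "side", "replicate"]


class FormatError(ValueError):
    """Raised when a measurement file is structurally unreadable."""


@dataclass(frozen=True)
class ReadReport:
    """Row-level accounting for :func:`read_measurements`."""

    n_read: int
    n_dropped: int
    #: (1-based data row number, reason) for every rejected row
    dropped: tuple[tuple[int, str], ...] = ()

    @property
    def n_kept(self) -> int:
        return self.n_read - self.n_dropped


@dataclass
class TraitMatrix:
    """Balanced left/right replicate block for one trait stratum.

    Attributes
    ----------
    trait_key
        ``(sex, tooth, metric)`` identifying the stratum.
    individuals
        Ordered individual ids; rows of ``left`` and ``right`` align with it.
    left, right
        ``(J, M)`` arrays of mm readings.
    """

    trait_key: tuple[str, str, str]
    individuals: list[str]
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape or self.left.ndim != 2:
            raise ValueError("left and right must be equal-shape (J, M) arrays")
        if len(self.individuals) != self.left.shape[0]:
            raise ValueError("individuals must match the matrix row count")
        if self.n_individuals < 2 or self.n_replicates < 1:
            raise ValueError("TraitMatrix requires J >= 2 and M >= 1")
        if not (np.isfinite(self.left).all() and np.isfinite(self.right).all()):
            raise ValueError("measurements must be finite (balanced design)")

    @property
    def n_individuals(self) -> int:
        return self.left.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.left.shape[1]

    def to_array(self) -> np.ndarray:
        """Return a ``(J, 2, M)`` array; side axis ordered (left, right)."""
        return np.stack([self.left, self.right], axis=1)


def _require_columns(df: pd.DataFrame) -> None:
    for col in COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")


def validate_measurements(df: pd.DataFrame) -> tuple[pd.DataFrame, ReadReport]:
    """Validate a long-format measurement table row by row.

    Returns the retained rows (canonical column order and dtypes) and a
    :class:`ReadReport`.  Rejected rows — non-positive or non-finite values,
    unknown codes, arcade/class disagreeing with the tooth code, duplicate
    (individual, tooth, metric, side, replicate) keys — are dropped, never
    repaired.
    """
    _require_columns(df)
    df = df.loc[:, list(COLUMNS)].copy()
    n_read = len(df)
    dropped: list[tuple[int, str]] = []
    rownum = pd.RangeIndex(1, n_read + 1)  # 1-based, excluding header
    df.index = rownum

    df["value_mm"] = pd.to_numeric(df["value_mm"], errors="coerce")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    for col in ("sex", "arcade", "tooth_class", "metric"):
        df[col] = df[col].astype(str).str.strip().str.lower()
    df["tooth"] = df["tooth"].astype(str).str.strip().str.upper()
    df["side"] = df["side"].astype(str).str.strip().str.upper()
    df["individual_id"] = df["individual_id"].astype(str).str.strip()

    def reject(mask: pd.Series, reason: str) -> None:
        for i in df.index[mask]:
            dropped.append((int(i), reason))

    bad_value = ~(df["value_mm"] > 0) | ~np.isfinite(df["value_mm"])
    reject(bad_value, "value_mm must be a positive finite number")
    bad_sex = ~df["sex"].isin(_SEXES)
    reject(bad_sex & ~bad_value, "sex must be female or male")
    bad_tooth = ~df["tooth"].isin(TOOTH_ANATOMY)
    reject(bad_tooth & ~bad_value & ~bad_sex, "unknown tooth code")
    anatomy = df["tooth"].map(
        lambda t: TOOTH_ANATOMY.get(t, ("?", "?"))
    )
    bad_anat = (
        (df["arcade"] != anatomy.map(lambda a: a[0]))
        | (df["tooth_class"] != anatomy.map(lambda a: a[1]))
    ) & ~bad_tooth
    reject(bad_anat & ~bad_value & ~bad_sex, "arcade/tooth_class disagree with tooth code")
    bad_metric = ~df["metric"].isin(_METRICS)
    reject(bad_metric & ~bad_value & ~bad_sex & ~bad_tooth, "metric must be length or breadth")
    bad_side = ~df["side"].isin(_SIDES)
    reject(bad_side & ~bad_value, "side must be L or R")
    bad_rep = df["replicate"].isna() | (df["replicate"] < 1) | (df["replicate"] % 1 != 0)
    reject(bad_rep & ~bad_value, "replicate must be a positive integer")

    bad = bad_value | bad_sex | bad_tooth | bad_anat | bad_metric | bad_side | bad_rep
    kept = df.loc[~bad].copy()
    kept["replicate"] = kept["replicate"].astype(int)

    dup = kept.duplicated(subset=_KEY, keep="first")
    reject_rows = kept.index[dup]
    for i in reject_rows:
        dropped.append((int(i), "duplicate (individual, tooth, metric, side, replicate)"))
    kept = kept.loc[~dup]

    dropped.sort(key=lambda t: t[0])
    report = ReadReport(n_read=n_read, n_dropped=len(dropped), dropped=tuple(dropped))
    if report.n_dropped:
        logger.warning("dropped %d of %d measurement rows", report.n_dropped, n_read)
    return kept.reset_index(drop=True), report


def read_measurements(path, **csv_kwargs) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a long-format measurement CSV.

    Parameters
    ----------
    path
        CSV file with header row and the nine canonical columns.
    **csv_kwargs
        Extra options forwarded to :func:`pandas.read_csv` (dialect control).

    Returns
    -------
    (DataFrame, ReadReport)
        Validated records and the read/drop accounting.
    """
    try:
        raw = pd.read_csv(path, **csv_kwargs)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return validate_measurements(raw)


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write records to the canonical CSV dialect (UTF-8, comma, header)."""
    _require_columns(df)
    df.loc[:, list(COLUMNS)].to_csv(path, index=False)


def build_trait_matrices(
    records: pd.DataFrame,
    replicate_subset: Iterable[int] | None = None,
) -> dict[tuple[str, str, str], TraitMatrix]:
    """Assemble one balanced :class:`TraitMatrix` per (sex, tooth, metric).

    ``replicate_subset`` must be a contiguous range of replicate indices
    (default: every replicate present in ``records``).  Individuals missing
    any required cell — either side, any replicate in the subset — are
    excluded from that trait's matrix only (complete case per trait).  Traits
    with fewer than two complete individuals are skipped with a warning.
    """
    _require_columns(records)
    if replicate_subset is None:
        replicate_subset = sorted(records["replicate"].unique())
    subset = sorted(int(r) for r in replicate_subset)
    if not subset:
        raise ValueError("replicate_subset must be non-empty")
    if subset != list(range(subset[0], subset[-1] + 1)):
        raise ValueError(f"replicate_subset must be contiguous, got {subset}")
    available = set(records["replicate"].unique())
    missing = [r for r in subset if r not in available]
    if missing:
        raise ValueError(f"replicates {missing} absent from the data")

    sub = records[records["replicate"].isin(subset)]
    out: dict[tuple[str, str, str], TraitMatrix] = {}
    m = len(subset)
    for (sex, tooth, metric), g in sub.groupby(["sex", "tooth", "metric"], sort=True):
        wide = g.pivot_table(
            index="individual_id", columns=["side", "replicate"],
            values="value_mm", aggfunc="first", sort=True,
        )
        # complete case: both sides x all subset replicates present
        needed = [(s, r) for s in ("L", "R") for r in subset]
        have = [c for c in needed if c in wide.columns]
        if len(have) < len(needed):
            complete = wide.index[:0]
        else:
            complete = wide.index[wide[needed].notna().all(axis=1)]
        if len(complete) < 2:
            logger.warning(
                "trait (%s, %s, %s): fewer than 2 complete individuals; skipped",
                sex, tooth, metric,
            )
            continue
        block = wide.loc[complete]
        left = block[[("L", r) for r in subset]].to_numpy(float)
        right = block[[("R", r) for r in subset]].to_numpy(float)
        out[(sex, tooth, metric)] = TraitMatrix(
            trait_key=(sex, tooth, metric),
            individuals=list(complete),
            left=left.reshape(-1, m),
            right=right.reshape(-1, m),
        )
    return out


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("flucasym").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged per-trait FA10a index table.

    Thirty-one rows (9 female breadths, 7 female lengths, 9 male breadths,
    6 male lengths) with columns ``sex, metric, tooth, fa10a, n``: the
    published baboon dental FA10a indices and the per-trait sample sizes they
    were estimated from.  This is the input to the group-level variance tests.
    """
    df = _packaged_csv("table2_fa10a.csv")
    assert len(df) == 31, "packaged index table must have 31 rows"
    return df


def load_levene_reference() -> pd.DataFrame:
    """Load the reference group-variance test results that accompany the
    packaged index table (model label, F, between-groups df, p).

    Used by the reproduction report to state which Levene centering matches
    each reference F; it is never an input to any computation.
    """
    return _packaged_csv("levene_reference.csv")
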