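"""Plate normalization and phenotype-profile correlation for high-content screens.

A high-content siRNA screen yields many quantitative colony features per
well.  Features are Z-scored within each (plate, feature) group to remove
plate-level batch effects, replicates are averaged into one phenotype
profile per knockdown, and knockdown-to-knockdown Pearson correlations over
the feature axis quantify phenotypic similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCREEN_COLUMNS",
    "CorrelationMatrix",
    "PhenotypeProfiles",
    "LinearFit",
    "validate_screen_table",
    "zscore_by_plate",
    "aggregate_replicates",
    "rank_hits",
    "phenotype_correlation",
    "linear_fit",
    "read_screen_table",
    "write_screen_table",
]

SCREEN_COLUMNS = ("knockdown", "plate", "replicate", "feature", "value")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over labelled items."""

    labels: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.labels), len(self.labels)):
            raise ValueError("correlation matrix shape does not match labels")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal is not 1")
        if np.any(np.abs(r) > 1 + 1e-9):
            raise ValueError("correlation coefficients exceed |r| = 1")
        object.__setattr__(self, "r", r)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.r[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CorrelationMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class PhenotypeProfiles:
    """Replicate-averaged, Z-scored feature profiles, one row per knockdown.

    ``values`` is knockdowns x features; ``n_replicates_used`` counts the
    distinct replicates that contributed per knockdown; ``excluded`` lists
    knockdowns dropped for having fewer than the required replicates.
    """

    values: pd.DataFrame
    n_replicates_used: pd.Series
    excluded: tuple[str, ...] = ()

    @property
    def knockdowns(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


def validate_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check long-form screen-table structure: columns, finite values, unique keys."""
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screen table is missing columns: {missing}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("screen table contains non-finite values")
    keys = ["knockdown", "plate", "replicate", "feature"]
    if table.duplicated(subset=keys).any():
        dup = table[table.duplicated(subset=keys)].iloc[0]
        raise ValueError(
            "duplicate (knockdown, plate, replicate, feature) key: "
            f"{tuple(dup[k] for k in keys)}"
        )
    return table


def zscore_by_plate(
    table: pd.DataFrame, controls: Iterable[str] | None = None
) -> pd.DataFrame:
    """Z-score feature values within each (plate, feature) group.

    The normalized value is ``(v - m) / s`` with ``m``, ``s`` the group mean
    and sample SD (ddof=1).  With ``controls`` given, ``m`` and ``s`` come
    from the control knockdowns on that plate only; by default all wells of
    the plate are used.  Zero-variance groups raise, naming the groups.
    """
    validate_screen_table(table)
    out = table.copy()
    ref = table if controls is None else table[table["knockdown"].isin(set(controls))]
    if controls is not None and ref.empty:
        raise ValueError("no control wells found for the requested control labels")
    grp = ref.groupby(["plate", "feature"])["value"]
    mean = grp.mean()
    sd = grp.std(ddof=1)
    counts = grp.count()
    bad = sorted(
        mean.index[(counts < 2) | ~(sd > 0)].tolist()
    )  # NaN sd (n<2) and sd==0 both fail
    if bad:
        shown = ", ".join(f"(plate={p!r}, feature={f!r})" for p, f in bad[:10])
        raise ValueError(
            f"{len(bad)} (plate, feature) groups have zero variance or fewer "
            f"than 2 values and cannot be Z-scored: {shown}"
        )
    idx = pd.MultiIndex.from_frame(out[["plate", "feature"]])
    out["value"] = (
        out["value"].to_numpy(dtype=float) - mean.reindex(idx).to_numpy()
    ) / sd.reindex(idx).to_numpy()
    return out


def aggregate_replicates(
    table: pd.DataFrame, min_replicates: int = 2
) -> PhenotypeProfiles:
    """Average Z-scored values over replicates into per-knockdown profiles.

    A (knockdown, feature) value missing in one replicate is skipped in the
    mean; a feature with no value at all for a knockdown raises.  Knockdowns
    observed in fewer than ``min_replicates`` distinct replicates are
    excluded and reported in ``PhenotypeProfiles.excluded``.
    """
    validate_screen_table(table)
    if table.empty:
        raise ValueError("screen table is empty")
    n_reps = table.groupby("knockdown")["replicate"].nunique().sort_index()
    keep = n_reps[n_reps >= min_replicates]
    excluded = tuple(n_reps.index[n_reps < min_replicates])
    if keep.empty:
        raise ValueError("no knockdown has enough replicates")
    sub = table[table["knockdown"].isin(keep.index)]
    values = (
        sub.groupby(["knockdown", "feature"])["value"].mean().unstack("feature")
    ).sort_index()
    if values.isna().any().any():
        holes = [
            (kd, f) for kd, row in values.iterrows() for f in values.columns[row.isna()]
        ]
        shown = ", ".join(map(str, holes[:10]))
        raise ValueError(f"features with no measurement for a knockdown: {shown}")
    return PhenotypeProfiles(values, keep.rename("n_replicates_used"), excluded)


def rank_hits(
    profiles: PhenotypeProfiles, feature: str
) -> list[tuple[str, float]]:
    """Rank knockdowns ascending by one feature's averaged Z-score.

    Low scores come first (strong loss-of-function hits on e.g. a colony
    count feature); ties break lexicographically by knockdown name.
    """
    if feature not in profiles.values.columns:
        raise ValueError(f"unknown feature {feature!r}")
    scores = profiles.values[feature]
    order = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    return [(kd, float(s)) for kd, s in order]


def phenotype_correlation(
    profiles: PhenotypeProfiles, features: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Knockdown-to-knockdown Pearson correlation over the feature axis.

    ``features`` restricts the correlation to a feature subset (at least 3);
    default is all features.  A profile with zero variance over the subset
    raises, naming the knockdown.
    """
    mat = profiles.values
    if features is not None:
        missing = [f for f in features if f not in mat.columns]
        if missing:
            raise ValueError(f"unknown features: {missing}")
        mat = mat[list(features)]
    if mat.shape[1] < 3:
        raise ValueError(f"need at least 3 features, got {mat.shape[1]}")
    x = mat.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    flat = [kd for kd, s in zip(mat.index, sd) if not s > 0]
    if flat:
        raise ValueError(f"zero-variance profile for knockdowns: {flat}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(tuple(mat.index), r)


def linear_fit(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least-squares line through (x, y); r_squared = (Pearson r)^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not x.std(ddof=1) > 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue) ** 2
    if not np.isfinite(r2):  # constant y: no linear association
        r2 = 0.0
    return LinearFit(float(res.slope), float(res.intercept), r2)


def read_screen_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path, sep="\t", dtype={"knockdown": str, "plate": str, "feature": str}
    )
    return validate_screen_table(table)


def write_screen_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_screen_table(table)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
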