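"""Cleveland-schema tabular data: reading, cleaning, recoding, scaling and
synthetic generation.

The schema is the standard 13-feature + binary-target layout of the
Cleveland heart-disease dataset: five continuous measurements (age, resting
blood pressure, serum cholesterol, maximum heart rate, ST depression) and
eight integer-coded categorical features, plus a ``target`` column (1 =
disease). The synthetic generator emulates this schema with class-
conditional distributions so that a configurable subset of features carries
signal; it stands in for the undeposited study data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: sentinel strings parsed as missing (the UCI dialect uses "?")
MISSING_SENTINELS = ("?", "")


@dataclass(frozen=True)
class FeatureSchema:
    name: str
    kind: str                       # continuous | categorical
    lo: float
    hi: float
    codes: tuple[float, ...] = ()   # enumerated values for categorical


#: the 13 candidate features, in dataset column order
SCHEMA: tuple[FeatureSchema, ...] = (
    FeatureSchema("age", CONTINUOUS, 29, 77),
    FeatureSchema("sex", CATEGORICAL, 0, 1, (0, 1)),
    FeatureSchema("cp", CATEGORICAL, 0, 3, (0, 1, 2, 3)),
    FeatureSchema("trestbps", CONTINUOUS, 94, 200),
    FeatureSchema("chol", CONTINUOUS, 126, 564),
    FeatureSchema("fbs", CATEGORICAL, 0, 1, (0, 1)),
    FeatureSchema("restecg", CATEGORICAL, 0, 2, (0, 1, 2)),
    FeatureSchema("thalach", CONTINUOUS, 71, 202),
    FeatureSchema("exang", CATEGORICAL, 0, 1, (0, 1)),
    FeatureSchema("oldpeak", CONTINUOUS, 0, 6.2),
    FeatureSchema("slope", CATEGORICAL, 0, 2, (0, 1, 2)),
    FeatureSchema("ca", CATEGORICAL, 0, 3, (0, 1, 2, 3)),
    FeatureSchema("thal", CATEGORICAL, 0, 2, (0, 1, 2)),
)

TARGET = "target"
FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in SCHEMA)
COLUMNS: tuple[str, ...] = FEATURE_NAMES + (TARGET,)
_SCHEMA_BY_NAME: Mapping[str, FeatureSchema] = {s.name: s for s in SCHEMA}


def schema_for(name: str) -> FeatureSchema:
    return _SCHEMA_BY_NAME[name]


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class DatasetTable:
    """n x p numeric feature matrix with binary labels and column metadata.

    ``ranges`` maps each column name to ``(min, max, kind)``. Labels are
    binary {0, 1} after :func:`recode_target`; straight after
    :func:`read_table` they may still carry the raw five-level coding, and
    features may contain NaN until :func:`clean` runs.
    """

    features: np.ndarray
    labels: np.ndarray
    names: list[str]
    ranges: dict[str, tuple[float, float, str]]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-d matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on sample count")
        if self.features.shape[1] != len(self.names):
            raise ValueError("features and names disagree on column count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.names)
        df[TARGET] = self.labels
        return df

    def copy(self) -> "DatasetTable":
        return DatasetTable(self.features.copy(), self.labels.copy(),
                            list(self.names), dict(self.ranges))


@dataclass(frozen=True)
class SynthConfig:
    """Configuration for the synthetic Cleveland-schema generator.

    ``informative`` features differ between classes: continuous ones by a
    mean shift of ``effect_size`` pooled standard deviations, categorical
    ones by moving ``categorical_shift`` probability mass between low and
    high codes. All other features are identically distributed across
    classes. ``missing_rate`` injects missingness into ca/thal, mirroring
    where the real data has null values. Defaults mirror the 1025-row
    cohort composition (526 healthy vs 499 disease).
    """

    n_disease: int = 499
    n_healthy: int = 526
    features: tuple[str, ...] = FEATURE_NAMES
    informative: tuple[str, ...] = ("cp", "thalach", "oldpeak")
    effect_size: float = 2.0
    categorical_shift: float = 0.6
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease < 0 or self.n_healthy < 0:
            raise ValueError("class sizes must be non-negative")
        if not self.informative:
            raise ValueError("informative feature set must be non-empty")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        stray = set(self.informative) - set(self.features)
        if stray:
            raise ValueError(
                f"informative features not in the generated schema: {sorted(stray)}"
            )


# ---------------------------------------------------------------------------
# Reading and cleaning
# ---------------------------------------------------------------------------

def _default_ranges(names: Sequence[str]) -> dict[str, tuple[float, float, str]]:
    return {n: (_SCHEMA_BY_NAME[n].lo, _SCHEMA_BY_NAME[n].hi,
                _SCHEMA_BY_NAME[n].kind) for n in names}


def read_table(path: str | Path) -> DatasetTable:
    """Read a CSV with the 14-column Cleveland schema.

    Headers are matched case-insensitively; '?' and empty cells parse as
    missing. Values outside the documented ranges raise warnings (rows are
    retained); missing required columns or non-numeric cells are errors.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing required column(s): {', '.join(missing_cols)}")
    raw = raw[list(COLUMNS)]

    is_missing = raw.isna() | raw.isin(MISSING_SENTINELS)
    coerced = raw.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & ~is_missing
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {raw.iat[r, c]!r} at row {r}, column {bad.columns[c]!r}"
        )
    # re-parse with numpy's correctly-rounded converter so values written by
    # write_table round-trip bit-exactly
    numeric = pd.DataFrame(
        np.where(is_missing, "nan", raw).astype(float),
        columns=raw.columns,
    )

    for s in SCHEMA:
        col = numeric[s.name]
        out = col.notna() & ((col < s.lo) | (col > s.hi))
        if out.any():
            warnings.warn(
                f"{int(out.sum())} value(s) in column {s.name!r} outside the "
                f"documented range {s.lo} to {s.hi}; rows retained",
                stacklevel=2,
            )

    labels = numeric[TARGET].to_numpy()
    if np.isnan(labels).any():
        raise ValueError("missing values in the target column")
    return DatasetTable(
        features=numeric[list(FEATURE_NAMES)].to_numpy(dtype=float),
        labels=labels.astype(int),
        names=list(FEATURE_NAMES),
        ranges=_default_ranges(FEATURE_NAMES),
    )


def clean(data: DatasetTable) -> DatasetTable:
    """Drop every row containing a missing value; log removals per column."""
    nan_mask = np.isnan(data.features)
    keep = ~nan_mask.any(axis=1)
    for j, name in enumerate(data.names):
        removed = int(nan_mask[:, j].sum())
        if removed:
            logger.info("clean: %d row(s) removed for missing %s", removed, name)
    if not keep.any():
        raise ValueError("cleaning removed every row")
    return DatasetTable(data.features[keep], data.labels[keep],
                        list(data.names), dict(data.ranges))


def recode_target(raw: np.ndarray) -> np.ndarray:
    """Collapse the five-level diagnosis code to binary: 0 -> 0, {1,2,3,4} -> 1."""
    arr = np.asarray(raw)
    values = set(np.unique(arr).tolist())
    if not values <= {0, 1, 2, 3, 4}:
        raise ValueError(
            f"target values outside {{0,...,4}}: {sorted(values - {0, 1, 2, 3, 4})}"
        )
    return (arr > 0).astype(int)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingParams:
    """Fitted z-score parameters (continuous columns only)."""

    means: dict[str, float]
    sds: dict[str, float]

    def transform(self, data: DatasetTable) -> DatasetTable:
        out = data.copy()
        for name, m in self.means.items():
            j = out.names.index(name)
            out.features[:, j] = (out.features[:, j] - m) / self.sds[name]
        return out


def scale_features(
    data: DatasetTable,
    mode: str = "zscore",
    fit_rows: np.ndarray | None = None,
) -> tuple[DatasetTable, ScalingParams]:
    """Standardise continuous columns; categorical columns are untouched.

    Statistics are computed on ``fit_rows`` only (all rows by default) so a
    training partition can supply them and the returned :class:`ScalingParams`
    can transform held-out data without leakage. Zero-variance columns are
    left unscaled with a warning. ``mode='none'`` is the identity.
    """
    if mode == "none":
        return data.copy(), ScalingParams({}, {})
    if mode != "zscore":
        raise ValueError(f"unknown scaling mode {mode!r}")
    rows = np.arange(data.n_samples) if fit_rows is None else np.asarray(fit_rows)
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in data.names:
        _, _, kind = data.ranges.get(name, (None, None, CONTINUOUS))
        if kind != CONTINUOUS:
            continue
        col = data.features[rows, data.names.index(name)]
        sd = float(np.std(col))
        if sd == 0.0:
            warnings.warn(f"column {name!r} has zero variance; left unscaled",
                          stacklevel=2)
            continue
        means[name] = float(np.mean(col))
        sds[name] = sd
    params = ScalingParams(means, sds)
    return params.transform(data), params


# ---------------------------------------------------------------------------
# Synthetic generation and writing
# ---------------------------------------------------------------------------

def _truncnorm_sample(rng, lo, hi, mean, sd, n):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _categorical_probs(k: int, shift: float, direction: int) -> np.ndarray:
    """Class-conditional multinomial over k codes.

    Baseline is uniform; a positive ``direction`` tilts mass toward high
    codes, negative toward low codes, proportionally to ``shift``.
    """
    if k == 1:
        return np.ones(1)
    rank = (np.arange(k) - (k - 1) / 2) / ((k - 1) / 2)   # in [-1, 1]
    p = 1.0 + direction * shift * rank
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def generate(config: SynthConfig) -> DatasetTable:
    """Generate a class-conditional synthetic table with the Cleveland schema.

    Continuous features are truncated normals inside the documented ranges
    (mean at the range midpoint, SD = range/6 before class shifts);
    informative ones are shifted by ``effect_size`` pooled SDs between the
    classes. Categorical features are per-class multinomials over the
    enumerated codes; informative ones have ``categorical_shift`` mass moved
    between classes. Rows are shuffled; everything is driven by
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n1, n0 = config.n_disease, config.n_healthy
    n = n0 + n1
    if n == 0:
        raise ValueError("empty dataset requested")
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])

    cols: list[np.ndarray] = []
    for name in config.features:
        s = _SCHEMA_BY_NAME[name]
        informative = name in config.informative
        if s.kind == CONTINUOUS:
            mid, sd = (s.lo + s.hi) / 2.0, (s.hi - s.lo) / 6.0
            delta = (config.effect_size * sd / 2.0) if informative else 0.0
            healthy = _truncnorm_sample(rng, s.lo, s.hi, mid - delta, sd, n0)
            disease = _truncnorm_sample(rng, s.lo, s.hi, mid + delta, sd, n1)
        else:
            k = len(s.codes)
            shift = config.categorical_shift if informative else 0.0
            p0 = _categorical_probs(k, shift, -1)
            p1 = _categorical_probs(k, shift, +1)
            codes = np.asarray(s.codes, dtype=float)
            healthy = rng.choice(codes, size=n0, p=p0)
            disease = rng.choice(codes, size=n1, p=p1)
        cols.append(np.concatenate([healthy, disease]))

    features = np.column_stack(cols)
    if config.missing_rate > 0:
        for name in ("ca", "thal"):
            if name in config.features:
                j = list(config.features).index(name)
                hole = rng.random(n) < config.missing_rate
                features[hole, j] = np.nan

    order = rng.permutation(n)
    return DatasetTable(
        features=features[order],
        labels=labels[order],
        names=list(config.features),
        ranges=_default_ranges(config.features),
    )


def write_table(data: DatasetTable, path: str | Path) -> None:
    """Write a table as CSV with the schema's lower-case headers."""
    df = data.to_frame()
    # %.17g guarantees bit-exact float round-trips through the CSV
    df.to_csv(path, index=False, na_rep="", float_format="%.17g")
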