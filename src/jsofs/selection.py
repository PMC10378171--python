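"""Binary Jellyfish feature selection.

The continuous optimizer searches a box [-4, 4]^p; each coordinate is pushed
through a sigmoid transfer function and thresholded to yield a feature
inclusion mask (never empty). The cost of a mask is the cross-validated
misclassification rate of a classifier trained on the masked columns,
optionally blended with a convex subset-size penalty; the optimizer
minimises it directly (wrapper selection).

The inner evaluation used by the fitness is independent of, and meant to be
nested inside, the outer protocol in :mod:`jsofs.evaluation`, so selection
bias does not leak into reported metrics. The initial population is seeded
with the all-ones position (the full mask), so the full-feature solution is
always evaluated and the returned cost can never exceed it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data import DatasetTable
from .evaluation import SplitSpec, _check_both_classes, _clone, iter_splits, make_model
from .jso import JSOParams, SearchSpace, TraceRecord, optimize, trace_frame

logger = logging.getLogger(__name__)

#: half-width of the continuous box; spans sigmoid outputs ~[0.018, 0.982]
BOX_HALF_WIDTH = 4.0

COST_MODES = ("error", "rmse")


@dataclass(frozen=True)
class FeatureMask:
    """Boolean inclusion vector over the p candidate features; never empty."""

    included: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.included, dtype=bool)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("mask must be a 1-d boolean vector")
        if not arr.any():
            raise ValueError("feature mask must include at least one feature")
        object.__setattr__(self, "included", arr)

    @property
    def n_selected(self) -> int:
        return int(self.included.sum())

    @property
    def size(self) -> int:
        return self.included.size

    def names(self, all_names: Sequence[str]) -> list[str]:
        return [n for n, inc in zip(all_names, self.included) if inc]

    @classmethod
    def full(cls, p: int) -> "FeatureMask":
        return cls(np.ones(p, dtype=bool))


@dataclass(frozen=True)
class FitnessSpec:
    """How a candidate mask is scored.

    cost = error_weight * (mean inner-CV misclassification rate)
         + size_weight * (selected fraction of features)

    ``cost_mode='rmse'`` replaces the misclassification rate with the root
    mean squared error of the hard 0/1 predictions (an alternative cost that
    some selection traces report).
    """

    classifier_id: str = "dt"
    error_weight: float = 1.0
    size_weight: float = 0.0
    cost_mode: str = "error"
    inner_eval: SplitSpec = field(
        default_factory=lambda: SplitSpec(mode="kfold", k=5, stratified=True, seed=0)
    )

    def __post_init__(self) -> None:
        if not 0 <= self.error_weight <= 1 or not 0 <= self.size_weight <= 1:
            raise ValueError("weights must lie in [0, 1]")
        if self.size_weight > 0 and abs(self.error_weight + self.size_weight - 1) > 1e-12:
            raise ValueError("error_weight + size_weight must equal 1 when "
                             "size_weight > 0")
        if self.cost_mode not in COST_MODES:
            raise ValueError(f"cost_mode must be one of {COST_MODES}")


@dataclass
class SelectionResult:
    mask: FeatureMask
    best_cost: float
    trace: list[TraceRecord]
    selected_names: list[str]


# ---------------------------------------------------------------------------
# Transfer function
# ---------------------------------------------------------------------------

def binarize(
    position: np.ndarray,
    rule: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> FeatureMask:
    """Map a continuous position to a feature mask via a sigmoid transfer.

    s_j = 1/(1 + exp(-x_j)). Deterministic rule: include j iff s_j >= 0.5
    (i.e. x_j >= 0). Stochastic rule: include j iff draw_j < s_j with one
    uniform draw per coordinate. An all-excluded outcome forces the
    coordinate with maximal s_j on (lowest index on ties).
    """
    x = np.asarray(position, dtype=float)
    s = expit(x)
    if rule == "deterministic":
        included = s >= 0.5
    elif rule == "stochastic":
        if rng is None:
            raise ValueError("stochastic binarization needs an rng")
        included = rng.random(s.size) < s
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")
    if not included.any():
        included = included.copy()
        included[int(np.argmax(s))] = True
    return FeatureMask(included)


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def fitness(mask: FeatureMask, data: DatasetTable, spec: FitnessSpec) -> float:
    """Cross-validated cost of a feature mask (lower is better).

    Deterministic given the seeds inside ``spec.inner_eval`` and the pinned
    classifier defaults.
    """
    X = data.features[:, mask.included]
    y = np.asarray(data.labels).astype(int)
    model = make_model(spec.classifier_id)
    errors: list[float] = []
    for f, (tr, te) in enumerate(iter_splits(spec.inner_eval, y)):
        try:
            _check_both_classes(y[tr], "training partition")
        except ValueError as exc:
            raise ValueError(f"fold {f}: {exc}") from None
        m = _clone(model)
        try:
            m.fit(X[tr], y[tr])
        except ValueError as exc:
            # e.g. AdaBoost refusing a worse-than-random first stump on a
            # useless mask: score the fold as total error instead of
            # aborting the whole search over a bad candidate
            logger.warning("fitness: fold %d fit failed (%s); scoring 1.0", f, exc)
            errors.append(1.0)
            continue
        pred = np.asarray(m.predict(X[te]))
        if spec.cost_mode == "rmse":
            errors.append(float(np.sqrt(np.mean((pred - y[te]) ** 2))))
        else:
            errors.append(float(np.mean(pred != y[te])))
    err = float(np.mean(errors))
    return spec.error_weight * err + spec.size_weight * (mask.n_selected / mask.size)


class _CachedMaskObjective:
    """Objective over continuous positions with memoised mask costs.

    Many positions binarize to the same mask, so caching by the mask's byte
    pattern makes the wrapper search cost proportional to the number of
    distinct masks visited, not the number of position evaluations.
    """

    def __init__(self, data: DatasetTable, spec: FitnessSpec):
        self.data = data
        self.spec = spec
        self.cache: dict[bytes, float] = {}

    def mask_cost(self, mask: FeatureMask) -> float:
        key = np.packbits(mask.included).tobytes()
        if key not in self.cache:
            self.cache[key] = fitness(mask, self.data, self.spec)
        return self.cache[key]

    def __call__(self, x: np.ndarray) -> float:
        return self.mask_cost(binarize(x))


# ---------------------------------------------------------------------------
# Selection driver
# ---------------------------------------------------------------------------

def select_features(
    data: DatasetTable,
    spec: FitnessSpec | None = None,
    space_params: JSOParams | None = None,
) -> SelectionResult:
    """Run binary Jellyfish search over feature masks.

    Optimizes fitness(binarize(x)) over [-4, 4]^p with the continuous JSO;
    the initial population is seeded with the all-ones position so the full
    mask is always among the evaluated solutions. Deterministic given
    ``space_params.seed``.
    """
    if spec is None:
        spec = FitnessSpec()
    if space_params is None:
        space_params = JSOParams()
    p = data.n_features
    if p < 2:
        raise ValueError("feature selection needs at least 2 candidate features")
    space = SearchSpace(lower=-BOX_HALF_WIDTH * np.ones(p),
                        upper=BOX_HALF_WIDTH * np.ones(p))
    objective = _CachedMaskObjective(data, spec)
    best, trace = optimize(objective, space, space_params,
                           seed_positions=[np.ones(p)])
    mask = binarize(best.position)
    logger.info("select_features: %d/%d features, best cost %.6g "
                "(%d distinct masks evaluated)",
                mask.n_selected, p, best.cost, len(objective.cache))
    return SelectionResult(
        mask=mask,
        best_cost=float(best.cost),
        trace=trace,
        selected_names=mask.names(data.names),
    )


def write_selection_report(result: SelectionResult, out_dir: str | Path) -> None:
    """Write the selection artifacts: selected names, best cost, trace CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "selected_features.txt").write_text(
        "\n".join(result.selected_names) + "\n"
    )
    trace_frame(result.trace).to_csv(out / "trace.csv", index=False)
    (out / "selection.json").write_text(
        json.dumps(
            {
                "selected_features": result.selected_names,
                "mask": result.mask.included.astype(int).tolist(),
                "best_cost": result.best_cost,
                "iterations": len(result.trace),
            },
            indent=2,
        )
        + "\n"
    )
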