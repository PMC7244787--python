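"""Hyper-parameter search over the discrete 6-D hypercube.

The objective is the mean held-out AUPRC of an internal cross-validation
(band-aware when band ids are present).  Two strategies:

* exhaustive grid search over explicit per-axis value lists;
* Bayesian optimization over inclusive integer intervals — a Gaussian-process
  surrogate with a Matern kernel is fitted to the evaluation history and the
  next lattice point is the expected-improvement maximiser over a random
  candidate pool (exhaustive when the lattice is small).

Infeasible combinations (e.g. more parts than training negatives) are
recorded as failed evaluations with score ``-inf`` rather than raised.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from . import hyper_ensemble
from .datamodel import Dataset, HyperParams
from .exceptions import ConfigurationError
from .folds import FoldAssignment, band_aware_kfold, stratified_kfold
from .metrics import auprc

AXIS_ORDER = ("n_parts", "fp", "ratio", "k", "n_trees", "m_try")

Axis = Sequence[int] | tuple[int, int]


@dataclass(frozen=True)
class ParamSpace:
    """Per-axis value lists (grid) or inclusive integer intervals (BO).

    A list axis enumerates explicit values; an ``(lo, hi)`` interval spans
    every integer in between.  Axis order is fixed:
    n_parts, fp, ratio, k, n_trees, m_try.
    """

    n_parts: Axis
    fp: Axis
    ratio: Axis
    k: Axis
    n_trees: Axis
    m_try: Axis

    def axes(self) -> dict[str, Axis]:
        return {name: getattr(self, name) for name in AXIS_ORDER}

    @staticmethod
    def _is_interval(axis: Axis) -> bool:
        return isinstance(axis, tuple) and len(axis) == 2

    def __post_init__(self) -> None:
        for name, axis in self.axes().items():
            minimum = 0 if name == "fp" else 1
            if self._is_interval(axis):
                lo, hi = axis
                if lo > hi:
                    raise ConfigurationError(f"axis {name}: interval lower {lo} > upper {hi}")
                if lo < minimum:
                    raise ConfigurationError(f"axis {name}: values must be >= {minimum}")
            else:
                values = list(axis)
                if not values:
                    raise ConfigurationError(f"axis {name} is empty")
                if any(v < minimum for v in values):
                    raise ConfigurationError(f"axis {name}: values must be >= {minimum}")

    def axis_values(self, name: str) -> list[int]:
        axis = getattr(self, name)
        if self._is_interval(axis):
            lo, hi = axis
            return list(range(lo, hi + 1))
        return [int(v) for v in axis]

    def lattice_size(self) -> int:
        return math.prod(len(self.axis_values(name)) for name in AXIS_ORDER)

    def has_interval_axis(self) -> bool:
        return any(self._is_interval(getattr(self, name)) for name in AXIS_ORDER)


@dataclass
class Evaluation:
    h: HyperParams
    mean_auprc: float
    fold_auprcs: list[float]
    failed: bool = False
    failure_reason: str = ""


@dataclass
class TuneResult:
    """Search history plus the argmax (ties: first encountered)."""

    evaluations: list[Evaluation]
    best: HyperParams
    n_evaluations: int
    strategy: str

    def to_records(self) -> list[dict]:
        out = []
        for e in self.evaluations:
            rec = e.h.as_dict()
            rec["mean_auprc"] = e.mean_auprc
            rec["fold_auprcs"] = e.fold_auprcs
            rec["failed"] = e.failed
            out.append(rec)
        return out


def enumerate_grid(space: ParamSpace) -> list[HyperParams]:
    """Cartesian product of explicit list axes, in fixed axis order."""
    for name in AXIS_ORDER:
        if ParamSpace._is_interval(getattr(space, name)):
            raise ConfigurationError(
                f"grid enumeration requires explicit value lists; axis {name} is an interval"
            )
    combos = itertools.product(*(space.axis_values(name) for name in AXIS_ORDER))
    return [HyperParams(**dict(zip(AXIS_ORDER, combo))) for combo in combos]


def _internal_folds(train_data: Dataset, n_folds: int, seed: int) -> FoldAssignment:
    if train_data.band_ids is not None:
        return band_aware_kfold(train_data.band_ids, train_data.labels, n_folds, seed)
    return stratified_kfold(train_data.labels, n_folds, seed)


def internal_cv_auprc(
    train_data: Dataset,
    h: HyperParams,
    n_folds: int,
    seed: int,
    n_workers: int = 1,
) -> tuple[float, list[float]]:
    """Mean held-out AUPRC over the internal folds (band-aware if bands present).

    Raises :class:`ConfigurationError` when ``h`` is infeasible for some
    internal training split; search drivers convert this to a failed
    evaluation with score ``-inf``.
    """
    assignment = _internal_folds(train_data, n_folds, seed)
    fold_scores = []
    for fold in range(n_folds):
        train_split = train_data.subset(assignment.train_indices(fold))
        test_split = train_data.subset(assignment.test_indices(fold))
        model = hyper_ensemble.train(train_split, h, n_workers=n_workers, master_seed=seed + fold)
        scores = hyper_ensemble.predict(model, test_split.features)
        fold_scores.append(auprc(scores, test_split.labels))
    return float(np.mean(fold_scores)), fold_scores


def _evaluate(
    train_data: Dataset, h: HyperParams, n_folds: int, seed: int, n_workers: int
) -> Evaluation:
    try:
        mean_score, fold_scores = internal_cv_auprc(train_data, h, n_folds, seed, n_workers)
    except ConfigurationError as exc:
        return Evaluation(h=h, mean_auprc=-np.inf, fold_auprcs=[], failed=True, failure_reason=str(exc))
    return Evaluation(h=h, mean_auprc=mean_score, fold_auprcs=fold_scores)


def _best_of(evaluations: list[Evaluation]) -> HyperParams:
    best = max(range(len(evaluations)), key=lambda i: (evaluations[i].mean_auprc, -i))
    return evaluations[best].h


def grid_search(
    space: ParamSpace,
    train_data: Dataset,
    n_folds: int,
    seed: int,
    n_workers: int = 1,
) -> TuneResult:
    """Evaluate every grid point by internal CV; best = first argmax."""
    evaluations = [
        _evaluate(train_data, h, n_folds, seed, n_workers) for h in enumerate_grid(space)
    ]
    return TuneResult(
        evaluations=evaluations,
        best=_best_of(evaluations),
        n_evaluations=len(evaluations),
        strategy="grid",
    )


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def _encode(h: HyperParams, scales: np.ndarray) -> np.ndarray:
    vec = np.array([getattr(h, name) for name in AXIS_ORDER], dtype=float)
    return vec / scales


def bayes_search(
    space: ParamSpace,
    objective: Optional[Callable[[HyperParams], float]] = None,
    *,
    train_data: Optional[Dataset] = None,
    n_folds: int = 9,
    max_iter: int = 60,
    n_init: int = 10,
    seed: int = 0,
    n_workers: int = 1,
    tol: float = 1e-4,
    patience: int = 10,
    candidate_pool: int = 2048,
) -> TuneResult:
    """Bayesian optimization over the integer lattice of ``space``.

    ``objective`` maps a :class:`HyperParams` to the value to maximise; when
    omitted, the internal-CV AUPRC on ``train_data`` is used.  ``n_init``
    lattice points are sampled at random, then each iteration fits a GP
    surrogate to the finite history and proposes the expected-improvement
    maximiser among an unevaluated candidate pool.  Stops at ``max_iter``
    total evaluations or after ``patience`` consecutive proposals improving
    the best value by at most ``tol``.  Never re-evaluates a lattice point.
    """
    if max_iter < n_init:
        raise ConfigurationError(f"max_iter={max_iter} must be >= n_init={n_init}")
    axis_values = [space.axis_values(name) for name in AXIS_ORDER]
    lattice_size = space.lattice_size()
    rng = np.random.default_rng(seed)

    if objective is None:
        if train_data is None:
            raise ConfigurationError("bayes_search needs either an objective or train_data")

        def objective(h: HyperParams, _data=train_data) -> float:
            ev = _evaluate(_data, h, n_folds, seed, n_workers)
            return ev.mean_auprc if not ev.failed else -np.inf

    def random_point() -> HyperParams:
        return HyperParams(
            **{name: int(rng.choice(values)) for name, values in zip(AXIS_ORDER, axis_values)}
        )

    def key(h: HyperParams) -> tuple:
        return tuple(getattr(h, name) for name in AXIS_ORDER)

    evaluations: list[Evaluation] = []
    seen: set[tuple] = set()

    def evaluate(h: HyperParams) -> None:
        value = objective(h)
        failed = not np.isfinite(value)
        evaluations.append(
            Evaluation(
                h=h,
                mean_auprc=value if not failed else -np.inf,
                fold_auprcs=[],
                failed=failed,
            )
        )
        seen.add(key(h))

    n_init_eff = min(n_init, lattice_size, max_iter)
    attempts = 0
    while len(evaluations) < n_init_eff and attempts < 50 * n_init_eff:
        h = random_point()
        attempts += 1
        if key(h) not in seen:
            evaluate(h)

    scales = np.array([max(max(v), 1) for v in axis_values], dtype=float)
    kernel = ConstantKernel(1.0) * Matern(length_scale=np.ones(6), nu=2.5) + WhiteKernel(1e-4)
    best_value = max((e.mean_auprc for e in evaluations), default=-np.inf)
    stale = 0

    while len(evaluations) < min(max_iter, lattice_size) and stale < patience:
        finite = [e for e in evaluations if not e.failed]
        proposal: Optional[HyperParams] = None
        if len(finite) >= 2:
            X = np.array([_encode(e.h, scales) for e in finite])
            y = np.array([e.mean_auprc for e in finite])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gp = GaussianProcessRegressor(
                        kernel=kernel,
                        normalize_y=True,
                        n_restarts_optimizer=1,
                        random_state=int(rng.integers(2**31 - 1)),
                    ).fit(X, y)
                candidates: list[HyperParams] = []
                if lattice_size <= candidate_pool:
                    for combo in itertools.product(*axis_values):
                        h = HyperParams(**dict(zip(AXIS_ORDER, combo)))
                        if key(h) not in seen:
                            candidates.append(h)
                else:
                    cand_keys: set[tuple] = set()
                    for _ in range(4 * candidate_pool):
                        if len(candidates) >= candidate_pool:
                            break
                        h = random_point()
                        kh = key(h)
                        if kh not in seen and kh not in cand_keys:
                            cand_keys.add(kh)
                            candidates.append(h)
                if candidates:
                    C = np.array([_encode(h, scales) for h in candidates])
                    mu, sigma = gp.predict(C, return_std=True)
                    ei = _expected_improvement(mu, sigma, max(y))
                    proposal = candidates[int(np.argmax(ei))]
            except Exception:  # surrogate failure -> random fallback
                proposal = None
        if proposal is None:
            for _ in range(50 * 6):
                h = random_point()
                if key(h) not in seen:
                    proposal = h
                    break
        if proposal is None:
            break
        evaluate(proposal)
        new_best = max(best_value, evaluations[-1].mean_auprc)
        stale = stale + 1 if new_best - best_value <= tol else 0
        best_value = new_best

    return TuneResult(
        evaluations=evaluations,
        best=_best_of(evaluations),
        n_evaluations=len(evaluations),
        strategy="bayes",
    )
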