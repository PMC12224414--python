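"""Nested cross-validation and hyperparameter search for decoders.

The outer loop estimates out-of-sample prediction: items are partitioned
into k stratified folds (equal animate/inanimate counts per fold); each fold
is held out in turn while hyperparameters are tuned on the remaining items
with an inner stratified cross-validation, the tuned model is refit on all
non-holdout items, and its holdout predictions are collected.  After all
folds, every item has exactly one prediction from a model that never saw it.

Hyperparameter search is either an explicit grid or a Hyperband-style
successive-halving bracket: configurations sampled log-uniformly compete at
increasing solver-iteration budgets, with the worst 1 - 1/eta eliminated at
each rung.  Inner-loop score is the Frobenius norm of (true - predicted)
coordinates on the inner holdout, averaged over inner folds.  Ties prefer
the smallest alpha, then the smallest omega (simpler models).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import FoldPlanError, RSLError
from .estimators import RSLDecoder

__all__ = [
    "FoldPlan",
    "SearchSpec",
    "CVPrediction",
    "make_fold_plan",
    "inner_loop_score",
    "hyperband_search",
    "nested_cv_decode",
]


@dataclass
class FoldPlan:
    """Stratified partition of items into disjoint test sets."""

    folds: list[np.ndarray]
    item_ids: list[str]
    domains: list[str]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def train_indices(self, fold: int) -> np.ndarray:
        test = set(self.folds[fold].tolist())
        return np.array([i for i in range(len(self.item_ids)) if i not in test])


def make_fold_plan(
    item_ids: Sequence[str],
    domains: Sequence[str],
    k_outer: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Partition items into k_outer folds with exact per-domain balance."""
    item_ids = [str(i) for i in item_ids]
    domains = [str(d) for d in domains]
    if len(item_ids) != len(domains):
        raise RSLError("item_ids and domains must have equal length")
    labels, counts = np.unique(domains, return_counts=True)
    if any(c % k_outer for c in counts):
        raise FoldPlanError(
            f"per-domain counts {dict(zip(labels, counts))} are not divisible by k={k_outer}"
        )
    skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    folds = [test for _, test in skf.split(np.zeros(len(item_ids)), domains)]
    per_fold = [np.unique([domains[i] for i in f], return_counts=True)[1] for f in folds]
    if any(len(set(c)) != 1 for c in per_fold):
        raise FoldPlanError("stratified split failed to balance domains exactly")
    return FoldPlan(folds=folds, item_ids=item_ids, domains=domains, seed=seed)


@dataclass(frozen=True)
class SearchSpec:
    """How hyperparameters are chosen.

    ``method="hyperband"`` samples ``n_configs`` configurations log-uniformly
    from ``bounds`` and runs a successive-halving bracket with elimination
    factor ``eta`` and resource = FISTA iteration budget up to ``max_budget``.
    ``method="grid"`` evaluates ``candidates`` (list of param dicts) at full
    budget.  ``method="fixed"`` uses ``candidates[0]`` with no search.

    ``rule`` picks among the fully-evaluated configurations: ``best`` takes
    the minimum mean inner error; ``1se`` takes the most strongly
    regularized configuration (largest alpha, then omega) whose mean error
    is within one standard error of the best — the usual choice when the
    goal is support recovery rather than raw prediction.
    """

    method: str = "hyperband"
    bounds: tuple[float, float] = (1e-4, 1e1)
    n_configs: int = 27
    eta: int = 3
    max_budget: int = 3000
    candidates: tuple = ()
    n_inner: int = 9
    rule: str = "best"

    def sample(self, family: str, rng: np.random.Generator) -> list[dict]:
        lo, hi = np.log10(self.bounds[0]), np.log10(self.bounds[1])
        names = ("alpha",) if family == "lasso" else ("alpha", "lam", "omega")
        out = []
        for _ in range(self.n_configs):
            out.append({k: float(10 ** rng.uniform(lo, hi)) for k in names})
        return out


def _make_estimator(family: str, params: dict, budget: int | None = None,
                    **est_kw) -> RSLDecoder:
    kw = dict(family=family, standardize=True)
    kw.update(est_kw)
    if family != "none":
        kw.update(params)
    if budget is not None:
        kw["max_iter"] = budget
    if family == "none":
        kw["allow_singular"] = True
    return RSLDecoder(**kw)


def _inner_folds(train_idx: np.ndarray, domains: Sequence[str], n_inner: int,
                 seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    y = np.asarray([domains[i] for i in train_idx])
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    return [(train_idx[tr], train_idx[te]) for tr, te in skf.split(np.zeros(len(train_idx)), y)]


def _inner_errors(X, U, inner_folds, family, params, budget=None, **est_kw) -> np.ndarray:
    errs = []
    for tr, te in inner_folds:
        est = _make_estimator(family, params, budget, **est_kw)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # truncated-budget fits may not converge
            est.fit(X[tr], U[tr])
        errs.append(float(np.linalg.norm(U[te] - est.predict(X[te]))))
    return np.asarray(errs)


def inner_loop_score(
    X: np.ndarray,
    U: np.ndarray,
    inner_folds: list[tuple[np.ndarray, np.ndarray]],
    family: str,
    params: dict,
    budget: int | None = None,
    **est_kw,
) -> float:
    """Mean over inner folds of ||U_holdout - X_holdout beta||_F."""
    return float(_inner_errors(X, U, inner_folds, family, params, budget, **est_kw).mean())


def _tie_key(score: float, params: dict) -> tuple:
    return (score, params.get("alpha", 0.0), params.get("omega", 0.0))


def hyperband_search(
    X: np.ndarray,
    U: np.ndarray,
    inner_folds: list[tuple[np.ndarray, np.ndarray]],
    family: str,
    spec: SearchSpec,
    seed: int = 0,
    **est_kw,
) -> tuple[dict, pd.DataFrame]:
    """Successive-halving search; returns (best params, evaluation history)."""
    rng = np.random.default_rng(seed)
    if spec.method == "fixed":
        if not spec.candidates:
            raise RSLError("fixed search needs one candidate")
        return dict(spec.candidates[0]), pd.DataFrame()
    if spec.method == "grid":
        configs = [dict(c) for c in spec.candidates]
        if not configs:
            raise RSLError("grid search needs a nonempty candidate list")
        rungs = [(len(configs), spec.max_budget)]
    elif spec.method == "hyperband":
        configs = spec.sample(family, rng)
        n_rungs = max(1, math.ceil(math.log(len(configs), spec.eta)))
        rungs = []
        n, b = len(configs), max(1, spec.max_budget // spec.eta ** (n_rungs - 1))
        for _ in range(n_rungs):
            rungs.append((n, b))
            n = max(1, math.ceil(n / spec.eta))
            b = min(spec.max_budget, b * spec.eta)
    else:
        raise RSLError(f"unknown search method {spec.method!r}")
    if not configs:
        raise RSLError("empty configuration bracket")

    history = []
    survivors = configs
    final_scored: list[tuple[float, float, dict]] = []
    for rung, (n_keep, budget) in enumerate(rungs):
        scored = []
        for params in survivors:
            errs = _inner_errors(X, U, inner_folds, family, params, budget, **est_kw)
            mean = float(errs.mean())
            se = float(errs.std(ddof=1) / np.sqrt(len(errs))) if len(errs) > 1 else 0.0
            scored.append((mean, se, params))
            history.append({"rung": rung, "budget": budget, "score": mean, "se": se, **params})
        scored.sort(key=lambda t: _tie_key(t[0], t[2]))
        final_scored = scored
        if spec.method == "hyperband" and rung < len(rungs) - 1:
            keep = max(1, math.ceil(len(scored) / spec.eta))
            survivors = [p for _, _, p in scored[:keep]]
    best_mean, best_se, best = final_scored[0]
    if spec.rule == "1se":
        eligible = [(m, p) for m, _, p in final_scored if m <= best_mean + best_se]
        best = max(
            eligible, key=lambda t: (t[1].get("alpha", 0.0), t[1].get("omega", 0.0))
        )[1]
    elif spec.rule != "best":
        raise RSLError(f"unknown selection rule {spec.rule!r}")
    return best, pd.DataFrame(history)


@dataclass
class CVPrediction:
    """Out-of-sample predictions for every item, assembled across folds."""

    predicted: np.ndarray
    item_ids: list[str]
    fold_of_item: np.ndarray
    chosen_params: list[dict]
    inner_history: list[pd.DataFrame] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.predicted.shape[1])]
        df = pd.DataFrame(self.predicted, index=self.item_ids, columns=cols)
        df["fold"] = self.fold_of_item
        return df


def nested_cv_decode(
    X: np.ndarray,
    U: np.ndarray,
    fold_plan: FoldPlan,
    family: str = "growl",
    search: SearchSpec | None = None,
    seed: int = 0,
    keep_history: bool = False,
    **est_kw,
) -> CVPrediction:
    """Tune (inner loop), refit, and predict each outer holdout in turn.

    For ``family="none"`` no hyperparameters exist and the inner loop is
    skipped.  Predictor standardization is refit inside every training
    split, so holdout items never influence the fitted model.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    n, r = U.shape
    if X.shape[0] != n:
        raise RSLError("X and U must have matching item counts")
    search = search or SearchSpec()
    predicted = np.full((n, r), np.nan)
    fold_of_item = np.full(n, -1, dtype=int)
    chosen: list[dict] = []
    histories: list[pd.DataFrame] = []
    for f, test_idx in enumerate(fold_plan.folds):
        train_idx = fold_plan.train_indices(f)
        if family == "none":
            best, hist = {}, pd.DataFrame()
        else:
            inner = _inner_folds(train_idx, fold_plan.domains, search.n_inner,
                                 seed=(seed * 1009 + f) % 2**31)
            best, hist = hyperband_search(
                X, U, inner, family, search, seed=(seed * 7919 + f) % 2**31, **est_kw
            )
        est = _make_estimator(family, best, **est_kw)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(X[train_idx], U[train_idx])
        predicted[test_idx] = est.predict(X[test_idx])
        fold_of_item[test_idx] = f
        chosen.append(best)
        if keep_history:
            histories.append(hist)
    assert not np.isnan(predicted).any()
    return CVPrediction(
        predicted=predicted,
        item_ids=list(fold_plan.item_ids),
        fold_of_item=fold_of_item,
        chosen_params=chosen,
        inner_history=histories,
    )
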