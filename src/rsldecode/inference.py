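"""Permutation-based inference for cross-validated decoding statistics.

Cross-validated correlations are negatively biased under the null, so a
zero-centered t test is inappropriate.  Instead, the full decoding workflow
is rerun with the rows of the target matrix randomly permuted (default 100
permutations per subject), giving each statistic an empirical per-subject
null.  A group-level null is resampled by drawing one null value per
subject and averaging, repeated many times (default 10,000).  One-tailed
empirical p-values use p = (b + 1) / (m + 1), where b counts null values
exceeding the observed statistic; p-values are adjusted for the false
discovery rate (Benjamini-Hochberg by default).  Reported statistics are
centered on their permutation-null means to correct the bias.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import RSLError
from .model_selection import FoldPlan, SearchSpec, nested_cv_decode

__all__ = [
    "decode_statistics",
    "permuted_decode",
    "group_null",
    "empirical_p",
    "fdr_adjust",
    "center_on_null",
]


def decode_statistics(
    predicted: np.ndarray, U: np.ndarray, domains: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-dimension Pearson correlations of predicted vs true coordinates,
    for all items and (if domains are given) each domain subset."""
    predicted = np.asarray(predicted, dtype=float)
    U = np.asarray(U, dtype=float)
    subsets: dict[str, np.ndarray] = {"all": np.arange(U.shape[0])}
    if domains is not None:
        dom = np.asarray(list(domains))
        for lab in np.unique(dom):
            subsets[str(lab)] = np.flatnonzero(dom == lab)
    rows = []
    for sub, idx in subsets.items():
        for d in range(U.shape[1]):
            a, b = predicted[idx, d], U[idx, d]
            if a.std() == 0 or b.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(a, b)[0, 1])
            rows.append({"dimension": d + 1, "subset": sub, "value": r})
    return pd.DataFrame(rows)


def permuted_decode(
    X: np.ndarray,
    U: np.ndarray,
    fold_plan: FoldPlan,
    family: str = "growl",
    search: SearchSpec | None = None,
    n_perm: int = 100,
    seed: int = 0,
    domains: Sequence[str] | None = None,
    stat_fn: Callable[[np.ndarray, np.ndarray], pd.DataFrame] | None = None,
    include_identity: bool = False,
    retune: bool = True,
    **est_kw,
) -> pd.DataFrame:
    """Null statistics from decoding row-permuted targets.

    Each permutation shuffles the rows of U once and reruns the full nested
    cross-validation, so statistics for different dimensions and subsets
    within a run share a coherent null.  With ``retune=False`` the observed
    run's per-fold hyperparameters are reused instead of re-searched (cheaper,
    less conservative).  ``include_identity`` prepends permutation 0 with the
    unpermuted target as a self-check.
    """
    if n_perm < 1:
        raise RSLError("n_perm must be >= 1")
    if stat_fn is None:
        stat_fn = lambda pred, tgt: decode_statistics(pred, tgt, domains)
    rng = np.random.default_rng(seed)
    n = U.shape[0]
    if not retune:
        observed = nested_cv_decode(X, U, fold_plan, family, search, seed=seed, **est_kw)
        fixed = [SearchSpec(method="fixed", candidates=(tuple(p.items()),))
                 for p in observed.chosen_params]

    frames = []
    perms = []
    if include_identity:
        perms.append(np.arange(n))
    perms.extend(rng.permutation(n) for _ in range(n_perm))
    for pi, perm in enumerate(perms):
        Up = U[perm]
        if retune:
            pred = nested_cv_decode(X, Up, fold_plan, family, search, seed=seed, **est_kw)
            predicted = pred.predicted
        else:
            predicted = _decode_with_fixed(X, Up, fold_plan, family, fixed, **est_kw)
        stats = stat_fn(predicted, Up)
        stats.insert(0, "perm", pi if include_identity else pi + 1)
        frames.append(stats)
    return pd.concat(frames, ignore_index=True)


def _decode_with_fixed(X, U, fold_plan, family, fixed_specs, **est_kw):
    from .model_selection import _make_estimator
    import warnings as _w
    predicted = np.full_like(U, np.nan, dtype=float)
    for f, test_idx in enumerate(fold_plan.folds):
        train_idx = fold_plan.train_indices(f)
        params = dict(fixed_specs[f].candidates[0]) if family != "none" else {}
        est = _make_estimator(family, params, **est_kw)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            est.fit(X[train_idx], U[train_idx])
        predicted[test_idx] = est.predict(X[test_idx])
    return predicted


def group_null(
    per_subject_stats: Sequence[np.ndarray] | dict,
    n_group: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Resampled group-average null: one draw per subject, averaged, n_group times."""
    if isinstance(per_subject_stats, dict):
        per_subject_stats = list(per_subject_stats.values())
    arrays = [np.asarray(a, dtype=float) for a in per_subject_stats]
    if len(arrays) == 0:
        raise RSLError("need at least one subject")
    if any(a.size == 0 for a in arrays):
        raise RSLError("every subject needs a nonempty null distribution")
    rng = np.random.default_rng(seed)
    draws = np.stack([a[rng.integers(0, a.size, size=n_group)] for a in arrays])
    return draws.mean(axis=0)


def empirical_p(observed: float, null_vector: np.ndarray) -> float:
    """One-tailed permutation p-value, p = (b + 1)/(m + 1)."""
    null_vector = np.asarray(null_vector, dtype=float)
    if null_vector.size == 0:
        raise RSLError("null distribution is empty")
    if not np.isfinite(observed) or not np.isfinite(null_vector).all():
        raise RSLError("NaN/inf in observed statistic or null distribution")
    b = int(np.sum(null_vector > observed))
    return (b + 1) / (null_vector.size + 1)


def fdr_adjust(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (or BY) adjusted p-values; order-preserving, >= raw."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise RSLError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if key is None:
        raise RSLError(f"unknown FDR method {method!r}")
    return multipletests(p, method=key)[1]


def center_on_null(observed: float, null_vector: np.ndarray) -> float:
    """Bias-corrected statistic: observed minus the permutation-null mean."""
    null_vector = np.asarray(null_vector, dtype=float)
    if null_vector.size == 0:
        raise RSLError("null distribution is empty")
    return float(observed - null_vector.mean())
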