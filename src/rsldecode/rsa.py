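"""Representational similarity analysis baseline.

Standard RSA correlates the lower triangle of a neural similarity matrix
(NSM, pairwise similarities between measured item patterns) with the lower
triangle of a target representational similarity matrix (RSM).  The module
exists both as the comparison method and for the simulation study showing
when RSA succeeds and fails: a discrete binary animacy code and a code for
the dominant component yield robust RSM correlations, while faithful graded
multidimensional codes can look weak or null.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateItemError, UndefinedCorrelationError, RSLError
from .semantic import SemanticEmbedding, SimilarityMatrix
from .simulate import CONDITION_NAMES, NoiseSpec, SignalCondition, sweep_conditions

__all__ = ["compute_nsm", "rsa_correlation", "run_simulation_study1", "summarize_study1"]


def compute_nsm(
    X: np.ndarray,
    item_ids: Sequence[str] | None = None,
    subset: Sequence[int] | None = None,
    measure: str = "pearson",
) -> SimilarityMatrix:
    """Neural similarity matrix: pairwise pattern similarity over items.

    ``measure`` is ``pearson`` (default; identical to cosine similarity of
    row-centered patterns) or ``cosine`` (patterns compared as given).
    ``subset`` selects item rows (by index) before anything is computed.
    """
    X = np.asarray(X, dtype=float)
    ids = list(item_ids) if item_ids is not None else [str(i) for i in range(X.shape[0])]
    if subset is not None:
        subset = np.asarray(subset)
        X = X[subset]
        ids = [ids[i] for i in subset]
    if X.shape[0] < 3:
        raise RSLError("need at least 3 items to build an NSM")
    if X.shape[1] < 2:
        raise RSLError("need at least 2 features")
    if measure == "pearson":
        if (X.std(axis=1) == 0).any():
            bad = [ids[i] for i in np.flatnonzero(X.std(axis=1) == 0)]
            raise DegenerateItemError(f"constant pattern row(s) for item(s): {bad}")
        S = np.corrcoef(X)
    elif measure == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = [ids[i] for i in np.flatnonzero(norms == 0)]
            raise DegenerateItemError(f"all-zero pattern row(s) for item(s): {bad}")
        R = X / norms[:, None]
        S = R @ R.T
    else:
        raise RSLError(f"unknown measure {measure!r}")
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, ids, kind="neural")


def rsa_correlation(
    nsm: SimilarityMatrix, rsm: SimilarityMatrix, method: str = "pearson"
) -> float:
    """Correlation between the strictly-lower triangles of NSM and RSM."""
    if nsm.item_ids != rsm.item_ids:
        raise RSLError("NSM and RSM must share the same items in the same order")
    a, b = nsm.lower_triangle(), rsm.lower_triangle()
    if a.std() == 0 or b.std() == 0:
        raise UndefinedCorrelationError("zero variance in a similarity triangle")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise RSLError(f"unknown method {method!r}")


def run_simulation_study1(
    embedding: SemanticEmbedding,
    target_rsm: SimilarityMatrix,
    conditions: Sequence[str | SignalCondition] = CONDITION_NAMES,
    noise: NoiseSpec = NoiseSpec(),
    method: str = "pearson",
) -> pd.DataFrame:
    """RSA over the full condition x noise-level x repetition sweep.

    For every generated feature set the NSM is computed and correlated with
    the full target RSM.  Returns a tidy table (condition, level, rep, rho);
    use :func:`summarize_study1` for per-level means and 95% CIs.
    """
    datasets = sweep_conditions(embedding, conditions, noise)
    rows = []
    for (cond, level, rep), X in datasets.items():
        nsm = compute_nsm(X, item_ids=embedding.item_ids)
        rho = rsa_correlation(nsm, target_rsm, method=method)
        rows.append({"condition": cond, "level": level, "rep": rep, "rho": rho})
    return pd.DataFrame(rows)


def summarize_study1(results: pd.DataFrame, ci: float = 0.95) -> pd.DataFrame:
    """Per-(condition, level) mean rho with a t-based confidence interval."""
    def agg(g: pd.DataFrame) -> pd.Series:
        x = g["rho"].to_numpy()
        mean = x.mean()
        if len(x) > 1 and x.std(ddof=1) > 0:
            half = stats.t.ppf(0.5 + ci / 2, len(x) - 1) * x.std(ddof=1) / np.sqrt(len(x))
        else:
            half = 0.0
        return pd.Series({"mean_rho": mean, "ci_low": mean - half, "ci_high": mean + half,
                          "n": len(x)})

    out = (
        results.groupby(["condition", "level"])[["rho"]]
        .apply(agg)
        .reset_index()
    )
    return out
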