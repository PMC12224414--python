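"""Trial-timeseries preprocessing, temporal windowing, and evaluation.

Voltage epochs (items x electrodes x timepoints) are averaged over stimulus
repetitions, boxcar-downsampled, flattened into an items x (electrode, time)
feature matrix, and censored for extreme outliers (columns, then rows, whose
marginal mean sits more than 5 SD from the grand mean).  Feature matrices
are sliced into opening windows (a growing aperture anchored at stimulus
onset) or moving windows (fixed 100 ms width, stepped 50 ms), decoded per
window, and scored: Pearson correlations between predicted and true
coordinates per dimension and item subset, and per-item correlations
between predicted and true similarity rows within comparison scopes (all
other items / same domain / other domain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RSLError
from .inference import (
    center_on_null,
    decode_statistics,
    empirical_p,
    fdr_adjust,
    group_null,
    permuted_decode,
)
from .model_selection import CVPrediction, FoldPlan, SearchSpec, make_fold_plan, nested_cv_decode
from .semantic import SemanticEmbedding, reconstruct_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTimeseries",
    "NeuralFeatureMatrix",
    "WindowSpec",
    "boxcar_downsample",
    "average_repetitions",
    "censor_outliers",
    "flatten_timeseries",
    "slice_windows",
    "evaluate_predictions",
    "score_reconstruction",
    "run_study",
]


@dataclass
class TrialTimeseries:
    """Per-item voltage epochs: items x electrodes x timepoints."""

    voltages: np.ndarray
    rate_hz: float
    epoch_ms: tuple[float, float] = (0.0, 1000.0)
    item_ids: list[str] | None = None
    domains: list[str] | None = None
    repetitions_averaged: bool = True

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 3:
            raise RSLError("voltages must be items x electrodes x timepoints")

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.rate_hz
        return self.epoch_ms[0] + step * np.arange(self.voltages.shape[2])


@dataclass
class NeuralFeatureMatrix:
    """Items x concatenated (electrode, time) features with provenance."""

    X: np.ndarray
    column_map: list[tuple[int, int]]
    item_ids: list[str]
    domains: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise RSLError("X must be 2-D")
        if len(self.column_map) != self.X.shape[1]:
            raise RSLError("column_map length must equal the number of columns")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([t for _, t in self.column_map])


@dataclass(frozen=True)
class WindowSpec:
    """Temporal feature-selection scheme over the trial epoch."""

    mode: str = "full"
    onsets: tuple[float, ...] = ()
    widths: tuple[float, ...] = ()

    @classmethod
    def opening(cls, epoch_ms: float = 1000.0, first: float = 50.0,
                step: float = 100.0) -> "WindowSpec":
        """Growing aperture from onset: 0-50, 0-100, then +step up to the epoch."""
        widths = [first] + list(np.arange(step, epoch_ms + step / 2, step))
        return cls("opening", tuple(0.0 for _ in widths), tuple(widths))

    @classmethod
    def moving(cls, width: float = 100.0, step: float = 50.0,
               epoch_ms: float = 1000.0) -> "WindowSpec":
        """Fixed-width windows stepped across the epoch (last onset epoch-width)."""
        onsets = np.arange(0.0, epoch_ms - width + step / 2, step)
        return cls("moving", tuple(onsets), tuple(width for _ in onsets))

    @classmethod
    def full(cls, epoch_ms: float = 1000.0) -> "WindowSpec":
        return cls("full", (0.0,), (epoch_ms,))

    def windows(self) -> list[tuple[float, float]]:
        return [(o, o + w) for o, w in zip(self.onsets, self.widths)]


def boxcar_downsample(voltages: np.ndarray, from_hz: float, to_hz: float) -> np.ndarray:
    """Average consecutive samples within non-overlapping boxcars.

    Works on the last axis; ``from_hz`` must be an integer multiple of
    ``to_hz`` (e.g., 1000 Hz -> 100 Hz averages 10 ms boxcars).
    """
    ratio = from_hz / to_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise RSLError(f"{from_hz} Hz is not an integer multiple of {to_hz} Hz")
    k = int(round(ratio))
    v = np.asarray(voltages, dtype=float)
    n = v.shape[-1]
    if n % k:
        raise RSLError(f"{n} samples do not divide into {k}-sample boxcars")
    return v.reshape(*v.shape[:-1], n // k, k).mean(axis=-1)


def average_repetitions(voltages: np.ndarray) -> np.ndarray:
    """Mean voltage over stimulus repetitions (axis 1 of items x reps x ...).

    Missing repetitions may be encoded as NaN; items are then averaged over
    the available repetitions (logged).
    """
    v = np.asarray(voltages, dtype=float)
    if v.ndim < 2:
        raise RSLError("expected items x repetitions x ... array")
    if np.isnan(v).any():
        n_missing = int(np.isnan(v).all(axis=tuple(range(2, v.ndim))).sum())
        logger.info("averaging over available repetitions (%d missing)", n_missing)
        with np.errstate(invalid="ignore"):
            return np.nanmean(v, axis=1)
    return v.mean(axis=1)


def censor_outliers(
    nfm: NeuralFeatureMatrix, threshold_sd: float = 5.0
) -> tuple[NeuralFeatureMatrix, dict]:
    """Drop extreme columns, then rows, by marginal-mean deviation.

    A column (then, after recomputation on the surviving columns, a row) is
    rejected when its marginal mean lies more than ``threshold_sd`` standard
    deviations of the marginal means from the grand mean.  Row removal uses
    statistics recomputed after column removal, so a wild cell removed with
    its column cannot also cost its row.
    """
    if threshold_sd <= 0:
        raise RSLError("threshold_sd must be positive")
    X = nfm.X
    col_means = X.mean(axis=0)
    sd = col_means.std(ddof=0)
    keep_cols = (
        np.abs(col_means - X.mean()) <= threshold_sd * sd
        if sd > 0
        else np.ones(X.shape[1], dtype=bool)
    )
    if not keep_cols.any():
        raise RSLError("outlier censoring removed every column")
    X2 = X[:, keep_cols]
    row_means = X2.mean(axis=1)
    sd_r = row_means.std(ddof=0)
    keep_rows = (
        np.abs(row_means - X2.mean()) <= threshold_sd * sd_r
        if sd_r > 0
        else np.ones(X.shape[0], dtype=bool)
    )
    report = {
        "removed_columns": np.flatnonzero(~keep_cols).tolist(),
        "removed_rows": np.flatnonzero(~keep_rows).tolist(),
    }
    out = NeuralFeatureMatrix(
        X=X2[keep_rows],
        column_map=[c for c, k in zip(nfm.column_map, keep_cols) if k],
        item_ids=[i for i, k in zip(nfm.item_ids, keep_rows) if k],
        domains=(
            [d for d, k in zip(nfm.domains, keep_rows) if k]
            if nfm.domains is not None
            else None
        ),
    )
    return out, report


def flatten_timeseries(ts: TrialTimeseries) -> NeuralFeatureMatrix:
    """Concatenate electrodes' timecourses into one feature vector per item."""
    n, e, t = ts.voltages.shape
    X = ts.voltages.reshape(n, e * t)
    times = ts.times_ms
    column_map = [(el, int(round(times[ti]))) for el in range(e) for ti in range(t)]
    ids = ts.item_ids if ts.item_ids is not None else [str(i) for i in range(n)]
    return NeuralFeatureMatrix(X, column_map, list(ids), ts.domains)


def slice_windows(
    nfm: NeuralFeatureMatrix, spec: WindowSpec
) -> list[tuple[tuple[float, float], NeuralFeatureMatrix]]:
    """Select feature columns by time tag for each window in the spec."""
    out = []
    times = nfm.times
    for onset, offset in spec.windows():
        mask = (times >= onset) & (times < offset)
        if not mask.any():
            raise RSLError(f"window [{onset}, {offset}) ms selects no columns")
        sub = NeuralFeatureMatrix(
            X=nfm.X[:, mask],
            column_map=[c for c, k in zip(nfm.column_map, mask) if k],
            item_ids=list(nfm.item_ids),
            domains=nfm.domains,
        )
        out.append(((onset, offset), sub))
    return out


def evaluate_predictions(
    predicted: CVPrediction | np.ndarray,
    embedding: SemanticEmbedding,
    domains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Coordinate-level evaluation: Pearson r per dimension x item subset."""
    pred = predicted.predicted if isinstance(predicted, CVPrediction) else predicted
    if domains is None:
        domains = embedding.domains
    return decode_statistics(pred, embedding.coords, domains)


def score_reconstruction(
    pred_coords: np.ndarray,
    embedding: SemanticEmbedding,
    domains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Similarity-level evaluation of predicted coordinates.

    Predicted similarities (coords @ coords.T) are compared row-by-row with
    the rank-r truncation of the true matrix: for each item, its predicted
    similarities to (a) all other items, (b) same-domain items, (c)
    other-domain items are correlated with the true values, and the
    correlations are averaged over item groups (all / each domain).
    """
    pred_coords = np.asarray(pred_coords, dtype=float)
    if pred_coords.shape != embedding.coords.shape:
        raise RSLError("predicted coordinates must match the embedding shape")
    if domains is None:
        domains = embedding.domains
    if domains is None:
        raise RSLError("domains are required for scoped similarity scoring")
    dom = np.asarray(list(domains))
    S_pred = pred_coords @ pred_coords.T
    S_true = embedding.coords @ embedding.coords.T
    n = len(dom)
    scopes = {}
    for i in range(n):
        others = np.arange(n) != i
        scopes[i] = {
            "all others": others,
            "same domain": others & (dom == dom[i]),
            "other domain": others & (dom != dom[i]),
        }
    for i in range(n):
        for name, mask in scopes[i].items():
            if mask.sum() < 3:
                raise RSLError(f"scope {name!r} has fewer than 3 comparison items")
    per_item = {name: np.full(n, np.nan) for name in ("all others", "same domain", "other domain")}
    for i in range(n):
        for name, mask in scopes[i].items():
            a, b = S_pred[i, mask], S_true[i, mask]
            if a.std() > 0 and b.std() > 0:
                per_item[name][i] = np.corrcoef(a, b)[0, 1]
    groups = {"all": np.ones(n, dtype=bool)}
    for lab in np.unique(dom):
        groups[str(lab)] = dom == lab
    rows = []
    for gname, gmask in groups.items():
        for sname, vals in per_item.items():
            sel = vals[gmask]
            mean = float(np.nanmean(sel)) if np.isfinite(sel).any() else np.nan
            rows.append({"group": gname, "scope": sname, "value": mean})
    return pd.DataFrame(rows)


def run_study(
    subjects: dict[str, NeuralFeatureMatrix],
    embedding: SemanticEmbedding,
    window_spec: WindowSpec,
    family: str = "growl",
    search: SearchSpec | None = None,
    n_perm: int = 100,
    n_group: int = 10_000,
    k_outer: int = 10,
    seed: int = 0,
    censor: bool = True,
    retune_permutations: bool = True,
    **est_kw,
) -> dict:
    """Full per-subject, per-window decode -> evaluate -> inference bundle.

    For every subject and window: nested-CV decoding of the embedding,
    coordinate-level statistics, and a per-subject permutation null.  Group
    level: statistics are averaged over subjects, a resampled group null is
    built per statistic, and empirical p-values (FDR-adjusted together
    within the bundle) and null-centered values are reported.  Subjects that
    fail are recorded and excluded from the group tables.
    """
    if not window_spec.windows():
        raise RSLError("empty window list")
    rng = np.random.default_rng(seed)
    U = embedding.coords
    obs_frames, null_frames, failed = [], [], []
    for si, (name, nfm) in enumerate(subjects.items()):
        try:
            if censor:
                nfm, _ = censor_outliers(nfm)
            dom = nfm.domains or embedding.domains
            plan = make_fold_plan(nfm.item_ids, dom, k_outer=k_outer, seed=seed + si)
            idx = [embedding.item_ids.index(i) for i in nfm.item_ids]
            U_s = U[idx]
            for (onset, offset), wnfm in slice_windows(nfm, window_spec):
                wid = f"{onset:g}-{offset:g}"
                pred = nested_cv_decode(
                    wnfm.X, U_s, plan, family, search, seed=seed + si, **est_kw
                )
                stats = decode_statistics(pred.predicted, U_s, dom)
                stats.insert(0, "window", wid)
                stats.insert(0, "subject", name)
                obs_frames.append(stats)
                nulls = permuted_decode(
                    wnfm.X, U_s, plan, family, search, n_perm=n_perm,
                    seed=int(rng.integers(2**31)), domains=dom,
                    retune=retune_permutations, **est_kw,
                )
                nulls.insert(0, "window", wid)
                nulls.insert(0, "subject", name)
                null_frames.append(nulls)
        except Exception as exc:  # keep other subjects alive
            logger.warning("subject %s failed: %s", name, exc)
            failed.append((name, str(exc)))
    if not obs_frames:
        raise RSLError("every subject failed")
    observed = pd.concat(obs_frames, ignore_index=True)
    nulls = pd.concat(null_frames, ignore_index=True)

    keys = ["window", "dimension", "subset"]
    rows = []
    for key, grp in observed.groupby(keys):
        nn = nulls
        for k, v in zip(keys, key):
            nn = nn[nn[k] == v]
        per_subject = [g["value"].to_numpy() for _, g in nn.groupby("subject")]
        gnull = group_null(per_subject, n_group=n_group, seed=int(rng.integers(2**31)))
        obs_mean = float(grp["value"].mean())
        sem = float(grp["value"].std(ddof=1) / np.sqrt(len(grp))) if len(grp) > 1 else 0.0
        rows.append({
            **dict(zip(keys, key)),
            "observed": obs_mean,
            "sem": sem,
            "centered": center_on_null(obs_mean, gnull),
            "p": empirical_p(obs_mean, gnull),
            "n_subjects": len(grp),
        })
    group = pd.DataFrame(rows)
    group["p_adj"] = fdr_adjust(group["p"])
    return {
        "observed": observed,
        "nulls": nulls,
        "group": group,
        "failed_subjects": failed,
    }
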