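"""Target semantic space: similarity matrices and their low-rank embedding.

The decoding target is built in three steps: binary feature norms (items x
features) are column-mean-centered and converted to a cosine similarity
matrix S; S is decomposed by SVD into r orthogonal components; each item's
coordinates on the r components, weighted by the square roots of the
singular values, form the embedding U that decoding models predict.  The
product of the embedding with its transpose reconstructs the rank-r
truncation of S, which is how predicted coordinates are scored as predicted
similarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateItemError, RSLError

__all__ = [
    "FeatureNormMatrix",
    "SimilarityMatrix",
    "SemanticEmbedding",
    "build_cosine_rsm",
    "svd_embed",
    "reconstruct_similarity",
    "binary_animacy_rsm",
]

_SYM_TOL = 1e-10


@dataclass
class FeatureNormMatrix:
    """Binary item x feature matrix with item labels and animacy domains.

    ``values`` entries must be 0/1 (before any centering); ``domains`` maps
    each item to one of two labels, conventionally ``animate``/``inanimate``.
    """

    values: np.ndarray
    item_ids: list[str]
    domains: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RSLError("feature norms must be a 2-D items x features array")
        n = self.values.shape[0]
        if len(self.item_ids) != n:
            raise RSLError("item_ids length does not match the number of rows")
        if len(set(self.item_ids)) != n:
            raise RSLError("item_ids must be unique")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise RSLError("feature norm entries must be binary (0/1)")
        if (self.values.sum(axis=1) == 0).any():
            bad = [self.item_ids[i] for i in np.flatnonzero(self.values.sum(axis=1) == 0)]
            raise RSLError(f"items with all-zero feature rows: {bad}")
        if self.domains is not None:
            if len(self.domains) != n:
                raise RSLError("domains length does not match the number of items")
            labels = set(self.domains)
            if len(labels) != 2:
                raise RSLError(f"expected exactly two domain labels, got {sorted(labels)}")

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "FeatureNormMatrix":
        """Read norms from delimited text: first column item id, optional
        ``domain`` column, remaining columns binary features."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        domains = None
        if "domain" in df.columns:
            domains = df["domain"].astype(str).tolist()
            df = df.drop(columns=["domain"])
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], domains)


@dataclass
class SimilarityMatrix:
    """Symmetric item x item similarity matrix.

    ``kind`` records provenance: ``target-semantic`` (from feature norms),
    ``binary-animacy``, ``neural`` (from measured patterns) or ``predicted``
    (from decoded coordinates).
    """

    values: np.ndarray
    item_ids: list[str]
    kind: str = "target-semantic"

    _BOUNDED_KINDS = ("target-semantic", "binary-animacy", "neural")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise RSLError("similarity matrix must be square")
        if len(self.item_ids) != n:
            raise RSLError("item_ids length does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise RSLError("similarity matrix is not symmetric within 1e-10")
        if self.kind in self._BOUNDED_KINDS:
            if np.abs(self.values).max() > 1 + 1e-8:
                raise RSLError(f"{self.kind} similarities must lie in [-1, 1]")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Strictly-lower-triangle values (the n(n-1)/2 unique pairs)."""
        i, j = np.tril_indices(self.n_items, k=-1)
        return self.values[i, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_ids, columns=self.item_ids)


@dataclass
class SemanticEmbedding:
    """Item coordinates on r orthogonal components of a similarity matrix.

    ``coords`` holds the root-weighted singular vectors (V * sqrt(sigma)), so
    ``coords @ coords.T`` reproduces the rank-r truncation of the source
    matrix.  ``variance_explained`` is each component's share sigma_k / sum(sigma).
    """

    coords: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    r: int
    item_ids: list[str]
    domains: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise RSLError("singular values must be nonincreasing")
        if np.any(self.singular_values < -1e-12):
            raise RSLError("singular values must be nonnegative")

    @property
    def n_items(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.item_ids, columns=cols)


def build_cosine_rsm(norms: FeatureNormMatrix) -> SimilarityMatrix:
    """Cosine similarity of column-mean-centered feature-norm rows.

    Feature columns are mean-centered, then every pair of item rows is
    compared by cosine similarity.  Constant feature columns contribute
    nothing after centering; they are retained but flagged with a warning.
    """
    V = norms.values
    if V.shape[0] < 2 or V.shape[1] < 2:
        raise RSLError("need at least 2 items and 2 features")
    n_const = int((V.std(axis=0) == 0).sum())
    if n_const:
        warnings.warn(
            f"{n_const} constant feature column(s) contribute nothing after centering",
            stacklevel=2,
        )
    C = V - V.mean(axis=0, keepdims=True)
    row_norms = np.linalg.norm(C, axis=1)
    if (row_norms == 0).any():
        bad = [norms.item_ids[i] for i in np.flatnonzero(row_norms == 0)]
        raise DegenerateItemError(f"all-zero centered rows for item(s): {bad}")
    R = C / row_norms[:, None]
    S = R @ R.T
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(norms.item_ids), kind="target-semantic")


def svd_embed(
    rsm: SimilarityMatrix,
    r: int,
    domains: Sequence[str] | None = None,
    animate_label: str = "animate",
) -> SemanticEmbedding:
    """Decompose a symmetric similarity matrix into r root-weighted components.

    The symmetric eigendecomposition is the SVD for the (positive
    semi-definite) cosine matrices this package produces; any small negative
    eigenvalues arising from centering/rounding are clipped to zero before
    square roots are taken (with a warning stating the clip magnitude).

    Sign convention: if ``domains`` is given, each component is oriented so
    the mean coordinate of ``animate_label`` items is nonnegative; otherwise
    so the largest-magnitude loading is positive.  SVD signs are otherwise
    arbitrary and downstream correlations are sign-sensitive.
    """
    n = rsm.n_items
    if not 1 <= r <= n:
        raise RSLError(f"rank r={r} must satisfy 1 <= r <= {n}")
    vals, vecs = np.linalg.eigh(rsm.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals.min() < -1e-10:
        warnings.warn(
            f"clipping negative eigenvalues (most negative {vals.min():.3e}) to zero",
            stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    rank = int((vals > vals[0] * 1e-12).sum()) if vals[0] > 0 else 0
    if r > rank:
        warnings.warn(
            f"requested r={r} exceeds numerical rank {rank}; trailing components are zero",
            stacklevel=2,
        )
    sigma = vals[:r]
    U = vecs[:, :r] * np.sqrt(sigma)[None, :]
    # orient components deterministically
    for k in range(r):
        if domains is not None:
            dom = np.asarray(domains)
            ref = U[dom == animate_label, k].mean()
        else:
            ref = U[np.argmax(np.abs(U[:, k])), k]
        if ref < 0:
            U[:, k] = -U[:, k]
    total = vals.sum()
    ve = sigma / total if total > 0 else np.zeros(r)
    return SemanticEmbedding(
        coords=U,
        singular_values=sigma,
        variance_explained=ve,
        r=r,
        item_ids=list(rsm.item_ids),
        domains=list(domains) if domains is not None else None,
    )


def reconstruct_similarity(
    coords: np.ndarray, item_ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Predicted similarities from (predicted) coordinates: coords @ coords.T."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise RSLError("coords must be 2-D (items x r)")
    if not np.isfinite(coords).all():
        raise RSLError("coords must be finite")
    S = coords @ coords.T
    S = (S + S.T) / 2.0
    ids = list(item_ids) if item_ids is not None else [str(i) for i in range(len(S))]
    return SimilarityMatrix(S, ids, kind="predicted")


def binary_animacy_rsm(
    domains: Sequence[str], item_ids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Categorical target: 1 for same-domain item pairs, 0 otherwise."""
    dom = np.asarray(list(domains))
    labels = set(dom.tolist())
    if len(labels) > 2:
        raise RSLError(f"expected at most two domain labels, got {sorted(labels)}")
    S = (dom[:, None] == dom[None, :]).astype(float)
    ids = list(item_ids) if item_ids is not None else [str(i) for i in range(len(dom))]
    return SimilarityMatrix(S, ids, kind="binary-animacy")
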