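"""Synthetic data generators.

Two families of fixtures with known ground truth:

* Feature-set simulations: 24 simulated features responding to the items of
  a semantic embedding under five signal conditions (a binary animacy code,
  three one-dimensional graded codes, and a full three-dimensional code),
  with half the features carrying signal and half uniform noise, swept over
  graded additive uniform noise.  These are the inputs for the RSA-vs-RSL
  comparison at small scale.

* Synthetic electrophysiology: items x (electrodes x timepoints) voltage
  matrices in which a row-sparse, correlated, non-axis-aligned linear code
  for the 3-D embedding is planted within a latency band.  This exercises
  exactly the structural assumptions the grOWL regularizer encodes (sparse,
  redundant, spanning) and gives the window pipeline a planted ground truth.

Every generator is a pure function of its parameters and seed; independent
streams are derived per dataset from (master seed, condition, level, rep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import RSLError
from .semantic import SemanticEmbedding

__all__ = [
    "CONDITION_NAMES",
    "SignalCondition",
    "NoiseSpec",
    "SyntheticEphys",
    "make_synthetic_norms",
    "make_condition_dataset",
    "sweep_conditions",
    "make_synthetic_ephys",
]

CONDITION_NAMES = ("binary", "oneD-1", "oneD-2", "oneD-3", "full")


def make_synthetic_norms(
    n_items: int = 100,
    n_subcategories: int = 3,
    n_domain_features: int = 20,
    n_subcat_features: int = 2,
    n_idiosyncratic: int = 28,
    p_idiosyncratic: float = 0.3,
    seed: int = 0,
):
    """Synthetic binary feature norms with animate/inanimate block structure.

    A stand-in for real feature-norming data: half the items are animate,
    half inanimate; each domain splits into subcategories.  Features are
    domain markers (shared by one domain), subcategory markers, and
    idiosyncratic Bernoulli features.  The resulting cosine similarity
    matrix has a dominant first component separating the domains with
    weaker components for within-domain structure, mimicking the spectrum
    of real norming studies.  Returns a FeatureNormMatrix.
    """
    from .semantic import FeatureNormMatrix

    if n_items % 2:
        raise RSLError("n_items must be even (half animate, half inanimate)")
    rng = np.random.default_rng(seed)
    half = n_items // 2
    domains = ["animate"] * half + ["inanimate"] * half
    sub_of = np.concatenate([np.full(len(ch), i) for i, ch in
                             enumerate(np.array_split(np.arange(half), n_subcategories))])
    blocks = []
    # domain markers, possessed with subcategory-graded probability so the
    # dominant component also spreads items out within each domain (real
    # norms' first component individuates subcategories, not just domains)
    grade = np.linspace(0.95, 0.45, n_subcategories)
    dom_block = np.zeros((n_items, 2 * n_domain_features))
    for off, cols in ((0, slice(0, n_domain_features)),
                      (half, slice(n_domain_features, 2 * n_domain_features))):
        probs = grade[sub_of]
        dom_block[off : off + half, cols] = rng.random((half, n_domain_features)) < probs[:, None]
    blocks.append(dom_block)
    # subcategory markers (animate subcats better separated than inanimate,
    # as in real norms: extra marker features for animate subcategories)
    for start, extra in ((0, n_subcat_features), (half, 0)):
        width = n_subcat_features + extra
        sub_block = np.zeros((n_items, n_subcategories * width))
        for s in range(n_subcategories):
            rows = start + np.flatnonzero(sub_of == s)
            sub_block[rows, s * width : (s + 1) * width] = 1
        blocks.append(sub_block)
    blocks.append((rng.random((n_items, n_idiosyncratic)) < p_idiosyncratic).astype(float))
    V = np.concatenate(blocks, axis=1)
    # guard the no-all-zero-row invariant (idiosyncratic block is random)
    V[V.sum(axis=1) == 0, -1] = 1
    ids = [f"item{k:03d}" for k in range(n_items)]
    return FeatureNormMatrix(V, ids, domains)


@dataclass(frozen=True)
class SignalCondition:
    """One hypothesis about what the simulated features encode.

    ``binary``: signal features take one state (+1/-1) for animate items and
    the opposite for inanimate.  ``oneD-k``: signal features are copies of
    embedding component k.  ``full``: signal features split evenly across
    the three components.  In every condition the remaining
    ``n_features - n_signal`` features are uniform noise over the signal range.
    """

    name: str
    n_features: int = 24
    n_signal: int = 12
    dims_encoded: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.name not in CONDITION_NAMES:
            raise RSLError(f"unknown condition {self.name!r}; expected one of {CONDITION_NAMES}")
        if self.n_signal > self.n_features:
            raise RSLError("n_signal cannot exceed n_features")
        if self.name == "full" and self.n_signal % len(self.dims_encoded or (1, 2, 3)) != 0:
            raise RSLError("full condition requires n_signal divisible by the encoded dims")

    @classmethod
    def from_name(cls, name: str, n_features: int = 24, n_signal: int = 12) -> "SignalCondition":
        dims: tuple[int, ...]
        if name == "binary":
            dims = ()
        elif name.startswith("oneD-"):
            dims = (int(name.split("-")[1]),)
        elif name == "full":
            dims = (1, 2, 3)
        else:
            raise RSLError(f"unknown condition {name!r}")
        return cls(name, n_features, n_signal, dims)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive measurement-noise sweep: Uniform(-h, +h) half-widths.

    Signal features are standardized (unit variance), so half-widths are in
    signal-SD units.  Defaults: 11 levels linearly spaced on [0, 16], 20
    runs per level — wide enough that RSA on the weakest one-dimensional
    codes visibly decays to null while the binary/dominant codes stay
    reliably positive.
    """

    levels: tuple[float, ...] = tuple(np.linspace(0.0, 16.0, 11))
    reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.size == 0 or np.any(np.diff(lv) <= 0) or lv[0] < 0:
            raise RSLError("noise levels must be strictly increasing and start at >= 0")
        if self.reps < 1:
            raise RSLError("reps must be >= 1")


@dataclass
class SyntheticEphys:
    """Planted-signal voltage fixture.

    ``X`` is items x (electrodes*timepoints); ``column_map`` gives
    (electrode, time_ms) per column; ``ground_truth_mixing`` is the r x m
    mixing matrix G (column-sparse: only planted columns are nonzero) such
    that the clean signal is ``coords_z @ G``.
    """

    X: np.ndarray
    column_map: list[tuple[int, int]]
    ground_truth_mixing: np.ndarray
    signal_window: tuple[float, float]
    group_structure: list[list[int]]
    seed: int
    item_ids: list[str]
    domains: list[str] | None = None

    @property
    def support(self) -> np.ndarray:
        """Indices of signal-carrying columns."""
        return np.flatnonzero(np.any(self.ground_truth_mixing != 0, axis=0))


def _zscore_cols(A: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (A - A.mean(axis=0)) / sd


def _signal_block(embedding: SemanticEmbedding, condition: SignalCondition,
                  rng: np.random.Generator) -> np.ndarray:
    """Noise-free signal features (items x n_signal), unit variance each."""
    n = embedding.n_items
    Z = _zscore_cols(embedding.coords)
    k = condition.n_signal
    if condition.name == "binary":
        if embedding.domains is None:
            raise RSLError("binary condition requires item domains on the embedding")
        dom = np.asarray(embedding.domains)
        code = np.where(dom == dom[0], 1.0, -1.0)
        signs = rng.choice((-1.0, 1.0), size=k)
        return code[:, None] * signs[None, :]
    if condition.name.startswith("oneD"):
        d = condition.dims_encoded[0]
        if embedding.coords.shape[1] < d:
            raise RSLError(f"embedding has fewer than {d} components")
        signs = rng.choice((-1.0, 1.0), size=k)
        return Z[:, d - 1][:, None] * signs[None, :]
    # full: n_signal/3 features per component
    per = k // len(condition.dims_encoded)
    cols = []
    for d in condition.dims_encoded:
        signs = rng.choice((-1.0, 1.0), size=per)
        cols.append(Z[:, d - 1][:, None] * signs[None, :])
    return np.concatenate(cols, axis=1)


def make_condition_dataset(
    embedding: SemanticEmbedding,
    condition: SignalCondition | str,
    noise_halfwidth: float,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Simulated feature responses (items x n_features) for one condition.

    Half the features carry the condition's signal; the rest draw uniform
    values over the signal range.  Finally every entry receives additive
    Uniform(-noise_halfwidth, +noise_halfwidth) measurement noise.
    """
    if noise_halfwidth < 0:
        raise RSLError("noise_halfwidth must be nonnegative")
    if isinstance(condition, str):
        condition = SignalCondition.from_name(condition)
    if embedding.coords.shape[1] < 3:
        raise RSLError("embedding must have r >= 3 components")
    if condition.n_features % 2:
        raise RSLError("n_features must be even (half signal, half noise)")
    rng = np.random.default_rng(seed)
    S = _signal_block(embedding, condition, rng)
    lo, hi = S.min(), S.max()
    n = embedding.n_items
    noise_feats = rng.uniform(lo, hi, size=(n, condition.n_features - condition.n_signal))
    X = np.concatenate([S, noise_feats], axis=1)
    X = X + rng.uniform(-noise_halfwidth, noise_halfwidth, size=X.shape)
    return X


def sweep_conditions(
    embedding: SemanticEmbedding,
    conditions: Sequence[SignalCondition | str] = CONDITION_NAMES,
    noise: NoiseSpec = NoiseSpec(),
) -> dict[tuple[str, float, int], np.ndarray]:
    """All (condition, noise level, repetition) datasets, seed-reproducible.

    Streams are spawned per dataset from (master seed, condition index,
    level index, rep) so generation order never matters.
    """
    conds = [SignalCondition.from_name(c) if isinstance(c, str) else c for c in conditions]
    out: dict[tuple[str, float, int], np.ndarray] = {}
    for ci, cond in enumerate(conds):
        for li, level in enumerate(noise.levels):
            for rep in range(noise.reps):
                ss = np.random.SeedSequence(noise.seed, spawn_key=(ci, li, rep))
                out[(cond.name, float(level), rep)] = make_condition_dataset(
                    embedding, cond, float(level), ss
                )
    return out


def make_synthetic_ephys(
    embedding: SemanticEmbedding,
    n_electrodes: int = 20,
    n_timepoints: int = 100,
    n_signal_columns: int = 40,
    group_size: int = 2,
    signal_window: tuple[float, float] = (150.0, 700.0),
    snr: float = 4.0,
    seed: int = 0,
    epoch_ms: float = 1000.0,
) -> SyntheticEphys:
    """Plant a row-sparse, redundant, spanning linear code in voltage noise.

    The clean signal is ``coords_z @ G`` where G has ``n_signal_columns``
    nonzero columns, all inside ``signal_window``, arranged in
    ``group_size``-sized groups of near-duplicate columns (pairwise clean
    correlation >= 0.9) with dense (all-components-nonzero) entries.
    Gaussian noise is scaled so that sd(clean signal on planted columns) /
    sd(noise) = ``snr``.
    """
    m = n_electrodes * n_timepoints
    if n_signal_columns > m:
        raise RSLError("n_signal_columns exceeds the number of columns")
    if group_size < 1:
        raise RSLError("group_size must be >= 1")
    if n_signal_columns > 0 and not np.isfinite(snr):
        pass  # infinite snr means noiseless: allowed
    if n_signal_columns == 0 and np.isfinite(snr):
        raise RSLError("cannot satisfy a finite snr with zero signal columns")
    rng = np.random.default_rng(seed)
    n = embedding.n_items
    r = embedding.coords.shape[1]
    Z = _zscore_cols(embedding.coords)

    dt = epoch_ms / n_timepoints
    times = np.arange(n_timepoints) * dt
    in_window = (times >= signal_window[0]) & (times < signal_window[1])
    eligible = np.flatnonzero(np.tile(in_window, n_electrodes))
    if n_signal_columns > eligible.size:
        raise RSLError("signal_window too narrow for the requested signal columns")
    support = np.sort(rng.choice(eligible, size=n_signal_columns, replace=False))

    G = np.zeros((r, m))
    groups: list[list[int]] = []
    idx = 0
    while idx < n_signal_columns:
        members = support[idx : idx + group_size].tolist()
        # dense base direction: resample small entries so every component
        # contributes (the non-axis-aligned "spanning" assumption)
        base = rng.standard_normal(r)
        while np.abs(base).min() < 0.3:
            base = rng.standard_normal(r)
        for col in members:
            jitter = 0.05 * np.linalg.norm(base) * rng.standard_normal(r)
            G[:, col] = base + jitter
        groups.append(members)
        idx += group_size

    clean = Z @ G
    if n_signal_columns > 0:
        sig_sd = clean[:, support].std()
        if sig_sd == 0:
            raise RSLError("planted signal has zero variance; snr is infeasible")
    else:
        sig_sd = 0.0
    noise_sd = 0.0 if not np.isfinite(snr) else sig_sd / snr if snr > 0 else 1.0
    X = clean + rng.standard_normal((n, m)) * noise_sd

    column_map = [(e, int(round(t))) for e in range(n_electrodes) for t in times]
    return SyntheticEphys(
        X=X,
        column_map=column_map,
        ground_truth_mixing=G,
        signal_window=signal_window,
        group_structure=groups,
        seed=seed,
        item_ids=list(embedding.item_ids),
        domains=list(embedding.domains) if embedding.domains is not None else None,
    )
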