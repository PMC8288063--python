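"""Incremental PCA over quadrant-restricted layer activations.

Layer activations are large and unequal in size across layers; projecting
every layer's quadrant-restricted activation onto the same number of
principal components (default 1024 — the flattened dimensionality of the
bottleneck, the smallest analyzed layer) makes the downstream RDM regression
comparable across layers and keeps it from overfitting.  The transform is
learned single-pass from a stream of training-set activations (images
disjoint from the 24 test stimuli) with scikit-learn's IncrementalPCA, then
applied to test activations.

One transform is fit per (layer, quadrant).  When a layer-quadrant's
flattened dimensionality (or the fit-stream size) is below the requested
component count, the transform keeps the full available rank and records the
effective count explicitly.  Component signs are fixed so each component's
largest-magnitude loading is positive, making results platform-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReductionConfig",
    "FittedTransform",
    "FeatureMatrix",
    "fit_incremental_transform",
    "transform",
    "component_sweep",
    "DEFAULT_SWEEP_GRID",
]

DEFAULT_SWEEP_GRID = tuple(2 ** n for n in range(3, 11))  # 8 .. 1024


@dataclass(frozen=True)
class ReductionConfig:
    n_components: int = 1024
    sweep_grid: tuple[int, ...] = DEFAULT_SWEEP_GRID
    n_fit_images: int = 2000   # desk-scale stand-in for the 10,000-image stream
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if list(self.sweep_grid) != sorted(set(self.sweep_grid)):
            raise ValueError("sweep grid must be strictly increasing")


@dataclass
class FittedTransform:
    """A fitted (layer, quadrant) PCA projection."""

    layer: str
    quadrant: str
    mean: np.ndarray              # fit-stream mean, used for centring
    components: np.ndarray        # (n_components_eff, d), orthonormal rows
    explained_variance: np.ndarray
    n_requested: int
    fit_ids: frozenset = frozenset()

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def capped(self) -> bool:
        return self.n_components < self.n_requested


@dataclass
class FeatureMatrix:
    """images x components for one (layer, quadrant), row-aligned to ids."""

    layer: str
    quadrant: str
    ids: list
    values: np.ndarray


def _quiet_partial_fit(ipca, chunk: np.ndarray) -> None:
    # sklearn's variance-ratio bookkeeping divides by zero on constant
    # columns; harmless here (we never use the ratio)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            ipca.partial_fit(chunk)


def _fix_signs(components: np.ndarray) -> np.ndarray:
    flips = np.sign(components[np.arange(len(components)),
                               np.argmax(np.abs(components), axis=1)])
    flips[flips == 0] = 1.0
    return components * flips[:, None]


def fit_incremental_transform(batches: Iterable[np.ndarray], layer: str = "",
                              quadrant: str = "", n_components: int = 1024,
                              fit_ids: Iterable | None = None) -> FittedTransform:
    """Single-pass incremental PCA over a stream of flattened activations.

    ``batches`` yields (batch, d) arrays in a fixed order (determinism comes
    from the stream order; there is no internal randomness).  The component
    count is capped at min(d, total samples) with the cap recorded, never
    silent; requesting more components than ``d`` when the caller declared
    the dimensionality via a first batch raises only if nothing can be
    fitted.
    """
    from sklearn.decomposition import IncrementalPCA

    batches = iter(batches)
    try:
        first = np.asarray(next(batches), dtype=float)
    except StopIteration:
        raise ValueError("empty activation stream") from None
    d = first.shape[1]
    n_eff = min(n_components, d)
    if n_eff < 1:
        raise ValueError("cannot fit a transform with zero components")
    # partial_fit needs >= n_components samples per batch: buffer until that
    # holds, then stream; a trailing remainder smaller than the component
    # count is dropped once at least one batch has been fitted
    ipca = None
    pending: list[np.ndarray] = [first]
    n_pending = len(first)
    for b in batches:
        b = np.asarray(b, dtype=float)
        if b.shape[1] != d:
            raise ValueError(f"inconsistent stream dimensionality: {b.shape[1]} != {d}")
        pending.append(b)
        n_pending += len(b)
        if n_pending >= n_eff:
            if ipca is None:
                ipca = IncrementalPCA(n_components=n_eff)
            _quiet_partial_fit(ipca, np.concatenate(pending, axis=0))
            pending, n_pending = [], 0
    if pending and (ipca is None or n_pending >= n_eff):
        if ipca is None:
            n_eff = min(n_eff, n_pending)  # stream shorter than the request
            ipca = IncrementalPCA(n_components=n_eff)
        _quiet_partial_fit(ipca, np.concatenate(pending, axis=0))
    comps = _fix_signs(ipca.components_)
    return FittedTransform(layer, quadrant, ipca.mean_.copy(), comps,
                           ipca.explained_variance_.copy(), n_components,
                           frozenset(fit_ids or ()))


def transform(features: np.ndarray, fitted: FittedTransform,
              ids: Sequence | None = None) -> FeatureMatrix:
    """Project test activations with a fitted transform (fit-stream centring)."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != fitted.mean.shape[0]:
        raise ValueError(
            f"dimensionality mismatch: got {features.shape}, transform expects "
            f"(*, {fitted.mean.shape[0]})")
    if ids is not None and fitted.fit_ids:
        overlap = set(ids) & set(fitted.fit_ids)
        if overlap:
            raise ValueError(f"test stimuli appear in the fit stream: {sorted(overlap)[:5]}")
    vals = (features - fitted.mean) @ fitted.components.T
    return FeatureMatrix(fitted.layer, fitted.quadrant,
                         list(ids) if ids is not None else list(range(len(features))),
                         vals)


def component_sweep(run_similarity: Callable[[int], pd.DataFrame],
                    grid: Sequence[int] = DEFAULT_SWEEP_GRID) -> pd.DataFrame:
    """Mean/sd of data-model similarity per component count.

    ``run_similarity(n_components)`` must return a long table with columns
    (subject, roi, quadrant, layer, tau); the sweep aggregates mean and sd
    across layers and subjects per quadrant, mirroring the
    components-vs-similarity summary figure.
    """
    rows = []
    for n in grid:
        tab = run_similarity(int(n))
        for (roi, quadrant), sub in tab.groupby(["roi", "quadrant"]):
            rows.append((int(n), roi, quadrant,
                         float(sub["tau"].mean()),
                         float(sub["tau"].std(ddof=0)),
                         int(len(sub))))
    return pd.DataFrame(rows, columns=["n_components", "roi", "quadrant",
                                       "tau_mean", "tau_sd", "n_values"])
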