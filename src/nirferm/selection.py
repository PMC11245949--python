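"""Wavelength-selection methods for PLSR models.

Three selectors are provided:

* ``select_by_beta`` — keep a fixed count of wavelengths with the largest
  absolute regression coefficients;
* ``select_by_vip`` — keep wavelengths whose VIP score strictly exceeds a
  threshold (1 by default, the usual "informative variable" cut);
* ``cafs_select`` — covering-array feature selection: partition the spectrum
  into contiguous bands, use the rows of a strength-t covering array over
  {exclude, include} as screening masks, score each band by how much its
  inclusion lowers cross-validated RMSE, and refine the retained bands down
  to individual wavelengths by |beta| ranking.

All three are deterministic given data, parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .covering_array import build_covering_array
from .plsr import PLSRModel, VIPResult, compute_vip, fit_plsr

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    """Raised on invalid selector parameters."""


class EmptySelectionError(SelectionError):
    """Raised when a threshold rule selects no wavelength at all."""


class NoInformativeBandError(SelectionError):
    """Raised when no band improves cross-validated RMSE."""


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run.

    ``indices`` are sorted positions into the wavelength axis; ``scores`` is
    the full per-wavelength score vector the selection was ranked on (so the
    non-selected wavelengths can be inspected too).
    """

    method: str
    indices: np.ndarray
    scores: np.ndarray
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        p = self.scores.size
        if self.indices.size == 0:
            raise EmptySelectionError(f"{self.method}: empty selection")
        if np.unique(self.indices).size != self.indices.size:
            raise SelectionError("selected indices must be unique")
        if self.indices.min() < 0 or self.indices.max() >= p:
            raise SelectionError("selected index out of range")
        if not np.all(np.isfinite(self.scores[self.indices])):
            raise SelectionError("selected wavelength has a non-finite score")
        self.indices = np.sort(self.indices)

    @property
    def n_selected(self) -> int:
        return self.indices.size


def _top_by_magnitude(scores: np.ndarray, n_keep: int) -> np.ndarray:
    """Indices of the n_keep largest scores; ties break to the lower index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    return np.sort(order[:n_keep])


def select_by_beta(model: PLSRModel, n_keep: int = 15) -> SelectionResult:
    """Keep the ``n_keep`` wavelengths with the largest |beta|."""
    p = model.n_wavelengths
    if not 1 <= n_keep <= p:
        raise SelectionError(f"n_keep must lie in [1, {p}], got {n_keep}")
    scores = np.abs(model.coef)
    return SelectionResult(
        method="beta",
        indices=_top_by_magnitude(scores, n_keep),
        scores=scores,
        params={"n_keep": n_keep},
    )


def select_by_vip(vip: VIPResult, threshold: float = 1.0) -> SelectionResult:
    """Keep wavelengths whose VIP strictly exceeds the threshold."""
    if threshold <= 0:
        raise SelectionError("threshold must be positive")
    indices = np.flatnonzero(vip.vip > threshold)
    if indices.size == 0:
        raise EmptySelectionError(
            f"no VIP score exceeds the threshold {threshold}"
        )
    return SelectionResult(
        method="vip",
        indices=indices,
        scores=vip.vip.copy(),
        params={"threshold": threshold},
    )


def partition_bands(p: int, band_count: int) -> list[np.ndarray]:
    """Split wavelength indices 0..p-1 into contiguous, near-equal bands."""
    if not 1 <= band_count <= p:
        raise SelectionError(f"band_count must lie in [1, {p}]")
    return [np.asarray(b) for b in np.array_split(np.arange(p), band_count)]


def _cv_rmse(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_splits: int,
    seed: int,
) -> float:
    """Mean held-out RMSE of a PLSR fit over a seeded K-fold split."""
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    rmses = []
    for train, test in kf.split(X):
        a = min(n_components, X.shape[1], train.size - 1)
        model = fit_plsr(X[train], y[train], a)
        resid = model.predict(X[test]) - y[test]
        rmses.append(float(np.sqrt(np.mean(resid**2))))
    return float(np.mean(rmses))


def cafs_band_scores(
    X: np.ndarray,
    y: np.ndarray,
    *,
    strength: int = 2,
    band_count: int = 50,
    n_components: int = 8,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Covering-array screening scores for contiguous wavelength bands.

    Builds CA(N; t, band_count, 2), treats symbol 1 as "band included",
    fits a cross-validated PLSR per row, and scores each band as

        score_b = mean RMSE over rows excluding b - mean RMSE over rows
                  including b

    so positive scores mark bands whose inclusion helps prediction.
    Returns (band scores, band index lists, per-row RMSE).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    bands = partition_bands(p, band_count)
    if strength > band_count:
        raise SelectionError("covering-array strength exceeds the band count")
    ca = build_covering_array(strength, band_count, 2, seed=seed)

    row_rmse = np.full(ca.n_rows, np.nan)
    for r, row in enumerate(ca.matrix):
        cols = np.concatenate([bands[b] for b in np.flatnonzero(row)]) if row.any() else None
        if cols is None:
            logger.info("covering-array row %d includes no band; skipped", r)
            continue
        row_rmse[r] = _cv_rmse(X[:, cols], y, n_components, cv_folds, seed + 1)

    valid = np.isfinite(row_rmse)
    scores = np.empty(band_count)
    for b in range(band_count):
        included = valid & (ca.matrix[:, b] == 1)
        excluded = valid & (ca.matrix[:, b] == 0)
        if not included.any() or not excluded.any():  # pragma: no cover
            raise SelectionError(f"band {b} lacks include/exclude contrast")
        scores[b] = row_rmse[excluded].mean() - row_rmse[included].mean()
    return scores, bands, row_rmse


def cafs_select(
    X: np.ndarray,
    y: np.ndarray,
    *,
    strength: int = 2,
    band_count: int = 50,
    n_final: int = 30,
    n_components: int = 8,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Covering-array feature selection over contiguous wavelength bands.

    Bands with a positive screening score are retained; a PLSR refit on the
    retained wavelengths then ranks them by |beta| and the top ``n_final``
    are returned.  Deterministic under a fixed seed.
    """
    band_scores, bands, row_rmse = cafs_band_scores(
        X,
        y,
        strength=strength,
        band_count=band_count,
        n_components=n_components,
        cv_folds=cv_folds,
        seed=seed,
    )
    retained = np.flatnonzero(band_scores > 0)
    if retained.size == 0:
        raise NoInformativeBandError("no band improves cross-validated RMSE")

    cols = np.concatenate([bands[b] for b in retained])
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    a = min(n_components, cols.size, X.shape[0] - 1)
    refit = fit_plsr(X[:, cols], y, a)
    n_keep = min(n_final, cols.size)
    local = _top_by_magnitude(np.abs(refit.coef), n_keep)
    indices = np.sort(cols[local])

    # per-wavelength score: the screening score of the owning band
    p = X.shape[1]
    scores = np.empty(p)
    for b, band in enumerate(bands):
        scores[band] = band_scores[b]
    return SelectionResult(
        method="cafs",
        indices=indices,
        scores=scores,
        params={
            "strength": strength,
            "band_count": band_count,
            "n_final": n_final,
            "n_components": n_components,
            "cv_folds": cv_folds,
            "n_rows": int(np.isfinite(row_rmse).sum()),
            "retained_bands": retained.tolist(),
        },
        seed=seed,
    )


def vip_from_model(model: PLSRModel, threshold: float = 1.0) -> SelectionResult:
    """Convenience wrapper: compute VIP from a model and threshold it."""
    return select_by_vip(compute_vip(model, threshold), threshold)
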