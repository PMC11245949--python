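"""Single-response partial least squares regression via NIPALS.

PLSR projects the spectra X and the response y onto a small number of latent
components chosen to maximise covariance between the two blocks, then
regresses y in the latent space; the composite is the familiar linear model
y-hat = X beta + b0.  For a single response the NIPALS weight step is
non-iterative (w_a is the normalised covariance X'y of the deflated blocks),
so the decomposition is fully deterministic.

The model records, per component, the response sum of squares it explains
(SS_a), which is what the variable-importance-in-projection (VIP) score
aggregates:

    v_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a )

so that sum_j v_j^2 = p for every fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PLSRError(ValueError):
    """Raised on invalid fitting inputs or rank problems."""


@dataclass
class PLSRModel:
    """A fitted single-response PLSR model.

    Attributes
    ----------
    n_components
        Number of latent components A.
    x_weights
        (p, A) weight matrix; columns have unit norm.
    x_scores
        (n, A) training scores; columns are mutually orthogonal.
    x_loadings
        (p, A) loadings P.
    y_loadings
        (A,) inner regression coefficients q.
    coef
        (p,) regression coefficients on the original predictor scale.
    intercept
        Scalar offset so that y-hat = X coef + intercept.
    x_mean, y_mean, x_scale
        Centering / scaling applied internally during fitting.
    ss
        (A,) response sum of squares explained per component.
    """

    n_components: int
    x_weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray
    ss: np.ndarray

    @property
    def n_wavelengths(self) -> int:
        return self.coef.size

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the response for new spectra (columns must match training)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_wavelengths:
            raise PLSRError(
                f"X has {X.shape[1]} wavelengths, model expects {self.n_wavelengths}"
            )
        return X @ self.coef + self.intercept


@dataclass
class VIPResult:
    """Per-variable VIP scores; the squared scores sum to p by construction."""

    vip: np.ndarray
    threshold: float = 1.0


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    scale: bool = False,
    allow_truncation: bool = False,
) -> PLSRModel:
    """Fit a PLS1 model with the NIPALS decomposition.

    X and y are mean-centered internally; set ``scale=True`` to additionally
    divide each column by its standard deviation (off by default because
    absorbance spectra share units and autoscaling inflates noise bands).

    When the residual X block runs out of covariance with y before
    ``n_components`` are extracted the fit fails, unless
    ``allow_truncation=True`` in which case the model keeps the components
    found so far (useful inside cross-validation on near-noise-free data).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise PLSRError("X and y have inconsistent sample counts")
    if n < 2:
        raise PLSRError("at least two samples are required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise PLSRError("non-finite values in X or y")
    if n_components < 1:
        raise PLSRError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise PLSRError(
            f"n_components={n_components} exceeds the rank bound "
            f"min(n-1, p) = {min(n - 1, p)}"
        )
    if np.ptp(y) == 0:
        raise PLSRError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
    else:
        x_scale = np.ones(p)
    Xa = (X - x_mean) / x_scale
    ya = y - y_mean

    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    ss = np.empty(n_components)

    n_found = n_components
    for a in range(n_components):
        w = Xa.T @ ya
        norm_w = np.linalg.norm(w)
        if norm_w <= np.finfo(float).eps * max(n, p):
            if allow_truncation and a > 0:
                n_found = a
                break
            raise PLSRError(
                f"component {a + 1}: residual X carries no covariance with y "
                "(rank exhausted); reduce n_components"
            )
        w /= norm_w
        t = Xa @ w
        tt = float(t @ t)
        if tt <= np.finfo(float).tiny:
            if allow_truncation and a > 0:
                n_found = a
                break
            raise PLSRError(f"component {a + 1}: degenerate score vector")
        p_a = Xa.T @ t / tt
        q_a = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_a)
        ya = ya - q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
        ss[a] = q_a ** 2 * tt

    if n_found < n_components:
        W, T, P, q, ss = (
            W[:, :n_found], T[:, :n_found], P[:, :n_found], q[:n_found], ss[:n_found]
        )

    # beta on the centered/scaled scale, then mapped back to original units
    beta = W @ np.linalg.solve(P.T @ W, q)
    coef = beta / x_scale
    intercept = y_mean - float(x_mean @ coef)

    return PLSRModel(
        n_components=n_found,
        x_weights=W,
        x_scores=T,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        ss=ss,
    )


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`PLSRModel.predict`."""
    return model.predict(X)


def compute_vip(model: PLSRModel, threshold: float = 1.0) -> VIPResult:
    """Variable importance in projection from a fitted model."""
    total = float(model.ss.sum())
    if total <= 0:
        raise PLSRError("total explained sum of squares is zero")
    p = model.n_wavelengths
    # weights are unit-norm by construction; normalise anyway for safety
    w2 = (model.x_weights / np.linalg.norm(model.x_weights, axis=0)) ** 2
    vip = np.sqrt(p * (w2 @ model.ss) / total)
    return VIPResult(vip=vip, threshold=threshold)


def save_model(model: PLSRModel, path) -> None:
    """Serialize a fitted model to a plain-text key-value document."""
    def fmt(a: np.ndarray) -> str:
        return ",".join(format(x, ".17g") for x in np.asarray(a).ravel())

    with open(path, "w") as fh:
        fh.write("format: nirferm-plsr-1\n")
        fh.write(f"n_components: {model.n_components}\n")
        fh.write(f"n_wavelengths: {model.n_wavelengths}\n")
        fh.write(f"intercept: {model.intercept:.17g}\n")
        fh.write(f"y_mean: {model.y_mean:.17g}\n")
        for name in ("coef", "x_mean", "x_scale", "y_loadings", "ss"):
            fh.write(f"{name}: {fmt(getattr(model, name))}\n")
        for name in ("x_weights", "x_loadings"):
            arr = getattr(model, name)
            for a in range(arr.shape[1]):
                fh.write(f"{name}[{a}]: {fmt(arr[:, a])}\n")


def load_model(path) -> PLSRModel:
    """Load a model written by :func:`save_model` (scores are not stored)."""
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.partition(":")
            fields[key.strip()] = value.strip()
    if fields.get("format") != "nirferm-plsr-1":
        raise PLSRError("not a nirferm PLSR model file")

    def arr(key: str) -> np.ndarray:
        return np.array([float(x) for x in fields[key].split(",")])

    A = int(fields["n_components"])
    p = int(fields["n_wavelengths"])
    W = np.column_stack([arr(f"x_weights[{a}]") for a in range(A)])
    P = np.column_stack([arr(f"x_loadings[{a}]") for a in range(A)])
    return PLSRModel(
        n_components=A,
        x_weights=W,
        x_scores=np.zeros((0, A)),
        x_loadings=P,
        y_loadings=arr("y_loadings"),
        coef=arr("coef"),
        intercept=float(fields["intercept"]),
        x_mean=arr("x_mean"),
        y_mean=float(fields["y_mean"]),
        x_scale=arr("x_scale"),
        ss=arr("ss"),
    )


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_components: int = 15,
    n_splits: int = 5,
    seed: int = 0,
) -> int:
    """Pick the component count minimising K-fold cross-validated RMSE.

    Intended for use inside a training fold so the choice never sees held-out
    data.  Ties go to the smaller component count.
    """
    from sklearn.model_selection import KFold

    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    n_splits = min(n_splits, n)
    a_max = min(max_components, p, n - 1 - (n // n_splits))
    a_max = max(a_max, 1)
    grid = range(1, a_max + 1)
    press = np.zeros(a_max)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed % 2**31)
    for train, test in kf.split(X):
        for a in grid:
            try:
                model = fit_plsr(X[train], y[train], a)
            except PLSRError:
                press[a - 1 :] += np.inf
                break
            resid = model.predict(X[test]) - y[test]
            press[a - 1] += float(resid @ resid)
    return int(np.argmin(press)) + 1
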