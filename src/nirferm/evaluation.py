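"""Cross-validated model assessment and distributional checks.

Metrics follow standard chemometric practice: held-out R-squared, root mean
square error, and the ratio of performance to deviation RPD = SD / RMSE,
where SD is the (population) standard deviation of the reference values of
the evaluated dataset.  Models are assessed with a repeated K-fold protocol
(K = 5, 30 repetitions by default); every metric is computed on held-out
folds only, and the aggregate is the mean over all repetition x fold cells.

The one-sample Kolmogorov-Smirnov statistic against a fitted normal
distribution is included for checking (non-)normality of reference values:

    D+ = max_i ( i/n - Z_i ),   D- = max_i ( Z_i - (i-1)/n ),
    D  = max(D+, D-),           Z_i = F(X_(i))

with F the normal CDF at the sample mean and (population) SD unless fixed
parameters are supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import KFold

from .plsr import PLSRModel, fit_plsr, select_n_components


class EvaluationError(ValueError):
    """Raised on invalid metric or protocol inputs."""


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricSet:
    """R-squared, RMSE and RPD for one prediction vector."""

    r2: float
    rmse: float
    rpd: float
    n: int
    sd: float
    rpd_defined: bool = True


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    sd_reference: float | None = None,
    *,
    r2_denominator: str = "observed",
) -> MetricSet:
    """Compute R-squared, RMSE and RPD = SD / RMSE.

    ``sd_reference`` fixes the SD used for RPD (e.g. the SD of the full
    response vector when evaluating per-fold); by default the population SD
    of ``y_true`` is used.  A perfect prediction (RMSE = 0) yields an
    infinite RPD flagged via ``rpd_defined=False``.

    ``r2_denominator`` selects the R-squared normalisation: ``"observed"``
    (the standard sum of squares of y about its mean) or ``"predicted"``
    (sum of squares of y-hat about the observed mean), the latter retained
    only for audit because it is not bounded by 1.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise EvaluationError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise EvaluationError("at least two observations are required")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise EvaluationError("non-finite values in inputs")
    n = y_true.size
    resid = y_pred - y_true
    rss = float(resid @ resid)
    rmse = math.sqrt(rss / n)
    y_mean = float(y_true.mean())
    if r2_denominator == "observed":
        tss = float(np.sum((y_true - y_mean) ** 2))
    elif r2_denominator == "predicted":
        tss = float(np.sum((y_pred - y_mean) ** 2))
    else:
        raise EvaluationError("r2_denominator must be 'observed' or 'predicted'")
    if tss == 0:
        raise EvaluationError("zero-variance denominator in R-squared")
    r2 = 1.0 - rss / tss
    sd = float(np.std(y_true)) if sd_reference is None else float(sd_reference)
    if rmse > 0:
        return MetricSet(r2=r2, rmse=rmse, rpd=sd / rmse, n=n, sd=sd)
    return MetricSet(r2=r2, rmse=0.0, rpd=math.inf, n=n, sd=sd, rpd_defined=False)


# ---------------------------------------------------------------------------
# repeated K-fold protocol
# ---------------------------------------------------------------------------

#: A model recipe: (X_train, y_train, seed) -> fitted object with .predict(X).
ModelRecipe = Callable[[np.ndarray, np.ndarray, int], PLSRModel]


def plsr_recipe(
    n_components: int | None = None,
    *,
    max_components: int = 15,
    indices: np.ndarray | None = None,
) -> ModelRecipe:
    """Recipe fitting PLSR on (optionally pre-selected) wavelengths.

    With ``n_components=None`` the component count is chosen per training
    fold by an inner cross-validation, so held-out folds never inform it.
    """
    idx = None if indices is None else np.asarray(indices, dtype=np.int64)

    def fit(X: np.ndarray, y: np.ndarray, seed: int) -> PLSRModel:
        Xs = X if idx is None else X[:, idx]
        if n_components is None:
            a = select_n_components(Xs, y, max_components=max_components, seed=seed)
        else:
            a = min(n_components, Xs.shape[1], Xs.shape[0] - 1)
        model = fit_plsr(Xs, y, a, allow_truncation=True)
        if idx is None:
            return model
        return _SubsetPredictor(model, idx)

    return fit


class _SubsetPredictor:
    """Wraps a PLSR model fitted on a wavelength subset of the full axis."""

    def __init__(self, model: PLSRModel, indices: np.ndarray):
        self.model = model
        self.indices = indices

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.atleast_2d(X)[:, self.indices])


@dataclass
class CVReport:
    """Per-repetition, per-fold held-out metrics with aggregation."""

    frame: pd.DataFrame
    k: int
    reps: int
    base_seed: int
    sd_reference: float
    rep_seeds: list[int] = field(default_factory=list)

    def aggregate(self) -> dict[str, float]:
        """Mean and SD over all repetition x fold cells."""
        out = {}
        for name in ("r2", "rmse", "rpd"):
            col = self.frame[name].replace([np.inf], np.nan)
            out[f"{name}_mean"] = float(col.mean())
            out[f"{name}_sd"] = float(col.std(ddof=1)) if len(col) > 1 else 0.0
        return out

    @property
    def r2_mean(self) -> float:
        return self.aggregate()["r2_mean"]

    @property
    def rmse_mean(self) -> float:
        return self.aggregate()["rmse_mean"]

    @property
    def rpd_mean(self) -> float:
        return self.aggregate()["rpd_mean"]

    def to_csv(self, path) -> None:
        """Write the per-cell frame with the protocol parameters attached."""
        frame = self.frame.copy()
        frame["k"] = self.k
        frame["reps"] = self.reps
        frame["base_seed"] = self.base_seed
        frame["sd_reference"] = self.sd_reference
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CVReport":
        frame = pd.read_csv(path)
        k = int(frame["k"].iloc[0])
        reps = int(frame["reps"].iloc[0])
        base_seed = int(frame["base_seed"].iloc[0])
        sd = float(frame["sd_reference"].iloc[0])
        cells = frame[["rep", "fold", "r2", "rmse", "rpd", "n"]].copy()
        rep_seeds = [(base_seed + rep) % 2**31 for rep in range(reps)]
        return cls(
            frame=cells, k=k, reps=reps, base_seed=base_seed,
            sd_reference=sd, rep_seeds=rep_seeds,
        )


def run_repeated_kfold(
    X: np.ndarray,
    y: np.ndarray,
    recipe: ModelRecipe,
    *,
    k: int = 5,
    reps: int = 30,
    base_seed: int = 0,
    sd_reference: float | None = None,
) -> CVReport:
    """Repeated K-fold cross-validation of a model recipe.

    In every repetition the samples are reshuffled (seed = base_seed + rep)
    and split into K folds; each sample is held out exactly once per
    repetition.  The recipe — which must encapsulate any data-driven choices
    such as component-count selection — is refit on each training fold and
    scored on the held-out fold.  The SD entering RPD is the population SD
    of the full response vector unless overridden.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < k:
        raise EvaluationError(f"need at least k={k} samples, got {n}")
    if base_seed is None:
        raise EvaluationError("a base seed is required for reproducibility")
    sd = float(np.std(y)) if sd_reference is None else float(sd_reference)

    records = []
    rep_seeds = []
    for rep in range(reps):
        seed = (int(base_seed) + rep) % 2**31
        rep_seeds.append(seed)
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (train, test) in enumerate(kf.split(X)):
            model = recipe(X[train], y[train], seed)
            y_pred = np.asarray(model.predict(X[test]), dtype=float).ravel()
            if test.size == 1:
                # leave-one-out limit: R-squared is undefined per fold
                rmse = float(abs(y_pred[0] - y[test][0]))
                metrics = MetricSet(
                    r2=math.nan, rmse=rmse,
                    rpd=sd / rmse if rmse > 0 else math.inf,
                    n=1, sd=sd, rpd_defined=rmse > 0,
                )
            else:
                metrics = compute_metrics(y[test], y_pred, sd)
            records.append(
                {
                    "rep": rep,
                    "fold": fold,
                    "r2": metrics.r2,
                    "rmse": metrics.rmse,
                    "rpd": metrics.rpd,
                    "n": metrics.n,
                }
            )
    frame = pd.DataFrame.from_records(records)
    return CVReport(
        frame=frame, k=k, reps=reps, base_seed=int(base_seed),
        sd_reference=sd, rep_seeds=rep_seeds,
    )


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov statistic
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    """One-sample KS statistic against a (fitted) normal distribution."""

    d: float
    d_plus: float
    d_minus: float
    n: int
    mean: float
    sd: float


def ks_statistic(
    x: np.ndarray,
    mean: float | None = None,
    sd: float | None = None,
) -> KSResult:
    """KS distance between the empirical CDF of ``x`` and a normal CDF.

    By default the normal parameters are the maximum-likelihood fit (sample
    mean, population SD).  Pass ``mean``/``sd`` to test against a fixed
    distribution instead.  For n = 1 with fitted parameters the degenerate
    CDF value at the observation is taken as 1/2, giving D = 1/2.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 1 or not np.all(np.isfinite(x)):
        raise EvaluationError("need at least one finite observation")
    mu = float(x.mean()) if mean is None else float(mean)
    sigma = float(np.std(x)) if sd is None else float(sd)
    if sigma == 0:
        if n > 1:
            raise EvaluationError("zero sample SD: KS statistic undefined")
        z = np.array([0.5])
    else:
        z = norm.cdf(x, loc=mu, scale=sigma)
    i = np.arange(1, n + 1)
    d_plus = float(np.max(i / n - z))
    d_minus = float(np.max(z - (i - 1) / n))
    return KSResult(
        d=max(d_plus, d_minus), d_plus=d_plus, d_minus=d_minus,
        n=n, mean=mu, sd=sigma,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(
    full: CVReport,
    optimized: Mapping[str, CVReport],
    *,
    n_variables: Mapping[str, int] | None = None,
    full_n_variables: int | None = None,
) -> pd.DataFrame:
    """Tabulate full-spectrum vs optimized-model cross-validated metrics.

    All reports must share the same fold seeds (same base seed, K and
    repetition count) so rows are comparable; a mismatch is an error.
    """
    n_variables = dict(n_variables or {})
    rows = []

    def row(name: str, report: CVReport, nvar) -> dict:
        agg = report.aggregate()
        return {
            "model": name,
            "n_variables": nvar,
            "r2": agg["r2_mean"],
            "r2_sd": agg["r2_sd"],
            "rmse": agg["rmse_mean"],
            "rmse_sd": agg["rmse_sd"],
            "rpd": agg["rpd_mean"],
            "rpd_sd": agg["rpd_sd"],
        }

    rows.append(row("full", full, full_n_variables))
    for name, report in optimized.items():
        if report.rep_seeds != full.rep_seeds or report.k != full.k:
            raise EvaluationError(
                f"report {name!r} was built with different fold seeds"
            )
        rows.append(row(name, report, n_variables.get(name)))
    return pd.DataFrame(rows)
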