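"""Regression of the acceleration count on the reduced FHRV features.

Two models are fitted to the 8-column reduced representation:

* a single-hidden-layer feed-forward neural network (tanh hidden units,
  identity output) trained by backpropagation with early stopping on a
  held-out validation subset, the hidden size selected on a 1..10 grid;
  per-input relevance is the connection-weight contribution
  C_i = |sum_j a_ij b_j| through the hidden layer;
* an ordinary-least-squares multiple linear regression baseline with the
  standard diagnostic set (Durbin-Watson, Tolerance/VIF, P-P plot and
  residual-vs-fitted coordinates).

Performance is summarized per subset (train/validation/test/overall) by
the Pearson correlation R, the determination coefficient
R^2 = 1 - SSE/SST, and the root-mean-square error.  Targets (counts) are
left unnormalized; ANN inputs are z-scored with training-set statistics.
Response surfaces probe the fitted network over two inputs at fixed
gestational weeks {30, 37, 41} and FHR means {110, 140, 170} bpm with
the remaining inputs at their corpus medians.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.neural_network import MLPRegressor
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "SplitIndices",
    "ANNModel",
    "MetricReport",
    "MLRMResult",
    "ResponseSurfaces",
    "split_data",
    "train_ann",
    "ann_importance",
    "regression_metrics",
    "fit_mlrm",
    "response_surface",
]

SPLIT_RATIOS = (0.70, 0.15, 0.15)


@dataclasses.dataclass
class SplitIndices:
    """Random 70:15:15 partition of record indices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.train_idx.size + self.val_idx.size + self.test_idx.size


@dataclasses.dataclass
class ANNModel:
    """Weights and scaling of the selected feed-forward network."""

    input_weights: np.ndarray   # (n_inputs, hidden_size)
    hidden_biases: np.ndarray   # (hidden_size,)
    output_weights: np.ndarray  # (hidden_size,)
    output_bias: float
    hidden_size: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    feature_names: tuple[str, ...]
    transfer_names: tuple[str, str] = ("tanh", "identity")
    training_log: dict = dataclasses.field(default_factory=dict)

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            x = x.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        xs = (np.asarray(x, dtype=float) - self.x_mean) / self.x_scale
        hidden = np.tanh(xs @ self.input_weights + self.hidden_biases)
        return hidden @ self.output_weights + self.output_bias


@dataclasses.dataclass
class MetricReport:
    """R, R^2 and RMSE per subset plus observed/predicted values."""

    per_subset: dict[str, dict[str, float]]
    y_obs: np.ndarray
    y_pred: np.ndarray

    @property
    def y_mean(self) -> float:
        return float(np.mean(self.y_obs))


@dataclasses.dataclass
class MLRMResult:
    coefficients: pd.Series
    standardized_coefficients: pd.Series
    p_values: pd.Series
    confidence_intervals: pd.DataFrame
    residuals: np.ndarray
    fitted: np.ndarray
    r: float
    r2: float
    r2_adjusted: float
    model_error: float
    durbin_watson: float
    tolerance: pd.Series
    vif: pd.Series
    pp_plot: np.ndarray          # (n, 2): theoretical vs observed probability
    residual_vs_fitted: np.ndarray  # (n, 2): standardized predicted vs residual


@dataclasses.dataclass
class ResponseSurfaces:
    vary: tuple[str, str]
    grid_x: np.ndarray
    grid_y: np.ndarray
    surfaces: dict[tuple[int, float], np.ndarray]  # (week, fhr_mean) -> grid
    fixed_values: dict[str, float]


def split_data(n_records: int, seed: int, ratios: tuple[float, float, float] = SPLIT_RATIOS) -> SplitIndices:
    """Random disjoint train/validation/test partition with sizes given by
    largest-remainder rounding of the 70:15:15 ratios."""
    if n_records < 10:
        raise ValueError("need at least 10 records to split")
    shares = np.array(ratios, dtype=float) * n_records
    sizes = np.floor(shares).astype(int)
    for i in np.argsort(-(shares - sizes))[: n_records - sizes.sum()]:
        sizes[i] += 1
    perm = np.random.default_rng(seed).permutation(n_records)
    edges = np.cumsum(sizes)
    return SplitIndices(
        train_idx=np.sort(perm[: edges[0]]),
        val_idx=np.sort(perm[edges[0] : edges[1]]),
        test_idx=np.sort(perm[edges[1] :]),
        seed=seed,
    )


def regression_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(R, R^2, RMSE): Pearson correlation, determination coefficient
    1 - SSE/SST with SST about the mean of the observations, and the
    root-mean-square error.  R^2 is NaN when the observations have zero
    variance."""
    y = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if y.size == 0 or y.size != yp.size:
        raise ValueError("y_obs and y_pred must have equal nonzero length")
    rmse = float(np.sqrt(np.mean((y - yp) ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn("zero variance in observations; R^2 undefined", stacklevel=2)
        return float("nan"), float("nan"), rmse
    r2 = 1.0 - float(np.sum((y - yp) ** 2)) / sst
    r = float(np.corrcoef(y, yp)[0, 1]) if np.std(yp) > 0 else float("nan")
    return r, r2, rmse


def _metric_report(model: ANNModel, x: np.ndarray, y: np.ndarray, split: SplitIndices) -> MetricReport:
    y_pred = model.predict(x)
    subsets = {
        "train": split.train_idx,
        "val": split.val_idx,
        "test": split.test_idx,
        "overall": np.arange(y.size),
    }
    per_subset = {}
    for name, idx in subsets.items():
        r, r2, rmse = regression_metrics(y[idx], y_pred[idx])
        per_subset[name] = {"R": r, "R2": r2, "RMSE": rmse}
    return MetricReport(per_subset=per_subset, y_obs=np.asarray(y, float), y_pred=y_pred)


def train_ann(
    reduced: pd.DataFrame,
    y: np.ndarray,
    split: SplitIndices,
    hidden_grid: tuple[int, ...] = tuple(range(1, 11)),
    n_restarts: int = 5,
    max_epochs: int = 1000,
    patience: int = 50,
    learning_rate: float = 0.01,
    seed: int = 0,
) -> tuple[ANNModel, MetricReport]:
    """Train single-hidden-layer networks over a hidden-size grid and keep
    the one with the best validation R^2.

    Each candidate is trained with adam backpropagation (full passes via
    partial_fit) and early stopping on the validation RMSE with the given
    patience; the best validation checkpoint is kept.  Inputs are z-scored
    with training-set statistics (stored in the model); targets stay raw.
    """
    if any(not 1 <= h <= 10 for h in hidden_grid):
        raise ValueError("hidden sizes must lie in [1, 10]")
    feature_names = tuple(reduced.columns)
    x = reduced.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("missing values in inputs or targets")
    mu = x[split.train_idx].mean(axis=0)
    sc = x[split.train_idx].std(axis=0)
    sc[sc == 0] = 1.0
    xs = (x - mu) / sc
    xtr, ytr = xs[split.train_idx], y[split.train_idx]
    xval, yval = xs[split.val_idx], y[split.val_idx]

    ss = np.random.SeedSequence((seed, 0xA11))
    rng = np.random.default_rng(ss)
    best = None  # (val_rmse, h, weights, epochs, converged)
    for h in hidden_grid:
        for _rep in range(n_restarts):
            net = MLPRegressor(
                hidden_layer_sizes=(h,),
                activation="tanh",
                solver="adam",
                learning_rate_init=learning_rate,
                alpha=1e-4,
                batch_size=min(200, xtr.shape[0]),
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            best_val, best_w, wait, epoch = np.inf, None, 0, 0
            for epoch in range(1, max_epochs + 1):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # per-step convergence chatter
                    net.partial_fit(xtr, ytr)
                val_rmse = float(np.sqrt(np.mean((yval - net.predict(xval)) ** 2)))
                if val_rmse < best_val - 1e-12:
                    best_val = val_rmse
                    best_w = (
                        [w.copy() for w in net.coefs_],
                        [b.copy() for b in net.intercepts_],
                    )
                    wait = 0
                else:
                    wait += 1
                    if wait > patience:
                        break
            converged = epoch < max_epochs
            if best is None or best_val < best[0]:
                best = (best_val, h, best_w, epoch, converged)
    val_rmse, h, (coefs, intercepts), epochs, converged = best
    if not converged:
        warnings.warn(
            f"selected network (hidden size {h}) reached max_epochs={max_epochs} "
            "without early stopping; best checkpoint returned",
            stacklevel=2,
        )
    model = ANNModel(
        input_weights=coefs[0],
        hidden_biases=intercepts[0],
        output_weights=coefs[1].ravel(),
        output_bias=float(np.ravel(intercepts[1])[0]),
        hidden_size=h,
        x_mean=mu,
        x_scale=sc,
        feature_names=feature_names,
        training_log={"epochs": epochs, "best_val_rmse": val_rmse, "hidden_grid": list(hidden_grid)},
    )
    return model, _metric_report(model, x, y, split)


def ann_importance(model: ANNModel) -> pd.DataFrame:
    """Connection-weight contribution of each input: C_i = |sum_j a_ij b_j|,
    reported raw and normalized to sum 1 (zeros when all weights vanish)."""
    raw = np.abs(model.input_weights @ model.output_weights)
    total = raw.sum()
    normalized = raw / total if total > 0 else np.zeros_like(raw)
    return pd.DataFrame(
        {"contribution": raw, "normalized": normalized}, index=list(model.feature_names)
    )


def fit_mlrm(reduced: pd.DataFrame, y: np.ndarray) -> MLRMResult:
    """Ordinary least squares of the count on the 8 reduced predictors,
    with standardized coefficients, 95% CIs, and the diagnostic set
    (Durbin-Watson, Tolerance/VIF, P-P and residual-vs-fitted plots)."""
    x = reduced.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("need more records than predictors + 1")
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("missing values in inputs or targets")
    design = sm.add_constant(pd.DataFrame(x, columns=reduced.columns))
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (reduced.columns[i], reduced.columns[j])
            for i in range(p) for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {pairs}")
    fit = sm.OLS(y, design).fit()
    # Standardized coefficients from z-scored predictors and response.
    zx = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    std_fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    std_coefs = pd.Series(std_fit.params[1:], index=reduced.columns)
    resid = fit.resid
    vif = pd.Series(
        [variance_inflation_factor(design.to_numpy(), i + 1) for i in range(p)],
        index=reduced.columns,
    )
    zresid = np.sort((resid - resid.mean()) / resid.std(ddof=1))
    emp = (np.arange(1, n + 1) - 0.5) / n
    pp = np.column_stack([stats.norm.cdf(zresid), emp])
    zfit = (fit.fittedvalues - fit.fittedvalues.mean()) / fit.fittedvalues.std(ddof=1)
    return MLRMResult(
        coefficients=pd.Series(fit.params.to_numpy() if hasattr(fit.params, "to_numpy") else fit.params,
                               index=["intercept", *reduced.columns]),
        standardized_coefficients=std_coefs,
        p_values=pd.Series(np.asarray(fit.pvalues), index=["intercept", *reduced.columns]),
        confidence_intervals=pd.DataFrame(
            np.asarray(fit.conf_int(alpha=0.05)),
            index=["intercept", *reduced.columns],
            columns=["lower", "upper"],
        ),
        residuals=np.asarray(resid),
        fitted=np.asarray(fit.fittedvalues),
        r=float(np.corrcoef(y, fit.fittedvalues)[0, 1]),
        r2=float(fit.rsquared),
        r2_adjusted=float(fit.rsquared_adj),
        model_error=float(np.sqrt(fit.mse_resid)),
        durbin_watson=float(durbin_watson(np.asarray(resid))),
        tolerance=1.0 / vif,
        vif=vif,
        pp_plot=pp,
        residual_vs_fitted=np.column_stack([np.asarray(zfit), np.asarray((resid - resid.mean()) / resid.std(ddof=1))]),
    )


def response_surface(
    model: ANNModel,
    reduced: pd.DataFrame,
    vary: tuple[str, str] = ("NL_variability", "NL_complexity"),
    weeks: tuple[int, ...] = (30, 37, 41),
    fhr_means: tuple[float, ...] = (110.0, 140.0, 170.0),
    grid_size: int = 25,
) -> ResponseSurfaces:
    """Predicted acceleration count over a grid of two inputs.

    The two varied inputs span their observed ranges; all other inputs are
    held at their corpus medians except the gestational week and FHR mean,
    which take each (week, fhr_mean) combination in turn, giving 9
    surfaces.  Surfaces are deterministic given the model and grid.
    """
    for name in vary:
        if name not in reduced.columns:
            raise ValueError(f"unknown input name '{name}'")
    medians = reduced.median(axis=0)
    g1 = np.linspace(reduced[vary[0]].min(), reduced[vary[0]].max(), grid_size)
    g2 = np.linspace(reduced[vary[1]].min(), reduced[vary[1]].max(), grid_size)
    xx, yy = np.meshgrid(g1, g2, indexing="ij")
    surfaces: dict[tuple[int, float], np.ndarray] = {}
    for wk in weeks:
        for fm in fhr_means:
            base = medians.copy()
            base["week"] = wk
            base["mean_fhr"] = fm
            grid = pd.DataFrame(
                np.tile(base.loc[list(model.feature_names)].to_numpy(float), (xx.size, 1)),
                columns=model.feature_names,
            )
            grid[vary[0]] = xx.ravel()
            grid[vary[1]] = yy.ravel()
            surfaces[(wk, fm)] = model.predict(grid).reshape(xx.shape)
    return ResponseSurfaces(
        vary=vary,
        grid_x=g1,
        grid_y=g2,
        surfaces=surfaces,
        fixed_values={c: float(medians[c]) for c in reduced.columns if c not in vary},
    )
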