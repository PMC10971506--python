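"""Empirical ebullition models and their evaluation.

The suite covers three families:

* **Literature forms** — polynomial-in-binned-temperature, modified
  Arrhenius, autoregressive, pressure-threshold, multiple-regression and
  small neural-network relationships proposed for other aquatic systems.
  Each is registered with its functional form and predictor set and can be
  run with fixed coefficients or refitted to a new data set.
* **Additive model (GAM)** — the flux is a sum of univariate penalized
  spline shape functions of the drivers (P-splines: B-spline bases with a
  difference penalty, smoothing chosen by GCV).
* **Evaluation metrics** — R2 of a linear fit of observed on predicted,
  RMSE, Nash-Sutcliffe efficiency, the relative error of the accumulated
  flux over stated continuous windows (negative = overestimation), and a
  PRESS-based predicted R2 (clamped at zero) as an overfitting indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.interpolate import BSpline

TIMESCALES = ("10min", "1h", "1d", "1w", "biweekly")

FORMS = ("binned_polynomial", "arrhenius", "autoregressive",
         "pressure_threshold", "ann", "gam", "linear")


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    """Metrics for one model at one timescale."""

    r2: float
    rmse: float
    nse: float
    rel_error_pct: float | None      # None when accumulated observed flux is 0
    predicted_r2: float | None = None
    n: int = 0
    windows: tuple = ()

    def to_dict(self) -> dict:
        return {"R2": self.r2, "RMSE": self.rmse, "NSE": self.nse,
                "Rel_error_pct": self.rel_error_pct,
                "predicted_R2": self.predicted_r2, "n": self.n}


def evaluate_model(
    observed,
    predicted,
    accumulation_windows: list[tuple] | None = None,
    index: pd.DatetimeIndex | None = None,
) -> PerformanceReport:
    """Compare predicted with observed fluxes (non-transformed scale).

    * R2: coefficient of determination of an OLS fit observed ~ predicted.
    * RMSE: root-mean-square error.
    * NSE: 1 - sum((o-p)^2) / sum((o-mean(o))^2).
    * Rel_error: 100 * (sum(o) - sum(p)) / sum(o) over the concatenation of
      ``accumulation_windows`` (continuous-record periods); negative values
      flag overestimation.  Undefined (None) when the accumulated observed
      flux is zero.
    """
    from .timeseries import RegularSeries

    if isinstance(observed, RegularSeries):
        index = observed.index
        observed = observed.values
    if isinstance(predicted, RegularSeries):
        predicted = predicted.values
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must share a grid")
    ok = ~np.isnan(o) & ~np.isnan(p)
    o_v, p_v = o[ok], p[ok]
    if o_v.size < 3:
        raise ValueError("too few paired samples to evaluate")

    if np.ptp(p_v) == 0:
        r2 = 0.0  # constant prediction carries no linear information
    else:
        r2 = float(stats.linregress(p_v, o_v).rvalue ** 2)
    rmse = float(np.sqrt(np.mean((o_v - p_v) ** 2)))
    denom = np.sum((o_v - o_v.mean()) ** 2)
    nse = float(1.0 - np.sum((o_v - p_v) ** 2) / denom) if denom > 0 else np.nan

    if accumulation_windows and index is not None:
        sel = np.zeros(o.size, dtype=bool)
        for start, end in accumulation_windows:
            sel |= (index >= pd.Timestamp(start)) & (index <= pd.Timestamp(end))
        sel &= ok
    else:
        sel = ok
    total_o = float(np.sum(o[sel]))
    total_p = float(np.sum(p[sel]))
    rel = None if total_o == 0 else 100.0 * (total_o - total_p) / total_o
    return PerformanceReport(r2=r2, rmse=rmse, nse=nse, rel_error_pct=rel,
                             n=int(o_v.size),
                             windows=tuple(accumulation_windows or ()))


# ---------------------------------------------------------------------------
# Binned-response model (flux vs. binned covariate + polynomial fit)
# ---------------------------------------------------------------------------

@dataclass
class BinnedResponse:
    bin_centers: np.ndarray
    bin_means: np.ndarray
    p10: np.ndarray
    p90: np.ndarray
    counts: np.ndarray
    poly_coeffs: np.ndarray       # highest power first (numpy convention)
    poly_cov: np.ndarray

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.poly_coeffs, np.asarray(x, dtype=float))

    def confidence_band(self, x, level: float = 0.95):
        """Pointwise CI of the fitted polynomial from the coefficient cov."""
        x = np.asarray(x, dtype=float)
        deg = self.poly_coeffs.size - 1
        V = np.vander(x, deg + 1)
        var = np.einsum("ij,jk,ik->i", V, self.poly_cov, V)
        dof = max(self.bin_centers.size - self.poly_coeffs.size, 1)
        half = stats.t.ppf(0.5 + level / 2, dof) * np.sqrt(np.maximum(var, 0.0))
        mid = self.predict(x)
        return mid - half, mid + half


def binned_response_model(
    flux: np.ndarray,
    covariate: np.ndarray,
    bin_width: float = 1.0,
    degree: int = 3,
) -> BinnedResponse:
    """Bin the covariate, average the flux per bin, fit a polynomial.

    Mirrors the classic mean-flux-vs-binned-sediment-temperature model: per
    1-unit bin the mean flux plus 10th/90th percentile bars, and a
    least-squares polynomial (default cubic) through the bin means.
    """
    f = np.asarray(flux, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = ~np.isnan(f) & ~np.isnan(c)
    f, c = f[ok], c[ok]
    if f.size == 0:
        raise ValueError("no valid flux/covariate pairs")
    edges = np.arange(np.floor(c.min() / bin_width) * bin_width,
                      c.max() + bin_width, bin_width)
    idx = np.digitize(c, edges) - 1
    centers, means, p10, p90, counts = [], [], [], [], []
    for b in range(edges.size - 1):
        sel = idx == b
        if not sel.any():
            continue
        centers.append(edges[b] + bin_width / 2)
        means.append(f[sel].mean())
        p10.append(np.percentile(f[sel], 10))
        p90.append(np.percentile(f[sel], 90))
        counts.append(int(sel.sum()))
    if len(centers) < 3:
        raise ValueError("binned_response_model: need at least 3 non-empty bins")
    centers = np.asarray(centers)
    means = np.asarray(means)
    deg = min(degree, len(centers) - 1)
    if len(centers) > deg + 1:
        coeffs, cov = np.polyfit(centers, means, deg, cov=True)
    else:
        coeffs = np.polyfit(centers, means, deg)
        cov = np.zeros((deg + 1, deg + 1))
    return BinnedResponse(bin_centers=centers, bin_means=means,
                          p10=np.asarray(p10), p90=np.asarray(p90),
                          counts=np.asarray(counts),
                          poly_coeffs=coeffs, poly_cov=cov)


# ---------------------------------------------------------------------------
# Penalized additive model (P-spline GAM)
# ---------------------------------------------------------------------------

class AdditiveModel:
    """Gaussian additive model with univariate P-spline shape functions.

    Each predictor enters through a cubic B-spline basis (default 10 basis
    functions) penalized by squared second differences of its coefficients;
    a single smoothing parameter shared across terms is selected by
    generalized cross-validation (GCV) over a log grid.  Zero-variance
    predictors are dropped with a warning.  Because the model is a linear
    smoother, leave-one-out (PRESS) residuals — and hence the predicted R2
    used to flag overfitting — come directly from the hat-matrix diagonal.
    """

    def __init__(self, n_splines: int = 10, degree: int = 3,
                 lambda_grid: np.ndarray | None = None):
        self.n_splines = n_splines
        self.degree = degree
        self.lambda_grid = (np.logspace(-3, 6, 10) if lambda_grid is None
                            else np.asarray(lambda_grid, dtype=float))
        self.terms_: list[str] = []
        self.knots_: dict[str, np.ndarray] = {}
        self.centers_: dict[str, np.ndarray] = {}
        self.coef_: np.ndarray | None = None
        self.lambda_: float | None = None
        self.edf_: float | None = None
        self.press_: float | None = None
        self.hat_diag_: np.ndarray | None = None
        self.train_range_: dict[str, tuple[float, float]] = {}

    # -- basis -------------------------------------------------------------
    def _make_knots(self, x: np.ndarray) -> np.ndarray:
        lo, hi = float(x.min()), float(x.max())
        inner = self.n_splines - self.degree + 1
        grid = np.linspace(lo, hi, inner)
        return np.concatenate([[lo] * self.degree, grid, [hi] * self.degree])

    def _basis(self, name: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.train_range_[name]
        xc = np.clip(x, lo, hi)
        B = BSpline.design_matrix(xc, self.knots_[name], self.degree).toarray()
        return B - self.centers_[name]  # sum-to-zero: centred over training data

    def _design(self, table: pd.DataFrame, fit: bool) -> np.ndarray:
        blocks = [np.ones((len(table), 1))]
        for name in self.terms_:
            x = table[name].to_numpy(dtype=float)
            if fit:
                self.train_range_[name] = (float(x.min()), float(x.max()))
                self.knots_[name] = self._make_knots(x)
                self.centers_[name] = np.zeros(self.n_splines)
                B = self._basis(name, x)
                self.centers_[name] = B.mean(axis=0)
                B = B - self.centers_[name]
            else:
                B = self._basis(name, x)
            blocks.append(B)
        return np.hstack(blocks)

    def _penalty(self) -> np.ndarray:
        k = self.n_splines
        D = np.diff(np.eye(k), n=2, axis=0)
        P_term = D.T @ D
        m = 1 + len(self.terms_) * k
        P = np.zeros((m, m))
        for t in range(len(self.terms_)):
            a = 1 + t * k
            P[a:a + k, a:a + k] = P_term
        return P

    # -- fitting -----------------------------------------------------------
    def fit(self, table: pd.DataFrame, y: np.ndarray) -> "AdditiveModel":
        y = np.asarray(y, dtype=float)
        keep = table.notna().all(axis=1).to_numpy() & ~np.isnan(y)
        table = table.loc[keep]
        y = y[keep]
        self.terms_ = []
        for name in table.columns:
            if table[name].nunique() <= 1:
                warnings.warn(f"dropping zero-variance predictor {name!r}")
                continue
            self.terms_.append(name)
        if not self.terms_:
            raise ValueError("no usable predictors")
        n = len(table)
        if n < 10 * len(self.terms_):
            raise ValueError(
                f"need at least {10 * len(self.terms_)} rows for "
                f"{len(self.terms_)} smooth terms, got {n}")
        X = self._design(table, fit=True)
        P = self._penalty()
        XtX = X.T @ X
        Xty = X.T @ y
        sst = np.sum((y - y.mean()) ** 2)
        # centred spline blocks share a null direction with the difference
        # penalty (block-constant coefficients); a tiny ridge keeps the
        # normal matrix invertible without affecting the fit
        ridge = 1e-8 * np.trace(XtX) / XtX.shape[0] * np.eye(XtX.shape[0])

        best = None
        for lam in self.lambda_grid:
            A = XtX + lam * P + ridge
            try:
                coef = np.linalg.solve(A, Xty)
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                continue
            fitted = X @ coef
            resid = y - fitted
            hat = np.einsum("ij,jk,ik->i", X, Ainv, X)
            edf = float(hat.sum())
            denom = max(n - edf, 1e-8)
            gcv = n * float(resid @ resid) / denom**2
            if best is None or gcv < best[0]:
                best = (gcv, lam, coef, hat, edf, resid)
        if best is None:
            raise RuntimeError("additive model fit failed for every smoothing value")
        _, self.lambda_, self.coef_, self.hat_diag_, self.edf_, resid = best
        with np.errstate(divide="ignore"):
            loo = resid / np.clip(1.0 - self.hat_diag_, 1e-8, None)
        self.press_ = float(loo @ loo)
        self.sst_ = float(sst)
        self.fitted_ = y - resid
        self.y_ = y
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        missing = [t for t in self.terms_ if t not in table.columns]
        if missing:
            raise KeyError(f"missing predictors: {missing}")
        ok = table[self.terms_].notna().all(axis=1).to_numpy()
        out = np.full(len(table), np.nan)
        if ok.any():
            X = self._design(table.loc[ok, self.terms_], fit=False)
            out[ok] = X @ self.coef_
        return out

    def partial_dependence(self, name: str, grid: np.ndarray | None = None):
        """Centred shape function of one predictor."""
        if name not in self.terms_:
            raise KeyError(name)
        lo, hi = self.train_range_[name]
        if grid is None:
            grid = np.linspace(lo, hi, 100)
        B = self._basis(name, np.asarray(grid, dtype=float))
        t = self.terms_.index(name)
        k = self.n_splines
        beta = self.coef_[1 + t * k: 1 + (t + 1) * k]
        return grid, B @ beta

    # -- reporting ---------------------------------------------------------
    def predicted_r2(self) -> float:
        """PRESS-based out-of-sample R2, clamped at zero (<= 0 means the
        model predicts held-out points no better than the mean)."""
        raw = 1.0 - self.press_ / self.sst_
        return float(max(raw, 0.0))

    def r2(self) -> float:
        resid = self.y_ - self.fitted_
        return float(1.0 - (resid @ resid) / self.sst_)


def fit_gam(response: np.ndarray, table: pd.DataFrame,
            n_splines: int = 10) -> AdditiveModel:
    """Fit the additive model; thin convenience wrapper."""
    return AdditiveModel(n_splines=n_splines).fit(table, response)


# ---------------------------------------------------------------------------
# Literature model registry: fixed forms, optional refitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A registered empirical model: functional form + predictors.

    ``coefficients`` is either a dict (fixed, ready to evaluate) or the
    string ``"fit"`` (to be estimated from data with :func:`refit_model`).
    ``log_transform`` marks forms whose response is modelled on a log scale;
    predictions are back-transformed before metric evaluation and the offset
    used to admit zero fluxes is stored with the coefficients.
    """

    name: str
    form: str
    timescale: str
    predictors: list[str]
    coefficients: dict | str = "fit"
    log_transform: bool = False
    response: str = "ch4_flux"
    source: str = ""
    fitted_object: object = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown model form {self.form!r}")
        if self.timescale not in TIMESCALES:
            raise ValueError(f"unknown timescale {self.timescale!r}")

    @property
    def is_fixed(self) -> bool:
        return isinstance(self.coefficients, dict)


def load_registry(path: str | Path | None = None) -> list[ModelSpec]:
    """Load model specs from the YAML registry (package default if None)."""
    if path is None:
        path = Path(__file__).parent / "data" / "literature_models.yml"
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh)
    return [ModelSpec(**e) for e in entries]


def _require(table: pd.DataFrame, predictors: list[str], name: str) -> None:
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise KeyError(f"model {name!r}: missing predictor(s) {missing}")


def _coef(spec: ModelSpec, key: str):
    try:
        return spec.coefficients[key]
    except (TypeError, KeyError):
        raise ValueError(f"model {spec.name!r}: missing coefficient {key!r}") from None


def predict_literature_model(spec: ModelSpec, table: pd.DataFrame) -> np.ndarray:
    """Evaluate a registered model with fixed coefficients on a table.

    The table carries one column per predictor at the spec's timescale
    (derived columns such as lagged fluxes or pressure changes included).
    """
    if not spec.is_fixed and spec.fitted_object is None:
        raise ValueError(f"model {spec.name!r} has no coefficients; refit first")
    _require(table, spec.predictors, spec.name)
    X = table[spec.predictors]

    if spec.form in ("linear", "autoregressive"):
        pred = np.full(len(X), float(_coef(spec, "intercept")))
        for p in spec.predictors:
            pred = pred + float(_coef(spec, p)) * X[p].to_numpy(dtype=float)
    elif spec.form == "binned_polynomial":
        x = X[spec.predictors[0]].to_numpy(dtype=float)
        coeffs = np.asarray(_coef(spec, "poly"), dtype=float)  # highest power first
        pred = np.polyval(coeffs, x)
    elif spec.form == "arrhenius":
        t = X[spec.predictors[0]].to_numpy(dtype=float)
        pred = float(_coef(spec, "flux_at_20C")) * np.exp(
            float(_coef(spec, "theta")) * (t - 20.0))
    elif spec.form == "pressure_threshold":
        p_tot = X[spec.predictors[0]].to_numpy(dtype=float)
        k = float(_coef(spec, "rate_constant"))
        thr = float(_coef(spec, "pressure_threshold"))
        pred = k * np.clip(thr - p_tot, 0.0, None)
    elif spec.form == "ann":
        if spec.fitted_object is None:
            raise ValueError(f"ANN model {spec.name!r} must be trained on data first")
        ok = X.notna().all(axis=1).to_numpy()
        pred = np.full(len(X), np.nan)
        if ok.any():
            pred[ok] = spec.fitted_object.predict(X.loc[ok].to_numpy(dtype=float))
    elif spec.form == "gam":
        if spec.fitted_object is None:
            raise ValueError(f"GAM model {spec.name!r} must be fitted on data first")
        return predict_gam_spec(spec, table)
    else:  # pragma: no cover - guarded by ModelSpec validation
        raise ValueError(spec.form)

    if spec.log_transform:
        offset = float(_coef(spec, "log_offset")) if spec.is_fixed else 0.0
        pred = np.exp(pred) - offset
    return np.asarray(pred, dtype=float)


def predict_gam_spec(spec: ModelSpec, table: pd.DataFrame) -> np.ndarray:
    pred = spec.fitted_object.predict(table)
    if spec.log_transform:
        pred = np.exp(pred) - spec.coefficients.get("log_offset", 0.0)
    return pred


def refit_model(
    spec: ModelSpec,
    table: pd.DataFrame,
    response: np.ndarray,
    seed: int = 0,
    min_rows_per_coef: int = 10,
) -> ModelSpec:
    """Re-estimate a model's coefficients on a training table.

    Least squares for linear/polynomial/autoregressive forms, nonlinear
    least squares for Arrhenius and pressure-threshold forms, gradient
    training for the small neural network, penalized fitting for the GAM.
    The returned spec is a valid input to :func:`predict_literature_model`.
    """
    _require(table, spec.predictors, spec.name)
    y = np.asarray(response, dtype=float)
    X = table[spec.predictors]
    ok = X.notna().all(axis=1).to_numpy() & ~np.isnan(y)
    Xv = X.loc[ok]
    yv = y[ok]

    n_coefs = {"linear": len(spec.predictors) + 1,
               "autoregressive": len(spec.predictors) + 1,
               "binned_polynomial": 4, "arrhenius": 2,
               "pressure_threshold": 2,
               "ann": 5 * (len(spec.predictors) + 2) + 1,
               "gam": 10 * len(spec.predictors) + 1}[spec.form]
    if yv.size < min_rows_per_coef * min(n_coefs, 10):
        raise ValueError(
            f"model {spec.name!r}: {yv.size} training rows is too few for "
            f"{n_coefs} coefficients")

    target = yv
    log_offset = 0.0
    if spec.log_transform:
        pos = yv[yv > 0]
        log_offset = 0.5 * float(pos.min()) if pos.size else 1.0
        target = np.log(yv + log_offset)

    out = ModelSpec(name=spec.name, form=spec.form, timescale=spec.timescale,
                    predictors=list(spec.predictors), log_transform=spec.log_transform,
                    response=spec.response, source=spec.source)

    if spec.form in ("linear", "autoregressive"):
        A = np.column_stack([np.ones(yv.size)] +
                            [Xv[p].to_numpy(dtype=float) for p in spec.predictors])
        beta, *_ = np.linalg.lstsq(A, target, rcond=None)
        coefs = {"intercept": float(beta[0])}
        coefs.update({p: float(b) for p, b in zip(spec.predictors, beta[1:])})
    elif spec.form == "binned_polynomial":
        x = Xv[spec.predictors[0]].to_numpy(dtype=float)
        coefs = {"poly": [float(c) for c in np.polyfit(x, target, 3)]}
    elif spec.form == "arrhenius":
        t = Xv[spec.predictors[0]].to_numpy(dtype=float)

        def f(t, f20, theta):
            return f20 * np.exp(theta * (t - 20.0))

        p0 = (max(float(np.mean(target)), 1e-6), 0.1)
        try:
            popt, _ = optimize.curve_fit(f, t, target, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"arrhenius refit did not converge: {exc}") from exc
        coefs = {"flux_at_20C": float(popt[0]), "theta": float(popt[1])}
    elif spec.form == "pressure_threshold":
        p_tot = Xv[spec.predictors[0]].to_numpy(dtype=float)

        def f(p, k, thr):
            return k * np.clip(thr - p, 0.0, None)

        p0 = (max(float(np.std(target)), 1e-6), float(np.percentile(p_tot, 75)))
        try:
            popt, _ = optimize.curve_fit(f, p_tot, target, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise RuntimeError(f"threshold refit did not converge: {exc}") from exc
        coefs = {"rate_constant": float(popt[0]), "pressure_threshold": float(popt[1])}
    elif spec.form == "ann":
        from sklearn.neural_network import MLPRegressor
        from sklearn.preprocessing import StandardScaler
        from sklearn.pipeline import make_pipeline

        net = make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=(5,), activation="tanh",
                         solver="lbfgs", max_iter=5000, random_state=seed))
        net.fit(Xv.to_numpy(dtype=float), target)
        out.fitted_object = net
        coefs = {"architecture": "5-unit tanh hidden layer"}
    elif spec.form == "gam":
        gam = AdditiveModel().fit(Xv, target)
        out.fitted_object = gam
        coefs = {"lambda": gam.lambda_, "edf": gam.edf_}
    else:  # pragma: no cover
        raise ValueError(spec.form)

    if spec.log_transform:
        coefs["log_offset"] = log_offset
    out.coefficients = coefs
    return out
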