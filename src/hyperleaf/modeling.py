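"""Single-variable model fitting, evaluation metrics, cross-validation and
stepwise multivariable regression for pigment estimation.

Five single-variable model forms relate an index value x to a pigment
content y:

    linear       y = a0 + a1*x
    power        y = a0 * x^a1
    exponential  y = a0 * exp(a1*x)
    logarithmic  y = a0 * ln(a1*x)
    quadratic    y = a0 + a1*x + a2*x^2

Linear/quadratic use ordinary least squares. Power and exponential are fit
by true nonlinear least squares in original units, initialized from the
log-linearized OLS solution (so the reported error structure matches the
form as printed rather than its log transform). The logarithmic form is
recovered from OLS of y on ln x: slope = a0, a1 = exp(intercept / a0).

Goodness-of-fit metrics follow the conventions of the field:
R^2 = 1 - SS_res/SS_tot, MAPE = (100/n) * sum|y - yhat| / |y|,
RMSE = sqrt(mean((y - yhat)^2)), and SD_APE = the sample standard deviation
(n-1 denominator) of the individual absolute percentage errors.

Cross-validation uses a seeded uniform shuffle into k near-equal folds
(default k=5, no stratification); per-fold modeling (train) and validation
(held-out) metrics are reported together with their means.

Stepwise regression is classic forward-entry / backward-removal on
partial-F p-values (defaults 0.05 in / 0.10 out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from hyperleaf.indices import IndexDescriptor, IndexTable

log = logging.getLogger(__name__)

MODEL_FORMS = ("linear", "power", "exponential", "logarithmic", "quadratic")
_N_COEF = {"linear": 2, "power": 2, "exponential": 2, "logarithmic": 2, "quadratic": 3}


class Metrics(NamedTuple):
    r2: float
    mape: float  # percent
    rmse: float  # target units
    sd_ape: float  # percent


def model_metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """R^2, MAPE, RMSE and SD_APE of predictions against observations.

    Samples with y == 0 are excluded from the percentage errors (their
    count is logged); they still contribute to R^2 and RMSE.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    res = y - yhat
    ss_res = float((res**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("nan"))
    rmse = float(np.sqrt((res**2).mean()))
    nonzero = y != 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        log.warning("%d zero-valued samples excluded from percentage errors", n_dropped)
    if nonzero.sum() == 0:
        return Metrics(r2, float("nan"), rmse, float("nan"))
    ape = 100.0 * np.abs(res[nonzero]) / np.abs(y[nonzero])
    mape = float(ape.mean())
    sd_ape = float(ape.std(ddof=1)) if ape.size > 1 else 0.0
    return Metrics(r2, mape, rmse, sd_ape)


@dataclass
class FittedModel:
    """A fitted model form with coefficients and training metrics."""

    form: str
    coefficients: tuple[float, ...]  # (a0, a1[, a2])
    metrics: Metrics
    n: int
    predictor: IndexDescriptor | str | None = None
    target: str | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.form == "linear":
                out = c[0] + c[1] * x
            elif self.form == "quadratic":
                out = c[0] + c[1] * x + c[2] * x**2
            elif self.form == "power":
                out = np.where(x > 0, c[0] * np.sign(x) * np.abs(x) ** c[1], np.nan)
            elif self.form == "exponential":
                out = c[0] * np.exp(c[1] * x)
            elif self.form == "logarithmic":
                ax = c[1] * x
                out = np.where(ax > 0, c[0] * np.log(np.where(ax > 0, ax, 1.0)), np.nan)
            else:
                raise ValueError(f"unknown form {self.form!r}")
        return out

    def to_card(self) -> dict:
        """JSON-serializable model card."""
        pred = self.predictor
        if isinstance(pred, IndexDescriptor):
            pred = pred.name()
        return {
            "form": self.form,
            "coefficients": list(self.coefficients),
            "metrics": self.metrics._asdict(),
            "n": self.n,
            "predictor": pred,
            "target": self.target,
        }


def fit_form(
    x: np.ndarray,
    y: np.ndarray,
    form: str,
    predictor: IndexDescriptor | str | None = None,
    target: str | None = None,
) -> FittedModel:
    """Fit one of the five model forms; see the module docstring."""
    if form not in MODEL_FORMS:
        raise ValueError(f"unknown model form {form!r}; expected one of {MODEL_FORMS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < _N_COEF[form] + 1:
        raise ValueError(f"need at least {_N_COEF[form] + 1} samples for the {form} form")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")

    if form == "linear":
        a1, a0 = np.polyfit(x, y, 1)
        coef = (float(a0), float(a1))
    elif form == "quadratic":
        a2, a1, a0 = np.polyfit(x, y, 2)
        coef = (float(a0), float(a1), float(a2))
    elif form == "power":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("power form requires x > 0 and y > 0")
        b1, b0 = np.polyfit(np.log(x), np.log(y), 1)
        p0 = (float(np.exp(b0)), float(b1))
        popt, _ = curve_fit(lambda x, a0, a1: a0 * np.power(x, a1), x, y, p0=p0, maxfev=20000)
        coef = (float(popt[0]), float(popt[1]))
    elif form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential form requires y > 0 for initialization")
        b1, b0 = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(b0)), float(b1))
        popt, _ = curve_fit(lambda x, a0, a1: a0 * np.exp(a1 * x), x, y, p0=p0, maxfev=20000)
        coef = (float(popt[0]), float(popt[1]))
    else:  # logarithmic
        if np.any(x <= 0):
            raise ValueError("logarithmic form requires x > 0")
        slope, intercept = np.polyfit(np.log(x), y, 1)
        if abs(slope) < 1e-12:
            raise ValueError("degenerate logarithmic fit: slope is zero")
        coef = (float(slope), float(np.exp(intercept / slope)))

    model = FittedModel(form, coef, Metrics(np.nan, np.nan, np.nan, np.nan), n, predictor, target)
    model.metrics = model_metrics(y, model.predict(x))
    return model


@dataclass
class CVReport:
    """k-fold cross-validation report: per-fold and mean metrics."""

    k: int
    seed: int
    form: str
    fold_modeling: list[Metrics]
    fold_validation: list[Metrics]

    @staticmethod
    def _mean(ms: list[Metrics]) -> Metrics:
        arr = np.array([list(m) for m in ms], dtype=float)
        return Metrics(*np.nanmean(arr, axis=0))

    @property
    def mean_modeling(self) -> Metrics:
        return self._mean(self.fold_modeling)

    @property
    def mean_validation(self) -> Metrics:
        return self._mean(self.fold_validation)


def kfold_cv(
    x: np.ndarray, y: np.ndarray, form: str, k: int = 5, seed: int = 0
) -> CVReport:
    """Seeded k-fold cross-validation of one model form.

    Samples are shuffled uniformly (no stratification) and split into k
    near-equal folds; each fold is held out once. Modeling metrics are
    computed on the training portion, validation metrics on the held-out
    fold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    modeling, validation = [], []
    for held in folds:
        train = np.setdiff1d(perm, held, assume_unique=True)
        model = fit_form(x[train], y[train], form)
        modeling.append(model_metrics(y[train], model.predict(x[train])))
        validation.append(model_metrics(y[held], model.predict(x[held])))
    return CVReport(k=k, seed=seed, form=form, fold_modeling=modeling, fold_validation=validation)


# ---------------------------------------------------------------------------
# stepwise multivariable regression
# ---------------------------------------------------------------------------

@dataclass
class StepwiseModel:
    """Multivariable linear model selected by stepwise entry/removal."""

    selected: list[str]
    coefficients: dict[str, float]  # includes "const"
    r2: float
    adj_r2: float
    metrics: Metrics
    trace: list[tuple[str, str, float]]  # (action, name, p-value)
    note: str | None = None

    def predict(self, X: np.ndarray, names: Sequence[str]) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self.coefficients["const"])
        pos = {nm: k for k, nm in enumerate(names)}
        for nm in self.selected:
            out = out + self.coefficients[nm] * X[:, pos[nm]]
        return out


def stepwise_regression(
    X,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    max_steps: int = 200,
) -> StepwiseModel:
    """Forward-entry / backward-removal stepwise linear regression.

    ``X`` is a (n_samples, n_candidates) matrix or an :class:`IndexTable`
    (typically restricted to the R/dR/ddR single-band families).
    Candidates enter at the smallest partial-F p-value below ``entry_p``
    and are removed when their p-value exceeds ``removal_p``. If nothing
    passes entry, an intercept-only model is returned with a note.
    """
    import statsmodels.api as sm

    if isinstance(X, IndexTable):
        if names is None:
            names = X.column_names()
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_candidates) aligned with y")
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate")
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    names = list(names)

    selected: list[int] = []
    trace: list[tuple[str, str, float]] = []

    def _pvalues(cols: list[int]) -> np.ndarray:
        design = sm.add_constant(X[:, cols]) if cols else np.ones((y.size, 1))
        fit = sm.OLS(y, design).fit()
        return fit.pvalues[1:] if cols else np.array([])

    for _ in range(max_steps):
        changed = False
        # forward entry
        remaining = [k for k in range(X.shape[1]) if k not in selected]
        best_k, best_p = None, np.inf
        for k in remaining:
            p = _pvalues(selected + [k])[-1]
            if np.isfinite(p) and p < best_p:
                best_k, best_p = k, float(p)
        if best_k is not None and best_p < entry_p:
            selected.append(best_k)
            trace.append(("enter", names[best_k], best_p))
            changed = True
        # backward removal
        while selected:
            ps = _pvalues(selected)
            worst = int(np.argmax(ps))
            if ps[worst] > removal_p:
                removed = selected.pop(worst)
                trace.append(("remove", names[removed], float(ps[worst])))
                changed = True
            else:
                break
        if not changed:
            break

    note = None
    if not selected:
        note = "no candidate passed the entry threshold; intercept-only model"
        coefs = {"const": float(y.mean())}
        yhat = np.full_like(y, y.mean())
        return StepwiseModel([], coefs, 0.0, 0.0, model_metrics(y, yhat), trace, note)

    design = sm.add_constant(X[:, selected])
    fit = sm.OLS(y, design).fit()
    coefs = {"const": float(fit.params[0])}
    for pos, k in enumerate(selected, start=1):
        coefs[names[k]] = float(fit.params[pos])
    yhat = fit.predict(design)
    return StepwiseModel(
        selected=[names[k] for k in selected],
        coefficients=coefs,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        metrics=model_metrics(y, yhat),
        trace=trace,
        note=note,
    )


# ---------------------------------------------------------------------------
# published single-variable model presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublishedModelPreset:
    """A published linear pigment model y = slope * x + intercept.

    The predictor x is a two-band index given by family, transform and the
    two wavelengths; :meth:`descriptor` resolves it onto a concrete grid.
    """

    stage: str
    pigment: str
    family: str
    transform: str
    wl_i: float
    wl_j: float
    slope: float
    intercept: float
    formula: str

    def descriptor(self, grid) -> IndexDescriptor:
        return IndexDescriptor(
            self.family, self.transform, grid.nearest(self.wl_i), grid.nearest(self.wl_j)
        )

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def to_model(self) -> FittedModel:
        return FittedModel(
            "linear",
            (self.intercept, self.slope),
            Metrics(np.nan, np.nan, np.nan, np.nan),
            0,
            predictor=self.formula,
            target=self.pigment,
        )


#: The eight published single-variable pigment models (tillering/heading
#: stages of rice). Predictors: x1 = lg(R715)/lg(R500), x2 = lg(R715)/lg(R660),
#: x3 = lg(R718)/lg(R450), x4/x5 = normalized first-derivative pairs at
#: (997, 747)/(997, 728) nm, x6 = normalized d(lg(1/R)) pair at (747, 792) nm.
PUBLISHED_MODELS: tuple[PublishedModelPreset, ...] = (
    PublishedModelPreset("tillering", "Ca", "ratio", "lgR", 715, 500, 1217.948, -301.306, "lg(R715)/lg(R500)"),
    PublishedModelPreset("tillering", "Cb", "ratio", "lgR", 715, 660, 557.723, -126.609, "lg(R715)/lg(R660)"),
    PublishedModelPreset("tillering", "C", "ratio", "lgR", 715, 500, 1596.104, -405.674, "lg(R715)/lg(R500)"),
    PublishedModelPreset("tillering", "Cxc", "ratio", "lgR", 718, 450, 188.087, -22.582, "lg(R718)/lg(R450)"),
    PublishedModelPreset("heading", "Ca", "normalized", "dR", 997, 747, 7874.223, -8009.138, "(dR997-dR747)/(dR997+dR747)"),
    PublishedModelPreset("heading", "Cb", "normalized", "dR", 997, 728, 933.651, -1006.710, "(dR997-dR728)/(dR997+dR728)"),
    PublishedModelPreset("heading", "C", "normalized", "dR", 997, 747, 10159.684, -10340.279, "(dR997-dR747)/(dR997+dR747)"),
    PublishedModelPreset("heading", "Cxc", "normalized", "dlg1R", 747, 792, 175.113, -52.628, "(dlg(1/R)747-dlg(1/R)792)/(dlg(1/R)747+dlg(1/R)792)"),
)
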