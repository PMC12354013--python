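"""Progress-curve fitting, residual diagnostics, and model selection.

`ProgressCurveFitter` is a scikit-learn-style estimator that fits one of
the three growth models (mono, bi, lagged mono-exponential) to a progress
curve by bounded nonlinear least squares.  `KineticModelSelector`
implements the escalation ladder used for acyltransferase time courses:
start mono-exponential; if its residuals show systematic structure,
escalate to the bi-exponential and lagged models and pick among them
using residual patterns and AICc.

"Systematic" residual structure is formalized as a Wald-Wolfowitz runs
test on residual signs (the underlying study judged this visually) plus
an early-lag score: the mean residual sign over the first quartile of
timepoints, which is strongly positive when the model underestimates
early intensities (the signature of a lag phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import least_squares
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from .models import (
    BiExpParams,
    LaggedMonoExpParams,
    MODEL_EVALUATORS,
    MonoExpParams,
    PARAM_TYPES,
    ProgressCurve,
)

MODEL_IDS = ("mono", "bi", "lagged", "lagged_bi")

# free-parameter counts (lagged_bi is a convergence probe only)
_N_FREE = {"mono": 2, "bi": 4, "lagged": 5, "lagged_bi": 7}


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares fit."""

    model_id: str
    params: object
    r_squared: float
    residuals: NDArray[np.float64]
    converged: bool
    n_iter: int
    aic_c: float
    message: str = ""

    @property
    def ss_res(self) -> float:
        return float(self.residuals @ self.residuals)


@dataclass
class DiagnosticsReport:
    """Residual-randomness diagnostics for one fit."""

    runs_test_p: float
    early_lag_score: float
    systematic: bool
    n_runs: int = 0
    mid_sign_score: float = 0.0


@dataclass
class ModelSelectionResult:
    """Chosen model plus every fit attempted and the decision trail."""

    chosen: str
    fits: dict[str, FitResult]
    rationale: list[str] = field(default_factory=list)

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.chosen]


# ---------------------------------------------------------------------------
# diagnostics


def runs_test_pvalue(signs: ArrayLike) -> tuple[float, int]:
    """One-sided Wald-Wolfowitz runs test on a +/- sign sequence.

    Tests against *too few* runs (sign clustering), the signature of a
    model that under- then over-estimates the data; a perfectly
    alternating sequence has maximal runs and p near 1.  Uses the normal
    approximation to the run-count distribution and returns (p-value,
    number of runs).  When one sign is entirely absent the sequence is a
    single run: p -> 0 for length >= 8, else 1 (too short to judge).
    """
    s = np.asarray(signs)
    s = s[s != 0]
    n = len(s)
    if n == 0:
        return 1.0, 0
    runs = 1 + int(np.count_nonzero(s[1:] != s[:-1]))
    n_pos = int(np.count_nonzero(s > 0))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        # single run of one sign: probability of so few runs under
        # randomness is 2^(1-n) for a fair sign process
        return (float(2.0 ** (1 - n)) if n >= 8 else 1.0), runs
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0, runs
    z = (runs - mu) / math.sqrt(var)
    return float(norm.cdf(z)), runs


def residual_diagnostics(
    fit: FitResult,
    curve: ProgressCurve,
    alpha: float = 0.05,
    zero_tol: float = 1e-12,
) -> DiagnosticsReport:
    """Runs test and early-lag score for a fit's residuals.

    Residuals are data - model.  Residuals whose magnitude is below
    zero_tol times the curve maximum are treated as exact zeros and
    dropped from the sign sequence (an all-zero residual vector yields
    runs_test_p = 1, systematic = False).
    """
    if len(fit.residuals) != len(curve):
        raise ValueError("fit and curve lengths differ")
    scale = float(np.max(np.abs(curve.intensities))) or 1.0
    signs = np.sign(np.where(np.abs(fit.residuals) <= zero_tol * scale, 0.0, fit.residuals))
    p, n_runs = runs_test_pvalue(signs)
    n = len(curve)
    q1 = max(1, n // 4)
    early = float(np.mean(signs[:q1]))
    mid = float(np.mean(signs[q1 : max(q1 + 1, 3 * n // 4)]))
    return DiagnosticsReport(
        runs_test_p=p,
        early_lag_score=early,
        systematic=bool(p < alpha),
        n_runs=n_runs,
        mid_sign_score=mid,
    )


# ---------------------------------------------------------------------------
# initialization


def initialize_parameters(curve: ProgressCurve, model_id: str):
    """Heuristic starting parameters for each model.

    mono: I_max from the curve maximum, k from a log-linear fit of
    log(1 - I/I_max_guess) over the first half (falling back to
    1/median(t) when that fails); bi: split the mono k into (3k, k/3)
    with a 60/40 amplitude split; lagged: t0 at the steepest numerical
    gradient, alpha = 0.5 min^-1, C = first intensity.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model '{model_id}'")
    n_free = _N_FREE[model_id]
    if len(curve) < 2 * n_free:
        raise ValueError(
            f"model '{model_id}' needs >= {2 * n_free} points, curve has {len(curve)}"
        )
    t, y = curve.times, curve.intensities
    i_max = float(np.max(y))
    k_fallback = 1.0 / float(np.median(t))
    k_guess = k_fallback
    degenerate = i_max <= 0
    if not degenerate:
        half = max(2, len(t) // 2)
        frac = 1.0 - y[:half] / (1.05 * i_max)
        mask = frac > 1e-9
        if mask.sum() >= 2:
            slope = np.polyfit(t[:half][mask], np.log(frac[mask]), 1)[0]
            if slope < 0:
                k_guess = -float(slope)
    if model_id == "mono":
        return MonoExpParams(i_max=max(i_max, 0.0) or 1.0, k=k_guess)
    if model_id == "bi":
        amp = max(i_max, 1.0 if degenerate else i_max)
        return BiExpParams(a1=0.6 * amp, a2=0.4 * amp, k1=3.0 * k_guess, k2=k_guess / 3.0)
    # lagged (and the lagged_bi probe builds on this)
    grad = np.gradient(y, t)
    t0 = float(t[int(np.argmax(grad))])
    base = LaggedMonoExpParams(
        a=max(i_max, 0.0) or 1.0, k=k_guess, t0=t0, alpha=0.5, c=max(float(y[0]), 0.0)
    )
    if model_id == "lagged":
        return base
    return {  # lagged_bi probe: dict of start values
        "a1": 0.6 * base.a,
        "a2": 0.4 * base.a,
        "k1": 3.0 * k_guess,
        "k2": k_guess / 3.0,
        "t0": t0,
        "alpha": 0.5,
        "c": base.c,
    }


# ---------------------------------------------------------------------------
# fitting


def _aicc(ss_res: float, n: int, n_free: int) -> float:
    """Corrected Akaike information criterion for a Gaussian LSQ fit.

    k counts the free model parameters plus the noise variance.  ss_res
    is floored to keep noiseless (machine-zero) fits finite.
    """
    k = n_free + 1
    ss = max(ss_res, n * 1e-30)
    aic = n * math.log(ss / n) + 2 * k
    denom = n - k - 1
    return aic + (2 * k * (k + 1) / denom if denom > 0 else math.inf)


def _pack(model_id: str, params) -> np.ndarray:
    if model_id == "mono":
        return np.array([params.i_max, params.k])
    if model_id == "bi":
        return np.array([params.a1, params.a2, params.k1, params.k2])
    if model_id == "lagged":
        return np.array([params.a, params.k, params.t0, params.alpha, params.c])
    p = params  # lagged_bi dict
    return np.array([p["a1"], p["a2"], p["k1"], p["k2"], p["t0"], p["alpha"], p["c"]])


def _unpack(model_id: str, x: np.ndarray):
    if model_id == "mono":
        return MonoExpParams(i_max=max(x[0], 0.0), k=max(x[1], 0.0))
    if model_id == "bi":
        return BiExpParams(
            a1=max(x[0], 0.0), a2=max(x[1], 0.0), k1=max(x[2], 0.0), k2=max(x[3], 0.0)
        )
    if model_id == "lagged":
        return LaggedMonoExpParams(
            a=max(x[0], 0.0), k=max(x[1], 0.0), t0=max(x[2], 0.0),
            alpha=max(x[3], 1e-9), c=x[4],
        )
    return dict(zip(("a1", "a2", "k1", "k2", "t0", "alpha", "c"), x))


def _eval(model_id: str, params, t: np.ndarray) -> np.ndarray:
    if model_id == "lagged_bi":
        p = params
        gate = 1.0 / (1.0 + np.exp(-p["alpha"] * (t - p["t0"])))
        growth = p["a1"] * -np.expm1(-p["k1"] * t) + p["a2"] * -np.expm1(-p["k2"] * t)
        return growth * gate + p["c"]
    return MODEL_EVALUATORS[model_id](params, t)


def _bounds(model_id: str, t_max: float) -> tuple[np.ndarray, np.ndarray]:
    big = np.inf
    if model_id == "mono":
        return np.array([0.0, 0.0]), np.array([big, big])
    if model_id == "bi":
        return np.zeros(4), np.full(4, big)
    if model_id == "lagged":
        return (
            np.array([0.0, 0.0, 0.0, 1e-9, -big]),
            np.array([big, big, t_max, 10.0, big]),
        )
    return (
        np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1e-9, -big]),
        np.array([big, big, big, big, t_max, 10.0, big]),
    )


def fit_progress_curve(curve: ProgressCurve, model_id: str, init=None) -> FitResult:
    """Bounded least-squares fit of one model to one progress curve.

    Rates and amplitudes are bounded below by zero; t0 lies within
    [0, max time] and alpha in (0, 10] min^-1.  Non-convergence never
    raises; it is annotated on the result.  R^2 uses SS_tot about the
    mean intensity and may be negative for terrible fits.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model '{model_id}'")
    y = curve.intensities
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities contain NaN/Inf")
    if init is None:
        init = initialize_parameters(curve, model_id)
    t = curve.times
    x0 = _pack(model_id, init)
    lo, hi = _bounds(model_id, float(t[-1]))
    x0 = np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0, hi))

    def resid(x):
        return _eval(model_id, _unpack(model_id, x), t) - y

    sol = least_squares(
        resid, x0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
    )
    params = _unpack(model_id, sol.x)
    model_y = _eval(model_id, params, t)
    residuals = y - model_y
    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return FitResult(
        model_id=model_id,
        params=params,
        r_squared=r2,
        residuals=residuals,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        aic_c=_aicc(ss_res, len(y), _N_FREE[model_id]),
        message=sol.message,
    )


def compare_fits(a: FitResult, b: FitResult) -> dict:
    """Pairwise comparison: ΔR², ΔAICc, and the preferred fit.

    Preference: lower AICc; exact ties go to the model with fewer free
    parameters (deterministic).
    """
    if len(a.residuals) != len(b.residuals):
        raise ValueError("fits are not on the same curve (length mismatch)")
    d_r2 = a.r_squared - b.r_squared
    d_aicc = a.aic_c - b.aic_c
    if d_aicc < 0:
        preferred = a.model_id
    elif d_aicc > 0:
        preferred = b.model_id
    else:
        preferred = a.model_id if _N_FREE[a.model_id] <= _N_FREE[b.model_id] else b.model_id
    return {"delta_r_squared": d_r2, "delta_aic_c": d_aicc, "preferred": preferred}


# ---------------------------------------------------------------------------
# estimators


class ProgressCurveFitter(BaseEstimator, RegressorMixin):
    """Fit one kinetic growth model to intensity-versus-time data.

    Parameters
    ----------
    model : {"mono", "bi", "lagged"}, default "mono"
        Which growth model to fit.
    init : parameter object, optional
        Starting parameters; defaults to the heuristic initializer.

    Attributes
    ----------
    params_ : fitted parameter object (canonical-ordered for "bi")
    result_ : FitResult with residuals, R^2, AICc and convergence info
    r_squared_, aic_c_, converged_ : convenience mirrors of result_

    Examples
    --------
    >>> fitter = ProgressCurveFitter(model="mono").fit(t, intensity)
    >>> fitter.params_.k
    """

    def __init__(self, model: str = "mono", init=None):
        self.model = model
        self.init = init

    def _to_curve(self, X, y) -> ProgressCurve:
        t = np.asarray(X, dtype=float).reshape(-1)
        return ProgressCurve(times=t, intensities=np.asarray(y, dtype=float))

    def fit(self, X, y):
        """Fit to times X (1-D or column vector, minutes) and intensities y."""
        return self.fit_curve(self._to_curve(X, y))

    def fit_curve(self, curve: ProgressCurve):
        """Fit directly from a ProgressCurve."""
        self.result_ = fit_progress_curve(curve, self.model, init=self.init)
        self.params_ = self.result_.params
        self.r_squared_ = self.result_.r_squared
        self.aic_c_ = self.result_.aic_c
        self.converged_ = self.result_.converged
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Evaluate the fitted model at times X."""
        if not hasattr(self, "params_"):
            raise AttributeError("fit the estimator before calling predict")
        t = np.asarray(X, dtype=float).reshape(-1)
        return _eval(self.model, self.params_, t)


class KineticModelSelector(BaseEstimator):
    """Model-selection ladder for acyl-transfer progress curves.

    The ladder: (1) fit mono; accept it if the residuals pass the runs
    test; (2) otherwise fit the bi-exponential and lagged models,
    discarding candidates that fail to converge or do not improve on the
    mono R^2; (3) a strongly positive early-lag score on the mono
    residuals argues for the lagged model, an early-positive/mid-negative
    sign-flip for the bi-exponential — either heuristic decides only if
    its candidate is within `aicc_guard` of the best AICc; (4) remaining
    ties go to the lower AICc.  A lagged bi-exponential probe can be
    requested; it is never auto-selected unless it beats the lagged model
    by more than `aicc_guard`.

    Attributes
    ----------
    selection_ : ModelSelectionResult (chosen model, all fits, rationale)
    best_model_ : str, the chosen model id
    """

    def __init__(
        self,
        runs_alpha: float = 0.05,
        early_lag_threshold: float = 0.5,
        mid_flip_threshold: float = 0.25,
        aicc_guard: float = 10.0,
        probe_lagged_bi: bool = False,
    ):
        self.runs_alpha = runs_alpha
        self.early_lag_threshold = early_lag_threshold
        self.mid_flip_threshold = mid_flip_threshold
        self.aicc_guard = aicc_guard
        self.probe_lagged_bi = probe_lagged_bi

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.fit_curve(ProgressCurve(times=t, intensities=np.asarray(y, dtype=float)))

    def fit_curve(self, curve: ProgressCurve):
        trail: list[str] = []
        fits: dict[str, FitResult] = {}
        mono = fit_progress_curve(curve, "mono")
        fits["mono"] = mono
        diag = residual_diagnostics(mono, curve, alpha=self.runs_alpha)
        trail.append(
            f"mono fit: R2={mono.r_squared:.6f}, runs-test p={diag.runs_test_p:.3g}, "
            f"early_lag={diag.early_lag_score:+.2f}, mid_sign={diag.mid_sign_score:+.2f}"
        )
        if not diag.systematic:
            trail.append("mono residuals not systematic: choose mono")
            self._finish(curve, "mono", fits, trail, diag)
            return self
        trail.append("mono residuals systematic: escalate to bi and lagged models")

        candidates: dict[str, FitResult] = {}
        for mid in ("bi", "lagged"):
            f = fit_progress_curve(curve, mid)
            fits[mid] = f
            if not f.converged:
                trail.append(f"{mid}: did not converge, discarded")
            elif f.r_squared <= mono.r_squared:
                trail.append(f"{mid}: R2={f.r_squared:.6f} does not exceed mono, discarded")
            else:
                candidates[mid] = f
                trail.append(f"{mid}: R2={f.r_squared:.6f}, AICc={f.aic_c:.2f}, kept")

        if not candidates:
            trail.append("no candidate improved on mono: keep mono (annotated systematic)")
            self._finish(curve, "mono", fits, trail, diag)
            return self

        chosen = min(candidates, key=lambda m: candidates[m].aic_c)
        best_aicc = candidates[chosen].aic_c
        mid_flip = (
            diag.early_lag_score > self.mid_flip_threshold
            and diag.mid_sign_score < -self.mid_flip_threshold
        )
        if mid_flip and "bi" in candidates:
            if candidates["bi"].aic_c <= best_aicc + self.aicc_guard:
                chosen = "bi"
                trail.append("early+/mid- residual sign flip on mono fit: prefer bi")
        elif diag.early_lag_score > self.early_lag_threshold and "lagged" in candidates:
            if candidates["lagged"].aic_c <= best_aicc + self.aicc_guard:
                chosen = "lagged"
                trail.append("strong positive early-lag score on mono fit: prefer lagged")
        trail.append(f"chosen {chosen} (AICc={candidates[chosen].aic_c:.2f})")

        if self.probe_lagged_bi:
            probe = fit_progress_curve(curve, "lagged_bi")
            fits["lagged_bi"] = probe
            if (
                probe.converged
                and "lagged" in fits
                and probe.aic_c < fits["lagged"].aic_c - self.aicc_guard
            ):
                chosen = "lagged_bi"
                trail.append("lagged_bi probe beat lagged by more than the AICc guard")
            else:
                trail.append("lagged_bi probe did not improve the fit; ignored")

        self._finish(curve, chosen, fits, trail, diag)
        return self

    def _finish(self, curve, chosen, fits, trail, mono_diag):
        self.selection_ = ModelSelectionResult(chosen=chosen, fits=fits, rationale=trail)
        self.best_model_ = chosen
        self.mono_diagnostics_ = mono_diag
        self.best_fit_ = fits[chosen]
        self.n_features_in_ = 1

    def predict(self, X):
        if not hasattr(self, "best_fit_"):
            raise AttributeError("fit the estimator before calling predict")
        t = np.asarray(X, dtype=float).reshape(-1)
        return _eval(self.best_model_, self.best_fit_.params, t)


def select_model(curve: ProgressCurve, **kwargs) -> ModelSelectionResult:
    """Run the model-selection ladder on a progress curve."""
    sel = KineticModelSelector(**kwargs)
    sel.fit_curve(curve)
    return sel.selection_
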