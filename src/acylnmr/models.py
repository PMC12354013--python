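"""Closed-form progress-curve models for acyltransferase kinetics.

Three nested models describe product signal intensity I(t) during an
acyl-transfer reaction monitored by serial HSQC experiments:

* mono-exponential growth      I(t) = I_max (1 - e^{-k t})
* bi-exponential growth        I(t) = A1 (1 - e^{-k1 t}) + A2 (1 - e^{-k2 t})
* lagged mono-exponential      I(t) = A (1 - e^{-k t}) / (1 + e^{-alpha (t - t0)}) + C

Times are minutes since cofactor addition; intensities are arbitrary
units.  Rates k are relative first-order rate constants (min^-1) that
approximate k_cat under substrate excess.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import ArrayLike, NDArray


def _check_times(times: ArrayLike) -> NDArray[np.float64]:
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        idx = int(np.argmax(np.atleast_1d(t < 0)))
        raise ValueError(f"negative time at index {idx}: t={np.atleast_1d(t)[idx]}")
    return t


@dataclass(frozen=True)
class MonoExpParams:
    """Parameters of the mono-exponential growth model.

    Attributes
    ----------
    i_max : float
        Asymptotic maximum intensity (a.u.), >= 0.
    k : float
        Relative rate constant (min^-1), >= 0.
    """

    i_max: float
    k: float

    def __post_init__(self) -> None:
        if self.i_max < 0:
            raise ValueError(f"i_max must be >= 0, got {self.i_max}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")

    n_free = 2


def _canonical_biexp(a1: float, a2: float, k1: float, k2: float) -> tuple[float, float, float, float]:
    if k1 < k2:
        a1, a2, k1, k2 = a2, a1, k2, k1
    return a1, a2, k1, k2


@dataclass(frozen=True)
class BiExpParams:
    """Parameters of the bi-exponential growth model.

    Attributes
    ----------
    a1, a2 : float
        Amplitudes of the two exponential components (a.u.), >= 0.
    k1, k2 : float
        Relative rate constants (min^-1), >= 0.  Canonical ordering
        k1 >= k2 is enforced at construction by swapping components,
        so component 1 is always the faster one.
    """

    a1: float
    a2: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rates must be >= 0")
        a1, a2, k1, k2 = _canonical_biexp(self.a1, self.a2, self.k1, self.k2)
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)
        object.__setattr__(self, "k1", k1)
        object.__setattr__(self, "k2", k2)

    n_free = 4


@dataclass(frozen=True)
class LaggedMonoExpParams:
    """Parameters of the lagged mono-exponential model.

    A logistic gate centered at the transition time t0 (slope alpha)
    multiplies the exponential growth term; C is the initial amplitude of
    the uncharacterized process that masks growth at early timepoints.
    """

    a: float
    k: float
    t0: float
    alpha: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")

    n_free = 5


@dataclass
class ProgressCurve:
    """Product intensity versus time for one reaction time course.

    times are minutes since cofactor addition and must be strictly
    increasing with times[0] > 0 (experiment 1 is pre-initiation and never
    appears).  deadtime and experiment_length record the acquisition
    schedule that generated the timepoint list.
    """

    times: NDArray[np.float64]
    intensities: NDArray[np.float64]
    label: str = ""
    deadtime: float | None = None
    experiment_length: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("times and intensities must be 1-D")
        if len(self.times) != len(self.intensities):
            raise ValueError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.intensities)} intensities"
            )
        if len(self.times) and self.times[0] <= 0:
            raise ValueError("times[0] must be > 0 (experiment 1 is excluded)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def with_intensities(self, intensities: ArrayLike) -> "ProgressCurve":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


def eval_mono_exp(params: MonoExpParams, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate I_max (1 - e^{-k t}) elementwise; non-decreasing in t."""
    t = _check_times(times)
    return params.i_max * -np.expm1(-params.k * t)


def eval_bi_exp(params: BiExpParams, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate the two-component growth sum; asymptote is a1 + a2."""
    t = _check_times(times)
    return params.a1 * -np.expm1(-params.k1 * t) + params.a2 * -np.expm1(-params.k2 * t)


def eval_lagged_mono_exp(params: LaggedMonoExpParams, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate gated growth A (1-e^{-kt}) sigma(alpha (t-t0)) + C.

    The gate is the logistic function; it equals 1/2 exactly at t = t0 and
    is evaluated as written at t = 0 (no clamping).
    """
    t = _check_times(times)
    gate = 1.0 / (1.0 + np.exp(-params.alpha * (t - params.t0)))
    return params.a * -np.expm1(-params.k * t) * gate + params.c


def amplitude_fraction(params: BiExpParams) -> tuple[float, float]:
    """Fraction of total amplitude in the fast and slow components.

    A ~60%/40% split over five equivalent sites indicates a 3:2 split of
    lysines between the fast and slow rate classes.
    """
    total = params.a1 + params.a2
    if total <= 0:
        raise ValueError("total amplitude must be > 0")
    return params.a1 / total, params.a2 / total


def rate_ratio(params: BiExpParams) -> float:
    """Fold difference k1/k2 between fast and slow components (>= 1)."""
    if params.k2 <= 0:
        raise ValueError("k2 must be > 0 to form a rate ratio")
    return params.k1 / params.k2


MODEL_EVALUATORS = {
    "mono": eval_mono_exp,
    "bi": eval_bi_exp,
    "lagged": eval_lagged_mono_exp,
}

PARAM_TYPES = {
    "mono": MonoExpParams,
    "bi": BiExpParams,
    "lagged": LaggedMonoExpParams,
}
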