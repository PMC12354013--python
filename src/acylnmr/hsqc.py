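"""Synthetic 2D 1H,13C-HSQC time series and window-projection extraction.

Spectra are already-processed absorptive matrices (real intensities on a
ppm grid); free-induction decays, Fourier transformation and phasing are
acquisition-side and out of scope.  Peaks are separable 2D Gaussians at
the catalog chemical shifts.  Reduction to a progress curve follows the
window-projection protocol: pick a narrow F2 (1H) column window around
the product resonance, form a skyline (max) projection over 13C for each
experiment, take its maximum as that experiment's intensity, and drop
experiment 1 (pre-initiation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.typing import NDArray

from . import constants as C
from .models import LaggedMonoExpParams, ProgressCurve
from .simulate import AcquisitionSchedule, SiteRateProfile, aggregate_curve

_GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class AxisMeta:
    """One spectral axis on a linear ppm grid, downfield (high ppm) left."""

    n_points: int
    sweep_width: float
    center: float
    nucleus: str = "1H"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.sweep_width <= 0:
            raise ValueError("sweep_width must be > 0")

    @property
    def ppm_grid(self) -> NDArray[np.float64]:
        """ppm value of each index; decreasing (index 0 is the downfield edge)."""
        edge = self.center + self.sweep_width / 2.0
        return edge - self.sweep_width * np.arange(self.n_points) / self.n_points

    @property
    def ppm_range(self) -> tuple[float, float]:
        g = self.ppm_grid
        return float(g[-1]), float(g[0])


def default_h_axis() -> AxisMeta:
    """1024-point 1H axis, 9.8 ppm sweep centered at 4.69 ppm."""
    return AxisMeta(n_points=1024, sweep_width=9.8, center=4.69, nucleus="1H")


def default_c_axis() -> AxisMeta:
    """64-point 13C axis, 70 ppm sweep centered at 35 ppm (all catalog shifts on-grid)."""
    return AxisMeta(n_points=64, sweep_width=70.0, center=35.0, nucleus="13C")


@dataclass(frozen=True)
class Resonance:
    """One cross peak: 1H/13C position, Gaussian FWHM widths, and its role.

    intensity_role controls how the peak evolves through a time series:
    product peaks follow the kinetic signal, cofactor peaks decay by
    conservation, byproduct and static peaks stay constant.
    """

    name: str
    h_ppm: float
    c_ppm: float
    h_width: float = 0.03
    c_width: float = 0.6
    intensity_role: str = "static"

    def __post_init__(self) -> None:
        if self.h_width <= 0 or self.c_width <= 0:
            raise ValueError("peak widths must be > 0")
        if self.intensity_role not in ("product", "cofactor", "byproduct", "static"):
            raise ValueError(f"unknown intensity_role '{self.intensity_role}'")


@dataclass
class Spectrum2D:
    """Real-valued 2D spectrum, matrix indexed [13C row][1H column]."""

    matrix: NDArray[np.float64]
    h_axis: AxisMeta
    c_axis: AxisMeta
    experiment_index: int = 0
    timestamp: float = 0.0
    pre_initiation: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.c_axis.n_points, self.h_axis.n_points):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match axes "
                f"({self.c_axis.n_points}, {self.h_axis.n_points})"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains non-finite values")


@dataclass(frozen=True)
class WindowSpec:
    """F2 (1H) ppm window bounds for column selection."""

    h_lo: float
    h_hi: float
    #: Raw processing-software index bounds, metadata only.
    raw_indices: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.h_lo < self.h_hi:
            raise ValueError("require h_lo < h_hi")


AC_WINDOW = WindowSpec(*C.AC_WINDOW_PPM, raw_indices=C.AC_WINDOW_INDICES)
PR_WINDOW = WindowSpec(*C.PR_WINDOW_PPM, raw_indices=C.PR_WINDOW_INDICES)


def acetylation_catalog() -> list[Resonance]:
    """Resonances visible in a 13C-acetylation time course."""
    return [
        Resonance("acetyllysine", *C.ACETYLLYSINE, intensity_role="product"),
        Resonance("acetyl-CoA", *C.ACETYL_COA, intensity_role="cofactor"),
    ]


def propionylation_catalog() -> list[Resonance]:
    """Resonances visible in a 13C-propionylation time course."""
    return [
        Resonance("propionyllysine-CH3", *C.PROPIONYLLYSINE, intensity_role="product"),
        Resonance("propionyllysine-CH2", *C.PROPIONYLLYSINE_METHYLENE, intensity_role="product"),
        Resonance("propionyl-CoA-CH3", *C.PROPIONYL_COA_METHYL, intensity_role="cofactor"),
        Resonance("propionyl-CoA-CH2", *C.PROPIONYL_COA_METHYLENE, intensity_role="cofactor"),
        Resonance("propionate-CH3", *C.PROPIONATE_METHYL, intensity_role="byproduct"),
        Resonance("propionate-CH2", *C.PROPIONATE_METHYLENE, intensity_role="byproduct"),
    ]


# ---------------------------------------------------------------------------
# axis mapping


def ppm_to_index(axis: AxisMeta, ppm: float) -> int:
    """Nearest grid index for a ppm value; index 0 at the downfield edge."""
    lo, hi = axis.ppm_range
    half_step = axis.sweep_width / axis.n_points / 2.0
    if ppm < lo - half_step or ppm > hi + half_step:
        raise ValueError(
            f"{ppm} ppm is outside the {axis.nucleus} axis range [{lo:.3f}, {hi:.3f}]"
        )
    edge = axis.center + axis.sweep_width / 2.0
    idx = round((edge - ppm) * axis.n_points / axis.sweep_width)
    return int(np.clip(idx, 0, axis.n_points - 1))


def index_to_ppm(axis: AxisMeta, index: int) -> float:
    """ppm value at a grid index (inverse of ppm_to_index on the grid)."""
    if not 0 <= index < axis.n_points:
        raise ValueError(f"index {index} out of range for {axis.nucleus} axis")
    return float(axis.ppm_grid[index])


# ---------------------------------------------------------------------------
# synthesis


def synthesize_spectrum(
    resonances: list[Resonance],
    intensities: list[float],
    h_axis: AxisMeta,
    c_axis: AxisMeta,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    experiment_index: int = 0,
    timestamp: float = 0.0,
) -> Spectrum2D:
    """Sum of separable 2D Gaussian peaks with given peak heights.

    Each resonance contributes intensity * exp(-((h-h0)/sh)^2/2) *
    exp(-((c-c0)/sc)^2/2) with sigmas derived from the FWHM widths, so
    the on-grid maximum equals the supplied intensity (up to grid
    quantization).  Optional additive Gaussian grid noise.
    """
    if len(resonances) != len(intensities):
        raise ValueError("resonances and intensities lengths differ")
    h_grid = h_axis.ppm_grid
    c_grid = c_axis.ppm_grid
    mat = np.zeros((c_axis.n_points, h_axis.n_points))
    for res, amp in zip(resonances, intensities):
        # validate position on both axes (raises if off-grid)
        ppm_to_index(h_axis, res.h_ppm)
        ppm_to_index(c_axis, res.c_ppm)
        if amp == 0:
            continue
        sh = res.h_width / _GAUSS_FWHM
        sc = res.c_width / _GAUSS_FWHM
        gh = np.exp(-0.5 * ((h_grid - res.h_ppm) / sh) ** 2)
        gc = np.exp(-0.5 * ((c_grid - res.c_ppm) / sc) ** 2)
        mat += amp * np.outer(gc, gh)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        mat += rng.normal(0.0, noise_sigma, size=mat.shape)
    return Spectrum2D(
        matrix=mat, h_axis=h_axis, c_axis=c_axis,
        experiment_index=experiment_index, timestamp=timestamp,
    )


def synthesize_timeseries(
    profile: SiteRateProfile,
    catalog: list[Resonance],
    schedule: AcquisitionSchedule,
    h_axis: AxisMeta | None = None,
    c_axis: AxisMeta | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    cofactor_initial: float | None = None,
    gate: LaggedMonoExpParams | None = None,
    include_pre_initiation: bool = True,
) -> list[Spectrum2D]:
    """Serial HSQC series following the multisite kinetics.

    Product resonances track the aggregate occupancy signal at each
    schedule time (optionally gated by a lag phase); cofactor resonances
    decay by conservation, (initial - transferred)/initial, when
    cofactor_initial is given (units of per-site amplitude; defaults to
    2 equivalents per site), and byproduct/static peaks stay constant at
    unit height.  Experiment 1 is emitted first as a pre-initiation
    spectrum with all product peaks absent and flagged as such.
    """
    h_axis = h_axis or default_h_axis()
    c_axis = c_axis or default_c_axis()
    if cofactor_initial is None:
        cofactor_initial = 2.0 * profile.n_sites * profile.per_site_amplitude
    rng = np.random.default_rng(seed)
    curve = aggregate_curve(profile, schedule, gate=gate)
    spectra: list[Spectrum2D] = []

    def peak_heights(product_signal: float) -> list[float]:
        heights = []
        for res in catalog:
            if res.intensity_role == "product":
                heights.append(product_signal)
            elif res.intensity_role == "cofactor":
                transferred = min(product_signal, cofactor_initial)
                heights.append(
                    cofactor_initial and (cofactor_initial - transferred) / cofactor_initial
                )
            else:
                heights.append(1.0)
        return heights

    if include_pre_initiation:
        spec = synthesize_spectrum(
            catalog, peak_heights(0.0), h_axis, c_axis,
            noise_sigma=noise_sigma, rng=rng, experiment_index=1, timestamp=0.0,
        )
        spec.pre_initiation = True
        spectra.append(spec)
    for i, (t, signal) in enumerate(zip(curve.times, curve.intensities)):
        spectra.append(
            synthesize_spectrum(
                catalog, peak_heights(float(signal)), h_axis, c_axis,
                noise_sigma=noise_sigma, rng=rng,
                experiment_index=i + 2, timestamp=float(t),
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# extraction


def window_columns(h_axis: AxisMeta, window: WindowSpec) -> NDArray[np.intp]:
    grid = h_axis.ppm_grid
    cols = np.nonzero((grid >= window.h_lo) & (grid <= window.h_hi))[0]
    if len(cols) == 0:
        raise ValueError(
            f"window [{window.h_lo}, {window.h_hi}] ppm selects no 1H columns"
        )
    return cols


def extract_window_projection(
    spectrum: Spectrum2D, window: WindowSpec, mode: str = "max"
) -> NDArray[np.float64]:
    """1D trace over 13C from an F2 column window.

    mode "max" is a skyline projection (per 13C row, the maximum over the
    window's 1H columns); "sum" sums the columns instead.
    """
    cols = window_columns(spectrum.h_axis, window)
    sub = spectrum.matrix[:, cols]
    if mode == "max":
        return sub.max(axis=1)
    if mode == "sum":
        return sub.sum(axis=1)
    raise ValueError(f"unknown projection mode '{mode}'")


def extract_intensity_series(
    series: list[Spectrum2D],
    window: WindowSpec,
    schedule: AcquisitionSchedule,
    mode: str = "max",
    label: str = "",
) -> ProgressCurve:
    """Reduce a spectrum series to a progress curve.

    Per experiment, the maximum of the window projection.  A leading
    pre-initiation spectrum (experiment 1) is dropped; the remaining
    experiments must match the schedule length, and times come from the
    schedule.
    """
    post = [s for s in series if not s.pre_initiation]
    if len(post) != schedule.n_experiments:
        raise ValueError(
            f"series has {len(post)} post-initiation spectra but the schedule "
            f"expects {schedule.n_experiments}"
        )
    intensities = [float(extract_window_projection(s, window, mode=mode).max()) for s in post]
    return ProgressCurve(
        times=schedule.times(),
        intensities=np.asarray(intensities),
        label=label,
        deadtime=schedule.deadtime,
        experiment_length=schedule.experiment_length,
    )


# ---------------------------------------------------------------------------
# persistence: JSON sidecar + one text matrix per experiment


def save_series(series: list[Spectrum2D], directory: str | Path, meta: dict | None = None) -> None:
    """Persist a series as sidecar.json plus experiment_<i>.txt matrices."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "h_axis": asdict(series[0].h_axis),
        "c_axis": asdict(series[0].c_axis),
        "experiments": [
            {
                "experiment_index": s.experiment_index,
                "timestamp": s.timestamp,
                "pre_initiation": s.pre_initiation,
                "file": f"experiment_{s.experiment_index:04d}.txt",
            }
            for s in series
        ],
        "meta": meta or {},
    }
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    for s in series:
        np.savetxt(directory / f"experiment_{s.experiment_index:04d}.txt", s.matrix)


def load_series(directory: str | Path) -> list[Spectrum2D]:
    """Load a series persisted by save_series."""
    directory = Path(directory)
    sidecar = json.loads((directory / "sidecar.json").read_text())
    h_axis = AxisMeta(**sidecar["h_axis"])
    c_axis = AxisMeta(**sidecar["c_axis"])
    series = []
    for exp in sidecar["experiments"]:
        mat = np.loadtxt(directory / exp["file"])
        series.append(
            Spectrum2D(
                matrix=mat.reshape(c_axis.n_points, h_axis.n_points),
                h_axis=h_axis, c_axis=c_axis,
                experiment_index=exp["experiment_index"],
                timestamp=exp["timestamp"],
                pre_initiation=exp["pre_initiation"],
            )
        )
    return series
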