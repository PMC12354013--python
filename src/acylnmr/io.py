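"""File I/O for progress curves, peak lists, and fit reports.

Progress curves are two-column delimited text (time_min, intensity) with
`#`-prefixed comment headers carrying metadata as key=value pairs; peak
lists are two-column (m/z, intensity) text in the same style.  Fit and
selection reports serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .fitting import DiagnosticsReport, FitResult, ModelSelectionResult
from .maldi import PeakList
from .models import ProgressCurve


def write_progress_curve(curve: ProgressCurve, path: str | Path) -> None:
    """Write a curve as commented two-column text; lossless round-trip."""
    path = Path(path)
    lines = []
    if curve.label:
        lines.append(f"# label={curve.label}")
    if curve.deadtime is not None:
        lines.append(f"# deadtime={curve.deadtime!r}")
    if curve.experiment_length is not None:
        lines.append(f"# experiment_length={curve.experiment_length!r}")
    for k, v in curve.meta.items():
        lines.append(f"# {k}={v}")
    lines.append("# time_min\tintensity")
    for t, y in zip(curve.times, curve.intensities):
        lines.append(f"{float(t)!r}\t{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_progress_curve(path: str | Path) -> ProgressCurve:
    """Read a curve written by write_progress_curve (or any 2-column text)."""
    path = Path(path)
    label = ""
    deadtime = None
    experiment_length = None
    meta: dict = {}
    times, intensities = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                key = key.strip()
                val = val.strip()
                if key == "label":
                    label = val
                elif key == "deadtime":
                    deadtime = float(val)
                elif key == "experiment_length":
                    experiment_length = float(val)
                else:
                    meta[key] = val
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not times:
        raise ValueError(f"{path}: no data rows (header-only or empty file)")
    return ProgressCurve(
        times=np.asarray(times),
        intensities=np.asarray(intensities),
        label=label,
        deadtime=deadtime,
        experiment_length=experiment_length,
        meta=meta,
    )


def write_peaklist(peaks: PeakList, path: str | Path, header: dict | None = None) -> None:
    """Write an m/z-intensity list as commented two-column text."""
    lines = [f"# {k}={v}" for k, v in (header or {}).items()]
    lines.append("# mz\tintensity")
    for mz, inten in zip(peaks.mz, peaks.intensity):
        lines.append(f"{float(mz)!r}\t{float(inten)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaklist(path: str | Path) -> PeakList:
    """Read a two-column (whitespace or comma) m/z-intensity text file."""
    mz, inten = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        mz.append(float(parts[0]))
        inten.append(float(parts[1]))
    if not mz:
        raise ValueError(f"{path}: no data rows")
    return PeakList(mz=np.asarray(mz), intensity=np.asarray(inten))


def _params_dict(params) -> dict:
    if isinstance(params, dict):
        return dict(params)
    return dataclasses.asdict(params)


def fit_report_dict(fit: FitResult, diagnostics: DiagnosticsReport | None = None) -> dict:
    """JSON-ready report of one fit."""
    out = {
        "model_id": fit.model_id,
        "params": _params_dict(fit.params),
        "r_squared": fit.r_squared,
        "aic_c": fit.aic_c,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }
    if diagnostics is not None:
        out["diagnostics"] = dataclasses.asdict(diagnostics)
    return out


def selection_report_dict(selection: ModelSelectionResult) -> dict:
    """JSON-ready report of a model-selection run."""
    return {
        "chosen": selection.chosen,
        "fits": {mid: fit_report_dict(f) for mid, f in selection.fits.items()},
        "rationale": selection.rationale,
    }


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, default=float) + "\n")


def fit_report_table(fit: FitResult) -> str:
    """Plain-text one-fit summary table."""
    rows = [("model", fit.model_id), ("R^2", f"{fit.r_squared:.6f}"),
            ("AICc", f"{fit.aic_c:.3f}"), ("converged", str(fit.converged))]
    rows += [(k, f"{v:.6g}") for k, v in _params_dict(fit.params).items()]
    width = max(len(k) for k, _ in rows)
    return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def compute_cofactor_equivalents(
    n_lysines: int, substrate_conc: float, equivalents_per_lysine: float = 2.0
) -> float:
    """Cofactor concentration for a target molar excess per lysine.

    Returns n_lysines * equivalents_per_lysine * substrate_conc in the
    units of substrate_conc (e.g. 5 lysines x 2 eq x 500 uM = 5000 uM).
    """
    if n_lysines <= 0 or substrate_conc <= 0 or equivalents_per_lysine <= 0:
        raise ValueError("all inputs must be > 0")
    return n_lysines * equivalents_per_lysine * substrate_conc
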