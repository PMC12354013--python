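"""Peptide mass arithmetic and MALDI acylation-state ladders.

A MALDI-TOF spectrum of an acylation reaction shows a ladder of [M+H]+
peaks spaced by the acyl mass shift, one per modification state j
(0..n_lysines).  Under uniform ionization efficiency the relative peak
intensities report the acylation-state distribution, which the multisite
kinetic model predicts as a Poisson-binomial.  Peaks are monoisotopic
sticks (the upstream peak picking deconvolutes isotopologue envelopes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from pyteomics import mass as _pymass

from .constants import (
    ACETYL_SHIFT,
    C13_DELTA,
    H4_TAIL_SEQUENCE,
    LABELED_CARBONS,
    PROPIONYL_SHIFT,
    PROTON_MASS,
)
from .simulate import SiteRateProfile, state_distribution

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideSpec:
    """Substrate peptide; defaults to the H4(1-25)W tail construct."""

    sequence: str = H4_TAIL_SEQUENCE

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(f"unknown residue letters: {sorted(bad)}")

    @property
    def n_lysines(self) -> int:
        return self.sequence.count("K")


@dataclass(frozen=True)
class AcylSpec:
    """Acyl modification chemistry: type, isotopic labeling, mass shift."""

    acyl_type: str = "acetyl"
    isotope: str = "natural"

    def __post_init__(self) -> None:
        if self.acyl_type not in ("acetyl", "propionyl"):
            raise ValueError(f"unknown acyl_type '{self.acyl_type}'")
        if self.isotope not in ("natural", "13C"):
            raise ValueError(f"unknown isotope '{self.isotope}'")

    @property
    def mass_shift(self) -> float:
        return acyl_mass_shift(self)


@dataclass
class PeakList:
    """m/z (Da, strictly increasing) and intensity (a.u.) columns."""

    mz: NDArray[np.float64]
    intensity: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be > 0")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.mz)


def peptide_monoisotopic_mass(spec: PeptideSpec, protonated: bool = False) -> float:
    """Monoisotopic mass in Da (residue masses + water); [M+H]+ adds a proton."""
    m = _pymass.fast_mass(spec.sequence)
    return m + PROTON_MASS if protonated else m


def acyl_mass_shift(acyl: AcylSpec) -> float:
    """Mass added per modified lysine, in Da.

    Natural acetyl adds CH2CO (42.01057), propionyl C2H4CO (56.02621).
    13C labeling adds one 13C-12C mass excess per labeled carbon
    transferred: 2 for acetyl (from 1,1',2,2'-13C acetic anhydride),
    3 for propionyl (from 13C6 propionic anhydride).
    """
    base = ACETYL_SHIFT if acyl.acyl_type == "acetyl" else PROPIONYL_SHIFT
    if acyl.isotope == "13C":
        base += LABELED_CARBONS[acyl.acyl_type] * C13_DELTA
    return base


def state_masses(peptide: PeptideSpec, acyl: AcylSpec, n_states: int | None = None) -> NDArray[np.float64]:
    """[M+H]+ masses of the 0..n acylation states (the ladder positions)."""
    n = peptide.n_lysines if n_states is None else n_states - 1
    base = peptide_monoisotopic_mass(peptide, protonated=True)
    return base + acyl.mass_shift * np.arange(n + 1)


def state_peaklist(
    profile: SiteRateProfile, t: float, peptide: PeptideSpec, acyl: AcylSpec
) -> PeakList:
    """Synthetic stick spectrum at time t.

    One peak per acylation state j at [M+H]+ + j*mass_shift with
    intensity equal to the Poisson-binomial state probability; the
    intensities sum to 1.
    """
    if profile.n_sites != peptide.n_lysines:
        raise ValueError(
            f"profile has {profile.n_sites} sites but peptide has "
            f"{peptide.n_lysines} lysines"
        )
    dist = state_distribution(profile, t)
    return PeakList(mz=state_masses(peptide, acyl), intensity=dist.probs)


def call_states(
    peaks: PeakList,
    peptide: PeptideSpec,
    acyl: AcylSpec,
    tolerance_da: float = 0.25,
) -> tuple[NDArray[np.float64], float]:
    """Assign observed peaks to acylation states.

    Each peak goes to the nearest ladder mass if within tolerance_da;
    returns per-state intensity fractions (normalized to total assigned
    intensity) and the unassigned intensity fraction of the total.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be > 0")
    if 2 * tolerance_da >= acyl.mass_shift:
        raise ValueError(
            f"tolerance {tolerance_da} Da makes adjacent state windows overlap "
            f"(shift {acyl.mass_shift:.5f} Da)"
        )
    ladder = state_masses(peptide, acyl)
    fractions = np.zeros(len(ladder))
    unassigned = 0.0
    for mz, inten in zip(peaks.mz, peaks.intensity):
        j = int(np.argmin(np.abs(ladder - mz)))
        if abs(ladder[j] - mz) <= tolerance_da:
            fractions[j] += inten
        else:
            unassigned += inten
    total = peaks.intensity.sum()
    assigned = fractions.sum()
    if assigned > 0:
        fractions /= assigned
    return fractions, (unassigned / total if total > 0 else 0.0)


def mean_called_state(fractions: NDArray[np.float64]) -> float:
    """Average number of acyl marks per peptide implied by state fractions."""
    return float(np.arange(len(fractions)) @ fractions)
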