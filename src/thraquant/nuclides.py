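"""Emission data and decay math for the ²²⁷Th → ²²³Ra chain.

²²⁷Th (half-life 18.7 d) decays to ²²³Ra (11.4 d), whose own daughters
(²¹⁹Rn, ²¹⁵Po, ²¹¹Pb, ²¹¹Bi, ²⁰⁷Tl) all have half-lives of minutes or less
and are therefore treated as in secular equilibrium with ²²³Ra on imaging
timescales.  Photon lines of the daughters are folded into a single
``Ra223chain`` spectrum; ``Th227`` carries only the parent's lines.

Activities follow the two-member Bateman solution

    A_Th(t) = A_Th(0) · exp(−λ_Th t)
    A_Ra(t) = A_Th(0) · λ_Ra/(λ_Ra−λ_Th) · (exp(−λ_Th t) − exp(−λ_Ra t))
              + A_Ra(0) · exp(−λ_Ra t)

with decay constants λ = ln 2 / T½ in days⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EmissionLine",
    "NuclideSpectrum",
    "DecayParameters",
    "ActivityPair",
    "emission_lines",
    "bateman_activities",
    "cumulated_activity",
]

#: Half-lives in days.
HALF_LIFE_TH227 = 18.7
HALF_LIFE_RA223 = 11.4

#: Nuclides aggregated into the Ra-223 equilibrium group.
_RA_CHAIN_MEMBERS = ("Ra223", "Rn219", "Po215", "Pb211", "Bi211", "Tl207")


@dataclass(frozen=True)
class EmissionLine:
    """A single γ/x-ray line: energy in keV, intensity in photons per decay."""

    energy: float
    intensity: float

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError(f"line energy must be positive, got {self.energy}")
        if not (0 < self.intensity <= 1):
            raise ValueError(
                f"line intensity must be in (0, 1], got {self.intensity}"
            )


@dataclass(frozen=True)
class NuclideSpectrum:
    """Photon emission spectrum of a nuclide group."""

    label: str
    lines: tuple[EmissionLine, ...]

    def energies(self) -> np.ndarray:
        return np.array([l.energy for l in self.lines])

    def intensities(self) -> np.ndarray:
        return np.array([l.intensity for l in self.lines])


@dataclass(frozen=True)
class DecayParameters:
    """Half-lives (days) and derived decay constants (per day)."""

    half_life_Th227: float = HALF_LIFE_TH227
    half_life_Ra223: float = HALF_LIFE_RA223

    @property
    def lambda_Th(self) -> float:
        return math.log(2.0) / self.half_life_Th227

    @property
    def lambda_Ra(self) -> float:
        return math.log(2.0) / self.half_life_Ra223


@dataclass(frozen=True)
class ActivityPair:
    """Activities of the two isotopes (MBq) at a time (days since reference)."""

    A_Th227: float
    A_Ra223: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.A_Th227 < 0 or self.A_Ra223 < 0:
            raise ValueError("activities must be nonnegative")


def _load_line_table(path: Path | None = None) -> dict[str, list[EmissionLine]]:
    """Read the bundled (or user-supplied) nuclide line table."""
    if path is None:
        ref = resources.files("thraquant.data") / "emission_lines.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, list[EmissionLine]] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        nuclide, energy, intensity = line.split("\t")
        table.setdefault(nuclide, []).append(
            EmissionLine(float(energy), float(intensity))
        )
    return table


def emission_lines(label: str, table_path: Path | None = None) -> NuclideSpectrum:
    """Return the photon spectrum of a nuclide group.

    Parameters
    ----------
    label
        ``"Th227"`` for the parent alone, or ``"Ra223chain"`` for ²²³Ra plus
        its short-lived daughters in secular equilibrium (branching taken as
        unity along the main chain).
    table_path
        Optional override of the bundled line table (same tab-separated
        ``nuclide energy_keV intensity`` layout).
    """
    table = _load_line_table(table_path)
    if label == "Th227":
        lines = table.get("Th227", [])
    elif label == "Ra223chain":
        lines = [l for m in _RA_CHAIN_MEMBERS for l in table.get(m, [])]
    else:
        raise ValueError(
            f"unknown nuclide label {label!r}; expected 'Th227' or 'Ra223chain'"
        )
    lines = sorted(lines, key=lambda l: l.energy)
    return NuclideSpectrum(label=label, lines=tuple(lines))


def bateman_activities(
    initial: ActivityPair,
    t: float,
    decay: DecayParameters = DecayParameters(),
) -> ActivityPair:
    """Evolve a (²²⁷Th, ²²³Ra) activity pair forward by ``t`` days.

    Uses the closed-form Bateman solution for a two-member chain; the
    daughter term combines ingrowth from the parent with decay of any
    initial daughter activity.
    """
    if t < 0:
        raise ValueError(f"elapsed time must be nonnegative, got {t}")
    lam_th, lam_ra = decay.lambda_Th, decay.lambda_Ra
    a_th = initial.A_Th227 * math.exp(-lam_th * t)
    ingrowth = (
        initial.A_Th227
        * lam_ra
        / (lam_ra - lam_th)
        * (math.exp(-lam_th * t) - math.exp(-lam_ra * t))
    )
    a_ra = ingrowth + initial.A_Ra223 * math.exp(-lam_ra * t)
    return ActivityPair(A_Th227=a_th, A_Ra223=a_ra, time=initial.time + t)


def cumulated_activity(times, activities) -> float:
    """Trapezoid-rule integral of a sampled time–activity curve (MBq·days).

    No extrapolation is performed beyond the first or last sample.
    """
    times = np.asarray(times, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if times.ndim != 1 or times.shape != activities.shape:
        raise ValueError("times and activities must be 1-D arrays of equal length")
    if times.size < 2:
        raise ValueError("need at least two samples to integrate")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(activities, times))
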