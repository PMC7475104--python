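"""Scatter-component spectra and their empirical per-window adaptation.

The unmixing model treats scattered photons as a fixed spectral *shape*
per isotope, scaled by a free coefficient ``B`` times the isotope
activity.  Shapes can come from two places:

* :func:`load_scatter_basis` — externally tabulated spectra (e.g. Monte
  Carlo output of the acquisition geometry) resampled onto the standard
  energy grid;
* :func:`parametric_scatter` — a bundled analytic stand-in built from
  single-Compton-scatter kinematics: for each emission line the
  Klein–Nishina scattered-photon energy distribution between the
  backscatter limit E₀/(1+2E₀/511) and E₀, weighted by the line
  intensity and a thickness-dependent scatter fraction, then blurred
  with the detector energy resolution.

Because real acquisition geometries deviate from any fixed shape, a set
of per-isotope, per-window multipliers ν adapts the shape's window
integrals; :func:`calibrate_nu` recovers them from measurements with
known activities (parent-dominant data first, daughter-dominant data
second, alternated to a fixed point).

Scatter shapes are normalized to unit integral: absolute scale lives
entirely in the fitted product B·A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import (
    ComponentSpectrum,
    DetectorSpec,
    EnergyWindow,
    STANDARD_WINDOWS,
    _FWHM_TO_SIGMA,
    energy_grid,
    energy_resolution,
    window_integral,
)
from .nuclides import NuclideSpectrum

__all__ = [
    "ScatterSpectrum",
    "ScatterCoefficients",
    "load_scatter_basis",
    "parametric_scatter",
    "scatter_window_integrals",
    "calibrate_nu",
]

_ELECTRON_REST_KEV = 511.0
#: Electron density of water, cm⁻³.
_NE_WATER = 3.343e23


@dataclass
class ScatterSpectrum(ComponentSpectrum):
    """Relative scatter count density on the standard grid (unit integral)."""

    isotope: str = ""
    provenance: str = "parametric"  # or "external"
    reference_thickness: float | None = None

    def normalized(self) -> "ScatterSpectrum":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero scatter spectrum")
        return ScatterSpectrum(
            grid=self.grid,
            values=self.values / total,
            label=self.label,
            isotope=self.isotope,
            provenance=self.provenance,
            reference_thickness=self.reference_thickness,
        )


@dataclass
class ScatterCoefficients:
    """Per-isotope, per-window multipliers ν adapting a scatter shape.

    Keys are isotope labels ("Th227", "Ra223chain"); each maps to one
    multiplier per acquisition window, in window order.  Defaults to 1.
    """

    nu: dict[str, np.ndarray] = field(default_factory=dict)
    windows: tuple[EnergyWindow, ...] = STANDARD_WINDOWS
    reference_thickness: float | None = None

    def for_isotope(self, isotope: str) -> np.ndarray:
        if isotope in self.nu:
            return np.asarray(self.nu[isotope], dtype=float)
        return np.ones(len(self.windows))

    def set(self, isotope: str, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.windows),):
            raise ValueError("need one coefficient per window")
        if np.any(values <= 0):
            raise ValueError("nu coefficients must be positive")
        self.nu[isotope] = values

    def to_dict(self) -> dict:
        return {
            "reference_thickness_mm": None
            if self.reference_thickness is None
            else 10.0 * self.reference_thickness,
            "windows": [str(w) for w in self.windows],
            "nu": {k: list(map(float, v)) for k, v in self.nu.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScatterCoefficients":
        windows = tuple(
            EnergyWindow(*map(float, w.split("-"))) for w in d.get("windows", [])
        ) or STANDARD_WINDOWS
        ref = d.get("reference_thickness_mm")
        out = cls(
            windows=windows,
            reference_thickness=None if ref is None else ref / 10.0,
        )
        for iso, vals in d.get("nu", {}).items():
            out.set(iso, vals)
        return out


def load_scatter_basis(
    energies,
    values,
    isotope: str,
    reference_thickness: float | None = None,
) -> ScatterSpectrum:
    """Resample a tabulated (energy, relative counts) spectrum onto the
    standard grid by linear interpolation; zero outside the input range."""
    energies = np.asarray(energies, dtype=float)
    values = np.asarray(values, dtype=float)
    if energies.ndim != 1 or energies.shape != values.shape:
        raise ValueError("energies and values must be 1-D of equal length")
    if np.any(np.diff(energies) <= 0):
        raise ValueError("energies must be strictly ascending")
    if np.any(values < 0):
        raise ValueError("scatter values must be nonnegative")
    grid = energy_grid()
    resampled = np.interp(grid, energies, values, left=0.0, right=0.0)
    return ScatterSpectrum(
        grid=grid,
        values=resampled,
        label=f"S_{isotope}",
        isotope=isotope,
        provenance="external",
        reference_thickness=reference_thickness,
    )


def _klein_nishina_energy_pdf(E0: float, E_sc: np.ndarray) -> np.ndarray:
    """Unnormalized Klein–Nishina distribution of the scattered-photon
    energy E_sc for incident energy E0 (both keV)."""
    alpha = E0 / _ELECTRON_REST_KEV
    rho = E_sc / E0  # fraction of incident energy kept by the photon
    out = np.zeros_like(E_sc)
    valid = (rho >= 1.0 / (1.0 + 2.0 * alpha)) & (rho <= 1.0)
    r = rho[valid]
    cos_theta = 1.0 - (1.0 / r - 1.0) / alpha
    sin2 = 1.0 - cos_theta**2
    out[valid] = r + 1.0 / r - sin2
    return out


def _sigma_kn_total(E0: float) -> float:
    """Total Klein–Nishina cross-section per electron (cm²)."""
    a = E0 / _ELECTRON_REST_KEV
    r0 = 2.8179403e-13
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return float(2 * np.pi * r0**2 * (t1 + t2 + t3))


def compton_mu(E0: float) -> float:
    """Incoherent (Compton) linear attenuation coefficient of water, cm⁻¹."""
    return _NE_WATER * _sigma_kn_total(E0)


def parametric_scatter(
    spec: NuclideSpectrum,
    x: float,
    det: DetectorSpec | None = None,
    low_energy_cutoff: float = 20.0,
) -> ScatterSpectrum:
    """Single-Compton-scatter stand-in for a Monte Carlo scatter spectrum.

    Each line contributes a Klein–Nishina continuum weighted by its
    intensity and the water scatter fraction 1−exp(−μ_C(E₀)·x/2); the sum
    is blurred by the detector resolution and normalized to unit integral
    (shape only — absolute scale is fitted downstream).
    """
    if x <= 0:
        raise ValueError("thickness must be positive for a scatter spectrum")
    if det is None:
        det = DetectorSpec()
    grid = energy_grid()
    raw = np.zeros_like(grid)
    for line in spec.lines:
        E0 = line.energy
        if E0 < low_energy_cutoff:
            continue
        pdf = _klein_nishina_energy_pdf(E0, grid)
        total = pdf.sum()
        if total <= 0:
            continue
        scatter_fraction = 1.0 - np.exp(-compton_mu(E0) * x / 2.0)
        raw += line.intensity * scatter_fraction * pdf / total
    # blur: convolve with an energy-dependent Gaussian, column-normalized so
    # the blur redistributes but never creates counts
    blurred = np.zeros_like(raw)
    for j, (Ej, w) in enumerate(zip(grid, raw)):
        if w <= 0:
            continue
        sigma = float(energy_resolution(det, Ej)) * _FWHM_TO_SIGMA
        kernel = np.exp(-0.5 * ((grid - Ej) / sigma) ** 2)
        blurred += w * kernel / kernel.sum()
    blurred[grid < low_energy_cutoff] = 0.0
    return ScatterSpectrum(
        grid=grid,
        values=blurred,
        label=f"S_{spec.label}",
        isotope=spec.label,
        provenance="parametric",
        reference_thickness=x,
    ).normalized()


def scatter_window_integrals(
    S: ScatterSpectrum,
    nu: ScatterCoefficients,
    windows: tuple[EnergyWindow, ...] = STANDARD_WINDOWS,
) -> np.ndarray:
    """Per-window ν-scaled integrals ν_j · ∫_j S dE."""
    coeffs = nu.for_isotope(S.isotope)
    if coeffs.shape != (len(windows),):
        raise ValueError("nu coefficients do not match the window set")
    plain = np.array([window_integral(S, w) for w in windows])
    return coeffs * plain


def calibrate_nu(
    parent_dominant,
    daughter_dominant,
    components,
    B: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-12,
):
    """Recover per-window ν from measurements with known activities.

    Parameters
    ----------
    parent_dominant, daughter_dominant
        Each a tuple ``(measured_counts, duration, (A_Th, A_Ra))`` with
        ``measured_counts`` the 4 background-corrected geometric-mean
        window counts.  The first set should be acquired when the parent
        dominates (e.g. the day of filling), the second when the daughter
        has grown in.
    components
        A :class:`~thraquant.unmixing.SpectralComponents` holding primary
        and scatter window integrals at the calibration thickness.
    B
        Scatter scale assumed during calibration (the product B·ν is what
        the data determine; B is conventionally fixed to 1 here and
        re-fitted freely at quantification time).

    Returns
    -------
    ScatterCoefficients
        With entries for both isotopes.  Windows whose scatter-shape
        integral is zero are reported with ν = 1.
    """
    p_th, p_ra = components.primary_Th, components.primary_Ra
    s_th, s_ra = components.scatter_Th, components.scatter_Ra
    n_win = len(components.windows)
    nu_th = np.ones(n_win)
    nu_ra = np.ones(n_win)

    def _solve_one(meas, dur, acts, own_s, own_a, other_term):
        # per-window: meas/dur = primaries + B*(own_a*nu*own_s + other_term)
        counts_rate = np.asarray(meas, dtype=float) / dur
        a_th, a_ra = acts
        primaries = a_th * p_th + a_ra * p_ra
        nu = np.ones(n_win)
        ok = (own_s > 0) & (own_a > 0)
        nu[ok] = (counts_rate[ok] - primaries[ok] - B * other_term[ok]) / (
            B * own_a * own_s[ok]
        )
        return np.clip(nu, 1e-9, None), ok

    undefined = np.zeros(n_win, dtype=bool)
    for _ in range(max_iter):
        prev = np.concatenate([nu_th, nu_ra])
        meas, dur, acts = parent_dominant
        nu_th, ok_th = _solve_one(
            meas, dur, acts, s_th, acts[0], acts[1] * nu_ra * s_ra
        )
        meas, dur, acts = daughter_dominant
        nu_ra, ok_ra = _solve_one(
            meas, dur, acts, s_ra, acts[1], acts[0] * nu_th * s_th
        )
        undefined = ~ok_th | ~ok_ra
        if np.max(np.abs(np.concatenate([nu_th, nu_ra]) - prev)) < tol:
            break

    out = ScatterCoefficients(
        windows=components.windows,
        reference_thickness=components.thickness,
    )
    out.set("Th227", nu_th)
    out.set("Ra223chain", nu_ra)
    return out
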