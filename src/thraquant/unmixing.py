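"""Spectral unmixing of dual-isotope window counts.

The measured, background-corrected geometric-mean counts in the four
acquisition windows are modeled per window j as

    m_j = T · [ A_Th·∫_j P_Th + A_Ra·∫_j P_Ra
                + B·( A_Th·ν_Th,j·∫_j S_Th + A_Ra·ν_Ra,j·∫_j S_Ra ) ]

with T the acquisition duration, P the primary (unscattered) component
spectra from the analytical camera model, S the unit-normalized scatter
shapes, ν the per-window scatter adaptation coefficients and B a free
scale tying scattered counts to activity.  The three parameters
(A_Th, A_Ra, B) are estimated by nonnegative least squares on the four
window equations.

The public surface follows the statsmodels idiom: build a
:class:`SpectralUnmixingModel` from a measurement and precomputed
:class:`SpectralComponents`, call :meth:`~SpectralUnmixingModel.fit`,
and read estimates off the returned :class:`UnmixingResults`.
:func:`solve_activities` and :func:`pixelwise_decompose` are thin
functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .camera import (
    AttenuationTable,
    CollimatorSpec,
    ComponentSpectrum,
    DetectorSpec,
    EnergyWindow,
    STANDARD_WINDOWS,
    primary_spectrum,
    window_integral,
)
from .nuclides import emission_lines
from .scatter import ScatterCoefficients, ScatterSpectrum, parametric_scatter

__all__ = [
    "ConjugateMeasurement",
    "ActivityEstimate",
    "SpectralComponents",
    "SpectralUnmixingModel",
    "UnmixingResults",
    "conjugate_geometric_mean",
    "model_window_counts",
    "solve_activities",
    "pixelwise_decompose",
]

logger = logging.getLogger(__name__)

_ZERO_SNAP = 1e-9


def conjugate_geometric_mean(ant, post):
    """√(anterior·posterior) counts; zero if either view is zero.

    Inputs must be nonnegative (clip background-corrected counts upstream).
    """
    ant = np.asarray(ant, dtype=float)
    post = np.asarray(post, dtype=float)
    if np.any(ant < 0) or np.any(post < 0):
        raise ValueError("counts must be nonnegative; clip before taking the mean")
    return np.sqrt(ant * post)


@dataclass
class ConjugateMeasurement:
    """Background-corrected anterior/posterior ROI counts in the four
    acquisition windows, with duration (s) and water-equivalent thickness
    (cm)."""

    window_counts_ant: np.ndarray
    window_counts_post: np.ndarray
    duration: float
    water_thickness: float
    roi_id: str = ""
    windows: tuple[EnergyWindow, ...] = STANDARD_WINDOWS

    def __post_init__(self) -> None:
        self.window_counts_ant = np.asarray(self.window_counts_ant, dtype=float)
        self.window_counts_post = np.asarray(self.window_counts_post, dtype=float)
        n = len(self.windows)
        if self.window_counts_ant.shape != (n,) or self.window_counts_post.shape != (n,):
            raise ValueError(f"need one anterior and one posterior count per window ({n})")
        if np.any(self.window_counts_ant < 0) or np.any(self.window_counts_post < 0):
            raise ValueError("window counts must be nonnegative (clip upstream)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def geometric_mean_counts(self) -> np.ndarray:
        return conjugate_geometric_mean(self.window_counts_ant, self.window_counts_post)

    @classmethod
    def from_geometric_mean(
        cls, gm_counts, duration, water_thickness, roi_id="", windows=STANDARD_WINDOWS
    ) -> "ConjugateMeasurement":
        """Build a measurement whose two views both equal the given
        geometric-mean counts (convenient for ROI-level data)."""
        gm = np.asarray(gm_counts, dtype=float)
        return cls(gm, gm.copy(), duration, water_thickness, roi_id, windows)


@dataclass(frozen=True)
class ActivityEstimate:
    """Fitted activities (MBq), scatter scale B, residual sum of squared
    count differences, and a convergence flag."""

    A_Th227: float
    A_Ra223: float
    B: float
    residual: float
    converged: bool = True

    def __iter__(self):
        return iter((self.A_Th227, self.A_Ra223, self.B))


@dataclass
class SpectralComponents:
    """Window integrals of the four component spectra at one thickness.

    ``primary_*`` are counts·s⁻¹·MBq⁻¹ per window; ``scatter_*`` are the
    (dimensionless) window integrals of the unit-normalized scatter
    shapes, already multiplied by their ν coefficients.
    """

    primary_Th: np.ndarray
    primary_Ra: np.ndarray
    scatter_Th: np.ndarray
    scatter_Ra: np.ndarray
    thickness: float
    windows: tuple[EnergyWindow, ...] = STANDARD_WINDOWS
    nu: ScatterCoefficients | None = None

    def with_nu(self, nu: ScatterCoefficients) -> "SpectralComponents":
        """Return a copy whose scatter integrals carry the given ν."""
        base_th = self.scatter_Th
        base_ra = self.scatter_Ra
        old_th = self.nu.for_isotope("Th227") if self.nu else np.ones(len(self.windows))
        old_ra = (
            self.nu.for_isotope("Ra223chain") if self.nu else np.ones(len(self.windows))
        )
        return SpectralComponents(
            primary_Th=self.primary_Th,
            primary_Ra=self.primary_Ra,
            scatter_Th=base_th / old_th * nu.for_isotope("Th227"),
            scatter_Ra=base_ra / old_ra * nu.for_isotope("Ra223chain"),
            thickness=self.thickness,
            windows=self.windows,
            nu=nu,
        )

    @classmethod
    def prepare(
        cls,
        thickness: float,
        coll: CollimatorSpec | None = None,
        det: DetectorSpec | None = None,
        att: AttenuationTable | None = None,
        scatter_Th: ScatterSpectrum | None = None,
        scatter_Ra: ScatterSpectrum | None = None,
        nu: ScatterCoefficients | None = None,
        windows: tuple[EnergyWindow, ...] = STANDARD_WINDOWS,
    ) -> "SpectralComponents":
        """Assemble component window integrals for a given thickness.

        Defaults: bundled nuclide data, Siemens-Intevo-HE camera preset,
        bundled water attenuation, parametric single-scatter shapes at the
        same thickness, ν ≡ 1.
        """
        coll = coll or CollimatorSpec()
        det = det or DetectorSpec()
        att = att or AttenuationTable.water()
        th = emission_lines("Th227")
        ra = emission_lines("Ra223chain")
        p_th = primary_spectrum(th, thickness, coll, det, att)
        p_ra = primary_spectrum(ra, thickness, coll, det, att)
        s_th = (scatter_Th or parametric_scatter(th, max(thickness, 1e-6), det)).normalized()
        s_ra = (scatter_Ra or parametric_scatter(ra, max(thickness, 1e-6), det)).normalized()
        nu = nu or ScatterCoefficients(windows=windows)
        nu_th = nu.for_isotope("Th227")
        nu_ra = nu.for_isotope("Ra223chain")
        return cls(
            primary_Th=np.array([window_integral(p_th, w) for w in windows]),
            primary_Ra=np.array([window_integral(p_ra, w) for w in windows]),
            scatter_Th=nu_th * np.array([window_integral(s_th, w) for w in windows]),
            scatter_Ra=nu_ra * np.array([window_integral(s_ra, w) for w in windows]),
            thickness=thickness,
            windows=windows,
            nu=nu,
        )


def model_window_counts(
    A_Th: float,
    A_Ra: float,
    B: float,
    duration: float,
    components: SpectralComponents,
) -> np.ndarray:
    """Forward-model the geometric-mean counts in each window."""
    c = components
    rate = (
        A_Th * c.primary_Th
        + A_Ra * c.primary_Ra
        + B * (A_Th * c.scatter_Th + A_Ra * c.scatter_Ra)
    )
    return duration * rate


class SpectralUnmixingModel:
    """Nonnegative least-squares unmixing of one conjugate measurement.

    Parameters
    ----------
    measurement
        Background-corrected window counts with duration and thickness.
    components
        Precomputed component window integrals; must match the
        measurement's thickness (checked loosely).
    weighted
        If True, weight each window residual by 1/√max(measured, 1)
        (approximate Poisson weighting).  Off by default, matching the
        unweighted objective of the reference procedure.
    """

    def __init__(
        self,
        measurement: ConjugateMeasurement,
        components: SpectralComponents,
        weighted: bool = False,
    ):
        self.measurement = measurement
        self.components = components
        self.weighted = weighted
        self.gm_counts = measurement.geometric_mean_counts
        self._weights = (
            1.0 / np.sqrt(np.maximum(self.gm_counts, 1.0)) if weighted else None
        )

    # -- objective ---------------------------------------------------------
    def _residual_vector(self, params: np.ndarray) -> np.ndarray:
        a_th, a_ra, b = params
        modeled = model_window_counts(
            a_th, a_ra, b, self.measurement.duration, self.components
        )
        r = modeled - self.gm_counts
        return r * self._weights if self._weights is not None else r

    def objective(self, params) -> float:
        """Sum of squared (optionally weighted) count differences."""
        r = self._residual_vector(np.asarray(params, dtype=float))
        return float(r @ r)

    # -- starting points ---------------------------------------------------
    def _starts(self) -> list[np.ndarray]:
        c, dur = self.components, self.measurement.duration
        y = self.gm_counts
        # primary-only closed-form seed (B = 0)
        m_primary = dur * np.column_stack([c.primary_Th, c.primary_Ra])
        seed_p, _ = optimize.nnls(m_primary, y)
        # full linear seed with B fixed at 1
        m_full = dur * np.column_stack(
            [c.primary_Th + c.scatter_Th, c.primary_Ra + c.scatter_Ra]
        )
        seed_f, _ = optimize.nnls(m_full, y)
        # Ra-only seed
        m_ra = dur * (c.primary_Ra + c.scatter_Ra)
        denom = float(m_ra @ m_ra)
        a_ra_only = float(m_ra @ y) / denom if denom > 0 else 0.0
        return [
            np.array([seed_p[0], seed_p[1], 0.0]),
            np.array([seed_p[0], seed_p[1], 1.0]),
            np.array([seed_f[0], seed_f[1], 1.0]),
            np.array([0.0, max(a_ra_only, 0.0), 1.0]),
        ]

    def fit(self) -> "UnmixingResults":
        y = self.gm_counts
        if np.all(y == 0):
            return UnmixingResults(
                self, ActivityEstimate(0.0, 0.0, 1.0, 0.0, converged=True)
            )
        best = None
        any_converged = False
        for x0 in self._starts():
            sol = optimize.least_squares(
                self._residual_vector,
                np.clip(x0, 0.0, None),
                bounds=(0.0, np.inf),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=2000,
            )
            any_converged = any_converged or sol.success
            cost = 2.0 * sol.cost  # scipy uses 0.5*sum(r^2)
            cand = (cost, sol.x[2], sol.x)
            if best is None or cand[:2] < best[:2]:
                best = cand
        cost, _, x = best
        x = np.where(np.abs(x) < _ZERO_SNAP, 0.0, x)
        est = ActivityEstimate(
            A_Th227=float(x[0]),
            A_Ra223=float(x[1]),
            B=float(x[2]),
            residual=self.objective(x),
            converged=bool(any_converged),
        )
        return UnmixingResults(self, est)


class UnmixingResults:
    """Estimates and diagnostics from a fitted :class:`SpectralUnmixingModel`."""

    def __init__(self, model: SpectralUnmixingModel, estimate: ActivityEstimate):
        self.model = model
        self.estimate = estimate

    @property
    def params(self) -> pd.Series:
        e = self.estimate
        return pd.Series(
            {"A_Th227": e.A_Th227, "A_Ra223": e.A_Ra223, "B": e.B},
            name=self.model.measurement.roi_id or "estimate",
        )

    @property
    def residual(self) -> float:
        return self.estimate.residual

    @property
    def converged(self) -> bool:
        return self.estimate.converged

    def fittedvalues(self) -> np.ndarray:
        e = self.estimate
        return model_window_counts(
            e.A_Th227, e.A_Ra223, e.B, self.model.measurement.duration, self.model.components
        )

    def summary(self) -> str:
        m = self.model.measurement
        e = self.estimate
        lines = [
            "Spectral unmixing results",
            "=" * 48,
            f"ROI:                {m.roi_id or '(unnamed)'}",
            f"duration:           {m.duration:.0f} s",
            f"water thickness:    {m.water_thickness:.1f} cm",
            f"A_Th227:            {e.A_Th227:.4f} MBq",
            f"A_Ra223:            {e.A_Ra223:.4f} MBq",
            f"B (scatter scale):  {e.B:.4f}",
            f"residual (counts2): {e.residual:.4g}",
            f"converged:          {e.converged}",
            "-" * 48,
            f"{'window':>10} {'measured':>10} {'fitted':>10}",
        ]
        fitted = self.fittedvalues()
        for w, meas, fit in zip(m.windows, self.model.gm_counts, fitted):
            lines.append(f"{str(w):>10} {meas:>10.1f} {fit:>10.1f}")
        return "\n".join(lines)


def solve_activities(
    m: ConjugateMeasurement,
    components: SpectralComponents,
    weighted: bool = False,
) -> ActivityEstimate:
    """Fit (A_Th227, A_Ra223, B) to one conjugate measurement."""
    return SpectralUnmixingModel(m, components, weighted=weighted).fit().estimate


def pixelwise_decompose(
    window_images_ant,
    window_images_post,
    thickness,
    components: SpectralComponents,
    duration: float,
    count_floor: float = 5.0,
    mode: str = "conjugate",
):
    """Per-pixel unmixing of co-registered window images.

    Parameters
    ----------
    window_images_ant, window_images_post
        Sequences of 4 2-D arrays (counts), one per acquisition window, in
        window order.  In ``mode="anterior"`` the posterior images are
        ignored and the anterior counts stand in for the geometric mean.
    thickness
        Scalar water-equivalent thickness (cm) or a 2-D map of it.
    count_floor
        Pixels whose four-window summed geometric-mean counts fall below
        this are masked (set to 0 in all outputs, False in the mask).

    Returns
    -------
    (A_Th_image, A_Ra_image, B_image, mask)
    """
    ant = np.stack([np.asarray(a, dtype=float) for a in window_images_ant])
    if ant.shape[0] != len(components.windows):
        raise ValueError("need one anterior image per window")
    if mode == "conjugate":
        post = np.stack([np.asarray(p, dtype=float) for p in window_images_post])
        if post.shape != ant.shape:
            raise ValueError("anterior and posterior image stacks must match")
        gm = conjugate_geometric_mean(np.clip(ant, 0, None), np.clip(post, 0, None))
    elif mode == "anterior":
        gm = np.clip(ant, 0, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    shape = gm.shape[1:]
    thickness_map = np.broadcast_to(np.asarray(thickness, dtype=float), shape)
    a_th = np.zeros(shape)
    a_ra = np.zeros(shape)
    b_img = np.zeros(shape)
    mask = gm.sum(axis=0) >= count_floor
    uniform_thickness = np.all(thickness_map == thickness_map.flat[0])
    comp = components
    for idx in np.argwhere(mask):
        i, j = idx
        if not uniform_thickness:
            comp = SpectralComponents.prepare(float(thickness_map[i, j]))
        meas = ConjugateMeasurement.from_geometric_mean(
            gm[:, i, j], duration, float(thickness_map[i, j]), roi_id=f"px({i},{j})"
        )
        est = solve_activities(meas, comp)
        a_th[i, j] = est.A_Th227
        a_ra[i, j] = est.A_Ra223
        b_img[i, j] = est.B
    return a_th, a_ra, b_img, mask
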