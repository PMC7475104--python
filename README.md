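# thraquant

Quantitative dual-isotope planar γ-camera imaging of ²²⁷Th and ²²³Ra.

²²⁷Th (T½ = 18.7 d) is an α-emitter entering targeted-alpha-therapy
trials; it decays to ²²³Ra (T½ = 11.4 d), which can detach from the
carrier molecule and follow its own biodistribution. Measuring both
activities in vivo with a NaI(Tl) γ-camera is hard: the isotopes'
photopeaks sit close together, and downscatter plus finite energy
resolution mix their counts across acquisition windows. `thraquant`
implements a spectral-analysis approach for conjugate-view planar
acquisitions in four energy windows (75–100, 135–165, 215–260 and
260–285 keV): the measured geometric-mean window counts are fitted with
a weighted sum of analytically modeled primary-photon spectra and
empirically adapted scatter shapes, yielding the activity of each
isotope in a region of interest — and, per pixel, separate images of
the two distributions.

## The model

For background-corrected geometric-mean counts in window *j* over an
acquisition of duration *T*:

    m_j = T · [ A_Th ∫_j P_Th(E) dE + A_Ra ∫_j P_Ra(E) dE
              + B ( A_Th ν_Th,j ∫_j S_Th(E) dE + A_Ra ν_Ra,j ∫_j S_Ra(E) dE ) ]

* **Primary spectra** `P(E)` per unit activity are built analytically:
  `10⁶ · n(E) · η_G · η_ε(E) · exp(−μ(E)x/2)`, with emission
  probabilities `n(E)` from the bundled decay-chain table, collimator
  geometric efficiency `η_G = [kD²/(L(D+T))]²`, crystal photopeak
  efficiency `η_ε = 1 − exp(−τ_NaI(E)·t)`, conjugate-view geometric-mean
  attenuation through water-equivalent thickness `x`, and a Gaussian
  energy-resolution blur with fractional FWHM `w·√(140/E)` (w = 0.09 for
  a Siemens Intevo).
* **Scatter shapes** `S(E)` are fixed unit-integral spectral shapes per
  isotope — either externally supplied (e.g. Monte Carlo output) or the
  bundled single-Compton Klein–Nishina parametric model — adapted to the
  measured geometry by per-window coefficients ν calibrated from
  acquisitions with known activities.
* `(A_Th, A_Ra, B)` are estimated by nonnegative least squares over the
  four windows (multi-start trust-region solver; unweighted objective by
  default).

Decay-chain math (two-member Bateman solution, secular equilibrium of
²²³Ra's sub-hour daughters), ROI handling with local background
subtraction, scout-image thickness calibration, and a synthetic phantom
simulator with Poisson noise complete the pipeline.

## Worked example

Fit one ROI-level measurement (counts from a 20-min conjugate
acquisition of a sphere holding ≈0.50 MBq ²²⁷Th and ≈0.07 MBq ²²³Ra
behind 20 cm of water):

```python
import numpy as np
from thraquant import SpectralComponents, ConjugateMeasurement, SpectralUnmixingModel

comp = SpectralComponents.prepare(thickness=20.0)   # Siemens-Intevo-HE preset
counts = np.array([1852.0, 276.0, 1320.0, 374.0])   # GM counts per window
m = ConjugateMeasurement.from_geometric_mean(counts, duration=1200.0,
                                             water_thickness=20.0,
                                             roi_id="sphere83@day2")
res = SpectralUnmixingModel(m, comp).fit()
print(res.summary())
```

```
Spectral unmixing results
================================================
ROI:                sphere83@day2
duration:           1200 s
water thickness:    20.0 cm
A_Th227:            0.4870 MBq
A_Ra223:            0.0723 MBq
B (scatter scale):  1.1235
residual (counts2): 204.1
converged:          True
------------------------------------------------
    window   measured     fitted
    75-100     1852.0     1854.3
   135-165      276.0      277.1
   215-260     1320.0     1320.4
   260-285      374.0      360.0
```

The fit separates the two isotopes from the window pattern: the
215–260 keV window is dominated by ²²⁷Th (236/256 keV lines), 75–100 keV
by ²²³Ra x-rays and low-energy lines; `B` scales the scatter shapes.

A complete synthetic study — two spheres in a warm background, 13 time
points over 29 days — runs in seconds:

```python
from thraquant import jaszczak_torso, jaszczak_rois, simulate_timeseries_study, quantify_study, cumulated_activity

phantom, plan = jaszczak_torso(seed=7)
study = simulate_timeseries_study(phantom, plan)
df = quantify_study(study, jaszczak_rois())
d = df[df.compartment == "sphere83"].sort_values("time_days")
for iso in ("Th227", "Ra223"):
    est = cumulated_activity(d.time_days, d[f"A_{iso}_est"])
    true = cumulated_activity(d.time_days, d[f"A_{iso}_true"])
    print(iso, round(est, 2), round(true, 2), f"{100*abs(est-true)/true:.1f}%")
```

```
Th227 9.54 9.61 0.7%
Ra223 5.87 5.9 0.4%
```

i.e. the trapezoid-integrated (cumulated) activity of each isotope is
recovered to well within 10% despite Poisson noise — single-time-point
estimates scatter more, which is why dosimetry integrates over the
curve.

A `thraquant` CLI exposes `simulate`, `quantify`, `decompose`,
`roi-counts` and `scout-thickness` subcommands over the same library.

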