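# hemoshear

Pulsatile wall-shear-stress analysis of idealized sidewall aneurysms.

Low and abnormal wall shear stress (WSS) on the aneurysm sac is a leading
candidate mechanism for intracranial-aneurysm rupture.  The standard study
design simulates pulsatile blood flow over each aneurysm, reduces the wall
field to a handful of metrics, and asks which of them separate ruptured
from unruptured lesions.  `hemoshear` packages that whole work-up at desk
scale for methodological work: a parametric planar geometry model replaces
patient angiograms, a validated 2-D finite-volume SIMPLE solver replaces
the commercial CFD step, and calibrated synthetic cohorts replace the
patient population — while every definition downstream (metrics, strata,
statistics) follows the clinical pipeline.

## The model in brief

Flow: incompressible Newtonian blood (ρ = 1050 kg/m³, μ = 3.5·10⁻³ Pa·s)
in a channel with a sidewall sac; no-slip rigid walls, flat inlet profile,
zero outlet pressure; single-harmonic inflow `Q(t) = Q̄ + (Q_max − Q̄)
sin(2πt/T)` with Q̄ = 185 ml/min, Q_max = 301 ml/min, 64 bpm (Reynolds
≈ 364, Womersley ≈ 2.3).  Three cardiac cycles are integrated; the last is
analyzed.

Per wall element *i*, the cycle-averaged WSS is

    WSS_i = (1/T) ∫₀ᵀ |wss_i(t)| dt ,   wss_i = μ |∂u_t/∂n| at the wall.

From the averaged field: **MWSS** (arc-length-weighted sac mean), **HWSS**
(highest sac value), **PWSS** (parent-wall mean sampled 1 cm from the
neck), **LSAR** (fraction of sac arc with WSS below 0.1·PWSS), and the
ratios **M-P** = MWSS/PWSS, **H-P** = HWSS/PWSS.  Sacs with aspect ratio
height/neck ≥ 1.4 and neck < 4 mm are *narrow-necked*, all others *wide*.
Cohorts (default 72 aneurysms, 41 ruptured / 31 unruptured) are compared
per metric with a normality-gated t / Mann–Whitney choice, Spearman
correlations against morphology, and a univariate screen (p < 0.05)
feeding backward stepwise logistic regression for rupture.

## Worked example

One hemispherical sac (radius 2 mm) on a 3.24 mm parent channel, three
pulsatile cycles (`python examples/03_single_aneurysm_metrics.py`):

```
MWSS  (mean sac WSS)        :  0.205 Pa
HWSS  (highest sac WSS)     :  0.961 Pa
PWSS  (parent WSS at 1 cm)  :  5.842 Pa
LSAR  (low-shear area ratio):  0.920
M-P ratio                   : 0.0350
H-P ratio                   : 0.1645
```

The parent wall sees ~5.8 Pa of developed shear while the shear-driven
sac recirculation leaves most of the dome below the 0.58 Pa low-shear
threshold (LSAR 0.92) — deep sacs decouple from the parent flow, the
physical effect behind the low-WSS rupture hypothesis.  Solver fidelity is
checked against closed forms (`examples/02_pulsatile_channel_validation.py`):

```
Womersley number: 2.294 (physiological ~2.32)
centerline velocity, last cycle: relative L2 error vs analytic = 0.856%
```

The other examples build geometries and morphometry (`01`), run the
cohort statistics on a calibrated metric-mode cohort (`04`), and run the
full geometry→CFD→statistics loop on a small cohort (`05`).  A thin CLI
(`hemoshear generate-geometry | mesh | simulate | run | stats`) wraps the
same stages for shell use.

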