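# spiralflow

Highly accelerated 4D-flow cardiovascular MR, end to end at desk scale:
pseudo-spiral Cartesian k-t sampling design, retrospectively gated
acquisition simulation on a digital pulsatile-vessel phantom,
temporal-total-variation compressed-sensing reconstruction, and
quantitative flow-rate / wall-shear-stress analysis with Bland-Altman
comparison across acceleration factors.

## Who this is for

4D-flow CMR measures all three blood-velocity components per voxel per
cardiac frame, enabling biomarkers such as wall shear stress (WSS), but
fully sampled acquisitions take tens of minutes.  `spiralflow` is a
research sandbox for studying how aggressive Cartesian undersampling plus
compressed sensing degrades those quantitative biomarkers, using a fully
synthetic, analytically known phantom so every error can be measured
against ground truth.

## The method

**Sampling.**  The two phase-encode coordinates (k_y, k_z) are laid out
along quadratic pseudo-spiral arms on the Cartesian grid,

    r(φ) = φ²,   φ ∈ [0, 2πl],  n = 100 readouts per arm, l = 3 turns,

with each successive arm rotated by the tiny golden angle
180°/(τ + 6) ≈ 23.63° (τ the golden ratio).  This yields a variable-density
pattern with a fully sampled centre.  The acceleration factor is
R = N_fully / N_undersampled with N_fully = N_ky · N_kz · N_card · N_flow.
Every profile is acquired for all four flow-encoding segments (reference +
x, y, z) before moving on, and profiles advance continuously through the
cardiac cycle, so retrospective "absolute" binning (frame =
⌊Δt_R-top / frame duration⌋) gives each cardiac frame its own incoherent
mask.

**Reconstruction.**  Per flow segment, the binned k-t data y are
reconstructed by approximately solving

    m̂ = argmin_m  ½‖F_U m − y‖₂² + λ · TV_t(m),   λ = 0.01, 10 iterations,

with F_U the coil-weighted undersampling Fourier operator and TV_t the ℓ1
norm of cyclic first-order temporal differences, using monotone FISTA with
an exact-step dual prox for the TV term.  Velocities decode from phase
differences to the reference segment, v_d = ∠(m_d · m̄_ref)/π · venc with
venc = 150 cm/s.

**Quantification.**  Flow rate Q(t) integrates the through-plane velocity
over a lumen ROI; WSS is τ = 2ηε̇·n evaluated in a local wall frame as
τ = η(∂v_x'/∂z', ∂v_y'/∂z', 0) with η = 3.2·10⁻³ Pa·s, the wall-normal
derivatives taken from a quadratic fit to velocities sampled along the
inward normal.  Paired peak-systolic values across acceleration factors
are compared with Bland-Altman statistics (bias, 1.96-SD limits of
agreement) and orthogonal regression.

## Worked example

```python
import numpy as np
import spiralflow as sf

report = sf.run_experiment(sf.ExperimentConfig(r_values=[2, 10, 20], seed=1))
for label, run in report["runs"].items():
    c = report["comparisons"][label]["velocity"]
    print(f"{label:>4}: effective R {run['r_effective']:5.2f}  "
          f"peak Q {run['peak_flow_ml_s']:5.2f} ml/s  "
          f"mean WSS {run['mean_wss_pa']:5.3f} Pa  "
          f"rho {c['pearson_rho']:6.4f}  LOA width {c['loa_width']:5.2f} cm/s")
```

prints (seed 1):

```
  R2: effective R  4.06  peak Q  8.89 ml/s  mean WSS 1.302 Pa  rho 1.0000  LOA width  0.00
 R10: effective R 14.33  peak Q  8.68 ml/s  mean WSS 1.230 Pa  rho 0.9814  LOA width 22.12
 R20: effective R 26.99  peak Q  7.61 ml/s  mean WSS 1.097 Pa  rho 0.9272  LOA width 42.22
```

Each row is one simulated scan of the same pulsatile tube (10 ml/s peak,
3 ml/s mean inlet flow at 60 bpm ± 5%).  As the target acceleration grows,
the retrospectively measured effective R grows with it, the voxel-wise
velocity correlation against the R = 2 reference decreases, and the
Bland-Altman limits of agreement widen — peak flow and WSS become
progressively underestimated while remaining usable through R ≈ 20, the
behaviour this kind of protocol shows on real scanners.  The analytic
ground truth for the same scene is peak Q = 10 ml/s and Poiseuille wall
shear 1.51 Pa at peak systole; part of the remaining gap is cardiac-frame
averaging, not reconstruction error.

A command-line interface covers the same pipeline
(`spiralflow design|recon|run|compare`), e.g.

```bash
spiralflow design --matrix 160x40 --frames 19 --r 10 --tr 8.9 --out profiles.txt
spiralflow run --seed 1 --out sweep/
spiralflow compare --results-dir sweep/ --reference R2
```

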