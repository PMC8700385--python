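# ivimfusion

Histology–MRI fusion and intravoxel incoherent motion (IVIM) parameter
estimation for prostate multi-b-value diffusion MRI, with the cohort
statistics of a lesion-vs-contralateral diagnostic study.

## Who this is for

Researchers validating IVIM analysis chains for prostate cancer (PCa)
imaging: transferring a pathologist's whole-mount lesion outline onto
the DWI grid through control-point registration against T2-weighted MRI,
fitting the biexponential decay per voxel, and reproducing the
diagnostic statistics such a study reports.  Because no public dataset
exists for this workflow, the package ships a first-class synthetic-data
module — phantoms, Rician-noisy DWI stacks, histology/T2 scene pairs
with known ground-truth transforms, and cohorts with configurable age
trends and lesion effects — so every stage can be tested end to end.

## The model

The DWI signal at diffusion weighting `b` (s/mm²) decays as

    S(b) / S0 = f · exp(−b (D* + D)) + (1 − f) · exp(−b D)

where `f` is the perfusion fraction, `D` the molecular diffusion
coefficient, `D*` the perfusion-related pseudo-diffusion coefficient
(both mm²/s) and `S0` the signal at b = 0.  The mono-exponential ADC is
fitted alongside for comparison.  Two estimators are provided:

* **segmented fit** — high-b mono-exponential for D, intercept for f,
  bounded nonlinear least squares for D*, polished by a final bounded
  fit of all four parameters;
* **Bayesian shrinkage prior (BSP) fit** — a hierarchical model drawing
  every voxel's transformed parameters from a shared Gaussian prior,
  sampled by Metropolis-within-Gibbs; borrowing strength across the ROI
  stabilizes the notoriously noisy D*.

See `docs/methods.md` for the full model, priors, defaults and
numerical conventions.

## Worked example

```python
import numpy as np
from ivimfusion import AcquisitionScheme, SegmentedIVIMFitter, ivim_signal
from ivimfusion.synthetic import NoiseModel, add_rician_noise

scheme = AcquisitionScheme()          # 0 ... 2000 s/mm^2, 10 b-values
truth = dict(f=0.427, d=0.51e-3, dstar=3.73e-3, s0=100.0)  # PCa-like
clean = ivim_signal(scheme.array, **truth)
noisy = add_rician_noise(np.tile(clean, (500, 1)),
                         NoiseModel(snr=50, seed=20, s0_ref=100.0))

est = SegmentedIVIMFitter().fit(noisy)
print(f"f      median {np.median(est.f_)*100:6.1f} %   (truth 42.7)")
print(f"D      median {np.median(est.d_)*1e3:6.3f}     (truth 0.510)")
print(f"D*     median {np.median(est.dstar_)*1e3:6.3f}     (truth 3.730)")
print(f"ADC    median {np.median(est.adc_)*1e3:6.3f}")
```

prints

```
f      median   43.5 %   (truth 42.7)
D      median  0.500     (truth 0.510)
D*     median  3.687     (truth 3.730)
ADC    median  1.047
```

i.e. at SNR 50 the segmented fit's median estimate recovers f within
one percentage point, D and D* within a few percent, and the ADC
(1.047 × 10⁻³ mm²/s) sits above D because perfusion inflates the
apparent diffusion.  D and D* are in 10⁻³ mm²/s.

The full pipeline — simulate a 38-subject cohort, register each
patient's synthetic histology to T2, carry the lesion ROI to the DWI
grid, mirror the contralateral ROI, fit, and produce the report
tables — runs from the shell:

```bash
ivimfusion run --seed 1 --outdir runs/demo
```

and writes the cohort ground truth, fusion overlays, ROI samples, the
paired lesion/normal comparison, diagnostic-accuracy and
age-correlation tables, and a manifest with per-stage hashes (two runs
with the same seed are bit-identical).

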