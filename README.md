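# drdifc

Simulation and calibration toolkit for **dual-ratio diffuse in-vivo flow
cytometry (DiFC)** — fluorescence detection of labeled circulating cells
through millimetres of scattering tissue.

DiFC shines laser light into tissue and watches for transient fluorescence
peaks as labeled cells cross the sensitivity region of a source–detector
fiber pair. Its depth reach is limited by tissue autofluorescence (AF)
background and by coupling noise. The **dual ratio**

    DR = sqrt( (I_l,I · I_l,II) / (I_s,I · I_s,II) )

— the geometric mean of two symmetric long/short source–detector intensity
ratios — cancels every multiplicative factor attached to a single optode
(coupling, gain, drift) *exactly*, and de-weights the superficial tissue
where AF concentrates. This package provides the full forward model needed
to ask when DR beats conventional single-distance (SD) sensing:

* a native, seeded Monte-Carlo photon-transport kernel (Henyey–Greenstein
  scattering, Fresnel surface, pencil-beam sources and NA-cone detectors)
  plus a diffusion-theory closed form as an independent oracle;
* the fluorescence Jacobian `W = Φ_src·Φ_det·V` and reflectance algebra for
  point targets and distributed AF (homogeneous or surface-weighted);
* the SD/SR/DR measurement types and the Gaussian coupling-coefficient
  noise model `I = C_src·C_det·C_NC·R` with `2·popt + pNC = 1`, where `pNC`
  is the noise fraction DR cannot cancel;
* trace calibration (robust background/noise estimation, peak detection,
  current→reflectance conversion, coefficient fitting);
* the derived analyses: SNR maps, flow traces, maximum-measurable-depth
  scans, and pNC sweeps;
* a synthetic-trace generator with known ground truth, a YAML-configured
  workflow runner and a `drdifc` command-line interface.

## Worked example

Calibrate a synthetic phantom trace (170 nA background, relative noise
σrel = 0.031, twenty 47.3 nA cell transits over 60 s at 2 kHz):

```python
from drdifc import (ConversionConstant, PeakSchedule, calibrate_trace,
                    make_trace)

trace = make_trace(background=170.0, sigma_rel=0.031,
                   schedule=PeakSchedule.regular(20, 47.3, 60.0),
                   duration=60.0, seed=1)
res = calibrate_trace(trace, ConversionConstant())
print(f"background {res.background_na:.1f} nA "
      f"({res.background_r*1e12:.1f} pW/mm2)")
print(f"noise      {res.noise_na:.2f} nA, sigma_rel {res.sigma_rel:.4f}")
print(f"peaks      {len(res.peaks)}, mean {res.mean_peak_na:.1f} nA")
```

prints

```
background 170.0 nA (46.1 pW/mm2)
noise      5.19 nA, sigma_rel 0.0305
peaks      20, mean 48.3 nA
```

i.e. the chain recovers the generating background (and its 46.1 pW/mm²
reflectance equivalent), the relative noise, and every scheduled transit;
a 47.3 nA peak against 5.29 nA noise is an SNR of ≈ 8.95.

The exact-cancellation law in two lines:

```python
import numpy as np
from drdifc import IntensityQuartet, NoiseParams, dual_ratio, sample_intensities

r = IntensityQuartet(s_I=3.0, l_I=1.1, s_II=2.9, l_II=1.05)
draws = sample_intensities(r, NoiseParams(sigma_rel=0.031, p_nc=0.0),
                           n_draws=100_000, seed=2)
dr = np.sqrt(draws[:, 1] * draws[:, 3] / (draws[:, 0] * draws[:, 2]))
print(np.max(np.abs(dr / dual_ratio(r) - 1.0)))   # 4.4e-16
```

With `p_nc = 0` every sampled DR equals the theoretical one to machine
precision although each intensity carries 3.1 % noise; with `p_nc > 0` the
DR noise follows `sqrt(p_nc)·σrel`.

End-to-end workflows run from the shell:

```sh
drdifc --workdir run --seed 7 full-chain   # MC ×4 → Jacobians → depth table
drdifc --workdir run simulate-trace
drdifc --workdir run calibrate
```

`run/depth_scan.csv` then holds the maximum measurable depth (deepest
|SNR| > 1) per measurement type. At the package's desk-scale photon budget
the surface-weighted AF case ranks DR deepest (DR > SD ρ=4 mm > SD ρ=3 mm),
and the homogeneous case demotes DR below the best SD — the central
qualitative result — while the pNC sweep shows DR keeps its advantage only
up to a few-percent non-cancelable noise fraction.

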