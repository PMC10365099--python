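# t2ie

Multi-echo T2 relaxometry with reproducibility analysis: estimate
multi-compartment T2 spectra from 32-echo spin-echo MRI, derive the
intra/extra-cellular T2 time (T2IE) and myelin water fraction, and quantify
how reproducible those maps are across runs, sessions, scanners and
subjects.

## The problem

The multi-echo T2 signal of brain tissue is a mixture of water pools with
distinct transverse relaxation times: myelin-trapped water (T2 < 40 ms),
intra/extra-cellular (IE) water (40–200 ms) and free water (> 200 ms).
Writing the measured echo train as `y = A(α) x`, where `x ≥ 0` is the
spectrum on a fixed grid of 60 log-spaced T2 values (10–2000 ms) and
`A(α)` is the dictionary of Extended Phase Graph (EPG) echo trains at the
voxel's effective refocusing flip angle α, the inverse problem is severely
ill-posed and must be regularized. The package implements the three
estimators whose reproducibility is under study:

* **X²−I**: Tikhonov-regularized NNLS, `min ‖Ax−y‖² + λ²‖x‖², x ≥ 0`, with
  λ chosen so the data residual is a fixed factor (1.02) above the
  unregularized minimum;
* **L-curve−I**: the same problem with λ at the maximum-curvature corner of
  the (log residual norm, log solution norm) curve;
* **MIML**: a multilayer perceptron (6 × 256 ReLU units, 60-unit softmax
  output) trained on synthetic EPG signal/spectrum pairs with an
  L2 + Wasserstein loss.

The scalar of interest is the amplitude-weighted geometric mean of the
spectrum restricted to the IE window,

    T2IE = exp( Σ_{40 ≤ T2_i ≤ 200} w_i ln T2_i / Σ w_i ),

which is scale-free and immune to partial-volume mass outside the window.
Reproducibility is quantified by coefficients of variation grouped by
effect (inter-run / inter-session / inter-scanner / inter-subject), the
two-way random-effects single-measurement consistency ICC, and pairwise
Wilcoxon rank-sum tests with Bonferroni correction.

Because no public dataset accompanies this design, a synthetic study
generator emulates it: 20 subjects × 2 sites × 2 sessions × 2 runs
(160 scans) of a block phantom with known regional T2IE, nested normal
effects per design factor, a spatially smooth refocusing-FA field, and
Rician noise at clinical SNR.

## Worked example

```python
import numpy as np
from t2ie import (AcquisitionProtocol, build_t2_grid, build_fa_bank,
                  select_lambda_chi2, t2ie)

protocol = AcquisitionProtocol()          # 32 echoes, TE = ΔTE = 10.68 ms
grid = build_t2_grid()                    # 60 log-spaced T2s, 10-2000 ms
bank = build_fa_bank(protocol, grid)

# noiseless voxel: single T2 pool at grid node 24, flip angle 165°
A = bank.lookup(165.0)
w = np.zeros(60); w[24] = 1.0
y = A @ w
spec = select_lambda_chi2(A, y, grid=grid)
print(round(grid.values[24], 2), round(t2ie(spec), 2))
```

prints `86.3 86.3`: the chi-square criterion recovers the 86.3 ms
ground-truth T2IE of the synthesized voxel exactly on noiseless data.

The full pipeline is driven by one YAML config through the CLI:

```bash
t2ie run -c config.yaml --method lcurve_identity --arm raw --seed 1
```

which simulates the study, estimates per-voxel flip angles from a
Gaussian-smoothed copy of the data (4.8 mm FWHM), fits every voxel,
writes T2IE per-ROI tables, and prints the median CoV per effect.

## Acceptance script

`scripts/acceptance.py` regenerates everything from scratch at a reduced
desk scale (4 subjects × 2 × 2 × 2 = 32 scans): it simulates the study,
runs all three estimation methods end to end, and computes each method's
full reproducibility report (median CoV per effect, per-ROI ICC, pairwise
tests), writing its JSON result to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A typical run prints, per method, median CoVs in the sub-2% regime with
the inter-subject effect largest, e.g. for X²−I:

```
[chi2_identity] fitted in 11 s
median CoV by effect (%):
inter_run       0.576
inter_scanner   0.670
inter_session   0.386
inter_subject   1.583
```
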