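# Methods

## Signal model

A CPMG-style multi-echo spin-echo acquisition (32 echoes, TE₁ = ΔTE =
10.68 ms, TR = 1 s, nominal refocusing angle 180°, 1.6 mm isotropic
voxels) is simulated with the Extended Phase Graph (EPG) formalism. The
recursion tracks the real-valued configuration states (F⁺(k), F⁻(k), Z(k))
under the CPMG phase condition, with one unit of gradient dephasing per
half echo-spacing and n_echoes + 2 configuration orders (exact for the
train length). Two conventions matter and are deliberate:

* **T1 handling.** The assumed T1 is not part of the acquisition record, so
  it is a configurable `t1_assumed` (default 1000 ms, a white/gray-matter
  compromise at 3T). Longitudinally stored pathways relax with T1 between
  pulses, but the equilibrium regrowth term is omitted so echo amplitudes
  are independent of proton-density recovery. Setting `t1_assumed` very
  large disables T1 relaxation entirely, which brackets the behaviour of
  implementations that ignore it.
* **Verified physics over folklore.** Two intuitive "invariants" are false
  and the tests document it: with T1 > T2 the slowly decaying z-stored
  pathways can push even echoes *above* the 180° monoexponential, and at
  short T2 with imperfect refocusing, increasing T2 can *decrease* late
  echoes (the echo is the magnitude of a signed pathway sum). Both effects
  are confirmed to machine precision by an independent isochromat
  (Bloch-rotation ensemble) oracle, which is also the reference the EPG
  kernel is validated against (≤ 1e-4 relative, in practice ~1e-15).

## Dictionaries and flip-angle estimation

Dictionaries map non-negative spectra on a 60-point log-spaced T2 grid
(10–2000 ms) to echo trains; columns are raw EPG amplitudes (no
normalization — the spectrum carries the proton-density scale). Flip
angles live on two grids: 15 equally spaced coarse values on [90°, 180°]
for estimation, and a fine bank with 0.33° steps for fitting. The fine
grid 90 + k·0.33 does not land on 180 exactly, so 180.0 is appended (274
keys total); nearest-key lookup breaks ties toward the smaller key. Bank
matrices are built lazily and cached; lookups are bit-identical to eager
construction.

Per voxel, the effective FA is estimated from a Gaussian-smoothed copy of
the data (4.8 mm FWHM, σ = FWHM/2.355 converted to voxels, nearest-edge
padding); the smoothed copy is used *only* here. Unregularized NNLS
against each coarse dictionary yields 15 mean-square errors; a cubic
interpolating spline through them is evaluated at 0.01° steps and its
global minimum localizes the FA. Because the interpolant overshoots near
sharp minima (the MSE drops to ~0 at the true FA and the spline argmin can
be biased by up to ~2°), the estimate is refined by scoring the actual
NNLS MSE on fine-grid keys within ±3.5° of the spline minimum and
returning the best-fitting key. Measured on noiseless data this brings the
recovery error below 0.25° at coarse-grid angles and below 0.15° off-grid.
Boundary minima at 90°/180° are accepted as-is; all-zero voxels are
flagged unfitted (NaN), never zero-filled.

## Regularized NNLS and λ selection

`reg_nnls` solves `min ‖Ax−y‖² + λ²‖x‖², x ≥ 0` exactly as Lawson–Hanson
NNLS on the augmented system [A; λI] vs [y; 0]; the reported residual is
the data term only. The λ grid is 60 log-spaced points spanning
[1e-5, 10] × (largest dictionary column norm), wide enough to bracket
under- and over-regularization at any signal scale.

* **Chi-square criterion** (factor 1.02, configurable): largest λ with
  residual ≤ factor × the unregularized minimum, located by a grid walk and
  bisection to 1e-3 relative tolerance on the factor. A perfect
  unregularized fit short-circuits with a degenerate-fit flag.
* **L-curve criterion**: Menger (circumcircle) curvature over consecutive
  triplets of (log residual², log ‖x‖²), maximum-curvature corner refined
  by golden-section between the bracketing grid points (outer neighbours
  held fixed). Ties go to the smaller λ. Two degeneracies fall back to the
  smallest grid λ with a warning: a numerically exact fit at the weakest
  regularization (relative residual < 1e-10 — no corner exists and no
  smoothing is warranted) and a flat/collinear curve (curvature < 1e-9).

Residual monotonicity and solution-norm monotonicity along the λ grid are
property-tested, as is agreement of both criteria on noiseless voxels
(within 2% in T2IE) and a median |T2IE bias| < 3% at first-echo SNR 100.

## MIML

The MLP (32 → 6 × 256 ReLU → 60 softmax) is implemented in numpy with
manual backpropagation and Adam (lr 5e-4, β = 0.9/0.999, batch 2000),
because no deep-learning framework is available in the target
environment; this also makes training bit-reproducible for a fixed seed.
The loss is `‖p − t‖² + w · W₁(p, t)` with weight ratio 1:1 (configurable);
W₁ is the 1D Wasserstein distance `Σ |CDF_p − CDF_q| Δ` with the grid's
constant log-spacing as the ground metric (a linear-ms metric is a
parameter away). Its exact subgradient w.r.t. the prediction — a reversed
cumulative sum of signed gap widths — is propagated through the softmax
Jacobian.

Training pairs are synthetic: spectra with 1–3 lognormal lobes (random
log-centers across the grid, log-widths 0.08–0.35, Dirichlet fractions),
FA uniform on [90°, 180°] snapped to the bank, EPG forward signals,
Rician noise at first-echo SNR uniform on [40, 200], and unit-first-echo
signal normalization (predictions are therefore invariant to global signal
scale). The lobe prior, loss weighting and SNR range are package choices
documented here, not measured values. The desk-scale default is 50,000
pairs / 30 epochs (the original corpus was 1.12 million pairs); the
acceptance test trains 50,000 pairs for 12 epochs to fit a CPU-minute
budget and still recovers held-out noiseless single-lobe T2IE with ~1.4%
median error (criterion: < 5%).

## T2IE and MWF

T2IE is the amplitude-weighted geometric mean of the spectrum over the
inclusive window [40, 200] ms; it is undefined (NaN, never zero) when the
window carries no mass. Amplitude weighting is what makes the metric
scale-free, so normalized MIML spectra and unnormalized NNLS spectra give
identical values. Mass strictly outside the window cannot move it —
the partial-volume immunity holds exactly at the level of the definition
and is asserted exactly in tests. MWF is the fraction of total mass below
40 ms (strict inequality at the cutoff).

## Denoising arm

The optional pre-fit arm estimates each echo volume's noise SD by the
robust wavelet detail estimator — median absolute deviation of the
finest-scale fully high-pass (HHH) one-level Haar coefficients divided by
0.6745 — implemented directly since PyWavelets is unavailable; the
orthonormal Haar transform maps i.i.d. Gaussian noise of SD σ to
coefficients of SD σ. Each volume is then smoothed by
Rudin–Osher–Fatemi total variation (`skimage.restoration.
denoise_tv_chambolle`, tolerance 2e-4, ≤ 200 iterations) with weight 2σ.
σ is estimated on magnitude data without Rician bias correction — a known
limitation at low SNR. Toggling raw/denoised is a single config switch;
all downstream code is shared.

## Synthetic study generator

The generator states a world; it is not tuned to outcomes:

* **Design**: 20 subjects × 2 sites × 2 sessions/site × 2 runs/session
  (160 scans), fully enumerated.
* **Truth**: regional true T2IE = baseline + independent zero-mean normal
  effects drawn once per subject, (subject, site), (subject, site,
  session) and (subject, site, session, run) tuples. Site/session effects
  are drawn per subject (no global site offset), matching how the effect
  groupings are defined. Default SDs — subject 1.0, site 0.35, session
  0.35, run 0.15 ms — are generator choices placing CoVs in the sub-2%
  regime typical of this metric, with the hierarchy
  run < session = site < subject that the analysis must recover.
* **Phantom**: three 8×8×8 blocks with baselines (66, 72, 78) ms — inside
  the range reported for brain ROIs — and myelin fractions (0.12, 0.08,
  0.04). Per region the spectrum is a myelin lobe (lognormal, 20 ms
  center, log-width 0.15) plus an IE lobe whose center is solved by
  root-finding so the *full* spectrum's windowed geometric mean equals the
  scan's true T2IE (contract tested to 1%). Targets beyond the attainable
  range (≈ 175 ms with the default widths) are clipped with a warning.
* **Acquisition**: per-voxel FA from a smoothed Gaussian random field
  (mean 165°, SD 8°, ~2-voxel correlation), EPG forward signals, Rician
  magnitude noise with σ = (mean true first echo)/SNR (default first-echo
  SNR 100; a Gaussian arm exists only inside unit tests).

What a green test does *not* establish: the phantom has no anatomy, no
partial-volume mixing across region boundaries, no registration error, no
B0/B1 artifacts beyond the smooth FA field, and identical spectra within
a region. Real-data CoV/ICC magnitudes are therefore out of reach by
design; the analysis-level claims tested are ordering and calibration
properties, not the human dataset's numbers.

## Reproducibility statistics

ROI means are arithmetic means over labeled voxels, NaN-flagged voxels
excluded. Effect groupings: inter-run groups the runs within each
(subject, site, session); inter-session the per-session means (runs
averaged first) within (subject, site); inter-scanner the per-site means
within subject; inter-subject the per-subject means per site. CoV uses
the sample SD (n−1; the population variant is a parameter). The ICC is
the two-way random-effects, single-measurement, consistency form,
ICC(C,1) = (MS_rows − MS_err)/(MS_rows + (k−1) MS_err), computed from the
ANOVA decomposition of the complete subjects × measurements matrix, with
the standard 95% F-based confidence interval (a stated "0.095" confidence
level upstream is read as the obvious typo for 0.95). Pairwise effect
comparisons use the two-sided Wilcoxon rank-sum test — exact for small
untied samples, normal approximation with tie/continuity correction
otherwise — Bonferroni-corrected over the pairs tested. Tests are run
within each ROI (each ROI has its own CoV distribution per effect,
mirroring per-tissue comparison panels); pooling ROIs into one list per
effect would structurally inflate the session-vs-scanner comparison,
because scanner-level values carry half the session variance even when
the session and site SDs are equal.

## Pipeline and CLI

One validated YAML config (unknown keys rejected) drives
simulate → [denoise] → FA map → spectral fit → T2IE/MWF → ROI tables →
report; every output directory carries a manifest with the config hash,
and all randomness flows from the config seed. CLI verbs `simulate`,
`fit`, `stats`, `run` map onto the library; scalar-map and ROI-table
persistence use NIfTI-1 and CSV. The `fit` verb computes the derived
metrics and ROI tables in the same pass (spectra are not persisted
voxelwise by default), and `stats` emits the report CSVs
(`cov_by_effect.csv`, `icc_by_roi.csv`, `pairwise_tests.csv`,
`roi_summary.csv`).

## Known limitations

* Slice-profile effects, magnetization transfer, exchange and diffusion in
  internal gradients are outside the forward model.
* The chi-square factor (1.02) and λ-grid span are literature-standard
  defaults, not values fixed by the study being emulated; both are config.
* MIML accuracy depends on the synthetic prior; spectra far outside the
  1–3-lobe lognormal family are extrapolation.
* The wavelet σ estimator is applied to magnitude (Rician) data without
  bias correction, slightly overestimating signal and underestimating σ at
  very low SNR.
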