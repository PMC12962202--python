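# famfat

A desk-scale toolkit for **flip-angle-modulated (FAM) 2D chemical-shift-encoded
(CSE) MRI** proton-density fat-fraction (PDFF) mapping. PDFF — the fraction of
MR-visible protons attributable to fat, `F/(W+F)` — is the quantitative imaging
biomarker of hepatic steatosis. Conventional PDFF protocols are 3D-encoded,
constant-flip, steady-state spoiled gradient-echo acquisitions: they require
breath-holding, and their steady state weights fat and water by different
T1-dependent saturation factors, biasing the measured fat fraction. A FAM
acquisition instead collects each 2D slice in under two seconds with **centric
phase encoding from equilibrium magnetization**, so the center of k-space —
which dominates quantitative ROI values — carries a T1-independent signal
`M0 sin(α₁)`; the flip angles of later excitations are modulated to shape the
outer-k-space signal envelope, balancing point-spread-function broadening,
residual T1 sensitivity, and SNR.

The package is aimed at quantitative-MRI researchers who want to study this
acquisition regime without a scanner: it provides

- **`famfat.signal_model`** — the multi-peak fat phasor
  `c(TE) = Σₚ aₚ exp(i2πfₚTE)`, the CSE voxel signal
  `s(TEₙ) = (W + F·cₙ)·e^(−R2*·TEₙ)·e^(i2πψTEₙ)`, the SPGR steady state
  `sinα(1−E1)/(1−E1·cosα)`, and the closed-form apparent (T1-biased) PDFF;
- **`famfat.sequence_design`** — centric orderings, the transient
  flip/relaxation recursion, FAM schedule solving by exact inversion of the
  magnetization recursion against a target k-space signal profile, PSF
  metrics, Cramér–Rao bounds on PDFF noise, protocol presets for 0.55T /
  1.5T / 3T, and a best-effort Pulseq `.seq` text export;
- **`famfat.phantom` / `famfat.acquisition_sim`** — a digital 16-vial
  PDFF × T1 phantom (PDFF 0–30%, water T1 200–1400 ms) and a forward
  simulator that reproduces both the FAM transient k-space weighting and the
  constant-flip steady-state regime, with seeded complex Gaussian noise;
- **`famfat.fitting`** — confounder-corrected magnitude, complex, and hybrid
  PDFF/R2*/field-map fitting, with smoothness-regularized field-map
  estimation on a discrete off-resonance grid;
- **`famfat.analysis`** — ROI summaries, bias against the low-flip
  reference-vial convention, Bland–Altman limits of agreement,
  repeatability/reproducibility coefficients (each `1.96·SD` of paired
  differences), voxel-wise SD noise surrogates, and the field-strength-
  dependent R2* exclusion rule.

## Worked example

The T1-bias mechanism in one line — a steady-state 3D-style protocol at 3T
(TR 6.4 ms, flip 3°) reading a voxel whose true PDFF is 30%, with liver-like
T1s (fat 382 ms, water 809 ms):

```python
>>> from famfat import apparent_pdff_steady_state
>>> print(f"apparent PDFF: {100*apparent_pdff_steady_state(0.30, 3.0, 6.4, 809.0, 382.0):.1f}%")
apparent PDFF: 31.7%
```

Fat, with its shorter T1, is less saturated than water, so the steady state
overestimates the fat fraction by 1.7 percentage points. The FAM design
avoids this bias at the center of k-space. Designing the 3T FAM protocol:

```sh
$ famfat design --preset 3T --out design_out
{
  "crlb_pdff_sd_pct_at_snr50": 1.2574981205923617,
  "protocol": "3T",
  "psf": {
    "fwhm_broadening": 1.157138766321141,
    "max_sidelobe": 0.23967657106150017
  },
  "t1_weighting_discrepancy": 0.06901227104396002,
  "timing": {
    "per_slice_exact_s": 1.3392,
    "per_slice_s": 1.3,
    "total_s": 41.6
  }
}
```

The report says: one slice is acquired in 1.3 s (TR 9.3 ms × 144 phase-encode
lines; 41.6 s for 32 slices), the k-space weighting broadens the
point-spread function by ~16% relative to uniform weighting, the normalized
weighting differs by at most 7% between species with T1 300 ms and 1400 ms
(confined to the outer k-space lines — the DC weight is exactly T1
independent), and at SNR 50 the echo-time design supports a PDFF standard
deviation of ~1.3% per voxel for magnitude fitting.

An end-to-end phantom run (simulate → fit → bias table → report):

```sh
famfat pipeline --preset 3T --out run_out
```

writes `roi_table.csv`, `bias_table.csv` and `report.json`; with the default
noiseless FAM protocol the maximum absolute ROI bias across all 16
PDFF × T1 vials is below 1% PDFF.

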