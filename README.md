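# pseudoct

Quantitative PET requires attenuation correction (AC): 511 keV
annihilation photons are absorbed and scattered along each line of
response, and without a map of linear attenuation coefficients (a
μ-map, conventionally derived from a co-acquired CT) the reconstructed
tracer concentration is badly biased. `pseudoct` implements a
deep-learning route around the CT: a convolutional encoder-decoder
(CED) is trained to map **non-attenuation-corrected (NAC) PET** slices
directly to continuously valued **pseudo-CT** images in Hounsfield
units, which are then converted to μ-maps and used for AC — so a
quantitative PET image can be produced from the emission data alone.

Because clinical PET/CT data and vendor reconstruction chains are not
shippable, the package closes the whole loop on synthetic data at desk
scale: a seeded head-phantom generator (soft-tissue head, bone skull
shell, internal air cavities, brain-like FDG uptake), an attenuated
parallel-beam projector with Poisson counting noise, and an
ordered-subsets MLEM (OSEM) reconstructor stand in for the scanner.
Every stage is a first-class, tested component.

## Method

* **μ-map from CT** — piecewise-linear scaling:
  μ = μ_w·(1 + HU/1000) for HU ≤ 0 (clamped at air), and
  μ = μ_w + k_bone·HU for HU > 0, with μ_w = 0.096 cm⁻¹ at 511 keV.
* **Forward model** — per line of response
  `E[y] = s · exp(−∫ μ dl) · ∫ a dl`, 2D parallel-beam, slice by slice,
  with optional Poisson draws; OSEM folds the attenuation factors into
  the system model (24 iterations, 3 subsets, 4 mm Gaussian post
  filter by default).
* **Conditioning** — PET scaled by 6000 Bq/ml, CT by (HU + 1000)/2000,
  a per-volume bounding-box crop from the PET object, bilinear
  resampling to the network matrix, and the Softsign map
  x ↦ x/(1+|x|); every step has an exact inverse so predictions come
  back to HU on the source grid.
* **Network** — a VGG-style encoder (conv → batch-norm → ReLU, 2×2
  max-pool per stage) mirrored by a bilinear-unpooling decoder with a
  single-filter output convolution; parameter-free additive shortcut
  connections link each encoder stage to its mirror decoder stage
  (inserted before batch-norm/ReLU, the full pre-activation form), plus
  an input→output shortcut. The full 13-conv-layer configuration
  (64→512 filters, four shortcuts) and reduced desk-scale instances
  share one code path. The stack is implemented in numpy with explicit
  backprop and an Adam optimiser (lr 0.001, mini-batch 12, MSE loss),
  and the checkpoint at the least-loss epoch is kept.
* **Evaluation** — tissue Dice after thresholding (bone > 300 HU,
  air < −400 HU, soft otherwise), MAE in HU, pixel-wise percent error
  `(I_test − I_ref)/I_ref × 100` against the CT-corrected reference,
  and ROI statistics with paired t-tests under a Bonferroni-corrected
  significance level (0.05/21 ≈ 0.0024 for 21 regions).

## Worked example

```python
from pseudoct.pipeline import StudyConfig, run_study

result = run_study(StudyConfig(master_seed=1))
print({k: round(v, 3) for k, v in result.metrics.items()
       if k.startswith(("dice", "mae", "pet", "nac"))})
```

This simulates 48 head phantoms (40 train / 8 held out), reconstructs
NAC PET for each, trains the reduced encoder-decoder for 60 epochs,
synthesises pseudo-CTs for the held-out phantoms and reconstructs
attenuation-corrected PET with them (about 11 minutes on one CPU).
Output at seed 1:

```
{'dice_soft': 0.929, 'dice_bone': 0.838, 'dice_air': 0.993,
 'dice_air_cavity': 0.028, 'mae_hu': 188.5,
 'mae_hu_baseline_all_soft': 253.7,
 'pet_abs_err_pct_pseudo_ac': 9.157, 'pet_abs_err_pct_nac': 64.57,
 'nac_to_pseudo_error_ratio': 7.052}
```

Read: the pseudo-CT recovers the soft-tissue head and the skull (Dice
0.93 / 0.84) and the head–air boundary (whole-volume air Dice 0.99),
beats the trivial "everything is soft tissue" CT on mean absolute HU
error inside the head, and — once used for attenuation correction —
cuts the PET quantification error of the uncorrected reconstruction
seven-fold (9.2 % vs 64.6 % mean absolute error against CTAC).
`dice_air_cavity` is the air Dice restricted to the head interior: at
this desk scale the 5–9 mm sinus-like cavities are *not* recovered,
because their contrast does not survive the NAC reconstruction (see
the limitations section of `docs/methods.md`). `result.roi_table`
holds the per-region signed/absolute percent errors with paired
t-tests.

The same pipeline is scriptable from the shell:

```bash
pseudoct full-run --seed 1 --out runs/demo
pseudoct full-run --seed 1 --out runs/oracle --oracle-pseudo-ct  # closed loop: 0% error
```

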