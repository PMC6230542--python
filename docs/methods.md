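# Methods

This note records the models, conventions and design choices behind
`pseudoct`, in the spirit of a package methods appendix: what is
simulated, what is fitted, which knobs matter, and what the synthetic
results do and do not demonstrate.

## Problem setting

PET attenuation correction needs a μ-map (linear attenuation
coefficients at 511 keV) that is normally derived from a co-acquired
CT. The package implements the alternative studied here: estimate a
continuously valued pseudo-CT from the *non-attenuation-corrected*
(NAC) PET image itself with a convolutional encoder-decoder, convert
it to a μ-map, and reconstruct quantitatively. The reference standard
throughout is CT-based attenuation correction (CTAC) computed with the
same reconstruction code, so discrepancies isolate the pseudo-CT, not
the reconstructor.

## Synthetic phantoms

`phantom.generate_phantom` draws head-like volumes from a seeded
population: an outer soft-tissue scalp ellipse, a closed bone shell
(thickness 5–9 mm), a brain interior with a gray-matter cortical band
and deep-gray nucleus over a white-matter core, and 1–3 sinus-like air
cavities (radius 5–9 mm) in the anterior brain; slice axes taper
toward the volume ends. Defaults are a 64×64 grid, 8 slices, 3 mm
pixels and 6 mm slices — a deliberate desk-scale stand-in for clinical
head volumes; a 200-pixel configuration exists for full-scale runs.

Hounsfield plateaus (air −1000, soft 40, bone 1200, each jittered ±5 %
per phantom) plus band-limited texture (clipped at ±60 HU in soft
tissue, ±250 HU in bone) are placed strictly inside the standard
threshold bands, so thresholding the generated CT (bone > 300,
air < −400) recovers the generator's tissue labels exactly — the
property that makes Dice against ground truth well defined.

Activity levels (Bq/ml): cortical/deep gray 12 000, white matter
4 000, scalp 1 500, bone 300, optional hot lesion 24 000, air exactly
zero; a ±10 % smooth heterogeneity field is applied. These give a
gray:white ratio of 3:1, in the range expected for FDG brain uptake.
Optional abnormalities (a skull-defect sector, a focal hot lesion)
exercise the method's behaviour on out-of-population anatomy.

What the phantoms do **not** model: anatomical atlases, bone-marrow HU
distributions, motion, scatter or randoms. Passing the recovery tests
shows that the pipeline is self-consistent and that the network can
learn the NAC→CT mapping this physics implies — not that it reaches
clinical accuracy on real heads.

## Physics and reconstruction

Geometry is 2D parallel-beam per axial slice: 120 views over
[0°, 180°), radial bins of one pixel width covering the grid diagonal.
The projector is pixel-driven with linear interpolation onto the two
neighbouring bins and a constant per-pixel path length (pixel size in
cm). Consequences used by the tests: projection preserves mass at
every view, forward and back projection are exact transposes, and an
axis-aligned ray reproduces the hand-computed `a·l·exp(−μt)` value.

Attenuation uses the standard PET factorisation — one `exp(−∫μ dl)`
factor per full line of response — applied identically when simulating
counts and inside the OSEM system model, which is what makes the
closed-loop oracle (pseudo-CT ≡ true CT ⇒ bitwise-identical
reconstruction) an exact identity rather than an approximation.

OSEM: interleaved angle subsets (angle *i* → subset *i* mod *m*),
uniform positive initialisation, multiplicative updates with an
ε = 1e−12 ratio guard, rays with zero sensitivity excluded; defaults
24 iterations / 3 subsets with a 4 mm FWHM Gaussian post filter,
matching a standard clinical brain protocol. NAC images use the same
protocol without the attenuation factors. The reconstruction is
calibrated: the sinogram records its count scale, so converged images
return to Bq/ml and CTAC agrees with the true activity up to
partial-volume blur. The default count scale yields ≈2×10⁵ expected
counts per slice. Scatter and randoms are not simulated, so no scatter
correction exists to omit.

## Conditioning and its inverse

PET is divided by 6000 Bq/ml; CT is mapped by (HU + 1000)/2000 — the
offset is chosen so the air floor lands exactly at 0. One bounding box
per volume (union over slices of pixels above 1 % of the PET maximum,
2-pixel margin) is computed from the PET object and applied to both
modalities, keeping the slice stack geometrically consistent for 3D
reassembly. Slices are resampled to the network matrix with
corner-aligned bilinear interpolation and compressed with Softsign.
Softsign is applied to inputs *and* targets, so the two modalities
share a dynamic range and "scale the output back to HU" is the exact
inverse chain: clip to (−1, 1), invert Softsign, undo the CT scaling,
resample into the crop box, fill outside with air. The round trip is
exact to ≪1 HU at matched resolution.

## Network

Encoder stages are (n_conv, filters) unit layers of convolution →
batch-norm → ReLU followed by 2×2 stride-2 max-pooling; the full
configuration is the 13-convolution VGG16 ladder
(2,64)(2,128)(3,256)(3,512)(3,512). The decoder mirrors the stages
with ×2 bilinear un-pooling; its first convolution per stage maps into
the mirror stage's width, the output layer is a single-filter
convolution. Shortcuts are parameter-free elementwise additions from
each encoder stage's pre-pool feature map into the mirror decoder
stage, inserted after that stage's first convolution and **before**
its batch-norm and ReLU (full pre-activation); one per inter-stage
boundary (four in the full configuration). A final shortcut adds the
input image to the output — both live in the Softsign domain, where
the addition is well defined, and it gives the network an exact
identity path (zeroing the output convolution reproduces the input
bit-for-bit, a tested contract).

Input sides must divide by 2^n_stages; the 200×180 interface matrix is
zero-padded (at the normalised-air value) to 224×192 and cropped back.
Weights are He-normal (std √(2/fan_in)), batch-norm starts at scale 1 /
shift 0 with running-statistic momentum 0.99; inference uses running
statistics and is deterministic.

The stack is plain numpy (im2col convolutions over BLAS, explicit
backward passes, exact adjoints for pooling and un-pooling) with Adam.
Working precision is float32; a float64 mode exists and is used by the
finite-difference gradient check, which validates every parameter
class of the assembled network.

## Training and model selection

MSE in the Softsign domain, Adam at a fixed learning rate of 0.001,
mini-batches of 12 slices, seed-shuffled epochs; with 4 800 training
slices, 50 epochs correspond to exactly 20 000 updates. A checkpoint
is taken each epoch and the least-training-loss epoch is returned
(ties → earliest); an optional held-out selection split exists but is
off by default, training-loss selection being the literal protocol.
The desk-scale recovery study trains a reduced three-stage network
(stages (1,16),(1,32),(2,64), ≈158 k parameters) on 40 phantoms
(320 slices) for 60 epochs — chosen because the cavity-scale detail is
the last feature to converge and the loss has plateaued by then at
this problem size.

## Evaluation

Dice per tissue class after strict thresholding; for internal air
cavities, the air Dice is additionally computed inside the true head
mask (non-air tissue with per-slice hole filling), since whole-volume
air Dice is dominated by the background. MAE is reported over the head
mask; the comparison baseline is the trivial pseudo-CT that paints the
whole head soft tissue. PET percent-error maps exclude voxels whose
reference intensity is below 1 % of the reference maximum (the
percent error is undefined near zero). ROI statistics summarise
subject-level ROI means (mean ± sd, min, max of signed and absolute
error) over the phantom-defined regions, with two-sided paired
t-tests on ROI-mean activities; zero-variance differences report
p = 1 (degenerate t). The Bonferroni threshold is α/m with m the
number of ROIs (0.05/21 ≈ 0.0024 with a 21-region atlas). Whether the
pooled summary row aggregates voxels or ROI means is ambiguous in
general; the package reports the pooled-over-ROI-means version,
labelled `all_regions`.

## Numerical and degenerate-case conventions

Both-empty Dice is defined as 1 (vacuous agreement, logged). Exact
threshold values fall to soft tissue. `inverse_softsign` refuses
|y| ≥ 1; network outputs are clipped to 1−1e−9 before inversion.
Sinograms with realised noise must hold integers. Volumes are
(rows, cols, slices) with the axial axis last, boxes are 0-based
half-open, μ is in 1/cm with mm spacing converted internally. One
master seed fans out into named substreams (phantom geometry per
index, projection noise per phantom, weight init, epoch shuffle), so
datasets are reproducible under reordering and any stage can be rerun
in isolation; two runs with the same configuration are bit-identical.

## Known limitations

No time-of-flight, PSF modelling, scatter/randoms simulation, 3D
(septa-less) projection, or learning-rate schedules. The NAC and
corrected reconstructions share one OSEM implementation (clinically,
NAC protocols differ, e.g. in time-of-flight usage). Phantom realism
is deliberately minimal; desk-scale Dice/MAE numbers characterise this
synthetic population only and are not comparable to values measured on
clinical cohorts.

A concrete desk-scale limit the package's own evaluation exposes: the
5–9 mm internal air cavities are not recovered (head-interior air Dice
≈ 0.03 in the recovery study). This is an information limit of the
study conditions rather than a training failure — a threshold detector
applied directly to the NAC image, even without Poisson noise, reaches
at most ≈ 0.06 on the same metric, i.e. the cavity contrast (a ~30 %
local dip over two to three pixels) is erased by the reconstruction
chain before the network ever sees it. Soft tissue, skull and the
head–air boundary, whose spatial scales exceed the reconstruction
resolution, are recovered well. At clinical resolution real sinuses
span several times more voxels, so this limit is specific to the
64×64 / 3 mm desk configuration.
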