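# Methods

## Problem and model

`petmip` classifies lymphoma subtype surrogates from two maximum-intensity
projections (anterior and lateral) of an ¹⁸F-FDG PET volume plus a vector of
routine clinical variables, in the presence of scanner-manufacturer batch
effects. The pipeline is: DICOM/NIfTI activity volume → body-weight SUV →
MIP per view → resize-with-padding to a square → per-image min-max
normalization → shared-weight CNN encoder → scanner-conditioned
normalization (SCN) of each pooled view embedding → concatenation with a
three-layer clinical encoder → classifier head → sigmoid probability.

### SUV conversion

Raw stored values are converted to activity with the DICOM rescale slope and
intercept (negatives clamped to zero, counted in the log). The injected dose
is decay-corrected to the acquisition start, dose = dose₀·2^(−Δt/T½) with
T½ = 6586.2 s for ¹⁸F (overridable in the metadata); true attenuation
correction is assumed already applied by the scanner, as is standard for
clinical PET exports. SUVbw = activity × weight × 1000 / dose assumes 1 g/mL
tissue density.

### Geometry

Volumes are indexed (z, y, x) with z inferior→superior, y
anterior→posterior, x patient-left→patient-right. The anterior MIP is the
maximum over y (a z×x image), the lateral MIP the maximum over x (z×y);
both are emitted head-up. Resizing scales the longest side to the target
(310 px at full scale; tests and studies use 32–64 px), bilinear, then
zero-pads symmetrically to a square. Min-max normalization is per image;
a constant image maps to zeros (the 0/0 case is defined away). No SUV
windowing is applied before normalization by default; a configurable cap
exists but is off.

A consequence asserted in the tests: per-image min-max normalization exactly
cancels any global multiplicative scanner gain. The batch effects that
survive — and that SCN targets — are the non-multiplicative ones:
point-spread blur and noise texture.

### Scanner-conditioned normalization

For a pooled embedding x of one item, SCN standardizes instance-wise with
the population mean/variance over the feature axis and recalibrates with
manufacturer-indexed learnable tables:

x̂ = (x − μₓ)/√(σₓ² + ε),  y = x̂ ⊙ γₛ + βₛ,  ε = 10⁻⁶.

γ starts at ones, β at zeros (identity recalibration). Statistics are never
pooled across items, so train/eval behaviour is identical and
batch-size-independent; with all rows tied, SCN is exactly layer
normalization with affine parameters. SCN is applied once, to the pooled
embedding of each view (shared tables across views); inserting it at
several backbone stages was considered and rejected for this build — the
post-pooling location is where vendor statistics concentrate after global
average pooling, and a single site keeps the parameter count per vendor at
2D. A manufacturer absent from training has no learned row: prediction
raises by default, or, on explicit opt-in (`unseen_manufacturer="mean"`),
substitutes the mean of the learned γ and β rows. The external-cohort
evaluations in this package use that fallback deliberately, to measure
generalization to a vendor never seen in training — the hardest case.

### Network and training

The shipped backbone is a four-block strided CNN (3×3 conv, stride 2, ReLU;
channels 8–16–32–64) with global average pooling — sized so CPU training on
64×64 inputs takes seconds per epoch. The ImageNet-scale backbone names are
accepted in the configuration but raise immediately: they need a GPU
deep-learning stack this package deliberately does not depend on; every
gradient here is hand-derived and finite-difference-verified. The clinical
encoder is exactly three dense layers (ReLU, default widths 64-32-16).
Anterior and lateral share backbone weights; their embeddings are
concatenated, then joined by the clinical embedding and passed to a small
dense head (one logit, clamped to ±15 before the sigmoid).

Loss is mean class-weighted binary cross-entropy; "auto" weights are
w_c = n/(2n_c). Optimization is AdamW (default lr 10⁻³, weight decay 10⁻⁴,
batch 32). A validation split (20%, label-stratified, carved from the
training cases only) drives early stopping (patience 5, best-epoch weights
restored) and reduce-on-plateau scheduling (×0.5 after 3 stale epochs).
Model selection in the grid search uses validation AUC, ties broken by
validation loss then enumeration order. Every random draw flows from
explicit seeds; two runs with the same configuration and seed are
bit-identical.

### Evaluation statistics

AUC is the Mann–Whitney statistic computed from midranks (ties count ½).
Sensitivity/specificity/MCC are taken at threshold 0.5 on the probability
(a Youden-optimal threshold chosen on validation data is available behind a
flag); the MCC zero-denominator convention is 0, logged. Confidence
intervals are percentile bootstrap, B = 1000, with class-stratified case
resampling so every resample contains both classes. Cohort comparisons
follow the structure of the data: independent cohorts (internal vs
external) use the unpaired DeLong test with the variance from each cohort's
structural components (V₁₀, V₀₁); two models on the same cases use a paired
bootstrap of the AUC difference with p = 2·min(P(Δ*≤0), P(Δ*≥0)).

### Grad-CAM

Heat maps tap the final convolutional stage (the standard choice): channel
weights are spatially averaged gradients of the class-1 logit (negated for
class 0), the map is the rectified weighted sum of feature maps, bilinearly
upsampled and max-normalized. Localization is quantified as the fraction of
the top-10% hottest pixels inside the lesion mask projected through the
same MIP/resize geometry; 10% is a fixed choice, and because the score is
bounded above by mask-area/0.1 it is compared against the chance level (the
mask's area fraction) as a ratio, not an absolute margin.

## The synthetic phantom

The phantom emulates what the pipeline needs and nothing more: an
ellipsoidal body at background SUV 1, lesions as isotropic Gaussian blobs
truncated at half maximum (the half-max voxels form the ground-truth mask),
per-vendor gain/blur/noise signatures, DICOM-equivalent metadata (weight
~N(70, 12) kg, dose ~N(370, 40) MBq, uptake ~N(60, 7) min, int16 rescale
encoding that round-trips to one quantization step), and class-correlated
clinical covariates drawn around adult-lymphoma population values with
configurable standardized mean shifts. Default class prevalence is 1:5
(minority class 1), stages 1–4 with multiplicities (1–2, 2–4, 3–6, 5–9)
lesions.

Class signal enters through three configurable channels: lesion contrast
(per-class mean peak SUV), spatial pattern (class 0 forms a contiguous,
supradiaphragmatic-leaning chain with a narrow anterior–posterior spread —
visible only in the lateral view — class 1 is dispersed), and the clinical
shifts (defaults: LDH +0.9 SD, NLR +0.6, age +0.4, ALC −0.4, Hb −0.3,
plus class-dependent Deauville probabilities). Per-class lesion size is
also available and is used by the localization study, because lesion extent
is the only planted signal that is strictly lesion-local. Everything can be
switched off: with identical lesion parameters, shared spatial priors and
zero clinical effects, a trained model sits at chance (asserted in the
tests).

Vendor signatures default to gains 0.9–1.3, PSF blur σ 2–6 mm and noise CV
0.05–0.18 across four manufacturers — a realistic inter-vendor spread.
Noise is log-normal with unit mean so activity stays positive.

Two named study conditions freeze the cohorts the ablation experiments use:

* **Harmonization study** (`scn_study_phantom`): strong image signal
  (class means 5 vs 7 SUV, tight chains) over four vendors, one held out as
  the external site — there is substantial image information for SCN to
  harmonize, mirroring an image-driven classifier deployed across vendors.
* **Modality study** (`modality_study_phantom`): weak anterior-visible
  contrast (5 vs 5.4), a strong lateral-only anterior–posterior dispersion
  signature, default clinical shifts — each added modality carries
  genuinely new information, so the anterior ≤ dual-view ≤ multimodal
  ordering has a planted mechanism.

### What the phantom does not emulate

No attenuation/scatter physics, no sinogram-level reconstruction, no
anatomy (organs, physiologic uptake, bladder/brain hot spots), no
inter-institution protocol variation beyond the vendor signature, and
missingness only as missing-completely-at-random. Passing tests therefore
demonstrate that the machinery is correct and that the harmonization and
fusion mechanisms behave directionally as designed under controlled batch
effects — not that the specific accuracy levels transfer to patient data.

## Problem sizes and numerical choices

The ablation studies run five seeded 400-case cohorts at 64×64 image
resolution with the small CNN (25 epochs max, patience 5) — sizes chosen so
the full suite and the acceptance script each complete in minutes on one
CPU while leaving the directional effects clearly resolved. Calibration
studies use 1000 null simulations (DeLong type-I at binormal AUC ≈ 0.76)
and 500 coverage simulations at n = 200, B = 1000. Degenerate cases are
defined explicitly rather than silently: zero-variance clinical variables
are dropped with a warning, constant images normalize to zero, empty lesion
masks make the localization score an error, single-class inputs are
rejected by every metric, and a divergent training loss aborts with
diagnostics.

## Known limitations

* The small CNN is not an ImageNet backbone; absolute AUCs on the phantom
  say nothing about clinical performance.
* The SCN mean-row fallback for unseen vendors is a heuristic; with many
  trained vendors a learned prototype or nearest-vendor scheme might do
  better.
* Percentile bootstrap CIs slightly undercover at the sample sizes studied
  (≈0.93–0.96 empirical for nominal 0.95), a known property of the
  percentile method.
* The phantom's clinical covariates are independent given the class; real
  laboratory panels are correlated.
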