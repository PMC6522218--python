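# Methods

This note records the scientific conventions behind `liverlesion`: the
model and its assumptions, the parameter defaults and why they were
chosen, what the synthetic phantom does and does not emulate, and the
numerical decisions that make the test suite exact.

## Problem setting

Focal liver lesions are routinely characterized on abdominal MRI from
their enhancement kinetics after an extracellular contrast agent
(dynamic contrast-enhanced, DCE, series), their T2-weighted brightness,
and patient context: cysts do not enhance and are strongly T2-bright;
hemangiomas fill in slowly from the periphery; adenomas enhance in the
arterial phase without washout; HCCs enhance arterially and wash out, and
arise predominantly in cirrhotic livers; metastases show portal-venous
ring enhancement and imply a known primary tumor. The package turns these
visual criteria into a reproducible feature vector per lesion and a
five-class tree-ensemble classifier.

Inputs per patient are a motion-corrected DCE series (the package assumes
co-registration has already happened), a T2-weighted image, single-slice
lesion and healthy-parenchyma masks, an aortic ROI, and three binary risk
flags (steatosis, cirrhosis, known primary tumor). All feature
computations are 2D, matching single-slice annotations; lesions smaller
than 3×3 pixels are rejected because texture statistics on them are
unreliable.

## Preprocessing

**Intensity standardization.** Each DCE series is linearly remapped so
that 0 is the scanner background and 1 is the maximum over time of the
mean intensity in the aortic ROI. The background level is fixed at 0
rather than the image minimum; the aortic peak maps to exactly 1 and
higher values are deliberately not clamped. A series whose aortic peak
does not exceed the background is rejected as degenerate. T2 images are
never normalized: a cyst brighter than spinal fluid is diagnostic
information that a per-image rescaling would destroy.

**TIPS filtering.** Before any curve is read, voxel time profiles are
smoothed with a bilateral filter whose range term is the Euclidean
distance between whole time-intensity profiles (time-intensity-profile
similarity). The window is square with half-width
`ceil(2 σ_spatial / pixel_spacing)` pixels, shrinking at image borders;
weights are normalized per voxel, so spatially constant series are exact
fixed points. Defaults: σ_spatial = 2 mm, σ_profile = 0.15 normalized
intensity units — strong enough to suppress the phantom's acquisition
noise, weak enough that enhancing/non-enhancing boundaries survive (the
profile term sees a rim-versus-centre profile difference of ~0.3 units as
effectively infinite). Both are configuration keys. Curve features and
the TTP map are computed on the filtered series; image histograms and
texture are computed on the normalized, unfiltered frames, since spatial
smoothing would bias exactly the statistics (SD, contrast, entropy) that
texture analysis is after.

## Feature definitions

**Kinetic descriptors.** The eight descriptors of a curve with values
`v[t]` and baseline `c0 = v[0]` are: maximum enhancement
`ME = max(v) − c0`; time to peak `TTP` (earliest maximum); time of
arrival `TOA` (earliest time with `v − c0 ≥ 0.1·ME`; defined as TTP when
ME ≤ 0); uptake rate `ME / max(TTP − TOA, Δt)`; washout rate
`(v[TTP] − v[end]) / max(t_end − TTP, Δt)`; trapezoidal AUC of `v − c0`;
average plateau (mean of the last three values minus `c0`); and SER, the
mean early enhancement (time points 2–4) over the average plateau (with a
1e-6 guard). `Δt` is the first inter-frame interval, which keeps both
rates finite when a curve peaks at the first or last frame. These are
reconstructions of descriptors that are standard in breast-DCE radiomics
but have no single canonical formula; every threshold sits in the
configuration.

**Curves.** Per-pixel CECs divide each pixel TIC by that pixel's
pre-contrast value (ε = 1e-6 guards empty denominators). Average curves
are pixel means per time point. The lesion/parenchyma ratio curves are
defined on the ROI-average curves; for the within-lesion SD features a
per-pixel CE ratio (pixel CEC over average parenchyma CEC) is used,
because an SD needs per-pixel values to exist.

**Phase selection.** Acquisition protocols rarely label frames, so two
conventions pick the phase images: the *late arterial* frame is the frame
after the aortic peak, and the *portal-venous* frame is the frame nearest
70 s after the aortic time of arrival. Both are overridable indices in
the extraction configuration.

**Radial gradient.** Each masked voxel contributes
`(I(v) − I(c)) · dist(v, c)` with `c` the masked pixel nearest the mask
centroid; values are min–max normalized to [0, 1] per lesion (a
homogeneous lesion maps to all zeros). Note that per-lesion min–max
normalization makes the *absolute* level of these values less meaningful
than their distribution shape; the six histogram statistics are the
features.

**Ring enhancement.** 360 rays (1° spacing) are cast from the central
pixel; intensities are sampled every half pixel with bilinear
interpolation out to the mask edge plus two pixels (truncated at the
image border). The sample with the maximum absolute first derivative
(forward difference) marks the strongest enhancement transition; its
distance from the centre is divided by the distance to the *mask edge*
and clipped to [0, 1]. Normalizing by the mask-edge distance (rather than
the search length including the 2-px margin) is what makes the score
interpretable: a bright rim at the lesion boundary scores ≈ 1 on every
ray, and an annulus at half the radius scores ≈ 0.5. The derivative
magnitude is used so the descriptor finds the rim whichever side of it
the intensity falls off. Because any lesion that contrasts with
parenchyma has *some* boundary transition, the mean saturates near 1 for
many lesion types; the discriminative signal lies in lesions whose
strongest transition is interior (fill-in hemangiomas) and in the
across-ray SD (heterogeneous enhancement).

**Histogram statistics.** Mean, sample SD (ddof = 1), skewness and excess
kurtosis with the population-moment (biased) estimators — chosen so test
values are exact — and linear-interpolation percentiles. A constant
sample has skewness and kurtosis defined as 0.

**Texture.** ROI intensities are quantized into 32 equal-width bins over
the ROI's own min–max range (ROI-local, because T2 is unnormalized; a
flat ROI maps to level 0). The GLCM sums symmetric co-occurrence counts
over the four principal directions at offset 1 px, restricted to pairs
with both pixels inside the mask, and is normalized after summation. The
13 Haralick statistics use base-2 logarithms with `0·log 0 = 0`; sum
variance is taken about the sum average, difference variance about the
mean of the difference distribution, correlation is 0 for a degenerate
marginal, and `IMC2 = sqrt(max(0, 1 − 2^(−2(HXY2 − HXY))))`. The
across-series texture variance is the population variance of each feature
over the per-frame GLCMs, each frame quantized on its own range so gain
changes do not masquerade as texture change.

**Inventory calibration.** A straightforward enumeration of the feature
plan gives 168 image-derived features (48 curve + 42 histogram + 78
texture). The default `paper164` inventory drops the four least
well-defined heterogeneity descriptors — the SDs of the washout rate and
of the time of arrival for the CEC and CE-ratio pixel curves, which are
dominated by tie-breaking on noisy pixel curves — to yield a 164-feature
image inventory; `full168` keeps all. Uncomputable features on degenerate
ROIs are set to 0 and logged; tree ensembles tolerate neutral fill-ins.
Risk factors enter as 0/1 flags and the lesion area as
`pixel count × pixel area` in cm².

## Classifier and evaluation

The ensemble is scikit-learn's `ExtraTreesClassifier` behind the
package's own configuration surface: 700 trees, minimum 5 samples per
leaf, `round(√k)` features per node (7 for the 50-feature model, 4 for
the 19-feature ablation models), per-sample weights inversely
proportional to the training-fold class frequency, and a deterministic
per-fold seed (master seed + fold index). Univariate one-way ANOVA
F-scores (implemented directly; cross-checked against
`sklearn.f_classif`) rank features, the top k = 50 are kept, and — the
part that matters for honesty of the estimate — this selection is redone
inside every leave-one-patient-out fold. Folds whose training part lost
an entire class are skipped with a warning; with realistic cohort sizes
this never happens.

Evaluation mirrors the reference report exactly, including its
unconventional per-class "specificity", which is numerically the
column-wise positive predictive value (diagonal over predicted-column
total). It is implemented under the name `specificity_as_printed`, and
the textbook TN-based specificity is reported alongside. Reported values
are rounded half-away-from-zero to two decimals; raw values are kept. Of
note, the one-vs-other accuracy of the cyst class recomputes to
209/213 = 0.98 from the published matrix while the published table prints
0.99; the package reports the recomputed value and makes no attempt to
force agreement. ROC analysis is one-vs-rest on the fold probabilities
(`p_k` against the pooled rest), AUC by the trapezoid over the threshold
sweep, operating point by Youden's J with the lowest threshold on ties;
the benign/malignant ROC scores each lesion by `p_HCC + p_metastasis`.

## The phantom

The phantom exists to give every stage a ground-truth cohort with the
class structure the classifier assumes. One "volume" is a single 64×64
slice at 1.5 mm pixel spacing; the DCE series is 16 frames at 12 s
spacing (0–180 s) — the frame count matches the clinical protocol the
pipeline targets, the timing is a convention since acquisition times are
protocol-dependent. Voxel kinetics follow per-class piecewise-linear
templates (baseline, linear rise to the peak, linear decline losing
`washout_fraction` of the peak by the series end) plus white Gaussian
noise (default SD 0.02 in normalized units, ~3% of a typical lesion
peak); the same noise, scaled ×400, perturbs the T2 image, whose
intensities live on a scanner-like scale of hundreds. The aorta is
rendered to peak above every tissue voxel so normalization is well
defined; the liver background follows a portal-peaking parenchyma
template.

Spatial patterns: metastases render their enhancing ring as a 2-px band
straddling just *outside* the mask boundary with a damped (×0.35)
interior — portal-venous rim enhancement sits at the lesion margin, and
this placement is what makes the ring descriptor score ≈ 1 there;
hemangiomas (fill-in) enhance their outer ~1.5-px in-mask layer on the
template clock and delay the centre's peak by 60 s (the rim template
keeps a mild 10% washout so its time to peak survives TIPS smoothing
adjacent to the delayed centre); all other classes are homogeneous.
Risk flags are drawn per patient from class priors (cirrhosis 0.8 for
HCC patients else 0.05; primary tumor 0.9 for metastasis patients else
0.1; steatosis 0.2 throughout) — informative but deliberately not
deterministic. Cohorts allocate lesion classes by largest remainder
against the configured class mix (default uniform), 1–4 lesions per
patient, and are pure functions of the seed.

What the phantom does **not** emulate: k-space acquisition and MR
artifacts, pharmacokinetic compartment kinetics (the templates are
shape-level descriptions), breathing motion and registration error, 3D
structure, lesion-appearance overlap between classes, and intra-class
biological variability beyond placement/size/noise. Consequently the
phantom classes are *strongly* separable by construction: the pipeline
reaching ~1.0 LOPO accuracy on the default 50-patient cohort validates
the plumbing and the absence of leakage, not clinical performance, and no
clinical claim should be read into phantom accuracies. The separability
knob (templates differing only in peak amplitude) exists precisely to
show accuracy degrading gracefully as class contrast shrinks toward the
noise floor.

## Problem sizes and numerical conventions

The shipped evaluation cohort is 50 patients (~125 lesions), which the
full pipeline (TIPS filtering, 168 features per lesion, 50 LOPO folds of
700 trees) processes in well under a minute; the test suite uses smaller
cohorts (10–16 patients) for ordering properties and oracle comparisons
at 5×5 to 10×10 fixtures. Tie-breaks are deterministic throughout:
earliest time on curve maxima, lowest index on equal ANOVA scores, lowest
threshold on equal Youden J. Division guards (ε = 1e-6) protect the CEC,
ratio curves and SER; degenerate statistics (flat ROIs, zero-variance
marginals) are defined as 0 rather than NaN so feature vectors never
carry missing values.

## Known limitations

- The kinetic-descriptor formulas and the TIPS kernel parameters are
  documented reconstructions, not published constants; results depend on
  them through the configuration defaults.
- The exact composition of a 164-feature inventory cannot be derived
  uniquely from the feature plan; the `paper164`/`full168` switch makes
  the calibration explicit instead of hiding it.
- Per-lesion min–max normalization of the radial-gradient histogram
  discards absolute scale; an alternative direction-cosine formulation
  exists in the literature but is not implemented.
- The phantom's 2D, noise-only variability makes phantom accuracies an
  upper bound with no clinical meaning (see above).
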