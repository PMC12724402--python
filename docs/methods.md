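# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `perceptseg`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The task and its data

One experimental *block* is one participant segmenting one image into a
prescribed number K of perceptual segments (K = 2…5).  Each trial cues two
image locations and records a binary same/different judgment plus a reaction
time.  Analyses operate on a 15×15 grid over the 256×256-pixel image; grid
cells are the uniform partition with half-open edges (the last edge closed),
so every in-image pixel maps to exactly one cell.  The minimal schedule is
`cells · (K−1)` trials — one independent constraint per free probability per
cell — giving 225/450/675/900 trials for K = 2…5.

## Map estimator

Each cell *i* holds a probability vector *p<sub>i</sub>* ∈ Δ<sup>K−1</sup>.
A trial cueing cells *i*, *j* is modeled as Bernoulli with
P(same) = Σ<sub>k</sub> p<sub>ik</sub>p<sub>jk</sub> — the probability that
independent label draws from the two cells coincide.  The objective is the
log-likelihood minus λ·Σ<sub>4-neighbor pairs</sub>‖p<sub>i</sub>−p<sub>j</sub>‖²,
with λ = 5 (the smoothing strength used for the human data this design
follows).  This pairwise-likelihood-plus-smoothness form is the simplest
model consistent with the construct; it is a faithful but independent
estimator, not a port of any existing implementation.

Numerics:

- Cells are parametrized by unconstrained scores through a softmax, so the
  simplex constraint is implicit and the gradient is analytic (verified
  against finite differences, max abs. error ≈ 2.5·10⁻⁷).
- Optimization is L-BFGS (scipy), stopping at relative objective change
  < 1e-6 or 2000 iterations; predicted probabilities are clipped to
  [1e-9, 1−1e-9] inside logs; the returned map is renormalized to machine
  precision.
- Initialization is uniform probabilities plus seeded score noise of
  magnitude **0.5**.  The uniform point is a label-symmetric saddle; with
  very small init noise (e.g. 1e-2) the relative-change stopping rule fires
  while the optimizer is still crossing the flat neighborhood of the saddle
  and the fit stalls near-uniform.  Noise of 0.5 clears the saddle in ~150
  iterations; the recovered map is invariant (after label matching) to the
  initialization seed.
- Segment labels are arbitrary.  For evaluation against a known ground
  truth only, labels are matched by solving the assignment problem on the
  confusion matrix; participant-facing outputs are never relabeled.

Degenerate inputs behave sensibly: all-"same" responses collapse to a
single-label map (the smoothness term breaks ties), and non-convergence is
reported through a diagnostics flag rather than an exception.

## Entropy, uncertainty, and Information Gain

All information quantities use base-2 logarithms.  Per-cell uncertainty is
the Shannon entropy of *p<sub>i</sub>* (0·log 0 := 0), bounded by log₂K; a
map's summary uncertainty is the mean entropy expressed as percent of that
bound (the bound depends on K, so percent-of-maximum is the comparable
scale across blocks).

Map similarity: MI of the joint label histogram over co-located cells, with
empty joint bins contributing zero.  MI is symmetric and invariant to
relabeling; the implementation is tested against a brute-force double sum on
an exhaustive small-grid corpus at 1e-12.  The permutation null shuffles the
spatial locations of one map's values (marginals preserved), 10,000 draws by
default, and

    IG% = 100 · (MI_obs − mean MI_null) / mean MI_null.

The add-one convention p = (1 + #{null ≥ obs})/(n_perm + 1) keeps p in
(0, 1].  When the null mean is zero (a constant map carries no information)
the result is flagged degenerate with IG = 0 rather than raising.  Note that
mean MI_null is the finite-sample MI bias of independent maps
(≈ (K−1)²/(2N ln 2) bits for N cells), which is why genuinely shared
structure produces IG in the 10³–10⁴ % range.  Continuous maps (entropy
maps) are quantized into 8 equal-width bins over the pooled range of both
maps before MI — MI needs discrete marginals, and pooling the range makes
identical maps quantize identically.

## Structureless-block exclusion

Participants who ignore the task produce responses unrelated to the cue
positions; their blocks must be excluded.  A map-space test ("is the fitted
map spatially structured?") is unreliable for two reasons found during
development: (i) MI(map, map) equals the map's label entropy and exceeds
every spatial-shuffle null value for *any* non-constant map, so self-IG is
always significant; and (ii) the smoothness penalty makes even
random-response fits break symmetry into large, reproducible domains —
estimator bias that map-space nulls mistake for structure.

The implemented criterion is therefore *response-space*: split the block's
trials into odd and even halves, fit a map to each, and let each half-map
predict the held-out half's responses.  The observed out-of-sample Bernoulli
log-likelihood is compared with a permutation null that shuffles the
held-out responses across trials (add-one p; default 1000 permutations; a
single-label fitted map is flagged outright).  A genuine segmenter's
held-out responses are predictable (small p); random responding is
unpredictable regardless of what structure the estimator hallucinates into
each half, so p > α flags the block.  On synthetic data this separates
cleanly (see `tests/test_acceptance.py`): response-shuffled surrogates and
full-lapse observers are flagged, reliable observers are retained.

## Reaction times

- **Slow-tail filter**: trials with log RT strictly above the within-block
  90th percentile are dropped.  The percentile uses linear interpolation
  between order statistics (no convention is canonical; this is numpy's
  default and is recorded here).  The filter is applied per block by
  default, with a pooled variant behind a flag.  The removed set is
  invariant to the log base and to unit rescaling.
- **Medians** carry 95% percentile-bootstrap CIs with 9,999 resamples.
  Bootstrap draws resample the sorted values so that the interval depends
  only on the empirical distribution, making medians and CIs exactly
  invariant to trial reordering.
- **z-scoring** standardizes each participant×stimulus block to mean 0,
  SD 1 before pooling, removing stimulus- and presentation-specific scale
  confounds; zero-variance blocks are flagged and excluded from pooling.
- **Learning curve**: RT = α·2^(−t/τ) fitted by nonlinear least squares in
  linear RT space (scipy `curve_fit`, positivity bounds, p0 = (max RT,
  span/4)).  τ is the trial count that halves RT; the fit is
  scale-equivariant (α scales, τ invariant).  With multiplicative lognormal
  noise the absolute-error objective weights early trials most, which is
  where the decay is identified; recovery simulations in the test suite
  bound the median τ error.
- **Inconsistency delay**: mean RT(inconsistent) − mean RT(consistent) with
  a within-class percentile bootstrap; single-trial classes yield a point
  estimate flagged degenerate.

## Gaze

Streams are 500-Hz samples; each retained sample carries exactly one
sampling interval (2 ms) of dwell — no fixation/saccade parsing, since the
analyses are density-based.  Cleaning removes blink-flagged samples and
samples outside the image.  The dwell map convolves the per-pixel dwell
histogram with an isotropic Gaussian (σ = 10 px, truncated at 4σ).  Border
handling: each sample's weight is pre-divided by its kernel's in-image mass
(computed by smoothing a ones-image), which renormalizes every kernel within
the image and conserves total dwell to machine precision through both
smoothing and the mass-preserving 15×15 downsampling.

Coverage is **threshold-free visitation**: the percent of 15×15 cells
containing at least one cleaned sample within a cumulative window from
viewing onset.  A density-threshold variant exists behind a parameter, but
visitation is the parameter-free choice and preserves cohort ordering
logic.  One consequence, quantified by the generator's own simulations: at
windows shorter than ~3–4 s coverage is limited by the number of fixations
made, not by their scatter, so scatter manipulations order coverage reliably
only from mid-windows on (the per-window ordering test starts at 4 s;
full-epoch coverage and whole-curve means order at any realistic contrast).

## EEG

Epochs are consumed cleaned (preprocessing such as filtering, bad-channel
repair, ICA and epoch rejection happens upstream): channels × time × epochs
in μV at 512 Hz, −500…1000 ms around trial onset, with per-epoch RTs.

- Epoch exclusion: drop the slowest ⌈0.1·n⌉ epochs (ties broken by epoch
  order), then any epoch with RT > 2.5 s — in that order.
- Average reference subtracts the cross-channel mean per time point; GFP is
  invariant to it, ERPs are not.
- Baseline correction subtracts each channel's mean over −100…0 ms (a
  −25…0 ms variant avoids contamination from the previous trial's response;
  the two differ only by a per-channel constant per epoch).
- ERPs average epochs, then optionally a named channel subset (the
  occipital/parieto-occipital set O1, Oz, O2, PO7, PO3, POz, PO4, PO8 for
  the visual analyses); aggregation to cohort level weights each
  participant equally regardless of block count.
- Pointwise cohort tests are Welch (unequal-variance) two-sample t-tests at
  every time sample — the robust default when only "independent-samples
  t-test" is specified — with contiguous p < 0.05 runs shorter than 50 ms
  discarded as transients.  Degenerate-variance time points get p = 1.
- GFP is the spatial standard deviation across electrodes (population
  convention, matching the formula √mean((amplitude − mean amplitude)²)),
  computed per participant and tested at 50-ms-sampled time points,
  uncorrected.
- Topographic frames take nearest-sample channel values, clipped to ±10 μV
  for display while retaining raw values.
- The cluster permutation test thresholds |t| at the two-sided p < 0.05
  quantile (conservative df = min group size − 1), forms same-sign clusters
  over temporal contiguity and Delaunay channel adjacency, scores them by
  summed t, and permutes cohort labels with a max-|mass| null and add-one
  p-values.  It is implemented in-package because the p-value and threshold
  conventions above are pinned; no multiple-comparison correction is applied
  to the pointwise/GFP tests (the cluster test is the corrected
  alternative).

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

- **Ground truths**: seeded Voronoi partitions of the grid; site sets whose
  smallest region falls below half an equal share are redrawn, since
  perceptual segments occupy substantial image area and a few-cell sliver
  is unresolvable at the minimal schedule.
- **Textures**: a single white-noise image filtered through per-region
  oriented band-pass filters (Fourier-domain Gaussian in radial frequency
  and orientation), blended through softened region masks so seams are
  continuous.  Orientation parameters denote the spectral peak direction
  and are verified by a Fourier-peak oracle.
- **Observers**: each cue samples its cell's label (true label with
  probability `certainty`, else uniform over the rest); "same" iff the
  samples match; a `lapse`-probability coin flip overrides the response.
  RT = (floor + α·2^(−t/τ))·exp(lognormal noise).  The floor (0 in the
  bare model, 0.40/0.52 s in the NT/ASD presets) keeps preset medians near
  the observed 445/572 ms ordering; preset trial constants are 18.4/21.9
  trials and both cohorts share the response-noise parameters (certainty
  0.85, lapse 0.05), since uncertainty and self-consistency did not differ
  between cohorts.
- **Gaze**: fixation centers from an isotropic Gaussian around the image
  center (spread 45/65 px, durations 9.0/10.5 s, ~3 fixations/s for
  NT/ASD), 500-Hz samples with 1-px jitter.
- **EEG**: each epoch sums Gaussian-bump components weighted by a posterior
  channel profile (maximum weight 1, so the best channel carries the
  nominal amplitude) plus seeded 1/f-plus-white noise (slope 1, 8 μV,
  20% white floor).  Presets: NT component at 350 ms, 10 μV; ASD at
  425 ms, 7 μV (a +75 ms, ×0.7 contrast) — consistent with a prominent
  posterior deflection in the 300–400 ms range and a later, smaller
  response in the ASD-like cohort.
- The channel montage is a schematic 10-20-style 2-D layout of the standard
  64 electrode names, generated by package code and shipped as a small CSV
  fixture; positions are topologically sensible (posterior channels
  cluster low) but not anatomically calibrated.

What the generators do *not* emulate: image-content-driven gaze (saliency),
correlated cue-pair sampling, RT dependence on response consistency,
non-stationary EEG noise, volume-conduction-realistic topographies, and
inter-participant map disagreement structure.  Passing tests therefore
certify the estimators and statistics under known generative conditions;
they do not certify effect sizes on real data.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from a master seed via `SeedSequence(master,
spawn_key=(stage, index))`, so a configuration reproduces its summary byte
for byte.  The validation suite uses deliberately moderate problem sizes —
20-seed recovery batches at twice the minimal schedule, 200-repetition null
calibrations at 300 permutations, 8 + 8 simulated EEG participants at 30
epochs — chosen to give stable pass/fail margins for the properties being
checked; the defaults in the library itself (10,000 permutations, 9,999
bootstrap resamples) match the published analysis settings.

## Known limitations

- The map estimator is the package's own construction; equivalence to other
  estimators of the same construct is behavioral (map recovery), not
  numerical.
- IG normalization divides by the shuffle-null mean, so IG% grows with grid
  size and K through the null bias; compare IG values only at matched
  geometry.
- The cluster test's conservative threshold df slightly favors fewer, larger
  clusters compared with per-point df; cluster p-values are calibrated by
  their own permutation null either way.
- Coverage is visitation-based; dwell-weighted coverage would differ for
  observers who revisit few locations for long.
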