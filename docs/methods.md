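# Methods

## Scope and model of the data

The package analyzes trial-aligned population calcium imaging from a
head-fixed operant task, together with the task's schedule logic and the
slice-electrophysiology metrics used to characterize the downstream
synapses. Real movies/traces can be supplied in the documented formats
(multi-page TIFF or HDF5 movies, labeled-mask TIFFs, trace HDF5/CSV,
event-log CSV, voltage/current CSV); all development and validation runs on
the synthetic generator, which plants known ground truth for every stage.

### Generative model of a session

For neuron *i* at frame time *t* in a session of duration *T*:

    F_i(t) = b · (1 − d · t/T) + a_i · Σ_p  j_{i,p} · s(t − t_p) + ε_i(t)

- `b = 1` baseline fluorescence (arbitrary units).
- `d` tonic decline fraction, default **0.3** — a 30% within-session
  decline of basal fluorescence, the proxy for a falling tonic firing
  rate. The ramp is linear in frame index, so the last/first-frame ratio is
  exactly `1 − d`.
- `a_i` the neuron's planted peri-press amplitude: +0.5 for excited cells,
  −0.5 for inhibited, 0 for non-responders (defaults). Population
  composition defaults to the 79/153/73-of-305 reference proportions,
  scaled by largest remainder to any requested population size.
- `s(·)` the response shape: a boxcar over [−1 s, +2 s] relative to the
  press convolved with a single-exponential calcium kernel (τ = 0.6 s,
  GCaMP6m-like) and peak-normalized, so the planted amplitude is the peak
  deviation. The −1 s onset plants anticipatory modulation: press decoding
  uses a strictly pre-press epoch, so a generator whose responses began at
  the press would carry no pre-press class signal at all; press-predictive
  activity implies modulation that precedes the movement.
- `j_{i,p}` trial-to-trial amplitude jitter, truncated normal with 20% CV
  (clipped at 0). Single-trial variability of these neurons is not
  characterized in the source data, so this is a free parameter of the
  emulation, not a claim about the biology.
- `ε` i.i.d. Gaussian noise, default SD 0.2 — chosen so a single trial has
  SNR ≈ 2.5 in z-units, a regime where single-trial category calls are
  unreliable but 40-trial averages are clean.
- A drug-injection condition multiplies all responder amplitudes by
  `1 − attenuation` (default attenuation 0.8 in the tracked-pair
  analyses).

What the generator does **not** emulate: photon/shot noise and
photobleaching, neuropil contamination, correlated (shared latent) noise
across neurons, non-rigid motion, cell-shape information, and any
within-category response heterogeneity beyond amplitude jitter. Passing
tests therefore demonstrate that the pipeline's inference machinery is
correct on data matching its own assumptions — not that those assumptions
hold for any particular recording.

### Schedule

Acquisition sessions are 1 h; an active-lever press outside a timeout and
under the reward cap triggers a 1.6-s tone cue, sucrose delivery 3 s after
the press, and a 20-s timeout. Caps follow the acquisition ladder
(10, 10, 20, 20, then 40). Extinction sessions deliver neither cue nor
sucrose (and hence never start a timeout); cue-induced reinstatement
delivers the cue only, with the timeout from cue onset. The timeout
interval is half-open `[t, t + 20 s)` — a press exactly at the boundary is
reinforced — with 1 ns of slack so the rule is robust to the binary
representation of decimal timestamps. The cap is consumed when sucrose is
triggered; a delivery whose start would fall past the session end is not
logged. "Active lever pressing rate" in the extinction criterion is read
as the daily press count, since sessions are fixed-length.

## Analysis choices

- **Peri-event window**: 10 s pre, 3 s press-to-reward, 10 s post
  (23 s; 690 timepoints at 30 Hz). Trials truncated by a session edge are
  excluded and counted, not padded.
- **Z-scoring**: each trial's own −10…−5 s baseline mean is subtracted
  (removing slow tonic drift from the aligned traces); the divisor is the
  per-neuron SD of the baseline segment pooled across trials, set to 1
  when it is exactly 0 (noiseless fixtures). The baseline ends 5 s before
  the press to keep approach-related anticipatory activity out of the
  reference segment.
- **Component count**: PCA on the neuron × timepoint trial-average with
  neurons as observations; the knee is the component at the maximal
  discrete second difference of the explained-variance-ratio curve, with a
  floor of 2 (rank-1 input returns 1 with a warning; a flat curve —
  maximal second difference < 0.01 — warns and returns the floor). Note
  three cluster centroids span only two dimensions after centering, so a
  knee at 2 is the expected outcome for three planted ensembles.
- **Clustering**: sklearn `SpectralClustering` with a symmetric k-NN
  connectivity graph, `knn = round(sqrt(n))`, seeded k-means with 10
  restarts; `k = 3` by default, `k = "auto"` via the eigengap among the
  first 6 normalized-Laplacian eigenvalues. A graph with more connected
  components than clusters is an error advising a larger `knn`.
- **Category calls**: cluster mean of the trial-averaged z-score over the
  0–3 s press-to-reward segment against ±0.5 z (configurable). Categories
  are derived from the data only; planted labels are used solely for
  scoring recovery.
- **Decoding**: one 1-s pre-press epoch per usable press and an equal
  number of baseline epochs drawn without replacement from a 1-s grid that
  excludes [−10 s, +13 s] around every press (the modeled response span),
  so baselines overlap neither responses nor each other. Classifier is
  LDA (deterministic, hyperparameter-free; linear SVM available for the
  population path), stratified seeded 5-fold CV. The per-neuron path is a
  closed-form 1-D shared-variance Gaussian LDA vectorized across neurons,
  verified against per-column sklearn fits. The shuffle null permutes
  labels (100 permutations by default), and scores subtract the null mean
  pooled over the neuron's group.
- **Known emulation artifact**: the tonic decline makes every epoch
  feature a function of session time for *all* neurons, so non-responders'
  cross-validated accuracy sits slightly below their permutation null
  (the familiar below-chance CV bias on a shared confound) and their
  shuffle-subtracted scores center a few hundredths below 0 rather than at
  0. Responder scores (≈ +0.4) dwarf this. The zero-centering property is
  asserted with the decline disabled.
- **Tracking**: optimal one-to-one assignment (Hungarian) on centroid
  distance with a 3-px gate; shape similarity is deliberately omitted (a
  hook exists) since synthetic fixtures carry no shape information. The
  tracked-pair generator places fresh cells a half ROI-pitch diagonal away
  from the unshared cells' positions so the planted correspondence is the
  unique optimum rather than one end of a degenerate assignment cascade.
- **Ephys**: inputs are per-sweep peak amplitudes (sign convention: inward
  negative, enforced). RI uses the `I(+50)/−I(−70)` definition. Wash
  windows are the first and last 5 min of the recording itself, requiring
  ≥3 samples each.
- **Stats**: two-way ANOVA via the OLS decomposition (type II; identical
  to type I on the balanced designs used here), repeated measures as a
  subject-blocked decomposition without sphericity correction. Degenerate
  conventions: zero effect SS → F = 0, p = 1; perfect fit with nonzero
  effect SS → F = ∞, p = 0. Sidak applies to an explicit contrast list.
  Chi-squared uses no continuity correction. A paired t with zero-variance
  nonzero-mean differences reports the infinite-t convention.
- **Registration**: integer-pixel rigid translation per frame via phase
  cross-correlation against a mean- or first-frame reference, out-of-frame
  pixels filled with the frame median. This deliberately replaces
  heavier motion-correction machinery: correctness is established by exact
  planted-shift recovery, and nothing downstream depends on the
  registration algorithm. Subpixel motion and non-rigid deformation are
  out of scope.

## Validation problem sizes

The pipeline-level checks run 20 seeds of a 305-neuron, 40-trial, 30-Hz,
1-h session (the study-scale configuration) for ensemble recovery and
decoding; 200 random press sets against a 1-ms brute-force schedule
oracle; 1000 simulated null datasets for ANOVA calibration. Unit tests use
10-Hz, 60–100-neuron fixtures. The full suite and the acceptance script
each complete in about a minute on one CPU.

## Known limitations

- ROI masks are inputs; no segmentation is provided.
- No spike deconvolution, neuropil subtraction, or biophysical
  calcium-binding model; fluorescence is treated as the observable.
- Tracking is centroid-only and limited to session pairs.
- The repeated-measures ANOVA is a blocked decomposition, not a mixed
  model; no sphericity correction or effect sizes.
- Decoding offers no nonlinear decoders or temporal generalization.
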