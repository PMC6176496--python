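# Methods

This note documents the models implemented in `mmnconn`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user should know before trusting or
extending the results.

## Study design being modeled

An auditory oddball protocol: blocks of 300 pure tones — 200 standards
(500 Hz) and 50 + 50 deviants (450/550 Hz) — in uniformly random order,
75 ms tone duration, 1000 ms offset-to-onset inter-stimulus interval
(stimulus onset asynchrony 1075 ms), recorded at 1 kHz from 64 channels.
The two deviant pitches are distinct labels in every event table but are
pooled into a single *deviant* condition for analysis. Each virtual subject
is measured in two states, awake and anesthesia, and the group design is
fully paired (2 conditions × 2 states per subject).

## Preprocessing

* **Filtering.** Zero-phase FIR (Hamming window, `firwin` design) with
  transition bands of 25% of each edge; 0.5–40 Hz for ERP extraction,
  30–40 Hz (gamma) for connectivity. Zero-phase realization matters because
  any phase distortion would bias the phase-difference statistics
  downstream. The continuous-recording path uses `mne.filter.filter_data`
  (phase="zero"); the epoch-level gamma filter applies the identical kernel
  in a single FFT convolution across all trials and ROIs for speed. Edge
  transients stay outside the interior analysis window.
* **Deviant selection.** A deviant enters the analysis only when its three
  immediately preceding tones are all standards, so every analyzed deviant
  violates an established regularity. In a random 2:1 sequence about 30% of
  deviants survive.
* **Epoching.** Half-open [−100, 700) ms windows, onset at t = 0, 0-based
  sample indexing; 800 samples at 1 kHz. Events whose window leaves the
  recording are skipped and logged. Baseline correction subtracts the
  per-trial, per-channel mean of [−100, 0) ms.
* **Artifact rejection.** Automated: any trial whose peak-to-peak range
  exceeds 100 µV (default) on any channel is removed and logged. This
  replaces manual screening for the sake of reproducibility.
* **Re-referencing.** To the average of the two mastoids (M1/M2) when both
  are present; otherwise the data are assumed pre-referenced.
* **MMN.** Difference wave = deviant average − standard average. Its peak
  is the most negative sample at Fz within a configurable 100–250 ms search
  window (ties resolve to the earliest latency, for determinism); the
  analysis window is the 100 ms interval centered there, and an error — not
  clipping — is raised if it would leave the epoch. MMN *presence* requires
  a trough ≤ −0.5 µV and a negative window mean (both configurable; the
  criterion is this package's own, as no standard one exists); subjects
  without an MMN are excluded from group analysis and logged.
* **Window reuse.** The window found in the awake state is applied
  unchanged to the anesthesia recordings of the same subject, on the
  grounds that anesthetics attenuate ERP amplitude but not latency; this
  lets connectivity be compared at the same post-stimulus time frame even
  when no observable MMN exists under anesthesia.
* **Trial-count matching.** wPLI has a positive small-sample bias that
  shrinks with the number of trials, so comparing 200 standards against
  ~30 valid deviants would manufacture a condition difference. By default
  the pipeline subsamples standard trials (without replacement,
  seed-derived) to the valid-deviant count. Configurable off.

## Inverse stage

Depth-weighted minimum-norm estimation with fixed-orientation sources:

    K = W Lᵀ (L W Lᵀ + λ I)⁻¹,   W = diag(‖l_j‖^(−2γ)),

applied identically to every trial (the whole chain is linear, which the
tests exploit: scaling, superposition, average-commutation, and exact
reconstruction through an orthogonal leadfield at λ = 0).

* γ = 0.5 by default (moderate depth weighting).
* λ defaults to `trace(L W Lᵀ)/(n_sensors · SNR²)` with amplitude SNR 3,
  the conventional choice for evoked data; any λ ≥ 0 can be passed.
* Noise covariance is assumed identity (the λI term).
* The leadfield is always an input, never computed here; desk-scale
  fixtures use random gain matrices with controlled condition number
  (geometric singular-value profile). ROI signals are arithmetic means of
  member-source time courses under a supplied source-to-ROI parcellation.

## Connectivity: wPLI

Phases come from the analytic signal (Hilbert transform) computed over the
**full epoch** and only then cropped to the 100 ms window, keeping the
transform's edge artifacts away from the analyzed samples. For ROIs i, j
with phase differences Δ over all windowed samples of all n trials:

    wPLI_ij = |mean(sin Δ)| / mean(|sin Δ|)   ∈ [0, 1].

The default pools trials and samples into a single ratio. This is the form
consistent with the measure's interpretation — 1 when one signal always
leads or lags the other across trials, 0 when phase differences are
completely random across trials — and with all boundary cases: a constant
nonzero lag in every trial gives exactly 1; i.i.d. uniform lags across
trials give 0 in the large-n limit; Δ ≡ 0 (the volume-conduction
signature) gives 0 by the degenerate-denominator rule (a trial or pool with
`mean |sin Δ| = 0` contributes 0 — discounting zero-lag coupling is exactly
the estimator's purpose). A within-trial-ratio-averaged-across-trials
variant is available (`method="per_trial"`); note it saturates at 1
whenever each trial's lag is stable within the trial, regardless of
cross-trial consistency, which is why it is not the default. Both variants
are verified against independent brute-force loop oracles to 1e−12.

Only the gamma band (30–40 Hz) is analyzed by default; the band is
configurable.

## Networks and long/short-distance statistics

The symmetric 148 × 148 wPLI matrix is thresholded by **edge density** d:
the ⌊d·N(N−1)/2 + 0.5⌋ strongest edges are kept (ties broken by (i, j)
index order, for determinism). The density grid runs 6–90% in 1% steps;
6% is the integrity floor 2·ln(148)/147 ≈ 0.068 (average degree 2 ln N),
reported as a truncated integer percent. Densities below the floor warn
but do not fail.

With the 148 ROIs grouped into 14 areas — ventral prefrontal, dorsal
prefrontal, central, temporal, parietal, occipital, cingulate × hemisphere —
each kept edge is *short* (both endpoints in one area, summed into that
area's S_k) or *long* (endpoints in two areas, its weight summed into
**both** areas' L_k). Consequently `L_all = Σ L_k` counts every inter-area
edge twice, and the conserved quantity is `S_all + L_all/2 = total kept
weight` (asserted to 1e−9 in the tests). `Ratio = L_all/S_all`; when
`S_all = 0` (possible at low densities on small networks) the Ratio is an
explicit NaN, never infinity, and the grid-mean summary averages over the
densities where it is defined. At 148 ROIs with the shipped atlas this
degeneracy does not occur. The sweep is computed by prefix sums over the
once-sorted edge list and is verified to match direct per-density
thresholding.

The ROI → area table ships as an editable CSV
(`src/mmnconn/data/destrieux_14area.csv`). The assignment of the 74
Destrieux (aparc.a2009s) region names per hemisphere to the seven coarse
areas is a best-effort keyword mapping (insula grouped with temporal,
anterior lateral-fissure rami with ventral prefrontal, lingual regions with
occipital); users with a preferred grouping should edit the CSV and pass it
via `atlas_path`.

## Group statistics

Classical two-sided paired t-tests (t = mean(d)/(sd(d)/√n), df = n−1) at
α = 0.05, arranged into five table families mirroring the analysis design:
Ratio by condition within state; S_all and L_all by state within condition;
L_all and S_all by condition within state; per-area L_k by condition; and
per-area L_k by state. No multiple-testing correction is applied by default
(the 14 per-area tests are reported uncorrected, as is common in this
literature); Benjamini–Hochberg is available behind a flag and logs a
notice. Zero-variance paired differences make t undefined: the scalar test
raises, while the table builder records such a comparison as NaN /
not-significant with a warning (this arises only in fully deterministic
simulations, see below). Unbalanced designs (any subject missing any of the
four condition × state cells) are an error listing the missing cells, never
silent dropping.

## Synthetic generator

**What it emulates.** (i) The oddball event statistics above. (ii)
Gamma-band ROI oscillations: within a trial all ROIs share one carrier
frequency drawn uniformly from 30–40 Hz, each with an independent uniform
initial phase; a planted coupling (i → j, lag θ, strength s) replaces the
follower's phase offset with `angle(s·e^{i(φ_i+θ)} + (1−s)·e^{iφ_free})`,
so s = 1 yields perfect constant-lag locking and s = 0 independence.
Couplings can be condition-specific (standard / deviant / both); the
anesthesia state multiplies every strength by `anesthesia_attenuation`.
White observation noise (sd 0.3 on unit-amplitude oscillations) is added;
after the 30–40 Hz filter its phase jitter is negligible. (iii) Sensor
recordings: leadfield × source activity + sensor noise, with evoked
components added on a fixed fronto-central topography; deviants carry an
extra −3 µV component at 160 ms (width 40 ms) — the MMN generator — which
is omitted under anesthesia while shared components are attenuated.

**Parameter defaults and rationale.** Planted coupling strength 0.95: in
the mixture model the phase-difference distribution concentrates enough
that wPLI saturates near 1 for s ≳ 0.7, so 0.95 is comfortably in the
detectable regime while leaving room for attenuation studies.
`anesthesia_attenuation` 0.25: an attenuated strength of ~0.24 puts a pair
statistically at the uncoupled noise floor of a ~30-trial wPLI estimate,
emulating the collapse of long-range communication under deep sedation.
Tone-frequency content (450/500/550 Hz audio) is *not* synthesized — only
the labels matter downstream.

**Determinism contract.** All randomness derives from one integer seed via
named `SeedSequence` substreams, so stages rerun independently and
bit-identically. The ROI-signal substream is deliberately shared between
states: the awake and anesthesia arrays differ *only* through the
attenuation of coupling strengths, so attenuation 1.0 reproduces the awake
arrays exactly. This makes state contrasts maximally paired, and it means a
coupling-free simulation yields literally identical awake/anesthesia
metrics (hence the NaN rule in the stats stage).

**What passing tests do not show.** The generator's oscillations are
stationary sinusoids with constant within-trial lags — no 1/f background,
no amplitude dynamics, no true dipolar topographies, no eye/muscle
artifacts, no inter-subject anatomical variability (subjects differ only by
seed). Detection and type-I results on this ground truth validate the
*estimators and pipeline logic*, not their sensitivity on real EEG.

## Problem sizes used in the shipped checks

Chosen so the full suite runs in a few minutes on one core; they are the
package's desk-scale defaults, not limits of the method:

* cohort contrast: 20 replicates × 12 subjects, 48 ROIs grouped into the
  14 areas, full 300-tone blocks (~30 matched trials per condition), 12
  deviant-only prefrontal→temporal couplings; the awake contrast must be
  significant (deviant > standard) and the anesthesia contrast null in
  ≥ 90% of replicates;
* type-I error: 200 replicates × 12 subjects, 28 ROIs, 60-tone blocks,
  no couplings; the awake Ratio test's rejection rate must lie within
  Monte-Carlo error of α = 0.05;
* estimator boundary values: 50 trials (constant-lag limit) and 5000
  trials (random-lag limit), recomputed by `scripts/acceptance.py`.

## Known limitations

* EDF can be read (via mne's bundled reader) but not written; persistent
  containers are HDF5/TSV/CSV/JSON.
* The wMNE stage assumes an identity noise covariance; a full covariance
  is accepted in form but not estimated from data.
* The per-trial wPLI variant's saturation behavior (above) makes it
  unsuitable for designs where lags are stable within trials; it exists
  for comparison only.
* The default ROI → area table is a keyword reconstruction, not an
  authoritative anatomical product; edit the CSV for serious use.
* `Ratio` inherits the double-counting of inter-area edges in `L_all`; use
  the conservation identity when comparing against tools that count each
  edge once.
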