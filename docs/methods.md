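# Methods

This note documents the models, numerical conventions and design choices
behind `oscnet`, in the order data flows through the pipeline.

## Task model (`taskgen`)

Trials present a 5-item binary base sequence per modality (2⁵ = 32 per
modality), repeated cyclically over *n* items with only the final item
allowed to deviate. The trial length follows a truncated geometric law:
after each of items 8–19 the trial stops with a constant hazard *h*
(default 0.15), with all residual mass on 20, so the conditional stopping
probability is flat across the interior of the range and the endpoint is
unpredictable. The hazard value is not dictated by the task description;
0.15 gives a non-degenerate spread over 8–20 (mean ≈ 13) and is exposed in
`HazardConfig`. Final-item violations occur independently per modality with
probability 0.5.

Corrected accuracy is (hit − FA)/(1 − FA). RT trimming keeps
correct-response RTs within 3 SD of their mean, computed in a **single
pass** (mean/SD estimated once, no re-estimation after exclusion); the
trimming convention in the field is ambiguous on iteration and a single
pass is the simpler, deterministic choice. The 1-back/2-back memory-control
load is carried as a trial attribute (`nback`) so contrasts can condition
on it; no behavioral ANOVA machinery is bundled.

Two performance models fill in responses. `FlatPerformanceModel` draws
correctness at fixed accuracy. `PhaseTunedPerformanceModel` draws a latent
cross-region phase delay φ per trial from a von Mises law centered on the
preferred lag φ\* with task-dependent concentration κ, then sets
P(correct) = p₀ + a·cos(φ − φ\*) and RT = r₀ − b·cos(φ − φ\*) + noise. The
realized φ is stored on the trial so the signal generator can plant the
*same* lag in the neural data — behavior and coupling share one latent
variable, which is what the phase-tuning analyses assume.

## Source space (`sourcespace`)

Source locations are vertices of a recursively subdivided icosahedron
projected to the unit sphere: 10·4ᵏ + 2 vertices per hemisphere (12, 42,
162 at depths 0–2), two mirrored hemispheres, and mesh edges as the spatial
neighbor relation. Adjacency never crosses hemispheres (no cortical
morphing is modeled, so there is no principled inter-hemispheric edge).
Location exclusions (e.g. midline sites unlikely to generate signal) are an
arbitrary config list; excluded vertices keep their indices but drop out of
`kept_mask` and out of every neighbor set — the neighbor relation is taken
on the **post-exclusion** polyhedron, since a removed location cannot
mediate adjacency in the analysis.

## Beamformer (`beamform`)

Classical LCMV: per location, W = (Lᵀ C⁻¹ L)⁻¹ Lᵀ C⁻¹ with the 3-column
lead field L of that location, giving exact unit gain (W L = I₃). Diagonal
loading defaults to 5% of the mean sensor variance; loading proportional
to the covariance scale keeps the filters invariant to global data
rescaling. The three filters are collapsed onto the orientation of maximal
projected variance (dominant eigenvector of W C Wᵀ, unit-norm weights);
eigenvector sign is fixed by requiring a positive projection of the
combined filter onto the location's first lead-field column (first nonzero
weight positive when no lead field is supplied). Condition comparisons
assume a common filter built from condition-balanced pooled covariance.
The forward model in this package is deliberately a toy: random unit-norm
Gaussian lead-field columns with random source orientations and white
sensor noise at a configured SNR. It exists to validate the filter algebra
and recovery behavior, not to emulate head geometry.

## Spectral estimation (`spectral`)

Frequencies are octave-spaced: centers f_min·2^(k·step); the defaults
2^2.5 ≈ 5.66 Hz to 2^7 = 128 Hz in 0.25-octave steps give 19 centers
(5.66 is treated as exactly 2^2.5). Spectral smoothing targets a 3/4-octave
full bandwidth B(f) = f·(2^(3/8) − 2^(−3/8)) at every frequency:

* f ≥ 16 Hz — fixed 250 ms windows; the DPSS taper count follows the
  standard 2TW − 1 heuristic with half-bandwidth W = B/2, i.e.
  K = max(1, ⌊T·B − 1⌋) (1 taper at 16 Hz, 15 at 128 Hz);
* f < 16 Hz — a single taper with the window stretched to T = 2/B, which
  yields the same fractional smoothing.

This makes time-frequency smoothing homogeneous on the log-frequency grid,
which the cluster neighbor relation (one 0.25-octave step ≡ one bin)
implicitly assumes. Coefficients are computed by complex demodulation:
unit-energy DPSS taper × carrier e^(−2πift), phase referenced to the window
center; windows reaching past the epoch are zero-padded (implemented by
truncating the shifted kernel). Time-bin centers run 0, 100, …, 700 ms
inclusive for a 0–700 ms segment (8 bins; 25 ms steps for evoked
analyses); a center on the epoch edge is half zero-padded.

Tapers are kept as an extra observation index: power and coherency average
cross-products over trials *and* tapers, the standard multitaper
convention. Whether cross-products are averaged before or after taper
pooling is a genuine degree of freedom; pooling tapers into the observation
axis was chosen because it treats tapers exactly like independent
replicates, and the `SpectralSet` keeps per-taper coefficients so the
alternative can be computed if needed.

The induced (non-phase-locked) signal is the epoch minus its condition's
across-trial mean waveform; when condition counts are unequal the mean is
estimated from an equal-size random subsample per condition (seeded) so no
condition dominates the evoked estimate.

## Coupling (`coupling`)

ImC uses the coherency normalization Im(⟨XY\*⟩ / √(⟨|X|²⟩⟨|Y|²⟩)) with
canonical pair ordering i < j; values are antisymmetric under pair swap and
the sign is kept so condition contrasts are directional. Zero-power bins
are set to 0 and flagged in a mask rather than propagating NaN, keeping the
downstream clustering well-defined (a zero never survives thresholding, so
the choice is conservative).

PAC uses the Tort-style KL modulation index with 18 phase bins — that
method's standard bin count — on phase/amplitude time courses obtained by
zero-phase 4th-order Butterworth band-pass (theta 5–7 Hz, beta 12–32 Hz)
plus the analytic signal at the native sampling rate, rather than from the
coarse TF grid; instantaneous time courses are what a within-epoch
phase-amplitude histogram needs. The shift predictor recomputes the MI
with amplitude epochs permuted by a random derangement (no epoch paired
with itself; 100 surrogates by default), preserving stimulus-locked
structure while destroying within-trial correspondence; the reported
contrast is raw MI minus the surrogate mean (a z-scored variant is also
returned). PAC site selection takes locations whose integrated cluster
statistic exceeds mean + 1 SD within their cluster, falling back to the
single top location (with a warning) when the map is too uniform for any
site to clear the threshold.

## Cluster statistics (`netcluster`)

For 2×2 within-subject designs the main-effect and interaction F values
are computed as the square of the paired t on the corresponding
within-subject contrast, which is exact for 2×2 repeated measures and
makes F ≡ t² for 2-condition designs by construction. Thresholding uses
the two-tailed t (on |t|) or one-tailed F critical value at the
cluster-forming alpha. The neighborhood filter runs **once**, with
neighbor counts taken on the pre-filter significance map (an iterated
filter is another fixed point but the single pass matches the antecedent
cluster-filtering literature and is order-independent); the ratio
comparison is inclusive (≥, default 0.3), and a bin with no possible
neighbors survives vacuously. Connected components are found on the sparse
bin-adjacency matrix (Kronecker sum of the frequency chain, time chain and
spatial/pair adjacency); positive and negative t bins cluster separately,
and F components are split post hoc by the sign of the underlying t so
each reported cluster has a consistent direction.

Permutation inference reruns the full map → threshold → filter → cluster
chain per resample with labels shuffled within subject (sign flips for
paired designs, independent cell relabeling for 2×2 factors). The null
distribution collects the per-resample **maximum absolute cluster mass
pooled over signs**, and each observed cluster is tested on |mass| with
p = (1 + #{null ≥ |mass|})/(n_perm + 1), which cannot return zero. Pooling
the signed maxima (rather than keeping one null per sign, each tested at
0.05) was chosen because it is the variant that controls the two-tailed
family-wise error at the nominal level; per-sign nulls at 0.05 each would
roughly double the family-wise rate. The type-I calibration in the
acceptance suite verifies this empirically. Cluster projections integrate
the statistic over space per (f, t), or over frequency, time and the
partner location per location; for pair clusters each member contributes
to both endpoints, so the spatial projection sums to exactly twice the
time-frequency projection.

## Synthetic scenario (`synthgen`)

Each epoch is the sum of:

* 1/f^β background noise per location (β = 1, unit SD, synthesized in the
  frequency domain), amplitude 1;
* a theta oscillation (6 Hz, amplitude 1) at two 4-location patches — a
  seed vertex plus three mesh neighbors per hemisphere, so the planted
  pairs form a connected cluster in pair space. The cross-patch phase lag
  is the trial's latent φ: von Mises around φ\* = π/2 with κ = 4 in the
  prediction task and κ = 0 (uniform) in memory. φ\* = π/2 puts the planted
  lag at the maximum of the imaginary part; κ values were fixed once to
  give a clearly suprathreshold prediction-vs-memory ImC contrast at the
  default study size;
* a beta oscillation (20 Hz, amplitude 1, random phase per epoch and site)
  at the right-hemisphere patch whose envelope is scaled ×1.5 when the
  previous item (attended modality) matches the current one and ×1.0
  otherwise;
* at the PAC amplitude site, the beta envelope is additionally multiplied
  by (1 + d·cos θ(t)) with the theta phase of the PAC phase site and
  d = 0.6. Because the theta phase offset is randomized at the **trial**
  level, a trial-shuffling shift predictor destroys the coupling while
  stimulus-locked structure survives — the property the shift-predictor
  normalization needs.

Default study size: 12 subjects × 60 trials per task × modality cell, one
prediction-segment epoch per trial, 400 Hz, 0–700 ms epochs on a depth-0
bilateral icosphere (24 locations, 276 pairs). These sizes were chosen so
the full generator-to-permutation-test chain runs in seconds per study on
one CPU while every planted effect remains recoverable; the Monte-Carlo
acceptance runs use 40 trials per condition and a single hemisphere for
the no-effect calibration, where spatial extent carries no information.

**What the generator does not emulate:** realistic head geometry and
sensor noise covariance, physiological artifacts, inter-subject anatomical
variability, spatially correlated (leaked) noise between locations, more
than one oscillatory source per band, and effect sizes calibrated to real
cortex. Passing tests therefore demonstrate that the *analysis chain* is
correct and calibrated — not that real MEG effects of any particular size
would be detected.

## Numerical conventions and edge cases

* Coefficient phase convention: X ∝ e^{+iφ} for a cosine of phase φ, so
  arg(X_a X_b\*) equals the planted lag φ_a − φ_b.
* Paired t with zero variance across subjects is defined as 0 (the bin
  cannot be significant); degenerate LCMV projected covariance, all-zero
  spectra, empty conditions, and zero-total-amplitude PAC raise errors.
* Behavioral phase bins: 8 bins centered on zero delay (first bin
  [−π/8, π/8)); centering on zero makes "peak at zero delay" a statement
  about a single bin. Equal-count |delay| bins split ties by stable sort
  order. Split-half accuracy tuning uses one random split with both
  directions averaged (seeded); tuning curves average components
  unweighted and report per-bin counts.
* All randomness flows through `numpy.random.Generator` arguments;
  identical seeds reproduce sessions, studies and permutation tests
  exactly.

## Known limitations

The permutation engine vectorizes sign flips for paired designs but loops
for 2×2 relabeling; very large 2×2 maps are correspondingly slower. The
neighborhood filter and clustering operate on dense binary vectors over
the bin space, which is fine up to ~10⁶ bins but not beyond. The evoked
(25 ms) time grid and the 3-D power-cluster path share all code with the
coupling path but have been exercised mainly at the sizes in the test
suite. Serialization stores epoch labels in a JSON sidecar, so extremely
large label tables cost proportionally.
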