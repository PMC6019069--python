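# Methods

This note documents the models, conventions and numerical choices behind
`depthgauge`, and what the synthetic-data generators do and do not emulate.

## System overview

Planktonic *Platynereis dumerilii* larvae carry two photoreceptor systems:
pigmented rhabdomeric photoreceptors (rPRCs, eyespots and adult eyes) that
mediate positive phototaxis over a broad spectral band, and non-pigmented,
UV-sensitive ciliary photoreceptors (cPRCs) of the brain that mediate
downward swimming under UV-violet light. The two behaviors are antagonistic:
under mixed UV/blue illumination from above there is a UV fraction at which
they cancel and net vertical displacement is zero — the *balance point* of a
ratio-chromatic depth gauge. The package implements the analysis chain for
each data modality of that system, plus generators producing synthetic
versions of every input with ground truth exposed.

## Connectome analysis

**Conventions.** Synapse matrices are square, nonnegative-integer, rows
presynaptic and columns postsynaptic, indexed by `cell_id` and paired with an
annotation table (`cell_id`, `name`, `cell_class`, `side`) over a controlled
class vocabulary. Grouping by class sums synapse counts and conserves the
grand total.

**Bridge search.** `find_bridge_paths` enumerates every directed path of at
most `max_hops` edges (default 2) from any cell of the source circuit to any
cell of the target circuit, where an edge exists when its synapse count is at
least `min_synapses` (default 1 — the EM study did not state a count
threshold for calling a connection, so it is a parameter rather than a
guess). Intermediary cells must belong to neither circuit: within-circuit
relays are not bridges. A one-hop path between circuits (e.g. the
IN_RGW→IN_sn synapses, where IN_RGW sits in the cPRC circuit and IN_sn in the
rPRC circuit) is reported as a `direct:` bridge class; two-hop paths are
keyed by the intermediary's class. The MS cells form a single bridge class
even though they contact both vMN and IN_pro targets, following how the
anatomical description enumerates its contact sites. Paths are deduplicated
at the cell level and returned in lexicographic order so results are
deterministic. The implementation delegates path enumeration to
`networkx.all_simple_paths` on the thresholded digraph; tests check it
against an exhaustive triple-loop enumeration on random ≤12-node graphs.

**Membrane morphometrics.** Each ciliary branch is an open cylinder
(lateral area π·d·L, no end caps — branch tips are a negligible fraction of
the surface). With the measured branch statistics (mean diameter 130 nm,
total length 677 µm per cell) this yields ≈276 µm² per cPRC. Basal-body
counts, when supplied, are validated against a configurable plausibility
range (default 12–15 per cell).

## Stimulus and radiometry

Photon flux is P·λ/(h·c) with CODATA-exact h and c, so results are
bit-reproducible; comparisons against 2-significant-figure printed values
use half-even rounding. The stimulation geometry ratio is frame area over
circular ROI area; with a 254×254 px frame the 18–24 px ROI range spans
≈253.6–142.6, and the exact formula is reported without forcing agreement
with any quoted round-number range. Duty-cycle mixtures are two epochs,
(UV, f·T) and (fill, (1−f)·T) on a default 500 ms period, kept as real
milliseconds (no frame quantization, since the monochromator switching
granularity is unspecified); `time_averaged_ratio` inverts the construction
exactly. Spectrum peaks are the global maximum after optional moving-average
smoothing (window in nm, converted to an odd point count via the median grid
step), with ties broken toward the shorter wavelength; difference spectra
are pointwise dark − light after linear resampling onto the overlapping dark
grid.

## Calcium imaging

dF/F0 supports two baselines. Fixed mode uses the mean of a pre-stimulus
frame window. Time-dependent mode divides by a reference-region series
(an area with no calcium activity), which cancels any per-frame
multiplicative artefact — stimulation-laser bleed-through, detector gain —
applied to the whole frame; with a `pre_window` the ratio is additionally
re-referenced to its pre-stimulus mean so traces start at zero. This
invariance is exact and is asserted in tests.

Correlation maps compute Pearson r between a seed trace and every pixel
series in one vectorized pass; zero-variance pixels map to 0 (not NaN) so
the [−1, 1] two-color rendering is clean.

**Response typing.** A *dip* is the first sustained excursion below
−`dip_threshold` after onset; a *rise* is the first sustained excursion
above +`depol_threshold` after the dip ends (or after onset when there is no
dip). "Sustained" means at least 3 consecutive frames, rejecting
single-frame noise. Thresholds default to 3× the pre-stimulus standard
deviation with a floor of 0.05 dF/F0 so noise-free traces remain
classifiable. Decision table: dip then rise → `biphasic_cPRC`; dip without
rise → `hyperpolarizing_only`; rise beginning within 10 s of onset without a
dip → `onset_depolarizing`; later rise → `delayed_depolarizing`; otherwise
`none`. A rise after stimulus offset still counts — the delayed
depolarization outlives the stimulus. Joint cell types combine the violet
(405 nm) and blue (488 nm) features: `cPRC_like` (biphasic at violet,
sustained dip at blue), `RGW_follower` (biphasic at violet, silent at blue),
`SN_early` (onset depolarization at violet only), `SN_late` (delayed
depolarization at violet; blue response absent or weaker than a configurable
amplitude ratio, default 0.5 — this boundary is a convention, not a
measured quantity, since the study describes the blue response of these
cells only qualitatively as "weaker").

## Behavior

Trajectories are (t, x, z) in mm with z upward, in a column of default
160 mm water height. Binned displacement uses contiguous half-open 30-s bins
from stimulus onset; larvae entering or leaving mid-bin are excluded from
that bin (exclusion avoids biased partial displacements). Windowed net
displacement is the across-larvae mean of z(end) − z(start); named presets
cover the windows used by the assays (1.5–3.5 min after onset for the
column action spectra and ratio experiments; last 45 s of a 60-s cuvette
step). The per-larva displacement definition is used throughout (rather
than a population center-of-mass proxy), because it supports the
whole-bin-presence exclusion rule; both agree for larvae tracked
throughout.

**Tracking.** Detections are centroids of thresholded connected components;
linking is greedy nearest neighbor within a maximum distance, closest pairs
first, ties to the lowest track id. Greedy linking (not global assignment)
is adequate at the planted densities and is a documented limitation for
crossing tracks.

**Balance point.** Given net displacement on an increasing UV-fraction grid,
the estimator linearly interpolates between the two fractions bracketing the
positive-to-negative sign change; with several crossings it uses the one
descending from the largest positive response. A response that never changes
sign (the UV/red control) raises `NoSignChangeError`.

**Statistics.** Group comparisons are Welch two-sample t-tests (the variance
assumption is not stated in the source assays, so the unequal-variance form
is the safe default) with either Holm-Šidák step-down correction
(stage thresholds α_i = 1 − (1−α)^(1/(m−i+1))) or single-step
Šidák-Bonferroni. Step-down rejections are always a superset of the
single-step ones; family-wise error control is verified by simulation
(10,000 null replicates, m = 10).

## Synthetic-data generators

**Connectome fixture.** Cell counts follow the reconstructed anatomy (4
cPRCs, 4 RGW and 4 NOS interneurons, ≥4 flask-shaped sensory cells, 6
premotor interneurons, 2 MS cells, 2 Ser-h1 cells, etc.; the anatomically
fixed counts are validated). Edges are realized all-to-all within each edge
class of the circuit topology; flask-shaped sensory cells get no outputs and
no rPRC-circuit cell projects into the cPRC circuit. Synapse counts are
drawn uniformly from a per-fixture range (default 2–8), or pinned to the
midpoint in deterministic mode for exact tests. The fixture therefore
satisfies, by construction, the circuit assertions the analysis must
recover: three forward bridge classes, six IN_preMN intermediaries, zero
reverse paths.

**Movies.** Planted cells are Gaussian blobs over a uniform background.
cPRC pixels have an elevated resting baseline (400 vs 150 intensity units),
mirroring the high dark-state calcium that makes these cells identifiable
without stimulation; the knockout flag lowers it and silences the cPRC
kernels. Class- and wavelength-conditional dF/F kernels implement the
response phenomenology (biphasic, sustained dip, onset, delayed; the
late sensory neurons respond to blue at 0.3× amplitude). A multiplicative
whole-frame gain (default 1.05) during the stimulation epoch emulates
stimulation-laser bleed-through, and shot-like Gaussian noise with
sd = noise_scale·√intensity emulates photon noise. Not emulated: motion,
bleaching, anatomical shape, overlapping neuropil — so classification
results on these movies demonstrate the correctness of the trace pipeline,
not segmentation robustness on real anatomy.

**Behavior model.** Vertical drift is
v_pt·S_pt(λ_eff) − v_uv·S_uv(λ_eff)·[t > latency], plus Gaussian diffusion
and reflecting boundaries; λ_eff weights are the schedule's per-wavelength
time fractions. Sensitivity curves are raised-cosine bumps — behavioral
stand-ins, not opsin spectra: phototaxis centered at 490 nm with 130 nm
half-width (support ≈360–620 nm), avoidance centered at 380 nm with 62 nm
half-width (support ≈318–442 nm). These half-widths were chosen once so the
simulated action spectrum is downward at 340–400 nm, upward at 440–600 nm
and approximately neutral near 420 nm, matching the qualitative behavioral
boundaries. The avoidance latency is a hard switch at 60 s ("approximately
one minute"); a smooth linear ramp is available via `latency_ramp_s`.
Phototaxis speed defaults to 0.3 mm/s — a placeholder at the right order of
magnitude for a ~200 µm larva, since no absolute speeds are printed in the
source text; accordingly all magnitude-based tests are sign- or
ratio-based, never absolute. The avoidance speed is calibrated from the
zero-drift condition at the configured balance fraction (default 0.40)
under the 380/480 mixture:
v_uv = v_pt·(f*·S_pt(380) + (1−f*)·S_pt(480)) / (f*·S_uv(380)).
Diffusion defaults to 0.15 mm/√s. Every stochastic routine takes an
explicit seed and is bit-reproducible.

**Videos.** Trajectories are rendered as Gaussian blobs (z maps to rows
counted up from the bottom row) plus sensor noise. Rendering plus tracking
recovers ground-truth displacement within 5% and positions within 2 px at
the planted densities.

**Spectra.** The dark pigment is a log-normal-in-wavelength template
(default λ-max 384 nm, 50 nm FWHM on a 300–500 nm, 1 nm grid) — a stand-in
for a measured absorbance curve, not a claim about opsin photochemistry.
Bleaching retains 20% of the dark band and adds a photoproduct 84 nm
blue-shifted, so both the dark spectrum and the dark−light difference
spectrum peak at the configured λ-max. Default additive noise (sd 0.005 of
the unit peak) lets an 11-nm moving average recover the peak within ±2 nm
in ≥95% of draws.

## Problem sizes

Tests and the acceptance script use reduced problem sizes chosen as the
package's own defaults for desk-scale verification: movies of 64×64 px and
160 frames (the full imaging geometry, 254×254 px at 1.25 frames/s, is the
generator default), 20–200 larvae per behavioral condition, 240-s runs at
1-s steps, and 10,000 replicates for the family-wise-error simulation. The
ratio-metric acceptance experiment uses 200 larvae per UV fraction on a
0–100% grid in 10% steps.

## Known limitations

- Greedy nearest-neighbor linking can swap identities when tracks cross;
  the generators used for validation plant non-crossing larvae.
- The behavior model's sensitivity curves are parametric bumps; simulated
  action-spectrum *shapes* should not be read as quantitative predictions.
- The weak-vs-none boundary for blue responses of late sensory neurons
  (amplitude ratio 0.5) is unvalidated against data.
- Boundary reflection slightly compresses large displacements near the
  column ends; the balance-point estimator is insensitive to this because
  displacements near the zero crossing are small.
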