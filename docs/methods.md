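# Methods

This note documents the models, parameter choices and numerical details
behind each module, what the synthetic fixtures do and do not emulate, and
the design decisions taken where the analysis was genuinely open.

## Synthetic sessions

The generator produces the inputs the analyses assume, with ground truth
attached.

**Trajectory.** Velocity follows a two-dimensional mean-reverting
(Ornstein–Uhlenbeck) process integrated at the 30 Hz tracking rate with
reflecting walls. Two parameters matter: the target mean speed (default
8 cm/s, a typical open-field exploration speed; the stationary speed is
Rayleigh, so the per-component sd is mean_speed·√(2/π)) and the velocity
persistence time (default 0.7 s). Sessions default to 20 min in a 40 cm
arena for CA1-style recordings and 15 min in a 100 cm arena for MEC-style
recordings. In the 100 cm arena roughly half to two-thirds of 2-cm bins
pass the 0.1 s occupancy criterion after 10–15 min — sessions much shorter
than that under-cover the large arena and should not be used for
border/grid analyses.

**Spikes.** Inhomogeneous Poisson by thinning: candidates are drawn
homogeneously at the tuning peak along the path and accepted with
probability rate/peak, with the rate held constant within each tracking
frame (exact at 30 Hz relative to the smoothness of the tuning functions).
Tuning archetypes: isotropic Gaussian place/aperiodic fields (peak 10/8 Hz,
sd 4/10 cm), the canonical three-cosine grid model rectified at zero
(peak 15 Hz, spacing 40 cm, random orientation and phase), exponential
decay from one wall for border cells (peak 10 Hz, length constant 8 cm),
and high-rate weakly modulated interneurons (15 Hz, ±20% sinusoidal
modulation). These rates and widths are realistic for mouse CA1/MEC units.

**LFP.** A sum of narrow-band components — defaults at 8, 25, 40, 70 and
120 Hz with decreasing amplitude — whose instantaneous frequency wanders
within the stated bandwidth, on a 1/f-shaped noise floor, sampled at
1 kHz.

**Images.** Vessels are persistent random walks entering from the image
border, dilated to ~9 px width at intensity 0.8 over 0.1 background, with
optional bright (1.0) circular artifacts placed disjoint from the vessel
footprint, plus Gaussian pixel noise. The noiseless vessel footprint is
returned as ground truth.

**What the fixtures do not emulate:** theta-phase coding, replay,
head-direction or speed tuning, electrode drift, spike-sorting errors,
occupancy inhomogeneity of real mice (thigmotaxis), uneven illumination or
out-of-focus blur in the images. Passing recovery tests therefore
demonstrates correctness of the computations under the stated statistical
model, not robustness to every artifact of real recordings.

## Rate maps and metrics

2 × 2 cm bins with half-open intervals [k·b, (k+1)·b) and 0-based indices;
bins with < 0.1 s dwell are invalid and excluded from every statistic.
Spike positions are linearly interpolated from the 30 Hz tracking at spike
times (the alternative — nearest frame — shifts bin assignment by up to
half a frame of travel). Smoothing uses a Gaussian of sd = kernel/5 bins
(sd 1 for the CA1 5 × 5 kernel, sd 2 for the MEC 10 × 10 kernel),
truncated at the kernel extent, with weights renormalized over the valid
support so invalid bins neither give nor receive rate; validity exclusion
is applied before smoothing. Fields use 4-connectivity (shared edges), the
20%-of-peak threshold and the 8-bin minimum. Spatial information uses
occupancy renormalized over valid bins; zero-rate bins contribute zero, and
a silent unit is reported as SI 0 with a flag rather than an error.

## Autocorrelograms, grid score, border score

The autocorrelogram evaluates the product-moment correlation at every lag
over the overlapping valid-bin pairs (computed with FFT cross-correlations
of the map, its square and its validity mask — algebraically identical to
direct summation); lags with < 20 overlapping bins or zero variance are
undefined. The grid-score annulus runs from the edge of the central field
(bins connected to the zero lag above r = 0.2) to 1.25× the mean distance
of the six nearest local maxima; the map is rotated about its center by
bilinear interpolation, corner regions rotated out of support are excluded,
and the score is min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀). Units whose
autocorrelogram has no peaks beyond the central field get an undefined
score and are flagged.

For the border score, wall coverage counts field bins in the single
row/column adjacent to each wall, and the wall distance of a bin is
measured in whole bins from that row/column — wall-adjacent bins are at
distance zero, which is what lets a perfect one-bin wall strip attain
b = +1 exactly (a bin-center convention would cap b strictly below 1).
dm uses the smoothed rates, consistent with field detection.

## Cell-type classification

Features are the 11 listed in the README, in fixed order; undefined grid or
border scores are imputed to the dataset minimum (flagged per unit) so
DBSCAN receives complete vectors. z-scoring is per dataset, never pooled.
Defaults: UMAP n_neighbors 15, min_dist 0.1, 2 components, fixed seed;
DBSCAN eps 0.5, min_samples 5 in the embedded space. All are exposed and
echoed into outputs.

Labeling works on cluster-mean z-profiles of SI, grid score, border score
and MFR. One anchor cluster per type is chosen by rank: highest grid score
→ grid; highest border score → border; highest MFR − SI → interneuron;
highest SI − grid − border → aperiodic spatial (the subtraction expresses
"spatially informative but neither periodic nor wall-locked"; plain
highest-SI mislabels grid fragments, and imputed grid scores distort a
SI − grid contrast for border cells). Because density clustering routinely
splits one physiological type into several pure clusters, each unanchored
cluster inherits the type of the nearest anchor profile (Euclidean in the
4-d z-profile space) if within distance 2.5, else stays undefined; 2.5
sits between the observed within-type profile spread (≈1.7) and the
distance between different archetype profiles (≈3). DBSCAN noise points
stay labeled noise. Exact ties on a deciding statistic raise an explicit
ambiguity error rather than resolving silently.

On the default MEC fixture population (30 grid, 20 interneuron, 15 border,
15 aperiodic units, 600 s sessions) the pipeline recovers ≈96% of
ground-truth types on average across seeds; residual confusions are
aperiodic cells whose Gaussian fields happen to sit against a wall and
genuinely resemble border cells in feature space.

## Bayesian decoder

Encoding maps divide per-bin spike counts by dwell on the 60 × 60 grid and
smooth with a Gaussian of sd 1 bin truncated to a 5 × 5 support; a floor of
0.01 Hz prevents a single empty bin from zeroing the likelihood. All
posterior algebra is in the log domain (window counts reach tens of spikes;
direct products underflow). Window spike counts use half-open intervals
[c − τ/2, c + τ/2); argmax ties break to the lowest linear bin index for
determinism.

The continuity scale is σ_t = K·V^d with V the speed implied by the two
previous estimates and the encoding-period mean speed for the first two
windows. V is floored at 0.25 cm/s — below any movement criterion — because
a momentarily static estimate would otherwise collapse the prior to a
delta function and freeze the path (observable with very small
populations). K = ∞ disables the constraint, reducing the decoder exactly
to one-step maximum a posteriori with a flat prior. The spatial prior P(x)
defaults to flat; an occupancy-derived prior can be supplied through the
posterior interface. With 50 simulated place cells in the 40 cm arena the
mean reconstruction error is ≈3 cm; it degrades to ≈15 cm with 2 cells and
decreases monotonically with population size.

## LFP band power

Movement bouts: running speed smoothed with a 0.5 s Gaussian must exceed
2 cm/s for at least 1 s; qualifying runs are tiled into fixed 5 s bouts so
every bout contributes the same spectral resolution. PSDs are Welch
averages of 1 s Hann windows with 50% overlap (resolving the 4 Hz lower
theta edge within a 5 s bout); band power is the trapezoidal area under the
PSD across each band. gamma1 defaults to 30–50 Hz; the band table is a
plain dict and fully configurable. Parseval (PSD integral vs. signal
variance) holds within 5% on stationary fixtures.

## Vessel masks and coverage

Artifact candidates are connected components above mean + 2 sd intensity
passing circularity 4πA/P² ≥ 0.8 (rejects elongated vessel profiles) and a
center-vs-annulus brightness ratio ≥ 1.5. Their disks are replaced by
linear interpolation from a surrounding ring (exact on constant
backgrounds, bounded by the ring values otherwise) before a sd-1 Gaussian
smooth. Canny edges (sigma tied to the smoothing kernel) are masked around
artifact locations, closed with a 5 px disk — the closing radius must span
half the vessel lumen, because vessels crossing the image border never form
closed contours and hole-filling alone cannot recover them — dilated by
2 px, hole-filled, and eroded by the same 2 px to undo the dilation bias.
Filled interiors are validated against the underlying fluorescence (Otsu
split of the cleaned image): a pocket of background enclosed between two
nearby vessels is not lumen and is not absorbed into the mask. Components
under 64 px are dropped, and detected artifact disks are carved out of the
final mask. On the synthetic noise grid (noise sd 0.01–0.05, five seeds
each) Dice against ground truth is ≈0.90–0.92.

Coverage is the percentage of mask pixels whose stain intensity exceeds the
positivity threshold (Otsu within the mask by default; a fixed value can be
given). z-scores are computed strictly within a staining batch; batches
with one section or zero variance yield flagged undefined z.

## Behavioral scoring

Strategy classes: futile if no escape within 60 s, otherwise chain if more
than 4 decoy errors else spatial — a trial with exactly 4 errors counts as
spatial. The block-level strategy score is the mean of the per-trial ranks
(futile 0, chain 1, spatial 2) divided by 2, a declared convention mapping
all-futile to 0 and all-spatial to 1. Probe zones are twelve 30° arcs
centered on the exits; frames are assigned purely by angle, so zone times
partition the tracked duration exactly even if a frame strays outside the
nominal maze radius (such frames are flagged). Error counts are consumed
as inputs; body-part tracking is out of scope. Ratios: OPM
(moved − stable)/total, NOR (novel − familiar)/total, investigation
right/total, anxiety tasks (closed − open)/total; zero totals yield flagged
undefined ratios.

## Problem sizes used in the test suite

Recovery benchmarks run on 600 s MEC sessions (80 units) across 20 seeds
for classification, 20 seeds of 6-unit sessions for grid-score
discrimination, and 700 s CA1 sessions with 50 place cells across 10 seeds
for the decoder sweep; these sizes give stable statistics while keeping the
default `pytest` run to a few minutes. Classification recovery is assessed
as mean accuracy across seeds.

## Known limitations

Grid spacing/orientation estimation, head-direction and conjunctive codes,
1-D track linearization, replay decoding, spike–field coupling and
artifact rejection beyond bout selection are out of scope. The classifier's
labeling assumes the four archetype populations are present; datasets
missing a class will still assign each anchor label to some cluster, so
profiles should be inspected before trusting labels on atypical data. The
decoder assumes Poisson spiking conditioned on position and stationary
tuning between encoding and decoding periods.
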