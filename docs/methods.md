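# Methods

This note documents the models implemented in `neuromotif`, the default
parameters and why they were chosen, the scope of the synthetic-data
generator, and the numerical decisions that affect results.

## 1. Structural layouts and motif catalogue

A `StructuralLayout` is a set of labelled population nodes with planar
positions (µm), a binary directed adjacency matrix, and optional per-edge
polyline geometry. The catalogue contains ten motifs on 3–4 nodes:

| id | nodes | description |
|----|-------|-------------|
| A1 | 3 | fully bidirectional triangle |
| A2 | 3 | directed ring |
| A3 | 3 | bidirectional ring |
| A4 | 3 | directed chain |
| A5 | 3 | star fed from a hub |
| B1 | 3 | directed path |
| B2 | 3 | bidirectional path |
| B3 | 4 | Y-junction |
| B4 | 4 | ring with one diagonal |
| B5 | 4 | two bidirectional diagonals that cross once |

Triangle motifs sit on an equilateral triangle and square motifs on a
square, both with 1000 µm sides — the scale at which distinct somatic
clusters can be bridged by guided axon bundles. B5 is the only motif whose
*drawing* contains an edge crossing (at the square's centre); its *graph*
is still planar. This distinction — geometric crossing versus graph
non-planarity — is central to the package, so both analyses exist:

- `compute_crossings` enumerates interior pairwise intersections of edge
  polylines, merging intersection points within a tolerance (default
  1 µm × 10⁻⁶) and reporting each crossing's multiplicity (number of edges
  through the point). Endpoint contacts are not crossings.
- `decompose_crossings` rewrites any crossing of multiplicity m > 2 into
  pairwise crossings by bending all but one participating edge around the
  point with offsets of m·10·tolerance along the edge normal. Adjacency
  and node positions are untouched; only the drawing changes.
- `is_planar` wraps a linear-time planarity test and classifies the
  Kuratowski witness of a non-planar graph as K5 or K3,3 by the number of
  branch vertices (degree ≥ 3) in the witness subgraph.

`bridge_adjacency` returns the two four-population reference designs used
for guidance-field experiments: all six bidirectional connections
(field off, 12 directed edges) or only the two crossing diagonals
(field on, 4 directed edges).

## 2. Synthetic-data generator

The generator produces data with known ground truth at every level. Its
defaults are the study conditions; analyses and tests run against them
unmodified.

### 2.1 Neuron placement and spiking

`layout_neurons` places `n_per_node` somata uniformly inside a disc of
radius `node_radius` around each population node. `simulate_spikes`
produces a binary spike raster on a regular frame grid:

- each neuron fires spontaneously with probability `p_base` per frame;
- each population starts a burst with probability `p_burst` per frame; a
  burst lasts `burst_len` frames and recruits each member neuron with
  probability `p_in`;
- one frame after a burst starts, each structural successor population
  starts its own burst with probability `p_trans` (*single-hop*
  propagation: induced bursts do not propagate further — see §6).

### 2.2 Fluorescence model

Spikes are convolved with a causal exponential kernel
`amp · exp(−t/tau_ca)` (AR(1) filter), scaled by a baseline of
1000 fluorescence units, optionally multiplied by a bleaching envelope
`exp(−t/bleach_tau)`, and corrupted with i.i.d. Gaussian noise of
standard deviation `noise_sd` (relative units). `render_stack` draws each
soma as a uniform disc in a 16-bit image stack, so the image-processing
path can be tested end to end against the same ground truth.

### 2.3 Neurite trajectories

`simulate_trajectories` grows 2-D random walks with Gaussian turning
noise. With `field_on=True` a restoring torque biases headings toward the
channel axis. A reflecting barrier beside the axis models a physical
channel wall: crossing steps are projected back onto the wall
(perfectly inelastic contact, restitution 0 — see §6).

### 2.4 Default parameters

| parameter | default | unit | rationale |
|-----------|---------|------|-----------|
| `n_per_node` | 25 | neurons | ~100 somata over 4 populations; dense enough for population statistics, small enough to segment |
| `node_radius` | 150 | µm | somatic cluster footprint, well separated at 1000 µm spacing |
| `frame_rate` | 2 | Hz | typical wide-field calcium imaging rate |
| `duration` | 600 | s | 1200 frames; enough transients per neuron for correlation estimates |
| `p_base` | 0.01 | /frame | sparse spontaneous activity (~1.2 events/min) |
| `p_burst` | 0.02 | /frame | network bursts are the dominant coordinated events |
| `p_in` | 0.8 | — | most, not all, members join a population burst |
| `p_trans` | 0.7 | — | reliable but imperfect propagation along an axon bundle |
| `burst_len` | 2 | frames | 1 s burst at 2 Hz |
| `tau_ca` | 2.0 | s | calcium-indicator decay constant |
| `amp` | 0.3 | ΔF/F0 | single-transient amplitude |
| `noise_sd` | 0.03 | ΔF/F0 | amplitude-to-noise ratio 10 |
| `soma_diameter` | 10 | µm | typical soma size |

`noise_sd = 0` is allowed (noiseless traces are needed for exactness
tests); negative values are rejected.

## 3. Calcium processing

`extract_traces` segments a mean-intensity image by Otsu threshold,
labels connected components, filters them by area against the expected
soma disc, and averages pixel intensities per label and frame. The stack
is kept in its native integer dtype throughout; only the per-ROI means
are floats (see §5).

`compute_dff` forms (F − F0)/F0 with F0 the per-neuron temporal mean or a
low percentile (default 10th) for bleaching recordings; F0 ≤ 0 is an
error naming the offending neuron.

### 3.1 Spike-onset detection

`detect_spikes` marks frame t of neuron i as an onset when both:

1. **level test** — ΔF/F0 exceeds a per-frame population threshold
   θ(t) = Q25(t) + 0.674·ŝ_pop + margin_k·scale, where Q25(t) is the
   cross-neuron lower quartile at frame t, ŝ_pop is the median across
   neurons of a robust per-neuron noise scale
   (1.4826·median|ΔF differences|/√2), 0.674·ŝ_pop corrects the lower
   quartile of a Gaussian background up to its mean, and
   scale = min(recording-wide standard deviation, 2·ŝ_pop);
2. **rise test** — the first difference of ΔF/F0 exceeds
   margin_k·√2·ŝ_i, the per-neuron noise scale of a difference of two
   noisy samples.

Design rationale: a naive frame-wise mean + k·sd threshold is
self-defeating in this regime, because network bursts recruit a large
fraction of neurons simultaneously, which drags the frame mean and
standard deviation up with the signal and pushes the threshold above the
transients themselves. The lower quartile is immune to co-activation of
up to half the neurons; the bias correction restores precision during
sparse activity; clamping the margin scale at 2·ŝ_pop prevents the
threshold from tracking burst amplitude; and the rise test confines
detections to onset frames rather than decay tails.

`match_onsets` scores a detected raster against ground truth with a
±`tol_frames` tolerance (binary dilation of the truth/detection rasters)
and returns (recall, precision); empty denominators give NaN.

## 4. Functional networks and graph statistics

`correlation_matrix` computes, for each neuron pair, the maximum Pearson
correlation over integer lags 0…`max_lag` (default 5 frames = 2.5 s,
covering the burst-propagation delay plus kernel smearing); the matrix is
symmetrized by taking the element-wise maximum of the two lag directions.
Constant traces yield zero correlation with a warning.

`build_functional_network` thresholds the correlation matrix at a
percentile (default 99) of a surrogate ensemble built by circularly
shifting each neuron's trace by a random offset (default 20 surrogates,
minimum 19 so the 99th percentile is defined). Surrogate offsets are
keyed to neuron identity, so results are invariant to row order.

`small_world_metrics` normalizes the clustering coefficient C and
characteristic path length L by the means of a null ensemble (default 20
graphs) of degree-preserving double-edge-swap rewirings (or Erdős–Rényi
graphs matching n and edge count): γ = C/C_null, λ = L/L_null,
small-world index σ = γ/λ. L is averaged over connected pairs only and
reported with the fraction of pairs covered. Null ensembles without
triangles make γ (and σ) NaN, with a warning.

## 5. Numerical choices

- **Determinism.** Every stochastic routine takes an explicit seed.
  The pipeline derives one sub-seed per stage from
  SHA-256(f"{seed}:{stage}") mod 2³¹, so stages can be rerun in
  isolation and configuration changes only alter downstream stages.
  Surrogates use `SeedSequence([seed, surrogate_index, neuron_id])`,
  giving neuron-order invariance. The pipeline report echoes the full
  configuration *except* `output_dir`, which is a storage location, not
  part of the run: identical configurations and seeds produce
  byte-identical files wherever they are written.
- **Memory.** Image stacks are rendered by accumulating in float32 and
  converting frame-by-frame to uint16; trace extraction never converts
  the stack to float. A default-scale stack (1200 × 676 × 676) then fits
  comfortably in a few GiB.
- **Robust statistics.** Noise scales use the median absolute first
  difference (× 1.4826/√2), which ignores both slow drift and sparse
  transients.
- **Exactness.** Clustering and path length are plain sums/means over
  integer adjacency structures and are reproducible bit-for-bit for a
  fixed row order; under node relabelling they agree to summation-order
  rounding (~10⁻¹⁶).

## 6. Scope, open choices, and limitations

- **Single-hop propagation.** Induced bursts do not themselves propagate,
  so activity cannot reverberate around cycles. This keeps the mapping
  from structural edges to pairwise correlations direct and analyzable;
  it under-models recurrent amplification in strongly cyclic motifs.
- **Catalogue geometry.** Node positions for the catalogue motifs are
  canonical (equilateral triangle / square with 1000 µm sides);
  experimental layouts can be loaded from JSON instead.
- **Inelastic walls.** Trajectory–barrier contacts use restitution 0
  (projection onto the wall). Growth cones adhere rather than bounce,
  but no contact-mechanics data back a specific restitution value.
- **Detector operating regime.** The threshold reinterprets a per-frame
  "mean + k·sd" rule with robust statistics (§3.1). It assumes transients
  are positive-going and that fewer than half of the neurons share a
  background state per frame; inhibitory (negative) signals are out of
  scope.
- **Fluorescence model.** Noise is Gaussian and white; there is no shot
  noise, motion, neuropil contamination, or overlapping-soma
  cross-talk beyond geometric disc overlap in rendered stacks.
- **Population-level inference.** The population functional matrix
  averages neuron-pair correlations between populations; it does not
  attempt directed (causal) inference, so bidirectional and unidirectional
  structural edges are not distinguished functionally.
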