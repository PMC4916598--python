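"""Synthetic data with known ground truth for the full pipeline.

The generator emulates the desk-scale conditions of compartmentalized
population cultures observed by calcium imaging: 25-100 neurons per
population node, spontaneous plus burst-coupled spiking whose
inter-population coupling follows a chosen structural adjacency, calcium
transients sampled at 2 Hz for 10 minutes, additive Gaussian noise and
optional bleaching drift, rendered image stacks, and neurite trajectories
with and without a phenomenological repelling boundary (the electrode
effect).

Spiking model (discrete frames)
-------------------------------
Each neuron fires spontaneously with per-frame probability ``p_base``.
Each population independently initiates a burst with per-frame probability
``p_burst``; during a burst (``burst_len`` frames) its neurons fire with
probability ``p_in`` per frame.  A burst propagates to each structural
successor population with probability ``p_trans`` and a one-frame delay
(directed edges propagate source → target only); propagated bursts do not
re-propagate.  This minimal model produces the two signatures the pipeline
is built to detect: strong intra-population correlation and
structural-edge-dependent inter-population correlation.

Calcium model
-------------
``F_i(t) = F0 · (1 + amp · (s_i ∗ κ)(t)) · b(t) + ε`` with a causal
single-exponential kernel ``κ(t) = exp(−t / tau_ca)`` (instantaneous rise;
the rise time is sub-frame at 2 Hz), optional bleaching
``b(t) = exp(−t / bleach_tau)``, and i.i.d. Gaussian noise of standard
deviation ``noise_sd · F0``.  ``F0`` is fixed at 1000 arbitrary units so
the signal-to-noise ratio is simply ``amp / noise_sd``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from neuromotif._errors import ValidationError
from neuromotif.structure import StructuralLayout
from neuromotif.neurites import Trajectory

__all__ = [
    "SimulationConfig", "GroundTruth", "BurstEvent",
    "layout_neurons", "simulate_spikes", "render_traces", "render_stack",
    "simulate_trajectories", "F0_UNITS",
]

F0_UNITS = 1000.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic recording.

    Defaults emulate a 2 Hz, 10-minute recording of four populations of
    25 neurons each with burst coupling along structural edges.
    """

    n_per_node: int = 25
    node_radius: float = 150.0          # μm
    frame_rate: float = 2.0             # Hz
    duration: float = 600.0             # s
    p_base: float = 0.01                # per-frame spontaneous spike prob.
    p_burst: float = 0.02               # per-frame burst initiation prob.
    p_in: float = 0.8                   # within-burst per-frame spike prob.
    p_trans: float = 0.7                # burst transmission prob. per edge
    burst_len: int = 2                  # frames
    tau_ca: float = 2.0                 # s, calcium decay
    amp: float = 0.3                    # transient amplitude, ΔF/F0 units
    noise_sd: float = 0.03              # fraction of baseline F0
    bleach_tau: float | None = None     # s, or None for no bleaching
    soma_diameter: float = 10.0         # μm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_base", "p_burst", "p_in", "p_trans"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} must be in [0, 1]")
        for name in ("frame_rate", "duration", "tau_ca", "amp",
                     "node_radius", "soma_diameter"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name}={v} must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_per_node < 1:
            raise ValidationError("n_per_node must be >= 1")
        if self.burst_len < 1:
            raise ValidationError("burst_len must be >= 1")
        if self.bleach_tau is not None and not self.bleach_tau > 0:
            raise ValidationError("bleach_tau must be positive or None")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BurstEvent:
    """One population burst: origin, start frame and where it propagated."""

    population: str
    start_frame: int
    propagated_to: list[str]


@dataclass
class GroundTruth:
    """True spike raster plus the structural adjacency and burst log."""

    raster: np.ndarray                  # (n_neurons, n_frames) uint8
    adjacency: np.ndarray               # structural adjacency used
    events: list[BurstEvent] = field(default_factory=list)
    frame_rate: float = 2.0

    @property
    def n_neurons(self) -> int:
        return self.raster.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raster.shape[1]

    def onsets(self) -> np.ndarray:
        """Rising edges of the raster (first frame of each spike run)."""
        padded = np.pad(self.raster, ((0, 0), (1, 0)))
        return ((padded[:, 1:] == 1) & (padded[:, :-1] == 0)).astype(np.uint8)

    def events_to_json(self) -> list[dict]:
        return [{"population": e.population, "start_frame": e.start_frame,
                 "propagated_to": e.propagated_to} for e in self.events]


def layout_neurons(layout: StructuralLayout,
                   config: SimulationConfig) -> pd.DataFrame:
    """Place ``n_per_node`` neurons uniformly in a disc around each node.

    Returns a table with columns ``neuron_id, population, x_um, y_um,
    soma_diameter_um``.  Deterministic under ``config.seed``.  Overlapping
    node discs trigger a warning, not an error.
    """
    rng = np.random.default_rng(config.seed)
    pos = layout.positions
    n_pop = layout.n_populations
    for i in range(n_pop):
        for j in range(i + 1, n_pop):
            if np.linalg.norm(pos[i] - pos[j]) < 2 * config.node_radius:
                warnings.warn(
                    f"node discs {i} and {j} overlap", stacklevel=2)
    rows = []
    nid = 0
    for k, label in enumerate(layout.population_labels):
        # uniform in disc via radius = R * sqrt(u)
        r = config.node_radius * np.sqrt(rng.random(config.n_per_node))
        theta = rng.uniform(0, 2 * np.pi, config.n_per_node)
        for rr, th in zip(r, theta):
            rows.append({
                "neuron_id": nid,
                "population": label,
                "x_um": pos[k, 0] + rr * np.cos(th),
                "y_um": pos[k, 1] + rr * np.sin(th),
                "soma_diameter_um": config.soma_diameter,
            })
            nid += 1
    return pd.DataFrame(rows)


def simulate_spikes(layout: StructuralLayout,
                    neurons: pd.DataFrame,
                    config: SimulationConfig,
                    forced_bursts: list[tuple[str, int]] | None = None
                    ) -> GroundTruth:
    """Generate the ground-truth spike raster under the burst model.

    ``forced_bursts`` optionally injects deterministic bursts as
    ``(population_label, start_frame)`` pairs (used for targeted tests).
    """
    unknown = set(neurons["population"]) - set(layout.population_labels)
    if unknown:
        raise ValidationError(f"neurons reference unknown populations {unknown}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_frames = config.n_frames
    n_neurons = len(neurons)
    labels = list(layout.population_labels)
    pop_index = {lab: k for k, lab in enumerate(labels)}
    members = [np.flatnonzero(neurons["population"].to_numpy() == lab)
               for lab in labels]

    raster = (rng.random((n_neurons, n_frames)) < config.p_base).astype(np.uint8)

    # burst initiations per population
    starts: list[tuple[int, int, bool]] = []  # (pop, frame, is_origin)
    init = rng.random((len(labels), n_frames)) < config.p_burst
    for k in range(len(labels)):
        for t in np.flatnonzero(init[k]):
            starts.append((k, int(t), True))
    for lab, t in forced_bursts or ():
        starts.append((pop_index[lab], int(t), True))
    starts.sort(key=lambda s: (s[1], s[0]))

    events: list[BurstEvent] = []
    successors = [np.flatnonzero(layout.adjacency[k]) for k in
                  range(len(labels))]
    queue = list(starts)
    for k, t, is_origin in queue:
        # neurons of the population fire during the burst window
        t_end = min(t + config.burst_len, n_frames)
        if t < n_frames and len(members[k]):
            burst_spikes = rng.random((len(members[k]), t_end - t)) < config.p_in
            raster[np.ix_(members[k], np.arange(t, t_end))] |= \
                burst_spikes.astype(np.uint8)
        if not is_origin:
            continue
        propagated = []
        for succ in successors[k]:
            if rng.random() < config.p_trans:
                propagated.append(labels[succ])
                if t + 1 < n_frames:
                    queue.append((int(succ), t + 1, False))
        events.append(BurstEvent(labels[k], t, propagated))

    return GroundTruth(raster=raster, adjacency=layout.adjacency.copy(),
                       events=events, frame_rate=config.frame_rate)


def render_traces(truth: GroundTruth, config: SimulationConfig):
    """Convolve the raster with the calcium kernel and add noise.

    Returns a :class:`neuromotif.calcium.FluorescenceRecording` with
    ``F_i(t) = F0 (1 + amp (s_i ∗ κ)(t)) b(t) + ε``.
    """
    from neuromotif.calcium import FluorescenceRecording

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    raster = truth.raster.astype(float)
    if raster.size == 0:
        raise ValidationError("empty raster")
    dt = 1.0 / config.frame_rate
    decay = np.exp(-dt / config.tau_ca)
    # causal exponential kernel convolution as an AR(1) filter
    conv = lfilter([1.0], [1.0, -decay], raster, axis=1)
    t = np.arange(truth.n_frames) * dt
    bleach = (np.exp(-t / config.bleach_tau)
              if config.bleach_tau is not None else np.ones_like(t))
    traces = F0_UNITS * (1.0 + config.amp * conv) * bleach
    traces = traces + rng.normal(0.0, config.noise_sd * F0_UNITS, traces.shape)
    return FluorescenceRecording(
        traces=traces, frame_rate=config.frame_rate,
        neuron_ids=list(range(truth.n_neurons)))


def render_stack(neurons: pd.DataFrame,
                 recording,
                 pixel_size: float = 2.0,
                 background: float = 100.0,
                 margin_um: float = 25.0) -> np.ndarray:
    """Rasterize neurons as uniform discs into a 16-bit image stack.

    Each neuron is drawn as a disc of its soma diameter at its coordinates
    with its per-frame trace intensity; overlapping discs sum and clip at
    the uint16 maximum.  Returns an array of shape (frames, H, W).
    """
    from skimage.draw import disk

    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    traces = recording.traces
    n_frames = traces.shape[1] if len(neurons) else recording.traces.shape[1]
    if len(neurons):
        x = neurons["x_um"].to_numpy()
        y = neurons["y_um"].to_numpy()
        x0, y0 = x.min() - margin_um, y.min() - margin_um
        w = int(np.ceil((x.max() + margin_um - x0) / pixel_size)) + 1
        h = int(np.ceil((y.max() + margin_um - y0) / pixel_size)) + 1
    else:
        x0 = y0 = 0.0
        h = w = int(np.ceil(2 * margin_um / pixel_size))
    # accumulate in float32: a 10-minute default-scale stack in float64
    # would not fit typical memory budgets, and uint16 output needs far
    # less precision than float32 carries
    stack = np.full((n_frames, h, w), float(background), dtype=np.float32)
    for row_idx, row in enumerate(neurons.itertuples(index=False)):
        cx = (row.x_um - x0) / pixel_size
        cy = (row.y_um - y0) / pixel_size
        radius = row.soma_diameter_um / 2.0 / pixel_size
        rr, cc = disk((cy, cx), radius, shape=(h, w))
        stack[:, rr, cc] += traces[row_idx][:, None].astype(np.float32)
    np.clip(stack, 0, np.iinfo(np.uint16).max, out=stack)
    out = np.empty(stack.shape, dtype=np.uint16)
    for k in range(n_frames):   # frame-wise to avoid a second full-size copy
        out[k] = stack[k]
    return out


def simulate_trajectories(n: int,
                          field_on: bool,
                          channel_axis: tuple[float, float] = (1.0, 0.0),
                          step: float = 5.0,
                          turn_sd: float = 20.0,
                          barrier: tuple[tuple[float, float], tuple[float, float]] | None = None,
                          seed: int = 0,
                          n_steps: int = 100,
                          div_days: float = 6.0,
                          restitution: float = 0.0) -> list[Trajectory]:
    """Biased random walks emulating neurite growth, with optional bounce.

    Each walk starts at the origin heading along ``channel_axis`` and turns
    by i.i.d. Gaussian increments (sd ``turn_sd`` degrees) per step of
    ``step`` μm.  When ``field_on``, steps that would enter the forbidden
    half-plane ``barrier`` bounce off its boundary: the perpendicular
    heading component is reversed and scaled by ``restitution`` (default 0,
    i.e. the growth cone re-aligns with the electrode edge, reproducing the
    observed final trajectories parallel to the electrode direction;
    ``restitution=1`` gives a pure specular reflection).

    ``barrier`` is ``((px, py), (nx, ny))``: a boundary point and the
    outward normal of the forbidden side (points q with
    ``(q - p) · n > 0`` are forbidden).  Default: half-plane 20 μm to the
    left of the axis (normal rotated +90° from ``channel_axis``).
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    rng = np.random.default_rng(seed)
    axis = np.asarray(channel_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    axis_angle = np.arctan2(axis[1], axis[0])
    if barrier is None:
        normal = np.array([-axis[1], axis[0]])
        barrier = (tuple(20.0 * normal), tuple(normal))
    b_point = np.asarray(barrier[0], dtype=float)
    b_normal = np.asarray(barrier[1], dtype=float)
    b_normal = b_normal / np.linalg.norm(b_normal)
    # barrier boundary direction, oriented along the channel axis
    b_dir = np.array([-b_normal[1], b_normal[0]])
    if np.dot(b_dir, axis) < 0:
        b_dir = -b_dir
    b_angle = np.arctan2(b_dir[1], b_dir[0])

    sd = np.deg2rad(turn_sd)
    out: list[Trajectory] = []
    for k in range(n):
        theta = axis_angle
        p = np.zeros(2)
        pts = [p.copy()]
        for _ in range(n_steps):
            theta = theta + rng.normal(0.0, sd)
            nxt = p + step * np.array([np.cos(theta), np.sin(theta)])
            if field_on and np.dot(nxt - b_point, b_normal) > 0:
                # bounce: reverse and damp the perpendicular heading component
                phi = np.angle(np.exp(1j * (theta - b_angle)))
                theta = b_angle - restitution * phi
                nxt = p + step * np.array([np.cos(theta), np.sin(theta)])
                if np.dot(nxt - b_point, b_normal) > 0:
                    # still inside (grazing geometry): slide along the boundary
                    theta = b_angle
                    nxt = p + step * b_dir
            p = nxt
            pts.append(p.copy())
        out.append(Trajectory(points=np.array(pts), div_days=div_days,
                              traj_id=f"traj{k:04d}"))
    return out
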