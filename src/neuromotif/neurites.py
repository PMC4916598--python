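"""Neurite trajectory morphometrics.

Quantities computed on traced neurite extensions:

* orientation of a neurite (or point cloud) relative to the channel axis,
  from the major axis of the second-central-moment ellipse;
* angular distribution of orientations with a Gaussian fit and FWHM;
* deviation events — points where the local growth angle changes by more
  than a relative threshold compared to 50 μm (five growth-cone diameters)
  earlier along the arc;
* average growth speed, extension arc length divided by days in vitro;
* z centerline of a neurite in a confocal cross-section stack;
* directional growth fraction — share of neurites whose net displacement
  stays within a cone around the channel axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from neuromotif._errors import ValidationError

__all__ = [
    "Trajectory", "AngularDistribution", "DeviationEvent",
    "orientation_angle", "angular_fwhm", "deviation_events", "growth_speed",
    "z_centerline", "directional_fraction",
    "trajectories_to_csv", "trajectories_from_csv",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass
class Trajectory:
    """An ordered neurite path in 2D or 3D with its culture age.

    ``points`` is an ``(m, 2)`` or ``(m, 3)`` array in μm with m ≥ 2 and no
    repeated consecutive points; ``div_days`` (> 0) is the number of days
    in vitro over which the extension grew.
    """

    points: np.ndarray
    div_days: float
    traj_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 \
                or self.points.shape[1] not in (2, 3):
            raise ValidationError("trajectory needs >= 2 points in 2D or 3D")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValidationError("consecutive trajectory points must differ")
        if not self.div_days > 0:
            raise ValidationError("div_days must be positive")

    @property
    def arc_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0),
                                    axis=1).sum())

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each vertex (starts at 0)."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class AngularDistribution:
    """Histogram of orientation angles with a Gaussian fit.

    180 bins of 1° over [−90°, +90°); ``fwhm_degrees`` is
    2·sqrt(2 ln 2) times the fitted Gaussian sd.  ``converged`` is False
    when the fit failed (histogram still populated).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    centre: float = np.nan
    sd: float = np.nan
    amplitude: float = np.nan
    fwhm_degrees: float = np.nan
    converged: bool = False


@dataclass
class DeviationEvent:
    """A growth-direction change along a neurite.

    ``arc_position`` is the arc length s (μm) at the evaluation point;
    ``angle`` and ``angle_before`` are the absolute tangent angles to the
    channel axis at s and s − lookback; ``relative_change`` exceeds the
    detection threshold.
    """

    arc_position: float
    angle: float
    angle_before: float
    relative_change: float


def orientation_angle(points: np.ndarray,
                      axis: tuple[float, float] = (1.0, 0.0),
                      weights: np.ndarray | None = None) -> float:
    """Major-axis angle of a point set relative to ``axis``, in (−90, 90].

    Fits the second-central-moment ellipse of the (optionally weighted)
    point set; the returned angle is that of its major axis measured
    against the channel direction, 0° meaning parallel.  Accepts a binary
    mask image instead of points (nonzero pixels become (x, y) = (col, row)
    coordinates).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2 and pts.shape[1] not in (2,):
        # treat as a mask image
        rr, cc = np.nonzero(pts)
        if weights is None:
            weights = pts[rr, cc].astype(float)
        pts = np.column_stack([cc, rr]).astype(float)
    if pts.shape[0] < 2:
        raise ValidationError("orientation_angle needs >= 2 points")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    mean = np.average(pts, axis=0, weights=w)
    centered = pts - mean
    cov = (centered * w[:, None]).T @ centered / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    ang = np.degrees(np.arctan2(major[1], major[0])
                     - np.arctan2(ax[1], ax[0]))
    # orientation is defined modulo 180°, mapped to (−90, 90]
    ang = (ang + 90.0) % 180.0 - 90.0
    if ang == -90.0:
        ang = 90.0
    return float(ang)


def _gaussian(x, amplitude, centre, sd):
    return amplitude * np.exp(-0.5 * ((x - centre) / sd) ** 2)


def angular_fwhm(angles, n_min: int = 30) -> AngularDistribution:
    """Histogram orientation angles and fit a Gaussian to estimate FWHM.

    ``angles`` in degrees are folded into [−90°, 90°) and binned at 1°
    resolution (180 bins); a least-squares Gaussian fit to the bin counts
    yields the FWHM.  With fewer than ``n_min`` angles, or on fit failure,
    the histogram is returned with ``converged=False``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValidationError("angular_fwhm needs at least 2 angles")
    folded = (angles + 90.0) % 180.0 - 90.0
    edges = np.linspace(-90.0, 90.0, 181)
    counts, _ = np.histogram(folded, bins=edges)
    dist = AngularDistribution(bin_edges=edges, counts=counts)
    if angles.size < n_min or np.count_nonzero(counts) < 3:
        return dist
    centres = (edges[:-1] + edges[1:]) / 2.0
    try:
        p0 = [counts.max(), centres[np.argmax(counts)], 10.0]
        popt, _ = curve_fit(_gaussian, centres, counts, p0=p0,
                            maxfev=10000)
    except (RuntimeError, ValueError):
        return dist
    amplitude, centre, sd = popt
    sd = abs(sd)
    dist.amplitude = float(amplitude)
    dist.centre = float(centre)
    dist.sd = float(sd)
    dist.fwhm_degrees = float(FWHM_FACTOR * sd)
    dist.converged = True
    return dist


def _tangent_angles(traj: Trajectory,
                    axis: tuple[float, float]) -> np.ndarray:
    """Absolute angle (degrees) of the local tangent to the channel axis.

    Central differences at interior vertices, one-sided at the ends; 3D
    trajectories use their xy projection.
    """
    pts = traj.points[:, :2]
    tangents = np.empty_like(pts)
    tangents[1:-1] = pts[2:] - pts[:-2]
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    ang = np.degrees(np.arctan2(tangents[:, 1], tangents[:, 0])
                     - np.arctan2(ax[1], ax[0]))
    ang = (ang + 180.0) % 360.0 - 180.0
    return np.abs(ang)


def deviation_events(traj: Trajectory,
                     lookback: float = 50.0,
                     threshold: float = 0.10,
                     floor: float = 5.0,
                     axis: tuple[float, float] = (1.0, 0.0)
                     ) -> list[DeviationEvent]:
    """Detect growth-direction deviations along a traced neurite.

    At each vertex with arc position s ≥ ``lookback``, the absolute tangent
    angle θ(s) is compared to θ(s − lookback) (linearly interpolated); an
    event is recorded when |θ(s) − θ(s−lookback)| / max(|θ(s−lookback)|,
    ``floor``) exceeds ``threshold``.  The floor regularizes the relative
    change when the earlier angle is near 0°.  Returns an empty list with a
    warning when the trajectory is shorter than ``lookback``.
    """
    s = traj.arc_positions()
    if s[-1] < lookback:
        warnings.warn("trajectory shorter than lookback; no events",
                      stacklevel=2)
        return []
    theta = _tangent_angles(traj, axis)
    events: list[DeviationEvent] = []
    for k in range(len(s)):
        if s[k] < lookback:
            continue
        theta_before = float(np.interp(s[k] - lookback, s, theta))
        change = abs(theta[k] - theta_before) / max(abs(theta_before), floor)
        if change > threshold:
            events.append(DeviationEvent(
                arc_position=float(s[k]), angle=float(theta[k]),
                angle_before=theta_before, relative_change=float(change)))
    return events


def growth_speed(traj: Trajectory) -> float:
    """Average growth speed: extension arc length / days in vitro (μm/day)."""
    return traj.arc_length / traj.div_days


def z_centerline(stack: np.ndarray, smoothing_sd: float = 1.0
                 ) -> pd.DataFrame:
    """Per-slice neurite centre in a cross-section stack.

    ``stack`` has shape (n_slices, n_z, n_y): each slice is a cross-section
    perpendicular to the channel with the vertical (z) axis first.  Each
    slice is Gaussian-smoothed, thresholded (Otsu), and the
    intensity-weighted centroid of suprathreshold pixels is reported as the
    slice's (z, y) centre.  Blank slices are omitted.  Returns a DataFrame
    with columns ``slice, z, y``.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.filters import threshold_otsu

    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValidationError("stack must be 3D with >= 2 slices")
    rows = []
    for k, img in enumerate(stack):
        sm = gaussian_filter(img, smoothing_sd)
        if np.ptp(sm) == 0:
            continue
        thr = threshold_otsu(sm)
        mask = sm > thr
        if not mask.any():
            continue
        weights = sm[mask]
        zz, yy = np.nonzero(mask)
        rows.append({"slice": k,
                     "z": float(np.average(zz, weights=weights)),
                     "y": float(np.average(yy, weights=weights))})
    return pd.DataFrame(rows, columns=["slice", "z", "y"])


def deflection_height(centers: pd.DataFrame, reference_z: float = 0.0
                      ) -> float:
    """Maximum centre height above a reference plane (μm or px units)."""
    if centers.empty:
        return float("nan")
    return float(centers["z"].max() - reference_z)


def directional_fraction(trajs: list[Trajectory],
                         axis: tuple[float, float] = (1.0, 0.0),
                         cone_half_angle: float = 30.0
                         ) -> tuple[float, int]:
    """Fraction of neurites growing in the channel direction.

    A trajectory counts as directional when the angle between its net
    displacement (last point − first point, xy projection) and ``axis`` is
    at most ``cone_half_angle`` degrees.  Returns (fraction, count).
    """
    if not trajs:
        raise ValidationError("directional_fraction needs >= 1 trajectory")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    n_dir = 0
    for traj in trajs:
        disp = traj.points[-1, :2] - traj.points[0, :2]
        norm = np.linalg.norm(disp)
        if norm == 0:
            continue
        cosang = np.clip(np.dot(disp, ax) / norm, -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) <= cone_half_angle:
            n_dir += 1
    return n_dir / len(trajs), n_dir


# ---------------------------------------------------------------------------
# I/O


def trajectories_to_csv(trajs: list[Trajectory], path) -> None:
    rows = []
    for traj in trajs:
        for k, pt in enumerate(traj.points):
            row = {"id": traj.traj_id, "point_index": k,
                   "x_um": pt[0], "y_um": pt[1],
                   "div_days": traj.div_days}
            if traj.points.shape[1] == 3:
                row["z_um"] = pt[2]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def trajectories_from_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    out = []
    for tid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("point_index")
        out.append(Trajectory(points=grp[cols].to_numpy(),
                              div_days=float(grp["div_days"].iloc[0]),
                              traj_id=str(tid)))
    return out
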