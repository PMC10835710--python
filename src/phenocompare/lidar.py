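"""Lidar canopy phenotyping: scan geometry, plot cropping, outlier removal,
99th-percentile height, and gap-fraction LAI inversion.

Geometry convention
-------------------
Beam angles are measured from straight down within the scan plane, so a
downward-looking scanner mounted ``mount_height`` meters above the ground
maps a return at range ``r`` and beam angle ``beta`` to

    x = r * sin(beta)            (signed horizontal offset)
    y = mount_height - r * cos(beta)   (height above ground)

For gap-fraction binning, each beam is assigned the zenith angle of its
*line* measured from vertical (0 deg = vertical, 90 deg = horizontal), which
maps the whole sector into the canonical 0-90 deg zenith bins regardless of
the scanner's downward orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import LidarScanSet, PointCloud, ValidationError

#: Fixed zenith-bin boundaries (degrees from vertical) for the gap-fraction profile.
GAP_BIN_EDGES_DEG = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0])

#: 30 inches in meters (exact, 0.0254 m/in): half-width of the analyzed strip.
DEFAULT_HALF_WIDTH_M = 30 * 0.0254  # 0.762


class EmptyPlotError(ValidationError):
    """A filtering stage removed every point from the plot."""


@dataclass
class PlotConfig:
    """Processing parameters for one plot."""

    half_width: float = DEFAULT_HALF_WIDTH_M  # meters left/right of the lidar kept
    trim_fraction: float = 0.15  # fraction of scans dropped at each end
    grubbs_alpha: float = 0.01
    height_percentile: float = 99.0
    ground_eps: float = 0.1  # returns at y <= this are canopy gaps (m)
    below_ground_tol: float = 0.05  # returns below -tol are dropped (m)


@dataclass
class GapFractionProfile:
    """Per-zenith-bin gap fractions P_i with beam bookkeeping."""

    bin_edges_deg: np.ndarray
    gap_fraction: np.ndarray  # P_i per bin, NaN where the bin is empty
    n_beams: np.ndarray  # beams assigned to each bin
    n_gaps: np.ndarray  # beams counted as gaps in each bin
    replaced: np.ndarray  # True where a zero P_i was replaced
    empty: np.ndarray  # True where the bin received no beams

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}


@dataclass
class PlotPhenotypes:
    """End-to-end outputs for one plot, with filter provenance."""

    height: float  # meters
    lai: float  # dimensionless
    n_points_used: int
    gap_profile: GapFractionProfile
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "height": self.height,
            "lai": self.lai,
            "n_points_used": self.n_points_used,
            "gap_profile": self.gap_profile.to_dict(),
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def zenith_from_beam_angle(beta_deg) -> np.ndarray:
    """Zenith angle of the beam *line* from vertical, in [0, 90] degrees."""
    z = np.abs(np.asarray(beta_deg, float))
    return np.where(z > 90.0, 180.0 - z, z)


def polar_to_cartesian(
    scans: LidarScanSet, below_ground_tol: float = 0.05
) -> PointCloud:
    """Transform polar beam returns to (x, y) points above ground.

    Beams without a return are skipped.  Points more than
    ``below_ground_tol`` meters below ground are dropped (their count is
    recoverable by comparing sizes); small negative heights are clamped to 0.
    """
    beta = np.deg2rad(scans.angles)
    n_scans = scans.n_scans
    r = scans.ranges
    x = r * np.sin(beta)[None, :]
    y = scans.mount_height - r * np.cos(beta)[None, :]
    scan_index = np.broadcast_to(np.arange(n_scans)[:, None], r.shape)
    keep = np.isfinite(r) & (y >= -below_ground_tol)
    y = np.maximum(y[keep], 0.0)
    return PointCloud(x=x[keep], y=y, scan_index=scan_index[keep].copy())


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def trim_scan_indices(n_scans: int, trim_fraction: float) -> np.ndarray:
    """Indices of the scans retained after dropping ceil(f*n) at each end."""
    n_trim = int(np.ceil(trim_fraction * n_scans))
    return np.arange(n_trim, n_scans - n_trim)


def preprocess_plot(
    cloud: PointCloud,
    half_width: float = DEFAULT_HALF_WIDTH_M,
    trim_fraction: float = 0.15,
) -> PointCloud:
    """Crop the cloud to |x| <= half_width and drop edge scans.

    The first and last ``ceil(trim_fraction * n_scans)`` scans (by scan
    index over the full original scan range) are removed to avoid plot edges.
    """
    keep_x = np.abs(cloud.x) <= half_width
    if not keep_x.any():
        raise EmptyPlotError("the |x| crop removed every point")
    n_scans = int(cloud.scan_index.max()) + 1 if len(cloud) else 0
    kept_scans = trim_scan_indices(n_scans, trim_fraction)
    keep_scan = np.isin(cloud.scan_index, kept_scans)
    keep = keep_x & keep_scan
    if not keep.any():
        raise EmptyPlotError("the scan trim removed every point")
    return PointCloud(x=cloud.x[keep], y=cloud.y[keep], scan_index=cloud.scan_index[keep])


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution,
    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)), t = t_{alpha/(2n), n-2}."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_filter(
    y: Sequence[float], alpha: float = 0.01, max_iter: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs outlier removal.

    Repeatedly removes the single most extreme value while
    G = max|y - mean| / sd exceeds the critical value at ``alpha``.
    Constant data removes nothing; n < 3 skips the filter.
    Returns ``(kept, removed)`` arrays (kept preserves input order).
    """
    y = np.asarray(y, float)
    keep = np.ones(y.size, dtype=bool)
    removed_idx: list[int] = []
    if max_iter is None:
        max_iter = y.size
    for _ in range(max_iter):
        idx = np.flatnonzero(keep)
        vals = y[idx]
        n = vals.size
        if n < 3:
            break
        mean = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(vals - mean)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g <= grubbs_critical_value(n, alpha):
            break
        keep[idx[j]] = False
        removed_idx.append(idx[j])
    return y[keep], y[np.array(removed_idx, int)] if removed_idx else np.empty(0)


def estimate_height(cloud_or_y, percentile: float = 99.0) -> float:
    """Plot height = 99th percentile of point heights, with linear
    interpolation between order statistics."""
    y = cloud_or_y.y if isinstance(cloud_or_y, PointCloud) else np.asarray(cloud_or_y, float)
    if y.size == 0:
        raise EmptyPlotError("cannot estimate height of an empty cloud")
    return float(np.percentile(y, percentile, method="linear"))


# ---------------------------------------------------------------------------
# Gap fraction and LAI
# ---------------------------------------------------------------------------


def gap_fraction_profile(
    scans: LidarScanSet,
    ground_eps: float = 0.1,
    bin_edges_deg: np.ndarray = GAP_BIN_EDGES_DEG,
) -> GapFractionProfile:
    """Per-zenith-bin canopy gap fractions.

    A beam counts as a *gap* when the canopy did not intercept it: it either
    produced no return, or its return lies at ground level
    (y <= ``ground_eps``; set 0 to count only no-return beams).  Bins with a
    raw gap fraction of exactly 0 are replaced by 1/4 of the next more
    skyward (nearer-vertical) bin's gap fraction, resolved skyward-first so a
    chain of zeros propagates; a zero in the most skyward bin, which has no
    skyward neighbor, uses the floor 1/(4 * beams in that bin).
    """
    edges = np.asarray(bin_edges_deg, float)
    n_bins = edges.size - 1
    zen = zenith_from_beam_angle(scans.angles)
    bin_of = np.clip(np.digitize(zen, edges[1:-1], right=False), 0, n_bins - 1)

    beta = np.deg2rad(scans.angles)
    y = scans.mount_height - scans.ranges * np.cos(beta)[None, :]
    is_gap = ~np.isfinite(scans.ranges) | (y <= ground_eps)

    n_beams = np.zeros(n_bins, int)
    n_gaps = np.zeros(n_bins, int)
    for b in range(n_bins):
        mask = bin_of == b
        n_beams[b] = mask.sum() * scans.n_scans
        n_gaps[b] = int(is_gap[:, mask].sum())

    empty = n_beams == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(empty, np.nan, n_gaps / np.maximum(n_beams, 1))

    p = raw.copy()
    replaced = np.zeros(n_bins, bool)
    for b in range(n_bins):  # most skyward (bin 0) outward
        if empty[b] or p[b] != 0.0:
            continue
        skyward = b - 1
        while skyward >= 0 and empty[skyward]:
            skyward -= 1
        if skyward >= 0:
            p[b] = p[skyward] / 4.0
        else:
            p[b] = 1.0 / (4.0 * n_beams[b])
        replaced[b] = True
    return GapFractionProfile(
        bin_edges_deg=edges,
        gap_fraction=p,
        n_beams=n_beams,
        n_gaps=n_gaps,
        replaced=replaced,
        empty=empty,
    )


def lai_from_gap_fractions(profile: GapFractionProfile) -> float:
    """Discretized Miller inversion of the gap-fraction profile:

        LAI = 2 * sum_i (-ln P_i) * cos(theta_i) * sin(theta_i) * dtheta_i

    with theta_i the bin midpoint and dtheta_i the bin width (radians),
    summed over non-empty bins.  Zero for an all-open canopy (all P_i = 1).
    """
    edges = np.deg2rad(profile.bin_edges_deg)
    mid = 0.5 * (edges[:-1] + edges[1:])
    width = np.diff(edges)
    p = profile.gap_fraction
    use = ~profile.empty
    if np.any(p[use] <= 0.0):
        raise ValidationError("gap fraction of 0 reached the inversion; replacement missing")
    terms = -np.log(p[use]) * np.cos(mid[use]) * np.sin(mid[use]) * width[use]
    return float(2.0 * terms.sum())


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def _trim_scans(scans: LidarScanSet, trim_fraction: float) -> LidarScanSet:
    kept = trim_scan_indices(scans.n_scans, trim_fraction)
    return LidarScanSet(
        angles=scans.angles,
        ranges=scans.ranges[kept],
        mount_height=scans.mount_height,
        angular_resolution=scans.angular_resolution,
        max_range=scans.max_range,
    )


def process_plot(scans: LidarScanSet, config: PlotConfig | None = None) -> PlotPhenotypes:
    """Run the full pipeline on one plot's scans.

    Height branch: polar -> Cartesian, crop to |x| <= half_width, trim edge
    scans, Grubbs outlier removal on the height distribution, then the 99th
    percentile.  LAI branch: gap-fraction profile of the edge-trimmed scans,
    then the Miller inversion.  Deterministic: identical inputs give
    identical outputs.
    """
    config = config or PlotConfig()
    try:
        cloud = polar_to_cartesian(scans, below_ground_tol=config.below_ground_tol)
        n_raw = len(cloud)
        if n_raw == 0:
            raise EmptyPlotError("no returns in any scan")
        cropped = preprocess_plot(
            cloud, half_width=config.half_width, trim_fraction=config.trim_fraction
        )
        kept, removed = grubbs_filter(cropped.y, alpha=config.grubbs_alpha)
        if kept.size == 0:
            raise EmptyPlotError("Grubbs filtering removed every point")
        height = estimate_height(kept, percentile=config.height_percentile)
    except EmptyPlotError as err:
        if "no returns" not in str(err):
            raise
        # an empty field scene: no canopy returns at all
        n_raw = 0
        kept = np.empty(0)
        removed = np.empty(0)
        height = 0.0

    trimmed = _trim_scans(scans, config.trim_fraction)
    profile = gap_fraction_profile(trimmed, ground_eps=config.ground_eps)
    lai = lai_from_gap_fractions(profile)

    provenance = {
        "config": asdict(config),
        "n_returns_raw": int(n_raw),
        "n_points_after_crop_trim": int(kept.size + removed.size),
        "n_grubbs_removed": int(removed.size),
        "n_scans": int(scans.n_scans),
        "n_scans_after_trim": int(trimmed.n_scans),
    }
    return PlotPhenotypes(
        height=float(height),
        lai=float(lai),
        n_points_used=int(kept.size),
        gap_profile=profile,
        provenance=provenance,
    )
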