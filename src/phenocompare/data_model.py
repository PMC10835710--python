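"""Core domain types shared across the package.

The central container is :class:`RepeatedMeasuresTable`, a long-format table of
repeated measurements ``y_ijM`` of subject *j* (a field plot, plant, or
patient) by method *M*, replicate *i*.  Lidar data enter as
:class:`LidarScanSet` (polar beam returns) and become a :class:`PointCloud`
after the geometric transform in :mod:`phenocompare.lidar`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ("subject", "method", "replicate", "value")


class ValidationError(ValueError):
    """An input violates a structural invariant."""


class SchemaError(ValidationError):
    """A file is missing required columns or metadata."""


class InsufficientDataError(ValidationError):
    """Not enough observations for the requested computation."""


# ---------------------------------------------------------------------------
# Repeated-measures tables
# ---------------------------------------------------------------------------


@dataclass
class RepeatedMeasuresTable:
    """Long-format repeated measurements: one row per (subject, method, replicate).

    Parameters
    ----------
    data
        DataFrame with columns ``subject``, ``method``, ``replicate``,
        ``value``.  (subject, method, replicate) triples must be unique and
        values finite.
    units_label
        Unit of the ``value`` column, e.g. ``"l/min"`` or ``"m"``.
    """

    data: pd.DataFrame
    units_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        df = self.data.loc[:, list(CANONICAL_COLUMNS)].copy()
        df["value"] = pd.to_numeric(df["value"])
        if not np.isfinite(df["value"].to_numpy(float)).all():
            raise ValidationError("non-finite measurement values present")
        dup = df.duplicated(subset=["subject", "method", "replicate"])
        if dup.any():
            offenders = df.loc[dup, ["subject", "method", "replicate"]]
            raise ValidationError(
                "duplicate (subject, method, replicate) triples:\n"
                f"{offenders.to_string(index=False)}"
            )
        if (df["replicate"].to_numpy() < 1).any():
            raise ValidationError("replicate ids must be positive integers")
        self.data = df.reset_index(drop=True)

    # -- basic queries ------------------------------------------------------

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject"].unique().tolist())

    @property
    def methods(self) -> list:
        return sorted(self.data["method"].unique().tolist())

    @property
    def k(self) -> int:
        """Number of distinct subjects."""
        return self.data["subject"].nunique()

    def n_replicates(self, method) -> pd.Series:
        """Replicate count per subject for one method."""
        sub = self.data[self.data["method"] == method]
        return sub.groupby("subject")["value"].size()

    def values(self, subject, method) -> np.ndarray:
        """Replicate values for one (subject, method), ordered by replicate id."""
        sub = self.data[
            (self.data["subject"] == subject) & (self.data["method"] == method)
        ].sort_values("replicate")
        return sub["value"].to_numpy(float)

    def subject_means(self, method) -> pd.Series:
        sub = self.data[self.data["method"] == method]
        return sub.groupby("subject")["value"].mean()

    def replicate_wide(self, method) -> pd.DataFrame:
        """Subjects × replicates matrix for one method (NaN where absent)."""
        sub = self.data[self.data["method"] == method]
        return sub.pivot(index="subject", columns="replicate", values="value")

    # -- construction / I/O -------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Sequence[tuple], units_label: str = ""
    ) -> "RepeatedMeasuresTable":
        """Build from (subject, method, replicate, value) tuples."""
        df = pd.DataFrame(records, columns=list(CANONICAL_COLUMNS))
        return cls(df, units_label=units_label)

    @classmethod
    def from_arrays(
        cls,
        subject: Sequence,
        method: Sequence,
        replicate: Sequence,
        value: Sequence,
        units_label: str = "",
    ) -> "RepeatedMeasuresTable":
        df = pd.DataFrame(
            {
                "subject": subject,
                "method": method,
                "replicate": replicate,
                "value": value,
            }
        )
        return cls(df, units_label=units_label)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)


def read_repeated_measures_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    units_label: str = "",
) -> RepeatedMeasuresTable:
    """Read a long-format repeated-measures CSV.

    ``column_map`` maps canonical names (``subject``, ``method``,
    ``replicate``, ``value``) to the file's column names; identity is assumed
    for names not listed.  A missing replicate column is tolerated: replicate
    ids are then assigned 1..n in file order within each (subject, method).
    """
    df = pd.read_csv(path)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical != "replicate":
            raise SchemaError(
                f"column {source!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(df.columns)}"
            )
    df = df.rename(columns=rename)
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby(["subject", "method"]).cumcount() + 1
    return RepeatedMeasuresTable(df, units_label=units_label)


# ---------------------------------------------------------------------------
# Lidar scans and point clouds
# ---------------------------------------------------------------------------


@dataclass
class LidarScanSet:
    """A set of 2-D lidar scans on a common angular grid.

    Beam angles are degrees from straight down within the scan plane
    (0 = nadir, ±90 = horizontal, |angle| > 90 = above horizontal).  Ranges
    are meters from the scanner; NaN marks a beam with no return.
    """

    angles: np.ndarray  # (n_beams,) degrees from straight down
    ranges: np.ndarray  # (n_scans, n_beams) meters, NaN = no return
    mount_height: float  # meters above ground
    angular_resolution: float  # degrees
    max_range: float = 30.0  # meters

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        self.ranges = np.atleast_2d(np.asarray(self.ranges, float))
        if self.angular_resolution <= 0:
            raise ValidationError("angular_resolution must be > 0")
        if self.mount_height <= 0:
            raise ValidationError("mount_height must be > 0")
        if self.angles.ndim != 1 or self.ranges.shape[1] != self.angles.size:
            raise ValidationError("ranges must be (n_scans, n_beams)")
        span = self.angles.max() - self.angles.min() if self.angles.size else 0.0
        if span > 270.0 + 1e-9:
            raise ValidationError(f"beam angles span {span:.1f}° > 270° sector")
        finite = self.ranges[np.isfinite(self.ranges)]
        if finite.size and ((finite <= 0).any() or (finite > self.max_range + 1e-9).any()):
            raise ValidationError("ranges must lie in (0, max_range] or be no-return")

    @property
    def n_scans(self) -> int:
        return self.ranges.shape[0]

    @property
    def n_beams(self) -> int:
        return self.angles.size

    def write_csv(self, path) -> None:
        """Write as (scan_index, angle_deg, range_m) rows; blank range = no return."""
        n_scans, n_beams = self.ranges.shape
        scan_idx = np.repeat(np.arange(n_scans), n_beams)
        ang = np.tile(self.angles, n_scans)
        rng = self.ranges.ravel()
        df = pd.DataFrame({"scan_index": scan_idx, "angle_deg": ang, "range_m": rng})
        df.to_csv(path, index=False, na_rep="")


@dataclass
class PointCloud:
    """Cartesian returns: x horizontal from the lidar, y above ground (meters)."""

    x: np.ndarray
    y: np.ndarray
    scan_index: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.scan_index = np.asarray(self.scan_index, int)
        if not (self.x.shape == self.y.shape == self.scan_index.shape):
            raise ValidationError("x, y, scan_index must have identical shapes")

    def __len__(self) -> int:
        return self.x.size


def read_scan_config(path) -> dict:
    """Read a flat ``key = value`` sidecar config (mount_height, angular_resolution, max_range...)."""
    config: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, val = line.split("=", 1)
        elif ":" in line:
            key, val = line.split(":", 1)
        else:
            raise SchemaError(f"cannot parse config line: {raw!r}")
        key = key.strip()
        val = val.strip()
        try:
            config[key] = float(val)
        except ValueError:
            config[key] = val
    return config


def read_lidar_scan_csv(
    path,
    mount_height: float | None = None,
    angular_resolution: float | None = None,
    max_range: float = 30.0,
    config_path=None,
    no_return_sentinel: float | None = None,
) -> LidarScanSet:
    """Read lidar scans from (scan_index, angle_deg, range_m) rows.

    A blank range field (the default encoding) or an explicit
    ``no_return_sentinel`` value marks a beam without a return.  Scanner
    metadata comes from keyword arguments or a sidecar key-value config file.
    """
    if config_path is not None:
        cfg = read_scan_config(config_path)
        mount_height = mount_height if mount_height is not None else cfg.get("mount_height")
        angular_resolution = (
            angular_resolution
            if angular_resolution is not None
            else cfg.get("angular_resolution")
        )
        max_range = cfg.get("max_range", max_range)
        no_return_sentinel = (
            no_return_sentinel
            if no_return_sentinel is not None
            else cfg.get("no_return_sentinel")
        )
    if mount_height is None or angular_resolution is None:
        raise SchemaError("mount_height and angular_resolution are required (argument or sidecar config)")

    df = pd.read_csv(path)
    for col in ("scan_index", "angle_deg", "range_m"):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path}")
    idx = df["scan_index"].to_numpy()
    if (np.diff(idx) < 0).any():
        raise ValidationError("scan_index must be non-decreasing in file order")

    groups = df.groupby("scan_index", sort=True)
    angles_ref = None
    rows = []
    for _, grp in groups:
        ang = grp["angle_deg"].to_numpy(float)
        rng = grp["range_m"].to_numpy(float)
        if no_return_sentinel is not None:
            rng = np.where(rng == no_return_sentinel, np.nan, rng)
        if angles_ref is None:
            angles_ref = ang
        elif ang.shape != angles_ref.shape or not np.allclose(ang, angles_ref):
            raise ValidationError("all scans must share one angular grid")
        rows.append(rng)
    if angles_ref is None:
        raise ValidationError("no scans in file")
    return LidarScanSet(
        angles=angles_ref,
        ranges=np.vstack(rows),
        mount_height=float(mount_height),
        angular_resolution=float(angular_resolution),
        max_range=float(max_range),
    )


# ---------------------------------------------------------------------------
# Simulation config for repeated measures
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Configuration for the repeated-measures generator y = mu_j + b_M + e_ijM.

    ``sigma`` gives each method's residual scale: a nonnegative number
    (constant variance, LAI-like), an ``(a, c)`` pair for the mean-dependent
    scale ``sigma(mu) = a + c*mu`` (height-like), or a callable ``mu -> sigma``.
    """

    mu: Sequence[float]
    bias: Mapping[str, float]
    sigma: Mapping[str, float | tuple | Callable[[np.ndarray], np.ndarray]]
    replicates: int | Mapping[str, int] = 2
    seed: int = 0
    units_label: str = ""

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        if self.mu.size < 1:
            raise ValidationError("at least one subject required")
        if set(self.bias) != set(self.sigma):
            raise ValidationError("bias and sigma must cover the same methods")
        for m in self.bias:
            if self.n_for(m) < 2:
                raise ValidationError("replicates must be >= 2 for every method")
            sig = self.sigma_for(m)
            if (sig < 0).any():
                raise ValidationError(f"sigma for method {m!r} must be >= 0")

    def n_for(self, method) -> int:
        if isinstance(self.replicates, Mapping):
            return int(self.replicates[method])
        return int(self.replicates)

    def sigma_for(self, method) -> np.ndarray:
        """Per-subject residual scale for one method."""
        spec = self.sigma[method]
        if callable(spec):
            sig = np.asarray(spec(self.mu), float)
        elif isinstance(spec, tuple):
            a, c = spec
            sig = a + c * self.mu
        else:
            sig = np.full(self.mu.shape, float(spec))
        return np.broadcast_to(sig, self.mu.shape).astype(float)
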