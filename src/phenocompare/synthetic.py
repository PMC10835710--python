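"""Seeded generators with known ground truth.

Two simulators back the test surface of the package:

* :func:`simulate_repeated_measures` draws from the measurement model
  ``y_ijM = mu_j + b_M + e_ijM`` with constant or mean-dependent residual
  scale, so bias/variance estimators can be checked against planted truth.
* :func:`simulate_lidar_scene` ray-casts a horizontally uniform canopy slab
  under Beer-Lambert extinction, so the height estimator and the
  gap-fraction LAI inversion can be checked against a known canopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .comparison import _two_tailed_f_p
from .data_model import LidarScanSet, RepeatedMeasuresTable, SimConfig, ValidationError
from .lidar import GAP_BIN_EDGES_DEG, zenith_from_beam_angle

__all__ = [
    "CanopySimConfig",
    "simulate_repeated_measures",
    "simulate_lidar_scene",
    "estimate_test_error_rates",
]


def simulate_repeated_measures(config: SimConfig) -> RepeatedMeasuresTable:
    """Draw a repeated-measures table from y_ijM = mu_j + b_M + e_ijM.

    Residuals are Normal(0, sigma_M(mu_j)^2), independent across records.
    Reproducible: the same config (including seed) yields the same table.
    """
    rng = np.random.default_rng(config.seed)
    mu = np.asarray(config.mu, float)
    k = mu.size
    subjects = np.array([f"s{j+1}" for j in range(k)])
    frames = []
    for method in config.bias:
        n = config.n_for(method)
        sig = config.sigma_for(method)
        e = rng.standard_normal((k, n)) * sig[:, None]
        y = mu[:, None] + config.bias[method] + e
        frames.append(
            (
                np.repeat(subjects, n),
                np.full(k * n, method),
                np.tile(np.arange(1, n + 1), k),
                y.ravel(),
            )
        )
    subject = np.concatenate([f[0] for f in frames])
    method_col = np.concatenate([f[1] for f in frames])
    replicate = np.concatenate([f[2] for f in frames])
    value = np.concatenate([f[3] for f in frames])
    return RepeatedMeasuresTable.from_arrays(
        subject, method_col, replicate, value, units_label=config.units_label
    )


# ---------------------------------------------------------------------------
# Lidar scene
# ---------------------------------------------------------------------------


@dataclass
class CanopySimConfig:
    """A 2-D downward-scanning lidar over a horizontally uniform canopy slab.

    The canopy occupies heights [canopy_base, canopy_top] with leaf area
    index ``true_lai`` and extinction coefficient ``extinction`` (the G
    function of the gap-fraction model, default 0.5 for a spherical leaf
    angle distribution).  A beam whose line sits at zenith angle theta is
    intercepted with probability 1 - exp(-extinction * true_lai / cos(theta));
    intercepted beams return at an extinction-weighted (truncated
    exponential) depth inside the slab, non-intercepted beams return from the
    ground when it is within range, else not at all.  Gaussian range noise
    with sd ``range_noise_sd`` (default the scanner's +/- 40 mm precision)
    is added to every return.

    ``zenith_mode`` controls the zenith angle used for the interception draw:
    ``"bin-midpoint"`` (default) uses the midpoint of the gap-fraction zenith
    bin the beam falls in, so each bin's gap fraction follows Beer's law at
    the bin midpoint exactly (up to binomial noise) — the property the
    inversion is validated against; ``"exact"`` uses the beam's own zenith
    angle, which adds within-bin averaging effects the 5-bin inversion cannot
    resolve (see the methods note).
    """

    plot_length: float = 3.0  # meters of travel represented by the scans
    n_scans: int = 600
    mount_height: float = 4.0  # meters
    angular_resolution: float = 0.25  # degrees
    #: beam angles (deg from nadir).  Beams within ~8 deg of horizontal can
    #: reach neither the canopy slab nor the ground inside the 30 m range
    #: from a 4 m mount (cos z < mount_height / max_range), so they carry no
    #: canopy information; the default sector stops at +/-82 deg.
    sector: tuple[float, float] = (-82.0, 82.0)
    canopy_top: float = 2.0  # meters (true height H)
    canopy_base: float = 0.2  # meters
    true_lai: float = 2.0  # dimensionless L
    extinction: float = 0.5  # k_ext
    range_noise_sd: float = 0.04  # meters
    max_range: float = 30.0  # meters
    zenith_mode: str = "bin-midpoint"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.canopy_base < self.canopy_top < self.mount_height):
            raise ValidationError("need 0 <= canopy_base < canopy_top < mount_height")
        if self.true_lai < 0:
            raise ValidationError("true_lai must be >= 0")
        if self.range_noise_sd < 0:
            raise ValidationError("range_noise_sd must be >= 0")
        if self.angular_resolution <= 0:
            raise ValidationError("angular_resolution must be > 0")
        if self.sector[1] - self.sector[0] > 270.0:
            raise ValidationError("sector wider than the scanner's 270 degrees")
        if self.zenith_mode not in ("bin-midpoint", "exact"):
            raise ValidationError(f"unknown zenith_mode {self.zenith_mode!r}")

    @property
    def beam_spacing(self) -> float:
        """Spatial resolution scale at the mount height (m): res[rad] * mount_height."""
        return np.deg2rad(self.angular_resolution) * self.mount_height


def simulate_lidar_scene(config: CanopySimConfig) -> tuple[LidarScanSet, dict]:
    """Ray-cast one plot; returns (scans, truth) with truth = {height, lai}.

    Only beams below the horizontal can traverse the canopy slab (the
    scanner sits above the canopy); beams at or above the horizontal never
    return.  All randomness is drawn from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    angles = np.arange(
        config.sector[0], config.sector[1] + config.angular_resolution / 2.0,
        config.angular_resolution,
    )
    n_beams = angles.size
    n_scans = config.n_scans
    zen_exact = zenith_from_beam_angle(angles)
    downward = np.abs(angles) < 90.0 - 1e-12

    if config.zenith_mode == "bin-midpoint":
        edges = GAP_BIN_EDGES_DEG
        mids = 0.5 * (edges[:-1] + edges[1:])
        bin_of = np.clip(np.digitize(zen_exact, edges[1:-1]), 0, mids.size - 1)
        zen_draw = mids[bin_of]
    else:
        zen_draw = zen_exact

    cos_draw = np.cos(np.deg2rad(zen_draw))
    cos_exact = np.cos(np.deg2rad(zen_exact))
    L, kext = config.true_lai, config.extinction
    with np.errstate(divide="ignore", over="ignore"):
        tau = np.where(cos_draw > 1e-12, kext * L / np.maximum(cos_draw, 1e-12), np.inf)
    p_int = np.where(downward, 1.0 - np.exp(-tau), 0.0)
    if L == 0.0:
        p_int = np.zeros_like(p_int)

    intercepted = rng.random((n_scans, n_beams)) < p_int[None, :]

    ranges = np.full((n_scans, n_beams), np.nan)

    # ground returns for non-intercepted downward beams within range
    with np.errstate(divide="ignore"):
        r_ground = np.where(cos_exact > 1e-12, config.mount_height / np.maximum(cos_exact, 1e-12), np.inf)
    ground_ok = downward & (r_ground <= config.max_range)
    ground_mask = ~intercepted & ground_ok[None, :]
    ranges[ground_mask] = np.broadcast_to(r_ground[None, :], ranges.shape)[ground_mask]

    # intercepted beams: truncated-exponential depth inside the slab
    if intercepted.any():
        slab = config.canopy_top - config.canopy_base
        rho = kext * L / slab  # per along-path meter; survival over full path matches Beer
        with np.errstate(divide="ignore"):
            r_top = np.where(
                cos_exact > 1e-12,
                (config.mount_height - config.canopy_top) / np.maximum(cos_exact, 1e-12),
                np.inf,
            )
            s_max = np.where(cos_exact > 1e-12, slab / np.maximum(cos_exact, 1e-12), np.inf)
        idx_scan, idx_beam = np.nonzero(intercepted)
        u = rng.random(idx_beam.size)
        smax = s_max[idx_beam]
        with np.errstate(over="ignore"):
            trunc_mass = -np.expm1(-rho * smax)  # 1 - exp(-rho*smax)
        s = -np.log1p(-u * trunc_mass) / rho
        r = r_top[idx_beam] + s
        ranges[idx_scan, idx_beam] = r

    if config.range_noise_sd > 0:
        has_return = np.isfinite(ranges)
        ranges[has_return] += rng.normal(0.0, config.range_noise_sd, has_return.sum())
        np.clip(ranges, 1e-6, config.max_range, out=ranges)
    else:
        with np.errstate(invalid="ignore"):
            ranges = np.where(ranges > config.max_range, np.nan, ranges)

    scans = LidarScanSet(
        angles=angles,
        ranges=ranges,
        mount_height=config.mount_height,
        angular_resolution=config.angular_resolution,
        max_range=config.max_range,
    )
    truth = {
        "height": config.canopy_top if L > 0 else 0.0,
        "lai": L,
        "config": asdict(config),
    }
    return scans, truth


# ---------------------------------------------------------------------------
# Test calibration
# ---------------------------------------------------------------------------


def estimate_test_error_rates(
    scenario: dict, reps: int = 10_000, seed: int = 0
) -> dict:
    """Empirical rejection rate of the pooled two-tailed F-test.

    ``scenario`` keys: ``variance_ratio`` (sigma_B^2 / sigma_A^2, 1 under the
    null), ``n_per_subject``, ``k_subjects``, ``alpha``.  Each rep simulates
    normal repeated measures for two methods, pools the per-subject
    within-subject variances (df-weighted), and applies the same two-tailed
    F p-value the scalar API uses.  Returns the rejection rate with its
    Monte-Carlo standard error.
    """
    if reps < 100:
        raise ValidationError("reps must be >= 100")
    ratio = float(scenario.get("variance_ratio", 1.0))
    n = int(scenario.get("n_per_subject", 2))
    k = int(scenario.get("k_subjects", 10))
    alpha = float(scenario.get("alpha", 0.05))
    if ratio < 0 or n < 2 or k < 1:
        raise ValidationError("variance_ratio >= 0, n_per_subject >= 2, k_subjects >= 1 required")
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((reps, k, n))
    b = rng.standard_normal((reps, k, n)) * np.sqrt(ratio)
    s2_a = a.var(axis=2, ddof=1).mean(axis=1)  # equal df: pooled = plain mean
    s2_b = b.var(axis=2, ddof=1).mean(axis=1)
    df = k * (n - 1)
    p = _two_tailed_f_p(s2_b / s2_a, df, df)
    rate = float(np.mean(p < alpha))
    return {
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(max(rate * (1 - rate), 1e-12) / reps)),
        "df": df,
        "reps": reps,
    }


def f_test_power(variance_ratio: float, df_num: int, df_den: int, alpha: float = 0.05) -> float:
    """Closed-form power of the two-tailed F-test when the true ratio is
    ``variance_ratio``: P(F > f_u / R) + P(F < f_l / R) for F ~ F(df_num, df_den)."""
    f_lo = stats.f.ppf(alpha / 2.0, df_num, df_den)
    f_hi = stats.f.ppf(1.0 - alpha / 2.0, df_num, df_den)
    return float(
        stats.f.sf(f_hi / variance_ratio, df_num, df_den)
        + stats.f.cdf(f_lo / variance_ratio, df_num, df_den)
    )
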