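"""Bias and variance statistics for two-method comparison with repeated measures.

The model behind every routine here is

    y_ijM = mu_j + b_M + e_ijM

for subject j = 1..k, replicate i = 1..n, and method M, with residuals of
mean zero and either a constant variance sigma_M^2 or a per-subject variance
sigma_Mj^2.  Accuracy is assessed by a two-tailed t-test of the between-method
bias b_AB = b_B - b_A; precision by two-tailed F-tests of within-subject
variance ratios, pooled across subjects (df-weighted) when the variance does
not depend on the subject mean.  Bland-Altman limits of agreement and the
coefficient of repeatability are provided for comparison with that tradition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import InsufficientDataError, RepeatedMeasuresTable, ValidationError

__all__ = [
    "BiasResult",
    "VarianceEstimate",
    "VarianceComparison",
    "LOAResult",
    "Verdict",
    "MethodComparisonReport",
    "estimate_bias",
    "within_subject_variances",
    "compare_variances",
    "pool_variances",
    "limits_of_agreement",
    "coefficient_of_repeatability",
    "replicate_correlation",
    "homogeneity_check",
    "compare_methods",
]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass
class BiasResult:
    """Between-method bias estimate and two-tailed t-test of bias = 0."""

    b_hat: float
    se: float
    t_stat: float
    df: int
    p_value: float
    alpha: float
    significant: bool
    mode: str = "paired-subject-means"
    degenerate: bool = False  # zero variance of differences

    def ci(self, conf_level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for the bias."""
        tcrit = stats.t.ppf(0.5 + conf_level / 2.0, self.df)
        return (self.b_hat - tcrit * self.se, self.b_hat + tcrit * self.se)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VarianceEstimate:
    """Within-subject sample variance with chi-square confidence interval."""

    sigma2_hat: float
    df: int
    subject_id: object = "pooled"
    method_id: object = None
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    conf_level: float = 0.95

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VarianceComparison:
    """Two-tailed F-test of sigma_A^2 / sigma_B^2 = 1."""

    f_ratio: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    significant: bool
    larger_method: object = "none"
    subject_id: object = "pooled"
    infinite_ratio: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LOAResult:
    """Bland-Altman limits of agreement, mean(d) +/- k * sd(d)."""

    mean_diff: float
    sd_diff: float
    k_multiplier: float
    loa_lower: float
    loa_upper: float
    n_differences: int
    pairing: str
    threshold: float | None = None
    within_threshold: bool | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Verdict:
    """Deterministic interpretation of a method comparison.

    ``precision`` is one of ``"a_more_precise"``, ``"b_more_precise"``,
    ``"equally_precise"`` — derived from the pooled F-test when variances were
    pooled, otherwise from counts of subjects with a significantly larger
    variance for each method.
    """

    biased: bool
    precision: str
    n_subjects_a_larger: int
    n_subjects_b_larger: int
    loa_within_threshold: bool | None
    summary: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MethodComparisonReport:
    method_a: object
    method_b: object
    units_label: str
    bias: BiasResult
    per_subject_variances: Mapping[object, list]
    per_subject_comparisons: list
    pooled_variances: Mapping[object, VarianceEstimate] | None
    pooled_comparison: VarianceComparison | None
    pooling: str
    loa: LOAResult
    correlation: float
    correlation_seed: int
    verdict: Verdict
    alpha: float

    def to_dict(self) -> dict:
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "units_label": self.units_label,
            "alpha": self.alpha,
            "pooling": self.pooling,
            "bias": self.bias.to_dict(),
            "per_subject_variances": {
                str(m): [v.to_dict() for v in vs]
                for m, vs in self.per_subject_variances.items()
            },
            "per_subject_comparisons": [c.to_dict() for c in self.per_subject_comparisons],
            "pooled_variances": (
                {str(m): v.to_dict() for m, v in self.pooled_variances.items()}
                if self.pooled_variances
                else None
            ),
            "pooled_comparison": (
                self.pooled_comparison.to_dict() if self.pooled_comparison else None
            ),
            "loa": self.loa.to_dict(),
            "correlation": self.correlation,
            "correlation_seed": self.correlation_seed,
            "verdict": self.verdict.to_dict(),
        }


# ---------------------------------------------------------------------------
# Vectorized primitives (shared by the scalar API and the calibration code)
# ---------------------------------------------------------------------------


def _two_tailed_f_p(f_ratio, df_num, df_den):
    """p = 2 * min(P(F <= f), P(F >= f)), capped at 1.  Vectorized."""
    lower = stats.f.cdf(f_ratio, df_num, df_den)
    upper = stats.f.sf(f_ratio, df_num, df_den)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _loa_limits(d, k_multiplier, axis=-1):
    """(mean, sd, lower, upper) of mean(d) +/- k*sd(d) along ``axis``."""
    d = np.asarray(d, float)
    mean = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    return mean, sd, mean - k_multiplier * sd, mean + k_multiplier * sd


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _subject_mean_diffs(table: RepeatedMeasuresTable, method_a, method_b) -> pd.Series:
    means_a = table.subject_means(method_a)
    means_b = table.subject_means(method_b)
    shared = means_a.index.intersection(means_b.index)
    return (means_b[shared] - means_a[shared]).sort_index()


def estimate_bias(
    table: RepeatedMeasuresTable,
    method_a,
    method_b,
    alpha: float = 0.05,
    mode: str = "paired-subject-means",
) -> BiasResult:
    """Estimate the between-method bias b_B - b_A and test bias = 0.

    Default mode: per-subject mean differences (method_b minus method_a) with
    a one-sample two-tailed t-test of mean zero.  ``mode="two-sample"`` runs a
    two-sample equal-variance t-test on the two sets of subject means instead.
    """
    d = _subject_mean_diffs(table, method_a, method_b)
    if len(d) < 2:
        raise InsufficientDataError(
            f"need >= 2 shared subjects; got {len(d)} for ({method_a!r}, {method_b!r})"
        )
    if mode == "paired-subject-means":
        b_hat = float(d.mean())
        sd = float(d.std(ddof=1))
        df = len(d) - 1
        se = sd / np.sqrt(len(d))
        degenerate = sd == 0.0
        if degenerate:
            t_stat = 0.0 if b_hat == 0 else np.inf * np.sign(b_hat)
            p = 1.0 if b_hat == 0 else 0.0
            if b_hat != 0:
                warnings.warn("zero variance of differences with nonzero mean; p is a limiting value")
        else:
            t_stat = b_hat / se
            p = float(2.0 * stats.t.sf(abs(t_stat), df))
    elif mode == "two-sample":
        ma = table.subject_means(method_a).to_numpy(float)
        mb = table.subject_means(method_b).to_numpy(float)
        b_hat = float(mb.mean() - ma.mean())
        df = ma.size + mb.size - 2
        sp2 = ((ma.size - 1) * ma.var(ddof=1) + (mb.size - 1) * mb.var(ddof=1)) / df
        se = float(np.sqrt(sp2 * (1.0 / ma.size + 1.0 / mb.size)))
        degenerate = se == 0.0
        if degenerate:
            t_stat = 0.0 if b_hat == 0 else np.inf * np.sign(b_hat)
            p = 1.0 if b_hat == 0 else 0.0
        else:
            t_stat = b_hat / se
            p = float(2.0 * stats.t.sf(abs(t_stat), df))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BiasResult(
        b_hat=b_hat,
        se=float(se),
        t_stat=float(t_stat),
        df=int(df),
        p_value=float(p),
        alpha=alpha,
        significant=bool(p < alpha),
        mode=mode,
        degenerate=bool(degenerate),
    )


def variance_ci(s2: float, df: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Chi-square pivot CI for a normal variance: (df*s2/chi2_up, df*s2/chi2_lo)."""
    tail = (1.0 - conf_level) / 2.0
    upper_q = stats.chi2.ppf(1.0 - tail, df)
    lower_q = stats.chi2.ppf(tail, df)
    return (df * s2 / upper_q, df * s2 / lower_q)


def within_subject_variances(
    table: RepeatedMeasuresTable,
    method,
    conf_level: float = 0.95,
    strict: bool = False,
) -> list[VarianceEstimate]:
    """Per-subject sample variance about the subject-method mean, df = n_j - 1."""
    out: list[VarianceEstimate] = []
    grouped = table.data[table.data["method"] == method].groupby("subject")["value"]
    if grouped.ngroups == 0:
        raise InsufficientDataError(f"method {method!r} not present in table")
    for subject, vals in grouped:
        v = vals.to_numpy(float)
        if v.size < 2:
            if strict:
                raise InsufficientDataError(
                    f"subject {subject!r} has {v.size} replicate(s) for {method!r}"
                )
            warnings.warn(f"subject {subject!r} excluded: <2 replicates for {method!r}")
            continue
        s2 = float(v.var(ddof=1))
        df = v.size - 1
        lo, hi = variance_ci(s2, df, conf_level)
        out.append(
            VarianceEstimate(
                sigma2_hat=s2,
                df=df,
                subject_id=subject,
                method_id=method,
                ci_lower=float(lo),
                ci_upper=float(hi),
                conf_level=conf_level,
            )
        )
    if not out:
        raise InsufficientDataError(f"no subject has >= 2 replicates for {method!r}")
    return out


def compare_variances(
    a: VarianceEstimate, b: VarianceEstimate, alpha: float = 0.05
) -> VarianceComparison:
    """Two-tailed F-test of sigma_A^2 / sigma_B^2 = 1.

    ``larger_method`` is set only when the test is significant at ``alpha``.
    """
    if a.df < 1 or b.df < 1:
        raise InsufficientDataError("both variance estimates need df >= 1")
    if b.sigma2_hat == 0.0:
        if a.sigma2_hat == 0.0:
            raise ValidationError("both variances are zero; ratio indeterminate")
        f = np.inf
        p = 0.0
        infinite = True
    else:
        f = a.sigma2_hat / b.sigma2_hat
        p = float(_two_tailed_f_p(f, a.df, b.df))
        infinite = False
    significant = bool(p < alpha)
    larger = "none"
    if significant:
        larger = a.method_id if f > 1 else b.method_id
    subject = a.subject_id if a.subject_id == b.subject_id else (a.subject_id, b.subject_id)
    return VarianceComparison(
        f_ratio=float(f),
        df_num=int(a.df),
        df_den=int(b.df),
        p_value=float(p),
        alpha=alpha,
        significant=significant,
        larger_method=larger,
        subject_id=subject,
        infinite_ratio=infinite,
    )


def pool_variances(
    estimates: Sequence[VarianceEstimate], conf_level: float = 0.95
) -> VarianceEstimate:
    """df-weighted pooled variance: sum(df_j * s2_j) / sum(df_j), df = sum(df_j)."""
    if not estimates:
        raise InsufficientDataError("cannot pool an empty list of variance estimates")
    methods = {e.method_id for e in estimates}
    if len(methods) > 1:
        raise ValidationError(f"pooling across methods {methods} is not meaningful")
    dfs = np.array([e.df for e in estimates], float)
    s2s = np.array([e.sigma2_hat for e in estimates], float)
    if (dfs < 1).any():
        raise InsufficientDataError("every estimate must have df >= 1")
    df = int(dfs.sum())
    s2 = float((dfs * s2s).sum() / dfs.sum())
    lo, hi = variance_ci(s2, df, conf_level)
    return VarianceEstimate(
        sigma2_hat=s2,
        df=df,
        subject_id="pooled",
        method_id=estimates[0].method_id,
        ci_lower=float(lo),
        ci_upper=float(hi),
        conf_level=conf_level,
    )


def _paired_differences(
    table: RepeatedMeasuresTable, method_a, method_b, pairing: str
) -> np.ndarray:
    """Differences method_b - method_a under the requested pairing."""
    if pairing == "subject-means":
        return _subject_mean_diffs(table, method_a, method_b).to_numpy(float)
    if pairing != "replicate-index":
        raise ValueError(f"unknown pairing {pairing!r}")
    diffs = []
    wide_a = table.replicate_wide(method_a)
    wide_b = table.replicate_wide(method_b)
    shared = wide_a.index.intersection(wide_b.index)
    for subject in shared:
        va = wide_a.loc[subject].dropna()
        vb = wide_b.loc[subject].dropna()
        if len(va) != len(vb):
            raise ValidationError(
                f"subject {subject!r} has {len(va)} vs {len(vb)} replicates; "
                "replicate-index pairing needs equal counts — use pairing='subject-means'"
            )
        diffs.append(vb.to_numpy(float) - va.to_numpy(float))
    return np.concatenate(diffs)


def limits_of_agreement(
    table: RepeatedMeasuresTable,
    method_a,
    method_b,
    k_multiplier: float = 1.96,
    pairing: str = "replicate-index",
    threshold: float | None = None,
) -> LOAResult:
    """Bland-Altman limits of agreement for differences method_b - method_a.

    ``pairing="replicate-index"`` pairs i-th replicate with i-th replicate
    within each subject (all replicate pairs contribute); ``"subject-means"``
    uses one difference of subject means per subject.  The sign convention is
    "new method minus old method" when method_b is the new one.
    """
    d = _paired_differences(table, method_a, method_b, pairing)
    if d.size < 2:
        raise InsufficientDataError("need >= 2 paired differences")
    mean, sd, lo, hi = _loa_limits(d, k_multiplier)
    within = None
    if threshold is not None:
        within = bool(-threshold <= lo and hi <= threshold)
    return LOAResult(
        mean_diff=float(mean),
        sd_diff=float(sd),
        k_multiplier=k_multiplier,
        loa_lower=float(lo),
        loa_upper=float(hi),
        n_differences=int(d.size),
        pairing=pairing,
        threshold=threshold,
        within_threshold=within,
    )


def coefficient_of_repeatability(
    table: RepeatedMeasuresTable, method, convention: str = "zero-mean-sd"
) -> float:
    """CR = 2 x sd of within-subject differences (replicate 1 - replicate 2).

    ``"zero-mean-sd"`` takes the sd about zero, 2*sqrt(mean(d^2)) — the
    classical repeatability definition under the no-bias-between-replicates
    assumption; ``"sample-sd"`` uses the ordinary sample sd of the differences.
    Subjects with more than two replicates contribute their first two only.
    """
    wide = table.replicate_wide(method)
    if wide.shape[1] > 2:
        warnings.warn(f"method {method!r} has >2 replicates; using the first two")
    if wide.shape[1] < 2:
        raise InsufficientDataError(f"no subject has >= 2 replicates for {method!r}")
    first_two = wide.iloc[:, :2].dropna()
    if first_two.empty:
        raise InsufficientDataError(f"no subject has >= 2 replicates for {method!r}")
    d = first_two.iloc[:, 0].to_numpy(float) - first_two.iloc[:, 1].to_numpy(float)
    if convention == "zero-mean-sd":
        return float(2.0 * np.sqrt(np.mean(d**2)))
    if convention == "sample-sd":
        return float(2.0 * d.std(ddof=1))
    raise ValueError(f"unknown convention {convention!r}")


def replicate_correlation(
    table: RepeatedMeasuresTable, method_a, method_b, seed: int = 0
) -> float:
    """Pearson r after randomly pairing replicates of the two methods per subject.

    Within each shared subject the replicates of method_a are permuted with a
    seeded RNG and paired, in order, against the replicates of method_b (the
    shorter list truncates the pairing).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    wide_a = table.replicate_wide(method_a)
    wide_b = table.replicate_wide(method_b)
    shared = wide_a.index.intersection(wide_b.index)
    if len(shared) == 0:
        raise InsufficientDataError("no shared subjects")
    xs, ys = [], []
    for subject in shared:
        va = wide_a.loc[subject].dropna().to_numpy(float)
        vb = wide_b.loc[subject].dropna().to_numpy(float)
        va = rng.permutation(va)
        m = min(va.size, vb.size)
        xs.append(va[:m])
        ys.append(vb[:m])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValidationError("zero variance in one method's values; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def homogeneity_check(
    variances: Sequence[VarianceEstimate] | Sequence[float],
    subject_means: Sequence[float],
    level: float = 0.05,
) -> tuple[str, dict]:
    """OLS of variance on subject mean; recommend pooling unless the slope is
    significantly positive (one-sided test at ``level``).

    Returns ``(recommendation, diagnostics)`` with recommendation ``"pool"``
    or ``"per-subject"``.  Always overridable by the caller.
    """
    s2 = np.array(
        [v.sigma2_hat if isinstance(v, VarianceEstimate) else float(v) for v in variances],
        float,
    )
    mu = np.asarray(subject_means, float)
    if s2.size != mu.size:
        raise ValidationError("variances and subject_means must have equal length")
    if s2.size < 3:
        raise InsufficientDataError("need >= 3 subjects to assess a variance-mean trend")
    fit = stats.linregress(mu, s2)
    one_sided_p = fit.pvalue / 2.0 if fit.slope > 0 else 1.0 - fit.pvalue / 2.0
    recommendation = "per-subject" if (fit.slope > 0 and one_sided_p < level) else "pool"
    diagnostics = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "one_sided_p": float(one_sided_p),
        "r_value": float(fit.rvalue),
    }
    return recommendation, diagnostics


def _precision_verdict(
    method_a,
    method_b,
    pooled_comparison: VarianceComparison | None,
    per_subject_comparisons: Sequence[VarianceComparison],
) -> tuple[str, int, int]:
    n_a = sum(1 for c in per_subject_comparisons if c.significant and c.larger_method == method_a)
    n_b = sum(1 for c in per_subject_comparisons if c.significant and c.larger_method == method_b)
    if pooled_comparison is not None:
        if not pooled_comparison.significant:
            return "equally_precise", n_a, n_b
        if pooled_comparison.larger_method == method_a:
            return "b_more_precise", n_a, n_b
        return "a_more_precise", n_a, n_b
    # per-subject regime: the method with fewer significantly-larger variances wins
    if n_a > n_b:
        return "b_more_precise", n_a, n_b
    if n_b > n_a:
        return "a_more_precise", n_a, n_b
    return "equally_precise", n_a, n_b


def compare_methods(
    table: RepeatedMeasuresTable,
    method_a,
    method_b,
    alpha: float = 0.05,
    k_multiplier: float = 1.96,
    threshold: float | None = None,
    pooling: str = "auto",
    seed: int = 0,
    bias_mode: str = "paired-subject-means",
    conf_level: float = 0.95,
) -> MethodComparisonReport:
    """Full two-method comparison: bias, per-subject and pooled variance
    F-tests, limits of agreement, randomized-pairing correlation, and a
    deterministic verdict.

    ``pooling="auto"`` pools the per-subject variances unless either method
    shows a significantly positive variance-vs-mean trend.
    """
    if pooling not in ("auto", "pool", "per-subject"):
        raise ValueError(f"unknown pooling {pooling!r}")
    bias = estimate_bias(table, method_a, method_b, alpha=alpha, mode=bias_mode)

    per_subject = {
        m: within_subject_variances(table, m, conf_level=conf_level)
        for m in (method_a, method_b)
    }
    # per-subject F-tests on subjects present for both methods
    by_subject_a = {v.subject_id: v for v in per_subject[method_a]}
    by_subject_b = {v.subject_id: v for v in per_subject[method_b]}
    shared_subjects = sorted(set(by_subject_a) & set(by_subject_b), key=str)
    per_subject_comparisons = []
    for s in shared_subjects:
        va, vb = by_subject_a[s], by_subject_b[s]
        if va.sigma2_hat == 0.0 and vb.sigma2_hat == 0.0:
            continue  # tie: no information
        per_subject_comparisons.append(compare_variances(va, vb, alpha=alpha))

    if pooling == "auto":
        decided = "pool"
        for m in (method_a, method_b):
            means = table.subject_means(m)
            ests = [v for v in per_subject[m] if v.subject_id in means.index]
            if len(ests) >= 3:
                rec, _ = homogeneity_check(
                    ests, [means[v.subject_id] for v in ests], level=alpha
                )
                if rec == "per-subject":
                    decided = "per-subject"
    else:
        decided = pooling

    pooled_variances = None
    pooled_comparison = None
    if decided == "pool":
        pooled_variances = {
            m: pool_variances(per_subject[m], conf_level=conf_level)
            for m in (method_a, method_b)
        }
        pooled_comparison = compare_variances(
            pooled_variances[method_a], pooled_variances[method_b], alpha=alpha
        )

    # LOA: replicate-index pairing when counts allow, else subject means
    try:
        loa = limits_of_agreement(
            table, method_a, method_b, k_multiplier=k_multiplier,
            pairing="replicate-index", threshold=threshold,
        )
    except ValidationError:
        loa = limits_of_agreement(
            table, method_a, method_b, k_multiplier=k_multiplier,
            pairing="subject-means", threshold=threshold,
        )

    correlation = replicate_correlation(table, method_a, method_b, seed=seed)

    precision, n_a, n_b = _precision_verdict(
        method_a, method_b, pooled_comparison, per_subject_comparisons
    )
    bias_word = "biased" if bias.significant else "unbiased"
    precision_word = {
        "equally_precise": f"equally as precise as {method_a}",
        "a_more_precise": f"less precise than {method_a}",
        "b_more_precise": f"more precise than {method_a}",
    }[precision]
    summary = f"{method_b} is {bias_word} and {precision_word}"
    verdict = Verdict(
        biased=bias.significant,
        precision=precision,
        n_subjects_a_larger=n_a,
        n_subjects_b_larger=n_b,
        loa_within_threshold=loa.within_threshold,
        summary=summary,
    )
    return MethodComparisonReport(
        method_a=method_a,
        method_b=method_b,
        units_label=table.units_label,
        bias=bias,
        per_subject_variances=per_subject,
        per_subject_comparisons=per_subject_comparisons,
        pooled_variances=pooled_variances,
        pooled_comparison=pooled_comparison,
        pooling=decided,
        loa=loa,
        correlation=correlation,
        correlation_seed=seed,
        verdict=verdict,
        alpha=alpha,
    )
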