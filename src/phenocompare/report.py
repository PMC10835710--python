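"""Figure panels and verdict tables for a two-method comparison.

Renders the standard three-panel layout: (A) a correlation plot of the two
methods against the 1-to-1 line, (B) a Bland-Altman bias plot (differences
vs pair means, with mean-bias, standard-error and limits-of-agreement
lines), and (C) per-subject within-subject variances against subject means,
with filled symbols marking subjects where a method's variance is
significantly larger (two-tailed F-test) and an OLS trend line that is
visualization-only (the chi-square sampling distribution of a variance
violates regression assumptions).  When variances were pooled, panel C
carries an inset of the two pooled variances with their 95% chi-square
confidence limits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .comparison import MethodComparisonReport

PANEL_COLORS = {"a": "tab:blue", "b": "tab:orange"}


@dataclass
class ReportBundle:
    figure_paths: list
    table_paths: list
    manifest_path: Path


def _verdict_table(report: MethodComparisonReport) -> pd.DataFrame:
    v = report.verdict
    return pd.DataFrame(
        [
            {
                "method_a": report.method_a,
                "method_b": report.method_b,
                "units": report.units_label,
                "bias": f"{report.bias.b_hat:.6g}",
                "bias_p": f"{report.bias.p_value:.4g}",
                "biased": v.biased,
                "precision": v.precision,
                "n_subjects_a_larger": v.n_subjects_a_larger,
                "n_subjects_b_larger": v.n_subjects_b_larger,
                "pooling": report.pooling,
                "pooled_f_p": (
                    f"{report.pooled_comparison.p_value:.4g}"
                    if report.pooled_comparison
                    else ""
                ),
                "loa_lower": f"{report.loa.loa_lower:.6g}",
                "loa_upper": f"{report.loa.loa_upper:.6g}",
                "loa_within_threshold": v.loa_within_threshold,
                "correlation": f"{report.correlation:.4f}",
                "summary": v.summary,
            }
        ]
    )


def _per_subject_table(report: MethodComparisonReport) -> pd.DataFrame:
    rows = []
    for c in report.per_subject_comparisons:
        rows.append(
            {
                "subject": c.subject_id,
                "f_ratio": c.f_ratio,
                "df_num": c.df_num,
                "df_den": c.df_den,
                "p_value": c.p_value,
                "significant": c.significant,
                "larger_method": c.larger_method,
            }
        )
    return pd.DataFrame(rows)


def _paired_values(report, table):
    a = table.subject_means(report.method_a)
    b = table.subject_means(report.method_b)
    shared = a.index.intersection(b.index)
    return a[shared].to_numpy(float), b[shared].to_numpy(float)


def render_comparison_report(
    report: MethodComparisonReport,
    table,
    out_dir,
    formats=("png",),
    name: str = "comparison",
) -> ReportBundle:
    """Write figure panels, verdict/per-subject tables, and a manifest.

    ``table`` is the RepeatedMeasuresTable the report was computed from (the
    figures need the underlying observations, not just the summaries).
    Re-rendering the same report yields byte-identical table files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unit = f" ({report.units_label})" if report.units_label else ""

    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))

    # Panel A: correlation plot of subject means with 1-to-1 line
    ax = axes[0]
    ma, mb = _paired_values(report, table)
    ax.scatter(ma, mb, s=25, color="0.2")
    lims = [min(ma.min(), mb.min()), max(ma.max(), mb.max())]
    ax.plot(lims, lims, "k--", lw=1, label="1:1")
    ax.set_xlabel(f"{report.method_a}{unit}")
    ax.set_ylabel(f"{report.method_b}{unit}")
    ax.set_title(f"A  r = {report.correlation:.2f}")
    ax.legend(frameon=False)

    # Panel B: Bland-Altman bias plot
    ax = axes[1]
    diffs = mb - ma
    means = (ma + mb) / 2.0
    ax.scatter(means, diffs, s=25, color="0.2")
    b = report.bias
    ax.axhline(b.b_hat, ls="--", color="k", label=f"bias = {b.b_hat:.3g}")
    for sign in (-1, 1):
        ax.axhline(b.b_hat + sign * b.se, ls="-.", color="0.4", lw=0.9)
    for y in (report.loa.loa_lower, report.loa.loa_upper):
        ax.axhline(y, ls=":", color="0.4")
    if report.loa.threshold is not None:
        for sign in (-1, 1):
            ax.axhline(sign * report.loa.threshold, color="tab:red", lw=0.8, alpha=0.6)
    ax.set_xlabel(f"pair mean{unit}")
    ax.set_ylabel(f"{report.method_b} - {report.method_a}{unit}")
    ax.set_title(f"B  bias p = {b.p_value:.2g}, LOA [{report.loa.loa_lower:.3g}, {report.loa.loa_upper:.3g}]")
    ax.legend(frameon=False)

    # Panel C: per-subject variances vs subject means
    ax = axes[2]
    larger = {
        c.subject_id: c.larger_method
        for c in report.per_subject_comparisons
        if c.significant
    }
    for key, method in (("a", report.method_a), ("b", report.method_b)):
        means_m = table.subject_means(method)
        ests = report.per_subject_variances[method]
        x = np.array([means_m[v.subject_id] for v in ests])
        y = np.array([v.sigma2_hat for v in ests])
        filled = np.array([larger.get(v.subject_id) == method for v in ests])
        color = PANEL_COLORS[key]
        ax.scatter(x[~filled], y[~filled], facecolors="none", edgecolors=color, label=str(method))
        if filled.any():
            ax.scatter(x[filled], y[filled], color=color)
        if x.size >= 3 and np.ptp(x) > 0:
            fit = stats.linregress(x, y)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, fit.intercept + fit.slope * xs, ls="--", color=color, lw=1, alpha=0.7)
    ax.set_xlabel(f"subject mean{unit}")
    ax.set_ylabel(f"within-subject variance{unit and unit[:-1] + '²)'}")
    ax.set_title("C  per-subject variances (OLS lines: visualization only)")
    ax.legend(frameon=False)

    if report.pooled_variances is not None:
        inset = ax.inset_axes([0.55, 0.55, 0.4, 0.4])
        labels, vals, los, his, colors = [], [], [], [], []
        for key, method in (("a", report.method_a), ("b", report.method_b)):
            pv = report.pooled_variances[method]
            labels.append(str(method))
            vals.append(pv.sigma2_hat)
            los.append(pv.sigma2_hat - pv.ci_lower)
            his.append(pv.ci_upper - pv.sigma2_hat)
            colors.append(PANEL_COLORS[key])
        inset.bar(np.arange(len(labels)), vals, yerr=[los, his], color=colors, capsize=3)
        inset.set_xticks(np.arange(len(labels)), labels)
        p = report.pooled_comparison.p_value if report.pooled_comparison else float("nan")
        inset.set_title(f"pooled (p = {p:.2g})", fontsize=8)
        inset.tick_params(labelsize=7)

    fig.tight_layout()
    figure_paths = []
    for fmt in formats:
        path = out_dir / f"{name}.{fmt}"
        fig.savefig(path, dpi=150)
        figure_paths.append(path)
    plt.close(fig)

    verdict_path = out_dir / f"{name}_verdict.csv"
    _verdict_table(report).to_csv(verdict_path, index=False)
    per_subject_path = out_dir / f"{name}_per_subject_f.csv"
    _per_subject_table(report).to_csv(per_subject_path, index=False)

    manifest_path = out_dir / f"{name}_manifest.json"
    manifest = {
        "report": report.to_dict(),
        "seed": report.correlation_seed,
        "phenocompare_version": _version(),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return ReportBundle(
        figure_paths=figure_paths,
        table_paths=[verdict_path, per_subject_path],
        manifest_path=manifest_path,
    )


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("phenocompare")
    except PackageNotFoundError:
        return "unknown"
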