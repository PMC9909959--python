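"""Normality-gated two-group comparison of %BTV profiles.

The comparison protocol: each sample is first screened with a one-sample
Kolmogorov-Smirnov test against a normal law with the sample's own mean and
SD (no Lilliefors correction — with estimated parameters the test is known
to be conservative, which is documented rather than corrected, to keep the
gate as literally specified).  If both samples pass at alpha = 0.05 the
groups are compared with a pooled-variance Student t-test, otherwise with a
two-sided Mann-Whitney U.  Results are reported as mean +/- SD with the
per-bin P value; significance is P < alpha.  No multiple-testing correction
is applied by default (per-bin P values are reported as-is); Holm or
Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .densitometry import BTVProfile, DensityScheme

ALPHA = 0.05


@dataclass
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool


@dataclass
class GroupComparison:
    """One density bin's two-group comparison."""

    bin_label: str
    group_means_sd: tuple[tuple[float, float], tuple[float, float]]
    test_used: str  # "student_t" | "mann_whitney" | "degenerate"
    p_value: float
    significant: bool
    degenerate: bool = False


def ks_normal(sample, alpha: float = ALPHA) -> NormalityResult:
    """One-sample KS test against N(sample mean, sample SD)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"need n >= 3 for the normality screen, got {x.size}")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = sps.kstest(x, "norm", args=(float(x.mean()), sd))
    return NormalityResult(statistic=float(stat), p_value=float(p), is_normal=p > alpha)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if float(np.std(x, ddof=1)) == 0:
        return False
    return ks_normal(x, alpha=alpha).is_normal


def compare_groups(
    a,
    b,
    alpha: float = ALPHA,
    bin_label: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison with the KS normality gate.

    Degenerate input (both samples constant and equal) cannot be tested;
    P = 1 is reported with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    means_sd = (
        (float(a.mean()), float(a.std(ddof=1))),
        (float(b.mean()), float(b.std(ddof=1))),
    )
    if means_sd[0][1] == 0 and means_sd[1][1] == 0 and a[0] == b[0]:
        return GroupComparison(bin_label, means_sd, "degenerate", 1.0, False, degenerate=True)
    if _is_normal(a, alpha) and _is_normal(b, alpha):
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        test = "student_t" if not welch else "welch_t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney"
    p = float(p)
    return GroupComparison(bin_label, means_sd, test, p, p < alpha)


def _adjust(pvals: list[float], method: str | None) -> list[float]:
    if method is None:
        return pvals
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(pvals, method=method)[1])


@dataclass
class BTVReport:
    """Table-shaped comparison output.

    ``between`` maps side -> 12-row DataFrame of group A vs group B;
    ``within`` maps group name -> 12-row DataFrame of left vs right.
    """

    bone: str
    between: dict[str, pd.DataFrame] = field(default_factory=dict)
    within: dict[str, pd.DataFrame] = field(default_factory=dict)


def _rows_for(
    profiles_a: list[BTVProfile],
    profiles_b: list[BTVProfile],
    names: tuple[str, str],
    alpha: float,
    welch: bool,
    correction: str | None,
) -> pd.DataFrame:
    scheme = DensityScheme.default()
    pa = np.stack([p.pct for p in profiles_a])
    pb = np.stack([p.pct for p in profiles_b])
    comps = [
        compare_groups(pa[:, i], pb[:, i], alpha=alpha, bin_label=scheme.labels[i], welch=welch)
        for i in range(12)
    ]
    adj = _adjust([c.p_value for c in comps], correction)
    rows = []
    for i, c in enumerate(comps):
        (ma, sa), (mb, sb) = c.group_means_sd
        rows.append(
            {
                "density_class": scheme.class_of_bin[i],
                "hu_range": scheme.labels[i],
                f"{names[0]}_mean": ma,
                f"{names[0]}_sd": sa,
                f"{names[1]}_mean": mb,
                f"{names[1]}_sd": sb,
                "test": c.test_used,
                "p_value": adj[i],
                "significant": bool(adj[i] < alpha) and not c.degenerate,
            }
        )
    return pd.DataFrame(rows)


def btv_report(
    cohort_a: list[BTVProfile],
    cohort_b: list[BTVProfile],
    group_names: tuple[str, str] = ("judo", "control"),
    alpha: float = ALPHA,
    welch: bool = False,
    paired: bool = False,
    correction: str | None = None,
) -> BTVReport:
    """Per-bin group comparison of %BTV, per side, plus left-right contrasts.

    All profiles must come from the same bone.  The left-vs-right contrast
    within each group is two-sample by default; ``paired=True`` switches to
    a paired test (paired t when both difference screens pass, otherwise
    Wilcoxon signed-rank).
    """
    bones = {p.bone for p in cohort_a + cohort_b}
    if len(bones) != 1:
        raise ValueError(f"profiles mix bones: {sorted(bones)}")
    bone = bones.pop()
    report = BTVReport(bone=bone)
    by_side = {
        side: (
            [p for p in cohort_a if p.side == side],
            [p for p in cohort_b if p.side == side],
        )
        for side in ("right", "left")
    }
    for side, (a, b) in by_side.items():
        if len(a) >= 3 and len(b) >= 3:
            report.between[side] = _rows_for(a, b, group_names, alpha, welch, correction)
    for name, cohort in zip(group_names, (cohort_a, cohort_b)):
        left = [p for p in cohort if p.side == "left"]
        right = [p for p in cohort if p.side == "right"]
        if len(left) >= 3 and len(right) >= 3:
            if paired and len(left) == len(right):
                report.within[name] = _paired_rows(left, right, alpha)
            else:
                report.within[name] = _rows_for(left, right, ("left", "right"), alpha, welch, correction)
    return report


def _paired_rows(left: list[BTVProfile], right: list[BTVProfile], alpha: float) -> pd.DataFrame:
    scheme = DensityScheme.default()
    pl = np.stack([p.pct for p in left])
    pr = np.stack([p.pct for p in right])
    rows = []
    for i in range(12):
        d = pl[:, i] - pr[:, i]
        if np.std(d, ddof=1) == 0:
            test, p = "degenerate", 1.0
        elif _is_normal(d, alpha):
            test, p = "paired_t", float(sps.ttest_rel(pl[:, i], pr[:, i]).pvalue)
        else:
            test, p = "wilcoxon", float(sps.wilcoxon(pl[:, i], pr[:, i]).pvalue)
        rows.append(
            {
                "density_class": scheme.class_of_bin[i],
                "hu_range": scheme.labels[i],
                "left_mean": float(pl[:, i].mean()),
                "left_sd": float(pl[:, i].std(ddof=1)),
                "right_mean": float(pr[:, i].mean()),
                "right_sd": float(pr[:, i].std(ddof=1)),
                "test": test,
                "p_value": p,
                "significant": bool(p < alpha) and test != "degenerate",
            }
        )
    return pd.DataFrame(rows)
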