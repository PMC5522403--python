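"""Seven-group nonparametric comparison of memory-guided-saccade errors.

Trials are grouped by stimulation condition and by the target's visual
hemifield relative to the stimulated hemisphere: a no-TMS baseline
(collapsed across hemifields) plus contralateral and ipsilateral groups
for each of the three stimulation sites (PFC, sPCS, IPS2) — seven groups.

Before pooling, two collapsing checks are run with Wilcoxon rank-sum
tests: left-vs-right visual field in the baseline condition, and pairwise
comparisons across the five memory delays.  Pooling is licensed only when
these are non-significant.

Per error metric (MGS, FEP) a Kruskal–Wallis omnibus test gates six
Wilcoxon rank-sum post-hoc comparisons of each TMS group against baseline;
no multiple-comparison correction is applied by default.  Tests are
two-sided, exact for small samples (n <= 20 per group, no ties) and
normal-approximation with tie correction otherwise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_LABELS",
    "SITE_HEMISPHERES",
    "TestReport",
    "CollapseReport",
    "rank_sum_test",
    "assign_laterality",
    "collapse_checks",
    "run_group_tests",
    "per_subject_delta",
    "report_text",
]

GROUP_LABELS = ("noTMS", "PFC-contra", "PFC-ipsi", "sPCS-contra",
                "sPCS-ipsi", "IPS2-contra", "IPS2-ipsi")

#: stimulated hemisphere per site: left sPCS, left IPS2, right dlPFC
SITE_HEMISPHERES = {"sPCS": "L", "IPS2": "L", "PFC": "R"}

METRICS = ("mgs_error", "fep_error")


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when both samples have n <= 20 and the pooled
    data are tie-free; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("rank-sum test needs at least 2 observations per sample")
    pooled = np.concatenate([a, b])
    exact = len(a) <= 20 and len(b) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def assign_laterality(scores: pd.DataFrame,
                      site_hemispheres: dict[str, str] | None = None) -> pd.DataFrame:
    """Label each trial with its performance group.

    Requires columns ``condition`` (site name or ``noTMS``) and ``target_x``
    (degrees; positive = right visual field).  Targets are never on the
    vertical meridian, so the hemifield is unambiguous.
    """
    site_hemispheres = site_hemispheres or SITE_HEMISPHERES
    out = scores.copy()
    if (out["target_x"] == 0).any():
        raise ValueError("target on the vertical meridian: hemifield undefined")
    hemifield = np.where(out["target_x"] > 0, "R", "L")
    out["hemifield"] = hemifield

    def label(row) -> str:
        if row["condition"] == "noTMS":
            return "noTMS"
        site = row["condition"]
        if site not in site_hemispheres:
            raise ValueError(f"unknown stimulation site {site!r}")
        lat = "ipsi" if row["hemifield"] == site_hemispheres[site] else "contra"
        return f"{site}-{lat}"

    out["group"] = out.apply(label, axis=1)
    return out


@dataclass
class CollapseReport:
    """Outcome of the pooling checks."""

    lr_stat: float
    lr_p: float
    collapse_lr: bool
    delay_pvalues: dict[tuple[float, float], float]
    collapse_delays: bool
    alpha: float


def collapse_checks(scores: pd.DataFrame, alpha: float = 0.05,
                    metric: str = "mgs_error") -> CollapseReport:
    """Check whether hemifield and delay strata may be pooled.

    Left-vs-right visual field is compared within the no-TMS condition; the
    delay check runs all pairwise rank-sum tests across delay bins (over
    included trials of all conditions) and takes the most significant one.
    """
    df = scores[~scores["excluded"]] if "excluded" in scores else scores
    base = df[df["condition"] == "noTMS"]
    left = base.loc[base["target_x"] < 0, metric].dropna()
    right = base.loc[base["target_x"] > 0, metric].dropna()
    for name, s in (("noTMS/left", left), ("noTMS/right", right)):
        if len(s) < 2:
            raise ValueError(f"stratum {name} has fewer than 2 trials")
    lr_stat, lr_p = rank_sum_test(left, right)

    delay_ps: dict[tuple[float, float], float] = {}
    delays = sorted(df["delay_s"].dropna().unique())
    for d1, d2 in itertools.combinations(delays, 2):
        a = df.loc[df["delay_s"] == d1, metric].dropna()
        b = df.loc[df["delay_s"] == d2, metric].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"delay stratum {d1} or {d2} has fewer than 2 trials")
        delay_ps[(d1, d2)] = rank_sum_test(a, b)[1]
    collapse_delays = all(p > alpha for p in delay_ps.values()) if delay_ps else True
    return CollapseReport(lr_stat=lr_stat, lr_p=lr_p, collapse_lr=lr_p > alpha,
                          delay_pvalues=delay_ps, collapse_delays=collapse_delays,
                          alpha=alpha)


@dataclass
class TestReport:
    """Omnibus and post-hoc results for one error metric."""

    metric: str
    h_statistic: float
    omnibus_p: float
    alpha: float
    group_n: dict[str, int]
    group_medians: dict[str, float]
    posthoc: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def omnibus_significant(self) -> bool:
        return self.omnibus_p < self.alpha

    def significant_groups(self) -> list[str]:
        return [g for g, (_, p) in self.posthoc.items() if p < self.alpha]

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "kruskal_h": self.h_statistic,
            "omnibus_p": self.omnibus_p,
            "alpha": self.alpha,
            "group_n": self.group_n,
            "group_medians": self.group_medians,
            "posthoc": {g: {"statistic": s, "p": p}
                        for g, (s, p) in self.posthoc.items()},
        }


def run_group_tests(scores: pd.DataFrame, alpha: float = 0.05,
                    metrics: tuple[str, ...] = METRICS) -> dict[str, TestReport]:
    """Kruskal-Wallis across the seven groups, gating rank-sum post-hocs.

    Post-hoc comparisons (each TMS group vs the no-TMS baseline) are run
    only when the omnibus test is significant at ``alpha``, matching the
    gated analysis convention; no further correction is applied.
    """
    df = scores[~scores["excluded"]] if "excluded" in scores else scores
    if "group" not in df:
        raise ValueError("scores must carry a 'group' column (assign_laterality)")
    reports: dict[str, TestReport] = {}
    for metric in metrics:
        samples = {}
        for g in GROUP_LABELS:
            vals = df.loc[df["group"] == g, metric].dropna().to_numpy()
            if len(vals) == 0:
                raise ValueError(f"empty group {g!r} for metric {metric!r}")
            samples[g] = vals
        try:
            with np.errstate(invalid="ignore"):
                h, p = sps.kruskal(*samples.values())
            if not np.isfinite(h):  # all values identical: maximal ties
                h, p = 0.0, 1.0
        except ValueError:
            h, p = 0.0, 1.0
        report = TestReport(
            metric=metric, h_statistic=float(h), omnibus_p=float(p), alpha=alpha,
            group_n={g: int(len(v)) for g, v in samples.items()},
            group_medians={g: float(np.median(v)) for g, v in samples.items()})
        if report.omnibus_significant:
            base = samples["noTMS"]
            for g in GROUP_LABELS[1:]:
                report.posthoc[g] = rank_sum_test(samples[g], base)
        reports[metric] = report
    return reports


def per_subject_delta(scores: pd.DataFrame,
                      metrics: tuple[str, ...] = METRICS) -> pd.DataFrame:
    """Per-subject baseline vs TMS mean error and their difference.

    One row per (subject, TMS group, metric): the subject's mean included-
    trial error at baseline, under TMS, and delta = TMS - baseline.
    Subjects missing either session are omitted with a warning.
    """
    df = scores[~scores["excluded"]] if "excluded" in scores else scores
    rows = []
    for subject, sub in df.groupby("subject"):
        base = sub[sub["group"] == "noTMS"]
        if len(base) == 0:
            warnings.warn(f"subject {subject!r} has no baseline session; omitted",
                          stacklevel=2)
            continue
        for g in GROUP_LABELS[1:]:
            tms = sub[sub["group"] == g]
            if len(tms) == 0:
                continue
            for metric in metrics:
                b = base[metric].mean()
                t = tms[metric].mean()
                rows.append({"subject": subject, "group": g, "metric": metric,
                             "baseline_error": b, "tms_error": t,
                             "delta": t - b, "n_baseline": len(base),
                             "n_tms": len(tms)})
    return pd.DataFrame(rows)


def report_text(reports: dict[str, TestReport]) -> str:
    """Human-readable summary table of the group tests."""
    lines = []
    for metric, r in reports.items():
        lines.append(f"=== {metric} ===")
        lines.append(f"Kruskal-Wallis H = {r.h_statistic:.3f}, "
                     f"p = {r.omnibus_p:.4g} "
                     f"({'significant' if r.omnibus_significant else 'n.s.'} "
                     f"at alpha = {r.alpha})")
        for g in GROUP_LABELS:
            med = r.group_medians[g]
            n = r.group_n[g]
            line = f"  {g:12s} n = {n:4d}  median = {med:.3f} deg"
            if g in r.posthoc:
                s, p = r.posthoc[g]
                flag = " *" if p < r.alpha else ""
                line += f"  vs baseline: p = {p:.4g}{flag}"
            lines.append(line)
    return "\n".join(lines)
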