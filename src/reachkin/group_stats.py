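"""Nonparametric group comparisons, correlations and FDR flagging.

Mirrors the analysis protocol: Levene (Brown-Forsythe) and one-sample
Kolmogorov-Smirnov assumption checks, Mann-Whitney U for between-group
contrasts, Pearson correlations between kinematics and adaptive-functioning
covariates, and Benjamini-Hochberg FDR flags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from reachkin.kinematics import FEATURE_NAMES
from reachkin.trajectory_io import Group


@dataclass(frozen=True)
class TestResult:
    feature: str
    test: str
    statistic: float
    p_value: float
    median_a: float | None = None
    median_b: float | None = None
    direction: str | None = None  # "a>b", "a<b" or "a=b"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _direction(med_a: float, med_b: float) -> str:
    if med_a > med_b:
        return "a>b"
    if med_a < med_b:
        return "a<b"
    return "a=b"


def mann_whitney_u(a, b, feature: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration for small tie-free samples (n_a + n_b <= 12),
    otherwise the normal approximation with midrank tie correction and
    continuity correction. Identical constant samples return p = 1 with the
    degenerate flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs at least one observation")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(
            feature, "mann-whitney", a.size * b.size / 2.0, 1.0,
            med_a, med_b, "a=b", degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(
        feature, "mann-whitney", float(res.statistic), float(min(res.pvalue, 1.0)),
        med_a, med_b, _direction(med_a, med_b),
    )


def levene_test(a, b, feature: str = "") -> TestResult:
    """Brown-Forsythe variant of Levene's test (deviations from group medians)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("levene_test needs >= 3 observations per group")
    dev_a = np.abs(a - np.median(a))
    dev_b = np.abs(b - np.median(b))
    if np.all(dev_a == dev_a[0]) and np.all(dev_b == dev_b[0]) and dev_a[0] == dev_b[0]:
        return TestResult(feature, "levene", 0.0, 1.0, degenerate=True)
    stat, p = stats.levene(a, b, center="median")
    if not np.isfinite(stat):
        return TestResult(feature, "levene", 0.0, 1.0, degenerate=True)
    return TestResult(feature, "levene", float(stat), float(p))


def ks_test(sample, feature: str = "") -> TestResult:
    """One-sample KS test against a normal fitted by sample mean and SD."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("ks_test needs >= 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return TestResult(feature, "ks", 1.0, 0.0, degenerate=True)
    stat, p = stats.kstest(x, "norm", args=(x.mean(), sd), mode="asymp")
    return TestResult(feature, "ks", float(stat), float(p))


def pearson_r(x, y, feature: str = "") -> TestResult:
    """Pearson correlation with two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return TestResult(feature, "pearson", float(res.statistic), float(res.pvalue))


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up procedure; returns a boolean reject mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * (np.arange(1, m + 1) / m)
    passing = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


_PAIR_DEFAULT = ((Group.ADULT, Group.TD), (Group.TD, Group.ASD))


def _aggregate(features: pd.DataFrame, level: str) -> pd.DataFrame:
    if level == "trial":
        return features
    if level == "subject":
        return (
            features.groupby(["subject", "group"], as_index=False)[list(FEATURE_NAMES)]
            .mean()
        )
    raise ValueError(f"unknown unit of analysis {level!r}")


def compare_groups(
    features: pd.DataFrame,
    pairs=_PAIR_DEFAULT,
    level: str = "trial",
    feature_names=FEATURE_NAMES,
) -> pd.DataFrame:
    """Mann-Whitney comparison of every feature for each group pair.

    Assumption checks (Levene on the pair, KS per group) are attached per
    row. ``level`` selects trial-level rows (as collected) or subject means.
    Returns one row per (comparison, feature).
    """
    df = _aggregate(features, level)
    rows = []
    for ga, gb in pairs:
        ga, gb = Group(ga), Group(gb)
        a_df = df[df["group"] == ga.value]
        b_df = df[df["group"] == gb.value]
        if len(a_df) < 2 or len(b_df) < 2:
            raise ValueError(f"missing or underpopulated group in pair {ga.value} vs {gb.value}")
        for feat in feature_names:
            a = a_df[feat].to_numpy()
            b = b_df[feat].to_numpy()
            mwu = mann_whitney_u(a, b, feat)
            lev = levene_test(a, b, feat)
            ks_a = ks_test(a, feat)
            ks_b = ks_test(b, feat)
            rows.append(
                {
                    "comparison": f"{ga.value}_vs_{gb.value}",
                    "feature": feat,
                    "u_statistic": mwu.statistic,
                    "p_value": mwu.p_value,
                    f"median_{ga.value}": mwu.median_a,
                    f"median_{gb.value}": mwu.median_b,
                    "direction": {"a>b": f"{ga.value}>{gb.value}",
                                  "a<b": f"{ga.value}<{gb.value}",
                                  "a=b": "equal"}[mwu.direction],
                    "levene_p": lev.p_value,
                    f"ks_p_{ga.value}": ks_a.p_value,
                    f"ks_p_{gb.value}": ks_b.p_value,
                }
            )
    return pd.DataFrame(rows)


def correlate_with_scores(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    groups=(Group.TD, Group.ASD),
    covariates=("communication", "daily_living", "socialization"),
    level: str = "trial",
    q: float = 0.05,
    feature_names=FEATURE_NAMES,
) -> pd.DataFrame:
    """Pearson correlations of features against per-subject covariates.

    With ``level="trial"`` each subject's score is broadcast to their trials;
    ``level="subject"`` correlates subject means. BH FDR flags are assigned
    per (group, covariate) column family. Returns one row per
    (group, covariate, feature) with r, p_value and fdr_flag.
    """
    df = _aggregate(features, level)
    merged = df.merge(scores, on=["subject", "group"], how="inner")
    rows = []
    for g in groups:
        g = Group(g)
        gdf = merged[merged["group"] == g.value]
        for cov in covariates:
            fam = []
            for feat in feature_names:
                res = pearson_r(gdf[feat].to_numpy(), gdf[cov].to_numpy(), feat)
                fam.append(
                    {
                        "group": g.value,
                        "covariate": cov,
                        "feature": feat,
                        "r": res.statistic,
                        "p_value": res.p_value,
                        "n": len(gdf),
                    }
                )
            flags = fdr_bh([r["p_value"] for r in fam], q=q)
            for row, flag in zip(fam, flags):
                row["fdr_flag"] = bool(flag)
            rows.extend(fam)
    return pd.DataFrame(rows)


def render_correlation_table(corr: pd.DataFrame) -> str:
    """Render the correlation table as Markdown: one row per feature, one
    column per group x covariate, stars for significance, ** for p < 0.001,
    and [FDR] marking cells that survived correction."""
    cols = [(g, c) for g in corr["group"].unique() for c in corr["covariate"].unique()]
    features = list(dict.fromkeys(corr["feature"]))
    header = "| feature | " + " | ".join(f"{g}:{c}" for g, c in cols) + " |"
    sep = "|" + "---|" * (len(cols) + 1)
    lines = [header, sep]
    idx = corr.set_index(["group", "covariate", "feature"])
    for feat in features:
        cells = []
        for g, c in cols:
            row = idx.loc[(g, c, feat)]
            stars = "**" if row["p_value"] < 0.001 else ("*" if row["p_value"] < 0.05 else "")
            fdr = " [FDR]" if row["fdr_flag"] else ""
            cells.append(f"{row['r']:.3f}{stars}{fdr}")
        lines.append(f"| {feat} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
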