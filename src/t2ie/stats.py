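"""Reproducibility statistics: CoV by effect, two-way random-effects ICC,
and pairwise rank-sum tests.

The study design nests four sources of variability — run, session, scanner
(site) and subject.  Scan-level ROI means are grouped so that the scans
within a group differ only by the effect under study:

* inter-run: scans from the same subject, site and session;
* inter-session: per-session means (runs averaged) within subject and site;
* inter-scanner: per-site means (sessions and runs averaged) within subject;
* inter-subject: per-subject means (all of a subject's scans on one site
  averaged), grouped by site.

Within each group the coefficient of variation is ``sample SD / mean x 100``.
Reliability is summarized by the two-way random-effects, single-measurement,
consistency ICC — ICC(C,1) = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err)
from the two-way ANOVA of the subjects x measurements matrix — with 95%
F-based confidence bounds.  CoV distributions are compared pairwise across
effects with two-sided Wilcoxon rank-sum tests under Bonferroni correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EFFECTS",
    "EffectGrouping",
    "ICCResult",
    "ReproReport",
    "roi_means",
    "group_by_effect",
    "cov_percent",
    "cov_by_effect",
    "icc_consistency_single",
    "icc_by_roi",
    "pairwise_ranksum_bonferroni",
    "build_report",
]

EFFECTS = ("inter_run", "inter_session", "inter_scanner", "inter_subject")

ROI_TABLE_COLUMNS = ["scan_id", "subject", "site", "session", "run", "roi", "value"]


def roi_means(scalar_map: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Arithmetic mean of a scalar map per ROI label, NaN voxels excluded.

    Labels whose voxels are all NaN (or absent) produce no entry.
    """
    scalar_map = np.asarray(scalar_map, dtype=float)
    labels = np.asarray(labels)
    if scalar_map.shape != labels.shape:
        raise ValueError("scalar map and labels are not aligned")
    out: dict[int, float] = {}
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        vals = scalar_map[labels == lab]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"ROI {int(lab)} has no valid voxels; omitted", stacklevel=2)
            continue
        out[int(lab)] = float(vals.mean())
    return out


@dataclass
class EffectGrouping:
    """Groups of scalar values sharing everything except the studied effect.

    ``groups`` maps (roi, *group identifiers) to the list of values whose
    spread the effect explains.  Groups with fewer than two members are
    dropped (with a warning) since no variability can be computed in them.
    """

    effect: str
    groups: dict[tuple, list[float]]


def _grouped(table, by, value="value"):
    return table.groupby(by, sort=True)[value].mean().reset_index()


def group_by_effect(table: pd.DataFrame, effect: str) -> EffectGrouping:
    """Build the value groups for one effect from a scan x ROI table."""
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {EFFECTS}")
    missing = [c for c in ROI_TABLE_COLUMNS if c not in table.columns and c != "scan_id"]
    if missing:
        raise ValueError(f"ROI table missing columns: {missing}")

    if effect == "inter_run":
        data = table
        group_cols = ["roi", "subject", "site", "session"]
    elif effect == "inter_session":
        data = _grouped(table, ["roi", "subject", "site", "session"])
        group_cols = ["roi", "subject", "site"]
    elif effect == "inter_scanner":
        data = _grouped(table, ["roi", "subject", "site"])
        group_cols = ["roi", "subject"]
    else:  # inter_subject
        data = _grouped(table, ["roi", "site", "subject"])
        group_cols = ["roi", "site"]

    groups: dict[tuple, list[float]] = {}
    n_dropped = 0
    for key, sub in data.groupby(group_cols, sort=True):
        vals = sub["value"].tolist()
        if len(vals) < 2:
            n_dropped += 1
            continue
        groups[tuple(np.atleast_1d(key))] = vals
    if n_dropped:
        warnings.warn(
            f"{effect}: dropped {n_dropped} group(s) with fewer than 2 values",
            stacklevel=2,
        )
    return EffectGrouping(effect, groups)


def cov_percent(values, ddof: int = 1) -> float:
    """Coefficient of variation in percent: sample SD / mean x 100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(v.std(ddof=ddof) / mean * 100.0)


def cov_by_effect(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group CoV for every effect: columns effect, roi, group, cov_percent."""
    rows = []
    for effect in EFFECTS:
        grouping = group_by_effect(table, effect)
        for key, vals in grouping.groups.items():
            rows.append(
                {
                    "effect": effect,
                    "roi": key[0],
                    "group": "_".join(map(str, key[1:])),
                    "cov_percent": cov_percent(vals),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ICCResult:
    """Two-way random-effects, single-measurement, consistency ICC."""

    icc: float
    n_subjects: int
    k_measurements: int
    ci_lower: float
    ci_upper: float
    confidence: float = 0.95


def icc_consistency_single(matrix: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(C,1) from the two-way ANOVA of a subjects x measurements matrix.

    ``ICC = (MS_rows - MS_err) / (MS_rows + (k - 1) MS_err)`` with the
    standard F-based confidence interval.  The matrix must be complete
    (no NaN); incomplete subjects must be dropped by the caller.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains missing cells")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_total = np.sum((m - grand) ** 2)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    alpha = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_rows / ms_err if ms_err > 0 else np.inf
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    lower = (fl - 1) / (fl + k - 1)
    upper = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), n, k, float(lower), float(upper), confidence)


def icc_by_roi(table: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """ICC(C,1) per ROI with subjects as rows and the repeated scans as columns.

    Measurement columns are the (site, session, run) combinations in sorted
    order; subjects missing any combination are dropped with a warning.
    """
    rows = []
    for roi, sub in table.groupby("roi", sort=True):
        wide = sub.pivot_table(
            index="subject", columns=["site", "session", "run"], values="value"
        )
        complete = wide.dropna()
        if complete.shape[0] < wide.shape[0]:
            warnings.warn(
                f"ROI {roi}: dropped {wide.shape[0] - complete.shape[0]} incomplete subject(s)",
                stacklevel=2,
            )
        if complete.shape[0] < 2 or complete.shape[1] < 2:
            warnings.warn(f"ROI {roi}: not enough complete data for ICC", stacklevel=2)
            continue
        res = icc_consistency_single(complete.to_numpy(), confidence)
        rows.append(
            {
                "roi": roi,
                "icc": res.icc,
                "n_subjects": res.n_subjects,
                "k_measurements": res.k_measurements,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
            }
        )
    return pd.DataFrame(rows)


def pairwise_ranksum_bonferroni(
    cov_lists: dict[str, list[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test for every pair of effects.

    Exact p-values for small untied samples, normal approximation with tie
    and continuity correction otherwise; Bonferroni adjustment over the
    number of pairs actually tested.
    """
    effects = [e for e in cov_lists if len(cov_lists[e]) >= 2]
    skipped = set(cov_lists) - set(effects)
    if skipped:
        warnings.warn(f"effects skipped (fewer than 2 values): {sorted(skipped)}",
                      stacklevel=2)
    pairs = list(itertools.combinations(effects, 2))
    if not pairs:
        return pd.DataFrame(
            columns=["effect_a", "effect_b", "p_raw", "p_adjusted", "significant"]
        )
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        res = sps.mannwhitneyu(
            cov_lists[a], cov_lists[b], alternative="two-sided", method="auto"
        )
        p_adj = min(1.0, res.pvalue * n_pairs)
        rows.append(
            {
                "effect_a": a,
                "effect_b": b,
                "p_raw": float(res.pvalue),
                "p_adjusted": float(p_adj),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReproReport:
    """Machine-readable reproducibility summary of one method/arm."""

    cov: pd.DataFrame
    icc: pd.DataFrame
    tests: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.cov.to_csv(out_dir / "cov_by_effect.csv", index=False)
        self.icc.to_csv(out_dir / "icc_by_roi.csv", index=False)
        self.tests.to_csv(out_dir / "pairwise_tests.csv", index=False)
        self.summary.to_csv(out_dir / "roi_summary.csv", index=False)


def build_report(table: pd.DataFrame, confidence: float = 0.95) -> ReproReport:
    """Full reproducibility report from a scan x ROI value table.

    Pairwise effect comparisons are run within each ROI (each ROI has its
    own CoV distribution per effect, mirroring per-tissue comparison
    panels), with Bonferroni correction over the pairs tested in that ROI.
    """
    cov = cov_by_effect(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        icc = icc_by_roi(table, confidence)
    test_frames = []
    for roi, sub in cov.groupby("roi", sort=True):
        cov_lists = {
            eff: sub.loc[sub.effect == eff, "cov_percent"].dropna().tolist()
            for eff in EFFECTS
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = pairwise_ranksum_bonferroni(cov_lists)
        t.insert(0, "roi", roi)
        test_frames.append(t)
    tests = (
        pd.concat(test_frames, ignore_index=True)
        if test_frames
        else pd.DataFrame(
            columns=["roi", "effect_a", "effect_b", "p_raw", "p_adjusted", "significant"]
        )
    )
    summary = (
        table.groupby("roi")["value"].agg(["mean", "std", "count"]).reset_index()
    )
    return ReproReport(cov, icc, tests, summary)
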