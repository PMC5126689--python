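"""Subtype comparison and median-split survival analysis.

Patients are split at the median expression of a lincRNA (ties to the low
group), survival in the two groups is summarized by Kaplan-Meier
product-limit curves, compared by the log-rank test, and the high-vs-low
hazard ratio is estimated by a univariate Cox proportional-hazards model
(lifelines; Efron tie handling, immaterial for continuous times). Subtype
analysis contrasts ER+ tumors against ER- tumors and against normal tissue
with unpaired Wilcoxon rank-sum tests; a lincRNA is flagged ER+-specific
when both contrasts pass |log2FC| >= 1 and BH-adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .discovery_de import bh_adjust, log2_fold_change
from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "KMEstimate",
    "median_split",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "survival_screen",
    "subtype_compare",
]


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def median_split(expr: pd.Series | np.ndarray) -> pd.Series:
    """'high'/'low' group per patient by median split; ties go to 'low'."""
    s = pd.Series(expr, dtype=float) if not isinstance(expr, pd.Series) else expr.astype(float)
    if len(s) < 2:
        raise ValueError("need >= 2 patients")
    med = float(s.median())
    if (s == s.iloc[0]).all():
        raise ValueError("all expression values equal; no split possible")
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


def km_estimate(time, event) -> KMEstimate:
    """Kaplan-Meier estimate from times and event indicators.

    Subjects censored at an event time are counted at risk at that time
    and removed afterwards (standard product-limit convention).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter().fit(time, event)
    tbl = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0.0 and kmf.event_table["observed"].iloc[0] == 0 else kmf.event_table
    tbl = tbl[tbl["observed"] > 0]
    times = tbl.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in times])
    return KMEstimate(
        event_times=times,
        at_risk=tbl["at_risk"].to_numpy(dtype=int),
        events=tbl["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """1-df log-rank chi-square and p for two survival samples."""
    if int(np.sum(event_a)) + int(np.sum(event_b)) == 0:
        warnings.warn("no events in either group; log-rank undefined")
        return np.nan, np.nan
    res = _ll_logrank(
        np.asarray(time_a, float), np.asarray(time_b, float),
        event_observed_A=np.asarray(event_a, int),
        event_observed_B=np.asarray(event_b, int),
    )
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(
    time, event, group, ref: str = "low"
) -> tuple[float, tuple[float, float]]:
    """Univariate Cox HR of 'high' vs 'low' with a 95% Wald CI.

    A monotone likelihood (all events in one group before any in the
    other) is reported as an infinite/zero HR with a warning.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, float),
            "event": np.asarray(event, int),
            "x": (np.asarray(group) != ref).astype(float),
        }
    )
    if df.groupby("x")["event"].sum().min() == 0:
        warnings.warn("a group has no events; hazard ratio unbounded")
        mean_high = df.loc[df.x == 1, "event"].mean()
        return (np.inf if mean_high > 0 else 0.0), (np.nan, np.nan)
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return float(np.exp(beta)), (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))


def survival_screen(
    matrix: ExpressionMatrix,
    survival: pd.DataFrame,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Median-split survival association per feature.

    ``survival`` is indexed by (or carries) subject_id with ``time`` and
    ``event`` columns; subjects are matched to matrix columns by id.
    Returns per-feature log-rank chi2/p, HR with CI, group medians, and a
    ``hit`` flag at log-rank p < p_max.
    """
    surv = survival.set_index("subject_id") if "subject_id" in survival.columns else survival
    common = [s for s in matrix.samples if s in surv.index]
    if len(common) < 4:
        raise ValueError("need >= 4 subjects with survival data")
    surv = surv.loc[common]
    rows = []
    for fid in matrix.features:
        expr = matrix.values.loc[fid, common]
        try:
            grp = median_split(expr)
        except ValueError:
            continue
        hi, lo = grp == "high", grp == "low"
        chi2, p = logrank_test(
            surv.loc[hi.values, "time"], surv.loc[hi.values, "event"],
            surv.loc[lo.values, "time"], surv.loc[lo.values, "event"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hr, (lo_ci, hi_ci) = hazard_ratio(surv["time"], surv["event"], grp)
        rows.append(
            {
                "feature_id": fid,
                "chi2": chi2,
                "p_logrank": p,
                "hr": hr,
                "hr_lo": lo_ci,
                "hr_hi": hi_ci,
                "median_high": float(expr[hi].median()),
                "median_low": float(expr[lo].median()),
                "hit": bool(p < p_max) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def subtype_compare(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    fc_min_log2: float = 1.0,
    p_max: float = 0.05,
    min_class: int = 3,
) -> pd.DataFrame:
    """ER+ vs ER- and ER+ vs normal contrasts per feature.

    Unpaired Wilcoxon rank-sum per contrast with BH adjustment within each
    contrast; ``er_specific`` flags features where both contrasts pass
    |log2fc| >= fc_min_log2 and p_bh < p_max.
    """
    df = sheet.df
    er_pos = list(df.index[(df["tissue"] == "tumor") & (df.get("er_status") == "ER+")])
    er_neg = list(df.index[(df["tissue"] == "tumor") & (df.get("er_status") == "ER-")])
    normal = list(df.index[df["tissue"].isin(["adjacent", "normal"])])

    def contrast(a: list[str], b: list[str], tag: str) -> pd.DataFrame | None:
        if len(a) < min_class or len(b) < min_class:
            warnings.warn(f"contrast {tag}: class too small, skipped")
            return None
        A = matrix.values[a].to_numpy(dtype=float)
        B = matrix.values[b].to_numpy(dtype=float)
        lfc = np.array([log2_fold_change(A[i], B[i]) for i in range(A.shape[0])])
        p = np.array([stats.ranksums(A[i], B[i]).pvalue for i in range(A.shape[0])])
        return pd.DataFrame(
            {f"log2fc_{tag}": lfc, f"p_bh_{tag}": bh_adjust(p)}, index=matrix.features
        )

    parts = [
        contrast(er_pos, er_neg, "pos_vs_neg"),
        contrast(er_pos, normal, "pos_vs_normal"),
    ]
    parts = [p for p in parts if p is not None]
    if not parts:
        return pd.DataFrame(index=matrix.features)
    out = pd.concat(parts, axis=1)
    if len(parts) == 2:
        out["er_specific"] = (
            (out["log2fc_pos_vs_neg"].abs() >= fc_min_log2)
            & (out["p_bh_pos_vs_neg"] < p_max)
            & (out["log2fc_pos_vs_normal"].abs() >= fc_min_log2)
            & (out["p_bh_pos_vs_normal"] < p_max)
        )
    return out
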