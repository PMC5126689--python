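"""Replication-stage count-based differential expression.

The replication cohort is sequenced to raw counts, so testing moves to a
negative-binomial generalized linear model: library sizes are normalized
by the trimmed mean of M-values (TMM), per-feature dispersions are
estimated by method of moments and shrunk toward the cohort median, and
each feature is tested by a 1-df likelihood-ratio chi-square for the
tissue-type term, adjusting for age, race and sequencing batch. This is a
deliberately compact TMM + NB-GLM pathway written for auditability; trim
fractions and the shrinkage weight are exposed.

Cross-stage replication applies the published rule to each feature:
|log2FC| >= 1 (two-fold) with P < 0.05 in the paired tumor-vs-adjacent
comparison, the analogous rule tumor-vs-healthy-normal, and concordance of
the fold-change direction with the discovery stage. A relaxed fold-change
gate (|log2FC| >= 0.585, i.e. 1.5-fold) is supported.
"""

from __future__ import annotations

import importlib.resources
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .discovery_de import bh_adjust
from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "tmm_factors",
    "nb_dispersion",
    "nb_test",
    "replication_filter",
    "load_table2",
]


def tmm_factors(
    counts: ExpressionMatrix | pd.DataFrame,
    ref: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factor per sample.

    For each sample against a reference column, per-gene log2 ratios of
    library-size-scaled counts (M) and average log intensities (A) are
    computed over genes nonzero in both samples, doubly trimmed (30% of M,
    5% of A from each tail), and averaged with inverse-asymptotic-variance
    weights; the factor is 2 to that mean. Factors are rescaled to
    geometric mean 1. The reference defaults to the sample whose scaled
    upper quartile is closest to the cohort mean.
    """
    X = counts.values if isinstance(counts, ExpressionMatrix) else counts
    arr = X.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    for j, s in enumerate(X.columns):
        if lib[j] == 0:
            raise ValueError(f"sample {s!r} has all-zero counts")
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")

    if ref is None:
        with np.errstate(divide="ignore"):
            f75 = np.array([np.quantile(arr[:, j], 0.75) / lib[j] for j in range(arr.shape[1])])
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(X.columns).index(ref)
    r, Nr = arr[:, ref_j], lib[ref_j]

    logf = np.zeros(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_j:
            continue
        x, N = arr[:, j], lib[j]
        mask = (x > 0) & (r > 0)
        x_, r_ = x[mask], r[mask]
        M = np.log2((x_ / N) / (r_ / Nr))
        A = 0.5 * np.log2((x_ / N) * (r_ / Nr))
        # inverse asymptotic variance of M (delta method on binomial counts)
        v = (N - x_) / (N * x_) + (Nr - r_) / (Nr * r_)
        w = 1.0 / v
        n = M.size
        if n == 0:
            continue
        loM = np.floor(n * trim_m) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * trim_a) + 1
        hiA = n + 1 - loA
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep = (rank_m >= loM) & (rank_m <= hiM) & (rank_a >= loA) & (rank_a <= hiA)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        f = (w[keep] * M[keep]).sum() / w[keep].sum()
        if abs(f) > 1e-6:
            logf[j] = f
    factors = np.power(2.0, logf)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=X.columns, name="tmm_factor")


def nb_dispersion(
    counts: ExpressionMatrix | pd.DataFrame,
    groups: Sequence[str],
    shrink: float = 0.3,
    factors: pd.Series | None = None,
) -> tuple[float, pd.Series]:
    """Method-of-moments NB dispersion, shrunk toward the cohort median.

    Under var = mu + phi mu^2, the per-feature estimate solves
    phi = sum((y - mu)^2 - mu) / sum(mu^2) with mu the group-specific
    effective-library-scaled mean. Estimates are floored at 0 and each is
    shrunk as (1 - shrink) * phi_feature + shrink * median.
    """
    X = counts.values if isinstance(counts, ExpressionMatrix) else counts
    arr = X.to_numpy(dtype=float)
    groups = np.asarray(groups)
    lib = arr.sum(axis=0)
    eff = lib * (factors.to_numpy() if factors is not None else 1.0)
    rel = arr / eff[None, :]

    phi = np.zeros(arr.shape[0])
    for g in np.unique(groups):
        idx = groups == g
        if idx.sum() < 2:
            continue
        mu_rel = rel[:, idx].mean(axis=1)
        mu = mu_rel[:, None] * eff[None, idx]
        phi += ((arr[:, idx] - mu) ** 2 - mu).sum(axis=1)
    denom = np.zeros(arr.shape[0])
    for g in np.unique(groups):
        idx = groups == g
        if idx.sum() < 2:
            continue
        mu_rel = rel[:, idx].mean(axis=1)
        mu = mu_rel[:, None] * eff[None, idx]
        denom += (mu**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, phi / np.maximum(denom, 1e-300), 0.0)
    phi = np.maximum(phi, 0.0)
    expressed = arr.mean(axis=1) > 0
    common = float(np.median(phi[expressed])) if expressed.any() else 0.0
    shrunk = (1.0 - shrink) * phi + shrink * common
    return common, pd.Series(shrunk, index=X.index, name="dispersion")


def _design(
    groups: np.ndarray,
    covariates: pd.DataFrame | None,
    target: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Full and null design matrices: intercept + group + one-hot covariates."""
    n = len(groups)
    cols = [np.ones(n)]
    grp = (groups == target).astype(float)
    cols_null = [np.ones(n)]
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "if":
                v = col.to_numpy(dtype=float)
                sd = v.std()
                v = (v - v.mean()) / (sd if sd > 0 else 1.0)
                cols.append(v)
                cols_null.append(v)
            else:
                levels = sorted(col.astype(str).unique())[1:]  # first level = baseline
                for lev in levels:
                    v = (col.astype(str) == lev).to_numpy(dtype=float)
                    cols.append(v)
                    cols_null.append(v)
    X1 = np.column_stack(cols + [grp])
    X0 = np.column_stack(cols_null)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("design matrix is not full rank")
    return X1, X0


def nb_test(
    counts: ExpressionMatrix | pd.DataFrame,
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
    offsets: np.ndarray | None = None,
    dispersion: pd.Series | float | None = None,
    target: str = "tumor",
    fc_min_log2: float = 1.0,
    fdr_max: float = 0.05,
    maxiter: int = 100,
) -> pd.DataFrame:
    """Per-feature NB GLM likelihood-ratio test for the group term.

    Fits log-link NB regressions (IRLS, fixed dispersion) with and without
    the group indicator, on top of ``offsets`` (log effective library
    size; computed from column sums x TMM factors when omitted). Returns a
    table with log2fc (group coefficient / ln 2), lr_stat, p_raw, p_fdr,
    fitted group means, and a ``significant`` flag implementing
    FDR p < 0.05 with a two-fold change.
    """
    X = counts.values if isinstance(counts, ExpressionMatrix) else counts
    arr = X.to_numpy(dtype=float)
    groups = np.asarray(groups)
    if offsets is None:
        f = tmm_factors(X)
        offsets = np.log(arr.sum(axis=0) * f.to_numpy())
    offsets = np.asarray(offsets, dtype=float)

    if dispersion is None:
        _, dispersion = nb_dispersion(X, groups)
    if np.isscalar(dispersion):
        disp = np.full(arr.shape[0], float(dispersion))
    else:
        disp = dispersion.reindex(X.index).to_numpy(dtype=float)

    X1, X0 = _design(groups, covariates, target)
    in_grp = groups == target
    out = {
        "log2fc": np.full(arr.shape[0], np.nan),
        "lr_stat": np.full(arr.shape[0], np.nan),
        "p_raw": np.full(arr.shape[0], np.nan),
        "mu_target": np.full(arr.shape[0], np.nan),
        "mu_other": np.full(arr.shape[0], np.nan),
        "converged": np.zeros(arr.shape[0], dtype=bool),
    }
    for i in range(arr.shape[0]):
        y = arr[i]
        alpha = max(disp[i], 1e-8)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m1 = sm.GLM(y, X1, family=fam, offset=offsets).fit(maxiter=maxiter)
                m0 = sm.GLM(y, X0, family=fam, offset=offsets).fit(maxiter=maxiter)
            if not (m1.converged and m0.converged):
                continue
        except Exception:
            continue
        lr = max(0.0, 2.0 * (m1.llf - m0.llf))
        out["log2fc"][i] = m1.params[-1] / np.log(2.0)
        out["lr_stat"][i] = lr
        out["p_raw"][i] = stats.chi2.sf(lr, df=1)
        out["mu_target"][i] = m1.fittedvalues[in_grp].mean()
        out["mu_other"][i] = m1.fittedvalues[~in_grp].mean()
        out["converged"][i] = True

    res = pd.DataFrame(out, index=X.index)
    res["dispersion"] = disp
    ok = res["p_raw"].notna()
    res["p_fdr"] = np.nan
    res.loc[ok, "p_fdr"] = bh_adjust(res.loc[ok, "p_raw"].to_numpy())
    res["significant"] = (res["p_fdr"] < fdr_max) & (res["log2fc"].abs() >= fc_min_log2)
    return res


def replication_filter(
    discovery: pd.DataFrame,
    paired_rep: pd.DataFrame,
    tvn_rep: pd.DataFrame,
    fc_min_log2: float = 1.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Cross-stage replication verdict per feature.

    Inputs are tables indexed by feature id with ``log2fc`` and ``p``
    columns (``discovery`` needs only ``log2fc``). A feature passes a stage
    iff |log2fc| >= fc_min_log2 and p < p_max; ``direction_concordant``
    compares the sign of the paired replication fold change against
    discovery. Features missing from any table are excluded with a warning.
    """
    common = discovery.index.intersection(paired_rep.index).intersection(tvn_rep.index)
    dropped = len(discovery.index) - len(common)
    if dropped:
        warnings.warn(f"{dropped} feature(s) missing from a replication table; excluded")
    rows = []
    for fid in common:
        d_lfc = discovery.loc[fid, "log2fc"]
        p_lfc, p_p = paired_rep.loc[fid, "log2fc"], paired_rep.loc[fid, "p"]
        t_lfc, t_p = tvn_rep.loc[fid, "log2fc"], tvn_rep.loc[fid, "p"]
        rows.append(
            {
                "feature_id": fid,
                "direction_concordant": bool(np.sign(d_lfc) == np.sign(p_lfc)),
                "passes_paired": bool(abs(p_lfc) >= fc_min_log2 and p_p < p_max),
                "passes_tumor_vs_normal": bool(abs(t_lfc) >= fc_min_log2 and t_p < p_max),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


def load_table2() -> pd.DataFrame:
    """The packaged 37-lincRNA discovery/replication fold-change table.

    Columns: symbol, discovery_log2fc/_p, paired_log2fc/_p (replication,
    tumor vs adjacent), tvn_log2fc/_p (replication, tumor vs healthy
    normal); indexed by Ensembl gene id.
    """
    ref = importlib.resources.files("lincsig") / "fixtures" / "table2.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)
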