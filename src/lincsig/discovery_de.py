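"""Discovery-stage paired differential expression.

The discovery cohort is pair-matched tumor/adjacent tissue measured in
FPKM. Per feature we compute a log2 fold change of group means, a Wilcoxon
signed-rank test on the paired differences, and Benjamini-Hochberg
adjustment across features. On top of the per-feature tests sits a
permutation-based FDR estimate: the tumor/adjacent labels are exchanged
within each pair (a sign-flip null that preserves the pairing), the signed
standardized statistic is recomputed for every feature, and for a threshold
d the FDR is estimated as

    fdr_hat(d) = mean_b #{j : |s_j^(b)| >= d} / #{j : |s_j| >= d},

capped at 1 and monotonized (non-increasing in d) by a conservative
running maximum from the largest threshold downward. A feature is called
DE when it clears the
fold-change gate, the BH-adjusted p cutoff, and the smallest threshold d at
which the estimated FDR drops below the target (1% by default).

The signed standardized statistic is S / sqrt(sum r_i^2) where S is the
sum of signed mid-ranks of the nonzero paired differences; zero differences
are dropped before ranking (Wilcoxon convention).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleSheet

__all__ = [
    "log2_fold_change",
    "paired_wilcoxon",
    "bh_adjust",
    "signed_rank_z",
    "permutation_fdr",
    "select_de",
    "paired_arrays",
    "paired_de_table",
]


def log2_fold_change(
    tumor: np.ndarray, normal: np.ndarray, eps: float = 0.1
) -> float:
    """log2 of the (pseudocounted) ratio of group means, tumor vs normal."""
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    mt, mn = tumor.mean() + eps, normal.mean() + eps
    if mt == 0 and mn == 0:
        return 0.0
    return float(np.log2(mt / mn))


def signed_rank_z(diffs: np.ndarray) -> np.ndarray:
    """Signed standardized Wilcoxon statistic per row of a difference matrix.

    For each row, zero differences are dropped, absolute values mid-ranked,
    and z = sum(sign * rank) / sqrt(sum rank^2). Rows with no nonzero
    difference get z = 0.
    """
    D = np.atleast_2d(np.asarray(diffs, dtype=float))
    absd = np.abs(D)
    zero = absd == 0
    # rank zeros as +inf so nonzero entries keep their within-row ranks
    masked = np.where(zero, np.inf, absd)
    R = stats.rankdata(masked, axis=1, method="average")
    R[zero] = 0.0
    signedR = np.sign(D) * R
    S = signedR.sum(axis=1)
    denom = np.sqrt((R**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, S / np.where(denom > 0, denom, 1.0), 0.0)
    return z


def paired_wilcoxon(tumor: np.ndarray, normal: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Returns (signed standardized statistic, two-sided p). The null is exact
    for <= 25 nonzero differences without ties, otherwise a normal
    approximation with continuity correction. All-zero differences give
    (0.0, 1.0).
    """
    d = np.asarray(tumor, dtype=float) - np.asarray(normal, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0, 1.0
    z = float(signed_rank_z(d[None, :])[0])
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(
            d, zero_method="wilcox", correction=True, method=method
        )
    return z, float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def paired_arrays(
    matrix: ExpressionMatrix, sheet: SampleSheet
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract aligned tumor and adjacent arrays (features x pairs)."""
    pairs = sheet.pairs()
    if pairs.empty:
        raise ValueError("sample sheet defines no tumor/adjacent pairs")
    tumor = matrix.values[list(pairs["tumor"])].to_numpy(dtype=float)
    normal = matrix.values[list(pairs["adjacent"])].to_numpy(dtype=float)
    return tumor, normal, matrix.features


def paired_de_table(
    matrix: ExpressionMatrix, sheet: SampleSheet, eps: float = 0.1
) -> pd.DataFrame:
    """Per-feature discovery DE table: log2fc, statistic, p_raw, p_bh."""
    tumor, normal, features = paired_arrays(matrix, sheet)
    z = signed_rank_z(tumor - normal)
    lfc = np.empty(len(features))
    p = np.empty(len(features))
    for i in range(len(features)):
        lfc[i] = log2_fold_change(tumor[i], normal[i], eps=eps)
        _, p[i] = paired_wilcoxon(tumor[i], normal[i])
    return pd.DataFrame(
        {
            "feature_id": features,
            "log2fc": lfc,
            "statistic": z,
            "p_raw": p,
            "p_bh": bh_adjust(p),
        }
    ).set_index("feature_id")


def permutation_fdr(
    tumor: np.ndarray,
    normal: np.ndarray,
    d_grid: np.ndarray | None = None,
    B: int = 1000,
    seed: int = 0,
    _force_identity: bool = False,
) -> pd.DataFrame:
    """Permutation-based FDR over a grid of statistic thresholds.

    Each of the B permutations independently exchanges the tumor/adjacent
    labels within each pair with probability 1/2 (equivalently flips the
    sign of that pair's difference), recomputes the signed standardized
    statistic for every feature, and counts exceedances of each threshold.
    ``_force_identity`` is a test hook replacing the draws with the single
    identity permutation.

    Returns a DataFrame indexed by d with columns r_obs, r_perm_mean,
    fdr_raw and fdr_hat (monotonized; NaN where r_obs = 0).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    D = tumor - normal
    n_feat, n_pairs = D.shape

    absd = np.abs(D)
    zero = absd == 0
    masked = np.where(zero, np.inf, absd)
    R = stats.rankdata(masked, axis=1, method="average")
    R[zero] = 0.0
    signedR = np.sign(D) * R
    denom = np.sqrt((R**2).sum(axis=1))
    denom_safe = np.where(denom > 0, denom, 1.0)
    z_obs = np.where(denom > 0, signedR.sum(axis=1) / denom_safe, 0.0)

    rng = np.random.default_rng(seed)
    if _force_identity:
        flips = np.ones((n_pairs, 1))
        B = 1
    else:
        flips = rng.choice([-1.0, 1.0], size=(n_pairs, B))
    z_perm = (signedR @ flips) / denom_safe[:, None]
    z_perm[denom == 0, :] = 0.0

    if d_grid is None:
        d_grid = np.unique(np.abs(z_obs))
    d_grid = np.sort(np.asarray(d_grid, dtype=float))

    abs_obs = np.sort(np.abs(z_obs))
    abs_perm = np.sort(np.abs(z_perm).ravel())
    r_obs = abs_obs.size - np.searchsorted(abs_obs, d_grid, side="left")
    r_perm = (abs_perm.size - np.searchsorted(abs_perm, d_grid, side="left")) / B

    with np.errstate(invalid="ignore", divide="ignore"):
        fdr_raw = np.where(r_obs > 0, np.minimum(1.0, r_perm / np.maximum(r_obs, 1)), np.nan)
    # Monotone non-increasing in d, conservatively: running maximum from the
    # largest threshold downward, so a noise dip at one d cannot admit a
    # lower threshold than the curve beyond it supports.
    fdr_hat = fdr_raw.copy()
    valid = ~np.isnan(fdr_hat)
    if valid.any():
        rev = fdr_hat[valid][::-1]
        fdr_hat[valid] = np.maximum.accumulate(rev)[::-1]
    return pd.DataFrame(
        {
            "d": d_grid,
            "r_obs": r_obs,
            "r_perm_mean": r_perm,
            "fdr_raw": fdr_raw,
            "fdr_hat": fdr_hat,
        }
    ).set_index("d")


def select_de(
    results: pd.DataFrame,
    permfdr: pd.DataFrame,
    fc_min: float = 2.0,
    bh_max: float = 0.01,
    fdr_max: float = 0.01,
) -> tuple[list[str], float | None]:
    """Apply the discovery selection rule.

    A feature is selected iff |log2fc| >= log2(fc_min), p_bh < bh_max, and
    |statistic| >= d*, where d* is the smallest threshold on the FDR grid
    with estimated FDR < fdr_max. Returns (selected ids, d*); d* is None
    (empty selection, warning) when no threshold achieves the target.
    """
    ok = permfdr["fdr_hat"] < fdr_max
    if not ok.any():
        warnings.warn(f"no threshold achieves estimated FDR < {fdr_max}; empty selection")
        return [], None
    d_star = float(permfdr.index[ok].min())
    mask = (
        (results["log2fc"].abs() >= np.log2(fc_min))
        & (results["p_bh"] < bh_max)
        & (results["statistic"].abs() >= d_star)
    )
    return list(results.index[mask]), d_star
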