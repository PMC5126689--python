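"""Co-expression-based function inference for lincRNAs.

A lincRNA's putative function is read off the coding genes it is strongly
co-expressed with: Spearman correlations against all coding genes are
compared to a null distribution built from randomly shuffled
lincRNA/gene pairings (1000 draws by default), and genes with
|rho| >= 0.4 (a cutoff sitting above the null's extreme quantiles at
cohort-scale sample sizes) form the co-expressed set. That set is then
tested for over-representation in user-supplied gene sets (GMT) by an
upper-tail hypergeometric test with Benjamini-Hochberg adjustment across
sets; sets at adjusted p <= 0.05 are called enriched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .discovery_de import bh_adjust
from .io_formats import ExpressionMatrix

__all__ = [
    "CoexprProfile",
    "shuffled_null",
    "coexpressed_set",
    "hypergeom_enrichment",
]


@dataclass
class CoexprProfile:
    linc_id: str
    rho_by_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    null_quantiles: tuple[float, float] = (np.nan, np.nan)  # (0.5%, 99.5%)
    threshold: float = 0.4
    coexpressed: set[str] = field(default_factory=set)


def _rows(matrix) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


def shuffled_null(
    linc_matrix: ExpressionMatrix | pd.DataFrame,
    gene_matrix: ExpressionMatrix | pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Null Spearman distribution from randomly paired lincRNA/gene rows.

    Draws ``n_shuffles`` uniform (lincRNA, gene) pairings (with
    replacement when the pair space is smaller, noted by a warning) and
    returns the rho values with their (0.5%, 99.5%) quantiles.
    """
    L, G = _rows(linc_matrix), _rows(gene_matrix)
    if L.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    n_space = L.shape[0] * G.shape[0]
    if n_space < n_shuffles:
        warnings.warn(
            f"only {n_space} distinct pairs available; sampling with replacement"
        )
    rng = np.random.default_rng(seed)
    li = rng.integers(L.shape[0], size=n_shuffles)
    gi = rng.integers(G.shape[0], size=n_shuffles)
    # rank once per row, then Pearson on ranks
    Lr = stats.rankdata(L.to_numpy(dtype=float), axis=1)
    Gr = stats.rankdata(G.to_numpy(dtype=float), axis=1)
    Lr = (Lr - Lr.mean(axis=1, keepdims=True)) / np.maximum(Lr.std(axis=1, keepdims=True), 1e-12)
    Gr = (Gr - Gr.mean(axis=1, keepdims=True)) / np.maximum(Gr.std(axis=1, keepdims=True), 1e-12)
    rhos = (Lr[li] * Gr[gi]).mean(axis=1)
    q = (float(np.quantile(rhos, 0.005)), float(np.quantile(rhos, 0.995)))
    return rhos, q


def coexpressed_set(
    linc_id: str,
    linc_row: Sequence[float] | pd.Series,
    gene_matrix: ExpressionMatrix | pd.DataFrame,
    threshold: float = 0.4,
    null_quantiles: tuple[float, float] | None = None,
) -> CoexprProfile:
    """Genes strongly co-expressed with one lincRNA: |rho| >= threshold.

    The symmetric cutoff includes both signs (rho >= threshold or
    rho <= -threshold). When null quantiles are supplied, the effective
    threshold is raised to at least the null's 99.5% magnitude so the set
    stays supra-null. A constant lincRNA row yields an empty, flagged
    profile.
    """
    G = _rows(gene_matrix)
    x = np.asarray(linc_row, dtype=float)
    eff = threshold
    if null_quantiles is not None:
        eff = max(eff, abs(null_quantiles[0]), abs(null_quantiles[1]))
    if np.all(x == x[0]):
        warnings.warn(f"{linc_id}: constant expression, empty co-expression profile")
        return CoexprProfile(linc_id=linc_id, threshold=eff)
    xr = stats.rankdata(x)
    xr = (xr - xr.mean()) / xr.std()
    Gr = stats.rankdata(G.to_numpy(dtype=float), axis=1)
    sd = Gr.std(axis=1)
    Gr = (Gr - Gr.mean(axis=1, keepdims=True)) / np.maximum(sd[:, None], 1e-12)
    rho = (Gr * xr[None, :]).mean(axis=1)
    rho[sd == 0] = np.nan
    rho_s = pd.Series(rho, index=G.index)
    coex = set(rho_s.index[rho_s.abs() >= eff])
    return CoexprProfile(
        linc_id=linc_id,
        rho_by_gene=rho_s,
        null_quantiles=null_quantiles or (np.nan, np.nan),
        threshold=eff,
        coexpressed=coex,
    )


def hypergeom_enrichment(
    query: set[str],
    sets: Mapping[str, set[str]],
    universe: set[str],
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene set collection.

    For each set S (intersected with the universe), p = P[X >= k] with
    X ~ Hypergeom(|universe|, |S|, |query|) and k the observed overlap.
    BH adjustment runs across sets; ``significant`` marks p_bh <= p_max.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        S = members & universe
        k = len(S & query)
        p = float(stats.hypergeom.sf(k - 1, M, len(S), n)) if S else 1.0
        rows.append({"set": name, "overlap": k, "set_size": len(S), "p_raw": p})
    df = pd.DataFrame(rows).set_index("set")
    df["p_bh"] = bh_adjust(df["p_raw"].to_numpy()) if len(df) else []
    df["significant"] = df["p_bh"] <= p_max
    return df.sort_values("p_raw")
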