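"""Neighboring-gene orientation and co-expression analysis.

Each lincRNA is paired with the protein-coding gene at the smallest
boundary gap on its chromosome (0 when overlapping; ties broken toward the
lower-coordinate gene and flagged). Pair orientation is head-to-head (H2H,
divergent 5' ends), head-to-tail (H2T, same strand) or tail-to-tail (T2T,
convergent 3' ends). Coordinated expression change is quantified by an
ordinary least-squares fit of lincRNA log2 fold changes on partner-gene
log2 fold changes, compared against two constructed nulls: non-neighbor
pairs (> 1 Mb apart or on other chromosomes) and uniformly random pairs.
H2H over-representation among the DE pairs is tested with a one-sided
binomial tail against the catalog-wide H2H proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, GenomicFeature

__all__ = [
    "NeighborPair",
    "classify_orientation",
    "nearest_coding_gene",
    "neighbor_pairs",
    "fc_concordance",
    "pair_nulls",
    "h2h_enrichment",
    "pairwise_spearman",
]


@dataclass(frozen=True)
class NeighborPair:
    linc_id: str
    gene_id: str
    distance: int  # bp gap between closest boundaries, 0 if overlapping
    orientation: str  # H2H | H2T | T2T
    ambiguous: bool = False  # equidistant tie broken by coordinate


def classify_orientation(linc: GenomicFeature, gene: GenomicFeature) -> str:
    """H2H / H2T / T2T from the strand geometry of the two features.

    Same strand is head-to-tail. On opposite strands the pair is divergent
    (H2H) when the minus-strand feature's TSS lies at or left of the
    plus-strand feature's TSS, convergent (T2T) otherwise; overlapping
    opposite-strand features are classified by the same 5'-end rule.
    """
    if linc.chrom != gene.chrom:
        raise ValueError("features on different chromosomes")
    if linc.strand == gene.strand:
        return "H2T"
    minus, plus = (linc, gene) if linc.strand == "-" else (gene, linc)
    return "H2H" if minus.tss <= plus.tss else "T2T"


def nearest_coding_gene(
    linc: GenomicFeature,
    genes: Mapping[str, GenomicFeature],
) -> NeighborPair | None:
    """Pair a lincRNA with the protein-coding gene at minimal boundary gap.

    Equidistant candidates resolve to the lower-coordinate gene, flagged
    ambiguous. Returns None (with a warning) when the chromosome holds no
    coding gene.
    """
    best: tuple[int, int, str] | None = None  # (gap, start, gene_id)
    tie = False
    for gid, g in genes.items():
        if g.biotype != "protein_coding" or g.chrom != linc.chrom:
            continue
        gap = linc.gap_to(g)
        if best is None or (gap, g.start) < (best[0], best[1]):
            tie = best is not None and gap == best[0]
            best = (gap, g.start, gid)
        elif gap == best[0]:
            tie = True
    if best is None:
        warnings.warn(f"{linc.feature_id}: no protein-coding gene on {linc.chrom}")
        return None
    gap, _, gid = best
    return NeighborPair(
        linc_id=linc.feature_id,
        gene_id=gid,
        distance=gap,
        orientation=classify_orientation(linc, genes[gid]),
        ambiguous=tie,
    )


def neighbor_pairs(
    lincs: Mapping[str, GenomicFeature],
    genes: Mapping[str, GenomicFeature],
) -> list[NeighborPair]:
    """Nearest-coding-gene pair for every lincRNA in the catalog."""
    out = []
    for linc in lincs.values():
        if linc.biotype != "lincRNA":
            continue
        pair = nearest_coding_gene(linc, genes)
        if pair is not None:
            out.append(pair)
    return out


def fc_concordance(
    linc_log2fc: Sequence[float], gene_log2fc: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of lincRNA log2FC on partner log2FC: (slope, r2, slope-test p)."""
    x = np.asarray(gene_log2fc, dtype=float)
    y = np.asarray(linc_log2fc, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 pairs")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in predictor fold changes")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def pair_nulls(
    lincs: Mapping[str, GenomicFeature],
    genes: Mapping[str, GenomicFeature],
    mode: str,
    min_gap: int = 1_000_000,
    n_random: int = 1000,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Constructed null pairings.

    ``non_neighbor``: for each lincRNA, one uniformly drawn coding gene
    more than ``min_gap`` away (or on another chromosome); lincRNAs with no
    eligible gene are skipped with a warning. ``random``: ``n_random``
    uniform (lincRNA, gene) draws regardless of distance.
    """
    rng = np.random.default_rng(seed)
    linc_list = [f for f in lincs.values() if f.biotype == "lincRNA"]
    gene_list = [f for f in genes.values() if f.biotype == "protein_coding"]
    if not linc_list or not gene_list:
        raise ValueError("empty catalog")
    if mode == "random":
        li = rng.integers(len(linc_list), size=n_random)
        gi = rng.integers(len(gene_list), size=n_random)
        return [(linc_list[i].feature_id, gene_list[j].feature_id) for i, j in zip(li, gi)]
    if mode != "non_neighbor":
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for linc in linc_list:
        eligible = [
            g for g in gene_list
            if g.chrom != linc.chrom or (linc.gap_to(g) or 0) > min_gap
        ]
        if not eligible:
            warnings.warn(f"{linc.feature_id}: no gene beyond {min_gap} bp; skipped")
            continue
        g = eligible[int(rng.integers(len(eligible)))]
        out.append((linc.feature_id, g.feature_id))
    return out


def h2h_enrichment(k_h2h: int, n_pairs: int, p0: float) -> float:
    """One-sided binomial tail P[X >= k] for H2H over-representation."""
    if not 0 <= k_h2h <= n_pairs:
        raise ValueError("need 0 <= k_h2h <= n_pairs")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k_h2h - 1, n_pairs, p0))


def pairwise_spearman(
    matrix: ExpressionMatrix | pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Spearman rank correlation (mid-ranks) per (lincRNA, gene) pair.

    Computed over the given sample subset (all samples by default); pairs
    involving a constant vector get NaN.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if samples is not None:
        values = values[list(samples)]
    if values.shape[1] < 4:
        raise ValueError("need >= 4 samples for rank correlation")
    out = {}
    for lid, gid in pairs:
        x = values.loc[lid].to_numpy(dtype=float)
        y = values.loc[gid].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[(lid, gid)] = np.nan
            continue
        rho, _ = stats.spearmanr(x, y)
        out[(lid, gid)] = float(rho)
    return pd.Series(out, name="rho")
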