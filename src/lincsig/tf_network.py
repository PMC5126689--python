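"""TF-lincRNA bipartite network from ChIP-seq peaks.

A lincRNA is called bound by a TF when one of the TF's peaks overlaps, by
at least 1 bp, the window running from 2 kb upstream of the lincRNA's
transcription start site to its transcription end site (strand-aware
window, strand-agnostic peaks). Multiple peaks in one window collapse to a
single edge; degree counts distinct partners. TFs of degree >= 5 are
flagged as key TFs, and a separate expression filter marks TFs with
|log2FC| >= 0.585 (1.5-fold) and BH-adjusted P < 0.01 as differentially
expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .io_formats import GenomicFeature

__all__ = [
    "BipartiteNetwork",
    "promoter_body_window",
    "assign_edges",
    "key_tfs",
    "tf_de_filter",
]


@dataclass
class BipartiteNetwork:
    """LincRNA and TF node sets with TF->lincRNA binding edges.

    Nodes are the features that carry at least one edge (isolated loci and
    TFs with no assigned peak do not enter the network).
    """

    edges: set[tuple[str, str]] = field(default_factory=set)  # (tf, linc)

    @property
    def tf_nodes(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    @property
    def linc_nodes(self) -> set[str]:
        return {linc for _, linc in self.edges}

    @property
    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for tf, linc in self.edges:
            deg[tf] = deg.get(tf, 0) + 1
            deg[linc] = deg.get(linc, 0) + 1
        return deg

    @property
    def n_nodes(self) -> int:
        return len(self.tf_nodes) + len(self.linc_nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.tf_nodes, bipartite="tf")
        g.add_nodes_from(self.linc_nodes, bipartite="lincRNA")
        g.add_edges_from(self.edges)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["tf", "linc_id"])


def promoter_body_window(linc: GenomicFeature, upstream: int = 2000) -> tuple[int, int]:
    """[TSS - upstream, TES] window in genome coordinates, half-open.

    On '+': [start - upstream, end); on '-': [start, end + upstream);
    clipped at 0.
    """
    if linc.strand == "+":
        return max(0, linc.start - upstream), linc.end
    return linc.start, linc.end + upstream


def assign_edges(
    lincs: Mapping[str, GenomicFeature],
    peaks: Mapping[str, Iterable[GenomicFeature]],
    upstream: int = 2000,
) -> BipartiteNetwork:
    """Build the bipartite network: edge iff a TF peak overlaps the window."""
    edges: set[tuple[str, str]] = set()
    for tf, tf_peaks in peaks.items():
        for linc_id, linc in lincs.items():
            if linc.biotype != "lincRNA":
                continue
            lo, hi = promoter_body_window(linc, upstream)
            for p in tf_peaks:
                if p.chrom == linc.chrom and p.start < hi and lo < p.end:
                    edges.add((tf, linc_id))
                    break
    return BipartiteNetwork(edges=edges)


def key_tfs(network: BipartiteNetwork, min_degree: int = 5) -> set[str]:
    """TFs binding at least ``min_degree`` distinct lincRNAs."""
    deg = network.degree
    return {tf for tf in network.tf_nodes if deg[tf] >= min_degree}


def tf_de_filter(
    tf_de: pd.DataFrame,
    fc_min_log2: float = 0.585,
    p_max: float = 0.01,
) -> set[str]:
    """Differentially expressed TFs: |log2fc| >= 0.585 and p_bh < 0.01."""
    mask = (tf_de["log2fc"].abs() >= fc_min_log2) & (tf_de["p_bh"] < p_max)
    return set(tf_de.index[mask])
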