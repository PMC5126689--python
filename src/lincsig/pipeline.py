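"""End-to-end orchestration of the lincRNA signature pipeline.

Stages communicate only through files under a run directory, so each can
be rerun in isolation: simulate -> annotate -> de-discovery ->
de-replicate -> network -> neighbors -> function -> clinical. A single
:class:`RunConfig` holds every threshold of the analysis with the study's
values as defaults, plus the synthetic-cohort parameters; one global seed
expands into fixed per-stage offsets so stages are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_filter, clinical, discovery_de, function_inference
from . import neighbor_coexpr, replication_de, synthdata, tf_network
from .io_formats import (
    ExpressionMatrix,
    SampleSheet,
    load_config,
    read_bed,
    read_gtf,
    read_gmt,
    read_matrix,
    save_config,
    write_bed,
    write_gmt,
    write_gtf,
    write_matrix,
)

__all__ = ["RunConfig", "run_all", "STAGES"]

# fixed per-stage seed offsets
_OFFSETS = {
    "annotation": 1,
    "fpkm": 2,
    "counts": 3,
    "peaks": 4,
    "survival": 5,
    "permutation": 10,
    "neighbors": 11,
    "function": 12,
}


@dataclass
class RunConfig:
    """All analysis thresholds (study defaults) plus simulation parameters."""

    # annotation filtering
    min_len: int = 200
    coding_cutoff: float = 0.5
    fpkm_call: float = 0.3
    min_calling_rate: float = 0.20
    # discovery DE
    fc_min: float = 2.0
    bh_max: float = 0.01
    n_permutations: int = 1000
    fdr_max: float = 0.01
    lfc_eps: float = 0.1
    # replication
    rep_fc_min_log2: float = 1.0
    rep_fc_relaxed_log2: float = 0.585
    rep_p_max: float = 0.05
    # TF network
    window_upstream: int = 2000
    key_tf_min_degree: int = 5
    tf_fc_min_log2: float = 0.585
    tf_p_max: float = 0.01
    # neighbors
    non_neighbor_gap: int = 1_000_000
    n_random_pairs: int = 1000
    # function inference
    rho_threshold: float = 0.4
    n_shuffles: int = 1000
    enrich_p_max: float = 0.05
    # clinical
    survival_p_max: float = 0.05
    # simulation scenario
    n_linc: int = 40
    n_coding: int = 80
    n_pairs: int = 30
    rep_n_pairs: int = 25
    rep_n_controls: int = 12
    de_fraction: float = 0.2
    de_log2fc: float = 2.5
    sparsity: float = 0.1
    neighbor_rho: float = 0.5
    orientation_mix: dict = field(
        default_factory=lambda: {"H2H": 0.4, "H2T": 0.35, "T2T": 0.25}
    )
    dispersion: float = 0.2
    n_tfs: int = 6
    survival_hr: float = 3.0
    censor_rate: float = 0.2
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _OFFSETS[stage]) % (2**31)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**load_config(path))

    def to_yaml(self, path: str | Path) -> None:
        save_config(dataclasses.asdict(self), path)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    catalog, pair_truth = synthdata.gen_annotation(
        cfg.n_linc, cfg.n_coding, cfg.orientation_mix, seed=cfg.stage_seed("annotation")
    )
    linc_ids = [f for f, g in catalog.items() if g.biotype == "lincRNA"]

    # planted fold changes: alternating up/down on the first de_fraction lincs,
    # echoed at half strength on the partner gene of each DE lincRNA
    n_de = max(1, int(round(cfg.de_fraction * cfg.n_linc)))
    partner = dict(zip(pair_truth["linc_id"], pair_truth["gene_id"]))
    de_log2fc: dict[str, float] = {}
    for i, lid in enumerate(linc_ids[:n_de]):
        lfc = cfg.de_log2fc if i % 2 == 0 else -cfg.de_log2fc
        de_log2fc[lid] = lfc
        de_log2fc[partner[lid]] = 0.5 * lfc
    h2h = pair_truth[pair_truth["orientation"] == "H2H"]
    rho_pairs = list(zip(h2h["linc_id"], h2h["gene_id"]))

    rng = np.random.default_rng(cfg.stage_seed("peaks"))
    tf_edges = []
    for t in range(1, cfg.n_tfs + 1):
        k = int(rng.integers(3, min(9, cfg.n_linc)))
        chosen = rng.choice(linc_ids, size=k, replace=False)
        tf_edges += [(f"TF{t}", lid) for lid in sorted(chosen)]

    truth = synthdata.SimulationTruth(
        de_log2fc=de_log2fc,
        rho_pairs=rho_pairs,
        neighbor_rho=cfg.neighbor_rho,
        tf_edges=tf_edges,
        survival_hr=cfg.survival_hr,
        seed=cfg.seed,
    )

    fpkm, sheet = synthdata.gen_fpkm_cohort(
        catalog, cfg.n_pairs, truth, sparsity=cfg.sparsity, seed=cfg.stage_seed("fpkm")
    )
    counts, csheet = synthdata.gen_count_cohort(
        catalog, cfg.rep_n_pairs, cfg.rep_n_controls, truth,
        dispersion=cfg.dispersion, seed=cfg.stage_seed("counts"),
    )
    peaks = synthdata.gen_peaks(catalog, truth.tf_edges, jitter=0, seed=cfg.stage_seed("peaks"))

    # survival attached to the tumor arm: split on the first up-regulated
    # lincRNA so the planted hazard ratio is recoverable through its split
    surv_linc = next(l for l in linc_ids if de_log2fc.get(l, 0) > 0)
    tumors = sheet.samples_of("tumor")
    grp = clinical.median_split(fpkm.values.loc[surv_linc, tumors])
    survival = synthdata.gen_survival(
        n=len(tumors), survival_hr=cfg.survival_hr, censor_rate=cfg.censor_rate,
        seed=cfg.stage_seed("survival"), group=list(grp), ids=tumors,
    )

    gene_ids = [f for f, g in catalog.items() if g.biotype == "protein_coding"]
    up_partners = {partner[l] for l in linc_ids[:n_de] if de_log2fc.get(l, 0) > 0}
    down_partners = {partner[l] for l in linc_ids[:n_de] if de_log2fc.get(l, 0) < 0}
    grng = np.random.default_rng(cfg.stage_seed("function"))
    sets = {
        "UP_PARTNERS": up_partners or {gene_ids[0]},
        "DOWN_PARTNERS": down_partners or {gene_ids[-1]},
    }
    for i in range(3):
        sets[f"RANDOM_{i + 1}"] = set(grng.choice(gene_ids, size=8, replace=False))

    write_gtf(catalog, outdir / "annotation.gtf")
    pair_truth.to_csv(outdir / "neighbor_truth.tsv", sep="\t", index=False)
    write_matrix(fpkm, outdir / "fpkm.tsv")
    sheet.write(outdir / "fpkm_sheet.tsv")
    write_matrix(counts, outdir / "counts.tsv")
    csheet.write(outdir / "counts_sheet.tsv")
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for tf, plist in peaks.items():
        write_bed(plist, peak_dir / f"{tf}.bed")
    survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    write_gmt(sets, outdir / "sets.gmt")
    truth.to_json(outdir / "truth.json")
    return {
        "n_features": len(catalog),
        "n_linc": len(linc_ids),
        "n_planted_de": n_de,
        "n_tf_edges": len(tf_edges),
    }


def stage_annotate(cfg: RunConfig, outdir: Path) -> dict:
    catalog = read_gtf(outdir / "annotation.gtf")
    fpkm, _ = read_matrix(outdir / "fpkm.tsv", outdir / "fpkm_sheet.tsv", unit="FPKM")
    linc_ids = [f for f in fpkm.features if catalog[f].biotype == "lincRNA"]
    kept, profile = annotation_filter.calling_rate_filter(
        fpkm.subset(features=linc_ids), cfg.fpkm_call, cfg.min_calling_rate
    )
    write_gtf({k: catalog[k] for k in kept}, outdir / "kept_lincs.gtf")
    profile.to_csv(outdir / "calling_profile.tsv", sep="\t", index_label="feature_id")
    return {"n_linc_input": len(linc_ids), "n_linc_kept": len(kept)}


def stage_discovery(cfg: RunConfig, outdir: Path) -> dict:
    kept = list(read_gtf(outdir / "kept_lincs.gtf"))
    fpkm, sheet = read_matrix(outdir / "fpkm.tsv", outdir / "fpkm_sheet.tsv", unit="FPKM")
    sub = fpkm.subset(features=kept)
    table = discovery_de.paired_de_table(sub, sheet, eps=cfg.lfc_eps)
    tumor, normal, _ = discovery_de.paired_arrays(sub, sheet)
    fdr = discovery_de.permutation_fdr(
        tumor, normal, B=cfg.n_permutations, seed=cfg.stage_seed("permutation")
    )
    selected, d_star = discovery_de.select_de(
        table, fdr, fc_min=cfg.fc_min, bh_max=cfg.bh_max, fdr_max=cfg.fdr_max
    )
    table["selected"] = table.index.isin(selected)
    table.to_csv(outdir / "discovery.tsv", sep="\t")
    fdr.to_csv(outdir / "fdr.tsv", sep="\t")
    return {
        "n_tested": len(table),
        "n_selected": len(selected),
        "d_star": d_star,
    }


def stage_replicate(cfg: RunConfig, outdir: Path) -> dict:
    counts, csheet = read_matrix(outdir / "counts.tsv", outdir / "counts_sheet.tsv", unit="counts")
    discovery = pd.read_csv(outdir / "discovery.tsv", sep="\t", index_col=0)
    feats = list(discovery.index[discovery["selected"]]) or list(discovery.index)
    sub = counts.subset(features=feats)
    df = csheet.df

    def run(groups_keep: list[str], tag: str) -> pd.DataFrame:
        samples = list(df.index[df["tissue"].isin(groups_keep)])
        m = sub.subset(samples=samples)
        meta = df.loc[samples]
        res = replication_de.nb_test(
            m, meta["tissue"], covariates=meta[["age", "race", "batch"]],
            fc_min_log2=cfg.rep_fc_min_log2, fdr_max=cfg.rep_p_max,
        )
        res.to_csv(outdir / f"replication_{tag}.tsv", sep="\t")
        return res

    paired = run(["tumor", "adjacent"], "paired")
    tvn = run(["tumor", "normal"], "tvn")
    verdicts = replication_de.replication_filter(
        discovery,
        paired.rename(columns={"p_raw": "p"}),
        tvn.rename(columns={"p_raw": "p"}),
        fc_min_log2=cfg.rep_fc_min_log2,
        p_max=cfg.rep_p_max,
    )
    verdicts.to_csv(outdir / "replication_verdicts.tsv", sep="\t")
    n_rep = int((verdicts["passes_paired"] & verdicts["direction_concordant"]).sum())
    return {"n_candidates": len(feats), "n_replicated": n_rep}


def stage_network(cfg: RunConfig, outdir: Path) -> dict:
    lincs = read_gtf(outdir / "kept_lincs.gtf")
    peak_dir = outdir / "peaks"
    if not peak_dir.is_dir():
        raise FileNotFoundError(f"peaks directory missing: {peak_dir}")
    peaks = {p.stem: read_bed(p, tf_name=p.stem) for p in sorted(peak_dir.glob("*.bed"))}
    net = tf_network.assign_edges(lincs, peaks, upstream=cfg.window_upstream)
    net.to_frame().to_csv(outdir / "edges.tsv", sep="\t", index=False)
    deg = pd.Series(net.degree, name="degree").sort_values(ascending=False)
    deg.to_csv(outdir / "degrees.tsv", sep="\t", index_label="node")
    keys = sorted(tf_network.key_tfs(net, cfg.key_tf_min_degree))
    (outdir / "key_tfs.txt").write_text("\n".join(keys) + "\n")
    return {"n_nodes": net.n_nodes, "n_edges": len(net.edges), "key_tfs": keys}


def stage_neighbors(cfg: RunConfig, outdir: Path) -> dict:
    catalog = read_gtf(outdir / "annotation.gtf")
    kept = list(read_gtf(outdir / "kept_lincs.gtf"))
    discovery = pd.read_csv(outdir / "discovery.tsv", sep="\t", index_col=0)
    fpkm, sheet = read_matrix(outdir / "fpkm.tsv", outdir / "fpkm_sheet.tsv", unit="FPKM")

    lincs = {f: g for f, g in catalog.items() if g.biotype == "lincRNA"}
    genes = {f: g for f, g in catalog.items() if g.biotype == "protein_coding"}
    all_pairs = neighbor_coexpr.neighbor_pairs(lincs, genes)
    pair_df = pd.DataFrame(
        [
            {
                "linc_id": p.linc_id,
                "gene_id": p.gene_id,
                "distance": p.distance,
                "orientation": p.orientation,
            }
            for p in all_pairs
        ]
    ).set_index("linc_id")

    sel = [f for f in discovery.index[discovery["selected"]] if f in pair_df.index]
    if not sel:
        sel = [f for f in kept if f in pair_df.index]
    p0 = float((pair_df["orientation"] == "H2H").mean())
    k = int((pair_df.loc[sel, "orientation"] == "H2H").sum())
    p_enrich = neighbor_coexpr.h2h_enrichment(k, len(sel), min(max(p0, 1e-9), 1 - 1e-9))

    # fold-change concordance of the selected pairs, on observed FPKM
    tumor, normal, feats = discovery_de.paired_arrays(fpkm, sheet)
    lfc = pd.Series(
        [discovery_de.log2_fold_change(tumor[i], normal[i], eps=cfg.lfc_eps) for i in range(len(feats))],
        index=feats,
    )
    linc_fc = lfc.loc[sel].to_numpy()
    gene_fc = lfc.loc[pair_df.loc[sel, "gene_id"]].to_numpy()
    slope, r2, p_fit = neighbor_coexpr.fc_concordance(linc_fc, gene_fc)

    adjacent = sheet.samples_of("adjacent")
    rho_nb = neighbor_coexpr.pairwise_spearman(
        fpkm, list(zip(sel, pair_df.loc[sel, "gene_id"])), samples=adjacent
    )
    rnd = neighbor_coexpr.pair_nulls(
        lincs, genes, "random", n_random=cfg.n_random_pairs,
        seed=cfg.stage_seed("neighbors"),
    )
    rho_rand = neighbor_coexpr.pairwise_spearman(fpkm, rnd, samples=adjacent)

    pair_df["rho_adjacent"] = rho_nb.reset_index(level=1, drop=True).reindex(pair_df.index)
    pair_df.to_csv(outdir / "neighbor_pairs.tsv", sep="\t")
    summary = {
        "n_pairs": len(sel),
        "h2h_count": k,
        "h2h_p0": p0,
        "h2h_binomial_p": p_enrich,
        "fc_slope": slope,
        "fc_r2": r2,
        "fc_p": p_fit,
        "median_rho_neighbors": float(np.nanmedian(rho_nb)),
        "median_rho_random": float(np.nanmedian(rho_rand)),
    }
    (outdir / "neighbor_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def stage_function(cfg: RunConfig, outdir: Path) -> dict:
    catalog = read_gtf(outdir / "annotation.gtf")
    discovery = pd.read_csv(outdir / "discovery.tsv", sep="\t", index_col=0)
    fpkm, _ = read_matrix(outdir / "fpkm.tsv", outdir / "fpkm_sheet.tsv", unit="FPKM")
    sets = read_gmt(outdir / "sets.gmt")

    gene_ids = [f for f in fpkm.features if catalog[f].biotype == "protein_coding"]
    genes = fpkm.subset(features=gene_ids)
    sel = list(discovery.index[discovery["selected"]]) or list(discovery.index[:3])
    lincs = fpkm.subset(features=[f for f in sel if f in fpkm.features])

    _, null_q = function_inference.shuffled_null(
        lincs, genes, n_shuffles=cfg.n_shuffles, seed=cfg.stage_seed("function")
    )
    universe = set(gene_ids)
    rows, enr_frames = [], []
    for lid in lincs.features:
        prof = function_inference.coexpressed_set(
            lid, fpkm.values.loc[lid], genes, threshold=cfg.rho_threshold,
            null_quantiles=null_q,
        )
        rows.append(
            {"linc_id": lid, "threshold": prof.threshold, "n_coexpressed": len(prof.coexpressed),
             "coexpressed": ",".join(sorted(prof.coexpressed))}
        )
        if prof.coexpressed:
            enr = function_inference.hypergeom_enrichment(
                prof.coexpressed, sets, universe, p_max=cfg.enrich_p_max
            )
            enr["linc_id"] = lid
            enr_frames.append(enr.reset_index())
    pd.DataFrame(rows).to_csv(outdir / "coexpressed.tsv", sep="\t", index=False)
    if enr_frames:
        enrichment = pd.concat(enr_frames, ignore_index=True)
    else:
        enrichment = pd.DataFrame(columns=["set", "overlap", "set_size", "p_raw", "p_bh", "significant", "linc_id"])
    enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    return {
        "n_lincs_profiled": len(lincs.features),
        "n_enriched_sets": int(enrichment["significant"].sum()) if len(enrichment) else 0,
        "null_q995": null_q[1],
    }


def stage_clinical(cfg: RunConfig, outdir: Path) -> dict:
    fpkm, sheet = read_matrix(outdir / "fpkm.tsv", outdir / "fpkm_sheet.tsv", unit="FPKM")
    discovery = pd.read_csv(outdir / "discovery.tsv", sep="\t", index_col=0)
    survival = pd.read_csv(outdir / "survival.tsv", sep="\t")

    sel = list(discovery.index[discovery["selected"]]) or list(discovery.index[:5])
    tumors = sheet.samples_of("tumor")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surv_tbl = clinical.survival_screen(
            fpkm.subset(features=sel, samples=tumors), survival, p_max=cfg.survival_p_max
        )
        subtype = clinical.subtype_compare(fpkm.subset(features=sel), sheet)
    surv_tbl.to_csv(outdir / "survival_assoc.tsv", sep="\t")
    subtype.to_csv(outdir / "subtype_flags.tsv", sep="\t")
    n_flag = int(subtype["er_specific"].sum()) if "er_specific" in subtype.columns else 0
    return {
        "n_survival_hits": int(surv_tbl["hit"].sum()),
        "n_er_specific": n_flag,
    }


STAGES = {
    "simulate": stage_simulate,
    "annotate": stage_annotate,
    "de-discovery": stage_discovery,
    "de-replicate": stage_replicate,
    "network": stage_network,
    "neighbors": stage_neighbors,
    "function": stage_function,
    "clinical": stage_clinical,
}


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order; failures are recorded, later stages tried.

    Returns a report dict with per-stage status and counts; the report is
    also written to ``report.json`` under the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": {}, "ok": True}
    for name, fn in STAGES.items():
        try:
            info = fn(cfg, outdir)
            report["stages"][name] = {"status": "ok", **info}
        except Exception as exc:  # keep partial outputs, record the failure
            report["ok"] = False
            report["stages"][name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
            }
            traceback.print_exc()
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
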