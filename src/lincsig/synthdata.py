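"""Synthetic cohorts with known ground truth.

Every generator here emulates one statistical structure the analysis
downstream assumes, with the planted truth recorded so recovery is
checkable:

* an annotation of lincRNA / nearest-coding-gene pairs in chosen
  transcriptional orientations, with decoy coding genes placed far away;
* a paired tumor/adjacent FPKM cohort with log-normal baselines, planted
  log2 fold changes, optional dropout (sparse low-level lincRNA
  expression), and a shared latent factor inducing correlation for
  designated neighbor pairs;
* a negative-binomial count cohort with unequal library sizes and nuisance
  covariates, for the replication stage;
* ChIP-seq style peaks planted inside the promoter-to-gene-body windows of
  chosen lincRNAs;
* exponential survival times with a known hazard ratio between expression
  groups.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical calls are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GenomicFeature, SampleSheet

__all__ = [
    "SimulationTruth",
    "gen_annotation",
    "gen_fpkm_cohort",
    "gen_count_cohort",
    "gen_peaks",
    "gen_survival",
]

# Pair geometry: each lincRNA/partner-gene pair lives in its own block so the
# designated partner is unambiguously the nearest coding gene and everything
# else is > 1 Mb away.
_BLOCK = 3_000_000
_BLOCKS_PER_CHROM = 80
_MAX_CHROMS = 23
_MARGIN = 10_000  # offset of the first feature inside a block


@dataclass
class SimulationTruth:
    """Planted ground truth for one simulated study."""

    de_log2fc: dict[str, float] = field(default_factory=dict)
    rho_pairs: list[tuple[str, str]] = field(default_factory=list)
    neighbor_rho: float = 0.0
    tf_edges: list[tuple[str, str]] = field(default_factory=list)
    survival_hr: float = 1.0
    seed: int = 0

    @property
    def de_features(self) -> set[str]:
        return {f for f, lfc in self.de_log2fc.items() if lfc != 0}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_log2fc": self.de_log2fc,
            "rho_pairs": [list(p) for p in self.rho_pairs],
            "neighbor_rho": self.neighbor_rho,
            "tf_edges": [list(e) for e in self.tf_edges],
            "survival_hr": self.survival_hr,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_log2fc=d["de_log2fc"],
            rho_pairs=[tuple(p) for p in d["rho_pairs"]],
            neighbor_rho=d["neighbor_rho"],
            tf_edges=[tuple(e) for e in d["tf_edges"]],
            survival_hr=d["survival_hr"],
            seed=d["seed"],
        )


def _apportion(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over labeled proportions."""
    labels = list(proportions)
    raw = {k: n * proportions[k] for k in labels}
    counts = {k: int(math.floor(raw[k])) for k in labels}
    short = n - sum(counts.values())
    by_rem = sorted(labels, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def gen_annotation(
    n_linc: int,
    n_coding: int,
    orientation_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    gap_range: tuple[int, int] = (200, 100_000),
) -> tuple[dict[str, GenomicFeature], pd.DataFrame]:
    """Generate a catalog of lincRNA loci each with a designated nearest gene.

    Each lincRNA is placed with one partner coding gene at a log-uniform
    gap (default 200 bp - 100 kb) in the requested orientation; remaining
    coding genes are decoys >= 1 Mb from every lincRNA. Orientation counts
    follow ``orientation_mix`` by largest-remainder apportionment, so a mix
    of 14/37 H2H over 37 lincRNAs yields exactly 14 H2H pairs.

    Returns the catalog and a truth table with columns
    linc_id, gene_id, orientation, gap.
    """
    if orientation_mix is None:
        orientation_mix = {"H2H": 1 / 3, "H2T": 1 / 3, "T2T": 1 / 3}
    if abs(sum(orientation_mix.values()) - 1.0) > 1e-9:
        raise ValueError("orientation_mix proportions must sum to 1")
    if n_linc > n_coding:
        raise ValueError("need n_coding >= n_linc (each lincRNA gets a partner gene)")
    n_blocks = n_linc + (n_coding - n_linc)
    if n_blocks > _BLOCKS_PER_CHROM * _MAX_CHROMS:
        raise ValueError(
            f"chromosome capacity exceeded ({n_blocks} blocks); use fewer features"
        )
    rng = np.random.default_rng(seed)
    counts = _apportion(n_linc, orientation_mix)
    orientations = [k for k in ("H2H", "H2T", "T2T") for _ in range(counts.get(k, 0))]
    rng.shuffle(orientations)

    catalog: dict[str, GenomicFeature] = {}
    rows = []

    def block_coords(i: int) -> tuple[str, int]:
        chrom = f"chr{i // _BLOCKS_PER_CHROM + 1}"
        return chrom, (i % _BLOCKS_PER_CHROM) * _BLOCK

    lo, hi = gap_range
    for i in range(n_linc):
        chrom, base = block_coords(i)
        linc_len = int(round(np.exp(rng.uniform(np.log(500), np.log(5000)))))
        gene_len = int(round(np.exp(rng.uniform(np.log(2000), np.log(50_000)))))
        gap = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        orient = orientations[i]
        linc_start = base + _MARGIN
        linc_end = linc_start + linc_len
        gene_start = linc_end + gap
        gene_end = gene_start + gene_len
        if orient == "H2T":
            linc_strand, gene_strand = "+", "+"
        elif orient == "H2H":
            # divergent: the left feature's 5' end faces the right feature's
            linc_strand, gene_strand = "-", "+"
        else:  # T2T convergent
            linc_strand, gene_strand = "+", "-"
        lid, gid = f"LINC{i + 1:04d}", f"PCG{i + 1:04d}"
        catalog[lid] = GenomicFeature(lid, chrom, linc_start, linc_end, linc_strand, "lincRNA")
        catalog[gid] = GenomicFeature(gid, chrom, gene_start, gene_end, gene_strand, "protein_coding")
        rows.append({"linc_id": lid, "gene_id": gid, "orientation": orient, "gap": gap})

    for j in range(n_coding - n_linc):
        i = n_linc + j
        chrom, base = block_coords(i)
        gene_len = int(round(np.exp(rng.uniform(np.log(2000), np.log(50_000)))))
        start = base + _BLOCK // 2
        did = f"PCGD{j + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        catalog[did] = GenomicFeature(did, chrom, start, start + gene_len, strand, "protein_coding")

    return catalog, pd.DataFrame(rows, columns=["linc_id", "gene_id", "orientation", "gap"])


def _baseline_log_means(
    catalog: Mapping[str, GenomicFeature],
    rng: np.random.Generator,
    linc_log_mean: float,
    linc_log_sd: float,
    coding_log_mean: float,
    coding_log_sd: float,
) -> pd.Series:
    mus = {}
    for fid, feat in catalog.items():
        if feat.biotype == "lincRNA":
            mus[fid] = rng.normal(linc_log_mean, linc_log_sd)
        else:
            mus[fid] = rng.normal(coding_log_mean, coding_log_sd)
    return pd.Series(mus)


def _cohort_sheet(rng: np.random.Generator, n_pairs: int, prefix: str = "") -> pd.DataFrame:
    rows = []
    for i in range(1, n_pairs + 1):
        er = "ER+" if rng.random() < 0.8 else "ER-"
        age = float(np.round(np.clip(rng.normal(55, 12), 28, 90), 1))
        race = "white" if rng.random() < 0.8 else "black"
        batch = f"B{int(rng.integers(1, 3))}"
        common = {"pair_id": f"{prefix}P{i:03d}", "age": age, "race": race, "batch": batch}
        rows.append({"sample_id": f"{prefix}T{i:03d}", "tissue": "tumor", "er_status": er, **common})
        rows.append({"sample_id": f"{prefix}A{i:03d}", "tissue": "adjacent", "er_status": "NA", **common})
    return pd.DataFrame(rows)


def gen_fpkm_cohort(
    catalog: Mapping[str, GenomicFeature],
    n_pairs: int,
    truth: SimulationTruth,
    sparsity: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.8,
    linc_log_mean: float = math.log(2.0),
    linc_log_sd: float = 1.2,
    coding_log_mean: float = math.log(20.0),
    coding_log_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Paired tumor/adjacent FPKM matrix with planted fold changes.

    Adjacent-normal expression is log-normal around a per-feature baseline
    (lincRNAs low, coding genes higher); the tumor sample of each pair
    multiplies the baseline by 2**log2fc for planted features. Pairs listed
    in ``truth.rho_pairs`` share a per-sample latent factor weighted so the
    log-scale correlation between the two features is ~ ``truth.neighbor_rho``.
    Dropout (probability ``sparsity``) zeroes lincRNA entries, emulating
    sparse low-level lincRNA detection.
    """
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    if n_pairs < 3:
        raise ValueError("need n_pairs >= 3 for paired testing downstream")
    rng = np.random.default_rng(seed)
    features = list(catalog)
    mus = _baseline_log_means(
        catalog, rng, linc_log_mean, linc_log_sd, coding_log_mean, coding_log_sd
    )

    sheet_df = _cohort_sheet(rng, n_pairs)
    sample_ids = list(sheet_df["sample_id"])
    n_samples = len(sample_ids)
    is_tumor = (sheet_df["tissue"] == "tumor").to_numpy()

    a = math.sqrt(max(0.0, min(1.0, truth.neighbor_rho)))
    in_pair: dict[str, int] = {}
    for k, (lid, gid) in enumerate(truth.rho_pairs):
        in_pair[lid] = k
        in_pair[gid] = k
    latents = rng.normal(size=(len(truth.rho_pairs), n_samples))

    log_expr = np.empty((len(features), n_samples))
    for r, fid in enumerate(features):
        eps = rng.normal(size=n_samples)
        if fid in in_pair and a > 0:
            z = latents[in_pair[fid]]
            dev = a * z + math.sqrt(1 - a * a) * eps
        else:
            dev = eps
        row = mus[fid] + noise_sd * dev
        lfc = truth.de_log2fc.get(fid, 0.0)
        if lfc:
            row = row + np.where(is_tumor, lfc * math.log(2.0), 0.0)
        log_expr[r] = row

    fpkm = np.exp(log_expr)
    if sparsity > 0:
        linc_rows = np.array([catalog[f].biotype == "lincRNA" for f in features])
        drop = rng.random(fpkm.shape) < sparsity
        fpkm[linc_rows[:, None] & drop] = 0.0

    values = pd.DataFrame(fpkm, index=features, columns=sample_ids)
    return ExpressionMatrix(values, unit="FPKM"), SampleSheet(sheet_df)


def gen_count_cohort(
    catalog: Mapping[str, GenomicFeature],
    n_pairs: int,
    n_controls: int,
    truth: SimulationTruth,
    dispersion: float = 0.2,
    libsize_range: tuple[float, float] = (5e5, 2e6),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Replication-stage count matrix: NB counts with unequal library sizes.

    counts ~ NB(mean = libsize x relative abundance x 2**(log2fc if tumor),
    var = mu + dispersion * mu^2), drawn gamma-Poisson. Batch, age and race
    labels are assigned at random; controls are healthy-normal tissue.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    features = list(catalog)

    sheet_df = _cohort_sheet(rng, n_pairs, prefix="R")
    ctrl_rows = []
    for i in range(1, n_controls + 1):
        ctrl_rows.append(
            {
                "sample_id": f"RN{i:03d}",
                "tissue": "normal",
                "er_status": "NA",
                "pair_id": "",
                "age": float(np.round(np.clip(rng.normal(52, 11), 28, 90), 1)),
                "race": "white" if rng.random() < 0.8 else "black",
                "batch": f"B{int(rng.integers(1, 3))}",
            }
        )
    sheet_df = pd.concat([sheet_df, pd.DataFrame(ctrl_rows)], ignore_index=True)
    sample_ids = list(sheet_df["sample_id"])
    is_tumor = (sheet_df["tissue"] == "tumor").to_numpy()

    # relative abundances from a log-normal, normalized to sum 1
    w = np.exp(rng.normal(0.0, 1.5, size=len(features)))
    rel = w / w.sum()
    libsize = rng.uniform(*libsize_range, size=len(sample_ids))

    lfc = np.array([truth.de_log2fc.get(f, 0.0) for f in features])
    mu = libsize[None, :] * rel[:, None] * np.power(2.0, lfc[:, None] * is_tumor[None, :])
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    values = pd.DataFrame(counts, index=features, columns=sample_ids)
    return ExpressionMatrix(values, unit="counts"), SampleSheet(sheet_df)


def gen_peaks(
    catalog: Mapping[str, GenomicFeature],
    tf_edges: Sequence[tuple[str, str]],
    jitter: int = 0,
    seed: int = 0,
    peak_halfwidth: int = 100,
    n_decoys: int = 2,
) -> dict[str, list[GenomicFeature]]:
    """Plant one ChIP-seq peak per (TF, lincRNA) edge, plus far decoy peaks.

    Each planted edge yields a peak of width ``2*peak_halfwidth`` whose
    midpoint sits 1 kb upstream of the lincRNA TSS (inside the promoter
    window), displaced by a uniform integer in [-jitter, jitter]. Each TF
    additionally gets ``n_decoys`` peaks >= 10 kb away from every lincRNA
    window.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    peaks: dict[str, list[GenomicFeature]] = {}
    lincs = [f for f in catalog.values() if f.biotype == "lincRNA"]
    counter = 0
    for tf, lid in tf_edges:
        feat = catalog[lid]
        center = feat.start - 1000 if feat.strand == "+" else feat.end - 1 + 1000
        if jitter > 0:
            center += int(rng.integers(-jitter, jitter + 1))
        counter += 1
        peaks.setdefault(tf, []).append(
            GenomicFeature(
                f"{tf}_peak{counter}", feat.chrom,
                center - peak_halfwidth, center + peak_halfwidth,
                "+", "other", name=tf,
            )
        )
    for tf in list(peaks):
        for _ in range(n_decoys):
            feat = lincs[int(rng.integers(len(lincs)))]
            # 50 kb upstream of the block's features: far outside every window
            center = max(peak_halfwidth, feat.start - 50_000)
            counter += 1
            peaks[tf].append(
                GenomicFeature(
                    f"{tf}_peak{counter}", feat.chrom,
                    center - peak_halfwidth, center + peak_halfwidth,
                    "+", "other", name=tf,
                )
            )
    return peaks


def gen_survival(
    n: int,
    survival_hr: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_rate: float = 0.1,
    group: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exponential survival with a planted hazard ratio between groups.

    Subjects alternate between a 'low' and a 'high' expression group
    unless an explicit ``group`` vector is supplied; the 'high' group's
    event rate is ``baseline_rate * survival_hr``. Censoring is
    independent exponential, calibrated per group so the expected censored
    fraction equals ``censor_rate``. ``ids`` overrides the generated
    subject identifiers (e.g. to key survival to existing tumor samples).
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    if survival_hr <= 0:
        raise ValueError("survival_hr must be > 0")
    rng = np.random.default_rng(seed)
    if group is None:
        group = np.where(np.arange(n) % 2 == 0, "low", "high")
    else:
        group = np.asarray(group)
        if group.size != n:
            raise ValueError("group vector length must equal n")
    rate = np.where(group == "high", baseline_rate * survival_hr, baseline_rate)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        c_rate = rate * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    return pd.DataFrame(
        {
            "subject_id": list(ids) if ids is not None else [f"S{i + 1:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "group": group,
        }
    )
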