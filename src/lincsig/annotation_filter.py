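"""Build the analyzable lincRNA catalog from assembled transcripts.

Filter cascade: (1) keep transcripts whose locus overlaps a known lincRNA
by >= 1 bp (strand-agnostic); (2) drop transcripts shorter than 200 nt;
(3) drop transcripts whose noncoding-potential score is below 0.5 (scores
near 1 indicate noncoding; a missing score keeps the transcript, with a
warning). Isoforms mapping to one lincRNA locus are collapsed by the
arithmetic mean of their coverage and per-sample expression. Finally a
calling-rate filter keeps loci detected (FPKM >= 0.3) in at least 20% of
samples. All comparisons are inclusive at the quoted boundaries: length
200 is kept, score exactly 0.5 is kept, calling rate exactly 20% is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GenomicFeature

__all__ = [
    "TranscriptRecord",
    "filter_transcripts",
    "collapse_isoforms",
    "calling_rate_filter",
]


@dataclass
class TranscriptRecord:
    """One assembled transcript with its QC attributes.

    ``coding_score`` is a noncoding-potential score in [0, 1] (higher =
    more confidently noncoding); ``fpkm`` is the per-sample expression
    vector, ``coverage`` a scalar read-coverage summary.
    """

    transcript_id: str
    parent_linc_id: str
    locus: GenomicFeature
    length: int
    coding_score: float | None = None
    coverage: float = 0.0
    fpkm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.transcript_id}: length must be >= 1")
        if self.coding_score is not None and not (0 <= self.coding_score <= 1):
            raise ValueError(f"{self.transcript_id}: coding_score must be in [0, 1]")


def filter_transcripts(
    records: Sequence[TranscriptRecord],
    known: Mapping[str, GenomicFeature],
    min_len: int = 200,
    coding_cutoff: float = 0.5,
) -> tuple[list[TranscriptRecord], dict[str, int]]:
    """Apply the three transcript-level predicates; returns kept + tallies.

    Kept iff overlaps a known lincRNA locus (>= 1 bp), length >= min_len,
    and score >= coding_cutoff (missing score kept with warning). The three
    predicates are independent, so the kept set is order-invariant.
    """
    if not known:
        raise ValueError("known lincRNA catalog is empty")
    known_lincs = [f for f in known.values() if f.biotype == "lincRNA"] or list(known.values())
    kept: list[TranscriptRecord] = []
    tallies = {"no_overlap": 0, "too_short": 0, "coding": 0, "missing_score": 0}
    for rec in records:
        overlap_ok = any(rec.locus.overlaps(f) for f in known_lincs)
        length_ok = rec.length >= min_len
        if rec.coding_score is None:
            tallies["missing_score"] += 1
            score_ok = True
        else:
            score_ok = rec.coding_score >= coding_cutoff
        if not overlap_ok:
            tallies["no_overlap"] += 1
        if not length_ok:
            tallies["too_short"] += 1
        if not score_ok:
            tallies["coding"] += 1
        if overlap_ok and length_ok and score_ok:
            kept.append(rec)
    if tallies["missing_score"]:
        warnings.warn(
            f"{tallies['missing_score']} transcript(s) kept without a coding-potential score"
        )
    return kept, tallies


def collapse_isoforms(
    records: Iterable[TranscriptRecord],
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Collapse isoforms to one row per lincRNA locus by arithmetic mean.

    Returns a DataFrame indexed by parent_linc_id with a 'coverage' column
    and one column per sample holding the mean FPKM over isoforms.
    """
    groups: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        groups.setdefault(rec.parent_linc_id, []).append(rec)
    rows = {}
    for linc_id, grp in groups.items():
        row = {"coverage": float(np.mean([r.coverage for r in grp]))}
        if grp[0].fpkm is not None:
            mean_fpkm = np.mean([np.asarray(r.fpkm, dtype=float) for r in grp], axis=0)
            names = sample_ids or [f"s{i + 1}" for i in range(mean_fpkm.size)]
            row.update(dict(zip(names, mean_fpkm)))
        rows[linc_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def calling_rate_filter(
    matrix: ExpressionMatrix,
    fpkm_call: float = 0.3,
    min_rate: float = 0.20,
) -> tuple[list[str], pd.DataFrame]:
    """Keep features detected (FPKM >= fpkm_call) in >= min_rate of samples.

    Returns (kept feature ids, per-feature calling profile with columns
    n_called, n_samples, calling_rate). Both thresholds are inclusive.
    """
    if matrix.unit != "FPKM":
        raise ValueError("calling-rate filter applies to FPKM matrices")
    n_samples = len(matrix.samples)
    if n_samples == 0:
        raise ValueError("matrix has no samples")
    called = (matrix.values.to_numpy() >= fpkm_call).sum(axis=1)
    rate = called / n_samples
    profile = pd.DataFrame(
        {
            "n_called": called,
            "n_samples": n_samples,
            "calling_rate": rate,
        },
        index=matrix.features,
    )
    kept = [f for f, r in zip(matrix.features, rate) if r >= min_rate]
    return kept, profile
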