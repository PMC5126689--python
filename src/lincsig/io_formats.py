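"""Readers and writers for the formats the pipeline consumes.

Internal coordinate convention is 0-based half-open everywhere. GTF
(1-based, end-inclusive) is converted on read and write; BED is already
half-open and passes through untouched.

Genomic annotation is represented at gene level: a :class:`GenomicFeature`
is the union span of the transcripts annotated under one gene id (minimum
start, maximum end), which is the unit at which loci are filtered, scanned
for ChIP-seq peaks and paired with neighbors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenomicFeature",
    "SampleSheet",
    "ExpressionMatrix",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_sample_sheet",
    "read_gmt",
    "write_gmt",
    "load_config",
    "save_config",
]

VALID_STRANDS = {"+", "-"}
VALID_TISSUES = {"tumor", "adjacent", "normal"}


@dataclass(frozen=True)
class GenomicFeature:
    """A stranded genomic interval, 0-based half-open.

    ``name`` is a free annotation slot: the gene symbol for annotation
    records, the TF name for ChIP-seq peaks.
    """

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "other"
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.feature_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: end-1 on '+', start on '-'."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicFeature") -> bool:
        """Strand-agnostic interval intersection by >= 1 bp."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicFeature") -> int | None:
        """Boundary gap in bp; 0 if overlapping; None on different chromosomes."""
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


class SampleSheet:
    """Sample metadata table: tissue labels, tumor/adjacent pairing, covariates.

    Wraps a DataFrame indexed by ``sample_id`` with a ``tissue`` column in
    {tumor, adjacent, normal} and optional ``pair_id``, ``er_status``,
    ``batch``, ``age``, ``race`` columns. Each pair_id must label exactly
    one tumor and one adjacent sample.
    """

    REQUIRED = ["sample_id", "tissue"]
    OPTIONAL = ["pair_id", "er_status", "batch", "age", "race"]

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_ids: {dups}")
        if "tissue" not in df.columns:
            raise ValueError("sample sheet requires a 'tissue' column")
        bad = set(df["tissue"]) - VALID_TISSUES
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        if "pair_id" in df.columns:
            paired = df[df["pair_id"].notna() & (df["pair_id"] != "")]
            for pid, grp in paired.groupby("pair_id"):
                tissues = sorted(grp["tissue"])
                if tissues != ["adjacent", "tumor"]:
                    raise ValueError(
                        f"pair_id {pid!r} must label exactly one tumor and one "
                        f"adjacent sample, got {tissues}"
                    )
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.df.index[self.df["tissue"] == tissue])

    def pairs(self) -> pd.DataFrame:
        """One row per pair: columns pair_id, tumor, adjacent."""
        if "pair_id" not in self.df.columns:
            return pd.DataFrame(columns=["pair_id", "tumor", "adjacent"])
        paired = self.df[self.df["pair_id"].notna() & (self.df["pair_id"] != "")]
        rows = []
        for pid, grp in paired.groupby("pair_id", sort=True):
            rows.append(
                {
                    "pair_id": pid,
                    "tumor": grp.index[grp["tissue"] == "tumor"][0],
                    "adjacent": grp.index[grp["tissue"] == "adjacent"][0],
                }
            )
        return pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.df)

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="sample_id")


class ExpressionMatrix:
    """Feature x sample expression values, FPKM or integer counts."""

    def __init__(self, values: pd.DataFrame, unit: str):
        if unit not in {"FPKM", "counts"}:
            raise ValueError(f"unit must be 'FPKM' or 'counts', got {unit!r}")
        arr = values.to_numpy()
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative values")
        if unit == "counts":
            if not np.allclose(arr, np.round(arr), atol=0, rtol=0):
                raise ValueError("counts matrix must contain integers only")
            values = values.astype(np.int64)
        self.values = values
        self.unit = unit

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        v = self.values
        if features is not None:
            v = v.loc[list(features)]
        if samples is not None:
            v = v[list(samples)]
        return ExpressionMatrix(v, self.unit)


# ---------------------------------------------------------------------------
# GTF

_GTF_COLUMNS = [
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
]
_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def read_gtf(
    path: str | Path,
    biotype_filter: set[str] | None = None,
    feature_types: tuple[str, ...] = ("gene", "transcript", "exon"),
) -> dict[str, GenomicFeature]:
    """Read a GENCODE-dialect GTF into a gene-level catalog.

    Transcript and exon rows are grouped under their ``gene_id``; each gene
    becomes one :class:`GenomicFeature` spanning the union of its records
    (minimum start to maximum end), with coordinates shifted from GTF
    1-based inclusive to internal 0-based half-open.

    Records without a usable strand are rejected; the rejection count is
    emitted as a single warning. A malformed line raises ``ValueError``
    naming the line number.
    """
    biotypes = {"lincRNA", "protein_coding"}
    spans: dict[str, dict] = {}
    n_rejected = 0
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}: malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(parts)}"
                )
            seqname, _source, feat, start_s, end_s, _score, strand, _frame, attr = parts
            if feat not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GTF line {lineno}: {exc}") from None
            if strand not in VALID_STRANDS:
                n_rejected += 1
                continue
            attrs = _parse_attributes(attr)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}: malformed GTF line {lineno}: missing gene_id")
            biotype = attrs.get("gene_type", attrs.get("gene_biotype", "other"))
            if biotype not in biotypes:
                biotype = "other"
            n_records += 1
            start0 = start1 - 1  # GTF is 1-based inclusive
            rec = spans.setdefault(
                gene_id,
                {
                    "chrom": seqname,
                    "start": start0,
                    "end": end1,
                    "strand": strand,
                    "biotype": biotype,
                    "name": attrs.get("gene_name"),
                },
            )
            rec["start"] = min(rec["start"], start0)
            rec["end"] = max(rec["end"], end1)
            if biotype != "other":
                rec["biotype"] = biotype
    if n_records == 0:
        warnings.warn(f"{path}: no usable records, empty catalog")
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} record(s) without strand")
    catalog = {
        gid: GenomicFeature(feature_id=gid, **rec)
        for gid, rec in spans.items()
        if biotype_filter is None or rec["biotype"] in biotype_filter
    }
    return catalog


def write_gtf(catalog: Mapping[str, GenomicFeature] | Iterable[GenomicFeature], path: str | Path) -> None:
    """Write gene-level records back to GTF (1-based inclusive coordinates)."""
    feats = catalog.values() if isinstance(catalog, Mapping) else catalog
    with open(path, "w") as fh:
        for f in feats:
            attrs = f'gene_id "{f.feature_id}"; gene_type "{f.biotype}";'
            if f.name:
                attrs += f' gene_name "{f.name}";'
            fh.write(
                "\t".join(
                    [
                        f.chrom, "lincsig", "gene",
                        str(f.start + 1), str(f.end),
                        ".", f.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, tf_name: str | None = None) -> list[GenomicFeature]:
    """Read BED3+ peaks (already 0-based half-open; no coordinate shift).

    Rows with start >= end are rejected and counted in a single warning.
    Peaks carry ``tf_name`` in their ``name`` slot.
    """
    peaks: list[GenomicFeature] = []
    n_rejected = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                n_rejected += 1
                continue
            peaks.append(
                GenomicFeature(
                    feature_id=f"{tf_name or 'peak'}_{i}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+",  # peaks are unstranded; placeholder
                    biotype="other",
                    name=tf_name,
                )
            )
    if n_rejected:
        warnings.warn(f"{path}: rejected {n_rejected} record(s) with start >= end")
    return peaks


def write_bed(peaks: Iterable[GenomicFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or p.feature_id}\n")


# ---------------------------------------------------------------------------
# Expression matrices

def read_matrix(
    path: str | Path,
    sheet_path: str | Path,
    unit: str = "FPKM",
) -> tuple[ExpressionMatrix, SampleSheet]:
    """Read a TSV matrix (feature_id first column, sample header) plus sheet.

    Every matrix column must appear in the sheet; matrix columns and sheet
    rows are aligned on return.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    sheet = read_sample_sheet(sheet_path)
    missing = [s for s in values.columns if s not in sheet.df.index]
    if missing:
        raise ValueError(f"samples in matrix absent from sample sheet: {missing}")
    sheet = SampleSheet(sheet.df.loc[list(values.columns)])
    return ExpressionMatrix(values, unit=unit), sheet


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    if matrix.unit == "counts":
        matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    else:
        matrix.values.to_csv(
            path, sep="\t", index_label="feature_id", float_format="%.6g"
        )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "batch": str})
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT collection: name, description, member ids per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# Run configuration

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
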