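"""Readers and writers for the table formats the pipeline touches.

Conventions enforced here, once, for the whole package:

* variants are 1-based inclusive (VCF convention);
* bins and segments are 0-based half-open (BED / CNVKit convention);
* bin indices are anchored at position 0 of each contig.

Variant tables are plain :class:`pandas.DataFrame` objects with the columns
in :data:`VARIANT_COLUMNS`; bin and segment tables follow the CNVKit
``.cnr`` / ``.cns`` TSV dialect (``chromosome  start  end  log2`` plus
optional ``depth`` and ``weight``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a variant table; optional annotation columns follow.
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_count", "depth", "vaf"]

#: Optional population-frequency / annotation columns.
VARIANT_OPTIONAL_COLUMNS = [
    "af_gnomad_exome",
    "af_gnomad_genome",
    "af_1000g",
    "gene",
    "effect",
    "sample_id",
    "participant_id",
]

BIN_COLUMNS = ["chromosome", "start", "end", "log2"]

MANIFEST_COLUMNS = ["participant_id", "sample_id", "specimen", "timepoint_days"]

SPECIMEN_TYPES = frozenset({"cfDNA", "sphDNA", "FFPE"})


class FormatError(ValueError):
    """Malformed input table (bad row, overlap, missing column...)."""


# ---------------------------------------------------------------------------
# coordinate conversion — centralized so the two conventions never mix
# ---------------------------------------------------------------------------

def bin_index(pos: int | np.ndarray, bin_size: int) -> int | np.ndarray:
    """Index of the 0-based half-open bin containing a 1-based position."""
    return (np.asarray(pos) - 1) // bin_size


def bin_start(index: int, bin_size: int) -> int:
    """0-based start of bin *index*."""
    return index * bin_size


def variant_key(chrom, pos, ref, alt) -> str:
    """Canonical ``chrom:pos:ref:alt`` key used across modules."""
    return f"{chrom}:{pos}:{ref}:{alt}"


def strip_chr(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def _finalize_variants(df: pd.DataFrame, path) -> pd.DataFrame:
    """Compute VAF, drop depth-0 records, validate ranges."""
    n_zero = int((df["depth"] <= 0).sum())
    if n_zero:
        logger.warning("%s: dropped %d record(s) with depth 0", path, n_zero)
        df = df[df["depth"] > 0].copy()
    if "vaf" not in df.columns or df["vaf"].isna().all():
        df["vaf"] = df["alt_count"] / df["depth"]
    else:
        df["vaf"] = df["vaf"].fillna(df["alt_count"] / df["depth"])
    bad = df[(df["vaf"] < 0) | (df["vaf"] > 1) | (df["pos"] < 1)]
    if len(bad):
        raise FormatError(
            f"{path}: invalid record at line(s) {list(bad.index[:5])} "
            "(VAF outside [0,1] or pos < 1)"
        )
    df.attrs["n_dropped_depth0"] = n_zero
    return df.reset_index(drop=True)


def read_variants(
    path: str | Path,
    dialect: str = "TSV",
    sample_id: str | None = None,
    participant_id: str | None = None,
) -> pd.DataFrame:
    """Read a per-sample variant table.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"TSV"`` — flat table with columns ``chrom pos ref alt alt_count
        depth`` plus any optional annotation columns; or ``"VCF"`` — a VCF
        4.x file with per-sample ``AD`` (or ``AF`` + ``DP``) FORMAT fields.
    sample_id, participant_id
        Override / supply sample identity (TSV files may carry their own
        ``sample_id`` column).

    Returns
    -------
    DataFrame with :data:`VARIANT_COLUMNS`; 1-based inclusive positions;
    VAF computed as alt_count/depth when absent.  Depth-0 records are
    dropped and counted in ``df.attrs["n_dropped_depth0"]``.
    """
    dialect = dialect.upper()
    if dialect == "TSV":
        df = _read_variants_tsv(path)
    elif dialect == "VCF":
        df = _read_variants_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if sample_id is not None:
        df["sample_id"] = sample_id
    if participant_id is not None:
        df["participant_id"] = participant_id
    return df


def _read_variants_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in ("chrom", "pos", "ref", "alt", "alt_count", "depth") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("pos", "alt_count", "depth"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header + 1-based
            raise FormatError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced.astype(int)
    return _finalize_variants(df, path)


def _read_variants_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF  # deferred: only needed for the VCF dialect

    vcf = VCF(str(path))
    rows = []
    info_map = {
        "af_gnomad_exome": ("GNOMAD_EXOME_AF", "AF_gnomad_exome"),
        "af_gnomad_genome": ("GNOMAD_GENOME_AF", "AF_gnomad_genome"),
        "af_1000g": ("KG_AF", "AF_1000G"),
    }
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT):
            depth = alt_count = None
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is not None:
                ad0 = ad[0]
                alt_count = int(ad0[1 + ai])
                depth = int(sum(x for x in ad0 if x >= 0))
            else:
                dp = rec.format("DP")
                af = rec.format("AF")
                if dp is None or af is None:
                    raise FormatError(
                        f"{path}: record {rec.CHROM}:{rec.POS} lacks AD and AF+DP"
                    )
                depth = int(dp[0][0])
                alt_count = int(round(float(af[0][ai]) * depth))
            row = {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "alt_count": alt_count,
                "depth": depth,
                "gene": rec.INFO.get("GENE"),
                "effect": rec.INFO.get("EFFECT"),
            }
            for col, keys in info_map.items():
                val = None
                for key in keys:
                    val = rec.INFO.get(key)
                    if val is not None:
                        break
                row[col] = float(val) if val is not None else np.nan
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "alt_count", "depth"])
    return _finalize_variants(df, path)


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as TSV (round-trips with :func:`read_variants`)."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNVKit-dialect bins and segments
# ---------------------------------------------------------------------------

def _read_cnvkit_table(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: start >= end in {kind} table")
    sorted_df = df.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)
    if not df.reset_index(drop=True).equals(sorted_df):
        logger.warning("%s: %s rows unsorted; sorting by (chromosome, start)", path, kind)
    if kind == "segment":
        for _, grp in sorted_df.groupby("chromosome", sort=False):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise FormatError(f"{path}: overlapping segments on {grp['chromosome'].iloc[0]}")
    return sorted_df


def read_bins(path: str | Path) -> pd.DataFrame:
    """Read a CNVKit ``.cnr`` per-bin log2 table (0-based half-open)."""
    return _read_cnvkit_table(path, "bin")


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a CNVKit ``.cns`` segment table; overlapping segments are an error."""
    return _read_cnvkit_table(path, "segment")


def write_cnvkit_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED and manifest
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into (chromosome, start, end[, name]) columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs >= 3 columns")
    cols = ["chromosome", "start", "end"] + [f"name" if i == 3 else f"col{i}" for i in range(3, df.shape[1])]
    df.columns = cols[: df.shape[1]]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df.sort_values(["chromosome", "start"], kind="mergesort").reset_index(drop=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest.

    Columns: participant_id, sample_id, specimen ∈ {cfDNA, sphDNA, FFPE},
    timepoint_days (days from each participant's first sample, >= 0),
    optional purity_hint in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    return validate_manifest(df)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"manifest: duplicate sample_id {dup!r}")
    bad_spec = set(df["specimen"]) - SPECIMEN_TYPES
    if bad_spec:
        raise FormatError(f"manifest: unknown specimen type(s) {sorted(bad_spec)}")
    if (df["timepoint_days"].astype(int) < 0).any():
        raise FormatError("manifest: negative timepoint_days")
    if "purity_hint" in df.columns:
        hints = df["purity_hint"].dropna()
        if ((hints < 0) | (hints > 1)).any():
            raise FormatError("manifest: purity_hint outside [0, 1]")
    return df.reset_index(drop=True)


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(df).to_csv(path, sep="\t", index=False)


def initial_samples(manifest: pd.DataFrame) -> pd.DataFrame:
    """Each participant's first sample (minimum timepoint; ties → manifest order)."""
    idx = manifest.groupby("participant_id", sort=False)["timepoint_days"].idxmin()
    return manifest.loc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# PyClone-VI export
# ---------------------------------------------------------------------------

def write_pyclone_input(
    variants: pd.DataFrame,
    purities: Mapping[str, float],
    path: str | Path,
) -> pd.DataFrame:
    """Export clonal-analysis rows in PyClone-VI input format.

    ``variants`` must carry ``sample_id``, ``alt_count``, ``depth`` and an
    integer tumour copy number column ``cn_tumour`` per row.  The normal
    copy number is always 2 (diploid).  Allele-specific copy numbers cannot
    be phased from panel data, so major_cn = max(cn − 1, 1) and
    minor_cn = cn − major_cn for cn >= 1 (a documented simplification).

    Returns the exported table; also written tab-separated to *path*.
    """
    required = {"chrom", "pos", "ref", "alt", "sample_id", "alt_count", "depth", "cn_tumour"}
    missing = required - set(variants.columns)
    if missing:
        raise FormatError(f"pyclone export: missing column(s) {sorted(missing)}")
    missing_purity = set(variants["sample_id"]) - set(purities)
    if missing_purity:
        raise FormatError(f"pyclone export: no purity for sample(s) {sorted(missing_purity)}")
    cn = variants["cn_tumour"].astype(int)
    if (cn < 1).any():
        raise FormatError("pyclone export: rows with cn_tumour < 1 must be excluded upstream")
    major = np.maximum(cn - 1, 1)
    out = pd.DataFrame(
        {
            "mutation_id": [
                variant_key(c, p, r, a)
                for c, p, r, a in zip(variants["chrom"], variants["pos"], variants["ref"], variants["alt"])
            ],
            "sample_id": variants["sample_id"].values,
            "ref_counts": (variants["depth"] - variants["alt_count"]).astype(int).values,
            "alt_counts": variants["alt_count"].astype(int).values,
            "normal_cn": 2,
            "major_cn": major.values,
            "minor_cn": (cn - major).values,
            "tumour_content": [float(purities[s]) for s in variants["sample_id"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)
    return out
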