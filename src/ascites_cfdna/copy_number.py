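"""Purity-rescaled copy number, LGA counting and profile comparison.

A targeted-panel log2 copy ratio mixes tumour and normal DNA.  With
tumour fraction ``t`` and tumour copy number ``CN`` the expected ratio
against a diploid reference is (t*CN + 2(1-t)) / 2, so the observed
ratio inverts to

    cn_est = max(0, (2 * 2**log2r - 2(1-t)) / t).

Large-scale genomic alterations (LGAs) — copy-number changes between
adjacent > 10 Mb segments on the same chromosome — are a shallow-
sequencing surrogate for homologous-recombination deficiency; counts of
20 or more suggest HRD.

Segments whose read depth is an extreme high outlier (modified Z-score
above 3.5 over the sample's segments) are unreliable — typically probe
pile-ups — and are repaired to the mean of their flanking segments'
copy number before LGA counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MB = 1_000_000
MODIFIED_Z_SCALE = 0.6745  # Iglewicz–Hoaglin constant


@dataclass
class LGAResult:
    sample_id: str
    lga_count: int
    breakpoints: list  # (contig, position) per counted boundary

    def __post_init__(self):
        assert self.lga_count == len(self.breakpoints)


def cn_from_log2(log2r, t: float):
    """Purity-rescaled copy-number estimate from a log2 copy ratio.

    Inverts the mixture model ratio = (t*CN + 2(1-t))/2; clipped at 0.
    """
    if not 0 < t <= 1:
        raise ValueError("purity must be in (0, 1]")
    log2r = np.asarray(log2r, dtype=float)
    cn = (2.0 * np.exp2(log2r) - 2.0 * (1.0 - t)) / t
    cn = np.maximum(cn, 0.0)
    return float(cn) if cn.ndim == 0 else cn


def round_half_up(x):
    """Half-up rounding (2.5 -> 3), unlike numpy's banker's rounding."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def modified_zscore(values: np.ndarray) -> np.ndarray:
    """Iglewicz–Hoaglin modified Z: 0.6745 * (x - median) / MAD.

    When the MAD degenerates to 0 (more than half the values tied) the
    recommended fallback (x - median) / (1.253314 * meanAD) is used;
    if the mean absolute deviation is also 0 every score is 0.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    abs_dev = np.abs(values - med)
    mad = np.median(abs_dev)
    if mad > 0:
        return MODIFIED_Z_SCALE * (values - med) / mad
    mean_ad = abs_dev.mean()
    if mean_ad == 0:
        return np.zeros_like(values)
    return (values - med) / (1.253314 * mean_ad)


def repair_unreliable_segments(segments: pd.DataFrame, z_cutoff: float = 3.5) -> pd.DataFrame:
    """Repair segments whose read depth is an extreme high outlier.

    Modified Z-scores are computed over the sample's segments from the
    ``depth`` column; segments with Z > ``z_cutoff`` (one-sided, high)
    get ``cn_est`` replaced by the mean of the flanking segments'
    estimates (single flank at contig ends) and are flagged
    ``unreliable``.  ``cn_int`` is re-derived by half-up rounding.
    MAD of 0 flags nothing (warned).
    """
    segments = segments.reset_index(drop=True).copy()
    if "depth" not in segments.columns:
        raise ValueError("segments need a 'depth' column for reliability repair")
    z = modified_zscore(segments["depth"].to_numpy())
    if not z.any() and len(segments) > 1 and segments["depth"].nunique() > 1:
        logger.warning("segment depth spread degenerate; no segment flagged unreliable")
    segments["unreliable"] = z > z_cutoff
    cn = segments["cn_est"].to_numpy(dtype=float).copy()
    for i in np.flatnonzero(segments["unreliable"].to_numpy()):
        contig = segments.at[i, "chromosome"]
        neighbours = []
        if i - 1 >= 0 and segments.at[i - 1, "chromosome"] == contig and not segments.at[i - 1, "unreliable"]:
            neighbours.append(cn[i - 1])
        if i + 1 < len(segments) and segments.at[i + 1, "chromosome"] == contig and not segments.at[i + 1, "unreliable"]:
            neighbours.append(segments.at[i + 1, "cn_est"])
        if neighbours:
            cn[i] = float(np.mean(neighbours))
    segments["cn_est"] = cn
    segments["cn_int"] = round_half_up(cn)
    return segments


def annotate_copy_number(segments: pd.DataFrame, t: float) -> pd.DataFrame:
    """Add cn_est / cn_int columns to a segment (or bin) table."""
    out = segments.copy()
    out["cn_est"] = cn_from_log2(out["log2"].to_numpy(), t)
    out["cn_int"] = round_half_up(out["cn_est"])
    return out


def count_lga(segments: pd.DataFrame, min_len: int = 10 * MB,
              sample_id: str = "", per_segment: bool = False) -> LGAResult:
    """Count large-scale genomic alterations.

    Per chromosome, take the ordered subsequence of segments strictly
    longer than ``min_len`` (non-qualifying interveners are skipped);
    each boundary between consecutive members with differing integer
    copy number counts one LGA.  With ``per_segment=True`` the count is
    instead the number of qualifying segments that differ from their
    preceding qualifying neighbour (identical for alternating profiles;
    exposed because the counting unit is ambiguous in the field).
    """
    breakpoints = []
    for contig, grp in segments.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        qual = grp[(grp["end"] - grp["start"]) > min_len]
        cns = qual["cn_int"].to_numpy()
        starts = qual["start"].to_numpy()
        if per_segment:
            # count each qualifying segment that differs from at least one
            # qualifying neighbour, once
            involved = np.zeros(len(qual), dtype=bool)
            for j in range(1, len(qual)):
                if cns[j] != cns[j - 1]:
                    involved[j] = involved[j - 1] = True
            for j in np.flatnonzero(involved):
                breakpoints.append((contig, int(starts[j])))
        else:
            for j in range(1, len(qual)):
                if cns[j] != cns[j - 1]:
                    breakpoints.append((contig, int(starts[j])))
    return LGAResult(sample_id=sample_id, lga_count=len(breakpoints), breakpoints=breakpoints)


def call_gene_amplifications(segments: pd.DataFrame, genes: pd.DataFrame,
                             fold_threshold: float = 2.0) -> pd.DataFrame:
    """Length-weighted gene copy number and > 2-fold amplification calls.

    ``genes`` is a BED-style table (chromosome, start, end, name).  A
    gene's cn_est is the overlap-length-weighted mean of overlapping
    segments' cn_est; fold = cn_est / 2; amplified iff fold is strictly
    above ``fold_threshold``.  Genes with no overlapping segment get NaN
    and are not amplified.
    """
    rows = []
    for _, g in genes.iterrows():
        seg = segments[segments["chromosome"] == g["chromosome"]]
        ov_start = np.maximum(seg["start"].to_numpy(), g["start"])
        ov_end = np.minimum(seg["end"].to_numpy(), g["end"])
        w = np.maximum(ov_end - ov_start, 0)
        name = g.get("name", f"{g['chromosome']}:{g['start']}-{g['end']}")
        if w.sum() == 0:
            rows.append({"gene": name, "cn_est": np.nan, "fold": np.nan, "amplified": False})
            continue
        cn = float(np.average(seg["cn_est"].to_numpy(), weights=w))
        fold = cn / 2.0
        rows.append({"gene": name, "cn_est": cn, "fold": fold,
                     "amplified": bool(fold > fold_threshold)})
    return pd.DataFrame(rows)


def assign_bins_to_segments(bins: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """Integer copy number of the segment containing each bin midpoint
    (NaN-safe: bins outside any segment get -1)."""
    cn = np.full(len(bins), -1, dtype=int)
    mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    for contig, seg in segments.groupby("chromosome", sort=False):
        sel = (bins["chromosome"] == contig).to_numpy()
        if not sel.any():
            continue
        seg = seg.sort_values("start")
        idx = np.searchsorted(seg["start"].to_numpy(), mid[sel], side="right") - 1
        ok = idx >= 0
        inside = np.zeros(sel.sum(), dtype=bool)
        seg_end = seg["end"].to_numpy()
        inside[ok] = mid[sel][ok] < seg_end[idx[ok]]
        vals = np.full(sel.sum(), -1, dtype=int)
        vals[inside] = seg["cn_int"].to_numpy()[idx[inside]]
        cn[sel] = vals
    return cn


def profile_divergence(bins_a: pd.DataFrame, bins_b: pd.DataFrame,
                       segments_a: pd.DataFrame, segments_b: pd.DataFrame) -> float:
    """Percent of panel bins whose integer copy number differs between
    two samples sharing a bin grid."""
    if len(bins_a) != len(bins_b) or not (
        bins_a[["chromosome", "start", "end"]].reset_index(drop=True)
        .equals(bins_b[["chromosome", "start", "end"]].reset_index(drop=True))
    ):
        raise ValueError("bin grids differ between samples")
    cn_a = assign_bins_to_segments(bins_a, segments_a)
    cn_b = assign_bins_to_segments(bins_b, segments_b)
    return float(100.0 * np.mean(cn_a != cn_b))


def cluster_profiles(log2_matrix: pd.DataFrame, distance_cut: float = 0.5):
    """Hierarchically cluster per-sample log2 profiles.

    Rows are samples, columns bins.  Average linkage on correlation
    distance (1 - Pearson r).  Samples with a constant profile have an
    undefined correlation; their pairwise distances are set to 1 with a
    warning.  Returns ``(linkage_matrix, flat_cluster_labels)``; the
    linkage is deterministic for fixed input order.
    """
    if len(log2_matrix) < 2:
        raise ValueError("need >= 2 samples to cluster")
    x = log2_matrix.to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant profile(s); correlation distance set to 1",
                       int(constant.sum()))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    dist = 1.0 - corr
    dist[np.isnan(dist)] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    np.clip(dist, 0.0, 2.0, out=dist)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=distance_cut, criterion="distance")
    return link, pd.Series(labels, index=log2_matrix.index, name="cluster")


def region_density_test(reads_per_mb_a: Sequence[float],
                        reads_per_mb_b: Sequence[float]):
    """Paired t-test of per-sample read density between two regions.

    Returns ``(t, df, p)``; with zero variance of the paired differences
    the test is undefined and ``(nan, df, nan)`` is returned.
    """
    a = np.asarray(reads_per_mb_a, dtype=float)
    b = np.asarray(reads_per_mb_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 paired observations")
    diffs = a - b
    df = len(a) - 1
    if np.std(diffs, ddof=1) == 0:
        logger.warning("paired differences have zero variance; p undefined")
        return float("nan"), df, float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue)


def naive_segment(bins: pd.DataFrame, max_jump: float = 0.3) -> pd.DataFrame:
    """Fallback segmenter: merge consecutive bins while |Δ log2| < max_jump.

    Plumbing for users without a segment table; not a replacement for a
    real segmentation algorithm.
    """
    rows = []
    for contig, grp in bins.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        log2 = grp["log2"].to_numpy()
        depth = grp["depth"].to_numpy() if "depth" in grp.columns else np.full(len(grp), np.nan)
        start_i = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or abs(log2[i] - log2[i - 1]) >= max_jump:
                sl = slice(start_i, i)
                rows.append({
                    "chromosome": contig,
                    "start": int(grp["start"].iloc[start_i]),
                    "end": int(grp["end"].iloc[i - 1]),
                    "log2": float(np.mean(log2[sl])),
                    "depth": float(np.nanmean(depth[sl])),
                    "weight": i - start_i,
                })
                start_i = i
    return pd.DataFrame(rows)
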