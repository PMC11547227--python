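"""Loss-of-heterozygosity percentage over 100-kb genomic bins.

Germline heterozygous sites sit at VAF ~0.5 in a balanced genome.  Under
allelic imbalance (deletion of one allele, or copy-neutral LOH) the mean
VAF of a region drifts away from 0.5 in proportion to tumour purity.
The statistic here is the percentage of occupied, chromosome-limited
100-kb bins whose mean non-homozygous VAF falls strictly outside the
0.4–0.6 band.  All detected variants feed the statistic — panel germline
SNPs carry the signal — so the somatic triage filter is *not* applied
first.

Two reliability guards: mean read depth below 150x, or median VAF below
0.1 (too little heterozygous signal, e.g. very low purity with few
germline sites), mark the result unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .formats import bin_index
from .synthetic import GenomeModel

#: LOH% above which the sample exceeds the 16% HRD cut-off used with
#: whole-genome LOH scoring (strict >).
COLEMAN_LOH_CUTOFF = 16.0


@dataclass
class LOHResult:
    sample_id: str
    loh_percent: float  # 0..100; NaN when undefined
    occupied_bins: int
    loh_bins: int
    reliable: bool
    reason: Optional[str] = None
    exceeds_coleman_cutoff: bool = False

    def __post_init__(self):
        assert self.loh_bins <= self.occupied_bins


def loh_reliability(mean_depth: float, median_vaf: float,
                    min_depth: float = 150.0, min_median_vaf: float = 0.1
                    ) -> Tuple[bool, Optional[str]]:
    """Reliability guards over the sample's eligible variants.

    Reliable iff mean depth >= 150x and median VAF >= 0.1; the reason
    names the failing guard(s).
    """
    reasons = []
    if not mean_depth >= min_depth:
        reasons.append("low depth")
    if not median_vaf >= min_median_vaf:
        reasons.append("low median VAF")
    return (not reasons), ("; ".join(reasons) or None)


def loh_percent(
    variants: pd.DataFrame,
    genome: GenomeModel,
    sample_id: str = "",
    band: Tuple[float, float] = (0.4, 0.6),
    vaf_window: Tuple[float, float] = (0.05, 0.95),
    min_variants_per_bin: int = 1,
) -> LOHResult:
    """Percentage of occupied 100-kb bins with mean VAF outside [0.4, 0.6].

    Parameters
    ----------
    variants
        One sample's full variant table (germline + somatic), with
        ``chrom``, ``pos`` (1-based), ``vaf`` and ``depth``.
    genome
        Supplies contig lengths and the bin size; bins are anchored at
        each contig's position 0 and truncated at contig ends.
    band
        Mean-VAF band treated as heterozygous-balanced; a bin is LOH when
        its mean eligible VAF is strictly below band[0] or strictly above
        band[1].
    vaf_window
        The "non-homozygous" eligibility window: variants with VAF inside
        it (inclusive) feed the statistic, keeping allele-imbalanced
        heterozygotes while excluding fixed homozygotes.
    min_variants_per_bin
        Minimum eligible variants for a bin to count as occupied.
    """
    lo, hi = vaf_window
    eligible = variants[(variants["vaf"] >= lo) & (variants["vaf"] <= hi)]
    if eligible.empty:
        return LOHResult(sample_id=sample_id, loh_percent=float("nan"),
                         occupied_bins=0, loh_bins=0, reliable=False,
                         reason="no eligible variants")

    contig_len = dict(genome.contigs)
    unknown = set(eligible["chrom"]) - set(contig_len)
    if unknown:
        raise ValueError(f"variants on contig(s) absent from genome model: {sorted(unknown)}")

    idx = bin_index(eligible["pos"].to_numpy(), genome.panel_bins)
    keys = pd.DataFrame({"chrom": eligible["chrom"].to_numpy(), "bin": idx,
                         "vaf": eligible["vaf"].to_numpy()})
    grouped = keys.groupby(["chrom", "bin"])["vaf"].agg(["mean", "size"])
    occupied = grouped[grouped["size"] >= min_variants_per_bin]
    n_occ = len(occupied)
    loh_mask = (occupied["mean"] < band[0]) | (occupied["mean"] > band[1])
    n_loh = int(loh_mask.sum())
    pct = 100.0 * n_loh / n_occ if n_occ else float("nan")

    reliable, reason = loh_reliability(
        mean_depth=float(eligible["depth"].mean()),
        median_vaf=float(eligible["vaf"].median()),
    )
    if n_occ == 0:
        reliable, reason = False, "no occupied bins"
    return LOHResult(
        sample_id=sample_id,
        loh_percent=pct,
        occupied_bins=n_occ,
        loh_bins=n_loh,
        reliable=reliable,
        reason=reason,
        exceeds_coleman_cutoff=bool(n_occ and pct > COLEMAN_LOH_CUTOFF),
    )
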