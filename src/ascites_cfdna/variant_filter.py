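"""Somatic-likelihood triage without a matched germline sample.

With no germline reference, a variant is treated as likely somatic when it
is rare in each of three population databases (strictly below 0.05% in
gnomAD exomes, 0.5% in gnomAD genomes and 2% in 1000 Genomes — the
frequency form of a minor-allele-count < 100 rule).  A missing annotation
counts as rare: absence from population databases is itself somatic
evidence, and is recorded in the reason string for audit.

Verification, cohort-level outlier flagging of total variant counts (an
FFPE-artifact tell) and tumour mutation burden (TMB) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AF_COLUMNS = ("af_gnomad_exome", "af_gnomad_genome", "af_1000g")


@dataclass(frozen=True)
class FilterThresholds:
    """Triage cut-offs. All comparisons are strict, as printed."""

    max_af_exome: float = 0.0005
    max_af_genome: float = 0.005
    max_af_1000g: float = 0.02
    max_allele_count: int = 100  # applied only when counts are supplied
    verify_min_vaf: float = 0.05
    verify_min_depth: int = 150
    outlier_z: float = 3.0

    def af_cutoffs(self) -> Mapping[str, float]:
        return {
            "af_gnomad_exome": self.max_af_exome,
            "af_gnomad_genome": self.max_af_genome,
            "af_1000g": self.max_af_1000g,
        }


def is_likely_somatic(record, thresholds: FilterThresholds = FilterThresholds()):
    """Classify one variant record (mapping/Series) as likely somatic.

    Returns ``(passes, reason)``; ``passes`` is True iff the variant is
    strictly below threshold in every database with an annotation present.
    ``reason`` names the failing databases, or notes missing evidence.
    """
    failing = []
    n_present = 0
    for col, cutoff in thresholds.af_cutoffs().items():
        val = record.get(col) if hasattr(record, "get") else getattr(record, col, None)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            continue
        n_present += 1
        if not val < cutoff:
            failing.append(col.replace("af_", ""))
    counts = record.get("allele_count") if hasattr(record, "get") else None
    if counts is not None and not (isinstance(counts, float) and np.isnan(counts)):
        if not counts < thresholds.max_allele_count:
            failing.append("allele_count")
    if failing:
        return False, ",".join(failing)
    if n_present == 0:
        return True, "no population evidence"
    return True, "rare in all annotated databases"


def likely_somatic_mask(variants: pd.DataFrame,
                        thresholds: FilterThresholds = FilterThresholds()) -> pd.Series:
    """Vectorised :func:`is_likely_somatic` over a variant table."""
    mask = pd.Series(True, index=variants.index)
    for col, cutoff in thresholds.af_cutoffs().items():
        if col in variants.columns:
            vals = variants[col]
            mask &= vals.isna() | (vals < cutoff)
    if "allele_count" in variants.columns:
        vals = variants["allele_count"]
        mask &= vals.isna() | (vals < thresholds.max_allele_count)
    return mask


def build_participant_variant_index(variants: pd.DataFrame) -> Mapping[tuple, int]:
    """Map (participant_id, variant key) -> number of samples reporting it
    with at least one alternate read."""
    from .formats import variant_key

    seen = variants[variants["alt_count"] > 0]
    keys = [
        (p, variant_key(c, pos, r, a))
        for p, c, pos, r, a in zip(
            seen["participant_id"], seen["chrom"], seen["pos"], seen["ref"], seen["alt"]
        )
    ]
    counts: dict = {}
    sample_seen = set()
    for (p, k), s in zip(keys, seen["sample_id"]):
        if (p, k, s) in sample_seen:
            continue
        sample_seen.add((p, k, s))
        counts[(p, k)] = counts.get((p, k), 0) + 1
    return counts


def is_verifiable(record, participant_variant_index: Mapping[tuple, int],
                  thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """True iff the variant is reported in more than one of the
    participant's samples, or — if unique — has VAF > 0.05 and read depth
    > 150 (strict comparisons)."""
    from .formats import variant_key

    key = (
        record["participant_id"],
        variant_key(record["chrom"], record["pos"], record["ref"], record["alt"]),
    )
    if participant_variant_index.get(key, 0) > 1:
        return True
    return (record["vaf"] > thresholds.verify_min_vaf
            and record["depth"] > thresholds.verify_min_depth)


def flag_variant_count_outliers(counts: Mapping[str, int] | pd.Series,
                                outlier_z: float = 3.0) -> set:
    """Flag samples whose total variant count is a cohort outlier.

    The single most outlying sample (maximum |count − median|, ties broken
    toward the larger count) is excluded before computing the mean and SD,
    so that one grossly artefactual sample cannot mask itself.  Every
    sample — including the excluded one — whose Z-score against that
    mean/SD exceeds ``outlier_z`` in absolute value is flagged.

    With SD 0 (all remaining counts equal) any sample differing from the
    mean is flagged.
    """
    counts = pd.Series(counts, dtype=float)
    if len(counts) < 3:
        raise ValueError("need >= 3 samples for outlier flagging")
    median = counts.median()
    dev = (counts - median).abs()
    # ties on |deviation| -> larger count excluded
    order = sorted(counts.index, key=lambda s: (dev[s], counts[s]))
    excluded = order[-1]
    rest = counts.drop(excluded)
    mean = rest.mean()
    sd = rest.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return set(counts.index[counts != mean])
    z = (counts - mean) / sd
    return set(counts.index[z.abs() > outlier_z])


def tmb(n_somatic_verified: int, callable_mb: float = 1.94) -> float:
    """Tumour mutation burden: somatic variants per callable megabase,
    reported to one decimal place."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be > 0")
    return round(n_somatic_verified / callable_mb, 1)


def triage_variants(variants: pd.DataFrame,
                    thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """Annotate a cohort variant table with triage columns.

    Adds ``likely_somatic`` and, when participant/sample identity is
    present, ``verifiable``.  Rows are not removed; downstream stages
    select on the flags.
    """
    out = variants.copy()
    out["likely_somatic"] = likely_somatic_mask(out, thresholds)
    if {"participant_id", "sample_id"} <= set(out.columns):
        index = build_participant_variant_index(out)
        out["verifiable"] = [
            is_verifiable(row, index, thresholds) for _, row in out.iterrows()
        ]
    return out
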