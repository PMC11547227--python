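"""Genomic-instability consensus scoring.

Three shallow surrogate markers of genomic instability — LGA count,
LOH% and TMB — are combined into a 0–3 consensus score: the number of
markers strictly above their cohort medians.  Medians are computed over
each participant's *initial* sample only, so serial samples are scored
against a fixed cohort reference rather than moving their own baseline.

The score is a relative, cohort-internal ranking; the absolute HRD
cut-offs in the literature (LGA >= 20; LOH strictly above 16%) are
annotated separately as flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

HRD_LGA_CUTOFF = 20
HRD_LOH_CUTOFF = 16.0

MARKERS = ("lga", "loh_percent", "tmb")


def gi_consensus(table: pd.DataFrame,
                 initial_mask: Optional[pd.Series] = None,
                 recompute_medians_on_serial: bool = False
                 ) -> Tuple[pd.Series, Dict[str, float]]:
    """Per-sample genomic-instability score and the medians used.

    Parameters
    ----------
    table
        One row per sample with numeric columns ``lga``, ``loh_percent``
        and ``tmb``; optional boolean ``loh_reliable`` (unreliable LOH
        is excluded from the median and contributes 0 to that sample's
        score).
    initial_mask
        Boolean mask of the rows entering the medians (each
        participant's first sample).  None scores everyone against
        medians over all rows.
    recompute_medians_on_serial
        If True, medians are taken over all rows instead of the initial
        mask (the switchable alternative convention).

    Returns
    -------
    (scores, medians): integer 0–3 score per row, and the marker
    medians used.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 samples for cohort medians")
    ref = table if (initial_mask is None or recompute_medians_on_serial) \
        else table[initial_mask.to_numpy(bool)]
    reliable = table["loh_reliable"].astype(bool) if "loh_reliable" in table.columns \
        else pd.Series(True, index=table.index)
    ref_reliable = reliable.loc[ref.index]

    medians: Dict[str, float] = {}
    for marker in MARKERS:
        vals = ref[marker]
        if marker == "loh_percent":
            vals = vals[ref_reliable]
        vals = vals.dropna()
        if vals.empty:
            raise ValueError(f"marker {marker!r} has no usable values")
        medians[marker] = float(vals.median())

    score = pd.Series(0, index=table.index, dtype=int)
    score += (table["lga"] > medians["lga"]).astype(int)
    loh_above = (table["loh_percent"] > medians["loh_percent"]) & reliable
    score += loh_above.fillna(False).astype(int)
    score += (table["tmb"] > medians["tmb"]).astype(int)
    return score, medians


def annotate_hrd_thresholds(report: pd.DataFrame) -> pd.DataFrame:
    """Add the published absolute HRD cut-off flags.

    ``lga_ge_20``: LGA count at or above 20; ``loh_gt_16``: LOH%
    strictly above 16.
    """
    out = report.copy()
    out["lga_ge_20"] = out["lga"] >= HRD_LGA_CUTOFF
    out["loh_gt_16"] = out["loh_percent"] > HRD_LOH_CUTOFF
    return out
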