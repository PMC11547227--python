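"""Cancer-cell-fraction preparation, clone clustering and temporal shifts.

A variant's cancer cell fraction (CCF) in one sample follows from its
VAF ``v``, the sample's tumour fraction ``t`` and the local tumour copy
number ``cn``:

    m̂  = clip(round(v * (t*cn + 2(1-t)) / t), 1, cn)
    ccf = clip(v * (t*cn + 2(1-t)) / (t * m̂), 0, 1)

with the mutation multiplicity m̂ estimated by rounding (clonal-analysis
tools marginalise it internally; panel data cannot resolve it directly).

Input preparation applies two published exclusion rules: variants whose
locus has copy number 0 in any matched sample of the participant cannot
be analysed at all, and when any sample of a participant has tumour
content below 30%, only variants below 0.3 VAF in that sample are kept
(higher-VAF calls there are likelier germline leakage than somatic
signal).

Clustering is a deliberately transparent stand-in for full Bayesian
clonal inference: k-means on per-variant CCF vectors across samples,
with k chosen by BIC under a spherical Gaussian profile, best of a
fixed number of seeded restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .formats import variant_key

logger = logging.getLogger(__name__)


@dataclass
class ClonalCluster:
    cluster_id: int
    members: List[str]  # variant keys
    ccf_per_sample: Dict[str, float]

    def __post_init__(self):
        for s, c in self.ccf_per_sample.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"cluster CCF {c} outside [0,1] for {s}")


def ccf(v: float, t: float, cn_tumour: int, multiplicity: Optional[int] = None) -> float:
    """Cancer cell fraction of one variant observation.

    With ``multiplicity`` None the multiplicity is estimated by the
    rounding rule; pass an integer to fix it.
    """
    if t <= 0:
        raise ValueError("purity must be > 0")
    if cn_tumour < 1:
        raise ValueError("tumour copy number must be >= 1 (CN-0 loci are excluded)")
    scaled = v * (t * cn_tumour + 2.0 * (1.0 - t)) / t
    if multiplicity is None:
        multiplicity = int(np.clip(np.floor(scaled + 0.5), 1, cn_tumour))
    return float(np.clip(scaled / multiplicity, 0.0, 1.0))


def segment_cn_at(segments: pd.DataFrame, chrom: str, pos: int) -> Optional[int]:
    """Integer copy number of the segment containing a 1-based position."""
    seg = segments[(segments["chromosome"] == chrom)
                   & (segments["start"] < pos) & (pos <= segments["end"])]
    if seg.empty:
        return None
    return int(seg["cn_int"].iloc[0])


def prepare_clonal_inputs(
    variants: pd.DataFrame,
    purities: Mapping[str, float],
    segments: Mapping[str, pd.DataFrame],
    min_purity: float = 0.30,
    vaf_cap: float = 0.30,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Build per-(variant, sample) clonal-analysis rows for one participant.

    ``variants`` holds the participant's somatic variants across all
    samples (absent in a sample = alt_count 0 row, or no row — missing
    rows are filled with alt 0 at the sample's median depth).
    ``segments`` maps sample_id to that sample's copy-number-annotated
    segment table (``cn_int`` column required).

    Returns ``(rows, exclusions)``.  Exclusion reasons partition the
    dropped variants: ``cn0`` (copy number 0 in at least one matched
    sample) and ``low-purity-vaf`` (VAF at or above ``vaf_cap`` in a
    sample with purity below ``min_purity``).
    """
    sample_ids = list(purities)
    for sid in sample_ids:
        if sid not in segments:
            raise ValueError(f"sample {sid!r} has no segment table")

    df = variants.copy()
    df["key"] = [variant_key(c, p, r, a) for c, p, r, a in
                 zip(df["chrom"], df["pos"], df["ref"], df["alt"])]

    # complete the variant x sample grid
    meta = df.drop_duplicates("key").set_index("key")[["chrom", "pos", "ref", "alt"]]
    median_depth = {sid: float(df.loc[df["sample_id"] == sid, "depth"].median())
                    for sid in sample_ids}
    grid = []
    for key, m in meta.iterrows():
        for sid in sample_ids:
            obs = df[(df["key"] == key) & (df["sample_id"] == sid)]
            if len(obs):
                row = obs.iloc[0]
                alt_count, depth = int(row["alt_count"]), int(row["depth"])
            else:
                alt_count, depth = 0, int(median_depth[sid] or 100)
            grid.append({"key": key, "sample_id": sid, "chrom": m["chrom"],
                         "pos": int(m["pos"]), "ref": m["ref"], "alt": m["alt"],
                         "alt_count": alt_count, "depth": depth,
                         "vaf": alt_count / depth if depth else 0.0})
    rows = pd.DataFrame(grid)

    rows["cn_tumour"] = [
        segment_cn_at(segments[sid], c, p)
        for sid, c, p in zip(rows["sample_id"], rows["chrom"], rows["pos"])
    ]
    rows["cn_tumour"] = rows["cn_tumour"].fillna(2).astype(int)

    exclusions = []
    cn0_keys = set(rows.loc[rows["cn_tumour"] == 0, "key"])
    for key in sorted(cn0_keys):
        exclusions.append({"key": key, "reason": "cn0"})

    low_purity_samples = [s for s in sample_ids if purities[s] < min_purity]
    lp_keys = set()
    if low_purity_samples:
        mask = (rows["sample_id"].isin(low_purity_samples)
                & (rows["vaf"] >= vaf_cap) & ~rows["key"].isin(cn0_keys))
        lp_keys = set(rows.loc[mask, "key"])
        for key in sorted(lp_keys):
            exclusions.append({"key": key, "reason": "low-purity-vaf"})

    keep = ~rows["key"].isin(cn0_keys | lp_keys)
    rows = rows[keep].reset_index(drop=True)
    rows["purity"] = [float(purities[s]) for s in rows["sample_id"]]
    rows["normal_cn"] = 2
    return rows, pd.DataFrame(exclusions, columns=["key", "reason"])


def ccf_matrix(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-variant CCF vectors across samples (variants x samples)."""
    rows = rows.copy()
    rows["ccf"] = [
        ccf(v, t, cn) if cn >= 1 and t > 0 else 0.0
        for v, t, cn in zip(rows["vaf"], rows["purity"], rows["cn_tumour"])
    ]
    return rows.pivot_table(index="key", columns="sample_id", values="ccf")


def cluster_ccf(ccfs: pd.DataFrame, k_max: int = 8, n_restarts: int = 10,
                seed: int = 0, min_component_var: float = 2e-3) -> List[ClonalCluster]:
    """Cluster variants into clones by their CCF vectors.

    A k-means-initialised spherical Gaussian mixture is fitted for each
    k = 1..k_max (capped at the number of variants), each the best of
    ``n_restarts`` seeded initialisations; k is selected by BIC.  The
    mixture likelihood (rather than a hard-assignment profile) is what
    makes the BIC comparison across k well behaved.  The search stops
    once BIC has worsened for two consecutive k.

    ``min_component_var`` floors each component's variance at the CCF
    measurement-noise scale of deep targeted panels (sd ~0.045 at
    500–1000x): clipping CCFs into [0, 1] piles truncal variants up at
    exactly 1.0, and without the floor a component collapses onto that
    atom with spuriously high likelihood.

    Deterministic given ``seed``.  Cluster CCF per sample is the mean
    member CCF, clipped to [0, 1]; clusters are numbered by descending
    mean CCF.
    """
    if ccfs.isna().any().any():
        raise ValueError("every variant needs a CCF in every sample")
    x = ccfs.to_numpy(dtype=float)
    n = len(x)
    if n == 0:
        return []
    best = None
    worse_streak = 0
    for k in range(1, min(k_max, n) + 1):
        gm = GaussianMixture(n_components=k, covariance_type="spherical",
                             n_init=1 if k == 1 else n_restarts,
                             random_state=seed, reg_covar=min_component_var)
        labels = gm.fit_predict(x)
        bic = gm.bic(x)
        if best is None or bic < best[0]:
            best = (bic, labels, gm.means_)
            worse_streak = 0
        else:
            worse_streak += 1
            if worse_streak >= 2:
                break
    _, labels, centers = best
    order = np.argsort(-centers.mean(axis=1))
    rank = {int(old): new for new, old in enumerate(order)}
    clusters = []
    for old, new in sorted(rank.items(), key=lambda kv: kv[1]):
        members = list(ccfs.index[labels == old])
        if not members:
            continue
        mean_ccf = np.clip(x[labels == old].mean(axis=0), 0.0, 1.0)
        clusters.append(ClonalCluster(
            cluster_id=new, members=members,
            ccf_per_sample={s: float(c) for s, c in zip(ccfs.columns, mean_ccf)},
        ))
    return clusters


def detect_prevalence_shifts(clusters: Sequence[ClonalCluster],
                             sample_order: Sequence[str],
                             threshold: float = 0.10) -> pd.DataFrame:
    """Flag clone-prevalence changes between consecutive samples.

    A shift is flagged when |CCF(later) - CCF(earlier)| exceeds the
    threshold (absolute CCF points, strict) for a consecutive sample
    pair in ``sample_order``.
    """
    if len(sample_order) < 2:
        raise ValueError("need >= 2 samples ordered in time")
    rows = []
    for cl in clusters:
        for earlier, later in zip(sample_order[:-1], sample_order[1:]):
            delta = cl.ccf_per_sample[later] - cl.ccf_per_sample[earlier]
            rows.append({
                "cluster_id": cl.cluster_id, "from_sample": earlier,
                "to_sample": later, "delta_ccf": delta,
                "flagged": bool(abs(delta) > threshold),
            })
    return pd.DataFrame(rows)


def unrepresented_clone_warning(exclusions: pd.DataFrame,
                                anchor_key: Optional[str]) -> Optional[dict]:
    """Warn when the purity anchor variant itself was CN-0-excluded.

    A clonal deleterious TP53 variant sitting on a fully deleted segment
    cannot enter clustering, implying a high-frequency clone the cluster
    set cannot represent; reported as a warning record, not a cluster.
    """
    if anchor_key is None or exclusions.empty:
        return None
    hit = exclusions[(exclusions["key"] == anchor_key) & (exclusions["reason"] == "cn0")]
    if hit.empty:
        return None
    return {"warning": "unrepresented high-frequency clone",
            "anchor_variant": anchor_key,
            "detail": "purity anchor excluded by the CN-0 rule; an additional "
                      "high-CCF clone is implied but cannot be clustered"}
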