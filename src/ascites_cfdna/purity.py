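"""Tumour-fraction estimation from a deleterious TP53 anchor variant.

High-grade serous ovarian carcinoma almost universally inactivates TP53
early, typically by one point mutation plus loss of the wild-type allele
(the double-hit model).  Tumour cells then carry one mutant TP53 copy and
no wild-type copy, while admixed normal cells carry two wild-type copies.
With tumour fraction ``t`` the expected mutant allele fraction is

    v = t / (t + 2(1 - t)) = t / (2 - t)

which inverts to the purity estimator

    t = v / ((1 - v)/2 + v) = 2v / (1 + v).

When no deleterious TP53 point variant is measurable (e.g. the mutant
allele itself sits on a deleted segment), purity can instead be scaled
proportionally from another clonal variant's VAF against a reference
sample of known purity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SamplePurity:
    """Tumour fraction for one sample with the method that produced it."""

    sample_id: str
    t: float
    method: str  # tp53_double_hit | proportional | supplied
    anchor_variant: Optional[str] = None

    def __post_init__(self):
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"purity {self.t} outside [0, 1]")


def purity_from_tp53_vaf(v):
    """Tumour fraction t = 2v/(1+v) under the TP53 double-hit model.

    Monotone increasing, concave, with t(0)=0, t(1)=1 and t >= v
    everywhere (each tumour genome contributes one mutant allele but
    fewer total alleles than a diploid normal genome).
    """
    v = np.asarray(v, dtype=float)
    if np.any((v < 0) | (v > 1)):
        raise ValueError("VAF outside [0, 1]")
    t = 2.0 * v / (1.0 + v)
    return float(t) if t.ndim == 0 else t


def vaf_from_purity(t):
    """Expected deleterious-TP53 VAF v = t/(2-t); inverse of
    :func:`purity_from_tp53_vaf`."""
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("purity outside [0, 1]")
    v = t / (2.0 - t)
    return float(v) if v.ndim == 0 else v


def proportional_purity(v_sample: float, v_ref: float, t_ref: float) -> float:
    """Purity by proportional VAF scaling against a reference sample.

    Used when the double-hit anchor is unavailable: the same clonal
    variant's VAF in this sample and in a reference sample of known
    purity ``t_ref`` gives t = t_ref * v_sample / v_ref, clipped to [0, 1].
    """
    if v_ref <= 0:
        raise ValueError("reference VAF must be > 0")
    if not 0.0 <= t_ref <= 1.0:
        raise ValueError("reference purity outside [0, 1]")
    return float(np.clip(t_ref * v_sample / v_ref, 0.0, 1.0))


def select_anchor_variant(
    variants: pd.DataFrame,
    gene: str = "TP53",
    deleterious_only: bool = True,
) -> Optional[pd.Series]:
    """Pick the purity anchor: the deleterious variant of *gene* with
    maximum VAF (the clonal hit under the gatekeeper assumption).

    Returns None when the sample carries no qualifying variant.
    """
    if "gene" not in variants.columns:
        return None
    cand = variants[variants["gene"] == gene]
    if deleterious_only and "effect" in variants.columns:
        cand = cand[cand["effect"] == "deleterious"]
    if cand.empty:
        return None
    return cand.loc[cand["vaf"].idxmax()]


def estimate_sample_purity(
    variants: pd.DataFrame,
    sample_id: str,
    anchor_gene: str = "TP53",
    ref_vaf: Optional[float] = None,
    ref_purity: Optional[float] = None,
    ref_gene: Optional[str] = None,
    purity_hint: Optional[float] = None,
) -> SamplePurity:
    """Estimate one sample's tumour fraction, preferring the double-hit
    anchor, then proportional scaling, then a supplied hint.

    Parameters
    ----------
    variants
        This sample's somatic variant table (gene/effect annotated).
    ref_vaf, ref_purity, ref_gene
        Reference VAF and purity for the proportional fallback; the
        variant used is the max-VAF deleterious variant of ``ref_gene``
        in this sample.
    purity_hint
        Externally supplied purity (e.g. pathology estimate), last resort.
    """
    anchor = select_anchor_variant(variants, gene=anchor_gene)
    if anchor is not None and anchor["vaf"] > 0:
        from .formats import variant_key

        return SamplePurity(
            sample_id=sample_id,
            t=purity_from_tp53_vaf(float(anchor["vaf"])),
            method="tp53_double_hit",
            anchor_variant=variant_key(anchor["chrom"], anchor["pos"], anchor["ref"], anchor["alt"]),
        )
    if ref_vaf is not None and ref_purity is not None and ref_gene is not None:
        prop = select_anchor_variant(variants, gene=ref_gene, deleterious_only=False)
        if prop is not None:
            return SamplePurity(
                sample_id=sample_id,
                t=proportional_purity(float(prop["vaf"]), ref_vaf, ref_purity),
                method="proportional",
            )
    if purity_hint is not None:
        return SamplePurity(sample_id=sample_id, t=float(purity_hint), method="supplied")
    raise ValueError(f"purity undeterminable for sample {sample_id!r}: "
                     f"no {anchor_gene} anchor and no fallback")
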