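"""End-to-end orchestration: triage → purity → copy number → LOH →
clonal tracking → genomic-instability report.

:func:`analyse_cohort` is the in-memory engine working on the
DataFrames the formats module produces (or the simulator emits);
:func:`run_pipeline` is the file-in/file-out wrapper driven by a YAML
or dict config, writing per-stage TSVs, a cohort JSON report and a run
log.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from . import clonal as clonal_mod
from . import copy_number as cn_mod
from . import formats
from . import loh as loh_mod
from . import purity as purity_mod
from . import scoring
from . import variant_filter as vf
from .synthetic import GenomeModel, SimulatedCohort

logger = logging.getLogger(__name__)


@dataclass
class ParticipantClonalResult:
    participant_id: str
    clusters: list
    shifts: pd.DataFrame
    exclusions: pd.DataFrame
    warning: Optional[dict] = None


@dataclass
class CohortResult:
    """Everything the pipeline computes, per sample and per participant."""

    sample_table: pd.DataFrame          # purity, lga, loh, tmb, gi_score, flags
    medians: Dict[str, float]
    variants: pd.DataFrame              # triage-annotated long table
    outlier_samples: set
    segments: Dict[str, pd.DataFrame]   # copy-number annotated, repaired
    amplifications: Dict[str, pd.DataFrame]
    clonal: List[ParticipantClonalResult]
    divergence: pd.DataFrame            # consecutive-sample CN divergence
    profile_clusters: Optional[pd.Series] = None


def analyse_cohort(
    variants: pd.DataFrame,
    bins: Mapping[str, pd.DataFrame],
    segments: Mapping[str, pd.DataFrame],
    manifest: pd.DataFrame,
    genome: GenomeModel,
    thresholds: vf.FilterThresholds = vf.FilterThresholds(),
    genes: Optional[pd.DataFrame] = None,
    clonal_seed: int = 0,
    min_clonal_purity: float = 0.30,
    clonal_vaf_cap: float = 0.30,
) -> CohortResult:
    """Run every analysis stage over an in-memory cohort.

    ``variants`` is the long table across samples (one row per variant
    per sample; alt_count 0 marks non-detection); ``bins`` / ``segments``
    map sample_id to CNVKit-dialect tables.
    """
    manifest = formats.validate_manifest(manifest)
    sample_ids = list(manifest["sample_id"])

    # --- stage: variant triage -----------------------------------------
    stage = "filter"
    try:
        variants = vf.triage_variants(variants, thresholds)
        detected = variants[variants["alt_count"] > 0]
        counts = detected.groupby("sample_id").size().reindex(sample_ids, fill_value=0)
        outliers = (vf.flag_variant_count_outliers(counts, thresholds.outlier_z)
                    if len(counts) >= 3 else set())

        # --- stage: purity ---------------------------------------------
        stage = "purity"
        purities: Dict[str, purity_mod.SamplePurity] = {}
        hint_col = manifest["purity_hint"] if "purity_hint" in manifest.columns else None
        for i, sid in enumerate(sample_ids):
            sv = detected[(detected["sample_id"] == sid) & detected["likely_somatic"]]
            hint = float(hint_col.iloc[i]) if hint_col is not None \
                and not pd.isna(hint_col.iloc[i]) else None
            purities[sid] = purity_mod.estimate_sample_purity(
                sv, sid, purity_hint=hint)

        # --- stage: copy number -----------------------------------------
        stage = "cnv"
        seg_annot: Dict[str, pd.DataFrame] = {}
        lga: Dict[str, int] = {}
        amps: Dict[str, pd.DataFrame] = {}
        for sid in sample_ids:
            if sid not in segments:
                raise KeyError(f"sample {sid!r}: missing segments table")
            t = max(purities[sid].t, 1e-3)
            seg = cn_mod.annotate_copy_number(segments[sid], t)
            seg = cn_mod.repair_unreliable_segments(seg)
            seg_annot[sid] = seg
            lga[sid] = cn_mod.count_lga(seg, sample_id=sid).lga_count
            if genes is not None:
                amps[sid] = cn_mod.call_gene_amplifications(seg, genes)

        # --- stage: LOH --------------------------------------------------
        stage = "loh"
        loh_results = {
            sid: loh_mod.loh_percent(detected[detected["sample_id"] == sid],
                                     genome, sample_id=sid)
            for sid in sample_ids
        }

        # --- stage: TMB --------------------------------------------------
        stage = "tmb"
        tmbs = {}
        for sid in sample_ids:
            sv = detected[(detected["sample_id"] == sid) & detected["likely_somatic"]]
            if "verifiable" in sv.columns:
                sv = sv[sv["verifiable"]]
            tmbs[sid] = vf.tmb(len(sv), genome.callable_mb)

        # --- stage: clonal ----------------------------------------------
        stage = "clones"
        clonal_results = []
        for pid, part in manifest.groupby("participant_id", sort=False):
            psamples = list(part.sort_values("timepoint_days")["sample_id"])
            if len(psamples) < 2:
                continue
            pvars = variants[variants["sample_id"].isin(psamples)
                             & variants["likely_somatic"]]
            som_keys = {
                formats.variant_key(c, p, r, a)
                for c, p, r, a, alt in zip(pvars["chrom"], pvars["pos"],
                                           pvars["ref"], pvars["alt"],
                                           pvars["alt_count"]) if alt > 0
            }
            keep = [formats.variant_key(c, p, r, a) in som_keys
                    for c, p, r, a in zip(pvars["chrom"], pvars["pos"],
                                          pvars["ref"], pvars["alt"])]
            pvars = pvars[keep]
            if pvars.empty:
                continue
            p_pur = {sid: purities[sid].t for sid in psamples}
            rows, excl = clonal_mod.prepare_clonal_inputs(
                pvars, p_pur, {s: seg_annot[s] for s in psamples},
                min_purity=min_clonal_purity, vaf_cap=clonal_vaf_cap)
            warning = None
            anchor = purities[psamples[0]].anchor_variant
            warning = clonal_mod.unrepresented_clone_warning(excl, anchor)
            if rows.empty:
                clonal_results.append(ParticipantClonalResult(
                    pid, [], pd.DataFrame(), excl, warning))
                continue
            ccfs = clonal_mod.ccf_matrix(rows)[psamples]
            clusters = clonal_mod.cluster_ccf(ccfs, seed=clonal_seed)
            shifts = clonal_mod.detect_prevalence_shifts(clusters, psamples)
            clonal_results.append(ParticipantClonalResult(
                pid, clusters, shifts, excl, warning))

        # --- stage: divergence + profile clustering ----------------------
        stage = "divergence"
        div_rows = []
        for pid, part in manifest.groupby("participant_id", sort=False):
            psamples = list(part.sort_values("timepoint_days")["sample_id"])
            for a, b in zip(psamples[:-1], psamples[1:]):
                div_rows.append({
                    "participant_id": pid, "sample_a": a, "sample_b": b,
                    "percent_disparate": cn_mod.profile_divergence(
                        bins[a], bins[b], seg_annot[a], seg_annot[b]),
                })
        divergence = pd.DataFrame(
            div_rows, columns=["participant_id", "sample_a", "sample_b",
                               "percent_disparate"])
        profile_clusters = None
        if len(sample_ids) >= 2:
            log2_matrix = pd.DataFrame(
                {sid: bins[sid]["log2"].to_numpy() for sid in sample_ids}).T
            _, profile_clusters = cn_mod.cluster_profiles(log2_matrix)

        # --- stage: score -------------------------------------------------
        stage = "score"
        table = pd.DataFrame({
            "sample_id": sample_ids,
            "participant_id": manifest["participant_id"].to_numpy(),
            "specimen": manifest["specimen"].to_numpy(),
            "timepoint_days": manifest["timepoint_days"].to_numpy(),
            "purity": [purities[s].t for s in sample_ids],
            "purity_method": [purities[s].method for s in sample_ids],
            "lga": [lga[s] for s in sample_ids],
            "loh_percent": [loh_results[s].loh_percent for s in sample_ids],
            "loh_reliable": [loh_results[s].reliable for s in sample_ids],
            "loh_reason": [loh_results[s].reason for s in sample_ids],
            "tmb": [tmbs[s] for s in sample_ids],
            "total_variants": counts.to_numpy(),
            "variant_count_outlier": [s in outliers for s in sample_ids],
        })
        initial = formats.initial_samples(manifest)
        initial_mask = table["sample_id"].isin(initial["sample_id"])
        scores, medians = scoring.gi_consensus(table, initial_mask)
        table["gi_score"] = scores
        table = scoring.annotate_hrd_thresholds(table)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return CohortResult(
        sample_table=table, medians=medians, variants=variants,
        outlier_samples=outliers, segments=seg_annot, amplifications=amps,
        clonal=clonal_results, divergence=divergence,
        profile_clusters=profile_clusters,
    )


def analyse_simulated_cohort(cohort: SimulatedCohort, genes=None,
                             clonal_seed: int = 0, **kwargs) -> CohortResult:
    """Convenience wrapper running :func:`analyse_cohort` on a simulator
    output object."""
    return analyse_cohort(cohort.variants, cohort.bins, cohort.segments,
                          cohort.manifest, cohort.truth.genome, genes=genes,
                          clonal_seed=clonal_seed, **kwargs)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> CohortResult:
    """File-based pipeline run.

    ``config`` is a dict or a YAML file with keys::

        manifest: manifest.tsv
        genome: {contigs: [[chr1, 120000000], ...], panel_bins: 100000,
                 callable_mb: 1.94}
        samples:
          <sample_id>: {variants: x.tsv, dialect: TSV, bins: x.cnr,
                        segments: x.cns}
        genes: genes.bed        # optional
        seed: 0                 # clonal clustering seed

    Writes per-stage TSVs, ``report.json`` and ``run.log`` into
    ``outdir``; partial outputs are retained when a stage fails.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = formats.read_manifest(config["manifest"])
    gspec = config["genome"]
    genome = GenomeModel(contigs=tuple((c, int(l)) for c, l in gspec["contigs"]),
                         panel_bins=int(gspec.get("panel_bins", 100_000)),
                         callable_mb=float(gspec.get("callable_mb", 1.94)))
    genes = formats.read_bed(config["genes"]) if config.get("genes") else None

    var_frames, bins, segments = [], {}, {}
    for _, row in manifest.iterrows():
        sid = row["sample_id"]
        try:
            spec = config["samples"][sid]
        except KeyError:
            raise RuntimeError(f"pipeline stage 'load' failed: sample {sid!r} "
                               "missing from config") from None
        for key in ("variants", "bins", "segments"):
            if key not in spec:
                raise RuntimeError(
                    f"pipeline stage 'load' failed: sample {sid!r} missing {key!r}")
        var_frames.append(formats.read_variants(
            spec["variants"], dialect=spec.get("dialect", "TSV"),
            sample_id=sid, participant_id=row["participant_id"]))
        bins[sid] = formats.read_bins(spec["bins"])
        segments[sid] = formats.read_segments(spec["segments"])
    variants = pd.concat(var_frames, ignore_index=True)

    result = analyse_cohort(variants, bins, segments, manifest, genome,
                            genes=genes, clonal_seed=int(config.get("seed", 0)))

    result.sample_table.to_csv(outdir / "instability.tsv", sep="\t", index=False)
    result.variants.to_csv(outdir / "variants.annotated.tsv", sep="\t", index=False)
    result.divergence.to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    for sid, seg in result.segments.items():
        formats.write_cnvkit_table(seg, outdir / f"{sid}.segments.tsv")
    report = {
        "schema_version": 1,
        "package_version": __version__,
        "seed": int(config.get("seed", 0)),
        "medians": result.medians,
        "outlier_samples": sorted(result.outlier_samples),
        "samples": json.loads(result.sample_table.to_json(orient="records")),
        "clonal": [
            {
                "participant_id": r.participant_id,
                "n_clusters": len(r.clusters),
                "clusters": [
                    {"cluster_id": c.cluster_id, "n_variants": len(c.members),
                     "ccf_per_sample": c.ccf_per_sample} for c in r.clusters
                ],
                "shifts": json.loads(r.shifts.to_json(orient="records"))
                if len(r.shifts) else [],
                "exclusions": json.loads(r.exclusions.to_json(orient="records"))
                if len(r.exclusions) else [],
                "warning": r.warning,
            }
            for r in result.clonal
        ],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (outdir / "run.log").write_text(
        f"package ascites-cfdna {__version__}\n"
        f"python {platform.python_version()}\n"
        f"seed {config.get('seed', 0)}\n"
        f"samples {len(manifest)}\n"
    )
    return result
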