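"""Synthetic ascites-cfDNA cohorts with known ground truth.

Every downstream stage of the pipeline (triage, purity, copy number,
LOH, clonal tracking, instability scoring) is validated against cohorts
generated here, because the measurements the pipeline was designed for
come from patient sequencing that cannot be redistributed.

The generative model, per participant:

* an allele-specific segment layout tiling a reduced panel genome —
  a baseline diploid (1,1) state, alternating balanced gains (2,2)
  planted to create a known number of large-scale-alteration
  boundaries, copy-neutral LOH tracts (2,0), one hemizygous-deletion
  tract (1,0) around TP53 (the double-hit state) and one focal
  amplification;
* a clone tree: a truncal clone at cancer-cell fraction 1 in every
  sample (carrying the deleterious TP53 anchor variant) plus subclones
  whose CCFs differ across serial samples;
* germline heterozygous SNPs at a configurable density per 100-kb bin,
  with population allele-frequency annotations drawn so that a small
  configurable fraction is rare enough to leak through the somatic
  triage filter;
* read counts at each variant from a binomial (or beta-binomial, for
  overdispersion rho > 0) draw around the closed-form expected VAF

      v = (m * t * ccf + g * (1 - t)) / (t * CN_t + 2 * (1 - t))

  where m is the tumour multiplicity, g the normal-cell copies of the
  alternate allele (1 for germline het, 0 for somatic), t the tumour
  fraction and CN_t the local tumour copy number;
* per-bin log2 copy ratios log2((t*CN + 2(1-t))/2) plus Gaussian noise
  — the exact inverse of the purity rescaling applied downstream — and
  segment tables derived from the truth layout, since segmentation
  itself is consumed as input by the pipeline.

Truth and noise are separated: :func:`simulate_truth` fixes the biology
(layout, clones, SNPs, purities), :func:`render_cohort` draws the reads
and bin noise, so technical replicates of one truth use fresh render
seeds.  All randomness flows from ``numpy.random.default_rng``; the same
seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import formats

logger = logging.getLogger(__name__)

MB = 1_000_000
BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Reduced panel genome: contigs, bin size and callable footprint.

    The default emulates a targeted pan-cancer panel profiled in 100-kb
    copy-number bins with a 1.94 Mb small-variant callable footprint.
    Contig lengths are a six-chromosome subset; TP53 and MYC sit at
    their approximate hg19 coordinates on chr17 and chr8.
    """

    contigs: Tuple[Tuple[str, int], ...]
    panel_bins: int = 100_000
    callable_mb: float = 1.94

    def __post_init__(self):
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name} has non-positive length")

    @classmethod
    def default(cls) -> "GenomeModel":
        return cls(
            contigs=(
                ("chr1", 120 * MB),
                ("chr3", 100 * MB),
                ("chr5", 90 * MB),
                ("chr8", 146 * MB),
                ("chr13", 80 * MB),
                ("chr17", 81 * MB),
            )
        )

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.contigs)

    def n_bins(self, contig: str) -> int:
        length = dict(self.contigs)[contig]
        return -(-length // self.panel_bins)  # ceil: last bin truncated

    def bin_table(self) -> pd.DataFrame:
        """All chromosome-limited bins as a 0-based half-open table."""
        rows = []
        for name, length in self.contigs:
            starts = np.arange(0, length, self.panel_bins)
            ends = np.minimum(starts + self.panel_bins, length)
            rows.append(pd.DataFrame({"chromosome": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


TP53_LOCUS = ("chr17", 7_577_539)
MYC_LOCUS = ("chr8", 128_748_315)


def default_gene_bed(genome: GenomeModel) -> pd.DataFrame:
    """Gene intervals for amplification calling on the default genome."""
    genes = pd.DataFrame(
        [
            ("chr17", 7_560_000, 7_600_000, "TP53"),
            ("chr8", 128_740_000, 128_760_000, "MYC"),
            ("chr3", 60_000_000, 60_100_000, "PIK3CA"),
        ],
        columns=["chromosome", "start", "end", "name"],
    )
    present = {c for c, _ in genome.contigs}
    return genes[genes["chromosome"].isin(present)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# truth types
# ---------------------------------------------------------------------------

@dataclass
class TruthSegment:
    """Allele-specific truth segment (0-based half-open)."""

    contig: str
    start: int
    end: int
    allele_cn: Tuple[int, int]  # (a, b); total = a + b

    def __post_init__(self):
        a, b = self.allele_cn
        if a < 0 or b < 0:
            raise ValueError("negative allele copy number")
        if self.end <= self.start:
            raise ValueError("empty segment")

    @property
    def total_cn(self) -> int:
        return sum(self.allele_cn)

    @property
    def is_loh(self) -> bool:
        a, b = self.allele_cn
        return min(a, b) == 0 and self.total_cn >= 1


@dataclass
class TruthClone:
    clone_id: str
    ccf_per_sample: Dict[str, float]
    variants: List[dict] = field(default_factory=list)  # chrom,pos,ref,alt,multiplicity,gene,effect

    def __post_init__(self):
        for s, c in self.ccf_per_sample.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"CCF {c} for sample {s} outside [0,1]")


@dataclass
class ParticipantTruth:
    participant_id: str
    sample_ids: List[str]
    specimens: List[str]
    timepoints: List[int]
    purities: List[float]
    segments: List[TruthSegment]
    clones: List[TruthClone]
    germline: pd.DataFrame  # chrom,pos,ref,alt,multiplicity,af_* columns
    lga_count: int
    loh_bin_fraction: float


@dataclass
class CohortTruth:
    genome: GenomeModel
    participants: List[ParticipantTruth]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genome": {
                "contigs": list(map(list, self.genome.contigs)),
                "panel_bins": self.genome.panel_bins,
                "callable_mb": self.genome.callable_mb,
            },
            "participants": [
                {
                    "participant_id": p.participant_id,
                    "sample_ids": p.sample_ids,
                    "specimens": p.specimens,
                    "timepoints": p.timepoints,
                    "purities": p.purities,
                    "lga_count": p.lga_count,
                    "loh_bin_fraction": p.loh_bin_fraction,
                    "segments": [
                        {"contig": s.contig, "start": s.start, "end": s.end,
                         "allele_cn": list(s.allele_cn)}
                        for s in p.segments
                    ],
                    "clones": [
                        {"clone_id": c.clone_id, "ccf_per_sample": c.ccf_per_sample,
                         "variants": c.variants}
                        for c in p.clones
                    ],
                }
                for p in self.participants
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedCohort:
    """Rendered cohort: observed tables plus the truth that made them."""

    variants: pd.DataFrame  # long table, all samples
    bins: Dict[str, pd.DataFrame]
    segments: Dict[str, pd.DataFrame]
    manifest: pd.DataFrame
    truth: CohortTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        formats.write_manifest(self.manifest, outdir / "manifest.tsv")
        for sid, grp in self.variants.groupby("sample_id", sort=False):
            formats.write_variants(grp, outdir / f"{sid}.variants.tsv")
        for sid, df in self.bins.items():
            formats.write_cnvkit_table(df, outdir / f"{sid}.cnr")
        for sid, df in self.segments.items():
            formats.write_cnvkit_table(df, outdir / f"{sid}.cns")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# cohort configuration — defaults define the emulated study design
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design knobs for the simulator.

    Defaults emulate the sequencing study the pipeline targets: serial
    ascites cfDNA pairs at ~900x mean depth, tumour purity 0.30–0.93,
    a truncal clone plus two subclones, and genomes carrying both
    copy-neutral LOH and multi-boundary copy-number alteration runs.
    """

    genome: GenomeModel = field(default_factory=GenomeModel.default)
    n_participants: int = 6
    samples_per_participant: int = 2
    specimen: str = "cfDNA"
    timepoint_gap_days: Tuple[int, int] = (13, 559)
    purity_range: Tuple[float, float] = (0.30, 0.93)
    purities: Optional[Sequence[Sequence[float]]] = None  # explicit override
    mean_depth: int = 900
    depth_sdlog: float = 0.25
    n_clones: int = 3
    n_truncal_variants: int = 6
    n_subclone_variants: int = 4
    min_ccf_separation: float = 0.2
    loh_fraction: float = 0.4
    loh_fractions: Optional[Sequence[float]] = None  # per-participant override
    lga_range: Tuple[int, int] = (6, 16)
    lga_counts: Optional[Sequence[int]] = None  # explicit override per participant
    truncal_variant_counts: Optional[Sequence[int]] = None  # per-participant override
    germline_snps_per_bin: float = 1.0
    rare_germline_frac: float = 0.0005
    rho: float = 0.005
    bin_noise_sd: float = 0.05
    phase_mode: str = "tract"  # tract | random (germline alt-allele phasing in LOH)
    focal_amp_cn: int = 12
    inject_unreliable_segment: bool = False
    ffpe_extra_variants: int = 0  # applied to FFPE specimens only

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("overdispersion rho must be >= 0")
        if self.phase_mode not in ("tract", "random"):
            raise ValueError("phase_mode must be 'tract' or 'random'")
        if not 0 <= self.loh_fraction < 1:
            raise ValueError("loh_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# closed-form expectations and read-count noise
# ---------------------------------------------------------------------------

def expected_vaf(t: float, ccf: float, multiplicity: int, cn_tumour: int,
                 germline_copies: int = 0) -> float:
    """Expected allele fraction of a variant in a tumour/normal mixture.

    v = (m*t*ccf + g*(1-t)) / (t*CN_t + 2*(1-t)), clipped to [0, 1].
    ``germline_copies`` g is the normal-cell copy count of the alternate
    allele (0 somatic, 1 germline het).  A zero denominator (t = 1 with
    CN 0) returns 0 with a warning: no DNA from that locus at all.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("purity outside [0, 1]")
    if cn_tumour == 0 and multiplicity != 0:
        raise ValueError("multiplicity must be 0 when the tumour copy number is 0")
    if multiplicity > cn_tumour:
        raise ValueError("multiplicity exceeds tumour copy number")
    denom = t * cn_tumour + 2.0 * (1.0 - t)
    if denom == 0:
        warnings.warn("degenerate locus (t=1, CN=0): expected VAF defined as 0")
        return 0.0
    v = (multiplicity * t * ccf + germline_copies * (1.0 - t)) / denom
    return float(np.clip(v, 0.0, 1.0))


def _expected_vaf_array(t, ccf, m, cn, g):
    denom = t * cn + 2.0 * (1.0 - t)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (m * t * ccf + g * (1.0 - t)) / denom
    v = np.where(denom == 0, 0.0, v)
    return np.clip(v, 0.0, 1.0)


def sample_read_counts(expected: float | np.ndarray, depth: int | np.ndarray,
                       rho: float, rng: np.random.Generator):
    """Draw (alt_count, depth) with binomial or beta-binomial noise.

    rho = 0 gives a pure binomial; rho > 0 draws the per-variant success
    probability from Beta(p(1-rho)/rho, (1-p)(1-rho)/rho), giving
    variance inflation typical of targeted cfDNA panels.
    """
    p = np.atleast_1d(np.asarray(expected, dtype=float))
    n = np.atleast_1d(np.asarray(depth, dtype=int))
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if rho == 0:
        alt = rng.binomial(n, p)
    else:
        scale = (1.0 - rho) / rho
        interior = (p > 0) & (p < 1)
        pp = p.copy()
        if interior.any():
            pp_draw = rng.beta(np.maximum(p[interior] * scale, 1e-12),
                               np.maximum((1.0 - p[interior]) * scale, 1e-12))
            pp[interior] = pp_draw
        alt = rng.binomial(n, pp)
    if np.isscalar(expected) or np.ndim(expected) == 0:
        return int(alt[0]), int(n[0])
    return alt, n


# ---------------------------------------------------------------------------
# segment-layout construction
# ---------------------------------------------------------------------------

def random_segment_layout(contig: str, length: int, n_boundaries: int,
                          rng: np.random.Generator, bin_size: int = 100_000,
                          min_len: int = 10 * MB, cn_states: Tuple[int, int] = (2, 4),
                          ) -> List[TruthSegment]:
    """One contig split into n_boundaries+1 alternating-CN segments, each
    strictly longer than ``min_len`` and snapped to the bin grid.

    The alternation uses balanced allele states ((1,1) and (2,2)) so the
    layout perturbs total copy number without creating allelic imbalance.
    """
    k = n_boundaries + 1
    base = min_len + 5 * bin_size  # strictly > min_len with headroom
    if k * base > length:
        raise ValueError(f"{contig}: cannot fit {k} segments > {min_len} bp")
    spare_bins = (length - k * base) // bin_size
    w = rng.dirichlet(np.ones(k))
    extra = np.floor(w * spare_bins).astype(int)
    lengths = base + extra * bin_size
    lengths[-1] = length - int(lengths[:-1].sum())
    alleles = [(1, 1), (2, 2)]
    segs, pos = [], 0
    for i, ln in enumerate(lengths):
        segs.append(TruthSegment(contig, pos, pos + int(ln), alleles[i % 2]))
        pos += int(ln)
    return segs


def plant_lga_layout(genome: GenomeModel, k: int, rng: np.random.Generator,
                     min_len: int = 10 * MB) -> List[TruthSegment]:
    """Genome-wide layout with exactly ``k`` qualifying LGA boundaries."""
    caps = {}
    for name, length in genome.contigs:
        caps[name] = max(length // (min_len + 10 * genome.panel_bins) - 1, 0)
    if sum(caps.values()) < k:
        raise ValueError(f"genome too small for {k} LGA boundaries")
    order = list(dict(genome.contigs))
    rng.shuffle(order)
    alloc = {name: 0 for name in order}
    remaining = k
    for name in order:
        take = min(caps[name], remaining)
        alloc[name] = take
        remaining -= take
        if remaining == 0:
            break
    segs = []
    for name, length in genome.contigs:
        segs.extend(random_segment_layout(name, length, alloc[name], rng,
                                          bin_size=genome.panel_bins, min_len=min_len))
    return segs


def _overlay(segments: List[TruthSegment], contig: str, start: int, end: int,
             allele_cn: Tuple[int, int]) -> List[TruthSegment]:
    """Replace [start, end) on one contig with a new allele state,
    splitting whatever segments it intersects."""
    out = []
    for s in segments:
        if s.contig != contig or s.end <= start or s.start >= end:
            out.append(s)
            continue
        if s.start < start:
            out.append(TruthSegment(contig, s.start, start, s.allele_cn))
        if s.end > end:
            out.append(TruthSegment(contig, end, s.end, s.allele_cn))
    out.append(TruthSegment(contig, start, end, allele_cn))
    out.sort(key=lambda s: (s.contig, s.start))
    return out


def _snap(pos: int, bin_size: int) -> int:
    return (pos // bin_size) * bin_size


def _add_loh_tracts(segments: List[TruthSegment], genome: GenomeModel,
                    target_fraction: float, rng: np.random.Generator
                    ) -> List[TruthSegment]:
    """Overlay copy-neutral LOH tracts (2,0) on diploid (1,1) regions
    until the genome-wide LOH bin fraction reaches the target."""
    bin_size = genome.panel_bins
    total = genome.total_length
    contig_len = dict(genome.contigs)
    names = list(contig_len)

    def loh_len(segs):
        return sum(s.end - s.start for s in segs if s.is_loh)

    attempts = 0
    while loh_len(segments) < target_fraction * total and attempts < 4000:
        attempts += 1
        contig = names[rng.integers(len(names))]
        length = _snap(int(rng.uniform(5 * MB, 20 * MB)), bin_size)
        start = _snap(int(rng.uniform(0, contig_len[contig] - length)), bin_size)
        end = start + length
        # only convert pure diploid stretches: keeps total CN (hence the
        # segment table and LGA truth) untouched
        covering = [s for s in segments
                    if s.contig == contig and s.start < end and s.end > start]
        if any(s.allele_cn != (1, 1) for s in covering):
            continue
        segments = _overlay(segments, contig, start, end, (2, 0))
    if loh_len(segments) < target_fraction * total:
        logger.warning("LOH target fraction %.2f not reached (%.3f)",
                       target_fraction, loh_len(segments) / total)
    return segments


def merge_cn_segments(segments: List[TruthSegment]) -> pd.DataFrame:
    """Total-CN segment table: adjacent truth segments with equal total
    copy number merge (allele states are invisible to read-depth data)."""
    rows = []
    for s in sorted(segments, key=lambda s: (s.contig, s.start)):
        if rows and rows[-1]["chromosome"] == s.contig and rows[-1]["end"] == s.start \
                and rows[-1]["cn"] == s.total_cn:
            rows[-1]["end"] = s.end
        else:
            rows.append({"chromosome": s.contig, "start": s.start, "end": s.end,
                         "cn": s.total_cn})
    return pd.DataFrame(rows)


def _truth_lga_count(cn_segments: pd.DataFrame, min_len: int = 10 * MB) -> int:
    """Generator-side accounting of qualifying-boundary count."""
    count = 0
    for _, grp in cn_segments.groupby("chromosome", sort=False):
        qual = grp[(grp["end"] - grp["start"]) > min_len].sort_values("start")
        cns = qual["cn"].to_numpy()
        count += int(np.sum(cns[1:] != cns[:-1]))
    return count


def _truth_loh_fraction(segments: List[TruthSegment], genome: GenomeModel) -> float:
    loh = sum(s.end - s.start for s in segments if s.is_loh)
    return loh / genome.total_length


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def _draw_subclone_ccfs(n_sub: int, n_samples: int, sep: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Subclone CCF matrix with pairwise L-infinity separation >= sep
    (also against the truncal clone at 1.0 everywhere)."""
    for _ in range(2000):
        ccfs = rng.uniform(0.05, 0.85, size=(n_sub, n_samples)).round(2)
        all_rows = np.vstack([np.ones((1, n_samples)), ccfs])
        ok = True
        for i in range(len(all_rows)):
            for j in range(i + 1, len(all_rows)):
                if np.max(np.abs(all_rows[i] - all_rows[j])) < sep:
                    ok = False
        if ok:
            return ccfs
    raise RuntimeError("could not draw separated subclone CCFs")


def _random_locus(segments: List[TruthSegment], rng: np.random.Generator,
                  min_cn: int = 1) -> Tuple[str, int, TruthSegment]:
    candidates = [s for s in segments if s.total_cn >= min_cn]
    w = np.array([s.end - s.start for s in candidates], dtype=float)
    seg = candidates[rng.choice(len(candidates), p=w / w.sum())]
    pos = int(rng.integers(seg.start + 1, seg.end + 1))  # 1-based inclusive
    return seg.contig, pos, seg


def _segment_at(segments: List[TruthSegment], contig: str, pos: int) -> TruthSegment:
    for s in segments:
        if s.contig == contig and s.start < pos <= s.end:
            return s
    raise KeyError(f"no truth segment at {contig}:{pos}")


def _draw_alleles(rng, n):
    ref = BASES[rng.integers(0, 4, n)]
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return ref, alt


def simulate_truth(config: CohortConfig, seed: int) -> CohortTruth:
    """Fix the cohort biology: layouts, clones, SNPs, purities."""
    rng = np.random.default_rng(seed)
    genome = config.genome
    contig_len = dict(genome.contigs)
    participants = []
    for pi in range(config.n_participants):
        pid = f"P{pi + 1:02d}"
        n_samples = config.samples_per_participant
        sample_ids = [f"{pid}-{config.specimen.lower()}{j + 1}" for j in range(n_samples)]
        timepoints = [0] + sorted(
            int(rng.integers(*config.timepoint_gap_days)) for _ in range(n_samples - 1)
        )
        if config.purities is not None:
            purities = [float(t) for t in config.purities[pi]]
        else:
            purities = [float(np.round(rng.uniform(*config.purity_range), 3))
                        for _ in range(n_samples)]

        # ---- copy-number layout ---------------------------------------
        reserved = {c for c, _ in (TP53_LOCUS, MYC_LOCUS) if c in contig_len}
        if config.lga_counts is not None:
            k = int(config.lga_counts[pi])
        else:
            k = int(rng.integers(config.lga_range[0], config.lga_range[1] + 1))
        free_genome = GenomeModel(
            contigs=tuple((c, l) for c, l in genome.contigs if c not in reserved),
            panel_bins=genome.panel_bins, callable_mb=genome.callable_mb)
        segments = plant_lga_layout(free_genome, k, rng)
        for c in reserved:
            segments.append(TruthSegment(c, 0, contig_len[c], (1, 1)))
        segments.sort(key=lambda s: (s.contig, s.start))

        # TP53 double-hit deletion tract: < 10 Mb so it adds no LGA
        if TP53_LOCUS[0] in contig_len:
            c, p = TP53_LOCUS
            start = _snap(p - 3 * MB, genome.panel_bins)
            segments = _overlay(segments, c, start, start + 6 * MB, (1, 0))
        # focal amplification around MYC: < 10 Mb, strongly imbalanced
        if MYC_LOCUS[0] in contig_len:
            c, p = MYC_LOCUS
            start = _snap(p - 1 * MB, genome.panel_bins)
            segments = _overlay(segments, c, start, start + 2 * MB,
                                (config.focal_amp_cn - 1, 1))
        loh_target = (config.loh_fractions[pi] if config.loh_fractions is not None
                      else config.loh_fraction)
        segments = _add_loh_tracts(segments, genome, loh_target, rng)

        # ---- clones ----------------------------------------------------
        clones: List[TruthClone] = []
        truncal = TruthClone("truncal", {s: 1.0 for s in sample_ids})
        if TP53_LOCUS[0] in contig_len:
            ref, alt = _draw_alleles(rng, 1)
            truncal.variants.append({
                "chrom": TP53_LOCUS[0], "pos": TP53_LOCUS[1], "ref": str(ref[0]),
                "alt": str(alt[0]), "multiplicity": 1, "gene": "TP53",
                "effect": "deleterious",
            })
        n_truncal = (config.truncal_variant_counts[pi]
                     if config.truncal_variant_counts is not None
                     else config.n_truncal_variants)
        for vi in range(n_truncal - len(truncal.variants)):
            chrom, pos, seg = _random_locus(segments, rng)
            ref, alt = _draw_alleles(rng, 1)
            truncal.variants.append({
                "chrom": chrom, "pos": pos, "ref": str(ref[0]), "alt": str(alt[0]),
                "multiplicity": 1, "gene": f"GENE{rng.integers(100)}",
                "effect": "missense",
            })
        clones.append(truncal)
        n_sub = max(config.n_clones - 1, 0)
        if n_sub:
            ccfs = _draw_subclone_ccfs(n_sub, n_samples, config.min_ccf_separation, rng)
            for si in range(n_sub):
                clone = TruthClone(f"subclone{si + 1}",
                                   {s: float(c) for s, c in zip(sample_ids, ccfs[si])})
                for _ in range(config.n_subclone_variants):
                    chrom, pos, seg = _random_locus(segments, rng)
                    ref, alt = _draw_alleles(rng, 1)
                    clone.variants.append({
                        "chrom": chrom, "pos": pos, "ref": str(ref[0]),
                        "alt": str(alt[0]), "multiplicity": 1,
                        "gene": f"GENE{rng.integers(100)}", "effect": "missense",
                    })
                clones.append(clone)

        # ---- germline heterozygous SNPs -------------------------------
        germline = _simulate_germline(segments, genome, config, rng)

        cn_table = merge_cn_segments(segments)
        participants.append(ParticipantTruth(
            participant_id=pid, sample_ids=sample_ids,
            specimens=[config.specimen] * n_samples,
            timepoints=timepoints, purities=purities, segments=segments,
            clones=clones, germline=germline,
            lga_count=_truth_lga_count(cn_table),
            loh_bin_fraction=_truth_loh_fraction(segments, genome),
        ))
    return CohortTruth(genome=genome, participants=participants)


def _simulate_germline(segments: List[TruthSegment], genome: GenomeModel,
                       config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Heterozygous SNPs with per-segment haplotype-consistent phasing.

    Each truth segment carries two haplotype copy counts (a, b).  The
    alternate allele of each SNP sits on one haplotype; in ``tract``
    phase mode one haplotype per segment carries the alt alleles of all
    its SNPs (panel LOH detection by mean VAF relies on this coherence),
    in ``random`` mode each SNP phases independently.
    """
    rows = []
    for s in segments:
        n_bins_seg = max((s.end - s.start) // genome.panel_bins, 1)
        n = rng.poisson(config.germline_snps_per_bin * n_bins_seg)
        if n == 0:
            continue
        pos = np.sort(rng.integers(s.start + 1, s.end + 1, size=n))
        a, b = s.allele_cn
        if config.phase_mode == "tract":
            hap = np.full(n, rng.integers(2))
        else:
            hap = rng.integers(0, 2, size=n)
        mult = np.where(hap == 0, a, b)
        ref, alt = _draw_alleles(rng, n)
        rare = rng.random(n) < config.rare_germline_frac
        af_ex = np.where(rare, 0.0, rng.uniform(0.01, 0.5, n))
        af_ge = np.where(rare, 0.0, rng.uniform(0.01, 0.5, n))
        af_kg = np.where(rare, 0.0, rng.uniform(0.02, 0.5, n))
        rows.append(pd.DataFrame({
            "chrom": s.contig, "pos": pos, "ref": ref, "alt": alt,
            "multiplicity": mult, "cn_tumour": s.total_cn,
            "af_gnomad_exome": af_ex, "af_gnomad_genome": af_ge, "af_1000g": af_kg,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "multiplicity",
                                     "cn_tumour", "af_gnomad_exome",
                                     "af_gnomad_genome", "af_1000g"])
    df = pd.concat(rows, ignore_index=True)
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# rendering: reads and bins from a fixed truth
# ---------------------------------------------------------------------------

def _draw_depths(n, config: CohortConfig, rng) -> np.ndarray:
    d = rng.lognormal(np.log(config.mean_depth), config.depth_sdlog, size=n)
    return np.maximum(d.astype(int), 30)


def render_sample(part: ParticipantTruth, sample_ix: int, genome: GenomeModel,
                  config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Observed variant table for one sample of one participant.

    Every truth variant of the participant (germline and somatic in any
    clone) yields exactly one row; non-detection shows as alt_count 0.
    """
    sid = part.sample_ids[sample_ix]
    t = part.purities[sample_ix]

    frames = []
    g = part.germline
    if len(g):
        exp = _expected_vaf_array(t, 1.0, g["multiplicity"].to_numpy(float),
                                  g["cn_tumour"].to_numpy(float), 1.0)
        depth = _draw_depths(len(g), config, rng)
        alt, depth = sample_read_counts(exp, depth, config.rho, rng)
        frames.append(pd.DataFrame({
            "chrom": g["chrom"], "pos": g["pos"], "ref": g["ref"], "alt": g["alt"],
            "alt_count": alt, "depth": depth,
            "af_gnomad_exome": g["af_gnomad_exome"],
            "af_gnomad_genome": g["af_gnomad_genome"], "af_1000g": g["af_1000g"],
            "gene": None, "effect": None, "truth_class": "germline",
            "truth_ccf": 1.0,
        }))
    for clone in part.clones:
        if not clone.variants:
            continue
        cv = pd.DataFrame(clone.variants)
        cn = np.array([_segment_at(part.segments, c, p).total_cn
                       for c, p in zip(cv["chrom"], cv["pos"])], dtype=float)
        ccf = clone.ccf_per_sample[sid]
        exp = _expected_vaf_array(t, ccf, cv["multiplicity"].to_numpy(float), cn, 0.0)
        depth = _draw_depths(len(cv), config, rng)
        alt, depth = sample_read_counts(exp, depth, config.rho, rng)
        frames.append(pd.DataFrame({
            "chrom": cv["chrom"], "pos": cv["pos"], "ref": cv["ref"], "alt": cv["alt"],
            "alt_count": alt, "depth": depth,
            "af_gnomad_exome": np.nan, "af_gnomad_genome": np.nan, "af_1000g": np.nan,
            "gene": cv["gene"], "effect": cv["effect"],
            "truth_class": f"somatic:{clone.clone_id}", "truth_ccf": ccf,
        }))
    df = pd.concat(frames, ignore_index=True)
    df["vaf"] = df["alt_count"] / df["depth"]
    df["sample_id"] = sid
    df["participant_id"] = part.participant_id
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def render_bins_and_segments(part: ParticipantTruth, sample_ix: int,
                             genome: GenomeModel, config: CohortConfig,
                             rng: np.random.Generator
                             ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin log2 table (.cnr dialect) and truth-derived segment table
    (.cns) for one sample."""
    t = part.purities[sample_ix]
    bins = genome.bin_table().copy()
    cn_table = merge_cn_segments(part.segments)

    mid = (bins["start"] + bins["end"]) // 2
    bin_cn = np.full(len(bins), 2.0)
    for _, seg in cn_table.iterrows():
        sel = ((bins["chromosome"] == seg["chromosome"]) & (mid >= seg["start"])
               & (mid < seg["end"]))
        bin_cn[sel.to_numpy()] = seg["cn"]
    with np.errstate(divide="ignore"):
        log2_true = np.log2(np.maximum(t * bin_cn + 2 * (1 - t), 1e-6) / 2.0)
    bins["log2"] = log2_true + rng.normal(0.0, config.bin_noise_sd, len(bins))
    bins["depth"] = np.maximum(
        rng.lognormal(np.log(config.mean_depth), config.depth_sdlog, len(bins)), 1.0
    ).round(1)
    bins["weight"] = 1.0

    # Segment mean depth is drawn directly: inter-segment depth spread in
    # panel data reflects target/GC capture bias shared across a region,
    # not the CLT shrinkage of independent per-bin draws.
    seg_rows = []
    for _, seg in cn_table.iterrows():
        sel = ((bins["chromosome"] == seg["chromosome"]) & (mid >= seg["start"])
               & (mid < seg["end"])).to_numpy()
        seg_rows.append({
            "chromosome": seg["chromosome"], "start": int(seg["start"]),
            "end": int(seg["end"]), "log2": float(bins.loc[sel, "log2"].mean()),
            "depth": float(np.round(rng.lognormal(np.log(config.mean_depth), 0.10), 1)),
            "weight": int(sel.sum()),
        })
    segments = pd.DataFrame(seg_rows)

    if config.inject_unreliable_segment and len(segments) > 2:
        j = len(segments) // 2
        segments.loc[j, "depth"] *= 8
        segments.loc[j, "log2"] += 1.5
    return bins, segments


def inject_ffpe_artifacts(variants: pd.DataFrame, n_extra: int,
                          vaf_range: Tuple[float, float], rng: np.random.Generator,
                          genome: Optional[GenomeModel] = None) -> pd.DataFrame:
    """Add formalin-artifact-like noise variants to one sample's table.

    Artefacts are low-VAF variants at random loci with population AF 0,
    so they pass the somatic triage filter and inflate the sample's
    total variant count — the behaviour that makes artefact-laden FFPE
    samples stand out as cohort outliers.
    """
    if n_extra == 0:
        return variants
    genome = genome or GenomeModel.default()
    contigs = list(genome.contigs)
    idx = rng.integers(0, len(contigs), n_extra)
    pos = np.array([rng.integers(1, contigs[i][1] + 1) for i in idx])
    ref, alt = _draw_alleles(rng, n_extra)
    vaf = rng.uniform(*vaf_range, n_extra)
    depth = _draw_depths(n_extra, CohortConfig(genome=genome), rng)
    alt_count = np.maximum(np.round(vaf * depth).astype(int), 1)
    extra = pd.DataFrame({
        "chrom": [contigs[i][0] for i in idx], "pos": pos, "ref": ref, "alt": alt,
        "alt_count": alt_count, "depth": depth, "vaf": alt_count / depth,
        "af_gnomad_exome": 0.0, "af_gnomad_genome": 0.0, "af_1000g": 0.0,
        "gene": None, "effect": None, "truth_class": "ffpe_artifact",
        "truth_ccf": 0.0,
    })
    for col in ("sample_id", "participant_id"):
        if col in variants.columns and len(variants):
            extra[col] = variants[col].iloc[0]
    return pd.concat([variants, extra], ignore_index=True)


def render_cohort(truth: CohortTruth, config: CohortConfig, seed: int) -> SimulatedCohort:
    """Draw reads and bin noise for a fixed truth (technical replicate)."""
    rng = np.random.default_rng(seed)
    var_frames, bins, segments = [], {}, {}
    man_rows = []
    for part in truth.participants:
        for j, sid in enumerate(part.sample_ids):
            v = render_sample(part, j, truth.genome, config, rng)
            if config.ffpe_extra_variants and part.specimens[j] == "FFPE":
                v = inject_ffpe_artifacts(v, config.ffpe_extra_variants,
                                          (0.01, 0.10), rng, truth.genome)
            var_frames.append(v)
            b, s = render_bins_and_segments(part, j, truth.genome, config, rng)
            bins[sid], segments[sid] = b, s
            man_rows.append({
                "participant_id": part.participant_id, "sample_id": sid,
                "specimen": part.specimens[j], "timepoint_days": part.timepoints[j],
            })
    manifest = formats.validate_manifest(pd.DataFrame(man_rows))
    return SimulatedCohort(
        variants=pd.concat(var_frames, ignore_index=True),
        bins=bins, segments=segments, manifest=manifest, truth=truth,
    )


def simulate_cohort(config: CohortConfig, seed: int) -> SimulatedCohort:
    """Simulate a full cohort: truth plus one rendering.

    Deterministic: the same (config, seed) pair reproduces the cohort
    byte-for-byte.  Truth and rendering consume independent child seeds
    so replicates of the same truth can be drawn with
    :func:`render_cohort`.
    """
    truth_seed, render_seed = np.random.SeedSequence(seed).spawn(2)
    truth = simulate_truth(config, truth_seed.generate_state(1)[0] % (2**31))
    return render_cohort(truth, config, render_seed.generate_state(1)[0] % (2**31))
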