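import warnings

import numpy as np
import pandas as pd
import pytest

from ascites_cfdna import CohortConfig, simulate_cohort
from ascites_cfdna.synthetic import GenomeModel

warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_genome():
    """Three-contig genome small enough for fast per-test simulation."""
    return GenomeModel(
        contigs=(("chr1", 60_000_000), ("chr8", 146_000_000), ("chr17", 81_000_000))
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared by read-only tests."""
    return simulate_cohort(CohortConfig(n_participants=3), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_variant(**kw):
    """A single variant record as a Series with sensible defaults."""
    base = dict(chrom="chr17", pos=7_577_539, ref="G", alt="A",
                alt_count=30, depth=100, vaf=0.3,
                af_gnomad_exome=np.nan, af_gnomad_genome=np.nan, af_1000g=np.nan,
                gene=None, effect=None, sample_id="S1", participant_id="P1")
    base.update(kw)
    base["vaf"] = base["alt_count"] / base["depth"]
    return pd.Series(base)
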