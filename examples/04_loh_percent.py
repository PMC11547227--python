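"""Loss of heterozygosity as a percentage of 100-kb bins.

Simulates genomes with known LOH tract fractions at 70% purity and 500x
depth, then measures the share of occupied bins whose mean germline-SNP
VAF leaves the 0.4-0.6 band.
"""

import warnings

warnings.filterwarnings("ignore")

import ascites_cfdna as ac
from ascites_cfdna.loh import loh_percent

for f, seed in ((0.1, 31), (0.3, 32), (0.6, 33)):
    cfg = ac.CohortConfig(n_participants=1, samples_per_participant=1,
                          purities=[[0.7]], loh_fraction=f, lga_counts=[4],
                          germline_snps_per_bin=5.0, mean_depth=500, rho=0.0)
    c = ac.simulate_cohort(cfg, seed)
    planted = 100 * c.truth.participants[0].loh_bin_fraction
    res = loh_percent(c.variants[c.variants["alt_count"] > 0], c.truth.genome)
    print(f"planted LOH {planted:5.1f}% of bins  ->  measured {res.loh_percent:5.1f}%"
          f"  (occupied bins {res.occupied_bins}, reliable={res.reliable},"
          f" exceeds 16% HRD cut-off: {res.exceeds_coleman_cutoff})")

print()
print("Heterozygous SNPs sit at VAF 0.5 in balanced regions; allelic "
      "imbalance pushes bin means outside 0.4-0.6 in proportion to tumour "
      "content. The measurement tracks the planted fraction to within a few "
      "percentage points; samples under 150x or median VAF < 0.1 are flagged "
      "unreliable instead.")
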