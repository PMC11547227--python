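"""Tumour purity from the TP53 double-hit model.

In high-grade serous ovarian cancer one TP53 point mutation plus loss of
the wild-type allele leaves tumour cells with a single mutant copy, so
the mutant VAF reads out tumour fraction: t = 2v/(1+v).
"""

import numpy as np

from ascites_cfdna.purity import purity_from_tp53_vaf, vaf_from_purity

for v in (0.1, 1 / 3, 0.5, 0.88):
    print(f"TP53 VAF {v:.3f}  ->  tumour fraction {purity_from_tp53_vaf(v):.3f}")

print()
rng = np.random.default_rng(0)
for t in (0.25, 0.5, 0.75, 0.93):
    v_hat = rng.binomial(1000, vaf_from_purity(t), size=200) / 1000
    est = purity_from_tp53_vaf(v_hat).mean()
    print(f"planted purity {t:.2f}: mean estimate over 200 draws at 1000x = {est:.4f}")

print()
print("A VAF of 0.88 maps to ~94% tumour content; the simulation shows the "
      "estimator is unbiased to within +/-0.02 at 1000x depth.")
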