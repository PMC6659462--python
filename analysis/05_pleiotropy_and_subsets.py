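"""Pleiotropy screen and instrument-subset over-identification contrast.

The per-variant screen converts outcome log-odds to SD units and flags
variants with larger outcome than exposure effects; under the no-pleiotropy
generative law none should be flagged beyond noise. The over-identification
test contrasts IVW estimates from the two instrument subsets (the
neuronal-like / non-neuronal-like split), which instrument the same exposure
and should agree.
"""

import pandas as pd

from common import COHORT_CONFIG, get_scored, save
from mrkit.inference import overidentification_test, pleiotropy_screen
from mrkit.sumstats import harmonize
from mrkit.synthetic import cohort_to_summary_stats

cohort, tp, instruments, score = get_scored()
exp = cohort_to_summary_stats(cohort, "exposure").rename(columns={"SNP": "snp"})
out = cohort_to_summary_stats(cohort, "outcome").rename(columns={"SNP": "snp"})
pairs, _ = harmonize(exp, out)

screen = pleiotropy_screen(pairs, COHORT_CONFIG.case_fraction)
path = save(screen, "05_pleiotropy_screen.tsv")
print(f"pleiotropy screen: {int(screen['flagged'].sum())}/{len(screen)} variants flagged")

labels = instruments.labels()
pa = pairs[pairs["snp"].isin(instruments.subset(labels[0]).snps)]
pb = pairs[pairs["snp"].isin(instruments.subset(labels[1]).snps)]
comp = overidentification_test(pa, pb, labels[0], labels[1])
contrast = pd.DataFrame([{
    "subset_a": labels[0], "estimate_a": comp.estimate_a.beta, "se_a": comp.estimate_a.se,
    "subset_b": labels[1], "estimate_b": comp.estimate_b.beta, "se_b": comp.estimate_b.se,
    "z": comp.z, "p_difference": comp.p_difference,
}])
cpath = save(contrast, "05_subset_contrast.tsv")
print(f"over-identification: {labels[0]} {comp.estimate_a.beta:.3f} vs "
      f"{labels[1]} {comp.estimate_b.beta:.3f}, p_difference = {comp.p_difference:.2f}")
print(f"wrote {path} and {cpath}")
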