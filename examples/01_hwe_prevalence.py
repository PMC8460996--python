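"""Hardy-Weinberg birth prevalence from survey allele frequencies.

Builds a small synthetic tested-children table, estimates weighted A/S/C
allele frequencies, expands them to genotype prevalences under HWE and
attaches a stratified cluster-bootstrap CI.
"""

import numpy as np
import pandas as pd

from scdmort import AlleleFrequencies, hwe_genotypes, hwe_prevalence_with_ci

# national allele frequencies like Nigeria's: A 88%, S 11%, C 1%
freqs = AlleleFrequencies(0.880, 0.110, 0.010)
dist = hwe_genotypes(freqs)
print(f"HWE birth prevalence of HbSS: {100 * dist['SS']:.2f}%")
print(f"HWE birth prevalence of HbSC: {100 * dist['SC']:.2f}%")
# 1.21% of births carry HbSS when the S allele frequency is 11%.

# a toy survey: 40 clusters x 30 children drawn from those frequencies
rng = np.random.default_rng(0)
genotypes = ["AA", "AS", "AC", "SS", "SC", "CC"]
rows = [
    {
        "stratum_id": c % 4,
        "cluster_id": c,
        "child_id": f"{c}-{i}",
        "genotype": rng.choice(genotypes, p=dist.probs),
        "weight": rng.uniform(0.5, 1.5),
    }
    for c in range(40)
    for i in range(30)
]
survey = pd.DataFrame(rows)
result = hwe_prevalence_with_ci(survey, ("SS",), n_reps=500, seed=1)["SS"]
print(
    f"estimated HbSS prevalence: {100 * result.point:.2f}% "
    f"(95% CI {100 * result.lower:.2f}-{100 * result.upper:.2f})"
)
# The CI resamples survey clusters within strata, so it reflects the
# clustering of children within households and villages.
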