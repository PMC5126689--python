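"""Function inference by co-expression and median-split survival.

Profiles a lincRNA against all coding genes under a shuffled-pair null,
runs hypergeometric gene-set enrichment on its co-expressed set, then
tests a planted survival association with Kaplan-Meier / log-rank / Cox.
"""

import numpy as np
import pandas as pd

from lincsig import synthdata
from lincsig.clinical import hazard_ratio, logrank_test, median_split
from lincsig.function_inference import coexpressed_set, hypergeom_enrichment, shuffled_null

rng = np.random.default_rng(13)
n_samp, n_genes = 85, 120
latent = rng.normal(size=n_samp)
linc = latent + 0.6 * rng.normal(size=n_samp)
G = rng.normal(size=(n_genes, n_samp))
for g in range(12):  # a co-regulated module
    G[g] = latent + 0.8 * rng.normal(size=n_samp)
genes = pd.DataFrame(G, index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{j}" for j in range(n_samp)])

# null from many lincRNA rows so one module cannot dominate the shuffle
linc_pool = pd.DataFrame(
    np.vstack([linc, rng.normal(size=(19, n_samp))]),
    index=["L"] + [f"L{i}" for i in range(19)], columns=genes.columns,
)
_, null_q = shuffled_null(linc_pool, genes, n_shuffles=1000, seed=14)
prof = coexpressed_set("L", linc, genes, threshold=0.4, null_quantiles=null_q)
sets = {"MODULE": {f"g{i}" for i in range(12)},
        "RANDOM": {f"g{i}" for i in rng.choice(n_genes, 12, replace=False)}}
enr = hypergeom_enrichment(prof.coexpressed, sets, set(genes.index))
print(f"null 99.5% quantile: {null_q[1]:.2f}; effective threshold: {prof.threshold:.2f}")
print(f"co-expressed genes: {len(prof.coexpressed)}")
print(enr[["overlap", "set_size", "p_raw", "p_bh"]].round(6))

surv = synthdata.gen_survival(200, survival_hr=3.0, censor_rate=0.2, seed=15)
hi = surv["group"] == "high"
chi2, p = logrank_test(surv.loc[hi, "time"], surv.loc[hi, "event"],
                       surv.loc[~hi, "time"], surv.loc[~hi, "event"])
hr, (lo, up) = hazard_ratio(surv["time"], surv["event"], surv["group"])
print(f"\nplanted HR = 3.0: estimated HR {hr:.2f} (95% CI {lo:.2f}-{up:.2f}), "
      f"log-rank chi2 {chi2:.1f}, p {p:.2e}")
# The co-regulated module dominates the enrichment and the Cox estimate
# brackets the planted hazard ratio.
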