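"""Closed-form heterogeneity measures across a range of cluster variances.

Computes ICC, MOR, SOI and the 80% interval odds ratio for the canonical
fixed effects (beta0=0.5, beta1=-1.5, beta2=0.3, alpha=-0.3) at four
between-cluster variances.  These are analytic true values — no data are
involved — and serve as the reference against which simulation estimates
are judged.
"""

from clusterhet import true_values_table

table = true_values_table([0.2, 0.5, 1.0, 1.5])
print(table.round(4).to_string(index=False))
print(
    "\nReading: at sigma2_u = 0.5, 13.2% of latent outcome variance is "
    "between clusters (ICC);\na median cluster swap multiplies the odds by "
    "1.96 (MOR); the IOR-80 spans 1, so residual\ncluster heterogeneity "
    "dominates the cluster-covariate effect (SOI 38% < 50% reflects the\n"
    "negative alpha)."
)
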