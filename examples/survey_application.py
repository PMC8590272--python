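"""Heterogeneity analysis of a survey-structured dataset.

Builds a synthetic dataset with the skeleton of a community-clustered child
health survey (850 communities of 1-15 children, between-community variance
0.455, outcome prevalence ~0.63, a binary urban/rural-style community
covariate), then runs the full apply workflow: an unadjusted model
(intercept + random effect) and a covariate-adjusted model, each summarised
by the four heterogeneity measures with qualitative annotations.
"""

from pathlib import Path
from tempfile import mkdtemp

from clusterhet import application_preset, apply_workflow

out_dir = Path(mkdtemp(prefix="clusterhet_apply_"))
dataset = application_preset(seed=3)
csv = out_dir / "survey.csv"
dataset.to_csv(csv)

report = apply_workflow(csv, out_dir, seed=3)
print((out_dir / "apply_report.txt").read_text())
print(
    "The adjusted sigma2_u should land near the generating 0.455, giving "
    "ICC near 0.12 and\nMOR near 1.9; with a community-covariate odds ratio "
    "near 1.2, the IOR-80 spans 1 and the\nSOI sits near 50%: unexplained "
    "community heterogeneity outweighs the covariate effect."
)
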