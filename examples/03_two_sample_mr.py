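"""Two-sample MR: exposure and outcome measured in different cohorts.

Cohort 1 has genotypes + the exposure; cohort 2 has genotypes + the trait.
The causal effect (truth 0.5) is the trait-side variant effect divided by the
exposure-side variant effect, and the genetically predicted exposure in
cohort 2 tracks the true (unmeasured) exposure with slope ~1.
"""

import numpy as np

import mrnet
from mrnet.synthetic import summary_for_entity

spec = mrnet.SemSpec(
    entity_ids=["X"], adjacency=np.zeros((1, 1)), iv_map={"X": (["iv_X"], np.array([0.5]))}
)
trait = mrnet.TraitSpec(parent_entities=["X"], effects=np.array([0.5]))
cohort1, cohort2, summaries = mrnet.make_two_sample(
    spec, trait, n1=10_000, n2=10_000, seeds=(11, 12), maf=0.3
)

row_x = summary_for_entity(summaries["exposure"], "X").iloc[0]
row_y = summaries["outcome"].iloc[0]
est = mrnet.wald_ratio(row_y["beta"], row_y["se"], row_x["beta"], row_x["se"])
print(f"variant effect on X (cohort 1): {row_x['beta']:.3f} +/- {row_x['se']:.3f}")
print(f"variant effect on trait (cohort 2): {row_y['beta']:.3f} +/- {row_y['se']:.3f}")
print(
    f"two-sample causal estimate: {est.beta:.3f} (truth 0.5), "
    f"95% CI ({est.ci[0]:.3f}, {est.ci[1]:.3f})"
)

xhat = mrnet.two_sample_predict(
    summary_for_entity(summaries["exposure"], "X"), cohort2["genotypes"]
)
# cohort 2's exposure is never measured in practice; regenerate it here only
# to show the predictor is unbiased
_, omics2 = mrnet.simulate_dataset(spec, 10_000, seed=12, maf=0.3)
slope = np.polyfit(xhat, omics2["X"], 1)[0]
print(f"slope of true X on predicted X-hat in cohort 2: {slope:.3f} (expect ~1)")
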