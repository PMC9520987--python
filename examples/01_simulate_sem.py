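"""Simulate an instrumented linear-Gaussian SEM and check it against its
closed-form covariance.

Builds a sparse random DAG over 8 metabolite-like entities, attaches one
genetic instrument per entity, draws 20,000 samples, and compares the
empirical covariance with the analytic (I - W)^-T S (I - W)^-1.
"""

import numpy as np

import mrnet

spec = mrnet.attach_instruments(
    mrnet.sample_random_dag(8, expected_out_degree=1.0, seed=7), alpha=0.6
)
genotypes, omics = mrnet.simulate_dataset(spec, n_samples=20_000, seed=8, maf=0.3)

print("true directed edges (source -> target, weight):")
for s, t, w in spec.true_edges():
    print(f"  {s} -> {t}   {w:+.2f}")

analytic = mrnet.sem_covariance(spec, maf=0.3)
dev = np.abs(omics.cov().to_numpy() - analytic.to_numpy()).max()
print(f"\nmax |empirical - analytic| covariance deviation: {dev:.4f}")
print("(sampling noise scales like 1/sqrt(n); anything well below ~0.05 at")
print(" n=20k means the simulator reproduces its own moment structure)")
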