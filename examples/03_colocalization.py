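"""Ask whether a GWAS hit and an expression signal share a causal variant.

Simulates one LD block twice: once where GWAS and expression are driven by
the same causal SNP (expect high PP4) and once where two unlinked SNPs drive
them separately (expect high PP3).
"""
import numpy as np

from twaskit import coloc, synthdata as sd

N = 50_000
R = sd.ar1_correlation(200, 0.7)
rng = np.random.default_rng(4)
b = 10 / np.sqrt(N)  # causal effect giving expected |Z| = 10

beta = np.zeros(200)
beta[100] = b
z_gwas = sd.simulate_z(R, beta, N, rng)
z_expr = sd.simulate_z(R, beta, N, rng)
shared = coloc.coloc_posteriors(coloc.wakefield_log_abf(z_gwas, 1 / N),
                                coloc.wakefield_log_abf(z_expr, 1 / N))
print("same causal SNP:      "
      + "  ".join(f"PP{i}={v:.3f}" for i, v in enumerate(shared.as_array())))

b1, b2 = np.zeros(200), np.zeros(200)
b1[20], b2[180] = b, b  # far apart: effectively unlinked under AR(1) decay
z_gwas = sd.simulate_z(R, b1, N, rng)
z_expr = sd.simulate_z(R, b2, N, rng)
distinct = coloc.coloc_posteriors(coloc.wakefield_log_abf(z_gwas, 1 / N),
                                  coloc.wakefield_log_abf(z_expr, 1 / N))
print("distinct causal SNPs: "
      + "  ".join(f"PP{i}={v:.3f}" for i, v in enumerate(distinct.as_array())))
print("\nPP4 is the posterior probability of one shared causal variant; "
      "PP3 of two distinct ones.")
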