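"""Stability of the steady state: the (G_i0, G_i1) scatter and residuals.

Transcripts whose expression is reproduced by the steady-state term alone
have large |G_i0| and G_i1 near zero — they barely participate in the
transformation.  The steady-state residual max_T |ln X_i(T) - G_i0
lam_0(T)| quantifies this per gene.
"""

import numpy as np

from surprisal import (
    decompose,
    generate_planted_dataset,
    log_transform,
    stability_scatter,
    steady_state_residual,
)

x, truth = generate_planted_dataset(m=2000, t=4, seed=42)
d = decompose(log_transform(x))

points = stability_scatter(d)
g0 = np.array([p.g0 for p in points])
g1 = np.array([p.g1 for p in points])
stable = list(truth.stable_genes)
deviating = list(truth.deviating_genes)

print("mean |G_i0| / |G_i1| per planted group:")
print(f"  stable    genes: |G0| = {np.abs(g0[stable]).mean():.4f}   "
      f"|G1| = {np.abs(g1[stable]).mean():.5f}")
print(f"  deviating genes: |G0| = {np.abs(g0[deviating]).mean():.4f}   "
      f"|G1| = {np.abs(g1[deviating]).mean():.5f}")

res = steady_state_residual(d)
se = np.sqrt(res[stable].var(ddof=1) / len(stable)
             + res[deviating].var(ddof=1) / len(deviating))
z = (res[deviating].mean() - res[stable].mean()) / se
print("\nsteady-state residual (max log-fold change unexplained by lam0):")
print(f"  stable    mean = {res[stable].mean():.3f}")
print(f"  deviating mean = {res[deviating].mean():.3f}")
print(f"  separation = {z:.1f} pooled standard errors")
# stable transcripts change only by a small fraction across the course;
# the deviating group carries the transformation signal
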