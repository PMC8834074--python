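"""Fit and test a single gene's two-cell-type game interaction.

Simulates one gene whose expression in two interacting cell types follows a
two-node quasi-dynamic ODE along the niche index (strong mutual activation),
fits the full game model and the no-interaction null, decomposes the fitted
trajectories into independent and dependent components, and runs the
likelihood-ratio interaction test.
"""

import numpy as np

from qdgame import (default_ar1, default_pair_spec, fit_pairwise,
                    fit_pairwise_null, lr_interaction_test, simulate_pairwise)

# symmetric synergism: each cell type activates the other (strength 3);
# reduced-variance residuals (the regime where the independent/dependent
# attribution is well identified -- see docs/methods.md)
spec = default_pair_spec(strength_12=3.0, strength_21=3.0)
profile, truth = simulate_pairwise(spec, default_ar1(0.5), n=50, seed=1)

null = fit_pairwise_null(profile, seed=0)
full = fit_pairwise(profile, seed=0, null_fit=null)

print(f"log-likelihood  null (non-game): {null.loglik:8.2f}")
print(f"log-likelihood  full (game):     {full.loglik:8.2f}")

dec = full.decomposition
d12 = dec.net_dep[("type1", "type2")]
d21 = dec.net_dep[("type2", "type1")]
print(f"net dependent integral type1 <- type2: {d12:+.3f} "
      f"(truth {truth.net_dep[('n1', 'n2')]:+.3f})")
print(f"net dependent integral type2 <- type1: {d21:+.3f} "
      f"(truth {truth.net_dep[('n2', 'n1')]:+.3f})")
print("positive integrals mean each type's expression is pushed up by the "
      "other: mutual activation (synergism).  Magnitudes are conservatively "
      "attenuated because the power term absorbs the smooth part of each "
      "dependent curve (see docs/methods.md); the signs carry the call.")

res = lr_interaction_test(profile, n_perm=60, seed=0)
print(f"LR = {res['LR']:.1f}  threshold (95th pct of resampled null) = "
      f"{res['threshold']:.1f}  significant = {res['significant']}")

rmse = np.sqrt(np.mean((dec.mean["type1"] - truth.mean1[profile.order]) ** 2))
print(f"fitted-mean RMSE vs generating curve (type 1): {rmse:.3f}")
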