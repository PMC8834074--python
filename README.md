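# qdgame

Quasi-dynamic ODE game models for static paired expression data: interaction
testing and sparse signed network inference.

## The problem

Cross-sectional molecular data — one snapshot per embryo, sample or cell —
carry no clock, yet the questions that matter are dynamic: does the somatic
niche activate or inhibit the germ cells it surrounds?  Which genes drive
which?  `qdgame` implements a modeling framework that replaces time with an
expression-derived axis and reads interactions off the resulting dynamics.
It is aimed at computational biologists analyzing processed (normalized,
averaged) expression of paired cell populations, gene panels or single cells
within one tissue.

For one gene expressed in two interacting cell types across n units, define
the **niche index** N_i = y_1i + y_2i (the unit's total expression of the
gene).  Serializing units by ascending N turns the pair of profiles into
trajectories g_1(N), g_2(N) modeled by a two-node quasi-dynamic ODE:

    dg_k/dN = q_k(N) + q_{k←k'}(g_{k'}),   k = 1, 2

where the *independent* rate q_k = d/dN [α_k N^{β_k}] is the derivative of
an allometric power curve (part–whole scaling of the component with the
total) and the *dependent* rate q_{k←k'} is a Legendre polynomial series in
the partner's state.  Integrating the terms separately decomposes each
fitted trajectory into an independent curve plus a signed dependent curve
per direction: positive means activation, negative inhibition, near-zero
neutrality.  The sign pattern maps each gene to one of eleven qualitative
interaction classes (synergism, antagonism, altruism/exploitation,
directional variants, coexistence) and five regulator categories.  The model
is estimated by maximum likelihood with bivariate AR(1) residuals; the
interaction is tested by a likelihood ratio against the no-interaction
model, calibrated by resampling under the fitted null.  The same machinery
scales to m-node systems — genes or modules along a sample-level
**expression index** (EI), or cells along a gene-level EI — with
LASSO-based regulator selection, signed weighted directed edges, and an
outgoing-hubness coefficient H_j = Σ_{j'} ∫|dep_{j'←j}| / ∫ indep_{j'}.

## A worked example

```sh
python examples/pairwise_interaction.py
```

simulates one gene under strong mutual activation (n = 50 embryos), fits the
game and non-game models and prints:

```
log-likelihood  null (non-game):   124.68
log-likelihood  full (game):       186.68
net dependent integral type1 <- type2: +0.888 (truth +4.875)
net dependent integral type2 <- type1: +0.518 (truth +4.437)
positive integrals mean each type's expression is pushed up by the other: mutual activation (synergism).  ...
LR = 123.8  threshold (95th pct of resampled null) = 84.8  significant = True
fitted-mean RMSE vs generating curve (type 1): 0.110
```

Both net dependent integrals come out positive — the planted mutual
activation is recovered in sign — and the LR far exceeds the resampled null
threshold, so the interaction is called significant.  The magnitudes are
conservatively attenuated relative to the generating values because the
allometric power term absorbs the smooth part of each dependent curve; the
methods note discusses when this attribution is and is not identifiable.

Other entry points, one capability per script, live in `examples/`:
module clustering (`module_clustering.py`), whole-table screening with the
eleven-class taxonomy (`screen_genes.py`), gene networks
(`gene_network.py`), and cell–cell networks (`cell_network.py`).  A thin
CLI wraps the same functions (`qdgame simulate|fit-pair|test|screen|
cluster|network|cellnet|hubness`); every run writes a manifest with its
inputs, seed and parameters.

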