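# symptomnet

Regularized partial-correlation network analysis for ordinal symptom
questionnaires — built for the common psychometric design in which two
co-occurring symptom clusters (here: posttraumatic stress, PTS, measured by
six 0–4 items, and posttraumatic growth, PTG, measured by ten 0–5 items)
are analyzed jointly to find *central* symptoms and *bridge* symptoms
linking the clusters.

## What it computes

Given an n×p matrix of ordinal item responses and a community label per
item, the pipeline estimates:

1. **Polychoric correlations** between all item pairs, by two-step maximum
   likelihood (thresholds `τ_k = Φ⁻¹(cumulative proportion)` from the
   margins, then the latent correlation ρ from the contingency-table
   likelihood), with eigenvalue-clipping repair if the assembled matrix is
   indefinite.
2. **A Gaussian Graphical Model** via the graphical lasso, which maximizes
   `log det K − tr(SK) − λ Σ_{i≠j}|k_ij|` over precision matrices K, with
   the penalty λ selected by the Extended Bayesian Information Criterion
   `EBIC = −2L + E log n + 4 E γ log p` (γ = 0.5) along a 100-point
   log-spaced path. Edges are the partial correlations
   `w_ij = −k_ij / √(k_ii k_jj)`.
3. **Centralities**: one-step expected influence `EI(v) = Σ_j w_vj` and
   bridge expected influence `BEI(v) = Σ_{j∉community(v)} w_vj`, plus
   network descriptors (density, signed edge counts, strongest edges).
4. **Accuracy and stability**: nonparametric bootstrap 95% percentile CIs
   for edge weights, bootstrapped difference tests (α = 0.05) for edges and
   EIs, and the case-dropping bootstrap with the correlation-stability (CS)
   coefficient — the largest proportion of cases droppable such that, with
   95% probability, subset EI vectors correlate ≥ 0.7 with the original
   (CS > 0.5 read as high stability). Every bootstrap replicate re-runs the
   full pipeline including EBIC re-selection of λ.

Because raw data for such studies are rarely shareable, the package also
ships a **latent-Gaussian ordinal simulator** (`symptomnet.simulate`): a
known sparse two-community partial-correlation network is converted to a
latent correlation matrix, sampled, and discretized through fixed item
thresholds — so every stage above is testable by parameter recovery.

## Worked example

```
python analysis/01_simulate_cohort.py
python analysis/02_estimate_network.py
python analysis/03_centrality.py
python analysis/04_stability.py
```

which prints (seed 1):

```
cohort: n=406, p=16 (6 PTS / 10 PTG items)
PTS sum score: mean 5.64 (SD 2.85), 10.1% at or above cutoff 10
PTG sum score: mean 27.80 (SD 8.09)
true network: 40 edges (4 bridges, 2 of them negative)

selected penalty 0.0665 (EBIC over 100 values, gamma 0.5)
54 non-zero edges of 120 pairs (density 0.45); 50 positive, 4 negative;
mean weight 0.039
strongest positive edge PTG4--PTG6: 0.22
recovery vs simulation truth at n=406: 95% of 40 true edges detected with
the correct sign

strongest positive bridge: PTS3 (BEI +0.25)
case-dropping bootstrap (50/level over grid 0.05..0.75): CS coefficient
0.59 (high stability by the > 0.5 convention)
```

Read: at the study's sample size the pipeline recovers 95% of the true
edges with the correct sign, the two clusters are connected by a few
signed bridges, and the EI ordering survives dropping more than half of
the cases.

The same is available as a CLI: `symptomnet simulate | validate |
estimate | analyze` (see `symptomnet --help`). `analyze` writes TSV
artifacts (edge list, adjacency, node metrics, edge CIs, difference-test
matrices), a GraphML export, and a consolidated JSON report that is
byte-identical across reruns with the same config and seed.

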