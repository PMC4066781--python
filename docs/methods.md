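# Methods

## Model and procedure

`pathwire` tests whether a pathway's joint expression distribution differs
between two sample groups, and localises the difference to a chain of graph
neighbourhoods. The statistical engine works on the decomposable Gaussian
graphical model induced by the pathway topology:

1. **Moralization.** The directed pathway graph (gene–gene edges plus wired
   miRNA→target edges) is converted to an undirected graph by marrying the
   parents of every node and dropping directions. Cycles are permitted;
   cyclic edges simply become undirected.
2. **Triangulation.** A chordal cover is built by min-fill elimination. Ties
   are broken by smaller degree, then lexicographic node id, which makes the
   decomposition — and everything downstream — a deterministic function of
   the graph. Maximal cliques are read off the perfect elimination order.
3. **Junction tree.** A maximum-weight spanning forest of the clique graph
   (weight = separator size, Kruskal with lexicographic tie-break). The
   running intersection property is verified exhaustively after
   construction; a violation is an internal error, not a data error.
4. **Decomposable MLE.** For a sample covariance S aligned with the
   decomposition,

   K̂ = Σ_C [(S_C)⁻¹]⁰ − Σ_S [(S_S)⁻¹]⁰,
   logdet Σ̂ = Σ_C logdet S_C − Σ_S logdet S_S,

   with zero-padded blocks, cliques C and junction-tree separators S (with
   multiplicity). Covariance MLEs use denominator n_g, not n_g − 1: the MLE
   convention is required for the likelihood-ratio statistic below to be a
   true nested-model LRT and hence non-negative.
5. **Test statistics.**
   - Means: T² = (n₁n₂/n) · d′K̂d, with d = x̄₁ − x̄₂ and K̂ from the pooled
     within-group covariance (sample-size-weighted average of the per-group
     MLEs). Computed block-wise as Σ_C d_C′(S_C)⁻¹d_C − Σ_S d_S′(S_S)⁻¹d_S,
     so the full K̂ is never materialised.
   - Covariances: Λ = n·logdet Σ̂_pooled − n₁·logdet Σ̂₁ − n₂·logdet Σ̂₂,
     all log-determinants through the clique/separator factorisation. This
     is 2·log LR for equal-covariance vs. free-covariance decomposable
     models with group-specific means.

   Both statistics are scale-free under the concentration matrix, which is
   what lets mRNA and miRNA measurements with different scales share one
   matrix.
6. **Permutation inference.** Group labels are shuffled uniformly,
   preserving group sizes; p = (1 + #{stat_b ≥ stat_obs}) / (B + 1), so p can
   never be exactly zero and p ≥ 1/(B+1). Both statistics are evaluated on
   the same B relabelings, and all cliques of one pathway reuse one
   relabeling set. The per-permutation covariance algebra is stacked across
   relabelings (batched einsum / solve / slogdet), which keeps a B = 200 test
   of a 20-node pathway at a few milliseconds.
7. **Selection, paths, meta-pathway.** Pathway p-values are BH-adjusted
   separately for the mean family and the variance family; a pathway is
   selected when both q-values are ≤ 0.1 (an `either` mode is available as a
   config switch; descriptions of this two-step strategy vary between an
   or-rule and an and-rule, and the stricter BOTH rule is the default). Within a selected pathway every clique is tested (saturated model:
   a clique is complete), flagged significant when its combined p
   (min(p_mean, p_var) under the default `either` clique mode) is ≤ 0.05. A
   path is a junction-tree chain whose endpoints are significant with at
   most one non-significant interior clique ("gap"); leading/trailing gaps
   are trimmed by construction since they could only lower the score. Score:
   Σ over significant cliques of −log₁₀(p) minus γ per gap, γ defaulting to
   −log₁₀(α_clique) so one gap cancels exactly one boundary-significant
   clique. Ties break toward more cliques, then the lexicographically
   smallest node list. The best paths of all selected pathways are merged:
   node identity merges shared genes across pathways, and each path
   contributes the edges of its source pathway induced on the path's nodes —
   the induced-subgraph reading preserves clique structure, where a bare
   chain of separator edges would not. The merged graph (possibly
   disconnected) is re-decomposed per connected component; all candidate
   paths are pooled and ranked by score.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pct_min` | 0.8 | TargetScan P_ct threshold for predictions (inclusive) |
| `r_min` | 0.4 | minimum absolute Pearson r of the expression screen |
| `q_max_corr` | 0.05 | BH q threshold of the screen (family = all records surviving P_ct) |
| `alpha_pathway` | 0.1 | BH-adjusted selection threshold, applied per test family |
| `alpha_clique` | 0.05 | clique significance threshold on the combined p |
| `max_gaps` | 1 | non-significant cliques tolerated inside a path |
| `gap_penalty` | −log₁₀(α_clique) ≈ 1.30 | score penalty per gap |
| `permutations` | 1000 | B; benchmark studies in this repo use B = 200 |
| `ridge_lambda` | 1e−3 | ridge scale, active only when min(n₁,n₂) ≤ max clique size |
| `clique_mode` | either | which test(s) drive clique significance |
| `selection_mode` | both | pathway selection rule |

Correlation p-values use the two-sided t approximation
t = r·√((n−2)/(1−r²)) with n−2 df. The BH family for the screen is the full
post-P_ct prediction table; validated interactions bypass the screen
entirely. Thresholds are boundary-inclusive throughout.

## Numerical choices

- **Ridge.** When the smaller group is not larger than the widest clique,
  every clique/separator marginal gets λ·mean(diag)·I before inversion (per
  relabeling, per block). With λ = 0 a singular marginal raises an error
  that names the remedy. Λ ≥ 0 is a theorem only at λ = 0; tiny negative
  values under ridge are tolerated.
- **Cancellation at zero.** At λ = 0 both statistics are clamped at 0:
  identical groups produce T² = Λ = 0 up to ~1e−15 cancellation noise, and
  the clamp makes permutation ties at zero count as ties (identical groups
  give p = 1 exactly).
- **Determinism.** One user seed expands into independent per-stage
  SeedSequence streams (pathway tests, clique tests, meta analysis), so
  changing B in one stage does not perturb another stage's draws; pathways
  are processed in sorted id order; all output files are canonically sorted.
  Identical seed + config + inputs give byte-identical outputs (the run log's
  timestamp line aside).
- **Degenerate inputs.** Pathways with fewer than 2 measured features are
  skipped with a warning; unmeasured nodes are dropped, never imputed;
  zero-variance vectors drop a record from the correlation screen; reading a
  matrix with missing values is an error, not an imputation.

## Synthetic data

The generator emulates exactly the model class the engine assumes: zero-mean
Gaussian data Markov to the moralized pathway graph, with unit-diagonal
precision matrices, moral-edge weights drawn from −U(0.25, 0.35) and a
rescale toward diagonal dominance when positive definiteness would fail.
Group 2 differs by a planted local circuit (a chain of `planted_cliques`
junction-tree cliques, chosen deterministically): a mean shift of `delta`
baseline standard deviations per planted node, a multiplicative perturbation
of planted-edge precision weights (`cov_perturbation`), and a marginal
variance inflation of the planted nodes (`variance_scale`). The variance
component exists because concentration-edge changes of plausible magnitude
are nearly invisible to any covariance test at a few dozen samples per
group: in our power checks, even deleting the planted edges outright moved
the pathway-level covariance rejection rate by under five points at
n = 40/group. A dysregulated circuit with inflated marginal variance is the
detectable — and biologically common — covariance alteration.

The miRNA layer sets each miRNA to c·(mean of its target genes) + ε with
ε ~ N(0, σ_ε²); for a single target the population correlation is
c·σ_g/√(c²σ_g² + σ_ε²), and `noise_sd_for_r` inverts that relation. c = 0
gives null decoys for specificity checks.

Benchmark defaults — 20 genes, extra-edge density 0.08, n = 40/group,
δ = 1.5, variance_scale = 3, a two-clique planted chain, B = 200 — were
fixed once by a power analysis so that each test family is individually
detectable at the benchmark size (pathway-level power ≈ 0.95+ per family),
and the null calibration study uses 20 samples/group with no planted signal.
What the simulations do **not** emulate: microarray noise (probe effects,
normalization artifacts), non-Gaussian expression, many-to-many miRNA
regulation with pathway feedback, or annotation error in the graphs — so
passing recovery tests demonstrates correctness of the machinery under its
own model assumptions, not robustness to real-data violations of them.

## Design choices on genuinely open points

- The exact form of the two test statistics is an open design point in
  this family of clique-based pathway methods; this package fixes them as
  the decomposable Hotelling-type T² and the covariance-equality LRT above.
  Permutation calibration makes the exact statistic choice second-order.
- The path score's functional form is only qualitatively constrained
  (significant cliques help, gaps hurt); the −log₁₀ sum with γ =
  −log₁₀(α_clique) is this package's choice, unweighted by clique size.
- The composition table's ratio column reproduces the worked example's
  printed values only under a totals-over-genes truncation convention:
  (miRNAs + genes)/genes truncated to one decimal (127/29 = 4.38 → "4.3",
  80/28 = 2.86 → "2.8", where rounding would give 2.9), although such
  columns are conventionally labelled miRNAs-over-genes. The truncation
  convention is implemented; the label discrepancy is noted here.
- Gene identifiers are opaque, case-sensitive strings; no alias resolution.
- The evidence class of individual miRNA edges is not serialized in the
  SIF + node-attribute format (re-read wired graphs default miRNA edges to
  `validated`); class counts are reported at wire time.
- "Unifying truncated paths" happens through node-identity set union only;
  no additional path-merging rule is applied.

## Known limitations

- The final circuit is a single junction-tree path: when several paths tie
  at the maximum score (common when many cliques sit at the permutation
  floor 1/(B+1)), the tie-break is structural, and branches off the chosen
  path are not reported even if significant. Raising B sharpens scores and
  reduces ties.
- The covariance LRT has little power against pure partial-correlation
  rewiring at realistic sample sizes (see above); variance-scale changes
  dominate its power.
- Two groups only; no covariates; permutation assumes exchangeable samples
  under the null.
- Runtime scales with B × Σ(clique blocks); whole-database analyses at
  B = 10 000 are feasible on one CPU but take hours.
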