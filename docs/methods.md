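# Methods

This note records the models, numerical choices, and open design decisions
behind `senscreen`, in the order the pipeline runs.

## Training-set assembly

Structures are canonicalized to the RDKit canonical SMILES of the largest
fragment; that string is the dedup key, so tautomer- or stereo-distinct
inputs are distinct keys (stereo-aware dedup variants are out of scope).
Molecular weight uses average atomic masses of the neutral parent. The MW
window (default 150 < MW < 700 Da) is an open interval: boundary values are
excluded.

Duplicates *within* a label keep the first record in pool order. A key that
appears with *both* labels after the merge is removed from both sides: a
structure reported active against one target and inactive against another
carries no usable signal for a panel-level classifier, and removing it is
the bias-free choice (keeping either side would tilt the class balance by
curation order).

Inactive down-sampling keeps decoys whose **maximum** Tanimoto similarity
(Morgan radius 2, 1024 bits) to the active pool lies in a band, default
[0.50, 0.85]: above the band a decoy is near-identical to an active, below
it the decoy is trivially discriminable and teaches the model nothing.
Survivors are ranked by descending similarity with ties broken by canonical
key, so the result is order-independent.

## Descriptors

Four blocks, all deterministic per canonical key:

| block   | content                                   | size | kind       |
|---------|-------------------------------------------|------|------------|
| phys2d  | curated RDKit 1D/2D physchem set           | 52   | continuous |
| keyfp   | MACCS structural keys                      | 166  | binary     |
| extfp   | Morgan radius-2 fingerprint                | 1024 | binary     |
| pharmfp | pharmacophore-pair / distance-bin bits     | 147  | binary     |

The pharmacophore fingerprint is a 2D pair fingerprint: six feature classes
(H-bond donor, acceptor, positively ionizable, negatively ionizable,
aromatic, hydrophobe; SMARTS-defined) give 21 unordered class pairs, each
crossed with 7 through-bond (topological) distance bins
(1–2, 3, 4, 5, 6, 7–8, ≥9 bonds) — 147 bits. Pair fingerprints over binned
topological distances are the classical construction behind 147-bit
pharmacophore descriptors, and topological distances make the block exactly
reproducible: no conformer generation, no embedding seed. The cost is that
genuinely 3D arrangements (e.g. cis/trans display of the same feature pair)
are not distinguished.

Charge-equilibration (PEOE) descriptors are deliberately excluded from
phys2d: they can fail to converge on unusual structures and would break the
"row dropped only if the backend fails" contract for ordinary libraries.
Non-finite physchem values are imputed with the column mean.

## Feature selection

Three ordered steps, column count non-increasing:

1. **Zero variance**: drop columns with sample variance exactly 0.
2. **Correlation pruning**: one greedy pass over pairs in column order;
   when |Pearson r| > 0.95 (configurable) and both columns are alive, the
   later column is dropped. Order-dependence is intentional — it makes the
   result reproducible and biases retention toward the earlier, physically
   interpretable blocks.
3. **Representative selection**: hierarchical clustering of columns on
   1 − |r| with complete linkage, cut into *k* clusters (default 495);
   each cluster keeps its medoid, the column with the greatest mean |r| to
   its cluster (ties by column order). This is a reproducible,
   oracle-checkable scheme, not a reconstruction of any proprietary
   feature-selection routine. A known cost, visible in development: when
   *k* forces loose clusters, a strongly informative column can be replaced
   by a mediocre correlate. The pipeline accepts this as part of the
   protocol; *k* is exposed in configuration.

Standardization z-scores continuous columns with training statistics
(σ = 0 columns pass through unscaled); binary columns are untouched so the
{0,1} semantics survive. The stored statistics are reapplied verbatim to
screening libraries.

## Network and trainer

Architecture: inputs → one hidden layer (default 20 tanh units) → 2
logistic outputs, (active, inactive), targets one-hot. Weights initialize
uniform in ±1/√fan-in from a seeded generator.

The error is E(w) = ½ Σ‖y − t‖² plus, when configured, a ridge penalty
½λ‖w‖². The scaled-conjugate-gradient loop follows the standard
formulation: curvature along the conjugate direction p is estimated as
s = (E′(w + σp/|p|) − E′(w))·|p|/σ with σ = 10⁻⁵, scaled by λ (initial
10⁻⁶) to enforce positive definiteness; step size α = μ/δ with μ = pᵀr; the
comparison parameter Δ accepts or rejects the step, raising λ when
Δ < 0.25 and shrinking it when Δ > 0.75; the direction restarts to steepest
descent every W iterations (W = weight count). Accepted steps never
increase E. A run terminates on gradient norm < 10⁻⁶, a 30-iteration
plateau (relative improvement ≤ 10⁻⁹), or the epoch budget.

`fit()` wraps this in a seeded **multi-start**: if a run converges or
stalls before the budget is spent, remaining epochs go to fresh
initializations and the best final error wins. Small networks (the 2-2-2
XOR configuration) have well-known poor local minima; multi-start inside a
fixed budget removes them without changing the behavior of runs that use
their full budget. All restart seeds derive from the configured seed, so
training histories are bit-reproducible.

A plain full-batch gradient-descent trainer (fixed learning rate) is
included solely as the parameter scan's baseline learning rule.

### Regularization in the pipeline

The library default is λ = 0 (pure summed squared error). The *pipeline*
sets λ = 0.006 · n (n = training rows). Rationale: a 20-hidden-unit network
has far more weights than a ~1000-compound training set has rows; trained
to convergence it interpolates the label noise and, at the specificity-
weighted cutoffs, floods a large library with confident false positives.
During method development on the standard fixture, the unregularized
pipeline reached screen precision ≈ 0.2–0.35 while a reference
gradient-boosting model on identical features reached > 0.95 — evidence the
deficit was the learner, not the data. The per-sample parameterization
keeps the penalty's relative strength stable across problem sizes.

## Cross-validation, pruning, scan

Folds are stratified (each class dealt round-robin after a seeded shuffle),
so fold sizes differ by at most one and per-fold class balance is within
one compound of proportional — this stabilizes κ on modest sets. Every
compound is validated exactly once; its per-compound MSE is the mean
squared error over the two outputs from that single validation prediction
(repeat-averaging is available but off by default). Compounds with MSE >
0.4 are pruned as consistently misclassified, then feature selection is
re-run on the survivors before the final ensemble — the two-pass structure
matters because selection statistics change once noisy compounds leave.

The parameter scan cross-validates each grid entry (hidden sizes ×
learning rules) and flags the best by κ, then accuracy.

## Ensemble and screening

Ten members share data and differ only in initialization seed
(base_seed + i). Scores are member means; a compound is a hit iff
mean active output ≥ 0.95 **and** mean inactive output ≤ 0.05. Whether the
published cutoffs applied per network or to an aggregate is not specified
in the source material; the mean is the default and a `unanimous` mode
(every member passes both cutoffs) is provided. The "summed confusion
matrix" report is the sum of member validation-fold confusions — a
reporting convention, not a different classifier.

κ uses the two-rater marginal chance-agreement form. ROC curves sweep the
unique scores with ties grouped; AUC is trapezoidal and equals the
Mann–Whitney concordance probability, which the tests verify by exhaustive
pair enumeration.

## Prioritization

Filter rules are inclusive ranges on computed properties (MW, Crippen
cLogP, HBD, HBA, rotatable bonds, TPSA). The shipped defaults
(MW 250–450, cLogP ≤ 4.5, HBD ≤ 5, HBA ≤ 8, RotB ≤ 8, TPSA ≤ 120 Å²) are
an explicitly labeled lead-like placeholder; real campaigns should supply
their own rules file. Rejection is attributed to the first failing rule in
declared order; the pass set itself is order-independent.

k-medoids on Jaccard distance uses deterministic seeding (most central
point, then farthest-point) and Lloyd alternation to a fixed point; at
small n it matches exhaustive medoid search in the tests. Diversity
sampling allocates picks to clusters by largest remainder on cluster size
(every cluster ≥ 1 pick while the budget allows), starts each cluster at
its medoid, and extends by max-min distance.

## Process-network profiles

Enrichment of a gene list against a network is the hypergeometric upper
tail P(X ≥ k) with population N (default: the union of all network genes),
K = network size, n = list size, k = observed intersection; scipy's
log-space survival function is the backend and the tests pin it to
exhaustive tail summation at 10⁻¹² for N ≤ 2000. Significance is raw
p < 0.05 per network (matching per-cell presentation of such profiles);
Benjamini–Hochberg adjustment is available but off by default.

Two profiles are compared through their significance sets: the distance is
the upper-tail probability of sharing at least the observed number of
significant networks, over a catalogue of N = 169 networks by default. The
upper tail is chosen so that smaller values mean stronger-than-chance
agreement, which is the orientation a clustering distance needs; the
distance is symmetric by hypergeometric duality. Dendrograms use UPGMA
proper — inter-cluster distance is the mean over original leaf pairs — with
merge ties broken by the lexicographic pair of cluster representative
labels, and export to Newick with ultrametric branch lengths (height/2).

## Self-organizing map

Rectangular grid (default 10 × 10), online training for 200 epochs:
each epoch presents all vectors in a seeded shuffled order; every neuron
moves toward the sample with a Gaussian neighborhood weight in grid
distance. Learning rate decays linearly 0.5 → 0.01 and radius
max(w, h)/2 → 1. "Iterations" are epochs over the data, not single-vector
updates. Binary fingerprints are treated as Euclidean points so neuron
weights are fractional prototypes; loadings assign each vector to its
nearest neuron (ties to the lowest index) and always partition the data.
The U-matrix lists weight distances of adjacent neuron pairs.

## Synthetic study conditions

The generator decorates a small scaffold grammar — benzimidazolone,
benzamide, benzenesulfonamide, indole, arylpiperazine, nicotinamide cores —
with ~30 drug-like substituents, keeping unique, valid, MW-conforming
structures. Activity truth is a planted conjunctive threshold rule on
physchem descriptors (default: cLogP ≥ 2 and TPSA ≤ 80 Å²), so the signal
is learnable from the descriptor matrix while active and inactive chemical
spaces overlap in all other dimensions. Training labels flip with
probability `label_noise` (default 5%); screening libraries contain an
*exact* planted count of rule-true structures with the truth table held
apart from the records.

Standard conditions: 500 + 500 training compounds, 10,000-structure
library, 2% planted actives, 5% label noise. These are desk-scale: roughly
a 200× reduction of a ~2M-structure campaign, sized so the whole pipeline
runs in minutes on one CPU. What passing tests show: the pipeline recovers
a planted, descriptor-decidable activity signal through the full
assemble→featurize→select→train→prune→screen chain at high precision.
What they do not show: performance on real bioassay data, where activity
is not a deterministic function of computed descriptors, assay noise is
structured rather than independent flips, and library chemistry extends
far beyond a six-scaffold grammar.

The gene-universe generator plants networks of configurable size and gene
lists with exact intersection counts, so every enrichment p-value has a
closed-form oracle.

## Degenerate inputs and tie-breaks

Ties are broken deterministically everywhere: canonical-key order in
assembly and decoy ranking, column order in feature selection, lowest
neuron/cluster index in SOM and k-medoids, lexicographic label pairs in
UPGMA. κ is defined as 0 when chance agreement is 1 (single-class folds).
All-zero fingerprints get Jaccard distance 0 to each other (scipy
convention). Empty clusters after k-medoids collapse are dropped and
cluster ids compacted.

## Known limitations

- Descriptor catalogues are backend-defined; column counts differ from any
  specific external descriptor program, and the report records block sizes.
- The representative-selection scheme can discard a strongly informative
  column in favor of a correlate when the target count forces loose
  clusters (see Feature selection).
- The pharmacophore block is 2D; conformer-dependent pharmacophore
  geometry is not captured.
- Per-network vs aggregate cutoff semantics for the dual-output screen are
  a documented interpretation (mean by default).
- The SOM does not reproduce any specific published neuron membership;
  that would require the original structure set.
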