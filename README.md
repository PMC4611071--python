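# senscreen

A ligand-based virtual screening pipeline for discovering senescence-inducing
compounds, built around a panel-of-targets strategy: instead of screening
against a single protein, activity labels are pooled from confirmatory
bioassays against a panel of senescence-associated targets (p53, p21, WEE1,
HSP90, MDM2, ATM, DNMT1, and similar), and a neural-network ensemble learns
the shared chemical signature of that phenotype-focused panel.

The package is for computational chemists and chemical biologists who want to
reproduce, adapt, or stress-test this style of screen end to end — from raw
per-target activity lists to a prioritized, diversity-sampled candidate set —
including on fully synthetic data when the original compound lists are not
available.

## The method

**Training-set assembly.** Per-target active/inactive lists are pooled,
salt-stripped and canonicalized, filtered to a molecular-weight window
(150 < MW < 700 Da), deduplicated within labels, and purged of cross-label
clashes. Oversized inactive pools are down-sampled to decoys whose maximum
Tanimoto similarity to the actives lies in a configurable band
(default 0.50–0.85).

**Descriptors.** Four fused blocks per compound: curated 1D/2D
physicochemical descriptors, MACCS keys (166 bits), Morgan/ECFP4
fingerprints (1024 bits), and a 147-bit pharmacophore-pair fingerprint
(6 feature classes × 21 unordered pairs × 7 through-bond distance bins).
Feature selection removes zero-variance and highly correlated columns
(|r| > 0.95), then reduces to *k* representatives (default 495) by
hierarchical clustering of columns on 1 − |r| with complete linkage, keeping
each cluster's medoid.

**Classifier.** A multilayer perceptron with one hidden layer (20 tanh
neurons) and two logistic output neurons — one scoring "active", one
"inactive" — trained by scaled conjugate gradient (SCG) on the summed
squared error E(w) = ½ Σ‖y − t‖². SCG estimates curvature along each
conjugate direction by a finite-difference gradient perturbation
(σ = 10⁻⁵) and regularizes it with a Levenberg–Marquardt scale parameter λ,
so no line searches are needed; accepted steps never increase the training
error. Ten-fold stratified cross-validation drives a parameter scan, and
compounds with cross-validated per-compound MSE > 0.4 are pruned as label
noise before features are re-selected and the final model trained.

**Ensemble screen.** Ten networks with distinct seeds are trained on the
final matrix. A library compound is a *virtual hit* only if the member-mean
active output ≥ 0.95 **and** the inactive output ≤ 0.05 — a dual cutoff that
deliberately weights the screen for specificity. Performance is summarized
by confusion matrices (sensitivity, specificity, accuracy, Cohen's κ) and
ROC curves.

**Prioritization.** Hits pass physicochemical/ADMET range filters (a
user-editable rules file; the shipped lead-like defaults are a placeholder),
are clustered by k-medoids on Tanimoto distance over pharmacophore
fingerprints, and a cluster-covering, maximally diverse subset is drawn for
experimental follow-up.

**Biology-side profiling.** Gene lists are scored against a catalogue of
curated process networks by hypergeometric upper-tail p-values
P(X ≥ k) with k = |list ∩ network|; profiles are compared by the
cumulative hypergeometric probability of their significant-network overlap
and clustered by UPGMA (unweighted average linkage). Chemical space is
additionally mapped with a 10 × 10 self-organizing map (200 training
iterations) reporting neuron loadings and U-matrix neighbor distances.

## Worked example

Run the full eight-stage workflow on the built-in synthetic study conditions
(500 + 500 training compounds with 5% label noise; a 10,000-structure
library with an exact 2% planted active fraction):

```python
from senscreen.fixtures import LibrarySpec
from senscreen.pipeline import RunConfig, run_workflow, evaluate_screen

cfg = RunConfig(run_dir="run1", seed=1, fixture=LibrarySpec())
run_workflow(cfg)          # assemble ... featurize ... screen ... prioritize
print(evaluate_screen("run1"))
```

Output from this exact invocation:

```
{'n_hits': 106, 'n_true_actives': 200, 'tp': 89,
 'precision': 0.839622641509434, 'recall': 0.445}
```

Of the 10,000 screened structures the ensemble called 106 virtual hits at
the 0.95/0.05 cutoffs; 89 of them are genuine planted actives (precision
0.84), recovering 44.5% of the 200 actives hidden in the library — the
specificity-weighted operating point the dual cutoff is designed for.
Stage outputs (training set, descriptor matrices, per-compound CV error,
ensemble weights, hit table, cluster picks) land under `run1/`, and
re-running skips completed stages via checksums.

The same workflow is scriptable from the shell:

```bash
senscreen run --config config.yaml
senscreen fixtures --preset genes --seed 1 --out genes/
senscreen profile --lists genes/list0.txt --gmt genes/networks.gmt --out profiles/
```

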