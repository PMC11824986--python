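# mkelm

Cost-sensitive multi-kernel extreme learning machines for tabular
classification, built from reduced expectation-kernel autoencoders.

## The problem

In many diagnostic settings — biomedical screening is the canonical
case — the two kinds of mistakes are not equally bad: calling a sick
patient healthy costs far more than the reverse. A classifier tuned
for raw accuracy is then the wrong tool. `mkelm` provides classifiers
that (a) train in closed form in seconds, (b) fuse several similarity
measures instead of betting on one kernel, and (c) make decisions by
minimum expected misclassification cost instead of maximum posterior.

## The model

Everything rests on the extreme learning machine (ELM): a single
hidden layer `h(x) = σ(Wx + b)` with *fixed random* weights, and
output weights solved by ridge regression,

    β = Hᵀ(I/C + HHᵀ)⁻¹T   or   β = (I/C + HᵀH)⁻¹HᵀT,

whichever Gram matrix is smaller. Feature learning uses kernel
autoencoders made cheap by *reference points*: instead of the full
N×N kernel matrix, each sample is described by its similarity to N̂ ≪ N
randomly chosen reference rows (a rectangular Ω̂, solved at N̂×N̂
cost). The reduced **expectation-kernel** autoencoder (REKELM-AE)
first expands inputs through a random N(0,1) sigmoid layer of
L₁ = R1·d nodes and applies the kernel to the mapped rows, combining
random mapping and similarity mapping; its output weights Γ solve
Ω̂Γ = X by ridge.

Four similarity functions are fused — Gaussian RBF, squared Euclidean
distance, Manhattan distance, cosine — by two architectures:

* **MKP-ELM** (parallel): one REKELM-AE per kernel; an ELM classifier
  consumes the concatenated activated read-outs σ(XΓᵢᵀ).
* **MKR-ELM** (residual): the autoencoders are stacked,
  Y⁽ⁱ⁾ = Y⁽ⁱ⁻¹⁾ + reconstructᵢ(Y⁽ⁱ⁻¹⁾), each block seeing a
  [0, 1]-normalized view of the stream; the classifier consumes Y⁽ᵏ⁾.

Scores become posteriors by per-class sigmoid + row normalization, and
the decision layer picks `j* = argmin_j Σᵢ P(i|x)·c_ij` for an m×m
cost matrix `c_ij` (cost of predicting j when the truth is i). With
0-1 costs this is exactly argmax; with asymmetric costs it deliberately
trades accuracy for cost. Details, assumptions, and design rationale:
[docs/methods.md](docs/methods.md).

No external datasets are needed: a synthetic generator produces
Gaussian-cluster problems with controllable overlap and imbalance,
plus random and structured cost matrices.

## Worked example

```python
import numpy as np
import mkelm as mk

kernels = [mk.KernelSpec(f) for f in mk.DEFAULT_KERNEL_ORDER]

# a moderately overlapping 3-class problem
X, y = mk.generate_classification_data(
    mk.SyntheticSpec(n_samples=600, n_features=8, n_classes=3, seed=0)
)
X_tr, X_te, y_tr, y_te = mk.prepare_split(X, y, train_fraction=0.6, seed=0)

model = mk.fit_mkp_elm(X_tr, y_tr, kernels, r1=10, r2=0.05, L=1000, C=100, seed=0)
scores = mk.predict_model_scores(model, X_te)
posteriors = mk.scores_to_posteriors(scores)

cost = mk.make_cost_matrix(3, family="uniform_range", max_cost=20, seed=0)
argmax_pred = model.classifier.classes[np.argmax(scores, axis=1)]
minrisk_pred = mk.min_risk_decide(posteriors, cost)

for name, pred in [("argmax", argmax_pred), ("min-risk", minrisk_pred)]:
    rep = mk.evaluate(y_te, pred, cost)
    print(f"{name:8s} acc={rep.acc:.3f}  Tc={rep.total_cost:.0f}")
```

Output:

```
argmax   acc=0.875  Tc=322
min-risk acc=0.833  Tc=247
```

Reading it: the cost-blind argmax decision is 4 points more accurate,
but the minimum-risk decision cuts the total misclassification cost
`Tc = Σ errᵢⱼ·cᵢⱼ` by roughly a quarter — the intended trade under an
asymmetric cost matrix.

## Command line

The same pipeline as five subcommands (`mkelm --help` for all flags;
every flag can come from a YAML config via `--config`):

```bash
mkelm simulate --n-samples 300 --n-features 6 --n-classes 2 --seed 1 \
      --out data.csv --cost-out cost.csv --cost-family type_b
mkelm fit --data data.csv --arch mkr --seed 2 --out model.json
mkelm predict --model model.json --data data.csv \
      --min-risk --cost-matrix cost.csv --out pred.csv
mkelm evaluate --truth data.csv --predictions pred.csv \
      --cost-matrix cost.csv --out report.csv
# acc=0.9433 total_cost=90.0000
mkelm ablate --data data.csv --cost-matrix cost.csv --sweep kernels \
      --seeds 0,1,2 --out sweep.csv   # or --sweep r2
```

Runs are reproducible to the byte for a fixed `--seed`. Datasets are
CSV with feature columns and a `label` column; cost matrices are CSV
with a class-label header.

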