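# crossomics

Nonlinear integration of two omics data types measured on the same
samples. Given an input matrix **X** (N samples × p features, e.g.
miRNA expression) and an output matrix **Y** (N × q, e.g. gene
expression), the package learns a low-dimensional nonlinear embedding
**E** (N × r) of **X** that best preserves the information needed to
reconstruct **Y** — a nonlinear analogue of canonical correlation — and
then asks *which* input features, and which (input, output) pairs,
carry that shared signal. It is aimed at regulatory-pair screening
(miRNA → gene, methylation → expression, ...) where the relations may
be nonlinear and where clinical covariates must not masquerade as
biology.

## The model

The core is an asymmetric autoencoder

```
X (N×p) ──encoder──> E (N×r) ──┐
                               ├─ concat ──decoder──> Ŷ (N×q)
C (N×s confounders) ───────────┘
```

trained to minimize the mean squared reconstruction error of **Y**.
Clinical confounders **C** (age, sex, batch, receptor status, ...) are
encoded as a numeric design matrix and concatenated to the bottleneck:
the decoder can explain confounder-driven variation in **Y** directly,
so the narrow embedding is free — and, capacity being scarce,
pressured — to carry only signal *independent* of the confounders.

On top of the fitted network:

- **Permutation importance** (encoder fixed): permuting input column j
  and measuring the total squared displacement of the embedded points
  scores each input feature; the squared change of each reconstructed
  output in the same permutation scores every (input, output) pair.
- **Gamma-null local fdr**: importance scores are nonnegative and their
  null component is well described by a gamma distribution. With f the
  kernel density of the scores and f0 the gamma null fitted to the
  lower tail, fdr(z) = π0·f0(z)/f(z); the null proportion π0 is swept
  over 0.60–0.99 and chosen by the best below-mode fit. Scores above
  the smallest z with fdr(z) below the cutoff are significant.
- **Hyperparameter tuning** by embedding non-normality: among candidate
  settings whose embedding columns are not strongly correlated, prefer
  the embedding farthest from multivariate normal as measured by
  Mardia's skewness b1 and the distance of Mardia's kurtosis b2 from
  its normal reference r(r+2) (a projection-pursuit-style criterion).
- A **simulation generator** with known contributing features and five
  link functions (identity, |r|, high-frequency sine, square, step),
  10:1 signal-to-noise, for benchmarking recovery with PR-AUC.

## Worked example

Simulated data with 10 contributing inputs out of 100, driving 120 of
300 outputs through mixed linear/nonlinear links (N = 1000, ρ = 0.3):

```python
from crossomics import (ArchitectureSpec, SimConfig, TrainConfig, fit,
                        fit_local_fdr, permutation_importance, pr_auc,
                        select_significant, simulate_dataset)

ds = simulate_dataset(SimConfig(n_x=100, n_y=300, k=10, m=12, N=1000,
                                rho=0.3, prop_linear=0.5, seed=7))
arch = ArchitectureSpec(embed_dim=10, n_in_layers=3, n_out_layers=3,
                        dropout_max=0.4)
model = fit(ds.x, ds.y, None, arch, TrainConfig(seed=7))
print("selected epochs:", model.selected_epochs)

imp = permutation_importance(model, ds.x, seed=7)
print("recovery PR-AUC:", round(pr_auc(imp.scores, ds.truth_mask), 3))

sel = fit_local_fdr(imp.scores, fdr_cutoff=0.01)
hits = select_significant(sel, imp)
print(f"pi0={sel.pi0:.2f}, {len(hits)} significant, top:", hits[:10])
```

prints

```
selected epochs: 57
recovery PR-AUC: 1.0
pi0=0.60, 24 significant, top: ['x9', 'x6', 'x2', 'x7', 'x4', 'x1', 'x5', 'x3', 'x8', 'x0']
```

The ten contributing features (`x0`–`x9`) rank first without exception
(PR-AUC 1.0; the linear-correlation baseline reaches 0.82 on the same
data). The fdr stage also admits some non-contributing features: with
compound-symmetry correlation 0.3 every input column is correlated with
the true ones, so their embedding influence is genuinely nonzero —
score-based selection inherits that leakage, and the 100-score vector
is small for density estimation.

The same pipeline is available from the shell:

```sh
crossomics simulate --config sim.yaml --seed 7 --out data/
crossomics fit --config run.yaml --seed 7 --out run/
crossomics importance --config run.yaml --n-runs 10 --out run/
crossomics select --scores run/importance.tsv --fdr 0.01 --out run/
crossomics tune --config run.yaml --out tuning/
crossomics benchmark --config bench.yaml --replicates 5 --out bench.tsv
```

with a flat YAML config using the conventional parameter names
(`ncomp`, `in.layers`, `out.layers`, `max.dropout`, `flat.dropout`,
`max.epochs`, `importance.permutations`, `pairwise.importance`).

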