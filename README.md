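# brilliant

Group-guided penalized multivariate multiple linear regression for omics
association studies and multi-phenotype prediction.

Typical inputs are a high-dimensional predictor matrix (CpG methylation M
values, gene expression, genotypes, ...) and a multivariate response matrix
(pathway gene expression, cell-type fractions, clinical phenotypes), both of
which carry natural grouping structure — CpGs by nearby gene pathway, genes
by ontology term, signature genes by cell type.  The package selects
features, estimates effects and predicts outcomes while exploiting both
groupings *and* the correlation among responses.

## Model

For `n` samples, `Y = XB + E` with `Y ∈ R^{n×q}`, `X ∈ R^{n×p}`, coefficient
matrix `B ∈ R^{p×q}`, and error rows `~ N(0, Σ)`.  The P predictor groups
and Q response groups cross into `G = P·Q` intersection blocks `B_g` of the
coefficient matrix.  The estimate solves

```
min_B  (1/2n) tr[(Y − XB)ᵀ (Y − XB) Ω̃]  +  λ₁ Σ_{jk} |β_jk|  +  λ₂ Σ_g w_g ‖B_g‖₂
```

where `Ω̃` is a *working precision matrix* for the responses (a one-step
plug-in for `Σ⁻¹`, never re-estimated during fitting) and `w_g² =` number of
entries in block `g`.  The lasso term gives entry-level sparsity, the group
term selects whole predictor-group × response-group blocks, and `Ω̃` lets
correlated responses share strength.  With `Ω̃ = I` the fit reduces to the
unweighted multivariate sparse-group lasso; with `λ₂ = 0` and `Ω̃ = I` it is
q independent lasso regressions.

The solver is a mixed coordinate descent: an exact per-block zero-group
screen, closed-form lasso/group-lasso/mixed coordinate updates, and a
block-proximal activation step (see `docs/methods.md`).  A post-fit hard
threshold `b_thr` zeroes small coefficients to curb false positives.

Three working precisions are built in:

* `"block"` — invert the within-response-group sample covariances of the
  centered training responses (block-diagonal; the default),
* `"identity"`,
* user supplied (labelled TSV, array, or `WorkingPrecision`).

## Worked example

```python
import brilliant as b
from brilliant.tuning import grid_search

cfg = b.SimulationConfig(
    n_train=100, n_val=50, n_test=50,
    x_group_sizes=(10,)*4, y_group_sizes=(4,)*2,
    x_cov="AR1", rho_x=0.5, e_cov="AR1", rho_e=0.7,
    nonzero_block_frac=0.25, seed=42,
)
sim = b.simulate_dataset(cfg)
Xtr, Ytr = sim.split("train"); Xv, Yv = sim.split("val"); Xte, Yte = sim.split("test")

model = b.BrilliantModel(Ytr, Xtr, x_groups=sim.x_groups,
                         y_groups=sim.y_groups, precision="block")
gs = grid_search(model, Xv, Yv)        # tunes (lambda1, lambda2, b_thr)
res = gs.results
print(res.summary())
```

```
Group-guided penalized multivariate regression
======================================================
samples                 100    predictors            40
responses                 8    blocks (P x Q)    4 x 2
precision source   block_diagonal_estimated
------------------------------------------------------
lambda1             5.47441e-05
lambda2             5.47441e-05
b_thr                   8.45205
sweeps                    1    converged           True
final delta          9.6348e-05
objective               1.35044
------------------------------------------------------
nonzero in B_hat        292 / 320
nonzero in B_tilde       40 / 320
active blocks             2 / 8
======================================================
```

The validation search picked a weak penalty pair plus a hard threshold that
prunes the 292 fitted coefficients down to the 40 that matter (2 of the 8
blocks are truly nonzero in this replicate).  Scoring against the ground
truth:

```python
pred = res.predict(Xte).to_numpy()
B_est = res.fit.B_tilde / model.scaler.x_scale[:, None]   # original scale
rep = b.evaluate_fit(sim.B, B_est, Yte, pred)
print(f"test MSE  {rep.mse:.3f}")
print(f"MAEE      {rep.maee:.4f}")
print(f"precision {rep.precision:.3f}  recall {rep.recall:.3f}  F1 {rep.f1:.3f}")
```

```
test MSE  1.476
MAEE      0.0265
precision 1.000  recall 1.000  F1 1.000
```

Test MSE 1.476 is close to the irreducible error variance of 1 per
response; MAEE is the mean absolute error over all 320 coefficients; the
thresholded support recovers the true support exactly here.

## Command line

```sh
brilliant simulate --config sim.yaml --out data/
brilliant fit --x data/X.tsv --y data/Y.tsv \
    --x-groups data/x_groups.tsv --y-groups data/y_groups.tsv \
    --precision block --lambda1 0.01 --lambda2 0.01 --out fit/
brilliant predict --fit fit/ --x data/X.tsv --out yhat.tsv
brilliant tune --x data/X.tsv --y data/Y.tsv --x-groups data/x_groups.tsv \
    --y-groups data/y_groups.tsv --nested --folds 3 --seed 1 --out tuned/
brilliant evaluate --truth data/ --fit fit/ --out report.json
```

Matrices are TSV/CSV with a header row and a leading sample-ID column
(samples × features); group files are two-column TSVs
(`feature<TAB>group`, a feature under several groups creates overlap);
precision files are labelled square TSVs.  Missing values are rejected, not
imputed.  Logs go to stderr, results to files.

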