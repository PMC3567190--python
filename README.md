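# sparselmm

Sparse Bayesian linear mixed models for polygenic analysis of quantitative
(and 0/1-coded binary) traits.

The model combines a point-normal ("spike and slab") prior on per-marker
effects with a polygenic random effect whose covariance is the genomic
relatedness matrix, so that the classic linear mixed model (LMM/BLUP) and
Bayesian variable-selection regression (BVSR) are exact special cases. It
estimates:

- **PVE** — the proportion of phenotypic variance explained jointly by the
  sparse and polygenic terms ("chip heritability"),
- **PGE** — the share of that genetic variance attributable to the sparse
  (large) effects,
- per-marker **posterior inclusion probabilities** and effect sizes,
- **phenotype predictions** for held-out individuals (sparse part plus a
  BLUP-style random-effect transfer).

Inference is Metropolis–Hastings over the inclusion indicators and the
hyper-parameters `(h, rho, log pi)`, with the effect sizes, intercept and
error precision integrated out analytically. A single eigendecomposition of
the relatedness matrix makes each likelihood evaluation linear in the number
of individuals; the sampler additionally maintains rank-1 factorization
updates so indicator moves cost `O(n q)`.

## Layout

| module | contents |
|---|---|
| `sparselmm.geno_io` | BIMBAM mean-genotype / phenotype / kinship text I/O, imputation, centering, kinship construction |
| `sparselmm.model_core` | hyper-parameter re-parameterization, priors, PVE/PGE definitions |
| `sparselmm.eigen_likelihood` | eigen-basis transforms, analytic marginal likelihood, REML for the pure LMM, conditional effect draws |
| `sparselmm.mcmc` | rank-based proposals, MH sampler, posterior summaries, output files |
| `sparselmm.predict_eval` | prediction, RMSE / correlation / RPG / AUC / Brier, liability-scale PVE correction |
| `sparselmm.simulate` | GWAS-like genotype simulator and the scenario I / II phenotype architectures with exact realized-PVE control |
| `sparselmm.cli` | `sparselmm fit / predict / simulate / evaluate` |

## CLI quick start

```bash
# simulate a dataset (scenario I: 100 causal markers, true PVE 0.6)
sparselmm simulate --n 1000 --p 5000 --n-causal 100 --pve 0.6 \
    --seed 1 --out sim

# fit the full model (or --mode lmm / bvsr / lmm_bayes / bslmm_eb)
sparselmm fit --geno sim.geno.txt --pheno sim.pheno.txt \
    --mode bslmm --n-iter 350000 --burn-in 50000 --seed 1 --out fit

# predict held-out individuals and score the predictions
sparselmm predict --train-geno sim.geno.txt --train-pheno sim.pheno.txt \
    --test-geno test.geno.txt --fit-prefix fit --out pred
sparselmm evaluate --truth test.pheno.txt --pred pred.pred.txt
```

`fit` writes `<prefix>.hyp.txt` (kept draws of h, PVE, rho, PGE, pi, |gamma|),
`<prefix>.param.txt` (per-marker inclusion probability and mean effects),
`<prefix>.fit.json` (posterior means used by `predict`) and
`<prefix>.log.txt` (full config, seeds, input checksums, acceptance rates).

Phenotype values may be `NA`; such individuals are excluded from the
likelihood but kept in the kinship so they can be predicted. Binary traits
are fitted as quantitative; predictions can be interpreted as case
probabilities, and `predict_eval.liability_correction` converts
observed-scale PVE to the liability scale for case-control designs.

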