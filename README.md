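# pldasig

Mutation-signature extraction with **tumor-type-parallelized latent
Dirichlet allocation** (PLDA).

Somatic mutations in cancer genomes accumulate from distinct mutational
processes (UV exposure, APOBEC activity, tobacco smoke, ...), each leaving a
characteristic distribution over the 96 trinucleotide substitution classes
(SBS96) — a *mutation signature*.  Given a catalog `M` of per-sample SBS96
counts, signature analysis factorizes `M ≈ θ φ` into per-sample activities
θ and signature distributions φ.  Because different tumor types have
different active signatures, the activity matrix is very sparse when all
tumor types are pooled, and most methods must analyze each type separately
and merge signatures afterwards.

PLDA avoids the split: it is latent Dirichlet allocation with one Dirichlet
concentration vector α_l **per tumor type**,

    φ_k  ~ Dirichlet(β)                     k = 1..K
    θ_ls ~ Dirichlet(α_l)                   sample s of tumor type l
    z    ~ Cat(θ_ls),  v ~ Cat(φ_z)         for each of the n_ls mutations

so E[θ_lsk] = α_lk / Σ_k' α_lk' encodes which signatures are active where,
and a single joint fit yields one shared signature set, directly comparable
activities across tumor types, and signatures for rare tumor types with only
a handful of samples.  Inference is mean-field variational Bayes; the
hyperparameters α_l and β are learned by fixed-point iteration; the number
of signatures K is chosen by the variational lower bound (ELBO).  The
package is aimed at researchers running signature analyses on SBS96 count
matrices and at methodologists who need a fully seeded, simulation-backed
reference implementation.

## What's in the box

| module | contents |
| --- | --- |
| `plda.sbs96` | canonical SBS96 ordering and label parsing (`A[T>C]G` / `T>C,A,G`) |
| `plda.catalog` | `MutationCatalog`, `SignatureSet`, `ActivityMatrix`; TSV readers/writers (sample-per-row and COSMIC-matrix layouts); min-mutation sample filter |
| `plda.model` | variational state, coordinate updates, ELBO, hyperparameter fixed points, `fit`, `fit_fixed_signatures`, `expected_activity` |
| `plda.selection` | `select_k`: restarted fits over a K grid, best-ELBO selection |
| `plda.simulate` | generative simulator, built-in benchmark designs, surrogate signature generator |
| `plda.evaluate` | cosine-distance matching (duplicated / not-matched accounting), reconstruction rate, attributed mutations, nearest-known banding |
| `plda.cli` | `plda simulate|fit|select|evaluate|bench` |

## Worked example

Simulate a 5-tumor-type catalog from the generative process (two active
signatures per type, α = 0.5 active / 0.05 inactive, 30 samples per type,
200 mutations per sample), select K, and score the result:

```python
from plda import (generate_catalog, make_surrogate_signatures, match_signatures,
                  reconstruction_rate, select_k, five_type_scenario)

sigs = make_surrogate_signatures(5, 0.6, seed=7)     # well-separated signatures
design = five_type_scenario(sigs, samples_per_type=30, mutations_per_sample=200)
catalog, truth = generate_catalog(design, seed=7)

sel = select_k(catalog, 2, 8, restarts=3, base_seed=7)
print("chosen K:", sel.chosen_k)

m = match_signatures(sel.best_fit.phi, truth.phi_true, threshold=0.1)
print("matched:", m.correct_matched, "duplicated:", m.duplicated,
      "not matched:", m.not_matched)

rr, per_type = reconstruction_rate(catalog, sel.best_fit.theta, sel.best_fit.phi)
print(f"reconstruction rate: {rr:.4f}")
```

Output:

```
chosen K: 5
matched: 5 duplicated: 0 not matched: 0
reconstruction rate: 0.8857
```

The ELBO peaks at the true K (here −76270.0 at K=5 vs −76363.8 at K=6 and
−80137.8 at K=4); all five generating signatures are recovered one-to-one at
cosine distance < 0.001; and the fitted decomposition reproduces ~89% of
each sample's catalog under the min-overlap reconstruction rate (1.0 would
be exact reconstruction — unattainable here because 200 multinomial draws
per sample carry sampling noise the rank-5 model correctly refuses to fit).

The same run from the shell:

```sh
plda simulate --builtin five-type --samples-per-type 30 --mutations-per-sample 200 \
     --seed 7 --out sim/
plda select --catalog sim/catalog.tsv --kmin 2 --kmax 8 --restarts 3 --seed 7 \
     --min-mutations 0 --out run/
plda evaluate --catalog sim/catalog.tsv --fit-dir run/ --truth sim/truth_phi.tsv \
     --out eval/
```

Real catalogs are read from TSV (one row per sample: `sample_id`,
`tumor_type`, 96 count columns; or the COSMIC-matrix layout with a
sample-to-tumor-type map), and COSMIC-format signature files can be supplied
wherever signatures are accepted — e.g. `fit --fixed-signatures` re-estimates
only the activities of validated signatures.  Samples with fewer than 400
mutations are filtered by default before fitting (`--min-mutations`).

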