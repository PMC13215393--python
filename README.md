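# provgen

**Privacy-preserving release of SNP genotype datasets for GWAS outcome
validation.**

Genome-wide association studies (GWAS) compare genotype distributions
between case and control groups and publish the SNPs significantly
associated with a trait.  Verifying such findings requires re-running the
tests on the underlying data — which usually cannot be shared, because a
genotype matrix identifies its donors.  `provgen` lets a researcher publish
a differentially private surrogate of their dataset that is useless for
re-identification but good enough for a verifier to reproduce the reported
associations and detect unintentional errors in the published p-values.

The package is aimed at two audiences: researchers who want to share a
sanitized dataset alongside their findings, and verifiers (reviewers,
replicators) who want to check those findings against it.

## The mechanism

Genotypes are minor-allele dosages $D \in \{0,1,2\}^{n \times m}$.  The
release works in two stages:

1. **Perturbation.**  Each genotype is encoded as two allele bits
   ($0 \to 00$, $1 \to 01$, $2 \to 11$), giving
   $D_b \in \{0,1\}^{n \times 2m}$, and XORed with a binary noise matrix
   $B$: $\tilde D_b = D_b \oplus B$.  The noise law is a matrix-valued
   Bernoulli distribution whose column-association parameter $\Theta$
   (a $2m \times 2m$ log-linear association matrix) is estimated from a
   public reference panel of the same SNPs, then rescaled so that

   $$s_f \, \lVert \lambda(\Theta) \rVert_2 = \varepsilon_e,$$

   where $s_f = 2m$ is the per-record bit sensitivity and
   $\lVert\lambda(\Theta)\rVert_2$ the $\ell_2$ norm of $\Theta$'s
   eigenvalues — the sufficient condition for $\varepsilon_e$-differential
   privacy of the XOR mechanism.  Instead of sampling the matrix law
   exactly (intractable), each bit of $B$ is drawn independently from a
   calibrated marginal: with
   $\kappa_u = 2\,\mathrm{rowsum}(\Theta)_u - \Theta_{uu}$,

   $$\Pr(B_u = 1) = \begin{cases}
     1/2 & |\kappa_u| > \lVert\lambda(\Theta)\rVert_2 \\
     \bigl(1 + e^{\kappa_u}\bigr)^{-1} & \text{otherwise.}
   \end{cases}$$

   Every sigmoid-branch bit then leaks at most
   $\lVert\lambda(\Theta)\rVert_2$, so a record differing in all $2m$ bits
   leaks at most $\varepsilon_e$.

2. **Restoration.**  The noise drives every allele frequency toward 1/2.
   Utility is restored by aligning each SNP's minor-allele frequency (MAF)
   to the published value via optimal transport on the two-point allele
   space: the earth mover's distance between Bernoulli laws with means
   $\tilde{\mathcal M}_j$ and $\mathcal M^r_j$ is
   $|\tilde{\mathcal M}_j - \mathcal M^r_j|$, so
   $\lfloor |\tilde{\mathcal M}_j - \mathcal M^r_j| \cdot 2n \rfloor$
   randomly chosen alleles of the over-represented value are flipped,
   leaving each restored MAF within $1/2n$ of its target.  This is pure
   post-processing of the private output, so the DP guarantee is intact.
   Decoding back to genotypes maps the invalid pair $10$ to genotype 1.

The verifier-side machinery reproduces $\chi^2$ and allelic odds-ratio
tests, computes the *SNP retention rate* (fraction of reported-significant
SNPs still significant under the relaxed threshold $\alpha / 0.8$), and
measures how much that rate drops when errors are injected into the
published p-values.  A Hamming-distance membership-inference attack, data
fidelity metrics, Laplace-protected MAF release and a randomized-response
local-DP baseline round out the evaluation toolkit.

## Worked example

```python
import numpy as np
from provgen import (PrivacyBudget, compute_sensitivity, encode,
                     estimate_theta, scale_to_budget, calibrate, release,
                     run_gwas, validation_experiment,
                     generate_case_control, generate_panel)

# a 600-individual cohort, 200 SNPs, 5 planted associations (per-allele OR 3)
study = generate_case_control(m=200, n_case=300, n_control=300,
                              causal_indices=[0, 1, 2, 3, 4],
                              effect_or=3.0, seed=51)
cohort = study.dataset
panel = generate_panel(m=200, n=500, seed=52)   # public reference panel

budget = PrivacyBudget(epsilon_e=5.0, sensitivity=compute_sensitivity(200))
theta = scale_to_budget(estimate_theta(encode(panel)),
                        budget.sensitivity, budget.epsilon_e)
calib = calibrate(theta, budget)
print(f"eigenvalue norm of scaled Theta: {theta.eig_l2:.6f}")
print(f"mean per-bit flip probability:  {calib.flip_prob.mean():.4f}")

# researcher publishes per-group MAFs with the findings; release the dataset
labels = np.asarray(cohort.phenotype)
published = {lab: cohort.subset_rows(labels == lab).maf()
             for lab in ("case", "control")}
released = release(cohort, encode(panel), published, budget, seed=53)

p_orig = run_gwas(cohort, "chi2")
p_repr = run_gwas(released, "chi2")
print(f"causal SNP p-values (original): {np.array2string(p_orig[:5], precision=2)}")
print(f"causal SNP p-values (released): {np.array2string(p_repr[:5], precision=2)}")

rows = validation_experiment(cohort, released, test="chi2",
                             error_model="flip",
                             error_rates=[0.0, 0.1, 1.0], repeats=10, seed=54)
for r in rows:
    print(f"flip rate {r.error_rate:>4}: retention-rate difference "
          f"{r.mean_difference:+.3f}  (95% CI {r.ci_low:+.3f}..{r.ci_high:+.3f})")
```

Output:

```
eigenvalue norm of scaled Theta: 0.012500
mean per-bit flip probability:  0.5005
causal SNP p-values (original): [4.94e-13 8.88e-17 9.17e-16 9.55e-09 1.19e-13]
causal SNP p-values (released): [1.57e-13 1.81e-16 1.26e-13 6.80e-09 1.52e-13]
flip rate  0.0: retention-rate difference +0.000  (95% CI +0.000..+0.000)
flip rate  0.1: retention-rate difference +0.040  (95% CI +0.000..+0.080)
flip rate  1.0: retention-rate difference +0.649  (95% CI +0.615..+0.684)
```

At $\varepsilon_e = 5$ over 400 bits the budget per bit is tiny, so almost
every bit flips with probability ≈ 1/2 — the released matrix is nearly
independent of the original at the entry level (strong privacy).  Yet
because restoration pins each group's allele frequencies to the published
values, the planted associations reproduce almost exactly, and the
verifier cleanly separates honest findings (difference 0) from corrupted
ones: fully scrambled p-values shift the retention rate by ~0.65, while a
10% error rate already shows a visible offset.

## Command line

`provgen` exposes the pipeline as subcommands over genotype TSV
(`sample_id` + one column per rsID, cells 0/1/2, optional `phenotype`
column) and read-only VCF ingestion:

```sh
provgen --seed 11 simulate --snps 200 --cases 300 --controls 300 \
        --causal 5 --or 3.0 --out sim/
provgen gwas     --in sim/cohort.tsv --test chi2 --out findings.json
provgen --seed 11 release --in sim/cohort.tsv --reference sim/panel.tsv \
        --maf findings.json --epsilon 5.0 --out released.tsv
provgen --seed 11 validate --original sim/cohort.tsv --released released.tsv \
        --rates 0,0.1,0.5,1.0 --out report.tsv
provgen fidelity --a sim/cohort.tsv --b released.tsv --out metrics.json
provgen attack hdt --shared released.tsv --reference sim/panel.tsv \
        --victims victims.tsv --fpr 0.05
```

`encode`, `theta`, `perturb`, `restore` and `baseline ldp` expose the
individual stages.

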