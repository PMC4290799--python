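# privgwas

Differentially private release — and adversarial evaluation — of GWAS
summary statistics on haploblock-structured case/control cohorts.

## The problem

Aggregate genomic data leak identity. Given the minor-allele frequencies
of a case cohort, an attacker holding one person's genotypes can test
whether that person was *in* the cohort: with dosages `x_j ∈ {0,1,2}`
over `m` SNVs, released case frequencies `q_j` and reference-population
frequencies `p_j`, the likelihood-ratio membership statistic

    L = Σ_j [ x_j log(q_j / p_j) + (2 − x_j) log((1 − q_j)/(1 − p_j)) ]

is large for cohort members. The defence is to perturb the release under
ε-differential privacy: a randomized release `f` with
`Pr[f(D) = t] ≤ e^ε · Pr[f(D′) = t]` for any cohorts `D, D′` differing by
one individual. The scientific question is how much GWAS utility —
recovery of the truly associated SNVs by the allelic χ² test — survives
at a given budget ε.

`privgwas` implements both sides of this trade-off as a reusable toolkit
for methodologists and challenge organisers:

* **Frequency sharing (Task 1).** Two Laplace-mechanism baselines: the
  *naive* method perturbs each of the N per-SNV allele counts with noise
  scale `2N/ε` (one individual can change every count by 2); the
  *haplotype* method exploits linkage disequilibrium — within a
  haploblock only a handful of distinct haplotypes occur — and perturbs
  per-block haplotype-count histograms (sensitivity 2 per block, budget
  split across blocks proportionally to pool size), then derives the
  per-SNV counts. Far fewer, far less sensitive noise draws.
* **Top-K release (Task 2).** The identities of the K most significant
  SNVs via exponential-mechanism peeling (K rounds at ε/K), with either
  the χ² statistic itself as utility (sensitivity obtained by exhaustive
  enumeration over all 2×2 tables and single-individual moves) or a
  signed distance-to-significance "Hamming" utility with sensitivity 1.
* **Scoring.** The LR attack with its power protocol (threshold = the
  empirical 95 % quantile of a held-out test group; power = fraction of
  case members above it), χ² TPR/FPR of the perturbed scan at fixed
  p-value cutoffs, and top-K overlap.
* **Synthetic cohorts.** A haploblock cohort generator (mutation-tree
  haplotype pools, Hardy–Weinberg sampling, planted case/control shifts
  with recorded ground truth) that reproduces the challenge's two
  dataset archetypes without any external data.
* **Exact DP verification.** On enumerable toy domains the ε-DP
  inequality is certified exactly — selection probabilities are computed
  on both sides of *every* neighbouring dataset pair — rather than
  sampled.

## Worked example

```sh
privgwas simulate --preset task1-small --seed 0 --out fx
privgwas run-task1 --fixture fx --method haplotype --epsilon 1.0 --seed 42 --out run_hap
privgwas run-task1 --fixture fx --method naive     --epsilon 1.0 --seed 42 --out run_naive
```

prints (abridged):

```
[task1 haplotype eps=1] power=0.435  TPR@0.05=0.607  TPR@0.001=0.981  TPR@1e-05=0.863
[task1 naive     eps=1] power=0.220  TPR@0.05=0.955  TPR@0.001=0.889  TPR@1e-05=0.627
```

Reading: releasing the *exact* case frequencies of this fixture lets the
LR attack re-identify ~64 % of case members; at ε = 1 both mechanisms cut
that power (0.44 and 0.22 here — still above the α = 0.05 design point,
this is the "challenging" dataset archetype). On utility, the haplotype
method recovers 86 % of the truly genome-wide-significant SNVs
(p < 10⁻⁵) against 63 % for the naive method, whose 2N-scaled noise
clamps most counts to the boundary. The full JSON reports (power,
threshold, TPR/FPR per cutoff, input digests) are written to the output
directories.

```sh
privgwas simulate --preset task2-small --seed 0 --out fx2
privgwas run-task2 --fixture fx2 --epsilon 1.0 --seed 42 --ks 1,5,10 --out run_topk
```

```
[task2 chi2 eps=1] overlap@K=1: 1.00  overlap@K=5: 0.60  overlap@K=10: 0.10
```

With a total budget of 1 split over K selection rounds, the top SNV is
identified essentially always, and accuracy decays as K grows — the
characteristic inverse relation between K and private top-K utility.

The same pipelines are importable (`privgwas.cli.run_task1`,
`run_task2`) and every component (mechanisms, attack, scan, generator)
is a plain library function.

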