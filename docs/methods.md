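# Methods

## Setting and threat model

A *case* cohort of n diploid individuals is genotyped at N biallelic SNVs
arranged in haploblocks; a *control* cohort is public, and a *test*
cohort of population members outside both groups is held out for
calibration. The data owner wants to release the case cohort's
minor-allele frequencies (Task 1) or the identities of the K most
case/control-associated SNVs (Task 2) under ε-differential privacy.
Adjacency is add/remove one diploid individual from the case cohort
(unbounded DP); the control data, being public, are never perturbed.
Budgets compose sequentially: sub-releases' ε values add.

## Release mechanisms

**Naive frequency release.** The N minor-allele counts form one
histogram in which one individual contributes up to 2 alleles at every
site, so the L1 sensitivity is Δf = 2N. Each count receives i.i.d.
Laplace(0, 2N/ε) noise, is clamped to [0, 2n] (DP-safe post-processing),
and is released as a real number by default (`round_counts` rounds).
The single ε covers the whole vector.

**Haplotype-block release.** Within a haploblock, linkage disequilibrium
leaves only a small pool of observed haplotypes (far below the 2^s
combinatorial bound), so the block's haplotype-count histogram is a much
lower-dimensional object with per-block sensitivity 2 (one individual =
two chromosome copies per block). The pipeline: (1) the common pool is
taken from the public control cohort, pruning haplotypes with count
below 2 (singletons are not reproducible public knowledge); (2) observed
case haplotypes outside the pool are reassigned to the nearest pool
member by Hamming distance, ties to the lowest pool index, conserving
totals; (3) the total budget is split across blocks proportionally to
pool size, ε_b = ε·h_b/Σh — blocks with richer pools get more budget,
hence less noise per count; (4) each count receives Laplace(0, 2/ε_b)
noise, negatives are clamped and the block is renormalized to its exact
original total 2n (the χ² test downstream needs the margins); (5)
per-SNV minor counts are the summed counts of pool haplotypes carrying
the minor allele at that site. With noise disabled, steps (1)–(5)
reproduce the direct genotype tally exactly whenever the case
haplotypes are inside the pool, and the end-to-end identity
build → derive = direct counting holds exactly in all cases.

**Top-K release.** K rounds of exponential-mechanism peeling, each
spending ε/K on one selection from the not-yet-released SNVs with
probability ∝ exp(ε·u/(2KΔu)). Two utilities:

* `chi2` — the allelic 2×2 Pearson χ² statistic itself (no continuity
  correction; degenerate margins score 0). Its global sensitivity under
  the adjacency above is computed *exactly* by enumerating every
  achievable table (case minor count × control minor count) and every
  single-individual removal (dosage 0/1/2, count-feasible), cached per
  cohort-size pair. Enumerations beyond 10⁷ table-move pairs must be
  explicitly downgraded to the conservative bound 2(n_case+n_control),
  the largest attainable statistic.
* `hamming` — a signed distance-to-significance. States are (case minor
  count a, cohort size n); one *move* edits one individual's genotype at
  the site (a ± 1 or 2) or adds/removes one individual (n ± 1, a shifts
  0–2). The move distance between states is max(|Δn|, ⌈|Δa|/2⌉), with
  removals relaxed to count-feasibility. The score of a SNV relative to
  a boundary statistic B is +(d − ½) above the boundary, −(d − ½)
  below, and 0 exactly at it, where d ≥ 1 is the distance to the closed
  region on the other side. The half offset is what makes the score
  1-Lipschitz in the move metric — integer signed distances jump by 2
  across the boundary — and since adjacency is itself a move, Δu = 1
  exactly. This is the mechanism-level reason the distance utility needs
  far less selection randomness than the raw statistic, whose enumerated
  sensitivity is ~4–6 at challenge-scale cohorts. During peeling the
  boundary is the current K-th largest remaining statistic (plug-in
  choice; see Limitations).

True top-K sets are defined with ties at the K-th statistic broken by
SNV identifier, so "truth" is deterministic; p-values use the 1-df upper
tail with no genomic-control correction.

## Attack and scoring

**LR membership statistic.** Diploid dosage-weighted form of the
classical per-allele likelihood ratio: each of the two chromosome copies
contributes a log-ratio of released-case vs reference allele
probabilities. Frequencies are clipped to [10⁻⁶, 1−10⁻⁶] (identically
for both tables) so empirically monomorphic sites cannot produce
infinite terms. By default the released case frequency sits in the
numerator, so large L means case membership; `case_in_numerator=False`
gives the transposed textbook orientation (which merely negates L).

**Power protocol.** The threshold is the empirical 1−α quantile of the
test group's L values using the Weibull plotting position
(interpolation at q·(n+1)); among the standard empirical quantile
estimators this is the one whose null exceedance probability is α to
first order at n_test = 174 (pure order statistics give 1 − k/(n+1) =
0.051 or 0.046). Power is the fraction of case individuals *strictly*
above the threshold, accompanied by a one-sided exact binomial p-value
against α. When the evaluated individuals are population members outside
the released cohort, power is α in expectation by exchangeability; when
they are inside it, self-inclusion inflates power even without any
population difference — the protocol's design point is the
out-of-cohort null.

**Utility.** The χ² scan is run on the released (possibly non-integer)
counts against the public control counts; TPR and FPR at each cutoff are
computed against the scan of the unperturbed case data. Undefined
denominators (no truly significant SNV, or all significant) are reported
as missing with a reason, never coerced.

## Exact DP verification

On domains small enough to enumerate (a few thousand neighbour pairs),
`verify_exponential_dp` computes the exact selection probabilities of
every candidate on both sides of every neighbour pair and reports the
maximum |log probability ratio|; the mechanism is certified iff that
maximum is ≤ ε (tolerance 10⁻⁹). Exceeding the enumeration budget raises
rather than truncating. The bundled toy domain is 4 case individuals ×
2 SNVs against a fixed public control; the utility sensitivity fed to
the mechanism is itself enumerated over the same relation, so the
certificate is sharp enough that halving Δu is detected as a violation.

## Synthetic cohorts

The generator emulates the challenge's data shapes, not human genetics
in general. Per block, a pool of distinct haplotypes is built along a
simple mutation genealogy — an ancestral haplotype plus derived ones
carrying 1–3 private mutations, every site forced to segregate — with
Dirichlet-distributed frequencies sorted so the ancestral haplotype is
the most common. Individuals are two independent haplotype draws per
block (Hardy–Weinberg), blocks independent. This yields strong
within-block LD, essentially zero cross-block LD, and a skewed site
frequency spectrum (rare haplotypes contribute low-MAF private sites).

Planted associations shift probability mass onto a *risk haplotype* —
the rarest pool haplotype whose control frequency is still ≥ 0.015,
targeted near 0.028: rare enough to behave like a realistic risk
haplotype (and to make its private sites low-MAF), common enough to be
segregating in any public pool. Other haplotypes are rescaled
proportionally; the shifted simplex is validated before sampling.
Ground truth (planted SNVs, the infinite-data χ² ranking, the effect
map) is recorded at generation time.

Two presets pin the study conditions:

* `task1-small` — 311 SNVs in 14 haploblocks (pools of 3–5), 200 case /
  174 control / 174 test, six planted shifts of 0.16–0.20 assigned to
  the blocks best able to carry them. This reproduces the archetype of a
  single strongly associated locus: a few dozen genome-wide-significant
  sites, mostly at low control MAF, and an exact-release LR power well
  above 0.5.
* `task2-small` — 5000 *single-SNV* blocks (genome-wide sampled SNVs are
  effectively independent; long blocks would tie the top statistics and
  make top-1 identification ill-posed), 201/174/174, twenty planted
  contrasts with shifts 0.93 down to 0.30. Genome-wide comparisons of
  separately genotyped cohorts are dominated by a handful of
  near-maximal-contrast sites, which is what makes private top-1
  identification achievable at ε = 1 at all.

What the generator does **not** model: cross-block haplotype
correlation, recombination maps, coalescent-realistic LD decay,
population structure or admixture, genotyping error. Results on these
fixtures therefore speak to the mechanisms' behaviour under the
challenge's dimensionality and signal structure, not to performance on
arbitrary real cohorts.

Missing-data injection (a configurable masking rate on case genotypes)
exercises the preprocessing path: cohort SNV harmonisation, per-site and
per-individual completeness filters (iterated to a fixpoint so the
operation is idempotent), and Binomial(2, reference frequency)
imputation, which preserves exactly the marginal frequencies the χ² and
LR computations consume.

## Numerical and procedural choices

* Laplace noise is drawn by inverse CDF from one `default_rng(seed)`
  uniform per draw (`log1p` form), so sequences are platform-stable;
  exponential-mechanism scores are max-shifted before exponentiation.
* Proportional budget shares are computed in one vectorized expression;
  they sum to ε to ~10⁻¹⁶ relative error and compose sequentially.
* Released counts are reals; clamping is always applied before any
  downstream scan (the scan rejects negative counts outright).
* All pipeline outputs (fixtures, frequency tables, reports) are
  byte-reproducible under a fixed seed; reports embed version, seed,
  ε and input digests.
* Genotype files accept dosage tokens (0/1/2, `NA`/`?` missing) and
  two-letter allele pairs; letter SNVs take their minor allele from an
  explicit public map or, failing that, from within-file counts with
  ties broken to the alphabetically later allele. 1-based coordinates.

## Known limitations

* The Hamming utility's peeling boundary (the current K-th remaining
  statistic) is itself data-dependent; the exact DP certificate covers
  the fixed-boundary selection form. A fully end-to-end account would
  spend budget on the boundary or absorb it into the utility's
  sensitivity analysis.
* The χ²-utility sensitivity is the *global* enumerated maximum, which
  is attained at extreme tables; on typical data it is conservative, and
  mid-K utility suffers accordingly. Smooth-sensitivity or
  local-sensitivity refinements are deliberately out of scope.
* The uniform ε/K split across peeling rounds is the simplest valid
  composition; no attempt is made to optimise the split.
* The naive mechanism's Δf = 2N reading applies the budget once to the
  whole count vector; per-SNV budgeting variants are not implemented.
* The Hamming distance search is exact but per-SNV and Python-level;
  it is intended for cohort-scale candidate sets (hundreds of SNVs per
  round), while the χ² utility is fully vectorized and used for the
  5000-SNV sweeps.
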