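"""Task-1 release mechanisms: naive SNV-histogram and haplotype-block Laplace.

The *naive* mechanism treats the vector of minor-allele counts over N SNVs
as one histogram in which each diploid individual contributes 2 minor
alleles per SNV in the worst case, so the L1 sensitivity is 2N and every
count receives Laplace(0, 2N/epsilon) noise.

The *haplotype* mechanism exploits linkage disequilibrium: within a
haploblock only a handful of distinct haplotypes occur, far fewer than the
2^n combinatorial bound, so perturbing per-block haplotype-count
histograms needs far fewer (and individually less sensitive) noise draws.
One individual contributes exactly 2 haplotype copies per block, so each
block histogram has L1 sensitivity 2; the total budget is allocated
across blocks proportionally to their pool sizes and the per-block
releases compose sequentially.  Perturbed counts are clamped at 0 and
renormalized to the original per-block total, then per-SNV allele counts
are derived by summing the counts of haplotypes carrying the minor allele
at each site.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel import (
    AlleleFrequencyTable,
    BlockHaplotypes,
    BlockMap,
    HaplotypeMatrix,
    HaplotypeTable,
    ParameterError,
    ValidationError,
)
from .mechanisms import allocate_budget, laplace_noise

logger = logging.getLogger(__name__)


def perturb_naive(
    case_counts: AlleleFrequencyTable,
    epsilon: float,
    seed: int | None = None,
    round_counts: bool = False,
) -> AlleleFrequencyTable:
    """Laplace-perturb per-SNV minor-allele counts with Delta_f = 2N.

    Noisy counts are clamped to [0, total] (DP-safe post-processing) and
    kept real-valued unless ``round_counts`` is set.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    n = case_counts.n_snvs
    rng = np.random.default_rng(seed)
    noisy = case_counts.minor_counts + laplace_noise(n, 2.0 * n / epsilon, rng)
    noisy = np.clip(noisy, 0.0, case_counts.totals)
    if round_counts:
        noisy = np.round(noisy)
    return AlleleFrequencyTable(
        snv_ids=list(case_counts.snv_ids),
        minor_counts=noisy,
        totals=case_counts.totals.copy(),
    )


def build_haplotype_table(haps: HaplotypeMatrix, blocks: BlockMap) -> HaplotypeTable:
    """Tally distinct observed haplotype strings per block.

    Per-block totals equal 2 x the number of individuals (each chromosome
    copy contributes one haplotype per block).
    """
    if blocks.n_snvs != haps.n_snvs:
        raise ValidationError(
            f"block map covers {blocks.n_snvs} SNVs but haplotypes have {haps.n_snvs}"
        )
    entries = []
    for idx in blocks.blocks:
        sub = haps.alleles[:, idx]
        strings = ["".join(map(str, row)) for row in sub]
        uniq: dict[str, int] = {}
        for s in strings:
            uniq[s] = uniq.get(s, 0) + 1
        order = sorted(uniq, key=lambda h: (-uniq[h], h))
        entries.append(
            BlockHaplotypes(
                haplotypes=order,
                counts=np.array([float(uniq[h]) for h in order]),
                total=float(len(strings)),
            )
        )
    return HaplotypeTable(blocks=entries)


def common_haplotype_pool(
    public_table: HaplotypeTable, min_count: float = 2.0
) -> list[list[str]]:
    """Per-block common-haplotype pools from a public (e.g. control) cohort.

    Haplotypes with count below ``min_count`` (singletons by default) are
    pruned; a block whose every haplotype would be pruned keeps its single
    most common one.  Pool order is descending count, ties lexicographic —
    the order matters because rare-haplotype mapping breaks distance ties
    toward the lowest pool index.
    """
    pools = []
    for entry in public_table.blocks:
        keep = [h for h, c in zip(entry.haplotypes, entry.counts) if c >= min_count]
        if not keep:
            keep = [entry.haplotypes[int(np.argmax(entry.counts))]]
        pools.append(keep)
    return pools


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def map_rare_haplotypes(
    table: HaplotypeTable, common_pool: list[list[str]]
) -> HaplotypeTable:
    """Reassign counts of out-of-pool haplotypes to their nearest pool member.

    Nearest by Hamming distance, ties to the lowest pool index; totals are
    conserved exactly.
    """
    if len(common_pool) != table.n_blocks:
        raise ValidationError("pool list must have one entry per block")
    entries = []
    for entry, pool in zip(table.blocks, common_pool):
        if not pool:
            raise ValidationError("empty common-haplotype pool for a block with observations")
        counts = {h: 0.0 for h in pool}
        for h, c in zip(entry.haplotypes, entry.counts):
            if h in counts:
                counts[h] += c
            else:
                dists = [_hamming(h, p) for p in pool]
                counts[pool[int(np.argmin(dists))]] += c
        entries.append(
            BlockHaplotypes(
                haplotypes=list(pool),
                counts=np.array([counts[h] for h in pool]),
                total=entry.total,
            )
        )
    return HaplotypeTable(blocks=entries)


def perturb_haplotype(
    table: HaplotypeTable,
    epsilon_total: float,
    seed: int | None = None,
) -> HaplotypeTable:
    """Laplace-perturb per-block haplotype counts under a shared budget.

    The budget is split proportionally to pool sizes
    (:func:`~privgwas.mechanisms.allocate_budget`); block ``b`` receives
    Laplace(0, 2/eps_b) noise per count (per-block sensitivity 2: one
    individual carries two haplotype copies per block).  Negative noisy
    counts are clamped to 0 and each block is renormalized to its original
    total; an all-zero block after clamping falls back to uniform counts
    (logged).
    """
    if epsilon_total <= 0:
        raise ParameterError("epsilon_total must be positive")
    pool_sizes = table.pool_sizes()
    eps_blocks = allocate_budget(pool_sizes, epsilon_total)
    rng = np.random.default_rng(seed)
    entries = []
    for entry, eps_b in zip(table.blocks, eps_blocks):
        noisy = entry.counts + laplace_noise(len(entry.counts), 2.0 / eps_b, rng)
        noisy = np.clip(noisy, 0.0, None)
        s = noisy.sum()
        if s <= 0:
            logger.warning(
                "all haplotype counts clamped to zero in a block; "
                "falling back to uniform renormalization"
            )
            noisy = np.full_like(noisy, entry.total / len(noisy))
        else:
            noisy = noisy * (entry.total / s)
        entries.append(
            BlockHaplotypes(haplotypes=list(entry.haplotypes), counts=noisy, total=entry.total)
        )
    return HaplotypeTable(blocks=entries)


def haplotype_counts_to_allele_counts(
    table: HaplotypeTable, blocks: BlockMap, snv_ids: list[str]
) -> AlleleFrequencyTable:
    """Derive per-SNV minor-allele counts from per-block haplotype counts.

    The minor count at site j is the summed count of the haplotypes of
    j's block that carry allele 1 at j; the total is the block total.
    """
    if len(snv_ids) != blocks.n_snvs:
        raise ValidationError("snv_ids length must match the block map")
    if table.n_blocks != blocks.n_blocks:
        raise ValidationError("haplotype table and block map disagree on block count")
    minor = np.empty(blocks.n_snvs)
    totals = np.empty(blocks.n_snvs)
    for entry, idx in zip(table.blocks, blocks.blocks):
        if entry.haplotypes and len(entry.haplotypes[0]) != len(idx):
            raise ValidationError("haplotype length does not match block size")
        alleles = np.array(
            [[int(ch) for ch in h] for h in entry.haplotypes], dtype=float
        )  # (n_haps, block_size)
        minor[idx] = entry.counts @ alleles
        totals[idx] = entry.total
    return AlleleFrequencyTable(snv_ids=list(snv_ids), minor_counts=minor, totals=totals)


def perturb_haplotype_release(
    case_haps: HaplotypeMatrix,
    public_haps: HaplotypeMatrix,
    blocks: BlockMap,
    epsilon: float,
    seed: int | None = None,
    pool_min_count: float = 2.0,
) -> AlleleFrequencyTable:
    """Full haplotype-mechanism pipeline from phased cohorts to a release.

    Builds the common pool from the public cohort, maps rare case
    haplotypes onto it, perturbs the per-block histograms under the total
    budget and derives the released per-SNV frequencies.
    """
    pool = common_haplotype_pool(build_haplotype_table(public_haps, blocks), pool_min_count)
    case_table = map_rare_haplotypes(build_haplotype_table(case_haps, blocks), pool)
    noisy = perturb_haplotype(case_table, epsilon, seed=seed)
    return haplotype_counts_to_allele_counts(noisy, blocks, case_haps.snv_ids)
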