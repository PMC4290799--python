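"""Synthetic haploblock cohort generator with planted associations.

Emulates the structure of the challenge data — a few hundred SNVs spanning
consecutive haploblocks, a small haplotype pool per block, a case cohort
whose haplotype frequencies are shifted on some blocks, and held-out test
individuals — so that every release mechanism and every attack can be
exercised end to end without any external download.

The sampling model is deliberately simple: within each block an
individual's two chromosome copies are two independent draws from the
block's haplotype pool (Hardy-Weinberg within block) and blocks are
independent of one another.  Small per-block pools create strong
within-block linkage disequilibrium; there is no cross-block LD,
recombination map or population structure.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import (
    BlockMap,
    GenotypeMatrix,
    HaplotypeMatrix,
    MISSING,
    ParameterError,
    ValidationError,
)
from .io import (
    write_block_map,
    write_genotype_matrix,
    write_haplotype_matrix,
)
from .topk import _chi2_vec


@dataclass
class BlockStructure:
    """Haploblock partition plus per-block haplotype pools and frequencies."""

    block_map: BlockMap
    snv_ids: list[str]
    positions: np.ndarray
    pools: list[list[str]]  # distinct binary haplotype strings per block
    control_freqs: list[np.ndarray]  # simplex per block

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def snv_frequencies(self, block_freqs: list[np.ndarray]) -> np.ndarray:
        """Population minor-allele frequency per SNV implied by pool frequencies."""
        out = np.empty(self.n_snvs)
        for idx, pool, f in zip(self.block_map.blocks, self.pools, block_freqs):
            alleles = np.array([[int(ch) for ch in h] for h in pool], dtype=float)
            out[idx] = f @ alleles
        return out


@dataclass
class SyntheticTruth:
    """Ground truth recorded at generation time."""

    planted_snvs: list[str]
    true_ranking: list[str]  # SNVs by infinite-data chi-square, strongest first
    effects: dict[int, float]
    effect_threshold: float
    control_snv_freqs: np.ndarray
    case_snv_freqs: np.ndarray
    seed: int


@dataclass
class Cohorts:
    """Case/control/test cohorts drawn from one block structure."""

    structure: BlockStructure
    case_haps: HaplotypeMatrix
    control_haps: HaplotypeMatrix
    test_haps: HaplotypeMatrix
    case: GenotypeMatrix
    control: GenotypeMatrix
    test: GenotypeMatrix
    truth: SyntheticTruth


def generate_block_structure(
    n_blocks: int,
    snvs_per_block: tuple[int, int] = (19, 26),
    haplotypes_per_block: tuple[int, int] = (3, 5),
    seed: int = 0,
    concentration: float = 1.0,
    total_snvs: int | None = None,
) -> BlockStructure:
    """Random haploblock structure with Dirichlet pool frequencies.

    Block sizes and pool sizes are drawn uniformly from the given
    inclusive ranges; when ``total_snvs`` is set the rounding difference
    is spread across blocks so the total matches exactly.  Pool
    haplotypes come from a small mutation genealogy per block
    (:func:`_mutation_tree_pool`); their control-population frequencies
    are sorted Dirichlet(``concentration``) weights, the ancestral
    haplotype being the most common.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = snvs_per_block
    sizes = rng.integers(lo, hi + 1, size=n_blocks)
    if total_snvs is not None:
        if not n_blocks <= total_snvs:
            raise ParameterError("total_snvs too small for the block count")
        # spread the rounding difference over blocks, one SNV at a time
        diff = total_snvs - int(sizes.sum())
        step = 1 if diff > 0 else -1
        b = 0
        while diff != 0:
            if sizes[b % n_blocks] + step >= 1:
                sizes[b % n_blocks] += step
                diff -= step
            b += 1
    h_lo, h_hi = haplotypes_per_block
    pools: list[list[str]] = []
    freqs: list[np.ndarray] = []
    for s in sizes:
        cap = 2 ** min(int(s), 30)
        if h_lo > cap:
            raise ParameterError(
                f"pool size {h_lo} exceeds 2^{s} possible haplotypes of a block"
            )
        h = int(rng.integers(h_lo, min(h_hi, cap) + 1))
        pools.append(_mutation_tree_pool(int(s), h, rng))
        # descending Dirichlet weights: the ancestral haplotype is the most
        # common, recently derived ones the rarest
        freqs.append(np.sort(rng.dirichlet(np.full(h, concentration)))[::-1])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    block_map = BlockMap(
        blocks=[np.arange(bounds[b], bounds[b + 1]) for b in range(n_blocks)],
        n_snvs=int(bounds[-1]),
    )
    n = int(bounds[-1])
    positions = np.cumsum(rng.integers(100, 2000, size=n)) + 1
    snv_ids = [f"rs{i + 1:05d}" for i in range(n)]
    return BlockStructure(
        block_map=block_map,
        snv_ids=snv_ids,
        positions=positions,
        pools=pools,
        control_freqs=freqs,
    )


def _mutation_tree_pool(block_size: int, n_haplotypes: int, rng) -> list[str]:
    """Distinct block haplotypes generated along a simple mutation genealogy.

    The first haplotype is ancestral; each further one copies a random
    earlier haplotype and flips one to three previously untouched sites
    (its private mutations).  Sites left monomorphic are made segregating
    by a single extra mutation on a random non-ancestral haplotype.  This
    mimics how real haploblock pools look: few distinct haplotypes, a
    skewed site-frequency spectrum, and rare haplotypes distinguished by
    private alleles.
    """
    haps = [rng.integers(0, 2, size=block_size).astype(np.int8)]
    mutated = np.zeros(block_size, dtype=bool)
    while len(haps) < n_haplotypes:
        parent = haps[int(rng.integers(len(haps)))].copy()
        free = np.flatnonzero(~mutated)
        if free.size == 0:
            free = np.arange(block_size)
        k = min(int(rng.integers(1, 4)), free.size)
        sites = rng.choice(free, size=k, replace=False)
        parent[sites] ^= 1
        if any(np.array_equal(parent, h) for h in haps):
            continue
        mutated[sites] = True
        haps.append(parent)
    arr = np.array(haps)
    mono = np.flatnonzero(arr.min(axis=0) == arr.max(axis=0))
    for j in mono:
        arr[int(rng.integers(1, n_haplotypes)) if n_haplotypes > 1 else 0, j] ^= 1
    # re-deduplicate in the unlikely event the extra mutations collided
    if len({("".join(map(str, row))) for row in arr}) < n_haplotypes:
        return _mutation_tree_pool(block_size, n_haplotypes, rng)
    return ["".join(map(str, row)) for row in arr]


def shift_block_frequencies(
    freqs: np.ndarray, delta: float, risk_index: int | None = None
) -> np.ndarray:
    """Move ``delta`` probability mass onto the block's risk haplotype.

    By default the risk haplotype is the one whose control frequency is
    closest to 0.028 (preferring haplotypes at or above 0.015): risk
    haplotypes enriched in cases are typically rare in controls, yet they
    must be segregating there, or they would be absent from any public
    common-haplotype pool.  The remaining haplotypes are rescaled
    proportionally; raises before sampling if the shifted vector leaves
    the simplex.
    """
    if risk_index is None:
        eligible = np.flatnonzero(freqs >= 0.015)
        pick_from = eligible if eligible.size else np.arange(len(freqs))
        risk_index = int(pick_from[np.argmin(np.abs(freqs[pick_from] - 0.028))])
    f0 = freqs[risk_index]
    if f0 + delta > 1.0 + 1e-12 or delta < 0:
        raise ValidationError(
            f"shift {delta} pushes the risk-haplotype frequency {f0:.3f} off the simplex"
        )
    if f0 >= 1.0:
        raise ValidationError("cannot shift a monomorphic block")
    out = freqs * (1.0 - f0 - delta) / (1.0 - f0)
    out[risk_index] = f0 + delta
    return out


def _draw_haplotypes(
    structure: BlockStructure,
    block_freqs: list[np.ndarray],
    n_individuals: int,
    prefix: str,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    alleles = np.empty((2 * n_individuals, structure.n_snvs), dtype=np.int8)
    for idx, pool, f in zip(structure.block_map.blocks, structure.pools, block_freqs):
        hap_alleles = np.array([[int(ch) for ch in h] for h in pool], dtype=np.int8)
        picks = rng.choice(len(pool), size=2 * n_individuals, p=f)
        alleles[:, idx] = hap_alleles[picks]
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_individuals)]
    return HaplotypeMatrix(
        individual_ids=ids,
        snv_ids=list(structure.snv_ids),
        alleles=alleles,
        positions=structure.positions,
    )


def draw_cohort(
    structure: BlockStructure,
    n_individuals: int,
    seed: int,
    prefix: str = "ind",
    block_freqs: list[np.ndarray] | None = None,
) -> HaplotypeMatrix:
    """Draw one i.i.d. cohort from the structure's (or given) pool frequencies.

    Useful for protocols that need extra cohorts beyond case/control/test,
    e.g. null calibration with evaluated individuals outside the released
    cohort.
    """
    rng = np.random.default_rng(seed)
    return _draw_haplotypes(
        structure,
        block_freqs if block_freqs is not None else structure.control_freqs,
        n_individuals,
        prefix,
        rng,
    )


def generate_cohorts(
    structure: BlockStructure,
    n_case: int,
    n_control: int,
    n_test: int,
    effects: dict[int, float] | None = None,
    seed: int = 0,
    missing_rate: float = 0.0,
    effect_threshold: float = 0.05,
) -> Cohorts:
    """Draw case/control/test cohorts; the case pool frequencies carry the effects.

    ``effects`` maps block index -> frequency shift planted on that
    block's risk haplotype.  Control and test individuals are i.i.d. from
    the control pool frequencies, case individuals from the shifted ones;
    each individual is two independent haplotype draws per block.
    ``missing_rate`` masks that fraction of *case genotype* calls to
    exercise the filtering/imputation path (haplotypes stay complete).
    """
    effects = dict(effects or {})
    case_freqs = []
    for b, f in enumerate(structure.control_freqs):
        case_freqs.append(
            shift_block_frequencies(f, effects[b]) if b in effects else f.copy()
        )

    rng = np.random.default_rng(seed)
    case_haps = _draw_haplotypes(structure, case_freqs, n_case, "case", rng)
    control_haps = _draw_haplotypes(structure, structure.control_freqs, n_control, "ctrl", rng)
    test_haps = _draw_haplotypes(structure, structure.control_freqs, n_test, "test", rng)

    case = case_haps.collapse()
    if missing_rate > 0:
        mask = rng.random(case.dosages.shape) < missing_rate
        dosages = case.dosages.copy()
        dosages[mask] = MISSING
        case = GenotypeMatrix(
            individual_ids=case.individual_ids,
            snv_ids=case.snv_ids,
            dosages=dosages,
            positions=case.positions,
        )

    p = structure.snv_frequencies(structure.control_freqs)
    q = structure.snv_frequencies(case_freqs)
    stat = _chi2_vec(2.0 * n_case * q, 2.0 * n_case, 2.0 * n_control * p, 2.0 * n_control)
    order = sorted(range(structure.n_snvs), key=lambda j: (-stat[j], structure.snv_ids[j]))
    truth = SyntheticTruth(
        planted_snvs=[
            s for s, dq in zip(structure.snv_ids, np.abs(q - p)) if dq > effect_threshold
        ],
        true_ranking=[structure.snv_ids[j] for j in order],
        effects=effects,
        effect_threshold=effect_threshold,
        control_snv_freqs=p,
        case_snv_freqs=q,
        seed=seed,
    )
    return Cohorts(
        structure=structure,
        case_haps=case_haps,
        control_haps=control_haps,
        test_haps=test_haps,
        case=case,
        control=control_haps.collapse(),
        test=test_haps.collapse(),
        truth=truth,
    )


def plantable_blocks(
    structure: BlockStructure,
    n: int,
    band: tuple[float, float] = (0.015, 0.045),
    target: float = 0.028,
) -> list[int]:
    """Blocks best suited to carry a planted association, best first.

    A plantable block has a haplotype that is rare in controls yet
    clearly segregating (control frequency inside ``band``) — the profile
    of a realistic risk haplotype.  Blocks are ranked by how close their
    best candidate sits to ``target``.
    """
    scores = []
    for f in structure.control_freqs:
        eligible = f[f >= band[0]]
        scores.append(
            np.min(np.abs(eligible - target)) if eligible.size else np.inf
        )
    order = np.argsort(scores, kind="stable")
    return [int(b) for b in order[:n]]


# ---------------------------------------------------------------------------
# presets mirroring the two challenge tasks
# ---------------------------------------------------------------------------

#: Dataset-1-like conditions: 311 SNVs in 14 consecutive haploblocks,
#: 200 case / 174 control / 174 test diploid individuals, shared budget 1.
TASK1_PRESET = dict(
    n_blocks=14,
    snvs_per_block=(19, 26),
    haplotypes_per_block=(3, 5),
    total_snvs=311,
    n_case=200,
    n_control=174,
    n_test=174,
    # planted risk-haplotype shifts, strongest first, assigned to the
    # blocks best able to carry them; sized so the chi-square
    # significance profile resembles a single strongly associated locus
    # (tens of significant sites at p < 1e-5) and so that releasing the
    # exact case frequencies makes case members clearly re-identifiable
    effect_sizes=(0.20, 0.19, 0.18, 0.17, 0.17, 0.16),
)

#: Dataset-2-like conditions: 600 SNVs in 21 consecutive haploblocks with
#: weaker planted shifts — the "moderately challenging" archetype whose
#: re-identification risk the baseline mechanisms can fully mitigate.
TASK1_LARGE_PRESET = dict(
    n_blocks=21,
    snvs_per_block=(25, 32),
    haplotypes_per_block=(3, 5),
    total_snvs=600,
    n_case=200,
    n_control=174,
    n_test=174,
    effect_sizes=(0.16, 0.15, 0.13, 0.12),
)

#: Task-2-like conditions: 5000 SNVs sampled genome-wide and hence
#: effectively independent (single-SNV blocks), 201/174/174 individuals,
#: ten planted signals with strong graded contrasts.  Genome-wide
#: case/control comparisons between separately genotyped cohorts are
#: dominated by a handful of near-maximal-contrast sites, so the
#: strongest planted effects push the case frequency close to fixation.
TASK2_PRESET = dict(
    n_blocks=5000,
    snvs_per_block=(1, 1),
    haplotypes_per_block=(2, 2),
    total_snvs=5000,
    n_case=201,
    n_control=174,
    n_test=174,
    effect_sizes=tuple(np.round(np.linspace(0.93, 0.30, 20), 3)),
)


def preset_fixture(preset: dict, seed: int, missing_rate: float = 0.0) -> Cohorts:
    """Generate a cohort fixture from one of the preset condition sets."""
    structure = generate_block_structure(
        n_blocks=preset["n_blocks"],
        snvs_per_block=preset["snvs_per_block"],
        haplotypes_per_block=preset["haplotypes_per_block"],
        seed=seed,
        total_snvs=preset["total_snvs"],
    )
    deltas = preset["effect_sizes"]
    blocks = plantable_blocks(structure, len(deltas))
    effects = {b: float(d) for b, d in zip(blocks, deltas)}
    return generate_cohorts(
        structure,
        n_case=preset["n_case"],
        n_control=preset["n_control"],
        n_test=preset["n_test"],
        effects=effects,
        seed=seed + 1,
        missing_rate=missing_rate,
    )


def task1_fixture(seed: int = 0, **kw) -> Cohorts:
    return preset_fixture(TASK1_PRESET, seed, **kw)


def task2_fixture(seed: int = 0, **kw) -> Cohorts:
    return preset_fixture(TASK2_PRESET, seed, **kw)


PRESETS = {
    "task1-small": TASK1_PRESET,
    "task1-large": TASK1_LARGE_PRESET,
    "task2-small": TASK2_PRESET,
}


def write_challenge_fixture(cohorts: Cohorts, out_dir, force: bool = False) -> list[str]:
    """Write a cohort fixture as a challenge-format file set.

    Emits case/control/test genotype files in the challenge dialect,
    phased case/control haplotypes, the block map TSV and a truth JSON;
    refuses a non-empty existing directory unless ``force`` is set.
    Byte-identical for identical cohorts.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix(cohorts.case, out / "case.geno.txt")
    write_genotype_matrix(cohorts.control, out / "control.geno.txt")
    write_genotype_matrix(cohorts.test, out / "test.geno.txt")
    write_haplotype_matrix(cohorts.case_haps, out / "case.haps.txt")
    write_haplotype_matrix(cohorts.control_haps, out / "control.haps.txt")
    s = cohorts.structure
    write_block_map(s.block_map, s.snv_ids, out / "blocks.tsv", positions=s.positions)
    t = cohorts.truth
    truth = {
        "planted_snvs": t.planted_snvs,
        "true_ranking_top100": t.true_ranking[:100],
        "effects": {str(k): float(v) for k, v in sorted(t.effects.items())},
        "effect_threshold": t.effect_threshold,
        "seed": t.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    files = sorted(p.name for p in out.iterdir())
    return files


def file_digest(path) -> str:
    """Short sha256 digest used in run reports for reproducibility logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
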