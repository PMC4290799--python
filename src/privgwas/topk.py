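"""Differentially private release of the top-K most significant SNVs.

The released quantity is the *identity* of the K SNVs with the strongest
case/control allelic association.  Selection is by iterative peeling:
K rounds of the exponential mechanism, each spending epsilon/K, each over
the SNVs not yet selected, under one of two utility functions:

``chi2``
    The allelic chi-square statistic itself.  Its global sensitivity under
    add/remove-one-case-individual adjacency is obtained by exhaustive
    enumeration over all achievable 2x2 tables and single-individual
    moves (cached per cohort-size pair).

``hamming``
    A signed distance-to-significance: the minimum number of
    single-individual changes (genotype edits, additions or removals of
    one case individual) needed to move the SNV's chi-square across a
    boundary statistic, positive above the boundary, negative below.
    Scores are offset by 1/2 so that one individual's change moves any
    score by at most 1 — the utility has sensitivity exactly 1, which is
    why this utility needs far less selection randomness than the raw
    statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    AlleleFrequencyTable,
    EnumerationError,
    ParameterError,
    ValidationError,
)
from .mechanisms import exponential_mechanism

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chi-square association statistic
# ---------------------------------------------------------------------------

def chi2_stat(
    case_minor: float, case_total: float, control_minor: float, control_total: float
) -> float:
    """Allelic 2x2 Pearson chi-square (1 df, no continuity correction).

    Rows are case/control, columns minor/major allele counts.  Returns 0
    when a margin is degenerate (the pooled sample is all-minor or
    all-major).  Accepts real-valued (noisy) counts.
    """
    if case_minor > case_total or control_minor > control_total:
        raise ValidationError("minor count exceeds total")
    if case_minor < 0 or control_minor < 0:
        raise ValidationError("negative allele count")
    return float(
        _chi2_vec(
            np.asarray(case_minor, dtype=float),
            float(case_total),
            np.asarray(control_minor, dtype=float),
            float(control_total),
        )
    )


def _chi2_vec(a, case_total, c, control_total):
    """Vectorized Pearson chi-square over case minor counts ``a`` etc."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    b = case_total - a
    d = control_total - c
    n = case_total + control_total
    minor = a + c
    major = b + d
    denom = case_total * control_total * minor * major
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, stat, 0.0)


def chi2_pvalues(stats_: np.ndarray) -> np.ndarray:
    """Upper-tail 1-df p-values, monotone decreasing in the statistic."""
    return stats.chi2.sf(np.asarray(stats_, dtype=float), df=1)


@dataclass
class AssociationResult:
    """Per-SNV chi-square statistics and p-values of a case/control scan."""

    snv_ids: list[str]
    statistics: np.ndarray
    pvalues: np.ndarray

    def significant(self, cutoff: float) -> set[str]:
        return {s for s, p in zip(self.snv_ids, self.pvalues) if p < cutoff}


# ---------------------------------------------------------------------------
# utility sensitivities
# ---------------------------------------------------------------------------

_CHI2_SENSITIVITY_CACHE: dict[tuple[int, int], float] = {}


def chi2_sensitivity(
    n_case: int, n_control: int, allow_approx: bool = False, max_pairs: int = 10_000_000
) -> float:
    """Global sensitivity of :func:`chi2_stat` under add/remove one case individual.

    Exhaustively enumerates every achievable 2x2 table (case minor count
    ``a`` in 0..2*n_case, control minor count ``c`` in 0..2*n_control) and
    every single-individual removal (dosage 0, 1 or 2), taking the maximum
    absolute change of the statistic.  Additions are the reverse moves and
    are covered by symmetry.  The control cohort is public and fixed.

    For cohort sizes whose enumeration would exceed ``max_pairs``
    table-move pairs the exact computation is refused unless
    ``allow_approx`` is set, in which case the conservative analytic bound
    ``2 * (n_case + n_control)`` (the largest attainable statistic) is
    returned.
    """
    if n_case < 1 or n_control < 1:
        raise ParameterError("cohort sizes must be >= 1")
    key = (int(n_case), int(n_control))
    if key in _CHI2_SENSITIVITY_CACHE:
        return _CHI2_SENSITIVITY_CACHE[key]
    n_pairs = (2 * n_case + 1) * (2 * n_control + 1) * 3
    if n_pairs > max_pairs:
        if not allow_approx:
            raise EnumerationError(
                f"chi2 sensitivity enumeration needs {n_pairs} table-move pairs "
                f"(> {max_pairs}); pass allow_approx=True for the conservative bound"
            )
        return float(2 * (n_case + n_control))
    a = np.arange(2 * n_case + 1, dtype=float)[:, None, None]
    c = np.arange(2 * n_control + 1, dtype=float)[None, :, None]
    d = np.arange(3, dtype=float)[None, None, :]
    before = _chi2_vec(a, 2.0 * n_case, c, 2.0 * n_control)
    after = _chi2_vec(a - d, 2.0 * (n_case - 1), c, 2.0 * n_control)
    # the removed individual must actually be composable from the table:
    # it carries d minor and 2-d major alleles
    feasible = (a - d >= 0) & ((2 * n_case - a) - (2 - d) >= 0) & (n_case >= 2)
    diff = np.where(feasible, np.abs(after - before), 0.0)
    out = float(diff.max())
    _CHI2_SENSITIVITY_CACHE[key] = out
    return out


def _significance_region(case_total_alleles: int, control_minor, control_total, boundary):
    """Boolean mask over a = 0..2n of {chi2(a) >= boundary}."""
    a = np.arange(case_total_alleles + 1, dtype=float)
    return _chi2_vec(a, float(case_total_alleles), float(control_minor), float(control_total)) >= boundary


def _distance_to_set(a0: int, n0: int, control_minor, control_total, boundary, want_above: bool) -> float:
    """Min single-individual moves from (a0, n0) to a state on the target side.

    States are (case minor count a, case cohort size n); one move changes
    one individual's genotype (a by +-1 or +-2) or adds/removes one
    individual (n by +-1, a by 0..2 along with it), so the move distance
    between states is ``max(|n - n'|, ceil(|a - a'| / 2))``.  Removals are
    relaxed to count-feasibility.  Returns inf if no state on the target
    side exists anywhere on the grid.
    """
    best = math.inf
    dn = 0
    while dn < best:
        for n in {n0 - dn, n0 + dn}:
            if n < 1:
                continue
            region = _significance_region(2 * n, control_minor, control_total, boundary)
            hits = np.flatnonzero(region if want_above else ~region)
            if hits.size:
                a_dist = np.ceil(np.abs(hits - a0) / 2.0)
                cand = np.maximum(dn, a_dist).min()
                best = min(best, float(cand))
        dn += 1
        if dn > n0 + 64 and not math.isfinite(best):  # nothing anywhere nearby
            break
    return best


def hamming_utility(
    case_minor: float,
    case_total: float,
    control_minor: float,
    control_total: float,
    boundary_stat: float,
) -> float:
    """Signed, half-offset distance of a SNV's chi-square to ``boundary_stat``.

    ``+ (dist - 1/2)`` for SNVs strictly above the boundary, ``-(dist - 1/2)``
    strictly below, and exactly 0 at the boundary, where ``dist`` is the
    minimum number of single-individual changes needed to reach the other
    (closed) side.  The half offset makes the score 1-Lipschitz in the
    move metric, so its sensitivity under add/remove-one-individual
    adjacency is exactly 1.

    A site from which the boundary is unreachable anywhere on the count
    grid receives the floor ``-(2 * n_case)`` (logged).
    """
    n_case = int(round(case_total / 2))
    a0 = int(round(case_minor))
    stat = chi2_stat(a0, 2 * n_case, control_minor, control_total)
    if stat == boundary_stat:
        return 0.0
    above = stat > boundary_stat
    # distance to the closed region on the other side; the current side's
    # region is nonempty (the state itself), so only the other side can fail
    dist = _distance_to_set(
        a0, n_case, control_minor, control_total, boundary_stat, want_above=not above
    )
    if not math.isfinite(dist):
        logger.warning(
            "boundary %.3g unreachable for a monomorphic-like site; flooring score",
            boundary_stat,
        )
        return -float(2 * n_case)
    return (dist - 0.5) if above else -(dist - 0.5)


def hamming_scores(
    case_minor: np.ndarray,
    case_total: float,
    control_minor: np.ndarray,
    control_total: float,
    boundary_stat: float,
) -> np.ndarray:
    return np.array(
        [
            hamming_utility(a, case_total, c, control_total, boundary_stat)
            for a, c in zip(case_minor, control_minor)
        ]
    )


# ---------------------------------------------------------------------------
# release
# ---------------------------------------------------------------------------

@dataclass
class TopKRelease:
    """Outcome of a private top-K selection (SNVs in selection order)."""

    K: int
    released_snvs: list[str]
    utility_name: str
    epsilon_total: float

    def __post_init__(self) -> None:
        if len(self.released_snvs) != self.K:
            raise ValidationError("released list length must equal K")
        if len(set(self.released_snvs)) != self.K:
            raise ValidationError("released SNVs must be distinct")


def association_statistics(
    case_counts: AlleleFrequencyTable, control_counts: AlleleFrequencyTable
) -> np.ndarray:
    """Per-SNV chi-square statistics with the tables aligned by SNV id."""
    idx = control_counts.index_of(case_counts.snv_ids)
    if len(case_counts.snv_ids) != len(control_counts.snv_ids):
        raise ValidationError("case and control tables must share their SNV set")
    ct = float(np.unique(case_counts.totals)[0]) if case_counts.n_snvs else 0.0
    if not np.allclose(case_counts.totals, case_counts.totals[0]) or not np.allclose(
        control_counts.totals, control_counts.totals[0]
    ):
        # heterogeneous totals: fall back to per-SNV evaluation
        return np.array(
            [
                chi2_stat(
                    case_counts.minor_counts[j],
                    case_counts.totals[j],
                    control_counts.minor_counts[idx[j]],
                    control_counts.totals[idx[j]],
                )
                for j in range(case_counts.n_snvs)
            ]
        )
    return _chi2_vec(
        case_counts.minor_counts,
        ct,
        control_counts.minor_counts[idx],
        float(control_counts.totals[0]),
    )


def true_topk(
    case_counts: AlleleFrequencyTable, control_counts: AlleleFrequencyTable, k: int
) -> list[str]:
    """The exact (non-private) top-K, ties at the K-th statistic broken by SNV id."""
    stats_ = association_statistics(case_counts, control_counts)
    order = sorted(
        range(len(stats_)), key=lambda j: (-stats_[j], case_counts.snv_ids[j])
    )
    return [case_counts.snv_ids[j] for j in order[:k]]


def release_topk(
    case_counts: AlleleFrequencyTable,
    control_counts: AlleleFrequencyTable,
    k: int,
    epsilon_total: float,
    utility: str = "chi2",
    seed: int | None = None,
    sensitivity: float | None = None,
) -> TopKRelease:
    """Release K SNV identities by exponential-mechanism peeling.

    Each of the K rounds spends ``epsilon_total / K`` selecting one SNV
    from the not-yet-released pool (sequential composition exhausts the
    budget exactly).  ``sensitivity`` overrides the utility's Delta_u —
    by default the enumerated chi-square sensitivity for ``utility="chi2"``
    and 1 for ``utility="hamming"``.
    """
    if epsilon_total <= 0:
        raise ParameterError("epsilon_total must be positive")
    m = case_counts.n_snvs
    if not 1 <= k <= m:
        raise ParameterError(f"K must be in 1..{m}")
    if utility not in ("chi2", "hamming"):
        raise ParameterError(f"unknown utility {utility!r}")
    stats_ = association_statistics(case_counts, control_counts)
    idx = control_counts.index_of(case_counts.snv_ids)
    control_minor = control_counts.minor_counts[idx]
    control_total = float(control_counts.totals[0])
    case_total = float(case_counts.totals[0])

    if sensitivity is None:
        if utility == "chi2":
            n_case = int(round(case_total / 2))
            n_control = int(round(control_total / 2))
            sensitivity = chi2_sensitivity(n_case, n_control)
        else:
            sensitivity = 1.0

    rng = np.random.default_rng(seed)
    remaining = list(range(m))
    released: list[str] = []
    eps_round = epsilon_total / k
    for _ in range(k):
        rem_stats = stats_[remaining]
        if utility == "chi2":
            scores = rem_stats
        else:
            kth = min(k, len(remaining)) - 1
            boundary = float(np.sort(rem_stats)[::-1][kth])
            scores = hamming_scores(
                case_counts.minor_counts[remaining],
                case_total,
                control_minor[remaining],
                control_total,
                boundary,
            )
        pick = exponential_mechanism(scores, sensitivity, eps_round, rng=rng)
        released.append(case_counts.snv_ids[remaining[pick]])
        del remaining[pick]
    return TopKRelease(
        K=k, released_snvs=released, utility_name=utility, epsilon_total=epsilon_total
    )


def topk_overlap(released: TopKRelease | list[str], true_top: list[str]) -> float:
    """Fraction of the released SNVs that are among the actual top-K."""
    rel = released.released_snvs if isinstance(released, TopKRelease) else list(released)
    if len(rel) != len(true_top):
        raise ValidationError(
            f"released list (n={len(rel)}) and true top-K (n={len(true_top)}) differ in size"
        )
    return len(set(rel) & set(true_top)) / len(true_top)


# ---------------------------------------------------------------------------
# scorers for the exact DP verifier (toy enumerable domains)
# ---------------------------------------------------------------------------

def chi2_selection_scorer(control_minor: np.ndarray, control_total: int):
    """Scorer mapping a case dataset (tuple of dosage tuples) to chi2 per SNV."""
    control_minor = np.asarray(control_minor, dtype=float)

    def scorer(dataset) -> np.ndarray:
        geno = np.asarray(dataset, dtype=float)  # (n_individuals, n_snvs)
        a = geno.sum(axis=0)
        return _chi2_vec(a, 2.0 * geno.shape[0], control_minor, float(control_total))

    return scorer


def hamming_selection_scorer(
    control_minor: np.ndarray, control_total: int, boundary_stat: float
):
    """Scorer with the fixed-boundary Hamming utility per SNV."""
    control_minor = np.asarray(control_minor, dtype=float)

    def scorer(dataset) -> np.ndarray:
        geno = np.asarray(dataset, dtype=float)
        a = geno.sum(axis=0)
        return np.array(
            [
                hamming_utility(
                    a[t], 2.0 * geno.shape[0], control_minor[t], float(control_total), boundary_stat
                )
                for t in range(geno.shape[1])
            ]
        )

    return scorer
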