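"""Differential-privacy primitives.

Implements the two classical mechanisms used throughout the package —
Laplace noise addition for numeric releases and exponential-mechanism
selection for discrete releases — plus proportional budget allocation
across haploblocks and an *exact* verifier that certifies the
epsilon-DP inequality on enumerable domains by computing selection
probabilities on both sides of every neighbor pair.

Conventions
-----------
* Adjacency is add/remove one diploid individual (unbounded DP).
* Laplace noise is drawn by inverse CDF from a single
  ``numpy.random.default_rng(seed)`` uniform stream, one uniform per
  draw, so the sequence is platform-stable.
* The exponential mechanism uses the McSherry–Talwar form: candidate
  ``t`` is selected with probability proportional to
  ``exp(epsilon * u_t / (2 * delta_u))``.  The factor-2 conservatism is
  kept even for monotone utilities.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .datamodel import EnumerationError, ParameterError


def _as_rng(seed=None, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def laplace_noise(n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` i.i.d. Laplace(0, scale) draws via inverse CDF of one uniform each."""
    u = rng.random(n) - 0.5
    return -scale * np.sign(u) * np.log1p(-2.0 * np.abs(u))


def laplace_mechanism(
    values, sensitivity: float, epsilon: float, seed: int | None = None, rng=None
) -> np.ndarray:
    """Add i.i.d. Laplace(0, sensitivity / epsilon) noise to ``values``."""
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    if sensitivity <= 0:
        raise ParameterError("sensitivity must be positive")
    values = np.asarray(values, dtype=float)
    gen = _as_rng(seed, rng)
    return values + laplace_noise(values.size, sensitivity / epsilon, gen).reshape(
        values.shape
    )


def exponential_mechanism_probabilities(
    scores, sensitivity: float, epsilon: float
) -> np.ndarray:
    """Exact selection probabilities ``softmax(epsilon * u / (2 delta_u))``.

    Scores are max-shifted before exponentiation for numerical stability;
    the shift cancels in the normalisation, so probabilities are invariant
    under adding a constant to all scores.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    if sensitivity <= 0:
        raise ParameterError("utility sensitivity must be positive")
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ParameterError("empty candidate list")
    z = epsilon * scores / (2.0 * sensitivity)
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def exponential_mechanism(
    scores, sensitivity: float, epsilon: float, seed: int | None = None, rng=None
) -> int:
    """Select one candidate index with probability ``∝ exp(eps·u/(2Δu))``."""
    p = exponential_mechanism_probabilities(scores, sensitivity, epsilon)
    gen = _as_rng(seed, rng)
    return int(gen.choice(p.size, p=p))


def allocate_budget(block_haplotype_counts, epsilon_total: float) -> np.ndarray:
    """Split a total budget across blocks proportionally to haplotype counts.

    ``eps_b = epsilon_total * h_b / sum(h)``.  Blocks with more distinct
    haplotypes receive a larger share (hence less noise per count); the
    per-block releases compose sequentially so the shares sum to the total.
    """
    counts = np.asarray(block_haplotype_counts, dtype=float)
    if epsilon_total <= 0:
        raise ParameterError("epsilon_total must be positive")
    if counts.size == 0 or (counts < 1).any():
        raise ParameterError("all block haplotype counts must be >= 1")
    return epsilon_total * counts / counts.sum()


@dataclass
class DPVerification:
    """Outcome of an exact DP check over an enumerated neighbor relation."""

    max_log_ratio: float
    epsilon: float
    n_pairs: int
    witness: tuple | None = None  # (D, D', candidate index) attaining the max

    @property
    def passed(self) -> bool:
        return self.max_log_ratio <= self.epsilon + 1e-9


def verify_exponential_dp(
    candidate_scorer: Callable[[object], np.ndarray],
    neighbor_enumerator: Callable[[], Iterable[tuple[object, object]]],
    epsilon: float,
    sensitivity: float,
    max_pairs: int = 200_000,
) -> DPVerification:
    """Certify epsilon-DP of exponential-mechanism selection *exactly*.

    For every enumerated neighbor pair ``(D, D')`` the exact selection
    probabilities of every candidate are computed on both sides and the
    maximum ``|log(P_D(t) / P_D'(t))|`` is taken.  The mechanism satisfies
    epsilon-DP on the enumerated relation iff the maximum is at most
    ``epsilon`` (up to 1e-9 slack).

    Raises :class:`EnumerationError` rather than silently truncating when
    more than ``max_pairs`` pairs are enumerated.
    """
    max_ratio = -np.inf
    witness = None
    n_pairs = 0
    for D, Dp in neighbor_enumerator():
        n_pairs += 1
        if n_pairs > max_pairs:
            raise EnumerationError(
                f"neighbor enumeration exceeds the budget of {max_pairs} pairs"
            )
        p = exponential_mechanism_probabilities(candidate_scorer(D), sensitivity, epsilon)
        q = exponential_mechanism_probabilities(candidate_scorer(Dp), sensitivity, epsilon)
        ratios = np.abs(np.log(p) - np.log(q))
        t = int(np.argmax(ratios))
        if ratios[t] > max_ratio:
            max_ratio = float(ratios[t])
            witness = (D, Dp, t)
    if n_pairs == 0:
        raise ParameterError("neighbor enumerator produced no pairs")
    return DPVerification(
        max_log_ratio=max_ratio, epsilon=epsilon, n_pairs=n_pairs, witness=witness
    )


def enumerate_case_neighbors(
    n_individuals: int, n_snvs: int
) -> Iterable[tuple[tuple, tuple]]:
    """All (D, D') with D a size-``n`` case multiset and D' = D minus one individual.

    An individual is a tuple of dosages, one per SNV; a dataset is a sorted
    tuple of individuals.  Both directions of the DP inequality are covered
    because the verifier takes absolute log-ratios.
    """
    types = list(itertools.product((0, 1, 2), repeat=n_snvs))
    for D in itertools.combinations_with_replacement(types, n_individuals):
        for ind in sorted(set(D)):
            Dp = list(D)
            Dp.remove(ind)
            yield D, tuple(Dp)


def enumerated_utility_sensitivity(
    candidate_scorer: Callable[[object], np.ndarray],
    neighbor_enumerator: Callable[[], Iterable[tuple[object, object]]],
) -> float:
    """Exact global utility sensitivity max |u(D,t) - u(D',t)| over the relation."""
    worst = 0.0
    for D, Dp in neighbor_enumerator():
        gap = np.max(np.abs(candidate_scorer(D) - candidate_scorer(Dp)))
        worst = max(worst, float(gap))
    return worst
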