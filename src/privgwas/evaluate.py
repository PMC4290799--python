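"""Re-identification risk and utility scoring of perturbed releases.

Privacy risk is quantified with the likelihood-ratio (LR) membership
statistic: for an individual with minor-allele dosages ``x_j`` over ``m``
SNVs,

    L = sum_j [ x_j * log(q_j / p_j) + (2 - x_j) * log((1 - q_j) / (1 - p_j)) ]

where ``q_j`` is the (released) case-group minor-allele frequency and
``p_j`` the reference-population frequency.  Large L is evidence that the
individual's genome was averaged into the released frequencies.  The
diploid form weighs the two chromosome copies of the classical per-allele
statistic.

The *power* of the attack is the fraction of true case members whose L
exceeds a threshold calibrated on a held-out test group (the empirical
(1 - alpha) quantile of the test group's L values); a release is
considered protective when power is not significantly above alpha.

Utility is the agreement of the chi-square association scan on perturbed
versus original data: TPR/FPR of significance calls at fixed p-value
cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    ValidationError,
)
from .topk import AssociationResult, association_statistics, chi2_pvalues

#: Frequencies are clipped to [CLIP, 1 - CLIP] so monomorphic sites cannot
#: produce infinite log terms; applied identically to both tables.
CLIP = 1e-6


def _aligned_log_terms(
    snv_ids,
    case_freqs: AlleleFrequencyTable,
    ref_freqs: AlleleFrequencyTable,
    case_in_numerator: bool,
):
    q = case_freqs.frequencies[case_freqs.index_of(snv_ids)]
    p = ref_freqs.frequencies[ref_freqs.index_of(snv_ids)]
    if not case_in_numerator:
        q, p = p, q
    q = np.clip(q, CLIP, 1 - CLIP)
    p = np.clip(p, CLIP, 1 - CLIP)
    return np.log(q / p), np.log((1 - q) / (1 - p))


def lr_statistic(
    dosages,
    case_freqs: AlleleFrequencyTable,
    ref_freqs: AlleleFrequencyTable,
    snv_ids=None,
    case_in_numerator: bool = True,
) -> float:
    """LR membership statistic of one individual.

    ``dosages`` are the individual's minor-allele counts over ``snv_ids``
    (defaults to the case table's SNV order).  With
    ``case_in_numerator=False`` the roles of the two tables in the log
    ratios are swapped (the literal textbook orientation, under which
    large values favour *reference* membership).
    """
    dosages = np.asarray(dosages, dtype=float)
    if snv_ids is None:
        snv_ids = case_freqs.snv_ids
    if dosages.shape != (len(snv_ids),):
        raise ValidationError("dosage vector length must match the SNV list")
    minor_term, major_term = _aligned_log_terms(
        snv_ids, case_freqs, ref_freqs, case_in_numerator
    )
    return float(np.sum(dosages * minor_term + (2.0 - dosages) * major_term))


def lr_statistics(
    genotypes: GenotypeMatrix,
    case_freqs: AlleleFrequencyTable,
    ref_freqs: AlleleFrequencyTable,
    case_in_numerator: bool = True,
) -> np.ndarray:
    """Vector of LR statistics, one per individual of ``genotypes``."""
    if genotypes.has_missing():
        raise ValidationError("genotypes must be complete for the LR statistic")
    minor_term, major_term = _aligned_log_terms(
        genotypes.snv_ids, case_freqs, ref_freqs, case_in_numerator
    )
    d = genotypes.dosages.astype(float)  # (n_snvs, n_individuals)
    return d.T @ minor_term + (2.0 - d.T) @ major_term


@dataclass
class LRResult:
    """Per-individual LR statistics of the case and test groups."""

    case_ids: list[str]
    case_lr: np.ndarray
    test_ids: list[str]
    test_lr: np.ndarray
    threshold: float
    m: int  # number of SNV sites summed


@dataclass
class ReidPower:
    """Outcome of the re-identification protocol."""

    power: float
    threshold: float
    pvalue: float  # one-sided exact binomial test of power > alpha
    alpha: float
    lr: LRResult


def reid_power(
    case: GenotypeMatrix,
    test: GenotypeMatrix,
    released_case_freqs: AlleleFrequencyTable,
    ref_freqs: AlleleFrequencyTable,
    alpha: float = 0.05,
    case_in_numerator: bool = True,
) -> ReidPower:
    """Power of the LR membership attack against a released frequency table.

    The threshold is the empirical ``1 - alpha`` quantile of the test
    group's LR values (Weibull plotting position, whose null exceedance
    probability is alpha to first order); power is the fraction of case
    individuals strictly above it.  Also reports the one-sided exact
    binomial p-value for power exceeding alpha.
    """
    import warnings

    if test.n_individuals < 20:
        warnings.warn(
            f"test group has only {test.n_individuals} individuals; "
            "the threshold quantile is unstable",
            stacklevel=2,
        )
    case_lr = lr_statistics(case, released_case_freqs, ref_freqs, case_in_numerator)
    test_lr = lr_statistics(test, released_case_freqs, ref_freqs, case_in_numerator)
    threshold = float(np.quantile(test_lr, 1.0 - alpha, method="weibull"))
    n_above = int((case_lr > threshold).sum())
    power = n_above / case.n_individuals
    pvalue = stats.binomtest(
        n_above, case.n_individuals, alpha, alternative="greater"
    ).pvalue
    return ReidPower(
        power=power,
        threshold=threshold,
        pvalue=float(pvalue),
        alpha=alpha,
        lr=LRResult(
            case_ids=list(case.individual_ids),
            case_lr=case_lr,
            test_ids=list(test.individual_ids),
            test_lr=test_lr,
            threshold=threshold,
            m=case.n_snvs,
        ),
    )


def association_scan(
    case_counts: AlleleFrequencyTable, control_counts: AlleleFrequencyTable
) -> AssociationResult:
    """Chi-square allelic scan; accepts real-valued (noisy) case counts."""
    if (case_counts.minor_counts < 0).any() or (control_counts.minor_counts < 0).any():
        raise ValidationError("negative counts: clamp perturbed counts before scanning")
    stats_ = association_statistics(case_counts, control_counts)
    return AssociationResult(
        snv_ids=list(case_counts.snv_ids),
        statistics=stats_,
        pvalues=chi2_pvalues(stats_),
    )


@dataclass
class TprFpr:
    """Significance agreement between a perturbed and the true scan."""

    tpr: float | None
    fpr: float | None
    n_true_significant: int
    n_perturbed_significant: int
    cutoff: float
    undefined_reason: str | None = None


def tpr_fpr(
    perturbed_scan: AssociationResult, true_scan: AssociationResult, cutoff: float
) -> TprFpr:
    """TPR/FPR of the perturbed scan's significance calls at ``cutoff``.

    Truth = SNVs significant in the true scan.  Undefined denominators
    (empty truth, or truth covering the whole universe) are reported as
    ``None`` with a reason, never coerced to 0/0.
    """
    if not true_scan.snv_ids:
        raise ValidationError("empty SNV universe")
    if set(perturbed_scan.snv_ids) != set(true_scan.snv_ids):
        raise ValidationError("scans must cover the same SNV universe")
    universe = set(true_scan.snv_ids)
    truth = true_scan.significant(cutoff)
    positive = perturbed_scan.significant(cutoff)
    tpr = fpr = None
    reason = None
    if truth:
        tpr = len(positive & truth) / len(truth)
    else:
        reason = "no truly significant SNV at this cutoff"
    negatives = universe - truth
    if negatives:
        fpr = len(positive - truth) / len(negatives)
    else:
        reason = "every SNV is truly significant at this cutoff"
    return TprFpr(
        tpr=tpr,
        fpr=fpr,
        n_true_significant=len(truth),
        n_perturbed_significant=len(positive),
        cutoff=cutoff,
        undefined_reason=reason,
    )
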