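"""Cohort preprocessing: completeness filters, imputation, allele counting.

These mirror the harmonisation steps needed before any case/control
comparison: the two cohorts must share an SNV set, sites genotyped in too
few individuals are unreliable for frequency estimation, and sparsely
genotyped individuals are dropped before the remaining holes are imputed
from reference allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeMatrix,
    ValidationError,
)


@dataclass
class FilterReport:
    """Counts removed at each filtering step (accumulated to fixpoint)."""

    snvs_not_shared: int = 0
    snvs_low_coverage: int = 0
    case_individuals_removed: int = 0
    control_individuals_removed: int = 0
    n_snvs_kept: int = 0
    n_case_kept: int = 0
    n_control_kept: int = 0


def preprocess_filter(
    case: GenotypeMatrix,
    control: GenotypeMatrix,
    min_individuals_per_snv: int = 0,
    min_snvs_per_individual: int = 0,
) -> tuple[GenotypeMatrix, GenotypeMatrix, FilterReport]:
    """Harmonise case/control SNV sets and drop under-genotyped data.

    Steps, iterated to a fixpoint so the operation is idempotent:

    1. drop SNVs absent from either cohort;
    2. drop SNVs with fewer than ``min_individuals_per_snv`` non-missing
       *case* genotypes;
    3. drop individuals (in either cohort) with fewer than
       ``min_snvs_per_individual`` non-missing genotypes.

    Raises if nothing survives.
    """
    report = FilterReport()

    control_set = set(control.snv_ids)
    shared = [s for s in case.snv_ids if s in control_set]
    report.snvs_not_shared = (
        case.n_snvs - len(shared) + control.n_snvs - len(shared)
    )
    case_lookup = {s: i for i, s in enumerate(case.snv_ids)}
    case = case.subset(snv_idx=[case_lookup[s] for s in shared])
    lookup = {s: i for i, s in enumerate(control.snv_ids)}
    control = control.subset(snv_idx=[lookup[s] for s in shared])

    while True:
        changed = False
        # site coverage in the case cohort
        cover = (case.dosages != MISSING).sum(axis=1)
        keep_snv = cover >= min_individuals_per_snv
        if not keep_snv.all():
            report.snvs_low_coverage += int((~keep_snv).sum())
            idx = np.flatnonzero(keep_snv)
            case = case.subset(snv_idx=idx)
            control = control.subset(snv_idx=idx)
            changed = True
        # individual completeness, both cohorts
        for which in ("case", "control"):
            m = case if which == "case" else control
            if m.n_snvs == 0:
                break
            n_called = (m.dosages != MISSING).sum(axis=0)
            keep_ind = n_called >= min_snvs_per_individual
            if not keep_ind.all():
                removed = int((~keep_ind).sum())
                m = m.subset(individual_idx=np.flatnonzero(keep_ind))
                if which == "case":
                    report.case_individuals_removed += removed
                    case = m
                else:
                    report.control_individuals_removed += removed
                    control = m
                changed = True
        if case.n_snvs == 0 or case.n_individuals == 0 or control.n_individuals == 0:
            raise ValidationError("no data survives filters")
        if not changed:
            break

    report.n_snvs_kept = case.n_snvs
    report.n_case_kept = case.n_individuals
    report.n_control_kept = control.n_individuals
    return case, control, report


def impute_missing(
    matrix: GenotypeMatrix, ref_freqs: AlleleFrequencyTable, seed: int
) -> GenotypeMatrix:
    """Replace missing dosages by Binomial(2, reference frequency) draws.

    A simple frequency-preserving imputer: downstream chi-square and
    likelihood-ratio computations only consume marginal allele
    frequencies, which Binomial draws preserve in expectation.
    Deterministic under ``seed``; non-missing entries are untouched.
    """
    missing_rows = np.flatnonzero((matrix.dosages == MISSING).any(axis=1))
    if missing_rows.size == 0:
        return matrix
    lookup = {s: i for i, s in enumerate(ref_freqs.snv_ids)}
    for i in missing_rows:
        if matrix.snv_ids[i] not in lookup:
            raise ValidationError(
                f"SNV {matrix.snv_ids[i]!r} has missing genotypes but no reference frequency"
            )
    rng = np.random.default_rng(seed)
    dosages = matrix.dosages.copy()
    freqs = ref_freqs.frequencies
    for i in missing_rows:  # row-major order fixes the draw sequence
        f = freqs[lookup[matrix.snv_ids[i]]]
        holes = np.flatnonzero(dosages[i] == MISSING)
        dosages[i, holes] = rng.binomial(2, f, size=holes.size)
    return GenotypeMatrix(
        individual_ids=list(matrix.individual_ids),
        snv_ids=list(matrix.snv_ids),
        dosages=dosages,
        positions=matrix.positions,
    )


def compute_allele_counts(matrix: GenotypeMatrix) -> AlleleFrequencyTable:
    """Tally minor-allele counts per SNV; requires a complete matrix."""
    if matrix.has_missing():
        raise ValidationError(
            "matrix has missing genotypes; filter or impute before counting"
        )
    counts = matrix.dosages.sum(axis=1).astype(float)
    totals = np.full(matrix.n_snvs, 2.0 * matrix.n_individuals)
    return AlleleFrequencyTable(
        snv_ids=list(matrix.snv_ids), minor_counts=counts, totals=totals
    )
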