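"""Core containers for haploblock-structured case/control genotype studies.

All containers are thin, validated wrappers around numpy arrays.  The
canonical genotype encoding is the minor-allele *dosage*: 0, 1 or 2 copies
of the minor allele per diploid individual at a biallelic SNV.  Missing
genotypes are stored as the :data:`MISSING` sentinel, which is distinct
from every valid dosage and is never silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Sentinel for a missing genotype call.  Never a valid dosage.
MISSING: int = -9


class FormatError(ValueError):
    """A file does not conform to the expected challenge dialect."""


class ValidationError(ValueError):
    """A container invariant is violated."""


class ParameterError(ValueError):
    """A mechanism parameter is out of its admissible range."""


class EnumerationError(RuntimeError):
    """An exact enumeration would exceed its stated budget."""


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{what} are not unique")


@dataclass
class GenotypeMatrix:
    """Diploid minor-allele dosages, one row per SNV, one column per individual.

    Parameters
    ----------
    individual_ids
        Column labels; unique.
    snv_ids
        Row labels; unique.  Row order is genomic order.
    dosages
        Integer matrix of shape ``(n_snvs, n_individuals)`` with entries in
        ``{0, 1, 2}`` or :data:`MISSING`.
    positions
        Optional 1-based genomic coordinates, one per SNV.
    """

    individual_ids: list[str]
    snv_ids: list[str]
    dosages: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.snv_ids), len(self.individual_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.snv_ids)} SNVs x {len(self.individual_ids)} individuals"
            )
        _check_unique(self.snv_ids, "SNV ids")
        _check_unique(self.individual_ids, "individual ids")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.dosages[~valid].flat[0]
            raise ValidationError(f"invalid dosage value {bad!r}")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (len(self.snv_ids),):
                raise ValidationError("positions length does not match SNV count")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def subset(self, snv_idx=None, individual_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        snv_idx = np.arange(self.n_snvs) if snv_idx is None else np.asarray(snv_idx)
        ind_idx = (
            np.arange(self.n_individuals)
            if individual_idx is None
            else np.asarray(individual_idx)
        )
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in ind_idx],
            snv_ids=[self.snv_ids[i] for i in snv_idx],
            dosages=self.dosages[np.ix_(snv_idx, ind_idx)],
            positions=None if self.positions is None else self.positions[snv_idx],
        )


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: two chromosome copies per individual.

    ``alleles`` has shape ``(2 * n_individuals, n_snvs)``; rows ``2i`` and
    ``2i + 1`` are the two copies of individual ``i``.  Entry 1 means the
    minor allele.
    """

    individual_ids: list[str]
    snv_ids: list[str]
    alleles: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.shape != (2 * len(self.individual_ids), len(self.snv_ids)):
            raise ValidationError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"2 x {len(self.individual_ids)} copies x {len(self.snv_ids)} SNVs"
            )
        _check_unique(self.snv_ids, "SNV ids")
        _check_unique(self.individual_ids, "individual ids")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValidationError("haplotype alleles must be 0/1")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def collapse(self) -> GenotypeMatrix:
        """Sum the two chromosome copies of each individual into dosages."""
        dosages = (self.alleles[0::2] + self.alleles[1::2]).T.astype(np.int8)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            snv_ids=list(self.snv_ids),
            dosages=dosages,
            positions=self.positions,
        )


@dataclass
class BlockMap:
    """Partition of the SNV axis into contiguous, ordered haploblocks.

    ``blocks[b]`` is the ascending, contiguous array of SNV indices of
    block ``b``.  Blocks are disjoint and jointly cover ``range(n_snvs)``.
    """

    blocks: list[np.ndarray]
    n_snvs: int
    block_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=np.int64) for b in self.blocks]
        seen = np.concatenate(self.blocks) if self.blocks else np.array([], dtype=np.int64)
        for b in self.blocks:
            if len(b) == 0:
                raise ValidationError("empty block")
            if not (np.diff(b) == 1).all():
                raise ValidationError("block indices must be contiguous and ascending")
        if len(seen) != self.n_snvs or len(np.unique(seen)) != len(seen):
            raise ValidationError("blocks must disjointly cover all SNVs")
        if seen.size and (seen.min() != 0 or seen.max() != self.n_snvs - 1):
            raise ValidationError("blocks must cover exactly 0..n_snvs-1")
        if self.block_ids is None:
            self.block_ids = [f"B{i + 1}" for i in range(len(self.blocks))]
        elif len(self.block_ids) != len(self.blocks):
            raise ValidationError("block_ids length does not match block count")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of_snv(self) -> np.ndarray:
        """Array mapping SNV index -> block index."""
        out = np.empty(self.n_snvs, dtype=np.int64)
        for b, idx in enumerate(self.blocks):
            out[idx] = b
        return out


@dataclass
class BlockHaplotypes:
    """Observed haplotypes of one block with (possibly perturbed) counts."""

    haplotypes: list[str]
    counts: np.ndarray
    total: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.haplotypes) != len(self.counts):
            raise ValidationError("haplotype/count length mismatch")
        _check_unique(self.haplotypes, "haplotypes")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) > 1:
            raise ValidationError("haplotypes of one block must share a length")
        if any(set(h) - {"0", "1"} for h in self.haplotypes):
            raise ValidationError("haplotypes must be binary strings")
        if (self.counts < -1e-9).any():
            raise ValidationError("haplotype counts must be nonnegative")


@dataclass
class HaplotypeTable:
    """Per-block haplotype-count histograms (the haplotype mechanism's domain)."""

    blocks: list[BlockHaplotypes]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def pool_sizes(self) -> np.ndarray:
        return np.array([len(b.haplotypes) for b in self.blocks], dtype=np.int64)


@dataclass
class AlleleFrequencyTable:
    """Per-SNV minor-allele counts and frequencies.

    Counts are kept as reals because DP post-processing may release
    non-integer counts; frequencies are always ``count / total``.
    """

    snv_ids: list[str]
    minor_counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.minor_counts = np.asarray(self.minor_counts, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        n = len(self.snv_ids)
        if self.minor_counts.shape != (n,) or self.totals.shape != (n,):
            raise ValidationError("count arrays must match SNV id list")
        _check_unique(self.snv_ids, "SNV ids")
        if (self.totals <= 0).any():
            raise ValidationError("total allele counts must be positive")
        if (self.minor_counts < -1e-9).any() or (
            self.minor_counts > self.totals + 1e-9
        ).any():
            raise ValidationError("minor counts must lie in [0, total]")

    @property
    def frequencies(self) -> np.ndarray:
        return self.minor_counts / self.totals

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    def index_of(self, snv_ids) -> np.ndarray:
        """Positions of the given SNV ids; raises naming the first absentee."""
        lookup = {s: i for i, s in enumerate(self.snv_ids)}
        idx = []
        for s in snv_ids:
            if s not in lookup:
                raise ValidationError(f"SNV {s!r} missing from frequency table")
            idx.append(lookup[s])
        return np.asarray(idx, dtype=np.int64)


@dataclass
class PrivacyParams:
    """Privacy budget bookkeeping for a release.

    ``per_block_epsilon`` (when present) must sum to ``epsilon_total``:
    block releases compose sequentially, so their budgets add.
    """

    epsilon_total: float = 1.0
    per_block_epsilon: np.ndarray | None = None
    sensitivity: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon_total <= 0:
            raise ParameterError("epsilon_total must be positive")
        if self.sensitivity is not None and self.sensitivity <= 0:
            raise ParameterError("sensitivity must be positive")
        if self.per_block_epsilon is not None:
            self.per_block_epsilon = np.asarray(self.per_block_epsilon, dtype=float)
            if (self.per_block_epsilon <= 0).any():
                raise ParameterError("per-block budgets must be positive")
            if abs(self.per_block_epsilon.sum() - self.epsilon_total) > 1e-12 * max(
                1.0, self.epsilon_total
            ):
                raise ParameterError("per-block budgets must sum to epsilon_total")
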