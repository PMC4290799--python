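"""Readers and writers for the challenge text formats.

The genotype dialect is: a header line of whitespace-separated individual
IDs, then one line per SNV consisting of the SNV ID followed by one
genotype token per individual, rows in genomic order.  Two token alphabets
are accepted and may be mixed across SNVs:

* dosage tokens ``0``/``1``/``2`` (count of minor alleles), missing as
  ``NA`` or ``?``;
* two-letter allele pairs such as ``AC``, with the minor allele either
  supplied explicitly (e.g. taken from a public control cohort) or, by
  default, defined as the rarer allele within the file, ties broken so
  that the alphabetically later allele is minor.

Frequency tables, block maps and haplotype tables are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    AlleleFrequencyTable,
    BlockHaplotypes,
    BlockMap,
    FormatError,
    GenotypeMatrix,
    HaplotypeMatrix,
    HaplotypeTable,
    ValidationError,
)

_MISSING_TOKENS = {"NA", "?", "NN", "??"}


def read_genotype_matrix(path, minor_alleles: dict[str, str] | None = None) -> GenotypeMatrix:
    """Parse a challenge-dialect genotype file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        File to read.
    minor_alleles
        Optional mapping ``snv_id -> minor allele letter`` used to convert
        two-letter tokens to dosages.  When omitted, the minor allele of a
        letter-coded SNV is inferred from allele counts within the file.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    individual_ids = lines[0].split()
    if not individual_ids:
        raise FormatError(f"{path}: header line has no individual IDs")
    n_ind = len(individual_ids)

    snv_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != n_ind + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {n_ind + 1} fields "
                f"(SNV ID + {n_ind} genotypes), got {len(tokens)}"
            )
        snv_ids.append(tokens[0])
        rows.append(tokens[1:])

    dosages = np.full((len(snv_ids), n_ind), MISSING, dtype=np.int8)
    for i, (snv, tokens) in enumerate(zip(snv_ids, rows)):
        dosages[i] = _parse_row(tokens, snv, i + 2, path, minor_alleles)
    return GenotypeMatrix(individual_ids=individual_ids, snv_ids=snv_ids, dosages=dosages)


def _parse_row(tokens, snv_id, lineno, path, minor_alleles):
    row = np.full(len(tokens), MISSING, dtype=np.int8)
    letter_pairs: list[tuple[int, str]] = []
    for j, tok in enumerate(tokens):
        if tok in ("0", "1", "2"):
            row[j] = int(tok)
        elif tok in _MISSING_TOKENS:
            row[j] = MISSING
        elif len(tok) == 2 and tok.isalpha():
            letter_pairs.append((j, tok.upper()))
        else:
            raise FormatError(
                f"{path}: line {lineno}: unknown genotype token {tok!r}"
            )
    if letter_pairs:
        alleles = sorted({a for _, pair in letter_pairs for a in pair})
        if len(alleles) > 2:
            raise FormatError(
                f"{path}: line {lineno}: SNV {snv_id} has more than two alleles: {alleles}"
            )
        if minor_alleles is not None and snv_id in minor_alleles:
            minor = minor_alleles[snv_id]
        else:
            counts = {a: 0 for a in alleles}
            for _, pair in letter_pairs:
                for a in pair:
                    counts[a] += 1
            # rarer allele is minor; on a tie the alphabetically later one
            minor = min(counts, key=lambda a: (counts[a], [-ord(c) for c in a]))
        for j, pair in letter_pairs:
            row[j] = sum(1 for a in pair if a == minor)
    return row


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    """Write dosage tokens in the challenge dialect (missing as ``NA``)."""
    with open(path, "w") as fh:
        fh.write(" ".join(matrix.individual_ids) + "\n")
        for i, snv in enumerate(matrix.snv_ids):
            toks = ["NA" if d == MISSING else str(int(d)) for d in matrix.dosages[i]]
            fh.write(snv + " " + " ".join(toks) + "\n")


def read_haplotype_matrix(path) -> HaplotypeMatrix:
    """Read a phased haplotype file (tokens ``a|b`` with a, b in {0, 1})."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    individual_ids = lines[0].split()
    n_ind = len(individual_ids)
    snv_ids: list[str] = []
    cols: list[np.ndarray] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        tokens = line.split()
        if len(tokens) != n_ind + 1:
            raise FormatError(
                f"{path}: line {lineno}: expected {n_ind + 1} fields, got {len(tokens)}"
            )
        snv_ids.append(tokens[0])
        row = np.empty(2 * n_ind, dtype=np.int8)
        for j, tok in enumerate(tokens[1:]):
            parts = tok.split("|")
            if len(parts) != 2 or any(p not in ("0", "1") for p in parts):
                raise FormatError(
                    f"{path}: line {lineno}: unknown haplotype token {tok!r}"
                )
            row[2 * j] = int(parts[0])
            row[2 * j + 1] = int(parts[1])
        cols.append(row)
    alleles = np.array(cols, dtype=np.int8).T  # (2n copies, n_snvs)
    return HaplotypeMatrix(individual_ids=individual_ids, snv_ids=snv_ids, alleles=alleles)


def write_haplotype_matrix(haps: HaplotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(haps.individual_ids) + "\n")
        for i, snv in enumerate(haps.snv_ids):
            toks = [
                f"{haps.alleles[2 * j, i]}|{haps.alleles[2 * j + 1, i]}"
                for j in range(haps.n_individuals)
            ]
            fh.write(snv + " " + " ".join(toks) + "\n")


FREQ_COLUMNS = ["snv_id", "minor_count", "total", "frequency"]


def write_frequency_table(table: AlleleFrequencyTable, path, precision: int = 10) -> None:
    """Write a tab-separated frequency table (round-trips to `precision` places)."""
    df = pd.DataFrame(
        {
            "snv_id": table.snv_ids,
            "minor_count": [f"{c:.{precision}g}" for c in table.minor_counts],
            "total": [f"{t:.{precision}g}" for t in table.totals],
            "frequency": [f"{f:.{precision}f}" for f in table.frequencies],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> AlleleFrequencyTable:
    df = pd.read_csv(path, sep="\t", dtype={"snv_id": str})
    if list(df.columns) != FREQ_COLUMNS:
        raise FormatError(f"{path}: expected columns {FREQ_COLUMNS}, got {list(df.columns)}")
    freq = df["frequency"].to_numpy(dtype=float) if len(df) else np.array([])
    if len(df) and ((freq < 0) | (freq > 1)).any():
        bad = df["snv_id"][(freq < 0) | (freq > 1)].iloc[0]
        raise ValidationError(f"{path}: frequency outside [0, 1] at SNV {bad}")
    table = AlleleFrequencyTable(
        snv_ids=df["snv_id"].tolist(),
        minor_counts=df["minor_count"].to_numpy(dtype=float) if len(df) else np.array([]),
        totals=df["total"].to_numpy(dtype=float) if len(df) else np.array([]),
    )
    if len(df) and np.max(np.abs(table.frequencies - freq)) > 1e-6:
        raise ValidationError(f"{path}: frequency column inconsistent with count/total")
    return table


def write_block_map(blocks: BlockMap, snv_ids, path, positions=None) -> None:
    """TSV with columns block_id, snv_id, position (position 1-based)."""
    rows = []
    for b, idx in enumerate(blocks.blocks):
        for i in idx:
            pos = int(positions[i]) if positions is not None else i + 1
            rows.append((blocks.block_ids[b], snv_ids[i], pos))
    pd.DataFrame(rows, columns=["block_id", "snv_id", "position"]).to_csv(
        path, sep="\t", index=False
    )


def read_block_map(path, snv_ids) -> BlockMap:
    """Read a block TSV and resolve SNV ids against the given genomic order."""
    df = pd.read_csv(path, sep="\t", dtype={"block_id": str, "snv_id": str})
    lookup = {s: i for i, s in enumerate(snv_ids)}
    blocks: list[list[int]] = []
    ids: list[str] = []
    for block_id, grp in df.groupby("block_id", sort=False):
        idx = []
        for s in grp["snv_id"]:
            if s not in lookup:
                raise ValidationError(f"{path}: block {block_id} references unknown SNV {s!r}")
            idx.append(lookup[s])
        blocks.append(idx)
        ids.append(str(block_id))
    order = np.argsort([b[0] for b in blocks])
    return BlockMap(
        blocks=[np.asarray(blocks[i]) for i in order],
        n_snvs=len(snv_ids),
        block_ids=[ids[i] for i in order],
    )


def write_haplotype_table(table: HaplotypeTable, blocks: BlockMap, path, precision: int = 10) -> None:
    rows = []
    for b, entry in enumerate(table.blocks):
        for hap, count in zip(entry.haplotypes, entry.counts):
            rows.append((blocks.block_ids[b], hap, f"{count:.{precision}g}"))
    pd.DataFrame(rows, columns=["block_id", "haplotype", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_haplotype_table(path) -> HaplotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"block_id": str, "haplotype": str})
    entries = []
    for _, grp in df.groupby("block_id", sort=False):
        counts = grp["count"].to_numpy(dtype=float)
        entries.append(
            BlockHaplotypes(
                haplotypes=grp["haplotype"].tolist(),
                counts=counts,
                total=float(counts.sum()),
            )
        )
    return HaplotypeTable(blocks=entries)
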