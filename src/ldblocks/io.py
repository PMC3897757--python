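"""Readers and writers for linkage-format genotype data and gene tables.

Supported inputs
----------------
PED
    Whitespace- or tab-delimited; 6 leading pedigree columns (family,
    individual, father, mother, sex, phenotype) followed by two allele
    columns per marker.  Allele symbols ``0``, ``N`` and ``-`` denote a
    missing allele; a diploid call with either allele missing is MISSING.
    Pedigree columns are parsed and discarded: all individuals are treated
    as unrelated.
MAP / INFO
    Marker files in either the 4-column MAP dialect (chrom, id,
    genetic-distance, pos) or the 2-column INFO dialect (id, pos); the
    dialect is auto-detected from the column count.  The 2-column dialect
    carries no chromosome, so ``chrom_override`` is required.
Gene table
    Tab-separated with a header row naming the GeneRecord fields.
Precomputed LD
    Whitespace-delimited ``id1 id2 r2`` triples; unlisted pairs are
    undefined.

Lines starting with ``#`` and blank lines are ignored everywhere.
Genotypes are recoded to minor-allele dosage after a first pass establishes
allele frequencies; the minor allele is the less frequent allele over
non-missing calls, with an exact 0.5/0.5 tie broken toward the
lexicographically greater symbol so recoding is deterministic.
"""
from __future__ import annotations

import os
from collections import Counter
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import ContractError, GeneTableError, LinkageFormatError
from .model import MISSING, GeneRecord, GenotypePanel, Marker

#: Allele symbols that denote a missing allele in PED input.
MISSING_ALLELES = frozenset({"0", "N", "-"})


def _data_lines(path: str | os.PathLike) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def _read_marker_file(
    marker_path: str | os.PathLike, chrom_override: str | None
) -> list[tuple[str, str, int]]:
    """Parse a MAP or INFO file into (chrom, id, pos) triples in file order."""
    rows = list(_data_lines(marker_path))
    if not rows:
        raise LinkageFormatError(f"{marker_path}: no marker lines found")
    ncol = len(rows[0][1])
    if ncol not in (2, 4):
        raise LinkageFormatError(
            f"{marker_path}:{rows[0][0]}: expected 2 (INFO) or 4 (MAP) columns, got {ncol}"
        )
    if ncol == 2 and chrom_override is None:
        raise ContractError(
            f"{marker_path}: 2-column INFO dialect carries no chromosome; "
            "chrom_override is required"
        )
    out: list[tuple[str, str, int]] = []
    for lineno, fields in rows:
        if len(fields) != ncol:
            raise LinkageFormatError(
                f"{marker_path}:{lineno}: expected {ncol} columns, got {len(fields)}"
            )
        if ncol == 4:
            chrom, mid, _gdist, pos_s = fields
            if chrom_override is not None:
                chrom = chrom_override
        else:
            mid, pos_s = fields
            chrom = chrom_override  # type: ignore[assignment]
        try:
            pos = int(pos_s)
        except ValueError:
            raise LinkageFormatError(
                f"{marker_path}:{lineno}: position {pos_s!r} is not an integer"
            ) from None
        out.append((chrom, mid, pos))
    chroms = {c for c, _, _ in out}
    if len(chroms) > 1:
        raise LinkageFormatError(
            f"{marker_path}: markers span chromosomes {sorted(chroms)}; "
            "load each chromosome independently"
        )
    ids = [m for _, m, _ in out]
    dupes = [m for m, c in Counter(ids).items() if c > 1]
    if dupes:
        raise LinkageFormatError(f"{marker_path}: duplicate marker id(s) {dupes}")
    return out


def read_linkage(
    ped_path: str | os.PathLike,
    marker_path: str | os.PathLike,
    chrom_override: str | None = None,
) -> GenotypePanel:
    """Read a PED file plus marker file into a :class:`GenotypePanel`.

    Markers are re-sorted by position with the genotype matrix permuted in
    lockstep.  Monomorphic markers are retained (they are excluded later by
    the LD logic, where r-squared is undefined).

    Raises
    ------
    LinkageFormatError
        On column-count mismatches, >2 alleles at a marker, duplicate
        marker ids or duplicate positions.
    ContractError
        When the 2-column marker dialect is used without ``chrom_override``.
    """
    marker_rows = _read_marker_file(marker_path, chrom_override)
    m = len(marker_rows)
    expected = 6 + 2 * m

    samples: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, fields in _data_lines(ped_path):
        if len(fields) != expected:
            raise LinkageFormatError(
                f"{ped_path}:{lineno}: expected {expected} columns "
                f"(6 pedigree + 2 per marker for {m} markers), got {len(fields)}"
            )
        samples.append(f"{fields[0]}:{fields[1]}")
        allele_rows.append(fields[6:])
    if not samples:
        raise LinkageFormatError(f"{ped_path}: no genotype lines found")

    alleles = np.array(allele_rows, dtype=object)  # (n, 2m)
    n = len(samples)
    genotypes = np.empty((n, m), dtype=np.int8)
    marker_objs: list[Marker] = []
    for j, (chrom, mid, pos) in enumerate(marker_rows):
        a1 = alleles[:, 2 * j]
        a2 = alleles[:, 2 * j + 1]
        miss = np.isin(a1, tuple(MISSING_ALLELES)) | np.isin(a2, tuple(MISSING_ALLELES))
        observed = np.concatenate([a1[~miss], a2[~miss]])
        counts = Counter(observed.tolist())
        if len(counts) > 2:
            raise LinkageFormatError(
                f"{marker_path}: marker {mid!r} has {len(counts)} distinct alleles "
                f"{sorted(counts)}; biallelic input required"
            )
        if len(counts) == 0:
            major, minor = None, None
        elif len(counts) == 1:
            (major,) = counts
            minor = None
        else:
            (s1, c1), (s2, c2) = sorted(counts.items())
            if c1 == c2:
                major, minor = s1, s2  # tie: minor = lexicographically greater
            elif c1 < c2:
                major, minor = s2, s1
            else:
                major, minor = s1, s2
        col = np.zeros(n, dtype=np.int8)
        if minor is not None:
            col += (a1 == minor).astype(np.int8) + (a2 == minor).astype(np.int8)
        col[miss] = MISSING
        genotypes[:, j] = col
        pair = None if major is None else (major, minor)
        marker_objs.append(Marker(id=mid, chrom=chrom, pos=pos, alleles=pair))

    order = sorted(range(m), key=lambda j: marker_objs[j].pos)
    sorted_pos = [marker_objs[j].pos for j in order]
    for p, q in zip(sorted_pos, sorted_pos[1:]):
        if p == q:
            raise LinkageFormatError(
                f"{marker_path}: duplicate marker position {p}; positions must be unique"
            )
    return GenotypePanel(
        markers=[marker_objs[j] for j in order],
        samples=samples,
        genotypes=genotypes[:, order],
    )


def write_linkage(
    panel: GenotypePanel,
    ped_path: str | os.PathLike,
    marker_path: str | os.PathLike,
    dialect: str = "map",
) -> None:
    """Write a panel back to PED plus MAP (4-column) or INFO (2-column).

    Round-trip helper for fixtures: re-reading reproduces the identical
    dosage matrix and marker list.  Markers without recorded alleles are
    written with the symbols ``A`` (major) / ``C`` (minor).
    """
    if dialect not in ("map", "info"):
        raise ContractError(f"dialect must be 'map' or 'info', got {dialect!r}")
    with open(marker_path, "w", encoding="utf-8", newline="\n") as fh:
        for mk in panel.markers:
            if dialect == "map":
                fh.write(f"{mk.chrom}\t{mk.id}\t0\t{mk.pos}\n")
            else:
                fh.write(f"{mk.id}\t{mk.pos}\n")
    with open(ped_path, "w", encoding="utf-8", newline="\n") as fh:
        for i, sample in enumerate(panel.samples):
            fam, _, ind = sample.partition(":")
            if not ind:
                fam, ind = f"F{i + 1}", sample
            cols = [fam, ind, "0", "0", "0", "0"]
            for j, mk in enumerate(panel.markers):
                major, minor = mk.alleles if mk.alleles else ("A", "C")
                if minor is None:
                    minor = major
                g = int(panel.genotypes[i, j])
                if g == MISSING:
                    cols += ["0", "0"]
                elif g == 0:
                    cols += [major, major]
                elif g == 1:
                    cols += [major, minor]
                else:
                    cols += [minor, minor]
            fh.write("\t".join(cols) + "\n")


_REQUIRED_GENE_COLUMNS = [
    "entrez_id", "refseq_id", "symbol", "chrom", "tx_start", "tx_end", "strand",
]


def _parse_int_list(text: str) -> tuple[int, ...]:
    return tuple(int(tok) for tok in text.strip().rstrip(",").split(",") if tok.strip())


def read_gene_table(tsv_path: str | os.PathLike) -> list[GeneRecord]:
    """Read a tab-separated gene-annotation table with a header row.

    Required columns: entrez_id, refseq_id, symbol, chrom, tx_start, tx_end,
    strand.  Optional: exon_starts, exon_ends (comma-separated integers).
    Rows with malformed coordinates are rejected with their line number.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in _REQUIRED_GENE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneTableError(f"{tsv_path}: missing required column(s) {missing}")
    has_exons = "exon_starts" in df.columns and "exon_ends" in df.columns
    records: list[GeneRecord] = []
    for row_i, row in df.iterrows():
        lineno = int(row_i) + 2  # header is line 1
        try:
            tx_start = int(row["tx_start"])
            tx_end = int(row["tx_end"])
        except ValueError:
            raise GeneTableError(
                f"{tsv_path}:{lineno}: non-integer transcript coordinates "
                f"({row['tx_start']!r}, {row['tx_end']!r})"
            ) from None
        exon_starts = exon_ends = None
        if has_exons and row["exon_starts"].strip():
            try:
                exon_starts = _parse_int_list(row["exon_starts"])
                exon_ends = _parse_int_list(row["exon_ends"])
            except ValueError:
                raise GeneTableError(
                    f"{tsv_path}:{lineno}: malformed exon coordinate lists"
                ) from None
            if len(exon_starts) != len(exon_ends):
                raise GeneTableError(
                    f"{tsv_path}:{lineno}: exon_starts and exon_ends differ in length"
                )
        try:
            records.append(
                GeneRecord(
                    entrez_id=row["entrez_id"].strip(),
                    refseq_id=row["refseq_id"].strip(),
                    symbol=row["symbol"].strip(),
                    chrom=row["chrom"].strip(),
                    tx_start=tx_start,
                    tx_end=tx_end,
                    strand=row["strand"].strip(),
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
        except ContractError as exc:
            raise GeneTableError(f"{tsv_path}:{lineno}: {exc}") from None
    return records


def read_r2_table(path: str | os.PathLike, markers: list[Marker]):
    """Load externally precomputed pairwise r-squared values into an LDMatrix.

    The file holds whitespace-delimited ``marker_id_1 marker_id_2 r2``
    triples; pairs not listed are treated as undefined.  This reproduces the
    precomputed-measures-in, clusters-out workflow.
    """
    from .ld import LDMatrix

    index = {mk.id: i for i, mk in enumerate(markers)}
    k = len(markers)
    r2 = np.zeros((k, k))
    defined = np.zeros((k, k), dtype=bool)
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise LinkageFormatError(
                f"{path}:{lineno}: expected 3 columns (id1 id2 r2), got {len(fields)}"
            )
        id1, id2, val_s = fields
        for mid in (id1, id2):
            if mid not in index:
                raise LinkageFormatError(f"{path}:{lineno}: unknown marker id {mid!r}")
        try:
            val = float(val_s)
        except ValueError:
            raise LinkageFormatError(f"{path}:{lineno}: r2 {val_s!r} is not a number") from None
        if not 0.0 <= val <= 1.0:
            raise LinkageFormatError(f"{path}:{lineno}: r2 {val} outside [0, 1]")
        i, j = index[id1], index[id2]
        r2[i, j] = r2[j, i] = val
        defined[i, j] = defined[j, i] = True
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(defined, True)
    return LDMatrix(markers=list(markers), r2=r2, defined=defined)
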