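"""Core data model: markers, unphased genotype panels and gene annotation records.

Genotypes are stored as minor-allele dosage codes: 0, 1 or 2 copies of the
marker's minor allele, or :data:`MISSING` (-1) when either allele of the
diploid call is unknown.  A panel holds exactly one chromosome, with markers
in strictly increasing base-pair order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractError

#: Genotype code for a missing diploid call.
MISSING: int = -1

_VALID_CODES = (0, 1, 2, MISSING)


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP.

    Parameters
    ----------
    id
        Marker identifier (e.g. an rs-id); non-empty, unique within a panel.
    chrom
        Chromosome name.
    pos
        1-based base-pair coordinate.
    alleles
        Optional ``(major, minor)`` allele symbols; ``minor`` is ``None`` for
        a monomorphic marker.  Filled in by the reader after frequency
        computation; synthetic panels set it directly.
    """

    id: str
    chrom: str
    pos: int
    alleles: tuple[str, str | None] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ContractError("marker id must be non-empty")
        if int(self.pos) < 1:
            raise ContractError(f"marker {self.id!r}: pos must be >= 1, got {self.pos}")
        if self.alleles is not None:
            major, minor = self.alleles
            if minor is not None and major == minor:
                raise ContractError(f"marker {self.id!r}: alleles must be distinct")


@dataclass
class GenotypePanel:
    """Samples x markers matrix of unphased minor-allele dosages.

    Invariants enforced on construction: one chromosome per panel, marker
    positions strictly increasing, unique marker ids, every matrix entry one
    of {0, 1, 2, MISSING}.
    """

    markers: list[Marker]
    samples: list[str]
    genotypes: np.ndarray  # shape (n_samples, n_markers), int8

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ContractError("genotypes must be a 2-D samples x markers matrix")
        n_s, n_m = self.genotypes.shape
        if n_s != len(self.samples):
            raise ContractError(
                f"genotype rows ({n_s}) != number of samples ({len(self.samples)})"
            )
        if n_m != len(self.markers):
            raise ContractError(
                f"genotype columns ({n_m}) != number of markers ({len(self.markers)})"
            )
        chroms = {m.chrom for m in self.markers}
        if len(chroms) > 1:
            raise ContractError(
                f"a panel holds one chromosome; got {sorted(chroms)}"
            )
        pos = np.array([m.pos for m in self.markers])
        if pos.size and not np.all(np.diff(pos) > 0):
            raise ContractError("marker positions must be strictly increasing")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ContractError("marker ids must be unique within a panel")
        if not np.isin(self.genotypes, _VALID_CODES).all():
            raise ContractError("genotype codes must be 0, 1, 2 or MISSING (-1)")
        self._index = {m.id: i for i, m in enumerate(self.markers)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chrom(self) -> str | None:
        return self.markers[0].chrom if self.markers else None

    @property
    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    def marker_index(self, marker_id: str) -> int:
        from .errors import MarkerLookupError

        try:
            return self._index[marker_id]
        except KeyError:
            raise MarkerLookupError(f"marker {marker_id!r} not in panel") from None

    def dosages(self, marker: int | str) -> np.ndarray:
        """Genotype column for a marker (by index or id)."""
        idx = marker if isinstance(marker, int) else self.marker_index(marker)
        return self.genotypes[:, idx]

    def subset(self, indices: Sequence[int]) -> "GenotypePanel":
        """New panel restricted to the given marker indices (re-sorted by position)."""
        order = sorted(indices, key=lambda i: self.markers[i].pos)
        return GenotypePanel(
            markers=[self.markers[i] for i in order],
            samples=list(self.samples),
            genotypes=self.genotypes[:, order].copy(),
        )


@dataclass(frozen=True)
class GeneRecord:
    """One row of the gene-annotation table.

    At least one of ``entrez_id``, ``refseq_id``, ``symbol`` must be
    non-empty; ``tx_start`` <= ``tx_end`` (1-based, inclusive).  Exon lists
    are optional and used for display only.
    """

    entrez_id: str
    refseq_id: str
    symbol: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    exon_starts: tuple[int, ...] | None = None
    exon_ends: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ContractError(
                f"gene {self.display_id!r}: tx_start {self.tx_start} > tx_end {self.tx_end}"
            )
        if not (self.entrez_id or self.refseq_id or self.symbol):
            raise ContractError("a gene record needs at least one identifier")
        if self.strand not in ("+", "-"):
            raise ContractError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def display_id(self) -> str:
        return self.symbol or self.refseq_id or self.entrez_id
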