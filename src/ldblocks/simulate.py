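"""Synthetic genotype panels with planted perfect-LD block structure.

The generator plants structure rather than modelling evolution: each block
has one latent binary haplotype indicator per chromosome, drawn at the
block's minor allele frequency, and every SNP in the block copies that
indicator — within-block r-squared is exactly 1 whenever no data are
missing.  Between-block dependence is induced by a Gaussian copula: one
standard normal per block per chromosome, thresholded at the allele
frequency's quantile, with the Gaussian correlation solved per pair
(tetrachoric inversion) so that the correlation of the binary indicators
hits the requested target in expectation.  Chromosomes are then paired
randomly into unphased diploid genotypes, and missingness is applied
i.i.d.  Infeasible correlation specifications (non-positive-semidefinite,
or above the Frechet bound for unequal frequencies) fail before any
sampling.

All randomness flows from a single integer seed, and the planted partition
is returned alongside the panel so tests never have to re-derive it.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .errors import ContractError, SimulationSpecError
from .model import MISSING, GenotypePanel, Marker

__all__ = ["BlockSpec", "simulate_panel", "balanced_independent_pair"]

#: Default marker spacing: 1 kb starting at 10,001.
DEFAULT_START = 10_001
DEFAULT_SPACING = 1_000


@dataclass(frozen=True)
class BlockSpec:
    """Specification of a planted-block panel.

    Parameters
    ----------
    block_sizes
        SNPs per block (size-1 blocks are planted singletons).
    block_mafs
        Minor allele frequency per block, each in (0, 0.5].
    n_samples
        Diploid sample count.
    seed
        Mandatory integer seed for all randomness.
    missing_rate
        I.i.d. per-call missingness probability, in [0, 1).
    between_corr
        Optional symmetric matrix of target haplotype-indicator
        correlations between blocks, entries in [0, 1]; defaults to
        independence.
    positions
        Optional explicit 1-based positions, one per SNP; default 1 kb
        spacing starting at 10,001.
    chrom
        Chromosome name for all markers.
    """

    block_sizes: tuple[int, ...]
    block_mafs: tuple[float, ...]
    n_samples: int
    seed: int
    missing_rate: float = 0.0
    between_corr: tuple[tuple[float, ...], ...] | None = None
    positions: tuple[int, ...] | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(s) for s in self.block_sizes))
        object.__setattr__(self, "block_mafs", tuple(float(f) for f in self.block_mafs))
        if len(self.block_sizes) != len(self.block_mafs):
            raise SimulationSpecError("one MAF per block required")
        if not self.block_sizes:
            raise SimulationSpecError("at least one block required")
        if any(s < 1 for s in self.block_sizes):
            raise SimulationSpecError("block sizes must be >= 1")
        if any(not 0.0 < f <= 0.5 for f in self.block_mafs):
            raise SimulationSpecError("block MAFs must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationSpecError("missing_rate must lie in [0, 1)")
        if self.n_samples < 1:
            raise SimulationSpecError("n_samples must be >= 1")
        if self.positions is not None:
            pos = tuple(int(p) for p in self.positions)
            if len(pos) != sum(self.block_sizes):
                raise SimulationSpecError("one position per SNP required")
            if sorted(set(pos)) != list(pos):
                raise SimulationSpecError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)
        if self.between_corr is not None:
            mat = np.asarray(self.between_corr, dtype=float)
            k = len(self.block_sizes)
            if mat.shape != (k, k):
                raise SimulationSpecError(
                    f"between_corr must be {k}x{k}, got {mat.shape}"
                )
            if not np.allclose(mat, mat.T):
                raise SimulationSpecError("between_corr must be symmetric")
            if ((mat < 0) | (mat > 1)).any():
                raise SimulationSpecError("between_corr entries must lie in [0, 1]")
            object.__setattr__(
                self, "between_corr", tuple(tuple(row) for row in mat.tolist())
            )


def _binary_corr(rho: float, z1: float, z2: float, p1: float, p2: float) -> float:
    """Correlation of 1{Z1<z1}, 1{Z2<z2} under bivariate normal with corr rho."""
    p11 = float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([z1, z2])
    )
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _gaussian_sigma(spec: BlockSpec) -> np.ndarray:
    """Latent Gaussian correlation matrix hitting the binary targets."""
    k = len(spec.block_sizes)
    sigma = np.eye(k)
    if spec.between_corr is None:
        return sigma
    target = np.asarray(spec.between_corr, dtype=float)
    z = norm.ppf(spec.block_mafs)
    for i in range(k):
        for j in range(i + 1, k):
            t = target[i, j]
            if t == 0.0:
                continue
            hi = 1.0 - 1e-9
            f = lambda rho: _binary_corr(rho, z[i], z[j], spec.block_mafs[i], spec.block_mafs[j]) - t
            if f(hi) < 0.0:
                raise SimulationSpecError(
                    f"target correlation {t} between blocks {i} and {j} exceeds "
                    "the maximum attainable for their allele frequencies"
                )
            rho = t if abs(f(t)) < 1e-12 else brentq(f, 0.0, hi, xtol=1e-12)
            sigma[i, j] = sigma[j, i] = rho
    eigmin = float(np.linalg.eigvalsh(sigma).min())
    if eigmin < -1e-9:
        raise SimulationSpecError(
            f"correlation specification is not positive semidefinite "
            f"(min eigenvalue {eigmin:.3g})"
        )
    return sigma


def simulate_panel(spec: BlockSpec) -> tuple[GenotypePanel, list[tuple[str, ...]]]:
    """Generate a panel with planted blocks; returns (panel, truth partition).

    The truth partition lists the marker ids of every planted block in
    order (size-1 entries are planted singletons).
    """
    sigma = _gaussian_sigma(spec)  # validates feasibility before sampling
    k = len(spec.block_sizes)
    n = spec.n_samples
    rng = np.random.default_rng(spec.seed)

    z = norm.ppf(spec.block_mafs)
    latent = rng.multivariate_normal(np.zeros(k), sigma, size=2 * n)
    hap = (latent < z[np.newaxis, :]).astype(np.int8)  # (2n, k) indicator of minor
    perm = rng.permutation(2 * n)
    block_geno = hap[perm[:n]] + hap[perm[n:]]  # (n, k)

    # expand blocks to SNP columns (perfect LD by construction)
    cols = np.repeat(np.arange(k), spec.block_sizes)
    geno = block_geno[:, cols].astype(np.int8)

    if spec.missing_rate > 0.0:
        mask = rng.random(geno.shape) < spec.missing_rate
        geno[mask] = MISSING
    _recode_to_observed_minor(geno)

    m = geno.shape[1]
    if spec.positions is not None:
        positions = list(spec.positions)
    else:
        positions = [DEFAULT_START + DEFAULT_SPACING * i for i in range(m)]
    markers = [
        Marker(id=f"rs{i + 1}", chrom=spec.chrom, pos=positions[i], alleles=("A", "C"))
        for i in range(m)
    ]
    panel = GenotypePanel(
        markers=markers,
        samples=[f"S{i + 1}" for i in range(n)],
        genotypes=geno,
    )
    truth: list[tuple[str, ...]] = []
    offset = 0
    for s in spec.block_sizes:
        truth.append(tuple(markers[offset + t].id for t in range(s)))
        offset += s
    return panel, truth


def _recode_to_observed_minor(geno: np.ndarray) -> None:
    """Flip dosage columns whose observed allele frequency exceeds 0.5.

    Keeps the dosage coding consistent with the reader's minor-allele rule
    (minor = less frequent over non-missing calls; exact tie keeps the
    lexicographically greater symbol, here 'C').
    """
    for j in range(geno.shape[1]):
        col = geno[:, j]
        obs = col != MISSING
        if obs.any() and col[obs].mean() / 2.0 > 0.5:
            col[obs] = 2 - col[obs]


def reference_ld_ladder(
    r2_targets: Sequence[float],
    maf: float = 0.4,
    n_samples: int = 1_000,
    seed: int = 0,
    chrom: str = "1",
) -> GenotypePanel:
    """Panel with one reference marker and one variant per target r-squared.

    Uses a copy-or-redraw mixture: each variant's haplotype copies the
    reference haplotype with probability sqrt(r2_target) and is otherwise an
    independent draw at the same allele frequency, so the haplotype
    correlation equals sqrt(r2_target) — and the sample r-squared approaches
    the target — in expectation.  Unlike an explicit correlation-matrix
    specification, the implied one-factor dependence is consistent for any
    number of variants.  The reference is marker ``rs1``.
    """
    targets = [float(t) for t in r2_targets]
    if any(not 0.0 <= t <= 1.0 for t in targets):
        raise SimulationSpecError("r2 targets must lie in [0, 1]")
    if not 0.0 < maf <= 0.5:
        raise SimulationSpecError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    ref = (rng.random(n_hap) < maf).astype(np.int8)
    cols = [ref]
    for t in targets:
        copy = rng.random(n_hap) < np.sqrt(t)
        fresh = (rng.random(n_hap) < maf).astype(np.int8)
        cols.append(np.where(copy, ref, fresh).astype(np.int8))
    haps = np.column_stack(cols)
    perm = rng.permutation(n_hap)
    geno = (haps[perm[:n_samples]] + haps[perm[n_samples:]]).astype(np.int8)
    _recode_to_observed_minor(geno)
    m = geno.shape[1]
    markers = [
        Marker(id=f"rs{i + 1}", chrom=chrom,
               pos=DEFAULT_START + DEFAULT_SPACING * i, alleles=("A", "C"))
        for i in range(m)
    ]
    return GenotypePanel(
        markers=markers,
        samples=[f"S{i + 1}" for i in range(n_samples)],
        genotypes=geno,
    )


def balanced_independent_pair(
    n_haplotypes: int, copies_per_marker: int = 1
) -> GenotypePanel:
    """Two loci with exactly zero sample LD, phase-unambiguous by construction.

    The four two-locus haplotypes occur in exactly equal counts
    (``n_haplotypes`` must be divisible by 4) and are paired into diploids
    without double heterozygotes, so the haplotype table — and hence
    r-squared = 0 — is exact, and EM converges in a single iteration.

    With ``copies_per_marker`` > 1 each locus is replicated into that many
    identical adjacent markers, giving two perfect-LD blocks with exactly
    zero LD between them.
    """
    if n_haplotypes % 4 != 0 or n_haplotypes < 4:
        raise ContractError("n_haplotypes must be a positive multiple of 4")
    if copies_per_marker < 1:
        raise ContractError("copies_per_marker must be >= 1")
    q = n_haplotypes // 4
    # q chromosomes of each haplotype (0,0), (0,1), (1,0), (1,1).  Pair
    # identical haplotypes into homozygous diploids; when q is odd, the four
    # leftover chromosomes pair as (0,0)+(0,1) and (1,0)+(1,1).  Either way
    # no double heterozygote arises, haplotype counts are exact and equal,
    # and D = 0 exactly.
    pairs: list[tuple[int, int]] = []
    doubled = q // 2
    for hap in ((0, 0), (0, 1), (1, 0), (1, 1)):
        pairs += [(2 * hap[0], 2 * hap[1])] * doubled
    if q % 2 == 1:
        pairs += [(0, 1), (2, 1)]
    geno2 = np.array(pairs, dtype=np.int8)  # (2q, 2)
    cols = [0] * copies_per_marker + [1] * copies_per_marker
    geno = geno2[:, cols]

    markers = []
    for locus in range(2):
        base = DEFAULT_START + locus * DEFAULT_SPACING
        for c in range(copies_per_marker):
            suffix = "" if copies_per_marker == 1 else f"_{c + 1}"
            markers.append(
                Marker(
                    id=f"rs{locus + 1}{suffix}",
                    chrom="1",
                    pos=base + c,
                    alleles=("A", "C"),
                )
            )
    return GenotypePanel(
        markers=markers,
        samples=[f"S{i + 1}" for i in range(len(pairs))],
        genotypes=geno,
    )
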