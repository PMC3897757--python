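"""Minor allele frequencies and pairwise r-squared via two-locus EM.

For unphased diploid genotypes at two biallelic loci, only the
double-heterozygote class is phase-ambiguous.  The EM algorithm estimates
the four haplotype frequencies (p_AB, p_Ab, p_aB, p_ab; A/a = major/minor
at locus 1, B/b at locus 2) by splitting the double-heterozygote count
between the AB/ab and Ab/aB phases proportionally to the current
haplotype-product weights.  The squared correlation is then

    r^2 = D^2 / (p_A (1 - p_A) p_B (1 - p_B)),   D = p_AB p_ab - p_Ab p_aB

(the determinant form of D = p_AB - p_A p_B, exact when the four
frequencies sum to one).  Missing data are handled by pairwise-complete
deletion: each pair uses the samples non-missing at both loci.

Two exactness refinements matter for perfect-LD detection.  When the two
dosage vectors are identical, or mirror images (g2 = 2 - g1), the maximum
likelihood solution places all mass on one diagonal of the haplotype table
and is computed in closed form (r^2 exactly 1, no iteration).  And whenever
one diagonal of the estimated haplotype table is exactly empty, r^2 is
exactly 1 by algebra and is returned as such, immune to rounding.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError, UndefinedLDError
from .model import MISSING, GenotypePanel, Marker

__all__ = [
    "HaplotypeFreqs",
    "LDMatrix",
    "compute_maf",
    "em_haplotype_freqs",
    "r2_pair",
    "r2_matrix",
]


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Two-locus haplotype frequency estimate.

    Attributes
    ----------
    p_AB, p_Ab, p_aB, p_ab
        Frequencies of the four haplotypes; A/a = major/minor allele at the
        first locus, B/b at the second.  Sum to 1 within 1e-12.
    n_eff
        Samples with both genotypes non-missing.
    loglik
        Final observed-data log-likelihood.
    iterations
        EM iterations performed (0 when the closed form applied).
    converged
        False only when max_iter was reached before the tolerance.
    loglik_path
        Observed-data log-likelihood after each EM step, starting from the
        linkage-equilibrium initialization; non-decreasing.
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float
    n_eff: int
    loglik: float
    iterations: int
    converged: bool = True
    loglik_path: tuple[float, ...] = ()

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    @property
    def D(self) -> float:
        """Coefficient of linkage disequilibrium (determinant form)."""
        return self.p_AB * self.p_ab - self.p_Ab * self.p_aB


@dataclass
class LDMatrix:
    """Symmetric pairwise r-squared over a marker subset.

    ``defined`` is False where r-squared could not be computed (monomorphic
    locus in the pairwise-complete subsample, or no overlapping samples);
    such entries are masked, never silently zero.
    """

    markers: list[Marker]
    r2: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        k = len(self.markers)
        if self.r2.shape != (k, k) or self.defined.shape != (k, k):
            raise ContractError("LDMatrix arrays must be k x k for k markers")
        self._index = {mk.id: i for i, mk in enumerate(self.markers)}

    @property
    def k(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [mk.id for mk in self.markers]

    def index(self, marker_id: str) -> int:
        from .errors import MarkerLookupError

        try:
            return self._index[marker_id]
        except KeyError:
            raise MarkerLookupError(f"marker {marker_id!r} not in LD matrix") from None


def compute_maf(panel: GenotypePanel, marker: int | str) -> float:
    """Minor allele frequency: minor-allele count / (2 x non-missing samples).

    Returns 0 for monomorphic markers; raises :class:`UndefinedLDError`
    when every genotype at the marker is missing.
    """
    g = panel.dosages(marker)
    obs = g[g != MISSING]
    if obs.size == 0:
        raise UndefinedLDError(f"marker {marker!r}: all genotypes missing")
    return float(obs.sum(dtype=np.int64)) / (2.0 * obs.size)


def _pair_complete(panel: GenotypePanel, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    g1 = panel.genotypes[:, i]
    g2 = panel.genotypes[:, j]
    ok = (g1 != MISSING) & (g2 != MISSING)
    return g1[ok].astype(np.int64), g2[ok].astype(np.int64)


def _loglik(counts: np.ndarray, pAB: float, pAb: float, paB: float, pab: float) -> float:
    """Observed-data log-likelihood of a 3x3 genotype count table."""
    probs = (
        pAB * pAB, 2 * pAB * pAb, pAb * pAb,
        2 * pAB * paB, 2 * (pAB * pab + pAb * paB), 2 * pAb * pab,
        paB * paB, 2 * paB * pab, pab * pab,
    )
    ll = 0.0
    for n_ij, p_ij in zip(counts.ravel(), probs):
        if n_ij:
            if p_ij <= 0.0:
                return -math.inf
            ll += n_ij * math.log(p_ij)
    return ll


def em_haplotype_freqs(
    panel: GenotypePanel,
    i: int,
    j: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> HaplotypeFreqs:
    """Estimate two-locus haplotype frequencies by EM.

    Initialized at linkage equilibrium (products of the single-locus allele
    frequencies of the pairwise-complete subsample); stops when the largest
    absolute frequency change drops below ``tol``.  Non-convergence at
    ``max_iter`` is reported through the ``converged`` flag, not an
    exception.

    Raises
    ------
    UndefinedLDError
        No sample is non-missing at both loci, or either locus is
        monomorphic in the pairwise-complete subsample.
    """
    if tol <= 0:
        raise ContractError(f"tol must be > 0, got {tol}")
    g1, g2 = _pair_complete(panel, i, j)
    n = g1.size
    if n == 0:
        raise UndefinedLDError(
            f"markers {panel.markers[i].id!r}, {panel.markers[j].id!r}: "
            "no sample non-missing at both loci"
        )
    s1, s2 = int(g1.sum()), int(g2.sum())
    for s, idx in ((s1, i), (s2, j)):
        if s in (0, 2 * n):
            raise UndefinedLDError(
                f"marker {panel.markers[idx].id!r} monomorphic in the "
                "pairwise-complete subsample"
            )
    counts = np.bincount(g1 * 3 + g2, minlength=9).reshape(3, 3)

    # Deterministic association: identical or mirrored dosage vectors with at
    # least one non-double-heterozygote sample force the MLE onto one diagonal
    # of the haplotype table; no iteration needed.  (All-double-heterozygote
    # data are left to EM, whose symmetric equilibrium start is a fixed point.)
    shortcut_ok = int(counts[1, 1]) < n
    if shortcut_ok and np.array_equal(g1, g2):
        f = s1 / (2.0 * n)
        pAB, pAb, paB, pab = 1.0 - f, 0.0, 0.0, f
        ll = _loglik(counts, pAB, pAb, paB, pab)
        return HaplotypeFreqs(pAB, pAb, paB, pab, n, ll, 0, True, (ll,))
    if shortcut_ok and np.array_equal(g1, 2 - g2):
        f = s1 / (2.0 * n)
        pAB, pAb, paB, pab = 0.0, 1.0 - f, f, 0.0
        ll = _loglik(counts, pAB, pAb, paB, pab)
        return HaplotypeFreqs(pAB, pAb, paB, pab, n, ll, 0, True, (ll,))

    (n00, n01, n02), (n10, n11, n12), (n20, n21, n22) = counts.tolist()
    two_n = 2.0 * n
    pA = 1.0 - s1 / two_n
    pB = 1.0 - s2 / two_n
    pAB, pAb = pA * pB, pA * (1.0 - pB)
    paB, pab = (1.0 - pA) * pB, (1.0 - pA) * (1.0 - pB)
    path = [_loglik(counts, pAB, pAb, paB, pab)]

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        den = pAB * pab + pAb * paB
        w = 0.5 if den == 0.0 else pAB * pab / den  # E-step phase weight
        nAB = 2 * n00 + n01 + n10 + n11 * w
        nAb = 2 * n02 + n01 + n12 + n11 * (1.0 - w)
        naB = 2 * n20 + n21 + n10 + n11 * (1.0 - w)
        nab = 2 * n22 + n21 + n12 + n11 * w
        new = (nAB / two_n, nAb / two_n, naB / two_n, nab / two_n)
        delta = max(
            abs(new[0] - pAB), abs(new[1] - pAb), abs(new[2] - paB), abs(new[3] - pab)
        )
        pAB, pAb, paB, pab = new
        path.append(_loglik(counts, pAB, pAb, paB, pab))
        if delta < tol:
            converged = True
            break
    return HaplotypeFreqs(
        pAB, pAb, paB, pab, n, path[-1], iterations, converged, tuple(path)
    )


def r2_pair(freqs: HaplotypeFreqs) -> float:
    """Squared allelic correlation from haplotype frequencies, in [0, 1].

    Exactly 1.0 whenever one diagonal of the haplotype table is empty
    (perfect LD); otherwise D^2 / (p_A(1-p_A) p_B(1-p_B)), clamped against
    floating-point overshoot.
    """
    pA, pB = freqs.p_A, freqs.p_B
    va = pA * (1.0 - pA)
    vb = pB * (1.0 - pB)
    if va <= 0.0 or vb <= 0.0:
        raise UndefinedLDError("r2 undefined: a locus is monomorphic")
    if (freqs.p_Ab == 0.0 and freqs.p_aB == 0.0) or (
        freqs.p_AB == 0.0 and freqs.p_ab == 0.0
    ):
        return 1.0
    d = freqs.D
    return min(max(d * d / (va * vb), 0.0), 1.0)


def r2_matrix(
    panel: GenotypePanel,
    markers: Sequence[int | str] | None = None,
    maf_min: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDMatrix:
    """Pairwise r-squared over a marker subset after MAF filtering.

    Markers that are monomorphic, entirely missing, or below ``maf_min``
    are dropped before pairwise computation; an empty result is legal.
    Pairs whose r-squared is undefined are masked in ``defined``.
    """
    if markers is None:
        idxs = list(range(panel.n_markers))
    else:
        idxs = [m if isinstance(m, int) else panel.marker_index(m) for m in markers]
    keep: list[int] = []
    for idx in idxs:
        g = panel.genotypes[:, idx]
        obs = g[g != MISSING]
        if obs.size == 0:
            continue
        f = float(obs.sum(dtype=np.int64)) / (2.0 * obs.size)
        if min(f, 1.0 - f) <= 0.0:  # monomorphic
            continue
        if f < maf_min:
            continue
        keep.append(idx)
    keep.sort(key=lambda idx: panel.markers[idx].pos)

    k = len(keep)
    r2 = np.zeros((k, k))
    defined = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(defined, True)
    for a in range(k):
        for b in range(a + 1, k):
            try:
                freqs = em_haplotype_freqs(panel, keep[a], keep[b], tol=tol, max_iter=max_iter)
                val = r2_pair(freqs)
            except UndefinedLDError:
                continue
            r2[a, b] = r2[b, a] = val
            defined[a, b] = defined[b, a] = True
    return LDMatrix(markers=[panel.markers[idx] for idx in keep], r2=r2, defined=defined)
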