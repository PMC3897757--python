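"""Independent test oracles: brute-force counterparts of the package's algorithms.

These deliberately avoid the implementation's code paths: the haplotype
MLE is located by nested grid search over the likelihood surface, connected
components by union-find over explicit edge lists, and UPGMA by recomputing
every between-group average distance from the original leaf matrix at every
step.
"""
from __future__ import annotations

import numpy as np

from ldblocks.model import GenotypePanel, Marker


def make_panel(dosages, positions=None, chrom="1", ids=None) -> GenotypePanel:
    """Build a panel directly from a samples x markers dosage matrix."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if ids is None:
        ids = [f"rs{j + 1}" for j in range(m)]
    markers = [
        Marker(id=ids[j], chrom=chrom, pos=int(positions[j]), alleles=("A", "C"))
        for j in range(m)
    ]
    return GenotypePanel(
        markers=markers, samples=[f"S{i + 1}" for i in range(n)], genotypes=dosages
    )


def genotype_table(g1, g2) -> np.ndarray:
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    return np.bincount(g1 * 3 + g2, minlength=9).reshape(3, 3)


def _loglik_grid(counts, pAB, pAb, paB, pab):
    probs = (
        pAB**2, 2 * pAB * pAb, pAb**2,
        2 * pAB * paB, 2 * (pAB * pab + pAb * paB), 2 * pAb * pab,
        paB**2, 2 * paB * pab, pab**2,
    )
    ll = np.zeros_like(pAB)
    for n_ij, p in zip(counts.ravel().tolist(), probs):
        if n_ij:
            with np.errstate(divide="ignore"):
                ll = ll + n_ij * np.log(p)
    return ll


def grid_haplotype_mle(counts, coarse_step=0.02, rounds=7):
    """Brute-force likelihood maximizer over (p_AB, p_Ab, p_aB) grids.

    Starts from a coarse grid on the simplex and refines around the
    incumbent by a factor of 10 per round; final resolution coarse_step /
    10**rounds (2e-9 by default).
    """
    axis = np.arange(0.0, 1.0 + coarse_step / 2, coarse_step)
    pAB, pAb, paB = np.meshgrid(axis, axis, axis, indexing="ij")
    best, step = _grid_argmax(counts, pAB, pAb, paB)
    for _ in range(rounds):
        step /= 10.0
        offs = np.arange(-10, 11) * step
        pAB, pAb, paB = np.meshgrid(
            np.clip(best[0] + offs, 0.0, 1.0),
            np.clip(best[1] + offs, 0.0, 1.0),
            np.clip(best[2] + offs, 0.0, 1.0),
            indexing="ij",
        )
        best, _ = _grid_argmax(counts, pAB, pAb, paB, step_in=step)
    pab = 1.0 - best[0] - best[1] - best[2]
    return best[0], best[1], best[2], max(pab, 0.0)


def _grid_argmax(counts, pAB, pAb, paB, step_in=None):
    pab = 1.0 - pAB - pAb - paB
    ok = pab >= -1e-12
    ll = np.full(pAB.shape, -np.inf)
    ll[ok] = _loglik_grid(
        counts, pAB[ok], pAb[ok], paB[ok], np.maximum(pab[ok], 0.0)
    )
    flat = int(np.argmax(ll))
    idx = np.unravel_index(flat, ll.shape)
    step = step_in if step_in is not None else (pAB[1, 0, 0] - pAB[0, 0, 0])
    return (float(pAB[idx]), float(pAb[idx]), float(paB[idx])), step


def oracle_r2(pAB, pAb, paB, pab):
    pA, pB = pAB + pAb, pAB + paB
    d = pAB * pab - pAb * paB
    return d * d / (pA * (1 - pA) * pB * (1 - pB))


def union_find_components(adj) -> set[frozenset[int]]:
    """Connected components of a boolean adjacency matrix via union-find."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def clique_violations(adj, component) -> set[tuple[int, int]]:
    """All missing edges inside a component (exhaustive pair check)."""
    comp = sorted(component)
    return {
        (a, b)
        for ai, a in enumerate(comp)
        for b in comp[ai + 1 :]
        if not adj[a, b]
    }


def naive_upgma(D):
    """UPGMA recomputing every between-group average from the leaf matrix
    at every step; same (distance, row, column) tie-break as the package."""
    D = np.asarray(D, dtype=float)
    k = D.shape[0]
    members = {i: [i] for i in range(k)}
    active = list(range(k))
    merges = []
    next_id = k
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bj in range(ai + 1, len(active)):
                a, b = active[ai], active[bj]
                d = float(
                    np.mean([D[x, y] for x in members[a] for y in members[b]])
                )
                cand = (d, a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best
        members[next_id] = members[a] + members[b]
        active = [m for m in active if m not in (a, b)] + [next_id]
        merges.append((a, b, d))
        next_id += 1
    return merges
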