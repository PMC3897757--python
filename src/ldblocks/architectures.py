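"""LD architectures: gene-, SNP-, region- and chromosome-centered track sets.

An architecture is an ordered set of named tracks over the clusters (and
optionally singletons) of a genotype panel:

* gene-centered — clusters with at least one member inside the gene window
  ``[tx_start - flank_bp, tx_end + flank_bp]`` (all members displayed, even
  those outside the window); one track per cluster in hierarchical-tree
  order, or a single all-clusters track.
* region-centered — the same over every marker in the panel.
* SNP-centered — clusters among the markers with r-squared >= r2_min
  (default 0.5) to a reference SNP; the reference and its perfectly linked
  markers form the second track, the remaining tracks are ordered by
  decreasing r-squared to the reference (the value is embedded in the
  track name).
* chromosome-centered — every cluster on one track.

The first track always lists the names and positions of the displayed
SNPs; a singleton track (or, SNP-centered, per-singleton tracks at their
own r-squared) is added when requested.  The MAF filter is applied before
cluster construction, so rare SNPs never split or join a block.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .clusters import (
    Cluster,
    Dendrogram,
    agglomerate,
    build_clusters,
    cluster_distance_matrix,
    leaf_order,
)
from .errors import (
    AmbiguousGeneError,
    ContractError,
    EmptyArchitectureWarning,
    GeneLookupError,
    UndefinedLDError,
)
from .ld import LDMatrix, compute_maf, em_haplotype_freqs, r2_matrix, r2_pair
from .model import GeneRecord, GenotypePanel, Marker

logger = logging.getLogger(__name__)

__all__ = [
    "Architecture",
    "ArchitectureParams",
    "Track",
    "TrackItem",
    "gene_centered",
    "snp_centered",
    "region_centered",
    "chromosome_centered",
    "resolve_gene",
    "maf_color",
    "MAF_RAMP",
]

TrackItem = Union[Cluster, Marker]

#: Light-to-dark 5-step blue ramp for MAF bins [0,0.1), ..., [0.4,0.5].
MAF_RAMP: tuple[tuple[int, int, int], ...] = (
    (239, 243, 255),
    (189, 215, 231),
    (107, 174, 214),
    (49, 130, 189),
    (8, 81, 156),
)

NAMES_TRACK = "snp_names"
SINGLETON_TRACK = "singletons"


@dataclass(frozen=True)
class ArchitectureParams:
    flank_bp: int | None = None
    maf_min: float = 0.0
    epsilon: float = 1e-6
    r2_min: float | None = None
    include_singletons: bool = True
    hierarchical: bool | None = None
    color_by_maf: bool = False


@dataclass
class Track:
    """One named track: a list of clusters and/or single SNPs.

    ``r2`` is the SNP-centered ordering key (r-squared of the track's
    content to the reference SNP); rendered into the track name on export.
    """

    name: str
    items: list[TrackItem]
    r2: float | None = None


@dataclass
class Architecture:
    kind: str  # gene | snp | region | chromosome
    center: str
    tracks: list[Track]
    params: ArchitectureParams
    dendrogram: Dendrogram | None = None
    chrom: str | None = None
    mafs: dict[str, float] = field(default_factory=dict)

    @property
    def clusters(self) -> list[Cluster]:
        seen: set[str] = set()
        out: list[Cluster] = []
        for track in self.tracks:
            for item in track.items:
                if isinstance(item, Cluster) and item.name not in seen:
                    seen.add(item.name)
                    out.append(item)
        return out

    @property
    def displayed_markers(self) -> list[Marker]:
        """All markers shown on the names track, in position order."""
        for track in self.tracks:
            if track.name == NAMES_TRACK:
                return [mk for mk in track.items if isinstance(mk, Marker)]
        return []


def _chrom_matches(a: str | None, b: str) -> bool:
    strip = lambda c: c[3:] if c and c.lower().startswith("chr") else c
    return strip(a) == strip(b)


def _names_track(markers: Sequence[Marker]) -> Track:
    return Track(NAMES_TRACK, items=sorted(markers, key=lambda mk: mk.pos))


def _mafs_for(panel: GenotypePanel, markers: Sequence[Marker]) -> dict[str, float]:
    return {mk.id: compute_maf(panel, mk.id) for mk in markers}


def _blocked_architecture(
    panel: GenotypePanel,
    kind: str,
    center: str,
    window: tuple[float, float] | None,
    maf_min: float,
    epsilon: float,
    include_singletons: bool,
    hierarchical: bool,
    color_by_maf: bool,
    flank_bp: int | None,
) -> Architecture:
    """Shared builder for gene- and region-centered architectures."""
    ldm = r2_matrix(panel, maf_min=maf_min)
    clusters, singleton_ids = build_clusters(ldm, epsilon=epsilon)
    logger.info(
        "%s-centered %r: %d markers, %d after MAF >= %g filter",
        kind, center, panel.n_markers, ldm.k, maf_min,
    )

    in_window = (lambda pos: True) if window is None else (
        lambda pos: window[0] <= pos <= window[1]
    )
    retained = [c for c in clusters if any(in_window(mk.pos) for mk in c.members)]
    singles = [
        ldm.markers[ldm.index(mid)] for mid in singleton_ids
        if in_window(ldm.markers[ldm.index(mid)].pos)
    ]
    logger.info(
        "%s-centered %r: %d clusters retained, %d singletons in window",
        kind, center, len(retained), len(singles),
    )

    displayed: list[Marker] = [mk for c in retained for mk in c.members]
    if include_singletons:
        displayed += singles
    if not displayed:
        warnings.warn(
            f"{kind}-centered architecture {center!r}: no markers matched",
            EmptyArchitectureWarning,
            stacklevel=3,
        )

    tracks = [_names_track(displayed)]
    dendro: Dendrogram | None = None
    if retained:
        if hierarchical:
            dendro = agglomerate(cluster_distance_matrix(ldm, retained))
            for idx in leaf_order(dendro):
                tracks.append(Track(retained[idx].name, items=[retained[idx]]))
        else:
            tracks.append(Track("clusters", items=list(retained)))
    if include_singletons and singles:
        tracks.append(Track(SINGLETON_TRACK, items=list(singles)))

    params = ArchitectureParams(
        flank_bp=flank_bp, maf_min=maf_min, epsilon=epsilon,
        include_singletons=include_singletons, hierarchical=hierarchical,
        color_by_maf=color_by_maf,
    )
    return Architecture(
        kind=kind, center=center, tracks=tracks, params=params,
        dendrogram=dendro, chrom=panel.chrom, mafs=_mafs_for(panel, displayed),
    )


def gene_centered(
    panel: GenotypePanel,
    gene: GeneRecord,
    flank_bp: int = 10_000,
    maf_min: float = 0.0,
    epsilon: float = 1e-6,
    include_singletons: bool = True,
    hierarchical: bool = True,
    color_by_maf: bool = False,
) -> Architecture:
    """Architecture of LD blocks with >= 1 member inside the gene window.

    The window is ``[tx_start - flank_bp, tx_end + flank_bp]``, inclusive,
    in 1-based coordinates.  Blocks are built on the full panel, so a
    retained cluster is displayed in full even when some members fall
    outside the window.
    """
    if flank_bp < 0:
        raise ContractError(f"flank_bp must be >= 0, got {flank_bp}")
    if not _chrom_matches(panel.chrom, gene.chrom):
        raise ContractError(
            f"gene {gene.display_id!r} is on {gene.chrom!r}, panel holds {panel.chrom!r}"
        )
    window = (gene.tx_start - flank_bp, gene.tx_end + flank_bp)
    return _blocked_architecture(
        panel, "gene", gene.display_id, window, maf_min, epsilon,
        include_singletons, hierarchical, color_by_maf, flank_bp,
    )


def region_centered(
    panel: GenotypePanel,
    maf_min: float = 0.0,
    epsilon: float = 1e-6,
    include_singletons: bool = True,
    hierarchical: bool = True,
    color_by_maf: bool = False,
) -> Architecture:
    """Architecture over the genomic region covered by the imported panel."""
    center = f"{panel.chrom}:{panel.positions.min()}-{panel.positions.max()}" \
        if panel.n_markers else str(panel.chrom)
    return _blocked_architecture(
        panel, "region", center, None, maf_min, epsilon,
        include_singletons, hierarchical, color_by_maf, None,
    )


def chromosome_centered(
    panel: GenotypePanel,
    maf_min: float = 0.0,
    epsilon: float = 1e-6,
    include_singletons: bool = True,
    color_by_maf: bool = False,
) -> Architecture:
    """All clusters of the chromosome on a single track.

    Singletons, when included, go on an additional dedicated track.
    No dendrogram is attached.
    """
    ldm = r2_matrix(panel, maf_min=maf_min)
    clusters, singleton_ids = build_clusters(ldm, epsilon=epsilon)
    logger.info(
        "chromosome-centered %r: %d markers, %d after MAF filter, %d clusters, "
        "%d singletons",
        panel.chrom, panel.n_markers, ldm.k, len(clusters), len(singleton_ids),
    )
    singles = [ldm.markers[ldm.index(mid)] for mid in singleton_ids]
    displayed = [mk for c in clusters for mk in c.members]
    if include_singletons:
        displayed += singles
    tracks = [_names_track(displayed)]
    if clusters:
        tracks.append(Track("clusters", items=list(clusters)))
    if include_singletons and singles:
        tracks.append(Track(SINGLETON_TRACK, items=list(singles)))
    params = ArchitectureParams(
        maf_min=maf_min, epsilon=epsilon,
        include_singletons=include_singletons, color_by_maf=color_by_maf,
    )
    return Architecture(
        kind="chromosome", center=str(panel.chrom), tracks=tracks, params=params,
        chrom=panel.chrom, mafs=_mafs_for(panel, displayed),
    )


def snp_centered(
    panel: GenotypePanel,
    ref_snp_id: str,
    maf_min: float = 0.0,
    epsilon: float = 1e-6,
    r2_min: float = 0.5,
    include_singletons: bool = True,
    color_by_maf: bool = False,
) -> Architecture:
    """Architecture of all clusters in LD with a reference SNP.

    Only markers with defined r-squared >= ``r2_min`` (default 0.5) to the
    reference are considered.  Track 2 holds the reference SNP joined with
    every marker at r-squared >= 1 - epsilon to it; each remaining cluster
    (and, when included, each singleton) gets its own track annotated with
    its r-squared to the reference, ordered non-increasing, ties broken by
    the genomic position of the track's first SNP.
    """
    ref_idx = panel.marker_index(ref_snp_id)
    try:
        ref_maf = compute_maf(panel, ref_idx)
    except UndefinedLDError:
        ref_maf = 0.0
    if ref_maf <= 0.0:
        raise UndefinedLDError(
            f"reference SNP {ref_snp_id!r} is monomorphic; LD to it is undefined"
        )

    r2_to_ref: dict[str, float] = {ref_snp_id: 1.0}
    for idx, mk in enumerate(panel.markers):
        if idx == ref_idx:
            continue
        try:
            f = compute_maf(panel, idx)
        except UndefinedLDError:
            continue
        if min(f, 1.0 - f) <= 0.0 or f < maf_min:
            continue
        try:
            r2_to_ref[mk.id] = r2_pair(em_haplotype_freqs(panel, ref_idx, idx))
        except UndefinedLDError:
            continue
    candidates = [mid for mid, val in r2_to_ref.items() if val >= r2_min]
    logger.info(
        "snp-centered %r: %d markers, %d candidates at r2 >= %g",
        ref_snp_id, panel.n_markers, len(candidates), r2_min,
    )

    ldm = r2_matrix(panel, markers=candidates)
    clusters, singleton_ids = build_clusters(ldm, epsilon=epsilon)

    ref_set = {mid for mid, val in r2_to_ref.items() if val >= 1.0 - epsilon}
    ref_set.add(ref_snp_id)
    ref_markers = sorted(
        (mk for mk in ldm.markers if mk.id in ref_set), key=lambda mk: mk.pos
    )
    ref_item: TrackItem = (
        Cluster(members=tuple(ref_markers)) if len(ref_markers) >= 2 else ref_markers[0]
    )

    rest: list[tuple[float, int, str, list[TrackItem]]] = []
    for c in clusters:
        if set(c.member_ids) & ref_set:
            continue
        val = r2_to_ref[c.member_ids[0]]  # representative: first (leftmost) member
        rest.append((val, c.min_pos, c.name, [c]))
    if include_singletons:
        for mid in singleton_ids:
            if mid in ref_set:
                continue
            mk = ldm.markers[ldm.index(mid)]
            rest.append((r2_to_ref[mid], mk.pos, mk.id, [mk]))
    rest.sort(key=lambda t: (-t[0], t[1]))

    displayed = list(ref_markers) + [
        mk for _, _, _, items in rest for item in items
        for mk in (item.members if isinstance(item, Cluster) else (item,))
    ]
    tracks = [_names_track(displayed)]
    tracks.append(Track(ref_snp_id, items=[ref_item], r2=1.0))
    for val, _, name, items in rest:
        tracks.append(Track(name, items=items, r2=val))

    params = ArchitectureParams(
        maf_min=maf_min, epsilon=epsilon, r2_min=r2_min,
        include_singletons=include_singletons, color_by_maf=color_by_maf,
    )
    return Architecture(
        kind="snp", center=ref_snp_id, tracks=tracks, params=params,
        chrom=panel.chrom, mafs=_mafs_for(panel, displayed),
    )


def resolve_gene(gene_table: Sequence[GeneRecord], query: str) -> GeneRecord:
    """Find one gene by Entrez id, then RefSeq id, then (case-insensitive) symbol.

    Raises :class:`GeneLookupError` when nothing matches and
    :class:`AmbiguousGeneError` when several records match in the same
    identifier class.
    """
    q = query.strip()
    for matches in (
        [g for g in gene_table if g.entrez_id == q],
        [g for g in gene_table if g.refseq_id == q],
        [g for g in gene_table if g.symbol.casefold() == q.casefold()],
    ):
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            listing = ", ".join(
                f"{g.symbol or g.entrez_id}/{g.refseq_id} "
                f"({g.chrom}:{g.tx_start}-{g.tx_end})" for g in matches
            )
            raise AmbiguousGeneError(f"query {query!r} matches several genes: {listing}")
    raise GeneLookupError(f"no gene matches {query!r} by Entrez, RefSeq or symbol")


def maf_color(maf: float) -> tuple[int, int, int]:
    """Map a MAF in [0, 0.5] to the 5-bin light-to-dark color ramp.

    Bins have width 0.1; 0.5 falls in the darkest bin.  A cluster is
    colored by the mean MAF of its members.
    """
    if not -1e-9 <= maf <= 0.5 + 1e-9:
        raise ContractError(f"MAF must lie in [0, 0.5], got {maf}")
    return MAF_RAMP[min(4, int(max(maf, 0.0) / 0.1))]
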