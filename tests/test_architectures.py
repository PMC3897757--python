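"""Gene-, SNP-, region- and chromosome-centered architectures."""
import numpy as np
import pytest

from ldblocks import (
    BlockSpec,
    GeneRecord,
    build_clusters,
    chromosome_centered,
    compute_maf,
    em_haplotype_freqs,
    gene_centered,
    maf_color,
    r2_matrix,
    r2_pair,
    region_centered,
    resolve_gene,
    simulate_panel,
    snp_centered,
)
from ldblocks.architectures import MAF_RAMP, NAMES_TRACK, SINGLETON_TRACK
from ldblocks.clusters import Cluster
from ldblocks.errors import (
    AmbiguousGeneError,
    ContractError,
    EmptyArchitectureWarning,
    GeneLookupError,
    UndefinedLDError,
)
from ldblocks.model import Marker

from _oracles import make_panel


def gene_record(**kw):
    defaults = dict(entrez_id="100", refseq_id="NM_0001", symbol="GENE1",
                    chrom="1", tx_start=9_000, tx_end=16_000, strand="+")
    defaults.update(kw)
    return GeneRecord(**defaults)


@pytest.fixture
def six_marker_panel(rng):
    """Blocks {rs1,rs2,rs3} and {rs5,rs6}; rs4 a singleton."""
    a = rng.integers(0, 3, size=(60, 1)).astype(np.int8)
    b = rng.integers(0, 3, size=(60, 1)).astype(np.int8)
    c = rng.integers(0, 3, size=(60, 1)).astype(np.int8)
    geno = np.hstack([a, a, a, c, b, b])
    return make_panel(geno, positions=[10_000, 11_000, 12_000, 13_000, 14_000, 15_000])


class TestGeneCentered:
    def test_track_layout(self, six_marker_panel):
        arch = gene_centered(six_marker_panel, gene_record(), flank_bp=0)
        names = [t.name for t in arch.tracks]
        assert names[0] == NAMES_TRACK
        assert set(names[1:3]) == {"rs1", "rs5"}
        assert names[3] == SINGLETON_TRACK
        assert arch.dendrogram is not None
        assert len(arch.displayed_markers) == 6

    def test_flank_zero_keeps_cluster_with_outside_member(self, rng):
        # one member inside the gene, its duplicate 10 kb upstream
        a = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        panel = make_panel(np.hstack([a, a]), positions=[10_000, 20_000])
        gene = gene_record(tx_start=19_000, tx_end=21_000)
        arch = gene_centered(panel, gene, flank_bp=0)
        clusters = arch.clusters
        assert len(clusters) == 1
        assert clusters[0].member_ids == ("rs1", "rs2")  # displayed in full
        assert {mk.id for mk in arch.displayed_markers} == {"rs1", "rs2"}

    def test_window_excludes_far_singletons(self, six_marker_panel):
        gene = gene_record(tx_start=10_500, tx_end=12_500)
        arch = gene_centered(six_marker_panel, gene, flank_bp=0)
        # block rs1 touches the window; rs4 singleton and block rs5 do not
        assert [c.member_ids for c in arch.clusters] == [("rs1", "rs2", "rs3")]
        assert all(t.name != SINGLETON_TRACK for t in arch.tracks)

    def test_same_architecture_for_all_three_identifiers(self, six_marker_panel):
        table = [gene_record()]
        archs = [
            gene_centered(six_marker_panel, resolve_gene(table, q), flank_bp=0)
            for q in ("100", "NM_0001", "gene1")
        ]
        layouts = [[(t.name, [getattr(i, "id", None) or i.name for i in t.items])
                    for t in a.tracks] for a in archs]
        assert layouts[0] == layouts[1] == layouts[2]

    def test_wrong_chromosome_rejected(self, six_marker_panel):
        with pytest.raises(ContractError, match="chromosome|holds"):
            gene_centered(six_marker_panel, gene_record(chrom="2"))

    def test_empty_window_warns(self, six_marker_panel):
        gene = gene_record(tx_start=1, tx_end=2)
        with pytest.warns(EmptyArchitectureWarning):
            arch = gene_centered(six_marker_panel, gene, flank_bp=0)
        assert arch.clusters == []

    def test_flat_mode_single_track(self, six_marker_panel):
        arch = gene_centered(six_marker_panel, gene_record(), flank_bp=0,
                             hierarchical=False)
        cluster_tracks = [t for t in arch.tracks if t.name == "clusters"]
        assert len(cluster_tracks) == 1 and len(cluster_tracks[0].items) == 2
        assert arch.dendrogram is None


class TestResolveGene:
    table = [
        gene_record(),
        gene_record(entrez_id="101", refseq_id="NM_0002", symbol="GENE2"),
        gene_record(entrez_id="101x", refseq_id="NM_0003", symbol="GENE2"),
    ]

    def test_symbol_match(self):
        assert resolve_gene(self.table, "GENE1").refseq_id == "NM_0001"

    def test_ambiguous_symbol_lists_candidates(self):
        with pytest.raises(AmbiguousGeneError, match="NM_0002.*NM_0003"):
            resolve_gene(self.table, "GENE2")

    def test_entrez_precedence(self):
        # an Entrez hit wins even though it prefixes another record's id
        assert resolve_gene(self.table, "101").refseq_id == "NM_0002"

    def test_no_match(self):
        with pytest.raises(GeneLookupError):
            resolve_gene(self.table, "NOPE")


class TestSnpCentered:
    @pytest.fixture
    def graded_panel(self):
        """Reference block, a perfect duplicate, then blocks at graded LD."""
        spec = BlockSpec(
            block_sizes=(2, 2, 1, 1),  # ref+duplicate, 2-SNP block, singleton, weak
            block_mafs=(0.4, 0.4, 0.4, 0.4),
            n_samples=1500,
            seed=33,
            between_corr=(
                (1.0, 0.9, 0.78, 0.55),
                (0.9, 1.0, 0.78, 0.55),
                (0.78, 0.78, 1.0, 0.55),
                (0.55, 0.55, 0.55, 1.0),
            ),
        )
        panel, truth = simulate_panel(spec)
        return panel, truth

    def test_structure_and_ordering(self, graded_panel):
        panel, _ = graded_panel
        arch = snp_centered(panel, "rs1")
        assert arch.tracks[0].name == NAMES_TRACK
        ref_track = arch.tracks[1]
        assert ref_track.r2 == 1.0
        assert isinstance(ref_track.items[0], Cluster)
        assert ref_track.items[0].member_ids == ("rs1", "rs2")  # perfect duplicate
        tail = arch.tracks[2:]
        vals = [t.r2 for t in tail]
        assert vals == sorted(vals, reverse=True)
        # the weak block (true r2 ~ 0.3) is filtered at r2_min = 0.5
        shown = {mk.id for mk in arch.displayed_markers}
        assert "rs6" not in shown
        assert {"rs3", "rs4", "rs5"} <= shown

    def test_retained_set_matches_brute_force_scan(self, graded_panel):
        panel, _ = graded_panel
        arch = snp_centered(panel, "rs1", r2_min=0.5)
        ref = panel.marker_index("rs1")
        expected = {"rs1"}
        for idx, mk in enumerate(panel.markers):
            if idx == ref:
                continue
            try:
                val = r2_pair(em_haplotype_freqs(panel, ref, idx))
            except UndefinedLDError:
                continue
            if val >= 0.5:
                expected.add(mk.id)
        assert {mk.id for mk in arch.displayed_markers} == expected

    def test_annotations_strictly_from_reference(self, graded_panel):
        panel, _ = graded_panel
        arch = snp_centered(panel, "rs1")
        ref = panel.marker_index("rs1")
        for track in arch.tracks[2:]:
            first = track.items[0]
            first_id = first.member_ids[0] if isinstance(first, Cluster) else first.id
            val = r2_pair(em_haplotype_freqs(panel, ref, panel.marker_index(first_id)))
            assert track.r2 == pytest.approx(val, abs=1e-12)

    def test_isolated_reference(self, rng):
        a = rng.integers(0, 3, size=(200, 1)).astype(np.int8)
        b = rng.integers(0, 3, size=(200, 1)).astype(np.int8)
        panel = make_panel(np.hstack([a, b]))
        arch = snp_centered(panel, "rs1")
        assert [t.name for t in arch.tracks] == [NAMES_TRACK, "rs1"]
        assert isinstance(arch.tracks[1].items[0], Marker)

    def test_monomorphic_reference_rejected(self):
        panel = make_panel(np.zeros((10, 2), dtype=np.int8))
        with pytest.raises(UndefinedLDError, match="monomorphic"):
            snp_centered(panel, "rs1")


class TestRegionAndChromosome:
    def test_region_equals_gene_with_covering_window(self, six_marker_panel):
        gene = gene_record(tx_start=1, tx_end=1_000_000)
        g = gene_centered(six_marker_panel, gene, flank_bp=0)
        r = region_centered(six_marker_panel)
        assert [c.member_ids for c in g.clusters] == [c.member_ids for c in r.clusters]
        assert [t.name for t in g.tracks] == [t.name for t in r.tracks]

    def test_region_flat_single_track(self, six_marker_panel):
        arch = region_centered(six_marker_panel, hierarchical=False)
        assert [t.name for t in arch.tracks] == [NAMES_TRACK, "clusters", SINGLETON_TRACK]

    def test_chromosome_single_track_matches_build_clusters(self, six_marker_panel):
        arch = chromosome_centered(six_marker_panel)
        clusters, singles = build_clusters(r2_matrix(six_marker_panel))
        track = next(t for t in arch.tracks if t.name == "clusters")
        assert len(track.items) == len(clusters) == 2
        singleton_track = next(t for t in arch.tracks if t.name == SINGLETON_TRACK)
        assert [mk.id for mk in singleton_track.items] == singles
        assert arch.dendrogram is None

    def test_chromosome_no_blocks(self, rng):
        cols = [rng.integers(0, 3, size=(80, 1)).astype(np.int8) for _ in range(3)]
        panel = make_panel(np.hstack(cols))
        arch = chromosome_centered(panel, include_singletons=False)
        assert [t.name for t in arch.tracks] == [NAMES_TRACK]
        arch2 = chromosome_centered(panel, include_singletons=True)
        assert [t.name for t in arch2.tracks] == [NAMES_TRACK, SINGLETON_TRACK]


class TestPartitionInvariant:
    @pytest.mark.parametrize("maf_min", [0.0, 0.1])
    def test_every_passing_marker_appears_exactly_once(self, maf_min):
        spec = BlockSpec(block_sizes=(3, 2, 1, 1), block_mafs=(0.3, 0.2, 0.45, 0.05),
                         n_samples=120, seed=9)
        panel, _ = simulate_panel(spec)
        arch = region_centered(panel, maf_min=maf_min, include_singletons=True)
        counts = {}
        for track in arch.tracks:
            if track.name == NAMES_TRACK:
                continue
            for item in track.items:
                ids = item.member_ids if isinstance(item, Cluster) else (item.id,)
                for mid in ids:
                    counts[mid] = counts.get(mid, 0) + 1
        ldm = r2_matrix(panel, maf_min=maf_min)
        assert counts == {mid: 1 for mid in ldm.marker_ids}


class TestMafColor:
    @pytest.mark.parametrize("maf,expected", [
        (0.0, MAF_RAMP[0]),
        (0.5, MAF_RAMP[-1]),
        (0.09, MAF_RAMP[0]),
        (0.11, MAF_RAMP[1]),
    ])
    def test_bins(self, maf, expected):
        assert maf_color(maf) == expected

    def test_same_bin_same_color(self):
        assert maf_color(0.21) == maf_color(0.29)

    @pytest.mark.parametrize("bad", [-0.01, 0.51])
    def test_out_of_range(self, bad):
        with pytest.raises(ContractError):
            maf_color(bad)


def test_architecture_is_deterministic(six_marker_panel, tmp_path):
    from ldblocks import write_architecture

    paths = []
    for i in range(2):
        arch = gene_centered(six_marker_panel, gene_record(), flank_bp=0,
                             color_by_maf=True)
        p = tmp_path / f"run{i}.bed"
        write_architecture(arch, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]
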