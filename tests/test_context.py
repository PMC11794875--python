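"""Window extraction, similarity graph, MCL families, relevance, delineation."""

import networkx as nx
import numpy as np
import pytest

from azescan import context, synthfix
from azescan.context import GeneFeature
from azescan.errors import DataError, ParameterError


def lay_out_contig(n_per_side=25, gene_len=500, spacing=1000, contig="c1"):
    """Genes every `spacing` bp either side of a central anchor."""
    feats = []
    n_total = 2 * n_per_side + 1
    for i in range(n_total):
        start = 1 + i * spacing
        pid = "anchor" if i == n_per_side else f"g{i:03d}"
        feats.append(GeneFeature(contig_id=contig, start=start, end=start + gene_len - 1,
                                 strand="+", protein_id=pid))
    return feats


class TestExtractWindow:
    def test_arithmetic_layout_counts_and_distances(self):
        # genes every 1 kb, flank 20 kb -> 20 genes per side, distances 1..20
        feats = lay_out_contig(n_per_side=25, gene_len=500, spacing=1000)
        w = context.extract_window(feats, "anchor", flank=20_000)
        left = [g for g in w.genes if g.signed_offset < 0]
        right = [g for g in w.genes if g.signed_offset > 0]
        assert len(left) == len(right) == 20
        assert sorted(g.cds_distance for g in right) == list(range(1, 21))
        anchor_gene = next(g for g in w.genes if g.signed_offset == 0)
        assert anchor_gene.cds_distance == 0
        # intergenic gaps: 1000 - 500 = 500 bp between consecutive genes
        assert all(g.intergenic_gap == 500 for g in w.genes[1:])

    def test_truncated_at_contig_edge(self):
        feats = [
            GeneFeature("c1", 100, 700, "+", "anchor"),
            GeneFeature("c1", 1200, 1800, "+", "g1"),
        ]
        w = context.extract_window(feats, "anchor", flank=20_000, contig_length=5_000)
        assert w.span == (1, 5_000)
        assert w.gene_ids == ["anchor", "g1"]

    def test_zero_flank_is_parameter_error(self):
        feats = lay_out_contig(n_per_side=2)
        with pytest.raises(ParameterError):
            context.extract_window(feats, "anchor", flank=0)

    def test_missing_anchor_is_lookup_error(self):
        feats = lay_out_contig(n_per_side=2)
        with pytest.raises(DataError, match="nope"):
            context.extract_window(feats, "nope", flank=1000)

    def test_other_contigs_excluded(self):
        feats = lay_out_contig(n_per_side=2) + [
            GeneFeature("c2", 10, 500, "+", "elsewhere")
        ]
        w = context.extract_window(feats, "anchor", flank=50_000)
        assert "elsewhere" not in w.gene_ids


class TestSimilarityGraph:
    def test_identical_proteins_get_weight_one(self):
        seq = "MKVLITAGPTREALDPVRYISNHSSGKMGFAIAE"
        g = context.build_similarity_graph({"a": seq, "b": seq})
        assert g["a"]["b"]["weight"] == pytest.approx(1.0)

    def test_external_evalue_weights(self):
        from azescan.screen import HitRecord

        hits = [
            HitRecord("a", "b", 50.0, 0.9, 0.9, 1e-50, 100.0),
            HitRecord("b", "a", 50.0, 0.9, 0.9, 1e-30, 100.0),
        ]
        g = context.build_similarity_graph({"a": "M" * 30, "b": "M" * 30}, hits)
        assert g["a"]["b"]["weight"] == pytest.approx(50.0)  # max of the two directions

    def test_external_zero_evalue_capped(self):
        from azescan.screen import HitRecord

        hits = [HitRecord("a", "b", 99.0, 1.0, 1.0, 0.0, 500.0)]
        g = context.build_similarity_graph({"a": "M" * 30, "b": "M" * 30}, hits)
        assert g["a"]["b"]["weight"] == 200.0

    def test_unknown_id_in_hits_rejected(self):
        from azescan.screen import HitRecord

        hits = [HitRecord("a", "zzz", 50.0, 0.9, 0.9, 1e-10, 100.0)]
        with pytest.raises(DataError):
            context.build_similarity_graph({"a": "M" * 30, "b": "M" * 30}, hits)

    def test_unrelated_random_proteins_unconnected(self):
        rng = np.random.default_rng(0)
        seqs = {f"r{i}": synthfix.random_protein(rng, 150) for i in range(6)}
        g = context.build_similarity_graph(seqs)
        assert g.number_of_edges() == 0

    def test_needs_two_proteins(self):
        with pytest.raises(ParameterError):
            context.build_similarity_graph({"a": "M" * 30})


class TestMclCluster:
    @staticmethod
    def clique_graph(sizes, rng=None, weight=1.0):
        g = nx.Graph()
        node = 0
        truth = []
        for s in sizes:
            members = [f"n{node + k:03d}" for k in range(s)]
            node += s
            truth.append(set(members))
            for i, u in enumerate(members):
                g.add_node(u)
                for v in members[i + 1:]:
                    g.add_edge(u, v, weight=weight)
        return g, truth

    def test_two_disjoint_cliques_resolved(self):
        g, truth = self.clique_graph([4, 5])
        fam = context.mcl_cluster(g, 1.3)
        got = {}
        for n, f in fam.items():
            got.setdefault(f, set()).add(n)
        assert sorted(map(sorted, got.values())) == sorted(map(sorted, truth))

    def test_single_node_is_singleton_family(self):
        g = nx.Graph()
        g.add_node("only")
        assert context.mcl_cluster(g, 1.3) == {"only": "fam0000"}

    def test_planted_three_family_graph(self):
        # within-weight 1.0, between-weight 0.01: MCL at 1.3 keeps the 3 blocks
        g, truth = self.clique_graph([5, 4, 6])
        rng = np.random.default_rng(1)
        blocks = [sorted(t) for t in truth]
        for bi in range(len(blocks)):
            for bj in range(bi + 1, len(blocks)):
                u = blocks[bi][int(rng.integers(len(blocks[bi])))]
                v = blocks[bj][int(rng.integers(len(blocks[bj])))]
                g.add_edge(u, v, weight=0.01)
        fam = context.mcl_cluster(g, 1.3)
        got = {}
        for n, f in fam.items():
            got.setdefault(f, set()).add(n)
        assert sorted(map(sorted, got.values())) == sorted(map(sorted, truth))

    def test_matches_connected_components_on_clique_unions(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            sizes = rng.integers(1, 8, size=int(rng.integers(2, 6)))
            g, _ = self.clique_graph(list(sizes))
            fam = context.mcl_cluster(g, 1.3)
            got = {}
            for n, f in fam.items():
                got.setdefault(f, set()).add(n)
            comps = [set(c) for c in nx.connected_components(g)]
            assert sorted(map(sorted, got.values())) == sorted(map(sorted, comps))

    def test_inflation_must_exceed_one(self):
        g, _ = self.clique_graph([3])
        with pytest.raises(ParameterError):
            context.mcl_cluster(g, 1.0)


def make_windows(n_windows, offsets_by_family, window_genes=5):
    """Windows with gene ids '<fam>_<w>' planted at given signed offsets.

    Every other slot in the window is filled with a window-private filler
    gene so planted slot offsets equal CDS-rank distances exactly.
    """
    windows = []
    families = {}
    span = max(
        [window_genes] + [abs(o) for offs in offsets_by_family.values() for o in offs]
    )
    for w in range(n_windows):
        contig = f"c{w}"
        slots = {0: (f"anchor_{w}", "FAM_ANCHOR")}
        for fam, offs in offsets_by_family.items():
            off = offs[w % len(offs)]
            slots[off] = (f"{fam}_{w}", fam)
        for off in range(-span, span + 1):
            if off not in slots:
                slots[off] = (f"fill{off:+d}_{w}", f"FILL_{off:+d}_{w}")
        feats = []
        for i, off in enumerate(sorted(slots)):
            pid, fam = slots[off]
            start = 1 + i * 1000
            feats.append(GeneFeature(contig, start, start + 800, "+", pid))
            families[pid] = fam
        anchor_id = slots[0][0]
        windows.append(context.extract_window(feats, anchor_id, flank=100_000))
    return windows, families


class TestRelevanceScores:
    def test_always_adjacent_family_scores_window_count(self):
        windows, families = make_windows(88, {"FAM_X": [1]})
        table = context.relevance_scores(windows, families)
        fx = table.stats("FAM_X")
        assert fx.occurrence_count == 88
        assert fx.median_distance == 1.0
        assert fx.relevance == pytest.approx(88.0)

    def test_one_window_distance_ten(self):
        offsets = {f"F{i}": [i] for i in range(1, 11)}  # fillers at offsets 1..10
        windows, families = make_windows(1, offsets)
        table = context.relevance_scores(windows, families)
        assert table.stats("F10").relevance == pytest.approx(0.1)

    def test_anchor_family_flagged_infinite(self):
        windows, families = make_windows(5, {"FAM_X": [1]})
        table = context.relevance_scores(windows, families)
        anchor = table.stats("FAM_ANCHOR")
        assert anchor.is_anchor and anchor.relevance == float("inf")

    def test_even_count_median_is_mean_of_central_pair(self):
        windows, families = make_windows(2, {"FAM_X": [1, 2]})
        table = context.relevance_scores(windows, families)
        assert table.stats("FAM_X").median_distance == pytest.approx(1.5)

    def test_occurrences_count_windows_not_members(self):
        # two members of the family in ONE window: n_f stays 1
        feats = [
            GeneFeature("c0", 1, 800, "+", "m1"),
            GeneFeature("c0", 1001, 1800, "+", "anchor_0"),
            GeneFeature("c0", 2001, 2800, "+", "m2"),
        ]
        w = context.extract_window(feats, "anchor_0", flank=100_000)
        families = {"m1": "FAM_X", "m2": "FAM_X", "anchor_0": "FAM_ANCHOR"}
        table = context.relevance_scores([w], families)
        fx = table.stats("FAM_X")
        assert fx.occurrence_count == 1 and fx.member_count == 2

    def test_per_window_min_mode(self):
        feats = [
            GeneFeature("c0", 1, 800, "+", "m1"),
            GeneFeature("c0", 1001, 1800, "+", "anchor_0"),
            GeneFeature("c0", 2001, 2800, "+", "m2"),
            GeneFeature("c0", 3001, 3800, "+", "m3"),
        ]
        w = context.extract_window(feats, "anchor_0", flank=100_000)
        families = {"m1": "FAM_X", "m2": "FAM_X", "m3": "FAM_X",
                    "anchor_0": "FAM_ANCHOR"}
        t_all = context.relevance_scores([w], families, "all_occurrences")
        t_min = context.relevance_scores([w], families, "per_window_min")
        assert t_all.stats("FAM_X").median_distance == 1.0  # median of {1, 1, 2}
        assert t_min.stats("FAM_X").median_distance == 1.0  # nearest member only

    def test_window_count_scale_freeness(self):
        # duplicating every window doubles n_f, keeps the distance median
        windows, families = make_windows(10, {"FAM_X": [2]})
        t1 = context.relevance_scores(windows, families)
        windows2, families2 = make_windows(20, {"FAM_X": [2]})
        t2 = context.relevance_scores(windows2, families2)
        assert t2.stats("FAM_X").relevance == pytest.approx(
            2 * t1.stats("FAM_X").relevance
        )

    def test_unassigned_gene_is_data_error(self):
        windows, families = make_windows(2, {"FAM_X": [1]})
        del families[next(k for k in families if k.startswith("FAM_X"))]
        with pytest.raises(DataError):
            context.relevance_scores(windows, families)


class TestAnnotateRelevant:
    def _table(self, n_windows, offsets):
        windows, families = make_windows(n_windows, offsets)
        return context.relevance_scores(windows, families)

    def test_threshold_is_inclusive(self):
        # 8 windows at distance 4 -> relevance exactly 2.0
        table = self._table(8, {"FAM_E": [4], "F1": [1], "F2": [2], "F3": [3]})
        context.annotate_relevant(table, 2.0)
        assert "FAM_E" in table.marked_families()

    def test_below_threshold_unmarked(self):
        # 1 window, family at distance 1 -> relevance 1.0 < 2
        table = self._table(1, {"FAM_LOW": [1]})
        context.annotate_relevant(table, 2.0)
        assert "FAM_LOW" not in table.marked_families()

    def test_anchor_family_always_marked(self):
        table = self._table(2, {"FAM_LOW": [3]})
        context.annotate_relevant(table, 2.0)
        assert "FAM_ANCHOR" in table.marked_families()

    def test_empty_table_stays_empty(self):
        table = context.FamilyTable(gene_to_family={}, families=[], n_windows=0)
        context.annotate_relevant(table, 2.0)
        assert table.marked_families() == set()

    def test_raising_threshold_never_adds_families(self):
        table = self._table(6, {"F1": [1], "F2": [2], "F3": [3], "F4": [4]})
        marked = []
        for thr in (0.5, 1.0, 2.0, 4.0, 8.0):
            context.annotate_relevant(table, thr)
            marked.append(frozenset(table.marked_families()))
        for small, big in zip(marked[1:], marked):
            assert small <= big


class TestDelineateRegion:
    def _window_and_table(self, n_decoys_each_side=3, gap=2000):
        """5 conserved genes (plus anchor) flanked by sparse decoys."""
        windows = []
        families = {}
        n_windows = 8
        for w in range(n_windows):
            contig = f"c{w}"
            feats = []
            pos = 1
            # (kind, gap BEFORE the gene): decoys sit `gap` bp away from
            # their neighbors; the conserved core is tightly packed
            layout = (
                [("D", gap)] * n_decoys_each_side
                + [("K", gap), ("K", 100)]
                + [("A", 100)]
                + [("K", 100)] * 3
                + [("D", gap)] * n_decoys_each_side
            )
            ki = di = 0
            for j, (kind, gap_before) in enumerate(layout):
                if j > 0:
                    pos += gap_before
                if kind == "A":
                    pid, fam = f"anchor_{w}", "FAM_ANCHOR"
                elif kind == "K":
                    pid, fam = f"keep{ki}_{w}", f"FAM_K{ki}"
                    ki += 1
                else:
                    pid, fam = f"decoy{di}_{w}", f"FAM_D{di}_{w}"  # window-private
                    di += 1
                feats.append(GeneFeature(contig, pos, pos + 799, "+", pid))
                families[pid] = fam
                pos += 800
            windows.append(context.extract_window(feats, f"anchor_{w}", flank=100_000))
        table = context.relevance_scores(windows, families)
        return windows, table

    def test_all_supported_returns_full_window(self):
        windows, table = self._window_and_table(n_decoys_each_side=0)
        out = context.delineate_region(windows[0], table)
        assert out.gene_ids == windows[0].gene_ids

    def test_planted_conserved_region_recovered(self):
        windows, table = self._window_and_table()
        out = context.delineate_region(
            windows[0], table, max_gap=500, min_conservation=0.25, patience=2
        )
        kinds = {pid.split("_")[0][:4] for pid in out.gene_ids}
        assert len(out.gene_ids) == 6  # anchor + 5 conserved
        assert not any(k.startswith("deco") for k in kinds)

    def test_patience_zero_stops_at_first_unsupported(self):
        windows, table = self._window_and_table()
        out = context.delineate_region(
            windows[0], table, max_gap=500, min_conservation=0.25, patience=0
        )
        assert len(out.gene_ids) == 6

    def test_anchor_always_retained(self):
        windows, table = self._window_and_table()
        out = context.delineate_region(
            windows[0], table, max_gap=0, min_conservation=1.1, patience=0
        )
        assert out.gene_ids == [windows[0].anchor.protein_id]


class TestEndToEndPlantedRecovery:
    def test_marked_set_equals_planted_set(self):
        fx = synthfix.gen_neighborhoods(
            n_contexts=12,
            planted=[("famA", 1, 1.0), ("famB", -2, 0.9), ("famC", 3, 0.85)],
            window_genes=4,
            decoy_rate=2.0,
            seed=123,
        )
        windows = [
            context.extract_window(fx.features, a, 20_000)
            for a in fx.anchor_ids
        ]
        proteins = {g: fx.proteins[g] for w in windows for g in w.gene_ids}
        graph = context.build_similarity_graph(proteins)
        families = context.mcl_cluster(graph, 1.3)
        table = context.annotate_relevant(
            context.relevance_scores(windows, families), 2.0
        )
        truth_of = fx.truth.gene_family
        marked_truth = set()
        for fam_id in table.marked_families():
            members = {g for g, f in families.items() if f == fam_id}
            labels = {truth_of[g] for g in members}
            assert len(labels) == 1  # each marked family is pure
            marked_truth.add(labels.pop())
        assert marked_truth == {"anchor", "famA", "famB", "famC"}
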