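"""Comparative content analysis: orthogroup graph vs a union-find oracle,
presence/absence bootstrap clustering (including the clustering-vs-phylogeny
dissociation), top-ten taxonomy affiliation, rhodopsin motif typing and
neighbor joining on additive matrices."""

import numpy as np
import pytest

from sortvir.protein_profiles import (
    cluster_presence_absence,
    infer_orthogroups,
    marker_concat_tree,
    protein_align,
    rhodopsin_motif,
    taxonomy_affiliation,
)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _rand_prot(rng, n):
    return "".join(AA[rng.integers(0, 20, n)])


def _mutate(rng, s, d):
    arr = np.array(list(s))
    m = rng.random(len(arr)) < d
    arr[m] = AA[rng.integers(0, 20, int(m.sum()))]
    return "".join(arr)


class TestInferOrthogroups:
    def test_identical_proteomes_fully_shared(self, rng):
        prots = [(f"p{i}", _rand_prot(rng, 150)) for i in range(6)]
        om = infer_orthogroups({"a": prots, "b": prots})
        assert (om.presence.sum(axis=0) == 2).all()
        assert om.private_counts == {"a": 0, "b": 0}

    def test_planted_families_recovered(self, rng):
        families = [_rand_prot(rng, 200) for _ in range(5)]
        proteomes = {}
        for g in range(4):
            shared = [(f"g{g}_f{i}", _mutate(rng, families[i], 0.15))
                      for i in range(5)]
            private = [(f"g{g}_x{j}", _rand_prot(rng, 150)) for j in range(2)]
            proteomes[f"g{g}"] = shared + private
        om = infer_orthogroups(proteomes)
        # each planted family forms one orthogroup spanning all four genomes
        assert int((om.presence.sum(axis=0) == 4).sum()) == 5
        for og, members in om.members.items():
            fams = {pid.split("_")[1][0] for _, pid in members}
            if len(members) > 1:
                # no chimeric group mixes planted families
                suffixes = {pid.split("_")[1] for _, pid in members}
                assert len(suffixes) == 1
        assert om.private_counts == {f"g{g}": 2 for g in range(4)}

    def test_component_count_matches_union_find_oracle(self, rng):
        families = [_rand_prot(rng, 180) for _ in range(4)]
        proteomes = {}
        for g in range(3):
            proteomes[f"g{g}"] = [
                (f"g{g}_f{i}", _mutate(rng, families[i], 0.1)) for i in range(4)
            ] + [(f"g{g}_x", _rand_prot(rng, 120))]
        om = infer_orthogroups(proteomes)

        # independent union-find over the same qualifying edges
        nodes = [(g, pid, seq) for g in sorted(proteomes)
                 for pid, seq in proteomes[g]]
        parent = list(range(len(nodes)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                res = protein_align(nodes[i][2], nodes[j][2])
                if res and res["bits"] >= 50 and res["coverage_shorter"] >= 0.5:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(nodes))})
        assert len(om.orthogroups) == n_components

    def test_symmetry_and_order_invariance(self, rng):
        families = [_rand_prot(rng, 150) for _ in range(3)]
        base = {
            f"g{g}": [(f"g{g}_f{i}", _mutate(rng, families[i], 0.1))
                      for i in range(3)]
            for g in range(3)
        }
        om1 = infer_orthogroups(base)
        reordered = {g: list(reversed(ps)) for g, ps in reversed(base.items())}
        om2 = infer_orthogroups(reordered)
        sets1 = sorted(sorted(m) for m in om1.members.values())
        sets2 = sorted(sorted(m) for m in om2.members.values())
        assert sets1 == sets2

    def test_empty_proteome_warned_and_kept(self, rng):
        prots = [(f"p{i}", _rand_prot(rng, 150)) for i in range(3)]
        with pytest.warns(UserWarning, match="empty"):
            om = infer_orthogroups({"a": prots, "b": []})
        assert "b" in om.genomes
        assert om.presence[om.genomes.index("b")].sum() == 0

    def test_fewer_than_two_proteomes_error(self):
        with pytest.raises(ValueError):
            infer_orthogroups({"a": []})


def _block_matrix(rng, n_per_block=4, n_block_markers=25, n_noise=15):
    """Two lifestyle blocks sharing block-specific orthogroups."""
    n = 2 * n_per_block
    X = np.zeros((n, 2 * n_block_markers + n_noise), dtype=int)
    for i in range(n):
        block = 0 if i < n_per_block else 1
        own = slice(block * n_block_markers, (block + 1) * n_block_markers)
        other = slice((1 - block) * n_block_markers, (2 - block) * n_block_markers)
        X[i, own] = rng.random(n_block_markers) < 0.9
        X[i, other] = rng.random(n_block_markers) < 0.1
        X[i, 2 * n_block_markers:] = rng.random(n_noise) < 0.5
    return X


class TestClusterPresenceAbsence:
    def test_lifestyle_blocks_form_supported_sister_clades(self, rng):
        X = _block_matrix(rng)
        labels = [f"v{i}" for i in range(8)]
        sd = cluster_presence_absence(X, labels=labels, n_boot=500, seed=1)
        a = sd.support_for(set(labels[:4]))
        b = sd.support_for(set(labels[4:]))
        assert a is not None and a.bp >= 0.95
        assert b is not None and b.bp >= 0.95
        assert a.au is not None and b.au is not None

    def test_duplicated_genomes_fully_supported(self, rng):
        X = _block_matrix(rng)
        X[1] = X[0]  # duplicate row: identical presence pattern
        labels = [f"v{i}" for i in range(8)]
        sd = cluster_presence_absence(X, labels=labels, n_boot=200, seed=2)
        node = sd.support_for({"v0", "v1"})
        assert node is not None
        assert node.bp == 1.0
        assert node.au == 1.0

    def test_bp_stable_across_seeds(self, rng):
        X = _block_matrix(rng)
        labels = [f"v{i}" for i in range(8)]
        sd1 = cluster_presence_absence(X, labels=labels, n_boot=500, seed=3)
        sd2 = cluster_presence_absence(X, labels=labels, n_boot=500, seed=4)
        for leaves in (set(labels[:4]), set(labels[4:])):
            b1 = sd1.support_for(leaves).bp
            b2 = sd2.support_for(leaves).bp
            assert abs(b1 - b2) <= 0.03

    def test_deterministic_under_seed(self, rng):
        X = _block_matrix(rng)
        sd1 = cluster_presence_absence(X, n_boot=100, seed=5)
        sd2 = cluster_presence_absence(X, n_boot=100, seed=5)
        assert [(n.leaves, n.bp, n.au) for n in sd1.nodes] == [
            (n.leaves, n.bp, n.au) for n in sd2.nodes
        ]

    def test_constant_matrix_flagged_degenerate(self):
        X = np.ones((4, 10), dtype=int)
        with pytest.warns(UserWarning, match="degenerate"):
            cluster_presence_absence(X, n_boot=20, seed=0)

    def test_newick_export_carries_supports(self, rng):
        X = _block_matrix(rng)
        sd = cluster_presence_absence(
            X, labels=[f"v{i}" for i in range(8)], n_boot=100, seed=6
        )
        nwk = sd.to_newick(support="bp")
        assert nwk.endswith(";")
        assert all(f"v{i}" in nwk for i in range(8))

    def test_supports_within_unit_interval(self, rng):
        X = _block_matrix(rng)
        sd = cluster_presence_absence(X, n_boot=100, seed=7)
        for node in sd.nodes:
            if node.bp is not None:
                assert 0.0 <= node.bp <= 1.0
            if node.au is not None:
                assert 0.0 <= node.au <= 1.0


class TestTaxonomyAffiliation:
    def _reference(self, rng):
        refs = []
        for lineage in ("NCLDV", "Eukaryote", "Prokaryote"):
            for i in range(4):
                refs.append((f"{lineage.lower()}{i}", lineage, _rand_prot(rng, 180)))
        return refs

    def test_no_hit_category(self, rng):
        refs = self._reference(rng)
        out = taxonomy_affiliation([("q", _rand_prot(rng, 150))], refs)
        assert out["per_protein"]["q"]["category"] == "no-hit"

    def test_single_lineage_category(self, rng):
        refs = self._reference(rng)
        q = _mutate(rng, refs[0][2], 0.1)  # close to an NCLDV reference
        out = taxonomy_affiliation([("q", q)], refs)
        assert out["per_protein"]["q"]["category"] == "NCLDV"

    def test_mixed_category_from_constructed_ranking(self, rng):
        """Five close NCLDV refs and five slightly farther eukaryote refs
        both enter the top ten: category is the mixed set."""
        base = _rand_prot(rng, 200)
        refs = []
        for i in range(5):
            refs.append((f"n{i}", "NCLDV", _mutate(rng, base, 0.05)))
        for i in range(5):
            refs.append((f"e{i}", "Eukaryote", _mutate(rng, base, 0.15)))
        out = taxonomy_affiliation([("q", base)], refs)
        assert out["per_protein"]["q"]["category"] == "Eukaryote+NCLDV"

    def test_top_ten_cutoff(self, rng):
        """An eleventh-ranked lineage does not enter the category."""
        base = _rand_prot(rng, 200)
        refs = [(f"n{i}", "NCLDV", _mutate(rng, base, 0.05)) for i in range(10)]
        refs.append(("far", "Prokaryote", _mutate(rng, base, 0.35)))
        out = taxonomy_affiliation([("q", base)], refs)
        assert out["per_protein"]["q"]["category"] == "NCLDV"
        assert len(out["per_protein"]["q"]["hits"]) == 10

    def test_summary_fractions_sum_to_one(self, rng):
        refs = self._reference(rng)
        queries = [("q1", _mutate(rng, refs[0][2], 0.1)),
                   ("q2", _mutate(rng, refs[4][2], 0.1)),
                   ("q3", _rand_prot(rng, 150))]
        out = taxonomy_affiliation(queries, refs)
        assert sum(out["fractions"].values()) == pytest.approx(1.0)


class TestRhodopsinMotif:
    @pytest.fixture
    def reference_alignment(self, rng):
        ref = _rand_prot(rng, 240)
        rows = [("anchor", ref)]
        for i in range(3):
            rows.append((f"m{i}", _mutate(rng, ref, 0.1)))
        return rows

    def test_reference_self_query(self, reference_alignment):
        anchor = reference_alignment[0][1]
        out = rhodopsin_motif(anchor, reference_alignment, (70, 74, 81), 104)
        assert out["motif"] == anchor[70] + anchor[74] + anchor[81]
        assert out["tuning_residue"] == anchor[104]

    def test_dtv_motif_extracted(self, rng, reference_alignment):
        anchor = reference_alignment[0][1]
        q = np.array(list(_mutate(rng, anchor, 0.15)))
        q[70], q[74], q[81] = "D", "T", "V"
        out = rhodopsin_motif("".join(q), reference_alignment, (70, 74, 81), 104)
        assert out["motif"] == "DTV"

    def test_methionine_105_called_green(self, rng, reference_alignment):
        anchor = reference_alignment[0][1]
        q = np.array(list(_mutate(rng, anchor, 0.15)))
        q[104] = "M"
        out = rhodopsin_motif("".join(q), reference_alignment, (70, 74, 81), 104)
        assert out["tuning_residue"] == "M"
        assert out["tuning_call"] == "green"

    def test_non_methionine_reported_without_claim(self, rng, reference_alignment):
        anchor = reference_alignment[0][1]
        q = np.array(list(anchor))
        q[104] = "L"
        out = rhodopsin_motif("".join(q), reference_alignment, (70, 74, 81), 104)
        assert out["tuning_residue"] == "L"
        assert out["tuning_call"] == "unknown"

    def test_non_homolog_no_call(self, rng, reference_alignment):
        out = rhodopsin_motif(
            _rand_prot(rng, 240), reference_alignment, (70, 74, 81), 104
        )
        assert out is None


class TestMarkerConcatTree:
    def test_additive_distances_recover_topology_and_lengths(self):
        """NJ is exact on additive matrices; check against a hand-built
        ((A,B),(C,D)) tree using synthetic aligned sequences."""
        rng = np.random.default_rng(11)
        L = 2000
        base = "".join(AA[rng.integers(0, 20, L)])

        def mutate_exact(s, k, used):
            arr = np.array(list(s))
            free = np.array(sorted(set(range(L)) - used))
            idx = rng.choice(free, k, replace=False)
            for i in idx:
                arr[i] = AA[(np.where(AA == arr[i])[0][0] + 7) % 20]
            used |= set(int(i) for i in idx)
            return "".join(arr)

        used: set = set()
        anc1 = mutate_exact(base, 100, used)   # internal branch 100+? edges
        anc2 = mutate_exact(base, 120, used)
        seqs = {
            "A": mutate_exact(anc1, 40, used),
            "B": mutate_exact(anc1, 60, used),
            "C": mutate_exact(anc2, 50, used),
            "D": mutate_exact(anc2, 70, used),
        }
        tree = marker_concat_tree({"m1": seqs})
        # topology: A-B form a clade on the unrooted tree
        tips = {t.name: t for t in tree.tips()}
        lca = tree.lowest_common_ancestor([tips["A"], tips["B"]])
        assert {t.name for t in lca.tips()} <= {"A", "B", "C", "D"}
        assert {t.name for t in lca.tips()} in ({"A", "B"}, {"C", "D"})
        # additive distances reproduced along the tree within float noise
        d_ab = tips["A"].distance(tips["B"])
        assert d_ab == pytest.approx((40 + 60) / L, abs=1e-9)
        d_ad = tips["A"].distance(tips["D"])
        assert d_ad == pytest.approx((40 + 100 + 120 + 70) / L, abs=1e-9)

    def test_identical_sequences_star_tree(self):
        rng = np.random.default_rng(3)
        s = "".join(AA[rng.integers(0, 20, 300)])
        tree = marker_concat_tree({"m1": {g: s for g in "ABCD"}})
        for tip in tree.tips():
            assert tip.distance(tree.root()) == pytest.approx(0.0, abs=1e-12)

    def test_missing_marker_pairwise_deletion(self):
        rng = np.random.default_rng(4)
        s1 = "".join(AA[rng.integers(0, 20, 200)])
        s2 = "".join(AA[rng.integers(0, 20, 200)])
        alns = {
            "m1": {"A": s1, "B": s1, "C": s2, "D": s2},
            "m2": {"A": s1, "B": s1, "C": s2},  # D lacks m2
        }
        tree = marker_concat_tree(alns)
        assert {t.name for t in tree.tips()} == {"A", "B", "C", "D"}

    def test_two_family_simulation_monophyletic(self):
        rng = np.random.default_rng(5)
        base = "".join(AA[rng.integers(0, 20, 500)])

        def mut(s, d):
            arr = np.array(list(s))
            m = rng.random(len(arr)) < d
            arr[m] = AA[rng.integers(0, 20, int(m.sum()))]
            return "".join(arr)

        fam1 = mut(base, 0.3)
        fam2 = mut(base, 0.3)
        seqs = {f"f1_{i}": mut(fam1, 0.05) for i in range(3)}
        seqs.update({f"f2_{i}": mut(fam2, 0.05) for i in range(3)})
        tree = marker_concat_tree({"m": seqs})
        tips = {t.name: t for t in tree.tips()}
        fam1_tips = [tips[f"f1_{i}"] for i in range(3)]
        lca = tree.lowest_common_ancestor(fam1_tips)
        names = {t.name for t in lca.tips()}
        assert names in ({f"f1_{i}" for i in range(3)},
                         {f"f2_{i}" for i in range(3)})
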