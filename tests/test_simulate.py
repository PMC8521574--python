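"""Synthetic-data generator: trees, codon evolution, planted signals, gaps."""

import json

import numpy as np
import pytest

from evosig.alignments import CodonAlignment
from evosig.simulate import (
    SimConfig,
    eligible_unique_columns,
    inject_gaps,
    plant_unique_substitutions,
    simulate_orthogroup,
    simulate_tree,
    write_fixture_set,
)
from evosig.unique_subs import find_unique_substitutions


class TestSimulateTree:
    def test_three_leaf_tree_structure(self):
        t = simulate_tree(3, seed=1, mean_depth=0.5)
        assert t.n_leaves == 3
        assert t.n_edges == 4
        for e in t._tree.preorder_edge_iter():
            if e.tail_node is not None:
                assert e.length > 0

    def test_seventeen_leaves_gives_32_branches(self):
        t = simulate_tree(17, seed=3, mean_depth=0.5)
        assert t.n_leaves == 17
        assert t.n_edges == 32

    def test_seeded_determinism_byte_identical(self):
        a = simulate_tree(9, seed=7).newick()
        b = simulate_tree(9, seed=7).newick()
        assert a == b
        c = simulate_tree(9, seed=8).newick()
        assert a != c

    def test_too_few_taxa_error(self):
        with pytest.raises(ValueError, match="too few taxa"):
            simulate_tree(2, seed=0)

    def test_outgroup_attached_at_root(self):
        t = simulate_tree(6, seed=5, outgroup="sp06")
        root_children = t._tree.seed_node.child_nodes()
        labels = [c.taxon.label for c in root_children if c.is_leaf()]
        assert "sp06" in labels

    def test_focal_lineage_joins_late(self):
        # the focal terminal branch should be long relative to typical tips
        t = simulate_tree(17, seed=2, focal="sp01", mean_depth=0.5)
        tips = {
            lf.taxon.label: lf.edge.length for lf in t._tree.leaf_node_iter()
        }
        others = [v for k, v in tips.items() if k not in ("sp01", "sp17")]
        assert tips["sp01"] > np.median(others)


class TestSimulateOrthogroup:
    def test_zero_length_tree_gives_identical_sequences(self):
        nwk = "((sp01:0.0,sp02:0.0):0.0,sp03:0.0);"
        cfg = SimConfig(
            n_species=3, n_codons=50, tree_source=nwk,
            focal_species="sp01", outgroup_species="sp03", seed=4,
        )
        codons, prot, truth = simulate_orthogroup(cfg)
        assert (codons.codons == codons.codons[0]).all()
        assert (prot.matrix == prot.matrix[0]).all()

    def test_neutral_event_count_matches_branch_length(self):
        # single neutral class, kappa=1, uniform frequencies, one branch of
        # length 0.5: mean substitution events per site within 5% of 0.5
        nwk = "((A:0.0,B:0.5):0.0,C:0.0);"
        cfg = SimConfig(
            n_species=3, n_codons=10000, tree_source=nwk, p0=0.0, p1=1.0,
            kappa=1.0, focal_species="A", outgroup_species="C", seed=11,
        )
        _, _, truth = simulate_orthogroup(cfg)
        mean_events = truth.branch_events["B"]["events"].mean()
        assert abs(mean_events - 0.5) / 0.5 < 0.05

    def test_selected_sites_accumulate_more_foreground_nonsyn(self):
        # under omega2 >> 1 the focal branch accumulates a larger share of
        # nonsynonymous events at 2a/2b sites than at class-0 sites
        cfg = SimConfig(
            n_species=6, n_codons=4000, omega2=8.0, p0=0.4, p1=0.2,
            focal_species="sp01", outgroup_species="sp06", seed=21,
        )
        _, _, truth = simulate_orthogroup(cfg)
        cls = np.array(truth.site_classes)
        ev = truth.branch_events["sp01"]
        sel = np.isin(cls, ["2a", "2b"])
        ns_sel = ev["nonsyn"][sel].mean()
        ns_c0 = ev["nonsyn"][cls == "0"].mean()
        assert ns_sel > ns_c0

    def test_truth_labels_cover_every_site(self):
        cfg = SimConfig(
            n_species=5, n_codons=120, omega2=1.0, seed=2,
            focal_species="sp01", outgroup_species="sp05",
        )
        codons, prot, truth = simulate_orthogroup(cfg)
        assert len(truth.site_classes) == 120
        assert set(truth.site_classes) <= {"0", "1", "2a", "2b"}
        # omega2=1: foreground and background identical in distribution, yet
        # 2a/2b labels are still recorded
        assert any(c in ("2a", "2b") for c in truth.site_classes)

    def test_translation_consistency(self):
        cfg = SimConfig(
            n_species=5, n_codons=80, seed=9, gap_rate=0.05,
            focal_species="sp01", outgroup_species="sp05",
        )
        codons, prot, _ = simulate_orthogroup(cfg)
        assert prot.matrix.shape == codons.codons.shape
        redo = codons.to_protein()
        assert (redo.matrix == prot.matrix).all()


class TestPlantedSubstitutions:
    def _invariant_alignment(self, n_taxa=17, n_cols=40):
        mat = np.full((n_taxa, n_cols), "A", dtype="<U1")
        return CodonAlignment(
            [f"t{i:02d}" for i in range(n_taxa)],
            np.full((n_taxa, n_cols), 8, dtype=np.int16),  # all same codon
        )

    def test_zero_sites_is_identity(self):
        aln = self._invariant_alignment()
        out, cols = plant_unique_substitutions(aln, "t00", 0, seed=1)
        assert (out.codons == aln.codons).all()
        assert len(cols) == 0

    def test_planting_on_invariant_alignment(self):
        aln = self._invariant_alignment()
        out, cols = plant_unique_substitutions(aln, "t00", 5, seed=1)
        assert len(cols) == 5
        prot = out.to_protein()
        fi = prot.taxa.index("t00")
        for c in cols:
            col = prot.matrix[:, c]
            others = np.delete(col, fi)
            assert len(set(others)) == 1
            assert col[fi] != others[0]

    def test_insufficient_columns_error_names_shortfall(self):
        aln = self._invariant_alignment(n_cols=3)
        with pytest.raises(ValueError, match="need 10, found 3"):
            plant_unique_substitutions(aln, "t00", 10, seed=0)

    def test_detector_recovers_exactly_the_planted_set(self):
        cfg = SimConfig(
            n_species=10, n_codons=200, n_planted_unique_sites=6, seed=33,
            focal_species="sp01", outgroup_species="sp10",
        )
        codons, prot, truth = simulate_orthogroup(cfg, None)
        calls = find_unique_substitutions(prot, "sp01", flank=10)
        called = {c.column - 1 for c in calls}
        # every planted column must be recovered; extra natural unique
        # substitutions may also exist, so check against the eligible truth
        assert set(truth.planted_columns) <= called
        # and every call satisfies the uniqueness predicate
        fi = prot.taxa.index("sp01")
        for c in calls:
            col = prot.matrix[:, c.column - 1]
            others = np.delete(col, fi)
            assert len(set(others)) == 1 and col[fi] != others[0]


class TestInjectGaps:
    def test_zero_rate_is_identity(self, rng):
        aln = self._random_codon_alignment(rng)
        out = inject_gaps(aln, 0.0, seed=3)
        assert (out.codons == aln.codons).all()

    def test_full_protection_is_identity(self, rng):
        aln = self._random_codon_alignment(rng)
        out = inject_gaps(aln, 0.5, seed=3, protect_columns=range(aln.width))
        assert (out.codons == aln.codons).all()

    def test_gap_count_within_three_sigma_of_binomial(self, rng):
        aln = self._random_codon_alignment(rng, n_taxa=10, n_cols=1000)
        out = inject_gaps(aln, 0.1, seed=5)
        n_gapped = int((out.codons == -1).sum())
        n, p = 10 * 1000, 0.1
        sd = np.sqrt(n * p * (1 - p))
        assert abs(n_gapped - n * p) < 3 * sd

    @staticmethod
    def _random_codon_alignment(rng, n_taxa=6, n_cols=50):
        return CodonAlignment(
            [f"t{i}" for i in range(n_taxa)],
            rng.integers(0, 61, size=(n_taxa, n_cols)).astype(np.int16),
        )


class TestFixtureSet(object):
    def _configs(self, n=3):
        return [
            SimConfig(
                n_species=5, n_codons=30, seed=100 + i,
                focal_species="sp01", outgroup_species="sp05",
            )
            for i in range(n)
        ]

    def test_manifest_counts_and_roundtrip(self, tmp_path):
        manifest = write_fixture_set(self._configs(), tmp_path / "fx", tree_seed=1)
        assert len(manifest["orthogroups"]) == 3
        for og, files in manifest["orthogroups"].items():
            assert set(files) == {"protein", "cds", "gene_tree", "truth"}
            for f in files.values():
                assert (tmp_path / "fx" / f).exists()
        # FASTA round trip reproduces the in-memory sequences
        from evosig.alignments import ProteinAlignment

        og = sorted(manifest["orthogroups"])[0]
        aln = ProteinAlignment.from_fasta(
            tmp_path / "fx" / manifest["orthogroups"][og]["protein"]
        )
        assert aln.n_taxa == 5
        truth = json.loads(
            (tmp_path / "fx" / manifest["orthogroups"][og]["truth"]).read_text()
        )
        assert len(truth["site_classes"]) == 30

    def test_rerun_is_byte_identical(self, tmp_path):
        import hashlib

        def checksums(d):
            return {
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(d.iterdir())
            }

        write_fixture_set(self._configs(), tmp_path / "a", tree_seed=1)
        write_fixture_set(self._configs(), tmp_path / "b", tree_seed=1)
        assert checksums(tmp_path / "a") == checksums(tmp_path / "b")


def test_eligible_columns_requires_focal_taxon():
    aln = CodonAlignment(["a", "b", "c"], np.full((3, 5), 2, dtype=np.int16))
    with pytest.raises(ValueError, match="not in alignment"):
        eligible_unique_columns(aln, "zz")
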