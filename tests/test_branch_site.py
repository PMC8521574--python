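"""Codon threading, the pruning likelihood, the LRT and FDR machinery."""

import numpy as np
import pytest

from evosig.alignments import CodonAlignment, ProteinAlignment, thread_codons
from evosig.branch_site import (
    BranchSiteModel,
    BranchSiteParams,
    BranchSiteResults,
    bh_fdr,
    lrt_pvalue,
    selection_signature,
)
from evosig.codons import CODON_INDEX, uniform_frequencies
from evosig.simulate import SimConfig, simulate_orthogroup
from evosig.trees import PhyloTree

from _oracles import (
    brute_bh,
    enumeration_site_loglike,
    literal_enumeration_loglike,
)
from conftest import EIGHT_TAXON_NEWICK


class TestThreading:
    def test_direct_translation(self):
        prot = ProteinAlignment(["x"], np.array([list("MA")], dtype="<U1"))
        ca = thread_codons(prot, {"x": "ATGGCT"})
        assert [int(c) for c in ca.codons[0]] == [
            CODON_INDEX["ATG"], CODON_INDEX["GCT"],
        ]

    def test_gap_propagation(self):
        prot = ProteinAlignment(["x"], np.array([list("M-A")], dtype="<U1"))
        ca = thread_codons(prot, {"x": "ATGGCT"})
        assert int(ca.codons[0, 1]) == -1
        assert int(ca.codons[0, 0]) == CODON_INDEX["ATG"]

    def test_terminal_stop_stripped(self):
        prot = ProteinAlignment(["x"], np.array([list("MA")], dtype="<U1"))
        ca = thread_codons(prot, {"x": "ATGGCTTAA"})
        assert ca.width == 2

    def test_internal_stop_is_an_error(self):
        prot = ProteinAlignment(["x"], np.array([list("M*A")], dtype="<U1"))
        with pytest.raises(ValueError, match="stop"):
            thread_codons(prot, {"x": "ATGTAAGCT"})

    def test_translation_mismatch_names_taxon_and_position(self):
        prot = ProteinAlignment(["x"], np.array([list("MK")], dtype="<U1"))
        with pytest.raises(ValueError, match="'x' at protein column 2"):
            thread_codons(prot, {"x": "ATGGCT"})


def single_column_model(newick, states, focal, pi=None):
    tree = PhyloTree.from_newick(newick)
    taxa = sorted(states)
    ca = CodonAlignment(
        taxa, np.array([[states[t]] for t in taxa], dtype=np.int16)
    )
    return BranchSiteModel(
        ca, tree, focal, frequencies=pi if pi is not None else "uniform"
    )


class TestPruningEngine:
    def test_zero_time_two_leaves_same_codon_gives_log_pi(self):
        c = CODON_INDEX["ATG"]
        m = single_column_model("(A:0.0,B:0.0);", {"A": c, "B": c}, "A")
        ll = m._prune(2.0, 0.5)[0]
        assert ll[0] == pytest.approx(np.log(1.0 / 61.0), abs=1e-12)

    def test_all_gap_column_has_likelihood_one(self):
        m = single_column_model(
            "((A:0.1,B:0.2):0.1,C:0.3);", {"A": -1, "B": -1, "C": -1}, "A"
        )
        assert m._prune(2.0, 0.5)[0][0] == pytest.approx(0.0, abs=1e-12)

    def test_literal_enumeration_three_taxa(self):
        # every internal-state assignment summed in a plain python loop
        rng = np.random.default_rng(5)
        tree = PhyloTree.from_newick("((A:0.21,B:0.09):0.12,C:0.33);")
        pi = uniform_frequencies()
        for _ in range(3):
            states = {t: int(rng.integers(0, 61)) for t in "ABC"}
            m = single_column_model(
                "((A:0.21,B:0.09):0.12,C:0.33);", states, "A"
            )
            mine = m._prune(1.8, 0.4)[0][0]
            ref = literal_enumeration_loglike(tree, states, 1.8, 0.4, pi)
            assert mine == pytest.approx(ref, rel=1e-10)

    def test_exhaustive_enumeration_with_foreground_branch(self):
        rng = np.random.default_rng(17)
        nwk = "(((F:0.15,A:0.21):0.08,B:0.3):0.05,(C:0.12,D:0.22):0.09);"
        tree = PhyloTree.from_newick(nwk)
        pi = uniform_frequencies()
        for _ in range(5):
            states = {t: int(rng.integers(0, 61)) for t in "FABCD"}
            if rng.random() < 0.3:
                states["B"] = -1  # a gap leaf
            m = single_column_model(nwk, states, "F")
            mine = m._reprune_foreground(2.3, 0.25, 6.0)[0]
            ref = enumeration_site_loglike(
                tree, states, 2.3, 0.25, 6.0, pi, "F"
            )
            assert mine == pytest.approx(ref, rel=1e-9)


@pytest.fixture(scope="module")
def small_fit_data():
    cfg = SimConfig(
        n_species=8, n_codons=120, omega2=5.0, seed=77,
        tree_source=EIGHT_TAXON_NEWICK,
        focal_species="F", outgroup_species="OG",
    )
    ca, _, truth = simulate_orthogroup(
        cfg, PhyloTree.from_newick(EIGHT_TAXON_NEWICK, outgroup="OG")
    )
    tree = PhyloTree.from_newick(EIGHT_TAXON_NEWICK, outgroup="OG")
    return ca, tree


class TestModelLikelihood:
    def test_alt_with_omega2_one_equals_null(self, small_fit_data):
        ca, tree = small_fit_data
        m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
        p_alt = BranchSiteParams(kappa=2.0, omega0=0.3, p0=0.6, p1=0.2, omega2=1.0)
        # identical parameters, omega2 pinned at 1: same likelihood
        ll_alt = m.loglike(p_alt)
        ll_null = m.loglike(
            BranchSiteParams(kappa=2.0, omega0=0.3, p0=0.6, p1=0.2, omega2=1.0)
        )
        assert ll_alt == pytest.approx(ll_null, abs=1e-12)

    def test_pattern_compression_is_invisible(self, small_fit_data):
        ca, tree = small_fit_data
        m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
        p = BranchSiteParams(kappa=2.0, omega0=0.3, p0=0.6, p1=0.2, omega2=3.0)
        # per-column evaluation via the pattern map must reproduce loglike
        class_ll = m._class_loglikes(p)
        per_pattern = m._mix(p, class_ll)
        per_column = per_pattern[m._pattern_of_column]
        assert per_column.sum() == pytest.approx(m.loglike(p), rel=1e-12)

    def test_mixture_loglike_matches_per_site_bruteforce(self):
        # independent oracle: per-class enumeration + explicit mixture
        nwk = "(((F:0.15,A:0.21):0.08,B:0.3):0.05,(C:0.12,D:0.22):0.09);"
        tree = PhyloTree.from_newick(nwk)
        cfg = SimConfig(
            n_species=5, n_codons=30, omega2=4.0, seed=3, tree_source=nwk,
            focal_species="F", outgroup_species="D",
        )
        ca, _, _ = simulate_orthogroup(cfg, tree)
        m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
        p = BranchSiteParams(kappa=1.9, omega0=0.35, p0=0.5, p1=0.3, omega2=4.0)
        pi = uniform_frequencies()
        props = p.proportions()
        class_omegas = [(0.35, 0.35), (1.0, 1.0), (0.35, 4.0), (1.0, 4.0)]
        total = 0.0
        for col in range(ca.width):
            states = {t: int(ca.codons[ca.taxa.index(t), col]) for t in ca.taxa}
            site = 0.0
            for w, (bg, fg) in zip(props, class_omegas):
                site += w * np.exp(
                    enumeration_site_loglike(tree, states, 1.9, bg, fg, pi, "F")
                )
            total += np.log(site)
        assert m.loglike(p) == pytest.approx(total, rel=1e-8)

    def test_loglike_invariant_to_root_position(self):
        # reversible model: moving the root along a background branch
        # (rerooting on the outgroup) leaves the likelihood unchanged
        nwk = "((F:0.2,A:0.1):0.05,(B:0.1,OG:0.3):0.05);"
        t1 = PhyloTree.from_newick(nwk)
        t2 = PhyloTree.from_newick(nwk, outgroup="OG").rerooted_on_outgroup()
        cfg = SimConfig(
            n_species=4, n_codons=40, seed=8, tree_source=nwk,
            focal_species="F", outgroup_species="OG",
        )
        ca, _, _ = simulate_orthogroup(cfg, t1)
        p = BranchSiteParams(kappa=2.0, omega0=0.2, p0=0.7, p1=0.2, omega2=3.0)
        l1 = BranchSiteModel(ca, t1, "F", frequencies="uniform").loglike(p)
        l2 = BranchSiteModel(ca, t2, "F", frequencies="uniform").loglike(p)
        assert l1 == pytest.approx(l2, rel=1e-10)


class TestFitting:
    def test_nesting_and_determinism(self, small_fit_data):
        ca, tree = small_fit_data
        m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
        res = m.fit(seed=5)
        assert res.lnl_alt >= res.lnl_null - 1e-6
        res2 = BranchSiteModel(ca, tree, "F", frequencies="uniform").fit(seed=5)
        assert res.lnl_alt == res2.lnl_alt
        assert res.lnl_null == res2.lnl_null
        assert res.params_alt == res2.params_alt

    def test_null_data_pushes_omega2_to_lower_bound(self):
        # fitting the alternative to data generated without selection should
        # park omega2 at its bound 1 in at least half the replicates
        tree = PhyloTree.from_newick(EIGHT_TAXON_NEWICK, outgroup="OG")
        at_bound = 0
        n = 10
        for seed in range(n):
            cfg = SimConfig(
                n_species=8, n_codons=200, omega2=1.0, seed=900 + seed,
                tree_source=EIGHT_TAXON_NEWICK,
                focal_species="F", outgroup_species="OG",
            )
            ca, _, _ = simulate_orthogroup(cfg, tree)
            m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
            res = m.fit(seed=seed)
            at_bound += res.params_alt.omega2 < 1.0 + 1e-3
        assert at_bound >= n // 2

    def test_summary_renders(self, small_fit_data):
        ca, tree = small_fit_data
        res = BranchSiteModel(ca, tree, "F", frequencies="uniform").fit(seed=0)
        text = res.summary()
        assert "lnL(alt)" in text and "foreground lineage : F" in text


class TestLRT:
    def test_zero_statistic_gives_p_one(self):
        stat, p = lrt_pvalue(-100.0, -100.0)
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("stat,expected", [(3.841, 0.05), (6.635, 0.01)])
    def test_chi2_reference_points(self, stat, expected):
        _, p = lrt_pvalue(-100.0, -100.0 - stat / 2.0)
        assert p == pytest.approx(expected, abs=1e-3)

    def test_violated_nesting_raises(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-101.0, -100.0)

    def test_mixture_reference_halves_the_tail(self):
        _, p_plain = lrt_pvalue(-100.0, -102.0)
        _, p_mix = lrt_pvalue(-100.0, -102.0, mixture=True)
        assert p_mix == pytest.approx(p_plain / 2.0)


class TestBH:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_bruteforce_stepup(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(bh_fdr(p), brute_bh(p), atol=1e-12)


class TestPosteriors:
    def test_no_selected_mass_means_zero_posteriors(self, small_fit_data):
        ca, tree = small_fit_data
        m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
        p = BranchSiteParams(kappa=2.0, omega0=0.3, p0=0.7, p1=0.3, omega2=2.0)
        post = m.site_posteriors(p)
        assert np.allclose(post, 0.0)

    def test_class_posteriors_normalise(self, small_fit_data):
        ca, tree = small_fit_data
        m = BranchSiteModel(ca, tree, "F", frequencies="uniform")
        p = BranchSiteParams(kappa=2.0, omega0=0.3, p0=0.6, p1=0.2, omega2=4.0)
        w = m.class_posteriors(p)
        assert w.shape == (4, ca.width)
        assert np.allclose(w.sum(axis=0), 1.0, atol=1e-10)


def _result(pvalue, selected):
    return BranchSiteResults(
        model=None, params_alt=None, params_null=None, lnl_alt=0.0,
        lnl_null=0.0, statistic=0.0, pvalue=pvalue, site_posteriors=None,
        selected_sites=selected, posterior_cutoff=0.95, converged=True,
    )


class TestSelectionSignature:
    def test_requires_both_fdr_and_high_posterior_site(self):
        results = [
            _result(0.001, [12]),   # q small, site present -> flagged
            _result(0.002, []),     # q small, no site -> not flagged
            _result(0.9, [5, 9]),   # q large -> not flagged
        ]
        flags = selection_signature(results, fdr=0.05)
        assert flags == [True, False, False]
        assert all(r.qvalue is not None for r in results)
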