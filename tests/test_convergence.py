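import numpy as np
import pytest

import convscan as cs
from convscan.alphabet import AMINO_ACIDS
from convscan.ancestry import reconstruct
from convscan.convergence import (
    ScanOptions,
    SkippedGene,
    bh_fdr,
    detect_observed_sites,
    expected_site_lambda,
    gene_lambda,
    poisson_upper_tail,
    scan_gene,
    scan_gene_set,
)
from convscan.phylo_io import Alignment, FocalClade, PhyloTree, resolve_focal
from convscan.subst_model import build_rate_model, estimate_gene_frequencies


def _ai(x):
    return AMINO_ACIDS.index(x)


@pytest.fixture
def four_clade_tree():
    # two focal cherries (X: A1,A2 and Y: B1,B2); the zero-length background
    # tips C and D pin the reconstructed state of each focal parent exactly
    return PhyloTree.from_newick(
        "(((A1:0.05,A2:0.05):0.1,C:0.0):0.05,((B1:0.05,B2:0.05):0.1,D:0.0):0.05);"
    )


@pytest.fixture
def two_clades():
    return [FocalClade("x", ("A1", "A2")), FocalClade("y", ("B1", "B2"))]


def _recon_for(tree, seqs, model=None):
    aln = Alignment.from_sequences("g", seqs)
    if model is None:
        S = cs.jtt_exchangeabilities()
        model = build_rate_model(S, estimate_gene_frequencies(aln))
    return reconstruct(tree, aln, model), model


class TestDetectObservedSites:
    def test_divergent_origin_call(self, four_clade_tree, two_clades):
        # focal tips share A; background L and S pull the two focal-parent
        # reconstructions toward different residues
        seqs = {
            "A1": "A", "A2": "A", "B1": "A", "B2": "A", "C": "L", "D": "S",
        }
        recon, _ = _recon_for(four_clade_tree, seqs)
        focal = resolve_focal(four_clade_tree, two_clades)
        calls, n_used = detect_observed_sites(recon, focal)
        assert n_used == 1
        assert len(calls) == 1
        assert calls[0].target == "A"
        assert all(a != "A" for a in calls[0].ancestors)

    def test_parallel_call_subtype(self, four_clade_tree, two_clades):
        seqs = {"A1": "A", "A2": "A", "B1": "A", "B2": "A", "C": "S", "D": "S"}
        recon, _ = _recon_for(four_clade_tree, seqs)
        focal = resolve_focal(four_clade_tree, two_clades)
        calls, _ = detect_observed_sites(recon, focal)
        assert len(calls) == 1
        assert calls[0].parallel and calls[0].subtype == "parallel"

    def test_discordant_descendants_no_call(self, four_clade_tree, two_clades):
        seqs = {"A1": "A", "A2": "A", "B1": "V", "B2": "V", "C": "S", "D": "S"}
        recon, _ = _recon_for(four_clade_tree, seqs)
        focal = resolve_focal(four_clade_tree, two_clades)
        calls, _ = detect_observed_sites(recon, focal)
        assert calls == []

    def test_missing_focal_data_excluded(self, four_clade_tree, two_clades):
        # both focal cherries all-gap: the site cannot enter the test
        seqs = {"A1": "-", "A2": "-", "B1": "-", "B2": "-", "C": "S", "D": "S"}
        recon, _ = _recon_for(four_clade_tree, seqs)
        focal = resolve_focal(four_clade_tree, two_clades)
        calls, n_used = detect_observed_sites(recon, focal)
        assert calls == [] and n_used == 0


class TestExpectedSiteLambda:
    def test_zero_branch_lengths_give_zero(self, jtt_model):
        lam = expected_site_lambda([_ai("L"), _ai("S")], [0.0, 0.0], jtt_model)
        assert lam == 0.0

    def test_two_state_toy_is_q_squared(self, two_state_model):
        # both ancestors in state 0; the only convergent target is state 1
        t = 0.3
        q = two_state_model.transition_matrix(t)[0, 1]
        lam = expected_site_lambda([0, 0], [t, t], two_state_model)
        assert lam == pytest.approx(q * q, abs=1e-14)

    def test_ergodic_limit(self, jtt_model):
        # t -> inf: lambda -> sum over a not in {x1, x2} of pi[a]^2
        x1, x2 = _ai("L"), _ai("S")
        lam = expected_site_lambda([x1, x2], [500.0, 500.0], jtt_model)
        pi = jtt_model.pi.pi
        expect = sum(pi[a] ** 2 for a in range(20) if a not in (x1, x2))
        assert lam == pytest.approx(expect, rel=1e-8)

    def test_requires_two_branches(self, jtt_model):
        with pytest.raises(ValueError):
            expected_site_lambda([0], [0.1], jtt_model)


class TestGeneLambda:
    def test_single_site_matches_site_lambda(self, four_clade_tree, two_clades, jtt_model):
        seqs = {"A1": "A", "A2": "A", "B1": "V", "B2": "V", "C": "S", "D": "S"}
        recon, _ = _recon_for(four_clade_tree, seqs, jtt_model)
        focal = resolve_focal(four_clade_tree, two_clades)
        lam = gene_lambda(recon, focal, jtt_model)
        x = [recon.map_states[recon.node_index(n.parent_node), 0] for n in focal.nodes]
        site_lam = expected_site_lambda(x, focal.branch_lengths(), jtt_model)
        assert lam == pytest.approx(site_lam, abs=1e-14)

    def test_all_excluded_gives_zero(self, four_clade_tree, two_clades, jtt_model):
        seqs = {"A1": "-", "A2": "-", "B1": "-", "B2": "-", "C": "S", "D": "S"}
        recon, _ = _recon_for(four_clade_tree, seqs, jtt_model)
        focal = resolve_focal(four_clade_tree, two_clades)
        assert gene_lambda(recon, focal, jtt_model) == 0.0

    def test_additive_over_column_blocks(self, four_clade_tree, two_clades, jtt_model):
        rng = np.random.default_rng(3)
        cols = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 6)) for _ in range(8)]
        taxa = ("A1", "A2", "B1", "B2", "C", "D")
        seqs_full = {t: "".join(c[i] for c in cols) for i, t in enumerate(taxa)}
        recon, _ = _recon_for(four_clade_tree, seqs_full, jtt_model)
        focal = resolve_focal(four_clade_tree, two_clades)
        lam_full = gene_lambda(recon, focal, jtt_model)
        lam_parts = 0.0
        for c in cols:
            seqs = {t: c[i] for i, t in enumerate(taxa)}
            r, _ = _recon_for(four_clade_tree, seqs, jtt_model)
            lam_parts += gene_lambda(r, focal, jtt_model)
        assert lam_full == pytest.approx(lam_parts, rel=1e-10)

    def test_posterior_integrated_close_to_plugin_when_certain(
        self, four_clade_tree, two_clades, jtt_model
    ):
        seqs = {"A1": "A", "A2": "A", "B1": "A", "B2": "A", "C": "S", "D": "S"}
        recon, _ = _recon_for(four_clade_tree, seqs, jtt_model)
        focal = resolve_focal(four_clade_tree, two_clades)
        plug = gene_lambda(recon, focal, jtt_model)
        integ = gene_lambda(recon, focal, jtt_model, posterior_integrated=True)
        assert integ == pytest.approx(plug, rel=0.5)


class TestPoissonUpperTail:
    def test_k_zero_is_one(self):
        assert poisson_upper_tail(0, 5.0) == 1.0
        assert poisson_upper_tail(0, 0.0) == 1.0

    def test_lambda_one_k_three_closed_form(self):
        # 1 - e^{-1} (1 + 1 + 1/2)
        assert poisson_upper_tail(3, 1.0) == pytest.approx(
            1 - 2.5 * np.exp(-1), abs=1e-12
        )

    def test_degenerate_lambda_zero(self):
        assert poisson_upper_tail(1, 0.0) == 0.0


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_output_order_matches_input(self):
        q = bh_fdr([0.5, 0.001, 0.2])
        assert q[1] == min(q)

    def test_sorted_q_nondecreasing(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestScanGene:
    def test_short_gene_skipped_min_len(self, rodent_tree, rodent_clades, jtt_model):
        gene = cs.simulate_gene(rodent_tree, jtt_model, 25, 9)
        res = scan_gene(gene.alignment, rodent_tree, rodent_clades)
        assert isinstance(res, SkippedGene) and res.reason == "min_len"

    def test_thirty_residue_gene_scanned(self, rodent_tree, rodent_clades, jtt_model):
        gene = cs.simulate_gene(rodent_tree, jtt_model, 30, 9)
        res = scan_gene(gene.alignment, rodent_tree, rodent_clades)
        assert not isinstance(res, SkippedGene)
        assert res.n_sites_used == 30

    def test_missing_focal_taxon_policy(self, rodent_tree, rodent_clades, jtt_model):
        gene = cs.simulate_gene(rodent_tree, jtt_model, 40, 9)
        seqs = {t: gene.alignment.sequence(t) for t in gene.alignment.taxa if t != "Prob"}
        aln = Alignment.from_sequences("g", seqs)
        res = scan_gene(aln, rodent_tree, rodent_clades)
        assert isinstance(res, SkippedGene) and res.reason == "missing_focal_taxon"

    def test_background_taxon_pruned_vs_skipped(self, rodent_tree, rodent_clades, jtt_model):
        gene = cs.simulate_gene(rodent_tree, jtt_model, 40, 9)
        seqs = {t: gene.alignment.sequence(t) for t in gene.alignment.taxa if t != "Hgla"}
        aln = Alignment.from_sequences("g", seqs)
        res = scan_gene(aln, rodent_tree, rodent_clades)
        assert not isinstance(res, SkippedGene)
        res2 = scan_gene(
            aln, rodent_tree, rodent_clades, ScanOptions(missing_taxon_policy="skip")
        )
        assert isinstance(res2, SkippedGene) and res2.reason == "missing_taxon"

    def test_forced_sites_detected(self, rodent_tree, rodent_clades, jtt_model):
        rng = np.random.default_rng(15)
        gene = cs.simulate_gene(rodent_tree, jtt_model, 300, rng)
        gene = cs.inject_convergence(
            gene, rodent_clades, "forced-substitution", 5, rng, jtt_model
        )
        res = scan_gene(gene.alignment, rodent_tree, rodent_clades)
        # plug-in MAP ancestors can absorb a forced site when the focal
        # parent's reconstruction is pulled to the target, so require a
        # clear majority recovered rather than all five
        assert res.k_observed >= 3
        assert res.p_value < 1e-6

    def test_all_gap_focal_descendants(self, rodent_tree, rodent_clades, jtt_model):
        gene = cs.simulate_gene(rodent_tree, jtt_model, 40, 9)
        focal_tips = {"Prob", "Mmer", "Mung", "Dsag", "Osib", "Jjac"}
        seqs = {
            t: ("-" * 40 if t in focal_tips else gene.alignment.sequence(t))
            for t in gene.alignment.taxa
        }
        aln = Alignment.from_sequences("g", seqs)
        res = scan_gene(aln, rodent_tree, rodent_clades)
        assert res.k_observed == 0
        assert res.lambda_expected == 0.0
        assert res.p_value == 1.0


class TestScanGeneSet:
    def test_q_values_and_significance(self, rodent_tree, rodent_clades, jtt_model):
        rng = np.random.default_rng(30)
        genes = []
        for i in range(5):
            g = cs.simulate_gene(rodent_tree, jtt_model, 60, 200 + i, gene_id=f"g{i}")
            genes.append(g.alignment)
        results, skips = scan_gene_set(genes, rodent_tree, rodent_clades)
        assert len(results) == 5 and not skips
        q = bh_fdr([r.p_value for r in results])
        assert np.allclose([r.q_value for r in results], q)
        for r in results:
            assert r.significant == (r.p_value < 0.05 and r.q_value < 0.05)

    def test_single_gene_q_equals_p(self, rodent_tree, rodent_clades, jtt_model):
        g = cs.simulate_gene(rodent_tree, jtt_model, 60, 5, gene_id="g0")
        results, _ = scan_gene_set([g.alignment], rodent_tree, rodent_clades)
        assert results[0].q_value == pytest.approx(results[0].p_value)

    def test_zero_scannable_genes_errors(self, rodent_tree, rodent_clades, jtt_model):
        g = cs.simulate_gene(rodent_tree, jtt_model, 10, 5)
        with pytest.raises(ValueError):
            scan_gene_set([g.alignment], rodent_tree, rodent_clades)

    def test_pairwise_two_clades_matches_allmatch(self, jtt_model, four_clade_tree, two_clades):
        rng = np.random.default_rng(31)
        genes = []
        for i in range(4):
            g = cs.simulate_gene(four_clade_tree, jtt_model, 50, 300 + i, gene_id=f"g{i}")
            genes.append(g.alignment)
        res_all, _ = scan_gene_set(genes, four_clade_tree, two_clades, mode="allmatch")
        res_pw, _ = scan_gene_set(genes, four_clade_tree, two_clades, mode="pairwise")
        for a, b in zip(res_all, res_pw):
            assert a.k_observed == b.k_observed
            assert a.p_value == pytest.approx(b.p_value)

    def test_column_order_invariance_of_lambda(self, rodent_tree, rodent_clades, jtt_model):
        g = cs.simulate_gene(rodent_tree, jtt_model, 50, 8)
        aln = g.alignment
        perm = np.random.default_rng(0).permutation(50)
        shuffled = Alignment(aln.gene_id, aln.taxa, aln.states[:, perm])
        r1 = scan_gene(aln, rodent_tree, rodent_clades)
        r2 = scan_gene(shuffled, rodent_tree, rodent_clades)
        assert r1.lambda_expected == pytest.approx(r2.lambda_expected, rel=1e-12)
        assert r1.k_observed == r2.k_observed
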