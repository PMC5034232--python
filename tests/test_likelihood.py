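"""Pruning likelihood against exhaustive enumeration, and site-model fits."""

import numpy as np
import pytest
from scipy.linalg import expm

from primex.codon import (
    CODON_INDEX,
    N_CODONS,
    build_unnormalized_rate_matrix,
    site_class_distribution,
    uniform_codon_frequencies,
)
from primex.io import parse_newick
from primex.likelihood import (
    GeneLikelihood,
    fit_m0,
    fit_site_model,
    log_likelihood,
    lrt_m7_m8,
)
from primex.qc import CodonAlignment
from primex.simulate import SimulationSpec, simulate_codon_alignment


def _normalized_q(kappa, omega_values, weights, pi):
    """Mixture-scaled rate matrices, independently of the engine's caching."""
    qs = [build_unnormalized_rate_matrix(kappa, w, pi) for w in omega_values]
    rates = [-pi @ np.diag(q) for q in qs]
    R = float(np.dot(weights, rates))
    return [q / R for q in qs]


def _exhaustive_lnl_star3(aln, lengths, kappa, values, weights, pi):
    """Brute-force likelihood of a 3-taxon star: sum over the single
    internal node's 61 states with expm transition matrices."""
    qs = _normalized_q(kappa, values, weights, pi)
    states = [[CODON_INDEX[s[3 * i : 3 * i + 3]] for i in range(len(s) // 3)] for s in aln.sequences]
    total = 0.0
    for site in range(len(states[0])):
        site_lik = 0.0
        for c, q in enumerate(qs):
            Ps = [expm(q * t) for t in lengths]
            lik = sum(
                pi[x] * np.prod([Ps[k][x, states[k][site]] for k in range(3)])
                for x in range(N_CODONS)
            )
            site_lik += weights[c] * lik
        total += np.log(site_lik)
    return total


class TestPruningOracle:
    def test_two_taxa_zero_branches_single_site(self):
        """No evolution: the likelihood is just the root codon frequency."""
        aln = CodonAlignment(taxa=["A", "B"], sequences=["AAA", "AAA"])
        tree = parse_newick("(A:0.0,B:0.0);")
        lnl = log_likelihood(aln, tree, [0.5], [1.0], 2.0, uniform_codon_frequencies())
        assert lnl == pytest.approx(np.log(1 / 61), abs=1e-9)

    def test_three_taxon_star_matches_enumeration(self):
        """Pruning equals exhaustive summation over internal-node states."""
        aln = CodonAlignment(
            taxa=["A", "B", "C"],
            sequences=["ATGAAACCCGGGTTT", "ATGAAGCCCGGGTTT", "ATGAAACCAGGGTTA"],
        )
        tree = parse_newick("(A:0.2,B:0.3,C:0.1);")
        pi = uniform_codon_frequencies()
        values, weights = site_class_distribution("M7", p=0.5, q=1.5, ncat=4)
        got = log_likelihood(aln, tree, values, weights, 2.0, pi)
        expected = _exhaustive_lnl_star3(aln, [0.2, 0.3, 0.1], 2.0, values, weights, pi)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_four_taxon_tree_matches_enumeration(self):
        """Two internal nodes: 61^2 enumeration over ancestral states."""
        aln = CodonAlignment(
            taxa=["A", "B", "C", "D"],
            sequences=["ATGAAACCC", "ATGAAGCCC", "ATGAAACCA", "ATGTACCCA"],
        )
        t = {"A": 0.15, "B": 0.05, "C": 0.2, "D": 0.1, "AB": 0.12}
        tree = parse_newick(f"((A:{t['A']},B:{t['B']}):{t['AB']},C:{t['C']},D:{t['D']});")
        pi = uniform_codon_frequencies()
        values, weights = np.array([0.1, 1.5]), np.array([0.6, 0.4])
        got = log_likelihood(aln, tree, values, weights, 1.7, pi)

        qs = _normalized_q(1.7, values, weights, pi)
        states = [
            [CODON_INDEX[s[3 * i : 3 * i + 3]] for i in range(3)] for s in aln.sequences
        ]
        expected = 0.0
        for site in range(3):
            site_lik = 0.0
            for c, q in enumerate(qs):
                P = {k: expm(q * v) for k, v in t.items()}
                a, b, cc, d = (states[k][site] for k in range(4))
                # root at the internal node joining C and D; x = AB ancestor
                lik = 0.0
                for root in range(N_CODONS):
                    inner = sum(
                        P["AB"][root, x] * P["A"][x, a] * P["B"][x, b]
                        for x in range(N_CODONS)
                    )
                    lik += pi[root] * inner * P["C"][root, cc] * P["D"][root, d]
                site_lik += weights[c] * lik
            expected += np.log(site_lik)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_fully_masked_site_contributes_zero(self):
        seqs = ["ATGAAA", "ATGAAG", "ATGAAC"]
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        pi = uniform_codon_frequencies()
        base = CodonAlignment(taxa=["A", "B", "C"], sequences=[s[:3] for s in seqs])
        mask = np.zeros((3, 6), dtype=bool)
        mask[:, 3:] = True  # second codon fully masked in all taxa
        masked = CodonAlignment(taxa=["A", "B", "C"], sequences=seqs, mask=mask)
        lnl_base = log_likelihood(base, tree, [0.5], [1.0], 2.0, pi)
        lnl_masked = log_likelihood(masked, tree, [0.5], [1.0], 2.0, pi)
        assert lnl_masked == pytest.approx(lnl_base, abs=1e-10)

    def test_missing_taxon_in_tree_is_error(self):
        aln = CodonAlignment(taxa=["A", "Z"], sequences=["AAA", "AAA"])
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="absent from tree"):
            log_likelihood(aln, tree, [0.5], [1.0], 2.0, uniform_codon_frequencies())


_TREE_NEWICK = (
    "((CM:0.06,HM:0.06):0.12,(IR:0.03,(CR:0.02,(CC:0.015,(IC:0.01,MC:0.01)"
    ":0.008):0.01):0.02):0.12);"
)


class TestSiteModelFits:
    def test_m7_recovers_mean_omega_from_m0_data(self):
        """Data simulated at omega=0.3: the median fitted M7 mean p/(p+q)
        over replicate genes lands near the truth (single genes scatter
        with sd ~ 0.05 at 500 codons)."""
        tree = parse_newick(_TREE_NEWICK)
        m7_means, m0_omegas = [], []
        for seed in range(5):
            spec = SimulationSpec(tree=tree, n_codons=500, model="M0",
                                  omega=0.3, seed=seed)
            aln, _ = simulate_codon_alignment(spec)
            m0 = fit_m0(aln, tree, gene_id="g")
            m7 = fit_site_model(aln, tree, "M7", gene_id="g",
                                branch_lengths=m0.branch_lengths, kappa_init=m0.kappa)
            m0_omegas.append(m0.omega)
            m7_means.append(m7.p / (m7.p + m7.q))
        assert np.median(m7_means) == pytest.approx(0.3, abs=0.1)
        assert np.median(m0_omegas) == pytest.approx(0.3, abs=0.1)

    def test_m8_never_below_m7_and_fits_deterministic(self):
        tree = parse_newick(_TREE_NEWICK)
        spec = SimulationSpec(tree=tree, n_codons=500, model="M0", omega=0.3, seed=5)
        aln, _ = simulate_codon_alignment(spec)
        engine = GeneLikelihood(aln, tree)
        m0 = fit_m0(aln, tree, gene_id="g", engine=engine)
        kwargs = dict(branch_lengths=m0.branch_lengths, kappa_init=m0.kappa, engine=engine)
        m7a = fit_site_model(aln, tree, "M7", gene_id="g", **kwargs)
        m7b = fit_site_model(aln, tree, "M7", gene_id="g", **kwargs)
        assert (m7a.p, m7a.q, m7a.kappa, m7a.lnl) == (m7b.p, m7b.q, m7b.kappa, m7b.lnl)
        m8 = fit_site_model(aln, tree, "M8", gene_id="g", m7_fit=m7a,
                            branch_lengths=m0.branch_lengths, engine=engine)
        assert m8.lnl >= m7a.lnl - 1e-4


class TestLrt:
    def _fit(self, model, lnl, gene="g"):
        from primex.likelihood import SiteModelFit

        return SiteModelFit(gene_id=gene, model=model, lnl=lnl, kappa=2.0,
                            branch_lengths=np.ones(3), p=0.5, q=1.5,
                            p0=0.9 if model == "M8" else None,
                            omega_s=2.0 if model == "M8" else None)

    def test_equal_likelihoods_give_p_one(self):
        rec = lrt_m7_m8(self._fit("M7", -100.0), self._fit("M8", -100.0))
        assert rec.statistic == 0.0 and rec.pvalue == 1.0

    def test_chi2_two_df_closed_form(self):
        """For 2 df the survival function is exp(-D/2)."""
        rec = lrt_m7_m8(self._fit("M7", -100.0), self._fit("M8", -100.0 + 5.9915 / 2))
        assert rec.pvalue == pytest.approx(np.exp(-5.9915 / 2), rel=1e-6)
        assert rec.pvalue == pytest.approx(0.0500, abs=1e-4)

    def test_optimizer_noise_clamped_to_zero(self):
        rec = lrt_m7_m8(self._fit("M7", -100.0), self._fit("M8", -100.0 - 1e-6))
        assert rec.statistic == 0.0 and rec.pvalue == 1.0

    def test_gene_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            lrt_m7_m8(self._fit("M7", -1.0, "a"), self._fit("M8", -1.0, "b"))
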