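"""F_ST estimation, windowing, outlier calling, and candidate set logic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from mycopop.core import GroupAssignment
from mycopop.divergence import (
    McmcSettings,
    OutlierScanResult,
    allele_counts_by_population,
    assign_candidate_divergence_snps,
    bayesian_outlier_scan,
    call_outliers,
    candidate_genes,
    q_values,
    top_fraction_windows,
    wc_fst_sites,
    wc_fst_windows,
)
from mycopop.simulate import SimulationConfig, simulate_genotypes


def wc_oracle(genotype_counts):
    """Weir & Cockerham (1984) a/b/c from per-pop (n_RR, n_RA, n_AA) counts.

    Independent scalar transcription of the published estimator.
    """
    r = len(genotype_counts)
    n = [sum(c) for c in genotype_counts]
    p = [(2 * c[2] + c[1]) / (2 * ni) for c, ni in zip(genotype_counts, n)]
    h = [c[1] / ni for c, ni in zip(genotype_counts, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def matrix_from_counts(counts_per_pop):
    """Build a one-locus matrix + assignment from per-pop genotype counts."""
    dosages = []
    labels = {}
    i = 0
    for k, (n_rr, n_ra, n_aa) in enumerate(counts_per_pop):
        for g, count in ((0, n_rr), (1, n_ra), (2, n_aa)):
            for _ in range(count):
                dosages.append([g])
                labels[f"S{i}"] = chr(ord("A") + k)
                i += 1
    m = make_matrix(np.array(dosages, dtype=np.int8))
    return m, GroupAssignment(labels)


class TestWcFstSites:
    def test_identical_populations_no_among_pop_variance(self):
        # identical genotype counts: the among-population variance term s^2
        # is zero, so a (and theta) cannot be positive; the 1984 estimator's
        # finite-sample correction makes the realized a slightly negative
        # (it is unbiased, zero only in expectation)
        m, asg = matrix_from_counts([(3, 2, 1), (3, 2, 1)])
        out = wc_fst_sites(m, asg)
        assert out["a"].iloc[0] <= 0.0
        assert out["theta"].iloc[0] <= 0.0
        assert out["a"].iloc[0] == pytest.approx(wc_oracle([(3, 2, 1)] * 2)[0],
                                                 abs=1e-12)

    def test_worked_two_pop_example_matches_oracle(self):
        counts = [(4, 1, 0), (1, 1, 3)]
        m, asg = matrix_from_counts(counts)
        out = wc_fst_sites(m, asg)
        a, b, c = wc_oracle(counts)
        assert out["a"].iloc[0] == pytest.approx(a, abs=1e-9)
        assert out["b"].iloc[0] == pytest.approx(b, abs=1e-9)
        assert out["c"].iloc[0] == pytest.approx(c, abs=1e-9)
        assert out["theta"].iloc[0] == pytest.approx(a / (a + b + c), abs=1e-9)

    def test_near_fixed_difference_high_theta(self):
        # freqs 0.95 vs 0.05 in pops of 20 strains
        counts = [(0, 2, 19) if False else (0, 2, 18), (18, 2, 0)]
        m, asg = matrix_from_counts(counts)
        out = wc_fst_sites(m, asg)
        assert out["theta"].iloc[0] > 0.7

    def test_monomorphic_locus_flagged(self):
        m, asg = matrix_from_counts([(5, 0, 0), (5, 0, 0)])
        out = wc_fst_sites(m, asg)
        assert math.isnan(out["theta"].iloc[0])

    @pytest.mark.parametrize("n_pops", [2, 3])
    def test_random_fixtures_match_oracle(self, n_pops):
        rng = np.random.default_rng(n_pops * 7)
        for _ in range(30):
            counts = []
            for _ in range(n_pops):
                c = rng.multinomial(rng.integers(4, 12), [1 / 3] * 3)
                counts.append(tuple(int(x) for x in c))
            if any(sum(c) < 2 for c in counts):
                continue
            m, asg = matrix_from_counts(counts)
            out = wc_fst_sites(m, asg)
            a, b, c = wc_oracle(counts)
            for col, val in zip("abc", (a, b, c)):
                assert out[col].iloc[0] == pytest.approx(val, abs=1e-9)


class TestFstWindows:
    def test_single_site_window_equals_site_theta(self):
        sites = pd.DataFrame(
            {"scaffold": ["sc1"], "pos": [10], "a": [0.3], "b": [0.1], "c": [0.2]}
        )
        win = wc_fst_windows(sites)
        assert win["fst"].iloc[0] == pytest.approx(0.3 / 0.6)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        sites = pd.DataFrame(
            {
                "scaffold": ["sc1", "sc1"],
                "pos": [10, 20],
                "a": [1.0, 0.0],
                "b": [0.0, 0.0],
                "c": [1.0, 2.0],
            }
        )
        win = wc_fst_windows(sites)
        # ratio of sums: (1+0)/(2+2) = 0.25; mean of ratios would be 0.25 vs
        # (0.5 + 0)/2 = 0.25 -- use a case where they differ:
        assert win["fst"].iloc[0] == pytest.approx(1.0 / 4.0)
        sites2 = sites.assign(c=[0.0, 3.0])
        win2 = wc_fst_windows(sites2)
        assert win2["fst"].iloc[0] == pytest.approx(1.0 / 4.0)  # sums: 1/(1+3)
        mean_of_ratios = (1.0 + 0.0) / 2
        assert win2["fst"].iloc[0] != pytest.approx(mean_of_ratios)

    def test_empty_window_flagged(self):
        sites = pd.DataFrame(
            {"scaffold": ["sc1"], "pos": [6000], "a": [0.2], "b": [0.0], "c": [0.2]}
        )
        win = wc_fst_windows(sites)
        assert math.isnan(win["fst"].iloc[0])  # window 1..5000 has no site
        assert win["fst"].iloc[1] == pytest.approx(0.5)

    def test_window_theta_between_site_extremes(self):
        rng = np.random.default_rng(12)
        sites = pd.DataFrame(
            {
                "scaffold": "sc1",
                "pos": rng.choice(5000, 30, replace=False) + 1,
                "a": rng.uniform(0, 1, 30),
                "b": rng.uniform(0, 1, 30),
                "c": rng.uniform(0.1, 1, 30),
            }
        )
        win = wc_fst_windows(sites)
        ratios = sites["a"] / (sites["a"] + sites["b"] + sites["c"])
        assert ratios.min() <= win["fst"].iloc[0] <= ratios.max()


class TestTopFractionWindows:
    def make_windows(self, thetas):
        return pd.DataFrame(
            {
                "scaffold": "sc1",
                "start": np.arange(len(thetas)) * 5000 + 1,
                "end": (np.arange(len(thetas)) + 1) * 5000,
                "fst": thetas,
            }
        )

    def test_nearest_rank_count(self):
        win = self.make_windows(np.linspace(0, 1, 40))
        top = top_fraction_windows(win, 0.05)
        assert len(top) == 2  # ceil(0.05 * 40)

    def test_all_equal_keeps_all(self):
        win = self.make_windows([0.5] * 10)
        assert len(top_fraction_windows(win, 0.05)) == 10

    def test_matches_sort_and_slice_oracle_with_ties(self):
        rng = np.random.default_rng(40)
        thetas = np.round(rng.uniform(0, 1, 200), 2)  # rounding creates ties
        win = self.make_windows(thetas)
        top = top_fraction_windows(win, 0.05)
        k = math.ceil(0.05 * 200)
        cutoff = np.sort(thetas)[::-1][k - 1]
        expected = {i for i, t in enumerate(thetas) if t >= cutoff}
        got = {(s - 1) // 5000 for s in top["start"]}
        assert got == expected

    def test_undefined_windows_ignored(self):
        win = self.make_windows([0.9, np.nan, 0.1, np.nan])
        top = top_fraction_windows(win, 0.5)
        assert list(top["fst"]) == [0.9]


class TestQValuesAndCalls:
    def test_q_value_worked_example(self):
        q = q_values(np.array([0.01, 0.02, 0.10]))
        assert q == pytest.approx([0.01, 0.015, (0.01 + 0.02 + 0.10) / 3])

    def test_q_values_monotone_in_pep(self):
        rng = np.random.default_rng(6)
        pep = rng.uniform(0, 1, 200)
        q = q_values(pep)
        order = np.argsort(pep)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_tied_peps_share_q(self):
        q = q_values(np.array([0.2, 0.2, 0.05]))
        assert q[0] == q[1]

    def scan_from(self, pep, fst):
        loci = pd.DataFrame(
            {
                "scaffold": "sc1",
                "pos": np.arange(len(pep)) + 1,
                "alpha": 0.0,
                "inclusion_prob": 1 - np.asarray(pep),
                "pep": pep,
                "q_value": q_values(np.asarray(pep)),
                "fst": fst,
            }
        )
        return OutlierScanResult(
            loci=loci, beta=pd.DataFrame(), global_fst=float(np.mean(fst)),
            settings=McmcSettings(), seed=0, prior_odds=10.0,
        )

    def test_call_requires_both_predicates(self):
        scan = self.scan_from(
            pep=[0.001, 0.001, 0.9], fst=[0.1, 0.9, 0.9]
        )  # mean fst = 0.6333
        called = call_outliers(scan)
        assert list(called["pos"]) == [2]  # low q but low fst excluded; high
        # fst with high q excluded

    def test_random_scan_matches_two_predicate_oracle(self):
        rng = np.random.default_rng(14)
        pep = rng.uniform(0, 0.3, 100)
        fst = rng.uniform(0, 1, 100)
        scan = self.scan_from(pep, fst)
        called = set(call_outliers(scan)["pos"])
        q = q_values(pep)
        expected = {
            i + 1
            for i in range(100)
            if q[i] < 0.05 and fst[i] > np.mean(fst)
        }
        assert called == expected


class TestCandidateAssignment:
    WINDOW = 5000

    def windows_for(self, widx_list):
        return pd.DataFrame(
            {
                "scaffold": "sc1",
                "start": [w * self.WINDOW + 1 for w in widx_list],
                "end": [(w + 1) * self.WINDOW for w in widx_list],
                "fst": 0.9,
            }
        )

    def assign(self, membership):
        """membership: dict pair -> bool for one SNP in window 0."""
        outliers = pd.DataFrame({"scaffold": ["sc1"], "pos": [100]})
        tops = {
            pair: self.windows_for([0] if inside else [7])
            for pair, inside in membership.items()
        }
        out = assign_candidate_divergence_snps(outliers, tops, self.WINDOW)
        return set(out["groups"].iloc[0].split(",")) - {""}

    def test_two_pair_membership_assigns_shared_group(self):
        got = self.assign(
            {("I", "II"): True, ("I", "III"): True, ("II", "III"): False}
        )
        assert got == {"I"}

    def test_all_three_pairs_assigns_all_groups(self):
        got = self.assign(
            {("I", "II"): True, ("I", "III"): True, ("II", "III"): True}
        )
        assert got == {"I", "II", "III"}

    def test_single_pair_membership_assigns_nothing(self):
        got = self.assign(
            {("I", "II"): True, ("I", "III"): False, ("II", "III"): False}
        )
        assert got == set()

    def test_all_membership_patterns_match_bruteforce(self):
        pairs = [("I", "II"), ("I", "III"), ("II", "III")]
        for bits in itertools.product([False, True], repeat=3):
            membership = dict(zip(pairs, bits))
            got = self.assign(membership)
            expected = set()
            for g in ("I", "II", "III"):
                involving = [p for p in pairs if g in p]
                if all(membership[p] for p in involving):
                    expected.add(g)
            assert got == expected, f"pattern {bits}"

    def test_assignment_invariant_to_pair_order(self):
        outliers = pd.DataFrame({"scaffold": ["sc1"] * 3, "pos": [100, 6000, 12000]})
        tops = {
            ("I", "II"): self.windows_for([0, 1]),
            ("I", "III"): self.windows_for([0, 2]),
            ("II", "III"): self.windows_for([1, 2]),
        }
        a = assign_candidate_divergence_snps(outliers, tops, self.WINDOW)
        reversed_tops = dict(reversed(list(tops.items())))
        b = assign_candidate_divergence_snps(outliers, reversed_tops, self.WINDOW)
        pd.testing.assert_frame_equal(a, b)


class TestCandidateGenes:
    ANN = pd.DataFrame(
        {
            "scaffold": ["sc1"] * 4,
            "pos": [10, 20, 30, 40],
            "gene_id": ["g1", "g1", "", "g2"],
            "effect": ["missense_variant"] * 4,
        }
    )

    def test_intergenic_snp_contributes_no_gene(self):
        assigned = pd.DataFrame(
            {"scaffold": ["sc1"], "pos": [30], "groups": ["I"]}
        )
        lists, report = candidate_genes(assigned, self.ANN)
        assert lists == {}
        assert report.empty

    def test_two_snps_one_gene_deduplicated(self):
        assigned = pd.DataFrame(
            {"scaffold": ["sc1", "sc1"], "pos": [10, 20], "groups": ["I", "I"]}
        )
        lists, report = candidate_genes(assigned, self.ANN)
        assert lists == {"I": ["g1"]}

    def test_shared_gene_report(self):
        assigned = pd.DataFrame(
            {
                "scaffold": ["sc1"] * 3,
                "pos": [10, 20, 40],
                "groups": ["I", "II,III", "I"],
            }
        )
        lists, report = candidate_genes(assigned, self.ANN)
        assert lists == {"I": ["g1", "g2"], "II": ["g1"], "III": ["g1"]}
        row = report.set_index("gene_id").loc["g1"]
        assert row["groups"] == "I,II,III"
        assert row["n_groups"] == 3


def quick_settings():
    return McmcSettings(burn_in=600, n_iter=2400, thin=3)


class TestOutlierScan:
    def test_seeded_scan_is_deterministic(self):
        rng = np.random.default_rng(0)
        alt = rng.integers(0, 20, size=(50, 3))
        tot = np.full((50, 3), 20)
        s1 = bayesian_outlier_scan(alt, tot, settings=quick_settings(), seed=9)
        s2 = bayesian_outlier_scan(alt, tot, settings=quick_settings(), seed=9)
        pd.testing.assert_frame_equal(s1.loci, s2.loci)

    def test_no_structure_yields_no_calls(self):
        # all populations drawn from one shared frequency vector
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 150)
        tot = np.full((150, 3), 40)
        alt = rng.binomial(40, p[:, None], size=(150, 3))
        scan = bayesian_outlier_scan(alt, tot, settings=quick_settings(), seed=5)
        assert (scan.loci["q_value"] < 0.05).sum() == 0

    def test_planted_loci_have_higher_posterior_fst(self):
        cfg = SimulationConfig(
            n_populations=3, strains_per_population=(20, 20, 20),
            baseline_divergence=(0.1, 0.1, 0.1), inbreeding=(0, 0, 0),
            n_hybrids=0, n_loci=300, outlier_fraction=0.1,
            outlier_divergence=0.6, seed=21,
        )
        m, truth = simulate_genotypes(cfg)
        alt, tot, _ = allele_counts_by_population(m, truth.assignment())
        scan = bayesian_outlier_scan(alt, tot, settings=quick_settings(), seed=2)
        is_out = truth.loci["is_outlier"].to_numpy()
        fst = scan.loci["fst"].to_numpy()
        assert fst[is_out].mean() > fst[~is_out].mean()
        incl = scan.loci["inclusion_prob"].to_numpy()
        assert incl[is_out].mean() > incl[~is_out].mean() + 0.2
        called = scan.loci["q_value"] < 0.05
        if called.any():
            assert fst[called].mean() > fst[~called].mean()

    def test_call_set_shrinks_with_higher_neutral_prior_odds(self):
        cfg = SimulationConfig(
            n_populations=3, strains_per_population=(20, 20, 20),
            baseline_divergence=(0.1, 0.1, 0.1), inbreeding=(0, 0, 0),
            n_hybrids=0, n_loci=300, outlier_fraction=0.1,
            outlier_divergence=0.6, seed=21,
        )
        m, truth = simulate_genotypes(cfg)
        alt, tot, _ = allele_counts_by_population(m, truth.assignment())
        lax = bayesian_outlier_scan(
            alt, tot, prior_odds=10, settings=quick_settings(), seed=2
        )
        strict = bayesian_outlier_scan(
            alt, tot, prior_odds=100, settings=quick_settings(), seed=2
        )
        assert (strict.loci["q_value"] < 0.05).sum() <= (
            lax.loci["q_value"] < 0.05
        ).sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            bayesian_outlier_scan(np.zeros((5, 3)), np.zeros((5, 2)))
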