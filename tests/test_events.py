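"""Event calling, the exact NB conditional test, category assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from pioneerbind import synth, events
from pioneerbind.core import Genome, TagLibrary
from pioneerbind.events import (TestConfig as EventConfig, call_events,
                                rank_top, estimate_dispersion, nb_exact_test,
                                merge_summits, UNCLASSIFIED)


def _uniform_lib(rng, length, n, chrom="chr1"):
    pos = rng.integers(0, length, n)
    return TagLibrary.from_arrays([chrom] * n, pos, rng.random(n) < 0.5)


class TestCallEvents:
    def test_null_genome_yields_no_events(self):
        """Homogeneous Poisson background: no q<0.001 events."""
        g = Genome({"chr1": "A" * 1_000_000})
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lib = _uniform_lib(rng, 1_000_000, 100_000)
            ev = call_events([lib], None, g)
            hits += len(ev) > 0
        assert hits == 0

    def test_single_planted_site_recovered(self):
        g = Genome({"chr1": "A" * 1_000_000})
        rng = np.random.default_rng(1)
        truth_point = 500_000
        sig = truth_point + np.rint(rng.normal(0, 35, 200)).astype(int)
        bg = rng.integers(0, 1_000_000, 20_000)
        pos = np.concatenate([sig, bg])
        lib = TagLibrary.from_arrays(["chr1"] * len(pos), pos,
                                     rng.random(len(pos)) < 0.5)
        ev = call_events([lib], None, g)
        assert len(ev) == 1
        assert abs(ev.point.iloc[0] - truth_point) <= 50

    def test_control_scaling_invariance(self):
        """Doubling every control tag (and its total) leaves p unchanged."""
        g = Genome({"chr1": "A" * 200_000})
        rng = np.random.default_rng(2)
        sig = TagLibrary.from_arrays(
            ["chr1"] * 5_000,
            np.concatenate([rng.integers(0, 200_000, 4_800),
                            100_000 + rng.integers(-50, 50, 200)]),
            np.zeros(5_000, bool))
        cpos = rng.integers(0, 200_000, 3_000)
        ctrl1 = TagLibrary.from_arrays(["chr1"] * 3_000, cpos,
                                       np.zeros(3_000, bool))
        cpos2 = np.repeat(cpos, 2)
        ctrl2 = TagLibrary.from_arrays(["chr1"] * 6_000, cpos2,
                                       np.zeros(6_000, bool))
        e1 = call_events([sig], ctrl1, g)
        e2 = call_events([sig], ctrl2, g)
        assert np.allclose(e1.p_binding.to_numpy(), e2.p_binding.to_numpy())
        assert np.array_equal(e1.point.to_numpy(), e2.point.to_numpy())

    def test_zero_tag_signal(self):
        g = Genome({"chr1": "A" * 100_000})
        empty = TagLibrary.from_arrays([], [], [])
        assert len(call_events([empty], None, g)) == 0


class TestRankTop:
    def test_fewer_than_n_returns_all(self):
        ev = pd.DataFrame({"chrom": ["c"] * 3, "point": [1, 2, 3],
                           "q_binding": [0.1, 0.2, 0.3],
                           "signal": [5.0, 4.0, 3.0]})
        assert len(rank_top(ev, 10_000)) == 3

    def test_tie_broken_by_signal_then_matches_sort_oracle(self, rng):
        n = 500
        ev = pd.DataFrame({
            "chrom": rng.choice(["c1", "c2"], n),
            "point": rng.integers(0, 10_000, n),
            "q_binding": rng.choice([1e-5, 1e-4, 1e-3], n),
            "signal": rng.random(n).round(2)})
        out = rank_top(ev, 100)
        oracle = ev.sort_values(["q_binding", "signal", "chrom", "point"],
                                ascending=[True, False, True, True]).head(100)
        assert out[["chrom", "point"]].to_numpy().tolist() == \
            oracle[["chrom", "point"]].to_numpy().tolist()

    def test_prefix_property(self, rng):
        ev = pd.DataFrame({"chrom": ["c"] * 200,
                           "point": rng.integers(0, 9_999, 200),
                           "q_binding": rng.random(200),
                           "signal": rng.random(200)})
        small = rank_top(ev, 50)[["chrom", "point"]].to_numpy().tolist()
        big = rank_top(ev, 120)[["chrom", "point"]].to_numpy().tolist()
        assert big[:50] == small


class TestEstimateDispersion:
    def test_poisson_data_near_zero(self, rng):
        counts = rng.poisson(100.0, size=(2_000, 4))
        phi = estimate_dispersion(counts, np.full(4, 1e6),
                                  np.array([0, 0, 1, 1]))
        assert phi <= 0.02

    def test_nb_recovery(self, rng):
        phi0 = 0.2
        lam = rng.gamma(1 / phi0, 100 * phi0, size=(2_000, 4))
        counts = rng.poisson(lam)
        phi = estimate_dispersion(counts, np.full(4, 1e6),
                                  np.array([0, 0, 1, 1]))
        assert 0.15 <= phi <= 0.25

    def test_single_replicate_falls_back(self):
        counts = np.array([[5, 9], [3, 2]])
        phi = estimate_dispersion(counts, np.array([1e6, 1e6]),
                                  np.array([0, 1]), default=0.07)
        assert phi == 0.07


def _oracle_conditional_p(ya, t, phi, na=1, nb=1):
    """Independent enumeration of the two-sided conditional NB test,
    written from first principles (log-gamma NB pmf, doubled tail)."""
    k = np.arange(t + 1)
    mu_a, mu_b = t * na / (na + nb), t * nb / (na + nb)

    def logpmf(x, mu, n_reps):
        if phi == 0:
            return x * np.log(mu) - mu - gammaln(x + 1)
        r = n_reps / phi
        p = r / (r + mu)
        return (gammaln(x + r) - gammaln(r) - gammaln(x + 1)
                + r * np.log(p) + x * np.log1p(-p))

    lw = logpmf(k, mu_a, na) + logpmf(t - k, mu_b, nb)
    w = np.exp(lw - lw.max())
    pmf = w / w.sum()
    return min(1.0, 2 * min(pmf[: ya + 1].sum(), pmf[ya:].sum()))


class TestNbExactTest:
    def test_equal_counts_give_p_one(self):
        assert nb_exact_test([50], [50], [1e6], [1e6], 0.1) == 1.0

    def test_both_zero(self):
        assert nb_exact_test([0], [0], [1e6], [1e6], 0.1) == 1.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.integers(0, 200, 2)
            p1 = nb_exact_test([a], [b], [1e6], [1e6], 0.1)
            p2 = nb_exact_test([b], [a], [1e6], [1e6], 0.1)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_poisson_case_equals_binomial_enumeration(self, rng):
        """phi=0, equal library sizes: the conditional distribution is
        Binomial(t, 1/2); compare to direct enumeration."""
        from scipy.special import comb
        for _ in range(30):
            t = int(rng.integers(1, 200))
            ya = int(rng.integers(0, t + 1))
            pmf = np.array([comb(t, k, exact=True) for k in range(t + 1)],
                           dtype=float) / 2.0 ** t
            expect = min(1.0, 2 * min(pmf[: ya + 1].sum(), pmf[ya:].sum()))
            got = nb_exact_test([ya], [t - ya], [1e6], [1e6], 0.0)
            assert got == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi, rng):
        for _ in range(40):
            t = int(rng.integers(1, 201))
            ya = int(rng.integers(0, t + 1))
            got = nb_exact_test([ya], [t - ya], [1e6], [1e6], phi)
            assert got == pytest.approx(_oracle_conditional_p(ya, t, phi),
                                        abs=1e-10)

    def test_library_size_normalization(self):
        # equal per-million rates across unequal libraries: p = 1
        assert nb_exact_test([60], [30], [2e6], [1e6], 0.1) == 1.0
        # rescaling every library size by the same factor changes nothing
        p1 = nb_exact_test([30, 40], [20, 25], [1e6, 1e6], [1e6, 1e6], 0.1)
        p2 = nb_exact_test([30, 40], [20, 25], [3e6, 3e6], [3e6, 3e6], 0.1)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestMergeSummits:
    def test_chain_merge_matches_bruteforce_single_linkage(self, rng):
        pts = np.sort(rng.integers(0, 5_000, 300))
        df = pd.DataFrame({"chrom": "c1", "point": pts})
        merged = merge_summits(df, radius=60)
        # brute-force single linkage
        clusters = [[pts[0]]]
        for p in pts[1:]:
            if p - clusters[-1][-1] <= 60:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        assert len(merged) == len(clusters)
        mids = [(c[0] + c[-1]) // 2 for c in clusters]
        assert merged.point.tolist() == mids


class TestClassify:
    def test_identical_libraries_yield_no_asymmetric_labels(self, small_scenario):
        """Supplying the same TF's data as both A and B can produce no
        A>B or B>A sites."""
        libs = small_scenario.chip["A"]
        ev = small_scenario.called["A"]
        cfg = EventConfig(min_category=1)
        cat = events.classify_pairwise(ev, ev, libs, libs,
                                       small_scenario.input_lib, cfg)
        assert set(cat.sites.label.unique()) <= {"A=B", UNCLASSIFIED}
        assert (cat.sites.label == "A=B").mean() > 0.95

    def test_mutual_exclusivity_and_exhaustiveness(self, default_scenario):
        labels = default_scenario.categorized.sites.label
        vocab = {"A=B=C", "A>B,C", "B>A,C", "C>A,B", "A,B>C", "A,C>B",
                 "B,C>A", UNCLASSIFIED}
        assert labels.notna().all()
        assert set(labels.unique()) <= vocab

    def test_small_categories_not_retained(self, default_scenario):
        cat = default_scenario.categorized
        vc = cat.sites.label.value_counts()
        for lab, n in vc.items():
            retained = cat.sites.loc[cat.sites.label == lab, "retained"]
            expect = lab != UNCLASSIFIED and n >= 500
            assert (retained == expect).all()

    def test_type_one_error_calibrated_under_null(self, small_config):
        """Two TFs with identical rate tables: few q_diff<0.01 sites."""
        small_config.categories = [
            synth.CategoryConfig("E", "posterior", 150, 1.0)]
        g = synth.generate_genome(small_config, 21)
        tf1 = synth.TFSpec("A", {"posterior": 1.0})
        tf2 = synth.TFSpec("B", {"posterior": 1.0})
        g, truth = synth.plant_landscape(g, small_config, [tf1, tf2], 22)
        fracs = []
        for seed in range(3):
            libs1 = synth.simulate_chip(truth, tf1, seed=100 + seed)
            libs2 = synth.simulate_chip(truth, tf2, seed=200 + seed)
            inp = synth.simulate_input(truth, seed=300 + seed)[0]
            cfg = EventConfig(min_category=10)
            e1 = events.call_events(libs1, inp, g, cfg)
            e2 = events.call_events(libs2, inp, g, cfg)
            cat = events.classify_pairwise(e1, e2, libs1, libs2, inp, cfg)
            q = cat.pair_stats.q_diff.to_numpy()
            fracs.append((q < 0.01).mean() if len(q) else 0.0)
        assert np.mean(fracs) <= 0.02

    def test_category_recovery_small_scenario(self, small_scenario):
        truth = small_scenario.truth
        cat = small_scenario.categorized
        match = events.match_to_truth(cat.sites, truth.sites)
        mask = match.notna() & (match != "control")
        assert mask.sum() > 400
        assert (cat.sites.label[mask] == match[mask]).mean() >= 0.9

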