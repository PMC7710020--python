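"""Markov background, PWM scanning, FDR calibration, over-representation."""

import numpy as np
import pandas as pd
import pytest

from pioneerbind import motifs, synth
from pioneerbind.core import Genome
from pioneerbind.motifs import (MarkovBackground, ScoredMotif,
                                NoDiscriminativeThreshold, encode,
                                train_background, sample_sequences,
                                sample_codes, scan, max_scores,
                                calibrate_threshold, embed_motif_instances,
                                peaks_with_hits, overrepresentation,
                                hit_position_histogram)


@pytest.fixture(scope="module")
def bg_genome():
    cfg = synth.LandscapeConfig(chrom_lengths={"chr1": 400_000})
    return synth.generate_genome(cfg, 17)


@pytest.fixture(scope="module")
def bg(bg_genome):
    return train_background(bg_genome)


class TestTrainBackground:
    def test_all_a_genome_degenerate(self):
        g = Genome({"c": "A" * 20_000})
        bg = train_background(g, pseudocount=1.0)
        assert bg.conditional[0, 0] > 0.99  # p(A|AA) ~ 1 up to pseudocount

    def test_conditionals_normalized(self, bg):
        assert np.allclose(bg.conditional.sum(axis=1), 1.0)
        assert bg.initial.sum() == pytest.approx(1.0)

    def test_loglik_matches_product_oracle(self, bg, rng):
        """log-likelihood of a 10-mer equals the brute-force product of
        the initial term and conditional terms."""
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 10))
            codes = encode(seq)
            k = bg.order
            ctx0 = int(codes[0]) * 4 + int(codes[1])
            ll = np.log2(bg.initial[ctx0])
            for i in range(k, 10):
                ctx = int(codes[i - 2]) * 4 + int(codes[i - 1])
                ll += np.log2(bg.conditional[ctx, codes[i]])
            assert bg.log_likelihood(seq) == pytest.approx(ll, abs=1e-9)

    def test_order_validation(self, bg_genome):
        with pytest.raises(ValueError):
            train_background(bg_genome, order=-1)


class TestSampleSequences:
    def test_seed_determinism(self, bg):
        assert sample_sequences(bg, 5, 30, seed=3) == \
            sample_sequences(bg, 5, 30, seed=3)

    def test_trinucleotide_frequencies_converge(self, bg):
        mat = sample_codes(bg, 10_000, 30, seed=4)
        # P(next | context) from samples vs model, 3 sigma at n draws
        ctx = (mat[:, 10].astype(int) * 4 + mat[:, 11]).astype(int)
        nxt = mat[:, 12]
        for c in range(16):
            sel = nxt[ctx == c]
            if len(sel) < 200:
                continue
            obs = np.bincount(sel, minlength=4) / len(sel)
            exp = bg.conditional[c]
            sigma = np.sqrt(exp * (1 - exp) / len(sel))
            assert np.all(np.abs(obs - exp) < 3.5 * sigma + 1e-3)

    def test_length_one_uses_initial_marginal(self, bg):
        seqs = sample_sequences(bg, 2_000, 1, seed=5)
        assert {len(s) for s in seqs} == {1}
        freq = pd.Series(list("".join(seqs))).value_counts(normalize=True)
        marg = bg.initial.reshape(4, 4).sum(axis=1)
        for i, b in enumerate("ACGT"):
            assert freq.get(b, 0.0) == pytest.approx(marg[i], abs=0.05)


class TestScan:
    def test_consensus_score_closed_form_on_uniform_background(self):
        m = synth.default_motifs()["bipartite"]
        uniform = MarkovBackground(order=0,
                                   conditional=np.full((1, 4), 0.25),
                                   initial=np.array([1.0]),
                                   mono=np.full(4, 0.25))
        sm = ScoredMotif.from_motif(m, uniform, pseudocount=0.0)
        _, _, scores = scan(m.consensus, sm, both_strands=False)
        expect = np.log2(4 * m.matrix.max(axis=1)).sum()
        assert scores[0] == pytest.approx(expect, abs=1e-9)

    def test_reverse_complement_same_best_score(self, bg, rng):
        m = synth.default_motifs()["posterior"]
        sm = ScoredMotif.from_motif(m, bg)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 60))
            b1 = scan(seq, sm)[2].max()
            b2 = scan(synth._revcomp(seq), sm)[2].max()
            assert b1 == pytest.approx(b2, abs=1e-9)

    def test_n_windows_never_hit(self, bg):
        m = synth.default_motifs()["anterior"]
        sm = ScoredMotif.from_motif(m, bg)
        _, _, scores = scan("ACGTNACGTACG", sm)
        pos, _, _ = scan("ACGTNACGTACG", sm)
        n_touching = [i for i in range(len("ACGTNACGTACG") - m.width + 1)
                      if i <= 4 < i + m.width]
        got = scan("ACGTNACGTACG", sm, both_strands=False)[2]
        assert np.all(np.isneginf(got[n_touching]))

    def test_matches_bruteforce_rescorer(self, bg, rng):
        """All window scores equal an independent per-position rescorer."""
        m = synth.default_motifs()["posterior"]
        sm = ScoredMotif.from_motif(m, bg)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 200))
            pos, strands, scores = scan(seq, sm)
            for p, st, sc in zip(pos[::7], strands[::7], scores[::7]):
                window = seq[p: p + m.width]
                if st == "-":
                    window = "".join(comp[b] for b in reversed(window))
                brute = sum(
                    np.log2((m.matrix[j, "ACGT".index(b)] + 0.01)
                            / (1 + 0.04)) - np.log2(bg.mono["ACGT".index(b)])
                    for j, b in enumerate(window))
                assert sc == pytest.approx(brute, abs=1e-9)


class TestCalibrateThreshold:
    def test_planted_vs_null_admits_query_and_controls_fdr(self, bg):
        m = synth.default_motifs()["bipartite"]
        sm = ScoredMotif.from_motif(m, bg)
        query = embed_motif_instances(m, bg, 1_000, seed=6)
        null = sample_codes(bg, 20_000, 100, seed=7)
        thr = calibrate_threshold(sm, query, null, 0.1)
        qmax = max_scores(query, sm)
        nmax = max_scores(null, sm)
        q_rate = (qmax >= thr).mean()
        n_rate = (nmax >= thr).mean()
        assert q_rate >= 0.99
        assert n_rate / q_rate <= 0.1

    def test_same_distribution_has_no_threshold(self, bg):
        m = synth.default_motifs()["anterior"]
        sm = ScoredMotif.from_motif(m, bg)
        a = sample_codes(bg, 2_000, 100, seed=8)
        b = sample_codes(bg, 2_000, 100, seed=9)
        with pytest.raises(NoDiscriminativeThreshold):
            calibrate_threshold(sm, a, b, 0.1)

    def test_threshold_monotone_in_fdr_target(self, bg):
        m = synth.default_motifs()["bipartite"]
        query = embed_motif_instances(m, bg, 500, seed=10)
        null = sample_codes(bg, 5_000, 100, seed=11)
        thrs = []
        for target in (0.05, 0.1, 0.2, 0.5):
            sm = ScoredMotif.from_motif(m, bg)
            thrs.append(calibrate_threshold(sm, query, null, target))
        assert all(a >= b for a, b in zip(thrs, thrs[1:]))

    def test_null_quantile_variant(self, bg):
        m = synth.default_motifs()["bipartite"]
        sm = ScoredMotif.from_motif(m, bg)
        null = sample_codes(bg, 5_000, 100, seed=12)
        query = embed_motif_instances(m, bg, 500, seed=13)
        thr = calibrate_threshold(sm, query, null, 0.1, method="null_quantile")
        nmax = max_scores(null, sm)
        # ties at the threshold inflate >=; strictly-above respects the
        # quantile definition
        assert (nmax > thr).mean() <= 0.1 + 0.01


class TestPeaksWithHits:
    def _calibrated(self, bg, name="posterior"):
        m = synth.default_motifs()[name]
        sm = ScoredMotif.from_motif(m, bg)
        query = embed_motif_instances(m, bg, 1_000, seed=14)
        null = sample_codes(bg, 10_000, 100, seed=15)
        calibrate_threshold(sm, query, null, 0.1)
        return m, sm

    def test_offset_beyond_within_not_flagged(self, bg):
        m, sm = self._calibrated(bg)
        # clean background with one consensus planted at point+60
        point = 5_000
        seq = "A" * 10_000
        s = seq[: point + 60] + m.consensus + seq[point + 60 + m.width:]
        g2 = Genome({"chr1": s})
        peaks = pd.DataFrame({"chrom": ["chr1"], "point": [point]})
        flags60, _ = peaks_with_hits(peaks, g2, sm, within=50)
        flags70, _ = peaks_with_hits(peaks, g2, sm, within=70)
        assert not flags60[0] and flags70[0]

    def test_planted_peaks_flagged(self, small_scenario):
        """Nearly all planted posterior-motif peaks carry a detectable hit."""
        g = small_scenario.genome
        bg = train_background(g)
        m = synth.default_motifs()["posterior"]
        sm = ScoredMotif.from_motif(m, bg)
        query = embed_motif_instances(m, bg, 1_000, seed=16)
        null = sample_codes(bg, 10_000, 100, seed=17)
        calibrate_threshold(sm, query, null, 0.1)
        truth = small_scenario.truth
        sites = truth.sites[truth.sites.motif == "posterior"]
        flags, hits = peaks_with_hits(sites, g, sm)
        assert flags.mean() >= 0.95
        assert (hits.offset.abs() <= 50).all()

    def test_all_n_genome_no_flags(self, bg):
        m, sm = self._calibrated(bg)
        g = Genome({"c": "N" * 1_000})
        peaks = pd.DataFrame({"chrom": ["c"], "point": [500]})
        flags, hits = peaks_with_hits(peaks, g, sm)
        assert not flags.any() and len(hits) == 0


class TestOverrepresentation:
    def _fisher_oracle(self, a, b, c, d):
        """Two-sided Fisher p by hypergeometric enumeration from scratch."""
        from math import comb
        n, row1, col1 = a + b + c + d, a + b, a + c
        denom = comb(n, col1)
        lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
        probs = {k: comb(row1, k) * comb(n - row1, col1 - k) / denom
                 for k in range(lo, hi + 1)}
        cutoff = probs[a] * (1 + 1e-9)
        return sum(p for p in probs.values() if p <= cutoff)

    def test_p_matches_hypergeometric_enumeration(self, bg, bg_genome):
        m = synth.default_motifs()["bipartite"]
        sm = ScoredMotif.from_motif(m, bg)
        sm.threshold = 5.0
        res = overrepresentation(30, 100, bg_genome, sm,
                                 n_background=100, seed=20)
        bg_hits = int(round(res["background_rate"] * 100))
        expect = self._fisher_oracle(30, 70, bg_hits, 100 - bg_hits)
        assert res["p"] == pytest.approx(expect, rel=1e-9)

    def test_ratio_arithmetic(self, bg, bg_genome):
        m = synth.default_motifs()["bipartite"]
        sm = ScoredMotif.from_motif(m, bg)
        sm.threshold = 1e9  # nothing in the background can hit
        res = overrepresentation(50, 100, bg_genome, sm,
                                 n_background=200, seed=21)
        assert res["background_rate"] == 0.0 and np.isinf(res["rate_ratio"])

    def test_posterior_motif_ordering_across_categories(self, small_scenario):
        """Posterior-motif over-representation is higher at posterior-TF
        categories than at the anterior-only category."""
        g = small_scenario.genome
        bg = train_background(g)
        m = synth.default_motifs()["posterior"]
        sm = ScoredMotif.from_motif(m, bg)
        calibrate_threshold(sm, embed_motif_instances(m, bg, 1_000, seed=22),
                            sample_codes(bg, 10_000, 100, seed=23), 0.1)
        cat = small_scenario.categorized.sites
        ratios = {}
        for lab in ("B>A,C", "B,C>A", "A>B,C"):
            sub = cat[cat.label == lab]
            flags, _ = peaks_with_hits(sub, g, sm)
            res = overrepresentation(int(flags.sum()), len(flags), g, sm,
                                     n_background=2_000, seed=24)
            ratios[lab] = res["rate_ratio"]
        assert ratios["B>A,C"] > ratios["A>B,C"]
        assert ratios["B,C>A"] > ratios["A>B,C"]


class TestHitPositionHistogram:
    def test_central_mass_and_conservation(self):
        hits = pd.DataFrame({"offset": [0] * 10})
        counts, edges = hit_position_histogram(hits)
        assert counts.sum() == 10
        assert counts[np.searchsorted(edges, 0, side="right") - 1] == 10

    def test_normal_offsets_mode_near_zero(self, rng):
        offs = np.rint(rng.normal(0, 20, 2_000)).astype(int)
        hits = pd.DataFrame({"offset": offs})
        counts, edges = hit_position_histogram(hits, half_window=250, bin=10)
        mode_bin = np.argmax(counts)
        zero_bin = np.searchsorted(edges, 0, side="right") - 1
        assert abs(mode_bin - zero_bin) <= 1
        assert counts.sum() == np.sum(np.abs(offs) < 250)
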