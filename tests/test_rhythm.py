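"""Rhythm detection: exact nulls, the JTK-style scan, cosinor fits and
the lncRNA neighbor-phase statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chronospec as cs
from chronospec.rhythm import (
    _cached_null,
    _lag_grid,
    _pair_signs,
    _reference_tie_pattern,
    kendall_S_exact_null,
)


def brute_force_null(tie_pattern):
    """Enumerate Kendall's S between every permutation of distinct data
    values and a reference with the given tie groups."""
    ref = np.repeat(np.arange(len(tie_pattern), dtype=float), tie_pattern)
    sr = _pair_signs(ref)
    n = len(ref)
    counts = {}
    for perm in itertools.permutations(range(n)):
        s = int(_pair_signs(np.array(perm, dtype=float)) @ sr)
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()}


class TestExactNull:
    def test_n3_untied_enumeration(self):
        """n=3 without ties: S in {-3,-1,1,3} with mass {1,2,2,1}/6."""
        null = kendall_S_exact_null((1, 1, 1))
        assert null.max_S == 3
        np.testing.assert_allclose(null.pmf, [1 / 6, 2 / 6, 2 / 6, 1 / 6], atol=1e-15)

    @pytest.mark.parametrize(
        "pattern", [(1, 1, 1, 1), (2, 2, 2), (1, 2, 3), (2, 2, 2, 2), (4, 4)]
    )
    def test_matches_exhaustive_enumeration(self, pattern):
        """Exact pmf equals brute-force enumeration over all n! orderings."""
        null = kendall_S_exact_null(pattern)
        brute = brute_force_null(pattern)
        for u, prob in enumerate(null.pmf):
            s = 2 * u - null.max_S
            assert abs(prob - brute.get(s, 0.0)) < 1e-12

    @given(
        st.lists(st.integers(min_value=1, max_value=4), min_size=2, max_size=5).filter(
            lambda g: sum(g) <= 12
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_pmf_normalized_and_symmetric(self, groups):
        """Any tie pattern: pmf sums to 1 and is symmetric about S=0."""
        null = kendall_S_exact_null(tuple(groups))
        assert abs(null.pmf.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(null.pmf, null.pmf[::-1], atol=1e-12)

    def test_large_n_switches_to_normal_approximation(self):
        null = kendall_S_exact_null((10,) * 6, exact_limit=50)
        assert null.approximate
        assert 0.0 <= null.sf_S(50) <= 1.0
        # symmetric around zero
        assert abs(null.sf_S(0) - 0.5) < 0.05


class TestJtkTest:
    def test_constant_series_gives_p_one(self, grid_times):
        p, lag, tau = cs.jtk_test(np.full(24, 7.0), grid_times)
        assert p == 1.0 and tau == 0.0

    def test_noise_free_cosine_hits_floor_at_true_lag(self, grid_times):
        """A clean cosine peaking at 8 h is found at its lag with the
        smallest p the design can produce."""
        x = 10 + 5 * np.cos(2 * np.pi * (grid_times - 8) / 24)
        x = x + 0.01 * np.random.default_rng(0).normal(size=24)  # break replicate ties
        p, lag, tau = cs.jtk_test(x, grid_times)
        assert lag == 8.0
        # attainable floor: P(S = max) under the lag-8 tie pattern, x 12 lags
        ref = np.cos(2 * np.pi * (grid_times - 8) / 24)
        null = _cached_null(_reference_tie_pattern(ref))
        floor = null.sf_S(null.max_S) * len(_lag_grid(24.0, 2.0))
        assert p == pytest.approx(floor, rel=1e-9)

    def test_matches_exhaustive_permutation_single_replicate(self):
        """n=6 single-replicate p equals the brute-force permutation p
        (all 720 orderings), per lag, Bonferroni over lags."""
        times = np.arange(0, 24, 4.0)
        rng = np.random.default_rng(1)
        lags = _lag_grid(24.0, 2.0)
        for _ in range(3):
            x = rng.normal(size=6)
            best = np.inf
            for lag in lags:
                ref = np.round(np.cos(2 * np.pi * (times - lag) / 24), 9)
                sr = _pair_signs(ref)
                s_obs = float(_pair_signs(x) @ sr)
                hits = sum(
                    float(_pair_signs(np.array(perm)) @ sr) >= s_obs
                    for perm in itertools.permutations(x)
                )
                best = min(best, hits / 720)
            expected = min(1.0, best * len(lags))
            p, _, _ = cs.jtk_test(x, times)
            assert abs(p - expected) < 1e-12

    def test_invariant_under_monotone_transform(self, grid_times):
        """Rank test: exp/scale transforms leave p and lag unchanged."""
        rng = np.random.default_rng(4)
        x = 50 + 20 * np.cos(2 * np.pi * (grid_times - 12) / 24) + rng.normal(0, 5, 24)
        p1, l1, t1 = cs.jtk_test(x, grid_times)
        p2, l2, t2 = cs.jtk_test(np.exp(x / 30.0), grid_times)
        p3, l3, t3 = cs.jtk_test(3 * x + 7, grid_times)
        assert p1 == p2 == p3 and l1 == l2 == l3
        assert t1 == pytest.approx(t2) == pytest.approx(t3)


class TestCosinor:
    def test_recovers_parameters_exactly(self):
        t = np.arange(0, 24, 4.0)
        x = 5 + 2 * np.cos(2 * np.pi * (t - 4) / 24)
        amp, lag, mesor = cs.cosinor_amp_phase(x, t)
        assert amp == pytest.approx(2.0, abs=1e-10)
        assert lag == pytest.approx(4.0, abs=1e-10)
        assert mesor == pytest.approx(5.0, abs=1e-10)

    def test_pure_sine_peaks_at_quadrature(self):
        t = np.arange(0, 24, 4.0)
        amp, lag, _ = cs.cosinor_amp_phase(np.sin(2 * np.pi * t / 24), t)
        assert lag == pytest.approx(6.0, abs=1e-10)

    def test_rank_deficient_design_fatal(self):
        with pytest.raises(ValueError):
            cs.cosinor_amp_phase([1.0, 2.0], [0.0, 12.0])

    def test_amplitude_bias_small_under_nb_noise(self, grid_times):
        """Median relative amplitude bias within +-10% at A = 0.5 B."""
        rng = np.random.default_rng(2)
        B = 200.0
        rel = []
        for _ in range(200):
            mu = B * (1 + 0.5 * np.cos(2 * np.pi * (grid_times - 6) / 24))
            r = 1 / 0.1
            x = rng.negative_binomial(r, r / (r + mu)).astype(float)
            amp, _, _ = cs.cosinor_amp_phase(x, grid_times)
            rel.append(amp / (0.5 * B))
        assert abs(np.median(rel) - 1.0) < 0.1


class TestRhythmScan:
    def test_sample_order_irrelevant(self, standard_tpm):
        """Metadata travels with samples: shuffling columns + sheet rows
        together leaves every statistic identical."""
        tpm, _ = standard_tpm
        rng = np.random.default_rng(0)
        perm = rng.permutation(tpm.samples.index.to_numpy())
        shuffled = cs.ExpressionExperiment(
            tpm.values.loc[:, perm], tpm.samples.loc[perm], unit="TPM"
        )
        a = cs.rhythm_scan(tpm, tissue="liver", condition="control")
        b = cs.rhythm_scan(shuffled, tissue="liver", condition="control")
        pd.testing.assert_frame_equal(a, b)

    def test_underpowered_design_fatal(self, small_experiment):
        exp = small_experiment
        exp.unit = "TPM"
        with pytest.raises(ValueError, match="4 distinct timepoints"):
            cs.rhythm_scan(exp, tissue="liver")


class TestNeighborPhase:
    @staticmethod
    def _annot(rows):
        return cs.validate_annotation(
            pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])
        )

    @staticmethod
    def _rhythms(d):
        return pd.DataFrame(
            {"q": 0.001, "lag": pd.Series(d), "amp": 1.0, "mesor": 1.0}
        ).rename_axis("gene_id")

    def test_hand_enumerated_cluster_phase_difference(self):
        """One lncRNA at phase 6 with neighbors at {2,6,10}: the median
        circular phase difference is 4 h."""
        ann = self._annot(
            [
                ("lnc1", "chr1", 1000, 2000, "+", "lncRNA"),
                ("c1", "chr1", 10_000, 11_000, "+", "coding"),
                ("c2", "chr1", 20_000, 21_000, "+", "coding"),
                ("c3", "chr1", 30_000, 31_000, "+", "coding"),
            ]
        )
        res = cs.neighbor_phase_correlation(
            self._rhythms({"lnc1": 6.0}),
            self._rhythms({"c1": 2.0, "c2": 6.0, "c3": 10.0}),
            ann,
        )
        assert len(res["clusters"]) == 1
        assert res["clusters"]["median_abs_phase_diff"].iloc[0] == pytest.approx(4.0)

    def test_perfect_concordance_gives_r_one(self):
        rows, lnc, cod = [], {}, {}
        for k, phase in enumerate([2.0, 8.0, 14.0, 20.0]):
            base = k * 1_000_000
            rows.append((f"lnc{k}", "chr1", base, base + 1000, "+", "lncRNA"))
            rows.append((f"c{k}", "chr1", base + 5_000, base + 6_000, "+", "coding"))
            lnc[f"lnc{k}"] = phase
            cod[f"c{k}"] = phase
        res = cs.neighbor_phase_correlation(self._rhythms(lnc), self._rhythms(cod), self._annot(rows))
        assert res["global_r"] == pytest.approx(1.0)
        assert res["nearest_r"] == pytest.approx(1.0)

    def test_cluster_without_neighbor_dropped_and_counted(self):
        ann = self._annot(
            [
                ("lnc1", "chr1", 0, 1000, "+", "lncRNA"),
                ("c1", "chr2", 0, 1000, "+", "coding"),
            ]
        )
        res = cs.neighbor_phase_correlation(
            self._rhythms({"lnc1": 3.0}), self._rhythms({"c1": 3.0}), ann
        )
        assert res["n_dropped"] == 1 and len(res["clusters"]) == 0
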