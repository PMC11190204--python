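"""The NB differential-expression engine, per-timepoint calls and the
permutation baseline for the all-timepoint DEG fraction."""

import numpy as np
import pandas as pd
import pytest

import chronospec as cs


def _nb(rng, mu, n, alpha=0.1):
    r = 1 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mu)[:, None]), size=(len(mu), n)).astype(float)


class TestNbDeTest:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        A = _nb(rng, np.full(100, 50.0), 4)
        lfc, p = cs.nb_de_test(A, A.copy())
        np.testing.assert_allclose(lfc, 0.0, atol=1e-9)
        np.testing.assert_allclose(p, 1.0, atol=1e-9)

    def test_all_zero_gene(self):
        A = np.zeros((1, 4))
        A2 = np.vstack([A, np.full((1, 4), 10.0)])
        B2 = np.vstack([A, np.full((1, 4), 10.0)])
        lfc, p = cs.nb_de_test(A2, B2, np.ones(4), np.ones(4))
        assert lfc[0] == 0.0 and p[0] == 1.0

    def test_power_for_planted_fourfold(self):
        """4-fold change at mean 100, alpha=0.05, 4v4: power >= 0.9 at
        q < 0.05."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        n_null, n_alt = 1600, 400
        muA = np.concatenate([np.full(n_null, 100.0), np.full(n_alt, 400.0)])
        muB = np.full(n_null + n_alt, 100.0)
        r = 1 / 0.05
        A = rng.negative_binomial(r, r / (r + muA[:, None]), size=(2000, 4)).astype(float)
        B = rng.negative_binomial(r, r / (r + muB[:, None]), size=(2000, 4)).astype(float)
        lfc, p = cs.nb_de_test(A, B, np.ones(4), np.ones(4))
        q = multipletests(p, method="fdr_bh")[1]
        power = (q[n_null:] < 0.05).mean()
        assert power >= 0.9

    def test_size_factors_median_of_ratios(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(3, 1, 300)
        counts = np.outer(base, [1.0, 2.0, 0.5, 1.0]) * rng.lognormal(0, 0.05, (300, 4))
        sf = cs.size_factors(counts)
        np.testing.assert_allclose(sf / sf[3], [1.0, 2.0, 0.5, 1.0], rtol=0.05)
        # normalized to unit geometric mean
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, rel=1e-9)


class TestDePerTimepoint:
    def test_planted_constitutive_and_temporal_patterns(self):
        """An 8-fold gene at every timepoint is DE at all 6; a gene
        elevated only at CT8 is DE exactly there; a significant sub-2-fold gene
        is rejected by the fold gate."""
        rng = np.random.default_rng(3)
        cts = np.arange(0, 24, 4.0)
        # flat background genes keep median-of-ratios normalization honest
        n_bg = 60
        bg_mu = rng.lognormal(5, 0.5, n_bg)
        genes = ["const", "ct8_only", "subtle", "flat"] + [f"bg{i}" for i in range(n_bg)]
        cols, records = {}, []
        for tis, mult in (("liver", True), ("kidney", False)):
            for ct in cts:
                for rep in range(1, 5):
                    sid = f"{tis}_{int(ct)}_{rep}"
                    records.append((sid, tis, ct, rep, "control"))
                    mu = np.concatenate(
                        [
                            [
                                800.0 if mult else 100.0,
                                800.0 if (mult and ct == 8.0) else 100.0,
                                160.0 if mult else 100.0,
                                100.0,
                            ],
                            bg_mu,
                        ]
                    )
                    r = 1 / 0.005
                    cols[sid] = rng.negative_binomial(r, r / (r + mu)).astype(float)
        samples = pd.DataFrame(
            records, columns=["sample_id", "tissue", "ct", "replicate", "condition"]
        ).set_index("sample_id")
        exp = cs.ExpressionExperiment(
            pd.DataFrame(cols, index=pd.Index(genes, name="gene_id")), samples
        )
        res = cs.de_per_timepoint(exp, "liver", "kidney")
        assert res.summary.loc["const", "de_at_all_timepoints"]
        assert res.summary.loc["ct8_only", "de_timepoints"] == "CT8"
        assert not res.summary.loc["subtle", "is_deg"]  # fold gate: 1.6 < 2
        sub = res.table[res.table["gene_id"] == "subtle"]
        assert (sub["q"] < 0.05).any()  # significant, but gated
        assert not res.summary.loc["flat", "is_deg"]

    def test_swapping_tissues_negates_lfc(self, standard_sim):
        exp, _ = standard_sim
        ab = cs.de_per_timepoint(exp, "liver", "kidney")
        ba = cs.de_per_timepoint(exp, "kidney", "liver")
        np.testing.assert_allclose(ab.table["log2_fc"], -ba.table["log2_fc"], atol=1e-9)
        np.testing.assert_allclose(ab.table["p"], ba.table["p"], atol=1e-12)

    def test_bh_monotone_and_union_identity(self, standard_sim):
        exp, _ = standard_sim
        res = cs.de_per_timepoint(exp, "liver", "kidney")
        for _, grp in res.table.groupby("ct"):
            g = grp.sort_values("p")
            assert (np.diff(np.maximum.accumulate(g["q"].to_numpy())) >= -1e-12).all()
            assert (g["q"] >= g["p"] - 1e-12).all()
        union = set(res.table.loc[res.table["is_de"], "gene_id"])
        assert union == set(res.summary.index[res.summary["is_deg"]])

    def test_missing_timepoint_fatal(self, standard_sim):
        exp, _ = standard_sim
        keep = ~((exp.samples["tissue"] == "kidney") & (exp.samples["ct"] == 12.0))
        broken = cs.ExpressionExperiment(
            exp.values.loc[:, keep[keep].index], exp.samples.loc[keep]
        )
        with pytest.raises(ValueError, match="missing timepoints"):
            cs.de_per_timepoint(broken, "liver", "kidney")


class TestPermutationBaseline:
    def test_time_uniform_construction_matches_null(self):
        """All planted DEGs constitutive: the observed all-timepoint
        fraction sits inside the permutation null."""
        cfg = cs.SimulationConfig(
            n_genes=300, seed=4, frac_rhythmic=0.0, frac_temporal=0.0,
            frac_tissue_specific=0.3, nb_dispersion=0.05,
        )
        exp, _ = cs.simulate_experiment(cfg)
        obs, nulls, p = cs.permutation_all_timepoint_fraction(
            exp, "liver", "kidney", n_perm=20, seed=1
        )
        lo, hi = np.nanquantile(nulls, [0.025, 0.975])
        assert lo - 0.02 <= obs <= hi + 0.02

    def test_mixed_construction_falls_below_null(self):
        """50/50 constitutive/temporal: randomizing time erases temporal
        DEGs, so the observed fraction is below the null mean."""
        cfg = cs.SimulationConfig(
            n_genes=300, seed=4, frac_rhythmic=0.0, frac_temporal=0.15,
            frac_tissue_specific=0.15, nb_dispersion=0.05,
        )
        exp, _ = cs.simulate_experiment(cfg)
        obs, nulls, _ = cs.permutation_all_timepoint_fraction(
            exp, "liver", "kidney", n_perm=20, seed=1
        )
        assert obs < np.nanmean(nulls)

    def test_same_seed_identical_nulls(self):
        cfg = cs.SimulationConfig(n_genes=120, seed=6, nb_dispersion=0.05)
        exp, _ = cs.simulate_experiment(cfg)
        _, n1, _ = cs.permutation_all_timepoint_fraction(exp, "liver", "kidney", n_perm=12, seed=9)
        _, n2, _ = cs.permutation_all_timepoint_fraction(exp, "liver", "kidney", n_perm=12, seed=9)
        np.testing.assert_array_equal(n1, n2)

    def test_few_permutations_warn(self):
        cfg = cs.SimulationConfig(n_genes=60, seed=6, nb_dispersion=0.05)
        exp, _ = cs.simulate_experiment(cfg)
        with pytest.warns(UserWarning, match="fewer than 10"):
            cs.permutation_all_timepoint_fraction(exp, "liver", "kidney", n_perm=3, seed=0)


def test_wald_engine_agrees_with_pydeseq2_ranking():
    """Independent cross-check: the self-contained NB Wald engine ranks
    genes like DESeq2 on a planted two-group comparison (fold-change
    correlation and call overlap, not identical p-values)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    rng = np.random.default_rng(12)
    n_genes = 300
    mu = rng.lognormal(4, 1, n_genes)
    fold = np.ones(n_genes)
    fold[:60] = 4.0
    r = 1 / 0.05
    A = rng.negative_binomial(r, r / (r + (mu * fold)[:, None]), size=(n_genes, 4)).astype(float)
    B = rng.negative_binomial(r, r / (r + mu[:, None]), size=(n_genes, 4)).astype(float)
    lfc, p = cs.nb_de_test(A, B, np.ones(4), np.ones(4))

    counts = pd.DataFrame(
        np.hstack([A, B]).T.astype(int),
        columns=[f"g{i}" for i in range(n_genes)],
        index=[f"s{j}" for j in range(8)],
    )
    meta = pd.DataFrame({"condition": ["A"] * 4 + ["B"] * 4}, index=counts.index)
    import logging

    logging.getLogger().setLevel(logging.ERROR)
    dds = DeseqDataSet(counts=counts, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", "A", "B"], quiet=True)
    ds.summary()
    ref = ds.results_df

    corr = np.corrcoef(lfc, ref["log2FoldChange"].to_numpy())[0, 1]
    assert corr > 0.95
    ours = set(np.flatnonzero((p < 0.01) & (np.abs(lfc) >= 1)))
    theirs = set(np.flatnonzero((ref["padj"].to_numpy() < 0.01) & (np.abs(ref["log2FoldChange"].to_numpy()) >= 1)))
    jaccard = len(ours & theirs) / max(len(ours | theirs), 1)
    assert jaccard > 0.8
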