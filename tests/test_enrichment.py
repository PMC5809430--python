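"""Negative-binomial enrichment stage: normalization, dispersion, Wald, FDR."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phageprofiler.enrichment import (
    NBModelParams,
    adjust_bh,
    classify_peptides,
    estimate_dispersions,
    estimate_size_factors,
    filter_min_total,
    nb_wald_test,
    run_enrichment,
)
from phageprofiler.readproc import PeptideCountTable

ROLES_2X2 = {
    "u1": ("unselected", 1),
    "u2": ("unselected", 2),
    "s1": ("selected", 1),
    "s2": ("selected", 2),
}


def _table(counts: dict, roles=None) -> PeptideCountTable:
    df = pd.DataFrame(counts)
    df.index = [f"PEP{i:04d}" for i in range(len(df))]
    return PeptideCountTable(counts=df, roles=roles or ROLES_2X2)


def _null_nb_table(rng, n=10_000, mean=100.0, alpha=0.1) -> PeptideCountTable:
    mu = rng.lognormal(np.log(mean), 0.7, n)
    r = 1.0 / alpha
    cols = {c: rng.negative_binomial(r, r / (r + mu)) for c in ROLES_2X2}
    return _table(cols)


class TestMinTotalFilter:
    @pytest.mark.parametrize(
        "sel,unsel,kept",
        [
            (2, 1, False),  # total 3: below the minimum of 4 combined reads
            (2, 2, True),  # total 4: boundary is inclusive
            (0, 4, True),
            (0, 0, False),
        ],
    )
    def test_combined_total_boundary(self, sel, unsel, kept):
        table = _table({"u1": [unsel], "u2": [0], "s1": [sel], "s2": [0]})
        out = filter_min_total(table, min_total=4)
        assert (out.n_peptides == 1) is kept

    def test_empty_table_passes_through(self):
        table = _table({c: [] for c in ROLES_2X2})
        assert filter_min_total(table).n_peptides == 0


def _oracle_median_of_ratios(df: pd.DataFrame) -> np.ndarray:
    """Brute-force median-of-ratios, written independently of the implementation."""
    rows = [r for _, r in df.iterrows() if (r > 0).all()]
    factors = []
    for col in df.columns:
        ratios = []
        for r in rows:
            geo = np.prod([float(x) for x in r]) ** (1.0 / len(r))
            ratios.append(r[col] / geo)
        factors.append(np.median(ratios))
    return np.array(factors)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20]})
        sf = estimate_size_factors(df)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_column_gives_factor_ratio_two(self):
        df = pd.DataFrame({"a": [5, 10, 20, 3], "b": [10, 20, 40, 6]})
        sf = estimate_size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle_on_random_table(self, rng):
        # 51 rows: an odd count makes the median an actual ratio, so the
        # raw-scale oracle and the log-scale implementation must coincide
        df = pd.DataFrame(
            rng.poisson(30.0, size=(51, 4)), columns=["u1", "u2", "s1", "s2"]
        )
        df += 1  # keep every row all-positive so both paths use the same rows
        sf = estimate_size_factors(df)
        assert np.allclose(sf.to_numpy(), _oracle_median_of_ratios(df))

    def test_fallback_when_no_common_positive_peptide(self):
        df = pd.DataFrame({"a": [4, 0], "b": [0, 8]})
        with pytest.warns(UserWarning, match="falling back"):
            sf = estimate_size_factors(df)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)


class TestDispersions:
    def test_poisson_counts_shrink_to_near_zero(self, rng):
        table = _table({c: rng.poisson(100, 5000) for c in ROLES_2X2})
        params = estimate_dispersions(table, estimate_size_factors(table.counts))
        assert params.dispersions.mean() < 0.05

    def test_nb_dispersion_recovered_at_depth_100(self, rng):
        r = 2.0  # alpha = 0.5
        table = _table({c: rng.negative_binomial(r, r / (r + 100.0), 5000) for c in ROLES_2X2})
        params = estimate_dispersions(table, estimate_size_factors(table.counts))
        assert 0.3 <= params.dispersions.median() <= 0.7

    def test_constant_counts_have_zero_raw_dispersion(self):
        table = _table({c: [7, 13] for c in ROLES_2X2})
        params = estimate_dispersions(table, pd.Series(1.0, index=list(ROLES_2X2)))
        # raw moment estimate is 0 (s^2 = 0); only the floor remains
        assert (params.dispersions <= 1e-6).all()

    def test_single_replicate_uses_trend_with_warning(self, rng):
        roles = {"u1": ("unselected", 1), "s1": ("selected", 1)}
        table = _table({"u1": rng.poisson(50, 200), "s1": rng.poisson(50, 200)}, roles)
        with pytest.warns(UserWarning, match="single replicate"):
            estimate_dispersions(table, estimate_size_factors(table.counts))


class TestWaldTest:
    def test_identical_counts_give_zero_fold_change(self):
        table = _table({"u1": [10, 50], "u2": [10, 50], "s1": [10, 50], "s2": [10, 50]})
        params = NBModelParams(
            size_factors=pd.Series(1.0, index=table.counts.columns),
            dispersions=pd.Series(0.01, index=table.counts.index),
        )
        res = nb_wald_test(table, params)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-8)
        assert (res["p"] > 0.99).all()

    def test_fourfold_counts_give_log2fc_two(self):
        table = _table({"u1": [10], "u2": [10], "s1": [40], "s2": [40]})
        params = NBModelParams(
            size_factors=pd.Series(1.0, index=table.counts.columns),
            dispersions=pd.Series(0.05, index=table.counts.index),
        )
        res = nb_wald_test(table, params)
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_null_pvalues_uniform_with_known_dispersion(self, rng):
        """Complete null, alpha known: KS distance to U(0,1) below 0.02."""
        table = _null_nb_table(rng, n=10_000, alpha=0.1)
        sf = estimate_size_factors(table.counts)
        params = NBModelParams(
            size_factors=sf, dispersions=pd.Series(0.1, index=table.counts.index)
        )
        res = nb_wald_test(table, params)
        assert stats.kstest(res["p"], "uniform").statistic < 0.02

    def test_condition_swap_negates_fold_changes(self, rng):
        table = _null_nb_table(rng, n=300)
        rec = run_enrichment(table)
        swapped_roles = {
            s: ("selected" if r == "unselected" else "unselected", rep)
            for s, (r, rep) in table.roles.items()
        }
        rec_swapped = run_enrichment(
            PeptideCountTable(counts=table.counts, roles=swapped_roles)
        )
        common = rec.index.intersection(rec_swapped.index)
        assert np.allclose(
            rec.loc[common, "log2fc"], -rec_swapped.loc[common, "log2fc"], atol=1e-6
        )
        flip = {"cleaved": "depleted", "depleted": "cleaved", "neutral": "neutral"}
        assert (
            rec_swapped.loc[common, "label"]
            == rec.loc[common, "label"].map(flip)
        ).all()


class TestBH:
    def test_hand_computed_step_up(self):
        """(0.01,0.02,0.03,0.04) -> all 0.04 by the step-up recursion."""
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_nan_propagates_without_affecting_others(self):
        out = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], adjust_bh([0.01, 0.02]))

    def test_matches_hand_step_up_oracle_on_random_vectors(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(adjust_bh(p), oracle(p))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(100)
        assert (adjust_bh(p) >= p - 1e-12).all()


class TestClassification:
    @pytest.mark.parametrize(
        "p_fdr,log2fc,label",
        [
            (0.01, 0.8, "cleaved"),
            (0.01, -1.2, "depleted"),
            (0.2, 3.0, "neutral"),
            (0.2, -3.0, "neutral"),
        ],
    )
    def test_label_rule(self, p_fdr, log2fc, label):
        res = pd.DataFrame({"base_mean": [10.0], "log2fc": [log2fc], "se": [0.1],
                            "p": [p_fdr]})
        out = classify_peptides(res, alpha=0.05)
        assert out["label"].iloc[0] == label

    def test_null_discovery_fraction_controlled(self, rng):
        """Under the complete null, discoveries stay below alpha + 3 SE."""
        table = _null_nb_table(rng, n=10_000)
        rec = run_enrichment(table)
        frac = (rec["label"] != "neutral").mean()
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(rec))
        assert frac <= bound

    def test_planted_tenfold_effect_recovered(self, rng):
        """Top planted effects at depth 10^6 reads are labeled cleaved."""
        n = 10_000
        base = rng.dirichlet(np.full(n, 2.0))
        prob = np.full(n, 0.05)
        hot = rng.choice(n, 300, replace=False)
        prob[hot] = 0.5  # 10-fold cleavage probability for motif matchers
        sel = base * prob
        sel /= sel.sum()
        depth = 1_000_000
        cols = {
            "u1": rng.multinomial(depth, base),
            "u2": rng.multinomial(depth, base),
            "s1": rng.multinomial(depth, sel),
            "s2": rng.multinomial(depth, sel),
        }
        table = _table(cols)
        rec = run_enrichment(table)
        strongest = table.counts.index[hot[np.argsort(-base[hot])[:100]]]
        labels = rec.loc[rec.index.intersection(strongest), "label"]
        assert (labels == "cleaved").sum() >= 90


class TestAgainstDESeq2Oracle:
    def test_size_factors_and_fold_changes_track_pydeseq2(self, rng):
        """Independent cross-check of the re-implemented NB pipeline."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        n = 200
        mu = rng.lognormal(np.log(80), 0.8, n)
        fc = np.ones(n)
        fc[:30] = 4.0
        r = 5.0
        cols = {
            "u1": rng.negative_binomial(r, r / (r + mu)),
            "u2": rng.negative_binomial(r, r / (r + mu)),
            "s1": rng.negative_binomial(r, r / (r + mu * fc)),
            "s2": rng.negative_binomial(r, r / (r + mu * fc)),
        }
        table = _table(cols)
        table = filter_min_total(table)
        rec = run_enrichment(table, min_total=4)

        counts_t = table.counts.T
        meta = pd.DataFrame(
            {"condition": ["unselected", "unselected", "selected", "selected"]},
            index=counts_t.index,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(counts=counts_t, metadata=meta, design="~condition", quiet=True)
            dds.deseq2()
            ds = DeseqStats(
                dds, contrast=["condition", "selected", "unselected"], quiet=True
            )
            ds.summary()
        oracle = ds.results_df

        ours_sf = estimate_size_factors(table.counts)
        assert np.allclose(ours_sf.to_numpy(), dds.obs["size_factors"].to_numpy(), rtol=1e-6)

        common = rec.index.intersection(oracle.index)
        ok = rec.loc[common, "base_mean"] > 20  # well-estimated peptides
        r_corr = np.corrcoef(
            rec.loc[common[ok], "log2fc"], oracle.loc[common[ok], "log2FoldChange"]
        )[0, 1]
        assert r_corr > 0.95
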