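import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from taxdist import (
    FunnelConfig,
    OccurrenceMatrix,
    TaxdistError,
    TaxonomyTable,
    classify_regions,
    delta_plus,
    funnel,
    generate_null_ensemble,
    group_delta_table,
    randomize_assemblages,
)
from taxdist.nulls import _subset_deltas
from taxdist.distinctness import DistinctnessResult, weight_matrix
from _oracles import enumerate_subset_deltas


class TestFunnel:
    def test_full_pool_width_zero(self, toy_tax):
        pt = funnel(toy_tax, toy_tax.species, s=4, cfg=FunnelConfig(replicates=50, seed=1))
        d = delta_plus(toy_tax, toy_tax.species)
        assert pt.mean == pt.ci_lower == pt.ci_upper == pytest.approx(d)

    def test_matches_exhaustive_enumeration_at_s2(self, toy_tax):
        """Replicate distribution over the 6 possible 2-subsets of a 4-pool."""
        cfg = FunnelConfig(replicates=10_000, seed=5)
        pt = funnel(toy_tax, toy_tax.species, s=2, cfg=cfg)
        exact = enumerate_subset_deltas(toy_tax, toy_tax.species, 2)
        # replicate mean within binomial sampling error of the exact mean
        sd = np.std(exact) / np.sqrt(cfg.replicates)
        assert pt.mean == pytest.approx(np.mean(exact), abs=5 * sd + 1e-9)
        # every replicate value is one of the six possible subset values,
        # with frequencies near 1/6 each
        W = weight_matrix(toy_tax, toy_tax.species)
        deltas = _subset_deltas(W, 2, cfg.replicates, np.random.default_rng(0))
        values, counts = np.unique(deltas, return_counts=True)
        assert set(values) <= set(np.unique(exact))
        freqs = {v: 0.0 for v in np.unique(exact)}
        for v, c in zip(values, counts):
            freqs[v] += c / cfg.replicates
        for v in set(exact):
            expected = exact.count(v) / len(exact)
            assert freqs[v] == pytest.approx(expected, abs=5 * np.sqrt(expected / cfg.replicates) + 0.01)

    def test_deterministic_given_seed(self, fixture_dataset):
        tax, _ = fixture_dataset
        cfg = FunnelConfig(replicates=500, seed=42)
        a = funnel(tax, tax.species, 5, cfg)
        b = funnel(tax, tax.species, 5, cfg)
        assert a == b

    def test_out_of_range_s_rejected(self, toy_tax):
        with pytest.raises(TaxdistError):
            funnel(toy_tax, toy_tax.species, 1)
        with pytest.raises(TaxdistError):
            funnel(toy_tax, toy_tax.species, 5)

    def test_band_width_shrinks_to_zero(self, fixture_dataset):
        """CI width at the pool size is exactly 0 and is smaller than at low s."""
        tax, _ = fixture_dataset
        cfg = FunnelConfig(replicates=2_000, seed=3)
        lo_s = funnel(tax, tax.species, 3, cfg)
        hi_s = funnel(tax, tax.species, len(tax.species) - 1, cfg)
        full = funnel(tax, tax.species, len(tax.species), cfg)
        assert full.ci_upper - full.ci_lower == 0.0
        assert (hi_s.ci_upper - hi_s.ci_lower) < (lo_s.ci_upper - lo_s.ci_lower)


class TestClassifyRegions:
    def test_tie_with_limit_is_within(self):
        # all-congener pool: the funnel degenerates to the point 1.0, so an
        # observed Delta+ exactly equal to both limits must classify within
        tax = TaxonomyTable.from_records([(f"G sp{i}", "G", "F", "O", "C") for i in range(6)])
        results = [DistinctnessResult("R", 3, 1.0)]
        out = classify_regions(results, tax, tax.species, FunnelConfig(replicates=200, seed=0))
        assert out[0].flag == "within"
        assert out[0].ci_lower == out[0].ci_upper == 1.0

    def test_strict_inequalities_either_side(self):
        tax = TaxonomyTable.from_records([(f"G sp{i}", "G", "F", "O", "C") for i in range(6)])
        low = classify_regions(
            [DistinctnessResult("R", 3, 0.9)], tax, tax.species, FunnelConfig(replicates=200, seed=0)
        )
        high = classify_regions(
            [DistinctnessResult("R", 3, 1.1)], tax, tax.species, FunnelConfig(replicates=200, seed=0)
        )
        assert low[0].flag == "below" and high[0].flag == "above"

    def test_fixture_flags(self, fixture_dataset):
        tax, occ = fixture_dataset
        results = group_delta_table(tax, occ, tax.species)
        out = classify_regions(results, tax, tax.species, FunnelConfig(replicates=10_000, seed=11))
        flags = {r.region: r.flag for r in out}
        assert flags["ClusterBay"] == "below"
        assert flags["SpreadSea"] == "above"
        assert flags["MidSea"] == "within"
        assert flags["EmptyRock"] == "undefined"


class TestRandomizeAssemblages:
    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_column_sums_conserved_every_draw(self, seed):
        tax, occ = __import__("taxdist").simulate.paper_like_fixture()
        null = randomize_assemblages(occ, tax.species, seed=seed)
        assert (null.richness() == occ.richness()).all()

    def test_region_at_pool_size_gets_whole_pool(self, toy_tax):
        occ = OccurrenceMatrix(pd.DataFrame({"R1": [1, 1, 1, 1]}, index=toy_tax.species))
        null = randomize_assemblages(occ, toy_tax.species, seed=9)
        assert set(null.assemblage("R1")) == set(toy_tax.species)

    def test_richness_beyond_pool_rejected(self, toy_tax):
        occ = OccurrenceMatrix(pd.DataFrame({"R1": [1, 1, 1, 1]}, index=toy_tax.species))
        with pytest.raises(TaxdistError):
            randomize_assemblages(occ, toy_tax.species[:3], seed=0)

    def test_sampler_equivalence_with_funnel(self, fixture_dataset):
        """Null per-region Delta+ at richness s matches the funnel's subset
        distribution at the same s (two-sample KS, alpha = 0.01)."""
        tax, _ = fixture_dataset
        pool = tax.species
        s, n_draws = 8, 5_000
        occ = OccurrenceMatrix(
            pd.DataFrame({"R1": [1] * s + [0] * (len(pool) - s)}, index=pool)
        )
        null_deltas = np.array(
            [
                delta_plus(tax, randomize_assemblages(occ, pool, seed=i).assemblage("R1"))
                for i in range(n_draws)
            ]
        )
        W = weight_matrix(tax, pool)
        funnel_deltas = _subset_deltas(W, s, n_draws, np.random.default_rng(123))
        assert ks_2samp(null_deltas, funnel_deltas).pvalue > 0.01


class TestNullEnsemble:
    def test_shape_and_determinism(self, fixture_dataset):
        tax, occ = fixture_dataset
        e1 = generate_null_ensemble(occ, tax.species, tax, k=3, seed=7)
        e2 = generate_null_ensemble(occ, tax.species, tax, k=3, seed=7)
        # EmptyRock (richness 1) is excluded: 5 defined regions x 3 nulls
        assert e1.deltas.shape == (3, 5)
        assert "EmptyRock" not in e1.deltas.columns
        pd.testing.assert_frame_equal(e1.deltas, e2.deltas)
        for m1, m2 in zip(e1.matrices, e2.matrices):
            pd.testing.assert_frame_equal(m1.frame, m2.frame)

    def test_different_seeds_differ(self, fixture_dataset):
        tax, occ = fixture_dataset
        e1 = generate_null_ensemble(occ, tax.species, tax, k=1, seed=1)
        e2 = generate_null_ensemble(occ, tax.species, tax, k=1, seed=2)
        assert not e1.matrices[0].frame.equals(e2.matrices[0].frame)

    def test_pool_equal_to_assemblage_reproduces_observed(self, toy_tax):
        occ = OccurrenceMatrix(
            pd.DataFrame({"R1": [1, 1, 1, 1], "R2": [1, 1, 1, 1]}, index=toy_tax.species)
        )
        e = generate_null_ensemble(occ, toy_tax.species, toy_tax, k=1, seed=0)
        d = delta_plus(toy_tax, toy_tax.species)
        assert np.allclose(e.deltas.to_numpy(), d)


class TestCoverage:
    def test_uniform_assemblages_fall_within_95pct_band(self, fixture_dataset):
        """Uniform size-s draws from the pool escape the 95% funnel about 5%
        of the time (binomial tolerance over 500 draws)."""
        tax, _ = fixture_dataset
        pool = tax.species
        s, n_runs = 8, 500
        pt = funnel(tax, pool, s, FunnelConfig(replicates=10_000, seed=21))
        rng = np.random.default_rng(22)
        outside = 0
        for _ in range(n_runs):
            draw = list(rng.choice(pool, size=s, replace=False))
            d = delta_plus(tax, draw)
            outside += (d < pt.ci_lower) or (d > pt.ci_upper)
        rate = outside / n_runs
        tol = 3 * np.sqrt(0.05 * 0.95 / n_runs)  # ~0.029
        assert abs(rate - 0.05) <= tol + 0.01  # +0.01 for the discreteness of Delta+
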