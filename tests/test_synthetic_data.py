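"""Generator invariants: determinism, bias direction, convergence."""

import numpy as np
import pandas as pd
import pytest

from ednafi import (
    SamplingConfig,
    apply_disturbance,
    build_community,
    generate_env,
    generate_metric_table,
    generate_reference_sites,
    guild_metric,
    simulate_edna,
    simulate_tef,
    synthetic_species_pool,
)
from ednafi.io_fixtures import validate_env
from ednafi.synthetic_data import DEFAULT_BETA, ENV_RANGES


@pytest.fixture(scope="module")
def pool():
    return synthetic_species_pool()


@pytest.fixture
def truth(pool, rng):
    traits, base = pool
    env = generate_env(1, rng)
    return build_community("s0", env.iloc[0], traits, base, rng)


class TestSpeciesPool:
    def test_33_taxa_with_index_guilds(self, pool):
        traits, base = pool
        assert len(traits.taxa) == 33
        from ednafi.vocab import INDEX_GUILDS

        assert INDEX_GUILDS <= traits.vocabulary
        assert base.sum() == pytest.approx(1.0)

    def test_index_guilds_are_dissimilar(self, pool):
        """No two sensitive guilds share more than half their members."""
        traits, _ = pool
        sensitive = ["OXY-ab", "HINTOL-ab", "RWSP-ab"]
        for i, a in enumerate(sensitive):
            for b in sensitive[i + 1:]:
                ma, mb = traits.members(a), traits.members(b)
                overlap = len(ma & mb) / min(len(ma), len(mb))
                assert overlap <= 0.5, (a, b)


class TestEnvGeneration:
    def test_ranges_and_validity(self, rng):
        env = generate_env(300, rng)
        validate_env(env)
        for col, (lo, hi) in ENV_RANGES.items():
            assert env[col].between(lo, hi).all()

    def test_deterministic_under_seed(self):
        pd.testing.assert_frame_equal(generate_env(50, 7), generate_env(50, 7))


class TestDisturbance:
    def test_zero_is_identity(self, truth, pool):
        traits, _ = pool
        out = apply_disturbance(truth, 0.0, traits=traits)
        assert out is truth

    def test_full_disturbance_raises_tolerant_share(self, truth, pool):
        traits, _ = pool
        out = apply_disturbance(truth, 1.0, traits=traits)
        tol0 = guild_metric(truth.abundances, "TOL", "rel-individuals", traits).value
        tol1 = guild_metric(out.abundances, "TOL", "rel-individuals", traits).value
        assert tol1 > tol0
        assert out.abundances.sum() == pytest.approx(1.0)

    def test_sensitive_taxa_extirpated_at_full_pressure(self, truth, pool):
        traits, _ = pool
        out = apply_disturbance(truth, 1.0, traits=traits)
        assert len(out.abundances) < len(truth.abundances)

    def test_out_of_range_rejected(self, truth):
        with pytest.raises(ValueError, match="outside"):
            apply_disturbance(truth, 1.5)


class TestSimulateTef:
    def test_unbiased_large_effort_recovers_truth(self, truth, pool):
        """With all bias factors at 1 and a million draws, catch shares
        converge on true shares (law of large numbers)."""
        traits, _ = pool
        config = SamplingConfig(
            seed=5, tef_effort=1e6, pelagic_boost=1.0, benthic_penalty=1.0
        )
        catch = simulate_tef(truth, config, traits)
        shares = catch.data.iloc[0] / catch.data.iloc[0].sum()
        assert (shares - truth.abundances).abs().max() < 0.005

    def test_pelagic_boost_inflates_pelagic_share(self, pool):
        """Across 200 seeds, the pelagic catch share exceeds the true
        pelagic share in >= 95% of simulations under default bias."""
        traits, base = pool
        rng = np.random.default_rng(0)
        env = generate_env(1, rng)
        truth = build_community("s", env.iloc[0], traits, base, rng)
        true_pel = guild_metric(truth.abundances, "PEL", "rel-individuals", traits).value
        hits = 0
        for seed in range(200):
            catch = simulate_tef(truth, SamplingConfig(seed=seed), traits)
            row = catch.data.iloc[0]
            if row.sum() == 0:
                continue
            obs = guild_metric(row, "PEL", "rel-individuals", traits).value
            hits += int(obs > true_pel)
        assert hits >= 190

    def test_single_campaign_misses_rare_species(self, truth, pool):
        traits, _ = pool
        catch = simulate_tef(truth, SamplingConfig(seed=11), traits)
        assert (catch.data.iloc[0] > 0).sum() < len(truth.abundances)

    def test_zero_effort_warns_empty(self, truth, pool):
        traits, _ = pool
        with pytest.warns(UserWarning, match="effort"):
            catch = simulate_tef(truth, SamplingConfig(seed=1, tef_effort=0.0), traits)
        assert catch.data.to_numpy().sum() == 0


class TestSimulateEdna:
    def test_high_depth_no_overdispersion_recovers_truth(self, truth):
        config = SamplingConfig(
            seed=3, edna_depth=1_000_000, edna_concentration=np.inf, n_replicates=1
        )
        reads = simulate_edna(truth, config)
        shares = reads.data.iloc[0] / reads.data.iloc[0].sum()
        assert (shares - truth.abundances).abs().max() < 0.005

    def test_zero_depth_warns_empty(self, truth):
        with pytest.warns(UserWarning, match="depth"):
            reads = simulate_edna(truth, SamplingConfig(seed=1, edna_depth=0))
        assert reads.data.to_numpy().sum() == 0

    def test_same_seed_identical(self, truth):
        r1 = simulate_edna(truth, SamplingConfig(seed=9))
        r2 = simulate_edna(truth, SamplingConfig(seed=9))
        pd.testing.assert_frame_equal(r1.data, r2.data)

    def test_generated_tables_pass_validation(self, truth, pool):
        # constructing MotuTable validates; also exercise percent closure
        from ednafi import to_relative

        reads = simulate_edna(truth, SamplingConfig(seed=2))
        rel = to_relative(reads)
        assert np.allclose(rel.data.sum(axis=1), 100.0)


class TestReferenceSites:
    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match=">= 50"):
            generate_reference_sites(10, seed=0)

    def test_deterministic(self):
        a = generate_reference_sites(60, seed=4)
        b = generate_reference_sites(60, seed=4)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        pd.testing.assert_series_equal(
            a.communities[0].abundances, b.communities[0].abundances
        )

    def test_metric_table_families(self, rng):
        env = generate_env(100, rng)
        m = generate_metric_table(env, DEFAULT_BETA, rng)
        for count_col in ("LIM-rep", "STEN", "OMN-i", "TOL-i"):
            assert (m[count_col] == m[count_col].round()).all()
        for prop_col in ("LIM-rel", "OXY-rel", "OXY-ab"):
            assert m[prop_col].between(0, 1).all()


class TestMethodContrast:
    def test_tef_vs_edna_guild_direction(self, pool):
        """Simulated data reproduce the qualitative cross-method pattern:
        pelagic share higher in electrofishing, benthic share higher in
        eDNA, under the default bias configuration."""
        traits, base = pool
        rng = np.random.default_rng(42)
        env = generate_env(5, rng)
        pel_diff, ben_diff = [], []
        for i, site in enumerate(env.index):
            truth = build_community(site, env.loc[site], traits, base, rng)
            config = SamplingConfig(seed=100 + i)
            tef = simulate_tef(truth, config, traits, rng=rng)
            edna = simulate_edna(truth, config, rng=rng)
            trow = tef.data.iloc[0]
            erow = edna.data.sum(axis=0)
            pel_diff.append(
                guild_metric(trow, "PEL", "rel-individuals", traits).value
                - guild_metric(erow, "PEL", "rel-individuals", traits).value
            )
            ben_diff.append(
                guild_metric(trow, "BEN", "rel-individuals", traits).value
                - guild_metric(erow, "BEN", "rel-individuals", traits).value
            )
        assert np.mean(pel_diff) > 0
        assert np.mean(ben_diff) < 0
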