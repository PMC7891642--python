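"""Discard policy, MOTU trait assignment, pooling and closure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ednafi import (
    DiscardPolicy,
    MotuTable,
    TraitTable,
    ValidationError,
    apply_discards,
    concat_tables,
    pool_replicates,
    resolve_motu_traits,
    to_relative,
)
from ednafi.motu_processing import _largest_remainder


class TestApplyDiscards:
    def test_removes_taxon_and_recloses_percent(self):
        data = pd.DataFrame(
            [[50.0, 30.0, 20.0]], index=["s1"], columns=["Cypr_2", "a", "b"]
        )
        table = MotuTable(data, method="eDNA", unit="percent")
        out = apply_discards(table, DiscardPolicy({"Cypr_2": "farmed-only"}))
        assert "Cypr_2" not in out.taxa
        assert out.renormalized
        assert out.data.loc["s1"].sum() == pytest.approx(100.0)
        assert out.data.loc["s1", "a"] == pytest.approx(60.0)

    def test_empty_policy_is_identity(self, small_counts):
        out = apply_discards(small_counts, DiscardPolicy({}))
        pd.testing.assert_frame_equal(out.data, small_counts.data)

    def test_absent_taxon_is_noop(self, small_counts):
        out = apply_discards(small_counts, DiscardPolicy({"ghost": "other"}))
        pd.testing.assert_frame_equal(out.data, small_counts.data)

    def test_all_taxa_discarded_warns(self, small_counts):
        policy = DiscardPolicy({t: "other" for t in small_counts.taxa})
        with pytest.warns(UserWarning, match="all taxa"):
            out = apply_discards(small_counts, policy)
        assert out.data.shape[1] == 0

    def test_idempotent(self):
        data = pd.DataFrame([[50.0, 50.0]], index=["s1"], columns=["Cypr_2", "a"])
        table = MotuTable(data, method="eDNA", unit="percent")
        policy = DiscardPolicy({"Cypr_2": "farmed-only"})
        once = apply_discards(table, policy)
        twice = apply_discards(once, policy)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_unknown_reason_rejected(self):
        with pytest.raises(ValidationError, match="reason"):
            DiscardPolicy({"x": "because"})


class TestResolveMotuTraits:
    @pytest.fixture
    def member_traits(self):
        return TraitTable(
            {
                "Cottus gobio": frozenset({"BEN", "EUR", "INS"}),
                "Cottus petiti": frozenset({"BEN", "EUR", "INS"}),
                "Chondrostoma nasus": frozenset({"RHE", "POT"}),
                "Telestes souffia": frozenset({"RHE", "INS"}),
                "sp1": frozenset({"TOL"}),
                "sp2": frozenset({"RHE"}),
            }
        )

    def test_uniform_profile(self, member_traits):
        rule = resolve_motu_traits("Cot_sp", ["Cottus gobio", "Cottus petiti"], member_traits)
        assert rule.rule == "uniform-profile"
        assert rule.profile == frozenset({"BEN", "EUR", "INS"})

    def test_dominant_95(self, member_traits):
        catch = MotuTable(
            pd.DataFrame(
                [[96.0, 4.0]], index=["c1"],
                columns=["Chondrostoma nasus", "Telestes souffia"],
            ),
            method="TEF",
            unit="counts",
        )
        rule = resolve_motu_traits(
            "Cypr_1", ["Chondrostoma nasus", "Telestes souffia"], member_traits, catch
        )
        assert rule.rule == "dominant-95"
        assert rule.dominant_species == "Chondrostoma nasus"
        assert rule.profile == frozenset({"RHE", "POT"})

    def test_60_40_split_excluded(self, member_traits):
        catch = MotuTable(
            pd.DataFrame([[60.0, 40.0]], index=["c1"], columns=["sp1", "sp2"]),
            method="TEF",
            unit="counts",
        )
        rule = resolve_motu_traits("Mix", ["sp1", "sp2"], member_traits, catch)
        assert rule.rule == "excluded"
        assert rule.profile is None

    def test_missing_member_named(self, member_traits):
        with pytest.raises(ValidationError, match="ghost"):
            resolve_motu_traits("X", ["sp1", "ghost"], member_traits)

    def test_fixture_motus_resolve_as_published(self, table2):
        """On the packaged catch data, Cypr_1 -> nasus and Leu_spp -> leuciscus."""
        sub = table2.tef.provenance["species_subrows"]
        species_cols = {
            sp: sum(v for k, v in row.items() if k.endswith("_TEF") and not np.isnan(v))
            for sp, row in sub.items()
        }
        catch = MotuTable(
            pd.DataFrame([species_cols], index=["pooled"]), method="TEF", unit="counts"
        )
        member_traits = TraitTable(
            {
                "Chondrostoma nasus": frozenset({"RHE", "POT"}),
                "Telestes souffia": frozenset({"RHE", "INS"}),
                "Parachondrostoma toxostoma": frozenset({"RHE"}),
                "Leuciscus leuciscus": frozenset({"RHE", "OMN", "POT"}),
                "Leuciscus idus": frozenset({"EUR", "OMN"}),
            }
        )
        cypr = resolve_motu_traits(
            "Cypr_1",
            ["Chondrostoma nasus", "Telestes souffia", "Parachondrostoma toxostoma"],
            member_traits,
            catch,
        )
        assert cypr.rule == "dominant-95"
        assert cypr.dominant_species == "Chondrostoma nasus"
        leu = resolve_motu_traits(
            "Leu_spp", ["Leuciscus leuciscus", "Leuciscus idus"], member_traits, catch
        )
        assert leu.rule == "dominant-95"
        assert leu.dominant_species == "Leuciscus leuciscus"


class TestPoolReplicates:
    def test_pooled_pair_sums_counts(self, small_counts):
        out = pool_replicates(small_counts, {"pool": ["s1", "s2"]})
        expected = small_counts.data.loc["s1"] + small_counts.data.loc["s2"]
        pd.testing.assert_series_equal(out.data.loc["pool"], expected, check_names=False)
        assert out.provenance["pooled_replicates"]["pool"] == ["s1", "s2"]

    def test_identical_replicates_double(self):
        data = pd.DataFrame([[3.0, 7.0], [3.0, 7.0]], index=["r1", "r2"], columns=["a", "b"])
        table = MotuTable(data, method="eDNA", unit="counts")
        out = pool_replicates(table, {"p": ["r1", "r2"]})
        assert out.data.loc["p"].tolist() == [6.0, 14.0]

    def test_single_replicate_group_unchanged(self, small_counts):
        out = pool_replicates(small_counts, {"p": ["s1"]})
        pd.testing.assert_series_equal(
            out.data.loc["p"], small_counts.data.loc["s1"], check_names=False
        )

    def test_chosen_pair_of_ten_matches_hand_sum(self, rng):
        counts = rng.integers(0, 50, size=(10, 3)).astype(float)
        data = pd.DataFrame(counts, index=[f"r{i}" for i in range(10)], columns=list("abc"))
        table = MotuTable(data, method="eDNA", unit="counts")
        out = pool_replicates(table, {"p": ["r2", "r7"]})
        assert out.data.loc["p"].tolist() == (counts[2] + counts[7]).tolist()

    def test_percent_table_rejected(self, table2):
        with pytest.raises(ValidationError, match="count-unit"):
            pool_replicates(table2.edna, {"p": ["RS_A", "RS_B"]})

    def test_mixing_methods_rejected(self, small_counts):
        other = MotuTable(small_counts.data.copy(), method="TEF", unit="counts")
        with pytest.raises(ValidationError, match="mix methods"):
            concat_tables(small_counts, other)


class TestToRelative:
    def test_simple_proportions(self, small_counts):
        out = to_relative(small_counts)
        assert out.unit == "percent"
        assert out.data.loc["s1"].tolist() == [25.0, 75.0, 0.0]

    def test_single_taxon_row_closes_to_100(self):
        table = MotuTable(
            pd.DataFrame([[7.0]], index=["s"], columns=["a"]), method="TEF", unit="counts"
        )
        assert to_relative(table).data.loc["s", "a"] == 100.0

    def test_thirds_close_exactly(self):
        table = MotuTable(
            pd.DataFrame([[1.0, 1.0, 1.0]], index=["s"], columns=list("abc")),
            method="eDNA",
            unit="counts",
        )
        row = to_relative(table).data.loc["s"]
        assert row.sum() == pytest.approx(100.0, abs=0)
        assert sorted(row.tolist()) == [33.33, 33.33, 33.34]

    def test_zero_total_row_names_sample(self):
        table = MotuTable(
            pd.DataFrame([[0.0, 0.0]], index=["empty"], columns=["a", "b"]),
            method="eDNA",
            unit="counts",
        )
        with pytest.raises(ValidationError, match="empty"):
            to_relative(table)

    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=2, max_size=12),
        scale=st.integers(2, 1000),
    )
    @settings(deadline=None, max_examples=100)
    def test_scale_invariance_and_closure(self, counts, scale):
        """Percentages are invariant to uniform scaling and always close to 100."""
        if sum(counts) == 0:
            counts[0] = 1
        cols = [f"t{i}" for i in range(len(counts))]
        base = MotuTable(
            pd.DataFrame([counts], index=["s"], columns=cols, dtype=float),
            method="eDNA", unit="counts",
        )
        scaled = MotuTable(base.data * scale, method="eDNA", unit="counts")
        a, b = to_relative(base).data, to_relative(scaled).data
        pd.testing.assert_frame_equal(a, b)
        assert a.loc["s"].sum() == pytest.approx(100.0, abs=1e-9)


def test_largest_remainder_matches_enumeration():
    """Exhaustive check on small vectors against a brute-force optimum."""
    from itertools import product

    for vec in ([1, 1, 1], [1, 2, 4], [3, 3, 1], [5, 1, 1, 1]):
        values = np.array(vec, dtype=float)
        shares = values / values.sum() * 100.0
        got = _largest_remainder(shares, 100)
        assert got.sum() == 100
        # no alternative integer vector summing to 100 is uniformly closer
        best_err = np.abs(got - shares).sum()
        floors = np.floor(shares).astype(int)
        for extra in product(range(3), repeat=len(vec)):
            cand = floors + np.array(extra)
            if cand.sum() == 100:
                assert np.abs(cand - shares).sum() >= best_err - 1e-9
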