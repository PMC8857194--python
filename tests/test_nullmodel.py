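"""Null model: binning, matched sampling, ensembles, p-values, BH."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import herbnet
from herbnet.errors import SamplingError
from herbnet.network import build_network
from herbnet.nullmodel import (DEFAULT_BINS, BinSpec, NullConfig, NullEnsemble,
                               ReplicateEngine, bh_adjust, bin_profile,
                               empirical_pvalues, herb_bin, null_ensemble,
                               sample_matched_herbs, significance_table)
from herbnet.centrality import pathway_centralities
from herbnet.screening import ScreeningConfig, adme_filter, interaction_filter
from tests.conftest import OBSERVED_PROFILE, bh_oracle, make_catalog


def _herbs_with_counts(counts: dict[str, int]):
    compounds = {}
    herbs = {}
    for hid, n in counts.items():
        cids = {f"{hid}_c{i}" for i in range(n)}
        herbs[hid] = cids
        compounds.update({c: (50.0, 0.5) for c in cids})
    return make_catalog(herbs=herbs, compounds=compounds, interactions={})


class TestBinning:
    @pytest.mark.parametrize("count,expected", [
        (1, 0), (5, 0), (10, 0),     # gap value 10 closed into bin 1
        (11, 1), (20, 1),
        (21, 2), (40, 2),
        (41, 3), (100, 3),           # gap value 41 closed into bin 4
    ])
    def test_bin_edges(self, count, expected):
        assert DEFAULT_BINS.bin_of(count) == expected

    def test_herb_bin_uses_catalog_count(self):
        cat = _herbs_with_counts({"small": 5, "big": 41})
        assert herb_bin(cat, "small") == 0
        assert herb_bin(cat, "big") == 3
        with pytest.raises(KeyError):
            herb_bin(cat, "ghost")

    def test_bad_binspec_rejected(self):
        with pytest.raises(ValueError):
            BinSpec(upper_bounds=(20, 10))

    def test_profile_sums_and_matches_tally(self):
        rng = np.random.default_rng(0)
        counts = {f"h{i}": int(rng.integers(1, 60)) for i in range(50)}
        cat = _herbs_with_counts(counts)
        profile = bin_profile(cat, set(counts))
        assert sum(profile) == 50
        tally = [0, 0, 0, 0]
        for n in counts.values():  # one-line independent tally
            tally[0 if n <= 10 else 1 if n <= 20 else 2 if n <= 40 else 3] += 1
        assert list(profile) == tally

    def test_empty_profile(self):
        assert bin_profile(make_catalog({}, {}, {}), set()) == (0, 0, 0, 0)


class TestMatchedSampling:
    def test_forced_set_returned_exactly(self):
        cat = _herbs_with_counts({"a": 25, "b": 30, "c": 35})
        got = sample_matched_herbs(cat, (0, 0, 3, 0), np.random.default_rng(1))
        assert got == {"a", "b", "c"}

    def test_same_seed_identical_sample(self, desk_catalog):
        s1 = sample_matched_herbs(desk_catalog, OBSERVED_PROFILE,
                                  np.random.default_rng(42))
        s2 = sample_matched_herbs(desk_catalog, OBSERVED_PROFILE,
                                  np.random.default_rng(42))
        assert s1 == s2

    def test_insufficient_bin_raises_naming_it(self):
        cat = _herbs_with_counts({"a": 25})
        with pytest.raises(SamplingError, match="bin 3"):
            sample_matched_herbs(cat, (0, 0, 2, 0), np.random.default_rng(0))

    def test_within_bin_sampling_is_uniform(self):
        # 4 eligible herbs in bin 2, profile count 1, 2000 draws:
        # each herb's frequency within 3 sigma of 1/4
        cat = _herbs_with_counts({f"h{i}": 15 for i in range(4)})
        rng = np.random.default_rng(9)
        hits = {f"h{i}": 0 for i in range(4)}
        n = 2000
        for _ in range(n):
            (h,) = sample_matched_herbs(cat, (0, 1, 0, 0), rng)
            hits[h] += 1
        se = np.sqrt(0.25 * 0.75 / n)
        for h, k in hits.items():
            assert abs(k / n - 0.25) < 3 * se


class TestReplicateEngine:
    def test_matches_composed_pipeline(self, desk_catalog):
        cfg = ScreeningConfig()
        engine = ReplicateEngine(desk_catalog, cfg)
        kept = adme_filter(desk_catalog, cfg)
        inter = interaction_filter(desk_catalog, kept, cfg)
        rng = np.random.default_rng(123)
        for _ in range(5):
            herbs = sample_matched_herbs(desk_catalog, OBSERVED_PROFILE, rng)
            net = build_network(herbs, desk_catalog, inter, compounds_kept=kept)
            slow = pathway_centralities(net)
            fast = engine.centralities_for(herbs)
            assert set(fast) == set(slow)
            for p in slow:
                assert fast[p] == pytest.approx(slow[p], rel=1e-12)


class TestNullEnsemble:
    def test_single_forced_replicate(self):
        base = _herbs_with_counts({"a": 25, "b": 30, "c": 35})
        cat = make_catalog(
            herbs={h: set(r.compound_ids) for h, r in base.herbs.items()},
            compounds={c: (rec.ob, rec.dl)
                       for c, rec in base.compounds.items()},
            interactions={("a_c0", "t1"): 64.0, ("b_c0", "t1"): 81.0,
                          ("c_c0", "t2"): 90.0},
            memberships={("pw", "t1"), ("pw", "t2")})
        kept = adme_filter(cat)
        inter = interaction_filter(cat, kept)
        net = build_network({"a", "b", "c"}, cat, inter, compounds_kept=kept)
        ens = null_ensemble(cat, net, NullConfig(replicates=1, seed=0))
        expected = pathway_centralities(net)["pw"]
        assert ens.values["pw"].tolist() == [pytest.approx(expected)]

    def test_fixed_seed_reproducible(self, desk_catalog):
        kept = adme_filter(desk_catalog)
        inter = interaction_filter(desk_catalog, kept)
        herbs = sample_matched_herbs(desk_catalog, OBSERVED_PROFILE,
                                     np.random.default_rng(0))
        net = build_network(herbs, desk_catalog, inter, compounds_kept=kept)
        cfg = NullConfig(replicates=50, seed=17)
        e1 = null_ensemble(desk_catalog, net, cfg)
        e2 = null_ensemble(desk_catalog, net, cfg)
        assert set(e1.values) == set(e2.values)
        for p in e1.values:
            assert np.array_equal(e1.values[p], e2.values[p])

    def test_ensemble_mean_matches_larger_mc_oracle(self, desk_catalog):
        # production ensemble at R=200 vs an independently composed
        # Monte-Carlo run at 10x replicates: means within 2 SE
        kept = adme_filter(desk_catalog)
        inter = interaction_filter(desk_catalog, kept)
        herbs = sample_matched_herbs(desk_catalog, OBSERVED_PROFILE,
                                     np.random.default_rng(1))
        net = build_network(herbs, desk_catalog, inter, compounds_kept=kept)
        R = 200
        ens = null_ensemble(desk_catalog, net,
                            NullConfig(replicates=R, seed=100))
        profile = bin_profile(desk_catalog, herbs)
        oracle_rng = np.random.default_rng(999)
        oracle_R = 2000
        oracle_totals = np.empty(oracle_R)
        for i in range(oracle_R):
            sample = sample_matched_herbs(desk_catalog, profile, oracle_rng)
            onet = build_network(sample, desk_catalog, inter,
                                 compounds_kept=kept)
            oracle_totals[i] = sum(pathway_centralities(onet).values())
        # one scalar comparison: mean total centrality (sum over pathways),
        # obtained from the sparse store by linearity of the mean
        ens_mean_total = sum(v.sum() for v in ens.values.values()) / R
        se = np.sqrt(oracle_totals.var() / R + oracle_totals.var() / oracle_R)
        assert abs(ens_mean_total - oracle_totals.mean()) < 3 * se


class TestEmpiricalPvalues:
    def test_direct_count(self):
        ens = NullEnsemble(replicates=9,
                           values={"pw": np.array([1, 2, 3, 5.0, 6, 7, 4, 2, 1])})
        # 3 of 9 replicates >= 5.0 -> (1+3)/10
        assert empirical_pvalues({"pw": 5.0}, ens)["pw"] == pytest.approx(0.4)

    def test_observation_above_all_nulls(self):
        ens = NullEnsemble(replicates=99, values={"pw": np.arange(99.0)})
        assert empirical_pvalues({"pw": 1e6}, ens)["pw"] == pytest.approx(1 / 100)

    def test_zero_observation_with_all_zero_nulls(self):
        ens = NullEnsemble(replicates=50, values={})
        assert empirical_pvalues({"pw": 0.0}, ens)["pw"] == pytest.approx(1.0)

    def test_unseen_pathway_gets_minimum_p(self):
        ens = NullEnsemble(replicates=50, values={})
        assert empirical_pvalues({"pw": 3.0}, ens)["pw"] == pytest.approx(1 / 51)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        df = bh_adjust({"a": 0.01})
        assert df.q.tolist() == [pytest.approx(0.01)]

    def test_stepup_worked_examples(self):
        df = bh_adjust({"a": 0.01, "b": 0.02, "c": 0.03, "d": 0.04})
        assert df.q.tolist() == pytest.approx([0.04, 0.04, 0.04, 0.04])
        df2 = bh_adjust({"a": 0.005, "b": 0.1})
        assert df2.q.tolist() == pytest.approx([0.01, 0.1])

    def test_order_stability(self):
        ps = {"a": 0.03, "b": 0.01, "c": 0.7}
        forward = bh_adjust(ps)
        backward = bh_adjust(dict(reversed(list(ps.items()))))
        assert forward.equals(backward)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust({"a": bad})

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    def test_matches_independent_stepup_oracle(self, ps):
        named = {f"p{i:02d}": p for i, p in enumerate(ps)}
        df = bh_adjust(named).set_index("pathway_name")
        want = bh_oracle(np.array([named[k] for k in sorted(named)]))
        got = df.loc[sorted(named), "q"].to_numpy()
        assert np.allclose(got, np.minimum(want, 1.0), rtol=1e-12)


def test_significance_table_bytes_reproducible(desk_catalog, tmp_path):
    kept = adme_filter(desk_catalog)
    inter = interaction_filter(desk_catalog, kept)
    herbs = sample_matched_herbs(desk_catalog, OBSERVED_PROFILE,
                                 np.random.default_rng(4))
    net = build_network(herbs, desk_catalog, inter, compounds_kept=kept)
    obs = pathway_centralities(net)
    outs = []
    for run in range(2):
        ens = null_ensemble(desk_catalog, net, NullConfig(replicates=60, seed=5))
        table = significance_table(obs, ens)
        f = tmp_path / f"sig{run}.tsv"
        table.to_csv(f, sep="\t", index=False, lineterminator="\n")
        outs.append(f.read_bytes())
    assert outs[0] == outs[1]
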