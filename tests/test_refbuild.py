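"""Marker selection, moderated t, BH FDR and reference construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

import methdeconv as md

from conftest import bh_stepup_brute, make_beta, make_reference


def two_group_dataset(seed=0, n_cpgs=100, n_per_group=3, planted_delta=0.8, sd=0.02):
    """Two cell types, one planted DMC (cg0000) among null CpGs."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0.3, 0.7, size=n_cpgs)
    means = np.tile(base[:, None], (1, 2))
    means[0, 0] = np.clip(base[0] - planted_delta / 2, 0.01, 0.99)
    means[0, 1] = np.clip(means[0, 0] + planted_delta, 0.01, 0.99)
    cols, labels = {}, {}
    for c, ct in enumerate(["A", "B"]):
        for r in range(n_per_group):
            s = f"{ct}{r}"
            cols[s] = np.clip(means[:, c] + rng.normal(0, sd, n_cpgs), 0, 1)
            labels[s] = ct
    beta = md.BetaMatrix(pd.DataFrame(cols, index=[f"cg{i:04d}" for i in range(n_cpgs)]))
    return md.PurifiedDataset(beta, labels)


class TestModeratedT:
    def test_zero_prior_df_equals_ordinary_pooled_t(self):
        data = two_group_dataset(seed=1)
        table = md.moderated_t_one_vs_rest(data, "A", prior_df=0.0)
        a = data.beta.data[data.samples_of("A")].to_numpy()
        b = data.beta.data[data.samples_of("B")].to_numpy()
        ordinary = ttest_ind(a, b, axis=1).statistic
        np.testing.assert_allclose(table["t"].to_numpy(), ordinary, rtol=1e-10)

    def test_infinite_prior_df_uses_prior_variance_everywhere(self):
        data = two_group_dataset(seed=2)
        table = md.moderated_t_one_vs_rest(data, "A", prior_df=np.inf)
        # with complete shrinkage, t / delta is the same constant at every CpG
        ratio = table["t"] / table["delta"]
        assert ratio.std() / abs(ratio.mean()) < 1e-10

    def test_planted_dmc_has_largest_moderated_t(self):
        for seed in range(3):
            data = two_group_dataset(seed=seed)
            table = md.moderated_t_one_vs_rest(data, "A")
            assert table["t"].abs().idxmax() == "cg0000"

    def test_requires_two_samples_per_group(self):
        data = two_group_dataset()
        single = md.PurifiedDataset(
            md.BetaMatrix(data.beta.data[["A0", "B0", "B1"]]),
            {s: data.cell_type_of_sample[s] for s in ["A0", "B0", "B1"]},
        )
        with pytest.raises(ValueError, match="2 samples"):
            md.moderated_t_one_vs_rest(single, "A")


class TestBHFdr:
    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(
            md.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize("p, q", [([0.2], [0.2]), ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])])
    def test_edge_inputs(self, p, q):
        np.testing.assert_allclose(md.bh_fdr(p), q)

    def test_empty_input(self):
        assert md.bh_fdr([]).size == 0

    def test_matches_brute_force_stepup_definition(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(md.bh_fdr(p), bh_stepup_brute(p), atol=1e-12)


class TestDMCSelection:
    def test_planted_dmcs_recovered_with_few_false_calls(self):
        cfg = md.SynthConfig(
            n_cell_types=4, n_cpgs=600, n_dmcs_per_type=30, seed=7,
            replicate_sd=0.15, delta_range=(0.5, 0.9),
        )
        sim = md.synth_purified_dataset(cfg)
        selected = md.select_dmcs_one_vs_rest(sim.train, 0.05)
        all_planted = set(sim.ground_truth.index)
        false_counts = []
        for ct in sim.train.cell_types:
            truth = set(sim.ground_truth.index[sim.ground_truth["cell_type"] == ct])
            found = set(selected[ct].index)
            assert len(truth & found) >= 28
            # markers of *other* types are truly differential one-vs-rest, so a
            # false call is a selection not planted for any cell type
            false_counts.append(len(found - all_planted))
        # BH bounds the *expected* false fraction, so bound the mean per list
        assert np.mean(false_counts) <= 2

    def test_null_data_rarely_selects_anything(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            beta = make_beta(
                np.clip(rng.uniform(0.3, 0.7, size=(1000, 1)) + rng.normal(0, 0.03, (1000, 6)), 0, 1),
                samples=[f"s{i}" for i in range(6)],
            )
            data = md.PurifiedDataset(beta, {f"s{i}": "A" if i < 3 else "B" for i in range(6)})
            selected = md.select_dmcs_one_vs_rest(data, 0.05)
            if all(len(t) == 0 for t in selected.values()):
                hits += 1
        assert hits >= 27  # expected >= 95% of seeds; allow binomial slack

    def test_threshold_one_selects_everything(self):
        data = two_group_dataset(seed=3, n_cpgs=50)
        selected = md.select_dmcs_one_vs_rest(data, 1.0)
        assert all(len(t) == 50 for t in selected.values())


class TestPairwiseSelection:
    def test_threshold_examples(self):
        ref = make_reference([[0.02, 0.97], [0.10, 0.90]])
        _, union = md.select_dmcs_pairwise(ref, 0.9)
        assert union == {"cg0"}  # |0.8| delta misses a 0.9 threshold

    def test_union_of_pair_sets_counts_shared_once(self):
        # 3 types; pair deltas engineered so |A-B| fires at 2 CpGs,
        # |A-C| at 3 CpGs, |B-C| at 1 CpG, with one CpG shared by two pairs
        vals = np.array(
            [
                [0.02, 0.97, 0.50],  # A-B only
                [0.97, 0.02, 0.96],  # A-B and B-C (shared CpG)
                [0.02, 0.50, 0.97],  # A-C only
                [0.97, 0.50, 0.02],  # A-C only
                [0.02, 0.08, 0.97],  # A-C only
                [0.50, 0.50, 0.50],  # nothing
            ]
        )
        ref = make_reference(vals, cell_types=["A", "B", "C"])
        pairs, union = md.select_dmcs_pairwise(ref, 0.9)
        assert len(pairs[("A", "B")]) == 2
        assert len(pairs[("A", "C")]) == 3
        assert len(pairs[("B", "C")]) == 1
        assert len(union) == 5


class TestRankingAndReference:
    def _dmcs(self, deltas, cpgs):
        return pd.DataFrame(
            {"cell_type": "A", "mean_target": 0.5, "mean_rest": 0.5,
             "delta": deltas, "t": 0.0, "p": 0.5, "q": 0.01, "in_dhs": False},
            index=cpgs,
        )

    def test_top_k_orders_by_absolute_delta(self):
        dmcs = self._dmcs([0.7, -0.9, 0.8], ["cgC", "cgA", "cgB"])
        assert md.top_k_by_delta(dmcs, 2) == ["cgA", "cgB"]

    def test_top_k_truncates_to_available(self):
        dmcs = self._dmcs([0.5, 0.6], ["cg1", "cg2"])
        assert len(md.top_k_by_delta(dmcs, 100)) == 2

    def test_ties_break_lexicographically(self):
        dmcs = self._dmcs([0.8, -0.8], ["cgB", "cgA"])
        assert md.top_k_by_delta(dmcs, 1) == ["cgA"]

    def test_filter_to_dhs(self):
        dmcs = self._dmcs(np.linspace(0.1, 1, 10), [f"cg{i}" for i in range(10)])
        kept = md.filter_to_dhs(dmcs, {"cg0", "cg3", "cg5", "cg7"})
        assert len(kept) == 4 and kept["in_dhs"].all()
        assert len(md.filter_to_dhs(dmcs, set())) == 0
        assert len(md.filter_to_dhs(dmcs, set(dmcs.index) | {"cgX"})) == 10

    def test_centroid_is_replicate_mean(self):
        beta = make_beta([[0.2, 0.4, 0.6, 0.8]], samples=["a1", "a2", "b1", "b2"])
        data = md.PurifiedDataset(beta, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        ref = md.build_reference(data, ["cg0"])
        assert ref.data.loc["cg0", "A"] == pytest.approx(0.3)
        assert ref.data.loc["cg0", "B"] == pytest.approx(0.7)

    def test_missing_selected_cpg_rejected(self):
        beta = make_beta([[0.2, 0.6]], samples=["a1", "b1"])
        data = md.PurifiedDataset(beta, {"a1": "A", "b1": "B"})
        with pytest.raises(KeyError, match="cgX"):
            md.build_reference(data, ["cgX"])

    def test_union_row_count_mirrors_shared_picks(self):
        # 7 cell types x 50 picks with 17 CpGs shared between two types -> 333 rows
        picks = {}
        shared = [f"shared{i}" for i in range(17)]
        for c in range(7):
            own = [f"ct{c}_cg{i}" for i in range(50)]
            if c == 1:
                own = shared + own[17:]
            if c == 2:
                own = shared + own[17:]
            picks[f"CT{c}"] = own
        union = sorted(set().union(*picks.values()))
        assert len(union) == 333
        rng = np.random.default_rng(0)
        beta = make_beta(
            rng.uniform(size=(len(union), 7)), cpgs=union,
            samples=[f"s{c}" for c in range(7)],
        )
        data = md.PurifiedDataset(beta, {f"s{c}": f"CT{c}" for c in range(7)})
        ref = md.build_reference(data, union)
        assert ref.data.shape == (333, 7)
        assert not ref.data.index.has_duplicates

    def test_pipeline_without_dhs_is_same_code_path(self, blood_sim):
        ref_nodhs, picks = md.build_reference_pipeline(blood_sim.train, dhs_cpgs=None)
        union = set().union(*picks.values())
        assert set(ref_nodhs.cpg_ids) == union

    def test_planted_markers_dominate_top_k(self):
        cfg = md.SynthConfig(
            n_cell_types=3, n_cpgs=300, n_dmcs_per_type=10, seed=5,
            delta_range=(0.8, 0.9), replicate_sd=0.05,
        )
        sim = md.synth_purified_dataset(cfg)
        selected = md.select_dmcs_one_vs_rest(sim.train, 0.05)
        for ct in sim.train.cell_types:
            planted = set(sim.ground_truth.index[sim.ground_truth["cell_type"] == ct])
            assert planted <= set(selected[ct].index)
            top = set(md.top_k_by_delta(selected[ct], k=len(planted)))
            assert top == planted
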