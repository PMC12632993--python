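"""Generators: planted parameters must be exact and recoverable."""

import numpy as np
import pandas as pd
import pytest

from lossycomp import synthetic as syn
from lossycomp.containers import ValidationError
from lossycomp.neural import participation_ratio
from lossycomp.synthetic import (
    ContinuousParams,
    DesignError,
    MSTParams,
    ResponsePolicy,
    gen_responses,
)


class TestEmbeddingPairs:
    @pytest.mark.parametrize("dim", [2, 16, 64])
    def test_requested_separation_exact(self, dim):
        for angle in (0.1, np.pi / 2, 2.5):
            emb = syn.gen_embedding_pairs(5, dim, angle, seed=0)
            for pair in emb.pairs:
                t, l = emb.pair_vectors(pair)
                assert abs(t @ l - np.cos(angle)) < 1e-9
                assert abs(np.linalg.norm(t) - 1) < 1e-12
                assert abs(np.linalg.norm(l) - 1) < 1e-12

    def test_orthogonal_pair_has_unit_cosine_distance(self):
        emb = syn.gen_embedding_pairs(1, 8, np.pi / 2, seed=1)
        t, l = emb.pair_vectors(emb.pairs[0])
        assert abs((1 - t @ l) - 1.0) < 1e-9

    def test_small_angle_limit_vanishing_distance(self):
        emb = syn.gen_embedding_pairs(1, 8, 1e-6, seed=1)
        t, l = emb.pair_vectors(emb.pairs[0])
        assert 1 - t @ l < 1e-9

    def test_bitwise_reproducible(self):
        kw = dict(n_pairs=50, dim=64, separation=("uniform", 0.1, 1.5), seed=1)
        a = syn.gen_embedding_pairs(**kw)
        b = syn.gen_embedding_pairs(**kw)
        assert np.array_equal(a.items, b.items)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_pairs=0, dim=4, separation=0.5), dict(n_pairs=1, dim=1, separation=0.5),
         dict(n_pairs=1, dim=4, separation=0.0), dict(n_pairs=1, dim=4, separation=3.5)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            syn.gen_embedding_pairs(seed=0, **kwargs)


class TestShapeImages:
    def test_identical_factors_identical_pixels(self):
        row = pd.DataFrame([{"shape": "circle", "color": "red", "scale": 0.5,
                             "pos_x": 0.5, "pos_y": 0.5}] * 2)
        imgs = syn.gen_shape_images(2, 16, seed=0, factor_table=row)
        assert np.array_equal(imgs.images[0], imgs.images[1])

    def test_color_shift_confined_to_shape_mask(self):
        rows = pd.DataFrame([
            {"shape": "square", "color": "red", "scale": 0.5, "pos_x": 0.5, "pos_y": 0.5},
            {"shape": "square", "color": "blue", "scale": 0.5, "pos_x": 0.5, "pos_y": 0.5},
        ])
        imgs = syn.gen_shape_images(2, 16, seed=0, factor_table=rows)
        diff = np.abs(imgs.images[0] - imgs.images[1]).sum(axis=2)
        mask = syn._shape_mask("square", 16, 0.5, 0.5, 0.5)
        assert (diff[~mask] == 0).all()
        assert diff[mask].sum() > 0

    def test_reproducible_and_bounded(self):
        a = syn.gen_shape_images(10, 12, seed=3)
        b = syn.gen_shape_images(10, 12, seed=3)
        assert np.array_equal(a.images, b.images)
        assert a.images.min() >= 0 and a.images.max() <= 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            syn.gen_shape_images(0, 16, seed=0)


class TestTaskDesigns:
    def test_mst_counts(self, mst_table):
        assert (mst_table["phase"] == "study").sum() == 128
        assert (mst_table["phase"] == "test").sum() == 192

    def test_continuous_block_and_total_counts(self):
        table = syn.gen_task_tables("continuous", seed=0)
        assert len(table) == 642
        one = syn.gen_task_tables("continuous", ContinuousParams(n_blocks=1), seed=0)
        assert len(one) == 107
        comp = one["condition"].value_counts()
        assert comp["first"] == 32 and comp["repeat"] == 16
        assert comp["lure"] == 16 and comp["foil"] == 43

    def test_followers_always_after_first_presentation(self):
        table = syn.gen_task_tables("continuous", seed=5)
        first_pos = {
            r.stimulus: r.trial for r in table.itertuples() if r.condition == "first"
        }
        for r in table.itertuples():
            if r.condition in ("repeat", "lure"):
                base = r.stimulus.replace("_lure", "")
                assert first_pos[base] < r.trial

    def test_infeasible_lag_rejected(self):
        with pytest.raises(DesignError):
            syn.gen_task_tables("continuous", ContinuousParams(mean_lag=0.2), seed=0)

    def test_lure_bins_only_on_binnable_conditions(self, mst_table):
        binned = mst_table[mst_table["lure_bin"].notna()]
        assert set(binned["condition"]) <= {"lure", "repeat"}


class TestResponses:
    def test_full_discriminability_zero_bias_gives_perfect_ldi(self, mst_table):
        disc = {s: 1.0 for s in mst_table.loc[mst_table.condition == "lure", "stimulus"]}
        pol = ResponsePolicy(bias=(0.0, 0.0, 1.0), p_recognize=1.0, p_miss=0.0)
        t = gen_responses(mst_table, disc, pol, seed=0)
        lure = t[t.condition == "lure"]
        foil = t[t.condition == "foil"]
        assert (lure["response"] == "similar").all()
        assert (foil["response"] == "new").all()

    def test_zero_discriminability_equiprobable_bias_zero_expected_ldi(self):
        # bias-correction cancels: E[p(sim|lure)] == E[p(sim|foil)]
        base = syn.gen_task_tables("mst", MSTParams(n_study=64, n_test=96), seed=3)
        disc = {s: 0.0 for s in base.loc[base.condition == "lure", "stimulus"]}
        pol = ResponsePolicy(bias=(1 / 3, 1 / 3, 1 / 3), p_recognize=0.0, p_miss=0.0)
        diffs = []
        for rep in range(200):
            t = gen_responses(base, disc, pol, seed=rep)
            lure = t[(t.condition == "lure") & t.response.notna()]
            foil = t[(t.condition == "foil") & t.response.notna()]
            diffs.append((lure.response == "similar").mean() - (foil.response == "similar").mean())
        assert abs(np.mean(diffs)) < 0.02

    def test_bin_tied_discriminability_recovers_planted_order(self):
        from conftest import make_participants
        from lossycomp import behavior as bh
        from scipy.stats import spearmanr

        tables, _ = make_participants(30, seed0=50, disc_of_bin=lambda b: 0.15 * b)
        summaries = pd.concat([bh.compute_metrics(t).table for t in tables])
        per_bin = [summaries[f"ldi_bin{b}"].mean() for b in range(1, 6)]
        assert spearmanr(range(1, 6), per_bin).statistic == pytest.approx(1.0, abs=1e-9)

    def test_invalid_probabilities_rejected(self, mst_table):
        with pytest.raises(ValidationError):
            ResponsePolicy(bias=(0.5, 0.6, 0.2))
        with pytest.raises(ValidationError):
            disc = {s: 1.4 for s in mst_table.loc[mst_table.condition == "lure", "stimulus"]}
            gen_responses(mst_table, disc, seed=0)

    def test_reproducible(self, mst_table):
        disc = {s: 0.5 for s in mst_table.loc[mst_table.condition == "lure", "stimulus"]}
        a = gen_responses(mst_table, disc, seed=11)
        b = gen_responses(mst_table, disc, seed=11)
        assert a.equals(b)


class TestVoxelTimeseries:
    def test_planted_flat_spectrum_is_exact(self):
        lam = syn.planted_spectrum(10, 10)
        assert np.array_equal(lam, np.ones(10))
        lam1 = syn.planted_spectrum(5, 1)
        assert lam1[0] == 1 and lam1[1:].sum() == 0

    @pytest.mark.parametrize("er", [2.5, 7.0, 10.3, 119.0])
    def test_planted_spectrum_participation_ratio(self, er):
        lam = syn.planted_spectrum(120, er)
        pr = lam.sum() ** 2 / np.sum(lam**2)
        assert abs(pr - er) < 1e-9

    def test_estimator_generator_closure(self):
        region = syn.gen_voxel_timeseries(120, 1, 10.0, seed=7, n_timepoints=500)
        pr = participation_ratio(region.select(role="target")[0])
        assert abs(pr - 10.0) / 10.0 < 0.10

    def test_rank_exceeding_voxels_rejected(self):
        with pytest.raises(ValidationError):
            syn.gen_voxel_timeseries(10, 2, 11.0, seed=0)

    def test_reproducible_and_labelled(self):
        a = syn.gen_voxel_timeseries(20, 3, 4.0, ("coupled", 0.5), seed=2)
        b = syn.gen_voxel_timeseries(20, 3, 4.0, ("coupled", 0.5), seed=2)
        assert all(np.array_equal(x, y) for x, y in zip(a.trials, b.trials))
        assert set(a.labels["role"]) == {"target", "lure"}
        assert set(a.labels["outcome"]) == {"correct", "incorrect"}
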