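"""Fold construction, training loop, model selection, ensembling."""

import numpy as np
import pandas as pd
import pytest

from octseg.metrics import aggregate_boundary_errors
from octseg.phantom import generate_cohort
from octseg.segnet import NetConfig
from octseg.train import (FoldSplit, TrainConfig, average_fold_errors,
                          majority_vote, make_folds, run_experiment,
                          split_test_participants, train_fold)


@pytest.fixture(scope="module")
def tiny_cohort():
    from octseg.phantom import PhantomConfig

    cfg = PhantomConfig(height_px=48, width_px=64, n_slices=3,
                        axial_res_um=15.0, pit_depth_um=100.0,
                        rpe_depth_frac=0.75, undulation_amp_px=0.5,
                        speckle_scale=0.15, fleck_count=2)
    return generate_cohort(4, 1, 3, cfg, rng_seed=2)


@pytest.fixture(scope="module")
def tiny_net_cfg():
    return NetConfig(n_pool=4, base_filters=2, convs_per_level=2)


class TestFolds:
    def test_twelve_participants_six_folds_cover_everyone(self, desk_config):
        m = generate_cohort(12, 1, 3, desk_config, rng_seed=1)
        folds = make_folds(m, 6)
        assert len(folds) == 6
        seen = set()
        for f in folds:
            groups = m.groups()
            assert sorted(groups[p] for p in f.val_participants) == \
                ["high", "low"]
            assert len(f.train_participants) == 10
            seen.update(f.val_participants)
        assert seen == set(m.participant_ids())

    def test_same_manifest_gives_identical_folds(self, tiny_cohort):
        a = make_folds(tiny_cohort, 2)
        b = make_folds(tiny_cohort, 2)
        assert [(f.train_participants, f.val_participants) for f in a] == \
            [(f.train_participants, f.val_participants) for f in b]

    def test_two_participants_one_fold_rejected(self, desk_config):
        m = generate_cohort(2, 1, 3, desk_config, rng_seed=0)
        with pytest.raises(ValueError, match="empty training set"):
            make_folds(m, 1)

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FoldSplit(0, ["A", "B"], ["B"])

    def test_no_participant_in_both_sides(self, desk_config):
        m = generate_cohort(8, 2, 3, desk_config, rng_seed=3)
        for f in make_folds(m, 4):
            assert not set(f.train_participants) & set(f.val_participants)

    def test_split_test_participants_balanced(self, desk_config):
        m = generate_cohort(12, 1, 3, desk_config, rng_seed=1)
        tv, te = split_test_participants(m, 4)
        assert len(te.participants) == 4
        assert sorted(p.group for p in te.participants) == \
            ["high", "high", "low", "low"]
        assert not set(tv.participant_ids()) & set(te.participant_ids())


class TestTrainFold:
    def test_one_epoch_selects_that_checkpoint(self, tiny_cohort,
                                               tiny_net_cfg):
        folds = make_folds(tiny_cohort, 2)
        cfg = TrainConfig(epochs=1, n_runs=1, n_folds=2, seed=0)
        net, hist = train_fold(folds[0], tiny_cohort, tiny_net_cfg, cfg, 0)
        assert len(hist) == 1
        assert hist.attrs["best_val_dice"] == hist["val_dice"].iloc[0]

    def test_selected_dice_is_history_maximum(self, tiny_cohort,
                                              tiny_net_cfg):
        folds = make_folds(tiny_cohort, 2)
        cfg = TrainConfig(epochs=3, n_runs=1, n_folds=2, seed=1)
        net, hist = train_fold(folds[0], tiny_cohort, tiny_net_cfg, cfg, 1)
        assert hist.attrs["best_val_dice"] == hist["val_dice"].max()

    def test_augmentation_can_be_disabled(self, tiny_cohort, tiny_net_cfg):
        folds = make_folds(tiny_cohort, 2)
        cfg = TrainConfig(epochs=1, n_runs=1, n_folds=2, seed=0,
                          augment=False)
        net, hist = train_fold(folds[0], tiny_cohort, tiny_net_cfg, cfg, 0)
        assert np.isfinite(hist["train_loss"].iloc[0])


class TestRunExperiment:
    def test_single_cell_aggregate_equals_model_metric(self, tiny_cohort,
                                                       tiny_net_cfg):
        cfg = TrainConfig(epochs=1, n_runs=1, n_folds=1, seed=5)
        models, report = run_experiment(tiny_cohort, tiny_net_cfg, cfg)
        assert len(models) == 1
        assert report.attrs["mean_val_dice"] == \
            report["best_val_dice"].iloc[0]

    def test_seed_ledger_formula(self):
        cfg = TrainConfig(seed=17)
        assert cfg.run_fold_seed(2, 3) == 17 + 2000 + 3


class TestMajorityVote:
    def test_single_map_is_identity(self):
        lab = np.array([[0, 1], [2, 2]])
        assert np.array_equal(majority_vote([lab]), lab)

    def test_strict_majority_wins(self):
        votes = [1, 1, 1, 2, 2, 0]
        maps = [np.full((1, 1), v) for v in votes]
        assert majority_vote(maps)[0, 0] == 1

    def test_tie_broken_by_mean_probability(self):
        votes = [1, 1, 2, 2, 0, 0]
        maps = [np.full((1, 1), v) for v in votes]
        probs = [np.array([0.2, 0.45, 0.35]).reshape(3, 1, 1)] * 6
        assert majority_vote(maps, prob_maps=probs)[0, 0] == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([np.zeros((2, 2)), np.zeros((3, 3))])


class TestAverageFoldErrors:
    def _table(self, mae):
        return pd.DataFrame({"boundary": ["ILM", "RPE"],
                             "mae_px": [mae, mae + 1],
                             "me_px": [0.0, 0.1]})

    def test_identical_tables_unchanged(self):
        t = self._table(1.0)
        avg = average_fold_errors([t, t]).set_index("boundary")
        assert avg.loc["ILM", "mae_px"] == 1.0

    def test_two_fold_mean(self):
        avg = average_fold_errors([self._table(1.0),
                                   self._table(2.0)]).set_index("boundary")
        assert avg.loc["ILM", "mae_px"] == 1.5

    def test_random_tables_match_direct_mean(self, rng):
        tables = [self._table(rng.random()) for _ in range(6)]
        avg = average_fold_errors(tables).set_index("boundary")
        direct = np.mean([t["mae_px"].iloc[0] for t in tables])
        assert avg.loc["ILM", "mae_px"] == pytest.approx(direct)


class TestEnsembleAgreement:
    def test_agreeing_folds_make_both_paths_identical(self, tiny_cohort):
        """When every fold produces the same (clean) probability map, the
        ensemble path (vote + one graph search) and the average path
        (graph search per fold, errors averaged) give identical boundary
        errors."""
        from octseg.graphsearch import extract_boundaries
        from octseg.preprocess import (boundaries_to_regions, onehot_regions,
                                       pad_top)

        vol = tiny_cohort.participants[0].volumes[0]
        per_fold_pairs = {0: [], 1: []}
        ens_pairs = []
        for scan, truth in zip(vol.bscans, vol.boundaries):
            _, shifted = pad_top(scan.pixels, truth, 16)
            labels = boundaries_to_regions(shifted, scan.height_px + 16,
                                           scan.width_px)
            probs = onehot_regions(labels)  # what converged folds emit
            for k in per_fold_pairs:
                per_fold_pairs[k].append(
                    (extract_boundaries(probs, pad_rows=16), truth))
            voted = majority_vote([labels, labels],
                                  prob_maps=[probs, probs])
            ens_pairs.append((extract_boundaries(voted, pad_rows=16), truth))
        tables = [aggregate_boundary_errors(per_fold_pairs[k])
                  for k in per_fold_pairs]
        avg = average_fold_errors(tables).set_index("boundary")
        ens = aggregate_boundary_errors(ens_pairs).set_index("boundary")
        assert np.allclose(avg["mae_px"], ens["mae_px"])
        assert np.allclose(avg["me_px"], ens["me_px"])
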