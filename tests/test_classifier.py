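"""Concordant/discordant/block labelling and APD-node localisation."""

import numpy as np
import pytest

from alternans.alternans_classifier import (
    APDField,
    block_site_di,
    classify_strand,
    locate_nodes,
    phase_map,
)
from alternans.errors import ConfigError, InsufficientDataError, NotApplicableError
from alternans.synthetic_data import synth_apd_field
from alternans.tissue_solver import SpaceTimeField


class TestClassification:
    def test_planted_concordant(self):
        fld, _ = synth_apd_field("concordant")
        res = classify_strand(fld)
        assert res.label == "concordant" and res.sub_label == "concordant"

    def test_planted_discordant_with_node_at_boundary(self):
        fld, truth = synth_apd_field("discordant", node_position=18.0)
        res = classify_strand(fld)
        assert res.label == "discordant"
        assert abs(res.node_positions.min() - 18.0) <= fld.dx

    def test_planted_block_with_beat_index(self):
        fld, truth = synth_apd_field("block")
        res = classify_strand(fld)
        assert res.label == "block"
        assert res.block_beat == truth["block_beat"]
        assert res.block_node == truth["block_node"]

    def test_no_alternans_folds_into_concordant(self):
        fld, _ = synth_apd_field("concordant", apd_delta=0.0)
        res = classify_strand(fld)
        assert res.label == "concordant" and res.sub_label == "no_alternans"

    def test_cyclic_beat_shift_leaves_label_unchanged(self):
        for kind in ("concordant", "discordant"):
            fld, _ = synth_apd_field(kind, n_beats=14)
            base = classify_strand(fld).label
            rolled = APDField(
                apd=np.vstack([fld.apd[:5], np.roll(fld.apd[5:], 2, axis=0)]),
                activation=np.vstack(
                    [fld.activation[:5], np.roll(fld.activation[5:], 2, axis=0)]
                ),
                stim_times=fld.stim_times,
                dx=fld.dx,
            )
            assert classify_strand(rolled).label == base

    def test_too_few_beats_rejected(self):
        fld, _ = synth_apd_field("concordant", n_beats=8)
        with pytest.raises(InsufficientDataError):
            classify_strand(fld)  # 8 - 5 transient < 6

    def test_random_planted_nodes_recovered_within_one_node(self, rng):
        for _ in range(20):
            pos = rng.uniform(5.0, 25.0)
            fld, _ = synth_apd_field("discordant", node_position=pos)
            res = classify_strand(fld)
            assert res.label == "discordant"
            nearest = res.node_positions[np.argmin(np.abs(res.node_positions - pos))]
            assert abs(nearest - pos) <= fld.dx


class TestLocateNodes:
    def test_concordant_field_has_no_nodes(self):
        fld, _ = synth_apd_field("concordant")
        assert locate_nodes(fld).size == 0

    def test_first_node_distance_from_stim_site(self):
        fld, _ = synth_apd_field("discordant", node_position=21.0)
        res = classify_strand(fld)
        assert res.first_node_distance == pytest.approx(21.0, abs=fld.dx)


class TestBlockSiteDI:
    @staticmethod
    def _field_with_planted_di(di):
        # beat 6 arrives at the block node exactly `di` ms after the previous
        # beat's 90% repolarisation there
        fld, truth = synth_apd_field("block", n_beats=12, block_beat=6,
                                     block_node=100)
        bn = truth["block_node"]
        prev_end = fld.activation[5, bn] + fld.apd[5, bn]
        fld.activation[6, bn] = prev_end + di
        return fld

    def test_planted_di_recovered(self):
        fld = self._field_with_planted_di(20.0)
        di, collision = block_site_di(fld)
        assert di == pytest.approx(20.0) and not collision

    def test_arrival_at_repolarisation_flags_collision(self):
        fld = self._field_with_planted_di(0.0)
        di, collision = block_site_di(fld)
        assert di == 0.0 and collision

    def test_not_applicable_without_block(self):
        fld, _ = synth_apd_field("concordant")
        with pytest.raises(NotApplicableError):
            block_site_di(fld)


class TestBuildApdFieldContract:
    def test_coarse_frames_rejected(self):
        from alternans.alternans_classifier import build_apd_field

        fld = SpaceTimeField(v=np.zeros((10, 5), np.float32), dt_save=5.0,
                             dx=0.15, stim_times=np.array([10.0]))
        with pytest.raises(ConfigError):
            build_apd_field(fld)


class TestPhaseMap:
    def test_grid_fully_labelled_with_failures_contained(self):
        def runner(pcl, sg):
            if sg > 1.2 and pcl < 150:
                raise RuntimeError("simulated blow-up")
            kind = ("block" if pcl < 150 else
                    "discordant" if pcl < 170 else "concordant")
            return synth_apd_field(kind)[0]

        pm = phase_map([180.0, 160.0, 140.0], [0.8, 1.0, 1.4], runner)
        assert pm.labels.shape == (3, 3)
        assert pm.labels[0].tolist() == ["concordant"] * 3
        assert pm.labels[1].tolist() == ["discordant"] * 3
        assert pm.labels[2].tolist() == ["block", "block", "failed"]
        df = pm.to_frame()
        assert set(df.columns) >= {"pcl_ms", "s_gna", "label", "sub_label",
                                   "first_node_distance_mm", "block_di_ms"}

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigError):
            phase_map([], [1.0], lambda p, s: None)

    def test_cache_prevents_recomputation(self):
        calls = []

        def runner(pcl, sg):
            calls.append((pcl, sg))
            return synth_apd_field("concordant")[0]

        cache = {}
        phase_map([160.0], [1.0], runner, cache=cache)
        phase_map([160.0], [1.0], runner, cache=cache)
        assert len(calls) == 1
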