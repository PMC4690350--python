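"""Thresholding and percent-area overlap: exact counting identities,
symmetry, monotonicity, and recovery of embedded overlap fractions."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compartquant import CYTOPLASM, NUCLEUS, CompartmentMasks
from compartquant.colocalization import (coloc_condition_summary, coloc_per_cell,
                                         fix_thresholds, records_table,
                                         threshold_channel)


def square_masks(n: int = 24) -> CompartmentMasks:
    cell = np.zeros((n, n), dtype=np.int32)
    nucleus = np.zeros_like(cell)
    cell[2:-2, 2:-2] = 1
    nucleus[8:-8, 8:-8] = 1
    cyt = np.where((cell > 0) & (nucleus == 0), 1, 0).astype(np.int32)
    return CompartmentMasks(cell, nucleus, np.zeros_like(cell), cyt)


class TestThresholdChannel:
    def test_zero_threshold_on_positive_image_is_all_true(self):
        assert threshold_channel(np.ones((3, 3)), 0.0).all()

    def test_threshold_above_max_is_empty(self):
        assert not threshold_channel(np.full((3, 3), 5.0), 9.0).any()

    def test_strict_inequality(self):
        out = threshold_channel(np.array([1.0, 5.0, 9.0]), 5.0)
        assert np.array_equal(out, [False, False, True])

    @given(st.floats(0, 50), st.floats(0, 60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raising_threshold_never_grows_area(self, t1, t2):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 60, size=(16, 16))
        lo, hi = sorted((t1, t2))
        assert threshold_channel(img, hi).sum() <= threshold_channel(img, lo).sum()


class TestFixThresholds:
    def test_fixed_value_passthrough(self):
        out = fix_thresholds({"channel_A": np.arange(10.0)}, "fixed",
                             values={"channel_A": 42.0})
        assert out == {"channel_A": 42.0}

    def test_otsu_between_bimodal_modes_and_matches_exhaustive_search(self, rng):
        pool = np.concatenate([rng.normal(10, 1, 4000), rng.normal(100, 5, 4000)])
        pool = np.clip(pool, 0, None)
        t = fix_thresholds({"channel_A": pool}, "otsu")["channel_A"]
        assert 10 < t < 100
        # exhaustive between-class-variance search over 256 bins
        counts, edges = np.histogram(pool, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        best, best_t = -1.0, None
        for k in range(1, 256):
            w0, w1 = counts[:k].sum(), counts[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[:k] * centers[:k]).sum() / w0
            m1 = (counts[k:] * centers[k:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best:
                best, best_t = v, centers[k - 1]
        assert t == pytest.approx(best_t, abs=(edges[1] - edges[0]) * 2)

    def test_order_invariance(self, rng):
        pool = rng.uniform(0, 100, 5000)
        t1 = fix_thresholds({"c": pool}, "otsu")["c"]
        t2 = fix_thresholds({"c": rng.permutation(pool)}, "otsu")["c"]
        assert t1 == t2

    def test_constant_pool_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fix_thresholds({"c": np.full(100, 3.0)}, "otsu")

    def test_percentile_method(self):
        pool = np.arange(101, dtype=float)
        t = fix_thresholds({"c": pool}, "percentile", percentile=90)["c"]
        assert t == pytest.approx(90.0)


class TestColocPerCell:
    def test_identical_masks_give_100_100(self):
        masks = square_masks()
        m = masks.nucleus_labels > 0
        recs = coloc_per_cell(m, m, masks, 1)
        nuc = [r for r in recs if r.compartment == NUCLEUS][0]
        assert nuc.pct_a_in_b == 100.0 and nuc.pct_b_in_a == 100.0

    def test_disjoint_masks_give_0_0(self):
        masks = square_masks()
        a = np.zeros_like(masks.cell_labels, dtype=bool)
        b = np.zeros_like(a)
        a[9:11, 9:20] = True
        b[12:14, 9:20] = True
        nuc = [r for r in coloc_per_cell(a, b, masks, 1)
               if r.compartment == NUCLEUS][0]
        assert nuc.pct_a_in_b == 0.0 and nuc.pct_b_in_a == 0.0

    def test_counting_arithmetic(self):
        masks = square_masks(32)
        a = np.zeros_like(masks.cell_labels, dtype=bool)
        b = np.zeros_like(a)
        a[9, 8:18] = True            # 10 px inside nucleus
        b[9, 8:18] = True
        b[10, 8:18] = True           # 20 px, 10 shared
        nuc = [r for r in coloc_per_cell(a, b, masks, 1)
               if r.compartment == NUCLEUS][0]
        assert (nuc.area_a, nuc.area_b, nuc.shared) == (10, 20, 10)
        assert nuc.pct_a_in_b == 100.0 and nuc.pct_b_in_a == 50.0

    def test_zero_area_flagged_undefined(self):
        masks = square_masks()
        empty = np.zeros_like(masks.cell_labels, dtype=bool)
        full = masks.nucleus_labels > 0
        nuc = [r for r in coloc_per_cell(empty, full, masks, 1)
               if r.compartment == NUCLEUS][0]
        assert nuc.pct_a_in_b is None and nuc.pct_b_in_a == 0.0

    def test_unknown_cell_raises(self):
        masks = square_masks()
        m = masks.nucleus_labels > 0
        with pytest.raises(KeyError):
            coloc_per_cell(m, m, masks, 99)

    @given(st.integers(0, 2 ** 20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_identity_and_symmetry(self, seed):
        """pct_a_in_b·area_a = pct_b_in_a·area_b = 100·shared exactly (as
        rationals over the stored integer counts), and swapping channels
        swaps areas and percentages."""
        rng = np.random.default_rng(seed)
        masks = square_masks()
        a = rng.random((24, 24)) < rng.uniform(0, 1)
        b = rng.random((24, 24)) < rng.uniform(0, 1)
        for rec, swapped in zip(coloc_per_cell(a, b, masks, 1),
                                coloc_per_cell(b, a, masks, 1)):
            if rec.area_a:
                assert Fraction(100 * rec.shared, rec.area_a) * rec.area_a \
                    == 100 * rec.shared
                assert rec.pct_a_in_b == pytest.approx(
                    100 * rec.shared / rec.area_a)
            assert rec.shared <= min(rec.area_a, rec.area_b) \
                if (rec.area_a and rec.area_b) else True
            assert (rec.area_a, rec.area_b) == (swapped.area_b, swapped.area_a)
            assert rec.pct_a_in_b == swapped.pct_b_in_a


class TestColocSummary:
    def _records(self, values, condition="control", compartment=NUCLEUS):
        rows = []
        for i, v in enumerate(values, 1):
            rows.append({"field_id": "f", "cell_id": i, "condition": condition,
                         "replicate": "rep1", "compartment": compartment,
                         "area_a": 10, "area_b": 10, "shared": int(v / 10),
                         "pct_a_in_b": v, "pct_b_in_a": v, "pixel_area": 0.14,
                         "pct_a_defined": True, "pct_b_defined": True})
        return pd.DataFrame(rows)

    def test_constant_input_mean_100_sem_0(self):
        s = coloc_condition_summary(self._records([100.0] * 12))
        nuc = s[(s["compartment"] == NUCLEUS) & (s["direction"] == "pct_b_in_a")]
        assert nuc["mean"].item() == 100.0
        assert nuc["sem"].item() == 0.0

    def test_nine_cells_flagged_below_minimum(self):
        s = coloc_condition_summary(self._records([50.0] * 9), min_cells=10)
        assert s["below_min_cells"].all()

    def test_undefined_percentages_excluded_not_zeroed(self):
        recs = self._records([80.0] * 10)
        recs.loc[0, ["pct_b_in_a"]] = np.nan
        recs.loc[0, "pct_b_defined"] = False
        s = coloc_condition_summary(recs)
        nuc = s[(s["compartment"] == NUCLEUS) & (s["direction"] == "pct_b_in_a")]
        assert nuc["mean"].item() == 80.0
        assert nuc["n_undefined"].item() == 1
        assert nuc["n_cells"].item() == 9


class TestEmbeddedFractionRecovery:
    def test_embedded_nuclear_fraction_recovered(self):
        """A field with f=0.38 nuclear B-in-A puncta yields per-cell records
        whose mean pct_b_in_a is within a few points of 38."""
        from compartquant import SimulationConfig, generate_field
        from compartquant.segmentation import correct_background
        from compartquant.synthetic import puncta_midpoint_threshold
        cfg = SimulationConfig(
            n_cells=10, field_size=(320, 320), seed=17,
            coloc_fractions={c: {NUCLEUS: 0.38, CYTOPLASM: 0.38}
                             for c in ("control",)})
        field, truth = generate_field(cfg, "control")
        t = puncta_midpoint_threshold(cfg)
        recs = []
        for cid in truth.masks.cell_ids:
            a = threshold_channel(
                correct_background(field["channel_A"], cfg.background_level), t)
            b = threshold_channel(
                correct_background(field["channel_B"], cfg.background_level), t)
            recs.extend(coloc_per_cell(a, b, truth.masks, cid))
        table = records_table(recs)
        nuc = table[table["compartment"] == NUCLEUS]
        assert nuc["pct_b_in_a"].mean() == pytest.approx(38.0, abs=4.0)
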