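"""AR_cell arithmetic, gating, histogram report, mask overlays."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellqc import CellFeatureTable, LabelMask, gate_images, histogram_report, render_mask, score_images
from cellqc.exceptions import ParameterError, SchemaError
from cellqc.scoring import COLOR_ARTIFACT, COLOR_UNKNOWN, COLOR_VALID


def _tables(areas, artifact_flags, image_id="w0"):
    n = len(areas)
    cells = CellFeatureTable(
        pd.DataFrame(
            {
                "image_id": image_id,
                "object_id": np.arange(1, n + 1),
                "area_px": areas,
                "d0": np.zeros(n),
            }
        )
    )
    verdicts = pd.DataFrame(
        {
            "image_id": image_id,
            "object_id": np.arange(1, n + 1),
            "is_artifact": artifact_flags,
        }
    )
    return cells, verdicts


class TestScoreImages:
    def test_mixed_areas_exact_ratio(self):
        cells, verdicts = _tables([100, 300], [False, True])
        res = score_images(verdicts, cells)
        assert res.loc[0, "ar_cell"] == pytest.approx(0.75)
        assert res.loc[0, "artifact_area_px"] == 300
        assert res.loc[0, "total_area_px"] == 400

    def test_all_artifact_is_one(self):
        cells, verdicts = _tables([50, 60, 70], [True, True, True])
        assert score_images(verdicts, cells).loc[0, "ar_cell"] == 1.0

    def test_no_artifact_is_zero(self):
        cells, verdicts = _tables([50, 60], [False, False])
        assert score_images(verdicts, cells).loc[0, "ar_cell"] == 0.0

    def test_zero_object_image_undefined(self):
        cells, verdicts = _tables([100], [True])
        res = score_images(verdicts, cells, all_image_ids=["w0", "empty"])
        row = res.set_index("image_id").loc["empty"]
        assert row["n_objects"] == 0
        assert np.isnan(row["ar_cell"])

    def test_unknown_object_key_is_schema_error(self):
        cells, verdicts = _tables([100], [True])
        verdicts.loc[0, "object_id"] = 99
        with pytest.raises(SchemaError):
            score_images(verdicts, cells)


@settings(max_examples=1000, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(min_value=1, max_value=10_000), st.booleans()),
        min_size=1,
        max_size=12,
    ),
    st.integers(min_value=0, max_value=11),
)
def test_ar_cell_properties(objects, flip_idx):
    """Bounds, area conservation, and strict monotonicity of AR_cell."""
    areas = [a for a, _ in objects]
    flags = [f for _, f in objects]
    cells, verdicts = _tables(areas, flags)
    res = score_images(verdicts, cells).iloc[0]
    assert 0.0 <= res["ar_cell"] <= 1.0
    # conservation: artifact + valid = total, exactly
    valid_area = sum(a for a, f in objects if not f)
    assert res["artifact_area_px"] + valid_area == res["total_area_px"]
    assert res["total_area_px"] == sum(areas)
    # flipping one valid verdict to artifact strictly increases the ratio
    i = flip_idx % len(objects)
    if not flags[i]:
        flipped = list(flags)
        flipped[i] = True
        cells2, verdicts2 = _tables(areas, flipped)
        res2 = score_images(verdicts2, cells2).iloc[0]
        assert res2["ar_cell"] > res["ar_cell"]


class TestGateImages:
    def _results(self, ars):
        return pd.DataFrame(
            {"image_id": [f"w{i}" for i in range(len(ars))], "ar_cell": ars}
        )

    def test_strictly_greater_than_threshold(self):
        res = self._results([0.1, 0.51, 0.49, 0.5])
        kept, excluded = gate_images(res, threshold=0.5)
        assert excluded["image_id"].tolist() == ["w1"]
        assert "w3" in kept  # exactly at threshold is kept

    def test_threshold_one_keeps_all_defined(self):
        res = self._results([0.0, 0.5, 1.0, np.nan])
        kept, excluded = gate_images(res, threshold=1.0)
        assert set(kept) == {"w0", "w1", "w2"}
        assert excluded["reason"].tolist() == ["no objects"]

    def test_undefined_keep_policy(self):
        res = self._results([np.nan, 0.2])
        kept, excluded = gate_images(res, threshold=0.5, undefined_policy="keep")
        assert set(kept) == {"w0", "w1"}

    def test_invalid_threshold(self):
        with pytest.raises(ParameterError):
            gate_images(self._results([0.1]), threshold=1.5)


class TestHistogramReport:
    def test_counts_cover_defined_images(self):
        res = pd.DataFrame({"image_id": list("abcde"),
                            "ar_cell": [0.0, 0.2, 0.9, np.nan, 0.2]})
        report = histogram_report(res, bins=10)
        assert sum(report["counts"]) == 4
        assert report["n_undefined"] == 1
        assert set(report["quantiles"]) == {"p50", "p90", "p99"}

    def test_all_zero_single_bin(self):
        res = pd.DataFrame({"image_id": list("abc"), "ar_cell": [0.0, 0.0, 0.0]})
        report = histogram_report(res, bins=10)
        assert report["counts"][0] == 3
        assert sum(report["counts"][1:]) == 0

    def test_uniform_scores_spread_within_multinomial_tolerance(self):
        rng = np.random.default_rng(19)
        n, bins = 5000, 10
        res = pd.DataFrame(
            {"image_id": [f"w{i}" for i in range(n)], "ar_cell": rng.uniform(size=n)}
        )
        counts = np.array(histogram_report(res, bins=bins)["counts"])
        expected = n / bins
        assert (np.abs(counts - expected) < 5 * np.sqrt(expected)).all()

    def test_empty_input(self):
        report = histogram_report(pd.DataFrame(columns=["image_id", "ar_cell"]))
        assert report["counts"] == [] and report["n_defined"] == 0


class TestRenderMask:
    def _mask(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:8, 2:8] = 1
        labels[20:28, 20:30] = 2
        return LabelMask("w0", labels)

    def test_three_pixel_classes(self):
        mask = self._mask()
        verdicts = pd.DataFrame({"object_id": [1, 2], "is_artifact": [True, False]})
        rgb = render_mask(mask, verdicts, annotate=False)
        colors = {tuple(c) for c in rgb.reshape(-1, 3)}
        assert colors == {(0, 0, 0), COLOR_ARTIFACT, COLOR_VALID}

    def test_pixel_count_conservation(self):
        mask = self._mask()
        verdicts = pd.DataFrame({"object_id": [1, 2], "is_artifact": [True, False]})
        rgb = render_mask(mask, verdicts, annotate=False)
        assert (rgb == COLOR_ARTIFACT).all(axis=-1).sum() == (mask.labels == 1).sum()
        assert (rgb == COLOR_VALID).all(axis=-1).sum() == (mask.labels == 2).sum()

    def test_unknown_label_rendered_gray_with_warning(self, caplog):
        mask = self._mask()
        verdicts = pd.DataFrame({"object_id": [1], "is_artifact": [True]})
        with caplog.at_level("WARNING", logger="cellqc"):
            rgb = render_mask(mask, verdicts, annotate=False)
        assert (rgb == COLOR_UNKNOWN).all(axis=-1).any()
        assert "no verdict" in caplog.text

    def test_empty_mask_annotated(self):
        mask = LabelMask("w0", np.zeros((32, 48), dtype=np.int32))
        verdicts = pd.DataFrame({"object_id": [], "is_artifact": []})
        rgb = render_mask(mask, verdicts, annotate=True)
        assert rgb.shape == (32, 48, 3)
        # the white "0 objects" annotation is the only non-background ink
        # (antialiased glyph edges allowed)
        bright = (rgb > 128).all(axis=-1)
        assert bright.any()

    def test_deterministic_pixels(self):
        mask = self._mask()
        verdicts = pd.DataFrame({"object_id": [1, 2], "is_artifact": [True, False]})
        a = render_mask(mask, verdicts)
        b = render_mask(mask, verdicts)
        np.testing.assert_array_equal(a, b)
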