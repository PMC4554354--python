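import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

from focicount import (AnalysisParams, ChannelAssignment, ColocParams,
                       ConfigurationError, FociParams, InputError,
                       MeasureParams, SegmentationParams, SyntheticSpec,
                       analyze_image, bundle_results, export_results,
                       generate_image, run_batch)
from focicount.config import load_params, load_spec
from focicount.image_io import save_multichannel_tiff

# analysis configuration matched to the synthetic defaults: noise level at
# 4 sigma of the background noise, cutoff halfway up a focus peak
NOISE_LEVEL = 24.0
CUTOFF = 140.0


def _params(**kw):
    base = dict(
        assignment=ChannelAssignment(roi_channel=0, foci1_channel=1),
        seg=SegmentationParams(min_area=150),
        foci=FociParams(noise_level_1=NOISE_LEVEL, cutoff_1=CUTOFF),
        measure=MeasureParams(),
    )
    base.update(kw)
    return AnalysisParams(**base)


def _write_tree(tmp_path, specs, subdirs=None):
    """Write synthetic multi-channel TIFFs into a folder tree."""
    subdirs = subdirs or [""] * len(specs)
    paths = []
    for i, (spec, sub) in enumerate(zip(specs, subdirs)):
        img, _ = generate_image(spec)
        d = tmp_path / sub if sub else tmp_path
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"img_{i}.tif"
        save_multichannel_tiff(p, img)
        paths.append(p)
    return paths


class TestAnalyzeImage:
    def test_planted_counts_recovered_per_roi(self):
        spec = SyntheticSpec(n_nuclei=5, foci_per_nucleus=4, seed=31)
        img, _ = generate_image(spec)
        res = analyze_image(img, _params(), name="synthetic")
        assert len(res.roi_records) == 5
        assert [r.foci_count_1 for r in res.roi_records] == [4] * 5
        assert res.image_row["mean_foci_1"] == pytest.approx(4.0)

    def test_zero_foci_image(self):
        spec = SyntheticSpec(n_nuclei=3, foci_per_nucleus=0, seed=32)
        img, _ = generate_image(spec)
        res = analyze_image(img, _params(), name="empty")
        assert [r.foci_count_1 for r in res.roi_records] == [0, 0, 0]
        assert res.image_row["mean_foci_1"] == 0.0

    def test_roi_export_order_is_label_order_from_one(self):
        spec = SyntheticSpec(n_nuclei=6, foci_per_nucleus=2, seed=33)
        img, _ = generate_image(spec)
        res = analyze_image(img, _params(), name="x")
        assert [r.roi_id for r in res.roi_records] == list(range(1, 7))

    def test_foci2_consistency_enforced_at_params_level(self):
        with pytest.raises(ConfigurationError):
            _params(foci=FociParams(noise_level_1=5, noise_level_2=5))
        with pytest.raises(ConfigurationError):
            _params(coloc=ColocParams())


class TestRunBatch:
    def test_batch_mean_is_mean_of_image_means(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=4, foci_per_nucleus=c, seed=40 + c)
                 for c in (2, 4, 6)]
        _write_tree(tmp_path, specs, subdirs=["", "sub", "sub/deep"])
        bundle = run_batch(tmp_path, _params())
        assert len(bundle.per_image) == 3
        got = sorted(bundle.per_image["mean_foci_1"])
        assert got == pytest.approx([2.0, 4.0, 6.0])
        summary = bundle.batch_summary
        mean_row = summary[summary["aggregation"] == "mean_of_images"].iloc[0]
        assert mean_row["mean_foci_1"] == pytest.approx(4.0)

    def test_degenerate_image_recorded_and_batch_continues(self, tmp_path):
        _write_tree(tmp_path, [SyntheticSpec(n_nuclei=3, foci_per_nucleus=1,
                                             seed=50)])
        # constant image: auto threshold must fail for this file only
        import tifffile
        blank = np.full((2, 64, 64), 17, dtype=np.uint8)
        tifffile.imwrite(tmp_path / "a_blank.tif", blank,
                         photometric="minisblack")
        bundle = run_batch(tmp_path, _params())
        assert len(bundle.per_image) == 1
        assert len(bundle.failures) == 1
        assert "a_blank.tif" in bundle.failures[0][0]
        assert bundle.status == 2

    def test_corrupt_file_contained(self, tmp_path):
        _write_tree(tmp_path, [SyntheticSpec(n_nuclei=2, foci_per_nucleus=3,
                                             seed=51)])
        (tmp_path / "bad.tif").write_bytes(b"not a tiff at all")
        bundle = run_batch(tmp_path, _params())
        assert len(bundle.per_image) == 1
        assert any("bad.tif" in f[0] for f in bundle.failures)

    def test_empty_tree_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            run_batch(tmp_path, _params())


class TestAggregationConsistency:
    def test_per_image_recomputable_from_per_roi(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=4, foci_per_nucleus=c, seed=60 + c)
                 for c in (1, 5)]
        _write_tree(tmp_path, specs)
        bundle = run_batch(
            tmp_path, _params(measure=MeasureParams(percentile=80.0)))
        roi = bundle.per_roi
        for _, row in bundle.per_image.iterrows():
            kept = roi[(roi["image"] == row["image"])
                       & (~roi["excluded_by_percentile"])]
            assert row["mean_foci_1"] == pytest.approx(
                kept["foci_count_1"].mean())
            assert row["n_foci_1"] == kept["foci_count_1"].sum()

    def test_summary_recomputable_from_per_image(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=3, foci_per_nucleus=c, seed=70 + c)
                 for c in (0, 3, 6)]
        _write_tree(tmp_path, specs)
        bundle = run_batch(tmp_path, _params())
        summary = bundle.batch_summary
        mean_row = summary[summary["aggregation"] == "mean_of_images"].iloc[0]
        for col in ("mean_foci_1", "n_rois", "mean_density_1"):
            assert mean_row[col] == pytest.approx(
                bundle.per_image[col].mean())

    def test_no_focus_lost_by_percentile_flagging(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=5,
                               foci_per_nucleus=[1, 2, 2, 3, 9], seed=80)]
        _write_tree(tmp_path, specs)
        bundle = run_batch(
            tmp_path, _params(measure=MeasureParams(percentile=80.0)))
        assert bundle.per_roi["excluded_by_percentile"].sum() == 1
        assert bundle.per_roi["foci_count_1"].sum() == len(bundle.per_focus)


class TestExport:
    def test_csv_manifest_and_determinism(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=3, foci_per_nucleus=2, seed=90)]
        _write_tree(tmp_path / "in", specs)
        outs = []
        for run in ("one", "two"):
            params = _params(output_dir=str(tmp_path / run))
            bundle = run_batch(tmp_path / "in", params)
            export_results(bundle, params)
            outs.append(tmp_path / run)
        expected = {"per_focus.csv", "per_roi.csv", "per_image.csv",
                    "summary.csv", "failures.csv", "run_metadata.json"}
        assert expected <= {p.name for p in outs[0].iterdir()}
        for name in ("per_focus.csv", "per_roi.csv", "per_image.csv",
                     "summary.csv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_xlsx_mirrors_csv_sheets(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=2, foci_per_nucleus=1, seed=91)]
        _write_tree(tmp_path / "in", specs)
        params = _params(output_dir=str(tmp_path / "out"),
                         output_formats=("csv", "xlsx"))
        bundle = run_batch(tmp_path / "in", params)
        export_results(bundle, params)
        book = pd.read_excel(tmp_path / "out" / "results.xlsx",
                             sheet_name=None)
        assert {"per_focus", "per_roi", "per_image", "summary"} <= set(book)
        csv_roi = pd.read_csv(tmp_path / "out" / "per_roi.csv")
        assert len(book["per_roi"]) == len(csv_roi)

    def test_metadata_echoes_parameters(self, tmp_path):
        specs = [SyntheticSpec(n_nuclei=2, foci_per_nucleus=1, seed=92)]
        _write_tree(tmp_path / "in", specs)
        params = _params(output_dir=str(tmp_path / "out"))
        bundle = run_batch(tmp_path / "in", params)
        export_results(bundle, params)
        meta = json.loads((tmp_path / "out" / "run_metadata.json").read_text())
        assert meta["parameters"]["foci"]["noise_level_1"] == NOISE_LEVEL
        assert meta["parameters"]["seg"]["min_area"] == 150


class TestConfig:
    def _cfg(self, tmp_path, **overrides):
        cfg = {
            "input": {"roi_channel": 0, "foci1_channel": 1},
            "seg": {"min_area": 150},
            "foci": {"noise_level_1": NOISE_LEVEL, "cutoff_1": CUTOFF},
            "output": {"dir": str(tmp_path / "res")},
        }
        cfg.update(overrides)
        p = tmp_path / "config.yaml"
        p.write_text(yaml.safe_dump(cfg))
        return p

    def test_roundtrip_and_defaults(self, tmp_path):
        params = load_params(self._cfg(tmp_path))
        assert params.foci.noise_level_1 == NOISE_LEVEL
        assert params.seg.threshold_mode == "auto"
        assert params.seg.auto_method == "isodata"
        assert params.output_formats == ("csv",)

    def test_missing_noise_level_rejected(self, tmp_path):
        p = self._cfg(tmp_path, foci={})
        with pytest.raises(ConfigurationError, match="noise_level_1"):
            load_params(p)

    def test_coloc_without_foci2_rejected(self, tmp_path):
        p = self._cfg(tmp_path, coloc={"enabled": True})
        with pytest.raises(ConfigurationError):
            load_params(p)

    def test_unknown_section_rejected(self, tmp_path):
        p = self._cfg(tmp_path, bogus={"x": 1})
        with pytest.raises(ConfigurationError, match="bogus"):
            load_params(p)

    def test_synthetic_spec_loading(self, tmp_path):
        p = tmp_path / "spec.yaml"
        p.write_text(yaml.safe_dump({"image_size": [64, 64], "n_nuclei": 1,
                                     "seed": 3}))
        spec = load_spec(p)
        assert spec.image_size == (64, 64) and spec.n_nuclei == 1


class TestCli:
    def test_simulate_then_run_end_to_end(self, tmp_path):
        from click.testing import CliRunner
        from focicount.cli import main
        runner = CliRunner()
        spec_file = tmp_path / "spec.yaml"
        spec_file.write_text(yaml.safe_dump(
            {"n_nuclei": 3, "foci_per_nucleus": 2, "seed": 12}))
        r = runner.invoke(main, ["simulate", "--spec", str(spec_file),
                                 "--out", str(tmp_path / "imgs")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "imgs" / "synthetic_000.tif").exists()
        assert (tmp_path / "imgs" / "synthetic_000_truth.json").exists()

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({
            "input": {"roi_channel": 0, "foci1_channel": 1},
            "seg": {"min_area": 150},
            "foci": {"noise_level_1": NOISE_LEVEL, "cutoff_1": CUTOFF},
            "output": {"dir": str(tmp_path / "res")},
        }))
        r = runner.invoke(main, ["run", "--config", str(cfg),
                                 "--input", str(tmp_path / "imgs")])
        assert r.exit_code == 0, r.output
        per_roi = pd.read_csv(tmp_path / "res" / "per_roi.csv")
        assert len(per_roi) == 3
        assert per_roi["foci_count_1"].tolist() == [2, 2, 2]

    def test_validate_config_reports_errors(self, tmp_path):
        from click.testing import CliRunner
        from focicount.cli import main
        cfg = tmp_path / "bad.yaml"
        cfg.write_text(yaml.safe_dump({"input": {"roi_channel": 0}}))
        r = CliRunner().invoke(main, ["validate-config", str(cfg)])
        assert r.exit_code == 1

    def test_single_image_command(self, tmp_path):
        from click.testing import CliRunner
        from focicount.cli import main
        img, _ = generate_image(SyntheticSpec(n_nuclei=2, foci_per_nucleus=3,
                                              seed=14))
        save_multichannel_tiff(tmp_path / "one.tif", img)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(yaml.safe_dump({
            "input": {"roi_channel": 0, "foci1_channel": 1},
            "seg": {"min_area": 150},
            "foci": {"noise_level_1": NOISE_LEVEL, "cutoff_1": CUTOFF},
            "output": {"dir": str(tmp_path / "res")},
        }))
        r = CliRunner().invoke(main, ["single", str(tmp_path / "one.tif"),
                                      "--config", str(cfg)])
        assert r.exit_code == 0, r.output
        assert "2 ROI(s)" in r.output


class TestQcOverlay:
    def test_overlay_marks_roi_outline_and_foci(self, tmp_path):
        from focicount.qc import render_overlay, save_overlay
        spec = SyntheticSpec(n_nuclei=2, foci_per_nucleus=2, seed=95)
        img, _ = generate_image(spec)
        from focicount import segment, detect_foci_per_roi
        res = segment(img.channel("roi"), SegmentationParams(min_area=150))
        foci = detect_foci_per_roi(
            img, res.rois,
            FociParams(noise_level_1=NOISE_LEVEL, cutoff_1=CUTOFF))
        rgb = render_overlay(img, res.rois, foci)
        assert rgb.shape == (*img.shape, 3) and rgb.dtype == np.uint8
        # green outlines and red focus marks exist
        assert (rgb == np.array([0, 255, 0])).all(axis=-1).any()
        for f in foci:
            assert tuple(rgb[f.y, f.x]) == (255, 0, 0)
        save_overlay(tmp_path / "ov.png", img, res.rois, foci)
        assert (tmp_path / "ov.png").exists()
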