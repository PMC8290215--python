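"""Per-case orchestration, cohort summaries, file manifests and the CLI."""

import numpy as np
import pandas as pd
import pytest
import yaml

from aminopet import (
    CaseResult,
    Role,
    ThresholdMetrics,
    results_to_frame,
    run_case,
    run_phantom_case,
    save_phantom,
    summarize_cohort,
    write_outputs,
)
from conftest import small_spec


def fake_result(case_id, value):
    tm = ThresholdMetrics(ratio=1.7, btv_cc=value, within_cc=value / 2, outside_cc=value / 2,
                          outside_fraction=0.5, hd95_mm=value, svc_max_mm=value,
                          svc_mean_mm=value / 2)
    return CaseResult(case_id=case_id, gtv_cc=value, normal_reference=1.0,
                      thresholds={1.7: tm})


class TestRunPhantomCase:
    def test_concordant_construction_yields_zero_outside(self):
        from aminopet import TumorSpec
        spec = small_spec(tumor=TumorSpec(center_offset_mm=(-10, -12, 4),
                                          enhancement_radius_mm=15.0,
                                          infiltration_radius_mm=15.0,
                                          peak_tn_ratio=3.0, profile="step"))
        case, ph = run_phantom_case("concordant", spec)
        for tm in case.thresholds.values():
            assert tm.outside_fraction == 0.0
            # BTV == GTV up to the normal-reference estimate; surfaces coincide
            assert tm.hd95_mm <= 2.0 * np.sqrt(3.0)

    def test_infiltration_beyond_enhancement_detected(self, request):
        case, ph = run_phantom_case("infiltrating", small_spec())
        for tm in case.thresholds.values():
            assert tm.outside_fraction > 0.0
            assert tm.btv_cc > 0
        assert case.thresholds[1.7].outside_fraction >= case.thresholds[2.0].outside_fraction

    def test_rerun_is_deterministic(self):
        a, _ = run_phantom_case("rep", small_spec(noise_sigma_fraction=0.05))
        b, _ = run_phantom_case("rep", small_spec(noise_sigma_fraction=0.05))
        assert a == b

    def test_recurrence_fractions_reported(self):
        from aminopet import RecurrenceSpec
        spec = small_spec(recurrence=RecurrenceSpec(center_offset_mm=(-10, -12, 4),
                                                    radius_mm=6.0,
                                                    designed_outside_fraction=0.3,
                                                    vs_role=Role.GTV))
        case, ph = run_phantom_case("rec", spec)
        assert case.recurrence_outside["GTV"] == pytest.approx(
            ph.truth.recurrence_outside_fraction)
        assert set(case.recurrence_outside) == {"GTV", "BTV1.7", "BTV2", "PTV"}


class TestCohortSummary:
    def test_single_case_collapses(self):
        summary = summarize_cohort([fake_result("a", 3.0)])
        stats = summary["gtv_cc"]
        assert stats["mean"] == stats["min"] == stats["max"] == 3.0 and stats["n"] == 1

    def test_mean_and_range(self):
        summary = summarize_cohort([fake_result(c, v) for c, v in
                                    zip("abc", (1.0, 2.0, 3.0))])
        assert summary["gtv_cc"] == {"mean": 2.0, "min": 1.0, "max": 3.0, "n": 3}

    def test_permutation_invariance(self):
        results = [fake_result(c, v) for c, v in zip("abcd", (4.0, 1.0, 3.0, 2.0))]
        assert summarize_cohort(results) == summarize_cohort(results[::-1])

    def test_csv_round_trip(self, tmp_path):
        results = [fake_result(c, v) for c, v in zip("abc", (1.0, 2.0, 3.0))]
        csv_path, _ = write_outputs(results, tmp_path)
        frame = pd.read_csv(csv_path)
        in_memory = summarize_cohort(results)
        for col, stats in in_memory.items():
            vals = frame[col].dropna()
            assert stats["mean"] == pytest.approx(vals.mean())
            assert stats["min"] == pytest.approx(vals.min())
            assert stats["max"] == pytest.approx(vals.max())

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


class TestFileManifest:
    @pytest.fixture()
    def case_dir(self, tmp_path):
        from aminopet import generate_phantom
        ph = generate_phantom(small_spec(noise_sigma_fraction=0.05, psf_fwhm_mm=4.0))
        save_phantom(ph, tmp_path, case_id="p01")
        return tmp_path, ph

    def manifest(self, ph):
        off = ph.truth.spec.tumor.center_offset_mm
        grid = ph.suv.grid
        center = grid.center_mm()
        mirror = [center[0] - off[0], center[1] + off[1], center[2] + off[2]]
        return {
            "case_id": "p01",
            "suv": "p01_SUV.nii.gz",
            "gtv": "p01_GTV.nii.gz",
            "brain": "p01_BRAIN.nii.gz",
            "exclusions": ["p01_BASAL_GANGLIA.nii.gz"],
            "dose": "p01_DOSE.nii.gz",
            "prescription_gy": 60.0,
            "normal_roi_center_mm": mirror,
        }

    def test_file_pipeline_matches_in_memory(self, case_dir):
        tmp_path, ph = case_dir
        file_result = run_case(self.manifest(ph), base_dir=tmp_path)
        mem_result, _ = run_phantom_case(
            "p01", small_spec(noise_sigma_fraction=0.05, psf_fwhm_mm=4.0))
        assert file_result.gtv_cc == mem_result.gtv_cc
        assert file_result.normal_reference == pytest.approx(mem_result.normal_reference)
        for ratio in (1.7, 2.0):
            assert file_result.thresholds[ratio].btv_cc == pytest.approx(
                mem_result.thresholds[ratio].btv_cc)
            assert file_result.thresholds[ratio].covered_fraction == pytest.approx(
                mem_result.thresholds[ratio].covered_fraction)

    def test_missing_reference_spec_rejected(self, case_dir):
        tmp_path, ph = case_dir
        manifest = self.manifest(ph)
        del manifest["normal_roi_center_mm"]
        with pytest.raises(ValueError, match="normal_ref"):
            run_case(manifest, base_dir=tmp_path)

    def test_cli_run_and_segment(self, case_dir):
        from click.testing import CliRunner
        from aminopet.cli import main

        tmp_path, ph = case_dir
        manifest = {"cases": [self.manifest(ph)]}
        mpath = tmp_path / "cohort.yaml"
        mpath.write_text(yaml.safe_dump(manifest))
        runner = CliRunner()
        res = runner.invoke(main, ["run", "--manifest", str(mpath),
                                   "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "cases.csv").exists()
        assert (tmp_path / "out" / "cohort_summary.json").exists()

        res = runner.invoke(main, [
            "segment", "--suv", str(tmp_path / "p01_SUV.nii.gz"),
            "--brain", str(tmp_path / "p01_BRAIN.nii.gz"),
            "--ratio", "1.7", "--normal-ref", "1.0",
            "--exclude", str(tmp_path / "p01_BASAL_GANGLIA.nii.gz"),
            "--out", str(tmp_path / "p01_BTV.nii.gz")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "p01_BTV.nii.gz").exists()
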