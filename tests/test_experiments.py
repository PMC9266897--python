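"""Study drivers: grid runner, synthetic phantom, worked example, and I/O."""

import json

import numpy as np
import pytest

from larex import bm_sim as bm
from larex import experiments as ex
from larex import io as lio
from larex import omega as om
from larex import zproc


class TestGridSpec:
    def test_defaults_span_reported_range(self):
        spec = ex.GridSpec()
        assert spec.f_b[0] == pytest.approx(0.23e-3)
        assert spec.f_b[-1] == pytest.approx(8.52e-3)
        assert spec.k_ba_Hz[0] == 50.0 and spec.k_ba_Hz[-1] == 1000.0

    def test_non_increasing_axes_rejected(self):
        with pytest.raises(ValueError):
            ex.GridSpec(f_b=(2e-3, 1e-3), k_ba_Hz=(100.0, 200.0))

    def test_box_must_lie_inside_span(self):
        with pytest.raises(ValueError):
            ex.GridSpec(f_b=(1e-3, 2e-3), k_ba_Hz=(100.0, 200.0),
                        physiological_box=(0.5e-3, 5e-3, 100.0, 500.0))

    def test_desk_scale_guard(self):
        with pytest.raises(ValueError):
            ex.GridSpec(f_b=tuple(np.linspace(1e-3, 5e-3, 20)),
                        k_ba_Hz=tuple(np.linspace(100, 500, 20)),
                        physiological_box=(1e-3, 5e-3, 100.0, 500.0))


@pytest.fixture(scope="module")
def single_cell_maps():
    spec = ex.GridSpec(
        f_b=(1.8e-3,), k_ba_Hz=(400.0,),
        physiological_box=(1.8e-3, 1.8e-3, 400.0, 400.0),
    )
    return ex.run_insilico_grid(spec, seed=0)


class TestRunInsilicoGrid:
    def test_truth_maps_equal_grid_values(self, single_cell_maps):
        assert single_cell_maps.truth_f_b[0, 0] == 1.8e-3
        assert single_cell_maps.truth_k_ba[0, 0] == 400.0

    def test_larex_cell_within_error_bounds(self, single_cell_maps):
        assert single_cell_maps.within_bounds("LAREX-6pool")[0, 0]

    def test_two_pool_arex_cell_within_error_bounds(self, single_cell_maps):
        assert single_cell_maps.within_bounds("AREX-2pool")[0, 0]

    def test_masks_follow_bound_definition(self, single_cell_maps):
        m = single_cell_maps
        for method in m.spec.methods:
            expected = (m.admissible[method]
                        & (np.abs(m.delta_f_b(method)) <= 1e-3)
                        & (np.abs(m.delta_k_ba(method)) <= 300.0))
            assert np.array_equal(m.within_bounds(method), expected)


class TestPhantom:
    def test_noiseless_voxels_match_sample_mode(self):
        """A sigma = 0 phantom voxel gives exactly the sample-mode estimate
        for the same parameters."""
        rois = [dict(slice=np.s_[0:1, 0:1], f_b=3e-3, k_ba=300.0)]
        ph = ex.make_phantom(rois, shape=(1, 2), noise_sigma=0.0,
                             b1_levels=(0.6, 0.9, 1.2), seed=0)
        stack = zproc.normalize_reference(ph["cest"])
        config = om.ArexConfig.from_scheme(bm.scheme_3t(0.6))
        maps = ex.qcest_map(stack, bm.WATER_T1_S, config, method="LAREX",
                            mask=ph["mask"])
        voxel = zproc.ZStack(stack.Z[0, 0], stack.offsets_ppm, stack.B1_uT,
                             normalized=True)
        ref = om.qcest_larex(voxel, bm.WATER_T1_S, config)
        assert maps["admissible"][0, 0] == ref.admissible
        assert maps["f_b"][0, 0] == pytest.approx(ref.f_b, rel=1e-6)
        assert np.isnan(maps["f_b"][0, 1])  # outside every ROI

    def test_b0_shift_round_trip(self):
        """Injected B0 offsets are recovered by WASSR and the corrected
        estimates match the unshifted phantom within 10%."""
        rois = [dict(slice=np.s_[:, :], f_b=3e-3, k_ba=300.0)]
        shifts = np.array([[-0.2, 0.2]])
        config = om.ArexConfig.from_scheme(bm.scheme_3t(0.6))
        ph0 = ex.make_phantom(rois, shape=(1, 2), b0_shift_ppm=0.0,
                              b1_levels=(0.6, 0.9, 1.2), seed=1)
        ph = ex.make_phantom(rois, shape=(1, 2), b0_shift_ppm=shifts,
                             b1_levels=(0.6, 0.9, 1.2), seed=1)
        b0 = zproc.wassr_b0_map(ph["wassr"])
        assert np.abs(b0.shift_ppm - shifts).max() < 0.01
        stack = zproc.correct_b0(zproc.normalize_reference(ph["cest"]), b0)
        maps = ex.qcest_map(stack, bm.WATER_T1_S, config)
        ref = ex.qcest_map(zproc.normalize_reference(ph0["cest"]),
                           bm.WATER_T1_S, config)
        assert maps["admissible"].all() and ref["admissible"].all()
        assert np.abs(maps["f_b"] / ref["f_b"] - 1).max() < 0.12

    def test_roi_trend_preserved_in_rank_statistic(self):
        """Across ROIs with decreasing GAG fraction the LAREX estimates
        decrease in rank (Kendall tau, the study's trend statistic)."""
        from scipy.stats import kendalltau
        fbs = (5e-3, 4e-3, 3e-3, 2e-3, 1e-3)
        config = om.ArexConfig.from_scheme(bm.scheme_3t(0.6))
        est = []
        for fb in fbs:
            e = om.qcest_larex(ex.simulate_stack(bm.ivd6(fb, 300.0)),
                               bm.WATER_T1_S, config)
            est.append(e.f_b if e.admissible else 0.0)
        tau, _ = kendalltau(fbs, est)
        assert tau >= 0.6

    def test_relaxometry_series_recover_ground_truth(self):
        rois = [dict(slice=np.s_[:, :], f_b=2e-3, k_ba=200.0)]
        ph = ex.make_phantom(rois, shape=(1, 1), b1_levels=(0.6, 0.9, 1.2),
                             seed=0)
        T1, _, _ = zproc.fit_t1_ir(ph["ir_signals"][0, 0], ph["TI_s"])
        T2, _, _ = zproc.fit_t2_se(ph["se_signals"][0, 0], ph["TE_s"])
        assert T1 == pytest.approx(bm.WATER_T1_S, rel=1e-4)
        assert T2 == pytest.approx(bm.WATER_T2_S, rel=1e-4)

    def test_overlapping_rois_rejected(self):
        rois = [dict(slice=np.s_[0:1, 0:2], f_b=2e-3, k_ba=200.0),
                dict(slice=np.s_[0:1, 1:3], f_b=3e-3, k_ba=200.0)]
        with pytest.raises(ValueError):
            ex.make_phantom(rois, shape=(1, 3), b1_levels=(0.6, 0.9, 1.2))


@pytest.fixture(scope="module")
def report():
    return ex.fig5_report(seed=0, b1_levels=(0.6, 0.8, 1.0, 1.2), show_b1=0.8)


class TestFig5Report:
    def test_larex_estimate_within_error_bounds(self, report):
        est = report["larex"]
        assert est.admissible
        assert abs(est.f_b - ex.FIG5_FB) <= 1e-3
        assert abs(est.k_ba_Hz - ex.FIG5_KBA) <= 300.0

    def test_decomposition_is_tight(self, report):
        assert report["decomposition"]["rms_residual"] < 0.01
        comps = report["decomposition"]["components"]
        assert set(comps) == {"water", "amide", "hydroxyl", "noe1", "noe2", "mt"}

    def test_correction_removes_dilution_of_the_asymmetry(self, report):
        """The corrected asymmetry curve lies above the multi-pool raw curve
        (upfield pools dilute the raw metric) at every B1."""
        asym = report["mtr_asym"]
        assert np.all(asym["corrected"] > asym["raw"])

    def test_report_deterministic_for_fixed_seed(self, report):
        again = ex.fig5_report(seed=0, b1_levels=(0.6, 0.8, 1.0, 1.2),
                               show_b1=0.8)
        assert np.array_equal(again["mtr_asym"]["corrected"],
                              report["mtr_asym"]["corrected"])
        assert again["larex"].f_b == report["larex"].f_b


class TestIO:
    def test_nifti_stack_round_trip(self, tmp_path, rng):
        Z = rng.uniform(0.2, 1.0, size=(3, 4, 2, 5))
        stack = zproc.ZStack(Z, np.linspace(-2, 2, 5), [0.6, 1.2],
                             normalized=True)
        prefix = str(tmp_path / "stack")
        lio.write_nifti_stack(prefix, stack)
        back = lio.read_nifti_stack(prefix)
        assert np.allclose(back.Z, stack.Z, atol=1e-6)
        assert np.allclose(back.offsets_ppm, stack.offsets_ppm)
        assert back.normalized

    def test_estimates_table_columns(self, tmp_path):
        import pandas as pd
        path = tmp_path / "est.tsv"
        lio.write_estimates(path, [dict(id=0, method="LAREX", f_b_permil=1.9,
                                        k_ba_Hz=380.0, admissible=True)])
        df = pd.read_csv(path, sep="\t")
        assert {"method", "f_b_permil", "k_ba_Hz", "r_squared"} <= set(df.columns)


class TestCli:
    def test_simulate_then_quantify(self, tmp_path):
        from click.testing import CliRunner
        from larex.cli import main
        runner = CliRunner()
        spectra = str(tmp_path / "spec.tsv")
        out = str(tmp_path / "est.tsv")
        r1 = runner.invoke(main, ["simulate", "--system", "ideal2",
                                  "--b1", "0.6", "--b1", "0.9", "--b1", "1.2",
                                  "--out", spectra])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(main, ["qcest", spectra, "--method", "arex",
                                  "--out", out])
        assert r2.exit_code == 0, r2.output
        import pandas as pd
        df = pd.read_csv(out, sep="\t")
        assert df.loc[0, "method"] == "AREX"
        assert df.loc[0, "admissible"]

    def test_map_mode_quantification(self, tmp_path):
        from click.testing import CliRunner
        from larex.cli import main
        rois = [dict(slice=np.s_[0:1, 0:1], f_b=3e-3, k_ba=300.0)]
        ph = ex.make_phantom(rois, shape=(1, 1), b1_levels=(0.6, 0.9, 1.2))
        prefix = str(tmp_path / "stack")
        lio.write_nifti_stack(prefix, ph["cest"])
        out = str(tmp_path / "est.tsv")
        r = CliRunner().invoke(main, ["qcest", prefix, "--method", "larex",
                                      "--out", out])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "est_larex_fb.nii").exists()
        import pandas as pd
        df = pd.read_csv(out, sep="\t")
        assert df.loc[0, "admissible"]

    def test_fig5_command_writes_report(self, tmp_path):
        from click.testing import CliRunner
        from larex.cli import main
        runner = CliRunner()
        out = tmp_path / "fig5.json"
        r = runner.invoke(main, ["fig5", "--seed", "1", "--out", str(out)])
        assert r.exit_code == 0, r.output
        payload = json.loads(out.read_text())
        assert payload["estimates"]["LAREX"]["admissible"]
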