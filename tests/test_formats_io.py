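import json

import numpy as np
import pytest

from membranalysis import (
    RunConfig,
    ScatteringCurve,
    TransitionParams,
    TwoChannelImage,
    read_image_stack,
    read_results,
    read_scattering_curve,
    read_thermogram,
    write_image_stack,
    write_results,
    write_scattering_curve,
    write_thermogram,
)
from membranalysis.formats_io import (
    Thermogram,
    angstrom_inv_to_nm_inv,
    celsius_to_kelvin,
    kelvin_to_celsius,
    nm_inv_to_angstrom_inv,
)


def _write(path, text):
    path.write_text(text)
    return path


class TestScatteringReader:
    def test_nm_input_converted_to_inverse_angstrom(self, tmp_path):
        q_nm = np.linspace(0.15, 4.47, 60)
        body = "\n".join(f"{q} 10.0 0.1" for q in q_nm)
        p = _write(tmp_path / "c.dat", "# comment\n" + body + "\n")
        curve = read_scattering_curve(p, q_units="inverse_nanometer")
        assert curve.q[0] == pytest.approx(0.015)
        assert curve.q[-1] == pytest.approx(0.447)

    def test_angstrom_input_unchanged(self, tmp_path):
        p = _write(tmp_path / "c.dat", "0.1 5 0.5\n0.2 4 0.4\n0.3 3 0.3\n")
        curve = read_scattering_curve(p, q_units="inverse_angstrom")
        np.testing.assert_allclose(curve.q, [0.1, 0.2, 0.3])

    def test_missing_sigma_defaults_to_sqrt(self, tmp_path):
        p = _write(tmp_path / "c.dat", "0.1 4\n0.2 4\n0.3 4\n")
        curve = read_scattering_curve(p)
        np.testing.assert_allclose(curve.sigma_I, 2.0)

    def test_sqrt_rule_floors_intensity_at_one(self, tmp_path):
        p = _write(tmp_path / "c.dat", "0.1 0.25\n0.2 0.25\n")
        curve = read_scattering_curve(p)
        np.testing.assert_allclose(curve.sigma_I, 1.0)

    def test_non_finite_rows_dropped(self, tmp_path):
        p = _write(tmp_path / "c.dat", "0.1 5 0.5\n0.2 nan 0.4\n0.3 3 0.3\n")
        curve = read_scattering_curve(p)
        assert curve.q.size == 2

    def test_non_monotonic_q_raises_with_line_number(self, tmp_path):
        p = _write(tmp_path / "c.dat", "0.1 5 0.5\n0.3 4 0.4\n0.2 3 0.3\n")
        with pytest.raises(ValueError, match=r":3:"):
            read_scattering_curve(p)

    def test_negative_sigma_raises_with_line_number(self, tmp_path):
        p = _write(tmp_path / "c.dat", "0.1 5 0.5\n0.2 4 -0.4\n")
        with pytest.raises(ValueError, match=r":2:.*negative"):
            read_scattering_curve(p)

    def test_empty_file_raises(self, tmp_path):
        p = _write(tmp_path / "c.dat", "# only a comment\n")
        with pytest.raises(ValueError, match="empty"):
            read_scattering_curve(p)

    def test_write_read_round_trip(self, tmp_path):
        curve = ScatteringCurve(q=[0.1, 0.2, 0.3], I=[5.0, 4.0, 3.0], sigma_I=[0.5, 0.4, 0.3])
        p = tmp_path / "c.dat"
        write_scattering_curve(curve, p, header="demo")
        back = read_scattering_curve(p)
        np.testing.assert_allclose(back.q, curve.q)
        np.testing.assert_allclose(back.I, curve.I)
        np.testing.assert_allclose(back.sigma_I, curve.sigma_I)


class TestThermogramReader:
    def _csv(self, tmp_path, temps, cps):
        lines = ["temperature,cp"] + [f"{t},{c}" for t, c in zip(temps, cps)]
        return _write(tmp_path / "scan.csv", "\n".join(lines) + "\n")

    def test_celsius_window_converts_to_kelvin(self, tmp_path):
        temps = np.linspace(5, 55, 51)
        p = self._csv(tmp_path, temps, np.zeros(51))
        tg = read_thermogram(p, temperature_units="celsius")
        assert tg.T[0] == pytest.approx(278.15)
        assert tg.T[-1] == pytest.approx(328.15)

    def test_kelvin_input_unchanged(self, tmp_path):
        temps = np.linspace(280, 320, 41)
        p = self._csv(tmp_path, temps, np.zeros(41))
        tg = read_thermogram(p, temperature_units="kelvin")
        np.testing.assert_allclose(tg.T, temps)

    def test_duplicate_temperatures_averaged(self, tmp_path):
        temps = list(np.linspace(280, 300, 10)) + [300.0]
        cps = [0.0] * 9 + [1.0, 3.0]
        p = self._csv(tmp_path, temps, cps)
        tg = read_thermogram(p, temperature_units="kelvin")
        assert tg.Cp[-1] == pytest.approx(2.0)

    def test_row_order_does_not_matter(self, tmp_path):
        temps = np.linspace(280, 320, 20)
        cps = np.sin(temps)
        p1 = self._csv(tmp_path, temps, cps)
        tg1 = read_thermogram(p1, temperature_units="kelvin")
        order = np.random.default_rng(0).permutation(20)
        p2 = _write(
            tmp_path / "shuffled.csv",
            "temperature,cp\n" + "\n".join(f"{temps[i]},{cps[i]}" for i in order) + "\n",
        )
        tg2 = read_thermogram(p2, temperature_units="kelvin")
        np.testing.assert_allclose(tg1.T, tg2.T)
        np.testing.assert_allclose(tg1.Cp, tg2.Cp)

    def test_short_scan_rejected(self, tmp_path):
        p = self._csv(tmp_path, np.linspace(280, 290, 5), np.zeros(5))
        with pytest.raises(ValueError, match="too short"):
            read_thermogram(p, temperature_units="kelvin")

    def test_write_read_round_trip(self, tmp_path):
        tg = Thermogram(T=np.linspace(280, 320, 41), Cp=np.linspace(0, 1, 41))
        p = tmp_path / "scan.csv"
        write_thermogram(tg, p, temperature_units="kelvin")
        back = read_thermogram(p, temperature_units="kelvin")
        np.testing.assert_allclose(back.T, tg.T)
        np.testing.assert_allclose(back.Cp, tg.Cp)


class TestImageStackReader:
    def _stack(self, tmp_path, n_pages, shape=(16, 16)):
        frames = []
        rng = np.random.default_rng(0)
        for t in range(n_pages // 2):
            frames.append(
                TwoChannelImage(
                    I440=rng.integers(0, 100, shape).astype(float),
                    I490=rng.integers(0, 100, shape).astype(float),
                    timestamp=t,
                )
            )
        p = tmp_path / "stack.tif"
        write_image_stack(frames, p)
        return p, frames

    def test_ten_pages_pair_into_five_time_points(self, tmp_path):
        p, _ = self._stack(tmp_path, 10)
        assert len(read_image_stack(p)) == 5

    def test_two_pages_give_blue_from_first_page(self, tmp_path):
        p, frames = self._stack(tmp_path, 2)
        out = read_image_stack(p, channel_order="blue_first")
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].I440, frames[0].I440)

    def test_red_first_swaps_channels(self, tmp_path):
        p, frames = self._stack(tmp_path, 10)
        out = read_image_stack(p, channel_order="red_first")
        np.testing.assert_array_equal(out[0].I490, frames[0].I440)

    def test_odd_page_count_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "odd.tif"
        tifffile.imwrite(p, np.zeros((3, 8, 8), dtype=np.uint16), photometric="minisblack")
        with pytest.raises(ValueError, match="odd page count"):
            read_image_stack(p)


class TestResultsStore:
    def test_transition_params_round_trip(self, tmp_path):
        rec = TransitionParams(Tm=305.75, T_half=9.8, dH_cal=1.4, dH_vH=75.8, CU=54.1)
        p = tmp_path / "out.json"
        write_results(rec, p, config=RunConfig())
        back = read_results(p, registry={"TransitionParams": TransitionParams})
        assert back == rec
        doc = json.loads(p.read_text())
        assert set(doc["results"]["data"]) == {"Tm", "T_half", "dH_cal", "dH_vH", "CU"}

    def test_saxs_fit_round_trip(self, tmp_path, control_model):
        from membranalysis import SAXSFit
        from membranalysis.saxs import BilayerModel

        fit = SAXSFit(
            model=control_model, uncertainties={"z_H": 0.1}, chi2_reduced=1.0,
            d_B=50.2, n_uv_percent=52.0,
        )
        p = tmp_path / "fit.json"
        write_results(fit, p)
        back = read_results(p, registry={"SAXSFit": SAXSFit, "BilayerModel": BilayerModel})
        assert back == fit

    def test_empty_results_valid_json(self, tmp_path):
        p = tmp_path / "out.json"
        write_results([], p)
        assert read_results(p) == []

    def test_checksums_recorded(self, tmp_path):
        src = _write(tmp_path / "in.dat", "0.1 5 0.5\n")
        p = tmp_path / "out.json"
        write_results([], p, inputs=[src])
        doc = json.loads(p.read_text())
        assert str(src) in doc["input_checksums"]


class TestUnits:
    def test_q_conversion_round_trips_to_machine_precision(self):
        q = np.linspace(0.15, 4.47, 100)
        np.testing.assert_allclose(
            angstrom_inv_to_nm_inv(nm_inv_to_angstrom_inv(q)), q, rtol=2e-15
        )

    def test_temperature_conversion_round_trips_to_machine_precision(self):
        t = np.linspace(5, 55, 100)
        np.testing.assert_allclose(
            kelvin_to_celsius(celsius_to_kelvin(t)), t, rtol=0, atol=1e-12
        )


class TestRunConfig:
    def test_invalid_reference_gp_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(reference_gp=1.0)

    def test_non_positive_gas_constant_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(gas_constant=0.0)

    def test_yaml_load_with_cli_override(self, tmp_path):
        p = _write(tmp_path / "cfg.yaml", "temperature_units: kelvin\nrandom_seed: 7\n")
        cfg = RunConfig.from_yaml(p, temperature_units="celsius")
        assert cfg.temperature_units == "celsius"
        assert cfg.random_seed == 7
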