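"""Helicity diagnostics, summaries, and severity classification."""

import numpy as np
import pytest

from pulsarch.metrics import (
    BandSpec,
    GriddedField,
    MetricSummary,
    classify,
    default_pressure_bands,
    default_wss_bands,
    helicity_field,
    summarize,
)
from pulsarch.synthetic_data import abc_field, solid_body_rotation_field


class TestHelicity:
    def test_uniform_flow_zero(self):
        ones = np.ones((8, 8, 8))
        fld = GriddedField(spacing=(0.1, 0.1, 0.1), u=ones, v=2 * ones, w=-ones)
        np.testing.assert_allclose(helicity_field(fld), 0.0, atol=1e-13)

    def test_solid_body_rotation_zero(self):
        fld = solid_body_rotation_field(16)
        np.testing.assert_allclose(helicity_field(fld), 0.0, atol=1e-12)

    def test_abc_flow_matches_squared_speed(self):
        """Beltrami property: curl u = u, so H = |u|^2 pointwise."""
        fld = abc_field(48)
        H = helicity_field(fld, periodic=True)
        speed2 = fld.u**2 + fld.v**2 + fld.w**2
        h = fld.spacing[0]
        err = np.max(np.abs(H - speed2))
        assert err < 3.0 * h**2  # second-order differencing
        assert H[0, 0, 0] == pytest.approx(3.0, abs=5 * h**2)

    def test_abc_second_order_convergence(self):
        errs = []
        for n in (16, 32, 64):
            fld = abc_field(n)
            H = helicity_field(fld, periodic=True)
            errs.append(np.max(np.abs(H - (fld.u**2 + fld.v**2 + fld.w**2))))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)

    def test_zero_amplitude_abc_field(self):
        fld = abc_field(8, A=0.0, B=0.0, C=0.0)
        np.testing.assert_array_equal(helicity_field(fld, periodic=True), 0.0)

    def test_quadratic_scaling_in_velocity(self):
        fld = abc_field(16, A=1.0, B=0.7, C=0.4)
        scaled = GriddedField(spacing=fld.spacing, u=3 * fld.u, v=3 * fld.v, w=3 * fld.w)
        np.testing.assert_allclose(
            helicity_field(scaled, periodic=True),
            9.0 * helicity_field(fld, periodic=True),
            rtol=1e-12,
        )

    def test_reflection_invariance(self):
        fld = abc_field(16, A=0.5, B=1.0, C=0.25)
        neg = GriddedField(spacing=fld.spacing, u=-fld.u, v=-fld.v, w=-fld.w)
        np.testing.assert_allclose(
            helicity_field(neg, periodic=True),
            helicity_field(fld, periodic=True),
            rtol=1e-12,
        )

    def test_linear_field_constant_vorticity_exact(self):
        """Central differences are exact on a linear velocity field."""
        n = 9
        ax = np.linspace(0.0, 1.0, n)
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        # u = (2y + z, 3x, -x); curl = (0, 1+1, 3-2) = (0, 2, 1)
        fld = GriddedField(
            spacing=(ax[1], ax[1], ax[1]), u=2 * y + z, v=3 * x, w=-x
        )
        H = helicity_field(fld)
        expected = fld.u * 0.0 + fld.v * 2.0 + fld.w * 1.0
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_too_small_grid_rejected(self):
        a = np.ones((2, 4, 4))
        with pytest.raises(ValueError):
            helicity_field(GriddedField(spacing=(1, 1, 1), u=a, v=a, w=a))


class TestGriddedFieldIO:
    def test_vtk_round_trip(self, tmp_path):
        fld = abc_field(8, A=1.0, B=0.5, C=0.25)
        path = tmp_path / "abc.vtk"
        fld.to_vtk(path)
        back = GriddedField.from_vtk(path)
        assert back.shape == fld.shape
        np.testing.assert_allclose(back.u, fld.u, rtol=1e-15)
        np.testing.assert_allclose(back.w, fld.w, rtol=1e-15)
        assert back.spacing == pytest.approx(fld.spacing)

    def test_dataframe_export_columns(self):
        fld = abc_field(8)
        df = fld.to_dataframe()
        assert len(df) == 8**3
        assert list(df.columns[:3]) == ["x_m", "y_m", "z_m"]


class TestSummarize:
    def test_basic_triple(self):
        s = summarize([1.0, 2.0, 3.0], quantity="wss")
        assert (s.min, s.avg, s.max) == (1.0, 2.0, 3.0)

    def test_constant_array(self):
        s = summarize(np.full(17, 4.2))
        assert s.min == s.avg == s.max == 4.2

    def test_matches_streaming_oracle(self, rng):
        x = rng.uniform(0.0, 1.0, size=10**5)
        s = summarize(x)
        lo, hi, total = np.inf, -np.inf, 0.0
        for v in x:  # independent streaming pass
            lo, hi, total = min(lo, v), max(hi, v), total + v
        assert s.min == lo and s.max == hi
        assert s.avg == pytest.approx(total / x.size, rel=1e-12)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
        with pytest.raises(ValueError):
            summarize([1.0, np.nan])

    def test_summary_ordering_enforced(self):
        with pytest.raises(ValueError):
            MetricSummary(quantity="x", min=2.0, avg=1.0, max=3.0)


class TestClassification:
    def test_reported_wss_exemplars(self):
        """Low average WSS flags borderline; extreme max flags high risk."""
        bands = default_wss_bands()
        low_avg = MetricSummary(quantity="wss", min=0.005, avg=0.041, max=0.9)
        rep = classify(low_avg, bands)
        assert rep.entries["avg"][0] == "yellow"
        high_max = MetricSummary(quantity="wss", min=0.2, avg=1.2, max=6.01)
        assert classify(high_max, bands).entries["max"][0] == "red"

    def test_physiologic_band_is_green(self):
        bands = default_wss_bands()
        s = MetricSummary(quantity="wss", min=0.3, avg=1.0, max=1.4)
        rep = classify(s, bands)
        assert rep.entries["avg"][0] == "green"
        assert rep.entries["max"][0] == "green"
        assert rep.entries["min"][0] == "green"

    def test_band_edges_take_lower_severity(self):
        bands = default_wss_bands()
        s = MetricSummary(quantity="wss", min=0.05, avg=0.4, max=1.5)
        rep = classify(s, bands)
        assert rep.entries["avg"][0] == "green"   # edge of yellow|green
        assert rep.entries["max"][0] == "green"   # edge of green|yellow
        assert rep.entries["min"][0] == "green"
        s2 = MetricSummary(quantity="wss", min=0.2, avg=1.5, max=4.5)
        assert classify(s2, bands).entries["avg"][0] == "green"  # green|red edge
        assert classify(s2, bands).entries["max"][0] == "yellow"  # yellow|red edge

    def test_classification_monotone_in_max(self):
        bands = default_wss_bands()
        rank = {"green": 0, "yellow": 1, "red": 2}
        prev = -1
        for mx in np.linspace(0.5, 8.0, 60):
            s = MetricSummary(quantity="wss", min=0.3, avg=0.5, max=mx)
            cat = rank[classify(s, bands).entries["max"][0]]
            assert cat >= prev
            prev = cat

    def test_pressure_bands_normal_values_green(self):
        from pulsarch.metrics import MMHG_PA

        bands = default_pressure_bands()
        s = MetricSummary(
            quantity="pressure", min=75 * MMHG_PA, avg=95 * MMHG_PA, max=120 * MMHG_PA
        )
        rep = classify(s, bands)
        assert all(cat == "green" for cat, _ in rep.entries.values())

    def test_quantity_mismatch_rejected(self):
        s = MetricSummary(quantity="pressure", min=1, avg=2, max=3)
        with pytest.raises(ValueError):
            classify(s, default_wss_bands())

    def test_band_spec_validation(self):
        with pytest.raises(ValueError):
            BandSpec(edges=(1.0, 0.5), categories=("green", "yellow", "red"))
        with pytest.raises(ValueError):
            BandSpec(edges=(1.0,), categories=("green",))

    def test_report_json_round_trip(self, tmp_path):
        import json

        rep = classify(
            MetricSummary(quantity="wss", min=0.005, avg=0.041, max=6.01),
            default_wss_bands(),
        )
        path = tmp_path / "severity.json"
        rep.to_json(path)
        doc = json.loads(path.read_text())
        assert doc["classification"]["max"]["category"] == "red"
        assert doc["bands"]["note"] == "illustrative"
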