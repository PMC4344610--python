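"""Karplus evaluation, snapshot averaging and experiment comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from glyconf.errors import EmptyInputError, PairingError, ValidationError
from glyconf.karplus import (
    CouplingRecord,
    KarplusParams,
    compare_couplings,
    ensemble_j,
    get_karplus_params,
    karplus_j,
    load_karplus_sets,
    mean_absolute_deviation,
    packaged_coupling_records,
    read_coupling_records,
    write_coupling_records,
)

TVA = get_karplus_params("tvaroska1989")


class TestKarplusJ:
    def test_cos_squared_only_vanishes_at_90(self):
        assert karplus_j(90.0, KarplusParams("a", 1, 0, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_unit_coefficients_at_zero(self):
        assert karplus_j(0.0, KarplusParams("a", 1, 1, 1)) == pytest.approx(3.0)

    @pytest.mark.parametrize(
        "theta,expected",
        [
            # hand evaluation of 5.7 cos^2 - 0.6 cos + 0.5
            (0.0, 5.7 - 0.6 + 0.5),  # 5.6
            (60.0, 5.7 * 0.25 - 0.6 * 0.5 + 0.5),  # 1.625
            (180.0, 5.7 + 0.6 + 0.5),  # 6.8
        ],
    )
    def test_default_parameterization_regression(self, theta, expected):
        assert karplus_j(theta, TVA) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-360, 360))
    @settings(max_examples=100, deadline=None)
    def test_even_and_periodic(self, theta):
        j = karplus_j(theta, TVA)
        assert j == pytest.approx(karplus_j(-theta, TVA), abs=1e-9)
        assert j == pytest.approx(karplus_j(theta + 360.0, TVA), abs=1e-9)

    def test_default_sets_loadable(self):
        sets = load_karplus_sets()
        assert "tvaroska1989" in sets
        assert sets["tvaroska1989"].A == pytest.approx(5.7)

    def test_unknown_set_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            get_karplus_params("no_such_set")


class TestEnsembleJ:
    def test_constant_ensemble_equals_pointwise(self):
        assert ensemble_j([40.0] * 1000, TVA) == pytest.approx(karplus_j(40.0, TVA), abs=1e-12)

    def test_two_frame_mean(self):
        t1, t2 = 10.0, 100.0
        want = 0.5 * (karplus_j(t1, TVA) + karplus_j(t2, TVA))
        assert ensemble_j([t1, t2], TVA) == pytest.approx(want, abs=1e-12)

    def test_empty_ensemble_raises(self):
        with pytest.raises(EmptyInputError):
            ensemble_j([], TVA)

    def test_negative_weight_raises(self):
        with pytest.raises(ValidationError):
            ensemble_j([1.0, 2.0], TVA, weights=[1.0, -1.0])

    def test_zero_weight_sum_raises(self):
        with pytest.raises(ValidationError):
            ensemble_j([1.0, 2.0], TVA, weights=[0.0, 0.0])

    def test_bounded_by_ensemble_extremes(self, rng):
        t = rng.uniform(-180, 180, size=500)
        j = karplus_j(t, TVA)
        assert j.min() - 1e-12 <= ensemble_j(t, TVA) <= j.max() + 1e-12

    def test_linear_in_mixture_weights(self, rng):
        e1 = rng.normal(40.0, 10.0, size=400)
        e2 = rng.normal(180.0, 10.0, size=400)
        w = 0.3
        mixed = ensemble_j(np.concatenate([e1, e2]), TVA,
                           weights=np.concatenate([np.full(400, w), np.full(400, 1 - w)]))
        assert mixed == pytest.approx(w * ensemble_j(e1, TVA) + (1 - w) * ensemble_j(e2, TVA),
                                      abs=1e-10)

    def test_two_state_mixture_matches_quadrature_oracle(self, rng):
        """<J> over a sampled 0.7/0.3 wrapped-Gaussian mixture agrees with
        the analytic expectation by numerical quadrature, within 3 s.e."""
        w1, w2 = 0.7, 0.3
        mu1, mu2, sigma = 40.0, 0.0, 10.0
        n = 10_000
        comp = rng.random(n) < w1
        theta = np.where(comp, rng.normal(mu1, sigma, n), rng.normal(mu2, sigma, n))
        got = ensemble_j(theta, TVA)

        def gauss_expect(mu):
            # J is periodic, so integrating the unwrapped Gaussian is exact
            f = lambda t: karplus_j(t, TVA) * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
            lo, hi = mu - 8 * sigma, mu + 8 * sigma
            num, _ = quad(f, lo, hi, limit=200)
            den = sigma * np.sqrt(2 * np.pi)
            return num / den

        want = w1 * gauss_expect(mu1) + w2 * gauss_expect(mu2)
        se = np.std(karplus_j(theta, TVA), ddof=1) / np.sqrt(n)
        assert abs(got - want) <= 3 * se

    def test_averages_j_not_theta(self):
        """On an asymmetric bimodal ensemble <J(theta)> and J(<theta>)
        differ; the implementation must return the former."""
        theta = np.concatenate([np.full(800, 40.0), np.full(200, 180.0)])
        j_of_mean = karplus_j(float(np.mean(theta)), TVA)
        mean_of_j = 0.8 * karplus_j(40.0, TVA) + 0.2 * karplus_j(180.0, TVA)
        assert abs(mean_of_j - j_of_mean) > 0.2  # the discriminating setup
        assert ensemble_j(theta, TVA) == pytest.approx(mean_of_j, abs=1e-12)


class TestComparison:
    def test_packaged_table_sasa_row_compound3(self):
        exp = packaged_coupling_records("experimental")
        sasa = packaged_coupling_records("SASA")
        table = compare_couplings(exp, sasa)
        row = table.rows.query(
            "compound == '3' and linkage == 'Fuc-GlA' and torsion_kind == 'phi'"
        ).iloc[0]
        assert row["deviation_hz"] == pytest.approx(0.3, abs=1e-12)
        assert bool(row["within_error"])

    def test_packaged_table_in_vacuo_row_compound1(self):
        exp = packaged_coupling_records("experimental")
        vac = packaged_coupling_records("in_vacuo")
        table = compare_couplings(exp, vac)
        row = table.rows.query(
            "compound == '1' and linkage == 'Fuc-GlA' and torsion_kind == 'psi'"
        ).iloc[0]
        assert row["deviation_hz"] == pytest.approx(1.3, abs=1e-12)
        assert not bool(row["within_error"])

    def test_identical_sets_all_within(self):
        exp = packaged_coupling_records("experimental")
        clone = [CouplingRecord(r.compound, r.linkage, r.torsion_kind, "synthetic", r.value_hz)
                 for r in exp]
        table = compare_couplings(exp, clone)
        assert (table.rows["deviation_hz"] == 0).all()
        assert table.rows["within_error"].all()
        assert mean_absolute_deviation(table) == 0.0

    def test_orphan_rows_raise_pairing_error(self):
        exp = packaged_coupling_records("experimental")
        sasa = packaged_coupling_records("SASA")[:-1]
        with pytest.raises(PairingError, match="unmatched"):
            compare_couplings(exp, sasa)

    def test_deterministic_row_order(self):
        exp = packaged_coupling_records("experimental")
        sasa = packaged_coupling_records("SASA")
        t1 = compare_couplings(exp, sasa)
        t2 = compare_couplings(list(reversed(exp)), list(reversed(sasa)))
        assert t1.rows.equals(t2.rows)

    def test_mad_sasa_is_034(self):
        table = compare_couplings(packaged_coupling_records("experimental"),
                                  packaged_coupling_records("SASA"))
        assert len(table) == 14
        assert round(mean_absolute_deviation(table), 2) == pytest.approx(0.34)

    def test_mad_in_vacuo_is_08(self):
        table = compare_couplings(packaged_coupling_records("experimental"),
                                  packaged_coupling_records("in_vacuo"))
        assert len(table) == 14
        assert round(mean_absolute_deviation(table), 1) == pytest.approx(0.8)

    def test_single_row_mad_is_its_deviation(self):
        e = [CouplingRecord("1", "L", "phi", "experimental", 3.0)]
        c = [CouplingRecord("1", "L", "phi", "synthetic", 2.4)]
        assert mean_absolute_deviation(compare_couplings(e, c)) == pytest.approx(0.6)

    def test_csv_round_trip(self, tmp_path):
        records = packaged_coupling_records("experimental")
        p = tmp_path / "couplings.csv"
        write_coupling_records(records, p)
        assert read_coupling_records(p) == records

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValidationError):
            CouplingRecord("1", "L", "phi", "experimental", -1.0)
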