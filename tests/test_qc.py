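"""Figures of merit and the trustworthiness classifier."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hybridqc.errors import (
    ConfigurationError,
    DomainError,
    EstimationError,
    UndefinedWidthError,
)
from hybridqc.fitting import fit_g2
from hybridqc.instrument import (
    DEFAULT_TAU_GRID,
    DTOFHistogram,
    G2Curve,
    make_irf,
    simulate_dtof,
)
from hybridqc.optics import (
    DCS_GEOMETRY,
    FlowSpec,
    ModelCurve,
    OpticalProperties,
    dcs_g1,
    mix_g1,
    siegert_g2,
)
from hybridqc.qc import (
    QCMetrics,
    QCRuleSet,
    classify,
    dcs_qc_metrics,
    detect_secondary_decay,
    fwhm,
    trs_qc_metrics,
)


class TestFWHM:
    def test_symmetric_triangle(self):
        x = np.linspace(0, 2, 2001)
        y = np.maximum(0.0, 1.0 - np.abs(x - 1.0))
        assert fwhm((x, y)) == pytest.approx(1.0, abs=1e-3)

    def test_scale_invariance(self):
        x = np.linspace(0, 2, 2001)
        y = np.exp(-0.5 * ((x - 1.0) / 0.2) ** 2)
        assert fwhm((x, y)) == pytest.approx(fwhm((x, 17.3 * y)), rel=1e-12)

    def test_monotone_ramp_has_no_width(self):
        x = np.linspace(0, 1, 100)
        with pytest.raises(UndefinedWidthError):
            fwhm((x, x))


def _dtof_like_irf(irf, scale=1000.0):
    """DTOF with the IRF's shape plus a tiny pre-pulse background texture."""
    counts = irf.values * scale
    mask = irf.t_grid < irf.peak_time - 5 * irf.fwhm
    counts = counts.copy()
    counts[mask] += np.tile([0.0, 1e-3], mask.sum() // 2 + 1)[: mask.sum()]
    return DTOFHistogram(t_grid=irf.t_grid, counts=counts, wavelength=687.0)


class TestTRSMetrics:
    def test_identity_case(self, irf):
        m = trs_qc_metrics(_dtof_like_irf(irf), irf)
        assert m.rfwhm == pytest.approx(1.0, abs=1e-6)
        assert m.dfwhm == pytest.approx(0.0, abs=1e-6)
        assert m.peak_delay == pytest.approx(0.0, abs=irf.dt)

    def test_printed_definitions(self):
        # rFWHM and dFWHM are ratio and difference of the two widths
        irf = make_irf(fwhm=0.4, t0=3.0)
        wide = make_irf(fwhm=1.2, t0=4.0)
        d = _dtof_like_irf(wide)
        d = DTOFHistogram(t_grid=irf.t_grid, counts=d.counts, wavelength=687.0)
        m = trs_qc_metrics(d, irf)
        assert m.rfwhm == pytest.approx(3.0, rel=0.01)
        assert m.dfwhm == pytest.approx(0.8, rel=0.01)

    def test_snr_is_peak_over_background_std(self, irf):
        counts = np.zeros_like(irf.t_grid)
        mask = irf.t_grid < irf.peak_time - 5 * irf.fwhm
        counts[mask] = np.tile([90.0, 110.0], mask.sum() // 2 + 1)[: mask.sum()]  # std 10
        ipk = int(np.argmax(irf.values))
        counts[ipk - 2: ipk + 3] = [400.0, 800.0, 1000.0, 800.0, 400.0]
        d = DTOFHistogram(t_grid=irf.t_grid, counts=counts, wavelength=687.0)
        m = trs_qc_metrics(d, irf)
        assert m.snr == pytest.approx(100.0, rel=0.01)
        assert m.dynamic_range == pytest.approx(1.0, abs=0.01)

    def test_zero_variance_background_raises(self, irf):
        counts = irf.values * 1000.0
        d = DTOFHistogram(t_grid=irf.t_grid, counts=counts, wavelength=687.0)
        with pytest.raises(ConfigurationError, match="zero variance"):
            trs_qc_metrics(d, irf)

    def test_too_small_background_window_raises(self):
        early = make_irf(fwhm=0.4, t0=0.5)
        d = _dtof_like_irf(early)
        with pytest.raises(ConfigurationError):
            trs_qc_metrics(d, early)

    @pytest.mark.parametrize("musp", [5.0, 10.0, 15.0])
    @pytest.mark.parametrize("mua", [0.1, 0.3])
    def test_diffusive_media_broaden_the_dtof(self, irf, mua, musp):
        # rFWHM > 1 and dFWHM > 0 for every diffusive medium
        d = simulate_dtof(OpticalProperties(mua, musp, 687.0), irf=irf,
                          total_counts=1e6, background_rate=1.0, seed=0)
        m = trs_qc_metrics(d, irf)
        assert m.rfwhm > 1.0
        assert m.dfwhm > 0.0


class TestDCSMetricsAndSecondary:
    def test_metrics_fields_filled(self, healthy_props):
        ideal = siegert_g2(dcs_g1(DEFAULT_TAU_GRID, healthy_props, FlowSpec(1e-8),
                                  DCS_GEOMETRY), 0.49)
        g2 = G2Curve(tau_grid=ideal.abscissa, values=ideal.values, count_rate=90.0)
        fit = fit_g2(g2, healthy_props)
        m = dcs_qc_metrics(g2, fit)
        assert m.count_rate == 90.0
        assert m.beta == pytest.approx(0.49, rel=0.01)
        assert m.bfi == pytest.approx(1e-8, rel=0.01)
        assert m.tail_plateau == pytest.approx(0.0, abs=0.02)

    def test_refused_fit_leaves_nulls(self):
        g2 = G2Curve(tau_grid=DEFAULT_TAU_GRID, values=np.ones_like(DEFAULT_TAU_GRID),
                     count_rate=0.3)
        m = dcs_qc_metrics(g2, None)
        assert m.count_rate == 0.3
        assert m.beta is None and m.bfi is None

    def test_mixture_tail_plateau_resolved(self, healthy_props):
        fast = dcs_g1(DEFAULT_TAU_GRID, healthy_props, FlowSpec(1e-8), DCS_GEOMETRY)
        slow = dcs_g1(DEFAULT_TAU_GRID, healthy_props, FlowSpec(1e-11), DCS_GEOMETRY)
        ideal = siegert_g2(mix_g1([(fast, 0.75), (slow, 0.25)]), 0.49)
        g2 = G2Curve(tau_grid=ideal.abscissa, values=ideal.values, count_rate=50.0)
        m = dcs_qc_metrics(g2, fit_g2(g2, healthy_props))
        assert m.tail_plateau is not None and m.tail_plateau > 0.15

    def test_pure_curve_has_no_secondary_decay(self, healthy_props):
        g1 = dcs_g1(DEFAULT_TAU_GRID, healthy_props, FlowSpec(1e-8), DCS_GEOMETRY)
        assert detect_secondary_decay(g1, props=healthy_props).present is False

    def test_mixture_secondary_decay_recovered(self, healthy_props):
        fast = dcs_g1(DEFAULT_TAU_GRID, healthy_props, FlowSpec(1e-8), DCS_GEOMETRY)
        slow = dcs_g1(DEFAULT_TAU_GRID, healthy_props, FlowSpec(1e-10), DCS_GEOMETRY)
        res = detect_secondary_decay(mix_g1([(fast, 0.75), (slow, 0.25)]),
                                     props=healthy_props)
        assert res.present
        assert res.slow_weight == pytest.approx(0.25, abs=0.05)

    def test_flat_curve_has_no_decay_to_analyze(self, healthy_props):
        flat = ModelCurve(abscissa=DEFAULT_TAU_GRID,
                          values=np.ones_like(DEFAULT_TAU_GRID), kind="g1")
        with pytest.raises(EstimationError, match="no decay"):
            detect_secondary_decay(flat, props=healthy_props)


HEALTHY_METRICS = dict(
    fwhm_dtof=0.8, fwhm_irf=0.4, rfwhm=2.0, dfwhm=0.4, snr=2000.0,
    dynamic_range=3.5, peak_delay=0.8, count_rate=90.0, beta=0.49,
    bfi=1.2e-8, tail_plateau=0.0, residual_norm=0.005,
)


class TestClassify:
    def test_healthy_metrics_acceptable(self):
        v = classify(QCMetrics(**HEALTHY_METRICS))
        assert v.label == "acceptable" and v.reasons == []

    @pytest.mark.parametrize(
        "field,value,label,rule",
        [
            ("snr", 5.0, "reject", "snr_low"),
            ("dynamic_range", 2.0, "reject", "dynamic_range_low"),
            ("count_rate", 0.3, "reject", "count_rate_below_noise_level"),
            ("count_rate", 250.0, "suspect", "count_rate_saturated"),
            ("beta", 0.6, "suspect", "beta_high"),
            ("beta", 0.2, "suspect", "beta_low"),
            ("bfi", 1e-10, "suspect", "bfi_unreliable"),
            ("bfi", 5e-10, "suspect", "bfi_below_normal_range"),
            ("bfi", 2e-7, "suspect", "bfi_above_normal_range"),
            ("tail_plateau", 0.2, "suspect", "g1_tail_not_zero"),
            ("rfwhm", 0.9, "suspect", "rfwhm_not_broadened"),
            ("dfwhm", -0.1, "suspect", "dfwhm_not_positive"),
            ("peak_delay", 0.3, "suspect", "peak_delay_short"),
        ],
    )
    def test_single_violations(self, field, value, label, rule):
        m = QCMetrics(**{**HEALTHY_METRICS, field: value})
        v = classify(m)
        assert v.label == label
        assert rule in {r.rule for r in v.reasons}

    def test_refusal_dominates(self):
        v = classify(QCMetrics(**HEALTHY_METRICS), refusals=["insufficient dynamic range"])
        assert v.label == "reject"

    def test_reject_dominates_suspect(self):
        m = QCMetrics(**{**HEALTHY_METRICS, "snr": 5.0, "beta": 0.7})
        assert classify(m).label == "reject"

    def test_reasons_reproduce_label(self):
        m = QCMetrics(**{**HEALTHY_METRICS, "beta": 0.7, "tail_plateau": 0.1})
        v = classify(m)
        severities = {r.severity for r in v.reasons}
        expected = ("reject" if "hard" in severities
                    else "suspect" if severities else "acceptable")
        assert v.label == expected == "suspect"

    @given(st.data())
    def test_improving_any_metric_never_worsens_the_label(self, data):
        rules = QCRuleSet()
        compliant = {
            "snr": 100.0, "dynamic_range": 4.0, "peak_delay": 1.0, "rfwhm": 2.0,
            "dfwhm": 0.5, "count_rate": 50.0, "beta": 0.45, "bfi": 1e-8,
            "tail_plateau": 0.01,
        }
        field = data.draw(st.sampled_from(sorted(compliant)))
        bad_values = {
            "snr": 1.0, "dynamic_range": 0.5, "peak_delay": 0.1, "rfwhm": 0.5,
            "dfwhm": -0.5, "count_rate": 0.1, "beta": 0.9, "bfi": 1e-11,
            "tail_plateau": 0.5,
        }
        base = {**HEALTHY_METRICS, field: bad_values[field]}
        order = {"acceptable": 0, "suspect": 1, "reject": 2}
        worse = classify(QCMetrics(**base), rules=rules)
        better = classify(QCMetrics(**{**base, field: compliant[field]}), rules=rules)
        assert order[better.label] <= order[worse.label]

    def test_sto2_rules(self):
        from hybridqc.fitting import Hemodynamics

        m = QCMetrics(**HEALTHY_METRICS)
        low = Hemodynamics(c_hbo2=20, c_hhb=40, thc=60, sto2=33.3)
        high = Hemodynamics(c_hbo2=55, c_hhb=5, thc=60, sto2=91.7)
        ok = Hemodynamics(c_hbo2=40, c_hhb=20, thc=60, sto2=66.7)
        assert classify(m, hemo=low).label == "suspect"
        assert classify(m, hemo=high).label == "suspect"
        assert classify(m, hemo=ok).label == "acceptable"


class TestRuleSet:
    def test_yaml_round_trip(self, tmp_path):
        rules = QCRuleSet(snr_min=12.0, beta_window=(0.3, 0.6))
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        loaded = QCRuleSet.from_yaml(path)
        assert dataclasses.asdict(loaded) == dataclasses.asdict(rules)

    def test_unknown_field_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown rule"):
            QCRuleSet.from_dict({"snr_min": 10, "bogus": 1})

    def test_unordered_window_rejected(self):
        with pytest.raises(ConfigurationError):
            QCRuleSet(beta_window=(0.6, 0.3))
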