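"""Ventilator-equivalent parameters and truth-based evaluation."""

import numpy as np
import pytest

from depthresp import (AlignmentError, CycleMarkers, FilterSpec, FlowSeries,
                       VolumeSeries, assemble_report, compute_flow, detect_cycles,
                       evaluate_against_truth, filter_volume, minute_ventilation,
                       peak_flows, phase_times, respiratory_rate, tidal_volumes)
from depthresp.phantom import GroundTruth
from depthresp.respparams import RespiratoryReport


def make_series(values, fps=30.0):
    values = np.asarray(values, dtype=float)
    return VolumeSeries(time=np.arange(len(values)) / fps, volume=values, fps=fps)


def sinusoid_series(freq=0.25, amp=200.0, duration=30.0, fps=30.0):
    t = np.arange(int(duration * fps)) / fps
    return make_series(amp * np.sin(2 * np.pi * freq * t), fps=fps)


@pytest.fixture
def sine_setup():
    s = sinusoid_series()
    m = detect_cycles(s)
    f = compute_flow(s)
    return s, m, f


def markers_from_triples(triples):
    peaks = np.array([p for _, p, _ in triples])
    troughs = np.array(sorted({t for t, _, _ in triples} | {t for _, _, t in triples}))
    return CycleMarkers(peak_indices=peaks, trough_indices=troughs,
                        pairing=list(triples))


class TestRates:
    def test_seven_cycles_over_28s(self):
        triples = [(90 + 120 * i, 150 + 120 * i, 210 + 120 * i) for i in range(7)]
        m = markers_from_triples(triples)
        # span = (930 - 90) / 30 = 28 s, 7 cycles -> 15 breaths/min
        assert respiratory_rate(m, 30.0) == pytest.approx(15.0)

    def test_single_four_second_cycle(self):
        m = markers_from_triples([(0, 60, 120)])
        assert respiratory_rate(m, 30.0) == pytest.approx(15.0)


class TestTidalVolumes:
    def test_sinusoid_peak_to_trough(self, sine_setup):
        s, m, _ = sine_setup
        vts = tidal_volumes(s, m)
        np.testing.assert_allclose(vts, 400.0, rtol=0.01)

    def test_conventions_agree_on_symmetric_waveform(self, sine_setup):
        s, m, _ = sine_setup
        np.testing.assert_allclose(tidal_volumes(s, m, "expiratory"),
                                   tidal_volumes(s, m, "inspiratory"), rtol=0.01)

    def test_offset_invariance(self, sine_setup):
        s, m, _ = sine_setup
        shifted = make_series(s.volume + 1234.5)
        np.testing.assert_allclose(tidal_volumes(shifted, m), tidal_volumes(s, m),
                                   atol=1e-9)


class TestMinuteVentilation:
    def test_example(self):
        triples = [(90 + 120 * i, 150 + 120 * i, 210 + 120 * i) for i in range(7)]
        m = markers_from_triples(triples)
        mev = minute_ventilation([400.0] * 7, m, 30.0)
        assert mev == pytest.approx(6000.0)

    def test_identity_with_mean_vt_times_rr(self, sine_setup):
        s, m, _ = sine_setup
        vts = tidal_volumes(s, m)
        mev = minute_ventilation(vts, m, 30.0)
        assert mev == pytest.approx(vts.mean() * respiratory_rate(m, 30.0), abs=1e-9)


class TestPhaseTimes:
    def test_symmetric_sinusoid_one_to_one(self, sine_setup):
        _, m, _ = sine_setup
        ti, te, ie = phase_times(m, 30.0)
        assert ie == pytest.approx(1.0, abs=0.05)

    def test_explicit_single_cycle(self):
        m = markers_from_triples([(0, 30, 90)])  # ti = 1 s, te = 2 s
        ti, te, ie = phase_times(m, 30.0)
        assert (ti, te) == (1.0, 2.0)
        assert ie == pytest.approx(2.0)


class TestPeakFlows:
    def test_sinusoid_standard_convention(self, sine_setup):
        _, m, f = sine_setup
        expected = 2 * np.pi * 0.25 * 200.0
        flows = peak_flows(f, m, convention="standard")
        for pif, pef in flows:
            assert pif == pytest.approx(expected, rel=0.01)
            assert pef == pytest.approx(expected, rel=0.01)

    def test_sinusoid_paper_convention_doubles(self, sine_setup):
        _, m, f = sine_setup
        expected = 4 * np.pi * 0.25 * 200.0
        flows = [pair for pair in peak_flows(f, m, convention="paper")
                 if None not in pair]
        assert flows
        for pif, pef in flows:
            assert pif == pytest.approx(expected, rel=0.01)
            assert pef == pytest.approx(expected, rel=0.01)

    def test_constant_volume_reports_missing(self):
        s = make_series(np.full(300, 5.0))
        m = markers_from_triples([(0, 60, 120)])
        f = compute_flow(s)
        assert peak_flows(f, m, convention="paper") == [(None, None)]


class TestReport:
    def test_roundtrip_json(self, sine_setup):
        s, m, f = sine_setup
        report = assemble_report(s, f, m)
        text = report.to_json()
        again = RespiratoryReport.from_json(text)
        assert again.to_dict() == report.to_dict()

    def test_aggregates_are_consistent(self, sine_setup):
        s, m, f = sine_setup
        report = assemble_report(s, f, m)
        assert report.n_cycles == m.n_cycles
        assert report.minute_ventilation == pytest.approx(
            report.mean_vt * report.rr, abs=1e-9)
        assert report.ie_ratio == pytest.approx(report.mean_te / report.mean_ti)

    def test_amplitude_series_override(self):
        filt = filter_volume(sinusoid_series(freq=0.7), FilterSpec(fps=30.0))
        raw = sinusoid_series(freq=0.7)
        m = detect_cycles(filt)
        f = compute_flow(filt)
        from_filtered = assemble_report(filt, f, m)
        from_raw = assemble_report(filt, f, m, amplitude_series=raw)
        assert from_raw.mean_vt > from_filtered.mean_vt  # low-pass gain < 1 at 0.7 Hz
        assert from_raw.mean_vt == pytest.approx(400.0, rel=0.01)


class TestEvaluate:
    def _truth(self, series, vt=400.0, rr=15.0):
        return GroundTruth(time=series.time, true_volume=series.volume.copy(),
                           true_flow=np.zeros_like(series.volume), true_rr=rr,
                           true_vt=vt, true_ti=2.0, true_te=2.0, true_ie=1.0,
                           true_pif_standard=1.0, true_pef_standard=1.0,
                           true_pif_paper=2.0, true_pef_paper=2.0)

    def test_self_comparison_perfect(self, sine_setup):
        s, m, f = sine_setup
        report = assemble_report(s, f, m)
        metrics = evaluate_against_truth(report, s, self._truth(s))
        assert metrics["pearson_r"] == pytest.approx(1.0)
        assert metrics["vt_mape_pct"] == pytest.approx(0.0, abs=1.0)

    def test_offset_does_not_change_correlation(self, sine_setup):
        s, m, f = sine_setup
        report = assemble_report(s, f, m)
        shifted = make_series(s.volume + 500.0)
        metrics = evaluate_against_truth(report, shifted, self._truth(s))
        assert metrics["pearson_r"] == pytest.approx(1.0)

    def test_antiphase_is_minus_one(self, sine_setup):
        s, m, f = sine_setup
        report = assemble_report(s, f, m)
        neg = make_series(-s.volume)
        metrics = evaluate_against_truth(report, neg, self._truth(s))
        assert metrics["pearson_r"] == pytest.approx(-1.0)

    def test_length_mismatch_raises(self, sine_setup):
        s, m, f = sine_setup
        report = assemble_report(s, f, m)
        short = make_series(s.volume[:-10])
        with pytest.raises(AlignmentError):
            evaluate_against_truth(report, short, self._truth(s))
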