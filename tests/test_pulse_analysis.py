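"""Two-layer classifier: candidate gathering, dominance, symmetry,
triangulation, and the negation-duality property."""

import numpy as np
import pytest

from ppginv import (
    AnalysisParams,
    InvalidInputError,
    PulseCandidate,
    TooShortError,
    analyze_series,
    gather_candidates,
    generate_recording,
    phase_by_triangulation,
    prepare,
    symmetry_check,
    verify_dominance,
)
from ppginv.pulse_analysis import (
    INDETERMINATE,
    INVERTED,
    NON_INVERTED,
    PEAK,
    TROUGH,
    _cos_vertex_angle,
    find_local_extrema,
)


class TestGatherCandidates:
    def test_monotone_ramp_empty(self, make_series):
        assert gather_candidates(make_series(np.linspace(0, 1, 1000))) == []

    def test_constant_empty(self, make_series):
        assert gather_candidates(make_series(np.zeros(1000))) == []

    def test_single_sine_period(self, make_series):
        n = 4800
        x = np.sin(2 * np.pi * np.arange(n) / n)
        cands = gather_candidates(make_series(x))
        assert [c.kind for c in cands] == [PEAK, TROUGH]
        assert abs(cands[0].index - n // 4) <= 1
        assert abs(cands[1].index - 3 * n // 4) <= 1

    def test_plateau_midpoint(self, make_series):
        x = np.zeros(1000)
        x[490:495] = 1.0  # 5-sample plateau peak, midpoint at 492
        cands = gather_candidates(make_series(x))
        plateau = [c for c in cands if c.kind == PEAK and c.is_plateau]
        assert [c.index for c in plateau] == [492]

    def test_end_margin_dropped(self, make_series):
        x = np.zeros(1000)
        x[100] = 1.0  # within the 240-sample symmetry margin
        x[500] = 1.0
        cands = gather_candidates(make_series(x))
        assert all(c.index >= 240 for c in cands)
        assert any(c.index == 500 for c in cands)

    def test_too_short(self, make_series):
        series = make_series(np.zeros(500))
        series.values = series.values[:2]  # bypass constructor check
        with pytest.raises(TooShortError):
            gather_candidates(series)


class TestVerifyDominance:
    def test_clean_pulse_train_verified(self, make_prepared):
        series, _ = make_prepared(seed=2, duration_s=20.0)
        for c in gather_candidates(series):
            window = series.values[
                max(0, c.index - 150) : c.index + 151
            ]
            brute = (
                not np.any(window > series.values[c.index])
                if c.kind == PEAK
                else not np.any(window < series.values[c.index])
            )
            assert verify_dominance(series, c) == brute

    def test_larger_neighbour_disqualifies(self, make_series):
        x = np.zeros(1000)
        x[500] = 1.0
        x[600] = 2.0
        series = make_series(x)
        c = next(c for c in gather_candidates(series) if c.index == 500)
        assert not verify_dominance(series, c)

    def test_tie_does_not_disqualify(self, make_series):
        x = np.ones(1000)
        x[500] = 0.0
        x[520] = 0.0  # equal-valued trough inside the window
        x[400] = 2.0
        x[700] = 2.0
        series = make_series(x)
        trough = next(
            c for c in gather_candidates(series) if c.kind == TROUGH and c.index == 500
        )
        assert verify_dominance(series, trough)

    def test_bad_index_rejected(self, make_series):
        series = make_series(np.zeros(500))
        with pytest.raises(InvalidInputError):
            verify_dominance(series, PulseCandidate(index=999, kind=PEAK))


class TestSymmetryCheck:
    @staticmethod
    def _ramp(up_slope, down_slope, w=240):
        up = up_slope * np.arange(w + 1)
        down = up[-1] - down_slope * np.arange(1, w + 1)
        series = np.concatenate(
            [np.full(300, 0.0), up, down, np.full(300, down[-1])]
        )
        apex = 300 + w
        return series, apex

    def test_steep_rise_slow_fall_passes(self, make_series):
        x, apex = self._ramp(2.0, 1.0)
        passed, label = symmetry_check(make_series(x), PulseCandidate(apex, PEAK))
        assert passed and label == +1

    def test_mirrored_trough_passes(self, make_series):
        x, apex = self._ramp(2.0, 1.0)
        passed, label = symmetry_check(make_series(-x), PulseCandidate(apex, TROUGH))
        assert passed and label == -1

    def test_symmetric_triangle_fails(self, make_series):
        x, apex = self._ramp(1.0, 1.0)
        passed, label = symmetry_check(make_series(x), PulseCandidate(apex, PEAK))
        assert not passed and label is None

    def test_truncated_window_excluded_not_error(self, make_series):
        series = make_series(np.sin(np.arange(1000) / 20.0))
        passed, label = symmetry_check(series, PulseCandidate(index=10, kind=PEAK))
        assert not passed and label is None


class TestTriangulationGeometry:
    @pytest.mark.parametrize(
        "P, L, R, expected",
        [
            ((1, 1), (0, 0), (2, 0), 0.0),  # right angle at apex
            ((1, 2), (0, 0), (2, 0), 0.6),  # sharper apex -> acute
            ((1, 0.2), (0, 0), (2, 0), (1.04 + 1.04 - 4) / (2 * 1.04)),  # blunt
        ],
    )
    def test_law_of_cosines(self, P, L, R, expected):
        got = _cos_vertex_angle(np.array(P, float), np.array(L, float), np.array(R, float))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_cos_theta_bounded_and_gain_invariant(self, make_prepared):
        series, _ = make_prepared(seed=9, duration_s=20.0)
        cands = analyze_series(series)
        cos_a = [c.cos_theta for c in cands if c.cos_theta is not None]
        assert cos_a and all(-1.0 <= v <= 1.0 for v in cos_a)
        # positive affine transform of intensity leaves angles unchanged
        series.values = 3.5 * series.values + 17.0
        cos_b = [c.cos_theta for c in analyze_series(series) if c.cos_theta is not None]
        np.testing.assert_allclose(cos_a, cos_b, atol=1e-9)


class TestPhaseByTriangulation:
    def test_sharper_troughs_means_inverted(self):
        cands = [PulseCandidate(0, TROUGH, cos_theta=0.6) for _ in range(3)] + [
            PulseCandidate(0, PEAK, cos_theta=-0.9) for _ in range(3)
        ]
        assert phase_by_triangulation(cands) == INVERTED

    def test_no_angles_indeterminate(self):
        assert phase_by_triangulation([]) == INDETERMINATE
        assert phase_by_triangulation([PulseCandidate(0, PEAK, cos_theta=0.5)]) == INDETERMINATE

    def test_clean_recording_called_non_inverted(self, make_prepared):
        series, _ = make_prepared(seed=4, fraction_inverted=0.0)
        cands = analyze_series(series)
        peak_cos = [c.cos_theta for c in cands if c.kind == PEAK and c.cos_theta is not None]
        trough_cos = [c.cos_theta for c in cands if c.kind == TROUGH and c.cos_theta is not None]
        assert np.mean(peak_cos) > np.mean(trough_cos)
        assert phase_by_triangulation(cands) == NON_INVERTED


class TestNegationDuality:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_duality(self, make_prepared, make_series, seed):
        import dataclasses

        series, _ = make_prepared(seed=seed, duration_s=30.0, fraction_inverted=0.3)
        flipped = dataclasses.replace(series, values=-series.values)
        a = analyze_series(series)
        b = analyze_series(flipped)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.index == cb.index
            assert ca.kind != cb.kind
            assert ca.verified == cb.verified
            assert ca.symmetry_pass == cb.symmetry_pass
            if ca.label is not None:
                assert cb.label == -ca.label
            assert (ca.cos_theta is None) == (cb.cos_theta is None)
            if ca.cos_theta is not None:
                assert ca.cos_theta == cb.cos_theta  # exactly
        phases = {phase_by_triangulation(a), phase_by_triangulation(b)}
        assert phases in ({INVERTED, NON_INVERTED}, {INDETERMINATE})


def test_labels_only_for_symmetry_passing(make_prepared):
    series, _ = make_prepared(seed=6, duration_s=20.0, fraction_inverted=0.5)
    for c in analyze_series(series):
        if c.label is not None:
            assert c.symmetry_pass and c.label in (-1, +1)
        else:
            assert not c.symmetry_pass


def test_find_local_extrema_too_short():
    with pytest.raises(TooShortError):
        find_local_extrema(np.array([1.0, 2.0]))
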