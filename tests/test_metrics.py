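"""Inversion statistics: mu, DOI, binary classification, OOI, flags, grid."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppginv
from ppginv import (
    DuplicateMeasurementError,
    InvalidInputError,
    InversionEstimate,
    MetricParams,
    OccurrenceCell,
    UndefinedEstimateError,
    aggregate_grid,
    classify_inverted,
    degree_of_inversion,
    estimate_inversion,
    flags,
    mu_inversion,
    occurrence_of_inversion,
)
from ppginv.pulse_analysis import INDETERMINATE, INVERTED, NON_INVERTED

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


class TestMuInversion:
    @pytest.mark.parametrize(
        "labels, expected",
        [([1] * 10, 1.0), ([-1] * 10, -1.0), ([1, 1, -1, -1], 0.0)],
    )
    def test_mean_label(self, labels, expected):
        assert mu_inversion(labels) == expected

    def test_empty_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            mu_inversion([])

    def test_nonbinary_rejected(self):
        with pytest.raises(InvalidInputError):
            mu_inversion([1, 0, -1])


class TestDegreeOfInversion:
    @pytest.mark.parametrize("mu, doi", [(1.0, 0.0), (-1.0, 1.0), (0.5, 0.25)])
    def test_mapping(self, mu, doi):
        assert degree_of_inversion(mu) == doi

    def test_out_of_range(self):
        with pytest.raises(InvalidInputError):
            degree_of_inversion(1.5)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_round_trip_identity(self, mu):
        doi = degree_of_inversion(mu)
        assert 0.0 <= doi <= 1.0
        assert 1.0 - 2.0 * doi == pytest.approx(mu, abs=1e-15)


class TestClassify:
    @pytest.mark.parametrize("doi, expected", [(0.25, 0), (0.26, 1), (0.0, 0), (1.0, 1)])
    def test_strict_threshold(self, doi, expected):
        assert classify_inverted(doi) == expected

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_ooi_monotone_in_added_inverted_recording(self, dois):
        params = MetricParams()
        cell = OccurrenceCell(position=0, pressure="low", led="ir", dois=list(dois))
        before = occurrence_of_inversion(cell, params)
        cell.dois.append(0.9)  # above threshold
        assert occurrence_of_inversion(cell, params) >= before
        # adding an inverted label never decreases DOI
        labels = [1] * 5
        doi_before = degree_of_inversion(mu_inversion(labels))
        doi_after = degree_of_inversion(mu_inversion(labels + [-1]))
        assert doi_after >= doi_before


class TestOccurrence:
    def test_worked_example_one_in_twelve(self):
        cell = OccurrenceCell(0, "high", "ir", dois=[0.9] + [0.0] * 11)
        assert occurrence_of_inversion(cell) == pytest.approx(1 / 12)
        assert round(100 * occurrence_of_inversion(cell), 2) == 8.33

    def test_none_and_all(self):
        assert occurrence_of_inversion(OccurrenceCell(0, "low", "ir", [0.1] * 12)) == 0.0
        assert occurrence_of_inversion(OccurrenceCell(0, "low", "ir", [0.9] * 5)) == 1.0

    def test_empty_cell_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            occurrence_of_inversion(OccurrenceCell(0, "low", "ir", []))

    @given(st.permutations(list(np.linspace(0, 1, 9))))
    def test_permutation_invariance(self, dois):
        cell = OccurrenceCell(0, "low", "ir", dois=list(dois))
        ref = OccurrenceCell(0, "low", "ir", dois=sorted(dois))
        assert occurrence_of_inversion(cell) == occurrence_of_inversion(ref)


class TestFlags:
    def test_disagreement(self):
        est = InversionEstimate(
            mu_inversion=0.9, n_pulses=10, doi=0.05,
            symmetry_phase=NON_INVERTED, triangulation_phase=INVERTED,
        )
        assert flags(est).disagreement_flag

    def test_noise(self):
        est = InversionEstimate(
            mu_inversion=0.1, n_pulses=10, doi=0.45,
            symmetry_phase=NON_INVERTED, triangulation_phase=NON_INVERTED,
        )
        out = flags(est)
        assert out.noise_flag and not out.disagreement_flag
        assert out.mu_inversion == est.mu_inversion  # flags never alter the estimate

    def test_clean(self):
        est = InversionEstimate(
            mu_inversion=-0.95, n_pulses=10, doi=0.975,
            symmetry_phase=INVERTED, triangulation_phase=INVERTED,
        )
        out = flags(est)
        assert not out.noise_flag and not out.disagreement_flag

    def test_indeterminate_triangulation_is_not_disagreement(self):
        est = InversionEstimate(
            mu_inversion=0.9, n_pulses=10, doi=0.05,
            symmetry_phase=NON_INVERTED, triangulation_phase=INDETERMINATE,
        )
        assert not flags(est).disagreement_flag


def _estimate(doi, participant, position, pressure, led, excluded=False):
    mu = None if doi is None else 1 - 2 * doi
    est = InversionEstimate(
        mu_inversion=mu, n_pulses=0 if excluded else 50, doi=doi, excluded=excluded
    )
    meta = {"participant": participant, "position_mm": position, "pressure": pressure, "led": led}
    return est, meta


class TestAggregateGrid:
    def _study(self, inverted_cells=(), participants=4, positions=(-1, 0, 1)):
        out = []
        for s in range(participants):
            for pos in positions:
                for pres in ("low", "high"):
                    for led in ("ir", "green"):
                        doi = 0.9 if (pos, pres, led) in inverted_cells else 0.0
                        out.append(_estimate(doi, f"S{s+1}", pos, pres, led))
        return out

    def test_all_clean_all_zero(self):
        res = aggregate_grid(self._study())
        assert (res.grid["ooi"] == 0).all()
        assert (res.per_led["ooi"] == 0).all()
        assert (res.per_subject["occurrence"] == 0).all()

    def test_planted_cells_recovered_exactly(self):
        planted = {(0, "high", "ir"), (1, "low", "green")}
        res = aggregate_grid(self._study(inverted_cells=planted))
        for _, row in res.grid.iterrows():
            expected = 1.0 if (row.position_mm, row.pressure, row.led) in planted else 0.0
            assert row.ooi == expected

    def test_one_of_twelve(self):
        rows = [_estimate(0.9 if s == 0 else 0.0, f"S{s+1}", -5, "high", "ir") for s in range(12)]
        res = aggregate_grid(rows)
        assert res.grid.loc[0, "ooi"] == pytest.approx(1 / 12)

    def test_duplicate_key_rejected(self):
        rows = [_estimate(0.0, "S1", 0, "low", "ir")] * 2
        with pytest.raises(DuplicateMeasurementError):
            aggregate_grid(rows)

    def test_excluded_dropped_from_denominators(self):
        rows = [
            _estimate(0.9, "S1", 0, "low", "ir"),
            _estimate(None, "S2", 0, "low", "ir", excluded=True),
        ]
        res = aggregate_grid(rows)
        assert res.grid.loc[0, "n_recordings"] == 1
        assert res.grid.loc[0, "ooi"] == 1.0

    def test_grand_mean_consistency(self):
        planted = {(0, "high", "ir"), (0, "low", "ir"), (1, "high", "green")}
        res = aggregate_grid(self._study(inverted_cells=planted))
        for pos, group in res.per_led.groupby("position_mm"):
            grand = res.overall.set_index("position_mm").loc[pos, "mean_ooi"]
            assert group["ooi"].mean() == pytest.approx(grand)

    def test_all_excluded_empty(self):
        rows = [_estimate(None, "S1", 0, "low", "ir", excluded=True)]
        res = aggregate_grid(rows)
        assert res.grid.empty


class TestFractionRecovery:
    """A recording with inverted-beat fraction f yields DOI ~ f."""

    @pytest.mark.parametrize("frac", [0.0, 0.25, 0.6, 1.0])
    def test_doi_tracks_planted_fraction(self, make_prepared, frac):
        series, truth = make_prepared(seed=21, fraction_inverted=frac, duration_s=30.0)
        est = estimate_inversion(series)
        assert not est.excluded
        assert est.doi == pytest.approx(truth.fraction_inverted("ir"), abs=2 / est.n_pulses)
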