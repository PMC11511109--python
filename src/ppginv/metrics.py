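"""Inversion statistics and protocol-grid aggregation.

Per recording: the mean pulse label mu = (1/N) sum(a_i) with a_i = +1 for
non-inverted and -1 for inverted pulses; the degree of inversion
DOI = (1 - mu)/2 in [0, 1]; and a binary classification *inverted* iff
DOI > 0.25 (strict).  Per configuration cell (position x pressure x LED):
the occurrence of inversion OOI = fraction of analyzable recordings
classified inverted.  Recordings whose layers disagree are flagged, never
auto-resolved; recordings with |mu| < 0.3 are noise-flagged (inconsistent
pulses drive the mean label toward zero); excluded recordings are dropped
from every denominator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateMeasurementError,
    InvalidInputError,
    UndefinedEstimateError,
)
from .preprocess import PulseSeries
from .pulse_analysis import (
    INDETERMINATE,
    INVERTED,
    NON_INVERTED,
    AnalysisParams,
    PulseCandidate,
    analyze_series,
    phase_by_triangulation,
)


@dataclass
class MetricParams:
    """Thresholds: DOI > ``doi_threshold`` is a significantly inverted
    recording; |mu| < ``noise_mu_threshold`` raises the noise flag."""

    doi_threshold: float = 0.25
    noise_mu_threshold: float = 0.3

    def __post_init__(self) -> None:
        for name in ("doi_threshold", "noise_mu_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidInputError(f"{name} must be in (0, 1), got {v!r}")


@dataclass
class InversionEstimate:
    """Per-recording (per-channel) inversion summary."""

    mu_inversion: Optional[float]
    n_pulses: int
    doi: Optional[float]
    symmetry_phase: str = INDETERMINATE
    triangulation_phase: str = INDETERMINATE
    disagreement_flag: bool = False
    noise_flag: bool = False
    excluded: bool = False
    source_id: str = ""
    channel: str = ""


def mu_inversion(labels: Sequence[int]) -> float:
    """Mean pulse label over a recording, in [-1, 1].

    +1 means consistently non-inverted, -1 consistently inverted; values
    near zero indicate mixed polarity or noise.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise UndefinedEstimateError(
            "mu_inversion is undefined for a recording with no symmetry-passing "
            "pulses; mark the recording excluded"
        )
    if not np.all(np.isin(labels, (-1, 1))):
        raise InvalidInputError("labels must all be +1 or -1")
    return float(labels.mean())


def degree_of_inversion(mu: float) -> float:
    """DOI = (1 - mu)/2: 0 is completely non-inverted, 1 fully inverted."""
    if not -1.0 <= mu <= 1.0:
        raise InvalidInputError(f"mu must be in [-1, 1], got {mu!r}")
    return (1.0 - mu) / 2.0


def classify_inverted(doi: float, params: MetricParams | None = None) -> int:
    """Binary classification b = 1 iff DOI > threshold (strict)."""
    params = params or MetricParams()
    if not 0.0 <= doi <= 1.0:
        raise InvalidInputError(f"doi must be in [0, 1], got {doi!r}")
    return int(doi > params.doi_threshold)


@dataclass
class OccurrenceCell:
    """One (position, pressure, LED) configuration cell.

    ``dois`` holds the DOI of every *analyzable* recording at this
    configuration (excluded recordings are absent and do not count toward
    the denominator).
    """

    position: int
    pressure: str
    led: str
    dois: list = field(default_factory=list)

    @property
    def n_recordings(self) -> int:
        return len(self.dois)

    def n_inverted(self, params: MetricParams | None = None) -> int:
        params = params or MetricParams()
        return sum(classify_inverted(d, params) for d in self.dois)


def occurrence_of_inversion(cell: OccurrenceCell, params: MetricParams | None = None) -> float:
    """OOI: fraction of the cell's analyzable recordings classified inverted."""
    params = params or MetricParams()
    if cell.n_recordings == 0:
        raise UndefinedEstimateError(
            f"OOI undefined for empty cell (position {cell.position:+d}, "
            f"{cell.pressure}, {cell.led}); report the cell as missing, not zero"
        )
    return cell.n_inverted(params) / cell.n_recordings


def flags(estimate: InversionEstimate, params: MetricParams | None = None) -> InversionEstimate:
    """Return a copy with the disagreement and noise flags set.

    The disagreement flag fires iff both layer phases are defined and
    unequal; the noise flag iff |mu| is below the noise threshold.  Neither
    alters mu or DOI — flagged recordings are surfaced for an exclusion
    decision, never auto-excluded.
    """
    params = params or MetricParams()
    disagreement = (
        estimate.symmetry_phase != INDETERMINATE
        and estimate.triangulation_phase != INDETERMINATE
        and estimate.symmetry_phase != estimate.triangulation_phase
    )
    noise = (
        estimate.mu_inversion is not None
        and abs(estimate.mu_inversion) < params.noise_mu_threshold
    )
    return dataclasses.replace(estimate, disagreement_flag=disagreement, noise_flag=noise)


def estimate_from_candidates(
    candidates: Sequence[PulseCandidate],
    params: MetricParams | None = None,
    source_id: str = "",
    channel: str = "",
) -> InversionEstimate:
    """Build the per-recording estimate from annotated candidates."""
    params = params or MetricParams()
    labels = [c.label for c in candidates if c.symmetry_pass and c.label is not None]
    tri_phase = phase_by_triangulation(candidates)
    if not labels:
        est = InversionEstimate(
            mu_inversion=None,
            n_pulses=0,
            doi=None,
            symmetry_phase=INDETERMINATE,
            triangulation_phase=tri_phase,
            excluded=True,
            source_id=source_id,
            channel=channel,
        )
        return flags(est, params)
    mu = mu_inversion(labels)
    sym_phase = NON_INVERTED if mu > 0 else INVERTED if mu < 0 else INDETERMINATE
    est = InversionEstimate(
        mu_inversion=mu,
        n_pulses=len(labels),
        doi=degree_of_inversion(mu),
        symmetry_phase=sym_phase,
        triangulation_phase=tri_phase,
        source_id=source_id,
        channel=channel,
    )
    return flags(est, params)


def estimate_inversion(
    series: PulseSeries,
    analysis_params: AnalysisParams | None = None,
    metric_params: MetricParams | None = None,
) -> InversionEstimate:
    """Full classifier on one prepared series: candidates -> estimate + flags."""
    candidates = analyze_series(series, analysis_params)
    return estimate_from_candidates(
        candidates, metric_params, source_id=series.source_id, channel=series.channel
    )


@dataclass
class GridResult:
    """Occurrence-of-inversion grid and its marginal summaries.

    ``grid``: one row per (position, pressure, LED) cell with
    ``n_recordings``, ``n_inverted``, ``ooi``.  Marginals average cell OOI:
    ``per_led`` over pressures, ``per_pressure`` over LEDs, ``overall``
    over both (mean and median per position).  ``per_subject`` is each
    participant's inverted fraction over all their analyzable recordings.
    """

    grid: pd.DataFrame
    per_led: pd.DataFrame
    per_pressure: pd.DataFrame
    per_subject: pd.DataFrame
    overall: pd.DataFrame


_KEYS = ["participant", "position_mm", "pressure", "led"]


def aggregate_grid(
    estimates: Iterable[tuple[InversionEstimate, Mapping]],
    params: MetricParams | None = None,
) -> GridResult:
    """Group per-recording estimates into the protocol OOI grid.

    ``estimates`` yields ``(estimate, metadata)`` pairs where metadata —
    a mapping or a :class:`~ppginv.recording.RecordingMetadata` — supplies
    ``participant``, ``position_mm`` and ``pressure``; the LED comes from
    the metadata when present, otherwise from the estimate's channel.
    Excluded recordings are dropped from every denominator; duplicate keys
    raise :class:`DuplicateMeasurementError`.
    """

    def _get(meta, est, k):
        v = meta.get(k) if isinstance(meta, Mapping) else getattr(meta, k, None)
        if v is None and k == "led":
            v = est.channel
        return v

    params = params or MetricParams()
    rows = []
    seen = set()
    for est, meta in estimates:
        key = tuple(_get(meta, est, k) for k in _KEYS)
        if key in seen:
            raise DuplicateMeasurementError(f"duplicate measurement key {key}")
        seen.add(key)
        if est.excluded or est.doi is None:
            continue
        rows.append(dict(zip(_KEYS, key), doi=est.doi, inverted=classify_inverted(est.doi, params)))
    if not rows:
        empty = pd.DataFrame()
        return GridResult(empty, empty, empty, empty, empty)
    df = pd.DataFrame(rows)
    grid = (
        df.groupby(["position_mm", "pressure", "led"])
        .agg(n_recordings=("doi", "size"), n_inverted=("inverted", "sum"))
        .reset_index()
    )
    grid["ooi"] = grid["n_inverted"] / grid["n_recordings"]
    per_led = grid.groupby(["position_mm", "led"])["ooi"].mean().reset_index()
    per_pressure = grid.groupby(["position_mm", "pressure"])["ooi"].mean().reset_index()
    per_subject = df.groupby("participant")["inverted"].mean().rename("occurrence").reset_index()
    overall = (
        grid.groupby("position_mm")["ooi"].agg(mean_ooi="mean", median_ooi="median").reset_index()
    )
    return GridResult(grid, per_led, per_pressure, per_subject, overall)
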