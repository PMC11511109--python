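"""Two-layer pulse-inversion classifier.

Layer 1 (**symmetry**): every strict local extremum of the prepared series
is a pulse candidate whose extremum marks the end of systole.  A candidate
must first *dominate* its neighbourhood (no sample within +/-150 samples
beats it), then satisfy the systole/diastole asymmetry criterion: the mean
absolute first difference over the 240 samples (~0.3 s at 800 Hz) before
the reference point must strictly exceed that over the 240 samples after
it — the systolic deflection is the steepest part of the pulse.  Passing
peaks are labelled +1 (non-inverted), passing troughs -1 (inverted).

Layer 2 (**triangulation**): each verified candidate is triangulated with
its nearest non-candidate local extrema of the same kind on either side
(dicrotic waves, ripples).  The cosine of the vertex angle at the candidate
— time in seconds, intensity z-scored per series — measures sharpness:
acute (positive cosine) vertices are sharp systolic deflections.  A
recording whose troughs are sharper than its peaks on average is called
inverted by this layer; disagreement between the layers is flagged
downstream, never auto-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidInputError, TooShortError
from .preprocess import PulseSeries

PEAK = "peak"
TROUGH = "trough"

#: Phase labels returned by :func:`phase_by_triangulation`.
INVERTED = "inverted"
NON_INVERTED = "non-inverted"
INDETERMINATE = "indeterminate"


@dataclass
class AnalysisParams:
    """Classifier window sizes (defaults: 150-sample dominance check each
    side, 240-sample symmetry window each side, ~0.3 s at 800 Hz)."""

    verify_window: int = 150
    symmetry_window: int = 240

    def __post_init__(self) -> None:
        for name in ("verify_window", "symmetry_window"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise InvalidInputError(f"{name} must be a positive integer, got {v!r}")


@dataclass
class PulseCandidate:
    """One verified-or-not extremum reference point.

    ``label`` is defined only for symmetry-passing candidates: +1 for a
    peak (non-inverted pulse), -1 for a trough (inverted pulse).
    ``cos_theta`` is absent when triangulation is infeasible (no matching
    non-candidate neighbour extremum on one side).
    """

    index: int
    kind: str  # PEAK | TROUGH
    is_plateau: bool = False
    verified: bool = False
    symmetry_pass: bool = False
    label: Optional[int] = None
    cos_theta: Optional[float] = None

    @property
    def sign(self) -> int:
        return 1 if self.kind == PEAK else -1


def find_local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All interior local extrema, with plateaus collapsed to midpoints.

    Returns ``(indices, kinds, is_plateau)`` where ``kinds`` is +1 for
    maxima and -1 for minima.  A plateau (run of equal values that is
    higher/lower than both neighbouring runs) contributes one extremum at
    its midpoint.  Boundary runs are never extrema.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise TooShortError(f"need at least 3 samples to locate extrema, got {len(x)}")
    change = np.flatnonzero(np.diff(x) != 0)
    run_starts = np.concatenate(([0], change + 1))
    run_vals = x[run_starts]
    if len(run_vals) < 3:
        return np.empty(0, int), np.empty(0, int), np.zeros(0, bool)
    left, mid, right = run_vals[:-2], run_vals[1:-1], run_vals[2:]
    is_max = (mid > left) & (mid > right)
    is_min = (mid < left) & (mid < right)
    which = np.flatnonzero(is_max | is_min)
    run_ends = np.concatenate((run_starts[1:], [len(x)]))
    starts = run_starts[which + 1]
    lengths = run_ends[which + 1] - starts
    indices = starts + (lengths - 1) // 2
    kinds = np.where(is_max[which], 1, -1)
    return indices.astype(int), kinds.astype(int), lengths > 1


def gather_candidates(
    series: PulseSeries, params: AnalysisParams | None = None
) -> list[PulseCandidate]:
    """Gather all pulse candidates: interior local extrema ordered by index,
    excluding those whose symmetry window would truncate at a series end."""
    params = params or AnalysisParams()
    idx, kinds, plateau = find_local_extrema(series.values)
    n = len(series.values)
    w = max(params.symmetry_window, series.edge_margin)
    keep = (idx >= w) & (idx < n - w)
    return [
        PulseCandidate(index=int(i), kind=PEAK if k > 0 else TROUGH, is_plateau=bool(p))
        for i, k, p in zip(idx[keep], kinds[keep], plateau[keep])
    ]


def verify_dominance(
    series: PulseSeries, candidate: PulseCandidate, params: AnalysisParams | None = None
) -> bool:
    """Dominance check: a peak fails if any sample within +/-150 samples is
    strictly greater; a trough fails if any is strictly lower.  Ties do not
    disqualify.  Windows clip at series boundaries."""
    params = params or AnalysisParams()
    x = series.values
    i = candidate.index
    if not 0 <= i < len(x):
        raise InvalidInputError(f"candidate index {i} outside series of length {len(x)}")
    lo = max(0, i - params.verify_window)
    hi = min(len(x), i + params.verify_window + 1)
    window = x[lo:hi]
    if candidate.kind == PEAK:
        return not np.any(window > x[i])
    return not np.any(window < x[i])


def symmetry_check(
    series: PulseSeries, candidate: PulseCandidate, params: AnalysisParams | None = None
) -> tuple[bool, Optional[int]]:
    """Systole/diastole asymmetry criterion.

    ``m_pre``/``m_post`` are the mean absolute first differences over the
    ``symmetry_window`` samples before/after the reference point; the
    candidate passes iff ``m_pre > m_post`` (strict — a symmetric candidate
    carries no systole/diastole evidence).  Returns ``(passed, label)``.
    """
    params = params or AnalysisParams()
    x = series.values
    i, w = candidate.index, params.symmetry_window
    if i - w < 0 or i + w >= len(x):
        return False, None
    m_pre = np.mean(np.abs(np.diff(x[i - w : i + 1])))
    m_post = np.mean(np.abs(np.diff(x[i : i + w + 1])))
    if m_pre > m_post:
        return True, candidate.sign
    return False, None


def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        raise InvalidInputError("cannot z-score a constant series")
    return (values - values.mean()) / sd


def _cos_vertex_angle(P: np.ndarray, L: np.ndarray, R: np.ndarray) -> float:
    a = float(np.hypot(*(P - L)))
    b = float(np.hypot(*(P - R)))
    c = float(np.hypot(*(L - R)))
    return (a * a + b * b - c * c) / (2.0 * a * b)


def triangulate(
    series: PulseSeries,
    candidate: PulseCandidate,
    all_candidates: Sequence[PulseCandidate],
    _pools: Optional[dict] = None,
) -> Optional[float]:
    """Sharpness of one candidate: cosine of its triangulation vertex angle.

    The candidate is joined to the nearest strict (non-plateau) local
    extremum of the same kind on each side that is not itself a verified
    pulse candidate — dicrotic peaks, noise ripples.  Coordinates: time in
    seconds, intensity z-scored per series, so the angle is dimensionless
    and invariant to gain and to time translation.  Returns ``None`` when a
    matching neighbour is missing on either side (triangulation infeasible;
    the symmetry layer alone is then evaluated downstream).
    """
    if _pools is None:
        _pools = _neighbour_pools(series, all_candidates)
    pool, z = _pools[candidate.kind], _pools["z"]
    j = np.searchsorted(pool, candidate.index)
    if j == 0 or j >= len(pool):
        return None
    dt = 1.0 / series.sampling_rate
    li, ri, ci = int(pool[j - 1]), int(pool[j]), candidate.index
    P = np.array([ci * dt, z[ci]])
    L = np.array([li * dt, z[li]])
    R = np.array([ri * dt, z[ri]])
    return float(np.clip(_cos_vertex_angle(P, L, R), -1.0, 1.0))


def _neighbour_pools(
    series: PulseSeries, all_candidates: Sequence[PulseCandidate]
) -> dict:
    """Sorted index pools of non-candidate strict extrema, per kind."""
    idx, kinds, plateau = find_local_extrema(series.values)
    verified = {c.index for c in all_candidates if c.verified}
    free = ~np.isin(idx, list(verified)) & ~plateau
    return {
        PEAK: idx[free & (kinds > 0)],
        TROUGH: idx[free & (kinds < 0)],
        "z": _zscore(series.values),
    }


def phase_by_triangulation(candidates: Sequence[PulseCandidate]) -> str:
    """Recording-level phase from mean sharpness of peaks vs troughs.

    Inverted signals have sharper (more acute) troughs than peaks.  Returns
    ``indeterminate`` when either mean is undefined or the means tie.
    """
    peak_cos = [c.cos_theta for c in candidates if c.kind == PEAK and c.cos_theta is not None]
    trough_cos = [c.cos_theta for c in candidates if c.kind == TROUGH and c.cos_theta is not None]
    if not peak_cos or not trough_cos:
        return INDETERMINATE
    c_peak, c_trough = float(np.mean(peak_cos)), float(np.mean(trough_cos))
    if c_trough > c_peak:
        return INVERTED
    if c_peak > c_trough:
        return NON_INVERTED
    return INDETERMINATE


def analyze_series(
    series: PulseSeries, params: AnalysisParams | None = None
) -> list[PulseCandidate]:
    """Run both classifier layers, returning fully annotated candidates."""
    params = params or AnalysisParams()
    candidates = gather_candidates(series, params)
    for c in candidates:
        c.verified = verify_dominance(series, c, params)
        if c.verified:
            c.symmetry_pass, c.label = symmetry_check(series, c, params)
    pools = _neighbour_pools(series, candidates)
    for c in candidates:
        if c.verified:
            c.cos_theta = triangulate(series, c, candidates, _pools=pools)
    return candidates
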