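"""Synthetic multi-wavelength PPG generator with inversion ground truth.

Generates raw-sensor-convention recordings: for a *normal* pulse the
reflected intensity dips at systole (so the preprocessing negation step is
exercised); an *inverted* pulse is the exact mirror image.  Each beat is an
ABP-like template — steep systolic upstroke (half-cosine over a small
fraction of the beat), exponential-like diastolic decay, and an optional
dicrotic wave — concatenated with jittered beat periods, then overlaid
with sinusoidal baseline wander, white noise, optional transient motion
artifacts, a DC offset, and per-LED gains.

Inversion is controlled per beat, never mid-beat: either a contiguous
block of beats (emulating partly inverted recordings) or independent
per-beat draws.  The emitted :class:`GroundTruth` lists every beat's onset
and polarity so downstream estimates can be checked against the plan
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .protocol import (
    FORCE_RANGE_MMHG,
    LEDS,
    PARTICIPANTS,
    POSITIONS_MM,
    PRESSURES,
    ROOM_TEMP_RANGE_C,
    SKIN_TEMP_RANGE_C,
)
from .recording import RawRecording, RecordingMetadata

NORMAL = "normal"
INVERTED_POLARITY = "inverted"

#: Default per-LED amplitude multipliers (longer wavelengths penetrate
#: deeper and modulate more strongly in reflectance mode).
DEFAULT_LED_GAINS: dict[str, float] = {"ir": 1.0, "red": 0.8, "green": 0.5, "blue": 0.4}


@dataclass
class PulseTemplate:
    """Shape parameters of one synthetic beat.

    The upstroke occupies ``systolic_rise_fraction`` of the beat period
    (steeper than the decay — the asymmetry the symmetry layer of the
    classifier exploits); the diastolic limb decays with time constant
    ``decay_time_fraction`` of the period, carrying a Gaussian dicrotic
    wave of relative height ``dicrotic_amplitude`` centred at
    ``dicrotic_delay_fraction``.  ``amplitude`` is the AC magnitude in
    arbitrary ADC-like counts.
    """

    systolic_rise_fraction: float = 0.15
    dicrotic_amplitude: float = 0.2
    dicrotic_delay_fraction: float = 0.45
    dicrotic_width_fraction: float = 0.05
    decay_time_fraction: float = 0.18
    amplitude: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.systolic_rise_fraction < 0.5:
            raise InvalidInputError(
                "systolic_rise_fraction must be in (0, 0.5) so the upstroke is "
                f"steeper than the decay, got {self.systolic_rise_fraction!r}"
            )
        if not 0 <= self.dicrotic_amplitude <= 0.5:
            raise InvalidInputError(
                f"dicrotic_amplitude must be in [0, 0.5], got {self.dicrotic_amplitude!r}"
            )
        if not self.systolic_rise_fraction < self.dicrotic_delay_fraction < 1:
            raise InvalidInputError(
                "dicrotic_delay_fraction must lie in the diastolic limb, got "
                f"{self.dicrotic_delay_fraction!r}"
            )
        if self.amplitude <= 0:
            raise InvalidInputError(f"amplitude must be > 0, got {self.amplitude!r}")


@dataclass
class SimulationPlan:
    """Conditions for one synthetic recording (defaults match the study
    protocol: 90 s at 800 Hz).

    ``fraction_inverted`` is the target fraction of inverted beats;
    ``inversion_pattern`` is ``"block"`` (a contiguous inverted segment of
    deterministic length, emulating partly inverted recordings) or
    ``"random"`` (independent per-beat Bernoulli draws).  ``noise_sd`` and
    ``drift_amplitude`` are relative to the template amplitude; the default
    drift period of 30 s places baseline wander inside the high-pass
    stopband.  ``artifact_rate`` is transient motion spikes per minute.
    """

    seed: int
    duration_s: float = 90.0
    sampling_rate: float = 800.0
    heart_rate_bpm: float = 60.0
    hr_jitter: float = 0.03
    fraction_inverted: float = 0.0
    inversion_pattern: str = "block"
    noise_sd: float = 0.02
    drift_amplitude: float = 1.0
    drift_period_s: float = 30.0
    artifact_rate: float = 0.0
    dc_offset: float = 50000.0
    led_gains: dict = field(default_factory=lambda: dict(DEFAULT_LED_GAINS))

    def __post_init__(self) -> None:
        bad = []
        if self.duration_s <= 0:
            bad.append(f"duration_s={self.duration_s!r}")
        if self.sampling_rate <= 0:
            bad.append(f"sampling_rate={self.sampling_rate!r}")
        if self.heart_rate_bpm <= 0:
            bad.append(f"heart_rate_bpm={self.heart_rate_bpm!r}")
        if not 0 <= self.hr_jitter < 0.3:
            bad.append(f"hr_jitter={self.hr_jitter!r}")
        if not 0 <= self.fraction_inverted <= 1:
            bad.append(f"fraction_inverted={self.fraction_inverted!r}")
        if self.inversion_pattern not in ("random", "block"):
            bad.append(f"inversion_pattern={self.inversion_pattern!r}")
        if self.noise_sd < 0:
            bad.append(f"noise_sd={self.noise_sd!r}")
        if self.drift_amplitude < 0:
            bad.append(f"drift_amplitude={self.drift_amplitude!r}")
        if self.drift_period_s <= 0:
            bad.append(f"drift_period_s={self.drift_period_s!r}")
        if self.artifact_rate < 0:
            bad.append(f"artifact_rate={self.artifact_rate!r}")
        if set(self.led_gains) != set(LEDS):
            bad.append(f"led_gains keys={sorted(self.led_gains)!r}")
        if bad:
            raise InvalidInputError("invalid plan fields: " + ", ".join(bad))


@dataclass
class GroundTruth:
    """Per-beat onset sample and polarity (+1 normal, -1 inverted) per LED."""

    onsets: np.ndarray
    polarity: dict[str, np.ndarray]

    @property
    def n_beats(self) -> int:
        return len(self.onsets)

    def fraction_inverted(self, led: str = "ir") -> float:
        """Realized fraction of inverted beats on one channel."""
        return float(np.mean(self.polarity[led] == -1))

    def to_frame(self) -> pd.DataFrame:
        data = {"beat_index": np.arange(self.n_beats), "onset_sample": self.onsets}
        for led in LEDS:
            data[f"polarity_{led}"] = self.polarity[led]
        return pd.DataFrame(data)


def render_pulse(
    template: PulseTemplate, period_samples: int, polarity: str = NORMAL
) -> np.ndarray:
    """One beat in raw sensor convention.

    A normal beat dips at systole (global minimum at
    ``systolic_rise_fraction * period`` +/- 1 sample); an inverted beat is
    its exact sample-for-sample negation.  The beat starts at baseline 0
    and returns to it at the (exclusive) end of the period.
    """
    if period_samples < 16:
        raise InvalidInputError(f"period_samples must be >= 16, got {period_samples}")
    if polarity not in (NORMAL, INVERTED_POLARITY):
        raise InvalidInputError(f"polarity must be normal|inverted, got {polarity!r}")
    t = template
    u = np.arange(period_samples) / period_samples
    s = np.empty(period_samples)
    rise = u < t.systolic_rise_fraction
    s[rise] = 0.5 * (1.0 - np.cos(np.pi * u[rise] / t.systolic_rise_fraction))

    def diastole(v: np.ndarray) -> np.ndarray:
        return np.exp(-(v - t.systolic_rise_fraction) / t.decay_time_fraction) + (
            t.dicrotic_amplitude
            * np.exp(-(((v - t.dicrotic_delay_fraction) / t.dicrotic_width_fraction) ** 2))
        )

    dec = ~rise
    # subtract a ramp so the beat lands exactly on baseline at u = 1
    end = diastole(np.array([1.0]))[0]
    s[dec] = diastole(u[dec]) - end * (u[dec] - t.systolic_rise_fraction) / (
        1.0 - t.systolic_rise_fraction
    )
    shape = t.amplitude * s
    return shape if polarity == INVERTED_POLARITY else -shape


def _beat_schedule(plan: SimulationPlan, rng: np.random.Generator) -> list[tuple[int, int]]:
    n = int(round(plan.duration_s * plan.sampling_rate))
    nominal = plan.sampling_rate * 60.0 / plan.heart_rate_bpm
    beats, i = [], 0
    while i < n:
        period = int(round(nominal * np.clip(rng.normal(1.0, plan.hr_jitter), 0.7, 1.3)))
        period = max(period, 16)
        beats.append((i, period))
        i += period
    # close the schedule exactly at the recording end so every beat is
    # complete and the signal returns to baseline: a long-enough remainder
    # becomes the final beat's period, a short one is absorbed into it.
    onset, period = beats[-1]
    if n - onset >= 0.7 * nominal or len(beats) == 1:
        beats[-1] = (onset, n - onset)
    else:
        beats.pop()
        onset, _ = beats[-1]
        beats[-1] = (onset, n - onset)
    return beats


def _polarities(
    n_beats: int, fraction: float, pattern: str, rng: np.random.Generator
) -> np.ndarray:
    pol = np.ones(n_beats, dtype=int)
    if pattern == "block":
        n_inv = int(round(fraction * n_beats))
        start = int(rng.integers(0, n_beats - n_inv + 1)) if n_inv < n_beats else 0
        pol[start : start + n_inv] = -1
    else:
        pol[rng.random(n_beats) < fraction] = -1
    return pol


def generate_recording(
    plan: SimulationPlan,
    template: PulseTemplate | None = None,
    metadata: RecordingMetadata | None = None,
    fraction_by_led: Mapping[str, float] | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Render one 4-channel recording plus its beat-level ground truth.

    Identical plans and seeds reproduce identical output bit-for-bit.
    ``fraction_by_led`` overrides ``plan.fraction_inverted`` per channel
    (some LEDs can be inverted while others are normal in the same
    measurement); by default all channels share one polarity sequence.
    """
    template = template or PulseTemplate()
    rng = np.random.default_rng(plan.seed)
    n = int(round(plan.duration_s * plan.sampling_rate))
    beats = _beat_schedule(plan, rng)
    onsets = np.array([o for o, _ in beats])

    polarity: dict[str, np.ndarray] = {}
    if fraction_by_led is None:
        shared = _polarities(len(beats), plan.fraction_inverted, plan.inversion_pattern, rng)
        for led in LEDS:
            polarity[led] = shared
    else:
        for led in LEDS:
            polarity[led] = _polarities(
                len(beats), float(fraction_by_led[led]), plan.inversion_pattern, rng
            )

    # pulse trains (one per distinct polarity sequence)
    trains: dict[int, np.ndarray] = {}
    for led in LEDS:
        key = id(polarity[led])
        if key in trains:
            continue
        sig = np.zeros(n)
        for (onset, period), pol in zip(beats, polarity[led]):
            beat = render_pulse(
                template, period, NORMAL if pol > 0 else INVERTED_POLARITY
            )
            stop = min(onset + period, n)
            sig[onset:stop] += beat[: stop - onset]
        trains[key] = sig

    t = np.arange(n) / plan.sampling_rate
    drift = plan.drift_amplitude * template.amplitude * np.sin(
        2.0 * np.pi * t / plan.drift_period_s
    )
    artifacts = np.zeros(n)
    n_art = rng.poisson(plan.artifact_rate * plan.duration_s / 60.0)
    for _ in range(n_art):
        centre = rng.uniform(0, plan.duration_s)
        width = rng.uniform(0.05, 0.2)
        amp = rng.choice((-1.0, 1.0)) * rng.uniform(3.0, 6.0) * template.amplitude
        artifacts += amp * np.exp(-(((t - centre) / width) ** 2))

    channels = {}
    for led in LEDS:
        noise = rng.normal(0.0, plan.noise_sd * template.amplitude, n)
        channels[led] = plan.dc_offset + plan.led_gains[led] * (
            trains[id(polarity[led])] + drift + artifacts + noise
        )

    metadata = metadata or RecordingMetadata(
        participant="SYN", position_mm=0, pressure="medium", duration_s=plan.duration_s
    )
    rec = RawRecording(channels=channels, sampling_rate=plan.sampling_rate, metadata=metadata)
    return rec, GroundTruth(onsets=onsets, polarity=polarity)


InversionMap = Callable[[str, int, str, str], float]


def _as_map(inversion_map) -> InversionMap:
    if inversion_map is None:
        return lambda participant, position, pressure, led: 0.0
    if callable(inversion_map):
        return inversion_map
    mapping = dict(inversion_map)

    def lookup(participant: str, position: int, pressure: str, led: str) -> float:
        return float(mapping.get((position, pressure, led), 0.0))

    return lookup


def generate_study(
    seed: int,
    base_plan: SimulationPlan | None = None,
    template: PulseTemplate | None = None,
    participants: Sequence[str] = PARTICIPANTS,
    positions: Sequence[int] = POSITIONS_MM,
    pressures: Sequence[str] = PRESSURES,
    inversion_map: Optional[Mapping | InversionMap] = None,
) -> Iterator[tuple[RawRecording, GroundTruth]]:
    """Lazily generate one recording per (participant, position, pressure).

    ``inversion_map`` assigns the inverted-beat fraction per configuration
    cell: either a mapping ``(position, pressure, led) -> fraction`` or a
    callable ``(participant, position, pressure, led) -> fraction``;
    unlisted cells default to 0.  Metadata (contact force per pressure
    level, skin/room temperature per participant) is drawn within the
    observed protocol ranges.  Deterministic under ``seed``; recordings are
    yielded rather than returned as a list because the full default grid
    (12 x 11 x 3 recordings x 4 channels x 72 000 samples) would occupy
    ~0.9 GB if materialised at once.
    """
    base_plan = base_plan or SimulationPlan(seed=0)
    lookup = _as_map(inversion_map)
    master = np.random.default_rng(seed)
    temps = {
        p: (master.uniform(*SKIN_TEMP_RANGE_C), master.uniform(*ROOM_TEMP_RANGE_C))
        for p in participants
    }
    for participant in participants:
        for pressure in pressures:
            for position in positions:
                rec_seed = int(master.integers(0, 2**31))
                force = float(master.uniform(*FORCE_RANGE_MMHG[pressure]))
                plan_fields = {
                    f.name: getattr(base_plan, f.name) for f in fields(SimulationPlan)
                }
                plan_fields["seed"] = rec_seed
                plan = SimulationPlan(**plan_fields)
                meta = RecordingMetadata(
                    participant=participant,
                    position_mm=int(position),
                    pressure=pressure,
                    force_mmhg=force,
                    skin_temp_c=round(temps[participant][0], 1),
                    room_temp_c=round(temps[participant][1], 1),
                    duration_s=plan.duration_s,
                )
                fractions = {
                    led: lookup(participant, int(position), pressure, led) for led in LEDS
                }
                yield generate_recording(
                    plan, template, metadata=meta, fraction_by_led=fractions
                )


def enumerate_protocol(
    participants: Sequence[str] = PARTICIPANTS,
    positions: Sequence[int] = POSITIONS_MM,
    pressures: Sequence[str] = PRESSURES,
    leds: Sequence[str] = LEDS,
) -> pd.DataFrame:
    """Enumerate every channel-recording of the protocol grid.

    The default grid is 12 participants x 11 positions x 3 pressures x
    4 LED channels = 1 584 rows.
    """
    rows = [
        (p, pos, pres, led)
        for p in participants
        for pres in pressures
        for pos in positions
        for led in leds
    ]
    return pd.DataFrame(rows, columns=["participant", "position_mm", "pressure", "led"])
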