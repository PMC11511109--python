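"""In-memory data model for raw multi-wavelength PPG recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .protocol import LEDS, PRESSURES


@dataclass
class RecordingMetadata:
    """Acquisition metadata for one recording.

    Parameters
    ----------
    participant : str
        Participant identifier (e.g. ``"S1"``).
    position_mm : int
        Probe position relative to the artery central line, integer in
        [-5, 5]; positive is medial.
    pressure : str
        Strap contact-pressure level: ``low`` | ``medium`` | ``high``.
    force_mmhg : float
        Measured probe-skin contact force.
    skin_temp_c, room_temp_c : float
        Skin-surface and ambient temperature.
    duration_s : float
        Recording duration in seconds.
    """

    participant: str
    position_mm: int
    pressure: str
    force_mmhg: float = float("nan")
    skin_temp_c: float = float("nan")
    room_temp_c: float = float("nan")
    duration_s: float = 90.0

    def __post_init__(self) -> None:
        if not float(self.position_mm).is_integer() or not -5 <= self.position_mm <= 5:
            raise InvalidInputError(
                f"position_mm must be an integer in [-5, 5], got {self.position_mm!r}"
            )
        self.position_mm = int(self.position_mm)
        if self.pressure not in PRESSURES:
            raise InvalidInputError(
                f"pressure must be one of {PRESSURES}, got {self.pressure!r}"
            )
        if self.duration_s <= 0:
            raise InvalidInputError(f"duration_s must be > 0, got {self.duration_s!r}")


@dataclass
class RawRecording:
    """One multi-wavelength PPG capture in raw sensor convention.

    ``channels`` maps each LED name to an equal-length float array of
    detector intensity samples.  Raw convention: for a non-inverted pulse
    the reflected intensity *dips* at systole; preprocessing negates the
    signal so pulses point upward like an arterial blood pressure wave.
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    metadata: RecordingMetadata
    source_id: str = field(default="")

    def __post_init__(self) -> None:
        if set(self.channels) != set(LEDS):
            raise InvalidInputError(
                f"channels must be keyed by {LEDS}, got {sorted(self.channels)}"
            )
        lengths = {led: len(v) for led, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise InvalidInputError(f"channel lengths differ: {lengths}")
        if next(iter(lengths.values())) == 0:
            raise InvalidInputError("channels are empty")
        if not self.sampling_rate > 0:
            raise InvalidInputError(
                f"sampling_rate must be > 0, got {self.sampling_rate!r}"
            )
        self.channels = {led: np.asarray(v, dtype=float) for led, v in self.channels.items()}
        if not self.source_id:
            m = self.metadata
            self.source_id = f"{m.participant}_pos{m.position_mm:+d}_{m.pressure}"

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))
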