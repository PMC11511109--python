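"""Constants describing the measurement protocol of the twelve-participant
dorsalis-pedis study design that this package targets.

The grid is 12 participants x 11 probe positions (-5..+5 mm relative to the
artery central line, positive = medial) x 3 contact-pressure levels, with
four LED wavelength channels recorded simultaneously per measurement:
1 584 channel-recordings in total.
"""

from __future__ import annotations

import pandas as pd

#: LED channels of the multi-wavelength sensor, in on-disk column order.
LEDS: tuple[str, ...] = ("ir", "red", "green", "blue")

#: Probe contact-pressure levels, from loosest to tightest strap setting.
PRESSURES: tuple[str, ...] = ("low", "medium", "high")

#: Probe positions in mm relative to the artery central line (+ = medial).
POSITIONS_MM: tuple[int, ...] = tuple(range(-5, 6))

#: Participant identifiers.
PARTICIPANTS: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 13))

#: Default recording duration (s) and sampling rate (Hz) of the protocol.
RECORDING_DURATION_S: float = 90.0
SAMPLING_RATE_HZ: float = 800.0

# Per-participant probe contact force at the three strap-pressure levels
# (mmHg) and skin / room temperature (deg C), as measured for the twelve
# participants of the reference protocol.  Used both as a reference table
# and to bound the metadata synthesised for generated recordings.
_FORCE_TEMPERATURE_ROWS = [
    # participant, fmax, fmed, fmin, skin_c, room_c
    ("S1", 55.0, 21.3, 15.6, 34.1, 21.8),
    ("S2", 40.9, 15.3, 7.7, 31.1, 21.2),
    ("S3", 34.0, 14.0, 8.3, 32.2, 23.3),
    ("S4", 51.6, 29.8, 21.0, 32.3, 22.5),
    ("S5", 39.7, 21.3, 12.3, 34.1, 23.7),
    ("S6", 40.6, 15.7, 10.2, 28.9, 23.5),
    ("S7", 51.1, 37.6, 9.3, 32.1, 22.6),
    ("S8", 35.9, 16.8, 3.2, 36.2, 24.3),
    ("S9", 36.0, 16.3, 5.6, 31.9, 24.6),
    ("S10", 35.7, 32.6, 24.5, 31.1, 22.5),
    ("S11", 42.2, 38.0, 13.8, 32.4, 22.5),
    ("S12", 47.1, 27.5, 17.3, 35.3, 22.7),
]


def force_temperature_table() -> pd.DataFrame:
    """Per-participant contact force and temperature reference table.

    Columns: ``participant``, ``fmax_mmhg``, ``fmed_mmhg``, ``fmin_mmhg``,
    ``skin_temp_c``, ``room_temp_c``.
    """
    return pd.DataFrame(
        _FORCE_TEMPERATURE_ROWS,
        columns=[
            "participant",
            "fmax_mmhg",
            "fmed_mmhg",
            "fmin_mmhg",
            "skin_temp_c",
            "room_temp_c",
        ],
    )


#: Observed contact-force range (mmHg) per pressure level, from the table.
FORCE_RANGE_MMHG: dict[str, tuple[float, float]] = {
    "low": (3.2, 24.5),
    "medium": (14.0, 38.0),
    "high": (34.0, 55.0),
}

#: Observed temperature ranges (deg C), from the table.
SKIN_TEMP_RANGE_C: tuple[float, float] = (28.9, 36.2)
ROOM_TEMP_RANGE_C: tuple[float, float] = (21.2, 24.6)
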