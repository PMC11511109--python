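"""On-disk formats, run configuration, and the analysis/aggregation drivers.

A recording is stored as a plain CSV (``sample_index, ir, red, green,
blue``) with a JSON sidecar (``<stem>.meta.json``) carrying the sampling
rate and acquisition metadata.  Output bytes are deterministic: fixed
column order, fixed numeric formatting, sorted JSON keys.  Ground truth
(when written by the simulator) is a companion CSV with one row per beat.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidInputError, SchemaError
from .metrics import (
    GridResult,
    InversionEstimate,
    MetricParams,
    aggregate_grid,
    estimate_inversion,
)
from .preprocess import FilterParams, prepare
from .protocol import LEDS
from .pulse_analysis import AnalysisParams
from .recording import RawRecording, RecordingMetadata
from .synthetic import GroundTruth

log = logging.getLogger("ppginv")

_CSV_COLUMNS = ["sample_index", *LEDS]
_META_FIELDS = [f.name for f in dataclasses.fields(RecordingMetadata)]

ESTIMATE_COLUMNS = [
    "source_id",
    "participant",
    "position_mm",
    "pressure",
    "led",
    "n_pulses",
    "mu",
    "doi",
    "inverted",
    "noise_flag",
    "disagreement_flag",
    "excluded",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json")


def write_recording(recording: RawRecording, path: str | Path) -> tuple[Path, Path]:
    """Write CSV + JSON sidecar; byte-identical output for identical input."""
    path = Path(path).with_suffix(".csv")
    df = pd.DataFrame(
        {"sample_index": np.arange(recording.n_samples)}
        | {led: recording.channels[led] for led in LEDS}
    )
    meta = {
        "sampling_rate": recording.sampling_rate,
        "source_id": recording.source_id,
        **{k: getattr(recording.metadata, k) for k in _META_FIELDS},
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    sidecar = _sidecar(path)
    sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return path, sidecar


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording` (strict schema)."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise SchemaError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"malformed metadata JSON in {sidecar}: {e}") from e
    for k in ("sampling_rate", *_META_FIELDS):
        if k not in meta:
            raise SchemaError(f"metadata field {k!r} missing from {sidecar}")
    df = pd.read_csv(path)
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    if list(df.columns) != _CSV_COLUMNS:
        raise SchemaError(
            f"unexpected columns in {path}: {list(df.columns)} (want {_CSV_COLUMNS})"
        )
    try:
        metadata = RecordingMetadata(**{k: meta[k] for k in _META_FIELDS})
    except InvalidInputError as e:
        raise SchemaError(f"invalid metadata in {sidecar}: {e}") from e
    return RawRecording(
        channels={led: df[led].to_numpy(dtype=float) for led in LEDS},
        sampling_rate=float(meta["sampling_rate"]),
        metadata=metadata,
        source_id=str(meta.get("source_id", "")),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path).with_suffix(".csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(path, index=False, lineterminator="\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path)
    for col in ("beat_index", "onset_sample", *(f"polarity_{led}" for led in LEDS)):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    return GroundTruth(
        onsets=df["onset_sample"].to_numpy(int),
        polarity={led: df[f"polarity_{led}"].to_numpy(int) for led in LEDS},
    )


@dataclass
class RunConfig:
    """End-to-end run settings; defaults are the study pipeline values.

    Unknown keys in a YAML config are rejected.  ``exclude_ids`` lists
    per-channel source ids (``<recording>_<led>``) to drop from analysis —
    the machine-readable replacement for manual exclusion of flagged
    recordings.
    """

    hp_passband_hz: float = 0.1
    hp_stopband_hz: float = 0.05
    hp_stopband_atten_db: float = 60.0
    sg_window: int = 999
    sg_polyorder: int = 20
    verify_window: int = 150
    symmetry_window: int = 240
    doi_threshold: float = 0.25
    noise_mu_threshold: float = 0.3
    exclude_ids: list = field(default_factory=list)
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        try:
            return cls(**raw)
        except InvalidInputError as e:
            raise ConfigError(str(e)) from e

    def filter_params(self) -> FilterParams:
        return FilterParams(
            hp_passband_hz=self.hp_passband_hz,
            hp_stopband_hz=self.hp_stopband_hz,
            hp_stopband_atten_db=self.hp_stopband_atten_db,
            sg_window=self.sg_window,
            sg_polyorder=self.sg_polyorder,
        )

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(
            verify_window=self.verify_window, symmetry_window=self.symmetry_window
        )

    def metric_params(self) -> MetricParams:
        return MetricParams(
            doi_threshold=self.doi_threshold, noise_mu_threshold=self.noise_mu_threshold
        )


def _estimate_row(
    est: InversionEstimate, meta: RecordingMetadata, led: str, mparams: MetricParams
) -> dict:
    return {
        "source_id": est.source_id,
        "participant": meta.participant,
        "position_mm": meta.position_mm,
        "pressure": meta.pressure,
        "led": led,
        "n_pulses": est.n_pulses,
        "mu": est.mu_inversion,
        "doi": est.doi,
        "inverted": None if est.doi is None else int(est.doi > mparams.doi_threshold),
        "noise_flag": est.noise_flag,
        "disagreement_flag": est.disagreement_flag,
        "excluded": est.excluded,
    }


def analyze_recording(
    recording: RawRecording, config: RunConfig | None = None
) -> list[tuple[InversionEstimate, RecordingMetadata]]:
    """Run the full classifier on every channel of one recording."""
    config = config or RunConfig()
    mparams = config.metric_params()
    out = []
    for led in LEDS:
        source_id = f"{recording.source_id}_{led}"
        if source_id in config.exclude_ids:
            est = InversionEstimate(
                mu_inversion=None,
                n_pulses=0,
                doi=None,
                excluded=True,
                source_id=source_id,
                channel=led,
            )
            log.info("excluded %s: listed in exclude_ids", source_id)
        else:
            series = prepare(recording, led, config.filter_params())
            est = estimate_inversion(series, config.analysis_params(), mparams)
            if est.excluded:
                log.warning("excluded %s: no symmetry-passing pulses", source_id)
            if est.noise_flag:
                log.warning("noise flag on %s: |mu|=%.3f", source_id, abs(est.mu_inversion))
            if est.disagreement_flag:
                log.warning(
                    "disagreement flag on %s: symmetry=%s triangulation=%s",
                    source_id,
                    est.symmetry_phase,
                    est.triangulation_phase,
                )
        out.append((est, recording.metadata))
    return out


def run_analyze(
    config: RunConfig, inputs: Sequence[str | Path], out_csv: str | Path | None = None
) -> pd.DataFrame:
    """Analyze recordings from disk; one estimates row per channel series.

    Per-file failures are logged and skipped; every readable input series
    appears in the output exactly once, as a result row or an excluded row.
    Raises if *all* inputs fail.
    """
    rows = []
    n_failed = 0
    for path in inputs:
        try:
            rec = read_recording(path)
        except Exception as e:  # noqa: BLE001 - per-file isolation is the contract
            log.error("skipping %s: %s", path, e)
            n_failed += 1
            continue
        for est, meta in analyze_recording(rec, config):
            rows.append(_estimate_row(est, meta, est.channel, config.metric_params()))
    if inputs and n_failed == len(inputs):
        raise SchemaError(f"all {n_failed} input recording(s) failed to load")
    df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False, float_format="%.6f", lineterminator="\n")
    return df


def _estimates_from_frame(df: pd.DataFrame):
    for _, r in df.iterrows():
        excluded = bool(r["excluded"])
        est = InversionEstimate(
            mu_inversion=None if pd.isna(r["mu"]) else float(r["mu"]),
            n_pulses=int(r["n_pulses"]),
            doi=None if pd.isna(r["doi"]) else float(r["doi"]),
            excluded=excluded,
            source_id=str(r["source_id"]),
            channel=str(r["led"]),
        )
        meta = {
            "participant": r["participant"],
            "position_mm": int(r["position_mm"]),
            "pressure": r["pressure"],
            "led": r["led"],
        }
        yield est, meta


def run_aggregate(
    config: RunConfig,
    estimates: pd.DataFrame | str | Path,
    out_dir: str | Path | None = None,
) -> GridResult:
    """Aggregate an estimates table into the OOI grid and marginals.

    An all-excluded input yields empty outputs with a warning (a legitimate
    outcome of strict noise screening), not an error.
    """
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.read_csv(estimates)
        missing = [c for c in ESTIMATE_COLUMNS if c not in estimates.columns]
        if missing:
            raise SchemaError(f"estimates table is missing columns {missing}")
    result = aggregate_grid(_estimates_from_frame(estimates), config.metric_params())
    if result.grid.empty:
        log.warning("no analyzable recordings; aggregation output is empty")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("grid", "per_led", "per_pressure", "per_subject", "overall"):
            frame = getattr(result, name).copy()
            for col in frame.columns:
                if col == "ooi" or col.endswith("_ooi") or col == "occurrence":
                    frame[col.replace("ooi", "ooi_pct").replace("occurrence", "occurrence_pct")] = (
                        (100.0 * frame[col]).map(lambda v: f"{v:.2f}")
                    )
            frame.to_csv(out_dir / f"{name}.csv", index=False, lineterminator="\n")
    return result
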