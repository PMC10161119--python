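"""Machine log-file dialect: parsing, pulse→spot aggregation, pseudo log files.

A delivery log is one UTF-8 CSV per beam.  Leading ``# key=value`` lines
form the header (date, plan/beam ids, gantry angle, snout extension, total
prescribed MU, dialect version), followed by one CSV row per pulse.  The
machine delivers each spot as a train of pulses, repeating until the spot's
MU has been completely delivered; the delivered spot position is the
actual-MU-weighted mean of its pulses' actual positions.

A *pseudo log file* (PLF) encodes model-predicted delivered spots in the
same dialect, one pulse per spot, so the downstream dose stages can consume
predictions exactly as they would consume a real delivery record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .plan import Beam, TreatmentPlan

DIALECT = "protonspot-log-v1"

PULSE_COLUMNS = [
    "pulse_index", "spot_index", "nominal_energy_mev",
    "target_x_mm", "target_y_mm", "actual_x_mm", "actual_y_mm",
    "target_mu", "actual_mu",
]

FEATURE_COLUMNS = [
    "target_x_mm", "target_y_mm", "target_mu",
    "gantry_angle_deg", "snout_extension_mm", "nominal_energy_mev",
]

TARGET_COLUMNS = ["delivered_x_mm", "delivered_y_mm", "delivered_mu"]


class LogParseError(ValueError):
    """Raised when a log file violates the dialect; carries the line number."""


@dataclass
class PulseRecord:
    """One pulse row of the dialect (convenience view; bulk storage is tabular)."""

    pulse_index: int
    spot_index: int
    nominal_energy_mev: float
    target_x_mm: float
    target_y_mm: float
    actual_x_mm: float
    actual_y_mm: float
    target_mu: float
    actual_mu: float

    def __post_init__(self) -> None:
        if self.target_mu < 0 or self.actual_mu < 0:
            raise ValueError("pulse MUs must be non-negative")
        for v in (self.target_x_mm, self.target_y_mm, self.actual_x_mm, self.actual_y_mm):
            if not np.isfinite(v):
                raise ValueError("pulse coordinates must be finite")


def pulses_to_frame(records: list[PulseRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=PULSE_COLUMNS)


@dataclass
class LogHeader:
    date: str
    plan_id: str
    beam_id: str
    gantry_angle_deg: float
    snout_extension_mm: float
    total_prescribed_mu: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gantry_angle_deg < 360.0:
            raise ValueError("header gantry angle must lie in [0, 360)")


@dataclass
class LogFile:
    header: LogHeader
    pulses: pd.DataFrame  # columns = PULSE_COLUMNS, one row per pulse

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)


@dataclass
class SpotRecord:
    """One planned-and-delivered spot aggregated from its pulses."""

    spot_index: int
    nominal_energy_mev: float
    planned_x_mm: float
    planned_y_mm: float
    planned_mu: float
    delivered_x_mm: float
    delivered_y_mm: float
    delivered_mu: float
    zero_mu: bool = False  # delivered MU == 0: position undefined, excluded from training


def write_log_file(path: str | Path, log: LogFile) -> None:
    h = log.header
    lines = [
        f"# dialect={DIALECT}",
        f"# date={h.date}",
        f"# plan_id={h.plan_id}",
        f"# beam_id={h.beam_id}",
        f"# gantry_angle_deg={h.gantry_angle_deg!r}",
        f"# snout_extension_mm={h.snout_extension_mm!r}",
        f"# total_prescribed_mu={h.total_prescribed_mu!r}",
    ]
    body = log.pulses[PULSE_COLUMNS].to_csv(index=False)
    Path(path).write_text("\n".join(lines) + "\n" + body)


def parse_log_file(path: str | Path) -> LogFile:
    """Parse one log/PLF file; reject malformed files naming the line."""
    text = Path(path).read_text()
    lines = text.splitlines()
    header_kv: dict[str, str] = {}
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        try:
            key, value = line[1:].strip().split("=", 1)
        except ValueError:
            raise LogParseError(f"line {n_header}: malformed header line {line!r}")
        header_kv[key.strip()] = value
    if header_kv.get("dialect") != DIALECT:
        raise LogParseError(f"line 1: missing or unsupported dialect declaration")
    required = ["date", "plan_id", "beam_id", "gantry_angle_deg",
                "snout_extension_mm", "total_prescribed_mu"]
    for key in required:
        if key not in header_kv:
            raise LogParseError(f"header: missing key {key!r}")
    header = LogHeader(
        date=header_kv["date"],
        plan_id=header_kv["plan_id"],
        beam_id=header_kv["beam_id"],
        gantry_angle_deg=float(header_kv["gantry_angle_deg"]),
        snout_extension_mm=float(header_kv["snout_extension_mm"]),
        total_prescribed_mu=float(header_kv["total_prescribed_mu"]),
    )
    body = "\n".join(lines[n_header:])
    pulses = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    missing = [c for c in PULSE_COLUMNS if c not in pulses.columns]
    if missing:
        raise LogParseError(f"line {n_header + 1}: missing column(s) {missing}")
    try:
        pulses = pulses[PULSE_COLUMNS].astype(
            {c: (np.int64 if c in ("pulse_index", "spot_index") else float)
             for c in PULSE_COLUMNS})
    except (TypeError, ValueError) as exc:
        raise LogParseError(f"line {n_header + 2}: malformed body value ({exc})")
    # first body data row is file line n_header + 2 (1-based)
    offset = n_header + 2
    for col in ("target_mu", "actual_mu"):
        bad = np.flatnonzero(pulses[col].to_numpy() < 0)
        if bad.size:
            raise LogParseError(f"line {offset + bad[0]}: negative {col}")
    coords = pulses[["target_x_mm", "target_y_mm", "actual_x_mm", "actual_y_mm"]].to_numpy()
    bad = np.flatnonzero(~np.all(np.isfinite(coords), axis=1))
    if bad.size:
        raise LogParseError(f"line {offset + bad[0]}: non-finite coordinate")
    _check_contiguous(pulses["spot_index"].to_numpy(), offset)
    return LogFile(header, pulses.reset_index(drop=True))


def _check_contiguous(spot_index: np.ndarray, offset: int = 0) -> None:
    if spot_index.size == 0:
        return
    change = np.flatnonzero(np.diff(spot_index) != 0) + 1
    block_values = spot_index[np.concatenate([[0], change])]
    if len(np.unique(block_values)) != len(block_values):
        # find the first spot index that re-appears after its block closed
        seen: set[int] = set()
        for pos, v in zip(np.concatenate([[0], change]), block_values):
            if v in seen:
                raise LogParseError(f"line {offset + pos}: spot block {v} is not contiguous")
            seen.add(int(v))


def aggregate_pulses_to_spots(log: LogFile) -> list[SpotRecord]:
    """Collapse pulse rows into one :class:`SpotRecord` per spot.

    Delivered MU is the sum of pulse actual MUs; delivered position is the
    actual-MU-weighted mean of pulse actual positions.  Spots whose total
    actual MU is zero have no defined delivered position; they are returned
    flagged ``zero_mu`` and must be excluded from model training.
    """
    p = log.pulses
    spot_idx = p["spot_index"].to_numpy()
    _check_contiguous(spot_idx)
    if len(p) == 0:
        return []
    starts = np.concatenate([[0], np.flatnonzero(np.diff(spot_idx) != 0) + 1])
    a_mu = p["actual_mu"].to_numpy()
    t_mu = p["target_mu"].to_numpy()
    ax = p["actual_x_mm"].to_numpy()
    ay = p["actual_y_mm"].to_numpy()
    sum_amu = np.add.reduceat(a_mu, starts)
    sum_tmu = np.add.reduceat(t_mu, starts)
    wx = np.add.reduceat(a_mu * ax, starts)
    wy = np.add.reduceat(a_mu * ay, starts)
    ends = np.concatenate([starts[1:], [len(p)]])
    records: list[SpotRecord] = []
    for k, s in enumerate(starts):
        zero = sum_amu[k] == 0.0
        if zero:
            dx = dy = float("nan")
        elif int(ends[k] - s) == 1:
            # single-pulse spot: the weighted mean is the pulse itself, taken
            # verbatim so PLF round-trips are bit-exact
            dx, dy = float(ax[s]), float(ay[s])
        else:
            dx, dy = float(wx[k] / sum_amu[k]), float(wy[k] / sum_amu[k])
        records.append(SpotRecord(
            spot_index=int(spot_idx[s]),
            nominal_energy_mev=float(p["nominal_energy_mev"].iloc[s]),
            planned_x_mm=float(p["target_x_mm"].iloc[s]),
            planned_y_mm=float(p["target_y_mm"].iloc[s]),
            planned_mu=float(sum_tmu[k]),
            delivered_x_mm=dx,
            delivered_y_mm=dy,
            delivered_mu=float(sum_amu[k]),
            zero_mu=bool(zero),
        ))
    return records


def write_pseudo_log_file(beam: Beam, predictions: np.ndarray, plan_id: str = "",
                          path: str | Path | None = None, date: str = "1970-01-01") -> LogFile:
    """Encode model-predicted delivered spots as a one-pulse-per-spot PLF.

    ``predictions`` is (n_spots, 3): delivered x, y, MU per planned spot of
    this beam in delivery order.  Parsing and aggregating the PLF reproduces
    the predictions bit-exactly.
    """
    predictions = np.asarray(predictions, dtype=float)
    planned = [(layer.energy_mev, s) for layer in beam.layers for s in layer.spots]
    if predictions.shape != (len(planned), 3):
        raise ValueError(
            f"prediction count {predictions.shape} does not match "
            f"{len(planned)} planned spots")
    rows = {
        "pulse_index": np.arange(len(planned)),
        "spot_index": np.arange(len(planned)),
        "nominal_energy_mev": np.array([e for e, _ in planned]),
        "target_x_mm": np.array([s.x_mm for _, s in planned]),
        "target_y_mm": np.array([s.y_mm for _, s in planned]),
        "actual_x_mm": predictions[:, 0],
        "actual_y_mm": predictions[:, 1],
        "target_mu": np.array([s.mu for _, s in planned]),
        "actual_mu": predictions[:, 2],
    }
    header = LogHeader(date=date, plan_id=plan_id, beam_id=beam.beam_id,
                       gantry_angle_deg=beam.gantry_angle_deg,
                       snout_extension_mm=beam.snout_extension_mm,
                       total_prescribed_mu=float(np.sum(rows["target_mu"])))
    log = LogFile(header, pd.DataFrame(rows, columns=PULSE_COLUMNS))
    if path is not None:
        write_log_file(path, log)
    return log


def extract_plan_features(plan: TreatmentPlan) -> pd.DataFrame:
    """One feature row per planned spot, in delivery order.

    Columns: the six model features plus (beam_idx, layer_idx, spot_idx)
    for lossless mapping back into the plan.
    """
    rows = []
    for bi, beam in enumerate(plan.beams):
        for li, layer in enumerate(beam.layers):
            for si, spot in enumerate(layer.spots):
                rows.append((spot.x_mm, spot.y_mm, spot.mu,
                             beam.gantry_angle_deg, beam.snout_extension_mm,
                             layer.energy_mev, bi, li, si))
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["beam_idx", "layer_idx", "spot_idx"])


def spot_records_to_frame(records: list[SpotRecord], header: LogHeader) -> pd.DataFrame:
    """Tabulate aggregated spots of one beam together with its header fields."""
    df = pd.DataFrame([{
        "spot_index": r.spot_index,
        "nominal_energy_mev": r.nominal_energy_mev,
        "target_x_mm": r.planned_x_mm,
        "target_y_mm": r.planned_y_mm,
        "target_mu": r.planned_mu,
        "delivered_x_mm": r.delivered_x_mm,
        "delivered_y_mm": r.delivered_y_mm,
        "delivered_mu": r.delivered_mu,
        "zero_mu": r.zero_mu,
    } for r in records])
    df["gantry_angle_deg"] = header.gantry_angle_deg
    df["snout_extension_mm"] = header.snout_extension_mm
    df["beam_id"] = header.beam_id
    return df
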