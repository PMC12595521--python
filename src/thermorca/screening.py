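"""Heat-shock ATPase screen analytics.

The screen couples ATP hydrolysis to NADH oxidation, read as a decrease in
absorbance at 340 nm: an active enzyme produces a negative A340 slope, and
in the permissive long-endpoint variant of the screen any residual active
enzyme depletes the substrate, so the total A340 drop separates active from
inactive wells. This module turns raw traces (or a deposited results table)
into per-well activity calls, per-sequence maximum tolerated heat-shock
temperature (tmax), residual-activity percentages, and per-round tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel shock label for an unshocked (room temperature) well
RT: str = "RT"

#: tmax sentinel: active at room temperature but at no ladder temperature
RT_ONLY: str = "RT-only"

#: tmax sentinel: no activity even at room temperature
INACTIVE: str = "inactive"


@dataclass
class AssayTrace:
    """Timestamped A340 readings for one well.

    ``shock_temp`` is a ladder temperature in °C or the string ``"RT"``.
    ``role`` distinguishes sample wells from on-plate controls
    ("sample", "blank" for no-enzyme, "positive" for the unshocked
    positive control).
    """

    well_id: str
    sequence_id: str
    shock_temp: float | str
    concentration: float
    times: np.ndarray
    a340: np.ndarray
    role: str = "sample"
    undiluted: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.times.size < 3:
            raise ValueError(f"well {self.well_id!r}: need at least 3 readings")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"well {self.well_id!r}: times must be strictly increasing")
        if not np.all(np.isfinite(self.a340)):
            raise ValueError(f"well {self.well_id!r}: non-finite absorbance readings")

    @property
    def endpoint_drop(self) -> float:
        """Total absorbance decrease from first to last reading."""
        return float(self.a340[0] - self.a340[-1])


@dataclass
class ScreenRecord:
    """Per-sequence outcome of one screening round."""

    sequence_id: str
    round: str
    active_rt: bool
    active_at: dict[float, bool] = field(default_factory=dict)
    tmax: float | str = INACTIVE
    residual_pct: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.tmax, (int, float)) and not self.active_at.get(float(self.tmax), False):
            raise ValueError(
                f"{self.sequence_id}: tmax {self.tmax} is not an active temperature"
            )

    @property
    def tmax_numeric(self) -> float | None:
        """tmax as a number for modelling: ladder °C, 25 for RT-only, None if inactive."""
        if self.tmax == INACTIVE:
            return None
        if self.tmax == RT_ONLY:
            return 25.0
        return float(self.tmax)


# ---------------------------------------------------------------------------
# per-well kinetics


def fit_rate(trace: AssayTrace, window: float = 0.25) -> float:
    """Least-squares A340 slope (ΔA340/min) over the initial ``window``
    fraction of readings; activity shows as a negative slope.

    Raises if the window covers fewer than 3 points or the time axis is
    degenerate.
    """
    n = max(int(round(window * trace.times.size)), 3)
    if n > trace.times.size:
        raise ValueError(f"window of {n} points exceeds trace length {trace.times.size}")
    t, y = trace.times[:n], trace.a340[:n]
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis in fit window")
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def call_active(
    rate: float | None = None,
    control_rate: float = 0.0,
    control_sd: float = 0.0,
    endpoint_drop: float | None = None,
    positive_drop: float | None = None,
    mode: str = "endpoint",
    k: float = 3.0,
    endpoint_frac: float = 0.5,
    atol: float = 1e-9,
) -> bool:
    """Call a well active or inactive against its plate controls.

    kinetic mode: active iff the slope is more negative than the no-enzyme
    control by more than ``k`` control standard deviations
    (rate < control_rate − k·control_sd; a rate equal to control is
    inactive; ``atol`` absorbs float-level slope jitter on perfectly flat
    traces). endpoint mode (default, matching the permissive ~16 h screen):
    active iff the total A340 drop exceeds ``endpoint_frac`` of the
    positive control's drop.
    """
    if mode == "kinetic":
        if rate is None:
            raise ValueError("kinetic mode requires a fitted rate")
        return rate < control_rate - k * control_sd - atol
    if mode == "endpoint":
        if endpoint_drop is None or positive_drop is None:
            raise ValueError("uncontrolled plate: endpoint mode requires sample and positive-control drops")
        return endpoint_drop > endpoint_frac * positive_drop
    raise ValueError(f"unknown mode {mode!r}")


def assign_tmax(calls: dict[float | str, bool]) -> float | str:
    """Highest shock temperature with an active call.

    ``calls`` maps shock temperature (°C, plus the ``"RT"`` key, required)
    to the activity flag. Inactive at RT → ``"inactive"``; active at RT but
    at no ladder temperature → ``"RT-only"``; otherwise the maximum active
    temperature. A non-monotone pattern (inactive below an active
    temperature) still resolves to the maximum, with a warning logged.
    """
    if RT not in calls:
        raise ValueError("assign_tmax requires a room-temperature call")
    if not calls[RT]:
        return INACTIVE
    temps = sorted(t for t in calls if t != RT)
    active = [t for t in temps if calls[t]]
    if not active:
        return RT_ONLY
    tm = max(active)
    if any(not calls[t] for t in temps if t < tm):
        log.warning("non-monotone activity pattern %s; resolving tmax to max active temp %s", calls, tm)
    return float(tm)


def residual_activity(rate_post_shock: float, rate_rt: float) -> float:
    """Post-shock ATPase rate as a percentage of the same sequence's
    room-temperature rate, clipped below at 0."""
    if rate_rt == 0:
        raise ValueError("no baseline: room-temperature rate is zero")
    return max(100.0 * rate_post_shock / rate_rt, 0.0)


def normalize_concentration(measured: float, target: float = 5.0) -> tuple[float, bool]:
    """Dilution factor to bring a well to the target concentration (µM).

    Returns (factor, undiluted_flag): wells at or above target are diluted
    by measured/target; wells below target run neat (factor 1) with the
    flag set, mirroring screening practice for under-concentrated eluates.
    """
    if measured < 0:
        raise ValueError("measured concentration cannot be negative")
    if measured == 0:
        raise ValueError("no protein: measured concentration is zero")
    if measured >= target:
        return measured / target, False
    return 1.0, True


# ---------------------------------------------------------------------------
# plate → ScreenRecords


def analyze_traces(
    traces: list[AssayTrace],
    round_label: str = "natural",
    mode: str = "endpoint",
    window: float = 0.25,
    k: float = 3.0,
    endpoint_frac: float = 0.5,
) -> list[ScreenRecord]:
    """Turn a plate of traces into per-sequence ScreenRecords.

    Requires a no-enzyme blank for kinetic mode (role "blank") and an
    unshocked positive control for endpoint mode (role "positive"). For
    each sequence, per-temperature calls are collapsed to a tmax and a
    residual-activity percentage at the highest tolerated temperature.
    """
    blanks = [t for t in traces if t.role == "blank"]
    positives = [t for t in traces if t.role == "positive"]
    samples = [t for t in traces if t.role == "sample"]
    control_rate = control_sd = 0.0
    positive_drop = None
    if mode == "kinetic":
        if not blanks:
            raise ValueError("uncontrolled plate: kinetic mode needs a no-enzyme blank")
        rates = [fit_rate(b, window) for b in blanks]
        resid = np.concatenate([
            b.a340[: max(int(round(window * b.times.size)), 3)]
            - np.polyval(np.polyfit(b.times[: max(int(round(window * b.times.size)), 3)],
                                    b.a340[: max(int(round(window * b.times.size)), 3)], 1),
                         b.times[: max(int(round(window * b.times.size)), 3)])
            for b in blanks
        ])
        control_rate = float(np.mean(rates))
        # slope SE from residual scatter of the blank fits
        b0 = blanks[0]
        n = max(int(round(window * b0.times.size)), 3)
        t = b0.times[:n]
        control_sd = float(np.std(resid, ddof=2) / np.sqrt(np.sum((t - t.mean()) ** 2))) if resid.size > 2 else 0.0
    else:
        if not positives:
            raise ValueError("uncontrolled plate: endpoint mode needs a positive control")
        positive_drop = float(np.mean([p.endpoint_drop for p in positives]))

    by_seq: dict[str, dict[float | str, AssayTrace]] = {}
    for tr in samples:
        by_seq.setdefault(tr.sequence_id, {})[tr.shock_temp] = tr

    records = []
    for seq_id, wells in by_seq.items():
        calls: dict[float | str, bool] = {}
        for shock, tr in wells.items():
            if mode == "kinetic":
                calls[shock] = call_active(
                    rate=fit_rate(tr, window), control_rate=control_rate,
                    control_sd=control_sd, mode="kinetic", k=k,
                )
            else:
                calls[shock] = call_active(
                    endpoint_drop=tr.endpoint_drop, positive_drop=positive_drop,
                    mode="endpoint", endpoint_frac=endpoint_frac,
                )
        tm = assign_tmax(calls)
        residual = None
        if isinstance(tm, float) and RT in wells and tm in wells:
            rt_rate = fit_rate(wells[RT], window)
            if rt_rate != 0:
                residual = residual_activity(fit_rate(wells[tm], window), rt_rate)
        records.append(
            ScreenRecord(
                sequence_id=seq_id,
                round=round_label,
                active_rt=calls[RT],
                active_at={float(t): c for t, c in calls.items() if t != RT},
                tmax=tm,
                residual_pct=residual,
            )
        )
    return records


# ---------------------------------------------------------------------------
# round tallies


def tally_round(records: list[ScreenRecord], ladder: tuple[float, ...] = (38.0, 42.0, 46.0, 50.0)) -> pd.DataFrame:
    """Per-round counts and percentages, exact integer arithmetic.

    A sequence with tmax = T counts as "maintaining activity" at every
    ladder temperature ≤ T, so ladder counts are non-increasing with
    temperature by construction. Columns: tested, active_rt, inactive, one
    ``at_{T}C`` count and ``pct_{T}C`` percentage per ladder temperature.
    """
    rows = {}
    for rnd in sorted({r.round for r in records}):
        recs = [r for r in records if r.round == rnd]
        tested = len(recs)
        active_rt = sum(r.active_rt for r in recs)
        out = {"round": rnd, "tested": tested, "active_rt": active_rt, "inactive": tested - active_rt}
        for temp in ladder:
            n_at = sum(
                1 for r in recs
                if isinstance(r.tmax, float) and r.tmax >= temp
            )
            out[f"at_{temp:g}C"] = n_at
            out[f"pct_{temp:g}C"] = 100.0 * n_at / tested if tested else 0.0
        out["pct_active_rt"] = 100.0 * active_rt / tested if tested else 0.0
        rows[rnd] = out
    return pd.DataFrame(rows.values()).set_index("round")


def count_above(records: list[ScreenRecord], temp: float, inclusive: bool = True) -> int:
    """Number of sequences active at/above a temperature.

    "Active above T" is interpreted as tmax ≥ T by default (``inclusive``);
    set ``inclusive=False`` for a strict reading. The choice is logged.
    """
    log.info("count_above(%s): using %s comparison", temp, "tmax >= T" if inclusive else "tmax > T")
    if inclusive:
        return sum(1 for r in records if isinstance(r.tmax, float) and r.tmax >= temp)
    return sum(1 for r in records if isinstance(r.tmax, float) and r.tmax > temp)


# ---------------------------------------------------------------------------
# deposited-table dialect

#: header synonyms for the deposited screen-results table
TABLE_SYNONYMS: dict[str, list[str]] = {
    "id": ["id", "sequence_id", "seq_id", "name"],
    "sequence": ["sequence", "seq", "residues", "protein_sequence"],
    "round": ["round", "design_round", "screen_round", "origin"],
    "active": ["active", "activity", "active_rt", "is_active"],
    "max_temp": ["max_temp", "tmax", "highest_temp", "max_temperature", "highest_temperature_with_activity"],
}

_TRUTHY = {"true", "yes", "y", "1", "active"}
_FALSY = {"false", "no", "n", "0", "inactive"}


def read_screen_table(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Read a deposited-style results table, mapping header synonyms to the
    canonical columns id, sequence, round, active, max_temp."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    lower = {c.lower().strip(): c for c in df.columns}
    out = {}
    for canon, syns in TABLE_SYNONYMS.items():
        for syn in syns:
            if syn in lower:
                out[canon] = df[lower[syn]]
                break
    missing = {"id", "round", "active", "max_temp"} - set(out)
    if missing:
        raise ValueError(f"screen table missing required columns: {sorted(missing)}")
    res = pd.DataFrame(out)
    res["active"] = res["active"].map(_parse_flag)
    return res


def _parse_flag(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot parse activity flag {v!r}")


def records_from_table(df: pd.DataFrame, ladder: tuple[float, ...] = (38.0, 42.0, 46.0, 50.0)) -> list[ScreenRecord]:
    """Convert a canonical screen table into ScreenRecords (tmax taken at
    face value; per-temperature flags reconstructed from tmax)."""
    records = []
    for _, row in df.iterrows():
        active = bool(row["active"])
        raw = str(row["max_temp"]).strip()
        tm: float | str
        if not active or raw.lower() in ("inactive", "none", "nan", ""):
            tm = INACTIVE if not active else RT_ONLY
        elif raw.upper() in ("RT", "RT-ONLY"):
            tm = RT_ONLY
        else:
            tm = float(raw)
        active_at = {t: (isinstance(tm, float) and tm >= t) for t in ladder}
        records.append(
            ScreenRecord(
                sequence_id=str(row["id"]),
                round=str(row["round"]),
                active_rt=active,
                active_at=active_at,
                tmax=tm,
            )
        )
    return records


def write_screen_records(records: list[ScreenRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sequence_id": r.sequence_id,
                "round": r.round,
                "active_rt": r.active_rt,
                "tmax": r.tmax,
                "residual_pct": r.residual_pct,
                **{f"active_{t:g}C": flag for t, flag in sorted(r.active_at.items())},
            }
            for r in records
        ]
    ).to_csv(path, index=False)
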