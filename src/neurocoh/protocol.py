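"""Intermittent theta-burst stimulation (iTBS) protocol arithmetic and the
packaged stroke cohort.

The standard excitatory iTBS pattern delivers bursts of three pulses at
50 Hz, bursts repeating at 5 Hz; a 2 s train is repeated every 10 s over a
192 s session, giving 600 pulses in total.  Stimulation intensity is set
to 70% of the resting motor threshold (RMT, in % of maximum stimulator
output, %MSO), capped at the device limit of 40 %MSO — so any RMT above
40/0.7 ≈ 57.1 %MSO is delivered at exactly 40 %MSO.  An RMT recorded as
100 encodes "motor evoked potential not elicitable".

The packaged cohort table (30 stroke survivors, 15 per group) provides
demographics, lesion characteristics, upper-extremity Fugl-Meyer scores
and RMT, from which the delivered-intensity and demographic summaries are
recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ItbsParams",
    "ItbsSchedule",
    "itbs_schedule",
    "stimulation_intensity",
    "load_cohort",
    "cohort_summary",
]


@dataclass(frozen=True)
class ItbsParams:
    """iTBS pattern parameters (defaults: the standard 600-pulse session)."""

    pulses_per_burst: int = 3
    intra_burst_hz: float = 50.0
    burst_rate_hz: float = 5.0
    train_s: float = 2.0
    inter_train_onset_s: float = 10.0
    session_span_s: float = 192.0

    def __post_init__(self) -> None:
        vals = (self.pulses_per_burst, self.intra_burst_hz, self.burst_rate_hz,
                self.train_s, self.inter_train_onset_s, self.session_span_s)
        if any(v <= 0 for v in vals):
            raise ValueError("all iTBS parameters must be positive")
        n_bursts = self.train_s * self.burst_rate_hz
        if abs(n_bursts - round(n_bursts)) > 1e-9:
            raise ValueError("train_s x burst_rate_hz must be an integral burst count")
        if self.train_s > self.inter_train_onset_s:
            raise ValueError("train longer than the inter-train onset interval")


@dataclass
class ItbsSchedule:
    """Generated pulse times (s) and totals derived from them."""

    pulse_times: np.ndarray
    n_trains: int
    n_bursts: int
    n_pulses: int
    span_s: float


def itbs_schedule(p: ItbsParams | None = None) -> ItbsSchedule:
    """Enumerate every pulse of an iTBS session.

    Trains start at 0, ``inter_train_onset_s``, 2x, ... and a train is
    scheduled only if its full ``train_s`` fits within ``session_span_s``
    (with the defaults: 20 trains starting at 0..190 s).  Totals are counted
    from the generated schedule, not computed in closed form.
    """
    p = p or ItbsParams()
    bursts_per_train = int(round(p.train_s * p.burst_rate_hz))
    times = []
    n_trains = n_bursts = 0
    t_train = 0.0
    while t_train + p.train_s <= p.session_span_s + 1e-9:
        n_trains += 1
        for b in range(bursts_per_train):
            n_bursts += 1
            t_burst = t_train + b / p.burst_rate_hz
            for j in range(p.pulses_per_burst):
                times.append(t_burst + j / p.intra_burst_hz)
        t_train += p.inter_train_onset_s
    pulse_times = np.asarray(times)
    return ItbsSchedule(
        pulse_times=pulse_times,
        n_trains=n_trains,
        n_bursts=n_bursts,
        n_pulses=len(times),
        span_s=p.session_span_s,
    )


def stimulation_intensity(rmt: float, fraction: float = 0.7, cap: float = 40.0) -> float:
    """Delivered iTBS intensity in %MSO: ``min(fraction * RMT, cap)``.

    No rounding is applied.  ``rmt`` must lie in (0, 100]; 100 encodes
    "MEP not elicitable" and is treated like any other value (the cap
    applies).
    """
    if not 0 < rmt <= 100:
        raise ValueError("RMT must be in (0, 100] %MSO")
    return min(fraction * rmt, cap)


_COHORT_COLUMNS = {
    "subject_id", "group", "sex", "age", "paretic_hand", "chronicity_months",
    "stroke_type", "lesion_location", "ue_fma", "rmt_pct_mso",
}


def load_cohort() -> pd.DataFrame:
    """The packaged 30-subject stroke cohort (15 active / 15 sham)."""
    with resources.files("neurocoh").joinpath("data/cohort.csv").open() as fh:
        df = pd.read_csv(fh)
    missing = _COHORT_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"cohort fixture missing columns: {sorted(missing)}")
    counts = df["group"].value_counts()
    if not (counts.get("active") == 15 and counts.get("sham") == 15):
        raise ValueError("cohort fixture must contain 15 subjects per group")
    bad_fma = df[(df.ue_fma < 0) | (df.ue_fma > 66)]
    bad_rmt = df[(df.rmt_pct_mso <= 0) | (df.rmt_pct_mso > 100)]
    if len(bad_fma) or len(bad_rmt):
        raise ValueError("cohort fixture has out-of-range UE-FMA or RMT values")
    return df


def cohort_summary(
    table: pd.DataFrame, column: str, scope: str = "all"
) -> dict[str, float]:
    """Mean, sample SD (n-1) and range of a numeric cohort column.

    ``scope`` selects "all", "active" or "sham".  The derived column
    "intensity_pct_mso" (delivered iTBS intensity via
    :func:`stimulation_intensity`) is available in addition to the stored
    columns.
    """
    if scope not in {"all", "active", "sham"}:
        raise ValueError(f"unknown scope {scope!r}")
    sub = table if scope == "all" else table[table.group == scope]
    if column == "intensity_pct_mso":
        vals = sub["rmt_pct_mso"].map(stimulation_intensity).to_numpy(dtype=float)
    elif column in sub.columns:
        vals = pd.to_numeric(sub[column], errors="raise").to_numpy(dtype=float)
    else:
        raise KeyError(f"unknown cohort column {column!r}")
    return {
        "n": int(len(vals)),
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
    }
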