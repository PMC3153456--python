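"""Derived indicators, threshold detection, and time-series output.

The model's three readouts of cell fate are the available repair protein
(capability of the repair machinery), the per-time-scale rDSBC synthesis
flux (activity of damage-signal transfer to downstream pathways), and
the toxin burden / genome stability pair.  This module extracts those
tracks from a finished run, detects the characteristic times on them
(enzyme collapse, RP peak, activity turnover, stability half-loss), and
writes TSV/JSON artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import SimulationResult

#: default near-zero threshold, as a fraction of the series maximum
EPSILON_FRACTION = 0.01
#: default smoothing window (time scales) for sign-change detection on
#: noisy per-step tracks
DEFAULT_WINDOW = 25

TSV_COLUMNS = ["t", "dose_gy", "dna", "repair_gene", "dsb", "mrna", "rp",
               "rdsbc", "mdsbc", "toxins", "stability",
               "cum_dsb_generated", "cum_synthesized", "cum_dissynthesized"]


# ---------------------------------------------------------------------------
# Detection primitives
# ---------------------------------------------------------------------------

def first_below(series: Sequence[float], epsilon: float,
                after: int = 0) -> Optional[int]:
    """Smallest index t >= after with series[t] < epsilon; None if absent."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon!r}")
    arr = np.asarray(series, dtype=float)
    idx = np.nonzero(arr[after:] < epsilon)[0]
    return int(idx[0]) + after if idx.size else None


def moving_average(values: Sequence[float], window: int) -> np.ndarray:
    """Trailing moving average; element i averages the last <= window values."""
    arr = np.asarray(values, dtype=float)
    if window <= 1:
        return arr
    # fresh per-window sums (a running cumulative sum loses the sign of
    # tiny window means to cancellation)
    out = np.empty_like(arr)
    for i in range(arr.size):
        lo = max(0, i - window + 1)
        out[i] = arr[lo:i + 1].mean()
    return out


def sign_change_time(deltas: Sequence[float], smoothing_window: int = 1
                     ) -> Optional[int]:
    """First index where the window-averaged delta crosses from > 0 to < 0."""
    if smoothing_window < 1:
        raise ValueError(f"window must be >= 1, got {smoothing_window!r}")
    sm = moving_average(deltas, smoothing_window)
    for i in range(1, sm.size):
        if sm[i - 1] > 0.0 and sm[i] < 0.0:
            return i
    return None


# ---------------------------------------------------------------------------
# Indicator report
# ---------------------------------------------------------------------------

@dataclass
class IndicatorReport:
    """Indicator tracks and detected characteristic times of one run.

    Detected times are time-scale indices or None when the event does not
    occur within the run.
    """

    rp_available_track: list[float]
    rdsbc_flux_track: list[float]
    toxin_track: list[float]
    stability_track: list[float]
    t_mrna_zero: Optional[int]
    t_rp_peak: int
    t_rdsbc_sign_change: Optional[int]
    t_stability_half: Optional[int]

    def to_dict(self, include_tracks: bool = False) -> dict:
        d = {"t_mrna_zero": self.t_mrna_zero,
             "t_rp_peak": self.t_rp_peak,
             "t_rdsbc_sign_change": self.t_rdsbc_sign_change,
             "t_stability_half": self.t_stability_half}
        if include_tracks:
            d.update(rp_available_track=self.rp_available_track,
                     rdsbc_flux_track=self.rdsbc_flux_track,
                     toxin_track=self.toxin_track,
                     stability_track=self.stability_track)
        return d


def report(result: SimulationResult, epsilon: Optional[float] = None,
           window: int = DEFAULT_WINDOW) -> IndicatorReport:
    """Derive all indicator tracks and characteristic times from a run.

    Pure function of the result: identical trajectories give identical
    reports.  The mRNA near-zero crossing is searched after the mRNA
    peak with threshold ``epsilon`` (default: 1% of the track maximum);
    the activity turnover is the smoothed sign change of the per-step
    rDSBC flux increments.
    """
    if result.profile.total_steps < 1:
        raise ValueError("cannot derive indicators from an empty run")

    mrna = result.series("mrna")
    rp = result.series("rp")
    stability = result.series("stability")
    toxins = result.series("toxins")
    cum_r = np.asarray(result.series("cum_rdsbc_synth"))
    rdsbc_flux = np.diff(cum_r, prepend=cum_r[0]).tolist()

    mrna_max = max(mrna)
    eps = epsilon if epsilon is not None else EPSILON_FRACTION * mrna_max
    t_mrna_zero = (first_below(mrna, eps, after=int(np.argmax(mrna)))
                   if eps > 0 else None)
    t_rp_peak = int(np.argmax(rp))
    t_rdsbc_sign_change = sign_change_time(np.diff(rdsbc_flux), window)
    s0 = result.params.s0
    t_stability_half = first_below(stability, 0.5 * s0)

    return IndicatorReport(
        rp_available_track=list(rp),
        rdsbc_flux_track=rdsbc_flux,
        toxin_track=list(toxins),
        stability_track=list(stability),
        t_mrna_zero=t_mrna_zero,
        t_rp_peak=t_rp_peak,
        t_rdsbc_sign_change=t_rdsbc_sign_change,
        t_stability_half=t_stability_half,
    )


# ---------------------------------------------------------------------------
# TSV / JSON output
# ---------------------------------------------------------------------------

def result_frame(result: SimulationResult, record_every: int = 1) -> pd.DataFrame:
    """Tabulate a run, one row per recorded time scale.

    ``dose_gy`` in row t is the dose applied during time scale t (the
    t=0 row, the initial state, carries dose 0).
    """
    doses = [0.0] + list(result.profile.doses())
    rows = []
    total = result.profile.total_steps
    for t, state in enumerate(result.states):
        if t % record_every and t != total:
            continue
        rows.append({
            "t": t, "dose_gy": doses[t], "dna": state.dna,
            "repair_gene": state.repair_gene, "dsb": state.dsb,
            "mrna": state.mrna, "rp": state.rp, "rdsbc": state.rdsbc,
            "mdsbc": state.mdsbc, "toxins": state.toxins,
            "stability": state.stability,
            "cum_dsb_generated": state.cum_dsb_generated,
            "cum_synthesized": state.cum_synthesized,
            "cum_dissynthesized": state.cum_dissynthesized,
        })
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_timeseries(path, result: SimulationResult, record_every: int = 1) -> None:
    result_frame(result, record_every).to_csv(path, sep="\t", index=False,
                                              encoding="utf-8")


def write_report(path, result: SimulationResult,
                 rep: IndicatorReport | None = None) -> None:
    """Write the indicator report plus run metadata as JSON."""
    if rep is None:
        rep = report(result)
    final = result.states[-1]
    doc = {
        "mode": result.mode,
        "seed": result.seed,
        "total_steps": result.profile.total_steps,
        "parameter_provenance": _provenance(),
        "indicators": rep.to_dict(),
        "final_state": {k: getattr(final, k) for k in
                        ("dna", "repair_gene", "dsb", "mrna", "rp", "rdsbc",
                         "mdsbc", "toxins", "stability")},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def _provenance() -> str:
    from .core_model import PARAMETER_PROVENANCE
    return PARAMETER_PROVENANCE
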