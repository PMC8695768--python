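"""Cambial phenology and within-season extrema of phase trajectories.

Onset and end of wood cell development follow the standard micro-core rule:
the first and last sampling days on which enlarging cells are present (the
row-averaged count exceeds zero); duration is their difference.  Onset and
end are assigned to observed sampling dates — no interpolation between
visits, matching how weekly/biweekly campaigns are read.

Phase trajectories (cambial and enlarging counts) in bimodal climates show
two seasonal activity peaks separated by a mid-season lull.  These are
characterized by smoothing the raw counts with local linear regression
(tricube weights, LOWESS) and scanning the smoothed series for prominent
interior extrema; series boundary points are eligible as the first maximum
or the last minimum, since dormant-season counts often peak at the first
sampling date.  The two most prominent maxima, in day order, become the
first/second maxima; the intervening minimum and the minimum after the
second peak complete the Ft/Fb/St/Sb quadruple.  Bell-shaped phases
(wall-thickening) get a single max/min pair instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

__all__ = [
    "PhenologyRecord",
    "BimodalExtrema",
    "StandPhenology",
    "detect_onset_end",
    "smooth_series",
    "find_bimodal_extrema",
    "stand_phenology",
]


@dataclass(frozen=True)
class PhenologyRecord:
    """Per-tree onset/end/duration of wood cell development (DOY).

    ``empty`` marks a tree with no enlarging cells all season (no growth);
    the day fields are then None.
    """

    tree_id: str
    onset_doy: int | None
    end_doy: int | None
    duration_days: int | None

    def __post_init__(self) -> None:
        if self.onset_doy is not None:
            if self.end_doy is None or self.duration_days is None:
                raise ValueError("partial phenology record")
            if self.onset_doy > self.end_doy:
                raise ValueError("onset after end")
            if self.duration_days != self.end_doy - self.onset_doy:
                raise ValueError("duration must equal end - onset")

    @property
    def empty(self) -> bool:
        return self.onset_doy is None


@dataclass
class BimodalExtrema:
    """Seasonal extrema of one phase trajectory.

    For a bimodal series: ``first_max``/``first_min``/``second_max``/
    ``second_min`` as (DOY, cells) pairs in day order.  For a unimodal
    (bell-shaped) series only ``unimodal_max``/``unimodal_min`` are set and
    ``is_bimodal`` is False.  ``second_below_first`` reports whether the
    late-season peak stayed below the spring peak (typical, but recorded
    rather than enforced); ``ambiguous`` flags that more than two prominent
    maxima were found and the two most prominent were kept.
    """

    phase: str
    is_bimodal: bool
    first_max: tuple[float, float] | None = None
    first_min: tuple[float, float] | None = None
    second_max: tuple[float, float] | None = None
    second_min: tuple[float, float] | None = None
    unimodal_max: tuple[float, float] | None = None
    unimodal_min: tuple[float, float] | None = None
    second_below_first: bool | None = None
    ambiguous: bool = False


@dataclass(frozen=True)
class StandPhenology:
    """Stand-level mean (SD) of onset, end and duration across trees."""

    n_trees: int
    onset_mean: float
    onset_sd: float
    end_mean: float
    end_sd: float
    duration_mean: float
    duration_sd: float
    single_tree: bool = False


def detect_onset_end(series: pd.DataFrame | pd.Series, tree_id: str = "",
                     threshold: float = 0.0) -> PhenologyRecord:
    """Onset/end/duration from a per-tree enlarging-count series.

    ``series`` is either a frame with ``doy`` and ``n_enlarging`` columns or
    a Series indexed by DOY.  Onset is the first sampling day with count
    strictly above ``threshold`` (default 0: at least one row of cells
    observed enlarging), end the last such day.  An all-zero season yields
    an explicit empty record, not an exception.
    """
    if isinstance(series, pd.DataFrame):
        ser = series.set_index("doy")["n_enlarging"]
        if not tree_id and "tree_id" in series.columns:
            tree_id = str(series["tree_id"].iloc[0])
    else:
        ser = series
    ser = ser.sort_index()
    if (ser < 0).any():
        raise ValueError("negative cell counts in series")
    active = ser.index[ser.to_numpy(float) > threshold]
    if len(active) == 0:
        return PhenologyRecord(tree_id, None, None, None)
    onset, end = int(active[0]), int(active[-1])
    return PhenologyRecord(tree_id, onset, end, end - onset)


def smooth_series(series: pd.Series, span: float = 0.25) -> pd.Series:
    """LOWESS (local linear, tricube weights) smooth on the observed grid.

    ``series`` is indexed by DOY.  Deterministic, length-preserving;
    reproduces constants and straight lines exactly.  Requires at least 7
    points and ``0 < span <= 1``.
    """
    if not (0.0 < span <= 1.0):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(series) < 7:
        raise ValueError(f"need at least 7 points to smooth, got {len(series)}")
    ser = series.sort_index()
    x = ser.index.to_numpy(float)
    sm = _lowess(ser.to_numpy(float), x, frac=span, it=0, return_sorted=False)
    return pd.Series(sm, index=ser.index)


def _local_maxima(y: np.ndarray, prominence: float):
    """Interior and boundary local maxima with their prominences.

    Boundary points are made eligible by padding with the series minimum
    (so a declining dormant-season start can be a first maximum without a
    boundary point acquiring unbounded prominence); ties between equal
    heights resolve to the earliest index.
    """
    pad = float(np.min(y))
    padded = np.concatenate([[pad], y, [pad]])
    idx, props = find_peaks(padded, prominence=prominence)
    return idx - 1, props["prominences"]


def find_bimodal_extrema(smoothed: pd.Series, min_prominence: float = 0.5,
                         phase: str = "") -> BimodalExtrema:
    """Locate the seasonal maxima/minima of a smoothed phase trajectory.

    With two (or more) prominent maxima the two most prominent are kept and
    reported in day order together with the intervening minimum and the
    minimum after the second peak.  With a single prominent maximum the
    result is flagged unimodal, with the post-peak minimum attached.
    Monotone or flat series yield a degenerate result with no extrema.
    """
    ser = smoothed.sort_index()
    x = ser.index.to_numpy(float)
    y = ser.to_numpy(float)
    peaks, prom = _local_maxima(y, min_prominence)
    if peaks.size == 0:
        return BimodalExtrema(phase=phase, is_bimodal=False)
    if peaks.size == 1:
        p = int(peaks[0])
        after = y[p:]
        j = p + int(np.argmin(after))
        return BimodalExtrema(
            phase=phase, is_bimodal=False,
            unimodal_max=(float(x[p]), float(y[p])),
            unimodal_min=(float(x[j]), float(y[j])),
        )
    ambiguous = peaks.size > 2
    keep = peaks[np.argsort(-prom, kind="stable")[:2]]
    i1, i2 = int(min(keep)), int(max(keep))
    between = slice(i1, i2 + 1)
    jmin = i1 + int(np.argmin(y[between]))
    after = y[i2:]
    jend = i2 + int(np.argmin(after))
    return BimodalExtrema(
        phase=phase, is_bimodal=True,
        first_max=(float(x[i1]), float(y[i1])),
        first_min=(float(x[jmin]), float(y[jmin])),
        second_max=(float(x[i2]), float(y[i2])),
        second_min=(float(x[jend]), float(y[jend])),
        second_below_first=bool(y[i2] <= y[i1]),
        ambiguous=ambiguous,
    )


def stand_phenology(records: list[PhenologyRecord]) -> StandPhenology:
    """Mean and sample SD of onset, end and duration across a stand's trees.

    Empty (no-growth) records are excluded.  By linearity the mean duration
    always equals mean end minus mean onset.  A single contributing tree
    yields SDs of 0 with ``single_tree`` set.
    """
    live = [r for r in records if not r.empty]
    if not live:
        raise ValueError("no non-empty phenology records")
    onset = np.array([r.onset_doy for r in live], dtype=float)
    end = np.array([r.end_doy for r in live], dtype=float)
    dur = np.array([r.duration_days for r in live], dtype=float)
    single = len(live) == 1
    sd = (lambda v: 0.0) if single else (lambda v: float(np.std(v, ddof=1)))
    return StandPhenology(
        n_trees=len(live),
        onset_mean=float(onset.mean()), onset_sd=sd(onset),
        end_mean=float(end.mean()), end_sd=sd(end),
        duration_mean=float(dur.mean()), duration_sd=sd(dur),
        single_tree=single,
    )
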