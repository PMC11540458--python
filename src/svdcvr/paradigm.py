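"""Gas-challenge paradigm and end-tidal CO2 regressor handling.

A hypercapnic cerebrovascular-reactivity (CVR) exam alternates blocks of
medical air and a CO2-enriched gas mixture while BOLD volumes are acquired
every TR seconds.  This module builds the block schedule, resamples a raw
end-tidal CO2 (EtCO2) trace onto the volume time grid, and applies the
temporal shifts used by the delay-optimized CVR fit.

Conventions
-----------
* Volume ``v`` (0-based) is timestamped at its centre, ``(v + 0.5) * TR``.
* Shifting a regressor by a positive delay moves it later in time; samples
  pushed past the series edge hold the edge value, so every delay is fit on
  the same number of volumes.
* The delay grid is restricted to integer multiples of TR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AIR",
    "CO2",
    "ParadigmSchedule",
    "Etco2Trace",
    "RegressorSeries",
    "build_paradigm",
    "resample_etco2",
    "shift_regressor",
    "default_delay_grid",
    "read_etco2",
    "Etco2CoverageError",
]

AIR = "air"
CO2 = "co2"

#: Default delay search grid in TR units: generous positive lags because the
#: BOLD response trails the inhaled-gas stimulus, a short negative tail as a
#: sanity margin.  Must contain 0.
DELAY_GRID_TR = np.arange(-10, 41)


class Etco2CoverageError(ValueError):
    """EtCO2 recording covers too little of the scan to build a regressor."""


@dataclass(frozen=True)
class ParadigmSchedule:
    """Per-volume gas labelling of a block-design gas challenge.

    Attributes
    ----------
    tr_s : float
        Seconds per BOLD volume (repetition time).
    blocks : tuple of (str, float)
        Ordered ``(gas, duration_s)`` pairs; gases alternate starting with air.
    n_volumes : int
        Number of volumes fitting inside the total block duration.
    volume_gas : numpy.ndarray of str
        Gas label of each volume, by the block containing its centre time.
    """

    tr_s: float
    blocks: tuple[tuple[str, float], ...]
    n_volumes: int
    volume_gas: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not self.blocks:
            raise ValueError("block list must not be empty")
        for i, (gas, dur) in enumerate(self.blocks):
            if dur <= 0:
                raise ValueError(f"block {i} has non-positive duration {dur}")
            expected = AIR if i % 2 == 0 else CO2
            if gas != expected:
                raise ValueError(
                    "gas labels must alternate beginning with air "
                    f"(block {i} is {gas!r}, expected {expected!r})"
                )
        if len(self.volume_gas) != self.n_volumes:
            raise ValueError("volume_gas length must equal n_volumes")
        if abs(self.n_volumes * self.tr_s - self.total_duration_s) >= self.tr_s:
            raise ValueError("n_volumes inconsistent with total block duration")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    @property
    def volume_times_s(self) -> np.ndarray:
        """Centre time of each volume, ``(v + 0.5) * TR``."""
        return (np.arange(self.n_volumes) + 0.5) * self.tr_s


@dataclass(frozen=True)
class Etco2Trace:
    """Raw end-tidal CO2 samples: timestamps (s) and partial pressures (mm Hg)."""

    times_s: np.ndarray
    values_mmHg: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values_mmHg, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values_mmHg", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("an EtCO2 trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(v >= 0) and np.all(v <= 150)):
            raise ValueError("EtCO2 values must be finite and within [0, 150] mm Hg")

    @property
    def span_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


@dataclass(frozen=True)
class RegressorSeries:
    """EtCO2 regressor on the volume grid, with the delay applied to it."""

    values_mmHg: np.ndarray
    tr_s: float
    applied_delay_s: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values_mmHg, dtype=float)
        object.__setattr__(self, "values_mmHg", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("regressor must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("regressor values must be finite")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def __len__(self) -> int:
        return int(self.values_mmHg.size)


def build_paradigm(block_minutes, tr_s: float) -> ParadigmSchedule:
    """Build the per-volume gas schedule of an alternating air/CO2 challenge.

    Parameters
    ----------
    block_minutes : sequence of float
        Ordered block durations in minutes; odd-indexed blocks are the
        hypercapnic (CO2) blocks.  The standard 12-minute protocol is
        ``(2, 3, 2, 3, 2)``.
    tr_s : float
        Repetition time in seconds.

    Returns
    -------
    ParadigmSchedule
        With ``n_volumes = floor(total_seconds / tr_s)`` and each volume
        labelled by the block containing its centre time.
    """
    block_minutes = list(block_minutes)
    if not block_minutes:
        raise ValueError("block list must not be empty")
    if any(b <= 0 for b in block_minutes):
        raise ValueError("all block durations must be positive")
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")

    blocks = tuple(
        (AIR if i % 2 == 0 else CO2, 60.0 * m) for i, m in enumerate(block_minutes)
    )
    total_s = sum(d for _, d in blocks)
    n_volumes = int(np.floor(total_s / tr_s))
    if n_volumes < 1:
        raise ValueError("schedule too short: no complete volume fits in it")

    ends = np.cumsum([d for _, d in blocks])
    centres = (np.arange(n_volumes) + 0.5) * tr_s
    idx = np.searchsorted(ends, centres, side="right")
    idx = np.minimum(idx, len(blocks) - 1)  # guard FP round-off at the tail
    gases = np.array([g for g, _ in blocks])
    return ParadigmSchedule(
        tr_s=float(tr_s), blocks=blocks, n_volumes=n_volumes, volume_gas=gases[idx]
    )


def resample_etco2(trace: Etco2Trace, schedule: ParadigmSchedule) -> RegressorSeries:
    """Linearly interpolate an EtCO2 trace at each volume-centre time.

    Outside the recorded span the nearest sample value is held.  A recording
    covering less than half the scan is rejected (poor trace quality makes
    the regressor, and hence CVR, unusable).
    """
    if trace.span_s < 0.5 * schedule.total_duration_s:
        raise Etco2CoverageError(
            f"EtCO2 trace spans {trace.span_s:.0f} s, less than half the "
            f"{schedule.total_duration_s:.0f} s schedule"
        )
    values = np.interp(schedule.volume_times_s, trace.times_s, trace.values_mmHg)
    return RegressorSeries(values_mmHg=values, tr_s=schedule.tr_s, applied_delay_s=0.0)


def _delay_in_tr(delay_s: float, tr_s: float) -> int:
    k = delay_s / tr_s
    k_int = int(np.rint(k))
    if abs(k - k_int) > 1e-6:
        raise ValueError(
            f"delay {delay_s} s is not an integer multiple of TR = {tr_s} s"
        )
    return k_int


def shift_regressor(regressor: RegressorSeries, delay_s: float) -> RegressorSeries:
    """Shift a regressor later in time by ``delay_s`` (a multiple of TR).

    Output volume ``v`` takes the input value at ``v - delay/TR``; indices
    shifted beyond the edges hold the edge value, so all delays retain the
    full sample count and their residual sums are directly comparable.
    """
    k = _delay_in_tr(delay_s, regressor.tr_s)
    n = len(regressor)
    src = np.clip(np.arange(n) - k, 0, n - 1)
    return RegressorSeries(
        values_mmHg=regressor.values_mmHg[src],
        tr_s=regressor.tr_s,
        applied_delay_s=float(k * regressor.tr_s),
    )


def default_delay_grid(tr_s: float) -> np.ndarray:
    """Delay search grid in seconds: −10·TR … +40·TR in steps of one TR."""
    return DELAY_GRID_TR * float(tr_s)


_SPLIT = re.compile(r"[,\s;]+")


def read_etco2(path) -> Etco2Trace:
    """Read a 2-column (seconds, mmHg) delimited text trace.

    Comment lines start with ``#``; a single non-numeric header line is
    tolerated.  Delimiters may be whitespace, commas, or semicolons.
    """
    times: list[float] = []
    values: list[float] = []
    header_seen = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in _SPLIT.split(line) if p]
        try:
            t, v = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if not header_seen and not times:
                header_seen = True
                continue
            raise ValueError(f"unparseable EtCO2 line: {raw!r}")
        times.append(t)
        values.append(v)
    return Etco2Trace(times_s=np.array(times), values_mmHg=np.array(values))
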