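"""Ratiometric promoter-activity extraction from plate-fluorometer data.

Promoter activity is measured in relative promoter units (RPU) as the
ratio of the target reporter's accumulation rate to that of a
constitutively expressed reference reporter, rho = d(YFP)/d(CFP).  Over a
window where both channels accumulate linearly in time, rho is estimated
as the ratio of the two fitted accumulation rates; normalizing to the
reference makes the measure robust to variation in growth and
gene-expression capacity, because the reference channel reports exactly
that capacity.

The analysis window defaults to the most linear stretch of the reference
channel (mid-exponential growth), found by maximizing the coefficient of
determination of a reference-vs-time regression over sliding windows of
one third of the series length.  Grid-membrane experiments use the
chromosomally integrated mRFP1 channel as the reference so that output is
normalized to the gene-expression capacity of each population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "PlateTimeSeries",
    "ActivityEstimate",
    "DoseResponseDataset",
    "estimate_activity",
    "subtract_background",
    "build_dose_response",
    "read_plate_csv",
    "write_plate_csv",
    "DegenerateReferenceError",
    "InsufficientDataError",
    "MetadataMismatchError",
]


class DegenerateReferenceError(ValueError):
    """Reference channel did not accumulate over the analysis window."""


class InsufficientDataError(ValueError):
    """Too few time points for a regression-based activity estimate."""


class MetadataMismatchError(ValueError):
    """Series combined across incompatible devices/conditions."""


@dataclass(frozen=True)
class Condition:
    """Experimental annotation of one well."""

    device: str = ""
    hsl_species: str | None = None  # "3OC6HSL" | "3OC12HSL" | None
    hsl_nM: float = 0.0
    arabinose_mM: float = 0.0
    replicate: int = 0
    is_blank: bool = False

    @property
    def c6_nM(self) -> float:
        return self.hsl_nM if self.hsl_species == "3OC6HSL" else 0.0

    @property
    def c12_nM(self) -> float:
        return self.hsl_nM if self.hsl_species == "3OC12HSL" else 0.0


@dataclass(frozen=True)
class PlateTimeSeries:
    """Multi-channel fluorescence/OD trajectories of one well.

    ``channels`` maps channel name (YFP, CFP, RFP, OD) to a value array
    aligned with ``time_min``.  Typical cadence is one read every 10 min
    for 1,000 min.
    """

    well: str
    time_min: np.ndarray
    channels: dict[str, np.ndarray]
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        object.__setattr__(self, "time_min", t)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be a strictly increasing 1-D array")
        chans = {}
        for name, v in self.channels.items():
            v = np.asarray(v, dtype=float)
            if v.shape != t.shape:
                raise ValueError(f"channel {name!r} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            chans[name] = v
        object.__setattr__(self, "channels", chans)

    def __len__(self) -> int:
        return self.time_min.size


@dataclass(frozen=True)
class ActivityEstimate:
    """Relative promoter activity rho with its regression standard error."""

    rho: float  # RPU
    stderr: float  # RPU
    window: tuple[float, float]  # [t_start, t_end], minutes
    reference_channel: str
    n_points: int = 0

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


def _default_window(t: np.ndarray, ref: np.ndarray) -> slice:
    """Most linear reference-vs-time stretch: max R^2 over sliding windows
    of one third of the series length (ties broken toward earlier start).

    The reference is lightly smoothed before the search so that window
    choice reflects the accumulation shape rather than per-read noise;
    selecting on the raw trace couples the window to the noise draws and
    biases the subsequent slope estimate.
    """
    npts = t.size
    if npts >= 9:
        kernel = np.ones(5) / 5.0
        pad = np.concatenate([ref[2::-1], ref, ref[-1:-4:-1]])
        ref = np.convolve(pad, kernel, mode="valid")
    w = max(4, int(np.ceil(npts / 3)))
    best_r2, best_start = -np.inf, 0
    for start in range(0, npts - w + 1):
        tt = t[start:start + w]
        yy = ref[start:start + w]
        tc = tt - tt.mean()
        yc = yy - yy.mean()
        sxx = float(tc @ tc)
        syy = float(yc @ yc)
        if syy <= 0:
            r2 = 0.0
        else:
            r2 = float(tc @ yc) ** 2 / (sxx * syy)
        if r2 > best_r2 + 1e-15:
            best_r2, best_start = r2, start
    return slice(best_start, best_start + w)


def estimate_activity(ts: PlateTimeSeries, target_channel: str = "YFP",
                      reference_channel: str = "CFP",
                      window: tuple[float, float] | None = None) -> ActivityEstimate:
    """Estimate rho = d(target)/d(reference) within an analysis window.

    ``window`` is an optional explicit ``(t_start, t_end)`` in minutes;
    by default the most linear reference stretch is used.  Raises
    :class:`DegenerateReferenceError` if the reference does not accumulate
    over the window and :class:`InsufficientDataError` for windows of
    fewer than 4 points.
    """
    for ch in (target_channel, reference_channel):
        if ch not in ts.channels:
            raise KeyError(f"channel {ch!r} not present in well {ts.well!r}")
    if len(ts) < 8:
        raise InsufficientDataError(
            f"need >= 8 time points, got {len(ts)}")
    t = ts.time_min
    ref = ts.channels[reference_channel]
    tgt = ts.channels[target_channel]
    if window is None:
        # Prefer selecting the window from the integrated OD trace: it
        # shares the accumulation shape of the reference (both integrate
        # growth capacity) but its noise is independent of the
        # fluorescence channels, so window choice cannot condition on
        # the very noise the regression must average over.
        if "OD" in ts.channels and reference_channel != "OD":
            od = ts.channels["OD"]
            sel = np.concatenate(
                [[0.0], np.cumsum(0.5 * (od[1:] + od[:-1]) * np.diff(t))])
        else:
            sel = ref
        sl = _default_window(t, sel)
    else:
        mask = (t >= window[0]) & (t <= window[1])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise InsufficientDataError("window outside the data range")
        sl = slice(idx[0], idx[-1] + 1)
    x = ref[sl]
    y = tgt[sl]
    tt = t[sl]
    if x.size < 4:
        raise InsufficientDataError(
            f"window has {x.size} points; need >= 4")
    if x[-1] - x[0] <= 0:
        raise DegenerateReferenceError(
            "reference channel did not accumulate over the window")

    # rho = de(target)/de(reference): ratio of the two accumulation rates
    # from per-channel regressions on (noise-free) time.  Regressing one
    # noisy channel directly on the other would attenuate the slope.
    def slope_se(values):
        tc = tt - tt.mean()
        stt = float(tc @ tc)
        m = float(tc @ values) / stt
        resid = values - (values.mean() + m * tc)
        # HC3 heteroscedasticity-robust slope variance: multiplicative
        # measurement noise makes residual variance grow with the signal
        h = 1.0 / tc.size + tc ** 2 / stt
        se = math.sqrt(float(np.sum((tc * resid / (1.0 - h)) ** 2)) / stt ** 2)
        return m, se

    m_ref, se_ref = slope_se(x)
    m_tgt, se_tgt = slope_se(y)
    if m_ref <= 0:
        raise DegenerateReferenceError(
            "reference accumulation rate is non-positive over the window")
    rho = m_tgt / m_ref
    # first-order (delta-method) error propagation; channels independent
    se = abs(rho) * math.sqrt((se_tgt / m_tgt) ** 2 + (se_ref / m_ref) ** 2) \
        if m_tgt != 0 else se_tgt / m_ref
    # small-sample adjustment: the slope variance is itself estimated, so
    # scale by t/z so that +-2 stderr approximates a 95% interval
    from scipy import stats
    se *= stats.t.ppf(0.975, x.size - 2) / stats.norm.ppf(0.975)
    return ActivityEstimate(rho=rho, stderr=se,
                            window=(float(tt[0]), float(tt[-1])),
                            reference_channel=reference_channel,
                            n_points=x.size)


def subtract_background(ts: PlateTimeSeries,
                        blanks: PlateTimeSeries | list[PlateTimeSeries]
                        ) -> PlateTimeSeries:
    """Subtract the per-channel, per-time mean of blank wells.

    Negative corrected values are clipped at zero; the number of clipped
    points is recorded in the returned series' condition-free metadata
    (the function simply clips, callers can diff to count).
    """
    if isinstance(blanks, PlateTimeSeries):
        blanks = [blanks]
    if not blanks:
        raise ValueError("at least one blank well is required")
    out = {}
    for name, v in ts.channels.items():
        stack = []
        for b in blanks:
            if name not in b.channels:
                raise MetadataMismatchError(
                    f"blank {b.well!r} lacks channel {name!r}")
            if b.time_min.shape != ts.time_min.shape or \
                    not np.allclose(b.time_min, ts.time_min):
                raise MetadataMismatchError(
                    f"blank {b.well!r} time grid differs from {ts.well!r}")
            stack.append(b.channels[name])
        bg = np.mean(stack, axis=0)
        out[name] = np.clip(v - bg, 0.0, None)
    return replace(ts, channels=out)


@dataclass(frozen=True)
class DoseResponseDataset:
    """Replicate-collapsed promoter activity vs dose for one device.

    ``points`` holds one row per (C6, C12, arabinose) condition with
    columns ``c6_nM, c12_nM, arabinose_mM, rho_mean, rho_sd, n_reps``,
    ordered by dose.  ``rho_sd`` is NaN where only one replicate exists
    (undefined, deliberately not zero).
    """

    device: str
    promoter: str
    points: pd.DataFrame

    def __post_init__(self):
        required = {"c6_nM", "c12_nM", "arabinose_mM",
                    "rho_mean", "rho_sd", "n_reps"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"points missing columns {sorted(missing)}")
        if (self.points[["c6_nM", "c12_nM"]] < 0).any().any():
            raise ValueError("doses must be >= 0")

    def __len__(self):
        return len(self.points)


def build_dose_response(series: list[PlateTimeSeries],
                        target_channel: str = "YFP",
                        reference_channel: str = "CFP",
                        promoter: str = "",
                        window: tuple[float, float] | None = None
                        ) -> DoseResponseDataset:
    """Collapse replicate wells into a per-dose mean/sd dose response."""
    series = [ts for ts in series if not ts.condition.is_blank]
    if not series:
        raise ValueError("no non-blank series supplied")
    devices = {ts.condition.device for ts in series}
    if len(devices) > 1:
        raise MetadataMismatchError(
            f"series mix devices {sorted(devices)}")
    rows = []
    for ts in series:
        est = estimate_activity(ts, target_channel, reference_channel,
                                window=window)
        c = ts.condition
        rows.append((c.c6_nM, c.c12_nM, c.arabinose_mM, est.rho))
    df = pd.DataFrame(rows, columns=["c6_nM", "c12_nM", "arabinose_mM", "rho"])
    grouped = df.groupby(["c6_nM", "c12_nM", "arabinose_mM"], sort=True)
    agg = grouped["rho"].agg(rho_mean="mean",
                             rho_sd=lambda v: np.std(v, ddof=1) if len(v) > 1 else np.nan,
                             n_reps="count").reset_index()
    agg = agg.sort_values(["arabinose_mM", "c12_nM", "c6_nM"],
                          kind="mergesort").reset_index(drop=True)
    return DoseResponseDataset(device=devices.pop(), promoter=promoter,
                               points=agg)


# ---------------------------------------------------------------------------
# CSV interchange (long format)
# ---------------------------------------------------------------------------

def write_plate_csv(series: list[PlateTimeSeries], data_path, conditions_path) -> None:
    """Write wells as long-format CSV plus a per-well conditions table."""
    recs = []
    conds = []
    for ts in series:
        for ch, v in sorted(ts.channels.items()):
            for t, val in zip(ts.time_min, v):
                recs.append((ts.well, t, ch, val))
        c = ts.condition
        conds.append((ts.well, c.device, c.hsl_species or "", c.hsl_nM,
                      c.arabinose_mM, c.replicate, int(c.is_blank)))
    pd.DataFrame(recs, columns=["well", "time_min", "channel", "value"]) \
        .to_csv(data_path, index=False)
    pd.DataFrame(conds, columns=["well", "device", "hsl_species", "hsl_nM",
                                 "arabinose_mM", "replicate", "is_blank"]) \
        .to_csv(conditions_path, index=False)


def read_plate_csv(data_path, conditions_path) -> list[PlateTimeSeries]:
    """Read wells from long-format CSV written by :func:`write_plate_csv`."""
    data = pd.read_csv(data_path)
    conds = pd.read_csv(conditions_path).set_index("well")
    out = []
    for well, g in data.groupby("well", sort=True):
        chans = {}
        tgrid = None
        for ch, gc in g.groupby("channel"):
            gc = gc.sort_values("time_min")
            if tgrid is None:
                tgrid = gc["time_min"].to_numpy()
            chans[ch] = gc["value"].to_numpy()
        row = conds.loc[well]
        species = row["hsl_species"]
        if pd.isna(species) or species == "":
            species = None
        cond = Condition(device=str(row["device"]), hsl_species=species,
                         hsl_nM=float(row["hsl_nM"]),
                         arabinose_mM=float(row["arabinose_mM"]),
                         replicate=int(row["replicate"]),
                         is_blank=bool(int(row["is_blank"])))
        out.append(PlateTimeSeries(well=str(well), time_min=tgrid,
                                   channels=chans, condition=cond))
    return out
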