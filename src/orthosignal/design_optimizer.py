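"""Receiver-expression optimization for the two-channel device.

A two-channel receiver reads 3OC6HSL out through CFP (pLux76) and
3OC12HSL through YFP (pLas81).  Its quality is summarized by the
signal-to-crosstalk ratio at a reference dose (100 nM of one signal at a
time):

    (CFP_C6 * YFP_C12) / (CFP_C12 * YFP_C6)

where XFP_CY is the ratiometric expression of fluorescent protein X at
the reference dose of HSL Y (the other signal absent).  The ratio is 1
for a device whose two promoter blocks are identical, and swapping the
blocks inverts it.  Because both channels share the intracellular
receiver levels (r, s), the ratio traces out a landscape over (r, s);
raising LuxR first strengthens the intended CFP response but eventually
inflates both chemical crosstalk (LuxR binding 3OC12HSL) and genetic
crosstalk (LuxR activating pLas81), so the optimum is interior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import CrosstalkParameters, simplified_rate

__all__ = [
    "TwoChannelDevice",
    "channel_response",
    "signal_to_crosstalk",
    "optimize_levels",
    "OptimizationResult",
]

_SHARED_FIELDS = ("KR6", "KR12", "KS6", "KS12", "n", "r", "s")


@dataclass(frozen=True)
class TwoChannelDevice:
    """Two promoter contexts sharing receiver constants and levels.

    ``cfp_promoter`` (pLux76) and ``yfp_promoter`` (pLas81) must agree on
    every receiver-side field; the shared (r, s) are read from them.
    """

    cfp_promoter: CrosstalkParameters
    yfp_promoter: CrosstalkParameters

    def __post_init__(self):
        for f in _SHARED_FIELDS:
            a, b = getattr(self.cfp_promoter, f), getattr(self.yfp_promoter, f)
            if a != b:
                raise ValueError(
                    f"receiver-side field {f!r} differs between channels "
                    f"({a!r} vs {b!r})")

    @property
    def levels(self) -> tuple[float, float]:
        return self.cfp_promoter.r, self.cfp_promoter.s

    def with_levels(self, r: float, s: float) -> "TwoChannelDevice":
        return TwoChannelDevice(self.cfp_promoter.with_levels(r, s),
                                self.yfp_promoter.with_levels(r, s))

    def swapped(self) -> "TwoChannelDevice":
        return TwoChannelDevice(self.yfp_promoter, self.cfp_promoter)


def channel_response(device: TwoChannelDevice, channel: str, C6, C12):
    """Equilibrium response (RPU) of one fluorescence channel."""
    if channel == "CFP":
        return simplified_rate(device.cfp_promoter, C6, C12)
    if channel == "YFP":
        return simplified_rate(device.yfp_promoter, C6, C12)
    raise ValueError("channel must be 'CFP' or 'YFP'")


def signal_to_crosstalk(device: TwoChannelDevice,
                        dose: float = 100.0) -> float:
    """Signal-to-crosstalk ratio at ``dose`` nM, one signal at a time.

    Returns ``inf`` when a crosstalk response in the denominator is zero
    (crosstalk below basal resolution).
    """
    cfp_c6 = channel_response(device, "CFP", dose, 0.0)
    cfp_c12 = channel_response(device, "CFP", 0.0, dose)
    yfp_c6 = channel_response(device, "YFP", dose, 0.0)
    yfp_c12 = channel_response(device, "YFP", 0.0, dose)
    for v in (cfp_c6, cfp_c12, yfp_c6, yfp_c12):
        if not np.isfinite(v) or v < 0:
            raise ValueError("channel responses must be finite and >= 0")
    num = cfp_c6 * yfp_c12
    den = cfp_c12 * yfp_c6
    if den == 0.0:
        return float("inf")
    return float(num / den)


def _ratio_on_grid(device, r_grid, s_grid, dose):
    """Vectorized landscape: occupancies recomputed per (r, s) point."""
    rr, ss = np.meshgrid(r_grid, s_grid, indexing="ij")
    out = np.empty(rr.shape)

    # occupancy fractions at the four stimulation corners do not depend
    # on (r, s); precompute and scale.
    def weights(p: CrosstalkParameters, c6, c12):
        uR = ((p.KR6 * c6) ** p.n + (p.KR12 * c12) ** p.n) \
            / (1 + p.KR6 * c6 + p.KR12 * c12) ** p.n
        uS = ((p.KS6 * c6) ** p.n + (p.KS12 * c12) ** p.n) \
            / (1 + p.KS6 * c6 + p.KS12 * c12) ** p.n
        return p.KGR * uR, p.KGS * uS

    def response(p, c6, c12):
        wR, wS = weights(p, c6, c12)
        WR = wR * rr ** 2
        WS = wS * ss ** 2
        return (p.a0 + p.a1R * WR + p.a1S * WS) / (1 + WR + WS)

    cfp_c6 = response(device.cfp_promoter, dose, 0.0)
    cfp_c12 = response(device.cfp_promoter, 0.0, dose)
    yfp_c6 = response(device.yfp_promoter, dose, 0.0)
    yfp_c12 = response(device.yfp_promoter, 0.0, dose)
    with np.errstate(divide="ignore"):
        out = cfp_c6 * yfp_c12 / (cfp_c12 * yfp_c6)
    return out


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal receiver levels with the full landscape for isoline plots."""

    r_opt: float
    s_opt: float
    ratio_opt: float
    landscape: pd.DataFrame  # columns r, s, ratio
    s_identifiable: bool = True
    r_identifiable: bool = True


def optimize_levels(device: TwoChannelDevice,
                    r_range: tuple[float, float] = (0.1, 100.0),
                    s_range: tuple[float, float] = (0.1, 100.0),
                    density: int = 50, dose: float = 100.0,
                    refine: bool = True) -> OptimizationResult:
    """Locate the signal-to-crosstalk optimum over a log-spaced grid.

    The grid arg-max is optionally polished by Nelder-Mead in log space
    (clipped to the ranges); refinement never returns a worse objective
    than the best grid point.  If the objective is flat along an axis
    (e.g. no LasR-dependent terms anywhere), that axis is reported as
    unidentifiable and its grid midpoint returned.
    """
    if density < 25:
        raise ValueError("grid density must be >= 25 per axis")
    if min(r_range) <= 0 or min(s_range) <= 0:
        raise ValueError("ranges must be positive")
    r_grid = np.geomspace(r_range[0], r_range[1], density)
    s_grid = np.geomspace(s_range[0], s_range[1], density)
    Z = _ratio_on_grid(device, r_grid, s_grid, dose)

    finite = np.where(np.isfinite(Z), Z, -np.inf)
    i, j = np.unravel_index(np.argmax(finite), Z.shape)
    r_best, s_best, z_best = float(r_grid[i]), float(s_grid[j]), float(Z[i, j])

    r_ident = bool(np.ptp(Z, axis=0).max() > 1e-12 * max(abs(z_best), 1.0))
    s_ident = bool(np.ptp(Z, axis=1).max() > 1e-12 * max(abs(z_best), 1.0))
    if not s_ident:
        s_best = float(np.sqrt(s_range[0] * s_range[1]))
    if not r_ident:
        r_best = float(np.sqrt(r_range[0] * r_range[1]))

    if refine and r_ident and s_ident and np.isfinite(z_best):
        from scipy import optimize as _opt
        lo = np.log(np.array([r_range[0], s_range[0]]))
        hi = np.log(np.array([r_range[1], s_range[1]]))

        def neg(x):
            x = np.clip(x, lo, hi)
            v = signal_to_crosstalk(device.with_levels(*np.exp(x)), dose)
            return -v if np.isfinite(v) else np.inf

        res = _opt.minimize(neg, np.log([r_best, s_best]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-10})
        if np.isfinite(res.fun) and -res.fun > z_best:
            xr = np.clip(res.x, lo, hi)
            r_best, s_best = map(float, np.exp(xr))
            z_best = float(-res.fun)

    rr, ss = np.meshgrid(r_grid, s_grid, indexing="ij")
    landscape = pd.DataFrame({"r": rr.ravel(), "s": ss.ravel(),
                              "ratio": Z.ravel()})
    return OptimizationResult(r_opt=r_best, s_opt=s_best, ratio_opt=z_best,
                              landscape=landscape,
                              s_identifiable=s_ident, r_identifiable=r_ident)
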