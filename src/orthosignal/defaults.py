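"""Reference parameter values used across the package.

The promoter/receiver constants below form a self-consistent default
regime for the wild-type pLux promoter and the two specificity-mutant
promoters pLux76 (LuxR-specific) and pLas81 (LasR-specific).  They were
chosen to reproduce the characteristic orders of magnitude of the system:

* LuxR binds 3OC6HSL ~1e2-fold more tightly than 3OC12HSL, while LasR
  binds 3OC12HSL ~1e6-fold more tightly than 3OC6HSL, so chemical
  crosstalk runs almost entirely through LuxR:3OC12HSL.
* pLux responds maximally at ~10 RPU under weak (pCat) receiver
  expression, with residual ~0.7 RPU genetic crosstalk through LasR.
* pLux76 keeps LuxR responsiveness (promoter affinity reduced >10-fold)
  but its LasR affinity is indistinguishable from zero; pLas81 gains
  ~10-fold LasR affinity while its LuxR affinity drops ~100-fold.

Absolute magnitudes are this package's own calibration (documented in the
methods note) and are meant as a realistic working regime, not as a
measured parameter table.
"""

from __future__ import annotations

import numpy as np

from .core_model import CrosstalkParameters, HillTransfer, fit_hill_transfer, simplified_rate

__all__ = [
    "RECEIVER_CONSTANTS",
    "PROMOTERS",
    "promoter_params",
    "OPTIMAL_DEVICE_LEVELS",
    "receiver_yfp_hill",
    "DOSE_LADDER_NM",
    "ARABINOSE_LADDER_MM",
]

# Shared receiver-side constants (1/nM for K's; r = s = 1 is pCat-level
# expression by definition).
RECEIVER_CONSTANTS = dict(
    KR6=2e-3,    # LuxR : 3OC6HSL
    KR12=2e-5,   # LuxR : 3OC12HSL  (1e2-fold weaker)
    KS6=1e-8,    # LasR : 3OC6HSL   (1e6-fold weaker than KS12)
    KS12=1e-2,   # LasR : 3OC12HSL
    n=2.0,
)

# Promoter-specific blocks: regulator-promoter association constants
# (dimensionless, absorbing the dimerization and receiver-concentration
# scales) and transcription rates in RPU.
PROMOTERS: dict[str, dict[str, float]] = {
    "pLux": dict(KGR=2.0, KGS=0.1, a0=0.05, a1R=15.0, a1S=7.0),
    "pLux76": dict(KGR=0.15, KGS=0.0, a0=0.05, a1R=15.0, a1S=1.0),
    "pLas81": dict(KGR=0.02, KGS=1.0, a0=0.05, a1R=15.0, a1S=35.0),
}

# Receiver levels of the optimized double-receiver device (pCat units).
OPTIMAL_DEVICE_LEVELS = (5.89, 2.97)


def promoter_params(promoter: str, r: float = 1.0, s: float = 1.0) -> CrosstalkParameters:
    """Reference :class:`CrosstalkParameters` for a named promoter."""
    if promoter not in PROMOTERS:
        raise KeyError(f"unknown promoter {promoter!r}; "
                       f"known: {sorted(PROMOTERS)}")
    return CrosstalkParameters(**RECEIVER_CONSTANTS, **PROMOTERS[promoter],
                               r=r, s=s)


def receiver_yfp_hill(r: float | None = None, s: float | None = None) -> HillTransfer:
    """Hill refit of the optimized receiver's YFP (pLas81) channel.

    For spatial modeling the YFP channel of the double receiver is
    represented by a four-parameter Hill curve fitted to the mechanistic
    pLas81 dose response at the device's receiver levels.
    """
    r0, s0 = OPTIMAL_DEVICE_LEVELS
    p = promoter_params("pLas81", r if r is not None else r0,
                        s if s is not None else s0)
    C = np.geomspace(1e-2, 1e6, 120)
    rho = simplified_rate(p, np.zeros_like(C), C)
    return fit_hill_transfer(C, rho)


# Liquid-culture designs: 12 doses spanning 10 nM .. 25 uM, and the
# arabinose induction ladder 0 .. 8 mM.
DOSE_LADDER_NM = tuple(np.round(np.geomspace(10.0, 25000.0, 12), 3))
ARABINOSE_LADDER_MM = (0.0, 0.05, 0.2, 0.5, 1.0, 2.0, 4.0, 8.0)
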