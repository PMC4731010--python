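"""Synthetic plate-fluorometer and grid-membrane data with known truth.

The generator emulates the two kinds of raw data the analysis consumes:

* liquid-culture plate reads: per-well multi-channel fluorescence/OD time
  series on a 10-min cadence over 1,000 min.  Cells follow a Gompertz
  capacity curve; every fluorescence channel accumulates in proportion to
  the time-integral of capacity times that channel's promoter activity
  (the reference promoter has activity 1 RPU by definition), so the true
  relative activity of a target channel is exactly the slope of target
  against reference.  Measurements carry multiplicative lognormal noise
  plus an additive Gaussian background; blank wells contain background
  only.

* grid-membrane trajectories: the deterministic lattice simulation of
  :mod:`.spatial_sim` with per-observation multiplicative noise overlaid,
  emitted in the same long CSV schema the readers consume.

Every generated dataset is reproducible from its seed, and the returned
ground-truth record contains everything needed to recompute the noiseless
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CrosstalkParameters, HillTransfer, hill_rate, simplified_rate
from .inference import AraTransfer
from .ratiometric import Condition, PlateTimeSeries
from .spatial_sim import (GompertzGrowth, GridLayout, SpatialParameters,
                          Trajectory, checkerboard_layout, gompertz_capacity,
                          sender_receiver_layout, simulate, stripe_layout)
from . import defaults as _defaults

__all__ = [
    "GenerationDesign",
    "PlateGeneration",
    "generate_plate",
    "generate_grid",
    "plate_preset",
    "grid_preset",
    "PLATE_PRESETS",
    "GRID_PRESETS",
]

#: liquid-culture growth is faster than on-membrane growth
_LIQUID_GROWTH = GompertzGrowth(K_cap=1.0, k_g=0.012, t_i=240.0)

#: fluorescence gain, a.u. per (RPU * capacity * min)
_GAIN = 40.0


@dataclass(frozen=True)
class GenerationDesign:
    """Complete specification of one synthetic plate experiment.

    ``channel_models`` maps fluorescence channel names to an activity
    model: a float (constant activity, RPU), a
    :class:`CrosstalkParameters` (evaluated at the well's doses) or a
    :class:`HillTransfer` (evaluated at the well's 3OC12HSL dose).  The
    ``reference_channel`` must be a constant-activity channel.  When
    ``ara_transfer_r``/``ara_transfer_s`` are given, the receiver levels
    of every ``CrosstalkParameters`` model are overridden per well from
    the arabinose concentration.
    """

    device: str
    channel_models: dict[str, object]
    reference_channel: str = "CFP"
    doses: tuple[tuple[str, float], ...] = ()  # (species, nM)
    arabinose_mM: tuple[float, ...] = (0.0,)
    ara_transfer_r: AraTransfer | None = None
    ara_transfer_s: AraTransfer | None = None
    replicates: int = 3
    cadence_min: float = 10.0
    horizon_min: float = 1000.0
    noise_cv: float = 0.03  # multiplicative CV per observation
    background_mean: float = 50.0  # a.u.
    background_sd: float = 2.0  # a.u.
    growth: GompertzGrowth = field(default_factory=lambda: _LIQUID_GROWTH)
    n_blanks: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0 or self.background_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.reference_channel not in self.channel_models:
            raise ValueError("reference channel missing from channel_models")
        if not isinstance(self.channel_models[self.reference_channel],
                          (int, float)):
            raise ValueError("reference channel must have constant activity")
        for sp, dose in self.doses:
            if sp not in ("3OC6HSL", "3OC12HSL"):
                raise ValueError(f"unknown HSL species {sp!r}")
            if dose < 0:
                raise ValueError("doses must be >= 0")


@dataclass(frozen=True)
class PlateGeneration:
    """Generated wells plus the ground truth used to produce them."""

    series: list[PlateTimeSeries]  # includes blanks
    truth: dict  # per-well true activity and the design's parameters
    design: GenerationDesign


def _true_activity(model, c6: float, c12: float, r: float | None,
                   s: float | None) -> float:
    if isinstance(model, (int, float)):
        return float(model)
    if isinstance(model, HillTransfer):
        return hill_rate(model, c12)
    if isinstance(model, CrosstalkParameters):
        p = model
        if r is not None or s is not None:
            p = p.with_levels(r if r is not None else p.r,
                              s if s is not None else p.s)
        return simplified_rate(p, c6, c12)
    raise TypeError(f"unsupported channel model {type(model).__name__}")


def generate_plate(design: GenerationDesign) -> PlateGeneration:
    """Generate noisy plate wells for every dose x arabinose x replicate."""
    rng = np.random.default_rng(design.seed)
    t = np.arange(0.0, design.horizon_min + 0.5 * design.cadence_min,
                  design.cadence_min)
    cap = gompertz_capacity(design.growth, t)
    # accumulated expression integral, a.u. per RPU
    integ = _GAIN * np.concatenate(
        [[0.0], np.cumsum(0.5 * (cap[1:] + cap[:-1]) * np.diff(t))])
    sigma_ln = math.sqrt(math.log(1.0 + design.noise_cv ** 2))

    def noisy(true_values):
        mult = np.exp(rng.normal(-0.5 * sigma_ln ** 2, sigma_ln,
                                 size=true_values.shape))
        bg = design.background_mean + rng.normal(
            0.0, design.background_sd, size=true_values.shape)
        return true_values * mult + bg

    doses = design.doses if design.doses else ((None, 0.0),)
    series: list[PlateTimeSeries] = []
    truth_wells = {}
    widx = 0
    for ara in design.arabinose_mM:
        r_level = (design.ara_transfer_r(ara)
                   if design.ara_transfer_r is not None else None)
        s_level = (design.ara_transfer_s(ara)
                   if design.ara_transfer_s is not None else None)
        for species, dose in doses:
            c6 = dose if species == "3OC6HSL" else 0.0
            c12 = dose if species == "3OC12HSL" else 0.0
            for rep in range(design.replicates):
                well = f"W{widx:03d}"
                widx += 1
                chans = {}
                rho_truth = {}
                for name, model in design.channel_models.items():
                    rho = _true_activity(model, c6, c12, r_level, s_level)
                    rho_truth[name] = rho
                    chans[name] = noisy(rho * integ)
                chans["OD"] = noisy(0.4 * cap * _GAIN / 40.0)
                cond = Condition(device=design.device, hsl_species=species,
                                 hsl_nM=dose, arabinose_mM=ara,
                                 replicate=rep)
                series.append(PlateTimeSeries(well=well, time_min=t,
                                              channels=chans,
                                              condition=cond))
                truth_wells[well] = dict(rho=rho_truth, c6_nM=c6, c12_nM=c12,
                                         arabinose_mM=ara,
                                         r_level=r_level, s_level=s_level)
    for b in range(design.n_blanks):
        well = f"BLK{b:02d}"
        chans = {name: noisy(np.zeros_like(t))
                 for name in design.channel_models}
        chans["OD"] = noisy(np.zeros_like(t))
        series.append(PlateTimeSeries(
            well=well, time_min=t, channels=chans,
            condition=Condition(device=design.device, replicate=b,
                                is_blank=True)))
    truth = dict(seed=design.seed, device=design.device, wells=truth_wells,
                 reference_channel=design.reference_channel)
    return PlateGeneration(series=series, truth=truth, design=design)


def generate_grid(layout: GridLayout, params: SpatialParameters,
                  noise_cv: float = 0.1, seed: int = 0,
                  horizon_min: float = 1500.0,
                  save_every_min: float = 50.0
                  ) -> tuple[pd.DataFrame, Trajectory]:
    """Noisy long-format grid trajectory plus the noiseless truth.

    Runs the deterministic lattice simulation and overlays lognormal
    multiplicative noise (CV ``noise_cv``) on every reporter/capacity
    observation; signal fields are emitted noiseless (they are not
    directly observable).  With ``noise_cv = 0`` the emitted values equal
    the simulator's bit for bit.
    """
    traj = simulate(layout, params, horizon_min,
                    save_every_min=save_every_min)
    df = traj.to_long_dataframe()
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        observed = df["channel"].isin(["capacity", "cfp", "yfp", "rfp"])
        mult = np.exp(rng.normal(-0.5 * sigma ** 2, sigma,
                                 size=int(observed.sum())))
        df.loc[observed, "value"] = df.loc[observed, "value"] * mult
    return df, traj


# ---------------------------------------------------------------------------
# Named presets emulating the study's experiment designs
# ---------------------------------------------------------------------------

def _dose_ladder(species: str, include_zero: bool = True
                 ) -> tuple[tuple[str, float], ...]:
    doses = _defaults.DOSE_LADDER_NM
    ladder = tuple((species, float(d)) for d in doses)
    if include_zero:
        ladder = ((species, 0.0),) + ladder
    return ladder


def _both_species_ladder() -> tuple[tuple[str, float], ...]:
    return _dose_ladder("3OC6HSL") + _dose_ladder("3OC12HSL",
                                                  include_zero=False)


#: default arabinose -> level truths used by induction presets
DEFAULT_ARA_TRANSFER = AraTransfer(basal_level=0.2, vmax_level=25.0,
                                   ec50_ara=1.0, hill_ara=1.5)


def _preset_fig1B(**kw):
    """Strong (pLlacO1) expression of both receivers, wild-type pLux."""
    return GenerationDesign(
        device="pR0011LL123",
        channel_models={"YFP": _defaults.promoter_params("pLux", r=25.0,
                                                         s=25.0),
                        "CFP": 1.0},
        doses=_both_species_ladder(), **kw)


def _preset_fig1C(**kw):
    """Weak (pCat) expression of both receivers, wild-type pLux."""
    return GenerationDesign(
        device="pCatLL123",
        channel_models={"YFP": _defaults.promoter_params("pLux"),
                        "CFP": 1.0},
        doses=_both_species_ladder(), **kw)


def _preset_fig1F_luxr(**kw):
    """LuxR only at pCat level (r=1, s=0), wild-type pLux."""
    return GenerationDesign(
        device="pCatR123",
        channel_models={"YFP": _defaults.promoter_params("pLux", r=1.0,
                                                         s=0.0),
                        "CFP": 1.0},
        doses=_both_species_ladder(), **kw)


def _preset_fig1F_lasr(**kw):
    """LasR only at pCat level (r=0, s=1), wild-type pLux."""
    return GenerationDesign(
        device="pCatS123",
        channel_models={"YFP": _defaults.promoter_params("pLux", r=0.0,
                                                         s=1.0),
                        "CFP": 1.0},
        doses=_both_species_ladder(), **kw)


def _preset_fig1GH(**kw):
    """Weak LasR plus arabinose-inducible LuxR on pLux."""
    return GenerationDesign(
        device="pCatS123+pBADLuxR",
        channel_models={"YFP": _defaults.promoter_params("pLux", s=1.0),
                        "CFP": 1.0},
        doses=_both_species_ladder(),
        arabinose_mM=_defaults.ARABINOSE_LADDER_MM,
        ara_transfer_r=DEFAULT_ARA_TRANSFER, **kw)


def _preset_fig3D(**kw):
    """Optimized double receiver pR33S175 referenced to chromosomal mRFP1."""
    r, s = _defaults.OPTIMAL_DEVICE_LEVELS
    return GenerationDesign(
        device="pR33S175",
        channel_models={"CFP": _defaults.promoter_params("pLux76", r=r, s=s),
                        "YFP": _defaults.promoter_params("pLas81", r=r, s=s),
                        "RFP": 1.0},
        reference_channel="RFP",
        doses=_both_species_ladder(), **kw)


PLATE_PRESETS = {
    "fig1B": _preset_fig1B,
    "fig1C": _preset_fig1C,
    "fig1F_luxR": _preset_fig1F_luxr,
    "fig1F_lasR": _preset_fig1F_lasr,
    "fig1GH": _preset_fig1GH,
    "fig3D": _preset_fig3D,
}

GRID_PRESETS = {
    "sender_receiver": lambda: sender_receiver_layout(),
    "fig5A": lambda: stripe_layout(5, 2, 8),
    "fig5B": lambda: stripe_layout(5, 2, 8, relay_a="relay_C12toC6",
                                   relay_b="receiver"),
    "fig5C": lambda: stripe_layout(5, 2, 8, relay_a="relay_C6toC12",
                                   relay_b="receiver"),
    "checkerboard_induced": lambda: checkerboard_layout(16, center=6),
    "checkerboard_uninduced": lambda: checkerboard_layout(16, center=None),
}


def plate_preset(name: str, **overrides) -> GenerationDesign:
    """Named plate design emulating one of the study's experiments."""
    if name not in PLATE_PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: "
                       f"{sorted(PLATE_PRESETS)}")
    return PLATE_PRESETS[name](**overrides)


def grid_preset(name: str) -> GridLayout:
    """Named grid-membrane layout."""
    if name not in GRID_PRESETS:
        raise KeyError(f"unknown layout {name!r}; known: "
                       f"{sorted(GRID_PRESETS)}")
    return GRID_PRESETS[name]()
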