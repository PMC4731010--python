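"""Bayesian inference of crosstalk-model parameters from dose responses.

Fitting happens in log10-parameter space with uniform (scale-free) priors
over broad ranges, using the affine-invariant ensemble sampler.  The
likelihood is Gaussian on the replicate-mean activity with a per-point
standard deviation floored at a fraction of the predicted mean, which
absorbs day-to-day variability that replicate scatter on a single plate
underestimates.

Identifiability notes: the closed-form rate depends on (KGR, r) only
through KGR * r**2, so the receiver level r is pinned to 1 for devices
whose receivers are driven by pCat -- that convention defines the unit in
which all other levels are expressed.  Promoter constants are inferred
from single-receiver devices first; receiver levels of new two-channel
devices are then inferred with the promoter constants held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import CrosstalkParameters, simplified_rate
from .ratiometric import DoseResponseDataset

__all__ = [
    "AraTransfer",
    "FitParameter",
    "ParameterModel",
    "PosteriorSample",
    "log_likelihood",
    "fit_mcmc",
    "infer_ara_transfer",
    "infer_device_levels",
    "single_receiver_plan",
    "DEFAULT_BOUNDS",
]

# default log10 prior bounds by parameter kind
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "K": (-6.0, 2.0),     # association constants, 1/nM
    "KG": (-6.0, 2.0),    # promoter association (dimensionless)
    "rate": (-3.0, 4.0),  # transcription rates, RPU
    "level": (-2.0, 2.0),  # receiver levels, pCat units
    "n": (math.log10(0.5), math.log10(4.0)),
}


@dataclass(frozen=True)
class AraTransfer:
    """Saturating map from arabinose (mM) to receiver level (pCat units).

    ``basal_level + (vmax_level - basal_level) * a**h / (ec50**h + a**h)``;
    monotone nondecreasing by construction.
    """

    vmax_level: float
    ec50_ara: float  # mM
    hill_ara: float
    basal_level: float = 0.0

    def __post_init__(self):
        if min(self.vmax_level, self.basal_level, self.hill_ara) < 0:
            raise ValueError("levels and hill must be >= 0")
        if self.ec50_ara <= 0:
            raise ValueError("ec50_ara must be > 0")
        if self.vmax_level < self.basal_level:
            raise ValueError("vmax_level must be >= basal_level")

    def __call__(self, ara_mM):
        a = np.asarray(ara_mM, dtype=float)
        x = (a / self.ec50_ara) ** self.hill_ara
        out = self.basal_level + (self.vmax_level - self.basal_level) \
            * x / (1.0 + x)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitParameter:
    """One free (or pinned) coordinate of the sampling space."""

    name: str
    low: float  # log10 lower bound
    high: float  # log10 upper bound
    fixed: float | None = None  # linear-scale value; excludes from sampling

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError(f"{self.name}: empty prior support")


@dataclass
class ParameterModel:
    """Maps a sampling vector to per-dataset crosstalk parameters.

    ``bindings[i]`` maps each :class:`CrosstalkParameters` field of
    dataset ``i`` to either the name of a :class:`FitParameter` (shared or
    free) or a numeric constant.  This is how sharing is expressed: two
    datasets bound to the same parameter name share that coordinate.
    """

    parameters: list[FitParameter]
    bindings: list[dict[str, object]]

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self._by_name = {p.name: p for p in self.parameters}
        self.free = [p for p in self.parameters if p.fixed is None]
        for b in self.bindings:
            for f, ref in b.items():
                if isinstance(ref, str) and ref not in self._by_name:
                    raise KeyError(f"binding refers to unknown parameter {ref!r}")

    @property
    def free_names(self) -> list[str]:
        return [p.name for p in self.free]

    @property
    def ndim(self) -> int:
        return len(self.free)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.low for p in self.free])
        hi = np.array([p.high for p in self.free])
        return lo, hi

    def build(self, theta: np.ndarray) -> list[CrosstalkParameters]:
        """Per-dataset parameter objects for a free log10 vector."""
        values = {p.name: p.fixed for p in self.parameters}
        for p, v in zip(self.free, theta):
            values[p.name] = 10.0 ** v
        out = []
        for b in self.bindings:
            kw = {}
            for fname, ref in b.items():
                kw[fname] = values[ref] if isinstance(ref, str) else ref
            out.append(CrosstalkParameters(**kw))
        return out


def log_likelihood(params: CrosstalkParameters, data: DoseResponseDataset,
                   sd_floor_frac: float = 0.1,
                   sd_floor_abs: float = 1e-3) -> float:
    """Gaussian log-likelihood of a dose-response dataset.

    The per-point standard deviation is ``max(sd / sqrt(n),
    sd_floor_frac * |prediction|, sd_floor_abs)``; the multiplicative
    floor absorbs between-day variability not visible in within-plate
    replicate scatter.  Non-finite model output yields ``-inf``.
    """
    pts = data.points
    pred = simplified_rate(params, pts["c6_nM"].to_numpy(),
                           pts["c12_nM"].to_numpy())
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    if not np.all(np.isfinite(pred)):
        return -np.inf
    sd = pts["rho_sd"].to_numpy(dtype=float)
    n = pts["n_reps"].to_numpy(dtype=float)
    sem = np.where(np.isfinite(sd), sd / np.sqrt(np.maximum(n, 1.0)), 0.0)
    sigma = np.maximum.reduce([sem, sd_floor_frac * np.abs(pred),
                               np.full_like(pred, sd_floor_abs)])
    resid = pts["rho_mean"].to_numpy(dtype=float) - pred
    return float(np.sum(-0.5 * (resid / sigma) ** 2
                        - 0.5 * np.log(2.0 * np.pi * sigma ** 2)))


@dataclass(frozen=True)
class PosteriorSample:
    """Flattened post-warmup MCMC draws with diagnostics."""

    draws: np.ndarray  # (n_draws, n_params), log10 scale
    names: list[str]
    log_prob: np.ndarray  # (n_draws,)
    acceptance_fraction: float
    rhat: dict[str, float]
    ess: dict[str, float]
    seed: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.log_prob)):
            raise ValueError("non-finite log-posterior values in sample")

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def median(self, name: str) -> float:
        return float(np.median(self.column(name)))

    def credible_interval(self, name: str, level: float = 0.95
                          ) -> tuple[float, float]:
        a = 50.0 * (1.0 - level)
        lo, hi = np.percentile(self.column(name), [a, 100.0 - a])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            lo, hi = self.credible_interval(name)
            rows.append((name, self.median(name), lo, hi,
                         self.rhat.get(name, np.nan),
                         self.ess.get(name, np.nan)))
        return pd.DataFrame(rows, columns=["parameter", "median_log10",
                                           "q2.5_log10", "q97.5_log10",
                                           "rhat", "ess"])

    def to_frame(self) -> pd.DataFrame:
        """Long format (draw, parameter, value) for CSV export."""
        n = self.draws.shape[0]
        return pd.DataFrame({
            "draw": np.repeat(np.arange(n), len(self.names)),
            "parameter": np.tile(self.names, n),
            "value": self.draws.ravel(),
        })


def _log_posterior(theta, model: ParameterModel,
                   datasets: list[DoseResponseDataset],
                   lo: np.ndarray, hi: np.ndarray,
                   sd_floor_frac: float) -> float:
    if np.any(theta < lo) or np.any(theta > hi):
        return -np.inf
    total = 0.0
    for p, data in zip(model.build(theta), datasets):
        total += log_likelihood(p, data, sd_floor_frac=sd_floor_frac)
    return total


_FIELDS = ("KR6", "KR12", "KS6", "KS12", "KGR", "KGS",
           "a0", "a1R", "a1S", "n", "r", "s")


class _CompiledPosterior:
    """Precomputed arrays and bindings for fast posterior evaluation.

    Produces values identical to summing :func:`log_likelihood` over the
    datasets built by ``model.build`` (asserted by the test suite), while
    avoiding per-call dataclass construction and DataFrame access.
    """

    def __init__(self, model: ParameterModel,
                 datasets: list[DoseResponseDataset],
                 sd_floor_frac: float, sd_floor_abs: float = 1e-3):
        self.lo, self.hi = model.bounds()
        self.sd_floor_frac = sd_floor_frac
        self.sd_floor_abs = sd_floor_abs
        free_index = {p.name: k for k, p in enumerate(model.free)}
        fixed = {p.name: p.fixed for p in model.parameters
                 if p.fixed is not None}
        self.data = []
        for b, ds in zip(model.bindings, datasets):
            pts = ds.points
            sd = pts["rho_sd"].to_numpy(dtype=float)
            n = pts["n_reps"].to_numpy(dtype=float)
            sem = np.where(np.isfinite(sd),
                           sd / np.sqrt(np.maximum(n, 1.0)), 0.0)
            binding = []  # per field: (theta index or -1, constant)
            for f in _FIELDS:
                ref = b[f]
                if isinstance(ref, str):
                    if ref in free_index:
                        binding.append((free_index[ref], 0.0))
                    else:
                        binding.append((-1, float(fixed[ref])))
                else:
                    binding.append((-1, float(ref)))
            self.data.append((pts["c6_nM"].to_numpy(dtype=float),
                              pts["c12_nM"].to_numpy(dtype=float),
                              pts["rho_mean"].to_numpy(dtype=float),
                              sem, binding))

    def __call__(self, theta: np.ndarray) -> float:
        if np.any(theta < self.lo) or np.any(theta > self.hi):
            return -np.inf
        vals = 10.0 ** np.asarray(theta, dtype=float)
        total = 0.0
        for c6, c12, y, sem, binding in self.data:
            (KR6, KR12, KS6, KS12, KGR, KGS, a0, a1R, a1S, n, r, s) = (
                vals[i] if i >= 0 else c for i, c in binding)
            WR = KGR * r * r * ((KR6 * c6) ** n + (KR12 * c12) ** n) \
                / (1.0 + KR6 * c6 + KR12 * c12) ** n
            WS = KGS * s * s * ((KS6 * c6) ** n + (KS12 * c12) ** n) \
                / (1.0 + KS6 * c6 + KS12 * c12) ** n
            pred = (a0 + a1R * WR + a1S * WS) / (1.0 + WR + WS)
            if not np.all(np.isfinite(pred)):
                return -np.inf
            sigma = np.maximum.reduce([
                sem, self.sd_floor_frac * np.abs(pred),
                np.full_like(pred, self.sd_floor_abs)])
            total += float(np.sum(-0.5 * ((y - pred) / sigma) ** 2
                                  - 0.5 * np.log(2.0 * np.pi * sigma ** 2)))
        return total


def _map_start(log_prob, lo, hi, rng, n_starts=12):
    """Cheap multi-start Nelder-Mead MAP search to seed the walkers."""
    from scipy import optimize
    best_x, best_f = None, np.inf

    def nll(x):
        v = log_prob(np.clip(x, lo, hi))
        return -v if np.isfinite(v) else 1e12

    starts = lo + (hi - lo) * rng.uniform(0.05, 0.95,
                                          size=(n_starts, lo.size))
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"maxiter": 300 * lo.size,
                                         "xatol": 1e-4, "fatol": 1e-6})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return np.clip(best_x, lo + 1e-6, hi - 1e-6)


def fit_mcmc(datasets: list[DoseResponseDataset], model: ParameterModel,
             n_draws: int = 5000, seed: int = 0,
             n_walkers: int | None = None, burn_frac: float = 0.5,
             min_burn_steps: int = 1000, sd_floor_frac: float = 0.1,
             optimize_init: bool = True) -> PosteriorSample:
    """Sample the posterior over the model's free log10 parameters.

    Ensemble sampling with ``4 * ndim`` walkers (minimum 16) initialized
    in a small ball around a multi-start MAP estimate.  At least
    ``burn_frac`` of each chain -- and never fewer than
    ``min_burn_steps`` steps -- is discarded as warmup; the flattened
    remainder is thinned to exactly ``n_draws`` retained draws.  Runs are
    bit-reproducible for a given seed.  A split-R-hat above 1.1 on any
    parameter is reported in the diagnostics (not fatal).
    """
    import emcee

    if len(datasets) != len(model.bindings):
        raise ValueError("one binding per dataset is required")
    lo, hi = model.bounds()
    ndim = model.ndim
    if ndim == 0:
        raise ValueError("no free parameters to sample")
    if n_walkers is None:
        n_walkers = max(4 * ndim, 16)
    rng = np.random.default_rng(seed)
    log_prob = _CompiledPosterior(model, datasets, sd_floor_frac)

    if optimize_init:
        center = _map_start(log_prob, lo, hi, rng)
    else:
        center = 0.5 * (lo + hi)
    p0 = center + 0.01 * rng.standard_normal((n_walkers, ndim))
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)

    steps_keep = int(math.ceil(n_draws / n_walkers))
    burn = max(min_burn_steps,
               int(math.ceil(steps_keep * burn_frac / (1.0 - burn_frac))))
    n_steps = burn + steps_keep
    # differential-evolution moves mix far better than plain stretch moves
    # along the curved (KG, a1) and (K, n) ridges of this posterior
    moves = [(emcee.moves.DEMove(), 0.8),
             (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob, moves=moves)
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2 ** 31 - 1)).get_state()
    sampler.run_mcmc(p0, n_steps, progress=False)

    chain = sampler.get_chain()  # (step, walker, dim)
    lp = sampler.get_log_prob()
    kept = chain[burn:]
    kept_lp = lp[burn:]

    # diagnostics on the kept portion (walker-major for arviz)
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            import arviz as az
            posterior = np.moveaxis(kept, 1, 0)  # (chain, draw, dim)
            for j, name in enumerate(model.free_names):
                rhat[name] = float(az.rhat(posterior[:, :, j]))
                ess[name] = float(az.ess(posterior[:, :, j]))
    except Exception:  # diagnostics are best-effort
        pass

    draws = kept.reshape(-1, ndim)[-n_draws:]
    log_prob = kept_lp.reshape(-1)[-n_draws:]
    return PosteriorSample(draws=draws, names=model.free_names,
                           log_prob=log_prob,
                           acceptance_fraction=float(
                               np.mean(sampler.acceptance_fraction)),
                           rhat=rhat, ess=ess, seed=seed)


# ---------------------------------------------------------------------------
# Standard sharing plans
# ---------------------------------------------------------------------------

def single_receiver_plan(datasets: list[DoseResponseDataset],
                         levels: list[tuple[float, float]],
                         promoter: str = "pLux",
                         free_n: bool = True,
                         a0: float | None = None) -> ParameterModel:
    """Fig-1-style joint fit of single-receiver devices on one promoter.

    Receiver association constants and the cooperativity ``n`` are shared
    across datasets; the promoter block (KGR, KGS, a0, a1R, a1S) is
    shared because all devices carry the same promoter.  ``levels`` gives
    the known (r, s) of each device (pCat convention: 1 for a
    pCat-driven receiver, 0 for an absent one).  ``a0`` may be pinned to
    a measured basal activity; ``free_n`` pins n at 2 when False.
    """
    K = DEFAULT_BOUNDS["K"]
    KG = DEFAULT_BOUNDS["KG"]
    rate = DEFAULT_BOUNDS["rate"]
    params = [
        FitParameter("KR6", *K), FitParameter("KR12", *K),
        FitParameter("KS6", *K), FitParameter("KS12", *K),
        FitParameter(f"KGR_{promoter}", *KG),
        FitParameter(f"KGS_{promoter}", *KG),
        FitParameter(f"a1R_{promoter}", *rate),
        FitParameter(f"a1S_{promoter}", *rate),
        FitParameter(f"a0_{promoter}", *rate,
                     fixed=a0 if a0 is not None else None),
        FitParameter("n", *DEFAULT_BOUNDS["n"],
                     fixed=None if free_n else 2.0),
    ]
    bindings = []
    for (r, s) in levels:
        bindings.append({
            "KR6": "KR6", "KR12": "KR12", "KS6": "KS6", "KS12": "KS12",
            "KGR": f"KGR_{promoter}", "KGS": f"KGS_{promoter}",
            "a0": f"a0_{promoter}", "a1R": f"a1R_{promoter}",
            "a1S": f"a1S_{promoter}", "n": "n", "r": r, "s": s,
        })
    if len(bindings) != len(datasets):
        raise ValueError("need one (r, s) pair per dataset")
    return ParameterModel(parameters=params, bindings=bindings)


def infer_device_levels(cfp_data: DoseResponseDataset,
                        yfp_data: DoseResponseDataset,
                        cfp_params: CrosstalkParameters,
                        yfp_params: CrosstalkParameters,
                        n_draws: int = 5000, seed: int = 0,
                        bounds: tuple[float, float] | None = None
                        ) -> PosteriorSample:
    """Posterior over the receiver levels (r, s) of a two-channel device.

    Promoter constants (pLux76 for the CFP channel, pLas81 for YFP) are
    held fixed at previously fitted values; both channels' dose responses
    constrain the two levels jointly.
    """
    lo, hi = bounds if bounds is not None else DEFAULT_BOUNDS["level"]
    params = [FitParameter("r", lo, hi), FitParameter("s", lo, hi)]

    def bind(p: CrosstalkParameters):
        d = p.to_dict()
        d["r"], d["s"] = "r", "s"
        return d

    model = ParameterModel(parameters=params,
                           bindings=[bind(cfp_params), bind(yfp_params)])
    return fit_mcmc([cfp_data, yfp_data], model, n_draws=n_draws, seed=seed)


def infer_ara_transfer(dataset: DoseResponseDataset,
                       base_params: CrosstalkParameters,
                       which: str = "r", n_draws: int = 800,
                       seed: int = 0, n_band: int = 200):
    """Fit the arabinose -> receiver-level transfer curve.

    For each arabinose level present in ``dataset`` the receiver level
    (``which`` in {"r", "s"}) is inferred as a one-parameter posterior
    with all other constants fixed at ``base_params``; a saturating Hill
    curve is then fitted through the per-level posteriors.  Returns
    ``(AraTransfer, levels_frame, band)`` where ``levels_frame`` has the
    per-arabinose posterior medians/intervals and ``band`` is an
    (n_band, n_ara) array of curve evaluations from bootstrap fits
    propagating the level uncertainty.
    """
    if which not in ("r", "s"):
        raise ValueError("which must be 'r' or 's'")
    from scipy import optimize as _opt

    aras = np.sort(dataset.points["arabinose_mM"].unique())
    if aras.size < 3:
        raise ValueError("need >= 3 arabinose levels spanning the response")
    rows = []
    level_draws = []
    for i, a in enumerate(aras):
        sub = dataset.points[dataset.points["arabinose_mM"] == a]
        sub_ds = DoseResponseDataset(device=dataset.device,
                                     promoter=dataset.promoter,
                                     points=sub.reset_index(drop=True))
        lo, hi = DEFAULT_BOUNDS["level"]
        model = ParameterModel(
            parameters=[FitParameter(which, lo, hi)],
            bindings=[{**base_params.to_dict(), which: which}])
        post = fit_mcmc([sub_ds], model, n_draws=n_draws,
                        seed=seed * 1000 + i, n_walkers=16)
        med = post.median(which)
        ci = post.credible_interval(which)
        rows.append((a, 10.0 ** med, 10.0 ** ci[0], 10.0 ** ci[1]))
        level_draws.append(10.0 ** post.column(which))
    levels = pd.DataFrame(rows, columns=["arabinose_mM", "level",
                                         "level_lo", "level_hi"])

    def hill(a, basal, delta, ec50, h):
        x = (a / ec50) ** h
        return basal + delta * x / (1.0 + x)

    def fit_once(y):
        p0 = [max(y[0], 1e-3), max(y[-1] - y[0], 1e-3),
              max(np.median(aras[aras > 0]), 1e-3), 1.5]
        popt, _ = _opt.curve_fit(
            hill, aras, y, p0=p0,
            bounds=([0, 0, 1e-6, 0.1], [np.inf, np.inf, 1e3, 8.0]),
            maxfev=20000)
        return popt

    popt = fit_once(levels["level"].to_numpy())
    transfer = AraTransfer(basal_level=float(popt[0]),
                           vmax_level=float(popt[0] + popt[1]),
                           ec50_ara=float(popt[2]), hill_ara=float(popt[3]))

    rng = np.random.default_rng(seed)
    band = np.empty((n_band, aras.size))
    for b in range(n_band):
        y = np.array([draws[rng.integers(draws.size)]
                      for draws in level_draws])
        try:
            pb = fit_once(y)
        except RuntimeError:
            pb = popt
        band[b] = hill(aras, *pb)
    return transfer, levels, band
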