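"""Synthetic "true" population trajectories and tax-record observations.

Two trajectory generators are provided:

* a deterministic (optionally noisy) annual consumer-resource map whose
  attractor, under the shipped default parameters, is a stable limit cycle
  with a dominant period between 50 and 100 years, trough-to-peak annual
  growth rates of roughly 0.4-3%/yr and a long-term mean population size
  proportional to environmental productivity;
* a stochastic logistic model with catastrophic crashes arriving as a
  Bernoulli process, yielding highly fluctuating populations with local
  extinction events every few hundred years.

Trajectories live on an annual calendar grid in cal BP (years before
AD 1950), stored strictly decreasing so that reading left to right moves
from the past toward the present.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DynamicsParams",
    "ProductivityRegime",
    "PopulationTrajectory",
    "TaxRecordSeries",
    "SimulationError",
    "default_params",
    "default_regime_ladder",
    "equilibrium_state",
    "simulate_forager_dynamics",
    "simulate_catastrophe_dynamics",
    "concatenate_regimes",
    "simulate_tax_records",
    "BP_OF_AD_ZERO",
]

#: cal BP of year AD 0 (present = AD 1950).
BP_OF_AD_ZERO = 1950

#: Default four-level productivity ladder (geometric, ratio 2). The ratio is
#: chosen so a regime shift every 1000 years produces a long-term productivity
#: trend of ln(2)/1000 ~ 0.07%/yr.
DEFAULT_PRODUCTIVITY_LADDER = (0.5, 1.0, 2.0, 4.0)


class SimulationError(RuntimeError):
    """Raised when a simulation leaves its valid state space."""


@dataclass(frozen=True)
class DynamicsParams:
    """Parameter set for both population simulators.

    The consumer-resource map uses ``resource_regrowth`` .. ``decline_cap``;
    the catastrophe model uses ``intrinsic_rate``, ``capacity_scale``,
    ``noise_sd`` and the ``catastrophe_*`` fields.  ``capacity_scale`` maps
    a dimensionless productivity level onto a carrying capacity.
    """

    resource_regrowth: float = 0.8
    harvest_rate: float = 0.2
    handling_time: float = 10.0
    conversion_efficiency: float = 1.0
    maintenance_rate: float = 0.025
    growth_cap: float = 0.03
    decline_cap: float = 0.10
    capacity_scale: float = 25.0
    intrinsic_rate: float = 0.03
    noise_sd: float = 0.0
    catastrophe_rate: float = 0.0
    catastrophe_severity: float = 0.6
    severity_spread: float = 0.15
    immigration: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "resource_regrowth",
            "harvest_rate",
            "handling_time",
            "conversion_efficiency",
            "maintenance_rate",
            "growth_cap",
            "decline_cap",
            "capacity_scale",
            "intrinsic_rate",
            "noise_sd",
            "catastrophe_severity",
            "severity_spread",
            "immigration",
        ):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
        if not 0.0 <= self.catastrophe_rate <= 1.0:
            raise ValueError(
                f"catastrophe_rate must be a probability in [0, 1], got {self.catastrophe_rate}"
            )
        if not 0.0 <= self.catastrophe_severity <= 1.0:
            raise ValueError(
                f"catastrophe_severity must lie in [0, 1], got {self.catastrophe_severity}"
            )
        if self.conversion_efficiency <= self.maintenance_rate * self.handling_time:
            raise ValueError(
                "conversion_efficiency must exceed maintenance_rate * handling_time "
                "for a feasible interior equilibrium"
            )

    def replace(self, **kwargs) -> "DynamicsParams":
        return dataclasses.replace(self, **kwargs)


def default_params(**overrides) -> DynamicsParams:
    """Shipped default parameterization (tuned; see scripts/tune_dynamics.py)."""
    return DynamicsParams(**overrides)


@dataclass(frozen=True)
class ProductivityRegime:
    """A span of constant environmental productivity, [start_year, end_year) in cal BP."""

    productivity_level: float
    start_year: int
    end_year: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.productivity_level <= 0:
            raise ValueError(f"productivity_level must be > 0, got {self.productivity_level}")
        if self.start_year <= self.end_year:
            raise ValueError(
                "start_year must be > end_year on a cal BP axis "
                f"(got start={self.start_year}, end={self.end_year})"
            )

    @property
    def duration(self) -> int:
        return int(self.start_year - self.end_year)


def default_regime_ladder(
    boundaries: tuple[int, ...] = (10_000, 9_000, 8_000, 7_000, 5_881),
    productivities: tuple[float, ...] = DEFAULT_PRODUCTIVITY_LADDER,
) -> list[ProductivityRegime]:
    """Default step-change productivity history: shifts at 9000, 8000 and 7000 BP."""
    if len(boundaries) != len(productivities) + 1:
        raise ValueError("need len(boundaries) == len(productivities) + 1")
    return [
        ProductivityRegime(p, int(boundaries[i]), int(boundaries[i + 1]), label=f"regime_{i}")
        for i, p in enumerate(productivities)
    ]


@dataclass
class PopulationTrajectory:
    """Annual population-size series on a strictly decreasing cal BP grid."""

    years: np.ndarray
    size: np.ndarray
    regimes: list[ProductivityRegime] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.size = np.asarray(self.size, dtype=float)
        if self.years.shape != self.size.shape:
            raise ValueError("years and size must have the same length")
        if self.years.size and not np.all(np.diff(self.years) == -1):
            raise ValueError("years must be annual and strictly decreasing (cal BP)")
        if np.any(~np.isfinite(self.size)) or np.any(self.size < 0):
            raise ValueError("population sizes must be finite and non-negative")

    def __len__(self) -> int:
        return self.years.size

    @property
    def years_ad(self) -> np.ndarray:
        return BP_OF_AD_ZERO - self.years

    def regime_ids(self) -> np.ndarray:
        """Index of the regime each year falls in (-1 if not covered)."""
        ids = np.full(self.years.size, -1, dtype=np.int64)
        for i, reg in enumerate(self.regimes):
            mask = (self.years <= reg.start_year) & (self.years > reg.end_year)
            ids[mask] = i
        return ids

    def section_means(self) -> list[float]:
        ids = self.regime_ids()
        return [float(self.size[ids == i].mean()) for i in range(len(self.regimes))]

    def restrict(self, bp_old: int, bp_young: int) -> "PopulationTrajectory":
        mask = (self.years <= bp_old) & (self.years >= bp_young)
        return PopulationTrajectory(self.years[mask], self.size[mask], self.regimes, dict(self.meta))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cal_bp": self.years, "size": self.size, "regime_id": self.regime_ids()}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationTrajectory":
        df = pd.read_csv(path)
        for col in ("cal_bp", "size"):
            if col not in df.columns:
                raise ValueError(f"trajectory CSV is missing required column {col!r}")
        return cls(df["cal_bp"].to_numpy(), df["size"].to_numpy())


@dataclass
class TaxRecordSeries:
    """Annual taxpayer counts (AD years, increasing; gap years absent)."""

    years: np.ndarray
    taxpayers: np.ndarray
    gap_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.taxpayers = np.asarray(self.taxpayers, dtype=np.int64)
        if self.years.shape != self.taxpayers.shape:
            raise ValueError("years and taxpayers must have the same length")
        if self.years.size > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.taxpayers < 0):
            raise ValueError("taxpayer counts must be non-negative")

    def __len__(self) -> int:
        return self.years.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"year_ad": self.years, "taxpayers": self.taxpayers}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TaxRecordSeries":
        df = pd.read_csv(path)
        for col in ("year_ad", "taxpayers"):
            if col not in df.columns:
                raise ValueError(f"tax-record CSV is missing required column {col!r}")
        return cls(df["year_ad"].to_numpy(), df["taxpayers"].to_numpy())


# ---------------------------------------------------------------------------
# consumer-resource map
# ---------------------------------------------------------------------------

def equilibrium_state(params: DynamicsParams, productivity_level: float = 1.0):
    """Interior fixed point (population N*, resource R*) of the noiseless map.

    The map is written in resource units scaled by carrying capacity
    K = capacity_scale * productivity_level, which makes the dynamics
    invariant under changes of K and the mean population exactly
    proportional to productivity.
    """
    a = params.harvest_rate
    h = params.handling_time
    c = params.conversion_efficiency
    m = params.maintenance_rate
    g = params.resource_regrowth
    K = params.capacity_scale * productivity_level
    x_star = m / (a * (c - m * h))
    if not 0 < x_star < 1:
        raise ValueError(
            "no feasible interior equilibrium: scaled resource equilibrium "
            f"x* = {x_star:.4g} must lie in (0, 1); adjust harvest_rate or maintenance_rate"
        )
    n_star = c * g * x_star * (1.0 - x_star) / m
    return n_star * K, x_star * K


def _step(x: float, n: float, params: DynamicsParams, eps: float) -> tuple[float, float]:
    """One annual update of the scaled consumer-resource map."""
    a = params.harvest_rate
    h = params.handling_time
    intake = a * x / (1.0 + a * h * x)
    r = params.conversion_efficiency * intake - params.maintenance_rate
    r = min(max(r, -params.decline_cap), params.growth_cap)
    n_next = n * np.exp(r + eps)
    x_next = x + params.resource_regrowth * x * (1.0 - x) - intake * n
    return max(x_next, 1e-12), n_next


def simulate_forager_dynamics(
    params: DynamicsParams,
    regime: ProductivityRegime,
    init: tuple[float, float] | None = None,
    *,
    burn_in: int = 0,
    rng: np.random.Generator | None = None,
) -> PopulationTrajectory:
    """Simulate the annual consumer-resource map over one productivity regime.

    Parameters
    ----------
    params
        Dynamics parameters; with ``noise_sd == 0`` the run is deterministic.
    regime
        Productivity regime; the trajectory covers [start_year, end_year) on
        an annual cal BP grid (``regime.duration`` points).
    init
        Initial (population, resource) in absolute units.  ``None`` starts
        slightly off the interior equilibrium so the attractor is reached
        quickly.
    burn_in
        Years simulated and discarded before the reported span.

    Raises
    ------
    SimulationError
        If the state leaves the finite range (population explosion).
    """
    if regime.duration < 10:
        raise ValueError(f"regime duration must be >= 10 years, got {regime.duration}")
    K = params.capacity_scale * regime.productivity_level
    if init is None:
        n_star_abs, x_star_abs = equilibrium_state(params, regime.productivity_level)
        n, x = 0.95 * n_star_abs / K, 1.05 * x_star_abs / K
    else:
        n0, r0 = init
        if n0 <= 0 or r0 <= 0:
            raise ValueError("initial population and resource must be > 0")
        n, x = n0 / K, r0 / K
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_years = regime.duration
    eps = (
        rng.normal(0.0, params.noise_sd, size=burn_in + n_years)
        if params.noise_sd > 0
        else np.zeros(burn_in + n_years)
    )
    out = np.empty(n_years)
    for t in range(burn_in + n_years):
        if t >= burn_in:
            out[t - burn_in] = n * K
        x, n = _step(x, n, params, eps[t])
        if not (np.isfinite(n) and np.isfinite(x)) or n * K > 1e12:
            raise SimulationError(
                "non-finite or exploding state at year "
                f"{regime.start_year - t + burn_in} cal BP; "
                "check growth_cap/resource_regrowth against harvest_rate "
                f"(params: {params})"
            )
    years = np.arange(regime.start_year, regime.end_year, -1, dtype=np.int64)
    traj = PopulationTrajectory(years, out, [regime])
    traj.meta["final_state"] = (n * K, x * K)
    return traj


def concatenate_regimes(
    segments: list[tuple[ProductivityRegime, DynamicsParams]],
    *,
    burn_in: int = 500,
    init: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> PopulationTrajectory:
    """Run contiguous productivity regimes as one long trajectory.

    At each boundary the next segment starts from the final state of the
    previous one: the carrying capacity changes stepwise while population
    and relative resource depletion are carried across.  ``burn_in`` applies
    to the first segment only.
    """
    if not segments:
        raise ValueError("need at least one (regime, params) segment")
    regimes = [reg for reg, _ in segments]
    for prev, nxt in zip(regimes, regimes[1:]):
        if prev.end_year != nxt.start_year:
            raise ValueError(
                f"regimes must be contiguous: regime ending at {prev.end_year} BP "
                f"is followed by one starting at {nxt.start_year} BP"
            )
    if rng is None:
        rng = np.random.default_rng(segments[0][1].seed)
    pieces = []
    state = init
    for i, (reg, par) in enumerate(segments):
        seg = simulate_forager_dynamics(
            par, reg, state, burn_in=burn_in if i == 0 else 0, rng=rng
        )
        n_abs, r_abs = seg.meta["final_state"]
        # carry population and relative resource depletion across the step
        # change in carrying capacity
        k_this = par.capacity_scale * reg.productivity_level
        if i + 1 < len(segments):
            reg2, par2 = segments[i + 1]
            k_next = par2.capacity_scale * reg2.productivity_level
            state = (n_abs, r_abs / k_this * k_next)
        pieces.append(seg)
    years = np.concatenate([p.years for p in pieces])
    size = np.concatenate([p.size for p in pieces])
    return PopulationTrajectory(years, size, regimes)


# ---------------------------------------------------------------------------
# stochastic catastrophe model
# ---------------------------------------------------------------------------

def simulate_catastrophe_dynamics(
    params: DynamicsParams,
    years: tuple[int, int],
    seed: int | None = None,
    *,
    productivity_level: float = 1.0,
    init: float | None = None,
) -> PopulationTrajectory:
    """Stochastic logistic growth punctuated by catastrophic crashes.

    Crashes arrive as a Bernoulli process with per-year probability
    ``params.catastrophe_rate``; each crash multiplies the population by a
    surviving fraction drawn uniformly from ``catastrophe_severity`` +/-
    ``severity_spread`` (clipped to (0, 1]).  A population below one
    individual goes locally extinct (set to 0) and is re-seeded at
    ``params.immigration`` if that is positive.

    ``years`` is (start_bp, end_bp), start > end; the trajectory covers
    [start, end) annually.  Crash years are recorded in ``meta['crash_years']``.
    """
    start, end = int(years[0]), int(years[1])
    if start - end < 1:
        raise ValueError(f"span must be at least 1 year, got [{start}, {end})")
    if params.catastrophe_rate > 0 and not 0 < params.catastrophe_rate < 1:
        raise ValueError("catastrophe_rate must lie in (0, 1) per year")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    K = params.capacity_scale * productivity_level
    n = float(init) if init is not None else 0.1 * K
    n_years = start - end
    out = np.empty(n_years)
    crash_years = []
    grid = np.arange(start, end, -1, dtype=np.int64)
    for t in range(n_years):
        out[t] = n
        if n <= 0:
            n = params.immigration
            continue
        r = params.intrinsic_rate * (1.0 - n / K)
        eps = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
        n = n * np.exp(r + eps)
        if params.catastrophe_rate > 0 and rng.random() < params.catastrophe_rate:
            lo = max(params.catastrophe_severity - params.severity_spread, 1e-6)
            hi = min(params.catastrophe_severity + params.severity_spread, 1.0)
            n *= rng.uniform(lo, hi)
            crash_years.append(int(grid[t]))
        if n < 1.0:
            n = params.immigration
        if not np.isfinite(n):
            raise SimulationError(
                f"non-finite population at year {grid[t]} cal BP (params: {params})"
            )
    traj = PopulationTrajectory(grid, out, [])
    traj.meta["crash_years"] = crash_years
    return traj


# ---------------------------------------------------------------------------
# tax-record observation model
# ---------------------------------------------------------------------------

def simulate_tax_records(
    traj: PopulationTrajectory,
    family_size: float = 5.0,
    reporting_prob: float = 1.0,
    gaps: list[tuple[int, int]] | None = None,
    seed: int | None = None,
) -> TaxRecordSeries:
    """Observe a trajectory as annual taxpayer counts.

    Each year, taxpayers ~ Binomial(round(N / family_size), reporting_prob).
    ``gaps`` is a list of (start_ad, end_ad) inclusive intervals removed from
    the record (e.g. the 1621-1637 loss in the historical ledgers).
    """
    if not 0.0 <= reporting_prob <= 1.0:
        raise ValueError(f"reporting_prob must lie in [0, 1], got {reporting_prob}")
    if family_size < 1:
        raise ValueError(f"family_size must be >= 1, got {family_size}")
    rng = np.random.default_rng(seed)
    years_ad = traj.years_ad  # already increasing: cal BP is stored decreasing
    sizes = traj.size
    trials = np.rint(sizes / family_size).astype(np.int64)
    counts = rng.binomial(trials, reporting_prob)
    keep = np.ones(years_ad.size, dtype=bool)
    gaps = list(gaps or [])
    for lo, hi in gaps:
        keep &= ~((years_ad >= lo) & (years_ad <= hi))
    return TaxRecordSeries(years_ad[keep], counts[keep], gap_intervals=gaps)
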