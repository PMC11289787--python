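"""Daily life-cycle engine: clonal division, annual sex, capacity regulation.

The demographic template is the boom-bust year of a blooming planktonic
diatom: an 11-month stationary phase at low carrying capacity (1e2 cells)
alternating with a 1-month bloom at high capacity (1e5 cells).  Cells
divide twice a day during blooms and once every 5 days during stationary
phases.  Sex is annual, programmed on the day at the middle of the bloom:
a fixed fraction of the population (``sex_rate``) pairs off, each pair is
replaced by two zygotes formed from independently recombined gametes.
Every day, after reproduction, the population is down-sampled uniformly
at random to the day's carrying capacity — a genotype-blind cull that
plays the role of neutral selection and produces the post-bloom
bottleneck.

State is an ``(N, n_loci, 2)`` numpy array of microsatellite repeat
counts (see :mod:`diatomsim.genome`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .genome import (
    MAX_REPEATS,
    MIN_REPEATS,
    ChromosomeLayout,
    make_layout,
    meiosis_gametes,
    mutate_repeats,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Calendar",
    "Population",
    "ExtinctionError",
    "current_capacity",
    "founder_population",
    "clonal_step",
    "sex_event",
    "regulate",
    "step_day",
    "run",
]


class ExtinctionError(RuntimeError):
    """Population became empty (cannot happen under default regulation)."""


@dataclass(frozen=True)
class SimulationConfig:
    """All rates, capacities and calendar constants for one run.

    Rates
    -----
    mut_rate : per-locus per-homolog mitotic mutation probability per division.
    rec_rate : per-base crossover breakpoint probability at meiosis.
    sex_rate : fraction of the population participating in the annual sex
        event (0 disables sex).

    Demography
    ----------
    K_stationary / K_bloom : carrying capacities (cells) outside / inside
        blooms; regulation samples down to these daily.
    year_len, bloom_len : days; the bloom occupies day-of-year
        ``[bloom_start, bloom_start + bloom_len)``.
    sex_day : 1-based offset of the sex day within the bloom (15 = middle
        of a 30-day bloom).
    stationary_division_period : days between clonal divisions outside
        blooms (divisions fall on absolute days divisible by it).
    bloom_divisions_per_day : successive binary fissions per bloom day.

    Schedule
    --------
    burn_in_years : unmonitored growth before sampling starts.
    sample_years : monitored years after burn-in.
    """

    mut_rate: float = 1e-3
    rec_rate: float = 1e-6
    sex_rate: float = 0.35
    K_stationary: int = 100
    K_bloom: int = 100_000
    year_len: int = 365
    bloom_len: int = 30
    bloom_start: int = 1
    sex_day: int = 15
    stationary_division_period: int = 5
    bloom_divisions_per_day: int = 2
    burn_in_years: int = 11
    sample_years: int = 5
    offspring_per_mating: int = 2
    chrom_len: int = 100_000
    n_founders: int = 100
    founder_diversity: str = "clonal"
    layout_seed: int = 0
    founder_seed: int = 1
    process_seed: int = 2

    def __post_init__(self):
        if not 0.0 <= self.sex_rate <= 1.0:
            raise ValueError("sex_rate must be in [0, 1]")
        if self.bloom_start + self.bloom_len > self.year_len:
            raise ValueError("bloom must fit within the year")
        if not self.K_bloom >= self.K_stationary >= 2:
            raise ValueError("require K_bloom >= K_stationary >= 2")
        if self.bloom_len > 0 and not 1 <= self.sex_day <= self.bloom_len:
            raise ValueError("sex_day must fall within the bloom")

    @property
    def total_days(self) -> int:
        return (self.burn_in_years + self.sample_years) * self.year_len

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Calendar:
    """Position of an absolute day index within the simulated year."""

    t: int
    cfg: SimulationConfig

    @property
    def year(self) -> int:
        return self.t // self.cfg.year_len

    @property
    def day_of_year(self) -> int:
        return self.t % self.cfg.year_len

    @property
    def is_bloom_day(self) -> bool:
        c = self.cfg
        return c.bloom_len > 0 and c.bloom_start <= self.day_of_year < c.bloom_start + c.bloom_len

    @property
    def is_sex_day(self) -> bool:
        c = self.cfg
        return self.is_bloom_day and self.day_of_year == c.bloom_start + c.sex_day - 1

    @property
    def is_division_day(self) -> bool:
        if self.is_bloom_day:
            return True
        return self.t % self.cfg.stationary_division_period == 0


@dataclass
class Population:
    """Evolving state: day index plus the (N, n_loci, 2) genotype array."""

    t: int
    members: np.ndarray

    @property
    def size(self) -> int:
        return self.members.shape[0]


def current_capacity(cal: Calendar, cfg: SimulationConfig) -> int:
    """Carrying capacity of the day: K_bloom inside blooms, else K_stationary."""
    return cfg.K_bloom if cal.is_bloom_day else cfg.K_stationary


def founder_population(cfg: SimulationConfig, n_loci: int = 5) -> np.ndarray:
    """Founder population, drawn from ``founder_seed`` only.

    Default (``founder_diversity="clonal"``): a single homozygous
    genotype, repeat counts uniform in [5, 50] per locus, copied to all
    founders — all standing diversity then builds up by mutation during
    the burn-in, so heterozygosity approaches its mutation/sex/drift
    balance from below.  ``"max"``: every repeat count of every founder
    drawn independently (maximal initial diversity; useful for pure-drift
    decay settings).  Replicates and conditions sharing ``founder_seed``
    start from the identical population.
    """
    rng = np.random.default_rng(cfg.founder_seed)
    if cfg.founder_diversity == "max":
        return rng.integers(
            MIN_REPEATS, MAX_REPEATS + 1, size=(cfg.n_founders, n_loci, 2)
        ).astype(np.int16)
    if cfg.founder_diversity == "clonal":
        one = rng.integers(MIN_REPEATS, MAX_REPEATS + 1, size=(1, n_loci, 1))
        return np.broadcast_to(one, (cfg.n_founders, n_loci, 2)).astype(np.int16).copy()
    raise ValueError("founder_diversity must be 'clonal' or 'max'")


def clonal_step(pop: Population, cfg: SimulationConfig, rng: np.random.Generator) -> Population:
    """Clonal division for one day.

    Bloom day: every cell undergoes ``bloom_divisions_per_day`` successive
    binary fissions (x4 by default, each daughter mutating independently).
    Stationary division day: one fission (x2).  Other days: no change.
    """
    cal = Calendar(pop.t, cfg)
    if not cal.is_division_day:
        return pop
    n_div = cfg.bloom_divisions_per_day if cal.is_bloom_day else 1
    members = pop.members
    for _ in range(n_div):
        members = np.repeat(members, 2, axis=0)
        mutate_repeats(members, cfg.mut_rate, rng)
    return Population(t=pop.t, members=members)


def sex_event(
    pop: Population,
    cfg: SimulationConfig,
    layout: ChromosomeLayout,
    rng: np.random.Generator,
) -> Population:
    """Annual sexual event: a fraction ``sex_rate`` of cells mate in pairs.

    ``2 * floor(sex_rate * N / 2)`` participants are drawn uniformly
    without replacement and paired at random; each pair is consumed and
    replaced by ``offspring_per_mating`` zygotes, each fusing two
    independently drawn meiotic gametes (one per parent).  With two
    offspring per mating the population size is conserved.
    """
    n = pop.size
    if cfg.sex_rate == 0.0:
        return pop
    n_part = 2 * int(cfg.sex_rate * n / 2)
    if n_part < 2:
        logger.warning("day %d: too few cells (N=%d) for a sex event; skipped", pop.t, n)
        return pop
    perm = rng.permutation(n)
    participants = perm[:n_part]
    rest = perm[n_part:]
    pairs = participants.reshape(-1, 2)
    o = cfg.offspring_per_mating
    p1 = np.repeat(pairs[:, 0], o)
    p2 = np.repeat(pairs[:, 1], o)
    g1 = meiosis_gametes(pop.members, p1, layout, cfg.rec_rate, rng)
    g2 = meiosis_gametes(pop.members, p2, layout, cfg.rec_rate, rng)
    offspring = np.stack([g1, g2], axis=-1)
    members = np.concatenate([pop.members[rest], offspring.astype(pop.members.dtype)])
    return Population(t=pop.t, members=members)


def regulate(pop: Population, cfg: SimulationConfig, rng: np.random.Generator) -> Population:
    """Down-sample uniformly (genotype-blind) to the day's carrying capacity."""
    if pop.size == 0:
        raise ExtinctionError(f"population extinct on day {pop.t}")
    k = current_capacity(Calendar(pop.t, cfg), cfg)
    if pop.size <= k:
        return pop
    keep = rng.choice(pop.size, size=k, replace=False)
    return Population(t=pop.t, members=pop.members[keep])


def step_day(
    pop: Population,
    cfg: SimulationConfig,
    layout: ChromosomeLayout,
    rng: np.random.Generator,
) -> Population:
    """One full day: clonal division, then sex (if sex day), then regulation."""
    cal = Calendar(pop.t, cfg)
    pop = clonal_step(pop, cfg, rng)
    if cal.is_sex_day and cfg.sex_rate > 0.0:
        pop = sex_event(pop, cfg, layout, rng)
    pop = regulate(pop, cfg, rng)
    logger.debug(
        "day %d (yday %d, bloom=%s, sex=%s): N=%d",
        pop.t, cal.day_of_year, cal.is_bloom_day, cal.is_sex_day, pop.size,
    )
    return Population(t=pop.t + 1, members=pop.members)


def run(
    cfg: SimulationConfig,
    sample_days: "list[int] | None" = None,
    layout: ChromosomeLayout | None = None,
) -> Iterator[tuple[int, np.ndarray]]:
    """Run a full simulation, yielding ``(day, genotype array)`` snapshots.

    The founder population (day 0) evolves for
    ``(burn_in_years + sample_years) * year_len`` days; snapshots are the
    end-of-day states on ``sample_days`` (default: every day after
    burn-in).  Fully reproducible from the config's three seeds.
    """
    if layout is None:
        layout = make_layout(cfg.layout_seed, cfg.chrom_len)
    if sample_days is None:
        sample_days = list(range(cfg.burn_in_years * cfg.year_len, cfg.total_days))
    wanted = set(sample_days)
    last = max(wanted) if wanted else -1
    rng = np.random.default_rng(cfg.process_seed)
    pop = Population(t=0, members=founder_population(cfg, layout.n_loci))
    for t in range(cfg.total_days):
        pop = step_day(pop, cfg, layout, rng)
        day = t  # snapshot reflects the end of day t
        if day in wanted:
            yield day, pop.members.copy()
        if day == last:
            return
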