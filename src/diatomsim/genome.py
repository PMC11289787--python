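"""Chromosome layout, diploid microsatellite genotypes, mutation and meiosis.

The simulated genome is a single chromosome carrying five microsatellite
loci.  A microsatellite is a 1-6 bp motif tandem-repeated between 5 and 50
times; its allelic state is the repeat count, so a haplotype is fully
described by five small integers.  Mitotic mutation follows the symmetric
single-step stepwise mutation model with reflecting bounds at [5, 50].
Meiotic crossover breakpoints form per-base with probability ``rec_rate``
anywhere on the chromosome *except* strictly inside a repeat tract: a
breakpoint never interrupts a tandem repeat, so every locus inherits from
exactly one homolog.

Population-scale state is held as a numpy integer array of shape
``(n, n_loci, 2)`` (individual, locus, homolog).  The scalar dataclasses
below are thin views over the same routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_REPEATS = 5
MAX_REPEATS = 50
MOTIF_LEN_RANGE = (1, 6)

__all__ = [
    "MIN_REPEATS",
    "MAX_REPEATS",
    "MicrosatLocus",
    "ChromosomeLayout",
    "Haplotype",
    "Individual",
    "LayoutError",
    "make_layout",
    "load_layout",
    "mutate_repeats",
    "mutate_mitotic",
    "draw_breakpoints",
    "meiosis_gamete",
    "meiosis_gametes",
    "fuse_gametes",
    "mlg_key",
    "mlg_keys",
]


class LayoutError(ValueError):
    """Raised when microsatellite loci cannot be placed on the chromosome."""


@dataclass(frozen=True)
class MicrosatLocus:
    """One microsatellite: position, motif length, and its maximal extent.

    The occupied interval is ``[start, start + motif_len * MAX_REPEATS)``
    (0-based, half-open): the exclusion zone for crossover breakpoints is
    the maximal tract, so it does not depend on any individual's genotype.
    """

    locus_id: int
    start: int
    motif_len: int

    @property
    def end(self) -> int:
        return self.start + self.motif_len * MAX_REPEATS

    def __post_init__(self):
        if not (MOTIF_LEN_RANGE[0] <= self.motif_len <= MOTIF_LEN_RANGE[1]):
            raise ValueError(f"motif_len must be in {MOTIF_LEN_RANGE}")


@dataclass(frozen=True)
class ChromosomeLayout:
    """Static chromosome map shared by every individual of an experiment."""

    chrom_len: int
    loci: tuple[MicrosatLocus, ...]
    layout_seed: int
    min_repeats: int = MIN_REPEATS
    max_repeats: int = MAX_REPEATS
    # derived arrays, filled in __post_init__
    starts: np.ndarray = field(init=False, repr=False, compare=False)
    ends: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        starts = np.array([l.start for l in self.loci], dtype=np.int64)
        ends = np.array([l.end for l in self.loci], dtype=np.int64)
        if np.any(np.diff(starts) <= 0):
            raise ValueError("loci must be sorted by start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("locus intervals overlap")
        if starts[0] < 0 or ends[-1] > self.chrom_len:
            raise ValueError("locus interval outside chromosome")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def positions_in_loci(self, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall strictly inside a locus tract."""
        pos = np.asarray(pos)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        inside = idx >= 0
        inside[inside] = pos[inside] < self.ends[idx[inside]]
        return inside

    def to_table(self) -> str:
        """Layout as a small tab-separated table (0-based half-open starts)."""
        lines = ["locus_id\tstart\tmotif_len"]
        for l in self.loci:
            lines.append(f"{l.locus_id}\t{l.start}\t{l.motif_len}")
        return "\n".join(lines) + "\n"


def make_layout(
    layout_seed: int,
    chrom_len: int = 100_000,
    n_loci: int = 5,
    max_attempts: int = 1000,
) -> ChromosomeLayout:
    """Place ``n_loci`` disjoint microsatellites on a chromosome.

    Motif lengths are drawn uniformly in 1..6 bp, start coordinates
    uniformly on the chromosome; placement is rejection-sampled until all
    maximal tracts (``motif_len * 50`` bp) are disjoint and on-chromosome.
    Deterministic given ``layout_seed``.

    Raises
    ------
    LayoutError
        If no disjoint placement is found within ``max_attempts`` full
        redraws (chromosome too short).
    """
    rng = np.random.default_rng(layout_seed)
    for _ in range(max_attempts):
        motif_lens = rng.integers(MOTIF_LEN_RANGE[0], MOTIF_LEN_RANGE[1] + 1, size=n_loci)
        extents = motif_lens * MAX_REPEATS
        if extents.sum() > chrom_len:
            continue
        starts = rng.integers(0, chrom_len - extents + 1)
        order = np.argsort(starts)
        starts, motif_lens, extents = starts[order], motif_lens[order], extents[order]
        if np.all(starts[1:] >= (starts + extents)[:-1]):
            loci = tuple(
                MicrosatLocus(locus_id=i, start=int(s), motif_len=int(m))
                for i, (s, m) in enumerate(zip(starts, motif_lens))
            )
            return ChromosomeLayout(chrom_len=chrom_len, loci=loci, layout_seed=layout_seed)
    raise LayoutError(
        f"could not place {n_loci} disjoint microsatellites on {chrom_len} bp "
        f"after {max_attempts} attempts"
    )


def load_layout(text: str, chrom_len: int, layout_seed: int = -1) -> ChromosomeLayout:
    """Parse a layout from its tab-separated table representation."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    loci = []
    for ln in lines[1:]:
        lid, start, mlen = ln.split("\t")
        loci.append(MicrosatLocus(int(lid), int(start), int(mlen)))
    return ChromosomeLayout(chrom_len=chrom_len, loci=tuple(loci), layout_seed=layout_seed)


# ---------------------------------------------------------------------------
# scalar genotype containers


@dataclass(frozen=True)
class Haplotype:
    """Repeat counts at each locus along one homolog."""

    repeats: tuple[int, ...]

    def __post_init__(self):
        if any(not (MIN_REPEATS <= r <= MAX_REPEATS) for r in self.repeats):
            raise ValueError(f"repeat counts must lie in [{MIN_REPEATS}, {MAX_REPEATS}]")


@dataclass(frozen=True)
class Individual:
    """A diploid cell: two homologous haplotypes (phase is arbitrary)."""

    hap_a: Haplotype
    hap_b: Haplotype

    def to_array(self) -> np.ndarray:
        """(n_loci, 2) repeat-count array."""
        return np.stack([self.hap_a.repeats, self.hap_b.repeats], axis=-1).astype(np.int16)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "Individual":
        arr = np.asarray(arr)
        return cls(
            Haplotype(tuple(int(x) for x in arr[:, 0])),
            Haplotype(tuple(int(x) for x in arr[:, 1])),
        )


def mlg_key(ind: Individual) -> tuple[tuple[int, int], ...]:
    """Phase-invariant multilocus genotype key: sorted allele pair per locus."""
    return tuple(
        tuple(sorted((a, b))) for a, b in zip(ind.hap_a.repeats, ind.hap_b.repeats)
    )


def mlg_keys(pop: np.ndarray) -> np.ndarray:
    """Canonical (n, n_loci*2) MLG representation of a population array.

    Allele pairs are sorted within each locus so the result is invariant to
    homolog order; rows compare equal iff the MLGs are identical.
    """
    pop = np.asarray(pop)
    return np.sort(pop, axis=2).reshape(pop.shape[0], -1)


# ---------------------------------------------------------------------------
# mutation


def mutate_repeats(repeats: np.ndarray, mut_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply one round of stepwise mitotic mutation to an array of repeat counts.

    Each slot mutates independently with probability ``mut_rate``; a
    mutation moves the count by +-1 with equal probability, reflecting at
    the bounds (a +1 at 50 yields 49, a -1 at 5 yields 6).  Operates
    in place and also returns the array.
    """
    if not 0.0 <= mut_rate <= 1.0:
        raise ValueError("mut_rate must be a probability")
    if mut_rate == 0.0 or repeats.size == 0:
        return repeats
    flat = repeats.reshape(-1)
    n_mut = rng.binomial(flat.size, mut_rate)
    if n_mut == 0:
        return repeats
    # uniform subset of Binomial(n, p) size == per-slot Bernoulli(p) process
    idx = rng.choice(flat.size, size=n_mut, replace=False)
    steps = rng.integers(0, 2, size=n_mut) * 2 - 1
    new = flat[idx] + steps
    new[new > MAX_REPEATS] = MAX_REPEATS - 1
    new[new < MIN_REPEATS] = MIN_REPEATS + 1
    flat[idx] = new
    if not np.shares_memory(flat, repeats):
        repeats[...] = flat.reshape(repeats.shape)
    return repeats


def mutate_mitotic(ind: Individual, mut_rate: float, rng: np.random.Generator) -> Individual:
    """Stepwise-mutate every (locus, homolog) slot of one cell; input unchanged."""
    arr = ind.to_array()
    mutate_repeats(arr, mut_rate, rng)
    return Individual.from_array(arr)


# ---------------------------------------------------------------------------
# recombination and meiosis


def draw_breakpoints(
    layout: ChromosomeLayout, rec_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample crossover breakpoint positions for one meiosis.

    The breakpoint count is Binomial(chrom_len, rec_rate) — per-base
    Bernoulli formation; positions are uniform on the chromosome, and any
    position strictly inside a microsatellite tract is re-drawn until it
    lands outside (a breakpoint never interrupts a repeat).  Returns a
    sorted array of unique positions.
    """
    if not 0.0 <= rec_rate <= 1.0:
        raise ValueError("rec_rate must be a probability")
    if rec_rate == 0.0:
        return np.empty(0, dtype=np.int64)
    k = rng.binomial(layout.chrom_len, rec_rate)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.integers(0, layout.chrom_len, size=k)
    inside = layout.positions_in_loci(pos)
    while inside.any():
        pos[inside] = rng.integers(0, layout.chrom_len, size=int(inside.sum()))
        inside = layout.positions_in_loci(pos)
    return np.unique(pos)


def _gamete_from_breakpoints(
    pair: np.ndarray, starts: np.ndarray, bps: np.ndarray, start_homolog: int
) -> np.ndarray:
    """Resolve locus inheritance given sorted breakpoints and a start homolog.

    Walking left to right, the source homolog flips at each breakpoint, so
    the homolog over locus i is the start homolog XOR the parity of
    breakpoints lying before the locus start (well defined: no breakpoint
    falls inside a tract).
    """
    flips = np.searchsorted(bps, starts, side="left") % 2
    src = start_homolog ^ flips
    return pair[np.arange(len(starts)), src]


def meiosis_gamete(
    ind: Individual,
    layout: ChromosomeLayout,
    rec_rate: float,
    rng: np.random.Generator,
) -> Haplotype:
    """Form one gamete haplotype by crossover between the two homologs."""
    pair = ind.to_array()  # (n_loci, 2)
    start = int(rng.integers(0, 2))
    bps = draw_breakpoints(layout, rec_rate, rng)
    rep = _gamete_from_breakpoints(pair, layout.starts, bps, start)
    return Haplotype(tuple(int(x) for x in rep))


def meiosis_gametes(
    pop: np.ndarray,
    parent_idx: np.ndarray,
    layout: ChromosomeLayout,
    rec_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized meiosis: one gamete per entry of ``parent_idx``.

    Gametes whose meiosis draws zero breakpoints (the common case at low
    ``rec_rate``) copy the chosen homolog wholesale; the rest go through
    the same breakpoint machinery as :func:`meiosis_gamete`.
    Returns an (m, n_loci) repeat-count array.
    """
    m = len(parent_idx)
    n_loci = pop.shape[1]
    start = rng.integers(0, 2, size=m)
    parent_idx = np.asarray(parent_idx)
    out = pop[parent_idx[:, None], np.arange(n_loci)[None, :], start[:, None]].copy()
    if rec_rate > 0.0:
        counts = rng.binomial(layout.chrom_len, rec_rate, size=m)
        for i in np.flatnonzero(counts):
            pos = rng.integers(0, layout.chrom_len, size=counts[i])
            inside = layout.positions_in_loci(pos)
            while inside.any():
                pos[inside] = rng.integers(0, layout.chrom_len, size=int(inside.sum()))
                inside = layout.positions_in_loci(pos)
            bps = np.unique(pos)
            out[i] = _gamete_from_breakpoints(
                pop[parent_idx[i]], layout.starts, bps, int(start[i])
            )
    return out


def fuse_gametes(g1: Haplotype, g2: Haplotype) -> Individual:
    """Zygote formation: two gametes fuse into a diploid individual."""
    return Individual(hap_a=g1, hap_b=g2)
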