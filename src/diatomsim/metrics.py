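"""Per-snapshot population-genetic indices and the binomial deviance distance.

Four indices summarise a day's genetic state:

* ``A`` — allele count: distinct repeat values summed over loci.
* ``G`` — number of distinct multilocus genotypes (MLGs), i.e. distinct
  phase-invariant combinations of allele pairs; a proxy for the number of
  clonal lineages.
* ``H`` — observed heterozygosity: the fraction of individuals carrying
  two different alleles at a locus, averaged over loci.
* ``R`` — genotypic diversity (clonal richness), ``(G - 1) / (N - 1)``.

Daily allelic composition is also coded as a presence/absence matrix over
(locus, allele) columns; dissimilarity between days is the binomial
deviance distance, which on 0/1 data reduces to ``log(2)`` times the
number of mismatched presences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import mlg_keys

__all__ = [
    "MetricsRecord",
    "allele_count",
    "mlg_count",
    "heterozygosity",
    "genotypic_diversity",
    "snapshot_metrics",
    "metrics_table",
    "presence_matrix",
    "binomial_distance",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Genetic indices of one population snapshot."""

    day: int
    N: int
    A: int
    G: int
    H: float
    R: "float | None"
    condition_id: str = ""
    replicate: int = 0


def _check_snapshot(pop: np.ndarray) -> np.ndarray:
    pop = np.asarray(pop)
    if pop.ndim != 3 or pop.shape[0] == 0:
        raise ValueError("snapshot must be a non-empty (N, n_loci, 2) array")
    return pop


def allele_count(pop: np.ndarray) -> int:
    """A: number of distinct repeat values per locus, summed over loci."""
    pop = _check_snapshot(pop)
    return int(sum(len(np.unique(pop[:, i, :])) for i in range(pop.shape[1])))


def mlg_count(pop: np.ndarray) -> int:
    """G: number of distinct multilocus genotypes (phase-invariant)."""
    pop = _check_snapshot(pop)
    return int(np.unique(mlg_keys(pop), axis=0).shape[0])


def heterozygosity(pop: np.ndarray) -> float:
    """H: fraction of heterozygous individuals per locus, averaged over loci."""
    pop = _check_snapshot(pop)
    return float(np.mean(pop[:, :, 0] != pop[:, :, 1]))


def genotypic_diversity(G: int, N: int) -> "float | None":
    """R = (G - 1)/(N - 1); undefined (None) for N < 2."""
    if N < 2:
        return None
    return (G - 1) / (N - 1)


def snapshot_metrics(
    pop: np.ndarray, day: int = 0, condition_id: str = "", replicate: int = 0
) -> MetricsRecord:
    """All four indices of one snapshot."""
    pop = _check_snapshot(pop)
    n = pop.shape[0]
    g = mlg_count(pop)
    return MetricsRecord(
        day=day,
        N=n,
        A=allele_count(pop),
        G=g,
        H=heterozygosity(pop),
        R=genotypic_diversity(g, n),
        condition_id=condition_id,
        replicate=replicate,
    )


def metrics_table(records: "list[MetricsRecord]") -> pd.DataFrame:
    """Tidy table (day, condition_id, replicate, N, A, G, H, R)."""
    return pd.DataFrame(
        [
            {
                "day": r.day,
                "condition_id": r.condition_id,
                "replicate": r.replicate,
                "N": r.N,
                "A": r.A,
                "G": r.G,
                "H": r.H,
                "R": np.nan if r.R is None else r.R,
            }
            for r in records
        ]
    )


def presence_matrix(snapshots: "dict[int, np.ndarray]") -> pd.DataFrame:
    """Days x (locus, allele) presence/absence matrix.

    Rows are sampling days, columns are ``locus:allele`` labels over the
    union of alleles observed on any day; cells are 0/1.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    rows = {}
    for day, pop in snapshots.items():
        pop = _check_snapshot(pop)
        present = set()
        for i in range(pop.shape[1]):
            for a in np.unique(pop[:, i, :]):
                present.add(f"{i}:{int(a)}")
        rows[day] = present
    cols = sorted(
        {c for s in rows.values() for c in s},
        key=lambda c: (int(c.split(":")[0]), int(c.split(":")[1])),
    )
    mat = pd.DataFrame(
        [[1 if c in rows[d] else 0 for c in cols] for d in rows],
        index=list(rows),
        columns=cols,
        dtype=np.int64,
    )
    mat.index.name = "day"
    return mat


def binomial_distance(m: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Binomial deviance dissimilarity between all pairs of rows.

    For rows x, y over columns c, with n_c = x_c + y_c:

        d(x, y) = sum_c [x_c log(x_c/n_c) + y_c log(y_c/n_c) + n_c log 2] / n_c

    with the conventions 0*log 0 = 0 and a zero contribution for columns
    where n_c = 0.  Symmetric with a zero diagonal; on 0/1 data equals
    log(2) times the number of mismatched cells.
    """
    if isinstance(m, pd.DataFrame):
        index = m.index
        x = m.to_numpy(dtype=float)
    else:
        x = np.asarray(m, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if x.shape[0] < 2:
        raise ValueError("need at least two rows")

    def xlogx(v):
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log(v[nz])
        return out

    n_rows = x.shape[0]
    d = np.zeros((n_rows, n_rows))
    lx = xlogx(x)
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            n = x[i] + x[j]
            pos = n > 0
            ln = np.log(n[pos])
            num = (
                lx[i][pos] - x[i][pos] * ln
                + lx[j][pos] - x[j][pos] * ln
                + n[pos] * np.log(2.0)
            )
            d[i, j] = d[j, i] = float(np.sum(num / n[pos]))
    return pd.DataFrame(d, index=index, columns=index)
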