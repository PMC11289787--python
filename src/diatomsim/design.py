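"""Condition grid, sampling schedules and replicate-run orchestration.

The study design crosses three mutation rates (1e-4, 1e-3, 1e-2), four
recombination regimes (1e-8, 1e-6, 1e-4, 1e-2) and three sex rates
(20%, 35%, 50%) for 36 sexual conditions, plus one obligately clonal
control per mutation rate: 39 conditions, six replicate runs each, all
replicates of all conditions starting from the same founder population.

Two sampling cadences are supported: *standard* (every 60 days outside
blooms, every 7 days inside) and *high* (every 10 days outside, daily
inside).  The dedicated high-resolution set runs sex_rate=0.35,
rec_rate=1e-6 at all three mutation rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lifecycle import SimulationConfig, run
from .genome import make_layout
from .metrics import metrics_table, snapshot_metrics

MUT_RATES = (1e-4, 1e-3, 1e-2)
REC_RATES = (1e-8, 1e-6, 1e-4, 1e-2)
SEX_RATES = (0.2, 0.35, 0.5)

__all__ = [
    "MUT_RATES",
    "REC_RATES",
    "SEX_RATES",
    "Condition",
    "SamplingSchedule",
    "build_grid",
    "high_resolution_conditions",
    "sampling_days",
    "desk_profile",
    "run_experiment",
]


@dataclass(frozen=True)
class Condition:
    """One point of the parameter grid."""

    condition_id: str
    mut_rate: float
    rec_rate: float
    sex_rate: float

    @property
    def is_asexual_control(self) -> bool:
        return self.sex_rate == 0.0


def _cid(mut: float, rec: float, sex: float) -> str:
    if sex == 0.0:
        return f"m{mut:.0e}_asex"
    return f"m{mut:.0e}_r{rec:.0e}_s{sex:g}"


def build_grid() -> "list[Condition]":
    """The full 36 + 3 = 39 condition grid, deterministically ordered.

    36 sexual conditions (3 mutation x 4 recombination x 3 sex rates) plus
    one obligately clonal control (sex_rate = 0, recombination moot) per
    mutation rate.
    """
    grid = [
        Condition(_cid(m, r, s), m, r, s)
        for m in MUT_RATES
        for r in REC_RATES
        for s in SEX_RATES
    ]
    grid += [Condition(_cid(m, 0.0, 0.0), m, 0.0, 0.0) for m in MUT_RATES]
    return grid


def high_resolution_conditions() -> "list[Condition]":
    """The dedicated high-resolution set: sex 35%, rec 1e-6, each mut rate."""
    return [Condition(_cid(m, 1e-6, 0.35), m, 1e-6, 0.35) for m in MUT_RATES]


@dataclass(frozen=True)
class SamplingSchedule:
    """Sorted absolute sampling days within the monitored years."""

    resolution: str
    days: tuple[int, ...]


def sampling_days(resolution: str, cfg: SimulationConfig) -> SamplingSchedule:
    """Build the sampling-day list for one run.

    ``standard``: every 60 days outside blooms, every 7 days inside
    (stepping from the first bloom day).  ``high``: every 10 days outside,
    daily inside.  Both include, for each monitored year, the last
    pre-bloom day, the sex day and its neighbours, and the first
    post-bloom day.  All days lie after the burn-in.
    """
    if resolution not in ("standard", "high"):
        raise ValueError("resolution must be 'standard' or 'high'")
    outside_step = 60 if resolution == "standard" else 10
    inside_step = 7 if resolution == "standard" else 1
    t0 = cfg.burn_in_years * cfg.year_len
    days: set[int] = set()
    for year in range(cfg.burn_in_years, cfg.burn_in_years + cfg.sample_years):
        y0 = year * cfg.year_len
        b0 = y0 + cfg.bloom_start
        b1 = b0 + cfg.bloom_len  # first post-bloom day
        # within-bloom cadence, stepping from the first bloom day
        days.update(range(b0, b1, inside_step))
        # outside-bloom cadence over the rest of the year
        for d in range(y0, y0 + cfg.year_len, outside_step):
            if not (b0 <= d < b1):
                days.add(d)
        # anchor days: last pre-bloom, sex day +-1, first post-bloom
        sex_abs = b0 + cfg.sex_day - 1
        days.update({b0 - 1, sex_abs - 1, sex_abs, sex_abs + 1, b1})
    days = {d for d in days if t0 <= d < cfg.total_days}
    return SamplingSchedule(resolution=resolution, days=tuple(sorted(days)))


def desk_profile(**overrides) -> SimulationConfig:
    """Reduced-scale profile for interactive work and testing.

    Same structure as the full study but with K_bloom = 1e4 and a 2-year
    burn-in plus 2 monitored years, which keeps a full condition run in
    the seconds range on one core.
    """
    base = dict(K_bloom=10_000, burn_in_years=2, sample_years=2)
    base.update(overrides)
    return SimulationConfig(**base)


def run_experiment(
    grid: "list[Condition]",
    replicates: int = 6,
    resolution: str = "standard",
    base_cfg: SimulationConfig | None = None,
    master_seed: int = 0,
    outdir: "Path | str | None" = None,
    save_snapshots: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every condition x replicate and collect the tidy metrics table.

    All runs share one chromosome layout (seeded from ``master_seed``) and
    one founder population; process randomness is an independent stream
    per (condition, replicate).  Returns ``(metrics, manifest)``; a failed
    cell is flagged in the manifest without aborting the grid.
    """
    if base_cfg is None:
        base_cfg = SimulationConfig()
    root = np.random.SeedSequence(master_seed)
    layout_seed, founder_seed = (int(s) for s in root.generate_state(2) >> 1)
    layout = make_layout(layout_seed, base_cfg.chrom_len)
    schedule = sampling_days(resolution, base_cfg)
    records = []
    manifest_rows = []
    outdir = Path(outdir) if outdir is not None else None
    for ci, cond in enumerate(grid):
        for rep in range(replicates):
            proc = int(np.random.SeedSequence(master_seed, spawn_key=(ci, rep)).generate_state(1)[0] >> 1)
            status = "ok"
            try:
                cfg = base_cfg.with_(
                    mut_rate=cond.mut_rate,
                    rec_rate=cond.rec_rate,
                    sex_rate=cond.sex_rate,
                    layout_seed=layout_seed,
                    founder_seed=founder_seed,
                    process_seed=proc,
                )
                for day, snap in run(cfg, sample_days=list(schedule.days), layout=layout):
                    records.append(
                        snapshot_metrics(snap, day=day, condition_id=cond.condition_id, replicate=rep)
                    )
                    if save_snapshots and outdir is not None:
                        _dump_snapshot(outdir, cond.condition_id, rep, day, snap)
            except Exception as exc:  # noqa: BLE001 — per-cell isolation
                status = f"failed: {exc}"
            manifest_rows.append(
                {
                    "condition_id": cond.condition_id,
                    "replicate": rep,
                    "mut_rate": cond.mut_rate,
                    "rec_rate": cond.rec_rate,
                    "sex_rate": cond.sex_rate,
                    "process_seed": proc,
                    "status": status,
                }
            )
    metrics = metrics_table(records)
    manifest = pd.DataFrame(manifest_rows)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(outdir / "metrics.csv", index=False)
        manifest.to_csv(outdir / "manifest.csv", index=False)
        (outdir / "layout.tsv").write_text(layout.to_table())
        (outdir / "run_manifest.json").write_text(
            json.dumps(
                {
                    "master_seed": master_seed,
                    "layout_seed": layout_seed,
                    "founder_seed": founder_seed,
                    "resolution": resolution,
                    "replicates": replicates,
                    "n_conditions": len(grid),
                },
                indent=2,
            )
        )
    return metrics, manifest


def _dump_snapshot(outdir: Path, cid: str, rep: int, day: int, snap: np.ndarray) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    n, n_loci, _ = snap.shape
    cols = {}
    for i in range(n_loci):
        cols[f"locus_{i}_a"] = snap[:, i, 0]
        cols[f"locus_{i}_b"] = snap[:, i, 1]
    df = pd.DataFrame(cols)
    df.insert(0, "day", day)
    df.insert(1, "condition_id", cid)
    df.insert(2, "replicate", rep)
    df.to_csv(outdir / f"snapshot_{cid}_rep{rep}_day{day}.csv", index=False)
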