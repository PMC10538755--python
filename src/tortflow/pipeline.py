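"""Experiment orchestration: scenario x density runs and result tables.

Builds the surface and founder panel for an experiment specification, runs
replicated simulations, computes the genetic summary battery on sampled
generations, and writes result tables (per-generation time series and a
final-generation summary with population and subpopulation rows) plus
optional time-series plots of Ho and FST.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import founders as fnd
from . import popgen
from . import simulate as sim
from .landscape import build_scenario_surface


@dataclass
class ExperimentSpec:
    scenario: str = "no_barrier"
    density: str = "moderate"
    n_culverts: int = 3
    master_seed: int = 0
    founder_he: float = 0.81
    founder_ar: float = 13.0
    config: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    stat_generations: tuple = ()  # generations to compute stats at ((): all snapshots)
    subsample_n: int = popgen.DEFAULT_SAMPLE_SIZE
    out_dir: str | None = None


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    replicates: list
    summary: pd.DataFrame  # per (generation, replicate) stats
    timeseries: pd.DataFrame  # cross-replicate means/SDs per generation

    def final_census(self) -> np.ndarray:
        return np.array([r.census[-1] for r in self.replicates])


def _experiment_seeds(spec: ExperimentSpec):
    ss = np.random.SeedSequence(spec.master_seed)
    return ss.spawn(3)  # founders, replicates, subsampling


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Run one scenario x density experiment end to end."""
    if spec.config.n_replicates < 1:
        raise ValueError("need at least one replicate")
    founder_seed, rep_seed, sub_seed = _experiment_seeds(spec)
    surface = build_scenario_surface(
        spec.scenario, n_culverts=spec.n_culverts, density=spec.density
    )
    freqs = fnd.generate_frequencies(
        target_He=spec.founder_he, target_Ar=spec.founder_ar, seed=founder_seed
    )
    need = int(np.minimum(surface.carrying,
                          sim.SEED_COUNT.get(spec.density, surface.carrying)).sum()) \
        if spec.density != "variable" else surface.total_capacity
    panel = fnd.sample_founders(freqs, n=need, seed=founder_seed.spawn(1)[0])

    snapshot_gens = set(spec.stat_generations) or None
    reps = []
    for rep, child in enumerate(rep_seed.spawn(spec.config.n_replicates)):
        reps.append(
            sim.run_replicate(
                surface, spec.density, panel, spec.config, child,
                replicate=rep, snapshot_generations=snapshot_gens,
            )
        )

    sub_rng = np.random.default_rng(sub_seed)
    records = []
    for rep in reps:
        for gen in sorted(rep.snapshots):
            state = rep.snapshots[gen]
            rec = compute_snapshot_stats(
                state, surface, n=spec.subsample_n,
                seed=int(sub_rng.integers(2**31)),
            )
            rec.update(generation=gen, replicate=rep.replicate, n_total=state.n)
            records.append(rec)
    summary = pd.DataFrame(records)
    timeseries = aggregate_timeseries(summary, reps)

    if spec.out_dir:
        _write_outputs(spec, surface, reps, summary, timeseries)
    return ExperimentResult(spec=spec, replicates=reps, summary=summary,
                            timeseries=timeseries)


def compute_snapshot_stats(state, surface, n=popgen.DEFAULT_SAMPLE_SIZE,
                           seed=None) -> dict:
    """Diversity, FST, and Ne on one genotype snapshot (n=750 subsample)."""
    sample = popgen.subsample(state, n=n, seed=seed, surface=surface)
    div = popgen.diversity(sample)
    rec = {
        "n_sample": sample.n,
        "ho": div.ho, "ho_sd": div.ho_sd,
        "he": div.he, "he_sd": div.he_sd,
        "ar": div.ar, "ar_sd": div.ar_sd,
    }
    sides, counts = np.unique(sample.groups, return_counts=True)
    if len(sides) == 2 and counts.min() >= 2:
        rec["fst"] = popgen.pairwise_fst(sample)
    else:
        rec["fst"] = np.nan
    try:
        ne = popgen.ld_ne(sample)
        rec.update(ne=ne.point, ne_lo=ne.ci_low, ne_hi=ne.ci_high)
    except ValueError:
        rec.update(ne=np.nan, ne_lo=np.nan, ne_hi=np.nan)
    return rec


def aggregate_timeseries(summary: pd.DataFrame, reps) -> pd.DataFrame:
    """Cross-replicate means and SDs per generation."""
    census = pd.DataFrame(
        {
            "generation": np.tile(np.arange(len(reps[0].census)), len(reps)),
            "replicate": np.repeat([r.replicate for r in reps],
                                   len(reps[0].census)),
            "census": np.concatenate([r.census for r in reps]),
        }
    )
    agg = census.groupby("generation")["census"].agg(["mean", "std"])
    agg.columns = ["census_mean", "census_sd"]
    if len(summary):
        finite = summary.replace([np.inf, -np.inf], np.nan)
        stat = finite.groupby("generation")[["ho", "he", "ar", "fst", "ne"]].agg(
            ["mean", "std"]
        )
        stat.columns = ["_".join(c) for c in stat.columns]
        agg = agg.join(stat, how="left")
    return agg.reset_index()


def select_representative_snapshot(fst_by_replicate: dict) -> int:
    """Replicate whose FST is nearest the cross-replicate mean (ties: lowest id)."""
    if not fst_by_replicate:
        raise ValueError("no snapshots")
    ids = sorted(fst_by_replicate)
    values = np.array([fst_by_replicate[i] for i in ids], dtype=float)
    diffs = np.abs(values - values.mean())
    tied = diffs <= diffs.min() + 1e-12
    return ids[int(np.nonzero(tied)[0][0])]


def convergence_check(state, surface, sizes=None, seed=None) -> pd.DataFrame:
    """FST versus subsample size; flags where successive changes fall <10%.

    Reproduces the sampling-design check that fixed the working subsample at
    n = 750.
    """
    sizes = list(sizes) if sizes is not None else list(range(100, 1201, 100))
    if state.n < max(sizes):
        raise ValueError("snapshot smaller than the largest requested size")
    rng = np.random.default_rng(seed)
    rows = []
    for n in sizes:
        sample = popgen.subsample(state, n=n, seed=int(rng.integers(2**31)),
                                  surface=surface)
        try:
            fst = popgen.pairwise_fst(sample)
        except ValueError:
            fst = np.nan
        rows.append({"n": n, "fst": fst})
    df = pd.DataFrame(rows)
    flagged = sizes[-1]
    vals = df["fst"].to_numpy()
    for i in range(1, len(vals)):
        denom = abs(vals[i - 1])
        rel = abs(vals[i] - vals[i - 1]) / denom if denom > 0 else 0.0
        if np.all(
            [
                abs(vals[j] - vals[j - 1]) / abs(vals[j - 1]) < 0.10
                if abs(vals[j - 1]) > 0 else True
                for j in range(i, len(vals))
            ]
        ):
            flagged = sizes[i - 1]
            break
    df.attrs["converged_at"] = flagged
    return df


def _write_outputs(spec, surface, reps, summary, timeseries) -> None:
    from . import io as tio

    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "summary.csv", index=False)
    timeseries.to_csv(out / "fst_timeseries.csv", index=False)
    _table5_style(summary, reps).to_csv(out / "table5_style.csv", index=False)
    for rep in reps:
        for gen, state in rep.snapshots.items():
            tio.write_genepop(
                out / f"snapshot_r{rep.replicate}_g{gen}.gen",
                state.genotypes, groups=surface.side_of(state.col),
                locus_ids=[loc.locus_id for loc in state.loci],
            )
    with open(out / "spec.txt", "w") as fh:
        fh.write(repr(dataclasses.asdict(spec)))


def _table5_style(summary: pd.DataFrame, reps) -> pd.DataFrame:
    """Final-generation population-level summary row per replicate."""
    last = summary[summary["generation"] == summary["generation"].max()]
    rows = [{
        "level": "pop",
        "N_mean": np.mean([r.census[-1] for r in reps]),
        "N_sd": np.std([r.census[-1] for r in reps], ddof=1)
        if len(reps) > 1 else 0.0,
        "ne": last["ne"].mean(), "ar": last["ar"].mean(),
        "ho": last["ho"].mean(), "he": last["he"].mean(),
        "fst": last["fst"].mean(),
    }]
    return pd.DataFrame(rows)


def plot_timeseries(timeseries: pd.DataFrame, path, years_per_generation=17):
    """Time-series plot of Ho and FST (generation axis labeled in years)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    g = timeseries["generation"]
    if "ho_mean" in timeseries:
        axes[0].plot(g, timeseries["ho_mean"], marker="o", ms=3)
    axes[0].set_ylabel("$H_o$")
    if "fst_mean" in timeseries:
        axes[1].plot(g, timeseries["fst_mean"], marker="o", ms=3)
    axes[1].set_ylabel("$F_{ST}$")
    axes[1].set_xlabel(f"generation (~{years_per_generation} yr each)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
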