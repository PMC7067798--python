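"""Synthetic observation-layer data with known ground truth.

The live-imaging tables of the original study are not publicly deposited,
so every input the estimation pipeline consumes is generated here from
known parameters: per-object track tables (births, deaths, censoring),
per-time-instance count snapshots, and bulbous-tip count distributions.
Each generator is seed-deterministic and emits a
:class:`GroundTruthManifest` sufficient to regenerate its output.

Defaults mirror the study design: 60-min imaging windows at P60, 8
terminals per genotype for the live data, 40 terminals per stage for the
fixed-timepoint counts, and a 1-min snapshot cadence (the live cadence of
the source movies is not stated; it is a parameter, never hard-coded).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bulbs import build_generator
from .developmental import simulate_developmental, snapshot_counts
from .params import DevParams, MINUTES_PER_PERCENT

__all__ = [
    "GroundTruthManifest",
    "gen_track_table",
    "gen_bulb_observations",
    "gen_fixed_timepoints",
]


@dataclass(frozen=True)
class GroundTruthManifest:
    """Provenance of one synthetic dataset: parameters, sizes, seed."""

    scheme: str
    seed: int
    ground_truth: dict
    sample_sizes: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def gen_track_table(
    lambda_sF: float = 7.0,
    lambda_lF: float = 5.0,
    c2_sF: float = 0.5,
    c2_lF: float = 1.0 / 30.0,
    duration: float = 60.0,
    n_terminals: int = 8,
    snapshot_dt: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Stationary immigration-death filopodium tracks plus count snapshots.

    Each filopodium class is an independent immigration-death process:
    births Poisson in time at rate lambda * c2, lifetimes exponential at
    rate c2, initialized at stationarity (Poisson(lambda) objects alive at
    the window start; by memorylessness their remaining lifetimes are
    exponential, so they are emitted with birth at the window start).
    Objects alive when the window closes are emitted with an empty death
    time (censored).  Snapshot counts are taken on the ``snapshot_dt``
    grid, pooled over terminals.
    """
    if duration < snapshot_dt:
        raise ValueError("duration must be at least snapshot_dt")
    if min(lambda_sF, lambda_lF) < 0 or min(c2_sF, c2_lF) <= 0:
        raise ValueError("need lambdas >= 0 and retraction rates > 0")
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, duration + 1e-9, snapshot_dt)

    rows = []
    snap_frames = []
    for term in range(n_terminals):
        counts = {"sF": np.zeros(len(grid), dtype=int),
                  "lF": np.zeros(len(grid), dtype=int)}
        for cls, lam, c2 in (("sF", lambda_sF, c2_sF), ("lF", lambda_lF, c2_lF)):
            births = [0.0] * rng.poisson(lam)  # alive at window start
            n_new = rng.poisson(lam * c2 * duration)
            births += sorted(rng.uniform(0.0, duration, n_new))
            for k, b in enumerate(births):
                life = rng.exponential(1.0 / c2)
                d = b + life
                censored = d > duration
                rows.append(
                    {
                        "object_id": f"T{term}-{cls}{k}",
                        "class": "filopodium",
                        "t_birth_min": b,
                        "t_death_min": np.nan if censored else d,
                    }
                )
                end = duration if censored else d
                counts[cls] += (grid >= b) & (grid < end)
        snap_frames.append(
            pd.DataFrame({"t_min": grid, "sF": counts["sF"], "lF": counts["lF"]})
        )

    tracks = pd.DataFrame(rows, columns=["object_id", "class", "t_birth_min", "t_death_min"])
    snapshots = pd.concat(snap_frames, ignore_index=True)
    manifest = GroundTruthManifest(
        scheme="immigration-death-tracks",
        seed=seed,
        ground_truth={"lambda_sF": lambda_sF, "lambda_lF": lambda_lF,
                      "c2_sF": c2_sF, "c2_lF": c2_lF},
        sample_sizes={"n_terminals": n_terminals, "duration_min": duration,
                      "snapshot_dt_min": snapshot_dt, "n_tracks": len(tracks)},
    )
    return tracks, snapshots, manifest


def gen_bulb_observations(
    r3: float,
    c4: float,
    c5: float,
    c6: float,
    B50: float,
    N: int = 15,
    total_time: float = 50_000.0,
    sample_dt: float = 5.0,
    relaxation: float | None = None,
    seed: int = 0,
    f1_mode: str = "inhibition",
    generator_mode: str = "reaction_consistent",
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Empirical bulb-count marginals from an exact 2-D CTMC simulation.

    Simulates the same truncated (sB, synB) chain whose generator
    :func:`filokin.bulbs.build_generator` assembles (Gillespie on the
    lattice, reflecting at N), samples the state on a ``sample_dt`` grid
    after discarding a relaxation prefix (default: 10% of ``total_time``),
    and histograms the two marginals.  Returns (sB table, synB table,
    manifest); each table has columns ``count`` and ``frequency``.
    """
    import warnings

    gen = build_generator(r3, c4, c5, c6, B50, N=N,
                          f1_mode=f1_mode, generator_mode=generator_mode)
    G = gen.matrix
    rng = np.random.default_rng(seed)
    if relaxation is None:
        relaxation = 0.1 * total_time

    n_states = gen.n_states
    rates = G.copy()
    np.fill_diagonal(rates, 0.0)
    exits = rates.sum(axis=1)

    state = 0  # start empty: (0, 0)
    t = 0.0
    grid = np.arange(relaxation, total_time, sample_dt)
    if len(grid) < 100:
        warnings.warn(
            f"only {len(grid)} post-relaxation samples; distributions will be noisy"
        )
    samples = np.empty(len(grid), dtype=np.int64)
    g = 0
    while g < len(grid):
        rate = exits[state]
        t_next = t + (rng.exponential(1.0 / rate) if rate > 0 else np.inf)
        while g < len(grid) and grid[g] < t_next:
            samples[g] = state
            g += 1
        if t_next == np.inf:
            break
        t = t_next
        p = rates[state] / rate
        state = rng.choice(n_states, p=p)

    i = samples // (N + 1)
    j = samples % (N + 1)
    p_sB = np.bincount(i, minlength=N + 1) / len(samples)
    p_synB = np.bincount(j, minlength=N + 1) / len(samples)
    counts = np.arange(N + 1)
    tab_sB = pd.DataFrame({"count": counts, "frequency": p_sB})
    tab_synB = pd.DataFrame({"count": counts, "frequency": p_synB})
    manifest = GroundTruthManifest(
        scheme="bulb-ctmc-stationary-sampling",
        seed=seed,
        ground_truth={"r3": r3, "c4": c4, "c5": c5, "c6": c6, "B50": B50,
                      "N": N, "f1_mode": f1_mode, "generator_mode": generator_mode},
        sample_sizes={"total_time": total_time, "sample_dt": sample_dt,
                      "relaxation": relaxation, "n_samples": int(len(samples))},
    )
    return tab_sB, tab_synB, manifest


def gen_fixed_timepoints(
    params: DevParams,
    stages=(40, 50, 60, 70, 80, 90),
    terminals_per_stage: int = 40,
    seed: int = 0,
    scheme: str = "thinning",
) -> tuple[pd.DataFrame, GroundTruthManifest]:
    """Per-stage census emulating fixed-preparation counts.

    Runs the developmental model for ``terminals_per_stage`` independent
    terminals out to the last requested pupal stage and reads the state at
    every stage, then aggregates per-stage means and SEMs of filopodia
    (sF + lF), bulbous tips (sB + synB) and synapses.
    """
    stages = sorted(stages)
    if stages[0] < 40 or stages[-1] > 100:
        raise ValueError("stages must lie within P40..P100")
    t_stages = [(s - 40) * MINUTES_PER_PERCENT for s in stages]
    t_end = max(t_stages[-1], 1e-6)

    per_stage = {s: {"filopodia": [], "bulbs": [], "synapses": []} for s in stages}
    rng = np.random.default_rng(seed)
    for _ in range(terminals_per_stage):
        traj = simulate_developmental(
            params, 0.0, t_end, seed=int(rng.integers(2**31 - 1)), scheme=scheme
        )
        snaps = snapshot_counts(traj, t_stages)
        for s, row in zip(stages, snaps):
            per_stage[s]["filopodia"].append(row[0] + row[1])
            per_stage[s]["bulbs"].append(row[2] + row[3])
            per_stage[s]["synapses"].append(row[4])

    records = []
    for s in stages:
        rec = {"stage": s, "t_min": (s - 40) * MINUTES_PER_PERCENT}
        for key, vals in per_stage[s].items():
            arr = np.array(vals, dtype=float)
            rec[f"mean_{key}"] = arr.mean()
            rec[f"sem_{key}"] = arr.std(ddof=1) / np.sqrt(len(arr)) if len(arr) > 1 else np.nan
        records.append(rec)
    table = pd.DataFrame(records)
    manifest = GroundTruthManifest(
        scheme=f"developmental-fixed-timepoints/{scheme}",
        seed=seed,
        ground_truth=params.to_dict(),
        sample_sizes={"terminals_per_stage": terminals_per_stage,
                      "stages": list(stages)},
    )
    return table, manifest
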