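"""Winner-takes-all seed-pool model of bulbous-tip stabilization.

Filopodia compete for a conserved pool of synaptic seeding factors
(Syd-1 / Liprin-alpha scaffold proteins).  Four reactions:

* G1 — a new (empty) filopodium emerges, rate ``g1``;
* G2 — a filopodium holding i-1 seeds captures a free seed, rate
  ``S * c_in`` per filopodium (blocked at the cap i = n);
* G3 — a filopodium retracts and returns all its seeds to the pool; in
  ``competitive`` mode the rate is 1/max(i, 1) (seeds protect the
  filopodium — the winner-takes-all feedback), in ``upregulated`` mode a
  seed-independent constant (enhanced autophagic turnover strips the
  advantage);
* G4 — a filopodium releases one seed back to the pool, rate ``c_out``.

The free pool is initialized to ``round(n * mean_bulbs_P60)`` so genotypes
differ only in total seeding-factor abundance.  A filopodium counts as a
bulbous tip while it holds at least n/4 seeds.  Simulation is plain
Gillespie; a "time step" is one reaction event, with exponential waiting
times accumulated so lifetimes are reported in model time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import MechParams

__all__ = [
    "MechHistory",
    "BulbEpisode",
    "MechBulbSummary",
    "init_pool",
    "mech_propensities",
    "simulate_mechanistic",
    "analyze_bulbs",
]


def init_pool(n: int, mean_bulbs_P60: float) -> int:
    """Initial free-seed pool: nearest integer (half-up) of n * mean bulbs."""
    if n < 1 or mean_bulbs_P60 <= 0:
        raise ValueError(
            f"need n >= 1 and mean_bulbs_P60 > 0, got n={n}, {mean_bulbs_P60}"
        )
    return int(np.floor(n * mean_bulbs_P60 + 0.5))


def mech_propensities(pool: int, seed_counts, params: MechParams):
    """Per-reaction rates given the free pool and live-filopodium seed counts.

    Returns ``(g1, acc, rel, ret)`` where the last three are arrays aligned
    with ``seed_counts``: seed accumulation, seed release and retraction
    rates of each live filopodium.
    """
    i = np.asarray(seed_counts, dtype=np.int64)
    if np.any(i < 0) or np.any(i > params.n):
        raise ValueError("seed counts must lie in [0, n]")
    acc = np.where(i < params.n, pool * params.c_in, 0.0)
    rel = np.where(i > 0, params.c_out, 0.0)
    if params.mode == "competitive":
        ret = 1.0 / np.maximum(i, 1)
    else:
        ret = np.full(len(i), params.upregulated_const)
    return params.g1, acc, rel, ret


@dataclass(frozen=True)
class BulbEpisode:
    """A maximal contiguous period a filopodium spends at/above threshold."""

    filopodium_id: int
    start_time: float
    end_time: float
    start_step: int
    end_step: int
    censored: bool  # still above threshold when the run ended

    @property
    def lifetime(self) -> float:
        return self.end_time - self.start_time


@dataclass
class MechHistory:
    """Step-resolved record of a mechanistic run."""

    params: MechParams
    seed: int
    initial_pool: int
    times: np.ndarray  # model time after each step
    events: np.ndarray  # 0=G1 emerge, 1=G2 accumulate, 2=G3 retract, 3=G4 release
    pool: np.ndarray  # free pool after each step
    n_filopodia: np.ndarray
    n_bulbs: np.ndarray  # filopodia at/above threshold after each step
    episodes: list[BulbEpisode] = field(default_factory=list)
    # (birth time, end time, censored) per filopodium that ever lived
    filopodium_spans: list[tuple[float, float, bool]] = field(default_factory=list)

    @property
    def steps(self) -> int:
        return len(self.times)


def simulate_mechanistic(
    params: MechParams,
    steps: int = 100_000,
    seed: int = 0,
    return_seeds: bool = False,
) -> MechHistory:
    """Run the seed-pool model for a fixed number of reaction events.

    Resource conservation — free pool plus all held seeds equals the
    initial pool — is asserted after every event.
    """
    if steps < 2:
        raise ValueError(f"steps must be >= 2, got {steps}")
    rng = np.random.default_rng(seed)
    pool0 = init_pool(params.n, params.mean_bulbs_P60)
    pool = pool0
    thr = params.bulb_threshold

    seed_counts: list[int] = []  # live filopodia
    fil_ids: list[int] = []
    births: list[float] = []  # birth time aligned with seed_counts
    spans: list[tuple[float, float, bool]] = []
    next_id = 0
    above_since: dict[int, tuple[float, int]] = {}  # id -> (time, step) of crossing

    t = 0.0
    times = np.empty(steps)
    events = np.empty(steps, dtype=np.int8)
    pool_hist = np.empty(steps, dtype=np.int64)
    nfil_hist = np.empty(steps, dtype=np.int64)
    nbulb_hist = np.empty(steps, dtype=np.int64)
    episodes: list[BulbEpisode] = []
    n_bulbs = 0

    for step in range(steps):
        m = len(seed_counts)
        g1 = params.g1
        total = g1
        # per-filopodium rates, plain floats for speed
        accs = []
        rels = []
        rets = []
        for i in seed_counts:
            a = pool * params.c_in if i < params.n else 0.0
            r = params.c_out if i > 0 else 0.0
            if params.mode == "competitive":
                d = 1.0 / i if i > 0 else 1.0
            else:
                d = params.upregulated_const
            accs.append(a)
            rels.append(r)
            rets.append(d)
            total += a + r + d
        # g1 and g3 are always positive, so total > 0 is guaranteed
        assert total > 0.0
        t += rng.exponential(1.0 / total)
        u = rng.uniform(0.0, total)

        if u < g1:
            ev = 0
            seed_counts.append(0)
            fil_ids.append(next_id)
            births.append(t)
            next_id += 1
        else:
            u -= g1
            ev = -1
            for k in range(m):
                if u < accs[k]:
                    ev = 1
                    seed_counts[k] += 1
                    pool -= 1
                    if seed_counts[k] == thr:
                        above_since[fil_ids[k]] = (t, step)
                        n_bulbs += 1
                    break
                u -= accs[k]
                if u < rels[k]:
                    ev = 3
                    seed_counts[k] -= 1
                    pool += 1
                    if seed_counts[k] == thr - 1:
                        t0, s0 = above_since.pop(fil_ids[k])
                        episodes.append(BulbEpisode(fil_ids[k], t0, t, s0, step, False))
                        n_bulbs -= 1
                    break
                u -= rels[k]
                if u < rets[k]:
                    ev = 2
                    pool += seed_counts[k]  # retraction returns all seeds
                    if seed_counts[k] >= thr:
                        t0, s0 = above_since.pop(fil_ids[k])
                        episodes.append(BulbEpisode(fil_ids[k], t0, t, s0, step, False))
                        n_bulbs -= 1
                    spans.append((births[k], t, False))
                    del seed_counts[k]
                    del fil_ids[k]
                    del births[k]
                    break
                u -= rets[k]
            assert ev >= 0, "no reaction selected — propensity bookkeeping broken"

        assert pool >= 0
        assert pool + sum(seed_counts) == pool0, "seed conservation violated"
        times[step] = t
        events[step] = ev
        pool_hist[step] = pool
        nfil_hist[step] = len(seed_counts)
        nbulb_hist[step] = n_bulbs

    for fid, (t0, s0) in above_since.items():
        episodes.append(BulbEpisode(fid, t0, t, s0, steps - 1, True))
    episodes.sort(key=lambda e: e.start_time)
    for b in births:
        spans.append((b, t, True))
    spans.sort()

    return MechHistory(
        params=params,
        seed=seed,
        initial_pool=pool0,
        times=times,
        events=events,
        pool=pool_hist,
        n_filopodia=nfil_hist,
        n_bulbs=nbulb_hist,
        episodes=episodes,
        filopodium_spans=spans,
    )


@dataclass(frozen=True)
class MechBulbSummary:
    """Post-burn-in bulb statistics of a mechanistic run."""

    count_distribution: np.ndarray  # P(#bulbs = k) over retained steps
    mean_bulbs: float
    lifetimes: np.ndarray  # model-time episode durations
    censored: np.ndarray
    n_episodes: int
    burn_in_steps: int


def analyze_bulbs(
    history: MechHistory, burn_in_fraction: float = 0.5
) -> MechBulbSummary:
    """Bulb count distribution and episode lifetimes after burn-in.

    The first ``burn_in_fraction`` of steps is discarded as pre-steady
    state.  Counts are tallied per retained step; lifetimes come from
    above-threshold episodes that began after burn-in (episodes still open
    at the end of the run are flagged censored).
    """
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    cut = int(history.steps * burn_in_fraction)
    if cut >= history.steps:
        raise ValueError("no steps remain after burn-in")
    counts = history.n_bulbs[cut:]
    dist = np.bincount(counts) / len(counts)
    eps = [e for e in history.episodes if e.start_step >= cut]
    lifetimes = np.array([e.lifetime for e in eps])
    censored = np.array([e.censored for e in eps], dtype=bool)
    return MechBulbSummary(
        count_distribution=dist,
        mean_bulbs=float(counts.mean()),
        lifetimes=lifetimes,
        censored=censored,
        n_episodes=len(eps),
        burn_in_steps=cut,
    )
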