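"""Parameter estimation for the developmental model.

The estimation chain mirrors how the rate constants are derived from
live-imaging observables:

1. retraction constants ``c2_sF``, ``c2_lF`` — inverse mean lifetime of
   filopodia living under / at least 8 min (the short/long cutoff);
2. generation constants ``c1_*`` — the per-time-instance filopodium counts
   are Poisson, so lambda = c1 * f_F / c2 and c1 = lambda * c2 / f_F(P60);
3. ``c4`` — fixed at 1/120 per minute (transient bulbs are too rare to
   estimate per genotype);
4. ``c6`` — steepest slope of the synapse-accumulation curve divided by the
   mean number of synaptogenic bulbs over that interval;
5. ``(c5, B50, r3)`` — KL fit of the stationary bulb-count distributions
   (:mod:`filokin.bulbs`);
6. ``c3`` — inversion of the bulb-formation rate r3 at P60 through the
   filopodia census and f_FB(P60).

:class:`DevelopmentalModel` bundles the observation-layer data and runs the
chain via ``fit()``, returning a :class:`DevelopmentalFitResults` whose
``summary()`` reports every constant with its provenance (fixed vs
estimated).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bulbs as _bulbs
from .kinetics import compute_c3, eval_f_FB
from .params import DevParams, P60_MIN

__all__ = [
    "FilopodiumTrack",
    "estimate_retraction_rates",
    "estimate_lambda",
    "estimate_generation_rate",
    "estimate_c6",
    "steepest_slope",
    "bootstrap_estimate",
    "DevelopmentalModel",
    "DevelopmentalFitResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilopodiumTrack:
    """One tracked object: a filopodium or a bulbous tip.

    ``death`` of ``None`` marks a censored track (still alive when the
    imaging window closed).
    """

    object_id: str
    class_label: str  # "filopodium" | "bulb"
    birth: float
    death: float | None

    def __post_init__(self) -> None:
        if self.class_label not in ("filopodium", "bulb"):
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.death is not None and self.death < self.birth:
            raise ValueError(
                f"track {self.object_id}: death {self.death} before birth {self.birth}"
            )

    @property
    def censored(self) -> bool:
        return self.death is None

    @property
    def lifetime(self) -> float | None:
        return None if self.death is None else self.death - self.birth


def estimate_retraction_rates(
    tracks: list[FilopodiumTrack], cutoff: float = 8.0
) -> tuple[float, float]:
    """Retraction constants from filopodial lifetimes.

    ``c2_sF`` is the inverse mean lifetime of filopodia that lived less
    than ``cutoff`` minutes, ``c2_lF`` of those living at least ``cutoff``.
    Censored tracks are excluded (their count is logged).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    fil = [t for t in tracks if t.class_label == "filopodium"]
    n_cens = sum(t.censored for t in fil)
    if n_cens:
        logger.info("excluding %d censored filopodium tracks", n_cens)
    lifetimes = np.array([t.lifetime for t in fil if not t.censored])
    short = lifetimes[lifetimes < cutoff]
    long = lifetimes[lifetimes >= cutoff]
    if len(short) == 0:
        raise ValueError(f"no uncensored filopodia with lifetime < {cutoff} min")
    if len(long) == 0:
        raise ValueError(f"no uncensored filopodia with lifetime >= {cutoff} min")
    return 1.0 / float(short.mean()), 1.0 / float(long.mean())


def estimate_lambda(snapshots: pd.DataFrame, category: str) -> tuple[float, float]:
    """Mean count per time instance (Poisson MLE) and index of dispersion.

    ``snapshots`` is the per-time-instance count table (one row per
    sampling time, one column per category).  The index of dispersion
    (variance / mean) should be near 1 if the counts are Poisson; it is
    returned as a goodness diagnostic (NaN for a single snapshot or zero
    mean).
    """
    if category not in snapshots.columns:
        raise ValueError(
            f"unknown category {category!r}; columns: {list(snapshots.columns)}"
        )
    counts = snapshots[category].to_numpy(dtype=float)
    if len(counts) == 0:
        raise ValueError("need at least one snapshot")
    lam = float(counts.mean())
    if len(counts) < 2 or lam == 0:
        return lam, float("nan")
    return lam, float(counts.var(ddof=1) / lam)


def estimate_generation_rate(lambda_P60: float, c2: float, f_F_P60: float) -> float:
    """Zero-order generation constant c1 = lambda * c2 / f_F(P60)."""
    if f_F_P60 <= 0:
        raise ValueError(
            "f_F(P60) must be positive to invert the generation rate; the "
            "clamped drive polynomial evaluates to 0 here — supply a "
            "constant or tabulated drive instead"
        )
    return lambda_P60 * c2 / f_F_P60


def estimate_c6(delta_S: float, delta_t: float, mean_synB: float) -> float:
    """Synapse maturation constant from the accumulation slope.

    ``c6 = (delta_S / delta_t) / mean_synB``: the steepest synapse gain per
    minute divided by the mean number of stabilized synaptogenic bulbs over
    that interval.
    """
    if delta_t <= 0 or mean_synB <= 0:
        raise ValueError(
            f"delta_t and mean_synB must be positive, got {delta_t}, {mean_synB}"
        )
    if delta_S < 0:
        raise ValueError(f"delta_S must be >= 0, got {delta_S}")
    return (delta_S / delta_t) / mean_synB


def steepest_slope(stage_table: pd.DataFrame) -> tuple[float, float]:
    """Steepest inter-timepoint synapse gain from a (t_min, mean_S) table.

    Returns ``(delta_S, delta_t)`` of the interval with the largest slope.
    """
    if not {"t_min", "mean_S"} <= set(stage_table.columns):
        raise ValueError("stage table needs columns t_min and mean_S")
    tab = stage_table.sort_values("t_min")
    t = tab["t_min"].to_numpy(dtype=float)
    s = tab["mean_S"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two timepoints")
    dt = np.diff(t)
    ds = np.diff(s)
    if np.any(dt <= 0):
        raise ValueError("timepoints must be strictly increasing")
    k = int(np.argmax(ds / dt))
    return float(ds[k]), float(dt[k])


def bootstrap_estimate(
    data, statistic, n_boot: int = 1000, seed: int = 0, ci: float = 0.95
) -> tuple[float, float]:
    """Basic nonparametric bootstrap percentile interval for a statistic.

    Intended for the c2 and lambda estimators (resampling tracks or
    snapshots); returns the (lo, hi) percentile interval.
    """
    rng = np.random.default_rng(seed)
    data = list(data)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(len(data), size=len(data))
        stats[b] = statistic([data[i] for i in idx])
    alpha = (1 - ci) / 2
    return float(np.quantile(stats, alpha)), float(np.quantile(stats, 1 - alpha))


@dataclass(frozen=True)
class DevelopmentalFitResults:
    """Assembled genotype parameter set with estimation provenance."""

    params: DevParams
    provenance: dict[str, str]  # field -> "estimated" | "fixed" | "unestimated"
    diagnostics: dict[str, float] = field(default_factory=dict)
    bulb_fit: _bulbs.BulbFitResults | None = None

    def summary(self) -> str:
        p = self.params
        rows = [
            ("c1_sF (1/min)", p.c1_sF),
            ("c1_lF (1/min)", p.c1_lF),
            ("c2_sF (1/min)", p.c2_sF),
            ("c2_lF (1/min)", p.c2_lF),
            ("c3 (1/min/filopodium)", p.c3),
            ("c4 (1/min)", p.c4),
            ("c5 (1/min)", p.c5),
            ("c6 (1/min)", p.c6),
            ("B50 (count)", p.B50),
            ("t_half (min)", p.t_half),
        ]
        lines = [
            f"Developmental model fit — genotype {p.genotype_label!r}",
            "=" * 58,
            f"{'parameter':<26}{'value':>16}  provenance",
            "-" * 58,
        ]
        for label, v in rows:
            key = label.split()[0]
            prov = self.provenance.get(key, "fixed")
            lines.append(f"{label:<26}{v:>16.6g}  {prov}")
        if self.diagnostics:
            lines.append("-" * 58)
            for k, v in self.diagnostics.items():
                lines.append(f"{k:<26}{v:>16.6g}")
        return "\n".join(lines)

    def simulate(self, t_start: float = 0.0, t_end: float = 3000.0,
                 seed: int = 0, **kwargs):
        """Run the developmental SSA with the fitted parameter set."""
        from .developmental import simulate_developmental

        return simulate_developmental(self.params, t_start, t_end,
                                      seed=seed, **kwargs)


class DevelopmentalModel:
    """Observation-layer data for one genotype, ready for estimation.

    Parameters
    ----------
    tracks : list of FilopodiumTrack
        Lifetime data from the live-imaging window.
    snapshots : pandas.DataFrame
        Per-time-instance counts; must contain columns ``sF`` and ``lF``.
    obs_sB, obs_synB : array-like, optional
        Observed bulb count-frequency distributions (counts 0..len-1).
        Without them the bulb parameters (c5, B50, r3) are left
        unestimated.
    synapse_table : pandas.DataFrame, optional
        Per-stage mean synapse counts (columns ``t_min``, ``mean_S``) for
        the c6 slope; alternatively pass ``c6`` in ``fixed``.
    mean_synB : float, optional
        Mean stabilized-bulb count over the steepest-slope interval
        (needed with ``synapse_table``).
    fixed : dict, optional
        Overrides treated as fixed: ``c4`` (default 1/120), ``t_half``
        (default 1000), ``f_F_P60`` (default 1, the constant-drive
        convention), ``c6``, ``poly_coeffs``.
    """

    def __init__(
        self,
        tracks: list[FilopodiumTrack],
        snapshots: pd.DataFrame,
        obs_sB=None,
        obs_synB=None,
        synapse_table: pd.DataFrame | None = None,
        mean_synB: float | None = None,
        fixed: dict | None = None,
        genotype_label: str = "unnamed",
        cutoff: float = 8.0,
        N: int = 15,
    ):
        self.tracks = list(tracks)
        self.snapshots = snapshots
        self.obs_sB = None if obs_sB is None else np.asarray(obs_sB, dtype=float)
        self.obs_synB = None if obs_synB is None else np.asarray(obs_synB, dtype=float)
        self.synapse_table = synapse_table
        self.mean_synB = mean_synB
        self.fixed = dict(fixed or {})
        self.genotype_label = genotype_label
        self.cutoff = cutoff
        self.N = N

    @classmethod
    def from_dataframes(cls, tracks: pd.DataFrame, snapshots: pd.DataFrame,
                        **kwargs) -> "DevelopmentalModel":
        """Build from a track table (object_id, class, t_birth_min,
        t_death_min with NaN = censored) and a snapshot table."""
        objs = [
            FilopodiumTrack(
                object_id=str(oid),
                class_label=str(cls),
                birth=float(b),
                death=None if pd.isna(d) else float(d),
            )
            for oid, cls, b, d in zip(
                tracks["object_id"], tracks["class"],
                tracks["t_birth_min"], tracks["t_death_min"],
            )
        ]
        return cls(objs, snapshots, **kwargs)

    def fit(self, **bulb_fit_kwargs) -> DevelopmentalFitResults:
        """Run the full estimation chain and assemble a DevParams."""
        fx = self.fixed
        c4 = fx.get("c4", 1.0 / 120.0)
        t_half = fx.get("t_half", 1000.0)
        f_F_P60 = fx.get("f_F_P60", 1.0)
        poly = tuple(fx.get("poly_coeffs", (f_F_P60, 0.0, 0.0, 0.0, 0.0, 0.0)))
        prov: dict[str, str] = {"c4": "fixed", "t_half": "fixed"}
        diag: dict[str, float] = {}

        c2_sF, c2_lF = estimate_retraction_rates(self.tracks, self.cutoff)
        prov["c2_sF"] = prov["c2_lF"] = "estimated"

        lam_sF, disp_sF = estimate_lambda(self.snapshots, "sF")
        lam_lF, disp_lF = estimate_lambda(self.snapshots, "lF")
        diag["lambda_sF"] = lam_sF
        diag["lambda_lF"] = lam_lF
        diag["dispersion_sF"] = disp_sF
        diag["dispersion_lF"] = disp_lF
        c1_sF = estimate_generation_rate(lam_sF, c2_sF, f_F_P60)
        c1_lF = estimate_generation_rate(lam_lF, c2_lF, f_F_P60)
        prov["c1_sF"] = prov["c1_lF"] = "estimated"

        if "c6" in fx:
            c6 = fx["c6"]
            prov["c6"] = "fixed"
        elif self.synapse_table is not None:
            if self.mean_synB is None:
                raise ValueError("mean_synB is required with synapse_table")
            dS, dt = steepest_slope(self.synapse_table)
            c6 = estimate_c6(dS, dt, self.mean_synB)
            prov["c6"] = "estimated"
        else:
            raise ValueError("supply either fixed['c6'] or a synapse_table")

        bulb_fit = None
        if self.obs_sB is not None and self.obs_synB is not None:
            model = _bulbs.BulbStationaryModel(
                self.obs_sB, self.obs_synB, c4=c4, c6=c6, N=self.N
            )
            bulb_fit = model.fit(**bulb_fit_kwargs)
            c5, B50, r3 = bulb_fit.c5, bulb_fit.B50, bulb_fit.r3
            prov["c5"] = prov["B50"] = "estimated"
            diag["kl_total"] = bulb_fit.kl_total
            c3 = compute_c3(r3, lam_sF, lam_lF, eval_f_FB(P60_MIN, t_half))
            prov["c3"] = "estimated"
            diag["r3_P60"] = r3
        else:
            warnings.warn("no bulb observations: c5, B50, c3 left unestimated")
            c5, B50, c3 = 0.0, 1.0, 0.0
            prov["c5"] = prov["B50"] = prov["c3"] = "unestimated"

        params = DevParams(
            genotype_label=self.genotype_label,
            c1_sF=c1_sF, c1_lF=c1_lF, c2_sF=c2_sF, c2_lF=c2_lF,
            c3=c3, c4=c4, c5=c5, c6=c6, B50=B50, t_half=t_half,
            poly_coeffs=poly,
        )
        return DevelopmentalFitResults(
            params=params, provenance=prov, diagnostics=diag, bulb_fit=bulb_fit
        )
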