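"""Parameter and state containers for both stochastic models.

Two models share this module:

* the *developmental model* — a time-inhomogeneous Markov jump process for
  filopodia, bulbous tips and synapses in one R7 axon terminal, run over the
  second half of pupal development (:class:`DevParams`, :class:`DevState`);
* the *mechanistic model* — a winner-takes-all competition of filopodia for
  a conserved pool of synaptic seeding factors (:class:`MechParams`).

Genotype presets (:data:`PRESETS`) bundle a complete developmental
parameter set per genotype.  The per-genotype source tables of the original
study are not publicly deposited, so the presets are synthetic stand-ins:
rate constants calibrated once against the published anchors (the fixed
c4 = 1/120 min^-1, the synapse-slope derivation of c6, t_half = 1000 min,
the one-to-two concurrent synaptogenic bulbs of control terminals, the
three-to-four band of autophagy mutants, and 20-25 synapses formed over the
50 h between P40 and P90 in control).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "DevParams",
    "DevState",
    "MechParams",
    "PRINTED_FF_COEFFS",
    "MINUTES_PER_PERCENT",
    "P60_MIN",
    "PRESETS",
    "load_params",
    "save_params",
]

#: Developmental time convention: minutes of real time per percent of pupal
#: development; t = 0 at P40, so P60 is 60 * 20 = 1200 min.
MINUTES_PER_PERCENT = 60.0
P60_MIN = MINUTES_PER_PERCENT * 20.0

#: The filopodial-drive polynomial coefficients (p0..p5) as printed in the
#: source model.  With t in minutes these drive the clamped polynomial to 0
#: for t beyond roughly 460 min, i.e. well before P60 — almost certainly a
#: units/typesetting artefact.  They are kept verbatim for reference and
#: testing; the genotype presets use a constant drive instead (see
#: :meth:`DevParams.filopodial_drive`).
PRINTED_FF_COEFFS = (1.0, -1.45e-3, 2.06e-6, -1.29e-9, 3.31e-13, -2.97e-14)

_RATE_FIELDS = ("c1_sF", "c1_lF", "c2_sF", "c2_lF", "c3", "c4", "c5", "c6")


@dataclass(frozen=True)
class DevState:
    """Integer copy numbers of the developmental model at time ``t``.

    ``t`` is minutes after P40; ``sF``/``lF`` short- and long-lived
    filopodia, ``sB`` transient bulbous tips, ``synB`` stabilized
    synaptogenic bulbous tips, ``S`` synapses.
    """

    t: float = 0.0
    sF: int = 0
    lF: int = 0
    sB: int = 0
    synB: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"t must be >= 0 (minutes after P40), got {self.t}")
        for name in ("sF", "lF", "sB", "synB", "S"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.sF, self.lF, self.sB, self.synB, self.S)


@dataclass(frozen=True)
class DevParams:
    """Complete rate-constant set of the developmental model for one genotype.

    Rates are per minute.  ``c1_*`` zero-order filopodium generation,
    ``c2_*`` first-order retraction, ``c3`` bulb formation per filopodium,
    ``c4`` transient-bulb retraction, ``c5`` bulb stabilization, ``c6``
    synapse maturation.  ``B50`` is the half-saturation count of the
    bulb-formation auto-inhibition and ``t_half`` the half-time (min) of the
    sigmoidal bulb-propensity ramp.

    ``poly_coeffs`` are the drive-polynomial coefficients p0..p5; if
    ``drive_table`` is set (a sequence of ``(t_min, value)`` nodes) the
    drive is instead the piecewise-linear interpolant of that table —
    the supported workaround for the degenerate printed polynomial.
    """

    genotype_label: str = "unnamed"
    c1_sF: float = 0.0
    c1_lF: float = 0.0
    c2_sF: float = 0.0
    c2_lF: float = 0.0
    c3: float = 0.0
    c4: float = 1.0 / 120.0
    c5: float = 0.0
    c6: float = 0.0
    B50: float = 1.0
    t_half: float = 1000.0
    poly_coeffs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    f1_mode: str = "inhibition"
    drive_table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite non-negative rate, got {v}")
        if self.B50 <= 0:
            raise ValueError(f"B50 must be > 0, got {self.B50}")
        if self.t_half <= 0:
            raise ValueError(f"t_half must be > 0, got {self.t_half}")
        if len(self.poly_coeffs) != 6:
            raise ValueError(
                f"poly_coeffs must have exactly 6 entries, got {len(self.poly_coeffs)}"
            )
        object.__setattr__(self, "poly_coeffs", tuple(float(p) for p in self.poly_coeffs))
        if self.f1_mode not in ("inhibition", "as_printed"):
            raise ValueError(f"unknown f1_mode {self.f1_mode!r}")
        if self.drive_table is not None:
            tab = tuple((float(t), float(v)) for t, v in self.drive_table)
            if len(tab) < 2:
                raise ValueError("drive_table needs at least two (t, value) nodes")
            ts = [t for t, _ in tab]
            if sorted(ts) != ts:
                raise ValueError("drive_table times must be non-decreasing")
            object.__setattr__(self, "drive_table", tab)

    def filopodial_drive(self, t: float) -> float:
        """Evaluate the filopodial drive f_F at time ``t`` (min after P40).

        Uses the piecewise-linear ``drive_table`` when present, otherwise
        the clamped polynomial of ``poly_coeffs``.
        """
        if self.drive_table is not None:
            ts = [p[0] for p in self.drive_table]
            vs = [p[1] for p in self.drive_table]
            if t <= ts[0]:
                return max(0.0, vs[0])
            if t >= ts[-1]:
                return max(0.0, vs[-1])
            import numpy as np

            return max(0.0, float(np.interp(t, ts, vs)))
        value = 0.0
        for p in reversed(self.poly_coeffs):
            value = value * t + p
        return max(0.0, value)

    def replace(self, **kwargs) -> "DevParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["poly_coeffs"] = list(self.poly_coeffs)
        if self.drive_table is not None:
            d["drive_table"] = [list(p) for p in self.drive_table]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DevParams":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown DevParams keys: {sorted(unknown)}")
        if "c4" not in d:
            # the published model fixes the transient-bulb retraction constant
            d["c4"] = 1.0 / 120.0
        if "poly_coeffs" in d:
            d["poly_coeffs"] = tuple(d["poly_coeffs"])
        if d.get("drive_table") is not None:
            d["drive_table"] = tuple(tuple(p) for p in d["drive_table"])
        return cls(**d)


@dataclass(frozen=True)
class MechParams:
    """Winner-takes-all seed-pool model parameters.

    A filopodium holding ``i`` seeding factors (``i`` in [0, n]) gains a
    survival advantage: its retraction rate is 1/i in ``competitive`` mode.
    ``upregulated`` mode removes the advantage (retraction at the constant
    ``upregulated_const``), emulating enhanced autophagic turnover of the
    seeding factors.  Genotypes differ only in the initial free pool,
    ``round(n * mean_bulbs_P60)``.
    """

    n: int = 120
    c_in: float = 0.07
    c_out: float = 1.5
    g1: float = 0.019  # control bulb-emergence rate r3 at P60
    mode: str = "competitive"
    upregulated_const: float = 1.0 / 120.0
    mean_bulbs_P60: float = 1.1
    bulb_threshold: int | None = None
    genotype_label: str = "unnamed"

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(f"n must be >= 4, got {self.n}")
        for name in ("c_in", "c_out", "g1", "upregulated_const"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mode not in ("competitive", "upregulated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mean_bulbs_P60 <= 0:
            raise ValueError(f"mean_bulbs_P60 must be > 0, got {self.mean_bulbs_P60}")
        thr = self.bulb_threshold
        if thr is None:
            thr = math.ceil(self.n / 4)
            object.__setattr__(self, "bulb_threshold", thr)
        if not (1 <= thr <= self.n):
            raise ValueError(f"bulb_threshold must be in [1, n], got {thr}")

    def replace(self, **kwargs) -> "MechParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MechParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown MechParams keys: {sorted(unknown)}")
        return cls(**d)


def _f_FB(t: float, t_half: float) -> float:
    # duplicated from kinetics.eval_f_FB to keep this module import-free
    return 0.5 * (1.0 + math.tanh((3.0 / t_half) * (t - t_half)))


def _make_preset(
    label: str,
    *,
    lam_sF: float,
    lam_lF: float,
    mean_life_sF: float,
    mean_life_lF: float,
    r3_P60: float,
    c5: float,
    B50: float,
    c4: float = 1.0 / 120.0,
    c6: float = 5.0 / (1.1 * 600.0),
    t_half: float = 1000.0,
) -> DevParams:
    """Assemble a genotype preset from observable-level anchors.

    ``lam_*`` are the mean concurrent filopodium counts at P60 and
    ``mean_life_*`` the mean lifetimes (min) per class; with a constant
    filopodial drive the stationary counts of each class form an
    immigration-death process, so c1 = lambda * c2.  ``r3_P60`` is the
    total bulb-formation rate at P60, inverted to c3 via the census and
    f_FB(P60).
    """
    c2_sF = 1.0 / mean_life_sF
    c2_lF = 1.0 / mean_life_lF
    c3 = r3_P60 / ((lam_sF + lam_lF) * _f_FB(P60_MIN, t_half))
    return DevParams(
        genotype_label=label,
        c1_sF=lam_sF * c2_sF,
        c1_lF=lam_lF * c2_lF,
        c2_sF=c2_sF,
        c2_lF=c2_lF,
        c3=c3,
        c4=c4,
        c5=c5,
        c6=c6,
        B50=B50,
        t_half=t_half,
        poly_coeffs=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    )


#: Synthetic genotype presets (see module docstring for the calibration
#: anchors).  Control: one-to-two concurrent synaptogenic bulbs, ~20-25
#: synapses by P90.  atg-mutant (atg6/atg7 loss): longer-lived filopodia and
#: a relaxed seeding-factor limit (higher B50, higher bulb formation), three
#: to four concurrent bulbs.  atg-upregulated (autophagy gain): destabilized
#: bulbs (larger c4), weakened stabilization, near-flat feedback.
PRESETS: dict[str, DevParams] = {
    "control": _make_preset(
        "control",
        lam_sF=7.0,
        lam_lF=5.0,
        mean_life_sF=2.0,
        mean_life_lF=30.0,
        r3_P60=0.019,
        c5=0.05,
        B50=2.0,
    ),
    "atg-mutant": _make_preset(
        "atg-mutant",
        lam_sF=7.0,
        lam_lF=7.0,
        mean_life_sF=2.0,
        mean_life_lF=35.0,
        r3_P60=0.036,
        c5=0.05,
        B50=10.0,
    ),
    "atg-upregulated": _make_preset(
        "atg-upregulated",
        lam_sF=7.0,
        lam_lF=5.0,
        mean_life_sF=2.0,
        mean_life_lF=15.0,
        r3_P60=0.012,
        c5=0.02,
        B50=50.0,
        c4=1.0 / 40.0,
    ),
}

#: Mechanistic-model presets.  Genotypes differ only in the mean bulb count
#: that sizes the seed pool, except the upregulated variant which also loses
#: the competitive advantage (seed-count-independent retraction).
MECH_PRESETS: dict[str, MechParams] = {
    "control": MechParams(genotype_label="control", mean_bulbs_P60=1.1),
    "atg-mutant": MechParams(genotype_label="atg-mutant", mean_bulbs_P60=3.5),
    "atg-upregulated": MechParams(
        genotype_label="atg-upregulated", mean_bulbs_P60=0.7, mode="upregulated"
    ),
}


def save_params(params: DevParams | MechParams, path: str | Path) -> None:
    """Write a parameter set to JSON or YAML (by file extension)."""
    path = Path(path)
    payload = {"kind": type(params).__name__, **params.to_dict()}
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_params(path: str | Path) -> DevParams | MechParams:
    """Read a parameter set written by :func:`save_params`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(payload).__name__}")
    kind = payload.pop("kind", "DevParams")
    if kind == "MechParams":
        return MechParams.from_dict(payload)
    if kind == "DevParams":
        return DevParams.from_dict(payload)
    raise ValueError(f"{path}: unknown params kind {kind!r}")
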