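"""Fast-timescale bulbous-tip inference via a truncated 2-D Markov chain.

On the ~hour timescale of a live-imaging session the filopodial census and
the developmental ramp are effectively frozen, so the joint dynamics of
transient bulbs (``sB``, count i) and stabilized synaptogenic bulbs
(``synB``, count j) form a time-homogeneous continuous-time Markov chain on
the truncated lattice [0, N]^2 with transitions

* bulb birth      [i, j] -> [i+1, j]    at r3 * f1(j, B50)
* bulb retraction [i, j] -> [i-1, j]    at i * c4
* stabilization   [i, j] -> [i-1, j+1]  at i * c5   (reaction-consistent)
* maturation      [i, j] -> [i, j-1]    at j * c6

with a reflecting boundary at N.  The stationary law is the zero-eigenvalue
left eigenvector of the generator; its marginals are fitted to observed
count-frequency distributions by minimizing Kullback-Leibler divergence
over (c5, B50, r3), with c4 and c6 fixed upstream.

The literature formula typesets the stabilization entry as
G([i,j],[i,j+1]) = j*c5, which neither consumes a transient bulb nor scales
with i and so contradicts the reaction sB -> synB; that variant is kept
behind ``generator_mode="as_printed"`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize
from scipy.sparse.csgraph import connected_components

from .kinetics import eval_f1

__all__ = [
    "BulbGenerator",
    "StationaryDistribution",
    "build_generator",
    "stationary_distribution",
    "marginal_densities",
    "stationary_mean_bulbs",
    "kl_divergence",
    "fit_bulb_parameters",
    "BulbStationaryModel",
    "BulbFitResults",
]


@dataclass(frozen=True)
class BulbGenerator:
    """Generator matrix of the truncated (sB, synB) chain.

    ``matrix[a, b]`` is the rate from flattened state a to b, with state
    [i, j] at index ``i * (N + 1) + j``.  Rows sum to zero.
    """

    N: int
    r3: float
    c4: float
    c5: float
    c6: float
    B50: float
    f1_mode: str
    generator_mode: str
    matrix: np.ndarray

    @property
    def n_states(self) -> int:
        return (self.N + 1) ** 2

    def state_index(self, i: int, j: int) -> int:
        return i * (self.N + 1) + j


@dataclass(frozen=True)
class StationaryDistribution:
    """Stationary probability vector over flattened (sB, synB) states."""

    probabilities: np.ndarray
    eigenvalue: complex
    residual: float
    N: int

    def as_grid(self) -> np.ndarray:
        """Probabilities reshaped to (N+1, N+1), axis 0 = sB, axis 1 = synB."""
        return self.probabilities.reshape(self.N + 1, self.N + 1)


def build_generator(
    r3: float,
    c4: float,
    c5: float,
    c6: float,
    B50: float,
    N: int = 15,
    f1_mode: str = "inhibition",
    generator_mode: str = "reaction_consistent",
) -> BulbGenerator:
    """Assemble the truncated generator matrix with reflecting boundary at N."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    for name, v in (("r3", r3), ("c4", c4), ("c5", c5), ("c6", c6)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if B50 <= 0:
        raise ValueError(f"B50 must be > 0, got {B50}")
    if generator_mode not in ("reaction_consistent", "as_printed"):
        raise ValueError(f"unknown generator_mode {generator_mode!r}")

    m = N + 1
    G = np.zeros((m * m, m * m))

    def idx(i: int, j: int) -> int:
        return i * m + j

    for i in range(m):
        for j in range(m):
            a = idx(i, j)
            if i > 0:
                G[a, idx(i - 1, j)] += i * c4
            if j > 0:
                G[a, idx(i, j - 1)] += j * c6
            if i < N:
                G[a, idx(i + 1, j)] += r3 * eval_f1(j, B50, f1_mode)
            if generator_mode == "reaction_consistent":
                if i > 0 and j < N:
                    G[a, idx(i - 1, j + 1)] += i * c5
            else:  # as_printed
                if j < N:
                    G[a, idx(i, j + 1)] += j * c5
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))
    return BulbGenerator(
        N=N, r3=r3, c4=c4, c5=c5, c6=c6, B50=B50,
        f1_mode=f1_mode, generator_mode=generator_mode, matrix=G,
    )


def stationary_distribution(gen: BulbGenerator, tol: float = 1e-9) -> StationaryDistribution:
    """Stationary law of the chain: eigenvector of G^T at eigenvalue 0.

    Solves the full eigenproblem of the transposed generator, takes the
    eigenvector of the smallest-magnitude eigenvalue (analytically 0 for a
    conservative generator), clamps round-off negatives and renormalizes.
    Raises if the chain is reducible (multiple stationary laws).
    """
    G = gen.matrix
    eigvals, eigvecs = linalg.eig(G.T)
    order = np.argsort(np.abs(eigvals))
    lam0 = eigvals[order[0]]

    near_zero = np.sum(np.abs(eigvals) < tol * max(1.0, np.abs(G).max()))
    if near_zero > 1:
        n_comp, labels = connected_components(
            np.abs(G) > 0, directed=True, connection="strong"
        )
        raise ValueError(
            f"reducible chain: {near_zero} near-zero eigenvalues, "
            f"{n_comp} strongly connected components (labels {labels.tolist()})"
        )

    v = np.real(eigvecs[:, order[0]])
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9 * max(1.0, np.abs(v).max())):
        warnings.warn("stationary eigenvector has non-trivial negative entries")
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate stationary eigenvector (all zero after clamping)")
    v = v / total
    residual = float(np.abs(v @ G).max())
    return StationaryDistribution(probabilities=v, eigenvalue=lam0, residual=residual, N=gen.N)


def marginal_densities(dist: StationaryDistribution) -> tuple[np.ndarray, np.ndarray]:
    """Marginal count distributions (sB, synB) of a stationary law."""
    grid = dist.as_grid()
    p_sB = grid.sum(axis=1)
    p_synB = grid.sum(axis=0)
    return p_sB, p_synB


def stationary_mean_bulbs(dist: StationaryDistribution) -> dict[str, float]:
    """Stationary means: E[sB], E[synB] and E[sB + synB] (concurrent bulbs)."""
    p_sB, p_synB = marginal_densities(dist)
    counts = np.arange(dist.N + 1)
    mean_sB = float(p_sB @ counts)
    mean_synB = float(p_synB @ counts)
    return {"sB": mean_sB, "synB": mean_synB, "total": mean_sB + mean_synB}


def kl_divergence(p_obs, p_model, pseudocount: float = 1e-6) -> float:
    """Kullback-Leibler divergence D(observed || model) in nats.

    Both inputs are probability vectors on the same count support.  A
    pseudocount is added to every bin of both before renormalizing; with
    pseudocount 0 a model-zero bin carrying observed mass yields +inf (with
    a warning) rather than being dropped.
    """
    p = np.asarray(p_obs, dtype=float)
    q = np.asarray(p_model, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"support mismatch: {p.shape} vs {q.shape}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = (p + pseudocount) / (p + pseudocount).sum()
    q = (q + pseudocount) / (q + pseudocount).sum()
    support = p > 0
    if np.any(q[support] == 0):
        warnings.warn("model assigns zero probability to observed counts; KL is +inf")
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def _stationary_vector_direct(G: np.ndarray) -> np.ndarray:
    """Stationary vector by direct null-space solve (v G = 0, sum v = 1).

    Numerically equivalent to the zero-eigenvalue eigenvector of G^T but an
    order of magnitude faster; used inside the fitting loop.  One balance
    equation is replaced by the normalization constraint.
    """
    n = G.shape[0]
    A = G.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        v = linalg.solve(A, b)
    except linalg.LinAlgError:
        v = linalg.lstsq(A, b)[0]
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate stationary solve")
    return v / total


def _model_marginals(theta, c4, c6, N, f1_mode, generator_mode):
    c5, B50, r3 = np.exp(theta)
    gen = build_generator(r3, c4, c5, c6, B50, N=N,
                          f1_mode=f1_mode, generator_mode=generator_mode)
    v = _stationary_vector_direct(gen.matrix)
    grid = v.reshape(N + 1, N + 1)
    return grid.sum(axis=1), grid.sum(axis=0)


@dataclass(frozen=True)
class BulbFitResults:
    """KL fit of (c5, B50, r3) to observed bulb count distributions."""

    c5: float
    B50: float
    r3: float
    kl_total: float
    kl_sB: float
    kl_synB: float
    N: int
    c4: float
    c6: float
    n_starts: int
    starts: tuple = field(repr=False, default=())
    flags: tuple[str, ...] = ()

    def params(self) -> dict[str, float]:
        return {"c5": self.c5, "B50": self.B50, "r3": self.r3}

    def summary(self) -> str:
        lines = [
            "Bulbous-tip stationary KL fit",
            "=" * 42,
            f"{'truncation N':<22}{self.N:>20d}",
            f"{'fixed c4 (1/min)':<22}{self.c4:>20.6g}",
            f"{'fixed c6 (1/min)':<22}{self.c6:>20.6g}",
            "-" * 42,
            f"{'c5  (1/min)':<22}{self.c5:>20.6g}",
            f"{'B50 (count)':<22}{self.B50:>20.6g}",
            f"{'r3  (1/min)':<22}{self.r3:>20.6g}",
            "-" * 42,
            f"{'KL(sB)':<22}{self.kl_sB:>20.6g}",
            f"{'KL(synB)':<22}{self.kl_synB:>20.6g}",
            f"{'KL total':<22}{self.kl_total:>20.6g}",
            f"{'starts':<22}{self.n_starts:>20d}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def fit_bulb_parameters(
    obs_sB,
    obs_synB,
    c4: float,
    c6: float,
    N: int = 15,
    f1_mode: str = "inhibition",
    generator_mode: str = "reaction_consistent",
    pseudocount: float = 1e-6,
    grid_size: int = 5,
    n_refine: int = 3,
    x0: tuple[float, float, float] | None = None,
) -> BulbFitResults:
    """Fit (c5, B50, r3) by minimizing the summed KL divergence.

    The observed marginal distributions of sB and synB (probability vectors
    on counts 0..N) are compared with the model's stationary marginals.
    Optimization is over log-parameters (positivity by construction):
    a coarse log-spaced grid of ``grid_size**3`` candidates, then
    Nelder-Mead refinement from the best ``n_refine`` — fully deterministic.
    ``x0`` optionally seeds an extra refinement start at (c5, B50, r3).
    """
    p_sB = np.asarray(obs_sB, dtype=float)
    p_synB = np.asarray(obs_synB, dtype=float)
    if len(p_sB) != N + 1 or len(p_synB) != N + 1:
        raise ValueError(
            f"observed distributions must live on counts 0..N={N}, got lengths "
            f"{len(p_sB)}, {len(p_synB)}"
        )
    p_sB = p_sB / p_sB.sum()
    p_synB = p_synB / p_synB.sum()

    flags: list[str] = []
    if p_sB[0] > 1 - 1e-12 and p_synB[0] > 1 - 1e-12:
        flags.append("unidentifiable: all observed mass at zero for both species")
        warnings.warn(flags[-1])

    def objective(theta):
        try:
            m_sB, m_synB = _model_marginals(theta, c4, c6, N, f1_mode, generator_mode)
        except (ValueError, linalg.LinAlgError):
            return np.inf
        return (kl_divergence(p_sB, m_sB, pseudocount)
                + kl_divergence(p_synB, m_synB, pseudocount))

    c5_grid = np.log(np.geomspace(1e-4, 0.5, grid_size))
    B50_grid = np.log(np.geomspace(0.2, 50.0, grid_size))
    r3_grid = np.log(np.geomspace(1e-3, 0.5, grid_size))
    candidates = [
        (objective(np.array(th)), tuple(th))
        for th in (
            (a, b, c) for a in c5_grid for b in B50_grid for c in r3_grid
        )
    ]
    candidates.sort(key=lambda kv: kv[0])
    starts = [np.array(th) for _, th in candidates[:n_refine]]
    if x0 is not None:
        starts.append(np.log(np.asarray(x0, dtype=float)))

    best = None
    for s in starts:
        res = optimize.minimize(
            objective, s, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    c5, B50, r3 = np.exp(best.x)
    m_sB, m_synB = _model_marginals(best.x, c4, c6, N, f1_mode, generator_mode)
    kl_s = kl_divergence(p_sB, m_sB, pseudocount)
    kl_y = kl_divergence(p_synB, m_synB, pseudocount)
    return BulbFitResults(
        c5=float(c5), B50=float(B50), r3=float(r3),
        kl_total=float(best.fun), kl_sB=float(kl_s), kl_synB=float(kl_y),
        N=N, c4=c4, c6=c6,
        n_starts=len(starts), starts=tuple(map(tuple, starts)), flags=tuple(flags),
    )


class BulbStationaryModel:
    """Statsmodels-style wrapper: observed bulb distributions -> KL fit.

    Parameters
    ----------
    obs_sB, obs_synB : array-like
        Observed count-frequency distributions on counts 0..N (need not be
        normalized).
    c4, c6 : float
        Retraction and maturation constants, fixed upstream of this fit.
    N : int
        Truncation; must cover the observed support.
    """

    def __init__(self, obs_sB, obs_synB, c4: float, c6: float, N: int = 15,
                 f1_mode: str = "inhibition",
                 generator_mode: str = "reaction_consistent"):
        obs_sB = np.asarray(obs_sB, dtype=float)
        obs_synB = np.asarray(obs_synB, dtype=float)
        if len(obs_sB) > N + 1 or len(obs_synB) > N + 1:
            raise ValueError(
                f"truncation N={N} too small for observed support "
                f"({len(obs_sB) - 1}, {len(obs_synB) - 1})"
            )
        pad = lambda p: np.pad(p, (0, N + 1 - len(p)))
        self.obs_sB = pad(obs_sB) / obs_sB.sum()
        self.obs_synB = pad(obs_synB) / obs_synB.sum()
        self.c4 = c4
        self.c6 = c6
        self.N = N
        self.f1_mode = f1_mode
        self.generator_mode = generator_mode

    def fit(self, **kwargs) -> BulbFitResults:
        return fit_bulb_parameters(
            self.obs_sB, self.obs_synB, self.c4, self.c6, N=self.N,
            f1_mode=self.f1_mode, generator_mode=self.generator_mode, **kwargs,
        )
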