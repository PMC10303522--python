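"""Cuckoo-search optimization with Mantegna Lévy-flight steps.

Cuckoo search maintains a population of candidate solutions ("nests").
Each iteration, every non-best nest takes a Lévy-flight step — a
heavy-tailed random walk mixing many short moves with occasional long
jumps — and the move is kept only if it improves the nest's fitness
(greedy replacement); the best nest is retained unchanged (elitism).
A discovery probability Pa then gates a second update round: with the
printed convention, each non-best nest whose uniform draw R exceeds Pa is
given another greedy Lévy update; the conventional reading (the worst Pa
fraction of nests abandoned and re-seeded at random) is available via
``abandon_convention="standard"``.

Lévy steps are drawn by Mantegna's method: s = u / |v|^(1/β) with
u ~ N(0, σ²), v ~ N(0, 1) and

    σ = { Γ(1+β) sin(πβ/2) / [ β Γ((1+β)/2) 2^((β-1)/2) ] }^(1/β).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma

__all__ = [
    "SearchSpace",
    "CSConfig",
    "CSResult",
    "mantegna_sigma",
    "levy_step",
    "update_nest",
    "cs_optimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded search space with integer or continuous dimensions."""

    bounds: tuple  # of (lower, upper) pairs
    types: tuple  # of "integer" | "continuous"

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.types):
            raise ValueError("bounds and types lengths differ")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each dimension needs lower < upper")
        for t in self.types:
            if t not in ("integer", "continuous"):
                raise ValueError(f"unknown dimension type {t!r}")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=np.float64)

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=np.float64)

    @property
    def ranges(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        out = np.clip(np.asarray(x, dtype=np.float64), self.lower, self.upper)
        for d, t in enumerate(self.types):
            if t == "integer":
                out[d] = np.clip(np.rint(out[d]), self.bounds[d][0], self.bounds[d][1])
        return out

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        x = self.lower + rng.random(self.ndim) * self.ranges
        return self.clip(x)


@dataclass(frozen=True)
class CSConfig:
    """Cuckoo-search settings.

    Defaults follow common practice for the nest count, iteration budget
    and discovery probability (20 / 25 / 0.25), a unit step factor and the
    usual Lévy exponent β = 1.5.  ``levy_scale`` expresses the raw Lévy
    step in units of each dimension's range (5% by default): unscaled
    steps on integer ranges of hundreds overshoot constantly, while scales
    at or below 1% stall before the walk resolves the optimum.
    """

    n_nests: int = 20
    n_iterations: int = 25
    pa: float = 0.25
    alpha: float = 1.0
    beta: float = 1.5
    levy_scale: float = 0.05
    abandon_convention: str = "paper"  # "paper" | "standard"
    fitness_target: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nests < 2:
            raise ValueError("n_nests must be >= 2")
        if not 0 <= self.pa <= 1:
            raise ValueError("pa must lie in [0, 1]")
        if not 0 < self.beta < 2:
            raise ValueError("beta must lie in (0, 2)")
        if self.abandon_convention not in ("paper", "standard"):
            raise ValueError("abandon_convention must be 'paper' or 'standard'")


@dataclass
class CSResult:
    best_params: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness per iteration, non-increasing
    evaluations: int


def mantegna_sigma(beta: float) -> float:
    """Scale σ of the numerator Gaussian in Mantegna's Lévy generator."""
    if not 0 < beta < 2:
        raise ValueError("beta must lie in (0, 2)")
    num = gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = beta * gamma((1.0 + beta) / 2.0) * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


def levy_step(beta: float, rng: np.random.Generator, size=None) -> np.ndarray | float:
    """Heavy-tailed step(s) s = u / |v|^(1/β) via Mantegna's method."""
    sigma = mantegna_sigma(beta)
    shape = () if size is None else (size if isinstance(size, tuple) else (size,))
    u = rng.normal(0.0, sigma, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    # measure-zero guard: redraw exact zeros of v
    while np.any(v == 0.0):
        mask = v == 0.0
        v = np.where(mask, rng.normal(0.0, 1.0, size=shape), v)
    s = u / np.abs(v) ** (1.0 / beta)
    return float(s) if size is None else s


def update_nest(x: np.ndarray, alpha: float, beta: float, space: SearchSpace,
                rng: np.random.Generator, levy_scale: float = 0.05) -> np.ndarray:
    """One Lévy-flight move: x' = x + α ⊙ Lévy step, clamped to bounds,
    integer dimensions rounded after clamping."""
    s = levy_step(beta, rng, size=space.ndim)
    return space.clip(np.asarray(x, dtype=np.float64)
                      + alpha * levy_scale * space.ranges * s)


def _safe_eval(objective, x: np.ndarray) -> float:
    try:
        f = float(objective(x))
    except Exception:
        return np.inf
    return f if np.isfinite(f) else np.inf


def cs_optimize(objective, space: SearchSpace, cfg: CSConfig | None = None,
                log=None) -> CSResult:
    """Minimize ``objective`` over ``space`` by cuckoo search.

    The best-so-far fitness is recorded once per iteration and is monotone
    non-increasing; total objective evaluations never exceed
    n_nests * (2 * n_iterations + 1).  A failing or non-finite objective
    marks the nest infeasible (infinite fitness) and the search continues.
    """
    if cfg is None:
        cfg = CSConfig()
    rng = np.random.default_rng(cfg.seed)
    nests = np.array([space.sample(rng) for _ in range(cfg.n_nests)])
    fits = np.array([_safe_eval(objective, x) for x in nests])
    evals = cfg.n_nests
    history = []

    def best_index() -> int:
        return int(np.argmin(fits))  # ties broken by lower index

    for it in range(cfg.n_iterations):
        b = best_index()
        # Lévy-update round with greedy replacement; best nest retained
        for i in range(cfg.n_nests):
            if i == b:
                continue
            cand = update_nest(nests[i], cfg.alpha, cfg.beta, space, rng,
                               cfg.levy_scale)
            f = _safe_eval(objective, cand)
            evals += 1
            if f < fits[i]:
                nests[i], fits[i] = cand, f
        b = best_index()
        # discovery / abandonment round
        if cfg.abandon_convention == "paper":
            for i in range(cfg.n_nests):
                if i == b:
                    continue
                if rng.random() > cfg.pa:
                    cand = update_nest(nests[i], cfg.alpha, cfg.beta, space,
                                       rng, cfg.levy_scale)
                    f = _safe_eval(objective, cand)
                    evals += 1
                    if f < fits[i]:
                        nests[i], fits[i] = cand, f
        else:
            order = np.argsort(-fits, kind="stable")  # worst first
            n_abandon = int(np.floor(cfg.pa * (cfg.n_nests - 1)))
            dropped = 0
            for i in order:
                if dropped >= n_abandon:
                    break
                if i == b:
                    continue
                nests[i] = space.sample(rng)
                fits[i] = _safe_eval(objective, nests[i])
                evals += 1
                dropped += 1
        b = best_index()
        history.append(fits[b])
        if log is not None:
            log(it + 1, fits[b], nests[b])
        if cfg.fitness_target is not None and fits[b] <= cfg.fitness_target:
            break

    b = best_index()
    hist = np.minimum.accumulate(np.array(history)) if history else np.array([fits[b]])
    return CSResult(best_params=nests[b].copy(), best_fitness=float(fits[b]),
                    history=hist, evaluations=evals)
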