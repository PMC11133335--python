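"""AIC-driven selection of the number of stacks (NS).

The number of block rows s of the Hankel matrix is the complexity dial of
the realization: more stacks capture more of the signal's dynamics at the
price of more model parameters. Selection proceeds in three nested stages:

1. *min-AIC* — evaluate a coarse dyadic grid NS = 2^k, refine around the
   minimizer by step halving, and accept NS* (the AIC minimizer) if its
   relative reconstruction error is below an acceptance threshold;
2. *neighboring* — otherwise try NS* +/- 10 and accept the better of the
   two if it meets the threshold;
3. *distant* — otherwise expand outward from NS* in steps of 10 within an
   evaluation budget and return the smallest NS whose relative error is
   acceptable, or failing that comparable (within a margin) to the best
   error seen anywhere.

The AIC uses the Gaussian log-likelihood form N*ln(RSS/N) + 2*k with
k = r^2 + r*p + q*r, the free-entry count of the fitted (A_r, B_r, C_r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .era import (
    InstabilityError,
    build_hankel_pair,
    era_realize,
    reconstruct_series,
)
from .metrics import relative_error

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "compute_aic",
    "coarse_grid",
    "select_ns",
    "evaluate_ns",
]

_RSS_GUARD = 1e-300  # keeps the log finite on numerically exact fits


@dataclass
class SelectionConfig:
    """Tunables of the NS search."""

    k_min: int = 1
    k_max: int = 13
    rel_err_accept: float = 0.25
    rank_rtol: float = 1e-10
    r_max: int | None = None
    neighbor_offset: int = 10
    distant_step: int = 10
    eval_budget: int = 50
    rel_err_margin: float = 1.2

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.rel_err_accept < 0:
            raise ValueError("rel_err_accept must be >= 0")


@dataclass
class Evaluation:
    ns: int
    aic: float
    rel_err: float
    rank: int


@dataclass
class SelectionResult:
    """Outcome of the three-stage NS search, with the full audit trail."""

    ns_selected: int
    strategy: str  # min_aic | neighboring | distant
    aic_curve: list[tuple[int, float]]
    rel_err: float
    rank_used: int
    evaluations: list[Evaluation] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ns_selected": self.ns_selected,
            "strategy": self.strategy,
            "rel_err": self.rel_err,
            "rank_used": self.rank_used,
            "aic_curve": [[int(ns), float(a)] for ns, a in self.aic_curve],
        }


def compute_aic(observed: np.ndarray, reconstructed: np.ndarray, n_params: int) -> float:
    """Gaussian AIC: N*ln(RSS/N + guard) + 2*n_params, N = total sample count."""
    obs = np.asarray(observed, dtype=float)
    rec = np.asarray(reconstructed, dtype=float)
    if obs.shape != rec.shape:
        raise ValueError(f"shape mismatch: {obs.shape} vs {rec.shape}")
    n = obs.size
    if n == 0:
        raise ValueError("empty series")
    rss = float(np.sum((obs - rec) ** 2))
    return n * float(np.log(rss / n + _RSS_GUARD)) + 2 * n_params


def coarse_grid(k_range: tuple[int, int], m: int) -> list[int]:
    """Dyadic NS candidates {2^k} clipped to the validity interval [1, m-2]."""
    if m < 4:
        raise ValueError(f"series of length {m} too short for any stack count")
    k_min, k_max = k_range
    cands = [2**k for k in range(k_min, k_max + 1) if 1 <= 2**k <= m - 2]
    if not cands:
        raise ValueError(
            f"no candidate NS = 2^k with k in [{k_min}, {k_max}] fits length {m}"
        )
    return cands


def evaluate_ns(series: np.ndarray, ns: int, config: SelectionConfig) -> Evaluation:
    """Fit one stack count: realize, replay, score.

    Instability or rank failure yields infinite AIC / RelErr so the search
    simply avoids the candidate.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    q, m = y.shape
    try:
        pair = build_hankel_pair(y, ns)
        real = era_realize(pair, rank_rtol=config.rank_rtol, r_max=config.r_max)
        rec = reconstruct_series(real, m)
    except (InstabilityError, ValueError, np.linalg.LinAlgError):
        return Evaluation(ns=ns, aic=np.inf, rel_err=np.inf, rank=0)
    r, p = real.r, real.p
    n_params = r * r + r * p + q * r
    aic = compute_aic(y, rec, n_params)
    return Evaluation(ns=ns, aic=aic, rel_err=relative_error(y, rec), rank=real.r)


def _argmin_aic(evals: dict[int, Evaluation]) -> Evaluation:
    """AIC minimizer; ties go to the smallest NS (parsimony)."""
    return min(evals.values(), key=lambda e: (e.aic, e.ns))


def select_ns(series: np.ndarray, config: SelectionConfig | None = None) -> SelectionResult:
    """Three-stage NS selection on one (already downsampled) phase series."""
    config = config or SelectionConfig()
    y = np.atleast_2d(np.asarray(series, dtype=float))
    m = y.shape[1]
    grid = coarse_grid((config.k_min, config.k_max), m)
    evals: dict[int, Evaluation] = {}

    def ev(ns: int) -> Evaluation:
        ns = int(ns)
        if ns not in evals:
            evals[ns] = evaluate_ns(y, ns, config)
        return evals[ns]

    for ns in grid:
        ev(ns)

    # Stage 1: refine around the coarse minimizer by step halving down to 1.
    best = _argmin_aic(evals)
    sorted_grid = sorted(grid)
    i = sorted_grid.index(best.ns) if best.ns in sorted_grid else 0
    lo = sorted_grid[i - 1] if i > 0 else 1
    hi = sorted_grid[i + 1] if i + 1 < len(sorted_grid) else min(2 * best.ns, m - 2)
    step = max(1, (hi - lo) // 2)
    current = best.ns
    while step >= 1:
        moved = False
        for cand in (current - step, current + step):
            if lo <= cand <= hi and 1 <= cand <= m - 2:
                e = ev(cand)
                if (e.aic, e.ns) < (evals[current].aic, current):
                    current = e.ns
                    moved = True
        if not moved:
            if step == 1:
                break
            step //= 2

    if not any(np.isfinite(e.aic) for e in evals.values()):
        raise RuntimeError(
            "NS search exhausted without any finite-AIC candidate; evaluated "
            f"NS = {sorted(evals)}"
        )

    star = _argmin_aic(evals)

    def result(chosen: Evaluation, strategy: str) -> SelectionResult:
        curve = sorted((ns, e.aic) for ns, e in evals.items())
        return SelectionResult(
            ns_selected=chosen.ns,
            strategy=strategy,
            aic_curve=curve,
            rel_err=chosen.rel_err,
            rank_used=chosen.rank,
            evaluations=sorted(evals.values(), key=lambda e: e.ns),
        )

    if star.rel_err <= config.rel_err_accept:
        return result(star, "min_aic")

    # Stage 2: neighboring values NS* +/- offset.
    neighbors = [
        ev(ns)
        for ns in (star.ns - config.neighbor_offset, star.ns + config.neighbor_offset)
        if 1 <= ns <= m - 2
    ]
    if neighbors:
        best_nb = min(neighbors, key=lambda e: (e.rel_err, e.ns))
        if best_nb.rel_err <= config.rel_err_accept:
            return result(best_nb, "neighboring")

    # Stage 3: expand outward from NS* until the budget runs out, then take
    # the most parsimonious candidate whose relative error is comparable to
    # the best seen (within rel_err_margin of the minimum).
    offset = 2 * config.distant_step
    while len(evals) < config.eval_budget:
        added = False
        for ns in (star.ns - offset, star.ns + offset):
            if 1 <= ns <= m - 2 and ns not in evals and len(evals) < config.eval_budget:
                ev(ns)
                added = True
        offset += config.distant_step
        if not added and offset > m:
            break
    finite = [e for e in evals.values() if np.isfinite(e.rel_err)]
    best_err = min(e.rel_err for e in finite)
    # parsimony: the smallest NS whose error is acceptable, or failing that
    # comparable (within rel_err_margin) to the best error found anywhere
    threshold = max(config.rel_err_accept, config.rel_err_margin * best_err)
    comparable = [e for e in finite if e.rel_err <= threshold]
    chosen = min(comparable, key=lambda e: e.ns)
    return result(chosen, "distant")
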