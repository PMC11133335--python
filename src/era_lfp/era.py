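"""Eigensystem Realization Algorithm: Hankel pair, SVD truncation, replay.

Given an observed q-channel series y_1..y_m treated as the impulse response
(Markov parameters) of an unknown discrete-time linear system, the method
stacks the samples into a block-Hankel matrix H and its one-step shift H',
truncates the SVD of H at rank r, and reads off a reduced realization

    A_r = S^{-1/2} U_r* H' V_r S^{-1/2}
    B_r = first p columns of S^{1/2} V_r*
    C_r = first q rows   of U_r S^{1/2}

whose impulse response reconstructs the observed series. The number of
block rows s (the "number of stacks", NS) is the tuning parameter selected
upstream; the truncation rank r defaults to the numerical rank of H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HankelPair",
    "LinearRealization",
    "InstabilityError",
    "build_hankel_pair",
    "era_realize",
    "reconstruct",
    "reconstruct_series",
    "numerical_rank",
]


class InstabilityError(RuntimeError):
    """Raised when replaying an identified system diverges."""


@dataclass
class HankelPair:
    """Shift-stacked data matrices H and H' for a given stack count s.

    Block (i, j) of H is y_{i+j-1} and of H' is y_{i+j} (1-based blocks),
    so H has shape (s*q) x (m-s) for a q-channel series of length m.
    ``p`` is the input dimension of the impulse convention (1 for observed
    vector series).
    """

    H: np.ndarray
    H_shift: np.ndarray
    s: int
    q: int
    p: int
    m: int

    def __post_init__(self) -> None:
        if self.H.shape != self.H_shift.shape:
            raise ValueError("H and H' must have identical shapes")
        if self.H.shape != (self.s * self.q, self.m - self.s):
            raise ValueError(
                f"H has shape {self.H.shape}, expected "
                f"({self.s * self.q}, {self.m - self.s})"
            )


@dataclass
class LinearRealization:
    """Reduced realization (A_r, B_r, C_r) with its stack count and rank."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    s: int
    r: int
    singular_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        r = self.A.shape[0]
        if self.A.shape != (r, r) or self.B.shape[0] != r or self.C.shape[1] != r:
            raise ValueError("inconsistent realization shapes")
        if r != self.r:
            raise ValueError("rank field disagrees with matrix shapes")

    @property
    def q(self) -> int:
        return self.C.shape[0]

    @property
    def p(self) -> int:
        return self.B.shape[1]


def build_hankel_pair(series: np.ndarray, s: int) -> HankelPair:
    """Block-Hankel pair of a q x m series y_1..y_m.

    The k = 0 sample (identically zero under the impulse convention) is not
    part of ``series``; its first column is y_1. Valid stack counts are
    1 <= s <= m - 2 so that H' is well defined.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    q, m = y.shape
    if not 1 <= s <= m - 2:
        raise ValueError(
            f"stack count s={s} outside the valid interval [1, {m - 2}] "
            f"for a series of length {m}"
        )
    cols = m - s
    H = np.empty((s * q, cols))
    Hs = np.empty((s * q, cols))
    for i in range(s):
        H[i * q:(i + 1) * q, :] = y[:, i:i + cols]
        Hs[i * q:(i + 1) * q, :] = y[:, i + 1:i + 1 + cols]
    return HankelPair(H=H, H_shift=Hs, s=s, q=q, p=1, m=m)


def numerical_rank(singular_values: np.ndarray, rtol: float = 1e-10) -> int:
    """Count of singular values above ``rtol`` times the largest."""
    sv = np.asarray(singular_values)
    if sv.size == 0 or sv[0] <= 0:
        return 0
    return int(np.sum(sv > rtol * sv[0]))


def _signed_svd(H: np.ndarray):
    """SVD with a deterministic sign convention.

    The largest-magnitude entry of each left singular vector is forced
    non-negative (earliest index on ties), with the matching right singular
    vector flipped accordingly, so identical inputs yield identical factors.
    """
    U, sv, Vt = np.linalg.svd(H, full_matrices=False)
    for k in range(sv.size):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k, :] = -Vt[k, :]
    return U, sv, Vt


def era_realize(
    pair: HankelPair,
    r: int | None = None,
    *,
    rank_rtol: float = 1e-10,
    r_max: int | None = None,
) -> LinearRealization:
    """SVD-truncated realization from a Hankel pair.

    ``r`` defaults to the numerical rank of H (singular values above
    ``rank_rtol`` times the largest), optionally capped by ``r_max``.
    Requesting a rank beyond the numerical rank raises, naming the rank.
    """
    U, sv, Vt = _signed_svd(pair.H)
    nrank = numerical_rank(sv, rank_rtol)
    if nrank == 0:
        raise ValueError("Hankel matrix is numerically zero; nothing to realize")
    if r is None:
        r = nrank if r_max is None else min(nrank, r_max)
    if not 1 <= r <= nrank:
        raise ValueError(
            f"requested rank r={r} exceeds the numerical rank {nrank} of H"
        )
    sqrt_s = np.sqrt(sv[:r])
    Ur = U[:, :r]
    Vtr = Vt[:r, :]
    A = (Ur.T @ pair.H_shift @ Vtr.T) / np.outer(sqrt_s, sqrt_s)
    B = (sqrt_s[:, None] * Vtr)[:, :pair.p]
    C = (Ur * sqrt_s[None, :])[:pair.q, :]
    return LinearRealization(A=A, B=B, C=C, s=pair.s, r=r, singular_values=sv)


def reconstruct(
    realization: LinearRealization,
    m: int,
    *,
    state_norm_ceiling: float = 1e12,
) -> np.ndarray:
    """Impulse response y_0..y_{m-1} of a realization, shape (q, m).

    y_0 = 0 and y_k = C_r A_r^{k-1} B_r for k >= 1, computed by iterated
    state propagation (never explicit matrix powers); inputs follow the same
    collapsed-impulse convention as identification, so the state is seeded
    with the row sums of B_r. If the state norm ever exceeds
    ``state_norm_ceiling`` times its initial norm, the realization is
    unstable at this horizon and an :class:`InstabilityError` is raised
    instead of returning non-finite values.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    q = realization.q
    y = np.zeros((q, m))
    x = realization.B @ np.ones(realization.p)
    x0_norm = float(np.linalg.norm(x))
    ceiling = state_norm_ceiling * max(x0_norm, 1.0)
    for k in range(1, m):
        y[:, k] = realization.C @ x
        x = realization.A @ x
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > ceiling:
            raise InstabilityError(
                f"state norm exceeded {ceiling:.3e} at step {k} of {m}; "
                f"identified A (s={realization.s}, r={realization.r}) is unstable "
                "at this horizon"
            )
    return y


def reconstruct_series(
    realization: LinearRealization,
    m: int,
    *,
    state_norm_ceiling: float = 1e12,
) -> np.ndarray:
    """Reconstruction aligned with an observed series y_1..y_m (no k=0 zero)."""
    return reconstruct(
        realization, m + 1, state_norm_ceiling=state_norm_ceiling
    )[:, 1:]
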