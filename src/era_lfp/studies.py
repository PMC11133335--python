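"""Canned validation studies: parameter recovery and statistical power.

These are the package's desk-scale analogs of the biological findings the
pipeline is built around: exact recovery of known linear systems from their
impulse responses, decay of the selected stack count across a synthetic
euthanasia schedule, and the power of the group comparison at small sample
sizes. Problem sizes are chosen so each study runs in minutes on one CPU;
docs/methods.md discusses what they do and do not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .era import build_hankel_pair, era_realize, reconstruct_series
from .groups import mann_whitney, partition_phases, synthetic_ns_table
from .metrics import relative_error
from .pipeline import RunConfig, _phase_series
from .selection import SelectionConfig, select_ns
from .synthetic import SyntheticConfig, generate_state_space_system, generate_synthetic_lfp

__all__ = [
    "exact_recovery_study",
    "ns_decay_study",
    "mann_whitney_power_study",
    "NsDecayResult",
]


def eigenvalue_multiset_error(A_true: np.ndarray, A_est: np.ndarray) -> float:
    """Largest matched distance between two eigenvalue multisets."""
    ea, eb = np.linalg.eigvals(A_true), np.linalg.eigvals(A_est)
    cost = np.abs(ea[:, None] - eb[None, :])
    r, c = linear_sum_assignment(cost)
    return float(cost[r, c].max())


def exact_recovery_study(n_systems: int = 20, seed: int = 0):
    """Recover random stable systems from noise-free impulse responses.

    Orders cycle through 1..8 with 1-4 inputs/outputs; series length 8n,
    stack count 2n, truncation rank n. Returns the worst relative
    reconstruction error and worst eigenvalue multiset error.
    """
    worst_rel = worst_eig = 0.0
    for i in range(n_systems):
        n = (i % 8) + 1
        qp = (i % 4) + 1
        sys_ = generate_state_space_system(
            n, n_inputs=qp, n_outputs=qp, spectral_radius=0.9, seed=seed + i
        )
        from .synthetic import impulse_response

        y = impulse_response(sys_, 8 * n).samples[:, 1:]
        real = era_realize(build_hankel_pair(y, 2 * n), n)
        rec = reconstruct_series(real, y.shape[1])
        worst_rel = max(worst_rel, relative_error(y, rec))
        worst_eig = max(worst_eig, eigenvalue_multiset_error(sys_.A, real.A))
    return worst_rel, worst_eig


@dataclass
class NsDecayResult:
    ns_by_seed: np.ndarray          # seeds x phases
    median_ns: np.ndarray           # per phase
    strategies: list[list[str]] = field(default_factory=list)

    @property
    def non_increasing(self) -> bool:
        return bool(np.all(np.diff(self.median_ns) <= 0))

    @property
    def monotone_fraction(self) -> float:
        """Fraction of adjacent median pairs that do not increase."""
        d = np.diff(self.median_ns)
        return float(np.mean(d <= 0)) if d.size else 1.0


def ns_decay_study(
    n_seeds: int = 10,
    base_seed: int = 0,
    rate: float = 250.0,
    phase_duration: float = 8.0,
) -> NsDecayResult:
    """Select NS per phase on synthetic euthanasia recordings.

    The generator uses its default 7-phase schedules (system order,
    amplitude and spectral ceiling all strictly decreasing); the recording
    is smoothed, change-point downsampled onto an adaptive grid and
    NS-selected phase by phase. The headline statistic is the per-phase
    median selected NS across seeds, which should not increase along the
    schedule.
    """
    all_ns: list[list[int]] = []
    strategies: list[list[str]] = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = SyntheticConfig(rate=rate, phase_duration=phase_duration, seed=seed)
        rec = generate_synthetic_lfp(cfg)
        run_cfg = RunConfig(
            synthetic=cfg, seed=seed, cp_penalty=0.03, target_points=900,
            smoothing_window=7,
            selection=SelectionConfig(k_min=1, k_max=9, rank_rtol=0.02),
        )
        seq, strat = [], []
        for seg in partition_phases(rec, cfg.phase_duration):
            series, _ = _phase_series(seg.recording, run_cfg)
            sel = select_ns(series, run_cfg.selection)
            seq.append(sel.ns_selected)
            strat.append(sel.strategy)
        all_ns.append(seq)
        strategies.append(strat)
    arr = np.array(all_ns)
    return NsDecayResult(
        ns_by_seed=arr, median_ns=np.median(arr, axis=0), strategies=strategies
    )


def mann_whitney_power_study(
    n_replicates: int = 200,
    n_per_group: int = 5,
    gap_sd: float = 4.0,
    alpha: float = 0.01,
    base_seed: int = 0,
) -> float:
    """Rejection rate of the two-sided exact Mann-Whitney U test on
    synthetic complexity tables with a prescribed group separation."""
    hits = 0
    for i in range(n_replicates):
        table = synthetic_ns_table(
            n_per_group=n_per_group, gap_sd=gap_sd, n_phases=1,
            seed=base_seed + i,
        )
        a = table.loc[table.group == "AW", "ns"].to_numpy()
        b = table.loc[table.group == "AN", "ns"].to_numpy()
        if mann_whitney(a, b).p_value <= alpha:
            hits += 1
    return hits / n_replicates
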