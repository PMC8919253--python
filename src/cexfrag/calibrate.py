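"""Engineering known break probabilities in the surrogate.

The surrogate's purpose is to validate the analysis chain, and the sharpest
validation is parameter recovery: configure the generator so a chosen bond
class breaks with a known probability, then check that the estimated
probability agrees.  The dial is the bond-weakening factor applied to the
class (``ForceFieldParams.scaled_bonds``: k and D scaled together); the
class break probability is a smooth, monotonically decreasing function of
it once each run draws fresh Maxwell-Boltzmann velocities, so runs are
independent Bernoulli trials.

Calibration fits a two-parameter logistic dose-response curve
p(s) = 1 / (1 + exp((s - s0)/w)) to break fractions measured on a probe
grid of weakening factors and returns the factor at the target probability.
Evaluation must then use run seeds disjoint from the calibration seeds.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .chem import MolecularGraph
from .forcefield import ForceFieldParams
from .integrity import (
    DEFAULT_DECAY_SCALE,
    DEFAULT_PERSISTENCE_FS,
    DEFAULT_THRESHOLD,
    broken_bonds,
)
from .simulate import SimulationConfig, explode


def class_break_fraction(
    graph: MolecularGraph,
    ff_charged: ForceFieldParams,
    frames,
    baselines: dict,
    class_members,
    cfg: SimulationConfig,
    seeds,
    resample_velocities: bool = True,
    threshold: float = DEFAULT_THRESHOLD,
    persistence_fs: float = DEFAULT_PERSISTENCE_FS,
    decay_scale: float = DEFAULT_DECAY_SCALE,
) -> float:
    """Fraction of runs in which ANY member of the bond class broke.

    Run i starts from ``frames[i % len(frames)]``; with velocity resampling
    (the default here) ``seeds[i]`` drives an independent Maxwell-Boltzmann
    draw, so each run is an independent Bernoulli trial.
    """
    members = [frozenset(m) for m in class_members]
    events = 0
    for i, seed in enumerate(seeds):
        run_cfg = SimulationConfig(
            time_step_fs=cfg.time_step_fs,
            duration_ps=cfg.duration_ps,
            temperature_K=cfg.temperature_K,
            seed=int(seed),
            save_stride=cfg.save_stride,
        )
        traj = explode(
            frames[i % len(frames)],
            graph,
            ff_charged,
            run_cfg,
            resample_velocities=resample_velocities,
        )
        br = broken_bonds(traj, baselines, threshold, persistence_fs, decay_scale)
        events += any(m in br for m in members)
    return events / len(seeds)


def _logistic_mle(scales, events, trials):
    """MLE of (s0, w) for p(s) = 1/(1 + exp((s - s0)/w)), w > 0."""
    scales = np.asarray(scales, float)
    events = np.asarray(events, float)
    trials = np.asarray(trials, float)

    def nll(theta):
        s0, logw = theta
        p = 1.0 / (1.0 + np.exp((scales - s0) / np.exp(logw)))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(
            (events * np.log(p) + (trials - events) * np.log(1 - p)).sum()
        )

    best = None
    for s0_init in (scales.mean(), scales.min(), scales.max()):
        res = minimize(nll, [s0_init, np.log(0.05)], method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(np.exp(best.x[1]))


def calibrate_class_weakening(
    graph: MolecularGraph,
    ff_charged: ForceFieldParams,
    frames,
    baselines: dict,
    class_members,
    cfg: SimulationConfig,
    target: float = 0.5,
    probe_scales=(1.0, 0.9, 0.8, 0.7, 0.6),
    n_coarse: int = 25,
    n_refine: int = 55,
    refine_offsets=(-0.05, 0.0, 0.05),
    seed_base: int = 10_000,
) -> float:
    """Weakening factor at which the class breaks with probability ``target``.

    Two stages: a coarse probe grid locates the dose-response curve, then a
    high-count bracket around the estimated crossing pins it down; the
    logistic is refit on the pooled data and inverted at ``target``.  Seeds
    run upward from ``seed_base``; evaluation seeds must stay below it.
    """
    scales, events, trials = [], [], []
    seed = seed_base

    def probe(scale: float, n: int) -> None:
        nonlocal seed
        ff = ff_charged.scaled_bonds(class_members, scale)
        f = class_break_fraction(
            graph, ff, frames, baselines, class_members, cfg,
            seeds=seed + np.arange(n),
        )
        seed += n
        scales.append(scale)
        events.append(f * n)
        trials.append(n)

    for s in probe_scales:
        probe(s, n_coarse)
    s0, w = _logistic_mle(scales, events, trials)
    s_cross = s0 + w * np.log(1.0 / target - 1.0)
    lo, hi = min(probe_scales), max(probe_scales)
    s_cross = float(np.clip(s_cross, lo, hi))
    for off in refine_offsets:
        probe(float(np.clip(s_cross + off, lo, hi)), n_refine)
    s0, w = _logistic_mle(scales, events, trials)
    s_target = s0 + w * np.log(1.0 / target - 1.0)
    return float(np.clip(s_target, lo, hi))
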