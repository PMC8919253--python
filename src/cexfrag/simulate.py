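"""Trajectory generation: thermalization, configuration sampling, explosion.

The protocol emulated here is the standard two-stage recipe for modelling
X-ray-induced Coulomb explosion of a gas-phase ion: (1) thermalize the
singly protonated molecule near 300 K with a weak-coupling (Berendsen)
thermostat, (2) draw well-separated starting configurations from the
thermal trajectory, (3) from each, run a microcanonical (NVE)
velocity-Verlet production trajectory of the suddenly ionized +3 system
with a 0.5 fs time step for 1 ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem import MolecularGraph
from .forcefield import ForceFieldParams, PotentialEvaluator, atom_masses
from .units import ACC_CONV, kinetic_energy, kinetic_temperature


@dataclass
class SimulationConfig:
    """Protocol parameters (units: fs, ps, K)."""

    time_step_fs: float = 0.5
    duration_ps: float = 1.0  # production-run length
    temperature_K: float = 300.0
    coupling_ps: float = 0.1  # Berendsen time constant
    ensemble_size: int = 18
    min_separation_ps: float = 1.0  # between sampled starting configs
    seed: int = 0
    thermal_duration_ps: float | None = None  # default: (n-1)*separation + 1
    save_stride: int = 1  # store every k-th integration step

    def __post_init__(self) -> None:
        if self.time_step_fs <= 0:
            raise ValueError("time step must be positive")
        if self.duration_ps * 1000.0 < self.time_step_fs:
            raise ValueError("duration shorter than one time step")
        if self.ensemble_size < 1:
            raise ValueError("ensemble size must be >= 1")

    @property
    def thermal_ps(self) -> float:
        if self.thermal_duration_ps is not None:
            return self.thermal_duration_ps
        return (self.ensemble_size - 1) * self.min_separation_ps + 1.0


@dataclass
class Frame:
    time_fs: float
    positions: np.ndarray  # (N,3) Å
    velocities: np.ndarray  # (N,3) Å/fs


@dataclass
class Trajectory:
    """Uniformly spaced frames plus provenance metadata.

    ``energies`` holds total (kinetic + potential) energy in eV per stored
    frame for conservation diagnostics; it is not part of the XYZ round trip.
    """

    times_fs: np.ndarray  # (F,)
    positions: np.ndarray  # (F,N,3) Å
    velocities: np.ndarray  # (F,N,3) Å/fs
    metadata: dict = field(default_factory=dict)
    energies: np.ndarray | None = None

    def __post_init__(self) -> None:
        dt = np.diff(self.times_fs)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ValueError("frame times must be uniformly spaced")
        if self.positions.shape[0] != len(self.times_fs):
            raise ValueError("frame count mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.times_fs)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def frame(self, k: int) -> Frame:
        return Frame(
            float(self.times_fs[k]),
            self.positions[k].copy(),
            self.velocities[k].copy(),
        )


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature_K: float, rng: np.random.Generator
) -> np.ndarray:
    """Seeded Maxwell-Boltzmann draw (Å/fs), centre-of-mass motion removed."""
    from .units import EV_PER_U_A2_FS2, KB

    sigma = np.sqrt(KB * temperature_K / (masses * EV_PER_U_A2_FS2))
    v = rng.standard_normal((len(masses), 3)) * sigma[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def _integrate(
    pos: np.ndarray,
    vel: np.ndarray,
    masses: np.ndarray,
    ev: PotentialEvaluator,
    n_steps: int,
    dt: float,
    save_stride: int,
    t0: float = 0.0,
    berendsen: tuple | None = None,  # (T0, tau_fs) or None for NVE
):
    """Velocity-Verlet core; returns (times, positions, velocities, energies)."""
    inv_m = (ACC_CONV / masses)[:, None]
    e_pot, f = ev.energy_forces(pos)
    times, P, V, E = [t0], [pos.copy()], [vel.copy()], [
        e_pot + kinetic_energy(masses, vel)
    ]
    for step in range(1, n_steps + 1):
        vel = vel + 0.5 * dt * f * inv_m
        pos = pos + dt * vel
        e_pot, f = ev.energy_forces(pos)
        if not np.isfinite(pos).all() or not np.isfinite(f).all():
            raise FloatingPointError(f"integration diverged at step {step}")
        vel = vel + 0.5 * dt * f * inv_m
        if berendsen is not None:
            t_target, tau = berendsen
            t_now = kinetic_temperature(masses, vel)
            if t_now > 1e-12:
                lam = np.sqrt(1.0 + (dt / tau) * (t_target / t_now - 1.0))
                vel = vel * lam
        if step % save_stride == 0:
            times.append(t0 + step * dt)
            P.append(pos.copy())
            V.append(vel.copy())
            E.append(e_pot + kinetic_energy(masses, vel))
    return (np.array(times), np.array(P), np.array(V), np.array(E))


def thermalize(
    graph: MolecularGraph,
    ff: ForceFieldParams,
    cfg: SimulationConfig,
    start_positions: np.ndarray | None = None,
    start_velocities: np.ndarray | None = None,
) -> Trajectory:
    """Weak-coupling (Berendsen) thermalization run.

    Initial velocities are a seeded Maxwell-Boltzmann draw at the target
    temperature unless given explicitly; each integration step rescales
    velocities by lambda = sqrt(1 + (dt/tau)(T0/T - 1)).  Deterministic for
    a fixed seed.
    """
    _check_ff_coverage(graph, ff)
    masses = atom_masses(graph)
    if start_positions is None:
        from .geometry import reference_geometry

        start_positions = reference_geometry(graph, ff)
    if start_velocities is not None:
        vel = np.asarray(start_velocities, float).copy()
    else:
        rng = np.random.default_rng(cfg.seed)
        vel = maxwell_boltzmann_velocities(masses, cfg.temperature_K, rng)
    ev = PotentialEvaluator(ff, graph.n_atoms)
    n_steps = int(round(cfg.thermal_ps * 1000.0 / cfg.time_step_fs))
    t, p, v, e = _integrate(
        start_positions.copy(),
        vel,
        masses,
        ev,
        n_steps,
        cfg.time_step_fs,
        cfg.save_stride,
        berendsen=(cfg.temperature_K, cfg.coupling_ps * 1000.0),
    )
    meta = {
        "stage": "thermalization",
        "seed": cfg.seed,
        "charge": ff.total_charge(),
        "thermostat": "berendsen",
        "dt_fs": cfg.time_step_fs,
        "ff_hash": ff.content_hash(),
    }
    return Trajectory(t, p, v, meta, e)


def sample_starting_configs(traj: Trajectory, cfg: SimulationConfig) -> list:
    """n frames from a thermal trajectory, pairwise >= min_separation apart.

    Frames are taken from the end of the run backwards (the best-equilibrated
    part), then returned in time order.
    """
    n = cfg.ensemble_size
    sep_fs = cfg.min_separation_ps * 1000.0
    span = float(traj.times_fs[-1] - traj.times_fs[0])
    if span < (n - 1) * sep_fs:
        raise ValueError(
            f"trajectory spans {span:.0f} fs; need >= {(n - 1) * sep_fs:.0f} fs "
            f"for {n} configs {sep_fs:.0f} fs apart"
        )
    frames = []
    t_want = float(traj.times_fs[-1])
    for _ in range(n):
        k = int(np.searchsorted(traj.times_fs, t_want, side="right") - 1)
        frames.append(traj.frame(k))
        t_want = float(traj.times_fs[k]) - sep_fs
    return frames[::-1]


def explode(
    start: Frame,
    graph: MolecularGraph,
    ff_charged: ForceFieldParams,
    cfg: SimulationConfig,
    resample_velocities: bool = False,
) -> Trajectory:
    """Microcanonical explosion run from one starting frame.

    No thermostat: the sudden switch to the charged force field injects the
    Coulomb repulsion energy and velocity-Verlet propagates it.  By default
    the starting frame's thermal velocities are kept; ``resample_velocities``
    draws a fresh seeded Maxwell-Boltzmann set instead.
    """
    _check_ff_coverage(graph, ff_charged)
    masses = atom_masses(graph)
    if start.positions.shape != (graph.n_atoms, 3):
        raise ValueError("starting frame does not match topology atom count")
    vel = start.velocities.copy()
    if resample_velocities:
        rng = np.random.default_rng(cfg.seed)
        vel = maxwell_boltzmann_velocities(masses, cfg.temperature_K, rng)
    ev = PotentialEvaluator(ff_charged, graph.n_atoms)
    n_steps = int(round(cfg.duration_ps * 1000.0 / cfg.time_step_fs))
    t, p, v, e = _integrate(
        start.positions.copy(),
        vel,
        masses,
        ev,
        n_steps,
        cfg.time_step_fs,
        cfg.save_stride,
    )
    meta = {
        "stage": "explosion",
        "seed": cfg.seed,
        "charge": ff_charged.total_charge(),
        "thermostat": "none",
        "dt_fs": cfg.time_step_fs,
        "ff_hash": ff_charged.content_hash(),
    }
    return Trajectory(t, p, v, meta, e)


def _check_ff_coverage(graph: MolecularGraph, ff: ForceFieldParams) -> None:
    covered = {frozenset({b.i, b.j}) for b in ff.bond_terms}
    missing = graph.bonds - covered
    if missing:
        raise ValueError(f"force field missing parameters for {len(missing)} bonds")
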