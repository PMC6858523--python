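"""Langevin molecular dynamics and gradient-based HOMO-LUMO gap design.

The integrator is BAOAB splitting: half kick, half drift, Ornstein-Uhlenbeck
velocity update, half drift, half kick.  With temperature 0 and infinite
friction time it reduces exactly to velocity Verlet, which is the NVE limit
used for energy-conservation and time-reversibility checks.  The same
integrator runs on any force provider -- the synthetic reference surface or a
trained model -- through one shared interface (``energy_forces``).

Units: positions Angstrom, time fs, masses amu, energies eV.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .chem import ATOMIC_MASSES, Molecule
from .properties import DegeneracyError, gap_gradient, homo_lumo_gap, solve_orbitals

KB_EV = 8.617333262e-5           # Boltzmann constant, eV/K
EV_PER_AMU_A2_FS2 = 103.642697   # 1 amu Angstrom^2 / fs^2 in eV
ACCEL = 1.0 / EV_PER_AMU_A2_FS2  # (eV/Angstrom)/amu -> Angstrom/fs^2


class PropagationError(RuntimeError):
    """Non-finite force or energy during propagation."""


@dataclasses.dataclass
class MDConfig:
    timestep: float = 0.5        # fs
    temperature: float = 300.0   # K
    friction_time: float = 100.0 # fs; np.inf disables the thermostat
    n_steps: int = 1000
    seed: int = 0
    stride: int = 1              # record every stride-th step
    masses: dict = None          # element Z -> amu; default standard masses

    def __post_init__(self):
        if self.timestep <= 0 or self.friction_time <= 0:
            raise ValueError("timestep and friction_time must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclasses.dataclass
class Trajectory:
    positions: np.ndarray        # (n_frames, n_atoms, 3), Angstrom
    velocities: np.ndarray       # Angstrom/fs
    potential: np.ndarray        # eV
    kinetic: np.ndarray          # eV
    temperature: np.ndarray      # K
    times: np.ndarray            # fs

    @property
    def total_energy(self):
        return self.potential + self.kinetic


def _masses(mol: Molecule, cfg: MDConfig) -> np.ndarray:
    table = cfg.masses or ATOMIC_MASSES
    return np.array([table[z] for z in mol.atomic_numbers], float)


def maxwell_boltzmann_velocities(mol: Molecule, temperature: float, seed,
                                 masses=None) -> np.ndarray:
    """Seeded Maxwell-Boltzmann draw with center-of-mass motion removed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = np.array([(masses or ATOMIC_MASSES)[z] for z in mol.atomic_numbers], float)
    if temperature <= 0:
        return np.zeros((mol.n_atoms, 3))
    sig = np.sqrt(KB_EV * temperature * ACCEL / m)
    v = rng.normal(size=(mol.n_atoms, 3)) * sig[:, None]
    v -= (m[:, None] * v).sum(0) / m.sum()
    return v


def kinetic_energy(v: np.ndarray, m: np.ndarray) -> float:
    return 0.5 * EV_PER_AMU_A2_FS2 * float((m[:, None] * v * v).sum())


def instantaneous_temperature(v: np.ndarray, m: np.ndarray) -> float:
    return 2.0 * kinetic_energy(v, m) / (3.0 * len(m) * KB_EV)


def langevin_md(provider, mol: Molecule, cfg: MDConfig,
                velocities: np.ndarray = None) -> Trajectory:
    """Propagate with BAOAB Langevin dynamics on the provider's surface."""
    m = _masses(mol, cfg)
    rng = np.random.default_rng(cfg.seed)
    pos = mol.positions.copy()
    vel = maxwell_boltzmann_velocities(mol, cfg.temperature, rng, cfg.masses) \
        if velocities is None else np.asarray(velocities, float).copy()

    gamma = 0.0 if np.isinf(cfg.friction_time) else 1.0 / cfg.friction_time
    dt = cfg.timestep
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0) * KB_EV * cfg.temperature * ACCEL / m)

    def eval_forces(p):
        E, F = provider.energy_forces(mol.with_positions(p))
        if not (np.isfinite(E) and np.all(np.isfinite(F))):
            raise PropagationError(f"non-finite energy/forces at step {step}")
        return E, F

    step = 0
    E, F = eval_forces(pos)
    n_frames = cfg.n_steps // cfg.stride + 1
    traj = Trajectory(*(np.zeros((n_frames,) + s) for s in
                        ((mol.n_atoms, 3), (mol.n_atoms, 3), (), (), (), ())))

    def record(frame):
        traj.positions[frame] = pos
        traj.velocities[frame] = vel
        traj.potential[frame] = E
        traj.kinetic[frame] = kinetic_energy(vel, m)
        traj.temperature[frame] = instantaneous_temperature(vel, m)
        traj.times[frame] = step * dt

    record(0)
    for step in range(1, cfg.n_steps + 1):
        vel = vel + 0.5 * dt * ACCEL * F / m[:, None]          # B
        pos = pos + 0.5 * dt * vel                             # A
        if gamma > 0.0:                                        # O
            vel = c1 * vel + c2[:, None] * rng.normal(size=vel.shape)
        pos = pos + 0.5 * dt * vel                             # A
        E, F = eval_forces(pos)
        vel = vel + 0.5 * dt * ACCEL * F / m[:, None]          # B
        if step % cfg.stride == 0:
            record(step // cfg.stride)
    return traj


# -- HOMO-LUMO gap optimization ----------------------------------------

@dataclasses.dataclass
class GapOptimizationResult:
    molecule: Molecule           # final geometry
    gap_trace: list              # accepted-step gap values, eV (first = start)
    converged: bool
    message: str = ""


def _gap(provider, mol, n_electrons):
    H, S = provider.matrices(mol)
    return homo_lumo_gap(solve_orbitals(H, S, n_electrons))


def optimize_gap(provider, mol: Molecule, n_electrons: int, mode: str = "max",
                 step: float = 0.01, max_iter: int = 100, tol: float = 1e-4,
                 min_step: float = 1e-6) -> GapOptimizationResult:
    """Gradient ascent (``mode='max'``) or descent (``'min'``) on the gap.

    Follows +-step * grad(eps_gap); a trial move that changes the gap in the
    wrong direction halves the step instead of being accepted, so the trace of
    accepted gaps is monotone in the requested direction.  Trial geometries
    with interatomic distances below 0.5 Angstrom are rejected the same way
    (the surrogate surfaces are not meaningful there).
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    sign = 1.0 if mode == "max" else -1.0
    pos = mol.positions.copy()
    gap = _gap(provider, mol, n_electrons)
    trace = [gap]
    message, converged = "max_iter reached", False
    for _ in range(max_iter):
        try:
            g = gap_gradient(provider, mol.with_positions(pos), n_electrons)
        except DegeneracyError as err:
            message, converged = f"halted: {err}", False
            break
        accepted = False
        while step >= min_step:
            trial = pos + sign * step * g
            d = np.linalg.norm(trial[:, None] - trial[None, :], axis=-1)
            if np.any(d[np.triu_indices(len(trial), k=1)] < 0.5):
                step *= 0.5
                continue
            try:
                trial_gap = _gap(provider, mol.with_positions(trial), n_electrons)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if sign * (trial_gap - gap) > 0:
                delta = abs(trial_gap - gap)
                pos, gap = trial, trial_gap
                trace.append(gap)
                accepted = True
                step *= 1.25            # cautious growth after an accepted move
                if delta < tol:
                    message, converged = "converged: |delta gap| < tol", True
                break
            step *= 0.5
        if not accepted:
            message, converged = "no improving step above min_step", True
            break
        if converged:
            break
    return GapOptimizationResult(mol.with_positions(pos), trace, converged, message)
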