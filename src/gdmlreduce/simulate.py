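"""Synthetic molecular systems, thermal sampling, and an MD engine.

The toy potential-energy surface emulates the statistical structure of
ab-initio reference data for flexible molecules: stiff short-range bonded
terms (harmonic bonds and angles, cosine dihedrals) superposed on soft
long-range nonbonded interactions (Lennard-Jones plus screened Coulomb,
q_i q_j e^{−r/ℓ}/r).  Energies and forces are analytic and exact, so the
generated datasets carry noise-free labels.

The MD engine integrates NVE with velocity Verlet and Langevin dynamics
with the BAOAB splitting, optionally with a constant steering force of
equal magnitude and opposite direction on two chosen atoms (the
constant-force pulling protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (ACC_FACTOR, COULOMB_CONSTANT, KB,
                        KCAL_MOL_ANG_TO_PN, mass_of)
from .dataio import AtomicConfiguration, LabeledDataset


class IntegrationError(RuntimeError):
    """Unstable integration (energy overflow / NaN coordinates)."""


@dataclass
class ToyTopology:
    """Force-field terms of a synthetic bead molecule."""

    n_atoms: int
    atomic_numbers: np.ndarray
    bonds: np.ndarray        # (B, 2)
    bond_r0: np.ndarray      # Å
    bond_k: np.ndarray       # kcal mol⁻¹ Å⁻²
    angles: np.ndarray       # (A, 3), central atom second
    angle_theta0: np.ndarray  # rad
    angle_k: np.ndarray      # kcal mol⁻¹ rad⁻²
    dihedrals: np.ndarray    # (D, 4)
    dihedral_amp: np.ndarray  # kcal mol⁻¹
    dihedral_mult: np.ndarray  # integer multiplicity
    nonbonded_pairs: np.ndarray  # (P, 2); 1-2 and 1-3 pairs excluded
    lj_eps: np.ndarray       # kcal mol⁻¹ per pair
    lj_sigma: np.ndarray     # Å per pair
    charges: np.ndarray      # e per atom
    screening_length: float  # Å
    masses: np.ndarray = None  # amu; default from atomic numbers
    kind: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.masses is None:
            self.masses = np.array([mass_of(z) for z in self.atomic_numbers])
        if np.any(self.bonds >= self.n_atoms) or np.any(self.bonds < 0):
            raise ValueError("bond references an invalid atom")
        if np.any(self.bond_k < 0) or np.any(self.angle_k < 0):
            raise ValueError("negative stiffness")
        bonded = {tuple(sorted(b)) for b in self.bonds.tolist()}
        nb = {tuple(sorted(p)) for p in self.nonbonded_pairs.tolist()}
        if bonded & nb:
            raise ValueError("excluded (bonded) pairs appear in nonbonded list")


@dataclass
class MDTrajectory:
    """Sampled time series of an MD run (canonical units)."""

    times: np.ndarray              # fs
    positions: np.ndarray          # (S, N, 3) Å
    velocities: np.ndarray         # (S, N, 3) Å fs⁻¹
    potential_energy: np.ndarray   # kcal mol⁻¹
    kinetic_energy: np.ndarray
    total_energy: np.ndarray
    gyration_radii: np.ndarray     # Å
    timestep: float                # fs
    events: list = field(default_factory=list)
    thermostat: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.times.size


def _exclusion_pairs(bonds, n_atoms):
    """1-2 and 1-3 pairs implied by a bond list."""
    adj = [set() for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    excl = {tuple(sorted((a, b))) for a, b in bonds}
    for center in range(n_atoms):
        neigh = sorted(adj[center])
        for i in range(len(neigh)):
            for j in range(i + 1, len(neigh)):
                excl.add((neigh[i], neigh[j]))
    return excl


def build_toy_molecule(kind: str, n_atoms: int, seed: int = 0,
                       bond_r0: float = 1.5, bond_k: float = 300.0,
                       angle_theta0: float = 1.9111, angle_k: float = 60.0,
                       dihedral_amp: float = 1.2, dihedral_mult: int = 3,
                       lj_eps: float = 0.1, lj_sigma: float = 3.4,
                       charge_scale: float = 0.25,
                       screening_length: float = 10.0) -> ToyTopology:
    """Deterministic bead-molecule topology.

    ``chain``: linear backbone with alternating partial charges (long-range
    electrostatic structure, a peptide/fatty-acid analogue). ``ring``:
    closed chain. ``dimer``: two covalent fragments bound only by nonbonded
    terms (base-pair/host–guest analogue).  Charges get a small seeded
    jitter so no two beads are exactly equivalent.
    """
    rng = np.random.default_rng(seed)
    if kind in ("chain", "ring"):
        if n_atoms < 4:
            raise ValueError(f"{kind} needs at least 4 atoms")
        closed = kind == "ring"
        nb = n_atoms if closed else n_atoms - 1
        bonds = np.array([[i, (i + 1) % n_atoms] for i in range(nb)])
        na = n_atoms if closed else n_atoms - 2
        angles = np.array([[i, (i + 1) % n_atoms, (i + 2) % n_atoms]
                           for i in range(na)])
        nd = n_atoms if closed else n_atoms - 3
        dihedrals = np.array([[i, (i + 1) % n_atoms, (i + 2) % n_atoms,
                               (i + 3) % n_atoms] for i in range(nd)])
        charges = charge_scale * np.where(np.arange(n_atoms) % 2 == 0, 1, -1)
    elif kind == "dimer":
        if n_atoms < 6:
            raise ValueError("dimer needs at least 6 atoms")
        n1 = n_atoms // 2
        def frag(start, length):
            b = [[start + i, start + i + 1] for i in range(length - 1)]
            a = [[start + i, start + i + 1, start + i + 2]
                 for i in range(length - 2)]
            d = [[start + i, start + i + 1, start + i + 2, start + i + 3]
                 for i in range(length - 3)]
            return b, a, d
        b1, a1, d1 = frag(0, n1)
        b2, a2, d2 = frag(n1, n_atoms - n1)
        bonds = np.array(b1 + b2)
        angles = np.array(a1 + a2)
        dihedrals = np.array(d1 + d2) if d1 + d2 else np.empty((0, 4), int)
        # opposite alternating patterns so the fragments attract
        charges = np.empty(n_atoms)
        charges[:n1] = charge_scale * np.where(np.arange(n1) % 2 == 0, 1, -1)
        charges[n1:] = -charge_scale * np.where(
            np.arange(n_atoms - n1) % 2 == 0, 1, -1)
    else:
        raise ValueError(f"unknown toy-molecule kind {kind!r}")

    charges = charges * (1.0 + 0.2 * rng.uniform(-1, 1, n_atoms))
    excl = _exclusion_pairs(bonds, n_atoms)
    pairs = [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)
             if (i, j) not in excl]
    nonbonded = np.array(pairs) if pairs else np.empty((0, 2), int)
    np_count = nonbonded.shape[0]
    return ToyTopology(
        n_atoms=n_atoms,
        atomic_numbers=np.full(n_atoms, 6),
        bonds=bonds, bond_r0=np.full(len(bonds), bond_r0),
        bond_k=np.full(len(bonds), bond_k),
        angles=angles, angle_theta0=np.full(len(angles), angle_theta0),
        angle_k=np.full(len(angles), angle_k),
        dihedrals=dihedrals,
        dihedral_amp=np.full(len(dihedrals), dihedral_amp),
        dihedral_mult=np.full(len(dihedrals), dihedral_mult, dtype=int),
        nonbonded_pairs=nonbonded,
        lj_eps=np.full(np_count, lj_eps), lj_sigma=np.full(np_count, lj_sigma),
        charges=charges, screening_length=screening_length,
        kind=kind, seed=seed,
    )


def initial_configuration(topology: ToyTopology,
                          seed: int = 0) -> AtomicConfiguration:
    """Reasonable starting geometry (zig-zag chain / circle / stacked pair)."""
    rng = np.random.default_rng(seed)
    n = topology.n_atoms
    r0 = float(topology.bond_r0[0]) if len(topology.bond_r0) else 1.5
    theta = float(topology.angle_theta0[0]) if len(topology.angle_theta0) \
        else 1.9111

    def zigzag(length, offset=np.zeros(3)):
        dx = r0 * np.sin(theta / 2.0)
        dy = r0 * np.cos(theta / 2.0)
        pts = np.zeros((length, 3))
        pts[:, 0] = dx * np.arange(length)
        pts[:, 1] = dy * (np.arange(length) % 2)
        return pts + offset

    if topology.kind == "ring":
        radius = n * r0 / (2.0 * np.pi)
        ang = 2.0 * np.pi * np.arange(n) / n
        coords = np.column_stack([radius * np.cos(ang),
                                  radius * np.sin(ang), np.zeros(n)])
    elif topology.kind == "dimer":
        n1 = n // 2
        coords = np.vstack([zigzag(n1),
                            zigzag(n - n1, offset=np.array([0.0, 4.0, 0.0]))])
    else:
        coords = zigzag(n)
    coords = coords + 0.02 * rng.standard_normal(coords.shape)
    return AtomicConfiguration(topology.atomic_numbers, coords)


def toy_energy_forces(topology: ToyTopology, coords) -> tuple:
    """Exact analytic energy (kcal mol⁻¹) and forces (kcal (mol Å)⁻¹)."""
    if isinstance(coords, AtomicConfiguration):
        coords = coords.coordinates
    coords = np.asarray(coords, dtype=np.float64)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coordinates do not match topology")
    energy = 0.0
    forces = np.zeros_like(coords)

    # harmonic bonds
    if len(topology.bonds):
        ai, aj = topology.bonds[:, 0], topology.bonds[:, 1]
        dv = coords[ai] - coords[aj]
        r = np.linalg.norm(dv, axis=1)
        if np.any(r == 0):
            raise IntegrationError("coincident bonded atoms")
        dr = r - topology.bond_r0
        energy += float(np.sum(topology.bond_k * dr * dr))
        fmag = (-2.0 * topology.bond_k * dr / r)[:, None] * dv
        np.add.at(forces, ai, fmag)
        np.add.at(forces, aj, -fmag)

    # harmonic angles
    if len(topology.angles):
        a, b, c = (topology.angles[:, 0], topology.angles[:, 1],
                   topology.angles[:, 2])
        u = coords[a] - coords[b]
        v = coords[c] - coords[b]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.maximum(np.sqrt(1.0 - cos_t * cos_t), 1e-8)
        dt = theta - topology.angle_theta0
        energy += float(np.sum(topology.angle_k * dt * dt))
        # ∂cosθ/∂r_a and ∂cosθ/∂r_c, then θ-chain rule
        dcos_da = (v / nv[:, None] - cos_t[:, None] * u / nu[:, None]) \
            / nu[:, None]
        dcos_dc = (u / nu[:, None] - cos_t[:, None] * v / nv[:, None]) \
            / nv[:, None]
        coef = (2.0 * topology.angle_k * dt / sin_t)[:, None]
        fa = coef * dcos_da
        fc = coef * dcos_dc
        np.add.at(forces, a, fa)
        np.add.at(forces, c, fc)
        np.add.at(forces, b, -(fa + fc))

    # cosine dihedrals E = A(1 + cos mφ)
    if len(topology.dihedrals):
        a, b, c, d = (topology.dihedrals[:, 0], topology.dihedrals[:, 1],
                      topology.dihedrals[:, 2], topology.dihedrals[:, 3])
        b1 = coords[b] - coords[a]
        b2 = coords[c] - coords[b]
        b3 = coords[d] - coords[c]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        phi = np.arctan2(y, x)
        amp, mult = topology.dihedral_amp, topology.dihedral_mult
        energy += float(np.sum(amp * (1.0 + np.cos(mult * phi))))
        de_dphi = -amp * mult * np.sin(mult * phi)
        n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 1e-12)
        n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 1e-12)
        # signs fixed by the atan2(m1·n2, n1·n2) convention above
        dphi_da = (nb2 / n1sq)[:, None] * n1
        dphi_dd = (-nb2 / n2sq)[:, None] * n2
        t12 = (np.einsum("ij,ij->i", b1, b2) / nb2 ** 2)[:, None]
        t32 = (np.einsum("ij,ij->i", b3, b2) / nb2 ** 2)[:, None]
        dphi_db = -(1.0 + t12) * dphi_da + t32 * dphi_dd
        dphi_dc = t12 * dphi_da - (1.0 + t32) * dphi_dd
        for idx, dphi in ((a, dphi_da), (b, dphi_db),
                          (c, dphi_dc), (d, dphi_dd)):
            np.add.at(forces, idx, -de_dphi[:, None] * dphi)

    # nonbonded: Lennard-Jones + screened Coulomb
    if len(topology.nonbonded_pairs):
        pi = topology.nonbonded_pairs[:, 0]
        pj = topology.nonbonded_pairs[:, 1]
        dv = coords[pi] - coords[pj]
        r = np.linalg.norm(dv, axis=1)
        if np.any(r == 0):
            raise IntegrationError("coincident nonbonded atoms")
        sr6 = (topology.lj_sigma / r) ** 6
        e_lj = 4.0 * topology.lj_eps * (sr6 * sr6 - sr6)
        de_lj = 4.0 * topology.lj_eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        q = COULOMB_CONSTANT * topology.charges[pi] * topology.charges[pj]
        ell = topology.screening_length
        e_c = q * np.exp(-r / ell) / r
        de_c = -e_c * (1.0 / r + 1.0 / ell)
        energy += float(np.sum(e_lj) + np.sum(e_c))
        fpair = (-(de_lj + de_c) / r)[:, None] * dv
        np.add.at(forces, pi, fpair)
        np.add.at(forces, pj, -fpair)

    return energy, forces


class ToyPES:
    """Force provider wrapping a toy topology."""

    def __init__(self, topology: ToyTopology):
        self.topology = topology

    def energy_forces(self, coords):
        return toy_energy_forces(self.topology, coords)


class ModelPES:
    """Force provider wrapping a trained kernel model."""

    def __init__(self, model):
        self.model = model

    def energy_forces(self, coords):
        from .gdml import predict_energy_forces
        return predict_energy_forces(self.model, coords)


def as_force_provider(obj):
    if hasattr(obj, "energy_forces"):
        return obj
    if isinstance(obj, ToyTopology):
        return ToyPES(obj)
    from .gdml import GDMLModel
    if isinstance(obj, GDMLModel):
        return ModelPES(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as force provider")


def boltzmann_velocities(masses: np.ndarray, temperature: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Maxwell–Boltzmann velocities (Å fs⁻¹) at the given temperature."""
    std = np.sqrt(KB * temperature * ACC_FACTOR / masses)
    return std[:, None] * rng.standard_normal((masses.size, 3))


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Kinetic energy in kcal mol⁻¹ from amu and Å fs⁻¹."""
    return float(0.5 * np.sum(masses[:, None] * velocities ** 2) / ACC_FACTOR)


def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    return 2.0 * kinetic_energy(masses, velocities) / (3.0 * masses.size * KB)


def run_md(force_provider, initial: AtomicConfiguration, mode: str = "nve",
           dt: float = 0.5, n_steps: int = 1000, temperature: float = 300.0,
           friction: float = 0.01, external_force=None, seed: int = 0,
           sample_interval: int = 10, initial_velocities: str = "boltzmann",
           masses: np.ndarray = None, pull_mode: str = "instantaneous",
           pull_shared: bool = False) -> MDTrajectory:
    """Velocity-Verlet / BAOAB-Langevin dynamics with optional steering.

    ``external_force`` is ``((atom_a, atom_b), magnitude_pN)``; forces of
    ±magnitude act on the two atoms along their connecting line
    (re-evaluated each step unless ``pull_mode="fixed"``), pulling them
    apart.  By default the magnitude applies per atom; ``pull_shared``
    halves it.  In NVE mode steering makes the run non-conservative; it is
    recorded in the trajectory's thermostat/protocol record.
    """
    if dt <= 0:
        raise ValueError("timestep must be positive")
    if mode not in ("nve", "langevin"):
        raise ValueError(f"unknown mode {mode!r}")
    provider = as_force_provider(force_provider)
    rng = np.random.default_rng(seed)
    if masses is None:
        top = getattr(provider, "topology", None)
        masses = top.masses.copy() if top is not None else \
            np.array([mass_of(z) for z in initial.atomic_numbers])
    coords = initial.coordinates.copy()
    if initial_velocities == "boltzmann":
        vel = boltzmann_velocities(masses, temperature, rng)
    elif initial_velocities == "zero":
        vel = np.zeros_like(coords)
    else:
        raise ValueError(f"unknown initial_velocities {initial_velocities!r}")

    pull = None
    if external_force is not None:
        (pa, pb), mag_pn = external_force
        mag = mag_pn / KCAL_MOL_ANG_TO_PN
        if pull_shared:
            mag *= 0.5
        fixed_axis = None
        if pull_mode == "fixed":
            axis = coords[pb] - coords[pa]
            fixed_axis = axis / np.linalg.norm(axis)
        elif pull_mode != "instantaneous":
            raise ValueError(f"unknown pull_mode {pull_mode!r}")
        pull = (int(pa), int(pb), mag, fixed_axis)

    def eval_forces(r):
        e, f = provider.energy_forces(r)
        f = np.array(f, dtype=np.float64, copy=True)
        if pull is not None:
            pa, pb, mag, fixed_axis = pull
            if fixed_axis is None:
                axis = r[pb] - r[pa]
                axis = axis / np.linalg.norm(axis)
            else:
                axis = fixed_axis
            f[pb] += mag * axis
            f[pa] -= mag * axis
        return e, f

    events = []
    times, pos_s, vel_s, pe_s, ke_s, rg_s = [], [], [], [], [], []

    def record(step, e_pot):
        from .analysis import gyration_radius_coords
        times.append(step * dt)
        pos_s.append(coords.copy())
        vel_s.append(vel.copy())
        pe_s.append(e_pot)
        ke_s.append(kinetic_energy(masses, vel))
        rg_s.append(gyration_radius_coords(coords))

    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma_v = np.sqrt(KB * temperature * ACC_FACTOR / masses)[:, None]
    inv_m = (ACC_FACTOR / masses)[:, None]

    e_pot, f = eval_forces(coords)
    record(0, e_pot)
    for step in range(1, n_steps + 1):
        vel = vel + 0.5 * dt * f * inv_m
        if mode == "nve":
            coords = coords + dt * vel
        else:
            coords = coords + 0.5 * dt * vel
            vel = c1 * vel + c2 * sigma_v * rng.standard_normal(vel.shape)
            coords = coords + 0.5 * dt * vel
        if not np.all(np.isfinite(coords)):
            events.append({"type": "nan", "time": step * dt})
            break
        e_pot, f = eval_forces(coords)
        if not np.isfinite(e_pot) or abs(e_pot) > 1e12:
            events.append({"type": "energy_overflow", "time": step * dt})
            break
        vel = vel + 0.5 * dt * f * inv_m
        if step % sample_interval == 0:
            record(step, e_pot)

    pe = np.array(pe_s)
    ke = np.array(ke_s)
    return MDTrajectory(
        times=np.array(times), positions=np.array(pos_s),
        velocities=np.array(vel_s), potential_energy=pe, kinetic_energy=ke,
        total_energy=pe + ke, gyration_radii=np.array(rg_s), timestep=dt,
        events=events,
        thermostat={"mode": mode, "temperature": temperature,
                    "friction": friction, "seed": seed,
                    "external_force_pN": None if external_force is None
                    else float(external_force[1]),
                    "pull_mode": pull_mode},
    )


def generate_dataset(topology: ToyTopology, temperature: float = 300.0,
                     n_samples: int = 100, stride: int = 10, dt: float = 0.5,
                     seed: int = 0, equilibration_steps: int = 2000,
                     friction: float = 0.02) -> LabeledDataset:
    """Thermally sampled labeled dataset from Langevin dynamics on the toy PES.

    Runs BAOAB Langevin at the target temperature from the canonical
    starting geometry, discards the equilibration segment, and keeps one
    frame every ``stride`` steps, labeled with exact analytic energies and
    forces.  Bit-reproducible for a given seed.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    init = initial_configuration(topology, seed=seed)
    n_steps = equilibration_steps + n_samples * stride
    traj = run_md(ToyPES(topology), init, mode="langevin", dt=dt,
                  n_steps=n_steps, temperature=temperature, friction=friction,
                  seed=seed, sample_interval=stride)
    if traj.events:
        raise IntegrationError(
            f"sampling dynamics unstable ({traj.events[0]['type']}); "
            "reduce the timestep"
        )
    keep = traj.positions[-n_samples:]
    configs, energies, forces = [], [], []
    for frame in keep:
        e, f = toy_energy_forces(topology, frame)
        configs.append(AtomicConfiguration(topology.atomic_numbers, frame))
        energies.append(e)
        forces.append(f)
    return LabeledDataset(
        configs, np.array(energies), np.array(forces),
        name=f"toy-{topology.kind}-{topology.n_atoms}",
        provenance=(f"generate_dataset:kind={topology.kind};"
                    f"n={topology.n_atoms};T={temperature};dt={dt};"
                    f"stride={stride};seed={seed};prng=PCG64"),
    )


def detect_instability(trajectory: MDTrajectory, topology: ToyTopology,
                       clash_cutoff: float = 0.7,
                       fragment_factor: float = 2.5) -> list:
    """Steric-clash and fragmentation events over the sampled frames.

    A clash is any nonbonded pair closer than ``clash_cutoff`` Å; a
    fragmentation is any bond stretched beyond ``fragment_factor`` times its
    equilibrium length.  Events carry the sample time stamp.
    """
    if trajectory.n_samples == 0:
        raise ValueError("empty trajectory")
    events = list(trajectory.events)
    nb = topology.nonbonded_pairs
    bonds = topology.bonds
    for s in range(trajectory.n_samples):
        coords = trajectory.positions[s]
        t = float(trajectory.times[s])
        if len(nb):
            r = np.linalg.norm(coords[nb[:, 0]] - coords[nb[:, 1]], axis=1)
            for idx in np.flatnonzero(r < clash_cutoff):
                events.append({"type": "clash", "time": t,
                               "pair": tuple(int(v) for v in nb[idx]),
                               "distance": float(r[idx])})
        if len(bonds):
            r = np.linalg.norm(coords[bonds[:, 0]] - coords[bonds[:, 1]],
                               axis=1)
            limit = fragment_factor * topology.bond_r0
            for idx in np.flatnonzero(r > limit):
                events.append({"type": "fragmentation", "time": t,
                               "pair": tuple(int(v) for v in bonds[idx]),
                               "distance": float(r[idx])})
    return events
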