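"""Classical MD and time-correlation-function (TCF) spectroscopy.

Any object exposing ``energy/forces/dipole/polarizability(system)`` can be
propagated: the trained model and the analytic toy oracle share this
protocol.  The driver follows the usual recipe for vibrational spectra:
equilibrate in the NVT ensemble with an Andersen thermostat, launch an
ensemble of NVE segments from decorrelated snapshots, record the dipole
and polarizability along each segment under the protocol's applied field,
and Fourier-transform the autocorrelation of their time derivatives.

IR intensity comes from the TCF of μ̇; Raman is split into an isotropic
part (TCF of d tr(α)/3 dt, rotation-invariant, purely vibrational) and an
anisotropic part (TCF of the traceless tensor derivative, Frobenius
contraction), which carries the rotational structure.

Estimator choices (documented, not prescribed by the physics): central
finite differences for the time derivative with one-sided ends, a Hann
window on the lag axis, zero padding to the next power of two, and no
quantum correction factor on the classical TCF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .systems import AtomicSystem, ParameterError
from .units import C_CM_PER_FS, FORCE_TO_ACC, KB, masses_for

__all__ = [
    "MDState",
    "MDProtocol",
    "Trajectory",
    "Spectrum",
    "velocity_verlet_step",
    "andersen_thermostat",
    "maxwell_boltzmann_velocities",
    "run_md",
    "correct_dipole_branch",
    "tcf",
    "ir_spectrum",
    "polarizability_decompose",
    "raman_spectra",
]


@dataclass
class MDState:
    """Instantaneous MD state; positions Å, velocities Å fs⁻¹, masses amu."""

    system: AtomicSystem          # template carrying species/cell/pbc/field
    velocities: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)

    @property
    def positions(self) -> np.ndarray:
        return self.system.positions

    def kinetic_energy(self) -> float:
        """Kinetic energy in eV."""
        return float(
            0.5 * np.sum(self.masses * np.sum(self.velocities ** 2, axis=1))
            / FORCE_TO_ACC
        )

    @classmethod
    def from_system(cls, system: AtomicSystem, velocities=None) -> "MDState":
        masses = masses_for(system.species)
        if velocities is None:
            velocities = np.zeros_like(system.positions)
        return cls(system, velocities, masses)


@dataclass
class Trajectory:
    """Uniform-grid trajectory with recorded response properties."""

    dt: float                      # fs
    positions: np.ndarray          # (T, N, 3)
    velocities: np.ndarray         # (T, N, 3)
    energies: np.ndarray           # (T,) potential, eV
    dipoles: np.ndarray            # (T, 3)
    polarizabilities: Optional[np.ndarray] = None   # (T, 3, 3)
    thermostat: Dict = dc_field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.energies)


@dataclass
class Spectrum:
    """Wavenumber axis (cm⁻¹, increasing from 0) and intensity (arb.)."""

    wavenumber: np.ndarray
    intensity: np.ndarray
    meta: Dict = dc_field(default_factory=dict)

    def peak(self) -> float:
        """Wavenumber of the global intensity maximum (skipping the ω=0 bin)."""
        return float(self.wavenumber[1:][np.argmax(self.intensity[1:])])


# ---------------------------------------------------------------------------
# integrators


def velocity_verlet_step(state: MDState, model, dt: float,
                         forces: Optional[np.ndarray] = None
                         ) -> Tuple[MDState, np.ndarray]:
    """One symplectic velocity-Verlet step; returns (state, new forces).

    Passing the forces of the current state avoids re-evaluating them (the
    integrator then costs one force call per step).
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if forces is None:
        forces = model.forces(state.system)
    a0 = forces / state.masses[:, None] * FORCE_TO_ACC
    new_pos = state.positions + state.velocities * dt + 0.5 * a0 * dt * dt
    new_system = state.system.with_positions(new_pos)
    new_forces = model.forces(new_system)
    a1 = new_forces / state.masses[:, None] * FORCE_TO_ACC
    new_vel = state.velocities + 0.5 * (a0 + a1) * dt
    return MDState(new_system, new_vel, state.masses), new_forces


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    sigma = np.sqrt(KB * temperature * FORCE_TO_ACC / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def andersen_thermostat(state: MDState, temperature: float,
                        collision_prob: float, rng: np.random.Generator) -> MDState:
    """Resample each atom's velocity from Maxwell–Boltzmann with the given
    per-step collision probability; rate 0 leaves the state untouched."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    hit = rng.random(len(state.masses)) < collision_prob
    if not hit.any():
        return state
    vel = state.velocities.copy()
    vel[hit] = maxwell_boltzmann_velocities(state.masses, temperature, rng)[hit]
    return MDState(state.system, vel, state.masses)


@dataclass
class MDProtocol:
    """NVT equilibration followed by an ensemble of NVE sampling segments."""

    temperature: float = 300.0     # K
    dt: float = 0.1                # fs
    equil_steps: int = 2000
    n_segments: int = 4
    segment_steps: int = 2000
    gap_steps: int = 200           # NVT decorrelation between segment launches
    collision_prob: float = 0.02   # Andersen collision probability per step
    seed: int = 0
    record_alpha: bool = True


def run_md(system: AtomicSystem, model, protocol: MDProtocol) -> List[Trajectory]:
    """NVT equilibration, then ``n_segments`` NVE segments launched from
    decorrelated thermostatted snapshots; per-frame energy, dipole and
    (optionally) polarizability are recorded under the system's field."""
    rng = np.random.default_rng(protocol.seed)
    state = MDState.from_system(system)
    state = MDState(state.system,
                    maxwell_boltzmann_velocities(state.masses, protocol.temperature, rng),
                    state.masses)
    forces = model.forces(state.system)
    for _ in range(protocol.equil_steps):
        state, forces = velocity_verlet_step(state, model, protocol.dt, forces)
        state = andersen_thermostat(state, protocol.temperature,
                                    protocol.collision_prob, rng)

    segments: List[Trajectory] = []
    for _seg in range(protocol.n_segments):
        for _ in range(protocol.gap_steps):
            state, forces = velocity_verlet_step(state, model, protocol.dt, forces)
            state = andersen_thermostat(state, protocol.temperature,
                                        protocol.collision_prob, rng)
        seg_state = MDState(state.system, state.velocities.copy(), state.masses)
        seg_forces = forces
        n = protocol.segment_steps
        pos = np.empty((n, seg_state.system.n_atoms, 3))
        vel = np.empty_like(pos)
        ene = np.empty(n)
        dip = np.empty((n, 3))
        alp = np.empty((n, 3, 3)) if protocol.record_alpha else None
        for t in range(n):
            pos[t] = seg_state.positions
            vel[t] = seg_state.velocities
            ene[t] = model.energy(seg_state.system)
            dip[t] = model.dipole(seg_state.system)
            if protocol.record_alpha:
                alp[t] = model.polarizability(seg_state.system)
            seg_state, seg_forces = velocity_verlet_step(
                seg_state, model, protocol.dt, seg_forces)
        segments.append(Trajectory(
            dt=protocol.dt, positions=pos, velocities=vel, energies=ene,
            dipoles=dip, polarizabilities=alp,
            thermostat={"ensemble": "NVE", "T_init": protocol.temperature,
                        "seed": protocol.seed},
        ))
    return segments


# ---------------------------------------------------------------------------
# branch correction


def correct_dipole_branch(series: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Greedy sequential removal of polarization-quantum jumps.

    Each frame is shifted by the integer combination of e·(lattice vectors)
    that brings it closest to the previous corrected frame, producing a
    continuous series (up to the global branch of the first frame).
    """
    series = np.asarray(series, dtype=float).reshape(-1, 3)
    cell = np.asarray(cell, dtype=float).reshape(3, 3)
    if abs(np.linalg.det(cell)) < 1e-12:
        raise ParameterError("singular cell")
    out = series.copy()
    cellT = cell.T
    inv = np.linalg.inv(cellT)
    for t in range(1, len(series)):
        k = np.round(inv @ (out[t - 1] - series[t]))
        out[t] = series[t] + cellT @ k
    return out


# ---------------------------------------------------------------------------
# time-correlation functions and spectra


def _time_derivative(series: np.ndarray, dt: float) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends."""
    d = np.empty_like(series)
    d[1:-1] = (series[2:] - series[:-2]) / (2 * dt)
    d[0] = (series[1] - series[0]) / dt
    d[-1] = (series[-1] - series[-2]) / dt
    return d


def tcf(series: np.ndarray, max_lag: int, dt: float = 1.0) -> np.ndarray:
    """Autocorrelation of the time derivative of ``series``.

    ``series`` may be (T,), (T, 3) or (T, 3, 3); trailing axes are
    contracted (Frobenius for tensors).  Returns C(τ) for τ = 0..max_lag in
    frame units.
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[0]
    if T < 2:
        raise ParameterError("need at least two frames for a TCF")
    if max_lag >= T:
        max_lag = T - 1
    d = _time_derivative(series, dt).reshape(T, -1)
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        out[lag] = np.mean(np.sum(d[: T - lag] * d[lag:], axis=1))
    return out


def _spectrum_from_tcf(c: np.ndarray, dt: float, meta: Dict) -> Spectrum:
    n = len(c)
    window = 0.5 * (1 + np.cos(np.pi * np.arange(n) / max(n - 1, 1)))  # Hann half
    cw = c * window
    nfft = 1 << int(math.ceil(math.log2(max(4 * n, 8))))
    ft = np.fft.rfft(cw, n=nfft)
    freq = np.fft.rfftfreq(nfft, d=dt)          # 1 / fs
    wavenumber = freq / C_CM_PER_FS             # cm⁻¹
    intensity = np.maximum(ft.real, 0.0)
    meta = dict(meta, window="hann", nfft=nfft, dt_fs=dt)
    return Spectrum(wavenumber, intensity, meta)


def _avg_tcf(segments: Sequence[Trajectory], extract, max_lag: Optional[int]) -> Tuple[np.ndarray, float]:
    if len(segments) == 0:
        raise ParameterError("empty trajectory ensemble")
    dt = segments[0].dt
    if max_lag is None:
        max_lag = min(s.n_frames for s in segments) // 2
    acc = np.zeros(max_lag + 1)
    for seg in segments:
        if abs(seg.dt - dt) > 1e-12:
            raise ParameterError("segments must share the time step")
        acc += tcf(extract(seg), max_lag, seg.dt)
    return acc / len(segments), dt


def ir_spectrum(segments: Sequence[Trajectory], max_lag: Optional[int] = None) -> Spectrum:
    """IR spectrum: Fourier transform of the ensemble-averaged TCF of μ̇."""
    c, dt = _avg_tcf(segments, lambda s: s.dipoles, max_lag)
    return _spectrum_from_tcf(c, dt, {"kind": "IR"})


def polarizability_decompose(alphas: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split α(t) into α_iso = tr(α)/3 (scalar series) and the traceless
    anisotropic remainder α − α_iso·I."""
    alphas = np.asarray(alphas, dtype=float)
    single = alphas.ndim == 2
    a = alphas[None] if single else alphas
    iso = np.trace(a, axis1=-2, axis2=-1) / 3.0
    aniso = a - iso[:, None, None] * np.eye(3)
    if single:
        return float(iso[0]), aniso[0]
    return iso, aniso


def raman_spectra(segments: Sequence[Trajectory],
                  max_lag: Optional[int] = None) -> Tuple[Spectrum, Spectrum]:
    """(isotropic, anisotropic) Raman spectra from the polarizability TCFs."""

    def iso_series(seg: Trajectory):
        if seg.polarizabilities is None:
            raise ParameterError("trajectory has no polarizability record")
        return polarizability_decompose(seg.polarizabilities)[0]

    def aniso_series(seg: Trajectory):
        if seg.polarizabilities is None:
            raise ParameterError("trajectory has no polarizability record")
        return polarizability_decompose(seg.polarizabilities)[1]

    c_iso, dt = _avg_tcf(segments, iso_series, max_lag)
    c_aniso, _ = _avg_tcf(segments, aniso_series, max_lag)
    return (
        _spectrum_from_tcf(c_iso, dt, {"kind": "Raman-iso"}),
        _spectrum_from_tcf(c_aniso, dt, {"kind": "Raman-aniso"}),
    )
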