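"""MD integrators, thermostat statistics, branch correction, TCF spectra."""

import numpy as np
import pytest

from fieldpot import AtomicSystem
from fieldpot.dynamics import (
    MDProtocol,
    MDState,
    Trajectory,
    andersen_thermostat,
    correct_dipole_branch,
    ir_spectrum,
    maxwell_boltzmann_velocities,
    polarizability_decompose,
    raman_spectra,
    run_md,
    tcf,
    velocity_verlet_step,
)
from fieldpot.synthetic import OracleModel, ToyModelParams, gen_h2o_toy, wrap_dipole
from fieldpot.units import FORCE_TO_ACC, KB


class SpringModel:
    """One atom tethered harmonically to the origin (test integrator oracle)."""

    def __init__(self, k=10.0):
        self.k = k

    def energy(self, system):
        return 0.5 * self.k * float(np.sum(system.positions ** 2))

    def forces(self, system):
        return -self.k * system.positions

    def dipole(self, system):
        return np.zeros(3)

    def polarizability(self, system):
        return np.zeros((3, 3))


class FreeModel(SpringModel):
    def __init__(self):
        super().__init__(k=0.0)


def _state(pos, vel, species=("H",)):
    return MDState.from_system(
        AtomicSystem(species, pos), velocities=np.asarray(vel, dtype=float)
    )


def test_verlet_energy_conservation_harmonic():
    """Symplectic integration shows no secular energy drift on the harmonic
    oscillator: the windowed mean energy moves ≤ 1e-6 relative over 1e5
    steps at dt = T/100, and the bounded fluctuation stays at the (ω dt)²
    scale."""
    model = SpringModel(k=10.0)
    m = 1.00794
    omega = np.sqrt(model.k / m * FORCE_TO_ACC)   # rad / fs
    dt = 2 * np.pi / omega / 100.0
    state = _state([[0.3, 0.0, 0.0]], [[0.0, 0.0, 0.0]])
    e0 = model.energy(state.system) + state.kinetic_energy()
    forces = model.forces(state.system)
    energies = np.empty(100_000)
    for i in range(100_000):
        state, forces = velocity_verlet_step(state, model, dt, forces)
        energies[i] = model.energy(state.system) + state.kinetic_energy()
    drift = abs(energies[-1000:].mean() - energies[:1000].mean()) / e0
    assert drift < 1e-6
    assert np.max(np.abs(energies - e0)) / e0 < 2 * (omega * dt) ** 2


def test_verlet_zero_forces_linear_motion():
    state = _state([[0.0, 0.0, 0.0]], [[0.01, -0.02, 0.03]])
    model = FreeModel()
    for _ in range(100):
        state, _ = velocity_verlet_step(state, model, 0.5)
    assert np.allclose(state.positions, 50 * np.array([0.01, -0.02, 0.03]),
                       atol=1e-12)


def test_verlet_time_reversal():
    model = SpringModel(k=5.0)
    state = _state([[0.2, 0.1, -0.3]], [[0.01, 0.0, -0.02]])
    start = state.positions.copy()
    for _ in range(500):
        state, _ = velocity_verlet_step(state, model, 0.1)
    state = MDState(state.system, -state.velocities, state.masses)
    for _ in range(500):
        state, _ = velocity_verlet_step(state, model, 0.1)
    assert np.max(np.abs(state.positions - start)) < 1e-10


def test_andersen_equipartition():
    """Ideal-gas toy reaches ⟨KE⟩/atom = (3/2) k_B T within 2%."""
    rng = np.random.default_rng(8)
    n, T = 64, 300.0
    state = MDState.from_system(
        AtomicSystem(("H",) * n, rng.uniform(0, 10, (n, 3))),
        velocities=np.zeros((n, 3)),
    )
    model = FreeModel()
    samples = []
    for step in range(4000):
        state, _ = velocity_verlet_step(state, model, 1.0)
        state = andersen_thermostat(state, T, 0.1, rng)
        if step > 500:
            samples.append(state.kinetic_energy() / n)
    mean_ke = np.mean(samples)
    assert abs(mean_ke - 1.5 * KB * T) / (1.5 * KB * T) < 0.02


def test_andersen_zero_rate_is_nve():
    rng = np.random.default_rng(1)
    state = _state([[0.1, 0.0, 0.0]], [[0.01, 0.0, 0.0]])
    out = andersen_thermostat(state, 300.0, 0.0, rng)
    assert np.array_equal(out.velocities, state.velocities)


def test_andersen_reproducible():
    state = _state([[0.1, 0.0, 0.0]], [[0.01, 0.0, 0.0]])
    a = andersen_thermostat(state, 300.0, 1.0, np.random.default_rng(7))
    b = andersen_thermostat(state, 300.0, 1.0, np.random.default_rng(7))
    assert np.array_equal(a.velocities, b.velocities)


def test_run_md_protocol_shapes(toy):
    model = OracleModel(toy)
    system = gen_h2o_toy(toy)[0].system
    proto = MDProtocol(temperature=200.0, dt=0.2, equil_steps=20,
                       n_segments=2, segment_steps=30, gap_steps=5, seed=3)
    segments = run_md(system, model, proto)
    assert len(segments) == 2
    for seg in segments:
        assert seg.n_frames == 30
        assert seg.dt == 0.2
        assert seg.dipoles.shape == (30, 3)
        assert seg.polarizabilities.shape == (30, 3, 3)
    empty = run_md(system, model, MDProtocol(equil_steps=0, n_segments=0,
                                             segment_steps=10))
    assert empty == []


def test_nve_energy_conservation_water_oracle(toy):
    """No secular total-energy drift of the analytic water model over a
    0.5 ps NVE stretch at dt = 0.1 fs (windowed-mean change ≤ 1e-4 of the
    thermal energy scale)."""
    model = OracleModel(toy)
    system = gen_h2o_toy(toy)[0].system
    rng = np.random.default_rng(0)
    state = MDState.from_system(system)
    state = MDState(state.system,
                    maxwell_boltzmann_velocities(state.masses, 300.0, rng),
                    state.masses)
    forces = model.forces(state.system)
    energies = np.empty(5000)
    for i in range(5000):
        state, forces = velocity_verlet_step(state, model, 0.1, forces)
        energies[i] = model.energy(state.system) + state.kinetic_energy()
    scale = max(abs(energies[:100].mean()), 0.1)
    drift = abs(energies[-500:].mean() - energies[:500].mean()) / scale
    assert drift < 1e-4


# ---------------------------------------------------------------------------
# branch correction


def test_branch_correction_removes_injected_jump():
    cell = np.eye(3) * 10.0
    t = np.linspace(0, 4 * np.pi, 200)
    smooth = np.stack([3 * np.sin(t), 2 * np.cos(0.7 * t), 0.5 * t], axis=1)
    corrupted = smooth.copy()
    corrupted[120:, 0] += 10.0           # one quantum in x
    fixed = correct_dipole_branch(corrupted, cell)
    assert np.allclose(fixed, smooth, atol=1e-10)
    # already-continuous input is untouched
    assert np.allclose(correct_dipole_branch(smooth, cell), smooth)


def test_branch_correction_inverts_wrapping():
    cell = np.eye(3) * 10.0
    t = np.linspace(0, 6 * np.pi, 400)
    smooth = np.stack([8 * np.sin(t), 6 * np.sin(0.9 * t + 1), 0 * t], axis=1)
    wrapped = np.array([wrap_dipole(mu, cell) for mu in smooth])
    fixed = correct_dipole_branch(wrapped, cell)
    offset = fixed[0] - smooth[0]
    k = np.linalg.solve(cell.T, offset)
    assert np.allclose(k, np.round(k), atol=1e-9)   # global quantum only
    assert np.allclose(fixed - offset, smooth, atol=1e-9)


# ---------------------------------------------------------------------------
# TCFs and spectra


def test_tcf_constant_series_zero():
    series = np.ones((50, 3)) * 4.2
    assert np.allclose(tcf(series, 20, dt=0.5), 0.0)


def test_tcf_cosine_closed_form():
    dt, w0 = 0.5, 0.31
    t = np.arange(2000) * dt
    series = np.cos(w0 * t)
    c = tcf(series, 200, dt=dt)
    tau = np.arange(201) * dt
    expected = 0.5 * w0 ** 2 * np.cos(w0 * tau)   # ⟨ẋ(0)ẋ(τ)⟩ of A cos ωt
    assert np.max(np.abs(c - expected)) < 0.01 * 0.5 * w0 ** 2 + 1e-4


def test_tcf_lag_zero_is_derivative_variance():
    rng = np.random.default_rng(2)
    series = np.cumsum(rng.normal(0, 0.1, 300))
    dt = 0.25
    c = tcf(series, 10, dt=dt)
    d = np.empty_like(series)
    d[1:-1] = (series[2:] - series[:-2]) / (2 * dt)
    d[0] = (series[1] - series[0]) / dt
    d[-1] = (series[-1] - series[-2]) / dt
    assert np.isclose(c[0], np.mean(d * d))


def _cosine_trajectory(freq_cm, dt=0.5, n=4000, amp=1.0, alphas=None):
    from fieldpot.units import C_CM_PER_FS
    w = 2 * np.pi * freq_cm * C_CM_PER_FS     # rad / fs
    t = np.arange(n) * dt
    dip = np.stack([amp * np.cos(w * t), 0 * t, 0 * t], axis=1)
    pos = np.zeros((n, 1, 3))
    return Trajectory(dt=dt, positions=pos, velocities=pos.copy(),
                      energies=np.zeros(n), dipoles=dip,
                      polarizabilities=alphas)


def test_ir_peak_position_and_amplitude_scaling():
    freq = 1500.0  # cm⁻¹
    spec1 = ir_spectrum([_cosine_trajectory(freq)])
    bin_width = spec1.wavenumber[1] - spec1.wavenumber[0]
    assert abs(spec1.peak() - freq) <= bin_width
    spec2 = ir_spectrum([_cosine_trajectory(freq, amp=2.0)])
    i1 = spec1.intensity.max()
    i2 = spec2.intensity.max()
    assert np.isclose(i2 / i1, 4.0, rtol=1e-6)


def test_ir_two_frequencies():
    from fieldpot.units import C_CM_PER_FS
    dt, n = 0.5, 8000
    t = np.arange(n) * dt
    f1, f2 = 800.0, 2600.0
    w1 = 2 * np.pi * f1 * C_CM_PER_FS
    w2 = 2 * np.pi * f2 * C_CM_PER_FS
    dip = np.stack([np.cos(w1 * t), np.cos(w2 * t), 0 * t], axis=1)
    pos = np.zeros((n, 1, 3))
    traj = Trajectory(dt=dt, positions=pos, velocities=pos.copy(),
                      energies=np.zeros(n), dipoles=dip)
    spec = ir_spectrum([traj])
    bw = spec.wavenumber[1] - spec.wavenumber[0]
    # find the two dominant local maxima
    idx = np.argsort(spec.intensity)[::-1]
    found = []
    for i in idx:
        w = spec.wavenumber[i]
        if all(abs(w - f) > 10 * bw for f in found):
            found.append(w)
        if len(found) == 2:
            break
    assert sorted(abs(f - e) <= bw for f, e in zip(sorted(found), [f1, f2]))


def test_polarizability_decompose():
    iso, aniso = polarizability_decompose(np.diag([1.0, 2.0, 3.0]))
    assert iso == pytest.approx(2.0)
    assert abs(np.trace(aniso)) < 1e-12
    iso_i, aniso_i = polarizability_decompose(np.eye(3))
    assert np.allclose(aniso_i, 0.0)


def test_raman_rigid_rotor_iso_flat_aniso_peaked():
    """A rigidly rotating anisotropic molecule: α_iso is constant in time
    (rotation-invariant) so the iso spectrum is flat, while the traceless
    part carries the rotational line."""
    dt, n = 1.0, 6000
    t = np.arange(n) * dt
    w = 2 * np.pi * 300.0 * 2.99792458e-5     # 300 cm⁻¹ rotation
    body = np.diag([2.0, 1.0, 1.0])
    alphas = np.empty((n, 3, 3))
    for k, ang in enumerate(w * t):
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        alphas[k] = R @ body @ R.T
    pos = np.zeros((n, 1, 3))
    traj = Trajectory(dt=dt, positions=pos, velocities=pos.copy(),
                      energies=np.zeros(n), dipoles=np.zeros((n, 3)),
                      polarizabilities=alphas)
    iso_spec, aniso_spec = raman_spectra([traj])
    assert iso_spec.intensity.max() < 1e-12 * max(aniso_spec.intensity.max(), 1.0)
    # rotating rank-2 tensor modulates at twice the rotation frequency
    bw = aniso_spec.wavenumber[1] - aniso_spec.wavenumber[0]
    assert abs(aniso_spec.peak() - 600.0) <= bw


def test_constant_polarizability_gives_zero_spectra():
    n = 500
    alphas = np.repeat(np.eye(3)[None], n, axis=0) * 1.7
    pos = np.zeros((n, 1, 3))
    traj = Trajectory(dt=0.5, positions=pos, velocities=pos.copy(),
                      energies=np.zeros(n), dipoles=np.zeros((n, 3)),
                      polarizabilities=alphas)
    iso_spec, aniso_spec = raman_spectra([traj])
    assert np.allclose(iso_spec.intensity, 0.0)
    assert np.allclose(aniso_spec.intensity, 0.0)


def test_spectrum_shift_invariance():
    """Peak positions do not move when the trajectory time origin shifts."""
    traj = _cosine_trajectory(1200.0, n=5000)
    late = Trajectory(dt=traj.dt, positions=traj.positions[700:],
                      velocities=traj.velocities[700:],
                      energies=traj.energies[700:], dipoles=traj.dipoles[700:])
    s1 = ir_spectrum([traj], max_lag=1000)
    s2 = ir_spectrum([late], max_lag=1000)
    assert abs(s1.peak() - s2.peak()) <= s1.wavenumber[1] - s1.wavenumber[0]
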