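"""Langevin dynamics, constant-velocity pulling and temperature scans.

Each bead obeys the Langevin equation

    m r'' = -gamma r' + F_c + sqrt(2 gamma k_B T) xi

integrated with the Gronbech-Jensen/Farago velocity-Verlet discretisation,
which reduces to plain velocity Verlet for gamma = 0 and samples the
configurational ensemble without a stochastic-integration timestep bias.

Units. Internally everything is reduced: energies in eps, lengths in
Angstrom, bead mass m = 1, and time in the Go-model unit tau. User-facing
parameters (dt, gamma, pulling speed) are accepted in femtoseconds as is
conventional for this model family, and mapped through a single constant
``fs_per_tau`` (default 3000 fs, i.e. tau ~ 3 ps). Every per-step quantity
the model fixes (gamma*dt, v_pull*dt) is independent of that constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .forcefield import CGSystem, ForceFieldParams, _build_neighbor_list, _forces_kernel
from .structure import BeadChain, MembraneSlab

__all__ = [
    "IntegratorParams",
    "PullingProtocol",
    "SimTrace",
    "UnfoldingEvent",
    "langevin_step",
    "equilibrate",
    "run_free",
    "run_pulling",
    "detect_events",
    "melting_scan",
]

log = logging.getLogger(__name__)

#: Criterion for a broken native contact: r_ij > 1.5 sigma_ij.
CONTACT_BREAK_FACTOR = 1.5


@dataclass
class IntegratorParams:
    """Langevin/velocity-Verlet settings (user units: fs, eps)."""

    m: float = 1.0                  # bead mass, reduced
    gamma_fs: float = 8.14e-4       # friction, 1/fs (per unit mass)
    dt_fs: float = 15.0             # timestep, fs
    k_bt: float = 0.52              # thermal energy, eps
    seed: int = 0
    fs_per_tau: float = 3000.0      # fs per reduced time unit

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.gamma_fs < 0 or self.k_bt < 0:
            raise ValueError("gamma and k_BT must be non-negative")

    @property
    def dt(self) -> float:
        """Timestep in reduced time units."""
        return self.dt_fs / self.fs_per_tau

    @property
    def gamma(self) -> float:
        """Friction in reduced units (mass / tau)."""
        return self.gamma_fs * self.fs_per_tau


@dataclass
class PullingProtocol:
    """Constant-velocity pulling via a harmonic spring on one terminal bead."""

    pulled_bead: int = -1           # default: C-terminal
    anchored_bead: int = 0          # held fixed
    v_pull_fs: float = 2.035e-6     # A/fs
    k_pull: float = 0.2             # eps/A^2
    max_displacement: float = 400.0  # A
    stride: int = 200               # recording stride, steps
    axis: int = 2                   # pulling axis (z)

    def __post_init__(self) -> None:
        if self.v_pull_fs <= 0 or self.k_pull <= 0:
            raise ValueError("v_pull and k_pull must be positive")


@dataclass
class UnfoldingEvent:
    step: int
    displacement: float    # A, cantilever displacement at the force drop
    force: float           # eps/A at the peak
    n_unfolded: int        # residues unfolded up to the drop


@dataclass
class SimTrace:
    """Recorded pulling trajectory (one replica)."""

    displacement: np.ndarray   # A, cantilever displacement
    extension: np.ndarray      # A, pulled-bead coordinate along the axis
    force: np.ndarray          # eps/A, spring force
    q: np.ndarray              # fraction of intact native contacts
    n_unfolded: np.ndarray     # contiguous unfolded stretch from the pulled end
    energy: np.ndarray         # total potential energy, eps
    kinetic: np.ndarray        # total kinetic energy, eps
    steps: np.ndarray          # MD step of each record
    events: list[UnfoldingEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


# ------------------------------------------------------------------ stepping

def langevin_step(positions, velocities, force_fn, integrator: IntegratorParams,
                  rng: np.random.Generator | None = None, frozen: int | None = None):
    """One GJF velocity-Verlet update; returns (positions, velocities).

    ``force_fn(positions)`` must return the conservative forces. With
    gamma = 0 and T = 0 this is exactly velocity Verlet. ``frozen`` marks a
    bead excluded from the update (the anchored terminal).
    """
    m, dt, gamma, kbt = integrator.m, integrator.dt, integrator.gamma, integrator.k_bt
    a = (1 - gamma * dt / (2 * m)) / (1 + gamma * dt / (2 * m))
    b = 1 / (1 + gamma * dt / (2 * m))
    beta = np.zeros_like(positions)
    if gamma > 0 and kbt > 0:
        rng = rng or np.random.default_rng(integrator.seed)
        beta = rng.normal(0.0, np.sqrt(2 * gamma * kbt * dt), size=positions.shape)
    f0 = force_fn(positions)
    x1 = positions + b * dt * velocities + b * dt**2 / (2 * m) * f0 + b * dt / (2 * m) * beta
    if frozen is not None:
        x1[frozen] = positions[frozen]
    f1 = force_fn(x1)
    v1 = a * velocities + dt / (2 * m) * (a * f0 + f1) + b / m * beta
    if frozen is not None:
        v1[frozen] = 0.0
    if not np.all(np.isfinite(x1)):
        raise FloatingPointError("non-finite coordinate after Langevin step")
    return x1, v1


@njit(cache=True)
def _run_md_chunk(pos, vel, f, beta, con_i, con_j, con_sigma, native_mask,
                  chi_nat, membr_sign, z_min, z_max, ramp_w, eps, k_bb, d0,
                  sigma0, d_cut, k_chir, eps_membr, theta_literal,
                  m, dt, gamma, stride, nb_every, skin,
                  pulling, k_pull, v_step, pulled, anchored, axis,
                  anchor, anchor0, step0, nrec0,
                  rec_disp, rec_ext, rec_force, rec_q, rec_nunf, rec_epot,
                  rec_step, rec_ke):
    """One chunk of the fused MD loop. ``beta`` holds the pre-drawn,
    pre-scaled Gaussian impulses for each step of the chunk. Forces in
    ``f`` must be current for ``pos`` on entry and are current on exit.
    Returns (nrec, ke_accum, anchor, status); status < 0 flags a
    non-finite coordinate at global step -status."""
    n = pos.shape[0]
    chunk = beta.shape[0]
    a_c = (1.0 - gamma * dt / (2.0 * m)) / (1.0 + gamma * dt / (2.0 * m))
    b_c = 1.0 / (1.0 + gamma * dt / (2.0 * m))
    nb_i, nb_j = _build_neighbor_list(pos, native_mask, d_cut + skin)
    nrec = nrec0
    ke_accum = 0.0
    for local in range(chunk):
        step = step0 + local + 1
        # GJF position update + force-independent part of the velocity update
        for i in range(n):
            if i == anchored:
                continue
            for d in range(3):
                pos[i, d] += (b_c * dt * vel[i, d]
                              + b_c * dt * dt / (2.0 * m) * f[i, d]
                              + b_c * dt / (2.0 * m) * beta[local, i, d])
                vel[i, d] = (a_c * vel[i, d] + dt / (2.0 * m) * a_c * f[i, d]
                             + b_c / m * beta[local, i, d])
        if pulling:
            anchor += v_step
        if step % nb_every == 0:
            nb_i, nb_j = _build_neighbor_list(pos, native_mask, d_cut + skin)
        vbb, vnat, vnon, vchir, vmembr = _forces_kernel(
            pos, f, con_i, con_j, con_sigma, chi_nat, membr_sign, z_min, z_max,
            ramp_w, eps, k_bb, d0, sigma0, d_cut, k_chir, eps_membr, theta_literal,
            nb_i, nb_j)
        if pulling:
            f[pulled, axis] += k_pull * (anchor - pos[pulled, axis])
        # complete the velocity update with the new force
        ke = 0.0
        for i in range(n):
            if i == anchored:
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                continue
            for d in range(3):
                vel[i, d] += dt / (2.0 * m) * f[i, d]
            ke += 0.5 * m * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
        if not np.isfinite(pos[0, 0]):
            return nrec, ke_accum, anchor, -step
        ke_accum += ke
        if step % stride == 0:
            # Q and the unfolded stretch count only breakable contacts
            # (sequence separation >= 3): |j - i| = 2 pairs stay within
            # 1.5 sigma even on a taut backbone and would pin both numbers
            has_intact = np.zeros(n, np.bool_)
            intact = 0
            n_breakable = 0
            for k in range(con_i.shape[0]):
                i = con_i[k]
                j = con_j[k]
                if j - i < 3:
                    continue
                n_breakable += 1
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < (CONTACT_BREAK_FACTOR * con_sigma[k]) ** 2:
                    intact += 1
                    has_intact[i] = True
                    has_intact[j] = True
            nunf = 0
            direction = -1 if pulled > anchored else 1
            idx = pulled
            while 0 <= idx < n and not has_intact[idx]:
                nunf += 1
                idx += direction
            rec_disp[nrec] = anchor - anchor0
            rec_ext[nrec] = pos[pulled, axis]
            rec_force[nrec] = k_pull * (anchor - pos[pulled, axis]) if pulling else 0.0
            rec_q[nrec] = intact / max(n_breakable, 1)
            rec_nunf[nrec] = nunf
            rec_epot[nrec] = vbb + vnat + vnon + vchir + vmembr
            rec_ke[nrec] = ke
            rec_step[nrec] = step
            nrec += 1
    return nrec, ke_accum, anchor, 0


#: steps advanced per kernel call; noise for a chunk is drawn in one batch
CHUNK_STEPS = 2000


def _launch(system: CGSystem, pos, vel, integrator: IntegratorParams, n_steps: int,
            stride: int, pulling: bool, protocol: PullingProtocol | None, seed: int):
    n_rec = n_steps // stride + 1
    rec = {name: np.zeros(n_rec) for name in
           ("disp", "ext", "force", "q", "epot", "ke")}
    rec_nunf = np.zeros(n_rec, np.int64)
    rec_step = np.zeros(n_rec, np.int64)
    p = protocol or PullingProtocol()
    pulled = p.pulled_bead % system.n if pulling else (system.n - 1)
    anchored = p.anchored_bead % system.n if pulling else -1
    v_step = p.v_pull_fs * integrator.dt_fs  # A per step, invariant of fs_per_tau
    anchor0 = pos[pulled, p.axis] if pulling else 0.0
    anchor = anchor0

    rng = np.random.default_rng(seed)
    noise_sd = np.sqrt(2.0 * integrator.gamma * integrator.k_bt * integrator.dt)
    n = system.n
    f = np.zeros_like(pos)
    nb_i, nb_j = system.neighbor_list(pos, skin=2.5)
    _forces_kernel(pos, f, *system.kernel_args(), nb_i, nb_j)
    if pulling:
        f[pulled, p.axis] += p.k_pull * (anchor - pos[pulled, p.axis])

    nrec = 0
    ke_accum = 0.0
    done = 0
    while done < n_steps:
        chunk = min(CHUNK_STEPS, n_steps - done)
        if noise_sd > 0:
            beta = noise_sd * rng.standard_normal((chunk, n, 3))
        else:
            beta = np.zeros((chunk, n, 3))
        nrec, ke_chunk, anchor, status = _run_md_chunk(
            pos, vel, f, beta, system.con_i, system.con_j, system.con_sigma,
            system.native_mask, system.chi_nat, system.membr_sign,
            system.slab.z_min, system.slab.z_max, system.slab.ramp_width,
            *_ff_scalars(system.params),
            integrator.m, integrator.dt, integrator.gamma, stride, 100, 2.5,
            pulling, p.k_pull, v_step, pulled, anchored, p.axis,
            anchor, anchor0, done, nrec,
            rec["disp"], rec["ext"], rec["force"], rec["q"], rec_nunf,
            rec["epot"], rec_step, rec["ke"])
        ke_accum += ke_chunk
        if status < 0:
            raise FloatingPointError(f"non-finite coordinates at step {-status}")
        done += chunk
    return rec, rec_nunf, rec_step, nrec, ke_accum


def _ff_scalars(p: ForceFieldParams):
    return (p.eps, p.k_bb, p.d0, p.sigma0, p.d_cut, p.k_chir, p.eps_membr,
            1.0 if p.chirality_theta == "literal" else 0.0)


# ------------------------------------------------------------------ protocols

def equilibrate(chain: BeadChain, params: ForceFieldParams,
                integrator: IntegratorParams, n_steps: int = 200_000,
                slab: MembraneSlab | None = None, positions: np.ndarray | None = None,
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Unrestrained Langevin run from the native state.

    Returns (positions, velocities, Q) where Q is the intact-native-contact
    fraction averaged over the last half of the run. Warns if Q < 0.5.
    """
    system = CGSystem(chain, params, slab)
    pos = np.array(chain.positions if positions is None else positions, dtype=float)
    vel = np.zeros_like(pos)
    stride = max(n_steps // 200, 1)
    rec, _, _, nrec, _ = _launch(system, pos, vel, integrator, n_steps, stride,
                                 pulling=False, protocol=None, seed=integrator.seed)
    q = float(np.mean(rec["q"][nrec // 2:nrec])) if nrec else 1.0
    if q < 0.5:
        log.warning("equilibration left Q = %.2f < 0.5 at k_BT = %.2f eps", q, integrator.k_bt)
    return pos, vel, q


def run_free(chain: BeadChain, params: ForceFieldParams,
             integrator: IntegratorParams, n_steps: int, stride: int = 100,
             slab: MembraneSlab | None = None,
             positions: np.ndarray | None = None,
             velocities: np.ndarray | None = None) -> SimTrace:
    """Unrestrained dynamics with full energy/Q recording (no pulling)."""
    system = CGSystem(chain, params, slab)
    pos = np.array(chain.positions if positions is None else positions, dtype=float)
    vel = np.zeros_like(pos) if velocities is None else np.array(velocities, dtype=float)
    rec, rec_nunf, rec_step, nrec, _ = _launch(system, pos, vel, integrator,
                                               n_steps, stride, pulling=False,
                                               protocol=None, seed=integrator.seed)
    sl = slice(0, nrec)
    return SimTrace(
        displacement=rec["disp"][sl], extension=rec["ext"][sl],
        force=rec["force"][sl], q=rec["q"][sl], n_unfolded=rec_nunf[sl],
        energy=rec["epot"][sl], kinetic=rec["ke"][sl], steps=rec_step[sl],
        meta={"k_bt": integrator.k_bt, "seed": integrator.seed},
    )


def mean_kinetic_energy_per_dof(chain: BeadChain, params: ForceFieldParams,
                                integrator: IntegratorParams, n_steps: int,
                                slab: MembraneSlab | None = None) -> float:
    """Time-averaged kinetic energy per degree of freedom (eps) of a free run."""
    system = CGSystem(chain, params, slab)
    pos = np.array(chain.positions, dtype=float)
    vel = np.zeros_like(pos)
    _, _, _, _, ke_accum = _launch(system, pos, vel, integrator, n_steps,
                                   max(n_steps // 100, 1), pulling=False,
                                   protocol=None, seed=integrator.seed)
    return float(ke_accum / n_steps / (3 * system.n))


def run_pulling(chain: BeadChain, params: ForceFieldParams,
                integrator: IntegratorParams, protocol: PullingProtocol,
                slab: MembraneSlab | None = None,
                positions: np.ndarray | None = None,
                velocities: np.ndarray | None = None) -> SimTrace:
    """Constant-velocity pulling; the spring anchor starts at the pulled bead."""
    system = CGSystem(chain, params, slab)
    pos = np.array(chain.positions if positions is None else positions, dtype=float)
    vel = np.zeros_like(pos) if velocities is None else np.array(velocities, dtype=float)
    v_step = protocol.v_pull_fs * integrator.dt_fs
    n_steps = int(np.ceil(protocol.max_displacement / v_step))
    rec, rec_nunf, rec_step, nrec, _ = _launch(
        system, pos, vel, integrator, n_steps, protocol.stride,
        pulling=True, protocol=protocol, seed=integrator.seed)
    sl = slice(0, nrec)
    trace = SimTrace(
        displacement=rec["disp"][sl], extension=rec["ext"][sl],
        force=rec["force"][sl], q=rec["q"][sl],
        n_unfolded=rec_nunf[sl], energy=rec["epot"][sl],
        kinetic=rec["ke"][sl], steps=rec_step[sl],
        meta={"k_pull": protocol.k_pull, "v_pull_fs": protocol.v_pull_fs,
              "eps_membr": params.eps_membr, "k_bt": integrator.k_bt,
              "seed": integrator.seed},
    )
    trace.events = detect_events(trace)
    return trace


def detect_events(trace: SimTrace, drop_fraction: float = 0.3,
                  prominence_sd: float = 3.0, smooth: int = 5,
                  min_force: float = 0.0) -> list[UnfoldingEvent]:
    """Rupture events: force maxima followed by a drop > ``drop_fraction`` of
    the peak height, with prominence above ``prominence_sd`` thermal SDs.
    ``min_force`` restricts the list to major events (peak force above it)."""
    from scipy.signal import find_peaks

    f = trace.force
    if f.size < 3:
        return []
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        fs = np.convolve(f, kernel, mode="same")
    else:
        fs = f
    # thermal force scale from the flattest decile of the local variability
    local_sd = np.abs(np.diff(fs))
    sd = np.median(local_sd) / 0.6745 if local_sd.size else 0.0
    peaks, props = find_peaks(fs, prominence=max(prominence_sd * sd, 1e-12))
    events: list[UnfoldingEvent] = []
    for k, p in enumerate(peaks):
        nxt = peaks[k + 1] if k + 1 < len(peaks) else len(fs)
        if p + 1 >= nxt:
            continue
        valley = np.min(fs[p:nxt])
        if fs[p] <= 0 or (fs[p] - valley) < drop_fraction * fs[p]:
            continue
        if f[p] < min_force:
            continue
        drop_idx = p + int(np.argmin(fs[p:nxt]))
        events.append(UnfoldingEvent(
            step=int(trace.steps[p]),
            displacement=float(trace.displacement[p]),
            force=float(f[p]),
            n_unfolded=int(trace.n_unfolded[min(drop_idx, len(fs) - 1)]),
        ))
    return events


def melting_scan(chain: BeadChain, params: ForceFieldParams,
                 integrator: IntegratorParams, temperatures,
                 replicas: int = 2, n_steps: int = 100_000,
                 slab: MembraneSlab | None = None):
    """Equilibrium Q versus temperature and the Q = 0.5 crossing T_unfold.

    Runs ``replicas`` independent trajectories from the native state at each
    temperature, averages the intact-contact fraction over the last half of
    each run, and interpolates the first downward crossing of Q = 0.5.
    Returns (table, t_unfold) where table is a list of (T, mean Q, SE).
    """
    temperatures = np.asarray(sorted(temperatures), dtype=float)
    table = []
    for t_i, temp in enumerate(temperatures):
        qs = []
        for r in range(replicas):
            integ = replace(integrator, k_bt=float(temp),
                            seed=integrator.seed + 1000 * t_i + r)
            _, _, q = equilibrate(chain, params, integ, n_steps=n_steps, slab=slab)
            qs.append(q)
        qs = np.asarray(qs)
        se = qs.std(ddof=1) / np.sqrt(len(qs)) if len(qs) > 1 else 0.0
        table.append((float(temp), float(qs.mean()), float(se)))
    q_mean = np.array([row[1] for row in table])
    t_unfold = None
    for k in range(len(temperatures) - 1):
        if q_mean[k] >= 0.5 > q_mean[k + 1]:
            t0, t1 = temperatures[k], temperatures[k + 1]
            q0, q1 = q_mean[k], q_mean[k + 1]
            t_unfold = float(t0 + (q0 - 0.5) / (q0 - q1) * (t1 - t0))
            break
    if t_unfold is None:
        raise ValueError("Q = 0.5 crossing not bracketed by the temperature grid; "
                         "widen the grid")
    return table, t_unfold
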