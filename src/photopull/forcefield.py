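"""Energy terms and analytic forces of the coarse-grained Go model.

The potential energy of a bead configuration is

    E_p = V_BB + V_NAT + V_NON + V_CHIR + V_MEMBR

with a harmonic backbone tethering consecutive beads at d0 = 3.8 A, a
Lennard-Jones attraction on native contacts (sigma_ij = native C-alpha
distance), a truncated purely repulsive term on non-native pairs, a
chirality penalty active when the instantaneous chirality sign opposes the
native one, and an implicit-membrane slab term acting on the residues that
contact the membrane in the native structure (attractive toward the slab
for hydrophobic residues, repelling hydrophilic ones out of it).

Two code paths evaluate the same model: transparent numpy functions (the
public per-term API below) and fused numba kernels used by the Langevin
integrator; a test pins them against each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .structure import BeadChain, MembraneSlab

__all__ = [
    "ForceFieldParams",
    "EnergyBreakdown",
    "CGSystem",
    "backbone_energy",
    "native_energy",
    "nonnative_energy",
    "chirality_energy",
    "membrane_energy",
    "total_energy",
    "forces",
]

log = logging.getLogger(__name__)


@dataclass
class ForceFieldParams:
    """Model parameters; energies in eps, lengths in Angstrom."""

    eps: float = 1.0
    k_bb: float = 33.34          # eps/A^2
    d0: float = 3.8              # A
    sigma0: float = 5.0          # A, non-native repulsion
    d_cut: float = 5.61          # A, non-native truncation
    k_chir: float = 1.0          # eps
    eps_membr: float = 0.0       # eps; study values 4.03, 5.64, 7.25, 10
    chirality_theta: str = "heaviside"  # or "literal"

    def __post_init__(self) -> None:
        for name in ("eps", "k_bb", "d0", "sigma0", "d_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_chir < 0:
            raise ValueError("k_chir must be non-negative")
        if abs(self.d_cut - 2 ** (1 / 6) * self.sigma0) > 0.01:
            log.warning("d_cut=%.3f deviates from 2^(1/6)*sigma0=%.3f by more than 0.01 A",
                        self.d_cut, 2 ** (1 / 6) * self.sigma0)


@dataclass
class EnergyBreakdown:
    v_bb: float
    v_nat: float
    v_non: float
    v_chir: float
    v_membr: float

    @property
    def total(self) -> float:
        return self.v_bb + self.v_nat + self.v_non + self.v_chir + self.v_membr


# ---------------------------------------------------------------- numpy API

def backbone_energy(positions: np.ndarray, params: ForceFieldParams) -> float:
    d = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    return float(params.k_bb * np.sum((d - params.d0) ** 2))


def native_energy(positions: np.ndarray, native_contacts, params: ForceFieldParams) -> float:
    if not len(native_contacts):
        return 0.0
    ii, jj, sig = _contact_arrays(native_contacts)
    r = np.linalg.norm(positions[jj] - positions[ii], axis=1)
    if np.any(r == 0):
        raise ValueError("coincident beads in a native contact")
    s6 = (sig / r) ** 6
    return float(4 * params.eps * np.sum(s6 * s6 - s6))


def nonnative_energy(positions: np.ndarray, native_contacts, params: ForceFieldParams) -> float:
    ii, jj = _nonnative_pairs(len(positions), native_contacts)
    r = np.linalg.norm(positions[jj] - positions[ii], axis=1)
    inside = r < params.d_cut
    s6 = (params.sigma0 / r[inside]) ** 6
    return float(np.sum(4 * params.eps * (s6 * s6 - s6) + params.eps))


def chirality_energy(positions: np.ndarray, native_chi: np.ndarray, params: ForceFieldParams) -> float:
    c = _instantaneous_chirality(positions, params.d0)
    if c.size == 0:
        return 0.0
    mismatch = -c * native_chi
    if params.chirality_theta == "literal":
        theta = np.where(mismatch > 0, 1.0, -1.0)
    else:
        theta = (mismatch > 0).astype(float)
    return float(params.k_chir * np.sum(c * c * theta))


def membrane_energy(
    positions: np.ndarray,
    hydrophobic: np.ndarray,
    membrane_contact: np.ndarray,
    slab: MembraneSlab,
    params: ForceFieldParams,
) -> float:
    """Slab potential on native membrane-contact residues.

    Per hydrophobic contact residue the ramp profile is 0 inside the slab,
    rises linearly over ``ramp_width`` to eps_membr outside; hydrophilic
    contact residues feel the same profile multiplied by -1.
    """
    z = positions[:, 2]
    frac = _ramp_fraction(z, slab.z_min, slab.z_max, slab.ramp_width)
    sign = np.where(hydrophobic, 1.0, -1.0) * membrane_contact
    return float(params.eps_membr * np.sum(sign * frac))


def total_energy(positions: np.ndarray, chain: BeadChain, params: ForceFieldParams,
                 slab: MembraneSlab | None = None) -> EnergyBreakdown:
    slab = slab or MembraneSlab()
    vm = 0.0
    if params.eps_membr != 0.0 and chain.hydrophobic is not None:
        vm = membrane_energy(positions, chain.hydrophobic, chain.membrane_contact, slab, params)
    return EnergyBreakdown(
        v_bb=backbone_energy(positions, params),
        v_nat=native_energy(positions, chain.native_contacts or [], params),
        v_non=nonnative_energy(positions, chain.native_contacts or [], params),
        v_chir=(chirality_energy(positions, chain.native_chi, params)
                if chain.native_chi is not None and chain.native_chi.size else 0.0),
        v_membr=vm,
    )


def forces(positions: np.ndarray, chain: BeadChain, params: ForceFieldParams,
           slab: MembraneSlab | None = None) -> tuple[np.ndarray, EnergyBreakdown]:
    """Analytic forces F = -grad E_p (eps/A) via the fused kernel."""
    system = CGSystem(chain, params, slab)
    f = np.zeros_like(positions)
    nb_i, nb_j = system.neighbor_list(positions, skin=0.0)
    vbb, vnat, vnon, vchir, vmembr = _forces_kernel(
        positions, f, *system.kernel_args(), nb_i, nb_j)
    return f, EnergyBreakdown(vbb, vnat, vnon, vchir, vmembr)


# ------------------------------------------------------------- helpers

def _contact_arrays(native_contacts):
    ii, jj, sig = zip(*native_contacts)
    return (np.asarray(ii, np.int64), np.asarray(jj, np.int64), np.asarray(sig, float))


def _nonnative_pairs(n: int, native_contacts):
    """All pairs with j - i >= 2 that are not native contacts."""
    mask = np.triu(np.ones((n, n), dtype=bool), k=2)
    for i, j, _ in native_contacts:
        mask[min(i, j), max(i, j)] = False
    return np.nonzero(mask)


def _instantaneous_chirality(positions: np.ndarray, d0: float) -> np.ndarray:
    n = len(positions)
    if n < 4:
        return np.zeros(0)
    v = np.diff(positions, axis=0)
    cross = np.cross(v[:-2], v[1:-1])
    return np.einsum("ij,ij->i", cross, v[2:]) / d0**3


def _ramp_fraction(z, z_min, z_max, w):
    frac = np.zeros_like(z)
    below = z < z_min
    above = z > z_max
    frac[below] = np.minimum((z_min - z[below]) / w, 1.0)
    frac[above] = np.minimum((z[above] - z_max) / w, 1.0)
    return frac


# ------------------------------------------------------------- fused kernel

class CGSystem:
    """Array-packed topology + parameters feeding the numba kernels."""

    def __init__(self, chain: BeadChain, params: ForceFieldParams,
                 slab: MembraneSlab | None = None):
        slab = slab or MembraneSlab()
        self.chain = chain
        self.params = params
        self.slab = slab
        n = chain.n_residues
        self.n = n
        self.con_i, self.con_j, self.con_sigma = chain.contacts_as_arrays()
        self.native_mask = np.zeros((n, n), dtype=np.bool_)
        for i, j in zip(self.con_i, self.con_j):
            self.native_mask[i, j] = self.native_mask[j, i] = True
        self.chi_nat = (chain.native_chi if chain.native_chi is not None
                        else np.zeros(max(n - 3, 0)))
        sign = np.zeros(n, dtype=np.float64)
        if chain.hydrophobic is not None and chain.membrane_contact is not None:
            sign = np.where(chain.hydrophobic, 1.0, -1.0) * chain.membrane_contact
        self.membr_sign = sign

    def kernel_args(self):
        p, s = self.params, self.slab
        return (self.con_i, self.con_j, self.con_sigma, self.chi_nat,
                self.membr_sign, s.z_min, s.z_max, s.ramp_width,
                p.eps, p.k_bb, p.d0, p.sigma0, p.d_cut, p.k_chir,
                p.eps_membr, 1.0 if p.chirality_theta == "literal" else 0.0)

    def neighbor_list(self, positions: np.ndarray, skin: float = 2.0):
        cutoff = self.params.d_cut + skin
        return _build_neighbor_list(positions, self.native_mask, cutoff)


@njit(cache=True)
def _build_neighbor_list(pos, native_mask, cutoff):
    """Non-native pairs (j - i >= 2) within ``cutoff``, via a cell list."""
    n = pos.shape[0]
    cut2 = cutoff * cutoff
    inv = 1.0 / cutoff
    xmin, ymin, zmin = pos[0, 0], pos[0, 1], pos[0, 2]
    xmax, ymax, zmax = xmin, ymin, zmin
    for i in range(1, n):
        if pos[i, 0] < xmin: xmin = pos[i, 0]
        if pos[i, 0] > xmax: xmax = pos[i, 0]
        if pos[i, 1] < ymin: ymin = pos[i, 1]
        if pos[i, 1] > ymax: ymax = pos[i, 1]
        if pos[i, 2] < zmin: zmin = pos[i, 2]
        if pos[i, 2] > zmax: zmax = pos[i, 2]
    nx = max(int((xmax - xmin) * inv) + 1, 1)
    ny = max(int((ymax - ymin) * inv) + 1, 1)
    nz = max(int((zmax - zmin) * inv) + 1, 1)
    ncell = nx * ny * nz
    cell_of = np.empty(n, np.int64)
    counts = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        cx = int((pos[i, 0] - xmin) * inv)
        cy = int((pos[i, 1] - ymin) * inv)
        cz = int((pos[i, 2] - zmin) * inv)
        c = (cx * ny + cy) * nz + cz
        cell_of[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    cap = 64 * n
    nb_i = np.empty(cap, np.int64)
    nb_j = np.empty(cap, np.int64)
    k = 0
    for i in range(n):
        cx = int((pos[i, 0] - xmin) * inv)
        cy = int((pos[i, 1] - ymin) * inv)
        cz = int((pos[i, 2] - zmin) * inv)
        for ox in range(max(cx - 1, 0), min(cx + 2, nx)):
            for oy in range(max(cy - 1, 0), min(cy + 2, ny)):
                for oz in range(max(cz - 1, 0), min(cz + 2, nz)):
                    c = (ox * ny + oy) * nz + oz
                    for idx in range(counts[c], counts[c + 1]):
                        j = order[idx]
                        if j < i + 2 or native_mask[i, j]:
                            continue
                        dx = pos[j, 0] - pos[i, 0]
                        dy = pos[j, 1] - pos[i, 1]
                        dz = pos[j, 2] - pos[i, 2]
                        if dx * dx + dy * dy + dz * dz < cut2:
                            if k >= cap:
                                cap *= 2
                                tmp_i = np.empty(cap, np.int64)
                                tmp_j = np.empty(cap, np.int64)
                                tmp_i[:k] = nb_i[:k]
                                tmp_j[:k] = nb_j[:k]
                                nb_i, nb_j = tmp_i, tmp_j
                            nb_i[k] = i
                            nb_j[k] = j
                            k += 1
    return nb_i[:k].copy(), nb_j[:k].copy()


@njit(cache=True)
def _forces_kernel(pos, f, con_i, con_j, con_sigma, chi_nat, membr_sign,
                   z_min, z_max, ramp_w, eps, k_bb, d0, sigma0, d_cut,
                   k_chir, eps_membr, theta_literal, nb_i, nb_j):
    """Accumulate -grad E_p into ``f`` (zeroed here); return the breakdown."""
    n = pos.shape[0]
    f[:] = 0.0
    v_bb = 0.0
    v_nat = 0.0
    v_non = 0.0
    v_chir = 0.0
    v_membr = 0.0

    # backbone
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - d0
        v_bb += k_bb * dr * dr
        g = 2.0 * k_bb * dr / r  # dV/dr / r
        f[i, 0] += g * dx
        f[i, 1] += g * dy
        f[i, 2] += g * dz
        f[i + 1, 0] -= g * dx
        f[i + 1, 1] -= g * dy
        f[i + 1, 2] -= g * dz

    # native LJ
    for k in range(con_i.shape[0]):
        i = con_i[k]
        j = con_j[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = con_sigma[k] * con_sigma[k] / r2
        s6 = s2 * s2 * s2
        v_nat += 4.0 * eps * (s6 * s6 - s6)
        g = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2  # -dV/dr / r
        f[i, 0] -= g * dx
        f[i, 1] -= g * dy
        f[i, 2] -= g * dz
        f[j, 0] += g * dx
        f[j, 1] += g * dy
        f[j, 2] += g * dz

    # non-native repulsion (neighbor list; pairs beyond d_cut contribute 0)
    dcut2 = d_cut * d_cut
    for k in range(nb_i.shape[0]):
        i = nb_i[k]
        j = nb_j[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= dcut2:
            continue
        s2 = sigma0 * sigma0 / r2
        s6 = s2 * s2 * s2
        v_non += 4.0 * eps * (s6 * s6 - s6) + eps
        g = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        f[i, 0] -= g * dx
        f[i, 1] -= g * dy
        f[i, 2] -= g * dz
        f[j, 0] += g * dx
        f[j, 1] += g * dy
        f[j, 2] += g * dz

    # chirality: C_i = det[v_{i-1}, v_i, v_{i+1}] / d0^3 for beads 2..N-2 (1-based)
    d03 = d0 * d0 * d0
    for m in range(n - 3):
        a0 = m          # bead i-1 (0-based)
        v1x = pos[a0 + 1, 0] - pos[a0, 0]
        v1y = pos[a0 + 1, 1] - pos[a0, 1]
        v1z = pos[a0 + 1, 2] - pos[a0, 2]
        v2x = pos[a0 + 2, 0] - pos[a0 + 1, 0]
        v2y = pos[a0 + 2, 1] - pos[a0 + 1, 1]
        v2z = pos[a0 + 2, 2] - pos[a0 + 1, 2]
        v3x = pos[a0 + 3, 0] - pos[a0 + 2, 0]
        v3y = pos[a0 + 3, 1] - pos[a0 + 2, 1]
        v3z = pos[a0 + 3, 2] - pos[a0 + 2, 2]
        # c12 = v1 x v2, c23 = v2 x v3, c31 = v3 x v1
        c12x = v1y * v2z - v1z * v2y
        c12y = v1z * v2x - v1x * v2z
        c12z = v1x * v2y - v1y * v2x
        c23x = v2y * v3z - v2z * v3y
        c23y = v2z * v3x - v2x * v3z
        c23z = v2x * v3y - v2y * v3x
        c31x = v3y * v1z - v3z * v1y
        c31y = v3z * v1x - v3x * v1z
        c31z = v3x * v1y - v3y * v1x
        ci = (c12x * v3x + c12y * v3y + c12z * v3z) / d03
        mismatch = -ci * chi_nat[m]
        if theta_literal > 0.5:
            theta = 1.0 if mismatch > 0.0 else -1.0
        else:
            theta = 1.0 if mismatch > 0.0 else 0.0
        if theta != 0.0:
            v_chir += k_chir * ci * ci * theta
            gpre = 2.0 * k_chir * ci * theta / d03  # dV/d(det)
            # d(det)/dv1 = c23, d/dv2 = c31, d/dv3 = c12; chain to beads
            f[a0, 0] += gpre * c23x
            f[a0, 1] += gpre * c23y
            f[a0, 2] += gpre * c23z
            f[a0 + 1, 0] += gpre * (c31x - c23x)
            f[a0 + 1, 1] += gpre * (c31y - c23y)
            f[a0 + 1, 2] += gpre * (c31z - c23z)
            f[a0 + 2, 0] += gpre * (c12x - c31x)
            f[a0 + 2, 1] += gpre * (c12y - c31y)
            f[a0 + 2, 2] += gpre * (c12z - c31z)
            f[a0 + 3, 0] -= gpre * c12x
            f[a0 + 3, 1] -= gpre * c12y
            f[a0 + 3, 2] -= gpre * c12z

    # membrane slab (z only); one-sided derivative inside the ramps
    if eps_membr != 0.0:
        for i in range(n):
            s = membr_sign[i]
            if s == 0.0:
                continue
            z = pos[i, 2]
            if z < z_min:
                d = z_min - z
                if d < ramp_w:
                    v_membr += s * eps_membr * d / ramp_w
                    f[i, 2] += s * eps_membr / ramp_w
                else:
                    v_membr += s * eps_membr
            elif z > z_max:
                d = z - z_max
                if d < ramp_w:
                    v_membr += s * eps_membr * d / ramp_w
                    f[i, 2] -= s * eps_membr / ramp_w
                else:
                    v_membr += s * eps_membr

    return v_bb, v_nat, v_non, v_chir, v_membr
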