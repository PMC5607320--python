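"""Conformational-ensemble analysis of membrane-hydrophobicity effects.

Works on samples of a receptor's conformational ensemble described by the
inter-helix angle alpha (between two transmembrane helices) together with
the hydrophobic and hydrophilic transmembrane solvent-accessible surface
areas (SASA). A more hydrophobic membrane — e.g. one with a higher
cholesterol fraction c — favours conformations exposing more hydrophobic
surface; each frame is therefore reweighted by

    w(frame) ~ exp( kappa(c) * (A_HPHOB - A_ref) )

where kappa(c) >= 0 is a beta-scaled transfer free-energy coefficient per
unit area (kappa(0) = 0, monotone in c). The reweighted alpha distribution
P_c(alpha) and the normalized active/inactive population ratio

    [P_c(active) / P_c(inactive)] / [P_0(active) / P_0(inactive)]

quantify how membrane hydrophobicity shifts the conformational equilibrium
between the receptor's inactive (rhodopsin-like) and active
(metarhodopsin-II-like) states.

SASA is computed with the Shrake-Rupley rolling-probe algorithm on evenly
distributed sphere points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import AtomisticStructure, load_vdw_table

__all__ = [
    "CholesterolModel", "StateSplit", "helix_axis", "helix_angle",
    "shrake_rupley_sasa", "residue_sasa", "transmembrane_sasa_split",
    "reweight", "population_ratio", "generate_ensemble", "read_ensemble",
]


# -------------------------------------------------------------- helix angle

def helix_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Principal axis (unit vector) of a helix's C-alpha cloud, oriented N->C."""
    ca = np.asarray(ca_coords, float)
    if len(ca) < 4:
        raise ValueError("need at least 4 C-alpha positions to define a helix axis")
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def helix_angle(axis1: np.ndarray, axis2: np.ndarray) -> float:
    """Angle between two helix axes, in [0, pi]."""
    c = float(np.dot(axis1, axis2) / (np.linalg.norm(axis1) * np.linalg.norm(axis2)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


# ----------------------------------------------------------------------- SASA

def _sphere_points(n: int) -> np.ndarray:
    """n points near-uniform on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def shrake_rupley_sasa(positions: np.ndarray, radii: np.ndarray,
                       probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    Each atom's solvent-extended sphere (radius r_i + probe) is sampled at
    ``n_points`` test points; the accessible fraction is the fraction of
    points outside every other atom's extended sphere.
    """
    pos = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    n = len(pos)
    ext = radii + probe_radius
    unit = _sphere_points(n_points)
    areas = np.empty(n)
    # neighbor prefilter: atoms whose extended spheres can intersect
    for i in range(n):
        pts = pos[i] + ext[i] * unit
        d_atoms = np.linalg.norm(pos - pos[i], axis=1)
        nbr = np.flatnonzero((d_atoms < ext + ext[i]) & (np.arange(n) != i))
        if nbr.size:
            d = np.linalg.norm(pts[:, None, :] - pos[nbr][None, :, :], axis=-1)
            buried = np.any(d < ext[nbr][None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * ext[i] ** 2
    return areas


def residue_sasa(structure: AtomisticStructure, probe_radius: float = 1.4,
                 n_points: int = 960,
                 vdw_table: dict[str, float] | None = None) -> np.ndarray:
    """Per-residue SASA (A^2): per-atom areas summed within each residue."""
    vdw = load_vdw_table() if vdw_table is None else {k.upper(): v for k, v in vdw_table.items()}
    missing = sorted({e for e in structure.elements if e not in vdw})
    if missing:
        raise ValueError(f"no vdW radius for element(s): {', '.join(missing)}")
    radii = np.asarray([vdw[e] for e in structure.elements])
    atom_areas = shrake_rupley_sasa(structure.positions, radii, probe_radius, n_points)
    out = np.zeros(structure.n_residues)
    np.add.at(out, structure.residue_index - 1, atom_areas)
    return out


def transmembrane_sasa_split(per_residue_areas: np.ndarray,
                             hydrophobic: np.ndarray,
                             membrane_contact: np.ndarray) -> tuple[float, float]:
    """(A_HPHOB, A_HPHIL): transmembrane SASA split by hydrophobicity class."""
    areas = np.asarray(per_residue_areas, float)
    tm = np.asarray(membrane_contact, bool)
    hyd = np.asarray(hydrophobic, bool)
    return (float(areas[tm & hyd].sum()), float(areas[tm & ~hyd].sum()))


# ---------------------------------------------------------------- reweighting

@dataclass
class CholesterolModel:
    """kappa(c): beta-scaled hydrophobic-transfer coefficient per A^2.

    Anchored by membrane partitioning measurements of a small hydrophobic
    solute as a function of cholesterol content; the bundled example table
    is synthetic/illustrative (see data/cholesterol_transfer_example.tsv).
    ``a_ref`` is the reference hydrophobic area subtracted before
    exponentiation (any value gives the same normalized weights; it only
    conditions the arithmetic).
    """

    c_grid: np.ndarray
    kappa_grid: np.ndarray        # 1/A^2, monotone, kappa(0) = 0
    a_ref: float = 0.0

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, float)
        self.kappa_grid = np.asarray(self.kappa_grid, float)
        if self.c_grid[0] != 0.0 or self.kappa_grid[0] != 0.0:
            raise ValueError("the model must be anchored at kappa(0) = 0")
        if np.any(np.diff(self.c_grid) <= 0):
            raise ValueError("cholesterol grid must be strictly increasing")
        if np.any(np.diff(self.kappa_grid) < 0):
            raise ValueError("kappa must be monotone non-decreasing in c")

    def kappa(self, c: float) -> float:
        if not 0.0 <= c <= self.c_grid[-1]:
            raise ValueError(f"cholesterol fraction {c} outside the model range")
        return float(np.interp(c, self.c_grid, self.kappa_grid))

    @classmethod
    def from_table(cls, path, a_ref: float = 0.0) -> "CholesterolModel":
        df = pd.read_csv(Path(path), sep="\t", comment="#")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), a_ref)

    @classmethod
    def example(cls, a_ref: float = 0.0) -> "CholesterolModel":
        from importlib import resources
        with resources.as_file(resources.files("photopull.data")
                               .joinpath("cholesterol_transfer_example.tsv")) as p:
            return cls.from_table(p, a_ref)


@dataclass
class StateSplit:
    """Two disjoint alpha ranges labelling the conformational states."""

    active_range: tuple[float, float] = (0.0, 2.60)    # metarhodopsin-II-like
    inactive_range: tuple[float, float] = (2.60, np.pi)  # rhodopsin-like

    def __post_init__(self) -> None:
        lo1, hi1 = self.active_range
        lo2, hi2 = self.inactive_range
        if not (0 <= lo1 < hi1 <= np.pi and 0 <= lo2 < hi2 <= np.pi):
            raise ValueError("state ranges must be ordered and within [0, pi]")
        if max(lo1, lo2) < min(hi1, hi2):
            raise ValueError("state ranges must be disjoint")

    @classmethod
    def from_distribution(cls, alpha: np.ndarray, bandwidth: float = 0.08,
                          fallback_threshold: float = 2.60) -> "StateSplit":
        """Place the boundary at the density minimum between two modes.

        If P(alpha) is bimodal the threshold is the valley between the two
        highest modes; for a unimodal ensemble the fixed
        ``fallback_threshold`` is used.
        """
        from scipy.signal import find_peaks

        alpha = np.asarray(alpha, float)
        grid = np.linspace(0.0, np.pi, 400)
        dens = np.exp(-0.5 * ((grid[:, None] - alpha[None, :]) / bandwidth) ** 2).sum(axis=1)
        peaks, props = find_peaks(dens, prominence=0.05 * dens.max())
        if len(peaks) >= 2:
            top = peaks[np.argsort(dens[peaks])[-2:]]
            lo, hi = sorted(top)
            thr = float(grid[lo + int(np.argmin(dens[lo:hi + 1]))])
        else:
            thr = fallback_threshold
        return cls(active_range=(0.0, thr), inactive_range=(thr, np.pi))


def reweight(samples: pd.DataFrame, chol: CholesterolModel, c: float,
             bins: int | np.ndarray = 40):
    """Frame weights and the reweighted P_c(alpha) histogram.

    ``samples`` needs columns ``alpha_rad`` and ``a_hphob_A2``. Weights are
    proportional to exp(kappa(c) * (A_HPHOB - A_ref)), normalized to sum to
    one (overflow-safe via max-shift). Returns (weights, hist, edges); the
    histogram is a probability mass over alpha bins.
    """
    if len(samples) == 0:
        raise ValueError("empty ensemble")
    a = samples["a_hphob_A2"].to_numpy(float)
    alpha = samples["alpha_rad"].to_numpy(float)
    logw = chol.kappa(c) * (a - chol.a_ref)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    if isinstance(bins, int):
        bins = np.linspace(0.0, np.pi, bins + 1)
    hist, edges = np.histogram(alpha, bins=bins, weights=w)
    return w, hist, edges


def population_ratio(alpha: np.ndarray, split: StateSplit,
                     weights: np.ndarray, weights0: np.ndarray | None = None) -> float:
    """Active/inactive population ratio, normalized to the c = 0 ensemble.

    [P_c(active)/P_c(inactive)] / [P_0(active)/P_0(inactive)], with P_0
    taken from ``weights0`` (uniform if omitted).
    """
    alpha = np.asarray(alpha, float)
    w = np.asarray(weights, float)
    w0 = np.full_like(alpha, 1.0 / len(alpha)) if weights0 is None else np.asarray(weights0, float)
    lo_a, hi_a = split.active_range
    lo_i, hi_i = split.inactive_range
    act = (alpha >= lo_a) & (alpha < hi_a)
    inact = (alpha >= lo_i) & (alpha < hi_i)
    num_c, den_c = w[act].sum(), w[inact].sum()
    num_0, den_0 = w0[act].sum(), w0[inact].sum()
    if den_c == 0 or den_0 == 0 or num_0 == 0:
        raise ZeroDivisionError("a state has zero mass; cannot normalize the ratio")
    return float((num_c / den_c) / (num_0 / den_0))


# ------------------------------------------------------------- synthetic data

def generate_ensemble(n_frames: int, seed: int = 0, alpha_mode: float = 2.72,
                      alpha_sd: float = 0.20, a_hphob_peak: float = 2600.0,
                      a_curv: float = 900.0, a_noise: float = 40.0,
                      a_hphil_floor: float = 600.0, b_curv: float = 700.0,
                      b_noise: float = 30.0) -> pd.DataFrame:
    """Synthetic conformational ensemble with the assumed SASA-alpha coupling.

    alpha is a broad unimodal (truncated-Gaussian) distribution on [0, pi];
    the hydrophobic transmembrane SASA is a concave function of alpha whose
    maximum coincides with the alpha mode, the hydrophilic SASA is
    anti-correlated (convex, minimum at the mode); both carry Gaussian
    noise. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    alpha = rng.normal(alpha_mode, alpha_sd, size=2 * n_frames + 100)
    alpha = alpha[(alpha >= 0) & (alpha <= np.pi)][:n_frames]
    while len(alpha) < n_frames:  # pathological parameters only
        extra = rng.normal(alpha_mode, alpha_sd, size=n_frames)
        alpha = np.concatenate([alpha, extra[(extra >= 0) & (extra <= np.pi)]])[:n_frames]
    d2 = (alpha - alpha_mode) ** 2
    a_hphob = a_hphob_peak - a_curv * d2 + rng.normal(0, a_noise, n_frames)
    a_hphil = a_hphil_floor + b_curv * d2 + rng.normal(0, b_noise, n_frames)
    return pd.DataFrame({
        "frame": np.arange(n_frames),
        "alpha_rad": alpha,
        "a_hphob_A2": np.clip(a_hphob, 0, None),
        "a_hphil_A2": np.clip(a_hphil, 0, None),
    })


def read_ensemble(path) -> pd.DataFrame:
    """Read an ensemble TSV with columns frame, alpha_rad, a_hphob_A2, a_hphil_A2."""
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    required = {"frame", "alpha_rad", "a_hphob_A2", "a_hphil_A2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ensemble file lacks column(s): {', '.join(sorted(missing))}")
    return df
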