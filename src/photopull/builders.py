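"""Synthetic membrane-protein structures for simulation studies.

The experiments this package models pull bovine rhodopsin (PDB 1U19); when
that structure is not at hand, :func:`seven_tm_bundle` builds a synthetic
stand-in: a 348-residue, seven-transmembrane-helix bundle pre-oriented with
the membrane normal along z, with hydrophobic helix cores, hydrophilic
loops and tails, and backbone + side-chain pseudo-atoms dense enough for
the heavy-atom native-contact criterion. It is a synthetic construct, not
a homology model: use it for method validation, not for biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticBundle", "seven_tm_bundle", "ideal_helix", "toy_pdb"]

# Geometry constants (Angstrom)
CA_SPACING = 3.8
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN_DEG = 100.0
RING_RADIUS = 10.2
#: how far the central-leaning helix (index 2, the TM3 analogue) is pulled
#: toward the bundle core, Angstrom
CORE_SHIFT = 3.5

# KD-hydrophobic-rich helix pattern and polar loop pattern (26 / arbitrary len)
TM_PATTERN = "LVILAFVTLAIVMGFLILVAWSLVIF"
LOOP_PATTERN = "GSDKTNERQPHSGNDQKTSE"


@dataclass
class SyntheticBundle:
    pdb_text: str
    sequence: str
    helix_ranges: list[tuple[int, int]]  # 0-based inclusive residue ranges


def ideal_helix(n_res: int, rise: float = HELIX_RISE, radius: float = HELIX_RADIUS,
                turn_deg: float = HELIX_TURN_DEG) -> np.ndarray:
    """C-alpha coordinates of an ideal alpha-helix along +z, starting at z=0."""
    t = np.arange(n_res)
    ang = np.deg2rad(turn_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def _arc_loop(a: np.ndarray, b: np.ndarray, n_res: int, bulge: np.ndarray) -> np.ndarray:
    """``n_res`` C-alpha positions connecting a->b as a circular arc whose
    consecutive chords (including both junctions) are exactly 3.8 A.

    ``bulge`` sets the direction the arc bows into. The circle's opening
    angle is solved from sin(s) / sin(s/m) = chord / 3.8 (m = n_res + 1
    segments, s = half the arc angle), which has a unique root in (0, pi).
    """
    m = n_res + 1
    chord = float(np.linalg.norm(b - a))
    if chord >= m * CA_SPACING:
        raise ValueError("loop too short to bridge the gap")
    u = (b - a) / chord
    w = bulge - np.dot(bulge, u) * u
    w = w / max(np.linalg.norm(w), 1e-9)
    target = chord / CA_SPACING

    lo, hi = 1e-9, np.pi - 1e-9
    for _ in range(80):
        s = 0.5 * (lo + hi)
        if np.sin(s) / np.sin(s / m) > target:
            lo = s
        else:
            hi = s
    s = 0.5 * (lo + hi)
    r = chord / (2.0 * np.sin(s))
    center = a + r * np.sin(s) * u - r * np.cos(s) * w
    dphi = 2.0 * s / m
    ks = np.arange(1, n_res + 1)
    phi = -s + ks * dphi
    return center[None, :] + r * (np.sin(phi)[:, None] * u[None, :]
                                  + np.cos(phi)[:, None] * w[None, :])


def _tail_helix(n_res: int, attach: np.ndarray, direction: np.ndarray,
                reverse: bool) -> np.ndarray:
    """A tail as an ideal helix lying along ``direction`` whose junction
    residue sits 3.8 A from ``attach``.

    ``reverse`` True builds an N-terminal tail (runs toward the attachment
    point), False a C-terminal tail (runs away from it).
    """
    u = direction / np.linalg.norm(direction)
    h = ideal_helix(n_res)
    # rotate the helix axis (z) onto u
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    c = float(np.dot(z, u))
    if np.linalg.norm(v) < 1e-9:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    h = h @ rot.T
    start = attach + CA_SPACING * u
    if reverse:
        h = h[::-1].copy()
        return h + (start - h[-1])
    return h + (start - h[0])


def seven_tm_bundle(
    n_residues: int = 348,
    z_min: float = -17.034,
    z_max: float = 15.896,
    seed: int = 2017,
    helix_len: int = 26,
    loop_lens: tuple[int, ...] = (8, 10, 8, 16, 10, 14),
    n_tail: int = 36,
    jitter: float = 0.03,
) -> SyntheticBundle:
    """Build the synthetic seven-TM bundle (default: 348 residues).

    Helices sit on a ring of radius ~11 A with alternating up/down
    direction; the N-terminal tail lies on the extracellular (low-z) face
    and the C-terminal tail on the cytoplasmic (high-z) face, so pulling
    the C-terminus along +z matches the experiment's geometry.
    """
    rng = np.random.default_rng(seed)
    c_tail = n_residues - n_tail - 7 * helix_len - sum(loop_lens)
    if c_tail < 4:
        raise ValueError("residue budget leaves no C-terminal tail")
    z_mid = 0.5 * (z_min + z_max)

    # helix C-alpha blocks
    helices: list[np.ndarray] = []
    axes_xy = []
    for k in range(7):
        ang = 2 * np.pi * k / 7
        radius = RING_RADIUS - (CORE_SHIFT if k == 2 else 0.0)
        cx, cy = radius * np.cos(ang), radius * np.sin(ang)
        axes_xy.append((cx, cy))
        h = ideal_helix(helix_len)
        h[:, 2] -= h[:, 2].mean()
        if k % 2 == 1:  # odd helices run downward
            h = h[::-1].copy()
        h[:, 0] += cx
        h[:, 1] += cy
        h[:, 2] += z_mid
        helices.append(h)

    outward = np.array([np.cos(2 * np.pi * 3.5 / 7), np.sin(2 * np.pi * 3.5 / 7), 0.0])
    coords: list[np.ndarray] = []
    helix_ranges: list[tuple[int, int]] = []

    # N-terminal tail: a surface-lying helix approaching helix 1 from below
    start = helices[0][0]
    n_dir = np.array([0.85, -0.45, -0.28])
    coords.append(_tail_helix(n_tail, start, -n_dir, reverse=True))
    pos = n_tail
    for k in range(7):
        coords.append(helices[k])
        helix_ranges.append((pos, pos + helix_len - 1))
        pos += helix_len
        if k < 6:
            a = helices[k][-1]
            b = helices[k + 1][0]
            side = 1.0 if a[2] > z_mid else -1.0
            mid_xy = 0.5 * (a + b)
            bulge = np.array([mid_xy[0], mid_xy[1], 0.0])
            bulge = bulge / max(np.linalg.norm(bulge), 1e-9) + np.array([0, 0, 1.2 * side])
            loop = _arc_loop(a, b, loop_lens[k], bulge=bulge)
            coords.append(loop)
            pos += loop_lens[k]
    # C-terminal tail: surface-lying helix leaving the bundle on the high-z face
    a = helices[6][-1]
    coords.append(_tail_helix(c_tail, a, np.array([-0.72, 0.62, 0.31]), reverse=False))
    ca = np.vstack(coords)
    assert len(ca) == n_residues
    ca = ca + rng.normal(0.0, jitter, size=ca.shape)

    # sequence: hydrophobic pattern inside helices, polar outside
    seq = []
    in_helix = np.zeros(n_residues, dtype=bool)
    for lo, hi in helix_ranges:
        in_helix[lo:hi + 1] = True
    t_h = t_l = 0
    for i in range(n_residues):
        if in_helix[i]:
            seq.append(TM_PATTERN[t_h % len(TM_PATTERN)])
            t_h += 1
        else:
            seq.append(LOOP_PATTERN[t_l % len(LOOP_PATTERN)])
            t_l += 1
    sequence = "".join(seq)

    pdb_text = _write_pdb(ca, sequence, in_helix, axes_xy, rng)
    return SyntheticBundle(pdb_text=pdb_text, sequence=sequence, helix_ranges=helix_ranges)


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

_BULKY = set("FWYRKILMEQH")


def _write_pdb(ca: np.ndarray, sequence: str, in_helix: np.ndarray,
               axes_xy, rng: np.random.Generator) -> str:
    """Emit ATOM records with approximate backbone + side-chain heavy atoms."""
    n = len(ca)
    lines = []
    serial = 1
    for i in range(n):
        res3 = ONE_TO_THREE[sequence[i]]
        prev_u = _unit(ca[i] - ca[i - 1]) if i > 0 else _unit(ca[min(i + 1, n - 1)] - ca[i])
        next_u = _unit(ca[min(i + 1, n - 1)] - ca[i]) if i < n - 1 else prev_u
        # side-chain direction: outward from the nearest helix axis, else
        # perpendicular to the local chain direction
        if in_helix[i]:
            d2 = [(ca[i, 0] - x) ** 2 + (ca[i, 1] - y) ** 2 for x, y in axes_xy]
            x, y = axes_xy[int(np.argmin(d2))]
            out = _unit(np.array([ca[i, 0] - x, ca[i, 1] - y, 0.0]))
        else:
            ref = np.array([0.0, 0.0, 1.0])
            out = np.cross(next_u, ref)
            if np.linalg.norm(out) < 1e-6:
                out = np.cross(next_u, np.array([1.0, 0.0, 0.0]))
            out = _unit(out)
        perp = _unit(np.cross(next_u, out))
        atoms = [("N", "N", ca[i] - 1.2 * prev_u + 0.4 * perp),
                 ("CA", "C", ca[i]),
                 ("C", "C", ca[i] + 1.3 * next_u + 0.3 * perp),
                 ("O", "O", ca[i] + 1.3 * next_u + 0.3 * perp + 1.23 * out)]
        if sequence[i] != "G":
            atoms.append(("CB", "C", ca[i] + 1.53 * out))
            if sequence[i] in _BULKY:
                atoms.append(("CG", "C", ca[i] + 2.9 * out + 0.3 * perp))
        for name, element, xyz in atoms:
            xyz = xyz + rng.normal(0.0, 0.02, 3)
            lines.append(_atom_record(serial, name, res3, "A", i + 1, xyz, element))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def _atom_record(serial: int, name: str, res3: str, chain: str, resseq: int,
                 xyz: np.ndarray, element: str) -> str:
    """One fixed-column ATOM record (name in cols 13-16, coords 31-54)."""
    name4 = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:5d} {name4} {res3} {chain}{resseq:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
            f"{element:>2s}")


def toy_pdb(residues: list[tuple[str, np.ndarray]], chain: str = "A",
            extra_atoms: list[tuple[int, str, str, np.ndarray]] | None = None) -> str:
    """Minimal PDB text: one CA per residue plus optional extra atoms.

    ``residues`` is a list of (three-letter name, CA xyz); ``extra_atoms``
    holds (1-based residue index, atom name, element, xyz).
    """
    lines = []
    serial = 1
    records: list[tuple[int, str, str, str, np.ndarray]] = []
    for i, (res3, xyz) in enumerate(residues, start=1):
        records.append((i, "CA", "C", res3, np.asarray(xyz, float)))
    for idx, name, element, xyz in extra_atoms or []:
        res3 = residues[idx - 1][0]
        records.append((idx, name, element, res3, np.asarray(xyz, float)))
    records.sort(key=lambda r: r[0])
    for i, name, element, res3, xyz in records:
        lines.append(_atom_record(serial, name, res3, chain, i, xyz, element))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
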