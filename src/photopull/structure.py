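"""Structure preparation for the coarse-grained membrane-protein model.

Everything the structure-based (Go-type) force field needs is derived here
from a pre-oriented PDB file (membrane normal along z):

* one bead per residue, centred on the C-alpha atom;
* the native contact map, from an enlarged van-der-Waals overlap criterion
  applied to every heavy-atom pair (enlargement factor 1.244);
* hydrophobicity classes from the Kyte-Doolittle scale;
* membrane-contact flags from the native C-alpha z coordinate relative to
  the implicit membrane slab;
* native chirality of each internal bead (signed triple product of three
  consecutive virtual bonds).
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "AtomisticStructure",
    "BeadChain",
    "MembraneSlab",
    "StructureError",
    "parse_structure",
    "build_bead_chain",
    "native_contact_map",
    "classify_hydrophobicity",
    "assign_membrane_contact",
    "native_chirality",
    "load_vdw_table",
    "KYTE_DOOLITTLE",
    "prepare_topology",
]

log = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy index per one-letter residue code.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}

#: Default width of the linear ramp flanking the membrane slab (Angstrom).
RAMP_WIDTH_A = 3.0

#: Default enlargement factor for the vdW overlap contact criterion.
CONTACT_ENLARGEMENT = 1.244


class StructureError(ValueError):
    """Raised for unusable input structures (missing chain, missing C-alpha, ...)."""


def load_vdw_table() -> dict[str, float]:
    """Bundled heavy-atom van der Waals radii (Angstrom), keyed by element."""
    text = resources.files("photopull.data").joinpath("vdw_radii.json").read_text()
    table = json.loads(text)
    table.pop("comment", None)
    return {k.upper(): float(v) for k, v in table.items()}


@dataclass
class AtomisticStructure:
    """Heavy atoms of a single chain, grouped by residue.

    ``residue_index`` is 1-based and contiguous after parsing (gaps in the
    author numbering are renumbered, with a warning recorded in ``gaps``).
    """

    residue_index: np.ndarray      # (n_atoms,) int, 1-based bead index
    atom_names: list[str]          # (n_atoms,)
    elements: list[str]            # (n_atoms,) upper-case element symbols
    positions: np.ndarray          # (n_atoms, 3) Angstrom
    sequence: str                  # one-letter codes, one per residue
    gaps: list[tuple[int, int]] = field(default_factory=list)  # author numbering gaps

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atoms_of_residue(self, i: int) -> np.ndarray:
        """Row indices of the heavy atoms of 1-based residue ``i``."""
        return np.flatnonzero(self.residue_index == i)


@dataclass
class MembraneSlab:
    """Implicit membrane: a slab [z_min, z_max] with 3 A linear ramps outside."""

    z_min: float = -17.034
    z_max: float = 15.896
    ramp_width: float = RAMP_WIDTH_A

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError(f"z_min ({self.z_min}) must be < z_max ({self.z_max})")


@dataclass
class BeadChain:
    """One C-alpha bead per residue plus the native topology of the Go model."""

    positions: np.ndarray                  # (N, 3) native C-alpha coordinates, A
    sequence: str
    hydrophobic: np.ndarray | None = None      # (N,) bool
    membrane_contact: np.ndarray | None = None  # (N,) bool
    native_contacts: list[tuple[int, int, float]] | None = None  # 0-based (i, j, sigma_ij)
    native_chi: np.ndarray | None = None   # (N-3,) chirality of beads 2..N-2 (1-based)

    @property
    def n_residues(self) -> int:
        return len(self.positions)

    def contacts_as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not self.native_contacts:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        ii, jj, ss = zip(*self.native_contacts)
        return (np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64),
                np.asarray(ss, dtype=float))

    def to_topology_json(self) -> str:
        """Serialize the full topology to a JSON document."""
        doc = {
            "n_residues": self.n_residues,
            "sequence": self.sequence,
            "positions_A": np.round(self.positions, 4).tolist(),
            "hydrophobic": None if self.hydrophobic is None else self.hydrophobic.astype(int).tolist(),
            "membrane_contact": None if self.membrane_contact is None else self.membrane_contact.astype(int).tolist(),
            "native_contacts": [[int(i), int(j), round(float(s), 4)]
                                for i, j, s in (self.native_contacts or [])],
            "native_chirality": None if self.native_chi is None else np.round(self.native_chi, 6).tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_topology_json(cls, text: str) -> "BeadChain":
        doc = json.loads(text)
        return cls(
            positions=np.asarray(doc["positions_A"], dtype=float),
            sequence=doc["sequence"],
            hydrophobic=None if doc["hydrophobic"] is None else np.asarray(doc["hydrophobic"], bool),
            membrane_contact=None if doc["membrane_contact"] is None else np.asarray(doc["membrane_contact"], bool),
            native_contacts=[(int(i), int(j), float(s)) for i, j, s in doc["native_contacts"]],
            native_chi=None if doc["native_chirality"] is None else np.asarray(doc["native_chirality"], float),
        )

    def contacts_to_tsv(self) -> str:
        lines = ["i\tj\tsigma_ij_A"]
        for i, j, s in self.native_contacts or []:
            lines.append(f"{i}\t{j}\t{s:.4f}")
        return "\n".join(lines) + "\n"


def parse_structure(pdb_text: str, chain_id: str = "A") -> AtomisticStructure:
    """Parse one chain of a PDB file into heavy atoms grouped by residue.

    Hydrogens, waters and (non-MSE) heteroatoms are dropped; alternate
    locations resolve to the highest-occupancy conformer (Biopython default);
    selenomethionine is mapped to methionine. Gaps in the author residue
    numbering are kept as-is in the retained residues, renumbered
    contiguously, and logged.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure("s", io.StringIO(pdb_text))[0]
    if chain_id not in [c.id for c in model]:
        raise StructureError(f"chain {chain_id!r} not found in structure")
    chain = model[chain_id]

    res_idx: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    pos: list[np.ndarray] = []
    seq: list[str] = []
    gaps: list[tuple[int, int]] = []
    prev_author = None
    bead = 0
    for res in chain:
        het, resseq, _ = res.get_id()
        resname = res.get_resname().strip()
        if het.strip() and resname != "MSE":
            continue  # water / ligands
        if not (is_aa(res, standard=False) or resname in THREE_TO_ONE):
            continue
        one = THREE_TO_ONE.get(resname, "X")
        bead += 1
        if prev_author is not None and resseq != prev_author + 1:
            gaps.append((prev_author, resseq))
        prev_author = resseq
        seq.append(one)
        for atom in res:
            el = (atom.element or "").strip().upper()
            if el in ("H", "D", ""):
                continue
            res_idx.append(bead)
            names.append(atom.get_name())
            elements.append("S" if resname == "MSE" and el == "SE" else el)
            pos.append(atom.get_coord().astype(float))
    if bead == 0:
        raise StructureError(f"chain {chain_id!r} contains no amino-acid residues")
    if gaps:
        log.warning("chain %s has %d gap(s) in author numbering: %s; beads renumbered contiguously",
                    chain_id, len(gaps), gaps)
    return AtomisticStructure(
        residue_index=np.asarray(res_idx, dtype=np.int64),
        atom_names=names,
        elements=elements,
        positions=np.asarray(pos, dtype=float),
        sequence="".join(seq),
        gaps=gaps,
    )


def build_bead_chain(structure: AtomisticStructure) -> BeadChain:
    """One bead per residue at the native C-alpha position."""
    n = structure.n_residues
    coords = np.empty((n, 3), dtype=float)
    for i in range(1, n + 1):
        rows = structure.atoms_of_residue(i)
        ca = [r for r in rows if structure.atom_names[r] == "CA"]
        if not ca:
            raise StructureError(f"residue {i} ({structure.sequence[i - 1]}) lacks a C-alpha atom")
        coords[i - 1] = structure.positions[ca[0]]
    chain = BeadChain(positions=coords, sequence=structure.sequence)
    d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    bad = np.flatnonzero((d < 2.5) | (d > 4.5))
    if bad.size:
        if structure.gaps:
            log.warning("%d consecutive-bead distance(s) outside [2.5, 4.5] A (chain has gaps)", bad.size)
        else:
            log.warning("%d consecutive-bead distance(s) outside the [2.5, 4.5] A sanity window "
                        "at bead indices %s", bad.size, bad[:10].tolist())
    return chain


def native_contact_map(
    structure: AtomisticStructure,
    vdw_table: dict[str, float] | None = None,
    enlargement: float = CONTACT_ENLARGEMENT,
    min_separation: int = 2,
) -> list[tuple[int, int, float]]:
    """Native contacts from the enlarged vdW overlap criterion.

    Residues i and j (0-based output, ``j - i >= min_separation``) form a
    native contact iff some heavy-atom pair (a in i, b in j) satisfies
    ``dist(a, b) < enlargement * (r_vdw(a) + r_vdw(b))``. sigma_ij is the
    native C-alpha-C-alpha distance of the pair.
    """
    vdw = load_vdw_table() if vdw_table is None else {k.upper(): v for k, v in vdw_table.items()}
    missing = sorted({e for e in structure.elements if e not in vdw})
    if missing:
        raise StructureError(f"no vdW radius for element(s): {', '.join(missing)}")

    n = structure.n_residues
    radii = np.asarray([vdw[e] for e in structure.elements])
    res = structure.residue_index - 1  # 0-based
    pos = structure.positions

    ca_pos = build_bead_chain(structure).positions
    max_r = radii.max()
    cut = enlargement * 2.0 * max_r

    # Residue bounding spheres prune the O(n_res^2) residue-pair loop.
    centers = np.empty((n, 3))
    spans = np.empty(n)
    atom_rows = [np.flatnonzero(res == i) for i in range(n)]
    for i in range(n):
        p = pos[atom_rows[i]]
        centers[i] = p.mean(axis=0)
        spans[i] = np.linalg.norm(p - centers[i], axis=1).max()

    contacts: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + min_separation, n):
            if np.linalg.norm(centers[j] - centers[i]) > spans[i] + spans[j] + cut:
                continue
            pi, pj = pos[atom_rows[i]], pos[atom_rows[j]]
            d = np.linalg.norm(pi[:, None, :] - pj[None, :, :], axis=-1)
            thresh = enlargement * (radii[atom_rows[i]][:, None] + radii[atom_rows[j]][None, :])
            if np.any(d < thresh):
                sigma = float(np.linalg.norm(ca_pos[i] - ca_pos[j]))
                contacts.append((i, j, sigma))
    return contacts


def classify_hydrophobicity(sequence: str, threshold: float = 0.0) -> np.ndarray:
    """True where the Kyte-Doolittle index exceeds ``threshold`` (default 0)."""
    try:
        kd = np.asarray([KYTE_DOOLITTLE[a] for a in sequence])
    except KeyError as exc:
        raise StructureError(f"nonstandard residue code {exc.args[0]!r}") from None
    return kd > threshold


def assign_membrane_contact(chain: BeadChain, slab: MembraneSlab) -> np.ndarray:
    """True where the native C-alpha z lies within the slab extended by the ramp."""
    z = chain.positions[:, 2]
    return (z >= slab.z_min - slab.ramp_width) & (z <= slab.z_max + slab.ramp_width)


def native_chirality(chain: BeadChain, d0: float = 3.8) -> np.ndarray:
    """Signed chirality C_i of internal beads i = 2 .. N-2 (1-based).

    C_i = ((v_{i-1} x v_i) . v_{i+1}) / d0^3 with v_i = r_{i+1} - r_i,
    evaluated on the native coordinates. Returns an (N-3,) array (empty for
    N < 4); entry k corresponds to bead k+2 in 1-based numbering.
    """
    r = chain.positions
    n = len(r)
    if n < 4:
        return np.zeros(0)
    v = np.diff(r, axis=0)                      # v[k] = r_{k+1} - r_k, 0-based
    cross = np.cross(v[:-2], v[1:-1])
    return np.einsum("ij,ij->i", cross, v[2:]) / d0**3


def prepare_topology(
    pdb_text: str,
    chain_id: str = "A",
    slab: MembraneSlab | None = None,
    vdw_table: dict[str, float] | None = None,
    enlargement: float = CONTACT_ENLARGEMENT,
) -> BeadChain:
    """Full pipeline: PDB text -> bead chain with contacts, flags and chiralities."""
    slab = slab or MembraneSlab()
    structure = parse_structure(pdb_text, chain_id)
    chain = build_bead_chain(structure)
    chain.native_contacts = native_contact_map(structure, vdw_table, enlargement)
    chain.hydrophobic = classify_hydrophobicity(chain.sequence)
    chain.membrane_contact = assign_membrane_contact(chain, slab)
    chain.native_chi = native_chirality(chain)
    return chain
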