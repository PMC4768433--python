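"""Molecular structure I/O, fragment (atom-type) perception and atomic properties.

Structures are read from SDF/MOL (V2000, via RDKit) or plain XYZ files into a
lightweight :class:`Molecule3D`.  Hydrogens are suppressed by default —
descriptor tensors are built on heavy atoms — but the hydrogen count of each
heavy atom is retained so donor/methyl perception still works.

Fragment codes follow the usual atom-type vocabulary: A (H-bond acceptors),
C (non-aromatic carbons), D (H-bond donors), G (halogens), M (terminal
methyl carbons), P (aromatic carbons), X (heteroatoms).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .tensors import FragmentMask

__all__ = [
    "Molecule3D",
    "read_structures",
    "write_sdf",
    "assign_fragments",
    "property_vector",
    "gasteiger_charges",
    "PROPERTY_IDS",
    "FRAGMENT_IDS",
]

log = logging.getLogger(__name__)

PROPERTY_IDS = ("m", "v", "p", "e", "a", "c", "psa", "r", "h", "s")
FRAGMENT_IDS = ("A", "C", "D", "G", "M", "P", "X")

_HALOGENS = {"F", "Cl", "Br", "I"}


def _load_tables() -> dict:
    with resources.files("nlamd.data").joinpath("atomic_properties.json").open() as fh:
        return json.load(fh)


_TABLES = _load_tables()


@dataclass
class Molecule3D:
    """A molecule as a list of atoms with 3D coordinates and connectivity.

    ``bonds`` hold 0-based atom index pairs with a float order (1.5 flags an
    aromatic bond).  ``h_counts`` is the number of hydrogens (explicit before
    suppression, or implied by standard valence) attached to each atom.
    ``annotations`` carries optional per-atom property vectors keyed by
    property id (e.g. partial charges read from an SDF data field).
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    charges: list[int] = field(default_factory=list)
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    h_counts: list[int] = field(default_factory=list)
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.n_atoms
        if n < 1:
            raise ValueError("molecule needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.charges:
            self.charges = [0] * n
        if not self.h_counts:
            self.h_counts = self._implied_h_counts()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def _implied_h_counts(self) -> list[int]:
        """Hydrogens implied by default valences minus explicit bond orders."""
        if not self.bonds:
            return [0] * self.n_atoms
        val = _TABLES["default_valence"]
        used = [0.0] * self.n_atoms
        for i, j, order in self.bonds:
            o = 1.5 if order == 1.5 else float(order)
            used[i] += o
            used[j] += o
        out = []
        for el, u, q in zip(self.elements, used, self.charges):
            v = val.get(el)
            out.append(max(0, int(round(v + q - u))) if v is not None else 0)
        return out

    def heavy_neighbors(self, i: int) -> list[int]:
        nb = []
        for a, b, _ in self.bonds:
            if a == i:
                nb.append(b)
            elif b == i:
                nb.append(a)
        return [j for j in nb if self.elements[j] != "H"]

    def is_aromatic_atom(self, i: int) -> bool:
        return any(o == 1.5 and i in (a, b) for a, b, o in self.bonds)


# ---------------------------------------------------------------------------
# readers / writers


def _from_rdkit(rdmol, mol_id: str, suppress_h: bool) -> Molecule3D:
    from rdkit import Chem

    if suppress_h:
        h_counts = [a.GetTotalNumHs(includeNeighbors=True)
                    for a in rdmol.GetAtoms() if a.GetSymbol() != "H"]
        rdmol = Chem.RemoveHs(rdmol, sanitize=False)
    else:
        h_counts = [a.GetTotalNumHs(includeNeighbors=True) for a in rdmol.GetAtoms()]
    conf = rdmol.GetConformer()
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(rdmol.GetNumAtoms())])
    charges = [a.GetFormalCharge() for a in rdmol.GetAtoms()]
    bonds = []
    for b in rdmol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    annotations = {}
    for key, raw in rdmol.GetPropsAsDict().items():
        if key.startswith("ATOM_PROP_"):
            vals = np.array([float(x) for x in str(raw).split()])
            if vals.size == len(elements):
                annotations[key[len("ATOM_PROP_"):]] = vals
            else:
                log.warning("%s: %s has %d values for %d atoms; ignored",
                            mol_id, key, vals.size, len(elements))
    return Molecule3D(mol_id, elements, coords, charges, bonds, h_counts, annotations)


def _read_sdf(path: Path, suppress_h: bool) -> list[Molecule3D]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols = []
    for idx, rdmol in enumerate(supplier):
        if rdmol is None:
            log.warning("%s: record %d could not be parsed; skipped", path, idx)
            continue
        mol_id = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"mol{idx}"
        try:
            mols.append(_from_rdkit(rdmol, mol_id, suppress_h))
        except Exception as exc:  # noqa: BLE001 - per-record tolerance
            log.warning("%s: record %d rejected (%s); skipped", path, idx, exc)
    return mols


def _read_xyz(path: Path, suppress_h: bool) -> list[Molecule3D]:
    mols = []
    lines = Path(path).read_text().splitlines()
    pos, idx = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
            comment = lines[pos + 1].strip()
            elements, coords = [], []
            for rec in lines[pos + 2: pos + 2 + n]:
                parts = rec.split()
                elements.append(parts[0])
                coords.append([float(x) for x in parts[1:4]])
            if suppress_h:
                keep = [i for i, el in enumerate(elements) if el != "H"]
                elements = [elements[i] for i in keep]
                coords = [coords[i] for i in keep]
            mols.append(Molecule3D(comment or f"mol{idx}", elements, np.array(coords)))
            pos += 2 + n
            idx += 1
        except (ValueError, IndexError) as exc:
            log.warning("%s: malformed XYZ block at line %d (%s); skipped", path, pos + 1, exc)
            pos += 1
    return mols


def read_structures(path, fmt: str | None = None, suppress_hydrogens: bool = True) -> list[Molecule3D]:
    """Read molecules from an SDF/MOL (V2000) or XYZ file.

    Unparseable records are skipped with a warning; an empty result raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("sdf", "mol"):
        mols = _read_sdf(path, suppress_hydrogens)
    elif fmt == "xyz":
        mols = _read_xyz(path, suppress_hydrogens)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
    if not mols:
        raise ValueError(f"no valid molecular records in {path}")
    return mols


def write_sdf(mols: list[Molecule3D], path) -> None:
    """Write molecules as an SDF (V2000) file."""
    with open(path, "w") as fh:
        for mol in mols:
            fh.write(to_molblock(mol))
            for key, vals in mol.annotations.items():
                fh.write(f">  <ATOM_PROP_{key}>\n")
                fh.write(" ".join(f"{v:.6f}" for v in vals) + "\n\n")
            fh.write("$$$$\n")


def to_molblock(mol: Molecule3D) -> str:
    lines = [mol.id, "  nlamd", "", f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j, order in mol.bonds:
        code = 4 if order == 1.5 else int(order)
        lines.append(f"{i + 1:3d}{j + 1:3d}{code:3d}  0")
    for i, q in enumerate(mol.charges):
        if q:
            lines.append(f"M  CHG  1{i + 1:4d}{q:4d}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# fragment perception


def assign_fragments(mol: Molecule3D) -> dict[str, FragmentMask]:
    """Perceive the standard atom-type fragments of a molecule.

    Returns masks for every fragment whose prerequisites are met; fragments
    needing connectivity (C, D, M, P) are omitted (with a warning) when the
    molecule carries no bonds.
    """
    n = mol.n_atoms
    el = mol.elements
    masks: dict[str, FragmentMask] = {}
    g = np.array([e in _HALOGENS for e in el])
    x = np.array([e not in ("C", "H") for e in el])
    a = np.array([e in ("N", "O") and q <= 0 for e, q in zip(el, mol.charges)])
    masks["G"] = FragmentMask("G", g)
    masks["X"] = FragmentMask("X", x)
    masks["A"] = FragmentMask("A", a)
    if not mol.bonds:
        log.warning("%s: no connectivity; fragments C, D, M, P unavailable", mol.id)
        return masks
    d = np.array([e in ("N", "O") and h >= 1 for e, h in zip(el, mol.h_counts)])
    arom = np.array([mol.is_aromatic_atom(i) for i in range(n)])
    p = np.array([e == "C" for e in el]) & arom
    c = np.array([e == "C" for e in el]) & ~arom
    m = np.array([
        e == "C" and mol.h_counts[i] >= 3 and len(mol.heavy_neighbors(i)) <= 1
        for i, e in enumerate(el)
    ])
    masks["D"] = FragmentMask("D", d)
    masks["P"] = FragmentMask("P", p)
    masks["C"] = FragmentMask("C", c)
    masks["M"] = FragmentMask("M", m)
    return masks


# ---------------------------------------------------------------------------
# atomic properties


def _elemental(mol: Molecule3D, table: dict[str, float], prop: str) -> np.ndarray:
    out = np.empty(mol.n_atoms)
    for i, e in enumerate(mol.elements):
        if e not in table:
            raise KeyError(f"no {prop!r} value tabulated for element {e} (atom {i + 1} of {mol.id})")
        out[i] = table[e]
    return out


def _psa_contribution(mol: Molecule3D) -> np.ndarray:
    """Simplified Ertl-style topological PSA contributions for N/O/S atoms."""
    out = np.zeros(mol.n_atoms)
    for i, e in enumerate(mol.elements):
        h = mol.h_counts[i]
        if e == "O":
            out[i] = 20.23 if h >= 1 else 9.23
        elif e == "N":
            out[i] = 26.02 if h >= 2 else (12.03 if h == 1 else 3.24)
        elif e == "S":
            out[i] = 38.80 if h >= 1 else 25.30
    return out


def property_vector(mol: Molecule3D, prop: str) -> np.ndarray:
    """Per-atom property values aligned with the molecule's atom order.

    ``c`` (partial charge) is never defaulted: it must come from a per-atom
    annotation (SDF field ``ATOM_PROP_c``) or :func:`gasteiger_charges`.
    """
    if prop in mol.annotations:
        return np.asarray(mol.annotations[prop], dtype=float)
    if prop == "m":
        return _elemental(mol, _TABLES["m"], "m")
    if prop == "e":
        return _elemental(mol, _TABLES["e"], "e")
    if prop == "p":
        return _elemental(mol, _TABLES["p"], "p")
    if prop == "r":
        return _elemental(mol, _TABLES["r"], "r")
    if prop == "h":
        return _elemental(mol, _TABLES["h"], "h")
    if prop == "s":
        return _elemental(mol, _TABLES["s"], "s")
    if prop == "v":
        rad = _elemental(mol, _TABLES["vdw_radius"], "v")
        return (4.0 / 3.0) * math.pi * rad ** 3
    if prop == "a":
        base = _elemental(mol, _TABLES["a"], "a")
        return base + _TABLES["a"]["H"] * np.asarray(mol.h_counts, dtype=float)
    if prop == "psa":
        return _psa_contribution(mol)
    if prop == "u":  # unit property (linear forms)
        return np.ones(mol.n_atoms)
    if prop == "c":
        raise ValueError(
            f"{mol.id}: partial charges requested but no 'ATOM_PROP_c' annotation is "
            "present; annotate the input or call gasteiger_charges() explicitly"
        )
    raise ValueError(f"unknown property id {prop!r}")


def gasteiger_charges(mol: Molecule3D) -> np.ndarray:
    """Compute Gasteiger-Marsili charges via RDKit and cache them on the molecule."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rdmol = Chem.MolFromMolBlock(to_molblock(mol), removeHs=False, sanitize=True)
    if rdmol is None:
        raise ValueError(f"{mol.id}: structure could not be rebuilt for charge assignment")
    AllChem.ComputeGasteigerCharges(rdmol)
    q = np.array([float(a.GetProp("_GasteigerCharge")) for a in rdmol.GetAtoms()])
    mol.annotations["c"] = q
    return q
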