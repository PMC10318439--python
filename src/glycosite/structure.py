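"""Residue-level protein representation parsed from PDB files.

A structure is reduced to a single protein chain — one record per canonical
amino acid carrying backbone and side-chain heavy-atom coordinates — plus all
carbohydrate heteroresidues found in the file (any chain).  Carbohydrates are
kept without a distance prefilter; whether a residue is a binding residue is
decided downstream by the 4.2 Å heavy-atom contact rule.

Every residue is anchored at its Cβ atom (Cα for glycine), the side-chain
position that is most conserved between unbound and ligand-bound states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("glycosite")

# ---------------------------------------------------------------------------
# Amino-acid tables

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

# Common non-canonical residues mapped onto their canonical parent so the
# 20-letter feature space is preserved.  Anything else is skipped with a
# warning at parse time.
NONCANONICAL_TO_CANONICAL = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "KCX": "LYS",
}

# ---------------------------------------------------------------------------
# Carbohydrate component lookup
#
# Maps PDB chemical-component identifiers onto 16 monomer classes.  The table
# was compiled from the PDB chemical component dictionary and covers the
# frequent pyranose/furanose codes; unknown sugar-like components fall back to
# "other" via gemmi's tabulated residue kinds.

NON_SUGAR = "non-sugar"

MONOMER_LOOKUP = {
    # glucose
    "GLC": "Glc", "BGC": "Glc", "G1P": "Glc", "G6P": "Glc",
    # N-acetyl-glucosamine / glucosamine
    "NAG": "GlcNAc", "NDG": "GlcNAc", "GCS": "GlcNAc", "PA1": "GlcNAc",
    # glucuronic acid
    "GCU": "GlcA", "BDP": "GlcA",
    # fucose
    "FUC": "Fuc", "FUL": "Fuc", "FCA": "Fuc", "FCB": "Fuc",
    # mannose
    "MAN": "Man", "BMA": "Man", "M6P": "Man",
    # N-acetyl-mannosamine
    "BM3": "ManNAc", "MUB": "ManNAc",
    # galactose
    "GAL": "Gal", "GLA": "Gal", "GXL": "Gal",
    # N-acetyl-galactosamine / galactosamine
    "NGA": "GalNAc", "A2G": "GalNAc", "X6X": "GalNAc",
    # galacturonic acid
    "ADA": "GalA", "GTR": "GalA",
    # neuraminic / sialic acid
    "SIA": "Neu/Sia", "SLB": "Neu/Sia", "NAN": "Neu/Sia",
    # arabinose
    "ARA": "Ara", "ARB": "Ara", "AHR": "Ara",
    # xylose
    "XYS": "Xyl", "XYP": "Xyl", "LXC": "Xyl",
    # ribose
    "RIB": "Rib", "BDR": "Rib", "RIP": "Rib",
    # rhamnose
    "RAM": "Rha", "RM4": "Rha",
    # abequose
    "ABE": "Abe",
    # fructose
    "FRU": "Fru", "BDF": "Fru",
}

MONOMER_CLASSES = sorted(set(MONOMER_LOOKUP.values())) + ["other"]

# waters, common buffer components and ions seen as HETATM records
_NON_SUGAR_CODES = {
    "HOH", "WAT", "DOD", "NA", "CL", "MG", "ZN", "CA", "K", "MN", "FE",
    "CU", "NI", "CO", "CD", "SO4", "PO4", "GOL", "EDO", "ACT", "PEG",
    "DMS", "TRS", "MES", "NO3", "IOD", "BR",
}


def monomer_class(het_code: str) -> str:
    """Classify a PDB chemical-component id into one of the 16 carbohydrate
    monomer classes, ``"other"`` for a sugar not in the bundled lookup, or
    ``"non-sugar"`` for everything else (water, ions, amino acids, ...).

    Total function: never raises.
    """
    code = het_code.strip().upper()
    if code in MONOMER_LOOKUP:
        return MONOMER_LOOKUP[code]
    if code in _NON_SUGAR_CODES or code in AA_THREE_TO_ONE or code in NONCANONICAL_TO_CANONICAL:
        return NON_SUGAR
    info = gemmi.find_tabulated_residue(code)
    if info is not None and info.kind in (
        gemmi.ResidueKind.PYR,
        getattr(gemmi.ResidueKind, "KET", gemmi.ResidueKind.PYR),
    ):
        return "other"
    return NON_SUGAR


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class ResidueRecord:
    """One canonical amino-acid residue of the selected protein chain."""

    chain_id: str
    seq_index: int                      # author numbering
    aa: str                             # one-letter code, one of the 20
    ca: np.ndarray                      # (3,) Å
    cb: np.ndarray                      # (3,) Å; equals ca for glycine
    backbone: dict                      # atom name -> (3,) Å for N/CA/C/O
    heavy_atoms: np.ndarray             # (n_atoms, 3) Å, all heavy atoms
    phi: float | None = None            # radians in (-pi, pi] or None
    psi: float | None = None


@dataclass
class CarbohydrateUnit:
    """A carbohydrate heteroresidue (one monosaccharide unit)."""

    het_code: str
    monomer_class: str
    heavy_atoms: np.ndarray             # (n_atoms, 3) Å

    def __post_init__(self):
        self.heavy_atoms = np.asarray(self.heavy_atoms, dtype=float)
        if self.heavy_atoms.size == 0:
            raise ValueError(f"carbohydrate unit {self.het_code} has no heavy atoms")


@dataclass
class ProteinStructure:
    """A single protein chain plus adjacent carbohydrate units."""

    residues: list                      # list[ResidueRecord], chain order
    carbohydrates: list = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def cb_coords(self) -> np.ndarray:
        return np.array([r.cb for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def all_protein_atoms(self) -> np.ndarray:
        """All protein heavy atoms, stacked (n, 3)."""
        return np.concatenate([r.heavy_atoms for r in self.residues], axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Apply a rigid transform x -> R x + t to every coordinate."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def tx(x):
            return np.asarray(x, float) @ R.T + t

        residues = [
            replace(
                r,
                ca=tx(r.ca),
                cb=tx(r.cb),
                backbone={k: tx(v) for k, v in r.backbone.items()},
                heavy_atoms=tx(r.heavy_atoms),
            )
            for r in self.residues
        ]
        carbs = [
            CarbohydrateUnit(c.het_code, c.monomer_class, tx(c.heavy_atoms))
            for c in self.carbohydrates
        ]
        return ProteinStructure(residues, carbs, self.source_id)


# ---------------------------------------------------------------------------
# Parsing


def _select_altloc(atoms):
    """Group atoms by name, keeping one altloc per name: highest occupancy,
    ties broken alphabetically by altloc id (deterministic)."""
    by_name = {}
    for a in atoms:
        key = a.name
        prev = by_name.get(key)
        if prev is None:
            by_name[key] = a
        else:
            alt_prev = prev.altloc.strip("\x00") or "~"
            alt_new = a.altloc.strip("\x00") or "~"
            if a.occ > prev.occ or (a.occ == prev.occ and alt_new < alt_prev):
                by_name[key] = a
    return list(by_name.values())


def _pos(atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral Cβ position reconstructed from backbone N, Cα, C."""
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    b1 = ca - n
    b2 = c - ca
    b3 = np.cross(b1, b2)
    # standard reconstruction constants (1.53 Å bond, tetrahedral geometry)
    return -0.58273431 * b3 + 0.56802827 * b1 - 0.54067466 * b2 + ca


def parse_structure(pdb_text: str, chain: str | None = None,
                    source_id: str = "") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Parameters
    ----------
    pdb_text:
        Contents of a PDB file (ATOM/HETATM/TER records).
    chain:
        Chain id of the protein chain to keep.  ``None`` selects the first
        chain that contains canonical amino acids.  Carbohydrate
        heteroresidues are collected from *all* chains.

    Raises
    ------
    ValueError
        If the requested chain does not exist or contains no canonical
        residues.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no model in PDB input")
    model = st[0]

    chain_ids = [ch.name for ch in model]
    if chain is not None and chain not in chain_ids:
        raise ValueError(f"chain {chain!r} not found (available: {chain_ids})")

    residues: list[ResidueRecord] = []
    carbs: list[CarbohydrateUnit] = []
    selected_chain = chain

    for ch in model:
        for res in ch:
            name = res.name.strip().upper()
            cls = monomer_class(name)
            if cls != NON_SUGAR:
                atoms = _select_altloc([a for a in res if a.element.name != "H"])
                if atoms:
                    carbs.append(CarbohydrateUnit(name, cls, np.array([_pos(a) for a in atoms])))
                continue

            three = name
            if three in NONCANONICAL_TO_CANONICAL:
                three = NONCANONICAL_TO_CANONICAL[three]
            if three not in AA_THREE_TO_ONE:
                continue

            if selected_chain is None:
                selected_chain = ch.name
            if ch.name != selected_chain:
                continue

            atoms = _select_altloc([a for a in res if a.element.name != "H"])
            coords = {a.name: _pos(a) for a in atoms}
            if "CA" not in coords:
                logger.warning("skipping %s %s%d: no resolved CA", name, ch.name, res.seqid.num)
                continue
            aa = AA_THREE_TO_ONE[three]
            ca = coords["CA"]
            backbone = {k: coords[k] for k in ("N", "CA", "C", "O") if k in coords}
            if aa == "G":
                cb = ca.copy()
            elif "CB" in coords:
                cb = coords["CB"]
            elif all(k in coords for k in ("N", "CA", "C")):
                cb = ideal_cb(coords["N"], ca, coords["C"])
                logger.warning("reconstructed ideal CB for %s %s%d", name, ch.name, res.seqid.num)
            else:
                cb = ca.copy()
            heavy = np.array([_pos(a) for a in atoms])
            residues.append(ResidueRecord(
                chain_id=ch.name, seq_index=res.seqid.num, aa=aa,
                ca=ca, cb=cb, backbone=backbone, heavy_atoms=heavy,
            ))

    if not residues:
        raise ValueError(f"no canonical protein residues found in chain {chain!r}")
    return ProteinStructure(residues, carbs, source_id or st.name or "")


# ---------------------------------------------------------------------------
# Dihedral angles


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians, in (-pi, pi]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.arctan2(y, x)
    return np.pi if ang == -np.pi else float(ang)


def compute_dihedrals(structure: ProteinStructure) -> ProteinStructure:
    """Fill in backbone φ/ψ for every residue (in place; returns structure).

    φ of residue i needs C(i-1); ψ needs N(i+1).  Angles stay ``None`` where
    the required neighbor atoms are missing (chain termini, gaps).
    """
    res = structure.residues
    for i, r in enumerate(res):
        bb = r.backbone
        r.phi = None
        r.psi = None
        if all(k in bb for k in ("N", "CA", "C")):
            if i > 0 and "C" in res[i - 1].backbone and _bonded(res[i - 1].backbone["C"], bb["N"]):
                r.phi = dihedral(res[i - 1].backbone["C"], bb["N"], bb["CA"], bb["C"])
            if i + 1 < len(res) and "N" in res[i + 1].backbone and _bonded(bb["C"], res[i + 1].backbone["N"]):
                r.psi = dihedral(bb["N"], bb["CA"], bb["C"], res[i + 1].backbone["N"])
    return structure


def _bonded(c: np.ndarray, n: np.ndarray, max_dist: float = 2.0) -> bool:
    """Heuristic peptide-bond check so chain breaks yield undefined angles."""
    return float(np.linalg.norm(np.asarray(c) - np.asarray(n))) <= max_dist


# ---------------------------------------------------------------------------
# Output


def write_pdb(structure: ProteinStructure) -> str:
    """Serialize a ProteinStructure back to PDB text (protein chain +
    carbohydrate heteroresidues), suitable for round-tripping through
    :func:`parse_structure`."""
    lines = []
    serial = 1

    def fmt(record, serial, name, resname, chain_id, resseq, xyz, element):
        nm = f" {name:<3s}" if len(name) < 4 else name
        return (f"{record:<6s}{serial:>5d} {nm:<4s}{resname:>4s} {chain_id}"
                f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}")

    for r in structure.residues:
        resname = AA_ONE_TO_THREE[r.aa]
        named = dict(r.backbone)
        if r.aa != "G":
            named["CB"] = r.cb
        # emit named atoms first, then any remaining heavy atoms generically
        emitted = []
        for name in ("N", "CA", "C", "O", "CB"):
            if name in named:
                el = "N" if name == "N" else ("O" if name == "O" else "C")
                lines.append(fmt("ATOM", serial, name, resname, r.chain_id,
                                 r.seq_index, named[name], el))
                emitted.append(np.asarray(named[name]))
                serial += 1
        for atom in r.heavy_atoms:
            if any(np.allclose(atom, e, atol=1e-4) for e in emitted):
                continue
            lines.append(fmt("ATOM", serial, f"X{serial % 100:02d}", resname,
                             r.chain_id, r.seq_index, atom, "C"))
            serial += 1
    lines.append("TER")
    carb_chain = "X"
    for i, c in enumerate(structure.carbohydrates, start=1):
        for j, atom in enumerate(c.heavy_atoms, start=1):
            lines.append(fmt("HETATM", serial, f"C{j}", c.het_code, carb_chain,
                             i, atom, "C"))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def residue_table(structure: ProteinStructure, labels=None,
                  probabilities=None) -> pd.DataFrame:
    """Per-residue table (chain, author index, aa) with optional label and
    probability columns; written as TSV by callers."""
    df = pd.DataFrame({
        "chain": [r.chain_id for r in structure.residues],
        "author_index": [r.seq_index for r in structure.residues],
        "aa": [r.aa for r in structure.residues],
    })
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    if probabilities is not None:
        df["probability"] = np.asarray(probabilities, dtype=float)
    return df
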