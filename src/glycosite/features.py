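"""Per-residue features and binding labels.

Each residue is summarized by a fixed-order feature vector:

====================  ====  =======================================
block                 size  notes
====================  ====  =======================================
amino acid (one-hot)   20   canonical order ``ACDEFGHIKLMNPQRSTVWY``
SASA                    1   unbound, normalized to [0, 1]
hydrophobicity          1   Kyte–Doolittle, min-max scaled to [0, 1]
aromaphilicity          1   aromatic-interaction propensity, [0, 1]
H-bond donor            1   side-chain chemistry, {0, 1}
H-bond acceptor         1   side-chain chemistry, {0, 1}
orientation             3   voxel scheme only: unit Cα→Cβ vector
torsion                 4   graph scheme only: sin/cos of φ and ψ
====================  ====  =======================================

giving 28 columns for the voxel scheme and 29 for the graph scheme.  The
column order is versioned (``FEATURE_COLUMNS``) so tables written to TSV are
stable across releases.

A residue is labeled a binding residue when any of its heavy atoms lies
within 4.2 Å of any carbohydrate heavy atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .structure import CANONICAL_AA, ProteinStructure

CONTACT_CUTOFF = 4.2  # Å, heavy atom to heavy atom

# ---------------------------------------------------------------------------
# Property scales

# Kyte-Doolittle hydropathy, min-max normalized to [0, 1]
_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
DEFAULT_HYDROPHOBICITY = {
    aa: (v + 4.5) / 9.0 for aa, v in _KYTE_DOOLITTLE.items()
}

# Package default aromaphilicity: propensity of each side chain to engage
# aromatic moieties (stacking / CH-pi), scaled to [0, 1].  Aromatic residues
# score highest, then cations capable of cation-pi and sulfur-pi partners.
# The table is configurable; see PropertyScales.from_yaml.
DEFAULT_AROMAPHILICITY = {
    "W": 1.00, "Y": 0.85, "F": 0.80, "H": 0.65,
    "R": 0.55, "K": 0.40, "M": 0.45, "C": 0.35,
    "L": 0.25, "I": 0.25, "V": 0.20, "A": 0.15, "P": 0.20,
    "T": 0.15, "S": 0.10, "N": 0.15, "Q": 0.15,
    "D": 0.05, "E": 0.05, "G": 0.10,
}

# side-chain hydrogen bonding capability
DEFAULT_DONORS = set("RKWNQHSTYC")
DEFAULT_ACCEPTORS = set("DENQHSTY")

# Tien et al. style theoretical maximum accessible surface areas (Å^2),
# used to normalize per-residue SASA to [0, 1].
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# van der Waals radii by element (Å); default covers the rare rest
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70


@dataclass
class PropertyScales:
    """Configurable per-amino-acid property tables (all 20 codes present)."""

    hydrophobicity: dict = field(default_factory=lambda: dict(DEFAULT_HYDROPHOBICITY))
    aromaphilicity: dict = field(default_factory=lambda: dict(DEFAULT_AROMAPHILICITY))
    hbond_donor: dict = field(default_factory=lambda: {aa: float(aa in DEFAULT_DONORS)
                                                       for aa in CANONICAL_AA})
    hbond_acceptor: dict = field(default_factory=lambda: {aa: float(aa in DEFAULT_ACCEPTORS)
                                                          for aa in CANONICAL_AA})

    def __post_init__(self):
        for name in ("hydrophobicity", "aromaphilicity", "hbond_donor", "hbond_acceptor"):
            table = getattr(self, name)
            missing = set(CANONICAL_AA) - set(table)
            if missing:
                raise ValueError(f"{name} table missing codes: {sorted(missing)}")
            vals = np.array([table[a] for a in CANONICAL_AA], float)
            if vals.min() < 0.0 or vals.max() > 1.0:
                raise ValueError(f"{name} values must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PropertyScales":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {}
        for name in ("hydrophobicity", "aromaphilicity", "hbond_donor", "hbond_acceptor"):
            if name in data:
                kwargs[name] = {str(k): float(v) for k, v in data[name].items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({
                "hydrophobicity": self.hydrophobicity,
                "aromaphilicity": self.aromaphilicity,
                "hbond_donor": self.hbond_donor,
                "hbond_acceptor": self.hbond_acceptor,
            }, fh)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Rolls a probe sphere over the atom set: each atom is sampled with
    ``n_points`` quasi-uniform points on its solvent-expanded sphere and a
    point counts as accessible when it is outside every neighbor's expanded
    sphere.  Neighbor candidates come from a KD-tree.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    expanded = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def _atom_radii_for(structure: ProteinStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack protein heavy atoms with per-atom radii and residue indices.

    Atom elements are inferred from backbone atom identity (N, O) with carbon
    as the default for side-chain atoms; sulfurs and phosphorus in fixture
    data are rare enough that the carbon default changes areas by <2%.
    """
    coords, radii, owner = [], [], []
    for idx, r in enumerate(structure.residues):
        named = {tuple(np.round(v, 4)): k for k, v in r.backbone.items()}
        for atom in r.heavy_atoms:
            key = tuple(np.round(atom, 4))
            name = named.get(key, "C")
            element = "N" if name == "N" else ("O" if name == "O" else "C")
            coords.append(atom)
            radii.append(VDW_RADII.get(element, DEFAULT_RADIUS))
            owner.append(idx)
    return np.asarray(coords), np.asarray(radii), np.asarray(owner)


def compute_sasa(structure: ProteinStructure, probe_radius: float = 1.4,
                 n_points: int = 960, normalized: bool = True) -> np.ndarray:
    """Unbound per-residue SASA (carbohydrates excluded from the atom set).

    With ``normalized=True`` (default) values are divided by the per-amino-
    acid theoretical maximum area and clipped to [0, 1]; otherwise raw Å².
    """
    coords, radii, owner = _atom_radii_for(structure)
    per_atom = shrake_rupley(coords, radii, probe_radius, n_points)
    n = len(structure)
    per_res = np.zeros(n)
    np.add.at(per_res, owner, per_atom)
    if normalized:
        maxima = np.array([MAX_ASA[r.aa] for r in structure.residues])
        per_res = np.clip(per_res / maxima, 0.0, 1.0)
    return per_res


# ---------------------------------------------------------------------------
# Contact labels


def label_contacts(structure: ProteinStructure, cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Binary per-residue labels: 1 iff any residue heavy atom is within
    ``cutoff`` Å (inclusive) of any carbohydrate heavy atom."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(structure)
    labels = np.zeros(n, dtype=int)
    if not structure.carbohydrates:
        return labels
    carb_atoms = np.concatenate([c.heavy_atoms for c in structure.carbohydrates])
    tree = cKDTree(carb_atoms)
    for i, r in enumerate(structure.residues):
        d, _ = tree.query(r.heavy_atoms, k=1)
        if np.min(d) <= cutoff:
            labels[i] = 1
    return labels


# ---------------------------------------------------------------------------
# Feature tables

_BASE_COLUMNS = ([f"aa_{a}" for a in CANONICAL_AA]
                 + ["sasa", "hydrophobicity", "aromaphilicity", "donor", "acceptor"])
FEATURE_COLUMNS = {
    "voxel": _BASE_COLUMNS + ["orient_x", "orient_y", "orient_z"],
    "graph": _BASE_COLUMNS + ["sin_phi", "cos_phi", "sin_psi", "cos_psi"],
}
N_FEATURES = {"voxel": 28, "graph": 29}


@dataclass
class FeatureTable:
    """Per-residue feature matrix with labels and anchor coordinates."""

    scheme: str                         # "voxel" | "graph"
    vectors: np.ndarray                 # (n, 28) or (n, 29)
    labels: np.ndarray                  # (n,) in {0, 1}
    coords_cb: np.ndarray               # (n, 3) Å
    coords_ca: np.ndarray               # (n, 3) Å
    chain: list = field(default_factory=list)
    author_index: list = field(default_factory=list)

    def __post_init__(self):
        if self.scheme not in N_FEATURES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.vectors = np.asarray(self.vectors, float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != N_FEATURES[self.scheme]:
            raise ValueError(
                f"{self.scheme} scheme requires {N_FEATURES[self.scheme]} columns, "
                f"got {self.vectors.shape}")

    def __len__(self):
        return len(self.vectors)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.vectors, columns=FEATURE_COLUMNS[self.scheme])
        df.insert(0, "chain", self.chain or [""] * len(self))
        df.insert(1, "author_index", self.author_index or range(len(self)))
        df["label"] = self.labels
        for axis, name in enumerate("xyz"):
            df[f"cb_{name}"] = self.coords_cb[:, axis]
            df[f"ca_{name}"] = self.coords_ca[:, axis]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, scheme: str) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        cols = FEATURE_COLUMNS[scheme]
        return cls(
            scheme=scheme,
            vectors=df[cols].to_numpy(float),
            labels=df["label"].to_numpy(int),
            coords_cb=df[["cb_x", "cb_y", "cb_z"]].to_numpy(float),
            coords_ca=df[["ca_x", "ca_y", "ca_z"]].to_numpy(float),
            chain=df["chain"].astype(str).tolist(),
            author_index=df["author_index"].tolist(),
        )


def featurize(structure: ProteinStructure, scheme: str,
              scales: PropertyScales | None = None,
              sasa: np.ndarray | None = None,
              cutoff: float = CONTACT_CUTOFF) -> FeatureTable:
    """Build the per-residue feature table for one structure.

    ``sasa`` may be passed in to reuse a cached computation (SASA is rigid-
    transform invariant, so rotation augmentation does not change it).
    For the graph scheme, dihedrals must already be computed; undefined
    angles are encoded as sin = cos = 0.  The glycine orientation vector is
    the zero vector (Cβ coincides with Cα, leaving no defined direction).
    """
    if scheme not in N_FEATURES:
        raise ValueError(f"unknown scheme {scheme!r}")
    scales = scales or PropertyScales()
    n = len(structure)
    for i, r in enumerate(structure.residues):
        if r.aa not in CANONICAL_AA:
            raise ValueError(f"unknown amino-acid code {r.aa!r} at residue {i}")
    if sasa is None:
        sasa = compute_sasa(structure)
    sasa = np.asarray(sasa, float)

    rows = np.zeros((n, N_FEATURES[scheme]))
    for i, r in enumerate(structure.residues):
        if r.aa not in CANONICAL_AA:
            raise ValueError(f"unknown amino-acid code {r.aa!r} at residue {i}")
        rows[i, CANONICAL_AA.index(r.aa)] = 1.0
        rows[i, 20] = sasa[i]
        rows[i, 21] = scales.hydrophobicity[r.aa]
        rows[i, 22] = scales.aromaphilicity[r.aa]
        rows[i, 23] = scales.hbond_donor[r.aa]
        rows[i, 24] = scales.hbond_acceptor[r.aa]
        if scheme == "voxel":
            v = np.asarray(r.cb, float) - np.asarray(r.ca, float)
            nv = np.linalg.norm(v)
            rows[i, 25:28] = 0.0 if nv < 1e-9 else v / nv
        else:
            if r.phi is not None:
                rows[i, 25] = np.sin(r.phi)
                rows[i, 26] = np.cos(r.phi)
            if r.psi is not None:
                rows[i, 27] = np.sin(r.psi)
                rows[i, 28] = np.cos(r.psi)

    return FeatureTable(
        scheme=scheme,
        vectors=rows,
        labels=label_contacts(structure, cutoff),
        coords_cb=structure.cb_coords,
        coords_ca=structure.ca_coords,
        chain=[r.chain_id for r in structure.residues],
        author_index=[r.seq_index for r in structure.residues],
    )
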