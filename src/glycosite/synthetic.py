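"""Synthetic protein structures with planted carbohydrate-binding sites.

The generator builds ideal poly-peptide backbones from (φ, ψ) internal
coordinates (standard bond lengths and angles, trans peptide bonds) and
plants pyranose-ring-sized atom clusters next to chosen residues so that the
4.2 Å heavy-atom contact rule recovers exactly the planted residue set.  The
clusters are generic six-atom rings with ~1.5 Å spacing, not chemically exact
monosaccharides: contact labeling depends only on heavy-atom geometry.

Placement margins are explicit: contact atoms sit within
``4.2 - contact_margin`` Å of their target residue and farther than
``4.2 + contact_margin`` Å from every other residue, so labels are robust to
small numerical perturbations.  The ground truth is *validated by the
labeler* (a fixture is only emitted once ``label_contacts`` reproduces the
planted set exactly), never the other way around.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import (
    CANONICAL_AA,
    CarbohydrateUnit,
    ProteinStructure,
    ResidueRecord,
    compute_dihedrals,
    ideal_cb,
)

logger = logging.getLogger("glycosite")

# ideal backbone geometry (Å, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.1
OMEGA = 180.0

GEOMETRIES = {
    "helix": (-57.0, -47.0),
    "extended": (-139.0, 135.0),
    "random-coil": None,
}

_COIL_BASINS = [(-63.0, -43.0), (-120.0, 130.0), (-90.0, 120.0), (57.0, 47.0)]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic structure."""

    n_residues: int = 60
    geometry: str = "helix"
    n_sites: int = 1
    site_size: int = 4
    sugar_atoms_per_site: int = 6       # atoms per ring; one ring per target residue
    contact_margin: float = 0.5         # Å safety margin around the 4.2 Å cutoff
    n_decoys: int = 0                   # far-away non-contacting clusters
    seed: int = 0


# ---------------------------------------------------------------------------
# Internal-coordinate chain building


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A-B-C, |C-D|, angle(B,C,D) and dihedral(A,B,C,D)."""
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        -bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: np.ndarray) -> list[dict]:
    """Build N/CA/C/O coordinates for each residue from per-residue (φ, ψ)
    in degrees.  φ of the first residue is ignored (no preceding carbonyl);
    ψ of the last residue only orients its carbonyl oxygen."""
    phi_psi = np.asarray(phi_psi, float)
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")

    coords = []
    theta0 = np.deg2rad(A_N_CA_C)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([B_N_CA, 0.0, 0.0])
    c0 = ca0 + B_CA_C * np.array([-np.cos(theta0), np.sin(theta0), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})

    for i in range(1, n_res):
        prev = coords[-1]
        psi_prev = phi_psi[i - 1, 1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, B_N_CA, A_C_N_CA, OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, B_CA_C, A_N_CA_C, phi_psi[i, 0])
        coords.append({"N": n_i, "CA": ca_i, "C": c_i})

    # carbonyl oxygens: O_i is anti to N_{i+1} (dihedral N-CA-C-O = psi - 180)
    for i in range(n_res):
        bb = coords[i]
        psi = phi_psi[i, 1]
        bb["O"] = place_atom(bb["N"], bb["CA"], bb["C"], B_C_O, A_CA_C_O, psi - 180.0)
    return coords


def make_chain(spec: FixtureSpec) -> ProteinStructure:
    """Build an ideal protein chain (no carbohydrates) for the given spec."""
    if spec.n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if spec.geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {spec.geometry!r}; choose from {sorted(GEOMETRIES)}")

    rng = np.random.default_rng(spec.seed)
    if GEOMETRIES[spec.geometry] is not None:
        phi, psi = GEOMETRIES[spec.geometry]
        phi_psi = np.tile([phi, psi], (spec.n_residues, 1))
    else:
        basins = rng.integers(0, len(_COIL_BASINS), size=spec.n_residues)
        phi_psi = np.array([_COIL_BASINS[b] for b in basins], float)
        phi_psi += rng.normal(0.0, 5.0, size=phi_psi.shape)

    backbone = build_backbone(phi_psi)
    seq = rng.choice(list(CANONICAL_AA), size=spec.n_residues)

    residues = []
    for i, (bb, aa) in enumerate(zip(backbone, seq)):
        ca = bb["CA"]
        cb = ca.copy() if aa == "G" else ideal_cb(bb["N"], ca, bb["C"])
        atoms = [bb["N"], ca, bb["C"], bb["O"]] + ([] if aa == "G" else [cb])
        residues.append(ResidueRecord(
            chain_id="A", seq_index=i + 1, aa=str(aa),
            ca=ca, cb=cb, backbone=dict(bb),
            heavy_atoms=np.array(atoms),
        ))
    st = ProteinStructure(residues, [], source_id=f"synth-{spec.geometry}-{spec.seed}")
    return compute_dihedrals(st)


# ---------------------------------------------------------------------------
# Site planting


def _ring(center: np.ndarray, normal: np.ndarray, n_atoms: int,
          radius: float, phase: float) -> np.ndarray:
    """Planar ring of n_atoms around `center` perpendicular to `normal`."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = phase + 2 * np.pi * np.arange(n_atoms) / n_atoms
    return center + radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))


def _ring_through(contact: np.ndarray, u: np.ndarray, w: np.ndarray,
                  n_atoms: int, radius: float) -> np.ndarray:
    """Planar ring passing through `contact`, extending outward along u.

    The ring lies in the (u, w) plane with its center at contact + u*radius,
    so its nearest atom to the protein is the contact point itself and the
    remaining atoms sit farther out.
    """
    center = contact + u * radius
    ang = np.pi + 2 * np.pi * np.arange(n_atoms) / n_atoms
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))


def _perp_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    v -= (v @ u) * u
    n = np.linalg.norm(v)
    if n < 1e-9:
        return _perp_unit(u, rng)
    return v / n


def plant_sites(structure: ProteinStructure, spec: FixtureSpec,
                max_retries: int = 40) -> tuple[ProteinStructure, np.ndarray]:
    """Attach sugar-like clusters so the contact labeler recovers exactly the
    planted residues.  Returns (structure with carbohydrates, labels)."""
    from .features import label_contacts  # local import: features depends on structure only

    n = len(structure)
    if spec.n_sites * spec.site_size > n:
        raise ValueError("n_sites * site_size exceeds chain length")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x517E]))
    cb = structure.cb_coords
    ca = structure.ca_coords
    centroid = structure.all_protein_atoms().mean(axis=0)
    cutoff = 4.2
    lo, hi = 3.05, cutoff - spec.contact_margin
    if hi <= lo:
        raise ValueError("contact_margin too large for a usable placement band")
    ring_radius = spec.sugar_atoms_per_site * 1.5 / (2 * np.pi)  # ~1.5 Å spacing

    for attempt in range(max_retries):
        # choose site windows (contiguous runs), pairwise well separated
        starts = list(rng.permutation(n - spec.site_size + 1))
        chosen: list[int] = []
        for s in starts:
            center_s = cb[s:s + spec.site_size].mean(axis=0)
            if all(np.linalg.norm(center_s - cb[t:t + spec.site_size].mean(axis=0)) > 26.0
                   for t in chosen):
                chosen.append(int(s))
            if len(chosen) == spec.n_sites:
                break
        if len(chosen) < spec.n_sites:
            continue

        planted = sorted({i for s in chosen for i in range(s, s + spec.site_size)})
        planted_set = set(planted)
        other_atoms = np.concatenate(
            [structure.residues[i].heavy_atoms for i in range(n) if i not in planted_set])

        site_rings: list[list[np.ndarray]] = []
        ok = True
        for s in chosen:
            rings = []
            for i in range(s, s + spec.site_size):
                placed = None
                u0 = cb[i] - ca[i]
                if np.linalg.norm(u0) < 1e-6:          # glycine: point outward
                    u0 = cb[i] - centroid
                u0 /= np.linalg.norm(u0)
                own = structure.residues[i].heavy_atoms
                for trial in range(150):
                    # start near the side-chain direction, then widen the
                    # search to arbitrary directions (an extended strand's
                    # Cα→Cβ ray often passes too close to chain neighbors)
                    if trial == 0:
                        u = u0.copy()
                    elif trial < 40:
                        u = u0 + rng.normal(0.0, 0.35, 3)
                    else:
                        u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    w = _perp_unit(u, rng)
                    for d in np.arange(lo + 0.15, hi + 0.8, 0.12):
                        contact = cb[i] + u * d
                        ring = _ring_through(contact, u, w,
                                             spec.sugar_atoms_per_site,
                                             ring_radius)
                        dmin_own = np.min(np.linalg.norm(
                            ring[:, None, :] - own[None, :, :], axis=-1))
                        if not (lo < dmin_own <= hi):
                            continue
                        dmin_other = np.min(np.linalg.norm(
                            ring[:, None, :] - other_atoms[None, :, :], axis=-1))
                        if dmin_other <= cutoff + spec.contact_margin:
                            continue
                        placed = ring
                        break
                    if placed is not None:
                        break
                if placed is None:
                    ok = False
                    break
                rings.append(placed)
            if not ok:
                break
            site_rings.append(rings)
        if not ok:
            continue

        carbs = [CarbohydrateUnit("GLC", "Glc", ring)
                 for rings in site_rings for ring in rings]

        # decoys: clusters far outside the protein
        span = np.max(np.linalg.norm(structure.all_protein_atoms() - centroid, axis=-1))
        for _ in range(spec.n_decoys):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            center = centroid + u * (span + 12.0 + rng.uniform(0, 5))
            carbs.append(CarbohydrateUnit(
                "GLC", "Glc", _ring(center, u, spec.sugar_atoms_per_site,
                                    ring_radius, rng.uniform(0, 2 * np.pi))))

        candidate = ProteinStructure(structure.residues, carbs, structure.source_id)
        labels = label_contacts(candidate, cutoff)
        if set(np.flatnonzero(labels)) == planted_set:
            if spec.n_sites > 1:
                centers = [np.concatenate([r for r in rings]).mean(axis=0)
                           for rings in site_rings]
                if any(np.linalg.norm(centers[a] - centers[b]) <= 20.0
                       for a in range(len(centers)) for b in range(a)):
                    continue
            return candidate, labels

    raise RuntimeError(
        f"could not plant {spec.n_sites} site(s) of {spec.site_size} residues "
        f"after {max_retries} attempts (chain too short or margin too tight)")


def make_structure(spec: FixtureSpec) -> tuple[ProteinStructure, np.ndarray]:
    """Convenience: build the chain and plant its sites."""
    return plant_sites(make_chain(spec), spec)


# ---------------------------------------------------------------------------
# Dataset assembly


def make_dataset(n_structures: int, seed: int, imbalance: float = 0.05,
                 geometries=("helix", "extended", "random-coil"),
                 n_residue_range=(45, 75)):
    """Deterministic train/val/test fixture sets (~60/20/20 split).

    `imbalance` sets the target positive-label fraction per structure; the
    site size is rounded to the nearest residue count, matching the ~5%
    contact-residue frequency of real carbohydrate-bound structures.
    Returns (splits, manifest) where splits maps split name to a list of
    (ProteinStructure, labels) and manifest is a pandas DataFrame.
    """
    import pandas as pd

    if n_structures < 3:
        raise ValueError("need at least 3 structures for a three-way split")
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_structures):
        n_res = int(rng.integers(*n_residue_range))
        spec = FixtureSpec(
            n_residues=n_res,
            geometry=geometries[i % len(geometries)],
            n_sites=1,
            site_size=max(2, round(imbalance * n_res)),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        st, labels = make_structure(spec)
        st.source_id = f"synth{i:03d}"
        entries.append((st, labels))

    order = rng.permutation(n_structures)
    n_test = max(1, round(0.2 * n_structures))
    n_val = max(1, round(0.2 * n_structures))
    split_of = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            split_of[idx] = "test"
        elif rank < n_test + n_val:
            split_of[idx] = "val"
        else:
            split_of[idx] = "train"

    splits = {"train": [], "val": [], "test": []}
    rows = []
    for i, (st, labels) in enumerate(entries):
        sp = split_of[i]
        splits[sp].append((st, labels))
        rows.append({
            "id": st.source_id,
            "split": sp,
            "n_residues": len(st),
            "site_residues": ",".join(str(j) for j in np.flatnonzero(labels)),
        })
    return splits, pd.DataFrame(rows)
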