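"""Evaluation metrics for residue-level binding-site prediction.

Per-residue classification metrics (Dice, PPV, sensitivity, MCC) are
computed from confusion counts; site-level geometry is summarized by DCC,
the distance from each predicted site center to the nearest experimentally
determined site center.  "Independent binding sites" are single-linkage
clusters of positive residues whose Cβ atoms lie within a linkage cutoff
(default 8 Å) of each other; a site's center is the mean of its members'
Cβ coordinates.

Aggregation is macro: metrics are computed per structure, then averaged.
Coverage is the fraction of structures with at least one predicted binding
residue; DCC is averaged only over covered structures.  A prediction
"succeeds" on a structure when Dice > 0.6 or its best (smallest) DCC is
under 4 Å.

Degenerate-count conventions, applied consistently and flagged in reports:
Dice = 1 when TP = FP = FN = 0 (vacuously perfect), MCC = 0 on a zero
denominator, PPV/sensitivity = 0 on 0/0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .features import label_contacts
from .structure import ProteinStructure

DICE_SUCCESS = 0.6
DCC_SUCCESS = 4.0       # Å
LINK_CUTOFF = 8.0       # Å, Cβ-Cβ single linkage


# ---------------------------------------------------------------------------
# Confusion-count metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = np.asarray(pred, int).ravel()
    truth = np.asarray(truth, int).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (truth == 1))),
        fp=int(np.sum((pred == 1) & (truth == 0))),
        fn=int(np.sum((pred == 0) & (truth == 1))),
        tn=int(np.sum((pred == 0) & (truth == 0))),
    )


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Probabilities -> {0,1}; the threshold itself maps to 1 (inclusive)."""
    return (np.asarray(probs, float) >= threshold).astype(int)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity 2·TP / (TP+FP + TP+FN); 1.0 when all three are zero."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on a zero denominator."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    return float((c.tp * c.tn - c.fp * c.fn) / np.sqrt(float(denom)))


def ppv_sensitivity(c: ConfusionCounts) -> tuple[float, float]:
    """(precision TP/(TP+FP), recall TP/(TP+FN)); 0 on 0/0."""
    ppv = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return float(ppv), float(sens)


# ---------------------------------------------------------------------------
# Site clustering and DCC


@dataclass
class Site:
    members: np.ndarray         # residue indices
    center: np.ndarray          # (3,) mean Cβ


def cluster_sites(binary: np.ndarray, coords_cb: np.ndarray,
                  link_cutoff: float = LINK_CUTOFF) -> list[Site]:
    """Single-linkage clusters of positive residues (Cβ pairs ≤ cutoff linked).

    With ``link_cutoff=inf`` all positives collapse into one site (degenerate
    mode for sensitivity analyses).  No positives -> empty list.
    """
    if link_cutoff <= 0:
        raise ValueError("link_cutoff must be positive")
    binary = np.asarray(binary, int).ravel()
    pos = np.flatnonzero(binary)
    if len(pos) == 0:
        return []
    pts = np.asarray(coords_cb, float)[pos]
    if not np.isfinite(link_cutoff):
        return [Site(pos, pts.mean(axis=0))]
    tree = cKDTree(pts)
    pairs = list(tree.query_pairs(link_cutoff))
    n = len(pos)
    if pairs:
        rows = np.array([p[0] for p in pairs] + [p[1] for p in pairs])
        cols = np.array([p[1] for p in pairs] + [p[0] for p in pairs])
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        adj = csr_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)
    return [Site(pos[comp == k], pts[comp == k].mean(axis=0))
            for k in range(n_comp)]


def dcc(pred_sites: list[Site], true_sites: list[Site]) -> list[float]:
    """Distance from each predicted site center to the nearest true center.

    Empty when there are no predicted sites (the structure then counts
    against coverage instead of entering the DCC average).
    """
    if not true_sites:
        raise ValueError("true_sites must be non-empty")
    if not pred_sites:
        return []
    true_centers = np.array([s.center for s in true_sites])
    return [float(np.min(np.linalg.norm(true_centers - s.center, axis=1)))
            for s in pred_sites]


# ---------------------------------------------------------------------------
# Structure-set evaluation


@dataclass
class StructureReport:
    id: str
    dice: float
    ppv: float
    sensitivity: float
    mcc: float
    dcc_values: list
    predicted_any: bool
    success_dice: bool
    success_dcc: bool
    vacuous: bool = False       # no positives in truth nor prediction


@dataclass
class EvalReport:
    per_structure: list = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "per_structure": [asdict(r) for r in self.per_structure],
            "aggregate": self.aggregate,
        }
        text = json.dumps(payload, indent=1, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.per_structure:
            d = asdict(r)
            d["dcc_values"] = ";".join(f"{v:.3f}" for v in r.dcc_values)
            rows.append(d)
        return pd.DataFrame(rows)


@dataclass
class EvalConfig:
    threshold: float = 0.5
    link_cutoff: float = LINK_CUTOFF
    dice_success: float = DICE_SUCCESS
    dcc_success: float = DCC_SUCCESS


def evaluate(predictions: list, structures: list,
             config: EvalConfig | None = None,
             true_labels: list | None = None) -> EvalReport:
    """Score per-residue probability vectors against structure ground truth.

    `structures` supplies both the truth labels (via the 4.2 Å contact rule,
    unless `true_labels` is given) and the Cβ coordinates used for site
    clustering.  One prediction vector per structure, same residue order.
    """
    config = config or EvalConfig()
    if len(predictions) != len(structures):
        raise ValueError("one prediction vector per structure required")

    reports = []
    for s_i, (probs, st) in enumerate(zip(predictions, structures)):
        if not isinstance(st, ProteinStructure):
            raise TypeError("structures must be ProteinStructure instances")
        probs = np.asarray(probs, float).ravel()
        if len(probs) != len(st):
            raise ValueError(
                f"structure {st.source_id!r}: {len(probs)} probabilities "
                f"for {len(st)} residues")
        truth = np.asarray(true_labels[s_i], int) if true_labels is not None \
            else label_contacts(st)
        pred = binarize(probs, config.threshold)
        counts = confusion(pred, truth)
        cb = st.cb_coords
        pred_sites = cluster_sites(pred, cb, config.link_cutoff)
        true_sites = cluster_sites(truth, cb, config.link_cutoff)
        dcc_vals = dcc(pred_sites, true_sites) if true_sites else []
        ppv, sens = ppv_sensitivity(counts)
        d = dice(counts)
        reports.append(StructureReport(
            id=st.source_id or f"structure_{s_i}",
            dice=d,
            ppv=ppv,
            sensitivity=sens,
            mcc=mcc(counts),
            dcc_values=dcc_vals,
            predicted_any=bool(pred.any()),
            success_dice=d > config.dice_success,
            success_dcc=bool(dcc_vals) and min(dcc_vals) < config.dcc_success,
            vacuous=(counts.tp + counts.fp + counts.fn == 0),
        ))

    n = len(reports)
    covered = [r for r in reports if r.predicted_any]
    all_dcc = [min(r.dcc_values) for r in covered if r.dcc_values]
    aggregate = {
        "n_structures": n,
        "mean_dice": float(np.mean([r.dice for r in reports])),
        "mean_ppv": float(np.mean([r.ppv for r in reports])),
        "mean_sensitivity": float(np.mean([r.sensitivity for r in reports])),
        "mean_mcc": float(np.mean([r.mcc for r in reports])),
        "mean_dcc": float(np.mean(all_dcc)) if all_dcc else float("nan"),
        "coverage_pct": 100.0 * len(covered) / n,
        "pct_dice_over_0.6": 100.0 * sum(r.success_dice for r in reports) / n,
        "pct_dcc_under_4A": 100.0 * sum(r.success_dcc for r in reports) / n,
    }
    return EvalReport(reports, aggregate)
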