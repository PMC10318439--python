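"""Training loop: Adam on the soft Dice-complement loss.

Binding residues make up only ~5% of a typical structure, so plain
cross-entropy is dominated by the negative class.  The loss is therefore the
complement of a soft Dice coefficient,

    L = 1 - (2 Σ p·y + ε) / (Σ p + Σ y + ε),

computed on sigmoid probabilities (not thresholded predictions) so it stays
differentiable; ε is a small smoothing constant that also defines the
0/0 limit.  Dice ignores true negatives, which makes the loss insensitive
to the class imbalance.

Batching follows the published recipe: the graph model takes one structure
per optimizer step; the voxel model batches grids (default 20) and re-rotates
every structure freshly each epoch (rotation augmentation), so the network
sees a new orientation per epoch.  Batch loss is the mean of per-item Dice
losses, keeping each structure's contribution balanced.  The best checkpoint
is selected by validation Dice.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import autograd.numpy as anp
from autograd import value_and_grad

from .features import compute_sasa, featurize, PropertyScales
from .graphs import build_graph
from .metrics import confusion, dice
from .structure import ProteinStructure, compute_dihedrals
from .voxels import rotate_structure, voxelize

logger = logging.getLogger("glycosite")


def soft_dice_loss(probs, labels, eps: float = 1e-6):
    """Differentiable Dice-complement loss on probabilities in [0, 1].

    Returns a scalar in [0, 1]; 0 for a perfect binary match, 1 for fully
    disjoint predictions (as eps -> 0).
    """
    labels = anp.asarray(labels)
    if getattr(probs, "shape", None) != labels.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {labels.shape}")
    p = anp.ravel(probs)
    y = anp.ravel(labels) * 1.0
    inter = anp.sum(p * y)
    return 1.0 - (2.0 * inter + eps) / (anp.sum(p) + anp.sum(y) + eps)


class Adam:
    """Adam over a flat name->array parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            out[k] = p - self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
        return out


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 1000
    batch_size: int = 20            # grids (voxel model); the graph model uses 1
    seed: int = 0
    augment: bool = True            # fresh rotation per structure per epoch (voxel)
    smoothing_eps: float = 1e-6
    threshold: float = 0.5          # binarization for validation Dice

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _hard_dice(probs: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    pred = (np.asarray(probs) >= threshold).astype(int)
    return dice(confusion(pred, np.asarray(labels, int)))


def _prepare(structures) -> list[ProteinStructure]:
    """Accept ProteinStructure or (structure, labels) pairs."""
    out = []
    for item in structures:
        st = item[0] if isinstance(item, tuple) else item
        out.append(st)
    return out


def train(model, dataset, config: TrainConfig, val_dataset=None,
          scales: PropertyScales | None = None,
          log_csv=None):
    """Train either model; returns (best_params, history).

    `dataset` / `val_dataset` are lists of ProteinStructure (or
    (structure, labels) tuples, labels being recomputed from geometry
    anyway).  On return the model holds the weights *and* batch-norm
    running statistics of the epoch with the highest validation Dice
    (training Dice when there is no validation split); `best_params` is
    that same weight dict.
    """
    structures = _prepare(dataset)
    val_structures = _prepare(val_dataset) if val_dataset else []
    if not structures:
        raise ValueError("empty training dataset")
    scheme = model.scheme
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)

    for st in structures + val_structures:
        compute_dihedrals(st)
    # SASA is rigid-transform invariant: compute once, reuse across rotations
    sasa = {id(st): compute_sasa(st) for st in structures + val_structures}

    if scheme == "graph":
        graphs = [build_graph(featurize(st, "graph", scales, sasa[id(st)]))
                  for st in structures]
        val_graphs = [build_graph(featurize(st, "graph", scales, sasa[id(st)]))
                      for st in val_structures]

    history = []
    best = {"val_dice": -1.0, "params": copy.deepcopy(model.params),
            "state": copy.deepcopy(model.state), "epoch": 0}

    for epoch in range(config.epochs):
        if scheme == "graph":
            epoch_items = list(rng.permutation(len(graphs)))
            batches = [[graphs[i]] for i in epoch_items]     # one protein per step
            loss_fn = model.graph_loss
        else:
            grids = []
            for st in structures:
                rotated = rotate_structure(st, rng)[0] if config.augment else st
                table = featurize(rotated, "voxel", scales, sasa[id(st)])
                grids.extend(voxelize(table))
            order = rng.permutation(len(grids))
            batches = [[grids[i] for i in order[b:b + config.batch_size]]
                       for b in range(0, len(grids), config.batch_size)]
            loss_fn = model.grid_loss

        epoch_losses = []
        for batch in batches:
            def batch_loss(params):
                losses = [loss_fn(params, item, True, config.smoothing_eps)
                          for item in batch]
                return sum(losses) / len(losses)

            loss_val, grads = value_and_grad(batch_loss)(model.params)
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at epoch {epoch}; "
                    "reduce the learning rate or check the input features")
            model.params = optimizer.step(model.params, grads)
            epoch_losses.append(float(loss_val))

        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}

        if scheme == "graph":
            record["train_dice"] = float(np.mean(
                [_hard_dice(model.forward(g, training=False), g.labels,
                            config.threshold) for g in graphs]))
            if val_graphs:
                record["val_dice"] = float(np.mean(
                    [_hard_dice(model.forward(g, training=False), g.labels,
                                config.threshold) for g in val_graphs]))
        else:
            from .features import label_contacts
            from .nn import predict_structure

            def mean_dice(sts):
                return float(np.mean(
                    [_hard_dice(predict_structure(model, st, scales, sasa[id(st)]),
                                label_contacts(st), config.threshold)
                     for st in sts]))

            record["train_dice"] = mean_dice(structures)
            if val_structures:
                record["val_dice"] = mean_dice(val_structures)
        # checkpoint selection: validation Dice when a validation split
        # exists, training Dice otherwise
        record["val_dice"] = record.get("val_dice", record["train_dice"])

        if record["val_dice"] > best["val_dice"]:
            best = {"val_dice": record["val_dice"],
                    "params": copy.deepcopy(model.params),
                    "state": copy.deepcopy(model.state), "epoch": epoch}
            record["checkpoint"] = 1
        else:
            record["checkpoint"] = 0
        history.append(record)
        if log_csv is not None:
            _append_csv(log_csv, record)
        if epoch % 25 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %d loss %.4f val dice %.3f",
                        epoch, record["train_loss"], record["val_dice"])

    # leave the model at the best checkpoint: parameters and batch-norm
    # running statistics belong to the same epoch
    model.params = best["params"]
    model.state = best["state"]
    return best["params"], history


def _append_csv(path, record: dict) -> None:
    import os
    header = not os.path.exists(path)
    with open(path, "a") as fh:
        if header:
            fh.write(",".join(record.keys()) + "\n")
        fh.write(",".join(str(v) for v in record.values()) + "\n")
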