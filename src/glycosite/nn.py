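"""The two binding-site networks: a 3D voxel UNet and an equivariant GNN.

Both models are implemented on numpy arrays with reverse-mode automatic
differentiation supplied by ``autograd``; parameters live in flat
name->array dicts so an optimizer can treat them uniformly.

Voxel UNet
----------
Input is a (28, 36, 36, 36) feature grid; output a per-voxel binding
probability on the same grid.  The initial 5³ convolution (with bias) embeds
the 28 feature channels into 32; nine blocks follow: four encoder blocks
(double convolution = 2 × [5³ conv, stride 1, padding 2 -> batch norm ->
ReLU], then max pooling) walking the channels 32→64→128→256 over grids
36→18→9→3→1, one 512-channel bottleneck block, and four decoder blocks
(transposed convolution with kernel = stride = the grid ratio, concatenation
of the equal-size encoder output, double convolution) back up to 32 channels
at 36³.  A final 5³ convolution condenses 32 channels to one, and a sigmoid
yields probabilities.  Convolutions inside double-conv blocks carry no bias
(batch norm follows immediately); the embedding conv, the transposed convs
and the final conv keep theirs.  Total trainable parameters: 102,676,001.

Equivariant GNN
---------------
Nodes are residues (29 features, Cβ coordinates); edges connect pairs within
12 Å and carry the distance.  A linear layer lifts 29→64, then eight
equivariant graph convolutional layers (EGCL) follow.  Each EGCL builds edge
messages from (h_i, h_j, squared distance, edge attribute) through a
two-layer edge MLP, gates them with a one-layer sigmoid attention MLP,
aggregates by sum, updates node features through a two-layer node MLP with a
residual connection, and moves coordinates along (x_i - x_j) scaled by a
two-layer coordinate MLP (mean over incident edges).  Node probabilities
come from a scalar head: a 64→1 projection of the final embedding plus a
29→1 projection of the raw input features (input residual), batch
normalization over the resulting logit, and a sigmoid.  Because every
learned quantity depends on coordinates only through pairwise distances, the
output probabilities are invariant under rigid transforms, and the updated
coordinates are equivariant.  Total trainable parameters: 236,009.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import autograd.numpy as anp
from autograd.tracer import getval

from .features import featurize, PropertyScales
from .graphs import NEIGHBOR_CUTOFF, ResidueGraph, build_graph
from .structure import ProteinStructure, compute_dihedrals
from .voxels import VoxelGrid, voxelize, devoxelize_all

_DIST_SCALE = NEIGHBOR_CUTOFF  # Å; normalizes distances fed to edge MLPs

# ---------------------------------------------------------------------------
# Functional layers


def relu(x):
    return anp.maximum(x, 0.0)


def sigmoid(x):
    # tanh form is overflow-safe; clipping only removes the (zero) gradient
    # tail beyond saturation, where cosh would overflow
    return 0.5 * (anp.tanh(anp.clip(0.5 * x, -30.0, 30.0)) + 1.0)


def _zero_pad3(x, p: int):
    """Zero-pad the three spatial axes of (C, D, H, W) by p on each side."""
    if p == 0:
        return x
    C, D, H, W = x.shape
    for axis, size in ((1, D), (2, H), (3, W)):
        shape = list(x.shape)
        shape[axis] = p
        z = anp.zeros(tuple(shape), dtype=getval(x).dtype)
        x = anp.concatenate([z, x, z], axis=axis)
    return x


def conv3d(x, w, b=None, pad: int | None = None):
    """'Same' 3D convolution. x: (C, D, H, W); w: (Co, C, k, k, k).

    Computed as a sum of shifted matrix products (one GEMM per kernel
    offset), which keeps peak memory low and stays autodiff-traceable.
    """
    C, D, H, W = x.shape
    Co, _, k, _, _ = w.shape
    if pad is None:
        pad = (k - 1) // 2
    xp = _zero_pad3(x, pad)
    n = D * H * W
    y = None
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                sub = anp.reshape(xp[:, dz:dz + D, dy:dy + H, dx:dx + W], (C, n))
                term = anp.dot(w[:, :, dz, dy, dx], sub)
                y = term if y is None else y + term
    if b is not None:
        y = y + b[:, None]
    return anp.reshape(y, (Co, D, H, W))


def maxpool3d(x, f: int):
    """Non-overlapping max pooling by factor f per axis."""
    C, D, H, W = x.shape
    z = anp.reshape(x, (C, D // f, f, H // f, f, W // f, f))
    z = anp.transpose(z, (0, 1, 3, 5, 2, 4, 6))
    z = anp.reshape(z, (C, D // f, H // f, W // f, f ** 3))
    return anp.max(z, axis=-1)


def convtranspose3d(x, w, b=None, f: int = 2):
    """Transposed 3D convolution with kernel = stride = f (no overlap).
    x: (Ci, D, H, W); w: (Ci, Co, f, f, f) -> (Co, D*f, H*f, W*f)."""
    Ci, D, H, W = x.shape
    Co = w.shape[1]
    y = anp.einsum("idhw,ioabc->odahbwc", x, w)
    y = anp.reshape(y, (Co, D * f, H * f, W * f))
    if b is not None:
        y = y + anp.reshape(b, (Co, 1, 1, 1))
    return y


def batchnorm(x, gamma, beta, state: dict, key: str, training: bool,
              momentum: float = 0.1, eps: float = 1e-5):
    """Batch normalization over all axes except the channel/feature axis.

    For volumes (C, D, H, W) the channel axis is 0; for node matrices (N, F)
    the feature axis is 1.  Running statistics live in `state` (plain numpy,
    outside the autodiff trace) and are used in evaluation mode.
    """
    if x.ndim == 4:
        axes, shape = (1, 2, 3), (-1, 1, 1, 1)
    else:
        axes, shape = (0,), (1, -1)
    if training:
        mean = anp.mean(x, axis=axes)
        var = anp.var(x, axis=axes)
        r_mean, r_var = state[key]
        state[key] = ((1 - momentum) * r_mean + momentum * getval(mean),
                      (1 - momentum) * r_var + momentum * getval(var))
    else:
        mean, var = state[key]
    xhat = (x - anp.reshape(mean, shape)) / anp.sqrt(anp.reshape(var, shape) + eps)
    return xhat * anp.reshape(gamma, shape) + anp.reshape(beta, shape)


# ---------------------------------------------------------------------------
# Parameter initialisation helpers


def _he_conv(rng, co, ci, k, dtype):
    fan_in = ci * k ** 3
    return (rng.standard_normal((co, ci, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _glorot(rng, n_in, n_out, dtype):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out)).astype(dtype)


def count_parameters(params: dict) -> int:
    return int(sum(v.size for v in params.values()))


# ---------------------------------------------------------------------------
# Voxel UNet


@dataclass
class VoxelUNetConfig:
    in_channels: int = 28
    embed_channels: int = 32
    encoder_channels: tuple = (32, 64, 128, 256)
    bottleneck_channels: int = 512
    grid_sizes: tuple = (36, 18, 9, 3, 1)
    kernel: int = 5
    stride: int = 1
    padding: int = 2

    def __post_init__(self):
        self.encoder_channels = tuple(self.encoder_channels)
        self.grid_sizes = tuple(self.grid_sizes)
        if self.embed_channels != self.encoder_channels[0]:
            raise ValueError("embed_channels must equal the first encoder width")
        for a, b in zip(self.encoder_channels, self.encoder_channels[1:]):
            if b != 2 * a:
                raise ValueError("encoder channels must double at each block")
        if self.bottleneck_channels != 2 * self.encoder_channels[-1]:
            raise ValueError("bottleneck must double the last encoder width")
        for g, h in zip(self.grid_sizes, self.grid_sizes[1:]):
            if g % h != 0 or g // h not in (2, 3):
                raise ValueError("grid sizes must shrink by integer factors 2 or 3")
        if self.stride != 1 or self.padding != (self.kernel - 1) // 2:
            raise ValueError("only stride-1 'same' convolutions are supported")

    @property
    def pool_factors(self) -> tuple:
        return tuple(g // h for g, h in zip(self.grid_sizes, self.grid_sizes[1:]))

    @property
    def up_factors(self) -> tuple:
        return self.pool_factors[::-1]

    @property
    def decoder_channels(self) -> tuple:
        return self.encoder_channels[::-1]


class VoxelUNet:
    """Nine-block 3D UNet over 36³ voxel grids (see module docstring)."""

    scheme = "voxel"

    def __init__(self, config: VoxelUNetConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.config = config or VoxelUNetConfig()
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = self.config
        k = c.kernel
        p: dict[str, np.ndarray] = {}
        self.state: dict = {}

        def add_bn(name, ch):
            p[f"{name}.gamma"] = np.ones(ch, dtype)
            p[f"{name}.beta"] = np.zeros(ch, dtype)
            self.state[name] = (np.zeros(ch), np.ones(ch))

        def add_double(name, ci, co, first_bias=False):
            p[f"{name}.conv1.w"] = _he_conv(rng, co, ci, k, dtype)
            if first_bias:
                p[f"{name}.conv1.b"] = np.zeros(co, dtype)
            add_bn(f"{name}.bn1", co)
            p[f"{name}.conv2.w"] = _he_conv(rng, co, co, k, dtype)
            add_bn(f"{name}.bn2", co)

        cin = c.in_channels
        for i, co in enumerate(c.encoder_channels):
            # the first convolution doubles as the 28->32 embedding and keeps a bias
            add_double(f"enc{i + 1}", cin, co, first_bias=(i == 0))
            cin = co
        add_double("bottleneck", cin, c.bottleneck_channels)
        cin = c.bottleneck_channels
        for i, (co, f) in enumerate(zip(c.decoder_channels, c.up_factors)):
            p[f"dec{i + 1}.up.w"] = (rng.standard_normal((cin, co, f, f, f))
                                     * np.sqrt(2.0 / cin)).astype(dtype)
            p[f"dec{i + 1}.up.b"] = np.zeros(co, dtype)
            add_double(f"dec{i + 1}", 2 * co, co)
            cin = co
        p["final.w"] = _he_conv(rng, 1, cin, k, dtype)
        p["final.b"] = np.zeros(1, dtype)
        self.params = p

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.params)

    def _double(self, params, name, x, training):
        c1 = conv3d(x, params[f"{name}.conv1.w"], params.get(f"{name}.conv1.b"))
        c1 = relu(batchnorm(c1, params[f"{name}.bn1.gamma"], params[f"{name}.bn1.beta"],
                            self.state, f"{name}.bn1", training))
        c2 = conv3d(c1, params[f"{name}.conv2.w"])
        return relu(batchnorm(c2, params[f"{name}.bn2.gamma"], params[f"{name}.bn2.beta"],
                              self.state, f"{name}.bn2", training))

    def forward(self, channels, params: dict | None = None, training: bool = False,
                return_logits: bool = False):
        """(n_features, G, G, G) -> (G, G, G) per-voxel probabilities."""
        params = self.params if params is None else params
        c = self.config
        x = anp.asarray(channels) if isinstance(channels, np.ndarray) else channels
        skips = []
        for i in range(len(c.encoder_channels)):
            x = self._double(params, f"enc{i + 1}", x, training)
            skips.append(x)
            x = maxpool3d(x, c.pool_factors[i])
        x = self._double(params, "bottleneck", x, training)
        for i, f in enumerate(c.up_factors):
            x = convtranspose3d(x, params[f"dec{i + 1}.up.w"],
                                params[f"dec{i + 1}.up.b"], f)
            x = anp.concatenate([skips[-1 - i], x], axis=0)
            x = self._double(params, f"dec{i + 1}", x, training)
        logits = conv3d(x, params["final.w"], params["final.b"])[0]
        if return_logits:
            return logits
        return sigmoid(logits)

    def grid_loss(self, params, grid: VoxelGrid, training: bool = True,
                  eps: float = 1e-6):
        from .training import soft_dice_loss
        probs = self.forward(grid.channels.astype(self.dtype), params, training)
        return soft_dice_loss(probs, grid.labels, eps)


def build_voxel_unet(config: VoxelUNetConfig | None = None,
                     seed: int = 0) -> tuple[VoxelUNet, int]:
    """Instantiate the voxel UNet; returns (model, trainable parameter count)."""
    model = VoxelUNet(config, seed=seed)
    return model, model.n_parameters


# ---------------------------------------------------------------------------
# Equivariant graph network


@dataclass
class EGNNConfig:
    in_features: int = 29
    hidden: int = 64
    num_layers: int = 8
    edge_attr_dim: int = 1
    head_style: str = "logit_residual"   # or "feature_residual" (literal wiring)

    def __post_init__(self):
        if self.head_style not in ("logit_residual", "feature_residual"):
            raise ValueError(f"unknown head_style {self.head_style!r}")


class ResidueEGNN:
    """Eight-layer EGNN over residue graphs (see module docstring)."""

    scheme = "graph"

    def __init__(self, config: EGNNConfig | None = None, seed: int = 0,
                 dtype=np.float64):
        self.config = config or EGNNConfig()
        self.dtype = dtype
        c = self.config
        rng = np.random.default_rng(seed)
        h, fin = c.hidden, c.in_features
        p: dict[str, np.ndarray] = {}
        self.state: dict = {}

        def lin(name, n_in, n_out, bias=True):
            p[f"{name}.w"] = _glorot(rng, n_in, n_out, dtype)
            if bias:
                p[f"{name}.b"] = np.zeros(n_out, dtype)

        lin("embed", fin, h)
        edge_in = 2 * h + 1 + c.edge_attr_dim
        for l in range(c.num_layers):
            lin(f"egcl{l}.edge1", edge_in, h)
            lin(f"egcl{l}.edge2", h, h)
            lin(f"egcl{l}.att", h, 1)
            lin(f"egcl{l}.node1", 2 * h, h)
            lin(f"egcl{l}.node2", h, h)
            lin(f"egcl{l}.coord1", h, h)
            lin(f"egcl{l}.coord2", h, 1, bias=False)
            # residual branches start small so the feature stream (and with it
            # the logits) stays well-conditioned through 8 sum-aggregating
            # layers on an untrained network
            p[f"egcl{l}.node2.w"] *= 0.1
            p[f"egcl{l}.coord2.w"] *= 0.1
        if c.head_style == "logit_residual":
            lin("head", h, 1)
            lin("skip", fin, 1)
            p["bn.gamma"] = np.ones(1, dtype)
            p["bn.beta"] = np.zeros(1, dtype)
            self.state["bn"] = (np.zeros(1), np.ones(1))
        else:
            lin("proj", h, fin)
            p["bn.gamma"] = np.ones(fin, dtype)
            p["bn.beta"] = np.zeros(fin, dtype)
            self.state["bn"] = (np.zeros(fin), np.ones(fin))
            lin("head", fin, 1)
        self.params = p

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.params)

    @staticmethod
    def _graph_arrays(graph: ResidueGraph):
        """Directed edges plus dense aggregation operators (constants)."""
        n = graph.n_nodes
        edges, attr = graph.directed()
        e = len(edges)
        if e == 0:
            return edges, attr.reshape(-1, 1), np.zeros((n, 0)), np.zeros((n, 0))
        tgt = edges[:, 0]
        M_sum = np.zeros((n, e))
        M_sum[tgt, np.arange(e)] = 1.0
        deg = np.maximum(M_sum.sum(axis=1, keepdims=True), 1.0)
        return edges, attr.reshape(-1, 1), M_sum, M_sum / deg

    def forward(self, graph: ResidueGraph, params: dict | None = None,
                training: bool = False, return_coords: bool = False):
        """Per-node binding probabilities (n,); optionally also the updated
        coordinates, which transform equivariantly with the input."""
        params = self.params if params is None else params
        if graph.n_nodes == 0:
            raise ValueError("graph has no nodes")
        c = self.config
        edges, attr, M_sum, M_mean = self._graph_arrays(graph)
        x0 = anp.asarray(graph.node_features, dtype=self.dtype)
        coords = anp.asarray(graph.node_coords, dtype=self.dtype)
        h = anp.dot(x0, params["embed.w"]) + params["embed.b"]
        n_edges = len(edges)

        for l in range(c.num_layers):
            if n_edges:
                i, j = edges[:, 0], edges[:, 1]
                diff = coords[i] - coords[j]
                # distances scaled by the neighbor cutoff keep edge-MLP inputs
                # O(1); raw squared Ångström distances (up to 144) would
                # saturate the sigmoid head of an untrained network
                radial = anp.sum(diff ** 2, axis=1, keepdims=True) / _DIST_SCALE ** 2
                inp = anp.concatenate([h[i], h[j], radial, attr / _DIST_SCALE], axis=1)
                m = relu(anp.dot(inp, params[f"egcl{l}.edge1.w"]) + params[f"egcl{l}.edge1.b"])
                m = relu(anp.dot(m, params[f"egcl{l}.edge2.w"]) + params[f"egcl{l}.edge2.b"])
                gate = sigmoid(anp.dot(m, params[f"egcl{l}.att.w"]) + params[f"egcl{l}.att.b"])
                m = m * gate
                agg = anp.dot(M_sum, m)
                s = relu(anp.dot(m, params[f"egcl{l}.coord1.w"]) + params[f"egcl{l}.coord1.b"])
                s = anp.dot(s, params[f"egcl{l}.coord2.w"])
                coords = coords + anp.dot(M_mean, diff * s)
            else:
                agg = anp.zeros((graph.n_nodes, c.hidden))
            upd = relu(anp.dot(anp.concatenate([h, agg], axis=1),
                               params[f"egcl{l}.node1.w"]) + params[f"egcl{l}.node1.b"])
            h = h + anp.dot(upd, params[f"egcl{l}.node2.w"]) + params[f"egcl{l}.node2.b"]

        if c.head_style == "logit_residual":
            logit = (anp.dot(h, params["head.w"]) + params["head.b"]
                     + anp.dot(x0, params["skip.w"]) + params["skip.b"])
            logit = batchnorm(logit, params["bn.gamma"], params["bn.beta"],
                              self.state, "bn", training)
            probs = sigmoid(logit[:, 0])
        else:
            v = anp.dot(h, params["proj.w"]) + params["proj.b"] + x0
            v = batchnorm(v, params["bn.gamma"], params["bn.beta"],
                          self.state, "bn", training)
            probs = sigmoid((anp.dot(v, params["head.w"]) + params["head.b"])[:, 0])
        if return_coords:
            return probs, coords
        return probs

    def graph_loss(self, params, graph: ResidueGraph, training: bool = True,
                   eps: float = 1e-6):
        from .training import soft_dice_loss
        probs = self.forward(graph, params, training)
        return soft_dice_loss(probs, graph.labels, eps)


def build_egnn(config: EGNNConfig | None = None, seed: int = 0) -> tuple[ResidueEGNN, int]:
    """Instantiate the EGNN; returns (model, trainable parameter count)."""
    model = ResidueEGNN(config, seed=seed)
    return model, model.n_parameters


# ---------------------------------------------------------------------------
# Structure-level prediction


def predict_structure(model, structure: ProteinStructure,
                      scales: PropertyScales | None = None,
                      sasa: np.ndarray | None = None) -> np.ndarray:
    """Run the full pipeline for one structure: featurize, encode
    (grid or graph), forward in evaluation mode, and return one probability
    per residue (voxel predictions are mapped back through the residue map,
    covering every residue even when the protein spans several grids)."""
    scheme = getattr(model, "scheme", None)
    if scheme == "voxel":
        table = featurize(structure, "voxel", scales=scales, sasa=sasa)
        grids = voxelize(table)
        probs = [np.asarray(model.forward(g.channels.astype(model.dtype),
                                          training=False)) for g in grids]
        return devoxelize_all(grids, probs, len(structure))
    if scheme == "graph":
        if any(r.phi is None and r.psi is None for r in structure.residues[1:-1]):
            compute_dihedrals(structure)
        table = featurize(structure, "graph", scales=scales, sasa=sasa)
        graph = build_graph(table)
        return np.asarray(model.forward(graph, training=False))
    raise ValueError(f"model with unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path, model) -> None:
    """Weights + running stats as .npz, config as a JSON sidecar."""
    arrays = {f"param/{k}": v for k, v in model.params.items()}
    for k, (m, v) in model.state.items():
        arrays[f"state_mean/{k}"] = m
        arrays[f"state_var/{k}"] = v
    np.savez(path, **arrays)
    meta = {"class": type(model).__name__, "config": asdict(model.config)}
    with open(str(path).removesuffix(".npz") + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path):
    with open(str(path).removesuffix(".npz") + ".json") as fh:
        meta = json.load(fh)
    cls = {"VoxelUNet": VoxelUNet, "ResidueEGNN": ResidueEGNN}[meta["class"]]
    cfg_cls = {"VoxelUNet": VoxelUNetConfig, "ResidueEGNN": EGNNConfig}[meta["class"]]
    cfg = meta["config"]
    for key in ("encoder_channels", "grid_sizes"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    model = cls(cfg_cls(**cfg))
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    model.params = {k[len("param/"):]: data[k] for k in data.files
                    if k.startswith("param/")}
    model.state = {k[len("state_mean/"):]: (data[k],
                   data["state_var/" + k[len("state_mean/"):]])
                   for k in data.files if k.startswith("state_mean/")}
    return model
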