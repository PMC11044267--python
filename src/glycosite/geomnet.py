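"""Rotation-equivariant geometric transformer for interface prediction.

The network consumes a protein atomic point cloud described only by element
identities and coordinates.  Each atom carries a scalar state ``q`` (S
features, rotation-invariant) and a vector state ``p`` (S channels of 3-D
vectors, rotation-equivariant, initialized to zero).  Local geometry enters
exclusively through pairwise distances ``D`` and unit displacement vectors
``R`` over a k-nearest-neighbor graph, which makes every layer translation
invariant by construction.

Layer update (applied residually, 24 layers by default with a neighborhood
schedule growing from 8 to 64 neighbors):

* an invariant feature is built for every (i, j) neighbor pair from
  ``q_i``, ``q_j``, ``D_ij`` and the projections ``p_i . R_ij``,
  ``p_j . R_ij``;
* multi-head attention: queries from the central atom's invariants
  ``(q_i, |p_i|)``, keys and scalar values from the pair invariants;
* the vector-value track is a linear composition of geometric vectors only
  — ``R_ij``, the neighbor channels ``p_j`` and the central channels
  ``p_i`` — with invariant coefficients, so the output vector state rotates
  exactly with the input;
* atoms with fewer real neighbors than the neighborhood size attend to sink
  slots that behave as a neighbor with zero scalar and vector state and
  contribute zero values.

Atomic states are pooled into one state per residue by multi-head attention
over the residue's atoms, and a three-layer MLP decodes the residue scalar
state concatenated with the per-channel Euclidean norms of the residue
vector state into per-class interface probabilities through a sigmoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import autograd as ag
from .autograd import Parameter, Tensor
from .structio import AtomicStructure, SubunitPartition, partition_subunits
from .dataset import protein_residues

__all__ = [
    "ELEMENTS",
    "ModelConfig",
    "NeighborhoodGeometry",
    "InterfaceModel",
    "knn_geometry",
]

# the 29 elements most common in PDB structures, plus a catch-all class (the
# final slot) for anything else; hydrogens never reach the model
ELEMENTS = [
    "C", "N", "O", "S", "P", "SE", "FE", "ZN", "MG", "CA",
    "NA", "K", "CL", "MN", "CU", "NI", "CO", "CD", "HG", "I",
    "BR", "F", "MO", "W", "AS", "B", "LI", "SR", "PT",
]
CATCH_ALL = "X"


def _default_schedule() -> tuple[int, ...]:
    return (8,) * 6 + (16,) * 6 + (32,) * 6 + (64,) * 6


@dataclass(frozen=True)
class ModelConfig:
    scalar_size: int = 32          # S: scalar features = vector channels per atom
    n_layers: int = 24
    n_heads: int = 2
    key_size: int = 3
    nn_schedule: tuple[int, ...] = field(default_factory=_default_schedule)
    pooling_heads: int = 4
    embed_mlp_depth: int = 3
    decode_mlp_depth: int = 3
    n_element_classes: int = 30
    output_classes: tuple[str, ...] = ("carbohydrate", "cyclodextrin")
    dist_scale: float = 0.1        # Å^-1, conditions raw distances in the keys

    def __post_init__(self):
        sched = tuple(self.nn_schedule)
        if len(sched) != self.n_layers:
            raise ValueError("nn_schedule length must equal n_layers")
        if any(b < a for a, b in zip(sched, sched[1:])):
            raise ValueError("nn_schedule must be non-decreasing")
        if sched[0] != 8 or sched[-1] != 64:
            raise ValueError("nn_schedule must grow from 8 to 64 neighbors")
        object.__setattr__(self, "nn_schedule", sched)

    @classmethod
    def scaled_down(cls, scalar_size: int = 16, n_layers: int = 4) -> "ModelConfig":
        """A desk-scale configuration (used by the overfit harness and tests)."""
        step = max(1, n_layers // 4)
        sched = []
        for nn in (8, 16, 32, 64):
            sched.extend([nn] * step)
        sched = sched[: n_layers - 1] + [64]
        return cls(scalar_size=scalar_size, n_layers=n_layers, nn_schedule=tuple(sched))


@dataclass
class NeighborhoodGeometry:
    """kNN graph of one point cloud, sink-padded to a fixed neighbor count."""

    indices: np.ndarray  # (N, nn) neighbor atom indices; 0 on sink slots
    D: np.ndarray        # (N, nn) pair distances, Å; 0 on sink slots
    R: np.ndarray        # (N, nn, 3) unit displacements; 0 rows on sink slots
    mask: np.ndarray     # (N, nn) 1.0 for real pairs, 0.0 for sink slots


def knn_geometry(coords: np.ndarray, nn: int) -> NeighborhoodGeometry:
    """Nearest neighbors by Euclidean distance, self excluded, ties broken by
    ascending atom index; missing neighbors become sink slots."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N, 3)")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    k_real = min(nn, n - 1)
    indices = np.zeros((n, nn), dtype=np.intp)
    D = np.zeros((n, nn))
    R = np.zeros((n, nn, 3))
    mask = np.zeros((n, nn))
    if k_real > 0:
        if n <= 2048:
            d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            # lexsort is stable: equal distances resolve by atom index
            order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
            idx = order[:, :k_real]
        else:
            tree = cKDTree(coords)
            dist, idx = tree.query(coords, k=k_real + 1)
            keep = np.empty((n, k_real), dtype=np.intp)
            for i in range(n):
                row = [j for j in idx[i] if j != i][:k_real]
                keep[i] = row
            idx = keep
        indices[:, :k_real] = idx
        disp = coords[idx] - coords[:, None, :]
        dist = np.linalg.norm(disp, axis=-1)
        D[:, :k_real] = dist
        R[:, :k_real] = disp / dist[..., None]
        mask[:, :k_real] = 1.0
    return NeighborhoodGeometry(indices, D, R, mask)


def _linear_init(rng: np.random.Generator, fan_in: int, fan_out: int, scale: float = 1.0):
    return Parameter(rng.normal(0.0, scale / np.sqrt(fan_in), size=(fan_in, fan_out)))


class InterfaceModel:
    """The full predictor: embedding, transformer stack, pooling, decoder."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.params: dict[str, Parameter] = {}
        self._init_params(np.random.default_rng(seed))
        self._element_index = {e: i for i, e in enumerate(ELEMENTS[: self.config.n_element_classes - 1])}

    # -- parameters --------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config
        S, H, K, P = c.scalar_size, c.n_heads, c.key_size, c.pooling_heads
        F = 4 * S + 1   # pair invariants: q_i, q_j, p_i.R, p_j.R, distance
        G = 2 * S       # central-atom invariants: q_i, |p_i|
        p = self.params

        dims = [c.n_element_classes] + [S] * c.embed_mlp_depth
        for i, (a, b) in enumerate(zip(dims, dims[1:])):
            p[f"emb_W{i}"] = _linear_init(rng, a, b)
            p[f"emb_b{i}"] = Parameter(np.zeros(b))

        out_scale = 1.0 / np.sqrt(c.n_layers)  # keeps the residual stack well-scaled
        for l in range(c.n_layers):
            p[f"l{l}_Wq"] = _linear_init(rng, G, H * K)
            p[f"l{l}_bq"] = Parameter(np.zeros(H * K))
            p[f"l{l}_Wk"] = _linear_init(rng, F, H * K)
            p[f"l{l}_bk"] = Parameter(np.zeros(H * K))
            p[f"l{l}_Wvq"] = _linear_init(rng, F, H * S)
            p[f"l{l}_bvq"] = Parameter(np.zeros(H * S))
            p[f"l{l}_Wvr"] = _linear_init(rng, F, H * S)
            if l > 0:
                # the first layer sees an all-zero vector state, so gates on
                # p_i / p_j would be dead parameters there: vectors are
                # seeded from the unit displacements alone
                p[f"l{l}_Wvp"] = _linear_init(rng, F, H * S)
                p[f"l{l}_Wvi"] = _linear_init(rng, F, H * S)
            p[f"l{l}_Woq"] = _linear_init(rng, H * S, S, scale=out_scale)
            p[f"l{l}_Wop"] = _linear_init(rng, H * S, S, scale=out_scale)

        p["pool_Wa"] = _linear_init(rng, G, P)
        p["pool_ba"] = Parameter(np.zeros(P))
        p["pool_Wq"] = _linear_init(rng, P * S, S)
        p["pool_bq"] = Parameter(np.zeros(S))
        p["pool_Wp"] = _linear_init(rng, P * S, S)

        dims = [G] + [S] * (c.decode_mlp_depth - 1) + [len(c.output_classes)]
        for i, (a, b) in enumerate(zip(dims, dims[1:])):
            p[f"dec_W{i}"] = _linear_init(rng, a, b)
            p[f"dec_b{i}"] = Parameter(np.zeros(b))

    def parameters(self) -> list[Parameter]:
        return [self.params[k] for k in sorted(self.params)]

    # -- building blocks ---------------------------------------------------

    def element_onehot(self, elements: list[str]) -> np.ndarray:
        """One-hot over the element vocabulary; unknown elements go to the
        reserved catch-all class (the last of the 30)."""
        c = self.config
        onehot = np.zeros((len(elements), c.n_element_classes))
        for i, e in enumerate(elements):
            onehot[i, self._element_index.get(e.upper(), c.n_element_classes - 1)] = 1.0
        return onehot

    def init_atom_states(self, structure_or_elements) -> tuple[Tensor, Tensor]:
        """Embed elements into the scalar state; vector state starts at zero."""
        if isinstance(structure_or_elements, AtomicStructure):
            elements = structure_or_elements.elements
        else:
            elements = list(structure_or_elements)
        x = Tensor(self.element_onehot(elements))
        for i in range(self.config.embed_mlp_depth):
            x = x @ self.params[f"emb_W{i}"] + self.params[f"emb_b{i}"]
            if i < self.config.embed_mlp_depth - 1:
                x = x.elu()
        n = len(elements)
        p0 = Tensor(np.zeros((n, self.config.scalar_size, 3)))
        return x, p0

    @staticmethod
    def _pnorm(p: Tensor) -> Tensor:
        return ((p * p).sum(axis=-1) + 1e-12).sqrt()

    def gt_layer(self, layer: int, q: Tensor, p: Tensor, geom: NeighborhoodGeometry) -> tuple[Tensor, Tensor]:
        """One residual geometric-transformer update."""
        c = self.config
        S, H, K = c.scalar_size, c.n_heads, c.key_size
        N, nn = geom.indices.shape
        if q.shape[0] != N:
            raise ValueError("states and geometry refer to different atom counts")
        P = self.params
        mask = geom.mask[..., None]                       # (N, nn, 1)
        R = Tensor(geom.R)                                # (N, nn, 3)
        d = Tensor(geom.D[..., None] * c.dist_scale)      # (N, nn, 1)

        q_j = q.take(geom.indices) * mask                 # (N, nn, S)
        p_j = p.take(geom.indices) * mask[..., None]      # (N, nn, S, 3)
        ones = np.ones((1, nn, 1))
        q_i = q.reshape(N, 1, S) * ones                   # broadcast copy
        p_i4 = p.reshape(N, 1, S, 3)
        pi_dot = (p_i4 * geom.R[:, :, None, :]).sum(axis=-1)        # (N, nn, S)
        pj_dot = (p_j * geom.R[:, :, None, :]).sum(axis=-1)         # (N, nn, S)
        feat = ag.concatenate([q_i, q_j, pi_dot, pj_dot, d], axis=-1)

        central = ag.concatenate([q, self._pnorm(p)], axis=-1)      # (N, 2S)
        Q = (central @ P[f"l{layer}_Wq"] + P[f"l{layer}_bq"]).reshape(N, 1, H, K)
        Kk = (feat @ P[f"l{layer}_Wk"] + P[f"l{layer}_bk"]).reshape(N, nn, H, K)
        logits = (Q * Kk).sum(axis=-1) * (1.0 / np.sqrt(K))         # (N, nn, H)
        # all padding slots stand for the same single sink node: only the
        # first one enters the softmax, so the padding width is inert
        n_real = geom.mask.sum(axis=1, keepdims=True)
        allowed = np.arange(nn)[None, :] < np.minimum(n_real + 1, nn)
        logits = logits + Tensor((allowed[..., None] - 1.0) * 1e9)
        att = ag.softmax(logits, axis=1)                            # over neighbor slots

        Vq = ((feat @ P[f"l{layer}_Wvq"] + P[f"l{layer}_bvq"]).elu() * mask).reshape(N, nn, H, S)
        dq = (att.reshape(N, nn, H, 1) * Vq).sum(axis=1)            # (N, H, S)
        dq = dq.reshape(N, H * S) @ P[f"l{layer}_Woq"]

        # vector values: invariant coefficients times geometric vectors only
        a_r = ((feat @ P[f"l{layer}_Wvr"]) * mask).reshape(N, nn, H, S)
        v = a_r.reshape(N, nn, H, S, 1) * R.reshape(N, nn, 1, 1, 3)
        if f"l{layer}_Wvp" in P:
            a_p = ((feat @ P[f"l{layer}_Wvp"]) * mask).reshape(N, nn, H, S)
            a_i = ((feat @ P[f"l{layer}_Wvi"]) * mask).reshape(N, nn, H, S)
            v = (
                v
                + a_p.reshape(N, nn, H, S, 1) * p_j.reshape(N, nn, 1, S, 3)
                + a_i.reshape(N, nn, H, S, 1) * p.reshape(N, 1, 1, S, 3)
            )                                                       # (N, nn, H, S, 3)
        dp = (att.reshape(N, nn, H, 1, 1) * v).sum(axis=1)          # (N, H, S, 3)
        dp = dp.reshape(N, H * S, 3).swapaxes(-1, -2) @ P[f"l{layer}_Wop"]
        dp = dp.swapaxes(-1, -2)                                    # (N, S, 3)
        return q + dq, p + dp

    def _pool_residues(self, q: Tensor, p: Tensor, residue_atoms: list[list[int]]) -> tuple[Tensor, Tensor]:
        """Attention-pool atomic states into one state per residue."""
        c = self.config
        S, Ph = c.scalar_size, c.pooling_heads
        nres = len(residue_atoms)
        amax = max(len(idx) for idx in residue_atoms)
        pad_idx = np.zeros((nres, amax), dtype=np.intp)
        pad_mask = np.zeros((nres, amax))
        for r, idx in enumerate(residue_atoms):
            pad_idx[r, : len(idx)] = idx
            pad_mask[r, : len(idx)] = 1.0
        qa = q.take(pad_idx)                               # (R, A, S)
        pa = p.take(pad_idx)                               # (R, A, S, 3)
        h = ag.concatenate([qa, self._pnorm(pa)], axis=-1)  # (R, A, 2S)
        logits = h @ self.params["pool_Wa"] + self.params["pool_ba"]  # (R, A, Ph)
        logits = logits + Tensor((pad_mask[..., None] - 1.0) * 1e9)
        att = ag.softmax(logits, axis=1)
        q_r = (att.reshape(nres, amax, Ph, 1) * qa.reshape(nres, amax, 1, S)).sum(axis=1)
        q_r = q_r.reshape(nres, Ph * S) @ self.params["pool_Wq"] + self.params["pool_bq"]
        p_r = (att.reshape(nres, amax, Ph, 1, 1) * pa.reshape(nres, amax, 1, S, 3)).sum(axis=1)
        p_r = p_r.reshape(nres, Ph * S, 3).swapaxes(-1, -2) @ self.params["pool_Wp"]
        p_r = p_r.swapaxes(-1, -2)                         # (R, S, 3)
        return q_r, p_r

    def _decode(self, q_r: Tensor, p_r: Tensor) -> Tensor:
        x = ag.concatenate([q_r, self._pnorm(p_r)], axis=-1)
        for i in range(self.config.decode_mlp_depth):
            x = x @ self.params[f"dec_W{i}"] + self.params[f"dec_b{i}"]
            if i < self.config.decode_mlp_depth - 1:
                x = x.elu()
        return x.sigmoid()

    # -- forward pass ------------------------------------------------------

    def forward_tensor(
        self,
        structure: AtomicStructure,
        partition: SubunitPartition | None = None,
    ) -> tuple[Tensor, list[tuple[str, int, str]], list[str]]:
        """Run the network on the protein atoms of ``structure``.

        Returns per-residue probabilities as an autograd tensor of shape
        (n_residues, n_output_classes) plus the residue keys and names.
        Only protein atoms enter the model: ligands present in a training
        complex define the labels, not the input.
        """
        partition = partition or partition_subunits(structure)
        residues = protein_residues(structure, partition)
        if not residues:
            raise ValueError("no protein residues in structure")
        atom_idx = [i for _, _, idx in residues for i in idx]
        remap = {orig: k for k, orig in enumerate(atom_idx)}
        coords = structure.coords[atom_idx]
        elements = [structure.atoms[i].element for i in atom_idx]
        residue_atoms = [[remap[i] for i in idx] for _, _, idx in residues]

        q, p = self.init_atom_states(elements)
        geom_cache: dict[int, NeighborhoodGeometry] = {}
        for layer, nn in enumerate(self.config.nn_schedule):
            if nn not in geom_cache:
                geom_cache[nn] = knn_geometry(coords, nn)
            q, p = self.gt_layer(layer, q, p, geom_cache[nn])
        q_r, p_r = self._pool_residues(q, p, residue_atoms)
        probs = self._decode(q_r, p_r)
        return probs, [k for k, _, _ in residues], [n for _, n, _ in residues]

    def predict(
        self,
        structure: AtomicStructure,
        partition: SubunitPartition | None = None,
    ) -> pd.DataFrame:
        """Per-residue interface probabilities as a DataFrame."""
        probs, keys, names = self.forward_tensor(structure, partition)
        out = pd.DataFrame(
            {
                "chain": [k[0] for k in keys],
                "resnum": [k[1] for k in keys],
                "icode": [k[2] for k in keys],
                "resname": names,
            }
        )
        for j, cls in enumerate(self.config.output_classes):
            out[f"p_{cls}"] = probs.data[:, j]
        return out

    # -- serialization -----------------------------------------------------

    CHECKPOINT_VERSION = 1

    def save(self, path: str | Path) -> None:
        """Write a versioned checkpoint (npz with the config embedded)."""
        cfg = asdict(self.config)
        cfg["nn_schedule"] = list(cfg["nn_schedule"])
        cfg["output_classes"] = list(cfg["output_classes"])
        np.savez(
            path,
            __meta__=np.array(
                json.dumps({"version": self.CHECKPOINT_VERSION, "config": cfg})
            ),
            **{k: v.data for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "InterfaceModel":
        with np.load(path, allow_pickle=False) as blob:
            meta = json.loads(str(blob["__meta__"]))
            if meta.get("version") != cls.CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            cfg = meta["config"]
            cfg["nn_schedule"] = tuple(cfg["nn_schedule"])
            cfg["output_classes"] = tuple(cfg["output_classes"])
            model = cls(ModelConfig(**cfg))
            for k in model.params:
                model.params[k] = Parameter(blob[k])
        return model
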