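"""The improved hierarchical point-cloud segmentation network.

Encoder-decoder over raw coordinates: stacked set-abstraction (SA) layers that
halve the centre count (farthest point sampling + KNN grouping + shared MLP),
each augmented with

* local spatial encoding (LSE): per neighbour, the 10-vector
  [p_i, p_ik, p_i - p_ik, d(p_i, p_ik)] is mapped by a shared MLP to the
  feature width and concatenated with the neighbour's feature, and
* density-aware pooling (DAP): each centre is classified high/low density
  against its neighbourhood mean; max pooling aggregates the high-density
  branch, attention pooling the low-density branch, and the selected and
  complementary aggregates are concatenated and fused by an MLP.

Feature-propagation (FP) layers interpolate coarse features back onto finer
levels with inverse-distance weights over the 3 nearest coarse points, fused
with skip features by a unit MLP. A shared classifier head emits per-point
stem/leaf logits. Both LSE and DAP can be disabled, which reduces each SA
layer to plain grouped-MLP + max pooling for ablation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autograd import Tensor, concat, parameter, softmax
from .pointops import (
    DENSITY_EPS,
    Neighborhood,
    farthest_point_sample,
    full_cloud_density,
    knn_group,
    partition_by_density,
)

FP_EPS = 1e-8


class NetworkConfigError(ValueError):
    pass


@dataclass
class SALayerConfig:
    """One set-abstraction layer: centre count, neighbourhood size, MLP widths,
    and the two ablation switches."""

    n_centers: int
    K: int = 16
    mlp_channels: tuple[int, ...] = (64, 128)
    uses_lse: bool = True
    uses_dap: bool = True

    def __post_init__(self) -> None:
        if self.n_centers < 1:
            raise NetworkConfigError("n_centers must be >= 1")
        if self.K < 1:
            raise NetworkConfigError("K must be >= 1")
        if not self.mlp_channels:
            raise NetworkConfigError("mlp_channels must be non-empty")


@dataclass
class NetConfig:
    """Full architecture: input size, SA stack (halving centre counts), FP
    widths mirror the encoder; widths default to the 8192-point configuration."""

    num_points: int = 8192
    k: int = 16
    input_embed: tuple[int, ...] = (32, 32)
    sa_channels: tuple[tuple[int, ...], ...] = ((64, 128), (128, 256), (256, 512))
    fp_channels: tuple[int, ...] = (256, 128)
    head_channels: int = 128
    dropout: float = 0.5
    uses_lse: bool = True
    uses_dap: bool = True
    n_classes: int = 2
    seed: int = 0

    def sa_configs(self) -> list[SALayerConfig]:
        configs = []
        n = self.num_points
        for widths in self.sa_channels:
            n = n // 2
            configs.append(
                SALayerConfig(
                    n_centers=n,
                    K=self.k,
                    mlp_channels=tuple(widths),
                    uses_lse=self.uses_lse,
                    uses_dap=self.uses_dap,
                )
            )
        return configs


class SharedMLP:
    """Shared per-point MLP applied along the last axis.

    Each layer is linear -> channel normalization -> ReLU. Normalization is
    per channel over all points of the cloud (instance-norm statistics), the
    convention in hierarchical point networks; it is computed from the data
    of every forward pass, so train and eval behave identically. The last
    layer drops norm+ReLU when ``final_relu`` is false (score / logit heads).
    """

    LN_EPS = 1e-5

    def __init__(self, rng: np.random.Generator, in_dim: int, widths: Sequence[int],
                 final_relu: bool = True, norm: bool = True):
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        self.gammas: list[Optional[Tensor]] = []
        self.betas: list[Optional[Tensor]] = []
        self.final_relu = final_relu
        prev = in_dim
        for i, w in enumerate(widths):
            self.weights.append(parameter(rng, prev, (prev, w)))
            self.biases.append(Tensor(np.zeros(w), requires_grad=True))
            if norm and (final_relu or i < len(widths) - 1):
                self.gammas.append(Tensor(np.ones(w), requires_grad=True))
                self.betas.append(Tensor(np.zeros(w), requires_grad=True))
            else:
                self.gammas.append(None)
                self.betas.append(None)
            prev = w
        self.out_dim = prev

    def __call__(self, x: Tensor) -> Tensor:
        n_layers = len(self.weights)
        for i in range(n_layers):
            x = x @ self.weights[i] + self.biases[i]
            if self.final_relu or i < n_layers - 1:
                if self.gammas[i] is not None:
                    shape = x.shape
                    flat = x.reshape(-1, shape[-1])
                    mu = flat.mean(axis=0, keepdims=True)
                    xc = flat - mu
                    var = (xc * xc).mean(axis=0, keepdims=True)
                    normed = xc / (var + self.LN_EPS).sqrt()
                    x = (normed * self.gammas[i] + self.betas[i]).reshape(*shape)
                x = x.relu()
        return x

    def parameters(self) -> list[Tensor]:
        extras = [g for g in self.gammas if g is not None]
        extras += [b for b in self.betas if b is not None]
        return self.weights + self.biases + extras


def lse_encode(
    coords: np.ndarray,
    features: Tensor,
    nbhd: Neighborhood,
    mlp: SharedMLP,
) -> Tensor:
    """Position-enhanced neighbour features t_ik = r_ik (+) q_ik (M x K x 2d).

    r_ik = MLP([p_i (+) p_ik (+) (p_i - p_ik) (+) d(p_i, p_ik)]) with the MLP
    output width matching the feature width d of q_ik.
    """
    centers = coords[nbhd.center_indices]  # M x 3
    neighbors = coords[nbhd.neighbor_indices]  # M x K x 3
    rel = centers[:, None, :] - neighbors
    dist = nbhd.neighbor_distances[:, :, None]
    K = nbhd.K
    raw = np.concatenate(
        [np.broadcast_to(centers[:, None, :], neighbors.shape), neighbors, rel, dist],
        axis=-1,
    )  # M x K x 10
    r = mlp(Tensor(raw))
    q = features.take(nbhd.neighbor_indices)  # M x K x d
    if r.shape[-1] != q.shape[-1]:
        raise NetworkConfigError(
            f"LSE output width {r.shape[-1]} != feature width {q.shape[-1]}"
        )
    return concat([r, q], axis=-1)


def attention_pool(neighbor_features: Tensor, scorer: SharedMLP) -> Tensor:
    """Softmax-weighted neighbour sum: per-channel scores over the K axis."""
    scores = scorer(neighbor_features)
    if scores.shape != neighbor_features.shape:
        raise NetworkConfigError("scorer must preserve the feature width")
    weights = softmax(scores, axis=1)
    return (weights * neighbor_features).sum(axis=1)


def max_pool(neighbor_features: Tensor) -> Tensor:
    """Channelwise max over the K neighbours (M x K x d -> M x d)."""
    return neighbor_features.max(axis=1)


def dap_pool(
    t_ik: Tensor,
    high_mask: np.ndarray,
    fusion_mlp: Optional[SharedMLP],
    scorer: SharedMLP,
) -> Tensor:
    """Density-aware pooling.

    Both aggregates are computed for every centre; the density class decides
    which branch is the selected one. The concatenated [selected, complementary]
    vector is fused to the output width (identity fusion when fusion_mlp is
    None, used by shape tests).
    """
    f_att = attention_pool(t_ik, scorer)
    f_max = max_pool(t_ik)
    mask = Tensor(high_mask[:, None].astype(np.float64))
    inv = Tensor((~high_mask)[:, None].astype(np.float64))
    selected = f_max * mask + f_att * inv
    complementary = f_att * mask + f_max * inv
    fused = concat([selected, complementary], axis=-1)
    if fusion_mlp is not None:
        fused = fusion_mlp(fused)
    return fused


class SALayer:
    """Sampling + grouping + MLP lift + LSE + DAP (or plain grouped max-pool)."""

    def __init__(self, rng: np.random.Generator, in_dim: int, config: SALayerConfig):
        self.config = config
        d_out = config.mlp_channels[-1]
        if config.uses_lse or config.uses_dap:
            self.lift = SharedMLP(rng, in_dim, config.mlp_channels)
            d = d_out
            if config.uses_lse:
                self.lse_mlp = SharedMLP(rng, 10, (max(d // 2, 8), d))
                grouped_dim = 2 * d
            else:
                self.lse_mlp = None
                grouped_dim = d + 3  # relative coords appended instead
            if config.uses_dap:
                self.scorer = SharedMLP(rng, grouped_dim, (grouped_dim,), final_relu=False)
                self.fusion = SharedMLP(rng, 2 * grouped_dim, (d_out,))
            else:
                self.scorer = None
                self.fusion = SharedMLP(rng, grouped_dim, (d_out,))
        else:
            # vanilla PointNet++-style layer: group [rel_coords, features],
            # shared MLP, channelwise max
            self.lift = None
            self.lse_mlp = None
            self.scorer = None
            self.fusion = SharedMLP(rng, in_dim + 3, config.mlp_channels)
        self.out_dim = d_out

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for mod in (self.lift, self.lse_mlp, self.scorer, self.fusion):
            if mod is not None:
                params.extend(mod.parameters())
        return params

    def __call__(
        self, coords: np.ndarray, features: Tensor, seed: int = 0,
        start_index: int | None = None,
    ) -> tuple[np.ndarray, Tensor]:
        cfg = self.config
        centers = farthest_point_sample(coords, cfg.n_centers, seed=seed,
                                        start_index=start_index)
        nbhd = knn_group(coords, centers, cfg.K)
        if cfg.uses_lse or cfg.uses_dap:
            lifted = self.lift(features)
            if cfg.uses_lse:
                grouped = lse_encode(coords, lifted, nbhd, self.lse_mlp)
            else:
                q = lifted.take(nbhd.neighbor_indices)
                rel = coords[centers][:, None, :] - coords[nbhd.neighbor_indices]
                grouped = concat([Tensor(rel), q], axis=-1)
            if cfg.uses_dap:
                field, _ = full_cloud_density(coords, cfg.K)
                high = partition_by_density(field, nbhd)
                pooled = dap_pool(grouped, high, self.fusion, self.scorer)
            else:
                pooled = self.fusion(max_pool(grouped))
        else:
            q = features.take(nbhd.neighbor_indices)
            rel = coords[centers][:, None, :] - coords[nbhd.neighbor_indices]
            grouped = self.fusion(concat([Tensor(rel), q], axis=-1))
            pooled = max_pool(grouped)
        return coords[centers], pooled


def interpolate_features(
    coords_fine: np.ndarray, coords_coarse: np.ndarray, feats_coarse: Tensor
) -> Tensor:
    """Inverse-distance interpolation of coarse features onto fine points.

    Weights 1/(d + eps) over the 3 nearest coarse points, normalized to sum 1.
    """
    from scipy.spatial import cKDTree

    k = min(3, len(coords_coarse))
    tree = cKDTree(coords_coarse)
    dists, idx = tree.query(coords_fine, k=k)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    w = 1.0 / (dists + FP_EPS)
    w = w / w.sum(axis=1, keepdims=True)
    gathered = feats_coarse.take(idx)  # N_fine x k x d
    return (gathered * Tensor(w[:, :, None])).sum(axis=1)


class FPLayer:
    """Feature propagation: interpolate + concat skip + unit MLP."""

    def __init__(self, rng: np.random.Generator, coarse_dim: int, skip_dim: int,
                 out_dim: int):
        self.mlp = SharedMLP(rng, coarse_dim + skip_dim, (out_dim,))
        self.out_dim = out_dim

    def parameters(self) -> list[Tensor]:
        return self.mlp.parameters()

    def __call__(
        self,
        coords_coarse: np.ndarray,
        feats_coarse: Tensor,
        coords_fine: np.ndarray,
        feats_skip: Tensor,
    ) -> Tensor:
        interp = interpolate_features(coords_fine, coords_coarse, feats_coarse)
        return self.mlp(concat([interp, feats_skip], axis=-1))


class SegmentationNetwork:
    """Encoder (SA stack) + decoder (FP stack) + shared classifier head."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        sa_configs = config.sa_configs()
        # full-resolution input embedding: per-point MLP of the normalized
        # coordinates; also serves as the finest-level skip for the decoder
        self.embed = (
            SharedMLP(rng, 3, config.input_embed) if config.input_embed else None
        )
        in_dim = self.embed.out_dim if self.embed else 3
        self.sa_layers: list[SALayer] = []
        for sa_cfg in sa_configs:
            layer = SALayer(rng, in_dim, sa_cfg)
            self.sa_layers.append(layer)
            in_dim = layer.out_dim
        # decoder mirrors the encoder; finest skip is the input embedding
        self.fp_layers: list[FPLayer] = []
        finest_dim = self.embed.out_dim if self.embed else 3
        skip_dims = [finest_dim] + [l.out_dim for l in self.sa_layers[:-1]]
        coarse_dim = self.sa_layers[-1].out_dim
        fp_widths = list(config.fp_channels)
        while len(fp_widths) < len(self.sa_layers):
            fp_widths.append(fp_widths[-1])
        for lvl in reversed(range(len(self.sa_layers))):
            out_dim = fp_widths[len(self.sa_layers) - 1 - lvl]
            self.fp_layers.append(FPLayer(rng, coarse_dim, skip_dims[lvl], out_dim))
            coarse_dim = out_dim
        self.head_hidden = SharedMLP(rng, coarse_dim, (config.head_channels,))
        self.head_out = SharedMLP(
            rng, config.head_channels, (config.n_classes,), final_relu=False
        )
        # zero-init the final linear so an untrained head emits uniform logits
        self.head_out.weights[0].data[:] = 0.0
        self.dropout = config.dropout

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if self.embed is not None:
            params.extend(self.embed.parameters())
        for layer in self.sa_layers + self.fp_layers:
            params.extend(layer.parameters())
        params.extend(self.head_hidden.parameters())
        params.extend(self.head_out.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def forward(
        self,
        coords: np.ndarray,
        seed: int = 0,
        training: bool = False,
        fps_start: Optional[Sequence[int]] = None,
        dropout_seed: Optional[int] = None,
    ) -> Tensor:
        """Per-point logits (N x n_classes) for a normalized cloud.

        ``seed`` pins the FPS sampling hierarchy; ``dropout_seed`` (training
        only) draws the dropout mask independently of it, so repeated passes
        over one cloud can keep the same centres but fresh dropout.
        ``fps_start`` optionally pins the FPS start index of each SA layer
        (used by the permutation-equivariance test).
        """
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise NetworkConfigError(f"expected N x 3 coords, got {coords.shape}")
        if len(coords) != self.config.num_points:
            raise NetworkConfigError(
                f"expected {self.config.num_points} points, got {len(coords)}"
            )
        rng = np.random.default_rng(seed)
        f0 = Tensor(coords)
        if self.embed is not None:
            f0 = self.embed(f0)
        levels = [(coords, f0)]
        for i, layer in enumerate(self.sa_layers):
            c, f = levels[-1]
            start = None if fps_start is None else int(fps_start[i])
            layer_seed = int(rng.integers(0, 2**31 - 1))
            c2, f2 = layer(c, f, seed=layer_seed, start_index=start)
            levels.append((c2, f2))
        coords_out, feats = levels[-1]
        for j, fp in enumerate(self.fp_layers):
            lvl = len(self.sa_layers) - 1 - j
            c_fine, f_skip = levels[lvl]
            feats = fp(coords_out, feats, c_fine, f_skip)
            coords_out = c_fine
        h = self.head_hidden(feats)
        if training and self.dropout > 0:
            drop_rng = (
                np.random.default_rng(dropout_seed) if dropout_seed is not None else rng
            )
            keep = 1.0 - self.dropout
            mask = drop_rng.random(h.shape) < keep
            h = h * Tensor(mask.astype(np.float64) / keep)
        return self.head_out(h)

    # ---- checkpointing ----------------------------------------------------

    def state_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "config": asdict(self.config),
            "params": [p.data.copy() for p in self.parameters()],
        }

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state["params"]) != len(params):
            raise NetworkConfigError("checkpoint parameter count mismatch")
        for p, data in zip(params, state["params"]):
            if p.data.shape != np.asarray(data).shape:
                raise NetworkConfigError("checkpoint shape mismatch")
            p.data = np.asarray(data, dtype=np.float64).copy()

    def save(self, path) -> None:
        import json
        from dataclasses import asdict

        state = {
            "config": asdict(self.config),
            "params": [p.data.tolist() for p in self.parameters()],
        }
        with open(path, "w") as fh:
            json.dump(state, fh)

    @classmethod
    def load(cls, path) -> "SegmentationNetwork":
        import json

        with open(path) as fh:
            state = json.load(fh)
        cfg = state["config"]
        cfg["sa_channels"] = tuple(tuple(w) for w in cfg["sa_channels"])
        cfg["fp_channels"] = tuple(cfg["fp_channels"])
        cfg["input_embed"] = tuple(cfg.get("input_embed", ()))
        net = cls(NetConfig(**cfg))
        net.load_state_dict({"config": cfg, "params": state["params"]})
        return net
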