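"""Autoregressive prior over the discrete latent grid.

The prior factorizes p(z) over latent positions in raster order (row-major,
left-to-right, top-to-bottom): p(z) = prod_i p(z_i | z_<i).  Causality is
enforced structurally with masked convolutions (PixelCNN masks: the first
layer excludes the centre tap, later layers include it) and, optionally,
causally-masked self-attention as used at clinical scale; the desk preset
omits attention since a 16x16 grid is small, leaving the causality contract
unchanged.

Scan-wise anomaly scoring sums the per-position negative log-likelihood
(natural log) over cells whose NLL exceeds a threshold t_ar, itself
calibrated as a percentile (default 95th) of pooled per-cell NLL values on
healthy validation scans.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .nn import functional as F


@dataclass(frozen=True)
class ArConfig:
    codebook_size: int = 32                # K symbols
    channels: int = 64
    n_blocks: int = 3                      # masked 3x3 blocks after the first layer
    first_kernel: int = 5
    embed_dim: int = 16                    # 0 = feed one-hot symbols directly
    use_attention: bool = False
    augment_symmetries: bool = False       # flips/rot90 of the latent grid
    learning_rate: float = 1e-3
    epochs: int = 24
    batch_size: int = 16
    rng_seed: int = 0


def _pixelcnn_mask(kernel: int, include_center: bool) -> np.ndarray:
    m = np.zeros((kernel, kernel), dtype=np.float32)
    c = kernel // 2
    m[:c, :] = 1.0
    m[c, :c] = 1.0
    if include_center:
        m[c, c] = 1.0
    return m


class MaskedConv2d(nn.Module):
    """Convolution whose kernel is multiplied by a fixed raster-causal mask."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, include_center: bool,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, padding=kernel // 2, rng=rng)
        mask = _pixelcnn_mask(kernel, include_center)
        self.mask = nn.Tensor(mask[None, None].astype(np.float32))

    def forward(self, x):
        w = self.conv.weight * self.mask
        return F.conv2d(x, w, self.conv.bias, 1, self.conv.padding)


class CausalSelfAttention(nn.Module):
    """Single-head attention over raster-flattened positions, j <= i only."""

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.q = nn.Conv2d(ch, ch, 1, rng=rng)
        self.k = nn.Conv2d(ch, ch, 1, rng=rng)
        self.v = nn.Conv2d(ch, ch, 1, rng=rng)
        self.scale = 1.0 / np.sqrt(ch)

    def forward(self, x):
        N, C, H, W = x.shape
        L = H * W
        q = self.q(x).reshape(N, C, L).transpose(0, 2, 1)
        k = self.k(x).reshape(N, C, L)
        v = self.v(x).reshape(N, C, L).transpose(0, 2, 1)
        scores = (q @ k) * self.scale                      # (N, L, L)
        bias = np.triu(np.full((L, L), -1e9, dtype=np.float32), k=1)
        scores = scores + nn.Tensor(bias[None])
        attn = F.softmax(scores, axis=2)
        out = (attn @ v).transpose(0, 2, 1).reshape(N, C, H, W)
        return x + out


class _MaskedResBlock(nn.Module):
    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = MaskedConv2d(ch, ch, 3, True, rng)
        self.conv2 = nn.Conv2d(ch, ch, 1, rng=rng)

    def forward(self, x):
        return x + self.conv2(self.conv1(x.relu()).relu())


class ArPrior(nn.Module):
    def __init__(self, cfg: ArConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        self.rng = rng
        # a 1x1 embedding touches only its own position; the type-A first
        # convolution excludes the centre tap, so causality is preserved
        in_ch = cfg.embed_dim if cfg.embed_dim else cfg.codebook_size
        self.embed = (nn.Conv2d(cfg.codebook_size, cfg.embed_dim, 1, rng=rng)
                      if cfg.embed_dim else None)
        self.first = MaskedConv2d(in_ch, cfg.channels,
                                  cfg.first_kernel, False, rng)
        blocks: List[nn.Module] = []
        for _ in range(cfg.n_blocks):
            blocks.append(_MaskedResBlock(cfg.channels, rng))
            if cfg.use_attention:
                blocks.append(CausalSelfAttention(cfg.channels, rng))
        self.blocks = nn.Sequential(*blocks)
        self.head = nn.Conv2d(cfg.channels, cfg.codebook_size, 1, rng=rng)

    def forward(self, x):
        if self.embed is not None:
            x = self.embed(x)
        return self.head(self.blocks(self.first(x)).relu())


def _one_hot(latents: np.ndarray, K: int) -> np.ndarray:
    z = np.asarray(latents)
    oh = np.zeros((K,) + z.shape, dtype=np.float32)
    np.put_along_axis(oh, z[None], 1.0, axis=0)
    return oh


def nll_map(latents: np.ndarray, model: ArPrior) -> np.ndarray:
    """Per-position NLL (nats) of a latent grid under the causal model.

    The cells sum to -log p(z) of the whole grid.
    """
    z = np.asarray(latents)
    K = model.cfg.codebook_size
    if z.max() >= K or z.min() < 0:
        raise ValueError(f"latent index out of range [0, {K})")
    model.eval()
    with nn.no_grad():
        logits = model(nn.Tensor(_one_hot(z, K)[None]))
        lp = F.log_softmax(logits, axis=1).data[0]
    return -np.take_along_axis(lp, z[None], axis=0)[0].astype(np.float64)


def scan_score(nll: np.ndarray, t_ar: float) -> float:
    """Sum of NLL cells strictly above the threshold t_ar."""
    from .postprocess import scanwise_from_map

    if t_ar < 0:
        raise ValueError("t_ar must be >= 0")
    return scanwise_from_map(nll, t_ar)


def calibrate_t_ar(validation_nll_values: Sequence[float],
                   percentile: float = 95.0) -> float:
    """Percentile (linear interpolation) of pooled validation cell NLLs."""
    vals = np.asarray(list(validation_nll_values), dtype=np.float64).ravel()
    if vals.size == 0:
        raise ValueError("validation NLL collection is empty")
    return float(np.percentile(vals, percentile))


def train_ar(latent_dataset: Sequence[np.ndarray],
             cfg: Optional[ArConfig] = None) -> ArPrior:
    """Fit the causal prior by per-position cross-entropy on latent grids."""
    cfg = cfg or ArConfig()
    grids = [np.asarray(g) for g in latent_dataset]
    if not grids:
        raise ValueError("latent dataset is empty")
    model = ArPrior(cfg)
    model.train()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    K = cfg.codebook_size
    log: List[dict] = []
    n = len(grids)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = []
            for i in sel:
                g = grids[i]
                if cfg.augment_symmetries:
                    if rng.random() < 0.5:
                        g = g[:, ::-1]
                    g = np.rot90(g, int(rng.integers(0, 4)))
                batch.append(np.ascontiguousarray(g))
            z = np.stack(batch)
            x = nn.Tensor(np.stack([_one_hot(grids[i], K) for i in sel]))
            logits = model(x)
            loss = F.cross_entropy(logits, z, axis=1)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            nb += 1
        log.append({"epoch": epoch, "cross_entropy": total / nb})
    model.eval()
    model.train_log = log
    return model


def save_ar(model: ArPrior, path) -> None:
    state = model.state_dict()
    state["__config__"] = json.dumps(dataclasses.asdict(model.cfg))
    np.savez(Path(path), **state)


def load_ar(path) -> ArPrior:
    data = np.load(Path(path), allow_pickle=False)
    model = ArPrior(ArConfig(**json.loads(str(data["__config__"]))))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model
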