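"""Vector-quantized autoencoder over healthy en face images.

The encoder compresses an image by a fixed spatial factor (4x desk
default: a 128-px image yields a 32x32 latent grid; the clinical preset
uses 8x, 480 -> 60) into d-dimensional feature vectors, each replaced by
its nearest codebook prototype (Euclidean, ties to the lowest index).
Training minimizes

    L = |x - D(e)|_1  +  ||sg[E(x)] - e||^2  +  w_c * ||sg[e] - E(x)||^2

where sg is stop-gradient: the alignment term moves only codebook vectors,
the commitment term only the encoder, and reconstruction gradients pass
straight through the quantizer.  The per-cell squared distance between
encoder output and selected code — the Alignment Loss Map (ALM) — is the
pixel-wise anomaly score source: codes track healthy structure, so unusual
structure lands far from every prototype.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .imgio import read_image
from .synthetic import DatasetManifest


@dataclass(frozen=True)
class VqVaeConfig:
    """Architecture + training configuration.

    The desk preset (default) compresses 128-px phantoms 4x to a 32x32
    latent grid with a 64-key, 64-dim codebook: the finer-than-clinical
    spatial ratio keeps the latent grid large enough for stable
    tail-sum scan statistics at desk resolution.  ``clinical_preset`` restores
    the clinical-scale sizes (480 px, 8x ratio, K=128, d=256, 200 epochs).
    """

    image_size: int = 128
    channels: Tuple[int, ...] = (32,)      # stride-2 stages before the bottleneck
    embedding_dim: int = 64                # d
    codebook_size: int = 64                # K
    n_res_blocks: int = 2
    dropout_p: float = 0.1
    recon_loss: str = "l1"                 # "l1" | "l2"
    commitment_weight: float = 0.25
    learning_rate: float = 2e-3
    epochs: int = 16
    warmup_frac: float = 0.6               # autoencoder-only epochs before VQ
    batch_size: int = 4
    augment: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0 or not (0 <= self.dropout_p < 1):
            raise ValueError("invalid learning_rate or dropout_p")
        if self.codebook_size < 2:
            raise ValueError("codebook needs at least 2 prototypes")

    @property
    def downsample_factor(self) -> int:
        return 2 ** (len(self.channels) + 1)

    @property
    def latent_size(self) -> int:
        return self.image_size // self.downsample_factor


def clinical_preset() -> VqVaeConfig:
    return VqVaeConfig(image_size=480, channels=(64, 128), embedding_dim=256,
                       codebook_size=128, n_res_blocks=4, learning_rate=1e-4,
                       epochs=200, batch_size=4)


@dataclass
class VqVaeLoss:
    reconstruction: float
    alignment: float
    commitment: float
    total: float


class _ResBlock(nn.Module):
    def __init__(self, ch: int, dropout_p: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(ch, ch, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(ch, ch, 1, rng=rng)
        self.drop = nn.Dropout(dropout_p, rng)

    def forward(self, x):
        h = self.conv1(x.relu())
        h = self.drop(h.relu())
        return x + self.conv2(h)


class VqVae(nn.Module):
    def __init__(self, cfg: VqVaeConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        self.rng = rng
        chs = (1,) + tuple(cfg.channels) + (cfg.embedding_dim,)
        enc: List[nn.Module] = []
        for i, (cin, cout) in enumerate(zip(chs[:-1], chs[1:])):
            enc.append(nn.Conv2d(cin, cout, 4, stride=2, padding=1, rng=rng))
            if i < len(chs) - 2:                     # bottleneck stays linear
                enc += [nn.BatchNorm2d(cout), nn.ReLU()]
        for _ in range(cfg.n_res_blocks):
            enc.append(_ResBlock(cfg.embedding_dim, cfg.dropout_p, rng))
        self.encoder = nn.Sequential(*enc)

        dec: List[nn.Module] = []
        for _ in range(cfg.n_res_blocks):
            dec.append(_ResBlock(cfg.embedding_dim, cfg.dropout_p, rng))
        rchs = (cfg.embedding_dim,) + tuple(reversed(cfg.channels)) + (1,)
        for i, (cin, cout) in enumerate(zip(rchs[:-1], rchs[1:])):
            dec.append(nn.ConvTranspose2d(cin, cout, 4, stride=2, padding=1, rng=rng))
            if i < len(rchs) - 2:                    # image output stays linear
                dec += [nn.BatchNorm2d(cout), nn.ReLU()]
        self.decoder = nn.Sequential(*dec)
        self.codebook = nn.Tensor(
            rng.normal(0.0, 0.1, (cfg.codebook_size, cfg.embedding_dim))
            .astype(np.float32), requires_grad=True)


# ---------------------------------------------------------------------------
# functional surface (NumPy in / NumPy out)
# ---------------------------------------------------------------------------

def encode(image: np.ndarray, model: VqVae) -> np.ndarray:
    """Encode one image to an (h, w, d) feature grid (inference mode)."""
    img = np.asarray(image, dtype=np.float32)
    f = model.cfg.downsample_factor
    if img.ndim != 2 or img.shape[0] % f or img.shape[1] % f:
        raise ValueError(
            f"input size {img.shape} must be 2-D with sides divisible by "
            f"the encoder downsampling factor {f}")
    model.eval()
    with nn.no_grad():
        out = model.encoder(nn.Tensor(img[None, None]))
    return np.ascontiguousarray(out.data[0].transpose(1, 2, 0)).astype(np.float64)


def quantize(features: np.ndarray, codebook: np.ndarray
             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-prototype quantization of an (..., d) feature grid.

    Returns (indices, quantized features, alignment loss map), where the ALM
    holds the squared Euclidean distance of each feature vector to its
    selected code.  Ties go to the lowest index.
    """
    f = np.asarray(features, dtype=np.float64)
    e = np.asarray(codebook, dtype=np.float64)
    if f.shape[-1] != e.shape[-1]:
        raise ValueError(f"feature dim {f.shape[-1]} != codebook dim {e.shape[-1]}")
    d2 = ((f[..., None, :] - e) ** 2).sum(axis=-1)      # (..., K)
    indices = d2.argmin(axis=-1)
    alm = np.take_along_axis(d2, indices[..., None], axis=-1)[..., 0]
    return indices, e[indices], alm


def decode(quantized: np.ndarray, model: VqVae) -> np.ndarray:
    """Decode an (h, w, d) quantized grid back to an image."""
    q = np.asarray(quantized, dtype=np.float32)
    hw = model.cfg.latent_size
    if q.shape != (hw, hw, model.cfg.embedding_dim):
        raise ValueError(f"expected grid {(hw, hw, model.cfg.embedding_dim)}, "
                         f"got {q.shape}")
    model.eval()
    with nn.no_grad():
        out = model.decoder(nn.Tensor(q.transpose(2, 0, 1)[None]))
    return out.data[0, 0].astype(np.float64)


def vqvae_loss(x: np.ndarray, x_prime: np.ndarray, features: np.ndarray,
               quantized: np.ndarray, recon: str = "l1",
               commitment_weight: float = 1.0) -> VqVaeLoss:
    """Loss components on plain arrays (reporting / verification surface).

    reconstruction: mean |x - x'| (or mean squared error for ``recon='l2'``);
    alignment and commitment: mean over grid cells of the squared Euclidean
    distance between encoder vector and selected code — numerically equal,
    they differ only in which side receives gradient during training.
    """
    x, xp = np.asarray(x, dtype=np.float64), np.asarray(x_prime, dtype=np.float64)
    if x.shape != xp.shape:
        raise ValueError("x and x_prime shapes differ")
    f, q = np.asarray(features, dtype=np.float64), np.asarray(quantized, dtype=np.float64)
    if f.shape != q.shape:
        raise ValueError("features and quantized shapes differ")
    if recon == "l1":
        rec = float(np.abs(x - xp).mean())
    else:
        rec = float(((x - xp) ** 2).mean())
    align = float(((f - q) ** 2).sum(axis=-1).mean())
    commit = align
    return VqVaeLoss(rec, align, commit, rec + align + commitment_weight * commit)


def alignment_loss_map(image: np.ndarray, model: VqVae) -> np.ndarray:
    """ALM of one image under a trained model: encode, quantize, keep distances."""
    feats = encode(image, model)
    _, _, alm = quantize(feats, model.codebook.data)
    return alm


def alignment_loss_map_upscaled(alm: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-neighbour upscale of the ALM to image resolution.

    Nearest-neighbour preserves the exact score values (max never grows) and
    trivially preserves ordering under constant maps.
    """
    alm = np.asarray(alm, dtype=np.float64)
    h, w = alm.shape
    if target_size < max(h, w):
        raise ValueError("target_size must be >= latent size")
    rows = (np.arange(target_size) * h) // target_size
    cols = (np.arange(target_size) * w) // target_size
    return alm[np.ix_(rows, cols)]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _augment(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if rng.random() < 0.5:
        img = img[:, ::-1]
    k = int(rng.integers(0, 4))
    if k:
        img = np.rot90(img, k)
    return np.ascontiguousarray(img)


def _load_train_images(manifest: DatasetManifest) -> List[np.ndarray]:
    train = manifest.subset(split="train")
    if not train:
        raise ValueError("train split is empty")
    if any(r.label != "healthy" for r in train):
        raise ValueError("train split contains diseased images; "
                         "the detector is trained on healthy data only")
    return [read_image(manifest.resolve(r.image)) for r in train]


def _nearest_code(features: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Fast argmin over codes via the expanded-norm distance (training path)."""
    f = features.reshape(-1, features.shape[-1])
    d2 = (f * f).sum(1, keepdims=True) - 2.0 * (f @ codebook.T) \
        + (codebook * codebook).sum(1)
    return d2.argmin(1).reshape(features.shape[:-1])


def train_step(model: VqVae, batch: np.ndarray, opt: nn.Adam) -> VqVaeLoss:
    """One optimization step on an (N, H, W) float batch."""
    cfg = model.cfg
    x = nn.Tensor(np.asarray(batch, dtype=np.float32)[:, None])
    f = model.encoder(x)                               # (N, d, h, w)
    f_perm = f.transpose(0, 2, 3, 1)                   # (N, h, w, d)
    idx = _nearest_code(f_perm.data, model.codebook.data)
    e_sel = nn.gather_rows(model.codebook, idx)        # grads -> codebook

    # element-mean scaling keeps the VQ terms commensurate with the
    # reconstruction term regardless of the embedding dimension
    align = ((e_sel - nn.Tensor(f_perm.data)) ** 2.0).mean()
    commit = ((nn.Tensor(e_sel.data) - f_perm) ** 2.0).mean()
    # straight-through: value of the codes, gradient of the encoder features
    q_st = f_perm + nn.Tensor(e_sel.data - f_perm.data)
    xp = model.decoder(q_st.transpose(0, 3, 1, 2))
    if cfg.recon_loss == "l1":
        rec = (xp - x).abs().mean()
    else:
        rec = ((xp - x) ** 2.0).mean()
    loss = rec + align + cfg.commitment_weight * commit
    opt.zero_grad()
    loss.backward()
    opt.step()
    return VqVaeLoss(rec.item(), align.item(), commit.item(), loss.item())


def _kmeans_codebook(model: VqVae, images: Sequence[np.ndarray],
                     rng: np.random.Generator) -> None:
    """Initialize the codebook as k-means centroids of encoder features.

    Placing every prototype at the centre of a populated feature cluster
    makes the whole codebook active from the first quantized step, which is
    what lets the short desk-scale fine-tuning phase succeed where training
    the codes from random initialization collapses onto a single code.
    """
    from sklearn.cluster import KMeans

    model.eval()
    feats = []
    for img in images:
        with nn.no_grad():
            out = model.encoder(nn.Tensor(np.asarray(img, np.float32)[None, None]))
        feats.append(out.data[0].transpose(1, 2, 0).reshape(-1, model.cfg.embedding_dim))
    feats = np.concatenate(feats)
    if len(feats) > 20000:
        feats = feats[rng.choice(len(feats), 20000, replace=False)]
    km = KMeans(n_clusters=model.cfg.codebook_size, n_init=4,
                random_state=int(rng.integers(2 ** 31)))
    km.fit(feats.astype(np.float64))
    model.codebook.data = km.cluster_centers_.astype(np.float32)
    model.train()


def train_vqvae(manifest: DatasetManifest, cfg: Optional[VqVaeConfig] = None
                ) -> VqVae:
    """Train on the healthy train split of a manifest; returns the model.

    Refuses manifests whose train split contains diseased records.  The
    per-epoch loss log is attached as ``model.train_log``.
    """
    cfg = cfg or VqVaeConfig()
    cfg.validate()
    images = _load_train_images(manifest)
    model = VqVae(cfg)
    model.train()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    log: List[dict] = []
    n = len(images)
    n_warmup = int(round(cfg.epochs * cfg.warmup_frac))
    for epoch in range(cfg.epochs):
        if epoch == n_warmup:
            _kmeans_codebook(model, images, rng)
        quantized_phase = epoch >= n_warmup
        order = rng.permutation(n)
        totals = np.zeros(4)
        nb = 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            batch = np.stack([
                _augment(images[i], rng) if cfg.augment else images[i]
                for i in sel])
            if quantized_phase:
                res = train_step(model, batch, opt)
            else:
                res = _warmup_step(model, batch, opt)
            totals += [res.reconstruction, res.alignment, res.commitment, res.total]
            nb += 1
        log.append({"epoch": epoch, "phase": "vq" if quantized_phase else "warmup",
                    "reconstruction": totals[0] / nb,
                    "alignment": totals[1] / nb, "commitment": totals[2] / nb,
                    "total": totals[3] / nb})
    if cfg.epochs <= n_warmup:          # degenerate schedule: still init codes
        _kmeans_codebook(model, images, rng)
    model.eval()
    model.train_log = log
    return model


def _warmup_step(model: VqVae, batch: np.ndarray, opt: nn.Adam) -> VqVaeLoss:
    """Autoencoder-only step: the decoder sees unquantized features.

    Used for the warm-up phase; the quantizer enters once the feature space
    is informative enough for k-means codebook placement.
    """
    x = nn.Tensor(np.asarray(batch, dtype=np.float32)[:, None])
    xp = model.decoder(model.encoder(x))
    if model.cfg.recon_loss == "l1":
        rec = (xp - x).abs().mean()
    else:
        rec = ((xp - x) ** 2.0).mean()
    opt.zero_grad()
    rec.backward()
    opt.step()
    return VqVaeLoss(rec.item(), 0.0, 0.0, rec.item())


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_vqvae(model: VqVae, path) -> None:
    state = model.state_dict()
    state["__config__"] = json.dumps(dataclasses.asdict(model.cfg))
    np.savez(Path(path), **state)


def load_vqvae(path) -> VqVae:
    data = np.load(Path(path), allow_pickle=False)
    raw = json.loads(str(data["__config__"]))
    raw["channels"] = tuple(raw["channels"])
    model = VqVae(VqVaeConfig(**raw))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model
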