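"""Synthetic OCTA-like vessel phantoms with ground-truth masks.

Healthy en face angiography projections show bright curvilinear vessels on a
dark background, with a darker foveal avascular zone (FAZ) at the centre.
The generator emulates this with a bounded-curvature random walk per vessel,
stochastic branching, and a Gaussian cross-sectional intensity profile —
deliberately ridge-like so that Hessian-based vesselness responds to it.

Three anomaly classes can be injected, mirroring the lesion types seen in
diabetic retinopathy angiography:

* ``dropout``    — capillary non-perfusion: vessel signal inside a disk is
                   attenuated toward the local background level;
* ``tuft``       — neovascular tuft: a dense bright tangle of fine vessels
                   is added inside the disk;
* ``tortuosity`` — abnormal vessel course: a smooth sinusoidal displacement
                   field warps the image inside the disk.

Everything is a pure function of its config + seed, and anomaly injection
never touches pixels outside the declared region (exact equality).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import ConfigurationError
from .imgio import read_mask, write_image, write_mask

ANOMALY_KINDS = ("dropout", "tortuosity", "tuft")

# healthy split fractions (train/val/test); diseased go half to val, half to test
HEALTHY_SPLIT = (0.8, 0.1, 0.1)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the healthy vessel phantom.

    ``image_size`` 128 is the desk-scale default; 480 reproduces the
    working resolution of clinical en face projections after cropping.
    """

    image_size: int = 128
    n_seed_vessels: int = 10
    branch_probability: float = 0.05
    vessel_width_range: Tuple[float, float] = (1.8, 3.2)
    background_noise_sigma: float = 0.03
    fov_margin: int = 4
    include_faz: bool = True
    faz_radius_frac: float = 0.09
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        if not (0.0 <= self.branch_probability <= 1.0):
            raise ConfigurationError("branch_probability must be in [0, 1]")
        lo, hi = self.vessel_width_range
        if not (0 < lo <= hi):
            raise ConfigurationError("vessel_width_range must be positive and ordered")
        if self.image_size - 2 * self.fov_margin < 8:
            raise ConfigurationError(
                f"fov_margin {self.fov_margin} leaves no room in a "
                f"{self.image_size}px image")
        if self.background_noise_sigma < 0:
            raise ConfigurationError("background_noise_sigma must be >= 0")


@dataclass(frozen=True)
class AnomalySpec:
    """One injected lesion: a disk of given centre/radius, kind and severity."""

    kind: str
    center: Tuple[int, int]          # (row, col)
    radius: float
    severity: float
    rng_seed: int = 0

    def validate(self, image_size: int) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}; "
                             f"expected one of {ANOMALY_KINDS}")
        r, c = self.center
        if not (self.radius <= r <= image_size - 1 - self.radius and
                self.radius <= c <= image_size - 1 - self.radius):
            raise ValueError("anomaly region extends outside the image")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")


@dataclass
class ManifestRecord:
    image: str
    vessel_mask: str
    anomaly_mask: str        # empty string for healthy images
    label: str               # "healthy" | "diseased"
    split: str               # "train" | "val" | "test"


@dataclass
class DatasetManifest:
    records: List[ManifestRecord]
    root: Path

    def subset(self, split: Optional[str] = None,
               label: Optional[str] = None) -> List[ManifestRecord]:
        return [r for r in self.records
                if (split is None or r.split == split)
                and (label is None or r.label == label)]

    def resolve(self, rel: str) -> Path:
        return self.root / rel

    def to_csv(self, path) -> None:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        df.to_csv(path, index=False,
                  columns=["image", "vessel_mask", "anomaly_mask", "label", "split"])

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, keep_default_na=False)
        records = [ManifestRecord(str(r.image), str(r.vessel_mask),
                                  str(r.anomaly_mask), str(r.label), str(r.split))
                   for r in df.itertuples()]
        return cls(records=records, root=path.parent)

    def validate(self) -> None:
        for r in self.records:
            if r.label not in ("healthy", "diseased"):
                raise ValueError(f"bad label {r.label!r}")
            if r.split not in ("train", "val", "test"):
                raise ValueError(f"bad split {r.split!r}")
            if r.label == "diseased":
                if r.split == "train":
                    raise ValueError("diseased image in the train split")
                if not r.anomaly_mask:
                    raise ValueError("diseased record lacks an anomaly mask")
                m = read_mask(self.resolve(r.anomaly_mask))
                if not m.any():
                    raise ValueError(f"empty anomaly mask: {r.anomaly_mask}")


# ---------------------------------------------------------------------------
# healthy phantom
# ---------------------------------------------------------------------------

def _stamp(profile: np.ndarray, r: float, c: float, sigma: float) -> None:
    """Max-combine a Gaussian cross-section stamp centred at (r, c)."""
    size = profile.shape[0]
    rad = int(np.ceil(3.0 * sigma))
    r0, r1 = max(0, int(r) - rad), min(size, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(size, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - r
    cc = np.arange(c0, c1)[None, :] - c
    g = np.exp(-(rr * rr + cc * cc) / (2.0 * sigma * sigma))
    np.maximum(profile[r0:r1, c0:c1], g, out=profile[r0:r1, c0:c1])


def generate_vessel_tree(config: PhantomConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Grow a branching vessel phantom; return (image in [0,1], vessel mask).

    The vessel mask is the set of pixels whose rendered profile exceeds half
    the peak profile value (profiles peak at 1, so the cut is at 0.5).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    size = config.image_size
    margin = config.fov_margin
    lo_w, hi_w = config.vessel_width_range
    profile = np.zeros((size, size), dtype=np.float64)
    center = (size - 1) / 2.0
    faz_r = config.faz_radius_frac * size

    # Vessels radiate from a ring around the foveal avascular zone toward
    # the field-of-view border, mimicking the stereotyped macular geometry
    # of en face projections; curvature noise is bounded and a weak radial
    # restoring term keeps the course roughly centrifugal.
    max_steps = int(2.0 * size)
    queue = []
    for i in range(config.n_seed_vessels):
        ang = 2 * np.pi * (i + rng.uniform(-0.3, 0.3)) / max(config.n_seed_vessels, 1)
        r = center + 1.3 * faz_r * np.sin(ang)
        c = center + 1.3 * faz_r * np.cos(ang)
        heading = ang + rng.uniform(-0.5, 0.5)
        width = rng.uniform(lo_w, hi_w)
        queue.append((r, c, heading, width, max_steps, 0))

    # branching is quasi-regular: events occur at jittered intervals whose
    # rate equals branch_probability, which keeps the per-image vessel
    # density much more repeatable than memoryless branching would
    mean_gap = 1.0 / max(config.branch_probability, 1e-9)

    while queue:
        r, c, heading, width, steps, depth = queue.pop()
        sigma = width / 2.355                      # FWHM -> Gaussian sigma
        next_branch = mean_gap * rng.uniform(0.7, 1.3)
        travelled = 0.0
        while steps > 0:
            _stamp(profile, r, c, sigma)
            radial = np.arctan2(r - center, c - center)
            pull = np.arctan2(np.sin(radial - heading), np.cos(radial - heading))
            heading += 0.08 * pull + float(np.clip(rng.normal(0.0, 0.10),
                                                   -0.25, 0.25))
            r += np.sin(heading)
            c += np.cos(heading)
            steps -= 1
            travelled += 1.0
            if not (margin <= r < size - margin and margin <= c < size - margin):
                break
            if (depth < 3 and width > 1.0 and config.branch_probability > 0
                    and travelled >= next_branch):
                travelled = 0.0
                next_branch = mean_gap * rng.uniform(0.7, 1.3)
                turn = rng.uniform(np.pi / 6, np.pi * 7 / 18) * rng.choice([-1.0, 1.0])
                queue.append((r, c, heading + turn, width * 0.75,
                              steps // 2, depth + 1))

    if config.include_faz:
        center = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.hypot(yy - center, xx - center) / (config.faz_radius_frac * size)
        profile = profile * (1.0 - 0.85 * np.exp(-rr ** 4))

    mask = profile > 0.5
    noise = rng.normal(0.0, config.background_noise_sigma, (size, size))
    image = np.clip(0.10 + 0.80 * profile + noise, 0.0, 1.0)
    return image, mask


# ---------------------------------------------------------------------------
# anomaly injection
# ---------------------------------------------------------------------------

def _disk(size: int, center: Tuple[int, int], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def inject_anomaly(image: np.ndarray, vessel_mask: np.ndarray,
                   spec: AnomalySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Inject one lesion; return (modified image, anomaly mask).

    Pixels outside the disk are bit-identical to the input.  ``severity=0``
    leaves the image unchanged (the mask still marks the region).
    """
    size = image.shape[0]
    spec.validate(size)
    region = _disk(size, spec.center, spec.radius)
    rng = np.random.default_rng(spec.rng_seed)
    out = image.copy()
    sev = float(spec.severity)

    if spec.kind == "dropout":
        if sev > 0:
            bg = float(np.percentile(image[region], 20))
            out[region] = image[region] * (1.0 - sev) + bg * sev
    elif spec.kind == "tuft":
        tangle = np.zeros_like(image)
        n_twigs = max(6, int(spec.radius * 1.5))
        for _ in range(n_twigs):
            rr = spec.center[0] + rng.uniform(-0.6, 0.6) * spec.radius
            cc = spec.center[1] + rng.uniform(-0.6, 0.6) * spec.radius
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(int(spec.radius * 1.2)):
                _stamp(tangle, rr, cc, 0.55)
                heading += rng.normal(0.0, 0.9)
                rr += 0.8 * np.sin(heading)
                cc += 0.8 * np.cos(heading)
        gain = 0.25 + 0.55 * sev
        out[region] = np.clip(image[region] + gain * tangle[region], 0.0, 1.0)
    elif spec.kind == "tortuosity":
        yy, xx = np.mgrid[0:size, 0:size]
        rr = np.hypot(yy - spec.center[0], xx - spec.center[1]) / spec.radius
        win = np.where(rr < 1.0, np.cos(np.pi / 2 * np.clip(rr, 0, 1)) ** 2, 0.0)
        amp = sev * spec.radius * 0.25
        lam = spec.radius / 1.5
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        dr = amp * win * np.sin(2 * np.pi * (xx - spec.center[1]) / lam + ph1)
        dc = amp * win * np.sin(2 * np.pi * (yy - spec.center[0]) / lam + ph2)
        warped = map_coordinates(image, [yy + dr, xx + dc], order=1, mode="reflect")
        out[region] = warped[region]
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(spec.kind)

    return out, region


def random_anomaly_specs(rng: np.random.Generator, image_size: int,
                         vessel_mask: Optional[np.ndarray] = None,
                         n_min: int = 2, n_max: int = 3) -> List[AnomalySpec]:
    """Draw a few lesions with detectability-calibrated default ranges.

    Perfusion-altering lesions (dropout, tortuosity) are placed over
    vascularized tissue — erasing or warping empty background is not a
    perfusion anomaly.  Dropout severity defaults to subtotal attenuation,
    which leaves a residual dimmed flow signal as real non-perfusion does.
    """
    specs = []
    for _ in range(int(rng.integers(n_min, n_max + 1))):
        kind = str(rng.choice(ANOMALY_KINDS))
        radius = rng.uniform(0.10, 0.20) * image_size
        lo = int(np.ceil(radius)) + 1
        hi = image_size - 2 - int(np.ceil(radius))
        center = (int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))
        if vessel_mask is not None and kind != "tuft":
            best_cov = -1.0
            for _ in range(60):
                cand = (int(rng.integers(lo, hi)), int(rng.integers(lo, hi)))
                cov = vessel_mask[_disk(image_size, cand, radius)].mean()
                if cov > best_cov:
                    best_cov, center = cov, cand
                if cov >= 0.25:
                    break
        severity = (rng.uniform(0.3, 0.55) if kind == "dropout"
                    else rng.uniform(0.5, 0.9))
        specs.append(AnomalySpec(kind=kind, center=center, radius=float(radius),
                                 severity=float(severity),
                                 rng_seed=int(rng.integers(2 ** 31))))
    return specs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _healthy_split_sizes(n: int) -> Tuple[int, int, int]:
    n_val = int(round(HEALTHY_SPLIT[1] * n))
    n_test = int(round(HEALTHY_SPLIT[2] * n))
    return n - n_val - n_test, n_val, n_test


def make_dataset(n_healthy: int, n_diseased: int, config: PhantomConfig,
                 out_dir) -> DatasetManifest:
    """Generate a full phantom dataset on disk and return its manifest.

    Healthy images split 80/10/10 into train/val/test; diseased images are
    divided equally between val and test (none in train — the detectors are
    trained on healthy data only).
    """
    if n_healthy < 10:
        raise ValueError(f"need at least 10 healthy images, got {n_healthy}")
    config.validate()
    out_dir = Path(out_dir)
    for sub in ("images", "vessel_masks", "anomaly_masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(config.rng_seed)
    records: List[ManifestRecord] = []

    n_train, n_val, n_test = _healthy_split_sizes(n_healthy)
    healthy_splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    for i in range(n_healthy):
        seed = int(master.integers(2 ** 31))
        img, vmask = generate_vessel_tree(dataclasses.replace(config, rng_seed=seed))
        stem = f"healthy_{i:04d}"
        write_image(out_dir / "images" / f"{stem}.png", img)
        write_mask(out_dir / "vessel_masks" / f"{stem}.png", vmask)
        records.append(ManifestRecord(
            image=f"images/{stem}.png", vessel_mask=f"vessel_masks/{stem}.png",
            anomaly_mask="", label="healthy", split=healthy_splits[i]))

    n_val_d = n_diseased // 2
    for i in range(n_diseased):
        seed = int(master.integers(2 ** 31))
        img, vmask = generate_vessel_tree(dataclasses.replace(config, rng_seed=seed))
        amask = np.zeros(img.shape, dtype=bool)
        for aspec in random_anomaly_specs(master, config.image_size, vmask):
            img, m = inject_anomaly(img, vmask, aspec)
            amask |= m
        stem = f"diseased_{i:04d}"
        write_image(out_dir / "images" / f"{stem}.png", img)
        write_mask(out_dir / "vessel_masks" / f"{stem}.png", vmask)
        write_mask(out_dir / "anomaly_masks" / f"{stem}.png", amask)
        records.append(ManifestRecord(
            image=f"images/{stem}.png", vessel_mask=f"vessel_masks/{stem}.png",
            anomaly_mask=f"anomaly_masks/{stem}.png", label="diseased",
            split="val" if i < n_val_d else "test"))

    manifest = DatasetManifest(records=records, root=out_dir)
    manifest.to_csv(out_dir / "MANIFEST.csv")
    return manifest
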