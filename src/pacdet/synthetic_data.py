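"""Synthetic CT-like volumes with blob lesions and exact box annotations.

The generator emulates the structure the detector consumes: stacks of
grayscale axial slices in which soft-edged ellipsoidal lesions sit on a
smooth low-frequency background with additive Gaussian noise.  Difficulty
tiers control lesion size and contrast — "hard" means small and
low-contrast, mimicking lesion types whose contrast against surrounding
tissue is poor.  Each lesion's ground-truth box on every slice it intersects
is the tight bounding box of its rendered support, computed by pixel scan at
render time, so annotations are exact by construction.

Volumes are fully reproducible from (seed, parameters).  Datasets are
written as per-slice 16-bit PNGs with a CSV annotation table and a
COCO-style JSON mirror.

The module also generates the box-pair scenario families used to probe the
degeneracies of the IoU-family losses: proposals strictly inside one ground
truth (same IoU and GIoU everywhere), concentric equal-area proposals of
varying aspect (same IoU and DIoU), and a fixed-aspect fixed-center-distance
sweep (same IoU/GIoU/DIoU/CIoU; only the vertex-distance penalty varies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .box_losses import Box

__all__ = [
    "LesionSpec", "SyntheticVolume", "TIER_PARAMS", "GENERATOR_VERSION",
    "generate_volume", "write_dataset", "read_dataset", "make_sample_groups",
    "scenario_boxes", "build_detection_dataset", "detection_samples",
]

GENERATOR_VERSION = "1.0"

# tier -> (contrast range, in-plane radius range [px], noise sigma)
TIER_PARAMS = {
    "easy": {"contrast": (0.30, 0.50), "radius": (6.0, 12.0), "noise": 0.02},
    "medium": {"contrast": (0.15, 0.30), "radius": (4.0, 9.0), "noise": 0.04},
    "hard": {"contrast": (0.05, 0.15), "radius": (3.0, 6.0), "noise": 0.06},
}


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal blob lesion inside a volume."""

    center: tuple[float, float, float]   # (x, y, z); z in slice index units
    radii: tuple[float, float]           # in-plane (rx, ry) in pixels
    extent: float                        # through-plane half-extent in slices
    contrast: float                      # intensity delta, fraction of range
    tier: str = "easy"


@dataclass
class SyntheticVolume:
    """Rendered slice stack plus its exact per-slice annotations."""

    volume: np.ndarray                   # (Z, H, W) intensities in [0, 1]
    lesions: list[LesionSpec]
    annotations: pd.DataFrame            # slice_idx, x1, y1, x2, y2, lesion_id, tier
    seed: int
    tier: str
    volume_id: str = "vol000"

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volume.shape


def _render_lesion(volume: np.ndarray, spec: LesionSpec) -> list[tuple[int, Box]]:
    """Add one soft-edged ellipsoid; return (slice, support bounding box) pairs."""
    z_dim, h, w = volume.shape
    cx, cy, cz = spec.center
    rx, ry = spec.radii
    boxes = []
    yy, xx = np.mgrid[0:h, 0:w]
    for z in range(max(0, int(np.floor(cz - spec.extent))),
                   min(z_dim, int(np.ceil(cz + spec.extent)) + 1)):
        dz = (z - cz) / spec.extent
        if abs(dz) >= 1.0:
            continue
        shrink = np.sqrt(1.0 - dz * dz)
        rxz, ryz = rx * shrink, ry * shrink
        rho2 = ((xx + 0.5 - cx) / rxz) ** 2 + ((yy + 0.5 - cy) / ryz) ** 2
        profile = np.clip(1.0 - rho2, 0.0, None) ** 0.7  # soft edge
        mask = profile > 0
        if not mask.any():
            continue
        volume[z] += spec.contrast * profile
        rows, cols = np.nonzero(mask)
        # continuous corners enclosing the support pixels
        boxes.append((z, Box(float(cols.min()), float(rows.min()),
                             float(cols.max() + 1), float(rows.max() + 1))))
    return boxes


def generate_volume(seed: int, n_lesions: int, tier: str = "easy",
                    size=(64, 64, 12), volume_id: str = "vol000") -> SyntheticVolume:
    """Render a reproducible synthetic volume with ``n_lesions`` blobs.

    ``size`` is ``(H, W, Z)`` (or an int for a square H=W with Z=12); H and W
    must be divisible by 64 to satisfy the backbone's stride contract.
    """
    if tier not in TIER_PARAMS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {list(TIER_PARAMS)}")
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    if np.isscalar(size):
        size = (int(size), int(size), 12)
    h, w, z_dim = size
    if h % 64 or w % 64:
        raise ValueError(f"in-plane size {h}x{w} must be divisible by 64")
    params = TIER_PARAMS[tier]
    rng = np.random.default_rng(seed)
    # smooth anatomy-like background + per-tier Gaussian noise
    background = gaussian_filter(rng.normal(size=(z_dim, h, w)), sigma=(1.5, 8.0, 8.0))
    background = 0.40 + 0.12 * background / max(background.std(), 1e-9)
    volume = background + rng.normal(0.0, params["noise"], size=(z_dim, h, w))
    specs: list[LesionSpec] = []
    rows = []
    for lesion_id in range(n_lesions):
        for attempt in range(200):
            rx = rng.uniform(*params["radius"])
            ry = rng.uniform(*params["radius"])
            extent = rng.uniform(2.0, 4.0)
            margin_x, margin_y = rx + 1.0, ry + 1.0
            if 2 * margin_x >= w or 2 * margin_y >= h or 2 * extent >= z_dim:
                continue
            cx = rng.uniform(margin_x, w - margin_x)
            cy = rng.uniform(margin_y, h - margin_y)
            cz = rng.uniform(extent, z_dim - extent)
            # avoid near-duplicate placements so boxes stay well-defined
            if any(abs(cx - s.center[0]) < (rx + s.radii[0]) * 0.5
                   and abs(cy - s.center[1]) < (ry + s.radii[1]) * 0.5
                   and abs(cz - s.center[2]) < 2.0 for s in specs):
                continue
            spec = LesionSpec(center=(cx, cy, cz), radii=(rx, ry), extent=extent,
                              contrast=rng.uniform(*params["contrast"]), tier=tier)
            break
        else:
            raise ValueError(
                f"could not place lesion {lesion_id} in volume of size {size}")
        specs.append(spec)
        for z, box in _render_lesion(volume, spec):
            rows.append({"slice_idx": z, "x1": box.x1, "y1": box.y1,
                         "x2": box.x2, "y2": box.y2,
                         "lesion_id": lesion_id, "tier": tier})
    np.clip(volume, 0.0, 1.0, out=volume)
    ann = pd.DataFrame(rows, columns=["slice_idx", "x1", "y1", "x2", "y2",
                                      "lesion_id", "tier"])
    return SyntheticVolume(volume=volume, lesions=specs, annotations=ann,
                           seed=seed, tier=tier, volume_id=volume_id)


# -- I/O ---------------------------------------------------------------------

def write_dataset(volumes: list[SyntheticVolume], out_dir) -> Path:
    """Write slices as 16-bit PNGs plus CSV and COCO-style JSON annotations."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out_dir}: {exc}") from exc
    ann_frames = []
    images, coco_anns = [], []
    ann_id = 1
    for vol in volumes:
        vdir = out_dir / vol.volume_id
        vdir.mkdir(exist_ok=True)
        z_dim, h, w = vol.shape
        for z in range(z_dim):
            arr16 = np.round(vol.volume[z] * 65535.0).astype(np.uint16)
            path = vdir / f"slice_{z:03d}.png"
            try:
                Image.fromarray(arr16).save(path)  # uint16 -> 16-bit grayscale PNG
            except OSError as exc:
                raise OSError(f"failed writing {path}: {exc}") from exc
            images.append({"id": f"{vol.volume_id}/{z:03d}",
                           "file_name": str(path.relative_to(out_dir)),
                           "width": w, "height": h})
        df = vol.annotations.copy()
        df.insert(0, "volume_id", vol.volume_id)
        ann_frames.append(df)
        for _, r in vol.annotations.iterrows():
            coco_anns.append({
                "id": ann_id,
                "image_id": f"{vol.volume_id}/{int(r.slice_idx):03d}",
                "bbox": [r.x1, r.y1, r.x2 - r.x1, r.y2 - r.y1],
                "area": (r.x2 - r.x1) * (r.y2 - r.y1),
                "category_id": 1, "iscrowd": 0, "tier": r.tier,
            })
            ann_id += 1
    all_ann = (pd.concat(ann_frames, ignore_index=True) if ann_frames
               else pd.DataFrame(columns=["volume_id", "slice_idx", "x1", "y1",
                                          "x2", "y2", "lesion_id", "tier"]))
    all_ann.to_csv(out_dir / "annotations.csv", index=False)
    manifest = {"generator_version": GENERATOR_VERSION,
                "seeds": [v.seed for v in volumes],
                "tiers": [v.tier for v in volumes]}
    coco = {"images": images, "annotations": coco_anns,
            "categories": [{"id": 1, "name": "lesion"}], "info": manifest}
    (out_dir / "annotations.json").write_text(json.dumps(coco))
    return out_dir


def read_dataset(data_dir):
    """Read a written dataset back: (volumes as (Z,H,W) arrays in [0,1] keyed
    by volume id, annotation DataFrame)."""
    data_dir = Path(data_dir)
    ann = pd.read_csv(data_dir / "annotations.csv")
    volumes: dict[str, np.ndarray] = {}
    for vdir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        slices = []
        for png in sorted(vdir.glob("slice_*.png")):
            arr = np.asarray(Image.open(png), dtype=np.float64) / 65535.0
            slices.append(arr)
        if slices:
            volumes[vdir.name] = np.stack(slices)
    return volumes, ann


# -- sample grouping ---------------------------------------------------------

def make_sample_groups(volume, key_slice: int) -> np.ndarray:
    """Group the 9 consecutive slices centered on ``key_slice`` into three
    3-channel images, shape (3, 3, H, W); edge slices are replicated."""
    arr = volume.volume if isinstance(volume, SyntheticVolume) else np.asarray(volume)
    z_dim = arr.shape[0]
    idx = np.clip(np.arange(key_slice - 4, key_slice + 5), 0, z_dim - 1)
    return arr[idx].reshape(3, 3, *arr.shape[1:]).astype(np.float32)


def detection_samples(vol: SyntheticVolume, key_slices_only: bool = True) -> list[dict]:
    """Detector samples for a volume: 9-slice groups plus key-slice boxes.

    With ``key_slices_only`` (default) one sample is made per lesion key
    slice — the slice through the lesion center, mirroring datasets that
    annotate one key slice per lesion and provide neighbors as 3D context.
    Otherwise every annotated slice yields a sample.
    """
    if key_slices_only:
        key_slices = sorted({int(round(s.center[2])) for s in vol.lesions})
    else:
        key_slices = sorted(vol.annotations.slice_idx.unique())
    samples = []
    for z in key_slices:
        grp = vol.annotations[vol.annotations.slice_idx == z]
        if grp.empty:
            continue
        boxes = grp[["x1", "y1", "x2", "y2"]].to_numpy(dtype=np.float64)
        samples.append({"group": make_sample_groups(vol, int(z)),
                        "boxes": boxes,
                        "image_id": f"{vol.volume_id}/{int(z):03d}",
                        "tiers": grp["tier"].tolist()})
    return samples


def build_detection_dataset(n_volumes: int = 200, size=(64, 64, 12),
                            tier_mix: dict[str, float] | None = None,
                            mean_lesions: float = 1.2, seed: int = 7,
                            val_fraction: float = 0.2) -> dict:
    """Generate the desk-scale detection dataset.

    Tier counts follow ``tier_mix`` exactly (largest-remainder rounding);
    lesion counts per volume are Poisson with the configured mean, clamped to
    at least 1 so every volume contributes annotated slices.  Volumes are
    split into train/val by volume (not slice) to keep the evaluation
    honest.  Returns ``{"train": [...], "val": [...], "volumes": [...],
    "manifest": {...}}``.
    """
    tier_mix = tier_mix or {"easy": 1.0}
    total = sum(tier_mix.values())
    fracs = {t: v / total for t, v in tier_mix.items()}
    counts = {t: int(np.floor(f * n_volumes)) for t, f in fracs.items()}
    remainders = sorted(((fracs[t] * n_volumes - counts[t], t) for t in fracs),
                        reverse=True)
    for _, t in remainders[: n_volumes - sum(counts.values())]:
        counts[t] += 1
    rng = np.random.default_rng(seed)
    tiers = [t for t, c in counts.items() for _ in range(c)]
    rng.shuffle(tiers)
    volumes = []
    for i, tier in enumerate(tiers):
        n_lesions = max(1, int(rng.poisson(mean_lesions)))
        volumes.append(generate_volume(int(rng.integers(2 ** 31)), n_lesions,
                                       tier, size, volume_id=f"vol{i:03d}"))
    n_val = int(round(val_fraction * len(volumes)))
    val_vols = volumes[:n_val]
    train_vols = volumes[n_val:]
    train = [s for v in train_vols for s in detection_samples(v)]
    val = [s for v in val_vols for s in detection_samples(v)]
    manifest = {"generator_version": GENERATOR_VERSION, "seed": seed,
                "tier_counts": counts, "n_volumes": n_volumes,
                "n_train_samples": len(train), "n_val_samples": len(val)}
    return {"train": train, "val": val, "volumes": volumes, "manifest": manifest}


# -- degenerate-loss scenario families ---------------------------------------

def scenario_boxes(name: str, n: int = 8, seed: int = 0) -> list[tuple[Box, Box]]:
    """Box-pair families probing IoU-family degeneracies.

    * ``inclusion``: equal-area proposals strictly inside one GT at varying
      positions — IoU and GIoU identical across the family.
    * ``concentric``: equal-area, shared-center proposals of varying aspect
      inside the GT — IoU and DIoU identical, VDIoU separates them.
    * ``corner-sweep``: same-aspect proposals at a fixed center distance from
      the GT center — IoU, GIoU, DIoU and CIoU all constant, VDIoU varies.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[Box, Box]] = []
    if name == "inclusion":
        gt = Box(0.0, 0.0, 20.0, 20.0)
        for _ in range(n):
            x = rng.uniform(0.5, 11.5)
            y = rng.uniform(0.5, 11.5)
            pairs.append((gt, Box(x, y, x + 8.0, y + 8.0)))
    elif name == "concentric":
        gt = Box(0.0, 0.0, 10.0, 10.0)
        # widths >= heights throughout: mirrored aspects (w/h vs h/w) would
        # share a vertex-distance penalty by symmetry
        widths = np.linspace(6.0, 9.0, n)
        for w in widths:
            h = 36.0 / w  # equal area, inside the GT
            pairs.append((gt, Box(5.0 - w / 2, 5.0 - h / 2, 5.0 + w / 2, 5.0 + h / 2)))
    elif name == "corner-sweep":
        gt = Box(0.0, 0.0, 20.0, 20.0)
        angles = rng.uniform(0.0, 2 * np.pi, size=n)
        for th in angles:
            cx = 10.0 + 3.0 * np.cos(th)
            cy = 10.0 + 3.0 * np.sin(th)
            pairs.append((gt, Box(cx - 5.0, cy - 5.0, cx + 5.0, cy + 5.0)))
    else:
        raise ValueError(f"unknown scenario {name!r}; expected inclusion, "
                         f"concentric or corner-sweep")
    return pairs
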