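"""Seeded synthetic finger-vein image federations.

Real finger-vein datasets are near-infrared images of a finger: bright
tissue crossed by darker subcutaneous veins.  This module emulates that
appearance well enough to exercise every downstream stage — gradient
enhancement, embedding training, open-set verification — without any
download.  A federation is a set of clients whose datasets deliberately
differ in class count, samples per class, finger orientation, contrast,
illumination and noise, reproducing the non-IID heterogeneity of
multi-organization biometric collaborations.

The whole federation is a pure function of its spec: identical spec and
master seed give bit-identical pixels.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ClientSpec",
    "SyntheticFederationSpec",
    "VeinImage",
    "ClientDataset",
    "VeinTemplate",
    "Jitter",
    "generate_identity_pattern",
    "render_sample",
    "generate_federation",
    "apply_contrast",
    "write_dataset",
    "read_dataset",
]

_ORIENTATIONS = ("vertical", "horizontal")


@dataclass(frozen=True)
class ClientSpec:
    """Dataset shape and imaging conditions for one client.

    ``contrast_level`` rescales intensities about mid-gray 127.5 so that
    1.0 is the identity; ``noise_sd`` is additive Gaussian sensor noise in
    intensity units; ``illumination_offset`` shifts the global brightness.
    """

    n_classes: int
    samples_per_class: int
    image_height: int = 64
    image_width: int = 128
    orientation: str = "horizontal"
    contrast_level: float = 1.0
    noise_sd: float = 4.0
    illumination_offset: float = 0.0
    n_veins: int = 5

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("each client needs at least 2 classes")
        if self.samples_per_class < 2:
            raise ValueError(
                "samples_per_class must be >= 2 (open-set pairing needs "
                ">= 2 genuine samples)"
            )
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
        if not 0.0 < self.contrast_level <= 1.0:
            raise ValueError("contrast_level must lie in (0, 1]")
        if min(self.image_height, self.image_width) < 16:
            raise ValueError("images below 16x16 cannot resolve vein curves")


@dataclass(frozen=True)
class SyntheticFederationSpec:
    """Full description of a heterogeneous multi-client federation.

    ``shared_class_fraction`` > 0 makes that fraction of each client's
    classes (after the first client) reuse the previous client's
    identities, exercising the multi-owner prototype aggregation branch;
    the default 0 keeps labels disjoint across clients, matching the
    distinct-organization setting.
    """

    clients: tuple[ClientSpec, ...]
    master_seed: int = 0
    shared_class_fraction: float = 0.0

    def __post_init__(self) -> None:
        if len(self.clients) < 1:
            raise ValueError("a federation needs at least one client")
        if not 0.0 <= self.shared_class_fraction < 1.0:
            raise ValueError("shared_class_fraction must lie in [0, 1)")


@dataclass
class VeinImage:
    """One grayscale sample with its federation bookkeeping tags."""

    pixels: np.ndarray  # uint8, (H, W)
    client_id: int
    class_label: int
    orientation: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")


@dataclass
class ClientDataset:
    client_id: int
    spec: ClientSpec
    images: list[VeinImage]

    @property
    def labels(self) -> np.ndarray:
        return np.array([im.class_label for im in self.images])

    def classes(self) -> list[int]:
        return sorted({im.class_label for im in self.images})


@dataclass(frozen=True)
class VeinTemplate:
    """Renderable identity: smooth dark curves inside a finger mask.

    Control points are stored, not pixels, so one identity can be rendered
    many times under different jitter and imaging conditions.
    """

    shape: tuple[int, int]
    control_points: tuple[np.ndarray, ...]  # each (n_ctrl, 2) in pixel coords
    vein_depths: np.ndarray  # darkening amplitude per vein
    vein_widths: np.ndarray  # Gaussian cross-profile sigma per vein
    background_level: float
    finger_axis: str  # "h" if the finger runs along the width


@dataclass(frozen=True)
class Jitter:
    shift: tuple[float, float] = (0.0, 0.0)  # (dy, dx) pixels
    rotation_deg: float = 0.0
    brightness_offset: float = 0.0


def generate_identity_pattern(
    seed: int, shape: tuple[int, int], n_veins: int = 5, axis: str | None = None
) -> VeinTemplate:
    """Draw a new finger-vein identity as a set of smooth curve control points.

    The finger runs along ``axis`` ("h" along the width, "v" along the
    height; default: the image's longer dimension); veins are gently
    meandering curves spanning most of its length, each with its own depth
    (how dark) and width.  Deterministic for a given seed.
    """
    if n_veins < 1:
        raise ValueError("n_veins must be >= 1")
    h, w = shape
    if h < 16 or w < 16:
        raise ValueError("shape must be at least 16x16 to resolve curves")
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = "h" if w >= h else "v"
    long_len, short_len = (w, h) if axis == "h" else (h, w)

    n_ctrl = 6
    curves = []
    for _ in range(n_veins):
        # longitudinal positions spanning the finger, lateral meander
        longi = np.linspace(0.06 * long_len, 0.94 * long_len, n_ctrl)
        longi = longi + rng.uniform(-0.03, 0.03, n_ctrl) * long_len
        center = rng.uniform(0.25, 0.75) * short_len
        lat = center + rng.normal(0.0, 0.06 * short_len, n_ctrl)
        lat = np.clip(lat, 0.15 * short_len, 0.85 * short_len)
        if axis == "h":
            pts = np.stack([lat, longi], axis=1)  # (y, x)
        else:
            pts = np.stack([longi, lat], axis=1)
        curves.append(pts)

    return VeinTemplate(
        shape=(h, w),
        control_points=tuple(curves),
        vein_depths=rng.uniform(45.0, 85.0, n_veins),
        vein_widths=rng.uniform(1.2, 2.4, n_veins),
        background_level=float(rng.uniform(170.0, 200.0)),
        finger_axis=axis,
    )


def _catmull_rom(points: np.ndarray, samples_per_seg: int = 24) -> np.ndarray:
    """Densely sample a smooth curve through the control points."""
    p = np.vstack([points[0], points, points[-1]])
    t = np.linspace(0.0, 1.0, samples_per_seg, endpoint=False)
    out = []
    for i in range(len(points) - 1):
        p0, p1, p2, p3 = p[i], p[i + 1], p[i + 2], p[i + 3]
        tt = t[:, None]
        seg = 0.5 * (
            2 * p1
            + (-p0 + p2) * tt
            + (2 * p0 - 5 * p1 + 4 * p2 - p3) * tt**2
            + (-p0 + 3 * p1 - 3 * p2 + p3) * tt**3
        )
        out.append(seg)
    out.append(points[-1][None])
    return np.vstack(out)


def _finger_mask_profile(shape: tuple[int, int], axis: str) -> np.ndarray:
    """Soft elliptical finger silhouette in [0, 1] (1 = on-finger)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if axis == "h":
        ry, rx = 0.46 * h, 0.52 * w
    else:
        ry, rx = 0.52 * h, 0.46 * w
    r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    return 1.0 / (1.0 + np.exp(8.0 * (r2 - 1.0)))


def _render_clean(template: VeinTemplate, jitter: Jitter) -> np.ndarray:
    """Render template to float pixels (before contrast/noise), in [0, 255]."""
    h, w = template.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    mask = _finger_mask_profile(template.shape, template.finger_axis)
    img = template.background_level * mask + 40.0 * (1.0 - mask)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ang = np.deg2rad(jitter.rotation_deg)
    cos_a, sin_a = np.cos(ang), np.sin(ang)
    dy, dx = jitter.shift

    pix = np.stack([yy.ravel(), xx.ravel()], axis=1)
    for pts, depth, width in zip(
        template.control_points, template.vein_depths, template.vein_widths
    ):
        curve = _catmull_rom(pts)
        # rotate about the image center, then shift
        rel = curve - [cy, cx]
        rot = np.stack(
            [
                cos_a * rel[:, 0] - sin_a * rel[:, 1],
                sin_a * rel[:, 0] + cos_a * rel[:, 1],
            ],
            axis=1,
        )
        curve = rot + [cy + dy, cx + dx]
        # distance from every pixel to the sampled curve
        d2 = (
            (pix[:, 0:1] - curve[None, :, 0]) ** 2
            + (pix[:, 1:2] - curve[None, :, 1]) ** 2
        ).min(axis=1)
        img -= depth * np.exp(-d2 / (2.0 * width**2)).reshape(h, w) * mask

    return np.clip(img, 0.0, 255.0)


def apply_contrast(pixels: np.ndarray, contrast_level: float) -> np.ndarray:
    """x -> 127.5 + c * (x - 127.5), clipped to [0, 255]; c = 1 is identity."""
    if not 0.0 < contrast_level <= 1.0:
        raise ValueError("contrast_level must lie in (0, 1]")
    out = 127.5 + contrast_level * (np.asarray(pixels, dtype=float) - 127.5)
    return np.clip(out, 0.0, 255.0)


def render_sample(
    template: VeinTemplate,
    jitter: Jitter,
    contrast_level: float,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    client_id: int = 0,
    class_label: int = 0,
    orientation: str = "horizontal",
    illumination_offset: float = 0.0,
) -> VeinImage:
    """Render one acquisition of an identity under the given conditions."""
    img = _render_clean(template, jitter)
    img = img + illumination_offset + jitter.brightness_offset
    img = apply_contrast(img, contrast_level)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return VeinImage(
        pixels=pixels,
        client_id=client_id,
        class_label=class_label,
        orientation=orientation,
    )


def generate_federation(spec: SyntheticFederationSpec) -> list[ClientDataset]:
    """Generate every client's dataset; labels disjoint across clients.

    With ``shared_class_fraction`` > 0 the leading classes of client k > 0
    reuse client k-1's trailing identities (same global label, same vein
    template), so one class is owned by two clients.
    """
    root_ss = np.random.SeedSequence(spec.master_seed)
    client_seeds = root_ss.spawn(len(spec.clients))

    datasets: list[ClientDataset] = []
    next_label = 0
    prev_classes: list[tuple[int, VeinTemplate]] = []
    for cid, (cspec, ss) in enumerate(zip(spec.clients, client_seeds)):
        rng = np.random.default_rng(ss)
        n_shared = 0
        if cid > 0 and spec.shared_class_fraction > 0:
            n_shared = min(
                int(spec.shared_class_fraction * cspec.n_classes),
                len(prev_classes),
            )
        classes: list[tuple[int, VeinTemplate]] = []
        classes.extend(prev_classes[-n_shared:] if n_shared else [])
        shape = (cspec.image_height, cspec.image_width)
        axis = "v" if cspec.orientation == "vertical" else "h"
        for _ in range(cspec.n_classes - n_shared):
            tmpl_seed = int(rng.integers(0, 2**31 - 1))
            classes.append(
                (
                    next_label,
                    generate_identity_pattern(tmpl_seed, shape, cspec.n_veins, axis),
                )
            )
            next_label += 1

        images: list[VeinImage] = []
        for label, tmpl in classes:
            for _ in range(cspec.samples_per_class):
                jit = Jitter(
                    shift=(
                        float(rng.uniform(-2.0, 2.0)),
                        float(rng.uniform(-3.0, 3.0)),
                    ),
                    rotation_deg=float(rng.uniform(-3.0, 3.0)),
                    brightness_offset=float(rng.uniform(-6.0, 6.0)),
                )
                images.append(
                    render_sample(
                        tmpl,
                        jit,
                        cspec.contrast_level,
                        cspec.noise_sd,
                        rng,
                        client_id=cid,
                        class_label=label,
                        orientation=cspec.orientation,
                        illumination_offset=cspec.illumination_offset,
                    )
                )
        datasets.append(ClientDataset(client_id=cid, spec=cspec, images=images))
        prev_classes = classes
    return datasets


def write_dataset(datasets: list[ClientDataset], root: str | os.PathLike) -> None:
    """Write ``root/client_<k>/class_<label>/sample_<i>.png`` (8-bit gray)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        by_class: dict[int, list[VeinImage]] = {}
        for im in ds.images:
            by_class.setdefault(im.class_label, []).append(im)
        cdir = root / f"client_{ds.client_id}"
        for label, ims in sorted(by_class.items()):
            d = cdir / f"class_{label}"
            d.mkdir(parents=True, exist_ok=True)
            for i, im in enumerate(ims):
                Image.fromarray(im.pixels, mode="L").save(d / f"sample_{i}.png")
        with open(cdir / "meta.txt", "w") as fh:
            fh.write(f"orientation={ds.spec.orientation}\n")


def read_dataset(root: str | os.PathLike) -> list[ClientDataset]:
    """Read the class-per-directory layout back; inverse of write_dataset."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root not found: {root}")
    datasets = []
    client_dirs = sorted(
        [p for p in root.iterdir() if p.is_dir()],
        key=lambda p: p.name,
    )
    if not client_dirs:
        raise ValueError(f"no client directories under {root}")
    for cdir in client_dirs:
        cid = int(cdir.name.split("_")[-1])
        orientation = "horizontal"
        meta = cdir / "meta.txt"
        if meta.exists():
            for line in meta.read_text().splitlines():
                if line.startswith("orientation="):
                    orientation = line.split("=", 1)[1].strip()
        images: list[VeinImage] = []
        class_dirs = sorted(
            [p for p in cdir.iterdir() if p.is_dir()],
            key=lambda p: int(p.name.split("_")[-1]),
        )
        for kdir in class_dirs:
            label = int(kdir.name.split("_")[-1])
            files = sorted(kdir.iterdir())
            if not files:
                raise ValueError(f"empty class directory: {kdir}")
            for f in files:
                try:
                    with Image.open(f) as img:
                        pixels = np.asarray(img.convert("L"))
                except Exception as exc:
                    raise ValueError(f"not a readable image file: {f}") from exc
                images.append(
                    VeinImage(
                        pixels=pixels,
                        client_id=cid,
                        class_label=label,
                        orientation=orientation,
                    )
                )
        h, w = images[0].pixels.shape
        spec = ClientSpec(
            n_classes=len(class_dirs),
            samples_per_class=max(
                2, len(images) // max(len(class_dirs), 1)
            ),
            image_height=h,
            image_width=w,
            orientation=orientation,
        )
        datasets.append(ClientDataset(client_id=cid, spec=spec, images=images))
    return datasets
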