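"""Synthetic fluorescence-microscopy scenes with exact ground truth.

Every analysis stage of the package (soma/neurite morphometry, spine
skeletons, PLA dot calling, wound detection) is validated against scenes
produced here: neuron-like cells (a soma disk with branched neurites
bearing short spines), fields of nuclei overlaid with diffraction-limited
punctae, and time series of a closing cell-free wound band.

The forward model is the standard widefield/confocal emulation chain:
noise-free rasterization -> Gaussian PSF blur -> Poisson shot noise at a
configurable photon scale -> additive Gaussian read noise.  Ground-truth
masks are the *unblurred, unnoised* binary rasters, so pixel-count oracles
are exact.  Coordinates are 0-based (row, col) with origin at the top-left;
areas are in pixels (multiply by ``pixel_size**2`` for µm²).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "ImagingParams",
    "CellSpec",
    "GroundTruth",
    "SyntheticScene",
    "generate_neuron_scene",
    "generate_pla_scene",
    "generate_wound_series",
    "write_scene",
]


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition parameters for rendering a synthetic scene.

    Parameters
    ----------
    image_shape : (height, width) in pixels.
    pixel_size : physical pixel size, µm per pixel (reporting only).
    psf_sigma : Gaussian point-spread sigma, pixels; 0 disables blur.
    background_level : additive background, arbitrary intensity units.
    signal_level : amplitude of foreground structures above background.
    poisson_scale : photons per intensity unit; 0 disables shot noise.
    read_noise_sigma : sigma of additive Gaussian read noise; 0 disables.
    seed : base seed; identical seed and parameters give bit-identical
        scenes (one generator per scene, per-channel substreams).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.2
    psf_sigma: float = 1.0
    background_level: float = 20.0
    signal_level: float = 180.0
    poisson_scale: float = 1.0
    read_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image_shape must be positive")
        for name in ("psf_sigma", "poisson_scale", "read_noise_sigma",
                     "pixel_size", "background_level", "signal_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def noise_free(self) -> "ImagingParams":
        """Copy with blur and both noise sources switched off."""
        return dataclasses.replace(
            self, psf_sigma=0.0, poisson_scale=0.0, read_noise_sigma=0.0
        )


@dataclass(frozen=True)
class CellSpec:
    """Geometry of one neuron-like cell.

    ``neurites`` is a list of ``(polyline, width)`` pairs; each polyline is a
    sequence of (row, col) vertices whose first vertex must lie on the soma
    boundary (within one pixel).  ``spines`` is a list of
    ``(anchor, angle_deg, length, width)`` tuples whose anchor must lie on a
    neurite centre line (within that neurite's half width + 1 px).
    """

    soma_center: tuple[float, float]
    soma_radius: float
    neurites: tuple = ()
    spines: tuple = ()

    def __post_init__(self) -> None:
        if self.soma_radius <= 0:
            raise ValueError("soma_radius must be > 0")
        object.__setattr__(self, "neurites", tuple(
            (tuple(map(tuple, path)), float(w)) for path, w in self.neurites))
        object.__setattr__(self, "spines", tuple(
            (tuple(a), float(ang), float(ln), float(w))
            for a, ang, ln, w in self.spines))
        for path, w in self.neurites:
            if w <= 0 or len(path) < 2:
                raise ValueError("neurite needs width > 0 and >= 2 vertices")
            r0, c0 = path[0]
            d = np.hypot(r0 - self.soma_center[0], c0 - self.soma_center[1])
            if abs(d - self.soma_radius) > 1.5:
                raise ValueError(
                    "neurite path must start on the soma boundary "
                    f"(distance {d:.1f} vs radius {self.soma_radius})")
        for anchor, _ang, ln, w in self.spines:
            if ln <= 0 or w <= 0:
                raise ValueError("spine length and width must be > 0")
            if not self._on_a_neurite(anchor):
                raise ValueError(f"spine anchor {anchor} not on a neurite")

    def _on_a_neurite(self, point: tuple[float, float]) -> bool:
        p = np.asarray(point, float)
        for path, w in self.neurites:
            verts = np.asarray(path, float)
            for a, b in zip(verts[:-1], verts[1:]):
                if _point_segment_distance(p, a, b) <= w / 2 + 1.0:
                    return True
        return False


@dataclass
class GroundTruth:
    """Exact noise-free annotation of a scene; unused fields stay None."""

    cell_labels: np.ndarray | None = None        # int image, 0 = background
    cell_masks: list[np.ndarray] = field(default_factory=list)
    soma_mask: np.ndarray | None = None
    neurite_mask: np.ndarray | None = None
    soma_masks: list[np.ndarray] = field(default_factory=list)
    neurite_masks: list[np.ndarray] = field(default_factory=list)
    spine_skeletons: list[np.ndarray] = field(default_factory=list)
    nuclei_mask: np.ndarray | None = None
    dot_mask: np.ndarray | None = None
    wound_masks: np.ndarray | None = None        # (n_frames, h, w) bool
    times: np.ndarray | None = None              # hours, wound series only


@dataclass
class SyntheticScene:
    """A rendered multi-channel scene plus its generating truth.

    ``channels`` maps channel name (``actin``, ``nuclei``, ``pla``,
    ``frames``) to a float image (or stack for ``frames``).
    """

    channels: dict[str, np.ndarray]
    truth: GroundTruth
    params: ImagingParams
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rasterization primitives (binary, no anti-aliasing: truth must be exact)

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(p - (a + t * ab))))


def disk_mask(shape: tuple[int, int], center: tuple[float, float],
              radius: float) -> np.ndarray:
    """Pixels whose centre lies within ``radius`` of ``center``."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def thick_polyline_mask(shape: tuple[int, int], path: Sequence[tuple[float, float]],
                        width: float) -> np.ndarray:
    """Pixels within ``width/2`` of the polyline (round caps/joins)."""
    out = np.zeros(shape, bool)
    verts = np.asarray(path, float)
    half = width / 2.0
    for a, b in zip(verts[:-1], verts[1:]):
        lo = np.floor(np.minimum(a, b) - half - 1).astype(int)
        hi = np.ceil(np.maximum(a, b) + half + 1).astype(int)
        lo = np.clip(lo, 0, [shape[0] - 1, shape[1] - 1])
        hi = np.clip(hi, 0, [shape[0] - 1, shape[1] - 1])
        rr, cc = np.mgrid[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1]
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d = np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
        else:
            t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.hypot(pts[:, 0] - proj[:, 0], pts[:, 1] - proj[:, 1])
        sub = (d <= half).reshape(rr.shape)
        out[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1] |= sub
    return out


def _spine_segment(anchor, angle_deg, length):
    ang = np.deg2rad(angle_deg)
    # image convention: angle 0 -> +col, 90 -> -row (upward)
    tip = (anchor[0] - length * np.sin(ang), anchor[1] + length * np.cos(ang))
    return [tuple(anchor), tip]


# ---------------------------------------------------------------------------
# rendering

def _render(truth_raster: np.ndarray, params: ImagingParams,
            rng: np.random.Generator) -> np.ndarray:
    """Noise chain: blur -> Poisson -> read noise, over a background."""
    img = params.background_level + params.signal_level * truth_raster.astype(float)
    if params.psf_sigma > 0:
        img = ndi.gaussian_filter(img, params.psf_sigma)
    if params.poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * params.poisson_scale)
        img = img.astype(float) / params.poisson_scale
    if params.read_noise_sigma > 0:
        img = img + rng.normal(0.0, params.read_noise_sigma, img.shape)
    return img


def _channel_rng(params: ImagingParams, channel: str) -> np.random.Generator:
    # deterministic substream per channel, all derived from the scene seed
    sub = int.from_bytes(channel.encode(), "little") % (2 ** 31)
    return np.random.default_rng([params.seed, sub])


# ---------------------------------------------------------------------------
# scene generators

def generate_neuron_scene(specs: Sequence[CellSpec],
                          params: ImagingParams) -> SyntheticScene:
    """Render neuron-like cells into an F-actin channel with exact truth.

    Somas must not overlap and every structure must fit on the canvas.
    Truth per cell: soma mask (the rasterized disk), neurite mask (the rest
    of the cell: neurite shafts plus spines), whole-cell mask (their union),
    and the spine centre lines as 1-px skeleton masks.
    """
    shape = params.image_shape
    specs = list(specs)
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            d = np.hypot(a.soma_center[0] - b.soma_center[0],
                         a.soma_center[1] - b.soma_center[1])
            if d <= a.soma_radius + b.soma_radius:
                raise ValueError("layout error: overlapping somas")

    truth = GroundTruth(cell_labels=np.zeros(shape, np.int32))
    combined = np.zeros(shape, bool)
    for idx, spec in enumerate(specs, start=1):
        soma = disk_mask(shape, spec.soma_center, spec.soma_radius)
        arbor = np.zeros(shape, bool)
        for path, w in spec.neurites:
            arbor |= thick_polyline_mask(shape, path, w)
        spine_skel = np.zeros(shape, bool)
        for anchor, ang, ln, w in spec.spines:
            seg = _spine_segment(anchor, ang, ln)
            arbor |= thick_polyline_mask(shape, seg, w)
            spine_skel |= thick_polyline_mask(shape, seg, 1.0)
        cell = soma | arbor
        if _touches_border_or_outside(cell, spec, shape):
            raise ValueError("cell spec falls outside the image canvas")
        neurite = cell & ~soma
        truth.cell_masks.append(cell)
        truth.soma_masks.append(soma)
        truth.neurite_masks.append(neurite)
        truth.spine_skeletons.append(spine_skel & ~soma)
        truth.cell_labels[cell] = idx
        combined |= cell
    truth.soma_mask = (np.zeros(shape, bool) if not specs
                       else np.logical_or.reduce(truth.soma_masks))
    truth.neurite_mask = (np.zeros(shape, bool) if not specs
                          else np.logical_or.reduce(truth.neurite_masks))

    actin = _render(combined, params, _channel_rng(params, "actin"))
    return SyntheticScene({"actin": actin}, truth, params,
                          meta={"n_cells": len(specs)})


def _touches_border_or_outside(cell: np.ndarray, spec: CellSpec,
                               shape: tuple[int, int]) -> bool:
    r, c = spec.soma_center
    if not (0 <= r < shape[0] and 0 <= c < shape[1]):
        return True
    return bool(cell[0, :].any() or cell[-1, :].any()
                or cell[:, 0].any() or cell[:, -1].any())


def generate_pla_scene(n_nuclei: int, nucleus_radius: float, n_dots: int,
                       dot_radius: float, params: ImagingParams,
                       max_tries: int = 2000) -> SyntheticScene:
    """A nuclei (DAPI-like) channel plus a punctate PLA channel.

    Nuclei are non-overlapping disks; dots are small non-overlapping disks
    rendered as diffraction-limited punctae.  Truth records both masks, so
    dot/nuclei area ratios have exact references.
    """
    if n_nuclei < 0 or n_dots < 0:
        raise ValueError("counts must be >= 0")
    shape = params.image_shape
    rng = _channel_rng(params, "layout")

    nuclei_centers = _place_disks(rng, shape, n_nuclei, nucleus_radius,
                                  margin=nucleus_radius + 2, max_tries=max_tries)
    dot_centers = _place_disks(rng, shape, n_dots, dot_radius,
                               margin=dot_radius + 2, max_tries=max_tries,
                               min_sep=4 * dot_radius + 2)

    nuclei_mask = np.zeros(shape, bool)
    for ctr in nuclei_centers:
        nuclei_mask |= disk_mask(shape, ctr, nucleus_radius)
    dot_mask = np.zeros(shape, bool)
    for ctr in dot_centers:
        m = disk_mask(shape, ctr, dot_radius)
        if not m.any():                      # radius < 0.5: keep centre pixel
            m[int(round(ctr[0])), int(round(ctr[1]))] = True
        dot_mask |= m

    truth = GroundTruth(nuclei_mask=nuclei_mask, dot_mask=dot_mask)
    nuclei_img = _render(nuclei_mask, params, _channel_rng(params, "nuclei"))
    pla_img = _render(dot_mask, params, _channel_rng(params, "pla"))
    return SyntheticScene({"nuclei": nuclei_img, "pla": pla_img}, truth, params,
                          meta={"n_nuclei": n_nuclei, "n_dots": n_dots,
                                "nuclei_centers": [tuple(c) for c in nuclei_centers],
                                "dot_centers": [tuple(c) for c in dot_centers]})


def _place_disks(rng, shape, n, radius, margin, max_tries, min_sep=None):
    """Rejection-sample non-overlapping disk centres; error when stuck."""
    if min_sep is None:
        min_sep = 2 * radius + 1
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries * max(n, 1):
            raise ValueError(
                f"could not place {n} non-overlapping disks of radius {radius}")
        tries += 1
        cand = np.array([rng.uniform(margin, shape[0] - margin),
                         rng.uniform(margin, shape[1] - margin)])
        if all(np.hypot(*(cand - c)) > min_sep for c in centers):
            centers.append(cand)
    return centers


def generate_wound_series(times: Sequence[float], initial_gap_width: float,
                          closure_rate: float, params: ImagingParams,
                          cell_density: float = 0.035,
                          cell_radius: float = 6.0) -> SyntheticScene:
    """Frames of a confluent monolayer with a closing central vertical gap.

    At time ``t`` (hours) the cell-free band has width
    ``max(0, initial_gap_width - closure_rate * t)`` pixels, centred on the
    image.  Outside the band the field is textured with a dense additive
    field of Gaussian cell-like bumps (``cell_density`` per pixel); inside
    it is flat background, which is what texture-based wound detection keys
    on.  The truth wound mask per frame is the exact integer-width band.
    """
    times = np.asarray(times, float)
    if times.ndim != 1 or len(times) == 0 or times[0] != 0:
        raise ValueError("times must start at 0")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if initial_gap_width < 0 or closure_rate < 0:
        raise ValueError("gap width and closure rate must be >= 0")

    shape = params.image_shape
    h, w = shape
    rng = _channel_rng(params, "cells")
    n_cells = int(cell_density * h * w)
    centers = np.column_stack([rng.uniform(0, h, n_cells),
                               rng.uniform(0, w, n_cells)])
    radii = rng.uniform(0.6 * cell_radius, 1.4 * cell_radius, n_cells)
    amps = rng.uniform(0.4, 1.0, n_cells)

    frames = np.empty((len(times), h, w))
    wound_masks = np.zeros((len(times), h, w), bool)
    for k, t in enumerate(times):
        width_t = max(0.0, initial_gap_width - closure_rate * t)
        wpx = int(round(width_t))
        start = (w - wpx) // 2
        band = np.zeros(shape, bool)
        if wpx > 0:
            band[:, start: start + wpx] = True
        wound_masks[k] = band

        raster = np.zeros(shape, float)
        for (cr, cc), rad, amp in zip(centers, radii, amps):
            lo_r, hi_r = int(max(0, cr - rad - 1)), int(min(h, cr + rad + 2))
            lo_c, hi_c = int(max(0, cc - rad - 1)), int(min(w, cc + rad + 2))
            if lo_r >= hi_r or lo_c >= hi_c:
                continue
            rr, cc2 = np.mgrid[lo_r:hi_r, lo_c:hi_c]
            blob = (rr - cr) ** 2 + (cc2 - cc) ** 2 <= rad ** 2
            raster[lo_r:hi_r, lo_c:hi_c] = np.maximum(
                raster[lo_r:hi_r, lo_c:hi_c], amp * blob)
        # intracellular granularity: spatially correlated speckle (scale a
        # little above the PSF, so blur does not flatten it) gives confluent
        # regions the texture a windowed-std detector keys on
        srng = _channel_rng(params, f"speckle{k}")
        noise = ndi.gaussian_filter(srng.standard_normal(shape), 1.5)
        noise /= max(noise.std(), 1e-12)
        raster *= np.clip(1.0 + 0.9 * noise, 0.05, None)
        raster[band] = 0.0
        frames[k] = _render(raster, params, _channel_rng(params, f"frame{k}"))

    truth = GroundTruth(wound_masks=wound_masks, times=times)
    return SyntheticScene({"frames": frames}, truth, params,
                          meta={"initial_gap_width": initial_gap_width,
                                "closure_rate": closure_rate})


# ---------------------------------------------------------------------------
# persistence

def write_scene(scene: SyntheticScene, outdir: str | Path) -> Path:
    """Write channels as one multi-page TIFF plus a JSON truth sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tif_path = outdir / "scene.tif"
    with tifffile.TiffWriter(tif_path) as tw:
        for name, img in scene.channels.items():
            arr = np.asarray(img, np.float32)
            if arr.ndim == 2:
                tw.write(arr, description=name)
            else:
                for k in range(arr.shape[0]):
                    tw.write(arr[k], description=f"{name}[{k}]")
    sidecar = {
        "params": dataclasses.asdict(scene.params),
        "meta": _jsonable(scene.meta),
        "truth_areas": _truth_areas(scene.truth),
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))
    for name, mask in _truth_masks(scene.truth).items():
        import imageio.v3 as iio
        iio.imwrite(outdir / f"truth_{name}.png",
                    (mask.astype(np.uint8) * 255))
    return tif_path


def _truth_masks(truth: GroundTruth) -> dict[str, np.ndarray]:
    out = {}
    for name in ("soma_mask", "neurite_mask", "nuclei_mask", "dot_mask"):
        m = getattr(truth, name)
        if m is not None:
            out[name.replace("_mask", "")] = m
    if truth.cell_labels is not None:
        out["cells"] = truth.cell_labels > 0
    if truth.wound_masks is not None:
        for k in range(truth.wound_masks.shape[0]):
            out[f"wound_{k}"] = truth.wound_masks[k]
    return out


def _truth_areas(truth: GroundTruth) -> dict:
    return {name: int(mask.sum()) for name, mask in _truth_masks(truth).items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
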