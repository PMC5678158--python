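"""Synthetic multiplex-IHC field generator with planted TMEM ground truth.

Emulates 20X fields of a triple-chromogen stain (blue CD31 endothelium,
brown CD68 macrophages, red Mena tumor cells).  Cells are rendered as
filled disks of class-specific chromogen; fields are rendered through a
Beer-Lambert transmission model so that chromogen unmixing is a well-posed
linear inversion.  TMEM triples (one cell of each class in mutual contact)
are planted with known geometry, and every other structure is kept at a
configured minimum separation, so the downstream detector can be scored
against exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .stains import DEFAULT_BASIS, StainBasis

__all__ = [
    "CELL_CLASSES",
    "CHROMOGEN_OF_CLASS",
    "FieldSpec",
    "Cell",
    "GroundTruth",
    "FieldImage",
    "PlacementError",
    "generate_field",
    "generate_slide",
    "write_slide",
]

#: cell classes and the chromogen channel (row of the stain basis) each stains
CELL_CLASSES = ("tumor", "macrophage", "endothelial")
CHROMOGEN_OF_CLASS = {"endothelial": 0, "macrophage": 1, "tumor": 2}

_MAX_PLACEMENT_ATTEMPTS = 10_000


class PlacementError(RuntimeError):
    """Field too small to place a structure at the required separation."""


@dataclass(frozen=True)
class FieldSpec:
    """Geometry and content of one synthetic field of view.

    ``n_tumor``/``n_macrophage``/``n_endothelial`` are *extra* isolated
    cells on top of the ``n_triples`` planted TMEM structures.  The
    minimum separation applies between distinct structures (a triple
    counts as one structure) and must exceed twice the contact radius the
    detector will use, so the planted truth is unambiguous.
    """

    width_px: int = 1330   # 665 um at 0.5 um/px
    height_px: int = 1000  # 500 um
    microns_per_pixel: float = 0.5
    n_tumor: int = 4
    n_macrophage: int = 4
    n_endothelial: int = 4
    n_triples: int = 3
    cell_radius_um: tuple[float, float] = (3.0, 5.0)
    min_separation_um: float = 40.0
    noise_sd: float = 0.02
    concentration: float = 1.0
    endothelial_aspect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_macrophage", "n_endothelial", "n_triples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_radius_um[0] <= 0 or self.cell_radius_um[1] < self.cell_radius_um[0]:
            raise ValueError("invalid cell radius range")
        if self.min_separation_um <= 0 or self.microns_per_pixel <= 0:
            raise ValueError("separation and pixel size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def validate_against_contact_radius(self, contact_radius_um: float) -> None:
        if self.min_separation_um <= 2 * contact_radius_um:
            raise ValueError(
                "min_separation_um must exceed 2x the contact radius so that "
                "planted structures are unambiguous")


@dataclass(frozen=True)
class Cell:
    cell_class: str
    center_px: tuple[float, float]  # (x, y)
    radius_px: float
    aspect: float = 1.0
    angle: float = 0.0


@dataclass
class GroundTruth:
    """Planted cells, planted TMEM triples (cell-id triples), true count."""

    cells: list[Cell]
    triples: list[tuple[int, int, int]]

    @property
    def true_count(self) -> int:
        return len(self.triples)

    def to_json(self) -> str:
        return json.dumps({
            "cells": [
                {"class": c.cell_class, "center_px": list(c.center_px),
                 "radius_px": c.radius_px, "aspect": c.aspect,
                 "angle": c.angle}
                for c in self.cells
            ],
            "triples": [list(t) for t in self.triples],
            "true_count": self.true_count,
        }, indent=1)


@dataclass
class FieldImage:
    """Rendered field: 8-bit RGB plus the exact float transmission image.

    ``rgb`` is the quantised image a microscope file would hold;
    ``rgb_float`` is the pre-quantisation transmission (same 0-255 scale)
    kept so that unmixing can be verified as an exact linear inversion;
    ``concentrations`` are the planted per-pixel chromogen maps (H, W, 3)
    in OD units, channel order blue/brown/red.
    """

    rgb: np.ndarray
    rgb_float: np.ndarray
    concentrations: np.ndarray
    microns_per_pixel: float


def _paint_disk(plane, center_xy, radius, amplitude, aspect=1.0, angle=0.0):
    """Add ``amplitude`` over a (possibly elliptic) disk, bbox-limited."""
    h, w = plane.shape
    cx, cy = center_xy
    rmax = radius * max(1.0, aspect)
    x0, x1 = max(int(cx - rmax) - 1, 0), min(int(cx + rmax) + 2, w)
    y0, y1 = max(int(cy - rmax) - 1, 0), min(int(cy + rmax) + 2, h)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    if aspect != 1.0:
        ca, sa = np.cos(angle), np.sin(angle)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        mask = (u / (radius * aspect)) ** 2 + (v / radius) ** 2 <= 1.0
    else:
        mask = dx * dx + dy * dy <= radius * radius
    plane[y0:y1, x0:x1] += amplitude * mask


def _triple_geometry(rng, radii_px, gap_px):
    """Centers of a 3-cell contact cluster with pairwise boundary gaps = gap.

    Standard triangle construction from the three pairwise center
    distances, randomly rotated; returned centered on the centroid.
    """
    r1, r2, r3 = radii_px
    d12 = r1 + r2 + gap_px
    d13 = r1 + r3 + gap_px
    d23 = r2 + r3 + gap_px
    p1 = np.array([0.0, 0.0])
    p2 = np.array([d12, 0.0])
    x3 = (d12 ** 2 + d13 ** 2 - d23 ** 2) / (2 * d12)
    y3 = np.sqrt(max(d13 ** 2 - x3 ** 2, 0.0))
    p3 = np.array([x3, y3])
    pts = np.stack([p1, p2, p3])
    pts -= pts.mean(axis=0)
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    return pts @ rot.T


def generate_field(spec: FieldSpec, basis: StainBasis = DEFAULT_BASIS,
                   contact_radius_um: float = 2.0,
                   rng: np.random.Generator | None = None):
    """Render one field; returns ``(FieldImage, GroundTruth)``.

    Planted triples place their three cell boundaries at pairwise gaps of
    a quarter of the contact radius (comfortably inside the contact
    criterion); all distinct structures are separated by at least
    ``min_separation_um`` between centers, by rejection sampling with a
    hard attempt cap.
    """
    spec.validate_against_contact_radius(contact_radius_um)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mpp = spec.microns_per_pixel
    h, w = spec.height_px, spec.width_px
    sep_px = spec.min_separation_um / mpp
    gap_px = (contact_radius_um / mpp) / 4.0
    margin = (spec.cell_radius_um[1] * max(1.0, spec.endothelial_aspect)
              / mpp) + sep_px / 2

    structure_centers: list[np.ndarray] = []

    def _place(label: str) -> np.ndarray:
        if w - 2 * margin <= 0 or h - 2 * margin <= 0:
            raise PlacementError(f"field too small to place {label}")
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            c = np.array([rng.uniform(margin, w - margin),
                          rng.uniform(margin, h - margin)])
            if all(np.linalg.norm(c - o) >= sep_px for o in structure_centers):
                structure_centers.append(c)
                return c
        raise PlacementError(
            f"could not place {label} at separation "
            f"{spec.min_separation_um} um after {_MAX_PLACEMENT_ATTEMPTS} "
            "attempts")

    cells: list[Cell] = []
    triples: list[tuple[int, int, int]] = []

    def _radius_px():
        return rng.uniform(*spec.cell_radius_um) / mpp

    for k in range(spec.n_triples):
        center = _place(f"TMEM triple #{k + 1}")
        radii = [_radius_px() for _ in range(3)]
        offsets = _triple_geometry(rng, radii, gap_px)
        ids = []
        for cls, off, r in zip(CELL_CLASSES, offsets, radii):
            ids.append(len(cells))
            cells.append(Cell(cls, tuple(center + off), r))
        triples.append(tuple(ids))

    for cls, n in (("tumor", spec.n_tumor), ("macrophage", spec.n_macrophage),
                   ("endothelial", spec.n_endothelial)):
        for k in range(n):
            center = _place(f"isolated {cls} cell #{k + 1}")
            aspect = spec.endothelial_aspect if cls == "endothelial" else 1.0
            angle = rng.uniform(0, np.pi) if aspect != 1.0 else 0.0
            cells.append(Cell(cls, tuple(center), _radius_px(),
                              aspect=aspect, angle=angle))

    conc = np.zeros((h, w, 3))
    for c in cells:
        _paint_disk(conc[..., CHROMOGEN_OF_CLASS[c.cell_class]], c.center_px,
                    c.radius_px, spec.concentration, c.aspect, c.angle)

    od = conc @ basis.matrix            # (h, w, 3) RGB optical densities
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, od.shape)
    od = np.clip(od, 0.0, None)
    # transmission on the 0..255 scale, chosen so OD = -log((I+1)/256)
    # inverts it exactly on the float path
    rgb_float = np.clip(256.0 * np.exp(-od) - 1.0, 0.0, 255.0)
    rgb = np.round(rgb_float).astype(np.uint8)
    img = FieldImage(rgb=rgb, rgb_float=rgb_float, concentrations=conc,
                     microns_per_pixel=mpp)
    return img, GroundTruth(cells=cells, triples=triples)


def generate_slide(n_fields: int, spec_template: FieldSpec,
                   basis: StainBasis = DEFAULT_BASIS,
                   per_field_counts: list[int] | None = None,
                   contact_radius_um: float = 2.0):
    """Render a slide: one field per entry of ``per_field_counts``.

    The slide-level true MetaSite score is the sum of the three largest
    per-field true counts (all of them if fewer than three fields).
    """
    if n_fields < 1:
        raise ValueError("a slide needs at least one field")
    if per_field_counts is None:
        per_field_counts = [spec_template.n_triples] * n_fields
    if len(per_field_counts) != n_fields:
        raise ValueError("per_field_counts must have length n_fields")
    ss = np.random.SeedSequence(spec_template.seed)
    fields = []
    for i, (count, child) in enumerate(zip(per_field_counts, ss.spawn(n_fields))):
        spec_i = replace(spec_template, n_triples=int(count))
        rng = np.random.default_rng(child)
        fields.append(generate_field(spec_i, basis, contact_radius_um, rng=rng))
    return fields


def true_slide_score(per_field_counts) -> int:
    """Sum of the three largest per-field true counts."""
    counts = sorted(per_field_counts, reverse=True)
    return int(sum(counts[:3]))


def write_slide(fields, out_dir, fmt: str = "tiff") -> pd.DataFrame:
    """Write field images (TIFF or PNG), JSON ground-truth sidecars and the
    slide manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, gt) in enumerate(fields):
        stem = f"field_{i:03d}"
        if fmt == "tiff":
            fname = f"{stem}.tiff"
            tifffile.imwrite(out / fname, img.rgb)
        elif fmt == "png":
            fname = f"{stem}.png"
            Image.fromarray(img.rgb).save(out / fname)
        else:
            raise ValueError(f"unknown image format {fmt!r}")
        (out / f"{stem}.json").write_text(gt.to_json())
        rows.append({"field_id": stem, "file": fname,
                     "true_count": gt.true_count})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
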