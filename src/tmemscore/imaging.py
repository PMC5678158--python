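"""From RGB field images to per-field TMEM counts and the MetaSite score.

Pipeline: unmix the three chromogens into concentration maps (linear OD
inversion), segment cells per class (smooth, fixed OD threshold,
morphological opening, connected components, size filter), detect TMEM as
any (tumor, macrophage, endothelial) triple whose masks are pairwise
within the contact radius, and score the slide as the sum of TMEM counts
from the three highest-count fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure, morphology
from skimage.filters import gaussian

from .stains import DEFAULT_BASIS, StainBasis
from .slide_sim import CELL_CLASSES, CHROMOGEN_OF_CLASS, FieldImage

__all__ = [
    "ChannelStack",
    "CellObject",
    "DetectionParams",
    "TMEMSite",
    "MetaSiteResult",
    "unmix_field",
    "detect_cells",
    "detect_tmem",
    "score_slide",
    "score_fields",
    "score_image_set",
]


@dataclass
class ChannelStack:
    """Unmixed per-pixel chromogen concentrations (OD units).

    Channel order blue/CD31, brown/CD68, red/Mena.  Negative unmixed
    values are clipped to zero; the number of clipped pixels is kept as a
    QC counter.
    """

    concentrations: np.ndarray      # (H, W, 3)
    n_clipped: int
    microns_per_pixel: float = 0.5

    def channel(self, cell_class: str) -> np.ndarray:
        return self.concentrations[..., CHROMOGEN_OF_CLASS[cell_class]]


@dataclass
class CellObject:
    cell_class: str
    coords: np.ndarray              # (n_px, 2) array of (row, col)
    centroid: tuple[float, float]   # (x, y) in px
    area_um2: float
    mean_intensity: float


@dataclass(frozen=True)
class TMEMSite:
    """One detected triple-contact structure (ids index the class lists)."""

    tumor_id: int
    macrophage_id: int
    endothelial_id: int
    location_px: tuple[float, float]
    field_id: str = ""


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation and contact parameters (lengths in microns, OD units)."""

    threshold: float = 0.25
    smoothing_sd_um: float = 0.75
    min_area_um2: dict | float = 10.0
    opening_radius_px: int = 1
    contact_radius_um: float = 2.0

    def min_area_for(self, cell_class: str) -> float:
        if isinstance(self.min_area_um2, dict):
            return float(self.min_area_um2[cell_class])
        return float(self.min_area_um2)


@dataclass
class MetaSiteResult:
    """Per-field counts, field ranking and the top-3 MetaSite score."""

    per_field_counts: dict
    ranked_fields: list
    score: int
    qc: dict = field(default_factory=dict)
    sites: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"field_id": list(self.per_field_counts),
             "n_tmem": list(self.per_field_counts.values())})


def unmix_field(image: np.ndarray, basis: StainBasis = DEFAULT_BASIS,
                microns_per_pixel: float = 0.5) -> ChannelStack:
    """Invert the Beer-Lambert mix: OD = -log((I+1)/256), c = OD @ B^-1.

    Accepts an 8-bit RGB image or a float image on the same 0-255 scale
    (the exact transmission produced by the synthetic renderer).  Pixels
    saturated at 0 intensity take the OD of the 1/256 floor by
    construction of the transform.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    od = -np.log((img.astype(float) + 1.0) / 256.0)
    conc = od @ basis.inverse
    n_clipped = int(np.count_nonzero(conc < 0))
    return ChannelStack(np.clip(conc, 0.0, None), n_clipped, microns_per_pixel)


def detect_cells(channel: np.ndarray, cell_class: str,
                 params: DetectionParams = DetectionParams(),
                 microns_per_pixel: float = 0.5) -> list[CellObject]:
    """Segment one chromogen channel into cell objects.

    Gaussian smoothing, fixed threshold in OD units, morphological
    opening, connected components, then a minimum-area filter.
    """
    if params.threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    sigma_px = params.smoothing_sd_um / microns_per_pixel
    smooth = gaussian(channel, sigma=sigma_px, preserve_range=True)
    binary = smooth > params.threshold
    if params.opening_radius_px > 0:
        binary = morphology.opening(
            binary, morphology.disk(params.opening_radius_px))
    labels = measure.label(binary, connectivity=2)
    min_area_px = params.min_area_for(cell_class) / microns_per_pixel ** 2
    out = []
    for region in measure.regionprops(labels, intensity_image=channel):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid
        out.append(CellObject(
            cell_class=cell_class,
            coords=region.coords,
            centroid=(cx, cy),
            area_um2=float(region.area) * microns_per_pixel ** 2,
            mean_intensity=float(region.intensity_mean),
        ))
    return out


def _masks_in_contact(a: CellObject, b: CellObject, radius_px: float) -> bool:
    """True if the two pixel masks come within ``radius_px`` of each other."""
    # bounding-box prefilter before the exact nearest-pixel query
    amin, amax = a.coords.min(0), a.coords.max(0)
    bmin, bmax = b.coords.min(0), b.coords.max(0)
    if np.any(bmin - amax > radius_px) or np.any(amin - bmax > radius_px):
        return False
    d, _ = cKDTree(a.coords).query(b.coords, k=1,
                                   distance_upper_bound=radius_px + 1e-9)
    return bool(np.any(np.isfinite(d)))


def detect_tmem(cells_by_class: dict, contact_radius_um: float = 2.0,
                microns_per_pixel: float = 0.5, field_id: str = "",
                merge_shared_pairs: bool = False) -> list[TMEMSite]:
    """Enumerate TMEM: triples with all three pairwise mask contacts.

    Every distinct qualifying (tumor, macrophage, endothelial) triple is
    returned once.  With ``merge_shared_pairs`` triples sharing at least
    two member cells are merged into a single reported site (cluster
    mode).
    """
    if contact_radius_um <= 0:
        raise ValueError("contact radius must be positive")
    r_px = contact_radius_um / microns_per_pixel
    tumors = cells_by_class.get("tumor", [])
    macs = cells_by_class.get("macrophage", [])
    endos = cells_by_class.get("endothelial", [])

    def contact_matrix(xs, ys):
        return np.array([[_masks_in_contact(x, y, r_px) for y in ys]
                         for x in xs], dtype=bool).reshape(len(xs), len(ys))

    tm = contact_matrix(tumors, macs)
    te = contact_matrix(tumors, endos)
    me = contact_matrix(macs, endos)
    sites = []
    for i in range(len(tumors)):
        for j in range(len(macs)):
            if not tm[i, j]:
                continue
            for k in range(len(endos)):
                if te[i, k] and me[j, k]:
                    loc = np.mean([tumors[i].centroid, macs[j].centroid,
                                   endos[k].centroid], axis=0)
                    sites.append(TMEMSite(i, j, k, tuple(loc), field_id))
    if merge_shared_pairs:
        sites = _merge_clusters(sites)
    return sites


def _merge_clusters(sites: list[TMEMSite]) -> list[TMEMSite]:
    """Union triples sharing >= 2 member cells; keep one site per cluster."""
    parent = list(range(len(sites)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def shared(a, b):
        return ((a.tumor_id == b.tumor_id) + (a.macrophage_id == b.macrophage_id)
                + (a.endothelial_id == b.endothelial_id))

    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            if shared(sites[i], sites[j]) >= 2:
                parent[find(i)] = find(j)
    keep = {}
    for i, s in enumerate(sites):
        keep.setdefault(find(i), s)
    return list(keep.values())


def score_slide(per_field_counts, field_ids=None) -> MetaSiteResult:
    """MetaSite score: sum of the three largest per-field TMEM counts.

    With fewer than three fields all counts are summed.  Field ranking ties
    break by field id (the sum is unaffected).
    """
    counts = list(per_field_counts)
    if len(counts) == 0:
        raise ValueError("at least one field is required")
    if field_ids is None:
        field_ids = [f"field_{i:03d}" for i in range(len(counts))]
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], field_ids[i]))
    score = int(sum(counts[i] for i in order[:3]))
    return MetaSiteResult(
        per_field_counts=dict(zip(field_ids, counts)),
        ranked_fields=[field_ids[i] for i in order],
        score=score,
    )


def count_field(image, basis: StainBasis = DEFAULT_BASIS,
                params: DetectionParams = DetectionParams(),
                microns_per_pixel: float = 0.5, field_id: str = ""):
    """Run unmix -> segment x3 -> TMEM detection on one field image."""
    stack = unmix_field(image, basis, microns_per_pixel)
    cells = {cls: detect_cells(stack.channel(cls), cls, params,
                               microns_per_pixel)
             for cls in CELL_CLASSES}
    sites = detect_tmem(cells, params.contact_radius_um, microns_per_pixel,
                        field_id)
    qc = {"n_clipped_px": stack.n_clipped,
          **{f"n_{cls}": len(cells[cls]) for cls in CELL_CLASSES}}
    return sites, cells, qc


def score_fields(images, basis: StainBasis = DEFAULT_BASIS,
                 params: DetectionParams = DetectionParams(),
                 microns_per_pixel: float = 0.5,
                 field_ids=None) -> MetaSiteResult:
    """Score a slide given in-memory field images (arrays or FieldImage)."""
    images = list(images)
    if field_ids is None:
        field_ids = [f"field_{i:03d}" for i in range(len(images))]
    counts, qcs, all_sites = [], {}, []
    for fid, img in zip(field_ids, images):
        arr = img.rgb if isinstance(img, FieldImage) else np.asarray(img)
        mpp = img.microns_per_pixel if isinstance(img, FieldImage) else microns_per_pixel
        sites, _, qc = count_field(arr, basis, params, mpp, fid)
        counts.append(len(sites))
        qcs[fid] = qc
        all_sites.extend(sites)
    result = score_slide(counts, field_ids)
    result.qc = qcs
    result.sites = all_sites
    return result


def score_image_set(manifest, image_dir=None,
                    basis: StainBasis = DEFAULT_BASIS,
                    params: DetectionParams = DetectionParams(),
                    microns_per_pixel: float = 0.5) -> MetaSiteResult:
    """Score a slide from a manifest CSV/DataFrame (field_id, file)."""
    import imageio.v3 as iio

    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        image_dir = mpath.parent if image_dir is None else Path(image_dir)
        manifest = pd.read_csv(mpath)
    elif image_dir is None:
        image_dir = Path(".")
    images, ids = [], []
    shape = None
    for _, row in manifest.iterrows():
        path = Path(image_dir) / row["file"]
        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise IOError(f"cannot read field {row['field_id']!r} "
                          f"({path}): {exc}") from exc
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"field {row['field_id']!r} is not RGB")
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"field {row['field_id']!r} has shape {arr.shape}, "
                f"expected {shape}")
        images.append(arr)
        ids.append(str(row["field_id"]))
    return score_fields(images, basis, params, microns_per_pixel, ids)
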