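"""Per-well object identification for microwell montage images.

One embryo-model structure sits in each occupied microwell, so segmentation is
deliberately simple and deterministic: a weighted channel sum is smoothed,
globally thresholded (Otsu by default), hole-filled, connected-component
labeled and size-filtered.  No declumping/watershed is performed — the
microwell geometry guarantees one aggregate per well (documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border

from morphoscreen.phantoms import CHANNELS, SceneConfig


@dataclass
class SegmentationParams:
    """Detection parameters; diameters are in µm and converted via pixel_size.

    Gata6 is excluded from the default detection weights so that EB-like and
    amorphous-XEn classes (dim or absent ring signal) segment identically to
    ring-bearing classes: structures are defined by cell mass (nuclei) plus
    cortical actin.
    """

    channel_weights: dict[str, float] = field(
        default_factory=lambda: {"nuclei": 0.5, "actin": 0.5}
    )
    smooth_sigma_um: float = 3.2
    threshold_method: str = "otsu"
    min_diameter_um: float = 40.0
    max_diameter_um: float = 200.0
    exclude_border: bool = False


@dataclass
class SegmentedObject:
    object_id: int
    centroid: tuple[float, float]  # (row, col), pixel units
    bbox: tuple[int, int, int, int]
    pixel_count: int
    microwell_index: int | None = None
    duplicate: bool = False


@dataclass
class LabeledObjects:
    """Label mask (0 = background, labels consecutive from 1) + object table."""

    label_image: np.ndarray
    objects: list[SegmentedObject]

    def __len__(self) -> int:
        return len(self.objects)


def segment_montage(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size: float = 0.8,
    channel_names: tuple[str, ...] = CHANNELS,
) -> LabeledObjects:
    """Identify embryo-model structures in a (C, H, W) montage.

    Pipeline: weighted channel sum -> Gaussian smoothing -> global threshold
    (Otsu) -> hole filling -> connected components -> equivalent-diameter size
    filter -> optional border exclusion.  Deterministic.  An empty image yields
    an empty object list; non-finite pixels raise ValueError.
    """
    params = params or SegmentationParams()
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError("expected a (channels, H, W) image")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite pixels")

    combined = np.zeros(image.shape[1:], dtype=np.float64)
    for name, w in params.channel_weights.items():
        try:
            ci = channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present in image") from None
        combined += w * image[ci].astype(np.float64)

    sigma_px = params.smooth_sigma_um / pixel_size
    smoothed = ndi.gaussian_filter(combined, sigma_px)

    if params.threshold_method != "otsu":
        raise ValueError(f"unknown threshold_method {params.threshold_method!r}")
    if smoothed.max() == smoothed.min():
        return LabeledObjects(np.zeros(smoothed.shape, dtype=np.int32), [])
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    # degenerate-blank guard: fluorescent foreground is far brighter than
    # background; if Otsu only split the noise floor, report an empty image
    if mask.any() and mask.mean() < 1.0 and \
            smoothed[mask].mean() < 1.5 * smoothed[~mask].mean():
        return LabeledObjects(np.zeros(smoothed.shape, dtype=np.int32), [])
    mask = ndi.binary_fill_holes(mask)
    if params.exclude_border:
        mask = clear_border(mask)

    labels, _ = ndi.label(mask)
    min_area_px = np.pi / 4 * (params.min_diameter_um / pixel_size) ** 2
    max_area_px = np.pi / 4 * (params.max_diameter_um / pixel_size) ** 2

    out = np.zeros_like(labels, dtype=np.int32)
    objects: list[SegmentedObject] = []
    next_id = 1
    for rp in regionprops(labels):
        if not (min_area_px <= rp.area <= max_area_px):
            continue
        out[labels == rp.label] = next_id
        objects.append(
            SegmentedObject(
                object_id=next_id,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                bbox=tuple(int(v) for v in rp.bbox),
                pixel_count=int(rp.area),
            )
        )
        next_id += 1
    return LabeledObjects(out, objects)


def assign_microwells(labeled: LabeledObjects, scene: SceneConfig) -> LabeledObjects:
    """Assign each object to its nearest microwell center.

    At most one object per microwell is retained as primary (largest pixel
    count wins; area ties resolve to the lower label); the rest are flagged
    ``duplicate``.
    """
    centers = scene.microwell_centers()
    claimed: dict[int, SegmentedObject] = {}
    for obj in labeled.objects:
        d = np.hypot(centers[:, 0] - obj.centroid[0], centers[:, 1] - obj.centroid[1])
        widx = int(np.argmin(d))
        obj.microwell_index = widx
        obj.duplicate = False
        prev = claimed.get(widx)
        if prev is None:
            claimed[widx] = obj
        elif (obj.pixel_count, -obj.object_id) > (prev.pixel_count, -prev.object_id):
            prev.duplicate = True
            claimed[widx] = obj
        else:
            obj.duplicate = True
    return labeled
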