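"""Per-object morphometric features and morphotoxicity measurements.

Feature families mirror a high-content-screening profiling pipeline:

* area/size/shape (area, perimeter, form factor 4πA/P², eccentricity,
  solidity, extent, axis lengths),
* Zernike shape moments of the binary silhouette up to order 9,
* per-channel intensity statistics,
* radial intensity distribution in 4 edge-distance bins with the per-bin
  angular-wedge coefficient of variation (RadialCV),
* 13 Haralick statistics from a gray-level co-occurrence matrix,

plus two bespoke morphotoxicity measurements:

* ``measure_delamination`` — the annular detachment gap between the Gata6
  ring (XEn) and the nuclei-dense epiblast, as inner-XEn area minus Epi area,
* ``count_cavities`` — number of nuclei-dark lumens inside the Epi.

Feature tables are one row per object with namespaced columns
(``Area_``, ``Shape_``, ``Zernike_n_m``, ``Intensity_<channel>_``,
``Radial_bin<b>_``, ``Texture_<channel>_``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton as _sk_perimeter
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.feature import graycomatrix

from morphoscreen.phantoms import CHANNELS
from morphoscreen.segmentation import LabeledObjects


# --------------------------------------------------------------- area & shape


def measure_area_shape(mask: np.ndarray, pixel_size: float = 1.0) -> dict[str, float]:
    """Area/size/shape statistics of a single binary object mask.

    Area is pixel count x pixel_size²; the perimeter is the 4-direction
    Crofton estimate of the crack-boundary length (unbiased on discs, unlike
    the raw crack-edge count which overestimates circles by ~5%).  The form
    factor 4πA/P² is reported as computed (values slightly above 1 can occur
    from boundary discretization on near-circular objects).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    area_px = int(mask.sum())
    perim_px = float(_sk_perimeter(mask, directions=4))
    rp = regionprops(mask.astype(np.uint8))[0]
    area = area_px * pixel_size**2
    perim = perim_px * pixel_size
    form_factor = 4 * np.pi * area / perim**2 if perim > 0 else np.nan
    return {
        "Area_um2": area,
        "Shape_Perimeter": perim,
        "Shape_FormFactor": float(form_factor),
        "Shape_Eccentricity": float(rp.eccentricity),
        "Shape_Solidity": float(rp.solidity),
        "Shape_Extent": float(rp.extent),
        "Shape_MajorAxis": float(rp.axis_major_length) * pixel_size,
        "Shape_MinorAxis": float(rp.axis_minor_length) * pixel_size,
    }


# ------------------------------------------------------------------- Zernike


def zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial Zernike polynomial R_nm(rho) via the factorial sum."""
    out = np.zeros_like(rho, dtype=np.float64)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_indices(max_order: int = 9) -> list[tuple[int, int]]:
    """(n, m) pairs with n <= max_order, m >= 0, n - m even (30 for order 9)."""
    return [(n, m) for n in range(max_order + 1) for m in range(n % 2, n + 1, 2)]


def measure_zernike(mask: np.ndarray, max_order: int = 9) -> dict[str, float]:
    """Magnitudes of Zernike moments of the binary silhouette on the unit disc.

    The disc is the circumscribing circle centered at the mask centroid; the
    mask is normalized to unit total mass, so magnitudes are translation-
    invariant by construction and rotation-invariant up to discretization.
    A_nm = (n+1)/π · Σ_px f(px) R_nm(ρ) e^{-imθ}.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty object mask")
    idx = zernike_indices(max_order)
    rows, cols = np.nonzero(mask)
    n_px = rows.size
    if n_px == 1:
        return {f"Zernike_{n}_{m}": (1.0 / np.pi if (n, m) == (0, 0) else 0.0)
                for n, m in idx}
    cy, cx = rows.mean(), cols.mean()
    dy = rows - cy
    dx = cols - cx
    radius = np.sqrt(dy**2 + dx**2).max()
    rho = np.sqrt(dy**2 + dx**2) / radius
    theta = np.arctan2(dy, dx)
    f = 1.0 / n_px
    # precompute powers of rho once: R_nm only needs rho^0..rho^max_order
    powers = {k: rho**k for k in range(max_order + 1)}
    out: dict[str, float] = {}
    for n, m in idx:
        rad = np.zeros_like(rho)
        for s in range((n - m) // 2 + 1):
            c = ((-1) ** s * math.factorial(n - s)
                 / (math.factorial(s)
                    * math.factorial((n + m) // 2 - s)
                    * math.factorial((n - m) // 2 - s)))
            rad += c * powers[n - 2 * s]
        ang = np.exp(-1j * m * theta)
        a = (n + 1) / np.pi * f * np.sum(rad * ang)
        out[f"Zernike_{n}_{m}"] = float(abs(a))
    return out


# ----------------------------------------------------------------- intensity


def measure_intensity(mask: np.ndarray, image: np.ndarray,
                      channel: str = "") -> dict[str, float]:
    """Integrated / mean / sd / min / max intensity over the object mask."""
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(image, dtype=np.float64)[mask]
    prefix = f"Intensity_{channel}_" if channel else "Intensity_"
    if vals.size == 0:
        return {prefix + k: np.nan for k in ("Integrated", "Mean", "SD", "Min", "Max")}
    return {
        prefix + "Integrated": float(vals.sum()),
        prefix + "Mean": float(vals.mean()),
        prefix + "SD": float(vals.std()),
        prefix + "Min": float(vals.min()),
        prefix + "Max": float(vals.max()),
    }


# --------------------------------------------------- radial distribution / CV


def radial_bin_image(mask: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Bin index per object pixel (0-based, bin 0 innermost, -1 outside).

    Normalized distance is the distance-to-edge transform scaled per object:
    d = 1 - edt/edt_max, robust to irregular outlines (not concentric circles).
    """
    mask = np.asarray(mask, dtype=bool)
    edt = ndi.distance_transform_edt(mask)
    dmax = edt.max()
    if dmax <= 0:
        raise ValueError("object has no interior")
    d = 1.0 - edt / dmax
    bins = np.clip((d * n_bins).astype(int), 0, n_bins - 1)
    bins[~mask] = -1
    return bins


def wedge_image(mask: np.ndarray, n_wedges: int = 8) -> np.ndarray:
    """Equal angular sectors about the mask centroid (0-based, -1 outside)."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
    theta = np.arctan2(yy - cy, xx - cx)  # [-pi, pi)
    w = np.floor((theta + np.pi) / (2 * np.pi / n_wedges)).astype(int) % n_wedges
    w[~mask] = -1
    return w


def measure_radial_distribution(
    mask: np.ndarray,
    image: np.ndarray,
    n_bins: int = 4,
    n_wedges: int = 8,
    channel: str = "",
) -> dict[str, float]:
    """Radial intensity distribution in ``n_bins`` edge-distance bins.

    Per bin b (1 = innermost):

    * ``FracAtD``  — fraction of total object intensity falling in the bin,
    * ``MeanFrac`` — FracAtD normalized by the bin's pixel fraction
      (1 for a uniform image),
    * ``RadialCV`` — coefficient of variation of the mean intensity of the
      ``n_wedges`` angular sectors within the bin (pixel-count-normalized,
      so a uniform image gives 0 regardless of outline shape).

    Zero total intensity returns NaNs (flagged missing).
    """
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(image, dtype=np.float64)
    bins = radial_bin_image(mask, n_bins)
    wedges = wedge_image(mask, n_wedges)
    total = img[mask].sum()
    npx = mask.sum()
    suffix = f"_{channel}" if channel else ""
    out: dict[str, float] = {}
    for b in range(n_bins):
        sel = bins == b
        key = f"Radial_bin{b + 1}"
        if total <= 0 or not sel.any():
            out[f"{key}_FracAtD{suffix}"] = np.nan
            out[f"{key}_MeanFrac{suffix}"] = np.nan
            out[f"{key}_RadialCV{suffix}"] = np.nan
            continue
        frac = img[sel].sum() / total
        pix_frac = sel.sum() / npx
        out[f"{key}_FracAtD{suffix}"] = float(frac)
        out[f"{key}_MeanFrac{suffix}"] = float(frac / pix_frac)
        means = []
        for w in range(n_wedges):
            ws = sel & (wedges == w)
            if ws.any():
                means.append(img[ws].mean())
        means = np.asarray(means)
        mu = means.mean()
        out[f"{key}_RadialCV{suffix}"] = float(means.std() / mu) if mu > 0 else np.nan
    return out


# ------------------------------------------------------------------- texture

HARALICK_NAMES = (
    "ASM", "Contrast", "Correlation", "Variance", "IDM", "SumAverage",
    "SumVariance", "SumEntropy", "Entropy", "DifferenceVariance",
    "DifferenceEntropy", "IMC1", "IMC2",
)


def quantize_object(mask: np.ndarray, image: np.ndarray, levels: int = 8) -> np.ndarray:
    """Quantize object pixels to 1..levels over the per-object intensity range;
    background is 0 (excluded from co-occurrence counting)."""
    mask = np.asarray(mask, dtype=bool)
    img = np.asarray(image, dtype=np.float64)
    q = np.zeros(mask.shape, dtype=np.uint8)
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q[mask] = np.minimum(((img[mask] - lo) / (hi - lo) * levels).astype(int),
                             levels - 1) + 1
    else:
        q[mask] = 1
    return q


def haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics from a normalized co-occurrence matrix.

    Natural logarithms; the sum-variance statistic is centered on the sum
    average.  Correlation is NaN for a constant-intensity object (zero
    marginal variance).
    """
    eps = 1e-12
    L = P.shape[0]
    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    p_sum = np.zeros(2 * L + 1)  # index k = i + j, 2..2L
    p_diff = np.zeros(L)  # index k = |i - j|, 0..L-1
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * L + 1)
    k_diff = np.arange(L)

    asm = float((P**2).sum())
    contrast = float((k_diff**2 * p_diff).sum())
    if sd_x > eps and sd_y > eps:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = float("nan")
    variance = float(((ii - mu_x) ** 2 * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    sum_ent = float(-(p_sum[p_sum > 0] * np.log(p_sum[p_sum > 0])).sum())
    entropy = float(-(P[P > 0] * np.log(P[P > 0])).sum())
    diff_var = float(((k_diff - (k_diff * p_diff).sum()) ** 2 * p_diff).sum())
    diff_ent = float(-(p_diff[p_diff > 0] * np.log(p_diff[p_diff > 0])).sum())

    pxpy = np.outer(px, py)
    hxy = entropy
    nz = pxpy > 0
    hxy1 = float(-(P[nz] * np.log(pxpy[nz])).sum())
    hxy2 = float(-(pxpy[nz] * np.log(pxpy[nz])).sum())
    hx = float(-(px[px > 0] * np.log(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log(py[py > 0])).sum())
    denom = max(hx, hy)
    imc1 = float((hxy - hxy1) / denom) if denom > eps else float("nan")
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    return dict(zip(HARALICK_NAMES, (
        asm, contrast, correlation, variance, idm, sum_avg, sum_var,
        sum_ent, entropy, diff_var, diff_ent, imc1, imc2)))


def measure_texture(mask: np.ndarray, image: np.ndarray, scale: int = 3,
                    levels: int = 8, channel: str = "") -> dict[str, float]:
    """13 Haralick statistics at pixel offset ``scale``, averaged over the four
    standard directions; 8-level quantization over the per-object range."""
    q = quantize_object(mask, image, levels)
    glcm = graycomatrix(q, distances=[scale],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels + 1, symmetric=True, normed=False)
    prefix = f"Texture_{channel}_" if channel else "Texture_"
    per_dir = []
    for a in range(4):
        P = glcm[1:, 1:, 0, a].astype(np.float64)  # drop background row/col
        tot = P.sum()
        if tot == 0:
            continue
        per_dir.append(haralick_from_glcm(P / tot))
    if not per_dir:
        return {prefix + n: np.nan for n in HARALICK_NAMES}
    out = {}
    for n in HARALICK_NAMES:
        vals = np.array([d[n] for d in per_dir], dtype=float)
        out[prefix + n] = float(np.nanmean(vals)) if not np.isnan(vals).all() else np.nan
    return out


# ------------------------------------------- compartments: delamination, cavities


@dataclass
class CompartmentMeasures:
    """Ring/Epi compartment geometry of one object (NaN fields when no
    Gata6 ring is detected, e.g. EB-like and amorphous classes)."""

    object_id: int
    applicable: bool
    inner_xen_area: float = float("nan")  # µm²
    epi_area: float = float("nan")  # µm²
    delamination_area: float = float("nan")  # µm², floored at 0
    cavity_count: int = -1  # -1 = not applicable
    caspase_integrated: float = float("nan")
    caspase_radial_cv: tuple[float, float, float, float] = (
        float("nan"),) * 4  # type: ignore[assignment]


#: pre-threshold smoothing (px) applied to channel crops before compartment
#: detection; suppresses cell-scale granularity without moving boundaries
_COMPARTMENT_SMOOTH_PX = 1.5


def _background(img: np.ndarray, mask: np.ndarray) -> float:
    """Robust background estimate from pixels outside the object mask."""
    outside = np.asarray(img, dtype=np.float64)[~mask]
    if outside.size >= 20:
        return float(np.median(outside))
    return float(np.percentile(np.asarray(img, dtype=np.float64), 5))


def _largest_component(binary: np.ndarray):
    lab, n = ndi.label(binary)
    if n == 0:
        return None
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def _find_ring_interior(mask: np.ndarray, gata6: np.ndarray,
                        pixel_size: float, closing_radius_um: float = 4.0,
                        min_inner_area_um2: float = 500.0,
                        min_boundary_coverage: float = 0.5):
    """Detect the Gata6-bright XEn ring within an object and return the region
    enclosed by its inner contour, or None when no ring is found.

    The ring threshold is referenced to the image background (half-way to the
    95th-percentile Gata6 signal): Otsu within the object would hallucinate a
    ring on uniformly Gata6-bright (amorphous) blobs.  A detected ring must
    additionally hug most of the object's outer boundary — chains of scattered
    Gata6-positive cells (EB-like) do not qualify.
    """
    mask = np.asarray(mask, dtype=bool)
    g = ndi.gaussian_filter(np.asarray(gata6, dtype=np.float64),
                            _COMPARTMENT_SMOOTH_PX)
    vals = g[mask]
    if vals.size == 0:
        return None
    bg = _background(gata6, mask)
    peak = float(np.percentile(vals, 95))
    if peak <= 2 * max(bg, 1.0):
        return None  # no Gata6 signal at all
    thr = bg + 0.5 * (peak - bg)
    ring = mask & (g >= thr)
    r_px = max(int(round(closing_radius_um / pixel_size)), 1)
    ring = ndi.binary_closing(ring, structure=disk(r_px))
    ring &= mask
    ring_main = _largest_component(ring)
    if ring_main is None:
        return None
    # ring must cover most of the object's outer boundary
    boundary = mask & ~ndi.binary_erosion(mask)
    near_ring = ndi.binary_dilation(ring_main, structure=disk(2))
    if boundary.sum() == 0 or \
            (boundary & near_ring).sum() / boundary.sum() < min_boundary_coverage:
        return None
    filled = ndi.binary_fill_holes(ring_main)
    interior = filled & ~ring_main
    if interior.sum() * pixel_size**2 < min_inner_area_um2:
        return None
    return interior


def _find_epi(interior: np.ndarray, nuclei: np.ndarray, mask: np.ndarray):
    """Largest nuclei-bright component inside the ring interior, hole-filled
    (cavities are internal lumens and count as part of the Epi outline).

    The nuclei threshold is referenced to the image background rather than
    fit by Otsu: an interior without lumens is unimodal and Otsu would split
    the Epi's own intensity granularity in half.  The 0.35 relative threshold
    is the bias-calibrated edge estimate for the rendering model's blur scale
    (see docs/methods.md); half-max systematically shrinks the Epi here
    because the 95th-percentile reference overshoots the mean plateau level.
    """
    interior = np.asarray(interior, dtype=bool)
    nsm = ndi.gaussian_filter(np.asarray(nuclei, dtype=np.float64),
                              _COMPARTMENT_SMOOTH_PX)
    nvals = nsm[interior]
    if nvals.size == 0:
        return None, None
    bg = _background(nuclei, np.asarray(mask, dtype=bool))
    peak = float(np.percentile(nvals, 95))
    if peak <= 2 * max(bg, 1.0):
        return None, None  # no nuclei-bright Epi inside the ring
    thr = bg + 0.35 * (peak - bg)
    epi_px = interior & (nsm >= thr)
    comp = _largest_component(epi_px)
    if comp is None:
        return None, None
    filled = ndi.binary_fill_holes(comp)
    return comp, filled


def measure_delamination(
    mask: np.ndarray,
    gata6: np.ndarray,
    nuclei: np.ndarray,
    pixel_size: float,
    object_id: int = 0,
    min_cavity_area_um2: float = 50.0,
) -> CompartmentMeasures:
    """Delamination area = area enclosed by the XEn ring's inner contour minus
    the (hole-filled) Epi area, floored at 0; plus the cavity count of the Epi.

    Objects without a detectable Gata6 ring (EB-like, amorphous XEn) are
    returned with ``applicable=False``.
    """
    interior = _find_ring_interior(mask, gata6, pixel_size)
    if interior is None:
        return CompartmentMeasures(object_id=object_id, applicable=False)
    comp, filled = _find_epi(interior, nuclei, np.asarray(mask, dtype=bool))
    inner_area = float(interior.sum()) * pixel_size**2
    if filled is None:
        return CompartmentMeasures(
            object_id=object_id, applicable=True,
            inner_xen_area=inner_area, epi_area=0.0,
            delamination_area=inner_area, cavity_count=0,
        )
    epi_area = float(filled.sum()) * pixel_size**2
    delam = max(inner_area - epi_area, 0.0)
    cav = _count_holes(comp, filled, pixel_size, min_cavity_area_um2)
    return CompartmentMeasures(
        object_id=object_id, applicable=True,
        inner_xen_area=inner_area, epi_area=epi_area,
        delamination_area=delam, cavity_count=cav,
    )


def _count_holes(comp: np.ndarray, filled: np.ndarray, pixel_size: float,
                 min_area_um2: float) -> int:
    holes = filled & ~comp
    lab, n = ndi.label(holes)
    if n == 0:
        return 0
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return int((sizes * pixel_size**2 >= min_area_um2).sum())


def count_cavities(
    mask: np.ndarray,
    nuclei: np.ndarray,
    actin: np.ndarray,
    pixel_size: float,
    gata6: np.ndarray | None = None,
    min_cavity_area_um2: float = 50.0,
) -> int:
    """Number of nuclei-dark lumens (area >= ``min_cavity_area_um2``) inside
    the Epi compartment; -1 when no Epi region can be identified.

    The Epi is found inside the Gata6 ring interior when a ``gata6`` channel is
    given, otherwise inside the whole object mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if gata6 is not None:
        interior = _find_ring_interior(mask, gata6, pixel_size)
        if interior is None:
            return -1
    else:
        interior = mask
    comp, filled = _find_epi(interior, nuclei, mask)
    if comp is None:
        return -1
    return _count_holes(comp, filled, pixel_size, min_cavity_area_um2)


# ------------------------------------------------------------ table assembly


def measure_object(
    mask: np.ndarray,
    channels: dict[str, np.ndarray],
    pixel_size: float,
    max_zernike_order: int = 9,
    texture_scale: int = 3,
    radial_channels: tuple[str, ...] | None = None,
    texture_channels: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """The full feature vector of one object (all families, all channels)."""
    row: dict[str, float] = {}
    row.update(measure_area_shape(mask, pixel_size))
    row.update(measure_zernike(mask, max_zernike_order))
    for name, img in channels.items():
        row.update(measure_intensity(mask, img, channel=name))
    for name in radial_channels or tuple(channels):
        row.update(measure_radial_distribution(mask, channels[name], channel=name))
    for name in texture_channels or tuple(channels):
        row.update(measure_texture(mask, channels[name], scale=texture_scale,
                                   channel=name))
    return row


def measure_objects(
    labeled: LabeledObjects,
    image: np.ndarray,
    pixel_size: float,
    channel_names: tuple[str, ...] = CHANNELS,
    compartments: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table + compartment table for every segmented object.

    Images are cropped to each object's bounding box (padded by the texture
    offset) before measurement.  Returns ``(features, compartments)`` frames
    indexed by object_id.
    """
    image = np.asarray(image)
    chan = {name: image[i] for i, name in enumerate(channel_names)}
    feat_rows = []
    comp_rows = []
    pad = 4
    for obj in labeled.objects:
        r0, c0, r1, c1 = obj.bbox
        r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
        r1 = min(r1 + pad, labeled.label_image.shape[0])
        c1 = min(c1 + pad, labeled.label_image.shape[1])
        mask = labeled.label_image[r0:r1, c0:c1] == obj.object_id
        crops = {k: v[r0:r1, c0:c1] for k, v in chan.items()}
        row = {"object_id": obj.object_id}
        row.update(measure_object(mask, crops, pixel_size))
        feat_rows.append(row)
        if compartments and "gata6" in crops and "nuclei" in crops:
            cm = measure_delamination(mask, crops["gata6"], crops["nuclei"],
                                      pixel_size, object_id=obj.object_id)
            if cm.applicable and "caspase" in crops:
                cm.caspase_integrated = float(
                    np.asarray(crops["caspase"], dtype=np.float64)[mask].sum())
                rad = measure_radial_distribution(mask, crops["caspase"])
                cm.caspase_radial_cv = tuple(
                    rad[f"Radial_bin{b}_RadialCV"] for b in range(1, 5))
            comp_rows.append({
                "object_id": cm.object_id,
                "applicable": cm.applicable,
                "inner_xen_area": cm.inner_xen_area,
                "epi_area": cm.epi_area,
                "delamination_area": cm.delamination_area,
                "cavity_count": cm.cavity_count,
                "caspase_integrated": cm.caspase_integrated,
                **{f"caspase_radial_cv_bin{b + 1}": v
                   for b, v in enumerate(cm.caspase_radial_cv)},
            })
    features = pd.DataFrame(feat_rows)
    comps = pd.DataFrame(comp_rows)
    return features, comps
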