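"""Ground-truthed synthetic fluorescence phantoms of microwell embryo-model screens.

Each rendered structure emulates the projected 2D fluorescence appearance of a
stem-cell-based embryo model sitting in a 300 µm microwell, imaged in up to four
channels: nuclei (Hoechst), a Gata6 reporter marking extraembryonic endoderm
(XEn), F-actin (phalloidin), and optionally cleaved Caspase-3/7.

Five phenotype classes span the developmental continuum:

* ``XEnEpiC`` — terminal phenotype: Gata6-bright epithelialized XEn ring
  enclosing a nuclei-dense epiblast (Epi) disc with a single central,
  nuclei-dark, actin-rimmed pro-amniotic cavity (PAC).
* ``XEnEpiRosette`` — ring + Epi disc with a central actin focus, no open
  cavity yet.
* ``XEnNonPolarizedEpi`` — ring + uniform (non-polarized) Epi; may carry
  zero or several dispersed nuclei-dark cavities (a retinoic-acid-like
  morphotoxic variant).
* ``EBLike`` — embryoid-body-like: no coherent XEn ring, scattered
  Gata6-positive cells among Epi nuclei.
* ``AmorphousXEn`` — irregular Gata6-bright blob without an Epi compartment.

Morphotoxic variants are parameterized directly: ``delamination_gap_area``
renders a background-level annular gap between the XEn ring and the Epi mass,
``cavity_count``/``cavity_area_fraction`` control dispersed lumens, and
per-structure channel levels plus a 4-bin radial Caspase profile emulate
compartment-localized cell death.

Every rendered structure carries a :class:`StructureGroundTruth` row so the
downstream segmentation, morphometrics, classification and screen-statistics
stages can be validated without any external imaging data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage as ndi


class Phenotype(str, Enum):
    """The five embryo-model morphology classes."""

    XEN_EPIC = "XEnEpiC"
    XEN_EPI_ROSETTE = "XEnEpiRosette"
    XEN_NONPOLARIZED_EPI = "XEnNonPolarizedEpi"
    EB_LIKE = "EBLike"
    AMORPHOUS_XEN = "AmorphousXEn"


#: Canonical order used for class-mixture vectors.
PHENOTYPES: tuple[Phenotype, ...] = (
    Phenotype.XEN_EPIC,
    Phenotype.XEN_EPI_ROSETTE,
    Phenotype.XEN_NONPOLARIZED_EPI,
    Phenotype.EB_LIKE,
    Phenotype.AMORPHOUS_XEN,
)

#: Classes that possess an Epi compartment (and hence may carry cavities).
EPI_CLASSES = frozenset(
    {Phenotype.XEN_EPIC, Phenotype.XEN_EPI_ROSETTE, Phenotype.XEN_NONPOLARIZED_EPI}
)

#: Channel order of every rendered patch / montage.
CHANNELS: tuple[str, ...] = ("nuclei", "gata6", "actin", "caspase")


@dataclass
class NoiseModel:
    """Additive Gaussian background + intensity-scaled Poisson shot noise.

    ``poisson_scale`` is the photon-count per intensity unit: noisy pixel
    values are ``Poisson(I * poisson_scale) / poisson_scale + N(0, gaussian_sd)``
    so the relative shot noise at intensity I is ``1 / sqrt(I * poisson_scale)``.
    Defaults give an SNR at which the five classes remain separable in
    feature space (nuclei-level signal 3000 -> ~6% shot noise).
    """

    background_level: float = 100.0
    gaussian_sd: float = 12.0
    poisson_scale: float = 0.1


@dataclass
class PhantomSpec:
    """Generative parameters for a single embryo-model structure.

    Areas are in µm² of projected area; ``target_area`` is the area of the
    whole structure silhouette (outer XEn contour, gap included).
    """

    class_label: Phenotype
    target_area: float = 7000.0
    cavity_count: int = 0
    cavity_area_fraction: float = 0.06
    delamination_gap_area: float = 0.0
    xen_ring_thickness: float = 12.0
    channel_levels: dict[str, float] = field(
        default_factory=lambda: dict(nuclei=3000.0, gata6=3000.0, actin=2500.0, caspase=400.0)
    )
    caspase_bin_levels: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    shape_irregularity: float = 0.05
    rotation: float = 0.0

    def validate(self) -> None:
        if self.target_area <= 0:
            raise ValueError("target_area must be positive")
        if self.cavity_count < 0:
            raise ValueError("cavity_count must be >= 0")
        if self.delamination_gap_area < 0:
            raise ValueError("delamination_gap_area must be >= 0")
        if self.cavity_count > 0 and self.class_label not in EPI_CLASSES:
            raise ValueError(
                f"cavities are only defined for classes with an Epi compartment, "
                f"not {self.class_label.value}"
            )
        if self.cavity_count * self.cavity_area_fraction >= 1.0:
            raise ValueError("total cavity area must stay below the Epi area")


@dataclass
class SceneConfig:
    """Imaging scenario: microwell array geometry, optics scale, noise."""

    microwell_diameter: float = 300.0  # µm
    microwell_grid: tuple[int, int] = (15, 11)  # rows x cols per montage
    structures_per_well: int = 165
    pixel_size: float = 0.8  # µm / pixel (20x air objective scale class)
    bit_depth: int = 16
    noise: NoiseModel = field(default_factory=NoiseModel)
    well_pitch_factor: float = 1.2  # center-to-center pitch / diameter

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.structures_per_well > self.microwell_grid[0] * self.microwell_grid[1]:
            raise ValueError("structures_per_well exceeds the microwell grid size")

    @property
    def pitch_px(self) -> float:
        return self.microwell_diameter * self.well_pitch_factor / self.pixel_size

    @property
    def montage_shape(self) -> tuple[int, int]:
        rows, cols = self.microwell_grid
        p = self.pitch_px
        return int(np.ceil(rows * p)), int(np.ceil(cols * p))

    def microwell_centers(self) -> np.ndarray:
        """(n_wells, 2) array of (row, col) pixel centers, row-major order."""
        rows, cols = self.microwell_grid
        p = self.pitch_px
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.stack([(rr.ravel() + 0.5) * p, (cc.ravel() + 0.5) * p], axis=1)


@dataclass
class StructureGroundTruth:
    """Per-structure truth used to validate every downstream stage."""

    well_id: str
    microwell_index: int
    class_label: str
    centroid_row: float
    centroid_col: float
    true_area: float  # µm²
    true_gap_area: float  # µm²
    true_cavity_count: int
    true_caspase_integrated: float
    delaminated: bool


# --- class-specific default generative parameters -------------------------------
# Mean projected areas bracket the 5000-9000 µm² range of real structures;
# control XEn/EpiCs sit at 7000 µm².
CLASS_DEFAULTS: dict[Phenotype, dict] = {
    Phenotype.XEN_EPIC: dict(target_area=7000.0, cavity_count=1, cavity_area_fraction=0.18,
                             shape_irregularity=0.04),
    Phenotype.XEN_EPI_ROSETTE: dict(target_area=6500.0, cavity_count=0,
                                    shape_irregularity=0.05),
    Phenotype.XEN_NONPOLARIZED_EPI: dict(target_area=6500.0, cavity_count=0,
                                         shape_irregularity=0.06),
    Phenotype.EB_LIKE: dict(target_area=5000.0, cavity_count=0, shape_irregularity=0.09),
    Phenotype.AMORPHOUS_XEN: dict(target_area=3500.0, cavity_count=0,
                                  shape_irregularity=0.20),
}


def default_spec(class_label: Phenotype, **overrides) -> PhantomSpec:
    """A PhantomSpec with the class-specific defaults, optionally overridden."""
    params = dict(CLASS_DEFAULTS[class_label])
    params.update(overrides)
    return PhantomSpec(class_label=class_label, **params)


def sample_spec(
    class_label: Phenotype,
    rng: np.random.Generator,
    area_scale: float = 1.0,
    delaminated: bool = False,
    gap_mean: float = 1700.0,
    gap_sd: float = 400.0,
    cavity_count: int | None = None,
    caspase_bin_levels: Sequence[float] | None = None,
    area_cv: float = 0.07,
) -> PhantomSpec:
    """Draw a structure spec with natural biological variability.

    ``area_scale`` models dose-dependent size reduction; ``delaminated`` draws a
    detachment gap from N(gap_mean, gap_sd) truncated at 500 µm² so the gap is
    morphologically real rather than a noise-floor artifact.
    """
    spec = default_spec(class_label)
    area = spec.target_area * area_scale * float(np.clip(rng.normal(1.0, area_cv), 0.7, 1.3))
    gap = 0.0
    if delaminated and class_label in EPI_CLASSES:
        # cap at 55% of the analytic area inside the XEn ring so the Epi
        # remains a real compartment
        r_um = np.sqrt(area / np.pi)
        inner_area = np.pi * max(r_um - spec.xen_ring_thickness, 5.0) ** 2
        gap = float(np.clip(rng.normal(gap_mean, gap_sd), 500.0, 0.55 * inner_area))
    k = spec.cavity_count if cavity_count is None else int(cavity_count)
    # dispersed lumens are smaller the more of them there are (RA-like variants)
    frac = spec.cavity_area_fraction if k <= 1 else min(0.06, 0.18 / k)
    bins = tuple(caspase_bin_levels) if caspase_bin_levels is not None else spec.caspase_bin_levels
    return replace(
        spec,
        target_area=area,
        delamination_gap_area=gap,
        cavity_count=k,
        cavity_area_fraction=frac,
        caspase_bin_levels=bins,
        rotation=float(rng.uniform(0, 2 * np.pi)),
    )


# --- rendering -------------------------------------------------------------------


def _radial_profile(spec: PhantomSpec, rng: np.random.Generator):
    """Low-order (modes 2-6) random radial Fourier perturbation of a circle.

    Returns (R0_px_for_unit_area, amplitudes, phases); the base radius is
    corrected so the analytic area of the perturbed outline equals the target.
    """
    modes = np.arange(2, 7)
    raw = rng.uniform(0.3, 1.0, size=modes.size)
    amps = spec.shape_irregularity * raw / raw.sum()
    phases = rng.uniform(0, 2 * np.pi, size=modes.size) + modes * spec.rotation
    return modes, amps, phases


def _perturbed_radius(theta: np.ndarray, R0: float, modes, amps, phases) -> np.ndarray:
    pert = np.zeros_like(theta)
    for k, a, p in zip(modes, amps, phases):
        pert += a * np.cos(k * theta + p)
    return R0 * (1.0 + pert)


def render_structure(
    spec: PhantomSpec,
    scene: SceneConfig,
    rng: np.random.Generator,
    return_masks: bool = False,
):
    """Render one structure as a noise-free multi-channel patch.

    Returns ``(patch, truth)`` where ``patch`` is a float32 array of shape
    (4, H, W) containing signal plus the constant noise background level
    (so that integrated-intensity ground truth matches raw-image measurements
    in expectation), and ``truth`` is a :class:`StructureGroundTruth` with
    well/microwell fields left blank.  With ``return_masks=True`` a dict of
    compartment masks is appended (structure, ring, gap, epi, cavities).

    Shot/read noise is applied separately by :func:`apply_noise`.
    """
    spec.validate()
    scene.validate()
    ps = scene.pixel_size
    area_px = spec.target_area / ps**2

    modes, amps, phases = _radial_profile(spec, rng)
    # area of r(t)=R0(1+sum a_k cos(...)) is pi R0^2 (1 + 0.5 sum a_k^2)
    R0 = np.sqrt(area_px / (np.pi * (1.0 + 0.5 * np.sum(amps**2))))
    half = int(np.ceil(R0 * (1.0 + amps.sum()) + 4))
    size = 2 * half + 1
    if size * ps > scene.microwell_diameter:
        raise ValueError(
            f"structure of area {spec.target_area:.0f} µm² does not fit in a "
            f"{scene.microwell_diameter:.0f} µm microwell"
        )
    yy, xx = np.mgrid[:size, :size]
    dy = yy - half
    dx = xx - half
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    r_out = _perturbed_radius(theta, R0, modes, amps, phases)
    structure = rho <= r_out

    has_ring = spec.class_label in EPI_CLASSES or spec.class_label is Phenotype.AMORPHOUS_XEN
    ring = np.zeros_like(structure)
    gap = np.zeros_like(structure)
    epi_outer = np.zeros_like(structure)
    cavities = np.zeros_like(structure)
    cavity_count = 0

    if spec.class_label in EPI_CLASSES:
        t_px = max(spec.xen_ring_thickness / ps, 2.0)
        r_in = np.maximum(r_out - t_px, 1.0)
        inner = rho <= r_in
        ring = structure & ~inner
        area_in = int(inner.sum())
        gap_px = spec.delamination_gap_area / ps**2
        if gap_px >= 0.8 * area_in:
            raise ValueError("delamination gap exceeds the space inside the XEn ring")
        s = np.sqrt(max(area_in - gap_px, 0.0) / max(area_in, 1))
        epi_outer = rho <= s * r_in
        gap = inner & ~epi_outer

        if spec.cavity_count > 0:
            epi_area_px = int(epi_outer.sum())
            r_cav = np.sqrt(spec.cavity_area_fraction * epi_area_px / np.pi)
            r_epi_min = s * (R0 * (1.0 - amps.sum()) - t_px)
            centers = _place_cavities(spec, rng, r_epi_min, r_cav)
            for cy, cx in centers:
                cavities |= (yy - (half + cy)) ** 2 + (xx - (half + cx)) ** 2 <= r_cav**2
            cavities &= epi_outer
            cavity_count = spec.cavity_count
    elif spec.class_label is Phenotype.AMORPHOUS_XEN:
        ring = structure  # the whole blob is Gata6-bright XEn

    epi_cell = epi_outer & ~cavities

    patch = np.full((len(CHANNELS), size, size), scene.noise.background_level, dtype=np.float32)
    tex = _granularity(size, rng)
    lv = spec.channel_levels

    nuc = np.zeros((size, size), dtype=np.float32)
    if spec.class_label in EPI_CLASSES:
        nuc[epi_cell] = lv["nuclei"]
        nuc[ring] = 0.6 * lv["nuclei"]  # XEn nuclei are sparser
    elif spec.class_label is Phenotype.EB_LIKE:
        nuc[structure] = 0.9 * lv["nuclei"]
    else:  # amorphous XEn
        nuc[structure] = 0.5 * lv["nuclei"]
    patch[0] += nuc * tex

    gat = np.zeros((size, size), dtype=np.float32)
    if spec.class_label in EPI_CLASSES:
        gat[ring] = lv["gata6"]
        gat[epi_cell] = 0.05 * lv["gata6"]
    elif spec.class_label is Phenotype.AMORPHOUS_XEN:
        gat[structure] = lv["gata6"]
    else:  # EB-like: scattered Gata6+ cells
        n_punct = rng.integers(8, 16)
        for _ in range(n_punct):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.8) * R0
            py, px_ = half + rad * np.sin(ang), half + rad * np.cos(ang)
            gat[((yy - py) ** 2 + (xx - px_) ** 2) <= 4.0**2] = lv["gata6"]
        gat[~structure] = 0.0
    patch[1] += gat * tex

    act = np.zeros((size, size), dtype=np.float32)
    act[structure] = 0.25 * lv["actin"]
    cortex = structure & (rho > r_out - 2.5)
    act[cortex] = lv["actin"]
    if cavities.any():
        rim = ndi.binary_dilation(cavities, iterations=2) & ~cavities & epi_outer
        act[rim] = lv["actin"]
    if spec.class_label is Phenotype.XEN_EPI_ROSETTE:
        act[rho <= 4.0] = 1.2 * lv["actin"]  # apical actin focus at the rosette center
    patch[2] += act * tex

    cas = np.zeros((size, size), dtype=np.float32)
    if structure.any():
        edt = ndi.distance_transform_edt(structure)
        dmax = edt.max()
        dnorm = np.where(structure, 1.0 - edt / max(dmax, 1.0), 0.0)
        bins = np.clip((dnorm * 4).astype(int), 0, 3)
        levels = np.asarray(spec.caspase_bin_levels, dtype=np.float32)
        cas[structure] = lv["caspase"] * levels[bins[structure]]
    patch[3] += cas * tex

    com = ndi.center_of_mass(structure)
    truth = StructureGroundTruth(
        well_id="",
        microwell_index=-1,
        class_label=spec.class_label.value,
        centroid_row=float(com[0]),
        centroid_col=float(com[1]),
        true_area=float(structure.sum()) * ps**2,
        true_gap_area=float(gap.sum()) * ps**2,
        true_cavity_count=int(cavity_count),
        true_caspase_integrated=float(patch[3][structure].sum()),
        delaminated=bool(spec.delamination_gap_area > 0),
    )
    if return_masks:
        masks = dict(structure=structure, ring=ring, gap=gap, epi=epi_outer,
                     cavities=cavities, epi_cell=epi_cell)
        return patch, truth, masks
    return patch, truth


def _place_cavities(spec: PhantomSpec, rng: np.random.Generator,
                    r_epi: float, r_cav: float) -> list[tuple[float, float]]:
    """Non-overlapping cavity centers inside the Epi disc.

    The terminal XEn/EpiC phenotype has its single PAC at the center;
    multi-cavity (non-polarized Epi) variants disperse them.
    """
    if spec.class_label is Phenotype.XEN_EPIC and spec.cavity_count == 1:
        return [(0.0, 0.0)]
    wall = 5.0  # px of Epi tissue kept between a lumen and the Epi boundary
    max_r = r_epi - r_cav - wall
    if max_r <= 0:
        raise ValueError("cavities do not fit inside the Epi compartment")
    min_sep = 2 * r_cav + 4.0
    centers: list[tuple[float, float]] = []
    for _ in range(3000):
        if len(centers) == spec.cavity_count:
            break
        ang = rng.uniform(0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0, 1)) * max_r
        cand = (rad * np.sin(ang), rad * np.cos(ang))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < spec.cavity_count:
        # deterministic fallback: evenly spaced on a ring at 0.78 max_r
        k = spec.cavity_count
        phi0 = rng.uniform(0, 2 * np.pi)
        ring_r = 0.78 * max_r
        if 2 * ring_r * np.sin(np.pi / k) < min_sep:
            raise ValueError(
                f"could not place {k} disjoint cavities inside the Epi")
        centers = [(ring_r * np.sin(phi0 + 2 * np.pi * i / k),
                    ring_r * np.cos(phi0 + 2 * np.pi * i / k)) for i in range(k)]
    return centers


def _granularity(size: int, rng: np.random.Generator, sigma: float = 2.0,
                 amplitude: float = 0.22) -> np.ndarray:
    """Cell-scale multiplicative granularity so texture features are informative."""
    g = ndi.gaussian_filter(rng.standard_normal((size, size)), sigma)
    g /= max(g.std(), 1e-9)
    return np.clip(1.0 + amplitude * g, 0.3, None).astype(np.float32)


def apply_noise(patch: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Apply shot and read noise to a noise-free patch.

    Shot noise uses the Gaussian approximation N(I, I/poisson_scale): with the
    default background of 100 intensity units (10 photon counts) every pixel
    is in the regime where the approximation is indistinguishable from true
    Poisson sampling, and it is an order of magnitude faster on montage-sized
    arrays.
    """
    lam = np.maximum(np.asarray(patch, dtype=np.float32), np.float32(0.0))
    # one combined draw: Var = shot (lam / q) + read (sd²)
    sd = np.sqrt(lam / np.float32(noise.poisson_scale)
                 + np.float32(noise.gaussian_sd) ** 2)
    out = lam + sd * rng.standard_normal(patch.shape, dtype=np.float32)
    return np.clip(out, 0.0, 65535.0, out=out)


# --- scenario types --------------------------------------------------------------


@dataclass
class DoseGroup:
    """One condition x dose cell of the screen layout."""

    dose: float
    class_mixture: tuple[float, ...] = (0.72, 0.18, 0.04, 0.04, 0.02)
    area_scale: float = 1.0
    delaminated_fraction: float = 0.0
    gap_mean: float = 1700.0
    gap_sd: float = 400.0
    #: cavity-count distribution applied to XEn/non-polarized Epi structures
    cavity_distribution: dict[int, float] = field(default_factory=lambda: {0: 1.0})
    caspase_bin_levels: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    #: "iid" draws classes/variants independently per structure; "exact"
    #: allocates counts by largest remainder (isolates measurement error
    #: from sampling noise in recovery benchmarks)
    mixture_mode: str = "iid"

    def validate(self) -> None:
        if len(self.class_mixture) != len(PHENOTYPES):
            raise ValueError("class_mixture must have 5 entries")
        if abs(sum(self.class_mixture) - 1.0) > 1e-6:
            raise ValueError("class_mixture must sum to 1")
        if abs(sum(self.cavity_distribution.values()) - 1.0) > 1e-6:
            raise ValueError("cavity_distribution must sum to 1")
        if self.mixture_mode not in ("iid", "exact"):
            raise ValueError("mixture_mode must be 'iid' or 'exact'")


@dataclass
class Condition:
    name: str
    doses: list[DoseGroup]


@dataclass
class ScreenScenario:
    """Conditions x doses x replicate wells of a screening campaign."""

    conditions: list[Condition]
    replicates_per_condition: int = 3
    control_name: str = "control"

    def validate(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names in scenario")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        for c in self.conditions:
            for d in c.doses:
                d.validate()

    def wells(self):
        """Iterate (condition, dose_group, replicate, well_id)."""
        for cond in self.conditions:
            for dg in cond.doses:
                for rep in range(1, self.replicates_per_condition + 1):
                    wid = f"{cond.name}_d{dg.dose:g}_r{rep}"
                    yield cond, dg, rep, wid


def control_scenario(replicates: int = 3) -> ScreenScenario:
    """A control-only scenario at the published control composition
    (72% XEn/EpiC, 4% non-polarized Epi; remaining fractions are generator
    parameters, see docs/methods.md)."""
    return ScreenScenario(
        conditions=[Condition(name="control", doses=[DoseGroup(dose=0.0)])],
        replicates_per_condition=replicates,
    )


def _exact_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of n draws to probabilities."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def _draw_classes(dg: DoseGroup, n: int, rng: np.random.Generator) -> list[Phenotype]:
    probs = np.asarray(dg.class_mixture, dtype=float)
    if dg.mixture_mode == "exact":
        counts = _exact_counts(probs, n)
        labels = [ph for ph, c in zip(PHENOTYPES, counts) for _ in range(c)]
        rng.shuffle(labels)  # type: ignore[arg-type]
        return labels
    idx = rng.choice(len(PHENOTYPES), size=n, p=probs)
    return [PHENOTYPES[i] for i in idx]


def _draw_variant_flags(dg: DoseGroup, labels: list[Phenotype], rng: np.random.Generator):
    """Per-structure (delaminated, cavity_count) variant assignments."""
    n = len(labels)
    eligible = np.array([lab in EPI_CLASSES for lab in labels])
    delam = np.zeros(n, dtype=bool)
    if dg.delaminated_fraction > 0 and eligible.any():
        idx = np.flatnonzero(eligible)
        if dg.mixture_mode == "exact":
            k = int(round(dg.delaminated_fraction * n))
            k = min(k, idx.size)
            delam[rng.choice(idx, size=k, replace=False)] = True
        else:
            delam[idx] = rng.random(idx.size) < dg.delaminated_fraction

    cavities = np.full(n, -1, dtype=int)  # -1: class default
    np_idx = np.flatnonzero([lab is Phenotype.XEN_NONPOLARIZED_EPI for lab in labels])
    if np_idx.size and dg.cavity_distribution != {0: 1.0}:
        ks = np.array(sorted(dg.cavity_distribution))
        ps = np.array([dg.cavity_distribution[k] for k in ks])
        if dg.mixture_mode == "exact":
            counts = _exact_counts(ps, np_idx.size)
            assign = np.repeat(ks, counts)
            rng.shuffle(assign)
        else:
            assign = ks[rng.choice(ks.size, size=np_idx.size, p=ps)]
        cavities[np_idx] = assign
    return delam, cavities


def generate_well(
    dg: DoseGroup,
    scene: SceneConfig,
    rng: np.random.Generator,
    well_id: str = "well",
    render: bool = True,
):
    """Render one well montage and its ground-truth table.

    Returns ``(montage, truth_df)``; ``montage`` is a (4, H, W) uint16 array,
    or None when ``render=False`` (ground-truth-only enumeration mode, with
    analytic truth values).
    """
    dg.validate()
    scene.validate()
    n = scene.structures_per_well
    labels = _draw_classes(dg, n, rng)
    delam, cav = _draw_variant_flags(dg, labels, rng)
    specs = []
    for i, lab in enumerate(labels):
        specs.append(
            sample_spec(
                lab,
                rng,
                area_scale=dg.area_scale,
                delaminated=bool(delam[i]),
                gap_mean=dg.gap_mean,
                gap_sd=dg.gap_sd,
                cavity_count=None if cav[i] < 0 else int(cav[i]),
                caspase_bin_levels=dg.caspase_bin_levels,
            )
        )

    centers = scene.microwell_centers()
    occupied = rng.choice(centers.shape[0], size=n, replace=False) if n < centers.shape[0] \
        else np.arange(centers.shape[0])[:n]
    occupied = np.sort(occupied)

    rows = []
    if not render:
        for widx, spec in zip(occupied, specs):
            cy, cx = centers[widx]
            rows.append(
                StructureGroundTruth(
                    well_id=well_id, microwell_index=int(widx),
                    class_label=spec.class_label.value,
                    centroid_row=float(cy), centroid_col=float(cx),
                    true_area=spec.target_area,
                    true_gap_area=spec.delamination_gap_area,
                    true_cavity_count=spec.cavity_count,
                    true_caspase_integrated=float("nan"),
                    delaminated=spec.delamination_gap_area > 0,
                )
            )
        return None, _truth_frame(rows)

    shape = scene.montage_shape
    planes = np.full((len(CHANNELS),) + shape, scene.noise.background_level, dtype=np.float32)
    max_jitter_frac = 0.12
    for widx, spec in zip(occupied, specs):
        patch, truth = render_structure(spec, scene, rng)
        h = patch.shape[1]
        cy, cx = centers[widx]
        lim = max(scene.microwell_diameter / scene.pixel_size * max_jitter_frac
                  - 0.0, 0.0)
        jy, jx = rng.uniform(-lim, lim, size=2)
        top = int(round(cy + jy - h / 2))
        left = int(round(cx + jx - h / 2))
        top = int(np.clip(top, 0, shape[0] - h))
        left = int(np.clip(left, 0, shape[1] - h))
        planes[:, top:top + h, left:left + h] += patch - scene.noise.background_level
        truth.well_id = well_id
        truth.microwell_index = int(widx)
        truth.centroid_row += top
        truth.centroid_col += left
        rows.append(truth)

    noisy = apply_noise(planes, scene.noise, rng)
    montage = np.round(noisy).astype(np.uint16)
    return montage, _truth_frame(rows)


def _truth_frame(rows: list[StructureGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def generate_screen(
    scenario: ScreenScenario,
    scene: SceneConfig,
    out_dir: str | Path,
    seed: int = 0,
    render: bool = True,
) -> pd.DataFrame:
    """Generate a whole screen: per-well TIFFs, ground-truth CSVs, manifest.

    Deterministic given (scenario, scene, seed): every well gets an independent
    RNG stream derived from the seed and its well id.  Returns the manifest
    (one row per well) which is also written to ``out_dir/manifest.csv``.
    """
    scenario.validate()
    scene.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for cond, dg, rep, wid in scenario.wells():
        rng = rng_for(seed, wid)
        montage, truth = generate_well(dg, scene, rng, well_id=wid, render=render)
        gt_path = out / f"{wid}_truth.csv"
        truth.to_csv(gt_path, index=False)
        img_path = ""
        if render and montage is not None:
            img_path = f"{wid}.tif"
            tifffile.imwrite(
                out / img_path,
                montage,
                photometric="minisblack",
                planarconfig="separate",
                metadata={"axes": "CYX", "channels": list(CHANNELS)},
            )
        manifest.append(
            dict(well_id=wid, condition=cond.name, dose=dg.dose, replicate=rep,
                 image=img_path, truth=gt_path.name, n_structures=len(truth))
        )
    mdf = pd.DataFrame(manifest)
    mdf.to_csv(out / "manifest.csv", index=False)
    (out / "scene.yaml").write_text(yaml.safe_dump(scene_to_dict(scene)))
    return mdf


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """A reproducible, stream-independent RNG derived from (seed, tag)."""
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:8], "little"))


def scene_to_dict(scene: SceneConfig) -> dict:
    d = dict(scene.__dict__)
    d["noise"] = dict(scene.noise.__dict__)
    d["microwell_grid"] = list(scene.microwell_grid)
    return d


def scene_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    noise = NoiseModel(**d.pop("noise", {}))
    grid = tuple(d.pop("microwell_grid", (15, 11)))
    return SceneConfig(noise=noise, microwell_grid=grid, **d)


def scenario_from_dict(d: dict) -> ScreenScenario:
    conds = []
    for c in d["conditions"]:
        doses = []
        for g in c["doses"]:
            g = dict(g)
            if "class_mixture" in g:
                g["class_mixture"] = tuple(g["class_mixture"])
            if "caspase_bin_levels" in g:
                g["caspase_bin_levels"] = tuple(g["caspase_bin_levels"])
            if "cavity_distribution" in g:
                g["cavity_distribution"] = {int(k): float(v)
                                            for k, v in g["cavity_distribution"].items()}
            doses.append(DoseGroup(**g))
        conds.append(Condition(name=c["name"], doses=doses))
    return ScreenScenario(
        conditions=conds,
        replicates_per_condition=int(d.get("replicates_per_condition", 3)),
        control_name=d.get("control_name", "control"),
    )


def scenario_to_dict(sc: ScreenScenario) -> dict:
    return json.loads(json.dumps(dict(
        conditions=[dict(name=c.name, doses=[
            dict(dose=g.dose, class_mixture=list(g.class_mixture),
                 area_scale=g.area_scale, delaminated_fraction=g.delaminated_fraction,
                 gap_mean=g.gap_mean, gap_sd=g.gap_sd,
                 cavity_distribution={str(k): v for k, v in g.cavity_distribution.items()},
                 caspase_bin_levels=list(g.caspase_bin_levels),
                 mixture_mode=g.mixture_mode)
            for g in c.doses]) for c in sc.conditions],
        replicates_per_condition=sc.replicates_per_condition,
        control_name=sc.control_name,
    )))
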