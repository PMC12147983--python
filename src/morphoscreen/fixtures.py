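"""Labeled synthetic benchmark fixtures built from the phantom generator.

These helpers run the same measurement path as the screening pipeline
(render -> noise -> segment -> measure) on single-structure patches, producing
labeled feature tables for classifier training/evaluation benchmarks and
variant fixtures (delamination, cavities) for recovery benchmarks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from morphoscreen.features import count_cavities, measure_delamination, measure_object
from morphoscreen.phantoms import (
    CHANNELS,
    PHENOTYPES,
    PhantomSpec,
    Phenotype,
    SceneConfig,
    apply_noise,
    render_structure,
    sample_spec,
)
from morphoscreen.segmentation import SegmentationParams, segment_montage


def measure_patch(
    patch: np.ndarray,
    scene: SceneConfig,
    seg_params: SegmentationParams | None = None,
) -> tuple[dict[str, float], np.ndarray] | None:
    """Segment a single-structure patch and measure its largest object.

    Returns ``(feature_row, mask)`` or None if nothing segments (does not
    happen at default SNR).
    """
    seg = segment_montage(patch, seg_params, pixel_size=scene.pixel_size)
    if not seg.objects:
        return None
    obj = max(seg.objects, key=lambda o: o.pixel_count)
    mask = seg.label_image == obj.object_id
    channels = {name: patch[i] for i, name in enumerate(CHANNELS)}
    return measure_object(mask, channels, scene.pixel_size), mask


def featurize_spec(
    spec: PhantomSpec,
    scene: SceneConfig,
    rng: np.random.Generator,
    seg_params: SegmentationParams | None = None,
) -> dict[str, float] | None:
    """Render a spec with noise and return its measured feature row."""
    patch, _ = render_structure(spec, scene, rng)
    noisy = apply_noise(patch, scene.noise, rng)
    res = measure_patch(noisy, scene, seg_params)
    return None if res is None else res[0]


def labeled_feature_frame(
    n_per_class: int,
    scene: SceneConfig,
    rng: np.random.Generator,
    classes: tuple[Phenotype, ...] = PHENOTYPES,
    delaminated_fraction: float = 0.16,
) -> pd.DataFrame:
    """Labeled feature table with ``n_per_class`` structures per phenotype,
    drawn with natural variability at the default class separation and SNR.

    Training structures are curated from the screened population, so by
    default the ring-bearing classes include delaminated variants at the
    control-condition fraction (16%) — a phenotype class keeps its label
    whether or not the XEn layer has detached.
    """
    rows = []
    for ph in classes:
        for _ in range(n_per_class):
            spec = sample_spec(ph, rng,
                               delaminated=bool(rng.random() < delaminated_fraction))
            row = featurize_spec(spec, scene, rng)
            if row is None:
                continue
            row["label"] = ph.value
            rows.append(row)
    return pd.DataFrame(rows)


def delamination_feature_frame(
    n_per_class: int,
    scene: SceneConfig,
    rng: np.random.Generator,
    gap_mean: float = 1700.0,
    gap_sd: float = 400.0,
) -> pd.DataFrame:
    """Binary (delaminated / attached) training fixture.

    The attached class is curated to cover the full scored population — every
    phenotype is represented, with extra weight on the dominant terminal
    class — because the screen scores all five classes, while the delaminated
    class spans the ring-bearing phenotypes, the only ones where an XEn
    detachment gap exists.  Compositions are exact (a curator picks
    representatives deliberately), not random draws that could miss a rare
    class entirely at this training-set size.
    """
    ring_classes = (Phenotype.XEN_EPIC, Phenotype.XEN_EPI_ROSETTE,
                    Phenotype.XEN_NONPOLARIZED_EPI)
    attached_weights = np.array([0.40, 0.20, 0.14, 0.13, 0.13])  # all 5 classes
    delam_weights = np.array([0.60, 0.25, 0.15])  # ring classes only
    rows = []
    for delam, label in ((False, "attached"), (True, "delaminated")):
        classes = ring_classes if delam else PHENOTYPES
        weights = delam_weights if delam else attached_weights
        counts = np.floor(weights * n_per_class).astype(int)
        counts[np.argsort(-(weights * n_per_class - counts))[
            : n_per_class - counts.sum()]] += 1
        roster = [ph for ph, c in zip(classes, counts) for _ in range(c)]
        for ph in roster:
            spec = sample_spec(ph, rng, delaminated=delam,
                               gap_mean=gap_mean, gap_sd=gap_sd)
            row = featurize_spec(spec, scene, rng)
            if row is None:
                continue
            row["label"] = label
            rows.append(row)
    return pd.DataFrame(rows)


def delamination_training_from_well(
    scene: SceneConfig,
    rng: np.random.Generator,
    n_per_class: int = 30,
    seg_params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Binary (delaminated/attached) training table curated from a rendered
    training well, measured by the same segmentation path as the screen.

    Emulates classifier training on annotated structures picked from real
    montage images: a dedicated well is generated with an enriched delaminated
    fraction (45%, exact counts) so both classes are well represented, objects
    are matched to ground truth by microwell, and the first ``n_per_class``
    exemplars of each label (in microwell order) form the training set.
    """
    from morphoscreen.phantoms import DoseGroup, generate_well
    from morphoscreen.segmentation import assign_microwells

    dg = DoseGroup(
        dose=0.0,
        class_mixture=(0.55, 0.25, 0.10, 0.05, 0.05),
        delaminated_fraction=0.45,
        mixture_mode="exact",
    )
    montage, truth = generate_well(dg, scene, rng, well_id="training_well")
    seg = assign_microwells(
        segment_montage(montage, seg_params, pixel_size=scene.pixel_size), scene)
    channels = {name: montage[i] for i, name in enumerate(CHANNELS)}
    truth_by_well = truth.set_index("microwell_index")
    rows: list[dict] = []
    counts = {"attached": 0, "delaminated": 0}
    for obj in seg.objects:
        if obj.duplicate or obj.microwell_index not in truth_by_well.index:
            continue
        label = ("delaminated"
                 if bool(truth_by_well.loc[obj.microwell_index, "delaminated"])
                 else "attached")
        if counts[label] >= n_per_class:
            continue
        mask = seg.label_image == obj.object_id
        r0, c0, r1, c1 = obj.bbox
        pad = 4
        r0, c0 = max(r0 - pad, 0), max(c0 - pad, 0)
        r1 = min(r1 + pad, mask.shape[0])
        c1 = min(c1 + pad, mask.shape[1])
        crops = {k: v[r0:r1, c0:c1] for k, v in channels.items()}
        row = measure_object(mask[r0:r1, c0:c1], crops, scene.pixel_size)
        row["label"] = label
        rows.append(row)
        counts[label] += 1
        if all(v >= n_per_class for v in counts.values()):
            break
    return pd.DataFrame(rows)


def delamination_recovery(
    true_gap_um2: float,
    n: int,
    scene: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Measured delamination areas of ``n`` XEn/EpiC phantoms rendered with an
    exact detachment gap (noise applied), via the automated ring/inner-contour
    procedure."""
    out = []
    for _ in range(n):
        spec = sample_spec(Phenotype.XEN_EPIC, rng)
        # keep enough room inside the ring for the requested gap plus an Epi
        spec.target_area = max(spec.target_area, 2.7 * true_gap_um2)
        spec.delamination_gap_area = true_gap_um2
        spec.rotation = float(rng.uniform(0, 2 * np.pi))
        patch, _ = render_structure(spec, scene, rng)
        noisy = apply_noise(patch, scene.noise, rng)
        res = measure_patch(noisy, scene)
        if res is None:
            continue
        _, mask = res
        cm = measure_delamination(mask, noisy[1], noisy[0], scene.pixel_size)
        if cm.applicable:
            out.append(cm.delamination_area)
    return np.asarray(out)


def cavity_fixture_counts(
    distribution: dict[int, float],
    n: int,
    scene: SceneConfig,
    rng: np.random.Generator,
    exact: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render ``n`` structures with the given true cavity-count distribution
    and return (true_counts, measured_counts).

    Single-cavity structures are terminal XEn/EpiCs (central PAC); structures
    with 0 or >= 2 cavities are XEn/non-polarized Epi with dispersed lumens.
    With ``exact=True`` the composition follows the distribution by largest-
    remainder allocation (isolating counting error from sampling noise).
    """
    ks = np.array(sorted(distribution))
    ps = np.array([distribution[k] for k in ks], dtype=float)
    if abs(ps.sum() - 1.0) > 1e-6:
        raise ValueError("cavity distribution must sum to 1")
    if exact:
        raw = ps * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        truth = np.repeat(ks, counts)
        rng.shuffle(truth)
    else:
        truth = ks[rng.choice(ks.size, size=n, p=ps)]
    measured = []
    for k in truth:
        if k == 1:
            spec = sample_spec(Phenotype.XEN_EPIC, rng)
        else:
            spec = sample_spec(Phenotype.XEN_NONPOLARIZED_EPI, rng,
                               cavity_count=int(k))
        patch, _ = render_structure(spec, scene, rng)
        noisy = apply_noise(patch, scene.noise, rng)
        res = measure_patch(noisy, scene)
        if res is None:
            measured.append(-1)
            continue
        _, mask = res
        c = count_cavities(mask, noisy[0], noisy[2], scene.pixel_size,
                           gata6=noisy[1])
        measured.append(c)
    return truth, np.asarray(measured)
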