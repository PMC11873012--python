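"""End-to-end study pipelines over synthetic stimuli.

Three reproducible experiments mirror the canonical rodent object-vision
designs:

* ``transform_matrix`` -- two objects over a size x azimuth grid; readouts
  are trained on the "on-cross" cells (size axis at frontal azimuth, azimuth
  axis at an intermediate size) and tested everywhere, and the per-layer
  accuracy patterns are compared to a reference observer.
* ``occlusion`` -- training on a mixture of unoccluded and bubble-masked
  views over four transformation axes, accuracy along each axis for both
  test types, plus per-view bubbles saliency maps and a pixel baseline.
* ``variants`` -- a target object is discriminated from distractors, then
  random structural variants (regular and outline) probe spontaneous
  generalization, choice-triggered saliency and regular/outline consistency.

Every experiment takes a ``Profile`` that scales trial counts: the ``paper``
profile uses the published counts (5000 training images, 3000 masks, 5 runs,
five population scales), the ``desk`` profile shrinks them for quick runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import readout as ro
from . import saliency as sal
from .geometry import AugmentationConfig, ViewingGeometry, augment
from .networks import extract_activations, sample_units
from .stimuli import (
    Lobe,
    ObjectModel,
    ResponderSpec,
    StructuralVariantSpec,
    ViewParams,
    make_canonical_objects,
    make_structural_variant,
    render_view,
    simulate_responses,
    to_outline,
)


@dataclass(frozen=True)
class Profile:
    name: str
    n_train: int
    n_test: int
    n_masks: int
    n_runs: int
    scales: tuple[int, ...]
    n_perm_bubbles: int = 1000
    n_perm_tripod: int = 100
    n_variants: int = 1000


def paper_profile() -> Profile:
    return Profile(
        name="paper", n_train=5000, n_test=5000, n_masks=3000, n_runs=5,
        scales=(1_000, 5_000, 10_000, 50_000, 100_000), n_variants=3000,
    )


def desk_profile() -> Profile:
    return Profile(
        name="desk", n_train=1000, n_test=500, n_masks=500, n_runs=2,
        scales=(1_000, 10_000), n_perm_bubbles=200, n_perm_tripod=100,
        n_variants=500,
    )


def get_profile(name: str) -> Profile:
    if name == "paper":
        return paper_profile()
    if name == "desk":
        return desk_profile()
    raise ValueError("profile must be 'desk' or 'paper'")


@dataclass
class ExperimentReport:
    kind: str
    artifacts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    REQUIRED = {
        "transform_matrix": (
            "reference", "accuracy", "l1_curves", "pearson_curves",
            "hist_l1_min", "hist_pearson_max",
        ),
        "occlusion": (
            "accuracy", "degenerate_flags", "saliency_maps", "pixel_accuracy",
        ),
        "variants": (
            "choice_fraction_regular", "choice_fraction_outline",
            "saliency_regular", "saliency_outline",
            "map_correlation", "consistency",
        ),
    }

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED[self.kind] if k not in self.artifacts]
        if missing:
            raise ValueError(f"{self.kind} report is missing artifacts: {missing}")


# ---------------------------------------------------------------------------
# shared helpers

def make_distractor_objects() -> tuple[ObjectModel, ...]:
    """Fixed pool of lobed distractors differing from the tripod in lobe
    count and arrangement."""
    return (
        ObjectModel("bar2", (
            Lobe((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 0.34),
            Lobe((0.0, 0.0, 0.0), (0.0, -1.0, 0.0), 0.34),
        )),
        ObjectModel("ell", (
            Lobe((0.0, 0.0, 0.0), (0.0, 1.0, 0.1), 0.30),
            Lobe((0.0, 0.0, 0.0), (1.0, 0.0, -0.1), 0.30),
        )),
        ObjectModel("star4", (
            Lobe((0.0, 0.0, 0.0), (0.7, 0.7, 0.2), 0.28),
            Lobe((0.0, 0.0, 0.0), (-0.7, 0.7, -0.2), 0.28),
            Lobe((0.0, 0.0, 0.0), (0.7, -0.7, -0.2), 0.28),
            Lobe((0.0, 0.0, 0.0), (-0.7, -0.7, 0.2), 0.28),
        )),
        ObjectModel("fan5", (
            Lobe((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 0.24),
            Lobe((0.0, 0.0, 0.0), (0.95, 0.31, 0.15), 0.24),
            Lobe((0.0, 0.0, 0.0), (0.59, -0.81, -0.15), 0.24),
            Lobe((0.0, 0.0, 0.0), (-0.59, -0.81, 0.15), 0.24),
            Lobe((0.0, 0.0, 0.0), (-0.95, 0.31, -0.15), 0.24),
        )),
    )


def default_occlusion_views(default_size: float = 35.0) -> tuple[ViewParams, ...]:
    """Default view plus seven single-axis transformations (8 per object)."""
    return (
        ViewParams(size_deg=default_size),
        ViewParams(size_deg=default_size * 0.6),
        ViewParams(size_deg=default_size * 1.25),
        ViewParams(size_deg=default_size, azimuth_deg=30.0),
        ViewParams(size_deg=default_size, azimuth_deg=-30.0),
        ViewParams(size_deg=default_size, hshift_deg=9.0),
        ViewParams(size_deg=default_size, hshift_deg=-9.0),
        ViewParams(size_deg=default_size, inplane_deg=30.0),
    )


def build_ideal_observer(
    objects=None,
    views=None,
    geom: ViewingGeometry | None = None,
) -> sal.IdealObserver:
    """Template store of every object view used in the occlusion study.

    With the default two objects and eight views this yields 16 templates,
    labelled by object index.
    """
    geom = ViewingGeometry() if geom is None else geom
    objects = make_canonical_objects() if objects is None else objects
    views = default_occlusion_views() if views is None else views
    templates, labels = [], []
    for label, model in enumerate(objects):
        for view in views:
            templates.append(render_view(model, view, geom))
            labels.append(label)
    return sal.IdealObserver(np.stack(templates), np.array(labels))


def _reference_from_labels(pred, truth, conditions, meta=None) -> ro.AccuracyMatrix:
    correct = pd.Series(np.asarray(pred) == np.asarray(truth), name="correct")
    conditions = pd.DataFrame(conditions).reset_index(drop=True)
    cells = correct.groupby([conditions[c] for c in conditions.columns]).mean()
    return ro.AccuracyMatrix(cells, meta=dict(meta or {}))


def _readout_curves(
    network,
    layers,
    train_imgs, train_labels,
    test_imgs, test_labels, test_conditions,
    reference: ro.AccuracyMatrix | None,
    scales,
    rng: np.random.Generator,
    seed: int,
):
    """Train/evaluate readouts for each (layer, scale); compare to reference."""
    acts_train = network.collect(train_imgs, layers)
    acts_test = network.collect(test_imgs, layers)
    rows = []
    for layer in layers:
        for scale in scales:
            us = sample_units(acts_train[layer].shape[1], scale, rng, layer_id=layer)
            xtr = acts_train[layer][:, us.indices]
            xte = acts_test[layer][:, us.indices]
            xtr_z, xte_z, _ = ro.zscore(xtr, xte)
            svm = ro.train_readout(xtr_z, train_labels, seed=seed)
            acc = ro.evaluate(
                svm, xte_z, test_labels, test_conditions,
                meta={"layer": layer, "scale": scale},
            )
            row = {"layer": layer, "scale": scale, "accuracy": acc}
            if reference is not None:
                row["l1"] = ro.compare_l1(reference, acc)
                try:
                    row["pearson"] = ro.compare_pearson(reference, acc)
                except ValueError:  # saturated (constant) accuracy pattern
                    row["pearson"] = np.nan
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# transform-matrix experiment

@dataclass
class TransformMatrixSpec:
    network: object
    geom: ViewingGeometry = field(default_factory=ViewingGeometry)
    augmentation: AugmentationConfig | None = None
    objects: tuple[ObjectModel, ObjectModel] | None = None
    sizes: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)
    azimuths: tuple[float, ...] = (-60.0, -40.0, -20.0, 0.0, 20.0, 40.0, 60.0)
    cross_size: float = 30.0
    cross_azimuth: float = 0.0
    layers: tuple[int, ...] | None = None
    reference: ro.AccuracyMatrix | None = None
    responder: ResponderSpec | None = None
    seed: int = 0


def _on_cross_cells(spec: TransformMatrixSpec):
    cells = list(itertools.product(spec.sizes, spec.azimuths))
    return [
        (s, a) for s, a in cells
        if a == spec.cross_azimuth or s == spec.cross_size
    ]


def _render_cell(model, size, azim, spec, rng):
    img = render_view(model, ViewParams(size_deg=size, azimuth_deg=azim), spec.geom)
    if spec.augmentation is not None:
        img = augment(img, spec.augmentation, rng)
    return img


def _draw_matrix_trials(spec, cells, n, rng):
    objects = spec.objects or make_canonical_objects()
    imgs, labels, conds = [], [], []
    for _ in range(n):
        size, azim = cells[rng.integers(len(cells))]
        label = int(rng.integers(2))
        imgs.append(_render_cell(objects[label], size, azim, spec, rng))
        labels.append(label)
        conds.append({"size": size, "azimuth": azim})
    return np.stack(imgs), np.array(labels), pd.DataFrame(conds)


def run_transform_matrix(
    spec: TransformMatrixSpec, profile: Profile | str = "desk"
) -> ExperimentReport:
    """Per-layer accuracy matrices over the size x azimuth grid plus
    L1/Pearson comparisons against the reference observer."""
    profile = get_profile(profile) if isinstance(profile, str) else profile
    if spec.reference is None and spec.responder is None:
        raise ValueError(
            "transform-matrix experiment needs a reference AccuracyMatrix or a "
            "responder to build one"
        )
    layers = spec.layers or tuple(range(1, spec.network.depth + 1))
    on_cells = _on_cross_cells(spec)
    all_cells = list(itertools.product(spec.sizes, spec.azimuths))

    master = np.random.default_rng(spec.seed)
    all_rows = []
    reference = spec.reference
    for run in range(profile.n_runs):
        run_rng = np.random.default_rng(master.integers(2**31))
        tr_imgs, tr_labels, _ = _draw_matrix_trials(spec, on_cells, profile.n_train, run_rng)
        te_imgs, te_labels, te_conds = _draw_matrix_trials(spec, all_cells, profile.n_test, run_rng)
        if reference is None:
            pred = simulate_responses(spec.responder, list(te_imgs), run_rng)
            reference = _reference_from_labels(pred, te_labels, te_conds,
                                               meta={"observer": "responder"})
        rows = _readout_curves(
            spec.network, layers, tr_imgs, tr_labels, te_imgs, te_labels,
            te_conds, reference, profile.scales, run_rng, seed=spec.seed + run,
        )
        for row in rows:
            row["run"] = run
        all_rows.extend(rows)

    n_layers = len(layers)
    curves_l1, curves_r = [], []
    for run in range(profile.n_runs):
        for scale in profile.scales:
            sel = [r for r in all_rows if r["run"] == run and r["scale"] == scale]
            sel.sort(key=lambda r: r["layer"])
            curves_l1.append([r["l1"] for r in sel])
            curves_r.append([r["pearson"] for r in sel])
    curves_l1 = np.array(curves_l1)
    curves_r = np.array(curves_r)
    finite_r = curves_r[np.isfinite(curves_r).all(axis=1)]
    hist_r = (
        ro.extrema_histogram(finite_r, "max")
        if len(finite_r)
        else np.zeros(n_layers, dtype=int)
    )

    report = ExperimentReport(
        kind="transform_matrix",
        artifacts={
            "reference": reference,
            "accuracy": all_rows,
            "l1_curves": curves_l1,
            "pearson_curves": curves_r,
            "hist_l1_min": ro.extrema_histogram(curves_l1, "min"),
            "hist_pearson_max": hist_r,
            "layers": list(layers),
        },
        provenance={
            "seed": spec.seed, "profile": profile.name,
            "n_runs": profile.n_runs, "scales": list(profile.scales),
        },
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# occlusion experiment

@dataclass
class OcclusionSpec:
    network: object | None
    geom: ViewingGeometry = field(default_factory=ViewingGeometry)
    augmentation: AugmentationConfig | None = None
    objects: tuple[ObjectModel, ObjectModel] | None = None
    sizes: tuple[float, ...] = (21.0, 28.0, 35.0, 43.75)
    azimuths: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    hshifts: tuple[float, ...] = (-9.0, -4.5, 0.0, 4.5, 9.0)
    inplanes: tuple[float, ...] = (-30.0, -15.0, 0.0, 15.0, 30.0)
    default_size: float = 35.0
    bubble_spec: sal.BubbleMaskSpec = field(default_factory=sal.BubbleMaskSpec)
    occluded_fraction: float = 0.5
    layer: int | None = None
    saliency_views: tuple[ViewParams, ...] | None = None
    responder: ResponderSpec | None = None
    p_threshold: float = 0.05
    seed: int = 0


def _axis_pool(spec: OcclusionSpec):
    """Single-axis transformation pool: (axis, value, ViewParams)."""
    pool = []
    for s in spec.sizes:
        pool.append(("size", s, ViewParams(size_deg=s)))
    for a in spec.azimuths:
        pool.append(("azimuth", a, ViewParams(size_deg=spec.default_size, azimuth_deg=a)))
    for hs in spec.hshifts:
        pool.append(("hshift", hs, ViewParams(size_deg=spec.default_size, hshift_deg=hs)))
    for ip in spec.inplanes:
        pool.append(("inplane", ip, ViewParams(size_deg=spec.default_size, inplane_deg=ip)))
    return pool


def _draw_occlusion_trials(spec, pool, n, occluded_fraction, rng):
    objects = spec.objects or make_canonical_objects()
    shape = (spec.geom.res_h, spec.geom.res_w)
    imgs, masks, labels, conds = [], [], [], []
    for _ in range(n):
        axis, value, view = pool[rng.integers(len(pool))]
        label = int(rng.integers(2))
        img = render_view(objects[label], view, spec.geom)
        occluded = rng.random() < occluded_fraction
        if occluded:
            mask = sal.make_bubble_mask(spec.bubble_spec, shape, rng)
            img = sal.apply_mask(img, mask)
        else:
            mask = np.ones(shape, dtype=np.float32)
        if spec.augmentation is not None:
            img = augment(img, spec.augmentation, rng)
        imgs.append(img)
        masks.append(mask)
        labels.append(label)
        conds.append({"axis": axis, "value": value, "occluded": occluded})
    return np.stack(imgs), np.stack(masks), np.array(labels), pd.DataFrame(conds)


def _bubbles_trials_for_view(spec, model, view, n_masks, classify, rng):
    """Masked trials of one view; outcomes = classification correctness."""
    shape = (spec.geom.res_h, spec.geom.res_w)
    base = render_view(model, view, spec.geom)
    masks = sal.make_bubble_mask(spec.bubble_spec, shape, rng, n_masks=n_masks)
    imgs = np.empty((n_masks, *shape), dtype=np.float32)
    for i in range(n_masks):
        img = sal.apply_mask(base, masks[i])
        if spec.augmentation is not None:
            img = augment(img, spec.augmentation, rng)
        imgs[i] = img
    labels = classify(imgs, masks)
    return sal.MaskedTrialSet(masks, labels)


def run_occlusion(spec: OcclusionSpec, profile: Profile | str = "desk") -> ExperimentReport:
    """Accuracy along the four transformation axes (unoccluded/occluded) and
    per-view bubbles saliency maps, plus a pixel baseline."""
    profile = get_profile(profile) if isinstance(profile, str) else profile
    rng = np.random.default_rng(spec.seed)
    objects = spec.objects or make_canonical_objects()
    pool = _axis_pool(spec)
    views = spec.saliency_views or default_occlusion_views(spec.default_size)

    tr_imgs, _, tr_labels, _ = _draw_occlusion_trials(
        spec, pool, profile.n_train, spec.occluded_fraction, rng
    )
    half = profile.n_test // 2
    te_imgs_u, te_masks_u, te_labels_u, te_conds_u = _draw_occlusion_trials(
        spec, pool, half, 0.0, rng
    )
    te_imgs_o, te_masks_o, te_labels_o, te_conds_o = _draw_occlusion_trials(
        spec, pool, half, 1.0, rng
    )
    te_imgs = np.concatenate([te_imgs_u, te_imgs_o])
    te_masks = np.concatenate([te_masks_u, te_masks_o])
    te_labels = np.concatenate([te_labels_u, te_labels_o])
    te_conds = pd.concat([te_conds_u, te_conds_o], ignore_index=True)

    if spec.responder is not None:
        pred = np.asarray(
            simulate_responses(spec.responder, list(zip(te_imgs, te_masks)), rng)
        )
        if spec.responder.kind == "planted_feature":
            correct_vec = pred.astype(bool)  # already coded as correctness
        else:
            correct_vec = pred == te_labels
        cells = pd.Series(correct_vec, name="correct").groupby(
            [te_conds[c] for c in te_conds.columns]
        ).mean()
        acc = ro.AccuracyMatrix(cells, meta={"observer": "responder"})

        def correct_fn(imgs, masks):
            labs = simulate_responses(spec.responder, list(zip(imgs, masks)), rng)
            return np.asarray(labs)
    else:
        layer = spec.layer or spec.network.depth
        xtr = extract_activations(spec.network, layer, tr_imgs).data
        xte = extract_activations(spec.network, layer, te_imgs).data
        xtr_z, xte_z, kept = ro.zscore(xtr, xte)
        svm = ro.train_readout(xtr_z, tr_labels, seed=spec.seed)
        acc = ro.evaluate(svm, xte_z, te_labels, te_conds, meta={"layer": layer})

        def correct_fn(imgs, masks, _svm=svm, _layer=layer, _kept=kept, _xtr=xtr):
            x = extract_activations(spec.network, _layer, imgs).data
            mu = _xtr.mean(axis=0)[_kept]
            sd = _xtr.std(axis=0)[_kept]
            return _svm.predict((x[:, _kept] - mu) / sd)

    # degenerate occluded classification: one object ~always right, the other
    # ~always wrong
    occ_sel = te_conds["occluded"].to_numpy()
    if spec.responder is not None:
        correct_occ = np.asarray(correct_vec)[occ_sel]
    else:
        correct_occ = svm.predict(xte_z[occ_sel]) == te_labels[occ_sel]
    lab_occ = te_labels[occ_sel]
    per_obj = []
    for obj in (0, 1):
        m = lab_occ == obj
        per_obj.append(float(correct_occ[m].mean()) if m.any() else np.nan)
    flags = {
        "occluded_accuracy_per_object": per_obj,
        "degenerate": bool(
            not np.any(np.isnan(per_obj))
            and min(per_obj) < 0.10
            and max(per_obj) > 0.90
        ),
    }

    maps = {}
    for label, model in enumerate(objects):
        for vi, view in enumerate(views):
            if spec.responder is not None:
                def classify_correct(imgs, masks, _l=label):
                    labs = np.asarray(correct_fn(imgs, masks))
                    if spec.responder.kind == "planted_feature":
                        return labs  # already coded as correctness
                    return (labs == _l).astype(int)
            else:
                def classify_correct(imgs, masks, _l=label):
                    return (correct_fn(imgs, masks) == _l).astype(int)
            trials = _bubbles_trials_for_view(
                spec, model, view, profile.n_masks, classify_correct, rng
            )
            try:
                smap = sal.permutation_significance_bubbles(
                    trials, profile.n_perm_bubbles, spec.p_threshold, rng
                )
            except ValueError:
                smap = None  # single-outcome view: saliency undefined
            maps[(label, vi)] = smap

    pix = ro.pixel_baseline(tr_imgs, tr_labels, te_imgs, te_labels, te_conds, seed=spec.seed)

    report = ExperimentReport(
        kind="occlusion",
        artifacts={
            "accuracy": acc,
            "degenerate_flags": flags,
            "saliency_maps": maps,
            "pixel_accuracy": pix,
            "views": list(views),
        },
        provenance={"seed": spec.seed, "profile": profile.name,
                    "n_masks": profile.n_masks},
    )
    report.validate()
    return report


# ---------------------------------------------------------------------------
# structural-variants experiment

@dataclass
class VariantsSpec:
    network: object | None
    geom: ViewingGeometry = field(default_factory=ViewingGeometry)
    augmentation: AugmentationConfig | None = None
    target: ObjectModel | None = None
    distractors: tuple[ObjectModel, ...] | None = None
    view: ViewParams = field(default_factory=lambda: ViewParams(size_deg=35.0))
    variant_spec: StructuralVariantSpec = field(
        default_factory=lambda: StructuralVariantSpec(angle_jitter_deg=20.0,
                                                      length_jitter=0.25)
    )
    layer: int | None = None
    responder: ResponderSpec | None = None
    p_threshold: float = 0.01
    seed: int = 0


def run_variants(spec: VariantsSpec, profile: Profile | str = "desk") -> ExperimentReport:
    """Spontaneous generalization to random structural variants.

    Trains target-vs-distractors (network mode) or consults a responder,
    then collects choices for regular and outline variants, choice-triggered
    saliency maps for both styles, their correlation, and the
    regular-vs-outline consistency confusion matrix.
    """
    profile = get_profile(profile) if isinstance(profile, str) else profile
    rng = np.random.default_rng(spec.seed)
    target = spec.target or make_canonical_objects()[0]
    distractors = spec.distractors or make_distractor_objects()

    variants = [
        make_structural_variant(target, replace(spec.variant_spec, seed=int(s)))
        for s in rng.integers(2**31, size=profile.n_variants)
    ]
    reg_imgs, out_imgs = [], []
    for vm in variants:
        img = render_view(vm, spec.view, spec.geom)
        reg_imgs.append(img)
        out_imgs.append(to_outline(img))
    reg_imgs = np.stack(reg_imgs)
    out_imgs = np.stack(out_imgs)

    def maybe_augment(imgs):
        if spec.augmentation is None:
            return imgs
        return np.stack([augment(im, spec.augmentation, rng) for im in imgs])

    if spec.responder is not None:
        choices_reg = np.asarray(simulate_responses(spec.responder, list(maybe_augment(reg_imgs)), rng))
        choices_out = np.asarray(simulate_responses(spec.responder, list(maybe_augment(out_imgs)), rng))
    else:
        layer = spec.layer or spec.network.depth
        train_imgs, train_labels = [], []
        n_each = profile.n_train // (1 + len(distractors))
        for model, lab in [(target, 1)] + [(d, 0) for d in distractors]:
            for _ in range(n_each):
                img = render_view(model, spec.view, spec.geom)
                if spec.augmentation is not None:
                    img = augment(img, spec.augmentation, rng)
                train_imgs.append(img)
                train_labels.append(lab)
        train_imgs = np.stack(train_imgs)
        train_labels = np.array(train_labels)
        xtr = extract_activations(spec.network, layer, train_imgs).data
        xreg = extract_activations(spec.network, layer, maybe_augment(reg_imgs)).data
        xout = extract_activations(spec.network, layer, maybe_augment(out_imgs)).data
        xtr_z, xreg_z, kept = ro.zscore(xtr, xreg)
        mu, sd = xtr.mean(axis=0)[kept], xtr.std(axis=0)[kept]
        xout_z = (xout[:, kept] - mu) / sd
        svm = ro.train_readout(xtr_z, train_labels, seed=spec.seed)
        choices_reg = svm.predict(xreg_z).astype(int)
        choices_out = svm.predict(xout_z).astype(int)

    def style_map(imgs, choices):
        trials = sal.MaskedTrialSet(imgs, choices)
        return sal.permutation_significance_tripod(
            trials, profile.n_perm_tripod, spec.p_threshold, rng
        )

    smap_reg = style_map(reg_imgs, choices_reg)
    smap_out = style_map(out_imgs, choices_out)
    from .invariance import map_correlation, outline_consistency

    report = ExperimentReport(
        kind="variants",
        artifacts={
            "choice_fraction_regular": float(np.mean(choices_reg)),
            "choice_fraction_outline": float(np.mean(choices_out)),
            "saliency_regular": smap_reg,
            "saliency_outline": smap_out,
            "map_correlation": map_correlation(smap_reg.S, smap_out.S),
            "consistency": outline_consistency(choices_reg, choices_out),
        },
        provenance={"seed": spec.seed, "profile": profile.name,
                    "n_variants": profile.n_variants},
    )
    report.validate()
    return report
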