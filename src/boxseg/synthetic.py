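"""Synthetic multi-organ scenes, seen/unseen benchmarks and a robot user.

The generator emulates the premise that makes bounding-box segmentation of
unseen structures possible: every object class is salient against the
background (here: hyper-intense, with class-specific offset and texture)
while classes differ in geometry.  A subset of classes is used for
training; held-out classes play the role of previously unseen objects, so
the zero-shot behavior of the whole pipeline can be exercised without any
external data.

The robot user stands in for a human: it draws bounding boxes around
ground-truth instances and, given a predicted segmentation, places
corrective scribbles only inside mis-segmented areas — foreground
scribbles on the largest false-negative components, background scribbles
on the largest false-positive components, as skeleton segments capped in
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .crf import ScribbleSet
from .errors import InputError
from .instance_prep import (BoundingBox, TrainingInstance, extract_instances,
                            normalize_region, resize_for_network)


# ---------------------------------------------------------------------------
# Scene specification


@dataclass(frozen=True)
class ClassSpec:
    """One object class: shape family, contrast and texture."""

    family: str  # ellipse | lobed | bean | capsule (2D); ellipsoid | lobed (3D)
    intensity_offset: float = 0.3
    texture_sigma: float = 0.03
    count_range: tuple[int, int] = (1, 2)
    size_range: tuple[float, float] = (6.0, 13.0)  # nominal radius, pixels

    def __post_init__(self):
        if self.intensity_offset == 0:
            raise InputError("class intensity offset must be nonzero (objects are salient)")


@dataclass(frozen=True)
class SceneSpec:
    """Image geometry, class catalog and background noise model."""

    shape: tuple[int, ...] = (64, 64)
    classes: dict[str, ClassSpec] = field(default_factory=dict)
    background_level: float = 0.35
    noise_sigma: float = 0.04
    bias_field: bool = False
    bias_amplitude: float = 0.1
    seed: int = 0


DEFAULT_2D_CLASSES = {
    # seen: a smooth ellipse ("brain-like") and a lobed blob ("placenta-like")
    "ellipse": ClassSpec("ellipse", intensity_offset=0.35, texture_sigma=0.03),
    "lobed": ClassSpec("lobed", intensity_offset=0.30, texture_sigma=0.04),
    # unseen analogs sharing the hyper-intensity premise, different geometry
    "capsule": ClassSpec("capsule", intensity_offset=0.32, texture_sigma=0.03),
    "bean": ClassSpec("bean", intensity_offset=0.28, texture_sigma=0.04),
}


def default_scene_spec(class_names=None, shape=(64, 64), **overrides) -> SceneSpec:
    names = list(class_names) if class_names is not None else list(DEFAULT_2D_CLASSES)
    classes = {n: DEFAULT_2D_CLASSES[n] for n in names}
    return SceneSpec(shape=tuple(shape), classes=classes, **overrides)


@dataclass
class InstanceInfo:
    instance_id: int
    class_name: str
    label_value: int


@dataclass
class Scene:
    image: np.ndarray          # float, clipped to [0, 1]
    labels: np.ndarray         # class label per pixel, 0 background
    instance_map: np.ndarray   # instance id per pixel, 0 background
    instances: list[InstanceInfo]


# ---------------------------------------------------------------------------
# Shape rasterization


def _rot2(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _raster_2d(shape, family: str, center, radius: float, rng) -> np.ndarray:
    yy, xx = np.indices(shape).astype(np.float64)
    pts = np.stack([yy - center[0], xx - center[1]])
    rot = _rot2(rng.uniform(0, np.pi))
    u, v = np.tensordot(rot, pts, axes=1)
    aspect = rng.uniform(0.6, 0.95)
    a, b = radius, radius * aspect
    if family == "ellipse":
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if family == "lobed":
        theta = np.arctan2(v, u)
        r = np.hypot(u, v)
        wobble = np.ones_like(theta)
        for k in (2, 3, 5):
            wobble += rng.uniform(0.05, 0.18) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        return r <= radius * 0.85 * wobble
    if family == "capsule":
        # rounded bar: distance to a centered segment of half-length a
        half = a * 0.9
        t = np.clip(u, -half, half)
        return np.hypot(u - t, v) <= b * 0.55
    if family == "bean":
        body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        bite = ((u - 0.55 * a) / (0.75 * a)) ** 2 + (v / (0.6 * b)) ** 2 <= 1.0
        return body & ~bite
    raise InputError(f"unknown 2D shape family {family!r}")


def _raster_3d(shape, family: str, center, radius: float, rng) -> np.ndarray:
    zz, yy, xx = np.indices(shape).astype(np.float64)
    dz, dy, dx = zz - center[0], yy - center[1], xx - center[2]
    # thick-slice anisotropy: through-plane semi-axis shorter
    az = max(1.5, radius * rng.uniform(0.35, 0.6))
    ay = radius
    ax_ = radius * rng.uniform(0.7, 1.0)
    q = (dz / az) ** 2 + (dy / ay) ** 2 + (dx / ax_) ** 2
    if family in ("ellipse", "ellipsoid"):
        return q <= 1.0
    if family == "lobed":
        theta = np.arctan2(dx, dy)
        wobble = 1.0 + rng.uniform(0.08, 0.2) * np.cos(3 * theta + rng.uniform(0, 2 * np.pi))
        return q <= wobble
    raise InputError(f"unknown 3D shape family {family!r}")


def _smooth_field(shape, rng, scale=8, amplitude=0.1):
    coarse = rng.normal(0, 1, tuple(max(2, s // scale) for s in shape))
    field_ = ndimage.zoom(coarse, [s / c for s, c in zip(shape, coarse.shape)], order=3)
    field_ = field_[tuple(slice(0, s) for s in shape)]
    field_ /= max(1e-9, np.abs(field_).max())
    return 1.0 + amplitude * field_


# ---------------------------------------------------------------------------
# Scene generation


def generate_scene(spec: SceneSpec, seed: int | None = None) -> Scene:
    """Draw one scene with non-overlapping salient instances; deterministic
    given the seed (``spec.seed`` when ``seed`` is None)."""
    if not spec.classes:
        raise InputError("scene spec has no classes")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = spec.shape
    nd = len(shape)
    labels = np.zeros(shape, dtype=np.int32)
    inst_map = np.zeros(shape, dtype=np.int32)
    image = np.full(shape, spec.background_level, dtype=np.float64)
    instances: list[InstanceInfo] = []
    names = sorted(spec.classes)
    next_id = 1
    occupied = np.zeros(shape, dtype=bool)
    for label_value, name in enumerate(names, start=1):
        cs = spec.classes[name]
        count = int(rng.integers(cs.count_range[0], cs.count_range[1] + 1))
        placed = 0
        attempts = 0
        while placed < count and attempts < 300:
            attempts += 1
            radius = rng.uniform(*cs.size_range)
            margin = radius + 2
            center = [rng.uniform(margin, s - margin) if s > 2 * margin else s / 2
                      for s in shape]
            mask = (_raster_2d(shape, cs.family, center, radius, rng) if nd == 2
                    else _raster_3d(shape, cs.family, center, radius, rng))
            if not mask.any() or (mask & binary_dilate(occupied, 2)).any():
                continue
            labels[mask] = label_value
            inst_map[mask] = next_id
            tex = rng.normal(0, cs.texture_sigma, shape)
            image[mask] = spec.background_level + cs.intensity_offset + tex[mask]
            instances.append(InstanceInfo(next_id, name, label_value))
            occupied |= mask
            next_id += 1
            placed += 1
    image = np.clip(image, 0.0, 1.0)
    if spec.bias_field:
        image = image * _smooth_field(shape, rng, amplitude=spec.bias_amplitude)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, shape)
    return Scene(image, labels, inst_map, instances)


def binary_dilate(mask: np.ndarray, it: int) -> np.ndarray:
    if not mask.any():
        return mask
    return ndimage.binary_dilation(mask, iterations=it)


# ---------------------------------------------------------------------------
# Benchmark bundles


@dataclass
class TestCase:
    image: np.ndarray
    truth: np.ndarray          # binary instance mask, full canvas
    box: BoundingBox
    class_name: str
    unseen: bool


@dataclass
class Benchmark:
    train_instances: list[TrainingInstance]
    val_instances: list[TrainingInstance]
    test_cases: list[TestCase]
    seen_classes: tuple[str, ...]
    unseen_classes: tuple[str, ...]


def prepare_instance(inst: TrainingInstance, resize_mode="2d_min_side",
                     target=96) -> TrainingInstance:
    """Normalize and resize an instance for the network; the mask follows
    with nearest-neighbor interpolation."""
    region = resize_for_network(normalize_region(inst.region), resize_mode, target)
    from .instance_prep import _resize_array
    mask = _resize_array(inst.mask.astype(np.float32), region.shape, order=0)
    return TrainingInstance(region, (mask > 0.5).astype(np.uint8),
                            inst.source_image_id, inst.source_label)


def make_benchmark(seen_classes, unseen_classes, n_train: int, n_test: int,
                   seed: int, shape=(64, 64), n_val: int = 0,
                   resize_mode="2d_min_side", resize_target=96,
                   spec_overrides: dict | None = None) -> Benchmark:
    """Build a seen/unseen split: training instances come only from the
    seen classes; test instances cover all classes, tagged by novelty."""
    seen = tuple(seen_classes)
    unseen = tuple(unseen_classes)
    if set(seen) & set(unseen):
        raise InputError("seen and unseen class sets must be disjoint")
    overrides = spec_overrides or {}
    rng = np.random.default_rng(seed)
    train_spec = default_scene_spec(seen, shape=shape, **overrides)

    def collect(spec, n, margin_range=(0, 10), offset=0):
        out = []
        scene_seed = offset
        while len(out) < n:
            scene = generate_scene(spec, seed=int(rng.integers(2 ** 31)))
            insts = extract_instances(scene.image, scene.labels, rng,
                                      margin_range=margin_range,
                                      instance_map=scene.instance_map,
                                      image_id=scene_seed)
            names = {i.instance_id: i.class_name for i in scene.instances}
            for info, inst in zip(scene.instances, insts):
                inst.source_label = info.class_name
                out.append(inst)
            scene_seed += 1
        return out[:n]

    train_raw = collect(train_spec, n_train)
    val_raw = collect(train_spec, n_val) if n_val else []
    train_instances = [prepare_instance(i, resize_mode, resize_target) for i in train_raw]
    val_instances = [prepare_instance(i, resize_mode, resize_target) for i in val_raw]

    all_names = seen + unseen
    test_spec = default_scene_spec(all_names, shape=shape, **overrides)
    test_cases: list[TestCase] = []
    per_class: dict[str, int] = {n: 0 for n in all_names}
    quota = {n: n_test // len(all_names) + (1 if k < n_test % len(all_names) else 0)
             for k, n in enumerate(all_names)}
    while any(per_class[n] < quota[n] for n in all_names):
        scene = generate_scene(test_spec, seed=int(rng.integers(2 ** 31)))
        for info in scene.instances:
            if per_class[info.class_name] >= quota[info.class_name]:
                continue
            truth = scene.instance_map == info.instance_id
            tight = BoundingBox.of_mask(truth)
            m_lo = rng.integers(0, 11, size=len(shape))
            m_hi = rng.integers(0, 11, size=len(shape))
            box = tight.expanded(m_lo, m_hi, shape)
            test_cases.append(TestCase(scene.image, truth.astype(np.uint8), box,
                                       info.class_name, info.class_name in unseen))
            per_class[info.class_name] += 1
    return Benchmark(train_instances, val_instances, test_cases, seen, unseen)


# ---------------------------------------------------------------------------
# Robot user


@dataclass(frozen=True)
class RobotUserPolicy:
    """How the simulated user draws corrective scribbles."""

    length_range: tuple[int, int] = (4, 20)
    max_components: int = 2  # per label per round
    seed: int = 0


def _skeleton_scribble(component: np.ndarray, length: int) -> np.ndarray:
    """A length-capped run of skeleton pixels of one mis-segmented component."""
    if component.sum() <= 3:
        return component.copy()
    skel = skeletonize(component)
    if not skel.any():
        skel = ndimage.binary_erosion(component)
        if not skel.any():
            skel = component
    coords = np.argwhere(skel)
    # deterministic start: the skeleton pixel deepest inside the component
    edt = ndimage.distance_transform_edt(component)
    start = coords[np.argmax(edt[tuple(coords.T)])]
    coord_set = {tuple(c) for c in map(tuple, coords)}
    run = [tuple(start)]
    seen = {tuple(start)}
    frontier = [tuple(start)]
    nd = component.ndim
    offsets = [o for o in np.ndindex(*(3,) * nd) if any(v != 1 for v in o)]
    while frontier and len(run) < length:
        nxt = []
        for c in frontier:
            for o in offsets:
                nb = tuple(ci + oi - 1 for ci, oi in zip(c, o))
                if nb in coord_set and nb not in seen:
                    seen.add(nb)
                    run.append(nb)
                    nxt.append(nb)
                    if len(run) >= length:
                        break
            if len(run) >= length:
                break
        frontier = sorted(nxt)
    out = np.zeros_like(component)
    out[tuple(np.array(run).T)] = True
    return out


def robot_scribbles(pred: np.ndarray, truth: np.ndarray,
                    policy: RobotUserPolicy = RobotUserPolicy(),
                    seed: int | None = None) -> ScribbleSet:
    """Corrective scribbles strictly inside mis-segmented areas.

    Foreground scribbles go on the largest false-negative components,
    background scribbles on the largest false-positive components; a
    perfect prediction gets an empty set.  Deterministic given the seed.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise InputError("prediction and truth shapes differ")
    rng = np.random.default_rng(policy.seed if seed is None else seed)
    out = {}
    for key, wrong in (("fg", truth & ~pred), ("bg", pred & ~truth)):
        mask = np.zeros(pred.shape, dtype=bool)
        if wrong.any():
            comp, n = ndimage.label(wrong)
            sizes = ndimage.sum_labels(wrong, comp, index=np.arange(1, n + 1))
            order = np.argsort(sizes)[::-1][:policy.max_components]
            for ci in order:
                length = int(rng.integers(policy.length_range[0],
                                          policy.length_range[1] + 1))
                mask |= _skeleton_scribble(comp == ci + 1, length)
        out[key] = mask
    return ScribbleSet(out["fg"], out["bg"])
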