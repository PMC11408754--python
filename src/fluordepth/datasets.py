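"""Seeded training/test dataset assembly.

Binds the shape generators, the randomized optics draws, the SFDI simulator
and the LUT inversion into network-ready samples.  Training draws follow the
study conditions: widths U(10, 40) mm, depths U(1, 10) mm, mu_a
U(0.0015, 0.015) mm^-1, mu_s' U(0.75, 2) mm^-1, concentration U(1, 10)
ug/mL, and -- when background fluorescence is enabled -- a background level
of U(0.1%, 50%) of the tumor concentration.  Test sets fix the optics at
mu_a = 0.0045 mm^-1, mu_s' = 1 mm^-1 and C = 5 ug/mL.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np

from .grid import DEFAULT_GRID, GridSpec
from .lut import LUT, OpticalPropertyMaps, build_lut, optical_property_maps
from .optics import (
    CONCENTRATION_RANGE,
    DEFAULT_PHOTON_BUDGET,
    MU_A_RANGE,
    MU_S_PRIME_RANGE,
    FluorophoreSpec,
    OpticalProperties,
    SFDIStack,
    load_stack,
    save_stack,
    simulate_sample,
)
from .shapes import (
    DEPTH_RANGE_MM,
    WIDTH_RANGE_MM,
    GroundTruthMaps,
    ShapeVolume,
    augment_mesh,
    ground_truth_maps,
    max_depth_mm,
    random_csh,
    random_cylinder,
    random_spherical_harmonic,
)

__all__ = [
    "SampleRecord",
    "DatasetManifest",
    "Normalizer",
    "generate_training_set",
    "generate_test_set",
    "load_sample",
    "default_lut",
    "TEST_PROPS",
    "TEST_CONCENTRATION",
]

BG_FRACTION_RANGE = (0.001, 0.5)
TEST_PROPS = OpticalProperties(0.0045, 1.0)
TEST_CONCENTRATION = 5.0  # ug/mL

_FAMILIES = {
    "cylinder": random_cylinder,
    "sh": random_spherical_harmonic,
    "csh": random_csh,
}


@functools.lru_cache(maxsize=1)
def default_lut() -> LUT:
    """Shared 200 x 200 lookup table at the default refractive index."""
    return build_lut()


@dataclass
class SampleRecord:
    """One simulated sample and the randomized values that produced it."""

    id: str
    family: str
    mu_a: float
    mu_s_prime: float
    concentration: float
    bg_fraction: float
    seed: int
    provenance: dict = field(default_factory=dict)
    out_of_range: bool = False
    split: str = "train"
    # payload (in memory, or on disk under DatasetManifest.root / id)
    stack: SFDIStack | None = None
    prop_maps: OpticalPropertyMaps | None = None
    truth: GroundTruthMaps | None = None

    def header(self) -> dict:
        return {
            "id": self.id,
            "family": self.family,
            "mu_a": self.mu_a,
            "mu_s_prime": self.mu_s_prime,
            "concentration": self.concentration,
            "bg_fraction": self.bg_fraction,
            "seed": self.seed,
            "provenance": self.provenance,
            "out_of_range": self.out_of_range,
            "split": self.split,
        }


@dataclass
class Normalizer:
    """Input/target scaling shared by dataset assembly and the network.

    Property maps are min-max scaled by the training optics ranges, the
    fluorescence stack by a dataset-level 99th percentile, and the two
    targets by 10 mm and 10 ug/mL so the heads are commensurate.
    """

    fluor_p99: float
    mu_a_range: tuple = MU_A_RANGE
    mu_s_range: tuple = MU_S_PRIME_RANGE
    depth_scale: float = 10.0
    conc_scale: float = 10.0

    def inputs(self, prop_maps: OpticalPropertyMaps, fluorescence: np.ndarray):
        a = (prop_maps.mu_a - self.mu_a_range[0]) / (self.mu_a_range[1] - self.mu_a_range[0])
        s = (prop_maps.mu_s_prime - self.mu_s_range[0]) / (
            self.mu_s_range[1] - self.mu_s_range[0]
        )
        props = np.stack([a, s]).astype(np.float32)
        fluo = (fluorescence / self.fluor_p99).astype(np.float32)
        return props, fluo

    def targets(self, truth: GroundTruthMaps) -> np.ndarray:
        return np.stack(
            [truth.depth_mm / self.depth_scale, truth.concentration / self.conc_scale]
        ).astype(np.float32)

    def denormalize_targets(self, y: np.ndarray):
        """Inverse of :meth:`targets`: (depth_mm, concentration) maps."""
        return y[0] * self.depth_scale, y[1] * self.conc_scale

    def to_dict(self) -> dict:
        return {
            "fluor_p99": self.fluor_p99,
            "mu_a_range": list(self.mu_a_range),
            "mu_s_range": list(self.mu_s_range),
            "depth_scale": self.depth_scale,
            "conc_scale": self.conc_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            fluor_p99=d["fluor_p99"],
            mu_a_range=tuple(d["mu_a_range"]),
            mu_s_range=tuple(d["mu_s_range"]),
            depth_scale=d["depth_scale"],
            conc_scale=d["conc_scale"],
        )


@dataclass
class DatasetManifest:
    """Ordered sample collection with split tags and generation config."""

    records: list
    seed: int
    config: dict
    normalizer: Normalizer | None = None
    root: Path | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")

    def subset(self, split: str) -> list:
        return [r for r in self.records if r.split == split]

    def save(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(json.dumps({"seed": self.seed, "config": self.config,
                                 "normalizer": self.normalizer.to_dict() if self.normalizer else None}) + "\n")
            for rec in self.records:
                fh.write(json.dumps(rec.header()) + "\n")

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        lines = path.read_text().splitlines()
        head = json.loads(lines[0])
        records = [SampleRecord(**json.loads(ln)) for ln in lines[1:]]
        norm = Normalizer.from_dict(head["normalizer"]) if head.get("normalizer") else None
        return cls(records=records, seed=head["seed"], config=head["config"],
                   normalizer=norm, root=path.parent)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _simulate_record(
    sample_id: str,
    family: str,
    shape: ShapeVolume,
    props: OpticalProperties,
    concentration: float,
    bg_fraction: float,
    rng: np.random.Generator,
    seed: int,
    lut: LUT,
    photon_budget,
    allow_protrusion: bool = False,
    out_of_range: bool = False,
) -> SampleRecord:
    fluor = FluorophoreSpec(concentration=concentration)
    stack, truth = simulate_sample(
        shape, props, fluor, rng,
        photon_budget=photon_budget,
        bg_fraction=bg_fraction,
        allow_protrusion=allow_protrusion,
    )
    maps = optical_property_maps(stack, lut)
    return SampleRecord(
        id=sample_id,
        family=family,
        mu_a=props.mu_a,
        mu_s_prime=props.mu_s_prime,
        concentration=concentration,
        bg_fraction=bg_fraction,
        seed=seed,
        provenance=shape.provenance,
        out_of_range=out_of_range,
        stack=stack,
        prop_maps=maps,
        truth=truth,
    )


def generate_training_set(
    family: str,
    n: int,
    bg_enabled: bool = False,
    seed: int = 0,
    grid: GridSpec = DEFAULT_GRID,
    lut: LUT | None = None,
    photon_budget=DEFAULT_PHOTON_BUDGET,
    val_fraction: float = 0.1,
    out_dir=None,
) -> DatasetManifest:
    """Generate ``n`` training samples of one shape family, seeded.

    Every randomized quantity is drawn from its training interval; samples
    are split 90/10 into train/val under the same master seed.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    if n < 0:
        raise ValueError("n must be >= 0")
    lut = lut if lut is not None else default_lut()
    draw = _FAMILIES[family]
    children = np.random.SeedSequence(seed).spawn(n)
    records = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        shape = draw(rng, grid)
        props = OpticalProperties(rng.uniform(*MU_A_RANGE), rng.uniform(*MU_S_PRIME_RANGE))
        conc = rng.uniform(*CONCENTRATION_RANGE)
        bg = rng.uniform(*BG_FRACTION_RANGE) if bg_enabled else 0.0
        rec = _simulate_record(
            f"{family}-{i:05d}", family, shape, props, conc, bg,
            rng, i, lut, photon_budget,
        )
        records.append(rec)
    split_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5917]))
    n_val = int(round(val_fraction * n))
    val_idx = set(split_rng.permutation(n)[:n_val].tolist())
    for i, rec in enumerate(records):
        rec.split = "val" if i in val_idx else "train"
    manifest = DatasetManifest(
        records=records,
        seed=seed,
        config={"family": family, "n": n, "bg_enabled": bg_enabled,
                "photon_budget": photon_budget, "grid": grid.to_dict()},
    )
    manifest.normalizer = _fit_normalizer(manifest)
    if out_dir is not None:
        _persist(manifest, out_dir)
    return manifest


def _fit_normalizer(manifest: DatasetManifest) -> Normalizer:
    train = manifest.subset("train") or manifest.records
    if not train:
        return Normalizer(fluor_p99=1.0)
    vals = np.concatenate([r.stack.fluorescence.ravel() for r in train])
    p99 = float(np.percentile(vals, 99))
    return Normalizer(fluor_p99=p99 if p99 > 0 else 1.0)


def generate_test_set(
    family_or_meshes,
    n: int = 100,
    seed: int = 0,
    bg_enabled: bool = False,
    grid: GridSpec = DEFAULT_GRID,
    lut: LUT | None = None,
    photon_budget=DEFAULT_PHOTON_BUDGET,
    target_depth_mm: float | None = None,
) -> DatasetManifest:
    """Generate a test set at the fixed test optics.

    ``family_or_meshes`` is either a shape family name or a sequence of
    watertight surface meshes (patient-mesh mode).  Mesh mode scales each
    mesh to training-range widths/depths, rotates it about z by U(-180, 180)
    deg and preserves protrusion above the surface; ``target_depth_mm``
    forces a fixed (possibly out-of-training-range) depth, in which case the
    record is flagged.
    """
    lut = lut if lut is not None else default_lut()
    children = np.random.SeedSequence([seed, 0x7e57]).spawn(max(n, 1))
    records = []
    mesh_mode = not isinstance(family_or_meshes, str)
    if mesh_mode:
        meshes = list(family_or_meshes)
        if not meshes:
            raise ValueError("mesh mode requires at least one mesh")
        bad = [i for i, m in enumerate(meshes) if not m.is_watertight]
        if bad:
            raise ValueError(f"meshes at indices {bad} are not watertight")
    for i in range(n):
        rng = np.random.default_rng(children[i])
        bg = rng.uniform(*BG_FRACTION_RANGE) if bg_enabled else 0.0
        if mesh_mode:
            mesh = meshes[i % len(meshes)]
            shape, oor = _augmented_mesh_shape(mesh, rng, grid, target_depth_mm)
            rec = _simulate_record(
                f"mesh-{i:05d}", "mesh", shape, TEST_PROPS, TEST_CONCENTRATION,
                bg, rng, i, lut, photon_budget,
                allow_protrusion=True, out_of_range=oor,
            )
        else:
            shape = _FAMILIES[family_or_meshes](rng, grid)
            rec = _simulate_record(
                f"{family_or_meshes}-test-{i:05d}", family_or_meshes, shape,
                TEST_PROPS, TEST_CONCENTRATION, bg, rng, i, lut, photon_budget,
            )
        rec.split = "test"
        records.append(rec)
    return DatasetManifest(
        records=records,
        seed=seed,
        config={
            "mode": "mesh" if mesh_mode else family_or_meshes,
            "n": n,
            "bg_enabled": bg_enabled,
            "props": [TEST_PROPS.mu_a, TEST_PROPS.mu_s_prime],
            "concentration": TEST_CONCENTRATION,
            "target_depth_mm": target_depth_mm,
        },
    )


def _augmented_mesh_shape(mesh, rng, grid, target_depth_mm=None):
    """Draw augmentation targets, scale/rotate the mesh, and voxelize."""
    wx, wy = rng.uniform(*WIDTH_RANGE_MM, size=2)
    depth = target_depth_mm if target_depth_mm is not None else rng.uniform(*DEPTH_RANGE_MM)
    rot = rng.uniform(-180.0, 180.0)
    # measure the rotated bounds, then solve axis scales for the targets
    ang = np.deg2rad(rot)
    c, s = np.cos(ang), np.sin(ang)
    rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    v = (rz @ np.asarray(mesh.vertices, dtype=float).T).T
    depth_extent = v[:, 2].max() - min(v[:, 2].min(), 0.0)
    sx = wx / (v[:, 0].max() - v[:, 0].min())
    sy = wy / (v[:, 1].max() - v[:, 1].min())
    sz = depth / depth_extent
    shape = augment_mesh(mesh, (sx, sy, sz), rot, grid)
    oor = bool(depth > DEPTH_RANGE_MM[1] + 1e-9)
    shape.provenance.update({"targets_mm": (wx, wy, depth), "rot_z_deg": rot})
    return shape, oor


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_sample(record: SampleRecord, normalizer: Normalizer, root=None):
    """Network input/target arrays for one record.

    Returns ``((props, fluorescence), targets)`` with shapes (2, nx, ny),
    (n_fx, nx, ny) and (2, nx, ny), normalized per the network scheme.
    """
    if record.stack is None:
        if root is None:
            raise ValueError(f"record {record.id} has no payload and no root directory")
        _load_payload(record, root)
    props, fluo = normalizer.inputs(record.prop_maps, record.stack.fluorescence)
    targets = normalizer.targets(record.truth)
    return (props, fluo), targets


def _persist(manifest: DatasetManifest, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in manifest.records:
        d = out_dir / rec.id
        d.mkdir(exist_ok=True)
        save_stack(d / "stack.tiff", rec.stack)
        np.savez_compressed(
            d / "maps.npz",
            mu_a=rec.prop_maps.mu_a,
            mu_s_prime=rec.prop_maps.mu_s_prime,
            flag=rec.prop_maps.flag,
            depth_mm=rec.truth.depth_mm,
            concentration=rec.truth.concentration,
        )
    manifest.root = out_dir
    manifest.save(out_dir / "manifest.jsonl")


def _load_payload(record: SampleRecord, root) -> None:
    d = Path(root) / record.id
    if not d.exists():
        raise FileNotFoundError(f"sample directory missing for record {record.id}")
    record.stack = load_stack(d / "stack.tiff")
    with np.load(d / "maps.npz") as f:
        record.prop_maps = OpticalPropertyMaps(
            mu_a=f["mu_a"], mu_s_prime=f["mu_s_prime"], flag=f["flag"]
        )
        record.truth = GroundTruthMaps(
            depth_mm=f["depth_mm"], concentration=f["concentration"]
        )


def manifest_to_arrays(manifest: DatasetManifest, split: str | None = None):
    """Stack a manifest (or one split) into batched float32 arrays.

    Returns (props (N,2,H,W), fluorescence (N,6,H,W), targets (N,2,H,W)).
    """
    recs = manifest.subset(split) if split else manifest.records
    norm = manifest.normalizer
    if norm is None:
        raise ValueError("manifest has no fitted normalizer")
    xs_p, xs_f, ys = [], [], []
    for rec in recs:
        (p, f), y = load_sample(rec, norm, manifest.root)
        xs_p.append(p)
        xs_f.append(f)
        ys.append(y)
    return np.stack(xs_p), np.stack(xs_f), np.stack(ys)
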