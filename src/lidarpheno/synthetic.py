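"""Synthetic maize-scene generator with exact ground truth.

Plants are a vertical stem cylinder plus ruled ribbon leaves (chained
straight segments of constant width, drooping outward), placed on a
regular planting grid over smooth sinusoidal terrain.  Each leaf is
built entirely inside one of the plant's five equal height strata, so
the requested one-sided area per stratum is met exactly; the truth
record is nevertheless recomputed analytically from the surface mesh.
Sensor realism is limited to uniform-random surface sampling at a target
density, height-biased occlusion, and uniform outlier injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .cloud import GROUND, VEGETATION, PointCloud
from .errors import InfeasibleLeafAreaError, LidarPhenoError
from .geometry import areas_per_slab

N_LAYERS = 5


@dataclass(frozen=True)
class PlantSpec:
    """Target morphology of one synthetic plant."""

    height: float
    leaf_count_per_layer: tuple[int, ...]
    one_sided_area_per_layer: tuple[float, ...]
    leaf_inclination_mean: float = 60.0  # deg above horizontal
    stem_diameter: float = 0.02
    projected_fraction_target: float | None = None
    droop: float = 25.0  # deg of inclination lost tip-ward along the leaf

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if len(self.leaf_count_per_layer) != N_LAYERS or \
                len(self.one_sided_area_per_layer) != N_LAYERS:
            raise ValueError(f"need {N_LAYERS} per-layer entries")
        if any(a < 0 for a in self.one_sided_area_per_layer):
            raise ValueError("leaf areas must be >= 0")
        if self.projected_fraction_target is not None and not \
                0.0 <= self.projected_fraction_target <= 1.0:
            raise ValueError("projected_fraction_target must be in [0, 1]")
        if self.stem_diameter <= 0:
            raise ValueError("stem_diameter must be > 0")


@dataclass(frozen=True)
class SceneSpec:
    """Layout and sensor model of a synthetic plot."""

    n_varieties: int
    plants_per_variety: int
    column_spacing: float = 0.50
    row_spacing: float = 0.30
    terrain_amplitude: float = 0.0
    sensor_point_spacing: float = 0.004
    outlier_rate: float = 0.0
    occlusion_rate: float = 0.0
    seed: int = 0
    ground_margin: float = 0.3

    def __post_init__(self):
        if self.column_spacing <= 0 or self.row_spacing <= 0:
            raise ValueError("spacings must be > 0")
        for name in ("outlier_rate", "occlusion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sensor_point_spacing <= 0:
            raise ValueError("sensor_point_spacing must be > 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__ | {}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class GroundTruthRecord:
    """Exact per-plant truth computed from the generating surfaces."""

    plant_id: str
    true_height: float
    true_area_per_layer: np.ndarray        # 5 x m^2
    true_pad_per_layer: np.ndarray         # 5 x m^2/m^3
    true_pai: float                        # m^2/m^2, sum(PAD_k * dH)
    true_pla: float
    cell_bounds: tuple[float, float, float, float]
    n_leaf_points: int = 0
    n_stem_points: int = 0


@dataclass
class TerrainTruth:
    """Smooth terrain: sum of two low-frequency sinusoids."""

    amplitude: float
    wavelengths: tuple[float, float] = (8.0, 5.0)
    phases: tuple[float, float] = (0.0, 0.0)

    def elevation(self, x, y):
        if self.amplitude == 0.0:
            return np.zeros_like(np.asarray(x, dtype=float))
        lx, ly = self.wavelengths
        px, py = self.phases
        return self.amplitude * (
            0.6 * np.sin(2 * np.pi * np.asarray(x) / lx + px)
            + 0.4 * np.sin(2 * np.pi * np.asarray(y) / ly + py))


@dataclass
class Scene:
    """A generated plot: the cloud plus everything the generator knows."""

    cloud: PointCloud                      # unlabeled, for the pipeline
    true_labels: np.ndarray                # GROUND/VEGETATION/OUTLIER codes
    plant_index: np.ndarray                # per point; -1 = not a plant
    records: list[GroundTruthRecord]
    terrain: TerrainTruth
    spec: SceneSpec
    plant_specs: list[PlantSpec] = field(default_factory=list)


# ----------------------------------------------------------- plants

def _ray_box_distance(px: float, py: float, dx: float, dy: float,
                      hx: float, hy: float) -> float:
    """Distance from (px, py) to the rectangle |x|<=hx, |y|<=hy along
    direction (dx, dy)."""
    ts = []
    if abs(dx) > 1e-12:
        ts.append(((hx if dx > 0 else -hx) - px) / dx)
    if abs(dy) > 1e-12:
        ts.append(((hy if dy > 0 else -hy) - py) / dy)
    ts = [t for t in ts if t > 0]
    return min(ts) if ts else 0.0


def _build_leaf(rng, attach, azimuth_deg, incl_deg, droop_deg, area,
                z_lo, z_hi, half_cell, layer, n_seg=4, aspect=7.0,
                w_max=0.13):
    """Return (quads, triangles) for one ribbon leaf of exact one-sided
    area `area`, entirely inside [z_lo, z_hi) and the cell footprint."""
    az = math.radians(azimuth_deg)
    angles = np.radians(np.clip(
        incl_deg + droop_deg / 2
        - droop_deg * (np.arange(n_seg) + 0.5) / n_seg, 3.0, 85.0))
    rise_frac = float(np.sin(angles).mean())
    run_frac = float(np.cos(angles).mean())
    room = z_hi - z_lo - 0.01
    if room <= 0:
        raise InfeasibleLeafAreaError(layer, "stratum too thin for a leaf")
    l_pref = max(math.sqrt(area * aspect), area / w_max)
    width = min(w_max, math.sqrt(area / aspect))
    length = l_pref
    for _ in range(6):
        # shrink the footprint by half the ribbon width so the side
        # edges stay inside the cell, then ray-cast to the boundary
        hx = half_cell[0] - width / 2 - 0.004
        hy = half_cell[1] - width / 2 - 0.004
        if hx <= 0 or hy <= 0:
            raise InfeasibleLeafAreaError(
                layer, f"ribbon width {width:.3f} m exceeds the cell")
        r_avail = _ray_box_distance(attach[0], attach[1],
                                    math.cos(az), math.sin(az), hx, hy)
        l_v = room / rise_frac
        l_h = r_avail / max(run_frac, 1e-6)
        length = min(l_pref, l_v, l_h)
        if length <= 1e-4:
            raise InfeasibleLeafAreaError(
                layer, f"no room for a leaf of area {area:.4f} m^2")
        width = area / length
    if width > w_max + 1e-9:
        raise InfeasibleLeafAreaError(
            layer, f"area {area:.4f} m^2 needs width {width:.3f} m "
            f"> {w_max} m within the cell footprint")

    rise = length * rise_frac
    z_base = z_lo + 0.005 + float(rng.random()) * max(room - rise, 0.0)
    u = np.array([-math.sin(az), math.cos(az), 0.0])  # width direction
    dirs = np.stack([np.cos(angles) * math.cos(az),
                     np.cos(angles) * math.sin(az),
                     np.sin(angles)], axis=1)
    seg = length / n_seg
    spine = np.empty((n_seg + 1, 3))
    spine[0] = (attach[0], attach[1], z_base)
    for j in range(n_seg):
        spine[j + 1] = spine[j] + seg * dirs[j]
    quads, tris = [], []
    for j in range(n_seg):
        a = spine[j] - u * width / 2
        b = spine[j] + u * width / 2
        c = spine[j + 1] + u * width / 2
        d = spine[j + 1] - u * width / 2
        quads.append(np.array([a, b, c, d]))
        tris.append(np.array([a, b, c]))
        tris.append(np.array([a, c, d]))
    return quads, tris


def _sample_quads(rng, quads, spacing):
    """Uniform-random points on a set of quads, count = round(area/s^2)."""
    areas = np.array([np.linalg.norm(np.cross(q[1] - q[0], q[3] - q[0]))
                      for q in quads])
    total = areas.sum()
    n_total = int(round(total / spacing ** 2))
    if n_total <= 0:
        n_total = 1
    counts = rng.multinomial(n_total, areas / total)
    pts = []
    for q, m in zip(quads, counts):
        if m == 0:
            continue
        s = rng.random(m)[:, None]
        t = rng.random(m)[:, None]
        pts.append(q[0] + s * (q[1] - q[0]) + t * (q[3] - q[0]))
    return np.vstack(pts) if pts else np.empty((0, 3))


def generate_plant(spec: PlantSpec, point_spacing: float, seed: int,
                   cell: tuple[float, float] = (0.50, 0.30),
                   plant_id: str = "p0",
                   ) -> tuple[PointCloud, GroundTruthRecord]:
    """Generate one plant in a local frame centered on its cell.

    Returns the sampled point cloud (vegetation-labeled) and a truth
    record computed analytically from the generating surfaces.
    """
    if point_spacing <= 0:
        raise LidarPhenoError("point_spacing must be > 0")
    rng = np.random.default_rng(seed)
    half_cell = (cell[0] / 2, cell[1] / 2)
    cell_area = cell[0] * cell[1]
    h = spec.height
    dh = h / N_LAYERS
    r_stem = spec.stem_diameter / 2

    quads_all, tris_all = [], []
    # ranks roughly follow the long cell axis so large leaves fit
    base_az = float(rng.normal(0, 12))
    leaf_no = 0
    for k in range(N_LAYERS):
        area_k = spec.one_sided_area_per_layer[k]
        if area_k <= 0:
            continue
        n_leaves = max(1, int(spec.leaf_count_per_layer[k]))
        z_lo, z_hi = k * dh, (k + 1) * dh
        for _ in range(n_leaves):
            last_err = None
            for attempt in range(12):
                # steepen on retries: erect leaves need less room
                incl = float(np.clip(
                    rng.normal(spec.leaf_inclination_mean, 6)
                    + 4.0 * attempt, 15, 82))
                # distichous arrangement: leaves alternate between two
                # opposite ranks, so projections stack; widen the jitter
                # on retries until the ribbon fits
                az = (base_az + (leaf_no % 2) * 180.0
                      + rng.normal(0, 6 + 15 * attempt))
                if attempt >= 8:
                    # deterministic fallback along the long cell axis
                    az = (leaf_no % 2) * 180.0 + (attempt - 9) * 7.0
                attach = (r_stem * math.cos(math.radians(az)),
                          r_stem * math.sin(math.radians(az)))
                try:
                    quads, tris = _build_leaf(
                        rng, attach, az, incl, spec.droop,
                        area_k / n_leaves, z_lo, z_hi, half_cell,
                        layer=k + 1)
                    break
                except InfeasibleLeafAreaError as err:
                    last_err = err
            else:
                raise last_err
            quads_all.extend(quads)
            tris_all.extend(tris)
            leaf_no += 1

    leaf_pts = (_sample_quads(rng, quads_all, point_spacing)
                if quads_all else np.empty((0, 3)))

    # stem: lateral cylinder surface + an exact top ring
    stem_area = 2 * math.pi * r_stem * h
    n_stem = max(4, int(round(stem_area / point_spacing ** 2)))
    phi = rng.uniform(0, 2 * math.pi, n_stem)
    zs = rng.uniform(0, h, n_stem)
    stem_pts = np.column_stack([r_stem * np.cos(phi), r_stem * np.sin(phi),
                                zs])
    top_phi = np.linspace(0, 2 * math.pi, 8, endpoint=False)
    top_ring = np.column_stack([r_stem * np.cos(top_phi),
                                r_stem * np.sin(top_phi),
                                np.full(8, h)])
    stem_pts = np.vstack([stem_pts, top_ring])

    xyz = np.vstack([leaf_pts, stem_pts])
    cloud = PointCloud(xyz, np.full(len(xyz), VEGETATION, dtype=np.int8))

    # truth from the mesh, not from the request
    if tris_all:
        areas = areas_per_slab(np.stack(tris_all), np.linspace(0, h, 6))
    else:
        areas = np.zeros(N_LAYERS)
    pads = areas / (cell_area * dh)
    pai = float(pads.sum() * dh)

    shapes = [Point(0, 0).buffer(r_stem, quad_segs=16)]
    for q in quads_all:
        poly = Polygon(q[:, :2])
        if not poly.is_valid:
            poly = poly.buffer(0)
        shapes.append(poly)
    footprint = unary_union(shapes).intersection(
        box(-half_cell[0], -half_cell[1], half_cell[0], half_cell[1]))
    pla = float(footprint.area / cell_area)

    record = GroundTruthRecord(
        plant_id=plant_id, true_height=h,
        true_area_per_layer=areas, true_pad_per_layer=pads,
        true_pai=pai, true_pla=pla,
        cell_bounds=(-half_cell[0], -half_cell[1],
                     half_cell[0], half_cell[1]),
        n_leaf_points=len(leaf_pts), n_stem_points=len(stem_pts))
    return cloud, record


# ------------------------------------------------------------ scenes

def generate_scene(scene: SceneSpec, plant_specs: list[PlantSpec]) -> Scene:
    """Place plants on the grid, add terrain, ground, occlusion, outliers."""
    n_cells = scene.n_varieties * scene.plants_per_variety
    if len(plant_specs) == scene.n_varieties:
        plant_specs = [plant_specs[c] for c in range(scene.n_varieties)
                       for _ in range(scene.plants_per_variety)]
    if len(plant_specs) != n_cells:
        raise LidarPhenoError(
            f"need {n_cells} plant specs (or one per variety), "
            f"got {len(plant_specs)}")
    rng = np.random.default_rng(scene.seed)
    terrain = TerrainTruth(
        amplitude=scene.terrain_amplitude,
        phases=(float(rng.uniform(0, 2 * np.pi)),
                float(rng.uniform(0, 2 * np.pi))))

    cs, rs = scene.column_spacing, scene.row_spacing
    xyz_parts, plant_idx_parts, records = [], [], []
    heights = []
    cell = (cs, rs)
    i = 0
    for col in range(scene.n_varieties):
        for row in range(scene.plants_per_variety):
            cx, cy = (col + 0.5) * cs, (row + 0.5) * rs
            seed_i = int(rng.integers(0, 2 ** 31 - 1))
            cloud, rec = generate_plant(
                plant_specs[i], scene.sensor_point_spacing, seed_i,
                cell=cell, plant_id=f"c{col}_r{row}")
            pts = cloud.xyz.copy()
            base_z = float(terrain.elevation(cx, cy))
            pts[:, 0] += cx
            pts[:, 1] += cy
            pts[:, 2] += base_z
            rec.cell_bounds = (col * cs, row * rs, (col + 1) * cs,
                               (row + 1) * rs)
            records.append(rec)
            xyz_parts.append(pts)
            plant_idx_parts.append(np.full(len(pts), i, dtype=np.int32))
            heights.append((rec.true_height, base_z))
            i += 1

    veg = np.vstack(xyz_parts)
    veg_plant = np.concatenate(plant_idx_parts)

    # height-biased occlusion: lower canopy is harder to scan
    if scene.occlusion_rate > 0 and len(veg):
        z_rel = np.empty(len(veg))
        for j, (h, bz) in enumerate(heights):
            m = veg_plant == j
            z_rel[m] = np.clip((veg[m, 2] - bz) / h, 0, 1)
        w = 1.0 - z_rel
        p = np.clip(scene.occlusion_rate * w / max(w.mean(), 1e-12), 0, 1)
        keep = rng.random(len(veg)) >= p
        veg, veg_plant = veg[keep], veg_plant[keep]

    # ground: jittered grid over the plot plus a margin
    m = scene.ground_margin
    gx0, gy0 = -m, -m
    gx1 = scene.n_varieties * cs + m
    gy1 = scene.plants_per_variety * rs + m
    sp = scene.sensor_point_spacing
    nx = max(2, int(round((gx1 - gx0) / sp)))
    ny = max(2, int(round((gy1 - gy0) / sp)))
    gx = gx0 + (np.arange(nx) + 0.5) * (gx1 - gx0) / nx
    gy = gy0 + (np.arange(ny) + 0.5) * (gy1 - gy0) / ny
    gxx, gyy = np.meshgrid(gx, gy)
    gxx = gxx.ravel() + rng.uniform(-sp / 3, sp / 3, nx * ny)
    gyy = gyy.ravel() + rng.uniform(-sp / 3, sp / 3, nx * ny)
    gzz = np.asarray(terrain.elevation(gxx, gyy), dtype=float)
    ground = np.column_stack([gxx, gyy, gzz])

    xyz = np.vstack([ground, veg])
    labels = np.concatenate([
        np.full(len(ground), GROUND, dtype=np.int8),
        np.full(len(veg), VEGETATION, dtype=np.int8)])
    plant_index = np.concatenate([
        np.full(len(ground), -1, dtype=np.int32), veg_plant])

    n_out = int(round(scene.outlier_rate * len(xyz)))
    if n_out > 0:
        lo = xyz.min(axis=0)
        hi = xyz.max(axis=0)
        hi[2] += 0.3
        lo[2] -= 0.05
        outliers = rng.uniform(lo, hi, size=(n_out, 3))
        xyz = np.vstack([xyz, outliers])
        from .cloud import OUTLIER
        labels = np.concatenate(
            [labels, np.full(n_out, OUTLIER, dtype=np.int8)])
        plant_index = np.concatenate(
            [plant_index, np.full(n_out, -1, dtype=np.int32)])

    return Scene(cloud=PointCloud(xyz), true_labels=labels,
                 plant_index=plant_index, records=records,
                 terrain=terrain, spec=scene, plant_specs=list(plant_specs))


def random_plant_specs(n: int, seed: int,
                       height_range: tuple[float, float] = (0.4, 2.4),
                       pai_range: tuple[float, float] = (0.4, 3.2),
                       cell: tuple[float, float] = (0.50, 0.30),
                       ) -> list[PlantSpec]:
    """Plant specs spanning realistic maize height/area ranges."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        h = float(rng.uniform(*height_range))
        grow = (h - height_range[0]) / (height_range[1] - height_range[0])
        pai = float(rng.uniform(*pai_range)) * (0.4 + 0.6 * grow)
        total_area = pai * cell[0] * cell[1]
        w = np.array([0.10, 0.22, 0.28, 0.25, 0.15])
        w = w * rng.uniform(0.6, 1.4, N_LAYERS)
        areas = total_area * w / w.sum()
        max_leaf = 0.8 * (h / N_LAYERS) * 0.11  # keep leaves feasible
        counts = np.maximum(1, np.ceil(areas / max(max_leaf, 1e-4))
                            ).astype(int)
        counts = np.minimum(counts, 8)
        incl = 60.0 + float(rng.normal(0, 5))
        specs.append(PlantSpec(
            height=h,
            leaf_count_per_layer=tuple(int(c) for c in counts),
            one_sided_area_per_layer=tuple(float(a) for a in areas),
            leaf_inclination_mean=float(np.clip(incl, 20, 75)),
            stem_diameter=float(rng.uniform(0.015, 0.03)),
        ))
    return specs


# ------------------------------------------------------------ yields

def generate_yields(n_varieties: int, group_assignment: dict,
                    mean_reduction: dict, cv: float, seed: int,
                    replicates: int = 5, base_yield: float = 160.0,
                    between_variety_cv: float = 0.15,
                    within_variety_cv: float = 0.05):
    """Control/drought grain-yield table with configured group-mean
    yield-reduction rates.

    With ``cv = 0`` every variety's realized reduction equals its
    group's configured reduction exactly.
    """
    import pandas as pd

    if cv < 0:
        raise ValueError("cv must be >= 0")
    for g, r in mean_reduction.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"reduction for {g} must be in [0, 1)")
        if not any(v == g for v in group_assignment.values()):
            raise LidarPhenoError(f"group {g} has zero varieties")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_varieties):
        vid = f"V{i + 1:02d}"
        group = group_assignment[vid]
        r = mean_reduction[group]
        base = base_yield * math.exp(rng.normal(0, between_variety_cv))
        noise = float(rng.normal(0, cv)) if cv > 0 else 0.0
        factor = max(0.0, (1.0 - r) * (1.0 + noise))
        for rep in range(replicates):
            control = base * (1.0 + rng.normal(0, within_variety_cv))
            control = max(control, 1e-6)
            drought = control * factor
            rows.append((vid, "control", rep, control))
            rows.append((vid, "drought", rep, drought))
    return pd.DataFrame(rows, columns=["variety_id", "treatment",
                                       "replicate", "grain_yield"])
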