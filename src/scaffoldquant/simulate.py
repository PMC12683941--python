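"""Seeded synthetic 3D scaffold co-culture generator with ground truth.

The generator emulates the statistical structure the analysis assumes: a
scaffold-resident stromal network, CD19+ B cells adhering to stroma, CD3+
T cells infiltrating the volume, and a configurable fraction of B cells
engaged by a touching T cell. Engagement is what produces double-positive
("co-localized") masks downstream: the engaging T cell's CD3 clusters at
the contact interface, so the B-cell mask genuinely contains CD3 signal
(an immunological-synapse effect). CD19 transfer onto T cells
(trogocytosis) is deliberately not modeled, so the double-positive call is
expected on the B member of each engaged pair only.

Ground-truth marker semantics follow from that mechanism:

* CD19-positive masks: all B cells.
* CD3-positive masks: all T cells plus engaged (``coloc_flag``) B cells.

Matched noisy "FACS" anchor tables and viability / kinetic-lysis tables are
generated alongside, so every downstream stage can be verified against a
known truth without any patient data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError, PlacementError
from .stacks import DEFAULT_CHANNELS, DEFAULT_VOXEL_SIZE, ImageStack, LabelVolume

MARKER_CHANNELS = ("CD90", "CD19", "CD3", "CAR")

#: Which simulated classes are the "positive" population for each marker channel.
_POSITIVE_CLASSES = {
    "CD90": ("stromal",),
    "CD19": ("bcell",),
    "CD3": ("tcell", "tcell_car"),
    "CAR": ("tcell_car",),
}


def default_intensity_params() -> dict:
    """Per-class, per-channel (log-location, log-scale) of marker intensity.

    Log-normal with a wide location gap between positive and negative
    populations (~4.3 natural-log units against a 0.25-0.40 log-scale),
    emulating well-stained, well-compensated fluorescence.
    """
    neg = (math.log(8.0), 0.40)
    pos = (math.log(600.0), 0.25)
    params = {
        "stromal": {"nuclei": pos, "CD90": pos, "CD19": neg, "CD3": neg, "CAR": neg},
        "bcell": {"nuclei": pos, "CD90": neg, "CD19": pos, "CD3": neg, "CAR": neg},
        "tcell": {"nuclei": pos, "CD90": neg, "CD19": neg, "CD3": pos, "CAR": neg},
    }
    # CAR+ T cells differ from plain T cells only in the CAR channel.
    params["tcell_car"] = dict(params["tcell"], CAR=pos)
    return params


@dataclass
class ScaffoldSimConfig:
    """Parameters of one synthetic scaffold z-stack.

    Defaults describe the emulated co-culture: an effector-to-target ratio
    of 1:1 (``n_tcell == n_bcell``), a minority stromal scaffold population,
    B/T cells as spheres with the segmentation-scale ~10-pixel diameter, and
    stromal cells as elongated spherocylinders forming a touching network.
    """

    volume_shape: tuple = (64, 96, 96)
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    n_stromal: int = 18
    n_bcell: int = 32
    n_tcell: int = 32
    coloc_fraction: float = 0.3
    car_fraction: float = 0.5
    core_radius_fraction: float = 0.5
    cell_radius: float = 5.0
    stromal_radius: float = 3.0
    stromal_length: float = 16.0
    intensity_params: dict = field(default_factory=default_intensity_params)
    bleedthrough: float = 0.02
    noise_sd: float = 5.0
    psf_sigma: float = 1.0
    background: float = 2.0
    max_attempts: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_stromal", "n_bcell", "n_tcell"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("coloc_fraction", "car_fraction", "core_radius_fraction", "bleedthrough"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]; got {v}")
        if len(self.volume_shape) != 3 or any(s <= 0 for s in self.volume_shape):
            raise ConfigurationError(f"volume_shape must be 3 positive ints; got {self.volume_shape}")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ConfigurationError("noise_sd and psf_sigma must be >= 0")
        if self.cell_radius <= 0 or self.stromal_radius <= 0:
            raise ConfigurationError("cell radii must be > 0")
        for channel, pos_classes in _POSITIVE_CLASSES.items():
            pos_loc = min(self.intensity_params[c][channel][0] for c in pos_classes)
            for cls, per_channel in self.intensity_params.items():
                if cls in pos_classes:
                    continue
                if channel in per_channel and per_channel[channel][0] >= pos_loc:
                    raise ConfigurationError(
                        f"positive location for {channel} (classes {pos_classes}) must "
                        f"exceed the negative location of class {cls}"
                    )

    @property
    def n_coloc(self) -> int:
        """Number of B cells placed in contact with a T cell."""
        n = int(round(self.coloc_fraction * self.n_bcell))
        return min(n, self.n_tcell)


@dataclass
class GroundTruth:
    """Per-cell truth records for one simulated stack.

    ``coloc_flag`` marks the B member of each engaged B-T pair; the engaging
    T cell's id is recorded in ``partner_id`` (-1 when not applicable).
    """

    cells: pd.DataFrame

    COLUMNS = (
        "cell_id",
        "cell_class",
        "car_flag",
        "coloc_flag",
        "partner_id",
        "region",
        "centroid_z",
        "centroid_y",
        "centroid_x",
    )

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.cells.columns)
        if missing:
            raise ConfigurationError(f"ground-truth table missing columns {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def marker_positive(self, marker: str) -> pd.Series:
        """Boolean truth of per-mask marker positivity (see module docstring)."""
        c = self.cells
        if marker == "CD19":
            return c["cell_class"].eq("bcell")
        if marker == "CD3":
            return c["cell_class"].eq("tcell") | (c["cell_class"].eq("bcell") & c["coloc_flag"])
        if marker == "CD90":
            return c["cell_class"].eq("stromal")
        if marker == "CAR":
            return c["car_flag"].astype(bool)
        raise ConfigurationError(f"unknown marker {marker!r}")

    def marker_fraction(self, marker: str) -> float:
        """True positive fraction (0-1) of masks for one marker."""
        if self.n_cells == 0:
            return 0.0
        return float(self.marker_positive(marker).mean())

    def expected_class(self) -> pd.Series:
        """The four-way class the marker classifier should assign per cell."""
        cls = pd.Series("stromal", index=self.cells.index)
        cls[self.cells["cell_class"].eq("tcell")] = "tcell_only"
        b = self.cells["cell_class"].eq("bcell")
        cls[b & ~self.cells["coloc_flag"]] = "bcell_only"
        cls[b & self.cells["coloc_flag"]] = "coloc"
        return cls

    def class_fractions(self, region: str | None = None) -> pd.Series:
        """Fractions of {stromal, bcell, tcell}, optionally within one region."""
        c = self.cells if region is None else self.cells[self.cells["region"] == region]
        frac = c["cell_class"].value_counts(normalize=True)
        return frac.reindex(["stromal", "bcell", "tcell"], fill_value=0.0)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# geometry helpers

_NEIGHBOR_OFFSETS = np.array(
    [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]
)


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    grid = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1].reshape(3, -1).T
    return grid[(grid**2).sum(axis=1) <= radius**2]


def _capsule_voxels(center, axis, half_length, radius, shape):
    """Integer voxels within `radius` of the segment center +- half_length*axis."""
    r = int(math.ceil(radius + half_length))
    c = np.rint(center).astype(int)
    lo = np.maximum(c - r, 0)
    hi = np.minimum(c + r + 1, shape)
    if np.any(lo >= hi):
        return np.empty((0, 3), dtype=int)
    zz, yy, xx = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3).astype(float)
    rel = pts - np.asarray(center, dtype=float)
    t = np.clip(rel @ axis, -half_length, half_length)
    nearest = np.outer(t, axis)
    d2 = ((rel - nearest) ** 2).sum(axis=1)
    return pts[d2 <= radius**2].astype(int)


class _Placer:
    """Rejection-sampling placement of non-overlapping cell masks."""

    def __init__(self, shape, rng, max_attempts):
        self.shape = np.asarray(shape)
        self.rng = rng
        self.max_attempts = max_attempts
        self.labels = np.zeros(tuple(shape), dtype=np.int32)
        self.coords = {}  # cell_id -> (n, 3) voxel coords
        self.next_id = 1

    def _in_bounds(self, vox):
        return bool(np.all(vox >= 0) and np.all(vox < self.shape))

    def _free(self, vox):
        return not self.labels[vox[:, 0], vox[:, 1], vox[:, 2]].any()

    def touches(self, vox, mask) -> bool:
        """True if `vox` dilated by one voxel (26-neighborhood) hits `mask`."""
        shifted = (vox[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]).reshape(-1, 3)
        shifted = np.clip(shifted, 0, self.shape - 1)
        return bool(mask[shifted[:, 0], shifted[:, 1], shifted[:, 2]].any())

    def commit(self, vox) -> int:
        cell_id = self.next_id
        self.labels[vox[:, 0], vox[:, 1], vox[:, 2]] = cell_id
        self.coords[cell_id] = vox
        self.next_id += 1
        return cell_id

    def rollback(self, cell_id: int) -> None:
        """Undo the most recent commit (used when a paired placement fails)."""
        if cell_id != self.next_id - 1:
            raise ValueError("can only roll back the most recent placement")
        vox = self.coords.pop(cell_id)
        self.labels[vox[:, 0], vox[:, 1], vox[:, 2]] = 0
        self.next_id -= 1

    def random_unit(self):
        v = self.rng.normal(size=3)
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _class_mask(placer, ids):
    mask = np.zeros(tuple(placer.shape), dtype=bool)
    for i in ids:
        v = placer.coords[i]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True
    return mask


# ---------------------------------------------------------------------------
# main generator


def _place_cells(config: ScaffoldSimConfig, rng):
    """One placement pass; raises PlacementError on a geometric dead-end."""
    shape = tuple(config.volume_shape)
    placer = _Placer(shape, rng, config.max_attempts)

    # --- stromal spherocylinders, attached to the growing network when possible
    stromal_ids = []
    stromal_geom = {}  # id -> (center, axis): needed to carve the oval nucleus
    half_len = config.stromal_length / 2.0
    margin = config.stromal_radius + half_len
    for i in range(config.n_stromal):
        placed = False
        stromal_vox = np.concatenate([placer.coords[j] for j in stromal_ids]) if stromal_ids else None
        for attempt in range(config.max_attempts):
            if stromal_vox is not None and attempt < config.max_attempts // 2:
                anchor = stromal_vox[rng.integers(len(stromal_vox))]
                center = anchor + placer.random_unit() * (config.stromal_radius * 2 + 1.5)
            else:
                center = rng.uniform(margin, np.asarray(shape) - 1 - margin)
            axis = placer.random_unit()
            vox = _capsule_voxels(center, axis, half_len, config.stromal_radius, shape)
            if len(vox) and placer._free(vox):
                cell_id = placer.commit(vox)
                stromal_ids.append(cell_id)
                stromal_geom[cell_id] = (np.asarray(center, dtype=float), axis)
                placed = True
                break
        if not placed:
            raise PlacementError("stromal", i, config.n_stromal)

    stromal_mask = _class_mask(placer, stromal_ids)
    sphere = _sphere_offsets(config.cell_radius)
    r = config.cell_radius
    touch_reach = r + 1.8  # centers this close to a mask can touch it after dilation-by-1

    stroma_dist = (
        ndimage.distance_transform_edt(~stromal_mask) if stromal_ids else None
    )
    border = int(math.ceil(r))
    interior = np.zeros(shape, dtype=bool)
    interior[border:-border or None, border:-border or None, border:-border or None] = True

    def sphere_center_candidates(near_dist=None, away_dist=None):
        """Centers where a radius-r sphere fits without overlap, optionally
        within touching reach of a target mask (given its distance map) and
        out of reach of another. Near candidates come closest-first with a
        random tie-break; otherwise randomly permuted."""
        free_dist = ndimage.distance_transform_edt(placer.labels == 0)
        valid = (free_dist > r) & interior
        if near_dist is not None:
            valid &= near_dist <= touch_reach
        if away_dist is not None:
            valid &= away_dist > touch_reach
        candidates = np.argwhere(valid)
        if len(candidates) == 0:
            return candidates
        if near_dist is not None:
            key = near_dist[valid.nonzero()] + rng.uniform(0.0, 0.5, size=len(candidates))
            return candidates[np.argsort(key, kind="stable")]
        return candidates[rng.permutation(len(candidates))]

    def try_place_sphere(near_dist=None, away_dist=None, must_touch=None, must_not_touch=None):
        candidates = sphere_center_candidates(near_dist, away_dist)
        for center in candidates[: config.max_attempts]:
            vox = center + sphere
            if not placer._in_bounds(vox) or not placer._free(vox):
                continue
            if must_touch is not None and not placer.touches(vox, must_touch):
                continue
            if must_not_touch is not None and must_not_touch.any() and placer.touches(vox, must_not_touch):
                continue
            return placer.commit(vox)
        return None

    def mask_dist(mask):
        return ndimage.distance_transform_edt(~mask)

    n_coloc = config.n_coloc
    bcell_ids, tcell_ids = [], []
    partner_of_t, t_partner_b = {}, {}
    any_b = np.zeros(shape, dtype=bool)
    any_t = np.zeros(shape, dtype=bool)

    def add_to(mask, cell_id):
        v = placer.coords[cell_id]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True

    # --- engaged B-T pairs first, while the stromal surface is still free
    for i in range(n_coloc):
        placed_pair = False
        for _ in range(10):
            b_id = try_place_sphere(
                near_dist=stroma_dist, away_dist=None if not any_t.any() else mask_dist(any_t),
                must_touch=stromal_mask if stromal_ids else None, must_not_touch=any_t,
            )
            if b_id is None:
                raise PlacementError("bcell", i, config.n_bcell)
            b_mask = _single_mask(placer, b_id)
            t_id = try_place_sphere(
                near_dist=mask_dist(b_mask), away_dist=None if not any_b.any() else mask_dist(any_b),
                must_touch=b_mask, must_not_touch=any_b,
            )
            if t_id is not None:
                bcell_ids.append(b_id)
                tcell_ids.append(t_id)
                add_to(any_b, b_id)
                add_to(any_t, t_id)
                partner_of_t[t_id] = b_id
                t_partner_b[b_id] = t_id
                placed_pair = True
                break
            placer.rollback(b_id)  # partner shell blocked; retry elsewhere
        if not placed_pair:
            raise PlacementError("tcell", i, config.n_tcell)

    # --- remaining B cells: on stroma, clear of every T mask
    t_dist = mask_dist(any_t) if any_t.any() else None
    for i in range(n_coloc, config.n_bcell):
        b_id = try_place_sphere(
            near_dist=stroma_dist, away_dist=t_dist,
            must_touch=stromal_mask if stromal_ids else None, must_not_touch=any_t,
        )
        if b_id is None:
            raise PlacementError("bcell", i, config.n_bcell)
        bcell_ids.append(b_id)
        add_to(any_b, b_id)

    # --- remaining T cells: clear of every B mask
    b_dist = mask_dist(any_b) if any_b.any() else None
    for i in range(n_coloc, config.n_tcell):
        t_id = try_place_sphere(away_dist=b_dist, must_not_touch=any_b)
        if t_id is None:
            raise PlacementError("tcell", i, config.n_tcell)
        tcell_ids.append(t_id)
        add_to(any_t, t_id)
    bcell_masks = {i: _single_mask(placer, i) for i in bcell_ids}

    return placer, stromal_ids, stromal_geom, bcell_ids, tcell_ids, partner_of_t, t_partner_b, bcell_masks


def generate_scaffold_stack(config: ScaffoldSimConfig, rng=None):
    """Simulate one scaffold z-stack.

    Returns ``(stack, labels, truth)``: the multi-channel :class:`ImageStack`
    (channels nuclei/CD90/CD19/CD3/CAR), the matching :class:`LabelVolume`
    with one connected mask per simulated cell, and the :class:`GroundTruth`
    table. Identical config and seed give bit-identical outputs.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)
    # placement can dead-end on unlucky geometry; retry with the same
    # stream (bounded, deterministic for fixed config + seed)
    last_err = None
    for _ in range(8):
        try:
            (placer, stromal_ids, stromal_geom, bcell_ids, tcell_ids,
             partner_of_t, t_partner_b, bcell_masks) = _place_cells(config, rng)
            break
        except PlacementError as err:
            last_err = err
    else:
        raise last_err

    # --- CAR flags
    n_car = int(round(config.car_fraction * config.n_tcell))
    car_ids = set(rng.choice(tcell_ids, size=n_car, replace=False)) if n_car else set()

    # --- analysis masks (what the nuclear stain labels): lymphocytes have a
    # high nuclear:cytoplasmic ratio, so B/T masks are the whole sphere;
    # stromal cells keep an oval nucleus at the capsule center while the
    # elongated body carries only the CD90 (and bleed-through) signal.
    mask_coords = {}
    for cell_id in range(1, placer.next_id):
        if cell_id in stromal_geom:
            center, axis = stromal_geom[cell_id]
            nucleus = _capsule_voxels(
                center, axis, config.stromal_radius, config.stromal_radius, shape
            )
            mask_coords[cell_id] = nucleus if len(nucleus) else placer.coords[cell_id]
        else:
            mask_coords[cell_id] = placer.coords[cell_id]
    label_volume = np.zeros(shape, dtype=np.int32)
    for cell_id in range(1, placer.next_id):
        v = mask_coords[cell_id]
        label_volume[v[:, 0], v[:, 1], v[:, 2]] = cell_id

    # --- truth table
    records = []
    half_extent = (np.asarray(shape, dtype=float) - 1) / 2.0
    for cell_id in range(1, placer.next_id):
        vox = mask_coords[cell_id]
        centroid = vox.mean(axis=0)
        if cell_id in stromal_ids:
            cls = "stromal"
        elif cell_id in bcell_masks:
            cls = "bcell"
        else:
            cls = "tcell"
        ry = (centroid[1] - half_extent[1]) / max(half_extent[1], 1e-9)
        rx = (centroid[2] - half_extent[2]) / max(half_extent[2], 1e-9)
        region = "core" if math.hypot(ry, rx) <= config.core_radius_fraction else "periphery"
        records.append(
            dict(
                cell_id=cell_id,
                cell_class=cls,
                car_flag=cell_id in car_ids,
                coloc_flag=cell_id in t_partner_b,
                partner_id=t_partner_b.get(cell_id, partner_of_t.get(cell_id, -1)),
                region=region,
                centroid_z=centroid[0],
                centroid_y=centroid[1],
                centroid_x=centroid[2],
            )
        )
    truth = GroundTruth(pd.DataFrame.from_records(records, columns=list(GroundTruth.COLUMNS)))

    # --- intensities: per-cell log-normal draws, constant over the cell.
    # The nuclear stain fills the analysis mask (the nucleus); marker
    # channels fill the whole cell body (capsule for stroma).
    n_ch = len(DEFAULT_CHANNELS)
    clean = np.full((n_ch,) + shape, float(config.background))
    class_of = dict(zip(truth.cells["cell_id"], truth.cells["cell_class"]))
    for cell_id in range(1, placer.next_id):
        cls = class_of[cell_id]
        param_class = "tcell_car" if (cls == "tcell" and cell_id in car_ids) else cls
        for ci, channel in enumerate(DEFAULT_CHANNELS):
            vox = mask_coords[cell_id] if channel == "nuclei" else placer.coords[cell_id]
            mu, sigma = config.intensity_params[param_class][channel]
            clean[ci, vox[:, 0], vox[:, 1], vox[:, 2]] = math.exp(rng.normal(mu, sigma))

    # --- synaptic CD3 inside engaged B masks (contact patch, <= 2 voxels deep)
    cd3 = DEFAULT_CHANNELS.index("CD3")
    for b_id, t_id in sorted(t_partner_b.items()):
        b_vox, t_vox = placer.coords[b_id], placer.coords[t_id]
        dist, _ = cKDTree(t_vox).query(b_vox, k=1)
        patch = b_vox[dist <= 2.5]
        if len(patch) == 0:
            patch = b_vox[np.argsort(dist)[:20]]
        mu, sigma = config.intensity_params["tcell"]["CD3"]
        clean[cd3, patch[:, 0], patch[:, 1], patch[:, 2]] = math.exp(rng.normal(mu, sigma))

    # --- crosstalk, blur, noise
    total = clean.sum(axis=0)
    mixed = np.empty_like(clean)
    for ci in range(n_ch):
        mixed[ci] = clean[ci] + config.bleedthrough * (total - clean[ci])
    if config.psf_sigma > 0:
        for ci in range(n_ch):
            mixed[ci] = ndimage.gaussian_filter(mixed[ci], config.psf_sigma)
    if config.noise_sd > 0:
        mixed = mixed + rng.normal(0.0, config.noise_sd, size=mixed.shape)
    np.clip(mixed, 0.0, None, out=mixed)

    stack = ImageStack(mixed, DEFAULT_CHANNELS, tuple(config.voxel_size))
    labels = LabelVolume(label_volume, tuple(config.voxel_size))
    return stack, labels, truth


def _single_mask(placer, cell_id):
    mask = np.zeros(tuple(placer.shape), dtype=bool)
    v = placer.coords[cell_id]
    mask[v[:, 0], v[:, 1], v[:, 2]] = True
    return mask


# ---------------------------------------------------------------------------
# anchor tables


def generate_anchor_table(
    truth,
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
    group: str = "G1",
    conditions=("mock", "car"),
    markers=("CD3", "CD19"),
    rng=None,
) -> pd.DataFrame:
    """Noisy external-modality (flow-cytometry-like) positive fractions.

    ``truth`` may be one :class:`GroundTruth` or a sequence (fractions are
    averaged across them, emulating FACS pooled over corresponding
    cultures). Each replicate's positive_fraction is the true fraction (in
    percent) times ``1 + N(0, cv)``, clipped to [0, 100]; ``cv = 0``
    reproduces the truth exactly.
    """
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    truths = [truth] if isinstance(truth, GroundTruth) else list(truth)
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for condition in conditions:
        for marker in markers:
            true_pct = 100.0 * float(np.mean([t.marker_fraction(marker) for t in truths]))
            for rep in range(1, n_replicates + 1):
                value = true_pct * (1.0 + (rng.normal(0.0, cv) if cv > 0 else 0.0))
                rows.append(
                    dict(
                        group=group,
                        condition=condition,
                        marker=marker,
                        positive_fraction=float(np.clip(value, 0.0, 100.0)),
                        replicate_id=rep,
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assay tables


@dataclass
class AssaySimConfig:
    """Parameters of the synthetic viability and kinetic-lysis tables.

    Default specified lysis per group/region and the 9 h time-to-maximal
    lysis reproduce the study conditions of the emulated co-culture
    (periphery/core cytolysis ~28/20% for CLL and ~50/45% for ALL at an E:T
    ratio of 1:1; frames every 30 min).
    """

    groups: tuple = ("CLL", "ALL")
    regions: tuple = ("periphery", "core")
    target_alone_live: float = 80.0
    mock_lysis: float = 0.05
    car_lysis: dict = field(
        default_factory=lambda: {
            ("CLL", "periphery"): 0.279,
            ("CLL", "core"): 0.199,
            ("ALL", "periphery"): 0.502,
            ("ALL", "core"): 0.451,
        }
    )
    duration_min: int = 1440
    interval_min: int = 30
    time_to_max_min: int = 540
    decay_tau_min: float = 360.0
    max_area_um2: float = 30000.0
    basal_fraction: float = 0.05
    mock_fraction: float = 0.12
    n_objects: int = 6
    n_background_objects: int = 4
    noise_cv: float = 0.01

    def validate(self) -> None:
        lysis = dict(self.car_lysis)
        lysis["mock"] = self.mock_lysis
        for key, value in lysis.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"specified lysis for {key} must be in [0, 1]; got {value}")
        if not 0.0 < self.target_alone_live <= 100.0:
            raise ConfigurationError("target_alone_live must be in (0, 100]")
        if self.interval_min <= 0 or self.duration_min <= 0:
            raise ConfigurationError("time grid must be positive")


@dataclass
class AssaySeries:
    """Bundle of synthetic assay inputs for the cytotoxicity calculators."""

    viability: pd.DataFrame
    kinetics: dict

    @property
    def basal(self) -> pd.DataFrame:
        return self.kinetics["target_alone"]


def _kinetic_shape(t, t_max, tau):
    t = np.asarray(t, dtype=float)
    rise = t / t_max
    decay = np.exp(-(t - t_max) / tau)
    return np.where(t <= t_max, rise, decay)


def generate_assay_tables(config: AssaySimConfig | None = None, seed: int = 0) -> AssaySeries:
    """Viability and per-object kinetic-lysis tables with known effect sizes.

    The viability table satisfies ``car live = target_alone x (1 - lysis)``
    per group/region; kinetic traces rise linearly to the configured maximal
    lysis time, then decay, on a 30-min grid, with a basal (spontaneous)
    trace and small sub-threshold background objects that the size filter
    must remove.
    """
    if config is None:
        config = AssaySimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    rows = []
    for group in config.groups:
        for region in config.regions:
            ta = config.target_alone_live
            rows.append(dict(group=group, region=region, condition="target_alone", percent_live=ta))
            rows.append(
                dict(group=group, region=region, condition="mock", percent_live=ta * (1 - config.mock_lysis))
            )
            lysis = config.car_lysis[(group, region)]
            rows.append(dict(group=group, region=region, condition="car", percent_live=ta * (1 - lysis)))
    viability = pd.DataFrame(rows)

    time = np.arange(0, config.duration_min + 1, config.interval_min)
    basal_total = config.basal_fraction * config.max_area_um2 * time / config.duration_min
    signals = {
        "target_alone": basal_total,
        "mock": basal_total + config.mock_fraction * config.max_area_um2 * time / config.duration_min,
        "car": basal_total + config.max_area_um2 * _kinetic_shape(time, config.time_to_max_min, config.decay_tau_min),
    }

    kinetics = {}
    for condition, total in signals.items():
        weights = rng.dirichlet(np.full(config.n_objects, 5.0))
        sizes = rng.uniform(12.0, 26.0, size=config.n_objects)
        bg_sizes = rng.uniform(4.0, 10.0, size=config.n_background_objects)
        bg_area = 0.02 * config.max_area_um2
        recs = []
        for ti, t in enumerate(time):
            for oi in range(config.n_objects):
                noise = 1.0 + (rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0)
                recs.append(
                    dict(
                        time_min=int(t),
                        object_id=oi + 1,
                        size_um=float(sizes[oi]),
                        area_um2=float(max(total[ti] * weights[oi] * noise, 0.0)),
                        is_basal=condition == "target_alone",
                    )
                )
            for bi in range(config.n_background_objects):
                noise = 1.0 + (rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0)
                recs.append(
                    dict(
                        time_min=int(t),
                        object_id=config.n_objects + bi + 1,
                        size_um=float(bg_sizes[bi]),
                        area_um2=float(max(bg_area * noise, 0.0)),
                        is_basal=condition == "target_alone",
                    )
                )
        kinetics[condition] = pd.DataFrame(recs)
    return AssaySeries(viability=viability, kinetics=kinetics)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortConfig:
    """A multi-group, multi-patient synthetic imaging cohort.

    ``groups`` and ``conditions`` map names to :class:`ScaffoldSimConfig`
    field overrides applied on top of ``base``.
    """

    base: ScaffoldSimConfig = field(default_factory=ScaffoldSimConfig)
    groups: dict = field(default_factory=lambda: {"CLL": {}, "ALL": {}})
    conditions: dict = field(default_factory=lambda: {"car": {}})
    patients_per_group: int = 4
    images_per_patient: int = 2
    anchor_cv: float = 0.05
    anchor_replicates: int = 3


@dataclass
class CohortImage:
    group: str
    patient_id: str
    condition: str
    image_index: int
    stack_id: str
    stack: ImageStack
    labels: LabelVolume
    truth: GroundTruth


@dataclass
class CohortResult:
    images: list
    anchors: pd.DataFrame

    def truth_cells(self) -> pd.DataFrame:
        """All per-cell truth rows with cohort metadata columns attached."""
        frames = []
        for im in self.images:
            df = im.truth.cells.copy()
            df.insert(0, "stack_id", im.stack_id)
            df.insert(1, "patient_id", im.patient_id)
            df.insert(2, "group", im.group)
            df.insert(3, "condition", im.condition)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortResult:
    """Simulate a seeded cohort and its matched group-level anchor table."""
    if config is None:
        config = CohortConfig()
    ss = np.random.SeedSequence(seed)
    n_images = (
        len(config.groups) * len(config.conditions) * config.patients_per_group * config.images_per_patient
    )
    children = ss.spawn(n_images + 1)
    anchor_rng = np.random.default_rng(children[-1])

    images = []
    idx = 0
    for group, group_over in config.groups.items():
        for p in range(1, config.patients_per_group + 1):
            patient_id = f"{group}-P{p}"
            for condition, cond_over in config.conditions.items():
                for k in range(1, config.images_per_patient + 1):
                    sim_cfg = replace(config.base, **{**group_over, **cond_over})
                    rng = np.random.default_rng(children[idx])
                    stack, labels, truth = generate_scaffold_stack(sim_cfg, rng=rng)
                    images.append(
                        CohortImage(
                            group=group,
                            patient_id=patient_id,
                            condition=condition,
                            image_index=k,
                            stack_id=f"{patient_id}-{condition}-im{k}",
                            stack=stack,
                            labels=labels,
                            truth=truth,
                        )
                    )
                    idx += 1

    anchor_frames = []
    for group in config.groups:
        for condition in config.conditions:
            truths = [
                im.truth for im in images if im.group == group and im.condition == condition
            ]
            anchor_frames.append(
                generate_anchor_table(
                    truths,
                    cv=config.anchor_cv,
                    n_replicates=config.anchor_replicates,
                    group=group,
                    conditions=(condition,),
                    rng=anchor_rng,
                )
            )
    return CohortResult(images=images, anchors=pd.concat(anchor_frames, ignore_index=True))
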