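"""Synthetic dual-echo hippocampus phantoms.

Each phantom subject is a pair of curved tubular "hippocampi" voxelised on a
common RAS+ grid, a structural T1-like volume, and two effective-echo
fast-spin-echo images generated under the monoexponential decay model

    S(TE) = S0 * exp(-TE / T2) + Gaussian noise.

Ground truth (per-side volume, mean T2, long-axis profile) is recorded from
the generating parameters, so every downstream stage — T2 fitting, volumetry,
long-axis profiling, normative flagging — can be tested without real data.

Disease is emulated the way hippocampal sclerosis presents: a volume scale
factor (atrophy) and a multiplicative T2 elevation, either uniform or focal
(a Gaussian bump in normalised arc position along the long axis).

All randomness flows from one explicit seed. Draw order per operation is
fixed and documented so regeneration is stable: echoes draw noise for echo 1
then echo 2; cohorts draw, per subject in order, the shared size factor, the
per-side size factors (left, right), the per-side T2 values (left, right),
then one mirrored geometry jitter.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .imaging_io import LabelMask, Volume3D, write_volume

__all__ = [
    "Grid",
    "HippocampusSpec",
    "AcquisitionSpec",
    "TissueBackground",
    "CohortVariability",
    "SideTruth",
    "PhantomTruth",
    "PhantomSubject",
    "PhantomError",
    "TubeOutsideGridError",
    "RadiusTooSmallError",
    "OverlappingTubesError",
    "default_grid",
    "default_centerline",
    "default_hippocampus",
    "make_hippocampus_mask",
    "synthesize_dual_echo",
    "make_phantom_subject",
    "make_reference_cohort",
    "draw_healthy_metrics",
    "write_phantom_subject",
    "write_cohort",
]

#: nominal healthy hippocampal T2 (ms) and signal amplitude for the phantom
DEFAULT_T2_MS = 100.0
DEFAULT_S0 = 1000.0
#: nominal per-side hippocampal volume of the default geometry, mm^3
NOMINAL_VOLUME_MM3 = 3300.0

#: centerline discretisation (samples along the spline); 0.1 mm spacing on a
#: ~45 mm axis keeps the nearest-sample distance error far below voxel size
_N_ARC_SAMPLES = 600


class PhantomError(Exception):
    """Base class for phantom-construction failures."""


class TubeOutsideGridError(PhantomError):
    """The tube (centerline plus radius) exits the grid's world extent."""


class RadiusTooSmallError(PhantomError):
    """Tube radius below one voxel; the voxelisation would be unreliable."""


class OverlappingTubesError(PhantomError):
    """Left and right hippocampus tubes overlap."""


@dataclass(frozen=True)
class Grid:
    """A voxel lattice: shape plus voxel-index -> world-mm affine (RAS+)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    @classmethod
    def centered(cls, shape: Sequence[int], spacing: Sequence[float]) -> "Grid":
        """Axis-aligned RAS+ grid with the world origin at the lattice centre."""
        shape = tuple(int(s) for s in shape)
        spacing = np.asarray(spacing, dtype=float)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = -spacing * (np.asarray(shape) - 1) / 2.0
        return cls(shape=shape, affine=affine)

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.affine)[:3, :3])))

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world coordinates of the lattice's voxel-centre box."""
        idx_corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        world = idx_corners @ np.asarray(self.affine)[:3, :3].T + np.asarray(self.affine)[:3, 3]
        return world.min(axis=0), world.max(axis=0)


def default_grid(shape: Sequence[int] = (80, 96, 48), spacing_mm: float = 1.0) -> Grid:
    """1 mm isotropic RAS+ grid large enough for both default hippocampi."""
    return Grid.centered(shape, (spacing_mm,) * 3)


def default_centerline(side: str) -> np.ndarray:
    """Control points (world mm) of a curved, banana-shaped long axis.

    Runs posterior (tail) to anterior (head), arching laterally and in the
    superior direction, mirrored across the mid-sagittal plane per side.
    """
    pts = np.array(
        [
            [25.0, -22.0, -6.0],
            [28.0, -11.0, 0.0],
            [30.0, 0.0, 3.0],
            [28.0, 11.0, 0.0],
            [25.0, 22.0, -6.0],
        ]
    )
    if side == "left":
        pts = pts * np.array([-1.0, 1.0, 1.0])
    elif side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return pts


@dataclass
class HippocampusSpec:
    """Generating parameters for one hippocampus tube.

    ``atrophy_factor`` scales total volume (applied as a sqrt factor on the
    radius, keeping length fixed); ``t2_elevation`` multiplies the baseline
    T2 either uniformly (``focal_center=None``) or as a Gaussian bump in
    normalised arc position with SD ``focal_width`` peaking at
    ``focal_center`` (0 = posterior tail, 1 = anterior head).
    """

    side: str
    centerline: np.ndarray = None  # control points, world mm; default per side
    base_radius: float = 5.5
    taper: float = 0.5
    t2: float = DEFAULT_T2_MS
    s0: float = DEFAULT_S0
    atrophy_factor: float = 1.0
    t2_elevation: float = 1.0
    focal_center: float | None = None
    focal_width: float = 0.1

    def __post_init__(self) -> None:
        if self.centerline is None:
            self.centerline = default_centerline(self.side)
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.base_radius <= 0 or self.t2 <= 0 or self.s0 < 0:
            raise ValueError("base_radius and t2 must be > 0, s0 >= 0")
        if not 0 < self.atrophy_factor <= 1:
            raise ValueError("atrophy_factor must be in (0, 1]")
        if self.t2_elevation < 1:
            raise ValueError("t2_elevation must be >= 1")
        if not 0 < self.taper <= 1:
            raise ValueError("taper must be in (0, 1]")

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        """Tube radius (mm) at arc position s in [0, 1], cosine-like end taper."""
        base = self.base_radius * np.sqrt(self.atrophy_factor)
        return base * (self.taper + (1.0 - self.taper) * np.sin(np.pi * np.asarray(s)))

    def t2_at(self, s: np.ndarray) -> np.ndarray:
        """Generating T2 (ms) at arc position s, with uniform or focal elevation."""
        s = np.asarray(s, dtype=float)
        if self.focal_center is None:
            return np.full_like(s, self.t2 * self.t2_elevation)
        bump = np.exp(-((s - self.focal_center) ** 2) / (2.0 * self.focal_width**2))
        return self.t2 * (1.0 + (self.t2_elevation - 1.0) * bump)


@dataclass
class AcquisitionSpec:
    """Dual-echo FSE acquisition: echo times, grid, and noise level.

    Defaults follow a clinical T2-relaxometry protocol: effective echo times
    30 and 119 ms at TR 7600 ms. ``noise_sigma`` is the SD of additive
    Gaussian noise in signal units.
    """

    te1: float = 30.0
    te2: float = 119.0
    tr: float = 7600.0  # metadata only
    grid: Grid = field(default_factory=default_grid)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.te1 < self.te2:
            raise ValueError(f"need 0 < te1 < te2, got te1={self.te1}, te2={self.te2}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class TissueBackground:
    """Single background tissue class; exterior of the head is zero signal."""

    s0: float = 800.0
    t2: float = 80.0


@dataclass
class CohortVariability:
    """Between-subject spread of the healthy reference cohort.

    ``vol_shared_sd`` scales both sides together (head-size variation) and so
    cancels from L:R ratios; ``vol_side_sd`` is the per-side independent
    volume factor SD driving the volume-ratio spread; ``t2_sd`` (ms) the
    per-side T2 SD at a 100 ms mean; ``geom_jitter_mm`` jitters the control
    points, mirrored across the midline so geometry noise also cancels from
    ratios.
    """

    vol_shared_sd: float = 0.08
    vol_side_sd: float = 0.04
    t2_mean: float = DEFAULT_T2_MS
    t2_sd: float = 1.9
    geom_jitter_mm: float = 0.8


@dataclass
class SideTruth:
    volume_mm3: float
    mean_t2_ms: float
    profile_positions: np.ndarray
    profile_volume_mm3: np.ndarray
    profile_t2_ms: np.ndarray


@dataclass
class PhantomTruth:
    left: SideTruth
    right: SideTruth

    @property
    def lr_vol_ratio_pct(self) -> float:
        return 100.0 * self.left.volume_mm3 / self.right.volume_mm3

    @property
    def lr_qt2_ratio_pct(self) -> float:
        return 100.0 * self.left.mean_t2_ms / self.right.mean_t2_ms


@dataclass
class PhantomSubject:
    t1_like: Volume3D
    echo1: Volume3D
    echo2: Volume3D
    mask_left: LabelMask
    mask_right: LabelMask
    truth: PhantomTruth
    specs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tube voxelisation


def _sample_centerline(control_points: np.ndarray, n: int = _N_ARC_SAMPLES):
    """Densely sample a natural cubic spline through the control points.

    Returns (points (n,3), s (n,) normalised arc position in [0,1], length mm).
    """
    cp = np.asarray(control_points, dtype=float)
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
    spline = CubicSpline(chord / chord[-1], cp, axis=0)
    t = np.linspace(0.0, 1.0, n)
    pts = spline(t)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    return pts, arc / arc[-1], float(arc[-1])


def _voxelize_tube(spec: HippocampusSpec, grid: Grid):
    """Voxelise the tube; returns (mask_array uint8, arc_map float with NaN outside)."""
    pts, s, _length = _sample_centerline(spec.centerline)
    radii = spec.radius_at(s)
    r_max = float(radii.max())

    if r_max < grid.spacing.min():
        raise RadiusTooSmallError(
            f"peak tube radius {r_max:.2f} mm is below one voxel ({grid.spacing.min():.2f} mm)"
        )
    lo, hi = grid.world_bounds()
    if np.any(pts.min(axis=0) - r_max < lo) or np.any(pts.max(axis=0) + r_max > hi):
        raise TubeOutsideGridError("tube exits the grid's world extent")

    affine = np.asarray(grid.affine)
    inv = np.linalg.inv(affine)
    # candidate voxel box: world bbox of the tube mapped to indices
    corners = np.array(
        [[x, y, z] for x in (pts[:, 0].min() - r_max, pts[:, 0].max() + r_max)
         for y in (pts[:, 1].min() - r_max, pts[:, 1].max() + r_max)
         for z in (pts[:, 2].min() - r_max, pts[:, 2].max() + r_max)]
    )
    idx_corners = corners @ inv[:3, :3].T + inv[:3, 3]
    i_lo = np.maximum(np.floor(idx_corners.min(axis=0)).astype(int), 0)
    i_hi = np.minimum(np.ceil(idx_corners.max(axis=0)).astype(int) + 1, grid.shape)

    ii, jj, kk = np.meshgrid(
        np.arange(i_lo[0], i_hi[0]),
        np.arange(i_lo[1], i_hi[1]),
        np.arange(i_lo[2], i_hi[2]),
        indexing="ij",
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]

    tree = cKDTree(pts)
    dist, nearest = tree.query(world, workers=-1)
    inside = dist <= radii[nearest]
    # flat end caps: a point whose nearest sample is an endpoint must not
    # extend past the end plane (no spherical caps beyond the centerline)
    for end in (0, len(pts) - 1):
        at_end = nearest == end
        if at_end.any():
            tangent = pts[1] - pts[0] if end == 0 else pts[-1] - pts[-2]
            tangent = tangent / np.linalg.norm(tangent)
            axial = (world[at_end] - pts[end]) @ tangent
            beyond = axial < 0 if end == 0 else axial > 0
            sub = inside[at_end]
            sub[beyond] = False
            inside[at_end] = sub

    mask = np.zeros(grid.shape, dtype=np.uint8)
    arc = np.full(grid.shape, np.nan)
    sel = idx[inside].astype(int)
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = 1
    arc[sel[:, 0], sel[:, 1], sel[:, 2]] = s[nearest[inside]]

    # keep the largest 6-connected component (voxelisation can pinch at the taper)
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        raise RadiusTooSmallError("tube voxelisation is empty")
    if n_comp > 1:
        keep = np.argmax(ndimage.sum_labels(mask, labels, np.arange(1, n_comp + 1))) + 1
        mask = (labels == keep).astype(np.uint8)
        arc[labels != keep] = np.nan
    return mask, arc


def make_hippocampus_mask(spec: HippocampusSpec, grid: Grid) -> LabelMask:
    """Voxelise one hippocampus tube into a 6-connected binary mask."""
    mask, _ = _voxelize_tube(spec, grid)
    return LabelMask(data=mask, affine=np.asarray(grid.affine), side=spec.side)


def analytic_tube_volume_mm3(spec: HippocampusSpec) -> float:
    """Analytic volume of the tapered tube, integral of pi r(s)^2 ds."""
    pts, s, length = _sample_centerline(spec.centerline, n=4000)
    r = spec.radius_at(s)
    return float(np.trapezoid(np.pi * r**2, s * length))


# ---------------------------------------------------------------------------
# signal synthesis


def synthesize_dual_echo(
    s0: Volume3D, t2: Volume3D, acq: AcquisitionSpec
) -> tuple[Volume3D, Volume3D]:
    """Monoexponential dual-echo synthesis with additive Gaussian noise.

    echo_k = S0 * exp(-te_k / T2) + N(0, noise_sigma), noise drawn echo 1
    first then echo 2 from ``default_rng(acq.seed)``. TE is stored in each
    volume's ``meta['te_ms']``.
    """
    if np.any(s0.data < 0):
        raise ValueError("S0 must be >= 0 everywhere")
    if np.any(t2.data <= 0):
        raise ValueError("T2 must be > 0 everywhere")
    rng = np.random.default_rng(acq.seed)
    echoes = []
    for te in (acq.te1, acq.te2):
        signal = s0.data * np.exp(-te / t2.data)
        if acq.noise_sigma > 0:
            signal = signal + rng.normal(0.0, acq.noise_sigma, size=signal.shape)
        echoes.append(
            Volume3D(data=signal, affine=s0.affine.copy(), meta={"te_ms": float(te), "tr_ms": acq.tr})
        )
    return echoes[0], echoes[1]


# ---------------------------------------------------------------------------
# whole subjects


def default_hippocampus(side: str, **overrides) -> HippocampusSpec:
    return HippocampusSpec(side=side, **overrides)


def _head_mask(grid: Grid) -> np.ndarray:
    """Ellipsoidal 'head' region holding the background tissue class."""
    affine = np.asarray(grid.affine)
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in grid.shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    lo, hi = grid.world_bounds()
    center = (lo + hi) / 2.0
    semi = 0.48 * (hi - lo)
    q = ((world - center) / semi) ** 2
    return q.sum(axis=-1) <= 1.0


def _truth_profile(arc: np.ndarray, t2_field: np.ndarray, mask: np.ndarray,
                   voxvol: float, n_bins: int):
    s_vals = arc[mask > 0]
    t2_vals = t2_field[mask > 0]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(s_vals, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    vol = counts * voxvol
    t2_sum = np.bincount(which, weights=t2_vals, minlength=n_bins)
    t2_mean = np.where(counts > 0, t2_sum / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, vol.astype(float), t2_mean


def make_phantom_subject(
    left: HippocampusSpec,
    right: HippocampusSpec,
    acq: AcquisitionSpec,
    background: TissueBackground | None = None,
    truth_n_bins: int = 20,
) -> PhantomSubject:
    """Assemble a full synthetic subject with ground truth.

    Hippocampal voxels carry the side's generating T2 (baseline x elevation,
    focal bump in arc position when configured); the background is a single
    tissue class inside an ellipsoidal head, zero signal outside.
    """
    if left.side == right.side:
        raise ValueError("left and right specs must have distinct sides")
    background = background or TissueBackground()
    grid = acq.grid
    voxvol = grid.voxel_volume_mm3
    affine = np.asarray(grid.affine)

    mask_l, arc_l = _voxelize_tube(left, grid)
    mask_r, arc_r = _voxelize_tube(right, grid)
    if np.any(mask_l & mask_r):
        raise OverlappingTubesError("left and right tubes overlap")

    head = _head_mask(grid)
    s0_field = np.where(head, background.s0, 0.0)
    t2_field = np.full(grid.shape, background.t2)
    for spec, mask, arc in ((left, mask_l, arc_l), (right, mask_r, arc_r)):
        sel = mask > 0
        s0_field[sel] = spec.s0
        t2_field[sel] = spec.t2_at(arc[sel])

    s0_vol = Volume3D(data=s0_field, affine=affine.copy(), meta={"description": "S0"})
    t2_vol = Volume3D(data=t2_field, affine=affine.copy(), meta={"description": "T2 ms"})
    echo1, echo2 = synthesize_dual_echo(s0_vol, t2_vol, acq)

    t1_data = np.where(head, 600.0, 0.0)
    t1_data[(mask_l | mask_r) > 0] = 520.0
    t1_like = Volume3D(data=t1_data, affine=affine.copy(), meta={"description": "T1-like"})

    sides = {}
    for name, spec, mask, arc in (("left", left, mask_l, arc_l), ("right", right, mask_r, arc_r)):
        sel = mask > 0
        pos, vol, t2m = _truth_profile(arc, t2_field, mask, voxvol, truth_n_bins)
        sides[name] = SideTruth(
            volume_mm3=float(sel.sum()) * voxvol,
            mean_t2_ms=float(t2_field[sel].mean()),
            profile_positions=pos,
            profile_volume_mm3=vol,
            profile_t2_ms=t2m,
        )

    return PhantomSubject(
        t1_like=t1_like,
        echo1=echo1,
        echo2=echo2,
        mask_left=LabelMask(data=mask_l, affine=affine.copy(), side="left"),
        mask_right=LabelMask(data=mask_r, affine=affine.copy(), side="right"),
        truth=PhantomTruth(left=sides["left"], right=sides["right"]),
        specs={"left": left, "right": right, "acq": acq, "background": background},
    )


def make_reference_cohort(
    n: int,
    variability: CohortVariability | None = None,
    seed: int = 0,
    acq: AcquisitionSpec | None = None,
) -> list[PhantomSubject]:
    """n lesion-free subjects with parameters drawn from the stated Gaussians.

    Per subject the draws are, in order: shared size factor, left and right
    per-side size factors, left and right T2, one mirrored control-point
    jitter. Subjects are built with ``acq.seed`` offset by the subject index
    so echo noise also reproduces under ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    variability = variability or CohortVariability()
    acq = acq or AcquisitionSpec()
    rng = np.random.default_rng(seed)
    subjects = []
    base_cl = {"left": default_centerline("left"), "right": default_centerline("right")}
    for i in range(n):
        shared = rng.normal(1.0, variability.vol_shared_sd)
        side_f = {"left": rng.normal(1.0, variability.vol_side_sd),
                  "right": rng.normal(1.0, variability.vol_side_sd)}
        t2_side = {"left": rng.normal(variability.t2_mean, variability.t2_sd),
                   "right": rng.normal(variability.t2_mean, variability.t2_sd)}
        jitter = rng.normal(0.0, variability.geom_jitter_mm, size=base_cl["right"].shape)
        specs = {}
        for side in ("left", "right"):
            factor = np.clip(shared * side_f[side], 0.5, 1.5)
            mirrored = jitter * (np.array([-1.0, 1.0, 1.0]) if side == "left" else 1.0)
            specs[side] = HippocampusSpec(
                side=side,
                centerline=base_cl[side] + mirrored,
                base_radius=5.5 * float(np.sqrt(factor)),
                t2=float(np.clip(t2_side[side], 50.0, 200.0)),
            )
        sub_acq = dataclasses.replace(acq, seed=int((seed + 1) * 100_003 + i) % (2**31 - 1))
        subjects.append(make_phantom_subject(specs["left"], specs["right"], sub_acq))
    return subjects


def draw_healthy_metrics(n: int, seed: int = 0,
                         variability: CohortVariability | None = None):
    """Parametric healthy global metrics, no imaging: fast cohort stand-in.

    Draws per-side volumes and qT2 from the same generative model as
    ``make_reference_cohort`` (shared x per-side Gaussian size factors on a
    nominal volume; per-side Gaussian T2) and derives the L:R ratios. Returns
    a list of ``morphometry_profiles.GlobalMetrics``.
    """
    from .morphometry_profiles import GlobalMetrics

    variability = variability or CohortVariability()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        shared = rng.normal(1.0, variability.vol_shared_sd)
        vl = NOMINAL_VOLUME_MM3 * shared * rng.normal(1.0, variability.vol_side_sd)
        vr = NOMINAL_VOLUME_MM3 * shared * rng.normal(1.0, variability.vol_side_sd)
        tl = rng.normal(variability.t2_mean, variability.t2_sd)
        tr = rng.normal(variability.t2_mean, variability.t2_sd)
        out.append(
            GlobalMetrics(
                vol_left=vl, vol_right=vr, qt2_left=tl, qt2_right=tr,
                lr_vol_ratio_pct=100.0 * vl / vr, lr_qt2_ratio_pct=100.0 * tl / tr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# on-disk representation


def _truth_dict(truth: PhantomTruth) -> dict:
    d = {}
    for side in ("left", "right"):
        st: SideTruth = getattr(truth, side)
        d[side] = {
            "volume_mm3": st.volume_mm3,
            "mean_t2_ms": st.mean_t2_ms,
            "profile_positions": st.profile_positions.tolist(),
            "profile_volume_mm3": st.profile_volume_mm3.tolist(),
            "profile_t2_ms": [None if np.isnan(x) else x for x in st.profile_t2_ms],
        }
    d["lr_vol_ratio_pct"] = truth.lr_vol_ratio_pct
    d["lr_qt2_ratio_pct"] = truth.lr_qt2_ratio_pct
    return d


def write_phantom_subject(subject: PhantomSubject, out_dir: str, subject_id: str = "sub-01") -> dict:
    """Write NIfTI volumes/masks plus a JSON ground-truth sidecar; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, vol in (
        ("t1", subject.t1_like), ("echo1", subject.echo1), ("echo2", subject.echo2),
        ("mask_left", subject.mask_left), ("mask_right", subject.mask_right),
    ):
        p = os.path.join(out_dir, f"{subject_id}_{name}.nii.gz")
        write_volume(vol, p)
        paths[name] = p
    sidecar = os.path.join(out_dir, f"{subject_id}_truth.json")
    acq = subject.specs.get("acq")
    meta = {"te1_ms": acq.te1, "te2_ms": acq.te2} if acq is not None else {}
    with open(sidecar, "w") as fh:
        json.dump({"truth": _truth_dict(subject.truth), "acquisition": meta}, fh, indent=1)
    paths["truth"] = sidecar
    return paths


def write_cohort(subjects: list[PhantomSubject], out_dir: str) -> str:
    """Write a cohort and its manifest CSV; returns the manifest path."""
    rows = []
    for i, sub in enumerate(subjects):
        sid = f"sub-{i + 1:03d}"
        paths = write_phantom_subject(sub, os.path.join(out_dir, sid), sid)
        rows.append(
            {
                "subject_id": sid,
                **{k: os.path.relpath(v, out_dir) for k, v in paths.items()},
                "true_vol_left_mm3": sub.truth.left.volume_mm3,
                "true_vol_right_mm3": sub.truth.right.volume_mm3,
                "true_qt2_left_ms": sub.truth.left.mean_t2_ms,
                "true_qt2_right_ms": sub.truth.right.mean_t2_ms,
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
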