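"""Trajectory analytics for the alternating-access pumping mechanism.

Operates on a minimal reader contract — per-frame coordinates for a fixed
atom roster plus named atom groups — rather than on any binary MD format,
so everything here runs on plain-text fixtures.  The analyses mirror the
quantities that support the mechanism: the B8–AE1 gating distance (≈17 Å
inward vs ≈24 Å outward), inward/outward/occluded classification from the
conserved hydrophobic gate pairs, the R67–E115 ion-pair state, Na⁺ axial
probability densities around the buried site, Boltzmann-inverted 2D free
energy surfaces, and grid flood-fill continuity of the ion pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .units import rt_kcal

__all__ = [
    "TrajectoryEnsemble",
    "GatingDefinition",
    "ClassificationResult",
    "DensityProfile",
    "PMF2D",
    "PathwayResult",
    "distance_series",
    "rolling_average",
    "classify_conformations",
    "ion_pair_fraction",
    "sodium_axial_density",
    "pmf_2d",
    "fit_parabolic_curvature",
    "pathway_continuity",
]

VDW_RADII_A = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "FE": 1.4, "NA": 2.27,
               "P": 1.8, "H": 1.1}
_DEFAULT_VDW = 1.7


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms × 3 coordinates, an atom roster, and named selections."""

    coords: np.ndarray
    atoms: pd.DataFrame
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom roster does not match coordinate array")
        self.groups = {k: np.asarray(v, int) for k, v in self.groups.items()}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def select(self, group: str) -> np.ndarray:
        if group not in self.groups or len(self.groups[group]) == 0:
            raise KeyError(f"selection {group!r} is empty or undefined")
        return self.groups[group]


def distance_series(
    traj: TrajectoryEnsemble, group_a: str, group_b: str, mode: str = "min"
) -> np.ndarray:
    """Per-frame distance between two atom groups (min-pair or centroid)."""
    ia, ib = traj.select(group_a), traj.select(group_b)
    a = traj.coords[:, ia]  # (F, na, 3)
    b = traj.coords[:, ib]
    if mode == "centroid":
        return np.linalg.norm(a.mean(axis=1) - b.mean(axis=1), axis=1)
    if mode != "min":
        raise ValueError("mode must be 'min' or 'centroid'")
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))


def rolling_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with shrinking edge windows; same length out."""
    series = np.asarray(series, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series):
        raise ValueError("window exceeds series length")
    return (
        pd.Series(series).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


@dataclass
class GatingDefinition:
    """Gate pairs and thresholds for alternating-access classification.

    The intracellular gate is the L108(RnfA)–L22(RnfE) pair, the
    extracellular gate L103(RnfE)–L22(RnfA); each is open when its
    sidechain minimum distance exceeds ``open_A`` and closed below
    ``closed_A``.  Distances inside the band are resolved by the midpoint
    and counted as ambiguous — classification is stateless so that it is
    invariant to frame-order permutation.
    """

    intracellular_pair: tuple[str, str] = ("gate_ic_a", "gate_ic_b")
    extracellular_pair: tuple[str, str] = ("gate_ec_a", "gate_ec_b")
    open_A: float = 9.0
    closed_A: float = 6.0

    def __post_init__(self) -> None:
        if self.open_A <= self.closed_A:
            raise ValueError("open threshold must exceed closed threshold")


@dataclass
class ClassificationResult:
    """Per-frame labels plus leak/ambiguity diagnostics."""

    labels: np.ndarray
    leak_count: int
    ambiguous_count: int

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label))


def classify_conformations(
    traj: TrajectoryEnsemble, gates: GatingDefinition | None = None
) -> ClassificationResult:
    """Label frames inward/outward/occluded from the two gate distances.

    Intracellular open ∧ extracellular closed → inward; the converse →
    outward; both closed → occluded.  Both gates open would mean direct
    access across the membrane — an ion leak the mechanism forbids — so
    such frames are labelled 'leak' and counted.
    """
    gates = gates or GatingDefinition()
    d_ic = distance_series(traj, *gates.intracellular_pair)
    d_ec = distance_series(traj, *gates.extracellular_pair)
    mid = 0.5 * (gates.open_A + gates.closed_A)
    ambiguous = int(
        np.sum((d_ic > gates.closed_A) & (d_ic < gates.open_A))
        + np.sum((d_ec > gates.closed_A) & (d_ec < gates.open_A))
    )
    ic_open = d_ic >= mid
    ec_open = d_ec >= mid
    labels = np.where(
        ic_open & ~ec_open,
        "inward",
        np.where(~ic_open & ec_open, "outward",
                 np.where(ic_open & ec_open, "leak", "occluded")),
    )
    leaks = int(np.sum(labels == "leak"))
    if leaks:
        warnings.warn(
            f"{leaks} frame(s) with both gates open (possible ion leak)",
            stacklevel=2,
        )
    return ClassificationResult(labels=labels, leak_count=leaks,
                                ambiguous_count=ambiguous)


def ion_pair_fraction(
    traj: TrajectoryEnsemble,
    pair: tuple[str, str] = ("ionpair_n", "ionpair_o"),
    cutoff_A: float = 4.0,
    labels: np.ndarray | None = None,
) -> dict[str, float]:
    """Fraction of frames with the salt bridge closed, per conformational class.

    Closed means the minimum N–O distance of the pair is ≤ cutoff (4 Å, the
    common salt-bridge criterion).  Without labels a single 'all' class is
    reported; classes with no frames are omitted with a notice.
    """
    d = distance_series(traj, *pair)
    closed = d <= cutoff_A
    if labels is None:
        return {"all": float(closed.mean())}
    out = {}
    for cls in ("inward", "outward", "occluded", "leak"):
        mask = labels == cls
        if not mask.any():
            continue
        out[cls] = float(closed[mask].mean())
    return out


@dataclass
class DensityProfile:
    """Normalized probability density along the membrane normal."""

    bin_centers_A: np.ndarray
    density: np.ndarray

    def integral(self) -> float:
        dz = self.bin_centers_A[1] - self.bin_centers_A[0]
        return float(self.density.sum() * dz)


def sodium_axial_density(
    traj: TrajectoryEnsemble,
    ions: str = "sodium",
    reference_group: str = "ae1",
    bins: int = 80,
    z_range: tuple[float, float] = (-25.0, 25.0),
    labels: np.ndarray | None = None,
    label: str | None = None,
) -> DensityProfile:
    """Histogram of ion z-offsets from the reference centroid.

    The reference centroid (the AE1 cluster for RnfA/E, M246 for RnfD)
    defines z = 0 in every frame.  With `labels`/`label` given, only
    frames of that conformational class enter the histogram.
    """
    ii = traj.select(ions)
    ir = traj.select(reference_group)
    ref_z = traj.coords[:, ir, 2].mean(axis=1)
    dz = traj.coords[:, ii, 2] - ref_z[:, None]
    if labels is not None and label is not None:
        dz = dz[labels == label]
    vals = dz.ravel()
    vals = vals[(vals >= z_range[0]) & (vals <= z_range[1])]
    edges = np.linspace(z_range[0], z_range[1], bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if vals.size == 0:
        warnings.warn("no ions within the axial range; returning zero profile",
                      stacklevel=2)
        return DensityProfile(centers, np.zeros(bins))
    hist, _ = np.histogram(vals, bins=edges, density=True)
    return DensityProfile(centers, hist)


@dataclass
class PMF2D:
    """Boltzmann-inverted free-energy surface; empty bins are NaN."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    free_energy_kcal: np.ndarray
    temperature_K: float


def pmf_2d(
    rc1: np.ndarray,
    rc2: np.ndarray,
    temperature_K: float = 310.0,
    bins: int = 40,
) -> PMF2D:
    """−k_B·T·ln of the normalized 2D histogram, minimum shifted to zero.

    Empty bins come out as NaN (undefined, not zero).  The surface is
    invariant to adding a constant to the coordinates and scales linearly
    with temperature.
    """
    rc1 = np.asarray(rc1, float)
    rc2 = np.asarray(rc2, float)
    if rc1.size < bins * 10:
        warnings.warn("fewer than 10 samples per bin on average", stacklevel=2)
    hist, xe, ye = np.histogram2d(rc1, rc2, bins=bins)
    if (hist > 0).sum() <= 1:
        raise ValueError("all samples fall in one bin; surface is degenerate")
    prob = hist / hist.sum()
    with np.errstate(divide="ignore"):
        fes = -rt_kcal(temperature_K) * np.log(prob)
    fes[prob == 0] = np.nan
    fes -= np.nanmin(fes)
    return PMF2D(
        x_centers=0.5 * (xe[:-1] + xe[1:]),
        y_centers=0.5 * (ye[:-1] + ye[1:]),
        free_energy_kcal=fes,
        temperature_K=temperature_K,
    )


def fit_parabolic_curvature(pmf: PMF2D, max_radius: float | None = None):
    """Least-squares quadratic fit F ≈ c + ½·(kx·x² + ky·y²) about the minimum.

    Returns (kx, ky) in kcal/mol/unit².  For samples from an isotropic
    Gaussian of width σ the true curvature is k_B·T/σ².
    """
    F = pmf.free_energy_kcal
    X, Y = np.meshgrid(pmf.x_centers, pmf.y_centers, indexing="ij")
    imin = np.unravel_index(np.nanargmin(F), F.shape)
    x0, y0 = X[imin], Y[imin]
    dx, dy = X - x0, Y - y0
    mask = ~np.isnan(F)
    if max_radius is not None:
        mask &= dx**2 + dy**2 <= max_radius**2
    A = np.column_stack(
        [np.ones(mask.sum()), dx[mask], dy[mask], dx[mask] ** 2, dy[mask] ** 2]
    )
    coef, *_ = np.linalg.lstsq(A, F[mask], rcond=None)
    return 2.0 * coef[3], 2.0 * coef[4]


@dataclass
class PathwayResult:
    """Outcome of the grid flood-fill continuity analysis."""

    continuous: bool
    n_path_voxels: int
    grid_shape: tuple[int, int, int]
    path_mask: np.ndarray | None = None


def pathway_continuity(
    coords: np.ndarray,
    elements,
    z_bounds: tuple[float, float],
    probe_radius_A: float = 1.4,
    grid_A: float = 0.8,
    xy_bounds: tuple[float, float, float, float] | None = None,
    keep_mask: bool = False,
) -> PathwayResult:
    """Is there a water-probe-accessible channel across the membrane slab?

    Free space is voxelized (a voxel is free when it lies farther than
    probe + vdW radius from every atom), flood-filled from the cytoplasmic
    (high-z) face, and continuity holds when any voxel on the periplasmic
    (low-z) face is reached.  Monotone in probe radius: widening the probe
    can only close a channel.
    """
    if grid_A > probe_radius_A:
        raise ValueError("grid spacing must not exceed the probe radius")
    coords = np.asarray(coords, float)
    radii = np.array(
        [VDW_RADII_A.get(str(e).upper(), _DEFAULT_VDW) for e in elements]
    )
    zlo, zhi = min(z_bounds), max(z_bounds)
    sel = (coords[:, 2] >= zlo - 5.0) & (coords[:, 2] <= zhi + 5.0)
    coords, radii = coords[sel], radii[sel]
    if xy_bounds is None:
        xlo, xhi = coords[:, 0].min(), coords[:, 0].max()
        ylo, yhi = coords[:, 1].min(), coords[:, 1].max()
    else:
        xlo, xhi, ylo, yhi = xy_bounds
    xs = np.arange(xlo, xhi + grid_A / 2, grid_A)
    ys = np.arange(ylo, yhi + grid_A / 2, grid_A)
    zs = np.arange(zlo, zhi + grid_A / 2, grid_A)
    free = np.ones((len(xs), len(ys), len(zs)), dtype=bool)

    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    voxels = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(voxels)
    for pos, r in zip(coords, radii):
        hit = tree.query_ball_point(pos, r + probe_radius_A)
        if hit:
            free.ravel()[hit] = False

    labels, _ = ndimage.label(free)
    top = np.unique(labels[:, :, -1])
    bottom = np.unique(labels[:, :, 0])
    shared = set(top[top > 0]) & set(bottom[bottom > 0])
    if shared:
        mask = np.isin(labels, list(shared))
    else:
        # the connected set reachable from the cytoplasmic face
        mask = np.isin(labels, [l for l in top if l > 0]) if top.any() else np.zeros_like(free)
    return PathwayResult(
        continuous=bool(shared),
        n_path_voxels=int(mask.sum()),
        grid_shape=free.shape,
        path_mask=mask if keep_mask else None,
    )
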