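"""Protein size and shape metrics: radius of gyration and its distribution,
principal-axis (long axis / width / height) dimensions from marker residues,
and Shrake–Rupley solvent-accessible surface area.

The radius of gyration is the mass-weighted second moment about the center
of mass, Rg² = Σ mᵢ(rᵢ−R)²/Σ mᵢ. Anatomical dimensions project the distance
vector between two marker groups onto the gyration-tensor principal axes
(PA1 for the long axis, PA2 for width, PA3 for height). No periodic wrapping
is applied: the selection is assumed whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import Trajectory

#: Bondi van der Waals radii, nm (element-keyed; configurable per call)
BONDI_RADII_NM = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "F": 0.147, "CL": 0.175, "BR": 0.185, "I": 0.198,
    "NA": 0.227, "K": 0.275, "MG": 0.173, "CA": 0.231, "ZN": 0.139,
}


@dataclass
class RgSeries:
    """Per-frame radius of gyration (nm) with summary statistics."""

    values: np.ndarray
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("Rg must be non-negative")
        self.mean = float(self.values.mean())
        self.sd = float(self.values.std(ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class RgHistogram:
    """Density-normalized Rg histogram pooled over trajectories."""

    bin_edges: np.ndarray
    density: np.ndarray
    mean: float
    sd: float
    per_series_means: list

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DimensionResult:
    """Per-frame anatomical dimensions (nm); axes are not sorted by length."""

    la: np.ndarray
    w: np.ndarray
    h: np.ndarray

    def summary(self) -> dict:
        out = {}
        for name, arr in (("LA", self.la), ("W", self.w), ("H", self.h)):
            out[name] = (float(arr.mean()),
                         float(arr.std(ddof=1)) if len(arr) > 1 else 0.0)
        return out


@dataclass
class SasaResult:
    """Per-frame total SASA (nm²) of a selection."""

    values: np.ndarray
    probe_radius: float
    n_sphere_points: int


def _indices(traj: Trajectory, selection) -> np.ndarray:
    """Map atom ids (or None = all) to coordinate row positions."""
    if selection is None:
        return np.arange(traj.n_atoms)
    sel = np.asarray(selection, dtype=int)
    order = np.argsort(traj.topology.ids)
    pos = order[np.searchsorted(traj.topology.ids, sel, sorter=order)]
    if np.any(traj.topology.ids[pos] != sel):
        raise KeyError("selection contains unknown atom ids")
    return pos


def _com(coords, masses):
    return np.einsum("...ij,...i->...j", coords, masses) / masses.sum()


def radius_of_gyration(traj: Trajectory, selection=None) -> RgSeries:
    """Mass-weighted Rg per frame over the selection (assumed whole)."""
    idx = _indices(traj, selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    m = traj.topology.masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    x = traj.coords[:, idx, :]                       # (F, n, 3)
    com = _com(x, m)                                 # (F, 3)
    d2 = np.sum((x - com[:, None, :]) ** 2, axis=2)  # (F, n)
    return RgSeries(np.sqrt(d2 @ m / total))


def gyration_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted gyration tensor S = Σ mᵢ(rᵢ−R)(rᵢ−R)ᵀ / M for one frame."""
    com = coords.T @ masses / masses.sum()
    d = coords - com
    return (d * masses[:, None]).T @ d / masses.sum()


def rg_distribution(series, bin_width: float) -> RgHistogram:
    """Pooled, density-normalized Rg histogram from one or more RgSeries."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(series, RgSeries):
        series = [series]
    values = [np.asarray(s.values if isinstance(s, RgSeries) else s, dtype=float)
              for s in series]
    pooled = np.concatenate(values)
    if len(pooled) < 2:
        raise ValueError("at least 2 frames required for a distribution")
    lo = np.floor(pooled.min() / bin_width) * bin_width
    n = max(1, int(np.ceil((pooled.max() - lo) / bin_width + 1e-9)))
    edges = lo + bin_width * np.arange(n + 1)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    return RgHistogram(bin_edges=edges, density=density,
                       mean=float(pooled.mean()),
                       sd=float(pooled.std(ddof=1)),
                       per_series_means=[float(v.mean()) for v in values])


def axis_dimensions(traj: Trajectory, selection=None, marker_pairs=None,
                    degeneracy_rtol: float = 1e-8) -> DimensionResult:
    """Anatomical LA/W/H per frame.

    marker_pairs maps 'LA'/'W'/'H' to a pair (ids_a, ids_b) of atom-id groups;
    if None, groups are taken from the topology marker labels (two atoms per
    axis). Per frame, the principal axes of the mass-weighted gyration tensor
    (eigenvalues descending: PA1, PA2, PA3) are computed, and each dimension
    is the absolute component of the vector between the two marker-group
    centers of mass along its assigned axis. Axis sign/order ambiguity across
    frames is resolved by maximal overlap with the previous frame's axes;
    degenerate eigenvalues trigger a warning.
    """
    idx = _indices(traj, selection)
    m = traj.topology.masses[idx]
    if marker_pairs is None:
        marker_pairs = {}
        for ax in ("LA", "W", "H"):
            ids = traj.topology.ids[traj.topology.marker == ax]
            if len(ids) != 2:
                raise ValueError(f"topology does not define a marker pair for {ax}")
            marker_pairs[ax] = ([ids[0]], [ids[1]])
    pair_idx = {ax: (_indices(traj, a), _indices(traj, b))
                for ax, (a, b) in marker_pairs.items()}

    out = {ax: np.empty(traj.n_frames) for ax in ("LA", "W", "H")}
    prev_axes = None
    warned = False
    for f in range(traj.n_frames):
        x = traj.coords[f, idx, :]
        s = gyration_tensor(x, m)
        evals, evecs = np.linalg.eigh(s)           # ascending
        evals, evecs = evals[::-1], evecs[:, ::-1]  # PA1..PA3 descending
        degenerate = np.any(np.diff(evals) > -degeneracy_rtol *
                            max(evals[0], 1e-30))
        if degenerate and prev_axes is not None:
            # eigenvalue order is ambiguous: tie-break by greedy |overlap|
            # with the previous frame's axes
            if not warned:
                warnings.warn("near-degenerate gyration-tensor eigenvalues; "
                              "axis assignment tie-broken by continuity with "
                              "the previous frame")
                warned = True
            overlap = np.abs(prev_axes.T @ evecs)
            order = np.full(3, -1)
            for _ in range(3):
                i, j = np.unravel_index(np.argmax(overlap), overlap.shape)
                order[i] = j
                overlap[i, :] = -1
                overlap[:, j] = -1
            evecs = evecs[:, order]
        prev_axes = evecs
        for axis_name, pa in zip(("LA", "W", "H"), evecs.T):
            ia, ib = pair_idx[axis_name]
            ca = _com(traj.coords[f, ia, :], traj.topology.masses[ia])
            cb = _com(traj.coords[f, ib, :], traj.topology.masses[ib])
            out[axis_name][f] = abs(np.dot(ca - cb, pa))
    return DimensionResult(la=out["LA"], w=out["W"], h=out["H"])


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z ** 2))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _atom_radii(traj: Trajectory, idx, radii, radii_table):
    if radii is not None:
        r = np.asarray(radii, dtype=float)
        if r.ndim == 0:
            return np.full(len(idx), float(r))
        if len(r) == len(idx):
            return r
        return r[idx]
    table = radii_table or BONDI_RADII_NM
    out = np.empty(len(idx))
    for k, i in enumerate(idx):
        el = str(traj.topology.elements[i]).upper()
        if el not in table:
            raise KeyError(
                f"no van der Waals radius for element {el or '<blank>'!r}; "
                "supply per-atom radii or extend the radii table")
        out[k] = table[el]
    return out


def sasa(traj: Trajectory, selection=None, probe_radius: float = 0.14,
         n_sphere_points: int = 960, radii=None,
         radii_table: dict | None = None, frame=None) -> SasaResult:
    """Shrake–Rupley SASA of a selection, per frame (nm²).

    For every atom, ``n_sphere_points`` golden-spiral test points are placed
    on its probe-inflated sphere; the exposed fraction (points not buried in
    any neighbor's inflated sphere) times the sphere area is accumulated.
    Neighbor lookup uses a KD-tree. Only selection atoms occlude each other.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    idx = _indices(traj, selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    r_atom = _atom_radii(traj, idx, radii, radii_table)
    r_infl = r_atom + probe_radius
    unit = _sphere_points(n_sphere_points)
    frames = range(traj.n_frames) if frame is None else [frame]
    totals = np.zeros(len(list(frames)))
    frames = range(traj.n_frames) if frame is None else [frame]
    rmax = r_infl.max()
    for k, f in enumerate(frames):
        x = traj.coords[f, idx, :]
        tree = cKDTree(x)
        area = 0.0
        for a in range(len(idx)):
            pts = x[a] + r_infl[a] * unit
            neigh = [j for j in tree.query_ball_point(x[a], r_infl[a] + rmax)
                     if j != a]
            exposed = np.ones(n_sphere_points, dtype=bool)
            for j in neigh:
                d2 = np.sum((pts - x[j]) ** 2, axis=1)
                exposed &= d2 > r_infl[j] ** 2
            area += exposed.mean() * 4.0 * np.pi * r_infl[a] ** 2
        totals[k] = area
    return SasaResult(values=totals, probe_radius=probe_radius,
                      n_sphere_points=n_sphere_points)
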