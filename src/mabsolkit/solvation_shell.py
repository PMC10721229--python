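"""Surface-minimum-distance radial distribution functions, their linear-fit
rescaling, coordination numbers, and residence (survival) statistics.

"Distance to the protein surface" means the minimum atom-center distance from
a solvent/ion atom to any protein atom under the minimum-image convention
(orthorhombic boxes only). The unnormalized RDF is the per-frame count of
species atoms in each distance bin divided by the bin width, averaged over
frames, so its integral to r equals the mean number of species atoms within
r of the surface — an identity tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory_io import Trajectory
from .structure_metrics import _indices


@dataclass
class RadialProfile:
    """Counts-per-bin-width vs distance-to-surface, frame-averaged."""

    r: np.ndarray            # bin centers, nm
    values: np.ndarray       # mean count / bin width
    bin_width: float
    n_frames: int
    species: str = ""

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.concatenate([self.r - self.bin_width / 2,
                               [self.r[-1] + self.bin_width / 2]])


@dataclass
class RescaledProfile:
    """Profile divided by a linear fit over a stated window."""

    r: np.ndarray
    values: np.ndarray
    slope: float
    intercept: float
    fit_window: tuple
    bin_width: float


@dataclass
class SurvivalCurve:
    """Residence probability P(t) of species atoms near the surface."""

    lags: np.ndarray         # ps
    p: np.ndarray
    cutoff: float            # nm
    definition: str          # 'continuous' | 'intermittent'

    def __post_init__(self):
        if abs(self.p[0] - 1.0) > 1e-12:
            raise ValueError("P(0) must be 1")


def _min_image_surface_distances(traj: Trajectory, protein_idx, species_idx,
                                 frame: int) -> np.ndarray:
    """Min over protein atoms of the minimum-image distance, per species atom."""
    box = traj.box[frame]
    prot = np.mod(traj.coords[frame, protein_idx, :], box)
    spec = np.mod(traj.coords[frame, species_idx, :], box)
    # periodic KD-tree gives exact minimum-image nearest-neighbor distances
    tree = cKDTree(prot, boxsize=box)
    d, _ = tree.query(spec, k=1)
    return d


def surface_rdf(traj: Trajectory, protein_selection, species_selection,
                bin_width: float, r_max: float | None = None,
                species: str = "") -> RadialProfile:
    """Unnormalized surface-distance RDF, averaged over frames.

    Each species atom is binned by its minimum distance to the protein
    surface; counts are divided by the bin width. Distances are
    center-to-center (no van der Waals radii). Triclinic boxes are rejected.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    p_idx = _indices(traj, protein_selection)
    s_idx = _indices(traj, species_selection)
    if len(p_idx) == 0:
        raise ValueError("empty protein selection")
    if len(set(p_idx) & set(s_idx)) > 0:
        raise ValueError("protein and species selections must be disjoint")
    if r_max is None:
        r_max = float(traj.box.min()) / 2.0
    n_bins = int(np.ceil(r_max / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for f in range(traj.n_frames):
        d = _min_image_surface_distances(traj, p_idx, s_idx, f)
        c, _ = np.histogram(d, bins=edges)
        counts += c
    values = counts / traj.n_frames / bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r=centers, values=values, bin_width=bin_width,
                         n_frames=traj.n_frames, species=species)


def rescale_rdf(profile: RadialProfile,
                fit_window: tuple = (1.0, 2.0)) -> RescaledProfile:
    """Divide the profile by a straight line fitted on the window.

    Matches the normalization used for comparing hydration profiles between
    systems: a least-squares line a + b·r on the window, then division by the
    line at every bin center. Errors out if the line crosses zero inside the
    profile support (division blow-up).
    """
    lo, hi = fit_window
    mask = (profile.r >= lo) & (profile.r <= hi)
    if mask.sum() < 5:
        raise ValueError("need at least 5 bins inside the fit window")
    b, a = np.polyfit(profile.r[mask], profile.values[mask], 1)
    line = a + b * profile.r
    if np.any(line <= 0):
        raise ValueError("fitted line crosses zero inside the profile "
                         "support; rescaling would blow up")
    return RescaledProfile(r=profile.r, values=profile.values / line,
                           slope=float(b), intercept=float(a),
                           fit_window=(float(lo), float(hi)),
                           bin_width=profile.bin_width)


def coordination_number(profile: RadialProfile, r_cut: float) -> float:
    """Integral of the unnormalized profile from 0 to r_cut.

    The profile is a step function (count/bin-width per bin), so its exact
    integral is the cumulative bin sum plus the fractional part of the bin
    containing r_cut; this equals the mean species count within r_cut.
    """
    edges = profile.bin_edges
    if r_cut < 0 or r_cut > edges[-1] + 1e-12:
        raise ValueError(f"r_cut {r_cut:g} outside profile support "
                         f"[0, {edges[-1]:g}]")
    full = edges[1:] <= r_cut + 1e-15
    total = float(np.sum(profile.values[full]) * profile.bin_width)
    j = np.searchsorted(edges[1:], r_cut + 1e-15)
    if j < len(profile.values):
        total += float(profile.values[j] * (r_cut - edges[j]))
    return total


def cumulative_profile(profile: RadialProfile) -> np.ndarray:
    """Mean count within the right edge of each bin (exact step integral)."""
    return np.cumsum(profile.values) * profile.bin_width


def survival_probability(traj: Trajectory, protein_selection,
                         species_selection, cutoff: float = 0.35,
                         definition: str = "intermittent") -> SurvivalCurve:
    """Residence probability of species atoms within ``cutoff`` of the surface.

    h_i(t) = 1 if atom i is within the cutoff at frame t. The intermittent
    definition P(t) = ⟨h(t0)h(t0+t)⟩/⟨h(t0)⟩ allows excursions and return;
    the continuous definition requires uninterrupted residence over the whole
    interval. Both average over all time origins; frames must be uniformly
    spaced in time.
    """
    if definition not in ("continuous", "intermittent"):
        raise ValueError("definition must be 'continuous' or 'intermittent'")
    if traj.n_frames < 2:
        raise ValueError("at least 2 frames required")
    dt = np.diff(traj.time)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("frames must be uniformly spaced in time")
    p_idx = _indices(traj, protein_selection)
    s_idx = _indices(traj, species_selection)
    h = np.zeros((traj.n_frames, len(s_idx)), dtype=bool)
    for f in range(traj.n_frames):
        d = _min_image_surface_distances(traj, p_idx, s_idx, f)
        h[f] = d <= cutoff
    if not h.any():
        raise ValueError("no species atom ever within the cutoff")
    n_lags = traj.n_frames
    p = np.empty(n_lags)
    hf = h.astype(float)
    if definition == "continuous":
        # streak[t, i] = length of the run of consecutive frames inside,
        # starting at t; continuous survival over lag t needs streak >= t+1
        streak = np.zeros(h.shape, dtype=int)
        streak[-1] = h[-1]
        for f in range(traj.n_frames - 2, -1, -1):
            streak[f] = np.where(h[f], streak[f + 1] + 1, 0)
    for t in range(n_lags):
        origins = hf[:n_lags - t]
        if definition == "intermittent":
            joint = (origins * hf[t:]).sum()
        else:
            joint = np.count_nonzero(streak[:n_lags - t] >= t + 1)
        denom = origins.sum()
        p[t] = joint / denom if denom > 0 else np.nan
    lags = dt[0] * np.arange(n_lags) if traj.n_frames > 1 else np.array([0.0])
    return SurvivalCurve(lags=lags, p=p, cutoff=cutoff, definition=definition)
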