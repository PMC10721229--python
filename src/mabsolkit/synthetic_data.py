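"""Synthetic-data generators with known ground truth for every pipeline stage.

These emulate, statistically rather than physically, the inputs the analysis
consumes: (a) an ellipsoidal flexible protein as a rigid bead cloud under
random rigid motions plus an isotropic "breathing" scale fluctuation; (b) ion
clouds around a charged center whose ensemble-mean net charge decays
exponentially with a prescribed screening length; (c) umbrella-sampling
windows Boltzmann-sampled from an analytic PMF under harmonic bias; (d)
Guinier-regime small-angle scattering curves and linear SLS Debye-plot
series with noise. All generators are bitwise-reproducible under a fixed
seed. Defaults mirror the study conditions: 300 K, 150 mM 1:1 salt, 12 nm
box, 51 umbrella windows 3.0–8.0 nm with k = 1000 kJ/mol/nm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import T_DEFAULT, kt_kj_mol
from .pmf_virial import UmbrellaWindowSet
from .scattering_fits import ScatteringCurve, SLSSeries
from .trajectory_io import Topology, Trajectory


# ---------------------------------------------------------------------------
# ellipsoidal protein


@dataclass
class EllipsoidProteinSpec:
    """Rigid bead ellipsoid with axis-tip markers and a breathing mode.

    semi_axes: (a, b, c) in nm, strictly positive; the six marker beads sit
    at ±a·x̂, ±b·ŷ, ±c·ẑ on the surface. breathing_amplitude is the relative
    isotropic scale fluctuation, in [0, 0.5). n_beads must be 6 + 8k: the
    non-marker beads are generated as octant-symmetric 8-fold orbits so the
    gyration tensor is exactly diagonal in the body frame and the principal
    axes coincide exactly with the ellipsoid axes.
    """

    semi_axes: tuple = (3.9, 2.875, 2.275)
    n_beads: int = 406
    bead_mass: float = 110.0
    breathing_amplitude: float = 0.0
    marker_bead_ids: tuple = (0, 1, 2, 3, 4, 5)
    seed: int = 0

    def __post_init__(self):
        a = np.asarray(self.semi_axes, dtype=float)
        if a.shape != (3,) or np.any(a <= 0):
            raise ValueError("semi_axes must be three positive lengths")
        if not 0 <= self.breathing_amplitude < 0.5:
            raise ValueError("breathing_amplitude must lie in [0, 0.5)")
        if self.n_beads < 6:
            raise ValueError("n_beads must be at least 6 to place the markers")
        if (self.n_beads - 6) % 8 != 0:
            raise ValueError("n_beads must be 6 + 8k (octant-symmetric bead "
                             "orbits keep the principal axes exact)")
        if len(set(self.marker_bead_ids)) != 6:
            raise ValueError("six distinct marker bead ids required")


def _ellipsoid_beads(spec: EllipsoidProteinSpec) -> np.ndarray:
    """Body-frame bead coordinates; markers first, then 8-fold orbits."""
    a, b, c = spec.semi_axes
    markers = np.array([[a, 0, 0], [-a, 0, 0],
                        [0, b, 0], [0, -b, 0],
                        [0, 0, c], [0, 0, -c]], dtype=float)
    n_orbits = (spec.n_beads - 6) // 8
    rng = np.random.default_rng(spec.seed)
    orbit_pts = np.empty((0, 3))
    if n_orbits:
        u = np.abs(rng.standard_normal((n_orbits, 3)))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        base = u * np.array([a, b, c])
        signs = np.array([[sx, sy, sz] for sx in (1, -1)
                          for sy in (1, -1) for sz in (1, -1)], dtype=float)
        orbit_pts = (base[:, None, :] * signs[None, :, :]).reshape(-1, 3)
    n = spec.n_beads
    marker_ids = np.asarray(spec.marker_bead_ids, dtype=int)
    if marker_ids.min() < 0 or marker_ids.max() >= n:
        raise ValueError("marker_bead_ids out of range")
    beads = np.empty((n, 3))
    beads[marker_ids] = markers
    other = np.setdiff1d(np.arange(n), marker_ids)
    beads[other] = orbit_pts
    return beads


def gen_protein_trajectory(spec: EllipsoidProteinSpec, n_frames: int,
                           box_edge: float = 12.0) -> Trajectory:
    """Frames of the bead ellipsoid under random rigid motion and breathing.

    Each frame applies an isotropic scale 1 + A·u (u uniform in [−1, 1]),
    a uniformly random rotation and a random translation inside the box.
    Deterministic under the spec seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    body = _ellipsoid_beads(spec)
    n = len(body)
    rng = np.random.default_rng(spec.seed)
    coords = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        s = 1.0 + spec.breathing_amplitude * rng.uniform(-1.0, 1.0)
        rot = Rotation.random(random_state=rng).as_matrix()
        t = box_edge * rng.uniform(0.35, 0.65, size=3)
        coords[f] = (s * body) @ rot.T + t
    marker = np.full(n, "", dtype=object)
    for mid, label in zip(spec.marker_bead_ids,
                          ("LA", "LA", "W", "W", "H", "H")):
        marker[mid] = label
    top = Topology.simple(n, masses=spec.bead_mass, species="protein",
                          resnames="ELP")
    top.marker = marker
    return Trajectory(top, coords, np.full(3, box_edge),
                      time=np.arange(n_frames, dtype=float))


# ---------------------------------------------------------------------------
# ion cloud


@dataclass
class IonCloudSpec:
    """Monovalent ion cloud around a central charged 'protein' particle.

    The ensemble-mean net charge within r decays as
    Q_protein·exp(−r/target_zeta); counterion excess equals |protein_charge|
    and every frame is exactly neutral. bulk_concentration is nominal
    metadata (the generator fixes the pair count, not the density).
    """

    protein_charge: int = 11
    bulk_concentration: float = 0.15   # mol/L, nominal
    target_zeta: float = 0.79          # nm
    box_edge: float = 12.0             # nm
    n_ion_pairs: int = 148
    seed: int = 0

    def __post_init__(self):
        if self.target_zeta <= 0:
            raise ValueError("target_zeta must be positive")
        if self.box_edge <= 6.0 * self.target_zeta:
            raise ValueError("box_edge must exceed 6×target_zeta so the "
                             "screened profile fits the half-box")
        if self.n_ion_pairs < 0:
            raise ValueError("n_ion_pairs must be non-negative")
        if self.n_ion_pairs == 0 and self.protein_charge != 0:
            # still feasible (counterions only); nothing to reject
            pass


def gen_ion_cloud(spec: IonCloudSpec, n_frames: int = 200) -> Trajectory:
    """Frames of cations/anions around a central protein particle.

    Bulk ions (``n_ion_pairs`` of each sign) are uniform in the half-box
    sphere; |protein_charge| excess counterions have radii drawn by inverse
    CDF from the exponential density ∝ exp(−r/ζ) truncated at the half-box,
    so the mean net charge beyond r decays as Q·exp(−r/ζ). Directions are
    uniform on the sphere; each frame is exactly neutral.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    q = int(spec.protein_charge)
    n_pairs = spec.n_ion_pairs
    n_cat = n_pairs + (abs(q) if q < 0 else 0)
    n_an = n_pairs + (q if q > 0 else 0)
    n_atoms = 1 + n_cat + n_an
    r_half = spec.box_edge / 2.0
    zeta = spec.target_zeta
    rng = np.random.default_rng(spec.seed)
    center = np.full(3, r_half)

    def sphere_dirs(n):
        v = rng.standard_normal((n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    norm = 1.0 - np.exp(-r_half / zeta)
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        coords[f, 0] = center
        # bulk pairs: uniform density in the half-box sphere
        r_bulk = r_half * rng.uniform(size=2 * n_pairs) ** (1.0 / 3.0)
        # screening counterions: truncated exponential via inverse CDF
        r_scr = -zeta * np.log1p(-norm * rng.uniform(size=abs(q)))
        radii = np.concatenate([r_bulk[:n_pairs],           # bulk cations
                                r_scr if q < 0 else np.empty(0),
                                r_bulk[n_pairs:],           # bulk anions
                                r_scr if q > 0 else np.empty(0)])
        coords[f, 1:] = center + radii[:, None] * sphere_dirs(n_atoms - 1)

    species = np.array(["protein"] + ["cation"] * n_cat + ["anion"] * n_an,
                       dtype=object)
    charges = np.concatenate([[float(q)], np.ones(n_cat), -np.ones(n_an)])
    masses = np.concatenate([[50000.0], np.full(n_cat, 22.990),
                             np.full(n_an, 35.453)])
    top = Topology.simple(n_atoms)
    top.species = species
    top.charges = charges
    top.masses = masses
    top.resnames = np.array(["PRO"] + ["NA"] * n_cat + ["CL"] * n_an,
                            dtype=object)
    top.resids = np.arange(1, n_atoms + 1)
    return Trajectory(top, coords, np.full(3, spec.box_edge),
                      time=np.arange(n_frames, dtype=float))


# ---------------------------------------------------------------------------
# analytic PMFs and umbrella windows


@dataclass
class AnalyticPMFSpec:
    """Analytic ground-truth PMF ΔG(r) in kJ/mol over r_range (nm).

    Forms: 'flat' (ΔG ≡ 0), 'gaussian_well'
    (ΔG = −depth·exp(−(r−center)²/(2·width²))), and 'hard_wall_plus_well'
    (gaussian well plus an infinite wall below r_range[0]). well_depth ≥ 0 is
    the depth of the attraction: min ΔG = −well_depth.
    """

    form: str = "gaussian_well"
    well_depth: float = 14.0
    well_center: float = 3.6
    well_width: float = 0.25
    r_range: tuple = (3.0, 8.0)

    def __post_init__(self):
        if self.form not in ("flat", "gaussian_well", "hard_wall_plus_well"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        if self.r_range[0] >= self.r_range[1]:
            raise ValueError("r_range must be ordered")
        if self.well_depth < 0:
            raise ValueError("well_depth is a depth: must be >= 0")
        if self.well_width <= 0:
            raise ValueError("well_width must be positive")

    def evaluate(self, r) -> np.ndarray:
        """ΔG(r); analytic continuation outside r_range except hard walls."""
        r = np.asarray(r, dtype=float)
        if self.form == "flat":
            g = np.zeros_like(r)
        else:
            g = -self.well_depth * np.exp(
                -((r - self.well_center) ** 2) / (2.0 * self.well_width ** 2))
        if self.form == "hard_wall_plus_well":
            g = np.where(r < self.r_range[0], np.inf, g)
        return g


@dataclass
class UmbrellaProtocol:
    """Harmonic-bias window ladder; defaults follow the 51-window protocol
    (centers 3.0–8.0 nm in 0.1 nm steps, k = 1000 kJ/mol/nm², 300 K)."""

    window_centers: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(3.0, 8.0 + 1e-9, 0.1), 10))
    spring_constant: float = 1000.0    # kJ/mol/nm²
    samples_per_window: int = 5000
    temperature: float = T_DEFAULT
    seed: int = 0

    def __post_init__(self):
        self.window_centers = np.asarray(self.window_centers, dtype=float)
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")
        if self.spring_constant <= 0:
            raise ValueError("spring constant must be positive")
        if self.samples_per_window < 1:
            raise ValueError("samples_per_window must be at least 1")


def gen_umbrella_windows(pmf: AnalyticPMFSpec, protocol: UmbrellaProtocol,
                         burn_in: int = 1000, thinning: int = 10,
                         acceptance_floor: float = 0.05) -> UmbrellaWindowSet:
    """Metropolis-sample each window from exp(−[ΔG(x)+k/2(x−xᵢ)²]/RT).

    All windows are advanced in parallel (one chain per window) with a
    Gaussian proposal of width sqrt(RT/k); 1000 burn-in steps and 10× thinning
    decorrelate the samples. Fails if any window's acceptance rate drops
    below the floor (pathological spec).
    """
    centers = protocol.window_centers
    lo, hi = pmf.r_range
    if centers.min() < lo or centers.max() > hi:
        raise ValueError("window centers must lie inside the PMF r_range")
    rt = kt_kj_mol(protocol.temperature)
    k = protocol.spring_constant
    nw = len(centers)
    rng = np.random.default_rng(protocol.seed)
    step = np.sqrt(rt / k)

    def energy(x):
        return pmf.evaluate(x) + 0.5 * k * (x - centers) ** 2

    x = centers.copy()
    u = energy(x)
    n_keep = protocol.samples_per_window
    samples = np.empty((nw, n_keep))
    accepted = np.zeros(nw, dtype=np.int64)
    total_steps = burn_in + thinning * n_keep
    kept = 0
    chunk = 4096
    done = 0
    while done < total_steps:
        m = min(chunk, total_steps - done)
        prop = rng.standard_normal((m, nw)) * step
        unif = rng.uniform(size=(m, nw))
        for s in range(m):
            x_new = x + prop[s]
            u_new = energy(x_new)
            with np.errstate(over="ignore"):
                acc = unif[s] < np.exp(np.clip((u - u_new) / rt, None, 0.0))
            x = np.where(acc, x_new, x)
            u = np.where(acc, u_new, u)
            accepted += acc
            step_idx = done + s
            if step_idx >= burn_in and (step_idx - burn_in) % thinning == thinning - 1:
                samples[:, kept] = x
                kept += 1
        done += m
    rate = accepted / total_steps
    if np.any(rate < acceptance_floor):
        worst = int(np.argmin(rate))
        raise RuntimeError(
            f"Metropolis acceptance rate {rate[worst]:.3f} in window "
            f"{worst} (center {centers[worst]:g} nm) fell below the floor "
            f"{acceptance_floor}; the PMF/protocol combination is pathological")
    return UmbrellaWindowSet(centers=centers, spring_constants=k,
                             samples=list(samples),
                             temperature=protocol.temperature)


# ---------------------------------------------------------------------------
# scattering


def gen_sans_curve(rg: float, i0: float = 1.0, noise_sd: float = 0.0,
                   n_points: int = 100, seed: int = 0,
                   q_min: float | None = None,
                   q_max: float | None = None) -> ScatteringCurve:
    """Guinier-regime curve I(q) = I0·exp(−q²Rg²/3)·(1+ε), ε ~ N(0, noise_sd).

    The q grid spans below and above the Guinier limit 1.3/Rg (default
    0.1/Rg to 3/Rg). Multiplicative noise mirrors count statistics; noise
    draws leaving a negative intensity are redrawn (documented choice).
    """
    if rg <= 0 or i0 <= 0:
        raise ValueError("rg and i0 must be positive")
    q_min = 0.1 / rg if q_min is None else q_min
    q_max = 3.0 / rg if q_max is None else q_max
    if not q_min < 1.3 / rg < q_max:
        raise ValueError("q grid must span below and above the Guinier limit")
    q = np.linspace(q_min, q_max, n_points)
    ideal = i0 * np.exp(-(q ** 2) * rg ** 2 / 3.0)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd, size=n_points)
        bad = eps <= -1.0
        while np.any(bad):
            eps[bad] = rng.normal(0.0, noise_sd, size=int(bad.sum()))
            bad = eps <= -1.0
        intensity = ideal * (1.0 + eps)
        sigma = ideal * noise_sd
    else:
        intensity, sigma = ideal, None
    return ScatteringCurve(q=q, intensity=intensity, sigma=sigma,
                           metadata={"true_rg_nm": rg, "i0": i0,
                                     "noise_sd": noise_sd, "seed": seed})


def gen_sls_series(mw: float, b22: float, conc_grid_mg_ml=None,
                   noise_sd: float = 0.0, seed: int = 0) -> SLSSeries:
    """Debye-plot series KC/Rθ = 1/Mw + 2·B22·C with additive Gaussian noise.

    Concentrations in mg/mL (≥3 required); B22 in mol·mL/g². noise_sd is the
    additive noise standard deviation as a fraction of the intercept 1/Mw
    (instrument-noise character, hence additive).
    """
    if mw <= 0:
        raise ValueError("mw must be positive")
    if conc_grid_mg_ml is None:
        conc_grid_mg_ml = np.linspace(2.0, 12.0, 6)
    conc = np.asarray(conc_grid_mg_ml, dtype=float)
    if len(conc) < 3 or np.any(conc <= 0):
        raise ValueError("need >= 3 positive concentrations")
    c_g_ml = conc / 1000.0
    y = 1.0 / mw + 2.0 * b22 * c_g_ml
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd / mw, size=len(conc))
    return SLSSeries(conc_mg_ml=conc, kc_over_r=y,
                     metadata={"true_mw_g_mol": mw, "true_b22_mol_mL_g2": b22,
                               "noise_sd": noise_sd, "seed": seed})
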