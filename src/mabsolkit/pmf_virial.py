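"""Potentials of mean force from umbrella sampling (WHAM) and second osmotic
virial coefficients B22 from PMFs.

The WHAM estimator combines the biased histograms of harmonic umbrella
windows into a single unbiased probability profile by self-consistent
iteration of the window free energies; the PMF is −RT ln p(r), referenced to
zero at the largest sampled distance where the profile plateaus. B22 follows
from the McMillan–Mayer integral over g(r) = exp(−ΔG(r)/RT) under a spherical
approximation, with declared core (r below the sampled range) and tail
(r above it) conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import N_A, T_DEFAULT, kt_kj_mol

#: nm^3 -> cm^3 (mL)
_NM3_TO_ML = 1e-21


@dataclass
class ThermoConstants:
    """Temperature and the gas constant used in Boltzmann factors."""

    temperature: float = T_DEFAULT  # K

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        """RT in kJ/mol."""
        return kt_kj_mol(self.temperature)


@dataclass
class UmbrellaWindowSet:
    """Harmonic umbrella windows along a 1-D reaction coordinate (nm).

    centers: window restraint centers, strictly increasing;
    spring_constants: per-window k in kJ/mol/nm² (scalar broadcasts);
    samples: list of 1-D arrays (nm), one per window;
    temperature: K.
    """

    centers: np.ndarray
    spring_constants: np.ndarray
    samples: list
    temperature: float = T_DEFAULT

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("window centers must be strictly increasing")
        k = np.asarray(self.spring_constants, dtype=float)
        if k.ndim == 0:
            k = np.full(len(self.centers), float(k))
        if len(k) != len(self.centers):
            raise ValueError("one spring constant per window required")
        # k = 0 (unbiased window) is allowed: WHAM then reduces to Boltzmann
        # inversion of the pooled histogram
        if np.any(k < 0):
            raise ValueError("spring constants must be non-negative")
        self.spring_constants = k
        if len(self.samples) != len(self.centers):
            raise ValueError("one sample array per window required")
        self.samples = [np.asarray(s, dtype=float).ravel() for s in self.samples]
        if any(len(s) == 0 for s in self.samples):
            raise ValueError("every window needs at least one sample")
        if any(len(s) < 100 for s in self.samples):
            warnings.warn("some windows hold fewer than 100 samples; "
                          "the PMF uncertainty may be unreliable")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.centers)


@dataclass
class PMFProfile:
    """Free-energy profile ΔG(r) on a regular grid with the reference bin at 0."""

    r: np.ndarray                      # nm, bin centers
    delta_g: np.ndarray                # kJ/mol
    uncertainty: np.ndarray | None     # kJ/mol per bin (bootstrap sd)
    temperature: float
    reference: str = "max_r"
    n_iterations: int = 0

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.delta_g = np.asarray(self.delta_g, dtype=float)
        if np.any(~np.isfinite(self.delta_g)):
            raise ValueError("PMF must be finite on the sampled support")


@dataclass
class VirialResult:
    """Second osmotic virial coefficient from a PMF (mol·mL/g²)."""

    b22: float
    mw: float
    r_min: float
    r_max: float
    core_rule: str
    tail_rule: str
    core_contribution: float       # contribution to B22 from r < r_min
    quadrature_error: float        # |trapezoid − Simpson| estimate on B22
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# WHAM


def _window_counts(windows: UmbrellaWindowSet, edges: np.ndarray,
                   weights: list | None = None) -> np.ndarray:
    counts = np.empty((windows.n_windows, len(edges) - 1))
    for i, s in enumerate(windows.samples):
        w = None if weights is None else weights[i]
        counts[i], _ = np.histogram(s, bins=edges, weights=w)
    return counts


def _check_overlap(windows: UmbrellaWindowSet, counts: np.ndarray) -> None:
    occupied = counts > 0
    for i in range(windows.n_windows - 1):
        if not np.any(occupied[i] & occupied[i + 1]):
            raise ValueError(
                "non-overlapping umbrella windows: no shared occupied bin "
                f"between centers {windows.centers[i]:g} and "
                f"{windows.centers[i + 1]:g} nm")


def _wham_solve(counts, log_n_i, neg_u_over_rt, rt, tol, max_iter,
                log_f0=None):
    """Self-consistent WHAM iteration in log space.

    counts: (n_windows, n_bins) histogram (may be weighted);
    log_n_i: log of per-window total counts;
    neg_u_over_rt: (n_windows, n_bins) −U_i(x_j)/RT bias matrix.
    Returns (log_p normalized up to a constant, log_f, n_iter).
    """
    n_j = counts.sum(axis=0)
    occ = n_j > 0
    log_nj = np.where(occ, np.log(np.where(occ, n_j, 1.0)), -np.inf)
    log_f = np.zeros(counts.shape[0]) if log_f0 is None else log_f0.copy()
    for it in range(1, max_iter + 1):
        # log denominator_j = logsumexp_i [ log N_i + log f_i − U_ij/RT ]
        log_den = logsumexp(log_n_i[:, None] + log_f[:, None] + neg_u_over_rt,
                            axis=0)
        log_p = log_nj - log_den
        with np.errstate(invalid="ignore"):
            new_log_f = -logsumexp(neg_u_over_rt[:, occ] + log_p[None, occ],
                                   axis=1)
        delta = rt * np.max(np.abs(new_log_f - log_f))
        log_f = new_log_f
        if delta < tol:
            return log_p, log_f, it
    raise RuntimeError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(final free-energy residual {delta:.3e} kJ/mol)")


def wham(windows: UmbrellaWindowSet, n_bins: int = 200, tol: float = 1e-8,
         max_iter: int = 100_000, n_boot: int = 0, seed: int | None = None,
         reference_r: float | None = None) -> PMFProfile:
    """Reconstruct ΔG(r) from umbrella windows by self-consistent WHAM.

    The grid spans the sampled range with ``n_bins`` regular bins.
    Convergence is max |Δ(RT ln f_i)| < tol (kJ/mol). The zero of ΔG is set
    at the bin nearest ``reference_r`` — by default the largest window
    center, where the profile plateaus and the bin is well occupied (the
    extreme-tail bin beyond the last restraint carries O(RT) noise and would
    offset the whole profile). Bins beyond the reference are trimmed, so the
    reported profile ends at ΔG = 0 exactly. ``n_boot`` > 0 adds a per-bin
    Bayesian-bootstrap standard deviation (Dirichlet sample weights,
    warm-started from the converged solution).
    """
    rt = kt_kj_mol(windows.temperature)
    lo = min(s.min() for s in windows.samples)
    hi = max(s.max() for s in windows.samples)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers_grid = 0.5 * (edges[:-1] + edges[1:])
    counts = _window_counts(windows, edges)
    _check_overlap(windows, counts)

    log_n_i = np.log(np.array([len(s) for s in windows.samples], dtype=float))
    bias = 0.5 * windows.spring_constants[:, None] * (
        centers_grid[None, :] - windows.centers[:, None]) ** 2
    neg_u = -bias / rt

    log_p, log_f, n_iter = _wham_solve(counts, log_n_i, neg_u, rt, tol, max_iter)

    if reference_r is None:
        reference_r = min(float(windows.centers[-1]), float(hi))
    occ = counts.sum(axis=0) > 0
    j_ref = int(np.argmin(np.abs(centers_grid - reference_r)))
    if not occ[j_ref]:
        raise ValueError(f"reference bin at r = {reference_r:g} nm holds no "
                         "samples; choose a sampled reference")
    first = int(np.argmax(occ))
    keep = np.arange(first, j_ref + 1)
    if not np.all(occ[keep]):
        warnings.warn("interior bins with zero counts; reduce n_bins or add "
                      "samples — empty bins are dropped from the profile")
        keep = keep[occ[keep]]
    r = centers_grid[keep]
    g = -rt * log_p[keep]
    g = g - g[-1]  # reference bin is the last kept bin

    sigma = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, len(r)))
        for b in range(n_boot):
            weights = [rng.dirichlet(np.ones(len(s))) * len(s)
                       for s in windows.samples]
            counts_b = _window_counts(windows, edges, weights)
            log_p_b, _, _ = _wham_solve(counts_b, log_n_i, neg_u, rt,
                                        tol, max_iter, log_f0=log_f)
            g_b = -rt * log_p_b[keep]
            reps[b] = g_b - g_b[-1]
        reps[~np.isfinite(reps)] = np.nan
        sigma = np.nanstd(reps, axis=0, ddof=1)

    return PMFProfile(r=r, delta_g=g, uncertainty=sigma,
                      temperature=windows.temperature, n_iterations=n_iter)


# ---------------------------------------------------------------------------
# B22 from a PMF


def pmf_to_b22(pmf: PMFProfile, mw: float,
               constants: ThermoConstants | None = None,
               core_rule: str = "hard_core",
               tail_rule: str = "unity") -> VirialResult:
    """McMillan–Mayer B22 = −(2πN_A/Mw²)∫(g(r)−1)r²dr with g = exp(−ΔG/RT).

    The grid integral uses the trapezoid rule (Simpson difference reported as
    a quadrature-error estimate). core_rule 'hard_core' treats r < r_min as
    overlapping proteins (g = 0, contributing −r_min³/3 to the integral);
    'none' ignores the core. tail_rule 'unity' takes g = 1 beyond r_max (zero
    contribution) and requires the PMF to be zero-referenced there.
    Result in mol·mL/g² for Mw in g/mol and r in nm.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if np.any(np.diff(pmf.r) <= 0):
        raise ValueError("PMF grid must be strictly increasing")
    constants = constants or ThermoConstants(pmf.temperature)
    rt = constants.rt
    if tail_rule == "unity" and abs(pmf.delta_g[-1]) > 1e-6:
        raise ValueError(
            "tail rule g=1 requires ΔG(r_max)=0; re-reference the PMF "
            f"(found ΔG(r_max) = {pmf.delta_g[-1]:.3g} kJ/mol)")
    if tail_rule not in ("unity",):
        raise ValueError(f"unknown tail_rule {tail_rule!r}")
    if core_rule not in ("hard_core", "none"):
        raise ValueError(f"unknown core_rule {core_rule!r}")

    g_r = np.exp(-pmf.delta_g / rt)
    integrand = (g_r - 1.0) * pmf.r ** 2          # nm^2
    from scipy.integrate import simpson
    integral = np.trapezoid(integrand, pmf.r)     # nm^3
    integral_simpson = simpson(integrand, x=pmf.r)

    prefactor = -2.0 * np.pi * N_A / mw ** 2 * _NM3_TO_ML
    core_integral = -pmf.r[0] ** 3 / 3.0 if core_rule == "hard_core" else 0.0
    b22 = prefactor * (integral + core_integral)
    core_contribution = prefactor * core_integral
    quad_err = abs(prefactor * (integral - integral_simpson))

    return VirialResult(
        b22=float(b22), mw=float(mw), r_min=float(pmf.r[0]),
        r_max=float(pmf.r[-1]), core_rule=core_rule, tail_rule=tail_rule,
        core_contribution=float(core_contribution),
        quadrature_error=float(quad_err),
        metadata={"temperature": constants.temperature})


def write_umbrella_windows(windows: UmbrellaWindowSet, out_dir,
                           dt_ps: float = 1.0) -> str:
    """Write per-window pullx-dialect XVG files plus a JSON manifest.

    Returns the manifest path. Each window file holds (time ps, distance nm);
    the manifest records centers, spring constants and temperature.
    """
    from pathlib import Path
    from .trajectory_io import TableSeries, write_xvg
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, s in enumerate(windows.samples):
        name = f"window_{i:03d}.xvg"
        t = dt_ps * np.arange(len(s))
        write_xvg(TableSeries(["Time (ps)", "Position (nm)"],
                              np.column_stack([t, s])),
                  out / name, title=f"umbrella window {i}")
        files.append(name)
    manifest = {
        "centers_nm": windows.centers.tolist(),
        "spring_constants_kJ_mol_nm2": windows.spring_constants.tolist(),
        "temperature_K": windows.temperature,
        "files": files,
    }
    path = out / "windows.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return str(path)


def read_umbrella_windows(manifest_path) -> UmbrellaWindowSet:
    """Read an umbrella window set from a JSON manifest + XVG sample files."""
    from pathlib import Path
    from .trajectory_io import read_xvg
    path = Path(manifest_path)
    with open(path) as fh:
        manifest = json.load(fh)
    samples = []
    for name in manifest["files"]:
        table = read_xvg(path.parent / name)
        samples.append(table.data[:, 1])
    return UmbrellaWindowSet(
        centers=np.asarray(manifest["centers_nm"]),
        spring_constants=np.asarray(manifest["spring_constants_kJ_mol_nm2"]),
        samples=samples,
        temperature=float(manifest.get("temperature_K", T_DEFAULT)))


def b22_report(windows: UmbrellaWindowSet, mw: float, n_bins: int = 200,
               tol: float = 1e-8, max_iter: int = 100_000, n_boot: int = 50,
               seed: int | None = None, core_rule: str = "hard_core",
               tail_rule: str = "unity",
               sidecar_path=None) -> tuple[VirialResult, PMFProfile]:
    """End-to-end umbrella windows → WHAM → B22 with provenance metadata."""
    pmf = wham(windows, n_bins=n_bins, tol=tol, max_iter=max_iter,
               n_boot=n_boot, seed=seed)
    result = pmf_to_b22(pmf, mw, ThermoConstants(windows.temperature),
                        core_rule=core_rule, tail_rule=tail_rule)
    result.metadata.update({
        "n_windows": windows.n_windows,
        "window_centers_nm": windows.centers.tolist(),
        "spring_constants_kJ_mol_nm2": windows.spring_constants.tolist(),
        "samples_per_window": [len(s) for s in windows.samples],
        "wham": {"n_bins": n_bins, "tol": tol, "n_boot": n_boot, "seed": seed,
                 "iterations": pmf.n_iterations},
    })
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"b22_mol_mL_g2": result.b22, "mw_g_mol": result.mw,
                       "core_rule": result.core_rule,
                       "tail_rule": result.tail_rule,
                       "core_contribution": result.core_contribution,
                       "metadata": result.metadata}, fh, indent=2)
    return result, pmf
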