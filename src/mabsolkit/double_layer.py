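"""Electric double layer around a charged protein: the net-charge profile
Qnet(r) = Q_protein + n₊(r) − n₋(r), its exponential-decay (screening length)
fit, and the Poisson–Boltzmann Debye length for a monovalent 1:1 electrolyte.

Note on the PB closed form: the screening length is implemented in the
standard form ζ² = ε_r ε₀ k_B T / (2 e² N_A · 10³C), which for ε_r = 78,
C = 0.15 mol/L and T = 300 K gives ζ = 0.79 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import constants
from .solvation_shell import RadialProfile, cumulative_profile


@dataclass
class ChargeProfile:
    """Net charge (e) within distance r of the protein surface."""

    r: np.ndarray               # nm; cumulative charge through each bin
    qnet: np.ndarray            # e
    q_protein: float            # e
    n_cation: np.ndarray
    n_anion: np.ndarray


@dataclass
class ExponentialFit:
    """A0·exp(−r/ζ) fit of a net-charge profile over a window."""

    a0: float
    zeta: float                 # nm
    fit_window: tuple
    rms_residual: float
    covariance: np.ndarray      # 2x2 for (A0, ζ)

    def __post_init__(self):
        if self.zeta <= 0:
            raise ValueError("fitted screening length must be positive")


@dataclass
class ElectrolyteSpec:
    """Monovalent 1:1 electrolyte for the PB Debye length."""

    eps_r: float = 78.0
    temperature: float = constants.T_DEFAULT   # K
    concentration: float = 0.15                # mol/L

    def __post_init__(self):
        if min(self.eps_r, self.temperature, self.concentration) <= 0:
            raise ValueError("eps_r, temperature and concentration must be positive")


def net_charge_profile(cation_profile: RadialProfile,
                       anion_profile: RadialProfile,
                       q_protein: float) -> ChargeProfile:
    """Qnet(r) from cation/anion surface RDFs (monovalent ions assumed).

    n±(r) is the exact cumulative integral of each unnormalized profile;
    Qnet is reported at the right edge of each bin (the grid r).
    """
    if cation_profile.bin_width != anion_profile.bin_width or \
            len(cation_profile.r) != len(anion_profile.r) or \
            not np.allclose(cation_profile.r, anion_profile.r):
        raise ValueError("cation and anion profiles must share grid and bin width")
    n_plus = cumulative_profile(cation_profile)
    n_minus = cumulative_profile(anion_profile)
    r_edges = cation_profile.bin_edges[1:]
    return ChargeProfile(r=r_edges, qnet=q_protein + n_plus - n_minus,
                         q_protein=float(q_protein),
                         n_cation=n_plus, n_anion=n_minus)


def debye_fit(profile: ChargeProfile, window: tuple = (0.25, 1.0),
              mode: str = "nonlinear") -> ExponentialFit:
    """Fit Qnet(r) ≈ A0·exp(−r/ζ) on the window (default 0.25–1.0 nm).

    The default is nonlinear least squares in linear space, which tolerates
    Qnet crossing zero (low-charge proteins); mode='log' performs log-linear
    regression and requires strictly positive data in the window.
    """
    lo, hi = window
    mask = (profile.r >= lo) & (profile.r <= hi)
    if mask.sum() < 6:
        raise ValueError("need at least 6 grid points inside the fit window")
    r, q = profile.r[mask], profile.qnet[mask]
    if mode == "log":
        if np.any(q <= 0):
            raise ValueError("non-positive Qnet in window: log-linear mode "
                             "impossible, use the nonlinear mode")
        slope, intercept = np.polyfit(r, np.log(q), 1)
        if slope >= 0:
            raise ValueError("Qnet does not decay over the window")
        a0, zeta = float(np.exp(intercept)), float(-1.0 / slope)
        resid = q - a0 * np.exp(-r / zeta)
        cov = np.full((2, 2), np.nan)
    elif mode == "nonlinear":
        # initial guess from a log-linear fit where the data allow it
        if np.all(q > 0):
            s, b = np.polyfit(r, np.log(q), 1)
            p0 = (float(np.exp(b)), float(-1.0 / s) if s < 0 else 0.5)
        else:
            p0 = (max(profile.q_protein, 1.0), 0.5)
        popt, cov = curve_fit(lambda x, a, z: a * np.exp(-x / z), r, q,
                              p0=p0, maxfev=20000)
        a0, zeta = float(popt[0]), float(popt[1])
        resid = q - a0 * np.exp(-r / zeta)
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    return ExponentialFit(a0=a0, zeta=zeta, fit_window=(float(lo), float(hi)),
                          rms_residual=float(np.sqrt(np.mean(resid ** 2))),
                          covariance=np.asarray(cov, dtype=float))


def pb_debye_length(spec: ElectrolyteSpec | None = None, *,
                    eps_r: float | None = None,
                    temperature: float | None = None,
                    concentration: float | None = None) -> float:
    """Poisson–Boltzmann Debye length in nm for a monovalent 1:1 electrolyte.

    ζ = sqrt(ε_r ε₀ k_B T / (2 e² N_A C·10³)) with C in mol/L (converted to
    mol/m³ by the 10³ factor); constants pinned in :mod:`mabsolkit.constants`.
    """
    if spec is None:
        spec = ElectrolyteSpec(
            eps_r=78.0 if eps_r is None else eps_r,
            temperature=constants.T_DEFAULT if temperature is None else temperature,
            concentration=0.15 if concentration is None else concentration)
    eps = spec.eps_r * constants.EPS_0
    num = eps * constants.K_B * spec.temperature
    den = 2.0 * constants.E_CHARGE ** 2 * constants.N_A * spec.concentration * 1e3
    return float(np.sqrt(num / den) * 1e9)  # m -> nm
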