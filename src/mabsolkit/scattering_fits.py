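"""Experiment-side estimators: Guinier analysis of small-angle scattering
curves for the radius of gyration, and Debye-plot regression of static light
scattering series for the molecular weight and second virial coefficient.

In the Guinier regime the scattering intensity follows
I(q) = I(0) exp(−q²Rg²/3), so ln I is linear in q² with slope −Rg²/3; the fit
range is restricted self-consistently to q·Rg ≤ criterion (default 1.3).
For SLS, KC/Rθ is linear in concentration with intercept 1/Mw and slope 2·B22.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ScatteringCurve:
    """A (q, I(q)) curve; q in 1/nm, intensity in arbitrary units."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if len(self.intensity) != len(self.q):
            raise ValueError("q and I(q) length mismatch")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.q):
                raise ValueError("sigma length mismatch")


@dataclass
class GuinierResult:
    rg: float                 # nm
    i0: float
    q_range: tuple            # (q_min, q_max) of points used, 1/nm
    slope: float              # of ln I vs q², equals −Rg²/3
    r_squared: float
    n_points: int


@dataclass
class SLSSeries:
    """SLS concentration series: C in mg/mL, KC/Rθ in mol/g."""

    conc_mg_ml: np.ndarray
    kc_over_r: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.conc_mg_ml = np.asarray(self.conc_mg_ml, dtype=float)
        self.kc_over_r = np.asarray(self.kc_over_r, dtype=float)
        if len(self.conc_mg_ml) < 3:
            raise ValueError("at least 3 concentrations required")
        if np.any(self.conc_mg_ml <= 0):
            raise ValueError("concentrations must be positive")
        if len(self.kc_over_r) != len(self.conc_mg_ml):
            raise ValueError("length mismatch between C and KC/Rθ")

    @property
    def conc_g_ml(self) -> np.ndarray:
        return self.conc_mg_ml / 1000.0


@dataclass
class DebyePlotResult:
    b22: float                # mol·mL/g²
    mw_apparent: float        # g/mol
    slope: float              # raw regression slope = 2·B22, mol·mL/g²
    slope_stderr: float
    intercept_stderr: float


def q_from_angle(wavelength: float, theta: float) -> float:
    """Momentum transfer q = (4π/λ)·sin θ for wavelength λ (nm), θ (rad)."""
    if not 0 < theta < np.pi / 2:
        raise ValueError("theta must lie in (0, π/2)")
    return 4.0 * np.pi / wavelength * np.sin(theta)


def guinier_fit(curve: ScatteringCurve, criterion: float = 1.3,
                max_iter: int = 20) -> GuinierResult:
    """Self-consistent Guinier fit of ln I(q) vs q².

    Starts from the lowest decile of q, fits the line, recomputes the Guinier
    limit q_max = criterion/Rg from the fitted Rg, and refits until the point
    set is stable. Weighted by 1/σ_lnI² when intensity errors are given.
    """
    q, i_q = curve.q, curve.intensity
    if np.any(i_q <= 0):
        raise ValueError("intensities must be positive in the fitted range")
    ln_i = np.log(i_q)
    q2 = q ** 2
    # σ(ln I) = σ_I / I
    w = None if curve.sigma is None else (i_q / curve.sigma) ** 2

    mask = q <= np.quantile(q, 0.10)
    if mask.sum() < 5:
        mask = np.zeros_like(q, dtype=bool)
        mask[:5] = True
    seen = []
    for _ in range(max_iter):
        slope, intercept = _wls_line(q2[mask], ln_i[mask],
                                     None if w is None else w[mask])
        if slope >= 0:
            raise ValueError("no Guinier regime: ln I does not decay with q²")
        rg = float(np.sqrt(-3.0 * slope))
        q_max = criterion / rg
        new_mask = q <= q_max
        if new_mask.sum() < 5:
            raise ValueError(
                "fewer than 5 points below the self-consistent Guinier limit")
        if np.array_equal(new_mask, mask):
            break
        if new_mask.tobytes() in seen:
            if np.sum(mask ^ new_mask) <= 1:
                # boundary point dithering in and out of the discrete limit:
                # converge on the smaller (intersection) set
                mask = mask & new_mask
                slope, intercept = _wls_line(
                    q2[mask], ln_i[mask], None if w is None else w[mask])
                rg = float(np.sqrt(-3.0 * slope))
                # enforce self-consistency q_max·Rg <= criterion
                while q[mask].max() * rg > criterion + 1e-9 and mask.sum() > 5:
                    mask[np.max(np.where(mask)[0])] = False
                    slope, intercept = _wls_line(
                        q2[mask], ln_i[mask], None if w is None else w[mask])
                    rg = float(np.sqrt(-3.0 * slope))
                break
            raise ValueError(
                "Guinier point set oscillates between "
                f"{int(mask.sum())} and {int(new_mask.sum())} points; "
                "inspect the curve or fix the range manually")
        seen.append(mask.tobytes())
        mask = new_mask
    else:
        raise ValueError("Guinier point set did not stabilize")

    resid = ln_i[mask] - (slope * q2[mask] + intercept)
    ss_tot = np.sum((ln_i[mask] - ln_i[mask].mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else 1.0
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                         q_range=(float(q[mask].min()), float(q[mask].max())),
                         slope=float(slope), r_squared=r2,
                         n_points=int(mask.sum()))


def _wls_line(x, y, w=None):
    """Weighted least-squares line; returns (slope, intercept)."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    mx, my = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx == 0:
        raise ValueError("rank-deficient fit: no spread in x")
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    return float(slope), float(my - slope * mx)


def sls_debye_fit(series: SLSSeries) -> DebyePlotResult:
    """OLS of KC/Rθ on C (g/mL): B22 = slope/2, Mw = 1/intercept."""
    c = series.conc_g_ml
    if np.ptp(c) == 0:
        raise ValueError("rank-deficient Debye plot: all concentrations equal")
    res = stats.linregress(c, series.kc_over_r)
    if res.intercept <= 0:
        raise ValueError(
            "negative or zero Debye-plot intercept: unphysical, check the "
            "instrument calibration or the KC/Rθ values")
    return DebyePlotResult(
        b22=float(res.slope / 2.0),
        mw_apparent=float(1.0 / res.intercept),
        slope=float(res.slope),
        slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        intercept_stderr=(float(res.intercept_stderr)
                          if np.isfinite(res.intercept_stderr) else 0.0))


def optical_constant(dn_dc: float = 0.185, n0: float = 1.33,
                     wavelength_nm: float = 633.0) -> float:
    """Rayleigh optical constant K = 4π²n₀²(dn/dC)²/(N_A λ⁴) in mol·cm²/g².

    dn/dC in mL/g, λ in nm (converted to cm). Only needed when raw Rayleigh
    ratios are supplied instead of KC/Rθ.
    """
    from .constants import N_A
    lam_cm = wavelength_nm * 1e-7
    return 4.0 * np.pi ** 2 * n0 ** 2 * dn_dc ** 2 / (N_A * lam_cm ** 4)
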