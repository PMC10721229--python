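import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

import mabsolkit as mk
from mabsolkit.constants import N_A, kt_kj_mol
from mabsolkit.pmf_virial import read_umbrella_windows, write_umbrella_windows


def reference_wham_optimizer(windows, n_bins, rt):
    """Independent WHAM estimator: direct numerical maximization of the
    binned WHAM log-likelihood with L-BFGS (no fixed-point iteration).

    L(p) = Σ_j n_j log p_j − Σ_i N_i log Σ_j c_ij p_j, parameterized in
    log p_j. Returns (bin centers, −RT log p) unreferenced.
    """
    lo = min(s.min() for s in windows.samples)
    hi = max(s.max() for s in windows.samples)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.array([np.histogram(s, bins=edges)[0]
                       for s in windows.samples])
    n_j = counts.sum(axis=0)
    n_i = counts.sum(axis=1)
    log_c = -0.5 * windows.spring_constants[:, None] * (
        centers[None, :] - windows.centers[:, None]) ** 2 / rt
    occ = n_j > 0

    def neg_ll(theta):
        log_p = np.full(n_bins, -np.inf)
        log_p[occ] = theta - logsumexp(theta)
        ll = np.sum(n_j[occ] * log_p[occ])
        ll -= np.sum(n_i * logsumexp(log_c[:, occ] + log_p[None, occ], axis=1))
        return -ll

    theta0 = np.log(n_j[occ] / n_j[occ].sum())
    res = minimize(neg_ll, theta0, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    log_p = np.full(n_bins, -np.inf)
    log_p[occ] = res.x - logsumexp(res.x)
    return centers, -rt * log_p


@pytest.fixture(scope="module")
def small_gaussian_windows():
    pmf = mk.AnalyticPMFSpec(form="gaussian_well", well_depth=8.0,
                             well_center=4.0, well_width=0.3,
                             r_range=(3.0, 6.0))
    proto = mk.UmbrellaProtocol(window_centers=np.linspace(3.0, 6.0, 31),
                                samples_per_window=4000, seed=3)
    return pmf, mk.gen_umbrella_windows(pmf, proto)


class TestWham:
    def test_single_unbiased_window_reduces_to_boltzmann_inversion(self, rng):
        """With one window and zero spring constant, WHAM must return
        −RT ln(histogram) up to the reference shift."""
        rt = kt_kj_mol(300.0)
        samples = rng.normal(5.0, 0.3, size=20000)
        ws = mk.UmbrellaWindowSet(centers=[5.0], spring_constants=0.0,
                                  samples=[samples], temperature=300.0)
        prof = mk.wham(ws, n_bins=60, reference_r=samples.max())
        counts, edges = np.histogram(samples, bins=np.linspace(
            samples.min(), samples.max(), 61))
        with np.errstate(divide="ignore"):
            direct = -rt * np.log(counts.astype(float))
        keep = counts > 0
        direct = direct - direct[keep][-1]
        np.testing.assert_allclose(prof.delta_g, direct[keep][:len(prof.delta_g)],
                                   atol=1e-6)

    def test_flat_pmf_reconstructed_flat(self):
        pmf = mk.AnalyticPMFSpec(form="flat")
        proto = mk.UmbrellaProtocol(samples_per_window=2000, seed=4)
        ws = mk.gen_umbrella_windows(pmf, proto)
        prof = mk.wham(ws, n_bins=150, n_boot=20, seed=0)
        inner = (prof.r > 3.2) & (prof.r < 7.8)
        band = np.maximum(3 * prof.uncertainty[inner], 0.35)
        assert np.all(np.abs(prof.delta_g[inner]) < band)

    def test_gaussian_well_depth_recovered(self, small_gaussian_windows):
        pmf, ws = small_gaussian_windows
        prof = mk.wham(ws, n_bins=150)
        assert prof.delta_g.min() == pytest.approx(-8.0, abs=1.0)

    def test_matches_independent_likelihood_optimizer(self,
                                                      small_gaussian_windows):
        """Dual-route check: the fixed-point WHAM solution agrees with a
        direct numerical maximization of the same likelihood."""
        _, ws = small_gaussian_windows
        rt = kt_kj_mol(ws.temperature)
        n_bins = 80
        prof = mk.wham(ws, n_bins=n_bins,
                       reference_r=max(s.max() for s in ws.samples))
        centers, g_ref = reference_wham_optimizer(ws, n_bins, rt)
        finite = np.isfinite(g_ref)
        g_ref = g_ref - g_ref[finite][-1]
        ours = np.full(n_bins, np.nan)
        for j, c in enumerate(centers):
            k = np.argmin(np.abs(prof.r - c))
            if abs(prof.r[k] - c) < 1e-9:
                ours[j] = prof.delta_g[k]
        both = finite & np.isfinite(ours)
        assert np.max(np.abs(ours[both] - g_ref[both])) < 0.05

    def test_bias_constant_invariance(self, small_gaussian_windows):
        """Adding a constant to every window's bias leaves WHAM unchanged
        (the constant is absorbed into the window free energies), which is
        equivalent to shifting all centers and samples together."""
        _, ws = small_gaussian_windows
        prof = mk.wham(ws, n_bins=100)
        shifted = mk.UmbrellaWindowSet(
            centers=ws.centers + 2.0,
            spring_constants=ws.spring_constants,
            samples=[s + 2.0 for s in ws.samples],
            temperature=ws.temperature)
        prof2 = mk.wham(shifted, n_bins=100)
        np.testing.assert_allclose(prof2.r, prof.r + 2.0, atol=1e-9)
        np.testing.assert_allclose(prof2.delta_g, prof.delta_g, atol=1e-9)

    def test_non_overlapping_windows_error_names_gap(self, rng):
        ws = mk.UmbrellaWindowSet(
            centers=[3.0, 6.0], spring_constants=5000.0,
            samples=[rng.normal(3.0, 0.02, 500), rng.normal(6.0, 0.02, 500)],
            temperature=300.0)
        with pytest.raises(ValueError, match="3 .*6|non-overlapping"):
            mk.wham(ws, n_bins=100)

    def test_half_vs_full_sample_convergence(self, small_gaussian_windows):
        """Convergence diagnostic: the PMF from the first half of the samples
        deviates from the full-sample PMF by no more than a few bootstrap
        error bars over the well."""
        _, ws = small_gaussian_windows
        half = mk.UmbrellaWindowSet(
            centers=ws.centers, spring_constants=ws.spring_constants,
            samples=[s[:len(s) // 2] for s in ws.samples],
            temperature=ws.temperature)
        full_prof = mk.wham(ws, n_bins=100, n_boot=25, seed=1)
        half_prof = mk.wham(half, n_bins=100)
        inner = (full_prof.r > 3.3) & (full_prof.r < 5.7)
        interp = np.interp(full_prof.r[inner], half_prof.r, half_prof.delta_g)
        band = np.maximum(4 * full_prof.uncertainty[inner], 0.3)
        assert np.all(np.abs(interp - full_prof.delta_g[inner]) < band)


class TestPmfToB22:
    def test_zero_pmf_no_core_gives_zero(self):
        r = np.linspace(3.0, 8.0, 200)
        prof = mk.PMFProfile(r=r, delta_g=np.zeros_like(r), uncertainty=None,
                             temperature=300.0)
        res = mk.pmf_to_b22(prof, 49635.0, core_rule="none")
        assert res.b22 == pytest.approx(0.0, abs=1e-18)

    def test_hard_sphere_closed_form(self):
        """g = 0 below σ, 1 above: B22 = 2πN_Aσ³/(3Mw²), derived by direct
        integration of −(2πN_A/Mw²)∫(g−1)r²dr with (g−1) = −1 on [0, σ]."""
        sigma, mw = 3.0, 49635.0
        r = np.linspace(sigma, 9.0, 2001)
        prof = mk.PMFProfile(r=r, delta_g=np.zeros_like(r), uncertainty=None,
                             temperature=300.0)
        res = mk.pmf_to_b22(prof, mw)
        closed = 2 * np.pi * N_A * sigma ** 3 / (3 * mw ** 2) * 1e-21
        assert res.b22 == pytest.approx(closed, rel=1e-3)

    def test_square_well_closed_form(self):
        """Square well of depth ε on [σ, σ+w]: closed form
        (2πN_A/3Mw²)[σ³ − (e^{ε/RT}−1)((σ+w)³−σ³)]."""
        sigma, w, eps, mw = 3.0, 0.5, 5.0, 49635.0
        rt = kt_kj_mol(300.0)
        r = np.linspace(sigma, 9.0, 200001)
        dg = np.where(r <= sigma + w, -eps, 0.0)
        prof = mk.PMFProfile(r=r, delta_g=dg, uncertainty=None,
                             temperature=300.0)
        res = mk.pmf_to_b22(prof, mw)
        closed = 2 * np.pi * N_A / (3 * mw ** 2) * 1e-21 * (
            sigma ** 3 - (np.exp(eps / rt) - 1) *
            ((sigma + w) ** 3 - sigma ** 3))
        assert res.b22 == pytest.approx(closed, rel=1e-3)

    def test_repulsive_pmf_gives_positive_b22(self):
        r = np.linspace(3.0, 8.0, 500)
        dg = 10.0 * np.exp(-(r - 3.0) / 0.5)
        dg -= dg[-1]
        prof = mk.PMFProfile(r=r, delta_g=dg, uncertainty=None,
                             temperature=300.0)
        assert mk.pmf_to_b22(prof, 49635.0).b22 > 0

    def test_attractive_well_gives_negative_b22_and_monotonicity(self):
        r = np.linspace(3.0, 8.0, 500)
        spec = mk.AnalyticPMFSpec(form="gaussian_well", well_depth=14.0)
        shallow = mk.PMFProfile(r=r, delta_g=spec.evaluate(r),
                                uncertainty=None, temperature=300.0)
        spec27 = mk.AnalyticPMFSpec(form="gaussian_well", well_depth=27.0)
        deep = mk.PMFProfile(r=r, delta_g=spec27.evaluate(r),
                             uncertainty=None, temperature=300.0)
        b_shallow = mk.pmf_to_b22(shallow, 49635.0, core_rule="none").b22
        b_deep = mk.pmf_to_b22(deep, 49635.0, core_rule="none").b22
        assert b_shallow < 0
        assert b_deep < b_shallow  # deepening attraction never raises B22

    def test_deep_well_b22_is_strongly_negative_on_e_minus_2_scale(self):
        r = np.linspace(3.0, 8.0, 2000)
        spec = mk.AnalyticPMFSpec(form="gaussian_well", well_depth=27.0,
                                  well_center=3.6, well_width=0.25)
        prof = mk.PMFProfile(r=r, delta_g=spec.evaluate(r), uncertainty=None,
                             temperature=300.0)
        b22 = mk.pmf_to_b22(prof, 49635.0).b22
        assert b22 < -1e-2

    def test_unreferenced_tail_rejected(self):
        r = np.linspace(3.0, 8.0, 100)
        prof = mk.PMFProfile(r=r, delta_g=np.full_like(r, -2.0),
                             uncertainty=None, temperature=300.0)
        with pytest.raises(ValueError, match="re-reference"):
            mk.pmf_to_b22(prof, 49635.0)


class TestEndToEnd:
    def test_b22_report_matches_analytic_route(self, small_gaussian_windows):
        """Scaled-down end-to-end check (4×10³ samples/window): the B22 noise
        is dominated by exp(−ΔG_min/RT), so the band here is wider than at
        the full 5×10⁴-sample run exercised in the acceptance suite."""
        pmf, ws = small_gaussian_windows
        res, prof = mk.b22_report(ws, 49635.0, n_boot=0, n_bins=150)
        r = np.linspace(prof.r[0], prof.r[-1], 2000)
        analytic = mk.PMFProfile(r=r, delta_g=pmf.evaluate(r),
                                 uncertainty=None, temperature=300.0)
        res_a = mk.pmf_to_b22(analytic, 49635.0)
        assert res.b22 == pytest.approx(res_a.b22, rel=0.25)

    def test_window_files_round_trip(self, tmp_path, small_gaussian_windows):
        _, ws = small_gaussian_windows
        manifest = write_umbrella_windows(ws, tmp_path / "win")
        back = read_umbrella_windows(manifest)
        np.testing.assert_allclose(back.centers, ws.centers)
        for a, b in zip(back.samples, ws.samples):
            np.testing.assert_allclose(a, b, rtol=1e-6)
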