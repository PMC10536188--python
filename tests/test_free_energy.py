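import numpy as np
import pytest

from bbbkit import free_energy as fe
from bbbkit import synthetic_data as synth

kT = fe.KT_310K


def _gaussian_windows(centers, k_potential, k_bias, n, seed):
    """Exact samples of harmonic-potential windows: the biased density is
    Gaussian with stiffness k_potential + k_bias around the weighted centre."""
    rng = np.random.default_rng(seed)
    ktot = k_potential + k_bias
    return [fe.UmbrellaWindow(c, k_bias,
                              rng.normal(k_bias * c / ktot,
                                         np.sqrt(kT / ktot), size=n))
            for c in centers]


def test_flat_profile_from_uniform_samples():
    """Unbiased uniform samples give a flat profile."""
    rng = np.random.default_rng(0)
    w = fe.UmbrellaWindow(0.5, 0.0, rng.uniform(0, 1, size=200_000))
    profile = fe.wham_1d([w], n_bins=40)
    assert profile.converged
    assert np.nanmax(profile.g) < 0.3   # kJ/mol; ~3x the count noise


def test_harmonic_closed_form():
    """Unbiased Gaussian samples of a harmonic well reproduce
    G = 1/2 kappa xi^2 within 0.2 kJ/mol over the well."""
    kappa = 1000.0
    rng = np.random.default_rng(1)
    sd = np.sqrt(kT / kappa)
    w = fe.UmbrellaWindow(0.0, 0.0, rng.normal(scale=sd, size=400_000))
    profile = fe.wham_1d([w], n_bins=60)
    x = profile.bin_centers
    mask = np.abs(x) <= 2 * sd
    expected = 0.5 * kappa * x ** 2
    g = profile.g - profile.g[mask].min()
    e = expected - expected[mask].min()
    assert np.max(np.abs(g[mask] - e[mask])) < 0.2


def test_window_order_invariance():
    wins = _gaussian_windows(np.linspace(-1, 1, 8), 20.0, 100.0, 4000, 3)
    g1 = fe.wham_1d(wins, n_bins=50).g
    g2 = fe.wham_1d(wins[::-1], n_bins=50).g
    assert np.nanmax(np.abs(g1 - g2)) < 1e-6


def test_nonoverlapping_windows_rejected():
    rng = np.random.default_rng(0)
    w1 = fe.UmbrellaWindow(0.0, 1000.0, rng.normal(0.0, 0.01, 2000))
    w2 = fe.UmbrellaWindow(5.0, 1000.0, rng.normal(5.0, 0.01, 2000))
    with pytest.raises(ValueError, match="overlap"):
        fe.wham_1d([w1, w2], n_bins=100)


def test_unconverged_flagged():
    wins = _gaussian_windows(np.linspace(-1, 1, 6), 20.0, 100.0, 2000, 9)
    profile = fe.wham_1d(wins, max_iter=1)
    assert not profile.converged


def test_window_validation():
    with pytest.raises(ValueError):
        fe.UmbrellaWindow(0.0, -1.0, [0.1])
    with pytest.raises(ValueError):
        fe.UmbrellaWindow(0.0, 1.0, [])
    with pytest.raises(ValueError):
        fe.wham_1d([], n_bins=10)


# ---------------------------------------------------------------------------
# Bayesian bootstrap

def test_bootstrap_degenerate_replicas_zero_sd():
    wins = _gaussian_windows(np.linspace(-1, 1, 8), 20.0, 100.0, 2000, 2)
    sd = fe.bayesian_bootstrap(wins, n_boot=2, replica_seeds=[7, 7],
                               n_bins=40)
    assert np.nanmax(sd) == 0.0


def test_bootstrap_argument_validation():
    wins = _gaussian_windows([0.0, 0.5], 20.0, 100.0, 2000, 2)
    with pytest.raises(ValueError):
        fe.bayesian_bootstrap(wins, n_boot=1)
    with pytest.raises(ValueError):
        fe.bayesian_bootstrap(wins[:1], n_boot=10)
    with pytest.raises(ValueError):
        fe.bayesian_bootstrap(wins, n_boot=3, replica_seeds=[1, 2])


def test_bootstrap_error_scaling_with_sample_size():
    """Bootstrap SD shrinks like 1/sqrt(N): log-log slope -0.5 +- 0.15."""
    centers = np.linspace(-1.5, 1.5, 12)
    sizes = [1000, 2000, 4000, 8000]
    mean_sd = []
    for n in sizes:
        sds = [np.nanmean(fe.bayesian_bootstrap(
            _gaussian_windows(centers, 20.0, 100.0, n, 100 + r),
            n_boot=40, seed=r, n_bins=60)) for r in range(3)]
        mean_sd.append(np.mean(sds))
    slope = np.polyfit(np.log(sizes), np.log(mean_sd), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.15)


def test_bootstrap_sd_tracks_regeneration_spread():
    """Reported SD within 30% of the spread of 20 independent runs."""
    centers = np.linspace(-1.5, 1.5, 12)
    grid = np.linspace(-1.2, 1.2, 30)
    profiles = []
    for s in range(20):
        p = fe.wham_1d(_gaussian_windows(centers, 20.0, 100.0, 4000,
                                         500 + s), n_bins=50)
        profiles.append(np.interp(grid, p.bin_centers, p.g))
    regen_sd = float(np.std(profiles, axis=0).mean())
    p = fe.wham_1d(_gaussian_windows(centers, 20.0, 100.0, 4000, 500),
                   n_bins=50)
    boot = fe.bayesian_bootstrap(
        _gaussian_windows(centers, 20.0, 100.0, 4000, 500),
        n_boot=60, seed=3, n_bins=50)
    boot_sd = float(np.interp(grid, p.bin_centers, boot).mean())
    assert boot_sd == pytest.approx(regen_sd, rel=0.30)


def test_bin_count_stability_on_double_well():
    """Doubling the bin count moves the recovered central barrier < 0.3."""
    U = synth.double_well(barrier=6.0, well_position=1.0)
    wins = synth.sample_umbrella(U, np.linspace(-1.5, 1.5, 12),
                                 force_constant=200.0, n_steps=6000, seed=7,
                                 kT=kT)

    def central_barrier(n_bins):
        p = fe.wham_1d(wins, n_bins=n_bins)
        mask = np.abs(p.bin_centers) < 0.15
        return float(np.nanmin(p.g[mask]))

    assert abs(central_barrier(100) - central_barrier(200)) < 0.3


# ---------------------------------------------------------------------------
# Profile summaries

def _profile(x, g):
    return fe.FreeEnergyProfile(bin_centers=np.asarray(x, float),
                                g=np.asarray(g, float), g_error=None, kT=kT)


def test_flat_profile_summaries_zero():
    x = np.linspace(-5, 5, 101)
    s = fe.profile_summary(_profile(x, np.zeros_like(x)),
                           bulk_region=(-5, -4), center_region=(-0.5, 0.5))
    assert (s.entry_barrier, s.central_barrier, s.immersion_dg) == (0, 0, 0)


def test_membrane_like_piecewise_profile():
    """Bulk at 0, wells at -43, central hump at -30: immersion 43 kJ/mol,
    central barrier 13 kJ/mol (phosphatidylcholine-like shape)."""
    x = np.linspace(-5, 5, 201)
    g = np.zeros_like(x)
    g[np.abs(x) <= 2.5] = -43.0
    g[np.abs(x) <= 0.5] = -30.0
    s = fe.profile_summary(_profile(x, g), bulk_region=(-5, -4),
                           center_region=(-0.5, 0.5))
    assert s.immersion_dg == pytest.approx(43.0)
    assert s.central_barrier == pytest.approx(13.0)
    assert s.entry_barrier == pytest.approx(0.0)


def test_summary_gauge_invariance():
    x = np.linspace(-5, 5, 201)
    g = np.where(np.abs(x) <= 2.0, -23.0, 0.0)
    g[np.abs(x) <= 0.4] = -8.0
    s1 = fe.profile_summary(_profile(x, g), (-5, -4), (-0.5, 0.5))
    s2 = fe.profile_summary(_profile(x, g + 17.3), (-5, -4), (-0.5, 0.5))
    assert s2.entry_barrier == pytest.approx(s1.entry_barrier, abs=1e-9)
    assert s2.central_barrier == pytest.approx(s1.central_barrier, abs=1e-9)
    assert s2.immersion_dg == pytest.approx(s1.immersion_dg, abs=1e-9)


def test_entry_barrier_detected():
    x = np.linspace(-5, 5, 201)
    g = np.zeros_like(x)
    g[np.abs(x) <= 3.0] = 4.0    # rim before the well
    g[np.abs(x) <= 2.5] = -20.0
    s = fe.profile_summary(_profile(x, g), (-5, -4), (-0.5, 0.5))
    assert s.entry_barrier == pytest.approx(4.0)


def test_empty_region_rejected():
    x = np.linspace(-1, 1, 21)
    with pytest.raises(ValueError, match="region"):
        fe.profile_summary(_profile(x, np.zeros_like(x)), (5, 6), (-0.5, 0.5))


# ---------------------------------------------------------------------------
# File IO

def test_window_files_round_trip(tmp_path):
    wins = synth.sample_umbrella(synth.harmonic(50.0),
                                 [-0.5, 0.0, 0.5], force_constant=100.0,
                                 n_steps=1500, seed=4)
    meta = synth.write_window_files(wins, tmp_path / "windows")
    loaded = fe.read_metadata_file(meta)
    assert len(loaded) == 3
    for a, b in zip(wins, loaded):
        assert b.center == a.center
        assert b.force_constant == a.force_constant
        assert np.allclose(a.samples, b.samples, atol=1e-6)


def test_window_file_comment_handling(tmp_path):
    path = tmp_path / "w.dat"
    path.write_text("# comment\n@ xvg header\n0 0.11\n1 0.12\n")
    samples = fe.read_window_file(path)
    assert samples.tolist() == [0.11, 0.12]
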