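"""Density maps, z-profiles and Boltzmann inversion."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import lipidprint as lp
from lipidprint.density import KB
from lipidprint.topology import Trajectory

from conftest import SEED


def single_frame_traj(points_xy, box=(10.0, 10.0, 10.0), z=5.0):
    pos = np.c_[points_xy, np.full(len(points_xy), z)]
    return Trajectory(times=[0.0], positions=pos[None], box=np.array(box))


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

def test_single_static_bead_single_bin():
    traj = single_frame_traj(np.array([[2.55, 7.05]]))
    grid = lp.density_map(traj, [0], bins=10, sigma=0.0)
    area = grid.bin_volume
    assert np.count_nonzero(grid.density) == 1
    assert grid.density.max() == pytest.approx(1.0 / area)
    assert grid.density[2, 7] == grid.density.max()


def test_density_integral_equals_mean_count():
    rng = np.random.default_rng(SEED)
    traj = Trajectory(times=np.arange(4) * 0.1,
                      positions=rng.uniform(0, 10, (4, 200, 3)),
                      box=np.array([10.0, 10.0, 10.0]))
    grid = lp.density_map(traj, np.arange(200), bins=25, sigma=0.0)
    assert grid.density.sum() * grid.bin_volume == pytest.approx(200.0,
                                                                 rel=1e-6)


def test_uniform_density_within_poisson_bands():
    rng = np.random.default_rng(SEED)
    n, frames = 500, 20
    traj = Trajectory(times=np.arange(frames) * 0.1,
                      positions=rng.uniform(0, 10, (frames, n, 3)),
                      box=np.array([10.0, 10.0, 10.0]))
    grid = lp.density_map(traj, np.arange(n), bins=10, sigma=0.0)
    expected = n / 100.0  # per nm^2
    sd = np.sqrt(grid.raw_counts.mean()) / frames / grid.bin_volume
    assert np.all(np.abs(grid.density - expected) < 4 * sd)


def test_smoothing_conserves_mass():
    rng = np.random.default_rng(SEED)
    traj = Trajectory(times=[0.0],
                      positions=rng.uniform(0, 10, (1, 300, 3)),
                      box=np.array([10.0, 10.0, 10.0]))
    raw = lp.density_map(traj, np.arange(300), bins=40, sigma=0.0)
    smooth = lp.density_map(traj, np.arange(300), bins=40, sigma=3.0)
    assert smooth.density.sum() == pytest.approx(raw.density.sum(), rel=1e-9)


def test_density_translation_covariance():
    rng = np.random.default_rng(SEED)
    pos = rng.uniform(0, 10, (1, 200, 3))
    box = np.array([10.0, 10.0, 10.0])
    bins = 20
    shift_bins = 3
    delta = shift_bins * 10.0 / bins
    a = lp.density_map(Trajectory(times=[0.0], positions=pos, box=box),
                       np.arange(200), bins=bins, sigma=0.0)
    b = lp.density_map(Trajectory(times=[0.0], positions=pos + [delta, 0, 0],
                                  box=box), np.arange(200), bins=bins,
                       sigma=0.0)
    assert np.allclose(np.roll(a.density, shift_bins, axis=0), b.density)


def test_empty_selection_rejected():
    traj = single_frame_traj(np.zeros((3, 2)))
    with pytest.raises(ValueError, match="empty selection"):
        lp.density_map(traj, np.zeros(0, dtype=int), bins=5)


def test_3d_density_mode():
    rng = np.random.default_rng(SEED)
    traj = Trajectory(times=[0.0], positions=rng.uniform(0, 10, (1, 400, 3)),
                      box=np.array([10.0, 10.0, 10.0]))
    grid = lp.density_map(traj, np.arange(400), bins=8, sigma=0.0, axes="xyz")
    assert grid.density.shape == (8, 8, 8)
    assert grid.density.sum() * grid.bin_volume == pytest.approx(400.0)


# ---------------------------------------------------------------------------
# z-distributions
# ---------------------------------------------------------------------------

def test_z_profile_single_plane():
    traj = single_frame_traj(np.random.default_rng(0).uniform(0, 10, (50, 2)),
                             z=5.0)
    top = None
    zp = lp.z_distribution(traj, _dummy_top(50), np.arange(50), bins=20)
    assert zp.frequency.sum() == pytest.approx(1.0)
    assert np.count_nonzero(zp.frequency) == 1


def _dummy_top(n):
    return lp.BeadTopology(
        bead_name=np.array(["ROH"] * n), residue_id=np.arange(n) + 1000,
        residue_name=np.array(["CHOL"] * n), monomer_id=np.zeros(n, int),
        molecule_id=np.arange(n), molecule_class=np.array(["Chol"] * n))


def test_bulk_cholesterol_z_profile_bimodal(demo_run):
    """Cholesterol hydroxyls sit on the two leaflet planes with a depleted
    midplane (the demo system's outer-leaflet sites make the two modes
    unequal, but both are present)."""
    top = demo_run["topology"]
    traj = demo_run["traj_eq"]
    mspec = demo_run["mspec"]
    zp = lp.z_distribution(traj, top, "bead:ROH", bins=50)
    z_inner, z_outer = mspec.leaflet_z
    assert zp.modes[0] == pytest.approx(z_inner, abs=0.2)
    assert zp.modes[1] == pytest.approx(z_outer, abs=0.2)
    assert zp.midplane_minimum < 0.5 * max(zp.frequency)


def test_sitefree_symmetric_membrane_z_profile_is_mirror_symmetric():
    """Without binding sites, flip-flop equilibrates the two leaflets and the
    cholesterol z-distribution is mirror-symmetric about the midplane
    (two-sample KS on reflected samples, alpha = 0.01)."""
    # molecule leaflet states relax in 1/(2*rate) = 5 ns; sampling every
    # 25 ns (5 relaxation times) makes the pooled samples effectively iid,
    # so the alpha = 0.01 KS test is properly calibrated
    mspec = lp.MembraneSpec(lipids_per_leaflet=150, chol_flip_rate=0.1)
    pspec = lp.ProteinSpec(planted_sites=[])
    top, f0 = lp.build_system(mspec, pspec, seed=SEED + 11)
    traj = lp.simulate(top, f0, 6000, 0.1, seed=SEED + 12,
                       mspec=mspec, pspec=pspec)
    z_inner, z_outer = mspec.leaflet_z
    chol_heads = np.array([np.flatnonzero(top.molecule_id == m)[0]
                           for m in top.molecules_of_class("Chol")])
    z = traj.positions[::250, chol_heads, 2].ravel()
    mid = (z_inner + z_outer) / 2
    p = stats.ks_2samp(z - mid, mid - z).pvalue
    assert p > 0.01


def test_bound_filter_reveals_mid_membrane_density(demo_run):
    """Cholesterol bound at the buried interfacial site produces hydroxyl
    density between the leaflet modes, absent from the bulk profile."""
    top = demo_run["topology"]
    traj = demo_run["traj_eq"]
    bound = lp.z_distribution(traj, top, "bead:ROH", bins=50, bound_filter=0.6)
    bulk = lp.z_distribution(traj, top, "bead:ROH", bins=50)
    centers = bound.centers()
    mid = (centers > 4.4) & (centers < 5.6)
    assert bound.frequency[mid].sum() > 10 * bulk.frequency[mid].sum()
    assert bound.frequency[mid].sum() > 0.02


# ---------------------------------------------------------------------------
# Boltzmann inversion
# ---------------------------------------------------------------------------

def test_uniform_density_gives_zero_free_energy():
    rng = np.random.default_rng(SEED)
    traj = Trajectory(times=np.arange(30) * 0.1,
                      positions=rng.uniform(0, 10, (30, 400, 3)),
                      box=np.array([10.0, 10.0, 10.0]))
    grid = lp.density_map(traj, np.arange(400), bins=8, sigma=0.0)
    fe = lp.free_energy_from_density(grid, T=310.0, ref="global_mean")
    assert not fe.mask.any()
    assert np.nanmin(fe.delta_g) == 0.0
    # fluctuations only: well below thermal energy
    assert np.nanmax(fe.delta_g) < 0.35 * KB * 310


def test_density_ratio_e_gives_kbt():
    """A bin at rho = e * rho_ref lies k_B T = 2.577 kJ/mol below the
    reference at 310 K (before the min-zero shift)."""
    grid = lp.DensityGrid(edges=[np.arange(3.0), np.arange(3.0)],
                          density=np.array([[np.e, 1.0], [1.0, 1.0]]),
                          raw_counts=np.full((2, 2), 100), n_frames=1,
                          sigma_bins=0.0)
    fe = lp.free_energy_from_density(grid, T=310.0, ref=1.0)
    diff = fe.delta_g[0, 1] - fe.delta_g[0, 0]
    assert diff == pytest.approx(KB * 310.0, abs=1e-9)
    assert diff == pytest.approx(2.577, abs=1e-3)
    assert np.nanmin(fe.delta_g) == 0.0


def test_free_energy_invariant_to_total_count_rescaling():
    rng = np.random.default_rng(SEED)
    dens = rng.uniform(0.5, 2.0, (6, 6))
    grid = lp.DensityGrid(edges=[np.arange(7.0), np.arange(7.0)],
                          density=dens, raw_counts=np.full((6, 6), 50),
                          n_frames=1, sigma_bins=0.0)
    doubled = lp.DensityGrid(edges=grid.edges, density=2 * dens,
                             raw_counts=grid.raw_counts, n_frames=1,
                             sigma_bins=0.0)
    a = lp.free_energy_from_density(grid, ref="global_mean")
    b = lp.free_energy_from_density(doubled, ref="global_mean")
    assert np.allclose(a.delta_g, b.delta_g)


def test_all_bins_undersampled_is_error():
    grid = lp.DensityGrid(edges=[np.arange(3.0), np.arange(3.0)],
                          density=np.ones((2, 2)),
                          raw_counts=np.zeros((2, 2)), n_frames=1,
                          sigma_bins=0.0)
    with pytest.raises(ValueError, match="undersampled"):
        lp.free_energy_from_density(grid)


def boltzmann_sample_square_well(n, depth, r0, L, T, seed):
    """Rejection-sampling oracle: positions distributed as exp(-U/kT) for a
    radial square well of the given depth centred in the box."""
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * T)
    out = []
    total = 0
    while total < n:
        cand = rng.uniform(0, L, (4 * n, 2))
        r = np.hypot(cand[:, 0] - L / 2, cand[:, 1] - L / 2)
        u = np.where(r < r0, -depth, 0.0)
        keep = rng.random(len(cand)) < np.exp(-beta * u) * np.exp(-beta * depth)
        out.append(cand[keep])
        total += keep.sum()
    return np.vstack(out)[:n]


def test_square_well_depth_recovery():
    L, r0, depth, T = 10.0, 2.0, 2.5, 310.0
    pos = boltzmann_sample_square_well(100_000, depth, r0, L, T, seed=SEED)
    traj = single_frame_traj(pos, box=(L, L, 10.0))
    grid = lp.density_map(traj, np.arange(len(pos)), bins=50, sigma=0.0)
    fe = lp.free_energy_from_density(grid, T=T, ref="global_mean",
                                     min_count=10)
    cx, cy = np.meshgrid(grid.centers(0), grid.centers(1), indexing="ij")
    r = np.hypot(cx - L / 2, cy - L / 2)
    inside = (r < r0 - 0.3) & ~fe.mask
    outside = (r > r0 + 0.3) & ~fe.mask
    recovered = fe.delta_g[outside].mean() - fe.delta_g[inside].mean()
    assert recovered == pytest.approx(depth, abs=0.25)
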