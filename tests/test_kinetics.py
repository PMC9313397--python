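"""Binding events, kinetic profiles, displacement and anchor analyses."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import lipidprint as lp

from conftest import SEED, make_contact_series


def series_from_indicator(indicator, dt=0.1, residue=400, mol=1):
    frames = np.flatnonzero(indicator)
    rows = [(int(f), residue, 0, mol) for f in frames]
    return make_contact_series(rows, n_frames=len(indicator), dt=dt)


def dense_run_length_oracle(indicator, gap_tolerance, dt):
    """Reference event extraction by explicit scanning of a dense 0/1 series."""
    events, start, last = [], None, None
    for t, on in enumerate(indicator):
        if on:
            if start is None:
                start, last = t, t
            elif t - last > gap_tolerance + 1:
                events.append((start, last))
                start, last = t, t
            else:
                last = t
    if start is not None:
        events.append((start, last))
    return [(s * dt, e * dt, (e - s + 1) * dt) for s, e in events]


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

def test_event_extraction_examples():
    cs = series_from_indicator([1, 1, 0, 1])
    ev = lp.extract_events(cs, gap_tolerance=0)
    assert sorted(ev["duration_ns"].round(6)) == [pytest.approx(0.1),
                                                  pytest.approx(0.2)]
    merged = lp.extract_events(cs, gap_tolerance=1)
    assert len(merged) == 1
    assert merged["duration_ns"].iloc[0] == pytest.approx(0.4)


def test_no_contacts_no_events():
    cs = make_contact_series(np.zeros((0, 4)), n_frames=10)
    assert len(lp.extract_events(cs)) == 0


@pytest.mark.parametrize("gap", [0, 1])
def test_events_match_dense_oracle_on_random_series(gap):
    rng = np.random.default_rng(SEED)
    for _ in range(40):
        n = int(rng.integers(5, 200))
        indicator = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(int)
        cs = series_from_indicator(indicator)
        got = sorted(zip(lp.extract_events(cs, gap)["start_ns"].round(6),
                         lp.extract_events(cs, gap)["end_ns"].round(6),
                         lp.extract_events(cs, gap)["duration_ns"].round(6)))
        want = [(pytest.approx(s), pytest.approx(e), pytest.approx(d))
                for s, e, d in dense_run_length_oracle(indicator, gap, 0.1)]
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert g == w


def test_event_durations_sum_to_contact_frames(demo_run):
    """With gap_tolerance 0, per-pair event durations sum to dt times the
    pair's contact-frame count."""
    cs = demo_run["contacts"]
    ev = demo_run["events"]
    df = pd.DataFrame({"residue_id": cs.residue_id, "monomer_id": cs.monomer_id,
                       "molecule_id": cs.molecule_id, "frame": cs.frame})
    frames_per_pair = (df.drop_duplicates()
                       .groupby(["residue_id", "monomer_id", "molecule_id"])
                       .size())
    dur_per_pair = ev.groupby(["residue_id", "monomer_id", "molecule_id"]
                              )["duration_ns"].sum()
    aligned = pd.concat([frames_per_pair * cs.dt, dur_per_pair], axis=1)
    assert np.allclose(aligned.iloc[:, 0], aligned.iloc[:, 1])


# ---------------------------------------------------------------------------
# kinetic profile
# ---------------------------------------------------------------------------

def test_profile_single_persistent_molecule():
    n = 50
    cs = series_from_indicator([1] * n)
    ev = lp.extract_events(cs)
    prof = lp.kinetic_profile(ev, cs, "Chol")
    row = prof.table.loc[400]
    assert row["contact_duration"] == pytest.approx(n * 0.1)
    assert row["max_occupancy"] == pytest.approx(n * 0.1)
    assert row["contact_duration_norm"] == pytest.approx(1.0)
    assert row["n_distinct_partners"] == 1


def test_profile_alternating_molecules_decomposition():
    """Two molecules alternating every frame: full contact duration but
    maximum occupancy of a single frame."""
    rows = [(t, 400, 0, 1 if t % 2 == 0 else 2) for t in range(40)]
    cs = make_contact_series(rows, n_frames=40, classes={1: "Chol", 2: "Chol"})
    ev = lp.extract_events(cs)
    prof = lp.kinetic_profile(ev, cs, "Chol")
    row = prof.table.loc[400]
    assert row["contact_duration"] == pytest.approx(4.0)
    assert row["max_occupancy"] == pytest.approx(0.1)
    assert row["n_distinct_partners"] == 2


def test_profile_invariants_and_modes(demo_run):
    prof = demo_run["profile"]
    total = prof.total_time_ns
    t = prof.table
    assert (t["max_occupancy"] <= t["contact_duration"] + 1e-9).all()
    assert (t["contact_duration"] <= total + 1e-9).all()
    assert t["contact_duration_norm"].max() == pytest.approx(1.0)
    # molecule-sum mode may exceed the union but never undershoots it
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof_sum = lp.kinetic_profile(demo_run["events"], demo_run["contacts"],
                                      "Chol", topology=demo_run["topology"],
                                      duration_mode="sum")
    assert (prof_sum.table["contact_duration"]
            >= t["contact_duration"] - 1e-9).all()


def test_profile_from_persisted_series_matches(demo_run, tmp_path):
    cs = demo_run["contacts"]
    path = tmp_path / "c.tsv"
    cs.save_tsv(path)
    back = lp.ContactSeries.load_tsv(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof2 = lp.kinetic_profile(lp.extract_events(back), back, "Chol",
                                   topology=demo_run["topology"])
    pd.testing.assert_frame_equal(prof2.table, demo_run["profile"].table)


def test_ranking_rules():
    rows = [(t, 400, 0, 1) for t in range(10)] + [(t, 401, 0, 1) for t in range(5)]
    cs = make_contact_series(rows, n_frames=10)
    prof = lp.kinetic_profile(lp.extract_events(cs), cs, "Chol")
    assert list(lp.rank_residues(prof, "contact_duration", 1)) == [400]
    # all-equal profile: ties broken by ascending residue id
    rows = [(t, r, 0, 1) for t in range(5) for r in (402, 401, 400)]
    cs = make_contact_series(rows, n_frames=5)
    prof = lp.kinetic_profile(lp.extract_events(cs), cs, "Chol")
    assert list(lp.rank_residues(prof, "max_occupancy", 2)) == [400, 401]
    assert len(lp.rank_residues(prof, "max_occupancy", 99)) == 3


def test_ranking_invariant_to_monomer_relabelling(demo_run):
    cs = demo_run["contacts"]
    perm = {0: 2, 1: 3, 2: 1, 3: 0}
    relabelled = lp.ContactSeries(
        frame=cs.frame, residue_id=cs.residue_id,
        monomer_id=np.vectorize(perm.get)(cs.monomer_id),
        molecule_id=cs.molecule_id, n_frames=cs.n_frames, dt=cs.dt,
        cutoff=cs.cutoff, molecule_class=dict(cs.molecule_class))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof2 = lp.kinetic_profile(lp.extract_events(relabelled), relabelled,
                                   "Chol", topology=demo_run["topology"])
    for metric in ("contact_duration", "max_occupancy"):
        assert np.array_equal(
            lp.rank_residues(prof2, metric, 10),
            lp.rank_residues(demo_run["profile"], metric, 10))


# ---------------------------------------------------------------------------
# displacement maps
# ---------------------------------------------------------------------------

def test_displacement_frozen_lipids_zero():
    mspec = lp.MembraneSpec(lipids_per_leaflet=40, default_D=0.0,
                            chol_flip_rate=0.0)
    pspec = lp.ProteinSpec(planted_sites=[])
    top, f0 = lp.build_system(mspec, pspec, seed=2)
    traj = lp.simulate(top, f0, 10, 0.1, seed=3, mspec=mspec, pspec=pspec)
    grid = lp.displacement_map(traj, top, "Chol", cutoff=None, bins=5)
    sampled = grid.samples > 0
    assert np.allclose(grid.rate[sampled], 0.0)
    assert np.isnan(grid.rate[~sampled]).all()  # missing, not zero


def test_displacement_free_diffusion_matches_closed_form():
    """Mean step length of 2D Gaussian diffusion is sqrt(pi D dt)."""
    mspec = lp.MembraneSpec(lipids_per_leaflet=250, chol_flip_rate=0.0)
    pspec = lp.ProteinSpec(planted_sites=[])
    top, f0 = lp.build_system(mspec, pspec, seed=2)
    traj = lp.simulate(top, f0, 800, 0.1, seed=3, mspec=mspec, pspec=pspec)
    grid = lp.displacement_map(traj, top, "Chol", cutoff=None, bins=3)
    expected = np.sqrt(np.pi * mspec.default_D * 0.1) / 0.1
    # footprint rejection only slows the centre bin; check the corner bins
    corners = [grid.rate[0, 0], grid.rate[0, -1], grid.rate[-1, 0],
               grid.rate[-1, -1]]
    assert min(grid.samples[0, 0], grid.samples[-1, -1]) >= 1000
    for r in corners:
        assert r == pytest.approx(expected, rel=0.05)


def test_displacement_slower_over_slow_site(demo_run):
    """Bins covering the planted slow site show a lower mean displacement
    rate than bulk-adjacent bins away from any planted site (site-bound
    molecules only rattle in the pocket, bulk molecules diffuse freely)."""
    top = demo_run["topology"]
    pspec = demo_run["pspec"]
    traj = demo_run["traj_eq"]
    grid = lp.displacement_map(traj, top, "Chol", cutoff=0.6, bins=15)
    slow = [s for s in pspec.planted_sites if s.site_class == "non_annular"][0]
    ix = np.digitize(slow.center[0], grid.x_edges) - 1
    iy = np.digitize(slow.center[1], grid.y_edges) - 1
    site_rate = grid.rate[ix, iy]
    assert grid.samples[ix, iy] > 100
    # free 2D diffusion moves sqrt(pi D dt) per step; a pinned molecule only
    # rattles in its pocket. The planted sites cover the whole contact
    # annulus, so the bulk reference is the closed form rather than a
    # site-free bin.
    bulk_rate = np.sqrt(np.pi * demo_run["mspec"].default_D * traj.dt) / traj.dt
    assert site_rate < 0.8 * bulk_rate
    assert np.nanmax(grid.rate[grid.samples > 100]) > 1.2 * site_rate


# ---------------------------------------------------------------------------
# co-contacts and bead ratios
# ---------------------------------------------------------------------------

def test_co_contact_empty_anchor_warns():
    cs = make_contact_series([(0, 401, 0, 1)], n_frames=5)
    with pytest.warns(UserWarning, match="never in contact"):
        prof = lp.co_contact_profile(cs, 660, 0, "Chol")
    assert len(prof) == 0


def test_co_contact_simultaneous_neighbour():
    rows = [(t, 660, 0, 1) for t in range(10)] + \
           [(t, 657, 1, 1) for t in range(10)] + \
           [(t, 500, 0, 2) for t in range(10)]  # other molecule: excluded
    cs = make_contact_series(rows, n_frames=10, classes={1: "Chol", 2: "Chol"})
    prof = lp.co_contact_profile(cs, 660, 0, "Chol")
    assert prof.loc[657] == 10
    assert 500 not in prof.index


def test_co_contact_matches_brute_force_recount(demo_run):
    cs = demo_run["contacts"]
    prof = lp.co_contact_profile(cs, 660, 0, "Chol")
    # frame-by-frame conditional recount from the raw rows
    df = cs.restrict("Chol").to_dataframe()
    anchored = df[(df.residue_id == 660) & (df.monomer_id == 0)]
    bound = set(map(tuple, anchored[["frame", "molecule_id"]].to_numpy()))
    counts = {}
    for f, rid, mid, mol in df[["frame", "residue_id", "monomer_id",
                                "molecule_id"]].to_numpy():
        if (f, mol) in bound and not (rid == 660 and mid == 0):
            counts[rid] = counts.get(rid, 0) + 1
    assert dict(prof) == counts
    assert prof.loc[657] > 0  # the interfacial partner residue co-contacts


def test_bead_ratio_requires_multibead(demo_run):
    with pytest.raises(ValueError, match="single-bead"):
        lp.bead_contact_ratio(
            lp.ContactSeries(**{**demo_run["contacts"].__dict__,
                                "level": "bead"}),
            demo_run["topology"], 660, "Chol")


def test_bead_ratio_uniform_and_trivial():
    top = lp.BeadTopology(
        bead_name=np.array(["BB"] + list(lp.synthetic.CHOL_BEAD_NAMES)),
        residue_id=np.array([660] + [1000] * 8),
        residue_name=np.array(["ALA"] + ["CHOL"] * 8),
        monomer_id=np.zeros(9, int),
        molecule_id=np.array([0] + [1] * 8),
        molecule_class=np.array(["protein"] + ["Chol"] * 8))
    rows = []
    for t in range(8):
        rows.append((t, 660, 0, 1, 0, 1 + t))  # each bead once
    arr = np.array(rows)
    cs = lp.ContactSeries(
        frame=arr[:, 0], residue_id=arr[:, 1], monomer_id=arr[:, 2],
        molecule_id=arr[:, 3], protein_bead=arr[:, 4], lipid_bead=arr[:, 5],
        n_frames=8, dt=0.1, cutoff=0.6, level="bead",
        molecule_class={1: "Chol"})
    frac = lp.bead_contact_ratio(cs, top, 660, "Chol")
    assert np.allclose(frac.to_numpy(), 0.125)
    only_roh = lp.ContactSeries(
        frame=arr[:1, 0], residue_id=arr[:1, 1], monomer_id=arr[:1, 2],
        molecule_id=arr[:1, 3], protein_bead=arr[:1, 4],
        lipid_bead=np.array([1]), n_frames=8, dt=0.1, cutoff=0.6,
        level="bead", molecule_class={1: "Chol"})
    frac = lp.bead_contact_ratio(only_roh, top, 660, "Chol")
    assert frac.loc["ROH"] == pytest.approx(1.0)


def test_bead_ratio_eight_bead_cholesterol_fixture():
    """With 8-bead cholesterol pinned hydroxyl-first at a mid-membrane site,
    the contacts are carried by a combination of the hydroxyl bead and the
    adjacent sterol beads (the hydroxyl and its neighbour are both always in
    range of the pinned molecule, so they tie for the largest share)."""
    mspec = lp.MembraneSpec(lipids_per_leaflet=60, chol_beads=8)
    site = lp.BindingSiteSpec(660, 0, k_off=0.001, z=5.0, leaflet="both",
                              site_class="non_annular")
    pspec = lp.ProteinSpec(planted_sites=[site])
    top, f0 = lp.build_system(mspec, pspec, seed=SEED)
    traj = lp.simulate(top, f0, 500, 0.1, seed=SEED + 1, mspec=mspec,
                       pspec=pspec)
    cs = lp.contact_series(traj, top, 0.6, level="bead")
    frac = lp.bead_contact_ratio(cs, top, 660, "Chol")
    assert frac["ROH"] == pytest.approx(frac.max())
    near = frac.reindex(["ROH", "R1", "R2"]).fillna(0.0).sum()
    assert near > 0.9
    assert frac.sum() == pytest.approx(1.0)
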