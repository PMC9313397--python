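"""Shared fixtures: synthetic systems at several scales.

The expensive full-scale run (9000 frames, the bundled demo conditions) is
session-scoped and shared by the kinetics and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import lipidprint as lp

SEED = 202  # suite-wide base seed


@pytest.fixture(scope="session")
def demo_specs():
    mspec = lp.MembraneSpec()
    pspec = lp.ProteinSpec(planted_sites=lp.default_sites())
    return mspec, pspec


@pytest.fixture(scope="session")
def demo_system(demo_specs):
    mspec, pspec = demo_specs
    top, f0 = lp.build_system(mspec, pspec, seed=SEED)
    return top, f0


@pytest.fixture(scope="session")
def demo_run(demo_specs, demo_system):
    """Full-scale run: 9000 frames at dt = 0.1 ns (0.9 us), equilibration cut
    at 100 ns, with contact series, events and the cholesterol profile."""
    mspec, pspec = demo_specs
    top, f0 = demo_system
    traj = lp.simulate(top, f0, 9000, 0.1, seed=SEED + 1,
                       mspec=mspec, pspec=pspec)
    traj_eq = lp.slice_equilibrated(traj, 100.0)
    contacts = lp.contact_series(traj_eq, top, 0.6)
    events = lp.extract_events(contacts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profile = lp.kinetic_profile(events, contacts, "Chol", topology=top)
    return {"mspec": mspec, "pspec": pspec, "topology": top, "traj": traj,
            "traj_eq": traj_eq, "contacts": contacts, "events": events,
            "profile": profile}


@pytest.fixture()
def small_system():
    """Cheap system for I/O and geometry tests."""
    mspec = lp.MembraneSpec(lipids_per_leaflet=40)
    pspec = lp.ProteinSpec(planted_sites=lp.default_sites())
    top, f0 = lp.build_system(mspec, pspec, seed=SEED)
    return mspec, pspec, top, f0


def make_contact_series(rows, n_frames, dt=0.1, cutoff=0.6, classes=None,
                        level="molecule"):
    """Build a ContactSeries from (frame, residue, monomer, molecule) rows."""
    rows = np.asarray(rows, dtype=int).reshape(-1, 4)
    return lp.ContactSeries(
        frame=rows[:, 0], residue_id=rows[:, 1], monomer_id=rows[:, 2],
        molecule_id=rows[:, 3], n_frames=n_frames, dt=dt, cutoff=cutoff,
        level=level,
        molecule_class=classes or {int(m): "Chol" for m in set(rows[:, 3])},
    )
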