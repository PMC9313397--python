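"""Binding-event kinetics: contact duration, maximum occupancy, exchange.

The central decomposition: *contact duration* of a residue is the total time
it spends in contact with any lipid of a given class (frame union over
molecules), while *maximum occupancy* is the longest continuous contact with
one specific molecule. High contact duration with many distinct partner
molecules is the signature of an annular site (fast exchange with the bulk);
high maximum occupancy carried by one or two partners is the signature of a
non-annular site. Metrics are computed per (monomer, residue) copy and
averaged over monomer copies (and repeat runs) before ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import ContactSeries
from .topology import BeadTopology, Trajectory, min_image_vector

EVENT_COLUMNS = ["residue_id", "monomer_id", "molecule_id",
                 "start_frame", "end_frame", "start_ns", "end_ns", "duration_ns"]


def extract_events(contacts: ContactSeries, gap_tolerance: int = 0,
                   repeat: int = 0) -> pd.DataFrame:
    """Maximal runs of consecutive contact frames per (residue, molecule).

    Runs separated by at most ``gap_tolerance`` non-contact frames are merged
    (default 0 = strict). Durations are inclusive: a run of n frames lasts
    ``n * dt`` ns. Returns one row per binding event with the columns in
    :data:`EVENT_COLUMNS` plus ``repeat``.
    """
    if contacts.dt is None:
        raise ValueError("kinetics require a multi-frame trajectory (dt known)")
    dt = contacts.dt
    if len(contacts) == 0:
        df = pd.DataFrame(columns=EVENT_COLUMNS)
        df["repeat"] = pd.Series(dtype=int)
        return df
    df = pd.DataFrame({
        "residue_id": contacts.residue_id, "monomer_id": contacts.monomer_id,
        "molecule_id": contacts.molecule_id, "frame": contacts.frame,
    }).drop_duplicates()
    df = df.sort_values(["residue_id", "monomer_id", "molecule_id", "frame"],
                        kind="stable", ignore_index=True)
    key_change = (df[["residue_id", "monomer_id", "molecule_id"]]
                  .ne(df[["residue_id", "monomer_id", "molecule_id"]].shift())
                  .any(axis=1).to_numpy())
    gap = df["frame"].diff().to_numpy()
    new_run = key_change | (gap > gap_tolerance + 1)
    run_id = np.cumsum(new_run) - 1
    g = df.groupby(run_id)
    first = g.first()
    out = pd.DataFrame({
        "residue_id": first["residue_id"].to_numpy(),
        "monomer_id": first["monomer_id"].to_numpy(),
        "molecule_id": first["molecule_id"].to_numpy(),
        "start_frame": g["frame"].min().to_numpy(),
        "end_frame": g["frame"].max().to_numpy(),
    })
    out["start_ns"] = out["start_frame"] * dt
    out["end_ns"] = out["end_frame"] * dt
    out["duration_ns"] = (out["end_frame"] - out["start_frame"] + 1) * dt
    out["repeat"] = repeat
    return out


@dataclass
class KineticProfile:
    """Per-residue kinetic metrics for one lipid class.

    ``per_copy`` is indexed by (repeat, monomer_id, residue_id);
    ``table`` is the monomer-averaged report, indexed by residue_id, with
    columns ``contact_duration`` (ns), ``max_occupancy`` (ns),
    ``n_distinct_partners`` (mean over copies), their ``*_sem`` standard
    errors across copies, and ``*_norm`` columns normalised by the maximum
    over residues.
    """

    per_copy: pd.DataFrame
    table: pd.DataFrame
    lipid_class: str
    total_time_ns: float
    duration_mode: str


def kinetic_profile(events: pd.DataFrame | list, contacts: ContactSeries | list,
                    lipid_class: str, monomer_map=None, *,
                    topology: BeadTopology | None = None,
                    duration_mode: str = "union") -> KineticProfile:
    """Contact duration, maximum occupancy and distinct partners per residue.

    Parameters
    ----------
    events, contacts
        Output of :func:`extract_events` and its source series; lists of
        equal length pool repeat runs, each (repeat, monomer) counting as a
        separate copy of the chain.
    monomer_map
        Iterable of monomer ids to average over (default: all seen in the
        contact series).
    topology
        If given, residues that never contact the class appear in the table
        with all-zero metrics instead of being absent.
    duration_mode
        "union" (default): contact duration is the time the residue touches
        at least one molecule of the class. "sum": durations are summed over
        molecules (may exceed the trajectory length when several molecules
        touch at once).
    """
    ev_list = events if isinstance(events, list) else [events]
    cs_list = contacts if isinstance(contacts, list) else [contacts]
    if len(ev_list) != len(cs_list):
        raise ValueError("events and contacts repeat lists differ in length")
    dt = cs_list[0].dt
    if dt is None:
        raise ValueError("kinetics require a multi-frame trajectory")
    total_time = cs_list[0].n_frames * dt

    rows = []
    for rep, (ev, cs) in enumerate(zip(ev_list, cs_list)):
        sub = cs.restrict(lipid_class)
        class_mols = set(sub.molecule_class)
        evc = ev[ev["molecule_id"].isin(class_mols)]
        key = ["monomer_id", "residue_id"]
        if duration_mode == "union":
            cd = (pd.DataFrame({"monomer_id": sub.monomer_id,
                                "residue_id": sub.residue_id,
                                "frame": sub.frame})
                  .drop_duplicates().groupby(key).size() * dt)
        elif duration_mode == "sum":
            cd = evc.groupby(key)["duration_ns"].sum()
        else:
            raise ValueError(f"unknown duration_mode {duration_mode!r}")
        mo = evc.groupby(key)["duration_ns"].max()
        nd = evc.groupby(key)["molecule_id"].nunique()
        df = pd.DataFrame({"contact_duration": cd, "max_occupancy": mo,
                           "n_distinct_partners": nd}).fillna(0.0)
        df["repeat"] = rep
        rows.append(df.reset_index())
    per_copy = pd.concat(rows, ignore_index=True)

    monomers = (sorted(set(per_copy["monomer_id"])) if monomer_map is None
                else sorted(monomer_map))
    if topology is not None:
        res_ids = np.unique(topology.residue_id[topology.protein_mask])
        monomers = (sorted(np.unique(topology.monomer_id[topology.protein_mask]))
                    if monomer_map is None else monomers)
    else:
        res_ids = np.unique(per_copy["residue_id"])
    # full (repeat, monomer, residue) grid: copies with no events count as 0
    n_reps = len(ev_list)
    full = pd.MultiIndex.from_product(
        [range(n_reps), monomers, res_ids],
        names=["repeat", "monomer_id", "residue_id"])
    per_copy = (per_copy.set_index(["repeat", "monomer_id", "residue_id"])
                .reindex(full, fill_value=0.0).sort_index())

    if per_copy.empty or float(per_copy.to_numpy().sum()) == 0.0:
        warnings.warn(f"no {lipid_class} contacts: all-zero kinetic profile",
                      stacklevel=2)

    g = per_copy.groupby(level="residue_id")
    mean = g.mean()
    n_copies = n_reps * max(len(monomers), 1)
    sem = g.std(ddof=1).fillna(0.0) / np.sqrt(max(n_copies, 1))
    table = mean.copy()
    for c in ("contact_duration", "max_occupancy", "n_distinct_partners"):
        table[c + "_sem"] = sem[c]
        mx = mean[c].max()
        table[c + "_norm"] = mean[c] / mx if mx > 0 else 0.0
    return KineticProfile(per_copy=per_copy, table=table,
                          lipid_class=lipid_class, total_time_ns=total_time,
                          duration_mode=duration_mode)


def rank_residues(profile: KineticProfile, metric: str, k: int = 10) -> np.ndarray:
    """Top-``k`` residue ids by the monomer-averaged metric.

    Ties are broken by ascending residue id; ``k`` beyond the residue count
    returns the full ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in profile.table.columns:
        raise KeyError(f"unknown metric {metric!r}")
    t = profile.table.reset_index()
    t = t.sort_values([metric, "residue_id"], ascending=[False, True],
                      kind="stable")
    return t["residue_id"].to_numpy()[:k]


# ---------------------------------------------------------------------------
# Displacement maps
# ---------------------------------------------------------------------------

@dataclass
class DisplacementGrid:
    """Lateral map of mean lipid displacement rate (nm/ns).

    Bins with zero samples hold NaN in ``rate`` (missing, not zero).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    rate: np.ndarray      # (nx, ny) mean |step|/dt
    samples: np.ndarray   # (nx, ny) int


def displacement_map(traj: Trajectory, topology: BeadTopology, lipid_class: str,
                     cutoff: float | None = 0.6, bins: int = 30,
                     mode: str = "3d") -> DisplacementGrid:
    """Mean displacement rate of lipids near the protein, binned laterally.

    For each consecutive frame pair, molecules of the class with any bead
    within ``cutoff`` of any protein bead at the earlier frame contribute
    their minimum-image step length divided by dt, binned at the molecule's
    lateral position in the earlier frame. ``cutoff=None`` tracks all
    molecules of the class. ``mode`` selects 3D step length (default) or
    lateral-only.
    """
    if traj.n_frames < 2:
        raise ValueError("displacement map needs at least 2 frames")
    box = np.asarray(traj.frame_box(0), dtype=float)
    mols = topology.molecules_of_class(lipid_class)
    head = np.array([np.flatnonzero(topology.molecule_id == m)[0] for m in mols])
    lbead = np.flatnonzero(np.isin(topology.molecule_id, mols))
    bead2mol = np.searchsorted(mols, topology.molecule_id[lbead])
    p_idx = np.flatnonzero(topology.protein_mask)

    x_edges = np.linspace(0, box[0], bins + 1)
    y_edges = np.linspace(0, box[1], bins + 1)
    ssum = np.zeros((bins, bins))
    scount = np.zeros((bins, bins), dtype=int)
    dt = traj.dt

    static_protein = np.array_equal(traj.positions[0][p_idx],
                                    traj.positions[-1][p_idx])
    tree_p = None
    for t in range(traj.n_frames - 1):
        pos0, pos1 = traj.positions[t], traj.positions[t + 1]
        if cutoff is None:
            tracked = np.arange(len(mols))
        else:
            if tree_p is None or not static_protein:
                tree_p = cKDTree(np.mod(pos0[p_idx], box), boxsize=box)
            d, _ = tree_p.query(np.mod(pos0[lbead], box),
                                distance_upper_bound=cutoff)
            tracked = np.unique(bead2mol[d < cutoff])
        if len(tracked) == 0:
            continue
        hb = head[tracked]
        step = min_image_vector(pos0[hb], pos1[hb], box)
        if mode == "lateral":
            step = step[:, :2]
        rate = np.linalg.norm(step, axis=1) / dt
        xy = np.mod(pos0[hb, :2], box[:2])
        ix = np.clip(np.digitize(xy[:, 0], x_edges) - 1, 0, bins - 1)
        iy = np.clip(np.digitize(xy[:, 1], y_edges) - 1, 0, bins - 1)
        np.add.at(ssum, (ix, iy), rate)
        np.add.at(scount, (ix, iy), 1)

    with np.errstate(invalid="ignore"):
        mean = np.where(scount > 0, ssum / np.maximum(scount, 1), np.nan)
    return DisplacementGrid(x_edges=x_edges, y_edges=y_edges,
                            rate=mean, samples=scount)


# ---------------------------------------------------------------------------
# Anchor-conditioned analyses
# ---------------------------------------------------------------------------

def co_contact_profile(contacts: ContactSeries, anchor_residue_id: int,
                       anchor_monomer_id: int, lipid_class: str) -> pd.Series:
    """Residue contact counts of lipids while they are bound to an anchor.

    Over frames in which the anchor residue contacts at least one molecule of
    the class, counts (frame, residue) contacts between those same molecules
    and every other residue. Returns counts indexed by residue_id (pooled
    over monomers), anchor excluded.
    """
    sub = contacts.restrict(lipid_class)
    df = sub.to_dataframe()
    anchored = df[(df["residue_id"] == anchor_residue_id)
                  & (df["monomer_id"] == anchor_monomer_id)]
    if anchored.empty:
        warnings.warn("anchor residue is never in contact with "
                      f"{lipid_class}: empty co-contact profile", stacklevel=2)
        return pd.Series(dtype=int, name="co_contacts")
    bound = anchored[["frame", "molecule_id"]].drop_duplicates()
    joined = df.merge(bound, on=["frame", "molecule_id"])
    joined = joined[~((joined["residue_id"] == anchor_residue_id)
                      & (joined["monomer_id"] == anchor_monomer_id))]
    out = joined.groupby("residue_id").size()
    out.name = "co_contacts"
    return out


def bead_contact_ratio(contacts: ContactSeries, topology: BeadTopology,
                       residue_id: int, lipid_class: str,
                       monomer_id: int | None = None) -> pd.Series:
    """Fraction of bead-level contacts at a residue per lipid bead name.

    Requires a bead-resolution contact series and a multi-bead lipid model
    (e.g. 8-bead cholesterol); fractions sum to 1.
    """
    if contacts.level != "bead":
        raise ValueError("bead_contact_ratio needs contacts with level='bead'")
    mols = topology.molecules_of_class(lipid_class)
    beads_per_mol = np.array([(topology.molecule_id == m).sum() for m in mols])
    if len(beads_per_mol) and beads_per_mol.max() == 1:
        raise ValueError(
            f"{lipid_class} molecules are single-bead here; rebuild the "
            "system with the multi-bead representation (chol_beads=8) to "
            "resolve per-bead contact ratios")
    sub = contacts.restrict(lipid_class)
    df = sub.to_dataframe()
    df = df[df["residue_id"] == residue_id]
    if monomer_id is not None:
        df = df[df["monomer_id"] == monomer_id]
    if df.empty:
        warnings.warn(f"residue {residue_id} never contacts {lipid_class}",
                      stacklevel=2)
        return pd.Series(dtype=float, name="fraction")
    names = pd.Series(topology.bead_name[df["lipid_bead"].to_numpy()])
    counts = names.value_counts()
    frac = counts / counts.sum()
    frac.name = "fraction"
    return frac
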