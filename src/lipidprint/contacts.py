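"""Residue-lipid contact detection and first-shell statistics.

A contact exists when any bead of a protein residue and any bead of a lipid
molecule lie within the cutoff (default 0.6 nm, strict ``<``) under the
rectangular minimum-image convention. Detection uses a periodic k-d tree
(:class:`scipy.spatial.cKDTree` with ``boxsize``), which scales linearly in
bead count; candidate pairs are re-checked against the strict cutoff.

The contact counting unit is (frame, residue, molecule): several bead pairs
between one residue and one lipid in one frame count once. Bead-level
resolution (needed for per-bead contact ratios) is available via
``level="bead"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import (BeadTopology, Frame, GeometryError, Trajectory,
                       min_image_distance)

DEFAULT_CUTOFF = 0.6  # nm


@dataclass
class ContactSeries:
    """Sparse per-frame residue-lipid contact table.

    Parallel int arrays, one row per (frame, residue, molecule[, bead pair])
    contact. ``dt`` and ``n_frames`` describe the source trajectory so every
    kinetic metric can be computed from the series alone.
    """

    frame: np.ndarray
    residue_id: np.ndarray
    monomer_id: np.ndarray
    molecule_id: np.ndarray
    n_frames: int
    dt: float | None
    cutoff: float
    level: str = "molecule"             # "molecule" or "bead"
    protein_bead: np.ndarray | None = None
    lipid_bead: np.ndarray | None = None
    molecule_class: dict = field(default_factory=dict)  # molecule_id -> class

    def __len__(self) -> int:
        return len(self.frame)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame": self.frame, "residue_id": self.residue_id,
                "monomer_id": self.monomer_id, "molecule_id": self.molecule_id}
        if self.level == "bead":
            data["protein_bead"] = self.protein_bead
            data["lipid_bead"] = self.lipid_bead
        return pd.DataFrame(data)

    def restrict(self, lipid_class: str) -> "ContactSeries":
        """Rows whose lipid molecule belongs to one class."""
        ids = np.array([m for m, c in self.molecule_class.items()
                        if c == lipid_class], dtype=int)
        keep = np.isin(self.molecule_id, ids)
        return ContactSeries(
            frame=self.frame[keep], residue_id=self.residue_id[keep],
            monomer_id=self.monomer_id[keep], molecule_id=self.molecule_id[keep],
            n_frames=self.n_frames, dt=self.dt, cutoff=self.cutoff,
            level=self.level,
            protein_bead=None if self.protein_bead is None else self.protein_bead[keep],
            lipid_bead=None if self.lipid_bead is None else self.lipid_bead[keep],
            molecule_class={m: c for m, c in self.molecule_class.items()
                            if c == lipid_class},
        )

    # -- persistence (documented columnar layout) ---------------------------

    def save_tsv(self, path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            fh.write(f"# lipidprint-contacts v1 n_frames={self.n_frames} "
                     f"dt={'' if self.dt is None else self.dt} "
                     f"cutoff={self.cutoff} level={self.level}\n")
            fh.write("# classes " + " ".join(
                f"{m}:{c}" for m, c in sorted(self.molecule_class.items())) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path) -> "ContactSeries":
        with open(path) as fh:
            header = fh.readline().strip()
            fields = dict(kv.split("=", 1) for kv in header.split()[3:])
            class_line = fh.readline().strip().split()[2:]
            df = pd.read_csv(fh, sep="\t")
        classes = {int(kv.split(":")[0]): kv.split(":")[1] for kv in class_line}
        return cls(
            frame=df["frame"].to_numpy(), residue_id=df["residue_id"].to_numpy(),
            monomer_id=df["monomer_id"].to_numpy(),
            molecule_id=df["molecule_id"].to_numpy(),
            n_frames=int(fields["n_frames"]),
            dt=None if fields["dt"] == "" else float(fields["dt"]),
            cutoff=float(fields["cutoff"]), level=fields["level"],
            protein_bead=df["protein_bead"].to_numpy() if "protein_bead" in df else None,
            lipid_bead=df["lipid_bead"].to_numpy() if "lipid_bead" in df else None,
            molecule_class=classes,
        )


@dataclass
class ShellCountSeries:
    """Per-frame first-shell molecule counts with window averaging.

    ``counts`` holds the raw per-frame counts, one row per repeat;
    ``smoothed`` the centred moving average (window shrinks at the edges);
    ``mean``/``sd`` the across-repeat statistics of the smoothed series.
    """

    times: np.ndarray
    counts: np.ndarray      # (n_repeats, n_frames)
    smoothed: np.ndarray    # (n_repeats, n_frames)
    mean: np.ndarray
    sd: np.ndarray
    lipid_class: str
    window_ns: float

    def plateau(self, t_start: float = 0.0) -> float:
        """Mean of the across-repeat mean series for times >= t_start."""
        keep = self.times >= t_start - 1e-9
        return float(self.mean[keep].mean())


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _check_cutoff(cutoff: float, box: np.ndarray) -> None:
    if cutoff <= 0:
        raise GeometryError("cutoff must be > 0")
    if cutoff >= min(box) / 2.0:
        raise GeometryError(
            f"cutoff {cutoff} nm >= half the smallest box length {min(box) / 2}")


def find_contacts(frame: Frame, topology: BeadTopology, cutoff: float = DEFAULT_CUTOFF,
                  lipid_classes=None, level: str = "molecule") -> pd.DataFrame:
    """Residue-lipid contacts in one frame.

    Returns a DataFrame with columns ``residue_id, monomer_id, molecule_id``
    (plus ``protein_bead, lipid_bead`` for ``level="bead"``), one row per
    contact pair present in the frame.
    """
    box = np.asarray(frame.box, dtype=float)
    _check_cutoff(cutoff, box)
    pmask = topology.protein_mask
    lmask = topology.lipid_mask() if lipid_classes is None else np.isin(
        topology.molecule_class, list(lipid_classes))
    p_idx = np.flatnonzero(pmask)
    l_idx = np.flatnonzero(lmask)
    cols = ["residue_id", "monomer_id", "molecule_id"] + (
        ["protein_bead", "lipid_bead"] if level == "bead" else [])
    if len(p_idx) == 0 or len(l_idx) == 0:
        return pd.DataFrame({c: np.zeros(0, dtype=int) for c in cols})

    ppos = np.mod(frame.positions[p_idx], box)
    lpos = np.mod(frame.positions[l_idx], box)
    tree_p = cKDTree(ppos, boxsize=box)
    tree_l = cKDTree(lpos, boxsize=box)
    hits = tree_p.query_ball_tree(tree_l, cutoff)
    pi = np.repeat(np.arange(len(p_idx)), [len(h) for h in hits])
    li = np.concatenate([np.asarray(h, dtype=int) for h in hits]) if len(pi) \
        else np.zeros(0, dtype=int)
    if len(pi):
        # enforce the strict '<' convention on the candidate pairs
        d = min_image_distance(frame.positions[p_idx[pi]],
                               frame.positions[l_idx[li]], box)
        keep = d < cutoff
        pi, li = pi[keep], li[keep]

    pb, lb = p_idx[pi], l_idx[li]
    df = pd.DataFrame({
        "residue_id": topology.residue_id[pb],
        "monomer_id": topology.monomer_id[pb],
        "molecule_id": topology.molecule_id[lb],
    })
    if level == "bead":
        df["protein_bead"] = pb
        df["lipid_bead"] = lb
        return df.drop_duplicates(ignore_index=True)
    return df.drop_duplicates(ignore_index=True)


def contact_series(traj: Trajectory, topology: BeadTopology,
                   cutoff: float = DEFAULT_CUTOFF, lipid_classes=None,
                   level: str = "molecule") -> ContactSeries:
    """Detect contacts in every frame of a trajectory."""
    frames, chunks = [], []
    for i in range(traj.n_frames):
        df = find_contacts(traj.frame(i), topology, cutoff, lipid_classes, level)
        if len(df):
            frames.append(np.full(len(df), i, dtype=np.int32))
            chunks.append(df)
    if chunks:
        cat = pd.concat(chunks, ignore_index=True)
        frame_col = np.concatenate(frames)
    else:
        cat = find_contacts(traj.frame(0), topology, cutoff, lipid_classes, level).iloc[:0]
        frame_col = np.zeros(0, dtype=np.int32)
    lmask = topology.lipid_mask() if lipid_classes is None else np.isin(
        topology.molecule_class, list(lipid_classes))
    mol_class = {int(m): str(topology.molecule_class[topology.molecule_id == m][0])
                 for m in np.unique(topology.molecule_id[lmask])}
    return ContactSeries(
        frame=frame_col,
        residue_id=cat["residue_id"].to_numpy(dtype=np.int32),
        monomer_id=cat["monomer_id"].to_numpy(dtype=np.int32),
        molecule_id=cat["molecule_id"].to_numpy(dtype=np.int32),
        n_frames=traj.n_frames, dt=traj.dt, cutoff=cutoff, level=level,
        protein_bead=cat["protein_bead"].to_numpy(dtype=np.int32) if level == "bead" else None,
        lipid_bead=cat["lipid_bead"].to_numpy(dtype=np.int32) if level == "bead" else None,
        molecule_class=mol_class,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def moving_average(x: np.ndarray, window_frames: int) -> np.ndarray:
    """Centred moving average; the window shrinks at the two ends."""
    w = max(int(window_frames), 1)
    h = w // 2
    c = np.concatenate([[0.0], np.cumsum(np.asarray(x, dtype=float))])
    n = len(x)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def shell_counts_from_series(contacts: ContactSeries, lipid_class: str) -> np.ndarray:
    """Per-frame count of distinct molecules of a class in contact with the
    protein, recomputed from a stored contact series."""
    sub = contacts.restrict(lipid_class)
    counts = np.zeros(contacts.n_frames, dtype=int)
    if len(sub):
        df = pd.DataFrame({"frame": sub.frame, "mol": sub.molecule_id})
        per = df.drop_duplicates().groupby("frame").size()
        counts[per.index.to_numpy()] = per.to_numpy()
    return counts


def shell_count_series(trajs, topology: BeadTopology, lipid_class: str,
                       cutoff: float = DEFAULT_CUTOFF, window: float = 20.0,
                       contacts=None) -> ShellCountSeries:
    """First-shell molecule count of one lipid class vs time.

    ``trajs`` may be a single :class:`Trajectory` or a list of repeat
    trajectories; with repeats the returned series carries the across-repeat
    per-frame mean and standard deviation of the window-averaged counts.
    Precomputed :class:`ContactSeries` (same order) can be passed via
    ``contacts`` to skip re-detection.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if contacts is not None and not isinstance(contacts, (list, tuple)):
        contacts = [contacts]
    dt = trajs[0].dt
    if window < (dt or 0):
        raise ValueError("window must be >= dt")
    rows = []
    for k, traj in enumerate(trajs):
        cs = contacts[k] if contacts is not None else contact_series(
            traj, topology, cutoff, lipid_classes=[lipid_class])
        rows.append(shell_counts_from_series(cs, lipid_class))
    counts = np.array(rows)
    if counts.max(initial=0) == 0:
        import warnings

        warnings.warn(f"no {lipid_class} contacts found (class absent or "
                      "never in the shell)", stacklevel=2)
    wf = max(int(round(window / dt)) if dt else 1, 1)
    smoothed = np.array([moving_average(c, wf) for c in counts])
    return ShellCountSeries(
        times=trajs[0].times.copy(), counts=counts, smoothed=smoothed,
        mean=smoothed.mean(axis=0), sd=smoothed.std(axis=0, ddof=0),
        lipid_class=lipid_class, window_ns=window,
    )


@dataclass
class ContactFractionTable:
    """Per-residue lipid-class contact composition.

    ``counts``: DataFrame indexed by residue_id (pooled over monomer copies,
    per the reporting convention), one column per lipid class, entries =
    number of (frame, residue, molecule) contact rows. ``fractions``
    row-normalises; residues with zero contacts keep fraction 0 and are
    listed in ``uncontacted``.
    """

    counts: pd.DataFrame
    total_contacts: int

    @property
    def fractions(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        out = self.counts.div(tot.where(tot > 0, 1.0), axis=0)
        return out

    @property
    def uncontacted(self) -> np.ndarray:
        return self.counts.index[self.counts.sum(axis=1) == 0].to_numpy()


def contact_fractions(contacts: ContactSeries, topology: BeadTopology
                      ) -> ContactFractionTable:
    """Fraction of each residue's lipid contacts attributable to each class.

    Counting unit: one (frame, residue, lipid molecule) contact row. Counts
    are pooled over monomer copies before normalising.
    """
    if contacts.n_frames < 1:
        raise ValueError("contact series covers no frames")
    classes = sorted(set(contacts.molecule_class.values()))
    res_ids = np.unique(topology.residue_id[topology.protein_mask])
    table = pd.DataFrame(0, index=pd.Index(res_ids, name="residue_id"),
                         columns=classes, dtype=int)
    if len(contacts):
        cls_col = pd.Series(contacts.molecule_id).map(contacts.molecule_class)
        df = pd.DataFrame({"residue_id": contacts.residue_id, "cls": cls_col})
        grp = df.groupby(["residue_id", "cls"]).size().unstack(fill_value=0)
        table.loc[grp.index, grp.columns] += grp
    return ContactFractionTable(counts=table, total_contacts=int(table.values.sum()))


def enrichment_mask(table: ContactFractionTable, lipid_class: str,
                    threshold: float = 0.30) -> np.ndarray:
    """Residues where ``lipid_class`` accounts for strictly more than
    ``threshold`` of the contacts (the convention is strict '>': a residue
    at exactly the bulk fraction is not enriched). The natural threshold is
    the membrane's bulk fraction of the class (0.30 for cholesterol in the
    bundled compositions)."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must be in [0, 1)")
    frac = table.fractions[lipid_class]
    contacted = table.counts.sum(axis=1) > 0
    return table.counts.index[(frac > threshold) & contacted].to_numpy()
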