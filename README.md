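# lipidprint

Lipid–protein interaction fingerprinting for coarse-grained membrane
simulations.

Membrane proteins sit in a shell of lipids whose composition and dynamics —
their *lipid fingerprint* — shape folding, stability and function. Two kinds
of bound lipid matter: **annular** lipids at the protein surface, which
exchange rapidly with the bulk, and **non-annular** lipids wedged at subunit
or helix interfaces, which exchange slowly and often stabilise or regulate
the protein. `lipidprint` extracts both signatures from coarse-grained (CG)
trajectories, for computational membrane biophysicists who want the standard
fingerprint analyses as a tested, scriptable library rather than a pile of
one-off scripts.

## What it computes

Given a CG topology (GRO/PDB) and trajectory (XTC/TRR or a plain-text
format), with contacts defined by a 0.6 nm bead–bead cutoff under periodic
boundaries:

* **First-shell counts** — number of molecules of each lipid class within
  the cutoff of the protein versus time, window-averaged (default 20 ns),
  with mean ± SD across repeat runs.
* **Per-residue contact fractions and enrichment** — which lipid class each
  residue contacts, and the residues where a class exceeds its bulk fraction
  (e.g. cholesterol above 30%).
* **Binding-event kinetics** — for residue r, lipid class L, and molecule m
  with contact indicator c(r, m, t):

  - contact duration   `CD(r) = Σ_t [ ∃m : c(r,m,t) ] · dt`
  - maximum occupancy  `MO(r) = max_m (longest run of c(r,m,·)) · dt`
  - distinct partners  `N(r)  = #{ m : at least one event }`

  averaged across monomer copies and repeats, normalised by the maximum over
  residues. High CD with many partners ⇒ annular site; high MO with one or
  two partners ⇒ non-annular site — the package's classifier makes exactly
  this call.
* **Displacement maps, anchor-conditioned co-contacts, per-bead contact
  ratios** — where lipids slow down near the protein, which residues share
  a bound lipid with an anchor residue, and which cholesterol beads (the
  ROH hydroxyl versus sterol body) carry the interaction.
* **Density maps and spatial free energy** — time-averaged 2D densities
  (periodic Gaussian smoothing, σ = 3 bins) and the Boltzmann inversion
  `ΔG(x) = −k_B T ln ρ(x)/ρ_bulk` at 310 K, shifted so the sampled minimum
  is exactly 0.

A bundled synthetic membrane generator plants annular-regime and
non-annular-regime cholesterol sites with known on/off kinetics in a
diffusing two-leaflet bilayer around a static tetramer, so every metric is
validated against exact ground truth (see `docs/methods.md`).

## Worked example

```python
import lipidprint as lp

# synthetic demo: 30% cholesterol bilayer, planted fast sites at residues
# 355/358/362 (k_off = 0.1/ns) and a slow interfacial site at 660 (0.001/ns)
mspec = lp.MembraneSpec()
pspec = lp.ProteinSpec(planted_sites=lp.default_sites())
top, frame0 = lp.build_system(mspec, pspec, seed=7)
traj = lp.simulate(top, frame0, n_frames=9000, dt=0.1, seed=8,
                   mspec=mspec, pspec=pspec)

traj_eq  = lp.slice_equilibrated(traj, 100.0)          # drop first 100 ns
contacts = lp.contact_series(traj_eq, top, cutoff=0.6)
events   = lp.extract_events(contacts)
profile  = lp.kinetic_profile(events, contacts, "Chol", topology=top)

print("top contact duration:", lp.rank_residues(profile, "contact_duration", 3))
print("top max occupancy:  ", lp.rank_residues(profile, "max_occupancy", 3))
print(profile.table.loc[[355, 660],
      ["contact_duration", "max_occupancy", "n_distinct_partners"]].round(2))
print("classification:", lp.classify_sites(profile))
```

Output (seed 7):

```
top contact duration: [362 355 358]
top max occupancy:   [660 362 355]
            contact_duration  max_occupancy  n_distinct_partners
residue_id
355                   537.88          46.95                 21.0
660                   199.90         104.28                  0.5
classification: {660: 'non_annular', 657: 'non_annular', 362: 'annular', 355: 'annular',
                 358: 'annular', 419: 'annular', 431: 'annular', 444: 'annular', 456: 'annular'}
```

Read it as follows. Residue 355 (a fast-exchange surface site) is in contact
with cholesterol for 538 of the 800 analysed ns, but its longest
single-molecule contact is only ~47 ns and ~21 different cholesterol
molecules per monomer visit it — rapid exchange with the bulk, the annular
signature. Residue 660 (the buried interfacial site, engaged on one of the
four monomers) is bound for essentially the whole run on the engaged copy
(200 ns monomer-averaged contact duration = 800 ns on one of four copies),
holding the same one or two cholesterol molecules in contacts lasting
hundreds of ns — slow exchange, the non-annular signature. Its interfacial
partner residue 657 and other membrane-exposed surface residues with many
short-lived partners are classified alongside the planted anchors.

The same pipeline runs from a shell:

```
lipidprint simulate --out demo/ --seed 7
lipidprint contacts --traj demo/traj.txt --top demo/system.gro --out demo/contacts.tsv
lipidprint kinetics --contacts demo/contacts.tsv --lipid-class Chol --out demo/profile.tsv
lipidprint run --config run.yaml        # full fingerprint + report.json
```

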