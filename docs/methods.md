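# Methods

`lipidprint` quantifies how individual lipid species interact with a
membrane protein in coarse-grained (CG) simulations, and validates every
metric end-to-end against a bundled synthetic membrane whose binding
kinetics are planted and therefore exactly known. This note documents the
models, the defaults and the reasoning behind the open design choices.

## Contact model

A *contact* exists in a frame when any CG bead of a protein residue and any
bead of a lipid molecule lie within a cutoff under the rectangular
minimum-image convention. The default cutoff is 0.6 nm, the value most
widely used for CG lipid fingerprinting; the boundary is **strict** (`<`
0.6 nm). The literature phrase "within 0.6 nm" does not fix the boundary
convention; for continuous coordinates the choice is measure-zero, and the
strict form keeps the complementary "at or beyond" region closed. The cutoff
and convention are configurable.

The counting unit is the (frame, residue, molecule) triple: several bead
pairs between one residue and one lipid in one frame count once. This keeps
contact fractions independent of how many beads a lipid model uses and makes
"contact duration = total contact time" exact. A bead-resolved mode exists
for per-bead contact ratios.

Neighbour search uses a periodic k-d tree (`scipy.spatial.cKDTree` with
`boxsize`), with candidate pairs re-checked against the strict cutoff.
Equality with a brute-force all-pairs reference is asserted in the test
suite on hundreds of random systems. Rectangular boxes only; triclinic
inputs are rejected with a clear error.

## Kinetic metrics

From the sparse contact series the package derives, per (monomer, residue)
copy and per lipid class:

* **contact duration** — total time the residue touches *at least one*
  molecule of the class (frame union). The union definition keeps
  `max_occupancy <= contact_duration <= trajectory length` meaningful; a
  per-molecule-sum variant (`duration_mode="sum"`) is provided because the
  field's wording ("total contact time with a lipid type") admits both
  readings.
* **maximum occupancy** — the longest single-molecule continuous contact,
  from maximal runs of consecutive contact frames (inclusive: an n-frame run
  lasts n x dt). Runs separated by at most `gap_tolerance` non-contact
  frames can be merged; the default is 0 (no smoothing), since interruption
  smoothing is not part of the standard criteria.
* **distinct partners** — the number of different molecule ids with at least
  one binding event.

Metrics are averaged over monomer copies (and repeat runs, each (repeat,
monomer) being one copy) *at reporting time*, never at detection time, and
normalised per metric by the maximum over residues. Rank ties break by
ascending residue id.

High contact duration carried by many partners is the signature of an
*annular* site (fast exchange with bulk lipid); high maximum occupancy
carried by one or two partners marks a *non-annular* site at a subunit or
helix interface. The pipeline's classifier makes this heuristic explicit:
residues in the top-k of maximum occupancy with <= 3 partners are called
non-annular; residues in the top-k of contact duration with >= 20 partners
are called annular; everything else is left unclassified. The thresholds
are distilled from the qualitative contrast between interfacial sites that
see one or two molecules per 10 us and surface sites that see over a
hundred, rescaled to the synthetic run length; they are exposed in the run
configuration and should be treated as heuristics, not biology.

Displacement maps bin, at each molecule's lateral position, the minimum-image
step length per unit time of class molecules near the protein. The default
uses the 3D step length (a lateral-only mode exists; for planar CG membranes
the two differ only for flip-flopping or site-bound molecules). Bins without
samples are reported as missing, never as zero.

## Density maps and spatial free energy

Lateral (or optionally 3D) number densities are per-frame histograms of a
bead selection, wrapped into the primary cell, time-averaged, then smoothed
with a periodic Gaussian kernel (default sigma = 3 bins, bin width 0.1 nm;
smoothing conserves total mass). The spatial free energy is the Boltzmann
inversion

    dG(x) = -k_B T ln(rho(x) / rho_ref),  k_B = 0.0083144621 kJ/(mol K),

reported on a relative scale with the minimum over sampled bins fixed at
exactly 0. Default temperature 310 K (so k_B T = 2.577 kJ/mol). Bins with
fewer than 10 raw samples are masked, never zero-filled. The reference
density is either the global mean over sampled bins (making the map
invariant to a uniform rescaling of the lipid count) or the mean in a bulk
annulus at least 1.5 nm outside the protein's footprint. The free-energy
grid is 2D-lateral by default — sufficient for locating binding regions —
with the 3D grid available through `axes="xyz"`.

Because the synthetic lipids are an ideal gas, the inversion is exact there:
positions rejection-sampled under a known 2.5 kJ/mol square well recover the
depth within 0.25 kJ/mol at 1e5 samples (asserted in the suite).

## The synthetic membrane

The generator is the package's ground-truth instrument, not a physics
engine. It emulates the features the analyses measure and nothing else:

* **Geometry.** 15 x 15 x 10 nm box; membrane midplane at z = 5 nm; leaflet
  head planes at z = 3.6 and 6.4 nm. A static protein scaffold of 4 monomers
  x 32 one-bead residues sits on a cylinder of radius 2.55 nm (8 rings,
  0.8 nm spacing, staggered), with a hard cylindrical footprint of radius
  2.75 nm that free lipids cannot enter. Protein residue ids span 322-699.
* **Lipids.** Single-bead molecules at 300 per leaflet (~0.67 nm^2 per
  lipid, the standard CG packing) performing independent 2D Gaussian walks,
  per-axis step sd sqrt(2 D dt) with D = 0.1 nm^2/ns (the commonly observed
  CG lipid diffusivity), periodic wrapping and hard rejection of moves into
  the footprint. Lipid-lipid excluded volume is deliberately ignored so that
  density-based free energies have an exact ideal-gas reference.
  Cholesterol flip-flops between leaflets as a Poisson process (default
  0.001 /ns — about one flip per molecule per microsecond, fast enough to
  populate both leaflets in a desk-scale run). An optional 8-bead rigid-rod
  cholesterol (hydroxyl bead plus sterol/tail beads at 0.22 nm spacing,
  oriented along the normal) exists for the per-bead contact-ratio analysis
  and is off elsewhere for speed.
* **Compositions.** The bundled symmetric membrane is 70% PC / 30%
  cholesterol in both leaflets. The six-component asymmetric membrane keeps
  cholesterol at exactly 30% per leaflet and fills the remaining 70% with
  the phospholipids in their published proportions, rescaled per leaflet so
  fractions sum to one (the printed percentages do not); PS and PIP2 occur
  only in the inner leaflet. Class counts are exact by largest-remainder
  rounding.
* **Binding sites.** Markov two-state sites, not energetic ones: a vacant
  site captures a free lipid of its selective class whose lateral distance
  to the site centre is below the capture radius, with probability
  `k_on_prob` per frame (single occupancy; lowest molecule id wins a tie);
  the bound lipid is pinned at the centre plus N(0, 0.05 nm) jitter and
  unbinds with probability 1 - exp(-k_off dt) per frame, re-entering the
  bulk 0.3 nm outside the capture radius, where it competes with newcomers
  on roughly equal terms. Kinetic rather than energetic binding is
  sufficient to produce the fast/slow-exchange phenomenology with exactly
  controllable ground truth (exponential dwell times of mean 1/k_off).
* **Site placement.** Anchor residues are moved off the lattice into
  pockets such that *only* a site-bound lipid can contact them: anchors of
  leaflet-plane sites are recessed 0.65 nm inside the footprint; anchors of
  mid-membrane sites are shielded by the 1.4 nm normal offset from the head
  planes. Any other lattice bead within 0.85 nm of a site centre is pushed
  radially inward (the site sits in a carved cavity). This isolation is
  what makes contact-derived event statistics equal the planted kinetics —
  a passing bulk lipid can never touch an anchor.
* **Default sites.** Fast-exchange sites (k_off = 0.1 /ns, capture 0.7 nm)
  at a cluster of three residues (355, 358, 362) of every monomer on the
  outer head plane: with ~60% diffusion-limited occupancy these 12 sites
  accumulate well over 500 binding events in the default 9000-frame run. A
  slow-exchange site (k_off = 0.001 /ns, mean dwell 1000 ns — longer than
  the run) at residue 660 of one monomer, at mid-membrane depth, spanning
  the interface to the adjacent monomer through partner residue 657 placed
  0.5 nm from the centre; buried interfacial sites are not occupied in
  every chain copy, and planting the site on a single monomer reproduces
  that.
* **Scale.** The default run is 9000 frames at dt = 0.1 ns (0.9 us) — the
  production frame spacing of CG membrane studies at roughly one tenth of a
  typical single-replicate length. All statistics are computed after
  discarding the first 100 ns (the same one-ninth convention as discarding
  1 us of a 9 us analysed window).

**What the generator does not emulate** — and hence what passing tests do
not show about real membranes: lipid-lipid interactions and packing, 
membrane undulations and thickness fluctuations, protein conformational
dynamics, energetic (rather than kinetic) binding, multi-site cooperative
effects, solvent and electrostatics. The generator demonstrates that the
*analyses* are correct, not that any particular membrane behaves this way.

## The ground-truth oracle

Mean dwell times are analytic (1/k_off). Expected occupancy, event counts
and distinct-partner counts come from an independent stochastic replay of
the planted two-state chains: walkers of the selective class at the correct
surface density diffuse in an annulus of equal free area (hard inner
footprint, reflecting outer rim), and all sites bind/release them with the
same rules as the simulator. Identities are physical, so repeat visits are
counted correctly. A well-mixed (Poisson-arrival) chain was rejected during
design: lipid capture at a protein site is diffusion-limited and dominated
by repeat visits of nearby molecules, and the well-mixed model overestimates
partner turnover about threefold. The oracle shares no code with the
simulator beyond elementary numpy.

## Numerical choices and degenerate inputs

* Times in ns, lengths in nm throughout; file readers convert from the
  Å/ps conventions of the underlying formats.
* Frame spacing must be uniform within 1e-6 ns; a single-frame trajectory is
  valid but kinetic operations refuse it.
* Moving averages use a centred window that shrinks at the series ends (no
  padding).
* Residues with no contacts appear in tables with zero metrics and are
  flagged, not dropped; empty profiles warn rather than fail.
* Lenient parsing is the default (unknown residue names warn and are
  classified inert; corrupt trailing text frames truncate with a warning);
  `strict=True` turns both into errors.
* The pipeline is deterministic: identical configuration and seed give
  byte-identical output tables.

## Known limitations

* The free-energy module approximates, not reproduces, dedicated
  density-to-energy tools: the smoothing kernel and normalisation of such
  tools are not replicated, so absolute values should be read as relative
  site contrasts.
* Distinct-partner expectations from the oracle are approximations with a
  finite-geometry error of order 10%; tests therefore compare against its
  replicate bands, not point values.
* Only rectangular boxes and static (position-restrained) proteins are
  supported.
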