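# Methods

This note documents the models behind `gagnet`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Hydrogen-bond identification and energy

A candidate bond is a (donor D, hydrogen H, acceptor A) triple with D
and A in {O, N}.  Donors are heavy atoms with a statically assigned
covalent hydrogen (nearest O/N within 1.2 Å of the topology template);
acceptors are member atoms of acceptor-capable site classes.  Nitrogen
is admitted on both sides with the same thresholds as oxygen because the
N-acetyl amide is one of the bonding groups of these polymers.  The
criteria are

1. d(H, A) < 2.6 Å,
2. d(D, A) < 2.8 Å,
3. E > 6.25 kJ/mol, applied to the fully scaled energy

with E = 25·(2.6 − max(d_HA, 2.1))/0.5 · s_DHA · s_HAX kJ/mol.  The
constants (25 kJ/mol optimum, 2.1 Å saturation, 2.6 Å zero, 0.5 Å
normalisation, threshold 25 % of optimum) are the package defaults and
are configurable as a unit through `HBondCriteria`.

**Angular scale factors.** Only the 0–1 range and the two angles
(D–H–A; H–A–X) are fixed by the model; the functional form is a choice.
We use piecewise-linear ramps — 0 below `ramp_start`, 1 above
`ramp_end`, linear between — with defaults (100°, 165°) for D–H–A and
(85°, 165°) for H–A–X.  Ramps are monotone, bounded and cheap; both are
configurable.  When the acceptor has several covalent heavy neighbours,
X is the one giving the maximal scale factor (the most permissive
reading; `x_policy="first"` selects by atom order instead).

**Deduplication.** One hydrogen may report at most one acceptor per
frame (the highest-energy candidate); this prevents double-counting in
lifetime statistics.  `dedup="all"` disables it.

**A consistency note.** With an ~0.96 Å covalent O–H bond, criteria
(2) and (3) jointly make H···A distances above ≈ 2.2 Å undetectable at
*any* D–H–A angle: bending the bond enough to keep D–A under 2.8 Å
drives the angular scale factor, and with it the energy, under the
threshold.  Real bond-length distributions extend to 2.5 Å; under these
criteria that long tail is simply below detection.  The generator
plants the full published length law, so a (documented) fraction of
planted ON frames is correctly left undetected; validation suites that
isolate *kinetics* plant sites with bounds [1.55, 1.95] Å, inside the
criteria's own envelope, so lifetime estimates are not confounded by
length selectivity.

## Topology and site classes

Repeat units are templated pseudo-atom layouts, not sugar
stereochemistry: each of the 11 site classes per species contributes one
functional group per unit (hydroxyl C–O–H, amide C–N–H, carboxylate
C(O,O), carbonyl C=O, ether C–O, sulfate S(O,O,O)) with chemically
sensible covalent distances, spread 4.5 Å apart along the chain axis so
that no hydrogen bond exists at rest.  The class count 11 is forced by
the 66 = 11·12/2 intramolecular and 121 = 11² intermolecular pair-space
sizes; the default labels (COO, NH, OAC, SO4, hydroxyls O2H/O3H/O4H/O6H,
ring/glycosidic O5/O7/O8/O10) name the groups these polymers actually
bond through, and the whole set is user-overridable.  Covalent topology
is inferred once from template distances (heavy–heavy < 1.8 Å,
X–H < 1.2 Å).

The default system is one long HA chain (10 repeat units) and three
short CS chains (4 units each, stacked 14 Å apart) — a per-system stand
-in for the dense-network regime with its roughly 2.5:1 HA:CS ratio;
chain counts, not molarities, are the knob.

## Synthetic trajectories

Each planted site binds one donor group to one acceptor group (groups
are never shared between sites).  Its on/off state follows a two-state
Markov chain discretised at the frame spacing: per-frame probabilities
1 − exp(−k·Δt) with k_on temperature-independent and
k_off(T) = k_off,ref · exp[(E_a/R)(1/T_ref − 1/T)].  Defaults:
k_on = 2/ns, k_off,ref = 1/ns at T_ref = 310 K, E_a = 50 kJ/mol —
a plausible hydrogen-bond barrier giving a factor ≈ 1.9 in off-rate per
10 K, so that the 300/310/320 K scan produces clearly ordered bond
stabilities; with a 1 ns mean lifetime most bonds are short-lived
(≈ 86 % last at most 2 ns), matching the qualitative picture such
simulations report.  The published record fixes no rates; these are the
package's chosen study conditions, not fitted values.

ON frames draw d(H, A) from the site's truncated normal (default
1.77 ± 0.28 Å, hard bounds [1.5, 2.5] Å — the published mean length law)
and place the acceptor's whole functional group rigidly: D–H–A at 172°
or bent just enough to keep D–A ≤ 2.78 Å, H–A–X at 150°, and a per-site
roll angle about the A→X axis chosen once to keep the rest of the group
away from the donor (so e.g. a hydroxyl acceptor's own hydrogen cannot
fake a back-donated bond).  OFF frames park the acceptor 4.5 Å from H.
All other atoms get Gaussian jitter (σ = 0.05 Å).  The per-frame
ground truth is stored alongside the coordinates and is used only by
tests.

**What the generator does not emulate:** solvent and ions, forces and
thermostats, chain diffusion and conformational change, correlated
bond dynamics, equilibration transients.  Passing tests therefore
certify the *analysis* (detection, tracking, aggregation, graph
statistics) against known ground truth — they say nothing about force
fields or real GAG physics beyond the planted statistical structure.

Frame spacing defaults to 10 ps with 1000 frames (10 ns), the resolution
at which lifetime statistics of ns-scale bonds are cleanly measurable;
the femtosecond integration step of real MD is irrelevant to the
analysis.

## Lifetimes and distributions

Bond identity across frames is the (donor atom, acceptor atom) pair,
ignoring which hydrogen mediates (equivalent hydrogens may swap).
`gap_tolerance` (default 0) controls whether short absences split an
event; with merging, the duration covers the event's full frame span.
Events touching the first or last frame are flagged censored and
included by default — lifetime-recovery analyses exclude them to avoid
truncation bias.  Durations are frames × spacing; the half-frame
discretisation bias is ≤ Δt/2 and is negligible once dwells span tens
of frames.

Length distributions are fitted with a least-squares Gaussian through
the histogram bin heights (bin width 0.05 Å; amplitude, mean, sd free),
reporting the R² of the curve — a figure-style fit, deliberately not a
maximum-likelihood fit to the samples.  Fits are skipped (with a
warning) under 30 observations or for degenerate single-bin histograms.

## Pair maps

Intramolecular maps fold donor/acceptor orientation into unordered
class pairs (66 cells); the intermolecular map keeps (HA class, CS
class) orientation (121 cells), oriented by the donor's species.  Cells
display log10 of the summed energy (mean energy is also exported); the
base-10 logarithm of the total is the customary display scale for such
maps.  Counts and energies are conserved exactly: cell totals sum to
the observation totals.

## Class graphs and characteristic path length

Length edges average the geometric distance over all member-atom pairs
and frames (a cheaper class-centroid mode exists, non-default; length
analyses may also subsample frames via `frame_stride`).  Energy and
number edges exist only where bonds occurred: mean |energy| and mean
contacts per frame respectively.  The HA–CS graph is bipartite over
both molecules' classes with intermolecular edges only, and its mean
runs over HA-class × CS-class pairs.

For length graphs the optimal path minimises total weight (Dijkstra;
ties broken by fewer hops, then lexicographic node sequence).  For
energy and number graphs the convention "negate and minimise" means
*maximising* the total weight, which is only bounded over simple paths;
the maximum-weight simple path is found exactly by dynamic programming
over node subsets of the connected component (states (subset, last
node)).  The component limit is 22 nodes — exact but exponential, so
dense 22-node components take minutes; a documented branch-and-bound
fallback (`method="branch-and-bound"`) covers larger graphs.  On dense
equal-weight graphs the optimum is near-Hamiltonian, which is why
number-graph characteristic path lengths approach n − 1 as occupancy
grows.

Hop attribution: a pair's selected path with zero intermediate nodes
counts 1, with one intermediate node 2, and so on; the characteristic
path length is the mean over all pairs with a path.  Disconnected pairs
are excluded from the mean and reported separately (the record is
silent on their handling; exclusion keeps the value within [1, n − 1]).
The value is invariant under uniform scaling of length weights, since
only path selection matters.

Energy-distance graphs are fully implemented and tested on synthetic
data; no reference values exist for them, so they carry no external
comparison target.

## Numerical and I/O choices

- Units: Å and kJ/mol throughout; the kcal↔kJ factor 4.184 is a single
  named constant.
- Detection uses a per-frame k-d tree over acceptors; results are
  identical to exhaustive all-pairs search (tested).
- Multi-model PDB I/O goes through biotite; atoms are matched by
  (chain, residue, atom name) so file order is irrelevant; coordinate
  round trips are exact to the PDB fixed-point (10⁻³ Å).  A plain-text
  frame-stream format is provided for compact exchange.
- All table writers use fixed float formatting and sorted keys, so a
  fixed seed reproduces byte-identical output bundles.
- Validation suites use reduced problem sizes chosen for statistical
  sufficiency: e.g. lifetime recovery uses 44 sites × 5000 frames
  (≈ 2000 completed events, sampling error ≈ 2 %), the temperature scan
  20 sites × 2500 frames per temperature.

## Known limitations

- Pseudo-atom geometry cannot probe stereochemistry-dependent effects
  (specific neighbour preferences, chain stiffness).
- The exact 11-class labelling of real HA/CS maps is configuration, not
  a structural claim; users with real topologies should supply their own
  class selectors.
- The exact scale-factor ramps of the original detection software are
  unpublished; results near the angular cutoffs depend on the chosen
  ramp bounds.
- Whether the bipartite 22-node construction or an 11×11 pairing was
  used for published intermolecular number distances is unknown; the
  bipartite reading is the default, both are computable.
- Maximum-weight simple path search is exponential by nature; dense
  components above ~18 nodes are slow in the exact mode.
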