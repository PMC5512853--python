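# Methods

## Scope and model

`ppiface` quantifies how a hetero-dimer's binding pseudo-energy decomposes
into van der Waals, hydrogen-bond and electrostatic contributions, and how
each contribution scales with interface size across functional groups of
complexes. It is an *interface analysis* model, not a free-energy method:
the per-contact scores are force-field-style pseudo-energies whose absolute
scale cancels in every headline statistic (percentages, r², class ratios),
which are the quantities the package is built to report.

Assumptions baked into the model:

- Two protein chains; waters and all other HETATM ligands are removed
  before analysis (no water-mediated or ligand-mediated contacts).
- Heavy-atom chemistry. X-ray structures mostly lack hydrogens, so
  hydrogen bonds are detected between donor and acceptor N/O heavy atoms
  with no angular term by default (an optional donor-angle filter is out of
  scope for the current release; the cutoff geometry alone is used).
- Formal (not partial) charges: Asp/Glu carboxylates −0.5 per oxygen,
  Lys NZ +1, Arg NH1/NH2 +0.5 each. Histidine is neutral by default and
  chain termini are uncharged by default, both switchable
  (`assign_atom_classes(charge_his=..., charge_termini=...)`): crystal pH
  and terminal order are rarely known, and the defaults avoid inventing
  charge where the data are silent.
- Salt bridges deliberately score in *both* the H-bond and electrostatic
  channels when they satisfy both geometries. The channels answer different
  questions (directional contact vs charge attraction); removing the
  overlap is a documented configuration decision, not a default.

## Accessible surface area and the interface

ASA uses the Shrake–Rupley construction: each atom's sphere is inflated by
the probe radius (1.4 Å) and sampled with a deterministic Fibonacci
(golden-spiral) lattice of 960 points; points falling inside any
neighbouring inflated sphere are occluded. There is no RNG anywhere in the
SASA path, so results are bit-reproducible at fixed settings. 960 points
give <1% error against the closed-form isolated sphere and <2% per-atom
deviation from an independent reference implementation on test fixtures;
relative error grows for nearly buried atoms (a few Å² of ASA), which is
immaterial because such atoms contribute negligibly to ΔASA.

A residue is **interface** when its ASA drops by more than 0.1 Å² upon
complexation. The threshold is deliberately near zero — the definition is
"ASA changes on binding" — while suppressing lattice discretization noise;
it is a config knob (`delta_asa_threshold`) because reasonable
implementations have used anything from 0 to 1 Å². Non-interface residues
with free-chain relative exposure ≥ 5% of the residue-type theoretical
maximum (Tien-style values) are **surface**, the rest **core**. Interface
size pools both chains; interface area is half the summed ΔASA (each buried
Å² is counted once per partner).

## Contact detection and pseudo-energies

Channel cutoffs: 3.5 Å (H-bond), 6.0 Å (electrostatics), 8.0 Å (vdW).
Distance-based detection with per-channel cutoffs is standard practice; the
specific values follow common structural-biology usage and live in
`RunConfig` so they can be calibrated against reference complexes.

- H-bond energy: linear well `E(d) = E0 (1 − (d − d_opt)/(cutoff − d_opt))`
  clamped to `[E0, 0]`, `d_opt = 2.8 Å`, `E0 = −2 kcal/mol`. Simple,
  monotone, and bounded — adequate because only channel totals enter the
  statistics.
- Electrostatics: `E = 332.0637 q_i q_j / (ε(d) d)` with the
  distance-dependent dielectric `ε(d) = 4d`, i.e. `E ∝ 1/d²`, a common
  implicit-solvent screening choice. Repulsive terms are computed and kept
  in the records.
- vdW: 6-12 Lennard-Jones on all inter-chain heavy-atom pairs,
  `rmin_ij = r_i + r_j` (radii are Rmin/2-convention, AMBER-flavoured
  element defaults), `ε_ij = √(ε_i ε_j)`. Distances below `0.7 rmin` are
  evaluated at the clamp to keep clash energies finite. Note that
  heavy-atom donor–acceptor pairs at H-bond distance (≈2.9 Å) are inside
  the LJ repulsive wall — physically expected without explicit hydrogens;
  the attraction lives in the H-bond/electrostatic channels.

Pair search uses a k-d tree (`scipy.spatial.cKDTree`); a brute-force
O(n²) mode exists solely as an oracle and the test suite requires exact
(bitwise) agreement of records and energies on fixtures up to 2,000 atoms.

## Decomposition and the repulsion rule

Percentages are computed on magnitudes of *favourable* (negative) channel
totals: `pct_k = max(0, −E_k) / Σ max(0, −E_j) × 100`. A complex whose net
electrostatic total is repulsive — like-charge pairs outweighing
opposite-charge pairs at the interface — is flagged and contributes 0% for
that channel while the signed total is preserved in the output row. The
rule is applied per complex on the net channel total (not per contact):
the flagged entity is the complex. The same `max(0, −E)` form incidentally
covers the rare net-repulsive vdW total of a clash-dominated toy system,
keeping percentages non-negative and summing to 100 whenever any favourable
energy exists; a complex with none (e.g. non-contacting chains) carries
undefined percentages as an explicit sentinel, never NaN arithmetic.

## Group statistics

Each fit is a single-predictor OLS of one channel's favourable magnitude on
interface size (statsmodels), reporting r², the F statistic and its p-value
on (1, n−2) degrees of freedom — the per-component layout in which such
surveys tabulate one r² per channel per group. A joint multivariate fit of
size on all three channels is available (`regress_multivariate`) for
completeness. Regression responses default to the same caveat handling as
the percentages (net-repulsive → 0; `caveat="exclude"` drops those
complexes instead, `caveat="signed"` uses raw totals). Summaries report
arithmetic means and population SD (ddof=0; sample SD available via
`ddof=1`) of the percentage columns per group, and the class-B/class-A
ratio of mean electrostatic percentages.

Fits require ≥ 3 complexes and a non-degenerate size distribution; smaller
groups are skipped in batch reports and raise in direct calls.

## Synthetic data: what it emulates, what it does not

**Toy dimers** place residues on a 13 Å pitch — wider than every detection
cutoff plus side-chain excursions — so each planted interaction is
geometrically isolated and detection counts are exactly predictable:
donor–acceptor pairs at 2.8–3.2 Å, salt bridges with Lys NZ 3.6–4.9 Å from
the Asp carboxylate (each bridge yields exactly 2 charged-pair records and,
being beyond 3.5 Å, no H-bond record), filler interface residues packed
near the LJ minimum, non-interface residues ≥ 12 Å (in practice ≥ 17 Å)
from the partner chain. Residue identities (Leu vs Ser fillers) force the
polarity class. The geometry is idealised: no realistic backbone torsions,
no dense packing, no crystal-contact artefacts. Passing tests therefore
demonstrate correctness of the *measurement machinery* (detection, ASA
bookkeeping, classification), not that real interfaces look like the toys —
in particular the toys' percentage decompositions are H-bond/electrostatic
heavy because their vdW contact density is far below a real interface's.

**Energy tables** emulate the statistical structure of a curated 278-complex
hetero-dimer survey: the default functional composition is 40 enzymes,
144 regulators, 24 biological assemblies, 18 immune complexes, 25 enzyme
inhibitors and 27 regulator inhibitors (obligatory 208 / non-obligatory 52 /
immune 18). Interface sizes are integer-uniform on [20, 120] residues —
spanning small inhibitor interfaces to large obligatory assemblies; neither
the composition source nor typical size tables pin this range, so it is a
fixed package choice. Channel magnitudes are linear in size,
`|E| = slope·size + intercept + N(0, σ²)`, with defaults (slope 2.0 /
0.4 / 0.25, intercept 30 / 8 / 5 kcal/mol for vdW / H-bond / elec) chosen
so vdW carries roughly three quarters of the favourable energy, and σ
derivable from a requested population R² via
`R² = slope²·Var(size) / (slope²·Var(size) + σ²)` (the closed form the
recovery tests check against). Percentage-target mode instead draws
`pct_vdw` and `pct_hbond` from the requested normal laws (clipped to the
simplex, which biases means by ≲0.3 at the default settings) and assigns
the remainder to electrostatics. Intercepts keep magnitudes far from zero
so the favourable-magnitude clipping is negligible (<0.2% of rows at
defaults).

## Numerical choices and degenerate inputs

- Altloc resolution: highest occupancy, ties to altloc 'A'.
- Malformed ATOM records fail fast with the line number; unknown
  residue/atom names degrade gracefully to element-default radii, zero
  charge, no H-bond capability, with a warning.
- Coincident atoms warn and proceed (SASA treats them as fully mutually
  occluding; LJ clash clamp keeps energies finite).
- Non-contacting chains are a valid empty-interface result, not an error;
  polarity is then an explicit `None` (unclassifiable).
- Tie in polarity fractions → class B, since class A is defined by a
  strict "more non-polar than surface".
- All percentages are reported on [0, 100] and checked to sum to 100 ± 1e-6
  when defined.

## Problem sizes used in tests and the acceptance script

Planted-recovery runs use 50 toy dimers of 8–15 residues per chain;
oracle-equivalence fixtures stay ≤ 2,000 atoms; statistical recovery uses
200 survey-sized (278-row) tables for the regression check and 20 replicate
tables for percentage/ratio recovery. These sizes give sub-minute runtimes
while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- No π-stacking, cation-π or disulfide channels; no explicit-hydrogen
  placement; no polarizable or Poisson–Boltzmann electrostatics.
- Pseudo-energies are not calibrated free energies; only relative and
  percentage statements are meaningful.
- Single-model PDB input; mmCIF assemblies, NMR ensembles and symmetry
  mates are out of scope.
- The ΔASA interface definition counts any burial above 0.1 Å²; studies
  using residue-contact definitions will report somewhat different
  interface sizes for the same complex.
- Surface composition for the polarity class is computed on the unbound
  chains (pooled); computing it on the bound state is a one-line config
  change but alters borderline class assignments.
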