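# Methods

## Scope and model

`cypscreen` triages small molecules for CYP2D6 inhibition potential from
static docked poses. It does not score binding free energies, run dynamics,
or predict sites of metabolism; it asks two geometric questions of each
pose — *is the ligand parked over the reactive oxy-heme with a group that is
not a normal oxidation target?* and *if not, does it occlude the substrate
channel while gripping the anchoring carboxylates?* — and combines the
answers with 2D drug-likeness and a substructure alert for mechanism-based
inhibition (MBI).

## Descriptors (compound_library)

All descriptors are 2D (topological) and deterministic:

| descriptor | method | units |
|---|---|---|
| mw | sum of atomic masses incl. implicit H | g/mol |
| hbd | count of O–H plus N–H hydrogens on the neutral input form | count |
| hba | N + O atoms, excluding amide N, pyrrole-type aromatic N, nitro O | count |
| logP | Crippen atom-contribution scheme | – |
| logS | ESOL regression: 0.16 − 0.63·logP − 0.0062·MW + 0.066·rotB − 0.74·AP (AP = aromatic heavy-atom fraction) | – |
| psa | topological PSA (Ertl contributions) | Å² |
| rotB | non-ring single bonds between non-terminal heavy atoms, amide C–N excluded | count |

The reference study computed its table with a proprietary 3D package, so
exact agreement is expected only for mw and hbd (toolkit-independent
quantities); logP/logS/PSA/HbA/rotB differ compound-by-compound in the way
any two descriptor engines do. Display rounding: mw to the nearest integer;
internal values keep full precision.

Protonation at pH 7.4 is a rule list, not a pKa model: aliphatic amines are
treated as protonated (cations), carboxylic acids as deprotonated (anions),
phenols as neutral. The rules feed the interaction typing only; donor/
acceptor *counts* are taken on the neutral input form, which reproduces the
published HbD for the compounds used in the worked examples.

## CNS drug-likeness filter (cns_filter)

The primary guideline set (shipped as `pajouhesh`) uses "preferred (hard)"
bounds — MW ≤360 (500), HbD ≤0.5 (3.5), logP ≤3 (5), PSA 40–90 (120) — and
is evaluated with inclusive bounds. A value above a preferred bound but
within the hard bound is a soft violation: reported, never fatal (the
screen retained compounds such as naringenin with PSA above the preferred
range, so preferred bounds cannot be fatal). A value below the PSA floor or
above a hard bound is a hard violation; it is *rescued* when it falls
inside the corresponding range of a rescue guideline (defaults: Ghose,
Wager). The verdict counts unrescued hard violations: 0 → pass,
1 → pass_flagged, ≥2 → fail.

Design choices made where the design was genuinely open:

* **logS is inert by default.** The shipped Ghose logS range (−0.4 … 0.5)
  would reject nearly every lipophilic CNS compound in the library, so it
  is kept verbatim but excluded from evaluation unless requested
  (`--include-logs`).
* **The ≤1-violation retention policy** is the only reading consistent with
  a screen that keeps one-violation compounds while highlighting them.
* **Lipinski CNS/non-CNS columns** ship as named guideline sets but do not
  participate in rescue by default (configurable).

## Receptor preparation (receptor_prep)

PDB input is read with gemmi; alternate locations resolve to highest
occupancy; waters and all heteroatoms except the heme are stripped; exactly
one chain is kept. The porphyrin plane is the least-squares plane of the
four pyrrole nitrogens (SVD); the model rejects hemes whose nitrogens
deviate > 0.5 Å from a common plane.

**Compound I.** The reactive state is modelled minimally: one axial oxygen
on the distal side of the plane, along the normal through Fe, at a
configurable |Fe–O| (default 1.97 Å). The distal side is the side opposite
the axial cysteine sulfur (when an SG lies within 3.5 Å of Fe), otherwise
the side with fewer protein atoms within 5 Å. No partial charges or bond
orders are assigned; downstream rules are purely geometric.

**Variant construction.** Point mutations (e.g. F120I, A122S for the \*53
allele) replace the side chain beyond CB with an idealized template placed
by internal coordinates (NeRF) in the local N–CA–CB frame, extended-rotamer
torsions, standard bond lengths/angles. Backbone and CB coordinates are
untouched. No force-field minimization is performed; instead a steric-clash
report lists non-bonded pairs closer than 2.2 Å. This is adequate because
every downstream classification uses distance cutoffs tolerant to ~0.3 Å;
it is *not* a claim of conformational equivalence to a minimized variant.

**No hydrogens.** Hydrogens are never added; all detection criteria are
heavy-atom based (see below). This removes the dependence on any particular
protonation/H-placement engine.

## Interaction profiling (interaction_profiler)

Cutoffs (ProfilerParams defaults; Å):

* proximal/distal boundary: ligand-atom–Fe **< 6.0** (strict; 6.0 itself is
  distal). This is the one threshold that is a modelling commitment of the
  triage itself.
* hydrogen bond: donor–acceptor ≤ 3.5 with an antecedent-angle proxy
  (antecedent–donor–acceptor ≥ 90°) in place of the explicit D–H…A angle;
* ionic: cation–anion ≤ 4.0;
* π-stacking: ring-centroid distance ≤ 5.5; inter-plane angle ≤ 30° =
  parallel, 60–90° = T-shaped, otherwise oblique;
* hydrophobic: apolar C–C ≤ 4.0, one contact per ligand-atom/residue pair
  (closest pair); porphyrin carbons count as apolar receptor carbons;
* heme coordination: ligand N/O/S or methylenedioxy-type carbon ≤ 4.0 from
  Fe.

These secondary cutoffs are standard literature values, fixed as defaults
and overridable; the interaction *types* matter to the classifier, the
exact numbers only set the sensitivity. Receptor atoms are typed by
residue/atom-name tables (carboxylate O anions, Lys/Arg cations, Ser/Thr/
Tyr/backbone donors and acceptors, Phe/Tyr/His/Trp rings, apolar carbons);
ligand atoms by molecular-graph rules under the pH-7.4 model. Poses read
from PDBQT carry no bond orders, so aromaticity and H counts degrade there;
SDF input is preferred.

Numerical notes: ties in the minimum-distance atom break to the lowest
atom index; contact lists are deduplicated per atom pair and type and
sorted deterministically; the profiler is exactly invariant (to 1e-9 Å)
under rigid motions applied to receptor and pose together.

## Inhibition classification (inhibition_classifier)

Criterion (i), proximal: proximity = proximal AND (a heme-coordination
contact exists OR the closest atom to Fe carries a label from the
"not normally metabolized" list {hydroxyl, ether/methylenedioxy, amine,
aliphatic carbon}). The list is a configurable operationalization — the
complementary labels (aromatic carbon, carbonyl) are canonical CYP
oxidation sites.

Criterion (ii), distal: proximity = distal AND min Fe distance ≤
`occlusion_max` AND an ionic or hydrogen-bond contact to an anchoring
residue (default Glu216/Asp301). `occlusion_max` defaults to **12 Å**,
spanning the CYP2D6 substrate access channel; no published bound exists for
"prevents other ligands from reaching the heme", so this is a declared
package choice, configurable.

Aggregation: top-10 calls per receptor structure; a compound×variant flag
is set under the default **any** consensus when ≥1 structure has ≥1
qualifying call (majority voting available). Proximal and distal flags are
independent; "none" means both unset.

## MBI alert (structural_alerts)

The default pattern is benzodioxole (`c1ccc2c(c1)OCO2`), matched as a
subgraph with element/aromaticity/ring semantics, symmetry-equivalent atom
sets collapsed. The alert is geometry-independent; because the moiety can
also act reversibly, severity is upgraded to "MBI-candidate" only when the
compound additionally has a proximal verdict placing a moiety-compatible
atom closest to the iron.

## Synthetic fixtures (synthetic_fixtures)

The toy pocket emulates only the features the geometric rules read: a
planar porphyrin (Fe, 4 N at 2.05 Å, 12 macrocycle carbons), an axial
cysteine 2.3 Å below the plane, and idealized residues whose functional
groups are placed at exact distances/directions from Fe. It does not
emulate a protein fold, side-chain flexibility, solvent, or realistic
docking score distributions — so passing tests demonstrate correctness of
the geometric rules and classification logic, not docking accuracy on real
structures.

Probe poses are embedded with a seeded distance-geometry method and rigidly
placed; only the anchor atom's position is guaranteed, the rest of the
molecule is oriented away from the target. Ground-truth labels come from
the placement parameters and plain distance arithmetic on the constructed
geometry, never from the profiler; placements that cannot guarantee their
label with a safety margin (0.25 Å around the 6 and 12 Å boundaries,
0.5 Å clearance margins around contact cutoffs) raise an error and, in the
batch generator, are resampled. The standard case battery cycles five
families — proximal coordinating amine, proximal alcohol, distal
carboxylate-anchored amine, remote non-binder, and a mid-range non-binder
inside the occlusion window without anchor contacts — with randomized
directions, distances (proximal 2.8–3.7 Å; anchors at 6.5–8.5 Å; remote
16–24 Å) and pocket composition.

Problem sizes: the shipped test suite and the acceptance script use toy
pockets of ≤ 60 atoms and batteries of 50–60 cases, which exercise every
rule family while keeping the whole suite in the seconds range.

## External docking adapter (pipeline)

Docking is an optional adapter, never a dependency. The rendered command
records seed 0, the twelve flexible side chains (F112, F120/I120, E211,
E215, E216, R221, Q244, R296, I297, D301, S304, F483) and a search box
grown by 8 Å per face from the reference-ligand bounding box (or the
engine's autobox with the same additive buffer). Engine defaults differ
between versions, so provenance should record the engine version string
rather than pinning one.

## Known limitations

* Heavy-atom interaction rules miss orientation effects that explicit
  hydrogens would resolve; the antecedent-angle proxy is permissive.
* The pH-7.4 rule list ignores unusual pKa shifts (e.g. aromatic amines,
  vinylogous acids).
* Descriptor values other than mw/hbd are engine-dependent
  reconstructions; the filter on *computed* descriptors can therefore flag
  a slightly different subset than the filter on the published rows.
* The fixture entry for cannabidiol keeps the standard structure
  (C21H30O2, 314.5 g/mol) although the published table prints 315 under a
  mislabeled heading; the difference is within rounding.
* PDBQT poses lack bond orders: aromatic-ring detection and donor counts
  are degraded for that format.
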