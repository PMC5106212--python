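# Methods

This note documents the models and procedures implemented in `pcdhkit`, the
parameters that matter, the synthetic-data conditions the test suite runs
under, and the design choices made where the problem left the design open.

## Scientific setting

Clustered protocadherins (Pcdhs) give vertebrate neurons individual surface
identities. Each isoform's ectodomain carries six extracellular cadherin (EC)
domains: an antiparallel *trans* recognition dimer forms through EC1–EC4
(two mutually supporting sub-interfaces, EC1:EC4 and EC2:EC3), while a
same-membrane *cis* dimer forms through the membrane-proximal EC6 (with a
possible EC5 contribution). The package provides the quantitative machinery
used to characterise this system: rigid-body comparison of ectodomain
fragments, buried-surface and contact analysis of the dimer interfaces,
ortholog-conservation logos that expose isoform-specific interface residues,
rule-based compatibility screening of interacting residue pairs in
hypothetical heterodimers, and sedimentation-equilibrium model fitting that
classifies fragments as monomer, dimer, tetramer (dimer-of-dimers), or
non-specific self-associators.

## Coordinate model (`structure`)

Coordinates are read and written through gemmi (PDB and mmCIF); the
in-memory model keeps author numbering and insertion codes exactly as read
(insertion codes order after their base number). Alternate locations are
resolved at load time to the highest-occupancy conformer, ties broken by
file order — a deterministic policy matching common practice. Hydrogens are
dropped; the crystal structures this package targets do not model them.

EC-domain boundaries are supplied by configuration, never inferred: there is
no robust coordinate-only boundary detector for cadherin tandems, and the
boundaries interact with every downstream operator. The shipped
`domain_boundaries.csv` covers the thirteen relevant public entries with
intervals that follow the ~100-residue EC periodicity anchored on residue
numbers known for these structures; the file is explicitly marked
approximate and is meant to be edited against the actual depositions, which
the library never downloads itself (`scripts/fetch_depositions.py` populates
a local cache).

Calcium stoichiometry: cadherin EC–EC junctions chelate three Ca²⁺ each.
`count_linker_calcium` assigns a calcium ion (hetero atom, element CA) to a
junction when it lies within `cutoff` (default 6 Å) of any protein atom of
the junction's linker region, defined as the last/first `linker_residues`
(default 5) of the flanking domains. The count is invariant under rigid
motion and insensitive to the cutoff over a broad range because the ions sit
2.3–2.6 Å from their coordinating oxygens.

## Superposition and bend angles (`geometry`)

RMSDs are over paired Cα atoms after optimal least-squares superposition
(Kabsch, SVD form with the determinant correction to exclude reflections).
`trimmed_align` establishes initial residue pairs either by index or by a
global sequence alignment (BLOSUM62, gap open −10, extend −0.5; identical
sequences shortcut to index pairing), then iterates: superpose, reject pairs
deviating by more than `reject_cutoff` (default 2.0 Å), re-superpose, for up
to `max_cycles` (default 5) or until no pair is rejected. Retained-pair
counts and RMSDs are therefore comparable to, but not bit-identical with,
the interactive tools that popularised this refinement loop; downstream
comparisons treat the counts as tolerance-bounded. The trim never reduces
the problem below three pairs. Dimer-vs-dimer comparison concatenates both
chains and tries both chain correspondences, returning the lower-RMSD
pairing — this makes the comparison invariant to arbitrary chain labelling
of two-fold symmetric dimers.

Interdomain bends are computed per junction as the angle between the two
domains' principal inertial axes over their Cα sets, each axis oriented from
the N- to the C-terminal half centroid. A straight tandem scores 0; values
are unsigned in [0, 180). Collinear or axis-degenerate Cα sets raise a
geometry error rather than returning an arbitrary axis.

## Surface areas and interfaces (`interface`)

SASA uses Shrake–Rupley point sampling: each atom is inflated by the probe
radius (default 1.4 Å) and covered with a Fibonacci-lattice point set
(default 960 points; the lattice is a fixed function of the point count, so
areas are bit-reproducible). One non-standard refinement: the lattice for
each atom is expressed in a local frame built from the directions to its
occluding neighbours. Because that frame is rotation-covariant, per-atom
areas are exactly invariant under rigid motion of the structure — in
particular the two protomers of an exactly symmetric dimer receive
identical areas, rather than agreeing only to sampling error. Radii are a
protein-centric element table (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) with a
configurable fallback (default 1.70 Å) for unlisted elements.

Buried surface area follows the assembly convention: BSA = ASA(protomer A
alone) + ASA(protomer B alone) − ASA(complex), accumulated per residue and
summed over both protomers. A residue's percent-buried uses its ASA in the
isolated protomer as denominator (not a free tripeptide), matching the
"difference upon dimer formation" convention; values are clamped to
[0, 100]. Waters are always excluded; other hetero groups (glycans, ions)
are excluded by default with a flag to include them, so users can probe how
much modelled glycans contribute. Missing side-chain atoms are flagged per
residue but never rebuilt — rotamer completion is out of scope, and reported
areas for flagged residues should be read with wider tolerance. Contact
pairs are inter-protomer residue pairs with Cα–Cα distance strictly below
the cutoff (default 10 Å; ties at exactly the cutoff excluded).

## Conservation logos (`conservation`)

Ortholog sets are built with a one-isoform filter emulating the BLAST-based
practice: each candidate is scored by global pairwise alignment (BLOSUM62)
against every mouse isoform and accepted for its best-scoring isoform only
when second_score/best_score < margin (default 0.95) and the best score is
positive. The margin on a score ratio is a declared surrogate for
"significant similarity to more than one isoform" — it is deterministic and
needs no database statistics; the accepted set shrinks monotonically as the
margin tightens.

Logos are tabular. Alignment columns where the chosen reference sequence has
a gap are dropped; the remaining columns are numbered consecutively along
the reference. Per column: frequencies over the observed canonical residues,
the gap fraction (columns with gap fraction > 0.5 flagged), and information
content log₂20 − H in bits with no small-sample correction. Cross-isoform
variability classing calls a position constant when every isoform's
consensus residue is identical *and* each consensus frequency reaches the
purity threshold (default 0.8); consensus ties break lexicographically and
are flagged. Pairwise identity is matches over gap-excluded aligned columns
of a global alignment.

## Specificity rules (`specificity`)

The heterodimer screen reproduces, as explicit rules, the qualitative
argument used to read interface logos: residues that vary between isoforms
but are conserved within each isoform's orthologs, and that interact across
the dimer interface, determine specificity when the homodimer combination is
compatible while the heterodimer combination is not.

For a contact (a, b) and isoforms x, y the screen classifies the homodimer
combinations (xₐ,x_b) and (yₐ,y_b) and both heterodimer orientations
(xₐ,y_b), (yₐ,x_b), using consensus residues:

* opposite formal charges → favorable; like charges → electrostatic clash,
  with histidine counted positive (protonatable at interface pH, and
  observed clash-forming in this family);
* steric: a heterodimer pair whose combined side-chain volume (standard
  mean-volume table) exceeds the larger homodimer pair's combined volume by
  more than ΔV (default 40 Å³, roughly one CH₂-to-phenyl step) → steric
  clash — capturing correlated small/large variation without any atomic
  modelling;
* otherwise neutral.

A contact is a specificity candidate when both homo classes are
favorable/neutral and the worst hetero orientation clashes. Self-interacting
positions across the two-fold axis are pairs with a = b. The thresholds are
declared surrogates — the underlying phenomenon is not quantified in energy
terms anywhere — so the rule set and ΔV are configurable, and a per-sequence
(rather than consensus) mode can be emulated by building logos from
single-sequence alignments. Outputs are candidate flags with a rationale
string, never binding-affinity claims.

## Sedimentation equilibrium (`auc`)

Forward model: a buoyant species of monomer mass M at angular velocity ω has
reduced buoyant term σ₁ = M(1−v̄ρ)ω²/(2RT); an n-mer distributes as
c_n(r) = c_n(r_ref)·exp(nσ₁(r²−r_ref²)). Mass action couples the species at
the reference radius: monomer–dimer (K_D), monomer–dimer–tetramer (K_D,
K_24), or isodesmic (equal stepwise K_I, all orders). The isodesmic signal
is summed in closed form, Σ n c₁ xⁿ⁻¹ = c₁/(1−x)² with x = c₁/K_I, guarded
for x < 1 — no arbitrary truncation. Absorbance is extinction × path length
× total monomer-equivalent concentration plus a per-channel baseline. All
constants are molar dissociation constants on the monomer scale, reported in
μM. Simulated scans set the reference monomer concentration by solving
sector mass conservation (∫c·r dr / ∫r dr = loading) with Brent's method.

Global fitting shares the association constants across all scans, giving
each scan a free reference monomer concentration and each channel a free
baseline (extinction is fixed, not fitted, by default — it is degenerate
with concentration). The optimiser is trust-region-reflective nonlinear
least squares on log₁₀-parameters with bounds (K between 10⁻³ and 10⁵ μM),
multi-started over a log-spaced K grid with a seeded jitter; noiseless
self-generated data is recovered to machine precision. Standard errors come
from the linearised covariance via the delta method.

Classification fits four models (single species, monomer–dimer, isodesmic,
monomer–dimer–tetramer) and selects by corrected Akaike information on the
pooled residuals (the criterion behind the original software choice is not
public; AICc is a defensible default for nested-ish models of unequal
complexity). The two-stage model must win decisively (ΔAICc > 10) to label
tetramer. When a dimer-like model wins, the ratio of the isodesmic constant
to the dimer dissociation constant below 2 flags possible non-specific
binding: a genuine discrete dimer shows K_I well above K_D (higher orders
suppressed), while an indefinite self-associator shows K_I ≈ apparent K_D.

## Synthetic-data conditions (`synthetic`)

Every generator returns the artifact plus a truth record and is a
deterministic function of (parameters, seed); truths are verified at
generation time by independent brute-force checks (axis fits, O(n²) contact
scans, column purity) before being returned.

* **Pseudo-domain chains** are rigid rod-like clusters (Cα at 3.4 Å rise on
  a 1.5 Å-radius helical offset plus 0.15 Å seeded jitter, one side-chain
  sphere per residue), chained with prescribed junction bends and optional
  planted junction calciums. They are geometric stand-ins, not folds: the
  geometry and interface operators consume only coordinates, so fold realism
  adds nothing to those closures — but nothing about real β-sandwich packing,
  glycans, or crystal contacts is represented, and passing closures says
  nothing about annotation quality on real structures.
* **C2 dimers** place the second protomer by a 180° rotation about a
  two-fold axis perpendicular to the chain's long axis, displaced by half
  the separation so the operation is an exact involution of the complex.
* **Isoform families** (defaults: 3 isoforms × 20 species × 30 positions,
  2% per-site ortholog mutation) plant (i) variable positions with distinct
  per-isoform residues drawn from a volume-homogeneous neutral pool — so
  incidental variation can never fake the correlated small/large signal —
  and (ii) one covarying charge pair realised as E/K in one isoform and K/E
  in the others, the classic interface co-evolution signature. Planted
  columns are mutation-free so the planted signal is exact.
* **Equilibrium scan batches** default to the standard study conditions:
  loading absorbances 0.65/0.43/0.23 AU (280 nm, 10 mm reference path) in
  channels A/B/C, speeds from the 9 000–15 000 rpm ladder, 80 radial points
  over 5.95–6.35 cm, 25 °C. The synthetic species is a 50 kDa monomer with
  v̄ 0.73 mL/g, solvent density 1.005 g/mL, ε₂₈₀ 50 000 M⁻¹cm⁻¹ and 12 mm
  path — representative of a glycosylated four-domain ectodomain fragment.
  Points above 1.2 AU are dropped, emulating the usable linear range of the
  detector. The recovery studies use 3 speeds × 3 loadings with 0.0065 AU
  Gaussian noise (1% of the top loading).

## Pipeline (`pipeline`, `cli`)

Run configurations are validated by a strict schema (unknown keys rejected)
before any computation. Accession ids resolve against a local cache
directory only; a separate documented script populates it, keeping the
library download-free. Each report bundle writes CSV/JSON artifacts plus a
manifest with parameters, package version, seed, artifact checksums and
per-stage timers; re-running the same configuration reproduces identical
checksums. One failing input is recorded in the manifest and never aborts
the remaining analyses.

## Numerical choices and limitations

* Problem sizes in the shipped tests and the acceptance script (20-residue
  pseudo-domains, 960–2000 SASA points, 20-seed recovery ensembles, 3×3 scan
  grids) were chosen as the smallest sets that exercise each property
  cleanly; all are parameters, not limits.
* The trimmed-alignment retained-pair count depends on the rejection
  schedule; comparisons against published counts should allow ~10%.
* Bend angles depend on the domain-axis definition; alternative axis
  conventions shift absolute values by a few degrees, so cross-tool
  comparisons should allow ±3°.
* The SASA lattice's local-frame orientation makes areas rigid-motion
  invariant but they remain discretisation-dependent: doubling the point
  count moves totals by <0.5%.
* Percent-identity values move by roughly a point under different alignment
  parameters; treat them with ±2-point tolerance.
* The specificity rules are qualitative by design: they flag candidates,
  they do not rank or score them, and consensus-level evaluation hides
  within-isoform polymorphism at impure positions (which the purity
  threshold is meant to catch).
* Sedimentation fits assume ideal solutions (no nonideality term), a single
  extinction per fragment, and equilibrium at every speed; the classifier's
  ΔAICc threshold trades tetramer sensitivity against overfitting and is
  configurable.
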