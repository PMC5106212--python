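# pcdhkit

Structural and comparative-sequence analysis of clustered protocadherin
(Pcdh) ectodomains, for structural biologists and biophysicists studying
isoform-specific cell–cell recognition.

Clustered Pcdhs give vertebrate neurons individual surface identities: each
ectodomain carries six extracellular cadherin (EC) domains, with an
antiparallel *trans* recognition dimer formed through EC1–EC4 (EC1:EC4 and
EC2:EC3 sub-interfaces) and a same-membrane *cis* dimer formed through EC6.
`pcdhkit` implements the quantitative toolchain for dissecting this system:

* **Coordinates** — PDB/mmCIF I/O (via gemmi) preserving author numbering,
  EC-domain selection from a boundary config, and calcium-stoichiometry
  checks at EC–EC junctions (three Ca²⁺ per junction in intact linkers).
* **Geometry** — Kabsch superposition; trimmed Cα alignment
  (RMSD = √(Σ‖R·aᵢ+t−bᵢ‖²/n) over retained pairs, iteratively rejecting
  pairs deviating > 2 Å); two-fold-aware dimer-vs-dimer comparison;
  interdomain bend angles from oriented principal axes, reported as the
  deviation from a straight (180°) tandem.
* **Interfaces** — Shrake–Rupley SASA with a rotation-covariant point
  lattice; buried surface area as the change in accessible area over both
  protomers (BSA = ASA_A + ASA_B − ASA_AB); per-residue %BSA profiles and
  histograms; cross-interface contacts at Cα–Cα < 10 Å.
* **Conservation** — ortholog assignment with a one-isoform filter,
  reference-numbered sequence logos (information = log₂20 − H bits),
  constant/variable position classes across isoforms, pairwise identity
  matrices.
* **Specificity** — rule-based screening of interacting residue pairs:
  salt bridges favorable, juxtaposed like charges (His counted positive)
  electrostatic clashes, anti-correlated small/large substitutions steric
  clashes; candidates are pairs compatible in both homodimers but clashing
  in the hypothetical heterodimer.
* **Sedimentation equilibrium** — exponential radial concentration model
  c_n(r) = c_n(r_ref)·exp(n·σ₁·(r²−r_ref²)) with
  σ₁ = M(1−v̄ρ)ω²/2RT, coupled by mass action (monomer–dimer,
  monomer–dimer–tetramer, or closed-form isodesmic); global multi-scan
  fitting and a monomer/dimer/tetramer/non-specific classifier using the
  K_I/K_D < 2 rule.
* **Synthetic data** — seeded generators with verified ground truth for
  every input class, so the full pipeline is testable with no downloads.

## Worked example

```python
import pcdhkit as pk
from pcdhkit.auc import AssociationModel, global_fit, classify_oligomer
from pcdhkit.synthetic import (DEFAULT_SPECIES, gen_auc_dataset,
                               gen_c2_dimer, gen_domain_chain)

# a four-domain tandem with planted bends and junction calciums
chain, truth = gen_domain_chain(4, bend_angles_deg=[5.0, 32.6, 18.6],
                                seed=7, calcium_per_junction=3)
bend = pk.interdomain_angle(chain, truth.annotation["A"], ("EC2", "EC3"))
print(f"EC2-EC3 bend deviation: {bend.deviation_deg:.1f} deg")
print(pk.structure.count_linker_calcium(chain, truth.annotation).to_string(index=False))

# an antiparallel C2 dimer and its interface
dimer, _ = gen_c2_dimer(gen_domain_chain(2, seed=7)[0], separation=8.0, seed=7)
report = pk.compute_interface(dimer, ["A"], ["B"])
print(f"total BSA: {report.total_bsa:.1f} A^2 over both protomers, "
      f"{len(report.interfacial_residues)} interfacial residues, "
      f"{report.n_contacts} contacts")

# sedimentation-equilibrium scans (3 speeds x 3 loadings, 1% noise) and fits
scans, _ = gen_auc_dataset(AssociationModel("monomer_dimer", kd=20.0),
                           noise_sd=0.0065, speeds=(11000., 13000., 15000.),
                           seed=7)
fits = {k: global_fit(scans, k, DEFAULT_SPECIES, seed=0)
        for k in ("single", "monomer_dimer", "isodesmic",
                  "monomer_dimer_tetramer")}
label, ratio = classify_oligomer(fits["monomer_dimer"], fits["isodesmic"],
                                 fits["monomer_dimer_tetramer"], fits["single"])
kd = fits["monomer_dimer"].parameters["kd"]
print(f"oligomeric state: {label}; K_D = {kd:.1f} uM (K_I/K_D = {ratio:.1f})")
```

Output:

```
EC2-EC3 bend deviation: 32.8 deg
chain junction  n_ca
    A  EC1-EC2     3
    A  EC2-EC3     3
    A  EC3-EC4     3
total BSA: 945.5 A^2 over both protomers, 48 interfacial residues, 102 contacts
oligomeric state: dimer; K_D = 20.3 uM (K_I/K_D = 2.6)
```

The bend deviation recovers the planted 32.6°; each junction carries its
three calcium ions; the dimer interface buries ~950 Å² over both protomers;
and the global fit recovers the planted 20 μM dissociation constant within
2%, classifying the fragment as a specific dimer (K_I/K_D ≥ 2 means no
isodesmic, non-specific association is needed to explain the data).

A `pcdhkit` console command exposes the same pipeline from the shell
(`structure-report`, `specificity-report`, `auc-report`, `gen-fixtures`),
driven by a YAML config; every report directory includes a manifest with
parameters, seeds and artifact checksums, and re-running a config
reproduces identical checksums.

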