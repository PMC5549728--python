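# habind

Contact fingerprints, binding-mode classification, umbrella/WHAM
energetics and forced-unbinding assays for hyaluronan–receptor
trajectories.

Hyaluronan (HA), the polyanionic GlcUA–GlcNAc polysaccharide of the
extracellular matrix, binds the HA-binding domain (HABD) of the receptor
CD44 not in one way but in three topographically distinct, mutually
exclusive binding modes — the crystallographic groove mode, a *parallel*
mode lower on the groove face, and an *upright* mode perpendicular to the
groove. Together the three modes define an interaction fingerprint that
reconciles the widespread binding residues reported by mutagenesis and NMR
with the single arrangement seen by X-ray. `habind` turns the analyses
behind that picture into a reusable pipeline for anyone working with
protein–glycosaminoglycan trajectories:

* **Contact statistics** — per-residue binding percentages with replica
  standard errors (a residue is bound when any heavy atom lies within
  0.6 nm of the ligand), per-arginine atom-pair contact profiles, and
  polymer-residue × time contact contours,
  P_i = 100 · #frames(d_i ≤ 0.6 nm)/N.
* **Mode classification** — cosine similarity of an observed fingerprint
  against packaged reference fingerprints over 39 literature binding
  residues; labels `crystallographic | parallel | upright | unbound |
  ambiguous`, run-length transition detection, and per-frame A/B-form
  assignment from the Y42 backbone φ dihedral plus the R41 side-chain
  hydrogen bond.
* **Energetics** — weighted-histogram analysis (WHAM) of umbrella-sampling
  windows into a potential of mean force G(ξ) with Bayesian-bootstrap
  uncertainties; well depths ΔG_min, population-integrated ΔG_pop, and
  Boltzmann preference factors exp(ΔΔG/k_BT), in kJ/mol and k_BT.
* **Assays** — in-silico electrophoresis (detachment of the polyanion
  under a uniform field; a replica detaches when the contact count first
  reaches zero) and one-dimensional sliding of the receptor along the
  polymer (contact-centroid tracks, net displacement, MSD).
* **A synthetic generator** — an overdamped-Langevin toy system with three
  planted binding modes of ordered strength (ε = 12, 8, 5 kJ/mol),
  field-driven detachment and weak-mode sliding, used as ground truth for
  every estimator in the test suite.

## Worked example

The headline free-energy arithmetic: umbrella sampling gives well depths
of −22 kJ/mol for the parallel mode and −33 kJ/mol for the
crystallographic mode. Feeding those depths to the energetics stage:

```bash
cat > demo.yaml <<'YAML'
dg_inputs:
  crystallographic: -33.0
  parallel: -22.0
YAML
habind energetics --config demo.yaml --out demo_out --seed 1
cat demo_out/energetics.json
```

```json
{
 "kbt_kJ_per_mol": 2.5,
 "convention": "paper-arithmetic",
 "modes": {
  "crystallographic": {"dg_kJ_per_mol": -33.0, "dg_kbt": -13.2},
  "parallel":         {"dg_kJ_per_mol": -22.0, "dg_kbt": -8.8}
 },
 "preference_factors": {"crystallographic_vs_parallel": 81.45086866496814}
}
```

−22 kJ/mol is 8.8 k_BT and −33 kJ/mol is 13.2 k_BT; the 11 kJ/mol
(4.4 k_BT) gap makes the crystallographic mode ~80 times more favorable
than the parallel mode by point-minimum Boltzmann weight. (The default
thermal constant is the rounded 2.5 kJ/mol reporting convention; pass
`thermo: {convention: physical}` for R·T at the configured temperature.)

The same pipeline on synthetic trajectories with planted modes — three
replicas per mode, fingerprint and classify:

```python
from habind.pipeline import RunConfig, run_fingerprint

cfg = RunConfig.from_dict({"n_replicas": 3, "n_steps": 10_000},
                          outdir="demo_fp", seed=1)
res = run_fingerprint(cfg)
```

gives a reference-layout binding table (excerpt; percentages ± SE over
replicas):

```
residue  crystallographic  parallel     upright
     25         0.0 ± 0.0  91.7 ± 2.0   0.0 ± 0.0
     38         0.0 ± 0.0   0.0 ± 0.0  99.3 ± 0.7
     41       100.0 ± 0.0  91.7 ± 2.0  98.7 ± 0.9
     76       100.0 ± 0.0   0.0 ± 0.0   0.0 ± 0.0
    110         0.0 ± 0.0  91.7 ± 1.4   0.0 ± 0.0
    162         0.0 ± 0.0   0.0 ± 0.0  99.3 ± 0.3
```

The key residue (41) is bound in every mode, the groove residue 76 only in
the crystallographic mode, 110 only in the parallel mode, 162 only in the
upright mode — and every replica classifies back to its planted label.

## Command line

One subcommand per analysis, sharing `--config/--out/--seed`:

```
habind fingerprint   # binding-percent table + classification
habind classify      # alias for the fingerprint/classification stage
habind energetics    # umbrella/WHAM PMFs or direct dG conversions
habind efield        # detachment fractions under a field preset
habind sliding       # receptor tracks along the polymer
habind synth         # generate toy trajectories (PDB + columnar text)
```

Exit codes: 0 success, 2 config error, 3 data error, 4 convergence error.

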