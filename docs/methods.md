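# Methods

This note documents the models, estimators and numerical choices behind
`habind`: what each quantity is, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Contact statistics

All contact criteria are geometric. A protein residue is *in contact* with
the ligand in a frame when any of its heavy atoms lies within the cutoff
(default 0.6 nm, boundary inclusive: d ≤ 0.6 counts; "heavy" means element
≠ H, inferred from the element column or atom-name heuristics with an
override table) of any ligand heavy atom. Binding percentage of residue *i*
over a window of *N* frames is

    P_i = 100 × (# frames with residue i in contact) / N.

Replica aggregation reports the mean over replica percentages and the
standard error sd/√n (n = replica count, sample sd with ddof = 1); a single
replica carries a NaN sentinel rendered as "N/A".

Two estimators named "contacts" in the field are kept as distinct
operations: the residue-level boolean (percentages, fingerprints) and the
atom-pair count — the number of (residue atom, ligand atom) pairs within
the cutoff — used for per-arginine profiles and the polymer-residue × time
contact contours that track a receptor along the chain. Both are exact
enumerations; the distance kernel (minimum-image in orthorhombic boxes)
delegates to MDAnalysis and is validated against an O(N²), 27-image
brute-force oracle in the test suite.

Hydrogen bonds use the common geometric criterion: donor–acceptor distance
≤ 0.35 nm and, when explicit hydrogens are present, donor–H–acceptor angle
≥ 150°; both configurable. The criterion is a package default — contact
percentages in the reference table do not depend on it.

## Binding modes and classification

Hyaluronan binds the CD44 HA-binding domain in three mutually exclusive
arrangements — crystallographic (the groove mode resolved by X-ray),
parallel (lower on the groove face) and upright (perpendicular, toward the
C-terminal basic cluster). Each mode leaves a characteristic pattern of
per-residue binding percentages over 39 literature-identified binding
residues; the packaged reference table
(`habind/data/reference_fingerprints.tsv`) stores the three reference
fingerprints with their standard errors.

Classification is cosine similarity between an observed fingerprint and
each reference column. Cosine, not Euclidean distance, because run lengths
and occupancies scale the magnitudes while the *pattern* is the signature;
the classifier is therefore scale-invariant by construction. A window is
labeled with the best mode when its similarity reaches the ambiguity
threshold (default 0.80), `ambiguous` otherwise, and `unbound` when no
residue contacts the ligand at all. The threshold and the minimum segment
length for transition detection (default 5 windows; shorter runs are
absorbed into the preceding segment) are package choices — mode assignment
in the reference analysis was done by inspection, so no numeric values
exist to inherit. Both are configurable.

The A/B-form switch of the crystallographic complex is assigned per frame:
the backbone φ dihedral of Y42 (computed from C(41)–N(42)–CA(42)–C(42)
with the standard atan2 formula, IUPAC sign) acts as the bistable switch,
and a frame is B-form only when φ lies in the B basin *and* the R41 side
chain donates at least one hydrogen bond to the ligand. The basin split
defaults to sign (B: φ ∈ [−180°, 0°)), configurable — bistability is
established in the literature but no numeric basin boundaries are printed.
The conjunction with the R41 hydrogen bond encodes the defining property
that the A-form lacks direct R41–ligand contacts; it also implies B can
never be reported in ligand-free frames.

## HA residue numbering

Monosaccharides are named GlcUA/GlcNAc; the disaccharide whose minimum
heavy-atom distance to the key binding residue (R41) is smallest is
disaccharide 0, numbers decrease toward the reducing (GlcNAc) terminus and
increase toward the non-reducing (GlcUA) terminus. The assignment follows
chain chemistry, not file order, and is invariant under rigid-body motion
of the whole system. An exact tie between two disaccharides is resolved
toward the reducing end (documented tie-break). The reducing terminus is
inferred from the terminal monosaccharide types when unambiguous and must
be given explicitly otherwise.

## Umbrella sampling and WHAM

Window input is one plain-text time series per window (header: restraint
center and spring constant; body: time, ξ). The PMF G(ξ) is estimated by
the standard self-consistent WHAM iteration in log space,

    p_i  ∝  Σ_k n_ki / Σ_k N_k exp((f_k − U_k(ξ_i))/kBT),
    exp(−f_k/kBT) = Σ_i p_i exp(−U_k(ξ_i)/kBT),

iterated until max|Δf_k| < 10⁻⁶ kJ/mol (default; cap 10⁵ iterations,
non-convergence raises with the residual). Defaults: 100 bins over the
union of sampled ranges; bins with fewer than 5 total counts are dropped
(a handful of samples per bin carries kBT-scale noise). Profiles are
anchored so the mean of G over the bulk region — by default the trailing
20 % of the grid — is exactly zero. Windows whose sampled ranges leave a
gap raise a coverage error naming the gap.

Uncertainties are Bayesian-bootstrap (default 50 resamples, seeded):
Dirichlet weights over samples per window, WHAM re-solved per resample.
The bootstrap profile replicates are kept on the profile so functionals —
the well depth, population integrals — get their uncertainty from the
replicate distribution rather than from per-bin σ, which would ignore the
correlation between bins. Bootstrap honesty requires approximately
independent samples; the synthetic scans therefore store decorrelated
(strided) positions, see below.

Derived quantities:

* **ΔG_min** — minimum of G minus the bulk mean (≤ 0 when a well exists).
* **ΔG_pop** — population-integrated binding free energy,
  −kBT ln(∫_{ξ<ξ*} e^{−G/kBT} dξ / ∫_{ξ≥ξ*} e^{−G/kBT} dξ), trapezoidal on
  the grid. The partition ξ* defaults to the first grid point past the
  minimum where G has risen to within 1 kBT of bulk; the bound/unbound
  partition used in the reference analysis is not stated, so ξ* is always
  configurable and reported. ΔG_pop → ΔG_min for a deep narrow well, and a
  wide shallow well is *less* disfavored by population than by depth —
  the entropic compression asserted qualitatively in the tests.
* **Preference factor** — exp((ΔG_b − ΔG_a)/kBT), the Boltzmann preference
  of the stronger mode.

### Thermal constants

Two conventions, always reported with every converted number:

* `paper-arithmetic` (default): kBT = 2.5 kJ/mol. The printed
  conversions in the reference work (22 → 8.8 kBT, 33 → 13.2 kBT, and the
  80-fold factor from the 11 kJ/mol gap) are reproduced exactly by 2.5 and
  not by the physical constant at 310 K.
* `physical`: kBT = R·T/1000 with T configurable (≈ 2.577 kJ/mol at
  310 K). The synthetic dynamics always use the physical value.

## Detachment assay

Replica scoring follows the first-zero rule: the ligand is detached at the
earliest frame where the protein–ligand atom-pair contact count (standard
0.6 nm cutoff) reaches zero; later re-binding is ignored. A persistence
option (n consecutive zero frames) exists and defaults off. Replicas that
never reach zero are censored at the simulation end; the censoring time is
a required input, never a default, because the two field presets in the
reference assay ran for different times and a wrong default would silently
mix them. Summaries report the detachment fraction
100·n_detached/n_total and the mean ± SE of detachment times over the
*detached replicas only*, with an N/A sentinel for n_detached ≤ 1.

## Sliding along the polymer

The receptor's position along the chain is the contact-count-weighted mean
monosaccharide index (the centroid of its contact-contour column). Frames
without contacts are undefined (NaN, not an error); zero-contact gaps up
to a limit (default 20 frames) are linearly interpolated, reflecting the
transient, 10–20 ns partial detachments that punctuate sliding. Tracks
report net displacement (last minus first defined centroid), maximum
excursion, and mean squared displacement per lag over all valid time
origins. Partial-detachment events are intervals where the total contact
count drops below a low-watermark (default 25 % of the track median) while
staying nonzero and at least one residue of the retained set (default
108–114, the hydrogen-bond network stretch toward the reducing end) stays
bound throughout.

## The synthetic generator

The generator produces trajectories with the statistical structure the
analysis assumes, at desk scale. It emulates: a rigid ~25-bead receptor
with labeled pseudo-residues (a key site mapping to R41/Y42/R78/Y79 plus
three anchor patches mapping onto the 39-residue reference set, shared
groove residues carrying one bead per patch that uses them); a flexible
64-bead polyanionic chain of alternating GlcUA(−1e)/GlcNAc beads with
stiff harmonic bonds and restrained ends; three planted binding modes of
ordered strength; detachment under a uniform field acting on the charged
beads with the receptor held fixed; and sliding of a laterally tethered
receptor along the chain. It does not emulate: atomistic geometry or force
fields, explicit solvent, receptor rotation or internal flexibility,
counterion screening, or any electrostatics beyond the uniform applied
field. Passing tests therefore demonstrate that the estimators recover
planted structure from trajectories with realistic statistical features —
not that they reproduce any particular all-atom system.

Dynamics are overdamped Langevin (Euler–Maruyama),
Δx = (D/kBT)·F·Δt + √(2DΔt)·η, with D = 10⁻³ nm²/ps for beads and the
rigid receptor alike, Δt = 0.3 ps, 310 K. Construction validates
√(2DΔt) < 0.1 × well width; any per-step displacement beyond half the box
raises a stability error naming the step. The inner loop is a compiled
(numba) kernel; a pure-numpy reference implementation of the same forces
is kept and the two are asserted equal in the tests. Noise is pre-drawn
from a seeded numpy Generator, so identical (config, seed) pairs give
bit-identical trajectories regardless of the kernel path.

Forces: harmonic bonds (k = 2000 kJ mol⁻¹ nm⁻², b = 0.5 nm), chain-end
restraints, a weak lateral tether of the chain to its axis (the analog of
a chain held at a surface), soft excluded volume between every
receptor/polymer bead pair (r₀ = 0.35 nm), the field force qE on GlcUA
beads, and the binding wells: each active (key + planted patch) bead is
attracted to the GlcNAc beads by a Gaussian well of width 0.3 nm and
per-pair depth `pair_depth_scale` × ε_m (default scale 0.8). Attaching the
wells to GlcNAc only — the planted analog of the GlcNAc methyl anchoring
in the groove's hydrophobic pocket — makes the bound state corrugated
along the chain with a one-disaccharide period, so shallow modes hop
between registry sites while the deep mode stays put; per-pair (rather
than per-patch-normalized) depths keep the planted strength ordering both
per contact and in total, which is what the peeling-style detachment under
field actually probes. A one-sided wall below the chain axis acts on the
receptor only: physically, the receptor protrudes from a surface on one
side of the chain; numerically, it removes a toy-only escape path straight
through the 1D bead chain.

Default well depths ε = (12, 8, 5) kJ/mol for (crystallographic, upright,
parallel): the qualitative strength ordering with a spread of a few kBT,
deep enough that all three modes are stable over the nanosecond runs at
zero field (as the real modes are over microseconds) and shallow enough
that the strong-field preset detaches the weak modes within a few
nanoseconds.

Field presets: `strong` = 1.5 kJ mol⁻¹ nm⁻¹ e⁻¹, `weak` = 0.15 (one
tenth). The strong value was fixed once, by the same operational criterion
that defined it in the reference assay — strong enough that detachments
occur within the short simulation window while the deepest mode survives —
from a coarse scan of field strengths; at this value 20-replica fractions
order parallel > upright > crystallographic (≈ 85/30/0 % over 4 ns).

Umbrella scans are quasi-one-dimensional by design: the receptor moves
only along the detachment coordinate ξ against the planted mode well
U(ξ) = −ε·exp(−(ξ−ξ_b)²/2w²) (plus a soft wall at small ξ and, under
field, the linear work term −q_tot|E|·ξ), with the harmonic bias added.
Restraining the lateral degrees of freedom removes the 2kBT·ln ξ radial
Jacobian of a 3D distance coordinate, so WHAM recovers a planted depth ε
as ΔG_min = −ε without geometric corrections. The scan integrates at
Δt = 0.05 ps — finer than the 3D dynamics, because the combined
well-plus-bias stiffness makes the Euler equilibrium density measurably
too wide at 0.3 ps — and stores every 300th position (15 ps, about two
relaxation times of a stiff window), so the stored samples are
approximately independent and the bootstrap uncertainties downstream are
honest. With correlated samples the bootstrap CI under-covers by
several-fold; this was measured, and the stride chosen accordingly.

## Problem sizes

The default study conditions keep every stage desk-scale: fingerprint
windows of 3 ns (10 000 steps, 64-mer chain), detachment assays of 20
replicas × 4 ns on a 32-mer chain, sliding runs of ~25 ns (83 000 steps,
10 seeds per mode), umbrella scans of 26 windows × 360 000 steps. The full
test suite runs in about three minutes on one CPU; the acceptance script
in about two.

## Known limitations

* The receptor does not rotate; mode inter-conversion cannot occur in the
  toy, so transition detection is exercised on constructed label
  sequences, not on simulated transitions.
* The A/B-form machinery needs backbone atoms and is therefore exercised
  on hand-built atomistic fixtures; the bead-level toy has no φ dihedral.
* WHAM window free energies accumulate random-walk error across a long
  ladder of windows; with ~1000 independent samples per window the
  end-to-end drift is a few tenths of kJ/mol, visible in the flat-profile
  checks and covered by the bootstrap.
* DCD/XTC reading is delegated to MDAnalysis and assumes orthorhombic
  boxes; triclinic cells are out of scope throughout.
* The "paper-arithmetic" thermal constant is a reporting convention for
  reproducing printed conversions, not a physical statement; dynamics and
  statistics always use R·T.
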