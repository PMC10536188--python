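# Methods

This note records the models, conventions and numerical choices behind
each module, the assumptions they rest on, and what the synthetic-data
generators do and do not emulate.

## Structure-derived descriptors

Molecular weight is the sum of IUPAC 2021 conventional atomic weights over
an explicit element-count record; topological polar surface area (TPSA) is
the Ertl fragment-contribution sum over an explicit polar-group count
record. Composite groups are sums of the published single-atom fragments
(carboxylic acid = carbonyl O 17.07 Å² + hydroxyl 20.23 Å²; ester =
carbonyl O + ether O). Only O- and N-containing fragments are packaged —
sufficient for triterpenoids and the packaged test molecules; S/P
contributions are a deliberate extension point. The input is a
composition/group record rather than a SMILES string: automatic
functional-group perception is a solved problem elsewhere (e.g. RDKit) and
any perception layer can populate `MoleculeComposition`; the core stays
dependency-light and exactly auditable. Rounding happens only at report
time.

## Retention fitting

The Soczewiński–Wachtmeister relation log k = log kw − s·φ is fit by
ordinary least squares of log₁₀ k on the organic-modifier volume fraction
φ (stored as a fraction; percent-style inputs are normalized with a log
message). Replicate injections are averaged as retention *times* per
(system, φ) before the k transform — the way replicate runs are reduced at
the bench; the alternative (averaging log k) differs only for unequal
replicates. The slope is reported as a magnitude `s` together with a
`retention_decreases` flag: a non-decreasing retention line violates
reversed-phase retention theory and is flagged, not rejected, so that
screening runs surface bad series instead of dying. With exactly two
distinct φ the fit is exact by construction (R² = 1, residual SE 0).

## logBB model

The built-in model `EQ2` is the published three-descriptor regression
(intercept −0.114; ΔlogP −0.098; log kw +0.278; E +0.218; n = 40,
S = 0.436). Conventions:

* **ΔlogP sign.** ΔlogP is computed as logP_cw − log kw, the arithmetic
  that reproduces the printed per-system values (8.358, 7.339, 6.634);
  a verbal description of the quantity as "the difference between
  log kw and logP_cw" would give the opposite sign, and the printed
  numbers win. `delta_logp` is always recomputed from its parents and
  never trusted from an input file.
* **Backward elimination.** Starting from all candidates, the descriptor
  with the largest partial-t p-value above α (default 0.05) is removed,
  one per iteration, until all retained descriptors are significant
  (statsmodels OLS supplies the p-values). Eliminating everything returns
  an intercept-only model with a warning.
* **Cross-validation.** Leave-ten-out CV partitions the sample into
  disjoint folds of 10 by a seeded random permutation (smaller last fold
  with a warning), refits on each complement with plain normal equations,
  and reports PRESS = Σ(y − ŷ_cv)², R²CV = 1 − PRESS/TSS and
  RMSECV = √(PRESS/n). An `n_repeats` parameter redraws the partition and
  reports the mean (± SD of R²CV), since a single random partition is
  itself noisy.
* **Applicability domain.** Leverage h = x(XᵀX)⁻¹xᵀ with an intercept
  column, warning threshold h* = 3(p+1)/n (the Williams-plot convention).
  This is a documented convention choice; the built-in literature model
  carries no training design, so domain checks are only available for
  models fit here.
* **R²pred** is computed only when a genuine external test set is
  supplied; it is never imputed.

Model statistics: RMSE = √(SSR/n); the residual scale S = √(SSR/(n−p−1)).

## IC₅₀

Viability is the standard blank-corrected ratio
100·(OD_t − OD_b)/(OD_c − OD_b); inhibition is its exact complement. (A
published variant of this formula that cancels to zero is not usable as
printed; the blank-corrected form is the field's standard.) The IC₅₀ is
defined as the concentration at the 50% response level. The primary
estimator is a four-parameter logistic fit by seeded multi-start bounded
least squares (bottom ∈ [0, 50] %, top ∈ [50, 120] %, midpoint within two
decades of the dose range, Hill ∈ [0.05, 10]); the 50% crossing is solved
from the fitted curve. When the fit cannot cross 50% — or on request — the
estimator falls back to interpolation, linear in concentration, between
the bracketing doses; the method used is recorded in the result.
Responses that do not bracket 50% raise ("IC50 not identifiable in tested
range").

TLC-bioautography IC₅₀ inverts the linear densitometric calibration at
half of a user-supplied maximal-inhibition reference response (assay
images define no intrinsic 100% point, so the reference is an explicit
argument), then converts the solved applied amount to a molar
concentration through an explicit record (molar mass, stock concentration,
effective zone volume). Every constant is a parameter precisely because
laboratory unit conventions vary; any convention can be reproduced by
setting them.

## Contact classification

Contacts are heavy-atom distances in nm; hydrogens are parsed (Bio.PDB's
permissive parser, Å → nm, coordinates quantized at the format's 0.001 Å
precision) but excluded from analysis. A residue is in contact when any
ligand/residue heavy-atom pair is strictly below the cutoff (default
0.38 nm — wide enough for polar contacts and the longer nonpolar C–C
range). Classification is distance-only, with closed windows and boundary
ties included:

* hydrogen bond: O/N–O/N pair within 0.25–0.35 nm;
* nonpolar C–C: carbon pair within 0.30–0.38 nm;
* CH-π: ligand aliphatic carbon within the cutoff of an aromatic ring
  atom of Phe/Tyr/Trp/His (packaged ring-atom-name table). "Aliphatic"
  means a ligand carbon with no covalently bonded O/N (neighbour within
  0.17 nm) — a geometric proxy for sp³ non-polar-bonded carbons that
  needs no bond table;
* other_polar: in-contact residues matching none of the above.

No angular criteria are applied anywhere: this mirrors the cutoff-based
post-docking analysis the module implements, and is a known limitation —
a distance-only hydrogen bond is a necessary, not sufficient, condition.
Residue numbering follows the input file verbatim.

## WHAM and bootstrap errors

`wham_1d` solves the standard self-consistent equations on binned
histograms (uniform bins over the union of sampled ranges, default 200),
with harmonic biases w_i(ξ) = κ_i/2 (ξ − c_i)², deterministic
initialization f_i = 0, and convergence when max|Δf_i| < tol·kT
(tol = 1e-6). kT defaults to 2.5775 kJ/mol (310 K). Hitting the iteration
cap flags the profile unconverged rather than raising; adjacent windows
with no shared occupied bin raise ("insufficient window overlap"). The
first 1/8 of each window's samples is discarded as equilibration — the
same fraction as dropping 5 ns of a 40 ns window. Profiles are reported as
G = −kT ln p shifted to a minimum of zero (or to a zero-mean bulk region
on request).

Errors follow the Bayesian bootstrap of complete histograms: each replica
draws per-window weights from a flat Dirichlet (whole histograms are
reweighted, never individual samples), WHAM is re-solved, replicas are
aligned to the reference convention, and the per-bin SD is reported. This
estimator captures between-window inconsistency; error contributions that
affect all windows identically are invisible to it, which is why the test
suite cross-checks it against the spread of independently regenerated
datasets.

`profile_summary` reduces a profile to the three numbers a membrane-
permeation argument needs: immersion ΔG (bulk level minus the global
minimum), central barrier (maximum over a bilayer-centre region minus the
minimum), and entry barrier (maximum between the bulk edge and the well,
above bulk; 0 for monotone descent). All are invariant to additive shifts.

## Synthetic data

All generators are pure functions of their arguments, seed included. They
emulate the *statistical structure* the analysis modules assume — not
instruments:

* retention: log k linear in φ with Gaussian noise in log k (default SD
  0.01, which leaves fitted R² near 0.99 on the packaged 4-point φ
  grids), converted back to consistent retention times; per-system
  defaults (log kw, s, φ grid) packaged for the IAM/CHOL/ISRP systems.
* QSAR training tables: descriptors uniform over fixed ranges
  (ΔlogP 2–10, log kw 0–3, E 0.5–2.5), response linear with Gaussian
  residuals (defaults n = 40, σ = 0.436 — the published model's size and
  residual scale).
* densitometry: lanes on the packaged calibration line
  (y = 12491x − 12671) over the five-volume set 2–10 µL.
* MTT plates: 4PL viabilities (top 100, bottom 0) converted to ODs around
  control 0.9 / blank 0.08 with optional OD noise. The default midpoint
  620 µg/mL and Hill 0.5299 are the least-squares fit of that two-
  parameter sigmoid to the three packaged viability anchors (71.5/61/43 %
  at 100/300/1000 µg/mL), which it reproduces within 1.6 percentage
  points; they were fixed once from that fit.
* umbrella sampling: per-window Metropolis chains in U(ξ) + bias
  (default proposal SD 2√(kT/κ), acceptance near 50%; acceptance < 1%
  raises with advice). The packaged membrane-like potential is two
  Gaussian wells at ±1.5 nm with a Gaussian central hump, its amplitudes
  solved linearly so the well depth and hump height are pinned exactly
  (defaults 43 and 13 kJ/mol — a phosphatidylcholine-like shape; 23 kJ/mol
  wells give the phosphatidylglycerol-like variant). The default window
  layout is 40 windows over −5…5 nm with κ = 1000 kJ mol⁻¹ nm⁻².
* toy complexes: PDB text for template residues (aromatic rings as ideal
  planar polygons, serine/glycine probes) placed around a six-carbon
  aliphatic ring ligand with an optional hydroxyl; the default spec is an
  aromatic cage around the ligand, plus exact-distance probe fixtures.

What passing tests on these data show — and what they do not: the
generators have exactly the assumed noise structure (Gaussian, i.i.d.,
correctly specified models), so tests demonstrate the estimators are
implemented correctly and are well-behaved at the study's problem sizes.
They say nothing about model misspecification, heteroscedastic plates,
drifting baselines, peak-integration error, or force-field accuracy; real
instrument data can and do violate the assumptions.

## Problem sizes used in the automated checks

The Monte-Carlo checks run at the sizes the methods are meant for:
parameter recovery over 200 seeded 40-compound datasets; cross-validation
optimism over 100 seeds; the WHAM oracle at 20 windows × 20,000 Metropolis
samples against a quadrature-normalized Boltzmann inversion (compared over
the windowed span, where the estimate is interpolation rather than
extrapolation); bootstrap scaling over 1,000–8,000 samples per window with
exact Gaussian window sampling. Membrane-permeation numbers of
cluster-scale molecular dynamics (tens of kJ/mol immersion free energies)
are *not* recomputed here — they parameterize the synthetic test
potentials, and `profile_summary` is verified on constructed profiles with
exactly those well and hump depths.

## Known limitations

* No SMILES/structure perception; compositions and group counts are
  caller-supplied.
* The QSAR applicability domain is leverage-only (no structural-similarity
  domain), and the built-in literature model cannot offer one at all.
* Contact classes are distance-only; no angular hydrogen-bond or ring-
  geometry CH-π criteria, no π-π or cation-π classes.
* WHAM is strictly 1D with harmonic biases; no autocorrelation analysis is
  performed (the bootstrap operates on whole histograms instead).
* The Metropolis sampler is a toy: single-particle, no dynamics, intended
  for generator/estimator round-trips, not for physical sampling claims.
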