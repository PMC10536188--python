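# bbbkit

A toolkit for the computational chain used to assess the central-nervous-
system potential of small lipophilic natural products such as oleanolic
acid: biomimetic-chromatography lipophilicity, blood–brain-barrier QSAR,
bioassay IC₅₀ calibration, ligand–protein contact classification, and 1D
umbrella-sampling free-energy profiles. It is aimed at pharmacokinetics /
medicinal-chemistry researchers who want each step of that chain as a
tested, scriptable library rather than a collection of spreadsheet
formulas.

## What it computes

**Chromatographic lipophilicity.** Retention on membrane-like HPLC phases
(IAM, cholesterol-bonded, ISRP) follows the Soczewiński–Wachtmeister
relation

    log k = log kw − s·φ

where φ is the organic-modifier volume fraction. The intercept log kw
(retention extrapolated to pure water) is the lipophilicity descriptor;
`bbbkit.chromatography` fits it from raw retention/dead times with
replicate averaging.

**logBB QSAR.** The blood–brain distribution coefficient
logBB = log(C_brain/C_blood) is predicted by a multiple linear regression

    logBB = −0.114 − 0.098·ΔlogP + 0.278·log kw + 0.218·E
    (n = 40, R²CV = 78.25%, R²pred = 74.02%, S = 0.436)

with E the Abraham excess molar refraction and ΔlogP = logP_cw − log kw the
hydrogen-binding potential. The published coefficient set ships as the
built-in model `EQ2`; `bbbkit.qsar` also rebuilds such models from training
tables (MLR with backward elimination, leave-ten-out cross-validation with
PRESS/RMSECV/R²CV, leverage-based applicability domain).

**IC₅₀ machinery.** `bbbkit.bioassay` fits linear densitometric
calibration lines for TLC-bioautography enzyme assays (and inverts them at
half of a maximal-inhibition reference, with every unit-conversion constant
explicit), and fits four-parameter-logistic dose–response curves to
blank-corrected MTT viability data, solving for the 50% crossing with a
linear-interpolation fallback.

**Contact classification.** `bbbkit.contacts` maps ligand–protein contacts
from PDB coordinates under a heavy-atom distance cutoff (default 0.38 nm)
and classifies them by distance windows: hydrogen bonds (O/N–O/N within
0.25–0.35 nm), nonpolar C–C contacts (0.30–0.38 nm) and CH-π contacts
(ligand aliphatic carbon near a Phe/Tyr/Trp/His ring atom).

**Free-energy profiles.** `bbbkit.free_energy` implements the weighted
histogram analysis method (WHAM) for 1D umbrella sampling, Bayesian
bootstrap of complete histograms for per-bin errors, and profile summaries
(immersion ΔG, entry and central barriers) for membrane-permeation
arguments.

**Synthetic data.** `bbbkit.synthetic_data` provides seeded generators for
every input format above, so the whole pipeline is testable without any
instrument data: retention tables, 40-compound QSAR training sets,
densitometry lanes, MTT plates, umbrella-sampling trajectories from a
membrane-like double-minimum potential, and toy PDB complexes with an
aromatic cage around an aliphatic ligand.

## Worked example

Predict logBB for one compound measured on the three membrane-like systems
(logP_cw = 8.995, E = 1.46):

```sh
$ cat table3.csv
system,logkw,logPcw,E
ISRP,0.637,8.995,1.46
IAM,1.656,8.995,1.46
CHOL,2.361,8.995,1.46

$ bbbkit qsar predict --descriptors table3.csv
model: eq2 (built-in)
ISRP    dlogP=8.3580    logBB=-0.4377
IAM     dlogP=7.3390    logBB=-0.0546
CHOL    dlogP=6.6340    logBB=0.2105
```

ΔlogP is recomputed from (logP_cw − log kw); the logBB values are the
linear-model evaluations — all three lie near zero, i.e. comparable brain
and blood concentrations at steady state, with the sign depending on which
membrane-like lipophilicity descriptor feeds the model.

The same descriptors can come from raw retention times:

```sh
$ bbbkit simulate retention --system IAM --noise-sd 0 --seed 1 --out iam.csv
$ bbbkit lipophilicity fit --input iam.csv
system  logkw     s  r_squared  residual_se  n_points
   IAM  1.656 1.515        1.0 1.011461e-15         4
```

and a viability plate yields its IC₅₀ (here on a synthetic plate generated
around the packaged dose–response anchors, with OD noise):

```sh
$ bbbkit simulate mtt --noise-sd 0.005 --seed 2 --out plate.csv
$ bbbkit ic50 mtt --plate plate.csv
IC50 = 620.47 (method: 4pl)
```

Equivalent library calls exist for everything the CLI does; see the module
docstrings and `docs/methods.md`.

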