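# Methods

## Rate law

The core model is the steady-state rate equation of a substituted-enzyme
(ping-pong bi-bi) reaction with a dead-end inhibitor that may bind the
enzyme form awaiting either substrate:

v/E = kcat·A·B / [ Km_A·B·(1 + I/Ki_A) + Km_B·A·(1 + I/Ki_B) + A·B ]

All concentrations are micromolar and rates are normalised per enzyme
(v/E, s⁻¹); conversion to an absolute molar rate multiplies by the enzyme
concentration.  The equation is treated purely as a rate law: no
commitment is made to which enzyme form (oxidised or reduced flavin) each
Ki describes, since the two inhibition factors are attached to the two
Michaelis terms, not to a microscopic scheme.

An *absent* Ki is a structural state (`ki_a=None`), not a large sentinel
number, so the four model variants (no inhibition, competitive with A
only, with B only, or with both) differ in parameter count (3, 4, 4, 5)
rather than in numerical limits.  Useful identities, all covered by tests:
the law is symmetric under swapping the (A, Km_A, Ki_A) and
(B, Km_B, Ki_B) triples; v/E is bounded by kcat, strictly increasing in
each substrate and decreasing in inhibitor; at fixed co-substrate the law
reduces exactly to a one-substrate Michaelis–Menten form with

Vmax_app = kcat / (1 + Km_B·(1+I/Ki_B)/B),
Km_app = Km_A·(1+I/Ki_A) / (1 + Km_B·(1+I/Ki_B)/B)

(and symmetrically with A fixed); and 1/v is affine in 1/A with slope
(Km_A/kcat)(1+I/Ki_A).  A point with A = 0 or B = 0 returns rate 0 by
convention (no turnover without either substrate), including A = B = 0.

## Assay processing

Initial rates come from the unweighted ordinary-least-squares slope of
absorbance versus time over a window (default the first 60 s of a 1–2 min
trace), divided by Δε·ℓ.  The default Δε is 4300 M⁻¹cm⁻¹ for the
nitrofurazone reaction at 420 nm and the path length defaults to 1 cm.
The slope's *magnitude* is reported, so consuming or producing the
chromophore gives the same rate.

Enzyme concentration is estimated from A280 with a flavin correction:
FMN absorbs at both 280 and 454 nm while the apoprotein absorbs only at
280 nm, so the flavin term (A454/ε_FMN,454)·ε_FMN,280 is subtracted before
dividing by the protein extinction coefficient (ε sets: FMN 12 200 at
454 nm and 20 970 at 280 nm; apoprotein 31 190 for NfsA, 22 460 for NfsB).
All of A454 is treated as FMN-equivalent absorbance; whether that reading
reflects only excess free flavin or includes holoenzyme flavin is an
ambiguity of the correction as stated, and no attempt is made to separate
the bound-cofactor contribution.  An over-correction clamps at zero with a
warning.

Ionic strength is ½Σcᵢzᵢ² over all ions of each buffer component, in mM;
the inhibitor series are run iso-ionic because fumarate is doubly charged
at pH 7, so each mM of its disodium salt contributes 3 mM.

## Fitting and model discrimination

All fits minimise the unweighted sum of squared rate residuals (equal
weighting of points; no robust loss).  Parameters are optimised on a log
scale, which enforces positivity without hard bounds, using
Levenberg–Marquardt least squares (SciPy) with tolerances of 1e-14 on
cost, step and gradient — tight enough that noiseless generator→fitter
round-trips recover parameters to well under 0.1 % from starts perturbed
by ±50 %.  Start values come from apparent Michaelis–Menten fits of the
two uninhibited arms; the inhibition constants seed at the median positive
inhibitor concentration.

Uncertainties are asymptotic: the covariance of the log-parameters is
s²(JᵀJ)⁻¹ at the optimum, transformed to the linear scale by the delta
method.  Per-parameter p-values are two-sided t-tests of estimate/SE with
n−p degrees of freedom, the convention of common curve-fitting software.
A Ki requested without any positive inhibitor concentration in the design
raises a non-identifiability error before fitting; a near rank-deficient
Jacobian at the optimum (condition number above 1e10) warns instead, since
the fit is still the least-squares optimum even when an effectively
infinite Ki leaves its own value undetermined.

Nested variants are compared by the extra-sum-of-squares F-test,
F = ((RSS_r − RSS_f)/Δdf)/(RSS_f/df_f), at α = 0.05.  Two numerical
tie-breaks: if the full model's RSS is not below the reduced one's, F = 0
and p = 1; and when a fit's RSS falls below 1e-20 of the total squared
signal it is treated as numerically exact, so noiseless data cannot
produce spurious F statistics from floating-point residuals.
`detect_inhibition` walks the ladder: fit the no-inhibition model, test
each single-half variant against it, keep the lower-RSS significant one,
then test the two-Ki model against the survivor.

## Synthetic data

The generator reproduces the structure of the real experiments: two arms
(one substrate varied at a fixed concentration of the other, and vice
versa), each arm crossed with an inhibitor series that always contains a
zero-level control, with replicates per point.  Noise is multiplicative by
default — v·(1 + CV·ε) with ε standard normal, clipped at zero — because
spectrophotometric slope error scales with the signal; CV defaults to
0.05.  An additive-noise alternative is available.  Every dataset records
its full provenance (parameters, design, seed, package version) and a
fixed configuration reproduces its CSV byte-for-byte.

Preset designs encode the published study conditions: fumarate/NfsA
(nitrofurazone varied at 100 µM NADPH, NADPH varied at 75 µM
nitrofurazone, fumarate 0–2000 µM at 50 mM ionic strength),
succinate/NfsA (NADPH arm at 30 µM nitrofurazone, succinate 0–30 mM at
150 mM ionic strength) and NfsB (arms fixed at 100 µM NADH and 300 µM
nitrofurazone, candidate inhibitor at 0 and 1 mM).  Substrate grids are
7-point two-fold dilution series topping out near 10× the relevant Km —
the published figures show but do not tabulate their grids, so the grids
are package defaults, as is the replicate count (n = 3).  The NfsB
generating parameters (kcat 36 s⁻¹, Km 20 µM NFZ, 32 µM NADH) combine the
per-arm apparent constants reported for that enzyme into one uninhibited
global set.  Enzyme concentration defaults to 0.01 µM (~10 nM).

Progress curves are simulated as linear bleaching of the chromophore at
v·Δε·ℓ, with optional Gaussian read noise and an optional
substrate-depletion mode that integrates d[A]/dt = −v by fixed 10 ms Euler
steps so curves flatten as substrate runs out.

What the generator does *not* emulate — and hence what passing tests do
not establish about real assays: instrument drift and inner-filter
effects, enzyme inactivation over the trace, product inhibition, NADPH
absorbance overlap at 420 nm, and any heteroscedasticity beyond the
constant-CV model.

## Structure geometry

Coordinates are parsed with gemmi (PDB, mmCIF optional); the default
alternate-location policy keeps the highest-occupancy conformer of each
atom.  Contacts are distance-only criteria, appropriate for crystal
structures without hydrogens: ligand O/N to protein or cofactor O/N within
3.5 Å counts as a hydrogen bond; ligand O to Arg/Lys/His side-chain N
within 4.0 Å counts as a salt bridge (reported once, as the salt bridge);
ligand C to any C within 4.0 Å as nonpolar/stacking.  Waters are excluded
by default.  Fumarate's flavin-stacking geometry is summarised as the
distances of its two olefinic carbons (atoms C2/C3) to the FMN N5, the
hydride-transfer position.

Backbone superposition uses the Kabsch algorithm (SVD with a determinant
correction, so the rotation is always proper); atoms are paired by
(chain, residue number, atom name), falling back to residue-number pairing
for two single-chain models with different chain ids.  The default atom
set is CA; the RMSD between a ligand complex and the free enzyme depends
mildly on that choice, which is why it is configurable.  For crystals with
one subunit per asymmetric unit, `expand_crystal_symmetry` regenerates the
symmetry mates from the deposited cell and space group so that
partner-subunit ("primed") contacts are visible.

The test suite exercises this module on programmatically built synthetic
fixtures (including a labelled active-site mimic constructed to the
geometry observed in the NfsA–fumarate complex); deposited coordinate
files can be analysed with the same calls when available locally.

## Problem sizes and numerical choices

The standard simulated dataset is 70 points per inhibitor level pair
(2 arms × 7 concentrations × 5 levels × 1 replicate = 70 noiseless points,
or 210 with triplicates), which a global 5-parameter fit solves in
milliseconds.  The model-selection reliability check uses 100 seeds at 5 %
noise.  The brute-force oracles (20³ parameter grid for the optimizer
check; nested Euler-angle grid search for superposition) are deliberately
exhaustive rather than clever, since their only job is independence from
the code paths they validate.
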