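# Methods

## Equilibrium model of self-assembly and unfolding

The core model treats the native ensemble as linked dissociation
equilibria, octamer → tetramer → dimer → folded monomer → unfolded
monomer, with three temperature-dependent constants: `K_o` (association,
per molar, shared by both higher-order steps), `K_d` (dimerization,
per molar) and `K_U` (unfolding, dimensionless). Each follows the van't
Hoff relation with an enthalpy and a reference temperature; `K_U` is
referenced at the melting temperature where it equals one, so the model
has eight parameters: `T_O, T_D, T_m, dH_O, dH_D, dH_U, K_o(T_O),
K_d(T_D)`.

Internal units are kelvin, molar and joules with R = 8.314 J/(mol K);
converters (Celsius, micromolar, ...) live at the IO boundary only.
Association constants are stored; dissociation constants `K_O = 1/K_o`,
`K_D = 1/K_d` are exposed for reporting, since experimental work quotes
dissociation values.

**Mass balance.** Protomer conservation gives a degree-8 polynomial with
exactly one positive root (single sign change). The solver works in the
folded-monomer variable `[N] = [U]/K_U` — algebraically identical to the
polynomial in `[U]` but avoiding the `K_U^-8` coefficient blow-up at low
temperature — and uses 100 vectorized bisection steps on the bracket
`[0, C]`, which always contains the root. Robustness was preferred over
Newton-type speed; the bracket shrinks by 2^-100, far below the 1e-14
relative target, and the returned concentrations are verified against
the balance to 1e-9 relative (1e-15 absolute at C = 0).

**Heat capacity.** `ln Z` is not differentiated analytically; central
finite differences with a 0.01 K step are applied on a 0.1 K internal
grid and interpolated to the requested temperatures (`internal_step=None`
evaluates the stencil directly on the data grid inside fitting loops,
where curves are compared on coarse experimental grids). The output is
the excess molar heat capacity with no instrument baseline. Peak
counting uses a prominence filter of 2% of the curve amplitude to ignore
finite-difference ripple. Heat-capacity grids are restricted to
(250, 400) K; the mass-balance itself is defined for any positive
temperature.

**Presets.** `wt_150mM` encodes the physiological ionic-strength
condition: the dimerization and oligomerization parameters are obtained
by two-point van't Hoff inversion of the dissociation constants at 25
and 37 C (K_D 0.5 → 8 uM, K_O 30 → 45 uM: strongly and weakly
temperature-dependent respectively). The remaining unfolding pair was
chosen once, by scanning, to satisfy the qualitative calorimetric
pattern this condition shows — two resolved Cp maxima at 15 uM
protomer, a single peak by 141 uM, and a peak temperature that does not
decrease with concentration — and is frozen at dH_U = 130 kJ/mol,
T_m = 342.15 K. `wt_300mM` (high osmolarity; its constants are not
independently published) uses K_D 5 → 25 uM and K_O 20 → 30 uM, chosen
once to encode weaker dimerization, slightly stronger oligomerization
and hence a single cooperative transition at all concentrations.

## Calibration (model_fit)

Absolute DSC baselines are instrument-dependent and the steep
pre-transition region precludes direct fitting, so the objective is
semi-quantitative: per thermogram, the mean squared difference between
peak-normalized model and experimental excess Cp (invariant to uniform
rescaling of the measurement); plus squared species-fraction differences
against AUC-derived population tables. Default weights are 1:1 and
configurable. Model-evaluation failures return a large finite penalty
(1e6) rather than raising, so global optimizers can traverse bad
regions.

The van't Hoff parameterization makes each (T_ref, K_ref) pair a gauge
freedom; the fit therefore pins T_O = T_D = 298.15 K and searches six
identifiable parameters (three enthalpies, T_m, two log10 reference
constants). The global stage is seeded differential evolution (Sobol
initialization, deferred updating), followed by a Nelder-Mead polish
clipped to the bounds. Accuracy is defined by parameter recovery on
synthetic data: noiseless four-concentration datasets recover the
dissociation constants within a factor of two and T_m within 1 K;
with 2% peak-amplitude Gaussian noise, within a factor of three. The
test and acceptance runs use 36-point temperature grids, four
concentrations, two population tables and a differential-evolution
budget of maxiter 40 / popsize 10 — sizes at which the recovery
contracts above hold with comfortable margin.

Baseline subtraction offers a linear baseline through two transition-free
anchor windows or a sigmoidal (progress-weighted) chemical baseline; the
progress variable is the normalized cumulative excess area, iterated
three times.

## AUC populations (hydro)

Populations are trapezoidal areas of c(s) over per-species windows,
normalized over all windows; absorbance is proportional to protomer
mass, so signal fractions are protomer-mass fractions (identity mode)
and a molar mode divides by stoichiometry 8/4/2/1 and renormalizes.
Default windows are anchored on the bead-model reference s-values (1.1,
1.6, 2.4, 3.5 S) with cuts at geometric midpoints (1.33, 1.96, 2.90 S);
the monomer window opens at the grid start and the octamer window runs
to the grid end. Integration limits are an operational choice — the
source experiments do not define them — and under reaction-boundary
conditions peaks shift with loading concentration, so any window whose
maximum falls within 10% of the window width of an edge is flagged
rather than silently re-apportioned. A dimer peak observed at 2.1 S
(above the 1.6 S dilute-limit reference) is the canonical case: the
default windows flag it, and the analyst assigns it via explicit
windows.

## Binding analyses

* **Hill fit**: `signal = smin + (smax - smin) * c^n/(K^n + c^n)` with
  free amplitudes (anisotropy and fluorescence baselines are arbitrary),
  fitted by least squares in log10-concentration with the midpoint
  parameterized as log10 K. Reported intervals are 68% confidence
  (estimate ± one standard error from the covariance). A midpoint
  outside the data range sets a warning flag.
* **1:1 reference**: exact ligand-depletion quadratic, evaluated in the
  cancellation-safe form `2PL/(b + sqrt(b^2 - 4PL))`.
* **Apparent K_D from derivatives**: when no mechanistic model applies
  (polydisperse binder, multiple modes), the isotherm is re-gridded onto
  an even log10-concentration axis, smoothed by a 7-point local
  quadratic (Savitzky-Golay; the window is configurable and odd), and
  maxima of d(signal)/d(log c) are reported in ascending order. For a
  Hill curve the derivative peaks exactly at K_1/2. The signal is
  min-max normalized first, making the result affine-invariant; peaks
  need 5% of the maximum derivative in height, so a flat signal returns
  an empty list. The non-saturating high-concentration regime is
  reported as a detected inflection, not modeled mechanistically.
* **Coupling free energy**: `RT ln(K_a/K_b)/1000` kJ/mol, signed.
* **Intensity-averaged wavenumber**: `1e4 * sum(I/lambda)/sum(I)` with
  lambda in nm (units of 1e3 cm^-1), a robust scalar for combined
  intensity/wavelength shifts of emission spectra.

## Block-WSME ensemble model

Each block of consecutive residues is folded or unfolded; allowed
microstates are the fully unfolded state, single contiguous stretches,
and pairs of disjoint non-adjacent stretches — `1 + nu(nu+1)/2 +
C(nu+1, 4)` states for `nu` blocks. The default block size is 2 (the
137-residue chain gives 69 blocks and 919,311 states); block size is
configurable and the count is validated against this closed form.

Microstate free energy (relative to the unfolded reference) sums over
native contacts inside folded stretches: a van der Waals term per
contact (default -102 J/mol), implicit solvation per contact
`dCp * ((T - T_ref) - T ln(T/T_ref))` with dCp = -0.36 J/(mol K) and
T_ref = 385 K (T_ref is not independently fixed by the data and is
documented as a free knob), and Debye–Hückel screened Coulomb terms for
charged residues in contact (charges at pH 7: D/E -1, K/R +1, H 0,
termini ±1; dielectric 78.5; Debye length from the ionic strength at the
evaluation temperature; the per-pair distance is the minimal heavy-atom
distance from the contact map). Folded residues pay -T * dS_res with
dS_res = -16.5 J/(mol K). Contacts spanning two distinct stretches are
excluded by default (strict double-sequence approximation); an
interacting-stretch option exists but defaults off.

Thermodynamic sums exploit the factorization of two-stretch weights:
stretch free energies come from 2D inclusion–exclusion over a block-pair
energy matrix, and residue probabilities from prefix-sum recursions in
log space — O(nu^2) per temperature, no ensemble materialization, safe
at any temperature via log-sum-exp. Coupling maps enumerate the ensemble
explicitly (chunked, so memory stays bounded) to obtain joint
fold/unfold probabilities.

The coupling free energy is an operational log-odds measure,
`dG_c(i,j) = RT ln[P_ff P_uu / (P_fu P_uf)]`: zero for independent
residues, positive for residues that fold and unfold together (through
contacts or population redistribution), +inf on the diagonal, and a
signed-infinity sentinel (with a flag matrix) when a joint probability
vanishes — residues that never fold together report -inf. Difference
maps subtract two coupling matrices elementwise (ignoring sentinels) and
reduce per residue to the signed extremum over partners.

**H-NS model.** No coordinate set of the full-length monomer is
deposited, so the packaged model uses a synthetic contact map: helical
i/i+2,3,4 contacts inside the dimerization site, backbone helix and
DNA-binding domain (DBD), hairpin-style tertiary contacts inside the
DBD, none in the linker, with densities (documented in `bwsme_hns`)
chosen to encode the qualitative stability pattern of the protein —
flexible linker, marginally stable dimerization site melting in the
physiological range, strongly helical backbone, independently folding
DBD. Charges come from the real 137-residue sequence. Following the
experimental anchor that the DBD melts at 57 C independent of
concentration, the van der Waals energy per contact is calibrated by
bisection (0.1 K tolerance) to that midpoint; the calibrated value is
about -96 J/mol per contact. The Y61E phosphomimetic is encoded as a
charge substitution at position 61 with unchanged contact topology.

## Synthetic data

Generators produce model heat capacity plus linear baseline and additive
Gaussian noise; multi-Gaussian c(s) distributions with prescribed areas
(clipped at zero); Hill, 1:1 and two-mode isotherms; Gaussian emission
spectra; and ideal-geometry PDB structures (NeRF-built alpha-helices at
phi,psi = -57,-47 with N/CA/C/O/CB atoms, plus an antiparallel
helix-hairpin variant). All are pure functions of (parameters, seed).

What the generators deliberately do not emulate: partial unfolding
within oligomers (excluded from the equilibrium model itself), coupled
sedimentation (reaction boundaries) in c(s) — peaks sit where they are
placed — correlated or multiplicative instrument noise, scan-rate
effects in DSC, inner-filter and photobleaching artifacts in
fluorescence, and real side-chain packing in structures. Passing tests
therefore demonstrate the correctness and identifiability of the
analyses under idealized noise, not robustness to every instrumental
systematic of the corresponding experiments.

## Numerical choices and degenerate inputs

* Mass balance at C = 0 returns the empty system; partition terms are
  undefined without folded monomer and raise a degenerate-state error.
* Unfolding-curve midpoints that never cross one-half in the search
  window (always-unfolded linker, fully stable segment) return NaN;
  calibration maps such cases to the window edge to keep its bracket.
* Hill fits retry from jittered starts (seeded) on non-convergence.
* Boltzmann statistics everywhere go through log-sum-exp; no weight is
  ever exponentiated before normalization.
* Tie-break in diff-map extrema: `argmax` takes the first of equal
  absolute values (lowest partner index).

## Known limitations

* The equilibrium model has a single oligomerization constant above the
  dimer and no partial unfolding within oligomers; more complex schemes
  need more parameters than the data constrain.
* Window integration cannot apportion overlapping c(s) peaks; it flags
  them.
* The bWSME H-NS model is monomeric: dimer/oligomer ensembles are out of
  scope, and the synthetic contact map reproduces stability patterns,
  not atomic detail; coupling maps should be read comparatively (wild
  type vs variant), not as absolute energies.
* The coupling estimator is an operational definition; other pairwise
  linkage measures would order pairs similarly but differ in scale.
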