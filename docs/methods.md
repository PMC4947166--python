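# Methods

This note records the models implemented in `structms`, the assumptions
behind them, the defaults that matter, and what the synthetic generators do
and do not emulate. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Native-MS interpretation

Peaks are treated as centroided positions of unresolved native envelopes;
the only charge carrier modelled is the proton (1.007276 Da). Charge-series
assignment hypothesises a neutral mass from every (peak, charge) anchor,
extends it across the allowed charge range, and accepts a series when at
least two consecutive charges match within a mass tolerance (default
100 ppm, appropriate to broad native peaks). Overlapping candidates are
resolved greedily by summed intensity with a longest-series tie-break —
deterministic, and the same order of preference a manual annotator uses.
The neutral mass is the intensity-weighted mean of per-charge masses; its
weighted standard deviation is reported as the spread.

Centroids of adducted native peaks sit to the right of the bare-mass
position (the bare mass corresponds to the left edge of the peak), so an
optional left-edge mode subtracts a user-estimated tail width; it is off by
default because the package operates on centroids as given.

**Ligand counting.** `stoichiometry` defaults to an *adduct-aware* rule:
unresolved salt adducts can only add mass, so the ligand count is the
largest integer leaving a non-negative residual (with a slack of 0.1 ligand
masses to absorb centroid noise). A plain nearest-integer mode is
selectable. The distinction matters in practice: a 1,342.6 Da mass
difference against a 525 Da cofactor is two cofactors plus ~293 Da of
adducts, not three cofactors minus 232 Da.

Sequence-predicted masses are user inputs, not computed: the package has no
sequence for the construct and does not guess one. Likewise `adduct_mass`
evaluates user-supplied compositions (count × (neutral mass − displaced
protons × m_H)) rather than inferring a composition from a residual, which
is underdetermined.

## Drift-tube mobility and CCS

Constants: e = 1.602176634·10⁻¹⁹ C, k_B = 1.380649·10⁻²³ J/K, gas number
density at the 273.15 K / 760 torr standard state N = 2.6868·10²⁵ m⁻³;
buffer gas helium (4.002602 Da); all unit conversions live in
`structms.constants`.

The dead time t₀ is the intercept of mean arrival time against
x = P/(T·V). This regressor is the exact linear variable implied by the
drift-time form of the Mason–Schamp relation when P and T are recorded per
run, which is why the fit is exact (r² = 1) on noiseless synthetic sets.
The mean arrival time is computed on the dominant peak only (apex ±
2 × FWHM) so that minor conformers do not bias the calibration. A fitted
negative t₀ is clipped to zero with a warning.

`ccsd_from_run` converts every histogram bin by the closed-form drift-time
expression; `reduced_mobility` + `mason_schamp_ccs` implement the K₀ route
separately, and the test suite asserts bin-for-bin agreement below 1e-9
relative — a genuine dual-route check rather than one function calling the
other. Bins with t_d ≤ 0 after dead-time subtraction are dropped with a
warning. A CCSD can optionally be resampled onto a uniform 5 Å² grid
(intensity rescaled by local bin width, i.e. the Jacobian of the nonlinear
t → Ω map) for cross-charge-state comparison; the native, unevenly spaced
grid is the default because it conserves per-bin intensity exactly.

## Conformer families

A CCSD is modelled as Σᵢ aᵢ exp(−(Ω−cᵢ)²/2σᵢ²). The reference fit (free
centres, widths, non-negative heights) uses Levenberg–Marquardt (lmfit)
with centres initialised equally spaced across the support and 10 seeded
multi-start jitters; families are returned sorted by centre. Across other
charge states and stoichiometries the centres *and* widths are frozen and
only amplitudes are refit by non-negative least squares — the closest
reading of "retained across"; refitting widths as well is the natural
alternative and would only require passing the previous fit's families as
initial values to a fresh free fit. Populations are Gaussian areas
(a·σ·√2π) normalised per fit.

The number of families k is a user parameter (the study system used 4,
plus a fifth for the apo 22+ ion); `select_k_bic` offers a Bayesian
information criterion helper since no principled selection rule is implied
by the procedure itself. Unfolding profiles use the intensity-weighted
centroid per activation voltage — drift-time axis for raw runs, CCS axis
for CCSDs — with onset at the first voltage exceeding the lowest-voltage
baseline by 10 % (a package default; the procedure itself fixes no
threshold).

## Geometric CCS models

**Sphere limit.** V = M_w/ρ with ρ = 0.904 Da Å⁻³, r = (3V/4π)^(1/3),
Ω = scale·πr². The widely quoted geometric-to-helium conversion factor is
1.19; with this density that factor gives ≈3,580 Å² for a 112,270 Da
dimer, whereas reported lower bounds for the same inputs correspond to a
factor of ≈1.14. The package default is 1.14, with 1.19 selectable
(`SPHERE_SCALE_LITERATURE`); both are exposed because the literature is
internally inconsistent at the ~4 % level.

**EHSS.** Orientations are uniform random rotations (quaternion method,
seeded); per orientation, impact points are sampled uniformly on the disc
enclosing the projection (radius = max projected extent + largest atom
radius, recomputed per orientation), and each probe line is traced through
specular reflections off spheres of radius (atom radius + probe radius)
until escape, capped at 1,000 bounces (a capped trajectory keeps its
current deflection and logs). The momentum-transfer weight (1 − cos χ)
averaged over the disc times the disc area gives the per-orientation cross
section; the reported stderr is the between-orientation standard error.
For a single sphere the exact value is the geometric cross section, which
the Monte Carlo reproduces within its stderr; the projection approximation
(same sampling, hit-test only) is a strict lower bound.

Default radii are the helium-calibrated hard-sphere set of the EHSS
lineage (H 2.2, C 2.7, N 2.7, O 2.7, S 3.1 Å) with probe radius 0 — these
radii already include helium. A van der Waals + probe mode is provided.
Structures without hydrogens fail fast by default; a crude united-atom
mode inflates heavy-atom radii by 0.2 Å instead. Because published EHSS
implementations differ slightly in radii, absolute agreement with values
computed elsewhere is expected at the ~2 % level, not exactly.

**Shape summaries.** R_g is the unweighted root-mean-square distance from
the centroid (whole structure or backbone N/CA/C/O selection);
mass-weighting is a defensible alternative and trivially added, but the
unweighted convention is used and flagged. SASA is Shrake–Rupley
quadrature on a golden-spiral lattice (default 960 points/atom, probe
1.4 Å); single-sphere and two-sphere cap geometries are reproduced to the
quadrature tolerance.

## Differential HDX-MS

Exchangeable amides per peptide follow the DynamX convention,
len − 1 − (prolines after the first residue). Replicate-mean uptake is
divided by that count for relative fractional uptake. The summed
difference is Σ_t (mean apo − mean holo) per peptide, also expressed as a
percentage of the maximum possible summed uptake (n_t × exchangeable); the
t = 0 row is included (it contributes ≈0) and no back-exchange correction
is applied, matching the uncorrected-relative-uptake convention of the
consumed tables. Classification uses the plain >5 % threshold on the
per-residue projection (mean over covering peptides, residues start..end
inclusive); the threshold is applied to the summed relative difference —
a per-timepoint reading of the threshold is the documented alternative. A
per-timepoint two-sample test with a global α exists as a clearly-labelled
stricter extension, off by default because the baseline procedure is
purely threshold-based.

## Synthetic generators: what they emulate, and what not

All generators are pure functions of their arguments including the seed,
and attach their generating parameters as ground truth. Defaults encode
the study conditions: dimer envelopes at z = 19–23; a 525 Da cofactor; a
5.1 cm drift tube, six voltages from 20 to 50 V, helium at ~4 torr and
303.15 K; conformer families at 4,550 / 5,085 / 5,736 / 6,400 / 7,042 Å²
with σ = 150 Å² (widths are never printed in practice; 150 Å² makes
adjacent families overlap realistically); HDX exposures 0, 0.25, 5, 60,
240 min in triplicate over a 505-residue chain, with destabilised apo
regions 187–197, 223–240, 441–450 (protection ÷5) and protected apo
regions 108–123, 460–465 (protection ×5).

ATD peaks are Gaussians at t₀ + t_d with the diffusion-limited width
σ_t = t_d·√(16 k_B T ln2 / z e V)/(2√(2 ln2)); no mobility-dependent
transmission, detector saturation or space charge is modelled. The cell
pressure is jittered per run (0.5 % default) to exercise the regression;
temperature is held at its set point, which keeps the arrival-time/x
relation exactly linear — real data adds small temperature drift on top.
"Timing noise" is a per-run arrival-time offset ~N(0, fraction × t_d).
HDX kinetics use a single representative intrinsic amide rate (1 min⁻¹)
modulated by protection factors rather than sequence-dependent rate
tables — statistically structured like real uptake curves but chemically
non-physical, and labelled as such. Consequently, passing tests demonstrate
correctness of the analysis pipeline against known generative models, not
instrument-level realism.

## Numerical choices and problem sizes

Charge-series tolerance 100 ppm; family fits use 10 restarts with a fixed
seed; NNLS for amplitude refits is deterministic. Test-suite problem sizes
are chosen to finish in tens of seconds on one core while leaving
comfortable statistical margins: 20,000-draw CCSDs, 50-repeat dead-time
Monte Carlo, EHSS at 32–256 orientations × 250–1,500 impacts, 20-seed HDX
region-recovery sweeps. Degenerate inputs fail loudly: empty series,
all-equal regressors, non-physical drift times, all-zero amplitude
solutions and uncovered residues all either raise or warn as documented in
the docstrings.

## Known limitations

Travelling-wave calibration, pressure-gradient corrections and ion-heating
models are out of scope; trajectory-method and diffuse-scattering CCS are
not implemented (EHSS and PA only); isotope-resolved deconvolution is not
applicable to unresolved native peaks; HDX analysis is peptide-level only
(no EX1/bimodal analysis, no spectral deconvolution); PDB is the only
structure format, with altloc A retained and waters stripped.
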