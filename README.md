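# structms

Structural mass spectrometry of protein–cofactor complexes: a Python
toolkit for the analysis chain used to show how a non-covalently bound
cofactor changes the conformational landscape of a protein dimer — native
MS for mass and stoichiometry, drift-tube ion mobility for collision cross
sections (CCS), Gaussian deconvolution of CCS distributions into conformer
families, geometric CCS models on atomic coordinates, and peptide-level
differential hydrogen–deuterium exchange (HDX-MS).

The motivating system is the fungal ferulic acid decarboxylase Fdc1, a
~112 kDa homodimer whose prenylated-FMN (prFMN, 525 Da) cofactor compacts
and stabilises the fold. The package is written for mass spectrometrists
and structural biologists who want the same measurements on their own
systems, and every stage can be exercised on seeded synthetic data with
known ground truth — no instrument files required.

## What it computes

**Native MS** (`structms.spectra`). A native electrospray spectrum of an
intact complex shows peaks [M + *n*H]^*n*+ over a narrow charge range. From
centroided (m/z, intensity) lists the package assigns charge-state series,
estimates the neutral mass as the intensity-weighted mean of
*z*·(m/z − m_H) across the series, counts bound ligands from mass
differences (`stoichiometry`), and accounts residual mass as salt adducts
(`adduct_mass`).

**Ion mobility** (`structms.mobility`). Arrival times recorded at several
drift voltages are regressed on *P*/(*T·V*) to remove the instrument dead
time *t*₀; drift times then give reduced mobilities
*K*₀ = (*L*²/*t*_d*V*)(*P*/760)(273.15/*T*) and CCS via the Mason–Schamp
relation

&nbsp;&nbsp;&nbsp;&nbsp;Ω = (3*ze* / 16*N*) · √(2π / μ*k*_B*T*) · 1/*K*₀,

with μ the ion–helium reduced mass. Whole arrival-time histograms map to
CCS distributions (CCSDs).

**Conformer families** (`structms.conformers`). CCSDs are decomposed as
sums of Gaussian conformational families fitted once on a reference
distribution and then frozen (centres and widths) across charge states and
cofactor stoichiometries, with only non-negative amplitudes refit; the
package reports fractional populations per family and detects
collision-induced-unfolding onsets from centroid-vs-activation-voltage
profiles.

**Geometric CCS** (`structms.geometry`). Three estimators on hard-sphere
atomic models: the spherical-density lower bound
Ω_min = scale · π(3*M*_w/4πρ)^(2/3) with ρ = 0.904 Da Å⁻³; the projection
approximation (orientation-averaged shadow area); and exact hard-sphere
scattering (EHSS), which traces specular reflections of a probe line and
weights deflections by (1 − cos χ). Plus radius of gyration and
Shrake–Rupley solvent-accessible surface area for trajectory frames.

**Differential HDX-MS** (`structms.hdx`). From DynamX-style peptide uptake
tables: relative fractional uptake (uptake / exchangeable amides), apo −
holo summed uptake differences, >5 % threshold classification of contiguous
residue regions with elevated exchange in either state, and per-residue
projection for structure colouring.

**Synthetic data** (`structms.synthetic`). Seeded, pure-function generators
for every input above, each returning a ground-truth sidecar: charge-state
envelopes with adduct tailing, multi-voltage arrival-time sets from known
mobilities, Gaussian-mixture CCSDs, apo/holo uptake tables from a
protection-factor model, and toy structures with closed-form reference
values.

## Worked example

The smallest cross section the 112,270 Da dimer could present, assuming a
close-packed sphere:

```
$ structms geometry sphere-limit --mass 112270
{
 "ccs_A2": 3430.777179425621
}
```

about 14 % below the most compact conformer actually observed (~4,000 Å²),
i.e. the measured ion is near-globular but not a solid sphere. Ligand
stoichiometry from two measured masses — the doubly bound dimer is two
cofactors plus ~293 Da of retained metal/buffer adducts:

```
$ structms spectra stoich --mass-bound 113609 --mass-apo 112266.4
{
 "count": 2,
 "residual_da": 292.6000000000058
}
```

A full synthetic mobility calibration — generate six drift voltages at a
known reduced mobility with a 0.25 ms dead time, recover the dead time from
the multi-voltage regression, and convert one run to a CCSD:

```
$ structms synth atd --k0 2.2 --seed 1 --out-dir atd
$ structms mobility t0 atd/run_manifest.txt
{
 "t0_ms": 0.25000010111899384,
 "slope": 4249.181467739638,
 "r_squared": 0.9999999999998033
}
$ structms mobility ccsd atd/run_manifest.txt --out ccsd.csv
t0 = 0.2500 ms; CCSD apex 5071 A^2 -> ccsd.csv
```

The recovered dead time matches the programmed 0.25 ms and the CCSD apex
sits at the CCS implied by K₀ = 2.2 cm²V⁻¹s⁻¹ for this 21+ ion.

Every command has a library-level equivalent; see the module docstrings.

## Layout

```
src/structms/     spectra, mobility, conformers, geometry, hdx,
                  synthetic, io, cli, constants
tests/            unit, property and acceptance suites (pytest)
docs/methods.md   models, assumptions, parameter choices, limitations
scripts/          acceptance.py
```
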