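# Methods

`dmsprops` implements a complete, testable analogue of a differential
mobility spectrometry (DMS) property-screening study: raw compensation-
voltage scans are reduced to dispersion curves, the curves are classified
and featurized, and a random forest predicts condensed-phase molecular
properties, validated by leave-one-out and learning curves.  Because no
instrument data ship with the package, a synthetic-data generator with
known ground truth defines the study conditions; this note records the
models, the defaults and why they were chosen, and what the passing tests
do and do not demonstrate.

## The dispersion-curve model

A dispersion plot records, for one ion, the optimal compensation voltage
CV against separation voltage SV under fixed gas conditions.  The
generator uses the family (with `u = SV / sv_max`, `sv_max` = 4000 V)

```
CV(SV) = amplitude_c · u³  −  a_eff · u^p · exp(−(p/q)·(SV/turn_sv)^q)
```

* The positive cubic term is the leading odd-power (hard-sphere)
  expansion of differential mobility; `amplitude_c` (V) scales with
  molecular size.
* The damped power term models ion–solvent clustering that collapses at
  high field.  The `p/q` factor in the exponent places the minimum of
  the clustering term exactly at `SV = turn_sv` for any shape exponent
  `p`, so `turn_sv` is the type-B turn-around voltage.  The damping
  exponent is fixed at `q = 4`; the low-field exponent is held at
  `p = 1.8` campaign-wide (per-molecule variation in `p` is a nuisance
  dimension that carries no property information here).
* Temperature enters through
  `a_eff = amplitude_a · exp(−(T − 150 °C)/300 °C)`: hotter gas, weaker
  clustering, shallower negative excursion — strictly monotone, which
  the tests assert.
* The four behavior archetypes are realized as: type A (`amplitude_c = 0`,
  `turn_sv = sv_max`, monotone non-increasing), type B (both terms, an
  interior minimum), type C (`amplitude_a = 0`, monotone non-decreasing),
  and "complex" (a sinusoidal modulation term adding multiple reversals).

The sampled latent for clustering strength is the excursion **depth** D
(V) — the depth of the negative CV excursion — from which `amplitude_a`
is solved given `turn_sv` and `amplitude_c`.  Sampling the depth rather
than the raw amplitude keeps clustering strength statistically
independent of molecular size (the raw amplitude must grow with the
hard-sphere term for a type-B dip to be visible at all, which would
otherwise leak size information into every clustering-linked property),
and guarantees every type-B curve a discernible (≥ 1.5 V) turn-around.

## Property labels and the variance budget

Labels are affine links plus Gaussian noise:

```
g(D, t, ccs) = b0 + bd·D + bt·turn_sv + bc·(1000/CCS)
```

with per-property coefficients in `synthetic.PROPERTY_LINKS` and noise
levels in `synthetic.DEFAULT_NOISE_SD`.  The ground-truth CCS is
`(120 + 24·amplitude_c) · exp(0.20·z)`, z ~ N(0,1): the first factor is
the size information visible in the dispersion curve, the lognormal
factor is size information *not* encoded in the curve.  Only
permeability carries a CCS term (`bc = 0.25`·…, see source).  The
coefficients were set from a variance budget so that, at default noise,

* curve-derived terms explain most of the permeability variance
  (DMS-only features give a strong but imperfect fit),
* the curve-independent part of CCS contributes a measurable share
  (adding the CCS descriptor closes most of the remaining gap),
* CCS alone explains little (the negative control stays below R² 0.3).

A consequence worth noting: because CCS deliberately carries an
independent lognormal component (log-sd 0.20), predicting CCS itself
from DMS features bottoms out at a mean absolute percent error of
roughly fifteen percent at default noise — the irreducible share is the
independent factor itself.  With all noise off, CCS becomes an exact
function of `amplitude_c` and is fully recoverable.

The default campaign mixes ten topology classes (two quinoline families,
four intramolecular-hydrogen-bond topologies, four covalent-reactive-
group motifs) with class-specific behavior-type weights, depth baselines
and size ranges, in proportions 10/22/9/8/8/8/6/6/6/6 per 89 molecules.
Label missingness defaults mimic a screening database where pKb, EPSA
and logD are known only for subsets (≈ 52/89, 43/89, 34/89 present).
`noise_scale` multiplies every stochastic amplitude — label noise and
the 0.15 V CV measurement noise alike — so `noise_scale = 0` yields a
dataset in which every label is an exact function of the curve
parameters; this is the configuration for parameter-recovery tests,
whose premise is that the signal is fully recoverable.

## Ionogram processing and classification

Peak extraction fits `baseline + A·exp(−(cv − cv_opt)²/2σ²)` by
Levenberg–Marquardt least squares, initialized from the argmax and the
second moment; non-convergence and flat signals are flagged, never
raised.  Classification smooths the curve with a 3-point moving average
(edge points left unsmoothed — truncated windows would drag the
endpoints inward and can invert short curves), then applies excursion
logic with a 0.5 V prominence threshold: never rising above the running
minimum by more than the prominence → A; never falling below the running
maximum → C (a constant curve is the zero-differential-mobility
hard-sphere limit, also C); an interior minimum with a prominent drop
before, rise after, and no prominent re-dip → B, with the turn-around
refined as the vertex of the parabola through the minimum and its
neighbors; anything else → complex (an explicit class, not an error).
The defaults resist ~0.2 V CV noise: the acceptance test requires ≥ 95
correct calls on 100 noisy curves of known type and observes 99–100.

Separation between two species is scored as
`max over common SV of |ΔCV| / √(σ1² + σ2²)` — the number of combined
peak widths separating the ions at the most discriminating SV.

## Featurization

Curves are resampled by linear interpolation onto a shared grid
(default 0–4000 V in 250 V steps, 17 features); outside the measured
range the nearest CV is held and the point flagged in a coverage mask.
Per-property matrices drop molecules missing that label (never imputed),
sort rows by molecule id, optionally append the CCS descriptor, and
refuse the combination label = ccs with the CCS feature present.  Peak
widths are not used as features by default.

## Random forest and evaluation protocol

The regressor is a 500-tree random forest (scikit-learn backend;
bootstrap resampling, all features considered per split, scikit-learn
defaults otherwise, fixed `random_state`).  Evaluation follows two
protocols:

* **Iterative leave-one-out**: N retrainings for N molecules, each
  predicting only the withheld molecule.  R² is reported primarily as
  squared Pearson correlation, with the coefficient of determination
  alongside; MAE and mean absolute percent error (flagged undefined when
  any true value is zero) complete the summary.
* **Learning curves**: training fractions 0.1–0.6 in 0.1 steps, 10
  random by-molecule splits each — 60 distinct partitions — reporting
  mean and one standard deviation of train and test MAE per fraction.
  Per-split generators are seeded from (master seed, fraction index,
  repeat), so any split is reproducible in isolation.

Guard rails asserted in tests: no molecule in its own training fold (an
extreme-outlier label never contaminates its own prediction), shuffled
labels give median LOO R² < 0.2 over 20 permutation seeds (run at a
reduced size — 80 molecules, 100 trees — since a permutation null is
insensitive to both), and on CCS-dependent synthetic permeability the
ablation ordering R²(DMS+CCS) > R²(DMS-only) > R²(CCS-only) holds with
the CCS-only control below 0.3.

## Conformer search

The torsional model freezes bond lengths and angles and works purely in
dihedral space.  Energy = 12-6 Lennard-Jones (element-wise
Lorentz–Berthelot parameters) plus Coulomb on the carried partial
charges, over atom pairs three or more bonds apart (1-4 pairs scaled by
0.5), plus a three-term cosine torsion per rotatable dihedral (V1 = 0.8,
V2 = 0.4, V3 = 5.0 kJ/mol; the 3-fold barrier is set high enough that
staggered wells survive the Coulomb tilt of a +1 ion).  The analytic
dihedral gradient maps the cartesian pair gradient through each
dihedral's rotation generator and matches central finite differences to
1e-5 relative on clash-free chains.

Local minimization is L-BFGS in dihedral coordinates.  Basin hopping
perturbs every rotatable dihedral of the *running geometry* by at most
5° per step, minimizes a copy to identify the basin, and
Metropolis-accepts on minimized energies (kT = 2.5 kJ/mol ≈ 300 K; a
pure-descent mode is kT → 0).  The walk keeps the raw, unminimized
coordinates: with a 5° move cap, a walk that restarted from each basin
floor could never cross a torsional barrier, whereas the free diffusion
within a basin (all equal-minimized-energy moves accept) lets small
distortions accumulate.  Distinctness of stored minima uses energy
(0.1 kJ/mol) *and* circular dihedral RMSD (10°) jointly.  On the
one-dihedral test chain, 2000 steps recover all three wells of a
1°-grid-scan oracle for most seeds; the recovery is diffusion-limited
and stochastic, so the deterministic test pins a protocol seed.
Protonation-site enumeration attaches a proton 1 Å from a chosen
heteroatom (pointing away from the centroid), giving the proton +0.5 e
and the site +0.5 e; tautomers are out of scope.  Quantum refinement is
replaced by an XYZ export hook.

## Collision cross sections

CCS is computed by the Monte-Carlo projection approximation: average
over uniformly random orientations (unit-quaternion rotations) of the
projected area of the union of atomic disks of radius r_atom + r_probe,
each area estimated by uniform rejection sampling over the projection's
bounding box.  The shipped radius table (`vdw-n2-v1`) uses van der Waals
atomic radii with a 1.55 Å nitrogen-buffer probe.  The reported standard
error is the across-orientation standard error of the mean, which
includes the within-orientation sampling noise.  Tests check the
single-sphere closed form, a two-sphere quadrature oracle (to 0.5%),
rigid-motion invariance, union monotonicity, dimer additivity and the
~1/√n error scaling.  The projection approximation ignores long-range
potentials and multiple scattering; it is a size descriptor, not a
replacement for trajectory-method CCS values.

## Problem sizes and determinism

Default test and acceptance problem sizes — 120-molecule campaigns for
the regression checks, 89 for the screening-protocol bookkeeping, 500
noisy peaks, 100 classification curves, 2000 basin-hopping steps — were
chosen so the full pipeline re-runs comfortably on a single CPU while
keeping every statistical margin wide.  All randomness flows through
seeded `numpy` generators; fixed (config, seed) reproduces every output
byte-for-byte, which the suite asserts by hashing serialized datasets.

## Known limitations

* The synthetic curve family is a low-dimensional caricature: real
  dispersion plots reflect clustering thermodynamics, field heating and
  modifier chemistry that no five-parameter family captures.  Passing
  recovery tests show the *pipeline* is sound, not that real DMS data
  are this predictive.
* Property links are affine constructions; real structure–property
  relationships are not, and the 0.95 recovery bound is a property of
  the noise-free configuration only.
* One condition (150 °C, 1.5% methanol) feeds the feature pipeline;
  multi-temperature generation exists but no fidelity claim is made for
  how conditions combine.
* The toy potential has no bond/angle/inversion terms and is not a
  parameterized force field; its conformer energetics are illustrative.
* Single-peak ionogram fitting only; shouldered or co-eluting peaks are
  out of scope.
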