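# Methods

This note documents the models implemented in `junctionlab`, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical decisions taken where the design was
genuinely open.

## Junction representation

A four-way junction is built from four strands (X, R, B, H, the Lilley
labelling) of length 2·L; adjacent strand halves pair into four arms
(XR, RB, BH, HX), arm `s1s2` pairing the 3′ half of `s1` antiparallel
against the 5′ half of `s2`. Each nucleotide carries three
coarse-grained sites — sugar, phosphate, base — except that 5′ termini
have no phosphate, so a strand of n nucleotides contributes 3n − 1
sites; the reference junction (L = 17, 34-nt strands) has 404 sites and
68 base pairs. Nucleotide indexing is 0-based, 5′→3′ per strand.

The *core markers* are the eight bases flanking the branch point — by
default the innermost nucleotide of each strand half, overridable per
strand in the junction YAML. Four labelled non-complementary marker
pairs are tracked: TT and CC spanning strands X and H, AG1 and AG2
spanning R and B. These labels are strand-role names; under full
Watson–Crick complementarity of the arms the base identities at the
core slots cannot all be fixed independently (each X-half innermost
base is the complement of an H- or R-half innermost base), so the
shipped junction definition is an explicitly synthetic sequence and the
classifier uses geometry only. None of the four tracked pairs is a
complementary pair.

## Idealized conformer geometries

Templates are geometric scaffolds, not energy-minimized structures.
Arms are straight axes radiating from a common vertex with one base
pair per rise (default 3.4 Å) and the two base sites of a pair offset
±5 Å laterally (sugar ±8 Å, phosphate ±9.5 Å). Four conformers are
built: planar open (arms at 90° in a plane), tetrahedral open (arms
along tetrahedron vertices, 109.47°), and the two stacked isoforms as
two pseudo-duplex axes crossing at the vertex with the XR/HX angle set
to the nominal IDA (defaults: iso-I 140°, iso-II 90°).

What distinguishes the conformers for the distance classifier is the
core-marker placement:

- open templates put all eight markers on their arm axes at a fixed
  standoff (13 Å planar, 11.5 Å tetrahedral, with a common ±1 Å split
  separating the two markers of each arm), making all four marker-pair
  distances equal (18.4 / 18.8 Å) and above the 12 Å cutoff;
- stacked templates place the signature family (X/H markers for iso-I,
  R/B for iso-II) at 2.5 Å standoff with ±1.5 Å lateral offsets
  (pair distances ≤ 5 Å) and the complementary family at 11 Å standoff
  with ±9 Å offsets out of the axis plane (pair distances ≥ 18 Å), for
  every nominal IDA in (0°, 180°).

This guarantees at least a 6 Å margin on both sides of the 12 Å cutoff,
so 1 Å isotropic site noise (distance perturbations of scale σ√2)
essentially never crosses it — the basis of the ≥ 99 % classification
accuracy on rendered trajectories. A uniform coaxial construction with
a single lateral offset cannot achieve this separation (both marker
families end up equally close to the vertex), which is why the
per-family standoffs are used; the exact offsets are recorded in
`GeometryTemplate.params`.

Stacked templates are *calibrated*: the inter-axis angle is adjusted by
a bracketed root find until the measured IDA (vertex = centroid of the
eight core markers, arm direction = vertex → terminal-base-pair
centroid) equals the requested nominal value. The asymmetric core
placement shifts the marker centroid slightly off the axis crossing
(≈ 1–2° of IDA bias otherwise); calibration absorbs it, so a template
built at nominal 95.7° measures exactly 95.7°.

## Conformer classification and statistics

A frame is classified from its four core distances with a single
cutoff (default 12 Å, the minimum between the stacked and open peaks of
the pooled distance distributions): iso-I iff both X/H distances are
below the cutoff and the R/B family is not, iso-II for the mirror case,
*ambiguous* when both families are short (conflicting signatures are
reported, never silently assigned — max-aggregation is the conservative
rule and can only understate the stacked fractions), open otherwise.

Populations are equal-weight means of per-member fractions with the
member-to-member standard deviation / √m as the standard error;
interconversion is slow enough that single trajectories are not
ergodic, so members are never pooled frame-wise. An optional
equilibration window (50 ns in the analysis drivers) is discarded when
all members start from the same non-stationary state: with an all-open
start the ≈ 13 ns initial transient time-averaged over 2000 ns leaves a
small (+0.6 %) systematic excess in the open fraction that is
detectable at 100 members, and discarding the transient restores
agreement between all-open-seeded and population-seeded ensembles
within statistical uncertainty.

Transition matrices count ordered frame pairs at a configurable lag
(default 1 frame) pooled over members without crossing member
boundaries; pairs touching an ambiguous frame are excluded and counted.
Rows with no observations are NaN and flagged.

The inter-duplex angle is measured between the XR and HX arms (the
pair also written "XR and RH" in the FRET literature; the arm pair is a
parameter and reversed names are accepted): vertex at the core-marker
centroid, arm directions to the terminal-base-pair centroids, angle in
[0°, 180°]. Histogram bins default to 0.5 Å for distances and 2° for
angles.

## Switching kinetics

Conformer dynamics are a three-state continuous-time Markov chain with
the open state as the obligatory intermediate (direct iso-I↔iso-II rate
fixed at zero). Default rates, in 1/ns: k(I→O) = k(II→O) = 0.005,
k(O→I) = 0.030, k(O→II) = 0.0483̄ — a star chain whose closed-form
stationary distribution is exactly 6 / 36 / 58 % open / iso-I / iso-II,
the high-salt conformer bias, with mean stacked dwells of 200 ns and
mean open dwells of ≈ 13 ns so that a 2000 ns member shows a handful of
interconversions. Sampling is exact (Gillespie; exponential dwells)
and the event path is kept alongside the frame-discretized series, so
the through-open constraint can be checked exactly at the event level;
apparent direct stacked-to-stacked frame transitions arise only from
two jumps inside one frame interval and scale away with the frame
spacing (≲ 10⁻⁴ at 1 ns, ≲ 10⁻⁵ at 0.1 ns).

## Synthetic trajectories and melting data

The generators replace a molecular-dynamics engine with the exact
statistical structure the analysis consumes. Rendered trajectories are
template coordinates plus isotropic Gaussian site noise (σ, default
1 Å) plus a random rigid motion per frame; frame spacing defaults to
1 ns and ensembles to 100 members × 2000 ns, with member streams
spawned from one master seed (numpy seed sequences; streams never
collide and identical seeds reproduce byte-identical output).

Melting ensembles draw, at each grid temperature, the model α(T) from
the mass-action relation and then each frame as melted (all base-pair
separations uniform in [12, 30] Å) with probability α or intact
([4, 8] Å) otherwise; an optional per-pair mode melts every base pair
independently with probability α to exercise the more-than-half-broken
strand rule on partially melted junctions. Absorbance melts are
A(T) = A_low(T) + α(T)·(A_up(T) − A_low(T)) + Gaussian noise with
linear sloping baselines.

What the generators do *not* emulate: force-field energetics, partial
unstacking within a conformer, correlated (non-isotropic) fluctuations,
ion effects on kinetics, temperature-dependent conformer populations,
or sequence dependence. Passing tests therefore validate the analysis
machinery — estimators, classifiers, statistics — under known ground
truth, not the physics of any particular DNA model.

## Melting thermodynamics

The two-state tetramolecular equilibrium (junction ⇌ 4 distinct
strands, each strand at C/4) gives K = α⁴(C/4)³/(1 − α) =
exp(ΔS/R − ΔH/(R·T)), with ΔH, ΔS in the melting direction (both
positive) and R = 1.987204×10⁻³ kcal/(mol·K). `vant_hoff_alpha` solves
the relation in log space with a bracketed root finder (the residual is
strictly increasing in α, so the root is unique; tolerance 10⁻¹²), with
overflow-safe 0/1 limits for extreme parameters. Setting α = ½ at T_M
yields ΔH = T_M·ΔS − R·T_M·ln[(C/4)³/8]; every fit satisfies this
identity by construction, and T_M is reported from it (flagged when
outside the data span).

`fit_vant_hoff` is a trust-region least squares over (ΔH, ΔS),
initialized from a two-point van't Hoff line through the α = 0.25 and
0.75 crossings, tolerances 10⁻¹². The 0.1 < α < 0.9 window is applied
in two passes: a first fit on points whose *observed* α lies inside the
window, then a refit on points whose *model* α does. Windowing on the
noisy observations alone correlates inclusion with the noise near the
window edges and biases ΔH low by about 1 % at σ_α = 0.02; the
model-based re-window removes that selection bias (Monte-Carlo z ≈ 0.3
over 100 replicates) and is a no-op on noiseless data.
`melting_temperature` interpolates the α = ½ crossing linearly, after
isotonic-regression smoothing when noise produces multiple crossings.

The frame-based estimator uses a 10 Å base-pair cutoff and a strict
more-than-half broken-fraction rule. On all-or-none synthetic frames
the resulting α̂ is exactly invariant for cutoffs in [8, 12] Å and
thresholds in [0.40, 0.60]; at a 7 Å cutoff a quarter of an intact
strand's pairs fall in [7, 8) Å and the binomial tail
P[Bin(34, ¼) > threshold·34] (≈ 1.4 % at 0.40) bounds the deviation —
the robustness checks assert exactly that bound rather than pretending
exact invariance is possible there.

Defaults for the melting ground truth are ΔH = 120 kcal/mol and
T_M = 330 K at C = 6×10⁻⁷ M total strand concentration (a 150 nM
junction), which places ΔS ≈ 0.266 kcal/(mol·K) via the identity —
magnitudes in the range expected for a four-armed complex of 68 base
pairs.

## Debye screening

λ_D = √(ε₀·ε_r·k_B·T / (2·N_A·e²·I)) with the ionic strength equal to
the monovalent salt molarity (CODATA constants via scipy). Two
permittivity models: fixed ε_r = 78.0 (default), and an empirical
temperature–salt model ε(T, c) = (249.4 − 0.788·T + 7.20×10⁻⁴·T²) ×
(1 − 0.2551·c + 5.151×10⁻²·c² − 6.889×10⁻³·c³) (Stogryn-type water
permittivity with a NaCl molarity correction, the form used by
coarse-grained DNA models with Debye–Hückel electrostatics). Both give
λ_D < 6 Å at 300 mM and 300 K — the screening regime in which the
melting temperature stops depending on salt.

## Problem sizes and numerical choices

The analysis drivers and checks use 100 members × 2000 ns at 1 ns
frames for ensemble statistics (matching the study design the
generator emulates), 0.1 ns frames over 200 ns for the fine-spacing
transition checks, 200–500 frames per condition for rendered-trajectory
validation, 50–100 temperature points with 100–200 frames each for
melting curves, and 100 Monte-Carlo replicates for estimator
calibration — sizes at which every statistical tolerance in the test
suite is set by the analytic standard error of the quantity checked.
Ties and degenerate inputs: zero-exit-rate states yield constant
series (not errors); empty frame sets, empty members, crossing
baselines, non-bracketable roots and degenerate arm vectors raise
informative errors; row-less transition rows are NaN, never 0.

## Known limitations

- The geometry templates are scaffolds; absolute IDA values for the
  stacked conformers are inputs (nominal angles), not predictions.
- The switching model has memoryless dwells; real junction kinetics
  show heterogeneity (ion-binding substates) that the chain cannot
  produce.
- The melting generator draws pair separations independently of the
  junction geometry, so it validates the α estimator and fit machinery
  but carries no structural correlation between melting and conformer
  state.
- Experimental absorbance analysis assumes linear baselines on
  user-declared windows; melts whose baselines curve need external
  preprocessing.
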