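# Methods

## Measurement model

A slide carries several sub-arrays synthesized with identical randomized
layouts; each sub-array is incubated under one condition between two
imaging rounds. Spot fluorescence after hybridization (`F_hyb`, green
channel) measures duplex occupancy; fluorescence after incubation
(`F_post`) measures how much duplex survived. Because dissociated aptamer
is diluted into a large volume, re-hybridization is negligible and
dissociation is modeled as irreversible and first order over the interval
Δt:

```
S = F_post / (F_hyb · (1 − φ)),        k_total = −ln(S) / Δt
```

φ is the fractional fluorescence loss of the *same DA* on the unincubated
Calibration sub-array — a per-DA correction for handling losses and
photobleaching, transferable across sub-arrays only because layouts are
identical. Two normalizations are emitted side by side: the model-free
*relative loss* `100·ΔF_cond/ΔF_cal` (the Calibration condition is 100 %
by construction; this is the quantity heat maps display) and the
model-based rate in h⁻¹. The single-interval first-order form is an
assumption of this package: with one Δt the data cannot distinguish decay
laws, and the rate should be read as an effective first-order rate over
that interval.

The ligand-induced component is defined additively,
`k*_off,[L] = k_total,[L] − k_off`, with `k_off` taken from BufferOnly.
Note that in `k*` the φ-term cancels algebraically, so induced-fit calls
are insensitive to calibration error; φ still matters for `k_off` itself.
Its concentration dependence is modeled as Michaelis–Menten,
`k* = k*_max·[L]/(K_Fit+[L])` — the standard saturable approximation to
the Briggs–Haldane kinetics of the ternary system. `K_Fit` (M) is the
half-saturation ligand concentration of the induced-fit pathway; it is an
operational affinity of the *duplexed* construct, not of the free aptamer.

## Coordinates, names, library counting

Aptamer coordinates are 1-based; 5′-extension bases count −1, −2, … with no
coordinate 0, and all coordinate arithmetic (window ends, anchor
conversion `N3 = N5 + L − 1`) is done by string index so windows crossing
the consensus boundary behave correctly. Designs are named
`5ʹ_{N}{base}:{L}[:{MM}{base}]` (or 3′-anchored equivalently); parsing
validates the embedded base letters against the construct, which catches a
name paired with the wrong aptamer.

Perfect-match libraries of lengths X..Y on a length-L aptamer contain
`[(Y−X+1)(2L+1) − Y² + (X−1)²]/2` designs and single-mismatch libraries
`[Y(Y+1)(3L−2Y+2) − X(X−1)(3L−2X+4)]/6`; both closed forms are verified
against brute-force enumeration for every 1 ≤ X ≤ Y ≤ L ≤ 40 in the test
suite. Mismatches substitute the *probe* base: G/C/T → A (A·C, A·G, A·A
mismatches with the aptamer) and A → T (T·T), keeping destabilization
roughly uniform. Under this rule a substitution can never be a fixed
point, but a `degenerate` flag is still carried so enumerated counts stay
equal to the closed forms if the substitution table is customized. Probes
are always synthesized in the DNA alphabet (array chemistry), with a
3′ T₂₅ spacer by default and an optional 5′ T linker.

## Spot QC

Three per-spot rules are evaluated on the post-hybridization green image of
each sub-array, with strict inequalities exactly as stated and the sample
standard deviation (n−1):

1. signal < 200 RFU;
2. pixel CV (sd/signal) > mean(CV) + 3·sd(CV) over the sub-array;
3. local background > mean + 3·sd over the sub-array.

A spot failing any rule is removed from all rounds and channels; an ACE
with fewer than 3 passing replicates in *any* sub-array is excluded
dataset-wide and propagates as missing (blank heat-map tiles; means never
treat missing as zero). The native tables carry a single central statistic
per spot (the median pixel signal), so rule 1's "mean pixel signal" is
approximated by the median — a documented divergence that is immaterial
for the roughly symmetric pixel distributions the rules assume.

## Dose–response fitting

`DoseResponseModel.fit()` is unweighted bounded nonlinear least squares
(trust-region reflective): start values `k*_max₀ = max(k*)`,
`K₀ = geometric mean of [L]`; bounds `k*_max ∈ [0, 10·k*_max₀]`,
`K_Fit ∈ [10⁻³·min[L], 10³·max[L]]`; tolerances `xtol 1e−10`,
`ftol/gtol 1e−12`. Because start and bounds scale with the data the fit is
covariant under concentration-unit changes. Standard errors come from the
Jacobian at the optimum (`cov = RSS/(n−2)·(JᵀJ)⁻¹`). Negative k* values
(noise) enter the fit unfloored to avoid bias; flooring at zero is applied
only to displayed landscapes. Degenerate inputs are flagged, never silent:
all-non-positive k* yields `k*_max = 0` with `K_Fit` undefined;
non-convergence and active bounds are reported in `flags`. Fits require
≥3 distinct positive concentrations. Weighting by replicate variance was
considered and not adopted: with a shared noise model across the dilution
curve, unweighted least squares is the neutral choice.

With two slides, Calibration and BufferOnly per-DA fluorescences are
averaged across slides before any rate is taken; each ligand sub-array
then contributes one point of the 8-dilution curve.

## Thermodynamics

Duplex ΔG is a nearest-neighbor sum over the window using the unified
DNA/DNA parameter tables shipped with Biopython (`DNA_NN3` Watson–Crick
stacks, `DNA_IMM1` internal single mismatches, `DNA_TMM1` terminal
mismatches, initiation terms per terminal pair), evaluated at the assay
temperature with an entropic salt correction
`ΔS += 0.368·(n−1)·ln([Na⁺]_eq)` cal/(mol·K), where
`[Na⁺]_eq = [Na⁺] + 3.795·√[Mg²⁺]`; the correction vanishes at the 1 M
monovalent reference. RNA-containing duplexes are modeled as DNA:DNA (the
probes are DNA; the approximation slightly depresses predicted stabilities
of purine-rich hybrids, which is recorded here rather than corrected).
`self_dG` is an exhaustive search over simple candidates only — hairpins
with perfect stems ≥3 bp and loops ≥3 nt (stack sum + loop closure
penalty) and perfect contiguous self-dimers ≥3 bp (stacks + initiations +
homodimer symmetry entropy), capped at 0 — not a partition-function fold.
These estimates are for rank-order comparison against measured landscapes;
absolute agreement with folding servers is not claimed or tested.

## Synthetic data generator

The generator's defaults are the standard study conditions: 6 sub-arrays
per slide (1 Calibration, 1 BufferOnly, 4 ligand), 5 replicates per design,
Δt = 1 h, 8 log-spaced ligand concentrations from 0.124 µM to 10 mM split
across 2 slides, 10 % lognormal replicate noise per spot per imaging
round, φ = 0.15 handling loss, backgrounds Normal(80, 15) RFU clipped at
zero, pixel SD = 0.08 × signal, and 0.2 % planted morphology and background
failure rates (failures inflate pixel SD or background tenfold). The
hybridization level is a Langmuir-like occupancy in the predicted duplex
ΔG, `F_hyb = F_max/(1+exp((ΔG−ΔG₀)/s))` with `F_max = 30 000` RFU,
`ΔG₀ = −11 kcal/mol`, `s = 2.5 kcal/mol` — chosen so the shortest 7-mers
still sit comfortably above the 200 RFU QC threshold while long ACEs
saturate, as on a real scanner.

Preset truths: `atp_dna_like` plants induced fit exactly on 7–12-mers
overlapping the G-rich binding-site coordinates 4–12 of the extended ATP
DNA construct (`K_Fit = 200 µM`; `k*_max = 0.5 + site-overlap fraction`
h⁻¹, ×1.5 for mismatched variants of hot designs), and elevated `k_off` on
the 5′-extension/3′-stem coordinates; `cocaine_like` has structured
hybridization and stem-dependent `k_off` but zero induced fit everywhere;
`flat_null` is uniform. The 27-base ATP consensus is the classical
sequence; its 5-base 5′ extension (and the whole cocaine-like construct)
are synthetic stand-ins chosen to be consistent with the design names used
in the tests.

The generative decay model intentionally matches the analysis model, so a
zero-noise dataset is recovered to machine precision — the standard
simulation-based-calibration posture. Consequently, passing tests
demonstrate correctness of the inference chain, not robustness to model
misspecification: scanner optics, spatial gradients, biphasic decay,
quenching differences between constructs, and aptamer tertiary structure
are all outside what the generator emulates. The base pixel CV is constant
by construction so the planted morphology failures are recovered exactly;
real arrays would add CV dispersion and a corresponding false-flag rate.

## Detection calls and noise floor

For "is there induced fit?" calls, the k* noise floor is estimated without
ground truth from replicated BufferOnly sub-arrays: the per-DA difference
of k_total between two BufferOnly sub-arrays is a pure noise contrast with
variance 4σ_F²/Δt² (the calibration term cancels), while k* carries
3σ_F²/Δt², so the floor is √3/2 × the robust (MAD-based) sd of that
difference. A design is *detected* when |k*| > 3 × floor. Over hundreds of
designs, |z| > 3 excursions occur at a small rate even in a true null, so
"no induced fit" is asserted as an exceedance fraction ≤ 3 % (comfortably
above the nominal Gaussian 0.27 % to absorb mild heteroscedasticity),
never as literally zero; exact set equality between detected and planted
hotspots is asserted in the noiseless regime, where it holds identically.

## Problem sizes

The test and acceptance runs use the full ATP-like library (603 designs:
351 perfect-match 7–32-mers + 252 single-mismatch 12-mers) on two slides —
72 330 spot rows per noisy experiment — and the 204-design 8–15-mer
cocaine-like library; the counting property sweep covers all
1 ≤ X ≤ Y ≤ L ≤ 40. The whole suite runs in well under a minute on one
CPU.

## Known limitations

* One incubation interval: rates are effective first-order rates; no
  real-time kinetics, no biphasic modeling.
* Cooperative ligands (e.g., two-site binders) are fitted with the same
  hyperbolic form; `K_Fit` is then an apparent constant.
* The GPR reader is a best-effort column mapping, not a fidelity claim for
  any particular deposited dataset.
* Thermodynamics: no terminal dangles, no G-quadruplex energetics, no
  partition function; RNA strands approximated as DNA.
* Two-color normalization (red/green post-incubation ratio) is provided as
  an operation; the simulator does not generate a red channel.
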