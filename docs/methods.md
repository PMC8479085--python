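# Methods

This note records the models, conventions and numerical choices behind
`fragscreen`, and what the synthetic-data validation does and does not
demonstrate about real assay data.

## Isoelectric points

Net charge is the standard Henderson–Hasselbalch sum over ionizable
side chains (D, E, C, Y acidic; H, K, R basic) plus, optionally, the
terminal amine and carboxyl groups. The pKₐ table is the Bjellqvist set
as used by ExPASy ProtParam, including the residue-specific N-terminal
values (A 7.59, M 7.00, S 6.93, P 8.36, T 6.82, V 7.44, E 7.70; default
7.5) and C-terminal values (D 4.55, E 4.75; default 3.55). The table is
a plain data object and can be swapped.

The pI is found by bisection on pH 0–14 (net charge is strictly
decreasing in pH, so the crossing is unique). The bisection half-width
is 10⁻³ pH before rounding to two decimals, matching the precision at
which theoretical pI values are conventionally reported.

Two conventions are exposed because synthesized screening fragments are
N-acetylated/C-amidated: `free_termini=True` (the default) includes the
terminal charges and reproduces ProtParam's printed values for capped
peptides, which are computed this way by convention; `free_termini=False`
drops them for the chemically accurate charge of capped chains. A
peptide with a one-signed composition and fixed termini has no zero
crossing and raises rather than returning a boundary value.

Validation cross-checks 20 random 10-mers against Biopython's
independent implementation of the same convention (with its bisection
bracket widened from its default [4.05, 12], which would clamp very
acidic peptides).

## Spectral model and file format

A `Spectrum` is a strictly monotone axis (nm or cm⁻¹) with one intensity
per point plus sample, time and replicate metadata; a `SpectralSeries`
is a time/replicate-indexed collection sharing one axis. Files are
delimited text with a `# key: value` header (`modality`, `axis_kind`,
`units`, `sample_id`) followed by either long format
(`axis,intensity,time_h,replicate`) or wide format (one `t=<hours>`
column per time point). Floats are written as `%.17g` and parsed with
pandas' round-trip parser, so write→read is bitwise lossless. Intensity
units are carried as labels and never converted.

Band averages are arithmetic means over *closed* axis windows; the
phrasing "averaged between a and b nm" is read as inclusive of both
endpoints (a documented choice — instrument grids are dense enough that
it is immaterial in practice, but it makes the operation exactly
testable).

Savitzky–Golay smoothing defaults to 13 points, order 2 (the classical
quadratic smoothing filter) with reflect padding at the edges;
truncating (shrinking-window polynomial) edges are available. The axis
must be uniform to within 10⁻⁶ of its span, otherwise the operation
refuses and asks for resampling rather than silently distorting.

Linear combination of spectra on mismatched grids linearly interpolates
both onto the union of their axis points restricted to the overlap;
axes equal within 10⁻⁶ of span are combined directly.

## FTIR amide-I decomposition

The amide-I band is modelled as a sum of Gaussian components at
positions conventional for aggregating amyloid peptides: β-sheet
1627 cm⁻¹, unordered 1645 cm⁻¹, helix 1658 cm⁻¹, turn 1671 cm⁻¹.
Gaussian shape is a modelling choice (only positions are diagnostic);
centres may move ±4 cm⁻¹ from nominal, FWHMs are bounded to 8–40 cm⁻¹,
and amplitudes are non-negative. The fit is trust-region least squares
on the peak-normalized spectrum restricted to 1600–1700 cm⁻¹; structure
fractions are component areas over total fitted area, which makes them
exactly invariant to uniform intensity scaling. A relative residual
above 0.1, or an all-zero input, flags the result instead of raising.

Terminal acetyl/amide caps of synthetic fragments add genuine amide
signal in the unordered region (~1638–1650 cm⁻¹); this is not corrected
for, only noted, because the correction would require a per-peptide
reference that kinetic screens do not measure.

Because fractional structure contents are not independently known for
real samples, the decomposition is validated purely against synthetic
ground truth: noiseless band mixtures are recovered to 10⁻³, and at ~1 %
peak noise the mean absolute fraction error stays below 0.05 over 50
seeds.

## CD classification

Classification is positional and sign-based, not a basis-set
deconvolution, because the screening interpretation itself is
positional and 4-mm-cuvette far-UV data are unreliable below 200 nm.
With thresholds relative to the largest |ellipticity| (default 5 %):
negative extremum at 215–225 nm with positive signal at 195–205 nm →
β-sheet (this also captures the twisted-sheet signature of strong
positive ~200 nm ellipticity); two negative extrema near 208 and
220–230 nm without positive 195–205 nm signal → helix; dominant negative
extremum at 195–203 nm → unordered; anything else, including a flat
spectrum, → mixed/turn. The call is invariant to positive rescaling.

## Time courses and the inhibition percentage

ThT and scattering series reduce to (time, value, replicate) triples by
band averaging (475–485 nm and 550–555 nm). Plateau summaries are
per-replicate means over a closed time window (default 32–48 h), with
grand mean ± sample SD across replicates; n = 1 yields SD 0 plus a
small-sample flag. Error bars are SDs, and labelled as such.

IP = (1 − F*/F₀)·100 with F* = F_tot − c·F_frag. The correction c
defaults to 0.7 — the ratio of the fragment concentration in the
mixture to the pure-fragment reference concentration — and is a
parameter, not a constant, since it encodes the assay's concentration
design plus a linearity-of-fluorescence assumption. Negative IPs
(enhancement) and IPs above 100 % (over-correction) are reported with
flags, never clamped: clamping hides assay anomalies. When the three
time courses carry equal replicate counts, IP is computed per matched
replicate index and spread as the sample SD of per-replicate IPs;
otherwise grand means are used and the result is flagged unpaired
(replicates from independent experiments carry no true pairing; the
index matching only propagates spread).

Per-timepoint group comparisons use the two-tailed two-sample t-test,
pooled-variance by default (the conventional reading of a plain
"t-test"), Welch optional. The summary is the per-timepoint p-values
and their mean ± SD over the requested time range. Zero variance in
both groups gives p = 1 under exact equality and a flagged NaN
otherwise.

## RET difference spectra

The difference spectrum is D = s·F_mix − (F_A + F_B) with s the mixture
scale (2 for a half-and-half equimolar mixture), each series
replicate-averaged at the matched time (nearest neighbour within
0.5 h). The inputs are Savitzky–Golay filtered (13-point quadratic);
since both the filter and the subtraction are linear, the
implementation subtracts first and smooths the difference — identical
mathematically, and it keeps a perfectly additive (non-interacting)
system at exactly zero in floating point. ΔF_Phe and ΔF_Tyr are band
averages of D over 270–290 and 300–320 nm.

The RET call is sign-based: ΔF_Phe < −floor and ΔF_Tyr > +floor. The
default floor is 0, matching the qualitative bare-sign reading of
difference spectra; note that against pure noise the bare-sign rule
fires a quarter of the time by symmetry, so for automated screening
`estimate_noise_floor` sets the floor to k·SD (default k = 3) of the
windowed ΔF values over stated pre-interaction baseline times.

Förster theory enters as E = R₀⁶/(R₀⁶ + r⁶) with R₀ = 13.5 Å for the
Phe→Tyr pair; the analysis uses it only through the synthetic
generator's efficiency profiles (extracting distances from measured
efficiencies is out of scope).

Tyrosine quenching drift (water exposure early, sequestration into
aggregates later) is modelled in the generator but deliberately not
corrected in analysis: applied equally to all Tyr contributions it
cancels in the difference spectrum, and real-data deviations from that
cancellation are interpreted qualitatively, not removed.

## Synthetic data: what it emulates

Aggregation kinetics follow the Finke–Watzky two-step model
(A → B, rate k_n; A + B → 2B, rate k_e), chosen over a logistic because
it has a closed form, two interpretable rates, and the lag-free
saturating shape characteristic of stirred ThT assays:

    B(t) = A0 − (k_n/k_e + A0) / (1 + (k_n/(k_e·A0))·exp((k_n + k_e·A0)·t)).

Default conditions reproduce the assay design: parent at 35 µM with
k_n = 0.01 h⁻¹, k_e = 0.01 µM⁻¹h⁻¹ (ThT saturation by ~1 day);
fragments at 100 µM with k_n = 0.005, k_e = 0.002 (plateau by ~2 days).
The closed form is verified against numerical integration of the rate
equations to 10⁻⁶·A0 over a 3×3 rate grid.

Observation models place a ThT emission band at 480 nm (FWHM 20 nm,
gain 1 a.u./µM fibril — per-peptide, since hydrophobic fragments bind
ThT more avidly), a scattering band at 550 nm reading total aggregate
mass (fibrillar + amorphous; an `amorphous_fraction` routes mass into
ThT-silent aggregates), and Phe/Tyr emission bands at 287/310 nm
(FWHM 30/34 nm). Default noise is homoscedastic Gaussian per modality
(ThT 1 a.u. ≈ 3 % of the parent plateau, emission 0.5 a.u. against
~66 a.u. windowed signals), consistent with the few-percent error bars
of triplicate kinetic assays; proportional noise is available.

In mixture scenarios the fragment's contribution is the fragment-alone
signal scaled linearly by the concentration ratio (0.7), i.e. the
generator adopts the same linearity assumption the analysis correction
makes, rather than re-running the (concentration-nonlinear) kinetics at
the mixture concentration. This is deliberate: it makes the IP
estimator's target well-defined, so recovery tests measure pipeline
error, not the divergence between two kinetic conventions.

In RET scenarios the mixture donor band is scaled by 1 − E(t) and the
transferred quanta feed the acceptor band with emission yield 0.8;
E(t) may be constant or a profile (e.g. peaking mid-incubation and
decaying, as hetero-aggregates dissolve into homo-aggregates).

Reproducibility: every generator takes a master seed and derives
replicate streams from `numpy` seed sequences; changing the seed
changes noise realizations only. Mass balance
(monomer + fibrillar + amorphous = A0) holds to 10⁻⁹ at every time
point, and every generated file round-trips through the text format.

**What passing tests do not show.** The generator is an additive-band,
Gaussian-noise idealization: no baseline drift, photobleaching,
scattering contamination of fluorescence, inner-filter effects,
evaporation, or replicate-level kinetic variability (replicates share
one true curve and differ only in noise). Recovery of IP to within a
few percentage points on synthetic data therefore demonstrates the
estimator's correctness under its own assumptions, not the accuracy of
real-assay IPs, whose dominant errors are experimental.

## Problem sizes in the validation suite

The stochastic checks run at desk scale: 200 seeds × 4 inhibition
levels with 3 replicates and a 14-point time grid for IP recovery, 50
seeds for RET detection power (11 time points) and for noisy amide-I
round trips, and a 3×3 rate grid for the kinetics closed form. These
sizes give Monte-Carlo error comfortably below the tolerances tested
while keeping the full suite under a minute of compute.

## Known limitations

- The ProtParam terminal-pKₐ treatment for chemically capped peptides is
  not published; both conventions are exposed instead of guessing.
- The amide-I fit is a local optimizer with fixed starting amplitudes;
  heavily overlapped four-component spectra with large centre shifts can
  in principle find local minima (flagged by the residual threshold).
- CD rules assume a single dominant conformational signature; genuinely
  mixed spectra fall into the `mixed_turn` bucket by design.
- The t-test summary reports the mean ± SD of p-values over time for
  comparability with the screening literature; p-values at successive
  time points of one kinetic experiment are correlated, so this summary
  is descriptive, not an inference procedure.
- No multiple-testing correction across fragments, and no kinetic curve
  fitting (lag times, growth rates) in the analysis path — plateau
  summarization is the only reduction; curve models live only in the
  generator.
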