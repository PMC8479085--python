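# fragscreen

Analysis pipeline for screening amyloid-β (Aβ) derived peptide fragments as
inhibitors of Aβ₁₋₄₂ fibrillogenesis. The package is aimed at biophysics
groups running multi-modality kinetic assays — thioflavin-T (ThT)
fluorescence, 90° light scattering, FTIR and far-UV CD — on the parent
peptide, short overlapping fragments cut from its sequence, and their
mixtures, and needing a reproducible route from raw spectral time series to
the screening statistics.

## What it computes

**Sequence properties.** Fragments are cut from the 42-residue parent
sequence as 1-based inclusive windows (the standard screening set is
P1 = 1–10, P2 = 6–15, P3 = 11–20, P4 = 16–25, P5 = 21–30, P6 = 26–36,
P7 = 31–42). Net charge at a given pH is the Henderson–Hasselbalch sum

    Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)),

and the theoretical isoelectric point (pI) is the zero crossing of Z on
pH 0–14, found by bisection with the Bjellqvist pKₐ set used by ExPASy
ProtParam (including its residue-specific terminal pKₐ variants).

**Aggregation time courses.** ThT emission is averaged over 475–485 nm
(excitation 435 nm) and scattering over 550–555 nm; plateau levels are the
per-replicate means over a stated time window (default 32–48 h), reported
as grand mean ± SD across replicates.

**Inhibition percentage.** For a parent + fragment mixture at two-fold molar
excess of fragment,

    F* = F_tot − 0.7·F_frag,     IP = (1 − F*/F₀) × 100 %,

where F₀ is the parent-alone plateau, F_frag the fragment-alone plateau at
its reference concentration, and 0.7 the concentration-correction factor
(fluorescence assumed linear in peptide concentration). Per-timepoint
two-sample t-tests (pooled-variance by default) summarize group differences
as mean ± SD of the p-values over a time range.

**Secondary structure.** FTIR amide-I spectra are decomposed into
constrained Gaussian components (β-sheet ≈ 1627, unordered ≈ 1645, helix
≈ 1658, turn ≈ 1671 cm⁻¹) by non-negative least squares; CD spectra are
classified by band-position rules (e.g. a negative extremum at 215–225 nm
with positive ellipticity near 200 nm reads as β-sheet).

**Phe→Tyr RET.** Resonance energy transfer between phenylalanine
(donor, emission ≈ 287 nm) and tyrosine (acceptor, ≈ 310 nm; Förster
distance R₀ = 13.5 Å) is detected from the difference spectrum
D = 2·F_mix − F_A − F_B (13-point quadratic Savitzky–Golay smoothed):
ΔF_Phe < 0 together with ΔF_Tyr > 0, averaged over 270–290 nm and
300–320 nm respectively, indicates transfer, hence peptide–peptide
interaction.

A synthetic-data module generates all four modalities with known ground
truth (Finke–Watzky two-step aggregation kinetics, per-peptide ThT binding,
transfer-efficiency profiles, quenching drift, replicate noise) so the whole
pipeline is testable end to end.

## Worked example

Simulate a mixture experiment with 80 % true inhibition and recover the
statistic:

```
$ cat cfg.yaml
seed: 11
true_inhibition: 0.8
$ fragscreen simulate --scenario inhibition --config cfg.yaml --out sim
$ fragscreen ip --mix sim/mixture.csv --frag sim/fragment.csv --parent sim/parent.csv
{
  "ip_percent": 79.94948784709747,
  "sd": 0.4014706505805181,
  "per_replicate": [79.57846814068637, 79.89429671075686, 80.3756986898492],
  "inputs": {
    "F_tot": 70.68078511610322,
    "F_frag": 91.58117233018704,
    "F0": 32.78816042681411,
    "F_star": 6.573964484972294,
    "correction": 0.7,
    "window_h": [32.0, 48.0]
  },
  "flags": []
}
```

The mixture plateau (70.7 a.u.) minus 0.7 times the fragment-alone plateau
(91.6 a.u.) leaves F* = 6.6 a.u. of parent fibril signal against a
parent-alone plateau of 32.8 a.u., i.e. ~80 % inhibition — matching the
simulated ground truth to within replicate noise.

Sequence-level properties:

```
$ fragscreen pi --fasta seqs.fa
name    sequence        length  pI
P1      DAEFRHDSGY      10      4.54
P3      EVHHQKLVFF      10      7.01
```

P1 is strongly acidic (excess negative charge at neutral pH, resisting
self-aggregation), while P3 sits at nearly zero net charge at pH 7 —
consistent with its high aggregation propensity.

Other subcommands: `smooth`, `bandavg`, `timecourse`, `ret`, `ftir-fit`,
`cd-classify`, `simulate` (scenarios `inhibition`, `ret`, `ftir`); see
`fragscreen --help`.

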