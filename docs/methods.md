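# Methods

This note documents the models, rules and numerical choices behind
`halomet`, and what the synthetic-study tests do and do not demonstrate.

## Mass arithmetic

All masses derive from a version-stamped table of monoisotopic isotope
masses and abundances (CODATA/NIST values, `data/isotopes.json`), so
results do not drift with third-party library updates. The supported
element set is {C, H, N, O, S, Cl, Br} — the composition space of a
mid-size halogenated pesticide and its plant metabolites.

Protonated-ion m/z is computed as neutral monoisotopic mass + m(H) −
m(e). Subtracting the electron mass matters at the fourth decimal: the
parent ion computes to 473.0123, not 473.0128. Comparisons against
printed table values use half-away-from-zero rounding at the printed
precision, which is the convention such tables follow (e.g. a ppm error
of 2.4576 prints as 2.5).

ppm errors are offered in two modes. *Table mode* (default for catalog
validation) measures the observed m/z against the 4-decimal printed
calculated value; *full-precision mode* measures against the unrounded
theoretical mass. Published tables are not always internally consistent
between the two: in the packaged catalog, 20 of 22 printed errors
reproduce in table mode and the other two (IN-JCZ38, TP316) only from
full-precision inputs. One printed calculated m/z (IN-JCZ38, printed
491.0228) differs by one unit in the fourth decimal from the recomputed
value (491.02285, which rounds to 491.0229); the catalog loader
therefore tolerates exactly one unit in the fourth decimal — a
transcription-level rounding artifact — while anything larger is treated
as tampering and rejected.

### Nitrogen rule and RDBE

The nitrogen rule is applied to the *neutral* molecule: the parity of
the integer nominal mass must equal the parity of the nitrogen count.
(Applying it to the protonated ion would flip every parity; the neutral
convention is the one under which all 22 catalog formulas pass.)
Ring-plus-double-bond equivalents use C + 1 + (N − H − Cl − Br)/2;
candidate neutral formulas must have an integral RDBE in [0, 40]
(even-electron species).

## Isotopologue simulation

Patterns are computed by exact convolution: per element, the multinomial
distribution over isotope compositions of its n atoms; across elements,
the product distribution. Isotopologue species are then merged into
clusters whenever the gap between adjacent species is below the
aggregation bin (default 0.01 Da), with abundance-weighted centroid m/z,
and normalized to base peak = 100. The default bin merges the
near-isobaric ³⁷Cl (+1.99705) and ⁸¹Br (+1.99795) species of each A+2n
cluster into one centroid, matching unit-resolved A/A+1/A+2/A+4
reporting; a finer bin (e.g. 5 × 10⁻⁴ Da) separates the individual
species. For the parent ion the blended A+2 centroid is 475.0102 and
the A+4 centroid 477.0082, while the single-species values are 475.0102
(⁸¹Br) and 477.0073 (³⁷Cl⁸¹Br); instrument-reported "reference isotope
ions" correspond to within a millidalton of either convention, and both
are reported by the acceptance script. A pruning threshold (default
0.01% of base) bounds the combinatorics; with pruning disabled the
un-normalized distribution conserves total probability to 10⁻⁹, and the
convolution agrees with brute-force per-atom enumeration to 10⁻⁶
relative abundance.

For a one-Br-one-Cl ion, A+2/A ≈ 0.2424/0.7576 + 0.4931/0.5069 ≈ 1.32:
the A+2 cluster is the *base peak*. This ratio envelope ([1.25, 1.35])
is an invariant of the composition, independent of the carbon skeleton.

## Formula inference

Enumeration is an exact residual-mass recursive descent over elements in
decreasing mass order, with hydrogen solved from the residual; it is
complete within the element bounds (verified against a nested-loop
oracle on reduced bounds). Default bounds (C ≤ 40, H ≤ 60, N ≤ 10,
O ≤ 12, S ≤ 2, Cl ≤ 2, Br ≤ 2) cover every plausible TP of the parent
while keeping the search instantaneous. Because the source of TPs is a
halogenated parent, candidates must retain ≥ 1 Cl/Br by default
(switchable — fully dehalogenated products are chemically possible).

Ranking must be total and reproducible, so candidates sort by |ppm|
ascending, then isotope score descending, then fewer heteroatoms, then
the Hill string. The isotope-fit score treats theoretical clusters
≥ 25% of base as mandatory (missing one collapses the score
quadratically — a BrCl candidate without its A+2 scores < 0.5), while
clusters in the 5–25% band cost at most half their abundance share when
absent, so a spectrum reporting only the A/A+2/A+4 reference triplet
still scores > 0.9.

## Screening cascade

Stages run in the order control subtraction → intensity/S/N thresholds →
Cl/Br isotope filter → suspect matching, each returning a subset of its
input and logging eliminations to an audit trail. Control subtraction
uses "any control replicate" semantics (the strictest reading of
"present in the non-treated samples"); matching is 5 ppm / ±0.1 min.
Thresholds are area ≥ 10⁴ with S/N strictly > 10. The halogen filter
requires an A+2 companion at +1.997 ± 0.005 Da whose abundance ratio is
consistent (±25% relative) with some combination of 1–2 Cl and/or Br;
the 0.005 Da spacing tolerance accepts both halogen isotopes while
rejecting the +2.0067 double-¹³C companion of halogen-free organics.
S/N for detected features is defined explicitly (vendor software never
states its definition): apex intensity over the median intensity of
non-member peaks within ±0.5 Da. Inclusion lists merge candidate masses
within 25 ppm; the packaged catalog yields 20 entries from 22 compounds
(two isobaric pairs merge).

## Annotation

Fragment evidence is data, not code: characteristic product ions
(transcribed per compound) and generic neutral losses (anhydroglucose
162.0528, H₂O, HCl, HBr, CO, HCN, methylamine) with masses computed
from their formulas. Confidence follows the Schymanski scale as used in
TP screening practice: level 1 needs a reference standard; 2b needs
fragments plus prior literature/registration reports; 3 covers
fragment-supported assignments with open structural alternatives (e.g.
glycosylation positions — the two TP651 anomers are distinct catalog
entries distinguished only by RT); 5 is exact mass only. Levels 2a and
4 are representable but unused by this rule set.

Phase classification walks a curated pathway graph from the parent:
a conjugation edge (glycosylation, amino-acid conjugation) at the
terminal position makes a phase-II product; any carboxamide-bridge
cleavage on the path makes a breakdown product; otherwise phase-I.
Over the packaged catalog this yields the 11/6/4 partition. Two edges
(TP441 as a demethylation isomer, TP405 as dehydrochlorinated IN-MLA84)
are inferred from composition rather than stated mechanism; any
non-conjugation, non-cleavage choice gives the same phase-I label.

## Quantification

Calibration is an unweighted least-squares line over ≥ 5 monotone
levels (1/x weighting available; both are standard residue-analysis
practice and the choice is exposed rather than fixed). Recovery correction is
applied per sample — each extract is corrected by its own
internal-standard recovery, not a batch mean — and is the exact inverse
of a scalar matrix-loss factor. The LOD t-quantile is computed from the
Student distribution, never table-looked-up, and equals 3.143 (3 dp) at
seven injections with α = 0.01; LOD scales linearly with the replicate
standard deviation and LOQ/LOD is exactly 3.3 by construction.

## Reporting

M/P ratios use raw peak areas (relative abundance, the convention for
TPs lacking reference standards), mean-of-ratios over replicates with
sample sd; ratio-of-means is exposed as an alternative. Compounds below
the screening thresholds count as *not detected* (a "−" occurrence
flag), never as zero ratios. Parent-zero cells are flagged undefined.

## Synthetic-study generator

The generator emulates the study *design*, not any particular dataset:

* **Kinetics**: C(t) = A · (t/τ) · exp(1 − t/τ) · exp(−g·t) — a
  single-peak pulse (rise, peak near τ, decline) with a growth-dilution
  term. Defaults per tissue: xylem sap A = 38 ng/mL, τ = 12 d (peak at
  7–14 DAT on the sampling grid); young leaves 390 ng/g, τ = 21 d;
  mature leaves 1440 ng/g, τ = 28 d; flowers 530 ng/g, τ = 21 d; fruits
  5.3 ng/g, τ = 42 d. Amplitudes and peak times follow the reported
  residue series.
* **Metabolite formation**: metabolite area = parent area × f(t), with
  f(t) = f84 · (t/84)², f84 set per compound (0.3–56%) after the
  reported relative-abundance maxima and scaled per tissue (mature
  leaves 1.0, young leaves 0.3, flowers 0.11, fruits 0.15, xylem sap 0 —
  TPs are not translocated). The quadratic ramp keeps every M/P below
  10% through 28 DAT.
* **Recoveries**: per-sample scalar drawn from the per-matrix means
  (92.6 ± 8.3% young leaves, 81.0 ± 9.9% mature leaves, 105.7 ± 8.5%
  flowers, 74.1 ± 17.1% green fruits, 63.2 ± 14.5% ripening fruits),
  applied identically to analyte and internal standard.
* **Noise**: lognormal area noise at 20% RSD (replicate SDs in such
  studies run 10–30% of means); the IS-normalized quantification
  channel uses 5% RSD, consistent with QC-injection RSDs of a few
  percent; m/z jitter 1 ppm; RT jitter 0.02 min; isotope-cluster
  abundance jitter 5%. Matrix features (50 per study, 20% with
  halogen-like A+2 patterns) are planted identically in both groups;
  30 unstructured noise features are private to each sample.

All randomness flows from one seed; identical (config, seed) pairs are
bit-identical.

**What passing tests show — and don't.** On these simulations the
pipeline detects ≥ 95% of planted metabolites with M/P ≥ 1%, passes
zero matrix features, recovers parent concentrations with ≤ 15%
relative RMSE after recovery correction, and recovers planted M/P
fractions within three standard errors of the configured noise. The
generator does not model chromatographic peak shapes, ion suppression
beyond a scalar recovery, co-elution, or profile-mode spectra, so these
results validate the *logic and arithmetic* of the workflow, not its
performance on raw vendor data. The end-to-end checks use a scaled-down
design (mature leaves + flowers × 4 sampling days × 3 replicates ×
3 seeds): both tissues are sampled on those days in the full design,
and their parent signal keeps a 1% metabolite well above the 10⁴
intensity cutoff, so the test exercises the screen rather than the
detector floor.

## Degenerate inputs and tie-breaks

Empty candidate sets, empty spectra and empty hit lists are valid
outcomes, not errors. Zero replicate variance yields LOD 0 with a
warning. Single-replicate summary cells report an undefined sd with a
flag. Isobaric suspects are disambiguated by RT when known; suspects
without an expected RT match on m/z alone. Feature ordering is
normalized inside every screening stage, so outputs are invariant under
input permutations.

## Known limitations

* No structure elucidation: fragment rules are transparent lookups, not
  bond-breaking prediction; positional isomers are separate entries
  distinguished by RT only.
* The element set excludes P, F, Na/K adducts and charge states ≠ +1.
* Matrix-specific LOD/LOQ values of the original study are not
  reproducible without its raw replicate data; only the formula layer
  is implemented and verified.
* mzML ingestion is intentionally out of the core: MGF and CSV peak
  lists are the supported interchange formats.
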