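# Methods

`evlipid` implements the computational half of a combined LC-MS/MS + ³¹P NMR
characterization of plasma-derived exosome-like vesicles (EVs): MS2 lipid
assignment with a probabilistic match score, MS1 reconstruction
quantification within headgroups, ³¹P NMR deconvolution quantification of
phospholipid classes, the transwell blood-brain-barrier (BBB) permeability
partition, and DLS summary statistics. A synthetic-data generator produces
every input with known ground truth so that each stage can be validated by
parameter recovery.

## Lipid mass library

Species are a headgroup class (PC, PE, PI, PS, PG, SM, LPC, LPE, LPI, CL)
plus a chain composition in `C:D` notation (`d` prefix for sphingoid bases).
Elemental formulas are assembled from glycerophospho-headgroup cores (e.g.
glycerophosphocholine C₈H₂₀NO₆P) with each fatty acyl added as the free acid
CₙH₂ₙ₋₂dO₂ minus one condensation water; sphingomyelin is the sphingoid base
CₙH₂ₙ₊₃₋₂dNO₂ plus a phosphocholine residue and an N-acyl chain.
Monoisotopic masses are element-count sums over an embedded CODATA/NIST
table. sn-position is not distinguished (the MS cannot resolve it), so
`16:0/18:1` and `18:1/16:0` canonicalize to the same species.

Fragment prediction is a small editable rule registry rather than a full
fragmentation engine: positive mode gives the phosphocholine headgroup
cation at m/z 184.0733 (choline lipids) plus neutral losses of each acyl as
free acid and as ketene; negative mode gives per-chain carboxylate anions
and single-chain-loss ions computed from [M−H]⁻. Supported adducts are
[M+H]⁺, [M+Na]⁺, [M−H]⁻ and [M+HCOO]⁻, all singly charged. These rules are
sufficient for synthetic round trips and for distinguishing chain isomers;
ether/plasmalogen and oxidized lipids are out of scope.

The default search library enumerates chains of 12–24 carbons and 0–6
double bonds: all unordered pairs for diacyl classes, single chains for
lyso classes, five common sphingoid bases for SM, and — as a deliberate
restriction — cardiolipins with four identical chains only (the full
four-chain space is combinatorially explosive and no CL species is reported
in plasma EVs at quantifiable levels). ~21 700 species total.

## MS2 assignment score

For a candidate within the precursor tolerance, the spectrum's m/z span is
discretized into N bins of twice the fragment tolerance at the span
midpoint. If the candidate predicts T fragments, the spectrum has P peaks,
and k fragments match (each fragment consuming at most one peak, nearest
m/z first), the score is

    score = −log₁₀ P(X ≥ k),  X ~ Hypergeometric(N, T, P),

i.e. the chance that k or more predicted fragments are hit by randomly
placed peaks. The score is zero for k = 0, monotone in k, and independent
of peak intensities (a count-based formulation; intensity weighting is a
noted extension point). Candidates are ranked by score with ties broken by
smaller precursor error. Defaults: 10 ppm precursor, 20 ppm fragment
tolerance (accurate-mass Orbitrap-class data), minimum score 2
(P ≤ 0.01) — the acceptance threshold is a repository choice, since no
published threshold exists for this scoring variant. Manual confirmation is
operationalized as an exportable review table (top-3 candidates per
spectrum with matched fragments), not an interactive step.

Iterative-exclusion runs are merged by collapsing spectra that agree within
5 ppm precursor and 0.2 min retention time, keeping the richer peak list.

## MS1 quantification

Each assigned species is quantified by reconstructing the extracted-ion
chromatogram of its precursor within ±10 ppm over ±0.5 min around the
assigning MS2 spectrum's retention time (window width is a package choice;
full peak area, trapezoid rule, is integrated rather than apex intensity).
Abundances are reported relative to other species with the same headgroup —
lyso classes fold into their parent headgroup — and never across
headgroups, because no internal standards exist for absolute calibration.
Replicate spread is summarized with Tukey box statistics (type-7 linear
quantiles; whiskers to the most extreme point within 1.5×IQR).

## ³¹P NMR pipeline

1. **Apodization**: exponential line broadening, default 3.0 Hz; point k is
   scaled by exp(−π·lb·k·Δt). This adds exactly lb Hz (= lb/carrier ppm,
   carrier 242.93 MHz) to every Lorentzian linewidth without changing
   areas, trading resolution for SNR.
2. **Transform**: first FID point halved (DC correction), FFT, frequency
   axis in ppm (Hz divided by carrier MHz). Zero-order phase is chosen in
   closed form to maximize the total integrated real signal — for
   all-positive absorption spectra this equals positive-area maximization
   and replaces the manual phasing of interactive processing. First-order
   phasing is out of scope.
3. **Baseline**: polynomial (default order 2) fitted to signal-free points
   found by iterative 3σ clipping, then subtracted. Approximately
   idempotent; preserves peak areas of a spectrum plus ramp within 1%.
4. **Calibration**: the ppm axis is shifted so the tallest peak apex —
   phosphatidylcholine, the dominant class by construction of the assay —
   sits at exactly 0 ppm. Ties resolve to the higher-ppm apex with a
   warning; an all-noise spectrum (no point above 5× robust noise, MAD
   convention) raises a calibration error.
5. **Deconvolution**: nonlinear least squares (analytic Jacobian, trust
   region reflective, bounded) on a sum of pure Lorentzians — liquid-state
   ³¹P lineshape; Voigt is a noted extension. Initial centers come from
   local maxima exceeding 5× robust noise in both height and prominence;
   the high-level pipeline additionally seeds every shift-table position so
   classes near the quantifiability limit are fitted rather than silently
   missed (a detection-only seed misses ~1%-of-total peaks at SNR 100).
   Seeds closer than 0.06 ppm are merged to avoid splitting one line into
   two half-amplitude components. Fitted components below 1× noise in
   amplitude are discarded; centers may move at most 0.12 ppm from their
   seed and widths are bounded to 0.3 ppm, so a seeded-but-absent class
   cannot absorb a broad baseline swath. Areas use the closed form
   amplitude × fwhm × π/2.
6. **Assignment and quantification**: fitted peaks map to the nearest
   shift-table entry within tolerance (default ±0.12 ppm); unassigned peaks
   are excluded with a warning. Percentages are normalized over assigned
   area and sum to 100; classes under 3% are flagged not reliably
   quantifiable, matching the detection floor of the assay.

The packaged CUBO shift table (PC 0.0, SM −0.40, LPC +0.50, PE +0.85,
PI −0.95, PG +1.20, PS +1.50 ppm, all ±0.12) contains **synthetic,
user-editable** relative positions: the generator and the tests share this
table, so the pipeline's correctness never depends on literature shift
values. Replace the JSON with measured shifts for real samples.

## BBB permeability and DLS

Each assay compartment is an aliquot read from a pool:
total = reading × (total volume / sampled volume) / concentration factor
(e.g. a pellet from 1.4 mL resuspended in 280 µL is 5× concentrated).
Compartment totals are pooled (apical = supernatant + pellet, basal
likewise) and normalized so the four fates — passed the bare transwell
filter, passed the full barrier, retained apically, retained in endothelial
cells — sum to exactly 100%. The filter fraction is modeled as a
compartment of the same partition (the published four-row table sums to
100.0) rather than a separate no-cell control run.

DLS summaries use the intensity-weighted mean hydrodynamic diameter and the
relative-variance polydispersity index PDI = weighted variance / mean²,
which is 0 exactly for a point mass. Raw correlograms are not modeled, so
cumulant-fit PDI is out of scope; the relative-variance convention is the
documented stand-in.

## Synthetic-data generator

The generator carries **two ground truths per sample**: MS-visible species
fractions (within-headgroup, ionization-biased) and NMR mole fractions per
class. This mirrors real instruments: MS shows LPC 16:0 as a top-3
phosphocholine species while NMR puts total lyso-PC under its 3%
quantifiability limit; both facts hold simultaneously only because MS
response factors are not mole-proportional.

Default setpoints (editable JSON config): NMR class fractions PC 76.7%,
SM 20.3%, PE 1.5%, LPC 1.0%, PI 0.5%, PS absent; MS headgroup weights
PC 0.58, SM 0.24, PE 0.10, PI 0.08 with species profiles that are
PC 16:0/18:1-dominant and lyso-rich. Per-sample biological variability is
multiplicative lognormal jitter with σ = 0.03 on all fraction scopes
(renormalized), comparable to the ~5% relative replicate spread of the
NMR assay this emulates. The rank margins in the species profiles are wide
enough that the qualitative structure (PC > SM > PE/PI; a lyso-PC in the
top-3 PC species; no PS) survives the generator's own noise in ≥18/20
seeds.

LC-MS simulation: Gaussian elution at a uniform random retention time in
[1, 16] min of a 17-min gradient with a shared 0.06-min width (so XIC areas
stay proportional to abundances), MS1 scans every 0.05 min, per-species
lognormal intensity noise (σ = 0.15), 5 ppm Gaussian jitter on fragment
m/z, 2 ppm on precursor m/z (survey-scan accuracy is tighter than MS2
accuracy on Orbitrap-class instruments), uniform decoy peaks over the MS2
m/z range (the simplest null consistent with the hypergeometric score), and
four iterative-exclusion runs realized as abundance-ranked quartiles — a
precursor triggered in run k never reappears later.

³¹P simulation: one damped cosinusoid per class, amplitude equal to the
class mole fraction (so spectral areas are exactly proportional),
linewidths drawn from 0.02–0.08 ppm, a random global shift offset (absorbed
by calibration), 8192 complex points over a 12-ppm sweep, and complex white
noise scaled so the tallest noise-free spectral peak over noise σ equals
the requested SNR. Not modeled: relaxation pathways, ion suppression,
isotopologue envelopes, chromatographic physics — so passing tests
demonstrate correctness of the processing chain, not robustness to every
real-instrument artifact.

BBB readings are back-computed through the volume factors so the
percentage calculator inverts them exactly (plus optional Gaussian read
noise); DLS distributions are lognormal with exp(σ²)−1 = PDI, giving exact
target moments up to grid discretization.

## Numerical choices and degenerate inputs

- Robust noise is 1.4826 × MAD throughout.
- Fragment/peak matching processes fragments in ascending m/z; |Δm/z| ties
  go to the lower-m/z peak, making matching independent of input order.
- Quantile method is type-7 (linear interpolation).
- Empty inputs raise (`ValueError`) where the result would be undefined
  (no scans, zero total fluorescence, nothing assignable) and return empty
  results where emptiness is meaningful (no candidates within tolerance,
  peakless spectrum).
- Deconvolution non-convergence raises an error carrying the best-so-far
  fit.
- Problem sizes in the test-suite recovery studies — 5 replicates × 20
  seeds for NMR, 100 seeds for decoy robustness, ~25-species lipidomes —
  were chosen as the smallest sets that exercise the documented
  variability.

## Known limitations

- Fragment rules are minimal and headgroup-generic; positional isomers
  beyond chain composition, ether lipids, and isotope patterns are not
  modeled, and no decoy-database FDR is computed.
- MS quantification is relative within headgroup only.
- The BBB volume-accounting defaults describe one specific sampling scheme;
  all volume factors are explicit inputs because published methods rarely
  pin them down completely.
- PDI from relative variance is not numerically identical to cumulant-fit
  PDI for broad distributions.
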