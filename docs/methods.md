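# Methods

This note documents the models implemented in `gutiron`, the defaults
they carry, what the synthetic-data generators do and do not emulate,
and the numerical choices behind the results the tests and
`scripts/acceptance.py` compute.

## Growth model

Anaerobic growth is modelled with the modified Gompertz equation for
bacterial growth,

    OD600(t) = A · exp(−exp(k(λ − t) + 1)),   k = μₘ · e / A,

parameterized so that the three quantities a microbiologist reads off a
growth curve appear directly: the stationary-phase asymptote *A* (au),
the maximum specific growth rate *μₘ* (au/h), and the lag time *λ* (h).
Geometrically, the tangent to the curve at its inflection point
(t = λ + 1/k, OD = A/e) has slope μₘ and x-intercept λ; both identities
are exact consequences of the closed form and are enforced as invariants
(tested to 1e-9).

*A* is treated as an OD asymptote in absorbance units throughout,
matching how the fitted values are used downstream (an asymptote of
1.46 au, not a log population ratio); no logarithmic transform of the
data is applied.

**Fitting.** Nonlinear least squares in (log A, log μₘ, λ), which makes
positivity of A and μₘ structural; λ is bounded below at 0.
Initialization: A₀ = max(OD), μ₀ = steepest finite-difference slope,
λ₀ = first time OD exceeds 5 % of A₀ — robust for any sigmoid series
that spans lag and plateau. Convergence tolerances are tight
(xtol = ftol = gtol = 1e-15) so noiseless synthetic curves are recovered
to better than 1e-6 relative error; a fit reports its sum of squared
residuals, and flat or under-sampled (<5 point) curves fail loudly
rather than returning garbage. Replicates are fitted independently and
summarized as mean ± SD.

**Biomass factors.** OD maps linearly onto DNA concentration
(default 6.0 µg·mL⁻¹·au⁻¹), wet pellet mass (3.4 mg·mL⁻¹·au⁻¹) and cell
counts. `fit_conversion_factor` estimates such factors by ordinary least
squares with a free intercept and flags intercepts larger than 10 % of
the data range, which in practice indicates a blank problem.

## Cell accounting

The DNA mass of one chromosome equivalent is genome_bp × m_bp / N_A with
m_bp = 650 g/mol, the standard sodium-free average mass of a
double-stranded base pair. For the 6.26-Mbp *B. thetaiotaomicron*
VPI 5482 genome this gives 6.76 fg per cell and 1.48 × 10⁸ cells per µg
DNA (the two are exact inverses). Chained with the DNA-per-OD factor,
one OD unit corresponds to 8.9 × 10⁸ cells/mL (commonly rounded to
9 × 10⁸), and a maximum growth rate of 0.260 au/h to 2.3 × 10⁸ cells/h.
The package always computes these constants from the genome model rather
than storing rounded values; reports round only at display time. An
alternative occasionally quoted figure of ~1.3 × 10⁸ cells/µg is *not*
used — the genome-derived 1.48 × 10⁸ is kept consistently.

`heme_fraction` reports heme as a percentage of total iron to three
significant figures and tolerates a 5 % overshoot of heme above total
iron, since the two come from independent assays (LC-MS vs AA) with
independent errors.

## Quantification

Both instrument channels are linear:

- **AA (total iron):** absorbance vs ppm Fe standards (working range
  0.1–4 ppm). ppm is converted to µM via the iron molar mass
  (55.845 g/mol).
- **LC-Q-TOF-MS (heme, PPIX):** integrated EIC peak area vs µM standards
  (serial dilution 0.25–6 µM). Heme is extracted at m/z 616.17, PPIX at
  563.26; the 282.13 PPIX fragment is carried as annotation only.

Calibration curves are fitted with a free intercept (warning if
R² < 0.99 or the intercept exceeds 5 % of the maximum signal), and
quantification subtracts that intercept before dividing by the slope —
this reconciles a slope-only conversion formula with the reality of
blank offsets, and makes quantification invariant under any uniform
rescaling of instrument response applied to standards and samples alike.

EIC extraction sums, per scan, all intensities within ±0.02 Da of the
target m/z (Q-TOF-class accuracy; the width is a package default,
exposed in configuration). Peak areas are trapezoidal integrals over an
analyst-supplied retention window after subtracting a constant baseline
estimated as the median intensity outside the window; on baseline-free
synthetic data the subtraction is a no-op, which is tested.

Volume bookkeeping follows the bench workflow: the injected (diluted)
concentration from the standard curve is multiplied by the dilution
factor and by the extract-to-culture volume ratio to give nmol per mL of
original culture, then normalized by the culture's DNA yield to pmol per
µg DNA. Injected concentrations below 0.25 µM are flagged as below the
limit of detection; the numeric value is still reported (with the flag)
rather than zeroed, so downstream summaries remain computable. Technical
replicates are averaged after quantification.

## Reservoir extrapolation

The microbiome model defaults to 3.8 × 10¹³ cells at 5 pg wet mass each
(≈190 g, commonly quoted as ~200 g) with the 6.26-Mbp genome model,
giving 2.57 × 10⁵ µg of community DNA. A per-µg-DNA load L (pmol/µg)
then scales to L × total DNA × M × 10⁻⁹ mg. Two conventions matter:

- **The heme column is iron-equivalent mass** (M = 55.845 g/mol, one Fe
  atom per heme), not the mass of the hemin complex (651.94 g/mol).
  Only this convention makes the heme masses directly comparable to the
  total-iron masses, of which they are a subset; it is what reproduces
  heme pools of 2.0 and 1.7 mg from 140 and 120 pmol/µg.
- **Uncertainty** is propagated by the same linear scaling as the means
  (SD in pmol/µg → SD in mg); no covariance between conditions is
  assumed.

`buffer_days` divides the reservoir by the human daily iron absorption
range (1–3 mg/day) to express it as days of absorption buffered.

## Operon survey

Homology is a global-identity call: Needleman–Wunsch alignment under
match/mismatch/linear-gap scoring (+2/−1/−2) with percent identity
defined as identical columns over the *full* alignment length (gap
columns in the denominator — the conservative choice), thresholded at
30 %. Global rather than local identity is used; the simple scoring
scheme (no substitution matrix) is sufficient for threshold calls on
sequences simulated by substitution, and matrix support is a natural
extension. The aligner's traceback prefers diagonal over vertical over
horizontal moves, making reported alignments deterministic among
co-optimal ones; the score itself is checked in the test suite against
an exhaustive enumeration oracle and against Biopython's
`PairwiseAligner`.

Each genome is scored per bait as 0 (no hit), 1 (one hit) or 2 (two or
more copies), yielding the 6-character conservation pattern ordered
hmuY, R, S, T, U, V; tallies over genome sets are exact multiset counts.
Synteny requires all loci on one contig with adjacent intergenic gaps of
at most 20 kb (the convention of gene-cluster detection tools) and the
genomic gene order equal to the canonical operon order restricted to the
present genes, in either orientation — a reverse-strand operon reads
back-to-front and is accepted as synteny-preserving. Duplicated genes
break strict order by construction.

## Synthetic data: what it emulates, and what it does not

The generators are deterministic given a seed and reproduce the
statistical structure each analysis stage assumes:

- **Growth curves:** Gompertz signal plus additive Gaussian read noise
  (default SD 0.01 au), floored at zero. Default parameters are the
  rich-medium triplicate fit (A = 1.46 au, μₘ = 0.260 au/h, λ = 4.94 h)
  sampled every 30 min for 30 h.
- **Calibration series:** multiplicative Gaussian noise (default 1 %
  relative), matching the roughly constant relative error of instrument
  response; a zero standard yields a zero signal.
- **Chromatograms:** a dense scan grid (default 0.02 min interval, σ/5
  for the default 0.1-min peak width, which keeps trapezoidal areas
  within 1 % of the closed form h·σ·√(2π)) with Gaussian elution peaks
  per m/z channel; co-eluting peaks at one m/z sum. Per-scan m/z jitter
  (SD 0.003 Da) stays well inside the ±0.02 Da extraction window.
  Centroided events, isotope envelopes, ion suppression and instrument
  drift are *not* simulated.
- **Protein families:** derived sequences substitute exactly
  round(L × (100 − identity)/100) uniformly chosen sites of a random
  ancestor with different residues, so realized identity equals the
  target up to one site of rounding; no indels are introduced (the
  aligner still handles indels in real inputs).
- **Genome layouts:** operon loci laid out colinearly with configurable
  intergenic gaps; duplicated genes get a second copy 1 Mb away;
  `shuffle` permutes the cluster order to break synteny.
- **Culture bundles:** one forward model ties everything together. Each
  analytical subsample represents 10 mL of culture; the iron subsample
  (1 mL) is diluted 2× for AA, and the porphyrins are concentrated into
  0.1 mL, with heme injected at 25× dilution and PPIX neat — mirroring
  how an analyst places each analyte inside its calibrated range.  Both
  porphyrin channels are recorded in one chromatogram, each at its own
  injection dilution (a simulation convenience standing in for two
  technical injections).  Because every channel is linear, the
  quantification chain inverts the forward model exactly at zero noise —
  up to the EIC quadrature error of <0.1 % on the MS channels — and
  within 5 % at default noise.

Passing these tests demonstrates that the computational chain is
self-consistent and correctly inverts a faithful forward model of the
measurements; it does not validate matrix effects, extraction
recoveries, or biological variability in real samples. Likewise the
operon logic is validated on constructed genomes at desk scale, not by
reproducing database-scale survey counts, which depend on database
versions and profile-search tooling outside this package's scope.

## Problem sizes and runtime

Default test and acceptance workloads are deliberately compact: growth
fits use 60–61 point curves (20 replicates for the Monte-Carlo recovery
check), chromatograms hold 401 scans, alignment oracles enumerate all
pairs to length 3 and sample longer pairs, and constructed proteomes use
120–300-residue sequences. All are sizes a laptop handles in seconds
while still exercising every code path at the fidelity the analyses
require.

## Known limitations

- Single-species abstraction: the microbiome extrapolation assumes the
  whole community is *B. thetaiotaomicron*; community composition
  weighting is out of scope.
- The Gompertz fit assumes a single sigmoid phase; diauxic or declining
  cultures need a different model (logistic/Baranyi are non-goals).
- mzML is supported read-only (MS1 scans via pyteomics); the canonical
  on-disk chromatogram format is CSV.
- Alignment uses uniform match/mismatch scores; distant homologs that a
  substitution matrix or profile method would recover may be missed —
  consistent with identity-threshold surveys, but a known blind spot.
- The LOD flag is a fixed injected-concentration threshold (0.25 µM);
  signal-to-noise-based detection limits are not modelled.
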