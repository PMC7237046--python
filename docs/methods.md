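# Methods

## Model

`snpfold` quantifies how a single-nucleotide substitution in an RNA changes
the binding affinity of a single-stranded-RNA-binding protein (the working
example throughout is a HuR-like protein: 7-nt footprint, AU-rich
preference), when the only coupling between the variant and the protein is
the RNA's ensemble of secondary structures.

**Folding ensemble.** Secondary structures are all pseudoknot-free sets of
canonical pairs (GC, AU, GU) with hairpin loops of at least
`min_hairpin_loop = 3` unpaired bases.  The partition function
Z = Σ_structures exp(−E/kT) is computed by the standard O(N³) interval
recursion; the open chain carries weight 1, so G = −kT ln Z ≤ 0.  Hard
constraints remove every structure in which a constrained base is paired —
this is how a bound protein footprint is modelled: bound bases cannot pair.

**Built-in energy model.** The default energies are one term per pair type
(GC −3.0, AU −2.0, GU −1.0 kcal/mol), an optional per-stacked-pair bonus
(default 0), and T = 310.15 K (kT ≈ 0.6163 kcal/mol).  This deliberately
simple model makes the entire package exactly testable: an exhaustive
structure enumerator (N ≤ 25) reproduces every quantity to ~1e-15, and all
tests and acceptance properties run on it.  A `vienna` backend adapts the
same interface onto the ViennaRNA Python bindings (full Turner parameters)
for realistic energetics; it shares the constraint semantics but not the
absolute normalization of Z, so only free-energy differences and unpaired
probabilities should be compared across backends.  Dangling ends,
loop-length penalties and non-canonical pairs are outside the built-in
model.

**Opening free energy.** For a footprint interval [i, i+k),
p_open = Z(footprint forced unpaired)/Z and ΔG_open = −kT ln p_open ≥ 0.
The effect of a substitution on a fixed footprint is
ΔΔG = ΔG_open(mut) − ΔG_open(wt); the protein's intrinsic binding energy is
allele-independent and cancels, collapsing the four states
(wt/mut × bound/unbound) to two constrained folds per allele.  Note the
sign convention: positive ΔΔG means the mutant footprint is *harder* to
open, hence harder to bind.  (The opposite verbal convention also
circulates; this package follows the formula above literally.)

**Effective dissociation constant.** With a complete k-mer → K_D table
(RNAcompete-style, nM; `inf` = non-binder, contributing exactly zero), the
dilute single-occupancy limit gives

    1/K_eff = Σ_i  p_open([i, i+k)) / K_D(w_i)

summed over all footprint placements (`ensemble` mode) or one designated
placement (`single_site` mode, the hard-constraint analysis isolating the
central binding site).  Footprints overhanging the window are skipped — no
padding or wrap-around.  The closed form is validated against an
independent oracle that enumerates explicit (structure, bound-protein)
states and extracts K_eff from the dilute-limit bound fraction.  The
affinity ratio of a variant is K_eff(alt)/K_eff(ref); ratios above 1 mean
the alternate allele makes binding harder.  Multi-protein occupancy and
cooperativity are out of scope, as are protein-concentration-dependent
occupancy curves.

## Numerical choices

* The recursion runs unscaled first (exact; the open chain is weight 1).
  If Z overflows float64 — long or pairing-rich windows — it is recomputed
  with a per-nucleotide Boltzmann rescaling (`scale_energy`, default
  0.7 kcal/mol per base), which cancels exactly in the returned log Z.
  With the default scaling, sequences to roughly 600 nt are representable;
  beyond that an explicit overflow error is raised rather than a silent
  loss of precision.
* All probabilities are formed as exp(Δ log Z), never as ratios of raw Z.
* `1/inf = 0` is handled by skipping non-binder terms, so `inf` table
  entries are exact, not approximate.
* Ratios exactly equal to 1 (full float equality) are excluded from the
  binomial counts and reported separately.
* Coordinates are 0-based half-open everywhere internally; VCF positions
  are converted on read.  The "middle" of a site interval [start, end) is
  ⌊(start+end)/2⌋.

## Pipeline

Variants are paired with the nearest binding site whose middle lies within
40 nt (inclusive; ties to the smaller site start).  Within each site the
k-mer with minimal table K_D is the motif (ties leftmost); a window of
length L ∈ {101, 201, 401} (odd; default 201) is centred on the motif
center and both alleles are folded.  Records are skipped — never truncated
— and counted in a run report when the window overruns a transcript end,
the site is shorter than the footprint, the stated reference allele
mismatches the transcript, the transcript id is unknown, or the variant
falls outside the window (possible because the motif center need not
coincide with the site middle).  Canonical-transcript filtering is an
optional id-allowlist; coordinate liftover from genome to transcript is
out of scope (inputs are already in transcript coordinates).

**Asymmetry statistic.** The cohort summary counts ratios above and below
1 and reports the one-sided exact binomial p-value P(X ≥ n_above) for
X ~ Binomial(n_above + n_below, 1/2), computed via the regularized
incomplete beta function at any n (it is the exact tail sum, and at large
n it is cheaper than it looks).  The direction tested — an excess of
ratios above 1, i.e. of variants that make binding harder — is fixed in
advance, which keeps the p-value uniformly distributed under a symmetric
null; a "whichever direction won" p-value would not be.  Fold-change
strata are < 2, [2, 3), ≥ 3; distance histograms per stratum report the
population standard deviation with a seeded 1000-resample bootstrap SE;
cumulative ratio curves reciprocate sub-1 ratios onto [1, ∞).

## Synthetic data

The generators emulate the shape of the real inputs without any external
data:

* Transcripts: i.i.d. uniform bases.  Real transcripts have composition
  bias, repeats and genuine structure; none of that is emulated, so
  passing tests demonstrate correctness of the machinery and calibration
  under the stated null, not performance on biological sequence.
* Affinity tables: complete 4^k maps K_D(w) = K0 · exp(β · GC(w)) with
  lognormal jitter (defaults K0 = 5 nM, β = 6, σ = 0.5, k = 7), giving an
  AU-rich preference and a few-orders-of-magnitude dynamic range like an
  RNAcompete measurement; real tables are not a smooth function of GC
  content.
* Planted switch: a 13-nt duplex arm (AU-rich motif plus GC clamps) whose
  reverse complement sits 10 nt downstream; one allele of a variant in the
  partner arm — 23 nt from the motif center, well outside the motif —
  completes the duplex and sequesters the motif, the other breaks it.
  GC-rich clamps keep the planted effect strong under the simplified
  energetics.
* Cohorts mix planted cases (direction "gt" with probability `asymmetry`)
  and neutral cases (a random variant near a random site; symmetric by
  exchangeability of reference and alternate in a uniform-random
  transcript).  Transcripts carry a 40-nt margin beyond the analysis
  window so off-center motifs do not trigger edge skips.

## Statistical checks and problem sizes

The test suite runs the scan at 30 sequences × 101 nt (footprints 7 and
10), the planted-switch battery over 50 seeds at L = 201, and the null
calibration over 200 cohorts of 300 variants each at L = 61 in single-site
mode.  The calibration cohort size follows from the discreteness of the
exact binomial p-value: it is uniform only at its attainable atoms, with
step ≈ √(2/πn), so n ≈ 300 keeps that step (~0.046) below what a
200-sample Kolmogorov–Smirnov test at the 1% level can resolve.  Under the
built-in energy model the random-scan standard deviations are ~0.2–0.5
kcal/mol at 30 nt; kcal-scale magnitudes comparable to Turner-parameter
energetics are expected only under the `vienna` backend, so the shape
properties (zero distal mean, positive distal std, wider reach of the
larger footprint) are the tested claims, not absolute magnitudes.

## Known limitations

* The built-in energy model is not Turner-accurate by design; use the
  `vienna` backend for realistic magnitudes.
* Ensemble-mode K_eff over a length-L window costs ~L constrained folds
  (O(L⁴) overall); L = 401 windows are noticeably slow in ensemble mode.
* One protein, one footprint at a time; no cooperativity, no
  double-stranded binders, no indels or modified bases, no haplotypes.
* Window overruns are skipped, not truncated, so variants very close to
  transcript ends are systematically excluded and counted in the report.
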