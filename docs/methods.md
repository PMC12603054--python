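# Methods

This note documents the models behind `xlmsbench`: what the generator
emulates, how the identification chain works, which parameters matter,
and where the design was genuinely open.

## The simulated experiment

The target experiment is a single purified protein (Cas9-scale),
chemically crosslinked on lysines, digested with trypsin and measured by
nanoflow LC-MS/MS with FAIMS and data-dependent acquisition. The
generator reproduces the *statistical* structure of such a run — not the
physics — at the level where the downstream analyses are sensitive to it:
which precursors exist, how abundant they are, which are transmitted and
selected, and what their fragment spectra contain.

### Structure and links

The protein fold is a self-avoiding random walk of Cα atoms: steps of
3.8 ± 0.05 Å, a 3.5 Å clash distance, confined to a sphere of radius
3.2·n^⅓ Å (globular-protein packing density, ~130 Å³ per residue). A
surface-exposure proxy is the min–max-normalized distance from the
centroid; it stands in for solvent accessibility, which a Cα-only chain
cannot provide.

True links are drawn from lysine pairs whose carrier tryptic peptides do
not overlap. A crosslinked lysine blocks cleavage, so each linked site is
mapped to the shortest peptide (≤ 2 missed cleavages, 4–45 residues)
containing it away from the cleaved C-terminus. A fraction
`1 − overlength_fraction` (default 0.9) of links respects the linker's
maximum Cα–Cα span; the remainder is sampled beyond it, emulating the
over-length links real datasets contain through flexibility and false
assignments.

### Abundance, retention, charge

Precursor abundances are log-normal with default (μ = 13.8155, σ = 2.0)
on the natural log — median 10⁶, roughly 12 % of links below 10⁵ and 12 %
above 10⁷, matching the low/medium/high stratification bounds the
analysis uses. Abundance is coupled to surface exposure through a
Gaussian copula: the latent normal is ρ·z(exposure rank) + √(1−ρ²)·ε with
ρ = 0.6 by default. The realized Spearman correlation of a Gaussian
copula is (6/π)·asin(ρ/2) ≈ 0.58, and that is what recovery tests
measure. Retention time is a rank transform of summed Kyte–Doolittle
hydropathies of the two peptides across the gradient — only the ordering
is meaningful, which is all the feature-matching stage needs. Charge
profiles are a discretized normal over 3+–6+ centered by combined peptide
length; linear-peptide background precursors carry 1+–3+.

### FAIMS, features, spectra, acquisition

FAIMS is modeled as pure transmission filtering: a Gaussian in CV per
charge state, centered at −30 V for 1+/2+ and −49 V for ≥3+ (width 10 V).
No ion-accumulation or space-charge effects are modeled; the emulated
mechanism is background reduction and charge filtering. Transmission
efficiencies are free parameters — no quantitative curves exist to
calibrate against — so only the *positions* of the optima are meaningful.

One MS1 feature exists per (link, charge, CV) channel whose transmitted
intensity (abundance × charge fraction × transmission) clears a detection
floor of 5×10³. Feature m/z carries a ppm error drawn from
`mass_error_ppm` (default bias 0, sd 2 ppm); `intensitySum` is apex ×
U(2, 5); elution is triangular with ~0.4 min base width.

Fragment spectra contain the theoretical b/y ions (fragment charges 1–2)
with intensities uniform in [0.2, 1]× an abundance scale, plus Poisson
noise at `noise_peaks_per_100Da` (default 4) with intensities in
[0.005, 0.15]× scale. Cleavable linkers emit short/long arm fragments for
every link-spanning ion, producing the characteristic doublets. Isotope
envelopes, profile peaks and chimeric spectra are out of scope.

The DDA loop steps through the gradient one cycle (1 s) at a time,
rotating through the CV program. Each cycle records an MS1 of all
currently eluting features at that CV, then fragments the top-15 eligible
precursors (charge 3+–6+, m/z 375–1300, not excluded); fragmented
(m/z, CV) entries are excluded for 15 s. Every feature and spectrum
carries its generating link id, so acquisition, identification and
quantification can all be graded exactly.

### What passing tests do and do not show

Because spectra are generated from the same fragment model the search
uses, identification here is *easier* than on real data: there are no
co-isolated chimeras, no PTM surprises, no intensity-dependent peak
quality. End-to-end recovery (≈99 % at default noise) therefore validates
the *bookkeeping* — candidate enumeration, scoring monotonicity, FDR
accounting, coordinate mapping — not real-world search sensitivity.
Conversely, the FDR calibration, oracle-equivalence and contract tests
are substrate-independent and do transfer.

## Identification chain

The search database is the target digest (≤ 2 missed cleavages, length
≥ 4) plus pseudo-reverse decoys (sequence reversed, C-terminal residue
fixed, masses preserved). Decoys whose sequence collides with a target —
pseudo-reversal is a fixed point for palindromic prefixes — are dropped:
such decoys carry no error information and create degenerate score ties.

The linear first pass scores each spectrum against linear peptides within
10 ppm precursor tolerance; spectra with a confident linear PSM
(target-decoy q ≤ 0.01) are removed, and the median ppm error of those
PSMs recalibrates the remaining spectra (the median is exactly nulled by
construction). The crosslink search then enumerates peptide pairs whose
summed mass plus the linker spacer matches the precursor within 10 ppm
and takes the best candidate per spectrum by adaptive de-noised score.
Ties break toward fewer theoretical ions, then lexicographically-first
notation, making the search deterministic. For cleavable linkers an
optional doublet pre-filter restricts candidates to peptide masses
corroborated by arm doublets; it is off by default since doublet counts
rise with spectral complexity and bring false positives.

The score is the upper binomial tail of the matched-ion count. The
per-ion chance probability p = 2·tol·n_peaks/span (capped at 0.5) uses
the de-noised spectrum's peak count and m/z span, with tol evaluated at
the mean theoretical ion m/z. The published engines' scoring functions
are proprietary/unpublished, so a transparent, oracle-testable surrogate
was chosen deliberately; every acceptance-relevant decision uses score
ranks only. Numerically the tail is the regularized incomplete beta
function, falling back to scipy's log-sf below double underflow.

## FDR estimation

CSMs are TT/TD/DD by the decoy status of their two peptides. At each
score threshold FDR = max(0, #TD − #DD)/max(1, #TT): each TD carries one
decoy hit, each DD two, and subtracting DD avoids double-counting the
decoy background. q-values are the running minimum from the bottom of the
ranking; zero targets means q ≡ 1. Reported sets keep TT CSMs with
q ≤ 0.01.

In entrapment simulations (exchangeable null scores, class probabilities
¼/½/¼), the realized FDP of the 1 % filter averages ≈1.7 %: selecting the
threshold on the q running minimum is mildly anti-conservative when decoy
counts near the cut are small. The calibration tests therefore use a
2×α Monte-Carlo band. A +1-style pseudo-decoy correction would restore
strict conservativeness at a sensitivity cost; the uncorrected estimator
is kept as the simpler, commonly used form.

Residue-pair-level FDR re-applies the same estimator to URP best scores
over the unfiltered (target + decoy) aggregation. Whether pair-level
control should be inherited from or independent of CSM-level control is
genuinely underdetermined; both levels are exposed and the default
reporting path filters at CSM level first. Self-links (identical
protein position on both sides) are excluded.

## Feature matching and structure analysis

Feature detection links centroids across consecutive same-CV survey scans
within 10 ppm (charge states are taken as annotated by the simulator —
isotope-envelope charge calling is out of scope). Matching to CSMs
requires equal CV and charge and |Δm/z| ≤ 0.01 (read as absolute Th; the
tolerance is quoted unitless on the m/z scale where Th and ppm-scale
readings differ by ~an order of magnitude, and the absolute reading is
the stricter, simpler one). Among candidates the minimal
|rt_apex − (rt − shift)| wins, ties to the higher apex intensity. The
retention-time alignment is a single global offset, estimated as the
median (CSM rt − feature apex rt) over first-pass matches and applied in
a second pass — the simplest scheme that "minimizes" the RT difference;
no nonlinear warping is attempted (single-run matching does not need it).

Distances are Euclidean between Cα atoms — robust to missing side chains;
the cutoff (default 20 Å) is compared strictly (`< cutoff`) and is
configurable for side-chain-aware conventions. Residues absent from the
structure are excluded from proportions and reported as a count, never
imputed.

## CV-set optimization and benchmark metrics

Per-CV URP sets are partitioned exactly (UpSet regions); all CV k-subsets
are enumerated and ranked under three criteria: (1) largest union with
summed pairwise overlap as ascending tie-break ("most crosslinks, least
redundancy"), (2) smallest summed pairwise intersections, (3) largest
k-way intersection. "Overlap" is ambiguous between readings (1) and (2);
both are computed and every returned combination carries all three
statistics so users can re-rank. Replicate dispersion is the mean
absolute distance from the replicate mean — the error-bar convention the
benchmark comparisons use — rather than the conventional standard
deviation. Printed-percentage comparisons round half away from zero at
the printed precision; `percent_increase` reports one decimal and an
integer variant.

## Numerical and scale choices

Default problem sizes are chosen for a single-CPU desk run: a 700-residue
protein (~70 lysines, enough within-20 Å site pairs for 500 links), a
70 min gradient with three CVs (4200 MS1 cycles, ~7600 MS2), giving a
full pipeline run of ~45 s and a complete test suite under two minutes.
The mass table and monoisotopic constants come from pyteomics; masses are
memoized per configuration. All randomness flows from a single
`numpy.random.default_rng(seed)`; identical configurations produce
byte-identical output files, which the test suite asserts by hashing.

Known limitations: no inter-protein links (single-chain substrate), no
isotope or chimera modeling, transmission curves uncalibrated, linear
quantification limited to apex/sum bookkeeping, and a scoring surrogate
that ignores fragment intensities. These bound what conclusions transfer
to instrument data; the package's claims are about the analysis logic,
not about instruments.
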