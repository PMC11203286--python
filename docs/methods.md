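# Methods

## The analysis model

`floranmr` treats a ¹H-NMR spectrum of a flower extract as a holistic
metabolite fingerprint. The analysis chain makes three modelling
commitments:

1. **Fingerprint construction.** After referencing to TMS/TSP at
   0.0 ppm and baseline removal, the spectrum is reduced to rectangular
   buckets of 0.01 ppm over 1–12 ppm. Only positive intensities are
   integrated and no per-bucket scaling is applied: a bucket's value is
   the sum of `max(intensity, 0) × |axis step|` over the points whose ppm
   value falls in its half-open `[low, high)` interval. Buckets that
   overlap a residual-solvent window — water 4.75–5.06 ppm, methanol
   3.16–3.45 ppm, reference −0.05–0.05 ppm — are dropped entirely, which
   leaves 1040 of the 1100 buckets. Per spectrum, bucket values at or
   below the vector mean are set to 0 and the rest binned linearly onto
   the integers 1…100 (minimum above-mean value → 1, maximum → 100,
   round half up). This quantization makes fingerprints scale-free:
   multiplying a spectrum by any positive constant leaves its normalized
   vector unchanged.
2. **Classification.** Fingerprints are compared by Euclidean distance
   and clustered agglomeratively under Ward's minimum-variance
   criterion. Cutting the dendrogram at the number of species gives flat
   clusters; a species is *recovered* only if all of its samples share
   one cluster and that cluster contains nothing else. This purity
   definition is deliberately strict — one misplaced sample spoils both
   the donor and the recipient species.
3. **Identification.** Picked peaks are grouped into multiplets and
   matched against a library of 20 signatures (δ, multiplicity, *J*).
   A metabolite is identified only when *every* resonance of its
   signature is matched, so multi-resonance compounds (isoleucine has
   six entries) need their full pattern present; one observation may
   serve several metabolites, as in the crowded sugar region.

## Synthetic data generator

No public archive of flower-extract spectra backs this workflow, so the
generator is a first-class, tested component that produces cohorts with
the statistical structure the analysis assumes.

Spectra are built directly in the frequency domain. Each resonance is
expanded into multiplet lines — doublet: two half-weight lines `J/field`
apart; triplet: 1:2:1 lines spaced `J/field`; doublet of doublets: four
quarter-weight lines at `(±J1 ± J2)/(2·field)`; unresolved multiplets
(no *J* reported): five equal lines spanning 0.03 ppm, an envelope that
peak picking treats as one cluster. Lines are Lorentzians normalised to
unit apex height. Defaults emulate a routine 400 MHz acquisition: 32768
points over −0.5 to 12.5 ppm, 1.5 Hz linewidth (ordinary solution-state
resolution), Gaussian noise with σ = 0.002 of a unit singlet's height
(high signal-to-noise, as in clean survey spectra), and residual peaks
at 4.87 ppm (water), 3.31 ppm (methanol) and 0.0 ppm (reference) that
deliberately sit inside the exclusion windows so the exclusion logic is
always exercised.

A cohort design assigns each species a concentration profile over the
library. The packaged fixture (33 samples, 23 species) draws each
profile value from lognormal `exp(N(0, 1))` seeded by the species name
and a fixed profile seed, giving every species a distinct but
reproducible fingerprint; replicates within a species jitter
concentrations with a mean-preserving lognormal at cv = 0.10, a
realistic biological-replicate spread for plant extracts. Flower color
variants are expressed as explicit edits applied before rendering —
delete a resonance, scale a signature, or add a variant-specific signal
— for the three species in the fixture that carry color variants.
Seeding is splittable: `SeedSequence([master_seed, crc32(sample_id)])`
yields each sample's jitter and noise streams, so any sample can be
regenerated alone.

What the generator does *not* emulate: free-induction decay,
Fourier-transform artefacts, phase errors, pH- or temperature-dependent
shift drift, peak-shape distortions from imperfect shimming, and
between-species overlap of unknown (non-library) compounds. Passing
tests therefore show that the analysis chain is correct and
discriminates species under the stated concentration model — not that
real flower cohorts are this cleanly separable.

## Numerical choices

- **Bucket edges** come from index arithmetic (`low + i·width`), and
  points are classified against those exact float edge values with a
  binary search, so interval membership is bit-reproducible and matches
  a per-point linear-search oracle exactly. Exclusion overlap uses an
  epsilon of `width × 1e-6` to keep a bucket whose edge only touches a
  window boundary within float error.
- **Ward linkage** is implemented with the Lance–Williams update on
  squared distances (Ward.D2 semantics): two singletons merge at their
  Euclidean distance and heights are reported on the distance scale.
  Ties break toward the lowest (i, j) cluster-index pair. Tests check it
  against both scipy's implementation and an exhaustive oracle that
  evaluates every candidate merge's exact variance increase from
  centroids.
- **Calibration** takes the apex within ±0.2 ppm of the expected
  reference position; a reference is accepted only above 3× the median
  absolute deviation of the window, a robust, parameter-free floor. The
  operation is idempotent: a calibrated spectrum re-calibrates with
  shift 0.
- **Baseline** removal is asymmetric least squares (smoothness 1e7,
  asymmetry 0.01, ≤10 reweighting iterations) — the standard choice for
  spectroscopy baselines, fully specifiable, with a sparse pentadiagonal
  solve per iteration. Phase correction is intentionally absent
  (synthetic spectra are absorption-mode; real raw data must be phased
  upstream).
- **Peak picking** thresholds at 5× a noise floor of 1.4826 × MAD of
  the intensities; with sparse peaks the global MAD is dominated by
  baseline and converges to the noise σ. Under the default noise model
  a pure-noise spectrum yields a false peak with probability ≈ 1%.
- **Matching tolerances** are 0.03 ppm in δ and 1.0 Hz in *J* — within
  the library's reported precision (two decimals in ppm, one in Hz).
  Two matching rules deal with overlap explicitly. First, when chained
  peaks form one observation spanning several true multiplets (adjacent
  signals closer than the 12 Hz grouping window, e.g. malate,
  methionine and citrate at 2.73–2.79 ppm), the δ tolerance is measured
  to the observation's line span rather than its centroid; for an
  isolated multiplet the span collapses and the rule reduces to plain
  centroid distance. Second, a library doublet-of-doublets whose two
  couplings differ by less than the *J* tolerance (aspartate:
  *J* = 3.4, 3.5 Hz) is physically indistinguishable from a triplet at
  1.5 Hz linewidth, so an observed triplet is accepted for it, with the
  estimated *J* compared against the mean coupling.
- **Normalization quantization** rounds half up; normalized tables are
  integer-valued, which fixes the pipeline's byte-for-byte determinism
  across platforms.

## Problem sizes

The test suite and the acceptance script run everything at the study's
native scale — 33 spectra of 32768 points, 1040-bucket fingerprints —
because the whole pipeline completes in seconds; the Ward-oracle
cross-checks use 100 random problems at n ≤ 6, where exhaustive
variance search is exact and cheap. The effect-size sanity check scales
cv and noise by 1×/2×/4× and observes recovery degrade monotonically
(23 → 20 → 15 species at the fixture seed).

## Known limitations

- Matching is qualitative: relative peak areas are rendered proportional
  to proton counts but are not used as a matching criterion, since
  concentrations vary across samples.
- The region taxonomy assigns boundary shifts to the lower region
  (6.00 ppm is "sugar", 3.50 ppm is "organic/amino") — one fixed
  convention where common usage is ambiguous.
- JCAMP-DX support covers the `XYDATA=(X++(Y..Y))` AFFN subset written
  by this package and similar exporters, not compressed (DIFDUP) forms;
  raw Bruker directories are out of scope.
- The fixture roster reproduces the *structure* of a 33-sample,
  23-species survey (replicated color variants and varieties), not any
  measured concentrations; see the header of
  `src/floranmr/data/default_cohort.yaml`.
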