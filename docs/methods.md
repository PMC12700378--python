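# Methods

## Scope and model

`methylscan` analyses per-site modified-base pileups (bedMethyl, modkit
dialect) against a reference genome.  The underlying observation model is
binomial: at site *i* with true per-read methylation probability *p_i* and
valid coverage *d*, the modified count is Binomial(*d*, *p_i*), so the
reported frequency *f_i = n_mod/d* estimates *p_i* with variance
*p_i(1−p_i)/d*.  Everything downstream — thresholding, motif summaries,
palindrome calls, profiles — operates on these frequencies.  Basecalling,
alignment and pileup generation are out of scope; the package consumes
their output.

Coordinates are 0-based half-open throughout; GFF3 input is converted on
read.  Frequencies are fractions in [0, 1] internally and rendered as
percent only in report tables.

## Per-site statistics

- **Nucleotide filtering.** A 6mA record is kept only when the
  strand-aware reference base is adenine (plus-strand A for `+`,
  plus-strand T for `−`); 5mC analogously for cytosine.  This removes
  calls sitting on SNV/misalignment positions.  N bases never yield
  sites.
- **Replicate aggregation.** Sites are keyed by (contig, position,
  strand, modification).  A site is summarized when present in all
  replicate libraries (configurable); the SD is the *sample* SD (n−1) —
  with n = 3 replicates the population form would be substantially
  biased.  Zero-coverage sites have no frequency and are excluded, never
  silently scored 0.
- **WGA correction.** A whole-genome-amplified library is enzymatically
  unmethylated, so its apparent frequency estimates the modified-basecall
  error floor.  `corrected = clamp(mean − wga, 0, 1)`; sites missing from
  the control are corrected with 0 and flagged.  Correction applies to
  replicate means; per-library correction is available by correcting each
  library separately before aggregation.
- **Thresholds.** "Methylated" means frequency ≥ 0.70 (inclusive
  everywhere the 70% threshold appears).  Context anchors instead use
  strictly greater comparisons (> 0.80 for 6mA, > 0.50 for 5mC),
  mirroring the conventions the thresholds come from; both choices are
  deliberate and fixed.
- **SD–mean regression.** Ordinary least squares, linear and quadratic,
  of per-site SD on per-site mean.  Under the binomial model the SD is
  concave in the mean (≈ sqrt(p(1−p)/d) scaled by replicate structure),
  so the quadratic R² should exceed the linear R²; the fit report exposes
  both.  The 99th percentile used for the high-variance flag is computed
  with linear interpolation (numpy default), strictly-greater comparison.

## Motifs

A motif is an IUPAC string plus the index of the methylated base, always
written 5'→3' on the methylated strand.  Scanning matches the pattern on
the plus strand and its reverse IUPAC complement for minus-strand
occurrences; overlaps are all reported.  The methylated-base coordinate is
`match_start + mod_offset` (plus) or `match_start + len − 1 − mod_offset`
(minus).  A motif equal to its own reverse complement is palindromic and
yields one methylated adenine per strand per occurrence.

The built-in nine-motif catalogue (CTAG, CTAGY, CTNAG, TTCTNAG, CTAAG,
CTNNAG, CYTAGC, GTNNAC, TGNNCA) places the methylated adenine at the
position shared with the CTAG/CTNAG core; five of the nine are
palindromic.

**Palindrome calls.** An occurrence is *full* when both strands are ≥ the
threshold (default 0.70), *hemi* when exactly one is, *unmethylated*
otherwise.  The sources the 70% default comes from also mention a 75%
variant; `--full-threshold` exposes it, the inconsistency is not resolved
here.  Proportions are recomputed within each replicate to give a
per-class mean ± SD.

**Discovery** is a deliberately simple stand-in for dedicated tools such
as Nanomotif, adequate for dense small-genome methylomes: (i) collect
anchors (sites ≥ 0.70); (ii) enumerate every specific k-mer window
(k = 4..8) containing an anchor, read on the anchor's strand; (iii) score
each context that recurs in ≥ 2 anchors by the mean frequency of its full
genomic site set (via an exact k-mer position index, equivalent to the
scanner); (iv) greedily generalize positions to `N` or a two-letter code
while the expanded set's mean stays within 0.10 of the seed's; (v) trim
flanking `N`s, canonicalize (lexicographically smaller of motif/reverse
complement when the swap preserves the modified base), de-duplicate, and
drop motifs whose site set is a subset of an equally methylated accepted
motif.  Reported motifs must have mean ≥ 0.5 over ≥ 20 sites and are
sorted by genomic methylation fraction.  The anchor-support floor of 2 is
intentionally permissive: weakly methylated motifs (p ≈ 0.6 at depth 50)
produce only a handful of ≥ 0.70 anchors.  Degeneracy is limited to `N`
and two-letter codes, matching what appears in real viral motif
catalogues.

**In-silico digest.** Recognition occurrences are located on the plus
strand; the sensitive adenine is checked on both strands (absent sites
count as unmethylated).  `blocked_by_6mA` enzymes cut only when both
strands are below the threshold; `requires_6mA` enzymes cut when either
strand reaches it.  These are exact complements, so DpnI and DpnII
partition the GATC sites — the intended control behaviour.  Hpy166II
ships insensitive (its 6mA sensitivity at GTNNAC is not established);
XhoI and XbaI ship as blocked, reflecting their use as
methylation-blocking proxies.  Fragment lengths always sum to the genome
length.

## Context profiles

Offsets are strand-relative (negative = 5' of the anchor on its own
strand); minus-strand anchors read the reverse complement.  Anchors
within the flank of a contig end are dropped, not padded.  Co-methylation
profiles report, per signed offset, the mean frequency of same-strand and
opposite-strand sites of the same modification; offsets with no sites are
missing (NaN), never 0.  For a palindromic motif like GTNNAC the paired
adenine sits at opposite-strand offset −3, which the profile reproduces
by construction.

## Metagene profiles

Gene bodies are split into 10 bins with boundaries `floor(i·L/10)` (the
floor fixes remainders deterministically); 1 kb flanks are split into 20
windows of 50 bp.  U1..U20 run toward the gene start (U20 immediately
upstream), D1..D20 away from the end, all oriented along the coding
strand; *sense* sites lie on the coding strand.  Site frequencies are
averaged **per gene first**, then the median and a seeded bootstrap 95%
CI (1000 resamples) are taken across genes — so long genes do not
dominate; per-site weighting is available by pooling the per-gene tables.
Genes shorter than the bin count are excluded and counted; overlapping
genes each keep their own copy of shared sites.

The source analyses state significance levels but not the test; we use
two-sided Mann–Whitney with Holm correction (nonparametric — frequency
distributions are zero-inflated and heavy-tailed), which is a documented
deviation risk if the original used something else.  The compact letter
display assigns one letter per maximal clique of the
not-significantly-different graph, ordered by median, so two windows
share a letter iff no corrected test separates them.

## Enrichment

Sliding windows are left-anchored half-open intervals [s, s+5000) every
1000 bp; trailing windows are truncated and renormalized (score = high
sites / covered candidate sites in the window).  The anchoring choice is
ours — the verbal description is ambiguous between centred and anchored
windows.  z-scores are standardized over non-missing windows (population
SD); an all-constant track gets z = 0.  Tracks are computed per strand
and pooled, default per strand.

Per-gene motif overrepresentation replaces the DistAMo web service with a
transparent binomial model: with N genome-wide occurrences (strand
specific) on a genome of length L, the per-strand-base rate is
p̂ = N/(2L), a gene of length ℓ expects 2ℓp̂ occurrences, and
z = (obs − exp)/sqrt(exp(1−p̂)).  Any overlap between the match interval
and the gene interval counts.  Codon-redundancy weighting is **not**
reproduced; only the z ≥ 2 flag semantics are kept.  Because counts are
discrete, the empirical flag rate under a uniform null sits slightly
above the Gaussian 2.28% upper tail (Poisson skew), which the calibration
test accounts for.

## Synthetic methylomes

The generator emulates the statistical structure of a replicated
small-genome nanopore methylation experiment:

| parameter | default | rationale |
| --- | --- | --- |
| genome GC | 0.29 | AT-rich algal-virus-like composition |
| background p | 0.03 | basecaller noise on unmethylated adenines |
| mean depth | 50 | Flongle-scale coverage of a small genome |
| replicates | 3 | triplicate sequencing design |
| replicate jitter (logit SD) | 0.05 | small library effects atop binomial noise |
| WGA floor ε | 0.02 | modified-basecall error on amplified DNA |

Planting precedence at conflicting positions: artifact > promoter dip >
hypermethylated block > specific motif > leaky parent > background.
Palindromic motifs receive probabilities independently per strand (so the
full-methylation proportion is roughly the squared per-strand call
probability) unless a correlation parameter couples the strands'
read draws, or an explicit full/hemi/unmethylated mixture is planted.
Depth is Poisson truncated to ≥ 1 — implemented as max(1, Poisson), i.e.
the zero mass is moved to 1 — so every candidate site appears; genuine
zero-coverage handling is exercised separately in the format layer.
Jitter acts on the logit so probabilities stay in (0, 1) without
clipping; one jitter draw per library models a library-wide shift.

What the simulator does **not** emulate: read-level signal artefacts,
mappability structure, repeat-driven spurious 5mC calls, coverage
autocorrelation along the genome, or strand-biased error.  Passing the
recovery tests therefore demonstrates correctness of the statistical
pipeline under the stated model, not robustness to every failure mode of
real nanopore data.

## Validation scenarios and problem sizes

The reference scenarios (`methylscan.scenarios`, run by
`scripts/acceptance.py` and mirrored in the test suite) use 200 kb
genomes for motif/palindrome/WGA/discovery/enrichment checks (≈ 1000–2200
planted motif sites per scenario), a 400 kb genome with 200 genes for the
metagene promoter-dip check, 100 random 2 kb sequences × 9 motifs for the
scanner oracle, and 2000 uniform-probability sites at depth 30 for the
SD–mean shape.  These sizes give sampling errors comfortably inside each
check's tolerance while keeping a full run around a minute on one CPU.
All randomness flows from a single seed through named child seeds.

## Known limitations

- Discovery assumes motifs ≤ 8 bp with at most two-letter degeneracy and
  needs at least two sites of a motif to exceed the anchor threshold; very
  weak or very long motifs are out of reach.
- The WGA correction is a plain subtraction; it does not model
  context-dependent error rates.
- Gene-motif z-scores use a genome-wide homogeneous occurrence rate; GC
  or repeat heterogeneity will inflate flags in atypical regions.
- Metagene CIs bootstrap genes, not sites; with few genes the intervals
  are wide and the letter display conservative.
- 5mC is handled by the same machinery (filtering on C/G, anchor
  threshold 0.50) but all validation scenarios exercise 6mA.
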