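# Methods

## Event model and thresholds

A cassette (skipped) exon event carries 0-based half-open genomic
coordinates for the cassette and its two flanking constitutive exons,
per-replicate inclusion/skipping junction counts, per-replicate PSIs in
[0, 1], ΔPSI and an FDR. PSI from counts is the length-normalised
inclusion ratio (inc/inc_form_len) / (inc/inc_form_len +
skip/skip_form_len); a replicate with zero informative reads is
undefined (NaN) and excludes the event from testing rather than being
imputed. ΔPSI is mean(condition 2) − mean(condition 1), so a positive
value under factor over-expression means the factor promotes inclusion.

Regulated events: FDR < 0.05 and |ΔPSI| ≥ 0.15 (both bounds
configurable; a stringent 0.30 variant is provided for
functional-impact filtering). The reference (control) set is sampled
without replacement, seeded, from the non-regulated pool (FDR > 0.1 and
|ΔPSI| < 0.10), 2000 events by default; when the pool is smaller the
whole pool is used with a logged warning. The pool is sorted by event
id before sampling so the draw is reproducible regardless of input
order.

## Stand-in differential test

Real rMATS output carries its own statistics and is consumed as-is. For
synthetic cohorts the package applies a two-sided Welch t-test on
logit-transformed PSIs, clamped to [0.01, 0.99] before the logit to
bound the variance at the scale ends, followed by Benjamini–Hochberg
correction across all testable events (≥2 defined replicate PSIs per
condition; others are flagged untestable with FDR 1). Degenerate
zero-variance cases short-circuit: equal means give P = 1. On null
simulations this test runs slightly conservative at n = 4 replicates
(raw P < 0.05 rate ≈ 0.042), which the calibration tests accept within
the 0.05 ± 0.015 band.

## Composite RNA-map axis

Eight segments in transcript order: 3′ end of the upstream constitutive
exon (135 nt), 5′ and 3′ ends of the upstream intron (250 nt each), 5′
and 3′ ends of the cassette (135 nt each), 5′ and 3′ ends of the
downstream intron (250 nt each), 5′ end of the downstream constitutive
exon (135 nt). Intron segments are taken from both intron ends so that
both splice-site contexts are covered; the constitutive-exon segments
are the splice-site-proximal ends. A feature shorter than twice its
requested segment length is split at its midpoint with no overlap (the
5′ half receives the extra base when odd); a feature shorter than the
request is truncated. On the shared axis each segment is aligned to the
junction it is anchored at (5′-anchored left, 3′-anchored right), and a
truncated segment contributes only to the positions it covers — the
per-position denominator tracks contributing events. All sequences are
transcript-sense (reverse-complemented for minus-strand events),
uppercased, with ambiguity codes other than N mapped to N; bases
outside the chromosome are N.

Each event also has a private concatenated composite coordinate
(segment lengths as extracted) with a bijective
(segment, offset) ↔ position mapping for hit export.

## Motifs and scanning

Two motif kinds. Gapped dimer: two words separated by a spacer of
bounded length — the RBPMS element is CAC N(1–12) CAC; every
(left, right) occurrence pair with spacer in range yields a hit from
left-word start to right-word end, overlapping hits retained. IUPAC
word: the RBFOX element is GCAYG, covering GCACG and GCATG. N in the
scanned sequence never matches a word position (it may sit in a dimer
spacer). Scanning is transcript-sense only, since region sequences are
already strand-resolved. Mutated controls replace one position of an
IUPAC word with a concrete base not matched by the parent (default
RBFOX control GCAAG); coverage is the boolean union of hit intervals.

## RNA maps and permutation significance

The profile value at axis position p is the fraction of contributing
events whose 31-nt window centred at p, clipped at the segment
boundary (windows never span a junction, which would mix feature
classes), contains at least one covered base. The null is subset
resampling: test-set-sized random subsets of the pooled test+reference
events, 1000 iterations by default; the empirical one-sided P per
position is (1 + #{null ≥ observed})/(n_perm + 1), so P is never 0 and
its minimum is 1/(n_perm+1). A position is flagged significant when
P ≤ α (default 0.05) and the observed test coverage exceeds the
reference coverage. P-values are reported per position, unadjusted, as
is conventional for RNA-map displays; duplicate event ids within or
across sets are rejected.

Co-occurrence maps use the same machinery but an event contributes at p
only if a linked pair — two hits whose interval gap (0 when
overlapping) is at most 25 nt — is anchored (motif-A hit start) in the
clipped window. A mutated-control rerun of motif B is available in the
same call with identical seeds for a paired specificity contrast.

## k-mer enrichment, clustering, consensus

8-mer windows are counted in selected map segments (default: proximal
downstream intron); windows containing N are skipped. The enrichment
score of a k-mer is the ratio of its window frequencies in test vs
reference with a pseudocount of 0.5 on both counts; significance is the
empirical P from 1000 permutations of event labels, with P < 0.01 as
the cluster-membership cut. Significant 8-mers are aligned pairwise
(best gapless offset with overlap ≥ 5; distance 1 − matches/overlap)
and clustered by average linkage, tree cut at distance 0.4. Each
cluster aligns members to its seed (highest score, ties lexicographic),
builds an enrichment-weighted position-frequency matrix and reports the
IUPAC consensus of the 5-column window with maximal information
content (a base enters the consensus letter at frequency ≥ 0.25).
Pseudocount, cut height and weighting are tunables recorded in the
output metadata; they are stability choices, not fitted values. Shorter
words (e.g. GCATG) are scored by pooling the counts of all 8-mers
containing the word, with the same ratio and permutation machinery.
Note that with sparse per-8-mer counts the empirical P is discrete, so
isolated background 8-mers can reach P < 0.01 at moderate cohort
sizes; the discovery signal lives in the score-ranked top of the
significant list and in the clusters, which is what the tests assert.

## Co-regulation, congruence, overlap

For events tested in an over-expression (OE) and a knockdown (KD)
contrast, the KD ΔPSI is negated so a positive effect always means the
co-factor promotes inclusion. With both contrasts thresholded
identically (|ΔPSI| ≥ 0.15, FDR < 0.05): both significant with equal
signs → coordinate (category 1 included / 2 skipped); opposite signs →
antagonistic (3/4 by OE sign); OE-only → 5/6; KD-only → 7/8; neither →
uncalled. The numeric labels follow the convention that category 1 is
the OE-positive coordinate case; the mapping is exposed as a dict and
can be re-labelled. Congruence compares sign(ΔPSI_OE) with
sign(PSI_tissue − PSI_cell) among events significant in both contrasts;
exact zero deltas are left uncalled with a warning. Gene-set overlap
uses the hypergeometric upper tail P(X ≥ k), computed by summing
log-pmf terms (gammaln-based) via logsumexp; the universe N is always
supplied explicitly by the caller, never defaulted. The PSI heatmap
helper z-scores event rows (zero-variance rows map to 0) and clusters
with average linkage on Euclidean distance.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
not any particular sequencing experiment. Defaults (the study
conditions of the synthetic cohort): 1000 events, 4 replicates per
condition, read depth 100 per event, 10% of events activated and 17%
repressed at |ΔPSI| = 0.35 (regulated fraction skewed towards
repression), Beta-distributed replicate PSIs with concentration 250
(sd ≈ 0.03 at mid-range inclusion, matching good-quality bulk RNA-seq
PSI estimates), baseline inclusion uniform in [0.15, 0.85], PSIs
clamped to [0.02, 0.98]. Junction counts are binomial with
inclusion-form length 2 vs skipping-form length 1, so the
length-normalised ratio recovers the PSI in expectation. Geometry:
cassette exons 80–400 nt, introns 600–3000 nt, constitutive exons
150–300 nt, both strands — large enough for full-length map segments
while deliberately including truncation cases. Background sequence is
i.i.d. with composition A/C/G/T = 0.3/0.2/0.2/0.3 (AT-rich, intron-like).
Motif words are written in transcript sense at uniform offsets within a
configured segment window for a configured fraction of a target group
(and a background fraction of reference events), reverse-complemented
into the plus-strand genome for minus-strand events; the planted word,
segment, offset and length are recorded in the truth labels, and the
geometry helper is shared with the extractor so plants and extraction
agree by construction. A composite literal word (CACGCAC + 10-nt spacer
+ GCATG) plants linked motif pairs for the co-occurrence analysis.
Contrast-pair and congruence cohorts plant category labels directly,
with ΔPSI/FDR margins of at least 0.05/4× around every threshold so the
planted class is unambiguous; a congruent fraction of 0.75 mirrors the
tissue-congruence structure being modelled.

What the generator does **not** emulate: read-level noise and mapping
bias, correlated replicate structure, dinucleotide composition and
splice-site signals, overlapping genes, and motif
clustering/competition beyond the planted words. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the stated generative assumptions, not performance on real
tissue data.

## Calibration and problem sizes

The validation suite runs each analysis at desk scale: scanner oracle
equivalence on 1000 random 500-nt sequences; RNA-map recovery with 200
planted test events against a 2000-event reference (1000 permutations)
and a 20-seed null calibration in which one unplanted 2300-event cohort
is generated once and the seeds vary the test/reference split and
permutation stream — a valid Monte-Carlo over the no-signal null that
avoids regenerating genomes; k-mer and co-occurrence scenarios at
150–250 test events; differential calibration on a 6000-event null
cohort and 10 planted replicate cohorts; the hypergeometric sweep over
every N ≤ 30 case against exact rational arithmetic. The acceptance
script uses a 1000-event default cohort with a 500-event reference
sample (the simulated non-regulated pool is ~730 events, so a 2000
reference is not available at that cohort size and the classifier
would fall back to the whole pool).

## Known limitations

- The differential stand-in is not rMATS; it ignores count uncertainty
  (it tests the PSIs directly) and is mildly conservative at small n.
- Empirical permutation P-values are bounded below by 1/(n_perm+1);
  genome-scale multiple-testing control is deliberately out of scope
  for the per-position map display (a max-statistic familywise
  correction would be the natural extension).
- Gapped-dimer hits keep every (left, right) pair; coverage semantics
  make profiles insensitive to this choice, but hit counts are
  pair-counts, not merged occurrences.
- MXE/A5SS/A3SS/RI events are parsed but RNA maps are defined for
  cassette (SE) geometry only.
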