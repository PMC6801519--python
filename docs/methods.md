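# Methods

This note documents the models and procedures implemented in mitoatlas,
the parameters that matter, the numerical conventions, and what the
synthetic-data tests do and do not establish.

## Coordinate model

All public interfaces use 1-based inclusive coordinates, matching how
organelle annotation tables are printed. Circular molecules may carry
origin-spanning ("wrap") intervals; a wrap interval `(s, e)` on a
molecule of length `L` has length `L − s + 1 + e`. The origin placement
of a circular molecule is taken from the input FASTA; no rotation
canonicalisation is applied to inputs. Translation uses the standard
genetic code (plant mitochondria use the universal code); GTG/ACG
initiation is an opt-in flag that re-reads the first codon as
methionine, not a code change. N bases are allowed in genomes but never
seed repeat detection and always count as mismatches in identity
computations.

## Repeat detection

The detector implements the windowed dot-plot definition directly: on
every diagonal of every molecule-vs-molecule comparison (both
orientations), a window of `window` bp (default 30) is a hit when at
least `ceil(window × min_identity)` positions match (default 27/30,
i.e. a 90% score). Co-diagonal hits whose window starts are within
`window + max_gap` are chained; a chain is accepted when the spanned
identity still meets the threshold, otherwise it is split at its
weakest window and the halves re-evaluated. Accepted spans are trimmed
to their maximum-scoring subsegment (match `= 1 − t`, mismatch `= −t`
with `t` the identity threshold, evaluated in exact integer arithmetic
at scale 10⁶ with ties broken toward the longer, then leftmost span),
so random flank picked up by boundary windows is shed. Spans shorter
than `min_length` (default 100 bp) are dropped.

For speed, candidate windows are located by exact k-mer seeding with
`k = ceil((window − m)/(m + 1))` where `m` is the per-window mismatch
allowance (k = 7 at the defaults). Any qualifying window must contain
an exact run of at least that length, so seeding is lossless and the
output is provably identical to the exhaustive scan — the test suite
asserts this equivalence against an independent full-matrix oracle on
30 seeded instances. A second exact prefilter (total matches over each
seed's 2·window − k super-window) discards the ~99.8% of random seeds
whose neighbourhood cannot contain a qualifying window. Circular
molecules are scanned on their doubled sequence; folded duplicate hits
and sub-hits of the same alignment are removed by a containment check
that compares alignment offsets, so genuinely distinct shorter repeats
are never dropped. Cost grows with genome size roughly as
n²/4ᵏ window evaluations; organelle-scale molecules (tens to hundreds
of kb) are processed in seconds.

## Isoform enumeration

A single crossover between two repeat copies yields: two circles (direct
pair on one circle), an excised circle plus terminal fragments kept in
the record but flagged discarded (direct pair on a linear molecule), an
inversion of the enclosed segment (inverted pair), or a fused circle
(pair across two circles). Recombination between two linear molecules
(or linear + circular) is not defined here and is skipped with a
warning. The crossover is placed at the first base of the repeat by
default; the alternative convention (repeat end) is selectable and both
are recorded in provenance — for equal-length copies the two conventions
produce identical molecule lengths and differ only in junction bases.
Configurations are deduplicated by the sorted multiset of (topology,
length, canonical sequence) where the canonical form of a circle is the
lexicographically least rotation of the sequence or its reverse
complement (Booth's algorithm). Enumeration is breadth-first up to
`max_events` (default 1, guard at 3); events beyond the first locate
repeat copies by literal search in the product sequences and require an
unambiguous pair of loci.

In-silico PCR reports convergent primer-site pairs: an amplicon runs
from the 5' base of the plus-strand site to the 5' base of the
minus-strand site inclusive, so its length is at least the sum of the
primer lengths; circular molecules are searched across the origin and
products longer than the molecule are rejected.

## Editing calling

The caller consumes per-base A/C/G/T counts from unstranded libraries;
transcript orientation comes from the overlapping annotation. The
edited fraction at a site is `edited / (edited + reference)` — T/(T+C)
at a genomic C on a plus-strand transcript, A/(A+G) at a genomic G on a
minus-strand transcript — which is robust to third-base sequencing
errors in the denominator. A library supports a site when its own
fraction is ≥ `min_frac` (default 0.10) at depth ≥ `min_depth` (default
10, total counts); a site is called with support in ≥ `min_libs`
(default 2) libraries. The 10% rule is applied per library rather than
to the pooled fraction because it is paired with the 2-of-3 replicate
rule; the pooled efficiency is reported alongside. Unannotated
positions are evaluated in both orientations and reported as ambiguous
with the stronger orientation; positions passing in both orientations
are flagged conflicting, never silently resolved. Efficiency bins
follow the published convention: high strictly above 0.95, low strictly
below 0.25. Mismatch signatures (e.g. the A→T mis-incorporation
opposite m¹A) are reported from pooled counts at ≥ 20% frequency and
depth ≥ 50, excluding editing-type mismatches and called sites.

Consequences are evaluated on the spliced transcript in its own frame
and in the frames of any overlapping annotated CDS/ORF, which captures
edits that are missense in one gene and stop-creating in an overlapping
gene. ORF shortening is the codon-index distance between the annotated
genomic stop and the editing-created stop. Intron stem effects use the
Watson–Crick + G·U wobble pair table: a C→U edit improves a mapped stem
position when it converts a non-pairing combination into A–U or G–U,
disrupts it in the reverse direction, and is neutral otherwise. Stem
maps are user-supplied per intron (published structures do not include
coordinates); the synthetic generator emits consistent maps so the
operation is fully testable offline.

## Transcription units

No published segmentation algorithm exists for these data, so the
module uses a transparent two-parameter rule chosen for robustness to
depth spikes: depth is median-filtered (window 51) and thresholded at
`background_mult` (default 5) times the track-wide median (floored at
1); above-threshold runs closer than `merge_gap` (100) merge and runs
shorter than `min_unit_length` (150) are dropped. All four knobs are
exposed. On noiseless simulated coverage, boundaries are recovered
within half the smoothing window (±25 bp at the default).

Promoter scanning searches the unit strand within `upstream_window`
(100 nt) upstream of each 5' end for CRTA (CATA/CGTA) and TATATAA,
reporting all hits closest-first with their offsets; a 5' end with any
hit is classified promoter-driven, a 5' end within 20 nt of a
same-strand tRNA end is a t-element (RNase Z-like upstream, RNase
P-like downstream), and the remainder are processing sites. CRTA is a
weak 4-mer — chance hits occur in roughly half of 100-nt windows at
uniform base composition — so the promoter label is a screen, not a
determination, exactly as in manual annotation practice.

Stem-loops are inverted-repeat hairpins: arms of ≥ `min_stem` (8) bp
pairing with ≤ `max_mismatch` (1) internal mismatches around a loop of
3–20 nt. A hairpin is reported only if it is maximal (arms cannot be
extended outward for its loop; terminal mismatches are never part of a
stem) and loop-minimal (the loop cannot be shrunk by extending the
arms inward), which suppresses the nested shadows of every perfect
stem. Two hairpins separated by ≤ 10 nt merge into a double stem-loop.
The finder is asserted equal to an exhaustive enumeration oracle on
random windows. No thermodynamic model is used: "stable" here means
structurally well-paired, not a free-energy statement.

## Synteny

Blocks are found by chaining exact `seed_k`-mer anchors (default 15)
that advance co-linearly on both genomes with gaps ≤ `chain_gap` (500)
and bounded diagonal drift, in both orientations. A chain's identity is
a gap-free columnar comparison: anchor bases count as matches,
inter-anchor regions are compared columnwise over the shorter side and
any surplus counts as mismatches; block length is the query-genome
span. Blocks below 5 kb or 95% identity are dropped; overlapping chains
are resolved greedily by length, then identity, then leftmost
coordinate. Planted homologous regions ≥ 6 kb at ≤ 3% divergence are
recovered with boundary error well inside `chain_gap`, and the A→B and
B→A comparisons are mirror images.

## Synthetic data

The generator emulates the structure of a multichromosomal organelle
dataset at a down-scaled size chosen so the full test suite runs in
seconds: by default three molecules (50 kb linear + 20 kb and 10 kb
circles — the same large-linear-plus-two-circles architecture as the
potato mitogenome at ~1/6 scale), 5 repeat pairs of 120–2000 bp at
90–100% identity, 10 genes of 100–300 codons inside strand-specific
transcription units with 5–50× depth multipliers, 6 tRNAs (40%
plastid-like), 60 editing sites with efficiencies uniform on
[0.05, 1.0] so all bins are populated, promoters and 3' stem-loops on
half the units. Repeat copies are mutated by drawing the exact mutation
count for the target identity; genes have valid starts/stops and
stop-free interiors; every truth record is re-verified against the
emitted sequence at generation time. Pileup depth is Poisson(depth ×
unit multiplier); edited-read counts are Binomial(depth, efficiency ±
a small per-library jitter, default 0.02, clipped); sequencing errors
substitute uniformly at the stated rate (default 0.005). A single
master seed is fanned out to per-component substreams by fixed labels,
and identical seeds reproduce byte-identical outputs.

What passing these tests shows: the algorithms implement their stated
definitions exactly (oracle equivalences), conservation laws hold, and
detection rules achieve their nominal operating characteristics
(≥ 99% sensitivity at efficiency ≥ 0.15 and depth ~1000, zero false
positives at 0.5% error) under the generative model. What they do not
show: performance on real alignments, where mapping bias, strand
bleed-through, indel errors, paralogous mapping and coverage dips are
not modelled — uniform base composition is used (real mtDNA is
AT-rich), reads are not simulated, and no aligner is run. Genome-wide
published catalogue sizes (hundreds of editing sites, tens of
transcription units and promoters) depend on those data and on manual
curation, and are deliberately outside the offline test surface.

## Numerical conventions and degenerate inputs

Identity thresholds are compared in exact integer arithmetic (scale
10⁶) so oracle and fast path can never disagree by rounding. All
outputs are deterministically ordered (length descending with full
coordinate tie-breaks; sites by molecule and position), and re-running
any stage on identical inputs is byte-identical. Empty coverage tracks
yield no units; an all-reference pileup yields no sites with a warning;
pileups whose reference column contradicts the genome fail loudly with
the offending positions listed; unknown configuration keys are
rejected by name. The pipeline stops at the first stage error, leaving
earlier outputs intact.

## Known limitations

Cross-molecule recombination involving linear molecules is not
enumerated. Repeat families are reported as pairwise hits, not
multi-copy clusters. The in-silico PCR model is exact-match (or fixed
mismatch count) annealing without thermodynamics. UTR classification
requires transcription units; without them gene-proximal non-coding
sites fall back to intergenic. The editing caller does not model U→C
editing. Isoform stoichiometry (relative abundance of configurations
in vivo) is out of scope.
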