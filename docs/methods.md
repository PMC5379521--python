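# Methods

This note records the models, conventions and design choices behind
`mirsnp`, in the order the pipeline runs them, together with what the
synthetic benchmark does and does not establish.

## Coordinates and alphabets

Sequences are held internally as uppercase DNA (`U` → `T` on input; IUPAC
degenerate letters accepted in references and variant alleles). Intervals
are 0-based half-open internally; VCF positions are 1-based on input, and
every position in a written table is 1-based, including cleavage sites.
Degenerate bases in variant alleles are expanded to their two-base sets at
parse time; `-` (indel) alleles are excluded from the SNP analyses and
counted. Missing genotypes are removed from allele-frequency denominators,
never imputed.

## miRNA annotation

Collapsed reads are pooled across libraries, filtered to 16–30 nt, and
screened against optional exclusion sets (mRNA/rRNA/repeat proxies) by exact
substring match. Homology to the reference mature set uses Hamming distance
only (≤ 2 mismatches, no indels — the mismatch allowance is stated without
an indel allowance, so length-discordant reads are never assigned); ties go
to the first reference in file order. Reads without a homology assignment
are dropped when they have more than 15 exact genomic matches (both
strands, overlapping occurrences counted).

**Folding.** Precursor structures come from a Nussinov maximum-cardinality
nested pairing (allowed pairs A:T, G:C, G:T; minimum loop 3), with a
deterministic traceback that pairs the left end to the smallest admissible
partner achieving the optimum. Maximum pairing was chosen over an energy
model because it is exactly verifiable against brute-force enumeration at
test scale; `structure_from_dotbracket` is the import hook for structures
computed by an external thermodynamic folder, and every downstream criterion
works unchanged on imported structures.

**Window choice.** A single fixed read±200 nt window is unreliable under
maximum-cardinality folding: with ~180 nt of random flank the global
optimum frequently restructures the true stem. Candidate precursors are
therefore extracted as a ladder of anchored windows (read plus 25, 40, 60,
90, 130, 200 nt of flank, on each side, strand-aware), each folded and
evaluated; among passing windows the one with the fewest unpaired mature
bases wins, then the shortest window, then the leftmost. The ladder stops
early only when a window with zero unpaired mature bases has been found,
since no larger window can beat it on that key. Window sizes are
configurable (`DiscoveryConfig.flank_sizes`).

**Hairpin criteria** (all config-exposed, community-style defaults): the
mature must lie on one arm (no pairing within the mature, all partners on
one side), at most 4 mature bases unpaired, precursor paired fraction
≥ 0.5, and the mature's partners must be nearly contiguous (partner spread
at most 6 nt beyond the mature length). The spread criterion is what keeps
maximum-pairing folding honest: random sequence easily satisfies the other
three by scattering partners. Even so, an occasional random read passes all
four — at the default scenario scale roughly one spurious candidate locus
per dataset — which mirrors the false-positive behaviour of real hairpin
screens and is why candidate status is a class label rather than a filter.

**miRNA\*.** The predicted star spans `[partner(mature_end)+2,
partner(mature_start)+2]` in precursor coordinates — the canonical duplex
with 2-nt 3′ overhangs on both strands — with partners of unpaired mature
ends projected from the nearest paired base. A locus is upgraded from
`specific_candidate` to `specific_with_star` only when a read from a library
that also contains the mature equals the predicted star exactly (a ±1-nt
end tolerance is available but off by default).

A reverse-complement remark: hairpin evaluation is invariant under reverse
complementing the precursor *with its structure mirrored*, but refolding is
not, because G:T maps to the disallowed A:C under reverse complement; the
property test asserts the structural form of the invariance.

Expression is reported as RPM (`count × 10⁶ / library total`) per library,
with the library total taken over all reads supplied for that library.

## Target scoring

The scorer is the classical plant position-weighted penalty scheme
(mismatch 1, G:U 0.5, bulge 1 with at most one single-nucleotide bulge,
all doubled at miRNA positions 2–13, cutoff 4.0). The named predictors this
stands in for do not publish a single canonical parameterisation; this
scheme is the lineage of the standard plant target-finder scripts and has
the advantage of being exactly checkable by enumeration. A site bulge
between miRNA positions *b−1* and *b* is charged at position min(*b*, *m*).
Windows of length *m−1*, *m*, *m+1* are scanned with a vectorised
penalty-table scheme (prefix/suffix sums over bulge placements); reported
windows are re-scored through the reference single-pair scorer, so a
disagreement between the two paths would surface as a missing site rather
than a wrong score. Overlapping reported windows collapse to the lowest
score; ties prefer the bulge-free (length-*m*) window, then the leftmost —
an ungapped alignment of equal score is always the better reading of the
same duplex.

Cleavage is reported opposite miRNA position 10. When a bulge falls within
miRNA positions 9–11 the register is ambiguous; the bulge-free convention
`site_end − 9` is used and the call flagged approximate. Reported cleavage
coordinates are 1-based; an off-by-one between 0- and 1-based conventions
is exactly the kind of discrepancy this pins down.

## Nucleotide diversity

π is estimated per site as unbiased heterozygosity `n/(n−1)·(1 − Σ p²)`
(n = non-missing allele count) summed over variant sites and divided by the
full interval length — monomorphic sites count in the denominator, giving
the per-site scale on which miRNA-related locus classes are conventionally
compared. On complete haplotype matrices this equals the mean pairwise
Hamming fraction exactly (property-tested to 1e-12). Locus classes are
mature, precursor, 2-kb flank (clipped at chromosome ends, precursor
excluded) and binding site, each split by miRNA provenance
(conserved+known vs lineage-specific), plus the whole-genome background.
Binding sites are lifted to genome coordinates through ungapped gene
models; non-liftable sites are skipped.

Significance uses a length-matched permutation test: `n_perm` random
interval sets matched in number and length to the class (uniform placement
over chromosomes weighted by the number of valid starts), one-sided
`p = (1 + #{null π ≤ observed}) / (n_perm + 1)`. Ties count toward the
null, making the test conservative. `n_perm ≥ 99` is the recommended
floor; a value below 1 is an error. Under a null in which class intervals
come from the same placement process, the rejection rate at α = 0.05 is
calibrated (checked over 400 simulated datasets). The test seed is recorded
in the output table.

## SNP impact

A group's sequence at a locus is defined by its major allele (within-group
frequency > 0.5); exact ties — typically from degenerate-base expansion —
produce every tied haplotype. Multiple SNPs in one mature or transcript are
enumerated jointly up to 8 haplotypes, beyond which per-SNP marginals are
used. Genomic variants lift to mature-/transcript-local coordinates
strand-awarely, with alleles complemented on the minus strand.

The comparison runs the site search under the reference group's sequences
and under the alternative group's (snp-miRNA × snp-mRNA), then matches
sites by transcript and interval overlap (any overlap — a SNP can shift the
optimal window by a base). Reference-only sites are *disrupted* (= group-A
unique targets), alternative-only sites *created* (= group-B unique), the
rest *conserved*. "Created" is defined as absent from the reference
interaction set at the same cutoff.

Created sites are validated against the second group's annotated
transcripts: candidates shortlisted by a shared 12-mer prescreen, best
ortholog chosen by global-alignment identity (match 1, mismatch −1, gap −2;
identity = matches / alignment columns), acceptance requiring identity
strictly above 0.90 *and* that the ortholog carries a site for the same
miRNA, at or below the cutoff, overlapping the site region lifted through
the alignment. Global alignment replaces a BLAST search because in the
> 90%-identity regime the pair is essentially colinear and the dependency
is not needed.

## Degradome

Tags are 5′-prefix sequences (default 20 nt, minimum 15) mapped by exact
match; multi-transcript tags count on every match and are flagged.
Categories follow the CleaveLand convention: 0 unique maximum, 1 shared
maximum, 2 above the median, 3 at or below it (counts > 1), 4 singleton
tags; the median is taken over stored (nonzero) positions by default, with
a flag to include zeros. The significance model is a uniform-null binomial,
`p = P(X ≥ c)`, `X ~ Binomial(total_tags, 1/(L − tag_len + 1))`; a
count-shuffling resampling variant is provided as a cross-check. Both are
reconstructions — the upstream tooling does not publish its exact test —
and the α = 0.05 default is config-exposed. Interaction confirmation takes
the best call (lowest category, then highest count) within ±1 of the
predicted cleavage position.

## Synthetic scenarios

`make_scenario` builds a complete two-group dataset from one seed, with
fixed per-component child streams so adding a component does not perturb
the others. Defaults describe a desk-scale version of a two-group
resequencing design: 2 × 30 kb chromosomes; 8 hairpins (21-nt matures,
12-nt loops, one star-arm mismatch; 4 conserved families present in the
reference set, 2 specific loci with emitted star reads, 2 candidates); 12
transcripts of 600 nt written into the genome as ungapped gene models; 10
planted sites at exact scores; 3 A-unique, 2 B-unique and 2 neutral site
SNPs plus 2 mature-sequence SNPs, all as fixed ref/alt differences between
5 diploid samples per group; background SNPs at 10⁻³ per base placed
outside planted features; two read libraries; degradome tags at 40 per
confirmed site with half the mass on the predicted cleavage position.
Planted impact events use a score margin of 1.0 on each side of the 4.0
cutoff (site at 3.0, broken allele at ≥ 5.0), so recovery is a property of
correctness, not of luck.

The generator verifies every planted artifact against the analysis modules
at build time — hairpins re-folded and re-evaluated, sites re-scored
through `find_sites`, events re-searched under both alleles — so generator
bugs become generation errors. Identical config and seed give byte-identical
bundles.

What the benchmark does *not* emulate: sequencing error, expression-level
realism, indels, intron-containing gene models, linkage between background
SNPs, or purifying selection at miRNA loci (planted mature SNPs are fixed
differences, which *raise* π in those classes rather than lowering it as
domestication sweeps would). Passing tests therefore demonstrate that the
machinery measures what it claims on data whose truth is known, not that
any particular biological effect size will be observed in field data.

## Pipeline

Stages run discover → targets → diversity → impact → degradome; a missing
input fails pre-flight before any stage runs, and a stage failure halts the
run naming the stage (CLI exit codes: 2 validation, 3 stage failure). Every
output directory holds one `manifest.json` (tool version, config snapshot,
SHA-256 input digests, seed, per-stage row counts). All randomness flows
from the single configured seed, so a rerun on the same inputs reproduces
every table byte for byte. Default problem sizes throughout (scenario
scale, 199 permutations, oracle case counts) were chosen so the whole suite
and the acceptance script each run in about a minute on one CPU.
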