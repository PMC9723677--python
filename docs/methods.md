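# Methods

This note documents the models and procedures magrecode implements, the
choices made where the design was genuinely open, and what validation on
synthetic data does and does not establish.

## Coordinate and format conventions

All features are held internally in 0-based half-open coordinates; GFF3
(1-based inclusive) is converted only at read/write time, and the
converters are inverse bijections (property-tested on random intervals).
Sequences are uppercase ACGTN; any other character becomes N on input
with a warning carrying the substitution count. SECIS elements and
single-copy markers travel as ordinary GFF3 features with `SECIS` /
`marker` in the type column rather than a bespoke format, so one parser
serves the whole pipeline. Taxonomy strings follow the seven-rank prefix
convention (`d__` … `s__`), split on `;`.

## Relative evolutionary divergence

RED linearly interpolates node depths between a root fixed at 0 and
extant taxa fixed at 1: `RED(n) = p + (a/(a+b))(1−p)` with `b` the mean
branch-length distance from the node to its descendant leaves. Leaves are
set to 1 directly (the `b = 0` limit of the formula); a zero-length
subtree (`a + b = 0`) inherits the parent's value with a warning.
Multifurcations need no special treatment and are accepted as-is — the
formula is well defined on them, and resolving them arbitrarily would
fabricate signal. Because `a/(a+b) ∈ [0,1]`, RED is monotone
non-decreasing along every root-to-leaf path; this and agreement to
1e−12 with a naive recursive oracle are asserted on hundreds of random
trees.

**Multi-rooting.** One rooting is produced per phylum containing at least
two classes, with the root at the midpoint (50%) of the branch separating
that phylum from the rest of the tree. When the input carries a basal
bifurcation, the two root edges are first merged — the degree-2 root is a
rooting artefact, and the separating branch is their concatenation.
Non-monophyletic phyla are skipped with a warning rather than resolved by
guesswork; if no phylum qualifies, an error advises a single fixed
rooting. A taxon's RED is the median over rootings, excluding the rooting
in which its own phylum was the outgroup; an even count of retained
rootings takes the mean of the two central values (standard median). A
taxon is located in each rooted tree as the MRCA of its labelled leaves,
which is robust to the node rearrangements rerooting causes. Taxa
excluded from every rooting are reported as unassessable (`None`), not as
errors.

**Rank intervals and assignment.** Per-rank intervals are the median of
the per-taxon medians ± a half-width `h` (default 0.1, the value used for
rank normalisation in genome-taxonomy practice), clipped to [0, 1]. A
query value is assigned every rank whose interval contains it; the
primary rank is the one with the nearest median, ties broken toward the
more inclusive rank (deterministic and conservative). Values outside all
intervals get the nearest-median rank flagged `in_interval=False`.

**Alignment trimming.** A column is kept iff its most frequent non-gap
residue occurs in ≥ 40% (configurable) of *all* rows — gaps count in the
denominator, the stricter of the two readings and the one that removes
gap-dominated columns. Rows retaining < 80% of the residues they had
before column trimming are then dropped.

## Genome quality, ANI and dereplication

Quality is `Q = C − 4X` in percent, with no floor (a heavily contaminated
bin can score negative); the inclusion filter keeps `Q > 40` strictly.
ANI is estimated alignment-free: canonical (strand-minimum) 21-mers,
Jaccard `J`, Mash distance `D = −(1/k)·ln(2J/(1+J))`, `ANI = 100(1−D)`.
k = 21 balances specificity against k-mer-set size at the 100 kb–5 Mb
scale and is configurable; disjoint k-mer sets are flagged `unrelated`
with ANI reported as 0 rather than −∞. Dereplication is greedy
best-quality-first (ties broken lexicographically by id): a genome is
kept iff its ANI to every already-kept genome is ≤ the threshold, which
guarantees the kept set is pairwise non-redundant and coincides with
best-per-cluster selection whenever the >99% relation is transitive
(verified exhaustively against a brute-force oracle on small inputs).

## Recoding detection

The detectors consume annotations (product strings and opaque function
ids such as TIGRFAM accessions) produced by upstream gene callers and
HMM searches; homology search itself is out of scope here — the
contribution is the classification rules applied to hits.

**Stop-codon usage** counts the last three nucleotides of each CDS in
reading orientation (reverse-complemented on `−`). CDSs flagged partial,
shorter than 6 nt, or not ending in TAA/TAG/TGA are excluded from the
denominator and tallied separately, since contig-edge fragments would
bias the frequencies.

**Machinery classification** is the four-way scheme complete / partial /
tRNA-only / absent per trait. Sec requires PSTK, SepSecS, SPS and SelB
plus tRNAsec; SerRS performs the initial mischarging but is housekeeping
and is reported without counting toward completeness. Pyl requires PylS
(PylSn + PylSc fragments jointly count), PylB, PylC and PylD plus
tRNApyl. pylB/C/D hits are discarded unless co-located on a single
contig: the contig with the most distinct pylB/C/D genes wins (ties
lexicographic), and if no contig carries at least two, all such hits are
dropped as likely spurious — a lone scattered homologue has no cluster
context. A genome is *included* for downstream Pyl analysis when ≥ 2 of
the four required genes (50%) survive. The classification is a total
function, checked by an exhaustive truth table over all gene subsets ×
tRNA presence × co-location.

**Readthrough fusion.** A gene recoded at an internal stop appears to a
standard gene caller as two consecutive CDSs. For each CDS terminating in
the target codon, the next CDS downstream in translation direction on the
same contig and strand becomes a fusion candidate iff (i) annotations
match — case/whitespace-normalised product equality or a shared function
id; (ii) reading frames are consistent (genomic offset divisible by 3, so
the recoded stop stays in frame in the fusion); and (iii) the gap is
0–300 nt. Frame consistency and the gap bound are exposed as parameters
since different gene callers fragment differently; the defaults reflect
how a caller splits a gene at an in-frame stop (small, frame-preserving
gap).

**Selenoprotein–SECIS pairing.** Archaeal SECIS elements lie in the
3′ UTR, so the distance is measured gene-relative from the fused CDS
3′ end to the SECIS 5′ start in translation direction and must fall in
[30, 500] nt on the same contig and strand (both bounds configurable; an
alternative anchor at the in-frame UGA would shift distances by the
length of the downstream fragment and can be emulated by adjusting the
bounds). Each SECIS is assigned to at most one CDS — the nearest in
range — and a candidate with at least one pair is a confirmed
selenoprotein.

**tRNA cloverleaf features** are segmented from dot-bracket structures:
the outermost helix is the acceptor stem; the hairpins inside its
multiloop are, 5′→3′, the D arm, the anticodon arm, an optional variable
arm, and the T arm (≥ 3 required). Reported: D-stem base-pair count (a
6-bp D-stem is the diagnostic short variant versus the canonical 7 bp of
archaeal tRNAsec), the anticodon (middle 3 nt of the anticodon loop;
UCA → Sec-opal, CUA → Pyl-amber), and the unpaired 3′ overhang after the
acceptor stem (canonical CCA versus the unusual GC tail). All pairs must
be Watson–Crick or G·U; anything else is rejected as a malformed
structure.

## Trait history

Dollo parsimony (single gain, irreversible loss) is the model: a
multi-gene recoding system is vanishingly unlikely to be assembled twice
independently, whereas loss is easy. Fitch unordered parsimony is
deliberately not offered. The gain is placed at the MRCA of
trait-positive tips, or at the root with `force_root_present=True` — the
scenario in which external evidence argues the trait was ancestral even
though extant presence is confined to a nested clade. Below the gain, a
node is present iff it retains a present descendant; each maximal
all-absent subtree costs exactly one loss on its stem, which is provably
minimal under a single gain and is verified against exhaustive
enumeration of all single-gain scenarios on trees of 4–8 tips. The
machinery and tRNA components are reconstructed independently as binary
characters; *partial loss* (machinery lost, tRNA retained) is a derived
label, keeping the optimisation binary and exact.

## Synthetic data

The generator plants every signal the detectors look for and records the
layout as a ground-truth object. Defaults are the emulated study
conditions: stop usage 60/21/19% UAA/UAG/UGA (the amber-recoded lineage's
~21% UAG), GC 0.40 (middle of the observed 28.8–48.4% range across the
analysed MAGs), 500 CDSs per genome, SECIS elements 30–500 nt downstream
of UGA-readthrough genes, pylS placed ~6 kb from the co-located pylBCD
genes with a NAD kinase and hypothetical proteins in between, 2 UAG- and
3 UGA-readthrough genes (two–three selenoproteins per genome), 100
single-copy markers with completeness 0.94 and contamination 0.04 (the
high-quality type-MAG regime), and a 1% substitution rate for mutated
ANI pairs (the dereplication boundary). Readthrough genes are planted by
splitting a double-length ORF at an in-frame TAG/TGA into two CDSs with
identical annotations and a frame-preserving 0–30 nt gap, mirroring
gene-caller fragmentation. Markers emulate completeness/contamination as
`round(n × C)` distinct plus `round(n × X)` duplicated features — a
stand-in for marker-set QC tools, which are out of scope. The mutation
model is substitution-only (i.i.d. per site, uniform over the three
alternatives), keeping planted coordinates valid and making expected
identity exactly `1 − rate`. All randomness flows from one seeded
generator per call.

What the generator does *not* emulate: realistic codon usage or amino
acid composition, evolutionary sequence simulation along the tree,
indels and rearrangements, annotation noise (wrong or missing products),
chimeric contigs, and sequencing error. Perfect precision/recall on
planted features therefore demonstrates that the classification rules
are implemented exactly, not that they are robust to annotation error in
real MAGs — on real data the bottleneck is the upstream annotation
quality, which this package consumes rather than produces.

## Problem sizes and numerical choices

Validation runs use 200 random trees (≤ 20 leaves) for the RED oracle,
20 simulated trees for rank recovery, 100 simulated genomes (seeds
1–100, 500 CDSs each) for planted-feature recovery, exhaustive
enumeration up to 8 tips for Dollo, and 10 replicate 100 kb pairs for the
mutated-ANI anchor; the full suite and the reproduction script each run
in well under a minute. RED equivalence is asserted at 1e−12;
stop-usage calibration at a 4.5σ binomial band; the mutated-ANI anchor at
±0.3 points around 99.0. Rank-recovery labelling uses bins centred at
0.25/0.50/0.75 with half-width 0.05, so bin centres are separated by more
than twice the interval half-width — the regime in which interval
assignment is expected to be reliable.

## Known limitations

* ANI is a k-mer sketch-style estimate, not an alignment-based ANI;
  values a few tenths of a point from an aligner's output are expected.
* The RED multi-rooting skips non-monophyletic phyla instead of
  attempting a consensus placement.
* SECIS elements and gene homology are inputs; no covariance-model or
  HMM searching is performed.
* The cloverleaf parser requires a well-formed nested structure; it does
  not fold sequences and rejects pseudoknots and non-canonical pairs.
* `drop_gappy_rows` needs the pre-trimming alignment to compute retained
  fractions; without it every non-empty row is kept.
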