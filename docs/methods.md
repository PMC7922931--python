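# Methods

## Fragment recruitment

A read of length *n* is recruited to a reference genome when some ungapped,
full-length placement on either strand matches more than a fraction *t* of
its bases (default *t* = 0.97, i.e. strictly above 97 % identity). The
identity denominator is always *n* (`align_len = end − start`), and any
position involving an `N` in read or genome counts as a mismatch.

**Strictness at the boundary.** ">97 %" is implemented as strictly greater:
the minimum accepted match count is the smallest integer *m* with
*m*/*n* > *t*, computed with *t·n* snapped to the nearest integer when
within 10⁻⁹ so that decimal thresholds behave exactly (97 matches in 100 is
rejected, 98 accepted). The threshold is configurable for sensitivity
checks.

**q-gram candidate filter.** Two length-*n* strings with at most *k*
mismatches share at least *n − q + 1 − k·q* length-*q* substrings at
corresponding offsets. The recruiter indexes every N-free *q*-gram of the
genome (default *q* = 11, common recruitment practice), counts, per genome
diagonal, the read q-grams that land on it, and scores only diagonals
reaching the lemma bound with *k* = *n − m* (the exact maximum mismatch
count an accepted hit can have). The filter is therefore lossless: every
placement above threshold survives it, which the tests assert by comparing
full hit sets against a brute-force sliding-window Hamming scan. When the
bound is non-positive (short reads, low thresholds) the recruiter falls
back to scoring every placement.

**Sample semantics.** Genomes are treated as independent references: a read
may be recruited to several genomes, with no unique-mapping arbitration.
Within one genome only the best hit per read is kept (highest identity,
ties to the smallest start, then the forward strand), so repeat regions
cannot multiply one read's contribution to R; multi-copy repeats are
handled downstream by the coverage filter. Reads shorter than
`min_align_len` (default 30, below which an 11-gram filter is meaningless)
are skipped and counted. At most `max_reads` (default 10⁷) reads are taken
from the start of each file. Alignment is ungapped by design — it keeps the
brute-force oracle exact — and gapped or quality-aware scoring is out of
scope; qualities are parsed and carried but unused.

## Coverage-peak removal

Conserved repeats (16S rRNA operons, mobile elements) attract reads from
many taxa and inflate a genome's apparent abundance. The filter counts
recruited reads per locus — a locus is a hit's 0-based alignment start, not
a per-base pileup — and computes the mean M and standard deviation SD of
the counts **over covered loci only**. A hit is removed iff its locus count
exceeds M + 2·SD; a count equal to the threshold is kept. SD is the
population (divide-by-*n*) form by default, with a sample-SD switch. The
rule runs in exactly one pass: it is deliberately not idempotent (removing
a peak lowers M and SD, so a second pass could remove more), and the test
suite pins the single-pass semantics. Under uniform coverage SD = 0 and the
threshold degenerates to the mean, so nothing is removed; the partition of
loci is invariant under scaling all counts by a positive constant.

## Normalization and abundance matrices

Counts are scaled to a per-billion-read basis, N = R × 10⁹ / T, linear in R.
Environment-level values pool before normalizing — (ΣR) × 10⁹ / (ΣT) over
the environment's samples — which equals the mean of per-sample N only when
all T are equal; the ratio-of-sums form is what a concatenation of the
environment's read sets would give. Row autoscaling for display subtracts
the row mean and divides by the row population SD; constant rows map to
zero with a warning. Row/column ordering uses average-linkage (UPGMA)
hierarchical clustering on Euclidean distances, implemented directly as the
O(n³) agglomeration with a fixed tie-break (among minimal distances, merge
the lexicographically smallest cluster-id pair; children ordered small id
first) so leaf orders are reproducible; matrices here are at most a few
dozen rows, so the cubic cost is irrelevant, and the tests cross-check the
cophenetic distances against scipy's average-linkage on tie-free inputs.
Heatmap rendering is a convenience artifact, not a tested surface.

## Compatibility tables and canonical strain names

The packaged CSVs transcribe the printed tables: the strain list with
properties (47 strains, 25 flagged as selected for in vitro work), the
23-strain bacteria/yeast pairwise matrix (printed lower-triangular, closed
to a symmetric relation at load time; the printed duplicate *B. ambifaria*
LMG 11351 column agrees with the retained one everywhere), the 23 × 2
bacteria/fungus matrix against the two *Trichoderma harzianum* strains, the
12-strain × 4-compound biostimulant response table, and the three published
consortium membership lists. Self-pairs are compatible by convention —
never assayed, biologically vacuous, needed for clique logic. Untested
pairs (e.g. the fungus–fungus pair) are "missing": they get no graph edge,
are reported, and block a strict pass only under `strict_missing`.

Strain naming across the printed tables is inconsistent, so loading goes
through an explicit alias map with one canonical name per strain:
*Pichia*/*Komagataella pastoris* PP59, *Pseudomonas* sp./*P. granadensis*
A23/T3c, *Enterobacter* sp./*Rahnella* (also printed "Ranhella")
*aquatilis* BB23/T4d, *Azotobacter*/*Azospirillum brasilense* ATCC 29710,
and the LS136/LS163 codes of one *A. chroococcum* strain are recorded as
aliases; an unknown name raises rather than silently dropping a strain. The
LS136 = LS163 identification is plausible (both names attach to the same
species, and each table prints exactly one of them) but not certain; both
names are kept against one record and the ambiguity is noted in the loaded
tables' `notes`.

Function tags are normalized from the free-text strain properties into a
fixed vocabulary (nitrogen_fixation, P_solubilization, biocontrol,
amylolytic, IAA_production, siderophore, phytase, PGP_generic). One
addition comes from the narrative rather than the table: *P. fluorescens*
DR54 carries P_solubilization (field-trial soluble-P increase), flagged in
the fixture's notes column. Chitinase production is tagged as biocontrol.

## Consortium design and validation

The coexistence graph joins two strains iff their entry permits coexistence
under the chosen policy: strict = `+` only, lenient = `+` or `nc`. Lenient
is the default because one published six-member consortium contains a pair
whose fungal-plate assay was inconclusive (`nc`): under the strict reading
that consortium would be rejected, so the validator reports the unclear
pair rather than hard-failing, and both policies are always computed
(`passes_strict` implies `passes_lenient`). Candidate consortia are the
inclusion-maximal cliques (Bron–Kerbosch with pivoting, via networkx) of
the policy graph restricted to selected strains, filtered by size and by
coverage of the required function set; sub-consortia are derivable from a
maximal clique and are not expanded. Output order is deterministic (size
descending, then lexicographic members). Function coverage is reported, not
enforced as a pass/fail: the published consortia do not all cover every
listed function through table-attested tags alone, so a hard constraint
would reject published designs on fixture grounds.

Biostimulant scoring gives a compound the fraction of consortium members
with a `+` response; `nc` earns nothing but stays in the denominator (the
assay could not discriminate, so no credit). Ranking is by fraction, then
fewer `nc`, then compound id — which places the all-`nc` compound BS4 last
for every published consortium.

## Synthetic data

The generator emulates the structure of the real inputs at desk scale.
References descend from one random ancestor with per-genome substitution
rate *d* (`pairwise_divergence`, default 0.25 so that genomes are mutually
< 80 % identical and reads cannot cross-recruit through the backbone);
two genomes then share expected identity (1−d)² + d²/3. Each genome
receives a few copies (default 3, a typical rRNA operon count) of one
repeat element **identical across genomes** (default 1.5 kb, 16S-like), the
exact feature that produces both cross-genome recruitment and coverage
peaks. Reads (default 100 b, a short-read length) start uniformly on the
source genome and receive per-base substitutions at `read_divergence`
(default 0.02, representing environmental strains diverged from their
database representatives); a fraction (default 0.1) comes from a freshly
drawn unrelated genome. Substitutions always change the base, so the
mismatch count of an on-target read is exactly Binomial(n, rate) — this
makes the recruitment rate at threshold 0.97 predictable in closed form,
P[Bin(100, 0.02) ≤ 2] ≈ 0.677, and the calibration test and acceptance
script check the simulated rate against that tail within 3 percentage
points. Quality strings are constant `I` (Phred 40) and unused. The model
is substitution-only (no indels, no platform error profiles, no realistic
community abundance distributions): passing tests demonstrate the
correctness of the algorithms under their stated model, not recruitment
performance on real soil metagenomes, whose read volumes (10⁹-read
corpora) and taxonomic complexity are far beyond desk scale.

Compatibility simulation plants an all-`+` clique among `n` strains; other
pairs are `+` with probability `edge_density`, otherwise `nc` with
probability `nc_rate`, else `-`. Truth records (read origins, repeat
intervals, planted members) suffice to score sensitivity, specificity and
clique recovery without re-deriving ground truth, and every generator is a
pure function of its seed.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small instances chosen
to keep the independent oracles exact and exhaustive: recruiter equivalence
uses 50 random genomes of 1–10 kb with reads of 60–150 b against a full
sliding-window Hamming scan; clique enumeration is checked against
power-set enumeration up to 15 strains (2¹⁵ subsets) and planted-clique
recovery at 20 strains; the calibration uses 5 000 reads on a 20 kb genome.
Degenerate inputs are defined rather than rejected where a convention
exists (empty hit sets give empty profiles with M = SD = 0; constant rows
autoscale to zero; an empty read stream warns), and contract violations
(R > T, mismatched genome ids, asymmetric duplicate entries, unknown strain
names) raise with the offending item named.
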