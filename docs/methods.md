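# Methods

This note documents the models and procedures implemented in `nsltp`, the
parameters that matter, the synthetic-data model behind the tests, and the
design choices made where the workflow was genuinely open.

## Coordinates and formats

Internal coordinates are 0-based half-open on all interval types; GFF3
(1-based inclusive) and BED (0-based half-open) are converted only at the
I/O boundary. The GFF3 reader accepts the gene/mRNA/exon/CDS subset,
produces one gene model per mRNA, reports orphan exon/CDS rows with the
offending line number, and drops mRNAs whose spliced CDS is not a multiple
of three (with a warning) rather than raising — mirroring how non-coding
hits are silently excluded in genome-wide family surveys. When a gene has
several mRNAs the pipeline keeps the longest CDS and records the choice in
the run manifest. Translation uses the standard genetic code; any codon
containing N becomes X, stops render `*`, and a stop inside a CDS excludes
that record with a warning. DNA ambiguity codes other than N are rejected
at ingest: the motif scan needs hard cysteine calls, so a permissive
alphabet would only blur the one signal that matters.

## 8CM scanning

The scanner finds every set of eight cysteines consistent with the grammar
`C-Xg1-C-Xg2-CC-Xg3-CXC-Xg4-C-Xg5-C`: strictly increasing positions, C3/C4
adjacent, exactly one residue between C5 and C6, and each gap inside its
configured bounds. Default bounds are the union of the wheat per-type
spacing ranges with a small margin added to each maximum
(g1∈[3,21], g2∈[8,29], g3∈[8,23], g4∈[8,38], g5∈[3,22]); they are plain
data and fully user-configurable. Overlapping candidate arrangements are
resolved greedily by leftmost start, then smallest total span — the
literature does not state a resolution rule, so we chose the one that is
deterministic and keeps the most N-terminal, most compact motif; all
candidates are available via `all_candidates=True`. DNA-mode scanning is
six-frame conceptual translation followed by the per-frame protein scan.
The test suite proves the scanner equal to exhaustive enumeration over all
cysteine 8-tuples on peptides up to 400 residues.

## Classification

Mature proteins are the precursor minus the signal peptide (residues up to
the cleavage site) and, when an ω-site is annotated, minus the C-terminal
GPI pro-peptide (residues beyond the ω-site). Cleavage and ω-sites are
consumed from external-predictor tables; candidates with no annotation fall
back to a heuristic (the longest 16–30-residue N-terminal window with ≥70 %
hydrophobic residues, ending before C1) and are flagged `source=heuristic`
as lower-confidence calls. Candidates with no signal peptide at all are
excluded.

Type assignment follows the intron/GPI system used for plant nsLTPs, in
decision order: GPI ω-site ⇒ type G; no intron within or downstream of the
8CM region ⇒ type 2; a single intron exactly 5 / 1 / 4 nt after the last
base of the last 8CM cysteine codon ⇒ type 1 / C / D; a single downstream
intron at any other offset is still called type 2 when global-alignment
identity of the mature peptide to the structurally-called intronless type-2
members reaches `identity_override` (default 0.60 — the identity criterion
is named in the source workflow but no threshold is published, so this
default is a declared decision, logged in output); anything else is
unassigned. "n nucleotides after the last cysteine" is operationalized as:
intron offset = (CDS bases before the intron) − (CDS index of the last base
of the C8 codon), so offset 1 means the intron starts immediately after
that codon. Records with multiple 8CM matches are flagged and deferred to
unassigned rather than guessed.

HyPRP (proline-rich) flagging: the region from the mature N-terminus to C1
must be ≥15 residues with proline fraction ≥0.20; both cutoffs are
parameters. The historical exclusion of proteinase/α-amylase-inhibitor and
2S-albumin look-alikes is implemented as a user deny-list of IDs, not a
structure classifier.

## Physicochemistry

Molecular weight is the sum of average residue masses plus one water
(average, not monoisotopic, matching conventional protein-parameter tools;
the table ships as editable TSV). The isoelectric point solves
`charge(pH)=0` by bisection on [0,14] to 1e-4, with
`charge(pH) = Σ n⁺/(1+10^(pH−pKa)) − Σ n⁻/(1+10^(pKa−pH))` over the
ionizable side chains (D, E, C, Y, H, K, R) and both termini, using
EMBOSS-style pKa values (editable TSV). Cystines are treated as free
cysteines — the family's four disulphides are ignored for pI, since no pKa
scheme for bonded cysteines is standard.

## Duplication and evolution

Homology uses the 80/80 rule: global nucleotide alignment (match +1,
mismatch −1, gap open −5, extend −1), coverage = aligned fraction of the
shorter CDS ≥ 0.80, identity over aligned columns strictly > 0.80
("similarity" is implemented as alignment identity; the coverage
denominator is the shorter CDS — both undefined in the source workflow and
therefore declared here). Tandem clusters are maximal single-linkage chains
of homologous family genes adjacent in chromosome order;
`max_intervening` (default 0, i.e. strictly adjacent among family genes) is
exposed because "adjacent" is not defined more precisely in the field.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site fractions from the
code (averaged over the two sequences), observed differences split by
averaging over all orderings of the changed positions within each codon,
and Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3), flagged saturated at
p ≥ 3/4. Mutational steps through stop codons count as non-synonymous (a
common NG86 convention). NG86 was chosen as the canonical counting method
because the reference workflow ran an external calculator without naming a
model; γ/ML variants are out of scope. Codon pairs containing alignment
gaps or frame breaks are excluded from counting. Divergence times are
`T = Ks/(2r)` in MYA with the grass-standard synonymous rate
r = 6.5×10⁻⁹ substitutions/site/year (configurable).

## Phylogeny

Distances between mature proteins are 1 − identity from global BLOSUM62
alignment (gap open −10, extend −1; identity over aligned columns excluding
terminal gaps). Pairwise-alignment distances replace progressive MSA +
manual refinement, which is neither reproducible nor in scope; UPGMA itself
is the tree method of record for this family and is implemented directly:
merge the closest pair, distance to a merged cluster is the
cluster-size-weighted mean (the arithmetic mean over member pairs), node
height is d/2, ties broken by the lexicographically smallest leaf-label
pair so trees are byte-for-byte reproducible. The suite checks equality
with a naive O(n³) reference and ultrametricity to 1e-9. An option
restricts distances to the 8CM span (`--region 8cm` semantics via the
match coordinates) for comparability with motif-only alignments.

## Expression

FPKM matrices are log₂(x+1)-transformed (pseudocount 1, configurable) and
genes clustered by average linkage on correlation distance (1 − Pearson r
across samples), the tree cut to exactly k clusters (default 10). Profile
shape, not magnitude, is what groups genes across tissues, hence
correlation distance; Euclidean is available by flag. Constant-profile
genes (undefined correlation) are assigned to the nearest cluster centroid
in Euclidean space. Rows are sorted by gene id before clustering so results
are independent of input order. "Anther-enriched" has no published
numerical definition, so the call is an explicit operational rule: mean
FPKM over anther samples ≥ `min_fpkm` (default 2) **and** ≥ `fold`
(default 4) × the best other-tissue mean; "not expressed" is FPKM below
0.5 in every sample. All three numbers are CLI flags and are recorded in
the output manifest.

## Promoter enrichment

Known motifs are scored per promoter as overlapping occurrence counts on
both strands (palindromes counted once) and compared between the
anther-specific and background sets by a one-sided Wilcoxon rank-sum test
(normal approximation, tie-corrected, continuity-corrected), significant at
p < 0.05 per box with no multiple-testing correction — the output notes
this explicitly, and with many boxes the expected number of chance
significants is boxes × α.

De novo discovery enumerates, for k = 4..8, every canonical k-mer (the
lexicographically smaller of k-mer and reverse complement) present in at
least one positive promoter; sequence-level presence feeds a one-sided
Fisher's exact test (computed as the hypergeometric tail, vectorized); the
E-value is p × the number of candidates tested across all k (a Bonferroni
product); the best motif is accepted if E ≤ 0.05, its sites are erased from
the positives, and the loop repeats up to `max_motifs`. At most one IUPAC
wildcard generalization per motif (two-base codes at a single position) is
attempted on the best seed, keeping the candidate space enumerable and the
E-value honest; tested generalizations are included in the Bonferroni
count. Reported E-values are kept non-decreasing down the accepted list
(each is at least the preceding one), so the list order is also a
confidence order. Sequence-level presence drives the Fisher test while the
rank-sum test uses site counts, mirroring the semantics of the two standard
tools for these tasks.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (config, seed). The genome generator
plants nsLTP genes whose 8CM spacings are drawn from the observed per-type
wheat spacing sets, with the type-diagnostic structures (type 2 intronless;
types 1/C/D one intron at offset 5/1/4; type G an ω-site and 0–4 introns),
a fixed 25-residue hydrophobic signal-peptide stub standing in for an
external predictor, and a default type mix equal to the wheat family
composition (8.46 / 59.44 / 1.08 / 12.36 / 18.66 % for types 1/2/C/D/G).
Tandem arrays are adjacent genes derived from a shared seed CDS by exactly
counted synonymous/non-synonymous single-nucleotide changes (default 4 syn
+ 2 nonsyn per member) that never touch the motif cysteines, never create a
stop, and by default never create a new cysteine. Intergenic background and
non-cysteine residue pools exclude cysteine codons so planted motifs are
the only 8CM instances (re-enable with `allow_background_cysteines` for
stress tests). The default study conditions are 50 genes on 3 chromosomes
with 3 tandem arrays (sizes 3, 3, 4).

Expression is a log-normal FPKM model over a 19-sample panel (five tissues
at three stages each, plus pistil and anther): background genes exchange-
able across tissues (median 5), planted anther-enriched genes high in
anther (median 60) and low elsewhere (median 1.5), σ = 0.5, and a planted
all-zero fraction; enriched and silent fractions default to the observed
wheat proportions (17/461 and 30/461). No read-level simulation, codon
usage, isochores, or count noise (the enrichment caller must not depend on
the distribution family, and the tests would not get stronger for it).
Promoter sets are i.i.d. uniform DNA with the planted motif inserted once
per selected sequence at the stated per-set frequencies (defaults: AGAAA,
17 positives at 0.9, 444 negatives at 0.1, 1 kb).

Because background is cysteine-free and annotations are exact, perfect
recovery (type accuracy 1.0, clusters equal to truth) shows the pipeline's
logic is correct under its own assumptions — it does not show robustness to
mispredicted gene models, wrong cleavage sites, or pseudogenized motifs,
which real genomes contain. Power results on synthetic promoters depend
strongly on background length: a 5-mer occurs about twice per kilobase by
chance, so count-based tests at small positive-set sizes only have high
power against shorter backgrounds (the tests state the lengths they use).

## Numerical and degenerate-input choices

Bisection for pI always converges because the charge function is strictly
decreasing with opposite signs at the interval ends. Rank-sum tests with
all scores zero return p = 1 flagged degenerate; all scores identical but
non-zero return p = 0.5 (exchangeable, no ordering information). NG86 with
Ks = 0 leaves the ratio undefined and flags it, rather than dividing.
UPGMA, cluster labelling, motif tie-breaks and gene ordering all break ties
lexicographically, so every artifact the package writes is reproducible
byte for byte under a fixed seed.

## Known limitations

External predictors (signal peptide, GPI, gene finding, splice alignment)
are consumed as annotation tables, not re-implemented; the built-in
hydrophobicity heuristic is a deliberately simple stand-in and is flagged
as such in its outputs. Whole-genome synteny/segmental duplication,
homeologue assignment, bootstrap support, ML/NJ trees, PWM scanning and
motif visualization are out of scope. Printed family-scale figures from
real wheat data (461 genes, 54 clusters, 17 anther-enriched, per-clade
counts) depend on the full genome and external predictors and are not
reproduction targets at desk scale; the suite instead verifies printed
arithmetic, closed forms, and oracle equivalences, plus full recovery of
planted synthetic truth.
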