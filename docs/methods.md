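# Methods

This note documents the models and procedures genefam implements, the
parameters that matter, what the bundled simulator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Family census

The four families are defined by Pfam domain content alone (SuSy PF00862;
UDPGP PF01704; SPS requires both PF00534 and PF05116; SPP is PF05116 with no
confirming PF00534 hit). The profile model is a position-specific scoring
matrix, not a full profile HMM: consensus columns are seed-alignment columns
with < 50 % gaps; per-column probabilities use Laplace pseudocounts
(α = 0.5 per residue, mass split in proportion to background frequencies,
Robinson–Robinson defaults) and are scored as `2·log2(p/background)`
half-bits. Scanning is local (Smith–Waterman) with affine gaps
(open 7, extend 1 half-bits).

E-values come from an empirical null: 200 shuffled decoys drawn round-robin
from the proteome are scored, a Gumbel is fitted by the method of moments,
the location gets the Karlin–Altschul `β·ln(n/n₀)` length adjustment, and
the per-comparison p-value is multiplied by database size. This calibrates
the per-scan expectation: on a shuffled decoy proteome roughly one sequence
per scan reaches E ≤ 1. The decision thresholds — E ≤ 1.0 to search,
E ≤ 0.01 to confirm a domain — are the analysis' fixed operating points, as
is the removal rule: a member whose best hit covers < 70 % of the profile
(`min_coverage`, configurable; "partial domain" is not otherwise
quantified) *and* that carries no expression evidence is flagged
`partial_excluded`. Expression evidence is an explicit gene-id allow-list;
sourcing it (ESTs, RNA-seq) is the caller's responsibility. One locus is
represented by its longest-CDS transcript. A gene matching domains of two
families is assigned to the family with the lower supporting E-value, and
the conflict is logged.

## Expansion-mechanism classification

*Tandem.* A within-family pair is tandem when all four criteria hold:
(1) the local BLOSUM62 alignment (gap open 11 / extend 1, Karlin–Altschul
E-value with λ = 0.267, K = 0.041) covers ≥ 30 % of the query at E < 0.01 —
coverage counts aligned (non-gap) residues of the shorter sequence, since an
optimal aligner can stitch weak islands across long gaps and span-based
coverage would then be inflated on unrelated pairs; (2) identity ≥ 70 % over
aligned columns; (3) ≤ 10 intervening genes (gene rank difference − 1);
(4) the gap between gene bodies is within the genome-class window — 100 kb
for compact genomes (algae, Arabidopsis-sized), 350 kb otherwise.
Qualifying pairs are merged into arrays by single linkage, so arrays
partition their members.

*Segmental.* Anchor pairs (E ≤ 0.01 homologies between genes near family
loci) are chained by dynamic programming over gene ranks: chain score is the
anchor-score sum minus 1.0 per skipped rank unit, consecutive anchors must
advance strictly on both chromosomes (descending on the second for inverted
blocks), rank gaps are capped at 10, and chains need ≥ 5 anchor pairs to be
reported. The DP provably equals exhaustive best-chain search (tested on
all instances with ≤ 8 anchors). A family gene is segmental if it anchors a
block or lies within a block's anchor span extended by the 50 kb flank.

*Transposable elements.* Detection is purely structural, per class:

* LTR — two direct repeats of 100–3000 bp at ≥ 80 % identity, 1–15 kb
  apart, both starting `TG` and ending `CA`, flanked by an identical 4–6 bp
  target-site duplication. Candidates are seeded by exact 12-mers, extended
  by X-drop (match +1 / mismatch −2, drop 15), then boundary-refined to the
  TG…CA + TSD configuration, which restores exact boundaries on clean
  elements even when the extension over- or under-shoots by a few bases.
* Helitron — 5' terminus `TC` preceded by host `a`, 3' terminus `CTAG`
  followed by host `t`, and a hairpin — two arms of ≥ 11 bp that are
  reverse complements of each other — within 30 bp of *each* terminus. The
  "palindromic sequence" is read as a hairpin stem rather than a single
  self-reverse-complement word: an 11 bp self-complementary word occurs by
  chance several times per 50 kb window, which would make the detector
  useless, whereas a ≥ 11 bp stem is specific (measured decoy rate ≤ 2 %
  per window). Where several upstream `a·TC` contexts could pair with one
  terminus, the start whose hairpin sits closest to the terminus wins.
* CACTA — terminal inverted repeats ≥ 10 bp whose outer ends begin
  `CACTA`, with a 3 bp TSD.
* MULE / hAT — TIRs ≥ 40 bp with a 9–10 bp TSD, and ≥ 10 bp with an 8 bp
  TSD respectively, seeded by reverse-complement k-mer matches and extended
  exactly. Because identical TSDs can base-pair by chance at their outer
  bases and get swallowed by the extension, boundaries are re-validated
  with trims of up to 4 bp.

A family gene inside a detected element is TE-carried; its fragment type is
called by locally aligning its CDS (either strand) to the closest
full-length paralog: type 1 touches both CDS termini, type 2 only the 3'
end, type 3 only the 5' end, type 4 neither, where "touching" means the
aligned region reaches into the first/last 10 % of the parent CDS (the
threshold is a package choice; the underlying evidence is continuous).

*Retrogenes.* Single-exon members whose best multi-exon family paralog
reaches identity ≥ 50 % and coverage ≥ 0.7 (configurable); introns lost =
parent exon count − 1.

Mechanism labels are multi-valued — a gene can be, e.g., TE-carried inside
a segmentally duplicated block — and no precedence is imposed.

## Phylogeny, reconciliation, ancestral copies

Distances are Poisson-corrected p-distances over shared non-gap columns
(−ln(1−p); pairs with < 30 shared columns, or p at saturation, are
errors). Trees are canonical Saitou–Nei neighbor joining with a
deterministic label-order tie-break, so the topology is invariant to input
order; NJ recovers the generating topology exactly on additive matrices.
Bootstrap supports are the percentage of column-resampled replicates
containing each bipartition of the point tree.

For reconciliation the gene tree is rooted on the edge minimising implied
duplications; ties are broken by fewest implied losses, then by proximity
to the midpoint. The loss tie-break matters: duplication counts are often
rooting-invariant, and midpoint rooting alone can pick a deep rooting that
inflates ancestral counts. LCA reconciliation maps each node to the lowest
species-tree node containing its leaf species; an internal node is a
duplication iff its children's leaf-species sets intersect. Losses are
counted per edge as the species-tree depth step minus the one step a
speciation explains.

The ancestral (MRCA) copy count at a species divergence S counts gene
lineages present at that instant: speciation nodes mapping to S, plus edges
whose parent maps strictly above S and whose child maps strictly below it.
Under this convention a within-species duplication below S never changes
the count at S, and a single-copy congruent family gives 1 everywhere. No
losses beyond spanning edges are imputed, so counts are conservative
(ancestral copies can be under- but not over-counted by unseen losses).

## Selection analysis

*Pairwise Ka/Ks (NG86).* Synonymous site counts are fractional per codon:
at each position, the synonymous fraction of the single-base changes that
do not create a stop (so S + N = 3 per compared codon); sites are averaged
over the two sequences. Observed differences are averaged over all
orderings of the single-base steps between two codons, excluding
stop-traversing orderings with renormalisation (falling back to all
orderings in the rare case every ordering passes a stop). Codon columns
containing a gap or an ambiguous base are dropped pairwise. The
Jukes–Cantor correction −(3/4)·ln(1 − 4p/3) is applied to pS and pN;
pS or pN ≥ 0.75 raises a saturation error; Ks = 0 yields an undefined
(NaN) ratio rather than an error. The implementation agrees exactly with a
brute-force pathway-enumeration oracle, and on data simulated under its own
model (κ = 1) recovers ω ∈ {0.1, 0.5, 1, 2} to within 15 % in the median at
Ks ≈ 0.3. With transition bias (κ > 1) NG86 is knowingly biased downward —
that is the regime for the YN00-compatible mode, which re-weights site
counting by a κ estimate (K80, from the pair's aligned positions) and F3×4
target-codon frequencies; the two modes agree to |Δ(Ka/Ks)| ≤ 0.2 on
simulated data. The YN00 mode is a weighted counting method in the
Yang–Nielsen spirit, not a line-for-line reproduction of PAML's yn00.

*Pair filter.* Pairs with incomplete overlap are used only when the
ungapped overlap exceeds 150 bp with nucleotide identity ≥ 70 %.

*Sitewise scan.* The model is Muse–Gaut-style over the 61 sense codons
(universal code fixed; observed stop codons are a data error): single κ,
uniform codon frequencies, rates normalised so branch lengths are expected
substitutions per codon at ω = 1. The shared neutral scale is essential:
normalising each ω's matrix to its own mean rate would erase the rate
signal that distinguishes a fast-evolving positive site from a neutral one.
A global stage maximises the likelihood over (κ, branch scale, ω) by
Nelder–Mead on log parameters (Felsenstein pruning, per-node rescaling).
Each site's likelihood is then profiled over ω on a coarse grid spanning
[10⁻⁶, 50] (including ω = 1 exactly) in one vectorised pass and refined by
bounded search between the best grid point's neighbours to |Δω| ≤ 10⁻⁴.
The LRT statistic 2·(lnL(ω̂) − lnL(1)) is referred to χ²(1) without the
boundary ½-mixture correction — conservative for the positive tail — and a
site is positive (purifying) when ω̂ > 1 (< 1) and p < α = 0.05. All-gap
columns are reported untested.

Calibration (the package's own study condition, chosen once): a star
quartet with 0.5 neutral substitutions/codon per branch and 40-codon
alignments carrying one ω = 5 site. Measured over seeded replicates, the
planted site is called positive in ~55–65 % of replicates and truly
neutral sites are falsely called positive at ~4 % (below α); the two-sided
rejection rate at neutral sites is mildly above nominal at long branches —
a known small-sample property of the χ² approximation with four taxa, which
is why the positive-side rate is the calibrated quantity. The star shape
was selected from a pilot over quartet shapes because every branch is then
informative about the single site.

## Expression divergence

`normalize_expression` (log2(x+1), per-gene median centring) produces the
heat-map matrix. The divergence test itself runs on log2(x+1) *without*
centring: the centring constant is estimated from the data, and subtracting
it would add a shared noise shift to every tissue's comparison, inflating
the null per-tissue rate (measured ≈ 0.055 at α = 0.05). On the log scale
the default pooled-variance Student's t-test is exactly calibrated
(measured 0.0498 over 1000 null pairs); the Welch form is available but
conservative at 2–3 replicates. A pair is divergent when any tissue
differs at p < α; no multiple-testing correction is applied across tissues
by default (Benjamini–Hochberg behind a flag). Tissues with < 2 replicates
are skipped with a warning.

## The simulator

`genefam.simulate` generates the study conditions every truth-based test
runs against. One seed gene enters the species-tree root; along each branch
lineages gain copies by a Gillespie birth process with one rate per
mechanism (defaults: tandem 3.0, segmental 1.5, LTR 0.7, Helitron 0.45,
CACTA 0.45, retro 0.7 events per lineage per branch-length unit, giving
~30 extant genes on the default 4-species tree) and die at the loss rate
(default 0 — losses delete genes entirely, with no pseudogene remnants).
True ancestral counts are recorded as lineages present at each divergence
instant. Codon sequences evolve site-independently under per-site ω classes
(default 70 % ω = 0.1, 25 % ω = 0.5, 5 % ω = 1.0 — a purifying family) on
the shared neutral scale; no indels occur in coding sequence, so extant
CDSs are column-comparable by construction.

Genomes are materialised as chromosomes of single-exon filler genes (random
sense-codon CDSs — the decoy background and the collinearity anchors) at
~3 kb spacing in i.i.d. 40 % GC intergenic sequence. Family genes are
placed per origin mechanism: tandem children 1–3 slots from their parent;
segmental children inside a copied block of the parent plus 5 flanking
fillers on another chromosome; TE children wrapped in a class-specific
element (types 2–4 carry an in-frame CDS fragment as a single exon);
retrogene children as intronless full copies. Non-tandem insertions are
kept ≥ 12 gene slots from other family genes so planted mechanism labels
stay unambiguous. Expression matrices plant additive log-scale shifts
(effect 2.0, noise SD 0.5, 16 tissues × 3 replicates) in 1–3 tissues of a
child relative to its parent with probability 0.5.

What the simulator does *not* emulate — and hence what passing tests do not
establish about real data: realistic repeat landscapes and nested/decayed
TEs (detector false-positive rates on real genomes will be higher than on
i.i.d. decoys); indels and alignment error; rate variation beyond the ω
classes; pseudogene remnants after loss; isoform complexity;
platform-specific expression artefacts (the expression model deliberately
matches the t-test's assumptions).

## Verification experiment sizes

The acceptance battery uses: 1000 random 60-codon pairs for the NG86
oracle; 500 instances (≤ 8 anchors) for the chaining oracle; 100 loss-free
histories (all species-tree branches 0.25, 1500 codons, rates
0.5/0.25/0.25 — "small families, well-separated branches"; measured truth
match ≈ 98 %, the residual being duplications essentially coincident with a
speciation, which no sequence data can order); 35 planted elements per TE
class plus 100 decoy windows; 200 sitewise quartet replicates; 1000 null
expression pairs plus 4000 power replicates (the exact power at a 5-SD
shift with 3 replicates is 0.9928, so a small sample would straddle the
0.99 bound by chance). These sizes were chosen so each estimate's sampling
error is small relative to its acceptance margin.

## Known limitations

* The census PSSM lacks HMMER's forward-algorithm E-values and multi-domain
  architecture reasoning; a production domtblout can be substituted.
* Reconciliation assumes binary species trees and no horizontal transfer.
* The sitewise model has no among-site rate variation beyond ω itself, no
  codon-frequency estimation by default, and its χ²(1) reference is
  approximate at small taxon counts (positive tail conservative, purifying
  tail mildly anti-conservative).
* WGD is not distinguished from segmental duplication; the package reports
  segmental evidence and leaves WGD attribution to the user.
* Ka/Ks beyond pS/pN ≈ 0.75 is treated as saturated rather than estimated.
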