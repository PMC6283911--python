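# Methods

## The EAR motif and its detection

EAR (ERF-associated Amphiphilic Repression) motifs are short linear
repression signals in plant proteins.  Two pattern classes are recognised:

* **LxLxL** — a 5-residue window with leucine fixed at offsets 0, 2, 4;
* **DLNP** — D, L, N fixed at offsets 0–2 and a proline at the last
  position, with one free residue (DLNxP, 5-mer) or two (DLNxxP, 6-mer)
  in between.

The abstract-level consensus for the second class is often written DLNxxP
only; the identification rule used here admits both the 5-mer and the
6-mer, and the scanner reports both when they co-occur at the same
aspartate.  Free positions match any residue, including the degenerate
codes X/B/Z/U; fixed positions require the exact residue and therefore
never match a degenerate code.  This is deliberately conservative: an `X`
in a sequencing artifact cannot conjure a motif, only hide one.

Every overlapping match is reported.  Protein-level statements ("contains
LxLxL", "contains both patterns") use the union of hit patterns, since the
biology cares about presence, not multiplicity.

**Positional classes.**  Motif position within the protein (N-terminal /
Middle / C-terminal) matters because the flanking context differs between,
say, AUX/IAA repression domains and C-terminal ERF motifs.  No published
threshold defines the three zones, so we use configurable fractions with
default `n_frac = c_frac = 0.25`: a hit is N if it ends within the first
quarter (`end <= ceil(n_frac * L)`), C if it starts within the last quarter,
M otherwise, with N taking precedence in degenerate tiny-protein cases.

## Profile HMMs over seed windows

Seed proteins are partitioned into at most six subgroups — two patterns ×
three locations — and each subgroup trains one profile from its motif
windows: the motif plus up to **6 flanking residues per side** (12
adjoining residues total; the flank total is ambiguous in the source
description and per-side 6 / total 12 is our reading, configurable via
`flank`).

**Anchored alignment.**  Windows within a subgroup are aligned by
construction rather than by a general MSA algorithm: motif columns are
anchored on the fixed residues, the DLNxP 5-mer receives a single gap in
the second free position relative to DLNxxP, and clipped flanks are padded
with gaps.  This is exact for the window structure at hand and removes an
arbitrary aligner dependency.

**Profile construction.**  Columns with residue occupancy ≥ 0.5 become
match states.  Match emissions are smoothed toward the background:
`e(a) = (count(a) + τ·bg(a)) / (n + τ)` with pseudocount τ = 1.  Insert
states emit the background.  Transitions are counted from the gap
structure, with pseudocount 0.1 per allowed edge; the transition structure
is the full M/I/D grid (including I→D and D→I) with Begin entering M₁ or
D₁ and the model exiting from the last match or delete state.  The default
background is a database-average amino-acid composition (Swiss-Prot-like
frequencies); it is configurable per call.

**Scoring.**  Scores are log2-odds against an i.i.d. background model,
computed by dynamic programming that is *global in the profile, local in
the sequence*: every path traverses all match states but may start and end
anywhere in the sequence.  Viterbi (best path) is the reported bitscore;
forward (log-sum over paths) is available and is ≥ Viterbi by
construction.  Both are verified against exhaustive path enumeration to
1e-9 on small profiles.  Scoring is batch-vectorised over sequences
(padding positions carry −∞ emission odds, so they cannot contribute).

**E-values.**  Each profile is calibrated by scoring `n_null = 1000`
i.i.d. background sequences of fixed length 400 (a typical protein
length; one calibration per profile rather than per-target-length,
matching a single search-wide cutoff) and fitting a Gumbel law to the
max-score sample by maximum likelihood.  Then
`E(s) = db_size · P_gumbel(S ≥ s)`.  The empirical null sample is stored
with the fit as a diagnostic.  A degenerate null (zero variance) is an
error, not a silent fallback.

## The iterative identification loop

Starting from seed proteins that each contain a literal EAR pattern:

1. partition seeds into (pattern, location) subgroups and build one
   calibrated profile per occupied subgroup;
2. score every protein in the proteome against every profile;
3. keep proteins with **E < 0.01 for at least one profile** (the cutoff is
   applied per profile; any passing profile admits the protein) **and at
   least one literal EAR pattern** — the pattern filter is absolute and
   makes false discoveries structurally hard;
4. add novel proteins to the seed set and repeat until none appear.

Profiles are rebuilt from scratch each iteration; a newly added protein
contributes windows for all of its pattern hits.  The seed set grows
monotonically, so the loop terminates; `max_iter = 20` guards against
oscillation from calibration noise.  Calibration RNG streams are derived
per (iteration, subgroup) from one master seed, so runs are bit-for-bit
reproducible.  Subgroups with a single window still build a (sharp)
profile; no minimum seed count is imposed.

Ortholog-derived candidates are merged afterwards under the same literal
pattern filter, with provenance `seed` / `hmm(iteration k)` / `ortholog` /
`both` retained per protein.

## Orthology

Full inparanoid-style inparalog clustering is not needed downstream — only
ortholog *pairs* at a support cutoff are consumed — so orthology is
reduced to reciprocal best hits with bootstrap support.  Local alignment
uses BLOSUM62 with affine gaps, open 11 / extend 1 (the common protein
search defaults; the aligner charges `open + (L−1)·extend` for a gap of
length L).  Support is the percentage of `n_boot = 100` resamples of the
pair's aligned columns (with replacement) in which the pair outscores the
query's runner-up subject; a pair with no competitor has support 100, a
perfect tie converges to ~50% and is excluded at the default cutoff of
60.  For proteomes above ~2,000 sequences a shared-4-mer prefilter limits
exact DP to the 50 most promising subjects per query; results on tested
scales are unchanged because the prefilter only prunes low-identity
subjects that cannot be best hits.

## Enrichment statistics

**Cis-element enrichment.**  For a query of n genes, the observed motif
count X̄ over their promoters is compared with `n_random = 1000` random
same-size gene lists from the universe: μ and σ are the mean and sd of the
per-list totals.  The conventionally published statistic Z = (X̄−μ)/(σ/√n) is
reported verbatim alongside `z_raw = (X̄−μ)/σ`.  Because σ is already the
spread of a size-n list total, only the σ scale yields a calibrated test —
the √n division overstates significance by a factor of √n (a null
simulation rejects at ~0.4 instead of 0.05).  The default p-value is
therefore the upper tail of N(μ, σ); `literal=True` reproduces the
published formula exactly (lower-tail pnorm at scale σ/√n) for comparison
with tools that print that formula.  Random lists may overlap the query; sampling is
without replacement within a list.  Promoters are scanned single-strand by
default (`both_strands` adds the reverse complement); overlapping motif
matches are all counted.  Promoters are the 3,000 nt upstream of the TSS,
strand-aware and truncated at contig ends; the universe is whatever
promoter set the caller supplies.

**Gene-set over-representation.**  One-sided Fisher exact /
hypergeometric p per set from the 2×2 table against the universe
(identical by construction; verified against summed-tail enumeration), χ²
as an approximate option, significance at p ≤ 0.05, no multiple-testing
correction by default (Benjamini–Hochberg available as a flag).

**Differential expression.**  Per gene, a two-sample equal-variance
t-test and `log2(mean_a/mean_b)`; a gene is DE iff p < 0.05 and
|log2FC| > 1.  Genes with a nonpositive group mean are excluded with a
warning — fold change is undefined for them on a linear scale.

**Peak association.**  A gene carries an epigenetic mark iff any peak
overlaps its gene body or the strand-aware upstream window [tss−W, tss)
(mirrored on −).  All intervals half-open; W defaults to 1,000 nt with
2,000 nt the usual choice for rice and maize.

## Networks

**Co-expression.**  Pearson correlation over all gene pairs;
`MR(a,b) = sqrt(rank_a(b) · rank_b(a))` with 1-based PCC-descending
ranks.  Each gene keeps its `top_n = 300` neighbours (PCC descending or MR
ascending; ties broken lexicographically for determinism) and the edge set
is the union, hence symmetric and input-order invariant.  Zero-variance
genes are excluded with a warning.  An optional absolute-PCC floor is
exposed since source databases differ in their thresholds.

**Functional modules.**  Exact k-clique percolation (default k = 4): all
k-cliques are enumerated by expanding maximal cliques (Bron–Kerbosch via
networkx) into k-subsets, cliques sharing k−1 nodes are connected, and
modules are the node unions of connected clique components.  Modules may
overlap.  The implementation refuses graphs beyond ~2·10⁵ k-cliques rather
than approximate; exactness at desk scale is the point, and it is verified
against whole-subset brute force and an independent library implementation.

**Cross-species comparison.**  Two networks plus ortholog pairs yield the
orthologous node pairs present in both networks, per-species counts, and
an overlay graph whose edges are tagged `coexpression` (solid) or
`ortholog` (dashed) for rendering.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed).

* **Proteomes** — i.i.d. residues at a database-average composition
  (length ~ Normal(300, 75), floor 60); implanted proteins receive one
  consensus window (motif + 6-residue flanks) mutated per free position at
  `divergence_rate`; fixed pattern residues never mutate, so planted
  motifs always scan positive.  Flank consensus and mutation alphabet
  avoid L/D/P/N so mutations cannot create patterns; the random background
  still produces chance LxLxL hits at a realistic rate, which is exactly
  what the pattern filter and E-value cutoff are tested against.  DLNP
  implants are 6-mers with a 25% 5-mer fraction to exercise the gapped
  alignment path.
* **Promoters** — i.i.d. nucleotides at GC 0.38 (plant-typical), Poisson
  motif implants at class-specific rates, non-overlapping placement by
  rejection sampling.
* **Networks** — planted cliques of `module_size` plus independent noise
  edges over all nodes.
* **Expression** — multiplicative Gaussian noise (sd 0.15 of the mean)
  around group means separated by `effect_size` log2 units for DE genes.

None of this models domain structure, homologous families, positional
nucleotide composition or count noise.  Passing benchmarks therefore
demonstrate correctness and statistical calibration of the methods under
their own assumptions — not performance on real proteomes, where motif
context is conserved across families rather than implanted from one
consensus.

## Problem sizes and numerical choices

The test-suite and acceptance-script benchmarks use: 1,000-protein
proteomes with 50 implants and 10 seeds (recovery), 10 resampling runs at
70% of the full seed set, 200-protein duplicated proteomes (orthology,
length ~80 so the quadratic all-vs-all stays small), 300-promoter
universes of length 1,000 with 25-gene queries and `n_random = 200`
(enrichment calibration, 200 null replicates; power, 100 replicates at a
5× implant rate), exhaustive 2×2 tables to universe size 50, and 50
random ≤12-node graphs for clique percolation.  These sizes were chosen as
the package's own benchmark conditions.

Numerics: probability tables must normalise to 1 ± 1e-9 (enforced in the
profile constructor); scoring is in log2 space with −∞ sentinels for
impossible emissions; Gumbel fitting is scipy's ML fit with a hard error
on degenerate nulls; σ = 0 in cis enrichment maps to p ∈ {0, 1} with a
signed-infinity z sentinel; neighbour-ranking and clique orderings break
ties lexicographically so every output is deterministic.

## Known limitations

* The profile architecture has no B/E/J states and no glocal/local mode
  switch; bitscores are not comparable to other profile-search tools.
* Bootstrap support here resamples aligned columns against the runner-up;
  it is a stated substitute for inparanoid's bootstrap procedure and the
  numeric cutoffs are not interchangeable between tools.
* The cis-enrichment background resamples gene lists, not sequence
  composition; a query whose promoters differ compositionally from the
  universe (GC, repeats) will show inflated enrichment for
  composition-correlated motifs.
* Clique percolation is exponential in the worst case; the implementation
  is exact and bounded, not scalable.
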