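# earminer

Identification and functional analysis of **EAR motif-containing proteins**
in plants.

The EAR (ERF-associated Amphiphilic Repression) motif is the predominant
transcriptional repression signal known in plants: a short linear motif with
consensus **LxLxL** or **DLNx[1,2]P** (fixed residues at the stated offsets,
`x` any residue).  Proteins carrying it — many ERF, AUX/IAA, JAZ and Tify
family members — recruit co-repressors such as TOPLESS and SAP18 and silence
target genes through histone modification.  `earminer` is a toolkit for
finding these proteins in a proteome and analysing what they do:

* **Literal scanning** — every LxLxL / DLNxP / DLNxxP occurrence, with
  N-terminal / Middle / C-terminal classification and per-protein pattern
  membership.
* **Iterative profile-HMM search** — seeds are partitioned into six
  (pattern × location) subgroups; each subgroup's motif windows (motif ± 6
  flanking residues) train a profile HMM; every protein with
  E-value < 0.01 against any profile *and* a literal EAR pattern joins the
  seed set; the loop repeats until no novel protein appears.  Profile
  construction, Viterbi/forward scoring and Gumbel E-value calibration are
  implemented in the package.
* **Orthology transfer** — reciprocal-best-hit ortholog pairs (BLOSUM62
  local alignment, bootstrap support > 60%) carry candidates and
  protein–protein interaction networks across species.
* **Downstream analytics** — promoter cis-element enrichment with a
  resampled background (Z = (X̄−μ)/(σ/√n), 1,000 random gene lists),
  gene-set over-representation (Fisher/hypergeometric, P ≤ 0.05),
  differential expression (t-test p < 0.05 and |log2FC| > 1), TSS-window
  peak association, top-N co-expression networks (Pearson correlation and
  mutual rank) and k-clique-percolation functional modules (k = 4).
* **Synthetic data** — generators for proteomes with implanted EAR windows,
  promoters with controlled motif rates, networks with planted clique
  modules and grouped expression matrices, each with an exact truth table.

## Worked example

```python
from earminer import (
    find_ear_motifs, locate_hits, classify_pattern_membership,
    simulate_proteome, hmm_iterate,
)

# The two EAR motifs of the Arabidopsis GRAS protein RGL3, in context:
peptide = "GGGG" + "DLNYYP" + "GGGG" + "LLLAL" + "GGGG"
for h in locate_hits(find_ear_motifs(peptide), len(peptide)):
    print(h.pattern, h.start, h.end, h.matched, h.location)
print("membership:", classify_pattern_membership(find_ear_motifs(peptide)))
```

```
DLNP 5 10 DLNYYP M
LxLxL 15 19 LLLAL M
membership: both
```

The scanner reports one DLNxxP-class motif at residues 5–10 and one
LxLxL-class motif at 15–19 (both fall in the middle band of this short
peptide); the protein belongs to the "both patterns" class.  On a synthetic benchmark the full identification loop recovers
implanted EAR proteins from a small seed set:

```python
proteome, truth = simulate_proteome(n=1000, n_implant=50,
                                    divergence_rate=0.1, seed=1)
seeds = sorted(truth.index[truth.implanted])[:10]
candidates, logs = hmm_iterate(proteome, seeds, evalue_cutoff=0.01, seed=7)
implanted = set(truth.index[truth.implanted])
print(f"recovered {len(candidates.ids & implanted)}/50 implanted proteins,"
      f" {len(candidates.ids - implanted)} false discoveries")
```

```
recovered 49/50 implanted proteins, 0 false discoveries
```

Starting from 10 of the 50 implanted proteins, the loop converges in two
iterations and recovers 98% of the planted truth with no false positives —
the pattern filter discards every spurious E-value hit.

A command-line layer mirrors the library (`earminer scan`, `search`,
`orthologs`, `cis-enrich`, `gsea`, `de`, `peaks`, `coexpr`, `modules`,
`compare-net`, `simulate`, …); every run writes its table plus a provenance
JSON with config, seed and input checksums.  Short narrative scripts for
each capability live in `examples/`.

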