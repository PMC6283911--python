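"""Call ortholog pairs between two proteomes and transfer candidates.

Species B here is a noisy copy of species A, so the reciprocal-best-hit
mapping is known; candidate EAR proteins found in A are transferred to B
through the pairs.
"""

from earminer import (
    SequenceRecord,
    find_orthologs,
    simulate_proteome,
    transfer_candidates,
)

species_a, truth = simulate_proteome(n=40, n_implant=10, length_mean=100, seed=3)
# species B: same proteins with a small C-terminal rearrangement
species_b = [SequenceRecord("B_" + p.id, p.seq[:-10] + p.seq[:5])
             for p in species_a]

pairs = find_orthologs(species_a, species_b, n_boot=100, support_cutoff=60, seed=4)
print(f"{len(pairs)} ortholog pair(s) at bootstrap support > 60%")
print("first three:", [(p.gene_a, p.gene_b, round(p.support)) for p in pairs[:3]])

ear_in_a = set(truth.index[truth.implanted])
transferred = transfer_candidates(pairs, ear_in_a)
print(f"\n{len(ear_in_a)} EAR candidates in species A -> "
      f"{len(transferred)} transferred to species B via the pair mapping.")
print("Transferred ids are candidates only: the pipeline re-applies the "
      "literal EAR pattern filter before accepting them.")
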