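"""Recover implanted EAR proteins from a small seed set.

Runs the full identification loop — subgroup profiles, E-value filtering,
literal pattern filtering, iteration to convergence — on a synthetic
1,000-protein proteome with 50 implants, starting from 10 seeds.
"""

from earminer import hmm_iterate, simulate_proteome

proteome, truth = simulate_proteome(n=1000, n_implant=50,
                                    divergence_rate=0.1, seed=1)
implanted = set(truth.index[truth.implanted])
seeds = sorted(implanted)[:10]

candidates, logs = hmm_iterate(proteome, seeds, evalue_cutoff=0.01, seed=7)

for log in logs:
    print(f"iteration {log.iteration}: {log.seeds_in} seeds in, "
          f"{log.hits_passing_evalue} pass E<0.01, "
          f"{log.hits_passing_pattern} also carry a literal pattern, "
          f"{log.novel_added} novel")

recovered = len(candidates.ids & implanted)
false = len(candidates.ids - implanted)
print(f"\nrecovered {recovered}/{len(implanted)} implanted proteins, "
      f"{false} false discoveries")
print("Recovery near 100% with zero false positives is the expected regime: "
      "the literal-pattern filter vetoes any protein an HMM alone would "
      "over-call.")
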