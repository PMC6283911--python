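"""Iterative seed-expansion identification of EAR motif-containing proteins.

The loop: partition current seed proteins into (pattern, location)
subgroups, build one profile HMM per occupied subgroup from the seeds'
motif windows, calibrate it, score every protein in the target proteome,
keep proteins passing the E-value cutoff for at least one profile AND
containing a literal EAR pattern, add the novel ones to the seed set, and
repeat until no novel protein appears.  Candidates from an independent
ortholog transfer can then be merged in, subject to the same literal
pattern filter.

The seed set grows monotonically, so termination is guaranteed; a safety
cap (``max_iter``) guards against pathological calibration noise.  All
randomness (profile calibration) is derived from one master seed, one
child stream per (iteration, subgroup), so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord
from .motifs import DEFAULT_PATTERNS, EarMotifHit, find_ear_motifs, locate_hits
from .hmm import (
    ProfileHMM,
    SeedSubgroup,
    build_anchored_msa,
    build_profile,
    calibrate,
    evalue,
    extract_seed_windows,
    score_sequences,
)

__all__ = [
    "IterationLog",
    "CandidateSet",
    "partition_seeds",
    "hmm_iterate",
    "merge_candidates",
]


@dataclass(frozen=True)
class IterationLog:
    iteration: int
    seeds_in: int
    hits_passing_evalue: int
    hits_passing_pattern: int
    novel_added: int


@dataclass
class CandidateSet:
    """Candidate protein ids with provenance: seed | hmm(iteration k) | ortholog | both."""

    provenance: dict[str, str] = field(default_factory=dict)
    converged: bool = True

    @property
    def ids(self) -> set[str]:
        return set(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, pid: str) -> bool:
        return pid in self.provenance


def _hits_per_protein(
    proteins: list[SequenceRecord], n_frac: float, c_frac: float
) -> dict[str, list[EarMotifHit]]:
    out = {}
    for p in proteins:
        hits = find_ear_motifs(p.seq, DEFAULT_PATTERNS, protein_id=p.id)
        out[p.id] = locate_hits(hits, len(p.seq), n_frac, c_frac)
    return out


def partition_seeds(
    seeds: list[SequenceRecord],
    hits: dict[str, list[EarMotifHit]] | None = None,
    flank: int = 6,
    n_frac: float = 0.25,
    c_frac: float = 0.25,
) -> list[SeedSubgroup]:
    """Split seed motif windows into (pattern, location) subgroups.

    At most six subgroups exist (2 patterns x 3 locations); only occupied
    cells are returned.  A protein with several hits contributes a window
    to every relevant subgroup.  A seed without any literal hit is an error.
    """
    if hits is None:
        hits = _hits_per_protein(seeds, n_frac, c_frac)
    by_id = {p.id: p for p in seeds}
    groups: dict[tuple[str, str], SeedSubgroup] = {}
    for p in seeds:
        phits = hits.get(p.id, [])
        if not phits:
            raise ValueError(f"seed {p.id!r} contains no EAR pattern")
        for h in phits:
            loc = h.location or "M"
            key = (h.pattern, loc)
            grp = groups.setdefault(key, SeedSubgroup(h.pattern, loc))
            grp.windows.append(extract_seed_windows(by_id[h.protein_id], h, flank))
    return [groups[k] for k in sorted(groups)]


def _build_subgroup_profiles(
    subgroups: list[SeedSubgroup],
    n_null: int,
    null_len: int,
    rng: np.random.Generator,
) -> list[ProfileHMM]:
    profiles = []
    for grp in subgroups:
        msa = build_anchored_msa(grp.windows)
        hmm = build_profile(msa)
        hmm = calibrate(hmm, n_null=n_null, null_len=null_len, seed=rng)
        profiles.append(hmm)
    return profiles


def hmm_iterate(
    proteome: list[SequenceRecord],
    seed_ids: set[str] | list[str],
    evalue_cutoff: float = 0.01,
    max_iter: int = 20,
    seed: int | None = None,
    flank: int = 6,
    n_null: int = 1000,
    null_len: int = 400,
) -> tuple[CandidateSet, list[IterationLog]]:
    """Run the profile-search loop to convergence.

    Returns the candidate set (provenance-tagged) and one log row per
    iteration.  Every reported candidate carries a literal EAR pattern;
    the seed set is monotone non-decreasing across iterations.  If the
    loop is still adding proteins at ``max_iter`` the result is returned
    with ``converged=False`` and a warning.
    """
    seed_ids = set(seed_ids)
    if not seed_ids:
        raise ValueError("empty seed set")
    by_id = {p.id: p for p in proteome}
    missing = seed_ids - set(by_id)
    if missing:
        raise ValueError(f"seed id(s) not in proteome: {sorted(missing)[:5]}")

    all_hits = _hits_per_protein(proteome, 0.25, 0.25)
    pattern_positive = {pid for pid, hs in all_hits.items() if hs}
    for sid in seed_ids:
        if sid not in pattern_positive:
            raise ValueError(f"seed {sid!r} contains no EAR pattern")

    master = np.random.default_rng(seed)
    current = set(seed_ids)
    result = CandidateSet({sid: "seed" for sid in seed_ids})
    logs: list[IterationLog] = []
    seqs = [p.seq for p in proteome]
    pids = [p.id for p in proteome]
    db_size = len(proteome)

    for it in range(1, max_iter + 1):
        subgroups = partition_seeds(
            [by_id[i] for i in sorted(current)],
            {i: all_hits[i] for i in current},
            flank=flank,
        )
        # one child RNG per (iteration, subgroup) from the master seed
        rng = np.random.default_rng(master.integers(2**31))
        profiles = _build_subgroup_profiles(subgroups, n_null, null_len, rng)

        passing_e: set[str] = set()
        for hmm in profiles:
            scores = score_sequences(hmm, seqs, mode="viterbi")
            for pid, s in zip(pids, scores):
                if evalue(hmm, float(s), db_size) < evalue_cutoff:
                    passing_e.add(pid)
        passing_pat = passing_e & pattern_positive
        novel = passing_pat - current
        logs.append(
            IterationLog(it, len(current), len(passing_e), len(passing_pat), len(novel))
        )
        for pid in novel:
            result.provenance[pid] = f"hmm(iteration {it})"
        current |= novel
        if not novel:
            break
    else:
        result.converged = False
        warnings.warn(f"hmm_iterate did not converge within {max_iter} iterations")
    return result, logs


def merge_candidates(
    hmm_set: CandidateSet,
    ortholog_ids: set[str] | list[str],
    proteome: list[SequenceRecord],
) -> CandidateSet:
    """Union the profile-search candidates with ortholog-transferred ones.

    Ortholog candidates lacking any literal EAR pattern are dropped; ids
    present in both sources get provenance ``both``.
    """
    by_id = {p.id: p for p in proteome}
    merged = CandidateSet(dict(hmm_set.provenance), hmm_set.converged)
    for pid in set(ortholog_ids):
        if pid not in by_id:
            raise ValueError(f"ortholog candidate {pid!r} absent from proteome")
        if not find_ear_motifs(by_id[pid].seq, DEFAULT_PATTERNS, protein_id=pid):
            continue
        if pid in merged.provenance:
            merged.provenance[pid] = "both"
        else:
            merged.provenance[pid] = "ortholog"
    return merged
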