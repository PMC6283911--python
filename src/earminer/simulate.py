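"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters and seed: the same
call yields byte-identical output.  The truth table accompanying each
dataset records what was planted where, so recovery, false-discovery and
calibration rates can be measured exactly.

What is emulated — and what is not: proteins are i.i.d. residues from a
database-average composition with one EAR window implanted per positive
protein (no domain structure, no homologous families beyond the shared
window); promoters are i.i.d. nucleotides at a fixed GC with Poisson
motif implants (no positional composition); networks are planted cliques
plus independent noise edges; expression is Gaussian around group means.
These suffice to test correctness and calibration of the methods, not to
claim performance on real proteomes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, SequenceRecord
from .hmm import SWISSPROT_BACKGROUND

__all__ = [
    "simulate_proteome",
    "simulate_promoters",
    "simulate_network",
    "simulate_expression",
]

# Consensus seed windows per pattern: 6-residue flanks free of L, D and P so
# the flanks can never create or extend an EAR pattern by accident.
_FLANK_L = "AGSKTE"
_FLANK_R = "KTGESA"
_CONSENSUS_MOTIF = {
    ("LxLxL", 5): "LSLRL",
    ("DLNP", 5): "DLNSP",
    ("DLNP", 6): "DLNSSP",
}
_FIXED_OFFSETS = {
    ("LxLxL", 5): {0, 2, 4},
    ("DLNP", 5): {0, 1, 2, 4},
    ("DLNP", 6): {0, 1, 2, 5},
}
# residues allowed at mutated free positions: anything that cannot complete
# a pattern through the fixed residues
_SAFE_MUTATIONS = "AGSTEKRQVIFYWHMC"


def _mix_to_items(mix: dict[str, float]) -> tuple[list[str], np.ndarray]:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError(f"inconsistent mix {mix}")
    return keys, probs / probs.sum()


def _random_protein(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=bg))


def simulate_proteome(
    n: int = 1000,
    length_mean: int = 300,
    background_freqs: np.ndarray | None = None,
    n_implant: int = 50,
    pattern_mix: dict[str, float] | None = None,
    location_mix: dict[str, float] | None = None,
    divergence_rate: float = 0.1,
    dlnp5_frac: float = 0.25,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """I.i.d.-background proteome with EAR windows implanted in ``n_implant`` proteins.

    Each implanted protein gets one consensus window (motif + 6-residue
    flanks) mutated at ``divergence_rate`` per free position — fixed
    pattern residues never mutate, so the planted motif always scans
    positive.  Placement follows ``location_mix`` over N/M/C with the
    default quarter thresholds.  Truth columns: id, implanted, pattern,
    location, motif_start, motif_end (1-based), window.
    """
    if n_implant > n:
        raise ValueError("n_implant exceeds n")
    if not 0 <= divergence_rate <= 1:
        raise ValueError("divergence_rate must be in [0,1]")
    bg = SWISSPROT_BACKGROUND if background_freqs is None else np.asarray(background_freqs, float)
    bg = bg / bg.sum()
    patterns, p_probs = _mix_to_items(pattern_mix or {"LxLxL": 0.75, "DLNP": 0.25})
    locations, l_probs = _mix_to_items(location_mix or {"N": 1 / 3, "M": 1 / 3, "C": 1 / 3})
    rng = np.random.default_rng(seed)

    records: list[SequenceRecord] = []
    rows = []
    width = len(str(n))
    for i in range(n):
        pid = f"prot{i:0{width}d}"
        length = max(60, int(rng.normal(length_mean, length_mean / 4)))
        seq = list(_random_protein(rng, length, bg))
        implanted = i < n_implant
        pat = loc = win = ""
        m_start = m_end = 0
        if implanted:
            pat = patterns[rng.choice(len(patterns), p=p_probs)]
            loc = locations[rng.choice(len(locations), p=l_probs)]
            mlen = 5
            if pat == "DLNP":
                mlen = 5 if rng.random() < dlnp5_frac else 6
            motif = list(_CONSENSUS_MOTIF[(pat, mlen)])
            fixed = _FIXED_OFFSETS[(pat, mlen)]
            window = list(_FLANK_L) + motif + list(_FLANK_R)
            for j in range(len(window)):
                moff = j - len(_FLANK_L)
                if 0 <= moff < mlen and moff in fixed:
                    continue
                if rng.random() < divergence_rate:
                    window[j] = _SAFE_MUTATIONS[rng.integers(len(_SAFE_MUTATIONS))]
            # choose a motif start whose hit classifies as the target location
            q = int(np.ceil(0.25 * length))
            if loc == "N":
                lo, hi = 1, max(1, q - mlen + 1)
            elif loc == "C":
                lo, hi = length - q + 1, length - mlen + 1
            else:
                lo, hi = q + 2, length - q - mlen
            lo = max(1, min(lo, length - mlen + 1))
            hi = max(lo, min(hi, length - mlen + 1))
            m_start = int(rng.integers(lo, hi + 1))
            m_end = m_start + mlen - 1
            w_start = m_start - 1 - len(_FLANK_L)
            for j, c in enumerate(window):
                pos = w_start + j
                if 0 <= pos < length:
                    seq[pos] = c
            win = "".join(window)
        records.append(SequenceRecord(pid, "".join(seq)))
        rows.append(
            dict(id=pid, implanted=implanted, pattern=pat, location=loc,
                 motif_start=m_start, motif_end=m_end, window=win)
        )
    truth = pd.DataFrame(rows).set_index("id")
    return records, truth


def simulate_promoters(
    n_query: int = 50,
    n_background: int = 450,
    length: int = 3000,
    gc: float = 0.38,
    motif: str = "TGACGTCA",
    rate_query: float = 1.0,
    rate_background: float = 1.0,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Promoter set with Poisson motif implants at class-specific rates.

    ``rate_*`` is the expected number of implanted instances per promoter;
    instances land at uniform non-overlapping positions (rejection
    sampling with a retry cap).  Query promoters are named ``q*``,
    background ``b*``.  Truth columns: id, is_query, n_implanted,
    positions (0-based, comma-joined).
    """
    if len(motif) > length:
        raise ValueError("motif longer than promoter")
    if rate_query < 0 or rate_background < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.array(["A", "C", "G", "T"])
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records, rows = [], []
    specs = [("q", n_query, rate_query), ("b", n_background, rate_background)]
    for prefix, count, rate in specs:
        width = len(str(max(count, 1)))
        for i in range(count):
            pid = f"{prefix}{i:0{width}d}"
            seq = list(rng.choice(base, size=length, p=probs))
            k = int(rng.poisson(rate))
            placed: list[int] = []
            tries = 0
            while len(placed) < k and tries < 200 * max(k, 1):
                pos = int(rng.integers(0, length - len(motif) + 1))
                if all(abs(pos - q) >= len(motif) for q in placed):
                    placed.append(pos)
                tries += 1
            for pos in placed:
                seq[pos : pos + len(motif)] = list(motif)
            records.append(SequenceRecord(pid, "".join(seq)))
            rows.append(
                dict(id=pid, is_query=prefix == "q", n_implanted=len(placed),
                     positions=",".join(map(str, sorted(placed))))
            )
    truth = pd.DataFrame(rows).set_index("id")
    return records, truth


def simulate_network(
    n_modules: int = 3,
    module_size: int = 6,
    k: int = 4,
    noise_edge_prob: float = 0.01,
    n_background_nodes: int = 20,
    seed: int | None = None,
):
    """Graph with planted clique modules plus independent noise edges.

    Each planted module is a ``module_size``-clique on its own nodes, so
    with ``noise_edge_prob=0`` clique percolation at ``k <= module_size``
    recovers the modules exactly.  Returns (networkx graph, truth table
    mapping node -> module index, -1 for background).
    """
    import networkx as nx

    if module_size < k:
        raise ValueError("module_size must be >= k")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    rows = []
    node_id = 0
    for m in range(n_modules):
        members = [f"g{node_id + j:04d}" for j in range(module_size)]
        node_id += module_size
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                g.add_edge(a, b)
        rows.extend(dict(id=x, module=m) for x in members)
    for _ in range(n_background_nodes):
        x = f"g{node_id:04d}"
        node_id += 1
        g.add_node(x)
        rows.append(dict(id=x, module=-1))
    nodes = sorted(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if not g.has_edge(a, b) and rng.random() < noise_edge_prob:
                g.add_edge(a, b)
    truth = pd.DataFrame(rows).set_index("id")
    return g, truth


def simulate_expression(
    n_genes: int = 1000,
    n_de: int = 100,
    effect_size: float = 2.0,
    sigma: float = 0.15,
    samples_per_group: int = 4,
    base_mean: float = 100.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group expression matrix with ``n_de`` genes shifted by
    ``effect_size`` log2 units in group A.

    Noise is multiplicative Gaussian (sd ``sigma`` relative to the group
    mean), keeping values on a positive linear scale.  Returns the matrix
    (genes x samples, columns ``a1.. b1..``) and a truth table with the
    planted log2 fold change per gene.
    """
    if n_de > n_genes:
        raise ValueError("n_de exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    cols = [f"a{j + 1}" for j in range(samples_per_group)] + [
        f"b{j + 1}" for j in range(samples_per_group)
    ]
    lfc = np.zeros(n_genes)
    lfc[:n_de] = effect_size
    mean_a = base_mean * 2.0**lfc
    mean_b = np.full(n_genes, base_mean)
    a = mean_a[:, None] * (1 + sigma * rng.standard_normal((n_genes, samples_per_group)))
    b = mean_b[:, None] * (1 + sigma * rng.standard_normal((n_genes, samples_per_group)))
    mat = pd.DataFrame(
        np.clip(np.hstack([a, b]), 1e-6, None), index=genes, columns=cols
    )
    truth = pd.DataFrame({"id": genes, "log2fc": lfc, "is_de": lfc != 0}).set_index("id")
    return mat, truth
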