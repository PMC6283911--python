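"""Profile HMMs over EAR seed windows: build, score, calibrate.

A profile is trained on motif windows (the motif plus up to six flanking
residues per side) from one seed subgroup — one (pattern, location) cell.
Windows are put into a gapless anchored alignment (the only gap arises from
the 5-mer vs 6-mer DLNP length difference), converted into match states
with pseudocount-smoothed emissions, and scored against candidate proteins
by dynamic programming.

Scoring semantics: global in the profile, local in the sequence.  Every
path enters at Begin before any sequence position, traverses all match
states via match/insert/delete moves, and exits after the last match or
delete state.  The reported bitscore is the log2-odds of the best such
path against an i.i.d. background model (Viterbi); ``mode="forward"``
returns the log2 sum over all paths instead, so forward >= Viterbi always.

E-values come from an explicit null calibration: the maximum-score
distribution over i.i.d. background sequences is fitted with a Gumbel
(extreme-value) law by maximum likelihood, and
``E = db_size * P_gumbel(score >= s)``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gumbel_r

from .io import AMINO_ACIDS, SequenceRecord
from .motifs import EarMotifHit

__all__ = [
    "SWISSPROT_BACKGROUND",
    "SeedWindow",
    "SeedSubgroup",
    "Calibration",
    "ProfileHMM",
    "extract_seed_windows",
    "build_anchored_msa",
    "build_profile",
    "score_sequence",
    "score_sequences",
    "calibrate",
    "evalue",
]

# Average residue frequencies over well-curated protein databases, used as
# the default background model (renormalised below).
_BG = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "W": 0.0110, "Y": 0.0292, "V": 0.0687,
}
SWISSPROT_BACKGROUND = np.array([_BG[a] for a in AMINO_ACIDS])
SWISSPROT_BACKGROUND /= SWISSPROT_BACKGROUND.sum()

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_AMBIG = 20   # X/B/Z/U: neutral log-odds everywhere
_PAD = 21     # batch padding: impossible to emit
_NEG = -np.inf


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        idx = _AA_INDEX.get(c)
        if idx is None:
            if c in "XBZU":
                idx = _AMBIG
            else:
                raise ValueError(f"invalid residue {c!r} at position {i + 1}")
        out[i] = idx
    return out


@dataclass(frozen=True)
class SeedWindow:
    """A motif occurrence with flanking context, clipped at sequence ends."""

    protein_id: str
    window: str
    motif_offset: int
    motif_length: int
    pattern: str
    location: str


@dataclass
class SeedSubgroup:
    """All seed windows sharing one (pattern, location) cell."""

    pattern: str
    location: str
    windows: list[SeedWindow] = field(default_factory=list)


def extract_seed_windows(
    protein: SequenceRecord, hit: EarMotifHit, flank: int = 6
) -> SeedWindow:
    """Cut the motif plus up to ``flank`` residues per side out of the protein."""
    if hit.protein_id and hit.protein_id != protein.id:
        raise ValueError(f"hit belongs to {hit.protein_id!r}, not {protein.id!r}")
    if not (1 <= hit.start <= hit.end <= len(protein.seq)):
        raise ValueError("hit outside protein")
    left = max(0, hit.start - 1 - flank)
    right = min(len(protein.seq), hit.end + flank)
    return SeedWindow(
        protein.id,
        protein.seq[left:right],
        motif_offset=hit.start - 1 - left,
        motif_length=hit.length,
        pattern=hit.pattern,
        location=hit.location,
    )


def build_anchored_msa(windows: list[SeedWindow]) -> list[str]:
    """Align windows of one subgroup by anchoring on the motif's fixed residues.

    Flanks are padded with ``-`` where clipped; DLNxP (5-mer) rows receive a
    single gap in the second free position relative to DLNxxP, so the D/L/N
    block and the final P always share columns.  Rows come out equal length.
    """
    if not windows:
        raise ValueError("no windows")
    patterns = {w.pattern for w in windows}
    if len(patterns) > 1:
        raise ValueError(f"windows mix patterns {sorted(patterns)}")
    pattern = patterns.pop()
    motif_cols = 6 if pattern == "DLNP" else 5

    def motif_row(w: SeedWindow) -> str:
        m = w.window[w.motif_offset : w.motif_offset + w.motif_length]
        if pattern == "DLNP" and w.motif_length == 5:
            return m[:4] + "-" + m[4]      # D L N x - P
        if len(m) != motif_cols:
            raise ValueError(f"motif length {len(m)} incompatible with {pattern}")
        return m

    left_w = max(w.motif_offset for w in windows)
    right_w = max(len(w.window) - w.motif_offset - w.motif_length for w in windows)
    rows = []
    for w in windows:
        lf = w.window[: w.motif_offset]
        rf = w.window[w.motif_offset + w.motif_length :]
        rows.append(
            "-" * (left_w - len(lf)) + lf + motif_row(w) + rf + "-" * (right_w - len(rf))
        )
    assert len({len(r) for r in rows}) == 1
    return rows


@dataclass
class Calibration:
    """Gumbel fit (location, scale) to null max-scores plus the raw sample."""

    loc: float
    scale: float
    null_scores: np.ndarray


@dataclass
class ProfileHMM:
    n_match: int
    match_emissions: np.ndarray            # (K, 20)
    insert_emissions: np.ndarray           # (20,)
    background: np.ndarray                 # (20,)
    # outgoing transition probabilities; index m is the source state
    p_begin: np.ndarray                    # (2,) B -> M0, D0
    p_match: np.ndarray                    # (K-1, 3) M_m -> M,I,D
    p_insert: np.ndarray                   # (K-1, 3) I_m -> M,I,D
    p_delete: np.ndarray                   # (K-1, 3) D_m -> M,I,D
    calibration: Calibration | None = None

    def __post_init__(self) -> None:
        for name, table in (
            ("match_emissions", self.match_emissions),
            ("p_begin", self.p_begin[None, :]),
            ("p_match", self.p_match),
            ("p_insert", self.p_insert),
            ("p_delete", self.p_delete),
        ):
            sums = np.asarray(table).sum(axis=-1)
            if table.size and not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows do not sum to 1")
        if abs(self.insert_emissions.sum() - 1.0) > 1e-9:
            raise ValueError("insert_emissions do not sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "n_match": self.n_match,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "background": self.background.tolist(),
            "p_begin": self.p_begin.tolist(),
            "p_match": self.p_match.tolist(),
            "p_insert": self.p_insert.tolist(),
            "p_delete": self.p_delete.tolist(),
        }
        if self.calibration is not None:
            obj["calibration"] = {
                "loc": self.calibration.loc,
                "scale": self.calibration.scale,
                "null_scores": self.calibration.null_scores.tolist(),
            }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        obj = json.loads(Path(path).read_text())
        cal = None
        if "calibration" in obj:
            c = obj["calibration"]
            cal = Calibration(c["loc"], c["scale"], np.asarray(c["null_scores"]))
        return cls(
            n_match=obj["n_match"],
            match_emissions=np.asarray(obj["match_emissions"]),
            insert_emissions=np.asarray(obj["insert_emissions"]),
            background=np.asarray(obj["background"]),
            p_begin=np.asarray(obj["p_begin"]),
            p_match=np.asarray(obj["p_match"]),
            p_insert=np.asarray(obj["p_insert"]),
            p_delete=np.asarray(obj["p_delete"]),
            calibration=cal,
        )


def build_profile(
    msa: list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
    occupancy: float = 0.5,
    transition_pseudocount: float = 0.1,
) -> ProfileHMM:
    """Turn an anchored alignment into a profile HMM.

    Columns whose residue occupancy is at least ``occupancy`` become match
    states; interior low-occupancy columns feed insert states.  Match
    emissions are smoothed toward the background:
    ``e(a) = (count(a) + pseudocount * bg(a)) / (n + pseudocount)``.
    All-gap columns are dropped with a warning.
    """
    if not msa:
        raise ValueError("empty alignment")
    if len({len(r) for r in msa}) != 1:
        raise ValueError("alignment rows differ in length")
    bg = SWISSPROT_BACKGROUND if background is None else np.asarray(background, float)
    bg = bg / bg.sum()

    ncol = len(msa[0])
    nrow = len(msa)
    occ = np.array([sum(r[c] != "-" for r in msa) / nrow for c in range(ncol)])
    keep = [c for c in range(ncol) if occ[c] > 0]
    dropped = ncol - len(keep)
    if dropped:
        warnings.warn(f"dropped {dropped} all-gap column(s)")
    match_cols = [c for c in keep if occ[c] >= occupancy]
    if not match_cols:
        raise ValueError("no column reaches the match-state occupancy threshold")
    K = len(match_cols)
    col_state = {c: m for m, c in enumerate(match_cols)}
    first_mc, last_mc = match_cols[0], match_cols[-1]

    # emissions
    em = np.zeros((K, 20))
    for c, m in col_state.items():
        for r in msa:
            idx = _AA_INDEX.get(r[c])
            if idx is not None:
                em[m, idx] += 1
    totals = em.sum(axis=1, keepdims=True)
    em = (em + pseudocount * bg) / (totals + pseudocount)

    # transitions: walk each row through B, M/D at match columns, I at
    # interior insert columns; flank overhang outside the match block is
    # handled by locality and is not counted.
    tp = transition_pseudocount
    cb = np.full(2, tp)                       # B -> M0, D0
    cm = np.full((max(K - 1, 1), 3), tp)      # M_m -> M,I,D
    ci = np.full((max(K - 1, 1), 3), tp)      # I_m -> M,I,D
    cd = np.full((max(K - 1, 1), 3), tp)      # D_m -> M,I,D
    _STATE = {"M": 0, "I": 1, "D": 2}
    for r in msa:
        prev = "B"
        prev_m = -1
        for c in range(first_mc, last_mc + 1):
            if c in col_state:
                m = col_state[c]
                cur = "M" if r[c] != "-" else "D"
            elif r[c] != "-":
                m, cur = prev_m, "I"
            else:
                continue
            if prev == "B":
                # the walk starts at a match column, so cur is M or D here
                cb[0 if cur == "M" else 1] += 1
            else:
                src = {"M": cm, "I": ci, "D": cd}[prev]
                src[prev_m, _STATE[cur]] += 1
            prev, prev_m = cur, m
    if K == 1:
        cm = ci = cd = np.full((0, 3), tp)
    pb = cb / cb.sum()
    pm = cm / cm.sum(axis=1, keepdims=True) if cm.size else cm
    pi = ci / ci.sum(axis=1, keepdims=True) if ci.size else ci
    pd_ = cd / cd.sum(axis=1, keepdims=True) if cd.size else cd

    return ProfileHMM(
        n_match=K,
        match_emissions=em,
        insert_emissions=bg.copy(),
        background=bg,
        p_begin=pb,
        p_match=pm,
        p_insert=pi,
        p_delete=pd_,
    )


# ---------------------------------------------------------------------------
# scoring


def _log_tables(hmm: ProfileHMM):
    """Precompute log2 emission-odds and entry-transition tables for the DP."""
    K = hmm.n_match
    with np.errstate(divide="ignore"):
        mlo = np.full((K, 22), _NEG)
        mlo[:, :20] = np.log2(hmm.match_emissions / hmm.background)
        mlo[:, _AMBIG] = 0.0
        ilo = np.full(22, _NEG)
        ilo[:20] = np.log2(hmm.insert_emissions / hmm.background)
        ilo[_AMBIG] = 0.0
        lb = np.log2(hmm.p_begin)
        lm = np.log2(hmm.p_match) if hmm.p_match.size else np.zeros((0, 3))
        li = np.log2(hmm.p_insert) if hmm.p_insert.size else np.zeros((0, 3))
        ld = np.log2(hmm.p_delete) if hmm.p_delete.size else np.zeros((0, 3))
    return mlo, ilo, lb, lm, li, ld


def score_sequences(
    hmm: ProfileHMM, seqs: list[str], mode: str = "viterbi"
) -> np.ndarray:
    """Bitscore of every sequence against the profile (batched DP)."""
    if mode not in ("viterbi", "forward"):
        raise ValueError(f"unknown mode {mode!r}")
    if not seqs:
        return np.zeros(0)
    if any(len(s) < 1 for s in seqs):
        raise ValueError("sequence shorter than 1 residue")
    enc = [_encode(s) for s in seqs]
    lengths = np.array([len(e) for e in enc])
    Lmax = int(lengths.max())
    B = len(enc)
    X = np.full((B, Lmax), _PAD, dtype=np.int64)
    for i, e in enumerate(enc):
        X[i, : len(e)] = e

    K = hmm.n_match
    mlo, ilo, lb, lm, li, ld = _log_tables(hmm)
    if mode == "viterbi":
        def comb2(a, b):
            return np.maximum(a, b)
    else:
        def comb2(a, b):
            return np.logaddexp2(a, b)

    def comb(*args):
        out = args[0]
        for a in args[1:]:
            out = comb2(out, a)
        return out

    # entry-style log transitions, indexed by target state m
    in_m_m = np.full(K, _NEG); in_m_i = np.full(K, _NEG); in_m_d = np.full(K, _NEG)
    in_d_m = np.full(K, _NEG); in_d_i = np.full(K, _NEG); in_d_d = np.full(K, _NEG)
    in_i_m = np.full(K, _NEG); in_i_i = np.full(K, _NEG); in_i_d = np.full(K, _NEG)
    if K > 1:
        in_m_m[1:] = lm[:, 0]; in_m_i[1:] = li[:, 0]; in_m_d[1:] = ld[:, 0]
        in_d_m[1:] = lm[:, 2]; in_d_i[1:] = li[:, 2]; in_d_d[1:] = ld[:, 2]
        in_i_m[: K - 1] = lm[:, 1]; in_i_i[: K - 1] = li[:, 1]; in_i_d[: K - 1] = ld[:, 1]

    neg = np.full((B, K), _NEG)
    Mp, Ip = neg.copy(), neg.copy()
    # column j = 0: delete-only chains from Begin
    Dp = neg.copy()
    Dp[:, 0] = lb[1]
    for m in range(1, K):
        Dp[:, m] = Dp[:, m - 1] + in_d_d[m]
    result = comb(np.full(B, _NEG), Dp[:, K - 1])

    shift = lambda A: np.concatenate([np.full((B, 1), _NEG), A[:, :-1]], axis=1)
    for j in range(1, Lmax + 1):
        xj = X[:, j - 1]
        e = mlo[:, xj].T                     # (B, K)
        Mn = e + comb(shift(Mp) + in_m_m, shift(Ip) + in_m_i, shift(Dp) + in_m_d)
        Mn[:, 0] = e[:, 0] + lb[0]           # free local start before position j
        In = ilo[xj][:, None] + comb(Mp + in_i_m, Ip + in_i_i, Dp + in_i_d)
        Dn = neg.copy()
        restart = np.where(j <= lengths, lb[1], _NEG)
        Dn[:, 0] = restart
        for m in range(1, K):
            Dn[:, m] = comb(
                Mn[:, m - 1] + in_d_m[m],
                In[:, m - 1] + in_d_i[m],
                Dn[:, m - 1] + in_d_d[m],
            )
        result = comb(result, Mn[:, K - 1], Dn[:, K - 1])
        Mp, Ip, Dp = Mn, In, Dn
    return result


def score_sequence(hmm: ProfileHMM, seq: str, mode: str = "viterbi") -> float:
    """Bitscore of one sequence (Viterbi by default, forward optional)."""
    return float(score_sequences(hmm, [seq], mode=mode)[0])


# ---------------------------------------------------------------------------
# calibration / E-values


def calibrate(
    hmm: ProfileHMM,
    background: np.ndarray | None = None,
    n_null: int = 1000,
    null_len: int = 400,
    seed: int | np.random.Generator | None = None,
) -> ProfileHMM:
    """Fit a Gumbel law to Viterbi max-scores over i.i.d. null sequences.

    Returns a copy of the profile carrying the calibration; the empirical
    null sample is stored alongside the fit as a fallback/diagnostic.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100")
    bg = hmm.background if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(20, size=(n_null, null_len), p=bg)
    seqs = ["".join(AMINO_ACIDS[i] for i in row) for row in draws]
    scores = score_sequences(hmm, seqs, mode="viterbi")
    if float(np.std(scores)) < 1e-12:
        raise ValueError("degenerate null-score variance; cannot calibrate")
    loc, scale = gumbel_r.fit(scores)
    return dataclasses.replace(
        hmm, calibration=Calibration(float(loc), float(scale), scores)
    )


def evalue(hmm: ProfileHMM, bitscore: float, db_size: int) -> float:
    """Expected number of >= bitscore hits among ``db_size`` unrelated sequences."""
    if hmm.calibration is None:
        raise ValueError("profile is not calibrated; run calibrate() first")
    c = hmm.calibration
    return float(db_size * gumbel_r.sf(bitscore, loc=c.loc, scale=c.scale))
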