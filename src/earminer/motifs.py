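"""Literal EAR motif detection and classification.

The EAR (ERF-associated Amphiphilic Repression) motif is a short linear
repression signal in plant proteins with two recognised pattern classes:

* ``LxLxL`` — leucines at offsets 0, 2 and 4 of a 5-residue window;
* ``DLNP``  — D, L, N at offsets 0-2 and a proline at the last position,
  with one or two free residues in between (DLNxP, 5-mer; DLNxxP, 6-mer).

Free (``x``) positions match any residue, including the degenerate codes
X/B/Z/U.  Fixed positions require the exact residue, so a degenerate code
never satisfies a fixed position — conservative on low-quality sequence.

Positional classes follow the N-terminal / Middle / C-terminal split used
when grouping motif occurrences: a hit is N-terminal when it ends within
the first ``n_frac`` of the protein, C-terminal when it starts within the
last ``c_frac``, and Middle otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import EXTENDED_AA

__all__ = [
    "EarPattern",
    "EarMotifHit",
    "LXLXL",
    "DLNP",
    "DEFAULT_PATTERNS",
    "find_ear_motifs",
    "classify_location",
    "classify_pattern_membership",
]


@dataclass(frozen=True)
class EarPattern:
    """An EAR pattern class: fixed residues at offsets, per allowed length."""

    name: str
    # length -> {offset: required residue}
    fixed: dict[int, dict[int, str]]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.fixed))

    def matches(self, window: str) -> bool:
        """Does ``window`` (one of the allowed lengths) satisfy the pattern?"""
        constraints = self.fixed.get(len(window))
        if constraints is None:
            return False
        return all(window[off] == res for off, res in constraints.items())


LXLXL = EarPattern("LxLxL", {5: {0: "L", 2: "L", 4: "L"}})
DLNP = EarPattern(
    "DLNP",
    {
        5: {0: "D", 1: "L", 2: "N", 4: "P"},
        6: {0: "D", 1: "L", 2: "N", 5: "P"},
    },
)
DEFAULT_PATTERNS: tuple[EarPattern, ...] = (LXLXL, DLNP)


@dataclass(frozen=True)
class EarMotifHit:
    """A matched EAR pattern: 1-based inclusive protein coordinates."""

    protein_id: str
    pattern: str
    start: int
    end: int
    matched: str
    location: str = ""  # N | M | C, filled by classify_location

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_ear_motifs(
    seq: str,
    patterns: tuple[EarPattern, ...] = DEFAULT_PATTERNS,
    protein_id: str = "",
) -> list[EarMotifHit]:
    """Report every EAR pattern match in ``seq``, overlaps included.

    Both the 5-mer and 6-mer DLNP forms are reported when they co-occur at
    the same aspartate.  Hits are sorted by start position, then match
    length, then pattern name — deterministic for any input.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = [(i, c) for i, c in enumerate(seq) if c not in EXTENDED_AA]
    if bad:
        i, c = bad[0]
        raise ValueError(f"invalid residue {c!r} at position {i + 1}")
    hits: list[EarMotifHit] = []
    n = len(seq)
    for pat in patterns:
        for length in pat.lengths:
            for start in range(n - length + 1):
                window = seq[start : start + length]
                if pat.matches(window):
                    hits.append(
                        EarMotifHit(protein_id, pat.name, start + 1, start + length, window)
                    )
    hits.sort(key=lambda h: (h.start, h.length, h.pattern))
    return hits


def classify_location(
    hit: EarMotifHit, seq_len: int, n_frac: float = 0.25, c_frac: float = 0.25
) -> str:
    """Classify a hit as N-terminal, Middle or C-terminal within its protein.

    N wins over C when both conditions hold (very short proteins).
    """
    if not (0 < n_frac and 0 < c_frac and n_frac + c_frac <= 1):
        raise ValueError("require 0 < n_frac, c_frac and n_frac + c_frac <= 1")
    if not (1 <= hit.start <= hit.end <= seq_len):
        raise ValueError(
            f"hit {hit.start}..{hit.end} outside sequence of length {seq_len}"
        )
    if hit.end <= math.ceil(n_frac * seq_len):
        return "N"
    if hit.start >= seq_len - math.ceil(c_frac * seq_len) + 1:
        return "C"
    return "M"


def locate_hits(
    hits: list[EarMotifHit], seq_len: int, n_frac: float = 0.25, c_frac: float = 0.25
) -> list[EarMotifHit]:
    """Return hits with their ``location`` field filled in."""
    return [
        EarMotifHit(
            h.protein_id, h.pattern, h.start, h.end, h.matched,
            classify_location(h, seq_len, n_frac, c_frac),
        )
        for h in hits
    ]


def classify_pattern_membership(hits: list[EarMotifHit]) -> str:
    """Protein-level class from the union of its hit patterns.

    Returns one of ``LxLxL-only``, ``DLNP-only``, ``both``, ``none``.
    """
    names = {h.pattern for h in hits}
    if names == {"LxLxL"}:
        return "LxLxL-only"
    if names == {"DLNP"}:
        return "DLNP-only"
    if names >= {"LxLxL", "DLNP"}:
        return "both"
    return "none"
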