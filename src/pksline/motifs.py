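"""Degenerate catalytic-motif patterns and the scanner that locates them.

Pattern grammar: fixed residue letters, ``x`` wildcards, ``/``-separated
alternatives at a single position (``L/IG..``), and ``(x)`` for an optional
wildcard position (tried both present and absent). Matching tolerates up to
``max_mismatch`` substitutions at fixed-letter positions; wildcards match
anything.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple, Optional


class MotifMatch(NamedTuple):
    position: int       # 0-based start in the scanned sequence
    mismatches: int
    length: int         # length of the expanded match
    token_positions: tuple  # sequence offset of each pattern token (None if optional absent)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate protein motif with a mismatch budget.

    ``diagnostic_index`` is the token index (in the pattern, counting
    alternatives and optionals as one token) of the catalytic residue.
    """

    name: str
    pattern: str
    max_mismatch: int = 0
    diagnostic_index: Optional[int] = None
    tokens: tuple = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "tokens", _parse_pattern(self.pattern))
        if len(self.tokens) < 3:
            raise ValueError(f"pattern {self.pattern!r} too short (need >= 3 positions)")
        n_fixed = sum(1 for allowed, _ in self.tokens if allowed is not None)
        if self.max_mismatch >= n_fixed:
            raise ValueError(
                f"max_mismatch={self.max_mismatch} must be < {n_fixed} fixed letters"
            )


def _parse_pattern(pattern: str) -> tuple:
    """Tokenize to ((allowed_set | None), optional) pairs; None = wildcard."""
    tokens = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.index(")", i)
            inner = pattern[i + 1:j]
            allowed = None if inner == "x" else frozenset(inner)
            tokens.append((allowed, True))
            i = j + 1
        elif ch == "x":
            tokens.append((None, False))
            i += 1
        else:
            letters = {ch}
            i += 1
            while i + 1 < len(pattern) and pattern[i] == "/":
                letters.add(pattern[i + 1])
                i += 2
            tokens.append((frozenset(letters), False))
    return tuple(tokens)


def _expansions(tokens):
    """Yield concrete token tuples for every optional present/absent choice."""
    optional_idx = [k for k, (_, opt) in enumerate(tokens) if opt]
    for keep in itertools.product((True, False), repeat=len(optional_idx)):
        kept = dict(zip(optional_idx, keep))
        concrete = []
        token_map = []  # expanded offset per original token index, None if dropped
        for k, (allowed, opt) in enumerate(tokens):
            if opt and not kept[k]:
                token_map.append(None)
                continue
            token_map.append(len(concrete))
            concrete.append(allowed)
        yield tuple(concrete), tuple(token_map)


def scan_motif_detailed(sequence: str, motif: MotifPattern) -> list[MotifMatch]:
    """All matches of ``motif`` in ``sequence`` with full position bookkeeping."""
    out = []
    seen = set()
    for concrete, token_map in _expansions(motif.tokens):
        L = len(concrete)
        if L == 0 or L > len(sequence):
            continue
        for start in range(len(sequence) - L + 1):
            mm = 0
            for off, allowed in enumerate(concrete):
                if allowed is not None and sequence[start + off] not in allowed:
                    mm += 1
                    if mm > motif.max_mismatch:
                        break
            else:
                key = (start, mm, L)
                if key not in seen:
                    seen.add(key)
                    out.append(
                        MotifMatch(
                            position=start,
                            mismatches=mm,
                            length=L,
                            token_positions=tuple(
                                None if t is None else start + t for t in token_map
                            ),
                        )
                    )
    out.sort(key=lambda m: (m.position, m.mismatches, -m.length))
    return out


def scan_motif(sequence: str, motif: MotifPattern) -> list[tuple[int, int]]:
    """All (position, mismatches) where the motif matches within budget.

    Results are sorted by position, then mismatch count; a position matched
    by several optional-expansion variants is reported once per distinct
    mismatch count.
    """
    pairs = []
    seen = set()
    for m in scan_motif_detailed(sequence, motif):
        key = (m.position, m.mismatches)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    return pairs


# Validation motifs per domain type. The KS active-site pattern leaves the
# catalytic position a wildcard so that both the Cys (extension KS) and the
# Gln of a loading-module KSq match; the variant call reads the residue.
MOTIFS: dict[str, tuple[MotifPattern, ...]] = {
    "KS": (
        MotifPattern("KS_active_site", "TAxSSGL", 0, diagnostic_index=2),
        MotifPattern("KS_his_box1", "HGTGT", 0, diagnostic_index=0),
        MotifPattern("KS_his_box2", "KSxxGH", 0, diagnostic_index=5),
    ),
    "AT": (MotifPattern("AT_active_site", "GHSxG", 0, diagnostic_index=2),),
    "DH": (MotifPattern("DH_consensus", "HxxxGxxxP", 0, diagnostic_index=0),),
    "ER": (MotifPattern("ER_NADPH", "LxHxxxGGVGxxAxxxA", 1, diagnostic_index=0),),
    "KR": (MotifPattern("KR_NADP", "GGxGxxG", 0, diagnostic_index=0),),
    "ACP": (MotifPattern("ACP_ppant", "L/IG(x)DS", 0, diagnostic_index=4),),
    "TE": (MotifPattern("TE_active_site", "GxSxG", 0, diagnostic_index=2),),
}
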