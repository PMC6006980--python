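"""Functional subtyping of PKS domains.

AT (acyltransferase) domains are assigned an extender-unit specificity —
malonyl-CoA (no alpha-methyl branch) vs methylmalonyl-CoA (alpha-methyl
branch) — by two routes: reading specificity-determining residues off an
annotated reference alignment, and phylogenetic placement among reference
ATs of known specificity. KR (ketoreductase) domains are stereo-typed:
B-type (LDD signature, or its LED variant) yields R-configured alcohols,
A-type (diagnostic Trp) yields S-configured alcohols; neither signature
leaves the product configuration unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import pairwise_align, ScoreParams
from .phylo import at_alignment_and_tree
from .resources import ReferencePanel, get_site, load_at_panel, load_scaffolds

log = logging.getLogger(__name__)

# KR signature -> (stereo type, predicted hydroxyl configuration)
_KR_TABLE = {
    "LDD": ("B", "R"),
    "LED": ("B", "R"),
    "TRP": ("A", "S"),
    "none": ("unassigned", "unknown"),
}

_MIN_KR_REGION = 30


@dataclass(frozen=True)
class ATCall:
    """Extender-unit specificity call for one AT domain."""

    specificity: str  # malonyl | methylmalonyl | unknown
    residue_evidence: tuple = ()  # (anchor column, observed, expected-per-class)
    tree_support: Optional[float] = None
    confidence: float = 0.0
    method: str = "residues"
    discordant: bool = False
    phylo_specificity: Optional[str] = None


@dataclass(frozen=True)
class KRCall:
    """Stereo-type call for one KR domain.

    The invariant table is: LDD/LED => B => R; TRP => A => S;
    none => unassigned => unknown.
    """

    stereo_type: str
    signature: str
    predicted_oh_config: str
    conflict: bool = False
    reason: Optional[str] = None

    def __post_init__(self):
        expected = _KR_TABLE[self.signature]
        if (self.stereo_type, self.predicted_oh_config) != expected:
            raise ValueError(
                f"inconsistent KR call: {self.signature} implies {expected}"
            )


def _map_anchor_columns(query: str, anchor: str, columns: Sequence[int],
                        score_params: Optional[ScoreParams] = None) -> dict:
    """Residue of ``query`` aligned to each anchor column (None if gapped)."""
    aq, aa, _ = pairwise_align(query, anchor, score_params)
    # walk the alignment tracking anchor coordinates
    out = {}
    wanted = set(columns)
    qpos = apos = 0
    for cq, ca in zip(aq, aa):
        if ca != "-":
            if apos in wanted:
                out[apos] = cq if cq != "-" else None
            apos += 1
        if cq != "-":
            qpos += 1
    for col in columns:
        out.setdefault(col, None)
    return out


def classify_at_residues(at_region_sequence: str,
                         reference_panel: Optional[ReferencePanel] = None,
                         score_params: Optional[ScoreParams] = None) -> ATCall:
    """Specificity by majority vote over the diagnostic alignment columns.

    Confidence is the fraction of readable columns agreeing with the
    winning class. More than half the columns falling in gaps, or a tied
    vote, yields ``unknown``.
    """
    panel = reference_panel or load_at_panel()
    expected = panel.expected()
    observed = _map_anchor_columns(
        at_region_sequence, panel.anchor, panel.columns, score_params
    )
    readable = {c: r for c, r in observed.items() if r is not None}
    evidence = tuple(
        (c, observed[c], tuple((cls, expected[cls][c]) for cls in sorted(expected)))
        for c in panel.columns
    )
    if len(readable) < len(panel.columns) / 2.0 or not readable:
        return ATCall("unknown", evidence, confidence=0.0, method="residues")
    votes = {
        cls: sum(1 for c, r in readable.items() if expected[cls][c] == r)
        for cls in expected
    }
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return ATCall("unknown", evidence, confidence=0.0, method="residues")
    winner, nagree = ranked[0]
    return ATCall(
        winner, evidence, confidence=nagree / len(readable), method="residues"
    )


def classify_at_phylo(at_region_sequence: str,
                      reference_panel: Optional[ReferencePanel] = None,
                      n_bootstrap: int = 100, seed: int = 0,
                      score_params: Optional[ScoreParams] = None) -> ATCall:
    """Specificity by neighbor-joining placement among the reference panel.

    The call is the class of the smallest monophyletic reference clade
    containing the query; its support is the bootstrap percentage of the
    clade's subtending branch. A query basal to every class is unknown.
    """
    panel = reference_panel or load_at_panel()
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    query_id = "__query__"
    records = [(query_id, at_region_sequence)] + [
        (mid, seq) for mid, _, seq in panel.members
    ]
    _, tree = at_alignment_and_tree(records, n_bootstrap, seed, score_params)
    for side, support in tree.clades_containing(query_id):
        others = side - {query_id}
        classes = {panel.class_of(m) for m in others}
        if len(classes) == 1:
            return ATCall(
                classes.pop(),
                tree_support=support,
                confidence=(support or 0.0) / 100.0,
                method="phylogeny",
            )
    return ATCall("unknown", method="phylogeny")


def classify_at(at_region_sequence: str,
                reference_panel: Optional[ReferencePanel] = None,
                precedence: str = "residues",
                n_bootstrap: int = 100, seed: int = 0,
                score_params: Optional[ScoreParams] = None) -> ATCall:
    """Combined residue + phylogeny call.

    When the two routes disagree the configured precedence (default:
    residues) decides the specificity; both evidences are retained and the
    call is flagged discordant.
    """
    if precedence not in ("residues", "phylogeny"):
        raise ValueError(f"unknown precedence {precedence!r}")
    res = classify_at_residues(at_region_sequence, reference_panel, score_params)
    phy = classify_at_phylo(
        at_region_sequence, reference_panel, n_bootstrap, seed, score_params
    )
    discordant = (
        res.specificity != "unknown"
        and phy.specificity != "unknown"
        and res.specificity != phy.specificity
    )
    if res.specificity == "unknown":
        winner = phy.specificity
    elif phy.specificity == "unknown":
        winner = res.specificity
    else:
        winner = res.specificity if precedence == "residues" else phy.specificity
    return ATCall(
        winner,
        residue_evidence=res.residue_evidence,
        tree_support=phy.tree_support,
        confidence=res.confidence if precedence == "residues" else phy.confidence,
        method="combined",
        discordant=discordant,
        phylo_specificity=phy.specificity,
    )


def classify_kr(kr_region_sequence: str,
                reference_alignment: Optional[str] = None,
                score_params: Optional[ScoreParams] = None) -> KRCall:
    """Stereo-type a KR region from its diagnostic signatures.

    The B-type window is inspected for LDD (or the LED variant) and the
    A-type diagnostic position for Trp, both located by alignment to the
    packaged KR exemplar. Both signatures present is a conflict and yields
    unassigned.
    """
    anchor = reference_alignment or load_scaffolds()["KR"]
    if len(kr_region_sequence) < _MIN_KR_REGION:
        return KRCall("unassigned", "none", "unknown", reason="region_too_short")
    b_site = get_site("KR", "b_window")
    a_site = get_site("KR", "a_trp")
    cols = list(range(*b_site.span)) + [a_site.offset]
    observed = _map_anchor_columns(kr_region_sequence, anchor, cols, score_params)
    b_res = "".join(observed[c] or "-" for c in range(*b_site.span))
    has_b = b_res in ("LDD", "LED")
    has_a = observed[a_site.offset] == "W"
    if has_b and has_a:
        return KRCall("unassigned", "none", "unknown", conflict=True,
                      reason="conflicting_signatures")
    if has_b:
        sig = b_res
        return KRCall("B", sig, "R")
    if has_a:
        return KRCall("A", "TRP", "S")
    return KRCall("unassigned", "none", "unknown")


def call_dh_er_functionality(module_domains) -> tuple[bool, bool]:
    """(dh_functional, er_present) for one module's domain hits.

    A DH counts as functional iff a DH hit exists with its consensus motif
    intact (the hit is active); ER presence requires an active ER hit.
    """
    dh_functional = any(
        h.domain_type == "DH" and h.active for h in module_domains
    )
    er_present = any(
        h.domain_type == "ER" and h.active for h in module_domains
    )
    return dh_functional, er_present
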