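"""Locate PKS domains in a protein and validate their active sites.

Localization anchors candidate windows by local alignment of one exemplar
sequence per domain type (BLOSUM62, affine gaps) against the protein;
windows scoring above a configurable fraction of the exemplar self-score
are kept, made non-overlapping greedily by descending score, and then
validated by motif scanning and catalytic-residue inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .motifs import MOTIFS, MotifPattern, scan_motif_detailed
from .resources import load_scaffolds, load_sites
from .seq_io import ProteinRecord

log = logging.getLogger(__name__)

DEFAULT_WINDOW_THRESHOLD = 0.35
_MOTIF_SCAN_MARGIN = 8  # residues of slack around the aligned window


@dataclass(frozen=True)
class DomainHit:
    """A located PKS domain with motif evidence and active-site status.

    ``interval`` is 0-based half-open on the protein. ``sites`` maps
    exemplar site names to absolute protein positions (catalytic residues
    located through the anchoring alignment). An inactive hit always
    carries at least one reason.
    """

    domain_type: str
    interval: tuple[int, int]
    protein_id: str
    motif_matches: tuple = ()  # (motif name, absolute position, mismatches)
    active: bool = True
    reasons: tuple = ()
    score: float = 0.0
    sites: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.interval[0] < 0 or self.interval[1] <= self.interval[0]:
            raise ValueError(f"bad interval {self.interval}")
        if not self.active and not self.reasons:
            raise ValueError("inactive hit must record a reason")


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = mode
    return aligner


def _self_score(seq: str, aligner) -> float:
    m = aligner.substitution_matrix
    return float(sum(m[c, c] for c in seq))


def _best_local(aligner, protein: str, exemplar: str):
    """Best local alignment of exemplar in protein, or None below zero."""
    if len(protein) < 10:
        return None
    alns = aligner.align(protein, exemplar)
    if len(alns) == 0 or alns.score <= 0:
        return None
    return alns[0]


def _find_windows(aligner, protein: str, exemplar: str, threshold: float,
                  region=(0, None)) -> list:
    """Divide-and-conquer search for all above-threshold local hits."""
    start, end = region[0], region[1] if region[1] is not None else len(protein)
    sub = protein[start:end]
    aln = _best_local(aligner, sub, exemplar)
    if aln is None or aln.score < threshold:
        return []
    tblocks, qblocks = aln.aligned
    pstart = int(tblocks[0][0]) + start
    pend = int(tblocks[-1][1]) + start
    # exemplar offset -> absolute protein position, through aligned blocks
    sitemap = {}
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(qe - qs):
            sitemap[qs + k] = ts + k + start
    hit = (float(aln.score), pstart, pend, sitemap)
    left = _find_windows(aligner, protein, exemplar, threshold, (start, pstart))
    right = _find_windows(aligner, protein, exemplar, threshold, (pend, end))
    return left + [hit] + right


def _map_site(sitemap: dict, offset: int) -> Optional[int]:
    return sitemap.get(offset)


def _validate(domain_type: str, protein: str, pstart: int, pend: int,
              sitemap: dict, motif_mismatch: Optional[dict]) -> tuple:
    """Motif-scan the window; return (motif_matches, active, reasons)."""
    wstart = max(0, pstart - _MOTIF_SCAN_MARGIN)
    wend = min(len(protein), pend + _MOTIF_SCAN_MARGIN)
    window = protein[wstart:wend]
    matches = []
    missing = []
    for motif in MOTIFS[domain_type]:
        if motif_mismatch and motif.name in motif_mismatch:
            motif = MotifPattern(
                motif.name, motif.pattern, motif_mismatch[motif.name],
                motif.diagnostic_index,
            )
        found = scan_motif_detailed(window, motif)
        if found:
            best = min(found, key=lambda m: m.mismatches)
            matches.append((motif.name, best.position + wstart, best.mismatches))
        else:
            missing.append(f"missing_motif:{motif.name}")
    active = not missing
    reasons = list(missing)
    # catalytic-residue checks beyond motif presence
    sites = load_sites().get(domain_type, ())
    for site in sites:
        if site.kind != "diagnostic":
            continue
        pos = _map_site(sitemap, site.offset)
        if pos is None:
            continue
        res = protein[pos]
        if site.name in ("triad_H1", "triad_H2") and res != "H":
            active = False
            reasons.append(f"substituted:{site.name}={res}")
        if site.name == "acp_ser" and res != "S":
            active = False
            reasons.append("substituted:acp_ser")
        if site.name in ("triad_K", "triad_S", "triad_Y"):
            expected = {"triad_K": "K", "triad_S": "S", "triad_Y": "Y"}[site.name]
            if res != expected:
                active = False
                reasons.append(f"substituted:{site.name}={res}")
    return tuple(matches), active, tuple(reasons)


def detect_domains(record: ProteinRecord,
                   reference_profiles: Optional[dict] = None,
                   window_threshold: float = DEFAULT_WINDOW_THRESHOLD,
                   motif_mismatch: Optional[dict] = None) -> list[DomainHit]:
    """Locate and validate all PKS domains in one protein, ordered N->C.

    ``reference_profiles`` maps domain type to exemplar sequence (defaults
    to the packaged scaffolds). Hits are pairwise disjoint: overlaps are
    resolved greedily by descending alignment score, ties by leftmost
    start. KS windows whose catalytic position holds Gln are re-typed KSQ.
    """
    profiles = reference_profiles or load_scaffolds()
    aligner = _make_aligner("local")
    if len(record.sequence) < min(len(s) for s in profiles.values()):
        log.warning("protein %s shorter than smallest exemplar; no scan", record.id)
        return []

    candidates = []
    for dtype, exemplar in profiles.items():
        threshold = window_threshold * _self_score(exemplar, aligner)
        for score, pstart, pend, sitemap in _find_windows(
            aligner, record.sequence, exemplar, threshold
        ):
            candidates.append((score, pstart, pend, dtype, sitemap))

    # greedy non-overlap: best score first, leftmost on ties
    candidates.sort(key=lambda c: (-c[0], c[1]))
    chosen = []
    for cand in candidates:
        if all(cand[2] <= c[1] or cand[1] >= c[2] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[1])

    hits = []
    for score, pstart, pend, dtype, sitemap in chosen:
        motif_matches, active, reasons = _validate(
            dtype, record.sequence, pstart, pend, sitemap, motif_mismatch
        )
        abs_sites = {
            s.name: _map_site(sitemap, s.offset)
            for s in load_sites().get(dtype, ())
            if s.kind == "diagnostic" and _map_site(sitemap, s.offset) is not None
        }
        hit = DomainHit(
            domain_type=dtype,
            interval=(pstart, pend),
            protein_id=record.id,
            motif_matches=motif_matches,
            active=active,
            reasons=reasons,
            score=score,
            sites=abs_sites,
        )
        if dtype == "KS":
            hit = call_ks_variant(hit, record.sequence)
        hits.append(hit)
    return hits


def call_ks_variant(ks_hit: DomainHit, sequence: str) -> DomainHit:
    """Type a KS window as KS or KSQ from its catalytic-triad first residue.

    Gln at the catalytic position marks the decarboxylating loading-module
    variant (KSq); Cys marks a condensing KS; anything else leaves the hit
    typed KS but inactive with a recorded reason.
    """
    pos = ks_hit.sites.get("triad_C")
    if pos is None:
        return replace(
            ks_hit, domain_type="KS", active=False,
            reasons=ks_hit.reasons + ("triad_missing",),
        )
    res = sequence[pos]
    if res == "Q":
        return replace(ks_hit, domain_type="KSQ")
    if res == "C":
        return ks_hit
    return replace(
        ks_hit, domain_type="KS", active=False,
        reasons=ks_hit.reasons + (f"substituted:triad_C={res}",),
    )


def call_acp(acp_hit: DomainHit, sequence: str) -> bool:
    """True iff the phosphopantetheinylation Ser of L/IG(x)DS is present."""
    pos = acp_hit.sites.get("acp_ser")
    if pos is not None:
        return sequence[pos] == "S"
    # fall back to the motif match: Ser is the final motif position
    for name, mpos, _ in acp_hit.motif_matches:
        if name == "ACP_ppant":
            for m in scan_motif_detailed(sequence[mpos:mpos + 6], MOTIFS["ACP"][0]):
                ser = m.token_positions[-1]
                return ser is not None and sequence[mpos + ser] == "S"
    return False
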