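"""End-to-end glue: proteins in, annotated assembly line out."""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional, Sequence

from .assembly import AssemblyLine, build_assembly_line
from .config import RunConfig
from .domain_classify import (
    classify_at,
    classify_at_residues,
    classify_kr,
    call_dh_er_functionality,
)
from .domain_scan import detect_domains
from .seq_io import ProteinRecord

log = logging.getLogger(__name__)


def scan_records(records: Sequence[ProteinRecord],
                 config: Optional[RunConfig] = None) -> dict:
    """Domain hits per protein id."""
    config = config or RunConfig()
    return {
        rec.id: detect_domains(
            rec,
            window_threshold=config.window_threshold,
            motif_mismatch=config.motif_mismatch or None,
        )
        for rec in records
    }


def annotate_assembly(line: AssemblyLine, records: Sequence[ProteinRecord],
                      config: Optional[RunConfig] = None) -> AssemblyLine:
    """Fill AT/KR calls and DH/ER flags on a structurally built line."""
    config = config or RunConfig()
    seqs = {rec.id: rec.sequence for rec in records}
    for k, module in enumerate(line.modules):
        at_hit = next((h for h in module.domains if h.domain_type == "AT"), None)
        kr_hit = next((h for h in module.domains if h.domain_type == "KR"), None)
        at_call = None
        if at_hit is not None:
            region = seqs[at_hit.protein_id][slice(*at_hit.interval)]
            if config.at_method == "combined":
                at_call = classify_at(
                    region,
                    precedence=config.at_precedence,
                    n_bootstrap=config.n_bootstrap,
                    seed=config.seed,
                )
            else:
                at_call = classify_at_residues(region)
        kr_call = None
        if kr_hit is not None:
            region = seqs[kr_hit.protein_id][slice(*kr_hit.interval)]
            kr_call = classify_kr(region)
        dh_functional, er_present = call_dh_er_functionality(module.domains)
        line.modules[k] = replace(
            module,
            at_call=at_call,
            kr_call=kr_call,
            dh_functional=dh_functional,
            er_present=er_present,
        )
    return line


def analyze_records(records: Sequence[ProteinRecord],
                    orf_order: Optional[Sequence[str]] = None,
                    config: Optional[RunConfig] = None) -> AssemblyLine:
    """Scan, partition into modules, and classify, in one call."""
    config = config or RunConfig()
    order = list(orf_order) if orf_order else [rec.id for rec in records]
    hits = scan_records(records, config)
    line = build_assembly_line(hits, order)
    return annotate_assembly(line, records, config)
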