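"""Reading/writing of the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention happens only at the GFF3 boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

REPORT_FORMATS = ("tsv", "json", "gff3")


class SequenceFormatError(ValueError):
    """Raised for malformed or empty sequence input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    ``sequence`` is uppercase over the 20 standard residues plus X;
    ``source`` optionally names the ORF or cluster the protein came from.
    """

    id: str
    sequence: str
    source: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in VALID_RESIDUES:
                raise SequenceFormatError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ObservedChemotype:
    """Per-carbon description of an observed polyketide backbone.

    Carbons are numbered with C1 at the thioesterase-bound carbonyl.
    ``hydroxyls`` holds (carbon, configuration) with configuration one of
    "R", "S", "unknown"; ``double_bonds`` holds (delta, geometry) where a
    delta label n denotes the bond between carbons n and n+1.
    """

    carbon_count: int
    hydroxyls: tuple = ()
    double_bonds: tuple = ()
    methyl_branches: frozenset = frozenset()
    starter_unit: str = "acetate"

    def __post_init__(self):
        object.__setattr__(self, "hydroxyls", tuple(self.hydroxyls))
        object.__setattr__(self, "double_bonds", tuple(self.double_bonds))
        object.__setattr__(self, "methyl_branches", frozenset(self.methyl_branches))
        if self.starter_unit not in ("acetate", "propionate"):
            raise ValueError(f"unknown starter unit {self.starter_unit!r}")
        occupied = set()
        for c, conf in self.hydroxyls:
            if not 1 <= c <= self.carbon_count:
                raise ValueError(f"hydroxyl carbon {c} outside backbone")
            if conf not in ("R", "S", "unknown"):
                raise ValueError(f"bad hydroxyl configuration {conf!r}")
            if c in occupied:
                raise ValueError(f"carbon {c} assigned more than one state")
            occupied.add(c)
        for d, geom in self.double_bonds:
            if not 1 <= d < self.carbon_count:
                raise ValueError(f"double bond Δ{d} outside backbone")
            if geom not in ("E", "Z"):
                raise ValueError(f"bad double-bond geometry {geom!r}")
            # the bond consumes the beta-carbon state at d+1
            if d + 1 in occupied:
                raise ValueError(f"carbon {d + 1} assigned more than one state")
            occupied.add(d + 1)
        for c in self.methyl_branches:
            if not 1 <= c <= self.carbon_count:
                raise ValueError(f"methyl branch carbon {c} outside backbone")

    @property
    def hydroxyl_map(self) -> dict:
        return dict(self.hydroxyls)

    @property
    def double_bond_set(self) -> frozenset:
        return frozenset(d for d, _ in self.double_bonds)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into ProteinRecords (order preserved).

    Lowercase residues are uppercased; wrapped and unwrapped line layouts
    are equivalent. An empty file raises SequenceFormatError.
    """
    path = Path(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise SequenceFormatError(f"no records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_genbank_cds(path) -> list[ProteinRecord]:
    """Extract one ProteinRecord per translated CDS from a GenBank flat file.

    CDS features without a /translation qualifier are skipped with a warning.
    """
    path = Path(path)
    records = []
    for gb in SeqIO.parse(str(path), "genbank"):
        n = 0
        for feat in gb.features:
            if feat.type != "CDS":
                continue
            n += 1
            translations = feat.qualifiers.get("translation")
            if not translations:
                label = feat.qualifiers.get("locus_tag", [f"CDS_{n}"])[0]
                log.warning("CDS %s in %s lacks /translation; skipped", label, gb.id)
                continue
            name = feat.qualifiers.get(
                "locus_tag", feat.qualifiers.get("gene", [f"{gb.id}_CDS{n}"])
            )[0]
            records.append(
                ProteinRecord(
                    id=name,
                    sequence=translations[0].upper(),
                    source=gb.id,
                )
            )
    return records


def _hit_rows(hits) -> list[dict]:
    rows = []
    for h in hits:
        rows.append(
            {
                "protein_id": h.protein_id,
                "domain_type": h.domain_type,
                "start": h.interval[0],
                "end": h.interval[1],
                "active": h.active,
                "reasons": ";".join(h.reasons) if h.reasons else "",
                "motifs": ";".join(
                    f"{name}@{pos}/{mm}" for name, pos, mm in h.motif_matches
                ),
            }
        )
    return rows


def write_report(hits, path, format: str = "tsv", header_meta: Optional[dict] = None) -> None:
    """Write domain hits to TSV, JSON or GFF3.

    TSV and JSON keep the internal 0-based half-open coordinates (stated in
    a header comment / metadata field); GFF3 converts to 1-based inclusive.
    """
    if format not in REPORT_FORMATS:
        raise ValueError(
            f"unknown report format {format!r}; supported: {', '.join(REPORT_FORMATS)}"
        )
    hits = list(hits)
    meta = dict(header_meta or {})
    with open(path, "w") as fh:
        if format == "tsv":
            fh.write("# coordinates: 0-based half-open\n")
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            cols = ["protein_id", "domain_type", "start", "end", "active", "reasons", "motifs"]
            fh.write("\t".join(cols) + "\n")
            for row in _hit_rows(hits):
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        elif format == "json":
            payload = {
                "coordinates": "0-based half-open",
                "meta": meta,
                "hits": _hit_rows(hits),
            }
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        else:  # gff3
            fh.write("##gff-version 3\n")
            for k, v in meta.items():
                fh.write(f"#!{k} {v}\n")
            for h in hits:
                start0, end0 = h.interval
                attrs = f"ID={h.protein_id}.{h.domain_type}.{start0};domain_type={h.domain_type};active={str(h.active).lower()}"
                fh.write(
                    "\t".join(
                        [
                            h.protein_id,
                            "pksline",
                            "polypeptide_domain",
                            str(start0 + 1),  # GFF3 is 1-based inclusive
                            str(end0),
                            ".",
                            ".",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
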