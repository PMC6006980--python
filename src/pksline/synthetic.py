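"""Synthetic PKS clusters with known ground truth.

Proteins are concatenations of the packaged per-domain exemplar scaffolds
joined by neutral linkers, with class-determining residues injected
(loading-module KSq Gln, AT specificity block, KR LDD/LED/Trp signatures)
and optional seeded per-residue substitution noise that avoids the
annotated diagnostic and motif sites unless corruption is requested.

``make_rdm_fixture`` encodes the reedsmycin (RDM) assembly line of
Streptomyces youssoufiensis OUC6819: seventeen modules (one loading +
sixteen extension) across the four PKS ORFs RdmG/H/I/J, with the AT
specificities, KR stereo-types, DH/ER complements and terminal TE of that
pathway; ``make_observed_rdma`` encodes the corresponding observed RDM A
backbone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .assembly import AssemblyLine, ChemotypeTable, ModuleModel, predict_chemotype
from .domain_classify import ATCall, KRCall
from .resources import AT_CLASS_RESIDUES, get_site, load_scaffolds, load_sites
from .seq_io import ObservedChemotype, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
LINKER = "TSAAPEPTSAAPEPT"  # neutral inter-domain linker (no motif residues)


@dataclass(frozen=True)
class ModuleSpec:
    """Ground-truth labels for one module of a synthetic assembly line."""

    at: str = "malonyl"  # malonyl | methylmalonyl
    kr: Optional[str] = None  # None | A | B | unassigned
    kr_signature: Optional[str] = None  # LDD | LED for B-type (default LDD)
    dh: bool = False
    er: bool = False

    def __post_init__(self):
        if self.at not in AT_CLASS_RESIDUES:
            raise ValueError(f"unknown AT specificity {self.at!r}")
        if self.kr not in (None, "A", "B", "unassigned"):
            raise ValueError(f"unknown KR type {self.kr!r}")
        if self.kr == "B" and self.kr_signature is None:
            object.__setattr__(self, "kr_signature", "LDD")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A synthetic multi-ORF PKS architecture with generation parameters."""

    modules: tuple  # of ModuleSpec; index 0 is the loading module
    orf_split: tuple  # modules per ORF, contiguous partition
    orf_names: tuple
    noise_rate: float = 0.0
    seed: int = 0
    corrupt_diagnostics: tuple = ()  # (module_index, site_name) pairs
    at0_discordant: bool = False  # loading AT: phylogeny vs structure conflict

    def __post_init__(self):
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "orf_split", tuple(self.orf_split))
        object.__setattr__(self, "orf_names", tuple(self.orf_names))
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise rate must be in [0, 0.5)")
        if sum(self.orf_split) != len(self.modules):
            raise ValueError("orf_split must partition the modules")
        if len(self.orf_split) != len(self.orf_names):
            raise ValueError("one name per ORF required")

    def orf_of_module(self, index: int) -> str:
        acc = 0
        for name, count in zip(self.orf_names, self.orf_split):
            acc += count
            if index < acc:
                return name
        raise IndexError(index)


@dataclass
class SyntheticTruth:
    """Generated records plus every downstream expectation."""

    records: list
    spec: ArchitectureSpec
    expected_hits: dict  # orf name -> tuple of (domain_type, (start, end))
    assembly: AssemblyLine
    chemotype: ChemotypeTable


def make_rdm_fixture(noise_rate: float = 0.0, seed: int = 0) -> ArchitectureSpec:
    """The Rdm assembly-line architecture (RdmG/H/I/J, 17 modules).

    AT specificity is the sequence-level ground truth: methylmalonyl for
    modules 0-2 (the loading AT0 carries the phylogeny-vs-structure
    discordance), malonyl for 3-16. KR stereo-types: B for {1,2,3,12,13,14}
    (LDD) and {15,16} (LED), A for {6,7,9,10,11}, unassigned for {4,5,8}.
    Functional DH in {1,2,3,12,13,14,15,16}; the only ER is in module 1;
    the TE terminates the last ORF.
    """
    b_ldd = {1, 2, 3, 12, 13, 14}
    b_led = {15, 16}
    a_type = {6, 7, 9, 10, 11}
    unassigned = {4, 5, 8}
    dh = {1, 2, 3, 12, 13, 14, 15, 16}
    er = {1}
    mods = [ModuleSpec(at="methylmalonyl")]  # loading
    for m in range(1, 17):
        if m in b_ldd:
            kr, sig = "B", "LDD"
        elif m in b_led:
            kr, sig = "B", "LED"
        elif m in a_type:
            kr, sig = "A", None
        else:
            assert m in unassigned
            kr, sig = "unassigned", None
        mods.append(
            ModuleSpec(
                at="methylmalonyl" if m <= 2 else "malonyl",
                kr=kr, kr_signature=sig, dh=m in dh, er=m in er,
            )
        )
    return ArchitectureSpec(
        modules=tuple(mods),
        orf_split=(3, 4, 6, 4),
        orf_names=("RdmG", "RdmH", "RdmI", "RdmJ"),
        noise_rate=noise_rate,
        seed=seed,
        at0_discordant=True,
    )


def make_observed_rdma() -> ObservedChemotype:
    """The observed RDM A backbone chemotype.

    34 carbons; S-configured hydroxyls at C13/15/17/21/23; hydroxyls of
    undetermined configuration at C19/25/27/31; six E-double bonds at
    delta-2/4/6/8/10/28; methyl branches at C30/C32; acetate starter.
    """
    return ObservedChemotype(
        carbon_count=34,
        hydroxyls=tuple([(c, "S") for c in (13, 15, 17, 21, 23)]
                        + [(c, "unknown") for c in (19, 25, 27, 31)]),
        double_bonds=tuple((d, "E") for d in (2, 4, 6, 8, 10, 28)),
        methyl_branches=frozenset({30, 32}),
        starter_unit="acetate",
    )


def _module_domain_plan(index: int, spec: ModuleSpec) -> list[str]:
    if index == 0:
        return ["KSQ", "AT", "ACP"]
    plan = ["KS", "AT"]
    if spec.dh:
        plan.append("DH")
        if spec.er:
            plan.append("ER")
    if spec.kr is not None:
        plan.append("KR")
    plan.append("ACP")
    return plan


def _build_domain(dtype: str, spec: ModuleSpec) -> str:
    scaffolds = load_scaffolds()
    base = scaffolds["KS" if dtype == "KSQ" else dtype]
    seq = list(base)
    if dtype == "KSQ":
        seq[get_site("KS", "triad_C").offset] = "Q"
    elif dtype == "AT":
        # start from the class family consensus so phylogenetic placement
        # sees the same signal the reference panel encodes
        from .resources import load_at_panel
        seq = list(load_at_panel().class_consensus(spec.at))
        block = get_site("AT", "spec_block")
        seq[block.offset:block.offset + block.length] = AT_CLASS_RESIDUES[spec.at]
    elif dtype == "KR":
        if spec.kr == "B":
            w = get_site("KR", "b_window")
            seq[w.offset:w.offset + w.length] = spec.kr_signature
        elif spec.kr == "A":
            seq[get_site("KR", "a_trp").offset] = "W"
        # unassigned: leave the neutral scaffold (neither signature)
    return "".join(seq)


def assembly_from_architecture(arch: ArchitectureSpec) -> AssemblyLine:
    """The AssemblyLine an ideal annotation of the architecture yields."""
    modules = []
    for index, spec in enumerate(arch.modules):
        at_call = ATCall(
            specificity=spec.at,
            confidence=1.0,
            method="architecture",
            discordant=arch.at0_discordant and index == 0,
        )
        if spec.kr == "A":
            kr_call = KRCall("A", "TRP", "S")
        elif spec.kr == "B":
            kr_call = KRCall("B", spec.kr_signature, "R")
        elif spec.kr == "unassigned":
            kr_call = KRCall("unassigned", "none", "unknown")
        else:
            kr_call = None
        modules.append(
            ModuleModel(
                index=index,
                at_call=at_call,
                kr_call=kr_call,
                dh_functional=spec.dh and index > 0,
                er_present=spec.er and index > 0,
                source_orf=arch.orf_of_module(index),
            )
        )
    return AssemblyLine(modules=modules, te_present=True)


def generate_proteins(arch: ArchitectureSpec) -> SyntheticTruth:
    """Emit multi-ORF synthetic PKS proteins with full ground truth.

    Substitution noise is applied per residue at ``arch.noise_rate``
    outside the annotated sites; ``corrupt_diagnostics`` forces a
    substitution at a named site of a given module (or at ("TE", site) for
    the thioesterase). The same seed yields byte-identical output.
    """
    rng = random.Random(arch.seed)
    sites_by_domain = load_sites()
    corrupt = set(arch.corrupt_diagnostics)

    records = []
    expected_hits: dict[str, list] = {}
    module_index = 0
    for orf_name, count in zip(arch.orf_names, arch.orf_split):
        parts: list[str] = []
        protected: set[int] = set()
        hits: list = []
        pos = 0

        def append_domain(dtype: str, seq: str, owner):
            nonlocal pos
            start = pos
            site_domain = "KS" if dtype == "KSQ" else dtype
            chars = list(seq)
            for site in sites_by_domain.get(site_domain, ()):
                for k in range(*site.span):
                    protected.add(start + k)
                if (owner, site.name) in corrupt:
                    off = site.offset
                    old = chars[off]
                    chars[off] = "A" if old != "A" else "G"
            parts.append("".join(chars))
            pos += len(seq)
            hits.append((dtype, (start, start + len(seq))))
            parts.append(LINKER)
            pos += len(LINKER)

        for _ in range(count):
            spec = arch.modules[module_index]
            for dtype in _module_domain_plan(module_index, spec):
                append_domain(dtype, _build_domain(dtype, spec), module_index)
            module_index += 1
        if orf_name == arch.orf_names[-1]:
            append_domain("TE", load_scaffolds()["TE"], "TE")

        seq = list("".join(parts))
        if arch.noise_rate > 0:
            for i in range(len(seq)):
                if i in protected:
                    continue
                if rng.random() < arch.noise_rate:
                    seq[i] = rng.choice([a for a in AA if a != seq[i]])
        records.append(ProteinRecord(id=orf_name, sequence="".join(seq),
                                     source="synthetic_cluster"))
        expected_hits[orf_name] = list(hits)

    line = assembly_from_architecture(arch)
    return SyntheticTruth(
        records=records,
        spec=arch,
        expected_hits={k: tuple(v) for k, v in expected_hits.items()},
        assembly=line,
        chemotype=predict_chemotype(line),
    )


# simple deterministic back-translation table for GenBank emission
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "NNN",
}


def write_genbank(records: Sequence[ProteinRecord], path,
                  cluster_id: str = "SYNTH_CLUSTER") -> None:
    """Write a synthetic single-record GenBank file with one CDS per protein.

    The nucleotide sequence is a deterministic back-translation (one codon
    per residue) with spacers; only the CDS /translation qualifiers carry
    information for this pipeline.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    spacer = "N" * 60
    nt_parts = []
    features = []
    offset = 0
    for rec in records:
        nt = "".join(_CODON[a] for a in rec.sequence) + "TAA"
        loc = FeatureLocation(offset, offset + len(nt), strand=1)
        features.append(
            SeqFeature(
                loc, type="CDS",
                qualifiers={"locus_tag": [rec.id], "translation": [rec.sequence]},
            )
        )
        nt_parts.append(nt)
        nt_parts.append(spacer)
        offset += len(nt) + len(spacer)
    gb = SeqRecord(
        Seq("".join(nt_parts)),
        id=cluster_id, name=cluster_id[:16],
        description="synthetic PKS cluster emitted by pksline",
        annotations={"molecule_type": "DNA"},
        features=features,
    )
    from Bio import SeqIO
    SeqIO.write([gb], str(path), "genbank")
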