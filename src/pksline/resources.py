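"""Loaders for the packaged reference data.

The package ships synthetic consensus-like exemplar sequences (one per
domain type), a sidecar table of their diagnostic/motif sites, and a small
annotated AT reference panel. All coordinates are 0-based offsets within
the exemplar.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

DOMAIN_TYPES = ("KS", "AT", "DH", "ER", "KR", "ACP", "TE")

# Specificity-determining block on the AT exemplar (anchor coordinates) and
# the expected residues per extender-unit class, after the published
# malonyl/methylmalonyl key-residue convention (HAFH vs YASH).
AT_SPEC_COLUMNS = (70, 71, 72, 73)
AT_CLASS_RESIDUES = {
    "malonyl": "HAFH",
    "methylmalonyl": "YASH",
}


@dataclass(frozen=True)
class Site:
    domain: str
    name: str
    offset: int
    length: int
    kind: str  # "diagnostic" (single functional residue/block) or "motif" (validation span)
    note: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.offset, self.offset + self.length)


def _read_text(name: str) -> str:
    return resources.files("pksline.data").joinpath(name).read_text()


def _parse_fasta_text(text: str) -> dict[str, str]:
    seqs: dict[str, list] = {}
    key = None
    for line in text.splitlines():
        if line.startswith(">"):
            key = line[1:].split()[0]
            seqs[key] = []
        elif line.strip() and key is not None:
            seqs[key].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


@lru_cache(maxsize=1)
def load_scaffolds() -> dict[str, str]:
    """Exemplar sequence per domain type."""
    return _parse_fasta_text(_read_text("scaffolds.fasta"))


@lru_cache(maxsize=1)
def load_sites() -> dict[str, tuple[Site, ...]]:
    """Diagnostic/motif sites per domain type, from the sidecar TSV."""
    out: dict[str, list] = {}
    for line in _read_text("scaffold_sites.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("domain\t"):
            continue
        domain, name, off, length, kind, note = line.split("\t")
        out.setdefault(domain, []).append(
            Site(domain, name, int(off), int(length), kind, note)
        )
    return {k: tuple(v) for k, v in out.items()}


def get_site(domain: str, name: str) -> Site:
    for site in load_sites()[domain]:
        if site.name == name:
            return site
    raise KeyError(f"no site {name!r} for domain {domain}")


@dataclass(frozen=True)
class ReferencePanel:
    """AT specificity panel: anchor exemplar + labelled members + columns."""

    anchor: str
    members: tuple  # of (id, class_label, sequence)
    columns: tuple = AT_SPEC_COLUMNS
    class_residues: tuple = tuple(sorted(AT_CLASS_RESIDUES.items()))

    @property
    def classes(self) -> tuple:
        return tuple(sorted({cls for _, cls, _ in self.members}))

    def expected(self) -> dict[str, dict[int, str]]:
        """Expected residue per class per diagnostic column."""
        table = dict(self.class_residues)
        return {
            cls: {col: table[cls][i] for i, col in enumerate(self.columns)}
            for cls in table
        }

    def class_consensus(self, cls: str) -> str:
        """Majority-rule consensus sequence of one specificity class."""
        rows = [seq for _, c, seq in self.members if c == cls]
        if not rows:
            raise KeyError(cls)
        out = []
        for col in range(len(rows[0])):
            counts: dict[str, int] = {}
            for row in rows:
                counts[row[col]] = counts.get(row[col], 0) + 1
            out.append(max(sorted(counts), key=lambda a: counts[a]))
        return "".join(out)

    def class_of(self, member_id: str) -> str:
        for mid, cls, _ in self.members:
            if mid == member_id:
                return cls
        raise KeyError(member_id)


@lru_cache(maxsize=1)
def load_at_panel() -> ReferencePanel:
    seqs = _parse_fasta_text(_read_text("at_panel.fasta"))
    labels = {}
    for line in _read_text("at_panel.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("seq_id\t"):
            continue
        sid, cls = line.split("\t")
        labels[sid] = cls
    members = tuple((sid, labels[sid], seq) for sid, seq in seqs.items())
    return ReferencePanel(anchor=load_scaffolds()["AT"], members=members)
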