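"""Locate PKS domains in a synthetic two-module protein.

Builds a small assembly-line protein with known domain content, scans it,
and prints each hit. Intervals are 0-based half-open protein coordinates;
`active` means every catalytic motif and residue of that domain is intact.
"""

from pksline import ArchitectureSpec, ModuleSpec, detect_domains, generate_proteins

arch = ArchitectureSpec(
    modules=(
        ModuleSpec(at="malonyl"),                       # loading: KSq-AT-ACP
        ModuleSpec(at="methylmalonyl", kr="B", dh=True),  # KS-AT-DH-KR-ACP
    ),
    orf_split=(2,),
    orf_names=("demoORF",),
)
truth = generate_proteins(arch)
protein = truth.records[0]
print(f"protein {protein.id}: {len(protein)} aa")

for hit in detect_domains(protein):
    motifs = ", ".join(f"{name}@{pos}" for name, pos, _ in hit.motif_matches)
    print(f"  {hit.domain_type:>4} {hit.interval}  active={hit.active}  motifs: {motifs}")

# The first module starts with KSQ (the decarboxylating loading variant,
# catalytic Cys replaced by Gln); the second with a condensing KS.
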