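"""One-off generator for the packaged reference data (domain scaffolds + AT panel).

Run from repo root:  python scripts/make_reference_data.py
Writes src/pksline/data/{scaffolds.fasta,scaffold_sites.tsv,at_panel.fasta,at_panel.tsv}
"""

import re
import random
from pathlib import Path

AA = "ACDEFGHIKLMNPQRSTVWY"
OUT = Path("src/pksline/data")

# (scaffold length, [(offset, block)], sites rows)
# sites row: (site_name, offset, length, note)
DESIGNS = {
    "KS": dict(
        length=130,
        blocks=[(38, "TACSSGL"), (75, "HGTGT"), (105, "KSNIGH")],
        sites=[
            ("triad_C", 40, 1, "diagnostic", "catalytic Cys; Gln in loading-module KSq"),
            ("triad_H1", 75, 1, "diagnostic", "first catalytic His"),
            ("triad_H2", 110, 1, "diagnostic", "second catalytic His"),
            ("ks_as_block", 38, 7, "motif", "active-site block TACSSGL"),
            ("ks_his1_block", 75, 5, "motif", "His box HGTGT"),
            ("ks_his2_block", 105, 6, "motif", "His box KSNIGH"),
        ],
        motif_regex={"TAxSSGL": (re.compile(r"TA.SSGL"), 38)},
    ),
    "AT": dict(
        length=120,
        blocks=[(45, "GHSQG"), (70, "HAFH")],
        sites=[
            ("at_ser", 47, 1, "diagnostic", "catalytic Ser of the GHSxG motif"),
            ("spec_block", 70, 4, "diagnostic", "extender-unit specificity block: HAFH=malonyl, YASH=methylmalonyl"),
            ("at_as_block", 45, 5, "motif", "active-site GHSQG"),
        ],
        motif_regex={"GHSxG": (re.compile(r"GHS.G"), 45)},
    ),
    "DH": dict(
        length=90,
        blocks=[(35, "HRSLGEVLP")],
        sites=[
            ("dh_his", 35, 1, "diagnostic", "catalytic His of HxxxGxxxP"),
            ("dh_block", 35, 9, "motif", "consensus HxxxGxxxP"),
        ],
        motif_regex={"HxxxGxxxP": (re.compile(r"H...G...P"), 35)},
    ),
    "ER": dict(
        length=100,
        blocks=[(40, "LRHEAVGGVGLSATRWA")],
        sites=[("er_motif", 40, 17, "motif", "NADPH-binding LxHxxxGGVGxxAxxxA")],
        motif_regex={"ER": (re.compile(r"L.H...GGVG..A...A"), 40)},
    ),
    "KR": dict(
        length=130,
        blocks=[(10, "GGTGSLG"), (60, "VAA"), (72, "F"), (88, "K"), (100, "S"), (112, "Y")],
        sites=[
            ("nadp", 10, 7, "motif", "Rossmann NADP(H)-binding GGxGxxG"),
            ("b_window", 60, 3, "diagnostic", "B-type signature window: LDD (or LED variant) => R-OH"),
            ("a_trp", 72, 1, "diagnostic", "A-type diagnostic position: Trp => S-OH"),
            ("triad_K", 88, 1, "diagnostic", "catalytic Lys"),
            ("triad_S", 100, 1, "diagnostic", "catalytic Ser"),
            ("triad_Y", 112, 1, "diagnostic", "catalytic Tyr"),
        ],
        motif_regex={"GGxGxxG": (re.compile(r"GG.G..G"), 10)},
    ),
    "ACP": dict(
        length=70,
        blocks=[(30, "LGIDS")],
        sites=[
            ("acp_ser", 34, 1, "diagnostic", "phosphopantetheinylation Ser of L/IG(x)DS"),
            ("acp_block", 30, 5, "motif", "L/IG(x)DS motif block"),
        ],
        motif_regex={"LIGxDS": (re.compile(r"[LI]G.?DS"), 30)},
    ),
    "TE": dict(
        length=90,
        blocks=[(40, "GWSAG")],
        sites=[
            ("te_ser", 42, 1, "diagnostic", "catalytic Ser of GxSxG"),
            ("te_block", 40, 5, "motif", "active-site GxSxG"),
        ],
        motif_regex={"GxSxG": (re.compile(r"G.S.G"), 40)},
    ),
}

# residues that seed motif false positives when clustered; filler avoids none,
# we just re-roll until each scaffold's own motif is unique at its offset.


def build_scaffold(name, design, seed):
    rng = random.Random(seed)
    for attempt in range(200):
        seq = [rng.choice(AA) for _ in range(design["length"])]
        for off, block in design["blocks"]:
            seq[off:off + len(block)] = list(block)
        s = "".join(seq)
        ok = True
        for pat, (rx, off) in design["motif_regex"].items():
            matches = [m.start() for m in rx.finditer(s)]
            # overlapping finditer misses overlaps but good enough for vetting
            if matches != [off]:
                ok = False
                break
        if ok:
            return s
        rng = random.Random(seed + 1000 * (attempt + 1))
    raise RuntimeError(f"could not build clean scaffold for {name}")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    scaffolds = {}
    site_rows = []
    for i, (name, design) in enumerate(DESIGNS.items()):
        scaffolds[name] = build_scaffold(name, design, seed=20180619 + i)
        for site, off, length, kind, note in design["sites"]:
            site_rows.append((name, site, off, length, kind, note))

    with open(OUT / "scaffolds.fasta", "w") as fh:
        for name, seq in scaffolds.items():
            fh.write(f">{name} synthetic consensus-like exemplar\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")

    with open(OUT / "scaffold_sites.tsv", "w") as fh:
        fh.write("# diagnostic sites, 0-based offsets within each scaffold\n")
        fh.write("domain\tsite\toffset\tlength\tkind\tnote\n")
        for row in site_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    # ---- AT panel: 4 malonyl + 4 methylmalonyl variants of the AT scaffold
    rng = random.Random(64)
    at = scaffolds["AT"]
    protected = set(range(45, 50)) | set(range(70, 74))
    free = [i for i in range(len(at)) if i not in protected]
    class_pos = sorted(rng.sample(free, 16))
    mal_res = {}
    mm_res = {}
    for p in class_pos:
        choices = rng.sample([a for a in AA if a != at[p]], 2)
        mal_res[p], mm_res[p] = choices

    def make_member(class_res, spec_block, member_seed):
        r = random.Random(member_seed)
        seq = list(at)
        for p, res in class_res.items():
            seq[p] = res
        seq[70:74] = list(spec_block)
        pool = [i for i in free if i not in class_pos]
        for p in r.sample(pool, 4):
            seq[p] = r.choice([a for a in AA if a != seq[p]])
        return "".join(seq)

    panel = {}
    for k in range(4):
        panel[f"malAT{k+1}"] = ("malonyl", make_member(mal_res, "HAFH", 100 + k))
    for k in range(4):
        panel[f"mmAT{k+1}"] = ("methylmalonyl", make_member(mm_res, "YASH", 200 + k))

    with open(OUT / "at_panel.fasta", "w") as fh:
        for name, (cls, seq) in panel.items():
            fh.write(f">{name} synthetic AT reference, {cls}-CoA specific\n")
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")

    with open(OUT / "at_panel.tsv", "w") as fh:
        fh.write("# synthetic AT specificity reference panel; diagnostic columns are\n")
        fh.write("# 0-based offsets on the packaged AT scaffold (the alignment anchor)\n")
        fh.write("seq_id\tspecificity\n")
        for name, (cls, _) in panel.items():
            fh.write(f"{name}\t{cls}\n")

    print("wrote", sorted(p.name for p in OUT.iterdir()))
    for name, seq in scaffolds.items():
        print(name, len(seq), seq)


if __name__ == "__main__":
    main()
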