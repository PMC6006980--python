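"""Functional typing of AT and KR domains.

AT extender-unit specificity is read from the specificity-determining
columns of an annotated reference alignment (malonyl-CoA vs
methylmalonyl-CoA); KR domains are stereo-typed from the B-type LDD/LED
signature (R-configured alcohol) or the A-type Trp (S-configured alcohol).
"""

from pksline import classify_at_residues, classify_kr
from pksline.resources import get_site, load_at_panel, load_scaffolds

panel = load_at_panel()
for cls in ("malonyl", "methylmalonyl"):
    call = classify_at_residues(panel.class_consensus(cls))
    print(f"AT consensus of {cls:>13} class -> {call.specificity} "
          f"(confidence {call.confidence:.2f})")

kr = list(load_scaffolds()["KR"])
window = get_site("KR", "b_window")
for signature in ("LDD", "LED"):
    seq = kr.copy()
    seq[window.offset:window.offset + window.length] = signature
    call = classify_kr("".join(seq))
    print(f"KR with {signature} signature -> {call.stereo_type}-type, "
          f"{call.predicted_oh_config}-configured hydroxyl")

seq = kr.copy()
seq[get_site("KR", "a_trp").offset] = "W"
call = classify_kr("".join(seq))
print(f"KR with diagnostic Trp   -> {call.stereo_type}-type, "
      f"{call.predicted_oh_config}-configured hydroxyl")

call = classify_kr("".join(kr))
print(f"KR with no signature     -> {call.stereo_type} "
      f"({call.predicted_oh_config} configuration)")
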