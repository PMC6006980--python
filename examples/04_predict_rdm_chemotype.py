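"""The worked example: predict the reedsmycin A backbone and reconcile it.

The packaged fixture encodes the RdmG/H/I/J assembly line (1 loading + 16
extension modules, terminal TE). Colinearity predicts a 2*(16+1) = 34-carbon
macrolactone backbone; comparing the raw prediction with the observed RDM A
chemotype surfaces exactly the two published inconsistencies (the loading
AT's specificity and the skipped module-2 dehydratase), after which the
DH-skip override regenerates the final chemotype.
"""

from pksline import (
    apply_dh_skip_overrides,
    assembly_from_architecture,
    make_observed_rdma,
    make_rdm_fixture,
    predict_chemotype,
    reconcile,
    titer_fold_change,
)

line = assembly_from_architecture(make_rdm_fixture())
raw = predict_chemotype(line)
print(f"modules: {len(line.modules)} (1 loading + {line.n_extension} extension)")
print(f"backbone carbons: {raw.carbon_count}")
print(f"raw double bonds: Δ{sorted(raw.double_bonds)}")
print(f"hydroxyls: {dict(sorted(raw.hydroxyls.items()))}")
print(f"methyl branches: {sorted(raw.methyl_branches)}")

observed = make_observed_rdma()
discrepancies = reconcile(raw, line, observed)
print(f"\ndiscrepancies vs observed RDM A: {len(discrepancies)}")
for d in discrepancies:
    print(f"  module {d.module_index} [{d.category}]: "
          f"predicted {d.predicted}, observed {d.observed}")

final = apply_dh_skip_overrides(line, discrepancies)
print(f"\nfinal double bonds: Δ{sorted(final.double_bonds)}")
print(f"final hydroxyls: {dict(sorted(final.hydroxyls.items()))}")

print("\nreported titer fold-changes:")
print("  rdmA-inactivated / wild type:", titer_fold_change(155.3, 73.8))
print("  rdmF-overexpressed / wild type:", titer_fold_change(184.8, 73.8))
print("  wild type / rdmA-overexpressed:", titer_fold_change(73.8, 52.5))
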