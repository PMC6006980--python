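import random

import pytest
from hypothesis import given, settings, strategies as st

from pksline import (
    ATCall,
    KRCall,
    ModuleModel,
    AssemblyLine,
    ObservedChemotype,
    apply_dh_skip_overrides,
    build_assembly_line,
    make_observed_rdma,
    predict_chemotype,
    reconcile,
    titer_fold_change,
)
from pksline.assembly import (
    AssemblyError,
    Discrepancy,
    alpha_carbon,
    beta_carbon,
    _diff_observed,
)
from pksline.domain_scan import DomainHit


def _hit(dtype, start, pid="orf1"):
    return DomainHit(domain_type=dtype, interval=(start, start + 50),
                     protein_id=pid)


# ------------------------------------------------------------ partitioning

def test_build_assembly_line_on_rdm_fixture(rdm_hits):
    line = build_assembly_line(rdm_hits, ["RdmG", "RdmH", "RdmI", "RdmJ"])
    assert len(line.modules) == 17
    assert line.n_extension == 16
    assert line.te_present
    assert line.modules[0].domain_types[0] == "KSQ"
    orf_of = {m.index: m.source_orf for m in line.modules}
    assert orf_of[0] == orf_of[2] == "RdmG"
    assert orf_of[3] == orf_of[6] == "RdmH"
    assert orf_of[7] == orf_of[12] == "RdmI"
    assert orf_of[13] == orf_of[16] == "RdmJ"


def test_two_ks_give_two_modules():
    hits = [_hit("KSQ", 0), _hit("AT", 100), _hit("ACP", 200),
            _hit("KS", 300), _hit("AT", 400), _hit("ACP", 500)]
    line = build_assembly_line({"orf1": hits}, ["orf1"])
    assert len(line.modules) == 2


def test_orphan_domain_attaches_to_loading_with_violation():
    hits = [_hit("AT", 0), _hit("KSQ", 100), _hit("AT", 200),
            _hit("ACP", 300)]
    line = build_assembly_line({"orf1": hits}, ["orf1"])
    assert len(line.modules) == 1
    assert line.modules[0].domain_types[0] == "AT"
    assert any("orphan" in v for v in line.modules[0].grammar_violations)


def test_no_ks_is_fatal():
    with pytest.raises(AssemblyError, match="no modules"):
        build_assembly_line({"orf1": [_hit("AT", 0), _hit("ACP", 100)]},
                            ["orf1"])


# ------------------------------------------------------------ chemotype

def _module(index, at="malonyl", kr=None, dh=False, er=False):
    kr_call = None
    if kr == "A":
        kr_call = KRCall("A", "TRP", "S")
    elif kr == "B":
        kr_call = KRCall("B", "LDD", "R")
    elif kr == "unassigned":
        kr_call = KRCall("unassigned", "none", "unknown")
    return ModuleModel(index=index, at_call=ATCall(at), kr_call=kr_call,
                       dh_functional=dh, er_present=er)


def _line(ext_specs):
    modules = [_module(0)] + [
        _module(i + 1, **spec) for i, spec in enumerate(ext_specs)
    ]
    return AssemblyLine(modules=modules, te_present=True)


def test_minimal_line_keto_at_c3():
    table = predict_chemotype(_line([dict(at="malonyl")]))
    assert table.carbon_count == 4
    assert table.states == {3: "keto"}
    assert not table.methyl_branches
    assert table.starter_unit == "acetate"


def test_rdm_fixture_chemotype(rdm_raw_chemotype):
    t = rdm_raw_chemotype
    assert t.carbon_count == 34
    assert t.hydroxyls == {13: "S", 15: "S", 17: "S", 21: "S", 23: "S",
                           19: "unknown", 25: "unknown", 27: "unknown"}
    assert sorted(t.double_bonds) == [2, 4, 6, 8, 10, 28, 30]
    assert t.methyl_branches == frozenset({30, 32})
    assert t.starter_unit == "propionate"  # AT0 sequence-level call
    # module->carbon mapping: KR11 -> C13, KR6 -> C23
    assert beta_carbon(16, 11) == 13
    assert beta_carbon(16, 6) == 23
    # module 1 carries the single ER: its beta carbon is fully reduced
    assert t.states[33] == "methylene"


def test_dh_over_s_or_unknown_draws_no_bond():
    table = predict_chemotype(_line([dict(at="malonyl", kr="A", dh=True)]))
    assert table.states == {3: "OH_S"}
    assert any("no double bond" in f for f in table.flags)
    table = predict_chemotype(
        _line([dict(at="malonyl", kr="unassigned", dh=True)])
    )
    assert table.states == {3: "OH_unknown"}


def test_dh_without_kr_keeps_keto_and_flags():
    table = predict_chemotype(_line([dict(at="malonyl", dh=True)]))
    assert table.states == {3: "keto"}
    assert any("DH without KR" in f for f in table.flags)


def chain_growth_oracle(ext_specs):
    """Unit-by-unit chain construction, renumbered at the end.

    Independent of the closed-form position formulas: the chain is grown
    starter-first, each extension prepending its (carbonyl, alpha) pair at
    the thioester end; final numbering starts at the TE-bound carbonyl.
    """
    chain = [("starter_carbonyl", 0), ("starter_alpha", 0)]
    for m, _spec in enumerate(ext_specs, start=1):
        chain = [("carbonyl", m), ("alpha", m)] + chain
    positions = {}
    for c1, (role, m) in enumerate(chain, start=1):
        positions[(role, m)] = c1
    out = {}
    n = len(ext_specs)
    for m, spec in enumerate(ext_specs, start=1):
        # the beta carbon processed by module m is the carbonyl delivered
        # by the previous unit (the starter for module 1)
        if m == 1:
            out["beta", m] = positions[("starter_carbonyl", 0)]
        else:
            out["beta", m] = positions[("carbonyl", m - 1)]
        out["alpha", m] = positions[("alpha", m)]
    out["carbons"] = len(chain)
    return out


def test_closed_form_positions_match_chain_growth_oracle():
    """Exhaustive check for every architecture size N <= 20."""
    for n in range(1, 21):
        specs = [dict(at="malonyl")] * n
        oracle = chain_growth_oracle(specs)
        assert oracle["carbons"] == 2 * (n + 1)
        for m in range(1, n + 1):
            assert beta_carbon(n, m) == oracle["beta", m], (n, m)
            assert alpha_carbon(n, m) == oracle["alpha", m], (n, m)


@st.composite
def _architectures(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    specs = []
    for _ in range(n):
        kr = draw(st.sampled_from([None, "A", "B", "unassigned"]))
        dh = kr == "B" and draw(st.booleans())
        er = dh and draw(st.booleans())
        specs.append(dict(
            at=draw(st.sampled_from(["malonyl", "methylmalonyl"])),
            kr=kr, dh=dh, er=er,
        ))
    return specs


@settings(max_examples=80, deadline=None, derandomize=True)
@given(specs=_architectures())
def test_chemotype_parity_invariants(specs):
    """Hydroxyls at odd carbons, methyls at even; bond count bookkeeping."""
    n = len(specs)
    table = predict_chemotype(_line(specs))
    assert table.carbon_count == 2 * (n + 1)
    assert all(c % 2 == 1 for c in table.hydroxyls)
    assert all(c % 2 == 0 for c in table.methyl_branches)
    expected_bonds = sum(
        1 for s in specs if s["dh"] and not s["er"] and s["kr"] == "B"
    )
    assert len(table.double_bonds) == expected_bonds
    expected_methyls = sum(1 for s in specs if s["at"] == "methylmalonyl")
    assert len(table.methyl_branches) == expected_methyls


# ------------------------------------------------------------ reconcile

def test_rdm_reconciliation_finds_exactly_two_inconsistencies(
    rdm_fixture_line, rdm_raw_chemotype
):
    disc = reconcile(rdm_raw_chemotype, rdm_fixture_line, make_observed_rdma())
    assert len(disc) == 2
    by_cat = {d.category: d for d in disc}
    assert by_cat["at_specificity"].module_index == 0
    assert by_cat["dh_skip"].module_index == 2


def test_dh_skip_override_regenerates_final_chemotype(
    rdm_fixture_line, rdm_raw_chemotype
):
    disc = reconcile(rdm_raw_chemotype, rdm_fixture_line, make_observed_rdma())
    final = apply_dh_skip_overrides(rdm_fixture_line, disc)
    assert sorted(final.double_bonds) == [2, 4, 6, 8, 10, 28]
    assert 31 in final.hydroxyls  # module 2's hydroxyl retained


def test_reconcile_self_consistency(rdm_fixture_line, rdm_raw_chemotype):
    observed = rdm_raw_chemotype.to_observed()
    assert reconcile(rdm_raw_chemotype, rdm_fixture_line, observed) == []


def test_reconcile_counts_perturbations(rdm_fixture_line, rdm_raw_chemotype):
    """Flipping k known hydroxyl configurations yields exactly k findings."""
    rng = random.Random(5)
    base = rdm_raw_chemotype.to_observed()
    known = [c for c, conf in base.hydroxyls if conf in ("R", "S")]
    for k in (1, 2, 3):
        flip = set(rng.sample(known, k))
        perturbed = ObservedChemotype(
            carbon_count=base.carbon_count,
            hydroxyls=tuple(
                (c, ({"S": "R", "R": "S"}[conf] if c in flip else conf))
                if conf in ("R", "S") else (c, conf)
                for c, conf in base.hydroxyls
            ),
            double_bonds=base.double_bonds,
            methyl_branches=base.methyl_branches,
            starter_unit=base.starter_unit,
        )
        disc = reconcile(rdm_raw_chemotype, rdm_fixture_line, perturbed)
        assert len(disc) == k
        assert all(d.category == "kr_config" for d in disc)


def test_reconcile_symmetric_in_count(rdm_raw_chemotype):
    a = rdm_raw_chemotype.to_observed()
    b = make_observed_rdma()
    assert len(_diff_observed(a, b, 16)) == len(_diff_observed(b, a, 16))


def test_reconcile_size_mismatch_is_single_fatal(rdm_fixture_line,
                                                 rdm_raw_chemotype):
    small = ObservedChemotype(carbon_count=30)
    disc = reconcile(rdm_raw_chemotype, rdm_fixture_line, small)
    assert len(disc) == 1
    assert disc[0].category == "other"


def test_discrepancy_requires_disagreement():
    with pytest.raises(ValueError):
        Discrepancy(1, "kr_config", predicted="x", observed="x")


# ------------------------------------------------------------ titers

def test_titer_fold_changes():
    assert titer_fold_change(10.0, 10.0) == 1.00
    assert titer_fold_change(155.3, 73.8) == 2.10
    assert titer_fold_change(184.8, 73.8) == 2.50
    with pytest.raises(ValueError):
        titer_fold_change(0.0, 5.0)
    with pytest.raises(ValueError):
        titer_fold_change(5.0, -1.0)
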