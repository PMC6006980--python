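"""Module partitioning and colinearity-based chemotype prediction.

Domain hits are cut into modules at each ketosynthase (KS/KSQ); the ordered
module string across ORFs, ending in a thioesterase, is the assembly line.
The product backbone is then derived by the colinearity rules: with N
extension modules the backbone has 2(N+1) carbons, numbered C1 at the
TE-bound carbonyl. Module m (1..N) controls the beta-carbon 2N+3-2m: its KR
sets the carbon state (A-type -> S-OH, B-type -> R-OH, unassigned ->
OH of unknown configuration, absent/inactive -> ketone); a functional DH
dehydrates an R-configured hydroxyl to an E-double bond at delta(2N+2-2m)
(syn elimination on R-configured beta-hydroxy intermediates); DH + ER
reduces on to a methylene. A methylmalonyl-specific AT at module m places a
methyl branch at carbon 2N+2-2m; a methylmalonyl loading AT means a
propionate (rather than acetate) starter after in-situ decarboxylation by
the KSq domain.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .domain_classify import ATCall, KRCall
from .seq_io import ObservedChemotype

log = logging.getLogger(__name__)

# carbon states
KETO = "keto"
OH_R = "OH_R"
OH_S = "OH_S"
OH_UNKNOWN = "OH_unknown"
ENOYL_E = "enoyl_E"
METHYLENE = "methylene"

_OH_STATES = {OH_R: "R", OH_S: "S", OH_UNKNOWN: "unknown"}


class AssemblyError(ValueError):
    pass


@dataclass
class ModuleModel:
    """One loading (index 0) or extension module of the assembly line."""

    index: int
    domains: tuple = ()  # ordered DomainHit references
    at_call: Optional[ATCall] = None
    kr_call: Optional[KRCall] = None
    dh_functional: bool = False
    er_present: bool = False
    source_orf: str = ""
    grammar_violations: tuple = ()

    @property
    def is_loading(self) -> bool:
        return self.index == 0

    @property
    def domain_types(self) -> tuple:
        return tuple(h.domain_type for h in self.domains)


@dataclass
class AssemblyLine:
    """Ordered modules across ORFs plus the terminal thioesterase."""

    modules: list
    te_present: bool = False

    def __post_init__(self):
        if not self.modules:
            raise AssemblyError("assembly line needs at least one module")
        loaders = [m for m in self.modules if m.index == 0]
        if len(loaders) != 1 or self.modules[0].index != 0:
            raise AssemblyError("exactly one loading module at index 0 required")
        for k, m in enumerate(self.modules):
            if m.index != k:
                raise AssemblyError("module indices must be contiguous")

    @property
    def n_extension(self) -> int:
        return len(self.modules) - 1

    def extension_modules(self):
        return self.modules[1:]


@dataclass
class ChemotypeTable:
    """Per-carbon backbone states of the predicted, macrolactonized product.

    ``states`` holds beta-carbon states at odd positions 3..2N+1; an
    ``enoyl_E`` state at beta-carbon n+1 denotes the E-double bond delta-n.
    """

    carbon_count: int
    states: dict = field(default_factory=dict)
    methyl_branches: frozenset = frozenset()
    starter_unit: str = "acetate"
    ring_closure: Optional[int] = None
    flags: tuple = ()

    def __post_init__(self):
        if self.carbon_count % 2:
            raise ValueError("backbone carbon count must be even")
        for c, state in self.states.items():
            if c % 2 == 0 or not 3 <= c <= self.carbon_count - 1:
                raise ValueError(f"beta-carbon state at illegal position {c}")
            if state not in (KETO, OH_R, OH_S, OH_UNKNOWN, ENOYL_E, METHYLENE):
                raise ValueError(f"unknown state {state!r}")
        for c in self.methyl_branches:
            if c % 2:
                raise ValueError(f"methyl branch at odd carbon {c}")

    @property
    def double_bonds(self) -> frozenset:
        """Delta labels of the E-configured double bonds."""
        return frozenset(c - 1 for c, s in self.states.items() if s == ENOYL_E)

    @property
    def hydroxyls(self) -> dict:
        """carbon -> configuration for every hydroxyl-bearing beta carbon."""
        return {
            c: _OH_STATES[s] for c, s in self.states.items() if s in _OH_STATES
        }

    def to_observed(self) -> ObservedChemotype:
        """Encode as an observed-chemotype description (for reconciliation)."""
        return ObservedChemotype(
            carbon_count=self.carbon_count,
            hydroxyls=tuple(sorted(self.hydroxyls.items())),
            double_bonds=tuple((d, "E") for d in sorted(self.double_bonds)),
            methyl_branches=self.methyl_branches,
            starter_unit=self.starter_unit,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "carbon_count": self.carbon_count,
                "states": {str(k): v for k, v in sorted(self.states.items())},
                "methyl_branches": sorted(self.methyl_branches),
                "double_bonds": sorted(self.double_bonds),
                "starter_unit": self.starter_unit,
                "ring_closure": self.ring_closure,
                "flags": list(self.flags),
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["# per-carbon backbone table; C1 = TE-bound carbonyl",
                 "carbon\tstate\tmethyl_branch"]
        for c in range(1, self.carbon_count + 1):
            state = self.states.get(c, "")
            if c == 1:
                state = state or "lactone_carbonyl"
            lines.append(f"{c}\t{state}\t{'yes' if c in self.methyl_branches else ''}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class Discrepancy:
    """A predicted-vs-observed mismatch mapped to its responsible module."""

    module_index: Optional[int]
    category: str  # at_specificity | dh_skip | kr_config | other
    predicted: str
    observed: str

    def __post_init__(self):
        if self.predicted == self.observed:
            raise ValueError("a discrepancy requires predicted != observed")


def build_assembly_line(hits_by_orf: dict, orf_order: Sequence[str]) -> AssemblyLine:
    """Partition ordered domain hits into modules across ORFs.

    Modules are cut at each KS/KSQ hit; domains between consecutive KSs
    belong to the left module. The domain grammar
    KS-AT-[DH-[ER-]][KR-]ACP is checked; violations are logged on the
    module, not fatal. Leading domains before the first KS of the whole
    line attach to the loading module with a violation note.
    """
    modules: list[ModuleModel] = []
    current: list = []
    current_orf = None
    orphans: list = []

    def flush():
        nonlocal current
        if current:
            modules.append(
                ModuleModel(
                    index=len(modules),
                    domains=tuple(current),
                    source_orf=current_orf,
                )
            )
            current = []

    n_ks = 0
    for orf in orf_order:
        hits = sorted(hits_by_orf.get(orf, ()), key=lambda h: h.interval[0])
        for hit in hits:
            if hit.domain_type in ("KS", "KSQ"):
                flush()
                current_orf = orf
                current = [hit]
                n_ks += 1
            else:
                if n_ks == 0:
                    orphans.append(hit)
                else:
                    current.append(hit)
        # module boundaries may not straddle ORFs
        flush()
    if n_ks == 0:
        raise AssemblyError("no modules detectable: no KS/KSQ hit found")

    te_present = any(
        h.domain_type == "TE" for m in modules for h in m.domains
    )

    if orphans:
        first = modules[0]
        modules[0] = replace(
            first,
            domains=tuple(orphans) + first.domains,
            grammar_violations=first.grammar_violations
            + (f"{len(orphans)} orphan domain(s) before first KS attached to loading",),
        )
        log.warning("attached %d orphan domains to the loading module", len(orphans))

    for k, m in enumerate(modules):
        violations = list(m.grammar_violations)
        types = [t for t in m.domain_types if t != "TE"]
        if k == 0:
            if types and types[0] not in ("KSQ", "KS"):
                violations.append("loading module does not start with KS/KSQ")
            if "ACP" not in types:
                violations.append("loading module lacks ACP")
        else:
            for needed in ("AT", "ACP"):
                if needed not in types:
                    violations.append(f"extension module lacks {needed}")
        if "ER" in types and "DH" not in types:
            violations.append("ER without DH")
        if violations:
            modules[k] = replace(m, grammar_violations=tuple(violations))
            log.warning("module %d grammar: %s", k, "; ".join(violations))

    return AssemblyLine(modules=modules, te_present=te_present)


def beta_carbon(n_extension: int, module_index: int) -> int:
    """Backbone position of the beta carbon processed by a module's KR."""
    return 2 * n_extension + 3 - 2 * module_index


def alpha_carbon(n_extension: int, module_index: int) -> int:
    """Backbone position of a module's alpha carbon (methyl branch site)."""
    return 2 * n_extension + 2 - 2 * module_index


def predict_chemotype(line: AssemblyLine,
                      dh_skips: frozenset = frozenset()) -> ChemotypeTable:
    """Apply the colinearity rules to an assembly line.

    ``dh_skips`` marks modules whose (otherwise functional) DH is treated
    as inactive — the annotation produced by reconciliation against an
    observed structure; it is never inferred here.
    """
    n = line.n_extension
    flags = []
    states: dict[int, str] = {}
    methyls = set()

    loading = line.modules[0]
    loading_spec = loading.at_call.specificity if loading.at_call else "unknown"
    starter = "propionate" if loading_spec == "methylmalonyl" else "acetate"
    if loading_spec == "unknown":
        flags.append("loading AT specificity unknown; acetate starter assumed")

    for module in line.extension_modules():
        m = module.index
        if module.at_call is None:
            raise AssemblyError(f"extension module {m} lacks an AT call")
        beta = beta_carbon(n, m)
        alpha = alpha_carbon(n, m)
        if module.at_call.specificity == "methylmalonyl":
            methyls.add(alpha)

        kr = module.kr_call
        if kr is None:
            state = KETO
        elif kr.stereo_type == "A":
            state = OH_S
        elif kr.stereo_type == "B":
            state = OH_R
        else:
            state = OH_UNKNOWN

        if module.dh_functional and m not in dh_skips:
            if kr is None:
                flags.append(f"module {m}: DH without KR; keto retained")
            elif state == OH_R:
                state = ENOYL_E
                if module.er_present:
                    state = METHYLENE
            else:
                flags.append(
                    f"module {m}: DH over {state}; no double bond drawn"
                )
        elif module.er_present and not module.dh_functional:
            flags.append(f"module {m}: ER without functional DH ignored")
        states[beta] = state

    return ChemotypeTable(
        carbon_count=2 * (n + 1),
        states=states,
        methyl_branches=frozenset(methyls),
        starter_unit=starter,
        flags=tuple(flags),
    )


def _module_of_beta(n_extension: int, carbon: int) -> int:
    return (2 * n_extension + 3 - carbon) // 2


def _module_of_alpha(n_extension: int, carbon: int) -> int:
    return (2 * n_extension + 2 - carbon) // 2


def _diff_observed(a: ObservedChemotype, b: ObservedChemotype,
                   n_extension: int) -> list[Discrepancy]:
    """Symmetric per-module comparison of two chemotype descriptions."""
    out: list[Discrepancy] = []
    if a.carbon_count != b.carbon_count:
        return [Discrepancy(None, "other",
                            predicted=f"{a.carbon_count} carbons",
                            observed=f"{b.carbon_count} carbons")]
    if a.starter_unit != b.starter_unit:
        out.append(Discrepancy(0, "at_specificity",
                               predicted=a.starter_unit, observed=b.starter_unit))
    for c in sorted(a.methyl_branches ^ b.methyl_branches):
        m = _module_of_alpha(n_extension, c)
        pred = "methyl" if c in a.methyl_branches else "no methyl"
        obs = "methyl" if c in b.methyl_branches else "no methyl"
        out.append(Discrepancy(m, "at_specificity",
                               predicted=f"{pred} at C{c}",
                               observed=f"{obs} at C{c}"))

    oh_a, oh_b = a.hydroxyl_map, b.hydroxyl_map
    bonds_a, bonds_b = a.double_bond_set, b.double_bond_set
    for d in sorted(bonds_a ^ bonds_b):
        beta = d + 1
        m = _module_of_beta(n_extension, beta)
        in_a = d in bonds_a
        # a double bond on one side replacing a hydroxyl on the other is a
        # single DH-level disagreement (the paper's "skipped" DH pattern)
        other_oh = oh_b if in_a else oh_a
        if beta in other_oh:
            out.append(Discrepancy(
                m, "dh_skip",
                predicted=(f"Δ{d} double bond" if in_a else f"OH at C{beta}"),
                observed=(f"OH at C{beta}" if in_a else f"Δ{d} double bond"),
            ))
        else:
            out.append(Discrepancy(
                m, "dh_skip",
                predicted=(f"Δ{d} double bond" if in_a else f"no Δ{d} bond"),
                observed=(f"no Δ{d} bond" if in_a else f"Δ{d} double bond"),
            ))
    for c in sorted(set(oh_a) | set(oh_b)):
        in_a, in_b = c in oh_a, c in oh_b
        if in_a != in_b:
            # already covered if the other side carries the double bond
            d = c - 1
            if (in_a and d in bonds_b) or (in_b and d in bonds_a):
                continue
            m = _module_of_beta(n_extension, c)
            out.append(Discrepancy(
                m, "kr_config",
                predicted=("OH" if in_a else "no OH") + f" at C{c}",
                observed=("OH" if in_b else "no OH") + f" at C{c}",
            ))
        elif in_a and in_b:
            ca, cb = oh_a[c], oh_b[c]
            if "unknown" in (ca, cb) or ca == cb:
                continue
            m = _module_of_beta(n_extension, c)
            out.append(Discrepancy(
                m, "kr_config",
                predicted=f"{ca}-OH at C{c}", observed=f"{cb}-OH at C{c}",
            ))
    return out


def reconcile(predicted: ChemotypeTable, line: AssemblyLine,
              observed: ObservedChemotype) -> list[Discrepancy]:
    """Compare a predicted chemotype with an observed structure.

    Starter unit, methyl-branch set, per-position hydroxyl
    presence/configuration (unknown configurations match anything) and the
    double-bond set are compared; each mismatch is mapped back to the
    responsible module. A carbon-count mismatch short-circuits into a
    single fatal discrepancy.
    """
    return _diff_observed(predicted.to_observed(), observed, line.n_extension)


def apply_dh_skip_overrides(line: AssemblyLine,
                            discrepancies: Sequence[Discrepancy]) -> ChemotypeTable:
    """Re-predict with every reconciliation dh_skip applied as an override."""
    skips = frozenset(
        d.module_index for d in discrepancies
        if d.category == "dh_skip" and d.module_index is not None
    )
    return predict_chemotype(line, dh_skips=skips)


def titer_fold_change(mean_a: float, mean_b: float) -> float:
    """Fold change between two reported production means, 2 decimals."""
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("titer means must be positive")
    return round(mean_a / mean_b, 2)
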