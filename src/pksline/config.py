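"""Run configuration shared by the CLI and the pipeline helpers."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Resolved pipeline settings; echoed into every report header.

    ``window_threshold`` is the fraction of an exemplar's self-score a
    local-alignment window must reach to become a domain candidate.
    ``motif_mismatch`` overrides the per-motif mismatch budget by motif
    name. ``at_precedence`` decides the AT specificity when the residue and
    phylogeny routes disagree. ``n_bootstrap`` (default 1000) is the
    replicate count for AT placement supports.
    """

    window_threshold: float = 0.35
    motif_mismatch: dict = field(default_factory=dict)
    at_precedence: str = "residues"
    at_method: str = "residues"  # residues | combined
    n_bootstrap: int = 1000
    seed: int = 0
    output_format: str = "tsv"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)
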