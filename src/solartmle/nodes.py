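"""Node specifications for the longitudinal cohort.

Every column of the cohort table is a *node* with a role (baseline covariate
W, time-varying confounder L, treatment A, or outcome Y), a wave (1..3 —
the three questionnaire waves), and a value kind.  The temporal ordering of
the blocks is fixed to

    W, L1, A1, Y1, L2, A2, Y2, L3, Y3

with treatments measured only at waves 1 and 2 (no medication data exists at
the final wave) and outcomes at all three waves.  Within a block, columns
keep their listed order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

ROLES = ("baseline", "confounder", "treatment", "outcome")
VALUE_KINDS = ("binary", "continuous")

# rank of a block in the global temporal ordering
_ROLE_RANK = {"baseline": 0, "confounder": 1, "treatment": 2, "outcome": 3}


@dataclass(frozen=True)
class NodeSpec:
    """One cohort column: name, causal role, wave, and value kind."""

    name: str
    role: str
    wave: int
    value_kind: str = "binary"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for node {self.name!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r} for node {self.name!r}")
        if self.wave not in (1, 2, 3):
            raise ValueError(f"wave must be 1..3, got {self.wave} for node {self.name!r}")
        if self.role == "treatment" and self.wave == 3:
            raise ValueError(f"treatment node {self.name!r} at wave 3: treatments exist only at waves 1 and 2")

    @property
    def block_key(self) -> tuple[int, int]:
        # baselines sort before everything regardless of wave
        if self.role == "baseline":
            return (0, 0)
        return (self.wave, _ROLE_RANK[self.role])


def validate_ordering(specs: Iterable[NodeSpec]) -> list[NodeSpec]:
    """Check that the listed nodes follow the W, L1, A1, Y1, ... ordering.

    Returns the specs as a list.  Raises ``ValueError`` on a violation or on
    duplicate names.
    """
    specs = list(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate node names")
    keys = [s.block_key for s in specs]
    if keys != sorted(keys):
        raise ValueError("node specs violate the W, L1, A1, Y1, L2, A2, Y2, L3, Y3 ordering")
    return specs


def treatment_nodes(specs: Iterable[NodeSpec]) -> list[NodeSpec]:
    return [s for s in specs if s.role == "treatment"]


def outcome_node(specs: Iterable[NodeSpec], wave: int, value_kind: str = "binary") -> NodeSpec:
    cands = [s for s in specs if s.role == "outcome" and s.wave == wave and s.value_kind == value_kind]
    if not cands:
        raise ValueError(f"no {value_kind} outcome node at wave {wave}")
    return cands[0]


def history_names(specs: list[NodeSpec], node: NodeSpec) -> list[str]:
    """Names of all nodes strictly preceding ``node`` in the global ordering."""
    idx = [s.name for s in specs].index(node.name)
    return [s.name for s in specs[:idx]]


def load_node_specs(path: str | Path) -> list[NodeSpec]:
    """Read node specs from YAML: a list of {name, role, wave, value_kind}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = [
        NodeSpec(
            name=d["name"],
            role=d["role"],
            wave=int(d["wave"]),
            value_kind=d.get("value_kind", "binary"),
        )
        for d in raw
    ]
    return validate_ordering(specs)


def save_node_specs(specs: list[NodeSpec], path: str | Path) -> None:
    raw = [
        {"name": s.name, "role": s.role, "wave": s.wave, "value_kind": s.value_kind}
        for s in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
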