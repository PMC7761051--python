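"""MT-CPD identification and matched ST-CPD group assembly with data completeness.

An MT-CPD is a compound with promiscuity degree (PD) at or above a
threshold; its group targets are exactly the targets it is active
against.  For each group target one single-target compound (PD = 1,
active on that target, *explicitly* inactive on every other group
target) is drawn uniformly at random.  Untested disqualifies: every
group member must have a recorded outcome for every group target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from promidiag.activity_data import ACTIVE, INACTIVE, ActivityMatrix
from promidiag.errors import ConfigError


@dataclass(frozen=True)
class GroupSamplingConfig:
    pd_threshold: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.pd_threshold < 2:
            raise ConfigError(f"pd_threshold must be >= 2, got {self.pd_threshold}")


@dataclass(frozen=True)
class MTGroup:
    """One MT-CPD, its active-target set, and per-target matched ST-CPDs."""

    mt: str
    targets: Tuple[str, ...]
    st_by_target: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.st_by_target:
            raise ValueError(f"group for {self.mt} has no ST-CPDs")
        unknown = set(self.st_by_target) - set(self.targets)
        if unknown:
            raise ValueError(f"st_by_target keys outside group targets: {sorted(unknown)}")

    @property
    def st_compounds(self) -> List[str]:
        return sorted(set(self.st_by_target.values()))

    @property
    def members(self) -> List[str]:
        return [self.mt] + self.st_compounds


def identify_mt_compounds(matrix: ActivityMatrix, config: GroupSamplingConfig) -> List[str]:
    """All compounds with PD >= threshold, sorted by identifier."""
    return sorted(
        c for c in matrix.compounds if matrix.promiscuity_degree(c) >= config.pd_threshold
    )


def _eligible_candidates(matrix: ActivityMatrix, mt: str, target: str, group_targets: Tuple[str, ...]) -> List[str]:
    """PD-1 compounds active on ``target`` and explicitly inactive on every other group target."""
    out = []
    for c in matrix.active_on(target):
        if c == mt or matrix.promiscuity_degree(c) != 1:
            continue
        if all(matrix.outcome(c, t) == INACTIVE for t in group_targets if t != target):
            out.append(c)
    return out  # active_on is sorted, so candidates are too


def sample_st_group(
    matrix: ActivityMatrix,
    mt: str,
    rng: np.random.Generator,
    pd_threshold: int = 5,
) -> Optional[MTGroup]:
    """Assemble the group for one MT-CPD, or ``None`` when no target has any eligible ST-CPD."""
    if matrix.promiscuity_degree(mt) < pd_threshold:
        raise ValueError(
            f"{mt} has PD {matrix.promiscuity_degree(mt)} < threshold {pd_threshold}"
        )
    group_targets = tuple(matrix.active_targets(mt))
    st_by_target: Dict[str, str] = {}
    for target in group_targets:
        candidates = _eligible_candidates(matrix, mt, target, group_targets)
        if candidates:
            st_by_target[target] = candidates[int(rng.integers(len(candidates)))]
    if not st_by_target:
        return None
    return MTGroup(mt=mt, targets=group_targets, st_by_target=st_by_target)


def build_groups(matrix: ActivityMatrix, config: GroupSamplingConfig) -> List[MTGroup]:
    """One completeness-verified group per MT-CPD with at least one eligible ST-CPD.

    MT-CPDs are visited in sorted identifier order against a single
    seeded stream, so the result does not depend on input file ordering.
    """
    rng = np.random.default_rng(config.rng_seed)
    groups: List[MTGroup] = []
    for mt in identify_mt_compounds(matrix, config):
        group = sample_st_group(matrix, mt, rng, pd_threshold=config.pd_threshold)
        if group is not None:
            groups.append(group)
    return groups


def verify_completeness(group: MTGroup, matrix: ActivityMatrix) -> bool:
    """True iff the group satisfies every structural invariant against the matrix.

    The MT-CPD must be active on all group targets; each ST-CPD must be
    active on exactly its key target among the group targets and
    explicitly inactive on the rest; every member must have a recorded
    outcome for every group target; no ST-CPD appears twice.
    """
    if not group.st_by_target:
        return False
    if len(set(group.st_by_target.values())) != len(group.st_by_target):
        return False
    for t in group.targets:
        if matrix.outcome(group.mt, t) != ACTIVE:
            return False
    for key_target, st in group.st_by_target.items():
        for t in group.targets:
            expected = ACTIVE if t == key_target else INACTIVE
            if matrix.outcome(st, t) != expected:
                return False
    return True


def write_groups(groups: List[MTGroup], path) -> None:
    """Serialize groups as JSON Lines: {"mt", "targets", "st"} per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in groups:
            fh.write(
                json.dumps(
                    {"mt": g.mt, "targets": list(g.targets), "st": dict(sorted(g.st_by_target.items()))},
                    sort_keys=True,
                )
                + "\n"
            )


def read_groups(path) -> List[MTGroup]:
    groups: List[MTGroup] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            groups.append(MTGroup(mt=obj["mt"], targets=tuple(obj["targets"]), st_by_target=dict(obj["st"])))
    return groups
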