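"""Dataset ablation conditions: full, random removal, and NN removal.

NN removal discards the quantile of groups whose MT-CPDs have the
closest other-group MT-CPD neighbors, then (on the survivors) the
quantile whose ST-CPDs have the closest outside-group ST-CPD neighbors,
for the same net reduction as the size-matched random-removal control.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from promidiag.chem_similarity import Fingerprint, pack_fingerprints, tanimoto_matrix
from promidiag.errors import ConfigError
from promidiag.group_sampling import MTGroup


class Condition(str, enum.Enum):
    FULL = "FULL"
    RANDOM_REMOVAL = "RANDOM_REMOVAL"
    NN_REMOVAL = "NN_REMOVAL"


@dataclass(frozen=True)
class ConditionConfig:
    condition: Condition = Condition.FULL
    removal_fraction: float = 0.5
    nn_fraction_mt: float = 0.25
    nn_fraction_st: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        for name in ("removal_fraction", "nn_fraction_mt", "nn_fraction_st"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(self.nn_fraction_mt + self.nn_fraction_st - self.removal_fraction) > 1e-9:
            raise ConfigError(
                "nn_fraction_mt + nn_fraction_st must equal removal_fraction "
                f"({self.nn_fraction_mt} + {self.nn_fraction_st} != {self.removal_fraction})"
            )


def random_removal(
    groups: Sequence[MTGroup], config: ConditionConfig, rng: np.random.Generator
) -> List[MTGroup]:
    """Remove floor(fraction * n) groups uniformly at random (seeded)."""
    n = len(groups)
    if n < 2:
        raise ValueError(f"need >= 2 groups, got {n}")
    n_remove = int(np.floor(config.removal_fraction * n))
    if n_remove >= n:
        raise ValueError(f"removal_fraction {config.removal_fraction} would remove all {n} groups")
    # index by sorted MT id so the draw is independent of input ordering
    order = np.argsort([g.mt for g in groups])
    removed_idx = set(order[rng.choice(n, size=n_remove, replace=False)].tolist())
    return [g for i, g in enumerate(groups) if i not in removed_idx]


def _mt_side_scores(groups: Sequence[MTGroup], fingerprints: Mapping[str, Fingerprint]) -> np.ndarray:
    mt_ids = [g.mt for g in groups]
    x = pack_fingerprints(fingerprints, mt_ids)
    sim = tanimoto_matrix(x, x)
    np.fill_diagonal(sim, -np.inf)
    # a duplicated MT id across groups still scores 1.0 against its twin
    for i, a in enumerate(mt_ids):
        for j, b in enumerate(mt_ids):
            if i != j and a == b:
                sim[i, j] = 1.0
    return sim.max(axis=1)


def _st_side_scores(groups: Sequence[MTGroup], fingerprints: Mapping[str, Fingerprint]) -> np.ndarray:
    all_st = sorted({st for g in groups for st in g.st_compounds})
    x = pack_fingerprints(fingerprints, all_st)
    sim = tanimoto_matrix(x, x)
    col = {c: i for i, c in enumerate(all_st)}
    scores = np.empty(len(groups))
    for gi, g in enumerate(groups):
        own = set(g.st_compounds)
        outside = [col[c] for c in all_st if c not in own]
        if not outside:
            scores[gi] = -np.inf
            continue
        rows = [col[c] for c in g.st_compounds]
        scores[gi] = sim[np.ix_(rows, outside)].max()
    return scores


def nn_removal(
    groups: Sequence[MTGroup],
    fingerprints: Mapping[str, Fingerprint],
    config: ConditionConfig,
    return_manifest: bool = False,
):
    """Two-pass nearest-neighbor ablation with an exact net cut.

    Pass 1 removes the ``nn_fraction_mt`` quantile of groups ranked by the
    Tanimoto similarity of their MT-CPD to the nearest MT-CPD of any other
    group.  Pass 2 ranks the survivors by the max similarity of their
    ST-CPDs to the nearest ST-CPD outside the group and removes enough to
    reach floor(removal_fraction * n) total, matching ``random_removal``
    output size for equal fractions.  Ties break lexicographically by MT
    identifier.
    """
    n = len(groups)
    if n < 4:
        raise ValueError(f"need >= 4 groups for two-sided NN removal, got {n}")
    n_total = int(np.floor(config.removal_fraction * n))
    n_mt = int(np.floor(config.nn_fraction_mt * n))
    n_st = n_total - n_mt
    if n_total >= n:
        raise ValueError("fractions would remove all groups")

    manifest: List[Tuple[str, str, float]] = []

    mt_scores = _mt_side_scores(groups, fingerprints)
    mt_rank = sorted(range(n), key=lambda i: (-mt_scores[i], groups[i].mt))
    mt_removed = set(mt_rank[:n_mt])
    manifest.extend((groups[i].mt, "MT", float(mt_scores[i])) for i in sorted(mt_removed))

    survivors = [g for i, g in enumerate(groups) if i not in mt_removed]
    if n_st >= len(survivors):
        raise ValueError("insufficient groups left for the ST-side quantile")
    st_scores = _st_side_scores(survivors, fingerprints)
    st_rank = sorted(range(len(survivors)), key=lambda i: (-st_scores[i], survivors[i].mt))
    st_removed = set(st_rank[:n_st])
    manifest.extend((survivors[i].mt, "ST", float(st_scores[i])) for i in sorted(st_removed))

    out = [g for i, g in enumerate(survivors) if i not in st_removed]
    if return_manifest:
        return out, manifest
    return out


def apply_condition(
    groups: Sequence[MTGroup],
    fingerprints: Mapping[str, Fingerprint],
    config: ConditionConfig,
) -> List[MTGroup]:
    """Dispatch on the configured condition (FULL is the identity)."""
    if config.condition is Condition.FULL:
        return list(groups)
    if config.condition is Condition.RANDOM_REMOVAL:
        rng = np.random.default_rng(config.rng_seed)
        return random_removal(groups, config, rng)
    return nn_removal(groups, fingerprints, config)


def write_removal_manifest(manifest: Sequence[Tuple[str, str, float]], path) -> None:
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("group_mt\tside\tscore\n")
        for mt, side, score in manifest:
            fh.write(f"{mt}\t{side}\t{score:.17g}\n")
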