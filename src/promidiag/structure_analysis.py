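"""Analog-relationship detection and shared-MT-CPD target networks.

Analog detection is a deliberately simplified single-cut core-sharing
proxy: every acyclic single bond between heavy atoms is cut once, and
the larger fragment counts as a core when it outweighs the substituent
by a configurable heavy-atom ratio.  Two compounds are analogs when they
share at least one canonical core key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import networkx as nx

from promidiag.activity_data import CompoundRecord
from promidiag.errors import ConfigError, StructureError


@dataclass(frozen=True)
class AnalogConfig:
    min_core_to_substituent_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.min_core_to_substituent_ratio < 1.0:
            raise ConfigError(
                f"min_core_to_substituent_ratio must be >= 1, got {self.min_core_to_substituent_ratio}"
            )


def fragment_cores(smiles: str, config: AnalogConfig = AnalogConfig()) -> Set[str]:
    """Canonical core keys from single cuts of acyclic single bonds.

    Each cuttable bond (acyclic single bond between heavy atoms) is broken
    with dummy-atom attachment points; the larger fragment is emitted as a
    core key iff its heavy-atom count is at least ``ratio`` times the
    substituent's.  Keys are canonical SMILES with the attachment marker.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    keys: Set[str] = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        # uniform dummy labels: the attachment marker must not encode bond index
        frag_mol = Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)])
        frags = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
        if len(frags) != 2:
            continue  # cutting a bond in a macrocycle-free acyclic bond always splits; guard anyway
        heavy = [sum(1 for a in f.GetAtoms() if a.GetAtomicNum() > 1) for f in frags]
        core_idx = 0 if heavy[0] >= heavy[1] else 1
        sub_idx = 1 - core_idx
        if heavy[core_idx] >= config.min_core_to_substituent_ratio * heavy[sub_idx]:
            keys.add(Chem.MolToSmiles(frags[core_idx]))
    return keys


def analog_fraction(
    compounds: Sequence[CompoundRecord], config: AnalogConfig = AnalogConfig()
) -> float:
    """Fraction of compounds sharing at least one core key with another compound."""
    if not compounds:
        raise ValueError("empty compound list")
    core_sets: List[Set[str]] = []
    for rec in compounds:
        if rec.smiles is None:
            raise StructureError(f"compound {rec.id} has no structure")
        core_sets.append(fragment_cores(rec.smiles, config))
    key_owners: Dict[str, int] = {}
    for keys in core_sets:
        for k in keys:
            key_owners[k] = key_owners.get(k, 0) + 1
    n_analog = sum(1 for keys in core_sets if any(key_owners[k] > 1 for k in keys))
    return n_analog / len(compounds)


def analog_fraction_from_series(series_labels: Mapping[str, Optional[int]]) -> float:
    """Ground-truth analog fraction for fingerprint-only synthetic libraries.

    A compound is in an analog relationship iff it belongs to a series with
    at least one other member; singletons (``None``) never are.
    """
    if not series_labels:
        raise ValueError("empty series-label map")
    counts: Dict[int, int] = {}
    for s in series_labels.values():
        if s is not None:
            counts[s] = counts.get(s, 0) + 1
    n_analog = sum(
        1 for s in series_labels.values() if s is not None and counts[s] > 1
    )
    return n_analog / len(series_labels)


def build_target_network(
    mt_target_map: Mapping[str, Set[str]], min_shared: int = 50
) -> nx.Graph:
    """Targets as nodes (weight = MT-CPD count), edges for >= min_shared shared MT-CPDs."""
    for compound, targets in mt_target_map.items():
        if len(targets) < 2:
            raise ValueError(f"compound {compound} has fewer than 2 targets")
    graph = nx.Graph()
    per_target: Dict[str, Set[str]] = {}
    for compound, targets in mt_target_map.items():
        for t in targets:
            per_target.setdefault(t, set()).add(compound)
    for t, members in per_target.items():
        graph.add_node(t, mt_cpd_count=len(members))
    targets = sorted(per_target)
    for i, t in enumerate(targets):
        for u in targets[i + 1 :]:
            shared = len(per_target[t] & per_target[u])
            if shared >= min_shared:
                graph.add_edge(t, u, weight=shared)
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("target_a\ttarget_b\tshared_count\n")
        rows = sorted(tuple(sorted((a, b))) + (data["weight"],) for a, b, data in graph.edges(data=True))
        for a, b, weight in rows:
            fh.write(f"{a}\t{b}\t{weight}\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def apply_node_annotations(graph: nx.Graph, annotations: Mapping[str, str], attr: str = "function") -> None:
    """Attach optional per-target annotations (e.g. protein function) as node attributes."""
    for node in graph.nodes:
        if node in annotations:
            graph.nodes[node][attr] = annotations[node]
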