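"""Fingerprints, Tanimoto similarity, and nearest-neighbor profiling.

The default provider computes a radius-2 circular (Morgan) fingerprint
folded to 2048 bits via RDKit; a precomputed-bitstring path lets the rest
of the pipeline run without any chemistry toolkit.  All compound
comparison downstream is Tanimoto-based; distance is 1 - Tanimoto.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from promidiag.errors import MalformedRecordError, StructureError

MT = "MT"
ST = "ST"

MORGAN = "morgan_r2"
MACCS = "maccs"
PRECOMPUTED = "precomputed"


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary vector for one compound."""

    bits: np.ndarray
    n_bits: int = 2048
    provider_tag: str = PRECOMPUTED

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1 or arr.size != self.n_bits:
            raise ValueError(f"bits must be a flat vector of length {self.n_bits}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("bits must be binary")
        arr.setflags(write=False)
        object.__setattr__(self, "bits", arr)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    @classmethod
    def from_on_bits(cls, on_bits: Iterable[int], n_bits: int = 2048, provider_tag: str = PRECOMPUTED) -> "Fingerprint":
        arr = np.zeros(n_bits, dtype=np.uint8)
        arr[list(on_bits)] = 1
        return cls(bits=arr, n_bits=n_bits, provider_tag=provider_tag)

    @classmethod
    def from_bitstring(cls, s: str, provider_tag: str = PRECOMPUTED) -> "Fingerprint":
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0")
        return cls(bits=arr, n_bits=len(s), provider_tag=provider_tag)

    def to_bitstring(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)


def compute_fingerprint(smiles: str, provider: str = MORGAN, n_bits: int = 2048) -> Fingerprint:
    """Compute a fingerprint from a SMILES string via RDKit.

    ``morgan_r2`` gives the radius-2 circular fingerprint folded to
    ``n_bits``; ``maccs`` gives the 167-bit structural-key fingerprint
    (control representation, length fixed by the key set).
    """
    from rdkit import Chem  # deferred: precomputed path needs no chemistry toolkit

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    if provider == MORGAN:
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        bv = gen.GetFingerprint(mol)
        arr = np.zeros(n_bits, dtype=np.uint8)
        arr[list(bv.GetOnBits())] = 1
        return Fingerprint(bits=arr, n_bits=n_bits, provider_tag=MORGAN)
    if provider == MACCS:
        from rdkit.Chem import MACCSkeys

        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
        arr[list(bv.GetOnBits())] = 1
        return Fingerprint(bits=arr, n_bits=bv.GetNumBits(), provider_tag=MACCS)
    raise ValueError(f"unknown fingerprint provider {provider!r}")


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; defined as 0 when both vectors are all-zero."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.bitwise_and(a.bits, b.bits).sum())
    union = int(np.bitwise_or(a.bits, b.bits).sum())
    if union == 0:
        return 0.0
    return inter / union


def pack_fingerprints(
    fingerprints: Mapping[str, Fingerprint], ids: Sequence[str]
) -> np.ndarray:
    """Stack fingerprints for ``ids`` into an (n, n_bits) uint8 matrix."""
    lengths = {fingerprints[i].n_bits for i in ids}
    if len(lengths) > 1:
        raise ValueError(f"mixed fingerprint lengths: {sorted(lengths)}")
    return np.stack([fingerprints[i].bits for i in ids]).astype(np.uint8)


def tanimoto_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of two binary matrices (0/0 pairs -> 0)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"bit-length mismatch: {x.shape[1]} vs {y.shape[1]}")
    inter = x @ y.T
    union = x.sum(axis=1)[:, None] + y.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sim


def nn_profile(
    fingerprints: Mapping[str, Fingerprint], labels: Mapping[str, str]
) -> pd.DataFrame:
    """Per-compound nearest-neighbor Tanimoto similarity to each class.

    For every compound, the maximum similarity (self excluded) to any
    other MT compound and to any other ST compound.  Requires >= 2
    compounds per class, so each compound has an own-class neighbor.
    """
    ids = sorted(labels)
    lab = np.array([labels[i] for i in ids])
    for cls in (MT, ST):
        if int((lab == cls).sum()) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; cannot profile its own-class NN")
    x = pack_fingerprints(fingerprints, ids)
    sim = tanimoto_matrix(x, x)
    np.fill_diagonal(sim, -np.inf)
    mt_cols = lab == MT
    st_cols = lab == ST
    nn_mt = sim[:, mt_cols].max(axis=1)
    nn_st = sim[:, st_cols].max(axis=1)
    # a compound whose own class has only itself in a column subset cannot
    # occur here (guarded above), but a lone cross-class max of -inf can't
    # either since both classes have >= 2 members
    return pd.DataFrame(
        {"id": ids, "label": lab, "sim_nn_mt": nn_mt, "sim_nn_st": nn_st}
    )


def export_nn_table(profile: pd.DataFrame, path) -> None:
    """Write the NN profile as TSV (id, label, sim_nn_mt, sim_nn_st)."""
    profile.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_nn_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})


def write_fingerprints(fingerprints: Mapping[str, Fingerprint], path) -> None:
    """Write fingerprints as TSV ``compound_id<TAB>bitstring`` (bit 0 leftmost)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for cid in sorted(fingerprints):
            fh.write(f"{cid}\t{fingerprints[cid].to_bitstring()}\n")


def read_fingerprints(path) -> Dict[str, Fingerprint]:
    out: Dict[str, Fingerprint] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or set(parts[1]) - {"0", "1"}:
                raise MalformedRecordError(f"{path}:{lineno}: expected 'id<TAB>bitstring'")
            out[parts[0]] = Fingerprint.from_bitstring(parts[1])
    return out
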