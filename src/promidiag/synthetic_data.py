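"""Synthetic screening matrices and fingerprint libraries with planted structure.

The generator plants analog series (shared core bits plus per-compound
substituent bits) and assigns multi-target (MT) / single-target (ST)
roles either series-coherently (probability ``promiscuity_signal``) or
independently of series membership.  Coherent assignment yields the
nearest-neighbor asymmetry the analysis probes: MT compounds closer to
other MT compounds than to ST compounds, and vice versa.  At signal 0
fingerprints carry no label information and diagnostic ML sits at
chance level by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from promidiag.activity_data import (
    ACTIVE,
    INACTIVE,
    ActivityMatrix,
    write_activity_triplets,
)
from promidiag.chem_similarity import MT, ST, Fingerprint, write_fingerprints
from promidiag.errors import ConfigError

BACKGROUND = "background"


@dataclass(frozen=True)
class SimConfig:
    n_targets: int = 120
    n_series: int = 30
    series_size: Union[int, Tuple[int, ...]] = 8
    n_singletons: int = 40
    n_bits: int = 2048
    core_bits_per_series: int = 40
    core_bits_spread: float = 0.0
    substituent_bits_per_compound: int = 15
    promiscuity_signal: float = 1.0
    pd_mt: int = 5
    test_frequency_target: int = 90
    label_noise: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.core_bits_per_series + self.substituent_bits_per_compound > self.n_bits:
            raise ConfigError("core + substituent bits exceed fingerprint length")
        if not (0.0 <= self.core_bits_spread < 1.0):
            raise ConfigError(f"core_bits_spread must be in [0, 1), got {self.core_bits_spread}")
        if not (0.0 <= self.promiscuity_signal <= 1.0):
            raise ConfigError(f"promiscuity_signal must be in [0, 1], got {self.promiscuity_signal}")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ConfigError(f"label_noise must be in [0, 1], got {self.label_noise}")
        if self.pd_mt > self.n_targets:
            raise ConfigError(f"pd_mt {self.pd_mt} exceeds n_targets {self.n_targets}")
        if self.pd_mt < 2:
            raise ConfigError(f"pd_mt must be >= 2, got {self.pd_mt}")
        if self.test_frequency_target > self.n_targets:
            raise ConfigError("test_frequency_target exceeds n_targets")

    def series_sizes(self) -> List[int]:
        if isinstance(self.series_size, int):
            return [self.series_size] * self.n_series
        sizes = list(self.series_size)
        if len(sizes) != self.n_series:
            raise ConfigError("series_size sequence length must equal n_series")
        return sizes

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_targets": self.n_targets,
            "n_series": self.n_series,
            "series_size": self.series_size if isinstance(self.series_size, int) else list(self.series_size),
            "n_singletons": self.n_singletons,
            "n_bits": self.n_bits,
            "core_bits_per_series": self.core_bits_per_series,
            "core_bits_spread": self.core_bits_spread,
            "substituent_bits_per_compound": self.substituent_bits_per_compound,
            "promiscuity_signal": self.promiscuity_signal,
            "pd_mt": self.pd_mt,
            "test_frequency_target": self.test_frequency_target,
            "label_noise": self.label_noise,
            "rng_seed": self.rng_seed,
        }


@dataclass
class GroundTruth:
    """Per-compound generator truth: series membership and planted role."""

    series: Dict[str, Optional[int]] = field(default_factory=dict)
    planted: Dict[str, str] = field(default_factory=dict)
    mt_targets: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    series_core_bits: Dict[int, int] = field(default_factory=dict)

    @property
    def planted_mt(self) -> List[str]:
        return sorted(c for c, role in self.planted.items() if role == MT)

    @property
    def planted_st(self) -> List[str]:
        return sorted(c for c, role in self.planted.items() if role == ST)


def _target_names(n: int) -> List[str]:
    return [f"T{k:03d}" for k in range(n)]


def _series_flavor(si: int) -> str:
    # one fifth of series are MT-flavored
    return MT if si % 5 == 0 else ST


def _n_marker_bits(n_bits: int) -> int:
    return min(16, n_bits // 32)


def simulate_library(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[Dict[str, Fingerprint], GroundTruth]:
    """Generate analog-series fingerprints plus singletons.

    Each series draws a shared core bit-set; members add private
    substituent bits; singletons draw fully random bit-sets of the same
    total popcount, so within-series similarity exceeds between-series
    similarity in expectation.  With ``core_bits_spread`` > 0, per-series
    core sizes vary uniformly around the configured mean, yielding a
    spectrum of within-series tightness (some series NN-dense, some
    loose) as NN-based ablation assumes.

    A small reserved block of *marker* bits is weakly enriched in
    MT-flavored series members (on with probability 0.3 vs 0.1
    elsewhere), emulating weak global promiscuity-associated features:
    individually uninformative for nearest-neighbor ranking but usable
    by feature-weighting learners.
    """
    fingerprints: Dict[str, Fingerprint] = {}
    truth = GroundTruth()
    sizes = config.series_sizes()
    c_mean = config.core_bits_per_series
    n_markers = _n_marker_bits(config.n_bits)
    marker_bits = np.arange(config.n_bits - n_markers, config.n_bits)

    def draw_markers(p_on: float) -> np.ndarray:
        return marker_bits[rng.random(n_markers) < p_on]

    for si, size in enumerate(sizes):
        if config.core_bits_spread > 0:
            lo = max(2, int(round(c_mean * (1 - config.core_bits_spread))))
            hi = min(config.n_bits - config.substituent_bits_per_compound,
                     int(round(c_mean * (1 + config.core_bits_spread))))
            n_core = int(rng.integers(lo, hi + 1))
        else:
            n_core = c_mean
        truth.series_core_bits[si] = n_core
        core = rng.choice(config.n_bits, size=n_core, replace=False)
        rest = np.setdiff1d(np.arange(config.n_bits), core)
        p_marker = 0.3 if _series_flavor(si) == MT else 0.1
        for mi in range(size):
            sub = rng.choice(rest, size=config.substituent_bits_per_compound, replace=False)
            cid = f"S{si:03d}C{mi:03d}"
            on = np.unique(np.concatenate([core, sub, draw_markers(p_marker)]))
            fingerprints[cid] = Fingerprint.from_on_bits(on, n_bits=config.n_bits)
            truth.series[cid] = si
            truth.planted[cid] = BACKGROUND
    n_on = config.core_bits_per_series + config.substituent_bits_per_compound
    for xi in range(config.n_singletons):
        cid = f"X{xi:03d}"
        on = rng.choice(config.n_bits, size=n_on, replace=False)
        on = np.unique(np.concatenate([on, draw_markers(0.1)]))
        fingerprints[cid] = Fingerprint.from_on_bits(on, n_bits=config.n_bits)
        truth.series[cid] = None
        truth.planted[cid] = BACKGROUND
    return fingerprints, truth


def _planted_target_pool(config: SimConfig) -> List[str]:
    # confined enough that target sets overlap (so matched ST-CPDs exist),
    # wide enough that independent groups rarely contend for the same ST
    pool_size = min(config.n_targets, max(config.pd_mt, 6 * config.pd_mt))
    return _target_names(config.n_targets)[:pool_size]


def simulate_activity(
    library: Tuple[Dict[str, Fingerprint], GroundTruth],
    config: SimConfig,
    rng: np.random.Generator,
) -> ActivityMatrix:
    """Plant MT/ST roles and emit a complete, test-frequency-calibrated matrix.

    One fifth of the series are MT-flavored and the rest ST-flavored,
    keeping the ST-CPD supply several times larger than the MT-CPD count
    so matched ST-CPDs are plentiful (mirroring screening data, where
    single-target compounds far outnumber multi-target ones).  A series
    is *coherent* with probability ``promiscuity_signal`` scaled by its
    structural tightness (normalized expected within-series similarity):
    label agreement concentrates in close nearest-neighbor pairs, which
    is exactly the relationship NN-based ablation is designed to break.
    All members of a coherent series share the flavor's role (MT members
    share one target set of size ``pd_mt``; ST members share one
    target).  Members of incoherent series get roles drawn independently
    of series membership.  Singletons (structurally
    diverse compounds) get roles independently of structure by
    construction: 10% MT, 55% ST, the rest background, so MT compounds
    form analog relationships more often than ST compounds.  Every
    planted compound is explicitly tested (inactive) on the whole
    planted-target pool, which guarantees group completeness before
    noise; remaining tested cells are filled with inactives to approach
    ``test_frequency_target``; label noise then flips recorded outcomes
    in place.
    """
    fingerprints, truth = library
    pool = _planted_target_pool(config)
    all_targets = _target_names(config.n_targets)
    matrix = ActivityMatrix()

    def plant_mt(cid: str, targets: Sequence[str]) -> None:
        truth.planted[cid] = MT
        truth.mt_targets[cid] = tuple(sorted(targets))
        for t in pool:
            matrix.add(cid, t, ACTIVE if t in targets else INACTIVE)

    def plant_st(cid: str, target: str) -> None:
        truth.planted[cid] = ST
        for t in pool:
            matrix.add(cid, t, ACTIVE if t == target else INACTIVE)

    def random_mt_targets() -> List[str]:
        return list(rng.choice(pool, size=config.pd_mt, replace=False))

    sizes = config.series_sizes()
    member_ids = {
        si: [f"S{si:03d}C{mi:03d}" for mi in range(size)] for si, size in enumerate(sizes)
    }
    def tightness(si: int) -> float:
        if config.core_bits_spread <= 0:
            return 1.0
        sub2 = 2 * config.substituent_bits_per_compound
        c = truth.series_core_bits.get(si, config.core_bits_per_series)
        lo = max(2, int(round(config.core_bits_per_series * (1 - config.core_bits_spread))))
        hi = int(round(config.core_bits_per_series * (1 + config.core_bits_spread)))
        sim = c / (c + sub2)
        sim_lo, sim_hi = lo / (lo + sub2), hi / (hi + sub2)
        if sim_hi <= sim_lo:
            return 1.0
        return float(np.clip((sim - sim_lo) / (sim_hi - sim_lo), 0.0, 1.0))

    for si in range(config.n_series):
        flavor = _series_flavor(si)
        coherent = rng.random() < config.promiscuity_signal * (0.15 + 0.85 * tightness(si))
        if coherent and flavor == MT:
            targets = random_mt_targets()
            for cid in member_ids[si]:
                plant_mt(cid, targets)
        elif coherent and flavor == ST:
            target = str(rng.choice(pool))
            for cid in member_ids[si]:
                plant_st(cid, target)
        else:
            # roles independent of series membership (ST-heavy marginal)
            for cid in member_ids[si]:
                if rng.random() < 0.2:
                    plant_mt(cid, random_mt_targets())
                else:
                    plant_st(cid, str(rng.choice(pool)))

    # singletons: structure-independent roles (6% MT / 60% ST / 34% background)
    for cid in sorted(truth.series):
        if truth.series[cid] is not None:
            continue
        u = rng.random()
        if u < 0.06:
            plant_mt(cid, random_mt_targets())
        elif u < 0.66:
            plant_st(cid, str(rng.choice(pool)))
        else:
            for t in pool:
                matrix.add(cid, t, INACTIVE)

    # fill toward the per-compound test-frequency target with inactives
    extra_targets = [t for t in all_targets if t not in set(pool)]
    for cid in sorted(fingerprints):
        deficit = config.test_frequency_target - matrix.test_frequency(cid)
        if deficit <= 0 or not extra_targets:
            continue
        jitter = int(rng.integers(-max(1, deficit // 10), max(1, deficit // 10) + 1))
        n_extra = int(np.clip(deficit + jitter, 0, len(extra_targets)))
        for t in rng.choice(extra_targets, size=n_extra, replace=False):
            matrix.add(cid, str(t), INACTIVE)

    if config.label_noise > 0:
        noisy = ActivityMatrix()
        for compound, target, outcome in matrix.iter_outcomes():
            if rng.random() < config.label_noise:
                outcome = ACTIVE if outcome == INACTIVE else INACTIVE
            noisy.add(compound, target, outcome)
        matrix = noisy
    return matrix


def generate_benchmark(
    config: SimConfig,
    out_dir,
    rng: Optional[np.random.Generator] = None,
    flagged_fraction: float = 0.0,
) -> Dict[str, Path]:
    """Write a self-describing input bundle (matrix, fingerprints, flags, truth, manifest)."""
    from promidiag.activity_data import CompoundFlag

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    fingerprints, truth = simulate_library(config, rng)
    matrix = simulate_activity((fingerprints, truth), config, rng)

    paths = {
        "matrix": out_dir / "activity_triplets.tsv",
        "fingerprints": out_dir / "fingerprints.tsv",
        "flags": out_dir / "flags.tsv",
        "ground_truth": out_dir / "ground_truth.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_activity_triplets(matrix, paths["matrix"])
    write_fingerprints(fingerprints, paths["fingerprints"])

    flags = sorted(CompoundFlag, key=lambda f: f.value)
    flagged: List[Tuple[str, str]] = []
    if flagged_fraction > 0:
        ids = sorted(fingerprints)
        n_flag = int(np.floor(flagged_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_flag, replace=False)
        for i in sorted(chosen.tolist()):
            flag = flags[int(rng.integers(len(flags)))]
            flagged.append((ids[i], flag.value))
    with paths["flags"].open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tflag\n")
        for cid, flag in flagged:
            fh.write(f"{cid}\t{flag}\n")

    with paths["ground_truth"].open("w", encoding="utf-8") as fh:
        fh.write("compound_id\tseries\tplanted_class\tmt_targets\n")
        for cid in sorted(truth.series):
            series = "" if truth.series[cid] is None else str(truth.series[cid])
            targets = ",".join(truth.mt_targets.get(cid, ()))
            fh.write(f"{cid}\t{series}\t{truth.planted[cid]}\t{targets}\n")

    with paths["manifest"].open("w", encoding="utf-8") as fh:
        json.dump(
            {"schema_version": 1, "config": config.to_dict(), "flagged_fraction": flagged_fraction},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def read_ground_truth(path) -> GroundTruth:
    truth = GroundTruth()
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, series, planted, targets = line.split("\t")
            truth.series[cid] = int(series) if series else None
            truth.planted[cid] = planted
            if targets:
                truth.mt_targets[cid] = tuple(targets.split(","))
    return truth
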