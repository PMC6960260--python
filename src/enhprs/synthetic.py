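"""Motif-planted synthetic DNA with the statistical structure PRS assumes.

The pretraining–retraining strategy presumes a large class of broadly
active enhancers sharing common sequence signals, and small tissue classes
that carry those shared signals *plus* a tissue-private signal.  This
module emulates exactly that: position-weight-matrix (PWM) motifs planted
into i.i.d. background DNA.

* the pretraining set: positives carry each *shared* motif independently
  with its planting probability; negatives are pure background, at a 1:10
  positive:negative ratio;
* a tissue set: positives carry the shared motifs plus one tissue-private
  motif; small positive count, same ratio;
* a synthetic activity matrix whose designated "housekeeping" and
  "tissue-active" rows are recoverable exactly by the TPM filters.

Every generated record carries machine-readable ground truth (planted
motif names and positions) sufficient to recompute its label.  The
generator makes no attempt to model eRNA expression biology or real TPM
distributions beyond the cutoff structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import (
    EnhancerActivityMatrix,
    GenomicRegion,
    LabeledSequenceSet,
    SequenceRecord,
)

__all__ = [
    "MotifModel",
    "SyntheticSpec",
    "SyntheticDataset",
    "ActivityMatrixTruth",
    "default_spec",
    "pwm_from_consensus",
    "generate_background",
    "plant",
    "generate_pretraining_set",
    "generate_tissue_set",
    "generate_activity_matrix",
    "random_genome",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class MotifModel:
    """A PWM motif: one column-stochastic length-4 probability row per
    position, plus the fraction of positives that carry an instance."""

    name: str
    pwm: np.ndarray  # (width, 4); each position's probabilities sum to 1
    planting_probability: float = 0.8

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[1] != 4 or pwm.shape[0] < 4:
            raise ValueError("PWM must be (width >= 4) x 4")
        if np.any(pwm < 0) or not np.allclose(pwm.sum(axis=1), 1.0):
            raise ValueError("each PWM position must be a probability vector")
        if not (0 < self.planting_probability <= 1):
            raise ValueError("planting_probability must be in (0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.pwm.argmax(axis=1))


def pwm_from_consensus(name: str, consensus: str, match_prob: float = 0.85,
                       planting_probability: float = 0.8) -> MotifModel:
    """PWM giving ``match_prob`` to the consensus base at each position."""
    off = (1.0 - match_prob) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        pwm[i, _BASES.index(b)] = match_prob
    return MotifModel(name=name, pwm=pwm, planting_probability=planting_probability)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings: motifs, background composition, and sizes.

    Defaults mirror the study structure at desk scale: three shared motifs
    planted with probability 0.8, one private motif per tissue at 0.9,
    human-like background GC of 0.42, 600 pretraining positives and 200
    tissue positives at a 1:10 positive:negative ratio.
    """

    shared_motifs: tuple[MotifModel, ...]
    tissue_motifs: dict[str, MotifModel]
    gc: float = 0.42
    length: int = 1000
    n_pretrain_pos: int = 600
    n_tissue_pos: int = 200
    ratio: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if min(self.n_pretrain_pos, self.n_tissue_pos) < 1:
            raise ValueError("positive counts must be >= 1")
        for m in list(self.shared_motifs) + list(self.tissue_motifs.values()):
            if m.width > self.length:
                raise ValueError(f"motif {m.name} wider than sequence length")


_SHARED_CONSENSI = ("TGACTCAC", "CACGTGTTAC", "GGGGCGGGGTTA")
_TISSUE_CONSENSI = ("ATGCAAAT", "TTTGCGCAAC", "CAGCTGTTGG")


def default_spec(profile: str = "fast", seed: int = 0, n_tissues: int = 3) -> SyntheticSpec:
    """The default generator conditions.

    ``profile="full"`` uses 1000 bp sequences; ``"fast"`` uses 200 bp,
    preserving the motif structure while keeping training cheap.
    """
    if profile not in ("fast", "full"):
        raise ValueError("profile must be 'fast' or 'full'")
    if not (1 <= n_tissues <= len(_TISSUE_CONSENSI)):
        raise ValueError(f"n_tissues must be in [1, {len(_TISSUE_CONSENSI)}]")
    shared = tuple(
        pwm_from_consensus(f"shared_{i}", c, planting_probability=0.8)
        for i, c in enumerate(_SHARED_CONSENSI)
    )
    tissues = {
        f"tissue_{i}": pwm_from_consensus(f"private_{i}", c, planting_probability=0.9)
        for i, c in enumerate(_TISSUE_CONSENSI[:n_tissues])
    }
    return SyntheticSpec(
        shared_motifs=shared,
        tissue_motifs=tissues,
        length=200 if profile == "fast" else 1000,
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    """A labeled set plus per-record planting ground truth."""

    sequences: LabeledSequenceSet
    ground_truth: dict[str, list[tuple[str, int]]]  # id -> [(motif name, position)]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.sequences.records:
            planted = self.ground_truth.get(rec.id, [])
            rows.append({
                "id": rec.id, "label": rec.label,
                "motifs": ";".join(f"{n}@{p}" for n, p in planted) or ".",
            })
        return pd.DataFrame(rows)

    def write_manifest(self, path) -> None:
        self.truth_frame().to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=(n, length), p=p)


def _to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def generate_background(n: int, length: int, gc: float, seed: int,
                        id_prefix: str = "bg") -> LabeledSequenceSet:
    """i.i.d. background DNA with P(G)+P(C)=gc split equally; label 0."""
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    codes = _random_seq(rng, n, length, gc)
    records = [
        SequenceRecord(f"{id_prefix}_{i}", _to_str(codes[i]), 0) for i in range(n)
    ]
    return LabeledSequenceSet(records=records, fixed_length=length)


def plant(seq: str, motif: MotifModel, rng_or_seed) -> tuple[str, int]:
    """Write one PWM-sampled motif instance at a uniform random position.

    Returns the modified sequence and the planted start position.
    """
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    w = motif.width
    if w > len(seq):
        raise ValueError("motif wider than sequence")
    pos = int(rng.integers(0, len(seq) - w + 1))
    instance = "".join(
        _BASES[rng.choice(4, p=motif.pwm[i])] for i in range(w)
    )
    return seq[:pos] + instance + seq[pos + w:], pos


def _plant_all(
    seq: str, motifs: list[MotifModel], rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Plant each motif independently with its probability, avoiding
    overlaps between planted instances where possible (20 retries)."""
    planted: list[tuple[str, int]] = []
    occupied: list[tuple[int, int]] = []
    for motif in motifs:
        if rng.random() >= motif.planting_probability:
            continue
        w = motif.width
        pos = None
        for _ in range(20):
            cand = int(rng.integers(0, len(seq) - w + 1))
            if all(cand + w <= s or cand >= e for s, e in occupied):
                pos = cand
                break
        if pos is None:  # crowded sequence: accept an overlap
            pos = int(rng.integers(0, len(seq) - w + 1))
        instance = "".join(_BASES[rng.choice(4, p=motif.pwm[i])] for i in range(w))
        seq = seq[:pos] + instance + seq[pos + w:]
        occupied.append((pos, pos + w))
        planted.append((motif.name, pos))
    return seq, planted


def _generate_set(
    spec: SyntheticSpec,
    motifs: list[MotifModel],
    n_pos: int,
    id_prefix: str,
    seed: int,
) -> SyntheticDataset:
    rng = np.random.default_rng(seed)
    n_neg = n_pos * spec.ratio
    pos_codes = _random_seq(rng, n_pos, spec.length, spec.gc)
    neg_codes = _random_seq(rng, n_neg, spec.length, spec.gc)
    records: list[SequenceRecord] = []
    truth: dict[str, list[tuple[str, int]]] = {}
    for i in range(n_pos):
        seq, planted = _plant_all(_to_str(pos_codes[i]), motifs, rng)
        rid = f"{id_prefix}_pos_{i}"
        records.append(SequenceRecord(rid, seq, 1))
        truth[rid] = planted
    for i in range(n_neg):
        rid = f"{id_prefix}_neg_{i}"
        records.append(SequenceRecord(rid, _to_str(neg_codes[i]), 0))
        truth[rid] = []
    return SyntheticDataset(
        sequences=LabeledSequenceSet(records=records, fixed_length=spec.length),
        ground_truth=truth,
    )


def generate_pretraining_set(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Positives carry each shared motif independently with its planting
    probability; negatives are pure background at the imbalance ratio."""
    return _generate_set(
        spec, list(spec.shared_motifs), spec.n_pretrain_pos, "pre",
        spec.seed if seed is None else seed,
    )


def generate_tissue_set(
    spec: SyntheticSpec, tissue: str, seed: int | None = None
) -> SyntheticDataset:
    """Positives carry the shared motifs plus the tissue's private motif."""
    if tissue not in spec.tissue_motifs:
        raise KeyError(
            f"unknown tissue {tissue!r}; available: {sorted(spec.tissue_motifs)}"
        )
    base = spec.seed if seed is None else seed
    t_index = sorted(spec.tissue_motifs).index(tissue)
    rng_seed = int(np.random.default_rng([base, 7919, t_index]).integers(0, 2**31))
    motifs = list(spec.shared_motifs) + [spec.tissue_motifs[tissue]]
    return _generate_set(spec, motifs, spec.n_tissue_pos, tissue, rng_seed)


@dataclass
class ActivityMatrixTruth:
    """A synthetic activity matrix with its designated ground-truth rows."""

    matrix: EnhancerActivityMatrix
    housekeeping_rows: list[int]
    tissue_active_rows: dict[str, list[int]]


def generate_activity_matrix(
    spec: SyntheticSpec,
    n_regions: int,
    n_samples: int,
    seed: int | None = None,
    housekeeping_fraction: float = 0.2,
    tissue_active_per_sample: int | None = None,
) -> ActivityMatrixTruth:
    """TPM matrix whose designated rows are exactly recoverable by filters.

    Designated housekeeping rows have every entry nonzero, >= 0.08 and
    < 0.8; designated tissue-active rows exceed 0.8 in exactly one sample
    and keep at least one entry below 0.08 elsewhere (so they fail the
    housekeeping criterion); all remaining rows stay below both cutoffs.
    Applying the pretraining and per-tissue filters therefore recovers the
    designated rows exactly.
    """
    if n_regions < 1 or n_samples < 2:
        raise ValueError("need n_regions >= 1 and n_samples >= 2")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_house = max(1, int(round(housekeeping_fraction * n_regions)))
    per_sample = tissue_active_per_sample
    if per_sample is None:
        per_sample = max(1, (n_regions - n_house) // (4 * n_samples))
    need = n_house + per_sample * n_samples
    if need > n_regions:
        raise ValueError(
            f"{n_regions} regions cannot hold {n_house} housekeeping + "
            f"{per_sample} x {n_samples} tissue-active designations"
        )

    perm = rng.permutation(n_regions)
    house = sorted(int(i) for i in perm[:n_house])
    tissue_rows: dict[str, list[int]] = {}
    cursor = n_house
    sample_names = [f"sample_{j}" for j in range(n_samples)]
    for name in sample_names:
        tissue_rows[name] = sorted(int(i) for i in perm[cursor:cursor + per_sample])
        cursor += per_sample

    tpm = np.zeros((n_regions, n_samples))
    background = rng.random((n_regions, n_samples))
    low = rng.uniform(0.005, 0.07, size=(n_regions, n_samples))
    tpm[background < 0.4] = low[background < 0.4]  # sparse sub-cutoff noise

    for i in house:
        tpm[i] = rng.uniform(0.1, 0.79, size=n_samples)
    for j, name in enumerate(sample_names):
        for i in tissue_rows[name]:
            row = np.where(rng.random(n_samples) < 0.5,
                           rng.uniform(0.005, 0.07, size=n_samples), 0.0)
            row[j] = rng.uniform(0.81, 5.0)
            # guarantee one sub-0.08 nonzero entry so the row fails TPM_min
            other = (j + 1) % n_samples
            row[other] = rng.uniform(0.005, 0.07)
            tpm[i] = row

    regions = []
    for i in range(n_regions):
        start = 1000 + i * 2000
        length = int(rng.integers(150, 1001))
        regions.append(GenomicRegion("chrS", start, start + length))
    matrix = EnhancerActivityMatrix(regions=regions, sample_names=sample_names, tpm=tpm)
    return ActivityMatrixTruth(
        matrix=matrix, housekeeping_rows=house, tissue_active_rows=tissue_rows
    )


def random_genome(chrom_lengths: dict[str, int], gc: float = 0.42,
                  seed: int = 0) -> dict[str, str]:
    """Random chromosomes as plain strings (toy genomes for tests/demos)."""
    rng = np.random.default_rng(seed)
    return {
        name: _to_str(_random_seq(rng, 1, length, gc)[0])
        for name, length in chrom_lengths.items()
    }
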