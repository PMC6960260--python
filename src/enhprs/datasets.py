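"""Dataset construction for enhancer classification.

Builds pretraining and tissue-specific sequence sets from an enhancer
activity matrix (regions x tissues, TPM units, as produced by CAGE-based
eRNA quantification), a reference genome in FASTA, and pre-flattened
exclusion intervals in BED.  The pipeline mirrors the standard recipe for
FANTOM5-style data:

1. select positive regions by TPM cutoffs (a "housekeeping" set by minimum
   nonzero TPM across all samples, and per-tissue sets by a single-column
   cutoff);
2. drop regions shorter than a minimum length and fix every positive to a
   constant window length centred on the region midpoint;
3. reduce sequence redundancy by greedy identity clustering;
4. draw length-matched negative windows uniformly from intergenic space
   (genome minus exclusions), at a 1:10 positive:negative ratio.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "EnhancerActivityMatrix",
    "SequenceRecord",
    "LabeledSequenceSet",
    "SplitSpec",
    "FixLengthResult",
    "parse_activity_matrix",
    "select_pretraining_enhancers",
    "select_tissue_enhancers",
    "fix_length",
    "reduce_redundancy",
    "ungapped_identity",
    "sample_negatives",
    "make_splits",
    "make_kfold",
]

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomicRegion:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @classmethod
    def from_string(cls, s: str) -> "GenomicRegion":
        """Parse a ``chrom:start-end`` region id."""
        try:
            chrom, rest = s.split(":", 1)
            start_s, end_s = rest.split("-", 1)
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"malformed region id {s!r}; expected 'chrom:start-end'") from exc
        return cls(chrom=chrom, start=start, end=end)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class EnhancerActivityMatrix:
    """Regions x samples TPM table driving positive-set selection."""

    regions: list[GenomicRegion]
    sample_names: list[str]
    tpm: np.ndarray  # shape (n_regions, n_samples), non-negative

    def __post_init__(self) -> None:
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.regions), len(self.sample_names)):
            raise ValueError(
                f"TPM shape {self.tpm.shape} does not match "
                f"{len(self.regions)} regions x {len(self.sample_names)} samples"
            )
        if np.any(self.tpm < 0):
            raise ValueError("TPM values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpm.shape

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.tpm, index=[str(r) for r in self.regions], columns=self.sample_names
        )
        df.to_csv(path, sep="\t", index_label="region")


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str
    label: int
    source_region: GenomicRegion | None = None


@dataclass
class LabeledSequenceSet:
    """Fixed-length DNA records with binary labels and provenance."""

    records: list[SequenceRecord]
    fixed_length: int

    def __post_init__(self) -> None:
        ids = set()
        for rec in self.records:
            if len(rec.sequence) != self.fixed_length:
                raise ValueError(
                    f"record {rec.id}: length {len(rec.sequence)} != fixed_length {self.fixed_length}"
                )
            if rec.label not in (0, 1):
                raise ValueError(f"record {rec.id}: label must be 0 or 1")
            if rec.id in ids:
                raise ValueError(f"duplicate record id {rec.id}")
            ids.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Iterable[int]) -> "LabeledSequenceSet":
        return LabeledSequenceSet(
            records=[self.records[i] for i in indices], fixed_length=self.fixed_length
        )

    def concat(self, other: "LabeledSequenceSet") -> "LabeledSequenceSet":
        if other.fixed_length != self.fixed_length:
            raise ValueError("cannot concatenate sets of differing fixed_length")
        return LabeledSequenceSet(
            records=self.records + other.records, fixed_length=self.fixed_length
        )

    def write_fasta(self, path: str | Path) -> None:
        """FASTA with the label encoded in the description (``label=1``)."""
        with open(path, "w") as fh:
            for rec in self.records:
                src = f" source={rec.source_region}" if rec.source_region else ""
                fh.write(f">{rec.id} label={rec.label}{src}\n{rec.sequence}\n")

    def write_manifest(self, path: str | Path) -> None:
        rows = []
        for rec in self.records:
            r = rec.source_region
            rows.append(
                {
                    "id": rec.id,
                    "chrom": r.chrom if r else ".",
                    "start": r.start if r else -1,
                    "end": r.end if r else -1,
                    "label": rec.label,
                    "source": "region" if r else "synthetic",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_fasta(cls, path: str | Path) -> "LabeledSequenceSet":
        records: list[SequenceRecord] = []
        header: str | None = None
        chunks: list[str] = []

        def flush() -> None:
            if header is None:
                return
            fields = header.split()
            rid = fields[0]
            label = 0
            region = None
            for f in fields[1:]:
                if f.startswith("label="):
                    label = int(f[len("label="):])
                elif f.startswith("source="):
                    try:
                        region = GenomicRegion.from_string(f[len("source="):])
                    except ValueError:
                        region = None
            records.append(SequenceRecord(rid, "".join(chunks).upper(), label, region))

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    header = line[1:]
                    chunks = []
                else:
                    chunks.append(line)
            flush()
        if not records:
            raise ValueError(f"no records in {path}")
        lengths = {len(r.sequence) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"mixed sequence lengths in {path}: {sorted(lengths)}")
        return cls(records=records, fixed_length=lengths.pop())


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 10/12, 1/12, 1/12) or k folds."""

    train_fraction: Fraction = Fraction(10, 12)
    val_fraction: Fraction = Fraction(1, 12)
    test_fraction: Fraction = Fraction(1, 12)
    k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(Fraction(f) <= 0 for f in fracs):
            raise ValueError("all fractions must be > 0")
        if sum(Fraction(f) for f in fracs) != 1:
            raise ValueError(f"fractions must sum to 1, got {fracs}")
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2")


# ---------------------------------------------------------------------------
# Activity matrix parsing and positive-region selection
# ---------------------------------------------------------------------------

def parse_activity_matrix(
    path: str | Path, sample_name_map: str | Path | None = None
) -> EnhancerActivityMatrix:
    """Read a tab-separated activity matrix.

    The first column holds region ids as ``chrom:start-end`` strings; the
    header row names the samples.  ``sample_name_map`` optionally points to a
    two-column TSV mapping raw library ids to tissue names.

    Raises ``ValueError`` naming the offending row/column on non-numeric
    cells, duplicate region ids, or malformed regions.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no header (empty file)") from exc
    if df.columns.size == 0:
        raise ValueError(f"{path}: no sample columns found")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate region id(s): {dups}")

    regions = []
    for line_no, rid in enumerate(df.index, start=2):  # header is line 1
        try:
            regions.append(GenomicRegion.from_string(str(rid)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric TPM value {df.loc[row, col]!r} "
                f"at region {row}, sample {col}"
            )
        values[:, j] = converted.to_numpy()
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing TPM at region {df.index[i]}, sample {df.columns[j]}")

    sample_names = [str(c) for c in df.columns]
    if sample_name_map is not None:
        mapping = pd.read_csv(sample_name_map, sep="\t", header=None, index_col=0)[1].to_dict()
        sample_names = [mapping.get(n, n) for n in sample_names]
    return EnhancerActivityMatrix(regions=regions, sample_names=sample_names, tpm=values)


def select_pretraining_enhancers(
    m: EnhancerActivityMatrix, tpm_min_cutoff: float = 0.08
) -> list[GenomicRegion]:
    """Regions whose minimum *nonzero* TPM across samples is >= the cutoff.

    This selects broadly ("housekeeping") active enhancers: an enhancer with
    even its weakest detected activity above the floor is active nearly
    everywhere it is detected.  All-zero rows carry no nonzero value and are
    excluded.
    """
    if tpm_min_cutoff < 0:
        raise ValueError("tpm_min_cutoff must be >= 0")
    if len(m.regions) == 0:
        raise ValueError("empty activity matrix")
    masked = np.where(m.tpm > 0, m.tpm, np.inf)
    min_nonzero = masked.min(axis=1)
    keep = (min_nonzero >= tpm_min_cutoff) & np.isfinite(min_nonzero)
    return [r for r, k in zip(m.regions, keep) if k]


def select_tissue_enhancers(
    m: EnhancerActivityMatrix, sample: str, tpm_cutoff: float = 0.8
) -> list[GenomicRegion]:
    """Regions strictly exceeding ``tpm_cutoff`` TPM in one named sample.

    The default 0.8 sits at the upper quartile of genome-wide enhancer TPM,
    so exceeding it marks the enhancer as clearly active in that tissue.
    """
    if sample not in m.sample_names:
        raise KeyError(
            f"unknown sample {sample!r}; available: {m.sample_names[:10]}"
            + ("..." if len(m.sample_names) > 10 else "")
        )
    j = m.sample_names.index(sample)
    keep = m.tpm[:, j] > tpm_cutoff
    return [r for r, k in zip(m.regions, keep) if k]


# ---------------------------------------------------------------------------
# Length fixing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixLengthResult:
    region: GenomicRegion
    sequence: str | None
    window: GenomicRegion | None
    reason: str | None

    @property
    def accepted(self) -> bool:
        return self.sequence is not None


def fix_length(
    region: GenomicRegion,
    genome,
    target: int = 1000,
    min_len: int = 100,
) -> FixLengthResult:
    """Extract a ``target``-bp window centred on the region midpoint.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sliceable
    sequence).  Regions shorter than ``min_len`` are rejected, as are windows
    overrunning a chromosome end (dropped rather than clipped, so every
    accepted sequence has exactly ``target`` bp).
    """
    if region.chrom not in genome:
        raise KeyError(f"chromosome {region.chrom!r} absent from genome")
    if len(region) < min_len:
        return FixLengthResult(region, None, None, "below minimum length")
    mid = region.midpoint
    start = mid - target // 2
    end = start + target
    chrom_len = len(genome[region.chrom])
    if start < 0 or end > chrom_len:
        return FixLengthResult(region, None, None, "window exceeds chromosome bounds")
    seq = str(genome[region.chrom][start:end]).upper()
    window = GenomicRegion(region.chrom, start, end, region.strand)
    return FixLengthResult(region, seq, window, None)


# ---------------------------------------------------------------------------
# Redundancy reduction (greedy identity clustering, CD-HIT style)
# ---------------------------------------------------------------------------

def ungapped_identity(a: str, b: str) -> float:
    """Best ungapped-offset identity: max over offsets of matching bases
    divided by the shorter sequence's length."""
    if not a or not b:
        return 0.0
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    la, lb = len(xa), len(xb)
    short = min(la, lb)
    best = 0
    # slide b along a: offset = position of b[0] relative to a[0]
    for off in range(-(lb - 1), la):
        a0 = max(0, off)
        b0 = max(0, -off)
        n = min(la - a0, lb - b0)
        if n <= best:  # cannot beat current best
            continue
        matches = int(np.count_nonzero(xa[a0:a0 + n] == xb[b0:b0 + n]))
        if matches > best:
            best = matches
    return best / short


def _kmer_set(seq: str, k: int = 8) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def reduce_redundancy(
    seqs: Sequence[str],
    identity_cutoff: float = 0.8,
    word_size: int = 8,
    use_external: bool = False,
) -> list[int]:
    """Greedy longest-first clustering; returns indices of retained sequences.

    A sequence is discarded if its identity to any already-retained
    representative is >= ``identity_cutoff``.  Identity is the ungapped
    best-offset match fraction over the shorter sequence; pairs sharing no
    ``word_size``-mer are assumed below the cutoff and skipped.  Ties in the
    longest-first ordering are broken by input order, making the result
    deterministic.

    With ``use_external=True`` and a ``cd-hit-est`` binary on PATH, the
    clustering is delegated to it instead.
    """
    if not (0 < identity_cutoff <= 1):
        raise ValueError("identity_cutoff must be in (0, 1]")
    if use_external and shutil.which("cd-hit-est"):
        return _reduce_redundancy_cdhit(seqs, identity_cutoff)

    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    retained: list[int] = []
    rep_kmers: list[set[str]] = []
    for i in order:
        s = seqs[i]
        km = _kmer_set(s, word_size)
        redundant = False
        for j, rj in enumerate(retained):
            if km and rep_kmers[j] and not (km & rep_kmers[j]):
                continue
            if ungapped_identity(s, seqs[rj]) >= identity_cutoff:
                redundant = True
                break
        if not redundant:
            retained.append(i)
            rep_kmers.append(km)
    return sorted(retained)


def _reduce_redundancy_cdhit(seqs: Sequence[str], cutoff: float) -> list[int]:
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        fout = Path(tmp) / "out.fa"
        with open(fin, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        subprocess.run(
            ["cd-hit-est", "-i", str(fin), "-o", str(fout), "-c", str(cutoff), "-n", "5"],
            check=True, capture_output=True,
        )
        kept = []
        with open(fout) as fh:
            for line in fh:
                if line.startswith(">"):
                    kept.append(int(line[2:].strip()))
    return sorted(kept)


# ---------------------------------------------------------------------------
# Negative sampling from intergenic space
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read 3+-column BED into per-chromosome interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {line_no}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}: line {line_no}: end <= start")
            out.setdefault(chrom, []).append((start, end))
    return out


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _complement(intervals: list[tuple[int, int]], chrom_len: int) -> list[tuple[int, int]]:
    gaps = []
    pos = 0
    for s, e in _merge_intervals(intervals):
        s, e = max(0, s), min(chrom_len, e)
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < chrom_len:
        gaps.append((pos, chrom_len))
    return gaps


def sample_negatives(
    genome,
    exclusions: dict[str, list[tuple[int, int]]],
    n: int,
    length: int = 1000,
    seed: int = 0,
    id_prefix: str = "neg",
    max_attempts_factor: int = 50,
) -> LabeledSequenceSet:
    """Draw ``n`` label-0 windows uniformly from genome minus exclusions.

    Every returned window is disjoint from all exclusion intervals and free
    of ambiguous bases; windows containing N are rejected and redrawn.
    Reproducible for a fixed seed.  Raises ``RuntimeError`` (reporting how
    many windows were found) if the allowed space is exhausted.
    """
    rng = np.random.default_rng(seed)
    # allowed start positions per chromosome: complement gaps wide enough
    chroms: list[str] = []
    gap_lists: list[tuple[int, int]] = []
    weights: list[int] = []
    for chrom in sorted(genome.keys()):
        chrom_len = len(genome[chrom])
        for s, e in _complement(exclusions.get(chrom, []), chrom_len):
            n_starts = e - s - length + 1
            if n_starts > 0:
                chroms.append(chrom)
                gap_lists.append((s, e))
                weights.append(n_starts)
    total = int(np.sum(weights)) if weights else 0
    if total == 0:
        raise RuntimeError("no allowed interval can hold a window of the requested length")

    cum = np.cumsum(weights)
    records: list[SequenceRecord] = []
    seen_starts: set[tuple[str, int]] = set()
    attempts = 0
    max_attempts = max_attempts_factor * n
    while len(records) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"allowed space exhausted: drew only {len(records)} of {n} windows "
                f"after {attempts} attempts"
            )
        attempts += 1
        u = int(rng.integers(0, total))
        gi = int(np.searchsorted(cum, u, side="right"))
        offset = u - (cum[gi - 1] if gi > 0 else 0)
        chrom = chroms[gi]
        start = gap_lists[gi][0] + int(offset)
        seq = str(genome[chrom][start:start + length]).upper()
        if "N" in seq:
            continue
        key = (chrom, start)
        if key in seen_starts:
            continue
        seen_starts.add(key)
        region = GenomicRegion(chrom, start, start + length)
        records.append(
            SequenceRecord(f"{id_prefix}_{len(records)}", seq, 0, region)
        )
    return LabeledSequenceSet(records=records, fixed_length=length)


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def _allocate(n: int, fractions: Sequence[Fraction]) -> list[int]:
    """Largest-remainder allocation of n items to fractions (sums to n)."""
    raw = [Fraction(f) * n for f in fractions]
    counts = [int(r) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    short = n - sum(counts)
    for idx in sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))[:short]:
        counts[idx] += 1
    return counts


def make_splits(
    data: LabeledSequenceSet, spec: SplitSpec
) -> tuple[LabeledSequenceSet, LabeledSequenceSet, LabeledSequenceSet]:
    """Stratified train/validation/test partition, reproducible by seed.

    Partitions are disjoint and exhaustive; each split's class ratio matches
    the global ratio within one record per class.
    """
    labels = data.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(spec.seed)
    fracs = (spec.train_fraction, spec.val_fraction, spec.test_fraction)
    parts: list[list[int]] = [[], [], []]
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        counts = _allocate(len(idx), fracs)
        if any(c == 0 for c in counts):
            raise ValueError(
                f"class {lab}: a split fraction yields an empty split "
                f"(class size {len(idx)}, counts {counts})"
            )
        pos = 0
        for p, c in zip(parts, counts):
            p.extend(idx[pos:pos + c].tolist())
            pos += c
    return tuple(data.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


def make_kfold(data: LabeledSequenceSet, k: int, seed: int = 0) -> list[list[int]]:
    """Stratified k disjoint, exhaustive folds of record indices."""
    labels = data.labels
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [sorted(f) for f in folds]
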