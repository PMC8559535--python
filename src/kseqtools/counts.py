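"""Count-table I/O, filtering and sequence classification.

The pipeline's raw input is one de-replicated count file per sample mapping
unique variable-region sequences to read counts.  This module merges those
files into a :class:`CountTable` (sequences x samples integer matrix plus
per-sample metadata), applies the standard pre-fit filters (expected length,
no ambiguous bases, spike-in exclusion by edit distance), attributes spike-in
reads for absolute quantitation, decides which sequences are analyzable for
kinetic fitting, and classifies sequences to their nearest family center.

Count file dialect: two whitespace/tab-separated columns (sequence, count);
lines starting with ``#`` and blank lines are ignored.  Sequences are
uppercased on load and ``U`` is mapped to ``T`` (RNA libraries are sequenced
as cDNA).  The merged matrix round-trips through TSV with a ``#``-prefixed
JSON metadata header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "SpikeInConfig",
    "CountTable",
    "FilterResult",
    "FamilyAssignment",
    "load_counts",
    "edit_distance",
    "hamming_distance",
    "filter_sequences",
    "analyzable_mask",
    "mean_counts",
    "classify_to_family",
    "classify_table",
]

_VALID_BASES = frozenset("ACGT")


@dataclass
class SampleMeta:
    """Per-sample metadata.

    ``substrate_conc`` is the initial substrate concentration in molar,
    ``spike_in_amount`` the mass of spike-in RNA added in ng, and
    ``measured_total_rna`` a directly measured total-RNA amount in ng (either
    of the last two may be absent depending on the quantitation method).
    """

    sample_id: str
    substrate_conc: float = 0.0
    replicate: int = 1
    is_unreacted: bool = False
    total_reads: int | None = None
    spike_in_amount: float | None = None
    measured_total_rna: float | None = None

    def __post_init__(self) -> None:
        if self.substrate_conc < 0:
            raise ValueError(f"substrate_conc must be >= 0 ({self.sample_id})")
        if self.total_reads is not None and self.total_reads < 0:
            raise ValueError(f"total_reads must be >= 0 ({self.sample_id})")


@dataclass(frozen=True)
class SpikeInConfig:
    """Spike-in variable-region sequence and the edit-distance radius within
    which reads are attributed to it (inclusive)."""

    sequence: str
    max_edit_distance: int = 2

    def __post_init__(self) -> None:
        if self.max_edit_distance < 0:
            raise ValueError("max_edit_distance must be >= 0")


class CountTable:
    """Read counts of unique sequences across samples.

    ``counts`` is an integer DataFrame indexed by sequence with one column
    per sample (column order matches ``samples``).  Missing sequence/sample
    pairs are zeros.  Each sample's ``total_reads`` is the total reads
    sequenced for it, which may exceed the column sum once sequences have
    been filtered out.
    """

    def __init__(self, counts: pd.DataFrame, samples: Sequence[SampleMeta]):
        ids = [m.sample_id for m in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in samples")
        if list(counts.columns) != ids:
            counts = counts.reindex(columns=ids)
        if counts.isna().any().any():
            raise ValueError("counts contain missing values")
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for m in samples:
            if m.total_reads is not None and counts[m.sample_id].sum() > m.total_reads:
                raise ValueError(
                    f"column sum exceeds total_reads for sample {m.sample_id}"
                )
        self.counts = counts
        self.samples = list(samples)

    # -- basic accessors -------------------------------------------------
    @property
    def sequences(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.samples]

    def meta(self, sample_id: str) -> SampleMeta:
        for m in self.samples:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    @property
    def unreacted_id(self) -> str:
        ids = [m.sample_id for m in self.samples if m.is_unreacted]
        if len(ids) != 1:
            raise ValueError(
                f"expected exactly one unreacted sample, found {len(ids)}"
            )
        return ids[0]

    @property
    def reacted_ids(self) -> list[str]:
        return [m.sample_id for m in self.samples if not m.is_unreacted]

    def select(self, mask: pd.Series | np.ndarray | pd.Index) -> "CountTable":
        """Row-subset by boolean mask or sequence index; metadata unchanged."""
        if isinstance(mask, pd.Index):
            sub = self.counts.loc[mask]
        else:
            sub = self.counts.loc[np.asarray(mask, bool)]
        return CountTable(sub, self.samples)

    def __len__(self) -> int:
        return len(self.counts)

    # -- TSV round trip --------------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            for m in self.samples:
                fh.write("#sample\t" + json.dumps(asdict(m)) + "\n")
            self.counts.rename_axis("sequence").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        path = Path(path)
        metas = []
        with path.open() as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#sample\t"):
                metas.append(SampleMeta(**json.loads(line.split("\t", 1)[1])))
                body_start = i + 1
            elif not line.startswith("#"):
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        df = df.set_index("sequence")
        return cls(df, metas)


class CountFileError(ValueError):
    """Malformed count file (message names the file and line)."""


def _normalize_sequence(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _parse_count_file(path: Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise CountFileError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            seq = _normalize_sequence(fields[0])
            try:
                count = int(fields[1])
            except ValueError:
                raise CountFileError(
                    f"{path}:{lineno}: count {fields[1]!r} is not an integer"
                ) from None
            if count < 0:
                raise CountFileError(f"{path}:{lineno}: negative count {count}")
            if seq in counts:
                raise CountFileError(f"{path}:{lineno}: duplicate sequence {seq}")
            counts[seq] = count
    if not counts:
        logger.warning("count file %s is empty", path)
    return counts


def load_counts(
    paths: Mapping[str, str | Path] | Sequence[str | Path],
    metas: Sequence[SampleMeta],
) -> CountTable:
    """Merge per-sample count files into a :class:`CountTable`.

    ``paths`` maps sample_id to file path (or is a sequence aligned with
    ``metas``).  The sequence set is the union across samples; absent pairs
    are 0.  If a sample's ``total_reads`` is unset it is filled with the
    file's column sum.
    """
    if not isinstance(paths, Mapping):
        if len(paths) != len(metas):
            raise ValueError("paths and metas length mismatch")
        paths = {m.sample_id: p for m, p in zip(metas, paths)}
    columns = {}
    for m in metas:
        parsed = _parse_count_file(Path(paths[m.sample_id]))
        columns[m.sample_id] = pd.Series(parsed, dtype=np.int64)
    df = pd.DataFrame(columns).fillna(0).astype(np.int64)
    df.index.name = "sequence"
    metas = [
        SampleMeta(**{**asdict(m), "total_reads": int(df[m.sample_id].sum())})
        if m.total_reads is None
        else m
        for m in metas
    ]
    return CountTable(df, metas)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class FilterResult:
    """Outcome of :func:`filter_sequences`: the retained table, per-sample
    spike-in read counts ``n_sj``, and reads removed per (reason, sample)."""

    table: CountTable
    spike_counts: pd.Series
    tally: pd.DataFrame  # rows: spike_in/length/ambiguous; columns: samples


def _within_spike_radius(seq: str, spike: SpikeInConfig) -> bool:
    r = spike.max_edit_distance
    if abs(len(seq) - len(spike.sequence)) > r:
        return False
    d = edlib.align(seq, spike.sequence, mode="NW", task="distance", k=r)[
        "editDistance"
    ]
    return d != -1


def filter_sequences(
    table: CountTable,
    expected_length: int,
    spike: SpikeInConfig | None = None,
) -> FilterResult:
    """Remove sequences of wrong length, with ambiguous bases, or within the
    spike-in edit-distance radius; never fails, only tallies.

    Spike-in attribution runs first (so indel-bearing spike-in reads of
    length L±1, L±2 are counted into ``n_sj`` rather than discarded as
    length outliers), then the length filter, then the ambiguous-base
    filter.  Reads are conserved: retained + tallied = original column sums.
    """
    if expected_length <= 0:
        raise ValueError("expected_length must be > 0")
    reasons = {}
    for seq in table.sequences:
        if spike is not None and _within_spike_radius(seq, spike):
            reasons[seq] = "spike_in"
        elif len(seq) != expected_length:
            reasons[seq] = "length"
        elif not set(seq) <= _VALID_BASES:
            reasons[seq] = "ambiguous"
    reason_series = pd.Series(reasons, dtype=object)
    keep = ~table.sequences.isin(reason_series.index)
    tally_rows = []
    for reason in ("spike_in", "length", "ambiguous"):
        seqs = reason_series.index[reason_series == reason]
        tally_rows.append(table.counts.loc[seqs].sum(axis=0).rename(reason))
    tally = pd.DataFrame(tally_rows)
    spike_counts = tally.loc["spike_in"].rename("n_s")
    return FilterResult(table.select(keep), spike_counts, tally)


def analyzable_mask(table: CountTable) -> pd.Series:
    """True for sequences with a non-zero count in the unreacted sample and
    at least one non-zero count among reacted samples."""
    unreacted = table.unreacted_id  # raises unless exactly one
    reacted = table.reacted_ids
    mask = (table.counts[unreacted] > 0) & (table.counts[reacted].sum(axis=1) > 0)
    return mask.rename("analyzable")


def mean_counts(table: CountTable) -> pd.Series:
    """Mean read count per sequence across all samples (unreacted included);
    the principal predictor of estimation accuracy."""
    return table.counts.mean(axis=1).rename("mean_counts")


class FamilyAssignment(NamedTuple):
    family: int
    distance: int
    tie: bool


def classify_to_family(seq: str, centers: Sequence[str]) -> FamilyAssignment:
    """Assign a sequence to the nearest family center by Hamming distance.

    Ties go to the lowest family index and are flagged.
    """
    if not centers:
        raise ValueError("at least one family center required")
    dists = [hamming_distance(seq, c) for c in centers]
    d = min(dists)
    idx = dists.index(d)
    return FamilyAssignment(idx, d, dists.count(d) > 1)


def classify_table(
    sequences: Iterable[str], centers: Sequence[str]
) -> pd.DataFrame:
    """Vectorized :func:`classify_to_family` over many equal-length
    sequences; returns a DataFrame with family / distance / tie columns."""
    seqs = list(sequences)
    if not seqs:
        return pd.DataFrame(columns=["family", "distance", "tie"])
    L = len(centers[0])
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    dmat = np.empty((len(seqs), len(centers)), dtype=np.int64)
    for j, c in enumerate(centers):
        if len(c) != L:
            raise ValueError("family centers must share a common length")
        carr = np.frombuffer(c.encode(), dtype="S1")
        dmat[:, j] = (arr != carr).sum(axis=1)
    best = dmat.min(axis=1)
    fam = dmat.argmin(axis=1)
    tie = (dmat == best[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {"family": fam, "distance": best, "tie": tie}, index=pd.Index(seqs, name="sequence")
    )
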