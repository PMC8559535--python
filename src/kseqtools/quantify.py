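"""Absolute quantitation: counts -> amounts -> reacted fractions.

Read counts are converted to absolute per-sequence amounts using the total
RNA recovered in each sample, obtained either from a spike-in internal
standard,

    Q_j = (N_j - n_sj) / n_sj * q_sj,

where ``N_j`` is the sample's total reads, ``n_sj`` the reads attributed to
the spike-in and ``q_sj`` the spike-in mass added (ng), or from a direct
measurement (fluorometry / qPCR).  Per-sequence amounts are then

    q_ij = n_ij / (N_j - n_sj) * Q_j   (ng),

and reacted fractions are the ratio to the unreacted sample,

    f_ij = q_ij / q_i,unreacted.

Fractions above 1 (possible under measurement noise) are retained, not
clamped — clamping would bias the downstream fit, whose amplitude bound
A <= 1 already constrains the model — and are exposed via
``ReactedFractionTable.over_unity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import CountTable, SampleMeta

__all__ = [
    "SampleQuant",
    "QuantitationError",
    "AbundanceTable",
    "ReactedFractionTable",
    "total_rna_from_spikein",
    "quantify_samples",
    "absolute_amounts",
    "reacted_fractions",
    "compare_quantitation",
]


class QuantitationError(ValueError):
    pass


@dataclass(frozen=True)
class SampleQuant:
    """Total RNA recovered in a sample (ng) and how it was obtained."""

    total_rna: float
    method: str  # "spike-in" | "direct"

    def __post_init__(self) -> None:
        if self.total_rna < 0:
            raise ValueError("total_rna must be >= 0")
        if self.method not in ("spike-in", "direct"):
            raise ValueError(f"unknown quantitation method {self.method!r}")


def total_rna_from_spikein(n_total: int, n_spike: int, spike_amount: float) -> float:
    """Total RNA recovered from spike-in read share:
    ``(N_j - n_sj) / n_sj * q_sj``."""
    if n_spike <= 0:
        raise QuantitationError(
            "no spike-in reads detected; spike-in quantitation failed"
        )
    if n_total < n_spike:
        raise QuantitationError("total reads below spike-in reads")
    return (n_total - n_spike) / n_spike * spike_amount


def quantify_samples(
    samples: Sequence[SampleMeta],
    spike_counts: pd.Series | Mapping[str, int] | None = None,
    prefer: str = "direct",
) -> dict[str, SampleQuant]:
    """Build a per-sample :class:`SampleQuant`, preferring direct measurement
    over spike-in by default (set ``prefer='spike-in'`` to flip).

    Raises :class:`QuantitationError` for samples with neither method
    available, or with a spike-in configured but zero spike-in reads.
    """
    if prefer not in ("direct", "spike-in"):
        raise ValueError("prefer must be 'direct' or 'spike-in'")
    out: dict[str, SampleQuant] = {}
    for m in samples:
        has_direct = m.measured_total_rna is not None
        has_spike = (
            m.spike_in_amount is not None
            and spike_counts is not None
            and m.sample_id in dict(spike_counts)
        )
        use_direct = has_direct and (prefer == "direct" or not has_spike)
        if use_direct:
            out[m.sample_id] = SampleQuant(float(m.measured_total_rna), "direct")
        elif has_spike:
            if m.total_reads is None:
                raise QuantitationError(f"total_reads unset for {m.sample_id}")
            q = total_rna_from_spikein(
                m.total_reads, int(dict(spike_counts)[m.sample_id]), m.spike_in_amount
            )
            out[m.sample_id] = SampleQuant(q, "spike-in")
        else:
            raise QuantitationError(
                f"sample {m.sample_id}: no quantitation method available"
            )
    return out


@dataclass
class AbundanceTable:
    """Absolute per-sequence amounts (ng), sequences x samples."""

    amounts: pd.DataFrame
    samples: list[SampleMeta]

    @property
    def unreacted_id(self) -> str:
        ids = [m.sample_id for m in self.samples if m.is_unreacted]
        if len(ids) != 1:
            raise ValueError("expected exactly one unreacted sample")
        return ids[0]

    def select(self, mask) -> "AbundanceTable":
        return AbundanceTable(self.amounts.loc[np.asarray(mask, bool)], self.samples)


def absolute_amounts(
    table: CountTable,
    quants: Mapping[str, SampleQuant],
    spike_counts: pd.Series | Mapping[str, int] | None = None,
) -> AbundanceTable:
    """Convert counts to amounts: ``q_ij = n_ij / (N_j - n_sj) * Q_j``.

    ``spike_counts`` defaults to zero (direct quantitation without a
    spike-in).  When the table is complete, per-sample amounts sum to
    ``Q_j``.
    """
    spike = dict(spike_counts) if spike_counts is not None else {}
    cols = {}
    for m in table.samples:
        if m.total_reads is None:
            raise QuantitationError(f"total_reads unset for {m.sample_id}")
        n_s = int(spike.get(m.sample_id, 0))
        denom = m.total_reads - n_s
        if denom <= 0:
            raise QuantitationError(
                f"sample {m.sample_id}: no non-spike-in reads (N={m.total_reads}, "
                f"n_s={n_s})"
            )
        cols[m.sample_id] = (
            table.counts[m.sample_id] / denom * quants[m.sample_id].total_rna
        )
    return AbundanceTable(pd.DataFrame(cols), list(table.samples))


@dataclass
class ReactedFractionTable:
    """Reacted fractions f_ij (sequences x reacted samples) with per-column
    substrate concentration (M) and replicate labels."""

    fractions: pd.DataFrame
    conc: pd.Series  # per reacted column, molar
    replicate: pd.Series  # per reacted column

    @property
    def conditions(self) -> np.ndarray:
        return self.conc.to_numpy(dtype=float)

    @property
    def over_unity(self) -> pd.DataFrame:
        """Boolean mask of fractions above 1 (kept, flagged)."""
        return self.fractions > 1.0

    @property
    def sequences(self) -> pd.Index:
        return self.fractions.index

    def select(self, mask) -> "ReactedFractionTable":
        return ReactedFractionTable(
            self.fractions.loc[np.asarray(mask, bool)], self.conc, self.replicate
        )

    # -- TSV round trip with a metadata header block ---------------------
    def write_tsv(self, path: str | Path) -> None:
        import json

        with Path(path).open("w") as fh:
            fh.write("#conc_M\t" + json.dumps(self.conc.to_dict()) + "\n")
            fh.write("#replicate\t" + json.dumps(self.replicate.to_dict()) + "\n")
            self.fractions.rename_axis("sequence").to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ReactedFractionTable":
        import json
        from io import StringIO

        conc = rep = None
        lines = Path(path).read_text().splitlines(keepends=True)
        body = []
        for line in lines:
            if line.startswith("#conc_M\t"):
                conc = pd.Series(json.loads(line.split("\t", 1)[1]))
            elif line.startswith("#replicate\t"):
                rep = pd.Series(json.loads(line.split("\t", 1)[1]))
            elif not line.startswith("#"):
                body.append(line)
        df = pd.read_csv(StringIO("".join(body)), sep="\t").set_index("sequence")
        return cls(df, conc, rep)


def reacted_fractions(abund: AbundanceTable) -> ReactedFractionTable:
    """f_ij = q_ij / q_i,unreacted for reacted columns.

    Every retained sequence must have a positive unreacted amount (apply the
    analyzable mask upstream); a zero here indicates a pipeline bug.
    """
    unreacted = abund.unreacted_id
    q0 = abund.amounts[unreacted]
    if (q0 <= 0).any():
        raise ValueError(
            "zero unreacted amount encountered; apply analyzable_mask before "
            "computing reacted fractions"
        )
    reacted = [m for m in abund.samples if not m.is_unreacted]
    ids = [m.sample_id for m in reacted]
    frac = abund.amounts[ids].div(q0, axis=0)
    conc = pd.Series({m.sample_id: m.substrate_conc for m in reacted})
    rep = pd.Series({m.sample_id: m.replicate for m in reacted})
    return ReactedFractionTable(frac, conc.loc[ids], rep.loc[ids])


def compare_quantitation(
    spike: Mapping[str, float], direct: Mapping[str, float]
) -> dict:
    """Agreement report between spike-in and direct total-RNA estimates:
    Pearson correlation (when >= 3 samples) and per-sample spike/direct
    ratios.  Purely descriptive."""
    keys = [k for k in spike if k in direct]
    if not keys:
        raise ValueError("no shared samples between the two quantitations")
    s = np.array([spike[k] for k in keys], dtype=float)
    d = np.array([direct[k] for k in keys], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = dict(zip(keys, s / d))
    r = float(np.corrcoef(s, d)[0, 1]) if len(keys) >= 3 else None
    return {"pearson_r": r, "ratios": ratios, "n_samples": len(keys)}
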