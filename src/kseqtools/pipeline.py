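"""End-to-end drivers composing the count -> fraction -> fit -> uncertainty
stages; what the CLI and the examples call."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counts import CountTable, SpikeInConfig, analyzable_mask, filter_sequences
from .kinetics import KineticModelConfig, fit_pool
from .quantify import (
    ReactedFractionTable,
    absolute_amounts,
    quantify_samples,
    reacted_fractions,
)
from .uncertainty import bootstrap_pool, triplicate_pool

__all__ = ["PipelineInfo", "reacted_fraction_pipeline", "estimate_pool"]


@dataclass
class PipelineInfo:
    """Bookkeeping from the quantitation stage."""

    n_input: int
    n_analyzable: int
    spike_counts: pd.Series | None
    quant_methods: dict[str, str]
    filter_tally: pd.DataFrame | None


def reacted_fraction_pipeline(
    table: CountTable,
    spike: SpikeInConfig | None = None,
    expected_length: int | None = None,
    prefer: str = "direct",
) -> tuple[ReactedFractionTable, PipelineInfo]:
    """Counts to reacted fractions.

    Optionally filters (length / ambiguous bases / spike-in exclusion),
    quantifies each sample's total RNA (direct measurement preferred over
    spike-in by default), restricts to analyzable sequences (non-zero
    unreacted count and at least one non-zero reacted count) and forms
    f_ij = q_ij / q_i,unreacted.
    """
    n_input = len(table)
    spike_counts = None
    tally = None
    if expected_length is not None:
        if spike is None:
            res = filter_sequences(table, expected_length)
        else:
            res = filter_sequences(table, expected_length, spike)
        table, spike_counts, tally = res.table, res.spike_counts, res.tally
    quants = quantify_samples(table.samples, spike_counts, prefer=prefer)
    mask = analyzable_mask(table)
    abund = absolute_amounts(table.select(mask), quants, spike_counts)
    frac = reacted_fractions(abund)
    info = PipelineInfo(
        n_input,
        int(mask.sum()),
        spike_counts,
        {s: q.method for s, q in quants.items()},
        tally,
    )
    return frac, info


def estimate_pool(
    frac: ReactedFractionTable,
    cfg: KineticModelConfig = KineticModelConfig(),
    n_boot: int = 0,
    triplicate: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Point estimates for every sequence, optionally joined with bootstrap
    (``n_boot > 0``) and replicate-series uncertainty columns."""
    fits = fit_pool(frac, cfg, seed=seed)
    out = fits
    if n_boot > 0:
        out = out.join(bootstrap_pool(frac, fits, cfg, n_boot=n_boot, seed=seed))
    if triplicate:
        trip = triplicate_pool(frac, cfg).add_prefix("trip_")
        out = out.join(trip)
    return out
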