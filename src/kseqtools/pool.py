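"""Analytic mathematics of doped ("spiked") variant pools.

A doped pool is synthesized around one or more wild-type *family center*
sequences: at each of the ``L`` variable positions the wild-type base is
incorporated with probability ``1 - eta`` and each of the three substitutions
with probability ``eta / 3``.  Every sequence at Hamming distance ``d`` from
its center (a "``d``-th order mutant") therefore has the same expected
relative abundance within its family,

    p(d) = (1 - eta)^(L - d) * (eta / 3)^d,

and there are ``C(L, d) * 3^d`` such sequences per family.  This module
collects the closed-form consequences of that design: per-class abundances
and expected read counts, sequence-space coverage, the doping rate that
maximizes a target mutant order, and a first-order model of how per-base
sequencing error redistributes reads between Hamming-1 neighbors.

The sequencing-error model considers single-substitution read errors only
(each base misread with probability ``xi``, uniformly ``xi/3`` to each
alternative base; indels and multi-error reads are neglected as O(xi^2)).
A specific ``d``-th order mutant then *retains* reads with probability
``(1 - xi)^L`` and *gains* misread copies of its ``3L`` Hamming-1 neighbors:
``d`` reversion neighbors of order ``d - 1``, ``2d`` lateral neighbors of
order ``d``, and ``3(L - d)`` forward neighbors of order ``d + 1``, each
contributing with probability ``(xi / 3) * (1 - xi)^(L - 1)``.  Neighbor
abundances are the ensemble-average class probabilities above, which is what
makes the expected observed/true abundance ratio a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import pandas as pd

__all__ = [
    "DopedPoolDesign",
    "ErrorModel",
    "sequence_probability",
    "abundance_ratio",
    "mutant_class_size",
    "expected_counts",
    "coverage_fraction",
    "optimal_doping_rate",
    "observed_abundance_ratio",
    "spurious_read_fraction",
    "design_table",
    "error_table",
]


@dataclass(frozen=True)
class DopedPoolDesign:
    """Doped-pool design: variable-region length, per-position mutation rate,
    and the number of equimolar family centers.

    Parameters mirror the synthesis specification of a variant library:
    ``eta`` is the *total* probability of a non-wild-type base at each
    position (so each specific substitution appears at ``eta/3``).
    ``centers`` is optional; the purely analytic operations need only
    ``length``, ``eta`` and ``n_families``.
    """

    length: int = 21
    eta: float = 0.09
    n_families: int = 4
    centers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError(f"eta must be in [0, 1), got {self.eta}")
        if self.n_families < 1:
            raise ValueError(f"n_families must be >= 1, got {self.n_families}")
        for c in self.centers:
            if len(c) != self.length:
                raise ValueError(
                    f"family center {c!r} has length {len(c)}, expected {self.length}"
                )


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution sequencing error rate ``xi``."""

    xi: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi < 1.0:
            raise ValueError(f"xi must be in [0, 1), got {self.xi}")


def _check_order(d: int, length: int) -> None:
    if not 0 <= d <= length:
        raise ValueError(f"mutant order d={d} outside [0, {length}]")


def sequence_probability(d: int, design: DopedPoolDesign) -> float:
    """Expected relative abundance of one specific d-th order mutant within
    its family: ``(1 - eta)^(L - d) * (eta / 3)^d``.

    Summed over all class members and all orders this totals 1 per family.
    """
    _check_order(d, design.length)
    return (1.0 - design.eta) ** (design.length - d) * (design.eta / 3.0) ** d


def abundance_ratio(design: DopedPoolDesign) -> float:
    """Abundance of a d-th order mutant relative to a (d-1)-th order mutant,
    ``(eta/3) / (1 - eta)`` — independent of ``d``."""
    return (design.eta / 3.0) / (1.0 - design.eta)


def mutant_class_size(d: int, design: DopedPoolDesign) -> int:
    """Number of possible unique sequences at Hamming distance ``d`` from any
    of the family centers: ``n_families * C(L, d) * 3^d`` (exact integer)."""
    _check_order(d, design.length)
    return design.n_families * comb(design.length, d) * 3**d


def expected_counts(d: int, total_reads: int, design: DopedPoolDesign) -> float:
    """Expected read count of one specific d-th order mutant in a pool
    sequenced to ``total_reads``, with reads split equally among families.

    Sequencing error is not modelled here; see
    :func:`observed_abundance_ratio` for its effect.
    """
    if total_reads <= 0:
        raise ValueError(f"total_reads must be > 0, got {total_reads}")
    return total_reads / design.n_families * sequence_probability(d, design)


def coverage_fraction(n_detected: int, d: int, design: DopedPoolDesign) -> float:
    """Fraction of possible d-th order mutants observed: detected / possible."""
    size = mutant_class_size(d, design)
    if not 0 <= n_detected <= size:
        raise ValueError(
            f"n_detected={n_detected} outside [0, {size}] for order d={d}"
        )
    return n_detected / size


def optimal_doping_rate(d_target: int, length: int) -> float:
    """Doping rate ``eta`` that maximizes the abundance of a specific
    ``d_target``-order mutant.

    Maximizing ``(1 - eta)^(L - d) * (eta/3)^d`` in ``eta`` gives the closed
    form ``eta = d / L`` (stationary point of the log; monotone increasing in
    ``d_target``).  ``d_target = 0`` returns the degenerate maximum 0;
    ``d_target = L`` returns the boundary value 1.
    """
    _check_order(d_target, length)
    return d_target / length


def _retained_and_gain(d: int, err: ErrorModel, design: DopedPoolDesign) -> tuple[float, float]:
    """Expected reads of one specific d-mutant retained after sequencing
    error, and gained from misreads of its Hamming-1 neighbors (both in units
    of true per-sequence relative abundance)."""
    _check_order(d, design.length)
    L, xi = design.length, err.xi
    retained = sequence_probability(d, design) * (1.0 - xi) ** L
    per_neighbor = (xi / 3.0) * (1.0 - xi) ** (L - 1)
    gain = 0.0
    # neighbor classes: d reversions (order d-1), 2d lateral (order d),
    # 3(L-d) forward (order d+1); out-of-range terms drop at the boundaries
    for order, n_neighbors in ((d - 1, d), (d, 2 * d), (d + 1, 3 * (L - d))):
        if 0 <= order <= L and n_neighbors > 0:
            gain += n_neighbors * sequence_probability(order, design) * per_neighbor
    return retained, gain


def observed_abundance_ratio(d: int, err: ErrorModel, design: DopedPoolDesign) -> float:
    """Expected observed/true abundance ratio of a specific d-th order mutant
    under the single-substitution sequencing-error model.

    Equals 1 at ``xi = 0``; decreases with ``xi`` for the wild-type (pure
    loss), while higher-order mutants can rise above 1 when gains from their
    more abundant lower-order neighbors exceed their own losses.
    """
    retained, gain = _retained_and_gain(d, err, design)
    return (retained + gain) / sequence_probability(d, design)


def spurious_read_fraction(d: int, err: ErrorModel, design: DopedPoolDesign) -> float:
    """Fraction of a d-mutant's expected observed reads that are misreads of
    its Hamming-1 neighbors: ``gain / (gain + retained)``, in [0, 1)."""
    retained, gain = _retained_and_gain(d, err, design)
    if gain == 0.0:
        return 0.0
    return gain / (gain + retained)


def design_table(
    design: DopedPoolDesign, total_reads: int | None = None, max_order: int = 4
) -> pd.DataFrame:
    """Summary table per mutant order: class size, per-sequence probability
    and (if ``total_reads`` given) expected per-sequence read counts."""
    orders = list(range(min(max_order, design.length) + 1))
    rows = {
        "order": orders,
        "class_size": [mutant_class_size(d, design) for d in orders],
        "sequence_probability": [sequence_probability(d, design) for d in orders],
    }
    if total_reads is not None:
        rows["expected_counts"] = [
            expected_counts(d, total_reads, design) for d in orders
        ]
    return pd.DataFrame(rows)


def error_table(
    err: ErrorModel, design: DopedPoolDesign, max_order: int = 4
) -> pd.DataFrame:
    """Observed/true abundance ratio and spurious-read fraction per order."""
    orders = list(range(min(max_order, design.length) + 1))
    return pd.DataFrame(
        {
            "order": orders,
            "observed_to_true": [
                observed_abundance_ratio(d, err, design) for d in orders
            ],
            "spurious_read_fraction": [
                spurious_read_fraction(d, err, design) for d in orders
            ],
        }
    )
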