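"""Doped-pool arithmetic and the sequencing-error misassignment model,
checked against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kseqtools import (
    DopedPoolDesign,
    ErrorModel,
    abundance_ratio,
    coverage_fraction,
    design_table,
    expected_counts,
    mutant_class_size,
    observed_abundance_ratio,
    optimal_doping_rate,
    sequence_probability,
    spurious_read_fraction,
)

DESIGN = DopedPoolDesign(length=21, eta=0.09, n_families=4)
BASES = "ACGT"


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def doped_probability(seq: str, center: str, eta: float) -> float:
    """Exact synthesis probability of one sequence around a center."""
    p = 1.0
    for s, c in zip(seq, center):
        p *= (1.0 - eta) if s == c else eta / 3.0
    return p


def brute_force_observed(target: str, center: str, eta: float, xi: float) -> float:
    """Expected observed abundance of `target` by full enumeration of every
    pool sequence under the single-substitution read-error model."""
    L = len(center)
    total = 0.0
    for seq in itertools.product(BASES, repeat=L):
        seq = "".join(seq)
        p = doped_probability(seq, center, eta)
        dist = sum(a != b for a, b in zip(seq, target))
        if dist == 0:
            total += p * (1.0 - xi) ** L
        elif dist == 1:
            total += p * (xi / 3.0) * (1.0 - xi) ** (L - 1)
    return total


def neighbor_enumeration_gain(target: str, center: str, eta: float, xi: float) -> float:
    """Gain term by explicit enumeration of the 3L Hamming-1 neighbor
    strings (tractable at L = 21, unlike full enumeration)."""
    L = len(center)
    gain = 0.0
    for pos in range(L):
        for b in BASES:
            if b == target[pos]:
                continue
            neighbor = target[:pos] + b + target[pos + 1 :]
            gain += (
                doped_probability(neighbor, center, eta)
                * (xi / 3.0)
                * (1.0 - xi) ** (L - 1)
            )
    return gain


def mutate(center: str, positions: tuple[int, ...]) -> str:
    out = list(center)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


# ---------------------------------------------------------------------------
# abundances and counts
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "d, expected, rel",
    [
        (0, 0.1380, 1e-3),  # ~14% wild-type
        (1, 0.00455, 1e-2),  # ~0.45% per single mutant
    ],
)
def test_sequence_probability_reference_values(d, expected, rel):
    assert sequence_probability(d, DESIGN) == pytest.approx(expected, rel=rel)


def test_sequence_probability_trivial_and_errors():
    assert sequence_probability(0, DopedPoolDesign(length=5, eta=0.0)) == 1.0
    with pytest.raises(ValueError):
        sequence_probability(22, DESIGN)
    with pytest.raises(ValueError):
        sequence_probability(-1, DESIGN)


def test_abundance_ratio_values():
    assert abundance_ratio(DESIGN) == pytest.approx(0.033, abs=5e-4)
    assert abundance_ratio(DopedPoolDesign(eta=0.0)) == 0.0
    # uniform random pool: every residue equiprobable
    assert abundance_ratio(DopedPoolDesign(eta=0.75)) == pytest.approx(1.0)


@given(
    L=st.integers(1, 30),
    eta=st.floats(0.0, 0.99),
    d=st.integers(1, 30),
)
def test_probability_ratio_matches_abundance_ratio(L, eta, d):
    d = min(d, L)
    design = DopedPoolDesign(length=L, eta=eta, n_families=1)
    p_hi = sequence_probability(d, design)
    p_lo = sequence_probability(d - 1, design)
    if p_lo > 0:
        assert p_hi / p_lo == pytest.approx(abundance_ratio(design), rel=1e-12)


@given(L=st.integers(1, 40), eta=st.floats(0.0, 0.99))
def test_family_probability_normalizes(L, eta):
    design = DopedPoolDesign(length=L, eta=eta, n_families=1)
    total = sum(
        math.comb(L, d) * 3**d * sequence_probability(d, design) for d in range(L + 1)
    )
    assert total == pytest.approx(1.0, rel=1e-9)


@pytest.mark.parametrize("d, size", [(0, 4), (1, 252), (2, 7560), (3, 143_640), (4, 1_939_140)])
def test_mutant_class_sizes(d, size):
    assert mutant_class_size(d, DESIGN) == size


@pytest.mark.parametrize("L", [3, 4, 5])
def test_class_size_matches_enumeration(L):
    center = ("ACGTA" * 5)[:L]
    design = DopedPoolDesign(length=L, eta=0.1, n_families=1)
    tally = {}
    for seq in itertools.product(BASES, repeat=L):
        d = sum(a != b for a, b in zip(seq, center))
        tally[d] = tally.get(d, 0) + 1
    for d in range(L + 1):
        assert mutant_class_size(d, design) == tally[d]


@pytest.mark.parametrize(
    "d, expected, half_ulp",
    [(0, 1_136_125, 0.5), (1, 37_455, 0.5), (2, 1234, 0.5), (3, 40.7, 0.05), (4, 1.34, 0.005)],
)
def test_expected_counts_reference_totals(d, expected, half_ulp):
    # 0.1% or half a unit of the reference's printed precision
    got = expected_counts(d, 32_931_917, DESIGN)
    assert abs(got - expected) <= max(1e-3 * expected, half_ulp)


def test_expected_counts_trivial():
    assert expected_counts(0, 4, DopedPoolDesign(eta=0.0, n_families=4)) == 1.0


def test_coverage_fraction():
    assert coverage_fraction(143_482, 3, DESIGN) == pytest.approx(0.999, abs=5e-4)
    assert coverage_fraction(0, 2, DESIGN) == 0.0
    assert coverage_fraction(mutant_class_size(2, DESIGN), 2, DESIGN) == 1.0
    with pytest.raises(ValueError):
        coverage_fraction(10**9, 2, DESIGN)


# ---------------------------------------------------------------------------
# doping-rate optimization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("d, L", [(1, 2), (2, 21), (1, 21), (5, 12)])
def test_optimal_doping_rate_matches_grid_search(d, L):
    grid = np.arange(1e-4, 1.0, 1e-4)
    obj = (1.0 - grid) ** (L - d) * (grid / 3.0) ** d
    best = grid[np.argmax(obj)]
    assert abs(optimal_doping_rate(d, L) - best) <= 1e-4 + 1e-12


def test_optimal_doping_rate_boundaries_and_monotonicity():
    assert optimal_doping_rate(0, 21) == 0.0
    assert optimal_doping_rate(21, 21) == 1.0
    assert optimal_doping_rate(2, 21) == pytest.approx(0.0952, abs=1e-4)
    rates = [optimal_doping_rate(d, 21) for d in range(22)]
    assert all(b > a for a, b in zip(rates, rates[1:]))


# ---------------------------------------------------------------------------
# sequencing-error misassignment
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("d", [0, 1, 2, 3])
@pytest.mark.parametrize("xi", [0.003, 0.01])
def test_observed_ratio_matches_full_enumeration(d, xi):
    L = 5
    center = "ACGTA"
    design = DopedPoolDesign(length=L, eta=0.09, n_families=1)
    target = mutate(center, tuple(range(d)))
    oracle = brute_force_observed(target, center, 0.09, xi) / doped_probability(
        target, center, 0.09
    )
    got = observed_abundance_ratio(d, ErrorModel(xi), design)
    assert got == pytest.approx(oracle, rel=1e-12)


@pytest.mark.parametrize("d", [0, 1, 2, 4])
def test_spurious_fraction_matches_neighbor_enumeration_at_L21(d):
    center = "GGTCACAATGCGAATCTGGGA"  # arbitrary 21-mer
    design = DopedPoolDesign(length=21, eta=0.09, n_families=4)
    xi = 0.01
    target = mutate(center, tuple(range(d)))
    gain = neighbor_enumeration_gain(target, center, 0.09, xi)
    retained = doped_probability(target, center, 0.09) * (1.0 - xi) ** 21
    assert spurious_read_fraction(d, ErrorModel(xi), design) == pytest.approx(
        gain / (gain + retained), rel=1e-12
    )


def test_error_model_reference_behavior():
    em1 = ErrorModel(0.01)
    # no error: observed equals true for every order
    for d in range(5):
        assert observed_abundance_ratio(d, ErrorModel(0.0), DESIGN) == 1.0
        assert spurious_read_fraction(d, ErrorModel(0.0), DESIGN) == 0.0
    # wild-type: pure loss plus negligible gain
    assert observed_abundance_ratio(0, em1, DESIGN) == pytest.approx(0.816, abs=2e-3)
    assert observed_abundance_ratio(0, em1, DESIGN) < 1.0
    # double mutants gain more from abundant single-mutant neighbors than they lose
    assert observed_abundance_ratio(2, ErrorModel(1e-3), DESIGN) > 1.0
    # headline misassignment bounds
    assert spurious_read_fraction(1, em1, DESIGN) > 0.10
    assert max(
        spurious_read_fraction(d, ErrorModel(1e-4), DESIGN) for d in range(1, 5)
    ) < 0.005


@pytest.mark.parametrize("d", [0, 1, 3])
def test_spurious_fraction_monotone_in_xi(d):
    xis = np.linspace(0.0, 0.05, 11)
    vals = [spurious_read_fraction(d, ErrorModel(x), DESIGN) for x in xis]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_design_table_consistency():
    df = design_table(DESIGN, total_reads=32_931_917, max_order=4)
    assert df.shape[0] == 5
    assert (df.class_size == [4, 252, 7560, 143_640, 1_939_140]).all()
    np.testing.assert_allclose(
        df.expected_counts,
        [expected_counts(d, 32_931_917, DESIGN) for d in range(5)],
    )


def test_design_validation():
    with pytest.raises(ValueError):
        DopedPoolDesign(eta=1.0)
    with pytest.raises(ValueError):
        DopedPoolDesign(length=0)
    with pytest.raises(ValueError):
        DopedPoolDesign(centers=("ACGT",))  # wrong length for L=21
    with pytest.raises(ValueError):
        ErrorModel(-0.1)
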