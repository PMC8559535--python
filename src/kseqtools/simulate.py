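"""Synthetic-data generators with retained ground truth.

Two simulators make every stage of the pipeline testable without external
data:

Reacted-fraction grid
    Sequences laid out on a grid of true parameters (log10 k in [-1, 3],
    log10 A in [-2, 0]; 101 x 101 by default) with noisy observed fractions

        f_ij = f0_ij + err_ij,   err_ij ~ Normal(0, eps * f0_ij),

    where ``eps`` is the relative error of the reacted fraction (the noise
    scale parameter is the distribution's standard deviation; an alternative
    reading with variance ``eps * f0`` is available via
    ``noise_as_variance``).  Negative draws are reassigned to zero.

Pool count simulator
    ``M`` sequences with unreacted relative abundances ``p_i0`` (log-normal
    by default, normalized to 1), rate constants log-uniform over
    [0.1, 1000] min^-1 M^-1 and amplitudes uniform on [0, 1].  Reacted-
    sample read counts are one exact multinomial draw per sample with
    ``p_ij = p_i0 f_ij / sum_r p_r0 f_rj`` and ``N_j`` reads (40 per
    sequence by default, matching typical per-sequence sequencing depth);
    the unreacted sample is drawn from ``p_0``.  Total RNA recovered in each
    reacted sample is ``max(Normal(mu_j, rna_noise * mu_j), 0)`` around the
    true total ``mu_j = sum_i p_i0 f_ij`` (the unreacted input amount is
    known exactly and serves as the mass unit).

Condition sets (initial substrate concentration series):

    standard    2, 10, 50, 250 uM, triplicate (12 samples)
    replicates  2, 10, 50, 250 uM, four replicates (16 samples)
    extended    2, 10, 50, 250, 1250 uM, triplicate (15 samples)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountTable, SampleMeta
from .kinetics import KineticModelConfig, fit_batch, model_predict, convergence_spread
from .quantify import ReactedFractionTable
from .uncertainty import _bootstrap_samples, gamma_score
from .kinetics import FitResult

__all__ = [
    "CONDITION_SETS",
    "condition_layout",
    "GridSimConfig",
    "GridDataset",
    "SimulatedPool",
    "simulate_grid",
    "sample_pool_params",
    "simulate_pool_counts",
    "pool_reacted_fractions",
    "identifiability_map",
    "separability_boundary",
]

# substrate concentrations in uM and replicate count per set
CONDITION_SETS: dict[str, tuple[tuple[float, ...], int]] = {
    "standard": ((2.0, 10.0, 50.0, 250.0), 3),
    "replicates": ((2.0, 10.0, 50.0, 250.0), 4),
    "extended": ((2.0, 10.0, 50.0, 250.0, 1250.0), 3),
}


def condition_layout(name: str = "extended") -> pd.DataFrame:
    """Observation layout for a named condition set: one row per reacted
    sample with sample_id, substrate concentration (M) and replicate."""
    try:
        concs_uM, n_rep = CONDITION_SETS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition set {name!r}; choose from {sorted(CONDITION_SETS)}"
        ) from None
    rows = [
        {
            "sample_id": f"{c:g}uM-{r + 1}",
            "conc": c * 1e-6,
            "replicate": r + 1,
        }
        for c in concs_uM
        for r in range(n_rep)
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GridSimConfig:
    """Configuration of the reacted-fraction grid simulator."""

    log10_k_range: tuple[float, float] = (-1.0, 3.0)
    log10_A_range: tuple[float, float] = (-2.0, 0.0)
    n_k: int = 101
    n_A: int = 101
    epsilon: float = 0.0
    conditions: str = "extended"
    noise_as_variance: bool = False

    def __post_init__(self) -> None:
        if self.n_k < 2 or self.n_A < 2:
            raise ValueError("grid dimensions must be >= 2")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class GridDataset:
    """Simulated reacted fractions with ground truth.

    ``fractions`` is (n_seq, n_obs); ``truths`` has k / A / kA per row;
    ``conc`` and ``replicate`` describe the observation columns.
    """

    truths: pd.DataFrame
    conc: np.ndarray
    replicate: np.ndarray
    fractions: np.ndarray
    noiseless: np.ndarray

    def as_fraction_table(self) -> ReactedFractionTable:
        layout = [f"{c * 1e6:g}uM-{r}" for c, r in zip(self.conc, self.replicate)]
        df = pd.DataFrame(self.fractions, index=self.truths.index, columns=layout)
        return ReactedFractionTable(
            df,
            pd.Series(self.conc, index=layout),
            pd.Series(self.replicate, index=layout),
        )


def simulate_grid(
    cfg: GridSimConfig = GridSimConfig(),
    seed: int | np.random.Generator | None = None,
    model: KineticModelConfig = KineticModelConfig(),
) -> GridDataset:
    """Simulate noisy reacted fractions on the (log10 k, log10 A) grid."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout = condition_layout(cfg.conditions)
    conc = layout.conc.to_numpy()
    rep = layout.replicate.to_numpy()
    log10_k = np.linspace(*cfg.log10_k_range, cfg.n_k)
    log10_A = np.linspace(*cfg.log10_A_range, cfg.n_A)
    kk, aa = np.meshgrid(log10_k, log10_A, indexing="ij")
    k = 10.0**kk.ravel()
    A = 10.0**aa.ravel()
    idx = pd.Index(
        [f"grid_{i:05d}" for i in range(k.size)], name="sequence"
    )
    truths = pd.DataFrame(
        {"log10_k": kk.ravel(), "log10_A": aa.ravel(), "k": k, "A": A, "kA": k * A},
        index=idx,
    )
    f0 = A[:, None] * -np.expm1(-model.exposure * np.outer(k, conc))
    if cfg.epsilon > 0:
        scale = cfg.epsilon * f0
        if cfg.noise_as_variance:
            scale = np.sqrt(scale)
        f = np.clip(f0 + rng.normal(0.0, 1.0, f0.shape) * scale, 0.0, None)
    else:
        f = f0.copy()
    return GridDataset(truths, conc, rep, f, f0)


def sample_pool_params(
    M: int,
    seed: int | np.random.Generator | None = None,
    abundance_sigma: float = 2.0,
    log10_k_range: tuple[float, float] = (-1.0, 3.0),
    A_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ground-truth pool parameters (p0, k, A).

    Abundances are log-normal (sigma in log space controls pool evenness)
    normalized to sum to 1; k is log-uniform; A uniform.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=M)
    p0 /= p0.sum()
    k = 10.0 ** rng.uniform(*log10_k_range, size=M)
    A = rng.uniform(*A_range, size=M)
    return p0, k, A


@dataclass
class SimulatedPool:
    """Multinomially sampled count data with retained ground truth.

    ``table`` is a ready-to-analyze :class:`CountTable` whose sample
    metadata carries the noisy total-RNA measurements; ``truths`` holds
    (p0, k, A, kA) per sequence; ``total_rna_true`` the noise-free totals.
    """

    table: CountTable
    truths: pd.DataFrame
    total_rna_true: pd.Series
    total_rna_noisy: pd.Series


def simulate_pool_counts(
    p0: np.ndarray,
    k: np.ndarray,
    A: np.ndarray,
    model: KineticModelConfig = KineticModelConfig(),
    conditions: str = "extended",
    reads_per_seq: int = 40,
    rna_noise: float = 0.15,
    seed: int | np.random.Generator | None = None,
) -> SimulatedPool:
    """Simulate sequencing counts for a pool with known kinetics.

    Every sample (the unreacted pool and each reacted condition) receives
    one exact multinomial draw of ``reads_per_seq * M`` reads.  Reacted-
    sample totals get Gaussian relative noise ``rna_noise`` (clamped at 0);
    the unreacted total defines the mass unit and is exact.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p0 = np.asarray(p0, dtype=float)
    M = p0.size
    if not np.isclose(p0.sum(), 1.0, rtol=1e-9):
        raise ValueError("p0 must sum to 1")
    layout = condition_layout(conditions)
    N = int(reads_per_seq * M)
    idx = pd.Index([f"seq_{i:06d}" for i in range(M)], name="sequence")

    f = A[:, None] * -np.expm1(-model.exposure * np.outer(k, layout.conc.to_numpy()))
    mu = p0 @ f  # true total amount reacted per sample, unreacted pool = 1
    noisy = mu.copy()
    if rna_noise > 0:
        noisy = np.clip(rng.normal(mu, rna_noise * mu), 0.0, None)

    counts = {"unreacted": rng.multinomial(N, p0)}
    metas = [
        SampleMeta(
            "unreacted",
            substrate_conc=0.0,
            is_unreacted=True,
            total_reads=N,
            measured_total_rna=1.0,
        )
    ]
    for j, row in layout.iterrows():
        pj = p0 * f[:, j]
        pj /= pj.sum()
        counts[row.sample_id] = rng.multinomial(N, pj)
        metas.append(
            SampleMeta(
                row.sample_id,
                substrate_conc=float(row.conc),
                replicate=int(row.replicate),
                total_reads=N,
                measured_total_rna=float(noisy[j]),
            )
        )
    table = CountTable(pd.DataFrame(counts, index=idx), metas)
    truths = pd.DataFrame({"p0": p0, "k": k, "A": A, "kA": k * A}, index=idx)
    ids = layout.sample_id.tolist()
    return SimulatedPool(
        table,
        truths,
        pd.Series(mu, index=ids, name="total_rna_true"),
        pd.Series(noisy, index=ids, name="total_rna_noisy"),
    )


def pool_reacted_fractions(sim: SimulatedPool):
    """Convenience: run the quantitation pipeline (direct totals, no
    spike-in) on a simulated pool; returns (fractions, analyzable mask)."""
    from .pipeline import reacted_fraction_pipeline

    return reacted_fraction_pipeline(sim.table)


def identifiability_map(
    grid: GridDataset,
    model: KineticModelConfig = KineticModelConfig(),
    metric: str = "gamma",
    n_boot: int = 100,
    n_starts: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-grid-point identifiability surface.

    ``metric='gamma'`` and ``'sigma_A'`` come from bootstrap resampling of
    each point's fit; ``'delta_A'`` is the multi-start convergence spread
    (much slower: 20 trf fits per point).  Returns the truths frame with a
    ``value`` column appended.
    """
    if metric not in ("gamma", "sigma_A", "delta_A"):
        raise ValueError(f"unknown identifiability metric {metric!r}")
    conc = grid.conc
    values = np.empty(len(grid.truths))
    if metric == "delta_A":
        for pos in range(len(grid.truths)):
            rng = np.random.default_rng(np.random.SeedSequence([seed, pos]))
            values[pos] = convergence_spread(
                conc, grid.fractions[pos], model, n_starts=n_starts, seed=rng
            ).delta_A
    else:
        fits = fit_batch(conc, grid.fractions, model)
        karr = fits.k.to_numpy()
        Aarr = fits.A.to_numpy()
        for pos in range(len(grid.truths)):
            fhat = np.asarray(model_predict(karr[pos], Aarr[pos], conc, model))
            fit = FitResult(
                karr[pos],
                Aarr[pos],
                karr[pos] * Aarr[pos],
                fhat,
                float(fits.residual_norm.iloc[pos]),
                True,
            )
            rng = np.random.default_rng(np.random.SeedSequence([seed, pos]))
            samples = _bootstrap_samples(
                conc, grid.fractions[pos], fit, model, n_boot, rng
            )
            sd = samples.std(axis=0, ddof=1)
            if metric == "gamma":
                values[pos] = gamma_score(sd[0], samples[:, 1].mean(), sd[2])
            else:
                values[pos] = sd[1]
    out = grid.truths.copy()
    out["value"] = values
    return out


def separability_boundary(
    kA: np.ndarray,
    gamma: np.ndarray,
    gamma_threshold: float = 0.5,
    bin_width: float = 0.5,
) -> float:
    """kA level at which half the sequences become separable.

    Sequences are binned by log10(kA) (``bin_width`` decades); within each
    bin the fraction with ``gamma < gamma_threshold`` is computed, the
    fraction profile is made monotone by a running maximum from low kA, and
    the 50% crossing is interpolated.  Returns the crossing kA
    (min^-1 M^-1).
    """
    kA = np.asarray(kA, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    log_kA = np.log10(kA)
    edges = np.arange(log_kA.min(), log_kA.max() + bin_width, bin_width)
    centers, fracs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (log_kA >= lo) & (log_kA < hi)
        if sel.sum() == 0:
            continue
        centers.append((lo + hi) / 2.0)
        fracs.append(float((gamma[sel] < gamma_threshold).mean()))
    centers = np.asarray(centers)
    fracs = np.maximum.accumulate(np.asarray(fracs))
    if fracs[-1] < 0.5:
        return float("inf")
    if fracs[0] >= 0.5:
        return float(10.0 ** centers[0])
    # strictly increasing support for interpolation
    fr = fracs + np.arange(len(fracs)) * 1e-12
    return float(10.0 ** np.interp(0.5, fr, centers))
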