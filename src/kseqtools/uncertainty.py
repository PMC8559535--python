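"""Bootstrap uncertainty quantification and identifiability metrics.

Uncertainty on the fitted (k, A, kA) of each sequence is estimated by
resampling *relative residuals*: with point-estimate predictions
``fhat_ij`` and observations ``f_ij``, the relative residuals
``r_ij = (f_ij - fhat_ij) / fhat_ij`` are drawn with replacement to the
original sample size and re-applied as ``(1 + r*) * fhat_ij`` to form each
bootstrap dataset, which is then refitted.  Summaries over ``n_boot``
refits give per-parameter mean, s.d., median and two 95% confidence
intervals (normal-theory ``mean ± 1.96 s.d.`` and the 2.5–97.5 percentile
interval; the percentile interval is the default for reporting).

Identifiability of k and A separately (as opposed to their product) is
scored from the same bootstrap samples by

    gamma = log10(sigma_k * mu_A / sigma_kA),

near 0 when k and A are separable and increasingly positive as the k
estimate becomes noisier than the kA estimate, and by ``sigma_A``, the
bootstrap s.d. of A.  Per-sequence precision is summarized by the
fold-range, the ratio of the 97.5th to the 2.5th kA percentile.

Observations where ``fhat_ij = 0`` have no defined relative residual; they
are excluded from the residual pool and kept as fixed zeros in refits.

A replicate-series alternative (``triplicate_*``): each replicate at every
concentration is assigned to one series, each series is fitted separately,
and the CI-95 is ``mean ± 1.96 s.d.`` across series.  Replicate-based
intervals are typically overconfident relative to bootstrap ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import FitResult, KineticModelConfig, _profile_fit, model_predict
from .quantify import ReactedFractionTable

__all__ = [
    "BootstrapSummary",
    "TriplicateSummary",
    "bootstrap_fit",
    "bootstrap_pool",
    "gamma_score",
    "triplicate_uncertainty",
    "triplicate_pool",
    "ci_coverage",
    "binned_coverage",
    "accuracy_report",
]

_PARAMS = ["k", "A", "kA"]


def gamma_score(sigma_k: float, mu_A: float, sigma_kA: float) -> float:
    """Identifiability score ``log10(sigma_k * mu_A / sigma_kA)``.

    Degenerate cases: a perfectly determined fit (``sigma_kA = 0`` with
    ``sigma_k = 0``) scores 0; ``sigma_kA = 0`` with ``sigma_k > 0`` returns
    +inf.  Invariant under rescaling of the k axis (k and kA scale
    together).
    """
    if sigma_kA == 0.0:
        return 0.0 if sigma_k == 0.0 else math.inf
    return math.log10(sigma_k * mu_A / sigma_kA)


@dataclass
class BootstrapSummary:
    """Bootstrap statistics for one sequence.

    ``samples`` holds the n_boot (k, A, kA) estimates; ``mean``/``sd``/
    ``median`` are indexed by parameter; the CI frames have lo/hi columns.
    """

    n_boot: int
    samples: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    median: pd.Series
    ci95_normal: pd.DataFrame
    ci95_pctl: pd.DataFrame
    gamma: float
    fold_range: float

    @property
    def sigma_A(self) -> float:
        return float(self.sd["A"])


def _summarize(samples: pd.DataFrame, n_boot: int) -> BootstrapSummary:
    mean = samples.mean()
    sd = samples.std(ddof=1) if len(samples) > 1 else samples.iloc[0] * 0.0
    # constant columns are exactly constant (degenerate bootstrap), not eps-noisy
    sd[samples.nunique() == 1] = 0.0
    median = samples.median()
    lo_n = mean - 1.96 * sd
    hi_n = mean + 1.96 * sd
    lo_p = samples.quantile(0.025)
    hi_p = samples.quantile(0.975)
    ci_n = pd.DataFrame({"lo": lo_n, "hi": hi_n})
    ci_p = pd.DataFrame({"lo": lo_p, "hi": hi_p})
    gamma = gamma_score(float(sd["k"]), float(mean["A"]), float(sd["kA"]))
    lo, hi = float(lo_p["kA"]), float(hi_p["kA"])
    if hi == lo:
        fold = 1.0 if lo > 0 else math.nan
    elif lo <= 0:
        fold = math.inf
    else:
        fold = hi / lo
    return BootstrapSummary(n_boot, samples, mean, sd, median, ci_n, ci_p, gamma, fold)


def _bootstrap_samples(conc, y, fit: FitResult, cfg, n_boot, rng) -> np.ndarray:
    """(n_boot, 3) array of bootstrap (k, A, kA) estimates."""
    fhat = np.asarray(fit.fitted_fractions, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = fhat > 0
    r = (y[pos] - fhat[pos]) / fhat[pos]
    if r.size == 0 or not np.any(r):
        # no defined residuals (or all exactly zero): every resampled dataset
        # equals the original, so the bootstrap is a fixed point
        return np.tile([fit.k_hat, fit.A_hat, fit.kA_hat], (n_boot, 1))
    idx = rng.integers(0, r.size, size=(n_boot, r.size))
    Yb = np.zeros((n_boot, y.size))
    Yb[:, pos] = (1.0 + r[idx]) * fhat[pos]
    k, A, _ = _profile_fit(conc, Yb, cfg)
    return np.column_stack([k, A, k * A])


def bootstrap_fit(
    conc: np.ndarray,
    fractions: np.ndarray,
    fit: FitResult,
    cfg: KineticModelConfig = KineticModelConfig(),
    n_boot: int = 100,
    seed: int | np.random.Generator | None = None,
) -> BootstrapSummary:
    """Bootstrap the relative residuals of one sequence's fit."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _bootstrap_samples(np.asarray(conc, float), fractions, fit, cfg, n_boot, rng)
    samples = pd.DataFrame(arr, columns=_PARAMS)
    return _summarize(samples, n_boot)


def bootstrap_pool(
    frac: ReactedFractionTable,
    fits: pd.DataFrame,
    cfg: KineticModelConfig = KineticModelConfig(),
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap every fitted sequence of a pool.

    ``fits`` is the output of :func:`kseqtools.kinetics.fit_pool`.  Each
    sequence's RNG is seeded from ``(seed, row position)`` so results do not
    depend on batch order.  Returns one row per sequence with bootstrap
    mean/sd/median of k, A, kA, both CI-95 variants for kA, gamma and
    fold-range.
    """
    conc = frac.conditions
    Y = frac.fractions.loc[fits.index].to_numpy(dtype=float)
    rows = []
    for pos, seq in enumerate(fits.index):
        row = fits.loc[seq]
        fhat = np.asarray(model_predict(row["k"], row["A"], conc, cfg))
        fit = FitResult(
            row["k"], row["A"], row["kA"], fhat, row["residual_norm"], bool(row["converged"])
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, pos]))
        s = _summarize(
            pd.DataFrame(
                _bootstrap_samples(conc, Y[pos], fit, cfg, n_boot, rng), columns=_PARAMS
            ),
            n_boot,
        )
        rows.append(
            {
                "k_mean": s.mean["k"],
                "k_sd": s.sd["k"],
                "A_mean": s.mean["A"],
                "A_sd": s.sd["A"],
                "kA_mean": s.mean["kA"],
                "kA_sd": s.sd["kA"],
                "kA_median": s.median["kA"],
                "kA_ci_lo_normal": s.ci95_normal.loc["kA", "lo"],
                "kA_ci_hi_normal": s.ci95_normal.loc["kA", "hi"],
                "kA_ci_lo_pctl": s.ci95_pctl.loc["kA", "lo"],
                "kA_ci_hi_pctl": s.ci95_pctl.loc["kA", "hi"],
                "gamma": s.gamma,
                "fold_range": s.fold_range,
            }
        )
    return pd.DataFrame(rows, index=fits.index)


@dataclass
class TriplicateSummary:
    """Replicate-series fits for one sequence: per-series (k, A, kA)
    estimates and mean / sd / normal CI-95 across series."""

    estimates: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    ci95_normal: pd.DataFrame
    n_series: int

    @property
    def low_replicate(self) -> bool:
        return self.n_series < 3


def triplicate_uncertainty(
    conc: np.ndarray,
    fractions: np.ndarray,
    replicates: np.ndarray,
    cfg: KineticModelConfig = KineticModelConfig(),
) -> TriplicateSummary:
    """Fit each replicate series separately; CI-95 = mean ± 1.96 s.d."""
    conc = np.asarray(conc, float)
    y = np.asarray(fractions, float)
    replicates = np.asarray(replicates)
    est = []
    labels = []
    for s in np.unique(replicates):
        sel = replicates == s
        k, A, _ = _profile_fit(conc[sel], y[None, sel], cfg)
        est.append([float(k[0]), float(A[0]), float(k[0] * A[0])])
        labels.append(s)
    df = pd.DataFrame(est, columns=_PARAMS, index=pd.Index(labels, name="series"))
    mean = df.mean()
    sd = df.std(ddof=1) if len(df) > 1 else df.iloc[0] * 0.0
    ci = pd.DataFrame({"lo": mean - 1.96 * sd, "hi": mean + 1.96 * sd})
    return TriplicateSummary(df, mean, sd, ci, len(df))


def triplicate_pool(
    frac: ReactedFractionTable,
    cfg: KineticModelConfig = KineticModelConfig(),
    mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Vectorized replicate-series uncertainty over a whole pool.

    Returns per-sequence kA mean/sd and the normal CI-95 across series.
    """
    table = frac.fractions if mask is None else frac.fractions.loc[np.asarray(mask, bool)]
    conc = frac.conditions
    reps = frac.replicate.to_numpy()
    Y = table.to_numpy(dtype=float)
    kA_series = []
    for s in np.unique(reps):
        sel = reps == s
        k, A, _ = _profile_fit(conc[sel], Y[:, sel], cfg)
        kA_series.append(k * A)
    arr = np.column_stack(kA_series)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(len(arr))
    return pd.DataFrame(
        {
            "kA_mean": mean,
            "kA_sd": sd,
            "kA_ci_lo": mean - 1.96 * sd,
            "kA_ci_hi": mean + 1.96 * sd,
            "n_series": arr.shape[1],
        },
        index=table.index,
    )


def ci_coverage(truths: pd.Series, lo: pd.Series, hi: pd.Series) -> float:
    """Fraction of sequences whose true value lies inside [lo, hi]."""
    idx = truths.index.intersection(lo.index)
    if len(idx) == 0:
        raise ValueError("no shared sequences between truths and intervals")
    t = truths.loc[idx]
    inside = (t >= lo.loc[idx]) & (t <= hi.loc[idx])
    return float(inside.mean())


def binned_coverage(
    truths: pd.Series,
    lo: pd.Series,
    hi: pd.Series,
    mean_counts: pd.Series,
    bin_size: int = 25_000,
) -> pd.DataFrame:
    """Coverage within successive bins of ``bin_size`` sequences ranked by
    mean counts (highest first)."""
    idx = truths.index.intersection(lo.index)
    order = mean_counts.loc[idx].sort_values(ascending=False).index
    rows = []
    for start in range(0, len(order), bin_size):
        chunk = order[start : start + bin_size]
        rows.append(
            {
                "bin": len(rows),
                "n": len(chunk),
                "mean_counts_median": float(mean_counts.loc[chunk].median()),
                "coverage": ci_coverage(truths.loc[chunk], lo.loc[chunk], hi.loc[chunk]),
            }
        )
    return pd.DataFrame(rows)


def accuracy_report(
    truths: pd.Series,
    estimates: pd.Series,
    mean_counts: pd.Series,
    clip: tuple[float, float] = (0.01, 100.0),
    count_edges: tuple[float, ...] = (0.0, 10.0, 50.0, 200.0, 1000.0, math.inf),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate/truth ratios versus mean counts.

    Returns ``(per_sequence, strata)``: the per-sequence frame holds the raw
    and display-clipped ratio plus mean counts; the strata frame summarizes
    each count stratum with the median ratio, median absolute relative error
    and median fold error (``max(ratio, 1/ratio)``).  Sequences with zero
    truth are excluded and tallied in ``strata.attrs['n_zero_truth']``.
    """
    idx = truths.index.intersection(estimates.index)
    t = truths.loc[idx]
    nonzero = t != 0
    ratio = estimates.loc[idx[nonzero]] / t[nonzero]
    per_seq = pd.DataFrame(
        {
            "ratio": ratio,
            "ratio_display": ratio.clip(*clip),
            "mean_counts": mean_counts.loc[ratio.index],
        }
    )
    rows = []
    for lo_e, hi_e in zip(count_edges[:-1], count_edges[1:]):
        sel = per_seq[(per_seq.mean_counts >= lo_e) & (per_seq.mean_counts < hi_e)]
        if len(sel) == 0:
            continue
        r = sel.ratio
        rows.append(
            {
                "counts_lo": lo_e,
                "counts_hi": hi_e,
                "n": len(sel),
                "median_ratio": float(r.median()),
                "median_abs_rel_err": float((r - 1.0).abs().median()),
                "median_fold_err": float(np.maximum(r, 1.0 / r).median()),
            }
        )
    strata = pd.DataFrame(rows)
    strata.attrs["n_zero_truth"] = int((~nonzero).sum())
    return per_seq, strata
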