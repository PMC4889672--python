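"""Lorenz/Gini heterogeneity of the crossover map and design-aware tests.

The Gini coefficient of a recombination map orders the inter-marker intervals
by per-bp crossover rate and relates cumulative physical length to cumulative
genetic length (crossover fraction); 0 means a uniform rate, 1 means all
crossovers in one point.  The uniformity test conditions on the observed
per-side totals — the genotyping design fixed how many strains were typed on
each side — and compares the residual deviance of the offset+side model to a
multinomial null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import glm
from .panel_io import CrossoverTable, ValidationError


@dataclass
class GiniResult:
    gini: float
    lorenz_points: np.ndarray  # (k+1, 2): cumulative physical, genetic fractions
    side: str


def gini_from_rates(counts: np.ndarray, lengths: np.ndarray) -> GiniResult:
    """Gini and Lorenz curve from per-interval counts and lengths."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if len(counts) < 2:
        raise ValidationError("need at least 2 intervals")
    total = counts.sum()
    if total <= 0:
        raise ValidationError("zero total crossover count")
    order = np.argsort(counts / lengths, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(lengths[order]) / lengths.sum()])
    y = np.concatenate([[0.0], np.cumsum(counts[order]) / total])
    area = float(np.trapezoid(y, x))
    return GiniResult(gini=1.0 - 2.0 * area,
                      lorenz_points=np.column_stack([x, y]), side="both")


def lorenz_gini(table: CrossoverTable, side: str = "both") -> GiniResult:
    """Gini coefficient of the unmasked intervals of ``table`` on ``side``."""
    res = gini_from_rates(table.counts(side), table.lengths(side))
    res.side = side
    return res


@dataclass
class UniformNullEnsemble:
    """Crossover tables simulated under a uniform per-bp rate.

    For each side independently the observed side total is distributed over
    that side's unmasked intervals multinomially with probabilities
    proportional to interval length, preserving the sampling design.
    ``counts`` has shape (n_sims, n_unmasked_intervals) aligned with the
    unmasked rows of the source table.
    """

    counts: np.ndarray
    side_indicator: np.ndarray
    lengths: np.ndarray
    seed: int

    @property
    def n_sims(self) -> int:
        return self.counts.shape[0]


def simulate_uniform_null(table: CrossoverTable, n_sims: int,
                          seed: int) -> UniformNullEnsemble:
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = table.lengths()
    side_ind = table.side_indicator()
    counts = np.zeros((n_sims, len(lengths)), dtype=np.int64)
    for level in np.unique(side_ind):
        m = side_ind == level
        total = int(table.counts()[m].sum())
        if total <= 0:
            raise ValidationError("side with zero total crossovers")
        probs = lengths[m] / lengths[m].sum()
        counts[:, m] = rng.multinomial(total, probs, size=n_sims)
    return UniformNullEnsemble(counts, side_ind, lengths.astype(float), seed)


def uniformity_test(table: CrossoverTable,
                    ensemble: UniformNullEnsemble) -> tuple[float, float, np.ndarray]:
    """Monte-Carlo test of rate uniformity given the sampling design.

    Returns ``(p, observed_deviance, null_deviances)``.  The statistic is the
    residual deviance of the offset+side Poisson model; the p-value is the
    add-one fraction of simulated tables with deviance at least the observed.
    """
    lengths = table.lengths()
    if ensemble.counts.shape[1] != len(lengths):
        raise ValidationError("ensemble interval structure does not match table")
    side_ind = table.side_indicator()
    obs_fit = glm.base_fit(table)
    if not obs_fit.converged:
        raise ValidationError("base model did not converge on observed data")
    observed = obs_fit.residual_deviance
    null = np.array([
        glm.offset_side_deviance(ensemble.counts[i], lengths, side_ind)
        for i in range(ensemble.n_sims)])
    p = (1.0 + np.sum(null >= observed)) / (ensemble.n_sims + 1.0)
    return float(p), float(observed), null


def ks_compare(table: CrossoverTable, side: str) -> tuple[float, float]:
    """Two-sample two-sided KS test of crossover position between crosses.

    Counts are placed at their interval's right boundary (the per-strain data
    are interval-censored, so no finer convention exists); the asymptotic p
    is used as per-cross totals are in the hundreds.
    """
    df = table.unmasked(side)
    boundaries = df["end"].to_numpy()
    samples = []
    for cross in ("faxnil", "lonnil"):
        counts = df[f"count_{cross}"].to_numpy()
        if counts.sum() == 0:
            raise ValidationError(f"cross {cross} has no events on side {side}")
        samples.append(np.repeat(boundaries, counts))
    res = stats.ks_2samp(samples[0], samples[1], method="asymp")
    return float(res.statistic), float(res.pvalue)


def gini_downsample_compare(reference_table: CrossoverTable,
                            target_table: CrossoverTable,
                            n_perm: int = 1000,
                            seed: int = 0,
                            side: str = "both") -> tuple[float, np.ndarray, float]:
    """Down-sample a richer map to a target's event count and compare Ginis.

    The reference crossovers are repeatedly subsampled without replacement to
    the target's total; Gini is recomputed on the reference intervals each
    time.  Returns a two-sided add-one Monte-Carlo p (doubled one-sided tail,
    capped at 1), the subsampled Gini distribution, and the target Gini.
    """
    ref_counts = reference_table.counts(side)
    ref_lengths = reference_table.lengths(side)
    n_target = target_table.total(side)
    n_ref = int(ref_counts.sum())
    if n_target > n_ref:
        raise ValidationError("target has more crossovers than reference")
    target_gini = lorenz_gini(target_table, side).gini
    rng = np.random.default_rng(seed)
    events = np.repeat(np.arange(len(ref_counts)), ref_counts)
    ginis = np.empty(n_perm)
    for i in range(n_perm):
        take = rng.choice(events, size=n_target, replace=False)
        sub = np.bincount(take, minlength=len(ref_counts))
        ginis[i] = gini_from_rates(sub, ref_lengths).gini
    lo = (1 + np.sum(ginis <= target_gini)) / (n_perm + 1)
    hi = (1 + np.sum(ginis >= target_gini)) / (n_perm + 1)
    p = min(1.0, 2.0 * min(lo, hi))
    return float(p), ginis, float(target_gini)
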