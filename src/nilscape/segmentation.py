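"""Piecewise-constant crossover-rate domains by exact ML segmentation.

A side of the focal interval is modeled as K contiguous domains, each with a
single per-bp crossover rate; domain boundaries (knots) fall on marker
positions.  For fixed K the maximum-likelihood segmentation pools counts and
lengths within domains (the MLE rate of a domain is pooled count / pooled
length) and is found exactly by dynamic programming over interval boundaries.
The minimal adequate K is the smallest K whose likelihood-ratio statistic
against the saturated (one rate per interval) model is not extreme under a
parametric bootstrap from the fitted K-domain model, conditioning on the
observed side total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel_io import CrossoverTable, ValidationError


@dataclass
class Segmentation:
    side: str
    knots: list[int]           # interior boundary positions (marker positions)
    segment_rates: np.ndarray  # crossovers per bp, one per domain
    log_likelihood: float      # up to data-only constants shared across K
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_domains(self) -> int:
        return len(self.segment_rates)


def _segment_score(c: float, length: float) -> float:
    """Poisson profile log-likelihood of one domain, data constants dropped."""
    return c * np.log(c / length) - c if c > 0 else 0.0


def _dp_segment(counts: np.ndarray, lengths: np.ndarray,
                K: int) -> tuple[float, list[int]]:
    """Exact DP over all placements of K-1 knots; returns (score, cut indices).

    ``cuts`` are indices i such that a new domain starts at interval i.
    """
    n = len(counts)
    cc = np.concatenate([[0.0], np.cumsum(counts)])
    cl = np.concatenate([[0.0], np.cumsum(lengths)])

    NEG = -np.inf
    best = np.full((K + 1, n + 1), NEG)
    back = np.zeros((K + 1, n + 1), dtype=np.int64)
    best[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            i = np.arange(k - 1, j)
            dc = cc[j] - cc[i]
            dl = cl[j] - cl[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                seg = np.where(dc > 0, dc * np.log(dc / dl) - dc, 0.0)
            vals = best[k - 1, i] + seg
            i_best = int(np.argmax(vals))
            best[k, j] = vals[i_best]
            back[k, j] = i_best + (k - 1)
    cuts = []
    j = n
    for k in range(K, 0, -1):
        i = int(back[k, j])
        cuts.append(i)
        j = i
    return float(best[K, n]), sorted(cuts)


def saturated_score(counts: np.ndarray, lengths: np.ndarray) -> float:
    """Profile log-likelihood (same constants dropped) of one rate per interval."""
    return float(sum(_segment_score(float(c), float(l))
                     for c, l in zip(counts, lengths)))


def fit_segmentation(table: CrossoverTable, side: str, K: int) -> Segmentation:
    """Exact ML fit of K constant-rate domains on one side of the table."""
    df = table.unmasked(side)
    counts = (df["count_faxnil"] + df["count_lonnil"]).to_numpy(dtype=float)
    lengths = df["length"].to_numpy(dtype=float)
    n = len(counts)
    if not 1 <= K <= n:
        raise ValidationError(f"K={K} outside [1, {n}] for side {side}")
    score, cuts = _dp_segment(counts, lengths, K)
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    bounds_idx = cuts + [n]
    rates = []
    seg_bounds = []
    knots = []
    for a, b in zip(bounds_idx[:-1], bounds_idx[1:]):
        c = counts[a:b].sum()
        length = lengths[a:b].sum()
        rates.append(c / length)
        seg_bounds.append((int(starts[a]), int(ends[b - 1])))
        if a > 0:
            knots.append(int(starts[a]))
    return Segmentation(side=side, knots=knots,
                        segment_rates=np.array(rates),
                        log_likelihood=score, segment_bounds=seg_bounds)


def lrt_statistic(table: CrossoverTable, side: str, K: int) -> float:
    """2*(saturated − K-domain profile loglik); the K-domain residual deviance."""
    df = table.unmasked(side)
    counts = (df["count_faxnil"] + df["count_lonnil"]).to_numpy(dtype=float)
    lengths = df["length"].to_numpy(dtype=float)
    seg = fit_segmentation(table, side, K)
    return 2.0 * (saturated_score(counts, lengths) - seg.log_likelihood)


@dataclass
class DomainTestResult:
    side: str
    alpha: float
    n_sims: int
    seed: int
    per_k: list[dict]  # K, log_likelihood, lrt, p
    minimal_adequate_k: int | None


def min_adequate_domains(table: CrossoverTable, side: str,
                         alpha: float = 0.05, k_max: int = 40,
                         n_sims: int = 999, seed: int = 0) -> DomainTestResult:
    """Smallest K whose K-domain model is not rejected against the saturated one.

    For each K (ascending) the LRT statistic is compared to a null built by
    parametric bootstrap: ``n_sims`` tables drawn multinomially from the
    fitted K-domain rates, conditioned on the observed side total, each
    refitted at K.  p is the add-one Monte-Carlo fraction of bootstrap
    statistics at least the observed.  Stops at the first K with p >= alpha.
    """
    if n_sims < 99:
        raise ValidationError("n_sims must be >= 99")
    df = table.unmasked(side)
    counts = (df["count_faxnil"] + df["count_lonnil"]).to_numpy(dtype=float)
    lengths = df["length"].to_numpy(dtype=float)
    n = len(counts)
    total = int(counts.sum())
    k_max = min(k_max, n - 1)
    rng = np.random.default_rng(seed)
    sat = saturated_score(counts, lengths)
    per_k: list[dict] = []
    minimal: int | None = None
    for K in range(1, k_max + 1):
        score, cuts = _dp_segment(counts, lengths, K)
        obs_lrt = 2.0 * (sat - score)
        # expected per-interval probabilities under the fitted K-domain model
        bounds = cuts + [n]
        mu = np.empty(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg_c = counts[a:b].sum()
            seg_l = lengths[a:b].sum()
            mu[a:b] = lengths[a:b] * (seg_c / seg_l)
        probs = mu / mu.sum()
        exceed = 0
        for _ in range(n_sims):
            sim = rng.multinomial(total, probs).astype(float)
            sim_score, _ = _dp_segment(sim, lengths, K)
            sim_lrt = 2.0 * (saturated_score(sim, lengths) - sim_score)
            if sim_lrt >= obs_lrt:
                exceed += 1
        p = (1.0 + exceed) / (n_sims + 1.0)
        per_k.append(dict(K=K, log_likelihood=score, lrt=obs_lrt, p=p))
        if p >= alpha:
            minimal = K
            break
    return DomainTestResult(side=side, alpha=alpha, n_sims=n_sims, seed=seed,
                            per_k=per_k, minimal_adequate_k=minimal)
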