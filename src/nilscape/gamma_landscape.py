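"""Gamma-distributed crossover-rate landscapes: hotspot-compatibility simulation.

The per-kilobase crossover rate is drawn i.i.d. from a gamma distribution
whose shape parameter k tunes heterogeneity: k = 1 is an exponential
(hotspot-like) landscape, k → ∞ a uniform one (the gamma coefficient of
variation is 1/√k).  Crossovers are placed uniformly within bins, then binned
into the inter-marker intervals of a marker map, so simulated panels carry the
same interval censoring as the observed data.  Fitting the shape to an
observed Gini asks which landscapes are compatible with the measured
heterogeneity; the expected max/mean rate multiple translates a shape into
hotspot language.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .heterogeneity import GiniResult, gini_from_rates
from .panel_io import CrossoverTable, MarkerMap, ValidationError

SHAPE_CAP = 1e6  # beyond this the landscape is numerically uniform


@dataclass
class RateLandscape:
    """Per-bin crossover rates (crossovers/bp) over a physical span."""

    bin_size: int
    rates: np.ndarray
    span: tuple[int, int]
    kind: str = "gamma"  # uniform | gamma | hotspot

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        n_expect = int(np.ceil((self.span[1] - self.span[0]) / self.bin_size))
        if len(self.rates) != n_expect:
            raise ValidationError(
                f"{len(self.rates)} rates for span needing {n_expect} bins")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValidationError("rates must be finite and non-negative")

    @property
    def bin_starts(self) -> np.ndarray:
        return self.span[0] + self.bin_size * np.arange(len(self.rates))


def draw_gamma_landscape(shape: float, n_bins: int, total_rate: float,
                         seed: int, span_start: int = 1,
                         bin_size: int = 1000) -> RateLandscape:
    """i.i.d. gamma(shape) per-bin rates rescaled to an expected total.

    ``total_rate`` is the expected number of crossovers over the whole span;
    shapes above ``SHAPE_CAP`` are capped (numerically uniform).
    """
    if shape <= 0:
        raise ValidationError("gamma shape must be positive")
    if n_bins < 1:
        raise ValidationError("need at least one bin")
    shape = min(shape, SHAPE_CAP)
    rng = np.random.default_rng(seed)
    raw = rng.gamma(shape, 1.0, size=n_bins)
    raw = np.maximum(raw, 1e-300)
    rates = raw * (total_rate / (raw.sum() * bin_size))
    span = (span_start, span_start + n_bins * bin_size)
    return RateLandscape(bin_size, rates, span, "gamma")


def uniform_landscape(span: tuple[int, int], total_rate: float,
                      bin_size: int = 1000) -> RateLandscape:
    n_bins = int(np.ceil((span[1] - span[0]) / bin_size))
    rate = total_rate / (n_bins * bin_size)
    return RateLandscape(bin_size, np.full(n_bins, rate), span, "uniform")


def draw_positions(landscape: RateLandscape, n_crossovers: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Crossover positions: bin chosen ∝ rate·bin_size, uniform within bin."""
    weights = landscape.rates * landscape.bin_size
    if weights.sum() <= 0:
        raise ValidationError("all-zero landscape")
    probs = weights / weights.sum()
    bins = rng.choice(len(probs), size=n_crossovers, p=probs)
    return landscape.bin_starts[bins] + rng.uniform(0, landscape.bin_size,
                                                    size=n_crossovers)


def simulate_panel(landscape: RateLandscape, marker_map: MarkerMap,
                   n_crossovers: int, seed: int,
                   cross: str = "faxnil") -> CrossoverTable:
    """Draw crossovers from a landscape and censor them into marker intervals.

    Positions falling outside every inter-marker interval (the indel gap or
    beyond the outermost markers) are redrawn, so counts are conserved:
    exactly ``n_crossovers`` land in intervals.
    """
    if landscape.span[0] > marker_map.positions[0] or \
            landscape.span[1] < marker_map.positions[-1]:
        raise ValidationError("landscape span does not cover the marker map")
    rng = np.random.default_rng(seed)
    grid = marker_map.intervals()
    starts = grid["start"].to_numpy()
    ends = grid["end"].to_numpy()
    counts = np.zeros(len(grid), dtype=np.int64)
    remaining = n_crossovers
    for _ in range(1000):
        if remaining == 0:
            break
        pos = draw_positions(landscape, remaining, rng)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        hit = idx[ok]
        np.add.at(counts, hit, 1)
        remaining -= int(ok.sum())
    if remaining:
        raise ValidationError("landscape places essentially no mass on the map")
    df = grid.copy()
    df["count_faxnil"] = 0
    df["count_lonnil"] = 0
    df[f"count_{cross}"] = counts
    df["masked"] = False
    return CrossoverTable(df, "full")


def _interval_gini(landscape_shape: float, boundaries_starts: np.ndarray,
                   boundaries_ends: np.ndarray, lengths: np.ndarray,
                   span: tuple[int, int], n_crossovers: int,
                   rng: np.random.Generator, bin_size: int = 1000) -> float:
    """One Gini draw: fresh gamma landscape over span, panel, interval Gini."""
    n_bins = int(np.ceil((span[1] - span[0]) / bin_size))
    raw = np.maximum(rng.gamma(min(landscape_shape, SHAPE_CAP), 1.0, n_bins),
                     1e-300)
    probs_bin = raw / raw.sum()
    bins = rng.choice(n_bins, size=n_crossovers, p=probs_bin)
    pos = span[0] + bins * bin_size + rng.uniform(0, bin_size, n_crossovers)
    idx = np.searchsorted(boundaries_starts, pos, side="right") - 1
    ok = (idx >= 0) & (pos < boundaries_ends[np.clip(idx, 0, len(lengths) - 1)])
    counts = np.bincount(idx[ok], minlength=len(lengths))
    if counts.sum() < 2:
        return np.nan
    return gini_from_rates(counts, lengths).gini


def gini_envelope(shape: float, marker_map: MarkerMap, n_crossovers: int,
                  n_sims: int = 5000, seed: int = 0,
                  side: str = "both") -> tuple[float, dict[str, float]]:
    """Distribution of interval-censored Gini under a gamma(shape) landscape.

    Each simulation draws a fresh landscape and a fresh panel of
    ``n_crossovers`` events, then computes the Gini over the map's intervals.
    Returns the mean and the 2.5/50/97.5% quantiles.
    """
    if n_sims < 100:
        raise ValidationError("n_sims must be >= 100")
    ginis = simulate_ginis(shape, marker_map, n_crossovers, n_sims, seed, side)
    q = np.percentile(ginis, [2.5, 50, 97.5])
    return float(ginis.mean()), {"q2.5": float(q[0]), "q50": float(q[1]),
                                 "q97.5": float(q[2])}


def simulate_ginis(shape: float, marker_map: MarkerMap, n_crossovers: int,
                   n_sims: int, seed: int, side: str = "both") -> np.ndarray:
    if shape <= 0:
        raise ValidationError("gamma shape must be positive")
    grid = marker_map.intervals()
    if side != "both":
        grid = grid[grid["side"] == side].reset_index(drop=True)
    starts = grid["start"].to_numpy().astype(float)
    ends = grid["end"].to_numpy().astype(float)
    lengths = grid["length"].to_numpy().astype(float)
    span = (int(starts[0]), int(ends[-1]))
    rng = np.random.default_rng(seed)
    out = np.array([
        _interval_gini(shape, starts, ends, lengths, span, n_crossovers, rng)
        for _ in range(n_sims)])
    return out[~np.isnan(out)]


def gamma_gini_closed_form(shape: float) -> float:
    """Gini of the gamma distribution itself: Γ(k+½)/(Γ(k+1)·√π).

    The dense-marker, many-crossover limit of the simulated Gini.
    """
    return float(np.exp(special.gammaln(shape + 0.5)
                        - special.gammaln(shape + 1.0)) / np.sqrt(np.pi))


def max_rate_multiple(shape: float, n_bins: int, n_reps: int = 10_000,
                      seed: int = 0) -> float:
    """Monte-Carlo E[max/mean] of n_bins i.i.d. gamma(shape) per-kb rates.

    The expected fold of the most recombinant kilobase over the mean rate;
    each replicate records max/sample-mean and the replicates are averaged.
    """
    if shape <= 0:
        raise ValidationError("gamma shape must be positive")
    if n_bins < 1:
        raise ValidationError("need at least one bin")
    if n_reps < 100:
        warnings.warn("n_reps < 100: max/mean estimate will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    total = 0.0
    chunk = max(1, int(2e7) // n_bins)
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        draws = rng.gamma(shape, 1.0, size=(m, n_bins))
        total += float(np.sum(draws.max(axis=1) / draws.mean(axis=1)))
        done += m
    return total / n_reps


@dataclass
class GammaFit:
    shape: float
    ci95: tuple[float, float]
    observed_gini: float
    n_sims_per_eval: int
    seed: int


def fit_shape_to_gini(observed: GiniResult, marker_map: MarkerMap,
                      n_crossovers: int, n_sims: int = 1000, seed: int = 0,
                      side: str = "both", tol: float = 0.002,
                      bracket: tuple[float, float] = (0.05, 64.0),
                      ci_grid_step: float = 0.25,
                      compute_ci: bool = True) -> GammaFit:
    """Gamma shape whose mean simulated Gini matches an observed Gini.

    Bisection on the shape (mean simulated Gini is decreasing in shape) until
    the mean is within ``tol`` of the observed value; the 95% CI is the range
    of grid shapes whose simulated 2.5–97.5% Gini interval covers the
    observed value.
    """
    g = observed.gini
    if not 0.0 < g < 1.0:
        raise ValidationError("observed gini must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def mean_gini(shape: float) -> float:
        s = int(rng.integers(2**31))
        return float(np.mean(simulate_ginis(shape, marker_map, n_crossovers,
                                            n_sims, s, side)))

    lo, hi = bracket
    g_lo, g_hi = mean_gini(lo), mean_gini(hi)  # g_lo > g_hi (decreasing)
    if not (g_hi <= g <= g_lo):
        raise ValidationError(
            f"observed gini {g:.3f} outside achievable range "
            f"[{g_hi:.3f}, {g_lo:.3f}] for shape bracket {bracket}")
    mid, g_mid = lo, g_lo
    for _ in range(40):
        mid = np.sqrt(lo * hi)  # geometric bisection: shape spans decades
        g_mid = mean_gini(mid)
        if abs(g_mid - g) < tol or hi / lo < 1.01:
            break
        if g_mid > g:
            lo = mid
        else:
            hi = mid
    ci = (np.nan, np.nan)
    if compute_ci:
        grid = np.exp(np.arange(np.log(bracket[0]), np.log(bracket[1]) + 1e-9,
                                ci_grid_step))
        covered = []
        for s in grid:
            sims = simulate_ginis(s, marker_map, n_crossovers, n_sims,
                                  int(rng.integers(2**31)), side)
            q_lo, q_hi = np.percentile(sims, [2.5, 97.5])
            if q_lo <= g <= q_hi:
                covered.append(s)
        if covered:
            ci = (float(min(covered)), float(max(covered)))
    return GammaFit(shape=float(mid), ci95=ci, observed_gini=g,
                    n_sims_per_eval=n_sims, seed=seed)
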