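"""Synthetic study generator: every input the pipeline consumes, with truth records.

The default scenario mirrors the study design the pipeline targets: a 1.41-Mb
focal region split by a sorting indel into an 820-kb left and a 590-kb right
side, 277 markers (139 left / 138 right) with a ~4.4-kb median gap, two
reciprocal crosses with unequal left/right crossover totals
(387/243 and 244/241), and ~36% GC sequence (a C. elegans arm value).
Generators write truth records (true breakpoints, planted effects) so every
pipeline stage can be tested for recovery, never against a black box.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .gamma_landscape import RateLandscape, draw_gamma_landscape, uniform_landscape
from .panel_io import LEFT, RIGHT, MarkerMap, StrainGenotypes, ValidationError


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study; defaults emulate the target design."""

    seed: int = 0
    span: tuple[int, int] = (3_283_000, 4_693_000)
    indel_position: int = 4_103_000
    n_markers_left: int = 139
    n_markers_right: int = 138
    median_gap_bp: float = 4_400.0
    gap_log_sd: float = 0.54  # lognormal jitter: median 4.4 kb, mean ~5.1 kb
    landscape_kind: str = "gamma"
    gamma_shape_left: float = 1.70
    gamma_shape_right: float = 3.57
    # per-cross (left, right) crossover totals: the sampling skew of the design
    totals: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "faxnil": (387, 243), "lonnil": (244, 241)})
    gc: float = 0.36
    missing_rate: float = 0.0
    het_rate: float = 0.0
    double_recombinant_rate: float = 0.0
    planted_effects: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValidationError("GC must be in (0, 1)")
        for cross, (l, r) in self.totals.items():
            if l <= 0 or r <= 0:
                raise ValidationError(f"non-positive totals for cross {cross}")

    def rng_for(self, stage: str) -> np.random.Generator:
        tag = zlib.crc32(stage.encode())  # stable across processes
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)


def synth_marker_map(scenario: SyntheticScenario) -> MarkerMap:
    """Marker positions with lognormal gap jitter around the target median.

    Gaps are drawn per side and rescaled to tile the side span exactly, so
    the first/last markers sit at the side boundaries and the indel falls
    between the sides.
    """
    rng = scenario.rng_for("marker_map")
    span_l = scenario.indel_position - scenario.span[0]
    span_r = scenario.span[1] - scenario.indel_position
    out_pos: list[int] = []
    out_side: list[str] = []
    for side, n, lo, width in (
            (LEFT, scenario.n_markers_left, scenario.span[0],
             span_l - 1000 - scenario.n_markers_left),
            (RIGHT, scenario.n_markers_right, scenario.indel_position + 1000,
             span_r - 1000 - scenario.n_markers_right)):
        if n < 2:
            raise ValidationError("need at least 2 markers per side")
        if width < 2 * n:
            raise ValidationError(f"side span {width} too small for {n} markers")
        gaps = np.exp(rng.normal(np.log(scenario.median_gap_bp),
                                 scenario.gap_log_sd, size=n - 1))
        gaps = gaps / gaps.sum() * width
        pos = lo + np.concatenate([[0.0], np.cumsum(gaps)])
        pos = np.round(pos).astype(np.int64)
        pos = np.maximum.accumulate(pos + np.arange(n))  # enforce strict increase
        out_pos.extend(int(p) for p in pos)
        out_side.extend([side] * n)
    return MarkerMap(np.array(out_pos), np.array(out_side, dtype=object),
                     scenario.indel_position, scenario.span)


def synth_landscapes(scenario: SyntheticScenario,
                     marker_map: MarkerMap) -> dict[str, RateLandscape]:
    """Per-side rate landscapes of the scenario's kind."""
    rng = scenario.rng_for("landscape")
    out: dict[str, RateLandscape] = {}
    for side, shape in ((LEFT, scenario.gamma_shape_left),
                        (RIGHT, scenario.gamma_shape_right)):
        pos = marker_map.side_positions(side)
        span = (int(pos[0]), int(pos[-1]))
        total = float(sum(scenario.totals[c][0 if side == LEFT else 1]
                          for c in scenario.totals))
        if scenario.landscape_kind == "uniform":
            out[side] = uniform_landscape(span, total)
        else:
            n_bins = int(np.ceil((span[1] - span[0]) / 1000))
            out[side] = draw_gamma_landscape(
                shape, n_bins, total, int(rng.integers(2**31)),
                span_start=span[0])
    return out


def synth_genome(scenario: SyntheticScenario,
                 hot_windows: list[tuple[int, int]] | None = None,
                 planted_motif: str | None = None,
                 planted_per_kb: float = 0.0) -> tuple[str, int]:
    """i.i.d. genome at the target GC, with optional motif enrichment.

    Returns ``(sequence, origin)`` where origin is the physical position of
    the first base.  If a motif is given, occurrences are written at
    ``planted_per_kb`` extra copies per kb into ``hot_windows`` at random
    non-overlapping offsets.
    """
    rng = scenario.rng_for("genome")
    length = scenario.span[1] - scenario.span[0]
    p = np.array([(1 - scenario.gc) / 2, scenario.gc / 2,
                  scenario.gc / 2, (1 - scenario.gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    if planted_motif and planted_per_kb > 0:
        motif = np.frombuffer(planted_motif.encode(), dtype=np.uint8)
        k = len(motif)
        for w_start, w_end in hot_windows or []:
            a = w_start - scenario.span[0]
            b = w_end - scenario.span[0]
            n_copies = int(round((b - a) / 1000 * planted_per_kb))
            if n_copies * k * 3 > (b - a):
                raise ValidationError("requested planted density infeasible")
            taken: list[int] = []
            tries = 0
            while len(taken) < n_copies and tries < 100 * n_copies:
                off = int(rng.integers(a, b - k))
                if all(abs(off - t) >= k for t in taken):
                    bases[off:off + k] = motif
                    taken.append(off)
                tries += 1
    return bases.tobytes().decode(), scenario.span[0]


def synth_panel(scenario: SyntheticScenario, marker_map: MarkerMap,
                landscapes: dict[str, RateLandscape]
                ) -> tuple[list[StrainGenotypes], dict]:
    """Genotype panel with the scenario's per-side per-cross totals.

    Crossover positions are drawn from the side landscapes with exactly the
    configured totals (the genotyping design fixed them), genotype vectors
    are written A…B or B…A around each breakpoint, and noise (missing calls,
    het contamination, double recombinants) is injected at the configured
    rates.  The truth record stores every true breakpoint.
    """
    rng = scenario.rng_for("panel")
    positions = marker_map.positions
    strains: list[StrainGenotypes] = []
    truth: dict = {"strains": [], "scenario_seed": scenario.seed}
    idx = 0
    for cross, (n_left, n_right) in scenario.totals.items():
        for side, n in ((LEFT, n_left), (RIGHT, n_right)):
            land = landscapes[side]
            weights = land.rates * land.bin_size
            probs = weights / weights.sum()
            side_pos = marker_map.side_positions(side)
            lo, hi = side_pos[0], side_pos[-1]
            for _ in range(n):
                # rejection-sample a position strictly inside the side's markers
                for _try in range(10_000):
                    b = rng.choice(len(probs), p=probs)
                    pos = land.bin_starts[b] + rng.uniform(0, land.bin_size)
                    if lo < pos < hi and pos not in positions:
                        break
                else:
                    raise ValidationError("landscape incompatible with marker span")
                idx += 1
                sid = f"S{idx:04d}"
                orientation = "A->B" if rng.random() < 0.5 else "B->A"
                first, second = ("A", "B") if orientation == "A->B" else ("B", "A")
                calls = np.where(positions < pos, first, second).astype("U1")
                true_breaks = [float(pos)]
                if rng.random() < scenario.double_recombinant_rate:
                    # inject a second, distinct crossover on the same side
                    pos2 = pos
                    while not (lo < pos2 < hi) or abs(pos2 - pos) < 2 * scenario.median_gap_bp:
                        b2 = rng.choice(len(probs), p=probs)
                        pos2 = land.bin_starts[b2] + rng.uniform(0, land.bin_size)
                    a, c = sorted((pos, pos2))
                    mid = (positions > a) & (positions < c)
                    calls = np.where(mid, second, first).astype("U1")
                    true_breaks = [float(a), float(c)]
                n_miss = rng.binomial(len(calls), scenario.missing_rate)
                if n_miss:
                    calls[rng.choice(len(calls), size=n_miss, replace=False)] = "N"
                if rng.random() < scenario.het_rate:
                    start = int(rng.integers(0, len(calls) - 2))
                    calls[start:start + int(rng.integers(1, 4))] = "H"
                strains.append(StrainGenotypes(sid, cross, calls))
                truth["strains"].append(dict(
                    strain_id=sid, cross=cross, side=side,
                    breakpoints=true_breaks, orientation=orientation,
                    n_missing=int(n_miss)))
    return strains, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
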