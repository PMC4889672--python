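"""Marker maps, genotype panels, crossover tables: the data model of the pipeline.

A nested near-isogenic line (NIL) panel localizes one meiotic crossover per
strain to the interval between the last marker of one parental genotype and the
first marker of the other.  Strains are first sorted by an indel genotype into
a "left" and a "right" group, and each group is then densely genotyped at the
SNP markers on its side of the indel; the two sides are therefore sampled with
different intensities and every downstream model carries a side covariate.

Coordinates are 1-based physical positions.  The interval between consecutive
markers at ``p_i`` and ``p_{i+1}`` is the half-open span ``[p_i, p_{i+1})`` of
length ``p_{i+1} - p_i``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"
CROSSES = ("faxnil", "lonnil")

#: genotype call codes: A = recipient (N2), B = donor (CB4856), H = het, N = missing
CALL_CODES = ("A", "B", "H", "N")


class ValidationError(ValueError):
    """Raised when an input file or object violates a data-model invariant."""


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered physical marker positions with side labels.

    Parameters
    ----------
    positions
        Strictly increasing 1-based marker positions (bp).
    sides
        Per-marker side label, ``"left"`` or ``"right"``; all left positions
        must precede the sorting indel and all right positions follow it.
    indel_position
        Position (bp) of the indel used to sort strains into side groups.
    shared_span
        ``(start, end)`` of the region shared by both crosses; defaults to the
        first/last marker positions.
    """

    positions: np.ndarray
    sides: np.ndarray
    indel_position: int
    shared_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.sides = np.asarray(self.sides, dtype=object)
        if self.positions.ndim != 1 or len(self.positions) != len(self.sides):
            raise ValidationError("positions and sides must be equal-length 1-d sequences")
        diffs = np.diff(self.positions)
        if np.any(diffs <= 0):
            idx = int(np.argmax(diffs <= 0)) + 1
            raise ValidationError(f"positions not increasing at row {idx + 1} "
                                  f"(position {self.positions[idx]})")
        bad = set(self.sides) - {LEFT, RIGHT}
        if bad:
            raise ValidationError(f"unknown side labels: {sorted(bad)}")
        left = self.positions[self.sides == LEFT]
        right = self.positions[self.sides == RIGHT]
        if len(left) < 2 or len(right) < 2:
            raise ValidationError("need at least 2 markers per side")
        if left.max() >= self.indel_position or right.min() <= self.indel_position:
            raise ValidationError(
                "side labels inconsistent with indel_position: all left markers must "
                "lie below it and all right markers above it")
        if self.shared_span is None:
            self.shared_span = (int(self.positions[0]), int(self.positions[-1]))

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    def side_positions(self, side: str) -> np.ndarray:
        return self.positions[self.sides == side]

    def intervals(self) -> pd.DataFrame:
        """Inter-marker intervals between consecutive same-side markers.

        Returns a frame with columns start, end, side, length.  The span
        between the last left marker and the first right marker contains the
        sorting indel and is not genotypable on either array, so it is not an
        interval.
        """
        rows = []
        for side in (LEFT, RIGHT):
            pos = self.side_positions(side)
            for a, b in zip(pos[:-1], pos[1:]):
                rows.append((int(a), int(b), side, int(b - a)))
        df = pd.DataFrame(rows, columns=["start", "end", "side", "length"])
        return df.sort_values("start", ignore_index=True)

    def write_tsv(self, path) -> None:
        pd.DataFrame({"position": self.positions, "side": self.sides}).to_csv(
            path, sep="\t", index=False)


def read_marker_map(path, indel_position: int | None = None) -> MarkerMap:
    """Read a marker map TSV with columns ``position`` and ``side``.

    If ``indel_position`` is not given it is placed midway between the last
    left and first right marker.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("position", "side"):
        if col not in df.columns:
            raise ValidationError(f"marker map missing column {col!r}")
    try:
        positions = df["position"].astype(np.int64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"positions not parseable as integers: {exc}") from exc
    if np.any(positions <= 0):
        row = int(np.argmax(positions <= 0)) + 1
        raise ValidationError(f"non-positive position at row {row}")
    sides = df["side"].astype(str).str.lower().to_numpy()
    if indel_position is None:
        left = positions[sides == LEFT]
        right = positions[sides == RIGHT]
        if len(left) == 0 or len(right) == 0:
            raise ValidationError("cannot infer indel position without markers on both sides")
        indel_position = int((left.max() + right.min()) // 2)
    return MarkerMap(positions, sides, int(indel_position))


# ---------------------------------------------------------------------------
# Genotypes and breakpoint calling
# ---------------------------------------------------------------------------


@dataclass
class StrainGenotypes:
    """Per-marker genotype calls for one strain (one call per map marker)."""

    strain_id: str
    cross: str  # "faxnil" | "lonnil"
    calls: np.ndarray  # unicode array over CALL_CODES

    def __post_init__(self) -> None:
        self.calls = np.asarray(list(self.calls) if isinstance(self.calls, str)
                                else self.calls, dtype="U1")
        bad = set(self.calls) - set(CALL_CODES)
        if bad:
            raise ValidationError(f"strain {self.strain_id}: unknown calls {sorted(bad)}")
        if self.cross not in CROSSES:
            raise ValidationError(f"strain {self.strain_id}: unknown cross {self.cross!r}")


@dataclass
class CrossoverInterval:
    """A crossover localized between two marker positions."""

    strain_id: str
    left_bound: int
    right_bound: int
    orientation: str  # "A->B" | "B->A"
    cross: str = "faxnil"

    def __post_init__(self) -> None:
        if not self.left_bound < self.right_bound:
            raise ValidationError(
                f"strain {self.strain_id}: degenerate breakpoint bounds "
                f"({self.left_bound}, {self.right_bound})")


@dataclass
class QCReport:
    """Strain-level quality control outcome of breakpoint calling."""

    excluded: list[tuple[str, str]] = field(default_factory=list)
    n_retained: int = 0

    REASONS = ("multiple_failures", "ambiguous_at_breakpoint", "het_stretch",
               "double_recombinant", "non_recombinant")

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.excluded:
            out[reason] = out.get(reason, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["strain_id", "reason"])


def call_breakpoints(
    panel: Sequence[StrainGenotypes],
    marker_map: MarkerMap,
    max_missing: int = 2,
) -> tuple[list[CrossoverInterval], QCReport]:
    """Call one crossover breakpoint per strain and QC-filter the panel.

    A retained strain has exactly one A→B or B→A transition among its non-
    missing calls; the breakpoint interval runs from the last marker before
    the transition to the first marker after it, skipping missing (N) calls.

    Excluded, with reasons: more than ``max_missing`` N calls
    (``multiple_failures``); any heterozygous call — a single H exactly at the
    transition is ``ambiguous_at_breakpoint``, any other H run is
    ``het_stretch``; two or more transitions (``double_recombinant``); no
    transition (``non_recombinant``).
    """
    if len(panel) == 0:
        raise ValidationError("empty genotype panel")
    intervals: list[CrossoverInterval] = []
    report = QCReport()
    positions = marker_map.positions
    for strain in sorted(panel, key=lambda s: s.strain_id):
        calls = strain.calls
        if len(calls) != marker_map.n_markers:
            raise ValidationError(
                f"strain {strain.strain_id}: {len(calls)} calls for "
                f"{marker_map.n_markers} markers")
        n_missing = int(np.sum(calls == "N"))
        if n_missing > max_missing:
            report.excluded.append((strain.strain_id, "multiple_failures"))
            continue
        informative = np.flatnonzero((calls == "A") | (calls == "B"))
        het = np.flatnonzero(calls == "H")
        seq = calls[informative]
        changes = np.flatnonzero(seq[:-1] != seq[1:])
        if len(het) > 0:
            at_break = (len(het) == 1 and len(changes) == 1
                        and informative[changes[0]] < het[0] < informative[changes[0] + 1])
            report.excluded.append(
                (strain.strain_id, "ambiguous_at_breakpoint" if at_break else "het_stretch"))
            continue
        if len(changes) == 0:
            report.excluded.append((strain.strain_id, "non_recombinant"))
            continue
        if len(changes) > 1:
            report.excluded.append((strain.strain_id, "double_recombinant"))
            continue
        i = informative[changes[0]]
        j = informative[changes[0] + 1]
        orientation = "A->B" if calls[i] == "A" else "B->A"
        intervals.append(CrossoverInterval(
            strain.strain_id, int(positions[i]), int(positions[j]),
            orientation, strain.cross))
        report.n_retained += 1
    return intervals, report


def write_genotypes(panel: Sequence[StrainGenotypes], path) -> None:
    """Write a genotype panel TSV: strain_id, cross, then one call per marker."""
    n = len(panel[0].calls) if panel else 0
    cols = ["strain_id", "cross"] + [f"m{i+1}" for i in range(n)]
    rows = [[s.strain_id, s.cross, *s.calls] for s in panel]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_genotypes(path, marker_map: MarkerMap | None = None) -> list[StrainGenotypes]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    call_cols = [c for c in df.columns if c not in ("strain_id", "cross")]
    if marker_map is not None and len(call_cols) != marker_map.n_markers:
        raise ValidationError(
            f"panel has {len(call_cols)} call columns for "
            f"{marker_map.n_markers} markers")
    return [StrainGenotypes(row["strain_id"], row["cross"].lower(),
                            np.array([row[c] for c in call_cols], dtype="U1"))
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Crossover tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["start", "end", "side", "length",
                 "count_faxnil", "count_lonnil", "masked"]


@dataclass
class CrossoverTable:
    """Per-interval crossover counts for the two crosses.

    ``data`` holds one row per inter-marker interval (or merged bin) with
    columns start, end, side, length, count_faxnil, count_lonnil, masked.
    Masked intervals are retained in the table but excluded from every model
    fit and summary.
    """

    data: pd.DataFrame
    resolution: str = "full"

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"crossover table missing columns {missing}")
        df = df[TABLE_COLUMNS].reset_index(drop=True)
        df["masked"] = df["masked"].astype(bool)
        for c in ("start", "end", "length", "count_faxnil", "count_lonnil"):
            df[c] = df[c].astype(np.int64)
        if np.any(df["length"].to_numpy() != (df["end"] - df["start"]).to_numpy()):
            raise ValidationError("length != end - start")
        if np.any(df["length"].to_numpy() <= 0):
            raise ValidationError("non-positive interval length")
        if (df[["count_faxnil", "count_lonnil"]].to_numpy() < 0).any():
            raise ValidationError("negative counts")
        for side in df["side"].unique():
            sub = df[df["side"] == side].sort_values("start")
            if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
                raise ValidationError(f"overlapping intervals on side {side}")
        self.data = df

    # -- selection ---------------------------------------------------------

    def unmasked(self, side: str | None = None) -> pd.DataFrame:
        df = self.data[~self.data["masked"]]
        if side is not None and side != "both":
            df = df[df["side"] == side]
        return df.reset_index(drop=True)

    def counts(self, side: str | None = None, cross: str | None = None) -> np.ndarray:
        df = self.unmasked(side)
        if cross is None:
            return (df["count_faxnil"] + df["count_lonnil"]).to_numpy()
        return df[f"count_{cross}"].to_numpy()

    def lengths(self, side: str | None = None) -> np.ndarray:
        return self.unmasked(side)["length"].to_numpy()

    def side_indicator(self, side: str | None = None) -> np.ndarray:
        """1.0 for right-side intervals, 0.0 for left, over unmasked rows."""
        return (self.unmasked(side)["side"] == RIGHT).to_numpy(dtype=float)

    def total(self, side: str | None = None, cross: str | None = None) -> int:
        return int(self.counts(side, cross).sum())

    def with_counts(self, counts: np.ndarray,
                    cross: str = "faxnil") -> "CrossoverTable":
        """Copy of the table with unmasked counts for one cross replaced
        (the other cross zeroed).  Used by simulators."""
        df = self.data.copy()
        df["count_faxnil"] = 0
        df["count_lonnil"] = 0
        idx = df.index[~df["masked"]]
        if len(idx) != len(counts):
            raise ValidationError("counts length does not match unmasked intervals")
        df.loc[idx, f"count_{cross}"] = np.asarray(counts, dtype=np.int64)
        return CrossoverTable(df, self.resolution)

    # -- IO ----------------------------------------------------------------

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out["masked"] = out["masked"].astype(int)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, resolution: str = "full") -> "CrossoverTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, resolution)


def tabulate_crossovers(
    intervals: Iterable[CrossoverInterval],
    marker_map: MarkerMap,
) -> CrossoverTable:
    """Count crossovers per inter-marker interval and per cross.

    Each crossover increments exactly one interval.  A breakpoint spanning
    several intervals (missing calls at its flanks) increments the single
    interval containing the span midpoint.
    """
    grid = marker_map.intervals()
    counts = {c: np.zeros(len(grid), dtype=np.int64) for c in CROSSES}
    starts = grid["start"].to_numpy()
    ends = grid["end"].to_numpy()
    positions = set(int(p) for p in marker_map.positions)
    for xo in intervals:
        if xo.left_bound not in positions or xo.right_bound not in positions:
            raise ValidationError(
                f"strain {xo.strain_id}: breakpoint bound not a marker position")
        mid = (xo.left_bound + xo.right_bound) / 2.0
        hit = np.flatnonzero((starts <= mid) & (mid < ends))
        if len(hit) != 1:
            raise ValidationError(
                f"strain {xo.strain_id}: breakpoint midpoint {mid} not in any interval")
        counts[xo.cross][hit[0]] += 1
    df = grid.copy()
    df["count_faxnil"] = counts["faxnil"]
    df["count_lonnil"] = counts["lonnil"]
    df["masked"] = False
    return CrossoverTable(df, "full")


def mask_intervals(
    table: CrossoverTable,
    regions: Sequence[tuple[int, int]],
) -> CrossoverTable:
    """Flag any interval overlapping one of ``regions`` as masked.

    Regions are 1-based half-open ``(start, end)`` spans and must lie within
    the table's extent.
    """
    df = table.data.copy()
    lo = int(df["start"].min())
    hi = int(df["end"].max())
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    masked = df["masked"].to_numpy().copy()
    for r_start, r_end in regions:
        if r_end <= r_start:
            raise ValidationError(f"degenerate mask region ({r_start}, {r_end})")
        if r_end <= lo or r_start >= hi:
            raise ValidationError(
                f"mask region ({r_start}, {r_end}) outside table span ({lo}, {hi})")
        masked |= (starts < r_end) & (ends > r_start)
    df["masked"] = masked
    return CrossoverTable(df, table.resolution)


def rebin_25kb(
    table: CrossoverTable,
    target_bp: int = 25_000,
    min_events: int = 3,
) -> CrossoverTable:
    """Merge full-resolution intervals into ~``target_bp`` bins per side.

    Consecutive unmasked intervals are merged greedily until the running
    length reaches ``target_bp``; a trailing short bin is merged backward.
    Bins with fewer than ``min_events`` total crossovers are merged with
    their smaller neighbor until all pass.  Masked intervals break runs and
    are carried through unchanged.  Bin boundaries always fall on marker
    positions because bins are unions of inter-marker intervals.
    """
    if table.resolution != "full":
        raise ValidationError("rebin_25kb expects a full-resolution table")
    import warnings

    out_rows: list[dict] = []
    df = table.data
    for side in df["side"].unique():
        sub = df[df["side"] == side].sort_values("start").reset_index(drop=True)
        # split into runs of consecutive unmasked intervals
        run: list[pd.Series] = []
        runs: list[list[pd.Series]] = []
        for _, row in sub.iterrows():
            if row["masked"]:
                if run:
                    runs.append(run)
                    run = []
                out_rows.append(dict(row))
            else:
                run.append(row)
        if run:
            runs.append(run)
        for run in runs:
            total_len = sum(int(r["length"]) for r in run)
            if total_len < target_bp:
                warnings.warn(
                    f"side {side}: run length {total_len} bp below target "
                    f"{target_bp} bp; emitting a single bin", stacklevel=2)
            bins: list[list[pd.Series]] = []
            cur: list[pd.Series] = []
            cur_len = 0
            for row in run:
                cur.append(row)
                cur_len += int(row["length"])
                if cur_len >= target_bp:
                    bins.append(cur)
                    cur, cur_len = [], 0
            if cur:
                if bins:
                    bins[-1].extend(cur)  # trailing short bin merged backward
                else:
                    bins.append(cur)

            def bin_row(group: list[pd.Series]) -> dict:
                return dict(
                    start=int(group[0]["start"]), end=int(group[-1]["end"]),
                    side=side, length=int(sum(int(g["length"]) for g in group)),
                    count_faxnil=int(sum(int(g["count_faxnil"]) for g in group)),
                    count_lonnil=int(sum(int(g["count_lonnil"]) for g in group)),
                    masked=False)

            merged = [bin_row(b) for b in bins]
            # enforce the minimum-events rule by merging deficient bins with
            # the smaller adjacent bin
            def events(b: dict) -> int:
                return b["count_faxnil"] + b["count_lonnil"]

            while len(merged) > 1 and any(events(b) < min_events for b in merged):
                i = min(range(len(merged)), key=lambda j: events(merged[j]))
                if events(merged[i]) >= min_events:
                    break
                neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(merged)]
                j = min(neighbors, key=lambda j: merged[j]["length"])
                a, b = sorted((i, j))
                merged[a] = dict(
                    start=merged[a]["start"], end=merged[b]["end"], side=side,
                    length=merged[a]["length"] + merged[b]["length"],
                    count_faxnil=merged[a]["count_faxnil"] + merged[b]["count_faxnil"],
                    count_lonnil=merged[a]["count_lonnil"] + merged[b]["count_lonnil"],
                    masked=False)
                del merged[b]
            out_rows.extend(merged)
    out = pd.DataFrame(out_rows).sort_values(["start"]).reset_index(drop=True)
    return CrossoverTable(out, "25kb")
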