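"""Genomic correlates of crossover rate: per-interval feature aggregation and scans.

Feature tracks (ChIP signal, annotations) are aggregated over the unmasked
inter-marker intervals and each feature is tested in a univariate Poisson
model on top of the offset+side base — coefficient, percent deviance
explained, and an uncorrected chi-square p, with an optional control covariate
(the IgG binding control for nucleosome occupancy).  External BED/bedGraph
coordinates are 0-based half-open and converted to the internal 1-based
convention at the reader boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import glm
from .motif_scan import RegionSequence, count_repeat_features, interval_sequences
from .panel_io import CrossoverTable, ValidationError


@dataclass
class FeatureTrack:
    """Interval-valued genomic signal or annotation (internal 1-based coords)."""

    name: str
    data: pd.DataFrame  # columns start, end, value
    kind: str = "signal"  # signal | annotation

    def __post_init__(self) -> None:
        df = self.data[["start", "end", "value"]].sort_values("start").reset_index(drop=True)
        if np.any(df["end"].to_numpy() <= df["start"].to_numpy()):
            raise ValidationError(f"track {self.name}: degenerate span")
        if np.any(df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]):
            raise ValidationError(f"track {self.name}: overlapping spans")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValidationError(f"track {self.name}: non-finite values")
        self.data = df


def read_bedgraph(path, name: str | None = None,
                  kind: str = "signal") -> FeatureTrack:
    """Read a bedGraph/BED track; 0-based half-open converted to 1-based."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    out = pd.DataFrame({
        "start": df["start"].astype(np.int64) + 1,
        "end": df["end"].astype(np.int64) + 1,
        "value": pd.to_numeric(df["value"], errors="coerce").fillna(1.0),
    })
    return FeatureTrack(name or str(path), out, kind)


def gc_content(region: RegionSequence, table: CrossoverTable,
               side: str | None = None) -> np.ndarray:
    """(G+C)/(A+C+G+T) per unmasked interval; N bases excluded, all-N flagged NaN."""
    out = []
    for seq in interval_sequences(region, table, side):
        s = seq.upper()
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            warnings.warn("interval with no unambiguous bases; GC undefined",
                          stacklevel=2)
            out.append(np.nan)
        else:
            out.append((s.count("G") + s.count("C")) / acgt)
    return np.array(out)


def aggregate_track(track: FeatureTrack, table: CrossoverTable,
                    stat: str = "mean",
                    side: str | None = None) -> np.ndarray:
    """Aggregate a track over the unmasked intervals.

    ``mean``: length-weighted mean of overlapping signal (over the covered
    part; a warning reports intervals with partial coverage).  ``density``:
    overlap-prorated annotation count per interval bp (a point/row counts
    once when fully inside an interval).
    """
    df = table.unmasked(side)
    t_start = track.data["start"].to_numpy(dtype=float)
    t_end = track.data["end"].to_numpy(dtype=float)
    t_val = track.data["value"].to_numpy(dtype=float)
    out = np.empty(len(df))
    partial = 0
    for i, (a, b) in enumerate(zip(df["start"], df["end"])):
        ov = np.minimum(t_end, b) - np.maximum(t_start, a)
        ov = np.clip(ov, 0, None)
        covered = ov.sum()
        if stat == "mean":
            if covered == 0:
                out[i] = np.nan
                partial += 1
                continue
            if covered < b - a:
                partial += 1
            out[i] = float((t_val * ov).sum() / covered)
        elif stat == "density":
            frac = ov / (t_end - t_start)  # fraction of each span inside
            out[i] = float((t_val * frac).sum() / (b - a))
        else:
            raise ValidationError(f"unknown stat {stat!r}")
    if partial:
        warnings.warn(f"track {track.name}: {partial} intervals not fully covered",
                      stacklevel=2)
    return out


def repeat_density(region: RegionSequence, table: CrossoverTable,
                   feature: str, n: int,
                   side: str | None = None) -> np.ndarray:
    """Per-bp density of poly(A)>=n or (CA)>=n runs per unmasked interval."""
    seqs = interval_sequences(region, table, side)
    lengths = table.lengths(side).astype(float)
    counts = np.array([count_repeat_features(s, feature, n) for s in seqs],
                      dtype=float)
    return counts / lengths


def gene_features(genes: pd.DataFrame, table: CrossoverTable,
                  side: str | None = None) -> dict[str, np.ndarray]:
    """Gene density, intergenic and intronic proxies from a gene table.

    ``genes`` has columns gene_id, start, end, strand (1-based inclusive
    spans).  Gene density is TSS count per bp (the TSS is ``start`` on ``+``
    and ``end`` on ``-``); proportion intergenic is the bp fraction between
    nonconvergently transcribed neighbor pairs; proportion "intronic" here is
    the bp fraction covered by gene bodies (a proxy — exon structure is not
    modeled by this table).
    """
    df = table.unmasked(side)
    g = genes.sort_values("start").reset_index(drop=True)
    tss = np.where(g["strand"] == "+", g["start"], g["end"]).astype(float)
    starts = df["start"].to_numpy(dtype=float)
    ends = df["end"].to_numpy(dtype=float)
    lengths = (ends - starts)
    dens = np.array([np.sum((tss >= a) & (tss < b)) for a, b in zip(starts, ends)],
                    dtype=float) / lengths
    # intergenic spans between nonconvergent neighbor pairs: exclude pairs
    # (+ then -) which transcribe toward each other
    inter = []
    for (s1, e1, st1), (s2, e2, st2) in zip(
            g[["start", "end", "strand"]].itertuples(index=False),
            g[["start", "end", "strand"]].iloc[1:].itertuples(index=False)):
        if e1 < s2 and not (st1 == "+" and st2 == "-"):
            inter.append((e1 + 1, s2))
    body = [(int(s), int(e) + 1) for s, e in zip(g["start"], g["end"])]

    def frac_covered(spans: list[tuple[int, int]]) -> np.ndarray:
        out = np.zeros(len(df))
        if not spans:
            return out
        ss = np.array([s for s, _ in spans], dtype=float)
        ee = np.array([e for _, e in spans], dtype=float)
        for i, (a, b) in enumerate(zip(starts, ends)):
            ov = np.clip(np.minimum(ee, b) - np.maximum(ss, a), 0, None)
            out[i] = ov.sum() / (b - a)
        return out

    return {"gene_density": dens,
            "prop_intergenic": frac_covered(inter),
            "prop_genic": frac_covered(body)}


def univariate_scan(features: dict[str, np.ndarray], table: CrossoverTable,
                    side: str | None = None,
                    controls: dict[str, str] | None = None,
                    control_features: dict[str, np.ndarray] | None = None
                    ) -> pd.DataFrame:
    """Univariate Poisson scan of each feature over the offset+side base.

    ``controls`` maps a feature name to the name of a control covariate in
    ``control_features`` (e.g. nucleosome occupancy -> IgG); the feature's
    credited deviance is then its increment over base+control.  Returns a
    frame with coefficient, deviance explained (%), and uncorrected p, plus a
    Bonferroni column as an optional extra.
    """
    controls = controls or {}
    control_features = control_features or {}
    rows = []
    for name, vec in features.items():
        vec = np.asarray(vec, dtype=float)
        if np.nanstd(vec) == 0 or not np.all(np.isfinite(vec)):
            warnings.warn(f"feature {name!r} degenerate; skipped", stacklevel=2)
            rows.append(dict(feature=name, coefficient=np.nan,
                             deviance_explained=np.nan, p=np.nan,
                             degenerate=True))
            continue
        base_cov: dict[str, np.ndarray] = {}
        if name in controls:
            base_cov[controls[name]] = np.asarray(
                control_features[controls[name]], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = glm.fit_poisson(glm.spec_from_table(table, side, base_cov or None))
            fit = glm.fit_poisson(glm.spec_from_table(
                table, side, {**base_cov, name: vec}))
        drop = max(base.residual_deviance - fit.residual_deviance, 0.0)
        base_dev = base.residual_deviance
        rows.append(dict(
            feature=name, coefficient=fit.coefficients[name],
            deviance_explained=100.0 * drop / base_dev if base_dev > 0 else 0.0,
            p=float(stats.chi2.sf(drop, 1)) if drop > 0 else 1.0,
            degenerate=False))
    out = pd.DataFrame(rows)
    m = int((~out["degenerate"]).sum())
    out["p_bonferroni"] = np.minimum(out["p"] * max(m, 1), 1.0)
    return out


def correlation_cluster(features: dict[str, np.ndarray]
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix and average-linkage dendrogram leaf order."""
    names = []
    cols = []
    for name, vec in features.items():
        vec = np.asarray(vec, dtype=float)
        if np.nanstd(vec) == 0:
            warnings.warn(f"feature {name!r} has zero variance; excluded",
                          stacklevel=2)
            continue
        names.append(name)
        cols.append(vec)
    if len(names) < 2:
        raise ValidationError("need at least 2 non-degenerate features")
    mat = np.corrcoef(np.vstack(cols))
    dist = np.clip(1.0 - mat, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [names[i] for i in hierarchy.leaves_list(link)]
    return pd.DataFrame(mat, index=names, columns=names), order
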