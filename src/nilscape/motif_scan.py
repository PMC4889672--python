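"""Exhaustive double-strand k-mer association scan with a sequence-permutation null.

Every k-mer (4–8 bp; identified with its reverse complement) is counted
nonoverlapping in each inter-marker interval and its per-bp density is tested
as a covariate in the offset+side Poisson model.  Family-wise control over the
huge number of motifs uses a GC-preserving null: the nucleotides of each
interval are shuffled (exactly preserving per-interval base composition), all
motifs are recounted and refitted, and the minimum residual deviance per
motif-length class is the summary statistic.  The observed "additional
deviance explained" of a motif is its deviance explained minus the mean
best-motif deviance explained across permutations — the part not attributable
to the selection effect of scanning.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import glm
from .panel_io import CrossoverTable, ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass
class RegionSequence:
    """Genome sequence for the focal region with its physical origin.

    ``origin`` is the 1-based physical position of ``seq[0]``.
    """

    seq: str
    origin: int

    @classmethod
    def from_fasta(cls, path, origin: int) -> "RegionSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        name = list(fa.keys())[0]
        return cls(str(fa[name][:]).upper(), origin)

    def slice(self, start: int, end: int) -> str:
        """Sequence of the 1-based half-open physical span [start, end)."""
        a = start - self.origin
        b = end - self.origin
        if a < 0 or b > len(self.seq):
            raise ValidationError(
                f"span ({start}, {end}) outside sequence "
                f"({self.origin}, {self.origin + len(self.seq)})")
        return self.seq[a:b]


def interval_sequences(region: RegionSequence, table: CrossoverTable,
                       side: str | None = None) -> list[str]:
    """Per-unmasked-interval sequences, aligned with ``table.unmasked(side)``."""
    df = table.unmasked(side)
    return [region.slice(int(s), int(e))
            for s, e in zip(df["start"], df["end"])]


# ---------------------------------------------------------------------------
# Catalogs and counting
# ---------------------------------------------------------------------------


@dataclass
class MotifCatalog:
    k: int
    motifs: list[str]  # canonical: lexicographic min of motif and revcomp


def enumerate_motifs(k: int) -> MotifCatalog:
    """All canonical double-strand k-mers: (4^k + #palindromes)/2 entries."""
    if k < 1:
        raise ValidationError("motif length must be >= 1")
    motifs = []
    for tup in itertools.product("ACGT", repeat=k):
        m = "".join(tup)
        if m <= revcomp(m):
            motifs.append(m)
    return MotifCatalog(k, motifs)


def _motif_regex(motif: str) -> re.Pattern:
    rc = revcomp(motif)
    pat = motif if rc == motif else f"{motif}|{rc}"
    return re.compile(pat)


def count_nonoverlapping(sequence: str, motif: str) -> int:
    """Greedy left-to-right nonoverlapping count of a motif on either strand.

    A match of the motif or its reverse complement consumes k bases; N never
    matches.
    """
    return len(_motif_regex(motif.upper()).findall(sequence.upper()))


def count_catalog(sequences: list[str], catalog: MotifCatalog,
                  _cache: dict = {}) -> np.ndarray:
    """(n_intervals, n_motifs) nonoverlapping count matrix; regexes cached."""
    key = catalog.k
    if key not in _cache or _cache[key][0] is not catalog.motifs:
        _cache[key] = (catalog.motifs,
                       [_motif_regex(m) for m in catalog.motifs])
    patterns = _cache[key][1]
    out = np.empty((len(sequences), len(catalog.motifs)), dtype=np.int64)
    for i, seq in enumerate(sequences):
        s = seq.upper()
        for j, pat in enumerate(patterns):
            out[i, j] = len(pat.findall(s))
    return out


def count_repeat_features(sequence: str, feature: str, n: int) -> int:
    """Count maximal homopolymer or dinucleotide repeat runs on either strand.

    ``polyA_ge_n``: maximal runs of >= n consecutive A (or T, the other
    strand's A).  ``CA_ge_n``: maximal perfect (CA) or (TG) dinucleotide
    repeats with >= n units.  Each maximal run counts once.
    """
    if n < 2:
        raise ValidationError("repeat threshold must be >= 2")
    s = sequence.upper()
    if feature == "polyA_ge_n":
        return len(re.findall(rf"A{{{n},}}|T{{{n},}}", s))
    if feature == "CA_ge_n":
        return len(re.findall(rf"(?:CA){{{n},}}|(?:TG){{{n},}}", s))
    raise ValidationError(f"unknown repeat feature {feature!r}")


def count_degenerate_motif(sequence: str, pattern: str) -> int:
    """Nonoverlapping greedy count of an IUPAC/bracket pattern, either strand.

    The pattern may use IUPAC ambiguity codes (W, Y, R, ...) and/or explicit
    bracket groups like ``[AT]``; N in the *sequence* never matches.
    """
    tokens: list[str] = []  # each token: string of allowed bases
    i = 0
    pat = pattern.upper()
    while i < len(pat):
        ch = pat[i]
        if ch == "[":
            j = pat.find("]", i)
            if j < 0:
                raise ValidationError("unclosed bracket in pattern")
            group = pat[i + 1:j]
            if not group or set(group) - set("ACGT"):
                raise ValidationError(f"invalid bracket group [{group}]")
            tokens.append("".join(sorted(set(group))))
            i = j + 1
        else:
            if ch not in IUPAC:
                raise ValidationError(f"invalid IUPAC code {ch!r}")
            tokens.append(IUPAC[ch])
            i += 1

    def tok_re(tok: str) -> str:
        return tok if len(tok) == 1 else f"[{tok}]"

    fwd = "".join(tok_re(t) for t in tokens)
    rc_tokens = ["".join(sorted(b.translate(_BASE_COMP) for b in t))
                 for t in reversed(tokens)]
    rev = "".join(tok_re(t) for t in rc_tokens)
    pat_re = fwd if rev == fwd else f"{fwd}|{rev}"
    return len(re.findall(pat_re, sequence.upper()))


# ---------------------------------------------------------------------------
# Batched density fits (shared by the scan and its permutation null)
# ---------------------------------------------------------------------------


def _batch_density_fits(counts: np.ndarray, offset: np.ndarray,
                        side: np.ndarray | None, D: np.ndarray,
                        max_iter: int = 50,
                        tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit offset(+side)+density Poisson models for every column of D at once.

    Returns (coef_density, residual_deviance, degenerate_flag) per column.
    The math is identical to :func:`nilscape.glm.fit_poisson`; the IRLS
    normal equations are solved batched across motifs.
    """
    y = counts.astype(float)
    n, M = D.shape
    cols = [np.ones(n)] + ([side.astype(float)] if side is not None else [])
    p = len(cols) + 1
    X = np.empty((M, n, p))
    for j, c in enumerate(cols):
        X[:, :, j] = c
    X[:, :, -1] = D.T
    degen = D.std(axis=0) == 0
    beta = np.zeros((M, p))
    beta[:, 0] = np.log(y.sum() / np.exp(offset).sum() + 1e-300)
    dev = np.full(M, np.inf)
    active = np.ones(M, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("mnp,mp->mn", X, beta) + offset
        mu = np.exp(np.clip(eta, -700, 700))
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev_new = 2.0 * np.sum(term - (y - mu), axis=1)
        done = np.abs(dev - dev_new) <= tol * (np.abs(dev_new) + 0.1)
        dev = dev_new
        active = active & ~done
        if not active.any():
            break
        W = mu[active]
        z = (eta[active] - offset) + (y - mu[active]) / np.maximum(mu[active], 1e-300)
        Xa = X[active]
        XtW = Xa.transpose(0, 2, 1) * W[:, None, :]
        A = XtW @ Xa + 1e-9 * np.eye(p)
        b = np.einsum("mpn,mn->mp", XtW, z)
        beta[active] = np.linalg.solve(A, b[..., None])[..., 0]
    return beta[:, -1], dev, degen


# ---------------------------------------------------------------------------
# Scan and permutation null
# ---------------------------------------------------------------------------


@dataclass
class MotifTestResult:
    motif: str
    resolution: str
    effect_direction: str  # "+" | "-"
    residual_deviance: float
    deviance_explained: float           # % of base (offset+side) deviance
    nominal_p: float
    degenerate: bool = False
    expected_deviance_explained: float | None = None
    additional_deviance_explained: float | None = None
    permutation_p: float | None = None


@dataclass
class PermutationNull:
    n_perm: int
    seed: int
    # per motif-length class: (n_perm,) minima of residual deviance and the
    # per-permutation best-motif deviance explained (%)
    min_residual_deviance: dict[int, np.ndarray] = field(default_factory=dict)
    best_deviance_explained: dict[int, np.ndarray] = field(default_factory=dict)


def _scan_design(table: CrossoverTable, side: str | None):
    counts = table.counts(side)
    lengths = table.lengths(side).astype(float)
    offset = np.log(lengths)
    ind = table.side_indicator(side)
    side_col = ind if ind.min() != ind.max() else None
    base = glm.offset_side_deviance(
        counts, lengths, side_col if side_col is not None else np.zeros(len(counts)))
    return counts, lengths, offset, side_col, base


def scan_motifs(table: CrossoverTable, sequences: list[str],
                k_range: tuple[int, int] = (4, 6),
                side: str | None = None) -> list[MotifTestResult]:
    """Fit every canonical k-mer's per-bp density as a covariate.

    ``sequences`` must align with ``table.unmasked(side)``.  Nominal p is the
    1-df chi-square on the deviance drop versus the offset+side base model;
    multiple-testing control comes from :func:`permutation_null`.
    """
    counts, lengths, offset, side_col, base = _scan_design(table, side)
    if len(sequences) != len(counts):
        raise ValidationError("sequences do not align with unmasked intervals")
    results: list[MotifTestResult] = []
    for k in range(k_range[0], k_range[1] + 1):
        catalog = enumerate_motifs(k)
        occ = count_catalog(sequences, catalog)
        D = occ / lengths[:, None]
        coefs, devs, degen = _batch_density_fits(counts, offset, side_col, D)
        drop = np.maximum(base - devs, 0.0)
        for j, motif in enumerate(catalog.motifs):
            if degen[j]:
                results.append(MotifTestResult(
                    motif, table.resolution, "+", float(base), 0.0, 1.0,
                    degenerate=True))
                continue
            results.append(MotifTestResult(
                motif, table.resolution,
                "+" if coefs[j] >= 0 else "-",
                float(devs[j]),
                float(100.0 * drop[j] / base) if base > 0 else 0.0,
                float(stats.chi2.sf(drop[j], 1)) if drop[j] > 0 else 1.0))
    return results


def _shuffle_sequences(sequences: list[str],
                       rng: np.random.Generator) -> list[str]:
    out = []
    for seq in sequences:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        rng.shuffle(arr)
        out.append(arr.tobytes().decode())
    return out


def permutation_null(table: CrossoverTable, sequences: list[str],
                     k_range: tuple[int, int] = (4, 6),
                     n_perm: int = 1000, seed: int = 0,
                     side: str | None = None) -> PermutationNull:
    """GC-preserving sequence-permutation null for the exhaustive scan.

    Each permutation shuffles the nucleotides within every unmasked interval
    (base composition per interval exactly preserved), recounts all motifs
    and refits; the minimum residual deviance over motifs of each length is
    stored per permutation.
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    counts, lengths, offset, side_col, base = _scan_design(table, side)
    rng = np.random.default_rng(seed)
    null = PermutationNull(n_perm=n_perm, seed=seed)
    ks = list(range(k_range[0], k_range[1] + 1))
    catalogs = {k: enumerate_motifs(k) for k in ks}
    for k in ks:
        null.min_residual_deviance[k] = np.empty(n_perm)
        null.best_deviance_explained[k] = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = _shuffle_sequences(sequences, rng)
        for k in ks:
            occ = count_catalog(shuffled, catalogs[k])
            D = occ / lengths[:, None]
            _, devs, degen = _batch_density_fits(counts, offset, side_col, D)
            devs = np.where(degen, base, devs)
            best = float(devs.min())
            null.min_residual_deviance[k][i] = best
            null.best_deviance_explained[k][i] = (
                100.0 * max(base - best, 0.0) / base if base > 0 else 0.0)
    return null


def attach_permutation_pvalues(results: list[MotifTestResult],
                               null: PermutationNull) -> list[MotifTestResult]:
    """Fill permutation p and expected/additional deviance explained.

    ``permutation_p`` of a motif is the add-one fraction of permutations in
    which the best motif of the same length did at least as well (class
    minimum residual deviance <= the motif's observed residual deviance) —
    family-wise control per motif-length class.
    """
    for r in results:
        k = len(r.motif)
        if k not in null.min_residual_deviance:
            continue
        minima = null.min_residual_deviance[k]
        r.permutation_p = float(
            (1 + np.sum(minima <= r.residual_deviance)) / (null.n_perm + 1))
        r.expected_deviance_explained = float(
            np.mean(null.best_deviance_explained[k]))
        r.additional_deviance_explained = (
            r.deviance_explained - r.expected_deviance_explained)
    return results


def full_scan(table: CrossoverTable, sequences: list[str],
              k_range: tuple[int, int] = (4, 6), n_perm: int = 1000,
              seed: int = 0, side: str | None = None
              ) -> tuple[list[MotifTestResult], PermutationNull]:
    """Exhaustive scan plus permutation control in one call."""
    results = scan_motifs(table, sequences, k_range, side)
    null = permutation_null(table, sequences, k_range, n_perm, seed, side)
    return attach_permutation_pvalues(results, null), null


@dataclass
class MotifPairResult:
    motifs: tuple[str, str]
    residual_deviance: float
    deviance_explained: float
    nominal_p: float
    collinear: bool = False


def scan_motif_pairs(table: CrossoverTable, sequences: list[str],
                     motifs: list[str], side: str | None = None,
                     max_pairs: int = 20_000) -> list[MotifPairResult]:
    """Joint two-density fits for all pairs from a bounded motif subset.

    The full 4–8 bp pair space is far beyond desk scale; the subset size is
    checked against ``max_pairs`` before any computation.
    """
    n_pairs = len(motifs) * (len(motifs) + 1) // 2
    if n_pairs > max_pairs:
        raise ValidationError(
            f"{n_pairs} pairs exceed the configured budget of {max_pairs}")
    counts, lengths, offset, side_col, base = _scan_design(table, side)
    dens = {}
    for m in motifs:
        occ = np.array([count_nonoverlapping(s, m) for s in sequences], dtype=float)
        dens[m] = occ / lengths
    out: list[MotifPairResult] = []
    for a, b in itertools.combinations_with_replacement(motifs, 2):
        cov = {"side": side_col} if side_col is not None else {}
        if a == b:
            cov["density_a"] = dens[a]
            df_eff = 1
            collinear = True
        else:
            cov["density_a"] = dens[a]
            cov["density_b"] = dens[b]
            df_eff = 2
            collinear = False
        spec = glm.CountModelSpec(counts, offset, cov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = glm.fit_poisson(spec)
        drop = max(base - fit.residual_deviance, 0.0)
        out.append(MotifPairResult(
            (a, b), fit.residual_deviance,
            100.0 * drop / base if base > 0 else 0.0,
            float(stats.chi2.sf(drop, df_eff)) if drop > 0 else 1.0,
            collinear=collinear))
    return out
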