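import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nilscape as ns
from nilscape import glm, motif_scan as ms
from nilscape.panel_io import ValidationError
from tests.conftest import make_table

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


class TestCatalog:
    @pytest.mark.parametrize("k,expected", [(4, 136), (5, 512), (6, 2080)])
    def test_catalog_sizes(self, k, expected):
        # (4^k + #palindromes)/2; odd k has no palindromes
        assert len(ms.enumerate_motifs(k).motifs) == expected

    def test_no_reverse_complement_pairs(self):
        motifs = set(ms.enumerate_motifs(4).motifs)
        for m in motifs:
            rc = ms.revcomp(m)
            assert rc == m or rc not in motifs

    def test_canonical_is_lexicographic_min(self):
        motifs = ms.enumerate_motifs(4).motifs
        assert all(m <= ms.revcomp(m) for m in motifs)
        assert "AACA" in motifs and "TGTT" not in motifs

    def test_invalid_length_rejected(self):
        with pytest.raises(ValidationError):
            ms.enumerate_motifs(0)


class TestCounting:
    @pytest.mark.parametrize("seq,motif,expected", [
        ("AAAA", "AA", 2),          # exact tiling
        ("AACAACA", "AACA", 1),     # greedy consumption blocks the overlap
        ("TGTT", "AACA", 1),        # reverse-complement match
        ("", "AACA", 0),
        ("NNNNAACA", "AACA", 1),    # N never matches
    ])
    def test_greedy_nonoverlapping_examples(self, seq, motif, expected):
        assert ms.count_nonoverlapping(seq, motif) == expected

    @given(seq=dna)
    def test_strand_symmetry(self, seq):
        for motif in ("AACA", "GGATAG", "ACGT"):
            assert ms.count_nonoverlapping(seq, motif) == \
                ms.count_nonoverlapping(ms.revcomp(seq), motif)

    @given(seq=dna)
    def test_consumed_bases_bounded_by_length(self, seq):
        catalog = ms.enumerate_motifs(4)
        counts = ms.count_catalog([seq], catalog)[0]
        assert all(c * 4 <= max(len(seq), 0) for c in counts)

    @pytest.mark.parametrize("seq,feature,n,expected", [
        ("AAATAAAAC", "polyA_ge_n", 4, 1),   # only the 4-run qualifies
        ("TTTTT", "polyA_ge_n", 4, 1),       # reverse-strand run
        ("CACACACACA", "CA_ge_n", 5, 1),     # one maximal 5-unit repeat
        ("CACACA", "CA_ge_n", 5, 0),
        ("TGTGTGTGTGTG", "CA_ge_n", 5, 1),
    ])
    def test_repeat_features(self, seq, feature, n, expected):
        assert ms.count_repeat_features(seq, feature, n) == expected

    def test_repeat_threshold_validated(self):
        with pytest.raises(ValidationError):
            ms.count_repeat_features("AAAA", "polyA_ge_n", 1)


class TestDegenerateMotifs:
    def test_bracket_pattern_example(self):
        assert ms.count_degenerate_motif(
            "AAAAAATTATAT", "AAAA[AT]AT[TC]AT[AT]T") == 1

    def test_plain_pattern_equals_nonoverlapping(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300))
        for motif in ("AACA", "GGATAG"):
            assert ms.count_degenerate_motif(seq, motif) == \
                ms.count_nonoverlapping(seq, motif)

    def test_iupac_codes_expand(self):
        # W = A/T on either strand
        assert ms.count_degenerate_motif("CAAC", "CWGC") == 0
        assert ms.count_degenerate_motif("CAAC", "CWWC") == 1

    def test_empty_sequence_and_bad_code(self):
        assert ms.count_degenerate_motif("", "AACA") == 0
        with pytest.raises(ValidationError):
            ms.count_degenerate_motif("ACGT", "AXGT")


def planted_dataset(seed=0, n_intervals=24, length=500, beta=900.0,
                    motif="AACA", base_rate=6e-3):
    """Counts generated with log-rate proportional to a motif's density."""
    rng = np.random.default_rng(seed)
    seqs = ["".join(rng.choice(list("ACGT"), length,
                               p=[0.32, 0.18, 0.18, 0.32]))
            for _ in range(n_intervals)]
    lengths = np.full(n_intervals, length)
    dens = np.array([ms.count_nonoverlapping(s, motif) for s in seqs]) / length
    mu = lengths * base_rate * np.exp(beta * (dens - dens.mean()))
    counts = rng.poisson(mu)
    return make_table(lengths, counts), seqs


class TestScan:
    def test_planted_motif_ranks_first(self):
        table, seqs = planted_dataset(seed=5)
        results = ms.scan_motifs(table, seqs, (4, 4))
        best = min(results, key=lambda r: r.residual_deviance)
        assert best.motif == "AACA"
        assert best.effect_direction == "+"
        assert best.deviance_explained > 20

    def test_absent_motif_flagged_degenerate(self):
        table = make_table([20, 20, 20, 20, 20], [2, 3, 1, 2, 4])
        seqs = ["A" * 20] * 5  # no C/G/T: most motifs never occur
        results = ms.scan_motifs(table, seqs, (4, 4))
        gg = next(r for r in results if r.motif == "CCCC")
        assert gg.degenerate and gg.deviance_explained == 0.0

    def test_batch_fits_match_reference_irls(self):
        table, seqs = planted_dataset(seed=6)
        counts = table.counts()
        lengths = table.lengths().astype(float)
        D = np.column_stack([
            np.array([ms.count_nonoverlapping(s, m) for s in seqs]) / lengths
            for m in ("AACA", "GGAT", "ACGT")])
        coefs, devs, _ = ms._batch_density_fits(
            counts, np.log(lengths), None, D)
        for j, m in enumerate(("AACA", "GGAT", "ACGT")):
            ref = glm.fit_poisson(glm.CountModelSpec(
                counts, np.log(lengths), {"d": D[:, j]}))
            assert coefs[j] == pytest.approx(ref.coefficients["d"],
                                             rel=1e-5, abs=1e-5)
            assert devs[j] == pytest.approx(ref.residual_deviance, abs=1e-6)


class TestPermutationNull:
    def test_shuffle_preserves_base_composition(self):
        rng = np.random.default_rng(1)
        seqs = ["ACGTACGTTTGCA", "GGGCCCAAATTT"]
        shuffled = ms._shuffle_sequences(seqs, rng)
        for a, b in zip(seqs, shuffled):
            assert sorted(a) == sorted(b) and a != b or len(a) < 4

    def test_planted_effect_survives_family_wise_control(self):
        table, seqs = planted_dataset(seed=7)
        results, null = ms.full_scan(table, seqs, (4, 4), n_perm=99, seed=8)
        best = min(results, key=lambda r: r.residual_deviance)
        assert best.motif == "AACA"
        assert best.permutation_p < 0.05
        assert best.additional_deviance_explained == pytest.approx(
            best.deviance_explained - best.expected_deviance_explained)

    def test_expected_deviance_explained_positive_under_null(self):
        # the best of thousands of motifs always explains something
        rng = np.random.default_rng(2)
        lengths = np.full(16, 300)
        counts = rng.poisson(lengths * 5e-3)
        table = make_table(lengths, counts)
        seqs = ["".join(rng.choice(list("ACGT"), 300)) for _ in range(16)]
        null = ms.permutation_null(table, seqs, (4, 4), n_perm=99, seed=3)
        assert null.best_deviance_explained[4].mean() > 0.0

    def test_permutation_p_in_unit_interval_and_addone(self):
        table, seqs = planted_dataset(seed=9, beta=0.0)
        results, null = ms.full_scan(table, seqs, (4, 4), n_perm=99, seed=10)
        ps = [r.permutation_p for r in results if not r.degenerate]
        assert all(1 / 100 <= p <= 1.0 for p in ps)

    def test_n_perm_floor_enforced(self):
        table, seqs = planted_dataset(seed=11)
        with pytest.raises(ValidationError):
            ms.permutation_null(table, seqs, (4, 4), n_perm=10, seed=0)


class TestMotifPairs:
    def test_self_pair_flagged_and_equals_single(self):
        table, seqs = planted_dataset(seed=12)
        single = ms.scan_motifs(table, seqs, (4, 4))
        aaca = next(r for r in single if r.motif == "AACA")
        pairs = ms.scan_motif_pairs(table, seqs, ["AACA"])
        assert pairs[0].collinear
        assert pairs[0].residual_deviance == pytest.approx(
            aaca.residual_deviance, abs=1e-5)

    def test_joint_fit_nests_marginals(self):
        table, seqs = planted_dataset(seed=13)
        pairs = ms.scan_motif_pairs(table, seqs, ["AACA", "GGAT"])
        joint = next(p for p in pairs if p.motifs == ("AACA", "GGAT"))
        singles = [p for p in pairs if p.collinear]
        assert all(joint.deviance_explained >= s.deviance_explained - 1e-6
                   for s in singles)

    def test_pair_budget_enforced_before_computing(self):
        table, seqs = planted_dataset(seed=14)
        with pytest.raises(ValidationError, match="budget"):
            ms.scan_motif_pairs(table, seqs, ["AACA"] * 100, max_pairs=10)
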