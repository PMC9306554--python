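"""NG86 Ka/Ks counting, sliding windows and duplicate classification.

The hand-counted fixture: thirty codons alternating GGT/GCA. Every codon
in both sequences is fourfold degenerate at position 3 only, so each
contributes exactly 1 synonymous site (S = 30, N = 60). The second
sequence carries two third-position synonymous changes (GGT->GGC,
GGT->GGA), hence Sd = 2, Nd = 0, ps = 1/15 and
Ks = -(3/4) ln(1 - 4/45) = 0.0698196..., Ka = 0.
"""

import numpy as np
import pandas as pd
import pytest

from famevol import selection
from famevol.selection import (
    DuplicationCriteria,
    _pathway_counts,
    classify_duplicates,
    ng86_kaks,
    sliding_window_kaks,
)
from famevol.simulate import _random_cds, evolve_cds

SEQ1 = "GGTGCA" * 15  # 30 codons
SEQ2 = "GGC" + "GCA" + "GGA" + SEQ1[9:]  # two synonymous 3rd-position changes


class TestNG86HandCounting:
    def test_hand_counted_fixture(self):
        r = ng86_kaks(SEQ1, SEQ2)
        assert r.S == pytest.approx(30.0)
        assert r.N == pytest.approx(60.0)
        assert r.Sd == pytest.approx(2.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.ka == pytest.approx(0.0, abs=1e-12)
        assert r.ks == pytest.approx(-0.75 * np.log(1 - 4.0 / 45.0), abs=1e-12)
        assert r.ratio == pytest.approx(0.0, abs=1e-12)

    def test_identical_pair_ratio_undefined(self):
        r = ng86_kaks(SEQ1, SEQ1)
        assert r.ka == 0.0 and r.ks == 0.0
        assert r.ratio is None
        assert any("ratio undefined" in n for n in r.notes)

    def test_two_position_pathway_average(self):
        # TTT -> GTA: path via GTT gives 1 syn + 1 nonsyn, via TTA 2 nonsyn
        assert _pathway_counts("TTT", "GTA") == (0.5, 1.5)

    def test_stop_pathway_excluded(self):
        # TCA -> TGT: the route via TGA (stop) is discarded, leaving the
        # TCT route with one synonymous and one nonsynonymous step
        assert _pathway_counts("TCA", "TGT") == (1.0, 1.0)

    def test_site_conservation_and_symmetry(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = _random_cds(40, rng)
            b = evolve_cds(a, 0.8, 0.4, rng)
            fwd, rev = ng86_kaks(a, b), ng86_kaks(b, a)
            assert fwd.S + fwd.N == pytest.approx(3 * fwd.codons)
            assert fwd.Sd == pytest.approx(rev.Sd)
            assert fwd.Nd == pytest.approx(rev.Nd)
            assert fwd.ka == pytest.approx(rev.ka)
            assert fwd.ks == pytest.approx(rev.ks)

    def test_gap_codons_excluded_pairwise(self):
        r = ng86_kaks(SEQ1[:6] + "---", SEQ1[:9])
        assert r.codons == 2
        assert r.S + r.N == pytest.approx(6.0)

    def test_saturation_flagged_not_dropped(self):
        # Trp-only vs Gln-only: almost no synonymous sites, so the
        # pathway-averaged ps blows past 3/4 and Ks must be flagged
        a = "ATG" + "TGG" * 29
        b = "ATG" + "CAA" * 29
        r = ng86_kaks(a, b)
        assert r.ks is None and r.ratio is None
        assert any("Jukes-Cantor undefined" in n for n in r.notes)

    def test_agrees_with_independent_counting_implementation(self):
        import warnings

        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(31)
        for _ in range(5):
            a = _random_cds(100, rng)
            b = evolve_cds(a, 0.5, 0.3, rng)
            mine = ng86_kaks(a, b)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            # stop-pathway handling differs slightly between implementations
            assert mine.ka == pytest.approx(dn, abs=0.01)
            assert mine.ks == pytest.approx(ds, abs=0.01)


class TestSlidingWindow:
    def test_window_count_closed_form(self):
        a = _random_cds(100, np.random.default_rng(0))
        track = sliding_window_kaks(a, a, window_bp=150, step_bp=9)
        assert len(track.ratios) == (300 - 150) // 9 + 1 == 17

    def test_identical_sequences_all_undefined(self):
        a = _random_cds(60, np.random.default_rng(1))
        track = sliding_window_kaks(a, a)
        assert all(r is None for r in track.ratios)
        assert all(res.ka == 0 and res.ks == 0 for res in track.results)

    def test_non_codon_window_rejected(self):
        a = _random_cds(100, np.random.default_rng(2))
        with pytest.raises(ValueError):
            sliding_window_kaks(a, a, window_bp=100, step_bp=9)
        with pytest.raises(ValueError):
            sliding_window_kaks(a, a, window_bp=150, step_bp=10)

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_kaks("ATG" * 10, "ATG" * 10, window_bp=150)

    def test_detects_regime_shift_along_gene(self):
        """Purifying first half (w=0.2) vs relaxed second half (w=1.5):
        the windowed mean must rank the halves correctly in >=95% of
        seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(5000 + seed)
            left = _random_cds(300, rng)
            right = _random_cds(300, rng)
            a = left + right
            b = evolve_cds(left, 0.2, 0.3, rng) + evolve_cds(right, 1.5, 0.3, rng)
            track = sliding_window_kaks(a, b)
            half = len(track.ratios) // 2
            first = [r for r in track.ratios[:half] if r is not None]
            second = [r for r in track.ratios[half:] if r is not None]
            hits += np.mean(second) > np.mean(first)
        assert hits >= 0.95 * n_seeds


def toy_models(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def toy_identity(vals):
    ids = sorted({g for pair in vals for g in pair})
    m = pd.DataFrame(100.0, index=ids, columns=ids)
    for (a, b), v in vals.items():
        m.loc[a, b] = m.loc[b, a] = v
    return m


class TestClassifyDuplicates:
    def test_high_identity_different_chromosomes_is_segmental(self):
        gm = toy_models([("a", "chr1", 1000, 2000), ("b", "chr2", 1000, 2000)])
        pairs = classify_duplicates(gm, toy_identity({("a", "b"): 85.0}))
        assert [p.mode for p in pairs] == ["segmental"]

    def test_identity_below_threshold_not_reported(self):
        gm = toy_models([("a", "chr1", 1000, 2000), ("b", "chr1", 5000, 6000)])
        assert classify_duplicates(gm, toy_identity({("a", "b"): 75.0})) == []

    def test_same_chromosome_within_200kb_is_tandem(self):
        gm = toy_models([("a", "chr1", 1000, 2000), ("b", "chr1", 51000, 52000)])
        pairs = classify_duplicates(gm, toy_identity({("a", "b"): 90.0}))
        assert [p.mode for p in pairs] == ["tandem"]

    def test_same_chromosome_beyond_threshold_is_segmental(self):
        gm = toy_models([("a", "chr1", 1000, 2000), ("b", "chr1", 900000, 901000)])
        pairs = classify_duplicates(gm, toy_identity({("a", "b"): 90.0}))
        assert [p.mode for p in pairs] == ["segmental"]

    def test_inverted_rule_is_available(self):
        gm = toy_models([("a", "chr1", 1000, 2000), ("b", "chr1", 900000, 901000)])
        crit = DuplicationCriteria(tandem_is_proximal=False)
        pairs = classify_duplicates(gm, toy_identity({("a", "b"): 90.0}), crit)
        assert [p.mode for p in pairs] == ["tandem"]

    def test_simulated_modes_recovered_exactly(self, family):
        from famevol import align

        records, gene_models, truth = family
        proteins = {g: r.protein for g, r in records.items()}
        idm = align.identity_matrix(proteins)
        pairs = classify_duplicates(gene_models, idm)
        called = {frozenset((p.gene_a, p.gene_b)): p.mode for p in pairs}
        for (a, b), mode in truth.pair_modes.items():
            assert called[frozenset((a, b))] == mode

    def test_undefined_ratio_written_as_empty_field(self):
        pair = selection.DuplicatePair(
            "a", "b", 95.0, "tandem", ng86_kaks(SEQ1, SEQ1), None
        )
        table = selection.pairs_table([pair])
        assert table.loc[0, "ka_ks"] is None or pd.isna(table.loc[0, "ka_ks"])
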