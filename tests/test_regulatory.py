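"""Promoter extraction, IUPAC motif scanning and 2^-ddCt expression."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from famevol import regulatory as reg
from famevol.regulatory import (
    MotifDefinition,
    ddct_expression,
    extract_promoter,
    scan_motifs,
)


def naive_double_strand_counts(seq, motif):
    """Position-by-position oracle: expand IUPAC, check both strands."""
    def matches(s, pos, consensus):
        if pos + len(consensus) > len(s):
            return False
        return all(
            s[pos + k] in reg.IUPAC[sym] for k, sym in enumerate(consensus.upper())
        )

    rc = str(Seq(motif.consensus.upper()).reverse_complement())
    count = 0
    for pos in range(len(seq)):
        plus = matches(seq, pos, motif.consensus)
        minus = matches(seq, pos, rc)
        if reg.is_palindromic(motif.consensus):
            count += plus
        else:
            count += plus + minus
    return count


class TestScanMotifs:
    def test_single_plus_strand_hit(self):
        m = MotifDefinition("ABRE", "ACGTG", "hormone")
        res = scan_motifs({"p": "AAACGTGAA"}, (m,))
        assert res.counts.loc["p", "ABRE"] == 1
        assert list(res.hits["strand"]) == ["+"]

    def test_reverse_complement_pair_found_on_both_strands(self):
        motifs = (
            MotifDefinition("CGTCA-motif", "CGTCA", "hormone"),
            MotifDefinition("TGACG-motif", "TGACG", "hormone"),
        )
        res = scan_motifs({"p": "TGACGTCA"}, motifs)
        for m in motifs:
            assert res.counts.loc["p", m.name] == naive_double_strand_counts(
                "TGACGTCA", m
            ) == 2

    def test_overlapping_occurrences_all_counted(self):
        m = MotifDefinition("x", "AA", "stress")
        assert scan_motifs({"p": "AAAA"}, (m,)).counts.loc["p", "x"] == 3

    def test_palindrome_counted_once_per_position(self):
        m = MotifDefinition("pal", "ACGT", "light")
        res = scan_motifs({"p": "TACGTT"}, (m,))
        assert res.counts.loc["p", "pal"] == 1

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            MotifDefinition("bad", "ACQTG", "light")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=10, max_size=60),
        consensus=st.text(alphabet="ACGTRYSWKMN", min_size=3, max_size=6),
    )
    def test_matches_naive_oracle_on_random_sequences(self, seq, consensus):
        m = MotifDefinition("m", consensus, "light")
        got = scan_motifs({"p": seq}, (m,)).counts.loc["p", "m"]
        assert got == naive_double_strand_counts(seq, m)

    def test_counts_equal_recorded_positions(self):
        res = scan_motifs({"p": "TGACGTCATGACG"})
        totals = res.hits.groupby("motif").size()
        for motif in res.counts.columns:
            assert res.counts.loc["p", motif] == totals.get(motif, 0)


class TestExtractPromoter:
    def setup_method(self):
        rng = np.random.default_rng(12)
        self.genome = {
            "chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, 12000))
        }

    def test_plus_strand_interval(self):
        gene = {"chrom": "chr1", "strand": "+", "cds_start": 10001}
        prom = extract_promoter(gene, self.genome, length_bp=2000)
        # 1-based genomic interval [8001, 10000]
        assert prom == self.genome["chr1"][8000:10000]

    def test_minus_strand_reverse_complement(self):
        gene = {"chrom": "chr1", "strand": "-", "cds_end": 5000}
        prom = extract_promoter(gene, self.genome, length_bp=1500)
        expected = str(Seq(self.genome["chr1"][5000:6500]).reverse_complement())
        assert prom == expected

    def test_clipped_at_chromosome_start_with_warning(self):
        gene = {"chrom": "chr1", "strand": "+", "cds_start": 501}
        with pytest.warns(UserWarning, match="clipped"):
            prom = extract_promoter(gene, self.genome, length_bp=2000)
        assert len(prom) == 500

    def test_roundtrip_against_assembled_genome(self, family):
        from famevol.simulate import assemble_genome

        records, gm, _ = family
        chrom_lengths = dict(
            gm[["chrom", "chrom_length"]].drop_duplicates().itertuples(index=False)
        )
        genome = assemble_genome(records, chrom_lengths, seed=4)
        for r in records.values():
            gene = {
                "chrom": r.chrom,
                "strand": r.strand,
                "cds_start": r.start,
                "cds_end": r.end,
            }
            got = extract_promoter(gene, genome, length_bp=len(r.promoter))
            assert got == r.promoter


class TestDdct:
    def make_ct(self, rows):
        return pd.DataFrame(rows, columns=["gene", "sample", "replicate", "Ct"])

    def test_closed_form_fold_of_four(self):
        ct = self.make_ct(
            [
                ("t", "s", 1, 20.0), ("ref", "s", 1, 18.0),
                ("t", "cal", 1, 22.0), ("ref", "cal", 1, 18.0),
            ]
        )
        rel = ddct_expression(ct, "ref", "cal").set_index("sample")
        assert rel.loc["s", "fold_change"] == pytest.approx(4.0)

    def test_calibrator_sample_fold_is_one(self):
        ct = self.make_ct(
            [("t", "cal", r, 24.0) for r in (1, 2, 3)]
            + [("ref", "cal", r, 18.0) for r in (1, 2, 3)]
        )
        rel = ddct_expression(ct, "ref", "cal")
        assert rel["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_per_replicate_machine_offset(self):
        rng = np.random.default_rng(6)
        rows = []
        for r in (1, 2, 3):
            for g in ("t1", "t2", "ref"):
                for s in ("cal", "s1"):
                    rows.append((g, s, r, float(rng.uniform(18, 28))))
        ct = self.make_ct(rows)
        shifted = ct.copy()
        shifted.loc[shifted["replicate"] == 2, "Ct"] += 1.7
        base = ddct_expression(ct, "ref", "cal")
        off = ddct_expression(shifted, "ref", "cal")
        pd.testing.assert_frame_equal(base, off)

    def test_missing_reference_rejected(self):
        ct = self.make_ct([("t", "s", 1, 20.0), ("t", "cal", 1, 21.0)])
        with pytest.raises(ValueError):
            ddct_expression(ct, "ref", "cal")
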