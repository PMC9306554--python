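"""Ground-truth simulator: placement rules, codon evolution, promoter
planting and qPCR generation."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from famevol.regulatory import DEFAULT_MOTIFS, scan_motifs
from famevol.simulate import (
    DuplicationEvent,
    FamilySimConfig,
    STOPS,
    _random_cds,
    evolve_cds,
    plant_promoters,
    simulate_family,
    simulate_qpcr,
    write_family,
)


def no_internal_stops(cds):
    return all(cds[i : i + 3] not in STOPS for i in range(0, len(cds), 3))


class TestConfigValidation:
    def test_short_cds_rejected(self):
        with pytest.raises(ValueError):
            FamilySimConfig(cds_length_codons=10)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            FamilySimConfig(omega_map={"sp1": -0.1})

    def test_promoter_length_outside_window_rejected(self):
        with pytest.raises(ValueError):
            FamilySimConfig(promoter_length_bp=900)

    def test_unknown_duplication_parent_rejected(self):
        cfg = FamilySimConfig(
            n_species=1,
            n_ancestral_genes=1,
            duplication_events=(DuplicationEvent("sp1", "tandem", "g99"),),
            cds_length_codons=40,
        )
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_family(cfg)


class TestPlacement:
    def test_tandem_pair_shares_chromosome_within_threshold(self):
        cfg = FamilySimConfig(
            n_species=2,
            n_ancestral_genes=1,
            duplication_events=(DuplicationEvent("sp1", "tandem", "g1"),),
            cds_length_codons=40,
            seed=7,
        )
        records, _, truth = simulate_family(cfg)
        assert len(records) == 3
        ((parent, dup),) = truth.pair_modes
        a, b = records[parent], records[dup]
        assert a.chrom == b.chrom
        sep = abs((a.start + a.end) / 2 - (b.start + b.end) / 2)
        assert sep <= cfg.tandem_max_kb * 1000

    def test_segmental_pair_on_different_chromosomes(self):
        cfg = FamilySimConfig(
            n_species=1,
            n_ancestral_genes=1,
            duplication_events=(DuplicationEvent("sp1", "segmental", "g1"),),
            cds_length_codons=40,
            seed=3,
        )
        records, _, truth = simulate_family(cfg)
        ((parent, dup),) = truth.pair_modes
        assert records[parent].chrom != records[dup].chrom

    def test_gene_models_within_chromosome_bounds(self, family):
        _, gm, _ = family
        assert (gm["start"] >= 1).all()
        assert (gm["end"] <= gm["chrom_length"]).all()
        assert (gm["end"] > gm["start"]).all()

    def test_exons_tile_the_cds(self, family):
        records, _, _ = family
        for r in records.values():
            assert sum(b - a + 1 for a, b in r.exons) == len(r.cds)
            assert r.exons[0][0] == r.start and r.exons[-1][1] == r.end


class TestDeterminism:
    def test_identical_seed_gives_identical_files(self, tmp_path, family):
        cfg = FamilySimConfig(
            n_species=2,
            n_ancestral_genes=3,
            duplication_events=(
                DuplicationEvent("sp1", "tandem", "g1"),
                DuplicationEvent("sp2", "segmental", "g2"),
            ),
            cds_length_codons=60,
            seed=7,
        )
        paths = []
        for run in ("a", "b"):
            rec, gm, truth = simulate_family(cfg)
            paths.append(write_family(tmp_path / run, rec, gm, truth))
        for key in paths[0]:
            assert paths[0][key].read_bytes() == paths[1][key].read_bytes()


class TestEvolveCds:
    def test_zero_rate_returns_input(self):
        cds = _random_cds(50, np.random.default_rng(1))
        assert evolve_cds(cds, 1.0, 0.0, 2) == cds

    def test_omega_zero_fixes_only_synonymous_changes(self):
        rng = np.random.default_rng(4)
        cds = _random_cds(100, rng)
        out = evolve_cds(cds, 0.0, 0.5, rng)
        assert out != cds
        assert str(Seq(cds).translate()) == str(Seq(out).translate())

    def test_no_internal_stops_and_length_preserved(self):
        rng = np.random.default_rng(9)
        cds = _random_cds(80, rng)
        out = evolve_cds(cds, 2.0, 1.0, rng)
        assert len(out) == len(cds)
        assert no_internal_stops(out)

    def test_negative_omega_rejected(self):
        with pytest.raises(ValueError):
            evolve_cds("ATGGCT", -0.5, 0.1, 0)

    def test_internal_stop_input_rejected(self):
        with pytest.raises(ValueError):
            evolve_cds("ATGTAAGCT", 1.0, 0.1, 0)


class TestPlantPromoters:
    MOTIFS = tuple(m for m in DEFAULT_MOTIFS if m.name in {"ABRE", "MBS"})

    def test_scan_finds_exactly_the_planted_counts(self):
        proms, truth = plant_promoters(
            ["p1", "p2", "p3"], self.MOTIFS, {"ABRE": 2.0, "MBS": 1.0}, seed=5
        )
        scanned = scan_motifs(proms, self.MOTIFS).counts
        assert (scanned.loc[truth.index, truth.columns] == truth).all().all()

    def test_zero_rate_means_zero_hits(self):
        proms, truth = plant_promoters(["p1", "p2"], self.MOTIFS, {}, seed=1)
        scanned = scan_motifs(proms, self.MOTIFS).counts
        assert (scanned == 0).all().all()
        assert (truth == 0).all().all()

    def test_poisson_planting_mean_within_three_se(self):
        lam, n = 3.0, 200
        motifs = tuple(m for m in DEFAULT_MOTIFS if m.name == "ABRE")
        _, truth = plant_promoters(
            [f"p{i}" for i in range(n)],
            motifs,
            {"ABRE": lam},
            promoter_length_bp=1500,
            seed=13,
        )
        se = np.sqrt(lam / n)
        assert abs(truth["ABRE"].mean() - lam) <= 3 * se


class TestSimulateQpcr:
    def expr(self, folds):
        rows = [{"gene": "gA", "sample": s, "fold": f} for s, f in folds.items()]
        return pd.DataFrame(rows)

    def test_noise_free_fold_recovered_exactly(self):
        from famevol.regulatory import ddct_expression

        ct = simulate_qpcr(
            self.expr({"calibrator": 1.0, "s1": 4.0}), ct_noise_sd=0.0, seed=1
        )
        rel = ddct_expression(ct, "TUB1", "calibrator").set_index("sample")
        assert rel.loc["s1", "fold_change"] == pytest.approx(4.0)
        assert rel.loc["calibrator", "fold_change"] == pytest.approx(1.0)

    def test_reference_gene_constant_in_expectation(self):
        ct = simulate_qpcr(
            self.expr({"calibrator": 1.0, "s1": 8.0}), ct_noise_sd=0.0, seed=2
        )
        ref = ct[ct["gene"] == "TUB1"]
        assert ref["Ct"].nunique() == 1

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr(self.expr({"calibrator": 1.0, "s1": 0.0}))

    def test_noisy_recovery_unbiased_over_replicate_simulations(self):
        from famevol.regulatory import ddct_expression

        truth_fold = 2.0
        recovered = []
        for seed in range(100):
            ct = simulate_qpcr(
                self.expr({"calibrator": 1.0, "s1": truth_fold}),
                ct_noise_sd=0.2,
                seed=seed,
            )
            rel = ddct_expression(ct, "TUB1", "calibrator").set_index("sample")
            recovered.append(rel.loc["s1", "fold_change"])
        mean = np.mean(recovered)
        se = np.std(recovered, ddof=1) / np.sqrt(len(recovered))
        assert abs(mean - truth_fold) <= 3 * se


def test_truth_alignment_columns_equal_for_all_members(family):
    _, _, truth = family
    for fam in truth.alignments.values():
        assert len({len(p) for p in fam.values()}) == 1
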