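import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panmethyl import io as pio
from panmethyl.array_processing import build_profile
from panmethyl.kopl_design import AA20, MethylState, enumerate_library
from panmethyl.methylome_catalog import annotate_novelty, sites_from_frame
from panmethyl.selectivity_metrics import rank_proteome
from panmethyl.synthetic_data import (
    SimConfig,
    StrategySpec,
    TruthAntibody,
    gen_proteome,
    sim_kopl_array,
    sim_methylome,
    sim_psm_table,
    tryptic_peptides,
    write_fasta,
)
from tests.test_selectivity_metrics import make_pssm


class TestSimConfig:
    def test_composition_normalized(self):
        cfg = SimConfig(aa_composition={"A": 2.0, "K": 2.0})
        assert cfg.aa_composition["A"] == pytest.approx(0.5)
        assert abs(sum(cfg.aa_composition.values()) - 1.0) < 1e-9

    def test_rejects_bad_rate(self):
        with pytest.raises(ValueError):
            SimConfig(capture_rate=1.5)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "seed: 9\nn_proteins: 5\nnoise_cv: 0.1\n"
            "crosstalk_planting:\n  acetyl: [[0, 1, 2], 0.5]\n"
        )
        cfg = SimConfig.from_yaml(path)
        assert cfg.seed == 9 and cfg.n_proteins == 5
        assert cfg.crosstalk_planting["acetyl"] == ((0, 1, 2), 0.5)


class TestGenProteome:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=42, n_proteins=10)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(gen_proteome(cfg), p1)
        write_fasta(gen_proteome(SimConfig(seed=42, n_proteins=10)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        a = gen_proteome(SimConfig(seed=1, n_proteins=5))
        b = gen_proteome(SimConfig(seed=2, n_proteins=5))
        assert a != b

    def test_accession_format(self):
        proteome = gen_proteome(SimConfig(seed=0, n_proteins=3))
        assert list(proteome) == ["SYN0001", "SYN0002", "SYN0003"]

    def test_zero_lysine_composition_empty_ranked_list(self):
        comp = {a: 1.0 for a in AA20 if a != "K"}
        cfg = SimConfig(seed=0, n_proteins=5, aa_composition=comp)
        proteome = gen_proteome(cfg)
        assert all("K" not in seq for seq in proteome.values())
        ranked = rank_proteome(make_pssm(1.0), proteome)
        assert len(ranked) == 0

    def test_composition_within_3_sigma(self):
        cfg = SimConfig(seed=8, n_proteins=1000, mean_length=100)
        proteome = gen_proteome(cfg)
        joined = "".join(proteome.values())
        n = len(joined)
        for aa in ("A", "K", "L", "W"):
            p = cfg.aa_composition[aa]
            observed = joined.count(aa) / n
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < 3 * sigma

    def test_fasta_round_trips_through_reader(self, tmp_path):
        proteome = gen_proteome(SimConfig(seed=3, n_proteins=4))
        path = tmp_path / "p.fasta"
        write_fasta(proteome, path)
        assert pio.read_fasta(path) == proteome


class TestSimKoplArray:
    def test_zero_noise_exactly_proportional(self, me2_library):
        cfg = SimConfig(seed=0, noise_cv=0.0, n_replicates=2)
        truth = TruthAntibody.biased("ab", MethylState.me2,
                                     favored={(-1, "F"): 1.0}, base_weight=0.2)
        scan = sim_kopl_array(truth, me2_library, cfg)
        means = scan.records.groupby("feature_id")["raw_signal"].mean()
        for s in me2_library.sets:
            expected = truth.global_intensity * truth.preference[(s.fixed_offset, s.fixed_aa)]
            assert means[s.set_id] == pytest.approx(expected)

    def test_zero_cross_reactivity_zero_signal(self):
        me1_library = enumerate_library(MethylState.me1)
        cfg = SimConfig(seed=0, noise_cv=0.0)
        truth = TruthAntibody.uniform("ab", MethylState.me2,
                                      cross_reactivity={MethylState.me1: 0.0})
        scan = sim_kopl_array(truth, me1_library, cfg)
        assert (scan.records["raw_signal"] == 0).all()

    def test_profile_recovery_pearson(self, me2_library):
        cfg = SimConfig(seed=19, noise_cv=0.2, n_replicates=3)
        rng = np.random.default_rng(7)
        pref = {(s.fixed_offset, s.fixed_aa): float(rng.uniform(0.05, 1.0))
                for s in me2_library.sets}
        truth = TruthAntibody("ab", MethylState.me2, preference=pref)
        scan = sim_kopl_array(truth, me2_library, cfg)
        profile = build_profile(scan, me2_library)
        t = [pref[(s.fixed_offset, s.fixed_aa)] for s in me2_library.sets]
        o = [profile.value(s.fixed_offset, s.fixed_aa) for s in me2_library.sets]
        r, _ = stats.pearsonr(t, o)
        assert r >= 0.9

    def test_deterministic(self, me2_library):
        cfg = SimConfig(seed=5, noise_cv=0.3)
        truth = TruthAntibody.uniform("ab", MethylState.me2)
        s1 = sim_kopl_array(truth, me2_library, cfg)
        s2 = sim_kopl_array(truth, me2_library, cfg)
        pd.testing.assert_frame_equal(s1.records, s2.records)

    def test_truth_validation(self):
        with pytest.raises(ValueError):
            TruthAntibody("ab", MethylState.me2, preference={(-1, "F"): 0.0})
        with pytest.raises(ValueError):
            TruthAntibody("ab", MethylState.me2, preference={(-1, "F"): 1.0},
                          cross_reactivity={MethylState.me2: 0.5})


class TestSimMethylome:
    def test_zero_rates_empty_catalog(self, small_proteome):
        cfg = SimConfig(seed=0, site_rates={"me1": 0.0, "me2": 0.0, "me3": 0.0})
        out = sim_methylome(small_proteome, cfg)
        assert len(out.sites) == 0

    def test_sites_land_on_lysines(self, small_proteome):
        cfg = SimConfig(seed=2, site_rates={"me2": 0.1})
        out = sim_methylome(small_proteome, cfg)
        for acc, pos, _ in out.site_tuples():
            assert small_proteome[acc][pos - 1] == "K"

    def test_reference_fraction_one_zero_novel(self, small_proteome):
        cfg = SimConfig(seed=4, site_rates={"me2": 0.1}, reference_fraction=1.0)
        out = sim_methylome(small_proteome, cfg)
        sites = sites_from_frame(out.sites.assign(strategies="s"))
        assert annotate_novelty(sites, out.reference).percent_novel == 0.0

    def test_planted_novelty_within_3_sigma(self):
        cfg = SimConfig(seed=21, n_proteins=150, mean_length=400,
                        site_rates={"me2": 0.2}, reference_fraction=0.4)
        proteome = gen_proteome(cfg)
        out = sim_methylome(proteome, cfg)
        n = len(out.sites)
        assert n >= 500
        sites = sites_from_frame(out.sites.assign(strategies="s"))
        novelty = annotate_novelty(sites, out.reference).percent_novel
        sigma = 100.0 * np.sqrt(0.6 * 0.4 / n)
        assert abs(novelty - 60.0) < 3 * sigma

    def test_crosstalk_planting_produces_nearby_ptms(self, small_proteome):
        cfg = SimConfig(seed=6, site_rates={"me2": 0.15},
                        reference_fraction=0.0,
                        crosstalk_planting={"acetyl": ((0,), 1.0),
                                            "phospho-S": ((2, 3), 1.0)})
        out = sim_methylome(small_proteome, cfg)
        ref = out.reference.records
        acetyl = ref[ref["ptm_type"] == "acetyl"]
        planted = set(zip(out.sites["accession"], out.sites["position"]))
        assert set(zip(acetyl["accession"], acetyl["position"])) <= planted

    def test_motif_bias_plants_structure(self, small_proteome):
        pssm = make_pssm(0.0, cells={(1, "D"): 3.0})
        cfg = SimConfig(seed=9, site_rates={"me2": 0.15})
        biased = sim_methylome(small_proteome, cfg, motif_bias=pssm)
        plain = sim_methylome(small_proteome, cfg)

        def frac_d(sites_df):
            hits = 0
            for acc, pos in zip(sites_df["accession"], sites_df["position"]):
                seq = small_proteome[acc]
                if pos < len(seq) and seq[pos] == "D":
                    hits += 1
            return hits / len(sites_df)

        assert frac_d(biased.sites) > frac_d(plain.sites)

    def test_deterministic(self, small_proteome):
        cfg = SimConfig(seed=13, site_rates={"me1": 0.05})
        a = sim_methylome(small_proteome, cfg)
        b = sim_methylome(small_proteome, cfg)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        pd.testing.assert_frame_equal(a.reference.records, b.reference.records)


class TestTrypticPeptides:
    def test_cleaves_after_k_and_r(self):
        assert tryptic_peptides("AAKGGRCC") == [(1, "AAK"), (4, "GGR"), (7, "CC")]

    def test_methylated_k_blocks_cleavage(self):
        assert tryptic_peptides("AAKGGR", blocked_positions=frozenset({3})) == \
            [(1, "AAKGGR")]

    def test_coverage_is_partition(self, small_proteome):
        for seq in list(small_proteome.values())[:5]:
            peptides = tryptic_peptides(seq)
            assert "".join(p for _, p in peptides) == seq


class TestSimPsmTable:
    def test_full_capture_round_trip(self, small_proteome):
        from panmethyl.methylome_catalog import call_sites, filter_peptides
        cfg = SimConfig(seed=17, site_rates={"me2": 0.08}, capture_rate=1.0,
                        unenriched_rate=0.0, localization_jitter=0.0)
        methylome = sim_methylome(small_proteome, cfg)
        records = sim_psm_table(methylome, small_proteome, cfg)
        result = call_sites(filter_peptides(records), small_proteome)
        assert {s.key for s in result.sites} == set(methylome.site_tuples())

    def test_mod_indices_point_at_lysine(self, small_proteome):
        cfg = SimConfig(seed=23, site_rates={"me1": 0.05, "me3": 0.05})
        methylome = sim_methylome(small_proteome, cfg)
        for rec in sim_psm_table(methylome, small_proteome, cfg):
            for mod in rec.methyl_mods():
                assert rec.sequence[mod.residue_index - 1] == "K"

    def test_bias_zero_null_case(self, small_proteome):
        cfg = SimConfig(seed=29, site_rates={"me2": 0.2})
        methylome = sim_methylome(small_proteome, cfg)
        pssm = make_pssm(0.0, cells={(1, "D"): 1.0})
        strategies = [StrategySpec("s1", capture_rate=0.5),
                      StrategySpec("s2", capture_rate=0.5)]
        records = sim_psm_table(methylome, small_proteome, cfg,
                                capture_pssm=pssm, strategies=strategies)
        counts = pd.Series([r.strategy_label for r in records]).value_counts()
        n = len(methylome.sites)
        sigma = np.sqrt(n * 0.25)
        assert abs(counts.get("s1", 0) - counts.get("s2", 0)) < 8 * sigma

    def test_bias_sign_over_20_seeds(self, small_proteome):
        from panmethyl.selectivity_metrics import mean_pssm_score_by_group
        pssm = make_pssm(0.0, cells={(1, "D"): 1.0, (1, "E"): 1.0,
                                     (-1, "L"): 1.0, (-2, "S"): 0.5})
        strategies = [StrategySpec("biased", capture_rate=0.4, bias_strength=4.0),
                      StrategySpec("flat", capture_rate=0.4)]
        wins = 0
        for seed in range(20):
            cfg = SimConfig(seed=seed, site_rates={"me2": 0.2})
            methylome = sim_methylome(small_proteome, cfg)
            records = sim_psm_table(methylome, small_proteome, cfg,
                                    capture_pssm=pssm, strategies=strategies)
            groups = {"biased": [], "flat": []}
            for rec in records:
                for mod in rec.methyl_mods():
                    pos = rec.protein_start + mod.residue_index - 1
                    groups[rec.strategy_label].append((rec.accession, pos))
            out = mean_pssm_score_by_group(groups, small_proteome, pssm)
            means = dict(zip(out["group"], out["mean_score"]))
            wins += means["biased"] > means["flat"]
        assert wins >= 18

    def test_phospho_cooccurrence_rate_recovered(self, small_proteome):
        from panmethyl.crosstalk import peptide_cooccurrence
        cfg = SimConfig(seed=31, site_rates={"me2": 0.2},
                        phospho_cooccurrence_rate=0.2, unenriched_rate=0.0)
        methylome = sim_methylome(small_proteome, cfg)
        records = sim_psm_table(methylome, small_proteome, cfg)
        out = peptide_cooccurrence(records).set_index("strategy_label")
        pct = out.loc["enriched", "percent_cooccurrence"]
        assert 5.0 < pct < 35.0  # around the planted 20%, wide binomial margin

    def test_decoy_mods_have_low_probability(self, small_proteome):
        cfg = SimConfig(seed=37, site_rates={"me2": 0.1}, decoy_mod_rate=1.0,
                        unenriched_rate=0.0)
        methylome = sim_methylome(small_proteome, cfg)
        records = sim_psm_table(methylome, small_proteome, cfg)
        planted = {(a, p) for a, p, _ in methylome.site_tuples()}
        decoys = [
            m for rec in records for m in rec.methyl_mods()
            if (rec.accession, rec.protein_start + m.residue_index - 1) not in planted
        ]
        assert decoys and all(m.localization_probability < 0.5 for m in decoys)

    def test_psm_tsv_round_trip(self, small_proteome, tmp_path):
        cfg = SimConfig(seed=41, site_rates={"me2": 0.05},
                        phospho_cooccurrence_rate=0.3)
        methylome = sim_methylome(small_proteome, cfg)
        records = sim_psm_table(methylome, small_proteome, cfg)
        path = tmp_path / "psms.tsv"
        pio.write_psm_tsv(records, path)
        assert pio.read_psm_tsv(path) == records
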