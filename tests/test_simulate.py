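"""Synthetic-data generator: determinism, Mendelian truth, noise models."""

import numpy as np
import pytest

from famcoseg.markers import MISSING, read_genotype_ped, read_map
from famcoseg.pedigree import Phenotype, bit_complexity, read_ped, validate_pedigree
from famcoseg.simulate import (
    CausalSpec,
    ErrorSpec,
    PedigreeShape,
    SimulationConfig,
    assign_phenotypes,
    gene_drop,
    meiosis_bits,
    simulate_pedigree,
    simulate_study,
    write_study,
)

from conftest import make_first_cousins


class TestPedigreeShapes:
    def test_default_shape_structure(self):
        cfg = SimulationConfig(seed=1)
        ped = simulate_pedigree(cfg, 3)
        assert ped.family_id == "F3"
        assert validate_pedigree(ped) == []
        assert len(ped.founders) == 3          # couple + married-in spouse
        assert len(ped) == 2 + 2 + 1 + 2       # default 2 children, 2 grandkids

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=5)
        a = simulate_pedigree(cfg, 2)
        b = simulate_pedigree(cfg, 2)
        assert [m.individual_id for m in a] == [m.individual_id for m in b]

    def test_bit_complexity_within_default_limit(self):
        for shape in (PedigreeShape(), PedigreeShape(3, 3), PedigreeShape(4, 4)):
            cfg = SimulationConfig(seed=0)
            cfg.shape = shape
            ped = simulate_pedigree(cfg, 1)
            assert bit_complexity(ped) <= 16

    def test_infeasible_shape_raises(self):
        cfg = SimulationConfig(seed=0)
        cfg.shape = PedigreeShape(n_children=0)
        with pytest.raises(ValueError):
            simulate_pedigree(cfg, 1)


class TestGeneDrop:
    def test_zero_distance_never_recombines(self, rng):
        cms = np.zeros(40)
        for _ in range(50):
            bits = meiosis_bits(cms, rng)
            assert len(set(bits.tolist())) == 1

    def test_child_origins_subset_of_parents(self, rng):
        ped = make_first_cousins()
        cms = np.array([0.0, 25.0, 60.0])
        origins, row = gene_drop(ped, cms, rng)
        for m in ped:
            if m.is_founder:
                continue
            i = row[m.individual_id]
            fa = row[m.father_id]
            mo = row[m.mother_id]
            for j in range(len(cms)):
                assert origins[i, j, 0] in origins[fa, j]
                assert origins[i, j, 1] in origins[mo, j]

    def test_recombination_fraction_at_50cm(self, rng):
        """Haldane: theta(50 cM) = (1 - e^-1)/2 = 0.3161."""
        n = 10_000
        cms = np.array([0.0, 50.0])
        rec = sum(
            int(b[0] != b[1]) for b in (meiosis_bits(cms, rng) for _ in range(n))
        )
        expected = 0.5 * (1 - np.exp(-1.0))
        se = (expected * (1 - expected) / n) ** 0.5
        assert abs(rec / n - expected) < 4 * se


class TestPhenotypes:
    def test_full_penetrance_no_phenocopy(self, rng):
        ped = make_first_cousins()
        carrier = {m.individual_id: m.individual_id in {"gp1", "c1", "k1"}
                   for m in ped}
        out = assign_phenotypes(
            ped, carrier, CausalSpec(f_carrier=1.0, phenocopy=0.0), rng
        )
        for m in out:
            want = Phenotype.IGAN_AFFECTED if carrier[m.individual_id] \
                else Phenotype.UNAFFECTED
            assert m.phenotype is want

    def test_half_penetrance_binomial(self, rng):
        ped = make_first_cousins()
        carrier = {m.individual_id: True for m in ped}
        spec = CausalSpec(f_carrier=0.5, phenocopy=0.0, p_ua_carrier=0.0)
        n_carriers = 0
        n_affected = 0
        for _ in range(300):   # 300 x 8 = 2400 simulated carriers
            out = assign_phenotypes(ped, carrier, spec, rng)
            n_carriers += len(out)
            n_affected += sum(
                m.phenotype is Phenotype.IGAN_AFFECTED for m in out
            )
        frac = n_affected / n_carriers
        se = (0.25 / n_carriers) ** 0.5
        assert abs(frac - 0.5) < 4 * se

    def test_obligate_carrier_configurations_arise(self):
        """With incomplete penetrance, some studies contain an unaffected
        carrier sandwiched between affected generations."""
        found = False
        for seed in range(30):
            cfg = SimulationConfig(seed=seed)
            cfg.n_families = 2
            cfg.causal.f_carrier = 0.5
            study = simulate_study(cfg)
            for fam, truth in study.families.items():
                ped = truth.pedigree
                for m in ped:
                    if (
                        truth.causal_carriers[m.individual_id]
                        and m.phenotype is Phenotype.UNAFFECTED
                    ):
                        found = True
        assert found


class TestStudy:
    def test_causal_positions_unique_across_families(self):
        study = simulate_study(SimulationConfig(seed=9))
        positions = [t.causal_pos for t in study.families.values()]
        assert len(set(positions)) == len(positions)

    def test_one_carrier_founder_per_family(self):
        study = simulate_study(SimulationConfig(seed=9))
        for truth in study.families.values():
            founder_carriers = [
                m.individual_id
                for m in truth.pedigree.founders
                if truth.causal_carriers[m.individual_id]
            ]
            assert len(founder_carriers) == 1

    def test_background_count_matches_poisson_mean(self):
        counts = []
        for seed in range(60):
            cfg = SimulationConfig(seed=seed)
            cfg.n_families = 1
            study = simulate_study(cfg)
            counts.append(len(study.truth) - 1)  # minus the causal variant
        mean = np.mean(counts)
        # variants that drift out of the family are dropped, so the
        # realized count sits slightly below the configured mean
        cfg_mean = SimulationConfig().background.mean_count
        assert 0.8 * cfg_mean < mean <= cfg_mean + 1

    def test_noiseless_callers_identical_to_truth(self):
        cfg = SimulationConfig(seed=4)
        cfg.n_families = 2
        cfg.errors = cfg.errors.noiseless()
        cfg.errors.hard_fail_fraction = 0.0
        study = simulate_study(cfg)
        for fam in study.families:
            ug = {(r.chrom, r.pos) for r in study.ug_records[fam]}
            hc = {(r.chrom, r.pos) for r in study.hc_records[fam]}
            truth = {
                (c, int(p))
                for c, p in zip(
                    study.truth[study.truth.family == fam].chrom,
                    study.truth[study.truth.family == fam].pos,
                )
            }
            assert ug == truth and hc == truth

    def test_caller_union_recovery_rate(self):
        """With s_UG = s_HC = 0.9 the union recovers ~99% of variants."""
        total = 0
        called = 0
        for seed in range(30):
            cfg = SimulationConfig(seed=seed)
            cfg.n_families = 1
            cfg.errors = ErrorSpec(0.0, 0.0, 0.9, 0.9, 20.0, 5.0, 0.0)
            study = simulate_study(cfg)
            fam = study.pedigrees[0].family_id
            union = {
                (r.chrom, r.pos)
                for r in study.ug_records[fam] + study.hc_records[fam]
            }
            total += len(study.truth)
            called += len(union)
        rate = called / total
        se = (0.99 * 0.01 / total) ** 0.5
        assert abs(rate - 0.99) < 4 * se

    def test_dual_tag_fraction_closed_form(self):
        """Among called variants, the dual-caller fraction follows
        s_ug*s_hc / (1 - (1-s_ug)(1-s_hc))."""
        from famcoseg.cascade import merge_callers

        s = 0.8
        both = 0
        any_ = 0
        for seed in range(30):
            cfg = SimulationConfig(seed=100 + seed)
            cfg.n_families = 1
            cfg.errors = ErrorSpec(0.0, 0.0, s, s, 20.0, 5.0, 0.0)
            study = simulate_study(cfg)
            fam = study.pedigrees[0].family_id
            merged = merge_callers(study.ug_records[fam], study.hc_records[fam])
            any_ += len(merged)
            both += sum(len(r.callers) == 2 for r in merged)
        expected = s * s / (1 - (1 - s) ** 2)
        se = (expected * (1 - expected) / any_) ** 0.5
        assert abs(both / any_ - expected) < 4 * se


class TestWriteStudy:
    def test_round_trip_through_pipeline_readers(self, tmp_path):
        cfg = SimulationConfig(seed=21)
        cfg.n_families = 2
        study = simulate_study(cfg)
        paths = write_study(study, tmp_path)
        peds = read_ped(paths["ped"])
        assert len(peds) == 2
        panel = read_genotype_ped(paths["genotypes"], read_map(paths["map"]))
        np.testing.assert_array_equal(
            panel.genotypes, study.panel.genotypes
        )
        assert panel.individuals == study.panel.individuals
        # VCF headers declare the INFO contract and the seed
        text = paths["vcf_ug"].read_text()
        for key in ("EUR_MAF", "EFF", "IMPACT", "CADD", "MQ", "FS"):
            assert f"##INFO=<ID={key}" in text
        assert "famcoseg_seed=21" in text
        # truth row count equals injected variants
        import pandas as pd

        truth = pd.read_csv(paths["truth"], sep="\t")
        assert len(truth) == len(study.truth)

    def test_byte_identical_under_same_seed(self, tmp_path):
        cfg = SimulationConfig(seed=8)
        cfg.n_families = 2
        a = write_study(simulate_study(cfg), tmp_path / "a")
        b = write_study(simulate_study(cfg), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key
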