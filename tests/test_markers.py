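"""Marker QC: HWE exact test, Mendelian checks, LD pruning, panel gates."""

import math
from itertools import combinations

import numpy as np
import pytest

from famcoseg.markers import (
    MISSING,
    GenotypePanel,
    Marker,
    MarkerMap,
    QCError,
    hwe_exact_p,
    ld_prune,
    mendelian_consistent,
    qc_markers,
    read_genotype_ped,
    read_map,
    write_genotype_ped,
    write_map,
)
from famcoseg.pedigree import read_ped, write_ped

from conftest import make_sib_pair


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent exact HWE p: enumerate genotype tables with the same
    allele counts and sum probabilities of het counts no more probable
    than observed (probabilities from the multivariate hypergeometric)."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    nA = 2 * n - na
    if na == 0 or nA == 0:
        return 1.0
    probs = {}
    for het in range(min(na, nA) + 1):
        if (na - het) % 2:
            continue
        aa = (na - het) // 2
        AA = n - het - aa
        if AA < 0:
            continue
        # P(het) proportional to n! 2^het / (AA! het! aa!)
        logp = (
            het * math.log(2)
            - math.lgamma(AA + 1)
            - math.lgamma(het + 1)
            - math.lgamma(aa + 1)
        )
        probs[het] = logp
    mx = max(probs.values())
    norm = sum(math.exp(v - mx) for v in probs.values())
    p_obs = math.exp(probs[n_Aa] - mx) / norm
    return sum(
        math.exp(v - mx) / norm
        for v in probs.values()
        if math.exp(v - mx) / norm <= p_obs * (1 + 1e-12)
    )


class TestHWE:
    def test_balanced_small_table(self):
        # 4 A and 4 a alleles: het counts {0, 2, 4} enumerate to p = 1
        assert hwe_exact_p(1, 2, 1) == pytest.approx(1.0)

    def test_all_het_is_extreme(self):
        assert hwe_exact_p(0, 100, 0) < 1e-6

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(5, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "table", [(3, 5, 2), (10, 1, 10), (0, 3, 7), (12, 12, 1), (2, 0, 2)]
    )
    def test_matches_enumeration_oracle(self, table):
        assert hwe_exact_p(*table) == pytest.approx(
            hwe_enumeration_oracle(*table), rel=1e-9
        )

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 0, 1)


class TestMendelian:
    @pytest.mark.parametrize(
        "child,father,mother,ok",
        [
            ((0, 1), (0, 0), (0, 0), False),   # het child of two AA homs
            ((0, 0), (0, 1), (0, 1), True),
            ((1, 1), (MISSING, MISSING), (0, 0), False),  # mother must give A
            ((1, 1), (MISSING, MISSING), (0, 1), True),
            ((MISSING, MISSING), (0, 0), (1, 1), True),   # missing matches all
        ],
    )
    def test_truth_table(self, child, father, mother, ok):
        assert mendelian_consistent(child, father, mother) is ok


def _panel(genos, freqs=None, n_markers=None):
    genos = np.asarray(genos, dtype=np.int16)
    n_ind, n_mark = genos.shape[:2]
    markers = [
        Marker(f"M{j}", "1", float(j), j * 10**6 + 1, freqs or [0.5, 0.5])
        for j in range(n_mark)
    ]
    return GenotypePanel(
        [f"I{i}" for i in range(n_ind)], MarkerMap(markers), genos
    )


class TestQC:
    def _family_panel(self, rng, n_markers=40, maf=0.5):
        ped = make_sib_pair()
        geno = rng.integers(0, 2, size=(4, n_markers, 2)).astype(np.int16)
        # make children consistent with parents
        for j in range(n_markers):
            for c in (2, 3):
                geno[c, j, 0] = geno[0, j, rng.integers(2)]
                geno[c, j, 1] = geno[1, j, rng.integers(2)]
        markers = [
            Marker(f"M{j}", "1", float(j), j * 10**6 + 1, [0.5, 0.5])
            for j in range(n_markers)
        ]
        panel = GenotypePanel(
            ["fa", "mo", "s1", "s2"], MarkerMap(markers), geno
        )
        return ped, panel

    def test_individual_excluded_for_six_percent_missing(self, rng):
        ped, panel = self._family_panel(rng, n_markers=100)
        panel.genotypes[2, :6, :] = MISSING  # 6% > 5%
        _, report = qc_markers(panel, [ped], {"maf": -1.0, "hwe_p": 0.0})
        excl = [e for e in report.exclusions if e.kind == "individual"]
        assert [e.identifier for e in excl] == ["s1"]
        assert excl[0].reason == "missingness"

    def test_maf_exactly_at_threshold_excluded(self):
        # founders: 10 individuals, allele-1 count 1 of 20 -> MAF 0.05
        from famcoseg.pedigree import Individual, Pedigree

        ped = Pedigree(
            "Q", [Individual(f"I{i}", "Q") for i in range(10)]
        )
        geno = np.zeros((10, 1, 2), dtype=np.int16)
        geno[0, 0, 1] = 1
        panel = _panel(geno)
        with pytest.raises(QCError):
            # the single marker is excluded (threshold is <=), so nothing survives
            qc_markers(panel, [ped], {"maf": 0.05, "hwe_p": 0.0})

    def test_clean_panel_zero_exclusions(self, rng):
        """A complete, polymorphic, HWE-consistent panel loses nothing
        under the default thresholds."""
        from famcoseg.pedigree import Individual, Pedigree

        n_founders, n_markers = 40, 30
        ped = Pedigree(
            "Q", [Individual(f"I{i}", "Q") for i in range(n_founders)]
        )
        geno = rng.binomial(1, 0.5, size=(n_founders, n_markers, 2)).astype(
            np.int16
        )
        panel = _panel(geno)
        filtered, report = qc_markers(panel, [ped])
        assert report.exclusions == []
        assert len(filtered.map) == n_markers


class TestLDPrune:
    def test_duplicated_marker_dropped(self, rng):
        col = rng.integers(0, 2, size=(30, 1, 2)).astype(np.int16)
        geno = np.concatenate([col, col], axis=1)
        panel = _panel(geno)
        pruned, kept = ld_prune(panel, [f"I{i}" for i in range(30)])
        assert kept == [0]

    def test_independent_markers_mostly_kept(self, rng):
        geno = rng.integers(0, 2, size=(500, 30, 2)).astype(np.int16)
        panel = _panel(geno)
        _, kept = ld_prune(panel, [f"I{i}" for i in range(500)])
        # with n=500 founders the sampling r^2 ~ 1/n << 0.10
        assert len(kept) >= 29

    def test_threshold_is_strict(self, rng):
        """A pair at exactly the threshold r^2 is kept (strict >)."""
        geno = rng.integers(0, 2, size=(40, 2, 2)).astype(np.int16)
        panel = _panel(geno)
        x = (geno[:, 0, :] == 1).sum(axis=1).astype(float)
        y = (geno[:, 1, :] == 1).sum(axis=1).astype(float)
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        ids = [f"I{i}" for i in range(40)]
        _, kept_eq = ld_prune(panel, ids, r2_threshold=r2)
        assert kept_eq == [0, 1]
        _, kept_lt = ld_prune(panel, ids, r2_threshold=r2 * 0.999)
        assert kept_lt == [0]


class TestLinkageIO:
    def test_map_and_genotype_ped_round_trip(self, tmp_path, rng):
        ped = make_sib_pair()
        n_mark = 5
        markers = [
            Marker(f"M{j}", "2", float(3 * j), 3 * j * 10**6 + 7, [0.4, 0.6])
            for j in range(n_mark)
        ]
        mmap = MarkerMap(markers)
        geno = rng.integers(0, 2, size=(4, n_mark, 2)).astype(np.int16)
        geno[1, 2] = MISSING
        panel = GenotypePanel(["fa", "mo", "s1", "s2"], mmap, geno)
        write_map(mmap, tmp_path / "m.map")
        write_genotype_ped(panel, [ped], tmp_path / "g.ped")
        mmap2 = read_map(tmp_path / "m.map")
        panel2 = read_genotype_ped(tmp_path / "g.ped", mmap2)
        assert [m.name for m in mmap2] == [m.name for m in mmap]
        assert [m.bp for m in mmap2] == [m.bp for m in mmap]
        np.testing.assert_allclose(
            [m.allele_freqs for m in mmap2], [m.allele_freqs for m in mmap]
        )
        np.testing.assert_array_equal(panel2.genotypes, panel.genotypes)
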