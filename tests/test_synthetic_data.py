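"""Simulator structure: LD, pedigree relatedness, gene-drop, noise."""

import numpy as np
import pandas as pd
import pytest

from imputeval.io_formats import MISSING, Pedigree, UNKNOWN
from imputeval.ld_stats import r2, vanraden_grm, allele_frequencies
from imputeval.qc import QcThresholds, run_qc
from imputeval.synthetic_data import (
    SimConfig,
    add_noise,
    build_marker_map,
    gene_drop,
    make_study_fixture,
    pedigree_additive_relationship,
    simulate_founder_haplotypes,
    simulate_pedigree,
)


def small_config(**overrides):
    defaults = dict(
        seed=7, n_snps=600, n_chromosomes=3, n_founder_males=8,
        n_founder_females=16, n_generations=2, n_active_sires=4,
        n_reference_sires=30, n_breeding_females=15, n_young_sires=10,
        n_dams=12, ld_block_mean_snps=10,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestFounderHaplotypes:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        h1, _ = simulate_founder_haplotypes(cfg)
        h2, _ = simulate_founder_haplotypes(cfg)
        np.testing.assert_array_equal(h1, h2)

    def test_distinct_seeds_differ(self):
        h1, _ = simulate_founder_haplotypes(small_config(seed=7))
        h2, _ = simulate_founder_haplotypes(small_config(seed=8))
        assert not np.array_equal(h1, h2)

    def _adjacent_r2(self, haps, idx_pairs):
        vals = [r2(haps[:, a], haps[:, b]) for a, b in idx_pairs]
        return np.nanmean(vals)

    def test_no_copying_gives_no_ld(self):
        cfg = small_config(within_block_corr=0.0, n_snps=900)
        haps, mm = simulate_founder_haplotypes(cfg)
        pairs = [(j, j + 1) for j in range(0, 299, 2)]
        # null for independent pairs: E[r²] ~ 1/(n-1) with n haplotypes
        null = 1.0 / (haps.shape[0] - 1)
        assert self._adjacent_r2(haps, pairs) < 4 * null

    def test_copying_creates_within_block_ld(self):
        cfg = small_config(within_block_corr=0.95, n_snps=900)
        haps, mm = simulate_founder_haplotypes(cfg)
        pairs = [(j, j + 1) for j in range(0, 299)]
        strong = self._adjacent_r2(haps, pairs)
        cfg0 = small_config(within_block_corr=0.0, n_snps=900)
        haps0, _ = simulate_founder_haplotypes(cfg0)
        weak = self._adjacent_r2(haps0, pairs)
        assert strong > weak + 0.2

    def test_ld_decays_with_lag(self, study):
        """Mean r² at marker lag 1 > lag 5 > lag 20 on the default panel."""
        geno = study.genotypes.subset_individuals(study.reference_ids)
        chrom1 = study.marker_map.chrom_indices()[1]
        means = {}
        for lag in (1, 5, 20):
            vals = [r2(geno.dosage[:, chrom1[j]], geno.dosage[:, chrom1[j + lag]])
                    for j in range(0, 200)]
            means[lag] = np.nanmean(vals)
        assert means[1] > means[5] > means[20]

    def test_low_ld_region_breaks_chain(self):
        cfg = small_config(within_block_corr=0.95, n_snps=900,
                           low_ld_region=(1, 50, 120))
        haps, _ = simulate_founder_haplotypes(cfg)
        inside = [(j, j + 1) for j in range(55, 115)]
        outside = [(j, j + 1) for j in range(130, 190)]
        assert self._adjacent_r2(haps, outside) > \
            self._adjacent_r2(haps, inside) + 0.2


class TestSimulatedPedigree:
    def test_group_sizes_and_links(self):
        cfg = small_config()
        sim = simulate_pedigree(cfg)
        assert len(sim.reference_sire_ids) == cfg.n_reference_sires
        assert len(sim.young_sire_ids) == cfg.n_young_sires
        assert len(sim.dam_ids) == cfg.n_dams
        t = sim.pedigree.table.set_index("individual_id")
        ref = set(sim.reference_sire_ids)
        for ys in sim.young_sire_ids:
            assert t.loc[ys, "sire_id"] in ref
        outside = set(f"FM{i + 1}" for i in range(cfg.n_founder_males))- {
            f"FM{i + 1}" for i in range(cfg.n_founder_males // 2)}
        for vd in sim.dam_ids:
            assert t.loc[vd, "sire_id"] in outside

    def test_birth_years_respect_cutoff(self):
        sim = simulate_pedigree(small_config())
        t = sim.pedigree.table.set_index("individual_id")
        assert (t.loc[sim.reference_sire_ids, "birth_year"] < 2005).all()
        assert (t.loc[sim.young_sire_ids, "birth_year"] >= 2005).all()

    def test_young_sires_more_related_than_dams_in_pedigree(self):
        sim = simulate_pedigree(small_config())
        ids, a = pedigree_additive_relationship(sim.pedigree)
        index = {s: i for i, s in enumerate(ids)}
        ref = [index[i] for i in sim.reference_sire_ids]
        ys = [index[i] for i in sim.young_sire_ids]
        vd = [index[i] for i in sim.dam_ids]
        assert a[np.ix_(ys, ref)].mean() > a[np.ix_(vd, ref)].mean()

    def test_additive_relationship_basics(self):
        ped = Pedigree(pd.DataFrame({
            "individual_id": ["s", "d", "c1", "c2", "g"],
            "sire_id": ["0", "0", "s", "s", "c1"],
            "dam_id": ["0", "0", "d", "d", "d"],
            "birth_year": [1, 1, 2, 2, 3],
            "sex": ["M", "F", "M", "F", "M"],
        }))
        ids, a = pedigree_additive_relationship(ped)
        ix = {s: i for i, s in enumerate(ids)}
        assert a[ix["s"], ix["c1"]] == pytest.approx(0.5)  # parent-offspring
        assert a[ix["c1"], ix["c2"]] == pytest.approx(0.5)  # full sibs
        assert a[ix["s"], ix["d"]] == 0.0
        # g = c1 x d mating: inbred, diagonal 1 + 0.5*a(c1,d)
        assert a[ix["g"], ix["g"]] == pytest.approx(1 + 0.5 * a[ix["c1"], ix["d"]])


class TestGeneDrop:
    def test_no_recombination_homozygous_founders_predictable(self):
        cfg = small_config(chrom_length_morgans=0.0, n_snps=30)
        mm = build_marker_map(cfg)
        ped = Pedigree(pd.DataFrame({
            "individual_id": ["f1", "f2", "kid"],
            "sire_id": [UNKNOWN, UNKNOWN, "f1"],
            "dam_id": [UNKNOWN, UNKNOWN, "f2"],
            "birth_year": [1990, 1990, 1995],
            "sex": ["M", "F", "M"],
        }))
        pool = np.zeros((4, 30), dtype=np.int8)
        pool[2:] = 1  # f2 homozygous for B everywhere
        out = gene_drop(ped, pool, cfg, mm)
        np.testing.assert_array_equal(out.dosage[2], np.ones(30))

    def test_missing_parent_haplotypes_error(self):
        cfg = small_config(n_snps=30)
        mm = build_marker_map(cfg)
        ped = Pedigree(pd.DataFrame({
            "individual_id": ["f1", "kid"],
            "sire_id": [UNKNOWN, "f1"],
            "dam_id": [UNKNOWN, "ghost"],
            "birth_year": [1990, 1995],
            "sex": ["M", "M"],
        }))
        with pytest.raises(ValueError, match="ghost"):
            gene_drop(ped, np.zeros((2, 30), dtype=np.int8), cfg, mm)

    def test_parent_offspring_grm_matches_pedigree_expectation(
            self, study, post_qc):
        """Mean base-frequency GRM between young sires and their sires agrees
        with the pedigree expectation, which exceeds the textbook 0.5 here
        because of sire inbreeding and sire-dam co-ancestry."""
        _, filt, fmap = post_qc
        founders = study.genotypes.subset_individuals(study.founder_ids)
        idx = study.marker_map.index_of(fmap.snp_ids)
        p_base = allele_frequencies(founders.subset_snps(idx))
        grm = vanraden_grm(filt, p_base)
        ids, a = pedigree_additive_relationship(study.pedigree_true)
        aix = {s: i for i, s in enumerate(ids)}
        t = study.pedigree_true.table.set_index("individual_id")
        grm_pairs, ped_pairs = [], []
        gid = {s: i for i, s in enumerate(grm.ids)}
        for ys in study.young_sire_ids:
            sire = t.loc[ys, "sire_id"]
            if sire in gid:
                grm_pairs.append(grm.values[gid[ys], gid[sire]])
                ped_pairs.append(a[aix[ys], aix[sire]])
        assert np.mean(ped_pairs) >= 0.5  # parent-offspring baseline
        assert np.mean(grm_pairs) == pytest.approx(np.mean(ped_pairs), abs=0.05)

    def test_full_sib_vs_half_sib_ordering(self, study, post_qc):
        _, filt, fmap = post_qc
        t = study.pedigree_true.table.set_index("individual_id")
        grm = vanraden_grm(filt)
        gid = {s: i for i, s in enumerate(grm.ids)}
        parents = {i: (t.loc[i, "sire_id"], t.loc[i, "dam_id"])
                   for i in study.reference_ids}
        full, half = [], []
        ref = study.reference_ids
        for i in range(len(ref)):
            for j in range(i + 1, len(ref)):
                si, di = parents[ref[i]]
                sj, dj = parents[ref[j]]
                if si == sj and di == dj:
                    full.append(grm.values[gid[ref[i]], gid[ref[j]]])
                elif si == sj and di != dj:
                    half.append(grm.values[gid[ref[i]], gid[ref[j]]])
        assert len(full) > 3 and len(half) > 3
        assert np.mean(full) > np.mean(half)


class TestAddNoise:
    def test_zero_rates_identity(self):
        cfg = small_config(missing_rate=0.0, low_quality_rate=0.0)
        fx_map = build_marker_map(cfg)
        haps, _ = simulate_founder_haplotypes(cfg, fx_map)
        sim = simulate_pedigree(cfg)
        clean = gene_drop(sim.pedigree, haps, cfg, fx_map)
        noisy = add_noise(clean, cfg)
        np.testing.assert_array_equal(noisy.dosage, clean.dosage)
        assert (noisy.quality >= 0.70).all()

    def test_missing_rate_hits_binomial_count(self):
        cfg = small_config(missing_rate=0.05, n_snps=300)
        mm = build_marker_map(cfg)
        haps, _ = simulate_founder_haplotypes(cfg, mm)
        sim = simulate_pedigree(cfg)
        clean = gene_drop(sim.pedigree, haps, cfg, mm)
        noisy = add_noise(clean, cfg)
        n_cells = clean.dosage.size
        n_missing = int((noisy.dosage == MISSING).sum())
        sd = np.sqrt(n_cells * 0.05 * 0.95)
        assert abs(n_missing - 0.05 * n_cells) < 5 * sd

    def test_planted_low_call_rate_snp_removed_by_qc(self):
        cfg = small_config(n_snps=300)
        fx = make_study_fixture(cfg)
        geno = fx.genotypes.subset_individuals(fx.genotyped_ids())
        geno.dosage[::2, 5] = MISSING  # call rate 0.5 at SNP index 5
        bad_snp = fx.marker_map.snp_ids[5]
        report, _, fmap = run_qc(geno, fx.marker_map,
                                 QcThresholds(hwe_p_max=0.0, maf_min=0.0),
                                 reference_ids=fx.reference_ids)
        assert bad_snp not in set(fmap.snp_ids)


class TestStudyFixture:
    def test_same_seed_identical(self):
        a = make_study_fixture(small_config())
        b = make_study_fixture(small_config())
        np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
        np.testing.assert_array_equal(a.genotypes.quality, b.genotypes.quality)
        pd.testing.assert_frame_equal(a.pedigree.table, b.pedigree.table)

    def test_maf_floor_mostly_respected(self, study, post_qc):
        report, _, _ = post_qc
        frac_low_maf = report.exclusions["maf"] / study.marker_map.n_snps
        assert frac_low_maf < 0.05

    def test_mean10_gradient_matches_study_design(self, study, post_qc, study_grm):
        """Young sires are genomically closer to the reference than dams."""
        from imputeval.ld_stats import relatedness_summary

        rel_ys = relatedness_summary(study_grm, study.reference_ids,
                                     study.young_sire_ids)
        rel_d = relatedness_summary(study_grm, study.reference_ids,
                                    study.dam_ids)
        assert rel_ys["mean10"].mean() > rel_d["mean10"].mean()
        assert rel_ys["maxr"].mean() > rel_d["maxr"].mean()

    def test_recorded_pedigree_censors_dam_sires(self, study):
        recorded = study.pedigree.table.set_index("individual_id")
        truth = study.pedigree_true.table.set_index("individual_id")
        n_unknown = sum(
            recorded.loc[d, "sire_id"] == UNKNOWN for d in study.dam_ids
        )
        assert 0 < n_unknown < len(study.dam_ids)
        assert all(truth.loc[d, "sire_id"] != UNKNOWN for d in study.dam_ids)

    def test_write_bundle(self, tmp_path):
        fx = make_study_fixture(small_config(n_snps=100))
        fx.write(tmp_path, format="ped")
        for name in ("genotypes.ped", "genotypes.map", "genotypes.qual",
                     "pedigree.txt", "reference.ids", "young_sires.ids",
                     "dams.ids"):
            assert (tmp_path / name).exists()
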