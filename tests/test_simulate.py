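"""Forward simulator: recombination machinery, ground truth, phenotype
model, and file emission round-trips."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from riskhapscan.dosage import firth_logistic
from riskhapscan.io import read_ibd_segments, read_phased_vcf, read_phenotypes
from riskhapscan.simulate import (
    SimulationConfig,
    emit,
    simulate_cohort,
    simulate_haplotypes,
    simulate_phenotypes,
    true_ibd_segments,
)


def small_config(**kw):
    base = dict(
        seed=5, n_markers=120, pop_size={"ShowPet": 60, "Working": 40},
        n_dogs={"ShowPet": 25, "Working": 10}, founder_risk_copies=4,
        founder_expansion_weight=5.0, g_generations=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


def carrier_tracts_at_focal(truth, cfg):
    out = []
    for tracts in truth.descent_tracts:
        for s, e in tracts:
            if s <= cfg.focal_bp < e:
                out.append((s, e))
    return out


class TestAncestry:
    def test_zero_recombination_full_span_tracts(self):
        cfg = small_config(recomb_rate_cM_per_Mb=0.0)
        _, _, truth = simulate_haplotypes(cfg)
        tr = carrier_tracts_at_focal(truth, cfg)
        assert tr  # risk allele survived
        for s, e in tr:
            assert (s, e) == (cfg.region_start_bp, cfg.region_end_bp)

    def test_zero_generations_carriers_are_founder_copies(self):
        cfg = small_config(g_generations=0, founder_risk_copies=1,
                           n_dogs={"ShowPet": 60, "Working": 0})
        _, haps, truth = simulate_haplotypes(cfg)
        col = haps.alleles[:, truth.focal_index]
        carriers = haps.alleles[col == 1]
        assert len(carriers) >= 1
        # all carrier haplotypes are exact copies of a founder risk chromosome
        assert np.all(carriers == carriers[0])
        for tracts in truth.descent_tracts:
            for s, e in tracts:
                assert (s, e) == (cfg.region_start_bp, cfg.region_end_bp)

    def test_risk_alleles_lie_inside_descent_tracts(self):
        cfg = small_config()
        mm, haps, truth = simulate_haplotypes(cfg)
        pos = mm.position_bp
        for h in range(haps.n_haplotypes):
            if haps.alleles[h, truth.focal_index] != 1:
                continue
            inside = any(s <= cfg.focal_bp < e for s, e in truth.descent_tracts[h])
            assert inside

    def test_descent_tracts_disjoint(self):
        cfg = small_config()
        _, _, truth = simulate_haplotypes(cfg)
        for tracts in truth.descent_tracts:
            for (s1, e1), (s2, e2) in zip(tracts, tracts[1:]):
                assert e1 <= s2  # disjoint; abutting only across founders

    def test_mean_onesided_extent_matches_meiosis_oracle(self):
        # neutral spread of rare founder chromosomes in a large lineage,
        # checked against an independent g-meiosis Poisson-breakpoint
        # simulation of the focal-anchored tract. Shallow g and a low
        # carrier frequency keep pedigree collapse (which rejoins founder
        # material and lengthens tracts) below the Monte-Carlo noise floor.
        cfg = SimulationConfig(
            seed=29, n_markers=60, pop_size={"ShowPet": 600},
            n_dogs={"ShowPet": 600}, founder_risk_copies=40,
            founder_expansion_weight=0.0, carrier_advantage=0.0,
            g_generations=4, migration_rate=0.0,
        )
        rep_means, n_tracts = [], 0
        for rep in range(50):
            _, _, truth = simulate_haplotypes(
                SimulationConfig(**{**cfg.__dict__, "seed": 29 + rep}))
            ext = []
            for s, e in carrier_tracts_at_focal(truth, cfg):
                ext.append(cfg.focal_bp - s)
                ext.append(e - cfg.focal_bp)
            n_tracts += len(ext) // 2
            rep_means.append(np.mean(ext) / 1e6)
        assert n_tracts >= 2000

        # independent oracle: one-sided gap to the nearest breakpoint of g
        # pooled Poisson processes, truncated at the region edges
        rng = np.random.default_rng(77)
        g, rate = cfg.g_generations, cfg.recomb_rate_cM_per_Mb / 100.0
        span_l = (cfg.focal_bp - cfg.region_start_bp) / 1e6
        span_r = (cfg.region_start_bp + cfg.region_span_bp - cfg.focal_bp) / 1e6
        draws = rng.exponential(1.0 / (g * rate), size=(120_000, 2))
        oracle = 0.5 * (np.minimum(draws[:, 0], span_l)
                        + np.minimum(draws[:, 1], span_r)).mean()
        # replicate-level SE: tracts within a run share ancestry
        rep_means = np.asarray(rep_means)
        se = rep_means.std(ddof=1) / np.sqrt(len(rep_means))
        assert abs(rep_means.mean() - oracle) < 4 * se

    def test_allele_frequencies_preserved_in_expectation(self):
        cfg = SimulationConfig(
            seed=41, n_markers=400, pop_size={"ShowPet": 400},
            n_dogs={"ShowPet": 400}, founder_risk_copies=5,
            founder_expansion_weight=0.0, carrier_advantage=0.0,
            g_generations=5, migration_rate=0.0,
        )
        mm, haps, truth = simulate_haplotypes(cfg)
        final = haps.alleles.mean(axis=0)
        # drift changes individual frequencies but is directionless: averaged
        # over many markers the spectrum keeps the symmetric Beta(0.8, 0.8)
        # mean of 0.5
        assert abs(final.mean() - 0.5) < 0.05


class TestPhenotypes:
    def test_infinite_effect_makes_all_carriers_cases(self):
        cfg = small_config(per_allele_log_OR=50.0, baseline_log_odds=-4.0)
        mm, haps, truth = simulate_haplotypes(cfg)
        cohort = simulate_phenotypes(haps, truth, cfg)
        col = haps.alleles[:, truth.focal_index]
        dosage = col[0::2] + col[1::2]
        status = cohort.table.status.to_numpy()
        assert np.all(status[dosage >= 1] == "case")

    def test_null_effect_breaks_dosage_association(self):
        cfg = SimulationConfig(
            seed=13, n_markers=40, pop_size={"ShowPet": 2600},
            n_dogs={"ShowPet": 2500}, founder_risk_copies=600,
            founder_expansion_weight=0.0, carrier_advantage=0.0,
            g_generations=2, migration_rate=0.0,
            per_allele_log_OR=0.0, baseline_log_odds=-0.8,
        )
        mm, haps, truth = simulate_haplotypes(cfg)
        cohort = simulate_phenotypes(haps, truth, cfg)
        col = haps.alleles[:, truth.focal_index]
        dosage = col[0::2] + col[1::2]
        case = (cohort.table.status == "case").to_numpy().astype(int)
        table = np.zeros((3, 2))
        for d, c in zip(dosage, case):
            table[d, c] += 1
        table = table[table.sum(axis=1) > 0]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_configured_or_recovered_by_firth(self):
        cfg = SimulationConfig(
            seed=17, n_markers=40, pop_size={"ShowPet": 2100},
            n_dogs={"ShowPet": 2000}, founder_risk_copies=500,
            founder_expansion_weight=0.0, carrier_advantage=0.0,
            g_generations=2, migration_rate=0.0,
            per_allele_log_OR=1.0, baseline_log_odds=-1.2,
        )
        mm, haps, truth = simulate_haplotypes(cfg)
        cohort = simulate_phenotypes(haps, truth, cfg)
        col = haps.alleles[:, truth.focal_index]
        dosage = (col[0::2] + col[1::2]).astype(float)
        y = (cohort.table.status == "case").to_numpy().astype(float)
        X = np.column_stack([np.ones(len(y)), dosage])
        fit = firth_logistic(X, y, profile_ci=False)
        assert abs(fit.beta[1] - 1.0) < 2 * fit.se[1]

    def test_case_onset_never_exceeds_followup(self):
        cfg = small_config()
        ds = simulate_cohort(cfg)
        t = ds.cohort.table
        cases = t[t.status == "case"]
        assert (cases.age_onset_years <= cases.age_last_followup_years).all()
        controls = t[t.status == "control"]
        assert (controls.age_last_followup_years >= cfg.control_min_age).all()


class TestEmission:
    def test_round_trip_identity(self, tmp_path):
        ds = simulate_cohort(small_config())
        paths = emit(ds, tmp_path)
        mm2, haps2 = read_phased_vcf(paths["vcf"])
        np.testing.assert_array_equal(haps2.alleles, ds.haplotypes.alleles)
        assert haps2.haplotype_ids == ds.haplotypes.haplotype_ids
        cohort2 = read_phenotypes(paths["phenotypes"])
        assert cohort2.table.status.tolist() == ds.cohort.table.status.tolist()
        segs2 = read_ibd_segments(paths["ibd"])
        assert len(segs2) == len(true_ibd_segments(ds))

    def test_identical_seeds_byte_identical_outputs(self, tmp_path):
        a = emit(simulate_cohort(small_config(seed=9)), tmp_path / "a")
        b = emit(simulate_cohort(small_config(seed=9)), tmp_path / "b")
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_carrier_pair_count_bound(self):
        ds = simulate_cohort(small_config())
        segs = true_ibd_segments(ds).segments
        col = ds.haplotypes.alleles[:, ds.truth.focal_index]
        k = int((col == 1).sum())
        hap_index = {hid: i for i, hid in enumerate(ds.haplotypes.haplotype_ids)}
        carrier_pairs = set()
        cfg = ds.truth.config
        for r in segs.itertuples(index=False):
            ia = hap_index[(r.dog_a, r.side_a)]
            ib = hap_index[(r.dog_b, r.side_b)]
            if col[ia] == 1 and col[ib] == 1 and \
                    r.start_bp <= cfg.focal_bp <= r.end_bp:
                carrier_pairs.add((min(ia, ib), max(ia, ib)))
        assert len(carrier_pairs) <= k * (k - 1) // 2

    def test_zero_recombination_full_span_sharing(self):
        # single founder so that all carrier chromosomes are mutually IBD
        ds = simulate_cohort(small_config(recomb_rate_cM_per_Mb=0.0,
                                          founder_risk_copies=1))
        segs = true_ibd_segments(ds).segments
        col = ds.haplotypes.alleles[:, ds.truth.focal_index]
        k = int((col == 1).sum())
        cfg = ds.truth.config
        full = segs[(segs.start_bp == cfg.region_start_bp)
                    & (segs.end_bp == cfg.region_end_bp - 1)]
        hap_index = {hid: i for i, hid in enumerate(ds.haplotypes.haplotype_ids)}
        carrier_full = {
            tuple(sorted((hap_index[(r.dog_a, r.side_a)],
                          hap_index[(r.dog_b, r.side_b)])))
            for r in full.itertuples(index=False)
            if col[hap_index[(r.dog_a, r.side_a)]] == 1
            and col[hap_index[(r.dog_b, r.side_b)]] == 1
        }
        assert len(carrier_full) == k * (k - 1) // 2


def test_median_carrier_tract_shrinks_with_generations():
    """Older founder events leave shorter shared tracts on average."""
    from riskhapscan.sharing import median_shared_tracts, partition_by_focal_allele

    medians = {}
    for g in (5, 11, 25):
        vals = []
        for seed in (101, 102, 103):
            ds = simulate_cohort(SimulationConfig(
                seed=seed, g_generations=g, n_markers=600,
                pop_size={"ShowPet": 200}, n_dogs={"ShowPet": 80},
                founder_expansion_weight=40.0, migration_rate=0.0,
            ))
            part = partition_by_focal_allele(ds.haplotypes, ds.focal_spec)
            if len(part.risk_indices) < 2:
                continue
            summ = median_shared_tracts(ds.haplotypes, part.risk_indices,
                                        part.focal_index)
            vals.append(summ.panel_median_bp)
        medians[g] = np.mean(vals)
    assert medians[5] > medians[11] > medians[25]
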