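"""Regulatory phenotype simulator: spectrum, calibration, phenotypes."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import special, stats

from epiprs.select import assoc_scan
from epiprs.simulate import (
    SimConfig,
    assign_phenotypes,
    build_annotations,
    child_seed,
    compute_liability,
    draw_effects,
    normalize_genotypes,
    run_replicates,
    simulate_cohort,
    simulate_dataset,
)

BASE = SimConfig(n=400, m=200, causal_per_gene=50, seed=11)


class TestSimulateCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        a, b = simulate_cohort(BASE), simulate_cohort(BASE)
        np.testing.assert_array_equal(a.variants.haplotypes, b.variants.haplotypes)
        np.testing.assert_array_equal(a.maf, b.maf)
        np.testing.assert_array_equal(a.causal_sites, b.causal_sites)

    def test_rare_fraction_zero_keeps_causal_common(self):
        cohort = simulate_cohort(replace(BASE, rare_fraction=0.0))
        assert np.all(cohort.maf[cohort.causal_sites] >= 0.05)

    def test_rare_fraction_sets_exact_rare_count(self):
        cohort = simulate_cohort(replace(BASE, rare_fraction=0.5, n=2000))
        rare = cohort.maf[cohort.causal_sites] < 0.01
        assert rare.sum() == round(0.5 * cohort.causal_sites.size)
        assert np.all(cohort.maf[cohort.causal_sites][rare] >= 0.001)

    def test_empirical_mafs_track_drawn_mafs(self):
        """Binomial sampling oracle: at n=2000, >= 99% of common sites lie
        within 3 binomial standard errors of their drawn MAF."""
        cohort = simulate_cohort(replace(BASE, n=2000, seed=5))
        emp = cohort.variants.haplotypes.mean(axis=(1, 2))
        se = np.sqrt(cohort.maf * (1 - cohort.maf) / (2 * 2000))
        within = np.abs(emp - cohort.maf) <= 3 * se
        assert within.mean() >= 0.99

    def test_no_monomorphic_sites(self):
        cohort = simulate_cohort(replace(BASE, rare_fraction=1.0, n=2000))
        counts = cohort.variants.haplotypes.sum(axis=(1, 2))
        assert np.all((counts > 0) & (counts < 2 * 2000))

    def test_dosage_equals_haplotype_sum(self):
        cohort = simulate_cohort(BASE)
        np.testing.assert_array_equal(
            cohort.dosages(), cohort.variants.haplotypes.sum(axis=2).T
        )

    def test_tiny_n_with_rare_sites_raises(self):
        with pytest.raises(ValueError, match="increase n"):
            simulate_cohort(replace(BASE, n=4, rare_fraction=1.0))


class TestNormalizeGenotypes:
    def test_columns_are_standardized(self):
        X = normalize_genotypes(simulate_cohort(BASE))
        assert np.abs(X.mean(axis=0)).max() < 1e-12
        assert np.abs(X.var(axis=0) - 1).max() < 1e-12

    def test_matches_two_pass_oracle(self):
        cohort = simulate_cohort(BASE)
        d = cohort.dosages().astype(float)
        X = normalize_genotypes(cohort)
        k = 17
        mean = sum(d[:, k]) / len(d)
        var = sum((v - mean) ** 2 for v in d[:, k]) / len(d)
        np.testing.assert_allclose(X[:, k], (d[:, k] - mean) / np.sqrt(var), atol=1e-10)

    def test_monomorphic_column_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            normalize_genotypes(np.ones((10, 3)))


class TestAnnotations:
    def test_one_causal_gene_per_block(self):
        cohort = simulate_cohort(replace(BASE, m=200, n_blocks=2, causal_per_gene=40))
        ann = build_annotations(cohort)
        assert len(np.unique(ann.causal_gene_of_site)) == 2
        assert cohort.gene_anchors.size == 2

    def test_causal_sites_inside_res_others_outside(self):
        cohort = simulate_cohort(BASE)
        ann = build_annotations(cohort)
        pos = cohort.variants.pos
        chrom = cohort.variants.chrom

        def in_re(k):
            return any(
                c == str(chrom[k]) and s <= pos[k] < e for c, s, e in ann.re_intervals
            )

        assert all(in_re(k) for k in ann.causal_sites)
        assert not any(in_re(k) for k in ann.non_re_sites)

    def test_binding_density_matches_binomial_oracle(self):
        cfg = replace(BASE, n_tfs=10, tf_hit_prob=0.3, causal_per_gene=100, m=200)
        ann = build_annotations(simulate_cohort(cfg))
        total = int(ann.binding.sum())
        expect, sd = 10 * 100 * 0.3, np.sqrt(10 * 100 * 0.3 * 0.7)
        assert abs(total - expect) <= 3 * sd + 10  # +|T| for the no-site top-up

    def test_every_tf_binds_at_least_one_causal_site(self):
        ann = build_annotations(simulate_cohort(replace(BASE, tf_hit_prob=0.02)))
        assert np.all(ann.binding.sum(axis=1) >= 1)

    def test_coupled_mode_is_one_hot_per_causal_site(self):
        ann = build_annotations(simulate_cohort(BASE), sequence_coupled=True)
        per_site = ann.binding[:, ann.causal_sites].sum(axis=0)
        assert np.all(per_site >= 1)
        assert ann.tf_of_causal is not None


class TestLiability:
    def _components(self, cfg):
        cohort = simulate_cohort(cfg)
        ann = build_annotations(cohort)
        draws = draw_effects(cohort, ann)
        return compute_liability(normalize_genotypes(cohort), ann, draws, cfg)

    def test_zero_epi_proportion_gives_zero_component(self):
        comp = self._components(replace(BASE, h_epi2=0.0, h_direct2=0.5))
        assert np.all(comp.y_epi == 0)

    def test_exact_variance_calibration(self):
        cfg = replace(BASE, n=4000, h_epi2=0.5, h_direct2=0.3, h_inter2=0.0)
        comp = self._components(cfg)
        assert abs(comp.y_epi.var() - 0.5) < 1e-10
        assert abs(comp.y_direct.var() - 0.3) < 1e-10
        assert np.all(comp.y_inter == 0)
        assert abs(comp.y_env.var() - 0.2) / 0.2 < 0.05  # sampled, 5% band

    def test_interaction_component_calibrated(self):
        cfg = replace(BASE, n=2000, h_epi2=0.2, h_direct2=0.2, h_inter2=0.3, f_inter=0.5)
        comp = self._components(cfg)
        assert abs(comp.y_inter.var() - 0.3) < 1e-10

    def test_interaction_pairs_required_when_h_inter_positive(self):
        cfg = replace(BASE, h_epi2=0.2, h_direct2=0.2, h_inter2=0.3, f_inter=0.0)
        with pytest.raises(ValueError, match="f_inter"):
            self._components(cfg)

    def test_duplicated_individual_triggers_degenerate_error(self):
        cfg = BASE
        cohort = simulate_cohort(cfg)
        ann = build_annotations(cohort)
        draws = draw_effects(cohort, ann)
        X = np.tile(normalize_genotypes(cohort)[0], (cfg.n, 1))
        with pytest.raises(ValueError, match="constant"):
            compute_liability(X, ann, draws, cfg)

    def test_epi_and_direct_components_nearly_independent(self):
        comp = self._components(replace(BASE, n=4000, h_epi2=0.5, h_direct2=0.5))
        r = np.corrcoef(comp.y_epi, comp.y_direct)[0, 1]
        assert abs(r) < 0.05


class TestAssignPhenotypes:
    def _comp(self, cfg):
        cohort = simulate_cohort(cfg)
        ann = build_annotations(cohort)
        return compute_liability(
            normalize_genotypes(cohort), ann, draw_effects(cohort, ann), cfg
        )

    def test_threshold_mode_case_count_exact(self):
        cfg = replace(BASE, n=4000, prevalence=0.5)
        comp = assign_phenotypes(self._comp(cfg), cfg)
        assert comp.labels.sum() == 2000

    @pytest.mark.parametrize("prev", [0.1, 0.37])
    def test_threshold_mode_other_prevalences(self, prev):
        cfg = replace(BASE, n=1000, prevalence=prev)
        comp = assign_phenotypes(self._comp(cfg), cfg)
        assert comp.labels.sum() == round(1000 * prev)

    def test_bernoulli_mode_mean_mu_hits_prevalence(self):
        cfg = replace(BASE, n=2000, prevalence=0.3, phenotype_mode="bernoulli")
        comp = assign_phenotypes(self._comp(cfg), cfg)
        assert abs(comp.mu.mean() - 0.3) < 1e-8

    def test_bernoulli_equal_liabilities_closed_form(self):
        from epiprs.simulate import LiabilityComponents

        cfg = replace(BASE, prevalence=0.2, phenotype_mode="bernoulli")
        z = np.zeros(500)
        comp = LiabilityComponents(y_epi=z, y_direct=z, y_env=z, y_inter=z)
        comp = assign_phenotypes(comp, cfg)
        assert abs(comp.alpha0 - special.logit(0.2)) < 1e-9

    def test_bernoulli_case_fraction_calibrated_over_seeds(self):
        """Case fraction within 3*sqrt(p(1-p)/n) of the prevalence in at
        least 95 of 100 seeded draws."""
        cfg = replace(BASE, n=4000, prevalence=0.5, phenotype_mode="bernoulli")
        comp = self._comp(cfg)
        band = 3 * np.sqrt(0.5 * 0.5 / 4000)
        ok = 0
        for s in range(100):
            out = assign_phenotypes(comp, cfg, seed=s)
            ok += abs(out.labels.mean() - 0.5) <= band
        assert ok >= 95


class TestRareVariantDial:
    def test_rare_architecture_starves_per_site_carrier_counts(self):
        """The rare-fraction dial's mechanism: an all-rare causal
        architecture concentrates each site's signal in a handful of
        carriers, which is what degrades per-variant effect estimation
        downstream (each causal site still explains the same liability
        variance because genotypes are normalized before weighting)."""
        carriers = {}
        for rf in (0.0, 1.0):
            cfg = replace(BASE, n=2000, rare_fraction=rf, seed=7)
            cohort = simulate_cohort(cfg)
            dos = cohort.dosages()[:, cohort.causal_sites]
            carriers[rf] = np.median((dos > 0).sum(axis=0))
        assert carriers[1.0] <= 40  # MAF < 0.01 at n=2000
        assert carriers[0.0] >= 180  # MAF >= 0.05
        assert carriers[1.0] < carriers[0.0] / 4

    def test_rare_degrades_out_of_sample_linear_prediction(self):
        """A ridge-style linear model loses held-out accuracy when the
        causal architecture goes all-rare (the collapse the benchmark
        quantifies), while in-sample fit does not reveal it."""
        from epiprs.model import SplitSpec, auroc, split_cohort, train

        aucs = {0.0: [], 1.0: []}
        for rep in range(5):
            for rf in (0.0, 1.0):
                cfg = replace(
                    BASE, n=1500, m=100, h_epi2=0.9, h_direct2=0.05,
                    rare_fraction=rf, seed=child_seed(31, "lin", rep, rf),
                )
                ds = simulate_dataset(cfg)
                dos = ds.cohort.dosages().astype(float)
                tr, te = split_cohort(ds.labels, SplitSpec(seed=rep))
                mean, sd = dos[tr].mean(0), dos[tr].std(0)
                sd[sd == 0] = 1.0
                mdl = train((dos[tr] - mean) / sd, ds.labels[tr], kind="linear-penalized")
                aucs[rf].append(auroc(mdl.predict_scores((dos[te] - mean) / sd), ds.labels[te]))
        assert np.mean(aucs[1.0]) < np.mean(aucs[0.0])


class TestRunReplicates:
    def test_row_count_and_determinism(self):
        settings = {"a": replace(BASE, n=100, m=60, causal_per_gene=20)}

        def runner(cfg, rep):
            ds = simulate_dataset(cfg)
            return {"n_cases": int(ds.labels.sum())}

        t1 = run_replicates(settings, 20, runner, master_seed=3)
        t2 = run_replicates(settings, 20, runner, master_seed=3)
        assert len(t1) == 20
        assert t1.equals(t2)
        assert t1["seed"].nunique() == 20
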