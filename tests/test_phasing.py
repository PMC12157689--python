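import numpy as np
import pytest

from poeqtl.phasing import (ERROR_MASKED, IMPUTED, MENDELIAN, MISSING,
                            UNRESOLVED, HmmParams, LiStephensHMM,
                            impute_dosage, mendelian_phase,
                            phase_trio_dataset, phasing_error_rate,
                            resolve_triple_het)
from poeqtl.simulate import SimConfig, simulate_panel, simulate_trios

from .oracles import enumerate_dosage


class TestMendelianPhase:
    @pytest.mark.parametrize("gf,gm,gc,pat,mat,tag", [
        (0, 2, 1, 0, 1, MENDELIAN),     # forced by homozygous parents
        (2, 0, 1, 1, 0, MENDELIAN),
        (1, 1, 1, MISSING, MISSING, UNRESOLVED),   # triple heterozygous
        (2, 2, 1, MISSING, MISSING, ERROR_MASKED),  # incompatible, child het
        (0, 0, 1, MISSING, MISSING, ERROR_MASKED),
        (0, 1, 2, 1, 1, MENDELIAN),     # homozygous child phases itself
        (0, 1, 0, 0, 0, MENDELIAN),
        (1, 0, 1, 1, 0, MENDELIAN),     # het father, hom mother
        (1, 2, 1, 0, 1, MENDELIAN),
        (2, 2, 2, 1, 1, MENDELIAN),
        (0, 0, 2, 1, 1, MENDELIAN),     # incompatible but child homozygous
        (-1, 1, 1, MISSING, MISSING, UNRESOLVED),  # missing parent, ambiguous
        (-1, 0, 1, 1, 0, MENDELIAN),    # missing parent, still forced
    ])
    def test_single_site_rules(self, gf, gm, gc, pat, mat, tag):
        ph = mendelian_phase(np.array([gf]), np.array([gm]), np.array([gc]))
        assert ph.h_pat[0] == pat
        assert ph.h_mat[0] == mat
        assert ph.resolved_by[0] == tag

    def test_rejects_out_of_range_genotypes(self):
        with pytest.raises(ValueError):
            mendelian_phase(np.array([3]), np.array([0]), np.array([0]))

    def test_mendelian_sites_sum_to_child_genotype(self, small_study):
        t = small_study.trios
        ph = mendelian_phase(t.g_father[0], t.g_mother[0], t.g_child[0])
        m = ph.resolved_by == MENDELIAN
        assert np.array_equal(ph.h_pat[m] + ph.h_mat[m], t.g_child[0][m])

    def test_haplotypes_consistent_with_parent_alleles(self):
        """Where phased by rule on error-free trios, the paternal allele is
        one the father carries and the maternal one the mother carries."""
        cfg = SimConfig(n_trios=30, n_sites=400, genotype_error_rate=0.0,
                        seed=2)
        rng = np.random.default_rng(2)
        t = simulate_trios(simulate_panel(cfg, rng), cfg, rng)
        for i in range(5):
            ph = mendelian_phase(t.g_father[i], t.g_mother[i], t.g_child[i])
            m = ph.resolved_by == MENDELIAN
            gf, gm = t.g_father[i][m], t.g_mother[i][m]
            assert ((gf != 0) | (ph.h_pat[m] == 0)).all()
            assert ((gf != 2) | (ph.h_pat[m] == 1)).all()
            assert ((gm != 0) | (ph.h_mat[m] == 0)).all()
            assert ((gm != 2) | (ph.h_mat[m] == 1)).all()


class TestLiStephens:
    def test_unanimous_panel_gives_one_minus_eps(self):
        panel = np.ones((5, 3), dtype=np.int8)
        params = HmmParams(panel, rho=0.1, eps=0.01)
        q = np.array([1, -1, 1], dtype=np.int8)
        dos = impute_dosage(q, params)
        assert dos[1] == pytest.approx(0.99, abs=1e-9)
        assert dos[0] == 1.0 and dos[2] == 1.0  # observed passed through

    def test_split_panel_no_flanking_information_gives_half(self):
        panel = np.array([[1, 1, 1], [0, 0, 0]] * 3, dtype=np.int8)
        params = HmmParams(panel, rho=0.5, eps=0.001)
        # rho=0.5 with fully split panel and a fully masked query: symmetric
        q = np.array([-1, -1, -1], dtype=np.int8)
        dos = impute_dosage(q, params)
        assert np.allclose(dos, 0.5, atol=1e-12)

    @pytest.mark.parametrize("rho,eps", [(0.2, 0.05), (0.05, 0.001),
                                         (0.9, 0.3)])
    def test_matches_exhaustive_path_enumeration(self, rho, eps, rng):
        """Forward-backward posterior dosage equals brute-force enumeration
        over all template paths on a 2-haplotype, 3-site panel."""
        panel = np.array([[1, 0, 1], [0, 1, 1]], dtype=np.int8)
        q = np.array([1, -1, 1], dtype=np.int8)
        params = HmmParams(panel, rho=rho, eps=eps)
        dos = impute_dosage(q, params)
        oracle = enumerate_dosage(panel, q, rho, eps)
        assert np.allclose(dos, oracle, atol=1e-12)

    def test_enumeration_with_missing_panel_and_larger_state_space(self, rng):
        panel = np.array([[1, 0, -1, 1], [0, 1, 1, 0], [1, 1, 0, 0]],
                         dtype=np.int8)
        q = np.array([1, -1, 1, -1], dtype=np.int8)
        params = HmmParams(panel, rho=0.3, eps=0.02)
        dos = impute_dosage(q, params)
        oracle = enumerate_dosage(panel, q, 0.3, 0.02)
        assert np.allclose(dos, oracle, atol=1e-12)

    def test_dosage_calibration(self):
        """Among masked sites binned by imputed dosage, the empirical
        alt-allele frequency tracks the bin midpoint."""
        cfg = SimConfig(n_trios=60, n_sites=1500, seed=31)
        rng = np.random.default_rng(31)
        panel = simulate_panel(cfg, rng)
        t = simulate_trios(panel, cfg, rng)
        hmm = LiStephensHMM(HmmParams(panel.haplotypes, rho=0.005, eps=0.001))
        mask_rng = np.random.default_rng(99)
        queries, truths, masks = [], [], []
        for i in range(30):
            q = t.truth.child_pat[i].copy()
            m = mask_rng.random(cfg.n_sites) < 0.1
            q[m] = MISSING
            queries.append(q)
            truths.append(t.truth.child_pat[i])
            masks.append(m)
        dos = hmm.posterior_dosages(np.stack(queries))
        d = np.concatenate([dos[i][m] for i, m in enumerate(masks)])
        a = np.concatenate([truths[i][m] for i, m in enumerate(masks)])
        for lo in np.arange(0.0, 1.0, 0.2):
            sel = (d >= lo) & (d < lo + 0.2)
            if sel.sum() < 50:
                continue
            mid = d[sel].mean()
            freq = a[sel].mean()
            se = np.sqrt(mid * (1 - mid) / sel.sum()) + 1e-3
            assert abs(freq - mid) < 5 * se + 0.05


class TestResolve:
    def _phased(self, n=4):
        return mendelian_phase(np.array([1, 0, 1, 1]), np.array([1, 2, 1, 1]),
                               np.array([1, 1, 1, 1]))

    def test_larger_dosage_gets_alt_allele(self):
        ph = mendelian_phase(np.array([1]), np.array([1]), np.array([1]))
        out = resolve_triple_het(ph, np.array([0.9]), np.array([0.2]))
        assert (out.h_pat[0], out.h_mat[0]) == (1, 0)
        out = resolve_triple_het(ph, np.array([0.3]), np.array([0.8]))
        assert (out.h_pat[0], out.h_mat[0]) == (0, 1)
        assert out.resolved_by[0] == IMPUTED

    def test_tie_broken_reproducibly_by_seed(self):
        ph = mendelian_phase(np.array([1] * 50), np.array([1] * 50),
                             np.array([1] * 50))
        d = np.full(50, 0.5)
        a = resolve_triple_het(ph, d, d, rng=np.random.default_rng(7))
        b = resolve_triple_het(ph, d, d, rng=np.random.default_rng(7))
        assert np.array_equal(a.h_pat, b.h_pat)
        assert a.h_pat.min() >= 0  # complete
        assert 0 < a.h_pat.mean() < 1  # both outcomes occur

    def test_never_alters_mendelian_sites_and_completes(self):
        gf = np.array([0, 1, 1]); gm = np.array([2, 1, 0])
        gc = np.array([1, 1, 1])
        ph = mendelian_phase(gf, gm, gc)
        out = resolve_triple_het(ph, np.array([0.1, 0.9, 0.4]),
                                 np.array([0.7, 0.3, 0.6]))
        assert (out.h_pat[0], out.h_mat[0]) == (0, 1)  # untouched rule site
        assert (out.h_pat != MISSING).all() and (out.h_mat != MISSING).all()
        assert out.h_pat[1] == 1 and out.h_mat[1] == 0


class TestErrorRate:
    def test_exact_and_swapped(self):
        truth = np.array([1, 0, 1, 0])
        mask = np.array([True, True, False, True])
        assert phasing_error_rate(truth, truth.copy(), mask) == 0.0
        sw = truth.copy()
        sw[mask] = 1 - sw[mask]
        assert phasing_error_rate(truth, sw, mask) == 1.0

    def test_undefined_without_triple_het_sites(self):
        truth = np.array([1, 0])
        assert phasing_error_rate(truth, truth, np.zeros(2, bool)) is None

    def test_full_simulation_meets_accuracy_bound(self):
        """Mask-and-impute phasing errs at most once per 200 triple-het
        sites on LD-structured trios (moderate problem size)."""
        cfg = SimConfig(n_trios=60, n_sites=2000, seed=17)
        rng = np.random.default_rng(17)
        panel = simulate_panel(cfg, rng)
        t = simulate_trios(panel, cfg, rng)
        phased = phase_trio_dataset(t.g_father, t.g_mother, t.g_child,
                                    seed=1)
        errs = tot = 0
        for i, p in enumerate(phased):
            m = mendelian_phase(t.g_father[i], t.g_mother[i], t.g_child[i])
            triple = m.resolved_by == UNRESOLVED
            tot += int(triple.sum())
            errs += int((p.h_pat[triple]
                         != t.truth.child_pat[i][triple]).sum())
        assert tot > 500
        assert errs / tot <= 1.0 / 200.0
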