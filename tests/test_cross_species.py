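"""Ortholog mapping, Jaccard overlap with permutation null, perturbation
regression and module concordance."""

import numpy as np
import pandas as pd
import pytest

from crossmod.cross_species import (
    fit_perturbation_model,
    jaccard,
    map_orthologs,
    module_concordance,
    overlap_table,
    permutation_overlap_test,
)
from crossmod.data_io import HumanLFCTable, OrthologMap
from crossmod.preprocessing import log_transform
from crossmod.synthetic import (
    DesignConfig,
    generate_design,
    generate_human_reference,
    generate_mouse_expression,
)

from conftest import make_expression, make_metadata

RNG = np.random.default_rng(99)


def omap_of(pairs):
    return OrthologMap(pd.DataFrame(pairs, columns=["mouse", "human"]))


IDENTITY_MAP = omap_of([(f"m{i}", f"h{i}") for i in range(100)])


class TestJaccard:
    def test_anchor_values(self):
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == 0.5
        assert jaccard({"A"}, {"A"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0
        assert jaccard(set(), set()) == 0.0  # empty-union convention

    def test_matches_brute_force_oracle(self):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(1000):
            a = set(RNG.choice(universe, size=RNG.integers(0, 20), replace=False))
            b = set(RNG.choice(universe, size=RNG.integers(0, 20), replace=False))
            inter = sum(1 for x in a if x in b)
            union = len(a) + len(b) - inter
            expected = inter / union if union else 0.0
            assert jaccard(a, b) == expected


class TestMapOrthologs:
    def test_policies_agree_on_bijection(self):
        genes = [f"m{i}" for i in range(10)]
        a = map_orthologs(genes, IDENTITY_MAP, "all_pairs")
        b = map_orthologs(genes, IDENTITY_MAP, "one_to_one")
        assert sorted(map(tuple, a.to_numpy())) == sorted(map(tuple, b.to_numpy()))

    def test_one_to_many_policies_differ(self):
        omap = omap_of([("m0", "h0"), ("m0", "h0b"), ("m1", "h1")])
        ap = map_orthologs(["m0", "m1"], omap, "all_pairs")
        oo = map_orthologs(["m0", "m1"], omap, "one_to_one")
        assert len(ap) == 3
        assert oo["mouse"].tolist() == ["m1"]

    def test_round_trip_identity_on_retained(self):
        omap = omap_of([("m0", "h0"), ("m1", "h1"), ("m2", "h2"), ("m2", "h2b")])
        oo = map_orthologs(["m0", "m1", "m2"], omap, "one_to_one")
        back = {h: m for m, h in zip(oo["mouse"], oo["human"])}
        for m, h in zip(oo["mouse"], oo["human"]):
            assert back[h] == m

    def test_nothing_mapped_is_error(self):
        with pytest.raises(ValueError, match="no mouse genes"):
            map_orthologs(["absent"], IDENTITY_MAP)


class TestPermutationOverlap:
    UNIVERSE = [f"m{i}" for i in range(100)]

    def test_disjoint_human_module_p_one(self):
        res = permutation_overlap_test(
            self.UNIVERSE[:10], {"unrelated"}, self.UNIVERSE, IDENTITY_MAP,
            n_perm=200, seed=0,
        )
        assert res.jaccard == 0.0
        assert res.p == 1.0

    def test_module_equals_universe_p_one(self):
        human = {f"h{i}" for i in range(100)}
        res = permutation_overlap_test(
            self.UNIVERSE, human, self.UNIVERSE, IDENTITY_MAP,
            n_perm=100, seed=0,
        )
        assert res.p == 1.0

    def test_planted_overlap_hits_floor(self):
        """Module built from the human module's orthologs, universe 20x the
        module size: no null draw reaches J_obs, p = 1/(n_perm+1)."""
        universe = [f"m{i}" for i in range(1000)]
        omap = omap_of([(f"m{i}", f"h{i}") for i in range(1000)])
        module = universe[:50]
        human = {f"h{i}" for i in range(50)}
        res = permutation_overlap_test(module, human, universe, omap,
                                       n_perm=1000, seed=1)
        assert res.jaccard == 1.0
        assert res.p == pytest.approx(1 / 1001)

    def test_seed_deterministic_and_order_invariant(self):
        human = {f"h{i}" for i in range(5, 25)}
        a = permutation_overlap_test(self.UNIVERSE[:10], human, self.UNIVERSE,
                                     IDENTITY_MAP, n_perm=300, seed=7)
        shuffled = list(RNG.permutation(self.UNIVERSE))
        b = permutation_overlap_test(self.UNIVERSE[:10], human, shuffled,
                                     IDENTITY_MAP, n_perm=300, seed=7)
        assert a.p == b.p and a.jaccard == b.jaccard

    def test_module_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            permutation_overlap_test(["x"], {"h"}, self.UNIVERSE, IDENTITY_MAP)

    def test_overlap_table_applies_bh(self):
        modules = {"a": self.UNIVERSE[:20], "b": self.UNIVERSE[20:50]}
        catalog = {"h1": {f"h{i}" for i in range(20)},
                   "h2": {f"h{i}" for i in range(50, 60)}}
        table = overlap_table(modules, catalog, IDENTITY_MAP, n_perm=200, seed=3)
        assert len(table) == 4
        assert (table["padj"] >= table["p"] - 1e-15).all()


class TestPerturbationModel:
    def test_noise_free_closed_form(self):
        # one-hot design: beta = strain mean minus control mean
        values = np.array([[1.0, 1.0, 2.0, 2.0, 0.5, 0.5]])
        expr = make_expression(values, samples=[f"s{j}" for j in range(6)])
        meta = make_metadata(["B6", "B6", "KO", "KO", "OE", "OE"],
                             samples=expr.samples)
        eff = fit_perturbation_model(expr, meta)
        assert eff.betas.loc["g0", "KO"] == pytest.approx(1.0)
        assert eff.betas.loc["g0", "OE"] == pytest.approx(-0.5)
        assert eff.intercept["g0"] == pytest.approx(1.0)

    def test_constant_gene_all_zero(self):
        values = np.full((2, 6), 3.0)
        expr = make_expression(values)
        meta = make_metadata(["B6"] * 3 + ["KO"] * 3, samples=expr.samples)
        eff = fit_perturbation_model(expr, meta)
        assert np.allclose(eff.betas.to_numpy(), 0.0, atol=1e-12)

    def test_rank_deficient_design_named(self):
        values = RNG.normal(size=(3, 6))
        expr = make_expression(values)
        meta = make_metadata(
            ["B6"] * 3 + ["KO"] * 3,
            batches=["b1"] * 3 + ["b2"] * 3,  # batch == strain indicator
            samples=expr.samples,
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_perturbation_model(expr, meta, with_batch=True)

    def test_planted_effects_recovered(self):
        """MAE of per-gene beta estimates < 0.15 at sigma=0.3, n=6 (pooled
        over planted genes from 3 seeds; per-seed MAE at 100 genes has
        sampling noise comparable to the bound's headroom)."""
        errors = []
        for seed in range(3):
            cfg = DesignConfig(
                replicates={"strainA": 6, "B6": 6},
                batch_plan=None,
                module_sizes=(),
                n_background=2000,
                noise_sd=0.3,
                n_de_per_strain=100,
                de_lfc_range=(1.0, 1.0),
            )
            design = generate_design(cfg, seed)
            tpm, _, truth = generate_mouse_expression(design, cfg, 50 + seed)
            eff = fit_perturbation_model(log_transform(tpm), design)
            planted = truth.beta_true.to_numpy()
            est = eff.betas.loc[truth.beta_true.index,
                                truth.beta_true.columns].to_numpy()
            mask = planted != 0
            errors.append(np.abs(est[mask] - planted[mask]))
        assert np.concatenate(errors).mean() < 0.15


class TestModuleConcordance:
    @staticmethod
    def world(seed, r_matched=0.5, module=500, contamination=0.2):
        cfg = DesignConfig(
            replicates={"strainA": 6, "B6": 6},
            batch_plan=None,
            module_sizes=(module,),
            n_background=300,
            noise_sd=0.3,
            module_delta={("M1", "strainA"): 1.0},
            n_de_per_strain=0,
            r_matched=r_matched,
            contamination_frac=contamination,
        )
        design = generate_design(cfg, seed)
        tpm, _, truth = generate_mouse_expression(design, cfg, seed * 7 + 1)
        catalog, lfc, omap = generate_human_reference(truth, cfg, seed * 7 + 2)
        return design, tpm, truth, catalog, lfc, omap

    def test_planted_r_recovered(self):
        """r_target=0.5 on a 500-gene module: mean estimated r over 5 seeds
        within +-0.15 (finite-sample eigengene noise attenuates any single
        seed; the 10-seed version is an acceptance criterion)."""
        rs = []
        for seed in (0, 1, 2, 3, 4):
            design, tpm, truth, catalog, lfc, omap = self.world(seed)
            eff = fit_perturbation_model(log_transform(tpm), design)
            res = module_concordance(eff, lfc, catalog.sets["hs_M1"], omap,
                                     "strainA", human_name="hs_M1")
            rs.append(res.r)
            assert res.n >= 300
        assert np.mean(rs) == pytest.approx(0.5, abs=0.15)

    def test_too_few_genes_untestable(self):
        design, tpm, truth, catalog, lfc, omap = self.world(3)
        eff = fit_perturbation_model(log_transform(tpm), design)
        res = module_concordance(eff, lfc, {"HMGENE00000"}, omap, "strainA")
        assert res.untestable and np.isnan(res.r)

    def test_degenerate_beta_untestable(self):
        values = np.tile([[1.0, 1.0, 2.0, 2.0, 2.0, 2.0]], (5, 1))
        expr = make_expression(values, genes=[f"m{i}" for i in range(5)])
        meta = make_metadata(["B6", "B6"] + ["KO"] * 4, samples=expr.samples)
        eff = fit_perturbation_model(expr, meta)
        lfc = HumanLFCTable(
            pd.DataFrame({"TCX": RNG.normal(size=5)},
                         index=[f"h{i}" for i in range(5)])
        )
        res = module_concordance(eff, lfc, {f"h{i}" for i in range(5)},
                                 IDENTITY_MAP, "KO")
        assert res.untestable  # all betas identical -> zero variance

    def test_sign_coherence(self):
        """Negating every fitted beta flips the estimated r exactly."""
        design, tpm, truth, catalog, lfc, omap = self.world(4)
        eff = fit_perturbation_model(log_transform(tpm), design)
        res = module_concordance(eff, lfc, catalog.sets["hs_M1"], omap,
                                 "strainA")
        eff.betas = -eff.betas
        flipped = module_concordance(eff, lfc, catalog.sets["hs_M1"], omap,
                                     "strainA")
        assert flipped.r == pytest.approx(-res.r, abs=1e-12)
        assert flipped.p == pytest.approx(res.p, abs=1e-12)
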