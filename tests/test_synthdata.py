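"""Synthetic-study generator: determinism, planted effects, PPI, file round trips."""

import dataclasses

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from sibnet.filters import qualifying_variants
from sibnet.genesets import read_gmt
from sibnet.synthdata import (
    GeneSetParams,
    PPIParams,
    SimulationConfig,
    read_study,
    simulate_gene_sets,
    simulate_ppi,
    simulate_study,
    write_study,
)


class TestConfigValidation:
    def test_rejects_bad_rates_and_counts(self):
        with pytest.raises(ValueError):
            SimulationConfig(lambda_background=-1)
        with pytest.raises(ValueError):
            SimulationConfig(lambda_effect=float("nan"))
        with pytest.raises(ValueError):
            SimulationConfig(n_pairs_large=0, n_pairs_small=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_risk_genes=10, n_genes=5)
        with pytest.raises(ValueError):
            SimulationConfig(shared_fraction=1.5)

    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValueError):
            PPIParams(p_in=1.2)
        with pytest.raises(ValueError):
            GeneSetParams(risk_overlap=-0.1)


class TestSimulateStudy:
    def test_seed_determinism(self, small_config, small_study):
        again = simulate_study(small_config)
        assert again.variants.equals(small_study.variants)
        assert again.genotypes == small_study.genotypes
        assert again.phenotypes.equals(small_study.phenotypes)
        assert sorted(again.ppi.edges) == sorted(small_study.ppi.edges)

    def test_strata_respect_score_thresholds(self, small_study):
        scores = dict(zip(small_study.phenotypes["sample_id"], small_study.phenotypes["soct_cs"]))
        for row in small_study.pairs.itertuples(index=False):
            delta = abs(scores[row.sib_a] - scores[row.sib_b])
            stratum = small_study.truth.stratum_of[row.family_id]
            assert (delta >= 10) if stratum == "large" else (delta <= 4)

    def test_scores_within_instrument_range(self, small_study):
        assert small_study.phenotypes["soct_cs"].between(0, 30).all()

    def test_truth_effect_counts_match_realized_genotypes(self, small_study):
        """Planted severe-only counts in the truth equal what the matrix contains."""
        truth = small_study.truth
        per_sib = truth.per_sib.set_index("sample_id")
        gm = small_study.genotypes
        keys = np.asarray(gm.variant_keys, dtype=object)
        effect_rows = np.isin(keys, list(truth.effect_keys))
        for row in small_study.pairs.itertuples(index=False):
            for sib, other in ((row.sib_a, row.sib_b), (row.sib_b, row.sib_a)):
                carried = gm.sample_column(sib) >= 1
                n_eff = int((carried & effect_rows).sum())
                assert n_eff == per_sib.loc[sib, "n_effect"]
                if n_eff:  # planted effect variants are absent in the co-sib
                    other_carried = gm.sample_column(other) >= 1
                    assert not (carried & effect_rows & other_carried).any()

    def test_null_effect_balances_strata(self):
        cfg = SimulationConfig(
            n_pairs_large=40,
            n_pairs_small=40,
            n_genes=120,
            n_risk_genes=20,
            lambda_background=40.0,
            lambda_effect=0.0,
            seed=5,
        )
        study = simulate_study(cfg)
        per_sib = study.truth.per_sib.set_index("sample_id")
        strata = {"large": [], "small": []}
        for row in study.pairs.itertuples(index=False):
            stratum = study.truth.stratum_of[row.family_id]
            strata[stratum].extend(
                per_sib.loc[[row.sib_a, row.sib_b], "n_background"].tolist()
            )
        t, p = stats.ttest_ind(strata["large"], strata["small"])
        assert p > 0.01  # no planted difference

    def test_poisson_mean_additivity(self):
        """Severe sibs in large-Δ pairs carry λ_bg + λ_effect variants on average."""
        cfg = SimulationConfig(
            n_pairs_large=250,
            n_pairs_small=2,
            n_genes=400,
            n_risk_genes=40,
            lambda_background=700.0,
            lambda_effect=37.0,
            seed=17,
        )
        study = simulate_study(cfg)
        per_sib = study.truth.per_sib.set_index("sample_id")
        severe_totals = []
        scores = dict(zip(study.phenotypes["sample_id"], study.phenotypes["soct_cs"]))
        for row in study.pairs.itertuples(index=False):
            if study.truth.stratum_of[row.family_id] != "large":
                continue
            severe = row.sib_a if scores[row.sib_a] >= scores[row.sib_b] else row.sib_b
            severe_totals.append(
                per_sib.loc[severe, "n_background"] + per_sib.loc[severe, "n_effect"]
            )
        severe_totals = np.asarray(severe_totals, dtype=float)
        se = severe_totals.std(ddof=1) / np.sqrt(len(severe_totals))
        assert abs(severe_totals.mean() - 737.0) < 3 * se


class TestSimulatePPI:
    def test_disconnected_cliques(self):
        cfg = SimulationConfig(
            n_genes=10,
            n_risk_genes=5,
            ppi_params=PPIParams(n_modules=2, p_in=1.0, p_out=0.0),
            seed=3,
        )
        g = simulate_ppi(cfg)
        comps = [sorted(c) for c in nx.connected_components(g)]
        assert len(comps) == 2
        assert all(len(c) == 5 for c in comps)
        for c in comps:
            assert g.subgraph(c).number_of_edges() == 10  # 5-clique

    def test_no_self_loops_simple(self):
        cfg = SimulationConfig(n_genes=60, n_risk_genes=10, seed=4)
        g = simulate_ppi(cfg)
        assert not list(nx.selfloop_edges(g))
        assert not g.is_directed() and not g.is_multigraph()

    def test_risk_genes_in_module_zero(self):
        cfg = SimulationConfig(n_genes=80, n_risk_genes=15, seed=4)
        g = simulate_ppi(cfg)
        module_of = nx.get_node_attributes(g, "module")
        study_risk = simulate_study(
            dataclasses.replace(cfg, lambda_background=1.0, lambda_effect=0.0)
        ).truth.risk_genes
        assert all(module_of[g_] == 0 for g_ in study_risk)

    def test_edge_count_within_binomial_bounds(self):
        # two modules of 25: E = 2*C(25,2)*p_in + 625*p_out, check 99% bounds
        cfg = SimulationConfig(
            n_genes=50,
            n_risk_genes=25,
            ppi_params=PPIParams(n_modules=2, p_in=0.8, p_out=0.05),
            seed=6,
        )
        g = simulate_ppi(cfg)
        n_within, n_between = 2 * 300, 625
        mean = n_within * 0.8 + n_between * 0.05
        var = n_within * 0.8 * 0.2 + n_between * 0.05 * 0.95
        assert abs(g.number_of_edges() - mean) < 2.58 * np.sqrt(var)

    def test_uniform_density_when_p_equal(self):
        # degenerate negative control: p_in = p_out gives an Erdős–Rényi graph
        cfg = SimulationConfig(
            n_genes=60,
            n_risk_genes=10,
            ppi_params=PPIParams(n_modules=3, p_in=0.1, p_out=0.1),
            seed=8,
        )
        g = simulate_ppi(cfg)
        mean, var = 1770 * 0.1, 1770 * 0.1 * 0.9
        assert abs(g.number_of_edges() - mean) < 3 * np.sqrt(var)


class TestSimulateGeneSets:
    def test_full_overlap_equals_risk_module(self):
        cfg = SimulationConfig(
            n_genes=60,
            n_risk_genes=12,
            geneset_params=GeneSetParams(n_sets=5, risk_overlap=1.0),
            seed=9,
        )
        ppi = simulate_ppi(cfg)
        module0 = {g for g, m in nx.get_node_attributes(ppi, "module").items() if m == 0}
        sets = simulate_gene_sets(cfg, ppi)
        assert sets["SET_RISK_MODULE"] == module0

    def test_zero_overlap_disjoint_from_module(self):
        cfg = SimulationConfig(
            n_genes=60,
            n_risk_genes=12,
            geneset_params=GeneSetParams(n_sets=5, risk_overlap=0.0),
            seed=9,
        )
        ppi = simulate_ppi(cfg)
        module0 = {g for g, m in nx.get_node_attributes(ppi, "module").items() if m == 0}
        sets = simulate_gene_sets(cfg, ppi)
        assert not (sets["SET_RISK_MODULE"] & module0)

    def test_sizes_and_membership(self):
        cfg = SimulationConfig(
            n_genes=200,
            n_risk_genes=20,
            geneset_params=GeneSetParams(n_sets=50, size_min=10, size_max=50),
            seed=10,
        )
        ppi = simulate_ppi(cfg)
        sets = simulate_gene_sets(cfg, ppi)
        assert len(sets) == 50
        genes = set(ppi.nodes)
        for name in sets.names():
            if name != "SET_RISK_MODULE":
                assert 10 <= len(sets[name]) <= 50
            assert sets[name] <= genes


class TestWriteReadStudy:
    def test_round_trip_identity(self, small_study, tmp_path):
        write_study(small_study, tmp_path)
        loaded = read_study(tmp_path)
        assert loaded.genotypes == small_study.genotypes
        assert list(loaded.phenotypes["soct_cs"]) == list(small_study.phenotypes["soct_cs"])
        assert sorted(map(tuple, map(sorted, loaded.ppi.edges))) == sorted(
            map(tuple, map(sorted, small_study.ppi.edges))
        )
        assert loaded.truth.qualifying_keys == small_study.truth.qualifying_keys
        assert {n: m for n, m in loaded.gene_sets} == {n: m for n, m in small_study.gene_sets}
        for col in ("sift_damage", "af_espEA", "af_1kgALL"):
            assert np.allclose(
                loaded.variants[col], small_study.variants[col], equal_nan=True, atol=1e-6
            )

    def test_sidecar_dialect_round_trip(self, small_study, tmp_path):
        write_study(small_study, tmp_path, annotation="sidecar")
        loaded = read_study(tmp_path)
        assert list(loaded.variants["gene"]) == list(small_study.variants["gene"])
        assert loaded.genotypes == small_study.genotypes

    def test_refuses_overwrite(self, small_study, tmp_path):
        write_study(small_study, tmp_path)
        with pytest.raises(FileExistsError):
            write_study(small_study, tmp_path)
        write_study(small_study, tmp_path, overwrite=True)

    def test_written_files_byte_identical_across_runs(self, small_config, tmp_path):
        m1 = write_study(simulate_study(small_config), tmp_path / "a")
        m2 = write_study(simulate_study(small_config), tmp_path / "b")
        assert {k: v["sha256"] for k, v in m1.items()} == {
            k: v["sha256"] for k, v in m2.items()
        }

    def test_vcf_sample_count_two_per_pair(self, tmp_path):
        cfg = SimulationConfig(
            n_pairs_large=4,
            n_pairs_small=6,
            n_genes=40,
            n_risk_genes=8,
            lambda_background=5.0,
            lambda_effect=1.0,
            seed=12,
        )
        study = simulate_study(cfg)
        write_study(study, tmp_path)
        loaded = read_study(tmp_path)
        assert len(loaded.genotypes.samples) == 20

    def test_qualifying_filter_survives_round_trip(self, small_study, tmp_path):
        """Filter results are identical on the in-memory and re-read study."""
        write_study(small_study, tmp_path)
        loaded = read_study(tmp_path)
        q1, e1, _ = qualifying_variants(small_study.variants, small_study.genotypes)
        q2, e2, _ = qualifying_variants(loaded.variants, loaded.genotypes)
        assert list(q1["key"]) == list(q2["key"])
        assert e1 == e2

    def test_gmt_parses_with_reader(self, small_study, tmp_path):
        write_study(small_study, tmp_path)
        coll = read_gmt(tmp_path / "gene_sets.gmt")
        assert len(coll) == len(small_study.gene_sets)
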