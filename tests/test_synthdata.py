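"""Ground-truth plumbing: determinism, planted effects, oracle recounts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ahrcore import (
    SimulationConfig,
    StudyDesign,
    generate_all,
    generate_binding_probes,
    generate_go_dag,
    generate_homology_map,
    generate_promoters,
    generate_study,
    make_ground_truth,
)
from ahrcore.synthdata import (
    ConfigurationError,
    gene_id,
    tss_table,
    write_all,
)


def cfg(**kw) -> SimulationConfig:
    base = dict(n_genes=300, battery_size=6, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_battery_larger_than_genome_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(n_genes=5, battery_size=6)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(studies=(StudyDesign("rat", "liver", 1, 4),))

    def test_odd_promoter_length_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(promoter_length=5999)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            cfg(homology_mapped_fraction=1.2)


class TestDeterminism:
    def test_identical_config_reproduces_identical_artifacts(self, tmp_path):
        c = cfg(n_genes=120, battery_size=4)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        write_all(generate_all(c), d1)
        write_all(generate_all(c), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel

    def test_different_seeds_differ(self):
        s1 = generate_study(cfg(seed=1), 0)
        s2 = generate_study(cfg(seed=2), 0)
        assert not np.allclose(s1.matrix, s2.matrix)


class TestGenerateStudy:
    def test_null_config_mean_differences_within_noise(self):
        c = cfg(n_genes=2000, battery_size=0, effect_size_log2=0.0,
                noise_sd_log2=0.5, seed=7)
        study = generate_study(c, 0)
        fitsA = study.matrix[:, study.group_columns("active")]
        fitsB = study.matrix[:, study.group_columns("less_active")]
        diff = fitsB.mean(axis=1) - fitsA.mean(axis=1)
        n = 4
        bound = 4 * 0.5 / np.sqrt(n)
        assert (np.abs(diff) > bound).mean() < 0.01

    def test_noiseless_battery_effect_exact(self):
        c = cfg(n_genes=50, battery_size=1, effect_size_log2=1.0,
                noise_sd_log2=0.0, species_flip_fraction=0.0)
        truth = make_ground_truth(c)
        study = generate_study(c, 0, truth)
        gene = next(iter(truth.battery_genes))
        row = study.gene_ids.index(f"{study.species}_{gene}")
        xa = study.matrix[row, study.group_columns("active")]
        xb = study.matrix[row, study.group_columns("less_active")]
        assert xb.mean() - xa.mean() == pytest.approx(1.0)

    def test_battery_mean_shift_matches_oracle_resimulation(self):
        """Planted effect recovered within 3 SE, and an independent sampler
        with the same seed discipline reproduces the matrix exactly."""
        c = SimulationConfig(n_genes=2000, battery_size=20, effect_size_log2=1.0,
                             noise_sd_log2=0.5, species_flip_fraction=0.0, seed=7)
        truth = make_ground_truth(c)
        study = generate_study(c, 0, truth)
        rows = [study.gene_ids.index(f"{study.species}_{g}")
                for g in sorted(truth.battery_genes)]
        xa = study.matrix[np.ix_(rows, study.group_columns("active"))]
        xb = study.matrix[np.ix_(rows, study.group_columns("less_active"))]
        diffs = xb.mean(axis=1) - xa.mean(axis=1)
        se = 0.5 * np.sqrt(2 / 4) / np.sqrt(len(rows))
        assert abs(diffs.mean() - 1.0) < 3 * se
        # independent re-simulation with the documented stream discipline
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=7, spawn_key=(0, 0))
        )
        baseline = rng.normal(8.0, 2.0, size=2000)
        effect = np.zeros(2000)
        for g, per in truth.battery_effects.items():
            effect[int(g[1:]) - 1] = per[0]
        noise = rng.normal(0.0, 0.5, size=(2000, 8))
        expected = baseline[:, None] + noise
        expected[:, 4:] += effect[:, None]
        assert np.array_equal(study.matrix, expected)

    def test_species_flip_recorded_consistently(self):
        c = cfg(battery_size=30, species_flip_fraction=1.0)
        truth = make_ground_truth(c)
        species_of = [d.species for d in c.studies]
        for gene, per in truth.battery_effects.items():
            for idx, eff in per.items():
                want = c.effect_size_log2 if species_of[idx] == "mouse" else -c.effect_size_log2
                # first species keeps +, all-flip config negates the second
                if species_of[idx] == species_of[0]:
                    assert eff == c.effect_size_log2
                else:
                    assert eff == -c.effect_size_log2

    def test_bad_study_index_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_study(cfg(), 99)


class TestHomologyGeneration:
    def test_fully_mapped_no_duplicates_universe_is_everything(self):
        c = cfg(homology_mapped_fraction=1.0, homology_duplicate_fraction=0.0)
        hmap = generate_homology_map(c)
        from ahrcore import clean_map

        cleaned = clean_map(hmap)
        for species, hids in cleaned.hid_sets().items():
            assert len(hids) == c.n_genes

    def test_nothing_mapped_empty_universe(self):
        c = cfg(homology_mapped_fraction=0.0)
        hmap = generate_homology_map(c)
        assert hmap.records["hid"].notna().sum() == 0

    def test_survivor_count_matches_recount_oracle(self):
        c = SimulationConfig(n_genes=1000, battery_size=10, seed=3,
                             homology_mapped_fraction=0.9,
                             homology_duplicate_fraction=0.05)
        hmap = generate_homology_map(c)
        from ahrcore import clean_map

        cleaned = clean_map(hmap)
        # oracle: dict-based recount of the emitted table after removal rules
        for species in ("mouse", "rat"):
            rows = [
                (r.gene_id, r.hid)
                for r in hmap.records.itertuples()
                if r.species == species and pd.notna(r.hid)
            ]
            seen: dict[int, int] = {}
            for _, hid in rows:
                seen[int(hid)] = seen.get(int(hid), 0) + 1
            survivors = {g for g, h in rows if seen[int(h)] == 1}
            got = set(
                cleaned.records.loc[
                    cleaned.records["species"] == species, "gene_id"
                ]
            )
            assert got == survivors


class TestPromoterGeneration:
    def test_alphabet_and_window(self, small_data):
        seqs = small_data.promoters.sequences
        assert all(set(s) <= set("ACGT") for s in list(seqs.values())[:10])
        assert all(len(s) == 6000 for s in seqs.values())

    def test_no_g_alphabet_means_no_core_hits(self):
        """Forward AHRE-I core needs a G; a G-free sequence cannot match."""
        from ahrcore import compile_motif

        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACT"), size=500))
        core = compile_motif("GCGTG", "AHRE-I_core")
        assert not any(core.matches(seq, i) for i in range(len(seq) - 4))

    def test_planted_offset_outside_window_errors(self):
        c = cfg(n_genes=10, battery_size=0)
        truth = make_ground_truth(c)
        truth.planted_motifs[gene_id(0)] = [("AHRE-I_core", 3001, "+")]
        with pytest.raises(ConfigurationError):
            generate_promoters(c, truth)

    def test_conservation_in_unit_interval(self, small_data):
        for track in small_data.promoters.conservation.values():
            assert track.min() >= 0.0 and track.max() <= 1.0


class TestBindingGeneration:
    def test_probe_coordinates_near_tss(self):
        c = cfg(n_genes=40)
        probes = generate_binding_probes(c)
        tss = tss_table(c).set_index("gene")
        for r in probes.itertuples():
            gene = r.probe_id.rsplit("_p", 1)[0]
            center = (tss.loc[gene, "start"] + tss.loc[gene, "end"]) // 2
            assert abs((r.start + r.end) // 2 - center) <= 1000

    def test_min_p_matches_independent_t_test(self):
        c = SimulationConfig(n_genes=500, battery_size=5, seed=5,
                             binding_shift_log2=1.0, binding_sd_log2=1.0,
                             n_binding_replicates=3)
        probes = generate_binding_probes(c)
        from ahrcore import gene_binding_summary

        summary = gene_binding_summary(probes, tss_table(c))
        reps = [f"rep{i}" for i in (1, 2, 3)]
        oracle: dict[str, float] = {}
        for r in probes.itertuples():
            gene = r.probe_id.rsplit("_p", 1)[0]
            x = np.array([getattr(r, c_) for c_ in reps])
            p = stats.ttest_1samp(x, 0.0, alternative="greater").pvalue
            oracle[gene] = min(oracle.get(gene, 1.0), float(p))
        genes = sorted(oracle)
        assert summary.gene_p.loc[genes].to_numpy() == pytest.approx(
            [oracle[g] for g in genes]
        )

    def test_null_binding_fraction_near_test_size(self):
        c = SimulationConfig(n_genes=1000, battery_size=0, seed=9,
                             bound_background_rate=0.0)
        truth = make_ground_truth(c)
        assert not truth.bound_genes
        probes = generate_binding_probes(c, truth)
        from ahrcore import binding_fraction, gene_binding_summary

        summary = gene_binding_summary(probes, tss_table(c))
        frac = binding_fraction(set(summary.gene_p.index), summary)
        # min-p collapse over ~2.5 probes/gene inflates the per-gene rate
        # above 0.05; it must stay within the union bound of the probe count
        assert 0.01 < frac < 0.15

    def test_strong_separation_binds_all_bound_genes(self):
        c = cfg(n_genes=200, battery_size=10, binding_shift_log2=10.0,
                binding_sd_log2=1.0)
        truth = make_ground_truth(c)
        probes = generate_binding_probes(c, truth)
        from ahrcore import binding_fraction, gene_binding_summary

        summary = gene_binding_summary(probes, tss_table(c))
        bound = truth.bound_genes & set(summary.gene_p.index)
        assert binding_fraction(bound, summary) == pytest.approx(1.0, abs=0.02)


class TestDagGeneration:
    def test_structure_rooted_with_diamonds(self):
        dag = generate_go_dag(cfg(n_go_terms=40, seed=2))
        assert len(dag.roots) == 1
        multi_parent = [t for t in dag.terms if len(dag.parents(t)) >= 2]
        assert multi_parent
        # >= 3 levels below the root
        import networkx as nx

        root = next(iter(dag.roots))
        depth = max(
            len(p) for t in dag.terms
            for p in nx.all_simple_paths(dag.graph, t, root)
        )
        assert depth >= 4

    def test_ancestor_sets_match_reachability_oracle(self):
        dag = generate_go_dag(cfg(n_go_terms=40, seed=2))
        parent_of: dict[str, set[str]] = {t: set() for t in dag.terms}
        for child, parent in dag.edges:
            parent_of[child].add(parent)
        for term in dag.terms:
            # plain BFS transitive closure
            seen, frontier = set(), {term}
            while frontier:
                nxt = set()
                for t in frontier:
                    for p in parent_of[t]:
                        if p not in seen:
                            seen.add(p)
                            nxt.add(p)
                frontier = nxt
            assert dag.ancestors(term) == seen
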