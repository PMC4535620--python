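import numpy as np
import pandas as pd
import pytest

import serosom
from serosom import simulate_dataset, simulate_null, simulate_subtelomere, nb_counts
from serosom.simdata import SimConfig, ConditionSpec

from conftest import small_config


class TestConfigValidation:
    def test_module_exceeding_genome_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SimConfig(n_genes=100, module_sizes={s: 200 for s in "ABDH"})

    def test_unknown_program_rejected(self):
        with pytest.raises(ValueError, match="program"):
            ConditionSpec("X", 20, "A", program="frozen")

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            SimConfig(conditions=[
                ConditionSpec("A.31", 31, "A"),
                ConditionSpec("B.24", 24, "B", parent="nope", program="cold"),
            ])

    def test_overlapping_planted_sets_impossible(self, small_sim):
        # modules pairwise disjoint and disjoint from SAg/HSP genes
        _, truth, _, _ = small_sim
        seen: set[str] = set(truth.sag_genes) | set(truth.hsp_genes)
        for members in truth.module_members.values():
            assert not (seen & set(members))
            seen |= set(members)


class TestDataset:
    def test_determinism(self):
        cfg = small_config(seed=42)
        a = simulate_dataset(cfg)[0]
        b = simulate_dataset(small_config(seed=42))[0]
        assert a.counts.equals(b.counts) and a.lengths.equals(b.lengths)

    def test_design_shape(self, small_sim):
        cm, truth, _, _ = small_sim
        assert cm.counts.shape == (900, 21)
        assert cm.samples["condition"].nunique() == 7
        assert (cm.samples.groupby("condition").size() == 3).all()

    def test_mutual_exclusion(self, small_sim):
        # second-highest SAg mean <= 2% of the active SAg mean, per condition
        _, truth, _, _ = small_sim
        for cond in truth.condition_means.columns:
            sag_means = truth.condition_means.loc[truth.sag_genes, cond].sort_values()
            assert sag_means.iloc[-2] <= 0.02 * sag_means.iloc[-1]
            assert sag_means.idxmax() == truth.sag_active[cond]

    def test_active_sag_among_top_expressed(self, small_sim):
        _, truth, _, _ = small_sim
        for cond in ("A.31", "B.24", "D.24", "H.14"):
            col = truth.condition_means[cond]
            rank = (col > col[truth.sag_active[cond]]).sum()
            assert rank == 0

    def test_truth_consistency(self, small_sim):
        # recomputing log2 ratios of condition means reproduces de_flags exactly
        _, truth, _, _ = small_sim
        a, b = truth.condition_means["B.24"], truth.condition_means["D.24"]
        flags = truth.de_flags("B.24", "D.24")
        recomputed = np.where(a.to_numpy() == b.to_numpy(), 0.0, np.log2(a / b))
        assert np.array_equal(flags.to_numpy(), recomputed)
        assert ((flags != 0) == (a != b)).all()

    def test_zero_module_effect_gives_zero_flags(self):
        _, truth, _, _ = simulate_dataset(small_config(lfc_module=0.0))
        flags = truth.de_flags("B.24", "D.24")
        for members in truth.module_members.values():
            assert (flags.loc[members] == 0).all()

    def test_derived_conditions_leave_module_near_parent(self, small_sim):
        _, truth, _, _ = small_sim
        for parent, derived in [("B.24", "B.6"), ("D.24", "D.starv")]:
            sero = derived[0]
            flags = truth.de_flags(derived, parent).loc[truth.module_members[sero]]
            assert np.abs(flags).max() < 0.5

    def test_heatshock_decays_program_and_activates_hsps(self, small_sim):
        _, truth, _, _ = small_sim
        flags = truth.de_flags("D.HS", "D.24")
        assert (flags.loc[truth.hsp_genes] == 5.0).all()  # 32x activation
        assert flags.loc["SAG-51D"] < -3
        assert (flags.loc[truth.module_members["D"]] < -0.5).all()

    def test_mean_matrix_is_condition_mean_times_libsize(self, small_sim):
        cm, truth, _, _ = small_sim
        s = "D.24-2"
        cond = cm.samples.loc[s, "condition"]
        expected = truth.condition_means[cond] * truth.libsize_factors[s]
        assert np.allclose(truth.mean_matrix[s], expected)

    def test_heat_shock_intensity_modulates_replicates(self, small_sim):
        cm, truth, _, _ = small_sim
        for s in cm.condition_samples("D.HS"):
            lam = truth.hs_intensity[s]
            assert 0.75 <= lam <= 1.0
            expected_hsp = 200.0 * 32.0**lam * truth.libsize_factors[s]
            assert np.allclose(truth.mean_matrix.loc[truth.hsp_genes, s], expected_hsp)
        # stronger shock => more HSP induction and deeper SAg decay
        lams = truth.hs_intensity[cm.condition_samples("D.HS")]
        sag = truth.mean_matrix.loc["SAG-51D", lams.index] / truth.libsize_factors[lams.index]
        assert (sag[lams.sort_values().index].diff().dropna() < 0).all()


class TestNBCounts:
    def test_moment_check(self, rng):
        # Var within 5% of mu + alpha mu^2 over >= 1e4 draws
        mu, alpha, n = 50.0, 0.3, 40_000
        draws = nb_counts(np.full(n, mu), alpha, rng)
        expected = mu + alpha * mu**2
        assert abs(draws.var() / expected - 1) < 0.05
        assert abs(draws.mean() / mu - 1) < 0.05

    def test_poisson_limit(self, rng):
        draws = nb_counts(np.full(20_000, 30.0), 0.0, rng)
        assert abs(draws.var() / draws.mean() - 1) < 0.05

    def test_negative_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            nb_counts(np.array([-1.0]), 0.1, rng)


class TestNull:
    def test_exchangeable_groups(self):
        cm = simulate_null(5000, 3, 0.1, seed=0)
        a = cm.counts.iloc[:, :3].mean(axis=1)
        b = cm.counts.iloc[:, 3:].mean(axis=1)
        rel = (a - b) / (a + b + 1)
        assert abs(rel.mean()) < 0.01

    def test_determinism(self):
        assert simulate_null(50, 2, 0.1, seed=5).counts.equals(
            simulate_null(50, 2, 0.1, seed=5).counts
        )

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            simulate_null(0, 3, 0.1, seed=0)


class TestSubtelomere:
    def test_focal_rank_by_construction(self):
        smap, _, _ = simulate_subtelomere(n_scaffolds=1, focal_rank=2, k_upstream=5, seed=0)
        focal = [g for g in smap.scaffolds["sim_scaffold_1"].genes.index
                 if g.startswith("SAG")][0]
        _, rank = serosom.distance_to_telomere(smap, focal)
        assert rank == 2

    def test_no_spreading_gives_flat_profile(self):
        smap, expr, conds = simulate_subtelomere(spreading=False, noise_sd=0.0, seed=1)
        sc = next(iter(smap.scaffolds.values()))
        focal = [g for g in sc.genes.index if g.startswith("SAG")][0]
        prof = serosom.neighbour_profile(smap, expr, focal, 4, conds)
        down = prof.table[prof.table["downstream"]]
        on = down[[c for c in conds if c.startswith("ON")]].mean(axis=1)
        off = down[[c for c in conds if c.startswith("OFF")]].mean(axis=1)
        assert np.allclose(on, off, atol=1e-9)

    def test_spreading_matches_stated_decay_rule(self):
        # noise-free OFF profile drops by log10(1/decay) per step to telomere
        decay = 0.5
        smap, expr, conds = simulate_subtelomere(
            spreading=True, decay=decay, noise_sd=0.0, seed=2
        )
        sc = next(iter(smap.scaffolds.values()))
        focal = [g for g in sc.genes.index if g.startswith("SAG")][0]
        prof = serosom.neighbour_profile(smap, expr, focal, 4, conds)
        down = prof.table[prof.table["downstream"]].sort_values("rank_to_telomere")
        diff = (
            down[[c for c in conds if c.startswith("ON")]].mean(axis=1)
            - down[[c for c in conds if c.startswith("OFF")]].mean(axis=1)
        ).to_numpy()
        steps = 4 - down["rank_to_telomere"].to_numpy()
        assert np.allclose(diff, steps * np.log10(1 / decay), atol=1e-9)

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            simulate_subtelomere(focal_rank=8, k_upstream=3)


def test_write_dataset_roundtrip(tmp_path, small_sim):
    cm, truth, smap, go = small_sim
    paths = serosom.simdata.write_dataset(tmp_path, cm, truth, smap, go)
    samples = pd.read_csv(paths["samples"], sep="\t", index_col=0)
    back = serosom.CountMatrix.from_tsv(paths["counts"], samples)
    assert back.counts.equals(cm.counts)
    smap_back = serosom.SubtelomereMap.from_gff3(paths["annotation"])
    assert set(smap_back.scaffolds) == set(smap.scaffolds)
    sc, sc_back = smap.scaffolds["scaffold_A"], smap_back.scaffolds["scaffold_A"]
    assert sc_back.length == sc.length
    assert list(sc_back.genes.index) == list(sc.genes.index)
    assert sc_back.internal_sites == sc.internal_sites
    go_back = serosom.GODataset.from_files(paths["ontology"], paths["associations"])
    assert go_back.population == go.population
    some_gene = next(iter(go.annotations))
    assert go_back.annotations[some_gene] == go.annotations[some_gene]
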