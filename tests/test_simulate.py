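"""Synthetic-data generator: targets realized, determinism, contracts."""

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import random_unrooted_tree
from nitriscan.genome_io import write_genbank
from nitriscan.homology import local_align
from nitriscan.phylo import Msa, SubstitutionModel
from nitriscan.simulate import (ImplantSpec, InfeasibleSpec, SimSpec,
                                default_catalog, diverge_protein,
                                evolve_alignment, make_genome, make_panel,
                                make_sav_panel)


class TestMakeGenome:
    def test_gc_target_realized(self, small_catalog):
        spec = SimSpec(seed=5, orfs_per_strain=200, genome_gc_target=0.40)
        genome, truth = make_genome(spec, small_catalog)
        assert 0.39 <= genome.genome_gc <= 0.41

    # coding-sequence GC is bounded by amino-acid composition (e.g. Gly is
    # always 2/3 GC), so realizable targets live well inside (0.28, 0.65)
    @pytest.mark.parametrize("target", [0.32, 0.55, 0.62])
    def test_gc_target_across_range(self, small_catalog, target):
        spec = SimSpec(seed=7, orfs_per_strain=120, genome_gc_target=target)
        genome, _ = make_genome(spec, small_catalog)
        assert genome.genome_gc == pytest.approx(target, abs=0.012)

    def test_implant_interval_by_construction(self, implanted_genome):
        from nitriscan.synteny import interval_orf_count
        genome, truth = implanted_genome
        dur3 = [t for t in truth.implants if t.family == "dur3"]
        d = interval_orf_count(genome, (dur3[0].replicon_id, dur3[0].ordinal),
                               (dur3[1].replicon_id, dur3[1].ordinal))
        assert d.interval_orfs == 2  # ordinals 10 and 13

    def test_same_seed_byte_identical_genbank(self, small_catalog, tmp_path):
        spec = SimSpec(seed=9, orfs_per_strain=30, genome_gc_target=0.45)
        for name in ("a", "b"):
            genome, _ = make_genome(spec, small_catalog)
            write_genbank(genome, str(tmp_path / f"{name}.gbk"))
        assert (tmp_path / "a.gbk").read_bytes() == (tmp_path / "b.gbk").read_bytes()

    def test_infeasible_gc_rejected(self, small_catalog):
        with pytest.raises(InfeasibleSpec):
            SimSpec(seed=1, genome_gc_target=0.80,
                    implants=[ImplantSpec("dur3", gc_offset=0.10)])

    def test_generator_satisfies_record_invariants(self, small_catalog):
        spec = SimSpec(seed=13, orfs_per_strain=50, genome_gc_target=0.5,
                       implants=[ImplantSpec("ureC", copies=1,
                                             identity_to_ref=0.7,
                                             cluster_positions=[8])])
        genome, _ = make_genome(spec, small_catalog)
        genome.validate()  # raises on violation


class TestDivergeProtein:
    def test_target_one_unchanged(self, small_catalog):
        ref = small_catalog[0].aa_seq
        seq, realized = diverge_protein(ref, 1.0, seed=1)
        assert seq == ref and realized == 1.0

    def test_measured_identity_near_target(self, small_catalog):
        """local_align identity lands within a few points of the target."""
        ref = next(g for g in small_catalog if len(g.aa_seq) >= 250).aa_seq[:300]
        seq, realized = diverge_protein(ref, 0.45, seed=3)
        assert realized == pytest.approx(0.45, abs=0.02)
        res = local_align(seq, ref)
        assert res.identity == pytest.approx(0.45, abs=0.04)

    def test_monotone_in_target(self, small_catalog):
        ref = small_catalog[0].aa_seq
        measured = []
        for target in (0.9, 0.7, 0.5, 0.3):
            ids = [diverge_protein(ref, target, seed=s)[1] for s in range(20)]
            measured.append(np.mean(ids))
        assert all(a > b for a, b in zip(measured, measured[1:]))

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            diverge_protein("MKLV" * 10, 0.01, seed=1)


class TestEvolveAlignment:
    def test_zero_length_branches_identical_rows(self, rng):
        tree = random_unrooted_tree(5, rng, blen_lo=0.0, blen_hi=0.0)
        msa = evolve_alignment(tree, SubstitutionModel(matrix="LG"), 50, seed=2)
        assert len(set(msa.rows)) == 1

    def test_same_seed_reproduces(self, rng):
        tree = random_unrooted_tree(5, rng)
        m = SubstitutionModel(matrix="LG", alpha=1.0)
        a = evolve_alignment(tree, m, 100, seed=7)
        b = evolve_alignment(tree, m, 100, seed=7)
        assert a.rows == b.rows

    def test_substitution_counts_match_transition_probabilities(self):
        """Empirical state flow on one long branch matches P(t) within 3 sigma."""
        from nitriscan.phylo.trees import Node, Tree
        root = Node("")
        root.add(Node("A", 0.0))
        root.add(Node("B", 0.4))
        tree = Tree(root)
        model = SubstitutionModel(matrix="LG")
        msa = evolve_alignment(tree, model, 10000, seed=11)
        enc = msa.encoded()
        a, b = enc[msa.labels.index("A")], enc[msa.labels.index("B")]
        p = expm(model.rate_matrix() * 0.4)
        # with ~400 cells a few 3-sigma excursions are expected by chance;
        # demand that none exceeds 4.5 sigma and that >98% sit within 3
        excesses, cells = 0, 0
        for i in np.unique(a):
            n_i = int((a == i).sum())
            if n_i < 200:
                continue
            for j in range(20):
                obs = int(((a == i) & (b == j)).sum())
                mean = n_i * p[i, j]
                sd = np.sqrt(max(n_i * p[i, j] * (1 - p[i, j]), 1.0))
                cells += 1
                if abs(obs - mean) > 3 * sd:
                    excesses += 1
                assert abs(obs - mean) <= 4.5 * sd
        assert excesses <= max(1, int(0.02 * cells))


class TestMakePanel:
    def test_panel_files_written(self, small_catalog, tmp_path):
        panel = make_panel(seed=3, n_strains=4, orfs_per_strain=20,
                           catalog=small_catalog, out_dir=str(tmp_path))
        assert (tmp_path / "metadata.tsv").exists()
        assert (tmp_path / "catalog.fasta").exists()
        assert (tmp_path / "truth.json").exists()
        assert len(list(tmp_path.glob("*.gbk"))) == 4
        assert len(panel.genomes) == 4

    def test_truth_table_scores_copy_numbers(self, small_catalog):
        plan = {0: [ImplantSpec("dur3", copies=2, identity_to_ref=0.7,
                                cluster_positions=[3, 8])]}
        panel = make_panel(seed=5, n_strains=2, orfs_per_strain=15,
                           catalog=small_catalog, implant_plan=plan)
        assert panel.truth_copy_numbers()["S00"] == {"dur3": 2}
        assert panel.truth_copy_numbers()["S01"] == {}

    def test_sav_panel_carries_positive_rank_correlation(self):
        from nitriscan.morphometrics import sav_table
        from nitriscan.stats import spearman
        copies, metadata = make_sav_panel(seed=2, n_strains=12)
        savs = sav_table(metadata)["sav_per_um"].tolist()
        rho = spearman(copies, savs).statistic
        assert rho > 0.4
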