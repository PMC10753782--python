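"""Homolog screening: exact local alignment, assignment rules, copy numbers."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from nitriscan.homology import (AlphabetError, copy_number_matrix,
                                find_homologs, local_align)
from nitriscan.simulate import diverge_protein

_B62 = substitution_matrices.load("BLOSUM62")
_AAS = "ACDEFGHIKLMNPQRSTVWY"


def sw_affine_score(query: str, target: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Brute-force Gotoh local alignment score (match-state maximum).

    Independent of the production aligner: plain three-matrix dynamic
    programming where a length-k gap costs open + k*extend.  With positive
    gap penalties the optimal local alignment ends in a substitution column,
    so the maximum over the match matrix is the Smith-Waterman score.
    """
    n, m = len(query), len(target)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), neg)  # gap in target (consume query)
    Iy = np.full((n + 1, m + 1), neg)  # gap in query (consume target)
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_B62[query[i - 1]][target[j - 1]])
            Ix[i, j] = max(M[i - 1, j] - first, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - first, Iy[i, j - 1] - gap_extend)
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                                       Iy[i - 1, j - 1]))
            best = max(best, M[i, j])
    return best


class TestLocalAlign:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
        res = local_align(seq, seq)
        assert res.identity == 1.0 and res.coverage == 1.0

    def test_no_positive_segment_is_no_hit(self):
        assert local_align("AAAA", "CCCC") is None

    def test_score_matches_bruteforce_dp(self, rng):
        """Production SW equals an independent Gotoh DP on random short pairs."""
        aas = np.array(list(_AAS))
        for _ in range(60):
            q = "".join(rng.choice(aas, size=rng.integers(5, 31)))
            t = "".join(rng.choice(aas, size=rng.integers(5, 31)))
            expected = sw_affine_score(q, t)
            res = local_align(q, t)
            got = 0.0 if res is None else res.score
            assert got == pytest.approx(expected, abs=1e-9)

    def test_score_symmetric(self, rng):
        aas = np.array(list(_AAS))
        for _ in range(20):
            q = "".join(rng.choice(aas, size=20))
            t = "".join(rng.choice(aas, size=25))
            ra, rb = local_align(q, t), local_align(t, q)
            if ra is None:
                assert rb is None
            else:
                assert ra.score == rb.score

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError):
            local_align("MKL", "MKL", matrix="NOSUCH62")

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(AlphabetError):
            local_align("MK1", "MKL")


class TestFindHomologs:
    def test_implants_recovered_once_each(self, implanted_genome, small_catalog):
        genome, truth = implanted_genome
        hits = find_homologs(genome, small_catalog)
        by_family = {}
        for h in hits:
            by_family.setdefault(h.family, []).append(h)
        assert len(by_family.get("dur3", [])) == 2
        assert len(by_family.get("ureC", [])) == 1
        assert {h.orf[1] for h in by_family["dur3"]} == {10, 13}

    def test_sub_threshold_implant_not_hit(self, implanted_genome, small_catalog):
        """The utp implant was diverged to 35% identity: below the 40% rule."""
        genome, _ = implanted_genome
        hits = find_homologs(genome, small_catalog)
        assert all(h.family != "utp" for h in hits)

    def test_single_assignment_to_best_family(self, small_catalog):
        """An ORF similar to two families is counted only for the best one."""
        from nitriscan.genome_io import GenomeRecord, OrfFeature, Replicon
        ref = next(g for g in small_catalog if g.family == "ureC")
        near, _ = diverge_protein(ref.aa_seq, 0.9, seed=5)
        orf = OrfFeature("chr", 0, 1, 3 * len(near), "+", "A" * (3 * len(near)), near)
        genome = GenomeRecord("X", "AOA", "marine",
                              [Replicon("chr", "A" * (3 * len(near) + 10))], [orf])
        hits = find_homologs(genome, small_catalog, cov_threshold=0.0)
        assert len(hits) == 1 and hits[0].family == "ureC"

    def test_threshold_monotonicity(self, implanted_genome, small_catalog):
        """Raising the identity threshold never increases any count."""
        genome, _ = implanted_genome
        strains = [genome.strain_id]
        families = [g.family for g in small_catalog]
        prev = None
        for thr in (0.30, 0.40, 0.55, 0.70, 0.95):
            hits = find_homologs(genome, small_catalog, id_threshold=thr)
            counts = copy_number_matrix(hits, strains, families).table
            if prev is not None:
                assert (counts.values <= prev.values).all()
            prev = counts


class TestCopyNumberMatrix:
    def test_empty_hits_all_zero(self):
        m = copy_number_matrix([], ["S1", "S2"], ["ureC", "dur3"])
        assert (m.table.values == 0).all()

    def test_unknown_strain_rejected(self, implanted_genome, small_catalog):
        genome, _ = implanted_genome
        hits = find_homologs(genome, small_catalog)
        with pytest.raises(ValueError):
            copy_number_matrix(hits, ["OTHER"], ["dur3"])

    def test_counts_match_truth(self, implanted_genome, small_catalog):
        genome, truth = implanted_genome
        hits = find_homologs(genome, small_catalog)
        m = copy_number_matrix(hits, [genome.strain_id],
                               [g.family for g in small_catalog])
        expected = truth.copy_numbers()
        assert m.count("SYN1", "dur3") == expected["dur3"] == 2
        assert m.count("SYN1", "ureC") == expected["ureC"] == 1
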