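"""Homolog detection against a reference protein catalog.

The screening rule is deliberately simple, mirroring common practice in
comparative surveys of nitrifier gene content: a protein is a homolog of a
catalog family if an exact Smith-Waterman local alignment (BLOSUM62, affine
gaps, BLAST-style open 11 / extend 1) reaches >= 40% identity to the family's
reference sequence.  A reference-coverage floor (default 0.5) suppresses
spurious short local hits; set ``cov_threshold=0`` for the bare identity rule.

Exact dynamic programming replaces BLAST's heuristic seeding — genomes at
this scale are small enough that exhaustive alignment is cheap, at the cost
of occasionally finding marginal hits a seeded search would miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

PATHWAYS = ("ammonia", "urea", "polyamine", "cyanate", "taurine", "GBT", "methylamine")

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class AlphabetError(ValueError):
    """Residue outside the substitution-matrix alphabet."""


@dataclass
class ReferenceGene:
    """One catalog entry: a gene family defining a copy-number matrix column."""

    family: str
    ko_id: str
    aa_seq: str
    pathway: str = "ammonia"

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"{self.family}: empty reference sequence")


@dataclass
class HomologHit:
    strain_id: str
    orf: tuple[str, int]  # (replicon_id, ordinal)
    family: str
    score: float
    identity: float
    coverage: float


@dataclass
class AlignmentResult:
    score: float
    query_aligned: str
    target_aligned: str
    identity: float
    coverage: float


def read_catalog(path: str) -> list[ReferenceGene]:
    """Read the reference catalog FASTA; headers ``family|KO[|pathway[|desc]]``."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.description.split()[0].split("|")
        if len(parts) < 2:
            raise ValueError(f"catalog header {rec.description!r}: need family|KO")
        pathway = parts[2] if len(parts) > 2 and parts[2] in PATHWAYS else "ammonia"
        out.append(ReferenceGene(family=parts[0], ko_id=parts[1],
                                 aa_seq=str(rec.seq).upper(), pathway=pathway))
    seen: set[str] = set()
    for g in out:
        if g.family in seen:
            raise ValueError(f"duplicate family {g.family!r} in catalog")
        seen.add(g.family)
    return out


def write_catalog(catalog: list[ReferenceGene], path: str) -> None:
    with open(path, "w") as fh:
        for g in catalog:
            fh.write(f">{g.family}|{g.ko_id}|{g.pathway}\n{g.aa_seq}\n")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = sub
    # BLAST convention: a gap of length k costs open + k*extend.  Biopython
    # charges open_gap_score for the first gapped column and extend for the
    # rest, hence open = -(gap_open + gap_extend).
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_alphabet(seq: str, alphabet: str, what: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise AlphabetError(f"{what}: residues {sorted(bad)} outside matrix alphabet")


_MAX_TIEBREAK = 8  # co-optimal alignments examined for the end-coordinate tie-break


def local_align(query: str, target: str, matrix: str = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0) -> AlignmentResult | None:
    """Optimal Smith-Waterman local alignment of two proteins.

    Returns score, the aligned (gapped) pair, identity (identical columns /
    all aligned columns, gap columns included in the denominator) and
    coverage (aligned target residues / target length; the target is the
    catalog reference).  A best score <= 0 means no positive-scoring local
    segment exists and None is returned.  Among co-optimal alignments the one
    ending at the smallest (query, target) end coordinates is preferred.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    _check_alphabet(query, alphabet, "query")
    _check_alphabet(target, alphabet, "target")
    alignments = aligner.align(query, target)
    if alignments.score <= 0:
        return None
    best = None
    best_key = None
    for i, aln in enumerate(alignments):
        if i >= _MAX_TIEBREAK:
            break
        q_end = aln.aligned[0][-1][1]
        t_end = aln.aligned[1][-1][1]
        if best_key is None or (q_end, t_end) < best_key:
            best, best_key = aln, (q_end, t_end)
    q_gapped, t_gapped = str(best[0]), str(best[1])
    ncols = len(q_gapped)
    ident = sum(1 for a, b in zip(q_gapped, t_gapped) if a == b and a != "-")
    covered = sum(e - s for s, e in best.aligned[1])
    return AlignmentResult(score=float(alignments.score),
                           query_aligned=q_gapped, target_aligned=t_gapped,
                           identity=ident / ncols, coverage=covered / len(target))


def find_homologs(genome, catalog: list[ReferenceGene],
                  id_threshold: float = 0.40, cov_threshold: float = 0.50,
                  matrix: str = "BLOSUM62", gap_open: float = 11.0,
                  gap_extend: float = 1.0) -> list[HomologHit]:
    """Screen every ORF of a genome against every catalog family.

    An ORF passing the identity and coverage thresholds for one or more
    families is assigned to exactly one: the highest-scoring family, ties
    broken by higher identity then lexicographic family name.  This prevents
    double counting among homologous families (e.g. ABC-transporter ATPases).
    Hits are sorted by (family, replicon, ordinal).
    """
    if not catalog:
        raise ValueError("empty catalog")
    hits: list[HomologHit] = []
    for orf in genome.orfs:
        if not orf.aa_seq:
            continue
        best: tuple[float, float, str] | None = None  # (score, identity, family)
        best_res: AlignmentResult | None = None
        for ref in catalog:
            res = local_align(orf.aa_seq, ref.aa_seq, matrix=matrix,
                              gap_open=gap_open, gap_extend=gap_extend)
            if res is None or res.identity < id_threshold or res.coverage < cov_threshold:
                continue
            key = (res.score, res.identity, ref.family)
            # maximize score, then identity; ties -> lexicographically first family
            if best is None or (key[0], key[1]) > (best[0], best[1]) or (
                    (key[0], key[1]) == (best[0], best[1]) and key[2] < best[2]):
                best, best_res = key, res
        if best is not None and best_res is not None:
            hits.append(HomologHit(strain_id=genome.strain_id, orf=orf.ref,
                                   family=best[2], score=best[0],
                                   identity=best_res.identity,
                                   coverage=best_res.coverage))
    hits.sort(key=lambda h: (h.family, h.strain_id, h.orf))
    return hits


@dataclass
class CopyNumberMatrix:
    """Strain x family homolog counts (the heatmap behind gene-content figures)."""

    table: pd.DataFrame  # rows: strain_ids, cols: families, int counts

    def count(self, strain_id: str, family: str) -> int:
        return int(self.table.loc[strain_id, family])

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="strain_id")


def copy_number_matrix(hits: list[HomologHit], strains: list[str],
                       families: list[str]) -> CopyNumberMatrix:
    """Count distinct ORFs assigned to each (strain, family); absent pairs are 0."""
    counts = np.zeros((len(strains), len(families)), dtype=int)
    sidx = {s: i for i, s in enumerate(strains)}
    fidx = {f: i for i, f in enumerate(families)}
    seen: set[tuple[str, tuple[str, int]]] = set()
    for h in hits:
        if h.strain_id not in sidx:
            raise ValueError(f"hit references unknown strain {h.strain_id!r}")
        if h.family not in fidx:
            raise ValueError(f"hit references unknown family {h.family!r}")
        key = (h.strain_id, h.orf)
        if key in seen:
            continue
        seen.add(key)
        counts[sidx[h.strain_id], fidx[h.family]] += 1
    return CopyNumberMatrix(pd.DataFrame(counts, index=list(strains), columns=list(families)))
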