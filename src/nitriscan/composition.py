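"""GC content and Codon Adaptation Index calculators.

Per-gene GC% and CAI, compared against whole-genome baselines, are the two
composition channels of the lateral-gene-transfer screen: a recently acquired
gene keeps the donor's nucleotide composition, and a highly expressed native
gene matches the host's preferred-codon table.

CAI follows the Sharp & Li convention: the geometric mean over codons of the
relative adaptiveness w(codon) = f(codon)/max f(synonym), computed against a
reference set of (ideally highly expressed) CDS.  Methionine, tryptophan and
stop codons are excluded, as they admit no synonymous choice.
"""

from __future__ import annotations

import logging
import math
import statistics
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

_BACTERIAL = CodonTable.unambiguous_dna_by_id[11]

#: codon -> amino acid, sense codons only (bacterial code, table 11)
CODON_TO_AA: dict[str, str] = dict(_BACTERIAL.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_BACTERIAL.stop_codons)

#: amino acid -> sorted list of its codons
SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMS.setdefault(_aa, []).append(_codon)

#: amino acids with a single codon: no synonymous choice, excluded from CAI
SINGLE_CODON_AA = frozenset(aa for aa, cs in SYNONYMS.items() if len(cs) == 1)

_GAPS = frozenset("-.")


def gc_content(seq: str) -> float:
    """Fraction of G+C in a nucleotide sequence.

    The numerator counts G and C, with the two-fold ambiguity code S (G or C)
    contributing 0.5; the denominator counts every non-gap character, so other
    ambiguity codes (N, W, R, ...) dilute the fraction rather than being
    dropped.  Case-insensitive.
    """
    if not seq:
        raise ValueError("empty sequence")
    counts = Counter(seq.upper())
    denom = sum(n for ch, n in counts.items() if ch not in _GAPS)
    if denom == 0:
        raise ValueError("sequence contains only gap characters")
    num = counts["G"] + counts["C"] + 0.5 * counts["S"]
    return num / denom


@dataclass
class CodonWeights:
    """Relative adaptiveness w in (0,1] per sense codon."""

    weights: dict[str, float]
    reference_desc: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


def _split_codons(cds: str) -> list[str]:
    cds = cds.upper()
    codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def _has_internal_stop(codons: list[str]) -> bool:
    return any(c in STOP_CODONS for c in codons)


def codon_weights(cds_set: list[str], reference_desc: str = "") -> CodonWeights:
    """Build relative-adaptiveness weights from a reference CDS set.

    Within each amino acid, w = codon frequency / max synonymous frequency, so
    the most frequent synonym gets w = 1 (ties: all tied codons get 1).
    Codons never observed in the reference set receive the pseudo-weight
    0.5 / (count of the most frequent synonym), keeping them strictly positive
    but below any observed codon; amino acids entirely absent from the
    reference get w = 1 for all their synonyms (no information).
    CDS with internal stop codons are excluded and logged.
    """
    counts: Counter[str] = Counter()
    n_excluded = 0
    for cds in cds_set:
        codons = _split_codons(cds)
        if _has_internal_stop(codons):
            n_excluded += 1
            continue
        counts.update(c for c in codons if c in CODON_TO_AA)
    if n_excluded:
        logger.warning("codon_weights: excluded %d CDS with internal stops", n_excluded)
    weights: dict[str, float] = {}
    for aa, codons in SYNONYMS.items():
        mx = max(counts[c] for c in codons)
        for c in codons:
            if mx == 0:
                weights[c] = 1.0
            elif counts[c] == 0:
                weights[c] = 0.5 / mx
            else:
                weights[c] = counts[c] / mx
    return CodonWeights(weights=weights, reference_desc=reference_desc)


def cai(cds: str, weights: CodonWeights) -> float:
    """Codon Adaptation Index of one CDS: geometric mean of w over codons.

    Computed in log space; Met, Trp and stop codons are skipped (single-codon
    families carry no codon-choice signal), as are codons with ambiguous
    bases.  Raises ValueError if no usable codon remains.
    """
    codons = _split_codons(cds)
    logsum = 0.0
    n = 0
    for c in codons:
        aa = CODON_TO_AA.get(c)
        if aa is None or aa in SINGLE_CODON_AA:
            continue
        logsum += math.log(weights[c])
        n += 1
    if n == 0:
        raise ValueError("no usable codons for CAI")
    return math.exp(logsum / n)


@dataclass
class CompositionProfile:
    """Per-gene and genome-level composition values for one strain."""

    strain_id: str
    #: (family, (replicon_id, ordinal)) -> (gene GC fraction, gene CAI)
    per_gene: dict[tuple[str, tuple[str, int]], tuple[float, float]]
    genome_gc: float
    genome_cai_values: list[float] = field(default_factory=list)
    weights_mode: str = "all_cds"

    @property
    def genome_cai_median(self) -> float:
        return statistics.median(self.genome_cai_values)


_RIBOSOMAL_MIN = 10  # fall back to all-CDS weights below this many matches


def reference_cds(genome, mode: str = "ribosomal") -> tuple[list[str], str]:
    """Pick the CAI reference CDS set from a genome.

    ``ribosomal`` matches annotation labels containing 'ribosomal protein'
    (the classic highly expressed set) and falls back to all CDS when fewer
    than 10 are found; ``all_cds`` uses every CDS.
    """
    if mode == "ribosomal":
        ribo = [o.nt_seq for o in genome.orfs if "ribosomal protein" in o.label.lower()]
        if len(ribo) >= _RIBOSOMAL_MIN:
            return ribo, "ribosomal"
        logger.info("%s: %d ribosomal-protein CDS (<%d); using all CDS for CAI weights",
                    genome.strain_id, len(ribo), _RIBOSOMAL_MIN)
    return [o.nt_seq for o in genome.orfs], "all_cds"


def genome_profile(genome, hits, weights_mode: str = "ribosomal",
                   user_weights: CodonWeights | None = None) -> CompositionProfile:
    """Compose per-hit gene GC/CAI plus the whole-genome baseline.

    The genome baseline is the distribution of per-CDS CAI over every ORF
    (its median operationalises "genome CAI"), with GC taken from the genome
    record.  ``weights_mode`` selects the CAI reference set: 'ribosomal'
    (default, with all-CDS fallback), 'all_cds', or 'user' with explicit
    weights.
    """
    if weights_mode == "user":
        if user_weights is None:
            raise ValueError("weights_mode='user' requires user_weights")
        weights, mode_used = user_weights, "user"
    else:
        ref, mode_used = reference_cds(genome, weights_mode)
        weights = codon_weights(ref, reference_desc=f"{genome.strain_id}:{mode_used}")
    per_gene = {}
    for hit in hits:
        if hit.strain_id != genome.strain_id:
            continue
        orf = genome.orf(hit.orf)
        per_gene[(hit.family, hit.orf)] = (gc_content(orf.nt_seq), cai(orf.nt_seq, weights))
    baseline = []
    for orf in genome.orfs:
        try:
            baseline.append(cai(orf.nt_seq, weights))
        except ValueError:
            continue
    return CompositionProfile(strain_id=genome.strain_id, per_gene=per_gene,
                              genome_gc=genome.genome_gc,
                              genome_cai_values=baseline, weights_mode=mode_used)


def write_composition_tsv(profiles: list[CompositionProfile], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tfamily\treplicon\tordinal\tgene_gc\tgene_cai\t"
                 "genome_gc\tgenome_cai_median\tweights_mode\n")
        for p in profiles:
            med = p.genome_cai_median if p.genome_cai_values else float("nan")
            for (family, (rep, ordinal)), (gc, c) in sorted(p.per_gene.items()):
                fh.write(f"{p.strain_id}\t{family}\t{rep}\t{ordinal}\t{gc:.6f}\t"
                         f"{c:.6f}\t{p.genome_gc:.6f}\t{med:.6f}\t{p.weights_mode}\n")
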