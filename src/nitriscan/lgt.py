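"""Composite lateral-gene-transfer (LGT) screen.

A recently transferred gene betrays its donor three ways: its GC content
deviates from the recipient genome's, its codon usage (CAI against the host's
reference set) is atypical, and its position in the gene tree contradicts the
organismal grouping.  The screen evaluates all three channels per gene family
per lineage group and combines them into a verdict:

* ``LGT_candidate``  — the gene-vs-genome GC deviation is significant AND the
  gene tree does not show the group as congruent (the phylogeny must not
  contradict the compositional signal);
* ``vertical``       — otherwise, with sufficient data;
* ``indeterminate``  — fewer than 3 strains carry the gene in the group.

The CAI channel is advisory: it is reported alongside but does not gate the
verdict, since elevated CAI can equally indicate high native expression.
All evidence is retained in the output so users can re-combine it.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import pandas as pd

from .composition import CompositionProfile
from .stats import mann_whitney
from .phylo.trees import Tree

DEFAULT_ALPHA = 0.05
DEFAULT_SUPPORT_MIN = 70.0

_MIN_STRAINS = 3


@dataclass
class LgtVerdict:
    family: str
    group: str
    gc_p: float | None
    gc_direction: str           # gene_higher | gene_lower | none
    cai_p: float | None
    cai_direction: str
    phylo_flag: str             # congruent | incongruent | untested
    verdict: str                # LGT_candidate | vertical | indeterminate
    n_strains: int = 0


def _direction(sample_gene, sample_genome) -> str:
    diff = statistics.median(sample_gene) - statistics.median(sample_genome)
    if diff > 0:
        return "gene_higher"
    if diff < 0:
        return "gene_lower"
    return "none"


def gc_deviation_test(gene_gcs, genome_gcs, alpha: float = DEFAULT_ALPHA):
    """Two-sided Mann-Whitney of gene GC vs whole-genome GC across strains.

    Returns (p, direction); (None, 'indeterminate') with fewer than 3 values
    on either side.
    """
    if len(gene_gcs) < _MIN_STRAINS or len(genome_gcs) < _MIN_STRAINS:
        return None, "indeterminate"
    res = mann_whitney(gene_gcs, genome_gcs)
    return res.p_value, _direction(gene_gcs, genome_gcs)


def cai_comparison(gene_cais, genome_cai_baselines, alpha: float = DEFAULT_ALPHA):
    """Mann-Whitney of per-strain gene CAI vs per-strain genome median CAI."""
    if len(gene_cais) < _MIN_STRAINS or len(genome_cai_baselines) < _MIN_STRAINS:
        return None, "indeterminate"
    res = mann_whitney(gene_cais, genome_cai_baselines)
    return res.p_value, _direction(gene_cais, genome_cai_baselines)


def phylo_incongruence_flag(gene_tree: Tree, reference_grouping: dict[str, str],
                            support_min: float = DEFAULT_SUPPORT_MIN) -> str:
    """Does the gene tree contradict the reference strain grouping?

    ``incongruent`` when some labeled leaf's smallest well-supported
    (support >= support_min) enclosing clade contains only leaves of a
    different reference label; ``congruent`` when every labeled group is
    monophyletic (unrooted sense); ``untested`` when the tree carries no
    supports or neither condition resolves.
    """
    leaves = set(gene_tree.leaf_names())
    labeled = {l for l in leaves if l in reference_grouping}
    missing = [l for l in reference_grouping if l not in leaves]
    if not labeled:
        raise ValueError("no tree leaf matches the reference grouping"
                         + (f" (labels without leaves: {missing})" if missing else ""))
    supports = [n.support for n in gene_tree.internal_nodes() if n.support is not None]
    leafsets = gene_tree.clade_leafsets()

    # incongruence: a supported clade that isolates a leaf among foreign labels
    if supports:
        node_of: dict[str, object] = {}
        for node in gene_tree.postorder():
            if node.is_leaf:
                node_of[node.name] = node
        for leaf_name in labeled:
            label = reference_grouping[leaf_name]
            node = node_of[leaf_name].parent
            while node is not None:
                if node.support is not None and node.support >= support_min:
                    clade = leafsets[id(node)]
                    others = [l for l in clade if l != leaf_name and l in reference_grouping]
                    if others and all(reference_grouping[l] != label for l in others):
                        return "incongruent"
                    break
                node = node.parent

    # congruence: every labeled group monophyletic in the unrooted tree
    groups: dict[str, set[str]] = {}
    for leaf_name in labeled:
        groups.setdefault(reference_grouping[leaf_name], set()).add(leaf_name)
    bips = gene_tree.bipartitions()
    all_leaves = frozenset(leaves)
    anchor = min(all_leaves)

    def monophyletic(members: frozenset[str]) -> bool:
        if len(members) in (1, len(all_leaves)):
            return True
        side = members if anchor not in members else all_leaves - members
        if len(side) == 1 or len(side) == len(all_leaves) - 1:
            return True
        return side in bips

    if all(monophyletic(frozenset(g)) for g in groups.values()):
        return "congruent"
    return "untested"


def lgt_verdicts(profiles: list[CompositionProfile], trees: dict[str, Tree],
                 groups: dict[str, str], alpha: float = DEFAULT_ALPHA,
                 support_min: float = DEFAULT_SUPPORT_MIN) -> list[LgtVerdict]:
    """One verdict per (family, group) with all three evidence channels.

    ``groups`` maps strain_id -> group label (e.g. 'terrestrial AOA'); the
    GC and CAI tests compare, within each group, the strains carrying the
    family against the same strains' genome baselines.
    """
    by_strain = {p.strain_id: p for p in profiles}
    families = sorted({fam for p in profiles for (fam, _) in p.per_gene})
    group_labels = sorted(set(groups.values()))
    verdicts = []
    for family in families:
        tree = trees.get(family)
        for group in group_labels:
            strains = [s for s, g in groups.items() if g == group and s in by_strain]
            gene_gcs, gene_cais, genome_gcs, genome_cais = [], [], [], []
            for s in strains:
                prof = by_strain[s]
                vals = [(gc, c) for (fam, _), (gc, c) in prof.per_gene.items()
                        if fam == family]
                if not vals:
                    continue
                for gc, c in vals:
                    gene_gcs.append(gc)
                    gene_cais.append(c)
                genome_gcs.append(prof.genome_gc)
                if prof.genome_cai_values:
                    genome_cais.append(prof.genome_cai_median)
            n = len(genome_gcs)
            gc_p, gc_dir = gc_deviation_test(gene_gcs, genome_gcs, alpha)
            cai_p, cai_dir = cai_comparison(gene_cais, genome_cais, alpha)
            if tree is not None:
                grouping = {s: groups[s] for s in groups if s in set(tree.leaf_names())}
                try:
                    flag = phylo_incongruence_flag(tree, grouping, support_min)
                except ValueError:
                    flag = "untested"
            else:
                flag = "untested"
            if n < _MIN_STRAINS or gc_p is None:
                verdict = "indeterminate"
            elif gc_p < alpha and flag != "congruent":
                verdict = "LGT_candidate"
            else:
                verdict = "vertical"
            verdicts.append(LgtVerdict(family=family, group=group, gc_p=gc_p,
                                       gc_direction=gc_dir, cai_p=cai_p,
                                       cai_direction=cai_dir, phylo_flag=flag,
                                       verdict=verdict, n_strains=n))
    return verdicts


def verdicts_table(verdicts: list[LgtVerdict]) -> pd.DataFrame:
    return pd.DataFrame([vars(v) for v in verdicts],
                        columns=["family", "group", "gc_p", "gc_direction",
                                 "cai_p", "cai_direction", "phylo_flag",
                                 "verdict", "n_strains"])
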