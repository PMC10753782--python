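"""Synthetic genomes, homolog families and alignments with known ground truth.

Every pipeline stage is exercised against data whose answer is known by
construction: multi-ORF genomes with controlled GC% and codon bias, implanted
"alien" genes carrying an offset composition (the lateral-transfer signal),
gene clusters at set ordinal spacings, protein families diverged to target
identities, and alignments evolved along known trees.

Composition control works at the codon level: synonymous-codon probabilities
are tilted by a solved exponential weight on codon G+C so the expected coding
GC hits the target, and a ``codon_bias_strength`` in [0,1] interpolates
between near-uniform synonymous usage and a single-preferred-codon table
(giving CAI a controllable gradient).  GC offsets for implants therefore act
mostly through third positions, preserving the protein.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from .composition import CODON_TO_AA, SYNONYMS, gc_content
from .genome_io import GenomeRecord, OrfFeature, Replicon, StrainMetadata, write_genbank
from .homology import ReferenceGene, write_catalog
from .phylo.models import N_STATES, SubstitutionModel
from .phylo.msa import Msa
from .phylo.trees import Tree
from ._aa import AA_BACKGROUND_FREQS

_CODON_GC = {c: (c.count("G") + c.count("C")) for c in CODON_TO_AA}
_BIAS_KAPPA = 6.0  # log-odds boost of the preferred codon at full bias strength


class InfeasibleSpec(ValueError):
    """Requested composition targets cannot be realized."""


@dataclass
class ImplantSpec:
    """One implanted gene family: copies at set ordinals with offset composition."""

    family: str
    copies: int = 1
    gc_offset: float = 0.0          # percentage points / 100, added to genome target
    identity_to_ref: float = 1.0    # global identity of the implant protein to the reference
    cluster_positions: list[int] | None = None  # ordinals; None -> evenly spread
    alien_bias: bool = False        # use a donor preferred-codon table


@dataclass
class SimSpec:
    seed: int = 0
    n_strains: int = 1
    orfs_per_strain: int = 60
    genome_gc_target: float = 0.42
    codon_bias_strength: float = 0.3
    implants: list[ImplantSpec] = field(default_factory=list)
    tree: Tree | None = None

    def __post_init__(self) -> None:
        for imp in self.implants:
            total = self.genome_gc_target + imp.gc_offset
            if not 0.15 <= total <= 0.85:
                raise InfeasibleSpec(
                    f"{imp.family}: gc target {total:.2f} outside [0.15, 0.85]")


# ---------------------------------------------------------------------------
# Codon-level composition control


def _pick_preferred(rng: np.random.Generator) -> dict[str, str]:
    """A host-specific preferred-codon table (one synonym per amino acid)."""
    return {aa: codons[rng.integers(len(codons))] for aa, codons in SYNONYMS.items()}


def _codon_probs(beta: float, bias: float, preferred: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for aa, codons in SYNONYMS.items():
        logw = np.array([beta * _CODON_GC[c] + (_BIAS_KAPPA * bias if c == preferred[aa] else 0.0)
                         for c in codons])
        w = np.exp(logw - logw.max())
        out[aa] = w / w.sum()
    return out


def _expected_gc(beta: float, bias: float, preferred: dict[str, str],
                 aa_freqs: dict[str, float]) -> float:
    probs = _codon_probs(beta, bias, preferred)
    num = 0.0
    for aa, f in aa_freqs.items():
        codons = SYNONYMS[aa]
        num += f * float(np.dot(probs[aa], [_CODON_GC[c] for c in codons]))
    return num / 3.0


def solve_codon_distribution(target_gc: float, bias: float,
                             preferred: dict[str, str],
                             aa_freqs: dict[str, float]) -> dict[str, np.ndarray]:
    """Codon probabilities per amino acid whose expected coding GC hits target."""
    lo = _expected_gc(-30.0, bias, preferred, aa_freqs)
    hi = _expected_gc(30.0, bias, preferred, aa_freqs)
    if not lo <= target_gc <= hi:
        raise InfeasibleSpec(
            f"GC target {target_gc:.3f} outside achievable range [{lo:.3f}, {hi:.3f}]")
    beta = brentq(lambda b: _expected_gc(b, bias, preferred, aa_freqs) - target_gc,
                  -30.0, 30.0, xtol=1e-10)
    return _codon_probs(beta, bias, preferred)


def _aa_freqs_of(protein: str) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for aa in protein:
        if aa in SYNONYMS:
            freqs[aa] = freqs.get(aa, 0.0) + 1.0
    total = sum(freqs.values())
    return {aa: f / total for aa, f in freqs.items()}


def back_translate(protein: str, probs: dict[str, np.ndarray],
                   rng: np.random.Generator) -> str:
    """Sample a CDS encoding ``protein`` from per-amino-acid codon probabilities."""
    codons = []
    for aa in protein:
        cands = SYNONYMS[aa]
        codons.append(cands[rng.choice(len(cands), p=probs[aa])])
    codons.append("TAA")
    return "".join(codons)


# ---------------------------------------------------------------------------
# Protein divergence

_B62 = substitution_matrices.load("BLOSUM62")
_AAS = "ACDEFGHIKLMNPQRSTVWY"


def diverge_protein(ref: str, target_identity: float, seed: int) -> tuple[str, float]:
    """Substitute residues until global identity matches the target (+-2pp).

    Substitutions are BLOSUM62-weighted (conservative replacements preferred),
    so diverged family members stay alignable the way real homologs do.
    Returns (sequence, realized identity).  Position 0 is kept (start Met).
    """
    if not 0.05 < target_identity <= 1.0:
        raise ValueError("target identity must be in (0.05, 1]")
    if target_identity == 1.0:
        return ref, 1.0
    rng = np.random.default_rng(seed)
    n = len(ref)
    n_sub = int(round((1.0 - target_identity) * n))
    n_sub = min(n_sub, n - 1)
    positions = rng.choice(np.arange(1, n), size=n_sub, replace=False)
    seq = list(ref)
    for pos in positions:
        old = seq[pos]
        others = [a for a in _AAS if a != old]
        logw = np.array([float(_B62[old][a]) / 2.0 for a in others])
        w = np.exp(logw - logw.max())
        seq[pos] = others[rng.choice(len(others), p=w / w.sum())]
    return "".join(seq), 1.0 - n_sub / n


# ---------------------------------------------------------------------------
# Genome construction


@dataclass
class ImplantTruth:
    family: str
    replicon_id: str
    ordinal: int
    target_identity: float
    realized_identity: float
    gc_offset: float
    gene_gc: float


@dataclass
class TruthTable:
    strain_id: str
    genome_gc_target: float
    genome_gc_realized: float
    implants: list[ImplantTruth] = field(default_factory=list)

    def copy_numbers(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for imp in self.implants:
            out[imp.family] = out.get(imp.family, 0) + 1
        return out


def _random_protein(rng: np.random.Generator, min_len: int = 80,
                    max_len: int = 250) -> str:
    length = int(rng.integers(min_len, max_len + 1))
    aas = np.array(list(_AAS))
    p = np.array([AA_BACKGROUND_FREQS[a] for a in _AAS])
    body = "".join(rng.choice(aas, size=length - 1, p=p / p.sum()))
    return "M" + body


def make_genome(spec: SimSpec, catalog: list[ReferenceGene],
                strain_id: str = "S0", guild: str = "AOA",
                habitat: str = "terrestrial") -> tuple[GenomeRecord, TruthTable]:
    """Build one annotated genome with implanted gene copies and ground truth.

    Background CDS are drawn codon-by-codon from the solved bias-parameterized
    codon distribution; implants are diverged copies of catalog references,
    back-translated with the offset GC target (and, when ``alien_bias`` is
    set, a donor preferred-codon table), inserted at the requested ordinals.
    """
    rng = np.random.default_rng(spec.seed)
    preferred = _pick_preferred(rng)
    ref_by_family = {g.family: g for g in catalog}

    n_implants = sum(imp.copies for imp in spec.implants)
    if n_implants > spec.orfs_per_strain:
        raise InfeasibleSpec("more implant copies than ORF slots")
    slots: list[OrfFeature | None] = [None] * spec.orfs_per_strain

    implant_truths: list[tuple[int, str, float, float, float, str]] = []
    taken: set[int] = set()
    for imp in spec.implants:
        if imp.family not in ref_by_family:
            raise InfeasibleSpec(f"implant family {imp.family!r} absent from catalog")
        positions = imp.cluster_positions
        if positions is None:
            # evenly spread, skipping ordinals already claimed by other implants
            step = max(spec.orfs_per_strain // (imp.copies + 1), 1)
            positions = []
            for i in range(imp.copies):
                pos = min(step * (i + 1), spec.orfs_per_strain - 1)
                while pos in taken or pos in positions:
                    pos = (pos + 1) % spec.orfs_per_strain
                positions.append(pos)
        if len(positions) != imp.copies:
            raise InfeasibleSpec(f"{imp.family}: {imp.copies} copies but "
                                 f"{len(positions)} cluster positions")
        for copy_i, pos in enumerate(positions):
            if pos in taken or not 0 <= pos < spec.orfs_per_strain:
                raise InfeasibleSpec(f"{imp.family}: invalid/duplicate ordinal {pos}")
            taken.add(pos)
            ref = ref_by_family[imp.family]
            aa, realized = diverge_protein(
                ref.aa_seq, imp.identity_to_ref,
                seed=int(rng.integers(2 ** 31)))
            gene_pref = _pick_preferred(rng) if imp.alien_bias else preferred
            gene_bias = spec.codon_bias_strength if not imp.alien_bias else 0.8
            probs = solve_codon_distribution(
                spec.genome_gc_target + imp.gc_offset, gene_bias,
                gene_pref, _aa_freqs_of(aa))
            nt = back_translate(aa, probs, rng)
            implant_truths.append((pos, imp.family, imp.identity_to_ref,
                                   realized, imp.gc_offset, nt))

    # background codon distribution solved once against the background
    # amino-acid frequencies
    bg_freqs = {a: AA_BACKGROUND_FREQS[a] for a in _AAS}
    bg_probs = solve_codon_distribution(spec.genome_gc_target,
                                        spec.codon_bias_strength,
                                        preferred, bg_freqs)
    implant_nt = {pos: (fam, tid, rid, off, nt)
                  for pos, fam, tid, rid, off, nt in implant_truths}
    seq_parts: list[str] = []
    pos_bp = 0
    replicon_id = f"{strain_id}_chr"
    orfs: list[OrfFeature] = []
    truth = TruthTable(strain_id=strain_id, genome_gc_target=spec.genome_gc_target,
                       genome_gc_realized=0.0)
    for ordinal in range(spec.orfs_per_strain):
        # intergenic spacer with background GC
        spacer_len = int(rng.integers(15, 61))
        spacer = "".join(rng.choice(
            ["G", "C", "A", "T"], size=spacer_len,
            p=[spec.genome_gc_target / 2, spec.genome_gc_target / 2,
               (1 - spec.genome_gc_target) / 2, (1 - spec.genome_gc_target) / 2]))
        seq_parts.append(spacer)
        pos_bp += spacer_len
        if ordinal in implant_nt:
            fam, tid, rid, off, nt = implant_nt[ordinal]
            aa = str(Seq(nt[:-3]).translate(table=11))
            label = f"{fam} homolog (implant)"
        else:
            aa = _random_protein(rng)
            probs = bg_probs
            nt = back_translate(aa, probs, rng)
            label = "hypothetical protein"
        strand = "+" if rng.random() > 0.2 else "-"
        genomic = nt if strand == "+" else str(Seq(nt).reverse_complement())
        start = pos_bp + 1
        end = pos_bp + len(nt)
        seq_parts.append(genomic)
        pos_bp = end
        orfs.append(OrfFeature(replicon_id=replicon_id, ordinal=ordinal,
                               start=start, end=end, strand=strand,
                               nt_seq=nt, aa_seq=aa, label=label))
        if ordinal in implant_nt:
            truth.implants.append(ImplantTruth(
                family=fam, replicon_id=replicon_id, ordinal=ordinal,
                target_identity=tid, realized_identity=rid,
                gc_offset=off, gene_gc=gc_content(nt)))
    seq_parts.append("".join(rng.choice(
        ["G", "C", "A", "T"], size=30,
        p=[spec.genome_gc_target / 2, spec.genome_gc_target / 2,
           (1 - spec.genome_gc_target) / 2, (1 - spec.genome_gc_target) / 2])))
    genome = GenomeRecord(strain_id=strain_id, guild=guild, habitat=habitat,
                          replicons=[Replicon(replicon_id, "".join(seq_parts))],
                          orfs=orfs)
    truth.genome_gc_realized = genome.genome_gc
    genome.validate()
    return genome, truth


# ---------------------------------------------------------------------------
# Sequence evolution along a tree


def evolve_alignment(tree: Tree, model: SubstitutionModel, n_sites: int,
                     seed: int) -> Msa:
    """Simulate an alignment along a tree under the substitution model.

    The root sequence is drawn from the equilibrium frequencies; each site is
    assigned a rate class (invariant with probability p_inv, else a uniform
    gamma category) and evolved with the per-branch transition matrices.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    pi = model.frequencies
    rates, weights = model.rate_classes()
    classes = np.concatenate([[0.0], rates])
    probs = np.concatenate([[model.p_inv], weights])
    site_class = rng.choice(len(classes), size=n_sites, p=probs / probs.sum())
    site_rate = classes[site_class]

    root_states = rng.choice(N_STATES, size=n_sites, p=pi)
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = parent_states.copy()
        for rate in np.unique(site_rate):
            if rate == 0.0:
                continue
            mask = site_rate == rate
            p = model.transition_matrix(node.length * rate)
            cum = p.cumsum(axis=1)
            u = rng.random(mask.sum())
            par = parent_states[mask]
            child_states = (u[:, None] > cum[par]).sum(axis=1)
            child[mask] = np.minimum(child_states, N_STATES - 1)
        states[id(node)] = child

    from .phylo._lg import AA_ORDER
    labels, rows = [], []
    for leaf in tree.leaves():
        labels.append(leaf.name)
        rows.append("".join(AA_ORDER[s] for s in states[id(leaf)]))
    return Msa(labels, rows)


# ---------------------------------------------------------------------------
# Catalog and full panels

_DEFAULT_FAMILIES: list[tuple[str, str, str]] = [
    ("amoA", "K10944", "ammonia"), ("amoB", "K10945", "ammonia"),
    ("ureA", "K01430", "urea"), ("ureB", "K01429", "urea"),
    ("ureC", "K01428", "urea"), ("utp", "K08717", "urea"),
    ("dur3", "K20989", "urea"), ("urtA", "K11959", "urea"),
    ("cynS", "K01725", "cyanate"), ("focA_nirC", "K21990", "cyanate"),
    ("potA", "K11072", "polyamine"), ("tauD", "K03119", "taurine"),
]


def default_catalog(seed: int = 20240, families=None,
                    min_len: int = 180, max_len: int = 320) -> list[ReferenceGene]:
    """Random reference proteins for a default set of gene families.

    Family labels and KO ids follow the nitrifier LDON-gene naming; sequences
    are synthetic (no real protein data ships with the package).
    """
    rng = np.random.default_rng(seed)
    out = []
    for family, ko, pathway in (families or _DEFAULT_FAMILIES):
        out.append(ReferenceGene(family=family, ko_id=ko, pathway=pathway,
                                 aa_seq=_random_protein(rng, min_len, max_len)))
    return out


@dataclass
class Panel:
    genomes: list[GenomeRecord]
    metadata: list[StrainMetadata]
    catalog: list[ReferenceGene]
    truths: list[TruthTable]

    def truth_copy_numbers(self) -> dict[str, dict[str, int]]:
        return {t.strain_id: t.copy_numbers() for t in self.truths}


def _random_dims(rng: np.random.Generator, guild: str) -> tuple[str, list[float], list[float]]:
    if guild == "AOA":
        shape = "sphere" if rng.random() < 0.5 else "rod"
        widths = [float(rng.uniform(0.2, 0.9))]
    else:
        shape = "rod"
        widths = [float(rng.uniform(0.3, 1.5))]
    lengths = [float(rng.uniform(max(widths[0], 0.5), 3.0))] if shape == "rod" else []
    return shape, widths, lengths


def make_panel(seed: int, n_strains: int = 12, orfs_per_strain: int = 60,
               genome_gc_targets=None, codon_bias_strength: float = 0.3,
               guilds=None, habitats=None,
               implant_plan: dict[int, list[ImplantSpec]] | None = None,
               catalog: list[ReferenceGene] | None = None,
               out_dir: str | None = None) -> Panel:
    """A full pipeline-ready panel: genomes, metadata, catalog and truth.

    ``implant_plan`` maps strain index -> implant specs; GC targets default
    to a spread around 0.42.  When ``out_dir`` is given, GenBank files,
    metadata TSV, catalog FASTA and a truth JSON are written there.
    """
    rng = np.random.default_rng(seed)
    if catalog is None:
        catalog = default_catalog(seed=int(rng.integers(2 ** 31)))
    if guilds is None:
        guilds = ["AOA" if i < n_strains // 2 else "NOB" for i in range(n_strains)]
    if habitats is None:
        habitats = ["marine" if i % 2 else "terrestrial" for i in range(n_strains)]
    if genome_gc_targets is None:
        genome_gc_targets = [0.38 + 0.08 * (g != "AOA") + float(rng.uniform(-0.02, 0.02))
                             for g in guilds]
    implant_plan = implant_plan or {}
    genomes, truths, metadata = [], [], []
    for i in range(n_strains):
        sid = f"S{i:02d}"
        spec = SimSpec(seed=int(rng.integers(2 ** 31)), n_strains=1,
                       orfs_per_strain=orfs_per_strain,
                       genome_gc_target=genome_gc_targets[i],
                       codon_bias_strength=codon_bias_strength,
                       implants=implant_plan.get(i, []))
        genome, truth = make_genome(spec, catalog, strain_id=sid,
                                    guild=guilds[i], habitat=habitats[i])
        genomes.append(genome)
        truths.append(truth)
        shape, widths, lengths = _random_dims(rng, guilds[i])
        metadata.append(StrainMetadata(strain_id=sid, guild=guilds[i],
                                       habitat=habitats[i], shape=shape,
                                       widths=widths, lengths=lengths))
    panel = Panel(genomes, metadata, catalog, truths)
    if out_dir is not None:
        write_panel(panel, out_dir)
    return panel


# ---------------------------------------------------------------------------
# Study-condition panels for the LGT screen


def _ladder_tree(pairs: list[tuple[str, ...]], tip_len: float = 0.08,
                 internal_len: float = 0.08, cherry_len: float = 0.03) -> Tree:
    """A caterpillar tree over cherries/tips; pairs are tip-name tuples."""
    from .phylo.trees import Node, Tree as _Tree
    subtrees = []
    for names in pairs:
        if len(names) == 1:
            subtrees.append(Node(names[0], tip_len))
        else:
            parent = Node("", internal_len)
            for nm in names:
                parent.add(Node(nm, cherry_len))
            subtrees.append(parent)
    while len(subtrees) > 3:
        a = subtrees.pop(0)
        b = subtrees.pop(0)
        p = Node("", internal_len)
        p.add(a)
        p.add(b)
        subtrees.append(p)
    root = Node("")
    for s in subtrees:
        root.add(s)
    return _Tree(root)


def lgt_gene_tree(recipients: list[str], donors: list[str],
                  transfer: bool) -> Tree:
    """Generating gene tree for an LGT panel.

    Under transfer, each recipient's gene attaches as the cherry partner of a
    donor (donor-clade placement); under vertical descent the gene tree
    mirrors the species grouping (recipient clade vs donor clade).
    """
    if transfer:
        pairs = [(d, recipients[i % len(recipients)]) if i < len(recipients) else (d,)
                 for i, d in enumerate(donors)]
        return _ladder_tree(pairs)
    return _ladder_tree([tuple(recipients), tuple(donors)],
                        internal_len=0.15, cherry_len=0.08)


def make_lgt_panel(seed: int, transfer: bool, family: str = "utp",
                   n_recipients: int = 6, n_donors: int = 6,
                   orfs_per_strain: int = 30, gc_offset: float = 0.10,
                   n_sites: int = 300, bootstrap_reps: int = 100):
    """One complete LGT-screen panel with known provenance of the focal gene.

    Recipients are AT-leaning archaea-like strains, donors GC-rich
    bacteria-like strains; every strain carries one copy of ``family``.
    With ``transfer=True`` the recipients' copies carry the donor-like GC
    offset and an alien codon-usage table, and the gene tree places them
    inside the donor clade; with ``transfer=False`` the copies are native
    and the gene tree matches the organismal grouping.  Returns
    (profiles, trees, groups) ready for the verdict combiner, plus the truth
    tables.
    """
    from .composition import genome_profile
    from .homology import HomologHit
    from .phylo.inference import bootstrap_support

    rng = np.random.default_rng(seed)
    catalog = default_catalog(seed=int(rng.integers(2 ** 31)))
    recipients = [f"R{i}" for i in range(n_recipients)]
    donors = [f"B{i}" for i in range(n_donors)]
    profiles, truths = [], []
    groups: dict[str, str] = {}
    for sid in recipients + donors:
        is_recipient = sid.startswith("R")
        gc = (0.38 if is_recipient else 0.50) + float(rng.uniform(-0.015, 0.015))
        imp = ImplantSpec(family=family, copies=1,
                          gc_offset=(gc_offset if (transfer and is_recipient) else 0.0),
                          identity_to_ref=0.8,
                          cluster_positions=[orfs_per_strain // 2],
                          alien_bias=bool(transfer and is_recipient))
        spec = SimSpec(seed=int(rng.integers(2 ** 31)),
                       orfs_per_strain=orfs_per_strain, genome_gc_target=gc,
                       codon_bias_strength=0.3, implants=[imp])
        genome, truth = make_genome(spec, catalog, strain_id=sid,
                                    guild="AOA" if is_recipient else "NOB",
                                    habitat="terrestrial")
        hits = [HomologHit(strain_id=sid, orf=(t.replicon_id, t.ordinal),
                           family=t.family, score=0.0,
                           identity=t.realized_identity, coverage=1.0)
                for t in truth.implants]
        profiles.append(genome_profile(genome, hits, weights_mode="all_cds"))
        truths.append(truth)
        groups[sid] = "recipient" if is_recipient else "donor"

    gen_tree = lgt_gene_tree(recipients, donors, transfer)
    msa = evolve_alignment(gen_tree, SubstitutionModel(matrix="Poisson"),
                           n_sites, seed=int(rng.integers(2 ** 31)))
    rec_tree = bootstrap_support(msa, SubstitutionModel(matrix="Poisson"),
                                 n_reps=bootstrap_reps,
                                 seed=int(rng.integers(2 ** 31)))
    return profiles, {family: rec_tree}, groups, truths


def make_sav_panel(seed: int, n_strains: int = 12,
                   sav_per_copy: float = 3.0, noise_sd: float = 2.0):
    """Strain metadata whose SA/V rank-correlates with built-in dur3 copies.

    Cell diameters are back-computed from a target SA/V = 6 + slope*copies +
    noise (spherical cells), so the construction carries a known positive
    rank correlation.  Returns (copies per strain, metadata list).
    """
    rng = np.random.default_rng(seed)
    copies = [int(c) for c in rng.integers(0, 4, size=n_strains)]
    metadata = []
    for i, c in enumerate(copies):
        target = max(6.0 + sav_per_copy * c + float(rng.normal(0, noise_sd)), 1.0)
        metadata.append(StrainMetadata(
            strain_id=f"S{i:02d}", guild="AOA", habitat="marine",
            shape="sphere", widths=[6.0 / target], lengths=[]))
    return copies, metadata


def write_panel(panel: Panel, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for genome in panel.genomes:
        write_genbank(genome, os.path.join(out_dir, f"{genome.strain_id}.gbk"))
    write_catalog(panel.catalog, os.path.join(out_dir, "catalog.fasta"))
    with open(os.path.join(out_dir, "metadata.tsv"), "w") as fh:
        fh.write("strain_id\tguild\thabitat\tshape\twidths\tlengths\n")
        for m in panel.metadata:
            fh.write(f"{m.strain_id}\t{m.guild}\t{m.habitat}\t{m.shape}\t"
                     f"{';'.join(map(str, m.widths))}\t{';'.join(map(str, m.lengths))}\n")
    truth = {
        t.strain_id: {
            "genome_gc_target": t.genome_gc_target,
            "genome_gc_realized": t.genome_gc_realized,
            "copy_numbers": t.copy_numbers(),
            "implants": [vars(i) for i in t.implants],
        } for t in panel.truths}
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
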