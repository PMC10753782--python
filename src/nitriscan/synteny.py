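"""Gene-neighborhood analysis: interval-ORF distances and cluster reports.

The synteny distance between two genes is the number of annotated ORFs lying
strictly between them on the same replicon (adjacent genes -> 0).  Counting
annotation ordinals rather than base pairs keeps the metric robust to
intergenic-length variation and matches how gene-organization figures are
usually annotated.  On circular replicons the shorter way around is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: proximity class boundaries on the interval-ORF count
PROXIMITY_CLASSES = (
    ("adjacent", 0, 0),
    ("proximal", 1, 10),
    ("spaced", 11, 255),
    ("distant", 256, None),
)


@dataclass
class SyntenyDistance:
    strain_id: str
    family_a: str
    family_b: str
    orf_a: tuple[str, int]
    orf_b: tuple[str, int]
    interval_orfs: int | None
    same_replicon: bool


def classify_interval(interval_orfs: int) -> str:
    """Map an interval-ORF count to its proximity class (a partition)."""
    if interval_orfs < 0:
        raise ValueError("interval count must be non-negative")
    for name, lo, hi in PROXIMITY_CLASSES:
        if interval_orfs >= lo and (hi is None or interval_orfs <= hi):
            return name
    raise AssertionError("unreachable: classes partition the non-negative integers")


def interval_orf_count(genome, orf_a: tuple[str, int], orf_b: tuple[str, int],
                       family_a: str = "", family_b: str = "") -> SyntenyDistance:
    """ORFs strictly between two genes; symmetric; circular-aware.

    Cross-replicon pairs get ``same_replicon=False`` and an undefined (None)
    count.
    """
    a = genome.orf(orf_a)
    b = genome.orf(orf_b)
    if a.replicon_id != b.replicon_id:
        return SyntenyDistance(genome.strain_id, family_a, family_b,
                               orf_a, orf_b, None, False)
    gap = abs(a.ordinal - b.ordinal)
    interval = max(gap - 1, 0)
    rep = genome.replicon(a.replicon_id)
    if rep.circular:
        n = len(genome.orfs_on(a.replicon_id))
        wrap = max(n - gap - 1, 0)
        if gap > 0:
            interval = min(interval, wrap)
    return SyntenyDistance(genome.strain_id, family_a, family_b,
                           orf_a, orf_b, interval, True)


def cluster_report(hits, genome, pathway: str, catalog) -> pd.DataFrame:
    """Pathway gene neighborhood for one strain.

    Collects the strain's homolog hits whose family belongs to ``pathway``,
    orders them genomically (replicon, ordinal), and reports each consecutive
    pair with its interval-ORF count and proximity class — the textual
    analogue of a gene-organization diagram.  Consecutive hits on different
    replicons are emitted with class ``split`` and no count.
    """
    fam_pathway = {g.family: g.pathway for g in catalog}
    relevant = [h for h in hits
                if h.strain_id == genome.strain_id
                and fam_pathway.get(h.family) == pathway]
    relevant.sort(key=lambda h: h.orf)
    rows = []
    for h1, h2 in zip(relevant, relevant[1:]):
        d = interval_orf_count(genome, h1.orf, h2.orf, h1.family, h2.family)
        rows.append({
            "strain_id": genome.strain_id, "pathway": pathway,
            "family_a": h1.family, "family_b": h2.family,
            "replicon_a": h1.orf[0], "ordinal_a": h1.orf[1],
            "replicon_b": h2.orf[0], "ordinal_b": h2.orf[1],
            "interval_orfs": d.interval_orfs,
            "class": classify_interval(d.interval_orfs) if d.same_replicon else "split",
        })
    return pd.DataFrame(rows, columns=[
        "strain_id", "pathway", "family_a", "family_b", "replicon_a", "ordinal_a",
        "replicon_b", "ordinal_b", "interval_orfs", "class"])


def synteny_report(hits, genomes, catalog, pathways=None) -> pd.DataFrame:
    """Stack cluster reports over all strains and pathways."""
    if pathways is None:
        pathways = sorted({g.pathway for g in catalog})
    frames = [cluster_report(hits, g, p, catalog)
              for g in genomes for p in pathways]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return cluster_report([], genomes[0], "none", catalog) if genomes else pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
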