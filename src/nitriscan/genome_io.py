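"""Read annotated genomes and strain metadata into uniform records.

Genomes arrive either as GenBank flat files (CDS features with translations)
or as GFF3 + genomic FASTA.  Both routes produce the same :class:`GenomeRecord`
so every downstream stage (homolog scan, synteny, composition, LGT screen) is
agnostic to the on-disk encoding.  Coordinates are 1-based inclusive
throughout, following the GenBank/GFF3 convention; the synteny metric counts
annotation ordinals, not base pairs, so no half-open ambiguity can leak into
results.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .composition import gc_content

logger = logging.getLogger(__name__)

GUILDS = ("AOA", "AOB", "NOB", "comammox")
HABITATS = ("marine", "terrestrial")
SHAPES = ("sphere", "rod")

BACTERIAL_TABLE = 11


class GenomeIOError(ValueError):
    """Malformed genome input (parse errors, cross-reference failures)."""


class EmptyGenomeError(GenomeIOError):
    """Input contained no CDS features."""


@dataclass
class Replicon:
    replicon_id: str
    seq: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OrfFeature:
    """One annotated coding sequence.

    ``ordinal`` is the 0-based index of the ORF within its replicon in
    annotation order; it is the unit of the interval-ORF synteny distance.
    ``nt_seq`` is the stranded coding sequence (5'->3'), i.e. the reverse
    complement of the genomic slice for minus-strand features.
    """

    replicon_id: str
    ordinal: int
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # '+' or '-'
    nt_seq: str
    aa_seq: str
    label: str = ""

    @property
    def ref(self) -> tuple[str, int]:
        return (self.replicon_id, self.ordinal)


@dataclass
class GenomeRecord:
    strain_id: str
    guild: str
    habitat: str
    replicons: list[Replicon]
    orfs: list[OrfFeature]
    total_length: int = 0
    genome_gc: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_length:
            self.total_length = sum(len(r) for r in self.replicons)
        if not self.genome_gc and self.replicons:
            self.genome_gc = gc_content("".join(r.seq for r in self.replicons))

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def orf(self, ref: tuple[str, int]) -> OrfFeature:
        replicon_id, ordinal = ref
        for o in self.orfs:
            if o.replicon_id == replicon_id and o.ordinal == ordinal:
                return o
        raise KeyError(ref)

    def orfs_on(self, replicon_id: str) -> list[OrfFeature]:
        return [o for o in self.orfs if o.replicon_id == replicon_id]

    def validate(self) -> None:
        """Assert the record invariants; raises GenomeIOError on violation."""
        if self.total_length != sum(len(r) for r in self.replicons):
            raise GenomeIOError("total_length != sum of replicon lengths")
        by_rep: dict[str, list[OrfFeature]] = {}
        lens = {r.replicon_id: len(r) for r in self.replicons}
        for o in self.orfs:
            if o.end < o.start:
                raise GenomeIOError(f"ORF {o.ref}: end < start")
            if o.replicon_id not in lens:
                raise GenomeIOError(f"ORF {o.ref}: unknown replicon")
            if o.start < 1 or o.end > lens[o.replicon_id]:
                raise GenomeIOError(f"ORF {o.ref}: outside replicon bounds")
            by_rep.setdefault(o.replicon_id, []).append(o)
        for rid, orfs in by_rep.items():
            ords = [o.ordinal for o in orfs]
            if ords != list(range(len(orfs))):
                raise GenomeIOError(f"replicon {rid}: ordinals not dense 0..n-1")


@dataclass
class StrainMetadata:
    strain_id: str
    guild: str
    habitat: str
    shape: str
    widths: list[float] = field(default_factory=list)
    lengths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"unknown guild {self.guild!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if not self.widths or any(w <= 0 for w in self.widths):
            raise ValueError("widths must be non-empty and positive")
        if self.shape == "rod" and not self.lengths:
            raise ValueError("rod shape requires lengths")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("lengths must be positive")


def _translate(nt_seq: str) -> str:
    aa = str(Seq(nt_seq[: len(nt_seq) // 3 * 3]).translate(table=BACTERIAL_TABLE))
    return aa[:-1] if aa.endswith("*") else aa


def _parse_source_metadata(record) -> dict[str, str]:
    out: dict[str, str] = {}
    for feat in record.features:
        if feat.type == "source":
            if "strain" in feat.qualifiers:
                out["strain_id"] = feat.qualifiers["strain"][0]
            for note in feat.qualifiers.get("note", []):
                for tok in note.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        out[k] = v
    return out


def read_genbank(path: str, strain_id: str | None = None,
                 guild: str = "AOA", habitat: str = "terrestrial") -> GenomeRecord:
    """Parse a GenBank flat file into a :class:`GenomeRecord`.

    CDS features are taken in file order; features lacking a ``/translation``
    qualifier are translated with the bacterial code (table 11).  Guild and
    habitat default to the given arguments but are overridden by tokens
    ``guild=`` / ``habitat=`` found in a source-feature note (as written by
    :func:`write_genbank`).
    """
    replicons: list[Replicon] = []
    orfs: list[OrfFeature] = []
    meta: dict[str, str] = {}
    records = list(SeqIO.parse(path, "genbank"))
    if not records:
        raise GenomeIOError(f"{path}: no GenBank records found")
    if len(records) > 1:
        logger.warning("%s: %d contigs; genome may be a draft/MAG", path, len(records))
    for record in records:
        meta.update(_parse_source_metadata(record))
        topology = record.annotations.get("topology", "linear")
        replicons.append(Replicon(record.id, str(record.seq).upper(),
                                  circular=(topology == "circular")))
        ordinal = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            for part in feat.location.parts:
                if part.ref is not None:
                    raise GenomeIOError(
                        f"{record.id}: trans-spliced CDS at {feat.location} not supported")
            try:
                nt = str(feat.extract(record.seq)).upper()
            except Exception as exc:  # pragma: no cover - biopython detail
                raise GenomeIOError(f"{record.id}: cannot extract CDS {feat.location}: {exc}")
            aa = feat.qualifiers.get("translation", [None])[0] or _translate(nt)
            strand = "-" if feat.location.strand == -1 else "+"
            orfs.append(OrfFeature(
                replicon_id=record.id, ordinal=ordinal,
                start=int(feat.location.start) + 1, end=int(feat.location.end),
                strand=strand, nt_seq=nt, aa_seq=aa,
                label=feat.qualifiers.get("product", [""])[0]))
            ordinal += 1
    if not orfs:
        raise EmptyGenomeError(f"{path}: no CDS features")
    rec = GenomeRecord(
        strain_id=meta.get("strain_id") or strain_id or os.path.splitext(os.path.basename(path))[0],
        guild=meta.get("guild", guild), habitat=meta.get("habitat", habitat),
        replicons=replicons, orfs=orfs)
    rec.validate()
    return rec


def read_gff_fasta(gff_path: str, fasta_path: str, strain_id: str | None = None,
                   guild: str = "AOA", habitat: str = "terrestrial") -> GenomeRecord:
    """Parse GFF3 CDS features plus a genomic FASTA; same contract as
    :func:`read_genbank`.  GFF3 1-based inclusive coordinates are preserved."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    if not seqs:
        raise GenomeIOError(f"{fasta_path}: no sequences")
    db = gffutils.create_db(gff_path, dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    replicons = [Replicon(rid, seq) for rid, seq in seqs.items()]
    orfs: list[OrfFeature] = []
    counters: dict[str, int] = {rid: 0 for rid in seqs}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in seqs:
            raise GenomeIOError(
                f"{gff_path}: CDS references {feat.seqid!r} absent from FASTA")
        seq = seqs[feat.seqid]
        if feat.start < 1 or feat.end > len(seq):
            raise GenomeIOError(
                f"{gff_path}: CDS {feat.start}..{feat.end} outside {feat.seqid} "
                f"(length {len(seq)})")
        nt = seq[feat.start - 1: feat.end]
        if feat.strand == "-":
            nt = str(Seq(nt).reverse_complement())
        label = ""
        for key in ("product", "Name", "ID"):
            if key in feat.attributes:
                label = feat.attributes[key][0]
                break
        orfs.append(OrfFeature(
            replicon_id=feat.seqid, ordinal=counters[feat.seqid],
            start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            nt_seq=nt, aa_seq=_translate(nt), label=label))
        counters[feat.seqid] += 1
    if not orfs:
        raise EmptyGenomeError(f"{gff_path}: no CDS features")
    rec = GenomeRecord(
        strain_id=strain_id or os.path.splitext(os.path.basename(fasta_path))[0],
        guild=guild, habitat=habitat, replicons=replicons, orfs=orfs)
    rec.validate()
    return rec


def _parse_dims(cell: str) -> list[float]:
    cell = (cell or "").strip()
    if not cell:
        return []
    return [float(tok) for tok in cell.split(";") if tok.strip()]


def read_metadata(path: str) -> list[StrainMetadata]:
    """Parse the strain metadata table (TSV or CSV).

    Required columns: strain_id, guild, habitat, shape, widths, lengths;
    widths/lengths are semicolon-separated micrometre values.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise GenomeIOError(f"{path}: empty metadata table")
    sep = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(sep)]
    required = ["strain_id", "guild", "habitat", "shape", "widths", "lengths"]
    missing = [c for c in required if c not in header]
    if missing:
        raise GenomeIOError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in required}
    out = []
    for ln in lines[1:]:
        cells = ln.split(sep)
        out.append(StrainMetadata(
            strain_id=cells[idx["strain_id"]].strip(),
            guild=cells[idx["guild"]].strip(),
            habitat=cells[idx["habitat"]].strip(),
            shape=cells[idx["shape"]].strip(),
            widths=_parse_dims(cells[idx["widths"]]),
            lengths=_parse_dims(cells[idx["lengths"]]) if idx["lengths"] < len(cells) else []))
    return out


def write_genbank(genome: GenomeRecord, path: str) -> None:
    """Emit a GenomeRecord as a GenBank flat file; read_genbank round-trips it.

    Output is deterministic (fixed LOCUS date) so identical records produce
    byte-identical files.
    """
    records = []
    for i, rep in enumerate(genome.replicons):
        rec = SeqRecord(Seq(rep.seq), id=rep.replicon_id, name=rep.replicon_id[:16],
                        description=f"{genome.strain_id} replicon {rep.replicon_id}")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if rep.circular else "linear"
        rec.annotations["date"] = "01-JAN-2000"
        source = SeqFeature(FeatureLocation(0, len(rep.seq)), type="source")
        source.qualifiers["strain"] = [genome.strain_id]
        source.qualifiers["note"] = [f"guild={genome.guild} habitat={genome.habitat}"]
        rec.features.append(source)
        for orf in genome.orfs_on(rep.replicon_id):
            loc = FeatureLocation(orf.start - 1, orf.end,
                                  strand=-1 if orf.strand == "-" else 1)
            feat = SeqFeature(loc, type="CDS")
            feat.qualifiers["locus_tag"] = [f"{genome.strain_id}_{i}_{orf.ordinal:05d}"]
            if orf.label:
                feat.qualifiers["product"] = [orf.label]
            feat.qualifiers["transl_table"] = [str(BACTERIAL_TABLE)]
            feat.qualifiers["translation"] = [orf.aa_seq]
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def write_gff_fasta(genome: GenomeRecord, gff_path: str, fasta_path: str) -> None:
    """Emit the genome as GFF3 + FASTA (the alternate input encoding)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {len(rep)}\n")
        for orf in genome.orfs:
            attrs = f"ID=cds-{orf.replicon_id}-{orf.ordinal}"
            if orf.label:
                attrs += f";product={orf.label}"
            fh.write(f"{orf.replicon_id}\tnitriscan\tCDS\t{orf.start}\t{orf.end}\t.\t"
                     f"{orf.strand}\t0\t{attrs}\n")
    with open(fasta_path, "w") as fh:
        for rep in genome.replicons:
            fh.write(f">{rep.replicon_id}\n")
            for i in range(0, len(rep.seq), 70):
                fh.write(rep.seq[i:i + 70] + "\n")


def write_summary(genomes: list[GenomeRecord], path: str) -> None:
    """Per-genome summary TSV: strain, guild, habitat, ORF count, length, GC."""
    with open(path, "w") as fh:
        fh.write("strain_id\tguild\thabitat\tn_orfs\ttotal_length_bp\tgc_fraction\n")
        for g in genomes:
            fh.write(f"{g.strain_id}\t{g.guild}\t{g.habitat}\t{len(g.orfs)}\t"
                     f"{g.total_length}\t{g.genome_gc:.6f}\n")
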