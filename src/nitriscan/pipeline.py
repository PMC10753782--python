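"""End-to-end orchestration: scan -> synteny -> composition -> stats -> LGT
-> phylogenetics -> morphometrics, from a single config.

Every output is a TSV (or newick) with a header comment carrying the seed and
a hash of the configuration, so re-running an identical config reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import genome_profile, write_composition_tsv
from .genome_io import GenomeRecord, read_genbank, read_metadata, write_summary
from .homology import copy_number_matrix, find_homologs, read_catalog
from .lgt import lgt_verdicts, verdicts_table
from .morphometrics import sav_table
from .phylo import Msa, SubstitutionModel, bootstrap_support
from .stats import kruskal_dunn, t_test
from .synteny import synteny_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genomes: list[str]              # GenBank paths or glob patterns
    metadata: str
    catalog: str
    out_dir: str
    id_min: float = 0.40
    cov_min: float = 0.50
    alpha: float = 0.05
    bootstrap_reps: int = 1000
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "scan", "synteny", "composition", "groups", "lgt", "phylo", "morph"])

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (f"# nitriscan {__version__} seed={config.seed} "
            f"config={config.config_hash()}\n")


def _write_tsv(df: pd.DataFrame, path: str, config: RunConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", **kw)


def group_compare(values: dict[str, float], groups: dict[str, str],
                  method: str = "kruskal_dunn") -> pd.DataFrame:
    """Omnibus + pairwise comparisons of a per-strain quantity across groups.

    Groups with fewer than 2 members are skipped with a notice.  Each group
    row echoes range, median and n; test rows carry statistic and p.
    """
    by_group: dict[str, list[float]] = {}
    for strain, v in values.items():
        g = groups.get(strain)
        if g is not None and np.isfinite(v):
            by_group.setdefault(g, []).append(v)
    usable = {g: vs for g, vs in by_group.items() if len(vs) >= 2}
    for g in set(by_group) - set(usable):
        logger.info("group %s has <2 members; skipped", g)
    rows = []
    for g in sorted(usable):
        vs = sorted(usable[g])
        rows.append({"kind": "group", "name": g, "statistic": np.nan,
                     "p_value": np.nan,
                     "range": f"{vs[0]:.4g}-{vs[-1]:.4g}",
                     "median": float(np.median(vs)), "n": len(vs)})
    labels = sorted(usable)
    if len(labels) >= 2:
        samples = [np.asarray(usable[g]) for g in labels]
        if method == "ttest" and len(labels) == 2:
            res = t_test(samples[0], samples[1])
            rows.append({"kind": "test", "name": f"t:{labels[0]}|{labels[1]}",
                         "statistic": res.statistic, "p_value": res.p_value,
                         "range": "", "median": np.nan, "n": sum(len(s) for s in samples)})
        else:
            omnibus, pairwise = kruskal_dunn(samples, labels)
            rows.append({"kind": "test", "name": "Kruskal-Wallis",
                         "statistic": omnibus.statistic, "p_value": omnibus.p_value,
                         "range": "", "median": np.nan, "n": sum(len(s) for s in samples)})
            for res in pairwise:
                a, b = res.extra["pair"]
                rows.append({"kind": "test", "name": f"Dunn:{a}|{b}",
                             "statistic": res.statistic, "p_value": res.p_value,
                             "range": "", "median": np.nan, "n": sum(res.n)})
    return pd.DataFrame(rows, columns=["kind", "name", "statistic", "p_value",
                                       "range", "median", "n"])


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _load_genomes(config: RunConfig) -> list[GenomeRecord]:
    paths: list[str] = []
    for pattern in config.genomes:
        hits = sorted(glob.glob(pattern))
        paths.extend(hits if hits else [pattern])
    genomes = [read_genbank(p) for p in paths]
    if not genomes:
        raise FileNotFoundError("no genomes matched the config patterns")
    return genomes


def run_all(config: RunConfig) -> dict[str, str]:
    """Execute the configured stages; returns {output name: path}.

    Any stage failure aborts with a stage-named diagnostic; outputs written
    before the failure remain on disk and are listed in the manifest as
    partial.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "load"
    try:
        genomes = _load_genomes(config)
        metadata = read_metadata(config.metadata)
        catalog = read_catalog(config.catalog)
        path = os.path.join(config.out_dir, "genome_summary.tsv")
        write_summary(genomes, path)
        outputs["genome_summary"] = path
        guild_of = {m.strain_id: m.guild for m in metadata}
        habitat_of = {m.strain_id: m.habitat for m in metadata}

        hits = []
        if "scan" in config.stages:
            stage = "scan"
            logger.info("scan: %d genomes x %d families", len(genomes), len(catalog))
            for g in genomes:
                hits.extend(find_homologs(g, catalog, id_threshold=config.id_min,
                                          cov_threshold=config.cov_min))
            matrix = copy_number_matrix(hits, [g.strain_id for g in genomes],
                                        [c.family for c in catalog])
            path = os.path.join(config.out_dir, "copy_numbers.tsv")
            with open(path, "w") as fh:
                fh.write(_header(config))
                matrix.table.to_csv(fh, sep="\t", index_label="strain_id")
            outputs["copy_numbers"] = path

        if "synteny" in config.stages and hits:
            stage = "synteny"
            logger.info("synteny report")
            report = synteny_report(hits, genomes, catalog)
            path = os.path.join(config.out_dir, "synteny.tsv")
            _write_tsv(report, path, config)
            outputs["synteny"] = path

        profiles = []
        if "composition" in config.stages:
            stage = "composition"
            logger.info("composition profiles")
            profiles = [genome_profile(g, hits) for g in genomes]
            path = os.path.join(config.out_dir, "composition.tsv")
            tmp = path + ".body"
            write_composition_tsv(profiles, tmp)
            with open(tmp) as src, open(path, "w") as dst:
                dst.write(_header(config))
                dst.write(src.read())
            os.remove(tmp)
            outputs["composition"] = path

        if "groups" in config.stages:
            stage = "groups"
            logger.info("group comparisons")
            frames = []
            length = {g.strain_id: float(g.total_length) for g in genomes}
            gc = {g.strain_id: g.genome_gc for g in genomes}
            savs = sav_table(metadata).set_index("strain_id")["sav_per_um"].to_dict()
            for qty, vals in (("genome_length_bp", length), ("genome_gc", gc),
                              ("sav_per_um", savs)):
                df = group_compare(vals, guild_of)
                df.insert(0, "quantity", qty)
                df.insert(1, "partition", "guild")
                frames.append(df)
                df = group_compare(vals, habitat_of, method="ttest")
                df.insert(0, "quantity", qty)
                df.insert(1, "partition", "habitat")
                frames.append(df)
            path = os.path.join(config.out_dir, "group_comparison.tsv")
            _write_tsv(pd.concat(frames, ignore_index=True), path, config)
            outputs["group_comparison"] = path

        trees = {}
        if "phylo" in config.stages and hits:
            stage = "phylo"
            fam_hits: dict[str, list] = {}
            for h in hits:
                fam_hits.setdefault(h.family, []).append(h)
            genome_of = {g.strain_id: g for g in genomes}
            tree_dir = os.path.join(config.out_dir, "trees")
            os.makedirs(tree_dir, exist_ok=True)
            for family, fh_list in sorted(fam_hits.items()):
                if len(fh_list) < 4:
                    continue
                labels, seqs = [], []
                for h in fh_list:
                    label = h.strain_id if sum(
                        1 for x in fh_list if x.strain_id == h.strain_id) == 1 \
                        else f"{h.strain_id}.{h.orf[1]}"
                    labels.append(label)
                    seqs.append(genome_of[h.strain_id].orf(h.orf).aa_seq)
                msa = _pad_alignment(labels, seqs)
                logger.info("phylo: %s (%d sequences)", family, len(labels))
                model = SubstitutionModel(matrix="LG")
                tree = bootstrap_support(msa, model, n_reps=config.bootstrap_reps,
                                         seed=config.seed)
                trees[family] = tree
                tree.write(os.path.join(tree_dir, f"{family}.nwk"))
            outputs["trees"] = tree_dir

        if "lgt" in config.stages and profiles:
            stage = "lgt"
            logger.info("LGT screen")
            groups_map = {m.strain_id: f"{m.habitat} {m.guild}" for m in metadata}
            verdicts = lgt_verdicts(profiles, trees, groups_map, alpha=config.alpha)
            path = os.path.join(config.out_dir, "lgt_verdicts.tsv")
            _write_tsv(verdicts_table(verdicts), path, config)
            outputs["lgt_verdicts"] = path

        if "morph" in config.stages:
            stage = "morph"
            path = os.path.join(config.out_dir, "morphometrics.tsv")
            _write_tsv(sav_table(metadata), path, config)
            outputs["morphometrics"] = path

        manifest = {"version": __version__, "seed": config.seed,
                    "config": asdict(config), "config_hash": config.config_hash(),
                    "outputs": outputs, "partial": False}
    except Exception as exc:
        manifest = {"version": __version__, "seed": config.seed,
                    "config": asdict(config), "config_hash": config.config_hash(),
                    "outputs": outputs, "partial": True, "failed_stage": stage}
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise StageError(stage, exc) from exc
    path = os.path.join(config.out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    outputs["manifest"] = path
    return outputs


def _pad_alignment(labels: list[str], seqs: list[str]) -> Msa:
    """Pad unaligned homolog sequences to equal length with terminal gaps.

    A stand-in for an external multiple aligner: family members recovered at
    >=40% identity are largely collinear, so terminal padding yields a usable
    (if conservative) alignment for tree building.
    """
    width = max(len(s) for s in seqs)
    return Msa(labels, [s.ljust(width, "-") for s in seqs])
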