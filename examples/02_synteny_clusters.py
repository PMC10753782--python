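"""Gene-neighborhood report: interval-ORF distances in an implanted cluster.

Implants a urease-like cassette (ureA, ureC adjacent; utp two ORFs away;
dur3 far downstream) and prints the consecutive-pair report with interval
counts and proximity classes.
"""

from nitriscan.homology import find_homologs
from nitriscan.simulate import ImplantSpec, SimSpec, default_catalog, make_genome
from nitriscan.synteny import cluster_report

catalog = [g for g in default_catalog(seed=42)
           if g.family in {"ureA", "ureC", "utp", "dur3"}]
spec = SimSpec(seed=3, orfs_per_strain=60, genome_gc_target=0.42, implants=[
    ImplantSpec("ureA", identity_to_ref=0.8, cluster_positions=[10]),
    ImplantSpec("ureC", identity_to_ref=0.8, cluster_positions=[11]),
    ImplantSpec("utp", identity_to_ref=0.8, cluster_positions=[14]),
    ImplantSpec("dur3", identity_to_ref=0.8, cluster_positions=[45]),
])
genome, _ = make_genome(spec, catalog, strain_id="DEMO")
hits = find_homologs(genome, catalog)
report = cluster_report(hits, genome, "urea", catalog)
print(report.to_string(index=False))
print("\nInterval counts are ORFs strictly between consecutive pathway genes:"
      "\nureA-ureC adjacent (0), ureC-utp proximal (2), utp-dur3 spaced (30).")
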