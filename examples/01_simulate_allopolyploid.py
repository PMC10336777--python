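"""Simulate a three-subgenome allopolyploid and inspect its divergence.

Builds genomes in which the 3' UTR diverges faster than the CDS -- the
asymmetry that makes 3' tag reads subgenome-informative -- and measures the
realized substitution rates against the common ancestor.
"""

from polyhomeo3 import sim

# indel_rate=0 so a positional (Hamming) comparison measures the
# substitution rate directly; the default also applies small UTR indels
genomes = sim.simulate_subgenomes(
    sim.SimConfig(n_genes=50, cds_divergence=0.01, utr_divergence=0.05,
                  indel_rate=0.0, seed=1)
)

cds_len = genomes.config.cds_len
for label in genomes.labels:
    cds_diffs, utr_diffs, utr_sites = 0, 0, 0
    for s in genomes.structures[label]:
        anc = genomes.ancestor_transcripts[s.ancestral_index]
        cds_diffs += sum(a != b for a, b in zip(s.transcript[:cds_len], anc[:cds_len]))
        pairs = list(zip(s.transcript[cds_len:], anc[cds_len:]))
        utr_diffs += sum(a != b for a, b in pairs)
        utr_sites += len(pairs)
    print(
        f"subgenome {label}: CDS divergence {cds_diffs / (50 * cds_len):.4f}, "
        f"3' UTR divergence {utr_diffs / utr_sites:.4f}"
    )

# The printed per-site rates sit near the nominal 0.01 (CDS) and 0.05 (UTR):
# each subgenome lineage accumulated mutations independently, five-fold
# faster in the UTR, so homeolog discrimination is concentrated at the 3' end.
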