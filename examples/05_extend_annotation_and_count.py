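"""Show why 3'-ward annotation extension matters for 3' tag counting.

The annotation is truncated at the CDS (emulating missing 3' UTR
annotation); 3'-anchored reads then fall outside every gene.  Extending each
gene's 3' boundary -- stopping before the next same-strand gene -- recovers
them.
"""

from polyhomeo3 import aligner, sim
from polyhomeo3.annotation import extend_three_prime
from polyhomeo3.expression import compare_annotations, count_reads

genomes = sim.simulate_subgenomes(sim.SimConfig(n_genes=40, utr3_len=300, seed=7))
truncated = sim.truncate_utr_annotation(genomes, truncate_bp=300)

reads, _ = sim.simulate_3prime_reads(genomes, sim.ReadSimConfig(n_reads=5000, seed=8))
index = aligner.build_index(genomes.references)
calls = aligner.map_reads(index, reads)
unique = [c.record for c in calls if c.status == "unique"]

counts_trunc = count_reads(unique, truncated, annotation_tag="truncated")
extended = extend_three_prime(truncated, 500, genomes.chrom_lengths)
counts_ext = count_reads(unique, extended, annotation_tag="extended+500")

report = compare_annotations(counts_trunc, counts_ext)
print(f"assigned fraction, truncated annotation: {report['assigned_fraction_base']:.3f}")
print(f"assigned fraction, extended annotation:  {report['assigned_fraction_ext']:.3f}")
print(f"genes detected: {report['detected_base']} -> {report['detected_ext']}")
print(f"per-gene classes: {report['n_increased']} increased, "
      f"{report['n_same']} same, {report['n_decreased']} decreased")

# 3' tag reads sit in the UTR, so a CDS-only annotation assigns (almost)
# nothing; a uniform 3' extension recovers nearly every read while the
# same-strand collision rule keeps neighboring genes distinct.
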