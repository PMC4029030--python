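"""Build a self-contained synthetic benchmark.

Generates a 200 kb genome carrying a 2 kb segmental duplication at 95%
identity, implants three deletions into a donor haplotype, simulates 30x
Illumina-like paired-end reads (insert 300 +/- 30, cycle-dependent errors),
and writes FASTA + BAM + candidate BEDPE + truth table.  The three "decoy"
candidates join homologous positions of the two duplication copies — the
classic repeat artifact that discordant-pair callers report as a deletion.
"""

from svrescore.simulate import SimConfig, make_benchmark

cfg = SimConfig(seed=7)
paths, truth = make_benchmark(cfg, "scratch/benchmark")

print(f"reference : {paths.fasta}")
print(f"reads     : {paths.bam}")
print(f"candidates: {paths.bedpe}")
print(f"truth     : {paths.truth_tsv}")
print()
for t in truth:
    c = t.candidate
    print(f"{c.id:7s} {t.label:8s} {c.side5.contig}:{c.side5.position}"
          f"({c.side5.orientation}) -> {c.side3.contig}:{c.side3.position}"
          f"({c.side3.orientation})")
# Each line is one candidate junction; 'true_sv' rows are implanted
# deletions, 'decoy' rows join the two copies of the duplication.
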