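# svrescore

Probability-based rescoring and visualization of candidate structural
variants (SVs).

Discordant-pair SV callers flag a rearrangement wherever read-pairs map
with unexpected distance or orientation — and are notoriously fooled by
segmental duplications, where reads from one copy mis-map to the other.
`svrescore` takes a caller's candidate list (BEDPE), the alignments (BAM)
and the reference (FASTA), and re-evaluates every candidate generatively:
the supporting read-pairs are realigned to **three references** — one
containing the rearranged junction, and one contiguous reference around
each breakpoint — and the candidate is scored by the natural-log
likelihood ratio

```
L = log p_sv − max(log p_c5, log p_c3)
```

where each `log p` is a product of per-read-cycle binomials
`B(m_p; l_p, err_mm(p)) · B(i_p; l_p, err_ind(p))` over the mismatch and
indel counts observed in that alignment configuration, with
position-specific error rates `err_mm(p)`, `err_ind(p)` estimated from
concordant read-pairs of the same experiment. `L > 0` favours a real
junction; homology-driven artifacts score negative because their reads fit
one contiguous copy better than the joined sequence. Recommended pass
cutoff: `L ≥ 100` (170 for target-capture libraries). Candidates can be
pre-filtered by support (≥ 5 read-pairs, mean edit distance < 2.6, target
overlap), and every candidate can be rendered as a three-panel alignment
picture (one read-pair per row; gray bars, black 3′-end caps, red
mismatches, light-blue deletions/split-reads) for visual triage.

## Worked example

Everything is runnable from a seed — no downloads. The scripts in
`examples/` build a synthetic benchmark (200 kb genome, a 2 kb segmental
duplication at 95% identity, three implanted deletions, three decoy
junctions joining the duplication copies, 30× paired-end coverage) and push
it through the pipeline:

```
python examples/01_simulate_benchmark.py
python examples/02_error_profile.py
python examples/03_score_candidates.py
```

The scoring step prints:

```
id       label    pairs split     score  status
del3     true_sv     39    19   10773.0  pass
del1     true_sv     33    15    8963.4  pass
del2     true_sv     31    16    8792.9  pass
decoy2   decoy       14     0    -197.3  fail
decoy1   decoy       16     0    -242.5  fail
decoy3   decoy       15     0    -243.8  fail
```

Each implanted deletion is supported by ~30 read-pairs of which roughly
half are split-reads crossing the junction; the rearranged reference
explains them with nothing but sequencing error, so `L` is in the
thousands. The decoys — deletion-signature junctions between the two 95%
identical duplication copies — score negative: their reads fit the
contiguous 5′ copy perfectly, while the joined reference forces ~5%
mismatch on half of each pair. Ranking by score separates the two classes
perfectly. `examples/04_visualize.py` renders the three-panel pictures for
`del1` and `decoy1`.

The same workflow is available as a thin CLI:

```
svrescore simulate --outdir bench --seed 7
svrescore estimate-errors --bam bench/reads.bam --fasta bench/ref.fa --out profile.tsv
svrescore score --bedpe bench/candidates.bedpe --bam bench/reads.bam \
                --fasta bench/ref.fa --profile profile.tsv --outdir out
svrescore view  --bedpe bench/candidates.bedpe --bam bench/reads.bam \
                --fasta bench/ref.fa --profile profile.tsv --outdir out --format png
```

`score` writes `scores.tsv` sorted by score (the prioritization order) and
caches its realignments so `view` does not realign.

## Layout

```
src/svrescore/
  candidates.py   BEDPE parsing, support filters, read-pair/window retrieval
  references.py   per-candidate reference triple construction
  realign.py      Gotoh alignment kernels, per-cycle tallies
  errors.py       concordant-pair sampling, per-cycle error profile
  scoring.py      binomial model and the likelihood score
  plotting.py     glyph manifest + three-panel renderer
  simulate.py     synthetic genome / read / benchmark generator
  pipeline.py     high-level wiring and realignment cache
  cli.py          the `svrescore` command
docs/methods.md   model, assumptions, conventions, limitations
```

See `docs/methods.md` for the model's assumptions, the tally conventions
(why clipped bases count as mismatches), the error-profile estimator, and
what the synthetic benchmark does and does not emulate.
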