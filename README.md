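# ripersist

Quantify **intron persistence** from spliced long-read alignments and
benchmark short-read retained-intron (RI) callers against the resulting
persistent-intron sets. Ships with a synthetic splicing simulator so the
whole pipeline runs end to end with no external data.

## What it computes

**Persistence.** For an intron *i* of transcript *t* with at least 5
assigned long reads,

```
P_it = d_i * sum over reads r spanning i of [ R(r,i) * SF(r,i) * H(r,i) ] / D
```

* `d_i` — information density: fraction of assigned reads covering *i*
* `R(r,i)` — 1 iff read *r* wholly contains (retains) the intron
* `SF(r,i)` — spliced fraction of the read, target excluded (splicing progression)
* `H(r,i)` — scaled Hamming similarity of the read's splicing pattern to
  other reads with the same state at *i* (pattern concordance)
* `D` — number of assigned reads (default) or of spanning reads
  (`--mean-denominator spanning`)

Gene-level persistence is `P_i = max_t P_it` over isoforms containing the
intron; an intron is *persistent* when `P_i >= 0.1`.

**Benchmarking.** Short-read caller outputs (scored interval TSVs) are
harmonized onto the long-read intron ranges with length-weighted medians
(LWM), converted to boolean calls with per-tool threshold rules
(IRFinder-S, superintronic, iREAD, KMA, IntEREst, MAJIQ, rMATS, SUPPA2),
and scored as TP/FP/FN/TN against the persistent set. Summaries include
precision/recall/F1, a persistence-threshold sweep (0.1–0.9),
Fleiss' kappa inter-tool agreement, cross-tool consensus counts,
sliding intron-length-window performance (41 windows by default), and
1000-bin intron coverage / exon-overlap profiles.

## Command line

```sh
# synthetic dataset with ground truth
ripersist simulate --out-dir sim/ --seed 42

# intron features from annotation (+ optional genome / U2/U12 BEDs)
ripersist annotate --annotation sim/annotation.gtf --genome sim/genome.fa --out-dir out/

# read assignment + persistence
ripersist persist --annotation sim/annotation.gtf \
    --long-reads sim/long_reads.tsv --coverage sim/coverage.bedgraph \
    --out-dir out/

# score mock callers against persistent introns
ripersist benchmark --annotation sim/annotation.gtf \
    --long-reads sim/long_reads.tsv --coverage sim/coverage.bedgraph \
    --caller-dir sim/callers --out-dir out/

# all of the above in one deterministic run
ripersist run-all --config configs/default.yaml --out-dir run/ --seed 42
```

`--long-reads` accepts SAM/BAM or the plain-text fixture TSV
(`read_id chrom strand span_start span_end chain`). Options can also be
given in a YAML config (`--config`); explicit flags win. Every output
table starts with a provenance header line carrying the package version
and a configuration hash, and is written atomically.

## Package layout

| module | contents |
| --- | --- |
| `ripersist.intervals` | interval primitives, interval index, BED reader |
| `ripersist.annotation` | GTF parsing, intron derivation, intron features (length, GC, position, exon overlap, motif, spliceosome class) |
| `ripersist.longreads` | intron-chain extraction, best-match transcript assignment, retention matrices, target-gene selection |
| `ripersist.persistence` | information density, spliced fraction, Hamming similarity, P_it / P_i |
| `ripersist.benchmark` | LWM harmonization, call rules, truth categories, performance, kappa, consensus, binned summaries |
| `ripersist.coverage` | bedGraph-backed per-base coverage tracks |
| `ripersist.simulate` | synthetic genome/annotation/read/coverage/caller generators |
| `ripersist.pipeline` | stage orchestration used by the CLI and tests |
| `ripersist.cli` | `ripersist` entry point |
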