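# biasbench

Measure, categorize, predict and scan for **reference bias** in short-read
alignments of diploid genomes.

Reference bias is the tendency of read alignment to favor reads carrying the
reference allele, depressing observed ALT support at heterozygous (HET)
sites. biasbench quantifies it at three pipeline stages and localizes it
without any foreknowledge when needed:

- **simulate mode** — with truth-tagged simulated reads, computes three
  allelic-balance measures per HET site: simulation balance (SB), mapping
  balance (MB) and assignment balance (AB). Their differences
  (NMB = MB − SB, NAB = AB − SB) isolate the bias introduced by mapping and
  by evidence tallying, and a geometric classifier labels each site
  *balanced*, *loss*, *flux*, *local* or *outlier*.
- **predict mode** — with real reads and a phased VCF, ranks HET sites by
  predicted bias from two features (average MAPQ and context-aware AB) using
  two published score forms, after filtering phasing-artifact sites.
- **scan / compare mode** — reference-free: windowed read-depth, SNV-density
  and non-diploid Z-scores over a pileup call *biased* (score ≥ 5) and
  *suspicious* (score in [3, 5)) regions, chain nearby regions, and compare
  two alignment workflows under one jointly sampled baseline.

Two read-to-haplotype assignment algorithms are included: a **naive** method
that trusts the aligner's base-level placement, and a **context-aware**
method that searches read sequences for REF/ALT alleles embedded in phased
flanking sequence, anchored at either variant boundary so gap-placement
ambiguity in tandem repeats cannot flip the call. Variants inside repeats
are extended to an *effective variant*; nearby variants are clustered into
*cohorts* and assigned jointly.

Everything needed for testing is generated internally (random reference,
phased VCF, diploid consensus with exact coordinate maps, truth-tagged
paired-end simulator, idealized aligner, and bias injectors for
loss/flux/local/duplication scenarios) — no downloads.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis) for
the geometric classifier and interval logic, and `tests/test_acceptance.py`
with end-to-end criteria on a ~1 Mbp / ~2,000-HET / 30× synthetic fixture
(exact MB = SB and AB = SB identities under perfect alignment, assignment
oracle agreement, gap-shift robustness, category recovery, predictor AUC,
scan calibration/detection, comparison thresholds, determinism). The full
run takes ~2 minutes on one CPU.

## CLI

```sh
# truth-tagged simulation analysis (internal simulator + idealized aligner,
# or supply --bam + --truth for external alignments)
biasbench simulate --reference ref.fa --vcf donor.vcf --out-dir out/

# rank HET sites by predicted bias from a real BAM
biasbench predict --reference ref.fa --vcf donor.vcf --bam aln.bam \
    --max-mapq 42 --out-dir out/

# reference-free region scan (BAM or samtools-style mpileup text)
biasbench scan --bam aln.bam --out-dir out/
biasbench scan --mpileup aln.mpileup --bed features.bed --out-dir out/

# compare two alignment workflows with one joint baseline
biasbench compare --bam workflowA.bam --bam2 workflowB.bam --out-dir out/
```

Outputs are TSV/BED/JSON: per-site balance table (`balance.tsv`), category
table and summary, indel-balance strata, ranked prediction table, per-window
scores, biased/suspicious BEDs, comparison report, and a `provenance.json`
capturing the full configuration and seeds (identical seeds reproduce
byte-identical outputs). `--help` on any subcommand lists every knob
(flank length, cohort distance, effective-variant cap, classifier radius and
slopes, window/step, thresholds, chain gap, sample fraction, ...), all
defaulting to the published values.

## Package layout

| module | contents |
|---|---|
| `biasbench.core` | intervals, CIGAR walking, alignment record |
| `biasbench.variants` | phased VCF parsing, overlap removal, cohorts |
| `biasbench.fixtures` | synthetic reference/VCF/consensus/reads, perfect aligner, bias injectors |
| `biasbench.assignment` | naive + context-aware assignment, effective variants, anchoring |
| `biasbench.balance` | SB/MB/AB, NMB/NAB, indel-length strata |
| `biasbench.classify` | bias-category geometry, summaries, NMB–NAB plot |
| `biasbench.predict` | two-feature scores, affected-HET filter, ROC/PR |
| `biasbench.scan` | pileups, windowed Z-scores, region calling, comparison |
| `biasbench.io` | FASTA/FASTQ/VCF/SAM/BED/TSV boundaries |
| `biasbench.cli` | `biasbench simulate|predict|scan|compare` |
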