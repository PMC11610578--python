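# drrkit

Reference genomes are not interchangeable: hundreds of megabases of sequence
present in one human or great-ape assembly are absent from another, and
structural-variant breakpoints — inversions in particular — often land exactly
in those regions. `drrkit` is a toolkit for quantifying and characterizing
this reference variability and for dissecting inversion breakpoint junctions:

* **DRR calling** — a *differential reference region* (DRR) is a segment of a
  template genome, strictly larger than 10 kbp, that a query genome does not
  cover in a pairwise whole-genome alignment (PAF), after excluding known
  assembly gaps. Coverage, complement, gap subtraction and size filtering use
  exact per-base interval arithmetic.
* **Annotation** — repeat composition per RepeatMasker class (the union of
  features governs the total, so fractions are exact and "100% repetitive"
  means full tiling), centromere proximity within a 10 kbp window, and
  segmental-duplication overlap.
* **Population presence** — per short-read sample, the length-weighted mean
  depth across a DRR classifies it as present (strictly between 8× and 100×),
  absent (≤8×) or no-call (≥100×, collapsed repeat); per cohort a DRR is
  not-detected, rare (≤5% of samples) or common (>5%), with a high-frequency
  flag above 90%. Read summaries report the fraction of reads above MAPQ 20
  and the multimapping fraction.
* **Breakpoint junctions** — given a derivative sequence and its two oriented
  reference flanks, maximal exact extension resolves microhomology
  (`b_start < a_end`), insertion (`b_start > a_end`, classified templated vs
  random against ±1 kbp reference windows) or a blunt joint, and a rule
  cascade infers the likely repair mechanism: NAHR → complex MMBIR (≥3
  junctions) → MMBIR (≥100 bp junction unbalance) → MMEJ (≥2 bp
  microhomology) → NHEJ.
* **Synthetic data** — a seeded generator produces template/query genome
  pairs with implanted DRRs and matching truth BED/PAF, depth panels with
  known presence genotypes, and junction sequences with engineered
  microhomology/insertions, so the whole pipeline is testable offline.

## Worked example

Simulate a genome pair with three implanted regions, call DRRs from the
identity alignment, and classify their presence in a 50-sample depth panel:

```sh
drr simulate pair --seed 42 --outdir fix
drr call --paf fix/truth.paf --template-fai fix/template.fa.fai \
         --gaps fix/gaps.bed --out drrs.bed
drr simulate panel --seed 42 --outdir panel
drr popfreq --drrs drrs.bed --depth-dir panel --sam-dir panel --out popfreq.tsv
```

`drr call` prints `3 DRRs, 0.048 Mbp -> drrs.bed`: the three implanted
segments (12 714, 17 237 and 18 192 bp; summary TSV alongside the BED) are
recovered at their exact coordinates, e.g. `chr1 24851 37565 DRR_chr1_24851`.
`popfreq.tsv` then reports, per region, the cohort presence:

```
drr_id           n_present  n_total  presence_frac  class   high_frequency
DRR_chr1_24851   22         50       0.4400         common  False
DRR_chr1_220079  5          50       0.1000         common  False
DRR_chr2_257882  6          50       0.1200         common  False
```

— each region was simulated at a different allele frequency, and a presence
fraction above 5% classifies it as common. A junction example:

```python
from drrkit import JunctionInput, resolve_junction
call = resolve_junction(
    JunctionInput("ACGTACGTAACCGGTT", "ACGTACGTAA", "AACCGGTT"), min_anchor=6
)
call.microhomology_seq   # 'AA' — 2 bp microhomology, MMEJ-compatible
```

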