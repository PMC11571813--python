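# Methods

## The assay being modelled

In the RNA-tagging assay an RNA-binding protein (RBP) of interest is fused
to a poly(U) polymerase. Transcripts bound by the RBP in vivo acquire a 3'
stretch of uridines after their poly(A) tail; 3'-end sequencing then reveals
which transcripts were bound and, through the U-stretch length distribution,
how strongly. A fusion to the catalytically dead enzyme serves as the
background control: it cannot tail anything, so any U stretches it shows are
artifacts of sequencing.

Two empirical regularities anchor the quantification. Short U stretches
(1–3 nt) appear on all transcripts in proportion to their abundance — they
behave like sequencing errors and appear equally in the dead-enzyme
control. Long stretches (4 or more) mark genuine tagging: they concentrate
on specific genes, co-vary with each other across genes, and vanish in the
dead control. All statistics below follow from this split.

## Quantification pipeline (`utag.quant`)

1. **Tail extraction.** Read 2 covers the transcript 3' end in
   reverse-complement orientation. After re-orienting to the sense strand,
   the poly(A) tail is an A-run and the poly(U) stretch the T-run
   immediately after it (U reads as T in cDNA). The U count of a read is
   the length of the contiguous T-run following the *last* A-run of length
   ≥ `min_polya_run` (default 5; pure runs, no mismatch tolerance). Reads
   without a qualifying A-run are rejected (`no_polya`). Counts are capped
   at 16, the last matrix column; longer stretches are binned there.
2. **Gene assignment.** A read is assigned to a gene when its alignment
   position falls, on the same strand, in a 400-nt sense window around the
   gene's transcription termination site (TTS): 300 nt upstream, 100 nt
   downstream. Coordinates are 0-based half-open; on the plus strand the
   window is [TTS−300, TTS+100), on the minus strand the mirror image
   [TTS−99, TTS+301). Overlapping windows resolve to the nearest TTS, ties
   to the lexicographically smaller gene id. Antisense and out-of-window
   reads are dropped.
3. **UMI collapse.** One record survives per (gene, UMI) pair — the one
   with the largest U count, first-encountered on ties. The rationale for
   keeping the maximum: a truncated copy of a tailed molecule can lose part
   of its tail, whereas a spurious longer tail cannot arise from PCR
   duplication.
4. **Matrix.** Records are tabulated into a gene × U-length (0..16) count
   matrix; every annotated gene is a row. Raw totals equal the number of
   assigned, deduplicated reads. RPM normalization scales the matrix to a
   grand total of one million and is idempotent.
5. **Replicates.** A replicate passes QC when its raw total exceeds
   200,000 reads or its median binding reliability reaches a configurable
   floor (no universal value exists for the floor; it depends on the
   control distribution of the experiment at hand, so it is a parameter).
   Passing replicates are RPM-normalized, averaged entry-wise, and
   re-normalized.

## Binding statistics (`utag.stats`)

On the RPM matrix, per gene:

* expression `exp = Σ_{u=0..16} RPM(u)` — total 3'-end signal;
* binding score `bs = Σ_{u=4..13} u·RPM(u)` — the number of uridines
  attributable to genuine tagging, weighting longer (longer-bound)
  stretches more;
* modification level `m = bs/exp` — abundance-corrected binding.

Genes with `exp = 0` have undefined `m` and are excluded from downstream
statistics rather than imputed. Since `4·Σ_{4..13}RPM ≤ bs ≤ 13·Σ_{4..13}RPM`,
the fraction of a gene's signal carrying a 4+ U tail is bracketed by
`[m/13, m/4]` — a check asserted on every simulated matrix.

**Reliability.** The 17×17 Pearson correlation matrix of the U columns
across genes is the QC object. For each stretch length in 4..13 we take its
best correlation with any *other* stretch in that block (self excluded;
correlations on untransformed RPM values); the median of the ten values is
the *median binding reliability*. Genuine tagging gives values near 1;
the dead control has identically zero 4..16 columns, so the statistic is
undefined there and the library raises a dedicated error rather than
reporting a number.

**Targets.** Genes with `log2(m) > −2.7`, the dead-enzyme background level
(linear `2^−2.7 ≈ 0.1539`, printed as 0.15). The comparison is strict and
made in log2 space; the linear threshold is its exact equivalent, not a
second rule, and the two produce identical sets by construction.

**Enrichment.** Hypergeometric upper tail `P(X ≥ k)` per gene set, with the
expressed genes (`exp > 0`) as background. Raw p-values are reported with a
0.05 significance flag; a Benjamini–Hochberg `q` column is available behind
a flag but off by default so that reported significance matches the
raw-p convention of the threshold above.

**Mutant comparison.** Pearson correlation of `log2(m)` between mutant and
wild type over genes where `m > 0` in both (log2 of zero is undefined; an
optional pseudocount switches to all co-defined genes), plus the set
algebra of the two target sets (old = kept, new = gained, lost = WT-only)
and a hypergeometric overlap p-value.

## Synthetic experiment (`utag.synthetic`)

The generator's defaults are the study conditions used by the test suite
and the acceptance script: 2000 genes, log-normal abundance weights
(location 0, scale 1.5 — a heavy-tailed distribution typical of mRNA
abundance), 200 target genes, tailed fraction f = 0.2, tail lengths uniform
on 4..13 (supported on 4..16), error-stretch rate e = 0.05 with error
lengths uniform on 1..3, one million reads. The error rate is a chosen
plausible value, not an estimate of any particular dataset's error rate.

Mechanics: each molecule picks a gene in proportion to abundance; a
target-gene molecule is tailed with probability f (when the enzyme is
active); an *untailed* molecule acquires an error stretch with probability
e. Tail and error are mutually exclusive on one molecule — a simplification;
at these rates the probability of both is ~1%·molecule and would only add
to the tail length. Setting `enzyme_active=False` forces f = 0 and yields
the dead control; draws are consumed identically either way, so an
active/dead pair with one seed shares its molecule stream and differs only
in tailing.

Closed form used by the tests: with a point-mass tail length L in 4..13 and
no errors, the expected modification level of a target gene is `L·f`
(every tailed molecule contributes L to `bs` and every molecule contributes
1 to `exp`).

**Read-level simulation** emits the same molecule stream as paired reads:
read 1 a sense fragment inside the TTS window (the alignment coordinate is
recorded; alignment itself is out of scope), read 2 the reverse complement
of `body + A^p + T^u + adapter` with p uniform on 10..30. Gene bodies have
internal A- and T-runs broken above length 4 so the poly(A) run is always
the last qualifying A-run on the sense strand, making extraction exact by
construction. UMIs are random 8-mers, redrawn within a gene until unique
(default) so that UMI collapse is a no-op on simulated data and the
read-level pipeline reproduces the count-level matrix *exactly*; collision
behaviour of the dedup rule is exercised separately with crafted records.
Real libraries of course do contain collisions; the equivalence claim is
about the two simulators, not about real data.

What the generator does **not** emulate: base-call quality profiles, PCR
duplication beyond UMI identity, splice isoforms, antisense transcription,
internal priming, or gene-dependent error rates. Passing tests therefore
validate the pipeline's arithmetic and bookkeeping under the stated
generative model, not its robustness to those artifacts.

## Architecture conservation (`utag.architecture`)

Proteins carry Pfam-style domain annotations (1-based inclusive; overlaps
merged before counting) and per-residue disorder scores in [0,1], both as
inputs. IDR residues are those outside all domains with disorder strictly
above 0.5. Region fractions (domain/IDR/other) sum to 1; the domain *span*
is the extent from first domain start to last domain end as a fraction of
length. IDR amino-acid compositions are compared by Pearson correlation,
with rows ordered by similarity to the mean composition of a reference
group when labels are provided.

For an ortholog group, domains are matched across orthologs by
(family, rank-within-family) after sorting by position — an alignment-free
stand-in for ordering domains on a multiple sequence alignment, which is
out of scope. The *ancestral composition* is the (family, rank) pairs
present in strictly more than 30% of orthologs, ordered by median relative
position. An ortholog is *conserved* when its domain-family sequence
contains the ancestral family list as an in-order subsequence. IDR segments
are the spans outside the matched ancestral domains, keyed N-terminal /
between-domains / C-terminal; a segment qualifies when its across-ortholog
average disorder exceeds 0.5 and its average length is ≥ 15 residues.
Segment qualification and variability both use the conserved-organization
orthologs (segment correspondence is ill-defined when domains are missing).
Variability is std/mean of the disordered-residue counts with the sample
(n−1) standard deviation; `mean_ratio` averages over qualifying segments
and is reported missing when none qualifies.

The ortholog simulator diverges a template by per-residue substitutions,
indels restricted to non-domain segments, and independent whole-domain loss
with probability p; disorder is regenerated low (0.05–0.30) inside retained
domains and segment-character-preserving outside. With the >30% ancestral
rule intact, the conserved fraction concentrates around `(1−p)^d` for a
d-domain template, the closed form the recovery tests check against a
binomial 95% interval (at large p the ancestral set itself occasionally
shrinks, which raises the fraction — visible in the driver sweep at
p = 0.5 and expected from the rule).

## Numerical and scale choices

* All randomness flows through explicit integer seeds;
  `numpy.random.SeedSequence` spawning separates the truth, molecule and
  read-detail streams so count-level and read-level simulations share
  molecules exactly.
* Pearson correlations on zero-variance columns are recorded as missing
  (NaN) and skipped by downstream maxima/medians, never coerced to 0.
* Problem sizes in tests and drivers (one-million-read matrices, 50,000-read
  FASTQ round trips, 50-seed conservation sweeps) were chosen so the whole
  suite completes in well under a minute while keeping Monte-Carlo errors
  far from the asserted margins.
* Hypergeometric p-values use `scipy.stats.hypergeom.sf`; tests verify them
  against a direct combinatorial sum over all parameter combinations with
  N ≤ 12 and against literal enumeration of all draws for N ≤ 8.

## Known limitations

* The dedup "largest U count wins" rule is a heuristic; with unique UMIs it
  is a no-op, and no claim is made that it is optimal under heavy PCR
  duplication.
* The replicate-reliability floor and the GO collection are inputs without
  canonical defaults; results on real data depend on both.
* The architecture module's rank-based domain matching can mis-pair domains
  when paralogous domains reorder within a protein; MSA-based ordering
  would resolve this but is deliberately out of scope.
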