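# Methods

## Overview

`hydroxyscan` analyses reduced-representation hydroxymethylation profiling
(RRHP) data.  RRHP libraries are built by MspI digestion (C^CGG),
adapterization that recreates the restriction site, glucosylation of 5hmC at
the adapter junction, and a second MspI digestion that removes adapters from
unprotected (non-hydroxymethylated) junctions.  Only fragments carrying 5hmC
at a CCGG junction amplify, so a sequencing read beginning with `CCGG` is a
digital count of hydroxymethylation at one genomic site.  The analysis
chain is: site-universe enumeration → read quantification → annotation →
normalization → per-site differential statistics → region (DhMR) detection →
clustering, with a synthetic-data generator that produces every input the
chain consumes.

## Site universe and quantification

The assayable universe is every `CCGG` occurrence on the forward strand of
the reference.  The motif is its own reverse complement, so sites are
strand-collapsed: reads from either fragment end of a cut attribute to the
same motif entry.  Coordinates are 1-based inclusive internally; BED I/O
converts to 0-based half-open at the boundary.  Motifs overlapping `N`
cannot match and are skipped rather than raising, to tolerate masked
references.

Read filtering keeps a read iff it begins with the protected-site motif
(default `CCGG`), then removes one terminal `CG` adapter occurrence,
strips 3′ bases below a Phred floor (default 20), and requires ≥ 35 nt.
Only trailing-base quality trimming is implemented; no sliding-window
variant, since the contract is the stated effect (low-quality 3′ ends
removed) rather than any particular trimmer's heuristics.

Built-in placement is exact-match: a read is assigned to site *s* when its
sequence equals the reference from *s*'s motif start (forward) or the
reverse complement of the reference ending at the motif end.  Reads matching
more than one site are counted as ambiguous and assigned to none, avoiding
double counting deterministically.  Real-data users with an external aligner
import SAM/BED instead: a record counts toward the site whose coordinate
equals its 5′ motif start (leftmost base for forward records, rightmost
aligned base − 3 for reverse records).

## Annotation

Each site receives exactly one gene-context feature by the precedence
utr5 > utr3 > exon > intron > promoter > intergenic, evaluated over the
union of all overlapping transcripts.  Genic context is preferred over
another gene's promoter; the precedence is configurable because the
underlying composition fractions are reported as mutually exclusive without
a published tie rule.  UTR intervals are derived as exonic sequence outside
the CDS span (side chosen by strand), which makes GTF and BED12 input
behave identically and avoids relying on optional UTR feature rows.
Promoters are the 1 kb strictly upstream of each transcript's TSS,
strand-aware.

CpG landscape is island (inside a merged CGI interval), shore (gap distance
to the nearest island boundary ≤ 2 kb), shelf (≤ 4 kb), else open sea.
TSS-distance profiles use 50-bp bins over [−1000, +1000) with signed,
strand-aware distances (negative = upstream); a site within the window of
several TSSs contributes once per TSS, using every transcript's TSS rather
than one per gene.

## Normalization

Quantile normalization is applied *within* each cell type: each column's
sorted values are replaced by the mean of order statistics across that
group's columns.  Tied values in a column receive the mean of their
assigned target quantiles.  (With ties this means sorted columns agree only
up to tie groups; the exact sorted-column equality holds on tie-free data.)
Normalizing within cell types deliberately preserves between-cell-type
differences — including a global shift in 5hmC abundance — which is the
contrast of interest.

Low-count filtering keeps a site iff it has ≥ 10 normalized counts in ≥ 3
samples of at least one cell type.  log2-CPM is
`log2((count + 0.5) / (libsize + 1) × 1e6)` with the library size taken as
the sample's total counted reads before site filtering, so filtering does
not change the CPM scale.  The 0.5 / +1 offsets are the standard voom-style
choice and are configurable.

The mean–variance trend fits per-site least squares under a configurable
design (default intercept + cell type; age and sex can be added), lowess of
√(residual sd) against mean log2-count, and per-observation precision
weights equal to the interpolated value at each observation's fitted
log2-count raised to the −4th power.  The classical paired t-test operates
on unweighted log2-CPM; weights feed only the moderated pipeline.

A note on identifiability: a perfectly uniform group-wide log2 shift is
absorbed by per-sample CPM scaling (column totals shift with it).  The
parameter-recovery analyses therefore evaluate fold changes at matched
nominal depth (equal library sizes passed to `log_cpm`), and the narrative
simulation combines a global shift with sparse hypo-biased site effects so
a paper-like direction signature survives CPM scaling.

## Differential statistics

Per site, with pairs (A, B) and differences d = B − A:
t = mean(d) / (sd(d)/√n), df = n − 1, two-sided p from the t distribution.
Sites with sd(d) = 0 are flagged degenerate and carry t = 0, p = 1 (never
NaN), so downstream window statistics remain defined; degenerate sites get
one-sided p = 0.5.  The log2 fold change is the mean within-pair contrast,
orientation recorded in output metadata.  An unpaired two-sample option
(Welch or pooled) exists for designs whose pairing is unknown.

The moderated t uses an empirical-Bayes scaled inverse-chi-square prior on
per-site variances, estimated by moment matching on log variances
(digamma/trigamma inversion).  Posterior variance
s²ₚₒₛₜ = (d₀s₀² + d·s²)/(d₀ + d); moderated t has d + d₀ degrees of
freedom.  When observed log-variance spread does not exceed pure chi-square
sampling noise the prior degrees of freedom are infinite and s₀² is set to
the geometric mean of the observed variances, so identical inputs shrink to
themselves.

Volcano classes use strict inequalities: down iff log2FC < −1 and p < 0.05,
up iff log2FC > 1 and p < 0.05, else ns.  FDR is Benjamini–Hochberg.

## DhMR detection

One-sided p-values (direction of reduced or increased hydroxymethylation in
the B group) are combined over sliding windows of nine sequential sites per
chromosome (step one site) with Fisher's method: X² = −2 Σ ln p, chi-square
with 18 df.  p-values are floored at 1e−300 before the logarithm.  Windows
whose first-to-last inclusive span reaches 50 kb are skipped and tallied.
The `best` direction evaluates both one-sided tracks and reports the
smaller combined p with its label.

Genome-wide significance uses a Bonferroni denominator of ⌈n/9⌉
*non-overlapping* bins, not the number of sliding windows (the discovery
scan overlaps; the correction counts independent bins).  Chains of windows
sharing member sites are optionally collapsed to the member window with the
smallest combined p (ties → leftmost), giving disjoint reported loci;
collapsing can be disabled to inspect raw windows.

## Clustering

Dissimilarity is 1 − r (Pearson) over samples or sites; UPGMA merges the
closest clusters with the unweighted average (size-weighted Lance–Williams)
update.  Ties are broken by lowest leaf index and join heights use the d/2
convention by default; both choices are recorded so dendrograms are
bit-reproducible.  Heatmap matrices are per-site Z-scores (sample sd).
Top sites default to p < 0.01.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not any real
dataset:

* **Genome** — random background scrubbed of accidental `CCGG`, with a
  requested number (or Poisson rate, default 0.002/bp) of planted motifs
  ≥ 4 bp apart, disjoint CpG islands (0.4–1.5 kb), and non-overlapping
  coding gene models (2–4 exons, strand random, CDS inset from the
  transcript ends).  The in-silico digest of the output finds exactly the
  planted motifs.
* **Counts** — per-site baseline log2 means ~ Normal(5, 1.2) (counts on a
  log-normal scale around ~32, a realistic reduced-representation depth);
  subject random effects ~ Normal(0, 0.1) inducing within-pair correlation;
  the second cell type shifted by a global log2 offset (default −0.3,
  emulating global NSC hypo-hydroxymethylation) plus sparse per-site
  effects and planted nine-site DhMR runs; negative-binomial noise via
  gamma–Poisson mixing (dispersion 0.05 default; 0 gives Poisson); library
  size factors uniform in [0.8, 1.2].  Every non-null site appears in the
  ground-truth table.
* **Reads** — per site and sample, Poisson(depth × level) reads; each read
  is the reference fragment from the motif (either orientation) plus a
  terminal `CG` adapter; a stated fraction of decoy reads without the
  `CCGG` prefix exercises the filter.  Emitted per-site counts and decoy
  totals are logged exactly, enabling byte-exact round-trip checks.

The default design is 4 subjects (two case/sibling disease pairs, same-sex,
ages 9–18) × 2 cell types = 8 libraries, mirroring the study scale; the
default site count is 20,000 for desk-scale runtime.  What passing tests on
this generator do *not* show: alignment-stage artifacts (mismatches,
indels, multi-mapping beyond exact repeats), PCR duplicates, sequencing
error, batch effects, or the correlated genomic structure of real CpG
landscapes.

## Problem sizes and numerical choices

Simulation-based checks use: 10,000 sites × 4 pairs for site-level null
calibration; 1,000 non-overlapping nine-site bins for window-level
calibration; 20,000 sites for global-shift recovery; 20 replicates of
2,000 sites for planted-DhMR ranking; 5,000 sites for prior recovery —
sizes at which the binomial/recovery tolerances are meaningful while a full
run completes in seconds.  Fisher combination is validated against the
closed Poisson-series form of the even-df chi-square survival function to
1e−10.  The trigamma inverse uses Newton iteration to 1e−12 relative
tolerance.  Lowess span for the variance trend is 0.5.

## Known limitations

* Exact-match placement cannot handle sequencing errors; real data should
  arrive via `import_alignments`.
* With only four pairs, covariate adjustment (age, sex) nearly saturates
  the design; the default trend design is intercept + cell type, and
  covariates are opt-in.
* The moderated-t prior assumes variances exchangeable across sites; no
  trend-adjusted (per-abundance) prior is fitted.
* Fisher's combination assumes independent member p-values; adjacent sites
  in real data are correlated, so window p-values are anti-conservative
  there (the correction by non-overlapping bins mitigates but does not fix
  this).  No dependence-adjusted combination is provided.
* No liftover, no external regulatory-element (cCRE/TFBS) joins, no
  enrichment testing — gene lists are exported for external tools.
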