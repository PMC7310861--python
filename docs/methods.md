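# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; GTF and the Ensembl-export
TSV dialect (1-based inclusive) are converted at ingest, and BED output is
0-based half-open. A transcript's `stop_end` is the boundary after the
stop codon's last base in transcription direction: on `+` strands it
equals the half-open end of the stop codon, on `−` strands the 0-based
start (bases at lower coordinates are downstream). In the TSV dialect the
CDS span includes the stop codon, so `stop_end` converts directly from
the CDS end column; in GTF it comes from the `stop_codon` feature, or
from the CDS 3′ end advanced 3 spliced nt when that feature is absent
(flagging `stop_split` when the walk crosses a junction).

## 3′UTR-intron classification

Distances are *spliced* (exonic) nucleotides between `stop_end` and each
downstream exon-exon junction, exclusive of the stop codon itself: the
first 3′UTR base is offset 0, so a junction immediately after the stop
has distance 0 and is proximal. Junctions upstream of the stop are
ignored. The 50-nt rule: exactly one junction at d < 50 → PROXIMAL; one
junction at d ≥ 50, or two or more junctions at any distance → DISTAL.
Genes aggregate with DISTAL precedence over PROXIMAL; genes whose
isoforms are all single-exon are INTRONLESS, the rest NO_3UI. An
Ensembl `nonsense_mediated_decay` biotype is an orthogonal flag, kept
out of the proximal/distal partition so the two groupings can be crossed
or reported separately. Where a distal transcript carries several
junctions, the farthest distance is the representative one. APPRIS P1
ties are broken by smallest transcript id (logged). For cross-species
conservation, a gene counts as conserved only when every mapped ortholog
in every species is PROXIMAL; a missing ortholog link means not
conserved.

These choices — exclusive distance convention, farthest-junction report,
absence-means-not-conserved orthology — are deliberate resolutions of
genuinely open conventions, not facts about any particular annotation
release.

## Synthetic data

The generator lays one isoform per gene on a single synthetic chromosome
with inter-gene spacers, half of the genes on the minus strand. Exons are
160–320 nt (internal exons therefore pass the 150-nt meta-profile
eligibility bound), introns 80–500 nt, and the penultimate exon is
enlarged when a requested 3′UI distance needs the room. Requested class
labels round-trip exactly through the classifier for any seed. Sequence
content is irrelevant to every stage and is not emitted.

Footprints: each molecule picks a random junction (the 3′ end of a
non-terminal exon), a length uniform in 25–45 nt, and a placement that
covers the protected bases plus at least one flank on each side while
staying inside the exon. With the default protected interval −29..−20,
read 5′ ends therefore pile up at offsets ≤ −30 and 3′ ends at ≥ −19,
leaving the protected region depleted of ends — the signature the
detector looks for. The default midpoint −24.5 is chosen so that the
detector's rounding rule (half-offsets round toward the junction) reports
−24, the canonical EJC position. A configurable background fraction
(default 0.1) lands uniformly on exonic positions. PCR duplication draws
a geometric copy number per molecule (mean 1/(1−rate)); duplicates share
coordinates and the 5-mer random barcode, which is drawn uniformly from
the 4^5 space — collisions are allowed, exactly as in barcode-based
dedup of real libraries, so dedup recovers the molecule count only up to
collisions (the truth table lets tests verify this precisely).

Expression: gene baselines are log-normal (heavy right tail typical of
RNA-Seq), scaled by an expected library size (default 10^6), with the
class effect multiplying mutant-sample means by 2^log2FC and counts drawn
gamma-Poisson with dispersion α (var = μ + αμ², default α = 0.05). The
default design is three wild-type versus three mutant libraries. The
default composition keeps effect-bearing classes (proximal/distal 3′UI,
NMD-biotype) near 13% of genes — 3′UI-containing genes are a small
minority of a vertebrate transcriptome, and a one-sided majority of
changes would distort median-of-ratios normalisation in a way no real
dataset of this kind does. Default effect sizes (log2FC 1.0–1.5 on the
NMD-target classes) are free parameters of the simulation, chosen to sit
near the 1.5-fold call threshold; they are not measured quantities. An
optional rank-1 technical batch (per-gene N(0, sd) log2 effects on
designated samples) models libraries sequenced in separate runs.

What the generator does **not** emulate: sequence-dependent biases,
splice-site motifs, alignment or trimming artefacts, isoform-level count
ambiguity, or correlated gene modules. Passing tests therefore
demonstrate the correctness of the statistical machinery under the
stated model, not robustness to every artefact of real libraries.

## Meta-exon profile and deposition-site detection

Eligible exons are internal (neither first nor last) exons of multi-exon
APPRIS-principal transcripts, ≥ 150 nt (so the two 75-nt anchor windows
never overlap) and overlapped by ≥ 10 reads; both thresholds are exposed.
Coverage and read-end counts are pooled over exons with read weighting
(an exon contributes in proportion to its reads), coverage tracks are
normalised to unit sum, and end counts are kept raw so their totals equal
the number of read ends falling in the windows; unit-sum end densities
are derived on demand. Offsets are strand-aware, with offset −1 the last
exonic base on the 3′ anchor.

The detector scans a search window (default −40..−10) for the maximal
contiguous run where both 5′- and 3′-end densities fall below τ (default
0.2) times their respective in-window maxima, requiring a run of ≥ 3
offsets; the call reports the run as the protected interval, its length
as the width, and its midpoint (half-offsets rounded toward the junction)
as the mode. The τ-based rule is a reconstruction of "boundaries of the
minimal occupied site" drawn by eye in the source figures; it recovers
widths 6–14 nt to ± 1 nt at 10^4–10^5 reads in the test suite.

## Differential expression

Library-size offsets come from median-of-ratios size factors over genes
positive in every sample (falling back to total-count factors). Factors
of unwanted variation are estimated RUVs-style: log2(count+1) centred
within replicate groups, then the top-k left singular vectors of the
centred sample-by-gene matrix; k defaults to 1.

Per-gene NB dispersions are method-of-moments estimates shrunk fully onto
a mean-dispersion trend α(μ) = a0 + a1/μ fitted by trimmed least squares
across genes; with ≤ 3 replicates per group the raw genewise estimator is
far too noisy (it frequently goes negative and would be floored to
near-Poisson, making the LRT anticonservative), while the trend borrows
strength across the whole matrix. When unwanted-variation factors are in
the design, moments are taken about Poisson-fitted means under the full
design with an n/(n−p) correction, so variance explained by the factors
does not masquerade as biological dispersion. The floor is 10^-6, and the
genewise mode remains available. When fewer than 20 genes inform the
trend (tiny matrices), the estimator falls back to floored genewise
moments.

Each gene is fit under full (intercept + genotype + W) and reduced
(intercept + W) designs with a fixed-α NB GLM; p-values come from the
likelihood-ratio statistic against χ²(1), BH adjustment runs over all
tested genes with no independent filtering, and calls use fold change 1.5
and FDR 0.05. A warning is emitted when the p-value histogram departs
from uniformity on (0.5, 1] (a "hill shape"), the situation in which a
BH adjustment on the raw χ² p-values is miscalibrated; re-fitting an
empirical null is outside this package's scope. This is a contract-level
NB-GLM/LRT implementation, not a clone of any particular DE tool's
shrinkage machinery; the test suite verifies its calibration (type-I
error 0.05 ± 0.02 on 2000 null genes) and power (sensitivity ≥ 0.8,
empirical FDR ≤ 0.1 at log2FC 1.5, 3 vs 3, α = 0.05) directly.

## Enrichment statistics

Overlap significance is the upper-tail hypergeometric probability
P(X ≥ k), with the universe taken as the smaller of the two datasets'
tested-gene sets (genes assigned an adjusted p-value) and both sets
intersected with it. Class shifts use the asymptotic two-sample KS test;
ECDFs jump 1/N at each observation. Fold-change bins (> 1.5, 1.5..0,
0..−1.5, ≤ −1.5 in log2 units) assign boundary values to the lower bin.
The last bin is read as "< −1.5", the symmetric completion of the
partition. Isoform comparisons additionally report the median paired
difference of 3′UI+ minus 3′UI− fold changes.

## Problem sizes and determinism

Simulation defaults (200 multi-exon genes and 10^5 footprints for
deposition recovery; 300–2000 genes for DE calibration; 3 seeds for the
Monte-Carlo power checks) were chosen as the smallest sizes at which the
recovered quantities are stable to the tolerances the tests assert.
Every stochastic component takes an explicit integer seed and is
deterministic given it; identical configs reproduce byte-identical
artifacts, which the pipeline manifest records alongside a config hash.

## Known limitations

* The NB LRT relies on χ²(1) asymptotics; at 3 + 3 samples the realised
  type-I error is nearer 0.06 than 0.05, and conditioning on estimated
  unwanted-variation factors is not accounted for in the reference
  distribution. Under a strong batch the corrected test recovers
  sensitivity but with an elevated empirical FDR.
* The deposition detector assumes a single contiguous protected interval
  inside the search window; non-canonical EJC sites are out of scope.
* Ambiguous reads overlapping two genes are discarded, not fractionally
  assigned.
* The isoform quantification simulator draws fold changes directly rather
  than deriving them from read-level sampling; it exercises the pairing
  and shift logic, not a quantifier.
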