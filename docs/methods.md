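# Methods

## Problem setting

Hexaploid bread wheat carries three homeologous sub-genomes (A, B, D). The
claim under test is that the developing grain — specifically the
photosynthetic cross- and tube-cell layers of the pericarp, which play the
roles of mesophyll and bundle-sheath cells without Kranz anatomy — runs a
NAD-malic-enzyme-type C4 cycle that the leaf does not. The pipeline
assembles the molecular side of that claim from transcript-level RNA-Seq
summaries: expression of all six pathway genes (ppc, aat, mdh, me2, gpt,
ppdk; carbonic anhydrase optional) in grain across all three sub-genomes,
compartment-consistent gene copies, and a C4-diagnostic PEPC residue.

Raw reads are outside the package boundary: the input is a transcript ×
sample table of mapped pair and singleton counts, and a synthetic generator
supplies such tables with known ground truth.

## Synthetic data model

`synthetic_data.SimConfig` holds the study design. Defaults describe the
emulated study: 31 genotypes; grain sampled at 14 and 30 days post anthesis
plus a seedling-stage leaf tissue; the six NAD-ME genes up-regulated
`grain_up_fold = 8` in grain tissues; 100 genes × 3 sub-genomes;
transcript lengths 500–2000 nt; negative binomial dispersion 0.1; singleton
unit share 0.1; 10 transcripts deposited as 5 split fragment pairs.

- **Sequences.** One random ACGT ancestor per gene; each sub-genome copy is
  an independently mutated descendant at rate `homeolog_divergence / 2`
  (default pairwise divergence 5%, the allopolyploid-wheat ballpark). No
  indels, no Ns: homeolog separation and fragment stitching are the
  behaviors under test, not alignment robustness.
- **Counts.** Expected units per transcript and sample are
  `base_mean · (length/1000) · lognormal(0, σ=0.5) · tissue effect`, with
  the tissue effect `grain_up_fold` for designated transcripts in grain
  tissues and 0 outside grain for grain-unique transcripts. Pairs (2 units
  each) and singletons are two independent negative binomial layers with
  `Var = m + φm²`; φ → 0 recovers Poisson. Reads are never simulated —
  mapping bias, positional effects and library-preparation artifacts are
  deliberately absent, so passing tests demonstrate the statistics and the
  bookkeeping, not robustness to alignment noise.
- **Split fragments.** A parent is cut at a point in its middle third; with
  overlap `v` the fragments are `seq[:cut]` and `seq[cut−v:]`, so joining
  them while dropping the duplicated overlap once reconstructs the parent
  byte-exactly. Library sizes and depth are not pinned down by the study
  being emulated; `base_expression_mean = 50` gives the tests comfortable
  counting statistics without slowing them.
- **PEPC families.** Each simulated protein copy embeds exactly one
  17-residue diagnostic window (drawn from the packaged printed-window set,
  10th position overwritten with the requested residue) inside random
  flanks, with truth recorded per copy.

## Reference stitching

Fragment pairs are detected two ways, both configurable:

- **Suffix/prefix overlap** (default): candidate generation is seeded on an
  exact match between the first `min_overlap` (20) nt of the downstream
  fragment and the corresponding suffix window of the upstream one; the full
  overlap must then reach `min_identity` (0.95). The exact seed makes false
  joins on random sequence vanishingly unlikely (4⁻²⁰ per comparison) and
  keeps the search linear-ish via a prefix hash, at the cost of not
  tolerating mismatches inside the seed window. Records annotated with
  different sub-genomes are never paired: homeologs are close enough that a
  homologous region of the wrong copy passes the identity threshold, and
  sub-genome identity is precisely the information that resolves fragments
  to one gene copy.
- **Guide anchoring** (opt-in): two same-gene, same-sub-genome records that
  align (edlib infix alignment, identity ≥ 0.90 to allow for homeolog
  divergence) to disjoint, ordered intervals of a longer homeolog, with a
  gap ≤ 50 nt, are joined abutting (overlap 0). Overlap-free joins are
  accepted *only* in this mode — without a guide they are unverifiable.

Candidates are ranked by identity count, ties broken by longer overlap then
lexicographic ids, and accepted greedily with each fragment in at most one
pair. `build_modified_reference` replaces each pair with its merged record
at the first fragment's position, leaving all other records untouched and in
order, so `|out| = |in| − |events|` always. Three-or-more-fragment joins are
out of scope.

## Quantification

Units are `2·pairs + 1·singletons` (the convention that keeps RPKM
interpretable for paired-end data without switching to FPKM). Library size
is the per-sample unit total over the whole reference, never a gene subset.
Gene-level expression is the sum of copy RPKM within gene × sub-genome; the
A+B+D combined level is the sum over known sub-genomes, with
unknown-sub-genome transcripts excluded and reported. Genotype averaging is
an unweighted mean within tissue. Reported folds are rounded half away from
zero (124.83 → 125, 76.45 → 76), and a combined two-gene contrast is the
product of the rounded folds with the raw product reported alongside. The
denominator floor defaults to 0 with a hard error on a zero denominator —
silent pseudo-counts would distort exactly the large contrasts this
pipeline cares about.

Because RPKM is a relative measure, strong up-regulation of one gene set
deflates every other transcript's share in that tissue. At study scale
(tens of thousands of transcripts) this is negligible; on a 300-transcript
synthetic run it compresses the realized fold of the planted genes (≈5× for
a planted 8×) and pushes null transcripts toward "up in the other tissue".
The two-group simulations used for error-rate measurement therefore plant
effects symmetrically in both groups.

## Differential expression

The two tests are re-specifications of mean-based ("Gaussian") and
count-based ("EDGE") procedures that exist only inside a proprietary
workbench; they are documented here as this package's own definitions:

- **Mean test:** Welch unequal-variance t on log2(RPKM+1), two-sided;
  zero-variance degenerate rows give p = 1 when means are equal. Measured
  null type-I rate at α = 0.05 is ≈ 0.06 on negative binomial data —
  slightly liberal, as expected for a t-test on log counts.
- **Count test:** conditional on a transcript's combined unit total
  `n = k_A + k_B`, `k_A ~ Binomial(n, π_A)` under the null with `π_A` group
  A's normalized library share. Two-sided p doubles the smaller tail,
  capped at 1. Normalization uses total-unit library sizes; TMM-style
  factors are out of scope. The doubled-tail convention differs from a
  permutation test's conditioning: decisive fixtures agree within 0.02, but
  mid-range p-values (≈0.1–0.2) can differ by ~0.07.

Both p-vectors are Benjamini–Hochberg adjusted; a transcript is significant
only when both q-values are ≤ α (default 0.01). Among significant
transcripts, a group whose mean RPKM falls below `presence_floor = 0.5`
marks the transcript unique to the other group; otherwise the fold direction
assigns up_A/up_B. The emulated study's absolute transcript counts (26,477
common-significant, etc.) depend on its raw reads and proprietary tests and
are not reproduction targets; the suite instead measures FDR control
(mean empirical FDR ≤ 0.02 at nominal 0.01 under a 70% null mix) and ≥ 90%
category recovery at 8-fold planted effects with 10 genotypes per group.

## PEPC residue typing

The diagnostic site distinguishes malate-feedback-tolerant C4 PEPC from the
C3 form: R in C3 isoforms; S, Q, G or I (the substitutions observed across
known C4 lineages) mark a C4 candidate. The C4 set is configurable since
other substitutions may exist. Matching slides a 17-wide window over the
protein and scores identities against the packaged library of printed
reference windows ('?' placeholders never match); a placement needs
`min_identities = 11/17` — low enough for divergent homeologs, high enough
that random protein scores (~2/17 per window) never reach it. Ties break to
the leftmost offset, then library order. Nucleotide input is translated in
all six frames and the best-scoring frame kept; a copy is frame-intact when
some single frame holds a stop-free window at threshold. Canonical site
numbering (884 maize-style; 885/891 for the wheat chromosome-3/5 copies) is
metadata only — it depends on full-length sequences the pipeline may never
see.

Applying the rule to every packaged printed window reproduces the printed
label everywhere except one row: a Setaria italica copy whose window
carries Q at the diagnostic position yet is labeled C3 in the source table.
No published rule explains that label, so the classifier reports its
rule-based call with a divergence flag rather than guessing intent.

## Pathway evidence

The seven-enzyme schema (CA, PPC, AAT, MDH, ME2, GPT, PPDK) fixes each
enzyme's cell side and expected compartment; EC strings are carried as
printed in the source schema, including MDH's "1.1.1.31" which differs from
the standard malate dehydrogenase EC (1.1.1.37) and is flagged here rather
than silently corrected. A copy is C4-side when its annotated targeting
matches the enzyme's C4 compartment (mdh/me2 mitochondrial, ppdk
chloroplastic, aat cytosolic or mitochondrial, gpt cytosolic on both sides);
PEPC's two cytosolic copies are split by the residue class; unknown
targeting is ambiguous, never guessed — which means annotation rows that
print no targeting (the four aat C3 loci) come out ambiguous by design.
The verdict is positive iff all six genes have a C4-side copy with
grain/leaf fold ≥ 2 and grain mean ≥ 1 RPKM (direction is all the source
states; these thresholds are this package's own, configurable) and PEPC has
a C4-candidate call. The verdict is monotone: adding evidence never flips
positive to negative. An endosperm/aleurone exclusion contrast is
representable as an extra tissue but off by default — that data is external.
The concatenated printed locus label "7ADS4AL" is stored verbatim;
parsing it is not attempted.

## Numerical and bookkeeping choices

- Coordinates are 0-based half-open internally; FASTA is untouched.
- Fold rounding is half away from zero; BH adjustment comes from
  statsmodels; binomial tails from scipy.
- All generators are pure functions of (config, seed); every pipeline run
  logs its config and seed and is byte-reproducible from them.
- Problem sizes in tests and drivers (300–500 transcripts, 6–31 genotypes,
  50 simulation replicates, and a 100,717-record database for the
  stitching bookkeeping) were chosen to give stable statistics at
  interactive runtimes.

## Known limitations

- No read-level simulation: mapping bias, multi-mapping between homeologs,
  and sequencing error are all outside the model, so the generator cannot
  probe how much homeolog cross-mapping would blur sub-genome resolution at
  5% divergence.
- The suffix/prefix search requires an exact seed; a sequencing error inside
  the first 20 nt of a true junction would hide that candidate (the guide
  mode can still recover it).
- RPKM's compositional artifact is inherent to total-count normalization;
  at the small synthetic scale it visibly compresses folds (documented
  above) and is left in place rather than masked by a different normalizer.
- The binomial count test treats units within a group as exchangeable
  pooled counts; genotype-level overdispersion is only captured through the
  intersection with the mean-based test.
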