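# Methods

## Scope and data model

All computation happens on two in-memory structures: a `GenomeModel`
(replicons, genes sorted by position, optional arm/core compartments) and
dense per-base `StrandedTrack`s, one per (replicon, strand, library).
Coordinates are 0-based half-open everywhere inside the package; GFF3 I/O
converts at the boundary, bedGraph is already half-open. Two library
types are distinguished throughout: `long` (full-length-transcript
enriched, even gene-body coverage) and `short` (size-selected 40–300 nt,
dominated by UTR fragments and stable degradation products).

When coverage is built from alignments, every reported alignment record
is counted once per aligned reference block — multi-mapped reads
therefore contribute at each reported location. This is a documented
choice; counting primary alignments only would need a flag-filtering
pass upstream.

## Coverage statistics and thresholds

The mean expression value (MEV) of a gene on a strand is the integer
depth total divided by gene length in a single division, so it equals a
per-position summation exactly — tests assert exact equality against a
brute-force oracle, not approximate agreement. Antisense candidacy is
`MEV > t_mev OR peak > t_peak`, strict at the boundary; the disjunction
matters because many antisense species overlap only a small fraction of
a long gene and are visible only through the peak rule.

Threshold scaling between species is proportional to the non-ribosomal
mapped read count, with `t_peak = 2 × t_mev` held fixed; both the
direction of scaling and the 2:1 ratio are package conventions (the
reference pairs they reproduce are consistent with both). Internally all
thresholds keep full float precision; *display* values round half-up at
one decimal (`3.45 → 3.5`), because binary-float `round()` would print
`3.4` and the convention for reporting thresholds is half-up.

## Antisense classification

A gene's transcribed extent is measured by scanning outward from its
annotated boundaries on its own strand while depth stays ≥ `t_rt`,
bridging sub-floor gaps of ≤ `gap_tolerance` nt. Defaults: `t_rt` equals
the species `t_mev` (the pipeline sets this automatically), gap 5 nt.
Extents may traverse entire genes — multi-gene read-through is real
(operonic read-through can run ~1.6 kb across an opposite-strand gene)
and is deliberately not truncated.

Within each flagged gene, antisense islands (runs ≥ floor, gaps bridged)
are segmented first and classified independently, because one gene can
legitimately carry a 5′ divergent overlap *and* an independent internal
asRNA. Per island:

1. **Explained mass.** The fraction of the island's depth mass lying
   inside partner extents — 3′ read-through extents of convergent
   opposite-strand genes, or 5′ extents of divergent ones. If ≥ `c`
   (default 0.8) the island is a cutoRNA or divergent-overlap call, the
   category with the larger explained mass winning ties in favour of
   cutoRNA, and the dominant partner being recorded.
2. **Sharp start.** Otherwise, if depth just outside the island's 5′ edge
   (mean over `w` = 25 nt) stays below `β·max` (β = 0.2) while the first
   `w` nt inside reach it, the island has the step-like 5′ boundary of a
   dedicated promoter and is an asRNA.
3. Everything else is `unclassified` — uneven coverage without defined
   boundaries is a real and common outcome, not an error.

A cutoRNA pair call additionally requires ≥ `o_min` = 50 nt of overlap
between the extent and the partner's annotated interval. None of these
constants have a measured counterpart (the emulated workflow judged them
by eye in a genome browser); all are config-exposed and echoed in the run
manifest.

## sRNA calling

Candidate islands are maximal runs ≥ `t_isl` (default 10 reads/base)
inside contiguous intergenic segments — islands can never cross an
annotated gene on either strand — with ≤ `g` = 5 nt gaps bridged and
edges trimmed to ≥ α·max (α = 0.1). An island qualifying in *either*
library is kept (some genuine sRNAs appear only in the long library);
overlapping islands from the two libraries are merged and per-library
mean depths recorded.

UTR disambiguation is evidence-based, not proximity-based:

* `utr5_fragment`: the island's 3′ end (in strand orientation) lies
  within `d` = 20 nt of a same-strand gene start **and** coverage is
  continuous into that gene;
* `utr3_fragment`: continuous with an upstream same-strand gene's 3′
  signal **and** mean depth < `r` = 5 × that gene's terminal depth. An
  island 10× *stronger* than the gene it trails stays an sRNA however
  close it sits — this is what keeps genuine sRNAs expressed from sites
  a dozen nt downstream of a gene from being swallowed as UTR signal.

Length bounds (40–300 nt, the short library's size selection) reject but
never silently drop islands. Names are the species prefix plus the locus
digits of the nearest right-flanking protein-coding gene, with
deterministic `a, b, …` suffixes on collision and an `L` marker when only
a left flank exists at a chromosome end.

One caveat discovered during testing and worth stating: the *call count*
is not monotone in `t_isl`. Raising the floor also erodes the coverage
continuity that links UTR fragments to their genes and can split one
island into two, so suppressed islands re-emerge as sRNA calls. What is
monotone — and what the property test asserts — is the island structure
itself: every island at a higher floor nests inside one at a lower floor
and total covered length never grows.

## Conservation

With external homology searches, a link is any hit with E-value
strictly below 1e-06. When linking internally, sequences are compared
all-against-all with a plain Smith–Waterman (+2 match / −3 mismatch / −5
per gap position; deterministic tie-break by leftmost start). The
internal aligner reports no E-value, so a link requires ≥70% identity
over ≥30 aligned columns **and raw score ≥ 50**. The score floor is the
working substitute for the E-value cutoff: in >70% GC sequence, chance
local alignments between unrelated sRNAs routinely reach 70–80% identity
over 30–80 nt, but they score far below genuine homologies, which align
near full length (a worst-case pair of true homologs, each carrying 10%
substitutions from a common ancestor over ≥80 nt, still scores ≥80).
Conservation is any-hit by default; reciprocal-best is available by
flag. Identity is matched columns over alignment length with gap columns
in the denominator.

Per-compartment summaries count each sRNA in the compartment holding its
start position ("conserved" = linked to ≥1 other species); rows carry
`n`, `n_unique`, `n_conserved` and a half-up one-decimal percentage, with
0% exact when nothing is conserved. An sRNA outside every compartment is
a partition violation and raises.

The small-peptide screen takes homolog groups conserved in ≥2 species,
scans each member for same-strand ORFs (ATG/GTG start, TAA/TAG/TGA stop,
≥20 codons, initiator translated as Met), and accepts a group when some
choice of one ORF per member has pairwise relative length difference
≤10% and pairwise similarity ≥65% under a global alignment, where
similarity counts identities plus substitutions within the fixed groups
{ILVM} {FYW} {KRH} {DE} {NQ} {ST} {AG} {C} {P} over all alignment columns
(gaps count against).

## Stable fragments

Detection per gene on the short-library sense track: candidate windows
are runs ≥ `mask_fold` = 5 × the gene *median* depth (with an absolute
floor of 5 reads so silent genes yield nothing), merged over ≤3 nt gaps.
The baseline is the mean over the gene outside all candidate windows,
floored at 1 read (and flagged) when the rest of the gene is empty. A
candidate of length ≥ 20 nt is called when its mean exceeds `min_fold` =
100 × the baseline, strictly; comparing the region maximum instead is
available by flag. The median-based masking bar matters: a strong region
inflates the whole-gene mean enough that any run threshold tied to it
can exceed the region's own depth, and a per-base run test at the 100×
bar fragments genuinely >100× regions whose per-base noise straddles it —
the enrichment test is region-versus-rest-of-gene, so it is applied to
the region mean.

Location classes use a 25-nt end zone in transcript orientation: regions
overlapping it at the 5′ end are `utr5`, at the 3′ end
`utr3_or_intergenic_operon`, otherwise `internal`.

Content analysis reports GC/AT fractions of the region, its gene, and
the 15-nt window immediately 5′ of the region (truncated and flagged near
the transcript start), plus rare-codon fractions over in-frame codons
only. "Rare" is the bottom quartile of relative synonymous codon usage
computed genome-wide from all annotated coding genes.

## Synthetic data: what it emulates and what it does not

The generator lays out, per species, one replicon of 72 protein-coding
genes (lognormal lengths, median ≈ 800 nt, clipped 300–2000) with
exponential intergenic gaps, 0.72 GC sequence, five arm/core
compartments and ten gene clusters. Expression: lognormal long-library
gene depths (median ≈ 60, clipped 15–400), uniform 2–6 reads/base
short-library gene bodies, 10–40 nt default UTR extensions at 0.7× body
depth. Per-base counts are negative binomial (Gamma–Poisson, dispersion
50 — mild overdispersion so thresholds are tested honestly) plus
Poisson(0.05) background on every strand and library.

Planted per species: 6 asRNAs (sharp internal boxes, 30–80 reads/base),
8 cutoRNA pairs (read-through at 25–60 reads/base overlapping the
convergent partner by 100–300 nt), 4 divergent pairs (both 5′ UTRs
crossing 60–150 nt into the partner body), 16–18 sRNAs (40–300 nt;
cross-species families 80–280 nt), and stable regions — five 5′-end,
five 3′-end and six internal (30–90 nt) at log-uniform 100–1000× the
gene's short-library baseline, plus five 50× decoys that must never be
called. Homolog families share a base sequence with exactly
`round(0.10·L)` substituted sites per member; the exact-count scheme
bounds worst-case pairwise identity at 80%, which is what makes the
planted conservation truth table exactly recoverable rather than
recoverable in expectation. Default UTR extensions are suppressed on gap
sides hosting an sRNA so planted sRNAs stay discontinuous from gene
signal, and capped at half the gap elsewhere so tandem genes never fuse
into artificial operons.

What the fixture does *not* emulate — and hence what passing recovery
tests do not establish about real data: overlapping genes and real
operon structure, transcription start/stop heterogeneity (planted
features are boxes with NB noise, so "sharp 5′ boundary" is easier than
in real coverage), sequencing-depth gradients and mappability artifacts,
indels between homologs (point substitutions only), rRNA/tRNA
contamination, and condition-dependent expression. The recovery rates
the acceptance script reports are properties of these study conditions,
not of any real library.

## Determinism and numerics

Same seed, same output, byte for byte: all randomness flows from one
`SeedSequence` (generator), and the pipeline itself is deterministic —
reruns produce identical TSVs. Alignment DP is integer arithmetic; MEV
is integer total over integer length; tie-breaks (alignment start,
ranking by `(fold, gene_id, start)`, name suffixes in coordinate order)
are all total orders. The acceptance fixture (3 × 72 genes, ~85 kb per
replicon) runs end-to-end in well under a minute on one CPU; problem
sizes were chosen so the whole suite exercises every stage at
full-pipeline scale while staying quick to iterate on.

## Known limitations

* Candidacy, continuity and island floors are global per species; no
  local background model (e.g. for depth-variable real libraries).
* The internal homology link has no statistical calibration — the score
  floor is a practical separator under these study conditions, not a
  p-value.
* classification of an antisense island assumes its explaining partner
  extent was measurable in the same library; partners expressed below
  `t_rt` leave islands unclassified rather than guessed.
* Stable-fragment analysis reports sequence content only; it does not
  fold RNA or predict cleavage sites, so "structured" is an
  interpretation the caller must bring.
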