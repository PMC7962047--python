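# Methods

This note documents the models, conventions and numerical choices behind
repeatlens, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Repeat patterns and nomenclature

A repeat allele is a run-length encoding: an ordered list of (motif, count)
runs over 3-nt motifs, with adjacent runs always carrying different motifs.
`parse_pattern` accepts the literature notation of parenthesised groups
with optional multipliers — `(CTG)6(CCGCTG)13(CTG)5` — unrolling hexamer
and longer groups into triplet runs and merging equal neighbours; a literal
`n` multiplier is replaced by a caller-supplied value. `canonical_string`
renders the inverse, collapsing maximal blocks of alternating single-unit
CCG·CTG pairs into `(CCGCTG)k` (count omitted when k = 1; a trailing CTG
run may donate one unit to complete the final pair). A CCG run of count ≥ 2
never collapses, which matches how the field distinguishes `(CCG)2` from
hexamer blocks. Parsing a canonical rendering reproduces the original runs
exactly; this round trip is property-tested on random run lists.

Interruption inventories count every non-CTG unit per motif and localise
each by its distance, in units, to the two tract ends; a unit is classed
`five_prime`/`three_prime` by the nearer end, ties going 3′ (observed
interruptions in the bundled families are 3′-annotated, so ties follow the
field's reporting convention).

The bundled fixture table (`data/interrupted_allele_fixtures.tsv`) encodes
the study families G (37-unit hexamer allele), E (pure and 3′-interrupted
expansions), A4.1 (single 5′ CAG), B2 (three 5′ CCG) and L (pure > 900
units). Patterns written with `(CTG)n` carry fixed n-values (E1 440,
E2.1 350, E3 140, B2 280, L2 957, L3 1156) chosen once to land near the
reported repeat-size modes; they are configuration, not ground truth.

## Synthetic reads

The generator emulates a multiplexed single-locus amplicon run:

* **Layout** — `buffer(5) + barcode(16) + 5′ flank … tract … 3′ flank +
  revcomp(buffer + barcode)`, the two flanks totalling 361 bp including the
  two 20-nt primer sites, so the classic sizing formula
  `units = (product − 361)/3` holds for the unbarcoded product. The flank
  interiors are random-but-fixed synthetic sequence behind one module-level
  seed: the real flanking sequence is not bundled, and nothing downstream
  depends on more than its length and the anchor segments.
* **Mosaicism** — per-molecule total unit counts are drawn from a point
  mass, a discretised lognormal parameterised by its density mode
  (μ = ln mode + σ²), or a weighted mixture of lognormals. The spreads in
  the demo configuration (σ = 0.25 at mode 447, 0.20 at 383, 0.05 per
  mixture component at 173/215) reproduce the broad unimodal and narrow
  bimodal shapes typical of blood mosaicism at this locus, with maxima a
  little over twice the mode for the broadest allele.
* **Rescaling** — a target unit count resizes only the largest CTG run
  (ties toward 5′), holding every interruption block intact, matching the
  `(CTG)n(…fixed 3′ structure…)` convention of the literature patterns.
  Sampled counts are clipped so at least one unit remains in the variable
  run.
* **Errors** — each base errs independently with probability
  1 − target_quality, split substitution : insertion : deletion = 2 : 1 : 1.
  Reported read quality is the realised identity (1 − events/length);
  pass counts are shifted Poisson (mean 8, minimum 1). Per-read target
  accuracy is drawn on the Phred scale (QV ~ N(27, 3), truncated) unless a
  fixed quality is requested. QV20 corresponds to accuracy 0.99.
* **Output** — a single multiplexed FASTQ whose description field carries
  `np=<passes> rq=<quality>` (per-base qualities are constant and
  consistent with rq), with ~50% of reads emitted reverse-complemented, and
  a truth table TSV. Fixed inputs and seed give byte-identical files.

What the generator does **not** model: polymerase kinetics or raw subreads,
chimeras, adapter dimers, and the PCR bias toward preferential
amplification of shorter alleles. Passing tests therefore demonstrate
correctness of the computational pipeline under a clean error model, not
robustness to amplification artefacts in real libraries.

## Read preparation

Filtering keeps reads with pass_count ≥ 3 and read_quality ≥ 0.99 (QV20,
via QV = −10·log₁₀(error)); both thresholds are inclusive and configurable.
Demultiplexing assigns a read to the sample whose buffer+barcode prefix has
minimal edit distance (edlib, prefix mode, both orientations) within a
budget of 2 edits; ambiguous minima go to an unassigned bin. Tract
extraction anchors the 20-nt flank segments adjacent to the repeat with a
Hamming budget of 3 mismatches per anchor — no indels in anchors, so an
indel there demotes the read to not-full-length rather than shifting the
boundary. `on_target` means ≥ 1 anchor found, `full_length` both; the tract
is the sequence strictly between the inner flank boundaries (0-based
half-open), on the strand where the repeat reads as CTG. Replacing
reference alignment with flank anchoring is exact in amplicon context and
keeps the pipeline dependency-free. When more than `analysis_cap` (default
10,000) full-length reads are available, a seeded uniform subsample of
exactly the cap is analysed.

## Decomposition

The decomposer walks codons greedily in a chosen frame, classifying each
into the motif alphabet {CTG, CCG, CAG, CTC} or OTHER. Numerical choices:

* **Frame** — because the 5′ tract boundary comes from flank anchoring,
  the frame whose first pair of consecutive in-alphabet codons starts
  closest to the 5′ end is chosen (ties toward the smaller offset); a
  mid-tract indel switches the frame regime and would mis-vote a global
  codon count. Tracts with no confirmed pair fall back to the
  max-codon-count rule.
* **Re-synchronisation** — on an out-of-alphabet codon the reading point is
  shifted by ±1..2 nt; a shift is accepted if it resumes two consecutive
  alphabet codons (one confirming codon accepted as a fallback when no
  shift achieves two, which rescues tracts with a second error nearby).
* **Unit charging** — consumed bases are charged as one OTHER unit per ~3 nt
  (round(consumed/3)): a 2-nt consumption is a deleted unit (1), a single
  consumed base is a pure insertion (0), 5 nt charge 2. A frame offset of 2
  charges the two leading bases as one broken unit, as does a trailing 2-nt
  remainder. These conventions keep single indels length-neutral: one
  deletion inside a long CTG run yields the pre-deletion unit count with
  noise_units ≤ 1.
* **Rendering** — `call_pattern` drops OTHER runs and emits the canonical
  string, refusing reads whose noise fraction exceeds 10%.

A full dynamic-programming segmentation (`tests/dp_oracle.py`) serves as an
independent oracle: on seeded short tracts with ≤ 2 injected errors the
greedy totals agree with it on ≥ 99% of cases (measured 99.6–100% across
seeds); the disagreement residue is double errors interacting within a few
bases.

## Allele calling and mosaicism

Reads partition at 50 total units (the locus' normal/expanded boundary;
configurable). Percentages round to the nearest integer, halves away from
zero — this reproduces every published percent-expanded figure from its
printed read-count pair.

Mode estimation proceeds in two stages. `estimate_modes` evaluates a
Gaussian KDE (Silverman bandwidth) on the unit counts and keeps up to two
local maxima whose prominence exceeds 5% of the global maximum (fewer than
10 counts, or zero spread, fall back to the empirical mode). The argmax of
a broad mosaic distribution carries sampling jitter of many units, so
`refined_modes` — used by the sample summary — treats the KDE peaks as
mode *count and seeds* and refits them as a Gaussian mixture on log unit
counts (seeded, one component per retained peak), reporting each
component's density mode exp(μ − σ²). On degenerate inputs the refinement
passes the KDE/empirical estimate through unchanged. Reporting is limited
to two modes; the summary lists normal-allele modes first.

The interruption consensus is position-aware. At QV20, sequencing errors
fabricate interruption-like codons (deleting the G of a CTG yields a CTC;
~2 spurious units per 1000-unit read), so a plain per-read majority would
report interruptions on pure alleles. True interruptions recur at a fixed
distance from their nearer tract end across reads (the far end absorbs the
mosaic length variation), while error-induced ones scatter uniformly: only
interruption units whose anchored position recurs in ≥ 25% of reads
(window ± 2 units) are counted. The consensus then reports the majority
count per motif (`6x CCG`), a range (`2–3x CCG`) when the top two counts
each exceed 25% of reads, or `No obvious interruption`.

## TP-PCR simulation

The ladder model is positional: the repeat-annealing primer needs
`anneal_units = 5` consecutive CTG units (five full repeat-complementary
triplets), a site exists wherever such a window begins, and coordinates are
1-based units from the assayed end (3′ by default, implemented by
reversing the unit sequence). One peak per site at
`3·(q + anneal_units − 1) + 60` bp with intensity decaying exponentially
(rate 0.002/bp) — both the 60-bp offset and the decay are qualitative
stand-ins; only peak/gap *positions* are test surface. Gaps are maximal
site-free unit intervals flanked by sites. Interruptions closer together
than one annealing window cannot re-establish a site between them, so they
act as one cluster; gap count equals cluster count on every bundled
fixture, and the family traces reproduce the assay's qualitative geometry
(pure parent: no gap; two-interruption parent: two gaps; six-interruption
fetus: three gaps; hexamer allele: one large gap).

## Haplotype calling

Genotypes are unphased, so the call is compatibility-based: "A" when every
panel marker carries ≥ 1 haplotype-A allele, "non-A" when any marker
carries none, "ambiguous" (with the missing ids) when the panel is
incomplete. `matched_markers` counts markers with at least one matching
allele. A heterozygous-compatible sample could in principle carry both
alleles on the non-A chromosome; phased haplotyping is out of scope and
this limitation is deliberate.

## Problem sizes and determinism

The test suite runs the full pipeline at 40–300 reads per sample and the
parameter-recovery checks at 2000 reads per sample (modes 173, 447, 1156
and a 173/215 mixture, quality 0.99) — sizes at which the estimators'
behaviour is already stable while the whole suite stays fast. All
randomness flows through seeded numpy generators: fixed configuration and
seed give byte-identical FASTQ, truth and summary tables (figure files are
stable given fixed toolkit versions). `scripts/acceptance.py` recomputes
only desk-scale quantities (exact decompositions of published patterns and
count arithmetic) and is deterministic by construction.

## Known limitations

* No amplification-bias model: real amplicon libraries over-represent the
  normal allele and shorter expansions.
* The decomposer reports, but does not phase, interruption subpopulations;
  whether a minority 3-interruption cell population is a distinct allele or
  decomposition noise is left to the reported per-read distribution.
* Anchor-based extraction assumes the configured flank sequences; reads
  from other loci are off-target by construction rather than mapped.
* Intensity values in simulated TP-PCR traces are qualitative.
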