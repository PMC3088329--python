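# Methods

## Screening pipeline

Input is a FASTA multiple sequence alignment of protein-coding mtDNA
(equal-length records; IUPAC ambiguity letters and `-` gaps allowed).
The pipeline is:

1. **Collapse** identical residue strings to unique haplotypes (first
   occurrence kept, order preserved). All trait statistics are defined
   on unique haplotypes, not individuals, so deeply sampled haplotypes
   do not dominate the counts.
2. **Consensus**: per column, the most frequent base among A/C/G/T;
   ambiguity codes are excluded from the tally; ties resolve
   alphabetically (A < C < G < T). A column where gaps outnumber the
   most frequent base becomes a gap — this makes a minority insertion
   appear as consensus gaps so indel counting sees it as an insertion,
   rather than charging every other haplotype with a deletion.
3. **Reading frame**: the offset in {0,1,2} whose ungapped-consensus
   translation (invertebrate mitochondrial code, NCBI table 5) has the
   fewest internal stop codons; ties break to the smaller offset; if
   every frame exceeds 10 % internal stops the input is rejected as
   non-coding. A CLI flag overrides auto-detection.
4. **Substitution profiling** (below), then **trait evaluation**.

The consensus was chosen as the reference for substitution counting
because an intraspecific haplotype survey has no natural outgroup and
the consensus is reproducible from the input alone; any designated
reference sequence could be substituted by prepending it and reading
the site table.

## Counting conventions

* A **substitution event** is a distinct (column, non-consensus allele)
  pair, counted once however many haplotypes carry it. Two different
  alternative bases at one column are two events. This makes all counts
  invariant under haplotype duplication.
* Only columns inside complete codons (per the frame offset) carry
  classifiable events; leading/trailing partial-codon columns still
  count toward GC content. Columns whose only deviations are gaps or
  ambiguity codes are not variable.
* Multiple substitutions within one codon are classified independently,
  one change at a time against the consensus codon, avoiding pathwise
  ambiguity at the cost of ignoring within-codon epistasis (rare at
  intraspecific divergence).
* A change producing a stop codon is nonsynonymous *and* counts toward
  "additional stop codons" (separate traits). Additional stops are
  (haplotype, codon) pairs whose codon is a stop while the consensus
  codon is not, so a shared terminal stop never counts.
* **Transition**: {A,G} or {C,T} exchange. 3rd-position events split
  into ts3/tv3; the overall ts/tv ratio is reported without an
  acceptance range.
* **GpC context**: a C→T event whose 5′ *consensus* neighbour is G, read
  literally on the given strand (no reverse-complement CpG scan; the
  methylation literature writes the dinucleotide 5′→3′ as GC). A
  documented alternative would scan CpG context instead; the trait's
  denominator is C→T events with a defined 5′ base (an event at
  column 1 is excluded).
* **Indel events**: per haplotype, each maximal gap run against the
  consensus is one deletion (haplotype gapped) or one insertion
  (consensus gapped). Events whose length is not a multiple of 3 are
  additionally flagged as frameshifts.
* Internal coordinates are 0-based half-open; everything reported is
  1-based.

## Trait evaluation

The eleven traits (codon-position percentages, nonsynonymous
percentage, GpC share of C→T, insertion/deletion/extra-stop counts,
3rd-position ts/tv percentages, GC content) are compared against
expectation ranges for authentic insect mtDNA taken from the
literature. The ranges are treated as authoritative constants — they
derive from reference datasets external to the screened alignment — and
are user-overridable via a YAML file for other taxa or genes. Interval
traits pass inside `expected ± margin`; the three zero traits require
an exact 0.

Traits with a zero denominator (e.g. no C→T events at all) are "not
evaluable" and pass with an annotation: absence of events is no
evidence of nuclear origin. The verdict is PASS only when all eleven
traits pass (a relaxed k-of-11 mode exists for exploration and is
clearly labelled in the report).

Each observed proportion is annotated with a score confidence interval
obtained by inverting the one-degree-of-freedom chi-square
goodness-of-fit statistic (the Wilson interval, computed in closed
form). It is reporting-only and never overrides the published margins.

## Simulator

`numt_simulator` evolves haplotypes independently from one random
stop-free ancestor (star phylogeny — the screen tests site patterns,
not tree structure, so no genealogy is simulated). Per haplotype,
Poisson(`events_per_haplotype`) substitution events are realized by a
proposal/acceptance scheme:

1. a codon position is drawn from `position_weights`;
2. a (site, alternative base) proposal is drawn within that position
   with joint weight `kappa` for transitions and
   `gpc_ct_multiplier × kappa` for C→T at sites whose current 5′ base
   is G — the multiplier is a per-proposal *rate*, i.e. GpC sites
   mutate more often, which is the methylation mechanism being
   imitated;
3. proposals creating a stop are retained with probability
   `stop_acceptance`, other nonsynonymous proposals with
   `nonsyn_acceptance`, synonymous ones always; rejected proposals are
   redrawn within the same position, so `position_weights` describe the
   *realized* substitution spectrum with selection acting within codon
   positions.

Indels follow as Poisson(`indel_rate`) events per haplotype (deletion
or insertion with equal probability, geometric lengths); insertions
become new alignment columns gapped in every other haplotype. All draws
come from one seeded generator in fixed order, so identical parameters
give byte-identical alignments and event logs.

### Regime defaults

The **mito** regime encodes authentic insect mtDNA: realized position
weights (0.149, 0.045, 0.806), ancestral GC 0.29, no indels, no stop
fixation — all anchored to the published expectation centers. The three
knobs the literature gives only qualitatively were calibrated once, by
simulation, so the retained spectrum sits at the centers of the
published intervals, and then frozen: `kappa = 5.0` (3rd-position
transversions ≈ 15 %), `nonsyn_acceptance = 0.012` (nonsynonymous
≈ 7.5 %), `gpc_ct_multiplier = 2.4` (GpC share of C→T ≈ 25 % — note
even unmethylated mtDNA shows an above-baseline GpC share, since the
expectation center of 25 % exceeds the ~15 % context frequency).

`events_per_haplotype` defaults to 4.5, giving ≈ 220 distinct events
over 58 haplotypes × 519 codons. A default matching the reference
dataset's ≈ 125 events was considered and rejected: at that depth the
battery's own sampling noise becomes an irreducible false-flag floor
(the 2nd-position trait expects ~5 events against a 1–8 % window, and
the GpC trait ~17–19 C→T denominators against an 11–39 % window; each
alone fails 8–15 % of perfectly centered runs, capping the joint PASS
rate near 75–80 %). At 4.5 events/haplotype — still ordinary
intraspecific divergence, ~14 % variable columns — the mito regime
passes ≈ 94 % of seeds while the mean recovered spectrum stays within
~1.7 points of the configured weights.

The **numt** regime encodes a neutral nuclear pseudogene from the
qualitative contrasts the literature reports, and is labelled as
constructed, not measured: flat position weights, `kappa = 2`, all
nonsynonymous and stop-creating changes retained, `indel_rate = 0.15`
per haplotype, `gpc_ct_multiplier = 8`. It is flagged in ≈ 100 % of
runs, mostly by the zero-tolerance indel/stop traits.

### What the simulator does and does not show

The generator emulates the *mutational signatures* the screen reads:
position bias, transition bias, selection against amino-acid changes,
GpC-context hypermutation, indel tolerance and base composition. It
does not model genealogy, recombination, heteroplasmy, rate variation
among sites, or PCR/sequencing artefacts such as chimeras and
co-amplified mixtures. Passing the simulated battery therefore shows
the screen reads the intended signatures correctly; it does not show
how the screen behaves on low-level numt/mtDNA mixtures within one
amplicon, which produce patterns none of the regimes generate.

## Primer scanning

Conserved windows are maximal alignment stretches, gap-free in the
chosen core taxa, whose per-column degeneracy product (over the core)
stays within budget; a two-pointer sweep in log space finds them in one
pass. Non-core taxa never constrain the primer but are reported via
mismatch counts, mirroring the practice of adding outgroup taxa to an
alignment only to locate conservation. The degenerate consensus uses
the IUPAC letter covering exactly the observed base set. Amplicon
lengths are measured 5′-end of the forward site to 5′-end of the
reverse site inclusive (both primer footprints counted, as product
sizes are conventionally quoted); equally good alternative binding
sites raise an explicit ambiguity error rather than guessing. Melting
temperature and secondary structure are out of scope.

## Numerical and degenerate-input choices

* Consensus ties: alphabetical (deterministic and documented).
* Frame-detection failure threshold: > 10 % internal stops in all
  frames.
* `proportion_ci` uses `chi2.ppf(1 − α, 1)` and the closed-form score
  solution; no iteration, so no convergence concerns.
* Profiling a single unique haplotype returns all-zero counts (no
  events by definition); screening requires ≥ 2.
* An all-gap/ambiguity alignment has undefined GC content and raises.
* Simulator proposal loops are capped (10⁴ attempts) so a regime with
  acceptance 0 at a position that offers only nonsynonymous changes
  skips the event instead of spinning.

## Problem sizes

The test suite and the acceptance script validate at the reference
scale the screen targets — 58 haplotypes × 519 codons — with 100 seeded
runs per regime for the discrimination and spectrum-recovery checks,
plus ~200 smaller randomized alignments for the counting invariants.
These sizes were chosen to match the reference dataset's geometry while
keeping a full validation run around a minute.

## Known limitations

* The GpC-context trait follows the literal 5′-G reading; if the
  intended context were CpG the trait values would differ. The site
  table exposes every C→T event with its context so either convention
  can be audited.
* Expectation ranges are insect-COI-specific; other genes or taxa need
  a custom reference file.
* The screen detects datasets *dominated* by numt-derived sequence or
  containing clear pseudogene signatures; a single co-amplified numt
  haplotype among many authentic ones moves most traits only slightly.
* Percentages are computed on unique haplotypes; a survey weighted by
  individuals would need the uncollapsed counts (reported in the
  metadata) re-weighted externally.
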