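# Methods

## The question the pipeline addresses

"Bivalent chromatin" is classically inferred from overlapping H3K4me3 and
H3K27me3 ChIP-seq enrichment at a promoter.  That inference is ambiguous:
overlapping bulk signals arise equally from (a) single nucleosomes
carrying both marks, (b) neighbouring nucleosomes carrying one mark each
("zonal" bivalency), or (c) a heterogeneous cell population in which each
cell carries only one of the marks.  Sequential ChIP of mononucleosomes
(primary anti-H3K27me3, secondary anti-H3K4me3) physically selects
case (a).  The pipeline analyses such data; the simulator generates all
three cases under explicit parameters so each analysis stage can be
validated against known truth.

## Generative model

**Genome and annotation.**  Promoters are placed on a regular grid with
spacing ≥ 2 × (5000 + max K27 span) so islands of neighbouring genes can
never merge; strands are random.  Each gene carries one archetype:
`bivalent`, `K4_only`, `K27_only`, `silent_methylated`, or `none`.
Bivalent, K4-only and silent-methylated promoters receive a CpG island
within ±1500 bp of the TSS (density U(0.04, 0.12) CpG/bp).  Expression is
drawn per archetype on a log2 microarray-intensity scale (active K4-only
genes highest, silent genes lowest); two array probes per gene scatter
around the true value.  Silent-methylated promoters get one Infinium-style
probe with β ≥ 0.76 and a well-detected p-value, all other promoters only
probes with β < 0.25.  Enhancers are placed midway between promoter
arrays; 30 % contain a CpG island.

**Nucleosomes.**  Each promoter carries a phased array of 147-bp
footprints at a 200-bp repeat (147 + 53 linker), tiled to cover the
±5 kb profile window, one copy per simulated cell (default 100 cells).
Geometry is strand-oriented:

* **NDR** — positions with dyad offset in [0, 800) bp downstream of the
  TSS are occupied per cell with probability `ndr_occupancy` (default
  0.8), and marks on the remaining NDR-resident copies are retained with
  probability `ndr_mark_retention` (default 0.1).  Two mechanisms are
  deliberate: occupancy thinning shows up in the input track, but divides
  out of the chip/input ratio; the mark attenuation on fragile NDR
  nucleosomes is what produces the central dip of the normalized H3K4me3
  profile.  Silent promoters have full occupancy and no NDR.
* **Mark domains** — per gene, a K4 domain width is drawn from
  U(1000, 4000) bp centred on the TSS and a K27 width from U(4000, 8000)
  bp centred 2000 bp upstream.  These ranges are calibrated so the called
  islands land in the expected size ranges (K4 ≈ 1–4 kb, K27 ≈ 4–8 kb)
  and their overlap zones are smaller than either.
* **TSS-proximal position** — the nucleosome with dyad within 150 bp of
  the TSS and outside the NDR (the −1 nucleosome under the defaults).  At
  bivalent promoters each of its copies carries *both* marks with
  probability `f_biv`, otherwise one mark chosen per cell.  Elsewhere in
  the domain overlap each cell carries exactly one mark — zonal bivalency
  with no doubly-marked particle.
* **H2A.Z** — TSS-proximal copies of CpG-island genes carry H2A.Z with a
  logistic probability in the gene's expression rank (steepness 6); the
  exact form is a modelling choice, only the direction matters.

**Read emission.**  Total reads per track ~ Poisson(`depth`).  Each read
is background with probability W_bg/(W_bg + W_sig), where
W_bg = `bg_rate` × genome length (a *relative* background weight per bp,
default 1e-5) and W_sig sums per-position capture weights: ε₁ × marked
fraction for single ChIP, occupancy for input, and
ε₁ε₂ × bivalent + φε₂ × (K4-only) fractions for the sequential track.
Making background relative keeps total read count ≈ `depth` and makes the
sequential TSS signal strictly monotone in φ.  Signal reads start at the
147-bp fragment's 5′ end on a random strand; fragment boundaries get
±20 bp of uniform MNase wobble (`frag_jitter`).  Without the wobble every
read from a phased nucleosome would be byte-identical and the redundancy
filter would collapse the (deliberately concentrated) miniature-genome
pileup to ~2 reads per nucleosome, equalizing chip and input.  Reads also
carry simulated MAPQ/NM values so the quality filter has something to do.

## Analysis choices

* **Filters** — MAPQ "better than 20" is implemented strictly (> 20);
  duplicates keyed on (chrom, start, strand), first occurrence in sorted
  order retained, which makes the filter idempotent and order-independent.
* **Island caller** — windows tiled from coordinate 0, final partial
  window dropped; tag = 5′ end shifted by fragment_size/2 toward 3′.
  Eligibility is a Poisson upper tail against
  λ = N·W/(G·egf) at p ≤ 0.2.  Significance replaces SICER's
  random-background E-value machinery with a per-island Poisson tail +
  Benjamini–Hochberg at q ≤ 0.01 — self-contained and exactly testable
  against brute-force oracles.  In control mode the island rate is the
  library-scaled control count (pseudo-count 1) **floored at the
  genome-wide background expectation** for the island span.  The floor
  matters: candidate islands are pre-selected for high chip counts, so
  without it a randomly low control makes null islands significant; with
  it, 10 null replicates keep essentially no islands at q ≤ 0.01.
* **Classification** — default radius 2500 bp; the broader ±5000 bp
  "enriched promoter" definition is available via `radius`.  Bivalency
  requires the K4 and K27 islands to mutually overlap; promoters where
  both marks hit the window without island overlap are flagged
  `bivalent_zonal` and fall into class `none` under the strict default
  (a loose co-occurrence mode classes them bivalent).  Alternate
  transcripts are classified independently, one call per TSS.
* **Profiles** — coverage is extended-fragment overlap per 10-bp bin
  (fragment 200 bp from the 5′ end), not tag midpoints; bin k covers
  [tss − flank + k·bin, …) in oriented coordinates with the TSS at the
  left edge of the central bin; minus-strand rows are column-reversed.
  Normalization is a ratio of category means with pseudocount 0.5 —
  keeps zero-input bins finite without distorting enriched bins.
  Enhancer bodies are split into 10 equal intervals (floor-rounded
  edges) of mean per-base coverage, with 10-bp-binned 5-kb flanks.
* **Strata** — CpG density metric is the annotation's CpG-per-bp field,
  percentile-ranked within the analysed set; quantile groups are
  rank-based with ties broken by stable input order and remainders to the
  lowest groups; expression per gene is the max over probes.  An
  `ambiguous` methylation class (some β in [0.25, 0.75), none above)
  completes the partition beyond the two defined extremes.

## Problem sizes

The reference conditions used throughout the tests and the acceptance
script: 200 promoters (50 per archetype over four archetypes), 40
enhancers, ~5.2 Mb over two chromosomes, 100 cells, 2 × 10⁵ reads per
track, f_biv = 0.8, φ = 0.  The flow-through and per-seed replicate
controls use 100 promoters at 10⁵ reads.  These sizes give per-window
counts comfortably above the eligibility threshold at promoters while
keeping a full pipeline run in seconds.

## What passing tests do and do not show

The simulator produces idealized data: one nucleosome phase (no cell-to-
cell positional fuzz beyond optional jitter), uniform Poisson background,
no mappability structure, no copy-number variation, no PCR bias beyond an
optional duplication rate, no enhancer chromatin states (enhancer
intervals exist for CpG-split and profile plumbing only), and no
FASTQ/alignment stage.  Passing the suite therefore demonstrates that the
*analysis* is correct and well-calibrated under its own assumptions — not
that those assumptions capture every property of real sequencing data.
Real-data effects that would stress the pipeline (non-uniform background,
fragmented islands, antibody efficiency differences between marks) should
be explored by moving the simulator away from its defaults.

## Known limitations

* The island caller is a SICER-parameterized re-design, not a
  re-implementation; E-value-based score thresholds are not reproduced.
* Sequential-ChIP capture efficiencies ε₁, ε₂ rescale all signal weights
  jointly in single-ChIP tracks, so they are only identifiable relative
  to the background weight.
* `f_biv` has no genome-wide empirical prior; the default 0.8 is a study
  condition, not a biological claim.
* The methylation model is binary by construction; the `ambiguous` class
  never arises under simulator defaults.
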