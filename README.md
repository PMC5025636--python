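# bivalseq

Analysis pipeline for **sequential ChIP-seq (re-ChIP) of bivalent
mononucleosomes** — promoters carrying both the activating H3K4me3 and the
repressive H3K27me3 mark.  Bulk ChIP-seq can only show that the two marks
*overlap zonally* at a promoter; that overlap is equally consistent with a
heterogeneous cell population in which each cell carries one mark or the
other.  A sequential immunoprecipitation (anti-H3K27me3 followed by
anti-H3K4me3) of MNase-digested mononucleosomes selects the ~147-bp
particles that truly carry both marks at once.  `bivalseq` implements the
downstream computational analysis of such an experiment, together with a
generative model that makes every stage verifiable without external data.

Intended users: computational epigenomics people who want a small,
fully-seeded, text-file-based pipeline for promoter bivalency calls — and a
simulator that can express the difference between true mononucleosome
bivalency, population heterogeneity, and primary-IP flow-through.

## What it computes

1. **Read filtering** — duplicate removal at a redundancy threshold of 1
   per (chrom, start, strand), MAPQ > 20, NM ≤ 1.
2. **Island calling** (SICER-style parameterization).  Reads are shifted to
   fragment midpoints, counted in *W* = 200 bp windows, and windows with
   count *c* are eligible when the Poisson upper tail
   P(X ≥ c | λ) ≤ 0.2 against the background rate

       λ = N · W / (G · egf),   egf = 0.75.

   Eligible windows separated by at most *g* ineligible base pairs
   (g = 600 for narrow H3K4me3, g = 1000 for broad H3K27me3) merge into
   islands scored by Σ −ln Poisson(cᵢ; λ).  Island significance is a
   Poisson upper tail of the island tag count against the library-scaled
   control count (floored at the background expectation), with
   Benjamini–Hochberg control at q ≤ 0.01.
3. **Promoter classification** — a promoter is *bivalent* when an H3K4me3
   and an H3K27me3 island intersect the TSS ± 2500 bp window *and* each
   other; otherwise K4-exclusive / K27-exclusive / none.
4. **Profiles** — fragment coverage in 10-bp bins over TSS ± 5000 bp,
   strand-oriented, averaged per category and normalized as
   (mean chip + 0.5)/(mean input + 0.5); enhancer bodies are length-scaled
   into 10 intervals with 5000-bp flanks.
5. **Stratification** — promoter CpG status (island within ± 1500 bp of the
   TSS, sibling-transcript removal rule), CpG-density and expression
   quintiles, and Infinium-style methylation classes (any well-detected
   probe with β ≥ 0.75 → methylated; all β < 0.25 → unmethylated).
6. **Simulator** — miniature genome with phased nucleosome arrays, per-cell
   mark flags, a nucleosome-depleted region (NDR) downstream of active
   TSSs, and five read tracks (H3K4me3, H3K27me3, H2A.Z, sequential ChIP,
   input).  The key dials: `f_biv` (fraction of TSS-proximal nucleosome
   copies that are truly bivalent) and `phi` (flow-through rate of K4-only
   nucleosomes into the sequential IP).

## Worked example

```sh
bivalseq demo-config --out demo.yaml
bivalseq run-all --config demo.yaml --out demo_run
python -c "import json; print(json.load(open('demo_run/summary.json'))['class_counts'])"
```

The demo simulates 200 promoters (50 each of bivalent, K4-only, K27-only,
silent-methylated archetypes) at 2 × 10⁵ reads per track with
`f_biv = 0.8, phi = 0`, then runs the full pipeline.  Its `summary.json`
reports:

```
"archetype_recovery": 1.0,
"class_counts":  {"K27_exclusive": 50, "K4_exclusive": 50, "bivalent": 50, "none": 50},
"island_counts": {"H2AZ": 174, "K27": 100, "K4": 102},
"overlap_zones": {"n": 52, "min_width": 400, "median_width": 1600.0, "max_width": 3800}
```

Every promoter class matches its simulated archetype; the called H3K4me3
islands are narrow (median 2.4 kb), the H3K27me3 islands broad (median
5–6 kb), and the K4×K27 overlap zones smaller than either (median 1.6 kb)
— the size ordering expected for these marks.  The normalized
sequential-ChIP profile over bivalent promoters peaks within tens of bp
of the TSS (the bivalent nucleosome sits at the −1 position), while the
H3K4me3 profile dips in the depletion zone just downstream of the TSS and
the H3K27me3 profile is bimodal around it.

Each stage is also available standalone (`bivalseq simulate | filter |
call-islands | classify | stratify | profile`) on BED/TSV files.

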