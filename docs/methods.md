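# Methods

## Kinetic model of the washout experiment

Each gene carries one transcription unit with a pause site a uniform
20–60 bp downstream of the TSS.  During a block of pause release lasting
`block_minutes` (default 60), initiation continues at rate α per minute per
gene but released elongation is impossible, so at washout (t = 0) every
gene body is clear — the configuration validator enforces
`block_minutes · v ≥ max gene length` — and the pause site holds
`min(Poisson(α · block), capacity)` polymerases (capacity defaults to 1,
a steric-occlusion assumption).

At t = 0 each paused polymerase escapes after an exponential waiting time
with rate β (default half-time 30 s, i.e. β = ln 2 / 0.5 min⁻¹ — the
simplest memoryless escape model) and then translocates at the constant
rate v (default 2.2 kb/min).  Fresh initiations continue at α during the
label window and queue through the same escape step.  Premature
termination removes a polymerase per kb of travel with probability π
(default 0.02/kb), implemented as an exponential stopping distance with
mean 1000/π bp.

Only RNA synthesized during the label window is observed: a polymerase
released at time r contributes a labeled span from the pause site to
`min(v·(T − r), termination point, gene end)`.  Reads are Poisson with mean
`depth · labeled bp / 1000` (default depth 50 reads per kb of labeled RNA),
placed uniformly over the span on the sense strand, on top of a uniform
background of `bg` reads/kb/strand (default 2).  A per-sample recovery
efficiency thins every read source — signal, background, and spike-ins —
identically; this is the confound spike-in normalization removes.

The null genotype differs from wild type only through configured effects:
a 10% slower pause release (β × 0.9, identical v) and the per-enhancer
eRNA multipliers below.  Because the front position depends on v and only
weakly on β, the designed outcome is "no rate difference", mirroring a
lesion upstream of productive elongation.

## Steady-state model

Gene-body expected density is `depth · s_g · exp(−π · x_kb)` reads per kb,
where s_g is a per-gene lognormal strength (σ = 0.8) scattering expression
over ~2 orders of magnitude; the pause bin holds an extra α/β-occupancy
peak; past the TES the terminal density decays exponentially over
`term_distance` (default 2 kb).  Enhancers emit bidirectional eRNA centered
on the peak: transcript length is a truncated exponential (mean 1 kb,
bounds 0.2–2 kb), so expected coverage at distance d from the center is
the length survival function, normalized so an enhancer's total output is
`erna_rate · score · multiplier` reads (score lognormal, σ = 0.5).  In the
null condition a configured subset of enhancers (default 50 of 150)
carries multiplier 2; genes whose TSS lies within 20 kb of an enhancer
have their initiation rate multiplied by
`1 + 0.5 · (multiplier − 1) · exp(−d / 10 kb)`, a distance-decaying
coupling that produces the neighbor-gene upregulation gradient.

Spike-ins are eight species with abundances spanning two orders of
magnitude (total ≈ 2.5 × 10⁴ expected reads at efficiency 1); observed
counts are Poisson(abundance × per-condition efficiency), defaults 1.0
(wt) and 0.7 (null).

## Genome generator

Two 5-Mb chromosomes, 500 genes with lognormal lengths (median 9 kb,
σ(log) = 0.8, clipped to 2–100 kb), random strands, ≥ 2 kb flanks; the
resulting annotation yields ≈ 145 genes > 15 kb and ≈ 30 genes > 30 kb,
enough for stable 5- and 10-min metagenes while a full run stays in
seconds.  Intergenic enhancers (400 bp) keep ≥ 0.5 kb clear of every gene
span; standalone enhancers are kept > 12.5 kb apart so that the
superenhancer rule — clusters of ≥ 3 enhancers within 12.5 kb — recovers
exactly the 4 built clusters; 30 intragenic enhancers sit inside gene
bodies.

## Front calling and rate estimation

Per library, sense-strand density is extracted in TSS-relative bins (50 bp
default — coarse against the 20–60 bp pause region but small against the
kb-scale front), minus-strand genes flipped, each library scaled to reads
per million, and genes averaged unweighted (profile line-plot convention);
genes whose window would run off the chromosome are dropped.  Replicate
experiments are simulated in duplicate and averaged at the profile level
before front calling (averaging first is the convention adopted here; the
alternative order is not exposed).

Background is the median of the most distal 25% of the window — a robust
operationalization of "approaches background", since the window extends
well past any plausible front (−2…+18 kb at 5 min, −2…+34 kb at 10 min).
The threshold is background + 5% of (smoothed max − background).  A 5-bin
centered moving mean locates the peak and anchors the run detection (the
first run of ≥ 3 consecutive sub-threshold smoothed bins downstream of the
peak, which suppresses single-bin noise crossings); the reported position
is then refined on the *raw* profile — walking back to the last raw bin at
or above threshold and interpolating linearly inside the crossing bin — so
smoothing cannot smear a sharp front by half its window.  Scanning starts
at the profile maximum, not the TSS, so the pause peak cannot trigger a
spurious crossing.

The two-timepoint rate is `(x(T₂) − x(T₁)) / (T₂ − T₁)`; the
single-timepoint fallback `x(T)/T` is available when only one labeling
time exists.  Uncertainty comes from a gene-resampling bootstrap
(≥ 100 resamples, percentile 95% CI) over cached per-gene profile rows;
resamples whose front cannot be called are tolerated up to 20%.

A deliberate property of the assay, reproduced here: premature termination
thins the pioneering cohort with distance, so the *measured* front speed
slightly underestimates the true v (≈ 2.03–2.10 recovered at true 2.2
with π = 0.02/kb).  The estimate remains inside the published 2–2.4 kb/min
band and within 10% of truth; setting π = 0 removes the attenuation.

## Quantification choices

* **Normalization.** Spike mode multiplies each condition's counts by
  `median(known abundance / observed spike count)`; library mode scales per
  million.  Both are exposed because published analyses name both a
  count-based normalization and spike-ins without stating which governed
  the enhancer fold changes; the drivers report them side by side (they
  agree on the simulated data).
* **Fold change.** `(null + p)/(wt + p)` with pseudocount p = 1 normalized
  unit, classified up/down/unchanged at FC > 1.5 (and < 1/1.5).  This is a
  deliberate simplification of dispersion-aware differential testing: the
  threshold rule is the operative classifier being reproduced, and the
  calibration tests show it behaves as a detector (≤ 5% changed under the
  all-multipliers-one null, ≥ 90% of doubled enhancers called up).
* **eRNA windows** are peak ± 1 kb, counted on both strands (eRNA is
  bidirectional; no strand rule is imposed).
* **Distance strata** measure enhancer-edge to gene-TSS (the TSS is the
  transcriptional readout point) with bins [0, 20), [20, 40), [40, 60) kb —
  a gene exactly 20 kb away falls in the middle bin — and genes beyond
  60 kb excluded.
* **Processivity** is the distal (TES−5…−1 kb) over proximal
  (TSS+1…+5 kb) mean sense density; genes too short for both windows, or
  with zero proximal signal, are dropped with a warning.  The ratio equals
  `exp(−π · (L_kb − 6))` in expectation.
* **Readthrough** is mean sense density over (TES, TES+10 kb], clipped at
  chromosome edges and downstream neighbors; run-level summaries use the
  median across genes, which is robust to the minority of
  enhancer-coupled genes that are genuinely upregulated in the null.

## Annotation choices

Feature categories use the annotatePeaks-style midpoint rule with priority
promoter (TSS −1 kb…+100 bp) > TTS (TES −100 bp…+1 kb) > gene body >
intergenic; the windows are configurable assumptions.  Ties across genes
break by smallest |distance to TSS|, then lower coordinate.  The genome
background pie partitions every base by the same priority.  Single-exon
gene models mean the genic-body category is not subdivided into
exon/intron.  "Intergenic" and "bound gene" share one span definition —
the strand-aware [TSS − 0.5 kb, TES] window — and are logical complements.
Enrichment tertiles split summed peak score over the gene span at the
33.3/66.7 percentiles, ties to the lower tertile (all-equal scores
collapse into one tertile by construction).

## Reproducibility

One global seed fans out to per-stage child seeds by fixed offsets, so any
stage can be re-run in isolation; all randomness flows through
`numpy.random.default_rng` seeded sequences.  `run_all` writes every
intermediate as a standard text format (bedGraph, BED12, BED6, TSV) plus a
`report.json` whose floats are rounded to 6 decimals and keys sorted —
byte-identical across runs of the same config and seed.

## What the simulator does not model

Sequence-level reads (no FASTQ), splicing, divergent antisense
transcription at promoters (its magnitude in the motivating system is not
quantified, so it is excluded rather than guessed), exon/intron structure,
chromatin-profiling peak signal (peaks are consumed as intervals), and
per-gene elongation-rate variation (a single v; the estimator is aggregate
by design).  Passing tests therefore demonstrate correctness of the
estimators under the stated kinetic model, not robustness to every failure
mode of real libraries (mappability, GC bias, transcript isoform
ambiguity).
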