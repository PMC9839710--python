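# Methods

This note documents the models, defaults and numerical choices behind
`chiatac`, and what the synthetic-data experiments do and do not establish.

## Library model and PET extraction

A proximity-ligation + tagmentation fragment is modelled as
`tagA + J + tagB`, where `J` is the 19-nt bridge-linker junction
`CGCGATATCTTATCTGACT`. The double-stranded bridge linker has a one-base
overhang between its two printed strands; detection treats the junction as
this single 19-mer (biotin-dT read as T) or its reverse complement, with a
Hamming tolerance, so the overhang offset is immaterial to splitting and is
ignored in simulation.

Detection scans every offset of a read in both orientations and keeps the
lowest-mismatch, then leftmost match (forward orientation wins exact ties);
`max_mismatch` defaults to 2, large enough for sequencing errors yet small
enough that a random 19-mer placement is vanishingly unlikely to pass.
Fragments shorter than `min_tag_len = 16` nt after splitting are dropped,
matching the minimum retained read length after trimming. A read running
antisense to the fragment sees the junction reverse-complemented, which
identifies which side of the ligation each sub-read came from; one PET is
built per read pair with tags on both sides, taking the longest fragment
per side when both mates cover it. Read pairs with one usable side are
"singletons": they can contribute to 1D coverage but never to PETs —
whether the original pipelines merge them into peak coverage is not
established, so this package flags the choice rather than asserting it.

Deduplication collapses PETs with identical 5′ coordinates and strands of
both tags; no positional tolerance is applied because none is documented
for the assay, and exact-coordinate keys make duplicate multiplicity an
exact conserved quantity. PET span is the distance between tag midpoints,
for consistency with loop span (anchor-midpoint distance); `cis_long`
means span strictly greater than 8,000 bp, and the library yield statistic
is non-redundant cis-long PETs per 10⁸ raw read pairs.

Alignment is delegated: tags accept genomic coordinates from an external
aligner or, on synthetic data, from the generator's junction table (mate 1
always starts at the fragment's leading edge, so an A-side fragment of
length ℓ is `[endA − ℓ, endA)` and a B-side fragment `[startB, startB + ℓ)`
in every orientation). This keeps the pipeline testable without bundling
an aligner.

## Peak calling

Coverage is per-base tag pileup; SPMR (signal per million reads) divides by
total tags × 10⁻⁶. The caller is a deliberately minimal local-lambda
Poisson scan, not a reimplementation of any published caller: pileup at
every 10th base is tested against `max(chromosome mean, 1 kb window mean,
10 kb window mean)`, BH-corrected across all evaluated positions
genome-wide, merged within 100 bp, with calls < 100 bp discarded and the
summit at the pileup argmax. Defaults (q < 0.05, min length 100 bp, merge
gap 100 bp) are desk-scale choices; the caller's contract is truth
recovery on simulations (≥ 95% of 20×-enriched planted peaks; ~0 calls on
matched uniform coverage), not parity with a third-party tool. Peak
intensity is exposed both as the raw pileup maximum (browser-track
convention) and as the mean SPMR over the interval (used for
correlations); neither is asserted as the sole convention of the assay's
published analyses.

The noise-to-signal ratio of a peak is the mean SPMR over its two 500 bp
flanks divided by the mean SPMR over the peak; flanks truncate at
chromosome edges and a zero-signal peak yields an undefined (missing)
ratio.

## Loop calling

Deduplicated cis PETs are clustered by extending each end ±500 bp and
transitively merging PETs that overlap on both extended ends; anchors are
the union of member tag intervals. The 500 bp extension gives sub-peak
anchor resolution at desk scale.

Significance uses a stand-in null, not the cited interaction caller's
internals: the span density `f(s)` is a truncated power law fitted by
maximum likelihood to all cis PET spans on [1 kb, max span], and the
expected count of a candidate with anchors A, B at distance `d` is

    E[A,B] = N · f(d) · (a_A·w_B + a_B·w_A) / 2

with `N` the cis PET count, `a` the fraction of PET ends falling in each
anchor **extended by the clustering window** and `w` the extended widths.
Under uniform background this reduces exactly to `N·w_A·w_B·f(d)/G`. Two
choices here were forced by the null simulation rather than open:

- the extended window, because clustering captures any PET within
  ±extension of the anchors, so chance co-occurrence rates computed on raw
  anchor widths are underestimates; and
- multiple-testing correction over the **full lattice** of distinguishable
  anchor pairs at clustering resolution (1 kb bins spanning the occupied
  genome, same-chromosome pairs above the span cutoff), not merely the
  PET-supported clusters. Conditioning on a cluster having formed is a
  scan-statistics selection effect: on pure distance-decay background
  essentially every chance 3-PET cluster otherwise passes FDR < 0.05.
  Zero-count lattice cells have p ≈ 1 and can never be rejected, so BH
  with the enlarged family size applied to the observed candidates is
  exact.

Filters follow the assay's published thresholds: PET count ≥ 3, span
strictly > 8 kb, FDR < 0.05 (BH; the specific FDR procedure is not named
in the source analyses, BH is used throughout this package), then the
anchor-support filter retaining only loops whose two anchors each overlap
a called peak by ≥ 1 bp. Loop span is the anchor-midpoint distance.
Per-peak connectivity counts PETs with ≥ 1 end overlapping the peak; a PET
with both ends in one peak counts once (the alternative — twice — is not
documented for the original analyses; once is this package's assumption).

## Differential analyses

Consensus interactions: loops with PET count strictly > 10 (applied per
input library, the stricter reading of an ambiguous pre-filter) are
pooled; overlapping anchors (≥ 1 bp on half-open intervals — touching
intervals do not merge) merge transitively into unique anchors, and each
loop maps to a consensus (anchor, anchor) pair with a unique ID. Counts of
same-ID loops are summed per library and absent loops are zero-filled, so
column sums conserve per-library PET totals exactly; loops whose two
anchors merge into a single region are dropped with a warning (their
consensus identity is undefined).

Two normalisations mirror the two analyses they serve: loop tables use
median-of-ratios size factors (median of linear count-to-geometric-mean
ratios over features positive everywhere); accessibility tables use TMM
with reads-in-peaks library sizes (reference = library with
upper-quartile fraction closest to the mean; 30%/5% double trim on M/A;
precision-weighted mean M; factors rescaled to geometric mean 1).

Testing is an in-repo negative-binomial Wald test, a documented
simplification of the packages typically cited for such designs: per
feature, dispersion is method-of-moments from within-condition variance of
normalised counts, shrunk toward the across-feature mean with a prior
weight of 20 pseudo-degrees-of-freedom (strong shrinkage is appropriate
for 2-vs-2 designs, where the per-feature estimate has 2 df). The Wald
statistic tests `log(μ_B/μ_A)` on raw condition means with a delta-method
variance `(Σ_j q/s_j + α q²)/n²` per group; the 0.5 pseudocount enters
only the reported log2 fold change (and the statistic when a group mean is
zero). Conditions are ordered lexicographically, so relabelling exactly
negates fold changes. Rescaling one library's depth is absorbed by the
factors: calls are invariant, the reported fold change to ≈ 0.02 (exact
invariance is impossible while the variance retains per-library shot
noise, and median-of-ratios rescales all normalised counts by
depth^(1/4)). Thresholds: |log2FC| > 1 with FDR < 0.01 for both loops and
peaks by default. Acceptance of this test is calibration, not coefficient
parity: realised null false-call rate ≤ 5% at those thresholds and ≥ 80%
power for 4-fold effects.

The power simulation plants 4-fold effects *between means 50 and 200*
(half gains, half losses) in 25% of 2,000 features at NB dispersion 0.1,
2 vs 2. Balanced directions keep the size factors unbiased so the
simulation measures test power rather than normalisation robustness, and
both directions then have identical effect sizes; an all-gains design at
baseline 50 loses ~15 points of power to factor absorption and to losses
bottoming out at mean 12.5. These conditions were fixed once, from this
reasoning, before the corresponding checks were frozen.

Connectivity classification compares depth-normalised per-peak PET counts
between conditions (whether the original analyses normalised for depth
here is not documented; normalised counts are used and flagged); exact
ties are "unchanged", and the summary reports the fraction of
accessibility-up peaks with increased connectivity and of
accessibility-down peaks with decreased connectivity.

## Contact-matrix metrics

Matrices bin cis PET midpoints per chromosome (upper triangle stored).
Knight–Ruiz balancing uses the classic inner–outer Newton iteration on the
non-empty submatrix (target: unit row sums, tolerance 10⁻⁶), with a
Sinkhorn fallback on failure (logged) and empty bins masked NaN. The 0–1
pre-scaling some published workflows apply before KR is omitted: it
rescales the fixed point but not the balanced structure.

APA extracts the KR-balanced (2·10+1)² submatrix centred on each loop's
anchor-bin pair at 10 kb resolution, excluding loops closer to the
diagonal than the window or leaving the matrix; the Z-score compares the
central pixel of the aggregate to the mean and SD of the lower-left 6×6
corner (the corner nearest the diagonal, i.e. the locally highest
background — a conservative reference; 6×6 is the customary corner size
and is configurable).

The stratum-adjusted correlation smooths both matrices with a
(2·5+1)²-bin mean filter (edge-renormalised to avoid zero-padding
artefacts), computes Pearson correlations per diagonal up to 5 Mb, and
combines them with `N_k·sd(x_k)·sd(y_k)` weights; the genome summary is
the chromosome-length-weighted mean. Insulation at 25 kb bins averages the
w×w square crossing each bin (w = window/bin) and reports log2 against
the chromosome mean, with edges missing. Compartment scores divide each
diagonal by its mean (observed/expected), take the first principal
component of the resulting Pearson correlation matrix (≥ 20 non-empty
bins required), and orient the sign to correlate non-negatively with a
reference accessibility track.

## The synthetic generator: what it does and does not emulate

The generator reproduces the *statistical* structure the analysis relies
on: loops anchored at open-chromatin peaks with spans log-uniform on
10 kb–1 Mb; the tag–linker–tag read anatomy with randomised fragment
orientation and uniform tag lengths on [16, read_len − 20]; a PET mixture
of loop signal (default 45%), power-law cis background (35%, exponent
1.0), self-ligation ≤ 8 kb (15%), trans contacts (5% when the genome has
≥ 2 chromosomes, else 0) and PCR duplicates (10% exact copies); and
uniform-random genome sequence. The trans and duplicate fractions are free
parameters — the source analyses do not publish per-library values — and
the signal fraction is far above real libraries so that desk-scale depths
(10⁵ PETs on a 1 Mb genome) contain recoverable loops. Unsupported loop
anchors are kept ≥ 2 kb clear of every planted peak so support labels are
unambiguous ground truth. Adapters, quality decay, GC and Tn5 insertion
bias, restriction-site fragment ends and alignment error are *not*
simulated; passing tests therefore demonstrate correctness of the
computational contracts, not robustness to real-data artefacts upstream of
tag coordinates.

Problem sizes used by the test suite and acceptance script — a 1 Mb
single-chromosome genome, 100 peaks, 40 loops, 10⁵ read pairs, 2,000
differential features, 200–250-bin matrices — were chosen so the full
suite completes in a few minutes while every statistical check retains
3σ-scale resolution.

## Known limitations

- The loop null model is a simplified stand-in; absolute q-values are not
  comparable to the cited interaction callers, only the operating
  characteristics (null FDR control, truth recovery) are validated.
- The NB test's variance is delta-method on group means; with more than a
  handful of replicates a GLM fit would be preferable.
- Trans interactions are carried through PET classification but never
  tested for significance; compartments/insulation are cis-only.
- KR weights are computed on dense per-chromosome matrices, which caps
  practical matrix sizes at a few thousand bins per chromosome.
- On synthetic data, coordinates come from the generator's truth table;
  real libraries require an external aligner to produce tag coordinates
  before `build_pets`.
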