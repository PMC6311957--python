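# Methods

This note gives the exact definitions, conventions and algorithms implemented
by `cochip`. Module names in parentheses point at the implementation.

## Coordinate and data conventions (`cochip.core`, `cochip.io`)

- All genomic intervals are 0-based, half-open `[start, end)`, as in BED.
- A peak's **center** is `floor((start + end) / 2)`. Optionally
  (`use_summit=True`) the narrowPeak summit `start + summit_offset` replaces
  the center wherever a point location is needed; broadPeak records have no
  summit and always use the center.
- narrowPeak (BED6+4, 10 columns, TFs) and broadPeak (BED6+3, 9 columns, HMs)
  are parsed strictly: wrong column counts, non-numeric fields, `end <= start`
  or negative coordinates raise a `ParseError` naming file and line. Gzipped
  files are detected by suffix. `signalValue` is column 7; a narrowPeak summit
  of −1 means absent.
- Gene annotations are BED6 (TSS = `start` on `+`, `end − 1` on `−`) or a
  4-column TSV `gene_id, chrom, tss, strand`. Duplicate gene ids are rejected.
- Tracks are sorted on load; all downstream algorithms assume and preserve
  per-chromosome center order.

### Gene filtering

Before profiling, genes whose TSS windows could double-count signal are
removed: two genes conflict when they share a chromosome and
`|tss_i − tss_j| ≤ 2·half_window` (closed ±20 kb windows intersecting). The
filter is order-preserving and idempotent.

## TSS signal profiles and binding dynamics (`cochip.profile`)

Each kept gene contributes a ±20 kb window around its TSS, split into
`n_bins = 2·half_window / bin_size` bins (200 bins of 200 bp by default; the
divisibility is enforced). Windows are strand-oriented: for a `+` gene, peak
centers in `[tss − hw, tss + hw)` map to bin `(center − tss + hw) // bin_size`;
for a `−` gene the offset is negated (centers in `(tss − hw, tss + hw]`), so
bin 1 is always the far upstream edge and the TSS falls at the start of bin
101. A peak inside several genes' windows counts once per window.

The per-bin **signal intensity** over `n` genes is

    S_j = (1000 / n) · Σ_i N_ij

where `N_ij` is the count of peak centers of the factor in bin `j` of gene
`i`'s window — the expected peak count per bin per 1000 genes.

For a factor profiled in two cell lines with bin totals `T₁ = Σ_j S_j⁽¹⁾` and
`T₂`:

    f        = T₁ / T₂
    D_signal = (f − 1) / (f + 1)

`D_signal` is the algebraic identity `(T₁ − T₂)/(T₁ + T₂)`; it is bounded in
[−1, 1] and antisymmetric under swapping cell lines. Factors are classified

| class | condition |
|---|---|
| first-cell-line rich (`GM12878_rich_factor`) | `f > 1.5` and `D_signal > 0.2` |
| second-cell-line rich (`K562_rich_factor`) | `f < 0.6` and `D_signal < −0.25` |
| unbiased | `0.6 < f < 1.5` and `−0.25 < D_signal < 0.2` |
| unclassified | otherwise (boundary gaps) |

If both totals are zero the indices are undefined (error); if only the second
is zero, `f = ∞` and `D_signal = 1`. The auxiliary peak-count difference is
`|N₁ − N₂| / (N₁ + N₂)`.

## Peak co-localization (`cochip.colocalization`)

Two peaks with centers `c₁, c₂` and widths `w₁, w₂` on the same chromosome
**co-localize** when the center distance is strictly smaller than the mean
width:

    |c₁ − c₂| < (w₁ + w₂) / 2      (evaluated exactly as 2|c₁ − c₂| < w₁ + w₂)

### Overlap ratio

For factors A (N₁ peaks) and B (N₂ peaks),

    R_o = 2n / (N₁ + N₂)

with, in the default `matched` mode, `n = (hits_A + hits_B)/2` where `hits_X`
is the number of X peaks overlapped by at least one peak of the other factor —
this keeps `R_o ≤ 1` and equal to 1 exactly at perfect mutual matching. The
alternative `pairs` mode counts every overlapping pair as an event and can
exceed 1 when peaks overlap many partners.

Hit detection is O((N₁+N₂) log N) per chromosome: the predicate
`2|c₁−c₂| < w₁+w₂` is equivalent to open "stretched" intervals
`(2c − w, 2c + w)` intersecting, so against a center-sorted partner track a
binary search plus a prefix-maximum of right endpoints answers "does any
partner overlap this peak" exactly. The test suite proves equivalence with the
O(N²) predicate loop on hundreds of random track pairs.

Overlap can be restricted to a region set (e.g. enhancers): peaks whose
centers fall outside every region are discarded first; an empty restriction is
reported as a distinct error.

### Cross-cell-line pair dynamics

For a pair's ratios `R₁, R₂` in the two cell lines,

    I_RV = (R₁ − R₂) / (R₁ + R₂ + α),  α = 0.001

(α guards the 0/0 case). Over all pairs, outliers — the "dynamic" pairs — are
those with `I_RV` outside mean ± 2·SD (population SD).

### Average overlap ratio and combinations

For a factor with peaks `i = 1..N` against `m` other factors,

    R_av = (1/m) · Σ_i x_i / N

where `x_i` is the number of *distinct* other factors overlapping peak `i`.
Frequent k-factor combinations are maximal enumeration of k-cliques in the
graph whose edges are pairs with `R_o` strictly above a threshold (default
k = 3, threshold 0.6), reported with the minimum pairwise `R_o`.

## TF association strength and network (`cochip.tfas`)

The association strength of a factor to gene `i` is

    A_ij = Σ_k g_k · exp(−d_k / d₀)

summing peaks whose oriented TSS offset lies in the ±20 kb window
(half-open, strand-oriented exactly as in binning), with `g_k` the peak's
signalValue, `d_k` the |center − TSS| distance and `d₀ = 2` kb.

Pairwise Pearson correlations between TFAS columns use the standard two-pass
formula, clipped to [−1, 1]; constant columns yield NaN (flagged, not
silently dropped). The co-binding network keeps edges whose weight —
`max(R₁, R₂)` of the pair's overlap ratios, or the TFAS correlation — exceeds
a threshold (default 0.6); nodes carry the factor dynamics class and edges a
specificity: `GM12878_specific` / `K562_specific` when the pair is an `I_RV`
outlier (sign of `I_RV` picks the cell line), `unbiased` otherwise.

## Expression prediction (`cochip.expression`)

Genes are ranked by FPKM; the top `ceil(n/4)` are labeled **high**, the bottom
`ceil(n/4)` **low** (ties broken deterministically by gene id; a degenerate
all-equal table is an error). The classifier is scikit-learn's
`Pipeline(log1p → StandardScaler → SVC(C=1, RBF, gamma="auto"))`, evaluated by
stratified 5-fold cross-validation with a fixed seed; the transformer and
scaler are refit inside every training fold, so no information leaks from held-
out genes. With high as positive:

    Sn = TP/(TP + FN),  Sp = TN/(TN + FP),  Acc = (Sn + Sp)/2

Sn/Sp/Acc are averaged over folds; pooled confusion counts are also reported.
The scan evaluates each single factor and the all-factor set. A factor's
cross-cell-line prediction difference is

    D_Acc = (Acc₁ − Acc₂) / (Acc₁ + Acc₂)

and the pipeline reports the Pearson correlation between the per-factor
`D_Acc` and `D_signal` vectors when ≥ 3 factors are available.

## Synthetic data (`cochip.simulate`)

The generator plants recoverable structure; identical config + seed gives
byte-identical files.

- TSSs sit on a jittered grid spaced `chrom_length/(n_genes+1)` apart
  (validated > 40 kb so windows never overlap); strands are random.
- Each factor/cell-line track draws lognormal widths (moment-matched to
  mean 300/SD 150 bp for TFs, 1500/750 for HMs), lognormal signal values, and
  places a fraction `tss_enrichment` of centers within ±2 kb of a random TSS,
  the rest uniformly.
- **Planted enrichment** `f_true` for a factor sets the proximal fractions in
  the two cell lines to `2·t·f/(1+f)` and `2·t/(1+f)` so their expected ratio
  is `f_true` while the total peak count is unchanged. Note the *measured* `f`
  is compressed toward 1 by background peaks that land inside TSS windows; on
  a genome whose windows cover a fraction `c` of the chromosome, roughly
  `f ≈ (p₁ + (1−p₁)c) / (p₂ + (1−p₂)c)`. Recovery experiments therefore use
  sparse genomes (window coverage ≈ 10%).
- **Planted co-localization** `(A, B, co_rate)` rebuilds B's track: a
  `co_rate` fraction of A's peaks gets a B peak whose center offset is within
  `±((w_A + w_B)/2 − 1)` — strictly inside the overlap predicate — and the
  remaining B peaks are rejection-sampled so their distance to the nearest A
  center exceeds `(max w_A + w_B)/2`, making accidental overlap impossible.
  The matched-mode `R_o` of the pair is then exactly the realized coupled
  fraction.
- **Expression**: `FPKM_i = exp(β · mean_driver TFAS_i + ε)`, `ε ~ N(0, σ)`.
  With `σ = 0` expression is strictly monotone in the drivers' TFAS, so a
  single-driver SVM must reach ~perfect accuracy and any non-driver stays at
  chance.

## Pipeline (`cochip.pipeline`)

Stages run in dependency order — ingest → profile → colocalization (TF tracks
only) → TFAS (+ correlations) → network → predict — writing every result as
TSV plus a `MANIFEST.json` with sha256 hashes. `resume=True` reloads stage
outputs whose hashes still match instead of recomputing. Stages that need two
cell lines or ≥ 2 TF tracks are skipped with a warning when the inputs cannot
support them; any failure raises a `StageError` naming the stage, leaving
partial outputs on disk with the manifest marked incomplete. All randomness
(SVM fold shuffling) derives from the config seed.
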