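# Methods

This note documents the statistical procedures in `metaboqc`, the choices
made where several defensible conventions exist, and what the synthetic
data used in the test suite do and do not establish.

## Data model

The unit of observation is one (aliquot, compound) pair: an aliquot is a
single injection, carrying exactly one sample type, batch and timestamp.
After validation the grid is complete — every aliquot has a row for every
compound, with explicit missing values where the file had none — and the
injection order is the 1-based rank of the timestamp (stable sort, so
injections sharing a timestamp keep file order). The datetime format is
fixed to `YYYY-MM-DD HH:MM:SS`; other dialects are rejected rather than
guessed, because a silently misparsed month/day swap would scramble the
injection order that the drift correction and all plots depend on. Only
the literal `NA` (case-sensitive) and the empty string are missing
markers in numeric columns; anything else is a fatal parse error —
fail-fast beats silent coercion. Duplicate (aliquot, compound) rows are
fatal (the area would be ambiguous; we never average them). Unknown
sample-type labels are kept for plotting, treated like study samples
there, but excluded from every QC, blank and study-sample computation.

## IS normalization

`ratio = area / area_IS`, computed per row. When no IS measurement exists
— no IS assigned to the compound, or an aliquot where the IS was not
spiked (water blanks) — the IS area defaults to 1 and the ratio equals
the raw area. An IS area of exactly zero leaves the ratio missing rather
than infinite: a zero denominator carries no usable normalization
information, and an infinity would poison every downstream median.

IS suggestions evaluate every (compound, candidate IS) pair by the RSDqc
of the between-batch-corrected QC ratios and rank candidates ascending,
ties broken alphabetically so output is deterministic. Suggestions use
between-batch correction only (not within-batch detrending), and only
candidates measured in at least 80% of QC injections are considered, so a
sparsely measured IS cannot win on a handful of lucky points. Suggestions
are advisory: chemical-class and retention-time compatibility is the
analyst's call, and the assigned IS stays in force.

## Outlier testing (generalized ESD / Rosner)

At step *i* the test removes the point with the largest studentized
deviation `R_i = max|x − mean| / sd` (mean and sd over the points still in
play) and compares it with the two-sided critical value

```
lambda_i = (n − i) · t_{p, n−i−1} / sqrt((n − i − 1 + t²)(n − i + 1)),
p = 1 − alpha / (2 (n − i + 1))
```

The declared outliers are the first *i\** removals where *i\** is the
**largest** step with `R_i > lambda_i`; this look-ahead is what defeats
masking by multiple outliers. Defaults: `alpha = 0.05`,
`max_k = max(1, floor(n/5))`, and no test below `n = 10` — an ESD test on
the four QCs of a single batch would be noise. Zero-variance input yields
no outliers. All three knobs live in `QCConfig`.

QC aliquots are tested on their median compound/IS ratio across compounds
(QCs are replicate injections of one pool, so this median should be
constant); flagged QCs are automatically excluded from correction medians
and RSDqc. Study samples are tested on their median IS area across ISs —
their compounds vary biologically but their spiked IS amounts do not, so
an extreme median IS area indicates a misinjection. Flagged study samples
are reported but stay in all computations until the user excludes them:
whether an extreme sample is technical or biological is not a decision
software should make. Both tests pool aliquots across batches by default
(a per-batch mode exists in config); the correction medians pool across
batches too, so pooling keeps the reference population consistent.

## Batch correction

Between batches: per compound, `f_b = grand median / batch median`, where
the batch median is over the compound's ratios in the non-excluded
correction QCs of batch *b* and the grand median pools those ratios over
all batches. "Grand median" is read literally as the median of all pooled
QC ratios, not the median of per-batch medians; a config switch
(`pooled_grand_median`) provides the other convention. The correction QC
type defaults to SQC — pooled study material experiences drift the way the
study samples do — falling back to LQC with a warning when no SQC exists;
the two types are never mixed in one median. A non-positive or missing
batch median leaves the factor undefined (the affected ratios become
missing, never sign-flipped), and a single-batch study gets factors of 1.
After application, every batch's QC median equals the grand median by
construction — the test suite asserts this to 1e-10 relative.

Within batches: optional (off by default, per-compound opt-in), and
applied after the between-batch step since the median factors are defined
on raw ratios. Per (compound, batch) an OLS line of QC corrected ratios
against injection index is fitted — on QCs only, because study samples
vary biologically and would bias the trend — and each aliquot's ratio is
multiplied by `batch QC median / trend(i)`, which removes the slope while
preserving the batch median (so the between-batch alignment survives).
The fit requires at least 4 usable QCs; a fitted trend that is
non-positive anywhere in the batch disables the correction for that
compound-batch with a warning, because dividing by a vanishing trend
would explode the ratios.

## Compound quality metrics

* **RSDqc** = sample standard deviation / mean × 100 over pooled,
  non-excluded correction-QC corrected ratios. The *sample* (n−1) sd is
  used: QC sets are small and the unbiased-variance convention is
  standard. Computed both pre- and post-correction; classification uses
  post. Undefined with fewer than 2 usable QCs or a zero mean.
* **Background signal** = mean area over BLANK injections / median area
  over SAMPLE injections × 100, per compound. PROC (procedure blanks)
  can be included via config but are excluded by default — they probe
  preparation-borne signal, a different question.
* **QC detection** = percentage of QC injections (SQC and LQC both
  counted) with a present, strictly positive area; `NA` and 0 both count
  as undetected.

Tiers: *low signal to noise* when RSDqc > 30% **or** background > 40%
(strict inequalities); *high confidence* when RSDqc < 15% and not low;
*with caution* otherwise — so RSDqc exactly 15 or 30 lands in "with
caution" and background exactly 40 is not low. A compound undetected in
every QC, or with undefined RSDqc, is not reported at all and appears in
no workbook tab.

## Plots and report

Box-whisker summaries use the Tukey convention: linear-interpolation
quartiles, whiskers at the most extreme points within 1.5×IQR, the rest
drawn as dots. The PCA view takes study samples plus correction QCs,
log2-transforms each compound (offset: half its smallest positive value),
imputes missing values by the compound median, autoscales, and fixes
component signs so the loading of the alphabetically first compound is
non-negative (making scores reproducible across row orders). Group 95%
ellipses come from the chi-square(2) quantile of the group score
covariance. Ratio-like axes are log2-transformed throughout. Every plot
is computed first as a tidy frame and only then rendered, so each figure
is a pure function of exportable data.

## Synthetic data: what it emulates, what it does not

The generator produces the full recommended injection design and a
multiplicative signal model: lognormal compound baselines, per-batch
compound-level factors (not applied to IS areas — ISs are spiked at a
constant amount, and it is precisely the component of batch variation
that normalization cannot cancel which the median correction exists to
remove), optional linear drift, lognormal noise with a configurable
fraction of its log-variance shared between a compound and the ISs of the
same injection (default 0.95: stable-isotope ISs co-vary strongly with
their analytes through injection volume and ionisation), biological
variation on study samples only (log-sd 0.4), blanks at 5% of study
signal, and optional planted faults (a scaled QC; a misinjection scaling
a sample's compound and IS areas together).

It does **not** emulate: heteroscedastic noise at low intensity,
censoring at the detection limit, retention-time shifts, carryover
between injections, correlated compound panels, or nonlinear drift.
Passing tests therefore establish that the algorithms recover what they
model — multiplicative batch effects, linear drift, gross outliers —
not that every real-data pathology is handled.

Problem sizes in the test and acceptance suites (3 batches, 4–8 QCs and
14–30 study samples per batch, 3–6 compounds, 100 simulation seeds for
parameter recovery, 1000 vectors and 2000 null simulations for the ESD
checks) were chosen as the smallest designs that exercise every code path
with stable statistics.

## Known limitations

* Absolute quantification from CAL/ACAL curves is out of scope; the
  calibration levels are parsed and plotted but not fitted.
* Only first-order within-batch regression is offered — no LOESS or
  spline smoothing.
* The ESD tests assume approximately Gaussian aggregates; heavy-tailed
  QC median distributions will inflate the flag rate.
* The IS suggestion criterion is purely statistical (RSDqc); it cannot
  see chemical incompatibility between a compound and an IS.
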