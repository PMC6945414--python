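# Methods

## Empirical curve model

All measures are defined on the empirical ROC polyline of a finite sample
with P actual positives and N actual negatives. A descending threshold
sweep moves the curve up 1/P per positive and right 1/N per negative; a
group of tied scores containing `a` positives and `b` negatives becomes a
single diagonal segment with rise a/P and run b/N. This tie convention is
what makes the trapezoidal area equal the c statistic (which scores a tied
pair ½), and it is enforced everywhere: the curve builder, the concordance
matrix border walk, the integrals, and the weight vectors all treat a tied
group as one indivisible diagonal. Vertices are accumulated as integer
counts and divided only once at the end, so the border walk and the
threshold sweep produce bit-identical coordinates; consecutive collinear
segments are merged so that both routes yield the same canonical vertex
list. Fitted (binormal-smoothed) curves and convex hulls are out of scope:
every measure here is a statistic of the empirical staircase.

Two evaluation conventions make staircase integrals well defined and
additive: r(x) returns the *top* of a vertical segment, and r⁻¹(y) the
*left* end of a horizontal segment. Integrals are computed segment-exactly
(clip each polyline segment to the integration band, sum trapezoids), never
on a quadrature grid, so partition identities hold to machine precision
(observed ≤ 4e-16; tests assert 1e-10). Query coordinates are matched to
vertices with absolute tolerance 1e-9.

## Partial measures

For a partial curve with FPR ∈ [x1, x2] and TPR ∈ [y1, y2], both endpoints
on the curve:

* `pauc_vertical` — ∫ r(x) dx over [x1, x2] (width × average sensitivity);
* `pauc_horizontal` — ∫ 1 − r⁻¹(y) dy over [y1, y2] (height × average
  specificity);
* `pauc_concordant` — half their sum. The halving compensates the region
  both perspectives cover, so parts sum to AUC rather than 2·AUC; equal
  weighting of the two integrals is the only choice that preserves equality
  with the partial c statistic.

Degenerate parts are legal: a purely vertical partial curve has zero
vertical area but positive horizontal area and still satisfies the
area/concordance equality.

### Partial c statistic and its normalization

`partial_c` computes c_Δ over the weighted row and column stripes of the
concordance matrix with the pooled denominator 2PN and the weights inside
the sums. Two normalizations are exposed:

* `pooled` (default): c_Δ = (Σ_jk w⁺_j H_jk + Σ_jk w⁻_k H_jk) / 2PN. This
  is the form under which all-ones weights give c exactly, spanning
  partitions sum to c, and each part equals its concordant partial area.
* `stripe`: each stripe sum divided by its own size (2N·Σw⁺ and 2P·Σw⁻).
  This variant is pre-scaled to [0, 1] but is *not* additive and does not
  equal the partial area; it is provided for comparison only.

`normalize_partial_c` rescales a pooled c_Δ by its stripe extent,
2PN·c_Δ / (N·Σw⁺ + P·Σw⁻), the discrete analog of dividing the concordant
partial area by (Δx + Δy).

### Weights and boundary splits

`range_to_weights` gives each positive the fraction of its tied group's
vertical extent inside [y1, y2] and each negative the fraction of its
group's horizontal extent inside [x1, x2]. When a partition boundary falls
strictly inside a tied-group diagonal, all instances of the group receive
the same fractional weight (group-uniform split); tied instances are
exchangeable, so no within-group ordering is defensible. With this
convention the vertical-stripe and horizontal-stripe discrepancies against
the two component integrals cancel exactly in their half-sum, so
pAUC_c = c_Δ continues to hold at interpolated boundaries — the property
suite checks this on randomly cut diagonals. Because a group's overlap
fractions with adjacent bands sum exactly to its full extent in floating
point, per-instance weights across a spanning partition sum to 1 exactly,
which is what makes the Σ c_Δ = c identity exact rather than approximate.

### Boundary-resolution rules

An FPR value does not uniquely identify a point on a staircase (a vertical
segment shares one FPR among many TPRs). `resolve_partition` applies corner
rules: the leftmost part anchors its left endpoint at the most southwest
matching point and its right endpoint at the most northeast; every other
part uses the most northeast point for both. Adjacent parts therefore share
their boundary vertex, cover the curve jointly, and never overlap; shared
vertices contribute zero area twice, so nothing is double-counted.
Boundaries may equivalently be given as TPR values (same rules with axes
swapped) or as explicit `PartialRange` objects, which may cover any
non-overlapping subset of the curve including zero-extent pieces.
Overlapping explicit ranges are rejected: every summation identity is
stated for disjoint spans, and silently accepting overlap would break them.

## Comparison measures

* **Local c** — concordance inside one block of the matrix only. Kept as a
  foil: a regression test exhibits a dataset where every per-part local c
  is 1.0 while c = 0.75, so no convex combination of local values recovers
  c; cross-block pairs are invisible to it.
* **sPA** — McClish's standardized partial area,
  sPA = ½[1 + (pAUC − A_dg)/(A_max − A_dg)], with A_dg the chance-diagonal
  area over the band and A_max the full rectangle. Chance level maps to
  0.5, perfection to 1; improper curve segments below the diagonal give
  values under 0.5, possibly negative.
* **AP+/AP−** — average precision with step (rectangle) interpolation over
  descending score groups, matching the standard estimator (cross-checked
  against scikit-learn in the tests); AP− swaps class roles and negates
  scores to focus on the negatives.

## Synthetic data

`simulate_scores` draws negatives from Normal(0, σ₋) and positives from
Normal(d, σ₊) — the binormal model, the standard parametric picture of a
diagnostic score — with closed-form AUC Φ(d/√(σ₊² + σ₋²)) used to calibrate
the empirical c statistic (checked at P = N = 2000 against three
Hanley–McNeil standard errors for d ∈ {0, 1, 2}). An optional quantization
step rounds scores to a grid to inject ties. Defaults are unit variances
and separation 1 (AUC ≈ 0.76, a typical mid-strength classifier); the
identity suite samples P, N ∈ [2, 40] and separations in [0, 2.5] with a
0.5 quantization step on half the datasets, covering heavy ties and strong
imbalance in both directions. The generator emulates score distributions
only: it has no covariates, no calibration structure, and no
label noise, so passing tests certify the *measures*' algebra and
numerics on staircases of realistic shape, not any claim about classifier
quality on real data. The staircase fixtures are fixed label patterns with
arbitrary distinct descending scores: a balanced 10/10 staircase (the
classic textbook shape), a 5/15 imbalanced variant, and a curve opening
with a vertical segment for the degenerate-part case.

## Numerical choices and edge cases

* Coordinate matching tolerance 1e-9 (absolute); identity tests assert
  1e-10, observed deviations are at the 1e-16 level.
* Ties in H(·) are exactly 0.5; cell values {0, 0.5, 1} are exact floats,
  so the border walk compares with `==` safely.
* Degenerate classes (P = 0 or N = 0) raise an error naming the missing
  class; curves, matrices and precision-recall measures all require both.
* Normalized measures with a zero-extent denominator raise in the direct
  API and render as NaN/`-` in assembled reports, so degenerate parts can
  appear in a partition without aborting it.
* Score orientation is explicit (`higher_is_positive` default, negation at
  ingest for `lower_is_positive`); no auto-detection.
* The identity-suite problem sizes (100 datasets of ≤ 80 instances,
  partitions of 2–5 parts; calibration at P = N = 2000) keep the whole
  suite and the acceptance script in the low seconds while exercising every
  code path; the identities are exact, so larger samples add no power.

## Known limitations

* Empirical curves only; no confidence intervals or significance tests for
  partial areas.
* The concordance matrix is materialized densely (P×N), fine for the
  intended evaluation-set sizes but quadratic in memory.
* sPA below-diagonal behaviour is reported as-is (values < 0.5, possibly
  negative); no correction for improper curves is attempted.
* The CLI accepts FPR boundaries only; TPR boundaries and explicit ranges
  are library-level features.
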