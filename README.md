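# rocpartials

Partial-curve evaluation of classifiers and diagnostic tests on ROC data,
built around the **concordant partial AUC** and the **partial c statistic**.

## Why

The area under the ROC curve (AUC) summarizes discrimination over the whole
curve, but with imbalanced, low-prevalence data only part of the curve — the
high-specificity left side — matters. The classical partial AUC,

    pAUC = ∫_{x1}^{x2} r(x) dx,

integrates only the true positive rate over an FPR band, ignoring how the
negatives behave inside the band, and has no interpretation as concordance.
Precision–recall average precision has the mirror-image problem. This
package implements a partial measure that keeps all three interpretations of
the AUC (average sensitivity, average specificity, concordance):

    pAUC_x = ∫_{y1}^{y2} (1 − r⁻¹(y)) dy          (horizontal partial AUC)
    pAUC_c = ½ pAUC + ½ pAUC_x                    (concordant partial AUC)

together with its discrete twin, the partial c statistic

    c_Δ = (1 / 2PN) [ Σ_{j,k} w⁺_j H(g(p_j) − g(n_k))
                    + Σ_{j,k} w⁻_k H(g(p_j) − g(n_k)) ],

where H counts a correctly ranked positive/negative pair as 1, a tie as ½,
an inversion as 0, and the weights w⁺, w⁻ ∈ [0,1] are the fractions of each
instance's ROC step inside the partial curve. For every partial curve
pAUC_c = c_Δ exactly, and over any spanning, non-overlapping partition

    AUC = c = Σ_i (pAUC_c)_i = Σ_i (c_Δ)_i.

The package also provides the concordance matrix (the P×N grid of pairwise
ranking outcomes whose concordant/discordant border *is* the empirical ROC
curve), the local c statistic, range-normalized measures, McClish's
standardized partial area (sPA), dual-orientation average precision
(AP+/AP−), a binormal score simulator, and a CLI.

## Worked example

Simulate an imbalanced binormal dataset (60 positives, 240 negatives,
class separation 1.5 SD) and evaluate it on three FPR bands:

```sh
rocpartials simulate --pos 60 --neg 240 --separation 1.5 --seed 42 --out sim.tsv
rocpartials evaluate --scores sim.tsv --boundaries 0,0.33,0.66,1
```

```
i    FPR range       TPR range       pauc     pauc_c   pauc_x   c_delta  pauc_norm  pauc_x_norm  pauc_c_norm  c_delta_norm  spa      local_c
1    [0.00, 0.33]    [0.00, 0.95]    24.2%    56.0%    87.8%    56.0%    73.3%      92.5%        87.5%        87.5%         84.0%    77.4%
2    [0.33, 0.66]    [0.95, 0.98]    32.2%    17.1%    2.0%     17.1%    97.6%      59.6%        94.1%        94.1%         97.6%    77.5%
3    [0.66, 1.00]    [0.98, 1.00]    34.0%    17.3%    0.6%     17.3%    100.0%     33.3%        96.9%        96.9%         99.9%    97.6%
sum  -               -               90.4%    90.4%    90.4%    90.4%    -          -            -            -             -        -
whole: AUC = 90.4%  c = 90.4%  AP+ = 66.3%  AP- = 97.5%
```

Reading the table: the leftmost band carries most of the discriminative
value (pAUC_c = 56.0 of the 90.4 points), because the curve rises to
TPR 0.95 while keeping specificity high (pAUC_x = 87.8%). Each row's
pAUC_c equals its c_Δ, every additive column sums to AUC = c, and the
plain pAUC column shows its known defect — it grows monotonically with FPR
(24.2 → 34.0) even though the rightmost band is nearly uninformative
(normalized pAUC ≈ 100% just restates that TPR saturates there). The
whole-curve row adds both average-precision orientations; AP− ≫ AP+
reflects the 1:4 class imbalance.

The same analysis from Python:

```python
from rocpartials import read_scores, compute_report
report = compute_report(read_scores("sim.tsv"), [0, 0.33, 0.66, 1])
print(report.parts)        # full-precision DataFrame
print(report.whole)        # {'auc': ..., 'c': ..., 'ap_plus': ..., 'ap_minus': ...}
```

Boundaries given as FPR values are resolved to on-curve endpoints by the
southwest/northeast corner rules (see `docs/methods.md`); TPR boundaries and
explicit `PartialRange` lists are also accepted.

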