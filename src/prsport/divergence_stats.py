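"""Cross-population allele-frequency informativeness and PRS-shift tests.

A variant's per-SNP informativeness for a polygenic score grows with its
folded minor-allele frequency (heritability is maximized at intermediate
frequencies).  Comparing folded MAFs between two populations classifies each
variant into the region where population A is more informative, population B
is more informative, or a tie; an exact two-sided binomial test on the two
counts asks whether one population's frequencies are systematically closer
to 0.5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError, as_1d_float

A_MORE = "A_more_informative"
B_MORE = "B_more_informative"
TIE = "tie"


def folded_maf(freq):
    """Minor-allele frequency: min(f, 1-f), elementwise."""
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0) or np.any(f > 1) or not np.all(np.isfinite(f)):
        raise ValidationError("frequencies must lie in [0,1]")
    return np.minimum(f, 1.0 - f)


def classify_bowtie(f_a, f_b):
    """Label each variant by which population has the larger folded MAF.

    Scalar inputs return a single label; array inputs return an object array
    of labels.  Orientation-free: replacing f by 1-f in either population
    never changes the labels.
    """
    maf_a = folded_maf(f_a)
    maf_b = folded_maf(f_b)
    # tolerance so folding (f -> 1-f) cannot break ties through float noise
    diff = maf_a - maf_b
    labels = np.where(diff > 1e-12, A_MORE, np.where(diff < -1e-12, B_MORE, TIE))
    if labels.ndim == 0:
        return str(labels)
    return labels.astype(object)


def joint_frequency_table(variant_ids, f_a, f_b) -> pd.DataFrame:
    """Per-variant joint frequency table with bow-tie region labels."""
    f_a = as_1d_float(f_a, "f_a")
    f_b = as_1d_float(f_b, "f_b")
    return pd.DataFrame({
        "variant_id": variant_ids,
        "f_A": f_a,
        "f_B": f_b,
        "maf_A": folded_maf(f_a),
        "maf_B": folded_maf(f_b),
        "region": classify_bowtie(f_a, f_b),
    })


def bowtie_binomial_test(n_a_more: int, n_b_more: int, n_ties: int = 0,
                         tie_policy: str = "exclude") -> dict:
    """Exact two-sided binomial test of the bow-tie counts against 0.5.

    ``tie_policy="exclude"`` (default) drops ties from the trial count — the
    conservative conditional test; ``"split"`` adds half the ties to each
    side (an odd leftover tie is discarded).  Two-sidedness sums outcome
    probabilities no larger than the observed outcome's, which at p0 = 0.5
    coincides with doubling the smaller tail.
    """
    if n_a_more < 0 or n_b_more < 0 or n_ties < 0:
        raise ValidationError("counts must be non-negative")
    if tie_policy not in ("exclude", "split"):
        raise ValidationError(f"unknown tie_policy {tie_policy!r}")
    k_a, k_b = int(n_a_more), int(n_b_more)
    if tie_policy == "split":
        k_a += n_ties // 2
        k_b += n_ties // 2
    n = k_a + k_b
    if n == 0:
        raise ValidationError("no informative variants after tie handling")
    result = stats.binomtest(k_a, n, 0.5, alternative="two-sided")
    return {
        "n_A_more": k_a,
        "n_B_more": k_b,
        "n_ties": int(n_ties),
        "tie_policy": tie_policy,
        "n_trials": n,
        "proportion_A": k_a / n,
        "p_value": float(result.pvalue),
    }


def bowtie_test_from_frequencies(f_a, f_b, tie_policy: str = "exclude") -> dict:
    """Classify variants then run the bow-tie binomial test."""
    labels = classify_bowtie(np.atleast_1d(f_a), np.atleast_1d(f_b))
    return bowtie_binomial_test(
        int(np.sum(labels == A_MORE)), int(np.sum(labels == B_MORE)),
        n_ties=int(np.sum(labels == TIE)), tie_policy=tie_policy,
    )


#: Combined sample size at or below which the Mann-Whitney p-value is exact.
MANN_WHITNEY_EXACT_MAX_N = 20


def mann_whitney_shift(scores_a, scores_b) -> dict:
    """Two-sided Mann-Whitney U comparison of two score distributions.

    Exact p-value when the combined n is at most
    :data:`MANN_WHITNEY_EXACT_MAX_N` and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.  If every value
    is tied across both samples, returns p = 1 with a warning.
    """
    a = as_1d_float(scores_a, "scores_a")
    b = as_1d_float(scores_b, "scores_b")
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p-value is 1")
        return {"U": a.size * b.size / 2.0, "p_value": 1.0, "method": "degenerate"}
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= MANN_WHITNEY_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"U": float(res.statistic), "p_value": float(res.pvalue),
            "method": method}


def population_medians(scores_by_population: dict) -> pd.DataFrame:
    """Per-population medians of standardized scores, ranked high to low."""
    rows = []
    for name, values in scores_by_population.items():
        v = as_1d_float(values, name)
        if v.size == 0:
            raise ValidationError(f"population {name!r} has no scores")
        rows.append((name, float(np.median(v)), v.size))
    out = pd.DataFrame(rows, columns=["population", "median", "n"])
    out = out.sort_values("median", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
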