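"""EHH / iHS computation and the uniformity test on percentile placements.

EHH(x) for a core allele is the probability that two haplotypes drawn at
random (without replacement) from the allele's carriers are identical at
every site between the core and x inclusive.  iHH integrates EHH over
physical distance on each side of the core (trapezoid rule), truncated where
EHH decays below a threshold; the unstandardized iHS is ln(iHH_ancestral /
iHH_derived).  Standardization is within derived-allele-frequency bins.
Percentile placement against a genome-wide reference uses |iHS| magnitude,
and a one-sample Kolmogorov-Smirnov test asks whether a set of percentiles
is uniform on [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError, as_1d_float

#: EHH level below which integration stops (configurable per call).
DEFAULT_EHH_TRUNCATION = 0.05

#: Standardization bins: equal width on the derived-frequency interval
#: retained by the MAF > 0.05 availability rule.
DEFAULT_N_BINS = 20
BIN_RANGE = (0.05, 0.95)


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix with site positions and a core site."""

    haplotypes: np.ndarray  # (n_haplotypes, n_sites), 0/1
    positions: np.ndarray   # bp, strictly increasing
    core_index: int
    derived_allele: int = 1

    def __post_init__(self):
        hap = np.asarray(self.haplotypes, dtype=np.int8)
        if hap.ndim != 2:
            raise ValidationError("haplotypes must be a 2-D matrix")
        if not np.isin(hap, (0, 1)).all():
            raise ValidationError("haplotype entries must be 0/1")
        pos = np.asarray(self.positions, dtype=np.int64)
        if len(pos) != hap.shape[1]:
            raise ValidationError("positions length must match site count")
        if np.any(np.diff(pos) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if not 0 <= self.core_index < hap.shape[1]:
            raise ValidationError("core_index out of range")
        self.haplotypes = hap
        self.positions = pos

    @property
    def derived_freq(self) -> float:
        core = self.haplotypes[:, self.core_index]
        return float(np.mean(core == self.derived_allele))


def compute_ehh(panel: HaplotypePanel, core_allele: int) -> np.ndarray:
    """EHH of ``core_allele`` carriers at every site of the panel.

    Returns an array over sites; EHH at the core is 1 and values are
    non-increasing moving away from the core on either side.
    """
    hap = panel.haplotypes
    carriers = hap[hap[:, panel.core_index] == core_allele]
    n = carriers.shape[0]
    if n < 2:
        raise ValidationError("EHH undefined with fewer than 2 carriers")
    n_sites = hap.shape[1]
    ehh = np.empty(n_sites)
    denom = n * (n - 1)

    def sweep(indices):
        # group carriers by their growing shared segment; EHH is the
        # probability a random ordered pair falls in the same group
        groups = np.zeros(n, dtype=np.int64)
        for j in indices:
            col = carriers[:, j]
            # refine groups by the allele at site j
            groups = groups * 2 + col
            _, groups = np.unique(groups, return_inverse=True)
            counts = np.bincount(groups)
            ehh[j] = float((counts * (counts - 1)).sum()) / denom

    ehh[panel.core_index] = 1.0
    sweep(range(panel.core_index + 1, n_sites))
    sweep(range(panel.core_index - 1, -1, -1))
    return ehh


def _ihh_one_side(ehh_side: np.ndarray, pos_side: np.ndarray,
                  truncation: float) -> tuple[float, bool]:
    """Trapezoid integral of EHH from the core outward, stopping at the first
    site where EHH drops below ``truncation``.  ``ehh_side``/``pos_side``
    start at the core.  Returns (integral, decayed?)."""
    below = np.flatnonzero(ehh_side < truncation)
    if below.size:
        stop = below[0] + 1  # include the first sub-threshold site
        decayed = True
    else:
        stop = len(ehh_side)
        decayed = False
    x = np.abs(pos_side[:stop] - pos_side[0]).astype(float)
    return float(np.trapezoid(ehh_side[:stop], x)), decayed


def integrate_ehh(panel: HaplotypePanel, core_allele: int,
                  truncation: float = DEFAULT_EHH_TRUNCATION) -> tuple[float, bool]:
    """iHH for one allele: EHH integral over bp, both sides of the core."""
    ehh = compute_ehh(panel, core_allele)
    c = panel.core_index
    right, dec_r = _ihh_one_side(ehh[c:], panel.positions[c:], truncation)
    left, dec_l = _ihh_one_side(ehh[c::-1], panel.positions[c::-1], truncation)
    return left + right, dec_l and dec_r


def compute_ihs_unstandardized(panel: HaplotypePanel,
                               truncation: float = DEFAULT_EHH_TRUNCATION) -> dict:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at the core.

    Requires at least two carriers of each allele.  ``reliable`` is False
    when EHH of either allele fails to decay below the truncation threshold
    within the panel.
    """
    derived = panel.derived_allele
    ancestral = 1 - derived
    ihh_d, dec_d = integrate_ehh(panel, derived, truncation)
    ihh_a, dec_a = integrate_ehh(panel, ancestral, truncation)
    if ihh_a <= 0 or ihh_d <= 0:
        raise ValidationError("iHH must be positive; panel too small")
    return {
        "ihs": float(np.log(ihh_a / ihh_d)),
        "ihh_ancestral": ihh_a,
        "ihh_derived": ihh_d,
        "derived_freq": panel.derived_freq,
        "reliable": bool(dec_a and dec_d),
    }


def standardize_ihs(values, derived_freqs, n_bins: int = DEFAULT_N_BINS,
                    min_per_bin: int = 2):
    """Bin-standardize iHS by derived-allele frequency.

    Equal-width bins on [0.05, 0.95]; bins with fewer than ``min_per_bin``
    values are merged rightward (the last bin merges leftward).  Within each
    bin the mean is subtracted and the SD (ddof=1) divides; a merged bin with
    zero SD raises.
    """
    v = as_1d_float(values, "values")
    f = as_1d_float(derived_freqs, "derived_freqs")
    if v.size != f.size:
        raise ValidationError("values and derived_freqs must align")
    edges = np.linspace(*BIN_RANGE, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_bins - 1)

    # merge sparse bins with their right neighbour
    remap = np.arange(n_bins)
    counts = np.bincount(bin_idx, minlength=n_bins)
    for b in range(n_bins - 1):
        if counts[b] < min_per_bin:
            counts[b + 1] += counts[b]
            counts[b] = 0
            remap[remap == b] = b + 1
    last = n_bins - 1
    if counts[last] < min_per_bin and n_bins > 1:
        occupied = np.flatnonzero(counts[:last])
        if occupied.size == 0:
            raise ValidationError("too few values to standardize")
        remap[remap == last] = occupied[-1]
    bin_idx = remap[bin_idx]

    out = np.empty_like(v)
    for b in np.unique(bin_idx):
        mask = bin_idx == b
        if mask.sum() < 2:
            raise ValidationError(f"bin {b} has fewer than 2 values after merging")
        sd = v[mask].std(ddof=1)
        if sd == 0:
            raise ValidationError(f"bin {b} has zero iHS variance")
        out[mask] = (v[mask] - v[mask].mean()) / sd
    return out, bin_idx


def percentile_against_reference(target_values, reference_values) -> pd.DataFrame:
    """Percentile of each target |iHS| within the reference |iHS| distribution.

    percentile = fraction of reference values with magnitude <= the target's
    magnitude; an empty target set returns an empty frame.
    """
    ref = np.abs(as_1d_float(reference_values, "reference_values"))
    if ref.size == 0:
        raise ValidationError("reference distribution must be nonempty")
    tgt = np.abs(as_1d_float(target_values, "target_values"))
    ref_sorted = np.sort(ref)
    pct = np.searchsorted(ref_sorted, tgt, side="right") / ref.size
    return pd.DataFrame({"ihs_abs": tgt, "percentile": pct})


def ks_uniform_test(percentiles) -> dict:
    """One-sample KS test of percentiles against Uniform(0,1).

    D is the supremum gap between the empirical CDF and the uniform CDF;
    scipy chooses the exact small-sample distribution automatically and the
    asymptotic Kolmogorov distribution for large n.
    """
    p = as_1d_float(percentiles, "percentiles")
    if p.size == 0:
        raise ValidationError("need at least one percentile")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("percentiles must lie in [0,1]")
    res = stats.kstest(p, "uniform", method="auto")
    return {"D": float(res.statistic), "p_value": float(res.pvalue), "n": p.size}
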