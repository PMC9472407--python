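"""Score resolution, weight adjustment, imputation and PRS computation.

The scoring model: each score variant i contributes dose d_ij times an
adjusted weight beta_i = ln(OR_i) * r_i^2, where r_i^2 is the tagging
r-squared of the marker actually used (1 for directly genotyped variants).
Variants whose best proxy falls below the r-squared threshold (default 0.4)
are dropped, as are variants absent from the variant dictionary.  A
multi-marker expansion entry replaces one source variant with its listed
markers, each carrying its own weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError
from .io_formats import CohortData, ProxyMap, ScoreDefinition

DEFAULT_R2_THRESHOLD = 0.4


@dataclass
class ResolvedScore:
    """Outcome of matching a score against a genotyped marker set.

    ``used`` columns: source_id, used_id, r2, same_direction, plus one
    ``beta_<ancestry>`` column per ancestry (already r2-adjusted, log-odds
    scale).  ``dropped`` columns: source_id, reason.  ``expansions`` records
    multi-marker replacements (source_id, marker_ids).
    """

    score_name: str
    used: pd.DataFrame
    dropped: pd.DataFrame
    expansions: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.used)

    @property
    def ancestries(self) -> list[str]:
        return [c[len("beta_"):] for c in self.used.columns if c.startswith("beta_")]

    def betas(self, ancestry: str) -> np.ndarray:
        col = f"beta_{ancestry}"
        if col not in self.used.columns:
            raise ValidationError(
                f"unknown ancestry {ancestry!r}; available: {self.ancestries}"
            )
        return self.used[col].to_numpy(dtype=float)


def adjust_weight(odds_ratio: float, r_squared: float) -> float:
    """Adjusted effect size ln(OR) * r2."""
    if not odds_ratio > 0:
        raise ValidationError(f"odds ratio must be positive, got {odds_ratio}")
    if not 0.0 <= r_squared <= 1.0:
        raise ValidationError(f"r2 must lie in [0,1], got {r_squared}")
    return float(np.log(odds_ratio) * r_squared)


def _pick_proxy(candidates: pd.DataFrame, genotyped: set, threshold: float):
    """Best genotyped proxy at r2 >= threshold; ties broken by smaller
    ``distance`` (when the column is present), then lexicographic ID."""
    avail = candidates[candidates["proxy_id"].isin(genotyped)]
    avail = avail[avail["r2"] >= threshold]
    if avail.empty:
        return None
    if "distance" in avail.columns:
        keys = avail.assign(
            _dist=pd.to_numeric(avail["distance"], errors="coerce").fillna(np.inf)
        ).sort_values(["r2", "_dist", "proxy_id"],
                      ascending=[False, True, True], kind="stable")
    else:
        keys = avail.sort_values(["r2", "proxy_id"], ascending=[False, True],
                                 kind="stable")
    return keys.iloc[0]


def resolve_variants(score: ScoreDefinition, genotyped_ids, proxy_map: ProxyMap,
                     r2_threshold: float = DEFAULT_R2_THRESHOLD,
                     variant_dictionary=None) -> ResolvedScore:
    """Resolve every score variant to a usable marker, a drop, or an expansion.

    Resolution order per source variant:

    1. absent from ``variant_dictionary`` (when given) -> dropped, reason
       ``"unmatched"``;
    2. a multi-marker ``expand`` entry in the proxy map -> each listed marker
       becomes its own row carrying the entry's log-odds weight (one source
       variant can therefore contribute two or more markers);
    3. directly genotyped -> used with r2 = 1;
    4. best genotyped proxy with r2 >= ``r2_threshold`` -> used with the
       proxy's r2 (weight adjusted);
    5. otherwise dropped, reason ``"lacked proxy (r2 < threshold)"``.

    Expansion markers not genotyped are dropped individually with reason
    ``"expansion marker not genotyped"``.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValidationError(f"r2_threshold must lie in (0,1], got {r2_threshold}")
    genotyped = set(genotyped_ids)
    dictionary = set(variant_dictionary) if variant_dictionary is not None else None

    used_rows, dropped_rows, expansions = [], [], []
    ancestries = score.ancestries
    for i, row in score.variants.iterrows():
        sid = row["variant_id"]
        if dictionary is not None and sid not in dictionary:
            dropped_rows.append((sid, "unmatched"))
            continue
        expansion = proxy_map.expansion_for(sid)
        if len(expansion):
            markers = []
            for _, ent in expansion.iterrows():
                if ent["proxy_id"] not in genotyped:
                    dropped_rows.append(
                        (ent["proxy_id"], "expansion marker not genotyped")
                    )
                    continue
                rec = {
                    "source_id": sid, "used_id": ent["proxy_id"],
                    "r2": float(ent["r2"]),
                    "same_direction": bool(ent["same_direction"]),
                }
                for anc in ancestries:  # expansion weight replaces the source row
                    rec[f"beta_{anc}"] = float(ent["log_or"]) * float(ent["r2"])
                used_rows.append(rec)
                markers.append(ent["proxy_id"])
            if markers:
                expansions.append((sid, tuple(markers)))
            else:
                dropped_rows.append((sid, "no expansion marker genotyped"))
            continue
        if sid in genotyped:
            rec = {"source_id": sid, "used_id": sid, "r2": 1.0,
                   "same_direction": True}
            for anc in ancestries:
                rec[f"beta_{anc}"] = float(score.log_weights[anc][i])
            used_rows.append(rec)
            continue
        pick = _pick_proxy(proxy_map.proxies_for(sid), genotyped, r2_threshold)
        if pick is None:
            dropped_rows.append((sid, f"lacked proxy (r2 < {r2_threshold})"))
            continue
        r2 = float(pick["r2"])
        sign = 1.0 if bool(pick["same_direction"]) else -1.0
        rec = {"source_id": sid, "used_id": pick["proxy_id"], "r2": r2,
               "same_direction": bool(pick["same_direction"])}
        for anc in ancestries:
            rec[f"beta_{anc}"] = sign * float(score.log_weights[anc][i]) * r2
        used_rows.append(rec)

    used = pd.DataFrame(
        used_rows,
        columns=["source_id", "used_id", "r2", "same_direction"]
        + [f"beta_{a}" for a in ancestries],
    )
    dropped = pd.DataFrame(dropped_rows, columns=["source_id", "reason"])
    return ResolvedScore(score_name=score.score_name, used=used,
                         dropped=dropped, expansions=expansions)


def resolve_for_datasets(score: ScoreDefinition, genotyped_by_dataset: dict,
                         proxy_map: ProxyMap,
                         r2_threshold: float = DEFAULT_R2_THRESHOLD,
                         variant_dictionary=None,
                         mode: str = "optimal") -> dict[str, ResolvedScore]:
    """Resolve a score for several datasets at once.

    ``mode="optimal"`` resolves independently against each dataset's marker
    set (the best predictors per dataset); ``mode="shared"`` restricts to
    markers genotyped in every dataset, so all datasets use an identical set.
    """
    if mode not in ("optimal", "shared"):
        raise ValidationError(f"mode must be 'optimal' or 'shared', got {mode!r}")
    sets = {name: set(ids) for name, ids in genotyped_by_dataset.items()}
    if mode == "shared":
        common = set.intersection(*sets.values()) if sets else set()
        sets = {name: common for name in sets}
    return {
        name: resolve_variants(score, ids, proxy_map, r2_threshold,
                               variant_dictionary)
        for name, ids in sets.items()
    }


def impute_missing_doses(dosages: np.ndarray, site_labels):
    """Fill missing doses with per-(variant, site) means.

    Falls back to the cohort-wide mean for a (variant, site) cell with no
    observed doses.  Variants missing everywhere are flagged and left NaN.

    Returns ``(filled, fill_counts, all_missing_variants)`` where
    ``fill_counts`` is per-sample and ``all_missing_variants`` lists column
    indices that could not be filled at all.
    """
    d = np.asarray(dosages, dtype=float).copy()
    sites = np.asarray(site_labels)
    if len(sites) != d.shape[0]:
        raise ValidationError("site_labels length must match sample count")
    missing = ~np.isfinite(d)
    fill_counts = missing.sum(axis=1)
    if not missing.any():
        return d, fill_counts, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        global_mean = np.nanmean(np.where(missing, np.nan, d), axis=0)
    all_missing = [int(j) for j in np.flatnonzero(~np.isfinite(global_mean))]
    for site in pd.unique(sites):
        rows = sites == site
        block = d[rows]
        blk_missing = missing[rows]
        if not blk_missing.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            site_mean = np.nanmean(np.where(blk_missing, np.nan, block), axis=0)
        fill = np.where(np.isfinite(site_mean), site_mean, global_mean)
        block[blk_missing] = np.broadcast_to(fill, block.shape)[blk_missing]
        d[rows] = block
    for j in all_missing:
        d[:, j] = np.nan
    return d, fill_counts, all_missing


def compute_raw_prs(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Raw per-sample PRS: sum over markers of dose times adjusted weight."""
    d = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape[1] != len(w):
        raise ValidationError("weight vector length must match marker count")
    if not np.all(np.isfinite(d)):
        raise ValidationError("dose matrix contains missing values; impute first")
    return d @ w


def standardize_scores(raw_scores) -> np.ndarray:
    """Z-transform with sample SD (ddof=1): output mean 0, sample SD 1."""
    x = np.asarray(raw_scores, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need at least two scores to standardize")
    sd = x.std(ddof=1)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValidationError("scores have zero variance; cannot standardize")
    return (x - x.mean()) / sd


def score_cohort(cohort: CohortData, resolved: ResolvedScore, ancestry: str,
                 site_labels=None, standardize: bool = True) -> pd.DataFrame:
    """Score a cohort with a resolved score.

    Markers in ``resolved.used`` absent from the cohort are an error (the
    resolution should have been run against this cohort's marker set).
    Missing doses are mean-filled per site before summation.  Returns a
    DataFrame: sample, raw, standardized, n_filled, ancestry.
    """
    cols = [cohort.column_of(uid) for uid in resolved.used["used_id"]]
    sub = cohort.dosages[:, cols]
    if site_labels is None:
        if cohort.metadata is not None and "site" in cohort.metadata.columns:
            site_labels = cohort.metadata["site"].to_numpy()
        else:
            site_labels = np.zeros(len(cohort.sample_ids))
    filled, n_filled, all_missing = impute_missing_doses(sub, site_labels)
    betas = resolved.betas(ancestry)
    if all_missing:
        keep = np.setdiff1d(np.arange(filled.shape[1]), all_missing)
        filled, betas = filled[:, keep], betas[keep]
    raw = compute_raw_prs(filled, betas)
    out = pd.DataFrame({
        "sample": cohort.sample_ids,
        "raw": raw,
        "n_filled": n_filled,
        "ancestry": ancestry,
    })
    if standardize:
        out["standardized"] = standardize_scores(raw)
    return out
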