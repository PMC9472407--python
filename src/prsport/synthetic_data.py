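"""Synthetic cohorts, scores, proxy maps and haplotype panels.

Everything downstream of this module is exercised on data produced here:
two-population cohorts with Balding-Nichols frequency drift, HWE genotypes,
liability-threshold case/control status, tumor stage / Gleason labels for
cases, proxy variants tagging causal variants at a target r-squared, and
haplotype panels with an optional planted sweep for EHH/iHS work.

Reproducibility: every public entry point takes an integer seed; a single
cohort seed fans out to per-stage streams via :func:`prsport._util.stage_rng`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from ._util import ValidationError, as_1d_float, check_probability, stage_rng

#: Population frequencies are clamped to [FREQ_EPS, 1 - FREQ_EPS] so that
#: downstream binomial sampling and PCA scaling never see exact 0/1.
FREQ_EPS = 1e-6

#: Default tumor-stage category probabilities for cases (T1..T4).
DEFAULT_STAGE_PROBS = (0.374, 0.446, 0.102, 0.078)

#: Default Gleason band probabilities for cases (<=6, ==7, >=8).
DEFAULT_GLEASON_PROBS = (0.171, 0.436, 0.392)

#: Age bands (inclusive bounds, years) and per-status sampling probabilities.
AGE_BANDS = ((40, 69), (70, 79), (80, 89))
DEFAULT_AGE_PROBS_CASE = (0.245, 0.302, 0.453)
DEFAULT_AGE_PROBS_CONTROL = (0.243, 0.392, 0.365)

STAGE_LABELS = ("T1", "T2", "T3", "T4")


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class SiteSpec:
    """One study site: label, sample count and case fraction."""

    name: str
    n_samples: int
    case_fraction: float

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValidationError(f"site {self.name!r}: n_samples must be positive")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValidationError(
                f"site {self.name!r}: case_fraction must lie in (0,1)"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """A population drifted from the shared ancestral frequencies."""

    name: str
    fst: float
    sites: tuple[SiteSpec, ...]

    def __post_init__(self):
        fst = float(self.fst)
        if not (np.isfinite(fst) and 0.0 <= fst < 1.0):
            raise ValidationError(f"population {self.name!r}: fst must lie in [0,1)")
        if not self.sites:
            raise ValidationError(f"population {self.name!r}: needs at least one site")

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.sites)


@dataclass(frozen=True)
class GeneticArchitecture:
    """Variant frequencies, true effects and the disease model parameters.

    ``true_log_or`` maps a population label to a per-variant effect vector on
    the liability scale (up to the overall scaling implied by
    ``prs_liability_variance``).  ``prevalence`` is the disease prevalence K;
    cases are individuals whose latent liability exceeds the (1-K) quantile.
    """

    n_variants: int
    ancestral_freqs: np.ndarray
    true_log_or: dict[str, np.ndarray]
    prevalence: float
    prs_liability_variance: float

    def __post_init__(self):
        freqs = as_1d_float(self.ancestral_freqs, "ancestral_freqs")
        if len(freqs) != self.n_variants:
            raise ValidationError("ancestral_freqs length must equal n_variants")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ValidationError("ancestral_freqs must lie strictly inside (0,1)")
        object.__setattr__(self, "ancestral_freqs", freqs)
        effects = {}
        for label, vec in self.true_log_or.items():
            vec = as_1d_float(vec, f"true_log_or[{label!r}]")
            if len(vec) != self.n_variants:
                raise ValidationError(
                    f"true_log_or[{label!r}] length must equal n_variants"
                )
            effects[label] = vec
        object.__setattr__(self, "true_log_or", effects)
        check_probability(self.prevalence, "prevalence", open_left=True,
                          open_right=True)
        check_probability(self.prs_liability_variance, "prs_liability_variance")


@dataclass
class SimulatedCohort:
    """A simulated cohort plus the generating truth.

    ``dosages`` holds {0,1,2} doses with NaN for missing entries; rows align
    with ``metadata`` (columns: sample, site, status, age, stage, gleason),
    columns with ``variant_ids``.  ``truth`` records the seed, latent
    liabilities and per-population frequencies so any derived quantity can be
    recomputed.
    """

    population: str
    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValidationError("dosage matrix shape does not match id lists")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("doses must be in {0,1,2} or NaN")
        cases = self.metadata["status"].to_numpy() == "case"
        for col in ("stage", "gleason"):
            if col in self.metadata and self.metadata.loc[~cases, col].notna().any():
                raise ValidationError(f"{col} present for a control sample")


# ---------------------------------------------------------------------------
# Frequency / genotype / phenotype layers


def draw_population_frequencies(ancestral_freqs, fst: float,
                                seed: int | np.random.Generator) -> np.ndarray:
    """Draw drifted per-variant population frequencies.

    Balding-Nichols model: for drift F > 0 each population frequency is
    Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F*p*(1-p);
    F = 0 returns the ancestral frequencies unchanged.  Draws are clamped to
    [FREQ_EPS, 1-FREQ_EPS].
    """
    p = as_1d_float(ancestral_freqs, "ancestral_freqs")
    if p.size == 0:
        return p.copy()
    if not np.all(np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValidationError("ancestral frequencies must be finite and in (0,1)")
    fst = float(fst)
    if not (np.isfinite(fst) and 0.0 <= fst < 1.0):
        raise ValidationError(f"fst must lie in [0,1), got {fst}")
    if fst == 0.0:
        return p.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    draws = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(draws, FREQ_EPS, 1.0 - FREQ_EPS)


def simulate_genotypes(pop_freqs, n_individuals: int,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Draw an n_individuals x n_variants dose matrix, Binomial(2, f) per entry."""
    f = as_1d_float(pop_freqs, "pop_freqs")
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValidationError("population frequencies must lie in (0,1)")
    if n_individuals <= 0:
        raise ValidationError("n_individuals must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, f, size=(int(n_individuals), f.size)).astype(float)


def simulate_phenotypes(dosages: np.ndarray, architecture: GeneticArchitecture,
                        seed: int | np.random.Generator,
                        effect_label: str | None = None):
    """Liability-threshold phenotypes from a complete dose matrix.

    The genetic score (doses weighted by the population's true effects) is
    standardized and scaled to explain ``prs_liability_variance`` of the
    liability variance; an independent N(0, 1-v) residual is added.  Cases are
    samples whose liability exceeds the (1 - prevalence) standard-normal
    quantile.

    Returns ``(is_case, liability, genetic_score)`` where ``genetic_score`` is
    the standardized genetic component.
    """
    dosages = np.asarray(dosages, dtype=float)
    if effect_label is None:
        effect_label = next(iter(architecture.true_log_or))
    effects = architecture.true_log_or[effect_label]
    v = architecture.prs_liability_variance
    if v > 0 and not np.any(effects):
        raise ValidationError(
            "all true effects are zero but prs_liability_variance > 0"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = dosages @ effects
    sd = raw.std(ddof=0)
    if sd > 0:
        g = (raw - raw.mean()) / sd
    else:
        g = np.zeros_like(raw)
    liability = np.sqrt(v) * g + np.sqrt(1.0 - v) * rng.standard_normal(len(g))
    threshold = stats.norm.ppf(1.0 - architecture.prevalence)
    return liability > threshold, liability, g


def liability_score_auc(score_liability_corr: float, prevalence: float,
                        grid_size: int = 4001, span: float = 8.0) -> float:
    """Expected AUC of a Gaussian score for liability-threshold case status.

    ``score_liability_corr`` is the correlation r between the (standardized)
    score and the latent liability; a score that *is* the genetic component
    has r = sqrt(prs_liability_variance).  Computed by quadrature:
    with (s, l) standard bivariate normal, P(case | s) = Phi((r s - t)/
    sqrt(1 - r^2)) for threshold t, and
    AUC = integral f_case(s) F_control(s) ds.
    """
    r = float(score_liability_corr)
    if not -1.0 < r < 1.0:
        raise ValidationError("score-liability correlation must lie in (-1,1)")
    k = check_probability(prevalence, "prevalence", open_left=True, open_right=True)
    t = stats.norm.ppf(1.0 - k)
    s = np.linspace(-span, span, grid_size)
    phi = stats.norm.pdf(s)
    p_case = stats.norm.cdf((r * s - t) / np.sqrt(1.0 - r * r))
    f_case = phi * p_case / k
    f_ctrl = phi * (1.0 - p_case) / (1.0 - k)
    cdf_ctrl = integrate.cumulative_trapezoid(f_ctrl, s, initial=0.0)
    return float(np.trapezoid(f_case * cdf_ctrl, s))


def solve_liability_variance(target_auc: float, prevalence: float,
                             tagging_r2: float = 1.0) -> float:
    """Liability variance v such that a score tagging the genetic component at
    ``tagging_r2`` attains ``target_auc``; inverts :func:`liability_score_auc`
    with r = sqrt(tagging_r2 * v)."""
    if not 0.5 < target_auc < 1.0:
        raise ValidationError("target_auc must lie in (0.5, 1)")
    check_probability(tagging_r2, "tagging_r2", open_left=True)

    def gap(v):
        return liability_score_auc(np.sqrt(tagging_r2 * v), prevalence) - target_auc

    return float(optimize.brentq(gap, 1e-8, 1.0 - 1e-8, xtol=1e-10))


# ---------------------------------------------------------------------------
# Clinical labels / missingness


def _draw_categories(rng, probs, n):
    # published marginal tables round to 0.1%; absorb that slack, reject more
    probs = as_1d_float(probs, "category probabilities")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 5e-3:
        raise ValidationError("category probabilities must be >=0 and sum to 1")
    return rng.choice(len(probs), size=n, p=probs / probs.sum())


def simulate_aggressiveness(n_cases: int, seed: int | np.random.Generator, *,
                            stage_probs=DEFAULT_STAGE_PROBS,
                            gleason_probs=DEFAULT_GLEASON_PROBS,
                            liability: np.ndarray | None = None,
                            liability_effect: float = 0.0,
                            missing_rate: float = 0.0):
    """Draw tumor-stage and Gleason labels for cases.

    ``stage_probs`` are P(T1..T4); ``gleason_probs`` are P(<=6, ==7, >=8) and
    integers are drawn uniformly within the selected band (4-6, 7, 8-10).
    ``liability_effect`` > 0 tilts both classifiers toward aggressiveness for
    high-liability cases (logistic tilt on the top-category odds); 0 keeps
    labels independent of the PRS.  ``missing_rate`` blanks each label
    independently.  Returns ``(stage, gleason)`` as object/float arrays with
    None/NaN for missing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_cases < 0:
        raise ValidationError("n_cases must be non-negative")
    missing_rate = check_probability(missing_rate, "missing_rate", open_right=True)

    def tilted(probs, i):
        if liability_effect == 0.0 or liability is None:
            return probs
        p = np.asarray(probs, dtype=float).copy()
        top = p[-1]
        odds = top / (1.0 - top) * np.exp(liability_effect * liability[i])
        p_top = odds / (1.0 + odds)
        p[:-1] *= (1.0 - p_top) / (1.0 - top)
        p[-1] = p_top
        return p / p.sum()

    if liability_effect == 0.0 or liability is None:
        stage_idx = _draw_categories(rng, stage_probs, n_cases)
        gleason_band = _draw_categories(rng, gleason_probs, n_cases)
    else:
        _draw_categories(rng, stage_probs, 0)  # validate
        _draw_categories(rng, gleason_probs, 0)
        stage_idx = np.array(
            [rng.choice(4, p=tilted(stage_probs, i)) for i in range(n_cases)]
        )
        gleason_band = np.array(
            [rng.choice(3, p=tilted(gleason_probs, i)) for i in range(n_cases)]
        )

    stage = np.array([STAGE_LABELS[i] for i in stage_idx], dtype=object)
    gleason = np.where(
        gleason_band == 0, rng.integers(4, 7, n_cases),
        np.where(gleason_band == 1, 7, rng.integers(8, 11, n_cases)),
    ).astype(float)

    if missing_rate > 0 and n_cases > 0:
        stage[rng.random(n_cases) < missing_rate] = None
        gleason[rng.random(n_cases) < missing_rate] = np.nan
    return stage, gleason


def inject_missingness(dosages: np.ndarray, rate_per_variant: float,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Return a copy with each entry independently set to NaN at the given rate."""
    rate = float(rate_per_variant)
    if not (np.isfinite(rate) and 0.0 <= rate < 1.0):
        raise ValidationError(f"missingness rate must lie in [0,1), got {rate}")
    out = np.asarray(dosages, dtype=float).copy()
    if rate == 0.0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out[rng.random(out.shape) < rate] = np.nan
    return out


# ---------------------------------------------------------------------------
# Haplotypes / proxies


def simulate_sweep_haplotypes(n_haplotypes: int, n_sites: int, core_index: int,
                              sweep_strength: float,
                              seed: int | np.random.Generator, *,
                              site_freq: float = 0.3, core_freq: float = 0.5,
                              spacing_bp: int = 1000):
    """Binary haplotype panel with an optional planted sweep at the core.

    Neutral sites are i.i.d. Bernoulli(site_freq) per haplotype; the core
    carries the derived allele at frequency ``core_freq``.  With
    ``sweep_strength`` > 0 every derived-core carrier copies a shared template
    over a flanking segment whose per-side length (in sites) is geometric
    with mean ``sweep_strength``, producing elevated EHH/iHS at the core.

    Returns ``(haplotypes, positions, derived_is_one)`` where ``haplotypes``
    is an (n_haplotypes, n_sites) 0/1 int matrix and positions are bp.
    """
    if n_haplotypes < 4:
        raise ValidationError("need at least 4 haplotypes for EHH/iHS")
    if not 0 <= core_index < n_sites:
        raise ValidationError("core_index out of range")
    if sweep_strength < 0:
        raise ValidationError("sweep_strength must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hap = (rng.random((n_haplotypes, n_sites)) < site_freq).astype(np.int8)
    core = (rng.random(n_haplotypes) < core_freq).astype(np.int8)
    hap[:, core_index] = core
    if sweep_strength > 0:
        carriers = np.flatnonzero(core == 1)
        if carriers.size:
            template = (rng.random(n_sites) < site_freq).astype(np.int8)
            p_stop = 1.0 / (1.0 + sweep_strength)
            for h in carriers:
                left = int(rng.geometric(p_stop))
                right = int(rng.geometric(p_stop))
                lo = max(0, core_index - left)
                hi = min(n_sites, core_index + right + 1)
                hap[h, lo:hi] = template[lo:hi]
            hap[:, core_index] = core
    positions = np.arange(1, n_sites + 1, dtype=np.int64) * spacing_bp
    return hap, positions, True


def proxy_flip_probability(causal_freq: float, target_r2: float) -> float:
    """Per-allele flip probability so a copied proxy tags the causal variant
    at ``target_r2`` (squared Pearson correlation on haplotypes).

    The proxy allele is the causal allele XOR an independent Bernoulli(q)
    flip; q is solved numerically from the closed-form correlation of the
    two binary variables.
    """
    f = check_probability(causal_freq, "causal_freq", open_left=True, open_right=True)
    r2 = check_probability(target_r2, "target_r2", open_left=True)
    if r2 == 1.0:
        return 0.0

    def r2_of(q):
        fy = f * (1 - q) + (1 - f) * q
        cov = f * (1 - f) * (1 - 2 * q)
        return cov * cov / (f * (1 - f) * fy * (1 - fy)) - r2

    return float(optimize.brentq(r2_of, 0.0, 0.5 - 1e-12, xtol=1e-12))


def simulate_proxy_doses(dosages: np.ndarray, pop_freqs, target_r2: float,
                         seed: int | np.random.Generator):
    """Proxy dose matrix tagging each variant of ``dosages`` at ``target_r2``.

    Doses are split into two pseudo-haplotype alleles (the exact split does
    not matter under HWE) and each allele is flipped independently with the
    probability from :func:`proxy_flip_probability`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = np.asarray(dosages, dtype=float)
    f = as_1d_float(pop_freqs, "pop_freqs")
    n, m = d.shape
    # allele 1 is Bernoulli(d/2 rounded): for dose 1 put the copy on a random
    # haplotype; for doses 0/2 both alleles are fixed.
    a1 = np.where(d == 1.0, rng.integers(0, 2, (n, m)), d / 2.0)
    a2 = d - a1
    out = np.empty_like(d)
    for j in range(m):
        q = proxy_flip_probability(f[j], target_r2)
        flip1 = rng.random(n) < q
        flip2 = rng.random(n) < q
        out[:, j] = np.abs(a1[:, j] - flip1) + np.abs(a2[:, j] - flip2)
    return out


# ---------------------------------------------------------------------------
# Cohort assembly


def _draw_ages(rng, n, probs):
    band = _draw_categories(rng, probs, n)
    lo = np.array([AGE_BANDS[b][0] for b in band])
    hi = np.array([AGE_BANDS[b][1] for b in band])
    return rng.integers(lo, hi + 1).astype(float)


def simulate_cohort(pop: PopulationSpec, architecture: GeneticArchitecture,
                    seed: int, *,
                    effect_label: str | None = None,
                    missing_rate: float = 0.0,
                    age_missing_rate: float = 0.0,
                    clinical_missing_rate: float = 0.0,
                    aggressiveness_liability_effect: float = 0.0,
                    stage_probs=DEFAULT_STAGE_PROBS,
                    gleason_probs=DEFAULT_GLEASON_PROBS) -> SimulatedCohort:
    """Simulate one population's cohort end to end.

    Per site, cases are over-sampled by rejection from the liability model:
    genotypes/phenotypes are drawn in bulk and individuals are assigned to
    sites until each site's case and control quotas are filled.  Site labels
    therefore carry no genetic meaning (all sites share the population's
    frequencies), matching a design where cases and controls are frequency
    matched within site.
    """
    freq_rng = stage_rng(seed, "frequencies")
    geno_rng = stage_rng(seed, "genotypes")
    pheno_rng = stage_rng(seed, "phenotypes")
    age_rng = stage_rng(seed, "ages")
    aggr_rng = stage_rng(seed, "aggressiveness")
    miss_rng = stage_rng(seed, "missingness")

    pop_freqs = draw_population_frequencies(
        architecture.ancestral_freqs, pop.fst, freq_rng
    )

    n_cases_needed = {s.name: int(round(s.n_samples * s.case_fraction)) for s in pop.sites}
    for s in pop.sites:
        # keep at least one of each status per site
        n_cases_needed[s.name] = min(max(n_cases_needed[s.name], 1), s.n_samples - 1)
    n_ctrls_needed = {s.name: s.n_samples - n_cases_needed[s.name] for s in pop.sites}
    total = pop.n_samples

    rows_d, rows_liab, rows_g, rows_case, rows_site = [], [], [], [], []
    remaining_cases = dict(n_cases_needed)
    remaining_ctrls = dict(n_ctrls_needed)
    batch = max(256, 2 * total)
    guard = 0
    while (sum(remaining_cases.values()) + sum(remaining_ctrls.values())) > 0:
        guard += 1
        if guard > 10_000:  # pragma: no cover - prevalence pathologically small
            raise ValidationError("case quota unreachable; increase prevalence")
        d = simulate_genotypes(pop_freqs, batch, geno_rng)
        is_case, liab, g = simulate_phenotypes(
            d, architecture, pheno_rng, effect_label=effect_label
        )
        for i in range(batch):
            pool = remaining_cases if is_case[i] else remaining_ctrls
            site = next((s for s in pool if pool[s] > 0), None)
            if site is None:
                continue
            pool[site] -= 1
            rows_d.append(d[i])
            rows_liab.append(liab[i])
            rows_g.append(g[i])
            rows_case.append(bool(is_case[i]))
            rows_site.append(site)
            if (sum(remaining_cases.values()) + sum(remaining_ctrls.values())) == 0:
                break

    order = np.argsort(rows_site, kind="stable")
    dosages = np.asarray(rows_d, dtype=float)[order]
    liability = np.asarray(rows_liab)[order]
    genetic = np.asarray(rows_g)[order]
    is_case = np.asarray(rows_case)[order]
    site = np.asarray(rows_site, dtype=object)[order]

    n = len(is_case)
    sample_ids = [f"{pop.name}_{i:05d}" for i in range(n)]
    variant_ids = [f"var{j:04d}" for j in range(architecture.n_variants)]

    ages = np.where(
        is_case,
        _draw_ages(age_rng, n, DEFAULT_AGE_PROBS_CASE),
        _draw_ages(age_rng, n, DEFAULT_AGE_PROBS_CONTROL),
    )
    if age_missing_rate > 0:
        ages[age_rng.random(n) < age_missing_rate] = np.nan

    stage = np.full(n, None, dtype=object)
    gleason = np.full(n, np.nan)
    case_idx = np.flatnonzero(is_case)
    if case_idx.size:
        st, gl = simulate_aggressiveness(
            case_idx.size, aggr_rng,
            stage_probs=stage_probs, gleason_probs=gleason_probs,
            liability=liability[case_idx],
            liability_effect=aggressiveness_liability_effect,
            missing_rate=clinical_missing_rate,
        )
        stage[case_idx] = st
        gleason[case_idx] = gl

    dosages = inject_missingness(dosages, missing_rate, miss_rng)

    metadata = pd.DataFrame({
        "sample": sample_ids,
        "site": site,
        "status": np.where(is_case, "case", "control"),
        "age": ages,
        "stage": stage,
        "gleason": gleason,
        "population": pop.name,
    })
    truth = {
        "seed": seed,
        "pop_freqs": pop_freqs,
        "liability": liability,
        "genetic_score": genetic,
        "architecture": architecture,
        "effect_label": effect_label or next(iter(architecture.true_log_or)),
    }
    return SimulatedCohort(
        population=pop.name, sample_ids=sample_ids, variant_ids=variant_ids,
        dosages=dosages, metadata=metadata, truth=truth,
    )


def make_score_table(architecture: GeneticArchitecture,
                     variant_ids: list[str] | None = None, *,
                     chrom: str = "1", start_pos: int = 10_000,
                     spacing: int = 50_000) -> pd.DataFrame:
    """Scoring-file table (odds-ratio scale) from the true liability effects.

    Log odds ratios are taken equal to the liability-scale effects - a
    first-order approximation adequate for synthetic plumbing; the exact
    generating effects stay available in cohort ``truth``.
    """
    m = architecture.n_variants
    if variant_ids is None:
        variant_ids = [f"var{j:04d}" for j in range(m)]
    table = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": chrom,
        "pos": start_pos + spacing * np.arange(m),
        "effect_allele": "A",
        "other_allele": "G",
    })
    for label, eff in architecture.true_log_or.items():
        table[f"weight_{label}"] = np.exp(eff)
    return table
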