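"""Readers and writers for the formats the pipeline consumes and emits.

Formats
-------
Scoring file
    Tab-separated with ``#`` header lines declaring ``score_name`` and
    ``weight_scale`` (``OR`` or ``logOR``), then columns
    ``variant_id  chrom  pos  effect_allele  other_allele  weight_<ANCESTRY>...``.
    Weights are converted to the log-odds scale exactly once, at parse time.
Proxy map
    Tab-separated ``source_id  proxy_id  r2  same_direction  rule  log_or``.
    ``rule`` is ``proxy`` for ordinary single-proxy rows and ``expand`` for
    multi-marker inference rows (several rows sharing one ``source_id``, each
    carrying its own log-odds weight).
Genotypes
    VCF 4.2, diploid unphased GT, ``./.`` for missing.  Gzip is handled
    transparently everywhere (by extension).
iHS table
    Tab-separated ``variant_id  freq  ihs``; rows failing the MAF > 0.05
    availability rule (strict) are flagged, not dropped.
Metadata
    Tab-separated ``sample  site  status  age  stage  gleason  population``.
Haplotypes
    Tab-separated matrix: ``pos`` column then one 0/1 column per haplotype.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._util import ValidationError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Scoring files


@dataclass
class ScoreDefinition:
    """A published score: variant table plus per-ancestry log-odds weights.

    ``variants`` columns: variant_id, chrom, pos, effect_allele, other_allele.
    ``log_weights`` maps ancestry label -> per-variant ln(OR) array aligned
    with ``variants``.  ``source_scale`` records whether the file declared OR
    or logOR weights.
    """

    score_name: str
    variants: pd.DataFrame
    log_weights: dict[str, np.ndarray]
    source_scale: str = "OR"

    def __post_init__(self):
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate variant ID {dup!r} in score")
        n = len(self.variants)
        for label, w in self.log_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != n:
                raise ValidationError(
                    f"weight column {label!r} has {len(w)} values for {n} variants"
                )
            if not np.all(np.isfinite(w)):
                raise ValidationError(f"non-finite weight in column {label!r}")
            self.log_weights[label] = w

    @property
    def ancestries(self) -> list[str]:
        return list(self.log_weights)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def log_weight_of(self, variant_id: str, ancestry: str) -> float:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(variant_id)
        return float(self.log_weights[ancestry][idx[0]])


def read_score_file(path) -> ScoreDefinition:
    """Parse a scoring file; see the module docstring for the layout."""
    score_name = Path(str(path)).stem
    scale = None
    header_lines = 0
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    for line in lines:
        if not line.startswith("#"):
            break
        header_lines += 1
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            key, value = key.strip(), value.strip()
            if key == "score_name":
                score_name = value
            elif key == "weight_scale":
                scale = value
    if scale is None:
        raise ParseError(f"{path}: missing '# weight_scale=' header line")
    if scale not in ("OR", "logOR"):
        raise ParseError(f"{path}: unknown weight_scale {scale!r} (want OR or logOR)")

    body = "\n".join(lines[header_lines:])
    if not body.strip():
        raise ParseError(f"{path}: no variant rows after the header")
    table = pd.read_csv(io.StringIO(body), sep="\t", dtype={"chrom": str})
    required = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    weight_cols = [c for c in table.columns if c.startswith("weight_")]
    if not weight_cols:
        raise ParseError(f"{path}: no weight_<ancestry> columns")
    if table.empty:
        raise ParseError(f"{path}: empty variant section")

    dup = table["variant_id"].duplicated()
    if dup.any():
        line_no = header_lines + 2 + int(np.flatnonzero(dup)[0])
        raise ParseError(
            f"{path}:{line_no}: duplicate variant ID "
            f"{table['variant_id'][dup].iloc[0]!r}"
        )

    log_weights = {}
    for col in weight_cols:
        values = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if scale == "OR":
            bad |= values <= 0.0
        if bad.any():
            line_no = header_lines + 2 + int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}:{line_no}: invalid {scale} weight in column {col!r}"
            )
        log_weights[col[len("weight_"):]] = (
            np.log(values) if scale == "OR" else values
        )
    return ScoreDefinition(
        score_name=score_name,
        variants=table[required].reset_index(drop=True),
        log_weights=log_weights,
        source_scale=scale,
    )


def write_score_file(score: ScoreDefinition, path) -> None:
    table = score.variants.copy()
    for label, w in score.log_weights.items():
        table[f"weight_{label}"] = np.exp(w)
    with _open_text(path, "wt") as fh:
        fh.write(f"# score_name={score.score_name}\n# weight_scale=OR\n")
        table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Proxy maps


@dataclass
class ProxyMap:
    """Proxy and multi-marker expansion entries for score variants."""

    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["source_id", "proxy_id", "r2", "same_direction", "rule",
                     "log_or"]
        )
    )

    def __post_init__(self):
        e = self.entries
        if len(e):
            r2 = e["r2"].to_numpy(dtype=float)
            if np.any(r2 < 0) or np.any(r2 > 1):
                raise ValidationError("proxy r2 must lie in [0,1]")
            self_map = (e["source_id"] == e["proxy_id"]) & (e["r2"] < 1.0)
            if self_map.any():
                bad = e.loc[self_map, "source_id"].iloc[0]
                raise ValidationError(
                    f"variant {bad!r} maps to itself with r2 < 1"
                )

    def proxies_for(self, source_id: str) -> pd.DataFrame:
        e = self.entries
        return e[(e["source_id"] == source_id) & (e["rule"] == "proxy")]

    def expansion_for(self, source_id: str) -> pd.DataFrame:
        e = self.entries
        return e[(e["source_id"] == source_id) & (e["rule"] == "expand")]


def read_proxy_map(path) -> ProxyMap:
    table = pd.read_csv(_open_text(path), sep="\t", dtype={"source_id": str,
                                                           "proxy_id": str})
    if "rule" not in table.columns:
        table["rule"] = "proxy"
    table["rule"] = table["rule"].fillna("proxy")
    if "log_or" not in table.columns:
        table["log_or"] = np.nan
    if "same_direction" not in table.columns:
        table["same_direction"] = True
    table["same_direction"] = table["same_direction"].astype(bool)
    bad_rule = ~table["rule"].isin(["proxy", "expand"])
    if bad_rule.any():
        raise ParseError(
            f"{path}: unknown rule {table.loc[bad_rule, 'rule'].iloc[0]!r}"
        )
    try:
        table["r2"] = pd.to_numeric(table["r2"])
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric r2 column") from exc
    return ProxyMap(entries=table.reset_index(drop=True))


def write_proxy_map(pmap: ProxyMap, path) -> None:
    with _open_text(path, "wt") as fh:
        pmap.entries.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cohorts / VCF


@dataclass
class CohortData:
    """Dosage matrix plus variant and sample annotations.

    ``dosages`` is samples x variants, entries in {0,1,2} (float) with NaN
    for missing.  ``variants`` columns: variant_id, chrom, pos, ref, alt.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    metadata: pd.DataFrame | None = None
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self):
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValidationError("dosage rows do not match sample_ids")
        if m != len(self.variants):
            raise ValidationError("dosage columns do not match variant table")

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def column_of(self, variant_id: str) -> int:
        hits = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(hits) == 0:
            raise KeyError(variant_id)
        return int(hits[0])


_GT_TO_ALT_COUNT = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}  # cyvcf2 gt_types codes


def _orient_dose(alt_count, ref, alt, effect, other):
    """Return effect-allele dose from an ALT count, or None if unmatchable.

    Tries direct orientation, swapped orientation, then the strand-flipped
    complements of both; A/T and C/G ambiguous pairs only match directly.
    """
    if effect == alt and other == ref:
        return alt_count
    if effect == ref and other == alt:
        return 2.0 - alt_count
    try:
        flip_e = "".join(_COMPLEMENT[b] for b in effect)
        flip_o = "".join(_COMPLEMENT[b] for b in other)
    except KeyError:
        return None
    ambiguous = flip_e == other  # A/T or C/G pair: flip indistinguishable
    if ambiguous:
        return None
    if flip_e == alt and flip_o == ref:
        return alt_count
    if flip_e == ref and flip_o == alt:
        return 2.0 - alt_count
    return None


def read_genotypes_vcf(path, variant_subset: pd.DataFrame | None = None,
                       metadata: pd.DataFrame | None = None) -> CohortData:
    """Read diploid GTs from a VCF into a :class:`CohortData`.

    ``variant_subset``, when given, restricts to the listed ``variant_id``
    rows and orients each dose to count copies of that row's
    ``effect_allele`` (columns effect_allele/other_allele required).  Records
    whose alleles cannot be reconciled are reported in ``unmatched`` rather
    than raising.  Without a subset, doses count ALT copies.
    """
    wanted = None
    if variant_subset is not None:
        wanted = variant_subset.set_index("variant_id")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, var_rows, unmatched = [], [], []
    for record in vcf:
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        if wanted is not None and vid not in wanted.index:
            continue
        if len(record.ALT) != 1:
            unmatched.append(vid)
            continue
        alt = record.ALT[0]
        counts = np.array(
            [_GT_TO_ALT_COUNT.get(t, np.nan) for t in record.gt_types], dtype=float
        )
        ref_out, alt_out = record.REF, alt
        if wanted is not None:
            spec = wanted.loc[vid]
            oriented = _orient_dose(
                counts, record.REF, alt, str(spec["effect_allele"]),
                str(spec["other_allele"]),
            )
            if oriented is None:
                unmatched.append(vid)
                continue
            counts = oriented
            ref_out, alt_out = str(spec["other_allele"]), str(spec["effect_allele"])
        rows.append(counts)
        var_rows.append((vid, record.CHROM, record.POS, ref_out, alt_out))
    vcf.close()
    variants = pd.DataFrame(
        var_rows, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    )
    dosages = (
        np.asarray(rows, dtype=float).T
        if rows else np.empty((len(samples), 0))
    )
    return CohortData(
        sample_ids=samples, variants=variants, dosages=dosages,
        metadata=metadata, unmatched=unmatched,
    )


_DOSE_TO_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(cohort: CohortData, path) -> None:
    """Write a CohortData as VCF 4.2 (unphased GT; ALT counts = doses)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = pd.unique(cohort.variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.sample_ids) + "\n"
        )
        for j, row in cohort.variants.iterrows():
            gts = [
                _DOSE_TO_GT.get(d, "./.") if np.isfinite(d) else "./."
                for d in cohort.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# iHS tables, metadata, haplotypes


def read_ihs_table(path, maf_threshold: float = 0.05) -> pd.DataFrame:
    """Read ``variant_id  freq  ihs``; flag rows with MAF <= threshold.

    The availability rule is strict ("MAF > 0.05" keeps a row), so a
    frequency of exactly 0.95 or 0.05 is flagged ``excluded``.
    """
    table = pd.read_csv(_open_text(path), sep="\t")
    for col in ("variant_id", "freq", "ihs"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ihs = pd.to_numeric(table["ihs"], errors="coerce")
    if ihs.isna().any():
        line_no = 2 + int(np.flatnonzero(ihs.isna())[0])
        raise ParseError(f"{path}:{line_no}: non-numeric iHS value")
    table["ihs"] = ihs
    table["freq"] = pd.to_numeric(table["freq"])
    maf = np.minimum(table["freq"], 1.0 - table["freq"])
    # absorb float noise so a printed 0.95 folds to exactly the boundary
    table["excluded"] = ~(maf > maf_threshold + 1e-9)
    return table


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(
        _open_text(path), sep="\t",
        dtype={"sample": str, "site": str, "status": str},
    )
    if "stage" in meta.columns:
        meta["stage"] = meta["stage"].where(meta["stage"].notna(), None)
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        metadata.to_csv(fh, sep="\t", index=False)


def write_haplotypes(haplotypes: np.ndarray, positions: np.ndarray, path) -> None:
    table = pd.DataFrame(
        haplotypes.T, columns=[f"hap{i}" for i in range(haplotypes.shape[0])]
    )
    table.insert(0, "pos", positions)
    with _open_text(path, "wt") as fh:
        table.to_csv(fh, sep="\t", index=False)


def read_haplotypes(path):
    table = pd.read_csv(_open_text(path), sep="\t")
    positions = table.pop("pos").to_numpy(dtype=np.int64)
    hap = table.to_numpy(dtype=np.int8).T
    if not np.isin(hap, (0, 1)).all():
        raise ParseError(f"{path}: haplotype entries must be 0/1")
    return hap, positions
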