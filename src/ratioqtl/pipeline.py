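"""Ratio-QTL discovery pipeline.

Stages: candidate selection (GGM edges x known pQTLs), targeted scan with
discovery/replication, genome-wide ratio scan with distance pruning,
cis/trans and novelty annotation, the all-ratios-at-one-variant mode, and
the significance-rate-vs-partial-correlation summary.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assoc import AssocResult, linear_assoc
from .ggm import PcorEdge
from .pgain import log10_pgain, pgain_threshold
from .preprocess import inverse_normal_transform, make_ratio_phenotype

__all__ = [
    "CohortData",
    "KnownPqtl",
    "RQTLRecord",
    "ScanCounts",
    "annotate_cis_trans",
    "flag_novel",
    "prune_independent",
    "ratio_gwas",
    "select_candidate_tests",
    "split_cohort",
    "summarize_pgain_rate_by_pcor",
    "targeted_scan",
    "variant_all_ratios",
]


@dataclass(frozen=True)
class KnownPqtl:
    """A previously reported protein QTL."""

    variant: str
    protein: str
    neglog10_p: float = math.nan
    cis: bool | None = None


@dataclass
class RQTLRecord:
    """One ratio-variant association across discovery and replication."""

    protein1: str
    protein2: str
    variant: str
    chrom: str | None = None
    pos: int | None = None
    neglog10_p1: float = math.nan
    neglog10_p2: float = math.nan
    neglog10_p3: float = math.nan
    log10_pgain: float = math.nan
    significant: bool = False
    repl_neglog10_p3: float = math.nan
    repl_log10_pgain: float = math.nan
    replicated: bool | None = None
    cis1: bool | None = None
    cis2: bool | None = None
    novel: bool | None = None
    lead: bool = False

    @property
    def ratio(self) -> str:
        return f"{self.protein1}/{self.protein2}"


@dataclass
class ScanCounts:
    """Per-stage tallies of a targeted scan."""

    n_candidates: int = 0
    n_significant: int = 0
    n_replicated: int = 0
    discovery_threshold: float = math.nan
    replication_threshold: float = math.nan


@dataclass
class CohortData:
    """Aligned phenotype, genotype and covariate tables for one cohort."""

    proteins: pd.DataFrame
    genotypes: pd.DataFrame
    covariates: pd.DataFrame | None = None
    _int_cache: dict = field(default_factory=dict, repr=False)

    def int_protein(self, protein: str) -> pd.Series:
        """Inverse-normal transformed single-protein phenotype (cached)."""
        if protein not in self._int_cache:
            if protein not in self.proteins.columns:
                raise KeyError(f"unknown protein id: {protein!r}")
            self._int_cache[protein] = inverse_normal_transform(
                self.proteins[protein]
            )
        return self._int_cache[protein]

    def ratio_phenotype(self, pair: tuple[str, str]) -> pd.Series:
        key = ("ratio", *pair)
        if key not in self._int_cache:
            self._int_cache[key] = make_ratio_phenotype(self.proteins, pair)
        return self._int_cache[key]

    def dosage(self, variant: str) -> pd.Series:
        if variant not in self.genotypes.columns:
            raise KeyError(f"unknown variant id: {variant!r}")
        return self.genotypes[variant]


def split_cohort(cohort) -> tuple[CohortData, CohortData]:
    """Split a synthetic cohort into discovery and replication data."""
    def subset(ids):
        return CohortData(
            proteins=cohort.proteins.loc[ids],
            genotypes=cohort.genotypes.loc[ids],
            covariates=cohort.covariates.loc[ids],
        )

    return subset(cohort.discovery_ids), subset(cohort.replication_ids)


def select_candidate_tests(
    edges, pqtls
) -> list[tuple[tuple[str, str], str]]:
    """Candidate (ratio, variant) tests: each edge paired with every known
    pQTL variant of either of its proteins, de-duplicated."""
    pairs = []
    for e in edges:
        a, b = (e.a, e.b) if isinstance(e, PcorEdge) else tuple(e)[:2]
        pairs.append(tuple(sorted((a, b))))
    by_protein: dict[str, set[str]] = {}
    for q in pqtls:
        variant, protein = (
            (q.variant, q.protein) if isinstance(q, KnownPqtl) else tuple(q)[:2]
        )
        by_protein.setdefault(protein, set()).add(variant)
    out = set()
    for a, b in pairs:
        for v in by_protein.get(a, set()) | by_protein.get(b, set()):
            out.add(((a, b), v))
    return sorted(out)


def _ratio_assoc_triple(
    data: CohortData, pair: tuple[str, str], variant: str
) -> tuple[AssocResult, AssocResult, AssocResult]:
    g = data.dosage(variant)
    a1 = linear_assoc(
        data.int_protein(pair[0]), g, data.covariates, pair[0], variant
    )
    a2 = linear_assoc(
        data.int_protein(pair[1]), g, data.covariates, pair[1], variant
    )
    a3 = linear_assoc(
        data.ratio_phenotype(pair), g, data.covariates,
        f"{pair[0]}/{pair[1]}", variant,
    )
    return a1, a2, a3


def targeted_scan(
    candidates: list[tuple[tuple[str, str], str]],
    discovery: CohortData,
    replication: CohortData | None = None,
    alpha: float = 0.05,
    variant_info: pd.DataFrame | None = None,
) -> tuple[list[RQTLRecord], ScanCounts]:
    """Test each candidate ratio-variant pair; replicate the significant ones.

    Discovery significance requires log10 p-gain above the critical value
    for ``len(candidates)`` tests; replication, computed only for records
    significant in discovery, requires the critical value for the number of
    significant records.
    """
    counts = ScanCounts(n_candidates=len(candidates))
    if not candidates:
        return [], counts
    counts.discovery_threshold = pgain_threshold(len(candidates), alpha)
    records: list[RQTLRecord] = []
    for pair, variant in candidates:
        a1, a2, a3 = _ratio_assoc_triple(discovery, pair, variant)
        gain = log10_pgain(a1.neglog10_p, a2.neglog10_p, a3.neglog10_p)
        rec = RQTLRecord(
            protein1=pair[0],
            protein2=pair[1],
            variant=variant,
            neglog10_p1=a1.neglog10_p,
            neglog10_p2=a2.neglog10_p,
            neglog10_p3=a3.neglog10_p,
            log10_pgain=gain,
            significant=gain > counts.discovery_threshold,
        )
        if variant_info is not None and variant in variant_info.index:
            rec.chrom = str(variant_info.loc[variant, "chrom"])
            rec.pos = int(variant_info.loc[variant, "pos"])
        records.append(rec)

    significant = [r for r in records if r.significant]
    counts.n_significant = len(significant)
    if replication is not None and significant:
        counts.replication_threshold = pgain_threshold(len(significant), alpha)
        for rec in significant:
            b1, b2, b3 = _ratio_assoc_triple(
                replication, (rec.protein1, rec.protein2), rec.variant
            )
            rec.repl_neglog10_p3 = b3.neglog10_p
            rec.repl_log10_pgain = log10_pgain(
                b1.neglog10_p, b2.neglog10_p, b3.neglog10_p
            )
            rec.replicated = (
                rec.repl_log10_pgain > counts.replication_threshold
            )
        counts.n_replicated = sum(bool(r.replicated) for r in significant)
    return records, counts


def ratio_gwas(
    ratios: list[tuple[str, str]],
    data: CohortData,
    variant_info: pd.DataFrame,
    genomewide_alpha: float = 5e-8,
    pgain_base: float = 1e7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every ratio against every variant.

    Returns the full association table and the subset passing both the
    Bonferroni p cut (genomewide_alpha / n_ratios) and the p-gain cut
    (pgain_base * n_ratios).
    """
    if not ratios:
        raise ValueError("ratio list is empty")
    n_ratios = len(ratios)
    p_cut = -math.log10(genomewide_alpha / n_ratios)
    gain_cut = math.log10(pgain_base) + math.log10(n_ratios)

    protein_cache: dict[tuple[str, str], AssocResult] = {}

    def protein_assoc(protein: str, variant: str) -> AssocResult:
        key = (protein, variant)
        if key not in protein_cache:
            protein_cache[key] = linear_assoc(
                data.int_protein(protein), data.dosage(variant),
                data.covariates, protein, variant,
            )
        return protein_cache[key]

    rows = []
    for pair in ratios:
        pair = tuple(pair)
        ratio_pheno = data.ratio_phenotype(pair)
        for variant in data.genotypes.columns:
            a1 = protein_assoc(pair[0], variant)
            a2 = protein_assoc(pair[1], variant)
            a3 = linear_assoc(
                ratio_pheno, data.dosage(variant), data.covariates,
                f"{pair[0]}/{pair[1]}", variant,
            )
            gain = log10_pgain(a1.neglog10_p, a2.neglog10_p, a3.neglog10_p)
            rows.append(
                {
                    "ratio": f"{pair[0]}/{pair[1]}",
                    "protein1": pair[0],
                    "protein2": pair[1],
                    "variant": variant,
                    "chrom": str(variant_info.loc[variant, "chrom"]),
                    "pos": int(variant_info.loc[variant, "pos"]),
                    "n": a3.n,
                    "beta": a3.beta,
                    "se": a3.se,
                    "t": a3.t,
                    "neglog10_p1": a1.neglog10_p,
                    "neglog10_p2": a2.neglog10_p,
                    "neglog10_p3": a3.neglog10_p,
                    "log10_pgain": gain,
                }
            )
    full = pd.DataFrame(rows)
    retained = full[
        (full["neglog10_p3"] > p_cut) & (full["log10_pgain"] > gain_cut)
    ].reset_index(drop=True)
    return full, retained


def prune_independent(
    hits: pd.DataFrame, min_distance: int = 1_000_000
) -> pd.DataFrame:
    """Greedy distance pruning of associations for one ratio.

    Repeatedly keeps the strongest remaining hit and discards all others on
    the same chromosome within ``min_distance`` bp.  Ties on -log10 p break
    by position, then variant id, so the result is independent of input
    order.
    """
    if hits.empty:
        return hits.copy()
    df = hits.sort_values(
        ["neglog10_p3", "pos", "variant"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    kept: list[int] = []
    for i in df.index:
        ch, pos = df.at[i, "chrom"], df.at[i, "pos"]
        if all(
            df.at[j, "chrom"] != ch or abs(df.at[j, "pos"] - pos) > min_distance
            for j in kept
        ):
            kept.append(i)
    out = df.loc[kept].reset_index(drop=True)
    return out


def annotate_cis_trans(
    record: RQTLRecord,
    gene_table: pd.DataFrame,
    window: int = 1_000_000,
) -> RQTLRecord:
    """Flag each ratio protein cis/trans relative to the record's variant.

    A protein is cis when the variant sits on the gene's chromosome within
    strictly less than ``window`` bp of the nearest gene edge (distance 0
    inside the gene body).  ``gene_table`` is indexed by protein id with
    columns chrom, start, end.
    """
    if record.chrom is None or record.pos is None:
        raise ValueError(
            f"record {record.ratio} @ {record.variant} lacks coordinates"
        )
    flags = []
    for protein in (record.protein1, record.protein2):
        if protein not in gene_table.index:
            raise KeyError(f"no gene coordinates for protein {protein!r}")
        row = gene_table.loc[protein]
        if str(row["chrom"]) != str(record.chrom):
            flags.append(False)
            continue
        start, end = int(row["start"]), int(row["end"])
        if start <= record.pos <= end:
            dist = 0
        else:
            dist = min(abs(record.pos - start), abs(record.pos - end))
        flags.append(dist < window)
    return replace(record, cis1=flags[0], cis2=flags[1])


def flag_novel(
    records: list[RQTLRecord],
    known_pqtls,
    variant_info: pd.DataFrame,
    window: int = 1_000_000,
) -> list[RQTLRecord]:
    """Mark records novel when no known pQTL of either ratio protein lies
    within ``window`` bp on the same chromosome."""
    known: dict[str, list[tuple[str, int]]] = {}
    for q in known_pqtls:
        variant, protein = (
            (q.variant, q.protein) if isinstance(q, KnownPqtl) else tuple(q)[:2]
        )
        if variant not in variant_info.index:
            raise KeyError(
                f"known pQTL variant {variant!r} absent from variant map"
            )
        known.setdefault(protein, []).append(
            (
                str(variant_info.loc[variant, "chrom"]),
                int(variant_info.loc[variant, "pos"]),
            )
        )
    out = []
    for rec in records:
        if rec.chrom is None or rec.pos is None:
            raise ValueError(
                f"record {rec.ratio} @ {rec.variant} lacks coordinates"
            )
        novel = True
        for protein in (rec.protein1, rec.protein2):
            for ch, pos in known.get(protein, ()):
                if ch == str(rec.chrom) and abs(pos - rec.pos) <= window:
                    novel = False
        out.append(replace(rec, novel=novel))
    return out


def variant_all_ratios(
    variant: str,
    proteins: list[str],
    data: CohortData,
    pgain_min: float = 1e10,
) -> pd.DataFrame:
    """Test one variant against all unordered ratios of a protein subset.

    Returns the ratios whose log10 p-gain exceeds log10(pgain_min), sorted
    by p-gain descending, plus a ``n_tested`` attribute on the frame.
    """
    if len(proteins) < 2:
        raise ValueError("protein subset must contain at least 2 proteins")
    if variant not in data.genotypes.columns:
        raise KeyError(f"unknown variant id: {variant!r}")
    g = data.dosage(variant)
    singles = {
        p: linear_assoc(data.int_protein(p), g, data.covariates, p, variant)
        for p in proteins
    }
    cut = math.log10(pgain_min)
    rows = []
    n_tested = 0
    for a, b in itertools.combinations(sorted(proteins), 2):
        n_tested += 1
        a3 = linear_assoc(
            data.ratio_phenotype((a, b)), g, data.covariates, f"{a}/{b}", variant
        )
        gain = log10_pgain(
            singles[a].neglog10_p, singles[b].neglog10_p, a3.neglog10_p
        )
        if gain > cut:
            rows.append(
                {
                    "ratio": f"{a}/{b}",
                    "variant": variant,
                    "neglog10_p1": singles[a].neglog10_p,
                    "neglog10_p2": singles[b].neglog10_p,
                    "neglog10_p3": a3.neglog10_p,
                    "log10_pgain": gain,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "ratio", "variant", "neglog10_p1", "neglog10_p2",
            "neglog10_p3", "log10_pgain",
        ],
    )
    if not out.empty:
        out = out.sort_values("log10_pgain", ascending=False).reset_index(
            drop=True
        )
    out.attrs["n_tested"] = n_tested
    return out


def summarize_pgain_rate_by_pcor(
    results: pd.DataFrame, window: int = 10_000
) -> pd.DataFrame:
    """Moving-average fraction of significant p-gains along |pcor|.

    ``results`` needs columns ``abs_pcor`` and ``significant``.  With fewer
    rows than the window a single global fraction is returned with a
    warning.
    """
    if not {"abs_pcor", "significant"} <= set(results.columns):
        raise ValueError("results must have columns abs_pcor and significant")
    df = results.sort_values("abs_pcor", kind="mergesort").reset_index(
        drop=True
    )
    sig = df["significant"].astype(float)
    if len(df) < window:
        warnings.warn(
            f"only {len(df)} results for window {window}; "
            "returning the global fraction",
            stacklevel=2,
        )
        return pd.DataFrame(
            {
                "abs_pcor": [float(df["abs_pcor"].median())],
                "rate": [float(sig.mean())],
            }
        )
    rate = sig.rolling(window).mean()
    center = df["abs_pcor"].rolling(window).mean()
    ok = rate.notna()
    return pd.DataFrame(
        {"abs_pcor": center[ok].to_numpy(), "rate": rate[ok].to_numpy()}
    )
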