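"""Readers and writers for the pipeline's text formats.

Everything on disk is TSV with strict schemas; the missing token is ``NA``;
p-values and p-gains are serialized on the -log10 scale only.  Genotypes
use the PLINK ``.raw`` text dialect (six leading pedigree columns, then one
``variant_allele`` column per variant with additive dosages 0/1/2/NA).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .enrichment import InteractionReference
from .ggm import PcorEdge
from .pipeline import KnownPqtl, RQTLRecord

__all__ = [
    "RunConfig",
    "read_covariates",
    "read_edges",
    "read_gene_table",
    "read_genotypes_raw",
    "read_interaction_reference",
    "read_known_pqtls",
    "read_pair_classes",
    "read_protein_matrix",
    "read_rqtl_table",
    "read_variant_info",
    "write_edges",
    "write_genotypes_raw",
    "write_protein_matrix",
    "write_rqtl_table",
]

NA = "NA"

RAW_LEAD_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]

RQTL_COLUMNS = [
    "ratio", "protein1", "protein2", "variant", "chrom", "pos",
    "neglog10_p1", "neglog10_p2", "neglog10_p3", "log10_pgain",
    "significant", "repl_neglog10_p3", "repl_log10_pgain", "replicated",
    "cis1", "cis2", "novel", "lead",
]


@dataclass
class RunConfig:
    """All thresholds and knobs of a pipeline run, YAML round-trippable."""

    ggm_alpha: float = 0.05
    pqtl_alpha: float = 5e-8
    pgain_alpha: float = 0.05
    genomewide_alpha: float = 5e-8
    pgain_base: float = 1e7
    cis_window: int = 1_000_000
    novel_window: int = 1_000_000
    prune_distance: int = 1_000_000
    geno_max_missing: float = 0.1
    mind_max_missing: float = 0.1
    maf_min: float = 0.01
    mac_min: int = 100
    hwe_p_min: float = 1e-15
    sample_max_missing: float = 0.2
    protein_max_missing: float = 0.2
    string_score_min: float = 0.7
    variant_ratios_pgain_min: float = 1e10
    seed: int = 0
    cohort_column: str = "cohort"
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _read_tsv(path, required: list[str], index_col: str | None = None):
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if index_col is not None:
        dup = df[index_col][df[index_col].duplicated()]
        if len(dup):
            line = int(dup.index[0]) + 2
            raise ValueError(
                f"{path}: duplicate {index_col} {dup.iloc[0]!r} at line {line}"
            )
        df = df.set_index(index_col)
    return df


def _to_float(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                if pd.isna(v):
                    continue
                try:
                    float(v)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {v!r} in column "
                        f"{col!r} at line {i + 2}"
                    ) from None
        raise


def read_protein_matrix(path) -> pd.DataFrame:
    """Samples x proteins TSV; first column is the sample id."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=[NA], keep_default_na=False
    )
    if df.columns[0] != "sample_id":
        df = df.rename(columns={df.columns[0]: "sample_id"})
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(
            f"{path}: duplicate sample id {dup.iloc[0]!r} at line "
            f"{int(dup.index[0]) + 2}"
        )
    dup_cols = pd.Index(df.columns[1:])
    if dup_cols.has_duplicates:
        raise ValueError(
            f"{path}: duplicate protein id(s) "
            f"{sorted(dup_cols[dup_cols.duplicated()])}"
        )
    out = _to_float(df.set_index("sample_id"), path)
    out.index.name = "sample_id"
    return out


def write_protein_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=NA, index_label="sample_id")


def read_genotypes_raw(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """PLINK-.raw dialect genotypes -> (dosage matrix, effect-allele map)."""
    df = pd.read_csv(
        path, sep=r"\s+", dtype=str, na_values=[NA], keep_default_na=False
    )
    if list(df.columns[:6]) != RAW_LEAD_COLUMNS:
        raise ValueError(
            f"{path}: expected leading columns {RAW_LEAD_COLUMNS}, "
            f"got {list(df.columns[:6])}"
        )
    alleles: dict[str, str] = {}
    renames: dict[str, str] = {}
    for col in df.columns[6:]:
        if "_" not in col:
            raise ValueError(
                f"{path}: genotype column {col!r} lacks an _allele suffix"
            )
        vid, allele = col.rsplit("_", 1)
        alleles[vid] = allele
        renames[col] = vid
    dup = df["IID"][df["IID"].duplicated()]
    if len(dup):
        raise ValueError(
            f"{path}: duplicate IID {dup.iloc[0]!r} at line "
            f"{int(dup.index[0]) + 2}"
        )
    geno = df.set_index("IID")[list(renames)].rename(columns=renames)
    for col in geno.columns:
        obs = geno[col].dropna()
        bad = obs[~obs.isin(["0", "1", "2"])]
        if len(bad):
            raise ValueError(
                f"{path}: dosage {bad.iloc[0]!r} for variant {col!r} "
                f"(sample {bad.index[0]!r}) not in {{0, 1, 2, NA}}"
            )
    geno = geno.astype(float)
    geno.index.name = "sample_id"
    return geno, alleles


def write_genotypes_raw(
    geno: pd.DataFrame, alleles: dict[str, str], path
) -> None:
    out = pd.DataFrame(index=geno.index)
    out["FID"] = geno.index
    out["IID"] = geno.index
    out["PAT"] = 0
    out["MAT"] = 0
    out["SEX"] = 0
    out["PHENOTYPE"] = -9
    for vid in geno.columns:
        col = geno[vid]
        out[f"{vid}_{alleles.get(vid, 'A')}"] = [
            NA if pd.isna(v) else str(int(v)) for v in col
        ]
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_variant_info(path) -> pd.DataFrame:
    """Variant map TSV (id, chrom, pos, a1, a2) indexed by variant id."""
    df = _read_tsv(path, ["id", "chrom", "pos", "a1", "a2"], index_col="id")
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        bad = df.index[df["pos"] < 1][0]
        raise ValueError(f"{path}: variant {bad!r} has position < 1")
    return df


def write_variant_info(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="id", na_rep=NA)


def read_gene_table(path) -> pd.DataFrame:
    """Gene coordinate TSV (protein, chrom, start, end) indexed by protein."""
    df = _read_tsv(path, ["protein", "chrom", "start", "end"], index_col="protein")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="protein", na_rep=NA)


def read_covariates(path) -> pd.DataFrame:
    df = _read_tsv(path, [], index_col=None)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return _to_float(df, path)


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA)


def read_known_pqtls(path) -> list[KnownPqtl]:
    """Known pQTL TSV: variant, protein, neglog10_p columns."""
    df = _read_tsv(path, ["variant", "protein"])
    out = []
    for _, row in df.iterrows():
        nlp = float(row["neglog10_p"]) if "neglog10_p" in df.columns and not pd.isna(
            row.get("neglog10_p")
        ) else math.nan
        out.append(KnownPqtl(row["variant"], row["protein"], nlp))
    return out


def read_edges(path) -> list[PcorEdge]:
    df = _read_tsv(path, ["proteinA", "proteinB", "pcor", "neglog10p"])
    return [
        PcorEdge(
            row["proteinA"],
            row["proteinB"],
            float(row["pcor"]),
            float(row["neglog10p"]),
            str(row.get("significant", "True")) == "True",
        )
        for _, row in df.iterrows()
    ]


def write_edges(edges: list[PcorEdge], path) -> None:
    pd.DataFrame(
        [
            {
                "proteinA": e.a,
                "proteinB": e.b,
                "pcor": e.pcor,
                "neglog10p": e.neglog10_p,
                "significant": e.significant,
            }
            for e in edges
        ],
        columns=["proteinA", "proteinB", "pcor", "neglog10p", "significant"],
    ).to_csv(path, sep="\t", index=False, na_rep=NA)


def _opt_bool(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return NA
    return str(bool(v))


def write_rqtl_table(records: list[RQTLRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "ratio": r.ratio,
                "protein1": r.protein1,
                "protein2": r.protein2,
                "variant": r.variant,
                "chrom": NA if r.chrom is None else r.chrom,
                "pos": NA if r.pos is None else r.pos,
                "neglog10_p1": repr(r.neglog10_p1),
                "neglog10_p2": repr(r.neglog10_p2),
                "neglog10_p3": repr(r.neglog10_p3),
                "log10_pgain": repr(r.log10_pgain),
                "significant": str(r.significant),
                "repl_neglog10_p3": repr(r.repl_neglog10_p3),
                "repl_log10_pgain": repr(r.repl_log10_pgain),
                "replicated": _opt_bool(r.replicated),
                "cis1": _opt_bool(r.cis1),
                "cis2": _opt_bool(r.cis2),
                "novel": _opt_bool(r.novel),
                "lead": str(r.lead),
            }
        )
    pd.DataFrame(rows, columns=RQTL_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def read_rqtl_table(path) -> list[RQTLRecord]:
    df = _read_tsv(path, RQTL_COLUMNS)

    def opt_bool(v):
        if pd.isna(v):
            return None
        return v == "True"

    out = []
    for _, row in df.iterrows():
        out.append(
            RQTLRecord(
                protein1=row["protein1"],
                protein2=row["protein2"],
                variant=row["variant"],
                chrom=None if pd.isna(row["chrom"]) else row["chrom"],
                pos=None if pd.isna(row["pos"]) else int(row["pos"]),
                neglog10_p1=float(row["neglog10_p1"]),
                neglog10_p2=float(row["neglog10_p2"]),
                neglog10_p3=float(row["neglog10_p3"]),
                log10_pgain=float(row["log10_pgain"]),
                significant=row["significant"] == "True",
                repl_neglog10_p3=float(row["repl_neglog10_p3"]),
                repl_log10_pgain=float(row["repl_log10_pgain"]),
                replicated=opt_bool(row["replicated"]),
                cis1=opt_bool(row["cis1"]),
                cis2=opt_bool(row["cis2"]),
                novel=opt_bool(row["novel"]),
                lead=row["lead"] == "True",
            )
        )
    return out


def read_interaction_reference(
    path, score_min: float = 0.7, aliases: dict[str, str] | None = None
) -> InteractionReference:
    """STRING-dialect TSV (protein1, protein2, combined_score 0-1000).

    Scores are normalized to [0, 1]; identifiers are optionally mapped
    through an alias table before pairing.
    """
    df = _read_tsv(path, ["protein1", "protein2", "combined_score"])
    triples = []
    for _, row in df.iterrows():
        a, b = row["protein1"], row["protein2"]
        if aliases:
            a = aliases.get(a, a)
            b = aliases.get(b, b)
        if a == b:
            continue
        triples.append((a, b, float(row["combined_score"]) / 1000.0))
    return InteractionReference.from_pairs(triples, score_min=score_min)


def read_pair_classes(path) -> pd.DataFrame:
    """Pair-class annotation TSV: protein1, protein2, class."""
    return _read_tsv(path, ["protein1", "protein2", "class"])
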