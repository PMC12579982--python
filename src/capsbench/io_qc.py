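"""Variant-table I/O, gnomAD-style QC, score annotation, ClinVar stars.

The in-memory variant table is a plain :class:`pandas.DataFrame` with one
row per biallelic SNV.  Required columns:

``chrom, pos, ref, alt, context3, allele_count, filter_flags,
callable_fraction, coverage, consequence``

plus the derived ``is_singleton`` and optional ``methylation_level``,
``clinvar_significance``, ``clinvar_review_status``, ``clinvar_stars``.
Tool scores live in ``score_<tool>`` columns (NaN = missing).  Unknown
columns are preserved as pass-through annotations.

Coordinates are 1-based and fully closed, matching VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contexts import context_label_strings
from .errors import ConfigurationError, ContextError, RowValidationError, SchemaError
from .tools import ToolMeta, LOWER, score_column

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "context3",
    "allele_count",
    "filter_flags",
    "callable_fraction",
    "coverage",
    "consequence",
)

OPTIONAL_COLUMNS = (
    "methylation_level",
    "clinvar_significance",
    "clinvar_review_status",
    "clinvar_stars",
)

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

CONSEQUENCES = ("missense", "synonymous", "lof", "other")

SIGNIFICANCES = (
    "benign",
    "likely_benign",
    "uncertain",
    "likely_pathogenic",
    "pathogenic",
    "absent",
)


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    bad_ac = df.index[~(df["allele_count"] >= 1)]
    if len(bad_ac):
        raise RowValidationError(
            f"allele_count must be a positive integer, got {df.loc[bad_ac[0], 'allele_count']!r}",
            row=int(bad_ac[0]),
        )
    mid = df["context3"].astype(str).str[1]
    bad_mid = df.index[mid != df["ref"].astype(str)]
    if len(bad_mid):
        raise RowValidationError(
            f"ref {df.loc[bad_mid[0], 'ref']!r} does not match middle base of "
            f"context3 {df.loc[bad_mid[0], 'context3']!r}",
            row=int(bad_mid[0]),
        )
    bad_alt = df.index[df["ref"].astype(str) == df["alt"].astype(str)]
    if len(bad_alt):
        raise RowValidationError("ref equals alt", row=int(bad_alt[0]))
    df = df.copy()
    df["allele_count"] = df["allele_count"].astype(np.int64)
    df["is_singleton"] = df["allele_count"] == 1
    df["filter_flags"] = df["filter_flags"].fillna("").astype(str)
    for col in ("methylation_level", "clinvar_stars"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype("float64").astype("Int64")
    if "clinvar_significance" in df.columns:
        df["clinvar_significance"] = df["clinvar_significance"].fillna("absent")
    return df


def read_variant_table(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a variant table from TSV (default) or the VCF-lite dialect."""
    if dialect == "tsv":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "ref": str, "alt": str, "context3": str, "filter_flags": str},
            keep_default_na=True,
        )
        return _validate_table(df)
    if dialect == "vcf_lite":
        return _read_vcf_lite(path)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def write_variant_table(df: pd.DataFrame, path) -> None:
    """Write a variant table as TSV (inverse of :func:`read_variant_table`)."""
    out = df.drop(columns=["is_singleton"], errors="ignore")
    out.to_csv(path, sep="\t", index=False)


def _read_vcf_lite(path) -> pd.DataFrame:
    """Biallelic-SNV VCF with INFO keys AC, CONTEXT, COV, CALLF (+ MET, CSQ)."""
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                skipped += 1
                continue
            info = rec.info
            flags = [k for k in rec.filter.keys() if k != "PASS"]
            ac = info["AC"]
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": ref,
                    "alt": alt,
                    "context3": info["CONTEXT"],
                    "allele_count": ac[0] if isinstance(ac, tuple) else ac,
                    "filter_flags": ";".join(flags),
                    "callable_fraction": float(info["CALLF"]),
                    "coverage": float(info["COV"]),
                    "consequence": info.get("CSQ", "other"),
                    "methylation_level": info.get("MET", np.nan),
                }
            )
    if skipped:
        logger.warning("vcf_lite: skipped %d non-biallelic-SNV records", skipped)
    if not rows:
        raise SchemaError("vcf_lite file contains no biallelic SNV records")
    return _validate_table(pd.DataFrame(rows))


def write_vcf_lite(df: pd.DataFrame, path) -> None:
    """Write the VCF-lite dialect (minimal header, INFO-encoded annotations)."""
    flags = sorted({f for fl in df["filter_flags"].fillna("") for f in str(fl).split(";") if f})
    contigs = list(dict.fromkeys(df["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for f in flags:
            fh.write(f'##FILTER=<ID={f},Description="{f}">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Allele count">\n')
        fh.write('##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Reference trinucleotide">\n')
        fh.write('##INFO=<ID=COV,Number=1,Type=Float,Description="Median coverage">\n')
        fh.write('##INFO=<ID=CALLF,Number=1,Type=Float,Description="Callable fraction">\n')
        fh.write('##INFO=<ID=MET,Number=1,Type=Integer,Description="Methylation level">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        meth = df["methylation_level"] if "methylation_level" in df.columns else None
        for i, (_, row) in enumerate(df.iterrows()):
            filt = str(row["filter_flags"]) or "PASS"
            filt = filt.replace(";", ";") if filt != "PASS" else "PASS"
            info = (
                f"AC={int(row['allele_count'])};CONTEXT={row['context3']};"
                f"COV={row['coverage']:.6g};CALLF={row['callable_fraction']:.6g};"
                f"CSQ={row['consequence']}"
            )
            if meth is not None and pd.notna(meth.iloc[i]):
                info += f";MET={int(meth.iloc[i])}"
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t{filt}\t{info}\n"
            )


def assign_contexts(df: pd.DataFrame, on_ambiguous: str = "raise") -> pd.DataFrame:
    """Add a ``context_label`` column of collapsed-class strings.

    ``on_ambiguous`` controls what happens to rows whose context cannot
    be assigned (e.g. contains N): ``"raise"`` or ``"drop"`` (with a
    logged count).
    """
    meth = df["methylation_level"] if "methylation_level" in df.columns else None
    labels = context_label_strings(df["context3"], df["alt"], meth)
    labels.index = df.index
    bad = labels.isna()
    if bad.any():
        if on_ambiguous == "drop":
            logger.warning("dropped %d records with unassignable contexts", int(bad.sum()))
            df = df[~bad]
            labels = labels[~bad]
        else:
            i = df.index[bad][0]
            raise ContextError(
                f"row {i}: unassignable context {df.loc[i, 'context3']!r}>{df.loc[i, 'alt']!r}"
            )
    out = df.copy()
    out["context_label"] = labels.astype(str)
    return out


@dataclass(frozen=True)
class QCParams:
    """gnomAD-style site filters.

    Variants are kept only if they carry no filter flags, were called in
    at least ``min_callable_fraction`` of potential carriers, and have a
    median coverage of at least ``min_coverage``.  Both numeric rules
    are strict on the removal side: coverage below 30 is removed, 30 is
    kept; callable fraction below 0.8 is removed, 0.8 is kept.
    """

    min_callable_fraction: float = 0.8
    min_coverage: float = 30.0
    require_no_flags: bool = True

    def __post_init__(self):
        if not 0.0 <= self.min_callable_fraction <= 1.0:
            raise ConfigurationError("min_callable_fraction must be in [0, 1]")
        if self.min_coverage < 0:
            raise ConfigurationError("min_coverage must be nonnegative")


def qc_filter(df: pd.DataFrame, params: QCParams = QCParams()) -> pd.DataFrame:
    """Apply site-level QC; returns the passing subset (possibly empty)."""
    keep = pd.Series(True, index=df.index)
    if params.require_no_flags:
        flagged = df["filter_flags"].fillna("").astype(str) != ""
        logger.info("qc_filter: %d removed by filter flags", int(flagged.sum()))
        keep &= ~flagged
    low_call = df["callable_fraction"] < params.min_callable_fraction
    logger.info("qc_filter: %d removed by callable fraction", int((keep & low_call).sum()))
    keep &= ~low_call
    low_cov = df["coverage"] < params.min_coverage
    logger.info("qc_filter: %d removed by coverage", int((keep & low_cov).sum()))
    keep &= ~low_cov
    return df[keep].copy()


def read_score_table(path) -> pd.DataFrame:
    """Read a long-format score table: chrom, pos, ref, alt, tool, score."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "tool": str})
    for col in VARIANT_KEY + ["tool", "score"]:
        if col not in df.columns:
            raise SchemaError(f"score table: missing required column {col!r}")
    return df


def write_score_table(df: pd.DataFrame, path, tools=None) -> None:
    """Write ``score_<tool>`` columns as a long-format score table."""
    cols = [c for c in df.columns if c.startswith("score_")]
    if tools is not None:
        cols = [score_column(t) for t in tools if score_column(t) in df.columns]
    frames = []
    for col in cols:
        sub = df.loc[df[col].notna(), VARIANT_KEY].copy()
        sub["tool"] = col[len("score_"):]
        sub["score"] = df.loc[sub.index, col]
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=VARIANT_KEY + ["tool", "score"]
    )
    long.to_csv(path, sep="\t", index=False)


def annotate_scores(
    df: pd.DataFrame,
    scores: pd.DataFrame,
    registry: dict[str, ToolMeta],
) -> pd.DataFrame:
    """Attach each tool's most deleterious score per variant.

    The score table may hold several rows per variant (one per
    transcript); the retained value is the orientation-aware extreme —
    the minimum for lower-is-deleterious tools, the maximum otherwise.
    Scores outside a tool's valid range are treated as missing (with a
    logged count).  Variants absent from the score table keep all
    scores missing.
    """
    out = df.copy()
    for tool in sorted(scores["tool"].unique()):
        if tool not in registry:
            raise ConfigurationError(f"tool {tool!r} not present in the registry")
        meta = registry[tool]
        sub = scores.loc[scores["tool"] == tool, VARIANT_KEY + ["score"]].copy()
        lo, hi = meta.valid_range
        bad = ~sub["score"].between(lo, hi)
        if bad.any():
            logger.warning(
                "annotate_scores: %d %s score(s) outside [%g, %g] treated as missing",
                int(bad.sum()), tool, lo, hi,
            )
            sub = sub[~bad]
        how = "min" if meta.orientation == LOWER else "max"
        worst = sub.groupby(VARIANT_KEY, sort=False)["score"].agg(how)
        key = pd.MultiIndex.from_frame(out[VARIANT_KEY])
        out[score_column(tool)] = worst.reindex(key).to_numpy()
    return out


# ClinVar review-status phrases -> star tier.  Expert-panel (and practice
# guideline) review earns 3 stars; multiple concordant submitters with
# criteria earn 2; a single submitter with criteria earns 1; everything
# else — including conflicting interpretations — earns 0.
_STAR_MAP = {
    "practice guideline": 3,
    "reviewed by expert panel": 3,
    "criteria provided, multiple submitters, no conflicts": 2,
    "criteria provided, single submitter": 1,
    "criteria provided, conflicting interpretations": 0,
    "no assertion criteria provided": 0,
    "no assertion provided": 0,
    "no classification provided": 0,
    "no classification for the single variant": 0,
    "no interpretation for the single variant": 0,
}


def map_review_status_to_stars(status: str) -> int:
    """Map a ClinVar review-status phrase onto the 0-3 star scale."""
    key = " ".join(str(status).strip().lower().replace("_", " ").split())
    if key not in _STAR_MAP:
        logger.warning("unknown ClinVar review status %r mapped to 0 stars", status)
        return 0
    return _STAR_MAP[key]


def annotate_stars(df: pd.DataFrame) -> pd.DataFrame:
    """Derive ``clinvar_stars`` from ``clinvar_review_status`` where absent."""
    out = df.copy()
    if "clinvar_review_status" not in out.columns:
        return out
    has_status = out["clinvar_review_status"].notna()
    stars = out["clinvar_review_status"][has_status].map(map_review_status_to_stars)
    if "clinvar_stars" not in out.columns:
        out["clinvar_stars"] = pd.array([pd.NA] * len(out), dtype="Int64")
    fill = has_status & out["clinvar_stars"].isna()
    out.loc[fill, "clinvar_stars"] = stars[fill]
    out["clinvar_stars"] = out["clinvar_stars"].astype("Int64")
    return out
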