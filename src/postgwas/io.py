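"""Readers and writers for every flat file the pipeline touches.

Formats (all whitespace/tab separated, header required, 1-based inclusive
coordinates):

* GWAS summary statistics, COJO ``.ma`` dialect:
  ``SNP A1 A2 freq b se p N``
* cis-QTL flat table:
  ``probe_id probe_chr probe_bp gene_id SNP snp_chr snp_bp A1 A2 freq b se p N``
* genotype panel: one row per individual, dosages in {0,1,2}, with a
  sidecar SNP map ``<panel>.snps`` holding ``SNP chr bp A1 A2``
* probe/gene annotation: ``id chr start end strand class``
* gene lists: one symbol per line
* drug-gene interaction table:
  ``drug_id gene interaction_type indication adverse_bp``

Validation is strict: rows violating record invariants are rejected with
their line numbers logged, malformed headers raise :class:`FormatError`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synth import Genotypes

log = logging.getLogger(__name__)

GWAS_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
QTL_COLUMNS = [
    "probe_id", "probe_chr", "probe_bp", "gene_id",
    "SNP", "snp_chr", "snp_bp", "A1", "A2", "freq", "b", "se", "p", "N",
]
ANNOTATION_COLUMNS = ["id", "chr", "start", "end", "strand", "class"]
DRUG_COLUMNS = ["drug_id", "gene", "interaction_type", "indication", "adverse_bp"]

#: strand-ambiguous allele pairs dropped during harmonization when the
#: frequency is uninformative
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
AMBIGUOUS_FREQ_WINDOW = 0.15


class FormatError(ValueError):
    """A file does not conform to its declared schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def _validate_assoc(df: pd.DataFrame, path) -> pd.DataFrame:
    """Reject rows violating association-record invariants; log line numbers."""
    num = df[["freq", "b", "se", "p", "N"]].apply(pd.to_numeric, errors="coerce")
    ok = (
        num.notna().all(axis=1)
        & (num["se"] > 0)
        & (num["freq"] > 0)
        & (num["freq"] < 1)
        & (num["p"] > 0)
        & (num["p"] <= 1)
        & (num["N"] > 0)
    )
    if not ok.all():
        bad = df.index[~ok] + 2  # 1-based with header line
        log.warning("%s: rejected %d invalid row(s) at line(s) %s", path, (~ok).sum(),
                    list(bad[:20]))
    out = df[ok].copy()
    for c in ("freq", "b", "se", "p"):
        out[c] = pd.to_numeric(out[c])
    out["N"] = pd.to_numeric(out["N"]).astype(int)
    out["z"] = out["b"] / out["se"]
    return out.reset_index(drop=True)


def read_gwas(path) -> pd.DataFrame:
    """Read a COJO-.ma GWAS summary file into a validated table with a
    derived ``z`` column (``n`` aliased to the file's ``N``)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    _require_columns(df, GWAS_COLUMNS, path)
    out = _validate_assoc(df, path)
    out = out.rename(columns={"N": "n"})
    return out


def write_gwas(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "n" in out.columns and "N" not in out.columns:
        out = out.rename(columns={"n": "N"})
    out[GWAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qtl(path) -> pd.DataFrame:
    """Read a flat cis-QTL table (one row per probe x SNP)."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    _require_columns(df, QTL_COLUMNS, path)
    out = _validate_assoc(df, path)
    for c in ("probe_bp", "snp_bp", "probe_chr", "snp_chr"):
        out[c] = pd.to_numeric(out[c]).astype(int)
    return out.rename(columns={"N": "n"})


def write_qtl(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "n" in out.columns and "N" not in out.columns:
        out = out.rename(columns={"n": "N"})
    out[QTL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(path) -> Genotypes:
    """Read a genotype panel plus its ``.snps`` sidecar map."""
    path = Path(path)
    mat = np.loadtxt(path, dtype=np.int8, ndmin=2)
    bad = ~np.isin(mat, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(f"{path}: non-{{0,1,2}} dosage at row {i + 1}, column {j + 1}")
    snps = pd.read_csv(path.with_suffix(path.suffix + ".snps"), sep=r"\s+")
    _require_columns(snps, ["SNP", "chr", "bp", "A1", "A2"], path)
    if len(snps) != mat.shape[1]:
        raise FormatError(f"{path}: SNP map has {len(snps)} rows for {mat.shape[1]} columns")
    if "maf" not in snps.columns:
        freq = mat.mean(axis=0) / 2.0
        snps["maf"] = np.minimum(freq, 1 - freq)
    return Genotypes(matrix=mat, snps=snps)


def write_panel(genotypes: Genotypes, path) -> None:
    path = Path(path)
    np.savetxt(path, genotypes.matrix, fmt="%d")
    cols = [c for c in ("SNP", "chr", "bp", "A1", "A2", "maf") if c in genotypes.snps.columns]
    genotypes.snps[cols].to_csv(path.with_suffix(path.suffix + ".snps"), sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    _require_columns(df, ANNOTATION_COLUMNS, path)
    if (df["start"] > df["end"]).any():
        raise FormatError(f"{path}: start > end in annotation")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """Plain gene-symbol list, one per line; empty file -> empty list."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_drug_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    _require_columns(df, DRUG_COLUMNS, path)
    bad = ~df["indication"].isin(["hypertension", "hypotension", "other"])
    if bad.any():
        raise FormatError(f"{path}: invalid indication value(s) {df['indication'][bad].unique()}")
    return df


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# Aliases matching field-standard result-table verbs
write_results = write_table
read_results = read_table


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def recompute_p(df: pd.DataFrame) -> pd.DataFrame:
    """Fill/refresh p from z where absent or inconsistent."""
    df = df.copy()
    pz = 2.0 * stats.norm.sf(np.abs(df["b"] / df["se"]))
    if "p" not in df.columns:
        df["p"] = pz
    else:
        missing = df["p"].isna()
        df.loc[missing, "p"] = pz[missing]
    return df


def harmonize_alleles(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two association tables on SNP id and allele coding.

    The first table defines the reference coding.  For each shared SNP:

    * same A1/A2 -> kept as-is;
    * swapped A1/A2 -> second table's ``b`` (and ``z``) sign-flipped and
      ``freq`` replaced by 1-freq;
    * strand-ambiguous pair (A/T or C/G) with |freq-0.5| < 0.15 in either
      source -> dropped (frequency cannot arbitrate strand);
    * irreconcilable allele sets -> dropped.

    Drops are logged, never raised.  The operation is involutive: applying
    it to its own output changes nothing.
    """
    merged = a.merge(
        b, on="SNP", suffixes=("_a", "_b"),
    )
    if merged.empty:
        return a.iloc[0:0].copy(), b.iloc[0:0].copy()
    same = (merged["A1_a"] == merged["A1_b"]) & (merged["A2_a"] == merged["A2_b"])
    swapped = (merged["A1_a"] == merged["A2_b"]) & (merged["A2_a"] == merged["A1_b"])
    amb_pair = np.array(
        [tuple(x) in AMBIGUOUS_PAIRS for x in merged[["A1_a", "A2_a"]].to_numpy()]
    )
    ambiguous = amb_pair & (
        (np.abs(merged["freq_a"] - 0.5) < AMBIGUOUS_FREQ_WINDOW)
        | (np.abs(merged["freq_b"] - 0.5) < AMBIGUOUS_FREQ_WINDOW)
    ).to_numpy()
    keep = (same | swapped).to_numpy() & ~ambiguous
    dropped = int((~keep).sum())
    if dropped:
        log.info("harmonize_alleles: dropped %d SNP(s) (ambiguous or irreconcilable)", dropped)
    merged = merged[keep].reset_index(drop=True)
    flip = swapped.to_numpy()[keep]

    def split(side: str, flip_side: bool) -> pd.DataFrame:
        cols = {}
        for c in a.columns if side == "a" else b.columns:
            key = f"{c}_{side}" if f"{c}_{side}" in merged.columns else c
            cols[c] = merged[key].to_numpy()
        out = pd.DataFrame(cols)
        if flip_side and flip.any():
            out.loc[flip, "b"] = -out.loc[flip, "b"]
            if "z" in out.columns:
                out.loc[flip, "z"] = -out.loc[flip, "z"]
            out.loc[flip, "freq"] = 1.0 - out.loc[flip, "freq"]
            out.loc[flip, "A1"] = merged["A1_a"][flip].to_numpy()
            out.loc[flip, "A2"] = merged["A2_a"][flip].to_numpy()
        return out.reset_index(drop=True)

    return split("a", False), split("b", True)
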