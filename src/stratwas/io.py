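"""Readers and writers for the pipeline's file formats.

Formats: summary-statistics TSV (CHR, POS, A1, A2, FREQ_A1, BETA, SE, P,
N_CASES, N_CONTROLS, IS_PROXY; 1-based positions), weight TSV, LD matrix
TSV, counts TSV (genes x samples), covariates TSV, BED (0-based half-open,
column 4 = cell-type label), GMT, interaction edge list, druggable-gene
list, truth-table TSV. Schema violations raise :class:`SchemaError` naming
file, line and column; P = 0 is clamped to the smallest positive double
with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .twas import WeightSet

log = logging.getLogger(__name__)

SUMSTATS_COLS = ["CHR", "POS", "A1", "A2", "FREQ_A1", "BETA", "SE", "P",
                 "N_CASES", "N_CONTROLS", "IS_PROXY"]
WEIGHT_COLS = ["GENE", "CELL_TYPE", "CHR", "POS", "A1", "A2", "WEIGHT", "MODEL", "H2P", "TSS"]


class SchemaError(ValueError):
    """A file violated its schema; message names file, line and column."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring unknown column(s) %s", path, extra)


# ---------------------------------------------------------------------------
# summary statistics

def write_sumstats(stats: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "CHR": stats.chrom, "POS": stats.pos, "A1": stats.a1, "A2": stats.a2,
        "FREQ_A1": stats.freq, "BETA": stats.beta, "SE": stats.se, "P": stats.p,
        "N_CASES": stats.n_cases, "N_CONTROLS": stats.n_controls,
        "IS_PROXY": stats.is_proxy.astype(int) if hasattr(stats.is_proxy, "astype")
        else int(stats.is_proxy),
    })
    out.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SUMSTATS_COLS, path)
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if not (0 < row.FREQ_A1 < 1):
            raise SchemaError(f"{path}:{line}: column FREQ_A1 out of (0,1): {row.FREQ_A1}")
        if row.SE <= 0 and np.isfinite(row.SE):
            raise SchemaError(f"{path}:{line}: column SE must be > 0, got {row.SE}")
        if np.isfinite(row.P) and not (0 <= row.P <= 1):
            raise SchemaError(f"{path}:{line}: column P out of [0,1]: {row.P}")
        if row.POS <= 0:
            raise SchemaError(f"{path}:{line}: column POS must be 1-based positive")
    zero_p = df.P == 0
    if zero_p.any():
        log.warning("%s: %d rows with P=0 clamped to smallest positive double",
                    path, int(zero_p.sum()))
        df.loc[zero_p, "P"] = np.finfo(float).tiny
    out = pd.DataFrame({
        "variant": df.CHR.astype(str) + ":" + df.POS.astype(str),
        "chrom": df.CHR, "pos": df.POS, "a1": df.A1, "a2": df.A2, "freq": df.FREQ_A1,
        "beta": df.BETA, "se": df.SE, "z": df.BETA / df.SE, "p": df.P,
        "n_cases": df.N_CASES, "n_controls": df.N_CONTROLS,
        "is_proxy": df.IS_PROXY.astype(bool), "genotyping_rate": 1.0,
    })
    return out


# ---------------------------------------------------------------------------
# weights

def write_weights(weight_sets: list[WeightSet], path,
                  variants: pd.DataFrame | None = None) -> None:
    alleles = {}
    if variants is not None:
        alleles = {v: (a1, a2) for v, a1, a2 in zip(variants.variant, variants.a1,
                                                    variants.a2)}
    rows = []
    for w in weight_sets:
        for v, wt in zip(w.variants, w.weights):
            chrom, pos = v.split(":")
            a1, a2 = alleles.get(v, ("N", "N"))
            rows.append((w.gene, w.cell_type, int(chrom), int(pos), a1, a2,
                         wt, w.model_tag, w.h2_p, w.tss))
    pd.DataFrame(rows, columns=WEIGHT_COLS).to_csv(path, sep="\t", index=False)


def read_weights(path) -> list[WeightSet]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, WEIGHT_COLS, path)
    out = []
    for (gene, ct), grp in df.groupby(["GENE", "CELL_TYPE"], sort=False):
        variants = [f"{c}:{p}" for c, p in zip(grp.CHR, grp.POS)]
        h2p = float(grp.H2P.iloc[0])
        if not (0 < h2p <= 1):
            raise SchemaError(f"{path}: gene {gene}: column H2P out of (0,1]: {h2p}")
        out.append(WeightSet(gene=gene, cell_type=ct, chrom=int(grp.CHR.iloc[0]),
                             tss=int(grp.TSS.iloc[0]), variants=variants,
                             weights=grp.WEIGHT.to_numpy(float), h2_p=h2p,
                             model_tag=str(grp.MODEL.iloc[0])))
    return out


# ---------------------------------------------------------------------------
# LD, counts, covariates

def write_ld(ld: pd.DataFrame, path) -> None:
    ld.to_csv(path, sep="\t")


def read_ld(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SchemaError(f"{path}: LD matrix must be square, got {df.shape}")
    if not np.allclose(np.diag(df.to_numpy(float)), 1.0, atol=1e-6):
        raise SchemaError(f"{path}: LD matrix diagonal must be 1")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="GENE")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="GENE")
    vals = df.to_numpy()
    if (vals < 0).any():
        raise SchemaError(f"{path}: negative counts present")
    return df


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="SAMPLE")


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="SAMPLE")


# ---------------------------------------------------------------------------
# BED

def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", index=False,
                                                    header=False)


def read_bed(path) -> pd.DataFrame:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("track", "browser", "#")):
                continue
            parts = raw.split("\t")
            if len(parts) < 4:
                raise SchemaError(f"{path}:{i}: BED needs >=4 columns, got {len(parts)}")
            try:
                chrom = int(parts[0].removeprefix("chr"))
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise SchemaError(f"{path}:{i}: non-numeric coordinate: {exc}") from exc
            if start < 0:
                raise SchemaError(f"{path}:{i}: column start must be >= 0")
            if start >= end:
                raise SchemaError(f"{path}:{i}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end, parts[3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# GMT, edges, druggable

def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    path = Path(path)
    sets = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{i}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_a", "gene_b", "source"], path)
    return df


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path) -> list[str]:
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


# ---------------------------------------------------------------------------
# truth table

def write_truth(truth, path) -> None:
    t = truth.table.copy()
    t["eqtl_variants"] = [";".join(f"{v}:{w:.10g}" for v, w in truth.weights[g])
                          for g in t.gene]
    t.to_csv(path, sep="\t", index=False)


def read_truth(path):
    from .simulate import TruthTable
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "cell_type", "locus", "chrom", "tss",
                          "causal_stratum", "beta_liability", "eqtl_variants"], path)
    weights = {}
    for _, row in df.iterrows():
        pairs = []
        for item in str(row.eqtl_variants).split(";"):
            v, w = item.rsplit(":", 1)
            pairs.append((v, float(w)))
        weights[row.gene] = pairs
    truth = TruthTable(table=df.drop(columns="eqtl_variants"), weights=weights)
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# eQTL marginal statistics (cis slices used by coloc and SMR)

def write_eqtl_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_eqtl_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene", "cell_type", "variant", "beta", "se", "p", "n"], path)
    return df
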