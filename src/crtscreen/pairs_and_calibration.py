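"""Candidate-pair construction, calibration diagnostics, and discovery calling.

Candidate *cis* pairs link each protein-coding gene to every
candidate-enhancer gRNA targeting within 1 Mb of its TSS (inclusive).
In-silico negative-control pairs are built from gRNAs far from any
transcription factor TSS, paired with non-TF genes on other
chromosomes and downsampled to a fixed number of genes per gRNA; under
the no-regulation null their p-values should be uniform, which the KS
diagnostic checks (with Bonferroni flagging across groups). Discoveries
are called by Benjamini-Hochberg at a target FDR over the candidate
pairs alone — mixing positive controls into the BH family is known to
be anticonservative, so they are excluded.

Coordinates are 0-based; a gRNA's target site is represented by its
interval midpoint and distances are |midpoint - TSS|, strand ignored.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("crtscreen")

CIS_WINDOW = 1_000_000
NEG_MIN_DISTANCE = 1_000_000
GENES_PER_GRNA = 500

GENE_COLUMNS = ["id", "chrom", "position", "protein_coding", "is_tf"]
GRNA_COLUMNS = ["id", "chrom", "position", "targeting_class"]


# ---------------------------------------------------------------------------
# Coordinate ingestion
# ---------------------------------------------------------------------------

def gene_coordinates(frame: pd.DataFrame) -> pd.DataFrame:
    """Normalize a gene TSS table to [id, chrom, position, protein_coding, is_tf].

    Accepts the TSV layout (gene_id, chrom, tss, is_protein_coding,
    is_tf) or an already-normalized frame.
    """
    df = frame.copy()
    df = df.rename(
        columns={"gene_id": "id", "tss": "position", "is_protein_coding": "protein_coding"}
    )
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene coordinate table missing columns: {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    if (df["position"] < 0).any():
        raise ValueError("gene positions must be nonnegative")
    if df["id"].duplicated().any():
        raise ValueError("duplicate gene IDs")
    return df[GENE_COLUMNS]


def grna_coordinates(frame: pd.DataFrame) -> pd.DataFrame:
    """Normalize a gRNA site table to [id, chrom, position, targeting_class].

    Accepts (grna_id, chrom, start, end, class); the target site becomes
    the interval midpoint (integer division). ``targeting_class`` is one
    of candidate_enhancer | non_targeting | tss_control.
    """
    df = frame.copy()
    df = df.rename(columns={"grna_id": "id", "class": "targeting_class"})
    if "position" not in df.columns:
        if not {"start", "end"}.issubset(df.columns):
            raise ValueError("gRNA table needs either position or start/end columns")
        df["position"] = (df["start"].astype(int) + df["end"].astype(int)) // 2
    missing = set(GRNA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gRNA coordinate table missing columns: {sorted(missing)}")
    df["position"] = df["position"].astype(int)
    if (df["position"] < 0).any():
        raise ValueError("gRNA positions must be nonnegative")
    if df["id"].duplicated().any():
        raise ValueError("duplicate gRNA IDs")
    return df[GRNA_COLUMNS]


def read_bed6(path: str) -> pd.DataFrame:
    """Read a BED6 file into (id, chrom, start, end) with 0-based half-open intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "id", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
    )
    return df[["id", "chrom", "start", "end"]]


def _check_chromosomes(genes: pd.DataFrame, grnas: pd.DataFrame) -> None:
    offenders = sorted(set(grnas["chrom"]) - set(genes["chrom"]))
    if offenders:
        raise ValueError(
            f"gRNA chromosome names not found among gene chromosomes: {offenders}; "
            "check naming conventions (e.g. 'chr1' vs '1')"
        )


# ---------------------------------------------------------------------------
# Pair-set construction
# ---------------------------------------------------------------------------

def make_cis_pairs(genes: pd.DataFrame, grnas: pd.DataFrame, window: int = CIS_WINDOW) -> pd.DataFrame:
    """All (protein-coding gene, candidate-enhancer gRNA) pairs within ``window`` of the TSS.

    Same chromosome, |site - TSS| <= window (inclusive at the boundary).
    Output is deterministic: sorted by (gene_id, grna_id).
    """
    genes = gene_coordinates(genes)
    grnas = grna_coordinates(grnas)
    _check_chromosomes(genes, grnas)
    g = genes[genes["protein_coding"].astype(bool)]
    r = grnas[grnas["targeting_class"] == "candidate_enhancer"]
    merged = g.merge(r, on="chrom", suffixes=("_gene", "_grna"))
    merged = merged[(merged["position_grna"] - merged["position_gene"]).abs() <= window]
    out = pd.DataFrame(
        {
            "gene_id": merged["id_gene"],
            "grna_id": merged["id_grna"],
            "pair_type": "cis_candidate",
        }
    ).sort_values(["gene_id", "grna_id"], ignore_index=True)
    if out.duplicated(["gene_id", "grna_id"]).any():
        raise ValueError("duplicate (gene, gRNA) pairs produced; check input IDs")
    return out


def make_insilico_negative_pairs(
    genes: pd.DataFrame,
    grnas: pd.DataFrame,
    tf_gene_ids: Iterable[str],
    min_distance: int = NEG_MIN_DISTANCE,
    genes_per_grna: int = GENES_PER_GRNA,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-control pairs: TF-distal gRNAs x trans-chromosomal non-TF genes.

    A gRNA is eligible only if every transcription-factor TSS on its
    chromosome lies strictly more than ``min_distance`` away. Each
    eligible gRNA is paired with genes on *other* chromosomes (TF genes
    excluded) and the pairs are downsampled uniformly at random to
    ``genes_per_grna`` genes per gRNA under the given seed.
    """
    genes = gene_coordinates(genes)
    grnas = grna_coordinates(grnas)
    _check_chromosomes(genes, grnas)
    tf_ids = set(tf_gene_ids)
    unknown = tf_ids - set(genes["id"])
    if unknown:
        raise ValueError(f"TF gene IDs not in gene table: {sorted(unknown)[:5]}")

    tf = genes[genes["id"].isin(tf_ids)]
    eligible = []
    for _, row in grnas.iterrows():
        near = tf[tf["chrom"] == row["chrom"]]
        if near.empty or (near["position"] - row["position"]).abs().min() > min_distance:
            eligible.append(row)
    logger.info("%d of %d gRNAs eligible as in-silico negative controls", len(eligible), len(grnas))

    candidates = genes[~genes["id"].isin(tf_ids)]
    rng = np.random.default_rng(seed)
    rows = []
    for row in eligible:
        pool = candidates.loc[candidates["chrom"] != row["chrom"], "id"].to_numpy()
        pool = np.sort(pool)  # seed-stable regardless of input order
        if pool.size <= genes_per_grna:
            if pool.size < genes_per_grna:
                logger.warning(
                    "gRNA %s: only %d eligible genes (< cap %d); keeping all",
                    row["id"], pool.size, genes_per_grna,
                )
            chosen = pool
        else:
            chosen = rng.choice(pool, size=genes_per_grna, replace=False)
        rows.extend((gene, row["id"]) for gene in chosen)
    out = pd.DataFrame(rows, columns=["gene_id", "grna_id"])
    out["pair_type"] = "neg_control"
    return out.sort_values(["grna_id", "gene_id"], ignore_index=True)


def write_pairs_tsv(pairs: pd.DataFrame, path: str) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Calibration diagnostics and discovery calling
# ---------------------------------------------------------------------------

def ks_uniformity(p_values) -> tuple[float, float]:
    """One-sample KS statistic and p-value of the p-values against Uniform(0,1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 5:
        raise ValueError("need at least 5 p-values for the KS diagnostic")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    res = scipy.stats.kstest(p, "uniform")
    return float(res.statistic), float(res.pvalue)


def flag_miscalibrated(ks_pvalues, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni flagger: group g is flagged when its KS p-value < alpha / G."""
    ks = np.asarray(ks_pvalues, dtype=float)
    return ks < alpha / ks.size


def bh_discoveries(p_values, fdr: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at the target FDR.

    Apply to the candidate pair family only; folding positive controls
    into the family inflates the effective FDR.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject
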