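"""Post-hoc screens on per-gene result tables.

Three curation steps consumed from upstream selection and expression
scans (the codon-model fits and the DESeq2 model itself are upstream;
only their stated thresholds are applied here):

* free-ratio dN/dS curation — drop genes with implausible estimates;
* positively-selected-gene (PSG) intersection — a gene must pass both
  the branch-site test (LRT FDR < 0.05 with a BEB site posterior
  > 0.95) and the BUSTED-MH test (LRT FDR < 0.05);
* differentially-expressed-gene (DEG) thresholds per brain region, with
  a cross-region direction summary.

All filters are pure, idempotent functions of their input tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError, ValidationError

REGIONS = ("FB", "MB", "HB")

DNDS_COLUMNS = ["gene", "dN", "dS", "N", "S_sites", "sequence_length"]
PSG_COLUMNS = ["gene", "lrt_fdr_paml", "beb_max_posterior", "lrt_fdr_hyphy"]
DEG_COLUMNS = ["gene", "region", "fdr", "basemean", "log2fc"]


def _require(df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")


@dataclass
class DndsCuration:
    kept: pd.DataFrame
    removed: pd.DataFrame      # with a 'reasons' column
    mean_dnds: float | None    # mean dN/dS of the kept genes


def curate_dnds(records: pd.DataFrame) -> DndsCuration:
    """Free-ratio dN/dS curation.

    A gene is removed iff any of: dS > 1; N > sequence_length;
    N + S_sites >= sequence_length + 50; N*dN < 1; S_sites*dS < 1.
    Every removed gene carries the full list of reasons that applied.
    """
    _require(records, DNDS_COLUMNS)
    df = records.copy()
    reasons = {
        "dS>1": df["dS"] > 1,
        "N>length": df["N"] > df["sequence_length"],
        "N+S>=length+50": df["N"] + df["S_sites"] >= df["sequence_length"] + 50,
        "N*dN<1": df["N"] * df["dN"] < 1,
        "S*dS<1": df["S_sites"] * df["dS"] < 1,
    }
    remove = np.zeros(len(df), dtype=bool)
    for mask in reasons.values():
        remove |= mask.to_numpy(dtype=bool)
    reason_col = [
        ";".join(name for name, mask in reasons.items() if bool(mask.iloc[i]))
        for i in range(len(df))
    ]
    removed = df.loc[remove].copy()
    removed["reasons"] = [r for r, keep in zip(reason_col, remove) if keep]
    kept = df.loc[~remove].copy()
    if len(kept):
        mean_dnds = float((kept["dN"] / kept["dS"]).mean())
    else:
        mean_dnds = None
    return DndsCuration(kept=kept.reset_index(drop=True),
                        removed=removed.reset_index(drop=True),
                        mean_dnds=mean_dnds)


def intersect_psgs(records: pd.DataFrame) -> pd.DataFrame:
    """Final positively selected genes: significant in both frameworks.

    Kept iff lrt_fdr_paml < 0.05 AND beb_max_posterior > 0.95 AND
    lrt_fdr_hyphy < 0.05 (strict inequalities).  Output sorted by gene.
    """
    _require(records, PSG_COLUMNS)
    if records["gene"].duplicated().any():
        dupes = sorted(records.loc[records["gene"].duplicated(), "gene"])
        raise ValidationError(f"duplicate gene id(s): {dupes}")
    for col in ("lrt_fdr_paml", "beb_max_posterior", "lrt_fdr_hyphy"):
        vals = records[col]
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError(f"{col} outside [0, 1]")
    keep = (
        (records["lrt_fdr_paml"] < 0.05)
        & (records["beb_max_posterior"] > 0.95)
        & (records["lrt_fdr_hyphy"] < 0.05)
    )
    return records.loc[keep].sort_values("gene").reset_index(drop=True)


@dataclass
class DegSummary:
    kept: pd.DataFrame                 # with a 'direction' column
    per_region: dict[str, dict[str, int]]   # region -> {total, up, down}


def filter_degs(records: pd.DataFrame) -> DegSummary:
    """Differential-expression thresholds, applied per region.

    Kept iff fdr <= 0.05 AND basemean >= 10 AND |log2fc| >= 0.3
    (inclusive boundaries; the effect size is read as an absolute value
    since both up- and downregulated genes qualify).
    """
    _require(records, DEG_COLUMNS)
    unknown = set(records["region"]) - set(REGIONS)
    if unknown:
        raise ValidationError(f"unknown region label(s): {sorted(unknown)}")
    keep = (
        (records["fdr"] <= 0.05)
        & (records["basemean"] >= 10)
        & (records["log2fc"].abs() >= 0.3)
    )
    kept = records.loc[keep].copy()
    kept["direction"] = np.where(kept["log2fc"] >= 0, "up", "down")
    per_region = {}
    for region in REGIONS:
        sub = kept.loc[kept["region"] == region]
        per_region[region] = {
            "total": int(len(sub)),
            "up": int((sub["direction"] == "up").sum()),
            "down": int((sub["direction"] == "down").sum()),
        }
    return DegSummary(kept=kept.reset_index(drop=True), per_region=per_region)


@dataclass
class DirectionSummary:
    n_degs: int                       # union across regions
    n_down_where_deg: int             # down in every region where it is a DEG
    fraction_down_where_deg: float | None
    n_deg_all_regions: int            # DEG in every region
    n_down_all_regions: int           # DEG in every region and down in all
    fraction_down_all_regions: float | None


def summarize_deg_direction(deg_lists: dict[str, pd.DataFrame]
                            ) -> DirectionSummary:
    """Cross-region direction consistency of the DEG union.

    Reports two operationalisations of "reduced expression across all
    regions": down in every region where the gene is a DEG (the lenient
    reading), and DEG-and-down in every region supplied (the strict
    one).  Fractions are None ("n/a") when their denominator is zero.
    """
    if not deg_lists:
        raise ValidationError("need at least one region's DEG list")
    directions: dict[str, list[str]] = {}
    for region, df in deg_lists.items():
        _require(df, ["gene", "log2fc"])
        for _, row in df.iterrows():
            d = "down" if row["log2fc"] < 0 else "up"
            directions.setdefault(row["gene"], []).append(d)
    n_union = len(directions)
    n_down_lenient = sum(1 for ds in directions.values()
                         if all(d == "down" for d in ds))
    n_regions = len(deg_lists)
    all_region_genes = [g for g, ds in directions.items()
                        if len(ds) == n_regions]
    n_down_strict = sum(1 for g in all_region_genes
                        if all(d == "down" for d in directions[g]))
    return DirectionSummary(
        n_degs=n_union,
        n_down_where_deg=n_down_lenient,
        fraction_down_where_deg=(n_down_lenient / n_union
                                 if n_union else None),
        n_deg_all_regions=len(all_region_genes),
        n_down_all_regions=n_down_strict,
        fraction_down_all_regions=(n_down_strict / len(all_region_genes)
                                   if all_region_genes else None),
    )
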