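"""Gene-centric nitrogen accounting for a layered metagenome.

Extracts nitrogen-metabolism genes from a KO-annotated catalog, computes two
normalizations of per-layer gene coverage, and summarizes the pathway
inventory:

* **N-CPM** (nitrogen-focused coverage per million): a gene's coverage in a
  layer as parts-per-million of the summed coverage of *nitrogen-pathway*
  genes in that layer. Layer sums are exactly 1e6 by construction.
* **FDIC** (fraction of depth-integrated coverage): a gene's per-layer share
  of its own coverage summed across layers. Rows sum to 1; genes with zero
  coverage everywhere are reported separately.

Coverage input is taken as already length-normalized per gene; no length
correction is applied here.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Packaged nitrogen-metabolism KO vocabulary: KO -> (gene symbol, pathway
# category). Symbols sharing a KO model keep the combined symbol (nitrate
# reductase / nitrite oxidoreductase subunits cannot be separated by KO).
NITROGEN_KO_MAP: dict[str, tuple[str, str]] = {
    "K02586": ("nifD", "nitrogen fixation"),
    "K02588": ("nifH", "nitrogen fixation"),
    "K02591": ("nifK", "nitrogen fixation"),
    "K10535": ("hao", "hydroxylamine dehydrogenase"),
    "K05601": ("hcp", "hydroxylamine reductase"),
    "K00370": ("narG/narZ/nxrA", "denitrification"),
    "K00371": ("narH/narY/nxrB", "denitrification"),
    "K00374": ("narI/narV", "denitrification"),
    "K02567": ("napA", "denitrification"),
    "K02568": ("napB", "denitrification"),
    "K00368": ("nirK", "denitrification"),
    "K15864": ("nirS", "denitrification"),
    "K04561": ("norB", "denitrification"),
    "K02305": ("norC", "denitrification"),
    "K00376": ("nosZ", "denitrification"),
    "K03385": ("nrfA", "DNRA"),
    "K15876": ("nrfH", "DNRA"),
    "K00366": ("nirA", "assimilatory nitrate reduction"),
    "K00367": ("narB", "assimilatory nitrate reduction"),
    "K02575": ("NRT", "assimilatory nitrate reduction"),
}

CATEGORIES = (
    "nitrogen fixation",
    "assimilatory nitrate reduction",
    "DNRA",
    "hydroxylamine dehydrogenase",
    "hydroxylamine reductase",
    "denitrification",
)

# Gamma-subunit nitrate reductase genes participate in DNRA as well but are
# counted once, under denitrification, so that categories partition the set.
SHARED_WITH_DNRA = ("narI/narV",)

_KO_RE = re.compile(r"^K\d{5}$")


@dataclass
class PathwaySummary:
    """Unique-gene counts per symbol, per category, and overall."""

    per_symbol: dict[str, int]
    per_category: dict[str, int]
    total: int
    shared_note: str = (
        "narI/narV genes act in both denitrification and DNRA; "
        "counted once under denitrification."
    )


def filter_nitrogen_genes(annotations: pd.DataFrame, ko_map=None) -> pd.DataFrame:
    """Keep only genes whose KO is in the nitrogen vocabulary.

    Returns the annotation rows with ``symbol`` and ``category`` (re)assigned
    from the packaged map. Rows with malformed KO strings are dropped with a
    warning.
    """
    ko_map = NITROGEN_KO_MAP if ko_map is None else ko_map
    if "ko" not in annotations.columns:
        raise ValueError("annotation table must have a 'ko' column")
    ko = annotations["ko"].astype(str)
    malformed = ~ko.map(lambda k: bool(_KO_RE.match(k)))
    if malformed.any():
        warnings.warn(
            f"dropping {int(malformed.sum())} row(s) with malformed KO ids "
            f"(e.g. {ko[malformed].iloc[0]!r})"
        )
    keep = annotations.loc[~malformed & ko.isin(ko_map)].copy()
    keep["symbol"] = keep["ko"].map(lambda k: ko_map[k][0])
    keep["category"] = keep["ko"].map(lambda k: ko_map[k][1])
    return keep.reset_index(drop=True)


def compute_ncpm(
    coverage: pd.DataFrame,
    nitrogen_genes: pd.DataFrame,
    denominator: str = "nitrogen",
) -> pd.DataFrame:
    """Per-layer parts-per-million normalization of gene coverage.

    ``denominator='nitrogen'`` (default) divides by the summed coverage of
    nitrogen-pathway genes only; ``'all'`` divides by the summed coverage of
    every gene in the coverage table.
    """
    if denominator not in ("nitrogen", "all"):
        raise ValueError("denominator must be 'nitrogen' or 'all'")
    nit_ids = set(nitrogen_genes["gene_id"])
    sub = coverage[coverage["gene_id"].isin(nit_ids)].copy()
    denom_src = coverage if denominator == "all" else sub
    totals = denom_src.groupby("layer")["coverage"].sum()
    zero_layers = totals.index[totals == 0].tolist()
    if zero_layers:
        raise ValueError(f"zero total nitrogen coverage in layer(s) {zero_layers}")
    sub["ncpm"] = sub["coverage"] / sub["layer"].map(totals) * 1e6
    return sub[["gene_id", "layer", "ncpm"]].reset_index(drop=True)


def compute_fdic(table: pd.DataFrame, value_col: str = "ncpm"):
    """Fraction of depth-integrated coverage per gene.

    Returns ``(fdic_table, all_zero_gene_ids)``: genes whose value is zero in
    every layer have no defined depth profile and are listed separately.
    """
    if value_col not in table.columns:
        raise ValueError(f"column {value_col!r} not in table")
    totals = table.groupby("gene_id")[value_col].sum()
    all_zero = sorted(totals.index[totals == 0].tolist())
    sub = table[~table["gene_id"].isin(all_zero)].copy()
    sub["fdic"] = sub[value_col] / sub["gene_id"].map(totals)
    return sub[["gene_id", "layer", "fdic"]].reset_index(drop=True), all_zero


def pathway_summary(nitrogen_genes: pd.DataFrame) -> PathwaySummary:
    """Count unique genes per symbol and per category.

    Categories partition the gene set, so the overall total equals the sum of
    category counts and each category count equals the sum of its symbols'.
    """
    if nitrogen_genes["category"].isna().any():
        bad = nitrogen_genes.loc[nitrogen_genes["category"].isna(), "gene_id"].tolist()
        raise ValueError(f"gene(s) without category: {bad}")
    dedup = nitrogen_genes.drop_duplicates("gene_id")
    per_symbol = dedup.groupby("symbol")["gene_id"].nunique().to_dict()
    per_category = dedup.groupby("category")["gene_id"].nunique().to_dict()
    return PathwaySummary(
        per_symbol=per_symbol,
        per_category=per_category,
        total=int(dedup["gene_id"].nunique()),
    )


def depth_trend(
    ncpm: pd.DataFrame,
    selection,
    layer_a: int,
    layer_b: int,
    flat_tol: float = 0.05,
    value_col: str = "ncpm",
):
    """Fold change of mean normalized coverage between two layers.

    ``selection`` is a list of gene_ids. Fold = mean over the selected genes
    at ``layer_a`` / mean at ``layer_b``; with ``layer_a`` the shallower
    layer, fold > 1 means the signal decreases with depth. Returns
    ``(fold, direction)`` with direction in {'decreasing', 'increasing',
    'flat'} at the given flat tolerance.
    """
    sub = ncpm[ncpm["gene_id"].isin(set(selection))]
    for layer in (layer_a, layer_b):
        if not (sub["layer"] == layer).any():
            raise ValueError(f"layer {layer} not present for selected genes")
    mean_a = sub.loc[sub["layer"] == layer_a, value_col].mean()
    mean_b = sub.loc[sub["layer"] == layer_b, value_col].mean()
    if mean_b == 0:
        return np.inf, "decreasing"
    fold = mean_a / mean_b
    if fold > 1 + flat_tol:
        direction = "decreasing"
    elif fold < 1 / (1 + flat_tol):
        direction = "increasing"
    else:
        direction = "flat"
    return float(fold), direction
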