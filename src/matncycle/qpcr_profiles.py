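"""qPCR/RT-qPCR depth profiling: dual normalization, expression ratios, and
nonparametric layer statistics.

Copy numbers are normalized both per gram of mat and per nanogram of nucleic
acid (extraction efficiency differs between bases, so both are carried).
The cDNA/DNA ratio of a marker in a layer is used as a transcription proxy.
Layer differences are tested with Kruskal-Wallis followed by the
Conover-Iman post hoc on ranks, summarized as a compact letter display:
layers sharing a letter are not significantly different pairwise.

Below-detection-limit records are flagged upstream and excluded from
statistics here (no LOD/2 substitution is applied).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LayerTestResult:
    marker: str
    H: float
    p_global: float
    pairwise_p: pd.DataFrame  # symmetric, unit diagonal, layers x layers
    letters: dict             # layer -> letter string


def normalize_copies(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``copies_per_g`` and ``copies_per_ng`` columns.

    Raises a single error listing every row with non-positive mass.
    """
    bad = records.index[
        (records["mat_mass_g"] <= 0) | (records["na_mass_ng"] <= 0)
    ].tolist()
    if bad:
        raise ValueError(f"non-positive mat/nucleic-acid mass at rows {bad}")
    out = records.copy()
    out["copies_per_g"] = out["raw_copies"] / out["mat_mass_g"]
    out["copies_per_ng"] = out["raw_copies"] / out["na_mass_ng"]
    if "below_lod" not in out.columns:
        out["below_lod"] = False
    out.loc[out["raw_copies"] == 0, "below_lod"] = True
    return out


def expression_ratio(
    normalized: pd.DataFrame,
    basis: str = "per_g",
    aggregation: str = "mean",
) -> pd.DataFrame:
    """cDNA/DNA ratio per marker x layer on the chosen basis.

    Replicates are aggregated *before* the quotient (ratio of means by
    default — robust when one replicate's DNA value is near zero;
    ``aggregation='median'`` is the alternative). Layers whose DNA is
    entirely below the detection limit, or aggregates to zero, yield no
    ratio; the reason is recorded instead.
    """
    col = {"per_g": "copies_per_g", "per_ng": "copies_per_ng"}.get(basis)
    if col is None:
        raise ValueError("basis must be 'per_g' or 'per_ng'")
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    agg = np.mean if aggregation == "mean" else np.median
    rows = []
    for (marker, layer), grp in normalized.groupby(["marker", "layer"], sort=True):
        ok = grp[~grp["below_lod"]]
        dna = ok.loc[ok["template"] == "DNA", col].to_numpy()
        cdna = ok.loc[ok["template"] == "cDNA", col].to_numpy()
        if dna.size == 0:
            rows.append((marker, layer, np.nan, basis, "dna_below_lod"))
            continue
        dna_agg = agg(dna)
        if dna_agg == 0:
            rows.append((marker, layer, np.nan, basis, "dna_zero"))
            continue
        cdna_agg = agg(cdna) if cdna.size else np.nan
        reason = "" if cdna.size else "cdna_below_lod"
        rows.append((marker, layer, cdna_agg / dna_agg, basis, reason))
    return pd.DataFrame(
        rows, columns=["marker", "layer", "ratio_cdna_dna", "basis", "reason"]
    )


def shapiro_wilk_screen(values_by_marker: dict) -> pd.DataFrame:
    """Shapiro-Wilk normality screen per marker.

    Justifies the nonparametric path (which is always taken); markers with
    fewer than 3 values or zero variance are skipped with a warning.
    """
    rows = []
    for marker, values in values_by_marker.items():
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 3:
            warnings.warn(f"{marker}: <3 values, Shapiro-Wilk skipped")
            continue
        if np.ptp(x) == 0:
            warnings.warn(f"{marker}: constant sample, Shapiro-Wilk degenerate; skipped")
            continue
        w, p = stats.shapiro(x)
        rows.append((marker, x.size, float(w), float(p)))
    return pd.DataFrame(rows, columns=["marker", "n", "W", "p"])


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p.

    All-identical data is a well-defined no-separation case: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 values in total")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def conover_iman(groups, holm: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conover-Iman pairwise comparisons after Kruskal-Wallis.

    t statistics on rank sums use the pooled rank variance shrunk by
    (N-1-H)/(N-k) with N-k degrees of freedom; two-sided p-values, reported
    unadjusted by default (a Holm option is provided).

    Returns ``(pairwise_p, t_stats)`` as symmetric DataFrames indexed by
    group position (0-based).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    for i, g in enumerate(groups):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    sizes = np.array([g.size for g in groups])
    n_total = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    h, _ = kruskal_wallis(groups)
    bounds = np.cumsum(sizes)[:-1]
    rank_groups = np.split(ranks, bounds)
    mean_ranks = np.array([r.mean() for r in rank_groups])
    # tie-aware pooled rank variance
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)
    df = n_total - k
    scale = s2 * (n_total - 1 - h) / df if df > 0 else 0.0
    p_mat = np.ones((k, k))
    t_mat = np.zeros((k, k))
    pvals, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            denom = scale * (1 / sizes[i] + 1 / sizes[j])
            if denom <= 0:
                # degenerate: no rank variance left (identical data or H = N-1)
                t = np.inf if mean_ranks[i] != mean_ranks[j] else 0.0
                p = 0.0 if np.isinf(t) else 1.0
            else:
                t = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(denom)
                p = 2 * stats.t.sf(abs(t), df)
            t_mat[i, j], t_mat[j, i] = t, -t
            pvals.append(p)
            pairs.append((i, j))
    if holm and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        pvals = adj.tolist()
    for (i, j), p in zip(pairs, pvals):
        p_mat[i, j] = p_mat[j, i] = p
    idx = pd.RangeIndex(k)
    return (
        pd.DataFrame(p_mat, index=idx, columns=idx),
        pd.DataFrame(t_mat, index=idx, columns=idx),
    )


def compact_letters(pairwise_p: pd.DataFrame, alpha: float = 0.05, means=None) -> dict:
    """Compact letter display by insert-and-absorb.

    Two groups share a letter iff their pairwise p > alpha; the letter set is
    minimal in the insert-absorb sense. Letters are assigned in order of
    descending group mean (then index) so 'a' marks the largest group.
    """
    labels = list(pairwise_p.index)
    k = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    p = pairwise_p.to_numpy()
    # letters as sets of member positions; start with one letter covering all
    letter_sets = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if p[i, j] <= alpha:
                new_sets = []
                for s in letter_sets:
                    if i in s and j in s:
                        new_sets.extend([s - {i}, s - {j}])
                    else:
                        new_sets.append(s)
                # absorb: drop empty sets, proper subsets, and duplicates
                letter_sets = []
                for s in new_sets:
                    if s and not any(s < t for t in new_sets) and s not in letter_sets:
                        letter_sets.append(s)
    if means is None:
        order_key = {lab: pos[lab] for lab in labels}
    else:
        order_key = {lab: (-float(means[lab]), pos[lab]) for lab in labels}
    ranked = sorted(labels, key=lambda lab: order_key[lab])
    # order letters by their best-ranked member for stable naming
    def best_rank(s):
        return min(ranked.index(labels[i]) for i in s)

    letter_sets.sort(key=lambda s: (best_rank(s), sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for li, s in enumerate(letter_sets):
        ch = alphabet[li % len(alphabet)] * (1 + li // len(alphabet))
        for i in sorted(s):
            out[labels[i]] += ch
    return out


def test_layer_differences(
    normalized: pd.DataFrame,
    value_col: str = "copies_per_g",
    template: str | None = None,
    alpha: float = 0.05,
    holm: bool = False,
) -> list[LayerTestResult]:
    """Kruskal-Wallis + Conover-Iman + letters for every marker.

    Below-LOD records are excluded; layers left without data are dropped
    from that marker's test.
    """
    df = normalized[~normalized["below_lod"]]
    if template is not None:
        df = df[df["template"] == template]
    results = []
    for marker, grp in df.groupby("marker", sort=True):
        layers = sorted(grp["layer"].unique())
        groups = [grp.loc[grp["layer"] == l, value_col].to_numpy() for l in layers]
        if len(groups) < 2:
            warnings.warn(f"{marker}: fewer than 2 layers with data, skipped")
            continue
        h, p_global = kruskal_wallis(groups)
        p_mat, _ = conover_iman(groups, holm=holm)
        p_mat.index = p_mat.columns = layers
        means = {l: g.mean() for l, g in zip(layers, groups)}
        letters = compact_letters(p_mat, alpha=alpha, means=means)
        results.append(LayerTestResult(marker, h, p_global, p_mat, letters))
    return results
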