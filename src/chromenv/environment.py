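"""Chromatin-environment integration.

Assigns the predominant chromatin state to promoter windows, stratifies
regions and genes by H3K79me2 presence, classifies enhancer runs, links
enhancers to genes within 100 kb, and relates linked-gene expression to
enhancer H3K79me2 status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAssembly, Interval, PeakSet, gene_table
from .hmm import ENHANCER_STATES, Segmentation, state_priority
from .intervals import coverage_by_label, overlaps_any

H3K79_CATEGORIES = ("GB", "ENH", "GB-ENH", "none")


def assign_region_state(region: Interval, segmentation: Segmentation,
                        assembly: GenomeAssembly | None = None):
    """Predominant state of a region: the label covering the most bp.

    Ties break by the documented priority (active > bivalent > polycomb >
    weak > heterochromatin > quiescent, then lexicographic). A fully
    unannotated region gets ("unannotated", 1.0). Returns
    (state, coverage_fraction, second_state, second_fraction).
    """
    cov = coverage_by_label(region, segmentation, assembly=assembly)
    total = sum(cov.values())
    ranked = sorted(cov.items(), key=lambda kv: (-kv[1], state_priority(kv[0])))
    state, bp = ranked[0]
    second = ranked[1] if len(ranked) > 1 else (None, 0)
    return state, bp / total, second[0], second[1] / total


def gene_promoter_environment(genes, segmentation: Segmentation, window: int = 3000,
                              assembly: GenomeAssembly | None = None) -> pd.DataFrame:
    """Predominant chromatin state of each gene's TSS +/- ``window`` bp.

    Windows running past chromosome ends are clipped when an assembly is
    given. Also records the runner-up state and fraction (ambiguity check).
    """
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    rows = []
    for g in genes_df.itertuples():
        region = Interval(g.chrom, max(0, g.tss - window), g.tss + window + 1)
        state, frac, second, frac2 = assign_region_state(region, segmentation, assembly=assembly)
        rows.append((g.gene_id, state, frac, second, frac2))
    return pd.DataFrame(rows, columns=["gene_id", "predominant_state", "coverage_fraction",
                                       "second_state", "second_fraction"])


def split_regions_by_mark(regions: pd.DataFrame, mark_peaks: PeakSet,
                          min_overlap: int = 1) -> pd.DataFrame:
    """Partition state-labelled regions into mark+ / mark- and contrast states.

    ``regions`` must carry chrom/start/end/state columns. A region is "+" iff
    it overlaps any mark peak by >= ``min_overlap`` bp. Returns the region
    frame with a ``mark`` column ("+"/"-"); per-state proportions and
    chi-square p-values are in ``.attrs["contrast"]``.
    """
    out = regions.copy()
    if len(mark_peaks.df) == 0:
        out["mark"] = "-"
    else:
        flags = overlaps_any(out, mark_peaks.df, min_overlap=min_overlap)
        out["mark"] = np.where(flags, "+", "-")
    contrast = _state_contrast(out)
    out.attrs["contrast"] = contrast
    return out


def _state_contrast(regions: pd.DataFrame) -> pd.DataFrame:
    """Per-state 2x2 chi-square of state membership vs mark status."""
    states = sorted(regions["state"].unique())
    n_plus = int((regions["mark"] == "+").sum())
    n_minus = len(regions) - n_plus
    rows = []
    for state in states:
        in_state = regions["state"] == state
        a = int((in_state & (regions["mark"] == "+")).sum())
        b = int((in_state & (regions["mark"] == "-")).sum())
        table = np.array([[a, n_plus - a], [b, n_minus - b]])
        if table.sum() == 0 or n_plus == 0 or n_minus == 0:
            p = np.nan
        elif (stats.contingency.expected_freq(table + 1e-12) < 5).any():
            _, p = stats.fisher_exact(table)
        else:
            _, p, _, _ = stats.chi2_contingency(table)
        rows.append((state,
                     a / n_plus if n_plus else np.nan,
                     b / n_minus if n_minus else np.nan,
                     p))
    return pd.DataFrame(rows, columns=["state", "frac_plus", "frac_minus", "p"])


def classify_enhancers(segmentation: Segmentation, mark_peaks: PeakSet | None = None,
                       min_overlap: int = 1) -> pd.DataFrame:
    """Maximal runs of the four enhancer states as enhancer records.

    Records carry an ``enhancer_id``, their class (EnhA/EnhG/EnhW/EnhBiv) and,
    when ``mark_peaks`` is given, an H3K79me2 status column ("+"/"-").
    """
    if not any(s in segmentation.vocabulary for s in ENHANCER_STATES):
        raise ValueError("segmentation vocabulary has no enhancer states")
    df = segmentation.to_frame()
    enh = df[df["state"].isin(ENHANCER_STATES)].reset_index(drop=True)
    enh = enh.rename(columns={"state": "class"})
    enh.insert(0, "enhancer_id", [f"enh_{i}" for i in range(len(enh))])
    if mark_peaks is not None:
        if len(mark_peaks.df) == 0:
            enh["h3k79me2"] = "-"
        else:
            flags = overlaps_any(enh, mark_peaks.df, min_overlap=min_overlap)
            enh["h3k79me2"] = np.where(flags, "+", "-")
    return enh


def link_enhancer_genes(enhancers: pd.DataFrame, genes, mode: str = "nearest",
                        max_dist: int = 100_000) -> pd.DataFrame:
    """Link enhancers to genes within ``max_dist`` bp of either boundary.

    Distance is 0 when the gene body overlaps the enhancer, else the bp gap to
    the nearer boundary. ``nearest`` keeps the closest gene (ties kept and
    flagged); ``all`` keeps every gene in range. Enhancers without a gene in
    range get no rows.
    """
    if mode not in ("nearest", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    by_chrom = {c: g.reset_index(drop=True) for c, g in genes_df.groupby("chrom")}
    rows = []
    for e in enhancers.itertuples():
        g = by_chrom.get(e.chrom)
        if g is None:
            continue
        gap_left = e.start - g["end"].to_numpy()   # gene fully left
        gap_right = g["start"].to_numpy() - e.end  # gene fully right
        dist = np.maximum(np.maximum(gap_left, gap_right), 0)
        in_range = dist <= max_dist
        if not in_range.any():
            continue
        if mode == "all":
            for gid, d in zip(g.loc[in_range, "gene_id"], dist[in_range]):
                rows.append((e.enhancer_id, gid, int(d), False))
        else:
            dmin = dist[in_range].min()
            winners = g.loc[in_range & (dist == dmin), "gene_id"]
            tie = len(winners) > 1
            for gid in winners:
                rows.append((e.enhancer_id, gid, int(dmin), tie))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance", "tie"])


def enhancer_expression(enhancers: pd.DataFrame, links: pd.DataFrame,
                        expression: pd.Series) -> pd.DataFrame:
    """Mean linked-gene expression per enhancer, contrasted by H3K79me2 status.

    Per enhancer: mean expression (cpm) over its linked genes. Per enhancer
    class: two-sided Wilcoxon rank-sum between "+" and "-" enhancers, BH
    corrected across classes. Groups with < 2 enhancers get a missing p.
    """
    linked = links.merge(
        expression.rename("cpm"), left_on="gene_id", right_index=True, how="inner"
    )
    per_enh = linked.groupby("enhancer_id")["cpm"].mean().rename("mean_cpm")
    enh = enhancers.merge(per_enh, on="enhancer_id", how="inner")
    rows = []
    for cls, g in enh.groupby("class"):
        plus = g.loc[g["h3k79me2"] == "+", "mean_cpm"].to_numpy()
        minus = g.loc[g["h3k79me2"] == "-", "mean_cpm"].to_numpy()
        if len(plus) < 2 or len(minus) < 2:
            p = np.nan
        elif np.ptp(np.concatenate([plus, minus])) == 0:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(plus, minus, alternative="two-sided")
        rows.append((cls, len(plus), len(minus),
                     plus.mean() if len(plus) else np.nan,
                     minus.mean() if len(minus) else np.nan, p))
    out = pd.DataFrame(rows, columns=["class", "n_plus", "n_minus",
                                      "mean_cpm_plus", "mean_cpm_minus", "p"])
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out.attrs["per_enhancer"] = enh
    return out


def h3k79_gene_category(genes, mark_peaks: PeakSet, links: pd.DataFrame,
                        enhancers: pd.DataFrame, min_overlap: int = 1) -> pd.Series:
    """Per-gene H3K79me2 localisation: GB, ENH, GB-ENH or none.

    GB: gene body overlaps a mark peak (>= ``min_overlap`` bp). ENH: any
    linked enhancer is H3K79me2+. Genes absent from the links have ENH false.
    The four labels partition the gene set.
    """
    genes_df = genes if isinstance(genes, pd.DataFrame) else gene_table(genes)
    gb = overlaps_any(genes_df, mark_peaks.df, min_overlap=min_overlap) if len(mark_peaks.df) else (
        np.zeros(len(genes_df), dtype=bool)
    )
    plus_ids = set(enhancers.loc[enhancers["h3k79me2"] == "+", "enhancer_id"])
    enh_genes = set(links.loc[links["enhancer_id"].isin(plus_ids), "gene_id"])
    enh = genes_df["gene_id"].isin(enh_genes).to_numpy()
    cat = np.where(gb & enh, "GB-ENH", np.where(gb, "GB", np.where(enh, "ENH", "none")))
    return pd.Series(cat, index=genes_df["gene_id"], name="h3k79_category")


def category_by_class_contrast(categories: pd.Series, de_class: pd.Series):
    """Chi-square of H3K79me2 category vs DE class on the shared genes."""
    joined = pd.concat([categories, de_class.rename("de_class")], axis=1, join="inner")
    table = pd.crosstab(joined["h3k79_category"], joined["de_class"])
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy())
    return {"chi2": chi2, "p": p, "dof": dof, "table": table}
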