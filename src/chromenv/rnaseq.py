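"""Spike-in-anchored differential expression.

cpm filtering, RUVg-style removal of unwanted variation from control (ERCC)
genes, and a negative-binomial fold-change-threshold test: the null hypothesis
is |log2 fold change| <= log2(threshold), tested with a shifted Wald statistic
(the TREAT idea), so a gene is called only when its fold change credibly
exceeds the threshold, not merely differs from zero.

Library sizes exclude the control rows: depth normalization is carried by the
endogenous genes while the spike-ins inform the unwanted-variation factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Gene x sample raw counts with control flags and sample metadata."""

    counts: pd.DataFrame            # genes x samples, non-negative integers
    metadata: pd.DataFrame          # index = sample, columns incl. genotype
    control: pd.Series              # bool per gene (spike-in rows)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.metadata.index) != list(self.counts.columns):
            self.metadata = self.metadata.loc[self.counts.columns]
        self.control = self.control.reindex(self.counts.index).fillna(False).astype(bool)

    @property
    def samples(self):
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Depth over non-control genes only."""
        sizes = self.counts.loc[~self.control].sum(axis=0)
        if (sizes == 0).any():
            bad = sizes[sizes == 0].index.tolist()
            raise ValueError(f"zero library size for samples {bad}")
        return sizes

    @classmethod
    def from_frames(cls, counts, metadata, control_prefix="ERCC-", control_ids=None):
        if control_ids is not None:
            control = counts.index.isin(set(control_ids))
        else:
            control = counts.index.str.startswith(control_prefix)
        return cls(counts, metadata, pd.Series(control, index=counts.index))


def cpm(cm: CountMatrix, log: bool = False) -> pd.DataFrame:
    """Counts per million of non-control library size."""
    sizes = cm.library_sizes()
    out = cm.counts / sizes * 1e6
    if log:
        out = np.log2(out + 1)
    return out


def filter_expressed(cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 2) -> CountMatrix:
    """Keep genes with cpm >= min_cpm in at least min_samples samples.

    Control genes are always kept (they carry the normalization information).
    """
    c = cpm(cm)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    keep |= cm.control
    return CountMatrix(cm.counts.loc[keep], cm.metadata, cm.control.loc[keep])


def ruv_control_normalize(cm: CountMatrix, k: int = 1):
    """RUVg-style unwanted-variation removal anchored on control genes.

    log(count + 0.5) of the control genes is row-centered; the first ``k``
    right singular vectors of that (controls x samples) matrix give the
    per-sample unwanted factors W (samples x k, orthonormal columns). W is
    regressed out of every gene's log-expression.

    Returns (adjusted log2-cpm-scale log expression DataFrame, W DataFrame).
    """
    n_controls = int(cm.control.sum())
    if n_controls < 2:
        raise ValueError("need at least 2 control genes")
    if k >= min(n_controls, len(cm.samples)):
        raise ValueError(f"k={k} too large for {n_controls} controls x {len(cm.samples)} samples")
    logy = np.log(cm.counts.to_numpy(dtype=float) + PSEUDOCOUNT)
    z = logy[cm.control.to_numpy()]
    z = z - z.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[k - 1] <= 1e-12:
        raise ValueError(f"control submatrix rank < k={k}")
    w = vt[:k].T  # samples x k, orthonormal
    centered = logy - logy.mean(axis=1, keepdims=True)
    beta = centered @ w             # genes x k
    adjusted = logy - beta @ w.T
    adj = pd.DataFrame(adjusted, index=cm.counts.index, columns=cm.counts.columns)
    wdf = pd.DataFrame(w, index=cm.counts.columns,
                       columns=[f"W{i + 1}" for i in range(k)])
    return adj, wdf


# ---------------------------------------------------------------------------
# negative-binomial threshold test


def _moment_dispersions(y: np.ndarray, sizes: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion by a normalized method of moments.

    On depth-normalized counts q_ij = y_ij / s_j, Var(q) within a group is
    approximately mu/s_bar + phi mu^2; phi is solved per group and averaged.
    """
    phis = np.zeros(y.shape[0])
    weight = 0
    for idx in groups:
        if len(idx) < 2:
            continue
        q = y[:, idx] / sizes[idx]
        mu = q.mean(axis=1)
        v = q.var(axis=1, ddof=1)
        sbar = sizes[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (v - mu / sbar) / mu**2
        phi = np.where(np.isfinite(phi), phi, 0.0)
        phis += np.clip(phi, 0.0, 10.0) * (len(idx) - 1)
        weight += len(idx) - 1
    return phis / max(weight, 1)


@dataclass
class DEResult:
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def status_counts(self):
        return self.table["status"].value_counts().reindex(["up", "down", "not"], fill_value=0)


def de_threshold_test(cm: CountMatrix, group_col: str = "genotype",
                      test_level: str = "KO", ref_level: str = "CTL",
                      covariates: pd.DataFrame | None = None,
                      fc_threshold: float = 1.5, alpha: float = 0.05,
                      dispersion_shrink: float = 0.75) -> DEResult:
    """NB fold-change-threshold test of test_level vs ref_level.

    Per gene: moment dispersion shrunk toward the common dispersion
    (weight ``dispersion_shrink`` on the common value), log2 fold change from
    depth-normalized group means (or an NB GLM when covariates are supplied),
    and a shifted Wald test of H0: |log2fc| <= log2(fc_threshold), BH-corrected.
    Status is "up"/"down" only when fdr < alpha AND |fc| > fc_threshold.
    Control (spike-in) genes are excluded from testing.
    """
    if fc_threshold <= 1.0:
        raise ValueError("fc_threshold must exceed 1")
    meta = cm.metadata
    test_idx = np.flatnonzero((meta[group_col] == test_level).to_numpy())
    ref_idx = np.flatnonzero((meta[group_col] == ref_level).to_numpy())
    if len(test_idx) < 2 or len(ref_idx) < 2:
        raise ValueError("need >= 2 samples per group")

    keep = ~cm.control
    genes = cm.counts.index[keep]
    y = cm.counts.loc[keep].to_numpy(dtype=float)
    sizes = cm.library_sizes().to_numpy(dtype=float)

    phi_gene = _moment_dispersions(y, sizes, [test_idx, ref_idx])
    expressed = y.sum(axis=1) > 0
    phi_common = float(np.median(phi_gene[expressed])) if expressed.any() else 0.0
    phi = (1 - dispersion_shrink) * phi_gene + dispersion_shrink * phi_common
    phi = np.clip(phi, 1e-4, None)

    if covariates is None:
        lfc_ln, se_ln = _two_group_wald(y, sizes, test_idx, ref_idx, phi)
    else:
        lfc_ln, se_ln = _glm_wald(y, sizes, meta, group_col, test_level, ref_level,
                                  covariates, phi)

    tau = np.log(fc_threshold)
    # TREAT-style composite-null p: both tail shifts contribute
    z_hi = (np.abs(lfc_ln) - tau) / se_ln
    z_lo = (np.abs(lfc_ln) + tau) / se_ln
    p = stats.norm.sf(z_hi) + stats.norm.sf(z_lo)
    p = np.clip(p, 0.0, 1.0)
    allzero = y.sum(axis=1) == 0
    p[allzero] = 1.0

    fdr = multipletests(p, method="fdr_bh")[1]
    log2fc = lfc_ln / np.log(2)
    status = np.full(len(genes), "not", dtype=object)
    called = (fdr < alpha) & (np.abs(log2fc) > np.log2(fc_threshold))
    status[called & (log2fc > 0)] = "up"
    status[called & (log2fc < 0)] = "down"

    table = pd.DataFrame(
        {"gene_id": genes, "log2fc": log2fc, "p": p, "fdr": fdr,
         "status": status, "dispersion": phi, "flag_allzero": allzero}
    ).set_index("gene_id")
    return DEResult(table, params={
        "fc_threshold": fc_threshold, "alpha": alpha,
        "common_dispersion": phi_common,
        "n_test": len(test_idx), "n_ref": len(ref_idx),
        "covariates": list(covariates.columns) if covariates is not None else [],
    })


def _two_group_wald(y, sizes, test_idx, ref_idx, phi):
    """Closed-form group-mean estimator of the natural-log fold change.

    q_g = sum(y)/sum(s) per group; Var(log q_g) = 1/(q_g S_g) + phi S2_g/S_g^2
    from the NB mean-variance relation, delta method on the log.
    """
    out_lfc = np.empty(y.shape[0])
    out_se = np.empty(y.shape[0])
    stats_per_group = []
    for idx in (test_idx, ref_idx):
        s = sizes[idx]
        tot = y[:, idx].sum(axis=1)
        q = (tot + PSEUDOCOUNT) / s.sum()
        var_log = 1.0 / (q * s.sum()) + phi * (s**2).sum() / s.sum() ** 2
        stats_per_group.append((q, var_log))
    (q1, v1), (q0, v0) = stats_per_group
    out_lfc = np.log(q1) - np.log(q0)
    out_se = np.sqrt(v1 + v0)
    return out_lfc, out_se


def _glm_wald(y, sizes, meta, group_col, test_level, ref_level, covariates, phi):
    """Per-gene NB GLM (log link) with covariates; Wald on the group contrast."""
    import statsmodels.api as sm

    group = (meta[group_col] == test_level).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(group)), group, covariates.to_numpy(dtype=float)])
    offset = np.log(sizes)
    lfc = np.empty(y.shape[0])
    se = np.empty(y.shape[0])
    for i in range(y.shape[0]):
        fam = sm.families.NegativeBinomial(alpha=float(phi[i]))
        try:
            res = sm.GLM(y[i] + PSEUDOCOUNT, X, family=fam, offset=offset).fit(maxiter=50)
            lfc[i] = res.params[1]
            se[i] = res.bse[1]
        except Exception:
            lfc[i] = 0.0
            se[i] = np.inf
    se = np.where(np.isfinite(se) & (se > 0), se, np.inf)
    return lfc, se


# ---------------------------------------------------------------------------
# feature enrichment on DE classes


def _table_test(table: np.ndarray, rng: np.random.Generator | None = None,
                n_mc: int = 20000):
    """Chi-square, or a seeded Monte-Carlo chi-square when expected counts < 5."""
    table = np.asarray(table)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.size == 0 or min(table.shape) < 2:
        return np.nan, "degenerate"
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(table)
        return p, "chi2"
    # exact-style: condition on margins, permute category labels
    rng = rng or np.random.default_rng(0)
    obs = stats.chi2_contingency(table, correction=False)[0]
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    exceed = 0
    for _ in range(n_mc):
        perm = np.zeros_like(table)
        np.add.at(perm, (rows, rng.permutation(cols)), 1)
        s = stats.chi2_contingency(perm, correction=False)[0] if (
            (perm.sum(axis=0) > 0).all() and (perm.sum(axis=1) > 0).all()
        ) else 0.0
        if s >= obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_mc + 1), "monte_carlo_chi2"


def feature_enrichment(de: DEResult, features: pd.DataFrame, n_deciles: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Contrast up (and down) genes vs not-deregulated genes on gene features.

    Features frame must carry ``length``, ``biotype`` and ``chrom`` indexed by
    gene id. Length deciles are computed over all tested genes. Each contrast
    (class x feature) is a chi-square (Monte-Carlo when sparse), BH-corrected
    across contrasts.
    """
    joined = de.table.join(features, how="inner")
    joined["length_decile"] = pd.qcut(joined["length"].rank(method="first"),
                                      n_deciles, labels=range(1, n_deciles + 1))
    rng = np.random.default_rng(seed)
    rows = []
    for de_class in ("up", "down"):
        sel = joined[joined["status"].isin([de_class, "not"])]
        if (sel["status"] == de_class).sum() == 0:
            continue
        for feat in ("length_decile", "biotype", "chrom"):
            table = pd.crosstab(sel["status"] == de_class, sel[feat])
            p, method = _table_test(table.to_numpy(), rng=rng)
            rows.append((de_class, feat, p, method))
    out = pd.DataFrame(rows, columns=["de_class", "feature", "p", "method"])
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
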