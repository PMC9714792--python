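"""QC filtering, normalization, marker statistics and proportion testing.

Implements the per-cell quality-control rules (mitochondrial fraction,
detected-gene bounds), library-size log-normalization, Wilcoxon rank-sum
cluster markers with Bonferroni correction, control-matched gene-signature
scoring, cell-cycle phase calls, the arcsine-square-root cell-proportion
t test, and Fisher-exact gene-set enrichment with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCThresholds",
    "qc_filter",
    "lognormalize",
    "log2fc",
    "rank_sum_test",
    "find_markers",
    "signature_score",
    "cell_cycle_phase",
    "proportion_test",
    "ProportionTestResult",
    "fisher_enrichment",
]


@dataclass
class QCThresholds:
    """Per-cell QC bounds.

    ``max_mito_fraction``: cells with a higher fraction of counts in
    mitochondrial genes are removed (default 0.05, i.e. the ">5%" rule).
    ``min_genes``: cells detecting fewer genes are removed (default 200).
    ``mad_multiplier``: cells detecting more genes than
    ``median + mad_multiplier * MAD`` of detected genes are removed
    (raw MAD, no normal-consistency scaling; default 3).
    """

    max_mito_fraction: float = 0.05
    min_genes: int = 200
    mad_multiplier: float = 3.0

    def validate(self) -> None:
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def _mito_mask(adata: AnnData) -> np.ndarray:
    if "mt" in adata.var:
        return np.asarray(adata.var["mt"], dtype=bool)
    return np.array([g.upper().startswith("MT-") for g in adata.var_names])


def qc_filter(
    counts: AnnData,
    thresholds: QCThresholds | None = None,
    sample_key: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three QC rules; return kept cell ids and a per-cell report.

    The detected-gene upper bound is computed per sample when ``sample_key``
    names an ``obs`` column (each sample processed individually), otherwise
    on the whole matrix.  If no mitochondrial genes can be identified the
    mito rule is skipped with a warning and flagged in ``report.attrs``.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if counts.n_obs < 1:
        raise ValueError("empty matrix")
    X = _dense(counts.X)
    total = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    mito = _mito_mask(counts)

    report = pd.DataFrame(index=counts.obs_names.copy())
    report["total_counts"] = total
    report["n_genes"] = n_genes

    mito_rule_skipped = not mito.any()
    if mito_rule_skipped:
        warnings.warn("no mitochondrial genes found; mito rule skipped")
        report["mito_fraction"] = np.nan
        fail_mito = np.zeros(counts.n_obs, dtype=bool)
    else:
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(total > 0, X[:, mito].sum(axis=1) / np.maximum(total, 1), 0.0)
        report["mito_fraction"] = mito_frac
        fail_mito = mito_frac > thresholds.max_mito_fraction

    fail_low = n_genes < thresholds.min_genes

    if sample_key is not None:
        groups = counts.obs[sample_key].to_numpy()
    else:
        groups = np.zeros(counts.n_obs, dtype=int)
    upper = np.empty(counts.n_obs, dtype=float)
    for g in np.unique(groups):
        sel = groups == g
        med = np.median(n_genes[sel])
        mad = stats.median_abs_deviation(n_genes[sel], scale=1.0)
        upper[sel] = med + thresholds.mad_multiplier * mad
    fail_high = n_genes > upper
    report["gene_upper_bound"] = upper

    reasons = []
    for lo, hi, mt in zip(fail_low, fail_high, fail_mito):
        rs = []
        if mt:
            rs.append("mito")
        if lo:
            rs.append("low_genes")
        if hi:
            rs.append("high_genes")
        reasons.append(",".join(rs))
    report["removed"] = fail_mito | fail_low | fail_high
    report["reason"] = reasons
    report.attrs["mito_rule_skipped"] = mito_rule_skipped
    kept = list(counts.obs_names[~report["removed"].to_numpy()])
    return kept, report


def lognormalize(counts: AnnData, scale: float = 1e4) -> AnnData:
    """Library-size normalize to ``scale`` counts per cell, then log1p.

    value = log(1 + scale * count / cell_total).  Cells with zero total
    counts are dropped with a warning.  The scale factor and pseudocount are
    recorded in ``uns['normalization']``.
    """
    if counts.n_obs < 1 or counts.n_vars < 1:
        raise ValueError("empty matrix")
    X = _dense(counts.X).astype(np.float64)
    total = X.sum(axis=1)
    keep = total > 0
    if not keep.any():
        raise ValueError("no cell with positive total counts")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-count cells")
    out = counts[keep].copy()
    X = X[keep]
    out.X = np.log1p(scale * X / X.sum(axis=1, keepdims=True)).astype(np.float32)
    out.uns["normalization"] = {"scale": float(scale), "pseudocount": 1.0, "log": "natural"}
    return out


def log2fc(
    values_a: Sequence[float],
    values_b: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """log2 ratio of de-logged group means, pseudocount-guarded.

    ``log2((mean(expm1 a) + c) / (mean(expm1 b) + c))`` — antisymmetric in
    the two groups, 0 for identical groups.
    """
    a = np.expm1(np.asarray(values_a, dtype=float)).mean()
    b = np.expm1(np.asarray(values_b, dtype=float)).mean()
    return float(np.log2((a + pseudocount) / (b + pseudocount)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery
# ---------------------------------------------------------------------------

EXACT_MAX_N = 25


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration (via the exact Mann-Whitney null distribution) when
    both groups have <= 25 observations and no ties are present; otherwise
    the tie-corrected normal approximation (no continuity correction, so
    null rejection rates stay calibrated).  Fully tied data give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        return float(stats.mannwhitneyu(x, y, method="exact").pvalue)
    return float(
        stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False).pvalue
    )


def _wilcoxon_vectorized(X: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Tie-corrected normal-approximation rank-sum p per column of X."""
    n1 = int(in_group.sum())
    n2 = X.shape[0] - n1
    n = n1 + n2
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (cnt.astype(float) ** 3 - cnt).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    p = np.ones(X.shape[1])
    ok = var > 0
    z = (r1[ok] - mu) / np.sqrt(var[ok])
    p[ok] = 2.0 * stats.norm.sf(np.abs(z))
    return np.minimum(p, 1.0)


def _group_pvalues(X: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    n1 = int(in_group.sum())
    n2 = X.shape[0] - n1
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        return np.array(
            [rank_sum_test(X[in_group, j], X[~in_group, j]) for j in range(X.shape[1])]
        )
    return _wilcoxon_vectorized(X, in_group)


def find_markers(
    norm: AnnData,
    target: str,
    groupby: str = "population",
    min_pct: float = 0.25,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Cluster markers: one-vs-rest Wilcoxon with Bonferroni correction.

    Genes are pre-filtered by ``max(pct_in, pct_out) >= min_pct`` and
    ``|log2fc| >= lfc_min``; the Bonferroni factor is the number of genes
    actually tested.  Output is sorted by adjusted p then |log2fc|.
    """
    labels = np.asarray(norm.obs[groupby])
    in_group = labels == target
    if in_group.sum() < 3 or (~in_group).sum() < 3:
        raise ValueError("both target and complement need >= 3 cells")
    X = _dense(norm.X)
    pct_in = (X[in_group] > 0).mean(axis=0)
    pct_out = (X[~in_group] > 0).mean(axis=0)
    mean_in = np.expm1(X[in_group]).mean(axis=0)
    mean_out = np.expm1(X[~in_group]).mean(axis=0)
    lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
    tested = (np.maximum(pct_in, pct_out) >= min_pct) & (np.abs(lfc) >= lfc_min)
    idx = np.flatnonzero(tested)
    p = _group_pvalues(X[:, idx], in_group)
    p_adj = np.minimum(p * len(idx), 1.0)
    out = pd.DataFrame(
        {
            "gene": np.asarray(norm.var_names)[idx],
            "log2fc": lfc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p": p,
            "p_adj": p_adj,
        }
    )
    out["significant"] = out["p_adj"] < alpha
    out = out.sort_values(
        ["p_adj", "log2fc"], key=lambda s: -s.abs() if s.name == "log2fc" else s
    ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# signature scoring
# ---------------------------------------------------------------------------


def signature_score(
    norm: AnnData,
    signature: Sequence[str],
    n_bins: int = 24,
    ctrl_per_gene: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature score with expression-matched random controls.

    Genes are binned by their dataset-mean expression into ``n_bins``
    equal-size rank bins; for each signature gene ``ctrl_per_gene`` control
    genes are drawn uniformly (without replacement) from its bin, and the
    score is mean(signature genes) - mean(pooled control set) per cell.
    Deterministic given ``seed``.  Signature genes absent from the matrix
    are dropped with a warning; an empty intersection is an error.
    """
    var_index = {g: i for i, g in enumerate(norm.var_names)}
    present = [g for g in signature if g in var_index]
    missing = [g for g in signature if g not in var_index]
    if not present:
        raise ValueError(f"no signature gene found in matrix; missing: {missing}")
    if missing:
        warnings.warn(f"{len(missing)} signature genes not in matrix: {missing[:10]}")
    X = _dense(norm.X)
    gene_means = X.mean(axis=0)
    order = np.argsort(gene_means, kind="stable")
    bin_size = int(np.ceil(len(order) / n_bins))
    bin_of = np.empty(len(order), dtype=int)
    bin_of[order] = np.arange(len(order)) // bin_size
    bins = {b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of)}

    rng = np.random.default_rng(seed)
    sig_idx = np.array([var_index[g] for g in present])
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = bins[bin_of[gi]]
        k = min(ctrl_per_gene, len(pool))
        ctrl.update(rng.choice(pool, size=k, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl))
    return X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def cell_cycle_phase(
    norm: AnnData,
    s_genes: Sequence[str],
    g2m_genes: Sequence[str],
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """S/G2M signature scores and a per-cell phase call.

    Phase is G1 when both scores are <= 0, otherwise the phase of the larger
    score.  Returns a DataFrame with columns ``s_score``, ``g2m_score``,
    ``phase``.
    """
    s = signature_score(norm, s_genes, seed=seed, **kwargs)
    g2m = signature_score(norm, g2m_genes, seed=seed + 1, **kwargs)
    phase = np.where((s <= 0) & (g2m <= 0), "G1", np.where(s > g2m, "S", "G2M"))
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase}, index=norm.obs_names.copy()
    )


# ---------------------------------------------------------------------------
# proportions and enrichment
# ---------------------------------------------------------------------------


@dataclass
class ProportionTestResult:
    population: str
    proportions: dict  # condition -> {sample: proportion}
    t: float
    p: float


def proportion_test(
    meta: pd.DataFrame,
    population: str,
    sample_key: str = "sample",
    condition_key: str = "condition",
    population_key: str = "population",
    equal_var: bool = True,
) -> ProportionTestResult:
    """Arcsine-square-root transformed two-sample t test on proportions.

    Per-sample proportions of ``population`` are transformed with
    ``asin(sqrt(p))`` and compared between the two conditions with a
    two-tailed pooled-variance t test (Welch optional via ``equal_var``).
    """
    conditions = pd.unique(meta[condition_key])
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    per_sample: dict[str, dict[str, float]] = {}
    transformed: dict[str, list[float]] = {}
    for cond in conditions:
        sub = meta[meta[condition_key] == cond]
        samples = pd.unique(sub[sample_key])
        if len(samples) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 samples")
        per_sample[cond] = {}
        transformed[cond] = []
        for s in samples:
            cells = sub[sub[sample_key] == s]
            prop = float((cells[population_key] == population).mean())
            per_sample[cond][s] = prop
            transformed[cond].append(float(np.arcsin(np.sqrt(prop))))
    a = np.asarray(transformed[conditions[0]])
    b = np.asarray(transformed[conditions[1]])
    if np.ptp(np.concatenate([a, b])) == 0:
        t, p = 0.0, 1.0  # identical transformed values in every sample
    elif np.ptp(a) == 0 and np.ptp(b) == 0:
        t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0  # zero pooled variance
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return ProportionTestResult(
        population=population, proportions=per_sample, t=float(t), p=float(p)
    )


def fisher_enrichment(
    query: Sequence[str],
    sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment over gene sets, BH-corrected."""
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set or not query_set:
        raise ValueError("query and universe must be non-empty")
    if not query_set <= universe_set:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in sets.items():
        s = set(genes) & universe_set
        a = len(query_set & s)
        b = len(query_set) - a
        c = len(s) - a
        d = len(universe_set) - len(query_set) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(s), odds, p))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "odds_ratio", "p"]
    )
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values("p").reset_index(drop=True)
    return out
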