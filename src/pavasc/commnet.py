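"""Additive ligand-receptor communication scoring with a permutation null.

An interaction edge from source population S to target population T over a
database pair (ligand L, receptor R, w_db) is scored as

    weight = w_ligand + w_db + w_receptor

where w_ligand is the log2 fold change of L in S versus all other cells and
w_receptor that of R in T.  An edge is admitted when both genes qualify as
enriched (log2fc >= lfc_min and Bonferroni-adjusted Wilcoxon p < alpha).

Significance comes from a permutation null: population labels are shuffled
across cells within each sample (per-sample population sizes preserved) and
the additive weight is recomputed from the permuted group means.  The
permuted statistic intentionally omits the enrichment gate so that, under
the null, observed and permuted weights are exchangeable and the resulting
p-values are calibrated; the gate decides only which edges are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .sc_qc_stats import _dense, _group_pvalues

__all__ = [
    "expression_weights",
    "score_interactions",
    "permutation_test",
    "summarize_network",
    "NetworkSummary",
]


def expression_weights(
    norm: AnnData,
    genes: list[str],
    groupby: str = "population",
    min_pct: float = 0.25,
    lfc_min: float = 0.25,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per (population, gene) enrichment table over a gene list.

    Returns a DataFrame with columns ``population, gene, log2fc, p, p_adj,
    qualified``; ``qualified`` marks positive enrichment (log2fc >= lfc_min,
    max(pct) >= min_pct, Bonferroni-adjusted p < alpha).  The edge weight of
    a qualified gene is its log2fc.  Populations with fewer than
    ``min_cells`` cells are skipped with a warning.
    """
    present = [g for g in genes if g in set(norm.var_names)]
    if not present:
        raise ValueError("none of the requested genes is present in the matrix")
    col = {g: i for i, g in enumerate(norm.var_names)}
    idx = np.array([col[g] for g in present])
    X = _dense(norm.X)[:, idx]
    labels = np.asarray(norm.obs[groupby])
    rows = []
    for pop in pd.unique(labels):
        in_group = labels == pop
        if in_group.sum() < min_cells or (~in_group).sum() < min_cells:
            warnings.warn(f"population {pop!r} has < {min_cells} cells; skipped")
            continue
        pct_in = (X[in_group] > 0).mean(axis=0)
        pct_out = (X[~in_group] > 0).mean(axis=0)
        mean_in = np.expm1(X[in_group]).mean(axis=0)
        mean_out = np.expm1(X[~in_group]).mean(axis=0)
        lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        p = _group_pvalues(X, in_group)
        p_adj = np.minimum(p * X.shape[1], 1.0)
        qual = (
            (lfc >= lfc_min)
            & (np.maximum(pct_in, pct_out) >= min_pct)
            & (p_adj < alpha)
        )
        for j, g in enumerate(present):
            rows.append((pop, g, float(lfc[j]), float(p[j]), float(p_adj[j]), bool(qual[j])))
    return pd.DataFrame(
        rows, columns=["population", "gene", "log2fc", "p", "p_adj", "qualified"]
    )


def score_interactions(
    weights: pd.DataFrame, db: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Enumerate admissible edges and their additive weights.

    ``db`` needs columns ``ligand, receptor, weight`` (w_db in [0, 1]).
    An edge exists for every ordered (source, target) population pair —
    autocrine included — and database pair whose ligand qualifies in the
    source and whose receptor qualifies in the target.  Pairs referencing
    genes absent from the weights table are dropped and counted.
    """
    if not len(db):
        raise ValueError("empty ligand-receptor database")
    known = set(weights["gene"])
    dropped = int((~(db["ligand"].isin(known) & db["receptor"].isin(known))).sum())
    db_ok = db[db["ligand"].isin(known) & db["receptor"].isin(known)]
    qual = weights[weights["qualified"]]
    lig_w = {(r.population, r.gene): r.log2fc for r in qual.itertuples()}
    rows = []
    pops = list(pd.unique(weights["population"]))
    for pair in db_ok.itertuples():
        for src in pops:
            wl = lig_w.get((src, pair.ligand))
            if wl is None:
                continue
            for tgt in pops:
                wr = lig_w.get((tgt, pair.receptor))
                if wr is None:
                    continue
                rows.append(
                    (src, tgt, pair.ligand, pair.receptor, wl, float(pair.weight), wr,
                     wl + float(pair.weight) + wr)
                )
    edges = pd.DataFrame(
        rows,
        columns=[
            "source", "target", "ligand", "receptor",
            "w_ligand", "w_db", "w_receptor", "weight",
        ],
    )
    return edges, {"dropped_pairs": dropped, "db_pairs_used": int(len(db_ok))}


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


def _raw_lfc_matrix(
    E_sums: np.ndarray,
    tot_E: np.ndarray,
    n_in: np.ndarray,
    n_cells: int,
    pseudocount: float,
) -> np.ndarray:
    """log2fc of each gene (rows) in each population (cols) vs the rest."""
    mean_in = E_sums / n_in[None, :]
    mean_out = (tot_E[:, None] - E_sums) / (n_cells - n_in)[None, :]
    return np.log2((mean_in + pseudocount) / (mean_out + pseudocount))


def permutation_test(
    norm: AnnData,
    edges: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    groupby: str = "population",
    sample_key: str | None = "sample",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Add-one permutation p-values for interaction edges.

    For each permutation, population labels are shuffled across cells
    (within each sample when ``sample_key`` is given) and each edge's raw
    additive weight w_ligand + w_db + w_receptor is recomputed from the
    permuted group-mean log2 fold changes.  p = (1 + #{permuted >=
    observed}) / (1 + n_perm).  Deterministic given ``seed``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-value resolution")
    edges = edges.copy()
    if not len(edges):
        edges["p_perm"] = pd.Series(dtype=float)
        return edges

    labels = np.asarray(norm.obs[groupby])
    pops = list(pd.unique(labels))
    pop_col = {p: i for i, p in enumerate(pops)}
    genes = list(pd.unique(pd.concat([edges["ligand"], edges["receptor"]])))
    gene_row = {g: i for i, g in enumerate(genes)}
    col = {g: i for i, g in enumerate(norm.var_names)}
    E = np.expm1(_dense(norm.X)[:, [col[g] for g in genes]].astype(np.float64))
    tot_E = E.sum(axis=0)
    n_cells = norm.n_obs
    n_in = np.array([(labels == p).sum() for p in pops], dtype=float)

    lig_i = edges["ligand"].map(gene_row).to_numpy()
    rec_i = edges["receptor"].map(gene_row).to_numpy()
    src_i = edges["source"].map(pop_col).to_numpy()
    tgt_i = edges["target"].map(pop_col).to_numpy()
    w_db = edges["w_db"].to_numpy()

    onehot = np.zeros((n_cells, len(pops)))
    onehot[np.arange(n_cells), [pop_col[l] for l in labels]] = 1.0
    lfc_obs = _raw_lfc_matrix(E.T @ onehot, tot_E, n_in, n_cells, pseudocount)
    obs = lfc_obs[lig_i, src_i] + w_db + lfc_obs[rec_i, tgt_i]

    if sample_key is not None:
        sample_groups = [
            np.flatnonzero(np.asarray(norm.obs[sample_key]) == s)
            for s in pd.unique(norm.obs[sample_key])
        ]
    else:
        sample_groups = [np.arange(n_cells)]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(edges), dtype=np.int64)
    perm = np.arange(n_cells)
    for _ in range(n_perm):
        for idx in sample_groups:
            perm[idx] = idx[rng.permutation(len(idx))]
        S = E.T @ onehot[perm]
        lfc = _raw_lfc_matrix(S, tot_E, n_in, n_cells, pseudocount)
        stat = lfc[lig_i, src_i] + w_db + lfc[rec_i, tgt_i]
        exceed += stat >= obs
    edges["p_perm"] = (1.0 + exceed) / (1.0 + n_perm)
    return edges


def permutation_test_naive(
    norm: AnnData,
    edges: pd.DataFrame,
    n_perm: int,
    seed: int = 0,
    groupby: str = "population",
    sample_key: str | None = "sample",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Reference implementation: per-permutation per-population loop.

    Exactly equivalent to :func:`permutation_test` (same RNG stream, same
    statistic) but recomputes each group mean by explicit subsetting.  Kept
    as an oracle for testing the vectorized path.
    """
    edges = edges.copy()
    labels = np.asarray(norm.obs[groupby])
    pops = list(pd.unique(labels))
    genes = list(pd.unique(pd.concat([edges["ligand"], edges["receptor"]])))
    col = {g: i for i, g in enumerate(norm.var_names)}
    E = np.expm1(_dense(norm.X)[:, [col[g] for g in genes]].astype(np.float64))
    gene_row = {g: i for i, g in enumerate(genes)}

    def edge_stats(lab: np.ndarray) -> np.ndarray:
        lfc = {}
        for p in pops:
            sel = lab == p
            m_in = E[sel].mean(axis=0)
            m_out = E[~sel].mean(axis=0)
            lfc[p] = np.log2((m_in + pseudocount) / (m_out + pseudocount))
        return np.array(
            [
                lfc[e.source][gene_row[e.ligand]]
                + e.w_db
                + lfc[e.target][gene_row[e.receptor]]
                for e in edges.itertuples()
            ]
        )

    obs = edge_stats(labels)
    if sample_key is not None:
        sample_groups = [
            np.flatnonzero(np.asarray(norm.obs[sample_key]) == s)
            for s in pd.unique(norm.obs[sample_key])
        ]
    else:
        sample_groups = [np.arange(norm.n_obs)]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(edges), dtype=np.int64)
    perm = np.arange(norm.n_obs)
    for _ in range(n_perm):
        for idx in sample_groups:
            perm[idx] = idx[rng.permutation(len(idx))]
        exceed += edge_stats(labels[perm]) >= obs
    edges["p_perm"] = (1.0 + exceed) / (1.0 + n_perm)
    return edges


# ---------------------------------------------------------------------------
# network summary
# ---------------------------------------------------------------------------


@dataclass
class NetworkSummary:
    """Per-population ligand/receptor scores and pairwise edge tallies."""

    ligand_scores: dict = field(default_factory=dict)
    receptor_scores: dict = field(default_factory=dict)
    edge_counts: pd.DataFrame | None = None  # significant edges
    edge_counts_all: pd.DataFrame | None = None  # all admissible edges
    edge_weights: pd.DataFrame | None = None


def summarize_network(edges: pd.DataFrame, alpha: float = 0.05) -> NetworkSummary:
    """Aggregate significant edges into per-population scores.

    ligand_score(P) = sum of w_ligand over significant edges with source P;
    receptor_score(P) = sum of w_receptor over significant edges with target
    P.  Pairwise matrices tally edge counts (significant and all) and total
    weight between ordered population pairs.
    """
    pops = sorted(set(edges["source"]) | set(edges["target"])) if len(edges) else []
    sig = edges[edges["p_perm"] < alpha] if "p_perm" in edges else edges.iloc[0:0]
    lig = {p: float(sig.loc[sig["source"] == p, "w_ligand"].sum()) for p in pops}
    rec = {p: float(sig.loc[sig["target"] == p, "w_receptor"].sum()) for p in pops}

    def _matrix(df: pd.DataFrame, value: str | None) -> pd.DataFrame:
        m = pd.DataFrame(0.0, index=pops, columns=pops)
        for row in df.itertuples():
            m.loc[row.source, row.target] += 1.0 if value is None else getattr(row, value)
        return m

    return NetworkSummary(
        ligand_scores=lig,
        receptor_scores=rec,
        edge_counts=_matrix(sig, None),
        edge_counts_all=_matrix(edges, None),
        edge_weights=_matrix(sig, "weight"),
    )


def to_networkx(edges: pd.DataFrame, alpha: float = 0.05):
    """Significant-edge multigraph for plotting/export (GraphML-friendly)."""
    import networkx as nx

    g = nx.MultiDiGraph()
    sig = edges[edges["p_perm"] < alpha] if "p_perm" in edges else edges
    for row in sig.itertuples():
        g.add_edge(
            row.source,
            row.target,
            ligand=row.ligand,
            receptor=row.receptor,
            weight=float(row.weight),
        )
    return g
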