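"""Cluster annotation enrichment: hypergeometric tests, BH FDR, and
permutation controls (uniform and composition-matched samplers) scored by the
sum of the top ten -log10 Q-values."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cluster import ClusterAssignment
from .io import AnnotationTable

_EPS = np.finfo(float).eps


def map_idrs_to_proteins(
    assignment: ClusterAssignment, idr_to_protein: dict[str, str]
) -> dict[str, set[str]]:
    """Deduplicated protein sets per cluster; a protein contributing IDRs to
    several clusters appears in each of them."""
    out: dict[str, set[str]] = {}
    for lab, members in assignment.clusters.items():
        out[lab] = {idr_to_protein[m] for m in members if m in idr_to_protein}
    return out


def filter_terms(
    table: AnnotationTable, max_genes: int = 5000, classes=("GO",)
) -> AnnotationTable:
    """Remove terms annotated to more than ``max_genes`` proteins.  Applied to
    the listed term classes only (GO by default)."""
    if table.term_class not in classes:
        return table
    sizes = table.term_sizes
    big = {t for t, n in sizes.items() if n > max_genes}
    if not big:
        return table
    return AnnotationTable(
        protein_terms={p: ts - big for p, ts in table.protein_terms.items()},
        term_class=table.term_class,
    )


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n, K): k positives in a
    cluster of K proteins when n of the N background proteins carry the term."""
    if not (0 <= k <= min(K, n) <= N) or K > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, n, K))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EnrichmentResult:
    cluster: str
    table: pd.DataFrame  # term, k, K, n, N, p, q per row

    def retained(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr].reset_index(drop=True)


def enrich_cluster(
    cluster_proteins: set[str],
    background: set[str],
    annotations: AnnotationTable,
    max_genes: int = 5000,
) -> pd.DataFrame:
    """Hypergeometric enrichment of every (size-filtered) term in one cluster
    against the background, BH-corrected within the cluster."""
    annotations = filter_terms(annotations, max_genes=max_genes)
    cluster_proteins = cluster_proteins & background
    K = len(cluster_proteins)
    N = len(background)
    rows = []
    term_members: dict[str, set[str]] = {}
    for prot in background:
        for t in annotations.protein_terms.get(prot, ()):
            term_members.setdefault(t, set()).add(prot)
    for term in sorted(term_members):
        members = term_members[term]
        n = len(members)
        k = len(members & cluster_proteins)
        rows.append((term, k, K, n, N, hypergeom_test(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def enrich_all(
    assignment: ClusterAssignment,
    idr_to_protein: dict[str, str],
    annotations: AnnotationTable,
    max_genes: int = 5000,
    pool_bh: bool = False,
) -> pd.DataFrame:
    """Enrichment table over all clusters.  Background = all proteins
    contributing at least one clustered IDR.  ``pool_bh`` switches the BH
    correction from per-cluster (default) to pooled across clusters."""
    background = {
        idr_to_protein[i]
        for i in assignment.items
        if i in idr_to_protein
    }
    cluster_proteins = map_idrs_to_proteins(assignment, idr_to_protein)
    parts = []
    for lab in sorted(cluster_proteins):
        df = enrich_cluster(
            cluster_proteins[lab], background, annotations, max_genes=max_genes
        )
        df.insert(0, "cluster", lab)
        parts.append(df)
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["cluster", "term", "k", "K", "n", "N", "p", "q"]
    )
    if pool_bh and len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def top_ten_statistic(qvals) -> float:
    """Sum of the ten largest -log10 q-values (fewer contribute if fewer
    tests; zero-q floored at machine epsilon)."""
    q = np.asarray(qvals, dtype=float)
    if q.size == 0:
        return 0.0
    logq = -np.log10(np.maximum(q, _EPS))
    top = np.sort(logq)[::-1][:10]
    return float(top.sum())


@dataclass
class PermutationResult:
    cluster: str
    sampler: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_perm: int


def per_term_permutation_z(
    cluster_label: str,
    assignment: ClusterAssignment,
    idr_to_protein: dict[str, str],
    annotations: AnnotationTable,
    n_perm: int = 200,
    seed: int = 0,
    max_genes: int = 5000,
) -> pd.DataFrame:
    """Per-term Z of observed -log10 q against uniformly permuted clusters.

    Columns: term, observed q, -log10 q, null mean/sd of -log10 q, Z.
    """
    members = assignment.members(cluster_label)
    if not members:
        raise ValueError(f"unknown or empty cluster {cluster_label!r}")
    pool = [i for i in assignment.items if assignment.labels[i]]
    background = {idr_to_protein[i] for i in pool if i in idr_to_protein}
    annotations = filter_terms(annotations, max_genes=max_genes)

    def qtable(idrs) -> pd.Series:
        proteins = {idr_to_protein[i] for i in idrs if i in idr_to_protein}
        df = enrich_cluster(proteins, background, annotations, max_genes=max_genes)
        return df.set_index("term")["q"]

    obs = qtable(members)
    rng = np.random.default_rng(seed)
    null_logq = np.empty((n_perm, len(obs)))
    for b in range(n_perm):
        idx = rng.choice(len(pool), size=len(members), replace=False)
        q = qtable([pool[j] for j in idx]).reindex(obs.index).fillna(1.0)
        null_logq[b] = -np.log10(np.maximum(q.to_numpy(), _EPS))
    obs_logq = -np.log10(np.maximum(obs.to_numpy(), _EPS))
    mu = null_logq.mean(axis=0)
    sd = null_logq.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (obs_logq - mu) / sd, np.nan)
    return pd.DataFrame(
        {
            "term": obs.index,
            "q": obs.to_numpy(),
            "neg_log10_q": obs_logq,
            "null_mean": mu,
            "null_sd": sd,
            "Z": z,
        }
    )


def permutation_z(
    cluster_label: str,
    assignment: ClusterAssignment,
    idr_to_protein: dict[str, str],
    annotations: AnnotationTable,
    sampler: str = "uniform",
    composition_cells: dict[str, str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    max_genes: int = 5000,
) -> PermutationResult:
    """Observed top-ten statistic for a cluster versus equally sized clusters
    sampled from the clustered IDR pool.

    ``uniform`` draws members uniformly without replacement; the
    ``composition_matched`` sampler replaces each member with a uniform draw
    from its composition k-means cell (``composition_cells``: idr -> cell).
    """
    members = assignment.members(cluster_label)
    if not members:
        raise ValueError(f"unknown or empty cluster {cluster_label!r}")
    pool = [i for i in assignment.items if assignment.labels[i]]
    background = {idr_to_protein[i] for i in pool if i in idr_to_protein}
    annotations = filter_terms(annotations, max_genes=max_genes)

    def score(idrs) -> float:
        proteins = {idr_to_protein[i] for i in idrs if i in idr_to_protein}
        df = enrich_cluster(proteins, background, annotations, max_genes=max_genes)
        return top_ten_statistic(df["q"].to_numpy())

    observed = score(members)
    rng = np.random.default_rng(seed)
    if sampler == "uniform":
        draws = [
            [pool[j] for j in rng.choice(len(pool), size=len(members), replace=False)]
            for _ in range(n_perm)
        ]
    elif sampler == "composition_matched":
        if composition_cells is None:
            raise ValueError("composition_matched sampler needs composition_cells")
        by_cell: dict[str, list[str]] = {}
        for i in pool:
            by_cell.setdefault(composition_cells[i], []).append(i)
        draws = []
        for _ in range(n_perm):
            repl = [
                by_cell[composition_cells[m]][
                    rng.integers(len(by_cell[composition_cells[m]]))
                ]
                for m in members
            ]
            draws.append(repl)
    else:
        raise ValueError(f"unknown sampler {sampler!r}")
    null = np.array([score(d) for d in draws])
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mu)):
        warnings.warn(
            f"degenerate permutation null for cluster {cluster_label}", stacklevel=2
        )
        z = float("nan")
    else:
        z = (observed - mu) / sd
    return PermutationResult(
        cluster=cluster_label,
        sampler=sampler,
        observed=observed,
        null_mean=mu,
        null_sd=sd,
        z=z,
        n_perm=n_perm,
    )
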