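"""Empirical p-values and Z-score evolutionary signatures.

For each feature we summarize the across-ortholog distribution by its mean
and natural-log unbiased variance, compare the real ortholog set's summaries
to the simulated null ensemble, and emit a 2F signature vector (mean-Z block
then log-variance-Z block, catalog order).  MISSING is NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureCatalog, compute_features
from .simulate import SimulatedEnsemble


def summarize(values) -> tuple[float, float, int]:
    """(mean, log-variance, n_used) of the defined values.

    MISSING (NaN) mean with < 2 defined values; MISSING log-variance when the
    unbiased variance is zero."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 2:
        return (np.nan, np.nan, n)
    var = float(np.var(v, ddof=1))
    logvar = np.log(var) if var > 0 else np.nan
    return (float(v.mean()), logvar, n)


def empirical_pvalue(obs: float, null) -> float:
    """Two-tailed add-one empirical p-value on the replicate grid:
    ``p = min(1, 2 * min((1+#{null>=obs}), (1+#{null<=obs})) / (n+1))``."""
    null = np.asarray(null, dtype=float)
    null = null[np.isfinite(null)]
    n = null.size
    if n == 0:
        raise ValueError("empty null distribution")
    if not np.isfinite(obs):
        return np.nan
    p_hi = (1 + np.sum(null >= obs)) / (n + 1)
    p_lo = (1 + np.sum(null <= obs)) / (n + 1)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def zscore(x: float, mu: float, sigma: float) -> float:
    """(x - mu) / sigma; MISSING when sigma is zero or undefined."""
    if not np.isfinite(x) or not np.isfinite(mu) or not np.isfinite(sigma):
        return np.nan
    if sigma <= 0:
        return np.nan
    return (x - mu) / sigma


@dataclass
class NullDistribution:
    """Replicate-level feature summaries for one ensemble.

    ``means`` and ``logvars`` are (n_replicates, F) arrays in catalog order.
    """

    feature_names: list[str]
    means: np.ndarray
    logvars: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.means.shape[0]

    def mu_sigma(self):
        """Per-feature (mu, sigma) over defined replicates, for both
        statistics.  Cells with < 2 defined replicates are MISSING."""
        out = {}
        for stat, arr in (("mean", self.means), ("logvar", self.logvars)):
            finite = np.isfinite(arr)
            n_def = finite.sum(axis=0)
            filled = np.where(finite, arr, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mu = filled.sum(axis=0) / n_def
                ss = (np.where(finite, arr - mu, 0.0) ** 2).sum(axis=0)
                sd = np.sqrt(ss / (n_def - 1))
            mu = np.where(n_def >= 2, mu, np.nan)
            sd = np.where((n_def >= 2) & (sd > 0), sd, np.nan)
            out[stat] = (mu, sd)
        return out


def ortholog_feature_table(
    seqs: dict[str, str], catalog: FeatureCatalog
) -> pd.DataFrame:
    """Per-ortholog feature values (rows = species, columns = catalog)."""
    return pd.DataFrame.from_dict(
        {sp: compute_features(s, catalog) for sp, s in seqs.items() if s},
        orient="index",
        columns=catalog.names,
    )


def summarize_set(seqs: dict[str, str], catalog: FeatureCatalog):
    """(means, logvars) arrays over the catalog for one ortholog set."""
    F = len(catalog)
    rows = [
        np.fromiter(
            compute_features(s, catalog).values(), dtype=float, count=F
        )
        for s in seqs.values()
        if s
    ]
    means = np.full(F, np.nan)
    logvars = np.full(F, np.nan)
    if len(rows) < 2:
        return means, logvars
    table = np.vstack(rows)
    finite = np.isfinite(table)
    n_def = finite.sum(axis=0)
    filled = np.where(finite, table, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = filled.sum(axis=0) / n_def
        ss = (np.where(finite, table - mu, 0.0) ** 2).sum(axis=0)
        var = ss / (n_def - 1)
        logv = np.log(var)
    means[n_def >= 2] = mu[n_def >= 2]
    ok = (n_def >= 2) & (var > 0)
    logvars[ok] = logv[ok]
    return means, logvars


def null_distribution(
    ensemble: SimulatedEnsemble, catalog: FeatureCatalog
) -> NullDistribution:
    reps = ensemble.nonempty_replicates()
    means = np.empty((len(reps), len(catalog)))
    logvars = np.empty((len(reps), len(catalog)))
    for i, rep in enumerate(reps):
        means[i], logvars[i] = summarize_set(rep, catalog)
    return NullDistribution(
        feature_names=catalog.names, means=means, logvars=logvars
    )


@dataclass
class SignatureVector:
    """2F-dimensional Z-score signature: mean-Z block then log-variance-Z
    block, each in catalog order."""

    idr_id: str
    z: np.ndarray
    feature_names: list[str]

    @property
    def dimension(self) -> int:
        return len(self.z)

    @property
    def presence(self) -> float:
        return float(np.mean(np.isfinite(self.z)))

    @property
    def labels(self) -> list[str]:
        return [f"mean_Z:{n}" for n in self.feature_names] + [
            f"logvar_Z:{n}" for n in self.feature_names
        ]


@dataclass
class SignificanceCall:
    """Per-feature empirical p-values for mean and log-variance at level alpha."""

    idr_id: str
    feature_names: list[str]
    p_mean: np.ndarray
    p_logvar: np.ndarray
    alpha: float = 0.01

    @property
    def significant_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_mean < self.alpha

    @property
    def significant_logvar(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_logvar < self.alpha


def build_signature_from_summaries(
    idr_id: str,
    real_means: np.ndarray,
    real_logvars: np.ndarray,
    null: NullDistribution,
    alpha: float = 0.01,
) -> tuple[SignatureVector, SignificanceCall]:
    F = len(null.feature_names)
    ms = null.mu_sigma()
    z = np.full(2 * F, np.nan)
    p_mean = np.full(F, np.nan)
    p_logvar = np.full(F, np.nan)
    for j in range(F):
        for block, (x, arr, pvec) in enumerate(
            (
                (real_means[j], null.means[:, j], p_mean),
                (real_logvars[j], null.logvars[:, j], p_logvar),
            )
        ):
            stat = "mean" if block == 0 else "logvar"
            mu, sd = ms[stat][0][j], ms[stat][1][j]
            z[block * F + j] = zscore(x, mu, sd)
            col = arr[np.isfinite(arr)]
            if col.size and np.isfinite(x):
                pvec[j] = empirical_pvalue(x, col)
    sig = SignatureVector(idr_id=idr_id, z=z, feature_names=list(null.feature_names))
    call = SignificanceCall(
        idr_id=idr_id,
        feature_names=list(null.feature_names),
        p_mean=p_mean,
        p_logvar=p_logvar,
        alpha=alpha,
    )
    return sig, call


def build_signature(
    real_seqs: dict[str, str],
    ensemble: SimulatedEnsemble,
    catalog: FeatureCatalog | None = None,
    alpha: float = 0.01,
    idr_id: str = "",
) -> tuple[SignatureVector, SignificanceCall]:
    """Signature + significance for one real ortholog set against its null."""
    catalog = catalog or FeatureCatalog.default()
    real_means, real_logvars = summarize_set(real_seqs, catalog)
    null = null_distribution(ensemble, catalog)
    return build_signature_from_summaries(
        idr_id or ensemble.idr_id, real_means, real_logvars, null, alpha=alpha
    )


def count_significant(call: SignificanceCall) -> int:
    """Features significant in mean, log-variance, or both (counted once)."""
    return int(np.sum(call.significant_mean | call.significant_logvar))


def chance_expectation(
    nulls: list[NullDistribution], seed: int, alpha: float = 0.01
) -> np.ndarray:
    """Significant-feature counts when a random replicate of each ensemble is
    scored against the remaining replicates (leave-one-out)."""
    rng = np.random.default_rng(seed)
    counts = []
    for null in nulls:
        n = null.n_replicates
        if n < 3:
            raise ValueError("need >= 3 replicates for a leave-one-out null")
        pick = int(rng.integers(n))
        keep = np.ones(n, dtype=bool)
        keep[pick] = False
        loo = NullDistribution(
            feature_names=null.feature_names,
            means=null.means[keep],
            logvars=null.logvars[keep],
        )
        _, call = build_signature_from_summaries(
            "chance", null.means[pick], null.logvars[pick], loo, alpha=alpha
        )
        counts.append(count_significant(call))
    return np.array(counts)


def chance_count_distribution(nulls: list[NullDistribution]) -> np.ndarray:
    """Exhaustive version of :func:`chance_expectation`: every replicate of
    every ensemble is scored leave-one-out against its peers, returning the
    full distribution of significant-feature counts (one entry per
    replicate x IDR).  Identical quantity, enumeration instead of a random
    draw."""
    out = []
    for null in nulls:
        n = null.n_replicates
        sig = np.zeros((n, len(null.feature_names)), dtype=bool)
        for arr in (null.means, null.logvars):
            for j in range(arr.shape[1]):
                v = arr[:, j]
                fin = np.isfinite(v)
                vv = v[fin]
                m = vv.size
                if m < 3:
                    continue
                order = np.sort(vv)
                # ties included, self excluded; null size m-1 -> denominator m
                c_hi = m - np.searchsorted(order, vv, side="left") - 1
                c_lo = np.searchsorted(order, vv, side="right") - 1
                p = 2.0 * np.minimum(c_hi + 1, c_lo + 1) / m
                sig[np.flatnonzero(fin)[p < 0.01], j] |= True
        out.append(sig.sum(axis=1))
    return np.concatenate(out)


def filter_signatures(
    signatures: list[SignatureVector],
    min_abs_z: float = 3.0,
    min_presence: float = 0.95,
) -> list[SignatureVector]:
    """Keep signatures with max |Z| >= ``min_abs_z`` and data presence >=
    ``min_presence``."""
    kept = []
    for s in signatures:
        finite = s.z[np.isfinite(s.z)]
        if finite.size == 0:
            continue
        if np.max(np.abs(finite)) >= min_abs_z and s.presence >= min_presence:
            kept.append(s)
    return kept


def signature_matrix(signatures: list[SignatureVector]) -> pd.DataFrame:
    """Stack signatures into a (IDR x 2F) DataFrame, NaN for MISSING."""
    if not signatures:
        raise ValueError("no signatures to stack")
    labels = signatures[0].labels
    return pd.DataFrame(
        [s.z for s in signatures],
        index=[s.idr_id for s in signatures],
        columns=labels,
    )
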