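"""Column and local evolutionary-rate estimation and conserved-segment masking.

Per-column rate multipliers are maximum-likelihood under the pruning
algorithm with gaps treated as missing data.  The conserved-segment mask
comes from a two-state HMM contrasting each column's rate against the local
(31-column window) rate: a "conserved" state evolving at ``rho * local``
(rho < 1) versus background at the local rate.  This is a declared
simplification of indel-aware phylo-HMMs; externally computed masks can be
supplied downstream instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .io import GAP, AlignedOrthologSet, Phylogeny
from .simulate import N_STATES, SubstitutionModel, _AA_TO_INT

logger = logging.getLogger(__name__)

RATE_LOWER = 1e-4
RATE_UPPER = 100.0


@dataclass
class RateProfile:
    """Per-column rates, windowed local rates, and the conservation mask."""

    column_rates: np.ndarray
    local_rates: np.ndarray
    posterior: np.ndarray
    mask: np.ndarray
    window: int = 31
    rho: float = float("nan")
    log_likelihood: float = float("nan")

    @property
    def n_columns(self) -> int:
        return len(self.column_rates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(self.n_columns),
                "rate": self.column_rates,
                "local_rate": self.local_rates,
                "posterior": self.posterior,
                "mask": self.mask.astype(int),
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def local_rates(column_rates: np.ndarray, window: int = 31) -> np.ndarray:
    """Centered moving average of column rates, ignoring MISSING (NaN)
    entries, with edge windows truncated."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(column_rates, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        w = x[max(0, i - half): i + half + 1]
        w = w[np.isfinite(w)]
        out[i] = w.mean() if w.size else np.nan
    return out


def region_divergence(tree: Phylogeny) -> float:
    """Total branch length of a region's fitted tree."""
    return tree.total_length


class RateEstimator:
    """Pruning-algorithm likelihood machinery for one alignment + tree."""

    def __init__(
        self,
        oset: AlignedOrthologSet,
        tree: Phylogeny,
        model: SubstitutionModel | None = None,
    ):
        self.oset = oset
        self.tree = tree
        self.model = model or SubstitutionModel.default()
        leaves = set(tree.leaf_names)
        missing = set(oset.species) - leaves
        if missing:
            raise ValueError(f"species absent from tree: {sorted(missing)}")

        self.n_cols = oset.width
        # preorder node records: (parent, node_id, leaf_name, branch_length)
        self._nodes = list(tree.walk())
        obs = {}
        for sp, row in zip(oset.species, oset.rows):
            obs[sp] = np.array(
                [_AA_TO_INT.get(c, -1) if c != GAP else -1 for c in row],
                dtype=np.int64,
            )
        self._obs = obs
        col_counts = np.zeros(self.n_cols, dtype=int)
        for codes in obs.values():
            col_counts += codes >= 0
        self.column_coverage = col_counts

    def _leaf_partial(self, name: str) -> np.ndarray:
        codes = self._obs.get(name)
        part = np.ones((self.n_cols, N_STATES))
        if codes is None:
            return part  # tree leaf with no sequence: missing data
        seen = codes >= 0
        part[seen] = 0.0
        part[seen, codes[seen]] = 1.0
        return part

    def column_loglik(self, rates) -> np.ndarray:
        """Log-likelihood of every column with per-column rate multipliers
        (scalar broadcasts).  Vectorized over columns via the model's
        eigendecomposition."""
        m = self.model
        rates = np.broadcast_to(np.asarray(rates, dtype=float), (self.n_cols,))
        U, V, lam = m._U, m._V, m._eigvals
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_cols)
        children: dict[int, list[tuple[int, float]]] = {}
        root_id = None
        for parent, node_id, name, blen in self._nodes:
            if parent is None:
                root_id = node_id
            else:
                children.setdefault(parent, []).append((node_id, blen))
            if name is not None and node_id not in children:
                partials[node_id] = self._leaf_partial(name)
        # postorder = reversed preorder for dendropy's traversal
        for parent, node_id, name, blen in reversed(self._nodes):
            kids = children.get(node_id)
            if not kids:
                if node_id not in partials:  # internal node with no kids: skip
                    partials[node_id] = np.ones((self.n_cols, N_STATES))
                continue
            part = np.ones((self.n_cols, N_STATES))
            for kid, kblen in kids:
                child_part = partials.pop(kid)
                t = kblen * rates  # per-column distances
                E = np.exp(t[:, None] * lam[None, :])
                part *= ((child_part @ V.T) * E) @ U.T
            np.clip(part, 0.0, None, out=part)
            mx = part.max(axis=1)
            safe = mx > 0
            part[safe] /= mx[safe, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(safe, np.log(np.where(safe, mx, 1.0)), -np.inf)
            partials[node_id] = part
        root = partials[root_id]
        with np.errstate(divide="ignore"):
            return np.log(root @ m.freqs) + logscale

    def column_rates(self, n_grid: int = 41) -> np.ndarray:
        """Per-column ML rate in [1e-4, 100] by log-grid search with parabolic
        refinement; columns with < 2 ungapped residues are MISSING."""
        grid = np.exp(
            np.linspace(np.log(RATE_LOWER), np.log(RATE_UPPER), n_grid)
        )
        ll = np.stack([self.column_loglik(r) for r in grid])  # (grid, cols)
        best = np.argmax(ll, axis=0)
        log_grid = np.log(grid)
        rates = np.empty(self.n_cols)
        for j in range(self.n_cols):
            b = best[j]
            if b == 0 or b == n_grid - 1:
                rates[j] = grid[b]
                continue
            y0, y1, y2 = ll[b - 1, j], ll[b, j], ll[b + 1, j]
            denom = y0 - 2 * y1 + y2
            if denom >= 0:
                rates[j] = grid[b]
            else:
                step = log_grid[1] - log_grid[0]
                shift = 0.5 * step * (y0 - y2) / denom
                rates[j] = float(
                    np.exp(np.clip(log_grid[b] + shift,
                                   np.log(RATE_LOWER), np.log(RATE_UPPER)))
                )
        rates[self.column_coverage < 2] = np.nan
        return rates

    # -- two-state conservation HMM ------------------------------------

    def constraint_mask(
        self,
        column_rates: np.ndarray,
        local: np.ndarray,
        rho_init: float = 0.3,
        p_enter: float = 0.02,
        p_exit: float = 0.25,
        fit_transitions: bool = False,
        n_restarts: int = 3,
        max_iter: int = 50,
        tol: float = 1e-4,
        seed: int = 0,
        window: int = 31,
    ) -> tuple[np.ndarray, np.ndarray, float, float]:
        """Two-state HMM posterior decoding with EM-fitted rho.

        Transition probabilities are fixed by default (``p_enter`` into the
        conserved state, ``p_exit`` out of it): letting EM shrink them freely
        makes the conserved state absorb isolated chance-invariant columns
        and inflates the null mask rate well beyond 2%.  ``fit_transitions``
        enables the free-EM variant.  Returns (mask, posterior, rho,
        log_likelihood); with fewer columns than the local-rate window the
        mask is all-false (warned).
        """
        n = self.n_cols
        if n < window:
            warnings.warn(
                f"{n} columns < window {window}: conservation mask disabled",
                stacklevel=2,
            )
            return (
                np.zeros(n, dtype=bool), np.zeros(n), float("nan"), float("nan")
            )
        local = np.where(np.isfinite(local), local, np.nanmean(local))
        local = np.clip(local, RATE_LOWER, RATE_UPPER)
        log_bg = self.column_loglik(local)

        rng = np.random.default_rng(seed)
        best = None
        for restart in range(n_restarts):
            rho = rho_init if restart == 0 else float(rng.uniform(0.1, 0.8))
            fit = self._em(
                log_bg, local, rho, p_enter, p_exit, fit_transitions,
                max_iter, tol,
            )
            if best is None or fit[3] > best[3]:
                best = fit
        gamma, rho, trans, ll = best
        mask = gamma > 0.5
        return mask, gamma, rho, ll

    def _em(self, log_bg, local, rho, p_enter, p_exit, fit_transitions,
            max_iter, tol):
        trans = np.array([[1 - p_enter, p_enter], [p_exit, 1 - p_exit]])
        start = np.array([0.98, 0.02])  # background, conserved
        log_cons = self.column_loglik(np.clip(rho * local, RATE_LOWER, RATE_UPPER))
        prev_ll = -np.inf
        gamma = None
        for _ in range(max_iter):
            logB = np.stack([log_bg, log_cons], axis=1)  # (n, 2)
            gamma, xi_sum, ll = _forward_backward(logB, np.log(trans), np.log(start))
            if not np.isfinite(ll):
                break
            if fit_transitions:
                denom = xi_sum.sum(axis=1, keepdims=True)
                with np.errstate(invalid="ignore", divide="ignore"):
                    new_trans = np.where(denom > 0, xi_sum / denom, trans)
                trans = np.clip(new_trans, 1e-6, 1 - 1e-6)
                trans /= trans.sum(axis=1, keepdims=True)
                start = np.clip(gamma[0], 1e-6, 1 - 1e-6)
                start /= start.sum()
            # M-step: rho by bounded 1-D likelihood maximization
            g1 = gamma[:, 1]
            if g1.sum() > 1e-8:
                res = minimize_scalar(
                    lambda r: -float(
                        (g1 * self.column_loglik(
                            np.clip(r * local, RATE_LOWER, RATE_UPPER)
                        )).sum()
                    ),
                    bounds=(0.01, 0.99),
                    method="bounded",
                    options={"xatol": 1e-3},
                )
                rho = float(res.x)
                log_cons = self.column_loglik(
                    np.clip(rho * local, RATE_LOWER, RATE_UPPER)
                )
            if abs(ll - prev_ll) < tol:
                prev_ll = ll
                break
            prev_ll = ll
        return gamma[:, 1], rho, trans, prev_ll

    def profile(self, window: int = 31, seed: int = 0) -> RateProfile:
        col = self.column_rates()
        loc = local_rates(col, window=window)
        mask, post, rho, ll = self.constraint_mask(col, loc, seed=seed, window=window)
        return RateProfile(
            column_rates=col,
            local_rates=loc,
            posterior=post,
            mask=mask,
            window=window,
            rho=rho,
            log_likelihood=ll,
        )


def _forward_backward(logB, logT, log_start):
    """Scaled log-space forward-backward for a 2-state chain.

    Returns (gamma, expected transition counts, log-likelihood)."""
    n, k = logB.shape
    logB = np.where(np.isfinite(logB), logB, 0.0)  # missing columns: flat emission
    log_alpha = np.empty((n, k))
    log_alpha[0] = log_start + logB[0]
    for i in range(1, n):
        log_alpha[i] = logB[i] + logsumexp(
            log_alpha[i - 1][:, None] + logT, axis=0
        )
    ll = float(logsumexp(log_alpha[-1]))
    log_beta = np.zeros((n, k))
    for i in range(n - 2, -1, -1):
        log_beta[i] = logsumexp(
            logT + (logB[i + 1] + log_beta[i + 1])[None, :], axis=1
        )
    log_gamma = log_alpha + log_beta - ll
    gamma = np.exp(log_gamma)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((k, k))
    for i in range(n - 1):
        log_xi = (
            log_alpha[i][:, None]
            + logT
            + (logB[i + 1] + log_beta[i + 1])[None, :]
            - ll
        )
        xi_sum += np.exp(log_xi)
    return gamma, xi_sum, ll


def column_rates(
    oset: AlignedOrthologSet,
    tree: Phylogeny,
    model: SubstitutionModel | None = None,
) -> np.ndarray:
    return RateEstimator(oset, tree, model).column_rates()


def reference_site_rates(
    profile: RateProfile, oset: AlignedOrthologSet
) -> tuple[np.ndarray, np.ndarray]:
    """Map column rates/mask onto the reference row's ungapped positions.

    Returns (site_rates, site_mask) over reference residues; MISSING column
    rates fall back to the local rate, then to 1."""
    cols = [i for i, c in enumerate(oset.reference_row) if c != GAP]
    r = profile.column_rates[cols]
    loc = profile.local_rates[cols]
    r = np.where(np.isfinite(r), r, loc)
    r = np.where(np.isfinite(r), r, 1.0)
    return np.clip(r, RATE_LOWER, RATE_UPPER), profile.mask[cols]
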