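"""Null-model sequence evolution along a phylogeny.

A reversible 20-state substitution process (exact endpoint sampling through
the eigendecomposed transition kernel), power-law indels, optional
conservation-mask protection of root residues, and distance-scaling
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from importlib import resources

import numpy as np
import yaml

from .io import AA_ALPHABET, Phylogeny, Rejected

N_STATES = 20
_AA_TO_INT = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def encode(seq: str) -> np.ndarray:
    return np.array([_AA_TO_INT[c] for c in seq], dtype=np.int64)


def decode(states: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in states)


class SubstitutionModel:
    """Reversible amino-acid substitution model normalized to one expected
    substitution per site per unit time.

    ``q_ab = s_ab * pi_b`` off-diagonal, diagonal closes rows to zero, and the
    whole matrix is rescaled so ``-sum_a pi_a q_aa = 1``.
    """

    def __init__(self, freqs: np.ndarray, exchangeabilities: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        s = np.asarray(exchangeabilities, dtype=float)
        if freqs.shape != (N_STATES,):
            raise ValueError("freqs must have 20 entries")
        if np.any(freqs < 0) or np.any(s < 0):
            raise ValueError("negative model entries")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("stationary frequencies must sum to 1")
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        s = s.copy()
        np.fill_diagonal(s, 0.0)

        Q = s * freqs[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(freqs * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        Q /= mu

        self.freqs = freqs
        self.exchangeabilities = s
        self.Q = Q

        # reversible -> symmetrizable; eigendecompose once, P(t) cheap forever
        d = np.sqrt(freqs)
        B = (Q * d[:, None]) / d[None, :]
        eigvals, R = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = eigvals
        self._U = R / d[:, None]
        self._V = R.T * d[None, :]

    @classmethod
    def from_dict(cls, spec: dict) -> "SubstitutionModel":
        freqs = np.array([spec["stationary_freqs"][aa] for aa in AA_ALPHABET])
        ex = spec.get("exchangeabilities", "uniform")
        if isinstance(ex, str):
            if ex != "uniform":
                raise ValueError(f"unknown exchangeability preset {ex!r}")
            s = np.ones((N_STATES, N_STATES))
        else:
            s = np.array(
                [[ex[a].get(b, ex[b].get(a, 0.0)) for b in AA_ALPHABET]
                 for a in AA_ALPHABET],
                dtype=float,
            )
        return cls(freqs, s)

    @classmethod
    def default(cls) -> "SubstitutionModel":
        with resources.files("idrsig.data").joinpath("sub_model.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def uniform(cls) -> "SubstitutionModel":
        """Jukes-Cantor-style 20-state model (equal frequencies and rates)."""
        return cls(np.full(N_STATES, 1 / N_STATES), np.ones((N_STATES, N_STATES)))

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._U * np.exp(self._eigvals * t)[None, :]) @ self._V
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_rows(self, states: np.ndarray, dists) -> np.ndarray:
        """Row ``P(dists[i])[states[i], :]`` for each site i, vectorized."""
        states = np.asarray(states)
        dists = np.broadcast_to(np.asarray(dists, dtype=float), states.shape)
        E = np.exp(dists[:, None] * self._eigvals[None, :])
        P = (self._U[states] * E) @ self._V
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def sample_transitions(
        self, states: np.ndarray, dists, rng: np.random.Generator
    ) -> np.ndarray:
        if len(states) == 0:
            return states.copy()
        cum = np.cumsum(self.transition_rows(states, dists), axis=1)
        u = rng.random(len(states)) * cum[:, -1]
        return np.minimum((u[:, None] >= cum).sum(axis=1), N_STATES - 1)

    def expected_identity(self, t: float) -> float:
        """P(no observed change) for a site at stationarity after time t."""
        return float(self.freqs @ np.diag(self.transition_matrix(t)))


def build_rate_matrix(freqs, exchangeabilities) -> SubstitutionModel:
    return SubstitutionModel(freqs, exchangeabilities)


def estimate_stationary_freqs(seqs, pseudocount: float = 1.0) -> np.ndarray:
    """Pooled residue frequencies with ``pseudocount`` added per residue type."""
    counts = np.full(N_STATES, float(pseudocount))
    for seq in seqs:
        for c in seq:
            counts[_AA_TO_INT[c]] += 1
    return counts / counts.sum()


@dataclass(frozen=True)
class IndelModel:
    """Power-law indel process: rates per residue per unit time; lengths
    truncated-Zipf with exponent ``alpha``; inserted residues drawn from the
    substitution model's stationary frequencies."""

    ins_rate: float = 0.03
    del_rate: float = 0.03
    alpha: float = 1.8
    max_length: int = 50

    def __post_init__(self) -> None:
        if self.ins_rate < 0 or self.del_rate < 0:
            raise ValueError("indel rates must be >= 0")
        if self.alpha <= 1:
            raise ValueError("Zipf exponent must exceed 1")
        if self.max_length < 1:
            raise ValueError("max indel length must be >= 1")

    @cached_property
    def length_pmf(self) -> np.ndarray:
        k = np.arange(1, self.max_length + 1, dtype=float)
        w = k ** (-self.alpha)
        return w / w.sum()

    def sample_length(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.max_length, p=self.length_pmf)) + 1

    @classmethod
    def none(cls) -> "IndelModel":
        return cls(ins_rate=0.0, del_rate=0.0)


@dataclass
class _SiteState:
    aa: np.ndarray       # int residue codes
    rate: np.ndarray     # per-site rate multipliers
    masked: np.ndarray   # bool, protected root residues
    origin: np.ndarray   # root position index, -1 for inserted sites

    def copy(self) -> "_SiteState":
        return _SiteState(
            self.aa.copy(), self.rate.copy(), self.masked.copy(), self.origin.copy()
        )

    def __len__(self) -> int:
        return len(self.aa)


def _apply_deletion(state: _SiteState, length: int, rng) -> _SiteState:
    L = len(state)
    unmasked = np.flatnonzero(~state.masked)
    if unmasked.size == 0:
        return state
    start = int(unmasked[rng.integers(unmasked.size)])
    end = min(start + length, L)
    blocked = np.flatnonzero(state.masked[start:end])
    if blocked.size:  # truncate at the unmasked flank before the mask
        end = start + int(blocked[0])
    if end <= start:
        return state
    keep = np.ones(L, dtype=bool)
    keep[start:end] = False
    return _SiteState(
        state.aa[keep], state.rate[keep], state.masked[keep], state.origin[keep]
    )


def _apply_insertion(
    state: _SiteState, length: int, model: SubstitutionModel, rng
) -> _SiteState:
    pos = int(rng.integers(len(state) + 1))
    new_aa = rng.choice(N_STATES, size=length, p=model.freqs)
    return _SiteState(
        np.insert(state.aa, pos, new_aa),
        np.insert(state.rate, pos, np.ones(length)),
        np.insert(state.masked, pos, np.zeros(length, dtype=bool)),
        np.insert(state.origin, pos, np.full(length, -1, dtype=np.int64)),
    )


def _evolve_branch(
    state: _SiteState,
    t: float,
    model: SubstitutionModel,
    indels: IndelModel,
    rng: np.random.Generator,
) -> _SiteState:
    state = state.copy()
    if t <= 0 or len(state) == 0:
        return state
    state.aa = model.sample_transitions(state.aa, state.rate * t, rng)
    L = len(state)
    n_ins = rng.poisson(indels.ins_rate * t * L)
    n_del = rng.poisson(indels.del_rate * t * L)
    events = np.array(["I"] * n_ins + ["D"] * n_del)
    rng.shuffle(events)
    for ev in events:
        if len(state) == 0:
            break
        length = indels.sample_length(rng)
        if ev == "I":
            state = _apply_insertion(state, length, model, rng)
        else:
            state = _apply_deletion(state, length, rng)
    return state


def evolve_sequence(
    root: str,
    tree: Phylogeny,
    rates=1.0,
    model: SubstitutionModel | None = None,
    indels: IndelModel | None = None,
    scale: float = 1.0,
    seed=None,
    mask=None,
    return_origins: bool = False,
):
    """Simulate one ortholog set: evolve ``root`` down every branch of *tree*.

    ``rates`` is a scalar rate multiplier or a per-root-site array; ``mask``
    flags root positions that must never be deleted (substitutions still occur
    at their — typically slow — site rate).  An empty leaf sequence is a legal
    outcome under deletion.  Returns ``{leaf: sequence}``, plus
    ``{leaf: origin array}`` (root position per site, -1 for insertions) when
    ``return_origins`` is set.
    """
    if not root:
        raise ValueError("empty root sequence")
    if seed is None:
        raise ValueError("seed is mandatory for simulation")
    model = model or SubstitutionModel.default()
    indels = indels or IndelModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = len(root)
    rate_arr = np.broadcast_to(np.asarray(rates, dtype=float), (L,)).copy()
    if np.any(rate_arr <= 0):
        raise ValueError("site rates must be positive")
    mask_arr = (
        np.zeros(L, dtype=bool)
        if mask is None
        else np.asarray(mask, dtype=bool).copy()
    )
    if mask_arr.shape != (L,):
        raise ValueError("mask length must equal root length")
    states: dict[int, _SiteState] = {}
    leaves: dict[str, str] = {}
    origins: dict[str, np.ndarray] = {}
    for parent, node_id, name, blen in tree.walk():
        if parent is None:
            states[node_id] = _SiteState(
                encode(root), rate_arr, mask_arr, np.arange(L, dtype=np.int64)
            )
        else:
            states[node_id] = _evolve_branch(
                states[parent], blen * scale, model, indels, rng
            )
        if name is not None:
            leaves[name] = decode(states[node_id].aa)
            origins[name] = states[node_id].origin.copy()
    if return_origins:
        return leaves, origins
    return leaves


@dataclass
class SimulatedEnsemble:
    """N replicate null ortholog sets for one IDR."""

    idr_id: str
    replicates: list[dict[str, str]]

    @property
    def n(self) -> int:
        return len(self.replicates)

    @property
    def n_nonempty(self) -> int:
        return sum(
            1 for rep in self.replicates if all(len(s) > 0 for s in rep.values())
        )

    def nonempty_replicates(self) -> list[dict[str, str]]:
        return [r for r in self.replicates if all(len(s) > 0 for s in r.values())]


def simulate_ensemble(
    root: str,
    tree: Phylogeny,
    rates=1.0,
    model: SubstitutionModel | None = None,
    indels: IndelModel | None = None,
    scale: float = 1.0,
    n: int = 1000,
    seed=None,
    mask=None,
    idr_id: str = "",
) -> SimulatedEnsemble:
    """Simulate ``n`` independent replicates with per-replicate derived seeds
    ``(seed, i)``; fully reproducible given ``(seed, n)``."""
    if seed is None:
        raise ValueError("seed is mandatory for simulation")
    reps = []
    for i in range(n):
        rng = np.random.default_rng([int(seed), i])
        reps.append(
            evolve_sequence(
                root, tree, rates=rates, model=model, indels=indels,
                scale=scale, seed=rng, mask=mask,
            )
        )
    return SimulatedEnsemble(idr_id=idr_id, replicates=reps)


def filter_ensemble(
    ensemble: SimulatedEnsemble, min_nonempty: int = 950
) -> SimulatedEnsemble | Rejected:
    """Reject ensembles with fewer than ``min_nonempty`` fully non-empty
    replicates; accepted ensembles keep only the non-empty replicates."""
    k = ensemble.n_nonempty
    if k < min_nonempty:
        return Rejected(
            reason=f"{k} non-empty replicates (< {min_nonempty} required)",
            idr_id=ensemble.idr_id,
        )
    return SimulatedEnsemble(
        idr_id=ensemble.idr_id, replicates=ensemble.nonempty_replicates()
    )


@dataclass(frozen=True)
class CalibrationResult:
    scale: float
    pre_mean: float
    post_mean: float
    n_used: int
    n_skipped: int


def calibrate_scaling(trees, taxon_a: str, taxon_b: str) -> CalibrationResult:
    """Scaling factor making the mean patristic distance between the two
    calibration taxa across the supplied trees equal one."""
    dists = []
    skipped = 0
    for tree in trees:
        leaves = set(tree.leaf_names)
        if taxon_a not in leaves or taxon_b not in leaves:
            skipped += 1
            continue
        dists.append(tree.patristic_distance(taxon_a, taxon_b))
    if not dists:
        raise ValueError(
            f"no tree contains both calibration taxa {taxon_a!r} and {taxon_b!r}"
        )
    pre = float(np.mean(dists))
    if pre <= 0:
        raise ValueError("mean calibration distance is zero")
    s = 1.0 / pre
    return CalibrationResult(
        scale=s, pre_mean=pre, post_mean=s * pre, n_used=len(dists), n_skipped=skipped
    )
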