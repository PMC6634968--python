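"""Molecular-feature engine: catalog loading and per-sequence feature computation.

Features are computed on ungapped amino-acid sequences.  MISSING values are
represented as ``math.nan`` and arise only when a feature's definedness
predicate fails (e.g. charge patterning on a charge-free sequence).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .io import AA_ALPHABET

MISSING = math.nan

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")

FAMILIES = (
    "composition",
    "charge",
    "patterning",
    "complexity",
    "motif",
    "repeat",
    "physicochemical",
    "length",
)


def _load_constants() -> dict:
    with resources.files("idrsig.data").joinpath("constants.yaml").open() as fh:
        return yaml.safe_load(fh)


_CONSTANTS = _load_constants()
DEFAULT_PKA = _CONSTANTS["pka"]
HYDROPATHY_SCALES = _CONSTANTS["hydropathy_scales"]


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    family: str
    params: dict = field(default_factory=dict)
    defined_when: str = ""

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")


class FeatureCatalog:
    """An ordered, named collection of feature definitions."""

    def __init__(self, features: list[FeatureDefinition]):
        names = [f.name for f in features]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        self.features = list(features)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @classmethod
    def from_dict(cls, spec: dict) -> "FeatureCatalog":
        feats = [
            FeatureDefinition(
                name=d["name"],
                family=d["family"],
                params=dict(d.get("params") or {}),
                defined_when=d.get("defined_when", ""),
            )
            for d in spec["features"]
        ]
        return cls(feats)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalog":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FeatureCatalog":
        return _default_catalog()


@lru_cache(maxsize=1)
def _default_catalog() -> FeatureCatalog:
    with resources.files("idrsig.data").joinpath("catalog.yaml").open() as fh:
        return FeatureCatalog.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# primitive feature operations (public, individually testable)


def _check_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    if "-" in seq:
        raise ValueError("gapped sequence passed to feature computation")


def aa_fraction(seq: str, residue_set) -> float:
    """Fraction of residues belonging to ``residue_set``."""
    _check_seq(seq)
    rs = set(residue_set)
    return sum(1 for c in seq if c in rs) / len(seq)


def _phospho_sites(seq: str, pattern: str = "[ST]P") -> list[int]:
    return [m.start() for m in re.finditer(f"(?=({pattern}))", seq)]


def net_charge(
    seq: str,
    phospho_sites=None,
    phospho_charge: float = -2.0,
) -> float:
    """+1 per K/R, -1 per D/E, H neutral; optional phosphosite charges added."""
    _check_seq(seq)
    q = sum(1 for c in seq if c in _POSITIVE) - sum(1 for c in seq if c in _NEGATIVE)
    if phospho_sites:
        q += phospho_charge * len(phospho_sites)
    return float(q)


def scd(seq: str) -> float:
    """Sequence charge decoration: (1/N) * sum_{i<j} q_i q_j sqrt(j-i)."""
    _check_seq(seq)
    pos = np.array([i for i, c in enumerate(seq) if c in _POSITIVE or c in _NEGATIVE])
    if pos.size < 2:
        return 0.0
    q = np.array([1.0 if seq[i] in _POSITIVE else -1.0 for i in pos])
    diff = pos[None, :] - pos[:, None]  # j - i for j > i in upper triangle
    iu = np.triu_indices(pos.size, k=1)
    return float(np.sum(q[iu[0]] * q[iu[1]] * np.sqrt(diff[iu])) / len(seq))


def _delta(groups: np.ndarray, blob_sizes, binary: bool) -> float:
    """Mean over blob sizes of mean squared deviation of blob asymmetry from
    global asymmetry.  ``groups``: +1 for group A, -1 for group B, 0 neutral
    (kappa split); for binary splits every residue is +1 or -1."""
    L = groups.size
    a = (groups > 0).astype(float)
    b = (groups < 0).astype(float)
    ca = np.empty(L + 1)
    cb = np.empty(L + 1)
    ca[0] = cb[0] = 0.0
    np.cumsum(a, out=ca[1:])
    np.cumsum(b, out=cb[1:])
    fa_g = ca[L] / L
    fb_g = cb[L] / L
    if binary:
        gsig = (fa_g - fb_g) ** 2
    else:
        denom_g = fa_g + fb_g
        gsig = (fa_g - fb_g) ** 2 / denom_g if denom_g > 0 else 0.0
    total = 0.0
    used = 0
    for g in blob_sizes:
        if L < g:
            continue
        fa = (ca[g:] - ca[:-g]) / g
        fb = (cb[g:] - cb[:-g]) / g
        if binary:
            sig = (fa - fb) ** 2
        else:
            denom = fa + fb
            diff = fa - fb
            sig = np.divide(
                diff * diff, denom,
                out=np.zeros_like(denom), where=denom > 0,
            )
        dev = sig - gsig
        total += float((dev * dev).sum() / dev.size)
        used += 1
    if not used:
        return MISSING
    return total / used


def _segregated_arrangements(groups: np.ndarray) -> list[np.ndarray]:
    """Candidate maximally segregated/sandwiched rearrangements of one
    composition.  Deterministic block layouts: one group contiguous, the
    other group and the neutrals split around it at the ends (whole, halved,
    or absent on each side) — the arrangements that attain or approach the
    maximum blob-demixing value."""
    na = int((groups > 0).sum())
    nb = int((groups < 0).sum())
    nn = int((groups == 0).sum())
    out = []
    seen = set()
    for x, y, nx in (((1,), (-1,), na), ((-1,), (1,), nb)):
        X, Y, N = list(x) * nx, list(y) * (na + nb - nx), [0] * nn
        for xl in {0, nx // 2, nx}:
            for nl in {0, nn // 2, nn}:
                arr = tuple(X[:xl] + N[:nl] + Y + N[nl:] + X[xl:])
                if arr not in seen:
                    seen.add(arr)
                    out.append(np.array(arr, dtype=float))
    return out


@lru_cache(maxsize=262144)
def _candidate_deltas(
    na: int, nb: int, nn: int, g: int, binary: bool
) -> np.ndarray:
    """Single-blob-size delta of every canonical candidate arrangement,
    batch-vectorized.  Cached per composition and blob size so multi-blob
    variants (and different patterning features sharing a composition) reuse
    the same work."""
    groups = np.array([1] * na + [-1] * nb + [0] * nn, dtype=float)
    cands = np.stack(_segregated_arrangements(groups))
    L = cands.shape[1]
    if L < g:
        return np.full(cands.shape[0], np.nan)
    a = (cands > 0).astype(float)
    b = (cands < 0).astype(float)
    ca = np.concatenate([np.zeros((cands.shape[0], 1)), np.cumsum(a, axis=1)], axis=1)
    cb = np.concatenate([np.zeros((cands.shape[0], 1)), np.cumsum(b, axis=1)], axis=1)
    fa = (ca[:, g:] - ca[:, :-g]) / g
    fb = (cb[:, g:] - cb[:, :-g]) / g
    fa_g = na / L
    fb_g = nb / L
    if binary:
        sig = (fa - fb) ** 2
        gsig = (fa_g - fb_g) ** 2
    else:
        denom = fa + fb
        diff = fa - fb
        sig = np.divide(diff * diff, denom, out=np.zeros_like(denom),
                        where=denom > 0)
        dg = fa_g + fb_g
        gsig = (fa_g - fb_g) ** 2 / dg if dg > 0 else 0.0
    dev = sig - gsig
    return (dev * dev).mean(axis=1)


@lru_cache(maxsize=262144)
def _delta_max(na: int, nb: int, nn: int, blob_sizes: tuple, binary: bool) -> float:
    """Normalization maximum for a composition; depends only on group counts.
    The maximum is taken over candidate arrangements of the blob-size-averaged
    delta, matching :func:`_delta`'s averaging."""
    L = na + nb + nn
    vecs = [
        _candidate_deltas(na, nb, nn, g, binary)
        for g in blob_sizes
        if L >= g
    ]
    if not vecs:
        return MISSING
    return float(np.max(np.mean(vecs, axis=0)))


def patterning(seq: str, alphabet_split: str = "kappa", blob_sizes=(5, 6),
               residues: str | None = None) -> float:
    """Blob-level demixing statistic, normalized to [0, 1] by the maximum over
    segregated rearrangements of the same composition.

    ``alphabet_split``: ``kappa`` (K/R vs D/E, neutrals excluded from blob
    asymmetry denominators), ``omega`` (binary {P, charged} vs rest), or
    ``set`` (binary ``residues`` vs rest).  MISSING when the split is
    undefined for the composition or the sequence is shorter than every blob.
    """
    _check_seq(seq)
    if alphabet_split == "kappa":
        groups = np.array(
            [1 if c in _POSITIVE else -1 if c in _NEGATIVE else 0 for c in seq],
            dtype=float,
        )
        if not np.any(groups != 0):
            return MISSING
        binary = False
    elif alphabet_split == "omega":
        grp = _POSITIVE | _NEGATIVE | {"P"}
        groups = np.array([1 if c in grp else -1 for c in seq], dtype=float)
        if not np.any(groups > 0):
            return MISSING
        binary = True
    elif alphabet_split == "set":
        grp = set(residues or "")
        groups = np.array([1 if c in grp else -1 for c in seq], dtype=float)
        if not np.any(groups > 0):
            return MISSING
        binary = True
    else:
        raise ValueError(f"unknown alphabet split {alphabet_split!r}")

    blob_sizes = tuple(blob_sizes)
    delta = _delta(groups, blob_sizes, binary)
    if math.isnan(delta):
        return MISSING
    na = int((groups > 0).sum())
    nb = int((groups < 0).sum())
    dmax = _delta_max(na, nb, groups.size - na - nb, blob_sizes, binary)
    if not dmax or math.isnan(dmax):
        return MISSING
    return float(min(delta / dmax, 1.0))


def wf_complexity(seq: str, form: str = "entropy") -> float:
    """Wootton-Federhen complexity; entropy (K2) form in base 20 by default,
    in [0, 1].  ``form='multinomial'`` gives the K1 form."""
    _check_seq(seq)
    L = len(seq)
    counts = np.bincount([_AA_INDEX[c] for c in seq], minlength=20)
    if form == "entropy":
        p = counts[counts > 0] / L
        return float(-(p * np.log(p)).sum() / np.log(20))
    if form == "multinomial":
        logomega = (
            math.lgamma(L + 1) - sum(math.lgamma(int(n) + 1) for n in counts)
        )
        return float(logomega / (L * np.log(20)))
    raise ValueError(f"unknown complexity form {form!r}")


def isoelectric_point(
    seq: str, pka: dict | None = None, tol: float = 1e-4
) -> float:
    """pH where the Henderson-Hasselbalch net charge of the peptide (termini
    plus D/E/C/Y/H/K/R side chains) crosses zero, by bisection."""
    _check_seq(seq)
    pka = pka or DEFAULT_PKA
    side = pka["side_chains"]
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}

    def charge(ph: float) -> float:
        q = 1.0 / (1.0 + 10 ** (ph - pka["n_terminus"]))
        q -= 1.0 / (1.0 + 10 ** (pka["c_terminus"] - ph))
        for aa in "KRH":
            q += counts[aa] / (1.0 + 10 ** (ph - side[aa]))
        for aa in "DECY":
            q -= counts[aa] / (1.0 + 10 ** (side[aa] - ph))
        return q

    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = charge(mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def motif_density(seq: str, pattern: str, mask=None) -> float:
    """Matches of ``pattern`` per residue; overlapping matches all counted.
    A match is suppressed when its anchor (first) position is masked."""
    _check_seq(seq)
    anchors = [m.start() for m in re.finditer(f"(?=({pattern}))", seq)]
    if mask is not None:
        anchors = [a for a in anchors if not mask[a]]
    return len(anchors) / len(seq)


def repeat_density(seq: str, residue, min_run: int = 4) -> float:
    """Fraction of residues inside homopolymer/tract runs of length >= min_run
    over ``residue`` (a residue or residue set)."""
    _check_seq(seq)
    rs = set(residue)
    total = 0
    run = 0
    for c in seq + "\x00":  # sentinel flushes the final run
        if c in rs:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    return total / len(seq)


def max_run_fraction(seq: str) -> float:
    """Length of the longest single-residue run divided by sequence length."""
    _check_seq(seq)
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best / len(seq)


def hydrophobicity(seq: str, scale_id: str = "kyte_doolittle") -> float:
    """Mean per-residue value under a named hydropathy scale."""
    _check_seq(seq)
    try:
        scale = HYDROPATHY_SCALES[scale_id]
    except KeyError:
        raise ValueError(f"unknown hydropathy scale {scale_id!r}") from None
    return sum(scale[c] for c in seq) / len(seq)


# ---------------------------------------------------------------------------
# catalog evaluation
#
# The catalog is compiled once into closures over a per-sequence context
# (integer codes + residue counts), so shared work -- encoding, counting --
# happens once per sequence rather than once per feature.

_ASCII2IDX = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(AA_ALPHABET):
    _ASCII2IDX[ord(_aa)] = _i


class _SeqContext:
    __slots__ = ("seq", "codes", "counts", "length")

    def __init__(self, seq: str):
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = _ASCII2IDX[raw & 0x7F]
        if (codes < 0).any() or (raw > 127).any():
            bad = sorted(set(seq) - set(AA_ALPHABET))
            raise ValueError(f"non-standard residues in sequence: {bad}")
        self.seq = seq
        self.codes = codes
        self.counts = np.bincount(codes, minlength=20)
        self.length = len(seq)


@lru_cache(maxsize=256)
def _group_lut(split: str, residues: str | None) -> np.ndarray:
    lut = np.zeros(20)
    if split == "kappa":
        for c in _POSITIVE:
            lut[_AA_INDEX[c]] = 1.0
        for c in _NEGATIVE:
            lut[_AA_INDEX[c]] = -1.0
    else:
        grp = (
            _POSITIVE | _NEGATIVE | {"P"} if split == "omega"
            else set(residues or "")
        )
        lut[:] = -1.0
        for c in grp:
            lut[_AA_INDEX[c]] = 1.0
    return lut


def _patterning_core(groups: np.ndarray, split: str, blob_sizes: tuple) -> float:
    if split == "kappa":
        if not np.any(groups != 0):
            return MISSING
        binary = False
    else:
        if not np.any(groups > 0):
            return MISSING
        binary = True
    delta = _delta(groups, blob_sizes, binary)
    if math.isnan(delta):
        return MISSING
    na = int((groups > 0).sum())
    nb = int((groups < 0).sum())
    dmax = _delta_max(na, nb, groups.size - na - nb, blob_sizes, binary)
    if not dmax or math.isnan(dmax):
        return MISSING
    return float(min(delta / dmax, 1.0))


_IDX_POS = np.array([_AA_INDEX[c] for c in sorted(_POSITIVE)])
_IDX_NEG = np.array([_AA_INDEX[c] for c in sorted(_NEGATIVE)])
_CHARGE_LUT = np.zeros(20)
_CHARGE_LUT[_IDX_POS] = 1.0
_CHARGE_LUT[_IDX_NEG] = -1.0


@lru_cache(maxsize=64)
def _compiled_pattern(pattern: str):
    return re.compile(f"(?=({pattern}))")


def _pi_from_counts(counts: np.ndarray, pka: dict, tol: float = 1e-4) -> float:
    side = pka["side_chains"]
    n_pos = {aa: int(counts[_AA_INDEX[aa]]) for aa in "KRH"}
    n_neg = {aa: int(counts[_AA_INDEX[aa]]) for aa in "DECY"}

    def charge(ph: float) -> float:
        q = 1.0 / (1.0 + 10 ** (ph - pka["n_terminus"]))
        q -= 1.0 / (1.0 + 10 ** (pka["c_terminus"] - ph))
        for aa, n in n_pos.items():
            if n:
                q += n / (1.0 + 10 ** (ph - side[aa]))
        for aa, n in n_neg.items():
            if n:
                q -= n / (1.0 + 10 ** (side[aa] - ph))
        return q

    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = charge(mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _compile(defn: FeatureDefinition):
    """Compile a feature definition into ``fn(ctx, mask) -> float``."""
    p = defn.params
    fam = defn.family
    if fam == "composition":
        idxs = np.array(sorted(_AA_INDEX[c] for c in set(p["residues"])))
        return lambda ctx, mask: float(ctx.counts[idxs].sum()) / ctx.length
    if fam == "length":
        return lambda ctx, mask: float(ctx.length)
    if fam == "charge":
        kind = p["kind"]
        if kind == "net":
            return lambda ctx, mask: float(
                ctx.counts[_IDX_POS].sum() - ctx.counts[_IDX_NEG].sum()
            )
        if kind == "net_phospho":
            rx = _compiled_pattern(p.get("phospho_pattern", "[ST]P"))
            qp = float(p.get("phospho_charge", -2.0))
            return lambda ctx, mask: float(
                ctx.counts[_IDX_POS].sum() - ctx.counts[_IDX_NEG].sum()
            ) + qp * sum(1 for _ in rx.finditer(ctx.seq))
        if kind == "ncpr":
            return lambda ctx, mask: float(
                ctx.counts[_IDX_POS].sum() - ctx.counts[_IDX_NEG].sum()
            ) / ctx.length
        if kind == "asymmetry":
            def _asym(ctx, mask):
                fp = ctx.counts[_IDX_POS].sum() / ctx.length
                fm = ctx.counts[_IDX_NEG].sum() / ctx.length
                return (fp - fm) ** 2 / (fp + fm) if fp + fm > 0 else MISSING
            return _asym
        if kind == "scd":
            def _scd(ctx, mask):
                q = _CHARGE_LUT[ctx.codes]
                pos = np.flatnonzero(q)
                if pos.size < 2:
                    return 0.0
                qq = q[pos]
                iu0, iu1 = np.triu_indices(pos.size, k=1)
                return float(
                    (qq[iu0] * qq[iu1] * np.sqrt(pos[iu1] - pos[iu0])).sum()
                    / ctx.length
                )
            return _scd
        raise ValueError(f"unknown charge feature kind {kind!r}")
    if fam == "patterning":
        split = p["split"]
        blob_sizes = tuple(p.get("blob_sizes", (5, 6)))
        lut = _group_lut(split, p.get("residues"))
        return lambda ctx, mask: _patterning_core(
            lut[ctx.codes], split, blob_sizes
        )
    if fam == "complexity":
        kind = p.get("kind", "entropy")
        if kind == "entropy":
            def _wf(ctx, mask):
                pr = ctx.counts[ctx.counts > 0] / ctx.length
                return float(-(pr * np.log(pr)).sum() / np.log(20))
            return _wf
        if kind == "multinomial":
            return lambda ctx, mask: wf_complexity(ctx.seq, form="multinomial")
        if kind == "diversity":
            return lambda ctx, mask: float((ctx.counts > 0).sum()) / 20.0
        raise ValueError(f"unknown complexity kind {kind!r}")
    if fam == "motif":
        rx = _compiled_pattern(p["pattern"])

        def _motif(ctx, mask):
            if mask is None:
                return sum(1 for _ in rx.finditer(ctx.seq)) / ctx.length
            return sum(
                1 for m in rx.finditer(ctx.seq) if not mask[m.start()]
            ) / ctx.length

        return _motif
    if fam == "repeat":
        if p.get("kind") == "max_run":
            return lambda ctx, mask: max_run_fraction(ctx.seq)
        rs = p["residues"]
        min_run = int(p.get("min_run", 4))
        return lambda ctx, mask: repeat_density(ctx.seq, rs, min_run)
    if fam == "physicochemical":
        kind = p["kind"]
        if kind == "pi":
            return lambda ctx, mask: _pi_from_counts(ctx.counts, DEFAULT_PKA)
        if kind == "hydropathy":
            scale = HYDROPATHY_SCALES[p["scale"]]
            vec = np.array([scale[aa] for aa in AA_ALPHABET])
            return lambda ctx, mask: float(vec[ctx.codes].mean())
        raise ValueError(f"unknown physicochemical kind {kind!r}")
    raise ValueError(f"unknown family {fam!r}")


_EVALUATOR_CACHE: dict[int, list] = {}


def _evaluators(catalog: FeatureCatalog):
    key = id(catalog)
    ev = _EVALUATOR_CACHE.get(key)
    if ev is None:
        ev = [(f.name, _compile(f)) for f in catalog]
        _EVALUATOR_CACHE[key] = ev
    return ev


def compute_features(
    seq: str, catalog: FeatureCatalog | None = None, mask=None
) -> dict[str, float]:
    """Evaluate every catalog feature on one ungapped sequence.

    Returns an ordered ``{name: value}`` mapping with ``nan`` for MISSING.
    Deterministic; catalog order fixes output order.
    """
    if catalog is None:
        catalog = FeatureCatalog.default()
    if len(catalog) == 0:
        return {}
    _check_seq(seq)
    ctx = _SeqContext(seq)
    return {name: float(fn(ctx, mask)) for name, fn in _evaluators(catalog)}


def feature_function(name: str, catalog: FeatureCatalog | None = None):
    """Compiled evaluator ``seq -> value`` for a single named catalog feature."""
    catalog = catalog or FeatureCatalog.default()
    for defn in catalog:
        if defn.name == name:
            fn = _compile(defn)
            return lambda seq: float(fn(_SeqContext(seq), None))
    raise KeyError(f"feature {name!r} not in catalog")


def feature_matrix(seqs: dict[str, str], catalog: FeatureCatalog | None = None):
    """Feature values for a collection of sequences as a DataFrame
    (rows = sequence ids, columns = catalog order)."""
    import pandas as pd

    catalog = catalog or FeatureCatalog.default()
    return pd.DataFrame.from_dict(
        {sid: compute_features(s, catalog) for sid, s in seqs.items()},
        orient="index",
        columns=catalog.names,
    )
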