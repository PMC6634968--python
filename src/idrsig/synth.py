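"""Synthetic data generation: phylogenies, root IDRs, null and
constraint-carrying ortholog sets, and annotation tables with planted
cluster-term associations.

Everything the pipeline consumes can be generated here at desk scale, with
ground truth retained for recovery scoring.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureCatalog, feature_function
from .io import AA_ALPHABET, AnnotationTable, Phylogeny, Region
from .simulate import (
    IndelModel,
    SubstitutionModel,
    _SiteState,
    _evolve_branch,
    decode,
    encode,
)


class ConstraintError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a planted constraint."""


def gen_tree(n_taxa: int, depth: float, seed: int) -> Phylogeny:
    """Random coalescent-style ultrametric tree over ``sp01..spNN`` rescaled
    to root-to-tip ``depth``.  ``sp01`` and ``sp02`` are the designated
    calibration taxa."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    lineages = [(f"sp{i + 1:02d}", 0.0) for i in range(n_taxa)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = (f"({na}:{t - ha:.10f},{nb}:{t - hb:.10f})", t)
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    newick, height = lineages[0]
    factor = depth / height if height > 0 else 0.0
    tree = Phylogeny.from_newick(newick + ";")
    return tree.scaled(factor)


CALIBRATION_TAXA = ("sp01", "sp02")


def gen_root_idr(length: int, composition=None, seed: int = 0) -> str:
    """i.i.d. root sequence of exact ``length`` from ``composition`` (default:
    the bundled disorder-biased stationary frequencies)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        composition = SubstitutionModel.default().freqs
    composition = np.asarray(composition, dtype=float)
    composition = composition / composition.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(AA_ALPHABET), size=length, p=composition)
    return "".join(AA_ALPHABET[i] for i in idx)


@dataclass
class SyntheticOrthologSet:
    """Ungapped ortholog set with its root and true residue-homology map."""

    idr_id: str
    root: str
    leaves: dict[str, str]
    origins: dict[str, np.ndarray] = field(default_factory=dict)


def gen_null_ortholog_set(
    root: str,
    tree: Phylogeny,
    model: SubstitutionModel | None = None,
    indels: IndelModel | None = None,
    rates=1.0,
    scale: float = 1.0,
    mask=None,
    seed: int = 0,
    idr_id: str = "",
) -> SyntheticOrthologSet:
    """Pure null evolution of ``root`` down ``tree`` with homology retained."""
    from .simulate import evolve_sequence

    leaves, origins = evolve_sequence(
        root, tree, rates=rates, model=model, indels=indels, scale=scale,
        seed=seed, mask=mask, return_origins=True,
    )
    return SyntheticOrthologSet(
        idr_id=idr_id, root=root, leaves=leaves, origins=origins
    )


def estimate_null_sigma(
    root: str,
    tree: Phylogeny,
    feature: str,
    catalog: FeatureCatalog | None = None,
    model: SubstitutionModel | None = None,
    indels: IndelModel | None = None,
    scale: float = 1.0,
    n_pilot: int = 30,
    seed: int = 0,
) -> float:
    """Across-ortholog standard deviation of a feature's per-leaf values under
    null evolution, pooled over a pilot ensemble."""
    fn = feature_function(feature, catalog)
    values = []
    for i in range(n_pilot):
        oset = gen_null_ortholog_set(
            root, tree, model=model, indels=indels, scale=scale,
            seed=int(np.random.default_rng([seed, i]).integers(2**31)),
        )
        for s in oset.leaves.values():
            if s:
                v = fn(s)
                if np.isfinite(v):
                    values.append(v)
    if len(values) < 2:
        raise ConstraintError(f"cannot estimate null sigma for {feature!r}")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise ConstraintError(f"feature {feature!r} is constant under the null")
    return sd


def gen_constrained_ortholog_set(
    root: str,
    tree: Phylogeny,
    feature: str,
    mode: str = "variance-clamp",
    effect: float = 0.0,
    tolerance: float = 1.0,
    null_sigma: float | None = None,
    catalog: FeatureCatalog | None = None,
    model: SubstitutionModel | None = None,
    indels: IndelModel | None = None,
    rates=1.0,
    scale: float = 1.0,
    mask=None,
    seed: int = 0,
    idr_id: str = "",
    branch_budget: int = 300,
) -> SyntheticOrthologSet:
    """Stabilizing/directional selection emulated by per-branch rejection
    sampling: every node's sequence must keep ``feature`` inside a band.

    ``variance-clamp`` centers the band on the root's value;
    ``mean-shift`` centers it at ``root value + effect * null_sigma``.
    The band half-width is ``tolerance * null_sigma``.
    """
    if mode not in ("variance-clamp", "mean-shift"):
        raise ValueError(f"unknown constraint mode {mode!r}")
    model = model or SubstitutionModel.default()
    indels = indels or IndelModel()
    fn = feature_function(feature, catalog)
    if null_sigma is None:
        null_sigma = estimate_null_sigma(
            root, tree, feature, catalog=catalog, model=model, indels=indels,
            scale=scale, seed=seed,
        )
    root_value = fn(root)
    if not np.isfinite(root_value):
        raise ConstraintError(f"feature {feature!r} undefined on the root")
    half = tolerance * null_sigma
    rng = np.random.default_rng(seed)

    nodes = list(tree.walk())
    node_depth: dict[int, float] = {}
    for parent, node_id, _name, blen in nodes:
        node_depth[node_id] = (
            0.0 if parent is None else node_depth[parent] + blen * scale
        )
    max_depth = max(node_depth.values()) or 1.0

    def band_center(depth: float) -> float:
        if mode != "mean-shift":
            return root_value
        # directional selection: the target drifts toward the full shift in
        # proportion to depth, so each step only has to move a feasible
        # fraction of the total effect
        frac = min(depth / max_depth, 1.0)
        return root_value + effect * null_sigma * frac

    L = len(root)
    rate_arr = np.broadcast_to(np.asarray(rates, dtype=float), (L,)).copy()
    mask_arr = (
        np.zeros(L, dtype=bool) if mask is None
        else np.asarray(mask, dtype=bool).copy()
    )
    states: dict[int, _SiteState] = {}
    leaves: dict[str, str] = {}
    origins: dict[str, np.ndarray] = {}
    for parent, node_id, name, blen in nodes:
        if parent is None:
            states[node_id] = _SiteState(
                encode(root), rate_arr, mask_arr, np.arange(L, dtype=np.int64)
            )
        else:
            # evolve long branches in short segments so each rejection step
            # only needs a small feature drift to stay inside the band
            t_eff = blen * scale
            n_seg = max(1, int(np.ceil(t_eff / 0.25)))
            state = states[parent]
            for s in range(1, n_seg + 1):
                depth = node_depth[parent] + t_eff * s / n_seg
                center = band_center(depth)
                accepted = None
                for _ in range(branch_budget):
                    cand = _evolve_branch(
                        state, t_eff / n_seg, model, indels, rng
                    )
                    if len(cand) == 0:
                        continue
                    v = fn(decode(cand.aa))
                    if np.isfinite(v) and abs(v - center) <= half:
                        accepted = cand
                        break
                if accepted is None:
                    raise ConstraintError(
                        f"branch budget exhausted for {feature!r} ({mode}, "
                        f"effect={effect}, tolerance={tolerance}) on "
                        f"{name or f'node {node_id}'}"
                    )
                state = accepted
            states[node_id] = state
        if name is not None:
            leaves[name] = decode(states[node_id].aa)
            origins[name] = states[node_id].origin.copy()
    return SyntheticOrthologSet(
        idr_id=idr_id, root=root, leaves=leaves, origins=origins
    )


@dataclass(frozen=True)
class ConstraintProfile:
    feature: str
    mode: str = "variance-clamp"   # or "mean-shift"
    effect: float = 0.0            # in null-sigma units
    tolerance: float = 1.0         # band half-width, null-sigma units


@dataclass(frozen=True)
class BenchmarkSpec:
    n_classes: int = 3
    idrs_per_class: int = 40
    profiles: tuple[ConstraintProfile, ...] = ()
    n_taxa: int = 16
    depth: float = 1.0
    root_length: int = 100
    terms_per_class: int = 2
    class_coverage: float = 0.6
    background_coverage: float = 0.05
    noise_rate: float = 0.0
    n_background_terms: int = 5
    background_term_coverage: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profiles and len(self.profiles) != self.n_classes:
            raise ValueError("one constraint profile per class required")
        for c in (
            self.class_coverage, self.background_coverage,
            self.noise_rate, self.background_term_coverage,
        ):
            if not 0.0 <= c <= 1.0:
                raise ValueError("coverages must lie in [0, 1]")
        for p in self.profiles:
            if p.effect < 0:
                raise ValueError("effect sizes must be >= 0")


@dataclass
class Benchmark:
    spec: BenchmarkSpec
    tree: Phylogeny
    ortholog_sets: list[SyntheticOrthologSet]
    regions: list[Region]
    idr_to_protein: dict[str, str]
    annotations: AnnotationTable
    truth: dict[str, str]            # idr_id -> class label
    planted_terms: dict[str, list[str]]  # class label -> term ids


def gen_benchmark(
    spec: BenchmarkSpec,
    model: SubstitutionModel | None = None,
    indels: IndelModel | None = None,
    catalog: FeatureCatalog | None = None,
) -> Benchmark:
    """Full planted-class dataset: constrained ortholog sets per class plus an
    annotation table in which term membership tracks the classes."""
    model = model or SubstitutionModel.default()
    indels = indels or IndelModel()
    rng = np.random.default_rng(spec.seed)
    tree = gen_tree(spec.n_taxa, spec.depth, seed=spec.seed)

    profiles = spec.profiles or tuple(
        ConstraintProfile(feature="net_charge", mode="variance-clamp")
        for _ in range(spec.n_classes)
    )
    sigma_cache: dict[str, float] = {}
    osets: list[SyntheticOrthologSet] = []
    regions: list[Region] = []
    idr_to_protein: dict[str, str] = {}
    truth: dict[str, str] = {}
    for ci in range(spec.n_classes):
        label = f"class{ci + 1}"
        prof = profiles[ci]
        for j in range(spec.idrs_per_class):
            idr_id = f"idr_{label}_{j + 1:03d}"
            protein = f"prot_{label}_{j + 1:03d}"
            root = gen_root_idr(
                spec.root_length, composition=model.freqs,
                seed=int(rng.integers(2**31)),
            )
            if prof.feature not in sigma_cache:
                sigma_cache[prof.feature] = estimate_null_sigma(
                    root, tree, prof.feature, catalog=catalog, model=model,
                    indels=indels, seed=spec.seed,
                )
            draw_seed = int(rng.integers(2**31))
            if prof.effect == 0 and prof.tolerance == float("inf"):
                oset = gen_null_ortholog_set(
                    root, tree, model=model, indels=indels,
                    seed=draw_seed, idr_id=idr_id,
                )
            else:
                oset = None
                last_err: ConstraintError | None = None
                for attempt in range(5):  # rare branch-budget dead ends
                    try:
                        oset = gen_constrained_ortholog_set(
                            root, tree, prof.feature, mode=prof.mode,
                            effect=prof.effect, tolerance=prof.tolerance,
                            null_sigma=sigma_cache[prof.feature],
                            catalog=catalog, model=model, indels=indels,
                            seed=draw_seed + 9973 * attempt, idr_id=idr_id,
                        )
                        break
                    except ConstraintError as err:
                        last_err = err
                if oset is None:
                    raise last_err
            osets.append(oset)
            regions.append(Region(protein, 0, spec.root_length))
            idr_to_protein[idr_id] = protein
            truth[idr_id] = label

    proteins = sorted(set(idr_to_protein.values()))
    protein_class = {
        idr_to_protein[i]: lab for i, lab in truth.items()
    }
    protein_terms: dict[str, set[str]] = {p: set() for p in proteins}
    planted: dict[str, list[str]] = {}
    for ci in range(spec.n_classes):
        label = f"class{ci + 1}"
        terms = [f"TERM_{label}_{t + 1}" for t in range(spec.terms_per_class)]
        planted[label] = terms
        for term in terms:
            for p in proteins:
                cov = (
                    spec.class_coverage
                    if protein_class[p] == label
                    else spec.background_coverage
                )
                if rng.random() < cov:
                    protein_terms[p].add(term)
    for t in range(spec.n_background_terms):
        term = f"BG_{t + 1}"
        for p in proteins:
            if rng.random() < spec.background_term_coverage:
                protein_terms[p].add(term)
    if spec.noise_rate > 0:
        all_terms = sorted({t for ts in protein_terms.values() for t in ts})
        for p in proteins:
            for term in all_terms:
                if rng.random() < spec.noise_rate:
                    protein_terms[p].symmetric_difference_update({term})

    return Benchmark(
        spec=spec,
        tree=tree,
        ortholog_sets=osets,
        regions=regions,
        idr_to_protein=idr_to_protein,
        annotations=AnnotationTable(protein_terms=protein_terms, term_class="GO"),
        truth=truth,
        planted_terms=planted,
    )
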