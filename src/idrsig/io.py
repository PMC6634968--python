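"""Readers, writers, and filters for ortholog alignments, trees, regions, and annotations.

All coordinates are 0-based, half-open internally.  TSV readers accept
``one_based=True`` to convert 1-based inclusive input on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_VALID = set(AA_ALPHABET) | {GAP}
_AMBIGUOUS = set("BZXUJO*")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under its declared format."""


class CoordinateError(ValueError):
    """Raised when region coordinates do not fit the sequence they index."""


@dataclass(frozen=True)
class Region:
    """A contiguous protein segment, 0-based half-open."""

    protein_id: str
    start: int
    end: int
    kind: str = "disordered"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid region [{self.start},{self.end}) for {self.protein_id}"
            )
        if self.kind not in ("disordered", "ordered"):
            raise ValueError(f"unknown region kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Rejected:
    """Return state for filters that discard an input instead of raising."""

    reason: str
    idr_id: str = ""


@dataclass
class AlignedOrthologSet:
    """One IDR's gapped ortholog alignment keyed by species labels."""

    idr_id: str
    species: list[str]
    rows: list[str]
    reference_species: str
    region: Region | None = None

    def __post_init__(self) -> None:
        if len(self.species) != len(self.rows):
            raise ValueError("species/rows length mismatch")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise FormatError(f"ragged alignment rows (widths {sorted(widths)})")
        if self.reference_species not in self.species:
            raise ValueError(f"reference {self.reference_species!r} not in species")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_species(self) -> int:
        return len(self.species)

    def row(self, species: str) -> str:
        return self.rows[self.species.index(species)]

    def ungapped(self, species: str) -> str:
        return self.row(species).replace(GAP, "")

    @property
    def reference_row(self) -> str:
        return self.row(self.reference_species)


class Phylogeny:
    """Rooted tree with branch lengths in substitutions/site.

    Thin wrapper around a dendropy tree exposing the traversals the rate
    estimator and simulator need.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None and (edge.length or 0.0) < 0:
                raise ValueError("negative branch length")

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"unparseable Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def total_length(self) -> float:
        return sum(
            e.length or 0.0
            for e in self._tree.preorder_edge_iter()
            if e.tail_node is not None
        )

    def patristic_distance(self, a: str, b: str) -> float:
        pdm = self._tree.phylogenetic_distance_matrix()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        if ta is None or tb is None:
            raise KeyError(f"taxon missing from tree: {a if ta is None else b}")
        return pdm.patristic_distance(ta, tb)

    def scaled(self, factor: float) -> "Phylogeny":
        clone = self._tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Phylogeny(clone)

    def walk(self):
        """Yield (parent_id, node_id, name_or_None, branch_length) preorder.

        The root has parent_id None and branch length 0.
        """
        ids = {}
        for i, node in enumerate(self._tree.preorder_node_iter()):
            ids[id(node)] = i
            parent = ids[id(node.parent_node)] if node.parent_node else None
            name = node.taxon.label if node.taxon else None
            yield parent, i, name, (node.edge.length or 0.0)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class AnnotationTable:
    """Protein -> annotation-term memberships for one term class."""

    protein_terms: dict[str, set[str]]
    term_class: str = "GO"

    def __post_init__(self) -> None:
        if self.term_class not in ("GO", "phenotype", "literature"):
            raise ValueError(f"unknown term class {self.term_class!r}")

    @property
    def term_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for terms in self.protein_terms.values():
            for t in terms:
                sizes[t] = sizes.get(t, 0) + 1
        return sizes

    @property
    def terms(self) -> set[str]:
        return set(self.term_sizes)

    def proteins_with(self, term: str) -> set[str]:
        return {p for p, ts in self.protein_terms.items() if term in ts}


# ---------------------------------------------------------------------------
# readers


def _parse_fasta(handle) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise FormatError(f"empty FASTA header at line {lineno}")
            chunks = []
        else:
            if name is None:
                raise FormatError(f"sequence before header at line {lineno}")
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def read_alignment(
    path,
    idr_id: str = "",
    reference_species: str | None = None,
    region: Region | None = None,
    recode_ambiguous: bool = False,
) -> AlignedOrthologSet:
    """Read one gapped FASTA alignment into an :class:`AlignedOrthologSet`.

    Rows are uppercased.  Characters outside the 20-residue alphabet plus gap
    are rejected unless ``recode_ambiguous`` maps B/Z/X/U/J/O/* to gaps.
    """
    with open(path) as fh:
        records = _parse_fasta(fh)
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    species, rows = [], []
    for name, seq in records:
        seq = seq.upper()
        if recode_ambiguous:
            seq = "".join(GAP if c in _AMBIGUOUS else c for c in seq)
        bad = set(seq) - _VALID
        if bad:
            raise FormatError(
                f"record {name!r} contains characters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )
        species.append(name)
        rows.append(seq)
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise FormatError(f"ragged alignment in {path}: widths {sorted(widths)}")
    ref = reference_species if reference_species is not None else species[0]
    return AlignedOrthologSet(
        idr_id=idr_id or str(path),
        species=species,
        rows=rows,
        reference_species=ref,
        region=region,
    )


def read_sequences(path) -> dict[str, str]:
    """Read a plain (unaligned) FASTA into ``{name: sequence}``.

    No common-width requirement; gaps are stripped; alphabet still checked.
    """
    with open(path) as fh:
        records = _parse_fasta(fh)
    if not records:
        raise FormatError(f"empty FASTA file: {path}")
    out: dict[str, str] = {}
    for name, seq in records:
        seq = seq.upper().replace(GAP, "")
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise FormatError(
                f"record {name!r} contains characters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )
        if name in out:
            raise FormatError(f"duplicate record {name!r} in {path}")
        out[name] = seq
    return out


def write_alignment(oset: AlignedOrthologSet, path) -> None:
    with open(path, "w") as fh:
        for sp, row in zip(oset.species, oset.rows):
            fh.write(f">{sp}\n{row}\n")


def slice_region(alignment: AlignedOrthologSet, region: Region) -> AlignedOrthologSet:
    """Extract the alignment columns spanned by *region* on the reference row.

    Columns between the alignment columns of reference residues ``start`` and
    ``end - 1`` inclusive are returned, including interior gap-only columns.
    """
    ref = alignment.reference_row
    # alignment column index of each ungapped reference residue
    col_of_residue = [i for i, c in enumerate(ref) if c != GAP]
    if region.end > len(col_of_residue):
        raise CoordinateError(
            f"region [{region.start},{region.end}) exceeds reference ungapped "
            f"length {len(col_of_residue)}"
        )
    lo = col_of_residue[region.start]
    hi = col_of_residue[region.end - 1] + 1
    return AlignedOrthologSet(
        idr_id=f"{alignment.idr_id}:{region.start}-{region.end}",
        species=list(alignment.species),
        rows=[r[lo:hi] for r in alignment.rows],
        reference_species=alignment.reference_species,
        region=region,
    )


def filter_regions(regions: Sequence[Region], min_length: int = 30) -> list[Region]:
    """Keep regions of length >= ``min_length`` (default 30 aa), order preserved."""
    return [r for r in regions if r.length >= min_length]


def filter_ortholog_set(
    oset: AlignedOrthologSet, min_species: int = 10, min_residues: int = 10
) -> AlignedOrthologSet | Rejected:
    """Drop rows with < ``min_residues`` ungapped residues, then require
    >= ``min_species`` remaining rows; otherwise return a :class:`Rejected`."""
    keep = [
        i
        for i, r in enumerate(oset.rows)
        if len(r) - r.count(GAP) >= min_residues
    ]
    if len(keep) < min_species:
        return Rejected(
            reason=f"{len(keep)} species with >= {min_residues} residues "
            f"(< {min_species} required)",
            idr_id=oset.idr_id,
        )
    if len(keep) == oset.n_species:
        return oset
    kept_species = [oset.species[i] for i in keep]
    ref = (
        oset.reference_species
        if oset.reference_species in kept_species
        else kept_species[0]  # reference itself failed the residue filter
    )
    return AlignedOrthologSet(
        idr_id=oset.idr_id,
        species=kept_species,
        rows=[oset.rows[i] for i in keep],
        reference_species=ref,
        region=oset.region,
    )


def overlap_fraction(query: Region, targets: Iterable[Region]) -> float:
    """Fraction of *query* positions covered by the union of *targets*."""
    covered = 0
    prev_end = query.start
    intervals = []
    for t in targets:
        if t.protein_id != query.protein_id:
            raise ValueError(
                f"protein mismatch: {t.protein_id!r} vs {query.protein_id!r}"
            )
        lo, hi = max(t.start, query.start), min(t.end, query.end)
        if lo < hi:
            intervals.append((lo, hi))
    for lo, hi in sorted(intervals):
        lo = max(lo, prev_end)
        if hi > lo:
            covered += hi - lo
            prev_end = hi
    return covered / query.length


def read_tree(path) -> Phylogeny:
    return Phylogeny.from_file(path)


def read_regions(path, one_based: bool = False) -> list[Region]:
    """Read a region TSV with header columns protein_id, start, end[, kind]."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    except Exception as exc:
        raise FormatError(f"unparseable region TSV {path}: {exc}") from exc
    required = {"protein_id", "start", "end"}
    if not required.issubset(df.columns):
        raise FormatError(f"region TSV {path} missing columns {required - set(df.columns)}")
    regions = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        start, end = int(row.start), int(row.end)
        if one_based:
            start -= 1  # 1-based inclusive -> 0-based half-open
        kind = getattr(row, "kind", "disordered")
        try:
            regions.append(Region(str(row.protein_id), start, end, kind))
        except (CoordinateError, ValueError) as exc:
            raise FormatError(f"{path} line {lineno}: {exc}") from exc
    return regions


def write_regions(regions: Sequence[Region], path) -> None:
    pd.DataFrame(
        [(r.protein_id, r.start, r.end, r.kind) for r in regions],
        columns=["protein_id", "start", "end", "kind"],
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path, term_class: str = "GO") -> AnnotationTable:
    """Read a protein/term TSV (columns protein_id, term_id); duplicates deduplicated."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"unparseable annotation TSV {path}: {exc}") from exc
    if not {"protein_id", "term_id"}.issubset(df.columns):
        raise FormatError(f"annotation TSV {path} needs protein_id and term_id columns")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.protein_id, set()).add(row.term_id)
    return AnnotationTable(protein_terms=mapping, term_class=term_class)


def write_annotations(table: AnnotationTable, path) -> None:
    rows = [
        (p, t)
        for p, ts in sorted(table.protein_terms.items())
        for t in sorted(ts)
    ]
    pd.DataFrame(rows, columns=["protein_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix(
    df: pd.DataFrame, path, weights: Sequence[float] | None = None
) -> None:
    """Write a labeled matrix as tab-delimited text (Cluster 3.0-style layout).

    One header row, one leading label column, and an optional second column of
    per-row weights.  MISSING values are written as empty cells.
    """
    out = df.copy()
    out.index.name = out.index.name or "id"
    if weights is not None:
        out.insert(0, "GWEIGHT", list(weights))
    out.to_csv(path, sep="\t", na_rep="")


def read_matrix(path) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Inverse of :func:`write_matrix`; returns (matrix, weights-or-None)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"unparseable matrix {path}: {exc}") from exc
    weights = None
    if "GWEIGHT" in df.columns:
        weights = df.pop("GWEIGHT").to_numpy(dtype=float)
    return df.astype(float), weights
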