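"""Readers and writers for trees, genomic intervals, matrices and complex lists.

All coordinate and topology conventions are fixed in this module:

* Genomic intervals are 0-based, half-open ``[start, end)`` internally.  BED is
  native; GFF3's 1-based closed coordinates are converted on read.
* Tree branches are identified by their clade: the sorted set of descendant
  leaf taxa.  This makes branch identity stable across gene trees that share a
  topology with the species tree but may be missing taxa.
* Missing values in TSV matrices are the literal string ``NA``; in memory they
  are ``NaN`` (pandas), kept distinct from 0.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__

#: sentinel written to TSV for missing branch lengths / rates
MISSING_TOKEN = "NA"

#: decimal rendering used by every writer; %.17g round-trips IEEE doubles
FLOAT_FORMAT = "%.17g"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _comment_header(seed: int | None = None) -> str:
    tag = f"# ratecov {__version__}"
    if seed is not None:
        tag += f" seed={seed}"
    return tag + "\n"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def branch_id(clade: Iterable[str]) -> str:
    """Canonical string id of a branch: its descendant taxa, sorted, |-joined."""
    return "|".join(sorted(clade))


@dataclass(frozen=True)
class SpeciesTree:
    """A rooted binary tree whose non-root branches carry lengths.

    Branches are keyed by clade (frozenset of descendant leaf labels); the
    root branch is not represented.  A tree with n leaves has 2n - 2 branches.
    """

    taxa: tuple[str, ...]
    lengths: Mapping[frozenset, float]

    def __post_init__(self):
        taxa = set(self.taxa)
        if len(taxa) != len(self.taxa):
            raise FormatError("duplicate leaf labels in tree")
        for clade, ln in self.lengths.items():
            if not clade or not clade <= taxa:
                raise FormatError(f"clade {set(clade)} not within taxa")
            if not np.isfinite(ln) or ln < 0:
                raise FormatError(
                    f"branch {branch_id(clade)} has invalid length {ln!r}")

    @property
    def branch_ids(self) -> list[str]:
        """Branch ids ordered by clade size then lexicographically."""
        return [branch_id(c) for c in sorted(self.lengths,
                                             key=lambda c: (len(c), branch_id(c)))]

    @property
    def clades(self) -> list[frozenset]:
        return [frozenset(b.split("|")) for b in self.branch_ids]

    def to_newick(self) -> str:
        """Render the tree as a Newick string (lengths at %.17g)."""
        root = frozenset(self.taxa)

        def children(clade: frozenset) -> list[frozenset]:
            inside = [c for c in self.lengths if c < clade]
            out: list[frozenset] = []
            for c in sorted(inside, key=len, reverse=True):
                if not any(c < o for o in out):
                    out.append(c)
            return sorted(out, key=branch_id)

        def render(clade: frozenset) -> str:
            if len(clade) == 1:
                label = next(iter(clade))
            else:
                label = "(" + ",".join(
                    render(c) + ":" + FLOAT_FORMAT % self.lengths[c]
                    for c in children(clade)) + ")"
            return label

        return render(root) + ";"


def _tree_from_dendropy(tree: dendropy.Tree, where: str) -> SpeciesTree:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise FormatError(f"{where}: duplicate leaf labels")
    lengths: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if node.edge.length is None:
            raise FormatError(
                f"{where}: branch {branch_id(clade)} is missing a length")
        if clade in lengths:
            raise FormatError(f"{where}: duplicate clade {branch_id(clade)}")
        lengths[clade] = float(node.edge.length)
    return SpeciesTree(taxa=tuple(sorted(leaves)), lengths=lengths)


def parse_newick(text: str, where: str = "<string>") -> SpeciesTree:
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy reports the offending position
        raise FormatError(f"{where}: malformed Newick: {exc}") from exc
    return _tree_from_dendropy(tree, where)


def read_species_tree(path: str | Path) -> SpeciesTree:
    """Read a single Newick tree with branch lengths on every non-root branch."""
    return parse_newick(Path(path).read_text(), where=str(path))


def write_species_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Branch-length matrices
# ---------------------------------------------------------------------------

@dataclass
class BranchLengthMatrix:
    """Genes x master-branch lengths; NaN marks a missing branch.

    Columns are branch ids of a :class:`SpeciesTree`; rows are gene ids.
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.df.index.name = "gene_id"  # normalized so TSV round-trips exactly
        self.df.columns.name = None
        if self.df.index.has_duplicates:
            raise FormatError("duplicate gene ids in matrix")
        empty = self.df.isna().all(axis=1)
        if empty.any():
            raise FormatError(
                f"gene {empty.idxmax()!r} has no non-missing branch lengths")
        if (self.df.to_numpy() < 0).any():
            raise FormatError("negative branch length in matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def branches(self) -> list[str]:
        return list(self.df.columns)


def read_gene_trees(path: str | Path, species_tree: SpeciesTree) -> BranchLengthMatrix:
    """Project per-gene Newick trees onto the species tree's branch index.

    The input has one record per line: ``gene_id TAB newick``.  Each gene-tree
    branch is mapped to the master branch whose clade, restricted to the gene's
    taxa, is identical.  Master branches whose restrictions collide (taxa were
    pruned so that two master branches merge) are left missing for that gene,
    as are branches absent from the gene tree.  A gene-tree clade matching no
    master restriction is a topology error.
    """
    master_clades = species_tree.clades
    rows: dict[str, dict[str, float]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            gene, newick = line.split("\t", 1)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: expected 'gene_id<TAB>newick'")
        if gene in rows:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        gtree = parse_newick(newick, where=f"{path}:{lineno} ({gene})")
        taxa = set(gtree.taxa)
        if not taxa <= set(species_tree.taxa):
            extra = taxa - set(species_tree.taxa)
            raise FormatError(
                f"gene {gene!r}: taxa {sorted(extra)} not in species tree")
        # restriction of every master clade to this gene's taxa
        restricted: dict[frozenset, list[frozenset]] = {}
        for clade in master_clades:
            r = frozenset(clade & taxa)
            if r:
                restricted.setdefault(r, []).append(clade)
        row: dict[str, float] = {}
        for gclade, ln in gtree.lengths.items():
            if gclade == frozenset(taxa):
                continue  # root-adjacent clade of the restricted tree
            targets = restricted.get(gclade)
            if targets is None:
                raise FormatError(
                    f"gene {gene!r}: clade {branch_id(gclade)} is incompatible "
                    "with the species tree")
            if len(targets) == 1:
                row[branch_id(targets[0])] = ln
            # >1 target: pruning merged master branches -> all stay missing
        rows[gene] = row
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=species_tree.branch_ids, dtype=float)
    df = df.reindex(columns=species_tree.branch_ids)
    return BranchLengthMatrix(df)


def write_matrix_tsv(matrix: BranchLengthMatrix | pd.DataFrame,
                     path: str | Path, seed: int | None = None) -> None:
    """Write a gene x branch matrix; NA for missing, %.17g floats (round-trips)."""
    df = matrix.df if hasattr(matrix, "df") else matrix
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        df.to_csv(fh, sep="\t", na_rep=MISSING_TOKEN,
                  float_format=FLOAT_FORMAT, index_label="gene_id")


def read_matrix_tsv(path: str | Path) -> BranchLengthMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id",
                     na_values=[MISSING_TOKEN], keep_default_na=False)
    return BranchLengthMatrix(df.astype(float))


# ---------------------------------------------------------------------------
# Genomic intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Ordered chromosome name -> length (bp)."""

    chromosomes: dict[str, int]

    def __post_init__(self):
        for name, ln in self.chromosomes.items():
            if ln <= 0:
                raise FormatError(f"chromosome {name!r} has length {ln}")

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())


@dataclass
class IntervalSet:
    """An ordered collection of half-open genomic intervals."""

    intervals: list[Interval]
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def validate_against(self, genome: Genome) -> None:
        for iv in self.intervals:
            if iv.chrom not in genome.chromosomes:
                raise FormatError(f"unknown chromosome {iv.chrom!r}")
            if iv.end > genome.chromosomes[iv.chrom]:
                raise FormatError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {genome.chromosomes[iv.chrom]}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(chrom, start, end) as numpy arrays, in input order."""
        chrom = np.array([iv.chrom for iv in self.intervals], dtype=object)
        start = np.array([iv.start for iv in self.intervals], dtype=np.int64)
        end = np.array([iv.end for iv in self.intervals], dtype=np.int64)
        return chrom, start, end


def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read BED3+ (tab-separated, 0-based half-open, preserved as written)."""
    intervals: list[Interval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        if start >= end:
            raise FormatError(
                f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            score = float(fields[4])
        intervals.append(Interval(chrom, start, end, name, score))
    return IntervalSet(intervals, label or Path(path).stem)


def write_bed(s: IntervalSet, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        for iv in s:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(FLOAT_FORMAT % iv.score)
            fh.write("\t".join(fields) + "\n")


def read_gff3_features(path: str | Path, feature_types: Iterable[str],
                       label: str | None = None) -> IntervalSet:
    """Extract features of the given types from GFF3.

    GFF3 coordinates are 1-based closed; they are converted to 0-based
    half-open as (start - 1, end), so the converted length equals
    gff_end - gff_start + 1.
    """
    wanted = set(feature_types)
    intervals: list[Interval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise FormatError(f"{path}:{lineno}: fewer than 9 GFF3 columns")
        if fields[2] not in wanted:
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates")
        if end < start:
            raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
        name = None
        for attr in fields[8].split(";"):
            if attr.startswith(("ID=", "Name=")):
                name = attr.split("=", 1)[1]
                break
        intervals.append(Interval(fields[0], start - 1, end, name))
    return IntervalSet(intervals, label or Path(path).stem)


def read_genome_table(path: str | Path) -> Genome:
    """Read a chrom.sizes table: ``name TAB length`` per line."""
    chroms: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'name<TAB>length'")
        name = fields[0]
        if name in chroms:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        try:
            chroms[name] = int(fields[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer length")
    return Genome(chroms)


def write_genome_table(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, ln in genome.chromosomes.items():
            fh.write(f"{name}\t{ln}\n")


# ---------------------------------------------------------------------------
# Complex membership lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexSet:
    """A named, ordered set of gene/protein identifiers."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise FormatError(f"complex {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise FormatError(f"complex {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


def read_complexes(path: str | Path) -> list[ComplexSet]:
    """Read ``complex_name TAB member1,member2,...`` lines."""
    out: list[ComplexSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 'name<TAB>member1,member2,...'")
        name, members = fields[0], tuple(m for m in fields[1].split(",") if m)
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate complex {name!r}")
        seen.add(name)
        out.append(ComplexSet(name, members))
    return out


def write_complexes(complexes: Sequence[ComplexSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in complexes:
            fh.write(f"{c.name}\t{','.join(c.members)}\n")


def write_results_tsv(df: pd.DataFrame, path: str | Path,
                      seed: int | None = None) -> None:
    """Write a results table with the standard commented provenance header."""
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING_TOKEN,
                  float_format=FLOAT_FORMAT)
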