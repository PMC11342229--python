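"""Readers, validators and gene-level filters for five-taxon HGF analyses.

Every gene is represented by five sequences / five leaves bound to fixed
biological roles:

====== ==================================================================
Role   Meaning
====== ==================================================================
E_SUB  maternal subgenome of the allopolyploid (e.g. *C. arabica* E)
C_SUB  paternal subgenome of the allopolyploid (e.g. *C. arabica* C)
E_DIP  maternal diploid progenitor (e.g. *C. eugenioides*)
C_DIP  paternal diploid progenitor (e.g. *C. canephora*)
OUT    outgroup used to polarize alleles and root gene trees
====== ==================================================================

Role binding is by user-configurable regular expression on FASTA headers /
newick leaf labels, because deposited data sets rarely share a naming
convention. Genes that fail validation are skipped with a structured
:class:`SkipRecord`, never a crash: genome-wide pipelines must tolerate
bad genes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hgflow")

ROLES: Tuple[str, ...] = ("E_SUB", "C_SUB", "E_DIP", "C_DIP", "OUT")

#: IUPAC nucleotide codes accepted on input. U is normalized to T on read.
_IUPAC_AMBIG = set("RYSWKMBDHV")
_VALID_CHARS = set("ACGTN-") | _IUPAC_AMBIG

CATEGORIES: Tuple[str, ...] = ("NOT", "MTNI", "MTI", "MTEC", "PTNI", "PTI", "PTEC")


class HgflowError(Exception):
    """Base class for package errors."""


class RoleMapError(HgflowError):
    pass


class AlignmentError(HgflowError):
    pass


class CategoryTableError(HgflowError):
    pass


class TreeError(HgflowError):
    pass


@dataclass(frozen=True)
class SkipRecord:
    """Structured per-gene skip reason (gene excluded, run continues)."""

    gene_id: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.gene_id}\t{self.reason}"


@dataclass(frozen=True)
class RoleMap:
    """Binds the five roles to sequence-identifier regular expressions.

    A pattern matches a header via :func:`re.search`. For one gene each
    role must match exactly one sequence, and no sequence may be claimed
    by two roles.
    """

    patterns: Dict[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.patterns]
        if missing:
            raise RoleMapError(f"role map missing roles: {missing}")
        extra = [r for r in self.patterns if r not in ROLES]
        if extra:
            raise RoleMapError(f"role map has unknown roles: {extra}")
        for role, pat in self.patterns.items():
            try:
                re.compile(pat)
            except re.error as exc:
                raise RoleMapError(f"invalid pattern for {role}: {exc}") from exc

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "RoleMap":
        """Read a two-column TSV ``role<TAB>pattern``."""
        patterns: Dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RoleMapError(f"{path}:{lineno}: expected 2 tab-separated fields")
            role, pat = parts[0].strip(), parts[1].strip()
            patterns[role] = pat
        return cls(patterns)

    @classmethod
    def exact(cls) -> "RoleMap":
        """Role map for files whose headers are the role names themselves."""
        return cls({r: f"^{r}$" for r in ROLES})

    def assign(self, identifiers: Sequence[str]) -> Dict[str, str]:
        """Map each role to exactly one identifier.

        Raises :class:`RoleMapError` with a machine-readable message
        (``missing_role:X`` / ``ambiguous_role:X`` / ``multi_role:id``)
        when the binding is not one-to-one.
        """
        assigned: Dict[str, str] = {}
        claimed: Dict[str, str] = {}
        for role in ROLES:
            rx = re.compile(self.patterns[role])
            hits = [i for i in identifiers if rx.search(i)]
            if not hits:
                raise RoleMapError(f"missing_role:{role}")
            if len(hits) > 1:
                raise RoleMapError(f"ambiguous_role:{role}")
            ident = hits[0]
            if ident in claimed:
                raise RoleMapError(f"multi_role:{ident}")
            claimed[ident] = role
            assigned[role] = ident
        return assigned


def _normalize_sequence(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID_CHARS
    if bad:
        raise AlignmentError(f"invalid_characters:{''.join(sorted(bad))}")
    return s


@dataclass(frozen=True)
class GeneAlignment:
    """One gene's five aligned sequences, keyed by role.

    Sequences are upper-case, U normalized to T; all five must have
    identical length >= 1.
    """

    gene_id: str
    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.sequences]
        if missing:
            raise AlignmentError(f"missing_role:{missing[0]}")
        norm = {r: _normalize_sequence(s) for r, s in self.sequences.items()}
        lengths = {len(s) for s in norm.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal_lengths:{sorted(lengths)}")
        if lengths == {0}:
            raise AlignmentError("empty_alignment")
        object.__setattr__(self, "sequences", norm)

    @property
    def length(self) -> int:
        return len(self.sequences["OUT"])


@dataclass(frozen=True)
class CategoryAssignment:
    gene_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CategoryTableError(f"unknown category: {self.category!r}")


# Ingroup tree structure: a leaf is a role string, an internal node a
# 2-tuple of child structures. Branch lengths are irrelevant to topology
# identity and are not retained.
IngroupNode = Union[str, Tuple["IngroupNode", "IngroupNode"]]


@dataclass(frozen=True)
class GeneTree:
    """A rooted five-taxon gene tree reduced to its role-labelled shape.

    ``ingroup`` is the four-leaf subtree obtained after rooting at OUT,
    encoded as nested 2-tuples of role names. ``supports`` holds the
    bootstrap values (0-100) of the internal ingroup edges in no
    particular order; ``None`` entries mean the newick carried no label.
    """

    gene_id: str
    ingroup: IngroupNode
    supports: Tuple[Optional[float], ...] = ()

    def __post_init__(self) -> None:
        leaves = ingroup_leaves(self.ingroup)
        if sorted(leaves) != sorted(r for r in ROLES if r != "OUT"):
            raise TreeError(f"bad_ingroup_leaves:{sorted(leaves)}")

    def min_support(self) -> Optional[float]:
        """Smallest ingroup internal support; None if no labels present."""
        vals = [s for s in self.supports if s is not None]
        return min(vals) if vals else None

    def newick(self) -> str:
        def render(node: IngroupNode) -> str:
            if isinstance(node, str):
                return node
            return "(" + ",".join(render(c) for c in node) + ")"

        return f"({render(self.ingroup)},OUT);"


def ingroup_leaves(node: IngroupNode) -> List[str]:
    if isinstance(node, str):
        return [node]
    out: List[str] = []
    for child in node:
        out.extend(ingroup_leaves(child))
    return out


# ---------------------------------------------------------------------------
# FASTA reading / writing
# ---------------------------------------------------------------------------

def read_gene_alignment(path: Union[str, Path], roles: RoleMap) -> GeneAlignment:
    """Read one FASTA file into a :class:`GeneAlignment` (raises on error)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 5:
        raise AlignmentError(f"too_few_sequences:{len(records)}")
    by_id = {rec.id: str(rec.seq) for rec in records}
    assignment = roles.assign(list(by_id))
    return GeneAlignment(
        gene_id=path.stem,
        sequences={role: by_id[ident] for role, ident in assignment.items()},
    )


def read_gene_alignments(
    path: Union[str, Path], roles: RoleMap
) -> Tuple[List[GeneAlignment], List[SkipRecord]]:
    """Read a directory of per-gene FASTA files.

    Returns the valid alignments plus one :class:`SkipRecord` per gene
    that failed validation (missing/ambiguous role, unequal lengths, bad
    characters, unparseable file).
    """
    genes: List[GeneAlignment] = []
    skipped: List[SkipRecord] = []
    files = sorted(
        p for p in Path(path).iterdir()
        if p.suffix.lower() in {".fa", ".fasta", ".fna", ".aln"}
    )
    for fp in files:
        try:
            genes.append(read_gene_alignment(fp, roles))
        except (HgflowError, ValueError) as exc:
            rec = SkipRecord(gene_id=fp.stem, reason=str(exc))
            logger.warning("skip gene %s: %s", rec.gene_id, rec.reason)
            skipped.append(rec)
    return genes, skipped


def write_gene_alignment(gene: GeneAlignment, path: Union[str, Path]) -> None:
    """Write a gene back to FASTA with role names as headers."""
    records = [
        SeqRecord(Seq(gene.sequences[r]), id=r, description="") for r in ROLES
    ]
    SeqIO.write(records, str(path), "fasta")


def apply_length_filter(
    genes: Iterable[GeneAlignment], min_len: int = 99
) -> List[GeneAlignment]:
    """Keep genes whose alignment length is >= ``min_len`` (inclusive).

    The default of 99 bp is the shortest trimmed alignment admitted to
    the D tests. Retained/dropped counts are logged.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    genes = list(genes)
    kept = [g for g in genes if g.length >= min_len]
    logger.info(
        "length filter (>=%d bp): retained %d, dropped %d",
        min_len, len(kept), len(genes) - len(kept),
    )
    return kept


# ---------------------------------------------------------------------------
# Newick reading
# ---------------------------------------------------------------------------

def _tree_to_graph(tree: dendropy.Tree):
    """Adjacency view of a dendropy tree with per-edge support labels.

    The label of an internal node annotates the edge between that node
    and its parent in the parsed orientation (standard newick
    convention); re-rooting preserves edge identity so supports survive
    rooting at OUT.
    """
    adj: Dict[int, List[Tuple[int, Optional[float]]]] = {}
    nodes: Dict[int, dendropy.Node] = {}

    def support_of(node: dendropy.Node) -> Optional[float]:
        if node.is_leaf():
            return None
        label = node.label
        if label is None:
            return None
        try:
            return float(label)
        except ValueError:
            return None

    for node in tree.preorder_node_iter():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        if node.parent_node is not None:
            sup = support_of(node)
            adj[id(node)].append((id(node.parent_node), sup))
            adj.setdefault(id(node.parent_node), []).append((id(node), sup))
    return adj, nodes


def _parse_gene_tree(path: Path, roles: RoleMap) -> GeneTree:
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in leaves]
    if len(labels) != 5:
        raise TreeError(f"wrong_leaf_count:{len(labels)}")
    assignment = roles.assign(labels)  # may raise RoleMapError
    label_to_role = {ident: role for role, ident in assignment.items()}

    adj, nodes = _tree_to_graph(tree)
    out_leaf = next(l for l in leaves if label_to_role[l.taxon.label] == "OUT")

    supports: List[Optional[float]] = []

    def build(node_id: int, parent_id: int) -> IngroupNode:
        node = nodes[node_id]
        children = [(nid, sup) for nid, sup in adj[node_id] if nid != parent_id]
        if not children:
            return label_to_role[node.taxon.label]
        if len(children) != 2:
            raise TreeError("polytomy_in_ingroup")
        built = []
        for child_id, sup in children:
            if not nodes[child_id].is_leaf():
                supports.append(sup)
            built.append(build(child_id, node_id))
        return (built[0], built[1])

    # Root at OUT: the ingroup is everything on the far side of the OUT
    # edge. The OUT-adjacent node may be the parsed root (possibly a
    # trifurcation for unrooted newick) or an internal node.
    (nbr_id, _), = adj[id(out_leaf)]
    others = [(nid, sup) for nid, sup in adj[nbr_id] if nid != id(out_leaf)]
    if len(others) == 1:
        # OUT hangs off a rooted bifurcation: ingroup root is the sibling.
        ingroup = build(others[0][0], nbr_id)
    elif len(others) == 2:
        # Unrooted trifurcation at OUT's neighbor: the two other children
        # form the ingroup root's children; the edge supports between them
        # belong inside the ingroup.
        built = []
        for child_id, sup in others:
            if not nodes[child_id].is_leaf():
                supports.append(sup)
            built.append(build(child_id, nbr_id))
        ingroup = (built[0], built[1])
    else:
        raise TreeError("polytomy_in_ingroup")
    return GeneTree(gene_id=path.stem, ingroup=ingroup, supports=tuple(supports))


def read_gene_tree(path: Union[str, Path], roles: RoleMap) -> GeneTree:
    """Read one newick file, root at OUT, and reduce to a :class:`GeneTree`."""
    return _parse_gene_tree(Path(path), roles)


def read_gene_trees(
    path: Union[str, Path], roles: RoleMap
) -> Tuple[List[GeneTree], List[SkipRecord]]:
    """Read a directory of per-gene newick files; bad genes are skipped."""
    trees: List[GeneTree] = []
    skipped: List[SkipRecord] = []
    files = sorted(
        p for p in Path(path).iterdir()
        if p.suffix.lower() in {".nwk", ".newick", ".tre", ".tree", ".treefile"}
    )
    for fp in files:
        try:
            trees.append(_parse_gene_tree(fp, roles))
        except (HgflowError, Exception) as exc:  # dendropy raises its own types
            if isinstance(exc, KeyboardInterrupt):  # pragma: no cover
                raise
            rec = SkipRecord(gene_id=fp.stem, reason=str(exc))
            logger.warning("skip tree %s: %s", rec.gene_id, rec.reason)
            skipped.append(rec)
    return trees, skipped


# ---------------------------------------------------------------------------
# Category table
# ---------------------------------------------------------------------------

def read_category_table(path: Union[str, Path]) -> List[CategoryAssignment]:
    """Read a two-column TSV ``gene_id<TAB>category``.

    Unknown category tokens and malformed rows raise
    :class:`CategoryTableError` with the offending line number.
    """
    out: List[CategoryAssignment] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0].strip():
            raise CategoryTableError(f"{path}:{lineno}: malformed row")
        gene_id, category = parts[0].strip(), parts[1].strip()
        if category not in CATEGORIES:
            raise CategoryTableError(
                f"{path}:{lineno}: unknown category {category!r}"
            )
        out.append(CategoryAssignment(gene_id=gene_id, category=category))
    return out


def category_map(
    assignments: Iterable[CategoryAssignment], gene_ids: Iterable[str]
) -> Dict[str, str]:
    """Resolve a category per gene; genes absent from the table are NOT.

    The NOT category is defined as the complement of the organelle-
    targeted sets, so unlisted genes default there (with a warning).
    Table rows for genes outside ``gene_ids`` are ignored with a warning.
    """
    table = {a.gene_id: a.category for a in assignments}
    gene_ids = list(gene_ids)
    unknown = sorted(set(table) - set(gene_ids))
    if unknown:
        logger.warning("category table lists %d unknown gene ids (ignored)", len(unknown))
    result: Dict[str, str] = {}
    n_defaulted = 0
    for gid in gene_ids:
        if gid in table:
            result[gid] = table[gid]
        else:
            result[gid] = "NOT"
            n_defaulted += 1
    if n_defaulted:
        logger.warning("%d genes absent from category table; defaulted to NOT", n_defaulted)
    return result
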