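"""I/O and tree plumbing: alignments, species trees, focal-clade resolution, result tables.

Alignments are FASTA files of aligned amino-acid sequences; trees are rooted
Newick with branch lengths in expected substitutions per site.  Focal clades —
the lineages tested for convergence — are named tip sets resolved to the branch
subtending each set's most recent common ancestor.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from convscan.alphabet import AMINO_ACIDS, MISSING, decode_states, encode_sequence

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id",
    "n_sites_used",
    "k_observed",
    "k_parallel",
    "k_divergent_origin",
    "lambda_expected",
    "p_value",
    "q_value",
    "significant",
    "pcoc_sites",
    "pcoc_flag",
]


@dataclasses.dataclass(frozen=True)
class Alignment:
    """A per-gene amino-acid alignment.

    ``states`` holds integer residue codes (alphabetical index, 20 = missing)
    with one row per taxon, one column per site.
    """

    gene_id: str
    taxa: tuple[str, ...]
    states: np.ndarray  # int8, shape (n_taxa, n_sites)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError(f"duplicate taxon names in alignment {self.gene_id!r}")
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("states matrix does not match taxa")
        if self.states.shape[1] < 1:
            raise ValueError(f"alignment {self.gene_id!r} has no sites")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def sequence(self, taxon: str) -> str:
        return decode_states(self.row(taxon))

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(self.gene_id, tuple(taxa), self.states[idx])

    @classmethod
    def from_sequences(cls, gene_id: str, seqs: Mapping[str, str]) -> "Alignment":
        taxa = tuple(seqs)
        rows = [encode_sequence(seqs[t]) for t in taxa]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in {gene_id!r}: {sorted(lengths)}")
        return cls(gene_id, taxa, np.vstack(rows))


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned amino-acid FASTA file.

    Lowercase is folded to uppercase; ``-``, ``.`` and ``?`` become gaps; any
    letter outside the 20 canonical residues is stored as missing (X) with a
    warning.  Records of unequal length raise ``ValueError`` naming the
    offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    length = len(records[0].seq)
    seqs: dict[str, str] = {}
    for rec in records:
        s = str(rec.seq).upper()
        if len(s) != length:
            raise ValueError(
                f"record {rec.id!r} in {path} has length {len(s)}, expected {length}"
            )
        odd = sorted({c for c in s if c not in AMINO_ACIDS and c not in "-.?X"})
        if odd:
            logger.warning(
                "record %r in %s: non-standard letters %s stored as X", rec.id, path, odd
            )
        if rec.id in seqs:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seqs[rec.id] = s
    return Alignment.from_sequences(path.stem, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA (missing residues rendered as ``-``)."""
    records = [
        SeqRecord(Seq(aln.sequence(t)), id=t, description="") for t in aln.taxa
    ]
    SeqIO.write(records, str(path), "fasta")


class PhyloTree:
    """A rooted species tree with branch lengths in substitutions/site.

    Wraps a :class:`dendropy.Tree`.  Unnamed internal nodes are assigned
    stable labels (``nd<i>`` in preorder) so ancestral states can be reported
    per node.  A trifurcation at the root is accepted.
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self._tree = tree
        self._tree.is_rooted = True
        self._validate()
        self._label_internal()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises reader-specific errors
            raise ValueError(f"cannot parse Newick (duplicate labels or malformed): {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        t = self._tree
        labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in t.preorder_node_iter():
            if node is t.seed_node:
                continue
            bl = node.edge.length
            if bl is None:
                raise ValueError(
                    f"branch above {_node_desc(node)} lacks a branch length"
                )
            if not np.isfinite(bl) or bl < 0:
                raise ValueError(
                    f"branch above {_node_desc(node)} has invalid length {bl}"
                )

    def _label_internal(self) -> None:
        i = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label is None:
                node.label = f"nd{i}"
            i += 1

    # -- basic queries -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def postorder(self) -> list[dendropy.Node]:
        return list(self._tree.postorder_node_iter())

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def mrca_node(self, tip_labels: Iterable[str]) -> dendropy.Node:
        labels = list(tip_labels)
        missing = [x for x in labels if x not in self.taxa]
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        if len(labels) == 1:
            return self._tree.find_node_with_taxon_label(labels[0])
        return self._tree.mrca(taxon_labels=labels)

    # -- manipulation --------------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def pruned_to(self, tip_labels: Sequence[str]) -> "PhyloTree":
        """Working copy restricted to ``tip_labels``.

        Degree-two nodes left by pruning are suppressed with the lengths of
        the merged edges summed.
        """
        keep = set(tip_labels)
        missing = keep - set(self.taxa)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        t = self._tree.clone(depth=1)
        t.retain_taxa_with_labels(list(keep))
        # retain_taxa suppresses unifurcations, adding child+parent lengths.
        return PhyloTree(t)

    def newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".10g",
            ).strip()
        )


def _node_desc(node: dendropy.Node) -> str:
    if node.is_leaf():
        return f"tip {node.taxon.label!r}"
    tips = [l.taxon.label for l in node.leaf_iter()]
    return f"internal node ({','.join(sorted(tips)[:4])}...)" if len(tips) > 4 else (
        f"internal node ({','.join(sorted(tips))})"
    )


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty tree file {path}")
    return PhyloTree.from_newick(text)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


@dataclasses.dataclass(frozen=True)
class FocalClade:
    """A named convergent lineage, specified by the tips it spans."""

    name: str
    tips: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tips:
            raise ValueError(f"focal clade {self.name!r} has no tips")


@dataclasses.dataclass(frozen=True)
class FocalConfig:
    """Focal clades resolved against one tree.

    ``nodes[i]`` is the MRCA node of ``clades[i]`` (the tip node for a
    singleton clade); the focal branch is the edge above that node.
    """

    tree: PhyloTree
    clades: tuple[FocalClade, ...]
    nodes: tuple[dendropy.Node, ...]

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    def branch_lengths(self) -> np.ndarray:
        return np.array([n.edge.length for n in self.nodes], dtype=float)

    def parents(self) -> tuple[dendropy.Node, ...]:
        return tuple(n.parent_node for n in self.nodes)


def resolve_focal(
    tree: PhyloTree, clades: Sequence[FocalClade | tuple[str, Sequence[str]]]
) -> FocalConfig:
    """Resolve focal tip sets to branches on ``tree``.

    Requires at least two clades with pairwise disjoint tip sets whose MRCA
    nodes are not ancestrally related; each resolved node must have a parent
    (the convergence test needs the residue on both ends of the focal branch).
    """
    norm: list[FocalClade] = []
    for c in clades:
        if isinstance(c, FocalClade):
            norm.append(c)
        else:
            name, tips = c
            norm.append(FocalClade(name, tuple(tips)))
    if len(norm) < 2:
        raise ValueError("need at least two focal clades")
    seen: set[str] = set()
    for c in norm:
        overlap = seen & set(c.tips)
        if overlap:
            raise ValueError(f"focal clades overlap on tips {sorted(overlap)}")
        seen |= set(c.tips)
    nodes = [tree.mrca_node(c.tips) for c in norm]
    for c, n in zip(norm, nodes):
        if n.parent_node is None:
            raise ValueError(
                f"focal clade {c.name!r} resolves to the root; its ancestral "
                "state is undefined"
            )
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i != j and _is_ancestor(a, b):
                raise ValueError(
                    f"focal clade {norm[i].name!r} is nested above "
                    f"{norm[j].name!r}"
                )
    return FocalConfig(tree=tree, clades=tuple(norm), nodes=tuple(nodes))


def _is_ancestor(a: dendropy.Node, b: dendropy.Node) -> bool:
    node = b
    while node is not None:
        if node is a:
            return True
        node = node.parent_node
    return False


def write_results(results: Iterable, path: str | Path) -> None:
    """Write a gene-level result table as TSV, rows sorted by gene_id."""
    rows = []
    for r in results:
        if isinstance(r, Mapping):
            d = dict(r)
        elif dataclasses.is_dataclass(r):
            d = {k: getattr(r, k) for k in RESULT_COLUMNS if hasattr(r, k)}
        else:
            d = {k: getattr(r, k) for k in RESULT_COLUMNS}
        rows.append({k: d.get(k) for k in RESULT_COLUMNS})
    if not rows:
        raise ValueError("no results to write")
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values("gene_id")
    df.to_csv(path, sep="\t", index=False)
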