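"""Phylogenetic likelihood and marginal ancestral state reconstruction.

Site likelihoods come from Felsenstein's pruning algorithm with the stationary
profile as root prior.  Ancestral states are marginal (empirical-Bayes)
posteriors obtained from one post-order (inside) pass and one pre-order
(outside) pass; the reported state at a node is the posterior mode, with exact
ties broken alphabetically.  Missing residues contribute all-ones partial
likelihood vectors.  Per-node, per-site scaling keeps the passes stable on
long alignments without affecting the reported log-likelihood.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import dendropy
import numpy as np

from convscan.alphabet import MISSING, decode_state, encode_residue
from convscan.phylo_io import Alignment, PhyloTree
from convscan.subst_model import RateModel

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


class _IndexedTree:
    """Postorder-flattened view of a PhyloTree for array-based passes."""

    def __init__(self, tree: PhyloTree) -> None:
        self.nodes = tree.postorder()  # root last
        self.index_of = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.length = np.full(n, np.nan)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.is_tip = np.zeros(n, dtype=bool)
        self.labels: list[str] = []
        for i, node in enumerate(self.nodes):
            self.labels.append(tree.node_label(node))
            self.is_tip[i] = node.is_leaf()
            if node.parent_node is not None:
                p = self.index_of[id(node.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.length[i] = node.edge.length
        self.root = n - 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclasses.dataclass
class AncestralReconstruction:
    """Per-node, per-site posteriors, MAP states, and site log-likelihoods."""

    tree: PhyloTree
    node_labels: tuple[str, ...]  # postorder, root last
    posteriors: np.ndarray  # (n_nodes, n_sites, n_states), each row sums to 1
    map_states: np.ndarray  # (n_nodes, n_sites) int
    site_log_likelihoods: np.ndarray  # (n_sites,)
    tip_states: np.ndarray  # (n_nodes, n_sites) int; MISSING for internals
    observed_below: np.ndarray  # (n_nodes, n_sites) bool
    _index: _IndexedTree

    @property
    def n_sites(self) -> int:
        return self.site_log_likelihoods.shape[0]

    def node_index(self, node: dendropy.Node) -> int:
        return self._index.index_of[id(node)]

    def label_index(self, label: str) -> int:
        return self.node_labels.index(label)

    def posterior(self, label: str) -> np.ndarray:
        return self.posteriors[self.label_index(label)]

    def map_state(self, label: str) -> np.ndarray:
        return self.map_states[self.label_index(label)]

    def map_sequence(self, label: str) -> str:
        return "".join(decode_state(int(s)) for s in self.map_state(label))


def _tip_state_matrix(index: _IndexedTree, aln: Alignment) -> np.ndarray:
    """(n_nodes, n_sites) observed states; MISSING at internals and absent taxa."""
    states = np.full((index.n_nodes, aln.n_sites), MISSING, dtype=np.int16)
    rows = {t: i for i, t in enumerate(aln.taxa)}
    for i, node in enumerate(index.nodes):
        if index.is_tip[i]:
            label = node.taxon.label
            if label not in rows:
                raise KeyError(f"tree tip {label!r} absent from alignment")
            states[i] = aln.states[rows[label]]
    return states


def _inside_pass(
    index: _IndexedTree, tip_states: np.ndarray, model: RateModel
) -> tuple[list[np.ndarray], list[np.ndarray | None], np.ndarray, np.ndarray]:
    """Post-order conditional likelihoods.

    Returns per-node (scaled) inside vectors, per-node child messages through
    each edge, the per-site accumulated log-scales, and site log-likelihoods.
    """
    n = model.n_states
    n_sites = tip_states.shape[1]
    # indicator lookup: row MISSING (== index n) is all ones
    lookup = np.vstack([np.eye(n), np.ones((1, n))])
    up: list[np.ndarray] = [None] * index.n_nodes  # type: ignore[list-item]
    msg: list[np.ndarray | None] = [None] * index.n_nodes  # edge message to parent
    log_scale = np.zeros(n_sites)
    for i in range(index.n_nodes):
        if index.is_tip[i]:
            codes = np.minimum(tip_states[i].astype(int), n)  # MISSING -> ones row
            vec = lookup[codes]
        else:
            vec = np.ones((n_sites, n))
            for c in index.children[i]:
                vec = vec * msg[c]
            scale = vec.max(axis=1)
            scale = np.where(scale > 0, scale, 1.0)
            vec = vec / scale[:, None]
            log_scale += np.log(scale)
        up[i] = vec
        if index.parent[i] >= 0:
            P = model.transition_matrix(float(index.length[i]))
            msg[i] = vec @ P.T  # msg[x] = sum_y P[x,y] * up[y]
    root_like = up[index.root] @ model.pi.pi
    site_ll = np.log(np.maximum(root_like, _TINY)) + log_scale
    return up, msg, log_scale, site_ll


def _outside_pass(
    index: _IndexedTree,
    up: list[np.ndarray],
    msg: list[np.ndarray | None],
    model: RateModel,
) -> list[np.ndarray]:
    """Pre-order outside probabilities (scaled); root outside = prior."""
    n = model.n_states
    n_sites = up[0].shape[0]
    out: list[np.ndarray] = [None] * index.n_nodes  # type: ignore[list-item]
    out[index.root] = np.broadcast_to(model.pi.pi, (n_sites, n)).copy()
    for i in range(index.n_nodes - 1, -1, -1):  # reverse postorder = preorder
        if index.is_tip[i]:
            continue
        kids = index.children[i]
        for c in kids:
            partial = out[i].copy()
            for s in kids:
                if s != c:
                    partial *= msg[s]
            P = model.transition_matrix(float(index.length[c]))
            vec = partial @ P
            scale = vec.max(axis=1)
            scale = np.where(scale > 0, scale, 1.0)
            out[c] = vec / scale[:, None]
    return out


def reconstruct(
    tree: PhyloTree, aln: Alignment, model: RateModel
) -> AncestralReconstruction:
    """Site likelihoods plus marginal ancestral posteriors for every node.

    The tree's tip set must be covered by the alignment's taxa.  Columns with
    no observed residue carry no information: their likelihood is 1 (log 0)
    and every posterior equals the prior; a warning notes how many there are.
    """
    index = _IndexedTree(tree)
    tip_states = _tip_state_matrix(index, aln)
    empty = ~np.any(tip_states[index.is_tip] != MISSING, axis=0)
    if np.any(empty):
        logger.warning(
            "%s: %d column(s) with no observed residue carry no information",
            aln.gene_id,
            int(empty.sum()),
        )
    up, msg, _, site_ll = _inside_pass(index, tip_states, model)
    out = _outside_pass(index, up, msg, model)

    n_nodes, n_sites = index.n_nodes, aln.n_sites
    posteriors = np.empty((n_nodes, n_sites, model.n_states))
    for i in range(n_nodes):
        joint = out[i] * up[i]
        total = joint.sum(axis=1)
        total = np.where(total > 0, total, 1.0)
        posteriors[i] = joint / total[:, None]
    map_states = posteriors.argmax(axis=2)  # first max = alphabetical tie-break

    observed_below = np.zeros((n_nodes, n_sites), dtype=bool)
    for i in range(n_nodes):
        if index.is_tip[i]:
            observed_below[i] = tip_states[i] != MISSING
        else:
            for c in index.children[i]:
                observed_below[i] |= observed_below[c]

    return AncestralReconstruction(
        tree=tree,
        node_labels=tuple(index.labels),
        posteriors=posteriors,
        map_states=map_states,
        site_log_likelihoods=site_ll,
        tip_states=tip_states,
        observed_below=observed_below,
        _index=index,
    )


def _site_to_alignment(tree: PhyloTree, site: Mapping[str, object]) -> Alignment:
    """Build a one-column alignment from a {taxon: residue-or-state} mapping."""
    taxa = tuple(site)
    states = np.empty((len(taxa), 1), dtype=np.int8)
    for i, t in enumerate(taxa):
        v = site[t]
        states[i, 0] = v if isinstance(v, (int, np.integer)) else encode_residue(str(v))
    return Alignment("site", taxa, states)


def site_log_likelihood(
    tree: PhyloTree, site: Mapping[str, object], model: RateModel
) -> float:
    """Pruning log-likelihood of one alignment column.

    ``site`` maps each tip label to a residue letter (or a state index, which
    permits toy alphabets).  Missing tips contribute no information.
    """
    full = {t: site.get(t, MISSING) for t in tree.taxa}
    recon = reconstruct(tree, _site_to_alignment(tree, full), model)
    return float(recon.site_log_likelihoods[0])


def marginal_posteriors(
    tree: PhyloTree, site: Mapping[str, object], model: RateModel
) -> AncestralReconstruction:
    """Single-site convenience wrapper around :func:`reconstruct`."""
    full = {t: site.get(t, MISSING) for t in tree.taxa}
    return reconstruct(tree, _site_to_alignment(tree, full), model)


def map_ancestral_states(
    recon: AncestralReconstruction, confidence_floor: float = 0.0
) -> tuple[dict[str, str], np.ndarray]:
    """MAP residue strings per node, plus a low-confidence mask.

    A site is flagged low-confidence at a node when the winning posterior
    falls below ``confidence_floor`` (0 disables flagging).
    """
    best = np.take_along_axis(
        recon.posteriors, recon.map_states[:, :, None], axis=2
    )[:, :, 0]
    low_conf = best < confidence_floor
    seqs = {
        label: recon.map_sequence(label)
        for label in recon.node_labels
    }
    return seqs, low_conf
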