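"""Synthetic ortholog-alignment simulator with ancestral truth.

Generates per-gene amino-acid alignments by evolving sites along the species
tree under the reversible JTT+F process: root residues are drawn from the
stationary profile, and each branch substitutes states by sampling from the
branch's transition-matrix row.  Every internal-node state is recorded, so the
simulator doubles as a source of exact ancestral truth for calibration of the
reconstruction and convergence machinery.

Two mechanisms inject convergent signal into chosen sites:

* ``forced-substitution`` — a target residue differing from every focal
  branch's ancestral state is written onto the focal MRCA nodes and all their
  descendants, giving convergence that is true by construction;
* ``profile-shift`` — the site is re-evolved with the focal subtrees governed
  by a distinct preference profile, the data-generating process assumed by
  the profile-shift detector.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from convscan.alphabet import decode_state
from convscan.ancestry import _IndexedTree
from convscan.phylo_io import (
    Alignment,
    FocalClade,
    PhyloTree,
    read_tree,
    resolve_focal,
    write_alignment,
)
from convscan.subst_model import (
    RateModel,
    StationaryProfile,
    build_rate_model,
    jtt_exchangeabilities,
    jtt_frequencies,
)

FORCED = "forced-substitution"
PROFILE_SHIFT = "profile-shift"


def rodent_tree() -> PhyloTree:
    """The 13-taxon rodent species tree used as the default scaffold."""
    with resources.as_file(
        resources.files("convscan").joinpath("data/rodent_tree.nwk")
    ) as p:
        return read_tree(p)


def rodent_focal_clades() -> list[FocalClade]:
    """Default focal lineages: hamster, gerbil and jerboa groups."""
    return [
        FocalClade("hamster", ("Prob",)),
        FocalClade("gerbil", ("Mmer", "Mung")),
        FocalClade("jerboa", ("Dsag", "Osib", "Jjac")),
    ]


@dataclasses.dataclass
class SimulatedGene:
    """An alignment plus full ancestral truth."""

    gene_id: str
    alignment: Alignment
    tree: PhyloTree
    node_states: dict[str, np.ndarray]  # node label -> (n_sites,) true states
    convergent_sites: list[int]
    mechanism: str | None
    site_targets: dict[int, int]  # injected site -> target state (forced mode)
    profile: StationaryProfile

    @property
    def n_sites(self) -> int:
        return self.alignment.n_sites


def _sample_rows(P: np.ndarray, parent_states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw child states from the transition rows of the parent states."""
    cdf = P.cumsum(axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] > cdf[parent_states]).sum(axis=1)


def _evolve(
    index: _IndexedTree,
    model: RateModel,
    n_sites: int,
    rng: np.random.Generator,
    branch_models: Sequence[RateModel] | None = None,
    redraw: Mapping[int, np.ndarray] | None = None,
) -> np.ndarray:
    """Simulate states at every node; returns (n_nodes, n_sites) ints.

    ``redraw`` maps node indices to profiles from which that node's state is
    drawn anew instead of evolving from its parent — the completed-shift
    convention for convergent branches.
    """
    states = np.empty((index.n_nodes, n_sites), dtype=np.int64)
    states[index.root] = rng.choice(model.n_states, size=n_sites, p=model.pi.pi)
    for i in range(index.n_nodes - 1, -1, -1):  # preorder
        p = index.parent[i]
        if p < 0:
            continue
        if redraw is not None and i in redraw:
            states[i] = rng.choice(redraw[i].size, size=n_sites, p=redraw[i])
            continue
        m = branch_models[i] if branch_models is not None else model
        P = m.transition_matrix(float(index.length[i]))
        states[i] = _sample_rows(P, states[p], rng)
    return states


def simulate_gene(
    tree: PhyloTree,
    model: RateModel,
    n_sites: int,
    seed: int | np.random.Generator,
    gene_id: str = "gene",
) -> SimulatedGene:
    """Evolve one gene of ``n_sites`` iid sites along ``tree`` under ``model``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    index = _IndexedTree(tree)
    states = _evolve(index, model, n_sites, rng)
    node_states = {index.labels[i]: states[i] for i in range(index.n_nodes)}
    tip_rows = {
        index.labels[i]: decode_state_array(states[i])
        for i in range(index.n_nodes)
        if index.is_tip[i]
    }
    aln = Alignment.from_sequences(gene_id, tip_rows)
    return SimulatedGene(
        gene_id=gene_id,
        alignment=aln,
        tree=tree,
        node_states=node_states,
        convergent_sites=[],
        mechanism=None,
        site_targets={},
        profile=model.pi,
    )


def decode_state_array(states: np.ndarray) -> str:
    return "".join(decode_state(int(s)) for s in states)


def inject_convergence(
    gene: SimulatedGene,
    focal_clades: Sequence[FocalClade],
    mechanism: str,
    k_sites: int,
    seed: int | np.random.Generator,
    model: RateModel,
    shift_model: RateModel | None = None,
) -> SimulatedGene:
    """Overwrite ``k_sites`` randomly chosen sites with convergent signal.

    Returns a new :class:`SimulatedGene` with updated alignment, truth states
    and labels.  ``model`` is the background process (used to re-evolve sites
    and to pick forced targets from its stationary profile); ``shift_model``
    is required for the ``profile-shift`` mechanism.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = gene.n_sites
    if k_sites > n_sites:
        raise ValueError("cannot inject more convergent sites than sites")
    if k_sites == 0:
        return dataclasses.replace(
            gene, convergent_sites=[], mechanism=mechanism, site_targets={}
        )
    if mechanism not in (FORCED, PROFILE_SHIFT):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if mechanism == PROFILE_SHIFT and shift_model is None:
        raise ValueError("profile-shift injection needs a shift model")

    index = _IndexedTree(gene.tree)
    focal = resolve_focal(gene.tree, focal_clades)
    focal_idx = [index.index_of[id(n)] for n in focal.nodes]
    parent_idx = [index.parent[i] for i in focal_idx]
    subtree = _subtree_members(index, focal_idx)

    states = np.vstack([gene.node_states[index.labels[i]] for i in range(index.n_nodes)])
    chosen = np.sort(rng.choice(n_sites, size=k_sites, replace=False))
    targets: dict[int, int] = {}

    if mechanism == FORCED:
        pi = model.pi.pi
        for s in chosen:
            forbidden = {int(states[p, s]) for p in parent_idx}
            weights = pi.copy()
            for f in forbidden:
                weights[f] = 0.0
            weights /= weights.sum()
            a = int(rng.choice(model.n_states, p=weights))
            for i in subtree:
                states[i, s] = a
            targets[int(s)] = a
    else:
        # Completed preference shift: the state at each focal MRCA is drawn
        # from the shifted profile (at least one substitution on the focal
        # branch, the PCOC one-change convention) and the subtree then
        # evolves under the shifted process.
        branch_models = [
            shift_model if i in subtree else model for i in range(index.n_nodes)
        ]
        redraw = {i: shift_model.pi.pi for i in focal_idx}
        fresh = _evolve(
            index, model, k_sites, rng, branch_models=branch_models, redraw=redraw
        )
        states[:, chosen] = fresh

    node_states = {index.labels[i]: states[i] for i in range(index.n_nodes)}
    tip_rows = {
        index.labels[i]: decode_state_array(states[i])
        for i in range(index.n_nodes)
        if index.is_tip[i]
    }
    aln = Alignment.from_sequences(gene.gene_id, tip_rows)
    return SimulatedGene(
        gene_id=gene.gene_id,
        alignment=aln,
        tree=gene.tree,
        node_states=node_states,
        convergent_sites=[int(s) for s in chosen],
        mechanism=mechanism,
        site_targets=targets,
        profile=gene.profile,
    )


def _subtree_members(index: _IndexedTree, focal_idx: Sequence[int]) -> set[int]:
    """Indices of the focal MRCA nodes and every node beneath them."""
    members: set[int] = set()
    for i in range(index.n_nodes - 1, -1, -1):  # preorder
        if i in focal_idx or (index.parent[i] >= 0 and index.parent[i] in members):
            members.add(i)
    return members


@dataclasses.dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic ortholog sets.

    ``n_sites`` of 300 matches a typical trimmed single-copy ortholog; the
    base profile is a per-gene Dirichlet draw centred on the JTT frequencies
    (concentration 100), emulating gene-to-gene compositional variation.
    """

    tree: str | None = None  # path; None -> shipped rodent tree
    n_genes: int = 200
    n_sites: int = 300
    profile_source: str = "dirichlet"  # uniform | dirichlet | jtt | <path>
    dirichlet_concentration: float = 100.0
    n_convergent_sites: int = 0
    mechanism: str = FORCED
    shift_profile: str | None = None  # name in the default catalogue, or path
    branch_scale: float = 1.0
    pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**data)


def _gene_profile(
    config: SimulationConfig, rng: np.random.Generator
) -> StationaryProfile:
    src = config.profile_source
    if src == "uniform":
        return StationaryProfile(np.full(20, 0.05), name="uniform")
    if src == "jtt":
        return jtt_frequencies()
    if src == "dirichlet":
        alpha = jtt_frequencies().pi * config.dirichlet_concentration
        pi = rng.dirichlet(alpha)
        pi = np.maximum(pi, 1e-6)
        return StationaryProfile(pi / pi.sum(), name="dirichlet-draw")
    # otherwise: a file of 20 frequencies
    vals = np.array([float(x) for x in Path(src).read_text().split()])
    return StationaryProfile(vals / vals.sum(), name=Path(src).stem)


def _shift_profile(config: SimulationConfig) -> StationaryProfile:
    from convscan.profile_shift import default_catalogue

    name = config.shift_profile or "basic"
    if Path(name).exists():
        vals = np.array([float(x) for x in Path(name).read_text().split()])
        return StationaryProfile(vals / vals.sum(), name=Path(name).stem)
    return default_catalogue()[name]


def _scaled_tree(tree: PhyloTree, scale: float) -> PhyloTree:
    if scale == 1.0:
        return tree
    scaled = tree.copy()
    for node in scaled.postorder():
        if node.parent_node is not None:
            node.edge.length = node.edge.length * scale
    return scaled


def simulate_gene_set(
    config: SimulationConfig,
    out_dir: str | Path,
    focal_clades: Sequence[FocalClade] | None = None,
    force: bool = False,
) -> Path:
    """Write ``n_genes`` FASTA alignments plus a truth TSV.

    Per-gene seeds are derived deterministically from the master seed
    (``seed + gene index``) so sets are reproducible gene by gene.  The truth
    table lists one row per injected site (gene_id, site, mechanism,
    target_residue); genes without rows are null.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty")
    out.mkdir(parents=True, exist_ok=True)

    tree = read_tree(config.tree) if config.tree else rodent_tree()
    tree = _scaled_tree(tree, config.branch_scale)
    clades = list(focal_clades) if focal_clades is not None else rodent_focal_clades()
    S = jtt_exchangeabilities()
    master = np.random.default_rng(config.seed)

    shift_model = None
    if config.n_convergent_sites > 0 and config.mechanism == PROFILE_SHIFT:
        shift_model = build_rate_model(S, _shift_profile(config))

    rows = []
    for g in range(config.n_genes):
        rng = np.random.default_rng(config.seed + g)
        gene_id = f"gene_{g:04d}"
        profile = _gene_profile(config, rng)
        model = build_rate_model(S, profile)
        gene = simulate_gene(tree, model, config.n_sites, rng, gene_id=gene_id)
        if config.n_convergent_sites > 0:
            gene = inject_convergence(
                gene,
                clades,
                config.mechanism,
                config.n_convergent_sites,
                rng,
                model,
                shift_model=shift_model,
            )
        write_alignment(gene.alignment, out / f"{gene_id}.fa")
        for s in gene.convergent_sites:
            rows.append(
                {
                    "gene_id": gene_id,
                    "site": s,
                    "mechanism": gene.mechanism,
                    "target_residue": decode_state(gene.site_targets[s])
                    if s in gene.site_targets
                    else "-",
                }
            )
    import pandas as pd

    pd.DataFrame(
        rows, columns=["gene_id", "site", "mechanism", "target_residue"]
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
    return out
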