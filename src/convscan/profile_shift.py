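"""Profile-shift corroboration of convergence calls (PCOC-style).

For each alignment column, two branch-heterogeneous models are compared:

* **nonconvergent** — one amino-acid preference profile governs every branch;
* **convergent** — the focal (convergent) branches and every branch of their
  subtrees evolve under a second, distinct profile.

Each candidate profile comes from a small catalogue; the likelihood of each
model is maximised over catalogue entries (single profiles for the
nonconvergent model, ordered background/shift pairs for the convergent model)
and converted into a posterior probability with equal prior odds:

    PP = L1 / (L1 + L0)        (computed in log space)

A gene is flagged when at least one site exceeds the PP threshold (0.95 by
default).  This is a deliberately compact variant of the published PCOC
framework: the one-change component and the C60 profile catalogue are
replaced by a max-over-pairs Bayes factor over a 10-profile catalogue.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from convscan.ancestry import _IndexedTree, _site_to_alignment
from convscan.alphabet import MISSING
from convscan.phylo_io import Alignment, FocalClade, FocalConfig, PhyloTree, resolve_focal
from convscan.subst_model import (
    ExchangeabilityMatrix,
    RateModel,
    StationaryProfile,
    build_rate_model,
    jtt_exchangeabilities,
)

_TINY = np.finfo(float).tiny

DEFAULT_PP_THRESHOLD = 0.95


@dataclasses.dataclass(frozen=True)
class ProfileCatalogue:
    """A named set of candidate amino-acid preference profiles."""

    profiles: tuple[StationaryProfile, ...]

    def __post_init__(self) -> None:
        if len(self.profiles) < 2:
            raise ValueError("catalogue needs at least two profiles")
        names = [p.name for p in self.profiles]
        if len(names) != len(set(names)):
            raise ValueError("catalogue profile names must be unique")

    def __len__(self) -> int:
        return len(self.profiles)

    def __getitem__(self, key: int | str) -> StationaryProfile:
        if isinstance(key, str):
            for p in self.profiles:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.profiles[key]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.profiles)

    @classmethod
    def from_file(cls, path: str | Path) -> "ProfileCatalogue":
        """Read a plain-text catalogue: one profile per line, a name token
        followed by 20 frequencies (alphabetical residue order)."""
        profiles = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            name, vals = parts[0], np.array([float(x) for x in parts[1:]])
            profiles.append(StationaryProfile(vals / vals.sum(), name=name))
        return cls(tuple(profiles))


_DEFAULT: ProfileCatalogue | None = None


def default_catalogue() -> ProfileCatalogue:
    """The shipped 10-profile catalogue (physicochemical classes + baselines)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.as_file(
            resources.files("convscan").joinpath("data/profiles10.txt")
        ) as p:
            _DEFAULT = ProfileCatalogue.from_file(p)
    return _DEFAULT


@dataclasses.dataclass
class ProfileShiftResult:
    """Per-site profile-shift scores for one gene."""

    gene_id: str
    log_l0: np.ndarray  # best nonconvergent log-likelihood per site
    log_l1: np.ndarray  # best convergent log-likelihood per site
    pp: np.ndarray  # posterior probability of the convergent model
    threshold: float
    sites: np.ndarray  # indices of sites with pp > threshold
    flag: bool
    best_background: np.ndarray | None = None  # catalogue index per site
    best_shift: np.ndarray | None = None


# -- branch-heterogeneous pruning -----------------------------------------


def _hetero_site_loglik(
    index: _IndexedTree,
    tip_states: np.ndarray,
    branch_models: Sequence[RateModel],
    root_pi: np.ndarray,
) -> np.ndarray:
    """Pruning log-likelihood with a transition matrix per branch.

    ``branch_models[i]`` governs the branch above postorder node ``i``.
    """
    n = root_pi.size
    n_sites = tip_states.shape[1]
    lookup = np.vstack([np.eye(n), np.ones((1, n))])
    msg: list[np.ndarray | None] = [None] * index.n_nodes
    log_scale = np.zeros(n_sites)
    up_root = None
    for i in range(index.n_nodes):
        if index.is_tip[i]:
            vec = lookup[np.minimum(tip_states[i].astype(int), n)]
        else:
            vec = np.ones((n_sites, n))
            for c in index.children[i]:
                vec = vec * msg[c]
            scale = vec.max(axis=1)
            scale = np.where(scale > 0, scale, 1.0)
            vec = vec / scale[:, None]
            log_scale += np.log(scale)
        if index.parent[i] >= 0:
            P = branch_models[i].transition_matrix(float(index.length[i]))
            msg[i] = vec @ P.T
        else:
            up_root = vec
    like = up_root @ root_pi
    return np.log(np.maximum(like, _TINY)) + log_scale


def site_likelihood_with_assignment(
    tree: PhyloTree,
    site: Mapping[str, object],
    assignment: Mapping[str, StationaryProfile],
    root_profile: StationaryProfile,
    S: ExchangeabilityMatrix | None = None,
) -> float:
    """Log-likelihood of one column with an explicit branch -> profile map.

    ``assignment`` maps the label of each branch's child node to the profile
    governing that branch; the root prior is ``root_profile``.  Every non-root
    branch must be assigned.
    """
    S = S or jtt_exchangeabilities()
    full = {t: site.get(t, MISSING) for t in tree.taxa}
    aln = _site_to_alignment(tree, full)
    index = _IndexedTree(tree)
    from convscan.ancestry import _tip_state_matrix

    tip_states = _tip_state_matrix(index, aln)
    cache: dict[int, RateModel] = {}
    branch_models: list[RateModel | None] = [None] * index.n_nodes
    for i in range(index.n_nodes):
        if index.parent[i] < 0:
            continue
        label = index.labels[i]
        if label not in assignment:
            raise KeyError(f"branch above {label!r} has no assigned profile")
        prof = assignment[label]
        if id(prof) not in cache:
            cache[id(prof)] = build_rate_model(S, prof)
        branch_models[i] = cache[id(prof)]
    ll = _hetero_site_loglik(index, tip_states, branch_models, root_profile.pi)
    return float(ll[0])


def _focal_subtree_mask(index: _IndexedTree, focal_nodes) -> np.ndarray:
    """Boolean per postorder node: branch above it belongs to a focal subtree
    (the focal MRCA branch and every branch beneath it)."""
    mask = np.zeros(index.n_nodes, dtype=bool)
    focal_ids = {id(n) for n in focal_nodes}
    # postorder: propagate membership top-down via a preorder sweep
    for i in range(index.n_nodes - 1, -1, -1):
        node = index.nodes[i]
        if id(node) in focal_ids:
            mask[i] = True
        elif index.parent[i] >= 0 and mask[index.parent[i]]:
            mask[i] = True
    return mask


def profile_shift_scan(
    aln: Alignment,
    tree: PhyloTree,
    focal_clades: Sequence[FocalClade] | FocalConfig,
    catalogue: ProfileCatalogue | None = None,
    S: ExchangeabilityMatrix | None = None,
    pp_threshold: float = DEFAULT_PP_THRESHOLD,
    min_sites: int = 1,
) -> ProfileShiftResult:
    """Score every site of a gene for a convergent profile shift.

    The nonconvergent likelihood is maximised over single catalogue profiles;
    the convergent likelihood over ordered (background, shift) pairs of
    distinct profiles, the shift profile applying to the focal MRCA branches
    and all branches of their subtrees.
    """
    catalogue = catalogue or default_catalogue()
    S = S or jtt_exchangeabilities()
    if isinstance(focal_clades, FocalConfig):
        focal = focal_clades
        if focal.tree is not tree:
            focal = resolve_focal(tree, focal.clades)
    else:
        focal = resolve_focal(tree, focal_clades)

    index = _IndexedTree(tree)
    from convscan.ancestry import _tip_state_matrix

    tip_states = _tip_state_matrix(index, aln)
    mask = _focal_subtree_mask(index, focal.nodes)

    models = [build_rate_model(S, p) for p in catalogue.profiles]
    n_prof = len(models)
    n_sites = aln.n_sites

    ll_single = np.empty((n_prof, n_sites))
    for c, m in enumerate(models):
        branch_models = [m] * index.n_nodes
        ll_single[c] = _hetero_site_loglik(index, tip_states, branch_models, m.pi.pi)

    log_l0 = ll_single.max(axis=0)
    best_bg0 = ll_single.argmax(axis=0)

    log_l1 = np.full(n_sites, -np.inf)
    best_bg = np.zeros(n_sites, dtype=int)
    best_sh = np.zeros(n_sites, dtype=int)
    for c1 in range(n_prof):
        for c2 in range(n_prof):
            if c1 == c2:
                continue
            branch_models = [
                models[c2] if mask[i] else models[c1]
                for i in range(index.n_nodes)
            ]
            ll = _hetero_site_loglik(
                index, tip_states, branch_models, models[c1].pi.pi
            )
            better = ll > log_l1
            log_l1[better] = ll[better]
            best_bg[better] = c1
            best_sh[better] = c2

    # equal prior odds; PP in log space
    pp = 1.0 / (1.0 + np.exp(np.clip(log_l0 - log_l1, -700, 700)))
    sites = np.nonzero(pp > pp_threshold)[0]
    return ProfileShiftResult(
        gene_id=aln.gene_id,
        log_l0=log_l0,
        log_l1=log_l1,
        pp=pp,
        threshold=pp_threshold,
        sites=sites,
        flag=bool(sites.size >= min_sites),
        best_background=best_bg,
        best_shift=best_sh,
    )


def site_pp(
    tree: PhyloTree,
    site: Mapping[str, object],
    focal: FocalConfig | Sequence[FocalClade],
    catalogue: ProfileCatalogue | None = None,
    S: ExchangeabilityMatrix | None = None,
    pp_threshold: float = DEFAULT_PP_THRESHOLD,
) -> ProfileShiftResult:
    """Single-column convenience wrapper around :func:`profile_shift_scan`."""
    full = {t: site.get(t, MISSING) for t in tree.taxa}
    aln = _site_to_alignment(tree, full)
    return profile_shift_scan(
        aln, tree, focal, catalogue=catalogue, S=S, pp_threshold=pp_threshold
    )


def gene_profile_flag(
    result: ProfileShiftResult | np.ndarray,
    threshold: float = DEFAULT_PP_THRESHOLD,
    min_sites: int = 1,
) -> tuple[bool, np.ndarray]:
    """Gene-level flag: at least ``min_sites`` sites with PP above threshold."""
    pp = result.pp if isinstance(result, ProfileShiftResult) else np.asarray(result)
    sites = np.nonzero(pp > threshold)[0]
    return bool(sites.size >= min_sites), sites
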