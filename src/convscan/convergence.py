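"""Convergent-site detection and the Poisson excess test.

A site is called convergent when the residue at every focal node (the MRCA of
each designated lineage, or the tip itself for a singleton lineage) is the
same residue ``a`` while each focal node's immediate ancestor carries a
residue different from ``a``.  The call is *parallel* when all the ancestral
residues agree, *divergent-origin* otherwise; both kinds count toward the
observed total ``k``.

The neutral expectation for a gene is

    lambda = sum_sites sum_a prod_r [a != x_r] * P_{x_r -> a}(t_r)

with ``x_r`` the reconstructed (MAP) ancestor on focal branch ``r`` and
``t_r`` that branch's length, under the gene's JTT+F model.  ``k`` is compared
to ``lambda`` with a Poisson upper-tail test, and q-values across genes come
from Benjamini-Hochberg; a gene is significant when both p and q clear their
thresholds.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from convscan.alphabet import MISSING, decode_state
from convscan.ancestry import AncestralReconstruction, reconstruct
from convscan.phylo_io import (
    Alignment,
    FocalClade,
    FocalConfig,
    PhyloTree,
    read_alignment,
    resolve_focal,
)
from convscan.subst_model import (
    ExchangeabilityMatrix,
    RateModel,
    build_rate_model,
    estimate_gene_frequencies,
    jtt_exchangeabilities,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 30
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_Q_THRESHOLD = 0.05


@dataclasses.dataclass(frozen=True)
class SiteCall:
    """One convergent site: target residue and the per-branch ancestors."""

    site: int
    target: str
    ancestors: tuple[str, ...]
    parallel: bool  # all ancestral residues identical

    @property
    def subtype(self) -> str:
        return "parallel" if self.parallel else "divergent-origin"


@dataclasses.dataclass
class GeneConvergenceResult:
    gene_id: str
    n_sites_used: int
    k_observed: int
    k_parallel: int
    k_divergent_origin: int
    lambda_expected: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    pcoc_sites: int = 0
    pcoc_flag: bool = False
    site_calls: list[SiteCall] = dataclasses.field(default_factory=list)


@dataclasses.dataclass(frozen=True)
class SkippedGene:
    gene_id: str
    reason: str


# -- focal-state extraction ------------------------------------------------


def _focal_state_arrays(
    recon: AncestralReconstruction, focal: FocalConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site focal descendant states, ancestor states, and inclusion mask.

    Descendant state is the observed tip residue for a singleton clade and
    the MAP state of the clade MRCA otherwise; the ancestor is the MAP state
    of the focal node's parent.  A site is excluded when any focal descendant
    state is unresolvable: a gap at a focal tip, or a focal clade whose tips
    are all missing at that site.
    """
    n_sites = recon.n_sites
    R = focal.n_clades
    desc = np.empty((R, n_sites), dtype=np.int64)
    anc = np.empty((R, n_sites), dtype=np.int64)
    included = np.ones(n_sites, dtype=bool)
    for r, node in enumerate(focal.nodes):
        i = recon.node_index(node)
        p = recon.node_index(node.parent_node)
        anc[r] = recon.map_states[p]
        if node.is_leaf():
            tip = recon.tip_states[i].astype(np.int64)
            included &= tip != MISSING
            desc[r] = np.where(tip != MISSING, tip, 0)
        else:
            included &= recon.observed_below[i]
            desc[r] = recon.map_states[i]
    return desc, anc, included


def detect_observed_sites(
    recon: AncestralReconstruction, focal: FocalConfig
) -> tuple[list[SiteCall], int]:
    """Convergent-site calls and the number of sites entering the test."""
    desc, anc, included = _focal_state_arrays(recon, focal)
    same_target = np.all(desc == desc[0], axis=0)
    differs_from_anc = np.all(desc != anc, axis=0)
    hits = included & same_target & differs_from_anc
    calls = []
    for s in np.nonzero(hits)[0]:
        ancestors = tuple(decode_state(int(a)) for a in anc[:, s])
        calls.append(
            SiteCall(
                site=int(s),
                target=decode_state(int(desc[0, s])),
                ancestors=ancestors,
                parallel=len(set(ancestors)) == 1,
            )
        )
    return calls, int(included.sum())


# -- neutral expectation ---------------------------------------------------


def expected_site_lambda(
    x: Sequence[int], t: Sequence[float], model: RateModel
) -> float:
    """Probability that every focal branch substitutes to one shared residue.

    ``x[r]`` is the ancestral state and ``t[r]`` the length of focal branch
    ``r``; the site-level expectation sums, over target residues ``a`` distinct
    from every ``x[r]``, the product of per-branch transition probabilities.
    """
    if len(x) != len(t) or len(x) < 2:
        raise ValueError("need ancestor state and length for >= 2 focal branches")
    prod = np.ones(model.n_states)
    for xr, tr in zip(x, t):
        row = model.transition_matrix(float(tr))[int(xr)].copy()
        row[int(xr)] = 0.0
        prod *= row
    return float(prod.sum())


def _lambda_per_site(
    desc_anc: np.ndarray,
    included: np.ndarray,
    lengths: np.ndarray,
    model: RateModel,
    posteriors: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorised per-site lambda; optionally integrating ancestor posteriors."""
    R, n_sites = desc_anc.shape
    n = model.n_states
    prod = np.ones((n_sites, n))
    for r in range(R):
        P = model.transition_matrix(float(lengths[r]))
        if posteriors is None:
            rows = P[desc_anc[r]].copy()  # (n_sites, n)
            rows[np.arange(n_sites), desc_anc[r]] = 0.0
        else:
            # E_x[ P[x, a] for a != x ] under the ancestor posterior
            post = posteriors[r]  # (n_sites, n)
            rows = post @ P - post * np.diag(P)[None, :]
        prod *= rows
    lam = prod.sum(axis=1)
    lam[~included] = 0.0
    return lam


def gene_lambda(
    recon: AncestralReconstruction,
    focal: FocalConfig,
    model: RateModel,
    posterior_integrated: bool = False,
) -> float:
    """Gene-level expectation: per-site lambdas summed over included sites.

    Plug-in MAP ancestors by default; with ``posterior_integrated`` the
    per-branch ancestor is integrated over its marginal posterior.
    """
    desc, anc, included = _focal_state_arrays(recon, focal)
    lengths = focal.branch_lengths()
    post = None
    if posterior_integrated:
        post = np.stack(
            [
                recon.posteriors[recon.node_index(n.parent_node)]
                for n in focal.nodes
            ]
        )
    lam = _lambda_per_site(anc, included, lengths, model, posteriors=post)
    return float(lam.sum())


# -- test machinery --------------------------------------------------------


def poisson_upper_tail(k: int, lam: float) -> float:
    """p = P(X >= k) for X ~ Poisson(lam); k = 0 gives 1 by convention."""
    if k < 0 or lam < 0:
        raise ValueError("k and lambda must be non-negative")
    if k == 0:
        return 1.0
    if lam == 0.0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(q_sorted, 0.0, 1.0, out=q_sorted)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# -- gene-level scan -------------------------------------------------------


@dataclasses.dataclass
class ScanOptions:
    """Tunables for the per-gene scan.

    ``missing_taxon_policy`` controls genes that do not cover the full tree:
    ``"prune"`` drops absent background taxa from a working copy of the tree
    and proceeds as long as every focal tip is present; ``"skip"`` skips any
    gene not covering all tree taxa.
    """

    min_len: int = DEFAULT_MIN_LEN
    pseudocount: float = 1.0
    missing_taxon_policy: str = "prune"  # or "skip"
    posterior_integrated_lambda: bool = False
    rescale_branch_lengths: bool = False
    exchangeabilities: ExchangeabilityMatrix | None = None

    def get_exchangeabilities(self) -> ExchangeabilityMatrix:
        return self.exchangeabilities or jtt_exchangeabilities()


def _fit_branch_scale(
    tree: PhyloTree, aln: Alignment, model: RateModel
) -> float:
    """One global ML branch-length multiplier for the gene (bounded 1-D search)."""

    def neg_ll(log_scale: float) -> float:
        scale = float(np.exp(log_scale))
        scaled = tree.copy()
        for node in scaled.postorder():
            if node.parent_node is not None:
                node.edge.length = node.edge.length * scale
        r = reconstruct(scaled, aln, model)
        return -float(r.site_log_likelihoods.sum())

    res = optimize.minimize_scalar(
        neg_ll, bounds=(np.log(1e-3), np.log(10.0)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def scan_gene(
    aln: Alignment,
    tree: PhyloTree,
    focal_clades: Sequence[FocalClade],
    options: ScanOptions | None = None,
) -> GeneConvergenceResult | SkippedGene:
    """Scan one gene: frequencies -> rate model -> reconstruction -> k, lambda, p.

    Genes shorter than ``min_len`` sites are skipped (reason ``"min_len"``);
    genes missing focal taxa are skipped (reason ``"missing_focal_taxon"``),
    and genes missing background taxa are pruned or skipped per policy.
    The q-value is filled in later at the gene-set level.
    """
    opts = options or ScanOptions()
    if aln.n_sites < opts.min_len:
        logger.info("%s skipped: min_len (%d < %d)", aln.gene_id, aln.n_sites, opts.min_len)
        return SkippedGene(aln.gene_id, "min_len")

    tree_taxa = set(tree.taxa)
    aln_taxa = set(aln.taxa)
    focal_tips = {t for c in focal_clades for t in c.tips}
    if focal_tips - aln_taxa:
        return SkippedGene(aln.gene_id, "missing_focal_taxon")
    absent = tree_taxa - aln_taxa
    if absent:
        if opts.missing_taxon_policy == "skip":
            return SkippedGene(aln.gene_id, "missing_taxon")
        work_tree = tree.pruned_to(sorted(tree_taxa & aln_taxa))
    else:
        work_tree = tree

    focal = resolve_focal(work_tree, focal_clades)
    pi = estimate_gene_frequencies(aln, pseudocount=opts.pseudocount)
    model = build_rate_model(opts.get_exchangeabilities(), pi)

    if opts.rescale_branch_lengths:
        scale = _fit_branch_scale(work_tree, aln, model)
        work_tree = work_tree.copy()
        for node in work_tree.postorder():
            if node.parent_node is not None:
                node.edge.length = node.edge.length * scale
        focal = resolve_focal(work_tree, focal_clades)

    recon = reconstruct(work_tree, aln, model)
    calls, n_used = detect_observed_sites(recon, focal)
    lam = gene_lambda(
        recon, focal, model, posterior_integrated=opts.posterior_integrated_lambda
    )
    k = len(calls)
    k_par = sum(c.parallel for c in calls)
    return GeneConvergenceResult(
        gene_id=aln.gene_id,
        n_sites_used=n_used,
        k_observed=k,
        k_parallel=k_par,
        k_divergent_origin=k - k_par,
        lambda_expected=lam,
        p_value=poisson_upper_tail(k, lam),
        site_calls=calls,
    )


def _pairwise_scan(
    aln: Alignment,
    tree: PhyloTree,
    focal_clades: Sequence[FocalClade],
    options: ScanOptions,
) -> GeneConvergenceResult | SkippedGene:
    """Any-pair mode: test each clade pair, Bonferroni-combine by minimum p."""
    from itertools import combinations

    pairs = list(combinations(range(len(focal_clades)), 2))
    best: GeneConvergenceResult | None = None
    skipped: SkippedGene | None = None
    for i, j in pairs:
        res = scan_gene(aln, tree, [focal_clades[i], focal_clades[j]], options)
        if isinstance(res, SkippedGene):
            skipped = res
            continue
        if best is None or res.p_value < best.p_value:
            best = res
    if best is None:
        return skipped or SkippedGene(aln.gene_id, "no_testable_pair")
    best.p_value = min(1.0, best.p_value * len(pairs))
    return best


def scan_gene_set(
    alignments: Iterable[Alignment] | str | Path,
    tree: PhyloTree,
    focal_clades: Sequence[FocalClade],
    options: ScanOptions | None = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    mode: str = "allmatch",
) -> tuple[list[GeneConvergenceResult], list[SkippedGene]]:
    """Scan a set of genes and fill in BH q-values and significance flags.

    ``alignments`` is an iterable of :class:`Alignment` or a directory of
    FASTA files (``*.fa``/``*.fasta``/``*.faa``).  Significance requires both
    ``p < p_threshold`` and ``q < q_threshold``.  ``mode`` is ``"allmatch"``
    (one test requiring all focal lineages to converge) or ``"pairwise"``
    (minimum p over clade pairs, Bonferroni-corrected).
    """
    opts = options or ScanOptions()
    if isinstance(alignments, (str, Path)):
        paths = sorted(
            p
            for pat in ("*.fa", "*.fasta", "*.faa")
            for p in Path(alignments).glob(pat)
        )
        alignments = (read_alignment(p) for p in paths)

    results: list[GeneConvergenceResult] = []
    skips: list[SkippedGene] = []
    for aln in alignments:
        if mode == "pairwise":
            res = _pairwise_scan(aln, tree, focal_clades, opts)
        elif mode == "allmatch":
            res = scan_gene(aln, tree, focal_clades, opts)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if isinstance(res, SkippedGene):
            skips.append(res)
        else:
            results.append(res)
    if not results:
        raise ValueError("no scannable genes in the input set")
    results.sort(key=lambda r: r.gene_id)
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(r.p_value < p_threshold and r.q_value < q_threshold)
    return results, skips


def results_dataframe(results: Sequence[GeneConvergenceResult]) -> pd.DataFrame:
    """Flatten results into the standard output table."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_sites_used": r.n_sites_used,
                "k_observed": r.k_observed,
                "k_parallel": r.k_parallel,
                "k_divergent_origin": r.k_divergent_origin,
                "lambda_expected": r.lambda_expected,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
                "pcoc_sites": r.pcoc_sites,
                "pcoc_flag": r.pcoc_flag,
            }
            for r in sorted(results, key=lambda r: r.gene_id)
        ]
    )
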