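# Methods

## The convergence scan

`convscan` tests, gene by gene, whether designated focal lineages of a rooted
species tree show more convergent amino-acid substitutions than expected
under neutral sequence evolution.

**Substitution model.** Sequence evolution is a reversible continuous-time
Markov chain on the 20 amino acids. For each gene, `Q[x][y] = S[x][y]·π[y]`
(x ≠ y) with `S` the published JTT exchangeability matrix (shipped verbatim
as a plain-text asset in the PAML dat layout, `src/convscan/data/jtt.dat`)
and `π` the gene's own residue frequencies — empirical counts over all
non-missing residues with a Laplace pseudocount (default 1.0), the standard
"+F" estimator. `Q` is normalised so that one unit of branch length equals
one expected substitution per site at stationarity. Transition matrices
`P(t) = exp(Qt)` come from the symmetric eigendecomposition of
`D^{1/2} Q D^{-1/2}` (`D = diag(π)`), which is exact, stable, and O(1) per
additional branch length after one decomposition; matrices are cached per
(model, t). Among-site rate variation (gamma) is not modelled.

**Ancestral states.** Site likelihoods use Felsenstein pruning with `π` as
root prior; gaps, `X`, `.` and `?` are one missing class contributing
all-ones partial vectors. Ancestral reconstruction is *marginal*
(empirical-Bayes): one post-order and one pre-order pass give each internal
node's posterior over residues; the reported state is the posterior mode,
with exact ties broken alphabetically by one-letter code. Per-node per-site
scaling guards against underflow without affecting reported log-likelihoods.
An optional confidence floor can flag low-posterior MAP states but is off by
default. Columns with no observed residue carry likelihood 1 (log 0) and are
flagged with a warning.

**Site calls and the neutral expectation.** With focal lineages resolved to
the branches above their MRCA nodes (the tip branch for a singleton
lineage), a site is called convergent when every focal node's residue is the
same `a` and differs from that node's immediate ancestor's residue; both
"parallel" (identical ancestors) and "divergent-origin" calls count, and the
two subtypes are reported separately. Sites where any focal descendant state
is unresolvable (a gap at a focal tip, or a focal clade with no observed
residue at that site) are excluded from both the count and `n_sites_used`.
The gene-level expectation plugs the MAP ancestor states into

λ = Σ_sites Σ_a Π_r 1[a ≠ x_r] · P_{x_r → a}(t_r),

the probability that all focal branches independently substitute to one
shared residue different from each branch's own ancestor. A
posterior-integrated variant (averaging `x_r` over its marginal posterior)
is available behind a flag; the plug-in default mirrors the
reconstruct-then-count workflow the scan emulates. Focal branch lengths are
taken from the input tree; an optional per-gene global rescaling (1-D ML fit
of a single multiplier) is available but off by default.

**Test and multiplicity.** `p = P(X ≥ k)` for `X ~ Poisson(λ)` (`k = 0` ⇒
`p = 1`); Benjamini–Hochberg q-values are computed across all scanned genes,
and significance requires both `p` and `q` below their thresholds (defaults
0.05/0.05). The default test requires convergence across *all* focal
lineages simultaneously; a pairwise mode (minimum p over lineage pairs,
Bonferroni-corrected) is provided and reduces exactly to the default when
only two lineages are configured. Genes shorter than 30 aligned residues are
skipped (reason `min_len`), applied to the raw alignment length. Genes
missing focal taxa are skipped; genes missing background taxa are either
pruned (working tree with merged branch lengths, the default) or skipped,
per policy flag.

## Profile-shift corroboration

The second detector asks whether a site's amino-acid *preference* (profile)
changed on the focal branches, in the spirit of PCOC. Per site, the
nonconvergent likelihood L0 is maximised over single catalogue profiles
applied tree-wide; the convergent likelihood L1 over ordered pairs of
distinct profiles, the second applying to each focal MRCA branch and every
branch of its subtree. With equal prior odds, `PP = L1/(L1+L0)` in log-space
arithmetic. A gene is flagged when at least one site exceeds `PP > 0.95`
(both the threshold and the minimum site count are configurable, since
gene-level call rules vary between studies).

The shipped catalogue holds ten profiles: the JTT average frequencies, the
uniform profile, and eight sharply concentrated physicochemical classes
(hydrophobic AILMV, aromatic FWY, basic HKR, acidic DE, polar NQST, small
AGS, and single-residue proline and cysteine classes) with 99% of the mass
in class. The sharp concentration mirrors the C-series profiles used by
profile-change methods and matters quantitatively: because residues shared
within a clade are explained once through common ancestry, the site Bayes
factor is governed mainly by how expensive the *background* data are under
the shifted profile, which scales with the profile's concentration. Users
can load their own catalogue (plain text, name + 20 frequencies per line).

This is a deliberate simplification of the published PCOC framework: the
one-change component and the C60 catalogue are replaced by a
max-over-profile-pairs Bayes factor; bit-exact parity with PCOC scores is a
non-goal. One consequence of normalising each profile's rate matrix at its
own stationarity is that a no-contrast (constant) site can receive PP
slightly above 1/2 — profile pairs can differ marginally in retention rates
— though far below the 0.95 call threshold; PP = 0.5 exactly holds when the
focal branches are *assigned* the same profile as the background.

## The simulator

`simulate_gene` evolves i.i.d. sites along the tree: the root residue is
drawn from `π` and each branch substitutes by sampling its transition-matrix
row; every internal state is recorded, so simulated genes carry exact
ancestral truth. Defaults emulate trimmed single-copy ortholog sets on the
13-taxon rodent tree: 300-residue genes, per-gene base profiles drawn from a
Dirichlet centred on the JTT frequencies (concentration 100, giving
realistic gene-to-gene compositional variation), branch lengths from the
shipped tree (divergence-time gaps × 0.0015 substitutions/site/My,
root-to-tip ≈ 0.105). Per-gene seeds derive deterministically from the
master seed (`seed + gene index`), so gene sets are reproducible and
parallelisable.

Convergence is injected by two mechanisms. *Forced substitution* writes a
target residue (drawn from `π` excluding every focal parent's state) onto
each focal MRCA node and all of its descendants — convergence true by
construction, used to test counting machinery independent of reconstruction
error. *Profile shift* re-evolves the site with the focal subtrees governed
by a second profile; the state at each focal MRCA is drawn anew from the
shifted profile (a completed shift, the one-change convention) because with
realistic branch lengths of a few hundredths of a substitution per site a
purely continuous profile switch leaves no trace in the data at most sites.

What the simulator does *not* reproduce: indels and alignment error,
among-site rate variation and selection heterogeneity, codon-level effects,
non-stationary composition, and tree-estimation error. Calibration results
on synthetic data therefore bound the method's behaviour under its own
model assumptions, not under every property of real ortholog sets.

## Numerical choices and calibration scales

Tolerances: profiles sum to 1 within 1e-12; transition rows are stochastic
within 1e-12; pruning and posteriors match exhaustive enumeration within
1e-8 on small trees. Exact posterior ties resolve alphabetically. Transition
matrices at `t = 0` return the exact identity.

The calibration experiments (test suite and `scripts/acceptance.py`) use 200
genes of 300 sites on the 13-taxon tree for the null, power (2 and 5 forced
sites) and FDR (160 null + 40 signal) studies, 200 shifted plus 2000 null
sites for the profile-shift detector, with a cysteine-class shift as the
strong-shift condition and interpolations toward it as graded strengths.
These sizes give standard errors of a few percent on each reported rate.

## Known limitations

* Plug-in MAP ancestors slightly bias both `k` and `λ`; a forced convergent
  site can be absorbed when the focal parent's reconstruction is pulled to
  the target residue (the power studies show ~1 of 5 injected sites lost on
  average at study-like branch lengths).
* With three focal lineages `λ` is tiny, so the Poisson test is extremely
  conservative on null genes and essentially any recovered convergent site
  is significant; p-values are not uniform under the null (they are
  stochastically larger), which the calibration tests check explicitly.
* The profile-shift detector's specificity is bounded by chance
  substitutions on focal branches into a sharp profile class (~3% of null
  sites at PP > 0.95 at study-like branch lengths).
* Branch lengths are taken as given; the optional per-gene rescaling fits a
  single global factor, not per-branch lengths.
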