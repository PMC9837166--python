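"""The amino-acid substitution process: JTT exchangeabilities + gene frequencies.

The neutral model is a general time-reversible continuous-time Markov chain
``Q[x][y] = S[x][y] * pi[y]`` built from the published JTT exchangeability
matrix and equilibrium frequencies estimated from the gene under test (the
"+F" convention).  Q is normalised to one expected substitution per unit
branch length at stationarity; transition matrices P(t) = exp(Qt) are obtained
from a symmetric eigendecomposition of the reversibility-symmetrised generator
and cached per branch length.

The machinery is written for a generic alphabet size so small toy alphabets
can be used to validate the numerics against closed forms.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np

from convscan.alphabet import MISSING, N_STATES

_SUM_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class ExchangeabilityMatrix:
    """Symmetric non-negative exchangeabilities with zero diagonal."""

    S: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("exchangeability matrix must be square")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if np.any(np.diag(S) != 0):
            raise ValueError("exchangeability diagonal must be zero")
        off = S[~np.eye(S.shape[0], dtype=bool)]
        if np.any(off <= 0):
            raise ValueError("off-diagonal exchangeabilities must be positive")
        object.__setattr__(self, "S", S)

    @property
    def n_states(self) -> int:
        return self.S.shape[0]


@dataclasses.dataclass(frozen=True)
class StationaryProfile:
    """An equilibrium amino-acid frequency vector (all entries > 0, sum 1)."""

    pi: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.ndim != 1:
            raise ValueError("profile must be a vector")
        if np.any(pi <= 0):
            raise ValueError("profile entries must be strictly positive")
        if abs(pi.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"profile sums to {pi.sum()!r}, not 1")
        object.__setattr__(self, "pi", pi)

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, pseudocount: float = 1.0, name: str = ""
    ) -> "StationaryProfile":
        counts = np.asarray(counts, dtype=float)
        if pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        total = counts.sum() + counts.size * pseudocount
        if total <= 0 or np.any(counts + pseudocount <= 0):
            raise ValueError(
                "zero frequencies: no observed residues and pseudocount is 0"
            )
        return cls((counts + pseudocount) / total, name=name)


# -- PAML-style data asset -------------------------------------------------

# The shipped matrix uses the PAML residue order; internal state order is
# alphabetical by one-letter code.
_PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"
from convscan.alphabet import AMINO_ACIDS as _ALPHA_ORDER

_PAML_TO_ALPHA = np.array([_ALPHA_ORDER.index(a) for a in _PAML_ORDER])

JTT_ASSET_VERSION = "jtt-1992-paml"


def load_exchangeabilities(path: str | Path | None = None) -> tuple[
    ExchangeabilityMatrix, StationaryProfile
]:
    """Load exchangeabilities (and the file's reference frequencies).

    With no path, the shipped JTT matrix is used.  The file layout is the
    PAML dat convention: 19 lower-triangle rows then 20 frequencies, residues
    ordered ``ARNDCQEGHILKMFPSTWYV``.
    """
    if path is None:
        text = (
            resources.files("convscan").joinpath("data/jtt.dat").read_text()
        )
        name = "JTT"
    else:
        text = Path(path).read_text()
        name = Path(path).stem
    values = [float(tok) for tok in text.split()]
    if len(values) < 210:
        raise ValueError(f"matrix file holds {len(values)} numbers, need 210")
    tri, freqs = values[:190], np.array(values[190:210])
    S_paml = np.zeros((20, 20))
    k = 0
    for row in range(1, 20):
        for col in range(row):
            S_paml[row, col] = S_paml[col, row] = tri[k]
            k += 1
    # reindex from PAML order into alphabetical state order
    S = np.zeros((20, 20))
    pi = np.zeros(20)
    for i in range(20):
        pi[_PAML_TO_ALPHA[i]] = freqs[i]
        for j in range(20):
            S[_PAML_TO_ALPHA[i], _PAML_TO_ALPHA[j]] = S_paml[i, j]
    return (
        ExchangeabilityMatrix(S, name=name),
        StationaryProfile(pi / pi.sum(), name=f"{name}-freqs"),
    )


_JTT_CACHE: tuple[ExchangeabilityMatrix, StationaryProfile] | None = None


def jtt_exchangeabilities() -> ExchangeabilityMatrix:
    """The published JTT exchangeability matrix (alphabetical state order)."""
    global _JTT_CACHE
    if _JTT_CACHE is None:
        _JTT_CACHE = load_exchangeabilities()
    return _JTT_CACHE[0]


def jtt_frequencies() -> StationaryProfile:
    """The JTT reference equilibrium frequencies."""
    global _JTT_CACHE
    if _JTT_CACHE is None:
        _JTT_CACHE = load_exchangeabilities()
    return _JTT_CACHE[1]


# -- rate model ------------------------------------------------------------


class RateModel:
    """Normalised reversible rate matrix with cached transition matrices."""

    def __init__(self, Q: np.ndarray, pi: StationaryProfile) -> None:
        self.Q = np.asarray(Q, dtype=float)
        self.pi = pi
        self._check()
        self._decomp: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
        self._P_cache: dict[float, np.ndarray] = {}

    def _check(self) -> None:
        Q, pi = self.Q, self.pi.pi
        n = pi.size
        if Q.shape != (n, n):
            raise ValueError("Q and pi dimensions differ")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-10:
            raise ValueError("rate matrix rows must sum to zero")
        flux = pi[:, None] * Q
        if np.max(np.abs(flux - flux.T)) > 1e-8:
            raise ValueError("detailed balance violated")

    @property
    def n_states(self) -> int:
        return self.pi.n_states

    def _eigendecomposition(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # B = D^{1/2} Q D^{-1/2} is symmetric under reversibility
        if self._decomp is None:
            sqrt_pi = np.sqrt(self.pi.pi)
            B = (sqrt_pi[:, None] * self.Q) / sqrt_pi[None, :]
            B = 0.5 * (B + B.T)  # symmetrise away rounding noise
            w, U = np.linalg.eigh(B)
            self._decomp = (w, U, sqrt_pi)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows are substitution distributions from each state."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        t = float(t)
        P = self._P_cache.get(t)
        if P is None and t == 0.0:
            P = np.eye(self.n_states)
            P.setflags(write=False)
            self._P_cache[t] = P
        elif P is None:
            w, U, sqrt_pi = self._eigendecomposition()
            inner = (U * np.exp(w * t)) @ U.T
            P = inner / sqrt_pi[:, None] * sqrt_pi[None, :]
            np.clip(P, 0.0, 1.0, out=P)
            P.setflags(write=False)
            self._P_cache[t] = P
        return P


def estimate_gene_frequencies(aln, pseudocount: float = 1.0) -> StationaryProfile:
    """Empirical residue frequencies of a gene with a Laplace pseudocount.

    Counts run over every non-missing residue in the alignment;
    ``pi[a] = (count_a + pseudocount) / (total + 20 * pseudocount)``.
    """
    states = aln.states
    observed = states[states != MISSING]
    counts = np.bincount(observed.astype(np.int64), minlength=N_STATES).astype(float)
    return StationaryProfile.from_counts(
        counts, pseudocount=pseudocount, name=f"{aln.gene_id}-F"
    )


def build_rate_model(S: ExchangeabilityMatrix, pi: StationaryProfile) -> RateModel:
    """Assemble ``Q[x][y] = S[x][y] * pi[y]`` and normalise to unit rate."""
    if S.n_states != pi.n_states:
        raise ValueError("exchangeabilities and profile dimensions differ")
    Q = S.S * pi.pi[None, :]
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices_from(Q)] = -Q.sum(axis=1)
    rate = -float(np.dot(pi.pi, np.diag(Q)))
    if rate <= 0:
        raise ValueError("degenerate rate matrix")
    return RateModel(Q / rate, pi)


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """Functional alias for :meth:`RateModel.transition_matrix`."""
    return model.transition_matrix(t)
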