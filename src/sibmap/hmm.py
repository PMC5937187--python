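"""Hidden Markov machinery for full-sib linkage likelihoods.

The latent chain for one progeny is its inheritance vector: at locus j
the pair of bits (s_pat, s_mat), each 0 if the allele transmitted by
that parent came from the parent's maternal chromosome and 1 if from
its paternal chromosome.  There are four states, indexed here as
``2*s_pat + s_mat``.  Transitions factorize over the two meioses with
per-interval recombination fractions (r_pat, r_mat); emissions depend
on the locus OPGP, which translates a state into the progeny genotype.

Two observation models share this chain:

* the *genotype* model — progeny genotypes are observed without error
  (emission 1 if the state-implied genotype matches, else 0; missing
  genotypes emit 1);
* the *sequencing* model — the observation is the reference-allele read
  count a out of depth d, binomially sampled from the true genotype's
  alleles with a per-read miscall probability ε:

      P(a | AA) = C(d,a) (1-ε)^a ε^(d-a)
      P(a | AB) = C(d,a) (1/2)^d
      P(a | BB) = C(d,a) (1-ε)^(d-a) ε^a

  so heterozygotes sequenced at low depth appear homozygous with
  probability 2^(1-d) (allelic dropout), and miscalls are absorbed by ε
  rather than inflating the map.

Likelihoods are computed by the forward recursion with per-locus
renormalization (log scale factors accumulated), and posteriors for EM
by the scaled forward-backward pass.  Individuals are conditionally
independent given the OPGPs, so families multiply.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .segregation import OPGP_TABLE

__all__ = [
    "G_AA",
    "G_AB",
    "G_BB",
    "G_MISSING",
    "InheritanceState",
    "RecombinationParams",
    "ReadCountData",
    "GenotypeCallData",
    "InconsistentDataError",
    "OPGP_STATE_GENOTYPE",
    "transition_matrix",
    "genotype_emission",
    "read_count_prob",
    "sequencing_emission",
    "log_binom_coef",
    "read_count_probs",
    "sequencing_emissions",
    "genotype_emissions",
    "forward_logliks",
    "forward_loglik_individual",
    "total_loglik",
    "forward_backward",
]

# Genotype codes used throughout.
G_AA, G_AB, G_BB, G_MISSING = 0, 1, 2, -1

_GENO_CODE = {"AA": G_AA, "AB": G_AB, "BA": G_AB, "BB": G_BB}

# State bit masks: state index = 2*s_pat + s_mat.
_S_PAT = np.array([0, 0, 1, 1])
_S_MAT = np.array([0, 1, 0, 1])

# Rows (s, t) where the paternal / maternal bit differs (recombination).
FLIP_PAT = (_S_PAT[:, None] != _S_PAT[None, :])
FLIP_MAT = (_S_MAT[:, None] != _S_MAT[None, :])


def _build_state_genotypes() -> np.ndarray:
    """Genotype implied by (OPGP code, state) — array [17, 4], row 0 unused."""
    table = np.full((17, 4), -9, dtype=np.int8)
    for code, (z11, z10, z01, z00) in OPGP_TABLE.items():
        for s in range(4):
            pat_allele = z11 if _S_PAT[s] else z10
            mat_allele = z01 if _S_MAT[s] else z00
            n_b = (pat_allele == "B") + (mat_allele == "B")
            table[code, s] = (G_AA, G_AB, G_BB)[n_b]
    return table


#: ``OPGP_STATE_GENOTYPE[code, state]`` = genotype code implied by selecting
#: the state's parental chromosomes from the OPGP quadruple.
OPGP_STATE_GENOTYPE = _build_state_genotypes()


class InconsistentDataError(ValueError):
    """Observed data impossible under the error-free genotype model."""


@dataclass(frozen=True)
class InheritanceState:
    """One progeny's inheritance bits at a locus."""

    s_paternal: int
    s_maternal: int

    @property
    def index(self) -> int:
        return 2 * self.s_paternal + self.s_maternal


@dataclass
class RecombinationParams:
    """Recombination fractions per interval plus the sequencing error rate.

    ``r_paternal[j]`` / ``r_maternal[j]`` is the recombination fraction in
    that parent between locus j and j+1 (0-based; length M-1).  Intervals
    marked non-estimable are fixed at 0, which reparametrizes the next
    estimable fraction as recombination to the previous locus segregating
    in that parent.  In map estimation r is constrained to [0, 0.5]; phase
    inference relaxes the constraint to [0, 1].
    """

    r_paternal: np.ndarray
    r_maternal: np.ndarray
    epsilon: float = 0.0
    sex_specific: bool = True
    estimable_paternal: np.ndarray | None = None
    estimable_maternal: np.ndarray | None = None
    r_max: float = 0.5

    def __post_init__(self) -> None:
        self.r_paternal = np.atleast_1d(np.asarray(self.r_paternal, dtype=float))
        self.r_maternal = np.atleast_1d(np.asarray(self.r_maternal, dtype=float))
        if self.r_paternal.shape != self.r_maternal.shape:
            raise ValueError("paternal and maternal r vectors must have equal length")
        hi = max(self.r_max, 0.5)
        for r in (self.r_paternal, self.r_maternal):
            if np.any((r < 0) | (r > hi)):
                raise ValueError(f"recombination fractions must lie in [0, {hi}]")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.epsilon > 0.5:
            import warnings

            warnings.warn(
                f"epsilon={self.epsilon:.3f} exceeds 0.5: this is the "
                "allele-label-swap regime and rarely meaningful",
                stacklevel=2,
            )
        if not self.sex_specific and not np.allclose(self.r_paternal, self.r_maternal):
            raise ValueError("sex_specific=False requires r_paternal == r_maternal")
        if self.estimable_paternal is None:
            self.estimable_paternal = np.ones(len(self.r_paternal), dtype=bool)
        if self.estimable_maternal is None:
            self.estimable_maternal = np.ones(len(self.r_maternal), dtype=bool)


@dataclass
class ReadCountData:
    """Allele read counts for the progeny of one or more full-sib families.

    ``Y``/``D`` are ``(N, M)`` integer matrices of reference-allele counts
    and total depths over progeny × loci; depth 0 encodes missing.
    ``family_of`` maps each progeny row to its family index.  Parental
    counts, when available, are stored as ``(2F, M)`` matrices with the
    maternal parent of family f in row 2f and the paternal in row 2f+1.
    """

    Y: np.ndarray
    D: np.ndarray
    family_of: np.ndarray | None = None
    loci: "object | None" = None  # pandas.DataFrame(id, chrom, pos) when read from disk
    samples: list | None = None
    parent_Y: np.ndarray | None = None
    parent_D: np.ndarray | None = None
    sts: list | None = None  # per-family segregation type sequences

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.D = np.asarray(self.D, dtype=np.int64)
        if self.Y.shape != self.D.shape or self.Y.ndim != 2:
            raise ValueError("Y and D must be 2-D matrices of identical shape")
        if np.any(self.Y < 0) or np.any(self.Y > self.D):
            raise ValueError("require 0 <= Y <= D elementwise")
        if self.family_of is None:
            self.family_of = np.zeros(self.Y.shape[0], dtype=np.int64)
        else:
            self.family_of = np.asarray(self.family_of, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return self.Y.shape[0]

    @property
    def n_loci(self) -> int:
        return self.Y.shape[1]

    @property
    def n_families(self) -> int:
        return int(self.family_of.max()) + 1 if len(self.family_of) else 0

    def subset_loci(self, idx) -> "ReadCountData":
        """Return a copy restricted to the given locus indices."""
        idx = np.asarray(idx)
        loci = self.loci.iloc[idx].reset_index(drop=True) if self.loci is not None else None
        sts = (
            [[st_seq[i] for i in idx] for st_seq in self.sts]
            if self.sts is not None
            else None
        )
        return ReadCountData(
            Y=self.Y[:, idx],
            D=self.D[:, idx],
            family_of=self.family_of.copy(),
            loci=loci,
            samples=self.samples,
            parent_Y=None if self.parent_Y is None else self.parent_Y[:, idx],
            parent_D=None if self.parent_D is None else self.parent_D[:, idx],
            sts=sts,
        )


@dataclass
class GenotypeCallData:
    """Called progeny genotypes (error-free model); -1 encodes missing."""

    G: np.ndarray
    family_of: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int64)
        if self.G.ndim != 2:
            raise ValueError("G must be a 2-D matrix")
        if not np.all(np.isin(self.G, [G_MISSING, G_AA, G_AB, G_BB])):
            raise ValueError("G entries must be in {-1, 0, 1, 2}")
        if self.family_of is None:
            self.family_of = np.zeros(self.G.shape[0], dtype=np.int64)
        else:
            self.family_of = np.asarray(self.family_of, dtype=np.int64)

    @property
    def n_individuals(self) -> int:
        return self.G.shape[0]

    @property
    def n_loci(self) -> int:
        return self.G.shape[1]


# ---------------------------------------------------------------------------
# Transition and emission probabilities
# ---------------------------------------------------------------------------

def transition_matrix(r_pat: float, r_mat: float) -> np.ndarray:
    """4×4 inheritance-state transition matrix for one interval.

    The two meioses are independent, so the entry for (s1,s2) -> (t1,t2)
    is the product of per-parent factors 1-r if the bit is retained and
    r if it flips.
    """
    if not (0 <= r_pat <= 1 and 0 <= r_mat <= 1):
        raise ValueError("recombination fractions must lie in [0, 1]")
    pat = np.where(FLIP_PAT, r_pat, 1.0 - r_pat)
    mat = np.where(FLIP_MAT, r_mat, 1.0 - r_mat)
    return pat * mat


def genotype_emission(g: int | str, state: InheritanceState | int, opgp: int) -> float:
    """Error-free emission: P(genotype | state, OPGP) ∈ {0, 1}.

    Missing genotypes emit probability 1 for every state.
    """
    if isinstance(g, str):
        g = _GENO_CODE.get(g.upper(), G_MISSING) if g.upper() != "MISSING" else G_MISSING
    if g == G_MISSING:
        return 1.0
    s = state.index if isinstance(state, InheritanceState) else int(state)
    return 1.0 if OPGP_STATE_GENOTYPE[opgp, s] == g else 0.0


def read_count_prob(a: int, d: int, g: int | str, epsilon: float) -> float:
    """Binomial probability of a reference reads out of depth d given genotype g."""
    if isinstance(g, str):
        g = _GENO_CODE[g.upper()]
    if not 0 <= a <= d:
        raise ValueError("require 0 <= a <= d")
    if d == 0:
        return 1.0
    comb = np.exp(log_binom_coef(np.array([d]), np.array([a])))[0]
    if g == G_AB:
        return float(comb * 0.5**d)
    if g == G_AA:
        return float(comb * (1.0 - epsilon) ** a * epsilon ** (d - a))
    if g == G_BB:
        return float(comb * (1.0 - epsilon) ** (d - a) * epsilon**a)
    raise ValueError(f"invalid genotype code {g}")


def sequencing_emission(
    a: int, d: int, state: InheritanceState | int, opgp: int, epsilon: float
) -> float:
    """Sequencing-model emission: read-count probability at the state-implied genotype."""
    s = state.index if isinstance(state, InheritanceState) else int(state)
    g = int(OPGP_STATE_GENOTYPE[opgp, s])
    return read_count_prob(a, d, g, epsilon)


def log_binom_coef(d: np.ndarray, a: np.ndarray) -> np.ndarray:
    """log C(d, a), elementwise.  Computed once per dataset and reused
    across EM iterations (depths can exceed 100 in real data)."""
    d = np.asarray(d, dtype=float)
    a = np.asarray(a, dtype=float)
    return gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)


def read_count_probs(
    Y: np.ndarray, D: np.ndarray, epsilon: float, logC: np.ndarray | None = None
) -> np.ndarray:
    """P(Y | G) for all three genotypes — array shape ``Y.shape + (3,)``.

    Cells with depth 0 get probability 1 for every genotype (missing).
    Computed in log space; ``logC`` may carry precomputed log binomial
    coefficients for the same Y, D.
    """
    Y = np.asarray(Y, dtype=float)
    D = np.asarray(D, dtype=float)
    if logC is None:
        logC = log_binom_coef(D, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = np.log(epsilon) if epsilon > 0 else -np.inf
        log_1me = np.log1p(-epsilon)
        out = np.empty(Y.shape + (3,))
        # multiplying by 0 reads of an impossible class must give log 0 cleanly
        aa = logC + Y * log_1me + np.where(D - Y > 0, (D - Y) * log_e, 0.0)
        bb = logC + (D - Y) * log_1me + np.where(Y > 0, Y * log_e, 0.0)
        out[..., G_AA] = np.exp(aa)
        out[..., G_AB] = np.exp(logC + D * np.log(0.5))
        out[..., G_BB] = np.exp(bb)
    out[D == 0] = 1.0
    return out


def _gather_state_probs(
    per_geno: np.ndarray, opgps, family_of: np.ndarray
) -> np.ndarray:
    """Map per-genotype probabilities (N, M, 3) to per-state emissions (N, M, 4)."""
    n, m = per_geno.shape[:2]
    emis = np.empty((n, m, 4))
    opgps = [np.asarray(o, dtype=int) for o in opgps]
    for f, codes in enumerate(opgps):
        rows = np.nonzero(family_of == f)[0]
        if rows.size == 0:
            continue
        g_idx = OPGP_STATE_GENOTYPE[codes].astype(np.intp)  # (M, 4)
        sub = per_geno[rows]  # (n_f, M, 3)
        emis[rows] = np.take_along_axis(
            sub, np.broadcast_to(g_idx, (rows.size, m, 4)), axis=2
        )
    return emis


def sequencing_emissions(
    data: ReadCountData, opgps, epsilon: float, logC: np.ndarray | None = None
) -> np.ndarray:
    """Per-state emission tensor (N, M, 4) for the sequencing model."""
    per_geno = read_count_probs(data.Y, data.D, epsilon, logC=logC)
    return _gather_state_probs(per_geno, opgps, data.family_of)


def genotype_emissions(data: GenotypeCallData, opgps) -> np.ndarray:
    """Per-state emission tensor (N, M, 4) for the error-free genotype model."""
    n, m = data.G.shape
    per_geno = np.zeros((n, m, 3))
    for g in (G_AA, G_AB, G_BB):
        per_geno[..., g] = data.G == g
    per_geno[data.G == G_MISSING] = 1.0
    return _gather_state_probs(per_geno, opgps, data.family_of)


# ---------------------------------------------------------------------------
# Forward recursion and forward-backward
# ---------------------------------------------------------------------------

def _transition_stack(params: RecombinationParams) -> np.ndarray:
    """(M-1, 4, 4) transition matrices, non-estimable intervals fixed at r=0."""
    m1 = len(params.r_paternal)
    T = np.empty((m1, 4, 4))
    for j in range(m1):
        rp = params.r_paternal[j] if params.estimable_paternal[j] else 0.0
        rm = params.r_maternal[j] if params.estimable_maternal[j] else 0.0
        T[j] = transition_matrix(rp, rm)
    return T


def forward_logliks(emis: np.ndarray, params: RecombinationParams) -> np.ndarray:
    """Per-individual log-likelihoods via the scaled forward recursion.

    ``emis`` is the (N, M, 4) emission tensor; the initial distribution is
    uniform 1/4 over the four inheritance states.  Raises
    :class:`InconsistentDataError` if any individual's likelihood is
    identically zero (possible only in the error-free genotype model).
    """
    n, m, _ = emis.shape
    T = _transition_stack(params)
    alpha = 0.25 * emis[:, 0, :]
    ll = np.zeros(n)
    for j in range(m):
        if j > 0:
            alpha = (alpha @ T[j - 1]) * emis[:, j, :]
        c = alpha.sum(axis=1)
        if np.any(c <= 0):
            bad = np.nonzero(c <= 0)[0]
            raise InconsistentDataError(
                f"zero likelihood at locus {j} for individual(s) {bad.tolist()}: "
                "observed genotypes impossible under the error-free model"
            )
        ll += np.log(c)
        alpha = alpha / c[:, None]
    return ll


def _emissions_for(data, params: RecombinationParams, opgps, model: str) -> np.ndarray:
    if model == "sequencing":
        if not isinstance(data, ReadCountData):
            raise TypeError("sequencing model requires ReadCountData")
        return sequencing_emissions(data, opgps, params.epsilon)
    if model == "genotype":
        if not isinstance(data, GenotypeCallData):
            raise TypeError("genotype model requires GenotypeCallData")
        return genotype_emissions(data, opgps)
    raise ValueError(f"unknown model {model!r}")


def forward_loglik_individual(
    obs_ref,
    params: RecombinationParams,
    opgps,
    obs_depth=None,
    model: str = "sequencing",
) -> float:
    """Log-likelihood of a single individual's observations.

    For the sequencing model pass reference counts and depths; for the
    genotype model pass the genotype vector (codes, -1 missing) and
    ``model='genotype'``.  ``opgps`` is that family's OPGP code sequence.
    """
    if model == "sequencing":
        data = ReadCountData(
            Y=np.atleast_2d(obs_ref), D=np.atleast_2d(obs_depth)
        )
    else:
        data = GenotypeCallData(G=np.atleast_2d(obs_ref))
    emis = _emissions_for(data, params, [opgps], model)
    return float(forward_logliks(emis, params)[0])


def total_loglik(data, params: RecombinationParams, opgps, model: str = "sequencing") -> float:
    """Total log-likelihood over all individuals in all families.

    Individuals are conditionally independent given the OPGPs, so the
    multi-family log-likelihood is the sum of per-individual terms.
    ``opgps`` is a sequence of per-family OPGP code sequences.
    """
    emis = _emissions_for(data, params, opgps, model)
    return float(forward_logliks(emis, params).sum())


try:  # numba accelerates the per-individual forward-backward loops
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(f):
        return f


@_njit
def _fb_kernel(emis, T):  # pragma: no cover - exercised via forward_backward
    n, m, _ = emis.shape
    alphas = np.empty((n, m, 4))
    scales = np.empty((n, m))
    gamma = np.empty((n, m, 4))
    flip_pat = np.zeros(m - 1)
    flip_mat = np.zeros(m - 1)
    loglik = 0.0
    for i in range(n):
        c = 0.0
        for s in range(4):
            a = 0.25 * emis[i, 0, s]
            alphas[i, 0, s] = a
            c += a
        if c <= 0.0:
            return -1, 0.0, gamma, flip_pat, flip_mat
        scales[i, 0] = c
        for s in range(4):
            alphas[i, 0, s] /= c
        for j in range(1, m):
            c = 0.0
            for t in range(4):
                acc = 0.0
                for s in range(4):
                    acc += alphas[i, j - 1, s] * T[j - 1, s, t]
                v = acc * emis[i, j, t]
                alphas[i, j, t] = v
                c += v
            if c <= 0.0:
                return -1, 0.0, gamma, flip_pat, flip_mat
            scales[i, j] = c
            for t in range(4):
                alphas[i, j, t] /= c
        for j in range(m):
            loglik += np.log(scales[i, j])
        beta = np.ones(4)
        for s in range(4):
            gamma[i, m - 1, s] = alphas[i, m - 1, s]
        for j in range(m - 2, -1, -1):
            w = np.empty(4)
            for t in range(4):
                w[t] = emis[i, j + 1, t] * beta[t]
            cj1 = scales[i, j + 1]
            for s in range(4):
                for t in range(4):
                    x = alphas[i, j, s] * T[j, s, t] * w[t] / cj1
                    if (s >> 1) != (t >> 1):
                        flip_pat[j] += x
                    if (s & 1) != (t & 1):
                        flip_mat[j] += x
            newbeta = np.empty(4)
            for s in range(4):
                acc = 0.0
                for t in range(4):
                    acc += T[j, s, t] * w[t]
                newbeta[s] = acc / cj1
            beta = newbeta
            for s in range(4):
                gamma[i, j, s] = alphas[i, j, s] * beta[s]
    return 0, loglik, gamma, flip_pat, flip_mat


@_njit
def _em_iter_kernel(Y, D, logC, g_state, T, epsilon):  # pragma: no cover
    """One fused EM iteration for the sequencing model.

    Computes emissions from the read counts at the current epsilon, runs
    the scaled forward-backward pass, and accumulates the Baum-Welch
    statistics: expected recombination counts per interval and parent,
    and the numerator/denominator of the epsilon update (expected
    miscall-implied reads at homozygote-implied genotypes).
    """
    n, m = Y.shape
    flip_pat = np.zeros(m - 1)
    flip_mat = np.zeros(m - 1)
    eps_num = 0.0
    eps_den = 0.0
    loglik = 0.0
    log_half = np.log(0.5)
    log_1me = np.log1p(-epsilon)
    log_e = np.log(epsilon) if epsilon > 0.0 else -np.inf
    emis = np.empty((m, 4))
    alphas = np.empty((m, 4))
    scales = np.empty(m)
    for i in range(n):
        # per-locus emissions at the state-implied genotypes
        for j in range(m):
            d = D[i, j]
            y = Y[i, j]
            if d == 0:
                p_aa = 1.0
                p_ab = 1.0
                p_bb = 1.0
            else:
                la = logC[i, j] + y * log_1me
                if d > y:
                    la += (d - y) * log_e
                lb = logC[i, j] + (d - y) * log_1me
                if y > 0:
                    lb += y * log_e
                p_aa = np.exp(la)
                p_ab = np.exp(logC[i, j] + d * log_half)
                p_bb = np.exp(lb)
            for s in range(4):
                g = g_state[i, j, s]
                if g == 0:
                    emis[j, s] = p_aa
                elif g == 1:
                    emis[j, s] = p_ab
                else:
                    emis[j, s] = p_bb
        # forward
        c = 0.0
        for s in range(4):
            a = 0.25 * emis[0, s]
            alphas[0, s] = a
            c += a
        if c <= 0.0:
            return -1, 0.0, flip_pat, flip_mat, 0.0, 0.0
        scales[0] = c
        for s in range(4):
            alphas[0, s] /= c
        for j in range(1, m):
            c = 0.0
            for t in range(4):
                acc = 0.0
                for s in range(4):
                    acc += alphas[j - 1, s] * T[j - 1, s, t]
                v = acc * emis[j, t]
                alphas[j, t] = v
                c += v
            if c <= 0.0:
                return -1, 0.0, flip_pat, flip_mat, 0.0, 0.0
            scales[j] = c
            for t in range(4):
                alphas[j, t] /= c
        for j in range(m):
            loglik += np.log(scales[j])
        # backward, with gamma consumed on the fly for the epsilon update
        beta = np.ones(4)
        for j in range(m - 1, -1, -1):
            if j < m - 1:
                w = np.empty(4)
                for t in range(4):
                    w[t] = emis[j + 1, t] * beta[t]
                cj1 = scales[j + 1]
                for s in range(4):
                    for t in range(4):
                        x = alphas[j, s] * T[j, s, t] * w[t] / cj1
                        if (s >> 1) != (t >> 1):
                            flip_pat[j] += x
                        if (s & 1) != (t & 1):
                            flip_mat[j] += x
                newbeta = np.empty(4)
                for s in range(4):
                    acc = 0.0
                    for t in range(4):
                        acc += T[j, s, t] * w[t]
                    newbeta[s] = acc / cj1
                beta = newbeta
            w_aa = 0.0
            w_bb = 0.0
            for s in range(4):
                gpost = alphas[j, s] * beta[s]
                g = g_state[i, j, s]
                if g == 0:
                    w_aa += gpost
                elif g == 2:
                    w_bb += gpost
            d = D[i, j]
            y = Y[i, j]
            eps_num += w_aa * (d - y) + w_bb * y
            eps_den += (w_aa + w_bb) * d
    return 0, loglik, flip_pat, flip_mat, eps_num, eps_den


def transition_stack_from_r(r_pat, r_mat, est_pat=None, est_mat=None) -> np.ndarray:
    """(M-1, 4, 4) transition matrices; non-estimable intervals at r = 0."""
    rp = np.asarray(r_pat, dtype=float)
    rm = np.asarray(r_mat, dtype=float)
    if est_pat is not None:
        rp = np.where(est_pat, rp, 0.0)
    if est_mat is not None:
        rm = np.where(est_mat, rm, 0.0)
    rp = rp[:, None, None]
    rm = rm[:, None, None]
    return np.where(FLIP_PAT[None], rp, 1.0 - rp) * np.where(FLIP_MAT[None], rm, 1.0 - rm)


def em_iteration_stats(Y, D, logC, g_state, T, epsilon: float):
    """Fused E-step statistics for the sequencing model (fast path).

    ``T`` is the (M-1, 4, 4) transition stack.  Falls back to the
    emission-tensor + forward-backward route when numba is unavailable.
    Returns ``(loglik, flip_pat, flip_mat, eps_num, eps_den)``.
    """
    if _HAVE_NUMBA:
        status, ll, fp, fm, num, den = _em_iter_kernel(Y, D, logC, g_state, T, epsilon)
        if status < 0:
            raise InconsistentDataError("zero likelihood in forward pass")
        return ll, fp, fm, num, den
    per_geno = read_count_probs(Y, D, epsilon, logC=logC)
    emis = np.take_along_axis(per_geno, g_state, axis=2)
    ll, gamma, fp, fm = _forward_backward_numpy(emis, T)
    w_aa = np.where(g_state == G_AA, gamma, 0.0).sum(axis=2)
    w_bb = np.where(g_state == G_BB, gamma, 0.0).sum(axis=2)
    num = float(np.sum(w_aa * (D - Y) + w_bb * Y))
    den = float(np.sum((w_aa + w_bb) * D))
    return ll, fp, fm, num, den


def forward_backward(emis: np.ndarray, params: RecombinationParams):
    """Scaled forward-backward pass over all individuals.

    Returns ``(loglik, gamma, flip_pat, flip_mat)`` where ``gamma`` is the
    (N, M, 4) state posterior, and ``flip_pat[j]`` / ``flip_mat[j]`` are the
    expected numbers of paternal / maternal recombination events in
    interval j summed over individuals (the Baum-Welch statistics for the
    M-step of r).
    """
    T = _transition_stack(params)
    if _HAVE_NUMBA:
        status, loglik, gamma, flip_pat, flip_mat = _fb_kernel(
            np.ascontiguousarray(emis), T
        )
        if status < 0:
            raise InconsistentDataError("zero likelihood in forward pass")
        return loglik, gamma, flip_pat, flip_mat
    return _forward_backward_numpy(emis, T)


def _forward_backward_numpy(emis: np.ndarray, T: np.ndarray):
    n, m, _ = emis.shape
    alphas = np.empty((n, m, 4))
    scales = np.empty((n, m))
    alpha = 0.25 * emis[:, 0, :]
    for j in range(m):
        if j > 0:
            alpha = (alpha @ T[j - 1]) * emis[:, j, :]
        c = alpha.sum(axis=1)
        if np.any(c <= 0):
            raise InconsistentDataError("zero likelihood in forward pass")
        alpha = alpha / c[:, None]
        alphas[:, j] = alpha
        scales[:, j] = c
    loglik = float(np.log(scales).sum())

    gamma = np.empty((n, m, 4))
    flip_pat = np.zeros(m - 1)
    flip_mat = np.zeros(m - 1)
    beta = np.ones((n, 4))
    gamma[:, m - 1] = alphas[:, m - 1]
    for j in range(m - 2, -1, -1):
        w = emis[:, j + 1, :] * beta  # (N, 4)
        xi = alphas[:, j][:, :, None] * T[j][None, :, :] * w[:, None, :]
        xi /= scales[:, j + 1][:, None, None]
        flip_pat[j] = xi[:, FLIP_PAT].sum()
        flip_mat[j] = xi[:, FLIP_MAT].sum()
        beta = (w @ T[j].T) / scales[:, j + 1][:, None]
        gamma[:, j] = alphas[:, j] * beta
    return loglik, gamma, flip_pat, flip_mat
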