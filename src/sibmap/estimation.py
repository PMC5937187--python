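"""Maximum-likelihood map estimation via EM, and two-point diagnostics.

The E-step runs the scaled forward-backward pass per progeny; the
M-step updates each estimable recombination fraction as the expected
number of recombination events in its meioses divided by the number of
contributing meioses (the Baum-Welch ratio, specialized to the 2-bit
factorized inheritance chain), and the sequencing-error rate from the
expected number of miscall-implied reads at homozygote-implied
genotypes.  Both updates maximize the expected complete-data
log-likelihood, so the observed log-likelihood is non-decreasing at
every iteration; r updates are clipped to the admissible interval
(constrained M-step, which preserves the ascent property).

Recombination fractions that cannot be estimated — because the relevant
parent is homozygous at every locus up to the interval, or at the locus
just after it, in every family — are excluded (held at 0), which
reparametrizes the next estimable fraction as recombination to the
previous locus segregating in that parent.

Two-point estimation maximizes the 2-locus likelihood separately under
each admissible relative phase of the pair and keeps the phase with the
larger maximized likelihood, as used for recombination-fraction
heatmaps that diagnose marker ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from . import hmm
from .hmm import (
    GenotypeCallData,
    ReadCountData,
    RecombinationParams,
    log_binom_coef,
)
from .segregation import SegregationType, opgp_segregation_type

__all__ = [
    "MapEstimate",
    "TwoPointResult",
    "NoSharedMeiosisError",
    "estimable_intervals",
    "fit_map",
    "haldane_cM",
    "fit_twopoint",
    "twopoint_matrix",
    "map_table",
    "run_summary",
]


class NoSharedMeiosisError(ValueError):
    """Two loci are not informative in any shared parent."""


@dataclass
class MapEstimate:
    """Fitted map: recombination fractions, error rate, and Haldane distances."""

    params: RecombinationParams
    loglik: float
    distances_cM: np.ndarray
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def epsilon(self) -> float:
        return self.params.epsilon

    @property
    def total_cM(self) -> float:
        return float(np.nansum(self.distances_cM))


@dataclass
class TwoPointResult:
    """Two-point recombination fraction with its likelihood-chosen phase."""

    r_hat: float
    phase: dict
    loglik: float
    pair: tuple[int, int]


def estimable_intervals(sts_per_family) -> tuple[np.ndarray, np.ndarray]:
    """Mark which per-interval recombination fractions are estimable.

    ``sts_per_family`` is a sequence of per-family segregation-type
    sequences (entries may be ``None`` for undeterminable loci, treated
    as uninformative).  The paternal (maternal) fraction for the interval
    between loci j and j+1 is estimable unless locus j+1 is paternally
    (maternally) homozygous in every family, or every locus up to j is.
    """
    sts_per_family = [list(seq) for seq in sts_per_family]
    m = len(sts_per_family[0])
    if any(len(seq) != m for seq in sts_per_family):
        raise ValueError("all families must have the same number of loci")
    pat_inf = np.zeros(m, dtype=bool)
    mat_inf = np.zeros(m, dtype=bool)
    for seq in sts_per_family:
        for j, st in enumerate(seq):
            if st is None:
                continue
            st = SegregationType(st)
            pat_inf[j] |= st.paternal_informative
            mat_inf[j] |= st.maternal_informative

    def marks(inf: np.ndarray) -> np.ndarray:
        seen = np.cumsum(inf).astype(bool)  # informative locus at or before j
        return np.array([inf[j + 1] and seen[j] for j in range(m - 1)])

    return marks(pat_inf), marks(mat_inf)


def _sts_from_opgps(opgps) -> list[list[SegregationType]]:
    return [[opgp_segregation_type(int(c)) for c in codes] for codes in opgps]


def fit_map(
    data,
    opgps,
    *,
    sex_specific: bool = True,
    estimate_epsilon: bool = True,
    epsilon_init: float = 0.005,
    r_init: float = 0.1,
    max_iter: int = 1000,
    tol: float = 1e-6,
    model: str = "sequencing",
    r_max: float = 0.5,
) -> MapEstimate:
    """Fit recombination fractions (and optionally ε) by EM.

    Parameters
    ----------
    data
        :class:`~sibmap.hmm.ReadCountData` (sequencing model) or
        :class:`~sibmap.hmm.GenotypeCallData` (error-free genotype model).
    opgps
        Per-family OPGP code sequences (known or previously inferred).
    sex_specific
        Fit separate paternal/maternal fractions; otherwise one shared
        fraction per interval.
    r_max
        Upper bound for r: 0.5 for map estimation, 1.0 for the relaxed
        likelihood used in phase inference.
    """
    if data.n_individuals == 0 or data.n_loci == 0:
        raise ValueError("empty data")
    m = data.n_loci
    opgps = [np.asarray(o, dtype=int) for o in opgps]
    sts = _sts_from_opgps(opgps)
    if sex_specific:
        est_pat, est_mat = estimable_intervals(sts)
    else:
        # with a single fraction per interval either meiosis can inform it;
        # exclusion only if no parent is informative
        est_any, est_any2 = estimable_intervals(sts)
        est_pat = est_mat = est_any | est_any2

    n_meioses = data.n_individuals
    r_init_pat, r_init_mat = (
        r_init if isinstance(r_init, (tuple, list)) else (r_init, r_init)
    )
    r_pat = np.where(est_pat, r_init_pat, 0.0)
    r_mat = np.where(est_mat, r_init_mat, 0.0)
    epsilon = float(epsilon_init) if (estimate_epsilon and model == "sequencing") else (
        epsilon_init if model == "sequencing" else 0.0
    )

    if model == "sequencing":
        logC = log_binom_coef(data.D, data.Y)
        # genotype class implied by each (locus, state) per individual's family
        g_state = np.empty((data.n_individuals, m, 4), dtype=np.intp)
        for f, codes in enumerate(opgps):
            rows = data.family_of == f
            g_state[rows] = hmm.OPGP_STATE_GENOTYPE[codes].astype(np.intp)

    trace = []
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    if model == "genotype":
        geno_emis = hmm.genotype_emissions(data, opgps)
    for n_iter in range(1, max_iter + 1):
        T = hmm.transition_stack_from_r(r_pat, r_mat, est_pat, est_mat)
        if model == "sequencing":
            ll, flip_pat, flip_mat, eps_num, eps_den = hmm.em_iteration_stats(
                data.Y, data.D, logC, g_state, T, epsilon
            )
        else:
            ll, gamma, flip_pat, flip_mat = hmm._forward_backward_numpy(geno_emis, T)
        trace.append(ll)

        if sex_specific:
            upd_pat = np.clip(flip_pat / n_meioses, 0.0, r_max)
            upd_mat = np.clip(flip_mat / n_meioses, 0.0, r_max)
            r_pat = np.where(est_pat, upd_pat, 0.0)
            r_mat = np.where(est_mat, upd_mat, 0.0)
        else:
            upd = np.clip((flip_pat + flip_mat) / (2.0 * n_meioses), 0.0, r_max)
            r_pat = r_mat = np.where(est_pat, upd, 0.0)

        if estimate_epsilon and model == "sequencing" and eps_den > 0:
            # heterozygote-weighted reads carry no information about epsilon
            epsilon = min(eps_num / eps_den, 0.999)

        if np.abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    params = RecombinationParams(
        r_paternal=r_pat,
        r_maternal=r_mat,
        epsilon=epsilon,
        sex_specific=sex_specific,
        estimable_paternal=est_pat,
        estimable_maternal=est_mat,
        r_max=r_max,
    )
    dist = np.full(m - 1, np.nan)
    if r_max <= 0.5:
        for j in range(m - 1):
            if est_pat[j] or est_mat[j]:
                rs = []
                if est_pat[j]:
                    rs.append(r_pat[j])
                if est_mat[j]:
                    rs.append(r_mat[j])
                r_mean = float(np.mean(rs))
                dist[j] = haldane_cM(r_mean) if r_mean < 0.5 else np.inf
    return MapEstimate(
        params=params,
        loglik=trace[-1],
        distances_cM=dist,
        n_iter=n_iter,
        converged=converged,
        loglik_trace=np.asarray(trace),
    )


def haldane_cM(r: float) -> float:
    """Haldane map distance in centimorgans: d = -50 ln(1 - 2r)."""
    if not 0 <= r < 0.5:
        raise ValueError(f"Haldane distance infinite or undefined for r={r}")
    return -50.0 * np.log1p(-2.0 * r)


# --- two-point estimation ---------------------------------------------------

def _flip_code(code: int, flip_pat: bool, flip_mat: bool) -> int:
    """OPGP code after swapping chromosome labels within a parent."""
    from .segregation import OPGP_TABLE

    z11, z10, z01, z00 = OPGP_TABLE[code]
    if flip_pat:
        z11, z10 = z10, z11
    if flip_mat:
        z01, z00 = z00, z01
    quad = (z11, z10, z01, z00)
    for c, q in OPGP_TABLE.items():
        if q == quad:
            return c
    raise AssertionError("unreachable")


def fit_twopoint(
    data: ReadCountData,
    epsilon: float = 0.0,
    pair: tuple[int, int] = (0, 1),
    sts=None,
    **fit_kw,
) -> TwoPointResult:
    """Two-point recombination fraction between one locus pair.

    The 2-locus likelihood (single shared fraction, r ∈ [0, 0.5], fixed
    ε) is maximized separately under each admissible relative phase —
    coupling/repulsion per parent heterozygous at both loci — and the
    phase with the larger likelihood is returned.  Segregation types are
    taken from ``sts`` (per family) or from ``data.sts``.

    For a BI-BI pair under a tied r, a single flip's parent assignment is
    not identifiable (both choices give the same likelihood and the same
    r); ties are broken toward coupling, paternal before maternal.
    """
    if data.n_loci == 2:
        sub = data
        i, j = pair
    else:
        i, j = pair
        sub = data.subset_loci([i, j])
    sts = sts if sts is not None else sub.sts
    if sts is None:
        raise ValueError("segregation types required (pass sts= or set data.sts)")
    sts = [[SegregationType(s) for s in seq] for seq in sts]

    from .phasing import default_opgp

    shared_pat = any(
        seq[0].paternal_informative and seq[1].paternal_informative for seq in sts
    )
    shared_mat = any(
        seq[0].maternal_informative and seq[1].maternal_informative for seq in sts
    )
    if not (shared_pat or shared_mat):
        raise NoSharedMeiosisError(
            "the two loci are not informative in a shared parent in any family"
        )

    flips_pat = (False, True) if shared_pat else (False,)
    flips_mat = (False, True) if shared_mat else (False,)
    best = None
    for fp, fm in product(flips_pat, flips_mat):
        opgps = [
            np.array(
                [default_opgp(seq[0]), _flip_code(default_opgp(seq[1]), fp, fm)]
            )
            for seq in sts
        ]
        fit = fit_map(
            sub,
            opgps,
            sex_specific=False,
            estimate_epsilon=False,
            epsilon_init=epsilon,
            model="sequencing",
            **fit_kw,
        )
        if best is None or fit.loglik > best[0]:
            best = (fit.loglik, fp, fm, fit)
    ll, fp, fm, fit = best
    phase = {}
    if shared_pat:
        phase["paternal"] = "repulsion" if fp else "coupling"
    if shared_mat:
        phase["maternal"] = "repulsion" if fm else "coupling"
    return TwoPointResult(
        r_hat=float(fit.params.r_paternal[0]), phase=phase, loglik=ll, pair=(i, j)
    )


def twopoint_matrix(
    data: ReadCountData, parent: str = "paternal", epsilon: float = 0.0, **fit_kw
) -> np.ndarray:
    """Symmetric matrix of two-point r estimates for same-parent-informative pairs.

    ``parent`` selects loci heterozygous in the paternal or maternal
    parent (in at least one family).  Non-qualifying pairs are NaN; the
    diagonal is 0 for qualifying loci.
    """
    if parent not in ("paternal", "maternal"):
        raise ValueError("parent must be 'paternal' or 'maternal'")
    if data.sts is None:
        raise ValueError("data.sts required")
    m = data.n_loci
    attr = f"{parent}_informative"
    qual = np.array(
        [
            any(getattr(SegregationType(seq[j]), attr) for seq in data.sts)
            for j in range(m)
        ]
    )
    if qual.sum() < 2:
        raise ValueError("need at least two qualifying loci")
    out = np.full((m, m), np.nan)
    for j in np.nonzero(qual)[0]:
        out[j, j] = 0.0
    idx = np.nonzero(qual)[0]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = int(idx[a]), int(idx[b])
            try:
                res = fit_twopoint(data, epsilon=epsilon, pair=(i, j), **fit_kw)
            except NoSharedMeiosisError:
                continue
            out[i, j] = out[j, i] = res.r_hat
    return out


# --- exports ----------------------------------------------------------------

def map_table(est: MapEstimate, loci=None) -> pd.DataFrame:
    """Tab-friendly map table: per-locus interval estimates and cumulative cM."""
    m = len(est.params.r_paternal) + 1
    ids = list(loci["id"]) if loci is not None else [f"L{j+1}" for j in range(m)]
    cum = np.concatenate([[0.0], np.nancumsum(np.nan_to_num(est.distances_cM))])
    return pd.DataFrame(
        {
            "locus": ids,
            "order": np.arange(1, m + 1),
            "r_paternal": np.concatenate([[np.nan], est.params.r_paternal]),
            "r_maternal": np.concatenate([[np.nan], est.params.r_maternal]),
            "interval_cM": np.concatenate([[np.nan], est.distances_cM]),
            "cumulative_cM": cum,
        }
    )


def run_summary(est: MapEstimate) -> dict:
    """Machine-readable fit summary."""
    return {
        "loglik": float(est.loglik),
        "epsilon": float(est.epsilon),
        "n_iter": int(est.n_iter),
        "converged": bool(est.converged),
        "total_cM": est.total_cM,
    }
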