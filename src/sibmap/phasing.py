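"""Parental phase (OPGP) inference from progeny data.

The multipoint likelihood assumes the OPGPs are known; in practice only
the segregation types are (from the parents' genotypes).  Phase is
inferred per family by fixing every locus at the default OPGP of its
segregation-type block and maximizing the likelihood with the
recombination fractions *relaxed* to [0, 1]: a fraction estimated above
0.5 means the default phase is wrong relative to the previous locus
segregating in that parent, i.e. that parent's chromosome labels flip
from there on.  Walking the loci left to right and toggling a
per-parent flip parity whenever the relaxed estimate exceeds 0.5
recovers the OPGP sequence.

Phase is only identified modulo a 4-fold symmetry — relabelling either
parent's two chromosomes globally leaves the likelihood unchanged — so
inferred OPGP sequences are compared modulo that symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import _flip_code, fit_map
from .hmm import ReadCountData
from .segregation import SegregationType, call_genotype_from_counts

__all__ = [
    "PhaseResult",
    "default_opgp",
    "infer_opgps",
    "apply_global_flips",
    "phase_equal_mod_symmetry",
    "phase_table",
]

# Default (baseline) OPGP per segregation type: the lowest-numbered code of
# the block, i.e. the initialization quadruples (A,B,A,B), (A,B,A,A),
# (A,B,B,B), (A,A,A,B), (B,B,A,B) and (A,A,A,A).
_DEFAULT_OPGP = {
    SegregationType.BI: 1,
    SegregationType.PI_A: 5,
    SegregationType.PI_B: 7,
    SegregationType.MI_A: 9,
    SegregationType.MI_B: 11,
    SegregationType.U: 13,
}


def default_opgp(st: SegregationType | str) -> int:
    """Baseline OPGP code used to initialize phase inference."""
    return _DEFAULT_OPGP[SegregationType(st)]


@dataclass
class PhaseResult:
    """Inferred OPGP sequence for one family with its relaxed-fit diagnostics."""

    opgps: np.ndarray
    relaxed_r_paternal: np.ndarray
    relaxed_r_maternal: np.ndarray
    loglik: float
    ambiguous_intervals: set = field(default_factory=set)
    epsilon: float = 0.0
    min_ascent: float = 0.0  # smallest per-iteration log-likelihood change


def _u_locus_code(data: ReadCountData, family: int, j: int, depth_threshold: int = 5) -> int:
    """OPGP code (13..16) of an uninformative locus from parental calls."""
    if data.parent_Y is None:
        return 13
    mat = call_genotype_from_counts(
        int(data.parent_Y[2 * family, j]), int(data.parent_D[2 * family, j]), depth_threshold
    )
    pat = call_genotype_from_counts(
        int(data.parent_Y[2 * family + 1, j]), int(data.parent_D[2 * family + 1, j]), depth_threshold
    )
    return {
        ("AA", "AA"): 13,
        ("BB", "AA"): 14,  # paternal AA, maternal BB -> (A,A,B,B)
        ("AA", "BB"): 15,
        ("BB", "BB"): 16,
    }.get((mat, pat), 13)


def infer_opgps(
    family_data: ReadCountData,
    sts,
    *,
    model: str = "sequencing",
    epsilon: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    ambiguity_tol: float = 0.01,
) -> PhaseResult:
    """Infer the OPGP sequence of a single full-sib family.

    Parameters
    ----------
    family_data
        Read counts for one family's progeny.
    sts
        Segregation type per locus (known from the parents).
    epsilon
        Sequencing error rate to use; ``None`` estimates it jointly
        during the relaxed fit.

    Notes
    -----
    Relaxed estimates within ``ambiguity_tol`` of 0.5 carry no phase
    signal; the interval is flagged ambiguous and the default (no flip)
    is retained, with a warning.
    """
    sts = [SegregationType(s) for s in sts]
    m = len(sts)
    if family_data.n_loci != m:
        raise ValueError("sts length must match the number of loci")
    if family_data.n_families != 1:
        raise ValueError("phase is inferred family by family; pass one family")

    base = np.array([default_opgp(st) for st in sts])
    # start the relaxed fit near r = 0.5: the first M-step then reads the
    # flip direction per interval from emission-only posteriors, instead of
    # being dragged below 0.5 by a no-flip-biased start (which can strand
    # adjacent intervals on a saddle near 0.5 at low depth).  The slight
    # paternal/maternal asymmetry deterministically breaks the
    # parent-exchange symmetry of families whose loci are all BI.
    fit = fit_map(
        family_data,
        [base],
        sex_specific=True,
        estimate_epsilon=epsilon is None and model == "sequencing",
        epsilon_init=0.005 if epsilon is None else epsilon,
        r_init=(0.49, 0.51),
        max_iter=max_iter,
        tol=tol,
        model=model,
        r_max=1.0,
    )
    r_pat = fit.params.r_paternal
    r_mat = fit.params.r_maternal

    ambiguous: set[int] = set()
    flips_pat = np.zeros(m, dtype=bool)
    flips_mat = np.zeros(m, dtype=bool)
    for which, r, flips in (
        ("paternal", r_pat, flips_pat),
        ("maternal", r_mat, flips_mat),
    ):
        informative = [j for j, st in enumerate(sts) if getattr(st, f"{which}_informative")]
        parity = False
        for idx, j in enumerate(informative):
            if idx == 0:
                continue  # first informative locus anchors the baseline
            r_rel = r[j - 1]  # estimable interval ending at locus j
            if abs(r_rel - 0.5) < ambiguity_tol:
                ambiguous.add(j - 1)
                import warnings

                warnings.warn(
                    f"relaxed {which} recombination fraction {r_rel:.3f} for the "
                    f"interval into locus {j} is phase-ambiguous; keeping default phase",
                    stacklevel=2,
                )
            elif r_rel > 0.5:
                parity = not parity
            flips[j] = parity

    opgps = np.empty(m, dtype=int)
    for j, st in enumerate(sts):
        if st is SegregationType.U:
            opgps[j] = _u_locus_code(family_data, 0, j)
        else:
            opgps[j] = _flip_code(int(base[j]), bool(flips_pat[j]), bool(flips_mat[j]))

    return PhaseResult(
        opgps=opgps,
        relaxed_r_paternal=r_pat,
        relaxed_r_maternal=r_mat,
        loglik=fit.loglik,
        ambiguous_intervals=ambiguous,
        epsilon=fit.params.epsilon,
        min_ascent=float(np.min(np.diff(fit.loglik_trace))) if fit.n_iter > 1 else 0.0,
    )


def apply_global_flips(opgps, flip_pat: bool, flip_mat: bool) -> np.ndarray:
    """Relabel one or both parents' chromosomes at every locus."""
    return np.array([_flip_code(int(c), flip_pat, flip_mat) for c in opgps])


def phase_equal_mod_symmetry(a, b) -> bool:
    """True if two OPGP sequences agree up to global parental chromosome relabelling."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        return False
    return any(
        np.array_equal(apply_global_flips(a, fp, fm), b)
        for fp in (False, True)
        for fm in (False, True)
    )


def phase_table(result: PhaseResult, sts, family: int = 0, loci=None) -> pd.DataFrame:
    """Tab-friendly phase report for one family."""
    m = len(result.opgps)
    ids = list(loci["id"]) if loci is not None else [f"L{j+1}" for j in range(m)]
    return pd.DataFrame(
        {
            "locus": ids,
            "family": family,
            "st": [SegregationType(s).value for s in sts],
            "opgp": result.opgps,
            "relaxed_r_paternal": np.concatenate([[np.nan], result.relaxed_r_paternal]),
            "relaxed_r_maternal": np.concatenate([[np.nan], result.relaxed_r_maternal]),
            "ambiguous": [
                j - 1 in result.ambiguous_intervals for j in range(m)
            ],
        }
    )
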