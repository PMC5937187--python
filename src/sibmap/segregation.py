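"""Segregation types and ordered parental genotype pairs (OPGPs).

In an outcrossed full-sib family each biallelic locus is classified by
which parents are heterozygous: both-informative (BI, AB×AB),
maternal-informative (MI_A = AB×AA, MI_B = AB×BB), paternal-informative
(PI_A = AA×AB, PI_B = BB×AB), or uninformative (U, both parents
homozygous).  Crosses are written maternal × paternal; A is the
reference allele and B the alternate.

The phased arrangement of the four parental alleles at a locus is the
ordered parental genotype pair (OPGP), an integer code 1..16 mapping to
the quadruple (Z11, Z10, Z01, Z00): the paternal parent's paternal- and
maternal-chromosome alleles followed by the maternal parent's.  The 16
quadruples exhaust {A,B}^4 and group into fixed blocks per segregation
type.

Also provided: segregation-type inference from parental read counts and
a depth-adjusted chi-square test of progeny segregation ratios that
accounts for allelic dropout at low read depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "SegregationType",
    "ParentalGenotypes",
    "SegregationUndeterminableError",
    "OPGP_TABLE",
    "ST_BLOCKS",
    "opgp_alleles",
    "opgp_segregation_type",
    "classify_segregation_type",
    "call_genotype_from_counts",
    "infer_segregation_types",
    "segregation_test",
]


class SegregationType(str, Enum):
    """Locus category by parental heterozygosity (maternal × paternal)."""

    BI = "BI"      # AB × AB
    PI_A = "PI_A"  # AA × AB
    PI_B = "PI_B"  # BB × AB
    MI_A = "MI_A"  # AB × AA
    MI_B = "MI_B"  # AB × BB
    U = "U"        # both parents homozygous

    @property
    def paternal_informative(self) -> bool:
        return self in (SegregationType.BI, SegregationType.PI_A, SegregationType.PI_B)

    @property
    def maternal_informative(self) -> bool:
        return self in (SegregationType.BI, SegregationType.MI_A, SegregationType.MI_B)


class SegregationUndeterminableError(ValueError):
    """Raised when a segregation type cannot be determined from the parents."""


# OPGP code -> (Z11, Z10, Z01, Z00).  Paternal parent's chromosomes first
# (paternal then maternal chromosome), then the maternal parent's.
OPGP_TABLE: dict[int, tuple[str, str, str, str]] = {
    1: ("A", "B", "A", "B"),
    2: ("B", "A", "A", "B"),
    3: ("A", "B", "B", "A"),
    4: ("B", "A", "B", "A"),
    5: ("A", "B", "A", "A"),
    6: ("B", "A", "A", "A"),
    7: ("A", "B", "B", "B"),
    8: ("B", "A", "B", "B"),
    9: ("A", "A", "A", "B"),
    10: ("A", "A", "B", "A"),
    11: ("B", "B", "A", "B"),
    12: ("B", "B", "B", "A"),
    13: ("A", "A", "A", "A"),
    14: ("A", "A", "B", "B"),
    15: ("B", "B", "A", "A"),
    16: ("B", "B", "B", "B"),
}

# Contiguous OPGP code block for each segregation type.
ST_BLOCKS: dict[SegregationType, tuple[int, ...]] = {
    SegregationType.BI: (1, 2, 3, 4),
    SegregationType.PI_A: (5, 6),
    SegregationType.PI_B: (7, 8),
    SegregationType.MI_A: (9, 10),
    SegregationType.MI_B: (11, 12),
    SegregationType.U: (13, 14, 15, 16),
}

_GENOTYPES = ("AA", "AB", "BB")


def opgp_alleles(code: int) -> tuple[str, str, str, str]:
    """Return the ordered allele quadruple (Z11, Z10, Z01, Z00) for an OPGP code."""
    try:
        return OPGP_TABLE[int(code)]
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid OPGP code: {code!r} (must be an integer 1..16)") from exc


def opgp_segregation_type(code: int) -> SegregationType:
    """Return the segregation type whose block contains the given OPGP code."""
    opgp_alleles(code)  # validate
    for st, block in ST_BLOCKS.items():
        if code in block:
            return st
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ParentalGenotypes:
    """Called parental genotypes at one locus with their read depths.

    A genotype is ``None`` (missing) whenever its parent's depth did not
    reach the calling threshold.
    """

    maternal: str | None
    paternal: str | None
    maternal_depth: int = 0
    paternal_depth: int = 0


def _normalise_genotype(g: str) -> str:
    g = g.upper()
    if g == "BA":
        g = "AB"
    if g not in _GENOTYPES:
        raise ValueError(f"invalid genotype {g!r}: expected one of {_GENOTYPES}")
    return g


def classify_segregation_type(
    parents: ParentalGenotypes | tuple[str, str],
) -> SegregationType:
    """Classify a locus's segregation type from the parental genotypes.

    Accepts a :class:`ParentalGenotypes` or a plain ``(maternal, paternal)``
    genotype pair.  Raises :class:`SegregationUndeterminableError` if either
    genotype is missing.
    """
    if isinstance(parents, ParentalGenotypes):
        mat, pat = parents.maternal, parents.paternal
    else:
        mat, pat = parents
    if mat is None or pat is None:
        raise SegregationUndeterminableError("missing parental genotype")
    mat = _normalise_genotype(mat)
    pat = _normalise_genotype(pat)
    mat_het = mat == "AB"
    pat_het = pat == "AB"
    if mat_het and pat_het:
        return SegregationType.BI
    if mat_het:
        return SegregationType.MI_A if pat == "AA" else SegregationType.MI_B
    if pat_het:
        return SegregationType.PI_A if mat == "AA" else SegregationType.PI_B
    return SegregationType.U


def call_genotype_from_counts(a: int, d: int, depth_threshold: int) -> str | None:
    """Call a parental genotype from (reference count, depth).

    Heterozygous iff both alleles are observed; homozygous otherwise.
    Returns ``None`` when ``d <= depth_threshold`` (insufficient depth).
    No error correction is attempted at this step.
    """
    if d <= depth_threshold:
        return None
    if a == d:
        return "AA"
    if a == 0:
        return "BB"
    return "AB"


def infer_segregation_types(
    parent_ref: np.ndarray,
    parent_depth: np.ndarray,
    depth_threshold: int = 5,
) -> list[SegregationType | None]:
    """Infer per-locus segregation types from parental read counts.

    Parameters
    ----------
    parent_ref, parent_depth
        Arrays of shape ``(2, M)``: row 0 the maternal parent, row 1 the
        paternal parent; reference-allele counts and total depths.
    depth_threshold
        Both parents must have depth strictly greater than this for the
        type to be called (default 5, i.e. depth > 5).

    Returns a list of length M with ``None`` marking loci where the type
    is undeterminable.
    """
    parent_ref = np.asarray(parent_ref)
    parent_depth = np.asarray(parent_depth)
    if parent_ref.shape != parent_depth.shape or parent_ref.shape[0] != 2:
        raise ValueError("parent count arrays must both have shape (2, M)")
    if depth_threshold < 1:
        raise ValueError("depth_threshold must be >= 1")
    out: list[SegregationType | None] = []
    for j in range(parent_ref.shape[1]):
        mat = call_genotype_from_counts(parent_ref[0, j], parent_depth[0, j], depth_threshold)
        pat = call_genotype_from_counts(parent_ref[1, j], parent_depth[1, j], depth_threshold)
        if mat is None or pat is None:
            out.append(None)
        else:
            out.append(classify_segregation_type((mat, pat)))
    return out


# Mendelian genotype frequencies (AA, AB, BB) among progeny for each
# informative segregation type.
_ST_GENO_FREQ: dict[SegregationType, tuple[float, float, float]] = {
    SegregationType.BI: (0.25, 0.5, 0.25),
    SegregationType.MI_A: (0.5, 0.5, 0.0),
    SegregationType.PI_A: (0.5, 0.5, 0.0),
    SegregationType.MI_B: (0.0, 0.5, 0.5),
    SegregationType.PI_B: (0.0, 0.5, 0.5),
}


def _call_category_probs(d: np.ndarray, epsilon: float) -> np.ndarray:
    """P(observed call category | true genotype, depth d, error rate ε).

    Categories are read-based calls: index 0 = all-reference reads
    ("AA-like"), 1 = both alleles seen ("AB-like"), 2 = all-alternate
    ("BB-like").  Returns an array of shape ``(len(d), 3 genotypes, 3
    categories)`` for genotypes ordered (AA, AB, BB).  Depths must be >= 1.
    """
    d = np.asarray(d, dtype=float)
    one = np.ones_like(d)
    p = np.empty((d.shape[0], 3, 3))
    # true AA: a ~ Binomial(d, 1-eps)
    p[:, 0, 0] = (1.0 - epsilon) ** d
    p[:, 0, 2] = epsilon**d
    p[:, 0, 1] = one - p[:, 0, 0] - p[:, 0, 2]
    # true AB: a ~ Binomial(d, 1/2)
    p[:, 1, 0] = 0.5**d
    p[:, 1, 2] = 0.5**d
    p[:, 1, 1] = one - p[:, 1, 0] - p[:, 1, 2]
    # true BB: mirror of AA
    p[:, 2, 0] = epsilon**d
    p[:, 2, 2] = (1.0 - epsilon) ** d
    p[:, 2, 1] = one - p[:, 2, 0] - p[:, 2, 2]
    return p


def segregation_test(
    ref: np.ndarray,
    depth: np.ndarray,
    st: SegregationType,
    epsilon: float = 0.0,
) -> float:
    """Depth-adjusted chi-square test of progeny segregation ratios.

    Each progeny with nonzero depth is assigned a read-based call
    category (all-reference, mixed, all-alternate).  The expected
    probability of each category for individual i is the mixture over
    true genotypes of the Mendelian frequencies under ``st`` and the
    binomial read-count model at depth ``d_i`` with per-read miscall
    probability ``epsilon``; this adjusts the classical segregation
    chi-square for allelic dropout at low depth.  Degrees of freedom
    equal the number of distinct Mendelian genotype classes under the
    segregation type minus one.

    Returns the p-value.  Raises ``ValueError`` for an uninformative
    type or if every depth is zero.
    """
    if st not in _ST_GENO_FREQ:
        raise ValueError(f"segregation test undefined for segregation type {st}")
    ref = np.asarray(ref)
    depth = np.asarray(depth)
    if np.any(ref > depth) or np.any(ref < 0) or np.any(depth < 0):
        raise ValueError("require 0 <= ref <= depth at every individual")
    mask = depth > 0
    if not mask.any():
        raise ValueError("segregation test undefined: all depths are zero")
    a, d = ref[mask], depth[mask]

    observed = np.array(
        [np.sum(a == d), np.sum((a > 0) & (a < d)), np.sum(a == 0)], dtype=float
    )
    geno_freq = np.asarray(_ST_GENO_FREQ[st])
    cat_probs = _call_category_probs(d, epsilon)  # (n, geno, cat)
    per_ind = np.einsum("g,ngc->nc", geno_freq, cat_probs)
    expected = per_ind.sum(axis=0)

    # Pearson goodness-of-fit over the call categories with positive
    # expectation; as depth grows the dropout categories vanish and the df
    # collapses to (number of Mendelian genotype classes under the ST) - 1
    nonzero = expected > 1e-12
    if np.any(observed[~nonzero] > 0):
        return 0.0  # observed calls in an impossible category
    df = max(int(nonzero.sum()) - 1, 1)
    stat = float(np.sum((observed[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]))
    return float(stats.chi2.sf(stat, df))
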