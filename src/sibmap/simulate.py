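"""Generative model for full-sib sequencing data, and the simulation studies.

Data are generated exactly as the map model assumes, in four stages:

1. *Inheritance*: each progeny's per-parent inheritance bit starts as a
   fair coin flip at locus 1 and thereafter flips between adjacent loci
   with the true per-interval recombination fraction, independently
   across meioses (no interference).
2. *Genotypes*: inheritance bits select alleles from each locus's OPGP
   quadruple and concatenate them into AA/AB/BB calls.
3. *Depths*: per-cell sequencing depths are negative binomial with mean
   μ_d and dispersion δ (variance μ + μ²/δ), sampled through the
   gamma-Poisson mixture; δ defaults to 2.
4. *Reads*: d alleles are sampled with replacement from the true
   genotype, then each sampled allele is miscalled with probability ε
   (a two-stage draw, so the mechanism — not just the marginal binomial
   distribution — matches the model's assumptions).

Two study designs are provided: a depth × error grid on a fixed
12-locus, 100-progeny family with r = 0.01 everywhere, and a
fixed-sequencing-effort design (individuals × loci × mean depth held at
10,000, ε = 0.002) that trades depth against family size to locate the
depth minimizing the summed mean squared error of the recombination
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import fit_map
from .hmm import OPGP_STATE_GENOTYPE, G_AA, G_AB, G_BB, ReadCountData
from .phasing import infer_opgps, phase_equal_mod_symmetry
from .segregation import OPGP_TABLE, SegregationType, opgp_segregation_type

__all__ = [
    "SimConfig",
    "STUDY_STS_12",
    "STUDY_OPGPS_12",
    "study_config",
    "simulate_inheritance",
    "genotypes_from_inheritance",
    "simulate_depths",
    "simulate_reads",
    "simulate_dataset",
    "run_simulation_study",
]


@dataclass
class SimConfig:
    """All generative parameters of the simulator.

    ``opgps`` holds one OPGP code sequence per family; ``n_progeny`` the
    matching family sizes.  ``mean_depth`` may be a scalar or a
    per-locus vector.  The seed is mandatory: every draw flows from it.
    """

    n_progeny: list
    opgps: list
    r_paternal: np.ndarray
    r_maternal: np.ndarray
    mean_depth: float | np.ndarray = 10.0
    dispersion: float = 2.0
    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.n_progeny):
            self.n_progeny = [int(self.n_progeny)]
        self.opgps = [np.asarray(o, dtype=int) for o in self.opgps]
        if len(self.opgps) != len(self.n_progeny):
            raise ValueError("need one OPGP sequence per family")
        m = len(self.opgps[0])
        self.r_paternal = np.broadcast_to(np.asarray(self.r_paternal, float), (m - 1,)).copy()
        self.r_maternal = np.broadcast_to(np.asarray(self.r_maternal, float), (m - 1,)).copy()
        if np.any(np.asarray(self.mean_depth) <= 0) or self.dispersion <= 0:
            raise ValueError("mean_depth and dispersion must be positive")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")

    @property
    def n_families(self) -> int:
        return len(self.n_progeny)

    @property
    def n_loci(self) -> int:
        return len(self.opgps[0])

    @property
    def n_total(self) -> int:
        return int(sum(self.n_progeny))

    @property
    def sts(self) -> list:
        return [[opgp_segregation_type(int(c)) for c in codes] for codes in self.opgps]


# ---------------------------------------------------------------------------
# The 12-locus study layout.
#
# SYNTHETIC default layout.  Mixes BI, PI, and MI types (3/4/5) and
# places a paternal-informative locus between two maternal-informative
# loci at positions 4-6, a configuration that stresses estimation and
# phasing across stretches where one parent is uninformative.  Override
# ``opgps`` in :func:`study_config` to use a different layout.
# ---------------------------------------------------------------------------
STUDY_STS_12 = (
    SegregationType.BI,
    SegregationType.PI_A,
    SegregationType.MI_A,
    SegregationType.MI_A,   # locus 4: MI
    SegregationType.PI_A,   # locus 5: PI between two MI
    SegregationType.MI_B,   # locus 6: MI
    SegregationType.BI,
    SegregationType.PI_B,
    SegregationType.MI_A,
    SegregationType.PI_A,
    SegregationType.BI,
    SegregationType.MI_B,
)

#: OPGP codes for the study layout; several loci are phase-flipped relative
#: to the block defaults so phase inference is exercised non-trivially.
STUDY_OPGPS_12 = (1, 5, 9, 10, 6, 11, 4, 7, 9, 5, 2, 12)


def study_config(
    mean_depth: float,
    epsilon: float,
    n_progeny: int = 100,
    seed: int = 0,
    r: float = 0.01,
    opgps=STUDY_OPGPS_12,
) -> SimConfig:
    """Config for the 12-locus single-family design (r = 0.01 in both parents)."""
    return SimConfig(
        n_progeny=[n_progeny],
        opgps=[np.asarray(opgps, dtype=int)],
        r_paternal=np.full(len(opgps) - 1, r),
        r_maternal=np.full(len(opgps) - 1, r),
        mean_depth=mean_depth,
        dispersion=2.0,
        epsilon=epsilon,
        seed=seed,
    )


def simulate_inheritance(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Inheritance bits, shape (N, M, 2) with the last axis (paternal, maternal).

    The first locus derives from either grandparental chromosome with
    equal probability; thereafter the bit flips between loci j and j+1
    with that interval's true recombination fraction, independently per
    meiosis (no interference).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_total, config.n_loci
    bits = np.empty((n, m, 2), dtype=np.int8)
    bits[:, 0, :] = rng.integers(0, 2, size=(n, 2))
    for j in range(1, m):
        flip_p = rng.random((n,)) < config.r_paternal[j - 1]
        flip_m = rng.random((n,)) < config.r_maternal[j - 1]
        bits[:, j, 0] = bits[:, j - 1, 0] ^ flip_p
        bits[:, j, 1] = bits[:, j - 1, 1] ^ flip_m
    return bits


def genotypes_from_inheritance(inheritance: np.ndarray, opgps, family_of=None) -> np.ndarray:
    """Convert inheritance bits to genotype codes through the OPGP quadruples."""
    inheritance = np.asarray(inheritance)
    n, m, _ = inheritance.shape
    opgps = [np.asarray(o, dtype=int) for o in opgps]
    if family_of is None:
        family_of = np.zeros(n, dtype=int)
    state = 2 * inheritance[:, :, 0].astype(np.intp) + inheritance[:, :, 1].astype(np.intp)
    G = np.empty((n, m), dtype=np.int64)
    for f, codes in enumerate(opgps):
        rows = np.nonzero(family_of == f)[0]
        G[rows] = OPGP_STATE_GENOTYPE[codes[None, :], state[rows]]
    return G


def simulate_depths(
    config: SimConfig, rng: np.random.Generator | None = None, shape=None
) -> np.ndarray:
    """Negative-binomial depths (mean μ_d, dispersion δ) via gamma-Poisson.

    A gamma(shape=δ, scale=μ/δ) rate mixed through a Poisson gives the
    negative binomial with the stated mean and variance μ + μ²/δ.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if shape is None:
        shape = (config.n_total, config.n_loci)
    mu = np.broadcast_to(np.asarray(config.mean_depth, float), shape)
    lam = rng.gamma(shape=config.dispersion, scale=mu / config.dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_reads(
    genotypes: np.ndarray,
    depths: np.ndarray,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Reference-allele read counts given true genotypes and depths.

    Two-stage draw per cell: d alleles are sampled with replacement from
    the true genotype (for AB, reference-true reads ~ Binomial(d, 1/2)),
    then each sampled allele is miscalled with probability ε.  The
    marginal distribution is Binomial(d, 1-ε), Binomial(d, 1/2), and
    Binomial(d, ε) for AA, AB, and BB respectively.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    G = np.asarray(genotypes)
    D = np.asarray(depths)
    true_ref = np.where(G == G_AA, D, np.where(G == G_BB, 0, rng.binomial(D, 0.5)))
    if epsilon == 0:
        return true_ref.astype(np.int64)
    kept = rng.binomial(true_ref, 1.0 - epsilon)  # reference reads not miscalled
    gained = rng.binomial(D - true_ref, epsilon)  # alternate reads miscalled as reference
    return (kept + gained).astype(np.int64)


def simulate_dataset(config: SimConfig, rng: np.random.Generator | None = None):
    """Simulate a complete dataset.

    Returns ``(data, truth)`` where ``data`` is a
    :class:`~sibmap.hmm.ReadCountData` (including exact parental counts at
    depth 2×μ̄, so the filtering pipeline can be exercised) and ``truth``
    a dict with the inheritance bits and true genotypes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    family_of = np.repeat(np.arange(config.n_families), config.n_progeny)
    inheritance = simulate_inheritance(config, rng)
    G = genotypes_from_inheritance(inheritance, config.opgps, family_of)
    D = simulate_depths(config, rng)
    Y = simulate_reads(G, D, config.epsilon, rng)

    # parents: genotypes fixed by the OPGPs; sequenced like the progeny
    # but at twice the mean depth (parents are typically run repeatedly)
    f2 = 2 * config.n_families
    parent_G = np.empty((f2, config.n_loci), dtype=np.int64)
    for f, codes in enumerate(config.opgps):
        for j, c in enumerate(codes):
            z11, z10, z01, z00 = OPGP_TABLE[int(c)]
            nb_pat = (z11 == "B") + (z10 == "B")
            nb_mat = (z01 == "B") + (z00 == "B")
            parent_G[2 * f, j] = (G_AA, G_AB, G_BB)[nb_mat]      # maternal parent row
            parent_G[2 * f + 1, j] = (G_AA, G_AB, G_BB)[nb_pat]  # paternal parent row
    mu_par = np.broadcast_to(
        2.0 * np.asarray(config.mean_depth, float), (f2, config.n_loci)
    )
    parent_D = rng.poisson(
        rng.gamma(shape=config.dispersion, scale=mu_par / config.dispersion)
    ).astype(np.int64)
    parent_Y = simulate_reads(parent_G, parent_D, config.epsilon, rng)

    loci = pd.DataFrame(
        {
            "id": [f"L{j+1}" for j in range(config.n_loci)],
            "chrom": "1",
            "pos": 1 + 1000 * np.arange(config.n_loci),
        }
    )
    samples = []
    for f in range(config.n_families):
        samples += [f"F{f+1}_mother", f"F{f+1}_father"]
    samples += [
        f"F{family_of[i]+1}_p{i+1}" for i in range(config.n_total)
    ]
    data = ReadCountData(
        Y=Y,
        D=D,
        family_of=family_of,
        loci=loci,
        samples=samples,
        parent_Y=parent_Y,
        parent_D=parent_D,
        sts=config.sts,
    )
    truth = {"inheritance": inheritance, "genotypes": G, "parent_genotypes": parent_G}
    return data, truth


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------

DEPTH_GRID = (2.0, 10.0, 20.0)
ERROR_GRID = (0.0, 0.002, 0.01)
FIXED_EFFORT = 10_000
FIXED_EFFORT_DEPTHS = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)
FIXED_EFFORT_EPSILON = 0.002


def _one_replicate(config: SimConfig, infer_phase: bool, fit_kw: dict) -> dict:
    data, _ = simulate_dataset(config)
    true_opgps = config.opgps[0]
    sts = config.sts[0]
    out: dict = {}
    phase_ascent = 0.0
    if infer_phase:
        phase = infer_opgps(data, sts)
        out["phase_correct"] = phase_equal_mod_symmetry(phase.opgps, true_opgps)
        opgps = phase.opgps
        phase_ascent = phase.min_ascent
    else:
        opgps = true_opgps
    fit = fit_map(data, [opgps], **fit_kw)
    fit_ascent = float(np.min(np.diff(fit.loglik_trace))) if fit.n_iter > 1 else 0.0
    out.update(
        r_hat=fit.params.r_paternal.copy(),
        epsilon_hat=fit.params.epsilon,
        total_cM=fit.total_cM,
        converged=fit.converged,
        loglik=fit.loglik,
        min_ascent=min(fit_ascent, phase_ascent),
    )
    return out


def run_simulation_study(
    design: str = "depth_by_error",
    replicates: int = 100,
    seed: int = 1,
    n_progeny: int = 100,
    infer_phase: bool | None = None,
    depths=None,
    errors=None,
    r: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one of the two simulation study designs.

    ``depth_by_error`` crosses mean depths {2, 10, 20} with error rates
    {0, 0.002, 0.01} on the 12-locus, 100-progeny family (phase inferred
    per replicate, then the map refitted with non-sex-specific r and ε
    estimated).  ``fixed_effort`` fixes ε = 0.002 and individuals ×
    loci × depth = 10,000, varies the mean depth, and fits with the
    true phase.

    Returns ``(summary, per_replicate)`` data frames.  Replicates failing
    to converge are recorded, not fatal.
    """
    fit_kw = dict(sex_specific=False, estimate_epsilon=True, model="sequencing")
    rows = []
    if design == "depth_by_error":
        depths = DEPTH_GRID if depths is None else depths
        errors = ERROR_GRID if errors is None else errors
        infer_phase = True if infer_phase is None else infer_phase
        scenarios = [
            {"mean_depth": mu, "epsilon": eps, "n_progeny": n_progeny}
            for mu in depths
            for eps in errors
        ]
    elif design == "fixed_effort":
        depths = FIXED_EFFORT_DEPTHS if depths is None else depths
        infer_phase = False if infer_phase is None else infer_phase
        m = len(STUDY_OPGPS_12)
        scenarios = [
            {
                "mean_depth": mu,
                "epsilon": FIXED_EFFORT_EPSILON,
                "n_progeny": int(round(FIXED_EFFORT / (m * mu))),
            }
            for mu in depths
        ]
    else:
        raise ValueError(f"unknown design {design!r}")

    for si, sc in enumerate(scenarios):
        for rep in range(replicates):
            rep_seed = int(
                np.random.SeedSequence([seed, si, rep]).generate_state(1)[0] % (2**31)
            )
            config = study_config(
                sc["mean_depth"], sc["epsilon"], n_progeny=sc["n_progeny"],
                seed=rep_seed, r=r,
            )
            res = _one_replicate(config, infer_phase, fit_kw)
            row = {**sc, "replicate": rep, "seed": rep_seed, **res}
            rows.append(row)

    per_rep = pd.DataFrame(rows)
    m1 = len(STUDY_OPGPS_12) - 1
    summaries = []
    for keys, grp in per_rep.groupby(["mean_depth", "epsilon", "n_progeny"]):
        r_mat = np.stack(grp["r_hat"].to_numpy())
        summ = {
            "mean_depth": keys[0],
            "epsilon": keys[1],
            "n_progeny": keys[2],
            "replicates": len(grp),
            "mean_total_cM": float(grp["total_cM"].mean()),
            "q025_total_cM": float(grp["total_cM"].quantile(0.025)),
            "q975_total_cM": float(grp["total_cM"].quantile(0.975)),
            "mean_epsilon_hat": float(grp["epsilon_hat"].mean()),
            "sum_mse_r": float(np.sum(np.mean((r_mat - r) ** 2, axis=0))),
            "n_converged": int(grp["converged"].sum()),
            "min_ascent": float(grp["min_ascent"].min()),
        }
        for j in range(m1):
            summ[f"mean_r_{j+1}"] = float(r_mat[:, j].mean())
            summ[f"se_r_{j+1}"] = float(r_mat[:, j].std(ddof=1) / np.sqrt(len(grp)))
        if "phase_correct" in grp:
            summ["pct_phase_correct"] = float(100.0 * grp["phase_correct"].mean())
        summaries.append(summ)
    return pd.DataFrame(summaries), per_rep
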