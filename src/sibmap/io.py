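"""Readers, writers, and the SNP filtering pipeline.

Read counts travel in two equivalent on-disk forms: a minimal VCF whose
per-sample AD field carries (reference, alternate) read counts, and a
set of tab-delimited matrices (reference counts, depths, locus and
sample metadata).  The model consumes counts, never GT calls, so GT
fields are ignored on input.

The filtering pipeline mirrors a typical genotyping-by-sequencing
workflow for a full-sib family: minor-allele-frequency and missingness
filters on the raw counts, segregation-type inference from parental
depths, a depth-adjusted segregation chi-square test, and binning of
nearby SNPs (one seeded-random representative per bin) so each read
contributes at most one variant.  Every removal is audited by rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import ReadCountData
from .segregation import infer_segregation_types, segregation_test, SegregationType

__all__ = [
    "FilterConfig",
    "read_counts",
    "write_vcf",
    "write_tables",
    "read_tables",
    "filter_loci",
]

logger = logging.getLogger("sibmap")


@dataclass
class FilterConfig:
    """Thresholds for the locus filtering pipeline.

    ``maf_min``: minimum minor allele frequency, computed from pooled
    progeny read fractions.  ``max_missing``: maximum tolerated fraction
    of progeny with zero depth.  ``parent_depth_threshold``: both
    parents need depth strictly above this for segregation-type
    inference.  ``seg_test_alpha``: significance level of the
    depth-adjusted segregation test.  ``bin_distance_bp``: adjacent SNPs
    closer than this are binned, one kept by seeded random selection.
    """

    maf_min: float = 0.05
    max_missing: float = 0.20
    parent_depth_threshold: int = 5
    seg_test_alpha: float = 0.05
    bin_distance_bp: int = 180
    bin_seed: int = 0
    seg_test_epsilon: float = 0.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "max_missing", "seg_test_alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.parent_depth_threshold < 0 or self.bin_distance_bp < 0:
            raise ValueError("thresholds must be non-negative")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_counts(path, format: str = "vcf_ad", parents=None, family_of=None) -> ReadCountData:
    """Read allele counts from disk.

    ``format='vcf_ad'`` reads a VCF whose per-sample AD field holds
    (reference, alternate) read counts; multiallelic records are skipped
    with a warning and a missing AD yields depth 0.  ``format='table'``
    reads the tab-delimited matrices written by :func:`write_tables`
    (``path`` is the prefix).

    ``parents`` optionally names per-family (maternal, paternal) sample
    ids; the named samples become parent rows, all others progeny.
    ``family_of`` maps progeny sample id -> family index (default: one
    family).
    """
    if format == "table":
        return read_tables(path)
    if format != "vcf_ad":
        raise ValueError(f"unknown format {format!r}")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss = [], [], []
    ref_cols, depth_cols = [], []
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s:%s (line %d)", var.CHROM, var.POS, i + 1
            )
            continue
        ad = var.format("AD")
        if ad is None:
            ref = np.zeros(len(samples), dtype=np.int64)
            dep = np.zeros(len(samples), dtype=np.int64)
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes missing as negative sentinels
            ref = ad[:, 0]
            dep = ad[:, :2].sum(axis=1)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ref_cols.append(ref)
        depth_cols.append(dep)
    vcf.close()
    if not ids:
        raise ValueError(f"no usable biallelic records in {path}")
    Y_all = np.stack(ref_cols, axis=1)
    D_all = np.stack(depth_cols, axis=1)
    loci = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss})
    return _split_parents(Y_all, D_all, samples, loci, parents, family_of)


def _split_parents(Y_all, D_all, samples, loci, parents, family_of) -> ReadCountData:
    if parents is None:
        return ReadCountData(
            Y=Y_all,
            D=D_all,
            family_of=np.zeros(len(samples), dtype=int),
            loci=loci,
            samples=samples,
        )
    parents = [tuple(p) for p in parents]
    parent_ids = [s for pair in parents for s in pair]
    missing = [s for s in parent_ids if s not in samples]
    if missing:
        raise ValueError(f"parent sample(s) not in file: {missing}")
    prog_idx = [i for i, s in enumerate(samples) if s not in parent_ids]
    par_idx = [samples.index(s) for s in parent_ids]
    prog_samples = [samples[i] for i in prog_idx]
    if family_of is None:
        fam = np.zeros(len(prog_idx), dtype=int)
    else:
        fam = np.array([family_of[s] for s in prog_samples], dtype=int)
    return ReadCountData(
        Y=Y_all[prog_idx],
        D=D_all[prog_idx],
        family_of=fam,
        loci=loci,
        samples=prog_samples,
        parent_Y=Y_all[par_idx],
        parent_D=D_all[par_idx],
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=sibmap
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt) from read counts">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (not called)">
"""


def write_vcf(data: ReadCountData, path) -> None:
    """Write counts as a minimal VCF with per-sample AD fields.

    Parent columns (when present) come first, named by sample metadata.
    Alleles are written as placeholder bases A (reference) / C (alternate):
    the model is allele-label agnostic.
    """
    loci = data.loci
    if loci is None:
        loci = pd.DataFrame(
            {
                "id": [f"L{j+1}" for j in range(data.n_loci)],
                "chrom": "1",
                "pos": 1 + np.arange(data.n_loci),
            }
        )
    n_par = 0 if data.parent_Y is None else data.parent_Y.shape[0]
    if data.samples is not None and len(data.samples) == n_par + data.n_individuals:
        names = list(data.samples)
        par_names, prog_names = names[:n_par], names[n_par:]
    else:
        par_names = [f"parent{i+1}" for i in range(n_par)]
        prog_names = (
            list(data.samples)
            if data.samples is not None and len(data.samples) == data.n_individuals
            else [f"progeny{i+1}" for i in range(data.n_individuals)]
        )
    cols = par_names + prog_names
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cols) + "\n")
        for j in range(data.n_loci):
            fields = [
                str(loci["chrom"].iloc[j]),
                str(int(loci["pos"].iloc[j])),
                str(loci["id"].iloc[j]),
                "A",
                "C",
                ".",
                "PASS",
                ".",
                "GT:AD",
            ]
            for arrs in ((data.parent_Y, data.parent_D), (data.Y, data.D)):
                ys, ds = arrs
                if ys is None:
                    continue
                for i in range(ys.shape[0]):
                    a, d = int(ys[i, j]), int(ds[i, j])
                    fields.append(f"./.:{a},{d - a}")
            fh.write("\t".join(fields) + "\n")


def write_tables(data: ReadCountData, prefix) -> None:
    """Write paired tab-delimited matrices plus locus/sample metadata.

    Produces ``<prefix>.ref.tsv``, ``<prefix>.depth.tsv`` (rows: samples,
    parents first; columns: locus ids), ``<prefix>.loci.tsv`` and
    ``<prefix>.samples.tsv``.
    """
    prefix = str(prefix)
    loci = data.loci if data.loci is not None else pd.DataFrame(
        {"id": [f"L{j+1}" for j in range(data.n_loci)], "chrom": "1",
         "pos": 1 + np.arange(data.n_loci)}
    )
    n_par = 0 if data.parent_Y is None else data.parent_Y.shape[0]
    if data.samples is not None and len(data.samples) == n_par + data.n_individuals:
        names = list(data.samples)
    else:
        names = [f"parent{i+1}" for i in range(n_par)] + [
            f"progeny{i+1}" for i in range(data.n_individuals)
        ]
    roles, fams = [], []
    for f in range(n_par // 2):
        roles += ["mother", "father"]
        fams += [f, f]
    roles += ["progeny"] * data.n_individuals
    fams += list(data.family_of)
    Y = np.vstack([data.parent_Y, data.Y]) if n_par else data.Y
    D = np.vstack([data.parent_D, data.D]) if n_par else data.D
    pd.DataFrame(Y, index=names, columns=loci["id"]).to_csv(
        prefix + ".ref.tsv", sep="\t", index_label="sample"
    )
    pd.DataFrame(D, index=names, columns=loci["id"]).to_csv(
        prefix + ".depth.tsv", sep="\t", index_label="sample"
    )
    loci.to_csv(prefix + ".loci.tsv", sep="\t", index=False)
    pd.DataFrame({"id": names, "family": fams, "role": roles}).to_csv(
        prefix + ".samples.tsv", sep="\t", index=False
    )


def read_tables(prefix) -> ReadCountData:
    """Read the matrices written by :func:`write_tables`."""
    prefix = str(prefix)
    ref = pd.read_csv(prefix + ".ref.tsv", sep="\t", index_col="sample")
    dep = pd.read_csv(prefix + ".depth.tsv", sep="\t", index_col="sample")
    loci = pd.read_csv(prefix + ".loci.tsv", sep="\t", dtype={"chrom": str})
    samp = pd.read_csv(prefix + ".samples.tsv", sep="\t")
    if not ref.index.equals(dep.index) or ref.shape != dep.shape:
        raise ValueError("ref and depth tables disagree")
    is_parent = samp["role"].isin(["mother", "father"]).to_numpy()
    par = samp[is_parent].sort_values(["family", "role"])  # mother before father
    prog = samp[~is_parent]
    kwargs = {}
    if len(par):
        order = []
        for f in sorted(par["family"].unique()):
            fam = par[par["family"] == f]
            order.append(fam[fam["role"] == "mother"]["id"].iloc[0])
            order.append(fam[fam["role"] == "father"]["id"].iloc[0])
        kwargs = dict(
            parent_Y=ref.loc[order].to_numpy(dtype=np.int64),
            parent_D=dep.loc[order].to_numpy(dtype=np.int64),
        )
    return ReadCountData(
        Y=ref.loc[prog["id"]].to_numpy(dtype=np.int64),
        D=dep.loc[prog["id"]].to_numpy(dtype=np.int64),
        family_of=prog["family"].to_numpy(dtype=np.int64),
        loci=loci,
        samples=list(par["id"]) + list(prog["id"]) if len(par) else list(prog["id"]),
        sts=None,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Filtering pipeline
# ---------------------------------------------------------------------------

def filter_loci(data: ReadCountData, cfg: FilterConfig) -> tuple[ReadCountData, pd.DataFrame]:
    """Apply the locus filtering pipeline; returns (filtered data, audit).

    Rules, applied in order: minor allele frequency (from pooled progeny
    read fractions), missingness (fraction of progeny with depth 0),
    segregation-type inference from parental counts (loci with an
    undeterminable type dropped), the depth-adjusted segregation
    chi-square test, and distance binning with a seeded random
    representative.  The audit records, per input locus, whether it was
    kept and which rule removed it.
    """
    m = data.n_loci
    status = np.array(["kept"] * m, dtype=object)
    alive = np.ones(m, dtype=bool)

    with np.errstate(invalid="ignore"):
        tot_ref = data.Y.sum(axis=0).astype(float)
        tot_dep = data.D.sum(axis=0).astype(float)
        frac = np.divide(tot_ref, tot_dep, out=np.full(m, np.nan), where=tot_dep > 0)
    maf = np.fmin(frac, 1.0 - frac)
    bad = alive & (np.isnan(maf) | (maf < cfg.maf_min))
    status[bad] = "maf"
    alive &= ~bad

    miss = (data.D == 0).mean(axis=0)
    bad = alive & (miss >= cfg.max_missing)
    status[bad] = "missing"
    alive &= ~bad

    sts_per_family: list[list] = []
    if data.parent_Y is not None:
        n_fam = data.parent_Y.shape[0] // 2
        for f in range(n_fam):
            sts_per_family.append(
                infer_segregation_types(
                    data.parent_Y[2 * f : 2 * f + 2],
                    data.parent_D[2 * f : 2 * f + 2],
                    cfg.parent_depth_threshold,
                )
            )
        undet = np.array(
            [any(sts[j] is None for sts in sts_per_family) for j in range(m)]
        )
        bad = alive & undet
        status[bad] = "st_undeterminable"
        alive &= ~bad

        for j in np.nonzero(alive)[0]:
            for f, sts in enumerate(sts_per_family):
                st = sts[j]
                if st is None or st is SegregationType.U:
                    continue
                rows = data.family_of == f
                p = segregation_test(
                    data.Y[rows, j], data.D[rows, j], st, cfg.seg_test_epsilon
                )
                if p < cfg.seg_test_alpha:
                    status[j] = "segregation"
                    alive[j] = False
                    break

    if data.loci is not None and alive.any():
        rng = np.random.default_rng(cfg.bin_seed)
        idx = np.nonzero(alive)[0]
        chrom = data.loci["chrom"].to_numpy()
        pos = data.loci["pos"].to_numpy()
        order = idx[np.lexsort((pos[idx], chrom[idx].astype(str)))]
        bins: list[list[int]] = []
        for j in order:
            if (
                bins
                and chrom[bins[-1][-1]] == chrom[j]
                and abs(int(pos[j]) - int(pos[bins[-1][-1]])) < cfg.bin_distance_bp
            ):
                bins[-1].append(int(j))
            else:
                bins.append([int(j)])
        for b in bins:
            if len(b) > 1:
                keep = b[rng.integers(0, len(b))]
                for j in b:
                    if j != keep:
                        status[j] = "binned"
                        alive[j] = False

    audit = pd.DataFrame(
        {
            "locus": data.loci["id"] if data.loci is not None else np.arange(m),
            "kept": alive,
            "rule": status,
        }
    )
    kept_idx = np.nonzero(alive)[0]
    out = data.subset_loci(kept_idx)
    if sts_per_family:
        out.sts = [[sts[j] for j in kept_idx] for sts in sts_per_family]
    n_removed = {r: int((status == r).sum()) for r in pd.unique(status) if r != "kept"}
    logger.info("filter_loci: %d -> %d loci (removed %s)", m, len(kept_idx), n_removed)
    return out, audit
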