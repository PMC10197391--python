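"""SNP genotype handling and population-genetic statistics.

Covers the genetic side of the pipeline: reading diploid biallelic genotypes
from VCF, quality/MAF/call-rate filtering, per-population diversity (observed
and expected heterozygosity, SNP-site nucleotide diversity, FIS), a pooled
Hardy-Weinberg chi-square check of Ho against He, pairwise Weir & Cockerham
(1984) FST, and Pearson correlations of diversity with environmental values.

Genotypes are carried as an individuals x loci matrix of alternate-allele
dosages in {0, 1, 2} with -1 for missing calls. All statistics use
pairwise-complete calls per locus; within a population, a locus with fewer
than two called gene copies is skipped for that population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PairwiseMatrix

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "FstComponents",
    "read_vcf",
    "write_vcf",
    "filter_snps",
    "population_diversity",
    "ho_he_chi2",
    "wc_fst_pair",
    "fst_matrix",
    "diversity_env_correlation",
]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes: individuals x loci dosage codes.

    ``dosage[i, l]`` is the count of alternate alleles (0/1/2) for individual
    ``i`` at locus ``l``, or -1 for a missing call. ``loci`` holds per-locus
    metadata (chrom, pos, qual, ref, alt).
    """

    individuals: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    attrition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individuals = [str(x) for x in self.individuals]
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids are not unique")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.individuals)}, {len(self.loci)})"
            )
        if not np.isin(self.dosage, [MISSING, 0, 1, 2]).all():
            raise ValueError("dosage codes must be in {-1, 0, 1, 2}")
        if (self.loci["pos"] <= 0).any():
            raise ValueError("locus positions must be positive (1-based)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=self.loci.loc[keep].reset_index(drop=True),
            dosage=self.dosage[:, np.asarray(keep)],
        )

    def pop_indices(self, pop_assignment) -> dict[str, np.ndarray]:
        """Map population id -> row indices, validating the assignment.

        ``pop_assignment`` maps individual id to population id (dict or
        pandas Series). Every individual must be assigned exactly once.
        """
        assign = dict(pop_assignment.items() if hasattr(pop_assignment, "items")
                      else pop_assignment)
        missing = [i for i in self.individuals if i not in assign]
        if missing:
            raise ValueError(f"individuals without population assignment: {missing[:5]}")
        out: dict[str, list[int]] = {}
        for row, ind in enumerate(self.individuals):
            out.setdefault(str(assign[ind]), []).append(row)
        return {p: np.asarray(rows, dtype=int) for p, rows in out.items()}


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid biallelic genotypes from a VCF via cyvcf2.

    Multi-allelic records are dropped (counted); half-calls become missing
    (counted). Raises if no loci are retained.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    individuals = list(vcf.samples)
    if not individuals:
        raise ValueError(f"{path}: VCF has no samples")
    chroms, poss, quals, refs, alts = [], [], [], [], []
    rows = []
    n_multiallelic = 0
    n_halfcalls = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        g = np.array([gt[:2] for gt in v.genotypes], dtype=int)
        if g.shape[1] != 2:
            raise ValueError(f"{path}: non-diploid genotype at {v.CHROM}:{v.POS}")
        half = (g < 0).sum(axis=1) == 1
        n_halfcalls += int(half.sum())
        dos = g.sum(axis=1)
        dos[(g < 0).any(axis=1)] = MISSING
        rows.append(dos.astype(np.int8))
        chroms.append(v.CHROM)
        poss.append(v.POS)
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()
    if not rows:
        raise ValueError(
            f"{path}: zero biallelic loci retained ({n_multiallelic} multi-allelic dropped)"
        )
    if n_multiallelic or n_halfcalls:
        logger.info(
            "read_vcf: dropped %d multi-allelic records; %d half-calls set missing",
            n_multiallelic, n_halfcalls,
        )
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "qual": quals, "ref": refs, "alt": alts}
    )
    gm = GenotypeMatrix(
        individuals=individuals, loci=loci, dosage=np.stack(rows, axis=1)
    )
    gm.attrition = {"multiallelic_dropped": n_multiallelic, "half_calls": n_halfcalls}
    return gm


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal valid VCF 4.2 (GT only, QUAL populated)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals) + "\n"
        )
        for l in range(gm.n_loci):
            rec = gm.loci.iloc[l]
            gts = "\t".join(_GT[int(d)] for d in gm.dosage[:, l])
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{rec['alt']}\t"
                f"{rec['qual']:.2f}\tPASS\t.\tGT\t{gts}\n"
            )


def filter_snps(
    gm: GenotypeMatrix,
    min_qual: float = 30.0,
    min_maf: float = 0.01,
    min_call_rate: float = 0.7,
) -> GenotypeMatrix:
    """Apply site QUAL, minor-allele-frequency and call-rate filters.

    Mirrors the common VCFtools invocation (minQ 30, maf 0.01,
    max-missing 0.7, where "max-missing 0.7" is the *minimum* proportion of
    called genotypes). MAF is computed on non-missing calls. The returned
    matrix carries per-filter attrition counts in ``.attrition``.
    """
    qual = gm.loci["qual"].to_numpy(dtype=float)
    called = gm.called()
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(
            n_called > 0,
            np.where(called, gm.dosage, 0).sum(axis=0) / (2.0 * np.maximum(n_called, 1)),
            np.nan,
        )
        maf = np.minimum(p, 1.0 - p)
        call_rate = n_called / gm.n_individuals
    pass_qual = qual >= min_qual
    pass_maf = maf >= min_maf
    pass_rate = call_rate >= min_call_rate
    keep = pass_qual & pass_maf & pass_rate
    attrition = {
        "input_loci": gm.n_loci,
        "fail_qual": int((~pass_qual).sum()),
        "fail_maf": int((~pass_maf).sum()),
        "fail_call_rate": int((~pass_rate).sum()),
        "retained": int(keep.sum()),
    }
    logger.info("filter_snps: %s", attrition)
    if not keep.any():
        raise ValueError(f"all loci removed by filters: {attrition}")
    out = gm.subset_loci(keep)
    out.attrition = attrition
    return out


def _per_locus_stats(sub: np.ndarray):
    """Per-locus (n_called, alt-allele freq, het fraction) for one population."""
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    het = ((sub == 1) & called).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def population_diversity(gm: GenotypeMatrix, pop_assignment) -> pd.DataFrame:
    """Per-population Ho, He, pi (SNP sites), FIS and sample size.

    Per locus within a population: Ho = heterozygous / called genotypes;
    He = (n_g/(n_g-1)) (1 - p^2 - q^2) with n_g called gene copies (the
    unbiased small-sample estimator). pi is the same per-site unbiased
    heterozygosity, reported separately for interface parity (at SNP sites
    only, so it is *not* comparable to pi over full RAD loci).
    FIS = 1 - mean(Ho)/mean(He) (ratio of multilocus means); NaN-flagged
    where mean He is zero. Loci with <2 called gene copies are skipped.
    """
    groups = gm.pop_indices(pop_assignment)
    rows = []
    for pop, idx in groups.items():
        sub = gm.dosage[idx]
        n, p, h = _per_locus_stats(sub)
        use = n >= 1                       # >=1 genotype = >=2 gene copies
        if not use.any():
            logger.warning("population %s has no called genotypes at any locus", pop)
            rows.append({"pop_id": pop, "Ho": np.nan, "He": np.nan, "pi": np.nan,
                         "Fis": np.nan, "n_individuals": len(idx), "n_loci_used": 0})
            continue
        ng = 2.0 * n[use]
        ho = float(np.mean(h[use]))
        he_l = (ng / (ng - 1.0)) * (1.0 - p[use] ** 2 - (1.0 - p[use]) ** 2)
        he = float(np.mean(he_l))
        fis = 1.0 - ho / he if he > 0 else np.nan
        rows.append({
            "pop_id": pop, "Ho": ho, "He": he, "pi": he, "Fis": fis,
            "n_individuals": len(idx), "n_loci_used": int(use.sum()),
        })
    df = pd.DataFrame(rows).set_index("pop_id")
    bad = df[(df["Ho"] > 1) | (df["Ho"] < 0) | (df["He"] > 1) | (df["He"] < 0)]
    assert bad.empty, "heterozygosity out of [0,1] — internal error"
    return df


def ho_he_chi2(gm: GenotypeMatrix, pop_assignment) -> pd.DataFrame:
    """Pooled Hardy-Weinberg check of observed vs expected heterozygotes.

    Within each population, genotype calls are pooled over loci: the observed
    heterozygote count is compared with the Hardy-Weinberg expectation
    sum_l 2 p_l q_l n_l * 2n_l/(2n_l - 1) on the two-cell het/hom partition
    (1 df). The 2n/(2n-1) factor is Levene's small-sample correction: with
    p estimated from the same sample, the uncorrected 2pq n expectation is
    biased low and the pooled test rejects far too often. Populations where
    an expected cell is zero are flagged (NaN) rather than tested.
    """
    groups = gm.pop_indices(pop_assignment)
    rows = []
    for pop, idx in groups.items():
        sub = gm.dosage[idx]
        n, p, h = _per_locus_stats(sub)
        use = n >= 1
        n_tot = float(n[use].sum())
        obs_het = float(((sub == 1).sum(axis=0))[use].sum())
        nn = n[use].astype(float)
        levene = 2.0 * nn / np.maximum(2.0 * nn - 1.0, 1.0)
        exp_het = float((2.0 * p[use] * (1.0 - p[use]) * nn * levene).sum())
        if n_tot == 0 or exp_het <= 0 or (n_tot - exp_het) <= 0:
            rows.append({"pop_id": pop, "chi2": np.nan, "p": np.nan,
                         "obs_het": obs_het, "exp_het": exp_het, "flag": "degenerate"})
            continue
        chi2 = (obs_het - exp_het) ** 2 / exp_het + (
            (n_tot - obs_het) - (n_tot - exp_het)
        ) ** 2 / (n_tot - exp_het)
        rows.append({"pop_id": pop, "chi2": chi2,
                     "p": float(stats.chi2.sf(chi2, df=1)),
                     "obs_het": obs_het, "exp_het": exp_het, "flag": ""})
    return pd.DataFrame(rows).set_index("pop_id")


@dataclass
class FstComponents:
    """Per-locus Weir & Cockerham variance components and aggregate theta.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals. ``theta_weighted`` is the ratio
    estimator sum(a)/sum(a+b+c); ``theta_mean`` averages per-locus ratios over
    loci whose denominator is positive. Both are clamped to [-1, 1] against
    numerical noise.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    valid: np.ndarray
    theta_weighted: float
    theta_mean: float


def _wc_components(subA: np.ndarray, subB: np.ndarray):
    """Vectorized two-population Weir & Cockerham (1984) a, b, c per locus."""
    n1, p1, h1 = _per_locus_stats(subA)
    n2, p2, h2 = _per_locus_stats(subB)
    valid = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) > 2)
    n1 = n1.astype(float); n2 = n2.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1 ** 2 + n2 ** 2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c, valid


def wc_fst_pair(gm: GenotypeMatrix, pop_assignment, popA: str, popB: str) -> FstComponents:
    """Two-population Weir & Cockerham FST with per-locus components."""
    groups = gm.pop_indices(pop_assignment)
    for p in (popA, popB):
        if p not in groups:
            raise KeyError(f"unknown population {p!r}")
    a, b, c, valid = _wc_components(gm.dosage[groups[popA]], gm.dosage[groups[popB]])
    if not valid.any():
        raise ValueError(f"no shared informative loci between {popA} and {popB}")
    av, bv, cv = a[valid], b[valid], c[valid]
    denom = (av + bv + cv).sum()
    if denom == 0:
        raise ValueError(f"zero total variance between {popA} and {popB}")
    theta_w = float(np.clip(av.sum() / denom, -1.0, 1.0))
    per = av + bv + cv
    informative = per > 0
    theta_m = (
        float(np.clip(np.mean(av[informative] / per[informative]), -1.0, 1.0))
        if informative.any() else np.nan
    )
    return FstComponents(a=a, b=b, c=c, valid=valid,
                         theta_weighted=theta_w, theta_mean=theta_m)


def fst_matrix(
    gm: GenotypeMatrix, pop_assignment, statistic: str = "weighted"
) -> PairwiseMatrix:
    """Pairwise FST over all populations as a labeled symmetric matrix.

    Negative estimates (common for weakly differentiated pairs under the
    unbiased estimator) are retained, not clamped; the matrix flags them via
    ``has_negatives``.
    """
    if statistic not in {"weighted", "mean"}:
        raise ValueError("statistic must be 'weighted' or 'mean'")
    groups = gm.pop_indices(pop_assignment)
    pops = list(groups)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    vals = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            comp = wc_fst_pair(gm, pop_assignment, pops[i], pops[j])
            theta = comp.theta_weighted if statistic == "weighted" else comp.theta_mean
            vals[i, j] = vals[j, i] = theta
    pm = PairwiseMatrix(labels=pops, values=vals, kind="genetic")
    if pm.has_negatives:
        logger.info("fst_matrix: %d negative pairwise estimates retained",
                    int((pm.condensed() < 0).sum()))
    return pm


def diversity_env_correlation(
    diversity: pd.DataFrame, env_table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each diversity statistic with each env variable.

    Returns rows (statistic, variable, r, t, p) with t = |r| sqrt(df/(1-r^2)),
    df = n - 2, and a two-sided p from the t distribution. Zero-variance
    inputs are flagged with NaN.
    """
    stats_cols = [c for c in ("Ho", "He", "pi", "Fis") if c in diversity.columns]
    common = [p for p in diversity.index if p in env_table.index]
    if len(common) < 3:
        raise ValueError("need at least 3 populations shared with env table")
    div = diversity.loc[common]
    env = env_table.loc[common]
    rows = []
    df_resid = len(common) - 2
    for sc in stats_cols:
        y = div[sc].to_numpy(dtype=float)
        for var in env.columns:
            x = env[var].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append({"statistic": sc, "variable": var,
                             "r": np.nan, "t": np.nan, "p": np.nan,
                             "flag": "degenerate"})
                continue
            dfr = int(ok.sum()) - 2
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            if abs(r) >= 1.0:
                t = np.inf
                pval = 0.0
            else:
                t = abs(r) * np.sqrt(dfr / (1.0 - r ** 2))
                pval = 2.0 * float(stats.t.sf(t, df=dfr))
            rows.append({"statistic": sc, "variable": var, "r": r, "t": t,
                         "p": pval, "flag": ""})
    return pd.DataFrame(rows)
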