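"""No-replicate RNA-Seq differential expression.

The design is three single libraries (Wild Type, Pretumor, Tumor).  The
computation: FPKM filter on the reference sample, upper-quartile
between-sample normalization, a per-gene Fisher exact test of the gene's
count against the rest of the library between two samples, Storey
q-values for FDR, and direction grouping with a log2 fold-change heat
matrix for export.

Fisher's exact test on counts from overdispersed libraries is
anticonservative; with no replicates there is no way around that, and
the calibration guarantees here are stated for Poisson counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate


@dataclass
class CountMatrix:
    """Raw gene-level counts (genes x samples) with gene lengths."""

    gene_ids: list[str]
    gene_lengths_bp: list[int]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_lengths_bp) != n_genes:
            raise ValueError("gene ids/lengths inconsistent with count matrix")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample ids inconsistent with count matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if any(l <= 0 for l in self.gene_lengths_bp):
            raise ValueError("gene lengths must be positive")

    @property
    def library_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not found") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.sample_ids)
        df.insert(0, "length_bp", self.gene_lengths_bp)
        df.insert(0, "gene_id", self.gene_ids)
        return df


def write_count_matrix(m: CountMatrix, path: str | os.PathLike) -> None:
    m.to_frame().to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | os.PathLike) -> CountMatrix:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "length_bp"]:
        raise ValueError("count table must start with gene_id and length_bp columns")
    samples = list(df.columns[2:])
    return CountMatrix(
        gene_ids=df["gene_id"].astype(str).tolist(),
        gene_lengths_bp=df["length_bp"].astype(int).tolist(),
        sample_ids=samples,
        counts=df[samples].to_numpy(dtype=np.int64),
    )


@dataclass
class NormalizationFactors:
    """Per-sample upper-quartile values and mean-centered scale factors."""

    sample_ids: list[str]
    upper_quartile: np.ndarray
    scale_factor: np.ndarray

    def factor(self, sample_id: str) -> float:
        return float(self.scale_factor[self.sample_ids.index(sample_id)])


@dataclass
class DGEResult:
    gene_id: str
    contrast: str
    fold_change: float
    log2fc: float
    p: float
    q: float = float("nan")


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------


def compute_fpkm(m: CountMatrix) -> pd.DataFrame:
    """FPKM per gene and sample: count / (length_kb x million fragments)."""
    totals = m.library_totals
    if (totals <= 0).any():
        raise ValueError("library totals must be > 0")
    lengths_kb = np.asarray(m.gene_lengths_bp, dtype=float) / 1000.0
    millions = totals.astype(float) / 1e6
    fpkm = m.counts / (lengths_kb[:, None] * millions[None, :])
    return pd.DataFrame(fpkm, index=m.gene_ids, columns=m.sample_ids)


def fpkm_filter(m: CountMatrix, sample_id: str, threshold: float = 1.0) -> list[str]:
    """Genes with FPKM >= threshold in the named sample (the published
    analysis gated on the Wild Type retina)."""
    fpkm = compute_fpkm(m)
    col = fpkm[sample_id] if sample_id in fpkm.columns else None
    if col is None:
        raise KeyError(f"sample {sample_id!r} not found")
    return list(fpkm.index[col >= threshold])


# ---------------------------------------------------------------------------
# Upper-quartile normalization
# ---------------------------------------------------------------------------


def upper_quartile_factors(
    m: CountMatrix | np.ndarray, sample_ids: list[str] | None = None
) -> NormalizationFactors:
    """Between-sample scaling by the 75th percentile of non-all-zero genes.

    Scale factors are geometric-mean centered (factor_s = geomean(UQ)/UQ_s)
    so normalized counts stay on the count scale and the average rescaled
    library is unchanged.  Accepts a plain (possibly non-integer) array so
    already-normalized matrices can be re-examined.
    """
    if isinstance(m, CountMatrix):
        counts = m.counts
        sample_ids = list(m.sample_ids)
    else:
        counts = np.asarray(m, dtype=float)
        if sample_ids is None:
            sample_ids = [f"sample_{j + 1}" for j in range(counts.shape[1])]
    keep = counts.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("no gene has a nonzero count in any sample")
    uq = np.percentile(counts[keep], 75, axis=0)
    for sid, val in zip(sample_ids, uq):
        if val <= 0:
            raise ValueError(f"upper quartile is 0 for sample {sid!r}")
    geo = float(np.exp(np.mean(np.log(uq))))
    return NormalizationFactors(
        sample_ids=sample_ids,
        upper_quartile=uq,
        scale_factor=geo / uq,
    )


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

_TIE_REL = 1 + 1e-7  # tie tolerance for the point-probability rule


def _hypergeom_pmf(x: np.ndarray, n: int, row1: int, col1: int) -> np.ndarray:
    """Hypergeometric pmf over the support, via log-gamma (vectorized;
    avoids per-call distribution-object overhead at large margins)."""
    from scipy.special import gammaln

    def lchoose(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    logp = lchoose(row1, x) + lchoose(n - row1, col1 - x) - lchoose(n, col1)
    return np.exp(logp)


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int, *, rule: str = "point_probability"
) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    ``point_probability`` (default): sum of hypergeometric probabilities
    of all tables with the same margins whose probability does not exceed
    the observed table's (the dominant convention).  ``doubling``: twice
    the smaller one-sided tail, capped at 1.  Degenerate margins give 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    if lo == hi:
        return 1.0
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    if rule == "point_probability":
        p = float(pmf[pmf <= p_obs * _TIE_REL].sum())
    elif rule == "doubling":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Per-gene contrast
# ---------------------------------------------------------------------------


def dge_contrast(
    m: CountMatrix,
    factors: NormalizationFactors,
    sample_a: str,
    sample_b: str,
    *,
    gene_set: list[str] | None = None,
    pseudocount: float = 1.0,
) -> list[DGEResult]:
    """Fisher exact test and fold change per gene, A -> B.

    Normalization is applied before testing, in the published order: each
    gene's upper-quartile-rescaled count is compared against the
    rest-of-library on a *common effective library size* (the mean of the
    normalized totals), so the test asks whether the gene's normalized
    expression differs rather than whether library composition shifted.
    The fold change is the ratio of pseudocounted normalized counts,
    ((count_B + pc) * scale_B) / ((count_A + pc) * scale_A); the
    pseudocount never enters the test.
    """
    ia, ib = m.sample_index(sample_a), m.sample_index(sample_b)
    totals = m.library_totals
    sa, sb = factors.factor(sample_a), factors.factor(sample_b)
    eff_total = int(round((totals[ia] * sa + totals[ib] * sb) / 2))
    contrast = f"{sample_a}->{sample_b}"
    genes = gene_set if gene_set is not None else list(m.gene_ids)
    index = {g: i for i, g in enumerate(m.gene_ids)}
    results = []
    for gid in genes:
        gi = index[gid]
        ca = int(m.counts[gi, ia])
        cb = int(m.counts[gi, ib])
        na = int(round(ca * sa))
        nb = int(round(cb * sb))
        p = fisher_exact_two_sided(na, eff_total - na, nb, eff_total - nb)
        fc = ((cb + pseudocount) * sb) / ((ca + pseudocount) * sa)
        results.append(DGEResult(gid, contrast, fc, float(np.log2(fc)), p))
    return results


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def _storey_pi0(p: np.ndarray) -> float:
    """Storey pi0: lambda grid 0.05..0.95, cubic smoother, extrapolate to
    the grid maximum, clip to (0, 1]."""
    m = len(p)
    lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    spline = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def estimate_qvalues(pvalues, method: str = "storey") -> np.ndarray:
    """q-values from p-values; ``storey`` (default) or plain BH.

    q_i = pi0 * min over {j: p_j >= p_i} of p_j * m / rank(p_j); BH is the
    same with pi0 = 1 (the textbook step-up).  For fewer than 100 tests
    the smoother behind Storey's pi0 is unstable and BH is used instead.
    Output order matches input; q is nondecreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    if method not in ("storey", "bh"):
        raise ValueError(f"unknown method {method!r}")
    m = p.size
    pi0 = _storey_pi0(p) if method == "storey" and m >= 100 else 1.0
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(pi0 * q_sorted, 1.0)
    return q


def attach_qvalues(results: list[DGEResult], method: str = "storey") -> list[DGEResult]:
    q = estimate_qvalues([r.p for r in results], method=method)
    for r, qi in zip(results, q):
        r.q = float(qi)
    return results


# ---------------------------------------------------------------------------
# Direction grouping + heat matrix
# ---------------------------------------------------------------------------

GROUPS = (
    "Increased in Pretumor",
    "Decreased in Pretumor",
    "Increased in Tumor",
    "Decreased in Tumor",
)


def group_by_direction(
    pretumor_results: list[DGEResult],
    tumor_results: list[DGEResult],
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Group genes by direction of significant change per contrast.

    A gene joins "Increased in X" iff q <= q_threshold and fold change >=
    fc_threshold in the X contrast, "Decreased" symmetrically with fold
    change <= 1/fc_threshold.  Also returns the genes x contrasts log2
    fold-change heat matrix.
    """
    pre_genes = [r.gene_id for r in pretumor_results]
    tum_genes = [r.gene_id for r in tumor_results]
    if pre_genes != tum_genes:
        raise ValueError("contrasts must share the same gene universe")
    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for label, results in (("Pretumor", pretumor_results), ("Tumor", tumor_results)):
        for r in results:
            if r.q <= q_threshold and r.fold_change >= fc_threshold:
                groups[f"Increased in {label}"].append(r.gene_id)
            elif r.q <= q_threshold and r.fold_change <= 1.0 / fc_threshold:
                groups[f"Decreased in {label}"].append(r.gene_id)
    heat = pd.DataFrame(
        {
            "log2fc_pretumor": [r.log2fc for r in pretumor_results],
            "log2fc_tumor": [r.log2fc for r in tumor_results],
        },
        index=pre_genes,
    )
    heat.index.name = "gene_id"
    return groups, heat


def results_to_frame(
    pretumor_results: list[DGEResult],
    tumor_results: list[DGEResult],
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Combined per-gene DGE table (fold change, p, q per contrast, group)."""
    member: dict[str, list[str]] = {}
    for gname, gids in groups.items():
        for gid in gids:
            member.setdefault(gid, []).append(gname)
    rows = []
    for pre, tum in zip(pretumor_results, tumor_results):
        rows.append(
            {
                "gene_id": pre.gene_id,
                "fc_pretumor": pre.fold_change,
                "p_pretumor": pre.p,
                "q_pretumor": pre.q,
                "fc_tumor": tum.fold_change,
                "p_tumor": tum.p,
                "q_tumor": tum.q,
                "group": ";".join(member.get(pre.gene_id, [])),
            }
        )
    return pd.DataFrame(rows)
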