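"""Gene-level ChIP-seq binding quantification and differential binding.

A gene is called "bound" when its read coverage passes two thresholds at
once: at least 17 reads per kilobase pair (reads/kbp) and at least 100
reads in total (reads/gene).  Differential binding between conditions
(myoblast MB vs myotube MT) follows the negative-binomial generalized
linear model route: median-of-ratios size factors, per-gene dispersion
estimates, an NB two-group fit with a Wald test on the log2 fold change,
and Benjamini–Hochberg adjustment.  Sample similarity is summarized by
complete-linkage clustering of Euclidean distances between
variance-stabilized count profiles.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GeneModel",
    "GeneCountTable",
    "count_reads_per_gene",
    "reads_per_kbp",
    "classify_bound",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "vst_and_cluster",
    "ClusterResult",
]

DISPERSION_FLOOR = 1e-8
DEFAULT_RPK_THRESHOLD = 17.0
DEFAULT_READS_THRESHOLD = 100.0
DEFAULT_FRAGMENT_BP = 300


@dataclass(frozen=True)
class GeneModel:
    """Genomic gene range, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class GeneCountTable:
    """Genes × samples integer count matrix with sample and gene metadata.

    ``counts`` is indexed by gene id with one column per sample;
    ``sample_info`` is indexed by sample id and must carry a ``condition``
    column (MB / MT); ``gene_lengths`` gives each gene's length in bp.
    """

    counts: pd.DataFrame
    sample_info: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if "condition" not in self.sample_info.columns:
            raise ValueError("sample_info must have a 'condition' column")
        missing = set(self.counts.columns) - set(self.sample_info.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")


def _read_midpoints(reads: pd.DataFrame, extend_to_bp: int | None) -> pd.DataFrame:
    """Fragment midpoints per read, optionally after extending single-end
    reads to the estimated fragment length in the 5'→3' direction."""
    starts = reads["start"].to_numpy(dtype=np.int64)
    ends = reads["end"].to_numpy(dtype=np.int64)
    bad = np.nonzero(ends <= starts)[0]
    if bad.size:
        raise ValueError(f"malformed read interval at row {int(bad[0])}: end <= start")
    if extend_to_bp is not None and "strand" in reads.columns:
        strand = reads["strand"].to_numpy()
        fwd = strand != "-"
        ends = np.where(fwd, starts + extend_to_bp, ends)
        starts = np.where(fwd, starts, np.maximum(ends - extend_to_bp, 0))
    mid = (starts + ends) / 2.0
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "mid": mid})


def count_reads_per_gene(
    reads: pd.DataFrame,
    genes: list[GeneModel],
    mode: str = "midpoint",
    extend_to_bp: int | None = DEFAULT_FRAGMENT_BP,
) -> pd.Series:
    """Reads per gene for one sample.

    ``reads`` needs columns ``chrom, start, end`` (optionally ``strand``
    for fragment extension).  In ``midpoint`` mode a read is assigned to a
    gene iff its (extended-)fragment midpoint lies in [start, end); in
    ``any_overlap`` mode any base overlap counts.  Either way a read
    contributes at most once per gene; genes that overlap each other can
    both receive the same read.
    """
    if mode not in {"midpoint", "any_overlap"}:
        raise ValueError(f"unknown mode {mode!r}")
    for g in genes:
        if g.end <= g.start:  # GeneModel enforces this, but be explicit for dicts
            raise ValueError(f"gene {g.gene_id}: end <= start")
    out = pd.Series(0, index=[g.gene_id for g in genes], dtype=np.int64, name="reads_per_gene")
    if len(reads) == 0 or not genes:
        return out
    if mode == "midpoint":
        mids = _read_midpoints(reads, extend_to_bp)
        for chrom, sub in mids.groupby("chrom", sort=False):
            m = np.sort(sub["mid"].to_numpy())
            for g in genes:
                if g.chrom != chrom:
                    continue
                out[g.gene_id] = int(
                    np.searchsorted(m, g.end, side="left") - np.searchsorted(m, g.start, side="left")
                )
    else:
        starts = reads["start"].to_numpy(dtype=np.int64)
        ends = reads["end"].to_numpy(dtype=np.int64)
        bad = np.nonzero(ends <= starts)[0]
        if bad.size:
            raise ValueError(f"malformed read interval at row {int(bad[0])}: end <= start")
        for chrom, idx in reads.groupby("chrom", sort=False).indices.items():
            s = np.sort(starts[idx])
            e = np.sort(ends[idx])
            for g in genes:
                if g.chrom != chrom:
                    continue
                # overlap iff read.start < gene.end and read.end > gene.start
                n_start_ok = np.searchsorted(s, g.end, side="left")
                n_end_bad = np.searchsorted(e, g.start, side="right")
                out[g.gene_id] = int(n_start_ok - n_end_bad)
    return out


def reads_per_kbp(count, length_bp):
    """Average reads per 1000 bp: count / (length_bp / 1000)."""
    count = np.asarray(count, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if (length_bp <= 0).any():
        raise ValueError("length_bp must be positive")
    result = count / (length_bp / 1000.0)
    return float(result) if result.ndim == 0 else result


def classify_bound(
    counts,
    lengths_bp,
    gene_ids=None,
    rpk_threshold: float = DEFAULT_RPK_THRESHOLD,
    reads_threshold: float = DEFAULT_READS_THRESHOLD,
) -> pd.DataFrame:
    """Binding calls: bound ⇔ reads/kbp ≥ ``rpk_threshold`` AND
    reads/gene ≥ ``reads_threshold`` (both bounds inclusive)."""
    if rpk_threshold <= 0 or reads_threshold <= 0:
        raise ValueError("thresholds must be positive")
    counts = np.asarray(counts, dtype=float)
    rpk = reads_per_kbp(counts, lengths_bp)
    rpk = np.atleast_1d(rpk)
    counts = np.atleast_1d(counts)
    if gene_ids is None:
        gene_ids = np.arange(counts.size)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "reads_per_gene": counts,
            "reads_per_kbp": rpk,
            "bound": (rpk >= rpk_threshold) & (counts >= reads_threshold),
        }
    )


def size_factors(table: GeneCountTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    For each gene positive in every sample, the ratio of each sample's
    count to the gene's geometric mean is formed; a sample's size factor is
    the median of its ratios.
    """
    counts = table.counts if isinstance(table, GeneCountTable) else table
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = arr[all_positive]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def _condition_groups(table: GeneCountTable) -> dict[str, np.ndarray]:
    cond = table.sample_info.loc[table.counts.columns, "condition"]
    return {c: np.nonzero((cond == c).to_numpy())[0] for c in cond.unique()}


def estimate_dispersion(
    table: GeneCountTable,
    factors: pd.Series,
    floor: float = DISPERSION_FLOOR,
    shrink: bool = False,
) -> pd.Series:
    """Per-gene NB dispersion by the method of moments on normalized counts.

    Within each condition, with normalized counts ``K/s`` of mean ``m`` and
    sample variance ``v``, the moment estimate is
    ``(v - m * mean(1/s)) / m²`` (the ``mean(1/s)`` term removes the
    Poisson/shot-noise contribution under unequal library sizes).  Estimates
    are pooled across conditions weighted by degrees of freedom and floored
    at ``floor``.  With ``shrink`` the raw estimates are pulled halfway (in
    log space) toward a fitted mean-dispersion trend ``a1/m + a0``; off by
    default.
    """
    groups = _condition_groups(table)
    for c, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
    arr = table.counts.to_numpy(dtype=float)
    s = factors.loc[table.counts.columns].to_numpy(dtype=float)
    norm = arr / s
    num = np.zeros(arr.shape[0])
    den = np.zeros(arr.shape[0])
    for c, idx in groups.items():
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        inv_s = np.mean(1.0 / s[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_c = (v - m * inv_s) / m**2
        ok = m > 0
        w = idx.size - 1
        num[ok] += w * alpha_c[ok]
        den[ok] += w
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha[~np.isfinite(alpha)] = floor
    alpha = np.maximum(alpha, floor)
    disp = pd.Series(alpha, index=table.counts.index, name="dispersion")
    if shrink:
        base_mean = norm.mean(axis=1)
        ok = (base_mean > 0) & (alpha > floor)
        if ok.sum() >= 10:
            X = np.column_stack([1.0 / base_mean[ok], np.ones(ok.sum())])
            coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
            trend = np.maximum(coef[0] / np.maximum(base_mean, 1e-9) + coef[1], floor)
            disp = pd.Series(
                np.exp(0.5 * np.log(np.maximum(alpha, floor)) + 0.5 * np.log(trend)),
                index=table.counts.index,
                name="dispersion",
            )
    return disp


def _fit_group_log_mean(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-gene NB MLE of the group log mean with offsets.

    Model: counts ``y_gj ~ NB(mean = s_j * exp(theta_g), dispersion
    alpha_g)``.  Newton–Raphson on the score
    ``sum_j (y_gj - mu_gj) / (1 + alpha_g * mu_gj)`` with expected (Fisher)
    information ``sum_j mu_gj / (1 + alpha_g * mu_gj)``.  Returns
    ``(theta, fisher_info)``; genes whose group total is zero get
    ``theta = -inf`` and zero information.
    """
    tot = y.sum(axis=1)
    zero = tot == 0
    theta = np.where(zero, -np.inf, np.log(np.maximum(tot, 1e-300) / s.sum()))
    active = ~zero
    for _ in range(n_iter):
        if not active.any():
            break
        mu = s[None, :] * np.exp(theta[:, None])
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.zeros_like(theta)
        step[active] = score[active] / np.maximum(info[active], 1e-300)
        step = np.clip(step, -5.0, 5.0)
        theta = theta + np.where(active, step, 0.0)
        active = active & (np.abs(step) > tol)
    mu = s[None, :] * np.exp(np.where(np.isfinite(theta), theta, -np.inf)[:, None])
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return theta, info


def nb_wald_test(
    table: GeneCountTable,
    factors: pd.Series,
    dispersions: pd.Series,
    ref_condition: str = "MB",
    alt_condition: str = "MT",
    reference: str = "t",
) -> pd.DataFrame:
    """Per-gene NB Wald test of the log2 fold change (alt vs ref).

    Equivalent to an NB GLM with condition as the only covariate and size
    factors as offsets: each condition's mean is fitted by maximum
    likelihood at the given dispersion, the log2 fold change is the
    difference of fitted log2 means, and its standard error comes from the
    Fisher information.  The two-sided p-value refers the Wald statistic to
    a Student t distribution with the residual degrees of freedom
    (``n_samples - 2``) by default: with per-gene moment dispersion
    estimates and few replicates the asymptotic normal reference is
    anticonservative, and the t reference restores type-I error control (it
    converges to the normal as replication grows).  ``reference="normal"``
    selects the asymptotic reference.  Genes with zero counts throughout
    (or within one condition) have an undefined (NaN) p-value.
    Benjamini–Hochberg adjusted p-values are appended over the genes with
    defined p.
    """
    if reference not in {"t", "normal"}:
        raise ValueError(f"unknown reference {reference!r}")
    groups = _condition_groups(table)
    for c in (ref_condition, alt_condition):
        if c not in groups:
            raise ValueError(f"condition {c!r} not present")
    y = table.counts.to_numpy(dtype=np.int64)
    s = factors.loc[table.counts.columns].to_numpy(dtype=float)
    alpha = dispersions.loc[table.counts.index].to_numpy(dtype=float)
    idx_ref, idx_alt = groups[ref_condition], groups[alt_condition]
    theta_ref, info_ref = _fit_group_log_mean(y[:, idx_ref], s[idx_ref], alpha)
    theta_alt, info_alt = _fit_group_log_mean(y[:, idx_alt], s[idx_alt], alpha)
    ln2 = np.log(2.0)
    with np.errstate(invalid="ignore"):  # genes zero in both groups give NaN
        log2fc = (theta_alt - theta_ref) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1.0 / info_ref + 1.0 / info_alt) / ln2
        wald = log2fc / se
    defined = np.isfinite(wald)
    abs_w = np.abs(np.where(defined, wald, 0.0))
    if reference == "t":
        df_resid = max(idx_ref.size + idx_alt.size - 2, 1)
        p = np.where(defined, 2.0 * sps.t.sf(abs_w, df=df_resid), np.nan)
    else:
        p = np.where(defined, 2.0 * sps.norm.sf(abs_w), np.nan)
    base_mean = (y / s).mean(axis=1)
    res = pd.DataFrame(
        {
            "gene_id": table.counts.index,
            "baseMean": base_mean,
            "log2fc": log2fc,
            "lfcSE": se,
            "wald_stat": wald,
            "p_value": p,
        }
    ).set_index("gene_id")
    res["padj"] = bh_adjust(res["p_value"].to_numpy())
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are carried through unadjusted and do not count toward the
    number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    q = p[mask]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


@dataclass
class ClusterResult:
    """Sample clustering on variance-stabilized counts."""

    distances: pd.DataFrame
    linkage: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        return str(tree)

    def first_bipartition(self) -> tuple[set[str], set[str]]:
        """Sample sets of the two subtrees below the root merge."""
        n = len(self.sample_ids)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.linkage):
            members[n + i] = members[int(a)] | members[int(b)]
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        ids = np.asarray(self.sample_ids)
        return set(ids[sorted(members[a])]), set(ids[sorted(members[b])])


def vst_and_cluster(
    table: GeneCountTable | pd.DataFrame,
    factors: pd.Series,
    transform: str = "log2",
) -> ClusterResult:
    """Euclidean distances between variance-stabilized sample profiles and
    the complete-linkage merge tree.

    The default variance-stabilizing transform is ``log2(count/s + 1)`` on
    size-factor-normalized counts.
    """
    counts = table.counts if isinstance(table, GeneCountTable) else table
    if counts.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    s = factors.loc[counts.columns].to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / s
    if transform == "log2":
        vst = np.log2(norm + 1.0)
    elif transform == "sqrt":
        vst = np.sqrt(norm)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    dvec = pdist(vst.T, metric="euclidean")
    dist = pd.DataFrame(squareform(dvec), index=counts.columns, columns=counts.columns)
    Z = hierarchy.linkage(dvec, method="complete")
    return ClusterResult(distances=dist, linkage=Z, sample_ids=list(counts.columns))
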