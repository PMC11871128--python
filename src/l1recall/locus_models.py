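"""Locus-level models: activity clustering, the locus-efficiency regression
with a permutation background, per-locus total-RT regressions with a
resampling background, and the cluster-aggregate RNA model.

All models operate on log2, QC-adjusted values.  The efficiency model is a
single OLS over sample x locus observations,

    locus_TRT ~ efficiency_i * locus_RNA + tumor_type + p53 + const,

with one RNA slope per locus and tumor-type/p53 coefficients shared across
loci.  Empirical significance of each efficiency comes from refitting the
model on inputs whose locus labels have been randomly permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .cohort import CohortTable
from .qc_adjust import log2_transform

LOW_TRT_THRESHOLD = 0.0018


# ---------------------------------------------------------------------------
# Activity matrix and locus clustering
# ---------------------------------------------------------------------------


@dataclass
class LocusActivityMatrix:
    rna_means: pd.DataFrame     # loci x tumor types, mean log2-adjusted RNA
    trt_means: pd.DataFrame     # loci x tumor types, mean log2-adjusted TRT
    type_counts: pd.Series

    def locus_means(self, which: str = "trt") -> pd.Series:
        """Global per-locus mean weighting every tumor type equally."""
        m = self.trt_means if which == "trt" else self.rna_means
        return m.mean(axis=1)


def build_activity_matrix(
    cohort: CohortTable,
    rna_adjusted: pd.DataFrame | None = None,
    trt_adjusted: pd.DataFrame | None = None,
) -> LocusActivityMatrix:
    """Per-tumor-type means of log2-adjusted locus RNA and TRT.

    When pre-adjusted matrices are not supplied, plain log2(x + 0.5) of the
    cohort matrices is used.  Because the global locus mean is the unweighted
    mean of per-type means, each tumor type contributes equally regardless of
    its sample count.
    """
    rna = rna_adjusted if rna_adjusted is not None else log2_transform(cohort.rna)
    trt = trt_adjusted if trt_adjusted is not None else log2_transform(cohort.trt)
    rna = pd.DataFrame(rna, index=cohort.rna.index, columns=cohort.rna.columns)
    trt = pd.DataFrame(trt, index=cohort.trt.index, columns=cohort.trt.columns)
    types = cohort.samples["tumor_type"]
    counts = types.value_counts()
    keep = counts[counts > 0].index
    dropped = set(types.unique()) - set(keep)
    if dropped:
        warnings.warn(f"tumor types with no samples dropped: {sorted(dropped)}")
    group = types.to_numpy()
    rna_means = rna.groupby(group).mean().T
    trt_means = trt.groupby(group).mean().T
    return LocusActivityMatrix(rna_means, trt_means, counts)


@dataclass
class LocusClusterAssignment:
    table: pd.DataFrame   # locus -> rna_label, trt_label, low_trt, cluster

    @property
    def cluster_ids(self) -> pd.Series:
        return self.table["cluster"]

    def loci_in(self, cluster_id) -> list[str]:
        return list(self.table.index[self.table["cluster"] == cluster_id])


def _dendrogram_labels(matrix: pd.DataFrame, method: str, metric: str, t: float | None):
    if len(matrix) < 2:
        return np.ones(len(matrix), dtype=int)
    d = pdist(matrix.to_numpy(), metric=metric)
    if np.allclose(d, 0):
        warnings.warn("all locus profiles identical: single cluster")
        return np.ones(len(matrix), dtype=int)
    Z = hierarchy.linkage(d, method=method)
    if t is None:
        t = 0.7 * Z[:, 2].max()
    return hierarchy.fcluster(Z, t=t, criterion="distance")


def cluster_loci(
    matrix: LocusActivityMatrix,
    low_trt_threshold: float = LOW_TRT_THRESHOLD,
    method: str = "average",
    metric: str = "euclidean",
    t_rna: float | None = None,
    t_trt: float | None = None,
) -> LocusClusterAssignment:
    """Two dendrograms (RNA and TRT profiles) plus a low-TRT bin flag; loci
    sharing all three annotations form one final cluster."""
    if len(matrix.rna_means) < 2:
        raise ValueError("need at least 2 loci to cluster")
    rna_label = _dendrogram_labels(matrix.rna_means, method, metric, t_rna)
    trt_label = _dendrogram_labels(matrix.trt_means, method, metric, t_trt)
    low = (matrix.locus_means("trt") < low_trt_threshold).to_numpy()
    table = pd.DataFrame(
        {
            "rna_label": rna_label,
            "trt_label": trt_label,
            "low_trt": low,
        },
        index=matrix.rna_means.index,
    )
    final = {}
    for key, sub in table.groupby(["rna_label", "trt_label", "low_trt"], sort=True):
        final[key] = sub.index
    ids = {}
    for k, (key, loci) in enumerate(sorted(final.items(), key=lambda kv: str(kv[0]))):
        for locus in loci:
            ids[locus] = k
    table["cluster"] = pd.Series(ids)
    return LocusClusterAssignment(table)


# ---------------------------------------------------------------------------
# Long-format construction and the efficiency model
# ---------------------------------------------------------------------------


def make_long_table(
    cohort: CohortTable,
    rna_adjusted: pd.DataFrame | None = None,
    trt_adjusted: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rows = sample x locus with log2 locus TRT/RNA, tumor type and p53."""
    rna = rna_adjusted if rna_adjusted is not None else log2_transform(cohort.rna)
    trt = trt_adjusted if trt_adjusted is not None else log2_transform(cohort.trt)
    rna = pd.DataFrame(rna, index=cohort.rna.index, columns=cohort.rna.columns)
    trt = pd.DataFrame(trt, index=cohort.trt.index, columns=cohort.trt.columns)
    rows = rna.stack().rename("log2_rna").to_frame()
    rows["log2_trt"] = trt.stack()
    rows = rows.reset_index()
    rows.columns = ["sample_id", "locus", "log2_rna", "log2_trt"]
    meta = cohort.samples.set_index("sample_id")[["tumor_type", "p53_mut"]]
    rows = rows.join(meta, on="sample_id")
    # total RT burden (log2) repeated per row, for the total-RT models
    total = pd.Series(
        log2_transform(cohort.samples["total_rt"]),
        index=cohort.samples["sample_id"],
    )
    rows["log2_total_rt"] = rows["sample_id"].map(total)
    return rows


def _efficiency_design(long_table: pd.DataFrame, loci: list[str]):
    """Design matrix: per-locus RNA slope columns + shared type/p53/const."""
    n = len(long_table)
    locus_idx = pd.Categorical(long_table["locus"], categories=loci).codes
    X_rna = np.zeros((n, len(loci)))
    X_rna[np.arange(n), locus_idx] = long_table["log2_rna"].to_numpy()
    types = sorted(long_table["tumor_type"].unique())
    X_type = np.zeros((n, len(types) - 1))
    tcodes = pd.Categorical(long_table["tumor_type"], categories=types).codes
    for j in range(1, len(types)):
        X_type[:, j - 1] = tcodes == j
    X = np.column_stack(
        [X_rna, X_type, long_table["p53_mut"].to_numpy(), np.ones(n)]
    )
    names = (
        [f"eff_{l}" for l in loci]
        + [f"type_{t}" for t in types[1:]]
        + ["p53", "const"]
    )
    return X, names


@dataclass
class EfficiencyFit:
    efficiencies: pd.Series
    conf_int: pd.DataFrame        # locus -> lower, upper (95%)
    shared: pd.Series             # type/p53/const coefficients
    results: object = field(repr=False, default=None)


def fit_efficiency_model(long_table: pd.DataFrame) -> EfficiencyFit:
    """Single OLS with per-locus RNA slopes and shared covariates."""
    loci = sorted(long_table["locus"].unique())
    if len(loci) < 1:
        raise ValueError("no loci in table")
    if np.allclose(long_table["log2_rna"].var(), 0):
        raise ValueError("locus RNA has no variance; cannot fit efficiencies")
    X, names = _efficiency_design(long_table, loci)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        zero_var = [names[j] for j in range(X.shape[1] - 1) if X[:, j].std() == 0]
        raise ValueError(f"rank-deficient design; suspect columns: {zero_var}")
    res = sm.OLS(long_table["log2_trt"].to_numpy(), X).fit()
    params = pd.Series(res.params, index=names)
    ci = pd.DataFrame(res.conf_int(), index=names, columns=["lower", "upper"])
    eff = params[[f"eff_{l}" for l in loci]]
    eff.index = loci
    eff_ci = ci.loc[[f"eff_{l}" for l in loci]]
    eff_ci.index = loci
    shared = params[[n for n in names if not n.startswith("eff_")]]
    return EfficiencyFit(eff, eff_ci, shared, res)


@dataclass
class BackgroundDistribution:
    pool: np.ndarray                 # flat pool of resampled coefficients
    per_resampling_variance: np.ndarray
    n_resamplings: int

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.pool, q))


def efficiency_background(
    long_table: pd.DataFrame,
    loci_subset: list[str],
    n_resamplings: int = 1000,
    seed: int = 0,
) -> BackgroundDistribution:
    """Permutation background: locus labels randomly permuted, model refit.

    Restricted to ``loci_subset`` (typically loci with TRTs in at least two
    samples); each resampling preserves the multiset of locus labels.
    """
    if not loci_subset:
        raise ValueError("loci_subset must be nonempty")
    if n_resamplings < 100:
        warnings.warn("fewer than 100 resamplings: empirical p will be unstable")
    rng = np.random.default_rng(seed)
    sub = long_table[long_table["locus"].isin(loci_subset)].reset_index(drop=True)
    loci = sorted(loci_subset)
    labels = pd.Categorical(sub["locus"], categories=loci).codes.copy()
    n = len(sub)
    # fixed covariate block; only the locus interaction changes per permutation
    types = sorted(sub["tumor_type"].unique())
    tcodes = pd.Categorical(sub["tumor_type"], categories=types).codes
    X_fixed = np.zeros((n, len(types) - 1 + 2))
    for j in range(1, len(types)):
        X_fixed[:, j - 1] = tcodes == j
    X_fixed[:, -2] = sub["p53_mut"].to_numpy()
    X_fixed[:, -1] = 1.0
    rna = sub["log2_rna"].to_numpy()
    y = sub["log2_trt"].to_numpy()
    k = len(loci)
    pools = np.empty((n_resamplings, k))
    rows = np.arange(n)
    for r in range(n_resamplings):
        perm = labels[rng.permutation(n)]
        X_rna = np.zeros((n, k))
        X_rna[rows, perm] = rna
        X = np.concatenate([X_rna, X_fixed], axis=1)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pools[r] = beta[:k]
    return BackgroundDistribution(
        pool=pools.ravel(),
        per_resampling_variance=pools.var(axis=1, ddof=1),
        n_resamplings=n_resamplings,
    )


def empirical_p(value: float, pool: np.ndarray, side: str = "high") -> float:
    """(r+1)/(N+1) empirical tail probability against a background pool."""
    N = len(pool)
    if side == "high":
        r = int(np.sum(pool >= value))
    elif side == "low":
        r = int(np.sum(pool <= value))
    else:
        raise ValueError("side must be 'high' or 'low'")
    return (r + 1) / (N + 1)


CATEGORIES = (
    "significantly_high",
    "significantly_low",
    "slightly_high",
    "slightly_low",
    "typical",
)


def categorize_loci(
    fit_values: pd.Series,
    background: BackgroundDistribution,
    alpha: float = 0.05,
    n_hypotheses: int | None = None,
) -> pd.DataFrame:
    """One-sided empirical p per locus, Bonferroni corrected; non-significant
    loci outside the background IQR are slightly high/low; else typical."""
    pool = background.pool
    if n_hypotheses is None:
        n_hypotheses = len(fit_values)
    q25, q75 = np.percentile(pool, [25, 75])
    rows = []
    for locus, v in fit_values.items():
        p_high = empirical_p(v, pool, "high")
        p_low = empirical_p(v, pool, "low")
        direction = "high" if p_high <= p_low else "low"
        p_one = min(p_high, p_low)
        corrected = min(1.0, p_one * n_hypotheses)
        if corrected < alpha:
            cat = f"significantly_{direction}"
        elif v > q75:
            cat = "slightly_high"
        elif v < q25:
            cat = "slightly_low"
        else:
            cat = "typical"
        rows.append(
            {
                "locus": locus,
                "value": v,
                "p_one_sided": p_one,
                "p_corrected": corrected,
                "direction": direction,
                "category": cat,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


# ---------------------------------------------------------------------------
# Per-locus total-RT models and the cluster-RNA model
# ---------------------------------------------------------------------------


def _groupwise_slopes(
    y: np.ndarray, x: np.ndarray, codes: np.ndarray, k: int
) -> np.ndarray:
    """Closed-form per-group simple-regression slopes (cov/var), vectorized."""
    cnt = np.bincount(codes, minlength=k).astype(float)
    sx = np.bincount(codes, weights=x, minlength=k)
    sy = np.bincount(codes, weights=y, minlength=k)
    sxx = np.bincount(codes, weights=x * x, minlength=k)
    sxy = np.bincount(codes, weights=x * y, minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = sxx - sx * sx / cnt
        cov = sxy - sx * sy / cnt
        return np.where(var > 0, cov / var, np.nan)


@dataclass
class TotalRtFit:
    coefficients: pd.Series          # per-locus slope of total RT on locus RNA
    background: BackgroundDistribution
    categories: pd.DataFrame


def fit_total_rt_models(
    long_table: pd.DataFrame,
    loci: list[str] | None = None,
    n_resamplings: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TotalRtFit:
    """One simple OLS per locus: total RT burden ~ locus RNA + const.

    Background: resample observations with replacement across any sample and
    locus, permute the locus assignment of locus RNA, refit every per-locus
    model; the flat pool of ``n_resamplings x n_loci`` coefficients defines
    empirical significance, categorized as for efficiencies.
    """
    if loci is None:
        loci = sorted(long_table["locus"].unique())
    sub = long_table[long_table["locus"].isin(loci)].reset_index(drop=True)
    codes = pd.Categorical(sub["locus"], categories=loci).codes
    x = sub["log2_rna"].to_numpy()
    y = sub["log2_total_rt"].to_numpy()
    k = len(loci)
    slopes = _groupwise_slopes(y, x, codes, k)
    coef = pd.Series(slopes, index=loci)
    if coef.isna().any():
        warnings.warn(
            f"constant locus RNA, coefficient undefined: "
            f"{list(coef.index[coef.isna()])}"
        )
    rng = np.random.default_rng(seed)
    n = len(sub)
    pools = np.empty((n_resamplings, k))
    for r in range(n_resamplings):
        take = rng.integers(0, n, size=n)
        perm_codes = codes[rng.permutation(n)]
        pools[r] = _groupwise_slopes(y[take], x[take], perm_codes[take], k)
    bg = BackgroundDistribution(
        pool=pools.ravel()[~np.isnan(pools.ravel())],
        per_resampling_variance=np.nanvar(pools, axis=1, ddof=1),
        n_resamplings=n_resamplings,
    )
    cats = categorize_loci(coef.dropna(), bg, alpha=alpha, n_hypotheses=k)
    return TotalRtFit(coef, bg, cats)


@dataclass
class ClusterModelResult:
    coefficients: pd.Series
    conf_int: pd.DataFrame
    intercept: float
    fit_correlation: float
    results: object = field(repr=False, default=None)


def fit_cluster_model(
    cohort: CohortTable,
    assignment: LocusClusterAssignment,
    rna_adjusted: pd.DataFrame | None = None,
    total_rt_adjusted: np.ndarray | None = None,
) -> ClusterModelResult:
    """Total RT burden ~ sum over clusters of c_i * cluster_i RNA + const,

    where cluster_i RNA is the per-sample sum of log2-adjusted locus RNA over
    the loci assigned to cluster i (so when clusters partition the loci the
    cluster sums conserve the total per-sample RNA signal)."""
    rna = rna_adjusted if rna_adjusted is not None else log2_transform(cohort.rna)
    rna = pd.DataFrame(rna, index=cohort.rna.index, columns=cohort.rna.columns)
    y = (
        np.asarray(total_rt_adjusted, float)
        if total_rt_adjusted is not None
        else log2_transform(cohort.samples["total_rt"].to_numpy())
    )
    sums = {}
    for cid in sorted(assignment.table["cluster"].unique()):
        loci = assignment.loci_in(cid)
        s = rna[loci].sum(axis=1)
        if np.ptp(s.to_numpy()) > 0:
            sums[f"cluster_{cid}"] = s
    if not sums:
        raise ValueError("no cluster with varying aggregate RNA")
    X = pd.DataFrame(sums)
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        warnings.warn("collinear cluster sums: minimum-norm fit")
    res = sm.OLS(y, design).fit()
    fitted = res.fittedvalues
    r = float(np.corrcoef(y, fitted)[0, 1])
    coef = res.params.drop("const")
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    ci = ci.drop("const")
    return ClusterModelResult(coef, ci, float(res.params["const"]), r, res)
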