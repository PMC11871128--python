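"""p53 dual-regulation mediation decomposition and cohort-level tests.

Five OLS regressions decompose the total effect tau of p53 mutation on log2
RT burden into a component mediated by L1 RNA (alpha * beta_prime, which by
OLS algebra equals tau - tau_prime) and a direct component tau_prime:

    (1) RT  ~ tau        * p53 + c1
    (2) RT  ~ beta       * RNA + c2
    (3) RNA ~ alpha      * p53 + c3
    (4) RT  ~ beta_prime * RNA + tau_prime * p53 + c4
    (5) RNA ~ beta_star  * RT  + alpha_star  * p53 + c5

Also here: the RNA-quintile stratified rank tests, the LFS (germline TP53)
bootstrap comparison, gene-mutation stratified tests, and the
normal-tissue-RNA to tumor-p53 linear probability model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def _ols_slopes(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    design = np.column_stack([X, np.ones(len(y))])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def _standardize(coef: float, x: np.ndarray, y: np.ndarray, quoted: bool) -> float:
    """Standardized coefficient.

    Default (conventional): coef * sd(x) / sd(y), which is invariant under
    affine rescaling of either variable.  ``quoted=True`` gives the reversed
    ratio coef * sd(y) / sd(x) for comparison.
    """
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    return coef * (sy / sx if quoted else sx / sy)


@dataclass
class MediationResult:
    raw: dict
    standardized: dict
    pvalues: dict
    mediated_effect: float           # alpha * beta_prime (raw)
    mediated_fraction: float         # alpha*beta' / tau
    unmediated_fraction: float       # tau' / tau
    ci: dict                         # 95% bootstrap percentile CIs
    mediated_p: float                # delta-method (Sobel-type) p for alpha*beta'
    n_boot: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.raw:
            rows.append(
                {
                    "coefficient": name,
                    "raw": self.raw[name],
                    "standardized": self.standardized.get(name, np.nan),
                    "p": self.pvalues.get(name, np.nan),
                    "ci_low": self.ci.get(name, (np.nan, np.nan))[0],
                    "ci_high": self.ci.get(name, (np.nan, np.nan))[1],
                }
            )
        return pd.DataFrame(rows).set_index("coefficient")


def fit_mediation(
    rt,
    rna,
    p53,
    n_boot: int = 1000,
    seed: int = 0,
    quoted_standardization: bool = False,
) -> MediationResult:
    """Fit the five-equation decomposition with bootstrap CIs.

    ``rt`` and ``rna`` are log2, QC-adjusted vectors; ``p53`` is the 0/1
    altered indicator.  The identity tau - tau_prime = alpha * beta_prime
    holds to machine precision on any input.  Bootstrap CIs (percentile,
    resampling samples with replacement) cover the raw coefficients, the
    standardized coefficients and the mediated/unmediated fractions.
    """
    rt = np.asarray(rt, float)
    rna = np.asarray(rna, float)
    p53 = np.asarray(p53, float)
    if not (len(rt) == len(rna) == len(p53)):
        raise ValueError("rt, rna, p53 must have equal length")
    if np.ptp(p53) == 0:
        raise ValueError("p53 indicator is constant: design is degenerate")

    X1 = sm.add_constant(p53)
    m1 = sm.OLS(rt, X1).fit()
    m2 = sm.OLS(rt, sm.add_constant(rna)).fit()
    m3 = sm.OLS(rna, X1).fit()
    X4 = sm.add_constant(np.column_stack([rna, p53]))
    m4 = sm.OLS(rt, X4).fit()
    X5 = sm.add_constant(np.column_stack([rt, p53]))
    m5 = sm.OLS(rna, X5).fit()

    tau = m1.params[1]
    beta = m2.params[1]
    alpha = m3.params[1]
    beta_p, tau_p = m4.params[1], m4.params[2]
    beta_s, alpha_s = m5.params[1], m5.params[2]

    raw = {
        "tau": tau,
        "beta": beta,
        "alpha": alpha,
        "beta_prime": beta_p,
        "tau_prime": tau_p,
        "beta_star": beta_s,
        "alpha_star": alpha_s,
        "c1": m1.params[0],
        "c2": m2.params[0],
        "c3": m3.params[0],
        "c4": m4.params[0],
        "c5": m5.params[0],
    }
    q = quoted_standardization
    standardized = {
        "tau": _standardize(tau, p53, rt, q),
        "beta": _standardize(beta, rna, rt, q),
        "alpha": _standardize(alpha, p53, rna, q),
        "beta_prime": _standardize(beta_p, rna, rt, q),
        "tau_prime": _standardize(tau_p, p53, rt, q),
        "beta_star": _standardize(beta_s, rt, rna, q),
        "alpha_star": _standardize(alpha_s, p53, rna, q),
    }
    # the mediated effect standardizes like an effect of p53 on RT
    standardized["mediated"] = _standardize(alpha * beta_p, p53, rt, q)
    pvalues = {
        "tau": m1.pvalues[1],
        "beta": m2.pvalues[1],
        "alpha": m3.pvalues[1],
        "beta_prime": m4.pvalues[1],
        "tau_prime": m4.pvalues[2],
        "beta_star": m5.pvalues[1],
        "alpha_star": m5.pvalues[2],
    }
    mediated = alpha * beta_p
    med_frac = mediated / tau if tau != 0 else np.nan
    unmed_frac = tau_p / tau if tau != 0 else np.nan

    # delta-method (Sobel-type) significance of the mediated effect
    se_a, se_bp = m3.bse[1], m4.bse[1]
    se_med = np.sqrt(alpha**2 * se_bp**2 + beta_p**2 * se_a**2)
    z = mediated / se_med if se_med > 0 else np.nan
    mediated_p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan

    ci = _bootstrap_ci(rt, rna, p53, n_boot, seed, q) if n_boot > 0 else {}
    return MediationResult(
        raw=raw,
        standardized=standardized,
        pvalues=pvalues,
        mediated_effect=mediated,
        mediated_fraction=med_frac,
        unmediated_fraction=unmed_frac,
        ci=ci,
        mediated_p=mediated_p,
        n_boot=n_boot,
        seed=seed,
    )


def _bootstrap_ci(rt, rna, p53, n_boot, seed, quoted) -> dict:
    """Vectorized percentile bootstrap over samples (with replacement)."""
    rng = np.random.default_rng(seed)
    n = len(rt)
    idx = rng.integers(0, n, size=(n_boot, n))
    RT, RNA, P = rt[idx], rna[idx], p53[idx]
    ones = np.ones_like(RT)

    def slope2(Y, X):  # per-row simple regression slope
        xm = X.mean(axis=1, keepdims=True)
        ym = Y.mean(axis=1, keepdims=True)
        return ((X - xm) * (Y - ym)).sum(axis=1) / ((X - xm) ** 2).sum(axis=1)

    tau_b = slope2(RT, P)
    alpha_b = slope2(RNA, P)
    # eq4 per-row via 3x3 normal equations
    Xs = np.stack([RNA, P, ones], axis=2)          # (B, n, 3)
    G = np.einsum("bni,bnj->bij", Xs, Xs)
    h = np.einsum("bni,bn->bi", Xs, RT)
    sol = np.linalg.solve(G, h[..., None])[..., 0]
    beta_p_b, tau_p_b = sol[:, 0], sol[:, 1]
    mediated_b = alpha_b * beta_p_b
    with np.errstate(divide="ignore", invalid="ignore"):
        med_frac_b = mediated_b / tau_b
        unmed_frac_b = tau_p_b / tau_b

    def sd(M):
        return M.std(axis=1, ddof=1)

    if quoted:
        tau_s = tau_b * sd(RT) / sd(P)
        alpha_s = alpha_b * sd(RNA) / sd(P)
        beta_p_s = beta_p_b * sd(RT) / sd(RNA)
        tau_p_s = tau_p_b * sd(RT) / sd(P)
        med_s = mediated_b * sd(RT) / sd(P)
    else:
        tau_s = tau_b * sd(P) / sd(RT)
        alpha_s = alpha_b * sd(P) / sd(RNA)
        beta_p_s = beta_p_b * sd(RNA) / sd(RT)
        tau_p_s = tau_p_b * sd(P) / sd(RT)
        med_s = mediated_b * sd(P) / sd(RT)

    def pci(v):
        v = v[np.isfinite(v)]
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return {
        "tau": pci(tau_b),
        "alpha": pci(alpha_b),
        "beta_prime": pci(beta_p_b),
        "tau_prime": pci(tau_p_b),
        "mediated": pci(mediated_b),
        "mediated_fraction": pci(med_frac_b),
        "unmediated_fraction": pci(unmed_frac_b),
        "tau_std": pci(tau_s),
        "alpha_std": pci(alpha_s),
        "beta_prime_std": pci(beta_p_s),
        "tau_prime_std": pci(tau_p_s),
        "mediated_std": pci(med_s),
    }


# ---------------------------------------------------------------------------
# Quintile-stratified comparisons
# ---------------------------------------------------------------------------


def quintile_stratified_test(rt, rna, p53, n_strata: int = 5) -> pd.DataFrame:
    """Split samples into RNA quintiles; within each, two-sided rank-sum test
    of RT between p53 mutant and wild type, Bonferroni corrected over the
    strata.  Quintile sizes differ by at most one sample."""
    rt = np.asarray(rt, float)
    rna = np.asarray(rna, float)
    p53 = np.asarray(p53, int)
    n = len(rt)
    if n < 50:
        raise ValueError("need at least 50 samples for quintile stratification")
    order = np.argsort(rna, kind="stable")
    chunks = np.array_split(order, n_strata)
    rows = []
    for qi, idx in enumerate(chunks, start=1):
        mut = rt[idx][p53[idx] == 1]
        wt = rt[idx][p53[idx] == 0]
        if len(mut) == 0 or len(wt) == 0:
            rows.append(
                {
                    "quintile": qi,
                    "n": len(idx),
                    "n_mut": len(mut),
                    "n_wt": len(wt),
                    "p": np.nan,
                    "p_corrected": np.nan,
                    "effect_size": np.nan,
                    "testable": False,
                }
            )
            continue
        stat, p = stats.mannwhitneyu(mut, wt, alternative="two-sided")
        rows.append(
            {
                "quintile": qi,
                "n": len(idx),
                "n_mut": len(mut),
                "n_wt": len(wt),
                "p": p,
                "p_corrected": min(1.0, p * n_strata),
                "effect_size": float(abs(np.median(mut) - np.median(wt))),
                "testable": True,
            }
        )
    return pd.DataFrame(rows).set_index("quintile")


# ---------------------------------------------------------------------------
# LFS bootstrap comparison
# ---------------------------------------------------------------------------


@dataclass
class LfsComparison:
    observed_mean: float
    boot_means: np.ndarray = field(repr=False)
    p_value: float
    ci: tuple
    n_resamplings: int


def lfs_bootstrap_compare(
    values,
    lfs_flags,
    tumor_type,
    p53_mut,
    n_resamplings: int = 10_000,
    seed: int = 0,
) -> LfsComparison:
    """Compare LFS (germline TP53) tumors against indication-matched
    bootstrap draws from non-LFS, TP53-mutant tumors.

    Each of ``n_resamplings`` draws takes, per tumor type, as many non-LFS
    p53-mutant samples (with replacement) as the LFS set contains of that
    type.  Significance is a two-sided t-test between the bootstrap mean
    distribution and the true LFS values.
    """
    values = np.asarray(values, float)
    lfs = np.asarray(lfs_flags, int).astype(bool)
    ttype = np.asarray(tumor_type, dtype=object)
    p53 = np.asarray(p53_mut, int).astype(bool)
    if lfs.sum() < 1:
        raise ValueError("need at least one LFS sample")
    rng = np.random.default_rng(seed)
    pool_mask = p53 & ~lfs
    draws = []
    counts = pd.Series(ttype[lfs]).value_counts()
    for t, c in counts.items():
        pool_t = values[pool_mask & (ttype == t)]
        if len(pool_t) == 0:
            raise ValueError(f"no non-LFS p53-mutant samples of tumor type {t!r}")
        draws.append((pool_t, int(c)))
    boot = np.zeros(n_resamplings)
    total = counts.sum()
    for pool_t, c in draws:
        take = rng.integers(0, len(pool_t), size=(n_resamplings, c))
        boot += pool_t[take].sum(axis=1)
    boot /= total
    lfs_vals = values[lfs]
    _t, p = stats.ttest_ind(boot, lfs_vals, equal_var=False)
    return LfsComparison(
        observed_mean=float(lfs_vals.mean()),
        boot_means=boot,
        p_value=float(p),
        ci=(float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))),
        n_resamplings=n_resamplings,
    )


# ---------------------------------------------------------------------------
# Gene-mutation stratified tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneTestResult:
    gene: str
    stratum: str          # 'all' | 'p53_mut' | 'p53_wt'
    endpoint: str         # 'RNA' | 'RT'
    statistic: float
    p_raw: float
    p_corrected: float
    effect_size: float
    passed: bool
    skipped_reason: str | None = None


def gene_stratified_tests(
    samples: pd.DataFrame,
    genes: list[str],
    rna,
    rt,
    p53_col: str = "p53_mut",
    alpha: float = 0.01,
) -> list[GeneTestResult]:
    """Rank tests of adjusted RNA/RT against mutation status per gene.

    Pass 1: per gene, RNA and RT mutant-vs-WT over all samples (2G tests).
    Pass 2: genes other than TP53 stratified by p53 status (4 more tests per
    gene).  Bonferroni correction is applied over the full family of
    attempted tests; a comparison passes when corrected p < ``alpha`` and
    the median shift is at least the cohort-wide SD of the endpoint.
    """
    rna = np.asarray(rna, float)
    rt = np.asarray(rt, float)
    endpoints = {"RNA": rna, "RT": rt}
    sds = {k: np.std(v, ddof=1) for k, v in endpoints.items()}
    p53 = samples[p53_col].to_numpy().astype(bool)
    strata = {
        "all": np.ones(len(samples), bool),
        "p53_mut": p53,
        "p53_wt": ~p53,
    }
    jobs = []
    for gene in genes:
        jobs.append((gene, "all"))
    for gene in genes:
        if gene.upper() == "TP53":
            continue
        jobs.append((gene, "p53_mut"))
        jobs.append((gene, "p53_wt"))
    raw: list[dict] = []
    for gene, stratum in jobs:
        flag = samples[f"mut_{gene}"].to_numpy().astype(bool)
        mask = strata[stratum]
        for endpoint, vec in endpoints.items():
            mut = vec[mask & flag]
            wt = vec[mask & ~flag]
            if len(mut) == 0 or len(wt) == 0:
                raw.append(
                    {
                        "gene": gene,
                        "stratum": stratum,
                        "endpoint": endpoint,
                        "skip": "no mutant samples" if len(mut) == 0 else "no WT samples",
                    }
                )
                continue
            stat, p = stats.mannwhitneyu(mut, wt, alternative="two-sided")
            raw.append(
                {
                    "gene": gene,
                    "stratum": stratum,
                    "endpoint": endpoint,
                    "stat": float(stat),
                    "p": float(p),
                    "effect": float(abs(np.median(mut) - np.median(wt))),
                }
            )
    n_tests = sum(1 for r in raw if "p" in r)
    out = []
    for r in raw:
        if "skip" in r:
            out.append(
                GeneTestResult(
                    r["gene"], r["stratum"], r["endpoint"],
                    np.nan, np.nan, np.nan, np.nan, False, r["skip"],
                )
            )
            continue
        p_corr = min(1.0, r["p"] * n_tests)
        passed = p_corr < alpha and r["effect"] >= sds[r["endpoint"]]
        out.append(
            GeneTestResult(
                r["gene"], r["stratum"], r["endpoint"],
                r["stat"], r["p"], p_corr, r["effect"], passed,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Normal-tissue RNA to tumor p53 model
# ---------------------------------------------------------------------------


def normal_rna_to_p53(normal_rna, tumor_p53, tumor_type) -> dict:
    """Linear probability model: tumor p53 status ~ normal RNA + tumor type.

    Tumor type is categorical with its own coefficient per type; types with a
    uniform p53 outcome are dropped from the design with a warning.  Returns
    the standardized RNA coefficient (scale-invariant) and its p-value.
    """
    rna = np.asarray(normal_rna, float)
    y = np.asarray(tumor_p53, float)
    ttype = pd.Series(np.asarray(tumor_type, dtype=object))
    keep = np.ones(len(y), bool)
    for t, sub in ttype.groupby(ttype):
        outcomes = y[sub.index]
        if np.ptp(outcomes) == 0:
            warnings.warn(f"tumor type {t!r} has uniform p53 outcome; dropped")
            keep[sub.index] = False
    rna_k, y_k, ttype_k = rna[keep], y[keep], ttype[keep]
    dummies = pd.get_dummies(ttype_k, drop_first=True, dtype=float)
    X = sm.add_constant(
        np.column_stack([rna_k, dummies.to_numpy()])
        if dummies.shape[1]
        else rna_k
    )
    res = sm.OLS(y_k, X).fit()
    coef = res.params[1]
    std = coef * np.std(rna_k, ddof=1) / np.std(y_k, ddof=1)
    return {
        "coefficient": float(coef),
        "standardized_coefficient": float(std),
        "p": float(res.pvalues[1]),
        "n": int(keep.sum()),
        "results": res,
    }
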