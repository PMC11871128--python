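"""Synthetic multi-omic cohort generator.

Emulates the joined WGS + RNA-seq + annotation table the downstream models
consume: per-sample tumor type, p53 status, germline-p53 (LFS) flag, gene
mutation flags, a locus-level RNA matrix (TPM), a locus-level
transduction-bearing RT (TRT) count matrix, total RT burden, and technical
QC covariates.  All ground-truth parameters are recorded so statistical
modules can be calibrated against known effects.

Generative model (per sample s, locus i):

    log2 RNA_si = baseline_i + type_effect_t(s) + alpha * p53_s + eps,
                  eps ~ Normal(0, dispersion_i)
    TRT_si      ~ Poisson(e_i * RNA_si * exp(tau_prime * p53_s))
    total RT_s  = sum_i TRT_si + Poisson(background)

so effects are log-linear and OLS on log2 scales recovers them.  ``alpha``
is in log2 units; ``tau_prime`` multiplies the Poisson exposure on the
natural-log scale.  QC covariates contaminate the *observed* RNA and RT
linearly on the log2 scale with stated slopes, which the adjustment module
is expected to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .qc_adjust import RT_COVARIATES

DEFAULT_TYPES = ("esophageal", "lung_squamous", "colon", "prostate")


@dataclass(frozen=True)
class GeneSpec:
    """A mutated gene planted into the cohort with optional L1 effects."""

    mutation_prob: float = 0.1
    rna_shift: float = 0.0     # log2 shift of total RNA in mutant samples
    rt_shift: float = 0.0      # log2 shift of total RT in mutant samples
    stratum: str = "all"       # 'all' | 'p53_mut' | 'p53_wt'


@dataclass
class CohortParams:
    n_samples: int = 500
    tumor_types: tuple[str, ...] = DEFAULT_TYPES
    type_proportions: tuple[float, ...] | None = None
    p53_prob: float | dict = 0.4
    lfs_fraction: float = 0.01          # fraction of p53-mutant samples germline
    n_loci: int = 40
    baseline_log2: float | np.ndarray = 4.0
    dispersion: float | np.ndarray = 1.0
    efficiency: np.ndarray | None = None      # e_i; default log-uniform [0.01, 0.3]
    type_rna_effect: dict | None = None       # per-type log2 RNA offset
    alpha_true: float = 1.0                   # p53 effect on log2 RNA
    tau_prime_true: float = 0.55              # direct p53 effect on RT exposure (ln)
    rt_background: float = 0.5
    rna_contamination_slope: float = 0.0      # intronic-rate slope on observed log2 RNA
    rt_contamination_slopes: dict | None = None   # WGS-metric slopes on observed log2 RT
    genes: dict[str, GeneSpec] = field(default_factory=dict)
    seed: int = 0

    def resolved_proportions(self) -> np.ndarray:
        props = self.type_proportions
        if props is None:
            props = tuple(1.0 / len(self.tumor_types) for _ in self.tumor_types)
        props = np.asarray(props, float)
        if len(props) != len(self.tumor_types) or not np.isclose(props.sum(), 1.0):
            raise ValueError("type proportions must match tumor_types and sum to 1")
        if np.any(props <= 0):
            raise ValueError("degenerate type proportions")
        return props


@dataclass
class CohortTable:
    samples: pd.DataFrame        # one row per sample
    rna: pd.DataFrame            # samples x loci, TPM
    trt: pd.DataFrame            # samples x loci, counts
    truth: dict                  # generative parameters actually used

    def write(self, outdir: str | Path, prefix: str = "cohort") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.samples.to_csv(outdir / f"{prefix}_samples.tsv", sep="\t", index=False)
        self.rna.to_csv(outdir / f"{prefix}_rna_tpm.tsv", sep="\t")
        self.trt.to_csv(outdir / f"{prefix}_trt_counts.tsv", sep="\t")


def _qc_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name in RT_COVARIATES:
        if "read_length" in name:
            cols[name] = np.full(n, 150.0) + rng.normal(0, 1.0, n)
        elif "coverage" in name:
            base = 60.0 if name.startswith("tumor") else 30.0
            cols[name] = base + rng.normal(0, 5.0, n)
        elif "base_quality" in name:
            cols[name] = 30.0 + rng.normal(0, 1.0, n)
        else:  # fractions
            cols[name] = np.clip(rng.normal(0.01, 0.003, n), 0, 1)
    cols["intronic_rate"] = np.clip(rng.beta(4, 12, n), 0.01, 0.99)
    return pd.DataFrame(cols)


def simulate_cohort(params: CohortParams) -> CohortTable:
    """Draw a cohort table per the generative model; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    types = list(params.tumor_types)
    props = params.resolved_proportions()
    type_idx = rng.choice(len(types), size=n, p=props)
    tumor_type = np.array(types, dtype=object)[type_idx]

    if isinstance(params.p53_prob, dict):
        p53_p = np.array([params.p53_prob[t] for t in tumor_type])
    else:
        p53_p = np.full(n, float(params.p53_prob))
    p53 = (rng.random(n) < p53_p).astype(int)
    lfs = np.zeros(n, dtype=int)
    mut_idx = np.flatnonzero(p53 == 1)
    n_lfs = int(round(params.lfs_fraction * len(mut_idx)))
    if n_lfs:
        lfs[rng.choice(mut_idx, size=n_lfs, replace=False)] = 1

    m = params.n_loci
    baseline = np.broadcast_to(np.asarray(params.baseline_log2, float), (m,)).copy()
    dispersion = np.broadcast_to(np.asarray(params.dispersion, float), (m,)).copy()
    if np.any(dispersion <= 0):
        raise ValueError("dispersions must be > 0")
    if params.efficiency is None:
        efficiency = np.exp(
            rng.uniform(np.log(0.01), np.log(0.3), size=m)
        )
    else:
        efficiency = np.asarray(params.efficiency, float)
        if len(efficiency) != m or np.any(efficiency < 0):
            raise ValueError("efficiency must be length n_loci and >= 0")
    type_eff = params.type_rna_effect or {t: 0.0 for t in types}
    type_offset = np.array([type_eff.get(t, 0.0) for t in tumor_type])

    log2_rna = (
        baseline[None, :]
        + type_offset[:, None]
        + params.alpha_true * p53[:, None]
        + rng.normal(0, 1, size=(n, m)) * dispersion[None, :]
    )

    qc = _qc_covariates(n, rng)
    # gene mutation flags and their planted effects on total signal
    gene_flags = {}
    gene_rna_shift = np.zeros(n)
    gene_rt_shift = np.zeros(n)
    for gene, spec in params.genes.items():
        flag = (rng.random(n) < spec.mutation_prob).astype(int)
        gene_flags[f"mut_{gene}"] = flag
        in_stratum = {
            "all": np.ones(n, bool),
            "p53_mut": p53 == 1,
            "p53_wt": p53 == 0,
        }[spec.stratum]
        gene_rna_shift += spec.rna_shift * flag * in_stratum
        gene_rt_shift += spec.rt_shift * flag * in_stratum

    log2_rna = log2_rna + gene_rna_shift[:, None]
    rna_tpm = 2.0 ** log2_rna
    exposure = np.exp(params.tau_prime_true * p53 + np.log(2) * gene_rt_shift)
    lam = efficiency[None, :] * rna_tpm * exposure[:, None]
    trt = rng.poisson(lam)
    total_rt = trt.sum(axis=1) + rng.poisson(params.rt_background, size=n)

    # technical contamination of the observed values (log2-linear)
    intronic = qc["intronic_rate"].to_numpy()
    if params.rna_contamination_slope:
        shift = params.rna_contamination_slope * (intronic - intronic.mean())
        rna_tpm = rna_tpm * 2.0 ** shift[:, None]
    if params.rt_contamination_slopes:
        delta = np.zeros(n)
        for name, slope in params.rt_contamination_slopes.items():
            v = qc[name].to_numpy()
            delta += slope * (v - v.mean())
        total_rt = np.rint(
            np.maximum(0.0, (total_rt + 0.5) * 2.0 ** delta - 0.5)
        ).astype(int)

    locus_ids = [f"L{i:03d}" for i in range(m)]
    sample_ids = [f"sample{j:04d}" for j in range(n)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tumor_type": tumor_type,
            "p53_mut": p53,
            "lfs": lfs,
            "total_rt": total_rt,
            "total_rna_tpm": rna_tpm.sum(axis=1),
            **gene_flags,
        }
    )
    samples = pd.concat([samples, qc], axis=1)
    rna = pd.DataFrame(rna_tpm, index=sample_ids, columns=locus_ids)
    trt_df = pd.DataFrame(trt, index=sample_ids, columns=locus_ids)
    truth = {
        "efficiency": efficiency,
        "baseline_log2": baseline,
        "dispersion": dispersion,
        "alpha_true": params.alpha_true,
        "tau_prime_true": params.tau_prime_true,
    }
    return CohortTable(samples, rna, trt_df, truth)


# ---------------------------------------------------------------------------
# p53 regulation scenarios for mediation calibration
# ---------------------------------------------------------------------------


@dataclass
class ScenarioParams:
    """Gaussian structural-equation stand-in for the two p53 regulation modes.

    Values are on the log2, QC-adjusted scale the mediation model consumes,
    so planted coefficients are exactly the OLS estimands:

        rna = mu_rna + alpha * p53 + eps1,        eps1 ~ N(0, sd_rna)
        rt  = mu_rt + beta_prime * rna + tau_prime * p53 + eps2,
                                                  eps2 ~ N(0, sd_rt)

    ``rt_selection`` instead censors wild-type-p53 samples whose RT exceeds
    the ``survival_quantile`` of the wild-type RT distribution (cell death at
    high retrotransposition burden), redrawing to preserve n.  Selection is
    deliberately restricted to the extreme tail so that the induced,
    purely-selective association stays within sampling noise.
    """

    n_samples: int = 2000
    p53_prob: float = 0.4
    mu_rna: float = 2.0
    mu_rt: float = 1.0
    alpha: float = 1.0
    beta_prime: float = 0.8
    tau_prime: float = 0.8
    sd_rna: float = 1.0
    sd_rt: float = 1.5
    survival_quantile: float = 0.99
    tumor_types: tuple[str, ...] = DEFAULT_TYPES
    seed: int = 0


SCENARIOS = ("expression_only", "rt_selection", "dual")


def simulate_p53_scenario(model: str, params: ScenarioParams) -> pd.DataFrame:
    """Cohort under one p53 regulation scenario.

    expression_only: p53 acts on RNA only (tau_prime forced to 0).
    rt_selection:    p53 has no effect on RNA or RT generation (alpha and
                     tau_prime forced to 0) but wild-type cells with extreme
                     RT burden are removed and redrawn.
    dual:            both planted effects active.
    """
    if model not in SCENARIOS:
        raise ValueError(f"unknown scenario {model!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(params.seed)
    alpha = params.alpha
    tau = params.tau_prime
    if model == "expression_only":
        tau = 0.0
    elif model == "rt_selection":
        alpha = 0.0
        tau = 0.0

    n = params.n_samples
    p53 = (rng.random(n) < params.p53_prob).astype(int)
    tumor_type = rng.choice(list(params.tumor_types), size=n)

    def draw(p53_vec):
        k = len(p53_vec)
        rna = params.mu_rna + alpha * p53_vec + rng.normal(0, params.sd_rna, k)
        rt = (
            params.mu_rt
            + params.beta_prime * rna
            + tau * p53_vec
            + rng.normal(0, params.sd_rt, k)
        )
        return rna, rt

    rna, rt = draw(p53)
    if model == "rt_selection":
        wt = p53 == 0
        threshold = np.quantile(rt[wt], params.survival_quantile)
        for _ in range(100):
            doomed = wt & (rt > threshold)
            if not doomed.any():
                break
            k = int(doomed.sum())
            new_rna, new_rt = draw(np.zeros(k, dtype=int))
            rna[doomed] = new_rna
            rt[doomed] = new_rt
        rt[wt] = np.minimum(rt[wt], threshold)  # guard: enforce survival bound

    return pd.DataFrame(
        {
            "sample_id": [f"sample{j:04d}" for j in range(n)],
            "tumor_type": tumor_type,
            "p53_mut": p53,
            "log2_rna_adj": rna,
            "log2_rt_adj": rt,
        }
    )
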