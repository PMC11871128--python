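"""Technical-covariate adjustment of RNA and RT estimates.

Estimates are log2 transformed (pseudocount 0.5) and residualized against
technical covariates by ordinary least squares; the residuals are the
adjusted values used by every downstream model.  The log2 transform comes
first: residuals can be negative, so transforming afterwards would be
incoherent.  This ordering is recorded in the metadata the writers emit.
"""

from __future__ import annotations

import warnings

import numpy as np

PSEUDOCOUNT = 0.5

RT_COVARIATES = [
    "tumor_mean_read_length",
    "tumor_coverage",
    "tumor_mean_base_quality",
    "tumor_chimeric_fraction",
    "tumor_clipped_base_fraction",
    "normal_mean_read_length",
    "normal_coverage",
    "normal_mean_base_quality",
    "normal_chimeric_fraction",
    "normal_clipped_base_fraction",
]


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of y on [1, X]; minimum-norm solution when collinear."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("collinear covariates: minimum-norm fit used")
    return y - design @ beta


def log2_transform(values) -> np.ndarray:
    return np.log2(np.asarray(values, dtype=float) + PSEUDOCOUNT)


def adjust_rna(l1_tpm, intronic_rate) -> np.ndarray:
    """Adjusted L1 RNA: residuals of log2(TPM + 0.5) on intronic rate.

    Tumor and normal samples are expected to be fitted jointly: pass them in
    one call.  A constant intronic rate degenerates to centering (reported,
    not fatal).
    """
    y = log2_transform(l1_tpm)
    x = np.asarray(intronic_rate, dtype=float)
    if len(y) != len(x):
        raise ValueError("l1_tpm and intronic_rate must be equal length")
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0:
        warnings.warn("intronic rate constant: adjustment degenerates to centering")
        return y - y.mean()
    return _residualize(y, x[:, None])


def adjust_rt(rt_count, covariates) -> np.ndarray:
    """Adjusted RT burden: residuals of log2(count + 0.5) on the ten WGS
    metrics (five per tumor sample and five per paired normal), jointly."""
    y = log2_transform(rt_count)
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("covariates must be an (n_samples, n_covariates) array")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more samples than covariates")
    if np.all(np.ptp(X, axis=0) == 0):
        warnings.warn("all covariates constant: adjustment degenerates to centering")
        return y - y.mean()
    return _residualize(y, X)
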