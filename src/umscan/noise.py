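"""Bead-level noise statistics for probe-failure detection.

The across-bead standard deviations stored alongside the channel means allow
a per-probe, per-sample noise-to-signal statistic:

    R_hat   = (sigma_M + sigma_U + 100) / (U + M + 100)
    CV_logT = 1 / (ln(mu_T) / R_hat - R_hat / 2),   mu_T = U + M + 100

CV_logT approximates the coefficient of variation of the log total signal,
sigma_lnT / mu_lnT (exact for a lognormal total up to O(R^3) terms).  Probe
failure acquires background-only fluorescence, where R_hat (and hence
CV_logT) is large; when failure strikes only one genotype class the CV_logT
distribution across samples turns bimodal.  Two per-probe summaries capture
this: the bimodality coefficient BC(CV_logT), with 5/9 (the uniform
distribution's value) as the multimodality threshold, and the Pearson
correlation of CV_logT between monozygotic co-twins, cor_MZ(CV_logT), with a
conservative 0.8 threshold as a genetic control.  A probe with BC > 5/9 and
cor_MZ > 0.8 is flagged as ambivalent, genetics-related failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intensity import CohortDesign, IntensityMatrices

logger = logging.getLogger(__name__)

BC_UNIFORM = 5.0 / 9.0  # expected bimodality coefficient of a uniform variable

__all__ = [
    "BC_UNIFORM",
    "NoiseStatistics",
    "compute_R",
    "compute_cv_logt",
    "cv_logt_from_r",
    "bimodality_coefficient",
    "cor_mz",
    "flag_ambivalent_failure",
    "compute_noise_statistics",
]


def compute_R(intens: IntensityMatrices, offset: float = 100.0) -> pd.DataFrame:
    """Noise-to-signal ratio R_hat = (sigma_M + sigma_U + offset)/(U + M + offset)."""
    return (intens.sigma_M + intens.sigma_U + offset) / (intens.M + intens.U + offset)


def compute_cv_logt(intens: IntensityMatrices, offset: float = 100.0) -> pd.DataFrame:
    """Per-entry CV_logT = 1 / (ln(mu_T)/R - R/2) with mu_T = U + M + offset.

    Natural log throughout: the identification of CV_logT with
    sigma_lnT/mu_lnT only holds in base e.  Entries with a non-positive
    denominator (unrealistically large R) are set to missing with a logged
    count.
    """
    r = compute_R(intens, offset).to_numpy(dtype=float)
    mu_t = (intens.U + intens.M + offset).to_numpy(dtype=float)
    denom = np.log(mu_t) / r - r / 2.0
    bad = denom <= 0
    if bad.any():
        logger.warning("CV_logT: %d entries with non-positive denominator set to NA", bad.sum())
        denom = np.where(bad, np.nan, denom)
    return pd.DataFrame(1.0 / denom, index=intens.probe_ids, columns=intens.sample_ids)


def cv_logt_from_r(r: float | np.ndarray, mu_t: float | np.ndarray) -> float | np.ndarray:
    """CV_logT predicted from a known coefficient of variation r of the total.

    Identical to the entrywise formula, 1/(ln(mu_t)/r - r/2); useful for
    checking the lognormal approximation against simulated totals.
    """
    return 1.0 / (np.log(mu_t) / r - r / 2.0)


def bimodality_coefficient(x: np.ndarray | pd.DataFrame, axis: int = -1) -> float | np.ndarray | pd.Series:
    """Moment-based bimodality coefficient BC = (g1^2 + 1) / (g2 + c_n).

    g1 is the sample skewness m3/m2^1.5 and g2 the sample excess kurtosis
    m4/m2^2 - 3, both from biased central moments; c_n is the finite-sample
    correction 3(n-1)^2 / ((n-2)(n-3)).  Values above 5/9 point to bi- or
    multimodality.  Requires n >= 4 non-missing values and a non-constant
    input; otherwise returns missing.  Accepts a vector or a matrix (reduced
    along ``axis``; for a DataFrame, per row).
    """
    if isinstance(x, pd.DataFrame):
        vals = bimodality_coefficient(x.to_numpy(dtype=float), axis=1)
        return pd.Series(vals, index=x.index, name="bc")
    arr = np.asarray(x, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
        axis = 1
    arr = np.moveaxis(arr, axis, -1)
    mask = np.isfinite(arr)
    n = mask.sum(axis=-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(np.where(mask, arr, 0.0), axis=-1) / n
        d = np.where(mask, arr - mean[..., None], 0.0)
        m2 = (d**2).sum(axis=-1) / n
        m3 = (d**3).sum(axis=-1) / n
        m4 = (d**4).sum(axis=-1) / n
        g1 = m3 / m2**1.5
        g2 = m4 / m2**2 - 3.0
        corr = 3.0 * (n - 1.0) ** 2 / ((n - 2.0) * (n - 3.0))
        bc = (g1**2 + 1.0) / (g2 + corr)
    bc = np.where((n >= 4) & (m2 > 0), bc, np.nan)
    return float(bc[0]) if squeeze else bc


def _pair_columns(stat: pd.DataFrame, cohort: CohortDesign) -> tuple[np.ndarray, np.ndarray]:
    pairs = [p for p in cohort.twin_pairs() if p[0] in stat.columns and p[1] in stat.columns]
    if len(pairs) < 3:
        raise ValueError("cor_mz requires at least 3 complete twin pairs")
    a_ids, b_ids = zip(*pairs)
    return stat[list(a_ids)].to_numpy(float), stat[list(b_ids)].to_numpy(float)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation per row over pairwise-complete columns."""
    ok = np.isfinite(a) & np.isfinite(b)
    n = ok.sum(axis=1).astype(float)
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = a.sum(axis=1) / n
        mb = b.sum(axis=1) / n
        da = np.where(ok, a - ma[:, None], 0.0)
        db = np.where(ok, b - mb[:, None], 0.0)
        va = (da**2).sum(axis=1)
        vb = (db**2).sum(axis=1)
        r = (da * db).sum(axis=1) / np.sqrt(va * vb)
    r = np.where((n >= 3) & (va > 0) & (vb > 0), r, np.nan)
    return r


def cor_mz(stat: pd.DataFrame, cohort: CohortDesign) -> pd.Series:
    """Per-probe Pearson correlation of a statistic between MZ co-twins.

    Twin ordering inside a pair is fixed by lexicographic sample-id sort.
    Probes with a constant vector on either side are missing.
    """
    a, b = _pair_columns(stat, cohort)
    return pd.Series(_rowwise_pearson(a, b), index=stat.index, name="cor_mz")


def flag_ambivalent_failure(
    bc: pd.Series | np.ndarray,
    cor: pd.Series | np.ndarray,
    bc_thresh: float = BC_UNIFORM,
    cor_thresh: float = 0.8,
) -> pd.Series | np.ndarray:
    """Genetics-related probe failure flag: BC > 5/9 AND cor_MZ > 0.8.

    Strict inequalities; missing inputs yield False with a logged count.
    """
    bc_arr = np.asarray(bc, dtype=float)
    cor_arr = np.asarray(cor, dtype=float)
    if bc_arr.shape != cor_arr.shape:
        raise ValueError("bc and cor vectors must be aligned")
    n_missing = int((~np.isfinite(bc_arr) | ~np.isfinite(cor_arr)).sum())
    if n_missing:
        logger.warning("flag_ambivalent_failure: %d probes with missing inputs -> False", n_missing)
    with np.errstate(invalid="ignore"):
        flags = (bc_arr > bc_thresh) & (cor_arr > cor_thresh)
    if isinstance(bc, pd.Series):
        return pd.Series(flags, index=bc.index, name="ambivalent_failure")
    return flags


@dataclass
class NoiseStatistics:
    """Bundle of per-entry and per-probe noise statistics."""

    R_hat: pd.DataFrame
    cv_logt: pd.DataFrame
    bc: pd.Series
    cor_mz: pd.Series | None
    flags: pd.Series


def compute_noise_statistics(
    intens: IntensityMatrices,
    cohort: CohortDesign | None = None,
    offset: float = 100.0,
    bc_thresh: float = BC_UNIFORM,
    cor_thresh: float = 0.8,
) -> NoiseStatistics:
    """Compute R_hat, CV_logT, BC, cor_MZ (if twins available) and the flag."""
    r_hat = compute_R(intens, offset)
    cv = compute_cv_logt(intens, offset)
    bc = bimodality_coefficient(cv)
    cor = None
    if cohort is not None and cohort.twin_pair_id:
        try:
            cor = cor_mz(cv, cohort)
        except ValueError as exc:
            logger.warning("cor_MZ disabled: %s", exc)
    if cor is None:
        flags = pd.Series(False, index=cv.index, name="ambivalent_failure")
    else:
        flags = flag_ambivalent_failure(bc, cor, bc_thresh, cor_thresh)
    return NoiseStatistics(R_hat=r_hat, cv_logt=cv, bc=bc, cor_mz=cor, flags=flags)
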