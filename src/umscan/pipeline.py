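"""Epigenome-wide artifact scan tying the modules into one report.

``scan`` runs the per-probe statistics over a whole intensity matrix:
CV_logT, its bimodality coefficient, the twin correlation control (when
pairing is available), the dbscan K-call, and the ambivalent-failure flag;
optionally merges mechanistic variant classifications and co-methylation
verdicts.  The report has exactly one row per input probe -- probes that a
step cannot handle carry a reason instead of being silently dropped -- and a
metadata block sufficient to replay the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import version
from typing import Mapping

import numpy as np
import pandas as pd

from . import cometh, noise
from .clustering import KCallerParams, k_call
from .intensity import (
    CohortDesign,
    IntensityMatrices,
    ProbeDesign,
    compute_mvalue,
    quantile_normalize,
)
from .variants import VariantRecord, classify_cpg_sbe_snp

logger = logging.getLogger(__name__)

__all__ = ["ScanParams", "ArtifactReport", "scan"]


@dataclass(frozen=True)
class ScanParams:
    """All thresholds of the scan, surfaced with their calibrated defaults."""

    offset: float = 100.0
    bc_thresh: float = noise.BC_UNIFORM
    cor_thresh: float = 0.8
    kcaller: KCallerParams = field(default_factory=KCallerParams)
    cometh_window_bp: int = 1000
    r2_threshold: float = 0.25
    seed: int = 0


@dataclass
class ArtifactReport:
    """Per-probe scan table plus replay metadata."""

    table: pd.DataFrame
    metadata: dict


def scan(
    intens: IntensityMatrices,
    cohort: CohortDesign | None = None,
    params: ScanParams = ScanParams(),
    designs: Mapping[str, ProbeDesign] | None = None,
    variants: Mapping[str, VariantRecord] | None = None,
    positions: pd.DataFrame | None = None,
) -> ArtifactReport:
    """Scan every probe for genetic-artifact signatures.

    ``variants`` maps probe_id -> overlapping variant (classified against
    ``designs``); ``positions`` (chrom/pos per probe) enables co-methylation
    verdicts.  Missing twin metadata disables cor_MZ with a warning rather
    than an error.  Deterministic for a fixed ``params.seed``.
    """
    probe_ids = intens.probe_ids
    n_probes = len(probe_ids)
    meta: dict = {
        "package_version": version("umscan"),
        "n_probes": n_probes,
        "n_samples": len(intens.sample_ids),
        "params": {
            "offset": params.offset,
            "bc_thresh": params.bc_thresh,
            "cor_thresh": params.cor_thresh,
            "eps": params.kcaller.eps,
            "min_pts": params.kcaller.min_pts,
            "cometh_window_bp": params.cometh_window_bp,
            "r2_threshold": params.r2_threshold,
            "seed": params.seed,
        },
    }
    table = pd.DataFrame(index=probe_ids)
    table["note"] = ""
    if n_probes == 0:
        return ArtifactReport(table=table, metadata=meta)

    stats = noise.compute_noise_statistics(
        intens, cohort, params.offset, params.bc_thresh, params.cor_thresh
    )
    table["bc"] = stats.bc
    table["cor_mz"] = stats.cor_mz if stats.cor_mz is not None else np.nan
    if stats.cor_mz is None and cohort is not None:
        logger.warning("scan: twin metadata unusable; cor_MZ disabled")
    table["ambivalent_failure"] = stats.flags

    k_calls = np.full(n_probes, -1)
    um = np.stack([intens.U.to_numpy(float), intens.M.to_numpy(float)], axis=2)
    for i, pid in enumerate(probe_ids):
        pts = um[i]
        if pts.shape[0] < params.kcaller.min_pts:
            table.loc[pid, "note"] = "too few samples for K-calling"
            continue
        k_calls[i] = k_call(pts, params.kcaller)
    table["k_call"] = np.where(k_calls >= 0, k_calls, np.nan)

    if variants is not None:
        cats, sites, eks = {}, {}, {}
        for pid, var in variants.items():
            if pid not in table.index:
                continue
            if designs is None or pid not in designs:
                table.loc[pid, "note"] = "variant supplied without probe design"
                continue
            call = classify_cpg_sbe_snp(designs[pid], var)
            cats[pid] = call.category.value
            sites[pid] = call.site.value
            ek = call.expected_k
            eks[pid] = ek if ek is not None else np.nan
        table["category"] = pd.Series(cats).reindex(table.index)
        table["site"] = pd.Series(sites).reindex(table.index)
        table["expected_k"] = pd.Series(eks).reindex(table.index)

    if positions is not None:
        mq = quantile_normalize(compute_mvalue(intens))
        verdicts = {}
        for pid in probe_ids:
            if pid not in positions.index:
                table.loc[pid, "note"] = "no genomic position; co-methylation skipped"
                continue
            prof = cometh.comethylation_profile(
                mq, positions, pid,
                window_bp=params.cometh_window_bp,
                cohort=cohort,
                r2_threshold=params.r2_threshold,
            )
            verdicts[pid] = prof.verdict.value
        table["verdict"] = pd.Series(verdicts).reindex(table.index)

    assert len(table) == n_probes, "report must keep one row per input probe"
    return ArtifactReport(table=table, metadata=meta)
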