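"""End-to-end fitting pipelines: replicate matrices in, results table out."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import (
    HillFit,
    MeanProfile,
    QCThresholds,
    ThetaProfile,
    aggregate_replicates,
    assess_and_filter,
    compute_fraction_bound,
    fit_hill,
    minmax_scale,
    replicate_cv,
)
from .competition import CompetitionConfig, cheng_prusoff, fit_ic50
from .quant_io import ChannelMap, ReporterMatrix, normalize_total_signal

logger = logging.getLogger(__name__)


def _profiles_by_protein(
    matrices: Sequence[ReporterMatrix],
    channel_map: ChannelMap,
    normalize: bool = True,
    scale_per_replicate: bool = False,
    reference: str | None = None,
) -> dict[str, list[ThetaProfile]]:
    """theta per replicate, optionally min-max scaled per replicate.

    Incomplete profiles are dropped here (the completeness rule: theta must be
    measured at every titration point of every replicate); degenerate
    (constant) profiles are dropped after scaling.
    """
    by_protein: dict[str, list[ThetaProfile]] = {}
    for m in matrices:
        mat = normalize_total_signal(m) if normalize else m
        for prof in compute_fraction_bound(mat, channel_map, reference=reference):
            if not prof.complete:
                continue
            if scale_per_replicate:
                prof = minmax_scale(prof)
                if prof.degenerate:
                    logger.warning("%s/%s: constant profile dropped", m.replicate_id, prof.protein)
                    continue
            by_protein.setdefault(prof.protein, []).append(prof)
    return by_protein


def fit_titration(
    matrices: Sequence[ReporterMatrix],
    channel_map: ChannelMap,
    qc: QCThresholds,
    n_boot: int = 1000,
    seed: int = 0,
    normalize: bool = True,
    scale_per_replicate: bool = False,
    min_replicates: int | None = None,
) -> pd.DataFrame:
    """Fit Kd_app for every protein measured completely in every replicate.

    Returns one row per fitted protein with columns protein, bait, kd_app_nM,
    hill_n, r2, theta_pred_low, theta_pred_high, qc_pass, cv, n_replicates.
    Min-max scaling is applied to the replicate-averaged profile by default:
    scaling each noisy replicate separately anchors the scale on the most
    extreme noise excursion of that replicate and systematically flattens the
    apparent saturation, so averaging first is measurably more accurate
    (``scale_per_replicate=True`` restores the alternative order).  The CV is
    computed from replicate-wise fits of QC-passing proteins (the same
    initialization and bounds as the mean-profile fit) and is NaN when fewer
    than two replicate fits converge.
    """
    bait = matrices[0].bait_id if matrices else ""
    n_expected = min_replicates if min_replicates is not None else len(matrices)
    by_protein = _profiles_by_protein(matrices, channel_map, normalize, scale_per_replicate)
    records = []
    for protein in sorted(by_protein):
        profiles = by_protein[protein]
        if len(profiles) < n_expected:
            logger.warning("%s: measured in %d/%d replicates, dropped", protein, len(profiles), n_expected)
            continue
        mean = aggregate_replicates(profiles, n_boot=n_boot, seed=seed)
        if not scale_per_replicate:
            scaled = minmax_scale(
                ThetaProfile(protein, "mean", mean.mean_theta, complete=True)
            )
            if scaled.degenerate:
                continue
            mean = MeanProfile(protein, scaled.theta, mean.sem_theta, mean.n_replicates)
        fit = fit_hill(mean, channel_map)
        assess_and_filter([fit], qc)
        cv = np.nan
        if fit.qc_pass and len(profiles) >= 2:
            rep_kds = []
            for prof in profiles:
                rep = prof if scale_per_replicate else minmax_scale(prof)
                if rep.degenerate:
                    continue
                rf = fit_hill(
                    MeanProfile(protein, rep.theta, np.zeros_like(rep.theta), 1),
                    channel_map,
                )
                if rf.converged:
                    rep_kds.append(rf.kd_app)
            cv_val = replicate_cv(rep_kds)
            cv = cv_val if cv_val is not None else np.nan
        records.append(
            {
                "protein": protein,
                "bait": bait,
                "kd_app_nM": fit.kd_app,
                "hill_n": fit.hill_n,
                "r2": fit.r2,
                "theta_pred_low": fit.theta_pred_low,
                "theta_pred_high": fit.theta_pred_high,
                "qc_pass": fit.qc_pass,
                "cv": cv,
                "n_replicates": mean.n_replicates,
            }
        )
    return pd.DataFrame(records)


def fit_competition(
    matrices: Sequence[ReporterMatrix],
    channel_map: ChannelMap,
    kd_immobilized: float,
    cfg: CompetitionConfig = CompetitionConfig(),
    n_boot: int = 1000,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Fit IC50s on a competition series and Cheng-Prusoff-correct to Kd_app.

    Retained signal is anchored at 1 by ratioing to the lightest channel (the
    lowest competitor concentration, where binding is maximal) — the
    competition-mode analogue of the titration's saturating reference.  No
    data-driven rescale follows: the ratio is already a retention fraction on
    [0, 1], and forcing the observed top-concentration point to 0 would bias
    the IC50 downward whenever displacement is incomplete.  kd_free_nM is
    reported only for QC-passing fits.
    """
    bait = matrices[0].bait_id if matrices else ""
    by_protein = _profiles_by_protein(
        matrices, channel_map, normalize,
        scale_per_replicate=False, reference=channel_map.channel_labels[0],
    )
    records = []
    for protein in sorted(by_protein):
        profiles = by_protein[protein]
        if len(profiles) < len(matrices):
            continue
        mean = aggregate_replicates(profiles, n_boot=n_boot, seed=seed)
        fit = fit_ic50(mean, channel_map, cfg)
        kd_free = (
            cheng_prusoff(fit.ic50, kd_immobilized, cfg) if fit.qc_pass else np.nan
        )
        records.append(
            {
                "protein": protein,
                "bait": bait,
                "ic50_nM": fit.ic50,
                "hill_n": fit.hill_n,
                "r2": fit.r2,
                "qc_pass": fit.qc_pass,
                "kd_free_nM": kd_free,
                "n_replicates": mean.n_replicates,
            }
        )
    return pd.DataFrame(records)
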