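"""Hill-model fitting of fraction-bound titration profiles.

Workflow for one bait: reporter intensities are converted to fraction bound
theta (ratio of each titration point to the saturating reference channel),
min-max scaled to [0, 1] per replicate, averaged across replicates, and the
mean profile is fit by nonlinear least squares to the Hill-like saturation
curve

    theta(L) = 1 / ((Kd_app / L)^n + 1)

where L is the bait concentration, Kd_app the apparent dissociation constant
and n the Hill coefficient.  Fits are quality-filtered on goodness of fit
(squared Pearson correlation between observed and fitted values) and on the
predicted endpoints: a genuine nanomolar binder should be nearly unbound at
the lowest titration point and nearly saturated at the highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .errors import DomainError
from .quant_io import ChannelMap, ReporterMatrix

logger = logging.getLogger(__name__)

#: Solver initialization: Kd_app = 100 nM, n = 1.
INIT_KD_NM = 100.0
INIT_HILL_N = 1.0
#: Box bounds keep the solver stable on background proteins while spanning
#: every plausible affinity (sub-pM to 100 uM) and cooperativity.
KD_BOUNDS_NM = (1e-3, 1e5)
HILL_N_BOUNDS = (0.1, 10.0)


@dataclass
class ThetaProfile:
    """Per-replicate fraction-bound vector for one protein."""

    protein: str
    replicate_id: str
    theta: np.ndarray
    complete: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)


@dataclass
class MeanProfile:
    """Replicate-averaged scaled profile with bootstrap SEM per point."""

    protein: str
    mean_theta: np.ndarray
    sem_theta: np.ndarray
    n_replicates: int


@dataclass
class HillFit:
    """Fitted binding parameters and QC verdict for one protein."""

    protein: str
    kd_app: float
    hill_n: float
    r2: float
    theta_pred_low: float
    theta_pred_high: float
    converged: bool
    qc_pass: bool = False


@dataclass(frozen=True)
class QCThresholds:
    """Acceptance thresholds for fitted binding curves.

    ``r2_min`` is 0.95 for DNA-oligo experiments and 0.90 for nucleosome
    experiments; the endpoint rules require the predicted fraction bound to be
    below 0.25 at the lowest and above 0.75 at the highest titration point.
    """

    r2_min: float
    theta_low_max: float = 0.25
    theta_high_min: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.r2_min < 1:
            raise ValueError("r2_min must lie in (0, 1)")
        if not 0 <= self.theta_low_max < self.theta_high_min <= 1:
            raise ValueError("endpoint thresholds must satisfy 0 <= low < high <= 1")

    @classmethod
    def preset(cls, name: str) -> "QCThresholds":
        presets = {"dna": 0.95, "nucleosome": 0.90}
        try:
            return cls(r2_min=presets[name])
        except KeyError:
            raise ValueError(f"unknown QC preset {name!r}") from None


def hill_theta(L, kd: float, n: float):
    """Fraction bound at bait concentration ``L`` (nM) under the Hill model.

    Returns ``1 / ((kd / L)**n + 1)``; strictly increasing in L, equal to 0.5
    at L = kd for every n.  All arguments must be positive.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0) or kd <= 0 or n <= 0:
        raise DomainError("hill_theta requires positive L, kd and n")
    out = 1.0 / ((kd / L) ** n + 1.0)
    return float(out) if out.ndim == 0 else out


def compute_fraction_bound(
    m: ReporterMatrix, channel_map: ChannelMap, reference: str | None = None
) -> list[ThetaProfile]:
    """Ratio each protein's channel intensities to the reference channel.

    The reference (top-concentration) point is 1 by construction.  Rows with a
    missing channel, or a missing/zero reference intensity, come back with
    ``complete=False`` and are excluded from fitting downstream.  For
    competition-mode data pass ``reference`` as the lightest channel (lowest
    competitor concentration, maximal binding) instead.
    """
    ref = reference if reference is not None else channel_map.reference_channel
    if ref not in channel_map.channel_labels:
        raise ValueError(f"reference {ref!r} is not a channel label")
    profiles: list[ThetaProfile] = []
    order = list(channel_map.channel_labels)
    for protein, row in m.intensities[order].iterrows():
        vals = row.to_numpy(dtype=float)
        ref_val = row[ref]
        if np.isnan(ref_val) or ref_val <= 0:
            logger.warning(
                "%s/%s: reference channel missing or zero; profile incomplete",
                m.replicate_id, protein,
            )
            profiles.append(ThetaProfile(str(protein), m.replicate_id, vals * np.nan, False))
            continue
        theta = vals / ref_val
        complete = not np.isnan(theta).any()
        profiles.append(ThetaProfile(str(protein), m.replicate_id, theta, complete))
    return profiles


def minmax_scale(p: ThetaProfile) -> ThetaProfile:
    """Rescale a complete profile linearly so min = 0 and max = 1.

    A constant profile cannot be scaled and is flagged degenerate instead.
    """
    if not p.complete:
        raise ValueError(f"cannot scale incomplete profile for {p.protein}")
    lo, hi = float(np.min(p.theta)), float(np.max(p.theta))
    if hi <= lo:
        return replace(p, degenerate=True)
    return replace(p, theta=(p.theta - lo) / (hi - lo))


def aggregate_replicates(
    profiles: Sequence[ThetaProfile], n_boot: int = 1000, seed: int = 0
) -> MeanProfile:
    """Pointwise mean across replicates with a bootstrap SEM.

    The SEM at each titration point is the standard deviation of means of
    ``n_boot`` resamples drawn with replacement over replicates.  With a
    single replicate the SEM is zero and a warning is logged.
    """
    usable = [p for p in profiles if p.complete and not p.degenerate]
    if not usable:
        raise ValueError("no complete, non-degenerate replicate profiles to aggregate")
    protein = usable[0].protein
    stack = np.vstack([p.theta for p in usable])
    mean = stack.mean(axis=0)
    n_rep = stack.shape[0]
    if n_rep == 1:
        logger.warning("%s: single replicate, SEM set to 0", protein)
        sem = np.zeros_like(mean)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
        boot_means = stack[idx].mean(axis=1)
        sem = boot_means.std(axis=0, ddof=1)
    return MeanProfile(protein, mean, sem, n_rep)


def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and fitted values."""
    if np.std(observed) == 0 or np.std(predicted) == 0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


def fit_hill(p: MeanProfile, channel_map: ChannelMap) -> HillFit:
    """Least-squares fit of the Hill curve to a mean profile.

    Starts at Kd_app = 100 nM, n = 1 with box bounds Kd in [1e-3, 1e5] nM and
    n in [0.1, 10].  Non-convergence is reported through the ``converged``
    flag, never raised.
    """
    L = np.asarray(channel_map.concentrations, dtype=float)
    y = np.asarray(p.mean_theta, dtype=float)
    try:
        popt, _ = optimize.curve_fit(
            hill_theta, L, y,
            p0=[INIT_KD_NM, INIT_HILL_N],
            bounds=([KD_BOUNDS_NM[0], HILL_N_BOUNDS[0]], [KD_BOUNDS_NM[1], HILL_N_BOUNDS[1]]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return HillFit(p.protein, float("nan"), float("nan"), float("nan"),
                       float("nan"), float("nan"), converged=False)
    kd, n = float(popt[0]), float(popt[1])
    pred = hill_theta(L, kd, n)
    return HillFit(
        protein=p.protein,
        kd_app=kd,
        hill_n=n,
        r2=_r_squared(y, pred),
        theta_pred_low=float(pred[0]),
        theta_pred_high=float(pred[-1]),
        converged=True,
    )


def assess_and_filter(
    fits: Iterable[HillFit], thresholds: QCThresholds
) -> list[HillFit]:
    """Apply the QC filter and return the accepted fits.

    A fit passes iff it converged, its r^2 meets the preset minimum, and the
    predicted endpoints show near-complete depletion at the bottom
    (< ``theta_low_max``) and near-saturation at the top
    (> ``theta_high_min``) of the titration.  ``qc_pass`` is set in place on
    every fit.
    """
    accepted = []
    for f in fits:
        f.qc_pass = bool(
            f.converged
            and np.isfinite(f.r2)
            and f.r2 >= thresholds.r2_min
            and f.theta_pred_low < thresholds.theta_low_max
            and f.theta_pred_high > thresholds.theta_high_min
        )
        if f.qc_pass:
            accepted.append(f)
    return accepted


def replicate_cv(kd_values: Sequence[float]) -> float | None:
    """Coefficient of variation of replicate-wise fitted Kd_app values.

    Sample standard deviation over mean; undefined (None) with fewer than two
    values.
    """
    vals = np.asarray([v for v in kd_values if np.isfinite(v)], dtype=float)
    if vals.size < 2:
        return None
    return float(vals.std(ddof=1) / vals.mean())
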