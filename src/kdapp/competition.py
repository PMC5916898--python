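"""Competition titrations: IC50 fitting and the Cheng-Prusoff correction.

In a competition experiment the bait stays immobilized at a fixed
concentration while a free competitor ligand is titrated; the retained signal
of a specifically bound protein falls from 1 to 0 with a decreasing Hill
shape.  The half-displacement point IC50 is converted to an apparent
dissociation constant for the free ligand via

    Kd_app_free = IC50 / (1 + [immobilized] / Kd_app_immobilized)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .binding import (
    HILL_N_BOUNDS,
    INIT_HILL_N,
    INIT_KD_NM,
    KD_BOUNDS_NM,
    MeanProfile,
    _r_squared,
)
from .errors import DomainError
from .quant_io import ChannelMap


@dataclass(frozen=True)
class CompetitionConfig:
    """Immobilized-bait context for a competition series.

    ``immobilized_conc`` defaults to 200 nM, the bead-coupled oligo
    concentration used during the pre-incubation step.
    """

    immobilized_conc: float = 200.0
    r2_min: float = 0.95

    def __post_init__(self) -> None:
        if self.immobilized_conc <= 0:
            raise ValueError("immobilized concentration must be positive")


@dataclass
class CompetitionFit:
    """Fitted IC50 (nM), Hill slope and QC verdict for one protein."""

    protein: str
    ic50: float
    hill_n: float
    r2: float
    retention_pred_low: float
    retention_pred_high: float
    converged: bool
    qc_pass: bool = False


def competition_theta(L, ic50: float, n: float):
    """Retained (bound) fraction at free-competitor concentration ``L`` (nM).

    The decreasing mirror of the Hill curve: 1 - 1/((IC50/L)^n + 1), equal to
    0.5 at L = IC50.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0) or ic50 <= 0 or n <= 0:
        raise DomainError("competition_theta requires positive L, ic50 and n")
    out = 1.0 - 1.0 / ((ic50 / L) ** n + 1.0)
    return float(out) if out.ndim == 0 else out


def fit_ic50(
    p: MeanProfile, channel_map: ChannelMap, cfg: CompetitionConfig = CompetitionConfig()
) -> CompetitionFit:
    """Fit the decreasing competition curve to a scaled mean profile.

    Uses the same initialization (100 nM, n = 1) and box bounds as the direct
    Hill fit.  QC requires r^2 >= ``cfg.r2_min`` and predicted retention
    > 0.75 at the lowest and < 0.25 at the highest competitor concentration —
    i.e. the protein starts fully bound and is displaced essentially
    completely.  A non-competed (flat or increasing) profile fails QC.
    """
    L = np.asarray(channel_map.concentrations, dtype=float)
    y = np.asarray(p.mean_theta, dtype=float)
    try:
        popt, _ = optimize.curve_fit(
            competition_theta, L, y,
            p0=[INIT_KD_NM, INIT_HILL_N],
            bounds=([KD_BOUNDS_NM[0], HILL_N_BOUNDS[0]], [KD_BOUNDS_NM[1], HILL_N_BOUNDS[1]]),
            maxfev=10000,
        )
        converged = True
        ic50, n = float(popt[0]), float(popt[1])
        pred = competition_theta(L, ic50, n)
        r2 = _r_squared(y, pred)
        lo, hi = float(pred[0]), float(pred[-1])
    except (RuntimeError, ValueError):
        converged = False
        ic50 = n = r2 = lo = hi = float("nan")
    fit = CompetitionFit(p.protein, ic50, n, r2, lo, hi, converged)
    fit.qc_pass = bool(
        converged and np.isfinite(r2) and r2 >= cfg.r2_min and lo > 0.75 and hi < 0.25
    )
    return fit


def cheng_prusoff(
    ic50: float, kd_immobilized: float, cfg: CompetitionConfig = CompetitionConfig()
) -> float:
    """Convert a competition IC50 into the free ligand's Kd_app (nM).

    ``kd_free = ic50 / (1 + immobilized_conc / kd_immobilized)``; monotone
    increasing in both the IC50 and the immobilized bait's Kd, and tending to
    the raw IC50 as the immobilized bait becomes arbitrarily weak.
    """
    if ic50 <= 0 or kd_immobilized <= 0:
        raise DomainError("cheng_prusoff requires positive ic50 and kd_immobilized")
    return ic50 / (1.0 + cfg.immobilized_conc / kd_immobilized)
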