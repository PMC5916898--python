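"""Synthetic data with known ground truth for every pipeline stage.

The titration simulator draws specific binders whose expected reporter
intensity follows the Hill saturation curve and background proteins whose
expected intensity is flat across the titration (binding is
concentration-independent for non-specific carry-over), both under
multiplicative log-normal noise — the standard noise model for reporter-ion
intensities.  The log-normal sigma is chosen so that ``noise_cv`` is the
linear-scale coefficient of variation: sigma^2 = ln(1 + cv^2).

The competition simulator inverts the Cheng-Prusoff relation, giving each
specific binder an IC50 of ``true_kd * (1 + immobilized_conc /
kd_immobilized)`` so that the fit-and-correct pipeline should land back on
``true_kd``.

All simulators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .binding import hill_theta
from .competition import competition_theta
from .intervals import GenomicInterval, validate_genome
from .quant_io import ChannelMap, ExperimentDesign, ReporterMatrix


@dataclass(frozen=True)
class SimProteinSpec:
    """Ground truth for one simulated protein."""

    id: str
    specific: bool
    true_kd: float | None
    true_n: float | None
    abundance: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.specific and (self.true_kd is None or self.true_kd <= 0):
            raise ValueError("specific proteins need a positive true_kd")
        if self.specific and (self.true_n is None or self.true_n <= 0):
            raise ValueError("specific proteins need a positive true_n")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated titration or competition screen.

    Defaults mirror a typical screen: a ten-point, 3-fold titration from
    3 uM in triplicate, specific binders with Kd log-uniform across the
    nanomolar range, a large flat background, and 10% multiplicative noise.
    Abundances span three orders of magnitude (log-uniform) so recovery can
    be checked for abundance bias.
    """

    n_specific: int = 50
    n_background: int = 500
    kd_range: tuple[float, float] = (5.0, 500.0)
    hill_n: float = 1.0
    noise_cv: float = 0.10
    replicates: int = 3
    design: ExperimentDesign = field(
        default_factory=lambda: ExperimentDesign(top_concentration=3000.0)
    )
    seed: int = 0
    abundance_range: tuple[float, float] = (1e5, 1e8)
    background_slope: float = 0.0  # optional "sticky" background tilt per log10 conc
    dropout_rate: float = 0.0  # probability a cell is set missing

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_specific < 0 or self.n_background < 0:
            raise ValueError("protein counts must be >= 0")
        lo, hi = self.kd_range
        if not 0 < lo <= hi:
            raise ValueError("kd_range must be positive and ordered")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _draw_specs(cfg: SimConfig, rng: np.random.Generator) -> list[SimProteinSpec]:
    specs: list[SimProteinSpec] = []
    lo, hi = cfg.kd_range
    alo, ahi = cfg.abundance_range
    for i in range(cfg.n_specific):
        kd = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        ab = float(10 ** rng.uniform(np.log10(alo), np.log10(ahi)))
        specs.append(SimProteinSpec(f"SPEC_{i + 1:04d}", True, kd, cfg.hill_n, ab))
    for i in range(cfg.n_background):
        ab = float(10 ** rng.uniform(np.log10(alo), np.log10(ahi)))
        specs.append(SimProteinSpec(f"BG_{i + 1:04d}", False, None, None, ab))
    return specs


def _truth_table(specs: list[SimProteinSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [s.id for s in specs],
            "specific": [s.specific for s in specs],
            "true_kd": [s.true_kd if s.specific else np.nan for s in specs],
            "true_n": [s.true_n if s.specific else np.nan for s in specs],
            "abundance": [s.abundance for s in specs],
        }
    ).set_index("protein")


def _noisy_matrices(
    expected: np.ndarray,
    specs: list[SimProteinSpec],
    cmap: ChannelMap,
    cfg: SimConfig,
    rng: np.random.Generator,
    bait_id: str,
) -> list[ReporterMatrix]:
    sigma = _lognormal_sigma(cfg.noise_cv)
    matrices = []
    for r in range(cfg.replicates):
        noise = np.exp(rng.normal(0.0, sigma, size=expected.shape)) if sigma > 0 else 1.0
        vals = expected * noise
        if cfg.dropout_rate > 0:
            vals = np.where(rng.random(expected.shape) < cfg.dropout_rate, np.nan, vals)
        df = pd.DataFrame(
            vals, index=[s.id for s in specs], columns=list(cmap.channel_labels)
        )
        matrices.append(
            ReporterMatrix(
                experiment_id=f"sim_{bait_id}",
                bait_id=bait_id,
                replicate_id=f"rep{r + 1}",
                intensities=df,
            )
        )
    return matrices


def simulate_titration(cfg: SimConfig) -> tuple[list[ReporterMatrix], pd.DataFrame]:
    """Simulate one bait titration: one ReporterMatrix per replicate + truth.

    Specific protein intensity at concentration L is
    ``abundance * hill_theta(L, true_kd, true_n) * exp(eps)``; background is
    ``abundance * exp(eps)`` (optionally tilted by ``background_slope`` per
    decade of concentration), eps ~ Normal(0, sigma^2) i.i.d.
    """
    rng = np.random.default_rng(cfg.seed)
    cmap = cfg.design.channel_map()
    specs = _draw_specs(cfg, rng)
    L = np.asarray(cmap.concentrations)
    rows = []
    for s in specs:
        if s.specific:
            rows.append(s.abundance * hill_theta(L, s.true_kd, s.true_n))
        else:
            tilt = 10 ** (cfg.background_slope * np.log10(L / L[-1]))
            rows.append(s.abundance * tilt)
    expected = np.vstack(rows)
    matrices = _noisy_matrices(expected, specs, cmap, cfg, rng, bait_id="sim_bait")
    return matrices, _truth_table(specs)


def simulate_competition(
    cfg: SimConfig, kd_immobilized: float, immobilized_conc: float = 200.0
) -> tuple[list[ReporterMatrix], pd.DataFrame]:
    """Simulate a competition series against an immobilized bait.

    Each specific binder is displaced with
    ``IC50 = true_kd * (1 + immobilized_conc / kd_immobilized)`` so that
    fitting the decreasing curve and applying the Cheng-Prusoff correction
    recovers ``true_kd``.  Background proteins stay flat.
    """
    if kd_immobilized <= 0 or immobilized_conc <= 0:
        raise ValueError("kd_immobilized and immobilized_conc must be positive")
    rng = np.random.default_rng(cfg.seed)
    cmap = cfg.design.channel_map()
    specs = _draw_specs(cfg, rng)
    L = np.asarray(cmap.concentrations)
    rows = []
    truth = _truth_table(specs)
    ic50s = []
    for s in specs:
        if s.specific:
            ic50 = s.true_kd * (1.0 + immobilized_conc / kd_immobilized)
            rows.append(s.abundance * competition_theta(L, ic50, s.true_n))
            ic50s.append(ic50)
        else:
            rows.append(np.full_like(L, s.abundance, dtype=float))
            ic50s.append(np.nan)
    truth["true_ic50"] = ic50s
    expected = np.vstack(rows)
    matrices = _noisy_matrices(expected, specs, cmap, cfg, rng, bait_id="sim_competition")
    return matrices, truth


def simulate_interval_sets(
    genome: Mapping[str, int],
    n_chip: int,
    n_g4: int,
    frac_overlapping: float,
    length_bp: int,
    seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Simulate a ChIP peak set and a G4 peak set with known overlap.

    The G4 set is placed uniformly over the genome (chromosome chosen
    proportional to length).  A fraction ``frac_overlapping`` of chip peaks is
    placed to overlap a randomly chosen G4 peak by >= 1 bp; the rest are
    placed uniformly.
    """
    if not 0 <= frac_overlapping <= 1:
        raise ValueError("frac_overlapping must lie in [0, 1]")
    g = validate_genome(genome)
    chroms = list(g)
    lengths = np.array([g[c] for c in chroms], dtype=float)
    if length_bp <= 0 or length_bp > lengths.min():
        raise ValueError("length_bp must be positive and fit every chromosome")
    rng = np.random.default_rng(seed)

    def place_uniform() -> GenomicInterval:
        chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        start = int(rng.integers(0, g[chrom] - length_bp + 1))
        return GenomicInterval(chrom, start, start + length_bp)

    g4 = [place_uniform() for _ in range(n_g4)]
    n_over = int(round(frac_overlapping * n_chip))
    if n_over > 0 and not g4:
        raise ValueError("cannot place overlapping chip peaks without g4 peaks")
    chip: list[GenomicInterval] = []
    for _ in range(n_over):
        anchor = g4[int(rng.integers(0, len(g4)))]
        lo = max(0, anchor.start - length_bp + 1)
        hi = min(anchor.end - 1, g[anchor.chrom] - length_bp)
        start = int(rng.integers(lo, hi + 1))
        chip.append(GenomicInterval(anchor.chrom, start, start + length_bp))
    for _ in range(n_chip - n_over):
        chip.append(place_uniform())
    return chip, g4
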