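"""Reading, writing and normalizing reporter-ion quantification tables.

The central objects are :class:`ChannelMap`, which ties the ordered isobaric
reporter channels of one MS run to the bait concentrations of the titration
series, and :class:`ReporterMatrix`, the protein x channel intensity table for
one replicate of one bait.  Concentrations are in nM throughout the package;
configuration files may state uM and are converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidDesignError, NormalizationError, TableFormatError

logger = logging.getLogger(__name__)

#: Canonical TMT 10-plex reporter labels, lightest to heaviest.
TMT10_LABELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ChannelMap:
    """Ordered mapping of reporter channels to bait concentrations (nM).

    The heaviest channel carries the top (saturating) concentration and serves
    as the reference for fraction-bound ratios.  Concentrations must form a
    strictly increasing geometric series along the label order.
    """

    channel_labels: tuple[str, ...]
    concentrations: tuple[float, ...]
    reference_channel: str

    def __post_init__(self) -> None:
        labels = tuple(self.channel_labels)
        conc = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "channel_labels", labels)
        object.__setattr__(self, "concentrations", conc)
        if len(labels) != len(conc):
            raise InvalidDesignError("channel labels and concentrations differ in length")
        if len(set(labels)) != len(labels):
            raise InvalidDesignError("duplicate channel labels")
        if len(conc) < 2:
            raise InvalidDesignError("a titration needs at least two channels")
        if any(c <= 0 for c in conc):
            raise InvalidDesignError("all concentrations must be positive")
        diffs = np.diff(conc)
        if not np.all(diffs > 0):
            raise InvalidDesignError("concentrations must increase along the channel order")
        ratios = np.asarray(conc[1:]) / np.asarray(conc[:-1])
        if not np.allclose(ratios, ratios[0], rtol=_REL_TOL, atol=0.0):
            raise InvalidDesignError("successive concentration ratios are not constant")
        if self.reference_channel != labels[-1]:
            raise InvalidDesignError(
                "reference channel must be the heaviest label (top concentration)"
            )

    @property
    def n_points(self) -> int:
        return len(self.channel_labels)

    @property
    def dilution_factor(self) -> float:
        return self.concentrations[1] / self.concentrations[0]

    @property
    def top_concentration(self) -> float:
        return self.concentrations[-1]

    def concentration_of(self, label: str) -> float:
        return self.concentrations[self.channel_labels.index(label)]


def build_channel_map(
    top_concentration: float,
    dilution_factor: float,
    n_points: int,
    channel_labels: Sequence[str] | None = None,
) -> ChannelMap:
    """Construct a serial-dilution channel map.

    Channel ``i`` (0-indexed from the lightest label) is assigned
    ``top_concentration / dilution_factor**(n_points - 1 - i)`` nM; the
    heaviest label becomes the reference.  The default ten-point, 3-fold
    design from 3000 nM bottoms out at ~0.15 nM.
    """
    if top_concentration <= 0:
        raise InvalidDesignError("top concentration must be positive")
    if dilution_factor <= 1:
        raise InvalidDesignError(f"dilution factor must exceed 1, got {dilution_factor}")
    if n_points < 3:
        raise InvalidDesignError("need at least 3 titration points")
    if channel_labels is None:
        if n_points == len(TMT10_LABELS):
            channel_labels = TMT10_LABELS
        else:
            channel_labels = tuple(f"ch{i + 1}" for i in range(n_points))
    if len(channel_labels) != n_points:
        raise InvalidDesignError("number of labels must equal n_points")
    conc = tuple(
        top_concentration / dilution_factor ** (n_points - 1 - i) for i in range(n_points)
    )
    return ChannelMap(tuple(channel_labels), conc, channel_labels[-1])


@dataclass(frozen=True)
class ExperimentDesign:
    """Titration design: top concentration, dilution factor, points, replicates."""

    top_concentration: float
    dilution_factor: float = 3.0
    n_points: int = 10
    replicates: int = 3
    qc_preset: str = "dna"

    def __post_init__(self) -> None:
        if self.qc_preset not in ("dna", "nucleosome"):
            raise InvalidDesignError(f"unknown qc preset {self.qc_preset!r}")
        if self.replicates < 1:
            raise InvalidDesignError("need at least one replicate")
        # delegates numeric validation to build_channel_map
        self.channel_map()

    def channel_map(self, channel_labels: Sequence[str] | None = None) -> ChannelMap:
        return build_channel_map(
            self.top_concentration, self.dilution_factor, self.n_points, channel_labels
        )


_UNIT_TO_NM = {"nm": 1.0, "um": 1e3, "µm": 1e3, "mm": 1e6, "pm": 1e-3}


def load_design(path: str | Path) -> tuple[ExperimentDesign, ChannelMap, dict]:
    """Load a YAML design file.

    Recognized keys: ``channels`` (label list), either ``top`` + ``factor`` or
    an explicit ``concentrations`` list, optional ``unit`` (default nM),
    ``reference``, ``qc_preset``, ``replicates``, ``seed``.
    Returns the design, its channel map, and the raw config dict.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unit = str(cfg.get("unit", "nM")).lower()
    if unit not in _UNIT_TO_NM:
        raise InvalidDesignError(f"unknown concentration unit {unit!r}")
    scale = _UNIT_TO_NM[unit]
    labels = cfg.get("channels")
    if "concentrations" in cfg:
        conc = tuple(float(c) * scale for c in cfg["concentrations"])
        if labels is None:
            labels = TMT10_LABELS if len(conc) == 10 else tuple(f"ch{i+1}" for i in range(len(conc)))
        ref = cfg.get("reference", labels[-1])
        cmap = ChannelMap(tuple(labels), conc, ref)
        design = ExperimentDesign(
            top_concentration=cmap.top_concentration,
            dilution_factor=cmap.dilution_factor,
            n_points=cmap.n_points,
            replicates=int(cfg.get("replicates", 3)),
            qc_preset=cfg.get("qc_preset", "dna"),
        )
    else:
        design = ExperimentDesign(
            top_concentration=float(cfg["top"]) * scale,
            dilution_factor=float(cfg.get("factor", 3)),
            n_points=int(cfg.get("n_points", len(labels) if labels else 10)),
            replicates=int(cfg.get("replicates", 3)),
            qc_preset=cfg.get("qc_preset", "dna"),
        )
        cmap = design.channel_map(labels)
    return design, cmap, cfg


@dataclass
class ReporterMatrix:
    """Protein x channel reporter intensities for one replicate of one bait.

    ``intensities`` is indexed by protein accession with one column per
    channel label; missing values are NaN.  Rows with a missing channel are
    retained but reported by :meth:`incomplete_rows` — the completeness rule
    is enforced at fitting time, not at read time.
    """

    experiment_id: str
    bait_id: str
    replicate_id: str
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if (vals < 0).any():
            raise TableFormatError("negative reporter intensity")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.intensities.columns)

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.intensities.index)

    def incomplete_rows(self) -> pd.Series:
        """Boolean per protein: True if any channel value is missing."""
        return self.intensities.isna().any(axis=1)


def read_reporter_table(
    path: str | Path,
    channel_map: ChannelMap,
    *,
    protein_col: str = "protein",
    experiment_id: str = "",
    bait_id: str = "",
    replicate_id: str = "",
) -> ReporterMatrix:
    """Read a tab-delimited intensity table into a :class:`ReporterMatrix`.

    The table must carry a protein-identifier column plus one column per
    channel label in ``channel_map``.  Empty cells become missing values.
    """
    df = pd.read_csv(path, sep="\t", dtype={protein_col: str})
    if protein_col not in df.columns:
        raise TableFormatError(f"missing protein identifier column {protein_col!r}")
    for label in channel_map.channel_labels:
        if label not in df.columns:
            raise TableFormatError(f"missing channel column {label!r}")
    mat = df.set_index(protein_col)[list(channel_map.channel_labels)].astype(float)
    neg = mat.lt(0).any(axis=1)
    if neg.any():
        idx = int(np.flatnonzero(neg.to_numpy())[0])
        raise TableFormatError(f"negative intensity at row {idx} ({mat.index[idx]})")
    rm = ReporterMatrix(
        experiment_id=experiment_id or Path(path).stem,
        bait_id=bait_id,
        replicate_id=replicate_id or Path(path).stem,
        intensities=mat,
    )
    n_inc = int(rm.incomplete_rows().sum())
    if n_inc:
        logger.warning("%s: %d rows with missing channel values flagged incomplete", path, n_inc)
    return rm


def normalize_total_signal(m: ReporterMatrix) -> ReporterMatrix:
    """Equalize channel totals to the mean of the original column totals.

    Emulates total-peptide-amount normalization: each channel column is
    rescaled by a single factor, preserving within-channel proportions.
    Idempotent; a channel summing to zero is an error.
    """
    totals = m.intensities.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise NormalizationError(f"channel {bad!r} has non-positive total signal")
    target = float(totals.mean())
    scaled = m.intensities * (target / totals)
    return ReporterMatrix(m.experiment_id, m.bait_id, m.replicate_id, scaled)


_RESULT_COLUMNS = [
    "protein", "bait", "kd_app_nM", "hill_n", "r2",
    "theta_pred_low", "theta_pred_high", "qc_pass", "cv", "n_replicates",
]


def write_results_table(records: Iterable[Mapping], path: str | Path) -> None:
    """Write fitted results as a TSV with a fixed column order.

    Floats are written with 6 significant digits; text and boolean fields
    round-trip bit-exact through :func:`read_results_table`.
    """
    rows = list(records)
    df = pd.DataFrame(rows, columns=_RESULT_COLUMNS if not rows else None)
    if rows:
        cols = [c for c in _RESULT_COLUMNS if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df = df[cols]
    parent = Path(path).parent
    if not parent.exists():
        raise OSError(f"directory does not exist: {parent}")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
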