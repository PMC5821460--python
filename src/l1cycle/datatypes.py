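"""Shared data containers for the L1 cell-cycle analysis pipeline.

These are thin, validated wrappers around numpy arrays and pandas
DataFrames. Observable tables generated in-package always travel with
their ground truth (phase labels, event times, planted classes) so that
every estimator in the pipeline can be scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import defaults

__all__ = [
    "CellField",
    "ImageBundle",
    "CellCycleModel",
    "FTKinetics",
    "FACSTable",
    "PeptideTable",
    "PhaseFractions",
    "default_cell_cycle_model",
    "default_ft_kinetics",
]

PHASES = ("G1", "S", "G2M")

PEPTIDE_CHANNELS = ("V5_1", "V5_2", "IgG_1", "IgG_2")


class InvalidParameterError(ValueError):
    """A generator or estimator received out-of-contract parameters."""


@dataclass
class CellField:
    """2-D point field of cells with nuclear-positivity labels.

    ``cells`` has columns ``id`` (unique int), ``x``/``y`` (µm),
    ``nuclear_positive`` (bool) and ``pair_id`` (nullable int grouping
    post-mitotic daughter pairs).
    """

    cells: pd.DataFrame
    width: float
    height: float

    def __post_init__(self) -> None:
        required = {"id", "x", "y", "nuclear_positive", "pair_id"}
        missing = required - set(self.cells.columns)
        if missing:
            raise InvalidParameterError(f"CellField missing columns: {missing}")
        if self.width < 0 or self.height < 0:
            raise InvalidParameterError("field dimensions must be nonnegative")
        if len(self.cells):
            if self.cells["id"].duplicated().any():
                raise InvalidParameterError("cell ids must be unique")
            x, y = self.cells["x"].to_numpy(), self.cells["y"].to_numpy()
            if (x < 0).any() or (x > self.width).any() or (y < 0).any() or (y > self.height).any():
                raise InvalidParameterError("cell coordinates outside the field")
            pid = self.cells["pair_id"].dropna()
            if len(pid) and not (pid.value_counts() == 2).all():
                raise InvalidParameterError("pair_id must group exactly 2 cells")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(float)

    @property
    def nuclear_mask(self) -> np.ndarray:
        return self.cells["nuclear_positive"].to_numpy(bool)


@dataclass
class ImageBundle:
    """Two-channel raster (nuclear dye + marker) with per-cell ground truth.

    ``truth`` columns: id, cx_px, cy_px, nucleus_radius_px,
    nuclear_positive, nuclear_marker_mean, cytoplasm_marker_mean.
    """

    nuclear_channel: np.ndarray
    marker_channel: np.ndarray
    pixel_size: float  # µm / px
    truth: pd.DataFrame

    def __post_init__(self) -> None:
        if self.nuclear_channel.shape != self.marker_channel.shape:
            raise InvalidParameterError("channels must share shape")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if (np.asarray(self.nuclear_channel) < 0).any() or (np.asarray(self.marker_channel) < 0).any():
            raise InvalidParameterError("intensity rasters must be nonnegative")


@dataclass(frozen=True)
class CellCycleModel:
    """Doubling time and G1/S/G2-M durations (hours).

    Defines the age structure of an asynchronous exponentially growing
    population: age density f(a) = (2 ln2 / T) 2^(-a/T) on [0, T].
    Durations may be zero (degenerate boundary mixtures) but not negative.
    """

    T: float
    d_G1: float
    d_S: float
    d_G2M: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError("doubling time must be positive")
        if min(self.d_G1, self.d_S, self.d_G2M) < 0:
            raise InvalidParameterError("phase durations must be nonnegative")
        if abs(self.d_G1 + self.d_S + self.d_G2M - self.T) > 1e-9:
            raise InvalidParameterError("phase durations must sum to the doubling time")

    @property
    def boundaries(self) -> tuple[float, float]:
        """Ages at the G1→S and S→G2/M transitions."""
        return self.d_G1, self.d_G1 + self.d_S


@dataclass(frozen=True)
class FTKinetics:
    """Fast fluorescent-timer kinetics and detection thresholds.

    ``onset_mu``/``onset_sigma`` parameterize the lognormal delay between
    transcriptional induction and first visible fluorescence; ``k_mat``
    is the first-order blue→red maturation rate (1/h).
    """

    k_mat: float = defaults.K_MAT
    onset_mu: float = defaults.ONSET_MU
    onset_sigma: float = defaults.ONSET_SIGMA
    blue_detect_threshold: float = 10.0
    red_detect_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.k_mat <= 0:
            raise InvalidParameterError("maturation rate must be positive")
        if self.blue_detect_threshold < 0 or self.red_detect_threshold < 0:
            raise InvalidParameterError("detection thresholds must be nonnegative")

    def sample_onset_delays(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.onset_mu, self.onset_sigma, size=n)


@dataclass
class FACSTable:
    """Per-event flow-cytometry-style table.

    ``events`` columns: blue, red, dna (a.u., nonnegative) plus ground
    truth ``true_phase`` ({G1,S,G2M} or NA) and ``true_event_time``
    (hours before analysis, NA for cells without an event).
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"blue", "red", "dna"}
        if required - set(self.events.columns):
            raise InvalidParameterError("FACSTable needs blue/red/dna columns")
        for col in required:
            if (self.events[col].to_numpy(float) < 0).any():
                raise InvalidParameterError(f"negative intensities in {col}")
        for col in ("true_phase", "true_event_time"):
            if col not in self.events.columns:
                self.events[col] = pd.NA

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class PeptideTable:
    """Unique-peptide counts per protein across the four IP channels.

    Channels: V5_1, V5_2 (bait IPs, experiments 1 and 2) and IgG_1,
    IgG_2 (matched isotype controls). ``planted_class`` carries the
    generator's ground truth when synthetic.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_id", *PEPTIDE_CHANNELS}
        if required - set(self.rows.columns):
            raise InvalidParameterError("PeptideTable missing required columns")
        if "planted_class" not in self.rows.columns:
            self.rows["planted_class"] = pd.NA
        if len(self.rows):
            if self.rows["protein_id"].duplicated().any():
                raise InvalidParameterError("protein_id must be unique")
            counts = self.rows[list(PEPTIDE_CHANNELS)].to_numpy()
            if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
                raise InvalidParameterError("peptide counts must be nonnegative integers")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class PhaseFractions:
    """Fractions of cells in G1, S and G2/M; must sum to 1."""

    f_G1: float
    f_S: float
    f_G2M: float

    def __post_init__(self) -> None:
        vals = (self.f_G1, self.f_S, self.f_G2M)
        if any(v < -1e-12 or v > 1 + 1e-12 for v in vals):
            raise InvalidParameterError("fractions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-6:
            raise InvalidParameterError("fractions must sum to 1")

    @classmethod
    def from_percent(cls, g1: float, s: float, g2m: float) -> "PhaseFractions":
        """Build from (possibly rounded) percentages, renormalizing to 1."""
        tot = g1 + s + g2m
        if tot <= 0:
            raise InvalidParameterError("percentages must sum to a positive value")
        return cls(g1 / tot, s / tot, g2m / tot)

    def as_array(self) -> np.ndarray:
        return np.array([self.f_G1, self.f_S, self.f_G2M])


def default_cell_cycle_model() -> CellCycleModel:
    """Phase durations inverted from the asynchronous PI distribution at T = 24 h."""
    from .cyclekin import durations_from_fractions

    return durations_from_fractions(
        PhaseFractions(*defaults.ASYNC_FRACTIONS), defaults.DOUBLING_TIME_H
    )


def default_ft_kinetics() -> FTKinetics:
    return FTKinetics()
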