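"""Synthetic-data generators with full ground truth.

Every generator is seeded and deterministic, and every observable it
emits travels with the truth that produced it (phase labels, event
times, planted interactor classes), so downstream estimators can be
scored exactly. The generators emulate the statistical structure of the
source experiments:

* post-mitotic daughter-cell pairs of nuclear-ORF1p cells scattered in
  an otherwise uniform field (:func:`gen_cell_field`);
* two-channel high-content microscopy rasters — nuclear-dye disks plus
  a marker channel with cytoplasmic annuli and, for nuclear-positive
  cells, nuclear signal (:func:`gen_image`);
* the exponential-growth age structure of an asynchronous culture
  (:func:`sample_phases`), DNA-content mixtures (2N/4N Gaussians plus an
  S-phase bridge) and fast-FT blue/red kinetics for snapshot flow tables
  (:func:`gen_facs_snapshot`);
* synchronized-release GFP⁺ retrotransposition time courses with
  S-phase-restricted events and expression-onset delays
  (:func:`gen_timecourse`);
* IP-MS peptide-count tables with planted red/orange/yellow/gray
  interactor classes (:func:`gen_peptide_table`).

Not modelled: microscope optics (PSF, vignetting) and flow spectral
spillover; nuclear positivity is a static label per snapshot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import defaults
from .cyclekin import ft_trace
from .datatypes import (
    CellCycleModel,
    CellField,
    FACSTable,
    FTKinetics,
    ImageBundle,
    InvalidParameterError,
    PeptideTable,
    PhaseFractions,
    PHASES,
    default_cell_cycle_model,
)

__all__ = [
    "gen_cell_field",
    "gen_image",
    "sample_phases",
    "gen_facs_snapshot",
    "gen_timecourse",
    "TimeCourseTruth",
    "gen_peptide_table",
    "gen_ft_traces",
    "gen_fucci_cells",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Non-overlapping nucleus placement failed after bounded retries."""


# ---------------------------------------------------------------------------
# Cell fields and images
# ---------------------------------------------------------------------------

def gen_cell_field(
    n_cells: int,
    frac_nuclear: float,
    frac_paired: float = 0.0,
    pair_sep_mean: float = defaults.PAIR_SEP_MEAN_UM,
    pair_sep_sd: float = defaults.PAIR_SEP_SD_UM,
    width: float = 1000.0,
    height: float = 1000.0,
    seed: int = 0,
) -> CellField:
    """Scatter cells in a rectangle, planting daughter pairs of
    nuclear-positive cells.

    A fraction ``frac_nuclear`` of cells (in expectation) is
    nuclear-positive; of those, ``frac_paired`` are placed as
    two-cell clusters separated by a truncated-normal distance
    (``pair_sep_mean`` ± ``pair_sep_sd`` µm, truncated at 0) emulating
    recently divided daughters. All other cells are uniform in the
    field.
    """
    if n_cells < 0:
        raise InvalidParameterError("n_cells must be nonnegative")
    if not (0 <= frac_nuclear <= 1 and 0 <= frac_paired <= 1):
        raise InvalidParameterError("fractions must lie in [0, 1]")
    if width < 0 or height < 0:
        raise InvalidParameterError("field dimensions must be nonnegative")
    if pair_sep_mean < 0 or pair_sep_sd < 0:
        raise InvalidParameterError("pair separation parameters must be nonnegative")

    rng = np.random.default_rng(seed)
    cols = ["id", "x", "y", "nuclear_positive", "pair_id"]
    if n_cells == 0:
        df = pd.DataFrame(columns=cols)
        df["pair_id"] = df["pair_id"].astype("Int64")
        return CellField(df, width, height)

    n_nuclear = int(rng.binomial(n_cells, frac_nuclear))
    n_pairs = int(math.floor(frac_paired * n_nuclear / 2.0))

    xs = np.empty(n_cells)
    ys = np.empty(n_cells)
    nuclear = np.zeros(n_cells, dtype=bool)
    pair_id = np.full(n_cells, pd.NA, dtype=object)

    # paired nuclear cells first
    idx = 0
    for p in range(n_pairs):
        for _ in range(10_000):
            ax_, ay_ = rng.uniform(0, width), rng.uniform(0, height)
            if pair_sep_sd > 0:
                a = (0.0 - pair_sep_mean) / pair_sep_sd
                sep = stats.truncnorm.rvs(
                    a, np.inf, loc=pair_sep_mean, scale=pair_sep_sd,
                    random_state=rng,
                )
            else:
                sep = pair_sep_mean
            theta = rng.uniform(0, 2 * np.pi)
            bx, by = ax_ + sep * np.cos(theta), ay_ + sep * np.sin(theta)
            if 0 <= bx <= width and 0 <= by <= height:
                break
        else:  # pragma: no cover - pathological geometry
            raise PlacementError("could not place daughter pair inside field")
        xs[idx], ys[idx] = ax_, ay_
        xs[idx + 1], ys[idx + 1] = bx, by
        nuclear[idx:idx + 2] = True
        pair_id[idx] = p
        pair_id[idx + 1] = p
        idx += 2

    # remaining cells: uniform; leftover nuclear cells are singletons
    n_rest = n_cells - idx
    xs[idx:] = rng.uniform(0, width, n_rest)
    ys[idx:] = rng.uniform(0, height, n_rest)
    n_single_nuclear = n_nuclear - 2 * n_pairs
    nuclear[idx:idx + n_single_nuclear] = True

    order = rng.permutation(n_cells)  # decouple row order from construction
    df = pd.DataFrame(
        {
            "id": np.arange(n_cells),
            "x": xs[order],
            "y": ys[order],
            "nuclear_positive": nuclear[order],
            "pair_id": pd.array([pair_id[i] for i in order], dtype="Int64"),
        }
    )
    return CellField(df, width, height)


def gen_image(
    field: CellField,
    pixel_size: float = 1.0,
    nucleus_radius: int = 6,
    intensity_params: tuple[float, float, float, float] = (400.0, 250.0, 50.0, 8.0),
    seed: int = 0,
    cyto_width: int = 8,
    nuclear_dye_mean: float = 800.0,
    max_jitter_retries: int = 200,
) -> ImageBundle:
    """Render a field as a two-channel raster with a filled truth table.

    ``intensity_params`` is ``(nuclear_marker_mean, cyto_marker_mean,
    background, noise_sd)``. The nuclear-dye channel carries bright
    disks of radius ``nucleus_radius`` for every cell; the marker
    channel carries a cytoplasmic annulus (``nucleus_radius`` to
    ``nucleus_radius + cyto_width``) for every cell and nuclear-disk
    marker signal only for nuclear-positive cells. Gaussian noise is
    added to both channels and clipped at zero.

    Non-overlap is enforced at the cell-footprint level — no cell's
    cytoplasmic annulus may intersect another cell's nucleus (otherwise
    bleed-through marker signal corrupts nuclear compartment
    measurements in a way no negative control can calibrate away) — by
    jittering cell centers, with bounded retries before a
    :class:`PlacementError`.
    """
    if nucleus_radius < 2:
        raise InvalidParameterError("nucleus_radius must be >= 2 px")
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    nuc_mean, cyto_mean, background, noise_sd = intensity_params
    if noise_sd < 0 or background < 0:
        raise InvalidParameterError("background and noise must be nonnegative")

    rng = np.random.default_rng(seed)
    ny = max(int(math.ceil(field.height / pixel_size)) + 1, 2 * nucleus_radius + 2)
    nx = max(int(math.ceil(field.width / pixel_size)) + 1, 2 * nucleus_radius + 2)

    cells = field.cells
    centers = []
    # annulus of one cell must not reach the nucleus of another
    min_sep2 = (2 * nucleus_radius + cyto_width + 1) ** 2
    margin = nucleus_radius + 1
    for _, row in cells.iterrows():
        cx = row.x / pixel_size
        cy = row.y / pixel_size
        cx = min(max(cx, margin), nx - 1 - margin)
        cy = min(max(cy, margin), ny - 1 - margin)
        px, py = cx, cy
        ok = False
        for attempt in range(max_jitter_retries):
            if all((px - ox) ** 2 + (py - oy) ** 2 >= min_sep2 for ox, oy in centers):
                ok = True
                break
            jitter = nucleus_radius * (1 + attempt / 20.0)
            px = min(max(cx + rng.normal(0, jitter), margin), nx - 1 - margin)
            py = min(max(cy + rng.normal(0, jitter), margin), ny - 1 - margin)
        if not ok:
            raise PlacementError(
                f"could not place non-overlapping nucleus for cell {row.id}"
            )
        centers.append((px, py))

    nuclear_ch = np.full((ny, nx), float(background))
    marker_ch = np.full((ny, nx), float(background))
    Y, X = np.mgrid[0:ny, 0:nx]

    truth_rows = []
    for (px, py), (_, row) in zip(centers, cells.iterrows()):
        d2 = (X - px) ** 2 + (Y - py) ** 2
        disk = d2 <= nucleus_radius ** 2
        annulus = (d2 > nucleus_radius ** 2) & (
            d2 <= (nucleus_radius + cyto_width) ** 2
        )
        nuclear_ch[disk] += nuclear_dye_mean
        marker_ch[annulus] += cyto_mean
        is_nuclear = bool(row.nuclear_positive)
        if is_nuclear:
            marker_ch[disk] += nuc_mean
        truth_rows.append(
            {
                "id": int(row.id),
                "cx_px": px,
                "cy_px": py,
                "nucleus_radius_px": nucleus_radius,
                "nuclear_positive": is_nuclear,
                "nuclear_marker_mean": nuc_mean if is_nuclear else 0.0,
                "cytoplasm_marker_mean": cyto_mean,
            }
        )

    if noise_sd > 0:
        nuclear_ch = nuclear_ch + rng.normal(0, noise_sd, nuclear_ch.shape)
        marker_ch = marker_ch + rng.normal(0, noise_sd, marker_ch.shape)
    nuclear_ch = np.clip(nuclear_ch, 0, None)
    marker_ch = np.clip(marker_ch, 0, None)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "id", "cx_px", "cy_px", "nucleus_radius_px", "nuclear_positive",
            "nuclear_marker_mean", "cytoplasm_marker_mean",
        ],
    )
    return ImageBundle(nuclear_ch, marker_ch, pixel_size, truth)


# ---------------------------------------------------------------------------
# Cell-cycle sampling and FACS snapshots
# ---------------------------------------------------------------------------

def _sample_ages(model: CellCycleModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ages from the exponential-growth density f(a) = (2 ln2/T) 2^(-a/T)."""
    u = rng.uniform(0, 1, n)
    return -model.T * np.log2(1.0 - u / 2.0)


def _phase_of_age(model: CellCycleModel, ages: np.ndarray) -> np.ndarray:
    a1, a2 = model.boundaries
    phase = np.full(ages.shape, "G1", dtype=object)
    phase[(ages >= a1) & (ages < a2)] = "S"
    phase[ages >= a2] = "G2M"
    return phase


def sample_phases(model: CellCycleModel, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw (phase, age) for an asynchronous exponentially growing culture."""
    if n < 0:
        raise InvalidParameterError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    ages = _sample_ages(model, n, rng)
    return pd.DataFrame({"phase": _phase_of_age(model, ages), "age": ages})


def _dna_from_phase(
    phase: np.ndarray,
    rng: np.random.Generator,
    dna_cv: float,
    dna_2n: float,
    s_progress: Optional[np.ndarray] = None,
) -> np.ndarray:
    """DNA content: Gaussian 2N (G1), Gaussian 4N (G2M), 2N→4N bridge (S)."""
    n = phase.size
    base = np.empty(n)
    g1 = phase == "G1"
    g2 = phase == "G2M"
    s = phase == "S"
    base[g1] = dna_2n
    base[g2] = 2 * dna_2n
    if s.any():
        prog = rng.uniform(0, 1, int(s.sum())) if s_progress is None else s_progress[s]
        base[s] = dna_2n * (1.0 + prog)
    if dna_cv > 0:
        base = base * rng.normal(1.0, dna_cv, n)
    return np.clip(base, 0, None)


def gen_facs_snapshot(
    model: Optional[CellCycleModel] = None,
    kin: Optional[FTKinetics] = None,
    n: int = 10_000,
    event_rule: str = "uniform_in_S",
    mixture=None,
    dna_cv: float = defaults.DNA_CV,
    seed: int = 0,
    p_event: float = 0.3,
    dna_2n: float = defaults.DNA_2N,
    steady_blue: float = 100.0,
    baseline_scale: float = 1.5,
) -> FACSTable:
    """Snapshot flow table: DNA content plus fast-FT blue/red intensities.

    ``event_rule``:

    * ``uniform_in_S`` / ``uniform_in_cycle`` — each cell carries at most
      one retrotransposition event per cycle (probability ``p_event``) at
      a position uniform in S (or in the whole cycle). Expression starts
      after a lognormal onset delay; the blue pool then accumulates under
      ongoing transcription (steady state ``steady_blue``) while red
      grows by first-order maturation at ``kin.k_mat``.
    * ``fixed_phase_mixture`` — phases drawn directly from ``mixture``
      (a :class:`PhaseFractions` or a triple summing to 1); no events.

    All events also carry a small autofluorescence baseline on both
    channels so "auto" gating thresholds are well defined.
    """
    if n < 0:
        raise InvalidParameterError("n must be nonnegative")
    model = model if model is not None else default_cell_cycle_model()
    kin = kin if kin is not None else FTKinetics()
    rng = np.random.default_rng(seed)

    if event_rule == "fixed_phase_mixture":
        if mixture is None:
            raise InvalidParameterError("fixed_phase_mixture requires a mixture")
        if not isinstance(mixture, PhaseFractions):
            vals = tuple(float(v) for v in mixture)
            if abs(sum(vals) - 1.0) > 1e-6:
                raise InvalidParameterError("mixture must sum to 1 (tolerance 1e-6)")
            mixture = PhaseFractions(*vals)
        phase = np.array(PHASES, dtype=object)[
            rng.choice(3, size=n, p=mixture.as_array())
        ]
        dna = _dna_from_phase(phase, rng, dna_cv, dna_2n)
        blue = np.abs(rng.normal(0, baseline_scale, n))
        red = np.abs(rng.normal(0, baseline_scale, n))
        events = pd.DataFrame(
            {"blue": blue, "red": red, "dna": dna,
             "true_phase": phase, "true_event_time": pd.array([pd.NA] * n)}
        )
        return FACSTable(events)

    if event_rule not in ("uniform_in_S", "uniform_in_cycle"):
        raise InvalidParameterError(f"unknown event_rule {event_rule!r}")
    if mixture is not None:
        raise InvalidParameterError("mixture only applies to fixed_phase_mixture")

    ages = _sample_ages(model, n, rng)
    phase = _phase_of_age(model, ages)
    a1, a2 = model.boundaries
    s_prog = np.clip((ages - a1) / max(a2 - a1, 1e-12), 0, 1)
    dna = _dna_from_phase(phase, rng, dna_cv, dna_2n, s_progress=s_prog)

    # events within the current cycle only
    has_event = rng.uniform(0, 1, n) < p_event
    if event_rule == "uniform_in_S":
        e_pos = rng.uniform(a1, a2, n)
    else:
        e_pos = rng.uniform(0.0, model.T, n)
    occurred = has_event & (ages > e_pos)
    onset = kin.sample_onset_delays(n, rng)
    tau_expr = ages - e_pos - onset  # time expressing the timer
    expressing = occurred & (tau_expr > 0)

    blue = np.abs(rng.normal(0, baseline_scale, n))
    red = np.abs(rng.normal(0, baseline_scale, n))
    k = kin.k_mat
    te = tau_expr[expressing]
    blue[expressing] += steady_blue * (1.0 - np.exp(-k * te))
    red[expressing] += steady_blue * k * te - steady_blue * (1.0 - np.exp(-k * te))

    event_time = np.full(n, np.nan)
    event_time[occurred] = (ages - e_pos)[occurred]
    events = pd.DataFrame(
        {
            "blue": blue,
            "red": red,
            "dna": dna,
            "true_phase": phase,
            "true_event_time": pd.array(
                [t if np.isfinite(t) else pd.NA for t in event_time]
            ),
        }
    )
    return FACSTable(events)


# ---------------------------------------------------------------------------
# Synchronized-release time courses
# ---------------------------------------------------------------------------

@dataclass
class TimeCourseTruth:
    """GFP⁺ fraction per timepoint with per-cell event ground truth."""

    timepoints: np.ndarray     # h after release
    gfp_fraction: np.ndarray   # %
    truth: pd.DataFrame        # per cell: detect_time (h, NaN if never)
    model: CellCycleModel
    n_cells: int


def gen_timecourse(
    model: Optional[CellCycleModel] = None,
    timepoints: Sequence[float] = tuple(range(0, 25, 3)),
    n_cells: int = 20_000,
    seed: int = 0,
    p_event: float = 0.3,
    event_rule: str = "uniform_in_S",
    detect_delay_law: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    synchronized: bool = True,
) -> TimeCourseTruth:
    """Cumulative GFP⁺ fraction of a cohort released from mitotic arrest.

    Synchronized cells all start G1 at t = 0; unsynchronized cells start
    at an age drawn from the asynchronous age density (control arm). In
    each cycle a cell acquires at most one retrotransposition event
    (probability ``p_event``) at a position uniform in S (or uniform in
    the cycle); the cell is scored GFP⁺ at time t once
    ``event_time + detection_delay <= t``. ``detect_delay_law`` maps
    ``(rng, n) -> delays``; None means instantaneous detection.
    """
    t = np.asarray(timepoints, float)
    if t.size < 2:
        raise InvalidParameterError("need >= 2 timepoints")
    if not (np.diff(t) > 0).all():
        raise InvalidParameterError("timepoints must be strictly increasing")
    if n_cells <= 0:
        raise InvalidParameterError("n_cells must be positive")
    if event_rule not in ("uniform_in_S", "uniform_in_cycle"):
        raise InvalidParameterError(f"unknown event_rule {event_rule!r}")

    model = model if model is not None else default_cell_cycle_model()
    rng = np.random.default_rng(seed)
    a1, a2 = model.boundaries
    t_max = float(t[-1])

    a0 = np.zeros(n_cells) if synchronized else _sample_ages(model, n_cells, rng)
    n_cycles = int(math.ceil((t_max + model.T) / model.T)) + 1

    detect_time = np.full(n_cells, np.inf)
    for c in range(n_cycles):
        cycle_start = c * model.T - a0
        has_event = rng.uniform(0, 1, n_cells) < p_event
        if event_rule == "uniform_in_S":
            e_pos = rng.uniform(a1, a2, n_cells)
        else:
            e_pos = rng.uniform(0.0, model.T, n_cells)
        ev_time = cycle_start + e_pos
        delays = (
            np.zeros(n_cells) if detect_delay_law is None
            else np.asarray(detect_delay_law(rng, n_cells), float)
        )
        d_time = ev_time + delays
        valid = has_event & (ev_time >= 0)
        detect_time = np.where(valid, np.minimum(detect_time, d_time), detect_time)

    frac = np.array([(detect_time <= ti).mean() * 100.0 for ti in t])
    truth = pd.DataFrame(
        {"detect_time": np.where(np.isfinite(detect_time), detect_time, np.nan),
         "initial_age": a0}
    )
    return TimeCourseTruth(t, frac, truth, model, n_cells)


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

def gen_peptide_table(
    n_per_class: dict,
    count_law: tuple[str, float] = ("poisson", 5.0),
    seed: int = 0,
) -> PeptideTable:
    """Peptide-count table with planted interactor classes.

    Planted classes satisfy the confidence rules by construction:

    * red — bait (V5) peptides in both experiments, IgG empty in both;
    * orange — bait peptides in both experiments, IgG hits in at least
      one;
    * yellow — bait peptides in exactly one experiment, IgG empty;
    * gray — bait peptides in one experiment *with* IgG hits in that
      experiment (passes the 2-unique-peptide filter but is no
      interactor).

    ``count_law`` ("poisson", lam) sets the spread of bait counts; bait
    channels draw ``2 + Poisson(lam)`` so every planted row clears the
    minimum-unique-peptide filter.
    """
    law, lam = count_law
    if law != "poisson":
        raise InvalidParameterError(f"unknown count law {law!r}")
    for cls, n in n_per_class.items():
        if cls not in ("red", "orange", "yellow", "gray"):
            raise InvalidParameterError(f"unknown class {cls!r}")
        if n < 0:
            raise InvalidParameterError("class counts must be nonnegative")

    rng = np.random.default_rng(seed)
    rows = []

    def bait() -> int:
        return int(2 + rng.poisson(lam))

    def igg() -> int:
        return int(1 + rng.poisson(max(lam / 3.0, 0.5)))

    for cls in ("red", "orange", "yellow", "gray"):
        for i in range(int(n_per_class.get(cls, 0))):
            v1 = v2 = g1 = g2 = 0
            if cls == "red":
                v1, v2 = bait(), bait()
            elif cls == "orange":
                v1, v2 = bait(), bait()
                which = rng.integers(3)  # IgG hit in exp1, exp2 or both
                g1 = igg() if which in (0, 2) else 0
                g2 = igg() if which in (1, 2) else 0
            elif cls == "yellow":
                if rng.integers(2) == 0:
                    v1 = bait()
                else:
                    v2 = bait()
            else:  # gray: single-experiment with IgG contamination
                if rng.integers(2) == 0:
                    v1, g1 = bait(), igg()
                else:
                    v2, g2 = bait(), igg()
            rows.append(
                {"protein_id": f"SYN_{cls.upper()}_{i:04d}",
                 "V5_1": v1, "V5_2": v2, "IgG_1": g1, "IgG_2": g2,
                 "planted_class": cls}
            )

    df = pd.DataFrame(
        rows,
        columns=["protein_id", "V5_1", "V5_2", "IgG_1", "IgG_2", "planted_class"],
    )
    return PeptideTable(df)


# ---------------------------------------------------------------------------
# Fast-FT traces and FUCCI snapshots
# ---------------------------------------------------------------------------

def gen_ft_traces(
    n: int = 500,
    kin: Optional[FTKinetics] = None,
    times: Optional[np.ndarray] = None,
    noise_sd_frac: float = 0.05,
    amplitude_sigma: float = 0.2,
    seed: int = 0,
):
    """Noisy single-cell fast-FT traces (constant-burst kinetics).

    Each cell gets a lognormal burst amplitude and additive Gaussian
    noise with sd ``noise_sd_frac`` of its own plateau on both channels.
    Returns a list of :class:`~l1cycle.cyclekin.FTTrace`.
    """
    if n <= 0:
        raise InvalidParameterError("n must be positive")
    kin = kin if kin is not None else FTKinetics()
    if times is None:
        times = np.arange(0.0, 24.0 + 1e-9, 0.25)
    rng = np.random.default_rng(seed)
    traces = []
    for _ in range(n):
        amp = float(rng.lognormal(0.0, amplitude_sigma))
        base = ft_trace(kin, times, "constant_burst", amplitude=amp)
        sd = noise_sd_frac * amp
        blue = np.clip(base.blue + rng.normal(0, sd, times.size), 0, None)
        red = np.clip(base.red + rng.normal(0, sd, times.size), 0, None)
        traces.append(
            type(base)(times=times, blue=blue, red=red,
                       conversion_time=base.conversion_time)
        )
    return traces


def gen_fucci_cells(
    n_total: int,
    n_nuclear: int,
    model: Optional[CellCycleModel] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """FUCCI snapshot under the G1-only model of nuclear ORF1p.

    Nuclear-ORF1p cells are forced into G1 (red, Cdt1⁺ nuclei); the
    remaining cells draw their phase from the asynchronous age structure
    and are green (geminin⁺) in S/G2/M, red in G1.
    """
    if n_total < 0 or n_nuclear < 0 or n_nuclear > n_total:
        raise InvalidParameterError("need 0 <= n_nuclear <= n_total")
    model = model if model is not None else default_cell_cycle_model()
    rng = np.random.default_rng(seed)

    phases = np.empty(n_total, dtype=object)
    phases[:n_nuclear] = "G1"
    rest = _phase_of_age(model, _sample_ages(model, n_total - n_nuclear, rng))
    phases[n_nuclear:] = rest
    nuclear = np.zeros(n_total, dtype=bool)
    nuclear[:n_nuclear] = True
    color = np.where(phases == "G1", "red", "green")

    order = rng.permutation(n_total)
    return pd.DataFrame(
        {"nuclear_orf1p": nuclear[order], "nucleus_color": color[order],
         "true_phase": phases[order]}
    )
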