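"""Flow-cytometer pulse simulation and pulse-shape (PulSA) gating.

A cell transiting the interrogation beam produces a fluorescence pulse in
time. We model the noiseless pulse as a two-component Gaussian: the diffuse
reporter occupies the whole cell (spatial sigma ``cell_sigma_factor x
diameter``), while the inclusion is nearly a point source
(``punctum_sigma``). Each component is convolved with the Gaussian beam, so
its temporal sigma is ``sqrt(beam_sigma^2 + component_sigma^2) /
scan_speed``. Writing ``F`` for total fluorescence and ``f`` for the
punctate fraction, the signal is

    s(t) = F * [ (1-f) * N(t; sigma_diffuse) + f * N(t; sigma_punctate) ]

with unit-area Gaussians ``N``. The pulse *height* (FITC-H analog) is the
peak of ``s`` plus detector noise, the *width* (FITC-W analog) is the time
the noiseless signal spends above an absolute trigger threshold, and the
*area* is the time-integral of the signal, which equals ``F`` exactly
(zero-mean noise integrates away). Because the punctate component is
narrower, a punctate cell is taller and narrower than a diffuse cell of the
same ``F`` — the discrimination PulSA sorting exploits.

Gating follows the sorter protocol: an expression gate keeps cells within a
quantile band of pulse area, then the aggregate / non-aggregate gates take
the top and bottom ``target_fraction`` tails of the discriminant
``r = height / width``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

_SQRT2PI = math.sqrt(2.0 * math.pi)

PULSE_COLUMNS = ["cell_id", "height", "width", "area", "truth_aggregated"]


def normal_diameters(mean: float = 15.0, sd: float = 1.5) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Cell-diameter sampler (µm), truncated well away from zero."""

    def sample(rng: np.random.Generator, size: int) -> np.ndarray:
        return np.clip(rng.normal(mean, sd, size), mean / 4.0, None)

    return sample


@dataclass(frozen=True)
class OpticalModel:
    """Invented instrument optics for the pulse simulation.

    Parameters
    ----------
    beam_sigma:
        Gaussian interrogation-beam sigma, µm.
    cell_sigma_factor:
        Maps cell diameter to the spatial sigma of diffusely distributed
        fluorophores (0.25 ≈ diameter/4).
    punctum_sigma:
        Spatial sigma of an inclusion, µm; far below ``beam_sigma``.
    cell_diameter_sampler:
        Callable ``(rng, n) -> diameters`` in µm.
    scan_speed:
        Transit speed, µm per time unit; converts spatial sigmas to temporal.
    trigger_threshold:
        Absolute signal level defining pulse width. An absolute (not
        relative) threshold is deliberate: it keeps width increasing with
        total signal, as on a real cytometer.
    noise_sd:
        Gaussian detector noise added to the pulse height, signal units.
    """

    beam_sigma: float = 2.0
    cell_sigma_factor: float = 0.25
    punctum_sigma: float = 0.5
    cell_diameter_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default_factory=normal_diameters
    )
    scan_speed: float = 1.0
    trigger_threshold: float = 2.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.beam_sigma <= 0:
            raise ValueError("beam_sigma must be > 0")
        if self.punctum_sigma < 0:
            raise ValueError("punctum_sigma must be >= 0")
        if self.trigger_threshold < 0:
            raise ValueError("trigger_threshold must be >= 0")
        if self.scan_speed <= 0:
            raise ValueError("scan_speed must be > 0")


@dataclass(frozen=True)
class GateSpec:
    """Calibrated sort gates.

    ``aggregate_threshold`` / ``diffuse_threshold`` are closed bounds on the
    discriminant r = height/width: the aggregate gate is ``r >=
    aggregate_threshold``, the diffuse gate ``r <= diffuse_threshold``
    (boundary records belong to the gate). ``n_width_zero`` counts records
    excluded from calibration because their pulse never crossed the trigger.
    """

    q_lo: float
    q_hi: float
    target_fraction: float
    aggregate_threshold: float
    diffuse_threshold: float
    n_width_zero: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_lo < self.q_hi <= 1.0):
            raise ValueError("require 0 <= q_lo < q_hi <= 1")
        if not (0.0 < self.target_fraction <= 0.5):
            raise ValueError("target_fraction must be in (0, 0.5]")
        if self.aggregate_threshold <= self.diffuse_threshold:
            raise ValueError("gates must be disjoint (aggregate above diffuse)")


def _pulse_components(
    fluorescence: np.ndarray,
    punctate_fraction: np.ndarray,
    model: OpticalModel,
    diameters: np.ndarray,
):
    """Temporal sigmas and peak amplitudes of the two Gaussian components."""
    sigma_cell = model.cell_sigma_factor * diameters
    s_diff = np.sqrt(model.beam_sigma**2 + sigma_cell**2) / model.scan_speed
    s_punc = (
        math.sqrt(model.beam_sigma**2 + model.punctum_sigma**2) / model.scan_speed
    )
    a_diff = (1.0 - punctate_fraction) * fluorescence / (s_diff * _SQRT2PI)
    a_punc = punctate_fraction * fluorescence / (s_punc * _SQRT2PI)
    return a_diff, s_diff, a_punc, np.full_like(s_diff, s_punc)


def _width_above_threshold(a1, s1, a2, s2, threshold: float) -> np.ndarray:
    """Duration the mixture a1*exp(-t²/2s1²)+a2*exp(-t²/2s2²) exceeds the threshold.

    The mixture is even and strictly decreasing in |t|, so the crossing is
    found by vectorized bisection on t >= 0; width = 2 t*.
    """
    peak = a1 + a2
    n = len(peak)
    width = np.zeros(n)
    if threshold <= 0:
        width[peak > 0] = np.inf
        return width
    active = peak > threshold
    if not active.any():
        return width
    a1a, s1a, a2a, s2a = (x[active] for x in (a1, s1, a2, s2))
    smax = np.maximum(s1a, s2a)
    # envelope (a1+a2) exp(-t²/2 smax²) >= s(t), so its crossing brackets the root
    hi = smax * np.sqrt(2.0 * np.log(peak[active] / threshold))
    lo = np.zeros_like(hi)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        val = a1a * np.exp(-0.5 * (mid / s1a) ** 2) + a2a * np.exp(-0.5 * (mid / s2a) ** 2)
        above = val >= threshold
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    width[active] = lo + hi  # 2 * midpoint
    return width


def _acquire_arrays(
    fluorescence: np.ndarray,
    punctate_fraction: np.ndarray,
    model: OpticalModel,
    rng: np.random.Generator,
):
    n = len(fluorescence)
    diameters = model.cell_diameter_sampler(rng, n)
    a1, s1, a2, s2 = _pulse_components(fluorescence, punctate_fraction, model, diameters)
    peak = a1 + a2
    height = peak.copy()
    if model.noise_sd > 0:
        height = np.maximum(height + rng.normal(0.0, model.noise_sd, n), 0.0)
    width = _width_above_threshold(a1, s1, a2, s2, model.trigger_threshold)
    # the two components have unit area in time, so the integral is exactly F
    area = fluorescence.astype(float).copy()
    zero = fluorescence <= 0
    height[zero] = 0.0
    width[zero] = 0.0
    area[zero] = 0.0
    return height, width, area


def simulate_pulse(cell: Mapping, model: OpticalModel, seed: int = 0) -> dict:
    """Simulate a single cell's pulse; see module docstring for the physics.

    ``cell`` needs ``total_fluorescence`` and ``punctate_fraction`` (and
    optionally ``cell_id`` / ``aggregated``). Returns a dict with ``cell_id,
    height, width, area, truth_aggregated``.
    """
    fluor = float(cell["total_fluorescence"])
    if fluor < 0:
        raise ValueError("total_fluorescence must be >= 0")
    rng = np.random.default_rng(seed)
    h, w, a = _acquire_arrays(
        np.array([fluor]), np.array([float(cell.get("punctate_fraction", 0.0))]), model, rng
    )
    return {
        "cell_id": int(cell.get("cell_id", 0)),
        "height": float(h[0]),
        "width": float(w[0]),
        "area": float(a[0]),
        "truth_aggregated": bool(cell.get("aggregated", False)),
    }


def acquire_population(
    population: pd.DataFrame, model: OpticalModel, seed: int = 0
) -> pd.DataFrame:
    """Vectorized pulse acquisition: one PulseRecord row per cell, order kept.

    Pass-through columns (``guide_idx``, ``guide_id``) are retained when
    present so sorted subsets can be tallied without a join.
    """
    rng = np.random.default_rng(seed)
    n = len(population)
    if n == 0:
        return pd.DataFrame(columns=PULSE_COLUMNS)
    h, w, a = _acquire_arrays(
        population["total_fluorescence"].to_numpy(dtype=float),
        population["punctate_fraction"].to_numpy(dtype=float),
        model,
        rng,
    )
    out = pd.DataFrame(
        {
            "cell_id": population["cell_id"].to_numpy(),
            "height": h,
            "width": w,
            "area": a,
            "truth_aggregated": population["aggregated"].to_numpy(dtype=bool)
            if "aggregated" in population
            else np.zeros(n, dtype=bool),
        }
    )
    for col in ("guide_idx", "guide_id"):
        if col in population:
            out[col] = population[col].to_numpy()
    return out


def _order_statistic(sorted_values: np.ndarray, q: float) -> float:
    """The ceil(q*n)-th smallest value (at least the 1st); q=1 gives the max."""
    n = len(sorted_values)
    k = max(1, math.ceil(q * n))
    return float(sorted_values[min(k, n) - 1])


def gate_expression(records: pd.DataFrame, q_lo: float, q_hi: float) -> pd.DataFrame:
    """Keep records whose area lies in the closed quantile band [q_lo, q_hi].

    Bounds are the ceil(q*n)-th smallest areas (normative order-statistic
    convention); the empty input passes through empty.
    """
    if not (0.0 <= q_lo < q_hi <= 1.0):
        raise ValueError("require 0 <= q_lo < q_hi <= 1")
    if len(records) == 0:
        return records
    areas = np.sort(records["area"].to_numpy(dtype=float))
    lo = _order_statistic(areas, q_lo)
    hi = _order_statistic(areas, q_hi)
    mask = (records["area"] >= lo) & (records["area"] <= hi)
    return records.loc[mask]


def calibrate_pulsa_gates(records: pd.DataFrame, target_fraction: float, q_lo: float = 0.0, q_hi: float = 1.0) -> GateSpec:
    """Place the aggregate / diffuse gates as the top and bottom tails of r.

    Each gate threshold is the order statistic of r = height/width such that
    ``round(target_fraction * n)`` records (±1 under ties) fall inside.
    Records with width 0 never crossed the trigger; they are excluded from
    calibration and reported via ``GateSpec.n_width_zero``.
    """
    if not (0.0 < target_fraction <= 0.5):
        raise ValueError("target_fraction must be in (0, 0.5]")
    if len(records) == 0:
        raise ValueError("cannot calibrate gates on an empty record set")
    widths = records["width"].to_numpy(dtype=float)
    valid = widths > 0
    n_zero = int((~valid).sum())
    r = np.sort(records["height"].to_numpy(dtype=float)[valid] / widths[valid])
    n = len(r)
    if n == 0:
        raise ValueError("no records with positive width to calibrate on")
    k = int(round(target_fraction * n))
    if k == 0:
        agg_thr, dif_thr = np.inf, -np.inf
    else:
        agg_thr = float(r[n - k])  # k-th largest
        dif_thr = float(r[k - 1])  # k-th smallest
        if agg_thr <= dif_thr:
            raise ValueError("gates overlap; target_fraction too large for this distribution")
    return GateSpec(
        q_lo=q_lo,
        q_hi=q_hi,
        target_fraction=target_fraction,
        aggregate_threshold=agg_thr,
        diffuse_threshold=dif_thr,
        n_width_zero=n_zero,
    )


def apply_gates(records: pd.DataFrame, gates: GateSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (aggregate, diffuse) subsets by the r thresholds.

    Thresholds are closed on the gate side; width-0 records fall in neither.
    """
    widths = records["width"].to_numpy(dtype=float)
    valid = widths > 0
    r = np.full(len(records), np.nan)
    r[valid] = records["height"].to_numpy(dtype=float)[valid] / widths[valid]
    agg = records.loc[valid & (r >= gates.aggregate_threshold)]
    dif = records.loc[valid & (r <= gates.diffuse_threshold)]
    return agg, dif


def binned_aggregation_fraction(
    records: pd.DataFrame,
    aggregated: np.ndarray | str,
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Fraction of aggregated cells per expression (area) bin.

    ``aggregated`` is either a boolean array aligned to ``records`` or the
    name of a boolean column (e.g. ``"truth_aggregated"`` or a gate-derived
    label). Bins are ``[edge_i, edge_{i+1})`` with the last bin closed. Empty
    bins report ``n_cells = 0`` and a NaN fraction (undefined, not zero).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    if isinstance(aggregated, str):
        labels = records[aggregated].to_numpy(dtype=bool)
    else:
        labels = np.asarray(aggregated, dtype=bool)
        if len(labels) != len(records):
            raise ValueError("label array does not match records")
    areas = records["area"].to_numpy(dtype=float)
    idx = np.digitize(areas, edges, right=False) - 1
    idx[areas == edges[-1]] = len(edges) - 2  # last bin closed on the right
    n_bins = len(edges) - 1
    in_range = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[in_range], minlength=n_bins)
    agg_counts = np.bincount(idx[in_range], weights=labels[in_range].astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, agg_counts / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_cells": counts.astype(int),
            "n_aggregated": agg_counts.astype(int),
            "fraction_aggregated": frac,
        }
    )


def write_pulses_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records[PULSE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pulses_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PULSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pulse TSV missing columns {missing}")
    return df
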