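"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator draws from a seeded stream and returns the ground truth
alongside the data, so parameter-recovery tests are possible at every
stage:

* correlated ring-width series — a common AR(1) growth signal modulated
  by a negative-exponential age trend, per-tree noise, and optional
  missing/false rings;
* an annual Delta-14C truth curve — a slow random-walk baseline carrying
  a one-year spike with exponential relaxation (the canonical shape of a
  solar-energetic-particle event), plus noisy multi-lab records with
  optional constant per-lab offsets;
* per-sample annual 14C series dissected from the truth curve, including
  the two-stage "coarse every 4th ring, then 20 dense rings around the
  event" design;
* a site of dated construction elements drawn from configured felling
  phases.

Default magnitudes are the study conditions: a 15.8 per-mil spike,
1.5 per-mil single-year lab noise, and a 303-year chronology.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calendar_units import CalendarYear, RadiocarbonValue, convert
from .felling import DatedElement
from .miyake import SampleSeries
from .refcurve import AnnualDelta14CDataset, ReferenceCurve
from .trw import RingWidthSeries

__all__ = [
    "SimulationConfig",
    "simulate_trw",
    "simulate_reference",
    "simulate_sample_series",
    "simulate_site",
    "dispilio_offsets",
]

# The seven felling years the site simulator uses by default (astronomical).
DEFAULT_FELLING_PHASES = (-5327, -5319, -5310, -5293, -5281, -5257, -5139)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic generators; identical config + seed
    reproduce outputs bit for bit."""

    seed: int = 0
    # ring-width generator
    chronology_length: int = 303
    n_trees: int = 20
    segment_length_mean: int = 66
    ar1_coef: float = 0.7
    ar1_innov_sd: float = 0.2
    signal_weight: float = 1.0  # beta multiplying the common signal
    tree_noise_sd: float = 0.2  # per-tree log-width noise
    age_trend_scale: float = 0.6  # amplitude of the negative-exponential trend
    age_trend_decay: float = 30.0  # years
    missing_ring_rate: float = 0.0
    false_ring_rate: float = 0.0
    # reference-curve generator
    ref_first_year: int = -5308  # astronomical; default covers the 5259 BC era
    ref_length: int = 120
    baseline_level: float = 90.0  # per mil, mid-6th-millennium BC ambient
    baseline_rw_sd: float = 1.0  # per mil per year
    spike_year: int = -5258  # astronomical (= 5259 BC)
    spike_magnitude: float = 15.8  # per mil
    spike_decay: float = 40.0  # years, exponential relaxation
    lab_noise_sd: float = 1.5  # per mil
    lab_offsets: dict = field(default_factory=dict)  # lab -> per-mil offset
    labs: tuple = ("LabA", "LabB")

    def __post_init__(self):
        for name in ("ar1_innov_sd", "tree_noise_sd", "baseline_rw_sd", "lab_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.missing_ring_rate < 0.05:
            raise ValueError("missing_ring_rate must be in [0, 0.05)")
        if not 0 <= self.false_ring_rate < 0.05:
            raise ValueError("false_ring_rate must be in [0, 0.05)")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic sub-stream per generator (stable across runs)."""
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )


def _ar1(rng, n: int, phi: float, innov_sd: float) -> np.ndarray:
    x = np.empty(n)
    stat_sd = innov_sd / math.sqrt(max(1e-12, 1 - phi**2)) if abs(phi) < 1 else innov_sd
    x[0] = rng.normal(0, stat_sd)
    eps = rng.normal(0, innov_sd, n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_trw(config: SimulationConfig):
    """Ring-width series sharing a common AR(1) signal.

    Returns ``(signal, series_list, truth)``; truth is a DataFrame with the
    true lag (position of each series' first ring on the chronology axis,
    year 1 = first chronology ring) and any missing/false ring positions.
    """
    rng = config.rng("trw")
    L = config.chronology_length
    signal = _ar1(rng, L, config.ar1_coef, config.ar1_innov_sd)
    series, rows = [], []
    for i in range(config.n_trees):
        seg = int(np.clip(rng.poisson(config.segment_length_mean), 30, L))
        start = int(rng.integers(1, L - seg + 2))  # chronology year of first ring
        ages = np.arange(seg)
        trend = config.age_trend_scale * np.exp(-ages / config.age_trend_decay)
        noise = rng.normal(0, config.tree_noise_sd, seg)
        logw = (math.log(100.0) + trend
                + config.signal_weight * signal[start - 1 : start - 1 + seg] + noise)
        widths = np.exp(logw)
        missing, false = [], []
        if config.missing_ring_rate > 0 or config.false_ring_rate > 0:
            keep = []
            for j in range(seg):
                u = rng.random()
                if u < config.missing_ring_rate:
                    missing.append(j)
                    continue
                keep.append(j)
                if u > 1 - config.false_ring_rate:
                    false.append(j)
                    keep.append(j)  # duplicated ring
            widths = widths[np.array(keep, dtype=int)]
        s = RingWidthSeries(
            sample_id=f"SYN{i:05d}",
            first_relative_year=1,
            widths=widths,
            genus="Juniperus",
        )
        series.append(s)
        rows.append(
            {"sample_id": s.sample_id, "true_lag": start - 1,
             "segment_length": seg, "missing_rings": missing, "false_rings": false}
        )
    return signal, series, pd.DataFrame(rows)


def simulate_reference(config: SimulationConfig):
    """Annual Delta-14C truth curve plus noisy multi-lab records.

    The truth is a random-walk baseline with a one-year rise of
    ``spike_magnitude`` at ``spike_year`` followed by exponential
    relaxation with time constant ``spike_decay``.  Each lab reports
    truth + lab offset + N(0, lab_noise_sd) per year.
    Returns ``(truth_curve, dataset)``.
    """
    rng = config.rng("reference")
    years = np.arange(config.ref_first_year, config.ref_first_year + config.ref_length)
    baseline = config.baseline_level + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0, config.baseline_rw_sd, len(years) - 1))]
    )
    spike = np.zeros(len(years))
    if years[0] <= config.spike_year <= years[-1]:
        after = years >= config.spike_year
        spike[after] = config.spike_magnitude * np.exp(
            -(years[after] - config.spike_year) / config.spike_decay
        )
    elif config.spike_magnitude != 0:
        raise ValueError("spike_year outside reference coverage")
    truth = baseline + spike
    truth_curve = ReferenceCurve(
        int(years[0]), truth, np.full(len(years), 1e-9), np.ones(len(years), dtype=int)
    )
    rows = []
    for lab in config.labs:
        offset = config.lab_offsets.get(lab, 0.0)
        noise = rng.normal(0, config.lab_noise_sd, len(years))
        for y, t, e in zip(years, truth, noise):
            rows.append(
                {"lab": lab, "archive": f"{lab}-tree", "year": int(y),
                 "delta14c": t + offset + e, "sigma": config.lab_noise_sd}
            )
    return truth_curve, AnnualDelta14CDataset(pd.DataFrame(rows))


def dispilio_offsets(n_rings: int = 60, coarse_step: int = 4,
                     dense_center: int = 20, dense_halfwidth: int = 10) -> np.ndarray:
    """Two-stage dissection design: every ``coarse_step``-th ring over the
    sample, then every ring in a dense window of 2*halfwidth around the
    expected event position (offset from the waney edge)."""
    coarse = np.arange(0, n_rings, coarse_step)
    dense = np.arange(max(0, dense_center - dense_halfwidth),
                      min(n_rings, dense_center + dense_halfwidth))
    return np.unique(np.concatenate([coarse, dense]))


def simulate_sample_series(
    config: SimulationConfig,
    rc_truth: ReferenceCurve,
    true_end_year: int,
    offsets: Sequence[int],
    sample_id: str = "SYN-SAMPLE",
    quantity: str = "delta14c",
    rng: Optional[np.random.Generator] = None,
) -> SampleSeries:
    """Dissect a sample from the truth curve with lab noise.

    ``offsets`` are ring numbers from the waney edge (0 = final ring);
    every ``true_end_year - r`` must be covered by the truth curve.
    ``quantity`` may be "delta14c" or "age_bp" (ages derived exactly from
    the truth before noise is added in age space).
    """
    if rng is None:
        rng = config.rng(f"sample:{sample_id}")
    offsets = np.asarray(offsets, dtype=int)
    truth_vals = np.array([rc_truth.at(true_end_year - int(r))[0] for r in offsets])
    if quantity == "delta14c":
        values = truth_vals + rng.normal(0, config.lab_noise_sd, len(offsets))
        sigmas = np.full(len(offsets), config.lab_noise_sd)
    elif quantity == "age_bp":
        ages, sig = [], []
        for r, d in zip(offsets, truth_vals):
            rv = convert(
                RadiocarbonValue("delta14c", float(d), config.lab_noise_sd,
                                 CalendarYear(true_end_year - int(r))),
                "age_bp",
            )
            ages.append(rv.value)
            sig.append(rv.sigma)
        ages = np.asarray(ages)
        sigmas = np.asarray(sig)
        values = ages + rng.normal(0, 1.0, len(offsets)) * sigmas
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return SampleSeries(sample_id, offsets, values, sigmas, quantity=quantity)


def simulate_site(
    config: SimulationConfig,
    phase_years: Sequence[int] = DEFAULT_FELLING_PHASES,
    elements_per_phase: int = 6,
    waney_edge_prob: float = 0.6,
    sapwood_range: tuple[int, int] = (15, 30),
):
    """Dated construction elements drawn from configured felling phases.

    Elements without a waney edge lose a random number of outer sapwood
    rings, so their final measured ring predates the felling year.
    Returns ``(elements, truth)`` with per-element true phase years.
    """
    rng = config.rng("site")
    elements, rows = [], []
    k = 0
    for phase in phase_years:
        for _ in range(elements_per_phase):
            waney = bool(rng.random() < waney_edge_prob)
            sap = int(rng.integers(sapwood_range[0], sapwood_range[1] + 1))
            lost = 0 if waney else int(rng.integers(0, sap))
            elements.append(
                DatedElement(
                    sample_id=f"ELEM{k:04d}",
                    genus="Juniperus" if rng.random() < 0.7 else "Quercus",
                    end_year=int(phase) - lost,
                    has_waney_edge=waney,
                    n_sapwood_rings=sap - lost,
                )
            )
            rows.append({"sample_id": f"ELEM{k:04d}", "true_phase_year": int(phase)})
            k += 1
    return elements, pd.DataFrame(rows)
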