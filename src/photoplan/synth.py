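"""Synthetic flow-cytometry event data with known ground truth.

The generator emulates the in vitro study design behind the reference
surfaces: SH-SY5Y cells loaded with the AuNP-mTHPC nanocomplex, activated at
650 nm (PDT) or 532 nm (PTT) on a training grid of intensities
{1, 6, 15, 30} mW/cm^2 x durations {1, 4, 8} min with 2 replicates, plus
held-out test settings, combined-course settings, and untreated /
laser-only / nanoparticle-only controls with ~4% background death.

True per-sample death probabilities come from a ground-truth dose-response
surface (default: the published degree-2 reference polynomials).  Event
distributions are log-normal: dead cells draw PI from a high component and
carry reduced forward scatter; injected artifacts are debris (sub-floor fsc)
and doublets (fsc_area ~ 2 fsc).  Every stochastic call takes an explicit
seed and returns a ledger reconciling the emitted events with their hidden
labels, so downstream estimators can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventTable
from .surfaces import ResponseSurface, reference_surfaces

TRAIN_INTENSITIES = (1.0, 6.0, 15.0, 30.0)
TRAIN_DURATIONS = (1.0, 4.0, 8.0)
TEST_CONDITIONS = ((2.0, 25.0), (6.0, 12.0), (7.0, 18.0))  # (tau, I0)
COMBINED_CONDITIONS = ((4.0, 6.0), (4.0, 15.0), (8.0, 6.0), (8.0, 15.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and distribution parameters of the generator.

    Defaults are the study conditions: 12 training settings x 2 replicates
    per modality, 4% +/- 2.5% control background death, replicate noise SD
    0.03 on the fraction scale, 5% debris and 3% doublet injection.
    """

    modality: str = "PDT"
    intensities: tuple[float, ...] = TRAIN_INTENSITIES
    durations: tuple[float, ...] = TRAIN_DURATIONS
    replicates: int = 2
    test_conditions: tuple[tuple[float, float], ...] = TEST_CONDITIONS
    truth_surface: ResponseSurface | None = None  # default: modality's reference
    control_death: float = 0.04
    control_death_sd: float = 0.025
    noise_sd: float = 0.03
    events_per_sample: int = 5000
    debris_rate: float = 0.05
    doublet_rate: float = 0.03
    # event-level distribution parameters (log-normal medians / sigmas)
    live_fsc_median: float = 50_000.0
    dead_fsc_factor: float = 0.6
    fsc_sigma: float = 0.2
    ssc_median: float = 20_000.0
    ssc_sigma: float = 0.3
    live_pi_median: float = 100.0
    dead_pi_median: float = 2000.0
    pi_sigma: float = 0.5
    debris_fsc_range: tuple[float, float] = (200.0, 3000.0)
    singlet_area_sd: float = 0.05
    doublet_area_mean: float = 2.0
    doublet_area_sd: float = 0.1

    def resolved_truth(self) -> ResponseSurface:
        if self.truth_surface is not None:
            return self.truth_surface
        pdt, ptt = reference_surfaces()
        return pdt if self.modality == "PDT" else ptt

    def training_grid(self) -> list[tuple[float, float]]:
        return [(tau, i0) for tau in self.durations for i0 in self.intensities]


@dataclass
class GroundTruthLedger:
    """Hidden truth emitted alongside synthetic data.

    ``samples`` maps sample_id to its true adjusted death probability, raw
    (background-inclusive) probability, and exact injected counts; event
    labels (live/dead/debris/doublet) are kept per sample so gating and
    estimation can be reconciled against the truth exactly.
    """

    samples: dict = field(default_factory=dict)

    def record(self, sample_id: str, **info) -> None:
        self.samples[sample_id] = info

    def total_events(self) -> int:
        return sum(
            s.get("n_cells", 0) + s.get("n_debris", 0) + s.get("n_doublets", 0)
            for s in self.samples.values()
        )


def generate_condition_table(
    cfg: GeneratorConfig, seed: int, include_test: bool = False
) -> tuple[pd.DataFrame, GroundTruthLedger]:
    """Condition-level death-rate table with replicate noise.

    Per-replicate death fractions are ``clip(truth(tau, I0) + N(0, noise_sd),
    0, 1)``; control rows (untreated, laser_only, np_only; one per replicate)
    draw from ``N(control_death, control_death_sd)`` clipped.  Returns the
    tidy table (columns modality, intensity_mw_cm2, duration_min, replicate,
    control_kind, death_fraction) and a ledger of true values.
    """
    rng = np.random.default_rng(seed)
    truth = cfg.resolved_truth()
    ledger = GroundTruthLedger()
    rows = []
    conditions = cfg.training_grid()
    if include_test:
        conditions = conditions + list(cfg.test_conditions)
    for tau, i0 in conditions:
        d_true = float(truth.predict(tau, i0))
        for rep in range(1, cfg.replicates + 1):
            d = float(np.clip(d_true + rng.normal(0.0, cfg.noise_sd), 0.0, 1.0))
            rows.append(
                dict(
                    modality=cfg.modality,
                    intensity_mw_cm2=i0,
                    duration_min=tau,
                    replicate=rep,
                    control_kind="none",
                    death_fraction=d,
                )
            )
            ledger.record(f"{cfg.modality}_t{tau}_i{i0}_r{rep}", true_death=d_true, drawn=d)
    for kind in ("untreated", "laser_only", "np_only"):
        for rep in range(1, cfg.replicates + 1):
            d = float(np.clip(rng.normal(cfg.control_death, cfg.control_death_sd), 0.0, 1.0))
            rows.append(
                dict(
                    modality=cfg.modality,
                    intensity_mw_cm2=0.0,
                    duration_min=0.0,
                    replicate=rep,
                    control_kind=kind,
                    death_fraction=d,
                )
            )
            ledger.record(f"{cfg.modality}_{kind}_r{rep}", true_death=cfg.control_death, drawn=d)
    return pd.DataFrame(rows), ledger


def _sample_events(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str,
    modality: str,
    intensity: float,
    duration: float,
    replicate: int,
    control_kind: str,
    p_dead_raw: float,
    ledger: GroundTruthLedger,
) -> pd.DataFrame:
    n = cfg.events_per_sample
    n_debris = int(rng.binomial(n, cfg.debris_rate))
    n_doublet = int(rng.binomial(n - n_debris, cfg.doublet_rate / max(1e-12, 1 - cfg.debris_rate)))
    n_cells = n - n_debris - n_doublet
    dead = rng.random(n_cells) < p_dead_raw
    n_dead = int(dead.sum())

    fsc = np.exp(rng.normal(np.log(cfg.live_fsc_median), cfg.fsc_sigma, n_cells))
    fsc[dead] *= cfg.dead_fsc_factor
    pi = np.where(
        dead,
        np.exp(rng.normal(np.log(cfg.dead_pi_median), cfg.pi_sigma, n_cells)),
        np.exp(rng.normal(np.log(cfg.live_pi_median), cfg.pi_sigma, n_cells)),
    )
    ssc = np.exp(rng.normal(np.log(cfg.ssc_median), cfg.ssc_sigma, n_cells))
    area = fsc * rng.normal(1.0, cfg.singlet_area_sd, n_cells)

    # doublets: two live-sized cells stuck together; area scales ~2x
    d_fsc = np.exp(rng.normal(np.log(cfg.live_fsc_median), cfg.fsc_sigma, n_doublet))
    d_pi = np.exp(rng.normal(np.log(cfg.live_pi_median), cfg.pi_sigma, n_doublet))
    d_ssc = np.exp(rng.normal(np.log(cfg.ssc_median), cfg.ssc_sigma, n_doublet))
    d_area = d_fsc * rng.normal(cfg.doublet_area_mean, cfg.doublet_area_sd, n_doublet)

    lo, hi = cfg.debris_fsc_range
    b_fsc = rng.uniform(lo, hi, n_debris)
    b_pi = np.exp(rng.normal(np.log(cfg.live_pi_median), cfg.pi_sigma, n_debris))
    b_ssc = np.exp(rng.normal(np.log(cfg.ssc_median * 0.2), cfg.ssc_sigma, n_debris))
    b_area = b_fsc * rng.normal(1.0, cfg.singlet_area_sd, n_debris)

    labels = np.concatenate(
        [np.where(dead, "dead", "live"), np.full(n_doublet, "doublet"), np.full(n_debris, "debris")]
    )
    df = pd.DataFrame(
        {
            "sample_id": sample_id,
            "modality": modality,
            "intensity_mw_cm2": intensity,
            "duration_min": duration,
            "replicate": replicate,
            "control_kind": control_kind,
            "fsc": np.concatenate([fsc, d_fsc, b_fsc]),
            "ssc": np.concatenate([ssc, d_ssc, b_ssc]),
            "fsc_area": np.abs(np.concatenate([area, d_area, b_area])),
            "pi": np.concatenate([pi, d_pi, b_pi]),
        }
    )
    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    ledger.record(
        sample_id,
        p_dead_raw=p_dead_raw,
        n_cells=n_cells,
        n_dead=n_dead,
        n_debris=n_debris,
        n_doublets=n_doublet,
        labels=labels[perm],
    )
    return df


def generate_events(
    cfg: GeneratorConfig, seed: int, conditions: Sequence[tuple[float, float]] | None = None
) -> tuple[EventTable, GroundTruthLedger]:
    """Per-cell event table for the design grid plus controls.

    Each treated sample's raw death probability is ``clip(truth(tau, I0) +
    noise + control_death, 0, 1)`` so that subtracting the measured control
    death recovers the truth surface; controls use the background rate
    alone.  The ledger records every injected label and count.
    """
    rng = np.random.default_rng(seed)
    truth = cfg.resolved_truth()
    ledger = GroundTruthLedger()
    frames = []
    conds = list(conditions) if conditions is not None else cfg.training_grid()
    for tau, i0 in conds:
        d_true = float(truth.predict(tau, i0))
        for rep in range(1, cfg.replicates + 1):
            d_rep = float(np.clip(d_true + rng.normal(0.0, cfg.noise_sd), 0.0, 1.0))
            p_raw = float(np.clip(d_rep + cfg.control_death, 0.0, 1.0))
            sid = f"{cfg.modality}_t{tau:g}_i{i0:g}_r{rep}"
            frames.append(
                _sample_events(
                    cfg, rng, sid, cfg.modality, i0, tau, rep, "none", p_raw, ledger
                )
            )
            ledger.samples[sid]["true_adjusted_death"] = d_rep
            ledger.samples[sid]["true_surface_death"] = d_true
    for kind in ("untreated", "laser_only", "np_only"):
        for rep in range(1, cfg.replicates + 1):
            p = float(np.clip(rng.normal(cfg.control_death, cfg.control_death_sd), 0.0, 1.0))
            sid = f"{cfg.modality}_{kind}_r{rep}"
            frames.append(
                _sample_events(cfg, rng, sid, cfg.modality, 0.0, 0.0, rep, kind, p, ledger)
            )
    return EventTable(pd.concat(frames, ignore_index=True)), ledger


def generate_state_mixture(
    n: int,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    means: tuple[float, float, float] = (0.1, 0.3, 0.7),
    sds: tuple[float, float, float] = (0.05, 0.08, 0.10),
    seed: int = 0,
) -> np.ndarray:
    """Per-cell death-probability draws from a three-component mixture.

    ``weights`` are (unaffected, affected, dead) mixing proportions with
    component means defaulting to (0.1, 0.3, 0.7); draws are Gaussian within
    component, clipped to [0, 1].  Used to exercise the three-state
    classifier on populations with known composition.
    """
    w = np.asarray(weights, dtype=float)
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=w)
    mu = np.asarray(means, dtype=float)[comp]
    sd = np.asarray(sds, dtype=float)[comp]
    return np.clip(rng.normal(mu, sd), 0.0, 1.0)
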