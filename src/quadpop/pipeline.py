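"""End-to-end orchestration: simulate -> detect -> populations -> energetics
-> kinetics, with a JSON run configuration and reproducible seeding.

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage name, and all derived seeds are recorded in the
run manifest, so a full run is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import ExponentialFit
from .model import (
    FoldingKineticsModel,
    FoldingKineticsResults,
    QuadruplexPopulationModel,
    QuadruplexPopulationResults,
)
from .populations import Mixture, assign_components, map_components_to_species, podnano, fit_gaussian_mixture
from .simulate import (
    ConditionSpec,
    ProtocolSpec,
    TraceSet,
    make_condition,
    simulate_fpp_series,
    simulate_fx_dataset,
)
from .traces import (
    RuptureThresholds,
    detect_ruptures,
    events_to_frame,
    filter_trace,
    segment_cycles,
)
from .wlc import NtConversion, SsStretchParams, WLCParams

__all__ = [
    "DEFAULT_FPP_TIMES",
    "RunConfig",
    "stage_seeds",
    "detect_events",
    "analyze_fpp_condition",
    "run_pipeline",
]

logger = logging.getLogger("quadpop")

DEFAULT_FPP_TIMES = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)

_KINETIC_GROUPS = {
    "transcription": {"HQ": ["2G-HQ", "3G-HQ"], "GQ+GT": ["GQ", "GT"]},
    "no_transcription": {"GQ": ["GQ"], "GT": ["GT"], "GQ+GT": ["GQ", "GT"]},
}


def stage_seeds(master_seed: int, stages: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2^31) derived from the master seed."""
    out = {}
    for name in stages:
        digest = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
        out[name] = int.from_bytes(digest[:4], "big") % (2**31 - 1)
    return out


@dataclass
class RunConfig:
    """Run configuration (JSON-loadable; unspecified values take defaults)."""

    conditions: list[str] = field(
        default_factory=lambda: ["transcription", "deaza", "no_transcription"]
    )
    n_curves: int = 2000
    seed: int = 1
    n_boot: int = 3000
    outdir: str = "quadpop_run"
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    wlc: WLCParams = field(default_factory=WLCParams)
    ntconv: NtConversion = field(default_factory=NtConversion)
    ss: SsStretchParams = field(default_factory=SsStretchParams)
    thresholds: RuptureThresholds = field(default_factory=RuptureThresholds)
    fpp_enable: bool = True
    fpp_conditions: list[str] = field(
        default_factory=lambda: ["transcription", "no_transcription"]
    )
    fpp_times: list[float] = field(default_factory=lambda: list(DEFAULT_FPP_TIMES))
    fpp_cycles_per_time: int = 500

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict = {}
        for key in ("conditions", "n_curves", "seed", "n_boot", "outdir"):
            if key in raw:
                kw[key] = raw[key]
        if "protocol" in raw:
            kw["protocol"] = ProtocolSpec(**raw["protocol"])
        if "wlc" in raw:
            w = raw["wlc"]
            kw["wlc"] = WLCParams(
                persistence_length=w.get("persistence_length_nm", 50.9),
                stretch_modulus=w.get("stretch_modulus_pN", 1168.0),
                temperature=w.get("temperature_K", 296.15),
            )
        if "ntconv" in raw:
            c = raw["ntconv"]
            kw["ntconv"] = NtConversion(
                contour_per_nt=c.get("contour_per_nt_nm", 0.44),
                folded_width=c.get("folded_width_nm", 2.3),
            )
        if "ss" in raw:
            s = raw["ss"]
            kw["ss"] = SsStretchParams(
                ss_persistence_length=s.get("persistence_length_nm", 1.0),
                ss_contour_per_nt=s.get("contour_per_nt_nm", 0.44),
            )
        if "thresholds" in raw:
            kw["thresholds"] = RuptureThresholds(**raw["thresholds"])
        fpp = raw.get("fpp", {})
        if "enable" in fpp:
            kw["fpp_enable"] = fpp["enable"]
        if "conditions" in fpp:
            kw["fpp_conditions"] = fpp["conditions"]
        if "incubation_times_s" in fpp:
            kw["fpp_times"] = fpp["incubation_times_s"]
        if "n_cycles_per_time" in fpp:
            kw["fpp_cycles_per_time"] = fpp["n_cycles_per_time"]
        return cls(**kw)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def detect_events(
    traceset: TraceSet,
    wlc: WLCParams = WLCParams(),
    conv: NtConversion = NtConversion(),
    thresholds: RuptureThresholds = RuptureThresholds(),
    window: int = 11,
    polyorder: int = 2,
    decimate_to: float = 100.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter every cycle of a trace set and detect its rupture events.

    Returns the events table (events-CSV schema, plus ``incubation_time_s``
    for FPP data) and the cycle table (one row per cycle with its
    incubation-time annotation when present).
    """
    all_events = []
    cycle_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for frame in traceset.cycles():
            filtered = filter_trace(
                frame, window=window, polyorder=polyorder, decimate_to=decimate_to,
                raw_rate=traceset.protocol.sample_rate,
            )
            for cycle in segment_cycles(filtered):
                t_inc = cycle.incubation_time
                cycle_rows.append((cycle.cycle_id, t_inc))
                events = detect_ruptures(cycle, wlc, thresholds, conv)
                frame_ev = events_to_frame(events)
                if t_inc is not None:
                    frame_ev["incubation_time_s"] = t_inc
                all_events.append(frame_ev)
    non_empty = [f for f in all_events if not f.empty]
    events = pd.concat(non_empty, ignore_index=True) if non_empty else events_to_frame([])
    cycles = pd.DataFrame(cycle_rows, columns=["cycle_id", "incubation_time_s"])
    if cycles["incubation_time_s"].isna().all():
        cycles = cycles.drop(columns=["incubation_time_s"])
    return events, cycles


def analyze_fpp_condition(
    condition: str | ConditionSpec,
    incubation_times=DEFAULT_FPP_TIMES,
    n_cycles: int = 500,
    seed: int = 1,
    protocol: ProtocolSpec = ProtocolSpec(),
    wlc: WLCParams = WLCParams(),
    conv: NtConversion = NtConversion(),
    thresholds: RuptureThresholds = RuptureThresholds(),
    mixture: Mixture | None = None,
    middle_hq_fraction: float | None = None,
    groups: dict[str, list[str]] | None = None,
) -> FoldingKineticsResults:
    """Simulate and analyze one condition's FPP series end to end.

    Species are assigned from the dL mixture (fitted to the pooled FPP
    events when none is supplied); under transcription the unresolved ~4 nm
    population is split stochastically between 3G-HQ and GT using
    ``middle_hq_fraction`` (from the GT/HQ ratio deconvolution).
    """
    cond = make_condition(condition) if isinstance(condition, str) else condition
    seeds = stage_seeds(seed, ["fpp_sim", "fpp_label", "fpp_fit"])
    ts = simulate_fpp_series(
        cond, incubation_times, n_cycles, protocol, seeds["fpp_sim"], wlc
    )
    events, cycles = detect_events(ts, wlc, conv, thresholds)
    logger.info(
        "FPP %s: %d cycles, %d events detected", cond.name, len(cycles), len(events)
    )
    hq_possible = cond.name in ("transcription", "lithium", "mutant", "spacer")
    values = events["delta_L_flank_nm"].to_numpy(dtype=float)
    if mixture is None:
        pm = podnano(values, n_boot=500, seed=seeds["fpp_label"])
        mixture = fit_gaussian_mixture(values, max(len(pm.peaks), 1), pm.peak_centers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = assign_components(values, mixture)
    names = map_components_to_species(mixture, hq_possible)
    labels = np.array([names[c] if c >= 0 else "unassigned" for c in comp], dtype=object)
    if hq_possible and middle_hq_fraction is not None:
        rng = np.random.default_rng(seeds["fpp_label"])
        mid = labels == "3G-HQ"
        u = rng.uniform(size=int(mid.sum()))
        labels[mid] = np.where(u < middle_hq_fraction, "3G-HQ", "GT")
    events = events.copy()
    events["species_label"] = labels
    if groups is None:
        groups = _KINETIC_GROUPS.get(cond.name, {"folded": [s.name for s in cond.species_catalog]})
    km = FoldingKineticsModel(cycles, events, groups)
    return km.fit(seed=seeds["fpp_fit"])


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    config: RunConfig
    population: QuadruplexPopulationResults
    kinetics: dict[str, FoldingKineticsResults]
    seeds: dict[str, int]


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis described by ``config`` and write its report.

    Per condition: simulate, detect, deconvolve and account; then the
    cross-condition GT/HQ split, force classes, free energies and (when
    enabled) FPP kinetics.  Artifacts are written under ``config.outdir``
    with a manifest of every derived seed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_names = [f"fx:{c}" for c in config.conditions] + [
        "population_fit"
    ] + [f"fpp:{c}" for c in config.fpp_conditions]
    seeds = stage_seeds(config.seed, stage_names)

    events: dict[str, pd.DataFrame] = {}
    totals: dict[str, int] = {}
    for cond_name in config.conditions:
        cond = make_condition(cond_name)
        ts = simulate_fx_dataset(
            cond, config.protocol, config.n_curves, seeds[f"fx:{cond_name}"], config.wlc
        )
        ev, _ = detect_events(ts, config.wlc, config.ntconv, config.thresholds)
        logger.info("F-X %s: %d curves, %d events", cond_name, ts.n_curves, len(ev))
        events[cond_name] = ev
        totals[cond_name] = ts.n_curves

    popmodel = QuadruplexPopulationModel(
        events, totals, wlc=config.wlc, conv=config.ntconv, ss=config.ss
    )
    results = popmodel.fit(n_boot=config.n_boot, seed=seeds["population_fit"])

    kinetics: dict[str, FoldingKineticsResults] = {}
    if config.fpp_enable:
        for cond_name in config.fpp_conditions:
            mixture = results.mixtures.get(cond_name)
            kinetics[cond_name] = analyze_fpp_condition(
                cond_name,
                config.fpp_times,
                config.fpp_cycles_per_time,
                seeds[f"fpp:{cond_name}"],
                config.protocol,
                config.wlc,
                config.ntconv,
                config.thresholds,
                mixture=mixture,
                middle_hq_fraction=results.middle_hq_fraction,
            )
    elif "transcription" not in config.conditions or "deaza" not in config.conditions:
        logger.warning("condition pair for GT/HQ deconvolution missing")

    _write_report(out, config, results, kinetics, seeds)
    return ReportBundle(config, results, kinetics, seeds)


def _fit_to_dict(fit: ExponentialFit) -> dict:
    return {
        "amplitude": fit.amplitude,
        "tau_s": fit.tau,
        "tau_ci_s": list(fit.tau_ci),
        "amplitude_ci": list(fit.amplitude_ci),
        "floor_flag": fit.floor_flag,
        "tau_label": fit.tau_label(),
    }


def _write_report(
    out: Path,
    config: RunConfig,
    results: QuadruplexPopulationResults,
    kinetics: dict[str, FoldingKineticsResults],
    seeds: dict[str, int],
) -> None:
    results.percent_table().to_csv(out / "percent_formation.csv", float_format="%.1f")
    for cond, ev in results.labelled_events.items():
        ev.to_csv(out / f"events_{cond}.csv", index=False, float_format="%.4f")
    dg_rows = []
    for cond, per_sp in results.free_energies.items():
        for sp, est in per_sp.items():
            dg_rows.append((cond, sp, est.dG, est.bias, est.se, est.n))
    pd.DataFrame(
        dg_rows, columns=["condition", "species", "dG_kcal_mol", "bias", "se", "n"]
    ).to_csv(out / "free_energies.csv", index=False, float_format="%.3f")
    kin_dump = {
        cond: {name: _fit_to_dict(s.fit) for name, s in res.series.items()}
        for cond, res in kinetics.items()
    }
    with open(out / "kinetics_fits.json", "w", encoding="utf-8") as fh:
        json.dump(kin_dump, fh, indent=1)
    for cond, res in kinetics.items():
        pd.concat(
            [s.points.assign(series=name) for name, s in res.series.items()],
            ignore_index=True,
        ).to_csv(out / f"fpp_points_{cond}.csv", index=False, float_format="%.4f")
    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "conditions": config.conditions,
        "n_curves": config.n_curves,
        "n_boot": config.n_boot,
        "aggregates": results.aggregates(),
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in asdict(config).items()}, sort_keys=True
            ).encode()
        ).hexdigest(),
    }
    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(results.summary())
        fh.write("\n\n")
        for cond, res in kinetics.items():
            fh.write(f"[{cond}]\n{res.summary()}\n\n")
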