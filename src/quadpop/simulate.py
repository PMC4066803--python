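"""Physics-based generator of synthetic force-spectroscopy datasets.

Emulates the raw data of a stalled-transcription optical-tweezers assay on a
(GGGGA)4 G-core: constant-loading-rate force-extension (F-X) ramps and
force-pump-probe (FPP) force-jump cycles, recorded at 1000 Hz with Gaussian
acquisition noise.

Each pulling cycle carries at most one folded species, drawn from a
condition-specific prevalence table (regular transcription, deaza-GTP
transcription, no transcription, plus mutant / Li+ / spacer controls).  The
tether is an extensible WLC handle (contour ~1595 nm); an unfolding event
adds a truncated-normal contour increment dL and ruptures stochastically
following Bell-Evans first-passage kinetics at the protocol's loading rate.
The rupture appears in the trace as an extension jump with a concomitant
force drop (effective trap/tether stiffness ~1.5 pN/nm) that the feedback
re-ramps away within ~20 ms.  FPP cycles refold at zero force with
species-specific single-exponential kinetics before being probed by the next
ramp.

Every dataset carries a truth manifest (species, dL, rupture force per
cycle) so downstream detection and deconvolution can be scored against
ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .wlc import WLCParams, wlc_ratio

__all__ = [
    "EULER_GAMMA",
    "SpeciesSpec",
    "ConditionSpec",
    "ProtocolSpec",
    "TraceSet",
    "CONDITION_NAMES",
    "make_condition",
    "draw_species",
    "bell_evans_mode",
    "bell_evans_k0_for_mode",
    "bell_evans_k0_for_mean",
    "sample_rupture_force",
    "simulate_fx_dataset",
    "simulate_fpp_series",
    "construct_sequences",
]

EULER_GAMMA = 0.5772156649015329

#: effective trap+tether stiffness converting an extension jump into the
#: transient force drop seen at a rupture (pN/nm)
RUPTURE_DROP_STIFFNESS = 1.8
#: feedback recovery time of the force ramp after a rupture (s)
RUPTURE_RECOVERY_TAU = 0.06
#: lowest force at which the extensible-WLC ratio is evaluated; below this
#: the interpolation formula is unreliable and the analysis never looks
_F_FLOOR = 0.5


@dataclass(frozen=True)
class SpeciesSpec:
    """One folded species: geometry, Bell-Evans unfolding, folding kinetics.

    Attributes
    ----------
    name : str
        One of ``2G-HQ | 3G-HQ | GT | GQ | none``.
    delta_L_mean, delta_L_sd : float
        Contour-length change distribution (nm), truncated > 0.
    barrier_distance : float
        Bell-Evans distance to the transition state x‡ (nm).
    intrinsic_rate : float
        Bell-Evans zero-force unfolding rate k0 (1/s).
    fold_tau : float
        Zero-force refolding time constant (s).
    """

    name: str
    delta_L_mean: float
    delta_L_sd: float
    barrier_distance: float
    intrinsic_rate: float
    fold_tau: float

    def __post_init__(self) -> None:
        if self.name != "none":
            if self.delta_L_sd < 0:
                raise ValueError("delta_L_sd must be >= 0")
            if self.barrier_distance <= 0 or self.intrinsic_rate <= 0:
                raise ValueError("Bell-Evans parameters must be > 0")
            if self.fold_tau <= 0:
                raise ValueError("fold_tau must be > 0")
        elif self.delta_L_mean != 0:
            raise ValueError("species 'none' must have delta_L_mean = 0")


@dataclass(frozen=True)
class ConditionSpec:
    """Steady-state species prevalences and species catalog for one condition."""

    name: str
    prevalence: dict[str, float]
    species_catalog: tuple[SpeciesSpec, ...]

    def __post_init__(self) -> None:
        total = sum(self.prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {total}")
        if any(p < 0 for p in self.prevalence.values()):
            raise ValueError("prevalences must be >= 0")
        known = {s.name for s in self.species_catalog} | {"none"}
        if set(self.prevalence) - known:
            raise ValueError("prevalence refers to unknown species")

    def species(self, name: str) -> SpeciesSpec:
        for s in self.species_catalog:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class ProtocolSpec:
    """Pulling-protocol parameters shared by F-X and FPP experiments."""

    loading_rate: float = 5.5  # pN/s
    force_max: float = 45.0  # pN; ramp turnaround, below the dsDNA plateau
    jump_high: float = 45.0  # pN; FPP unfolding jump
    jump_low: float = 0.0  # pN; FPP incubation force
    probe_start: float = 10.0  # pN; FPP probe ramps start here
    jump_duration: float = 0.02  # s
    sample_rate: float = 1000.0  # Hz
    noise_sd_force: float = 0.5  # pN
    noise_sd_extension: float = 1.0  # nm
    handle_contour: float = 1595.0  # nm (2028 + 2690 bp x 0.338 nm/bp)

    def __post_init__(self) -> None:
        if not (
            0.0 <= self.jump_low < self.probe_start < self.jump_high <= self.force_max
        ):
            raise ValueError("require 0 <= jump_low < probe_start < jump_high <= force_max")
        if self.sample_rate <= 0 or self.loading_rate <= 0:
            raise ValueError("sample_rate and loading_rate must be > 0")


# ---------------------------------------------------------------------------
# condition catalog
# ---------------------------------------------------------------------------

_WLC_DEFAULT = WLCParams()
_KT = _WLC_DEFAULT.thermal_energy
_XDAG = 4.0  # nm, Bell-Evans barrier distance for all quadruplex species;
# gives a rupture-force spread (Gumbel scale kT/x‡ ~ 1.0 pN, SD ~ 1.3 pN)
# matching the printed force-histogram widths (~±1-2 pN)
_CAL_RATE = 5.5  # pN/s, loading rate at which force targets are calibrated


def bell_evans_mode(loading_rate: float, x_dag: float, k0: float, kt: float = _KT) -> float:
    """Most probable rupture force at constant loading rate (closed form)."""
    return kt / x_dag * math.log(loading_rate * x_dag / (k0 * kt))


def bell_evans_k0_for_mode(
    mode: float, x_dag: float = _XDAG, loading_rate: float = _CAL_RATE, kt: float = _KT
) -> float:
    """Zero-force rate giving the requested most-probable rupture force."""
    return loading_rate * x_dag / (kt * math.exp(mode * x_dag / kt))


def bell_evans_k0_for_mean(
    mean: float, x_dag: float = _XDAG, loading_rate: float = _CAL_RATE, kt: float = _KT
) -> float:
    """Zero-force rate giving the requested mean rupture force.

    The Bell-Evans rupture-force distribution is (to excellent accuracy for
    k0 << loading-rate scale) a reversed Gumbel with scale kT/x‡, so
    mean = mode - gamma * kT / x‡.
    """
    return bell_evans_k0_for_mode(mean + EULER_GAMMA * kt / x_dag, x_dag, loading_rate, kt)


def _hq_species(name: str, dl: float, sd: float, tau: float) -> SpeciesSpec:
    return SpeciesSpec(name, dl, sd, _XDAG, bell_evans_k0_for_mean(31.0), tau)


def _gq_like(name: str, dl: float, sd: float, tau: float) -> SpeciesSpec:
    return SpeciesSpec(name, dl, sd, _XDAG, bell_evans_k0_for_mean(25.0), tau)


def _conditions() -> dict[str, ConditionSpec]:
    # dL centers/widths per condition follow the measured population
    # histograms; folding time constants: HQ 30 ms, GQ/GT 10 ms with RNA
    # present (below the 20 ms FPP floor), 150 ms without transcription.
    transcription = ConditionSpec(
        "transcription",
        {"2G-HQ": 0.173, "3G-HQ": 0.094, "GT": 0.038, "GQ": 0.122, "none": 0.573},
        (
            _hq_species("2G-HQ", 1.8, 0.2, 0.030),
            _hq_species("3G-HQ", 3.8, 0.5, 0.030),
            _gq_like("GT", 3.8, 0.5, 0.010),
            _gq_like("GQ", 6.0, 0.6, 0.010),
        ),
    )
    deaza = ConditionSpec(
        "deaza",
        {"GT": 0.081, "GQ": 0.259, "none": 0.660},
        (
            _gq_like("GT", 3.3, 0.4, 0.010),
            _gq_like("GQ", 5.5, 0.2, 0.010),
        ),
    )
    no_transcription = ConditionSpec(
        "no_transcription",
        {"GT": 0.147, "GQ": 0.096, "none": 0.757},
        (
            _gq_like("GT", 4.2, 0.5, 0.150),
            _gq_like("GQ", 6.0, 0.6, 0.150),
        ),
    )
    # controls: residual folded structures with broad dL, labelled GQ
    def control(name: str, folded: float) -> ConditionSpec:
        return ConditionSpec(
            name,
            {"GQ": folded, "none": round(1.0 - folded, 10)},
            (_gq_like("GQ", 5.0, 1.5, 0.150),),
        )

    return {
        "transcription": transcription,
        "deaza": deaza,
        "no_transcription": no_transcription,
        "lithium": control("lithium", 0.067),
        "mutant": control("mutant", 0.02),
        "spacer": control("spacer", 0.079),
    }


_CONDITIONS = _conditions()
CONDITION_NAMES = tuple(_CONDITIONS)


def make_condition(name: str, config: dict | None = None) -> ConditionSpec:
    """Return the named condition's prevalence table and species catalog.

    ``config`` may override prevalences via ``{"prevalence": {...}}``; the
    override must still sum to 1.
    """
    try:
        cond = _CONDITIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; known: {sorted(_CONDITIONS)}"
        ) from None
    if config and "prevalence" in config:
        cond = ConditionSpec(name, dict(config["prevalence"]), cond.species_catalog)
    return cond


# ---------------------------------------------------------------------------
# stochastic draws
# ---------------------------------------------------------------------------


def draw_species(
    condition: ConditionSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n species names i.i.d. from the condition's prevalences."""
    names = sorted(condition.prevalence)
    probs = np.array([condition.prevalence[k] for k in names])
    return rng.choice(np.array(names, dtype=object), size=n, p=probs / probs.sum())


def sample_rupture_force(
    species: SpeciesSpec,
    loading_rate: float,
    rng: np.random.Generator,
    size=None,
    force_start: float = 0.0,
):
    """Sample rupture forces from the Bell-Evans first-passage density.

    At constant loading rate r the survival from force ``force_start`` is
    ``exp(-a (e^{bF} - e^{bF0}))`` with ``b = x‡/kT``, ``a = k0 kT/(r x‡)``;
    inverse-CDF sampling is exact.
    """
    if loading_rate <= 0:
        raise ValueError("loading_rate must be > 0")
    b = species.barrier_distance / _KT
    a = species.intrinsic_rate * _KT / (loading_rate * species.barrier_distance)
    u = rng.uniform(size=size)
    f = np.log(np.exp(b * force_start) - np.log(u) / a) / b
    return f if np.ndim(f) else float(f)


def _draw_delta_L(species: SpeciesSpec, rng: np.random.Generator) -> float:
    """Truncated-normal (> 0) contour-length change."""
    for _ in range(100):
        dl = rng.normal(species.delta_L_mean, species.delta_L_sd)
        if dl > 0:
            return float(dl)
    return max(species.delta_L_mean, 0.1)


# ---------------------------------------------------------------------------
# trace synthesis
# ---------------------------------------------------------------------------


def _ratio_safe(force: np.ndarray, wlc: WLCParams) -> np.ndarray:
    """x/L with the low-force region clamped (analysis never uses F < 5 pN)."""
    return np.maximum(wlc_ratio(np.maximum(force, _F_FLOOR), wlc), 0.0)


def _fx_cycle_frame(
    cycle_id: int,
    species: str,
    delta_L: float,
    f_rupture: float,
    protocol: ProtocolSpec,
    wlc: WLCParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthesize one stretch/relax F-X cycle at 1000 Hz."""
    r, rate = protocol.loading_rate, protocol.sample_rate
    n_up = int(round(protocol.force_max / r * rate)) + 1
    t_up = np.arange(n_up) / rate
    f_up = r * t_up
    contour_up = np.full(n_up, protocol.handle_contour)
    ruptured = species != "none" and f_rupture < protocol.force_max - 0.5
    if ruptured:
        i_r = int(np.searchsorted(f_up, f_rupture))
        dx_jump = delta_L * wlc_ratio(f_rupture, wlc)
        contour_up[i_r:] += delta_L
        # transient force drop, re-ramped by the feedback
        drop = RUPTURE_DROP_STIFFNESS * dx_jump
        f_up = f_up.copy()
        f_up[i_r:] -= drop * np.exp(-(t_up[i_r:] - t_up[i_r]) / RUPTURE_RECOVERY_TAU)
        f_up = np.maximum(f_up, 0.0)
    x_up = contour_up * _ratio_safe(f_up, wlc)

    n_dn = int(round(protocol.force_max / r * rate))
    t_dn = t_up[-1] + np.arange(1, n_dn + 1) / rate
    f_dn = protocol.force_max - r * (t_dn - t_up[-1])
    contour_dn = protocol.handle_contour + (delta_L if ruptured else 0.0)
    x_dn = contour_dn * _ratio_safe(f_dn, wlc)

    t = np.concatenate([t_up, t_dn])
    f = np.concatenate([f_up, f_dn])
    x = np.concatenate([x_up, x_dn])
    f = f + rng.normal(0.0, protocol.noise_sd_force, f.size)
    x = x + rng.normal(0.0, protocol.noise_sd_extension, x.size)
    phase = np.array(["stretch"] * n_up + ["relax"] * n_dn, dtype=object)
    return pd.DataFrame(
        {
            "time_s": t,
            "force_pN": f,
            "extension_nm": x,
            "cycle_id": cycle_id,
            "phase": phase,
        }
    )


def _fpp_cycle_frame(
    cycle_id: int,
    species: str,
    delta_L: float,
    f_rupture: float,
    incubation_time: float,
    protocol: ProtocolSpec,
    wlc: WLCParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthesize one FPP cycle: token hold at 0 pN, then the probe ramp.

    The unfold jump and the multi-second idle hold carry no analyzable
    signal, so the hold is stored as a 5-sample token annotated with the
    incubation time, and the probe ramp is truncated shortly after the
    rupture (or runs to force_max when nothing is folded).
    """
    r, rate = protocol.loading_rate, protocol.sample_rate
    n_hold = 5
    ruptured = species != "none" and f_rupture < protocol.force_max - 0.5
    f_end = min(protocol.force_max, f_rupture + 4.0) if ruptured else protocol.force_max
    n_probe = int(round((f_end - protocol.probe_start) / r * rate)) + 1
    t_hold = np.arange(n_hold) / rate
    t_probe = t_hold[-1] + protocol.jump_duration + np.arange(n_probe) / rate
    f_probe = protocol.probe_start + r * (t_probe - t_probe[0])
    contour = np.full(n_probe, protocol.handle_contour)
    if ruptured:
        i_r = int(np.searchsorted(f_probe, f_rupture))
        dx_jump = delta_L * wlc_ratio(f_rupture, wlc)
        contour[i_r:] += delta_L
        drop = RUPTURE_DROP_STIFFNESS * dx_jump
        f_probe = f_probe.copy()
        f_probe[i_r:] -= drop * np.exp(
            -(t_probe[i_r:] - t_probe[i_r]) / RUPTURE_RECOVERY_TAU
        )
        f_probe = np.maximum(f_probe, 0.0)
    x_probe = contour * _ratio_safe(f_probe, wlc)
    x_hold = np.zeros(n_hold)

    t = np.concatenate([t_hold, t_probe])
    f = np.concatenate([np.zeros(n_hold), f_probe])
    x = np.concatenate([x_hold, x_probe])
    f = f + rng.normal(0.0, protocol.noise_sd_force, f.size)
    x = x + rng.normal(0.0, protocol.noise_sd_extension, x.size)
    phase = np.array(["hold"] * n_hold + ["probe"] * n_probe, dtype=object)
    return pd.DataFrame(
        {
            "time_s": t,
            "force_pN": f,
            "extension_nm": x,
            "cycle_id": cycle_id,
            "phase": phase,
            "incubation_time_s": incubation_time,
        }
    )


@dataclass
class TraceSet:
    """A synthetic dataset: cycle-level truth plus lazily synthesized traces.

    ``manifest`` rows carry the generator truth (species, dL, rupture force,
    and for FPP data the incubation time) for every cycle; ``cycles()``
    regenerates the corresponding trace frames deterministically from the
    stored seed, so a TraceSet is cheap to hold and byte-stable to write.
    """

    kind: str  # "fx" | "fpp"
    condition: ConditionSpec
    protocol: ProtocolSpec
    wlc: WLCParams
    seed: int
    manifest: pd.DataFrame = field(repr=False)

    @property
    def n_curves(self) -> int:
        return len(self.manifest)

    def cycles(self) -> Iterator[pd.DataFrame]:
        """Yield one trace DataFrame per cycle, in cycle order."""
        child_seeds = np.random.SeedSequence(self.seed).spawn(len(self.manifest) + 1)
        for row, ss in zip(self.manifest.itertuples(index=False), child_seeds[1:]):
            rng = np.random.default_rng(ss)
            if self.kind == "fx":
                yield _fx_cycle_frame(
                    row.cycle_id, row.species, row.true_delta_L_nm,
                    row.true_rupture_force_pN, self.protocol, self.wlc, rng,
                )
            else:
                yield _fpp_cycle_frame(
                    row.cycle_id, row.species, row.true_delta_L_nm,
                    row.true_rupture_force_pN, row.incubation_time_s,
                    self.protocol, self.wlc, rng,
                )

    def to_frame(self) -> pd.DataFrame:
        """Materialize the full trace table (use only for modest n_curves)."""
        return pd.concat(list(self.cycles()), ignore_index=True)

    def to_tsv(self, path) -> None:
        """Write the trace table as TSV with fixed formatting (byte-stable)."""
        first = True
        with open(path, "w", encoding="utf-8") as fh:
            for frame in self.cycles():
                frame.to_csv(
                    fh, sep="\t", index=False, header=first,
                    float_format="%.4f", lineterminator="\n",
                )
                first = False

    def manifest_to_json(self, path) -> None:
        records = self.manifest.to_dict(orient="records")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1)


def simulate_fx_dataset(
    condition: ConditionSpec,
    protocol: ProtocolSpec = ProtocolSpec(),
    n_curves: int = 100,
    seed: int = 1,
    wlc: WLCParams = WLCParams(),
) -> TraceSet:
    """Simulate ``n_curves`` stretch/relax F-X cycles for one condition."""
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    species = draw_species(condition, n_curves, rng)
    delta_L = np.zeros(n_curves)
    f_rup = np.full(n_curves, np.nan)
    for i, name in enumerate(species):
        if name == "none":
            continue
        sp = condition.species(name)
        delta_L[i] = _draw_delta_L(sp, rng)
        f_rup[i] = sample_rupture_force(sp, protocol.loading_rate, rng)
    manifest = pd.DataFrame(
        {
            "cycle_id": np.arange(n_curves),
            "species": species,
            "true_delta_L_nm": delta_L,
            "true_rupture_force_pN": f_rup,
        }
    )
    return TraceSet("fx", condition, protocol, wlc, seed, manifest)


def fold_probability(
    condition: ConditionSpec, species_name: str, t: float
) -> float:
    """Generator law: P(species folded after incubation t at zero force).

    ``prevalence * (1 - exp(-t / fold_tau))``; saturates to the steady-state
    prevalence as t -> infinity.
    """
    sp = condition.species(species_name)
    return condition.prevalence[species_name] * (1.0 - math.exp(-t / sp.fold_tau))


def simulate_fpp_series(
    condition: ConditionSpec,
    incubation_times: Sequence[float],
    n_cycles: int = 500,
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int = 1,
    wlc: WLCParams = WLCParams(),
) -> TraceSet:
    """Simulate FPP force-jump cycles over a grid of incubation times.

    Per cycle the structure present at the probe is drawn from
    ``P(s, t) = prevalence_s (1 - exp(-t/tau_s))``, ``P(none) = 1 - sum``;
    rupture forces are Bell-Evans draws conditioned on surviving the jump to
    ``probe_start``.
    """
    times = list(incubation_times)
    if not times or any(t < 0 for t in times):
        raise ValueError("incubation_times must be non-empty and >= 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    rows = []
    cycle_id = 0
    folded_names = [s.name for s in condition.species_catalog]
    for t in times:
        probs = np.array([fold_probability(condition, s, t) for s in folded_names])
        p_none = 1.0 - probs.sum()
        p = np.concatenate([probs, [p_none]])
        names = folded_names + ["none"]
        picks = rng.choice(len(names), size=n_cycles, p=p)
        for k in picks:
            name = names[k]
            if name == "none":
                dl, fr = 0.0, np.nan
            else:
                sp = condition.species(name)
                dl = _draw_delta_L(sp, rng)
                fr = sample_rupture_force(
                    sp, protocol.loading_rate, rng, force_start=protocol.probe_start
                )
            rows.append((cycle_id, name, dl, fr, t))
            cycle_id += 1
    manifest = pd.DataFrame(
        rows,
        columns=[
            "cycle_id", "species", "true_delta_L_nm",
            "true_rupture_force_pN", "incubation_time_s",
        ],
    )
    return TraceSet("fpp", condition, protocol, wlc, seed, manifest)


def construct_sequences() -> dict[str, str]:
    """Bundled construct sequences (G-core, G-to-T mutant, ATTTTA spacer)."""
    from Bio import SeqIO

    path = resources.files("quadpop") / "data" / "constructs.fasta"
    with path.open("r") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
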