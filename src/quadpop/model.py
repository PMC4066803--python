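"""Model/Results objects tying the analysis stages together.

Two top-level analyses are exposed in the fit/results idiom:

* :class:`QuadruplexPopulationModel` — built from per-condition rupture
  events (detected or simulated); ``fit()`` runs the PoDNano deconvolution,
  Gaussian-mixture component assignment, percent-formation accounting, the
  GT/HQ ratio deconvolution across conditions, the rupture-force random
  deconvolution and per-species Jarzynski free energies, returning a
  :class:`QuadruplexPopulationResults` with a printable summary table.
* :class:`FoldingKineticsModel` — built from force-pump-probe cycles and
  their species-labelled events; ``fit()`` returns per-group exponential
  time constants with bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import populations as pop
from .energetics import FreeEnergyEstimate, jarzynski_dG, unfolding_work
from .kinetics import ExponentialFit, FPPSeries, fit_exponential, folded_fraction_series
from .traces import RuptureEvent
from .wlc import NtConversion, SsStretchParams, WLCParams

__all__ = [
    "QuadruplexPopulationModel",
    "QuadruplexPopulationResults",
    "FoldingKineticsModel",
    "FoldingKineticsResults",
]

# whether hybrid (DNA/RNA) quadruplexes can form: requires transcription
# with normal GTP (7-deaza guanine cannot make Hoogsteen quartets)
_HQ_POSSIBLE = {
    "transcription": True,
    "deaza": False,
    "no_transcription": False,
    "lithium": True,
    "mutant": True,
    "spacer": True,
}


def _events_frame_to_objects(events: pd.DataFrame) -> list[RuptureEvent]:
    return [
        RuptureEvent(
            cycle_id=int(r.cycle_id),
            rupture_force=float(r.F_rupture_pN),
            delta_x=float(r.delta_x_nm),
            delta_L_flank=float(r.delta_L_flank_nm),
            delta_L_wlcfit=float(r.delta_L_wlcfit_nm),
            nt=int(r.nt),
            species_label=getattr(r, "species_label", None),
        )
        for r in events.itertuples(index=False)
    ]


class QuadruplexPopulationModel:
    """Population analysis over one or more experimental conditions.

    Parameters
    ----------
    events : dict of condition -> DataFrame
        Detected rupture events (events-CSV schema, one accepted event per
        curve).
    n_curves : dict of condition -> int
        Total pulling curves per condition, event-bearing or not.
    """

    def __init__(
        self,
        events: dict[str, pd.DataFrame],
        n_curves: dict[str, int],
        wlc: WLCParams = WLCParams(),
        conv: NtConversion = NtConversion(),
        ss: SsStretchParams = SsStretchParams(),
    ) -> None:
        if set(events) != set(n_curves):
            raise ValueError("events and n_curves must cover the same conditions")
        self.events = events
        self.n_curves = n_curves
        self.wlc = wlc
        self.conv = conv
        self.ss = ss

    @classmethod
    def from_simulation(
        cls,
        conditions=("transcription", "deaza", "no_transcription"),
        n_curves: int | dict[str, int] = 2000,
        seed: int = 1,
        **kwargs,
    ) -> "QuadruplexPopulationModel":
        """Simulate F-X datasets per condition and detect their events."""
        from .pipeline import detect_events, stage_seeds
        from .simulate import ProtocolSpec, make_condition, simulate_fx_dataset

        protocol = kwargs.pop("protocol", ProtocolSpec())
        wlc = kwargs.pop("wlc", WLCParams())
        seeds = stage_seeds(seed, [f"fx:{c}" for c in conditions])
        events, totals = {}, {}
        for cond_name in conditions:
            n = n_curves[cond_name] if isinstance(n_curves, dict) else n_curves
            ts = simulate_fx_dataset(
                make_condition(cond_name), protocol, n, seeds[f"fx:{cond_name}"], wlc
            )
            ev, _ = detect_events(ts, wlc=wlc, **kwargs)
            events[cond_name] = ev
            totals[cond_name] = n
        return cls(events, totals, wlc=wlc)

    def fit(self, n_boot: int = 3000, seed: int = 1) -> "QuadruplexPopulationResults":
        """Run deconvolution, accounting, force classes and free energies."""
        rng = np.random.default_rng(seed)
        population_models: dict[str, pop.PopulationModel] = {}
        mixtures: dict[str, pop.Mixture] = {}
        summaries: dict[str, pop.ConditionSummary] = {}
        labelled: dict[str, pd.DataFrame] = {}

        for cond, ev in self.events.items():
            values = ev["delta_L_flank_nm"].to_numpy(dtype=float)
            if values.size >= 20:
                pm = pop.podnano(values, n_boot=n_boot, seed=int(rng.integers(2**31 - 1)))
                k = max(len(pm.peaks), 1)
                mixture = pop.fit_gaussian_mixture(values, k, init_means=pm.peak_centers)
                pm.mixture = mixture
            else:
                # too few events for deconvolution (control conditions):
                # a single broad component
                pm = None
                mixture = pop.Mixture(
                    np.array([1.0]),
                    np.array([values.mean() if values.size else 0.0]),
                    np.array([max(values.std(), 0.5) if values.size else 0.5]),
                )
            population_models[cond] = pm
            mixtures[cond] = mixture
            summaries[cond] = pop.percent_formation(
                values, self.n_curves[cond], mixture, cond,
                rna_present=_HQ_POSSIBLE.get(cond, True),
            )
            labelled[cond] = ev.copy()

        middle_hq_fraction = None
        if "transcription" in summaries and "deaza" in summaries:
            before = summaries["transcription"]
            try:
                after = pop.deconvolve_gt_hq(before, summaries["deaza"])
            except ZeroDivisionError:
                warnings.warn(
                    "deaza GQ percentage is zero (populations unresolved); "
                    "GT/HQ deconvolution skipped",
                    stacklevel=2,
                )
            else:
                summaries["transcription"] = after
                if before.middle_total > 0:
                    middle_hq_fraction = after.percent["3G-HQ"] / before.middle_total
        elif "transcription" in summaries:
            warnings.warn(
                "no deaza condition available; GT/HQ deconvolution skipped",
                stacklevel=2,
            )

        # species labels per event (middle population split stochastically)
        for cond, ev in labelled.items():
            if ev.empty:
                ev["species_label"] = pd.Series(dtype=object)
                continue
            values = ev["delta_L_flank_nm"].to_numpy(dtype=float)
            mixture = mixtures[cond]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp = pop.assign_components(values, mixture)
            names = pop.map_components_to_species(
                mixture, _HQ_POSSIBLE.get(cond, True)
            )
            labels = np.array(
                [names[c] if c >= 0 else "unassigned" for c in comp], dtype=object
            )
            if cond == "transcription" and middle_hq_fraction is not None:
                mid = labels == "3G-HQ"
                u = rng.uniform(size=int(mid.sum()))
                labels[mid] = np.where(u < middle_hq_fraction, "3G-HQ", "GT")
            ev["species_label"] = labels

        force_deconvolutions: dict[str, pop.ForceDeconvolution] = {}
        for cond, ev in labelled.items():
            forces = ev["F_rupture_pN"].to_numpy(dtype=float)
            if forces.size >= 20:
                force_deconvolutions[cond] = pop.random_force_deconvolution(
                    forces, k=2, seed=int(rng.integers(2**31 - 1))
                )

        free_energies: dict[str, dict[str, FreeEnergyEstimate]] = {}
        for cond, ev in labelled.items():
            per_species: dict[str, FreeEnergyEstimate] = {}
            for sp, grp in ev.groupby("species_label"):
                if sp == "unassigned" or len(grp) < 5:
                    continue
                works = [
                    unfolding_work(e, self.wlc, self.ss).net_work
                    for e in _events_frame_to_objects(grp)
                ]
                per_species[sp] = jarzynski_dG(
                    works, self.wlc.thermal_energy,
                    seed=int(rng.integers(2**31 - 1)),
                )
            if per_species:
                free_energies[cond] = per_species

        return QuadruplexPopulationResults(
            model=self,
            summaries=summaries,
            population_models=population_models,
            mixtures=mixtures,
            labelled_events=labelled,
            force_deconvolutions=force_deconvolutions,
            free_energies=free_energies,
            middle_hq_fraction=middle_hq_fraction,
            seed=seed,
        )


@dataclass
class QuadruplexPopulationResults:
    """Fitted population analysis across conditions."""

    model: QuadruplexPopulationModel
    summaries: dict[str, pop.ConditionSummary]
    population_models: dict[str, pop.PopulationModel | None]
    mixtures: dict[str, pop.Mixture]
    labelled_events: dict[str, pd.DataFrame]
    force_deconvolutions: dict[str, pop.ForceDeconvolution]
    free_energies: dict[str, dict[str, FreeEnergyEstimate]]
    middle_hq_fraction: float | None
    seed: int

    def percent_table(self) -> pd.DataFrame:
        """Species x condition percent-formation table."""
        cols = {}
        for cond, s in self.summaries.items():
            cols[cond] = {sp: s.percent.get(sp, 0.0) for sp in pop.SPECIES_ORDER}
        return pd.DataFrame(cols).reindex(list(pop.SPECIES_ORDER))

    def aggregates(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if "transcription" in self.summaries:
            s = self.summaries["transcription"]
            out["hq_total_transcription"] = pop.hq_total(s)
            out["gq_gt_total_transcription"] = pop.gq_gt_total(s)
            out["quadruplex_total_transcription"] = pop.quadruplex_total(s)
        if "no_transcription" in self.summaries:
            out["quadruplex_total_no_transcription"] = pop.quadruplex_total(
                self.summaries["no_transcription"]
            )
        return out

    def summary(self) -> str:
        """Plain-text report: percent table, aggregates, forces, dG."""
        lines = ["Quadruplex population analysis", "=" * 34, ""]
        lines.append("Percent formation (% of all F-X curves)")
        lines.append(self.percent_table().round(1).to_string())
        agg = self.aggregates()
        if agg:
            lines.append("")
            for k, v in agg.items():
                lines.append(f"{k:38s} {v:g}")
        for cond, fd in self.force_deconvolutions.items():
            means = fd.class_means
            lines.append("")
            lines.append(
                f"rupture-force classes [{cond}]: "
                + ", ".join(f"{m:.1f} pN (n={len(f)})" for m, f in zip(means, fd.class_forces))
            )
        for cond, per_sp in self.free_energies.items():
            lines.append("")
            lines.append(f"Jarzynski dG_unfold [{cond}] (kcal/mol):")
            for sp, est in sorted(per_sp.items()):
                lines.append(
                    f"  {sp:7s} {est.dG:5.1f} +/- {est.se:.1f} "
                    f"(bias {est.bias:+.1f}, n={est.n})"
                )
        return "\n".join(lines)

    def plot_populations(self, condition: str, ax=None):
        """dL histogram with the KDE and mixture overlay for one condition."""
        from .plotting import plot_delta_l_populations

        return plot_delta_l_populations(self, condition, ax=ax)


class FoldingKineticsModel:
    """Folded-fraction kinetics from labelled force-pump-probe events.

    Parameters
    ----------
    cycle_table : DataFrame
        One row per probe cycle (``cycle_id``, ``incubation_time_s``).
    events : DataFrame
        Detected events with ``cycle_id`` and ``species_label``.
    groups : dict
        Series name -> species label(s) pooled into that series, e.g.
        ``{"HQ": ["2G-HQ", "3G-HQ"], "GQ+GT": ["GQ", "GT"]}``.
    """

    def __init__(
        self,
        cycle_table: pd.DataFrame,
        events: pd.DataFrame,
        groups: dict[str, list[str]],
    ) -> None:
        self.cycle_table = cycle_table
        self.events = events
        self.groups = groups

    def fit(self, seed: int = 1, n_boot: int = 200) -> "FoldingKineticsResults":
        rng = np.random.default_rng(seed)
        series: dict[str, FPPSeries] = {}
        for name, species in self.groups.items():
            s = folded_fraction_series(self.cycle_table, self.events, species)
            s.fit = fit_exponential(
                s.points, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
            )
            series[name] = s
        return FoldingKineticsResults(series=series, seed=seed)


@dataclass
class FoldingKineticsResults:
    """Per-group exponential folding fits."""

    series: dict[str, FPPSeries]
    seed: int

    def fits(self) -> dict[str, ExponentialFit]:
        return {k: s.fit for k, s in self.series.items()}

    def summary(self) -> str:
        lines = ["Folding kinetics (force pump-probe)", "=" * 35]
        for name, s in self.series.items():
            fit = s.fit
            lines.append(
                f"{name:8s} A = {fit.amplitude:.3f}  tau = {fit.tau_label()}"
                f"  [95% CI {fit.tau_ci[0] * 1e3:.0f}-{fit.tau_ci[1] * 1e3:.0f} ms]"
                + ("  (below detection floor)" if fit.floor_flag else "")
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_kinetics

        return plot_kinetics(self, ax=ax)
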