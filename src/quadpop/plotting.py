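"""Convenience plots for population and kinetics results."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_delta_l_populations", "plot_force_classes", "plot_kinetics"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_delta_l_populations(results, condition: str, ax=None):
    """Histogram of event dL with the PoDNano KDE and mixture overlay."""
    ax = _get_ax(ax)
    ev = results.labelled_events[condition]
    values = ev["delta_L_flank_nm"].to_numpy(dtype=float)
    ax.hist(values, bins=40, density=True, alpha=0.4, label="events")
    pm = results.population_models.get(condition)
    if pm is not None:
        grid, dens = pm.kde_grid
        ax.plot(grid, dens, label="KDE")
        for pk in pm.peaks:
            ax.axvline(pk.center, ls=":", lw=0.8)
    mix = results.mixtures[condition]
    grid = np.linspace(values.min() - 1, values.max() + 1, 400)
    total = np.zeros_like(grid)
    for w, m, s in zip(mix.weights, mix.means, mix.sds):
        comp = w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        ax.plot(grid, comp, ls="--", lw=0.8)
        total += comp
    ax.plot(grid, total, lw=1.2, label="mixture")
    ax.set_xlabel("dL (nm)")
    ax.set_ylabel("density")
    ax.set_title(condition)
    ax.legend()
    return ax


def plot_force_classes(results, condition: str, ax=None):
    """Rupture-force histogram with the randomly deconvolved classes."""
    ax = _get_ax(ax)
    fd = results.force_deconvolutions[condition]
    allf = np.concatenate(fd.class_forces) if fd.class_forces else np.array([])
    bins = np.histogram_bin_edges(allf, bins=25)
    ax.hist(allf, bins=bins, alpha=0.35, label="all events")
    for i, f in enumerate(fd.class_forces):
        ax.hist(f, bins=bins, histtype="step", label=f"class {i} ({np.mean(f):.1f} pN)")
    ax.set_xlabel("rupture force (pN)")
    ax.set_ylabel("count")
    ax.set_title(condition)
    ax.legend()
    return ax


def plot_kinetics(results, ax=None):
    """Folded fraction vs incubation time with exponential fits."""
    ax = _get_ax(ax)
    for name, s in results.series.items():
        pts = s.points
        ax.errorbar(
            pts["incubation_time_s"], pts["folded_fraction"], yerr=pts["se"],
            fmt="o", ms=4, label=name,
        )
        if s.fit is not None:
            tg = np.geomspace(
                max(pts["incubation_time_s"].min(), 1e-3),
                pts["incubation_time_s"].max(), 200,
            )
            ax.plot(tg, s.fit.amplitude * (1 - np.exp(-tg / s.fit.tau)), lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("incubation time (s)")
    ax.set_ylabel("folded fraction")
    ax.legend()
    return ax
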