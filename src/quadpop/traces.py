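"""Turn raw force-extension traces into rupture events.

Pipeline: Savitzky-Golay filter the 1000 Hz recording and decimate to
100 Hz; segment into pulling cycles; scan the loading (stretch/probe) phase
of each cycle for abrupt force drops; for each accepted drop measure the
rupture force and the contour-length change dL by two independent routes:

* flanking points: the extension difference across the two data points
  flanking the rupture, translated to equal force via the local WLC slope,
  divided by the WLC ratio at the rupture force;
* WLC fits: the difference between contour lengths fitted to the relax
  branch and to the pre-rupture stretch branch (the stretch/relax extension
  difference at any common force, expressed as a contour change).

On clean data the two routes agree to a few percent; the flanking route is
the per-event measurement used for population histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .wlc import NtConversion, WLCParams, delta_L_from_jump, nt_count, wlc_ratio, wlc_ratio_slope

__all__ = [
    "ForceExtensionCycle",
    "RuptureEvent",
    "RuptureThresholds",
    "filter_trace",
    "segment_cycles",
    "detect_ruptures",
    "events_to_frame",
]

_LOADING_PHASES = ("stretch", "probe")


@dataclass
class ForceExtensionCycle:
    """One pulling cycle of filtered samples with per-sample phase labels."""

    cycle_id: int
    samples: pd.DataFrame  # columns time_s, force_pN, extension_nm, phase

    def __post_init__(self) -> None:
        t = self.samples["time_s"].to_numpy()
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing within a cycle")

    @property
    def incubation_time(self) -> float | None:
        if "incubation_time_s" in self.samples.columns:
            return float(self.samples["incubation_time_s"].iloc[0])
        return None


@dataclass
class RuptureEvent:
    """One unfolding transition."""

    cycle_id: int
    rupture_force: float  # pN
    delta_x: float  # nm, equal-force extension jump
    delta_L_flank: float  # nm, flanking-point route
    delta_L_wlcfit: float  # nm, WLC contour-fit route (NaN if no relax branch)
    nt: int
    species_label: str | None = None


@dataclass(frozen=True)
class RuptureThresholds:
    """Detection and acceptance settings (declared, matched to generator SNR)."""

    drop_min: float = 1.5  # pN, minimum force drop
    gap_max: int = 3  # filtered samples the drop may span
    fit_force_min: float = 5.0  # pN, lower bound of WLC fit windows
    delta_L_min: float = 0.5  # nm, acceptance window
    delta_L_max: float = 10.0
    flank_window: int = 8  # filtered samples averaged per flank


def filter_trace(
    raw: pd.DataFrame,
    window: int = 11,
    polyorder: int = 2,
    decimate_to: float = 100.0,
    raw_rate: float | None = None,
) -> pd.DataFrame:
    """Savitzky-Golay smooth force/extension, then decimate.

    Polynomials of degree <= ``polyorder`` pass unchanged, so constants and
    linear ramps are preserved exactly.  Decimation keeps every
    ``raw_rate / decimate_to``-th sample.  Already-decimated input (step 1)
    is returned filtered but not further decimated, making the operation
    idempotent at the target rate.
    """
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    t = raw["time_s"].to_numpy()
    if raw_rate is None:
        dt = np.median(np.diff(t)) if t.size > 1 else 1.0
        raw_rate = 1.0 / dt
    if raw_rate + 1e-9 < decimate_to:
        raise ValueError("raw rate below decimation target")
    step = max(int(round(raw_rate / decimate_to)), 1)
    out = raw.copy()
    for col in ("force_pN", "extension_nm"):
        x = out[col].to_numpy(dtype=float)
        if x.size >= window:
            out[col] = savgol_filter(x, window, polyorder)
    return out.iloc[::step].reset_index(drop=True)


def segment_cycles(trace: pd.DataFrame) -> list[ForceExtensionCycle]:
    """Split a (filtered) trace into pulling cycles.

    Uses the ``cycle_id`` column when present; otherwise splits at force
    turning points (a cycle is one loading ramp plus the following
    unloading ramp, if any) and labels phases accordingly.
    """
    if "cycle_id" in trace.columns:
        return [
            ForceExtensionCycle(int(cid), grp.reset_index(drop=True))
            for cid, grp in trace.groupby("cycle_id", sort=True)
        ]
    f = trace["force_pN"].to_numpy(dtype=float)
    if f.size < 3:
        raise ValueError("trace too short to segment")
    # coarse smoothing so noise does not fake turning points
    k = max(min(51, 2 * (f.size // 20) + 1), 3)
    fs = savgol_filter(f, k, 1) if f.size >= k else f
    rising = np.diff(fs) > 0
    turns = np.flatnonzero(np.diff(rising.astype(int)) != 0) + 1
    # only prominent turning points are ramp reversals: rupture force drops
    # also produce local extrema, but far from the ramp limits
    lo_f, hi_f = fs.min(), fs.max()
    span = hi_f - lo_f
    turns = [
        i for i in turns
        if (rising[i - 1] and fs[i] > lo_f + 0.7 * span)
        or (not rising[i - 1] and fs[i] < lo_f + 0.3 * span)
    ]
    maxima = [i for i in turns if rising[i - 1]]
    if not maxima and rising.all() == rising.any():
        # monotone single ramp -> one cycle
        phase = "stretch" if rising.any() else "relax"
        df = trace.copy().reset_index(drop=True)
        df["phase"] = phase
        return [ForceExtensionCycle(0, df)]
    minima = [i for i in turns if not rising[i - 1]]
    if not maxima:
        raise ValueError("no force turning points found; cannot segment")
    bounds = [0] + minima + [f.size]
    cycles = []
    for cid, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        if b - a < 3:
            continue
        df = trace.iloc[a:b].copy().reset_index(drop=True)
        seg_max = [m for m in maxima if a <= m < b]
        apex = (seg_max[0] - a) if seg_max else len(df)
        phase = np.array(["stretch"] * len(df), dtype=object)
        phase[apex:] = "relax"
        df["phase"] = phase
        cycles.append(ForceExtensionCycle(cid, df))
    if not cycles:
        raise ValueError("no segmentable cycles found")
    return cycles


def _fit_contour(force: np.ndarray, ext: np.ndarray, wlc: WLCParams) -> float:
    """Least-squares contour length for x = L * ratio(F) (linear in L)."""
    rho = wlc_ratio(force, wlc)
    denom = float(np.dot(rho, rho))
    if denom == 0.0:
        return np.nan
    return float(np.dot(ext, rho) / denom)


def detect_ruptures(
    cycle: ForceExtensionCycle,
    wlc: WLCParams = WLCParams(),
    thresholds: RuptureThresholds = RuptureThresholds(),
    conv: NtConversion = NtConversion(),
) -> list[RuptureEvent]:
    """Detect unfolding events in the loading phase of one filtered cycle.

    A candidate is a force drop of at least ``drop_min`` pN within at most
    ``gap_max`` consecutive filtered samples.  Events with dL outside the
    acceptance window are discarded as artifacts; when several events pass,
    only the largest-dL one is accepted for population accounting (one
    species per curve) and the rest are logged with a warning.  Zero events
    classifies the cycle as carrying no structure.
    """
    df = cycle.samples
    load = df[df["phase"].isin(_LOADING_PHASES)].reset_index(drop=True)
    if load.empty:
        raise ValueError("cycle has no loading (stretch/probe) phase")
    f = load["force_pN"].to_numpy(dtype=float)
    x = load["extension_nm"].to_numpy(dtype=float)
    n = f.size
    th = thresholds
    if n < 2 * th.flank_window + th.gap_max + 2:
        return []

    # largest drop starting at each sample within <= gap_max samples
    drops = np.full(n, -np.inf)
    spans = np.zeros(n, dtype=int)
    for g in range(1, th.gap_max + 1):
        d = f[:-g] - f[g:]
        better = d > drops[: n - g]
        drops[: n - g][better] = d[better]
        spans[: n - g][better] = g
    cand = np.flatnonzero(drops >= th.drop_min)
    if cand.size == 0:
        return []

    # cluster candidate onsets closer than gap_max+1 samples
    groups: list[list[int]] = [[int(cand[0])]]
    for i in cand[1:]:
        if i - groups[-1][-1] <= th.gap_max:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])

    events: list[RuptureEvent] = []
    w = th.flank_window
    for grp in groups:
        i_pre = max(grp, key=lambda i: drops[i])
        i_post = i_pre + spans[i_pre]
        # the filter smears the jump across its window, so the samples
        # immediately flanking the transition are mixtures of both branches;
        # average over clean samples one step away from each flank instead
        lo, hi = i_pre - w, i_post + 1 + w
        if lo < 0 or hi > n:
            continue
        f_rup = float(f[i_pre])
        if f_rup <= th.fit_force_min:
            continue
        pre_idx = slice(lo, i_pre)
        post_idx = slice(i_post + 1, hi)
        if np.any(f[pre_idx] <= 1.0) or np.any(f[post_idx] <= 1.0):
            continue
        # contour of the tether before rupture, for the local slope
        mask = (f[:i_pre] >= th.fit_force_min) & (f[:i_pre] <= f_rup - 0.5)
        if mask.sum() < 10:
            continue
        L_pre = _fit_contour(f[:i_pre][mask], x[:i_pre][mask], wlc)
        # flanking points translated to the rupture force along the WLC:
        # x / ratio(F) is the local contour estimate at each sample, so the
        # contour released is the difference of the flank-window means and
        # the equal-force extension jump follows by multiplying back with
        # ratio(F_rup)
        rho_rup = wlc_ratio(f_rup, wlc)
        l_flank_pre = float(np.mean(x[pre_idx] / wlc_ratio(f[pre_idx], wlc)))
        l_flank_post = float(np.mean(x[post_idx] / wlc_ratio(f[post_idx], wlc)))
        delta_x = (l_flank_post - l_flank_pre) * rho_rup
        if delta_x <= 0:
            continue
        dL_flank = delta_L_from_jump(f_rup, delta_x, wlc)
        if not (th.delta_L_min <= dL_flank <= th.delta_L_max):
            continue
        # second route: relax-branch contour fit, when a relax branch exists
        relax = df[df["phase"] == "relax"]
        dL_fit = np.nan
        if len(relax) >= 10:
            fr = relax["force_pN"].to_numpy(dtype=float)
            xr = relax["extension_nm"].to_numpy(dtype=float)
            rmask = (fr >= th.fit_force_min) & (fr <= f.max() - 0.5)
            if rmask.sum() >= 10:
                L_relax = _fit_contour(fr[rmask], xr[rmask], wlc)
                dL_fit = L_relax - L_pre
        events.append(
            RuptureEvent(
                cycle_id=cycle.cycle_id,
                rupture_force=f_rup,
                delta_x=float(delta_x),
                delta_L_flank=float(dL_flank),
                delta_L_wlcfit=float(dL_fit),
                nt=nt_count(dL_flank, conv),
            )
        )

    if len(events) > 1:
        warnings.warn(
            f"cycle {cycle.cycle_id}: {len(events)} events detected; "
            "keeping the largest-dL event for population accounting",
            stacklevel=2,
        )
        events = [max(events, key=lambda e: e.delta_L_flank)]
    return events


def events_to_frame(events: Sequence[RuptureEvent]) -> pd.DataFrame:
    """Events as a DataFrame (the events-CSV schema)."""
    return pd.DataFrame(
        [
            {
                "cycle_id": e.cycle_id,
                "F_rupture_pN": e.rupture_force,
                "delta_x_nm": e.delta_x,
                "delta_L_flank_nm": e.delta_L_flank,
                "delta_L_wlcfit_nm": e.delta_L_wlcfit,
                "nt": e.nt,
                "species_label": e.species_label,
            }
            for e in events
        ],
        columns=[
            "cycle_id", "F_rupture_pN", "delta_x_nm", "delta_L_flank_nm",
            "delta_L_wlcfit_nm", "nt", "species_label",
        ],
    )
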