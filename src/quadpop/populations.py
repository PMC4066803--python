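"""Population deconvolution of contour-length and rupture-force samples.

Three layers:

* PoDNano (population deconvolution at nanometer resolution): a Gaussian
  kernel-density estimate of the pooled dL sample, with peaks identified as
  KDE local maxima and confidence-bounded by bootstrap resampling (default
  3000 resamples).  Peaks supported in fewer than half the resamples are
  dropped as spurious.  The bandwidth is Silverman's rule on the pooled
  sample and is held fixed across resamples so peak counts are comparable.
* Gaussian-mixture fits (EM, initialized at the PoDNano peak centers) that
  turn the retained peaks into component weights/means/SDs and assign each
  event to a component by maximum posterior; percent formation per species
  is the fraction of all pulling curves whose event falls in a component.
* Two arithmetic deconvolutions: the GT/HQ ratio split of the ~4 nm
  population (using the deaza-GTP condition, where no hybrid quadruplex can
  form, to fix the GT:GQ ratio) and the seeded random deconvolution of two
  overlapping rupture-force populations (each event drawn into a class with
  probability equal to its posterior membership).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "SPECIES_ORDER",
    "Peak",
    "Mixture",
    "PopulationModel",
    "ConditionSummary",
    "InsufficientDataError",
    "silverman_bandwidth",
    "podnano",
    "fit_gaussian_mixture",
    "assign_components",
    "map_components_to_species",
    "percent_formation",
    "gt_hq_split",
    "deconvolve_gt_hq",
    "ForceDeconvolution",
    "random_force_deconvolution",
    "hq_total",
    "gq_gt_total",
    "quadruplex_total",
]

SPECIES_ORDER = ("2G-HQ", "3G-HQ", "GT", "GQ", "none")

#: component-mean boundaries separating the canonical dL populations (nm):
#: < 2.75 the two-G-tract hybrid, < 4.85 the ~4 nm (3G-HQ/GT) population,
#: above that the full G-quadruplex
_MIDDLE_LOW, _MIDDLE_HIGH = 2.75, 4.85


class InsufficientDataError(ValueError):
    """Raised when a deconvolution is attempted on too few values."""


@dataclass(frozen=True)
class Peak:
    """One KDE peak with its bootstrap confidence interval and support."""

    center: float
    ci_low: float
    ci_high: float
    support: float  # fraction of bootstrap resamples reproducing the peak


@dataclass(frozen=True)
class Mixture:
    """A 1-D Gaussian mixture in canonical (ascending-mean) order."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.means)

    def responsibilities(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)[:, None]
        log_p = (
            np.log(self.weights)
            - 0.5 * np.log(2 * np.pi * self.sds**2)
            - 0.5 * ((v - self.means) / self.sds) ** 2
        )
        log_p -= log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class PopulationModel:
    """KDE grid, bootstrap-retained peaks and (optionally) a mixture fit."""

    kde_grid: tuple[np.ndarray, np.ndarray]  # (value, density)
    peaks: list[Peak]
    n_boot: int
    bandwidth: float
    mixture: Mixture | None = None

    @property
    def peak_centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks])


@dataclass
class ConditionSummary:
    """Percent-formation table for one condition (the machine twin of the
    published population table).

    ``percent`` maps each species (plus ``none`` for curves without an
    unfolding event) to its one-decimal percentage of all pulling curves.
    Until the ~4 nm population has been split by :func:`deconvolve_gt_hq`,
    its total sits under ``3G-HQ`` for RNA-containing conditions (flagged by
    ``middle_unresolved``) and under ``GT`` for RNA-free ones.
    """

    condition: str
    percent: dict[str, float]
    n_curves: int
    n_events: int
    middle_unresolved: bool = False
    n_unassigned: int = 0

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"percents must sum to 100.0, got {total}")

    @property
    def middle_total(self) -> float:
        return round(self.percent.get("3G-HQ", 0.0) + self.percent.get("GT", 0.0), 1)


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, robust to zero-spread samples."""
    v = np.asarray(values, dtype=float)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    q75, q25 = np.percentile(v, [75, 25])
    iqr = float(q75 - q25) / 1.34
    eps = 1e-9 * max(1.0, float(np.abs(v).max()))
    scale = min([s for s in (sd, iqr) if s > eps], default=0.0)
    if scale <= eps:
        return 1e-3
    return 0.9 * scale * v.size ** (-0.2)


def _binned_kde(counts: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(counts, kernel, mode="same")


def _find_peaks(density: np.ndarray, rel_floor: float = 0.05) -> np.ndarray:
    """Local maxima of the density above ``rel_floor`` of its maximum.

    The floor discards micro-peaks raised by isolated outliers, which would
    otherwise survive bootstrap resampling often enough to fake support.
    """
    d = density
    up = d[1:-1] > d[:-2]
    down = d[1:-1] >= d[2:]
    idx = np.flatnonzero(up & down) + 1
    return idx[d[idx] > rel_floor * d.max()]


def _match_one_to_one(
    pooled: np.ndarray, boot: np.ndarray, radius: float
) -> dict[int, float]:
    """Greedy nearest one-to-one matching of bootstrap peaks to pooled
    peaks within ``radius``; returns {pooled index: matched center}."""
    pairs = [
        (abs(b - p), i, b)
        for i, p in enumerate(pooled)
        for b in boot
        if abs(b - p) <= radius
    ]
    pairs.sort(key=lambda t: t[0])
    out: dict[int, float] = {}
    used: set[float] = set()
    for _, i, b in pairs:
        if i in out or b in used:
            continue
        out[i] = b
        used.add(b)
    return out


def podnano(
    values: Sequence[float],
    n_boot: int = 3000,
    seed: int = 1,
    n_grid: int = 1024,
    match_radius: float = 1.0,
    min_support: float = 0.5,
) -> PopulationModel:
    """KDE + bootstrap peak deconvolution of a pooled 1-D sample.

    Peaks of the pooled-sample KDE are matched (nearest center, within
    ``match_radius``) to the peaks found in each of ``n_boot`` resamples
    taken with replacement at the original sample size; a pooled peak is
    retained if at least ``min_support`` of the resamples reproduce it, and
    its confidence interval is the 2.5-97.5 percentile range of the matched
    bootstrap centers.

    The KDE is evaluated on a fixed fine grid by binning the sample and
    convolving with a Gaussian kernel of the pooled Silverman bandwidth;
    bootstrap resamples are multinomial redraws of the bin counts, which
    makes 3000 resamples cheap without changing the estimator.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 20:
        raise InsufficientDataError(f"need >= 20 values, got {v.size}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    h = silverman_bandwidth(v)
    lo, hi = v.min() - 4 * h, v.max() + 4 * h
    grid = np.linspace(lo, hi, n_grid)
    dx = grid[1] - grid[0]
    counts, _ = np.histogram(v, bins=n_grid, range=(lo - dx / 2, hi + dx / 2))
    half = max(int(np.ceil(4 * h / dx)), 1)
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) * dx / h) ** 2)
    kernel /= kernel.sum() * v.size * dx  # normalized density per count

    density = _binned_kde(counts.astype(float), kernel)
    pooled_idx = _find_peaks(density)
    pooled_centers = grid[pooled_idx]

    rng = np.random.default_rng(seed)
    p = counts / counts.sum()
    matched: list[list[float]] = [[] for _ in pooled_centers]
    for _ in range(n_boot):
        cb = rng.multinomial(v.size, p).astype(float)
        db = _binned_kde(cb, kernel)
        idx_b = _find_peaks(db)
        if idx_b.size == 0:
            continue
        hits = _match_one_to_one(pooled_centers, grid[idx_b], match_radius)
        for j, c in hits.items():
            matched[j].append(c)
    peaks = []
    for c, hits in zip(pooled_centers, matched):
        support = len(hits) / n_boot
        if support < min_support:
            continue
        ci_lo, ci_hi = (
            np.percentile(hits, [2.5, 97.5]) if hits else (np.nan, np.nan)
        )
        peaks.append(Peak(float(c), float(ci_lo), float(ci_hi), support))
    peaks.sort(key=lambda pk: pk.center)
    return PopulationModel((grid, density), peaks, n_boot, h)


def fit_gaussian_mixture(
    values: Sequence[float],
    k: int,
    init_means: Sequence[float] | None = None,
    sd_floor: float = 0.05,
) -> Mixture:
    """EM fit of a k-component Gaussian mixture, canonically mean-sorted.

    Initialized at the supplied peak centers (quantiles when none are
    given); a degenerate component (SD below ``sd_floor``) triggers a refit
    with a variance floor and a warning.
    """
    v = np.asarray(list(values), dtype=float).reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if v.size < 5 * k:
        raise InsufficientDataError(f"need >= {5 * k} values for k={k}")
    if init_means is None:
        qs = np.linspace(0, 100, k + 2)[1:-1]
        init_means = np.percentile(v, qs)
    means_init = np.asarray(init_means, dtype=float).reshape(-1, 1)

    def _fit(reg: float) -> GaussianMixture:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            means_init=means_init,
            weights_init=np.full(k, 1.0 / k),
            precisions_init=np.full((k, 1, 1), 1.0 / max(np.var(v), 1e-6)),
            reg_covar=reg,
            max_iter=500,
            random_state=0,
        )
        gm.fit(v)
        return gm

    gm = _fit(1e-6)
    sds = np.sqrt(gm.covariances_.reshape(-1))
    if np.any(sds < sd_floor):
        warnings.warn(
            f"degenerate mixture component (sd < {sd_floor}); refitting with floor",
            stacklevel=2,
        )
        gm = _fit(sd_floor**2)
        sds = np.sqrt(gm.covariances_.reshape(-1))
    means = gm.means_.reshape(-1)
    weights = gm.weights_
    order = np.argsort(means)
    return Mixture(weights[order], means[order], np.maximum(sds[order], sd_floor))


def assign_components(values: Sequence[float], mixture: Mixture) -> np.ndarray:
    """Maximum-posterior component index per value; -1 when a value lies
    outside every component's 4-SD range (warned, bucketed as unassigned)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return np.zeros(0, dtype=int)
    resp = mixture.responsibilities(v)
    labels = resp.argmax(axis=1)
    inside = (
        np.abs(v[:, None] - mixture.means) <= 4.0 * mixture.sds
    ).any(axis=1)
    if np.any(~inside):
        warnings.warn(
            f"{int((~inside).sum())} event(s) outside all components' 4-SD "
            "range; bucketed as unassigned",
            stacklevel=2,
        )
    labels[~inside] = -1
    return labels


def map_components_to_species(mixture: Mixture, rna_present: bool) -> list[str]:
    """Name each mixture component after the canonical dL population.

    Components below ~2.75 nm are the two-G-tract hybrid (only possible with
    RNA present), the ~4 nm band is the unresolved 3G-HQ/GT population
    (pure GT without RNA), and anything larger is the full quadruplex.
    """
    names = []
    for m in mixture.means:
        if m < _MIDDLE_LOW:
            names.append("2G-HQ" if rna_present else "GT")
        elif m < _MIDDLE_HIGH:
            names.append("3G-HQ" if rna_present else "GT")
        else:
            names.append("GQ")
    return names


def _round_percent_100(raw: dict[str, float]) -> dict[str, float]:
    """One-decimal rounding that preserves a total of exactly 100.0
    (largest-remainder method)."""
    floors = {k: np.floor(v * 10) / 10 for k, v in raw.items()}
    deficit = round(100.0 - sum(floors.values()), 1)
    n_up = int(round(deficit * 10))
    order = sorted(raw, key=lambda k: raw[k] * 10 - np.floor(raw[k] * 10), reverse=True)
    out = dict(floors)
    for k in order[:n_up]:
        out[k] = round(out[k] + 0.1, 1)
    return {k: round(v, 1) for k, v in out.items()}


def percent_formation(
    event_values: Sequence[float],
    n_total_curves: int,
    mixture: Mixture,
    condition: str,
    rna_present: bool | None = None,
) -> ConditionSummary:
    """Percent formation per species from one condition's event dL values.

    Each event-bearing curve is assigned to the nearest mixture component by
    maximum posterior; a species' percent is 100 x (curves in its
    components) / (total curves), and curves without an event count as
    ``none``.
    """
    values = np.asarray(list(event_values), dtype=float)
    if n_total_curves < values.size:
        raise ValueError("n_total_curves must be >= number of event-bearing curves")
    if rna_present is None:
        rna_present = condition in ("transcription", "lithium", "spacer", "mutant")
    labels = assign_components(values, mixture) if values.size else np.zeros(0, int)
    comp_species = map_components_to_species(mixture, rna_present)
    counts = dict.fromkeys(SPECIES_ORDER, 0)
    n_unassigned = int(np.sum(labels == -1))
    for lab in labels[labels >= 0]:
        counts[comp_species[lab]] += 1
    counts["none"] = n_total_curves - int(np.sum(labels >= 0))
    raw = {k: 100.0 * c / n_total_curves for k, c in counts.items()}
    percent = _round_percent_100(raw)
    return ConditionSummary(
        condition=condition,
        percent=percent,
        n_curves=n_total_curves,
        n_events=int(values.size),
        middle_unresolved=rna_present and percent.get("3G-HQ", 0.0) > 0,
        n_unassigned=n_unassigned,
    )


def gt_hq_split(
    gq_reg: float, gt_deaza: float, gq_deaza: float, middle_total: float
) -> tuple[float, float]:
    """Split the ~4 nm population into GT and 3G-HQ percentages.

    The GT:GQ ratio is taken from the deaza-GTP condition (no hybrid
    quadruplex can form there), scaled by the regular-transcription GQ
    percentage: ``GT = GQ_reg x GT_deaza / GQ_deaza``; the hybrid balance is
    ``middle_total - GT``, clipped at zero with a warning.
    """
    if gq_deaza == 0:
        raise ZeroDivisionError("deaza GQ percentage is zero; ratio undefined")
    gt = round(gq_reg * gt_deaza / gq_deaza, 1)
    hq3 = round(middle_total - gt, 1)
    if hq3 < 0:
        warnings.warn(
            "GT estimate exceeds the ~4 nm peak total; clipping 3G-HQ to 0",
            stacklevel=2,
        )
        hq3 = 0.0
    return gt, hq3


def deconvolve_gt_hq(
    summary_transcription: ConditionSummary, summary_deaza: ConditionSummary
) -> ConditionSummary:
    """Resolve the transcription condition's ~4 nm population into GT and
    3G-HQ using the deaza condition's GT:GQ ratio."""
    gt, hq3 = gt_hq_split(
        summary_transcription.percent["GQ"],
        summary_deaza.percent["GT"],
        summary_deaza.percent["GQ"],
        summary_transcription.middle_total,
    )
    percent = dict(summary_transcription.percent)
    percent["GT"] = gt
    percent["3G-HQ"] = hq3
    return replace(
        summary_transcription, percent=percent, middle_unresolved=False
    )


@dataclass
class ForceDeconvolution:
    """Random deconvolution of overlapping rupture-force populations."""

    labels: np.ndarray  # class index per event, ascending class mean
    mixture: Mixture
    class_forces: list[np.ndarray]

    @property
    def class_means(self) -> np.ndarray:
        return np.array([
            float(np.mean(f)) if f.size else np.nan for f in self.class_forces
        ])

    def class_histogram(self, cls: int, bins=20):
        return np.histogram(self.class_forces[cls], bins=bins)


def random_force_deconvolution(
    forces: Sequence[float], k: int = 2, seed: int = 1
) -> ForceDeconvolution:
    """Assign each rupture force to one of ``k`` Gaussian classes by a
    seeded Bernoulli/categorical draw at its posterior membership.

    This reproduces class-wise force histograms for populations that
    overlap too much for hard assignment; with well-separated classes it
    reduces to near-deterministic labelling.
    """
    f = np.asarray(list(forces), dtype=float)
    if f.size < 20:
        raise InsufficientDataError(f"need >= 20 forces, got {f.size}")
    rng = np.random.default_rng(seed)
    try:
        mixture = fit_gaussian_mixture(f, k)
    except Exception:
        warnings.warn("force mixture failed to converge; single class", stacklevel=2)
        mixture = Mixture(
            np.array([1.0]), np.array([f.mean()]), np.array([max(f.std(), 0.05)])
        )
    resp = mixture.responsibilities(f)
    cum = np.cumsum(resp, axis=1)
    u = rng.uniform(size=f.size)[:, None]
    labels = (u > cum).sum(axis=1)
    class_forces = [f[labels == c] for c in range(mixture.k)]
    return ForceDeconvolution(labels, mixture, class_forces)


def hq_total(summary: ConditionSummary) -> float:
    """Combined hybrid-quadruplex percentage (2G-HQ + 3G-HQ), one decimal."""
    return round(summary.percent["2G-HQ"] + summary.percent["3G-HQ"], 1)


def gq_gt_total(summary: ConditionSummary) -> float:
    """Combined DNA-only (GQ + GT) percentage, one decimal."""
    return round(summary.percent["GQ"] + summary.percent["GT"], 1)


def quadruplex_total(summary: ConditionSummary) -> int:
    """All folded species combined, rounded to an integer percent."""
    folded = sum(v for k, v in summary.percent.items() if k != "none")
    return int(round(folded))
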