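"""Population-level statistics: Gaussian population fits with robust
trimming, logit-scale proportion statistics, per-site labeling summaries with
off-target classification, and ladder resolution analysis."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nanomap.calibration import Calibration, convert_length  # noqa: F401  (re-export)

_MAD_SCALE = 1.4826
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class PopulationStats:
    """Gaussian-fit summary of a measurement population."""

    n: int
    median: float
    sd: float
    ci95_mean: tuple[float, float]
    degenerate: bool = False
    method: str = "gaussian_mle_trimmed"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.ci95_mean[0] > self.ci95_mean[1]:
            raise ValueError("CI bounds out of order")


@dataclass(frozen=True)
class LogitStats:
    """Logit-scale statistics of a set of proportions."""

    n: int
    logit_mean: float
    logit_sd: float
    ci95_logit: tuple[float, float]
    p_hat: float
    ci95_p: tuple[float, float]
    outlier_pct: float
    n_excluded: int = 0  # p in {0, 1} dropped (no correction applied)


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def inv_logit(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def fit_gaussian_population(values: Sequence[float]) -> PopulationStats:
    """Gaussian location/scale by maximum likelihood after one 3-sigma
    (robust MAD-scaled) trimming pass.

    With fewer than 8 values, falls back to median/MAD with a warning. The
    ``median`` field carries the fitted location, matching how population
    medians are reported downstream.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("empty population")
    if np.ptp(x) == 0.0:
        v = float(x[0])
        return PopulationStats(int(x.size), v, 0.0, (v, v), degenerate=True)
    if x.size < 8:
        warnings.warn(
            f"only {x.size} values: falling back to median/MAD", RuntimeWarning, stacklevel=2
        )
        med = float(np.median(x))
        sd = float(_MAD_SCALE * np.median(np.abs(x - med)))
        half = _Z95 * sd / math.sqrt(x.size)
        return PopulationStats(int(x.size), med, sd, (med - half, med + half), method="median_mad")
    med = np.median(x)
    sigma_r = _MAD_SCALE * np.median(np.abs(x - med))
    if sigma_r > 0:
        keep = np.abs(x - med) <= 3.0 * sigma_r
        x = x[keep]
    loc = float(np.mean(x))
    scale = float(np.std(x))
    n = int(x.size)
    half = _Z95 * scale / math.sqrt(n)
    return PopulationStats(n, loc, scale, (loc - half, loc + half), degenerate=scale == 0.0)


def logit_stats(p_values: Sequence[float]) -> LogitStats:
    """Mean/sd/95% CI of proportions on the logit scale, back-transformed.

    Values exactly 0 or 1 are excluded (count surfaced via ``n_excluded``);
    ``outlier_pct`` is the share of retained proportions falling outside the
    back-transformed CI of the mean.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no proportions given")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must be within [0, 1]")
    boundary = (p == 0.0) | (p == 1.0)
    n_excluded = int(boundary.sum())
    p = p[~boundary]
    if p.size == 0:
        raise ValueError("all proportions are 0 or 1; logit undefined")
    lg = logit(p)
    mean = float(np.mean(lg))
    sd = float(np.std(lg, ddof=1)) if lg.size > 1 else 0.0
    half = _Z95 * sd / math.sqrt(lg.size)
    ci_l = (mean - half, mean + half)
    p_hat = float(inv_logit(np.array(mean)))
    ci_p = (float(inv_logit(np.array(ci_l[0]))), float(inv_logit(np.array(ci_l[1]))))
    outliers = np.mean((p < ci_p[0]) | (p > ci_p[1])) * 100.0
    return LogitStats(
        n=int(lg.size),
        logit_mean=mean,
        logit_sd=sd,
        ci95_logit=ci_l,
        p_hat=p_hat,
        ci95_p=ci_p,
        outlier_pct=float(outliers),
        n_excluded=n_excluded,
    )


def position_proportion_stats(
    positions_bp: Sequence[float],
    full_lengths_bp: Sequence[float],
) -> LogitStats:
    """Logit statistics of the long-segment proportion of a label site.

    Each molecule is bisected at the label; ``p`` is the longer segment's
    share of the full length, so p is in [0.5, 1) for interior labels.
    """
    pos = np.asarray(list(positions_bp), dtype=float)
    full = np.asarray(list(full_lengths_bp), dtype=float)
    if pos.shape != full.shape:
        raise ValueError("positions and lengths must align")
    if np.any(full <= 0):
        raise ValueError("full lengths must be positive")
    if np.any((pos < 0) | (pos > full)):
        raise ValueError("positions must lie within the molecule")
    long_seg = np.maximum(pos, full - pos)
    return logit_stats(long_seg / full)


def site_statistics(
    measurements: Sequence,
    assignments: Sequence,
    refmap,
    cal: Calibration | None = None,
    off_target_k: float = 2.0,
) -> pd.DataFrame:
    """Per expected site: molecule count, labeled fraction, position stats,
    and off-target counts.

    ``assignments`` are :class:`~nanomap.mapmatch.SiteAssignment` objects
    aligned with ``measurements`` (ambiguous/failed entries may be None and
    are skipped). A detected-but-unassigned label counts as off-target when
    it lies farther than ``off_target_k`` * (per-site position sd) from every
    expected site; each site's own sd is estimated from its assigned-label
    positions (median sd substituted when a site has too few observations).
    """
    cal = cal or Calibration()
    sites = list(refmap.sites)
    per_site_positions: dict[int, list[float]] = {i: [] for i in range(len(sites))}
    per_site_n: dict[int, int] = {i: 0 for i in range(len(sites))}
    unassigned_bp: list[float] = []
    n_used = 0
    for meas, asg in zip(measurements, assignments):
        if asg is None or asg.orientation == "ambiguous":
            continue
        n_used += 1
        oriented = asg.oriented_label_positions_bp(meas, cal)
        for i in range(len(sites)):
            per_site_n[i] += 1
            lab_idx = asg.site_to_label.get(i)
            if lab_idx is not None:
                per_site_positions[i].append(float(oriented[lab_idx]))
        for lab_idx in asg.unassigned_labels:
            unassigned_bp.append(float(oriented[lab_idx]))

    stats: dict[int, PopulationStats | None] = {}
    for i in range(len(sites)):
        vals = per_site_positions[i]
        if len(vals) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                stats[i] = fit_gaussian_population(vals)
        else:
            stats[i] = None
    sds = [s.sd for s in stats.values() if s is not None and s.sd > 0]
    fallback_sd = float(np.median(sds)) if sds else float("nan")

    off_target_total = 0
    for pos in unassigned_bp:
        near_any = False
        for i, site in enumerate(sites):
            sd = stats[i].sd if stats[i] is not None and stats[i].sd > 0 else fallback_sd
            if not math.isnan(sd) and abs(pos - site.pos_bp) <= off_target_k * sd:
                near_any = True
                break
        if not near_any and not math.isnan(fallback_sd):
            off_target_total += 1

    rows = []
    for i, site in enumerate(sites):
        st = stats[i]
        n_obs = len(per_site_positions[i])
        rows.append(
            dict(
                site_pos_bp=site.pos_bp,
                match_type=site.match_type,
                n_molecules=per_site_n[i],
                n_labeled=n_obs,
                labeled_fraction=(n_obs / per_site_n[i]) if per_site_n[i] else 0.0,
                position_mean_bp=st.median if st else float("nan"),
                position_sd_bp=st.sd if st else float("nan"),
                ci95_low_bp=st.ci95_mean[0] if st else float("nan"),
                ci95_high_bp=st.ci95_mean[1] if st else float("nan"),
            )
        )
    table = pd.DataFrame(rows)
    table.attrs["off_target_labels"] = off_target_total
    table.attrs["n_molecules_used"] = n_used
    table.attrs["n_unassigned_labels"] = len(unassigned_bp)
    return table


UNRESOLVED = float("inf")


def ladder_resolution(tables: Mapping[float, Sequence[float]]) -> float:
    """Smallest resolved step size (bp) of a ladder series.

    Each species population is Gaussian-fit; a step size ``s`` counts as
    resolved when every adjacent species pair with true step >= ``s`` has
    disjoint 95% CIs of the fitted mean. Returns the smallest such ``s``
    among the adjacent steps present, or ``math.inf`` (``UNRESOLVED``) when
    even the largest step fails.
    """
    if len(tables) < 2:
        raise ValueError("need at least two species")
    species = sorted(tables)
    fits = {s: fit_gaussian_population(tables[s]) for s in species}
    pairs = []
    for a, b in zip(species, species[1:]):
        step = b - a
        ci_a, ci_b = fits[a].ci95_mean, fits[b].ci95_mean
        disjoint = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
        pairs.append((step, disjoint))
    resolved = UNRESOLVED
    for step in sorted({s for s, _ in pairs}, reverse=True):
        if all(d for s, d in pairs if s >= step):
            resolved = step
        else:
            break
    return resolved
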