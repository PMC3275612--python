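"""Expression-vs-cumulative-frequency profiles.

A profile is an ordered set of points on a 0-1 cumulative-cell-frequency
axis (one unit = one cell-cycle time Tc).  Each segment of a region scheme
contributes one point: the segment's median expression plotted at the center
of an interval whose width is the segment's fraction of assigned cells,

    x_i = sum_{j<i} f_j + f_i / 2.

Because an asynchronous, exponentially growing population over-represents
young cells (age density 2^(-a)), raw frequency is a *surrogate* for time;
:func:`frequency_to_time` offers the exact age-distribution correction but
profiles keep the raw-frequency axis by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionProfile",
    "MergeReport",
    "extract_profile",
    "insert_boundary_points",
    "frequency_to_time",
    "cumulative_age_fraction",
    "combine_replicates",
    "merge_panels",
    "join_profiles",
]


# -- age distribution ---------------------------------------------------------

def cumulative_age_fraction(t):
    """Fraction of an exponential-growth population younger than age ``t``.

    The age density in steady exponential growth with binary division is
    ``2 ln2 · 2^(-a)`` on [0, 1); its CDF is ``F(t) = 2 (1 - 2^(-t))``.
    """
    t = np.asarray(t, dtype=float)
    return 2.0 * (1.0 - np.exp2(-t))


def frequency_to_time(x, mode: str = "identity"):
    """Map cumulative cell frequency to normalized cell-cycle time.

    ``identity`` returns ``x`` unchanged (the convention used for plotting);
    ``age_corrected`` inverts the exponential-growth age CDF,
    ``t = -log2(1 - x/2)``, so equal spans of ``t`` are equal spans of time
    rather than of cell frequency.  Endpoints are fixed: t(0)=0, t(1)=1.
    """
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("cumulative frequency must lie in [0, 1]")
    if mode == "identity":
        out = x.copy()
    elif mode == "age_corrected":
        out = -np.log2(1.0 - x / 2.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if scalar else out


# -- profile container --------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Ordered profile points on the cumulative-frequency axis.

    Attributes
    ----------
    x:
        Cumulative-frequency centers in [0, 1].
    values:
        Per-channel center statistic (median within segment) at each point.
    dispersion:
        Per-channel SEM (populated by :func:`combine_replicates`).
    ci:
        Per-channel 95% CI half-width (populated by :func:`combine_replicates`).
    counts:
        Events per segment (None for mixture-derived profiles).
    fractions:
        Cell fraction per segment; the frequency bookkeeping that produced x.
    synthetic:
        True for extrapolated boundary points, which carry no cells.
    axis_mode:
        ``raw-frequency`` or ``age-corrected-time``.
    """

    x: np.ndarray
    values: dict[str, np.ndarray]
    dispersion: dict[str, np.ndarray] = field(default_factory=dict)
    ci: dict[str, np.ndarray] = field(default_factory=dict)
    counts: np.ndarray | None = None
    fractions: np.ndarray | None = None
    synthetic: np.ndarray | None = None
    axis_mode: str = "raw-frequency"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        if self.synthetic is None:
            self.synthetic = np.zeros(self.x.size, dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
        if self.fractions is not None:
            self.fractions = np.asarray(self.fractions, dtype=float)
        self.validate()

    def validate(self):
        for name, v in self.values.items():
            if v.size != self.x.size:
                raise ValueError(f"channel {name!r} length mismatch")
        real = ~self.synthetic
        xr = self.x[real]
        if xr.size > 1 and not np.all(np.diff(xr) > 0):
            raise ValueError("x of real points must be strictly increasing")
        if self.counts is not None and np.any(self.counts[real] < 1):
            raise ValueError("real points must be backed by at least one event")
        if self.fractions is not None and self.fractions[real].size:
            centers = np.cumsum(self.fractions[real]) - self.fractions[real] / 2.0
            if not np.allclose(xr, centers, atol=1e-9):
                raise ValueError("x must equal cumulative fraction minus half own fraction")

    # -- convenience -------------------------------------------------------
    @property
    def channels(self) -> list[str]:
        return list(self.values)

    @property
    def n_points(self) -> int:
        return self.x.size

    def interp(self, channel: str, xs, include_synthetic: bool = True):
        """Linear interpolation of ``channel`` at positions ``xs``."""
        keep = np.ones(self.x.size, bool) if include_synthetic else ~self.synthetic
        order = np.argsort(self.x[keep], kind="stable")
        return np.interp(np.asarray(xs, float), self.x[keep][order],
                         self.values[channel][keep][order])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"x": self.x})
        for name, v in self.values.items():
            out[name] = v
        for name, v in self.dispersion.items():
            out[f"{name}_sem"] = v
        for name, v in self.ci.items():
            out[f"{name}_ci95"] = v
        if self.counts is not None:
            out["count"] = self.counts
        if self.fractions is not None:
            out["fraction"] = self.fractions
        out["synthetic"] = self.synthetic.astype(int)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ExpressionProfile":
        df = pd.read_csv(path)
        special = {"x", "count", "fraction", "synthetic"}
        values = {c: df[c].to_numpy() for c in df.columns
                  if c not in special and not c.endswith(("_sem", "_ci95"))}
        dispersion = {c[:-4]: df[c].to_numpy() for c in df.columns if c.endswith("_sem")}
        ci = {c[:-5]: df[c].to_numpy() for c in df.columns if c.endswith("_ci95")}
        return cls(
            x=df["x"].to_numpy(),
            values=values,
            dispersion=dispersion,
            ci=ci,
            counts=df["count"].to_numpy() if "count" in df else None,
            fractions=df["fraction"].to_numpy() if "fraction" in df else None,
            synthetic=df["synthetic"].to_numpy(dtype=bool) if "synthetic" in df else None,
        )


@dataclass
class MergeReport:
    """Agreement of a shared channel between two independently stained panels."""

    shared_channel: str
    max_abs_deviation: float
    grid: np.ndarray
    deviation: np.ndarray
    threshold: float | None = None

    @property
    def agrees(self) -> bool | None:
        if self.threshold is None:
            return None
        return bool(self.max_abs_deviation <= self.threshold)


# -- operations ---------------------------------------------------------------

def extract_profile(events, labels, channels, label_order=None) -> ExpressionProfile:
    """Turn ordered segment labels into an expression profile.

    ``labels`` holds one segment label per event (−1 = unassigned).  Segment
    fractions are computed relative to all *assigned* events; each segment's
    point sits at the center of its frequency interval and carries the median
    of every requested channel — including channels that played no part in
    the segmentation (indirect derivation).
    """
    labels = np.asarray(labels)
    if label_order is None:
        label_order = np.unique(labels[labels >= 0])
    assigned = labels >= 0
    total = int(assigned.sum())
    if total == 0:
        raise ValueError("no assigned events")
    events.require(*channels)

    fracs, meds, counts, kept = [], [], [], []
    for lab in label_order:
        sel = labels == lab
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"segment {lab} is empty; point skipped")
            continue
        kept.append(lab)
        counts.append(n)
        fracs.append(n / total)
        meds.append([float(np.median(events[ch][sel])) for ch in channels])
    fracs = np.asarray(fracs)
    meds = np.asarray(meds)
    x = np.cumsum(fracs) - fracs / 2.0
    return ExpressionProfile(
        x=x,
        values={ch: meds[:, i] for i, ch in enumerate(channels)},
        counts=np.asarray(counts),
        fractions=fracs,
    )


def _extrapolate(xs, ys, x0):
    """Linear extrapolation from the two points nearest ``x0``."""
    if xs.size < 2:
        warnings.warn("fewer than 2 real points in stretch; constant extension used")
        return float(ys[0])
    i = np.argsort(np.abs(xs - x0))[:2]
    (xa, xb), (ya, yb) = xs[i], ys[i]
    if xb == xa:
        return float(ya)
    return float(ya + (yb - ya) * (x0 - xa) / (xb - xa))


def insert_boundary_points(profile: ExpressionProfile, transition_indices=()) -> ExpressionProfile:
    """Add extrapolated points at x=0, x=1 and at expression transitions.

    A transition index ``t`` marks a change of expression regime between real
    points ``t-1`` and ``t``; one synthetic point is placed at the shared
    frequency boundary per adjoining stretch, extrapolated linearly from that
    stretch's two nearest real points.  Stretches with fewer than two points
    are extended as constants (with a warning).
    """
    real = np.flatnonzero(~profile.synthetic)
    n = real.size
    if n == 0:
        raise ValueError("profile has no real points")
    transitions = sorted(set(int(t) for t in transition_indices))
    for t in transitions:
        if not 0 < t < n:
            raise ValueError(f"transition index {t} out of range (1..{n - 1})")
    # stretch limits in real-point ordinals
    edges = [0, *transitions, n]
    stretches = [np.arange(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    x = profile.x[real]
    if profile.fractions is not None:
        frac = profile.fractions[real]
    else:
        frac = None

    def boundary_x(t):
        if frac is not None:
            return float(x[t - 1] + frac[t - 1] / 2.0)
        return float((x[t - 1] + x[t]) / 2.0)

    new_x, new_vals = [], {ch: [] for ch in profile.channels}

    def add_point(x0, stretch):
        new_x.append(x0)
        for ch in profile.channels:
            ys = profile.values[ch][real][stretch]
            new_vals[ch].append(_extrapolate(x[stretch], ys, x0))

    add_point(0.0, stretches[0])
    for t in transitions:
        left = stretches[[e for e in range(len(edges) - 1) if edges[e + 1] == t][0]]
        right = stretches[[e for e in range(len(edges) - 1) if edges[e] == t][0]]
        b = boundary_x(t)
        add_point(b, left)
        add_point(b, right)
    add_point(1.0, stretches[-1])

    m = len(new_x)
    all_x = np.concatenate([profile.x, new_x])
    order = np.argsort(all_x, kind="stable")
    synth = np.concatenate([profile.synthetic, np.ones(m, bool)])

    def cat(arr, fill):
        if arr is None:
            return None
        return np.concatenate([arr, np.full(m, fill, dtype=float)])

    return ExpressionProfile(
        x=all_x[order],
        values={ch: np.concatenate([profile.values[ch], new_vals[ch]])[order]
                for ch in profile.channels},
        dispersion={ch: cat(v, np.nan)[order] for ch, v in profile.dispersion.items()},
        ci={ch: cat(v, np.nan)[order] for ch, v in profile.ci.items()},
        counts=None if profile.counts is None
        else np.concatenate([profile.counts, np.zeros(m, int)])[order],
        fractions=cat(profile.fractions, 0.0)[order] if profile.fractions is not None else None,
        synthetic=synth[order],
        axis_mode=profile.axis_mode,
    )


def combine_replicates(profiles, confidence: float = 0.95) -> ExpressionProfile:
    """Point-wise mean of replicate profiles, with SEM and t-based CI.

    Replicates must come from identically structured schemes (equal point
    counts); within a point the center statistic is the mean of the
    replicate medians, matching the convention "means of median specific
    fluorescence".
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicates")
    npts = {p.n_points for p in profiles}
    if len(npts) != 1:
        raise ValueError(f"replicate point counts differ: {sorted(npts)}")
    channels = profiles[0].channels
    k = len(profiles)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=k - 1)
    x = np.mean([p.x for p in profiles], axis=0)
    values, sem, ci = {}, {}, {}
    for ch in channels:
        stack = np.stack([p.values[ch] for p in profiles])
        values[ch] = stack.mean(axis=0)
        sem[ch] = stack.std(axis=0, ddof=1) / np.sqrt(k)
        ci[ch] = tcrit * sem[ch]
    counts = None
    if all(p.counts is not None for p in profiles):
        counts = np.sum([p.counts for p in profiles], axis=0)
    synthetic = profiles[0].synthetic.copy()
    return ExpressionProfile(x=x, values=values, dispersion=sem, ci=ci,
                             counts=counts, synthetic=synthetic,
                             axis_mode=profiles[0].axis_mode)


def merge_panels(profile_a: ExpressionProfile, profile_b: ExpressionProfile,
                 shared_channel: str, grid=None, threshold: float | None = None):
    """Co-plot two independently measured panels through a shared channel.

    Neither profile is warped: both already live on the 0-1 frequency axis
    of their own (statistically identical) population.  The report's maximum
    absolute deviation of the shared channel, after linear interpolation on
    a common grid, quantifies whether the frequency domains agree well
    enough to license reading the two panels' private channels side by side.
    """
    if profile_a.axis_mode != profile_b.axis_mode:
        raise ValueError("profiles use different axis modes")
    for p in (profile_a, profile_b):
        if shared_channel not in p.values:
            raise KeyError(f"shared channel {shared_channel!r} missing")
    lo = max(profile_a.x.min(), profile_b.x.min())
    hi = min(profile_a.x.max(), profile_b.x.max())
    if grid is None:
        grid = np.unique(np.concatenate([profile_a.x, profile_b.x]))
        grid = grid[(grid >= lo) & (grid <= hi)]
    else:
        grid = np.asarray(grid, dtype=float)
    dev = np.abs(profile_a.interp(shared_channel, grid)
                 - profile_b.interp(shared_channel, grid))
    report = MergeReport(shared_channel, float(dev.max()), grid, dev, threshold)
    return [profile_a, profile_b], report


def join_profiles(profiles) -> ExpressionProfile:
    """Union of points from same-axis profiles, sorted by x.

    Used to densify a shared channel measured in several panels; frequency
    bookkeeping (fractions) no longer applies to the joined set.
    """
    profiles = [p for p in profiles if p.n_points > 0]
    if len(profiles) == 1:
        return profiles[0]
    if not profiles:
        raise ValueError("nothing to join")
    modes = {p.axis_mode for p in profiles}
    if len(modes) != 1:
        raise ValueError("profiles use different axis modes")
    channels = [ch for ch in profiles[0].channels
                if all(ch in p.values for p in profiles)]
    x = np.concatenate([p.x for p in profiles])
    order = np.argsort(x, kind="stable")
    values = {ch: np.concatenate([p.values[ch] for p in profiles])[order]
              for ch in channels}
    synthetic = np.concatenate([p.synthetic for p in profiles])[order]
    counts = None
    if all(p.counts is not None for p in profiles):
        counts = np.concatenate([p.counts for p in profiles])[order]
    # Ties in x are possible across panels; keep as-is but drop the strictly-
    # increasing guarantee by marking none — validation tolerates ties only on
    # synthetic points, so nudge exact duplicates apart by float epsilon.
    xs = x[order]
    for i in range(1, xs.size):
        if xs[i] <= xs[i - 1]:
            xs[i] = np.nextafter(xs[i - 1], 2.0)
    return ExpressionProfile(x=xs, values=values, counts=counts,
                             synthetic=synthetic, axis_mode=profiles[0].axis_mode)
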