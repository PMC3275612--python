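"""Ground-truth-known synthetic cytometry data.

Two generators live here:

* a one-dimensional multi-Gaussian DNA-content histogram (single G1 and
  G2+M components bounding a configurable number of S-phase components),
  the classic proof-of-principle input for profile extraction; and
* a full multi-channel population following the snapshot principle: every
  cell of an asynchronous, exponentially growing culture sits at some
  normalized cell-cycle position ``u`` in [0, 1), the age distribution is
  ``2 ln2 · 2^(-u)`` (newborns twice as frequent as dividers), and each
  marker channel is a programmed piecewise curve of ``u`` times
  multiplicative log-normal measurement noise.

The default :class:`PhaseModel` emulates a Molt4-like culture stained for
DNA, cyclin A2, cyclin B1 and phospho-S10-histone H3 (PHH3): cyclin A2 is
absent in G1 and accumulates from the G1/S boundary in two phases
(polynomial then exponential), cyclin B1 starts low but nonzero in late G1
with a slow-then-fast two-exponential rise, PHH3 jumps at mitotic entry;
degradation is ordered A2 → B1 → PHH3 dephosphorylation inside mitosis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable
from .extraction import ExpressionProfile, cumulative_age_fraction

__all__ = [
    "GaussianComponent",
    "GaussianMixture1D",
    "Histogram1D",
    "PiecewiseCurve",
    "PhaseModel",
    "SyntheticPopulation",
    "make_dna_mixture",
    "sample_histogram",
    "sample_population",
    "ground_truth_profile",
    "default_phase_model",
    "floor_reach_u",
    "position_from_frequency",
]


# -- 1-D mixture --------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    """One normal component of a DNA histogram model."""

    mean: float
    sd: float
    area: float
    label: str = ""

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("component sd must be positive")
        if not 0 < self.area <= 1:
            raise ValueError("component area must lie in (0, 1]")


@dataclass
class GaussianMixture1D:
    """Sum of Gaussian components modeling a DNA-content histogram."""

    components: list[GaussianComponent]

    def __post_init__(self):
        total = sum(c.area for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component areas sum to {total}, not 1")

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.components])

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(c.area * stats.norm.pdf(x, c.mean, c.sd) for c in self.components)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return sum(c.area * stats.norm.cdf(x, c.mean, c.sd) for c in self.components)

    def phase_fraction(self, label: str) -> float:
        return float(sum(c.area for c in self.components if c.label == label))

    def to_json(self, path=None):
        payload = [{"mean": c.mean, "sd": c.sd, "area": c.area, "label": c.label}
                   for c in self.components]
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "GaussianMixture1D":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("["):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls([GaussianComponent(**c) for c in payload])


def make_dna_mixture(g1_fraction: float, s_fraction: float, g2m_fraction: float,
                     g1_mean: float = 100.0, cv: float = 0.03,
                     n_s_components: int = 6, margin_sd: float = 3.0) -> GaussianMixture1D:
    """Build the multi-Gaussian DNA histogram model.

    The G1 component sits at ``g1_mean``, G2+M at twice that (the factor-of-2
    DNA states), both with ``sd = cv × mean``.  S phase is split into
    ``n_s_components`` equal-area components with means evenly spaced
    (exclusive) between the bounding clusters' ``± margin_sd × sd`` edges, so
    no S component intrudes on the spread of a terminal cluster; SDs are
    interpolated linearly (in mean) between the bounding SDs.  Set
    ``margin_sd=0`` to space S means over the full open 2C-4C interval.
    """
    fractions = (g1_fraction, s_fraction, g2m_fraction)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"phase fractions must sum to 1, got {sum(fractions)}")
    if min(fractions) <= 0:
        raise ValueError("all phase fractions must be positive (S fraction must be > 0)")
    if n_s_components < 1:
        raise ValueError("need at least one S component")
    if not 0 < cv <= 0.2:
        raise ValueError("cv must lie in (0, 0.2]")
    if margin_sd < 0:
        raise ValueError("margin_sd must be non-negative")

    g2m_mean = 2.0 * g1_mean
    sd1, sd2 = cv * g1_mean, cv * g2m_mean
    lo = g1_mean + margin_sd * sd1
    hi = g2m_mean - margin_sd * sd2
    if lo >= hi:
        raise ValueError("bounding clusters overlap; reduce cv or margin_sd")
    step = (hi - lo) / (n_s_components + 1)
    s_means = lo + step * np.arange(1, n_s_components + 1)
    s_sds = sd1 + (sd2 - sd1) * (s_means - g1_mean) / g1_mean

    comps = [GaussianComponent(g1_mean, sd1, g1_fraction, "G1")]
    comps += [GaussianComponent(float(m), float(s), s_fraction / n_s_components, "S")
              for m, s in zip(s_means, s_sds)]
    comps.append(GaussianComponent(g2m_mean, sd2, g2m_fraction, "G2M"))
    return GaussianMixture1D(comps)


@dataclass
class Histogram1D:
    """Sampled DNA values with their binning and generating component index."""

    values: np.ndarray
    component_indices: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray


def sample_histogram(mixture: GaussianMixture1D, n: int, seed: int,
                     bins: int = 256) -> Histogram1D:
    """Draw ``n`` events from the mixture (component chosen by area) and bin them."""
    if n < 1000:
        warnings.warn("n < 1000: phase-fraction recovery guarantees void")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(mixture.components), size=n, p=mixture.areas)
    values = rng.normal(mixture.means[idx], mixture.sds[idx])
    counts, edges = np.histogram(values, bins=bins)
    return Histogram1D(values, idx, edges, counts)


# -- programmed marker curves -------------------------------------------------

def _smoothstep(t):
    return t * t * (3.0 - 2.0 * t)


@dataclass(frozen=True)
class CurveSegment:
    """One piece of a programmed expression curve on [u0, u1)."""

    u0: float
    u1: float
    kind: str          # const | linear | poly | exp | smooth
    params: tuple

    def __call__(self, u):
        t = (np.asarray(u, dtype=float) - self.u0) / (self.u1 - self.u0)
        p = self.params
        if self.kind == "const":
            return np.full_like(t, p[0])
        if self.kind == "linear":
            return p[0] + (p[1] - p[0]) * t
        if self.kind == "poly":
            return sum(c * t**k for k, c in enumerate(p))
        if self.kind == "exp":
            return p[0] * np.exp(np.log(p[1] / p[0]) * t)
        if self.kind == "smooth":
            return p[0] + (p[1] - p[0]) * _smoothstep(t)
        raise ValueError(f"unknown segment kind {self.kind!r}")


class PiecewiseCurve:
    """Programmed expression as a function of cell-cycle position u ∈ [0, 1)."""

    def __init__(self, segments):
        self.segments = [s if isinstance(s, CurveSegment) else CurveSegment(**s)
                         for s in segments]
        if abs(self.segments[0].u0) > 1e-12 or abs(self.segments[-1].u1 - 1.0) > 1e-12:
            raise ValueError("curve segments must cover [0, 1)")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.u1 - b.u0) > 1e-12:
                raise ValueError("curve segments must be contiguous")

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        out = np.empty(u.shape, dtype=float)
        for seg in self.segments:
            sel = (u >= seg.u0) & (u < seg.u1) if seg is not self.segments[-1] \
                else (u >= seg.u0) & (u <= seg.u1)
            if np.any(sel):
                out[sel] = seg(u[sel])
        return out

    def to_dict(self):
        return [{"u0": s.u0, "u1": s.u1, "kind": s.kind, "params": list(s.params)}
                for s in self.segments]

    @classmethod
    def from_dict(cls, payload):
        return cls([CurveSegment(s["u0"], s["u1"], s["kind"], tuple(s["params"]))
                    for s in payload])


def floor_reach_u(curve, grid: int = 20001, frac: float = 0.02) -> float:
    """Position at which a rising-then-degrading curve first reaches its floor.

    The floor is the post-peak minimum; "reached" means within ``frac`` of the
    curve's dynamic range above it.  Used to assert the degradation order
    cyclin A2 → cyclin B1 → PHH3 on the curve definitions themselves.
    """
    u = np.linspace(0.0, 1.0, grid)
    v = curve(u)
    peak = int(np.argmax(v))
    tail = v[peak:]
    floor = tail.min()
    thresh = floor + frac * (v.max() - floor)
    return float(u[peak + int(np.argmax(tail <= thresh))])


# -- phase model --------------------------------------------------------------

@dataclass
class PhaseModel:
    """Generator spec for a multi-channel asynchronous population.

    ``phase_fractions`` are fractions of cell-cycle *time* Tc for
    (G1, S, G2, M); event frequencies follow after age weighting.  Marker
    curves map u ∈ [0, 1) to true expression in linear fluorescence units;
    the DNA channel is implied by ``dna_levels`` (2C through G1, linear
    2C→4C across S, 4C afterwards).  ``noise_cv`` is the coefficient of
    variation of the multiplicative log-normal measurement noise, per channel.
    """

    phase_fractions: tuple[float, float, float, float]
    marker_curves: dict[str, PiecewiseCurve]
    noise_cv: dict[str, float]
    dna_levels: tuple[float, float] = (100.0, 200.0)

    def __post_init__(self):
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if min(self.phase_fractions) <= 0:
            raise ValueError("phase fractions must be positive")
        c2, c4 = self.dna_levels
        if abs(c4 - 2.0 * c2) > 1e-9 * c2:
            raise ValueError("4C level must be exactly twice the 2C level")
        order = [ch for ch in ("cyclin_a2", "cyclin_b1", "phh3")
                 if ch in self.marker_curves]
        if order == ["cyclin_a2", "cyclin_b1", "phh3"]:
            floors = [floor_reach_u(self.marker_curves[c]) for c in order]
            if not floors[0] < floors[1] < floors[2]:
                raise ValueError(
                    f"degradation order violated: floors at {floors} "
                    "(need cyclin A2 < cyclin B1 < PHH3)")

    # phase boundaries in u
    @property
    def boundaries(self) -> tuple[float, float, float]:
        g1, s, g2, _ = self.phase_fractions
        return g1, g1 + s, g1 + s + g2

    def dna_curve(self, u):
        u = np.asarray(u, dtype=float)
        b1, b2, _ = self.boundaries
        c2, c4 = self.dna_levels
        return np.where(u < b1, c2,
                        np.where(u < b2, c2 + (c4 - c2) * (u - b1) / (b2 - b1), c4))

    def curve(self, channel: str):
        if channel == "dna":
            return self.dna_curve
        return self.marker_curves[channel]

    @property
    def channels(self) -> list[str]:
        return ["dna", *self.marker_curves]

    def phase_of(self, u):
        u = np.asarray(u, dtype=float)
        b1, b2, b3 = self.boundaries
        return np.select([u < b1, u < b2, u < b3], ["G1", "S", "G2"], default="M")

    def phase_frequencies(self, age_weighted: bool = True) -> dict[str, float]:
        """Analytic per-phase event occupancy (integral of the age density)."""
        edges = np.array([0.0, *self.boundaries, 1.0])
        f = cumulative_age_fraction(edges) if age_weighted else edges
        occ = np.diff(f)
        return dict(zip(("G1", "S", "G2", "M"), occ.tolist()))

    # -- JSON ---------------------------------------------------------------
    def to_json(self, path=None):
        payload = {
            "phase_fractions": list(self.phase_fractions),
            "dna_levels": list(self.dna_levels),
            "noise_cv": self.noise_cv,
            "marker_curves": {ch: c.to_dict() for ch, c in self.marker_curves.items()},
        }
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, source) -> "PhaseModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            phase_fractions=tuple(payload["phase_fractions"]),
            marker_curves={ch: PiecewiseCurve.from_dict(d)
                           for ch, d in payload["marker_curves"].items()},
            noise_cv=payload["noise_cv"],
            dna_levels=tuple(payload["dna_levels"]),
        )


def default_phase_model() -> PhaseModel:
    """Molt4-like study conditions.

    Time fractions G1/S/G2/M = 0.28/0.47/0.19/0.06, which after age weighting
    put ~35% of events in G1 and ~4.3% in mitosis.  Expression in arbitrary
    linear units; see the methods note for the shape rationale of each curve.
    """
    a2 = PiecewiseCurve([
        dict(u0=0.0, u1=0.28, kind="const", params=(0.0,)),
        dict(u0=0.28, u1=0.55, kind="poly", params=(0.0, 36.0, 54.0)),
        dict(u0=0.55, u1=0.92, kind="exp", params=(90.0, 300.0)),
        dict(u0=0.92, u1=0.945, kind="linear", params=(300.0, 210.0)),
        dict(u0=0.945, u1=0.965, kind="const", params=(210.0,)),
        dict(u0=0.965, u1=0.975, kind="exp", params=(210.0, 2.0)),
        dict(u0=0.975, u1=1.0, kind="const", params=(2.0,)),
    ])
    b1 = PiecewiseCurve([
        dict(u0=0.0, u1=0.25, kind="const", params=(8.0,)),
        dict(u0=0.25, u1=0.70, kind="exp", params=(8.0, 40.0)),
        dict(u0=0.70, u1=0.93, kind="exp", params=(40.0, 320.0)),
        dict(u0=0.93, u1=0.945, kind="linear", params=(320.0, 260.0)),
        dict(u0=0.945, u1=0.975, kind="const", params=(260.0,)),
        dict(u0=0.975, u1=0.9875, kind="exp", params=(260.0, 3.0)),
        dict(u0=0.9875, u1=1.0, kind="const", params=(3.0,)),
    ])
    # PHH3 dephosphorylation begins after cyclin B1 is gone but is not
    # complete at cytokinesis: cells end the cycle still well above the
    # interphase baseline (the one-generation snapshot carries no
    # inheritance, so newborns restart at baseline).
    phh3 = PiecewiseCurve([
        dict(u0=0.0, u1=0.88, kind="const", params=(5.0,)),
        dict(u0=0.88, u1=0.9475, kind="smooth", params=(5.0, 100.0)),
        dict(u0=0.9475, u1=0.9825, kind="const", params=(100.0,)),
        dict(u0=0.9825, u1=1.0, kind="smooth", params=(100.0, 30.0)),
    ])
    # side scatter tracks cell size (doubles over the cycle); pulse width is
    # flat except for elongated late-mitotic/cytokinetic cells
    ssc = PiecewiseCurve([dict(u0=0.0, u1=1.0, kind="exp", params=(150.0, 300.0))])
    width = PiecewiseCurve([
        dict(u0=0.0, u1=0.97, kind="const", params=(1.0,)),
        dict(u0=0.97, u1=1.0, kind="smooth", params=(1.0, 1.8)),
    ])
    return PhaseModel(
        phase_fractions=(0.28, 0.47, 0.19, 0.06),
        marker_curves={"cyclin_a2": a2, "cyclin_b1": b1, "phh3": phh3,
                       "ssc": ssc, "dna_width": width},
        noise_cv={"dna": 0.03, "cyclin_a2": 0.12, "cyclin_b1": 0.12,
                  "phh3": 0.12, "ssc": 0.15, "dna_width": 0.05},
    )


# -- population sampling ------------------------------------------------------

@dataclass
class SyntheticPopulation:
    """Events plus their generating truth (position u and phase label)."""

    events: EventTable
    truth: pd.DataFrame

    def __post_init__(self):
        if len(self.truth) != self.events.n_events:
            raise ValueError("truth and events must have equal length")
        u = self.truth["u"].to_numpy()
        if np.any((u < 0) | (u >= 1)):
            raise ValueError("u must lie in [0, 1)")

    def to_csv(self, path) -> None:
        data = self.events.data.copy()
        data["truth_u"] = self.truth["u"].to_numpy()
        data["truth_phase"] = self.truth["phase"].to_numpy()
        data.to_csv(path, index=False)


def position_from_frequency(x):
    """Inverse of the age CDF: cumulative frequency → cell-cycle position u."""
    return -np.log2(1.0 - np.asarray(x, dtype=float) / 2.0)


def sample_population(model: PhaseModel, n: int, seed: int,
                      age_weighted: bool = True,
                      doublet_fraction: float = 0.0,
                      gain: dict | None = None) -> SyntheticPopulation:
    """Sample an asynchronous population from the programmed curves.

    Positions come from the exponential-growth age density (or uniformly if
    ``age_weighted`` is false); each channel is its curve value at u times a
    log-normal factor of mean 1 and the channel's CV.  With
    ``doublet_fraction > 0`` that fraction of extra events are G1-G1
    aggregates: doubled DNA and pulse width, summed fluorescence — fodder for
    the singlet gate.  Doublets carry ``phase == "doublet"`` and ``u = 0``.
    ``gain`` scales whole channels (sample-level staining/instrument gain,
    see :func:`sample_replicates`).
    """
    if n < 1000:
        warnings.warn("n < 1000: phase-fraction recovery guarantees void")
    rng = np.random.default_rng(seed)
    raw = rng.random(n)
    u = position_from_frequency(raw) if age_weighted else raw

    cols: dict[str, np.ndarray] = {}
    for ch in model.channels:
        true = model.curve(ch)(u)
        cv = float(model.noise_cv.get(ch, 0.0))
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv * cv))
            factor = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))
            cols[ch] = true * factor
        else:
            cols[ch] = true
    phase = model.phase_of(u)

    if doublet_fraction > 0:
        nd = int(round(n * doublet_fraction))
        ud = position_from_frequency(rng.random((2, nd))) if age_weighted \
            else rng.random((2, nd))
        dcols = {}
        for ch in model.channels:
            true = model.curve(ch)(ud[0]) + model.curve(ch)(ud[1])
            if ch == "dna_width":
                true = model.curve(ch)(ud[0]) * 2.0  # twice the transit length
            cv = float(model.noise_cv.get(ch, 0.0))
            if cv > 0:
                sigma = np.sqrt(np.log1p(cv * cv))
                true = true * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=nd))
            dcols[ch] = true
        cols = {ch: np.concatenate([cols[ch], dcols[ch]]) for ch in cols}
        u = np.concatenate([u, np.zeros(nd)])
        phase = np.concatenate([phase, np.full(nd, "doublet")])

    if gain:
        cols = {ch: v * float(gain.get(ch, 1.0)) for ch, v in cols.items()}
    events = EventTable(pd.DataFrame(cols),
                        metadata={"generator": "sample_population", "seed": seed,
                                  "age_weighted": age_weighted, "n": n,
                                  "gain": dict(gain or {})})
    truth = pd.DataFrame({"u": u, "phase": phase})
    return SyntheticPopulation(events, truth)


#: replicate-to-replicate staining CV: tight for a stoichiometric DNA dye,
#: looser for indirect immunofluorescence
DEFAULT_STAIN_CV = {"dna": 0.015, "default": 0.03}


def sample_replicates(model: PhaseModel, n: int, n_replicates: int, seed: int,
                      stain_cv: dict | None = None,
                      age_weighted: bool = True) -> list[SyntheticPopulation]:
    """Independently stained and measured samples of one culture.

    Replicates share the phase model (one batch of cells) but each carries
    its own per-channel staining gain — replicate data contain staining
    error as well as sampling error.  Gains are log-normal with mean 1 and
    the per-channel ``stain_cv`` (``"default"`` covers unlisted channels).
    """
    cv = dict(DEFAULT_STAIN_CV)
    if stain_cv:
        cv.update(stain_cv)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        gain = {}
        for ch in model.channels:
            c = float(cv.get(ch, cv.get("default", 0.0)))
            if c > 0:
                sigma = np.sqrt(np.log1p(c * c))
                gain[ch] = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(sample_population(model, n, seed=sub_seed,
                                     age_weighted=age_weighted, gain=gain))
    return out


def ground_truth_profile(model: PhaseModel, channel: str, n_points: int = 512,
                         age_weighted: bool = True) -> ExpressionProfile:
    """Noiseless expression on the extraction output's frequency axis.

    Point j sits at cumulative frequency (j+½)/n_points; the plotted value is
    the programmed curve at the cell-cycle position holding that frequency
    (the age-CDF inverse when sampling is age weighted).  Serves as the
    recovery oracle for extracted profiles.
    """
    if channel not in model.channels:
        raise KeyError(f"channel {channel!r} not in model ({model.channels})")
    frac = np.full(n_points, 1.0 / n_points)
    x = np.cumsum(frac) - frac / 2.0
    u = position_from_frequency(x) if age_weighted else x
    return ExpressionProfile(x=x, values={channel: model.curve(channel)(u)},
                             fractions=frac,
                             counts=np.ones(n_points, dtype=int))
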