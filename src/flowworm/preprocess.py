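"""List-mode preprocessing ahead of profile extraction.

The chain mirrors standard practice for cell-cycle immunofluorescence
panels: (1) remove aggregates and debris with a high-level contour gate on
pulse width vs integrated DNA signal (R2); (2) gate mitotic cells on the
mitotic marker (R3) — late-mitotic/cytokinetic cells fall outside the
singlet gate and are restored later through R3; (3) subtract the
size-dependent non-specific cyclin background so the median cyclin signal
of G1 cells sits at ~0 ("specific fluorescence"); (4) trim outliers with
contour gates on cyclin vs DNA (R5, then a final pass R4); and (5) combine
everything with the boolean expression ``((R2 AND R4 AND R5) OR R3)`` to
recover one full cell-cycle's worth of the 2C stemline.

Contour gates are level sets of a binned kernel density estimate
(128×128 grid, Silverman bandwidth): the smallest region of the smoothed
density containing the requested percentage of probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats

from .events import EventTable, GateMask, combine_gates
from .gating import _smoothed_density

__all__ = [
    "ContourGateSpec",
    "singlet_gate",
    "mitotic_gate",
    "background_subtract",
    "outlier_gates",
    "contour_gate",
    "combine_gates",
    "s1_preprocess",
    "PreprocessResult",
]


@dataclass(frozen=True)
class ContourGateSpec:
    """A contour gate: two channels and the percent of density enclosed."""

    x_channel: str
    y_channel: str
    level: float = 99.0

    def __post_init__(self):
        if not 0 < self.level < 100:
            raise ValueError("contour level must lie strictly between 0 and 100")


def contour_gate(events: EventTable, spec: ContourGateSpec,
                 base_mask: np.ndarray | None = None,
                 name: str = "contour", bins: int = 128,
                 keep_main_component: bool = False) -> GateMask:
    """Events inside the smallest density region holding ``level`` % of mass.

    The density is estimated from the events selected by ``base_mask`` (all
    events by default) but the resulting gate is evaluated for *every*
    event, so excluded populations simply fall outside.
    """
    if events.n_events == 0:
        raise ValueError("empty event table")
    events.require(spec.x_channel, spec.y_channel)
    base = np.ones(events.n_events, bool) if base_mask is None \
        else np.asarray(base_mask, bool)
    xy_all = np.column_stack([events[spec.x_channel], events[spec.y_channel]])
    xy = xy_all[base]
    if len(xy) < 500:
        raise ValueError("need at least 500 events for density estimation")

    D, xe, ye = _smoothed_density(xy, bins=bins)
    order = np.argsort(D, axis=None)[::-1]
    mass = np.cumsum(D.ravel()[order])
    k = int(np.searchsorted(mass, spec.level / 100.0 * mass[-1]))
    threshold = D.ravel()[order[min(k, order.size - 1)]]

    keep = D >= threshold
    if keep_main_component:
        # keep only the level-set component around the main mode: a detached
        # dense blob (e.g. aggregates at twice the pulse width) stays outside
        # the contour however large the enclosed-mass level
        labels, _ = ndimage.label(keep)
        keep &= labels == labels[np.unravel_index(int(np.argmax(D)), D.shape)]

    ix = np.clip(np.searchsorted(xe, xy_all[:, 0], side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, xy_all[:, 1], side="right") - 1, 0, bins - 1)
    inside = keep[ix, iy]
    # points outside the estimation window are never inside the contour
    inside &= (xy_all[:, 0] >= xe[0]) & (xy_all[:, 0] <= xe[-1]) \
        & (xy_all[:, 1] >= ye[0]) & (xy_all[:, 1] <= ye[-1])
    return GateMask(name, inside,
                    f"{spec.level}% contour on {spec.x_channel} vs {spec.y_channel}")


def singlet_gate(events: EventTable, width_channel: str = "dna_width",
                 dna_channel: str = "dna", level: float = 99.0,
                 name: str = "R2") -> GateMask:
    """Aggregate/debris removal: contour gate on pulse width vs DNA signal.

    Doublets ride at roughly twice the pulse width of singlets with the same
    integrated signal and fall outside the high-density contour.  Note that
    elongated late-mitotic and cytokinetic cells are also excluded here;
    they are rejoined downstream via the mitotic gate.
    """
    return contour_gate(events, ContourGateSpec(width_channel, dna_channel, level),
                        name=name, keep_main_component=True)


def mitotic_gate(events: EventTable, phh3_channel: str = "phh3",
                 gated_on: GateMask | None = None,
                 threshold: float | None = None,
                 name: str = "R3") -> GateMask:
    """Gate PHH3-high (mitotic) cells.

    The threshold is placed at the density minimum between the interphase
    and mitotic modes of the PHH3 distribution (estimated on an asinh scale
    from the ``gated_on`` events), or taken from ``threshold`` verbatim.
    The gate itself is evaluated on *all* events so that mitotic cells
    excluded by the singlet gate can be restored by OR-ing with this mask.
    A unimodal distribution yields an empty mask and a warning.
    """
    events.require(phh3_channel)
    values = events[phh3_channel]
    if threshold is None:
        base = values if gated_on is None else values[gated_on.mask]
        t = np.arcsinh(base / 5.0)
        hist, edges = np.histogram(t, bins=256)
        sigma = max(t.std(ddof=1) * len(t) ** (-1 / 5.0) / (edges[1] - edges[0]), 1.0)
        dens = ndimage.gaussian_filter1d(hist.astype(float), sigma)
        peaks, props = signal.find_peaks(dens, prominence=0.002 * dens.max())
        main = peaks[np.argmax(dens[peaks])] if peaks.size else None
        upper = [p for p in peaks if main is not None and p > main]
        if main is None or not upper:
            warnings.warn("PHH3 distribution is unimodal; no mitotic cells gated")
            return GateMask(name, np.zeros(events.n_events, bool),
                            "mitotic gate: unimodal PHH3, empty")
        right = upper[-1]
        between = dens[main:right + 1]
        # the valley floor is usually flat; its midpoint is a far more
        # sample-stable cut than the literal argmin
        floor = between.min()
        low = np.flatnonzero(between <= floor + 0.02 * (between.max() - floor))
        valley = main + int(round(0.5 * (low[0] + low[-1])))
        centers = 0.5 * (edges[:-1] + edges[1:])
        threshold = float(5.0 * np.sinh(centers[valley]))
    return GateMask(name, values > threshold,
                    f"PHH3 > {threshold:.4g} on {phh3_channel}")


def background_subtract(events: EventTable, cyclin_channel: str,
                        ssc_channel: str = "ssc",
                        negative_mask: GateMask | np.ndarray | None = None,
                        max_pairs_points: int = 2000) -> EventTable:
    """Remove size-dependent non-specific cyclin fluorescence.

    Non-specific antibody binding scales with cell size, so raw cyclin
    signal rises through G1 as a function of side scatter even where no
    cyclin is present.  A Theil–Sen slope β of cyclin on SSC, fitted within
    the cyclin-negative reference cells (G1), is subtracted from all events:
    ``cyclin' = cyclin − β·SSC`` — the single-slope model implemented by a
    spillover-style linear subtraction.  After correction the reference
    median should sit within ε of zero (ε = 1% of the cyclin 90th
    percentile); a negative β estimate is clamped to 0 with a warning.
    """
    events.require(cyclin_channel, ssc_channel)
    if negative_mask is None:
        raise ValueError("negative_mask (cyclin-negative reference cells) required")
    mask = negative_mask.mask if isinstance(negative_mask, GateMask) \
        else np.asarray(negative_mask, bool)
    if not mask.any():
        raise ValueError("negative_mask selects no events")
    y = events[cyclin_channel][mask]
    x = events[ssc_channel][mask]
    if x.size > max_pairs_points:  # Theil–Sen is O(n²); thin deterministically
        order = np.argsort(x, kind="stable")
        pick = order[np.linspace(0, x.size - 1, max_pairs_points).astype(int)]
        x, y = x[pick], y[pick]
    beta = stats.theilslopes(y, x).slope
    if beta < 0:
        warnings.warn(f"estimated background slope β={beta:.4g} < 0; clamped to 0")
        beta = 0.0
    corrected = events[cyclin_channel] - beta * events[ssc_channel]
    out = events.with_channel(cyclin_channel, corrected)
    out.metadata.setdefault("background_beta", {})[cyclin_channel] = float(beta)

    med = float(np.median(corrected[mask]))
    eps = 0.01 * float(np.quantile(events[cyclin_channel], 0.9))
    if abs(med) > eps:
        warnings.warn(
            f"reference median after subtraction is {med:.4g} (ε={eps:.4g}); "
            "check the negative reference selection")
    return out


def outlier_gates(events: EventTable, cyclin_channel: str,
                  dna_channel: str = "dna",
                  interphase_mask: GateMask | np.ndarray | None = None,
                  level: float = 99.0, name: str = "R5") -> GateMask:
    """Outlier-trimming contour gate on cyclin vs DNA.

    Density is estimated on the ``interphase_mask`` events (typically
    R2 AND NOT R3); the same construction with a broader base mask serves as
    the final outlier gate of the chain.
    """
    base = None
    if interphase_mask is not None:
        base = interphase_mask.mask if isinstance(interphase_mask, GateMask) \
            else np.asarray(interphase_mask, bool)
    return contour_gate(events, ContourGateSpec(cyclin_channel, dna_channel, level),
                        base_mask=base, name=name)


@dataclass
class PreprocessResult:
    """Corrected events, the named gates, and the final combined mask."""

    events: EventTable
    masks: dict[str, GateMask]
    final: GateMask
    log: list[dict] = field(default_factory=list)


def s1_preprocess(events: EventTable, cyclin_channels=("cyclin_a2",),
                  dna_channel: str = "dna", width_channel: str = "dna_width",
                  phh3_channel: str = "phh3", ssc_channel: str = "ssc",
                  singlet_level: float = 99.0, outlier_level: float = 99.0,
                  mitotic_threshold: float | None = None) -> PreprocessResult:
    """Run the full preprocessing chain and return corrected, gated events.

    Steps: singlet gate (R2) → mitotic gate (R3) → per-cyclin background
    subtraction on G1 reference cells → interphase outlier gate (R5) → final
    outlier gate (R4, based on ``(R2 AND R5) OR R3``) → combined gate
    ``((R2 AND R4 AND R5) OR R3)``.  Gate counts are logged per step.
    """
    log: list[dict] = []
    r2 = singlet_gate(events, width_channel, dna_channel, singlet_level)
    log.append({"gate": "R2", "definition": r2.definition, "count": r2.count})
    r3 = mitotic_gate(events, phh3_channel, gated_on=r2,
                      threshold=mitotic_threshold)
    log.append({"gate": "R3", "definition": r3.definition, "count": r3.count})

    # G1 reference: singlet interphase cells inside the 2C DNA cluster.
    # The window must stay within the cluster's measurement spread — S-phase
    # cells express real cyclin correlated with size and would inflate β.
    from .pipeline import bounding_clusters
    dna = events[dna_channel]
    interphase = r2.mask & ~r3.mask
    (m1, s1), _ = bounding_clusters(dna[interphase])
    g1_ref = interphase & (dna < m1 + 2.0 * s1)
    corrected = events
    for ch in cyclin_channels:
        corrected = background_subtract(corrected, ch, ssc_channel,
                                        negative_mask=g1_ref)
        log.append({"step": f"background_subtract[{ch}]",
                    "beta": corrected.metadata["background_beta"][ch]})

    first_cyclin = cyclin_channels[0]
    r5 = outlier_gates(corrected, first_cyclin, dna_channel,
                       interphase_mask=interphase, level=outlier_level, name="R5")
    log.append({"gate": "R5", "definition": r5.definition, "count": r5.count})
    pre_final = (r2.mask & r5.mask) | r3.mask
    r4 = outlier_gates(corrected, first_cyclin, dna_channel,
                       interphase_mask=pre_final, level=outlier_level, name="R4")
    log.append({"gate": "R4", "definition": r4.definition, "count": r4.count})

    for gate in (r2, r3, r4, r5):
        corrected.add_mask(gate)
    final = combine_gates(corrected.masks, "((R2 AND R4 AND R5) OR R3)",
                          name="final")
    corrected.add_mask(final)
    log.append({"gate": "final", "definition": final.definition,
                "count": final.count})
    return PreprocessResult(corrected, corrected.masks, final, log)
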