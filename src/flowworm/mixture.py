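"""Multi-Gaussian decomposition of DNA-content histograms.

A DNA histogram from an asynchronous population is modeled as two bounding
Gaussian components (the 2C and 4C clusters, where DNA content is constant
and spread reflects measurement error only) plus a compound center made of
several equal-role S-phase Gaussians.  The fitted component means, plotted
at the centers of intervals equal to the component areas, give the
"perfect solution" expression profile against which contiguous-region
segmentation is benchmarked.

Fitting is maximum likelihood via EM with an ordering projection each
M-step: the first and last components stay the bounding clusters and the
S means are confined between them.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal

from .extraction import ExpressionProfile
from .synth import GaussianComponent, GaussianMixture1D

__all__ = ["fit_multigaussian", "profile_from_mixture"]


def _initial_mixture(values: np.ndarray, n_s: int) -> GaussianMixture1D:
    """Data-driven start: bounding components at the histogram's two modes."""
    hist, edges = np.histogram(values, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = ndimage.gaussian_filter1d(hist.astype(float), 3.0)
    peaks, _ = signal.find_peaks(dens, prominence=0.02 * dens.max())
    if peaks.size >= 2:
        lo, hi = centers[peaks[0]], centers[peaks[-1]]
    else:  # fall back to the factor-of-2 DNA states around the main mode
        main = centers[int(np.argmax(dens))]
        q10, q90 = np.quantile(values, [0.1, 0.9])
        lo, hi = (main, 2 * main) if main < 0.5 * (q10 + q90) else (main / 2, main)
    sd = 0.03 * lo
    s_means = lo + (hi - lo) * np.arange(1, n_s + 1) / (n_s + 1)
    comps = [GaussianComponent(float(lo), sd, 0.5, "G1")]
    comps += [GaussianComponent(float(m), 2 * sd, 0.35 / n_s, "S") for m in s_means]
    comps.append(GaussianComponent(float(hi), 2 * sd, 0.15, "G2M"))
    return GaussianMixture1D(comps)


def fit_multigaussian(values, n_s_components: int = 6,
                      init: GaussianMixture1D | None = None,
                      max_iter: int = 3000, tol: float = 1e-10,
                      area_tol: float = 5e-7, fix_s_lattice: bool = True,
                      bins: int = 256) -> GaussianMixture1D:
    """Constrained EM fit of ``2 + n_s_components`` Gaussians to DNA values.

    With ``fix_s_lattice`` (the default) the S components form a fixed
    lattice of Gaussians between the bounding clusters — their means and
    SDs stay at the initial grid and only their areas are estimated, as in
    classic structured DNA-histogram models where the S components are a
    basis for the synthesis continuum rather than identifiable populations.
    ``fix_s_lattice=False`` frees all parameters; individual S means and
    areas are then barely identifiable and convergence is very slow,
    although the bounding areas still come out right.

    Convergence is declared when the relative log-likelihood change drops
    below ``tol`` or every area fraction moves less than ``area_tol`` in an
    iteration.  Components whose SD collapses below a quarter of the
    histogram bin width are pruned with a warning; failure to converge
    raises with the log-likelihood trace attached.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2000:
        raise ValueError("need at least 2000 events for a stable fit")
    if n_s_components < 1:
        raise ValueError("need at least one S component")
    mix = init if init is not None else _initial_mixture(values, n_s_components)
    if len(mix.components) != 2 + n_s_components:
        raise ValueError("init has the wrong number of components")

    means = mix.means.astype(float)
    sds = mix.sds.astype(float)
    areas = mix.areas.astype(float)
    bin_width = np.ptp(values) / bins
    sd_floor = bin_width / 4.0
    trace: list[float] = []
    ll_prev = -np.inf
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        # E-step (inlined normal pdf: called thousands of times)
        z = (values[:, None] - means) / sds
        comp_pdf = areas / (np.sqrt(2 * np.pi) * sds) * np.exp(-0.5 * z * z)
        total = comp_pdf.sum(axis=1)
        total[total <= 0] = np.finfo(float).tiny
        resp = comp_pdf / total[:, None]
        ll = float(np.log(total).sum())
        trace.append(ll)
        if abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
        areas_prev = areas

        # M-step
        weight = resp.sum(axis=0)
        weight[weight <= 0] = np.finfo(float).tiny
        areas = weight / values.size
        areas /= areas.sum()
        new_means = (resp * values[:, None]).sum(axis=0) / weight
        var = (resp * (values[:, None] - new_means) ** 2).sum(axis=0) / weight
        new_sds = np.sqrt(np.maximum(var, 1e-300))
        if fix_s_lattice:  # only the bounding clusters move
            for j in (0, means.size - 1):
                means[j], sds[j] = new_means[j], new_sds[j]
        else:
            means, sds = new_means, new_sds

        # prune degenerate components
        if np.any(sds < sd_floor) and means.size > 2:
            keep = (sds >= sd_floor) | np.isin(np.arange(means.size),
                                               [0, means.size - 1])
            if not keep.all():
                warnings.warn(
                    f"pruned {np.count_nonzero(~keep)} component(s) with "
                    f"degenerate SD < {sd_floor:.4g}")
                means, sds, areas = means[keep], sds[keep], areas[keep]
                areas /= areas.sum()

        # projection: bounding components stay the extremes, S means between
        order = np.argsort(means, kind="stable")
        means, sds, areas = means[order], sds[order], areas[order]
        eps = 1e-6 * (means[-1] - means[0] + 1.0)
        means[1:-1] = np.clip(means[1:-1], means[0] + eps, means[-1] - eps)

        if areas.size == areas_prev.size \
                and float(np.abs(areas - areas_prev).max()) < area_tol:
            converged = True
            n_iter += 1
            break

    if not converged:
        err = RuntimeError(
            f"EM did not converge in {max_iter} iterations "
            f"(last Δll = {trace[-1] - trace[-2]:.3g})")
        err.loglik_trace = trace
        raise err

    labels = ["G1", *["S"] * (means.size - 2), "G2M"]
    out = GaussianMixture1D([
        GaussianComponent(float(m), float(s), float(a), lab)
        for m, s, a, lab in zip(means, sds, areas / areas.sum(), labels)])
    out.n_iter = n_iter
    out.loglik_trace = trace
    return out


def profile_from_mixture(mixture: GaussianMixture1D,
                         channel: str = "dna") -> ExpressionProfile:
    """The "perfect solution" profile: component means vs cumulative area.

    Components are ordered by mean; component i is plotted at
    ``x_i = (area before i) + area_i / 2`` with y its mean.  Boundary points
    can then be added with :func:`flowworm.extraction.insert_boundary_points`.
    """
    order = np.argsort(mixture.means, kind="stable")
    areas = mixture.areas[order]
    areas = areas / areas.sum()
    x = np.cumsum(areas) - areas / 2.0
    return ExpressionProfile(x=x, values={channel: mixture.means[order]},
                             fractions=areas)
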