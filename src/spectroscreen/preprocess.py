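"""Spectral preprocessing: rubberband baseline, normalizations,
Savitzky-Golay filtering/differentiation, and region truncation.

The rubberband baseline is the lower boundary of the convex hull of the
(wavenumber, absorbance) point set, linearly interpolated between hull
vertices; subtracting it removes smooth drift while anchoring the
corrected spectrum to zero at the hull touch points.  Normalizations
divide by a Euclidean norm (full axis, or the amide-I segment used as an
internal protein reference).  The Savitzky-Golay step performs local
least-squares polynomial smoothing and, optionally, the first derivative
with respect to wavenumber.  Truncation keeps the lipid (3050-2800 cm^-1)
and biofingerprint (1800-900 cm^-1) windows, where biofluid information
concentrates, and drops the rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateInputError,
    ParameterError,
    RangeError,
    SizeError,
    ValidationError,
)
from .spectra_io import Spectrum, SpectrumSet

DEFAULT_REGIONS = ((3050.0, 2800.0), (1800.0, 900.0))
DEFAULT_AMIDE_REGION = (1700.0, 1600.0)


# ---------------------------------------------------------------------------
# rubberband baseline
# ---------------------------------------------------------------------------

def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Monotone-chain lower convex hull of points sorted by ascending x."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above segment j->i
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband_baseline(spectrum: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Return ``(baseline, corrected)`` for the rubberband method.

    The baseline is the lower convex-hull boundary of the spectrum;
    ``corrected = spectrum - baseline`` is non-negative and exactly zero
    at every hull vertex (both endpoints included).
    """
    if len(spectrum.axis) < 3:
        raise SizeError("rubberband needs at least 3 points")
    x = spectrum.axis.values[::-1]  # ascending
    y = spectrum.absorbance[::-1]
    idx = _lower_hull_indices(x, y)
    base_asc = np.interp(x, x[idx], y[idx])
    base_asc[idx] = y[idx]  # exact at vertices regardless of rounding
    baseline = spectrum.with_absorbance(base_asc[::-1])
    corrected = spectrum.with_absorbance((y - base_asc)[::-1])
    return baseline, corrected


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def vector_normalize(spectrum: Spectrum, region: Sequence[float] | None = None) -> Spectrum:
    """Scale so the Euclidean norm over ``region`` (default: full axis) is 1."""
    if region is None:
        seg = spectrum.absorbance
    else:
        m = spectrum.axis.mask(region)
        if not m.any():
            raise RangeError(f"region {region} does not intersect the axis")
        seg = spectrum.absorbance[m]
    nrm = float(np.linalg.norm(seg))
    if nrm <= 0.0:
        raise DegenerateInputError("zero-norm segment: cannot normalize")
    return spectrum.with_absorbance(spectrum.absorbance / nrm)


def amide_i_normalize(
    spectrum: Spectrum, amide_region: Sequence[float] = DEFAULT_AMIDE_REGION
) -> Spectrum:
    """Divide by the Euclidean norm of the amide-I segment (1700-1600 cm^-1).

    The amide-I band serves as an internal protein reference; after this
    step that segment has unit norm.
    """
    return vector_normalize(spectrum, region=amide_region)


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------

def savgol(spectrum: Spectrum, window: int, polyorder: int, deriv: int = 0) -> Spectrum:
    """Savitzky-Golay smoothing / differentiation.

    The derivative (``deriv=1``) is taken with respect to wavenumber in
    ascending direction and stored back on the canonical descending
    axis, so peak-flank signs do not depend on scan direction.  Edges
    use the polynomial fitted on the boundary windows.
    """
    n = len(spectrum.axis)
    if window % 2 == 0 or window > n:
        raise ParameterError(f"window must be odd and <= {n}, got {window}")
    if not (window > polyorder >= deriv >= 0):
        raise ParameterError(
            f"need window > polyorder >= deriv >= 0, got ({window}, {polyorder}, {deriv})"
        )
    x = spectrum.axis.values[::-1]
    steps = np.diff(x)
    delta = float(steps.mean())
    if not np.allclose(steps, delta, rtol=1e-6, atol=1e-9 * abs(delta)):
        raise ParameterError("Savitzky-Golay requires a uniformly spaced axis")
    y = savgol_filter(
        spectrum.absorbance[::-1], window_length=window, polyorder=polyorder,
        deriv=deriv, delta=delta, mode="interp",
    )
    return spectrum.with_absorbance(y[::-1])


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def truncate_regions(
    sset: SpectrumSet, regions: Sequence[Sequence[float]] = DEFAULT_REGIONS
) -> SpectrumSet:
    """Keep only wavenumbers inside the closed union of ``regions``.

    Retained points keep their native values (no interpolation) and
    canonical descending order.
    """
    axis = sset.axis
    lo_ax, hi_ax = axis.values.min(), axis.values.max()
    mask = np.zeros(len(axis), dtype=bool)
    for region in regions:
        lo, hi = sorted(float(v) for v in region)
        if lo < lo_ax or hi > hi_ax:
            raise RangeError(
                f"region [{lo:g}, {hi:g}] outside axis range [{lo_ax:g}, {hi_ax:g}]"
            )
        mask |= axis.mask(region)
    if not mask.any():
        raise ValidationError("truncation removed every point")
    return sset.evolve(
        sset.to_matrix()[:, mask],
        "truncate_regions",
        {"regions": [list(map(float, r)) for r in regions]},
        axis_values=axis.values[mask],
    )


# ---------------------------------------------------------------------------
# pipeline configuration and execution
# ---------------------------------------------------------------------------

_KNOWN_STEPS = ("rubberband", "vector_norm", "amide_norm", "savgol", "truncate")


@dataclass
class PreprocessConfig:
    """Ordered preprocessing recipe plus the numeric knobs it uses.

    ``sg_window``/``sg_polyorder`` default to 9 points / order 2 — a
    band-shape-preserving smoothing choice at the dense grids typical of
    mid-IR acquisition; both are exposed here.
    """

    steps: tuple[str, ...] = ("truncate",)
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 1
    amide_region: tuple[float, float] = DEFAULT_AMIDE_REGION
    regions: tuple[tuple[float, float], ...] = DEFAULT_REGIONS
    name: str | None = None

    def __post_init__(self):
        for s in self.steps:
            if s not in _KNOWN_STEPS:
                raise ValidationError(f"unknown step {s!r}; known: {_KNOWN_STEPS}")
        if self.sg_window % 2 == 0 or not (
            self.sg_window > self.sg_polyorder >= self.sg_deriv >= 0
        ):
            raise ParameterError("need odd sg_window > sg_polyorder >= sg_deriv >= 0")
        if self.sg_deriv > 1:
            raise ParameterError("only deriv 0 or 1 supported")
        ivs = [tuple(sorted(map(float, r))) for r in self.regions]
        ivs.sort()
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ivs, ivs[1:]):
            if b_lo <= a_hi:
                raise ValidationError(f"regions overlap: {(a_lo, a_hi)} and {(b_lo, b_hi)}")


def preset(name: str, **overrides) -> PreprocessConfig:
    """Named preprocessing variants.

    - ``raw``: truncation only.
    - ``rubberband_amideI``: rubberband baseline, amide-I normalization,
      truncation.
    - ``savgol_deriv``: Savitzky-Golay smoothed first derivative,
      amide-I normalization, truncation.
    """
    table = {
        "raw": ("truncate",),
        "rubberband_amideI": ("rubberband", "amide_norm", "truncate"),
        "savgol_deriv": ("savgol", "amide_norm", "truncate"),
    }
    if name not in table:
        raise ValidationError(f"unknown preset {name!r}; known: {sorted(table)}")
    kw = dict(steps=table[name], name=name)
    if name == "savgol_deriv":
        kw["sg_deriv"] = 1
    kw.update(overrides)
    return PreprocessConfig(**kw)


PRESET_NAMES = ("raw", "rubberband_amideI", "savgol_deriv")


def apply_pipeline(sset: SpectrumSet, config: PreprocessConfig) -> SpectrumSet:
    """Run the configured steps in order, appending provenance per step.

    Pointwise transforms (baseline, normalization, derivative) run on
    the full spectrum; truncation is listed last in every preset so the
    rubberband never anchors to artificial cut endpoints.
    """
    out = sset
    for step in config.steps:
        if step == "truncate":
            out = truncate_regions(out, config.regions)
            continue
        mat = out.to_matrix()
        new = np.empty_like(mat)
        for i, s in enumerate(out.spectra):
            if step == "rubberband":
                new[i] = rubberband_baseline(s)[1].absorbance
            elif step == "vector_norm":
                new[i] = vector_normalize(s).absorbance
            elif step == "amide_norm":
                new[i] = amide_i_normalize(s, config.amide_region).absorbance
            elif step == "savgol":
                new[i] = savgol(
                    s, config.sg_window, config.sg_polyorder, config.sg_deriv
                ).absorbance
        params = {}
        if step == "savgol":
            params = {
                "window": config.sg_window,
                "polyorder": config.sg_polyorder,
                "deriv": config.sg_deriv,
            }
        elif step == "amide_norm":
            params = {"amide_region": list(config.amide_region)}
        out = out.evolve(new, step, params)
    return out
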