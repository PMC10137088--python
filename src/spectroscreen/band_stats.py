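"""Univariate band analysis: integrated band areas, weight-center
positions, normality and group-difference testing, and ROC curves with
Youden-optimal cutoffs.

A band is an integration window around a named vibrational mode; its
area (trapezoidal integral of absorbance over wavenumber) serves as a
scalar biomarker candidate, its weight center as the band position.  The
ROC area under the curve equals the Mann-Whitney probability that a
randomly chosen positive sample scores above a randomly chosen negative
(ties counted one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_curve

from .errors import (
    DegenerateInputError,
    RangeError,
    SizeError,
    ValidationError,
)
from .spectra_io import POSITIVE_LABEL, Spectrum, SpectrumSet

#: Default integration windows (cm^-1) around the three marker bands:
#: CH3 asymmetric stretch of lipids, amide I, and the carbohydrate /
#: glycosylated-protein band.  Spans cover the named modes without
#: running into neighbouring bands; all are configurable.
DEFAULT_BANDS = (
    ("2962", 2962.0, (2980.0, 2945.0)),
    ("1641", 1641.0, (1670.0, 1620.0)),
    ("1073", 1073.0, (1100.0, 1040.0)),
)


@dataclass(frozen=True)
class BandDefinition:
    """An integration window around a band center."""

    name: str
    center: float
    window: tuple[float, float]  # closed interval, any order

    def __post_init__(self):
        lo, hi = sorted(self.window)
        if not (lo < self.center < hi):
            raise ValidationError(
                f"band {self.name}: center {self.center} outside window [{lo}, {hi}]"
            )
        object.__setattr__(self, "window", (lo, hi))


def default_bands() -> list[BandDefinition]:
    return [BandDefinition(n, c, w) for n, c, w in DEFAULT_BANDS]


def _band_segment(spectrum: Spectrum, band: BandDefinition):
    m = spectrum.axis.mask(band.window)
    if not m.any():
        raise RangeError(f"band window {band.window} outside axis")
    lo, hi = band.window
    if lo < spectrum.axis.values.min() or hi > spectrum.axis.values.max():
        raise RangeError(f"band window {band.window} extends past the axis range")
    x = spectrum.axis.values[m][::-1]  # ascending for integration
    y = spectrum.absorbance[m][::-1]
    return x, y


def band_area(spectrum: Spectrum, band: BandDefinition, check_provenance: bool = False) -> float:
    """Trapezoidal integral of absorbance over the band window (abs·cm^-1)."""
    if check_provenance:
        warnings.warn(
            "band areas are meant for baseline-corrected, normalized spectra",
            stacklevel=2,
        )
    x, y = _band_segment(spectrum, band)
    return float(np.trapezoid(y, x))


def weight_center(spectrum: Spectrum, band: BandDefinition) -> float:
    """Intensity-weighted mean wavenumber over the band window."""
    x, y = _band_segment(spectrum, band)
    total = np.trapezoid(y, x)
    if total <= 0:
        raise DegenerateInputError("non-positive band area: weight center undefined")
    return float(np.trapezoid(x * y, x) / total)


def band_table(sset: SpectrumSet, bands: list[BandDefinition] | None = None) -> pd.DataFrame:
    """Per-sample area and weight center for every band.

    Spectra whose band segment has non-positive total area get ``NaN``
    weight centers (possible on derivative spectra).
    """
    bands = bands if bands is not None else default_bands()
    rows = []
    for s in sset.spectra:
        for b in bands:
            area = band_area(s, b)
            try:
                wc = weight_center(s, b)
            except DegenerateInputError:
                wc = np.nan
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "band": b.name,
                    "area": area,
                    "weight_center": wc,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def ks_normality(values) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample mean and (ddof=1) SD, so the
    p-value carries the usual estimated-parameter caveat (it is
    anti-conservative; a Lilliefors correction is not applied).  The
    p-value comes from the asymptotic Kolmogorov distribution.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise SizeError("normality test needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance: normality test undefined")
    d = stats.kstest(v, "norm", args=(v.mean(), sd)).statistic
    p = float(special.kolmogorov(np.sqrt(v.size) * d))
    return float(d), p


def two_sample_t(values_a, values_b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SizeError("t-test needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise DegenerateInputError("both groups constant and equal: t undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """ROC curve with AUC and the Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    positive_direction: str  # 'greater': larger values indicate disease


def roc(values, labels, positive_direction: str = "greater") -> ROCResult:
    """ROC analysis of a scalar marker against binary group labels.

    ``labels`` may be the group strings (positives = T2D) or 0/1.  The
    AUC equals the Mann-Whitney pair-comparison probability with ties
    counted one half.  The cutoff maximizes Youden's J = sensitivity +
    specificity - 1; J-ties are resolved toward higher specificity
    (fewer false positives, the screening-friendly side).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype.kind in "OUS":
        y = (lab == POSITIVE_LABEL).astype(int)
    else:
        y = lab.astype(int)
    if y.min() == y.max():
        raise ValidationError("both classes must be present for ROC analysis")
    if positive_direction not in ("greater", "less"):
        raise ValidationError("positive_direction must be 'greater' or 'less'")
    score = v if positive_direction == "greater" else -v

    fpr, tpr, thr = roc_curve(y, score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    sens, spec = tpr, 1.0 - fpr
    j = sens + spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best_i = best[np.argmax(spec[best])]  # ties -> higher specificity
    cut = float(thr[best_i])
    if positive_direction == "less":
        cut = -cut
    return ROCResult(
        thresholds=thr if positive_direction == "greater" else -thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=cut,
        cutoff_sensitivity=float(sens[best_i]),
        cutoff_specificity=float(spec[best_i]),
        positive_direction=positive_direction,
    )


def roc_summary(
    sset: SpectrumSet, bands: list[BandDefinition] | None = None
) -> pd.DataFrame:
    """Band-wise ROC summary (AUC, Youden cutoff, sens/spec at cutoff)."""
    bands = bands if bands is not None else default_bands()
    table = band_table(sset, bands)
    rows = []
    for b in bands:
        sub = table[table["band"] == b.name]
        r = roc(sub["area"].to_numpy(), sub["group"].to_numpy())
        rows.append(
            {
                "band": b.name,
                "auc": r.auc,
                "cutoff": r.cutoff,
                "sensitivity": r.cutoff_sensitivity,
                "specificity": r.cutoff_specificity,
            }
        )
    return pd.DataFrame(rows)
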