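"""Synthetic salivary mid-IR absorbance spectra with known group effects.

The generator emulates a two-group screening cohort measured in
replicate.  Each subject's latent spectrum is a sum of Gaussian
vibrational bands (lipid CH stretches, amides I/II, carbohydrate,
nucleic acid, plus a broad water hump above 3000 cm^-1).  Between-
subject variation has two layers, mirroring dried-biofluid films:

* a shared concentration factor (film thickness / dilution) scaling the
  whole spectrum, and
* independent per-band amplitude variation plus a small jitter of each
  band's center position.

Disease-group (T2D) subjects receive an additive amplitude shift on the
designated effect-carrier bands, expressed in units of the band's total
between-subject amplitude SD so the effect size ``d`` is directly
AUC-calibrated: two equal-variance normals separated by d have ROC
AUC = Phi(d / sqrt(2)).  The amide I band additionally shifts its center
position in T2D (a conformational-change signature), which survives any
intensity normalization and concentrates multivariate signal on the
band's own profile.

Each replicate measurement multiplies the subject spectrum by a scatter
factor and adds a smooth non-negative baseline (random quadratic drift
plus broad Gaussian undulations, emulating scattering residuals) and
white detector noise.  Ground-truth per-subject amplitudes and centers
are available alongside the spectra for parameter-recovery assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .spectra_io import SpectrumSet

#: Default band library:
#: (name, center cm^-1, sigma cm^-1, amplitude, subject_cv, d, center shift).
#: Amplitudes are unitless absorbance in the range typical of dried
#: biofluid films; subject_cv is the independent per-band amplitude CV
#: (the water hump and amide II vary more between subjects than the
#: sharper solute bands); d is the T2D amplitude effect in total-SD
#: units and the center shift (cm^-1) the T2D band-position effect.
DEFAULT_BAND_LIBRARY = (
    ("water", 3350.0, 150.0, 0.45, 0.25, 0.0, 0.0),
    ("ch3_2962", 2962.0, 12.0, 0.12, 0.10, 1.2, 0.0),
    ("ch2_2925", 2925.0, 14.0, 0.15, 0.10, 0.0, 0.0),
    ("ch_2870", 2870.0, 12.0, 0.10, 0.10, 0.0, 0.0),
    ("amide_i_1641", 1641.0, 25.0, 0.50, 0.10, 1.2, 3.0),
    ("amide_ii_1550", 1550.0, 20.0, 0.25, 0.25, 0.0, 0.0),
    ("carb_1073", 1073.0, 30.0, 0.30, 0.10, 1.2, 0.0),
    ("dna_918", 918.0, 10.0, 0.08, 0.10, 0.0, 0.0),
)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: A * exp(-(v - center)^2 / (2 width^2))."""

    name: str
    center: float
    width: float
    amplitude: float
    subject_cv: float = 0.10  # independent between-subject amplitude CV
    group_effect: float = 0.0  # additive T2D shift, units of total between-subject SD
    center_shift: float = 0.0  # T2D band-position shift, cm^-1

    def __post_init__(self):
        if self.width <= 0:
            raise ConfigError(f"band {self.name}: width must be > 0")
        if self.amplitude < 0:
            raise ConfigError(f"band {self.name}: amplitude must be >= 0")
        if self.subject_cv < 0:
            raise ConfigError(f"band {self.name}: subject_cv must be >= 0")


def default_bands() -> tuple[BandSpec, ...]:
    return tuple(BandSpec(*row) for row in DEFAULT_BAND_LIBRARY)


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the simulated cohort.

    Defaults mirror the screening study the pipeline targets: 23
    non-diabetic vs 45 type-2-diabetic subjects, three replicate spectra
    each, a 4000-400 cm^-1 axis at 2 cm^-1 spacing, and effect size
    d = 1.2 on the lipid CH3, amide I and carbohydrate bands.
    """

    n_nd: int = 23
    n_t2d: int = 45
    replicates: int = 3
    axis_start: float = 4000.0
    axis_stop: float = 400.0
    axis_step: float = 2.0
    bands: tuple[BandSpec, ...] = field(default_factory=default_bands)
    concentration_cv: float = 0.12  # shared film-thickness factor CV
    center_jitter: float = 1.5  # per-subject band-position SD, cm^-1
    replicate_noise_sd: float = 0.002  # absorbance units per point
    baseline_drift_max: float = 0.02  # quadratic drift coefficient scale
    wiggle_amp: float = 0.05  # broad baseline undulation amplitude
    n_wiggles: int = 4  # undulations per replicate
    wiggle_width: tuple[float, float] = (120.0, 350.0)  # sigma range, cm^-1
    scatter_range: tuple[float, float] = (0.9, 1.1)
    seed: int = 0

    def __post_init__(self):
        if self.n_nd < 1 or self.n_t2d < 1 or self.replicates < 1:
            raise ConfigError("subject and replicate counts must be >= 1")
        for val, nm in (
            (self.replicate_noise_sd, "replicate_noise_sd"),
            (self.baseline_drift_max, "baseline_drift_max"),
            (self.wiggle_amp, "wiggle_amp"),
            (self.concentration_cv, "concentration_cv"),
            (self.center_jitter, "center_jitter"),
        ):
            if val < 0:
                raise ConfigError(f"{nm} must be >= 0")
        if not (self.scatter_range[0] <= self.scatter_range[1]):
            raise ConfigError("scatter_range must be (lo, hi) with lo <= hi")
        n = round(abs(self.axis_start - self.axis_stop) / self.axis_step) + 1
        if n < 8 or self.axis_start <= 0 or self.axis_stop <= 0:
            raise ConfigError("invalid wavenumber axis")

    def axis_values(self) -> np.ndarray:
        n = round(abs(self.axis_start - self.axis_stop) / self.axis_step) + 1
        hi = max(self.axis_start, self.axis_stop)
        lo = min(self.axis_start, self.axis_stop)
        return np.linspace(hi, lo, n)  # canonical descending

    def total_sd(self, band: BandSpec) -> float:
        """Total between-subject amplitude SD of a band (concentration
        layer plus independent layer), the unit of ``group_effect``."""
        return band.amplitude * float(
            np.sqrt(self.concentration_cv**2 + band.subject_cv**2)
        )


def generate(config: SyntheticConfig, return_truth: bool = False):
    """Simulate the cohort; deterministic under ``config.seed``.

    Returns the SpectrumSet of all replicate spectra (subjects x
    replicates members, labelled ND/T2D) and, with ``return_truth=True``,
    also a DataFrame of the true per-subject band amplitudes and centers.
    """
    rng = np.random.default_rng(config.seed)
    axis = config.axis_values()
    bands = config.bands
    nb = len(bands)

    subjects = [f"ND{i+1:02d}" for i in range(config.n_nd)] + [
        f"T2D{i+1:02d}" for i in range(config.n_t2d)
    ]
    groups = ["ND"] * config.n_nd + ["T2D"] * config.n_t2d
    n_sub = len(subjects)
    t2d = np.array([g == "T2D" for g in groups], dtype=float)

    base = np.array([b.amplitude for b in bands])
    cvs = np.array([b.subject_cv for b in bands])
    shift = np.array([b.group_effect for b in bands]) * np.array(
        [config.total_sd(b) for b in bands]
    )
    conc = 1.0 + config.concentration_cv * rng.standard_normal(n_sub)
    amps = base[None, :] * conc[:, None] * (
        1.0 + cvs[None, :] * rng.standard_normal((n_sub, nb))
    )
    amps = np.maximum(amps + t2d[:, None] * shift[None, :], 0.0)

    centers = (
        np.array([b.center for b in bands])[None, :]
        + config.center_jitter * rng.standard_normal((n_sub, nb))
        + t2d[:, None] * np.array([b.center_shift for b in bands])[None, :]
    )
    widths = np.array([b.width for b in bands])

    u = np.linspace(-1.0, 1.0, axis.size)  # drift coordinate
    mats, sids, reps, grps = [], [], [], []
    for i, sid in enumerate(subjects):
        profiles = np.exp(
            -0.5 * ((axis[None, :] - centers[i][:, None]) / widths[:, None]) ** 2
        )
        signal = amps[i] @ profiles
        for r in range(1, config.replicates + 1):
            scatter = rng.uniform(*config.scatter_range)
            a, b = rng.uniform(
                -config.baseline_drift_max, config.baseline_drift_max, 2
            )
            c = rng.uniform(0, config.baseline_drift_max / 2)
            drift = a * u**2 + b * u
            for _ in range(config.n_wiggles):
                wc = rng.uniform(axis.min(), axis.max())
                ws = rng.uniform(*config.wiggle_width)
                drift = drift + rng.uniform(
                    -config.wiggle_amp, config.wiggle_amp
                ) * np.exp(-0.5 * ((axis - wc) / ws) ** 2)
            drift = drift - drift.min() + c  # smooth, non-negative
            noise = rng.normal(0.0, config.replicate_noise_sd, axis.size)
            mats.append(scatter * signal + drift + noise)
            sids.append(sid)
            reps.append(r)
            grps.append(groups[i])

    sset = SpectrumSet.from_matrix(
        axis, np.vstack(mats), subject_ids=sids, replicates=reps, groups=grps,
        provenance=[{"step": "synthetic_generate", "params": {"seed": config.seed}}],
    )
    if not return_truth:
        return sset
    truth = pd.DataFrame(amps, columns=[b.name for b in bands])
    for j, b in enumerate(bands):
        truth[f"{b.name}_center"] = centers[:, j]
    truth.insert(0, "subject_id", subjects)
    truth.insert(1, "group", groups)
    return sset, truth


def analytic_auc(d: float) -> float:
    """Closed-form ROC AUC of two unit-variance normals separated by d:
    Phi(d / sqrt(2))."""
    return float(norm.cdf(d / np.sqrt(2.0)))
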