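"""Spectrum containers and on-disk formats.

The atomic record is a :class:`Spectrum` — one wavenumber axis plus one
absorbance trace and its sample metadata (subject, replicate, group).  A
:class:`SpectrumSet` is an aligned collection sharing a single axis, the
working table every pipeline stage transforms; each transformation appends
to the set's provenance log so a finished run can be re-derived.

Supported formats: a wide CSV matrix (rows = wavenumbers, columns =
samples, or the transposed layout) and single-spectrum JCAMP-DX files
(``XYDATA=(X++(Y..Y))`` with plain AFFN numbers, or ``XYPOINTS``).

Wavenumber axes are canonically stored descending (4000 -> 400 cm^-1),
matching the instrument display convention; ascending input is accepted
and flipped on construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ValidationError

GROUP_LABELS = ("ND", "T2D")
#: The label treated as the positive (disease) class throughout.
POSITIVE_LABEL = "T2D"

#: Minimum number of points required when loading spectra from disk.
MIN_FILE_POINTS = 8


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class WavenumberAxis:
    """Strictly monotonic, positive wavenumber axis in cm^-1.

    Either orientation is accepted; :meth:`descending` returns the
    canonical (descending) version.
    """

    __slots__ = ("values",)

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValidationError("axis needs at least 2 points in one dimension")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("axis contains non-finite values")
        if np.any(arr <= 0):
            raise ValidationError("wavenumbers must be positive")
        d = np.diff(arr)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("axis must be strictly monotonic")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __setattr__(self, name, value):  # immutable
        raise AttributeError("WavenumberAxis is immutable")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        v = self.values
        return f"WavenumberAxis({v[0]:g}..{v[-1]:g} cm-1, n={v.size})"

    @property
    def is_descending(self) -> bool:
        return self.values[0] > self.values[-1]

    def descending(self) -> "WavenumberAxis":
        return self if self.is_descending else WavenumberAxis(self.values[::-1])

    def mask(self, interval: Sequence[float]) -> np.ndarray:
        """Boolean mask of points inside the closed interval (any order)."""
        lo, hi = sorted(float(v) for v in interval)
        return (self.values >= lo) & (self.values <= hi)


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a wavenumber axis, plus sample metadata."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    subject_id: str | None = None
    replicate: int = 1
    group: str | None = None

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.axis),):
            raise ValidationError(
                f"absorbance length {a.shape} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValidationError("absorbance contains NaN/Inf")
        if not self.axis.is_descending:
            object.__setattr__(self, "axis", self.axis.descending())
            a = a[::-1]
        if self.group is not None and self.group not in GROUP_LABELS:
            raise ValidationError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )
        a = a.copy()
        a.setflags(write=False)
        object.__setattr__(self, "absorbance", a)

    def with_absorbance(self, values: np.ndarray, axis: WavenumberAxis | None = None) -> "Spectrum":
        return replace(self, absorbance=np.asarray(values, float), axis=axis or self.axis)

    @property
    def sample_key(self) -> str:
        sid = self.subject_id if self.subject_id is not None else "sample"
        return f"{sid}_r{self.replicate}"


@dataclass
class SpectrumSet:
    """Aligned spectra sharing one axis, with an append-only provenance log."""

    axis: WavenumberAxis
    spectra: list[Spectrum]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.axis = self.axis.descending()
        for s in self.spectra:
            if s.axis != self.axis:
                raise ValidationError("all member spectra must share the set axis")

    # construction -----------------------------------------------------
    @classmethod
    def from_matrix(
        cls,
        axis_values: Sequence[float],
        matrix: np.ndarray,
        subject_ids: Sequence[str] | None = None,
        replicates: Sequence[int] | None = None,
        groups: Sequence[str | None] | None = None,
        provenance: list[dict] | None = None,
    ) -> "SpectrumSet":
        """Build a set from an (n_samples, n_points) matrix."""
        axis = WavenumberAxis(axis_values)
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != len(axis):
            raise ValidationError("matrix must be (n_samples, n_points)")
        if not axis.is_descending:
            axis = axis.descending()
            mat = mat[:, ::-1]
        n = mat.shape[0]
        subject_ids = list(subject_ids) if subject_ids is not None else [f"s{i+1}" for i in range(n)]
        replicates = list(replicates) if replicates is not None else [1] * n
        groups = list(groups) if groups is not None else [None] * n
        spectra = [
            Spectrum(axis, mat[i], subject_id=str(subject_ids[i]),
                     replicate=int(replicates[i]), group=groups[i])
            for i in range(n)
        ]
        return cls(axis, spectra, provenance=list(provenance or []))

    # views ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.spectra)

    def to_matrix(self) -> np.ndarray:
        return np.vstack([s.absorbance for s in self.spectra])

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.spectra],
                "replicate": [s.replicate for s in self.spectra],
                "group": [s.group for s in self.spectra],
            }
        )

    def labels(self) -> np.ndarray:
        return np.asarray([s.group for s in self.spectra], dtype=object)

    # transformation plumbing ------------------------------------------
    def evolve(
        self,
        matrix: np.ndarray,
        step: str,
        params: dict | None = None,
        axis_values: Sequence[float] | None = None,
    ) -> "SpectrumSet":
        """Return a new set with transformed data and ``step`` appended
        to the provenance log (the log itself is copied, never mutated)."""
        new = SpectrumSet.from_matrix(
            axis_values if axis_values is not None else self.axis.values,
            matrix,
            subject_ids=[s.subject_id for s in self.spectra],
            replicates=[s.replicate for s in self.spectra],
            groups=[s.group for s in self.spectra],
            provenance=self.provenance + [{"step": step, "params": dict(params or {})}],
        )
        return new

    def step_names(self) -> list[str]:
        return [p["step"] for p in self.provenance]


# ---------------------------------------------------------------------------
# CSV matrix format
# ---------------------------------------------------------------------------

def _attach_metadata(sample_keys, metadata):
    """Resolve (subject_id, replicate, group) per sample key."""
    ids, reps, grps = [], [], []
    meta = None
    if metadata is not None:
        meta = pd.read_csv(metadata) if not isinstance(metadata, pd.DataFrame) else metadata
        if "sample" not in meta.columns:
            raise FormatError("metadata table requires a 'sample' column")
        meta = meta.set_index(meta["sample"].astype(str))
    for key in sample_keys:
        key = str(key)
        if meta is not None and key in meta.index:
            row = meta.loc[key]
            ids.append(str(row.get("subject_id", key)))
            reps.append(int(row.get("replicate", 1)))
            g = row.get("group", None)
            grps.append(None if g is None or (isinstance(g, float) and np.isnan(g)) else str(g))
        else:
            m = re.match(r"^(.*)_r(\d+)$", key)
            if m:
                ids.append(m.group(1))
                reps.append(int(m.group(2)))
            else:
                ids.append(key)
                reps.append(1)
            grps.append(None)
    for g in grps:
        if g is not None and g not in GROUP_LABELS:
            raise ValidationError(
                f"unknown group label {g!r}; expected one of {GROUP_LABELS}"
            )
    return ids, reps, grps


def read_csv_matrix(
    path,
    orientation: str = "wide",
    metadata=None,
) -> SpectrumSet:
    """Read a CSV spectrum matrix.

    ``orientation='wide'``: first column holds wavenumbers, remaining
    columns one sample each (header row = sample keys).
    ``orientation='transposed'``: one row per sample; numeric column
    headers are wavenumbers; optional ``subject_id``/``replicate``/
    ``group`` columns carry metadata inline.

    ``metadata`` may be a CSV path or DataFrame with columns
    ``sample, subject_id, replicate, group`` keyed by sample header.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"ragged or incomplete rows in {path}")

    if orientation == "wide":
        try:
            wn = df.iloc[:, 0].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise FormatError(f"first column of {path} must be numeric wavenumbers") from exc
        _check_monotonic(wn, path)
        sample_keys = list(df.columns[1:])
        if not sample_keys:
            raise FormatError(f"{path} holds no sample columns")
        mat = df.iloc[:, 1:].to_numpy(dtype=float).T
    elif orientation == "transposed":
        meta_cols = [c for c in ("subject_id", "replicate", "group") if c in df.columns]
        spec_cols = [c for c in df.columns if c not in meta_cols]
        try:
            wn = np.asarray([float(c) for c in spec_cols])
        except ValueError as exc:
            raise FormatError(f"non-numeric wavenumber column headers in {path}") from exc
        _check_monotonic(wn, path)
        mat = df[spec_cols].to_numpy(dtype=float)
        ids = df["subject_id"].astype(str).tolist() if "subject_id" in meta_cols else None
        reps = df["replicate"].astype(int).tolist() if "replicate" in meta_cols else None
        grps = (
            [None if pd.isna(g) else str(g) for g in df["group"]]
            if "group" in meta_cols else None
        )
        if grps:
            for g in grps:
                if g is not None and g not in GROUP_LABELS:
                    raise ValidationError(
                        f"unknown group label {g!r}; expected one of {GROUP_LABELS}"
                    )
        if len(wn) < MIN_FILE_POINTS:
            raise FormatError(f"{path}: fewer than {MIN_FILE_POINTS} spectral points")
        out = SpectrumSet.from_matrix(wn, mat, subject_ids=ids, replicates=reps, groups=grps)
        out.provenance.append({"step": "read_csv_matrix", "params": {"path": str(path)}})
        return out
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")

    if len(wn) < MIN_FILE_POINTS:
        raise FormatError(f"{path}: fewer than {MIN_FILE_POINTS} spectral points")
    ids, reps, grps = _attach_metadata(sample_keys, metadata)
    out = SpectrumSet.from_matrix(wn, mat, subject_ids=ids, replicates=reps, groups=grps)
    out.provenance.append({"step": "read_csv_matrix", "params": {"path": str(path)}})
    return out


def _check_monotonic(wn: np.ndarray, path) -> None:
    d = np.diff(wn)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise FormatError(f"wavenumber axis in {path} is not strictly monotonic")


def write_csv_matrix(sset: SpectrumSet, path, metadata_path=None, float_format: str = "%.10g") -> None:
    """Write the wide CSV layout (rows = wavenumbers, cols = samples)."""
    path = Path(path)
    keys = [s.sample_key for s in sset.spectra]
    df = pd.DataFrame(sset.to_matrix().T, columns=keys)
    df.insert(0, "wavenumber", sset.axis.values)
    df.to_csv(path, index=False, float_format=float_format)
    if metadata_path is not None:
        meta = sset.metadata()
        meta.insert(0, "sample", keys)
        meta.to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##([^=]+)=\s*(.*)$")


def read_jcamp(path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file.

    Supports ``##XYDATA=(X++(Y..Y))`` tables in plain AFFN form and
    ``##XYPOINTS=(XY..XY)`` pair tables; ``XFACTOR``/``YFACTOR`` scaling
    is applied.  For XYDATA the axis is reconstructed from
    ``FIRSTX``/``LASTX``/``NPOINTS`` (already in real units per the
    standard); the leading X of each data line is used only as a check.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("$$")[0].rstrip()
            if not line:
                continue
            m = _LDR.match(line)
            if m:
                key = m.group(1).strip().upper().replace(" ", "")
                val = m.group(2).strip()
                if key in ("XYDATA", "XYPOINTS"):
                    mode = key
                    headers[key] = val
                elif key == "END":
                    mode = None
                else:
                    headers[key] = val
                    mode = None
            elif mode in ("XYDATA", "XYPOINTS"):
                data_lines.append(line)
    if "XYDATA" not in headers and "XYPOINTS" not in headers:
        raise FormatError(f"{path}: no XYDATA or XYPOINTS table")

    xf = float(headers.get("XFACTOR", 1.0))
    yf = float(headers.get("YFACTOR", 1.0))

    if "XYDATA" in headers:
        for req in ("FIRSTX", "LASTX", "NPOINTS"):
            if req not in headers:
                raise FormatError(f"{path}: missing required JCAMP header ##{req}")
        npts = int(float(headers["NPOINTS"]))
        firstx, lastx = float(headers["FIRSTX"]), float(headers["LASTX"])
        x = np.linspace(firstx, lastx, npts)
        ys: list[float] = []
        for line in data_lines:
            toks = line.replace(",", " ").split()
            ys.extend(float(t) for t in toks[1:])  # first token is the line's X
        if len(ys) != npts:
            raise FormatError(f"{path}: NPOINTS={npts} but {len(ys)} Y values found")
        y = np.asarray(ys) * yf
    else:
        xs, ys = [], []
        for line in data_lines:
            toks = re.split(r"[,;\s]+", line.strip())
            if len(toks) % 2:
                raise FormatError(f"{path}: odd token count in XYPOINTS line")
            vals = [float(t) for t in toks]
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
        x = np.asarray(xs) * xf
        y = np.asarray(ys) * yf
    if x.size < MIN_FILE_POINTS:
        raise FormatError(f"{path}: fewer than {MIN_FILE_POINTS} points")
    title = headers.get("TITLE", path.stem)
    return Spectrum(WavenumberAxis(x), y, subject_id=title)


def write_jcamp(spectrum: Spectrum, path, title: str | None = None) -> None:
    """Write a minimal JCAMP-DX file (XYPOINTS, unit factors)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"##TITLE={title or spectrum.subject_id or 'spectrum'}\n")
        fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        fh.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        fh.write(f"##FIRSTX={spectrum.axis.values[0]:.10g}\n")
        fh.write(f"##LASTX={spectrum.axis.values[-1]:.10g}\n")
        fh.write(f"##NPOINTS={len(spectrum.axis)}\n")
        fh.write("##XYPOINTS=(XY..XY)\n")
        for x, y in zip(spectrum.axis.values, spectrum.absorbance):
            fh.write(f"{x:.10g}, {y:.10g}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# axis alignment and replicate aggregation
# ---------------------------------------------------------------------------

def resample_common_axis(
    sets: SpectrumSet | Iterable[SpectrumSet],
    target: WavenumberAxis | Sequence[float],
) -> SpectrumSet:
    """Linearly interpolate every spectrum onto ``target``.

    The target must lie within the intersection of all input axis ranges:
    extrapolation is refused.
    """
    if isinstance(sets, SpectrumSet):
        sets = [sets]
    sets = list(sets)
    if not sets:
        raise ValidationError("no input sets")
    target = target if isinstance(target, WavenumberAxis) else WavenumberAxis(target)
    target = target.descending()
    t_lo, t_hi = target.values.min(), target.values.max()
    for ss in sets:
        lo, hi = ss.axis.values.min(), ss.axis.values.max()
        if t_lo < lo or t_hi > hi:
            raise RangeError(
                f"target axis [{t_lo:g}, {t_hi:g}] outside input range [{lo:g}, {hi:g}]"
            )
    spectra = []
    tgt_asc = target.values[::-1]
    for ss in sets:
        src_asc = ss.axis.values[::-1]
        for s in ss.spectra:
            y = np.interp(tgt_asc, src_asc, s.absorbance[::-1])[::-1]
            spectra.append(Spectrum(target, y, s.subject_id, s.replicate, s.group))
    prov = (sets[0].provenance if len(sets) == 1 else []) + [
        {"step": "resample_common_axis", "params": {"n_points": len(target)}}
    ]
    return SpectrumSet(target, spectra, provenance=prov)


def aggregate_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average each subject's replicate spectra pointwise.

    Output holds one spectrum per subject (in order of first appearance)
    with ``replicate=0`` marking the aggregate; the group label is
    preserved and must be consistent across a subject's replicates.
    """
    order: list[str] = []
    traces: dict[str, list[np.ndarray]] = {}
    groups: dict[str, str | None] = {}
    for s in sset.spectra:
        sid = s.subject_id
        if sid not in traces:
            order.append(sid)
            traces[sid] = []
            groups[sid] = s.group
        elif groups[sid] != s.group:
            raise ValidationError(
                f"subject {sid!r} has conflicting group labels "
                f"({groups[sid]!r} vs {s.group!r})"
            )
        traces[sid].append(s.absorbance)
    mat = np.vstack([np.mean(traces[sid], axis=0) for sid in order])
    out = SpectrumSet.from_matrix(
        sset.axis.values,
        mat,
        subject_ids=order,
        replicates=[0] * len(order),
        groups=[groups[sid] for sid in order],
        provenance=sset.provenance
        + [{"step": "aggregate_replicates", "params": {"n_subjects": len(order)}}],
    )
    return out
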