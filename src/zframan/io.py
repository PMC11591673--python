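"""Reading and writing Raman spectra, dataset manifests and pipeline tables.

Spectra are plain two-column text files (wavenumber in cm^-1, intensity in
detector counts); ``#`` starts a comment line and an optional
``wavenumber,intensity`` header is accepted.  All sample metadata lives in a
separate manifest CSV — spectrum files carry none, which matches the
heterogeneous exports of commercial instruments.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ORGANS = ("iris", "forebrain", "melanocytes", "heart", "muscle", "swim_bladder")

#: hours-post-fertilisation sampling grid
STAGES = (24, 48, 72, 96, 120, 144, 168)

#: observation window (first stage, last stage) per organ: iris and forebrain
#: are measurable from 24 hpf, melanocytes/heart/muscle from 48 hpf, and the
#: swim bladder only after inflation from 96 hpf.
ORGAN_WINDOWS: dict[str, tuple[int, int]] = {
    "iris": (24, 168),
    "forebrain": (24, 168),
    "melanocytes": (48, 168),
    "heart": (48, 168),
    "muscle": (48, 168),
    "swim_bladder": (96, 168),
}

MANIFEST_COLUMNS = ("file", "animal_id", "clutch_id", "organ", "stage_hpf", "replicate")

WAVENUMBER_MIN = 50.0
WAVENUMBER_MAX = 4100.0
MIN_POINTS = 50


class SpectrumParseError(ValueError):
    """Raised when a spectrum file contains malformed rows."""


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has too few points to be fit."""


class ManifestSchemaError(ValueError):
    """Raised when the manifest is missing required columns."""


def normalise_organ(name: str) -> str:
    """Map free-form organ names ('Swim Bladder') onto the canonical enum."""
    canon = re.sub(r"[\s\-]+", "_", str(name).strip().lower())
    if canon not in ORGANS:
        raise ValueError(
            f"unknown organ {name!r}; expected one of {', '.join(ORGANS)}"
        )
    return canon


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one acquisition: which animal, clutch, organ and stage."""

    animal_id: str
    clutch_id: str
    organ: str
    stage_hpf: int
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "organ", normalise_organ(self.organ))
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def check_window(self, strict: bool = False) -> None:
        """Warn (or raise) if the stage falls outside the organ's window."""
        lo, hi = ORGAN_WINDOWS[self.organ]
        if not lo <= self.stage_hpf <= hi:
            msg = (
                f"{self.organ} observed at {self.stage_hpf} hpf, outside its "
                f"usual window {lo}-{hi} hpf"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)


@dataclass
class Spectrum:
    """One acquisition: a strictly increasing wavenumber grid plus counts."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample: SampleMeta | None = None
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if nu.ndim != 1 or y.ndim != 1 or nu.size != y.size:
            raise ValueError("wavenumbers and intensities must be 1-D and equal length")
        if nu.size < MIN_POINTS:
            raise DegenerateSpectrumError(
                f"spectrum has {nu.size} points; need >= {MIN_POINTS}"
            )
        if not np.all(np.isfinite(nu)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in spectrum")
        if nu[0] > nu[-1]:  # descending export — reverse both in lockstep
            nu, y = nu[::-1].copy(), y[::-1].copy()
        d = np.diff(nu)
        if np.any(d == 0):
            raise ValueError("duplicate wavenumbers in spectrum")
        if np.any(d < 0):
            raise ValueError("wavenumbers are not monotone")
        if nu[0] < WAVENUMBER_MIN or nu[-1] > WAVENUMBER_MAX:
            raise ValueError(
                f"wavenumber span [{nu[0]:g}, {nu[-1]:g}] outside the accepted "
                f"[{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}] cm^-1 range"
            )
        self.wavenumbers = nu
        self.intensities = y

    def __len__(self) -> int:
        return self.wavenumbers.size


_HEADER_RE = re.compile(r"^[a-zA-Z_\"']")


def read_spectrum(path: str | Path, meta: SampleMeta | None = None) -> Spectrum:
    """Read a two-column text spectrum (whitespace, tab or comma delimited).

    Lines starting with ``#`` and a single alphabetic header line are skipped.
    Descending grids are silently reversed.
    """
    path = Path(path)
    nus: list[float] = []
    ys: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if _HEADER_RE.match(line) and not nus:
                continue  # column header such as "wavenumber,intensity"
            parts = [p for p in re.split(r"[,\t\s]+", line) if p]
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns")
            try:
                nus.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from exc
    if len(nus) < MIN_POINTS:
        raise DegenerateSpectrumError(
            f"{path}: only {len(nus)} data rows; need >= {MIN_POINTS}"
        )
    return Spectrum(np.array(nus), np.array(ys), sample=meta, source=str(path))


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# wavenumber_cm-1 intensity_counts\n")
        for nu, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(nu)!r} {float(y)!r}\n")


def read_manifest(path: str | Path, strict_stages: bool = True) -> dict[str, SampleMeta]:
    """Read the dataset manifest; returns ``{spectrum file: SampleMeta}``.

    Organ names are normalised case-insensitively; unknown organs are
    rejected.  Stages outside the 24..168 hpf / 24 h grid raise by default
    (``strict_stages=False`` downgrades to a warning).
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"manifest missing column(s): {', '.join(missing)}")
    out: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        stage = int(row["stage_hpf"])
        if stage not in STAGES:
            msg = f"stage {stage} hpf not on the sampling grid {STAGES}"
            if strict_stages:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        out[str(row["file"])] = SampleMeta(
            animal_id=str(row["animal_id"]),
            clutch_id=str(row["clutch_id"]),
            organ=str(row["organ"]),
            stage_hpf=stage,
            replicate=int(row["replicate"]),
        )
    return out


def manifest_frame(manifest: dict[str, SampleMeta]) -> pd.DataFrame:
    """Manifest as a tidy DataFrame (one row per spectrum file)."""
    return pd.DataFrame(
        [
            {
                "file": f,
                "animal_id": m.animal_id,
                "clutch_id": m.clutch_id,
                "organ": m.organ,
                "stage_hpf": m.stage_hpf,
                "replicate": m.replicate,
            }
            for f, m in manifest.items()
        ],
        columns=list(MANIFEST_COLUMNS),
    )


def write_table(rows: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a pipeline table as UTF-8 CSV, 12-significant-digit floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=index, float_format="%.12g", encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path)
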