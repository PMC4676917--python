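"""Thermogram container and ingest.

A thermogram is the far-UV CD observable used to follow thermal
unfolding: ellipticity at 222 nm (mdeg) recorded against temperature
(degrees C).  For a protein showing both cold and heat denaturation the
trace dips through a folded plateau between two sigmoidal transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Thermogram", "ThermogramIngestError", "read_thermogram"]

MIN_POINTS = 20
TEMP_SANITY_C = (-10.0, 110.0)


class ThermogramIngestError(ValueError):
    """Raised when a thermogram file cannot be turned into usable data."""


@dataclass
class Thermogram:
    """Temperature/ellipticity series for one construct.

    ``temperature`` (degrees C) is strictly increasing after construction:
    input is sorted and duplicate temperatures are averaged.  An optional
    per-point ``sigma`` (mdeg) enables weighted fitting.
    """

    temperature: np.ndarray
    ellipticity: np.ndarray
    label: str = ""
    metadata: str = ""
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ThermogramIngestError("temperature and ellipticity must be equal-length 1-D series")
        s = None if self.sigma is None else np.asarray(self.sigma, dtype=float)
        if s is not None and s.shape != t.shape:
            raise ThermogramIngestError("sigma must match the series length")
        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]
        if s is not None:
            s = s[order]
        # average duplicate temperatures
        uniq, inv = np.unique(t, return_inverse=True)
        if uniq.size != t.size:
            y = np.bincount(inv, weights=y) / np.bincount(inv)
            if s is not None:
                s = np.bincount(inv, weights=s) / np.bincount(inv)
            t = uniq
        if t.size < MIN_POINTS:
            raise ThermogramIngestError(
                f"need at least {MIN_POINTS} points for fitting, got {t.size}"
            )
        lo, hi = TEMP_SANITY_C
        if t.min() < lo or t.max() > hi:
            raise ThermogramIngestError(
                f"temperatures outside sanity window [{lo}, {hi}] degC"
            )
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ellipticity", y)
        object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.temperature.size

    def to_frame(self) -> pd.DataFrame:
        d = {"temperature_C": self.temperature, "ellipticity_mdeg": self.ellipticity}
        if self.sigma is not None:
            d["sigma_mdeg"] = self.sigma
        return pd.DataFrame(d)


def read_thermogram(path, dialect: str | None = None, label: str = "") -> Thermogram:
    """Read a two- or three-column delimited thermogram file.

    Accepts CSV or TSV (``dialect`` of ``"csv"``/``"tsv"``, or sniffed from
    the extension and content), an optional header row, and comment lines
    starting with ``#``.  Columns are temperature (degC), ellipticity
    (mdeg) and optionally a per-point sigma (mdeg).

    Raises
    ------
    ThermogramIngestError
        On fewer than 20 usable rows, or a non-numeric data cell (the
        message names the offending line number).
    """
    path = str(path)
    with open(path) as fh:
        raw = fh.read()
    if dialect == "csv":
        sep = ","
    elif dialect == "tsv":
        sep = "\t"
    elif dialect is None:
        first_data = next((l for l in raw.splitlines() if l.strip() and not l.startswith("#")), "")
        sep = "\t" if (path.endswith(".tsv") or "\t" in first_data) else ","
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    rows: list[tuple[float, ...]] = []
    for lineno, line in enumerate(raw.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        cells = [c.strip() for c in stripped.split(sep)]
        if len(cells) < 2:
            raise ThermogramIngestError(f"line {lineno}: expected >= 2 columns")
        try:
            rows.append(tuple(float(c) for c in cells[:3]))
        except ValueError:
            if not rows and lineno <= 2:
                continue  # header row
            raise ThermogramIngestError(
                f"line {lineno}: non-numeric cell in {cells!r}"
            ) from None
    if len(rows) < MIN_POINTS:
        raise ThermogramIngestError(
            f"{path}: only {len(rows)} usable rows (need {MIN_POINTS})"
        )
    arr = np.array([r[:2] for r in rows], dtype=float)
    sigma = None
    if all(len(r) >= 3 for r in rows):
        sigma = np.array([r[2] for r in rows], dtype=float)
    return Thermogram(arr[:, 0], arr[:, 1], label=label or path, sigma=sigma)
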