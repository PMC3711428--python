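"""Spectral spillover estimation and compensation for 3-color cytometry.

Each fluorophore (EGFP, ECFP, DsRed-Express) is detected primarily in one
detector (530/30, 450/40, 695/40 nm) but spills into the others.  The
spillover matrix S (rows = fluorophores, columns = detectors, each row
normalized to 1 at its primary detector) is estimated from single-color
control populations by least squares through the origin; compensation
applies its inverse to observed detector vectors, recovering per-fluorophore
signal estimates.  Negative compensated values are retained so that
population means stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .synthetic_flow import DETECTORS, FLUOROPHORES, PRIMARY_DETECTOR

#: column index of each fluorophore's primary detector
_PRIMARY_IDX = {f: DETECTORS.index(PRIMARY_DETECTOR[f]) for f in FLUOROPHORES}

#: default minimum primary-channel signal (a.u.) for an event to enter the
#: spillover regression, keeping autofluorescence-dominated events out
DEFAULT_SIGNAL_FLOOR = 10.0


@dataclass(frozen=True)
class SpectralModel:
    """A 3x3 spillover matrix and its inverse.

    ``spillover[i, j]`` is the fraction of fluorophore ``FLUOROPHORES[i]``
    signal appearing in detector ``DETECTORS[j]``, scaled so the primary
    detector entry is 1.
    """

    spillover: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.spillover, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("spillover must be a 3x3 matrix")
        object.__setattr__(self, "spillover", m)
        if not np.isfinite(self.condition_number) \
                or self.condition_number > 1e12:
            raise ValueError(
                f"spillover matrix is singular or near-singular "
                f"(condition number {self.condition_number:.3g})"
            )

    @property
    def compensation(self) -> np.ndarray:
        """Inverse of the spillover matrix (detectors -> fluorophores)."""
        return np.linalg.inv(self.spillover)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.spillover))

    def normalized(self) -> "SpectralModel":
        """Rescale each row to 1 at its primary detector (idempotent)."""
        m = self.spillover.copy()
        for i, f in enumerate(FLUOROPHORES):
            m[i] = m[i] / m[i, _PRIMARY_IDX[f]]
        return SpectralModel(m)

    @classmethod
    def identity(cls) -> "SpectralModel":
        """Each fluorophore seen only in its primary detector."""
        m = np.zeros((3, 3))
        for f, j in _PRIMARY_IDX.items():
            m[FLUOROPHORES.index(f), j] = 1.0
        return cls(m)

    # -- plain-text serialization -----------------------------------------

    def save(self, path: str | Path) -> None:
        lines = ["fluorophore\t" + "\t".join(DETECTORS)]
        for i, f in enumerate(FLUOROPHORES):
            lines.append(f + "\t" + "\t".join(f"{v:.10g}" for v in self.spillover[i]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SpectralModel":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[1:] != list(DETECTORS):
            raise ValueError(f"{path}: expected detector columns {DETECTORS}, "
                             f"got {header[1:]}")
        rows = {}
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows[parts[0]] = [float(v) for v in parts[1:]]
        try:
            m = np.array([rows[f] for f in FLUOROPHORES])
        except KeyError as exc:
            raise ValueError(f"{path}: missing fluorophore row {exc}") from exc
        return cls(m)


def estimate_spillover(controls: Mapping[str, pd.DataFrame],
                       signal_floor: float = DEFAULT_SIGNAL_FLOOR,
                       background: pd.DataFrame | None = None) -> SpectralModel:
    """Estimate the spillover matrix from single-color control populations.

    Parameters
    ----------
    controls
        Mapping of fluorophore name to an event table of cells expressing
        only that fluorophore.
    signal_floor
        Events whose primary-channel signal is below this value (a.u.) are
        excluded from the fit, so autofluorescence does not dominate the
        regression.
    background
        Optional mock (untransfected) event table; its per-channel mean is
        subtracted from every control before fitting.

    For each fluorophore, every detector signal is regressed against the
    primary-channel signal by least squares through the origin; the slopes
    form the fluorophore's spillover row, normalized to 1 at the primary
    detector.
    """
    missing = [f for f in FLUOROPHORES if f not in controls]
    if missing:
        raise ValueError(f"missing single-color control(s) for: "
                         f"{', '.join(missing)}")

    bg = np.zeros(3)
    if background is not None:
        bg = background[list(DETECTORS)].to_numpy(float).mean(axis=0)

    rows = np.zeros((3, 3))
    for i, f in enumerate(FLUOROPHORES):
        det = controls[f][list(DETECTORS)].to_numpy(float) - bg
        x = det[:, _PRIMARY_IDX[f]]
        mask = x >= signal_floor
        if mask.sum() < 2:
            raise ValueError(
                f"control for {f} has fewer than 2 events above the "
                f"{signal_floor} a.u. primary-signal floor"
            )
        xs = x[mask]
        denom = float(xs @ xs)
        rows[i] = det[mask].T @ xs / denom
    model = SpectralModel(rows).normalized()
    if model.condition_number > 1e6:
        raise ValueError(
            f"estimated spillover matrix is ill-conditioned "
            f"(condition number {model.condition_number:.3g})"
        )
    return model


def apply_compensation(events: pd.DataFrame, model: SpectralModel,
                       background: pd.DataFrame | None = None) -> pd.DataFrame:
    """Apply the compensation (inverse-spillover) matrix to an event table.

    Detector columns are replaced by the per-fluorophore signal estimates,
    each written into its fluorophore's primary detector column (so with an
    identity model the table is unchanged).  Negative values are retained;
    scatter and truth columns pass through untouched.  If ``background`` is
    given, its per-channel mean is subtracted before inversion.
    """
    missing = [c for c in DETECTORS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing detector columns: {missing}")
    out = events.copy()
    if not len(events):
        return out
    det = events[list(DETECTORS)].to_numpy(float)
    if background is not None:
        det = det - background[list(DETECTORS)].to_numpy(float).mean(axis=0)
    abundances = det @ model.compensation  # columns in fluorophore order
    for i, f in enumerate(FLUOROPHORES):
        out[PRIMARY_DETECTOR[f]] = abundances[:, i]
    return out
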