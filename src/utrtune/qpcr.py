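"""qPCR standard curves and relative quantification of reporter mRNA.

The control experiment verifies that tuned 5'-UTR designs act on translation
rather than mRNA abundance: reporter (ECFP) mRNA is quantified against a
standard curve built from a 10-fold plasmid dilution series (50 fg to 5 ng)
and normalized to the neomycin-resistance gene carried on the same vector.
Quantification goes through per-assay standard curves (Cq regressed on
log10 quantity); the 2^dCq shortcut is used only as a consistency check in
the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

#: the printed dilution-series design: 10-fold steps from 50 fg to 5 ng (pg)
STANDARD_QUANTITIES_PG = (0.05, 0.5, 5.0, 50.0, 500.0, 5000.0)
#: slope of a perfectly doubling reaction: -1/log10(2)
PERFECT_DOUBLING_SLOPE = -1.0 / math.log10(2.0)

ASSAYS = ("ECFP", "neo")


@dataclass(frozen=True)
class StandardCurve:
    """Linear Cq-vs-log10(quantity) calibration for one assay."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    @property
    def amplification_efficiency(self) -> float:
        """Per-cycle gain minus one; 1.0 for perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def cq(self, quantity: float) -> float:
        if quantity <= 0:
            raise ValueError("quantity must be positive")
        return self.intercept + self.slope * math.log10(quantity)

    def quantity(self, cq: float) -> float:
        """Invert the curve: quantity back-computed from a Cq value."""
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def save(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(
            f"slope\t{self.slope:.10g}\nintercept\t{self.intercept:.10g}\n"
            f"r_squared\t{self.r_squared:.10g}\n")

    @classmethod
    def load(cls, path) -> "StandardCurve":
        from pathlib import Path
        kv = dict(line.split("\t") for line in
                  Path(path).read_text().splitlines() if line.strip())
        return cls(slope=float(kv["slope"]), intercept=float(kv["intercept"]),
                   r_squared=float(kv.get("r_squared", 1.0)))


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: sample, assay (ECFP or neo), replicate index and Cq."""

    sample: str
    assay: str
    cq: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected {ASSAYS}")
        if self.cq <= 0:
            raise ValueError("cq must be positive")


def simulate_qpcr(quantities: Mapping[str, tuple[float, float]],
                  curve_ecfp: StandardCurve, curve_neo: StandardCurve,
                  noise_sd: float = 0.15, seed: int = 0,
                  n_replicates: int = 3) -> list[QpcrMeasurement]:
    """Generate triplicate Cq values for (ECFP, neo) template amounts.

    ``cq = intercept + slope * log10(amount) + N(0, noise_sd)``; Gaussian
    noise on Cq is the standard qPCR error structure.
    """
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasurement] = []
    for sample, (ecfp_amount, neo_amount) in quantities.items():
        for assay, curve, amount in (("ECFP", curve_ecfp, ecfp_amount),
                                     ("neo", curve_neo, neo_amount)):
            if amount <= 0:
                raise ValueError(
                    f"non-positive {assay} amount for sample {sample!r}")
            for rep in range(1, n_replicates + 1):
                cq = curve.cq(amount) + (rng.normal(0.0, noise_sd)
                                         if noise_sd > 0 else 0.0)
                out.append(QpcrMeasurement(sample, assay, float(cq), rep))
    return out


def fit_standard_curve(standards: Sequence[tuple[float, float]]
                       ) -> StandardCurve:
    """Ordinary least squares of Cq on log10(quantity)."""
    if len(standards) < 2:
        raise ValueError("at least 2 standard points are required")
    q = np.array([s[0] for s in standards], dtype=float)
    cq = np.array([s[1] for s in standards], dtype=float)
    if np.any(q <= 0):
        raise ValueError("standard quantities must be positive")
    if len(np.unique(q)) < 2:
        raise ValueError("at least 2 distinct standard quantities are required")
    res = stats.linregress(np.log10(q), cq)
    return StandardCurve(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def standard_dilution_series(curve: StandardCurve, noise_sd: float = 0.0,
                             seed: int = 0,
                             quantities: Sequence[float] = STANDARD_QUANTITIES_PG
                             ) -> list[tuple[float, float]]:
    """Simulate the plasmid dilution series (default: 50 fg to 5 ng)."""
    rng = np.random.default_rng(seed)
    return [(q, curve.cq(q) + (rng.normal(0.0, noise_sd) if noise_sd > 0
                               else 0.0))
            for q in quantities]


@dataclass(frozen=True)
class RelativeQuantity:
    sample: str
    ratios: tuple[float, ...]
    mean: float
    sd: float
    n: int


def relative_quantity(samples: Sequence[QpcrMeasurement],
                      curve_ecfp: StandardCurve,
                      curve_neo: StandardCurve
                      ) -> dict[str, RelativeQuantity]:
    """ECFP/neo quantity ratio per sample with triplicate mean +/- SD.

    Quantities are back-computed from the per-assay standard curves,
    ratioed replicate-by-replicate, then summarized (sample SD, n-1).
    """
    by_sample: dict[str, dict[str, dict[int, float]]] = {}
    for m in samples:
        by_sample.setdefault(m.sample, {}).setdefault(m.assay, {})[m.replicate] = m.cq

    out: dict[str, RelativeQuantity] = {}
    for sample, assays in by_sample.items():
        missing = [a for a in ASSAYS if a not in assays]
        if missing:
            raise ValueError(f"sample {sample!r} is missing assay(s): "
                             f"{', '.join(missing)}")
        reps = sorted(set(assays["ECFP"]) & set(assays["neo"]))
        if not reps:
            raise ValueError(f"sample {sample!r} has no paired replicates")
        ratios = tuple(
            curve_ecfp.quantity(assays["ECFP"][r])
            / curve_neo.quantity(assays["neo"][r])
            for r in reps
        )
        mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if len(ratios) >= 2 else math.nan
        out[sample] = RelativeQuantity(sample=sample, ratios=ratios,
                                       mean=mean, sd=sd, n=len(ratios))
    return out
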