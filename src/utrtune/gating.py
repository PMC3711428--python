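"""Gating chain and the translational-efficiency statistic.

The analysis reproduces the flow-cytometry workflow for engineered-UTR
reporters: dead cells are removed by forward/side scatter, cells are selected
in a narrow DsRed-Express window (1000 +/- 100 a.u. by default, 500 +/- 50 as
the alternative cut-off) so the trigger-protein dose is approximately
constant, and untransfected cells can be excluded below 100 a.u. DsRed.

The translational efficiency e of a construct is the ratio of the mean
reporter fluorescence (EGFP or ECFP, after compensation) in the presence of
the cognate RNA-binding protein to that with a non-cognate protein, computed
within the same gate.  Replicates (independent simulated experiments) are
summarized as mean +/- sample SD (n-1 denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_flow import DETECTORS, SCATTER

#: printed DsRed-Express analysis windows (center, halfwidth) in a.u.
DEFAULT_WINDOW = (1000.0, 100.0)
ALT_WINDOW = (500.0, 50.0)
#: DsRed threshold below which cells are considered untransfected
UNTRANSFECTED_THRESHOLD = 100.0
#: default scatter thresholds separating the dead-cell cluster
DEFAULT_FSC_MIN = 35_000.0
DEFAULT_SSC_MIN = 18_000.0


@dataclass(frozen=True)
class GateSpec:
    """One gate: a scatter cut, an inclusive window, or a minimum threshold.

    ``window`` keeps ``center - halfwidth <= v <= center + halfwidth``
    (bounds inclusive); ``min_threshold`` keeps ``v >= threshold``.
    """

    kind: str
    channel: str = "det695"
    center: float = 0.0
    halfwidth: float = 0.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("scatter", "window", "min_threshold"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.channel not in DETECTORS + SCATTER:
            raise ValueError(f"unknown channel {self.channel!r}")

    @classmethod
    def window(cls, center: float, halfwidth: float,
               channel: str = "det695") -> "GateSpec":
        return cls("window", channel=channel, center=center, halfwidth=halfwidth)

    @classmethod
    def min_threshold(cls, threshold: float,
                      channel: str = "det695") -> "GateSpec":
        return cls("min_threshold", channel=channel, threshold=threshold)

    def describe(self) -> str:
        if self.kind == "window":
            return f"{self.channel} {self.center:g}+/-{self.halfwidth:g}"
        if self.kind == "min_threshold":
            return f"{self.channel}>={self.threshold:g}"
        return "scatter"


def gate_scatter(events: pd.DataFrame, fsc_min: float = DEFAULT_FSC_MIN,
                 ssc_min: float = DEFAULT_SSC_MIN) -> pd.DataFrame:
    """Remove the low-scatter (dead-cell) cluster."""
    if fsc_min < 0 or ssc_min < 0:
        raise ValueError("scatter thresholds must be >= 0")
    if not len(events):
        return events
    keep = (events["fsc"] >= fsc_min) & (events["ssc"] >= ssc_min)
    return events.loc[keep]


def gate_window(events: pd.DataFrame, spec: GateSpec) -> pd.DataFrame:
    """Keep events whose channel value lies in the inclusive window."""
    if spec.kind != "window":
        raise ValueError(f"expected a window gate, got kind {spec.kind!r}")
    if spec.channel not in events.columns:
        raise ValueError(f"unknown channel {spec.channel!r} in event table")
    if not len(events):
        return events
    v = events[spec.channel]
    keep = (v >= spec.center - spec.halfwidth) & (v <= spec.center + spec.halfwidth)
    return events.loc[keep]


def gate_min(events: pd.DataFrame, spec: GateSpec) -> pd.DataFrame:
    """Keep events whose channel value is at or above the threshold."""
    if spec.kind != "min_threshold":
        raise ValueError(f"expected a min_threshold gate, got kind {spec.kind!r}")
    if spec.channel not in events.columns:
        raise ValueError(f"unknown channel {spec.channel!r} in event table")
    if not len(events):
        return events
    return events.loc[events[spec.channel] >= spec.threshold]


def apply_gate(events: pd.DataFrame, spec: GateSpec) -> pd.DataFrame:
    if spec.kind == "window":
        return gate_window(events, spec)
    if spec.kind == "min_threshold":
        return gate_min(events, spec)
    return gate_scatter(events)


@dataclass
class EfficiencyEstimate:
    """The efficiency statistic e with its gate and replicate summary."""

    e: float
    n_cognate: int = 0
    n_noncognate: int = 0
    gate: GateSpec | None = None
    channel: str = ""
    replicate_values: list[float] = field(default_factory=list)
    mean: float = math.nan
    sd: float = math.nan

    def __post_init__(self) -> None:
        if math.isnan(self.mean):
            self.mean = self.e


def estimate_efficiency(cognate: pd.DataFrame, noncognate: pd.DataFrame,
                        channel: str,
                        gate: GateSpec | None = None) -> EfficiencyEstimate:
    """Compute e = mean(reporter | cognate) / mean(reporter | non-cognate).

    ``channel`` is the compensated reporter detector (``det530`` for EGFP,
    ``det450`` for ECFP).  If ``gate`` is given, it is applied to both
    tables first; otherwise they are assumed pre-gated.
    """
    if channel not in cognate.columns or channel not in noncognate.columns:
        raise ValueError(f"unknown channel {channel!r} in event table")
    if gate is not None:
        cognate = apply_gate(cognate, gate)
        noncognate = apply_gate(noncognate, gate)
    if not len(cognate):
        raise ValueError("no events in the gated cognate condition")
    if not len(noncognate):
        raise ValueError("no events in the gated non-cognate condition")
    denom = float(noncognate[channel].mean())
    if denom == 0.0:
        raise ValueError("mean non-cognate signal is zero; e is undefined")
    e = float(cognate[channel].mean()) / denom
    return EfficiencyEstimate(e=e, n_cognate=len(cognate),
                              n_noncognate=len(noncognate), gate=gate,
                              channel=channel)


def summarize_replicates(estimates: Sequence[EfficiencyEstimate]
                         ) -> EfficiencyEstimate:
    """Mean and sample SD (n-1) of e over independent replicates.

    With a single replicate the mean is defined and the SD is reported as
    NaN (absent).
    """
    if not estimates:
        raise ValueError("cannot summarize an empty list of estimates")
    values = [est.e for est in estimates]
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else math.nan
    first = estimates[0]
    return EfficiencyEstimate(
        e=mean, n_cognate=sum(e.n_cognate for e in estimates),
        n_noncognate=sum(e.n_noncognate for e in estimates),
        gate=first.gate, channel=first.channel,
        replicate_values=values, mean=mean, sd=sd,
    )


@dataclass(frozen=True)
class CrosstalkEntry:
    construct: str
    e_single: float
    max_deviation: float
    criterion: float
    consistent: bool


def crosstalk_report(single: Mapping[str, EfficiencyEstimate],
                     co: Mapping[tuple[str, str], EfficiencyEstimate]
                     ) -> list[CrosstalkEntry]:
    """Check that co-transfection leaves each construct's e unchanged.

    For every construct present in both the single-reporter estimates and
    the co-transfection estimates, the maximum |e_co - e_single| over
    partners is compared against a two-standard-deviation criterion
    (2 * sqrt(sd_single^2 + sd_co^2), per the partner with the largest
    deviation); constructs within the criterion are flagged consistent.
    """
    overlap = {name for (name, _p) in co} & set(single)
    if not overlap:
        raise ValueError("no overlapping construct keys between single and "
                         "co-transfection estimates")
    report = []
    for name in sorted(overlap):
        base = single[name]
        worst_dev, worst_crit = 0.0, math.inf
        for (cname, _partner), est in co.items():
            if cname != name:
                continue
            dev = abs(est.e - base.e)
            sd_s = 0.0 if math.isnan(base.sd) else base.sd
            sd_c = 0.0 if math.isnan(est.sd) else est.sd
            crit = 2.0 * math.sqrt(sd_s ** 2 + sd_c ** 2)
            if dev >= worst_dev:
                worst_dev, worst_crit = dev, crit
        report.append(CrosstalkEntry(
            construct=name, e_single=base.e, max_deviation=worst_dev,
            criterion=worst_crit,
            consistent=bool(worst_dev <= max(worst_crit, 1e-12)),
        ))
    return report
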