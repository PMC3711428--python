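"""Synthetic flow-cytometry data for engineered-5'-UTR reporter experiments.

This module emulates the statistical structure of transient co-transfection
experiments in mammalian cells in which a fluorescent reporter (EGFP or ECFP)
carries a protein-binding RNA motif in its 5'-UTR and a trigger plasmid
expresses an RNA-binding protein (L7Ae, MS2 coat protein or S15) together with
IRES-coupled DsRed-Express.  The generator reproduces the features the
downstream analysis relies on:

* a broad log-normal total plasmid uptake shared by all plasmids in a mix,
  with a near-constant reporter:trigger copy ratio per cell;
* construct-specific translational repression: when the trigger protein is
  cognate to the 5'-UTR motif, reporter output is scaled by the construct's
  ground-truth efficiency ``e`` (ratio scale, 1 = no repression);
* IRES coupling, so DsRed-Express reports the per-cell trigger dose;
* 3-fluorophore -> 3-detector spectral spillover (450/40, 530/30, 695/40 nm
  detection), additive autofluorescence truncated at zero, and a low-scatter
  dead-cell cluster with inflated fluorescence dispersion.

Event tables are plain :class:`pandas.DataFrame` objects with columns
``fsc, ssc, det450, det530, det695`` plus generator-side ground-truth columns
(``viable`` and ``truth_*``) that an "observed" export strips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Constants: channels, fluorophores, cognate pairings, calibration
# --------------------------------------------------------------------------

DETECTORS = ("det450", "det530", "det695")
FLUOROPHORES = ("EGFP", "ECFP", "DsRed")
SCATTER = ("fsc", "ssc")
OBSERVED_COLUMNS = SCATTER + DETECTORS

#: detector in which each fluorophore is primarily measured
PRIMARY_DETECTOR = {"EGFP": "det530", "ECFP": "det450", "DsRed": "det695"}

MOTIFS = ("Kt", "dKt", "Kl", "Kl2", "MS2SL", "Fr15", "none")
TRIGGERS = ("L7Ae", "MS2CP", "S15", "none")

#: trigger protein that binds each 5'-UTR motif.  The defective kink-turn
#: (dKt) does not bind L7Ae in vitro, but its measured efficiency against the
#: L7Ae/MS2CP pair can exceed 1; it is therefore treated as "cognate" to L7Ae
#: so that its configured ground-truth efficiency (possibly > 1) is applied.
COGNATE = {"Kt": "L7Ae", "dKt": "L7Ae", "Kl": "L7Ae", "Kl2": "L7Ae",
           "MS2SL": "MS2CP", "Fr15": "S15", "none": None}

# a.u. calibration: DsRed gain of 1 a.u. per trigger-plasmid copy and a
# log-normal uptake with median 800 put the median DsRed of transfected cells
# at ~800 a.u., so both analysis windows (1000 +/- 100 and 500 +/- 50) sit
# on-distribution (each captures ~7-8% of transfected events).
DSRED_GAIN = 1.0
REPORTER_GAIN = {"EGFP": 5.0, "ECFP": 5.0}

# viable/dead forward- and side-scatter clusters (mean, sd)
VIABLE_SCATTER = {"fsc": (60_000.0, 8_000.0), "ssc": (35_000.0, 7_000.0)}
DEAD_SCATTER = {"fsc": (20_000.0, 6_000.0), "ssc": (10_000.0, 4_000.0)}

#: multiplicative log-normal measurement dispersion on fluorophore abundance;
#: dead cells get 3x the log-sd.
MEASUREMENT_SIGMA = 0.1
DEAD_DISPERSION_FACTOR = 3.0


def default_spillover_matrix() -> np.ndarray:
    """Ground-truth spillover, rows = fluorophores, columns = detectors.

    Rows are normalized to 1 at the primary detector.  Off-diagonal values
    are typical small cross-detection fractions for CFP/GFP/RFP-class
    fluorophores on 450/40, 530/30 and 695/40 nm detectors.
    """
    return np.array(
        [
            # det450, det530, det695
            [0.02, 1.00, 0.03],  # EGFP  (primary det530)
            [1.00, 0.25, 0.01],  # ECFP  (primary det450)
            [0.01, 0.08, 1.00],  # DsRed (primary det695)
        ]
    )


def identity_spillover_matrix() -> np.ndarray:
    """Spillover with each fluorophore seen only in its primary detector."""
    m = np.zeros((3, 3))
    for i, f in enumerate(FLUOROPHORES):
        m[i, DETECTORS.index(PRIMARY_DETECTOR[f])] = 1.0
    return m


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstructSpec:
    """A 5'-UTR reporter design and its simulation ground truth.

    Parameters
    ----------
    name
        Text label, e.g. ``"18 nt-3x Kl-ECFP"``.
    motif
        RNA motif in the 5'-UTR (``Kt``, ``dKt``, ``Kl``, ``Kl2``, ``MS2SL``,
        ``Fr15`` or ``none``).
    distance_nt
        1-based transcript coordinate of the first motif base (distance from
        the +1 transcription start of the CMV promoter).
    copies
        Number of tandem motif copies (0 only for motif-free or defective
        controls).
    reporter
        ``EGFP`` or ``ECFP``.
    true_efficiency
        Ground-truth translational efficiency e (ratio scale; 1 = no
        repression; defective-motif controls may exceed 1).
    """

    name: str
    motif: str = "none"
    distance_nt: int = 32
    copies: int = 0
    reporter: str = "EGFP"
    true_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; expected one of {MOTIFS}")
        if self.reporter not in REPORTER_GAIN:
            raise ValueError(f"unknown reporter {self.reporter!r}")
        if self.distance_nt <= 0:
            raise ValueError("distance_nt must be a positive 1-based coordinate")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if self.copies == 0 and self.motif not in ("none", "dKt"):
            raise ValueError(
                f"copies = 0 is only valid for motif-free or defective (dKt) "
                f"controls, not motif {self.motif!r}"
            )
        if self.true_efficiency < 0:
            raise ValueError("true_efficiency must be >= 0")

    def e_effective(self, trigger_protein: str) -> float:
        """Efficiency applied in the presence of ``trigger_protein``.

        The configured ground truth applies only when the trigger is cognate
        to the motif; any non-cognate (or absent) trigger leaves translation
        unrepressed (e = 1).
        """
        if trigger_protein not in TRIGGERS:
            raise ValueError(
                f"unknown motif/protein pairing: motif {self.motif!r} with "
                f"trigger {trigger_protein!r}"
            )
        if COGNATE[self.motif] == trigger_protein and trigger_protein != "none":
            return self.true_efficiency
        return 1.0


@dataclass(frozen=True)
class TransfectionMix:
    """Plasmid masses for one transfection.

    Default double-transfection masses are 0.1 ug reporter + 0.5 ug trigger;
    the triple (two-reporter) format uses 0.1 + 0.1 + 0.3 ug.  Per cell, all
    plasmids share one log-normal total-uptake factor; the reporter:trigger
    copy ratio equals the mass ratio up to a log-normal dispersion of sd
    ``copy_ratio_dispersion``.
    """

    reporter_masses: tuple[tuple[ConstructSpec, float], ...]
    trigger_mass: float = 0.5
    trigger_protein: str = "none"
    copy_ratio_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.trigger_protein not in TRIGGERS:
            raise ValueError(f"unknown trigger protein {self.trigger_protein!r}")
        if self.trigger_mass < 0:
            raise ValueError("trigger_mass must be >= 0")
        for spec, mass in self.reporter_masses:
            if mass < 0:
                raise ValueError(f"negative mass {mass} for construct {spec.name!r}")
            # raises on unknown pairing
            spec.e_effective(self.trigger_protein)
        if self.copy_ratio_dispersion < 0:
            raise ValueError("copy_ratio_dispersion must be >= 0")

    def copy_ratios(self) -> dict[str, float]:
        """Mean reporter:trigger copy-number ratio per construct."""
        if self.trigger_mass == 0:
            raise ValueError("trigger_mass must be positive to define copy ratios")
        return {spec.name: mass / self.trigger_mass
                for spec, mass in self.reporter_masses}


def double_transfection(construct: ConstructSpec, trigger_protein: str,
                        reporter_mass: float = 0.1, trigger_mass: float = 0.5,
                        copy_ratio_dispersion: float = 0.1) -> TransfectionMix:
    """The standard single-reporter mix (0.1 ug reporter + 0.5 ug trigger)."""
    return TransfectionMix(((construct, reporter_mass),), trigger_mass,
                           trigger_protein, copy_ratio_dispersion)


def triple_transfection(reporter_a: ConstructSpec, reporter_b: ConstructSpec,
                        trigger_protein: str, reporter_mass: float = 0.1,
                        trigger_mass: float = 0.3,
                        copy_ratio_dispersion: float = 0.1) -> TransfectionMix:
    """The two-reporter mix (0.1 ug each reporter + 0.3 ug trigger)."""
    if reporter_a.reporter == reporter_b.reporter:
        raise ValueError(
            f"two-reporter mixes need one EGFP-class and one ECFP-class "
            f"construct; got {reporter_a.reporter} twice"
        )
    return TransfectionMix(((reporter_a, reporter_mass),
                            (reporter_b, reporter_mass)),
                           trigger_mass, trigger_protein, copy_ratio_dispersion)


@dataclass(frozen=True)
class SimulationConfig:
    """Noise, uptake and instrument parameters for one simulated acquisition.

    ``uptake_lognormal_params`` is (location, scale) of the log-normal total
    uptake in trigger-copy units (median exp(location) ~ 800 keeps the
    printed DsRed analysis windows on-distribution).  ``autofluorescence``
    maps each detector to an additive Gaussian (mean, sd) in a.u., truncated
    at zero.  In ``hill`` repression mode the per-cell efficiency relaxes to
    1 at low trigger dose with midpoint ``hill_params[0]`` (a.u.) and Hill
    coefficient ``hill_params[1]``; the default midpoint (50 a.u.) is far
    below both DsRed analysis windows so the measured e sits on the plateau.
    """

    n_events: int = 200_000
    uptake_lognormal_params: tuple[float, float] = (float(np.log(800.0)), 1.0)
    dead_fraction: float = 0.1
    untransfected_fraction: float = 0.0
    autofluorescence: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {d: (2.0, 2.0) for d in DETECTORS})
    spillover_truth: np.ndarray = field(default_factory=default_spillover_matrix)
    repression_mode: str = "constant_e"
    hill_params: tuple[float, float] = (50.0, 2.0)
    measurement_sigma: float = MEASUREMENT_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not 0 <= self.dead_fraction < 1:
            raise ValueError("dead_fraction must be in [0, 1)")
        if not 0 <= self.untransfected_fraction < 1:
            raise ValueError("untransfected_fraction must be in [0, 1)")
        if self.repression_mode not in ("constant_e", "hill"):
            raise ValueError(f"unknown repression_mode {self.repression_mode!r}")
        m = np.asarray(self.spillover_truth, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("spillover_truth must be a 3x3 matrix")
        object.__setattr__(self, "spillover_truth", m)

    def noiseless(self) -> "SimulationConfig":
        """Copy with autofluorescence, dispersion and dead cells switched off."""
        return replace(
            self,
            dead_fraction=0.0,
            untransfected_fraction=0.0,
            autofluorescence={d: (0.0, 0.0) for d in DETECTORS},
            spillover_truth=identity_spillover_matrix(),
            measurement_sigma=0.0,
        )


# --------------------------------------------------------------------------
# Event generation
# --------------------------------------------------------------------------


def _empty_events(mix: TransfectionMix | None = None) -> pd.DataFrame:
    cols = list(OBSERVED_COLUMNS) + ["viable", "truth_untransfected",
                                     "truth_trigger_copies"]
    if mix is not None:
        cols += [f"truth_reporter_copies_{spec.name}"
                 for spec, _ in mix.reporter_masses]
    return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})


def simulate_cotransfection(config: SimulationConfig,
                            mix: TransfectionMix) -> pd.DataFrame:
    """Simulate one acquisition of a transfected-cell population.

    Returns a table of exactly ``config.n_events`` rows with observed columns
    ``fsc, ssc, det450, det530, det695`` plus ground-truth columns ``viable``,
    ``truth_untransfected``, ``truth_trigger_copies`` and one
    ``truth_reporter_copies_<name>`` per construct.  Provenance (seed, copy
    ratios, repression mode) is recorded in ``DataFrame.attrs``.

    The randomness stream is independent of the trigger-protein identity, so
    two runs differing only in the trigger (cognate vs non-cognate) see
    identical per-cell uptakes and noise draws.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    loc, scale = config.uptake_lognormal_params

    # shared total-uptake factor, in trigger-copy units
    trigger_copies = rng.lognormal(mean=loc, sigma=scale, size=n)

    # per-construct reporter copies: constant mass ratio x log-normal jitter
    ratios = mix.copy_ratios()
    reporter_copies: dict[str, np.ndarray] = {}
    for spec, _mass in mix.reporter_masses:
        eps = rng.normal(0.0, mix.copy_ratio_dispersion, size=n)
        reporter_copies[spec.name] = ratios[spec.name] * trigger_copies * np.exp(eps)

    dead = rng.random(n) < config.dead_fraction
    untransfected = rng.random(n) < config.untransfected_fraction
    if config.untransfected_fraction > 0:
        trigger_copies = np.where(untransfected, 0.0, trigger_copies)
        for name in reporter_copies:
            reporter_copies[name] = np.where(untransfected, 0.0,
                                             reporter_copies[name])

    # scatter: viable vs dead clusters, truncated at zero
    fsc = np.where(dead,
                   rng.normal(*DEAD_SCATTER["fsc"], size=n),
                   rng.normal(*VIABLE_SCATTER["fsc"], size=n))
    ssc = np.where(dead,
                   rng.normal(*DEAD_SCATTER["ssc"], size=n),
                   rng.normal(*VIABLE_SCATTER["ssc"], size=n))
    fsc = np.maximum(fsc, 0.0)
    ssc = np.maximum(ssc, 0.0)

    # fluorophore abundances (a.u. before spillover)
    abundance = np.zeros((n, 3))
    dsred_au = DSRED_GAIN * trigger_copies
    for spec, _mass in mix.reporter_masses:
        e_eff = _efficiency_per_cell(spec, mix.trigger_protein, dsred_au, config)
        col = FLUOROPHORES.index(spec.reporter)
        abundance[:, col] += (REPORTER_GAIN[spec.reporter]
                              * reporter_copies[spec.name] * e_eff)
    abundance[:, FLUOROPHORES.index("DsRed")] += dsred_au

    # multiplicative measurement dispersion; 3x log-sd for dead cells
    if config.measurement_sigma > 0:
        sigma = np.where(dead,
                         DEAD_DISPERSION_FACTOR * config.measurement_sigma,
                         config.measurement_sigma)
        abundance *= np.exp(rng.normal(0.0, 1.0, size=(n, 3)) * sigma[:, None])

    # spectral mixing + truncated-Gaussian autofluorescence
    det = abundance @ config.spillover_truth
    for j, d in enumerate(DETECTORS):
        mu, sd = config.autofluorescence.get(d, (0.0, 0.0))
        if mu != 0.0 or sd != 0.0:
            det[:, j] += np.maximum(rng.normal(mu, sd, size=n), 0.0)

    table = pd.DataFrame({"fsc": fsc, "ssc": ssc})
    for j, d in enumerate(DETECTORS):
        table[d] = det[:, j]
    table["viable"] = ~dead
    table["truth_untransfected"] = untransfected
    table["truth_trigger_copies"] = trigger_copies
    for name, copies in reporter_copies.items():
        table[f"truth_reporter_copies_{name}"] = copies
    if n == 0:
        table = _empty_events(mix)

    table.attrs["seed"] = config.seed
    table.attrs["copy_ratio"] = ratios
    table.attrs["trigger_protein"] = mix.trigger_protein
    table.attrs["repression_mode"] = config.repression_mode
    return table


def _efficiency_per_cell(spec: ConstructSpec, trigger_protein: str,
                         trigger_dose_au: np.ndarray,
                         config: SimulationConfig) -> np.ndarray | float:
    """Per-cell effective efficiency under the configured repression mode."""
    e = spec.e_effective(trigger_protein)
    if config.repression_mode == "constant_e" or e == 1.0:
        return e
    # hill: repression deepens with trigger dose, e -> 1 at zero dose
    k, h = config.hill_params
    occupancy = trigger_dose_au ** h / (k ** h + trigger_dose_au ** h)
    return 1.0 + (e - 1.0) * occupancy


def simulate_single_color_controls(config: SimulationConfig,
                                   fluorophore: str) -> pd.DataFrame:
    """Simulate a control population expressing a single fluorophore.

    Used to estimate the spillover matrix.  Only the named fluorophore has
    nonzero abundance; detector signals follow ``config.spillover_truth``
    plus autofluorescence.
    """
    if fluorophore not in FLUOROPHORES:
        raise ValueError(f"unknown fluorophore {fluorophore!r}; "
                         f"expected one of {FLUOROPHORES}")
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    loc, scale = config.uptake_lognormal_params
    copies = rng.lognormal(mean=loc, sigma=scale, size=n)
    gain = DSRED_GAIN if fluorophore == "DsRed" else REPORTER_GAIN[fluorophore]

    dead = rng.random(n) < config.dead_fraction
    fsc = np.maximum(np.where(dead, rng.normal(*DEAD_SCATTER["fsc"], size=n),
                              rng.normal(*VIABLE_SCATTER["fsc"], size=n)), 0.0)
    ssc = np.maximum(np.where(dead, rng.normal(*DEAD_SCATTER["ssc"], size=n),
                              rng.normal(*VIABLE_SCATTER["ssc"], size=n)), 0.0)

    abundance = np.zeros((n, 3))
    abundance[:, FLUOROPHORES.index(fluorophore)] = gain * copies
    if config.measurement_sigma > 0:
        sigma = np.where(dead, DEAD_DISPERSION_FACTOR * config.measurement_sigma,
                         config.measurement_sigma)
        abundance *= np.exp(rng.normal(0.0, 1.0, size=(n, 3)) * sigma[:, None])

    det = abundance @ config.spillover_truth
    for j, d in enumerate(DETECTORS):
        mu, sd = config.autofluorescence.get(d, (0.0, 0.0))
        if mu != 0.0 or sd != 0.0:
            det[:, j] += np.maximum(rng.normal(mu, sd, size=n), 0.0)

    table = pd.DataFrame({"fsc": fsc, "ssc": ssc})
    for j, d in enumerate(DETECTORS):
        table[d] = det[:, j]
    table["viable"] = ~dead
    table["truth_untransfected"] = np.zeros(n, dtype=bool)
    table["truth_trigger_copies"] = copies
    if n == 0:
        table = _empty_events()
    table.attrs["seed"] = config.seed
    table.attrs["fluorophore"] = fluorophore
    return table


def simulate_mock(config: SimulationConfig) -> pd.DataFrame:
    """Untransfected (mock) cells: autofluorescence and scatter only.

    The per-channel mean of a mock acquisition is the background estimate
    the compensation step can subtract before spillover correction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    dead = rng.random(n) < config.dead_fraction
    fsc = np.maximum(np.where(dead, rng.normal(*DEAD_SCATTER["fsc"], size=n),
                              rng.normal(*VIABLE_SCATTER["fsc"], size=n)), 0.0)
    ssc = np.maximum(np.where(dead, rng.normal(*DEAD_SCATTER["ssc"], size=n),
                              rng.normal(*VIABLE_SCATTER["ssc"], size=n)), 0.0)
    table = pd.DataFrame({"fsc": fsc, "ssc": ssc})
    for d in DETECTORS:
        mu, sd = config.autofluorescence.get(d, (0.0, 0.0))
        if mu != 0.0 or sd != 0.0:
            table[d] = np.maximum(rng.normal(mu, sd, size=n), 0.0)
        else:
            table[d] = np.zeros(n)
    table["viable"] = ~dead
    table["truth_untransfected"] = np.ones(n, dtype=bool)
    table["truth_trigger_copies"] = np.zeros(n)
    if n == 0:
        table = _empty_events()
    table.attrs["seed"] = config.seed
    return table


def simulate_triple_transfection(config: SimulationConfig,
                                 mix: TransfectionMix) -> pd.DataFrame:
    """Simulate the two-reporter (triple-transfection) format.

    Requires exactly two reporter constructs, one EGFP-class and one
    ECFP-class.  An untransfected subpopulation (``config.
    untransfected_fraction``) carries no plasmid and is identifiable by
    near-zero DsRed (<100 a.u. in the analysis chain).
    """
    if len(mix.reporter_masses) != 2:
        raise ValueError("triple transfection requires exactly two reporter "
                         "constructs")
    a, b = (spec for spec, _ in mix.reporter_masses)
    if a.reporter == b.reporter:
        raise ValueError(
            f"the two reporters must use distinct fluorophores; both are "
            f"{a.reporter}"
        )
    return simulate_cotransfection(config, mix)


# --------------------------------------------------------------------------
# Event-table I/O: CSV round trip and read-only FCS ingestion
# --------------------------------------------------------------------------


def write_events_csv(events: pd.DataFrame, path: str | Path,
                     observed_only: bool = False) -> None:
    """Write an event table as CSV (UTF-8, '.' decimal).

    With ``observed_only`` the generator-side truth columns (``viable`` and
    any ``truth_*``) are stripped, emulating what an instrument exports.
    """
    missing = [c for c in OBSERVED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing required columns: {missing}")
    out = events
    if observed_only:
        out = events[[c for c in events.columns
                      if c in OBSERVED_COLUMNS]]
    out.to_csv(path, index=False, float_format="%.10g")


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read an event-table CSV, validating the observed-column schema."""
    table = pd.read_csv(path)
    missing = [c for c in OBSERVED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required event columns: {', '.join(missing)}"
        )
    return table


def read_events_fcs(path: str | Path,
                    channel_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 file (float data) into an event table.

    ``channel_map`` maps FCS short channel names ($PnN) to the canonical
    columns (``fsc``, ``ssc``, ``det450``, ``det530``, ``det695``); channels
    already carrying canonical names need no map.  Unmapped channels are
    ignored.  Only list-mode single-precision ('F') or double-precision
    ('D') data are supported, which covers files exported by modern
    instruments and analysis software.
    """
    raw = Path(path).read_bytes()
    version = raw[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")

    def _offset(a: int, b: int) -> int:
        return int(raw[a:b].decode("ascii").strip() or 0)

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)

    text = raw[text_start:text_end + 1].decode("utf-8", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    keywords = {parts[i].strip().upper(): parts[i + 1]
                for i in range(0, len(parts) - 1, 2)}

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").strip().upper()
    if datatype not in ("F", "D"):
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r} "
                         "(only floating-point FCS data are readable)")
    byteord = keywords.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    if data_start == 0:
        data_start = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])

    names = [keywords.get(f"$P{i}N", f"P{i}").strip() for i in range(1, n_par + 1)]
    itemsize = 4 if datatype == "F" else 8
    count = n_par * n_tot
    data = np.frombuffer(raw, dtype=f"{endian}f{itemsize}",
                         count=count, offset=data_start)
    values = data.reshape(n_tot, n_par).astype(float)

    channel_map = dict(channel_map or {})
    columns: dict[str, np.ndarray] = {}
    for i, raw_name in enumerate(names):
        target = channel_map.get(raw_name, raw_name)
        if target in OBSERVED_COLUMNS:
            columns[target] = values[:, i]
    missing = [c for c in DETECTORS if c not in columns]
    if missing:
        known = ", ".join(names)
        raise ValueError(
            f"{path}: could not map FCS channels ({known}) onto required "
            f"detector columns {missing}; supply a channel_map"
        )
    for c in SCATTER:
        columns.setdefault(c, np.zeros(n_tot))
    return pd.DataFrame({c: columns[c] for c in OBSERVED_COLUMNS})
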