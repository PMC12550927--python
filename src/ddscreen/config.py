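"""Assay configuration and screening cutoffs.

The quadruplex assay measures SMN1, RPP30, SMN2, and TREC in one droplet
digital PCR well. Volume constants drive two unit systems:

* reaction units — copies/µL of the 20 µL PCR well, obtained directly from
  Poisson statistics on droplet counts;
* blood units — copies/µL of whole blood on the dried-blood-spot card,
  obtained through the punch/elution/input volume chain
  (copies per well / input µL) × (elution µL / blood µL per punch).

``AssayConfig`` holds both the volume chain and the fluorescence-cluster
parameters used by the synthetic droplet generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping

from .errors import ConfigError

#: Assay targets in channel order (channel 1..4 = FAM, HEX, Cy5, Cy5.5).
TARGETS = ("SMN1", "RPP30", "SMN2", "TREC")

DEFAULT_CHANNEL_MAP: dict[str, int] = {"SMN1": 1, "RPP30": 2, "SMN2": 3, "TREC": 4}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero toward +inf (half-up), e.g. 0.95 -> 1.0."""
    scale = 10.0 ** ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass
class AssayConfig:
    """Volumes, droplet geometry, and synthetic fluorescence-cluster model.

    Volumes are µL except ``droplet_volume_nl`` (nL). Amplitude parameters
    are per-channel tuples (channel 1..4) in arbitrary fluorescence units.

    ``rain_fraction`` is the proportion of template-containing droplets whose
    amplitude falls between the clusters (partial amplification);
    ``false_positive_rate`` is the per-droplet probability that an empty
    droplet shows a positive-cluster amplitude.
    """

    droplet_volume_nl: float = 0.85
    droplets_per_well: int = 20_000
    well_volume_ul: float = 20.0
    input_dna_volume_ul: float = 8.0
    elution_volume_ul: float = 50.0
    blood_per_punch_ul: float = 3.0
    channel_map: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP)
    )
    negative_amplitude_mean: tuple[float, ...] = (1000.0,) * 4
    negative_amplitude_sd: tuple[float, ...] = (150.0,) * 4
    positive_amplitude_mean: tuple[float, ...] = (9000.0,) * 4
    positive_amplitude_sd: tuple[float, ...] = (300.0,) * 4
    rain_fraction: float = 0.01
    false_positive_rate: float = 0.0
    run_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "droplet_volume_nl",
            "well_volume_ul",
            "input_dna_volume_ul",
            "elution_volume_ul",
            "blood_per_punch_ul",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.droplets_per_well <= 0:
            raise ConfigError("droplets_per_well must be > 0")
        if set(self.channel_map) != set(TARGETS):
            raise ConfigError(f"channel_map must map exactly the targets {TARGETS}")
        if sorted(self.channel_map.values()) != [1, 2, 3, 4]:
            raise ConfigError("channel_map must assign channels 1..4 uniquely")
        for ch in range(4):
            if self.positive_amplitude_mean[ch] <= self.negative_amplitude_mean[ch]:
                raise ConfigError(
                    f"positive amplitude mean must exceed negative (channel {ch + 1})"
                )
        if not 0 <= self.rain_fraction < 0.5:
            raise ConfigError("rain_fraction must be in [0, 0.5)")
        if not 0 <= self.false_positive_rate < 1:
            raise ConfigError("false_positive_rate must be in [0, 1)")
        if self.run_effect_sd < 0:
            raise ConfigError("run_effect_sd must be >= 0")

    # -- unit chain ------------------------------------------------------

    @property
    def blood_factor(self) -> float:
        """copies/µL blood per copy-per-well: (1/input) × (elution/blood)."""
        return (1.0 / self.input_dna_volume_ul) * (
            self.elution_volume_ul / self.blood_per_punch_ul
        )

    def channel_of(self, target: str) -> int:
        return self.channel_map[target]

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["channel_map"] = dict(self.channel_map)
        for key in (
            "negative_amplitude_mean",
            "negative_amplitude_sd",
            "positive_amplitude_mean",
            "positive_amplitude_sd",
        ):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AssayConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown AssayConfig keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in (
            "negative_amplitude_mean",
            "negative_amplitude_sd",
            "positive_amplitude_mean",
            "positive_amplitude_sd",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class ScreenCutoffs:
    """Decision cutoffs for the screening engine.

    ``rpp30_min_blood``: minimum reference-gene loading (copies/µL blood) a
    specimen must strictly exceed to be qualified — equivalent to the
    manufacturer's 100 copies/µL-reaction lower loading bound after unit
    conversion. ``trec_cutoff_blood``: TREC values strictly above this are
    screen-negative; at or below triggers the re-punch/retest/recall flag.
    ``min_gestational_weeks``: the TREC cutoff is validated for newborns at
    or above this gestational age only.
    """

    rpp30_min_blood: float = 4200.0
    trec_cutoff_blood: float = 57.0
    min_gestational_weeks: float = 34.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigError(f"{f.name} must be > 0")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreenCutoffs":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ScreenCutoffs keys: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass
class CohortModel:
    """Population model for synthetic screening cohorts.

    Copy-number frequencies default to the SMN1/SMN2 distribution observed
    in a screening population of 1867 newborns. The TREC distribution is
    lognormal with median 180 copies/µL blood and log-sd 0.586, placing the
    2.5th percentile near 57 copies/µL blood; RPP30 loading is lognormal
    with median 15,000 copies/µL blood so nearly all specimens qualify.
    """

    smn1_frequencies: dict[int, float] = field(
        default_factory=lambda: {1: 0.023, 2: 0.914, 3: 0.060, 4: 0.002, 5: 0.001}
    )
    smn2_frequencies: dict[int, float] = field(
        default_factory=lambda: {
            0: 0.048,
            1: 0.357,
            2: 0.557,
            3: 0.031,
            4: 0.003,
            5: 0.003,
            6: 0.001,
        }
    )
    trec_median: float = 180.0
    trec_log_sd: float = 0.586
    rpp30_median: float = 15_000.0
    rpp30_log_sd: float = 0.5
    preterm_fraction: float = 55.0 / 1867.0

    def __post_init__(self) -> None:
        for name, freqs in (
            ("smn1_frequencies", self.smn1_frequencies),
            ("smn2_frequencies", self.smn2_frequencies),
        ):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total!r})")
            if any(cn < 0 or p < 0 for cn, p in freqs.items()):
                raise ConfigError(f"{name} must have non-negative keys and values")
        if not 0 <= self.preterm_fraction <= 1:
            raise ConfigError("preterm_fraction must be in [0, 1]")
        for name in ("trec_median", "trec_log_sd", "rpp30_median", "rpp30_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "smn1_frequencies": dict(self.smn1_frequencies),
            "smn2_frequencies": dict(self.smn2_frequencies),
            "trec_median": self.trec_median,
            "trec_log_sd": self.trec_log_sd,
            "rpp30_median": self.rpp30_median,
            "rpp30_log_sd": self.rpp30_log_sd,
            "preterm_fraction": self.preterm_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortModel":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown CohortModel keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("smn1_frequencies", "smn2_frequencies"):
            if key in kwargs:
                kwargs[key] = {int(k): float(v) for k, v in kwargs[key].items()}
        return cls(**kwargs)
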