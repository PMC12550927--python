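"""Synthetic quadruplex ddPCR data: wells, replicate series, dilutions, cohorts.

The generator emulates the physics the pipeline must invert. For each target
the expected copies per well is derived from the sample's blood-unit
concentration by the same volume chain the quantification module uses
(guaranteeing round-trip consistency); the total molecule count is Poisson,
molecules are assigned to droplets multinomially, and each droplet's
fluorescence amplitude in the target's channel is drawn from the positive
Gaussian cluster if it contains at least one molecule, else from the
negative cluster. Rain (partial amplification) moves a fraction of
template-containing droplets to a uniform amplitude between the cluster
means; optional false positives move empty droplets to the positive
cluster. Per-droplet ground-truth occupancy labels are recorded so droplet
calling can be tested against an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .config import AssayConfig, CohortModel, TARGETS
from .errors import ConfigError, SaturationError
from .quantify import blood_to_copies_per_well

#: Largest resolvable load: beyond ~10 copies/droplet essentially every
#: droplet is positive and the Poisson inversion is undefined.
SATURATION_COPIES_PER_DROPLET = 10.0


class Role(str, Enum):
    NEWBORN = "newborn"
    BLANK = "blank"
    PROFICIENCY = "proficiency"
    PATIENT = "patient"


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth state of one specimen (simulation input)."""

    smn1_cn: int = 2
    smn2_cn: int = 2
    trec_blood: float = 180.0  # copies/µL blood
    rpp30_blood: float = 15_000.0  # copies/µL blood
    gestational_age_weeks: float = 39.0
    role: Role = Role.NEWBORN
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.smn1_cn < 0 or self.smn2_cn < 0:
            raise ConfigError("copy numbers must be >= 0")
        if self.trec_blood < 0 or self.rpp30_blood < 0:
            raise ConfigError("blood concentrations must be >= 0")
        if self.role is Role.BLANK and any(
            v != 0 for v in (self.smn1_cn, self.smn2_cn, self.trec_blood, self.rpp30_blood)
        ):
            raise ConfigError("blank role requires all targets at 0")

    def blood_concentrations(self) -> dict[str, float]:
        """Per-target copies/µL blood implied by the truth state.

        Gene targets scale with the genome concentration, which RPP30 fixes
        at rpp30_blood / 2 genomes-worth per µL blood.
        """
        genome = self.rpp30_blood / 2.0
        return {
            "SMN1": self.smn1_cn * genome,
            "SMN2": self.smn2_cn * genome,
            "RPP30": self.rpp30_blood,
            "TREC": self.trec_blood,
        }


def blank_truth(sample_id: str = "blank") -> SampleTruth:
    return SampleTruth(
        smn1_cn=0,
        smn2_cn=0,
        trec_blood=0.0,
        rpp30_blood=0.0,
        role=Role.BLANK,
        sample_id=sample_id,
    )


@dataclass
class DropletWell:
    """Per-droplet amplitudes of one well (rows = droplets, cols = channels 1..4)."""

    sample_id: str
    well_id: str
    amplitudes: np.ndarray
    truth_labels: Optional[np.ndarray] = None  # bool, same shape: contains template
    run_id: Optional[str] = None

    @property
    def accepted_events(self) -> int:
        return int(self.amplitudes.shape[0])

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2 or self.amplitudes.shape[1] != 4:
            raise ConfigError("amplitudes must be an (n_droplets, 4) matrix")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels, dtype=bool)
            if self.truth_labels.shape != self.amplitudes.shape:
                raise ConfigError("truth_labels shape must match amplitudes")


def _rng(cfg: AssayConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def expected_copies_per_well(truth: SampleTruth, cfg: AssayConfig) -> dict[str, float]:
    """Expected template molecules per well for each target."""
    return {
        t: blood_to_copies_per_well(c, cfg)
        for t, c in truth.blood_concentrations().items()
    }


def simulate_well(
    truth: SampleTruth,
    cfg: AssayConfig,
    rng: Optional[np.random.Generator] = None,
    well_id: str = "A01",
    loading_factor: float = 1.0,
) -> DropletWell:
    """Simulate one quadruplex well for a sample.

    ``loading_factor`` multiplies all target concentrations (used for
    run-level loading shifts in replicate series).

    Raises
    ------
    SaturationError
        If a target's expected load exceeds the resolvable range
        (10 × droplets_per_well copies per well).
    """
    rng = _rng(cfg, rng)
    n = cfg.droplets_per_well
    # droplets sample only their own volume of the well
    sampled_fraction = n * cfg.droplet_volume_nl * 1e-3 / cfg.well_volume_ul

    amplitudes = np.empty((n, 4), dtype=float)
    labels = np.zeros((n, 4), dtype=bool)
    for target in TARGETS:
        ch = cfg.channel_of(target) - 1
        copies_well = expected_copies_per_well(truth, cfg)[target] * loading_factor
        if copies_well > SATURATION_COPIES_PER_DROPLET * n:
            raise SaturationError(
                f"{target}: expected {copies_well:.0f} copies/well exceeds the "
                f"resolvable range for {n} droplets"
            )
        total = int(rng.poisson(copies_well * sampled_fraction))
        if total > 0:
            counts = rng.multinomial(total, np.full(n, 1.0 / n))
            occupied = counts > 0
        else:
            occupied = np.zeros(n, dtype=bool)
        labels[:, ch] = occupied

        amp = rng.normal(
            cfg.negative_amplitude_mean[ch], cfg.negative_amplitude_sd[ch], size=n
        )
        pos_idx = np.flatnonzero(occupied)
        if pos_idx.size:
            amp[pos_idx] = rng.normal(
                cfg.positive_amplitude_mean[ch],
                cfg.positive_amplitude_sd[ch],
                size=pos_idx.size,
            )
            if cfg.rain_fraction > 0:
                rain = pos_idx[rng.random(pos_idx.size) < cfg.rain_fraction]
                amp[rain] = rng.uniform(
                    cfg.negative_amplitude_mean[ch],
                    cfg.positive_amplitude_mean[ch],
                    size=rain.size,
                )
        if cfg.false_positive_rate > 0:
            empty_idx = np.flatnonzero(~occupied)
            fp = empty_idx[rng.random(empty_idx.size) < cfg.false_positive_rate]
            amp[fp] = rng.normal(
                cfg.positive_amplitude_mean[ch],
                cfg.positive_amplitude_sd[ch],
                size=fp.size,
            )
        amplitudes[:, ch] = amp

    return DropletWell(
        sample_id=truth.sample_id,
        well_id=well_id,
        amplitudes=amplitudes,
        truth_labels=labels,
    )


def simulate_replicates(
    truth: SampleTruth,
    cfg: AssayConfig,
    n_within: int,
    n_runs: int,
    rng: Optional[np.random.Generator] = None,
    run_effect_sd: Optional[float] = None,
) -> list[DropletWell]:
    """Replicate wells for precision studies: ``n_within`` wells × ``n_runs`` runs.

    An optional multiplicative lognormal run effect (sd on the log scale)
    shifts all target loadings of a run together, letting between-run
    variability exceed within-run Poisson noise. Off (0) by default.
    """
    if n_within < 1 or n_runs < 1:
        raise ConfigError("n_within and n_runs must be >= 1")
    rng = _rng(cfg, rng)
    sd = cfg.run_effect_sd if run_effect_sd is None else run_effect_sd
    wells = []
    for run in range(1, n_runs + 1):
        factor = float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0
        for rep in range(1, n_within + 1):
            well = simulate_well(
                truth,
                cfg,
                rng=rng,
                well_id=f"{truth.sample_id}-run{run}-w{rep:02d}",
                loading_factor=factor,
            )
            well.run_id = f"run{run}"
            wells.append(well)
    return wells


def simulate_dilution_series(
    top_blood_conc: float,
    levels: int,
    replicates: int,
    cfg: AssayConfig,
    rng: Optional[np.random.Generator] = None,
    target: str = "TREC",
    rpp30_blood: float = 15_000.0,
) -> list[tuple[float, DropletWell]]:
    """Two-fold serial dilution of one target in a target-free blood matrix.

    Expected concentrations are top/2^k for k = 0..levels-1, each measured
    in ``replicates`` wells; returns (expected copies/µL blood, well) pairs.
    """
    if levels < 2 or replicates < 1 or top_blood_conc <= 0:
        raise ConfigError("need levels >= 2, replicates >= 1, top_blood_conc > 0")
    rng = _rng(cfg, rng)
    out = []
    for k in range(levels):
        conc = top_blood_conc / 2.0**k
        for rep in range(1, replicates + 1):
            kwargs = {"trec_blood": 0.0, "smn1_cn": 2, "smn2_cn": 2}
            if target == "TREC":
                kwargs["trec_blood"] = conc
            truth = SampleTruth(
                rpp30_blood=rpp30_blood,
                sample_id=f"dil-L{k + 1}",
                **kwargs,
            )
            well = simulate_well(
                truth, cfg, rng=rng, well_id=f"dil-L{k + 1}-w{rep:02d}"
            )
            out.append((conc, well))
    return out


def simulate_cohort(
    n: int,
    cfg: AssayConfig,
    cohort: Optional[CohortModel] = None,
    rng: Optional[np.random.Generator] = None,
    make_wells: bool = True,
) -> list[tuple[SampleTruth, Optional[DropletWell]]]:
    """Screening cohort: copy numbers from the population frequencies, TREC
    and RPP30 lognormal, gestational ages split by the preterm fraction.

    With ``make_wells=False`` only the truth records are generated (cheap,
    for distribution studies at large n).
    """
    if n < 0:
        raise ConfigError("n must be >= 0")
    cohort = cohort or CohortModel()
    rng = _rng(cfg, rng)

    def draw_cn(freqs: dict[int, float], size: int) -> np.ndarray:
        cns = np.array(sorted(freqs))
        p = np.array([freqs[c] for c in cns], dtype=float)
        p = p / p.sum()
        return rng.choice(cns, size=size, p=p)

    smn1 = draw_cn(cohort.smn1_frequencies, n)
    smn2 = draw_cn(cohort.smn2_frequencies, n)
    trec = cohort.trec_median * np.exp(rng.normal(0.0, cohort.trec_log_sd, size=n))
    rpp30 = cohort.rpp30_median * np.exp(
        rng.normal(0.0, cohort.rpp30_log_sd, size=n)
    )
    preterm = rng.random(n) < cohort.preterm_fraction
    weeks = np.where(
        preterm, rng.uniform(28.0, 34.0, size=n), rng.uniform(34.0, 42.0, size=n)
    )

    out: list[tuple[SampleTruth, Optional[DropletWell]]] = []
    for i in range(n):
        truth = SampleTruth(
            smn1_cn=int(smn1[i]),
            smn2_cn=int(smn2[i]),
            trec_blood=float(trec[i]),
            rpp30_blood=float(rpp30[i]),
            gestational_age_weeks=float(weeks[i]),
            role=Role.NEWBORN,
            sample_id=f"NBS{i + 1:05d}",
        )
        well = (
            simulate_well(truth, cfg, rng=rng, well_id=f"NBS{i + 1:05d}")
            if make_wells
            else None
        )
        out.append((truth, well))
    return out
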