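"""Poisson absolute quantification and copy-number computation.

A droplet digital PCR well partitions the reaction into ~20,000 droplets.
Template molecules distribute over droplets by Poisson statistics, so the
mean copies per droplet is recovered from the fraction of negative droplets:

    lambda = -ln(n_negative / n_total)

and the reaction concentration is lambda / droplet volume. Copy number is
referenced to RPP30, a gene present at two copies per genome:

    CN(target) = 2 * conc(target) / conc(RPP30)

Blood-unit concentrations follow the punch/elution/input volume chain:

    copies/µL blood = (copies per well / input µL DNA)
                      × (elution µL / blood µL per punch)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .calling import ChannelCall
from .config import TARGETS, AssayConfig, round_half_up
from .errors import NoReferenceError, SaturationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PoissonEstimate:
    """Mean copies per droplet with reaction concentration and 95% CI."""

    lam: float
    conc_reaction: float  # copies/µL of reaction
    ci95_reaction: tuple[float, float]


@dataclass(frozen=True)
class CopyNumberCall:
    cn: float
    cn_reported: float  # rounded half-up to one decimal
    cn_integer: int  # nearest integer, ties (x.5) rounded up


@dataclass(frozen=True)
class TargetQuant:
    """Quantification of a single target in one well."""

    target: str
    n_positive: int
    n_negative: int
    lam: float
    conc_reaction: float
    copies_per_well: float
    conc_blood: float
    ci95_reaction: tuple[float, float]
    cn: Optional[float] = None
    cn_reported: Optional[float] = None
    cn_integer: Optional[int] = None


@dataclass(frozen=True)
class WellQuant:
    """Per-target quantification of one QC-passed well."""

    well_id: str
    targets: dict[str, TargetQuant]
    no_reference: bool = False  # RPP30 concentration was zero; CN undefined

    def __getitem__(self, target: str) -> TargetQuant:
        return self.targets[target]


def poisson_concentration(
    n_positive: int, n_total: int, droplet_volume_nl: float
) -> PoissonEstimate:
    """Estimate mean copies/droplet and copies/µL reaction from droplet counts.

    The 95% CI is a normal approximation on the log scale:
    Var(lambda_hat) = (e^lambda - 1) / n_total (delta method on the
    negative-droplet binomial fraction).

    Raises
    ------
    SaturationError
        If every droplet is positive (lambda undefined).
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must be in [0, n_total]")
    if n_positive == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration out of range"
        )
    lam = -math.log((n_total - n_positive) / n_total)
    scale = 1000.0 / droplet_volume_nl  # copies/droplet -> copies/µL
    if lam == 0.0:
        return PoissonEstimate(0.0, 0.0, (0.0, 0.0))
    se = math.sqrt((math.exp(lam) - 1.0) / n_total)
    lo = max(0.0, lam - Z95 * se)
    hi = lam + Z95 * se
    return PoissonEstimate(lam, lam * scale, (lo * scale, hi * scale))


def copy_number(conc_target: float, conc_rpp30: float) -> CopyNumberCall:
    """Copy number relative to the two-copy RPP30 reference.

    cn = 2 * conc_target / conc_rpp30; reported value is rounded half-up to
    one decimal (0.94 -> 0.9); the integer call is the nearest integer with
    x.5 rounded up.
    """
    if conc_rpp30 <= 0:
        raise NoReferenceError("RPP30 concentration is zero: copy number undefined")
    if conc_target < 0:
        raise ValueError("conc_target must be >= 0")
    cn = 2.0 * conc_target / conc_rpp30
    return CopyNumberCall(cn, round_half_up(cn, 1), int(round_half_up(cn, 0)))


def to_blood_concentration(copies_per_well: float, cfg: AssayConfig) -> float:
    """Convert copies per well to copies/µL blood via the volume chain."""
    if copies_per_well < 0:
        raise ValueError("copies_per_well must be >= 0")
    return copies_per_well * cfg.blood_factor


def blood_to_copies_per_well(conc_blood: float, cfg: AssayConfig) -> float:
    """Inverse of :func:`to_blood_concentration` (used by the simulator)."""
    if conc_blood < 0:
        raise ValueError("conc_blood must be >= 0")
    return conc_blood / cfg.blood_factor


def quantify_well(calls: Sequence[ChannelCall], cfg: AssayConfig) -> WellQuant:
    """Quantify all four targets of one well from its channel calls.

    SMN1 and SMN2 get copy-number calls referenced to RPP30; TREC and RPP30
    are reported in copies/µL blood. If RPP30 quantifies to zero (e.g. a
    blank well) concentrations are still reported but copy-number fields are
    None and ``no_reference`` is set; qualification fails downstream.
    """
    by_target: dict[str, ChannelCall] = {}
    for call in calls:
        for target, ch in cfg.channel_map.items():
            if call.channel == ch:
                by_target[target] = call
    missing = [t for t in TARGETS if t not in by_target]
    if missing:
        raise ValueError(f"missing channel calls for targets: {missing}")

    well_id = calls[0].well_id
    quants: dict[str, TargetQuant] = {}
    estimates: dict[str, PoissonEstimate] = {}
    for target in TARGETS:
        call = by_target[target]
        est = poisson_concentration(
            call.n_positive, call.n_positive + call.n_negative, cfg.droplet_volume_nl
        )
        estimates[target] = est
        copies_per_well = est.conc_reaction * cfg.well_volume_ul
        quants[target] = TargetQuant(
            target=target,
            n_positive=call.n_positive,
            n_negative=call.n_negative,
            lam=est.lam,
            conc_reaction=est.conc_reaction,
            copies_per_well=copies_per_well,
            conc_blood=to_blood_concentration(copies_per_well, cfg),
            ci95_reaction=est.ci95_reaction,
        )

    rpp30_conc = estimates["RPP30"].conc_reaction
    no_reference = rpp30_conc <= 0
    import dataclasses as _dc

    if not no_reference:
        # RPP30 is the reference: CN identically 2 by definition.
        quants["RPP30"] = _dc.replace(
            quants["RPP30"], cn=2.0, cn_reported=2.0, cn_integer=2
        )
        for target in ("SMN1", "SMN2"):
            cnc = copy_number(estimates[target].conc_reaction, rpp30_conc)
            quants[target] = _dc.replace(
                quants[target],
                cn=cnc.cn,
                cn_reported=cnc.cn_reported,
                cn_integer=cnc.cn_integer,
            )
    return WellQuant(well_id=well_id, targets=quants, no_reference=no_reference)
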