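"""Screening decision engine: qualification, TREC class, SMN class, second tier.

Decision rules (all comparisons strict, as printed on the assay's
proficiency-report footnotes):

* qualification — RPP30 > 4200 copies/µL blood (sufficient DNA loaded);
* TREC — > 57 copies/µL blood is screen-negative; at or below triggers the
  re-punch/retest/recall flag (screen-positive for SCID);
* SMN1 integer copy number — 0: presumptive SMA (second tier required),
  1: carrier (possible compound heterozygote, advisory follow-up),
  >= 2: normal.

A presumptive SMA call is confirmed or refuted by a second-tier Sanger
pair: assay A amplifies SMN1 only (primers on c.835-44G>A / c.888+100A>G,
discriminating sites away from c.840); assay B amplifies both SMN1 and
SMN2. True homozygous SMN1 exon 7 deletion → assay A no amplicon, assay B
homozygous c.840T (SMN2 only). Allele dropout at c.840 (e.g. c.840C>G
under the first-tier probe) → assay A yields an amplicon carrying the
c.840 variant while assay B is heterozygous — a first-tier false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .config import ScreenCutoffs
from .errors import SecondTierPreconditionError, UnqualifiedSampleError
from .quantify import WellQuant


class TrecClass(str, Enum):
    NEGATIVE = "Negative"
    POSITIVE = "Positive"
    UNQUALIFIED = "Unqualified"


class SmaClass(str, Enum):
    NORMAL = "Normal"
    CARRIER = "Carrier"
    SMA_PRESUMPTIVE = "SMA_presumptive"
    SMA_CONFIRMED = "SMA_confirmed"
    DROPOUT_FALSE_POSITIVE = "Dropout_false_positive"
    REVIEW_REQUIRED = "Review_required"


class AssayA(str, Enum):
    NO_AMPLICON = "no_amplicon"
    C840C = "c840C"
    C840G = "c840G"
    C840_OTHER = "c840_other"


class AssayB(str, Enum):
    HOM_C840T = "hom_c840T"
    HOM_C840C = "hom_c840C"
    HET_C_T = "het_C_T"
    HET_G_T = "het_G_T"
    OTHER = "other"


@dataclass(frozen=True)
class SangerOutcome:
    """Categorical second-tier sequencing result (chromatogram calls declared
    upstream; no base-calling here)."""

    assay_a: AssayA
    assay_b: AssayB


@dataclass(frozen=True)
class ScreenResult:
    sample_id: str
    qualified: bool
    trec_class: TrecClass
    sma_class: Optional[SmaClass]
    smn1_cn_integer: Optional[int]
    smn2_cn_integer: Optional[int]
    needs_second_tier: bool
    flags: tuple[str, ...] = field(default=())


def qualify_sample(rpp30_blood: float, cutoffs: Optional[ScreenCutoffs] = None) -> bool:
    """True iff RPP30 strictly exceeds the minimum blood-unit loading."""
    if rpp30_blood < 0:
        raise ValueError("rpp30_blood must be >= 0")
    cutoffs = cutoffs or ScreenCutoffs()
    return rpp30_blood > cutoffs.rpp30_min_blood


def classify_trec(
    trec_blood: float,
    rpp30_blood: float,
    cutoffs: Optional[ScreenCutoffs] = None,
) -> TrecClass:
    """TREC screening class; unqualified samples are not classified."""
    if trec_blood < 0:
        raise ValueError("trec_blood must be >= 0")
    cutoffs = cutoffs or ScreenCutoffs()
    if not qualify_sample(rpp30_blood, cutoffs):
        return TrecClass.UNQUALIFIED
    if trec_blood > cutoffs.trec_cutoff_blood:
        return TrecClass.NEGATIVE
    return TrecClass.POSITIVE


def classify_smn(
    smn1_cn_integer: int, smn2_cn_integer: int, qualified: bool = True
) -> tuple[SmaClass, bool]:
    """SMA class from integer copy numbers; returns (class, needs_second_tier)."""
    if smn1_cn_integer < 0 or smn2_cn_integer < 0:
        raise ValueError("copy numbers must be >= 0")
    if not qualified:
        raise UnqualifiedSampleError("cannot classify SMN on an unqualified sample")
    if smn1_cn_integer == 0:
        return SmaClass.SMA_PRESUMPTIVE, True
    if smn1_cn_integer == 1:
        return SmaClass.CARRIER, False
    return SmaClass.NORMAL, False


def interpret_second_tier(first_tier: SmaClass, outcome: SangerOutcome) -> SmaClass:
    """Resolve a presumptive SMA call with the orthogonal Sanger pair.

    * assay A no amplicon + assay B homozygous c.840T → SMA confirmed
      (SMN1 exon 7 absent, only SMN2 amplifies);
    * assay A amplicon carrying a c.840 variant + assay B heterozygous with
      T → allele-dropout false positive (SMN1 present, invisible to the
      first-tier probe);
    * anything else contradicts the first tier → review required.
    """
    if first_tier is not SmaClass.SMA_PRESUMPTIVE:
        raise SecondTierPreconditionError(
            "second-tier interpretation applies to presumptive SMA only"
        )
    if outcome.assay_a is AssayA.NO_AMPLICON and outcome.assay_b is AssayB.HOM_C840T:
        return SmaClass.SMA_CONFIRMED
    if outcome.assay_a in (AssayA.C840G, AssayA.C840_OTHER) and outcome.assay_b in (
        AssayB.HET_G_T,
        AssayB.OTHER,
    ):
        return SmaClass.DROPOUT_FALSE_POSITIVE
    return SmaClass.REVIEW_REQUIRED


def screen_values(
    sample_id: str,
    trec_blood: float,
    rpp30_blood: float,
    smn1_cn_integer: Optional[int],
    smn2_cn_integer: Optional[int],
    cutoffs: Optional[ScreenCutoffs] = None,
    second_tier: Optional[SangerOutcome] = None,
    gestational_age_weeks: Optional[float] = None,
) -> ScreenResult:
    """Pure decision function over already-quantified values."""
    cutoffs = cutoffs or ScreenCutoffs()
    qualified = qualify_sample(rpp30_blood, cutoffs)
    trec_class = classify_trec(trec_blood, rpp30_blood, cutoffs)
    flags: list[str] = []
    if (
        gestational_age_weeks is not None
        and gestational_age_weeks < cutoffs.min_gestational_weeks
    ):
        flags.append("trec-cutoff-not-validated-preterm")
    if trec_class is TrecClass.POSITIVE:
        flags.append("repunch-retest-recall")

    sma_class: Optional[SmaClass] = None
    needs_second_tier = False
    if qualified and smn1_cn_integer is not None and smn2_cn_integer is not None:
        sma_class, needs_second_tier = classify_smn(
            smn1_cn_integer, smn2_cn_integer, qualified
        )
        if sma_class is SmaClass.CARRIER:
            flags.append("possible-compound-heterozygote-followup")
        if needs_second_tier and second_tier is not None:
            sma_class = interpret_second_tier(sma_class, second_tier)
            if sma_class is SmaClass.REVIEW_REQUIRED:
                flags.append("second-tier-contradicts-first-tier")
    return ScreenResult(
        sample_id=sample_id,
        qualified=qualified,
        trec_class=trec_class,
        sma_class=sma_class,
        smn1_cn_integer=smn1_cn_integer,
        smn2_cn_integer=smn2_cn_integer,
        needs_second_tier=needs_second_tier,
        flags=tuple(flags),
    )


def screen_sample(
    quant: WellQuant,
    cutoffs: Optional[ScreenCutoffs] = None,
    second_tier: Optional[SangerOutcome] = None,
    gestational_age_weeks: Optional[float] = None,
    sample_id: Optional[str] = None,
) -> ScreenResult:
    """Screen one quantified well: qualify → TREC → SMN → (second tier)."""
    return screen_values(
        sample_id=sample_id or quant.well_id,
        trec_blood=quant["TREC"].conc_blood,
        rpp30_blood=quant["RPP30"].conc_blood,
        smn1_cn_integer=quant["SMN1"].cn_integer,
        smn2_cn_integer=quant["SMN2"].cn_integer,
        cutoffs=cutoffs,
        second_tier=second_tier,
        gestational_age_weeks=gestational_age_weeks,
    )
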