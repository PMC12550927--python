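"""Plain-text file formats for the pipeline.

Droplet tables and quantification results are CSV (wide numeric tables at
full precision); human-facing screening reports are TSV with display
rounding (copy numbers to one decimal, blood concentrations to integers).
Configuration is YAML with unknown keys rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import ChannelCall, ThresholdMethod
from .config import AssayConfig, CohortModel, ScreenCutoffs, round_half_up
from .errors import ConfigError, EmptyInputError, SchemaError
from .quantify import WellQuant
from .screening import AssayA, AssayB, SangerOutcome, ScreenResult
from .simulate import DropletWell

log = logging.getLogger("ddscreen")

DROPLET_COLUMNS = ["well_id", "droplet_index", "ch1_amp", "ch2_amp", "ch3_amp", "ch4_amp"]


@dataclass
class PipelineConfig:
    """Top-level configuration: assay constants, cutoffs, simulator model."""

    assay: AssayConfig = field(default_factory=AssayConfig)
    cutoffs: ScreenCutoffs = field(default_factory=ScreenCutoffs)
    cohort: CohortModel = field(default_factory=CohortModel)
    outdir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "assay": self.assay.to_dict(),
            "cutoffs": self.cutoffs.to_dict(),
            "cohort": self.cohort.to_dict(),
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {"assay", "cutoffs", "cohort", "outdir", "seed", "log_level"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(
            assay=AssayConfig.from_dict(d.get("assay", {})),
            cutoffs=ScreenCutoffs.from_dict(d.get("cutoffs", {})),
            cohort=CohortModel.from_dict(d.get("cohort", {})),
            outdir=str(d.get("outdir", ".")),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# -- droplet tables ------------------------------------------------------


def write_droplet_csv(
    wells: Iterable[DropletWell],
    path: str | Path,
    truth_path: Optional[str | Path] = None,
) -> None:
    """One row per droplet: well_id, droplet_index, ch1..ch4 amplitudes.

    Truth labels, when present and requested, go to a sibling CSV with the
    same keying columns.
    """
    rows, truth_rows = [], []
    for well in wells:
        n = well.accepted_events
        frame = pd.DataFrame(
            {
                "well_id": np.repeat(well.well_id, n),
                "droplet_index": np.arange(n),
                "ch1_amp": well.amplitudes[:, 0],
                "ch2_amp": well.amplitudes[:, 1],
                "ch3_amp": well.amplitudes[:, 2],
                "ch4_amp": well.amplitudes[:, 3],
            }
        )
        rows.append(frame)
        if truth_path is not None and well.truth_labels is not None:
            truth_rows.append(
                pd.DataFrame(
                    {
                        "well_id": np.repeat(well.well_id, n),
                        "droplet_index": np.arange(n),
                        "ch1_label": well.truth_labels[:, 0].astype(int),
                        "ch2_label": well.truth_labels[:, 1].astype(int),
                        "ch3_label": well.truth_labels[:, 2].astype(int),
                        "ch4_label": well.truth_labels[:, 3].astype(int),
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    if truth_path is not None and truth_rows:
        pd.concat(truth_rows, ignore_index=True).to_csv(truth_path, index=False)


def read_droplet_csv(path: str | Path) -> list[DropletWell]:
    """Read wells from a droplet CSV; row counts become accepted events."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty droplet file") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: droplet file has no rows")
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    amp_cols = DROPLET_COLUMNS[2:]
    for col in amp_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            raise SchemaError(f"{path}: non-numeric amplitude in column {col}")
        df[col] = coerced
    wells = []
    for well_id, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("droplet_index")
        wells.append(
            DropletWell(
                sample_id=str(well_id),
                well_id=str(well_id),
                amplitudes=grp[amp_cols].to_numpy(dtype=float),
            )
        )
    return wells


def write_plate_layout(layout: pd.DataFrame, path: str | Path) -> None:
    layout.to_csv(path, index=False)


def read_plate_layout(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty layout file") from exc
    required = ["sample_id", "well_id", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


# -- channel calls -------------------------------------------------------


def write_calls_csv(
    calls: Iterable[ChannelCall], path: str | Path, qc_pass: bool = True
) -> None:
    rows = [
        {
            "well_id": c.well_id,
            "channel": c.channel,
            "threshold": c.threshold,
            "n_pos": c.n_positive,
            "n_neg": c.n_negative,
            "method": c.method.value,
            "qc_pass": qc_pass,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calls_csv(path: str | Path) -> dict[str, list[ChannelCall]]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty calls file") from exc
    required = ["well_id", "channel", "threshold", "n_pos", "n_neg", "method"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    by_well: dict[str, list[ChannelCall]] = {}
    for _, row in df.iterrows():
        call = ChannelCall(
            well_id=str(row["well_id"]),
            channel=int(row["channel"]),
            threshold=float(row["threshold"]),
            n_positive=int(row["n_pos"]),
            n_negative=int(row["n_neg"]),
            method=ThresholdMethod(row["method"]),
        )
        by_well.setdefault(call.well_id, []).append(call)
    return by_well


# -- quantification ------------------------------------------------------


def quant_to_frame(quants: Iterable[WellQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        for target, tq in q.targets.items():
            rows.append(
                {
                    "well_id": q.well_id,
                    "target": target,
                    "n_pos": tq.n_positive,
                    "n_neg": tq.n_negative,
                    "lambda": tq.lam,
                    "conc_reaction": tq.conc_reaction,
                    "copies_per_well": tq.copies_per_well,
                    "conc_blood": tq.conc_blood,
                    "cn": tq.cn,
                    "cn_reported": tq.cn_reported,
                    "cn_integer": tq.cn_integer,
                }
            )
    return pd.DataFrame(rows)


def write_quant_csv(quants: Iterable[WellQuant], path: str | Path) -> None:
    quant_to_frame(quants).to_csv(path, index=False)


def read_quant_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty quant file") from exc
    required = ["well_id", "target", "conc_blood"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


# -- second-tier outcomes and screening reports --------------------------


def read_sanger_csv(path: str | Path) -> dict[str, SangerOutcome]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty second-tier file") from exc
    required = ["sample_id", "assay_a", "assay_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out = {}
    for _, row in df.iterrows():
        try:
            outcome = SangerOutcome(
                assay_a=AssayA(row["assay_a"]), assay_b=AssayB(row["assay_b"])
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: bad second-tier outcome: {exc}") from exc
        out[str(row["sample_id"])] = outcome
    return out


def write_screen_report(
    results: Sequence[ScreenResult],
    path: str | Path,
    blood_values: Optional[Mapping[str, tuple[float, float]]] = None,
) -> None:
    """Screening report TSV, one row per screened specimen.

    ``blood_values`` optionally maps sample_id → (trec_blood, rpp30_blood)
    for display (rounded to integer copies/µL blood).
    """
    rows = []
    for r in results:
        row = {
            "sample_id": r.sample_id,
            "qualified": r.qualified,
            "trec_class": r.trec_class.value,
            "sma_class": r.sma_class.value if r.sma_class else "",
            "smn1_cn": "" if r.smn1_cn_integer is None else r.smn1_cn_integer,
            "smn2_cn": "" if r.smn2_cn_integer is None else r.smn2_cn_integer,
            "flags": ";".join(r.flags),
        }
        if blood_values and r.sample_id in blood_values:
            trec, rpp30 = blood_values[r.sample_id]
            row["trec_blood"] = int(round_half_up(trec))
            row["rpp30_blood"] = int(round_half_up(rpp30))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
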