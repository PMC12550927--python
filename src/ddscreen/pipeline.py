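"""End-to-end pipeline: droplets → calls → quantification → screening report."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as dio
from .calling import call_well, qc_well
from .config import AssayConfig, ScreenCutoffs
from .errors import SaturationError
from .quantify import quantify_well
from .screening import SangerOutcome, screen_sample

log = logging.getLogger("ddscreen")


def run_pipeline(
    droplets_csv: str | Path,
    outdir: str | Path,
    layout_csv: Optional[str | Path] = None,
    sanger_csv: Optional[str | Path] = None,
    assay: Optional[AssayConfig] = None,
    cutoffs: Optional[ScreenCutoffs] = None,
    min_events: int = 10_000,
) -> pd.DataFrame:
    """Call, quantify, and screen every well of a droplet table.

    QC-failed and saturated wells are logged and excluded from the report.
    Writes calls.csv, quant.csv, and report.tsv under ``outdir`` and
    returns the report frame.
    """
    assay = assay or AssayConfig()
    cutoffs = cutoffs or ScreenCutoffs()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    wells = dio.read_droplet_csv(droplets_csv)
    layout = dio.read_plate_layout(layout_csv) if layout_csv else None
    sanger = dio.read_sanger_csv(sanger_csv) if sanger_csv else {}

    meta: dict[str, dict] = {}
    if layout is not None:
        for _, row in layout.iterrows():
            meta[str(row["well_id"])] = {
                "sample_id": str(row["sample_id"]),
                "gestational_age_weeks": float(row["gestational_age_weeks"])
                if "gestational_age_weeks" in layout.columns
                and pd.notna(row.get("gestational_age_weeks"))
                else None,
            }

    all_calls, quants, results, blood = [], [], [], {}
    for well in wells:
        qc = qc_well(well, min_events=min_events)
        if not qc.passed:
            log.warning("well %s excluded: %s", well.well_id, qc.reason)
            continue
        calls = call_well(well, assay, min_events=min_events)
        all_calls.extend(calls)
        try:
            quant = quantify_well(calls, assay)
        except SaturationError as exc:
            log.warning("well %s excluded: %s", well.well_id, exc)
            continue
        quants.append(quant)
        info = meta.get(well.well_id, {})
        sample_id = info.get("sample_id", well.well_id)
        outcome: Optional[SangerOutcome] = sanger.get(sample_id)
        result = screen_sample(
            quant,
            cutoffs=cutoffs,
            second_tier=outcome,
            gestational_age_weeks=info.get("gestational_age_weeks"),
            sample_id=sample_id,
        )
        results.append(result)
        blood[sample_id] = (
            quant["TREC"].conc_blood,
            quant["RPP30"].conc_blood,
        )

    dio.write_calls_csv(all_calls, outdir / "calls.csv")
    dio.write_quant_csv(quants, outdir / "quant.csv")
    dio.write_screen_report(results, outdir / "report.tsv", blood_values=blood)
    return pd.read_csv(outdir / "report.tsv", sep="\t")
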