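"""End-to-end orchestration: recordings → parameter table → MOA scores.

Ties the stages together in the fixed order ingest → cleaning → kinetics →
baseline normalization → area/well aggregation → hypothesis scoring, with
per-recording error handling so one bad recording does not abort a plate.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .cleaning import CleaningConfig, clean_recording
from .errors import TTMError
from .hypotheses import HypothesisTable, KineticParameter
from .kinetics import (
    KineticsConfig,
    aggregate,
    measure_recording,
    normalize_to_baseline,
)
from .scoring import concentration_response
from .simulate import ExperimentDesign, Recording, SimulatedDataset, simulate_experiment
from .traces import Trace

__all__ = ["process_recordings", "classify_dataset", "run_classification"]

log = logging.getLogger("ttmkit")


def process_recordings(recordings: Iterable[Recording],
                       cleaning: CleaningConfig | None = None,
                       kinetics: KineticsConfig | None = None) -> pd.DataFrame:
    """Turn raw recordings into a per-well normalized parameter table.

    Each area is cleaned and quantified at baseline and post, the post
    record is divided by its own baseline, and areas are averaged into one
    row per well.  Rejected recordings (interpeak failure, degenerate
    baseline, too few events, ...) are logged and skipped.
    """
    cleaning = cleaning or CleaningConfig()
    kinetics = kinetics or KineticsConfig()

    measured: dict[tuple, dict[str, object]] = {}
    for rec in recordings:
        key = (rec.drug, rec.concentration_uM, rec.well, rec.area)
        try:
            avg = clean_recording(rec.traces, cleaning)
            params = measure_recording(avg, kinetics)
        except TTMError as exc:
            log.warning("rejected %s %s well %s area %s (%s): %s",
                        rec.drug, rec.concentration_uM, rec.well, rec.area,
                        rec.phase, exc)
            continue
        measured.setdefault(key, {})[rec.phase] = params

    normalized: dict[tuple, list] = {}
    for (drug, conc, well, area), phases in measured.items():
        if "baseline" not in phases or "post" not in phases:
            log.warning("incomplete phase pair for %s %s well %s area %s",
                        drug, conc, well, area)
            continue
        try:
            ratio = normalize_to_baseline(phases["post"], phases["baseline"])
        except TTMError as exc:
            log.warning("dropped %s %s well %s area %s: %s",
                        drug, conc, well, area, exc)
            continue
        normalized.setdefault((drug, conc, well), []).append(ratio)

    rows = []
    for (drug, conc, well), areas in sorted(normalized.items()):
        try:
            mean, n = aggregate(areas)
        except TTMError as exc:
            log.warning("dropped well %s of %s %s: %s", well, drug, conc, exc)
            continue
        row = {"drug": drug, "concentration_uM": conc, "well": well, "n_areas": n}
        row.update({p.name: v for p, v in mean.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


def classify_dataset(dataset: SimulatedDataset,
                     cleaning: CleaningConfig | None = None,
                     kinetics: KineticsConfig | None = None,
                     table: HypothesisTable | None = None,
                     sd_mode: str = "sd") -> pd.DataFrame:
    """Process a simulated dataset and score every condition."""
    params = process_recordings(dataset.recordings, cleaning, kinetics)
    return concentration_response(params, table=table, sd_mode=sd_mode)


def run_classification(design: ExperimentDesign,
                       subset: str = "ALL") -> str:
    """Simulate one experiment and return the assigned MOA at the top dose."""
    dataset = simulate_experiment(design)
    scores = classify_dataset(dataset)
    drug_scores = scores[(scores["drug"] == design.drug) & (scores["subset"] == subset)]
    if drug_scores.empty:  # null designs have only vehicle rows for this label
        drug_scores = scores[(scores["drug"] == "vehicle") & (scores["subset"] == subset)]
    top = drug_scores["concentration_uM"].max()
    row = drug_scores[drug_scores["concentration_uM"] == top].iloc[0]
    return str(row["assigned"])
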