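"""Whole-body glucose and triglyceride (TGA) normalization with
control-genotype plate QC.

Each assay plate carries wells of experimental lines plus two control
genotypes: Canton-S (wild-type reference) and an Akhr mutant
(adipokinetic-hormone-receptor null), whose known phenotype — elevated
TGA with glucose similar to Canton-S — serves as a per-plate positive
control.  Analyte quantities are normalized per mg protein; a second
normalization divides each per-protein value by the plate's mean Canton-S
per-protein value, which cancels any multiplicative plate effect exactly
and is used for QC and sensitivity analysis (downstream models consume
the per-protein values).

Plate QC (Welch t-tests on control wells at alpha = 0.05): a plate FAILS
if Akhr TGA is not significantly above Canton-S TGA (one-sided) or if
Akhr glucose differs significantly from Canton-S glucose (two-sided);
plates with fewer than two replicate wells of either control are
"indeterminate" (kept, flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CONTROL_GENOTYPES = ("CantonS", "Akhr")


@dataclass(frozen=True)
class PlateReading:
    plate_id: str
    well: str
    genotype: str
    analyte: str            # "glucose" | "TGA"
    analyte_mg: float
    protein_mg: float
    sex: str
    temperature: float


@dataclass(frozen=True)
class PlateQCVerdict:
    plate_id: str
    analyte: str
    verdict: str            # "pass" | "fail" | "indeterminate"
    tga_p_one_sided: float | None
    glucose_p_two_sided: float | None
    reason: str


def normalize_per_protein(reading: PlateReading) -> float:
    """mg analyte per mg protein; wells without protein are rejected."""
    if reading.protein_mg <= 0:
        raise ValueError(
            f"well {reading.plate_id}/{reading.well}: protein quantity is "
            f"{reading.protein_mg}; well rejected"
        )
    return reading.analyte_mg / reading.protein_mg


def normalize_to_cantons(
    reading: PlateReading, plate_readings: list[PlateReading]
) -> float:
    """Per-protein value divided by the plate's mean Canton-S per-protein
    value for the same analyte (exactly cancels multiplicative plate
    effects)."""
    cantons = [
        r
        for r in plate_readings
        if r.plate_id == reading.plate_id
        and r.analyte == reading.analyte
        and r.genotype == "CantonS"
        and r.protein_mg > 0
    ]
    if not cantons:
        raise ValueError(
            f"plate {reading.plate_id} has no usable CantonS wells for "
            f"{reading.analyte}; plate unnormalizable"
        )
    ref = float(np.mean([normalize_per_protein(r) for r in cantons]))
    return normalize_per_protein(reading) / ref


def _control_values(frame: pd.DataFrame, genotype: str, analyte: str) -> np.ndarray:
    sub = frame[
        (frame["genotype"] == genotype)
        & (frame["analyte"] == analyte)
        & (frame["protein_mg"] > 0)
    ]
    return (sub["analyte_mg"] / sub["protein_mg"]).to_numpy()


def plate_qc(plate: pd.DataFrame, alpha: float = 0.05) -> PlateQCVerdict:
    """QC one plate against the Akhr/Canton-S control contract.

    ``plate`` is the tidy well table of a single plate (columns genotype,
    analyte, analyte_mg, protein_mg).  Both analytes must have control
    wells; with <2 replicate wells of either control the verdict is
    indeterminate.
    """
    plate_id = str(plate["plate_id"].iloc[0]) if "plate_id" in plate else "?"
    akhr_tga = _control_values(plate, "Akhr", "TGA")
    cs_tga = _control_values(plate, "CantonS", "TGA")
    akhr_glu = _control_values(plate, "Akhr", "glucose")
    cs_glu = _control_values(plate, "CantonS", "glucose")

    if min(len(akhr_tga), len(cs_tga), len(akhr_glu), len(cs_glu)) < 2:
        return PlateQCVerdict(
            plate_id, "both", "indeterminate", None, None,
            "fewer than 2 replicate control wells",
        )

    p_tga = stats.ttest_ind(
        akhr_tga, cs_tga, equal_var=False, alternative="greater"
    ).pvalue
    p_glu = stats.ttest_ind(akhr_glu, cs_glu, equal_var=False).pvalue

    if p_tga >= alpha:
        return PlateQCVerdict(
            plate_id, "both", "fail", float(p_tga), float(p_glu),
            "Akhr TGA not significantly above CantonS",
        )
    if p_glu < alpha:
        return PlateQCVerdict(
            plate_id, "both", "fail", float(p_tga), float(p_glu),
            "Akhr glucose differs significantly from CantonS",
        )
    return PlateQCVerdict(plate_id, "both", "pass", float(p_tga), float(p_glu), "ok")


def summarize_plates(
    plates: pd.DataFrame, alpha: float = 0.05, drop_failed: bool = True
) -> tuple[pd.DataFrame, list[PlateQCVerdict]]:
    """Normalize all wells and aggregate line-level metabolite summaries.

    Input is the tidy plate CSV (plate_id, well, genotype, analyte,
    analyte_mg, protein_mg, sex, temperature).  Returns a line x sex x
    temperature table with mean per-protein and Canton-S-normalized values
    for each analyte, plus the per-plate QC verdicts; wells of failed
    plates are excluded when ``drop_failed``.
    """
    verdicts = [plate_qc(grp, alpha) for _, grp in plates.groupby("plate_id", sort=False)]
    failed = {v.plate_id for v in verdicts if v.verdict == "fail"}

    frame = plates[plates["protein_mg"] > 0].copy()
    if drop_failed:
        frame = frame[~frame["plate_id"].astype(str).isin(failed)]
    frame["per_protein"] = frame["analyte_mg"] / frame["protein_mg"]
    cs_ref = (
        frame[frame["genotype"] == "CantonS"]
        .groupby(["plate_id", "analyte"])["per_protein"]
        .mean()
        .rename("cs_ref")
    )
    frame = frame.join(cs_ref, on=["plate_id", "analyte"])
    frame["cantons_normalized"] = frame["per_protein"] / frame["cs_ref"]

    lines = frame[~frame["genotype"].isin(CONTROL_GENOTYPES)]
    agg = (
        lines.groupby(["genotype", "sex", "temperature", "analyte"])
        .agg(
            per_protein=("per_protein", "mean"),
            per_protein_se=("per_protein", "sem"),
            cantons_normalized=("cantons_normalized", "mean"),
            n_replicates=("per_protein", "size"),
        )
        .reset_index()
        .rename(columns={"genotype": "line"})
    )
    wide = agg.pivot_table(
        index=["line", "sex", "temperature"],
        columns="analyte",
        values=["per_protein", "per_protein_se", "cantons_normalized", "n_replicates"],
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index().rename(
        columns={
            "per_protein_glucose": "glucose_per_protein",
            "per_protein_TGA": "tga_per_protein",
            "cantons_normalized_glucose": "glucose_cantons_norm",
            "cantons_normalized_TGA": "tga_cantons_norm",
        }
    )
    return wide, verdicts
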