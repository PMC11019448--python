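"""Cohort tables, the exclusion cascade, and extreme-phenotype subgroup selection.

A cohort is a list of :class:`CaseRecord` objects: the five regional tangle
counts plus the clinicopathologic covariates used by the analysis layer.
Records round-trip losslessly through a plain CSV/TSV with one row per case;
the MMSE series is packed into a single ``time:score;time:score`` column.

The exclusion cascade mirrors a brain-bank screening flow: cases are removed,
in order, when (1) AD is not the primary neuropathologic diagnosis, (2) the
brain is neuropathologically normal, (3) thioflavin-S tangle data are absent,
(4) a known AD gene variant is carried, or (5) hippocampal sclerosis is
present.  Each excluded case is attributed to the *first* matching rule, so
the per-rule tallies are disjoint and sum to the total excluded.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    REGIONS,
    CLixResult,
    DEFAULT_PSEUDOCOUNT,
    RegionCounts,
    ReferenceModel,
    Subtype,
    build_reference,
    compute_clix,
)
from .errors import SubgroupShortfallError, ValidationError

logger = logging.getLogger(__name__)

_BOOL_FIELDS = (
    "primary_dx_ad",
    "neuropath_normal",
    "ad_gene_variant",
    "hippocampal_sclerosis",
    "copathology_exclusion",
    "apoe_e4",
    "trem2_r47h",
    "atypical_syndrome",
    "tdp43_positive",
)
_FLOAT_FIELDS = (
    "age_onset_y",
    "age_death_y",
    "education_y",
    "duration_y",
    "brain_weight_g",
)
_INT_FIELDS = ("braak", "thal", "kalaria")


@dataclass
class CaseRecord:
    """One autopsied case: counts, covariates, and screening flags."""

    case_id: str
    counts: RegionCounts | None = None
    primary_dx_ad: bool = True
    neuropath_normal: bool = False
    ad_gene_variant: bool = False
    hippocampal_sclerosis: bool = False
    copathology_exclusion: bool = False
    age_onset_y: float | None = None
    age_death_y: float | None = None
    education_y: float | None = None
    duration_y: float | None = None
    sex: str | None = None  # "male" | "female"
    apoe_e4: bool | None = None
    trem2_r47h: bool | None = None
    atypical_syndrome: bool | None = None
    braak: int | None = None  # tangle stage 0-6
    thal: int | None = None  # amyloid phase 0-5
    kalaria: int | None = None  # cerebrovascular disease scale
    brain_weight_g: float | None = None
    tdp43_positive: bool | None = None
    mmse: tuple[tuple[float, float], ...] = ()

    def validate(self) -> None:
        """Raise :class:`ValidationError` on inconsistent fields.

        Age ordering and MMSE monotonicity are hard errors; a duration that
        disagrees with death-minus-onset by more than a year only warns.
        """
        if not self.case_id:
            raise ValidationError("case_id is mandatory")
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        for name in _FLOAT_FIELDS:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
        if self.brain_weight_g is not None and self.brain_weight_g <= 0:
            raise ValidationError("brain_weight_g must be positive")
        if (
            self.age_onset_y is not None
            and self.age_death_y is not None
            and self.age_onset_y > self.age_death_y
        ):
            raise ValidationError("age_onset_y exceeds age_death_y")
        if (
            self.age_onset_y is not None
            and self.age_death_y is not None
            and self.duration_y is not None
            and abs(self.duration_y - (self.age_death_y - self.age_onset_y)) > 1.0
        ):
            logger.warning(
                "case %s: duration_y %.1f != age_death - age_onset %.1f",
                self.case_id,
                self.duration_y,
                self.age_death_y - self.age_onset_y,
            )
        if self.braak is not None and not 0 <= self.braak <= 6:
            raise ValidationError(f"braak stage out of range: {self.braak}")
        if self.thal is not None and not 0 <= self.thal <= 5:
            raise ValidationError(f"thal phase out of range: {self.thal}")
        if self.kalaria is not None and self.kalaria < 0:
            raise ValidationError("kalaria scale must be >= 0")
        times = [t for t, _ in self.mmse]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("mmse times must be strictly increasing")
        for _, s in self.mmse:
            if not 0 <= s <= 30:
                raise ValidationError("mmse scores must lie in [0, 30]")


# --------------------------------------------------------------------------
# CSV round-trip

CSV_COLUMNS = (
    ("case_id",)
    + REGIONS
    + _BOOL_FIELDS[:5]
    + _FLOAT_FIELDS[:4]
    + ("sex",)
    + _BOOL_FIELDS[5:8]
    + _INT_FIELDS
    + ("brain_weight_g", "tdp43_positive", "mmse")
)


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _fmt_mmse(series: tuple[tuple[float, float], ...]) -> str:
    return ";".join(f"{_fmt(float(t))}:{_fmt(float(s))}" for t, s in series)


def _parse_bool(s: str, column: str) -> bool | None:
    if s in ("", "NA"):
        return None
    if s in ("1", "true", "True"):
        return True
    if s in ("0", "false", "False"):
        return False
    raise ValidationError(f"column {column}: cannot parse boolean {s!r}")


def _parse_float(s: str) -> float | None:
    return None if s in ("", "NA") else float(s)


def write_cohort(records: Iterable[CaseRecord], path: str | Path) -> None:
    """Write records to CSV (or TSV when the path ends in ``.tsv``)."""
    path = Path(path)
    delim = "\t" if path.suffix == ".tsv" else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(CSV_COLUMNS)
        for rec in records:
            row = []
            for col in CSV_COLUMNS:
                if col in REGIONS:
                    if rec.counts is None:
                        row.append("NA")
                    else:
                        v = getattr(rec.counts, col)
                        row.append("NA" if math.isnan(v) else repr(float(v)))
                elif col == "mmse":
                    row.append(_fmt_mmse(rec.mmse))
                else:
                    row.append(_fmt(getattr(rec, col)))
            w.writerow(row)


def _record_from_row(row: dict[str, str]) -> CaseRecord:
    region_vals = {}
    for r in REGIONS:
        s = row.get(r, "NA")
        region_vals[r] = math.nan if s in ("", "NA") else float(s)
    if all(math.isnan(v) for v in region_vals.values()):
        counts = None
    else:
        counts = RegionCounts(
            **region_vals,
            allow_missing=any(math.isnan(v) for v in region_vals.values()),
        )
    mmse_raw = row.get("mmse", "")
    mmse = []
    if mmse_raw not in ("", "NA"):
        for item in mmse_raw.split(";"):
            t, s = item.split(":")
            mmse.append((float(t), float(s)))
    kwargs: dict = {"case_id": row["case_id"], "counts": counts, "mmse": tuple(mmse)}
    for name in _BOOL_FIELDS:
        b = _parse_bool(row.get(name, "NA"), name)
        if name in _BOOL_FIELDS[:5]:
            # screening flags are mandatory booleans with safe defaults
            defaults = {"primary_dx_ad": True}
            kwargs[name] = defaults.get(name, False) if b is None else b
        else:
            kwargs[name] = b
    for name in _FLOAT_FIELDS:
        kwargs[name] = _parse_float(row.get(name, "NA"))
    for name in _INT_FIELDS:
        v = _parse_float(row.get(name, "NA"))
        kwargs[name] = None if v is None else int(v)
    sex = row.get("sex", "NA")
    kwargs["sex"] = None if sex in ("", "NA") else sex
    rec = CaseRecord(**kwargs)
    rec.validate()
    return rec


def read_cohort(
    path: str | Path, return_problems: bool = False
) -> list[CaseRecord] | tuple[list[CaseRecord], list[str]]:
    """Read a cohort table, collecting row-level problems instead of failing.

    Rows that fail validation are dropped and reported (with their line
    number) in the problem list; a missing ``case_id`` column is a hard
    error.  Unknown columns are ignored with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = "\t" if path.suffix == ".tsv" else ","
    records: list[CaseRecord] = []
    problems: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "case_id" not in reader.fieldnames:
            raise ValidationError(f"{path}: missing mandatory column case_id")
        unknown = set(reader.fieldnames) - set(CSV_COLUMNS)
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, sorted(unknown))
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValidationError, ValueError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        logger.warning("%s: %d rows rejected", path, len(problems))
    if return_problems:
        return records, problems
    return records


# --------------------------------------------------------------------------
# Exclusion cascade

#: Ordered cascade; each case is attributed to the first matching rule.
EXCLUSION_RULES: tuple[tuple[str, Callable[[CaseRecord], bool]], ...] = (
    ("not_ad", lambda c: not c.primary_dx_ad),
    ("normal", lambda c: c.neuropath_normal),
    ("no_thioflavin", lambda c: c.counts is None or c.counts.has_missing),
    ("gene_variant", lambda c: c.ad_gene_variant),
    ("hippocampal_sclerosis", lambda c: c.hippocampal_sclerosis),
)


@dataclass(frozen=True)
class ExclusionTally:
    """Counts from one pass of the exclusion cascade."""

    n_input: int
    n_not_ad: int
    n_normal: int
    n_no_thioflavin: int
    n_gene_variant: int
    n_hippocampal_sclerosis: int

    @property
    def n_excluded_total(self) -> int:
        return (
            self.n_not_ad
            + self.n_normal
            + self.n_no_thioflavin
            + self.n_gene_variant
            + self.n_hippocampal_sclerosis
        )

    @property
    def n_remaining(self) -> int:
        return self.n_input - self.n_excluded_total

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_not_ad": self.n_not_ad,
            "n_normal": self.n_normal,
            "n_no_thioflavin": self.n_no_thioflavin,
            "n_gene_variant": self.n_gene_variant,
            "n_hippocampal_sclerosis": self.n_hippocampal_sclerosis,
            "n_excluded_total": self.n_excluded_total,
            "n_remaining": self.n_remaining,
        }


def exclusion_reason(case: CaseRecord) -> str | None:
    """Name of the first cascade rule the case matches, or None if it survives."""
    for name, pred in EXCLUSION_RULES:
        if pred(case):
            return name
    return None


def apply_exclusions(
    cohort: Sequence[CaseRecord],
) -> tuple[list[CaseRecord], ExclusionTally]:
    """Run the cascade; survivors keep their input order."""
    counts = {name: 0 for name, _ in EXCLUSION_RULES}
    survivors = []
    for case in cohort:
        reason = exclusion_reason(case)
        if reason is None:
            survivors.append(case)
        else:
            counts[reason] += 1
    tally = ExclusionTally(
        n_input=len(cohort),
        n_not_ad=counts["not_ad"],
        n_normal=counts["normal"],
        n_no_thioflavin=counts["no_thioflavin"],
        n_gene_variant=counts["gene_variant"],
        n_hippocampal_sclerosis=counts["hippocampal_sclerosis"],
    )
    return survivors, tally


# --------------------------------------------------------------------------
# Scoring a cohort and selecting the digital-pathology subgroup


def score_cohort(
    records: Sequence[CaseRecord],
    reference: ReferenceModel | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    allow_missing: bool = False,
) -> tuple[pd.DataFrame, ReferenceModel]:
    """Score every record, deriving the reference from the cohort when absent.

    Returns a frame with one row per scoreable case (case_id, score, subtype,
    component percentiles, the copathology flag used by subgroup selection)
    plus the reference that was used.
    """
    scoreable = [r for r in records if r.counts is not None]
    if reference is None:
        complete = [r.counts for r in scoreable if not r.counts.has_missing]
        reference = build_reference(complete, pseudocount=pseudocount)
    rows = []
    for rec in scoreable:
        if rec.counts.has_missing and not allow_missing:
            continue
        res: CLixResult = compute_clix(
            rec.counts, reference, weights=weights, allow_missing=allow_missing
        )
        rows.append(
            {
                "case_id": rec.case_id,
                "score": res.score,
                "subtype": res.subtype.value,
                "hippocampal_pct": res.hippocampal_pct,
                "cortical_pct": res.cortical_pct,
                "ratio": res.ratio,
                "ratio_pct": res.ratio_pct,
                "copathology_exclusion": rec.copathology_exclusion,
            }
        )
    return pd.DataFrame(rows), reference


def select_subgroup(
    scored: pd.DataFrame,
    n_per_subtype: int,
    exclude_copathology: bool = True,
) -> pd.DataFrame:
    """Pick the deep-phenotyping subgroup from a scored cohort.

    Takes the ``n_per_subtype`` *lowest* scores from the hippocampal-sparing
    bin, the *highest* from the limbic-predominant bin, and, for typical AD,
    the scores closest to the cohort median (the most "centralized" cases).
    Cases flagged with a glial-relevant copathology (meningitis,
    encephalitis, (micro)infarct, Lewy body disease) are screened out first
    when requested.  Ties break on case_id so selection is deterministic.
    """
    required = {"case_id", "score", "subtype"}
    if not required <= set(scored.columns):
        raise ValidationError(f"scored frame must have columns {sorted(required)}")
    eligible = scored
    if exclude_copathology and "copathology_exclusion" in scored.columns:
        eligible = scored[~scored["copathology_exclusion"].astype(bool)]
    median_score = float(eligible["score"].median())
    parts = []
    for subtype, key in (
        (Subtype.HIPPOCAMPAL_SPARING, lambda df: df["score"]),
        (Subtype.TYPICAL, lambda df: (df["score"] - median_score).abs()),
        (Subtype.LIMBIC_PREDOMINANT, lambda df: -df["score"]),
    ):
        pool = eligible[eligible["subtype"] == subtype.value].copy()
        if len(pool) < n_per_subtype:
            raise SubgroupShortfallError(subtype.value, len(pool), n_per_subtype)
        pool["_key"] = key(pool)
        pool = pool.sort_values(["_key", "case_id"], kind="mergesort")
        parts.append(pool.head(n_per_subtype).drop(columns="_key"))
    out = pd.concat(parts, ignore_index=True)
    return out


def cohort_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Flatten records into a covariate DataFrame (one row per case).

    MMSE series are left out; the analysis layer derives the decline slope
    separately.
    """
    rows = []
    for rec in records:
        row: dict = {"case_id": rec.case_id}
        for f in fields(CaseRecord):
            if f.name in ("case_id", "counts", "mmse"):
                continue
            row[f.name] = getattr(rec, f.name)
        if rec.counts is not None:
            for r in REGIONS:
                row[r] = getattr(rec.counts, r)
        rows.append(row)
    return pd.DataFrame(rows)


def plant_flags(records: Sequence[CaseRecord], **updates) -> list[CaseRecord]:
    """Return copies of ``records`` with dataclass fields replaced."""
    return [replace(r, **updates) for r in records]
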