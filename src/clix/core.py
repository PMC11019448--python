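"""Corticolimbic index (CLix) scoring.

The CLix is a continuous 0-40 score summarising where a case sits on the
corticolimbic continuum of neurofibrillary-tangle burden.  It is built from
thioflavin-S tangle counts in five regions: two posterior-hippocampal
subregions (CA1, subiculum) and three association cortices (superior
temporal, inferior parietal, middle frontal).  Each count is converted to a
percentile against a reference distribution; the hippocampal:cortical count
ratio gets its own percentile; and the three ingredients are combined into
a single score.  Low scores indicate relative cortical predominance
(hippocampal-sparing AD), high scores relative cortical sparing
(limbic-predominant AD), with typical AD in between.

Percentiles use the mid-rank empirical CDF, ``100 * (below + 0.5*equal)/n``,
which is symmetric and handles ties without interpolation.  The composite is
an equal-weight mean of the ratio percentile, the hippocampal percentile and
the *reversed* cortical percentile, rescaled by 0.4 so the score spans 0-40;
the weights are configurable so alternative composites can be swapped in.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ReferenceTooSmallError, ScoreRangeError, ValidationError

logger = logging.getLogger(__name__)

#: Region order used everywhere a flat vector of counts appears.
REGIONS = ("ca1", "subiculum", "sup_temporal", "inf_parietal", "mid_frontal")
HIPPOCAMPAL_REGIONS = ("ca1", "subiculum")
CORTICAL_REGIONS = ("sup_temporal", "inf_parietal", "mid_frontal")

#: Added to numerator and denominator of the hippocampal:cortical ratio so
#: the ratio stays finite when a compartment is tangle-free (ghost-tangle-free
#: cortex does occur in extreme limbic-predominant cases).
DEFAULT_PSEUDOCOUNT = 0.5

#: Minimum number of complete cases accepted for a reference distribution.
MIN_REFERENCE_CASES = 20

SCORE_SCALE = 0.4  # maps the 0-100 composite onto 0-40


class Subtype(str, enum.Enum):
    """Three-way neuropathologic AD subtype binned from the CLix score."""

    HIPPOCAMPAL_SPARING = "hippocampal_sparing"
    TYPICAL = "typical"
    LIMBIC_PREDOMINANT = "limbic_predominant"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True, eq=False)
class RegionCounts:
    """Tangle counts (per standardized microscopic field) for the five regions.

    All five values must be finite and non-negative.  Missing regions are
    rejected unless the instance is built with ``allow_missing=True``, in
    which case a region may be NaN as long as each compartment (hippocampal,
    cortical) retains at least one observed region; downstream scoring then
    averages over the available regions of each compartment.
    """

    ca1: float
    subiculum: float
    sup_temporal: float
    inf_parietal: float
    mid_frontal: float
    allow_missing: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in REGIONS:
            v = getattr(self, name)
            if v is None or (math.isnan(v) and not self.allow_missing):
                raise ValidationError(f"region {name!r} is missing")
            if not math.isnan(v) and (not math.isfinite(v) or v < 0):
                raise ValidationError(
                    f"region {name!r} must be a finite non-negative count, got {v!r}"
                )
        if self.allow_missing:
            for compartment in (HIPPOCAMPAL_REGIONS, CORTICAL_REGIONS):
                if all(math.isnan(getattr(self, r)) for r in compartment):
                    raise ValidationError(
                        "every region of a compartment is missing: "
                        + "/".join(compartment)
                    )

    def __eq__(self, other) -> bool:
        # NaN-aware: two records with the same missing regions compare equal
        if not isinstance(other, RegionCounts):
            return NotImplemented
        return all(
            getattr(self, r) == getattr(other, r)
            or (math.isnan(getattr(self, r)) and math.isnan(getattr(other, r)))
            for r in REGIONS
        )

    def __hash__(self) -> int:
        return hash(tuple(getattr(self, r) for r in REGIONS))

    @property
    def has_missing(self) -> bool:
        return any(math.isnan(getattr(self, r)) for r in REGIONS)

    @property
    def hippocampal_mean(self) -> float:
        return float(np.nanmean([self.ca1, self.subiculum]))

    @property
    def cortical_mean(self) -> float:
        return float(
            np.nanmean([self.sup_temporal, self.inf_parietal, self.mid_frontal])
        )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, r) for r in REGIONS], dtype=float)


@dataclass(frozen=True)
class ReferenceModel:
    """Reference distributions defining the percentiles of the score.

    Holds, for each region, the sorted tangle counts of the reference cases,
    plus the sorted hippocampal:cortical ratios of the same cases.  Scores
    computed against a fixed, saved reference are stable across cohorts;
    :func:`build_reference` derives one from the cohort at hand.
    """

    per_region_counts: Mapping[str, np.ndarray]
    ratio_values: np.ndarray
    n_reference: int
    provenance: str = ""
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        if self.n_reference < MIN_REFERENCE_CASES:
            raise ReferenceTooSmallError(
                f"reference needs >= {MIN_REFERENCE_CASES} cases, "
                f"got {self.n_reference}"
            )
        if set(self.per_region_counts) != set(REGIONS):
            raise ValidationError(
                f"reference must cover exactly the regions {REGIONS}"
            )
        object.__setattr__(
            self,
            "per_region_counts",
            {
                r: np.asarray(self.per_region_counts[r], dtype=float)
                for r in REGIONS
            },
        )
        object.__setattr__(
            self, "ratio_values", np.asarray(self.ratio_values, dtype=float)
        )
        for name, arr in [
            *self.per_region_counts.items(),
            ("ratio_values", self.ratio_values),
        ]:
            if arr.ndim != 1 or len(arr) != self.n_reference:
                raise ValidationError(
                    f"reference list {name!r} must have length n_reference"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"reference list {name!r} has non-finite values")
            if np.any(np.diff(arr) < 0):
                raise ValidationError(f"reference list {name!r} is not sorted")
        if np.any(self.ratio_values <= 0):
            raise ValidationError("reference ratios must be positive")
        for r in REGIONS:
            if np.any(self.per_region_counts[r] < 0):
                raise ValidationError(f"reference counts for {r!r} must be >= 0")

    # -- (de)serialisation: plain JSON so reference files round-trip --------

    def to_dict(self) -> dict:
        return {
            **{r: self.per_region_counts[r].tolist() for r in REGIONS},
            "ratio_values": self.ratio_values.tolist(),
            "n_reference": self.n_reference,
            "provenance": self.provenance,
            "pseudocount": self.pseudocount,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceModel":
        return cls(
            per_region_counts={r: np.asarray(d[r], dtype=float) for r in REGIONS},
            ratio_values=np.asarray(d["ratio_values"], dtype=float),
            n_reference=int(d["n_reference"]),
            provenance=str(d.get("provenance", "")),
            pseudocount=float(d.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CLixResult:
    """A scored case: the CLix score, its components, and the subtype bin."""

    score: float
    hippocampal_pct: float
    cortical_pct: float
    ratio: float
    ratio_pct: float
    subtype: Subtype


def percentile(value: float, reference_values: Sequence[float] | np.ndarray) -> float:
    """Mid-rank ECDF percentile of ``value`` in a sorted reference list.

    Returns ``100 * (count_below + 0.5 * count_equal) / n``.  Monotone
    non-decreasing in ``value``; tied values get identical percentiles;
    a value outside the support maps to exactly 0 or 100.
    """
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise ValidationError("empty reference list")
    below = int(np.searchsorted(ref, value, side="left"))
    equal = int(np.searchsorted(ref, value, side="right")) - below
    return 100.0 * (below + 0.5 * equal) / ref.size


def hippocampal_cortical_ratio(
    counts: RegionCounts, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Ratio of mean hippocampal to mean cortical tangle counts.

    A pseudocount (default 0.5) is added to both terms so the ratio stays
    finite and positive even for a tangle-free cortex.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return (counts.hippocampal_mean + pseudocount) / (
        counts.cortical_mean + pseudocount
    )


def build_reference(
    cohort_counts: Iterable[RegionCounts],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    provenance: str = "cohort-derived",
) -> ReferenceModel:
    """Build a :class:`ReferenceModel` from the complete cases of a cohort.

    Requires at least 20 complete cases; any missing region is a validation
    error (incomplete cases must be filtered upstream).  The output depends
    only on the multiset of inputs, not their order.
    """
    cases = list(cohort_counts)
    for c in cases:
        if c.has_missing:
            raise ValidationError("reference cases must have all five regions")
    if len(cases) < MIN_REFERENCE_CASES:
        raise ReferenceTooSmallError(
            f"need >= {MIN_REFERENCE_CASES} complete cases, got {len(cases)}"
        )
    per_region = {
        r: np.sort(np.array([getattr(c, r) for c in cases], dtype=float))
        for r in REGIONS
    }
    ratios = np.sort(
        np.array([hippocampal_cortical_ratio(c, pseudocount) for c in cases])
    )
    return ReferenceModel(
        per_region_counts=per_region,
        ratio_values=ratios,
        n_reference=len(cases),
        provenance=provenance,
        pseudocount=pseudocount,
    )


def classify_subtype(score: float) -> Subtype:
    """Bin a CLix score: <10 hippocampal sparing, 10-30 typical, >=30 limbic
    predominant.

    The bins are half-open ([0,10), [10,30), [30,40]); a score of exactly 30
    is limbic predominant.
    """
    if not (0.0 <= score <= 40.0):
        raise ScoreRangeError(f"score {score!r} outside [0, 40]")
    if score < 10.0:
        return Subtype.HIPPOCAMPAL_SPARING
    if score < 30.0:
        return Subtype.TYPICAL
    return Subtype.LIMBIC_PREDOMINANT


def compute_clix(
    counts: RegionCounts,
    reference: ReferenceModel,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    allow_missing: bool = False,
) -> CLixResult:
    """Score one case against a reference.

    The composite is

        Q = (w_r * ratio_pct + w_h * hippocampal_pct + w_c * (100 - cortical_pct))
            / (w_r + w_h + w_c)
        score = 0.4 * Q

    with equal weights by default.  ``hippocampal_pct`` is the mean of the
    CA1 and subiculum percentiles, ``cortical_pct`` the mean of the three
    cortical percentiles, and ``ratio_pct`` the percentile of this case's
    hippocampal:cortical ratio among the reference ratios.

    If ``counts`` has missing regions they are only tolerated when
    ``allow_missing=True``, in which case each compartment mean is taken over
    the available regions (and the substitution is logged).
    """
    if counts.has_missing:
        if not allow_missing:
            raise ValidationError(
                "case has missing regions; pass allow_missing=True to score "
                "from the available regions of each compartment"
            )
        missing = [r for r in REGIONS if math.isnan(getattr(counts, r))]
        logger.warning(
            "scoring with missing regions %s using mean of available regions",
            missing,
        )
    w_r, w_h, w_c = weights
    if min(weights) < 0 or (w_r + w_h + w_c) <= 0:
        raise ValidationError("weights must be non-negative with positive sum")

    def compartment_pct(regions: tuple[str, ...]) -> float:
        pcts = [
            percentile(getattr(counts, r), reference.per_region_counts[r])
            for r in regions
            if not math.isnan(getattr(counts, r))
        ]
        return float(np.mean(pcts))

    hipp_pct = compartment_pct(HIPPOCAMPAL_REGIONS)
    cort_pct = compartment_pct(CORTICAL_REGIONS)
    ratio = hippocampal_cortical_ratio(counts, reference.pseudocount)
    ratio_pct = percentile(ratio, reference.ratio_values)

    q = (w_r * ratio_pct + w_h * hipp_pct + w_c * (100.0 - cort_pct)) / (
        w_r + w_h + w_c
    )
    score = SCORE_SCALE * q
    # guard against float drift at the boundaries
    score = min(max(score, 0.0), 40.0)
    return CLixResult(
        score=score,
        hippocampal_pct=hipp_pct,
        cortical_pct=cort_pct,
        ratio=ratio,
        ratio_pct=ratio_pct,
        subtype=classify_subtype(score),
    )
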