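"""Rule-based histopathology disease classification and cohort statistics.

Each tissue slide is scored by up to three blinded observers who count
histopathological abnormalities.  Per observer and tissue, a cutoff is set
from control animals as mean + 2 SD of the abnormality counts; an observer
marks a tissue "diseased" when the count strictly exceeds that cutoff, and
the tissue is declared diseased only when at least two of three observers
agree.  Ovarian disease (primordial-follicle loss, polycystic ovaries) and
the obese/lean phenotypes use analogous control-referenced cutoffs (2 SD
for the ovary, 1.5 SD for adiposity).  Cohort summaries report, per
disease, affected / evaluated counts with unevaluated animals excluded
from denominators, plus the multiple-disease tally (animals with two or
more classified pathologies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObserverScore",
    "AnimalRecord",
    "OvaryMeasurements",
    "CohortSummary",
    "observer_threshold",
    "classify_tissue",
    "classify_ovary",
    "classify_adiposity",
    "bmi",
    "adipocyte_mean_area",
    "summarize_cohort",
    "fisher_exact_2x2",
    "t_test_two_tailed",
    "load_f3_vinclozolin_males",
    "read_animal_records",
]

TISSUES = ("testis", "prostate", "kidney_m", "kidney_f", "ovary")

#: Disease columns counted toward the multiple-disease tally.
DISEASE_NAMES = (
    "early_puberty",
    "late_puberty",
    "testis",
    "prostate",
    "kidney",
    "tumor",
    "lean",
    "obese",
)


@dataclass(frozen=True)
class ObserverScore:
    animal_id: str
    tissue: str
    observer: int
    abnormality_count: int

    def __post_init__(self) -> None:
        if self.abnormality_count < 0:
            raise ValueError("abnormality_count must be non-negative")


@dataclass
class AnimalRecord:
    """One animal's disease calls and continuous phenotypes.

    ``disease_flags`` maps disease name -> True/False/None; None means the
    tissue was not evaluated for this animal and the animal is excluded
    from that disease's denominator.
    """

    animal_id: str
    disease_flags: dict[str, Optional[bool]] = field(default_factory=dict)
    lineage: Optional[str] = None
    generation: Optional[str] = None
    sex: Optional[str] = None
    puberty_age_days: Optional[float] = None
    wean_weight_g: Optional[float] = None
    body_weight_g: Optional[float] = None
    body_length_cm: Optional[float] = None
    adipocyte_mean_area_um2: Optional[float] = None

    def n_diseases(self) -> int:
        return sum(1 for v in self.disease_flags.values() if v is True)


@dataclass(frozen=True)
class OvaryMeasurements:
    animal_id: str
    primordial_follicle_counts: tuple[int, int, int]
    small_cyst_counts: tuple[int, int, int]
    large_cyst_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for name in ("primordial_follicle_counts", "small_cyst_counts", "large_cyst_counts"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name}: exactly three sections required")


@dataclass
class CohortSummary:
    affected: dict[str, int]
    evaluated: dict[str, int]
    frequency: dict[str, float]
    multiple_disease_affected: int
    multiple_disease_evaluated: int
    total_disease_distribution: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "disease": d,
                "affected": self.affected[d],
                "evaluated": self.evaluated[d],
                "frequency": self.frequency[d],
            }
            for d in self.affected
        ]
        rows.append(
            {
                "disease": "multiple",
                "affected": self.multiple_disease_affected,
                "evaluated": self.multiple_disease_evaluated,
                "frequency": (
                    self.multiple_disease_affected / self.multiple_disease_evaluated
                    if self.multiple_disease_evaluated
                    else float("nan")
                ),
            }
        )
        return pd.DataFrame(rows)


def observer_threshold(
    control_scores: Iterable[ObserverScore],
) -> dict[tuple[str, int], float]:
    """Per-(tissue, observer) cutoff = control mean + 2 * sample SD.

    The SD uses the n-1 denominator.  At least two control scores are
    required per (tissue, observer); anything less is an error rather than
    a silent default.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for s in control_scores:
        groups.setdefault((s.tissue, s.observer), []).append(s.abnormality_count)
    if not groups:
        raise ValueError("no control scores supplied")
    cutoffs: dict[tuple[str, int], float] = {}
    for key, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"need >=2 control scores for tissue/observer {key}, got {len(vals)}"
            )
        arr = np.asarray(vals, dtype=float)
        cutoffs[key] = float(arr.mean() + 2.0 * arr.std(ddof=1))
    return cutoffs


def classify_tissue(
    scores: Sequence[ObserverScore],
    cutoffs: Mapping[tuple[str, int], float],
) -> bool:
    """2-of-3 observer consensus call for one (animal, tissue).

    An observer marks diseased iff their abnormality count strictly
    exceeds their cutoff.  With all three observers present the tissue is
    diseased iff at least two mark it.  With only two observers present,
    both must agree (conservative consensus); fewer than two observers is
    an error, as is more than three.
    """
    if not scores:
        raise ValueError("no scores supplied")
    animals = {s.animal_id for s in scores}
    tissues = {s.tissue for s in scores}
    if len(animals) != 1 or len(tissues) != 1:
        raise ValueError("scores must be for a single (animal, tissue)")
    observers = [s.observer for s in scores]
    if len(set(observers)) != len(observers):
        raise ValueError("duplicate observer for one tissue")
    if len(scores) > 3:
        raise ValueError(f"more than 3 observers: {sorted(observers)}")
    if len(scores) < 2:
        raise ValueError("need at least 2 observers for a consensus call")
    marks = 0
    for s in scores:
        key = (s.tissue, s.observer)
        if key not in cutoffs:
            raise KeyError(f"no cutoff for tissue/observer {key}")
        if s.abnormality_count > cutoffs[key]:
            marks += 1
    if len(scores) == 3:
        return marks >= 2
    return marks == 2  # two observers present: unanimity required


@dataclass(frozen=True)
class OvaryControlStats:
    follicle_mean: float
    follicle_sd: float
    small_cyst_mean: float
    small_cyst_sd: float
    large_cyst_mean: float
    large_cyst_sd: float

    @classmethod
    def from_controls(cls, controls: Sequence[OvaryMeasurements]) -> "OvaryControlStats":
        if len(controls) < 2:
            raise ValueError("need >=2 control animals for ovary statistics")

        def ms(attr: str) -> tuple[float, float]:
            means = np.array([np.mean(getattr(c, attr)) for c in controls])
            return float(means.mean()), float(means.std(ddof=1))

        f = ms("primordial_follicle_counts")
        s = ms("small_cyst_counts")
        l = ms("large_cyst_counts")
        return cls(f[0], f[1], s[0], s[1], l[0], l[1])


def classify_ovary(
    m: OvaryMeasurements, control_stats: OvaryControlStats
) -> dict[str, bool]:
    """Follicle-loss and polycystic calls from section-averaged counts.

    Follicle loss: the animal's mean primordial-follicle count (over three
    sections) is strictly below the control mean minus 2 SD.  Polycystic:
    the mean small and/or large cyst count is strictly above the control
    mean plus 2 SD.  Boundary values are healthy (strict inequalities).
    """
    fol = float(np.mean(m.primordial_follicle_counts))
    small = float(np.mean(m.small_cyst_counts))
    large = float(np.mean(m.large_cyst_counts))
    cs = control_stats
    follicle_loss = fol < cs.follicle_mean - 2.0 * cs.follicle_sd
    polycystic = (small > cs.small_cyst_mean + 2.0 * cs.small_cyst_sd) or (
        large > cs.large_cyst_mean + 2.0 * cs.large_cyst_sd
    )
    return {"follicle_loss": follicle_loss, "polycystic": polycystic}


def bmi(body_weight_g: float, body_length_cm: float) -> float:
    """Body-mass index at one year: weight (g) / length (cm)^2."""
    if body_length_cm is None or not body_length_cm > 0:
        raise ValueError("body length required and must be positive for BMI")
    return body_weight_g / body_length_cm**2


def adipocyte_mean_area(per_image_areas: Sequence[Sequence[float]], top_n: int = 20) -> float:
    """Mean area of the ``top_n`` largest adipocytes from each image.

    With five images and the 20 largest cells each, 100 hypertrophic cells
    enter the mean (the metabolically relevant fraction).
    """
    selected: list[float] = []
    for areas in per_image_areas:
        arr = sorted(areas, reverse=True)[:top_n]
        if not arr:
            raise ValueError("image with no measured cells")
        selected.extend(arr)
    return float(np.mean(selected))


@dataclass(frozen=True)
class AdiposityControlStats:
    adipocyte_mean: float
    adipocyte_sd: float
    bmi_mean: float
    bmi_sd: float


def classify_adiposity(
    record: AnimalRecord,
    control_stats: AdiposityControlStats,
    require_both: bool = True,
) -> str:
    """Obese / lean / normal call from adipocyte area and BMI.

    Cutoffs sit 1.5 SD above/below the control mean (per sex, upstream).
    By default both criteria (adipocyte area and BMI) must exceed their
    cutoff for "obese" (or fall below for "lean"); ``require_both=False``
    flags an animal on either criterion.
    """
    if record.adipocyte_mean_area_um2 is None:
        raise ValueError(f"{record.animal_id}: adipocyte area missing")
    if record.body_weight_g is None or record.body_length_cm is None:
        raise ValueError(f"{record.animal_id}: body weight/length required for BMI")
    b = bmi(record.body_weight_g, record.body_length_cm)
    cs = control_stats
    area = record.adipocyte_mean_area_um2
    area_hi = area > cs.adipocyte_mean + 1.5 * cs.adipocyte_sd
    area_lo = area < cs.adipocyte_mean - 1.5 * cs.adipocyte_sd
    bmi_hi = b > cs.bmi_mean + 1.5 * cs.bmi_sd
    bmi_lo = b < cs.bmi_mean - 1.5 * cs.bmi_sd
    if require_both:
        if area_hi and bmi_hi:
            return "obese"
        if area_lo and bmi_lo:
            return "lean"
    else:
        if area_hi or bmi_hi:
            return "obese"
        if area_lo or bmi_lo:
            return "lean"
    return "normal"


def summarize_cohort(
    records: Sequence[AnimalRecord],
    diseases: Sequence[str] = DISEASE_NAMES,
) -> CohortSummary:
    """Affected / evaluated tallies per disease plus the multiple-disease count.

    A flag of None means "not evaluated" and removes the animal from that
    disease's denominator (the printed populations differ per column for
    exactly this reason).  Every animal enters the multiple-disease
    denominator; an animal is multiple-diseased when two or more of its
    evaluated flags are True.
    """
    seen: set[str] = set()
    for r in records:
        if r.animal_id in seen:
            raise ValueError(f"duplicate animal_id: {r.animal_id}")
        seen.add(r.animal_id)
    affected = {d: 0 for d in diseases}
    evaluated = {d: 0 for d in diseases}
    multiple = 0
    dist: dict[int, int] = {}
    for r in records:
        n_true = 0
        for d in diseases:
            flag = r.disease_flags.get(d)
            if flag is None:
                continue
            evaluated[d] += 1
            if flag:
                affected[d] += 1
                n_true += 1
        if n_true >= 2:
            multiple += 1
        dist[n_true] = dist.get(n_true, 0) + 1
    frequency = {
        d: (affected[d] / evaluated[d]) if evaluated[d] else float("nan")
        for d in diseases
    }
    return CohortSummary(
        affected=affected,
        evaluated=evaluated,
        frequency=frequency,
        multiple_disease_affected=multiple,
        multiple_disease_evaluated=len(records),
        total_disease_distribution=dict(sorted(dist.items())),
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities no greater than that of the observed
    table, margins fixed.
    """
    for x in (a, b, c, d):
        if not float(x).is_integer() or x < 0:
            raise ValueError("table entries must be non-negative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0))


def t_test_two_tailed(x: Sequence[float], y: Sequence[float]) -> float:
    """Classical equal-variance two-sample t-test, two-tailed p.

    Degenerate convention: if the pooled variance is zero, p = 1 when the
    means are equal and p = 0 when they differ (the statistic diverges).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    sx = x.var(ddof=1)
    sy = y.var(ddof=1)
    if sx == 0 and sy == 0:
        return 1.0 if math.isclose(x.mean(), y.mean()) else 0.0
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.pvalue)


def t_statistic(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pooled-variance t statistic and its degrees of freedom (nx + ny - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), len(x) + len(y) - 2


# ---------------------------------------------------------------------------
# Record I/O


def _parse_flag(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    if s in ("", "nan", "NA"):
        return None
    if s in ("+", "1", "True", "true"):
        return True
    if s in ("-", "0", "False", "false"):
        return False
    raise ValueError(f"unparseable disease flag: {v!r}")


def read_animal_records(path_or_frame, diseases: Sequence[str] = DISEASE_NAMES) -> list[AnimalRecord]:
    """Read a tidy TSV of per-animal disease flags ('+', '-', blank=NA)."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame
    else:
        df = pd.read_csv(path_or_frame, sep="\t", dtype=str, keep_default_na=False)
    records = []
    extra = {"lineage", "generation", "sex"} & set(df.columns)
    for _, row in df.iterrows():
        flags = {d: _parse_flag(row[d]) for d in diseases if d in df.columns}
        kw = {k: row[k] for k in extra}
        records.append(AnimalRecord(animal_id=row["animal_id"], disease_flags=flags, **kw))
    return records


def load_f3_vinclozolin_males() -> list[AnimalRecord]:
    """The transgenerational F3 vinclozolin male cohort, transcribed per animal."""
    ref = resources.files("epimark.data") / "table1_f3_vinclozolin_males.tsv"
    with resources.as_file(ref) as path:
        return read_animal_records(path)
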