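"""White-matter-hyperintensity bookkeeping and laterality scoring.

Lesions arrive as annotated records — region (vertebral, basilar or
posterior-cerebral-artery territory), side of the virtual falx split, the
maximum in-plane diameter and confluence flags — the way a blinded FLAIR
reader would tabulate them. Each region-side is rated on the ARWMC ordinal
scale (0 none, 1 focal only, 2 beginning confluence, 3 diffuse
involvement); within a region, the side with the higher score carries the
WMH laterality, ties are broken by counting lesions >= 5 mm, and a double
tie is classed 'even'. Subjects with any lesion form the WMH group; the
posterior-communicating-artery gate selects subjects in whom the basilar
artery plausibly feeds both posterior cerebral arteries (both PCom
hypoplastic/no-flow) and who carry PCA-region lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "REGIONS",
    "LesionRecord",
    "SubjectRecord",
    "arwmc_score",
    "region_laterality",
    "assign_group",
    "pcom_subset",
    "score_cohort",
    "TIEBREAK_MM",
]

REGIONS = ("VA", "BA", "PCA")
SIDES = ("left", "right")
TIEBREAK_MM = 5.0  # only lesions at least this large enter the tie-break count


@dataclass(frozen=True)
class LesionRecord:
    """One WMH lesion on the FLAIR read."""

    region: str       # VA | BA | PCA
    side: str         # left | right
    diameter_mm: float
    confluent: bool = False
    diffuse: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")
        if self.diffuse and not self.confluent:
            raise ValueError("a diffuse lesion is by definition confluent")


@dataclass
class SubjectRecord:
    """Covariates plus the lesion list and the scores derived from it."""

    subject_id: int
    age: float
    sex: str
    hypertension: bool = False
    diabetes: bool = False
    hyperlipidemia: bool = False
    pcom_left: str = "flow detected"    # or "hypoplastic/no flow"
    pcom_right: str = "flow detected"
    lesions: list = field(default_factory=list)

    @property
    def group(self) -> str:
        return assign_group(self)

    def region_scores(self) -> dict:
        """(region, side) -> ARWMC score for all six region-sides."""
        return {(rg, sd): arwmc_score([l for l in self.lesions
                                       if l.region == rg and l.side == sd])
                for rg in REGIONS for sd in SIDES}

    def region_lateralities(self) -> dict:
        scores = self.region_scores()
        out = {}
        for rg in REGIONS:
            out[rg] = region_laterality(
                scores[(rg, "left")], scores[(rg, "right")],
                [l for l in self.lesions if l.region == rg])
        return out


def arwmc_score(lesions) -> int:
    """ARWMC ordinal rating of one region-side.

    0 = no lesions; 1 = focal lesions only; 2 = beginning confluence
    (any confluent lesion); 3 = diffuse involvement. All input lesions must
    share region and side.
    """
    lesions = list(lesions)
    if not lesions:
        return 0
    keys = {(l.region, l.side) for l in lesions}
    if len(keys) > 1:
        raise ValueError(f"lesions span multiple region-sides: {sorted(keys)}")
    if any(l.diffuse for l in lesions):
        return 3
    if any(l.confluent for l in lesions):
        return 2
    return 1


def region_laterality(left_score: int, right_score: int, lesions) -> str:
    """Dominant WMH side of one region.

    The higher ARWMC score wins; on equal scores the side with more lesions
    >= 5 mm wins; a double tie is 'even'. Focal lesions under 5 mm count
    for presence (and hence the score) but not for the tie-break.
    """
    for s in (left_score, right_score):
        if s not in (0, 1, 2, 3):
            raise ValueError(f"ARWMC score must be 0-3, got {s}")
    if left_score != right_score:
        return "left" if left_score > right_score else "right"
    counts = {"left": 0, "right": 0}
    for l in lesions:
        if l.diameter_mm >= TIEBREAK_MM:
            counts[l.side] += 1
    if counts["left"] != counts["right"]:
        return "left" if counts["left"] > counts["right"] else "right"
    return "even"


def assign_group(subject) -> str:
    """'WMH' iff the subject carries at least one lesion, else 'control'."""
    lesions = subject.lesions if hasattr(subject, "lesions") else subject
    return "WMH" if len(lesions) > 0 else "control"


def pcom_subset(cohort: pd.DataFrame, lesions: pd.DataFrame) -> pd.DataFrame:
    """Subjects eligible for the PCA-laterality regression: both posterior
    communicating arteries hypoplastic/no-flow AND at least one PCA-region
    lesion. Requires a ``pcom_status`` column (or ``pcom_left``/``pcom_right``).
    """
    if "pcom_status" in cohort.columns:
        both_absent = cohort["pcom_status"] == "both_absent"
    elif {"pcom_left", "pcom_right"}.issubset(cohort.columns):
        both_absent = ((cohort["pcom_left"] == "hypoplastic/no flow")
                       & (cohort["pcom_right"] == "hypoplastic/no flow"))
    else:
        raise ValueError("missing PCom status columns")
    with_pca = cohort["subject_id"].isin(
        lesions.loc[lesions["region"] == "PCA", "subject_id"].unique())
    return cohort[both_absent & with_pca].copy()


def score_cohort(subjects: pd.DataFrame, lesions: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a cohort table: group membership, per
    region-side ARWMC scores and per-region lateralities."""
    recs = {sid: [] for sid in subjects["subject_id"]}
    for row in lesions.itertuples(index=False):
        recs[row.subject_id].append(LesionRecord(
            region=row.region, side=row.side, diameter_mm=row.diameter_mm,
            confluent=bool(row.confluent), diffuse=bool(row.diffuse)))
    out = subjects.copy()
    out["group"] = [assign_group(recs[s]) for s in out["subject_id"]]
    for rg in REGIONS:
        scores = {}
        lats = []
        for s in out["subject_id"]:
            region_lesions = [l for l in recs[s] if l.region == rg]
            sc = {sd: arwmc_score([l for l in region_lesions if l.side == sd])
                  for sd in SIDES}
            scores[s] = sc
            lats.append(region_laterality(sc["left"], sc["right"], region_lesions))
        for sd in SIDES:
            out[f"score_{rg}_{sd}"] = [scores[s][sd] for s in out["subject_id"]]
        out[f"lat_{rg}"] = lats
    return out
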