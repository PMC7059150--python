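"""Cohort stratification from donor disease annotations.

A tissue's samples are split into:

* ``disease_free`` — donor has no disease annotation of any kind;
* ``tissue_healthy`` — donor has none of the disease codes deemed relevant to
  the tissue and passes any tissue-specific predicate (e.g. for adipose:
  no type-2 diabetes AND BMI < 30);
* ``tissue_disease`` — the complement of tissue_healthy among retained
  samples;
* ``common`` — all retained samples (the general-population cohort).

An additional "unhealthy" aging cohort pools young tissue-healthy donors
with old donors meeting the full disease predicate; young donors meeting the
disease predicate are excluded because their disease is not age-associated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: clinical obesity boundary; BMI at or above counts as obese
DEFAULT_BMI_CUTOFF = 30.0


@dataclass
class TissueRule:
    """Disease codes relevant to one tissue, plus optional predicates."""

    codes: frozenset[str]
    bmi_cutoff: float | None = None  # BMI >= cutoff counts as diseased

    def __post_init__(self) -> None:
        self.codes = frozenset(self.codes)


@dataclass
class TissueDiseaseMap:
    """tissue name -> rule determining tissue-relevant disease."""

    rules: dict[str, TissueRule] = field(default_factory=dict)

    def __getitem__(self, tissue: str) -> TissueRule:
        try:
            return self.rules[tissue]
        except KeyError:
            raise KeyError(
                f"tissue {tissue!r} has no disease rule; known tissues: "
                f"{sorted(self.rules)}"
            ) from None

    @classmethod
    def from_dict(cls, d: dict) -> "TissueDiseaseMap":
        rules = {}
        for tissue, entry in d.items():
            if isinstance(entry, (list, set, tuple)):
                rules[tissue] = TissueRule(codes=frozenset(entry))
            else:
                rules[tissue] = TissueRule(
                    codes=frozenset(entry.get("codes", ())),
                    bmi_cutoff=entry.get("bmi_cutoff"),
                )
        return cls(rules)


def default_tissue_map() -> TissueDiseaseMap:
    """Rules for the three tissues whose healthy definitions are explicit:
    subcutaneous fat (no T2D, BMI < 30), tibial artery (no ischemic heart
    disease / heart attack / acute coronary syndrome), and lung (no chronic
    respiratory disease, asthma, or pneumonia).
    """
    return TissueDiseaseMap.from_dict(
        {
            "subcutaneous_fat": {"codes": ["T2D"], "bmi_cutoff": DEFAULT_BMI_CUTOFF},
            "tibial_artery": {
                "codes": [
                    "ischemic_heart_disease",
                    "heart_attack",
                    "acute_coronary_syndrome",
                ]
            },
            "lung": {"codes": ["chronic_respiratory_disease", "asthma", "pneumonia"]},
        }
    )


def _parse_codes(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    if isinstance(value, str):
        return frozenset(c.strip() for c in value.split(";") if c.strip())
    return frozenset(value)


def assign_cohorts(
    donors: pd.DataFrame,
    samples: pd.DataFrame,
    tissue: str,
    tissue_map: TissueDiseaseMap,
) -> pd.DataFrame:
    """Label each sample of a tissue with its cohort memberships.

    Returns a per-sample frame indexed like ``samples`` with boolean columns
    ``disease_free``, ``tissue_healthy``, ``tissue_disease``, ``common``,
    ``excluded`` and a string ``exclude_reason``. Donors with duplicate
    samples for the tissue keep only the highest-RIN sample. A donor whose
    BMI is missing where a BMI predicate applies is excluded with a logged
    reason rather than silently classified.
    """
    rule = tissue_map[tissue]
    samp = samples.loc[samples["tissue"] == tissue].copy()
    if len(samp) != len(samples):
        raise ValueError(
            f"{len(samples) - len(samp)} samples are not from tissue {tissue!r}"
        )
    # one sample per donor: keep highest RIN
    samp = samp.sort_values("rin", ascending=False, kind="mergesort")
    dup = samp.duplicated(subset="donor_id", keep="first")
    if dup.any():
        logger.warning("dropping %d duplicate samples (kept highest RIN)", dup.sum())
    samp = samp.loc[~dup].sort_index()

    merged = samp.merge(donors, on="donor_id", how="left", validate="one_to_one")
    codes = merged["disease_codes"].map(_parse_codes)
    n_missing_codes = merged["disease_codes"].isna().sum()
    if n_missing_codes:
        logger.warning(
            "%d donors have missing disease annotations; treated as absent",
            n_missing_codes,
        )

    disease_free = codes.map(len) == 0
    has_relevant = codes.map(lambda c: bool(c & rule.codes))

    excluded = pd.Series(False, index=merged.index)
    reason = pd.Series("", index=merged.index)
    if rule.bmi_cutoff is not None:
        bmi = merged["bmi"]
        missing_bmi = bmi.isna()
        if missing_bmi.any():
            logger.warning(
                "%d donors missing BMI where a BMI predicate applies; excluded",
                missing_bmi.sum(),
            )
            excluded |= missing_bmi
            reason[missing_bmi] = "missing BMI under BMI predicate"
        obese = bmi >= rule.bmi_cutoff
        tissue_healthy = ~has_relevant & ~obese.fillna(True)
    else:
        tissue_healthy = ~has_relevant

    tissue_healthy &= ~excluded
    tissue_disease = ~tissue_healthy & ~excluded
    common = ~excluded

    out = pd.DataFrame(
        {
            "sample_id": merged["sample_id"],
            "donor_id": merged["donor_id"],
            "disease_free": disease_free & ~excluded,
            "tissue_healthy": tissue_healthy,
            "tissue_disease": tissue_disease,
            "common": common,
            "excluded": excluded,
            "exclude_reason": reason,
        }
    )
    return out.reset_index(drop=True)


def build_unhealthy_cohort(
    assignment: pd.DataFrame,
    donors: pd.DataFrame,
    rule: TissueRule | None = None,
    young_range: tuple[float, float] = (20.0, 40.0),
    old_range: tuple[float, float] = (40.0, 70.0),
) -> list[str]:
    """Pool young tissue-healthy donors with old donors meeting the full
    disease predicate.

    The old arm requires the tissue-relevant disease annotation AND, where a
    BMI predicate applies to the tissue (adipose), BMI at or above the cutoff
    — i.e. T2D and obesity jointly, not either alone. Without a ``rule`` the
    old arm is simply the tissue-disease cohort. Ages are handled as
    young = [young_lo, young_hi) and old = [old_lo, old_hi], so a
    boundary-age donor falls in the old arm. Young donors who meet the
    disease criteria are excluded outright: their disease is not a
    consequence of aging, and retaining them masks age association.

    Returns the selected sample ids.
    """
    cols = ["donor_id", "age", "disease_codes"] + (
        ["bmi"] if "bmi" in donors.columns else []
    )
    merged = assignment.merge(
        donors[cols], on="donor_id", how="left", validate="one_to_one"
    )
    age = merged["age"]
    young = (age >= young_range[0]) & (age < young_range[1])
    old = (age >= old_range[0]) & (age <= old_range[1])
    diseased = merged["tissue_disease"].copy()
    if rule is not None:
        codes = merged["disease_codes"].map(_parse_codes)
        diseased &= codes.map(lambda c: bool(c & rule.codes))
        if rule.bmi_cutoff is not None:
            diseased &= (merged["bmi"] >= rule.bmi_cutoff).fillna(False)
    keep = (merged["tissue_healthy"] & young) | (diseased & old)
    result = merged.loc[keep, "sample_id"].tolist()
    if not result:
        warnings.warn("unhealthy cohort is empty", stacklevel=2)
    return result


def check_tissue_eligibility(assignment: pd.DataFrame) -> dict:
    """Apply the two sample-size gates for a tissue.

    * ``analysis_eligible``: strictly more than 80 retained samples;
    * ``healthy_vs_disease_eligible``: strictly more than 20% of retained
      samples come from tissue-disease donors.
    """
    n = int(assignment["common"].sum())
    n_disease = int(assignment["tissue_disease"].sum())
    disease_fraction = n_disease / n if n else 0.0
    return {
        "n_samples": n,
        "n_disease": n_disease,
        "disease_fraction": disease_fraction,
        "analysis_eligible": n > 80,
        "healthy_vs_disease_eligible": n > 0 and disease_fraction > 0.20,
    }
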