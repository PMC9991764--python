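"""Generator parameters for the synthetic high-CVD-risk cohort.

The defaults encode the study conditions the cohort emulates: n = 122
participants aged 56.0 +/- 12.6 y, 55.7% male, mean 24-h urinary sodium
around 2810 mg/d, roughly 90% of dietary sodium excreted in urine,
dietary-recall underreporting, a discretionary-salt share of ~15% of total
intake, and 7.4% incomplete urine collections.
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator


class GeneratorParams(BaseModel):
    """All knobs of the synthetic-cohort generator.

    Fractions are in [0, 1]; coefficients of variation (cv) are sd/mean of
    the corresponding multiplicative noise and must be non-negative.
    """

    model_config = {"frozen": True}

    n_participants: int = Field(default=122, ge=2)
    # True usual intake: mean chosen so that excretion_fraction * mean
    # reproduces the target mean 24-h urinary Na of ~2810 mg/d.
    mean_true_na: float = Field(default=3120.0, gt=0, description="mg/day")
    cv_true_na: float = Field(default=0.39, ge=0)
    excretion_fraction: float = Field(default=0.90, ge=0, le=1)
    day_cv_urine: float = Field(default=0.25, ge=0)
    recall_underreport_mean: float = Field(default=0.70, gt=0, le=1.2)
    recall_underreport_sd: float = Field(default=0.10, ge=0)
    recall_day_cv: float = Field(default=0.15, ge=0)
    discretionary_share: float = Field(default=0.15, ge=0, le=1)
    ffq_error_cv: float = Field(default=0.35, ge=0)
    spot_noise_cv: float = Field(default=0.50, ge=0)
    # Correlation (log scale) between spot concentrations and the day's
    # 24-h excretion; free parameter, no published generative model exists.
    spot_corr: float = Field(default=0.60, ge=-1, le=1)
    # Multiplies spot Na concentration; >1 pushes the spot conversion
    # equations toward overestimation of 24UNa.
    spot_scale: float = Field(default=1.0, gt=0)
    incomplete_collection_rate: float = Field(default=0.074, ge=0, le=1)
    pct_male: float = Field(default=0.557, ge=0, le=1)
    age_mean: float = Field(default=56.0, gt=0, description="years")
    age_sd: float = Field(default=12.6, ge=0)
    # Share of food-sourced Na carried by the Na-rich items that only the
    # extended NaFFQ asks about (the standard FFQ structurally misses it).
    naffq_item_share: float = Field(default=0.10, ge=0, le=1)
    # Instrument availability, emulating the study's per-method sample
    # sizes (spot 71, recalls 119, FFQ 87, NaFFQ 60 of 122). NaFFQ
    # respondents are a nested subset of FFQ respondents.
    frac_spot: float = Field(default=71 / 122, ge=0, le=1)
    frac_recall: float = Field(default=119 / 122, ge=0, le=1)
    frac_ffq: float = Field(default=87 / 122, ge=0, le=1)
    frac_naffq: float = Field(default=60 / 122, ge=0, le=1)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_nesting(self) -> "GeneratorParams":
        if self.frac_naffq > self.frac_ffq:
            raise ValueError("frac_naffq: NaFFQ respondents must be a subset of FFQ respondents")
        return self
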