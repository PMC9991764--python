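"""Score every estimation method on a cohort, producing the long-form
estimates table (participant_id, method_id, na_mg_per_day).

Method ids: u24 (reference), spot_kawasaki, spot_tanaka, spot_intersalt_k,
spot_intersalt_nok, spot_mage, spot_toft, dr24, dr24_sq, dr24_p15, ffq,
naffq. The vectorised pandas path used here is checked against the
per-object scorers of :mod:`dietna.dietary` in the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortBundle
from .dietary import (
    FREQUENCY_WEIGHTS,
    NA_MG_PER_DASH,
    Q1_RATES,
    QUESTION_B_RATES,
    FoodCompositionTable,
)
from .urinary import NA_MG_PER_MMOL, SPOT_EQUATION_IDS, evaluate_spot_equation

METHOD_IDS = (
    "u24",
    "spot_kawasaki",
    "spot_tanaka",
    "spot_intersalt_k",
    "spot_intersalt_nok",
    "spot_mage",
    "spot_toft",
    "dr24",
    "dr24_sq",
    "dr24_p15",
    "ffq",
    "naffq",
)

_SPOT_METHOD = {
    "kawasaki": "spot_kawasaki",
    "tanaka": "spot_tanaka",
    "intersalt_with_k": "spot_intersalt_k",
    "intersalt_without_k": "spot_intersalt_nok",
    "mage": "spot_mage",
    "toft": "spot_toft",
}


def score_u24(urine24: pd.DataFrame) -> pd.Series:
    """24-h urinary Na (mg/day) per participant."""
    values = urine24["na_mmol_l"] * urine24["volume_l"] * NA_MG_PER_MMOL
    return pd.Series(values.to_numpy(), index=urine24["participant_id"], name="u24")


def score_spot(spot: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """All six spot-equation estimates (mg/day); one column per method."""
    if spot.empty:
        return pd.DataFrame(columns=list(_SPOT_METHOD.values()))
    merged = spot.merge(profiles, on="participant_id", validate="one_to_one")
    out = {}
    for eq in SPOT_EQUATION_IDS:
        out[_SPOT_METHOD[eq]] = evaluate_spot_equation(
            eq,
            sex=merged["sex"].to_numpy(),
            age=merged["age_y"].to_numpy(),
            weight=merged["weight_kg"].to_numpy(),
            height=merged["height_cm"].to_numpy(),
            spot_na=merged["na_mmol_l"].to_numpy(),
            spot_k=merged["k_mmol_l"].to_numpy(),
            spot_creat=merged["creat_mg_dl"].to_numpy(),
        )
    return pd.DataFrame(out, index=pd.Index(merged["participant_id"], name="participant_id"))


def score_recalls(
    recalls: pd.DataFrame,
    dashes_per_yes: int = 2,
    dr15_share: float = 0.15,
    dr15_mode: str = "share_of_total",
) -> pd.DataFrame:
    """dr24, dr24_sq and dr24_p15 (mg/day) per participant."""
    if recalls.empty:
        return pd.DataFrame(columns=["dr24", "dr24_sq", "dr24_p15"])
    df = recalls.copy()
    df["item_na"] = df["item_grams"] * df["item_na_mg_per_100g"] / 100.0
    per_recall = df.groupby(["participant_id", "recall_idx"])["item_na"].sum()
    dr24 = per_recall.groupby("participant_id").mean()

    main = df[df["meal"].isin(("breakfast", "lunch", "dinner"))].copy()
    meal_grams = main.groupby(["participant_id", "recall_idx", "meal"]).agg(
        grams=("item_grams", "sum"), q1=("q1", "first"), q2=("q2", "first")
    )
    q1_rate = meal_grams["q1"].map(Q1_RATES).fillna(0.0)
    q1_sodium = q1_rate * meal_grams["grams"] / 100.0
    q2_sodium = np.where(meal_grams["q2"] == "yes", NA_MG_PER_DASH * dashes_per_yes, 0.0)
    sq_per_recall = (q1_sodium + q2_sodium).groupby(["participant_id", "recall_idx"]).sum()
    sq_mean = sq_per_recall.groupby("participant_id").mean().reindex(dr24.index, fill_value=0.0)

    if not 0 <= dr15_share < 0.5:
        raise ValueError("dr15_share must be in [0, 0.5)")
    if dr15_mode == "share_of_total":
        dr15 = dr24 / (1.0 - dr15_share)
    elif dr15_mode == "markup":
        dr15 = dr24 * (1.0 + dr15_share)
    else:
        raise ValueError(f"unknown dr15_mode {dr15_mode!r}")
    return pd.DataFrame({"dr24": dr24, "dr24_sq": dr24 + sq_mean, "dr24_p15": dr15})


def score_ffq(ffq: pd.DataFrame, table: FoodCompositionTable | None = None) -> pd.DataFrame:
    """ffq (standard scoring) and naffq (extended scoring) per participant.

    The standard score uses only the standard food list and ignores
    question b; the NaFFQ score (for NaFFQ respondents) uses the full
    extended list plus question-b sodium on cooked meals and salads.
    """
    if ffq.empty:
        return pd.DataFrame(columns=["ffq", "naffq"])
    table = table or FoodCompositionTable.bundled()
    comp = table.table
    df = ffq.merge(
        comp[["na_mg_per_100g", "is_cooked_meal_or_salad"]].join(
            comp.get("naffq_addition", pd.Series(0, index=comp.index)).rename("naffq_addition")
        ),
        left_on="item_id",
        right_index=True,
        how="left",
        validate="many_to_one",
    )
    if df["na_mg_per_100g"].isna().any():
        missing = sorted(df.loc[df["na_mg_per_100g"].isna(), "item_id"].unique())
        raise KeyError(f"unresolvable composition items: {missing}")
    df["weight"] = df["freq_cat"].map(FREQUENCY_WEIGHTS)
    if df["weight"].isna().any():
        bad = sorted(df.loc[df["weight"].isna(), "freq_cat"].unique())
        raise ValueError(f"unknown frequency categories: {bad}")
    df["daily_g"] = df["weight"] * df["portion_g"]
    df["item_na"] = df["daily_g"] * df["na_mg_per_100g"] / 100.0

    standard = df[df["naffq_addition"] == 0].groupby("participant_id")["item_na"].sum()

    naffq_df = df[df["naffq"] == 1].copy()
    if naffq_df.empty:
        naffq = pd.Series(dtype=float, name="naffq")
    else:
        base = naffq_df.groupby("participant_id")["item_na"].sum()
        qb_rate = naffq_df["question_b"].map(QUESTION_B_RATES)
        if qb_rate.isna().any():
            bad = sorted(naffq_df.loc[qb_rate.isna(), "question_b"].unique())
            raise ValueError(f"unknown question_b answers: {bad}")
        cooked_na = (
            (qb_rate * naffq_df["daily_g"] / 100.0)
            .where(naffq_df["is_cooked_meal_or_salad"].astype(bool), 0.0)
            .groupby(naffq_df["participant_id"])
            .sum()
        )
        naffq = base + cooked_na
    return pd.DataFrame({"ffq": standard, "naffq": naffq})


def score_cohort(
    bundle: CohortBundle,
    dashes_per_yes: int = 2,
    dr15_share: float = 0.15,
    dr15_mode: str = "share_of_total",
    composition: FoodCompositionTable | None = None,
) -> pd.DataFrame:
    """Long-form estimates table for every method with available data."""
    wide = pd.DataFrame(index=pd.Index(bundle.profiles["participant_id"], name="participant_id"))
    wide["u24"] = score_u24(bundle.urine24)
    spot = score_spot(bundle.spot, bundle.profiles)
    recalls = score_recalls(bundle.recalls, dashes_per_yes, dr15_share, dr15_mode)
    ffq = score_ffq(bundle.ffq, composition)
    for frame in (spot, recalls, ffq):
        for col in frame.columns:
            wide[col] = frame[col]
    long = (
        wide.reset_index()
        .melt(id_vars="participant_id", var_name="method_id", value_name="na_mg_per_day")
        .dropna(subset=["na_mg_per_day"])
    )
    long["method_id"] = pd.Categorical(long["method_id"], categories=METHOD_IDS, ordered=True)
    return long.sort_values(["method_id", "participant_id"], ignore_index=True)
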