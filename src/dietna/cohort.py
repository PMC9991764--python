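"""Synthetic high-CVD-risk cohort with a known measurement-error structure.

The generator draws a true usual sodium intake per participant and then
simulates every measurement instrument around it with the error structure
each instrument is assumed to have:

* 24-h urine: excretion_fraction x true intake x multiplicative day-to-day
  noise, decomposed into a collected volume and concentrations; a small
  fraction of collections is made incomplete by scaling the volume below
  the completeness threshold.
* Spot urine: concentrations drawn from log-normals whose log-scale values
  correlate with the day's 24-h excretion (configurable correlation).
* 24-h recalls: the food component (1 - discretionary_share of intake)
  times a participant-level underreporting factor and day noise, itemised
  into meals; the per-meal salt questions are the quantised inverse of the
  participant's true discretionary-salt rate.
* FFQ / NaFFQ: the food component times the underreporting factor and an
  instrument noise factor, allocated over composition-table items; the
  Na-rich items only the extended NaFFQ asks about carry a fixed share, and
  question b is the quantised inverse of the discretionary rate over cooked
  meals and salads.

Because every truth is stored, downstream bias, correlation and agreement
statistics have known generative expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import lognormal_factor, substream
from .dietary import (
    NA_MG_PER_DASH,
    Q1_RATES,
    QUESTION_B_RATES,
    DietaryRecall,
    FfqResponse,
    FoodCompositionTable,
    Meal,
)
from .params import GeneratorParams
from .urinary import NA_MG_PER_MMOL

PROFILE_COLUMNS = ["participant_id", "age_y", "sex", "weight_kg", "height_cm"]
TRUTH_COLUMNS = ["participant_id", "true_usual_na", "true_discretionary_na", "true_food_na"]
URINE24_COLUMNS = ["participant_id", "volume_l", "na_mmol_l", "k_mmol_l", "creat_mg_dl", "complete"]
SPOT_COLUMNS = ["participant_id", "na_mmol_l", "k_mmol_l", "creat_mg_dl"]
RECALL_COLUMNS = [
    "participant_id", "recall_idx", "meal", "item_grams", "item_na_mg_per_100g", "q1", "q2",
]
FFQ_COLUMNS = ["participant_id", "item_id", "freq_cat", "portion_g", "naffq", "question_b"]

_FILES = {
    "profiles": PROFILE_COLUMNS,
    "truth": TRUTH_COLUMNS,
    "urine24": URINE24_COLUMNS,
    "spot": SPOT_COLUMNS,
    "recalls": RECALL_COLUMNS,
    "ffq": FFQ_COLUMNS,
}

# Fraction of the discretionary intake added in cooking vs at the table.
COOKING_SHARE_OF_DISCRETIONARY = 0.75
# Probability that a recall-responding participant completes only 1 or 2
# of the three scheduled recalls.
P_ONE_RECALL = 0.04
P_TWO_RECALLS = 0.08
# Meal structure of a generated recall day.
MEAL_NAMES = ("breakfast", "lunch", "dinner", "other")
MEAL_BASE_SHARES = np.array([0.20, 0.35, 0.30, 0.15])
# FFQ frequency categories actually offered by the generator (a consumed
# food group is reported at least occasionally).
_FFQ_CATS = np.array(["1-3_per_month", "1-2_per_week", "3-6_per_week", "1_per_day", "2plus_per_day"])
_FFQ_CAT_P = np.array([0.15, 0.25, 0.30, 0.22, 0.08])


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, plus the generating parameters."""

    profiles: pd.DataFrame
    truth: pd.DataFrame
    urine24: pd.DataFrame
    spot: pd.DataFrame
    recalls: pd.DataFrame
    ffq: pd.DataFrame
    params: GeneratorParams | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "profiles": self.profiles,
            "truth": self.truth,
            "urine24": self.urine24,
            "spot": self.spot,
            "recalls": self.recalls,
            "ffq": self.ffq,
        }


def _truncnorm(rng, n, mean, sd, lo, hi):
    if sd == 0:
        return np.full(n, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _nearest_category(rates: dict[str, float], target: np.ndarray) -> np.ndarray:
    """Answer category whose mg/100 g rate is nearest to the target rate."""
    labels = np.array(list(rates.keys()))
    values = np.array(list(rates.values()))
    idx = np.abs(target[:, None] - values[None, :]).argmin(axis=1)
    return labels[idx]


def generate_cohort(params: GeneratorParams) -> CohortBundle:
    """Generate a complete cohort bundle; deterministic for a fixed seed."""
    if not isinstance(params, GeneratorParams):
        params = GeneratorParams(**params)
    n = params.n_participants
    width = max(4, len(str(n)))
    pids = np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])

    profiles = _generate_profiles(params, pids)
    truth = _generate_truth(params, pids)
    urine24, na24_content = _generate_urine24(params, pids, profiles, truth)
    spot = _generate_spot(params, pids, truth, na24_content)
    recalls = _generate_recalls(params, pids, truth)
    ffq = _generate_ffq(params, pids, truth)
    return CohortBundle(profiles, truth, urine24, spot, recalls, ffq, params)


def _generate_profiles(params: GeneratorParams, pids) -> pd.DataFrame:
    n = len(pids)
    rng = substream(params.seed, "profiles")
    male = rng.random(n) < params.pct_male
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18.0, 90.0)
    height = np.where(male, rng.normal(175.0, 7.0, n), rng.normal(162.0, 6.0, n))
    weight = np.where(male, rng.normal(86.0, 14.0, n), rng.normal(72.0, 13.0, n))
    height = np.clip(height, 140.0, 200.0)
    weight = np.clip(weight, 40.0, 150.0)
    return pd.DataFrame(
        {
            "participant_id": pids,
            "age_y": age,
            "sex": np.where(male, "M", "F"),
            "weight_kg": weight,
            "height_cm": height,
        }
    )


def _generate_truth(params: GeneratorParams, pids) -> pd.DataFrame:
    rng = substream(params.seed, "truth")
    true_usual = params.mean_true_na * lognormal_factor(rng, len(pids), params.cv_true_na)
    disc = params.discretionary_share * true_usual
    return pd.DataFrame(
        {
            "participant_id": pids,
            "true_usual_na": true_usual,
            "true_discretionary_na": disc,
            "true_food_na": true_usual - disc,
        }
    )


def _generate_urine24(params, pids, profiles, truth):
    n = len(pids)
    rng = substream(params.seed, "urine24")
    dayfac = lognormal_factor(rng, n, params.day_cv_urine)
    na24 = params.excretion_fraction * truth["true_usual_na"].to_numpy() * dayfac
    volume = np.clip(1.6 * lognormal_factor(rng, n, 0.30), 0.6, 4.5)
    na_conc = na24 / NA_MG_PER_MMOL / volume
    k24_mmol = 62.0 * lognormal_factor(rng, n, 0.30)
    k_conc = k24_mmol / volume
    male = (profiles["sex"] == "M").to_numpy()
    rate = np.where(
        male,
        _truncnorm(rng, n, 24.0, 2.5, 15.0, 33.0),
        _truncnorm(rng, n, 18.0, 2.2, 11.4, 24.6),
    )
    creat24_mg = rate * profiles["weight_kg"].to_numpy()
    creat_conc = creat24_mg / (10.0 * volume)  # mg/dL

    incomplete = rng.random(n) < params.incomplete_collection_rate
    # Incomplete collections: part of the day's urine is missing, i.e. the
    # collected volume drops below the screening threshold while the
    # concentrations stay physiological.
    short_volume = rng.uniform(0.15, 0.45, n)
    volume = np.where(incomplete, short_volume, volume)

    frame = pd.DataFrame(
        {
            "participant_id": pids,
            "volume_l": volume,
            "na_mmol_l": na_conc,
            "k_mmol_l": k_conc,
            "creat_mg_dl": creat_conc,
            "complete": (~incomplete).astype(int),
        }
    )
    return frame, na24


def _generate_spot(params, pids, truth, na24_content):
    n = len(pids)
    rng = substream(params.seed, "spot")
    avail = rng.random(n) < params.frac_spot

    s2 = np.log1p(params.cv_true_na**2) + np.log1p(params.day_cv_urine**2)
    if s2 > 0:
        mu = (
            np.log(params.excretion_fraction * params.mean_true_na)
            if params.excretion_fraction > 0
            else 0.0
        ) - s2 / 2.0
        z_day = (np.log(np.maximum(na24_content, 1e-12)) - mu) / np.sqrt(s2)
    else:
        z_day = np.zeros(n)

    rho = params.spot_corr
    eps = rng.standard_normal(n)
    z_spot = rho * z_day + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    sig2 = np.log1p(params.spot_noise_cv**2)
    na_conc = 100.0 * params.spot_scale * np.exp(np.sqrt(sig2) * z_spot - sig2 / 2.0)
    k_conc = 55.0 * lognormal_factor(rng, n, 0.40)
    creat_conc = 120.0 * lognormal_factor(rng, n, 0.50)

    frame = pd.DataFrame(
        {
            "participant_id": pids[avail],
            "na_mmol_l": na_conc[avail],
            "k_mmol_l": k_conc[avail],
            "creat_mg_dl": creat_conc[avail],
        }
    )
    return frame.reset_index(drop=True)


def _underreport_factors(params, rng, n):
    return _truncnorm(
        rng, n, params.recall_underreport_mean, params.recall_underreport_sd, 1e-9, 1.2
    )


def _generate_recalls(params, pids, truth) -> pd.DataFrame:
    n = len(pids)
    rng = substream(params.seed, "recalls")
    avail = rng.random(n) < params.frac_recall
    u = _underreport_factors(params, rng, n)
    r_draw = rng.random(n)
    n_recalls = np.where(r_draw < P_ONE_RECALL, 1, np.where(r_draw < P_ONE_RECALL + P_TWO_RECALLS, 2, 3))
    n_recalls = np.where(avail, n_recalls, 0)

    true_usual = truth["true_usual_na"].to_numpy()
    disc = truth["true_discretionary_na"].to_numpy()
    food_true = truth["true_food_na"].to_numpy()

    rows_pid, rows_idx, rows_meal = [], [], []
    rows_grams, rows_na100, rows_q1, rows_q2 = [], [], [], []

    idx = np.flatnonzero(n_recalls > 0)
    if idx.size:
        # day-level noise and meal allocations, drawn for 3 recalls per
        # participant so stream consumption is independent of n_recalls
        dayfac = lognormal_factor(rng, n * 3, params.recall_day_cv).reshape(n, 3)
        grams_total = rng.uniform(1000.0, 1800.0, (n, 3))
        g_shares = rng.gamma(MEAL_BASE_SHARES * 25.0, size=(n, 3, 4))
        g_shares /= g_shares.sum(axis=2, keepdims=True)
        na_shares = rng.gamma(MEAL_BASE_SHARES * 25.0, size=(n, 3, 4))
        na_shares /= na_shares.sum(axis=2, keepdims=True)

        for i in idx:
            food_i = (food_true[i]) * u[i]
            cooking = COOKING_SHARE_OF_DISCRETIONARY * disc[i]
            table_salt = disc[i] - cooking
            for r in range(n_recalls[i]):
                day_food = food_i * dayfac[i, r]
                grams = grams_total[i, r] * g_shares[i, r]
                na_meal = day_food * na_shares[i, r]
                main_grams = grams[:3].sum()
                cook_rate = cooking * 100.0 / main_grams if main_grams > 0 else 0.0
                q1_cat = _nearest_category(Q1_RATES, np.full(3, cook_rate))
                q2_yes = (table_salt / 3.0) > NA_MG_PER_DASH
                for m in range(4):
                    rows_pid.append(pids[i])
                    rows_idx.append(r + 1)
                    rows_meal.append(MEAL_NAMES[m])
                    rows_grams.append(grams[m])
                    rows_na100.append(na_meal[m] / grams[m] * 100.0)
                    if m < 3:
                        rows_q1.append(q1_cat[m])
                        rows_q2.append("yes" if q2_yes else "no")
                    else:
                        rows_q1.append("")
                        rows_q2.append("")

    return pd.DataFrame(
        {
            "participant_id": rows_pid,
            "recall_idx": rows_idx,
            "meal": rows_meal,
            "item_grams": rows_grams,
            "item_na_mg_per_100g": rows_na100,
            "q1": rows_q1,
            "q2": rows_q2,
        },
        columns=RECALL_COLUMNS,
    )


def _generate_ffq(params, pids, truth) -> pd.DataFrame:
    n = len(pids)
    rng = substream(params.seed, "ffq")
    avail_u = rng.random(n)
    is_naffq = avail_u < params.frac_naffq
    is_ffq = avail_u < params.frac_ffq  # NaFFQ respondents are nested

    u = _underreport_factors(params, rng, n)
    noise = lognormal_factor(rng, n, params.ffq_error_cv)
    food_true = truth["true_food_na"].to_numpy()
    disc = truth["true_discretionary_na"].to_numpy()
    target = food_true * u * noise

    comp = FoodCompositionTable.bundled().table
    std_items = comp.index[comp["naffq_addition"] == 0].to_numpy()
    add_items = comp.index[comp["naffq_addition"] == 1].to_numpy()
    na100 = comp["na_mg_per_100g"]
    cooked = comp["is_cooked_meal_or_salad"].astype(bool)
    from .dietary import FREQUENCY_WEIGHTS

    rows = {k: [] for k in FFQ_COLUMNS}
    idx = np.flatnonzero(is_ffq)
    for i in idx:
        items = list(std_items)
        allocs = [(1.0 - params.naffq_item_share) * target[i]] if is_naffq[i] else [target[i]]
        if is_naffq[i]:
            items += list(add_items)
        # per-item allocation shares within the standard / addition blocks
        std_shares = rng.gamma(2.0, size=len(std_items))
        std_shares /= std_shares.sum()
        cats = rng.choice(_FFQ_CATS, size=len(items), p=_FFQ_CAT_P)
        std_target = allocs[0]
        item_alloc = list(std_target * std_shares)
        if is_naffq[i]:
            add_shares = rng.gamma(2.0, size=len(add_items))
            add_shares /= add_shares.sum()
            item_alloc += list(params.naffq_item_share * target[i] * add_shares)

        weights = np.array([FREQUENCY_WEIGHTS[c] for c in cats])
        dens = na100.loc[items].to_numpy()
        portions = np.array(item_alloc) * 100.0 / (weights * dens)

        keep = np.array(item_alloc) > 0
        daily_grams_cooked = float(
            (weights * portions)[keep & cooked.loc[items].to_numpy()].sum()
        )
        if is_naffq[i]:
            rate_target = (
                disc[i] * u[i] * 100.0 / daily_grams_cooked if daily_grams_cooked > 0 else 0.0
            )
            qb = _nearest_category(QUESTION_B_RATES, np.array([rate_target]))[0]
        else:
            qb = ""
        for j, item in enumerate(items):
            if not keep[j]:
                continue
            rows["participant_id"].append(pids[i])
            rows["item_id"].append(item)
            rows["freq_cat"].append(cats[j])
            rows["portion_g"].append(portions[j])
            rows["naffq"].append(int(is_naffq[i]))
            rows["question_b"].append(qb)

    return pd.DataFrame(rows, columns=FFQ_COLUMNS)


# ---------------------------------------------------------------------------
# object views


def recalls_from_frame(recalls: pd.DataFrame) -> dict[str, list[DietaryRecall]]:
    """Group an itemised recall table into DietaryRecall objects."""
    out: dict[str, list[DietaryRecall]] = {}
    if recalls.empty:
        return out
    for (pid, ridx), grp in recalls.groupby(["participant_id", "recall_idx"], sort=True):
        meals = []
        for meal_name, mg in grp.groupby("meal", sort=False):
            items = tuple(zip(mg["item_grams"], mg["item_na_mg_per_100g"]))
            q1 = mg["q1"].iloc[0] or None
            q2 = mg["q2"].iloc[0] or None
            meals.append(Meal(name=meal_name, items=items, q1=q1, q2=q2))
        out.setdefault(str(pid), []).append(
            DietaryRecall(participant_id=str(pid), recall_idx=int(ridx), meals=tuple(meals))
        )
    return out


def ffq_from_frame(ffq: pd.DataFrame) -> dict[str, FfqResponse]:
    """Group an FFQ item table into FfqResponse objects."""
    out: dict[str, FfqResponse] = {}
    if ffq.empty:
        return out
    for pid, grp in ffq.groupby("participant_id", sort=True):
        naffq = bool(grp["naffq"].iloc[0])
        qb = grp["question_b"].iloc[0] or None
        out[str(pid)] = FfqResponse(
            participant_id=str(pid),
            version="naffq" if naffq else "standard",
            items=tuple(zip(grp["item_id"], grp["freq_cat"], grp["portion_g"])),
            question_b=qb if naffq else None,
        )
    return out


# ---------------------------------------------------------------------------
# persistence


def write_cohort(bundle: CohortBundle, directory) -> list[Path]:
    """Write the six cohort tables as headered CSV; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, columns in _FILES.items():
        frame = bundle.tables()[name]
        if frame.empty:
            frame = pd.DataFrame(columns=columns)
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths.append(path)
    if bundle.params is not None:
        config = directory / "generator_params.yaml"
        import yaml

        config.write_text(yaml.safe_dump(bundle.params.model_dump(), sort_keys=False))
        paths.append(config)
    return paths


def read_cohort(directory) -> CohortBundle:
    """Read a cohort bundle written by :func:`write_cohort`."""
    directory = Path(directory)
    frames = {}
    dtypes = {"q1": str, "q2": str, "question_b": str}
    for name, columns in _FILES.items():
        path = directory / f"{name}.csv"
        frame = pd.read_csv(path, dtype={k: v for k, v in dtypes.items() if k in columns})
        for col in ("q1", "q2", "question_b"):
            if col in frame.columns:
                frame[col] = frame[col].fillna("")
        frames[name] = frame
    params = None
    config = directory / "generator_params.yaml"
    if config.exists():
        import yaml

        params = GeneratorParams(**yaml.safe_load(config.read_text()))
    return CohortBundle(params=params, **frames)


def zero_noise_params(**overrides) -> GeneratorParams:
    """Parameters for the degenerate noise-free cohort.

    All noise CVs are 0, everything consumed is excreted, there is no
    underreporting, no discretionary salt, no structurally missed FFQ items
    and no missing instruments: every dietary estimate and the 24-h urine
    measurement then reproduce the true intake identically.
    """
    base = dict(
        cv_true_na=0.0,
        day_cv_urine=0.0,
        recall_day_cv=0.0,
        recall_underreport_mean=1.0,
        recall_underreport_sd=0.0,
        discretionary_share=0.0,
        ffq_error_cv=0.0,
        spot_noise_cv=0.0,
        excretion_fraction=1.0,
        incomplete_collection_rate=0.0,
        naffq_item_share=0.0,
        frac_spot=1.0,
        frac_recall=1.0,
        frac_ffq=1.0,
        frac_naffq=1.0,
    )
    base.update(overrides)
    return GeneratorParams(**base)
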