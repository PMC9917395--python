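"""Measurement blocking, inclusion rules, and covariate completion.

Raw D-dimer measurements are reduced to one value per patient-day (the
daily maximum), indexed from the day of trauma (day 0) and restricted to a
50-day horizon.  Patients are screened by a sequential exclusion flow;
missing region AIS values are completed by k-nearest-neighbour imputation
and the ISS is recomputed from the completed AIS profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from dditraj.errors import ValidationError

logger = logging.getLogger(__name__)

AIS_REGIONS = ("ais_head", "ais_face", "ais_chest", "ais_abdomen",
               "ais_extremities", "ais_external")

# sequential exclusion flow: (audit key, required column, predicate)
EXCLUSION_RULES = (
    ("few_ddimer_days", "n_ddimer_days", lambda s: s < 3),
    ("readmission", "readmission", lambda s: s.astype(bool)),
    ("long_interval", "interval_days", lambda s: s > 14),
    ("age_le_18", "age", lambda s: s <= 18),
    ("cancer", "cancer", lambda s: s.astype(bool)),
    ("pregnancy", "pregnancy", lambda s: s.astype(bool)),
)


def apply_exclusions(roster: pd.DataFrame) -> tuple[pd.Index, dict[str, int]]:
    """Apply the sequential screening rules; return included ids and audits.

    Rules run in fixed order — fewer than three D-dimer days, re-admission,
    trauma-to-hospitalisation interval over two weeks, age 18 or under,
    cancer, pregnancy — each counting only records not already excluded, so
    the audit counts plus the included count always equal the screened count.
    """
    audits: dict[str, int] = {}
    if len(roster) == 0:
        included = pd.Index([], name="patient_id")
        return included, {key: 0 for key, _, _ in EXCLUSION_RULES}
    for key, col, pred in EXCLUSION_RULES:
        if col not in roster.columns:
            raise ValidationError(f"roster lacks exclusion field {col!r}")
        na = roster[col].isna()
        if na.any():
            pid = roster.loc[na, "patient_id"].iloc[0] if "patient_id" in roster \
                else roster.index[na][0]
            raise ValidationError(
                f"missing exclusion field {col!r} for patient {pid}")
    remaining = roster
    for key, col, pred in EXCLUSION_RULES:
        hit = pred(remaining[col])
        audits[key] = int(hit.sum())
        remaining = remaining[~hit]
        logger.info("exclusion %-16s removed %4d, %4d remain",
                    key, audits[key], len(remaining))
    ids = remaining["patient_id"] if "patient_id" in remaining.columns \
        else remaining.index.to_series()
    return pd.Index(ids, name="patient_id"), audits


def block_daily_max(raw: pd.DataFrame, trauma_date=None, *,
                    horizon_days: int = 50, censor_lo: float = 0.0,
                    censor_hi: float = 40.0) -> pd.DataFrame:
    """Collapse raw measurements to daily maxima on days 0..horizon.

    ``raw`` must carry a ``value`` column and either an integer/float ``day``
    column (days since trauma) or a datetime ``timestamp`` column with
    ``trauma_date`` supplied; the day index is the floor of whole days since
    the trauma day.  Values are clipped to the censoring range and flagged
    ``censored_high``/``censored_low`` when clipped or already at a bound.
    Days beyond the horizon are dropped; negative days are an error.
    """
    df = raw.copy()
    if "day" in df.columns:
        day = np.floor(df["day"].to_numpy(dtype=float))
    elif "timestamp" in df.columns:
        if trauma_date is None:
            raise ValidationError("timestamp input requires trauma_date")
        ts = pd.to_datetime(df["timestamp"])
        t0 = pd.to_datetime(trauma_date).normalize()
        day = (ts.dt.normalize() - t0).dt.days.to_numpy(dtype=float)
    else:
        raise ValidationError("raw measurements need a 'day' or 'timestamp' column")
    if np.any(day < 0):
        raise ValidationError("measurement before trauma day (negative day index)")
    df["day"] = day.astype(int)
    df = df[df["day"] <= horizon_days]

    keys = ["patient_id", "day"] if "patient_id" in df.columns else ["day"]
    blocked = df.groupby(keys, as_index=False)["value"].max()
    clipped = blocked["value"].clip(censor_lo, censor_hi)
    blocked["censored_high"] = blocked["value"] >= censor_hi
    blocked["censored_low"] = blocked["value"] <= censor_lo
    n_clip = int((blocked["value"] != clipped).sum())
    if n_clip:
        logger.info("block_daily_max: clipped %d values to [%g, %g]",
                    n_clip, censor_lo, censor_hi)
    blocked["value"] = clipped
    return blocked.sort_values(keys, kind="mergesort").reset_index(drop=True)


def filter_min_days(series: pd.DataFrame, min_days: int = 3) -> bool:
    """True when a blocked series covers at least ``min_days`` distinct days."""
    if len(series) == 0:
        return False
    return series["day"].nunique() >= min_days


def iss_from_ais(ais: "pd.Series | np.ndarray | list") -> int:
    """Injury Severity Score from six region AIS values.

    Sum of squares of the three most severe region scores; any region at the
    maximal AIS of 6 ("unsurvivable") sets the ISS to 75.
    """
    a = np.asarray(ais, dtype=float)
    if a.shape[-1] != 6:
        raise ValidationError("ISS needs exactly six region AIS values")
    if np.any(np.isnan(a)) or np.any((a < 0) | (a > 6)):
        raise ValidationError("AIS values must be integers in 0..6")
    if np.any(a == 6):
        return 75
    top3 = np.sort(a)[-3:]
    return int(np.sum(top3 ** 2))


def impute_ais_knn(covariates: pd.DataFrame, k: int = 5,
                   feature_cols: tuple[str, ...] = ("age", "bmi", "sofa"),
                   ) -> pd.DataFrame:
    """Complete missing region AIS values from the k nearest complete rows.

    Distance is standardised Euclidean over the numeric features (plus a
    one-hot mechanism indicator when present); each missing region score is
    the rounded median of the donors' scores, kept within 0..6.  The ISS is
    recomputed from the completed AIS profile wherever it was missing or any
    region was imputed.
    """
    df = covariates.copy()
    regions = [c for c in AIS_REGIONS if c in df.columns]
    if not regions:
        raise ValidationError("no AIS region columns present")
    missing_any = df[regions].isna().any(axis=1)
    if not missing_any.any():
        return df

    feats = [c for c in feature_cols if c in df.columns]
    X = df[feats].astype(float).copy()
    if "mechanism" in df.columns:
        X["mech_penetrating"] = (df["mechanism"] == "penetrating").astype(float)
    if "iss" in df.columns:
        X["iss"] = df["iss"].astype(float)
    X = X.fillna(X.median(numeric_only=True))
    sd = X.std(ddof=0).replace(0, 1.0)
    Xs = ((X - X.mean()) / sd).to_numpy()

    donors = ~missing_any
    if donors.sum() < k:
        raise ValidationError(
            f"need at least k={k} complete donor rows, have {int(donors.sum())}")
    nn = NearestNeighbors(n_neighbors=k).fit(Xs[donors.to_numpy()])
    _, idx = nn.kneighbors(Xs[missing_any.to_numpy()])
    donor_pos = np.flatnonzero(donors.to_numpy())

    recipients = np.flatnonzero(missing_any.to_numpy())
    for row_i, neigh in zip(recipients, idx):
        neigh_rows = df.iloc[donor_pos[neigh]]
        for col in regions:
            if pd.isna(df.iloc[row_i][col]):
                med = float(np.median(neigh_rows[col].astype(float)))
                df.iloc[row_i, df.columns.get_loc(col)] = \
                    int(np.clip(round(med), 0, 6))
    df[regions] = df[regions].astype(int)
    if len(regions) == 6:
        redo = missing_any if "iss" not in df.columns else \
            (missing_any | df["iss"].isna())
        iss_vals = df.loc[redo, list(AIS_REGIONS)].apply(iss_from_ais, axis=1)
        if "iss" not in df.columns:
            df["iss"] = np.nan
        df.loc[redo, "iss"] = iss_vals
    logger.info("impute_ais_knn: completed %d rows with k=%d",
                int(missing_any.sum()), k)
    return df
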