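"""Phenotypic effects of a harmful haplotype on matings and offspring.

Because cows are rarely genotyped, a mating is classified through genotyped
male ancestors: a *risk* mating pairs a carrier bull with a cow whose own sire
is a carrier, so the offspring is homozygous with probability 1/8 (the cow
inherits the haplotype from her sire with probability 1/2, transmits with 1/2,
and the bull transmits with 1/2). The contrast group (*non-risk*) is
non-carrier bulls mated to daughters of carrier sires; matings to daughters
of non-carrier sires are excluded so the dam-side background matches.

For a fully penetrant embryonic lethal at baseline insemination success b the
expected deficit in risk matings is b/8 (6.25 percentage points at b = 0.5).
A perinatally lethal allele instead raises the stillbirth rate of risk-mating
calvings by penetrance/8, and a juvenile lethal lowers first-year survival by
(1/8) x P(death by day 365 | homozygote), which the Kaplan-Meier contrast
measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.proportion import proportions_ztest

RISK = "risk"
NON_RISK = "non_risk"
EXCLUDED = "excluded"


def classify_matings(
    records: pd.DataFrame,
    carriers,
    sire_col: str = "bull",
    dam_sire_col: str = "cow_sire",
) -> pd.Series:
    """Label records risk / non_risk / excluded from two male-ancestor columns.

    ``carriers`` is the set of known carrier ids; an id that is null/empty is
    an unknown status and excludes the record. Matings to daughters of
    non-carrier sires are excluded from the contrast.
    """
    carriers = set(carriers)
    sire = records[sire_col]
    dam_sire = records[dam_sire_col]
    known = sire.notna() & (sire != "") & dam_sire.notna() & (dam_sire != "")
    sire_carrier = sire.isin(carriers)
    dam_sire_carrier = dam_sire.isin(carriers)
    out = pd.Series(EXCLUDED, index=records.index, name="risk_status")
    out[known & sire_carrier & dam_sire_carrier] = RISK
    out[known & ~sire_carrier & dam_sire_carrier] = NON_RISK
    return out


@dataclass(frozen=True)
class ProportionContrast:
    rate_risk: float
    rate_non_risk: float
    difference_points: float  # risk minus non-risk, percentage points
    p_value: float
    n_risk: int
    n_non_risk: int


def _two_proportion_contrast(success, status) -> ProportionContrast:
    r = np.asarray(success[status == RISK], dtype=float)
    nr = np.asarray(success[status == NON_RISK], dtype=float)
    if len(r) == 0 or len(nr) == 0:
        raise ValueError("both risk and non-risk groups must be non-empty")
    p_r, p_nr = r.mean(), nr.mean()
    count = np.array([r.sum(), nr.sum()])
    nobs = np.array([len(r), len(nr)])
    pooled = count.sum() / nobs.sum()
    if pooled in (0.0, 1.0) or p_r == p_nr:
        p_val = 1.0
    else:
        _, p_val = proportions_ztest(count, nobs)
    return ProportionContrast(
        rate_risk=float(p_r),
        rate_non_risk=float(p_nr),
        difference_points=float((p_r - p_nr) * 100.0),
        p_value=float(p_val),
        n_risk=len(r),
        n_non_risk=len(nr),
    )


def insemination_contrast(records: pd.DataFrame, status: pd.Series) -> ProportionContrast:
    """Difference in per-service insemination success, risk minus non-risk.

    The P-value is the two-sample z test on proportions, the slope test of
    the covariate-free linear probability model of success on the risk
    indicator.
    """
    return _two_proportion_contrast(records["success"], status)


def stillbirth_contrast(calvings: pd.DataFrame, status: pd.Series) -> ProportionContrast:
    """Difference in stillbirth rate (percentage points), risk minus non-risk."""
    return _two_proportion_contrast(calvings["stillborn"], status)


def return_interval_proportion(
    records: pd.DataFrame,
    status: pd.Series,
    window_days: tuple[int, int] = (5, 32),
) -> ProportionContrast:
    """Proportion of first services followed by a re-service within a day window.

    A repeat insemination 5-32 days after the first marks a return at the next
    oestrus, i.e. very early pregnancy failure. For each cow's first service
    (by date) the flag is whether her next service falls in the closed window;
    group proportions are contrasted as in the other tests. Without any repeat
    services the contrast is undefined and P is reported as 1.
    """
    df = records.copy()
    df["_status"] = status
    df["date"] = pd.to_datetime(df["date"])
    df = df.sort_values(["cow", "date"], kind="mergesort")
    first = df.groupby("cow", sort=False).head(1).copy()
    nxt = df.groupby("cow", sort=False).nth(1)
    gap = (
        nxt.set_index("cow")["date"] - first.set_index("cow")["date"]
    ).dt.days.reindex(first["cow"])
    lo, hi = window_days
    flags = ((gap >= lo) & (gap <= hi)).fillna(False).to_numpy()
    st = first["_status"].to_numpy()
    if not flags.any():
        n_r = int((st == RISK).sum())
        n_nr = int((st == NON_RISK).sum())
        return ProportionContrast(0.0, 0.0, 0.0, 1.0, n_r, n_nr)
    return _two_proportion_contrast(
        pd.Series(flags.astype(float)), pd.Series(st)
    )


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray  # days
    survival: np.ndarray

    def at(self, day: float) -> float:
        i = np.searchsorted(self.times, day, side="right") - 1
        return float(self.survival[i]) if i >= 0 else 1.0


@dataclass
class SurvivalContrast:
    curves: dict  # group -> SurvivalCurve
    difference_points: dict  # day -> (risk - non_risk) * 100
    logrank_p: float
    n_risk: int
    n_non_risk: int


def km_survival(
    calvings: pd.DataFrame,
    status: pd.Series,
    horizon_days: int = 365,
    export_handling: str = "omit",
    eval_days: tuple[int, ...] = (10, 365),
) -> SurvivalContrast:
    """Kaplan-Meier first-year survival of live-born calves, by risk group.

    ``omit`` drops calves that leave recording within the horizon for reasons
    other than death (e.g. export); ``censor`` right-censors them at their
    exit day instead. Calves alive at the horizon are censored there. The
    group difference is reported in percentage points at each evaluation day,
    with the log-rank test P.
    """
    if export_handling not in ("omit", "censor"):
        raise ValueError("export_handling must be 'omit' or 'censor'")
    df = calvings.copy()
    df["_status"] = status.to_numpy()
    df = df[df["_status"].isin([RISK, NON_RISK])]
    df = df[df["stillborn"] == 0]

    birth = pd.to_datetime(df["birth_date"])
    exit_date = pd.to_datetime(df["exit_date"])
    age = (exit_date - birth).dt.days
    reason = df["exit_reason"].fillna("none")

    died = (reason == "death") & (age <= horizon_days)
    exported = (reason == "export") & (age <= horizon_days)
    if export_handling == "omit":
        keep = ~exported
        df, age, died = df[keep], age[keep], died[keep]
        duration = np.where(died, age, horizon_days)
    else:
        duration = np.where(died, age, np.where(exported, age, horizon_days))
    event = died.to_numpy()
    duration = np.asarray(duration, dtype=float)

    curves = {}
    for group in (RISK, NON_RISK):
        m = (df["_status"] == group).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"empty {group} group in survival analysis")
        km = KaplanMeierFitter()
        km.fit(duration[m], event[m])
        sf = km.survival_function_
        curves[group] = SurvivalCurve(
            group=group,
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
        )

    m_r = (df["_status"] == RISK).to_numpy()
    if event.sum() == 0:
        p = 1.0
    else:
        p = float(
            logrank_test(
                duration[m_r], duration[~m_r], event[m_r], event[~m_r]
            ).p_value
        )
    diffs = {
        day: (curves[RISK].at(day) - curves[NON_RISK].at(day)) * 100.0
        for day in eval_days
    }
    return SurvivalContrast(
        curves=curves,
        difference_points=diffs,
        logrank_p=p,
        n_risk=int(m_r.sum()),
        n_non_risk=int((~m_r).sum()),
    )
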