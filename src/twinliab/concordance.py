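"""Probandwise concordance with Wald confidence intervals.

The probandwise concordance of a syndrome is, among probands who have the
syndrome, the proportion whose co-twin also has it.  Each (proband with the
syndrome, co-twin) ordered pair is one *proband unit*: a doubly ascertained
concordant pair contributes two units, and a triplet proband with two
co-twins contributes two units.  Co-twins whose syndrome status is
indeterminate (missing symptom ratings) are excluded from the denominator
(complete-case handling), with the excluded count logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

log = logging.getLogger("twinliab")

UNIT_COLUMNS = ["proband_id", "cotwin_id", "pair_id", "cotwin_affected",
                "zygosity", "sample_id", "cotwin_sex", "cotwin_age_last_info"]


@dataclass
class ConcordanceResult:
    syndrome: str
    zygosity: str | None
    n: int                       # proband units
    k: int                       # concordant units
    concordance: float | None    # k / n, None when not estimable (n = 0)
    ci_low: float | None
    ci_high: float | None
    degenerate_ci: bool = False  # k in {0, n}: zero-width Wald interval

    @property
    def estimable(self) -> bool:
        return self.n > 0


def expand_units(profiles: pd.DataFrame, syndrome: str) -> pd.DataFrame:
    """Expand a profile frame into proband units for one syndrome.

    One row per ordered (proband with the syndrome, co-twin) pair.  Pairs
    with no proband are skipped with a warning; co-twins indeterminate for
    the syndrome are dropped with a logged count.
    """
    if syndrome not in profiles.columns:
        raise KeyError(f"syndrome column {syndrome!r} not present; "
                       "derive profiles first")
    df = profiles
    no_proband = ~df.groupby("pair_id")["proband"].transform("any")
    if no_proband.any():
        log.warning("%d pair(s) without a proband skipped",
                    df.loc[no_proband, "pair_id"].nunique())
        df = df[~no_proband]

    status = df[syndrome].astype("boolean")
    probands = df[df["proband"].astype(bool) & status.fillna(False).to_numpy()]
    cotwins = df[["individual_id", "pair_id", syndrome, "sex",
                  "age_last_info"]].rename(columns={
                      "individual_id": "cotwin_id",
                      syndrome: "cotwin_affected",
                      "sex": "cotwin_sex",
                      "age_last_info": "cotwin_age_last_info"})
    units = probands[["individual_id", "pair_id", "zygosity", "sample_id"]] \
        .rename(columns={"individual_id": "proband_id"}) \
        .merge(cotwins, on="pair_id")
    units = units[units["proband_id"] != units["cotwin_id"]]

    indeterminate = units["cotwin_affected"].isna()
    if indeterminate.any():
        log.info("syndrome %s: %d proband unit(s) dropped "
                 "(co-twin status indeterminate)", syndrome, int(indeterminate.sum()))
        units = units[~indeterminate]
    units = units.copy()
    units["cotwin_affected"] = units["cotwin_affected"].astype(bool)
    return units[UNIT_COLUMNS].reset_index(drop=True)


def wald_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float, bool]:
    """Wald (normal-approximation) binomial CI, clamped to [0, 1].

    Returns ``(low, high, degenerate)``; the interval is degenerate
    (zero-width) when k is 0 or n, since the estimated variance vanishes.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    p = k / n
    if k in (0, n):
        return p, p, True
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half), False


def probandwise_concordance(units: pd.DataFrame, syndrome: str = "",
                            zygosity: str | None = None,
                            level: float = 0.95) -> ConcordanceResult:
    """Probandwise concordance k/n over a unit frame, with Wald CI."""
    n = len(units)
    if n == 0:
        return ConcordanceResult(syndrome=syndrome, zygosity=zygosity,
                                 n=0, k=0, concordance=None,
                                 ci_low=None, ci_high=None)
    k = int(units["cotwin_affected"].sum())
    lo, hi, degen = wald_ci(k, n, level)
    return ConcordanceResult(syndrome=syndrome, zygosity=zygosity, n=n, k=k,
                             concordance=k / n, ci_low=lo, ci_high=hi,
                             degenerate_ci=degen)


def concordance_table(profiles: pd.DataFrame, syndromes: list[str],
                      by: tuple[str, ...] = ("zygosity",),
                      level: float = 0.95) -> list[ConcordanceResult]:
    """Probandwise concordance per syndrome within each stratum of ``by``."""
    results = []
    for syndrome in syndromes:
        units = expand_units(profiles, syndrome)
        if units.empty:
            results.append(probandwise_concordance(units, syndrome))
            continue
        for key, grp in units.groupby(list(by), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            zyg = key[list(by).index("zygosity")] if "zygosity" in by else None
            res = probandwise_concordance(grp, syndrome, zygosity=zyg, level=level)
            results.append(res)
    return results


def pairwise_concordance(profiles: pd.DataFrame, syndrome: str) -> tuple[int, int]:
    """Diagnostic pairwise concordance: (concordant pairs, pairs with >=1 case).

    Counts each ascertained pair once regardless of how many probands it
    carries; secondary to the probandwise statistic.
    """
    status = profiles.assign(_s=profiles[syndrome].astype("boolean"))
    agg = status.groupby("pair_id")["_s"].agg(
        affected="sum", determinate=lambda s: s.notna().all())
    agg = agg[agg["determinate"]]
    with_case = agg[agg["affected"] >= 1]
    return int((with_case["affected"] >= 2).sum()), len(with_case)
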