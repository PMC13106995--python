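"""Report writers: machine-readable TSV plus a human-readable text table.

Every estimate is printed with its confidence interval; degenerate or
missing interval limits are printed as ``not applicable`` (e.g. the Wald
interval at 0/8 concordant units, or the lower tetrachoric profile limit
when there are no concordant pairs).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .concordance import ConcordanceResult
from .liability import ACEEstimate, LiabilityFit
from .regression import RegressionResult

NOT_APPLICABLE = "not applicable"


def _fmt(x, pct: bool = False) -> str:
    if x is None:
        return NOT_APPLICABLE
    return f"{100 * x:.1f}" if pct else f"{x:.3f}"


def _concordance_row(r: ConcordanceResult) -> dict:
    degenerate = r.degenerate_ci or not r.estimable
    return {
        "syndrome": r.syndrome, "zygosity": r.zygosity or "",
        "n_units": r.n, "k_concordant": r.k,
        "concordance_pct": _fmt(r.concordance, pct=True),
        "ci_low_pct": NOT_APPLICABLE if degenerate else _fmt(r.ci_low, pct=True),
        "ci_high_pct": NOT_APPLICABLE if degenerate else _fmt(r.ci_high, pct=True),
    }


def _liability_row(r: LiabilityFit, label: str = "") -> dict:
    return {
        "syndrome": label, "K": r.K, "threshold": round(r.t, 4),
        "r_tetrachoric": _fmt(r.r_hat),
        "ci_low": NOT_APPLICABLE if r.ci_low is None else _fmt(r.ci_low),
        "ci_high": NOT_APPLICABLE if r.ci_high is None else _fmt(r.ci_high),
        "n_units": r.n, "k_concordant": r.k,
    }


def _ace_row(r: ACEEstimate, label: str = "") -> dict:
    return {
        "syndrome": label,
        "a2": _fmt(r.a2), "a2_ci_low": _fmt(r.a2_ci[0]), "a2_ci_high": _fmt(r.a2_ci[1]),
        "c2": _fmt(r.c2), "c2_ci_low": _fmt(r.c2_ci[0]), "c2_ci_high": _fmt(r.c2_ci[1]),
        "e2": _fmt(r.e2), "boundary": r.boundary,
    }


def results_frame(results: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Tabulate a homogeneous collection of result objects."""
    if not results:
        raise ValueError("no results to report")
    labels = labels or ["" for _ in results]
    rows = []
    for res, label in zip(results, labels):
        if isinstance(res, ConcordanceResult):
            rows.append(_concordance_row(res))
        elif isinstance(res, LiabilityFit):
            rows.append(_liability_row(res, label))
        elif isinstance(res, ACEEstimate):
            rows.append(_ace_row(res, label))
        elif isinstance(res, RegressionResult):
            frame = res.summary_frame().reset_index(names="term")
            frame.insert(0, "model", label)
            rows.extend(frame.to_dict("records"))
        else:
            raise TypeError(f"cannot report result of type {type(res).__name__}")
    return pd.DataFrame(rows)


def write_report(results: list, path: str | Path,
                 labels: list[str] | None = None) -> pd.DataFrame:
    """Write results as ``<path>.tsv`` and an aligned ``<path>.txt`` table."""
    df = results_frame(results, labels)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    with open(path.with_suffix(".txt"), "w", encoding="utf-8") as fh:
        fh.write(df.to_string(index=False))
        fh.write("\n")
    return df
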