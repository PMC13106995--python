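"""Twin-table schema: reading, validation, grouping into pairs, and run config.

The twin table is a TSV (or CSV) with one row per individual and the columns
of :data:`COLUMNS`.  Symptom columns are ternary: 0, 1, or missing (empty
string, ``NA`` or the conventional ``9`` rating code).  A pair may have three
members (a twin plus a co-sibling triplet); the grouping preserves that and
downstream proband-unit expansion handles it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger("twinliab")

SYMPTOM_COLUMNS = [
    "delusions",             # any delusion / thought interference
    "hallucinations",        # any hallucination
    "restricted_affect",
    "poverty_of_speech",
    "formal_thought_disorder",
    "inappropriate_affect",
]

COLUMNS = [
    "individual_id", "pair_id", "sample_id", "zygosity", "proband",
    "sex", "age_last_info", *SYMPTOM_COLUMNS, "psychotic_disorder",
]

_ZYGOSITY_TOKENS = {"mz": "MZ", "dz": "DZ"}
_SEX_TOKENS = {"f": "F", "female": "F", "m": "M", "male": "M"}
_BOOL_TOKENS = {"1": True, "true": True, "yes": True, "t": True,
                "0": False, "false": False, "no": False, "f": False}
_MISSING_TOKENS = {"", "na", "nan", "9", "none"}


class SchemaError(ValueError):
    """The file does not conform to the twin-table schema."""


class ValidationError(ValueError):
    """A row or pair violates a schema invariant."""


@dataclass(frozen=True)
class TwinPair:
    """Zygosity-labelled group of two (or three, for a triplet) individuals."""

    pair_id: str
    sample_id: str
    zygosity: str                 # "MZ" | "DZ"
    members: pd.DataFrame         # rows of the twin table for this pair

    @property
    def is_triplet(self) -> bool:
        return len(self.members) == 3

    @property
    def n_probands(self) -> int:
        return int(self.members["proband"].sum())


@dataclass
class AnalysisConfig:
    """Resolved run configuration.

    ``morbid_risk_per_syndrome`` maps syndrome label to lifetime morbid risk
    K in (0, 0.5); K fixes the liability threshold and is supplied by the
    user (population values are estimated outside this package).
    """

    morbid_risk_per_syndrome: dict[str, float] = field(default_factory=dict)
    fdr_q: float = 0.05
    ci_level: float = 0.95
    seed: int = 0
    glmm_quadrature_nodes: int = 21
    optimizer_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        for syn, k in self.morbid_risk_per_syndrome.items():
            if not 0.0 < k < 0.5:
                raise ValueError(
                    f"morbid risk for {syn!r} must lie strictly in (0, 0.5), got {k}")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.glmm_quadrature_nodes % 2 != 1:
            raise ValueError("glmm_quadrature_nodes must be odd")


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value file.

    Keyword overrides (e.g. from CLI flags) take precedence over the file.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cfg = AnalysisConfig(**raw)
    log.info("resolved config: %s", cfg)
    return cfg


def _parse_token(raw, mapping: dict, colname: str, row: int):
    token = str(raw).strip().lower()
    if token in mapping:
        return mapping[token]
    raise ValidationError(f"row {row}: unrecognised value {raw!r} in column {colname!r}")


def _parse_symptom(raw, colname: str, row: int):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return pd.NA
    token = str(raw).strip().lower()
    if token.endswith(".0"):
        token = token[:-2]
    if token in _MISSING_TOKENS:
        return pd.NA
    if token == "1":
        return True
    if token == "0":
        return False
    raise ValidationError(f"row {row}: symptom value {raw!r} in {colname!r} "
                          "must be 0, 1 or missing (NA/9)")


def read_twin_table(path: str | Path, dialect: str | None = None) -> list[TwinPair]:
    """Read and validate a twin table, returning pairs grouped by ``pair_id``.

    Validation: required columns present; zygosity/sex/boolean tokens from
    explicit case-insensitive lists; zygosity constant within pair; MZ pairs
    same-sex; pairs without any proband are dropped with a warning.
    """
    path = Path(path)
    if dialect is None:
        dialect = "CSV" if path.suffix.lower() == ".csv" else "TSV"
    sep = "," if dialect.upper() == "CSV" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return validate_twin_frame(df)


def validate_twin_frame(df: pd.DataFrame) -> list[TwinPair]:
    """Normalise an already-loaded string frame and group it into TwinPairs."""
    df = df.copy()
    out = pd.DataFrame(index=df.index)
    out["individual_id"] = df["individual_id"].astype(str)
    out["pair_id"] = df["pair_id"].astype(str)
    out["sample_id"] = df["sample_id"].astype(str)
    out["zygosity"] = [
        _parse_token(v, _ZYGOSITY_TOKENS, "zygosity", i)
        for i, v in zip(df.index, df["zygosity"])]
    out["proband"] = [
        _parse_token(v, _BOOL_TOKENS, "proband", i)
        for i, v in zip(df.index, df["proband"])]
    out["sex"] = [
        _parse_token(v, _SEX_TOKENS, "sex", i)
        for i, v in zip(df.index, df["sex"])]
    out["age_last_info"] = pd.to_numeric(df["age_last_info"], errors="raise")
    if (out["age_last_info"] < 0).any():
        bad = out.index[out["age_last_info"] < 0][0]
        raise ValidationError(f"row {bad}: negative age_last_info")
    for col in SYMPTOM_COLUMNS:
        out[col] = pd.array(
            [_parse_symptom(v, col, i) for i, v in zip(df.index, df[col])],
            dtype="boolean")
    pd_col = []
    for i, v in zip(df.index, df["psychotic_disorder"]):
        token = str(v).strip().lower()
        pd_col.append(pd.NA if token in _MISSING_TOKENS
                      else _parse_token(v, _BOOL_TOKENS, "psychotic_disorder", i))
    out["psychotic_disorder"] = pd.array(pd_col, dtype="boolean")

    pairs: list[TwinPair] = []
    for pair_id, grp in out.groupby("pair_id", sort=True):
        zyg = grp["zygosity"].unique()
        if len(zyg) > 1:
            raise ValidationError(f"pair {pair_id!r}: mixed zygosity {list(zyg)}")
        if zyg[0] == "MZ" and grp["sex"].nunique() > 1:
            raise ValidationError(f"pair {pair_id!r}: MZ members with discordant sex")
        if not (2 <= len(grp) <= 3):
            raise ValidationError(
                f"pair {pair_id!r}: {len(grp)} members (expected 2, or 3 for a triplet)")
        if not grp["proband"].any():
            log.warning("pair %r has no proband; dropped", pair_id)
            continue
        if len(grp) == 3:
            log.info("pair %r is a triplet (3 members)", pair_id)
        pairs.append(TwinPair(pair_id=str(pair_id),
                              sample_id=str(grp["sample_id"].iloc[0]),
                              zygosity=str(zyg[0]),
                              members=grp.reset_index(drop=True)))
    return pairs


def pairs_to_frame(pairs: list[TwinPair]) -> pd.DataFrame:
    """Concatenate pair members back into a single twin-table frame."""
    if not pairs:
        return pd.DataFrame(columns=COLUMNS)
    return pd.concat([p.members for p in pairs], ignore_index=True)[COLUMNS]


def write_twin_table(pairs: list[TwinPair] | pd.DataFrame,
                     path: str | Path, dialect: str = "TSV") -> None:
    """Write pairs (or a twin-table frame) in the schema's text format."""
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    df = df[COLUMNS].copy()
    for col in SYMPTOM_COLUMNS + ["psychotic_disorder"]:
        df[col] = df[col].map({True: "1", False: "0", pd.NA: "NA"}, na_action=None)
    for col in ("proband",):
        df[col] = df[col].map({True: "1", False: "0"})
    sep = "," if dialect.upper() == "CSV" else "\t"
    df.to_csv(path, sep=sep, index=False)
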