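"""Derivation of psychotic syndromes from binary lifetime symptom ratings.

Syndromes are boolean combinations of six core symptoms, taken over the
individual's lifetime:

* narrow positive (``pos2``): any delusion/thought interference AND any
  hallucination;
* broad negative (``neg_broad``): restricted affect OR poverty of speech;
  narrow negative (``neg_narrow``): both;
* broad disorganised (``dis_broad``): positive formal thought disorder OR
  inappropriate affect; narrow disorganised (``dis_narrow``): both.

Narrow syndromes are nested within broad ones by construction.  A syndrome
additionally requires the psychotic-disorder flag; where that flag is absent
it is recomputed as "at least one of the six symptoms present".

Missing symptom ratings propagate under Kleene three-valued logic (pandas
nullable booleans): a syndrome whose truth value genuinely depends on a
missing symptom is *indeterminate* (NA), not false — e.g. restricted affect
missing with poverty of speech present still gives a definite broad negative
syndrome, but with poverty of speech absent the broad syndrome is NA.
"""

from __future__ import annotations

import pandas as pd

SYNDROMES = ["pos2", "neg_broad", "neg_narrow", "dis_broad", "dis_narrow"]

SUBSYNDROMES = {
    "Pos2_Neg0": ("pos2", "neg_broad", False),       # Pos=2 and Neg=0
    "Pos2_NegBroad": ("pos2", "neg_broad", True),    # Pos=2 and Neg=1 or 2
    "Pos2_NegNarrow": ("pos2", "neg_narrow", True),  # Pos=2 and Neg=2
    "Pos2_Dis0": ("pos2", "dis_broad", False),       # Pos=2 and Dis=0
    "Pos2_DisBroad": ("pos2", "dis_broad", True),    # Pos=2 and Dis=1 or 2
    "Pos2_DisNarrow": ("pos2", "dis_narrow", True),  # Pos=2 and Dis=2
}

_SYMPTOMS = ["delusions", "hallucinations", "restricted_affect",
             "poverty_of_speech", "formal_thought_disorder",
             "inappropriate_affect"]


def derive_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """Append syndrome columns (nullable boolean) to a twin-table frame.

    Pure and idempotent: output depends only on the symptom columns and the
    psychotic-disorder flag.  Indeterminate values are pd.NA.
    """
    df = records.copy()
    sym = {c: df[c].astype("boolean") for c in _SYMPTOMS}

    any_symptom = sym[_SYMPTOMS[0]]
    for c in _SYMPTOMS[1:]:
        any_symptom = any_symptom | sym[c]
    disorder = df["psychotic_disorder"].astype("boolean") \
        if "psychotic_disorder" in df.columns \
        else pd.array([pd.NA] * len(df), dtype="boolean")
    # trust the flag where present; recompute from symptoms where absent
    disorder = disorder.where(disorder.notna(), any_symptom)

    df["pos2"] = sym["delusions"] & sym["hallucinations"] & disorder
    df["neg_broad"] = (sym["restricted_affect"] | sym["poverty_of_speech"]) & disorder
    df["neg_narrow"] = sym["restricted_affect"] & sym["poverty_of_speech"] & disorder
    df["dis_broad"] = (sym["formal_thought_disorder"] | sym["inappropriate_affect"]) & disorder
    df["dis_narrow"] = sym["formal_thought_disorder"] & sym["inappropriate_affect"] & disorder
    return df


def derive_subsyndromes(profiles: pd.DataFrame,
                        labels: list[str] | None = None) -> pd.DataFrame:
    """Append narrow-positive subsyndrome columns to a profile frame.

    Each subsyndrome is pos2 combined with the presence (or absence) of a
    negative/disorganised syndrome, under the same three-valued logic: e.g.
    ``Pos2_Dis0 = pos2 AND NOT dis_broad`` is indeterminate when pos2 holds
    but disorganisation is unrated.
    """
    labels = list(SUBSYNDROMES) if labels is None else labels
    df = profiles.copy()
    for label in labels:
        if label not in SUBSYNDROMES:
            raise KeyError(f"unknown subsyndrome label {label!r}; "
                           f"known: {sorted(SUBSYNDROMES)}")
        base, other, present = SUBSYNDROMES[label]
        rhs = df[other].astype("boolean")
        df[label] = df[base].astype("boolean") & (rhs if present else ~rhs)
    return df
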