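import numpy as np
import pandas as pd
import pytest

from twinliab.schema import COLUMNS, SYMPTOM_COLUMNS


def make_individual(individual_id, pair_id, zygosity="MZ", proband=False,
                    sex="F", age=50.0, sample_id="S1",
                    delusions=0, hallucinations=0, restricted_affect=0,
                    poverty_of_speech=0, formal_thought_disorder=0,
                    inappropriate_affect=0, psychotic_disorder="auto"):
    sym = dict(delusions=delusions, hallucinations=hallucinations,
               restricted_affect=restricted_affect,
               poverty_of_speech=poverty_of_speech,
               formal_thought_disorder=formal_thought_disorder,
               inappropriate_affect=inappropriate_affect)
    if psychotic_disorder == "auto":
        # missing (None) if every symptom is unrated, else any-symptom
        vals = [v for v in sym.values() if v is not None]
        psychotic_disorder = int(any(v == 1 for v in vals)) if vals else None
    return dict(individual_id=individual_id, pair_id=pair_id,
                sample_id=sample_id, zygosity=zygosity, proband=proband,
                sex=sex, age_last_info=age, **sym,
                psychotic_disorder=psychotic_disorder)


def frame_from_individuals(rows):
    """Build an analysis-ready twin-table frame (nullable boolean symptoms)."""
    df = pd.DataFrame(rows)[COLUMNS]
    for col in SYMPTOM_COLUMNS + ["psychotic_disorder"]:
        df[col] = pd.array([pd.NA if pd.isna(v) else bool(v) for v in df[col]],
                           dtype="boolean")
    df["proband"] = df["proband"].astype(bool)
    return df


def write_table_text(rows, path, sep="\t"):
    """Write raw rows (no normalisation) as a twin-table text file."""
    df = pd.DataFrame(rows)[COLUMNS]
    df = df.map(lambda v: "NA" if pd.isna(v) else v)
    df.to_csv(path, sep=sep, index=False)
    return path


@pytest.fixture
def three_pair_rows():
    """Three well-formed pairs: MZ concordant, MZ discordant, DZ discordant."""
    return [
        make_individual("a1", "p1", "MZ", proband=True, delusions=1, hallucinations=1),
        make_individual("a2", "p1", "MZ", proband=False, delusions=1, hallucinations=1),
        make_individual("b1", "p2", "MZ", proband=True, delusions=1, hallucinations=1),
        make_individual("b2", "p2", "MZ", proband=False),
        make_individual("c1", "p3", "DZ", proband=True, sex="M",
                        restricted_affect=1, poverty_of_speech=1),
        make_individual("c2", "p3", "DZ", proband=False),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
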