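"""Synthetic ascertained twin cohorts under the liability-threshold model.

The generator draws, per twin pair and per syndrome dimension (positive,
negative, disorganised), latent liabilities from a zero-mean unit-variance
multivariate normal whose cross-twin same-dimension correlation is the ACE
value ``r_MZ = a2 + c2`` or ``r_DZ = a2/2 + c2``.  The joint covariance over
(members x dimensions) is assembled from its ACE components, so it is
positive semi-definite by construction:

    Sigma = a2 * (M kron R) + c2 * (J kron I) + e2 * I

where ``M`` is the member matrix (1 on the diagonal, the zygosity factor
off it), ``R`` the within-person cross-dimension liability correlation, and
``J`` the all-ones matrix (shared environment is fully shared between twins
and dimension-specific).  An individual is affected on a dimension iff
liability plus the additive covariate shift exceeds ``t = Phi^-1(1 - K)``.

Affected individuals receive core symptoms for that dimension: both with
probability ``theta_both``, otherwise one chosen at random — so the broad
syndrome coincides with dimension affection (population risk exactly K) and
the narrow syndrome has risk ``K * theta_both``.

Ascertainment mimics proband sampling: every affected individual is flagged
as a proband independently with probability ``pi``; pairs with at least one
proband are retained, pairs where both twins are probands are doubly
ascertained and later contribute two proband units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .schema import COLUMNS, SYMPTOM_COLUMNS

_DIMENSIONS = ["pos", "neg", "dis"]
_CORE_SYMPTOMS = {
    "pos": ("delusions", "hallucinations"),
    "neg": ("restricted_affect", "poverty_of_speech"),
    "dis": ("formal_thought_disorder", "inappropriate_affect"),
}


@dataclass(frozen=True)
class TwoPathwayPreset:
    """Two-pathway architecture for the positive syndrome.

    Each pair belongs, with probability ``mix_weight``, to a high-heritability
    pathway (positive-dimension a2 = ``a2_high``) in which positive cases also
    carry disorganised symptoms; otherwise to a low-heritability pathway
    (``a2_low``) in which positive cases occur without them.  This encodes the
    hypothesis that delusions/hallucinations arising without disorganisation
    carry more environmental influence.
    """

    a2_low: float
    a2_high: float
    mix_weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_weight <= 1.0:
            raise ValueError("mix_weight must lie in [0, 1]")
        for v in (self.a2_low, self.a2_high):
            if not 0.0 <= v <= 1.0:
                raise ValueError("pathway a2 values must lie in [0, 1]")


def _default_cross_corr() -> np.ndarray:
    # modest positive co-occurrence of the three dimensions' liabilities
    r = np.full((3, 3), 0.4)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimulationParams:
    """Generative parameters of the synthetic twin cohort.

    Defaults are the package's reference study conditions: heritability 0.81
    on the liability scale with no shared environment, lifetime morbid risk
    1% per dimension, five thousand population pairs per zygosity, and 0.9
    per-affected-individual proband ascertainment.
    """

    a2: float = 0.81
    c2: float = 0.0
    K: float = 0.01
    n_mz: int = 5000
    n_dz: int = 5000
    ascertainment_prob: float = 0.9
    beta_sex: float = 0.0           # liability shift for male sex
    beta_age: float = 0.0           # liability shift per year of age
    theta_both: float = 0.5
    cross_syndrome_corr: np.ndarray = field(default_factory=_default_cross_corr)
    two_pathway: TwoPathwayPreset | None = None
    include_triplet: bool = False
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a2 <= 1.0 and 0.0 <= self.c2 <= 1.0
                and self.a2 + self.c2 <= 1.0 + 1e-12):
            raise ValueError(f"need a2, c2 >= 0 with a2 + c2 <= 1; "
                             f"got a2={self.a2}, c2={self.c2}")
        if not 0.0 < self.K < 0.5:
            raise ValueError(f"morbid risk K must lie in (0, 0.5), got {self.K}")
        if not 0.0 < self.ascertainment_prob <= 1.0:
            raise ValueError("ascertainment_prob must lie in (0, 1]")
        if not 0.0 <= self.theta_both <= 1.0:
            raise ValueError("theta_both must lie in [0, 1]")
        R = np.asarray(self.cross_syndrome_corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T) \
                or not np.allclose(np.diag(R), 1.0):
            raise ValueError("cross_syndrome_corr must be symmetric 3x3 "
                             "with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("cross_syndrome_corr must be positive semi-definite")
        object.__setattr__(self, "cross_syndrome_corr", R)

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2


def liability_covariance(a2: float, c2: float, zygosity_factor: float,
                         R: np.ndarray, n_members: int = 2) -> np.ndarray:
    """Joint (members x dimensions) liability covariance, PSD by construction."""
    m = np.full((n_members, n_members), zygosity_factor)
    np.fill_diagonal(m, 1.0)
    J = np.ones((n_members, n_members))
    d = R.shape[0]
    return (a2 * np.kron(m, R) + c2 * np.kron(J, np.eye(d))
            + (1.0 - a2 - c2) * np.eye(n_members * d))


def simulate_liabilities(n_pairs: int, a2: float, c2: float,
                         zygosity: str, R: np.ndarray,
                         rng: np.random.Generator,
                         n_members: int = 2) -> np.ndarray:
    """Draw liabilities, shape (n_pairs, n_members, n_dimensions)."""
    zf = 1.0 if zygosity == "MZ" else 0.5
    cov = liability_covariance(a2, c2, zf, R, n_members)
    # eigendecomposition root: tolerant of exactly singular covariances
    w, v = np.linalg.eigh(cov)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_pairs, cov.shape[0]))
    d = R.shape[0]
    return (z @ root.T).reshape(n_pairs, n_members, d)


def _assign_symptoms(affected: np.ndarray, theta_both: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Core-symptom indicators for one dimension given affection status."""
    n = affected.shape
    both = rng.random(n) < theta_both
    first = rng.random(n) < 0.5
    s1 = affected & (both | first)
    s2 = affected & (both | ~first)
    return s1, s2


def _simulate_zygosity_group(params: SimulationParams, zygosity: str,
                             n_pairs: int, rng: np.random.Generator,
                             pair_prefix: str) -> pd.DataFrame:
    t = float(norm.isf(params.K))
    R = params.cross_syndrome_corr
    L = simulate_liabilities(n_pairs, params.a2, params.c2, zygosity, R, rng)

    pathway = None
    if params.two_pathway is not None:
        tp = params.two_pathway
        pathway = rng.random(n_pairs) < tp.mix_weight  # True => high-a2 path
        zf = 1.0 if zygosity == "MZ" else 0.5
        for a2_path, mask in ((tp.a2_high, pathway), (tp.a2_low, ~pathway)):
            k = int(mask.sum())
            if k:
                r_pair = min(zf * a2_path + params.c2, 1.0)
                cov = np.array([[1.0, r_pair], [r_pair, 1.0]])
                w, v = np.linalg.eigh(cov)
                root = v * np.sqrt(np.clip(w, 0.0, None))
                L[mask, :, 0] = rng.standard_normal((k, 2)) @ root.T

    # covariates: twins share age; MZ same-sex, DZ sexes independent
    age = np.repeat(rng.uniform(20.0, 70.0, n_pairs)[:, None], 2, axis=1)
    if zygosity == "MZ":
        male = np.repeat((rng.random(n_pairs) < 0.5)[:, None], 2, axis=1)
    else:
        male = rng.random((n_pairs, 2)) < 0.5
    shift = params.beta_sex * male + params.beta_age * age

    affected = L + shift[:, :, None] > t  # (n_pairs, 2, 3)

    symptoms = {}
    for d, dim in enumerate(_DIMENSIONS):
        s1, s2 = _assign_symptoms(affected[:, :, d], params.theta_both, rng)
        c1, c2name = _CORE_SYMPTOMS[dim]
        symptoms[c1], symptoms[c2name] = s1, s2

    if pathway is not None:
        # couple disorganisation to the positive pathway: high-path positive
        # cases carry disorganised symptoms, low-path cases do not
        pos_aff = affected[:, :, 0]
        high = np.repeat(pathway[:, None], 2, axis=1)
        d1, d2 = _CORE_SYMPTOMS["dis"]
        both = rng.random((n_pairs, 2)) < params.theta_both
        first = rng.random((n_pairs, 2)) < 0.5
        forced1 = pos_aff & high & (both | first)
        forced2 = pos_aff & high & (both | ~first)
        symptoms[d1] = np.where(pos_aff, forced1, symptoms[d1])
        symptoms[d2] = np.where(pos_aff, forced2, symptoms[d2])

    any_symptom = np.zeros((n_pairs, 2), dtype=bool)
    for col in SYMPTOM_COLUMNS:
        any_symptom |= symptoms[col]

    pair_ids = np.array([f"{pair_prefix}{i:06d}" for i in range(n_pairs)])
    rows = {
        "individual_id": np.char.add(np.repeat(pair_ids, 2),
                                     np.tile(np.array(["_1", "_2"]), n_pairs)),
        "pair_id": np.repeat(pair_ids, 2),
        "sample_id": params.sample_id,
        "zygosity": zygosity,
        "proband": False,
        "sex": np.where(male.ravel(), "M", "F"),
        "age_last_info": age.ravel(),
    }
    for col in SYMPTOM_COLUMNS:
        rows[col] = symptoms[col].reshape(-1)
    rows["psychotic_disorder"] = any_symptom.ravel()
    df = pd.DataFrame(rows)
    for col in SYMPTOM_COLUMNS + ["psychotic_disorder"]:
        df[col] = df[col].astype("boolean")
    return df


def _append_triplet(df: pd.DataFrame, params: SimulationParams,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Add a third MZ co-sibling to one pair, sharing the MZ correlation."""
    L = simulate_liabilities(1, params.a2, params.c2, "MZ",
                             params.cross_syndrome_corr, rng, n_members=3)
    t = float(norm.isf(params.K))
    first_mz = df.loc[df["zygosity"] == "MZ", "pair_id"].iloc[0]
    mask = df["pair_id"] == first_mz
    sex = df.loc[mask, "sex"].iloc[0]
    age = df.loc[mask, "age_last_info"].iloc[0]
    shift = params.beta_sex * (sex == "M") + params.beta_age * age
    affected3 = L[0, 2, :] + shift > t
    row = {"individual_id": f"{first_mz}_3", "pair_id": first_mz,
           "sample_id": params.sample_id, "zygosity": "MZ", "proband": False,
           "sex": sex, "age_last_info": age}
    for d, dim in enumerate(_DIMENSIONS):
        s1, s2 = _assign_symptoms(np.array([affected3[d]]), params.theta_both, rng)
        c1, c2name = _CORE_SYMPTOMS[dim]
        row[c1], row[c2name] = bool(s1[0]), bool(s2[0])
    row["psychotic_disorder"] = any(row[c] for c in SYMPTOM_COLUMNS)
    out = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    for col in SYMPTOM_COLUMNS + ["psychotic_disorder"]:
        out[col] = out[col].astype("boolean")
    return out


def simulate_cohort(params: SimulationParams,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the unascertained population cohort as a twin-table frame.

    Reproducible: a given ``params.seed`` yields a bit-identical cohort.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    parts = []
    if params.n_mz:
        parts.append(_simulate_zygosity_group(params, "MZ", params.n_mz, rng, "mz"))
    if params.n_dz:
        parts.append(_simulate_zygosity_group(params, "DZ", params.n_dz, rng, "dz"))
    df = pd.concat(parts, ignore_index=True)
    if params.include_triplet:
        df = _append_triplet(df, params, rng)
    return df[COLUMNS]


def ascertain(cohort: pd.DataFrame, pi: float,
              seed: int | np.random.Generator | None = 0) -> pd.DataFrame:
    """Flag probands and retain ascertained pairs.

    Each individual with a psychotic disorder is independently flagged as a
    proband with probability ``pi``; only pairs with at least one proband
    are kept.  Concordant pairs with both members flagged are doubly
    ascertained.
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError(f"ascertainment probability must lie in (0, 1], got {pi}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    df = cohort.copy()
    affected = df["psychotic_disorder"].fillna(False).to_numpy(dtype=bool)
    df["proband"] = affected & (rng.random(len(df)) < pi)
    keep = df.groupby("pair_id")["proband"].transform("any")
    return df[keep].reset_index(drop=True)


def simulate_ascertained_cohort(params: SimulationParams) -> pd.DataFrame:
    """Convenience: simulate, then ascertain with ``params.ascertainment_prob``."""
    rng = np.random.default_rng(params.seed)
    cohort = simulate_cohort(params, rng)
    return ascertain(cohort, params.ascertainment_prob, rng)
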