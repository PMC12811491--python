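"""Construction of the standardized 8-variable phenotypic domain.

Raw participant measures (demographics, SSAGA AUD symptom count, pedigree
records, timeline follow-back drinking variables, lifetime kilograms of
alcohol, UPPS-P urgency subscales and constant-attention-task work counts)
are reduced to eight predictors: sex, age, education, family history
density (FHD), AUD symptoms, and three PCA composites — Drinking (five
log-transformed drinking variables), Urgency (positive/negative urgency)
and Alcohol seeking (neutral/aversive alcohol-preference contrasts).
All eight columns are z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "RawPhenotypeRow",
    "PCACompression",
    "PhenotypeMatrix",
    "PHENOTYPE_COLUMNS",
    "DRINKING_VARS",
    "FHD_WEIGHTS",
    "compute_fhd",
    "alcohol_preference",
    "log_transform_drinking",
    "zscore",
    "pca_compress",
    "assemble_phenotypes",
]

#: Final predictor order of the phenotypic domain.
PHENOTYPE_COLUMNS = (
    "sex",
    "age",
    "education",
    "fhd",
    "aud_symptoms",
    "drinking",
    "urgency",
    "alcohol_seeking",
)

#: Drinking-PCA inputs (drinks/drinking day, heavy drinking days/week,
#: drinks/week, greatest drinks in a day, lifetime kilograms).  Drinking
#: days per week (tlfb_ddw) is carried in the raw table but is not a
#: PCA input.
DRINKING_VARS = ("tlfb_ddd", "tlfb_hddw", "tlfb_dw", "tlfb_gdd", "ldh_kg")

#: FHD weight by degree of biological relatedness.
FHD_WEIGHTS = {
    "parent": 0.5,
    "full_sibling": 0.5,
    "grandparent": 0.25,
    "parent_sibling": 0.25,
}


@dataclass(frozen=True)
class PedigreeRecord:
    relation: str  # parent | full_sibling | grandparent | parent_sibling
    affected: bool

    def __post_init__(self):
        if self.relation not in FHD_WEIGHTS:
            raise ValueError(f"unknown relation {self.relation!r}")


@dataclass
class RawPhenotypeRow:
    participant_id: str
    sex: str  # "male" | "female"
    age: float
    education: float
    aud_symptoms: int
    pedigree: list[PedigreeRecord]
    tlfb_ddd: float
    tlfb_hddw: float
    tlfb_ddw: float
    tlfb_dw: float
    tlfb_gdd: float
    ldh_kg: float
    pos_urgency: float
    neg_urgency: float
    n_cww: int
    n_cwa: int
    a_cww: int
    a_cwa: int

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        for name in ("aud_symptoms", "tlfb_ddd", "tlfb_hddw", "tlfb_ddw", "tlfb_dw",
                     "tlfb_gdd", "ldh_kg", "n_cww", "n_cwa", "a_cww", "a_cwa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def compute_fhd(pedigree: list[PedigreeRecord]) -> float:
    """Family history density: weighted affected count over counted relatives.

    Affected parents and full siblings contribute 0.5 each, affected
    grandparents and parents' siblings 0.25 each; the denominator is the
    number of pedigree records supplied, affected or not.  Bounded in
    [0, 0.5].
    """
    if not pedigree:
        raise ValueError("empty pedigree: FHD denominator undefined")
    total = sum(FHD_WEIGHTS[r.relation] for r in pedigree if r.affected)
    return total / len(pedigree)


def alcohol_preference(cwa: float, cww: float) -> float:
    """Work-for-alcohol minus work-for-water contrast (one session)."""
    if cwa < 0 or cww < 0:
        raise ValueError("work counts must be non-negative")
    return cwa - cww


def log_transform_drinking(values: np.ndarray) -> np.ndarray:
    """ln(1+x) skew correction for the drinking-PCA inputs."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("drinking variables must be non-negative before log transform")
    return np.log1p(x)


def zscore(column: np.ndarray, name: str = "column") -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (n-1 denominator)."""
    x = np.asarray(column, dtype=float)
    if x.shape[0] < 2:
        raise ValueError(f"{name}: need at least 2 observations to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{name}: constant column cannot be z-scored")
    return (x - x.mean()) / sd


@dataclass
class PCACompression:
    """Eigen-decomposition record of a correlation-matrix PCA."""

    input_labels: tuple[str, ...]
    eigenvalues: np.ndarray          # all m, non-increasing
    loadings: np.ndarray             # m x retained_count
    explained_variance_fraction: np.ndarray  # per retained component
    retained_count: int
    scores: np.ndarray               # n x retained_count

    @property
    def pc1_scores(self) -> np.ndarray:
        return self.scores[:, 0]


def pca_compress(z_matrix: np.ndarray, labels: tuple[str, ...] | None = None) -> PCACompression:
    """PCA of standardized variables with Kaiser eigenvalue-one retention.

    The eigendecomposition is of the m×m sample correlation matrix
    (columns are assumed z-scored).  Components with eigenvalue > 1 are
    retained, with a forced minimum of one; each retained loading vector
    is oriented so its mean loading is positive.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("need an n x m matrix with m >= 2")
    n, m = z.shape
    if m > n:
        raise ValueError(f"rank-deficient input: {m} variables, {n} observations")
    if labels is None:
        labels = tuple(f"v{i}" for i in range(m))
    corr = z.T @ z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    retained = max(1, int(np.sum(eigvals > 1.0)))
    loadings = eigvecs[:, :retained].copy()
    for j in range(retained):
        mean_load = loadings[:, j].mean()
        if mean_load < 0 or (mean_load == 0 and loadings[np.argmax(loadings[:, j] != 0), j] < 0):
            loadings[:, j] = -loadings[:, j]
    scores = z @ loadings
    explained = eigvals[:retained] / eigvals.sum()
    return PCACompression(
        input_labels=tuple(labels),
        eigenvalues=eigvals,
        loadings=loadings,
        explained_variance_fraction=explained,
        retained_count=retained,
        scores=scores,
    )


@dataclass
class PhenotypeMatrix:
    """Standardized n×8 phenotypic domain in fixed column order."""

    values: np.ndarray
    column_labels: tuple[str, ...]
    participant_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    pca_reports: dict[str, PCACompression] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.column_labels))
        df.insert(0, "participant_id", self.participant_ids)
        return df


def assemble_phenotypes(rows: list[RawPhenotypeRow]) -> PhenotypeMatrix:
    """Build the standardized 8-column phenotypic domain.

    Columns, in order: sex (1 = male, 0 = female), age, education, FHD,
    AUD symptom count, Drinking (PC1 of the five log-transformed drinking
    variables), Urgency (PC1 of the two urgency subscales) and Alcohol
    seeking (PC1 of the neutral and aversive alcohol-preference
    contrasts).  Every column is z-scored after assembly.
    """
    if len(rows) < 8:
        raise ValueError(f"need at least 8 participants, got {len(rows)}")
    n = len(rows)
    ids = [r.participant_id for r in rows]

    sex = np.array([1.0 if r.sex == "male" else 0.0 for r in rows])
    age = np.array([r.age for r in rows], dtype=float)
    education = np.array([r.education for r in rows], dtype=float)
    fhd = np.array([compute_fhd(r.pedigree) for r in rows])
    aud = np.array([r.aud_symptoms for r in rows], dtype=float)

    drink_raw = np.column_stack(
        [[getattr(r, v) for r in rows] for v in DRINKING_VARS]
    )
    drink_log = log_transform_drinking(drink_raw)
    drink_z = np.column_stack(
        [zscore(drink_log[:, j], DRINKING_VARS[j]) for j in range(drink_log.shape[1])]
    )
    drink_pca = pca_compress(drink_z, DRINKING_VARS)

    urg_z = np.column_stack(
        [
            zscore(np.array([r.pos_urgency for r in rows], dtype=float), "pos_urgency"),
            zscore(np.array([r.neg_urgency for r in rows], dtype=float), "neg_urgency"),
        ]
    )
    urg_pca = pca_compress(urg_z, ("pos_urgency", "neg_urgency"))

    neutral_ap = np.array([alcohol_preference(r.n_cwa, r.n_cww) for r in rows])
    aversive_ap = np.array([alcohol_preference(r.a_cwa, r.a_cww) for r in rows])
    seek_z = np.column_stack(
        [zscore(neutral_ap, "neutral_ap"), zscore(aversive_ap, "aversive_ap")]
    )
    seek_pca = pca_compress(seek_z, ("neutral_ap", "aversive_ap"))

    raw_cols = np.column_stack(
        [sex, age, education, fhd, aud,
         drink_pca.pc1_scores, urg_pca.pc1_scores, seek_pca.pc1_scores]
    )
    means = raw_cols.mean(axis=0)
    sds = raw_cols.std(axis=0, ddof=1)
    values = np.column_stack(
        [zscore(raw_cols[:, j], PHENOTYPE_COLUMNS[j]) for j in range(8)]
    )
    return PhenotypeMatrix(
        values=values,
        column_labels=PHENOTYPE_COLUMNS,
        participant_ids=ids,
        means=means,
        sds=sds,
        pca_reports={"drinking": drink_pca, "urgency": urg_pca, "alcohol_seeking": seek_pca},
    )
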