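"""Synthetic connectome–phenotype cohorts with planted latent structure.

The generator emulates a cohort of community-dwelling heavy drinkers:
raw phenotype measures are drawn to match the study population's printed
marginals (drinking variables lognormal with a common log-scale
equicorrelation, urgency and alcohol-preference pairs bivariate Gaussian
at calibrated correlations, pedigrees giving family-history densities in
[0, 0.5]), and functional connectomes are built on the Fisher-z scale as
block-structured baselines plus planted sparse components that couple
chosen TNM edge blocks to sparse phenotype composites.  Mapping Fisher-z
values through tanh guarantees valid correlations; the planted weights
are returned as ground truth for recovery checks and are never consumed
by the fitted pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    BLOCKS,
    FunctionalConnectome,
    RegionRecord,
    RegionTable,
    TNMEdgeMask,
    build_edge_mask,
)
from .phenotypes import (
    PHENOTYPE_COLUMNS,
    PedigreeRecord,
    RawPhenotypeRow,
    assemble_phenotypes,
)

__all__ = [
    "PlantedComponent",
    "GeneratorSpec",
    "GroundTruth",
    "default_paper_like_spec",
    "correlated_gaussian",
    "equicorrelation",
    "synthetic_region_table",
    "generate_raw_phenotypes",
    "generate_connectomes",
    "generate_cohort",
    "write_cohort",
]

#: Cohort marginal targets (mean, sd, low, high) for the drinking measures.
DRINKING_MARGINALS = {
    "tlfb_ddd": (5.26, 4.10, 1.7, 26.0),
    "tlfb_hddw": (1.72, 1.72, 0.0, 7.0),
    "tlfb_ddw": (3.80, 1.70, 0.0, 7.0),
    "tlfb_dw": (21.20, 26.78, 3.2, 182.0),
    "tlfb_gdd": (10.44, 6.45, 3.0, 32.0),
    "ldh_kg": (183.56, 348.10, 5.3, 2185.87),
}

URGENCY_MARGINALS = {
    "pos_urgency": (6.55, 2.54, 4, 12),
    "neg_urgency": (8.07, 2.64, 4, 15),
}

#: Cumulative-work-for-water marginals and preference-contrast scales.
CAT_MARGINALS = {
    "n_cww": (200.73, 203.60, 0, 771),
    "a_cww": (180.89, 173.79, 0, 616),
}
CAT_CWA_BOUNDS = {"n_cwa": (1, 707), "a_cwa": (1, 708)}
#: Preference contrast (cwa - cww) mean and sd per condition.
CAT_PREFERENCE = {"neutral": (54.11, 75.0), "aversive": (89.76, 90.0)}


@dataclass(frozen=True)
class PlantedComponent:
    """One ground-truth latent association.

    ``wp_weights`` gives the sparse phenotype composite (labels from
    PHENOTYPE_COLUMNS; normalized to unit L2 internally), ``block_signs``
    the TNM blocks carrying connectivity signal with their directions,
    ``beta`` the effect size (Fisher-z units per composite SD along the
    unit-norm edge pattern) and ``edge_fraction`` the fraction of each
    block's edges in the support.
    """

    wp_weights: tuple[tuple[str, float], ...]
    block_signs: tuple[tuple[str, int], ...]
    beta: float
    edge_fraction: float = 0.15

    def wp_vector(self) -> np.ndarray:
        w = np.zeros(len(PHENOTYPE_COLUMNS))
        for label, weight in self.wp_weights:
            w[PHENOTYPE_COLUMNS.index(label)] = weight
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("planted component has an empty phenotype pattern")
        return w / norm


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the emulated cohort: n = 55 participants, 145 TNM
    regions (47 SN / 44 FPN / 54 DMN), within-network baseline couplings
    above between-network ones on the Fisher-z scale, and phenotype
    correlation targets calibrated so that the first principal component
    of each composite group explains the documented fractions (urgency
    r = 0.50 -> 75 %, drinking equicorrelation r = 0.6375 -> 71 %,
    seeking r = 0.48 -> 74 %).
    """

    n: int = 55
    n_sn: int = 47
    n_fpn: int = 44
    n_dmn: int = 54
    n_excluded: int = 0
    male_fraction: float = 24 / 55
    mu_within: float = 0.45
    mu_between: float = 0.15
    noise_sd: float = 0.15
    urgency_r: float = 0.50
    drinking_r: float = 0.6375
    seeking_r: float = 0.48
    affected_relative_p: float = 0.19
    planted: tuple[PlantedComponent, ...] = ()

    def __post_init__(self):
        for name in ("n_sn", "n_fpn", "n_dmn"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        for name in ("urgency_r", "drinking_r", "seeking_r"):
            r = getattr(self, name)
            if not (-1 < r < 1):
                raise ValueError(f"{name}={r} outside (-1, 1)")
        if any(c.beta < 0 for c in self.planted):
            raise ValueError("planted betas must be non-negative")


@dataclass
class GroundTruth:
    """Planted parameters and scores, stored exactly as generated."""

    wp: np.ndarray        # (k, 8) unit-norm phenotype patterns
    wc: np.ndarray        # (k, E) unit-norm edge patterns on the TNM mask
    betas: np.ndarray     # (k,)
    scores: np.ndarray    # (n, k) per-subject composite scores
    mask: TNMEdgeMask
    region_table: RegionTable


def default_paper_like_spec() -> GeneratorSpec:
    """Default cohort with three planted components echoing the study's
    reported associations: (Drinking, Age) with increased SN–FPN and
    SN–DMN coupling; (FHD, Urgency) with decreased SN–FPN and
    within-network coupling; (Alcohol seeking, Sex) with increased SN–DMN
    and decreased within-DMN coupling."""
    planted = (
        PlantedComponent(
            wp_weights=(("drinking", 1.0), ("age", 1.0)),
            block_signs=(("SN-FPN", +1), ("SN-DMN", +1)),
            beta=12.0,
            edge_fraction=0.50,
        ),
        PlantedComponent(
            wp_weights=(("fhd", 1.0), ("urgency", 1.0)),
            block_signs=(("SN-FPN", -1), ("SN-SN", -1), ("FPN-FPN", -1), ("DMN-DMN", -1)),
            beta=5.5,
            edge_fraction=0.35,
        ),
        PlantedComponent(
            wp_weights=(("alcohol_seeking", 1.0), ("sex", 1.0)),
            block_signs=(("SN-DMN", +1), ("DMN-DMN", -1)),
            beta=3.2,
            edge_fraction=0.45,
        ),
    )
    return GeneratorSpec(planted=planted)


def equicorrelation(m: int, r: float) -> np.ndarray:
    """m x m correlation matrix with all off-diagonal entries equal to r."""
    return np.full((m, m), r) + (1 - r) * np.eye(m)


def correlated_gaussian(rng: np.random.Generator, n: int, corr: np.ndarray) -> np.ndarray:
    """n samples of a zero-mean unit-variance Gaussian with given correlation."""
    corr = np.asarray(corr, dtype=float)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation target matrix is not positive definite") from exc
    return rng.standard_normal((n, corr.shape[0])) @ L.T


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match ln(1+x) ~ Normal(mu, sigma) to the (mean, sd) of x."""
    m1 = mean + 1.0
    sigma2 = np.log1p((sd / m1) ** 2)
    return np.log(m1) - sigma2 / 2, np.sqrt(sigma2)


def synthetic_region_table(spec: GeneratorSpec) -> RegionTable:
    """Schaefer-17-style lookup for a synthetic TNM parcellation.

    Regions are labeled with the eight TNM subnetworks (SalVentAttn A/B,
    Cont A/B/C, Default A/B/C) plus, optionally, excluded filler networks;
    hemispheres alternate.  Deterministic given the spec.
    """
    groups = []
    for count, subnets in (
        (spec.n_sn, ("SalVentAttnA", "SalVentAttnB")),
        (spec.n_fpn, ("ContA", "ContB", "ContC")),
        (spec.n_dmn, ("DefaultA", "DefaultB", "DefaultC")),
        (spec.n_excluded, ("VisCent", "SomMotA", "DorsAttnA", "LimbicA", "TempPar")),
    ):
        for i in range(count):
            groups.append(subnets[i % len(subnets)])
    records = []
    seen: dict[str, int] = {}
    for rid, net in enumerate(groups):
        hemi = "LH" if rid % 2 == 0 else "RH"
        key = f"{hemi}_{net}"
        seen[key] = seen.get(key, 0) + 1
        name = f"17Networks_{hemi}_{net}_Syn_{seen[key]}"
        records.append(RegionRecord(rid, name, net, hemi))
    from .atlas import assign_tnm_membership

    return assign_tnm_membership(RegionTable(records))


def generate_raw_phenotypes(spec: GeneratorSpec, seed) -> list[RawPhenotypeRow]:
    """Draw a synthetic raw phenotype table matching the cohort marginals."""
    rng = np.random.default_rng(seed)
    n = spec.n

    sex = rng.random(n) < spec.male_fraction
    if sex.all() or not sex.any():
        sex[0] = not sex[0]  # keep the column non-constant
    age = rng.uniform(21.0, 55.0, n)
    education = np.clip(np.round(rng.normal(15.40, 2.08, n)), 11, 20)
    aud = np.clip(rng.negative_binomial(2.04, 0.449, n), 0, 10)

    # Drinking measures: shared log-scale equicorrelation, lognormal marginals.
    drink_names = list(DRINKING_MARGINALS)
    z = correlated_gaussian(rng, n, equicorrelation(len(drink_names), spec.drinking_r))
    drink = {}
    for j, name in enumerate(drink_names):
        mean, sd, lo, hi = DRINKING_MARGINALS[name]
        mu, sigma = _lognormal_params(mean, sd)
        drink[name] = np.clip(np.expm1(mu + sigma * z[:, j]), lo, hi)

    # Urgency pair: bivariate Gaussian discretized to the scale ranges.
    u = correlated_gaussian(rng, n, equicorrelation(2, spec.urgency_r))
    urg = {}
    for j, name in enumerate(URGENCY_MARGINALS):
        mean, sd, lo, hi = URGENCY_MARGINALS[name]
        urg[name] = np.clip(np.round(mean + sd * u[:, j]), lo, hi)

    # Alcohol seeking: correlated preference contrasts added to lognormal
    # water-work baselines, rounded to trial counts.
    v = correlated_gaussian(rng, n, equicorrelation(2, spec.seeking_r))
    cat = {}
    for j, (cond, cww_name, cwa_name) in enumerate(
        (("neutral", "n_cww", "n_cwa"), ("aversive", "a_cww", "a_cwa"))
    ):
        mean, sd, lo, hi = CAT_MARGINALS[cww_name]
        mu, sigma = _lognormal_params(mean, sd)
        cww = np.clip(np.round(np.expm1(mu + sigma * rng.standard_normal(n))), lo, hi)
        pref_mean, pref_sd = CAT_PREFERENCE[cond]
        pref = pref_mean + pref_sd * v[:, j]
        lo_a, hi_a = CAT_CWA_BOUNDS[cwa_name]
        cat[cww_name] = cww
        cat[cwa_name] = np.clip(np.round(cww + pref), lo_a, hi_a)

    rows = []
    for i in range(n):
        pedigree = [
            PedigreeRecord("parent", bool(rng.random() < spec.affected_relative_p))
            for _ in range(2)
        ]
        pedigree += [
            PedigreeRecord("grandparent", bool(rng.random() < spec.affected_relative_p))
            for _ in range(4)
        ]
        pedigree += [
            PedigreeRecord("full_sibling", bool(rng.random() < spec.affected_relative_p))
            for _ in range(int(rng.integers(0, 3)))
        ]
        rows.append(
            RawPhenotypeRow(
                participant_id=f"sub-{i + 1:03d}",
                sex="male" if sex[i] else "female",
                age=float(age[i]),
                education=float(education[i]),
                aud_symptoms=int(aud[i]),
                pedigree=pedigree,
                tlfb_ddd=float(drink["tlfb_ddd"][i]),
                tlfb_hddw=float(drink["tlfb_hddw"][i]),
                tlfb_ddw=float(drink["tlfb_ddw"][i]),
                tlfb_dw=float(drink["tlfb_dw"][i]),
                tlfb_gdd=float(drink["tlfb_gdd"][i]),
                ldh_kg=float(drink["ldh_kg"][i]),
                pos_urgency=float(urg["pos_urgency"][i]),
                neg_urgency=float(urg["neg_urgency"][i]),
                n_cww=int(cat["n_cww"][i]),
                n_cwa=int(cat["n_cwa"][i]),
                a_cww=int(cat["a_cww"][i]),
                a_cwa=int(cat["a_cwa"][i]),
            )
        )
    return rows


def _planted_wc(spec: GeneratorSpec, comp: PlantedComponent,
                mask: TNMEdgeMask, rng: np.random.Generator,
                used: set[int]) -> np.ndarray:
    # supports are kept disjoint across components: each planted circuit
    # involves its own edges, so the latent associations are identifiable
    wc = np.zeros(mask.n_edges)
    for block, sign in comp.block_signs:
        if block not in BLOCKS:
            raise ValueError(f"unknown block {block!r}")
        edges = mask.block_edges(block)
        free = np.array([e for e in edges if e not in used])
        m = max(1, int(np.ceil(comp.edge_fraction * edges.size)))
        if m > free.size:
            raise ValueError(f"block {block} has too few free edges for the planted support")
        chosen = rng.choice(free, size=m, replace=False)
        used.update(int(e) for e in chosen)
        wc[chosen] = float(sign)
    norm = np.linalg.norm(wc)
    if norm == 0:
        raise ValueError("planted component has an empty edge pattern")
    return wc / norm


def generate_connectomes(
    spec: GeneratorSpec, phenotype_rows: list[RawPhenotypeRow], seed
) -> tuple[list[FunctionalConnectome], GroundTruth]:
    """Draw per-subject connectomes carrying the planted associations.

    On the Fisher-z scale each TNM edge is a block baseline plus the sum
    over planted components of beta * score * edge-pattern plus iid
    Gaussian noise; scores are the subjects' standardized phenotypes
    projected on the planted composite.  FC = tanh(z) keeps couplings in
    (-1, 1); FPN–DMN and excluded-region edges receive baseline + noise
    only.
    """
    rng = np.random.default_rng(seed)
    table = synthetic_region_table(spec)
    mask = build_edge_mask(table)
    n = len(phenotype_rows)
    if n != spec.n:
        raise ValueError(f"expected {spec.n} phenotype rows, got {n}")
    n_reg = table.n_regions

    k = len(spec.planted)
    if k:
        P = assemble_phenotypes(phenotype_rows).values
        wp = np.vstack([c.wp_vector() for c in spec.planted])
        used: set[int] = set()
        wc = np.vstack([_planted_wc(spec, c, mask, rng, used) for c in spec.planted])
        betas = np.array([c.beta for c in spec.planted])
        scores = P @ wp.T
        signal = (scores * betas) @ wc  # (n, E)
    else:
        wp = np.zeros((0, len(PHENOTYPE_COLUMNS)))
        wc = np.zeros((0, mask.n_edges))
        betas = np.zeros(0)
        scores = np.zeros((n, 0))
        signal = np.zeros((n, mask.n_edges))

    classes = table.tnm_classes
    iu, ju = np.triu_indices(n_reg, k=1)
    within = (classes[iu] == classes[ju]) & (classes[iu] != "EXCLUDED")
    mu_all = np.where(within, spec.mu_within, spec.mu_between)
    # positions of the masked edges inside the full upper triangle
    pos = (mask.pairs[:, 0] * (2 * n_reg - mask.pairs[:, 0] - 1)) // 2 + (
        mask.pairs[:, 1] - mask.pairs[:, 0] - 1
    )

    connectomes = []
    for i, row in enumerate(phenotype_rows):
        z = mu_all + rng.normal(0.0, spec.noise_sd, iu.size)
        z[pos] += signal[i]
        fc = np.eye(n_reg)
        fc[iu, ju] = np.tanh(z)
        fc[ju, iu] = fc[iu, ju]
        connectomes.append(FunctionalConnectome(row.participant_id, fc))

    truth = GroundTruth(wp, wc, betas, scores, mask, table)
    return connectomes, truth


def generate_cohort(
    spec: GeneratorSpec, seed
) -> tuple[list[RawPhenotypeRow], list[FunctionalConnectome], GroundTruth]:
    """Convenience wrapper: phenotypes then connectomes from one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_phe, s_con = ss.spawn(2)
    rows = generate_raw_phenotypes(spec, s_phe)
    connectomes, truth = generate_connectomes(spec, rows, s_con)
    return rows, connectomes, truth


# ---------------------------------------------------------------------------
# file output (the standard pipeline input formats)

def write_cohort(
    out_dir: str | Path,
    rows: list[RawPhenotypeRow],
    connectomes: list[FunctionalConnectome],
    truth: GroundTruth,
) -> dict[str, Path]:
    """Write region table, connectome matrices, phenotype + pedigree tables
    and a ground-truth JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["region_table"] = out / "region_table.csv"
    truth.region_table.to_frame().drop(columns="tnm_class").to_csv(
        paths["region_table"], index=False
    )

    pheno = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "sex": r.sex,
                "age": r.age,
                "education": r.education,
                "aud_symptoms": r.aud_symptoms,
                "tlfb_ddd": r.tlfb_ddd,
                "tlfb_hddw": r.tlfb_hddw,
                "tlfb_ddw": r.tlfb_ddw,
                "tlfb_dw": r.tlfb_dw,
                "tlfb_gdd": r.tlfb_gdd,
                "ldh_kg": r.ldh_kg,
                "pos_urgency": r.pos_urgency,
                "neg_urgency": r.neg_urgency,
                "n_cww": r.n_cww,
                "n_cwa": r.n_cwa,
                "a_cww": r.a_cww,
                "a_cwa": r.a_cwa,
            }
            for r in rows
        ]
    )
    paths["phenotypes"] = out / "phenotypes.csv"
    pheno.to_csv(paths["phenotypes"], index=False)

    ped = pd.DataFrame(
        [
            {"participant_id": r.participant_id, "relation": p.relation, "affected": p.affected}
            for r in rows
            for p in r.pedigree
        ]
    )
    paths["pedigree"] = out / "pedigree.csv"
    ped.to_csv(paths["pedigree"], index=False)

    conn_dir = out / "connectomes"
    conn_dir.mkdir(exist_ok=True)
    for fc in connectomes:
        np.savetxt(conn_dir / f"{fc.participant_id}.tsv", fc.matrix, delimiter="\t")
    paths["connectomes"] = conn_dir

    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "wp": truth.wp.tolist(),
                "wc_sparse": [
                    {int(i): float(v) for i, v in zip(np.flatnonzero(w), w[np.flatnonzero(w)])}
                    for w in truth.wc
                ],
                "betas": truth.betas.tolist(),
                "scores": truth.scores.tolist(),
                "phenotype_labels": list(PHENOTYPE_COLUMNS),
            }
        )
    )
    return paths
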