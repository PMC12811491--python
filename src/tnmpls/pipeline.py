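"""End-to-end orchestration: load inputs, fit, infer, summarize.

The pipeline composes the library stages — region lookup, phenotype
assembly, edge masking/vectorization, regularization selection, the rPLS
fit, per-component substrate inference and optional leave-one-out
stability — and writes all tables (TSV), the serialized model (JSON), the
resolved configuration and a run log.  Defaults mirror the analysis's
reported settings (k = 4 components, 50 % connectivity-weight retention,
at most 3 phenotype features, 1000 permutations at the 99th percentile,
top 5 % strength selection).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import TNMEdgeMask, build_edge_mask, compute_connectome, load_region_table, vectorize
from .inference import top_regions
from .phenotypes import PedigreeRecord, RawPhenotypeRow, assemble_phenotypes
from .pls import TripleNetworkPLS
from .stability import summarize_stability

logger = logging.getLogger("tnmpls")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "report",
           "read_phenotype_table"]

PHENO_REQUIRED = (
    "participant_id", "sex", "age", "education", "aud_symptoms",
    "tlfb_ddd", "tlfb_hddw", "tlfb_ddw", "tlfb_dw", "tlfb_gdd", "ldh_kg",
    "pos_urgency", "neg_urgency", "n_cww", "n_cwa", "a_cww", "a_cwa",
)


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class PipelineConfig:
    region_table: str
    phenotype_table: str
    pedigree_table: str
    out_dir: str
    connectome_dir: str | None = None
    timeseries_dir: str | None = None
    k: int = 4
    lambda_c: float | None = None          # None -> auto-selection
    lambda_p: float | None = None
    target_fraction: float = 0.5
    max_features: int = 3
    n_perm: int = 1000
    percentile: float = 99.0
    top_fraction: float = 0.05
    stability: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_phenotype_table(pheno_path, pedigree_path) -> list[RawPhenotypeRow]:
    """Load the raw phenotype table plus its long-format pedigree companion."""
    df = pd.read_csv(pheno_path, sep=None, engine="python")
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise PipelineError(f"[phenotypes] missing phenotype column(s): {missing}")
    ped = pd.read_csv(pedigree_path, sep=None, engine="python")
    for c in ("participant_id", "relation", "affected"):
        if c not in ped.columns:
            raise PipelineError(f"[phenotypes] pedigree table missing column {c!r}")
    ped_by_id: dict[str, list[PedigreeRecord]] = {}
    for _, row in ped.iterrows():
        ped_by_id.setdefault(str(row["participant_id"]), []).append(
            PedigreeRecord(str(row["relation"]), bool(row["affected"]))
        )
    rows = []
    for _, r in df.iterrows():
        pid = str(r["participant_id"])
        rows.append(
            RawPhenotypeRow(
                participant_id=pid,
                sex=str(r["sex"]),
                age=float(r["age"]),
                education=float(r["education"]),
                aud_symptoms=int(r["aud_symptoms"]),
                pedigree=ped_by_id.get(pid, []),
                tlfb_ddd=float(r["tlfb_ddd"]),
                tlfb_hddw=float(r["tlfb_hddw"]),
                tlfb_ddw=float(r["tlfb_ddw"]),
                tlfb_dw=float(r["tlfb_dw"]),
                tlfb_gdd=float(r["tlfb_gdd"]),
                ldh_kg=float(r["ldh_kg"]),
                pos_urgency=float(r["pos_urgency"]),
                neg_urgency=float(r["neg_urgency"]),
                n_cww=int(r["n_cww"]),
                n_cwa=int(r["n_cwa"]),
                a_cww=int(r["a_cww"]),
                a_cwa=int(r["a_cwa"]),
            )
        )
    return rows


def _load_connectivity(config: PipelineConfig, table, participant_ids) -> np.ndarray:
    """Stack per-participant edge vectors in phenotype row order."""
    from .atlas import FunctionalConnectome

    mask = build_edge_mask(table)
    rows = []
    for pid in participant_ids:
        if config.connectome_dir is not None:
            path = _find_participant_file(config.connectome_dir, pid)
            m = np.loadtxt(path, delimiter=None)
            fc = FunctionalConnectome(pid, m)
        elif config.timeseries_dir is not None:
            path = _find_participant_file(config.timeseries_dir, pid)
            ts = np.loadtxt(path, delimiter=None)
            fc = compute_connectome(ts, pid)
        else:
            raise PipelineError("[connectivity] neither connectome_dir nor timeseries_dir set")
        rows.append(vectorize(fc, mask).values)
    return np.vstack(rows), mask


def _find_participant_file(directory, pid) -> Path:
    d = Path(directory)
    for ext in (".tsv", ".csv", ".txt", ""):
        p = d / f"{pid}{ext}"
        if p.exists():
            return p
    raise PipelineError(f"[connectivity] no matrix file for participant {pid!r} in {d}")


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{name}] {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write its artifact bundle.

    Returns a dict with the fitted results, inference tables and output
    paths; on any stage error, partial outputs are removed and a
    stage-tagged PipelineError is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created = False
    try:
        table = _stage("atlas", load_region_table, config.region_table)
        rows = _stage("phenotypes", read_phenotype_table,
                      config.phenotype_table, config.pedigree_table)
        pheno = _stage("phenotypes", assemble_phenotypes, rows)
        C, mask = _stage("connectivity", _load_connectivity, config, table,
                         pheno.participant_ids)

        model = TripleNetworkPLS(C, pheno, edge_mask=mask)
        results = _stage(
            "fit", model.fit,
            k=config.k, lambda_c=config.lambda_c, lambda_p=config.lambda_p,
            target_fraction=config.target_fraction, max_features=config.max_features,
        )

        ss = np.random.SeedSequence(config.seed)
        perm_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.k)]
        inference = []
        for comp in range(config.k):
            sig = _stage("infer", results.block_significance, comp,
                         config.n_perm, config.percentile, perm_seeds[comp])
            profile = _stage("infer", results.strength_profile, comp, table)
            top = _stage("infer", top_regions, profile, config.top_fraction)
            from .inference import circuit_summary

            circuit = _stage("infer", circuit_summary,
                             results.components[comp].wc, mask, sig)
            inference.append(
                {"significance": sig, "strength": profile, "top_regions": top,
                 "circuit": circuit}
            )

        stability_tables = None
        if config.stability:
            ensemble = _stage("stability", results.loocv)
            stability_tables = _stage("stability", summarize_stability, ensemble)

        created = True
        bundle = {
            "config": config,
            "region_table": table,
            "mask": mask,
            "phenotypes": pheno,
            "results": results,
            "inference": inference,
            "stability": stability_tables,
            "out_dir": out,
        }
        _stage("write", _write_bundle, bundle)
        return bundle
    except PipelineError:
        if not created:
            for p in out.glob("*"):
                if p.is_dir():
                    shutil.rmtree(p)
                else:
                    p.unlink()
        raise


def _write_bundle(bundle: dict) -> None:
    out: Path = bundle["out_dir"]
    config: PipelineConfig = bundle["config"]
    results = bundle["results"]
    mask: TNMEdgeMask = bundle["mask"]
    table = bundle["region_table"]

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    results.save_json(out / "model.json")

    names = table.names
    for comp, inf in enumerate(bundle["inference"]):
        wc = results.components[comp].wc
        nz = np.flatnonzero(wc)
        pd.DataFrame(
            {
                "region_i": [names[mask.pairs[e, 0]] for e in nz],
                "region_j": [names[mask.pairs[e, 1]] for e in nz],
                "block": [mask.block_labels[e] for e in nz],
                "coefficient": wc[nz],
            }
        ).to_csv(out / f"component{comp + 1}_edges.tsv", sep="\t", index=False)
        inf["strength"].to_frame().to_csv(
            out / f"component{comp + 1}_strength.tsv", sep="\t", index=False
        )
        inf["top_regions"].to_csv(
            out / f"component{comp + 1}_top_regions.tsv", sep="\t", index=False
        )
        inf["significance"].to_frame().to_csv(
            out / f"component{comp + 1}_blocks.tsv", sep="\t", index=False
        )
        (out / f"component{comp + 1}_circuit.json").write_text(
            json.dumps(inf["circuit"].to_dicts(), indent=1)
        )

    if bundle["stability"] is not None:
        st = bundle["stability"]
        st["phenotype_distribution"].to_csv(
            out / "stability_phenotypes.tsv", sep="\t", index=False
        )
        np.savetxt(out / "stability_edge_sd.tsv", st["edge_sd"], delimiter="\t")

    log = {
        "tnmpls_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "n_participants": bundle["phenotypes"].n,
        "n_edges": mask.n_edges,
        "component_names": [results.component_name(i) for i in range(results.k)],
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))


def report(bundle: dict) -> str:
    """Human-readable per-component summary of a completed bundle."""
    results = bundle["results"]
    lines = [results.summary(), ""]
    for comp, inf in enumerate(bundle["inference"]):
        lines.append(f"Component {comp + 1} ({results.component_name(comp)}):")
        circuit = inf["circuit"]
        if len(circuit) == 0:
            lines.append("  no significant interactions")
        else:
            for e in circuit:
                arrow = e.direction if e.direction else f"within {e.endpoints[0]}"
                lines.append(f"  {arrow}: {e.sign} (contribution {e.observed:.3f} "
                             f"> null {e.null_percentile_value:.3f})")
        top = inf["top_regions"]
        shown = ", ".join(
            f"{r.region if 'region' in top.columns else r.region_id}({r.sign[0]})"
            for r in top.head(5).itertuples()
        )
        lines.append(f"  top regions: {shown}")
    if bundle.get("stability") is not None:
        flags = bundle["stability"]["stable"]
        lines.append("")
        lines.append(
            "Stability (LOOCV): "
            + ", ".join(
                f"component {i + 1} {'stable' if s else 'unstable'}"
                for i, s in enumerate(flags)
            )
        )
    return "\n".join(lines)
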