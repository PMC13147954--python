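"""End-to-end orchestration: qc -> knn -> clq -> niche -> crosstalk -> outcomes.

A run is driven by one :class:`RunConfig` (built in code or loaded from
YAML). Every stochastic stage draws its seed deterministically from the
global seed and the stage name, so enabling or disabling one stage never
shifts another stage's randomness. Artifacts are TSV/JSON files under
the output directory, and a :class:`RunReport` records row counts,
parameters and warnings per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc, crosstalk, niche, outcomes, spatial_io, synthgen

STAGES = ("qc", "clq", "niche", "crosstalk", "outcomes")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    dataset_dir: str | None = None
    simulate: synthgen.CohortConfig | None = None
    out_dir: str = "spatialtme_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    min_transcripts: int = 20
    target_total: float = 500.0
    clq_reference: str = "Malignant"
    clq_k: int = 20
    niche_k_neighbors: int = 50
    n_niches: int = 9
    lr_pairs: tuple[tuple[str, str, str, str], ...] = (
        ("DLL4", "NOTCH3", "Capillary", "mCAF"),
    )
    lr_range_um: float = crosstalk.DIFFUSIBLE_RANGE_UM
    proximity_ref: str = "mCAF"
    proximity_target: str = "Capillary"
    proximity_radius_um: float = 80.0
    immune_types: tuple[str, ...] = outcomes.DEFAULT_IMMUNE_TYPES
    survival_niche: int | None = None  # niche label; default = most abundant

    def validate(self) -> None:
        if (self.dataset_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of dataset_dir / simulate must be set")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    seed: int
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "stages": self.stages, "warnings": self.warnings},
            indent=2, default=_jsonable,
        )


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(type(x))


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; a ``simulate: {}`` block uses
    the default synthetic cohort, with any listed fields overridden."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "simulate"})
    if sim is not None:
        sim_seed = sim.pop("seed", stage_seed(cfg.seed, "simulate"))
        cfg.simulate = synthgen.default_config(seed=sim_seed, **sim)
    if isinstance(cfg.stages, list):
        cfg.stages = tuple(cfg.stages)
    return cfg


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order, writing artifacts to disk."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    truth = survival = None
    if config.simulate is not None:
        ds = synthgen.generate_cohort(config.simulate)
        cells, matrix = ds.cells, ds.matrix
        truth, survival = ds.truth, ds.survival
        spatial_io.write_dataset(cells, matrix, out / "dataset", survival=survival)
        truth.to_csv(out / "dataset" / "truth.tsv", sep="\t", index=False)
        report.add("simulate", n_cells=len(cells), n_genes=matrix.n_genes,
                   seed=config.simulate.seed)
    else:
        cells, matrix = spatial_io.read_dataset(config.dataset_dir)
        surv_path = Path(config.dataset_dir) / "survival.tsv"
        if surv_path.exists():
            survival = spatial_io.read_survival(surv_path)

    try:
        if "qc" in config.stages:
            cells, matrix, qc = spatial_io.qc_filter_cells(
                cells, matrix, config.min_transcripts
            )
            qc.per_fov.to_csv(out / "qc_per_fov.tsv", sep="\t", index=False)
            report.add("qc", min_transcripts=config.min_transcripts,
                       n_before=qc.n_cells_before, n_after=qc.n_cells_after)
        matrix = spatial_io.normalize(matrix, target_total=config.target_total)
        cells = cells.reset_index(drop=True)

        assignment = None
        if "clq" in config.stages:
            graph = coloc.build_knn(cells, k=config.clq_k)
            labels = cells["cell_type"].to_numpy()
            table = coloc.clq_density(cells, graph, labels, config.clq_reference)
            table.to_csv(out / "clq_density.tsv", sep="\t", index=False)
            report.add("clq", reference=config.clq_reference, k=config.clq_k,
                       n_rows=len(table), n_null=table.attrs["n_null"])

        if "niche" in config.stages:
            graph50 = coloc.build_knn(cells, k=config.niche_k_neighbors)
            comp = niche.neighborhood_composition(
                graph50, cells["cell_type"].to_numpy()
            )
            assignment = niche.cluster_niches(
                comp, n_niches=config.n_niches,
                seed=stage_seed(config.seed, "niche"),
            )
            pd.DataFrame(
                {"cell_id": cells["cell_id"], "niche": assignment.labels}
            ).to_csv(out / "niches.tsv", sep="\t", index=False)
            enr_type = niche.niche_enrichment(
                assignment, cells["cell_type"].to_numpy()
            )
            enr_type.to_csv(out / "niche_enrichment_type.tsv", sep="\t")
            enr_region = niche.niche_enrichment(assignment, cells["region"].to_numpy())
            enr_region.to_csv(out / "niche_enrichment_region.tsv", sep="\t")
            abundance = niche.niche_abundance(assignment, cells, level="patient")
            abundance.to_csv(out / "niche_abundance_patient.tsv", sep="\t")
            report.add("niche", K=config.n_niches, k_neighbors=config.niche_k_neighbors,
                       n_cells=len(cells), n_truncated=int(comp.truncated.sum()))

        if "crosstalk" in config.stages:
            flags = crosstalk.proximity_flags(
                cells, config.proximity_ref, config.proximity_target,
                mode="radius", threshold=config.proximity_radius_um,
            )
            de = crosstalk.proximity_de(matrix, flags)
            de.to_csv(out / "proximity_de.tsv", sep="\t", index=False)
            frac = crosstalk.proximal_fraction(cells, flags)
            frac.to_csv(out / "proximal_fraction.tsv", sep="\t", index=False)
            lr_rows = []
            for ligand, receptor, sender, receiver in config.lr_pairs:
                score = crosstalk.lr_score(
                    matrix, cells, ligand, receptor, sender, receiver,
                    range_um=config.lr_range_um,
                )
                lr_rows.append(
                    {"ligand": ligand, "receptor": receptor, "sender": sender,
                     "receiver": receiver, "score": score.pooled_score,
                     "L_bar": score.pooled_L, "R_bar": score.pooled_R,
                     "n_eligible": score.n_eligible_receivers}
                )
            pd.DataFrame(lr_rows).to_csv(out / "lr_scores.tsv", sep="\t", index=False)
            report.add("crosstalk", n_proximal=int(flags.proximal.sum()),
                       n_ref=int(flags.cell_rows.size),
                       n_de_genes=len(de), n_lr_pairs=len(lr_rows))

        if "outcomes" in config.stages:
            strata = outcomes.immune_fraction(cells, config.immune_types)
            strata.table.to_csv(out / "fov_strata.tsv", sep="\t", index=False)
            info = {"n_fov_high": int((strata.table["stratum"] == "high").sum()),
                    "n_fov_low": int((strata.table["stratum"] == "low").sum())}
            if survival is not None and assignment is not None:
                abundance = niche.niche_abundance(assignment, cells, level="patient")
                target = config.survival_niche or 1
                merged, lr = outcomes.km_by_group(survival, abundance[target])
                merged.to_csv(out / "survival_groups.tsv", sep="\t", index=False)
                (out / "logrank.json").write_text(json.dumps(
                    {"niche": target, "statistic": lr.statistic, "p": lr.p,
                     "n_high": lr.n_a, "n_low": lr.n_b}, indent=2))
                info.update(logrank_p=lr.p, survival_niche=target)
            report.add("outcomes", **info)
    except Exception as exc:  # abort with stage context and a partial report
        report.warnings.append(f"aborted: {type(exc).__name__}: {exc}")
        (out / "report.json").write_text(report.to_json())
        raise
    (out / "report.json").write_text(report.to_json())
    return report
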