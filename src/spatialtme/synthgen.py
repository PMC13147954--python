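"""Synthetic spatial cohorts with the structure the analyses assume.

The generator emulates an imaging-based single-cell spatial
transcriptomics cohort of hepatocellular carcinoma tissue:

* square FOVs (default 510 um side) tiled over tumor (T), invasive
  boundary (B) and adjacent normal (N) cores, several FOVs per patient;
* nine working cell types covering the major liver lineages, with the
  CAF compartment split into matrix-producing (mCAF) and inflammatory
  (iCAF) polarization states and the endothelium represented by
  capillary/LSEC cells;
* spatial niches planted as a Matern-style cluster process — cluster
  centers uniform in the FOV, member cells Gaussian around the center,
  background cells homogeneous Poisson with region-specific type
  proportions (mCAF share higher in T/B, iCAF higher in N);
* negative-binomial counts with type-specific signature means, per-cell
  totals scaled to a target near the reported per-cell medians
  (~800 transcripts/cell);
* a ligand -> receptor spatial coupling: receiver cells within the
  coupling radius of at least one sender get a planted log2 boost on a
  receptor program (DLL4 on capillaries -> NOTCH3 program on mCAFs);
* per-patient survival with hazard increasing in the abundance of a
  target planted niche.

Every random draw flows through one `numpy` Generator seeded from the
config, so identical (config, seed) pairs give byte-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .spatial_io import ExpressionMatrix

REGIONS = ("T", "B", "N")

ADMIN_CENSOR_MONTHS = 120.0


@dataclass
class NicheSpec:
    """One planted niche: a type mixture placed as Gaussian clusters."""

    name: str
    mixture: dict[str, float]
    radius_um: float = 30.0
    clusters_per_fov: int = 1
    cells_per_cluster: int = 80
    regions: tuple[str, ...] = REGIONS

    def validate(self, vocab: set[str], fov_size: float) -> None:
        s = sum(self.mixture.values())
        if not np.isclose(s, 1.0):
            raise ValueError(f"niche {self.name}: mixture sums to {s}, not 1")
        unknown = set(self.mixture) - vocab
        if unknown:
            raise ValueError(f"niche {self.name}: unknown types {sorted(unknown)}")
        if self.radius_um < 0 or self.radius_um >= fov_size:
            raise ValueError(f"niche {self.name}: radius {self.radius_um} invalid")


@dataclass
class GeneModel:
    """Type-specific negative-binomial expression model.

    Signature genes of a type have mean ``signature_mean`` in that type
    and ``base_mean`` elsewhere; all remaining genes sit at ``base_mean``
    in every type. Counts are NB(mean mu, dispersion theta) with variance
    mu + mu^2/theta; per-cell means are rescaled so expected totals hit
    ``total_target`` before any coupling boost is applied.
    """

    n_genes: int = 160
    signatures: dict[str, list[str]] = field(default_factory=dict)
    base_mean: float = 2.0
    signature_mean: float = 12.0
    dispersion: float = 2.0
    total_target: float = 800.0
    zero_outside: tuple[str, ...] = ()  # genes silent outside their own type
    extra_genes: tuple[str, ...] = ()   # named non-signature genes (base mean)
    gene_means: dict[str, float] = field(default_factory=dict)  # per-gene override

    def gene_names(self) -> list[str]:
        named = [g for genes in self.signatures.values() for g in genes]
        named += list(self.extra_genes)
        named = list(dict.fromkeys(named))
        fillers = [f"G{i:04d}" for i in range(self.n_genes - len(named))]
        if len(named) > self.n_genes:
            raise ValueError("more signature genes than n_genes")
        return named + fillers


@dataclass
class CouplingSpec:
    """Ligand -> receptor spatial coupling planted into the counts."""

    ligand: str = "DLL4"
    sender: str = "Capillary"
    receptor_program: tuple[str, ...] = ("NOTCH3",)
    receiver: str = "mCAF"
    radius_um: float = 30.0
    log2_effect: float = 1.0
    regions: tuple[str, ...] = REGIONS


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 0.02  # events per month
    # per unit abundance in [0, 1]; after a median split of the default
    # abundance gradient this gives an effective group hazard ratio ~2.4
    log_hr: float = float(np.log(6.0))
    censoring_rate: float = 0.2
    target_niche: str = "mCAFs_Chola"


@dataclass
class CohortConfig:
    n_patients: int = 8
    fovs_per_patient: dict[str, int] = field(
        default_factory=lambda: {"T": 2, "B": 1, "N": 1}
    )
    fov_size: float = 510.0
    cell_density: float = 900.0  # expected cells per FOV incl. planted
    baseline_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    niche_specs: list[NicheSpec] = field(default_factory=list)
    gene_model: GeneModel = field(default_factory=GeneModel)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    abundance_gradient: bool = True  # vary target-niche load across patients
    seed: int = 0

    def cell_types(self) -> list[str]:
        types = set()
        for props in self.baseline_proportions.values():
            types |= set(props)
        for spec in self.niche_specs:
            types |= set(spec.mixture)
        return sorted(types)

    def validate(self) -> None:
        if self.fov_size <= 0:
            raise ValueError("fov_size must be positive")
        if set(self.baseline_proportions) != set(REGIONS):
            raise ValueError(f"baseline proportions needed for all of {REGIONS}")
        for region, props in self.baseline_proportions.items():
            s = sum(props.values())
            if not np.isclose(s, 1.0):
                raise ValueError(f"region {region}: proportions sum to {s}")
        vocab = set(self.cell_types())
        for spec in self.niche_specs:
            spec.validate(vocab, self.fov_size)
        if self.coupling.radius_um >= self.fov_size:
            raise ValueError("coupling radius must be smaller than the FOV")
        if not np.isfinite(self.coupling.log2_effect):
            raise ValueError("coupling effect must be finite")
        if self.survival.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


@dataclass
class SyntheticDataset:
    cells: pd.DataFrame
    matrix: ExpressionMatrix
    truth: pd.DataFrame  # cell_id, planted_niche, proximal
    planted_de_genes: list[str]
    survival: pd.DataFrame
    abundance: pd.Series  # per-patient target-niche abundance (truth labels)
    config: CohortConfig


# ---------------------------------------------------------------------------
# spatial layer


def plant_niche_pattern(
    fov_size: float,
    background_props: dict[str, float],
    n_background: float,
    niche_specs: list[NicheSpec],
    rng: np.random.Generator,
    clusters_override: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Place one FOV's cells: planted niche clusters plus Poisson background.

    Cluster centers are uniform in the FOV, member cells isotropic
    Gaussian around their center (clipped to the FOV), background cells
    homogeneous Poisson with types drawn from ``background_props``.
    Returns columns x_um, y_um, cell_type, planted_niche ("background"
    for non-members).
    """
    xs, ys, types, planted = [], [], [], []
    bg_types = sorted(background_props)
    bg_p = np.array([background_props[t] for t in bg_types])
    n_bg = rng.poisson(n_background)
    if n_bg > 0:
        pos = rng.uniform(0, fov_size, size=(n_bg, 2))
        drawn = rng.choice(len(bg_types), size=n_bg, p=bg_p)
        xs.append(pos[:, 0]); ys.append(pos[:, 1])
        types.extend(bg_types[i] for i in drawn)
        planted.extend(["background"] * n_bg)
    centers: list[tuple[np.ndarray, float]] = []  # (xy, radius) of placed clusters
    for spec in niche_specs:
        n_clusters = spec.clusters_per_fov
        if clusters_override and spec.name in clusters_override:
            n_clusters = clusters_override[spec.name]
        mix_types = sorted(spec.mixture)
        mix_p = np.array([spec.mixture[t] for t in mix_types])
        for _ in range(n_clusters):
            # soft inhibition between cluster centers so planted niches stay
            # spatially distinct; falls back to the last candidate when the
            # FOV is too crowded to satisfy the separation
            for _try in range(200):
                center = rng.uniform(0, fov_size, size=2)
                if all(
                    np.hypot(*(center - c)) >= 2.0 * (spec.radius_um + r)
                    for c, r in centers
                ):
                    break
            centers.append((center, spec.radius_um))
            n_mem = spec.cells_per_cluster
            offsets = rng.normal(0, spec.radius_um, size=(n_mem, 2))
            pos = np.clip(center + offsets, 0, fov_size)
            drawn = rng.choice(len(mix_types), size=n_mem, p=mix_p)
            xs.append(pos[:, 0]); ys.append(pos[:, 1])
            types.extend(mix_types[i] for i in drawn)
            planted.extend([spec.name] * n_mem)
    if not xs:
        raise ValueError(
            "FOV generated zero cells (density too low and no niches planted)"
        )
    df = pd.DataFrame(
        {
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys),
            "cell_type": types,
            "planted_niche": planted,
        }
    )
    # break exact coordinate collisions so kNN has no ties; reflect at the
    # FOV border so jittered points stay inside [0, fov_size]
    while df.duplicated(subset=["x_um", "y_um"]).any():
        dup = df.duplicated(subset=["x_um", "y_um"])
        jittered = df.loc[dup, ["x_um", "y_um"]].to_numpy() + rng.uniform(
            -1e-6, 1e-6, size=(int(dup.sum()), 2)
        )
        jittered = np.abs(jittered)
        jittered = fov_size - np.abs(fov_size - jittered)
        df.loc[dup, ["x_um", "y_um"]] = jittered
    return df


# ---------------------------------------------------------------------------
# expression layer


def _type_mean_matrix(gene_model: GeneModel, types: list[str]) -> pd.DataFrame:
    unknown = sorted(set(types) - set(gene_model.signatures))
    if unknown:
        raise ValueError(f"cell types absent from the gene model: {unknown}")
    genes = gene_model.gene_names()
    mu = pd.DataFrame(gene_model.base_mean, index=genes, columns=types, dtype=float)
    for cell_type, sig in gene_model.signatures.items():
        if cell_type in types:
            mu.loc[sig, cell_type] = gene_model.signature_mean
    for gene, mean in gene_model.gene_means.items():
        if gene not in mu.index:
            raise ValueError(f"gene_means override for unknown gene {gene!r}")
        mu.loc[gene, :] = mean
    for gene in gene_model.zero_outside:
        owner = [t for t, sig in gene_model.signatures.items() if gene in sig]
        if not owner:
            raise ValueError(f"zero_outside gene {gene!r} has no owning signature")
        others = [t for t in types if t not in owner]
        mu.loc[gene, others] = 0.0
    return mu


def _proximal_receivers(
    cells: pd.DataFrame, coupling: CouplingSpec
) -> np.ndarray:
    """Truth proximal flag for every cell (False for non-receivers)."""
    from scipy.spatial import cKDTree

    flags = np.zeros(len(cells), dtype=bool)
    types = cells["cell_type"].to_numpy()
    coords = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    fov = cells["fov_id"].to_numpy()
    region = cells["region"].to_numpy()
    for fov_id in pd.unique(fov):
        in_fov = fov == fov_id
        if region[in_fov][0] not in coupling.regions:
            continue
        senders = np.flatnonzero(in_fov & (types == coupling.sender))
        receivers = np.flatnonzero(in_fov & (types == coupling.receiver))
        if senders.size == 0 or receivers.size == 0:
            continue
        tree = cKDTree(coords[senders])
        d, _ = tree.query(coords[receivers], k=1)
        flags[receivers[d <= coupling.radius_um]] = True
    return flags


def sample_expression(
    cells: pd.DataFrame,
    gene_model: GeneModel,
    coupling: CouplingSpec | None,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, list[str], np.ndarray]:
    """Draw NB counts for every cell; plant the coupling effect.

    Receiver cells within the coupling radius of a sender get a
    ``2**log2_effect`` multiplier on the receptor-program genes; per-cell
    mean vectors are then rescaled so the expected total equals
    ``total_target`` (boost first, scaling second, so expected totals are
    identical across proximity groups and the normalized view carries no
    group-level scale artifact). Returns (matrix, planted DE genes, truth
    proximal flags).
    """
    types = cells["cell_type"].to_numpy()
    vocab = sorted(pd.unique(types))
    mu_by_type = _type_mean_matrix(gene_model, vocab)
    genes = np.array(mu_by_type.index, dtype=object)
    type_idx = {t: i for i, t in enumerate(vocab)}
    mu = mu_by_type.to_numpy()[:, [type_idx[t] for t in types]]  # genes x cells
    planted_genes: list[str] = []
    proximal = np.zeros(len(cells), dtype=bool)
    if coupling is not None:
        missing = [g for g in (coupling.ligand, *coupling.receptor_program)
                   if g not in mu_by_type.index]
        if missing:
            raise ValueError(f"coupling genes absent from gene model: {missing}")
        proximal = _proximal_receivers(cells, coupling)
        if coupling.log2_effect != 0:
            prog_rows = [int(np.flatnonzero(genes == g)[0])
                         for g in coupling.receptor_program]
            mu[np.ix_(prog_rows, np.flatnonzero(proximal))] *= (
                2.0 ** coupling.log2_effect
            )
            planted_genes = list(coupling.receptor_program)
    col_tot = mu.sum(axis=0)
    if (col_tot == 0).any():
        bad = sorted(set(types[col_tot == 0]))
        raise ValueError(f"cell types with all-zero expression model: {bad}")
    mu = mu * (gene_model.total_target / col_tot)
    theta = gene_model.dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)
    counts[mu == 0] = 0  # NB with mean zero is identically zero
    matrix = ExpressionMatrix(
        genes=genes,
        cells=cells["cell_id"].to_numpy(dtype=object),
        counts=sp.csr_matrix(counts),
    )
    return matrix, planted_genes, proximal


def plant_fov_coupling(
    n_fovs: int = 60,
    cells_per_type: int = 100,
    r: float = 0.8,
    ligand: str = "DLL4",
    receptor: str = "NOTCH3",
    sender: str = "Capillary",
    receiver: str = "mCAF",
    seed: int = 0,
    n_filler_genes: int = 40,
    latent_sd: float = 0.5,
    log_mean: float = 2.5,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """A cohort whose FOV-level ligand and receptor pseudobulks correlate at r.

    Each FOV carries a bivariate-normal latent pair with correlation
    ``r`` driving the log-scale NB means of the ligand (in sender cells)
    and the receptor (in receiver cells); filler genes have constant
    means so per-cell totals stay stable. Intended for validating the
    per-FOV pseudobulk correlation analysis.
    """
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_fovs)
    mu_l = np.exp(log_mean + latent_sd * z[:, 0])
    mu_r = np.exp(log_mean + latent_sd * z[:, 1])
    genes = np.array([ligand, receptor]
                     + [f"F{i:03d}" for i in range(n_filler_genes)], dtype=object)
    rows = []
    blocks = []
    for f in range(n_fovs):
        for cell_type, mu_gene, gi in ((sender, mu_l[f], 0), (receiver, mu_r[f], 1)):
            mu = np.full((len(genes), cells_per_type), 5.0)
            mu[0], mu[1] = 0.0, 0.0
            mu[gi] = mu_gene
            theta = 10.0
            counts = rng.negative_binomial(theta, theta / (theta + np.maximum(mu, 1e-12)))
            counts[mu == 0] = 0
            blocks.append(counts)
            xy = rng.uniform(0, 510.0, size=(cells_per_type, 2))
            for i in range(cells_per_type):
                rows.append((xy[i, 0], xy[i, 1], f"F{f + 1:03d}", cell_type))
    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "fov_id", "cell_type"])
    cells.insert(0, "cell_id", [f"c{i:06d}" for i in range(len(cells))])
    cells["core_id"] = cells["fov_id"]
    cells["patient_id"] = cells["fov_id"]
    cells["region"] = "T"
    matrix = ExpressionMatrix(
        genes=genes,
        cells=cells["cell_id"].to_numpy(dtype=object),
        counts=sp.csr_matrix(np.hstack(blocks)),
    )
    return cells, matrix


# ---------------------------------------------------------------------------
# survival layer


def attach_survival(
    abundance: pd.Series,
    spec: SurvivalSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential event times with hazard baseline * exp(log_hr * abundance).

    Censoring: each patient is independently censored with probability
    ``censoring_rate`` (observation time uniform before the event), and
    administratively at 120 months. Returns patient_id, time_months,
    event.
    """
    a = abundance.to_numpy(dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("abundance must lie in [0, 1]")
    if spec.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0 <= spec.censoring_rate <= 1:
        raise ValueError("censoring rate must be in [0, 1]")
    hazard = spec.baseline_hazard * np.exp(spec.log_hr * a)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.uniform(size=a.size) < spec.censoring_rate
    u = rng.uniform(size=a.size)
    time = np.where(censored, u * np.minimum(t_event, ADMIN_CENSOR_MONTHS), t_event)
    event = (~censored).astype(int)
    admin = time > ADMIN_CENSOR_MONTHS
    time[admin] = ADMIN_CENSOR_MONTHS
    event[admin] = 0
    time = np.maximum(time, 1e-6)  # survival times must stay positive
    return pd.DataFrame(
        {"patient_id": abundance.index, "time_months": time, "event": event}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohort assembly


def generate_cohort(config: CohortConfig) -> SyntheticDataset:
    """Compose spatial, expression and survival layers into one cohort.

    FOV ids are ``{patient}_{region}{index}``; each (patient, region)
    pair is one tissue core. When ``abundance_gradient`` is set, the
    number of planted clusters of the survival target niche rises
    linearly across patients, so per-patient niche abundance varies and
    the survival association is identifiable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    target = config.survival.target_niche
    base_clusters = next(
        (s.clusters_per_fov for s in config.niche_specs if s.name == target), None
    )
    frames = []
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        override = None
        if config.abundance_gradient and base_clusters is not None:
            frac = p / max(config.n_patients - 1, 1)
            override = {target: int(round(2 * base_clusters * frac))}
        for region in REGIONS:
            n_fovs = config.fovs_per_patient.get(region, 0)
            specs = [s for s in config.niche_specs if region in s.regions]
            planted_expect = sum(
                (override.get(s.name, s.clusters_per_fov) if override
                 else s.clusters_per_fov) * s.cells_per_cluster
                for s in specs
            )
            n_bg = max(config.cell_density - planted_expect, 0.0)
            for f in range(n_fovs):
                fov = plant_niche_pattern(
                    config.fov_size,
                    config.baseline_proportions[region],
                    n_bg,
                    specs,
                    rng,
                    clusters_override=override,
                )
                fov["fov_id"] = f"{patient}_{region}{f + 1}"
                fov["core_id"] = f"{patient}_{region}"
                fov["patient_id"] = patient
                fov["region"] = region
                frames.append(fov)
    cells = pd.concat(frames, ignore_index=True)
    cells["cell_id"] = [f"c{i:06d}" for i in range(len(cells))]
    cols = ["cell_id", "x_um", "y_um", "fov_id", "core_id", "patient_id",
            "region", "cell_type"]
    truth_niche = cells["planted_niche"].to_numpy()
    cells = cells[cols + ["planted_niche"]]
    matrix, planted_genes, proximal = sample_expression(
        cells, config.gene_model, config.coupling, rng
    )
    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "planted_niche": truth_niche,
            "proximal": proximal,
        }
    )
    abundance = (
        pd.Series(truth_niche == target, index=cells["patient_id"])
        .groupby(level=0)
        .mean()
        .rename("abundance")
    )
    scale = abundance.max()
    survival = attach_survival(
        abundance / scale if scale > 0 else abundance, config.survival, rng
    )
    return SyntheticDataset(
        cells=cells.drop(columns="planted_niche"),
        matrix=matrix,
        truth=truth,
        planted_de_genes=planted_genes,
        survival=survival,
        abundance=abundance,
        config=config,
    )


# ---------------------------------------------------------------------------
# defaults emulating the studied cohort


CELL_TYPES = (
    "Malignant", "Hepatocyte", "Cholangiocyte", "Capillary",
    "mCAF", "iCAF", "T/NK", "B/Plasma", "Myeloid",
)

SIGNATURES: dict[str, list[str]] = {
    "Malignant": ["SPINK1", "HSPB1", "ENO1", "MIF", "NUPR1", "HSP90AA1"],
    "Hepatocyte": ["ALB", "APOA1", "TTR", "TF", "CYP3A4"],
    "Cholangiocyte": ["KRT19", "KRT7", "EPCAM", "SOX9"],
    "Capillary": ["DLL4", "PECAM1", "VWF", "CD34", "JAG1", "DLL1"],
    "mCAF": ["NOTCH3", "COL1A1", "ACTA2", "TAGLN", "COL1A2", "POSTN"],
    "iCAF": ["IL6", "CXCL12", "CCL19", "CCL21", "PDGFRA"],
    "T/NK": ["CD3E", "CD8A", "GZMB", "NKG7", "IL7R"],
    "B/Plasma": ["MS4A1", "CD79A", "MZB1", "IGHG1"],
    "Myeloid": ["CD68", "LYZ", "ITGAM", "C1QA", "S100A8"],
}

# NOTCH-response / angiogenesis program boosted in receivers near senders;
# mostly low-baseline response genes so the boost barely moves cell totals
RECEPTOR_PROGRAM = ("NOTCH3", "HES1", "HEY1", "ANGPT2", "ESM1", "APLN")
RESPONSE_GENES = ("HES1", "HEY1", "ANGPT2", "ESM1", "APLN")

BASELINE_PROPORTIONS: dict[str, dict[str, float]] = {
    "T": {"Malignant": 0.45, "Hepatocyte": 0.05, "Cholangiocyte": 0.03,
          "Capillary": 0.12, "mCAF": 0.12, "iCAF": 0.03, "T/NK": 0.08,
          "B/Plasma": 0.04, "Myeloid": 0.08},
    "B": {"Malignant": 0.20, "Hepatocyte": 0.20, "Cholangiocyte": 0.05,
          "Capillary": 0.10, "mCAF": 0.12, "iCAF": 0.06, "T/NK": 0.15,
          "B/Plasma": 0.04, "Myeloid": 0.08},
    "N": {"Malignant": 0.00, "Hepatocyte": 0.55, "Cholangiocyte": 0.05,
          "Capillary": 0.08, "mCAF": 0.03, "iCAF": 0.10, "T/NK": 0.10,
          "B/Plasma": 0.04, "Myeloid": 0.05},
}


def default_niche_specs() -> list[NicheSpec]:
    """Nine planted niches echoing the niche taxonomy of an HCC cohort."""
    return [
        NicheSpec("Malignant_Capi", {"Malignant": 0.55, "Capillary": 0.45},
                  regions=("T",)),
        NicheSpec("Capi_CAFs", {"Capillary": 0.45, "mCAF": 0.35, "iCAF": 0.20},
                  regions=("T", "B")),
        NicheSpec("Malignant_SPINK1", {"Malignant": 1.0}, regions=("T",)),
        NicheSpec("iCAFs_Immune",
                  {"iCAF": 0.40, "T/NK": 0.25, "Myeloid": 0.25, "B/Plasma": 0.10},
                  regions=("N",)),
        NicheSpec("CD8_CD4_DCs", {"T/NK": 0.55, "Myeloid": 0.45}, regions=("B",)),
        NicheSpec("mCAFs_Chola", {"mCAF": 0.55, "Cholangiocyte": 0.45},
                  regions=("T", "B")),
        NicheSpec("Tregs", {"T/NK": 0.95, "Hepatocyte": 0.05}, regions=("T",)),
        NicheSpec("B_Plasma", {"B/Plasma": 0.90, "T/NK": 0.10}, regions=("N",)),
        NicheSpec("Nphs", {"Myeloid": 0.95, "Hepatocyte": 0.05},
                  regions=("T", "B", "N")),
    ]


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default synthetic cohort used throughout the tests and docs."""
    gene_model = GeneModel(
        n_genes=160,
        signatures={k: list(v) for k, v in SIGNATURES.items()},
        zero_outside=("DLL4",),
        extra_genes=RESPONSE_GENES,
    )
    coupling = CouplingSpec(receptor_program=RECEPTOR_PROGRAM)
    cfg = CohortConfig(
        baseline_proportions={r: dict(p) for r, p in BASELINE_PROPORTIONS.items()},
        niche_specs=default_niche_specs(),
        gene_model=gene_model,
        coupling=coupling,
        survival=SurvivalSpec(),
        seed=seed,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-dict echo of a config, suitable for YAML serialization."""
    return asdict(config)
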