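"""Synthetic cohorts with the statistical structure of a family methylation study.

The generator emulates a multi-generation family cohort profiled on a
450K-style methylation array: seven extended pedigrees spanning four
generations (parent-offspring, sibling, avuncular, grand-avuncular, cousin
pairs ...), ages 6-85 assigned by generation, adult metabolic-syndrome status
at ~24% prevalence, and per-probe M values drawn from the additive polygenic
model the association stage assumes:

    M_p = mu_p + b_p * age + s_p * sex + C gamma_p + g + eps

with ``g ~ MVN(0, 2 Phi sigma_g^2)`` (matrix square root of ``2 Phi`` via a
symmetric eigendecomposition), iid residual noise, Dirichlet-distributed cell
proportions ``C`` acting through probe-specific loadings, and age slopes
``b_p`` of magnitude 0.02-0.04 M-units/year, positive for 64% of the
age-associated probes. ``heritability_h2`` splits the non-fixed variance
``residual_sd**2`` into polygenic and noise parts
(``sigma_g^2 = h2 * residual_sd^2``), so ``residual_sd=0`` is the exact
noiseless limit.

Probe positions form planted dense clusters (>= 10 probes, ~1 kb spacing,
one shared sign per region) against a background spaced > 10 kb apart, so
the cluster caller has ground truth to recover. A designated handful of
age probes get MetS-dependent slopes (MetS slope = multiplier x non-MetS
slope, negative multiplier by default, mirroring the observed sign flips).

Every quantity used to generate the data is emitted in a per-probe truth
table and a per-sample cell-proportion table, and the same file formats the
real-data mode reads can be written with :func:`write_cohort`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cellcomp import CELL_TYPES, CellTypeReference
from .pedigree import Individual, KinshipMatrix, Pedigree, kinship_matrix, write_pedigree
from .preprocess import GENE_REGIONS, m_to_beta

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_pedigree",
    "simulate_probe_map",
    "simulate_methylation",
    "simulate_cohort",
    "write_cohort",
]

# rng stream keys: one independent child stream per generation stage
_STREAM_PEDIGREE = 1
_STREAM_PROBEMAP = 2
_STREAM_METHYL = 3

ADULT_AGE = 18.0
CLUSTER_REGION_SIZE = 12  # probes per planted cluster region
MARRIAGE_PROB = 0.5       # chance that a 3rd+ child founds a new mating

# typical whole-blood composition, Dirichlet mean
_BLOOD_FRACTIONS = {
    "monocytes": 0.08,
    "granulocytes": 0.60,
    "CD8T": 0.08,
    "CD4T": 0.15,
    "NK": 0.04,
    "B": 0.05,
}
_DIRICHLET_CONC = 50.0
_N_REF_PROBES = 60
_CELL_NOISE_SD = 0.02


@dataclass
class SimulationConfig:
    n_families: int = 7
    generations: int = 4
    offspring_per_mating: tuple[int, int] = (2, 3)  # inclusive range
    n_probes: int = 2000
    n_age_probes: int = 60
    age_effect_range: tuple[float, float] = (0.02, 0.04)  # |slope|, M-units/year
    positive_fraction: float = 0.64
    heritability_h2: float = 0.4
    residual_sd: float = 0.3  # total non-fixed SD; h2 splits it
    sex_effect_sd: float = 0.1
    cell_effect_sd: float = 0.5  # SD of per-probe cell-composition loadings
    n_clustered_regions: int = 3
    cluster_probe_spacing: int = 1000  # bp
    mets_prevalence_adults: float = 0.24
    mets_slope_multiplier: float = -0.37  # MetS slope = multiplier * non-MetS slope
    n_mets_probes: int = 4
    cell_types: tuple[str, ...] = CELL_TYPES
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.offspring_per_mating, int):
            self.offspring_per_mating = (self.offspring_per_mating,) * 2
        if self.generations < 2:
            raise ValueError("generations must be >= 2")
        if not 0.0 <= self.heritability_h2 < 1.0:
            raise ValueError("heritability_h2 must be in [0, 1)")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.n_age_probes > self.n_probes:
            raise ValueError("n_age_probes cannot exceed n_probes")
        if self.n_clustered_regions * 10 > self.n_probes:
            raise ValueError("too many clustered regions for n_probes")
        if tuple(self.cell_types) != CELL_TYPES:
            raise ValueError(f"cell_types must be {CELL_TYPES}")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


@dataclass
class SyntheticCohort:
    pedigree: Pedigree
    phenotypes: pd.DataFrame          # index sample id: age, sex (0/1), mets (0/1/NaN)
    m_matrix: pd.DataFrame            # analysis probes x samples, M values
    beta_matrix: pd.DataFrame         # derived, 2^M / (2^M + 1)
    annotation: pd.DataFrame          # probe_id -> chromosome, position, gene, region
    truth: pd.DataFrame               # per-probe generating parameters
    cell_proportions: pd.DataFrame    # per-sample true mixing weights
    cell_reference: CellTypeReference
    cell_signal_beta: pd.DataFrame    # deconvolution probes x samples, beta
    kinship: KinshipMatrix
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Multi-generation families with the classic outbred relationship classes.

    Each family starts from a founder couple; every mating produces
    ``offspring_per_mating`` children; in non-final generations the first two
    children always marry an incoming founder spouse (guaranteeing sibling,
    avuncular and cousin pairs once ``generations >= 3``), later children
    marry with probability 1/2. No inbred matings are generated.
    """
    rng = cfg._rng(_STREAM_PEDIGREE)
    lo, hi = cfg.offspring_per_mating
    members: list[Individual] = []
    for f in range(1, cfg.n_families + 1):
        fid = f"F{f}"
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{fid}_I{counter:03d}"

        father, mother = new_id(), new_id()
        members.append(Individual(father, None, None, "male", fid))
        members.append(Individual(mother, None, None, "female", fid))
        couples = [(father, mother, 0)]  # (father, mother, generation of parents)
        for g in range(1, cfg.generations):
            next_couples = []
            for fa, mo, _ in couples:
                n_kids = int(rng.integers(lo, hi + 1))
                for c in range(n_kids):
                    kid = new_id()
                    sex = "male" if rng.random() < 0.5 else "female"
                    members.append(Individual(kid, fa, mo, sex, fid))
                    final = g == cfg.generations - 1
                    marries = (c < 2) or (rng.random() < MARRIAGE_PROB)
                    if not final and marries:
                        spouse = new_id()
                        sp_sex = "female" if sex == "male" else "male"
                        members.append(Individual(spouse, None, None, sp_sex, fid))
                        pair = (kid, spouse) if sex == "male" else (spouse, kid)
                        next_couples.append((*pair, g))
            couples = next_couples
    return Pedigree(members)


def _generation_depths(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}

    def d(iid: str) -> int:
        if iid in depth:
            return depth[iid]
        ind = ped[iid]
        parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
        depth[iid] = 0 if not parents else 1 + max(d(p) for p in parents)
        return depth[iid]

    for iid in ped.ids:
        d(iid)
    return depth


def _simulate_phenotypes(ped: Pedigree, cfg: SimulationConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Ages by generation (founders oldest), sex from the pedigree, adult MetS."""
    depth = _generation_depths(ped)
    # place the deepest generation near childhood, ~24 years per generation
    max_depth = max(depth.values())
    ages, sexes, mets = {}, {}, {}
    for ind in ped:
        d = depth[ind.id]
        if ind.is_founder and d == 0:
            # married-in founders sit at their spouse's generation; detect via kids
            kids = [m for m in ped if ind.id in (m.father_id, m.mother_id)]
            if kids:
                d = min(depth[k.id] for k in kids) - 1
        mean_age = 82.0 - 24.0 * d
        age = float(np.clip(mean_age + rng.uniform(-5.0, 5.0), 6.0, 85.0))
        ages[ind.id] = round(age, 1)
        sexes[ind.id] = 1 if ind.sex == "male" else 0
        if age >= ADULT_AGE:
            mets[ind.id] = float(rng.random() < cfg.mets_prevalence_adults)
        else:
            mets[ind.id] = np.nan
    pheno = pd.DataFrame({"age": ages, "sex": sexes, "mets": mets})
    pheno.index.name = "id"
    return pheno.loc[ped.ids]


# ---------------------------------------------------------------------------
# Probe map
# ---------------------------------------------------------------------------

def simulate_probe_map(cfg: SimulationConfig) -> pd.DataFrame:
    """Probe annotation with planted dense regions and sparse background.

    The first ``n_clustered_regions`` autosomes each carry one region of
    ``CLUSTER_REGION_SIZE`` probes at ``cluster_probe_spacing`` bp; remaining
    probes are laid out round-robin over chromosomes 1-22 at 20,001 bp steps
    (just beyond the 10 kb clustering gap). Cluster regions get one gene
    symbol each; a sample of background probes also carry genes so the
    enrichment background is non-trivial.
    """
    rng = cfg._rng(_STREAM_PROBEMAP)
    rows = []
    pid = 0

    def probe_id() -> str:
        nonlocal pid
        pid += 1
        return f"cg{pid:06d}"

    n_cluster_probes = cfg.n_clustered_regions * CLUSTER_REGION_SIZE
    if n_cluster_probes > cfg.n_probes:
        raise ValueError("n_probes too small for the requested cluster regions")
    for r in range(cfg.n_clustered_regions):
        chrom = str((r % 22) + 1)
        start = 500_000 + 200_000 * (r // 22)
        gene = f"CLGENE{r + 1}"
        for j in range(CLUSTER_REGION_SIZE):
            rows.append(
                {
                    "probe_id": probe_id(),
                    "chromosome": chrom,
                    "position": start + j * cfg.cluster_probe_spacing,
                    "gene": gene,
                    "region": GENE_REGIONS[j % len(GENE_REGIONS)],
                    "cluster_region": f"region{r + 1}",
                }
            )
    n_background = cfg.n_probes - n_cluster_probes
    per_chrom_pos = {str(c): 2_000_000 for c in range(1, 23)}
    for j in range(n_background):
        chrom = str((j % 22) + 1)
        pos = per_chrom_pos[chrom]
        per_chrom_pos[chrom] += 20_001
        gene = f"BGGENE{j // 5 + 1}" if rng.random() < 0.5 else ""
        rows.append(
            {
                "probe_id": probe_id(),
                "chromosome": chrom,
                "position": pos,
                "gene": gene,
                "region": GENE_REGIONS[j % len(GENE_REGIONS)] if gene else "intergenic",
                "cluster_region": "",
            }
        )
    ann = pd.DataFrame(rows).set_index("probe_id")
    return ann


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(ped: Pedigree, cfg: SimulationConfig) -> SyntheticCohort:
    """Draw the full synthetic cohort given a pedigree.

    See the module docstring for the generating model. Raises if the kinship
    matrix is not positive semidefinite (cannot happen for a valid pedigree).
    """
    rng = cfg._rng(_STREAM_METHYL)
    K = kinship_matrix(ped)
    samples = K.sample_ids
    n = len(samples)
    pheno = _simulate_phenotypes(ped, cfg, rng)
    ann = simulate_probe_map(cfg)
    probes = ann.index
    p = len(probes)

    # matrix square root of 2*Phi via symmetric eigendecomposition
    lam, U = np.linalg.eigh(K.two_phi)
    if lam.min() < -1e-8:
        raise ValueError("kinship matrix 2*Phi is not positive semidefinite")
    L = U * np.sqrt(np.clip(lam, 0.0, None))

    # --- per-probe generating parameters ------------------------------------
    is_cluster = (ann["cluster_region"] != "").to_numpy()
    cluster_ids = ann["cluster_region"].to_numpy()
    slopes = np.zeros(p)
    # planted region sign: one sign per region, positive with positive_fraction
    for r in sorted(set(cluster_ids) - {""}):
        mask = cluster_ids == r
        sign = 1.0 if rng.random() < cfg.positive_fraction else -1.0
        slopes[mask] = sign * rng.uniform(*cfg.age_effect_range, size=mask.sum())
    n_extra = max(0, cfg.n_age_probes - int(is_cluster.sum()))
    background_idx = np.flatnonzero(~is_cluster)
    extra = rng.choice(background_idx, size=min(n_extra, len(background_idx)),
                       replace=False)
    signs = np.where(rng.random(len(extra)) < cfg.positive_fraction, 1.0, -1.0)
    slopes[extra] = signs * rng.uniform(*cfg.age_effect_range, size=len(extra))
    is_age = slopes != 0.0

    # MetS-interaction probes among the non-cluster age probes
    mets_pool = [i for i in extra if slopes[i] != 0.0]
    mets_idx = np.array(
        rng.choice(mets_pool, size=min(cfg.n_mets_probes, len(mets_pool)),
                   replace=False) if mets_pool else [], dtype=int)
    slope_no_mets = slopes.copy()
    slope_mets = slopes.copy()
    slope_mets[mets_idx] = cfg.mets_slope_multiplier * slopes[mets_idx]

    mu = rng.uniform(-3.0, 3.0, size=p)
    sex_eff = rng.normal(0.0, cfg.sex_effect_sd, size=p)
    gamma = rng.normal(0.0, cfg.cell_effect_sd, size=(p, len(CELL_TYPES)))

    sigma_tot = cfg.residual_sd
    sigma_g = np.sqrt(cfg.heritability_h2) * sigma_tot
    sigma_e = np.sqrt(1.0 - cfg.heritability_h2) * sigma_tot

    # --- per-sample structure ------------------------------------------------
    age = pheno["age"].to_numpy(float)
    sex = pheno["sex"].to_numpy(float)
    mets01 = pheno["mets"].fillna(0.0).to_numpy(float)  # children follow non-MetS
    alpha = _DIRICHLET_CONC * np.array([_BLOOD_FRACTIONS[c] for c in CELL_TYPES])
    C = rng.dirichlet(alpha, size=n)  # n x 6

    eff_slope = slope_no_mets[:, None] + np.outer(slope_mets - slope_no_mets, mets01)
    M = (
        mu[:, None]
        + eff_slope * age[None, :]
        + np.outer(sex_eff, sex)
        + gamma @ C.T
        + sigma_g * (rng.normal(size=(p, n)) @ L.T)
        + sigma_e * rng.normal(size=(p, n))
    )
    m_matrix = pd.DataFrame(M, index=probes, columns=samples)
    beta_matrix = pd.DataFrame(m_to_beta(M), index=probes, columns=samples)

    # --- deconvolution reference and its bulk signal -------------------------
    ref_probes = [f"ref{j:03d}" for j in range(1, _N_REF_PROBES + 1)]
    ref_beta = pd.DataFrame(
        rng.uniform(0.05, 0.95, size=(_N_REF_PROBES, len(CELL_TYPES))),
        index=ref_probes, columns=list(CELL_TYPES),
    )
    bulk = C @ ref_beta.to_numpy().T + rng.normal(0.0, _CELL_NOISE_SD,
                                                  size=(n, _N_REF_PROBES))
    cell_signal = pd.DataFrame(
        np.clip(bulk.T, 1e-3, 1.0 - 1e-3), index=ref_probes, columns=samples
    )

    truth = pd.DataFrame(
        {
            "true_slope": slopes,
            "slope_no_mets": slope_no_mets,
            "slope_mets": slope_mets,
            "is_age_probe": is_age,
            "is_mets_probe": np.isin(np.arange(p), mets_idx),
            "cluster_region": cluster_ids,
            "baseline_m": mu,
            "sex_effect": sex_eff,
        },
        index=probes,
    )
    props = pd.DataFrame(C, index=samples, columns=list(CELL_TYPES))
    props.index.name = "id"
    return SyntheticCohort(
        pedigree=ped,
        phenotypes=pheno,
        m_matrix=m_matrix,
        beta_matrix=beta_matrix,
        annotation=ann.drop(columns=["cluster_region"]),
        truth=truth,
        cell_proportions=props,
        cell_reference=CellTypeReference(ref_beta),
        cell_signal_beta=cell_signal,
        kinship=K,
        config=cfg,
    )


def simulate_cohort(cfg: SimulationConfig | None = None) -> SyntheticCohort:
    """Pedigree + phenotypes + methylation in one deterministic call."""
    cfg = cfg or SimulationConfig()
    return simulate_methylation(simulate_pedigree(cfg), cfg)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, Path]:
    """Write the cohort in the same formats the real-data mode reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.ped",
        "phenotypes": outdir / "phenotypes.tsv",
        "beta": outdir / "beta.tsv",
        "m": outdir / "m_values.tsv",
        "annotation": outdir / "annotation.tsv",
        "truth": outdir / "truth.tsv",
        "cell_reference": outdir / "cell_reference.tsv",
        "cell_signal_beta": outdir / "cell_signal_beta.tsv",
        "cell_proportions": outdir / "cell_proportions_truth.tsv",
        "kinship": outdir / "kinship.tsv",
    }
    write_pedigree(cohort.pedigree, paths["pedigree"])
    cohort.phenotypes.to_csv(paths["phenotypes"], sep="\t")
    cohort.beta_matrix.to_csv(paths["beta"], sep="\t", index_label="probe_id")
    cohort.m_matrix.to_csv(paths["m"], sep="\t", index_label="probe_id")
    cohort.annotation.to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    cohort.truth.to_csv(paths["truth"], sep="\t", index_label="probe_id")
    cohort.cell_reference.write_tsv(paths["cell_reference"])
    cohort.cell_signal_beta.to_csv(paths["cell_signal_beta"], sep="\t",
                                   index_label="probe_id")
    cohort.cell_proportions.to_csv(paths["cell_proportions"], sep="\t")
    cohort.kinship.write_tsv(paths["kinship"])
    return paths
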