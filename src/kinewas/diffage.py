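"""MetS-dependent differential methylation-aging tests.

At candidate CpG sites the question is whether the per-year methylation slope
(and the intercept) differs between adults with metabolic syndrome (MetS,
ATPIII classification, 0/1) and those without. Two nested comparisons are run
within the same kinship-aware mixed model used for the genome-wide scan:

* equal slopes  — full model ``M ~ age + MetS + age:MetS + covariates`` versus
  the model without the interaction; the likelihood-ratio P is
  ``p_diff_slope``.
* equal intercepts — ``M ~ age + MetS + covariates`` versus ``M ~ age +
  covariates``; the likelihood-ratio P is ``p_diff_intercept``.

Group slopes are read off the interaction model: the non-MetS slope is the
age coefficient, the MetS slope adds the interaction coefficient. The pooled
slope (``beta_age_all``) comes from the model with no MetS terms and equals a
plain age-association fit on the same adult subset. MetS is undefined for
children, so samples without a status are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import KinshipCovariance, bonferroni_threshold, SignificanceConfig, \
    fit_probe, lrt_drop_term
from .pedigree import KinshipMatrix

__all__ = [
    "DifferentialAgingResult",
    "test_differential_aging",
    "run_differential_aging",
    "candidate_screen",
    "MIN_GROUP_SIZE",
]

MIN_GROUP_SIZE = 5  # smaller groups are flagged unreliable


@dataclass
class DifferentialAgingResult:
    probe_id: str
    beta_age_all: float
    beta_age_no_mets: float
    beta_age_mets: float
    p_diff_slope: float
    p_diff_intercept: float
    opposite_signs: bool
    converged: bool
    reliable: bool
    n_no_mets: int
    n_mets: int


def _subset_kinship(K: KinshipMatrix, samples: list[str]) -> np.ndarray:
    order = [K.sample_ids.index(s) for s in samples]
    return K.two_phi[np.ix_(order, order)]


def test_differential_aging(
    y: pd.Series,
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    cell_covariates: pd.DataFrame | None = None,
    probe_id: str = "",
    age_col: str = "age",
    sex_col: str = "sex",
    mets_col: str = "mets",
    use_kinship: bool = True,
) -> DifferentialAgingResult:
    """Slope/intercept equality tests by MetS status for one probe.

    ``y`` holds per-sample M values indexed by sample id; ``phenotypes`` must
    carry age, sex and a 0/1 MetS column (missing = excluded, e.g. children).
    With ``use_kinship=False`` the polygenic effect is dropped (plain OLS
    equivalent), for comparison against the mixed-model defaults.
    """
    pheno = phenotypes.loc[phenotypes[mets_col].notna()]
    samples = [s for s in y.index if s in pheno.index]
    if not samples:
        raise ValueError("no samples with defined MetS status")
    pheno = pheno.loc[samples]
    mets = pheno[mets_col].astype(float)
    n1, n0 = int((mets == 1).sum()), int((mets == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError(
            f"MetS indicator is constant ({n0} non-MetS vs {n1} MetS samples); "
            "both groups must be non-empty"
        )
    reliable = min(n0, n1) >= MIN_GROUP_SIZE
    if not reliable:
        warnings.warn(
            f"group sizes {n0}/{n1} below {MIN_GROUP_SIZE}; result flagged unreliable",
            stacklevel=2,
        )

    base = pheno[[age_col, sex_col]].astype(float)
    if cell_covariates is not None:
        base = base.join(cell_covariates.loc[samples].astype(float))
    two_phi = (
        _subset_kinship(K, samples) if use_kinship else np.eye(len(samples))
    )
    cov = KinshipCovariance(two_phi)
    yv = y.loc[samples]

    X_full = base.copy()
    X_full[mets_col] = mets
    X_full["age_x_mets"] = base[age_col] * mets
    X_add = base.copy()
    X_add[mets_col] = mets

    try:
        m_full = fit_probe(yv, X_full, cov)
        m_add = fit_probe(yv, X_add, cov)
        m_pool = fit_probe(yv, base, cov)
    except np.linalg.LinAlgError:
        return DifferentialAgingResult(probe_id, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, False, False, reliable, n0, n1)

    ok = m_full.fit.converged and m_add.fit.converged and m_pool.fit.converged
    if not ok:
        return DifferentialAgingResult(probe_id, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, False, False, reliable, n0, n1)
    b_age = m_full.coef(age_col)[0]
    b_int = m_full.coef("age_x_mets")[0]
    _, p_slope, ok1 = lrt_drop_term(m_full, "age_x_mets")
    _, p_icpt, ok2 = lrt_drop_term(m_add, mets_col)
    beta_no_mets = b_age
    beta_mets = b_age + b_int
    return DifferentialAgingResult(
        probe_id=probe_id,
        beta_age_all=m_pool.coef(age_col)[0],
        beta_age_no_mets=beta_no_mets,
        beta_age_mets=beta_mets,
        p_diff_slope=p_slope,
        p_diff_intercept=p_icpt,
        opposite_signs=bool(beta_no_mets * beta_mets < 0),
        converged=ok1 and ok2,
        reliable=reliable,
        n_no_mets=n0,
        n_mets=n1,
    )


def run_differential_aging(
    m_matrix: pd.DataFrame,
    probe_ids,
    phenotypes: pd.DataFrame,
    K: KinshipMatrix,
    cell_covariates: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Differential-aging tests over a set of candidate probes."""
    rows = []
    for probe in probe_ids:
        res = test_differential_aging(
            m_matrix.loc[probe, :], phenotypes, K, cell_covariates,
            probe_id=str(probe), **kwargs,
        )
        rows.append(vars(res))
    out = pd.DataFrame(rows)
    if out.empty:
        out = pd.DataFrame(columns=[f.name for f in
                                    DifferentialAgingResult.__dataclass_fields__.values()])
    out = out.set_index("probe_id")
    if annotation is not None:
        out = out.join(annotation, how="left")
    return out


def candidate_screen(
    results: pd.DataFrame,
    gene_list,
    sig: SignificanceConfig | None = None,
    threshold: float | None = None,
) -> list[str]:
    """Probes in listed candidate genes that pass genome-wide significance.

    ``results`` must carry ``gene`` and ``p_age`` columns. The threshold
    defaults to the Bonferroni cutoff stored by the scan, or is derived from
    ``sig``.
    """
    genes = set(gene_list)
    if not genes:
        warnings.warn("empty candidate gene list; no probes screened", stacklevel=2)
        return []
    if threshold is None:
        if sig is not None:
            threshold = bonferroni_threshold(sig)
        else:
            threshold = results.attrs.get("bonferroni_threshold")
        if threshold is None:
            raise ValueError("no significance threshold available")
    hit = results["gene"].isin(genes) & (results["p_age"] < threshold)
    return [str(i) for i in results.index[hit.fillna(False)]]
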