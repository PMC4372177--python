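"""Methylation QC and transforms: beta/M conversion, probe filters, quantile norm.

Conventions for the Illumina 450K-style platform:

* ``beta = I_m / (I_u + I_m + alpha)`` with methylated/unmethylated intensities
  and a small stabilizing offset ``alpha`` (platform convention 100); bounded
  fraction scale.
* ``M = log2((I_m + alpha) / (I_u + alpha))``; with ``alpha = 0`` this is the
  logit2 of beta. M values are preferred for regression because they are close
  to homoscedastic across the methylation range.

Probe-level QC:

* detection filter — drop a probe if its detection P value is >= 0.01 in more
  than 5% of samples;
* exclusion list — user-supplied ids (cross-reactive probes, polymorphic CpGs);
* range filter — drop probes whose beta range (max - min across samples) is
  below 0.17, the smallest difference the platform reliably discriminates.

The filters commute: the retained set is independent of the order in which
they are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "IntensityRecord",
    "QCConfig",
    "QCReport",
    "beta_from_intensities",
    "m_from_intensities",
    "beta_to_m",
    "m_to_beta",
    "detection_filter",
    "range_filter",
    "quantile_normalize",
    "apply_qc",
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "read_exclusion_list",
]

BETA_CLAMP = 1e-6  # beta in {0,1} clamped to [BETA_CLAMP, 1-BETA_CLAMP] before logit

GENE_REGIONS = ("TSS1500", "TSS200", "5'UTR", "First exon", "Body", "3'UTR", "intergenic")


@dataclass(frozen=True)
class IntensityRecord:
    """Methylated/unmethylated fluorescence intensities plus offset alpha."""

    i_m: float
    i_u: float
    alpha: float = 100.0


@dataclass
class QCConfig:
    detection_p_threshold: float = 0.01
    max_fail_fraction: float = 0.05
    beta_range_min: float = 0.17
    exclusion_list: frozenset[str] = field(default_factory=frozenset)
    apply_quantile_norm: bool = False

    def __post_init__(self):
        for name in ("detection_p_threshold", "max_fail_fraction", "beta_range_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        self.exclusion_list = frozenset(self.exclusion_list)


@dataclass
class QCReport:
    """Per-stage probe removal counts, written alongside filtered matrices."""

    n_input: int
    n_fail_detection: int
    n_excluded: int
    n_fail_range: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "input",
                    "detection_filter",
                    "exclusion_list",
                    "range_filter",
                    "retained",
                ],
                "n_probes_removed": [0, self.n_fail_detection, self.n_excluded,
                                     self.n_fail_range, 0],
                "n_probes": [self.n_input, None, None, None, self.n_retained],
            }
        )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def beta_from_intensities(rec: IntensityRecord):
    """Fraction-methylation ``I_m / (I_u + I_m + alpha)``."""
    denom = np.asarray(rec.i_u) + np.asarray(rec.i_m) + rec.alpha
    if np.any(denom <= 0):
        raise ValueError("beta undefined: I_u + I_m + alpha must be positive")
    return np.asarray(rec.i_m) / denom


def m_from_intensities(rec: IntensityRecord):
    """Log-ratio methylation ``log2((I_m + alpha) / (I_u + alpha))``."""
    num = np.asarray(rec.i_m, dtype=float) + rec.alpha
    den = np.asarray(rec.i_u, dtype=float) + rec.alpha
    if np.any(num <= 0) or np.any(den <= 0):
        raise ValueError("M undefined: shifted intensities must be positive")
    return np.log2(num / den)


def beta_to_m(beta):
    """logit2 transform; beta in {0,1} is clamped (with a warning) first."""
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0,1]")
    if np.any((b <= 0) | (b >= 1)):
        warnings.warn(
            f"beta values of exactly 0 or 1 clamped to [{BETA_CLAMP}, {1-BETA_CLAMP}]",
            stacklevel=2,
        )
        b = np.clip(b, BETA_CLAMP, 1.0 - BETA_CLAMP)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse logit2: ``2^M / (2^M + 1)``, numerically stable for large |M|."""
    m = np.asarray(m, dtype=float)
    # expit formulation avoids overflow for large positive M
    out = np.where(m >= 0, 1.0 / (1.0 + 2.0 ** (-m)), 2.0 ** m / (2.0 ** m + 1.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def detection_filter(detp: pd.DataFrame, cfg: QCConfig | None = None) -> pd.Index:
    """Retain probes whose detection-P failure fraction is within tolerance.

    A sample "fails" a probe when detection P >= ``detection_p_threshold``;
    the probe is dropped when the failing fraction exceeds
    ``max_fail_fraction`` (strictly more than 5% of samples by default).
    """
    cfg = cfg or QCConfig()
    fail_frac = (detp.to_numpy(float) >= cfg.detection_p_threshold).mean(axis=1)
    return detp.index[fail_frac <= cfg.max_fail_fraction]


def range_filter(beta: pd.DataFrame, cfg: QCConfig | None = None) -> pd.Index:
    """Retain probes whose beta range across samples is >= ``beta_range_min``.

    Probes "ranging" less than the platform's discrimination limit (0.17)
    cannot show a biologically meaningful change and are excluded.
    """
    cfg = cfg or QCConfig()
    if beta.shape[1] < 2:
        raise ValueError("beta range undefined with fewer than 2 samples")
    vals = beta.to_numpy(float)
    rng = vals.max(axis=1) - vals.min(axis=1)
    return beta.index[rng >= cfg.beta_range_min]


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-sample mean of
    order statistics; ties within a column receive the mean of the reference
    values their ranks span (the standard mean-rank convention).
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = values.to_numpy(float)
    ref = np.mean(np.sort(arr, axis=0), axis=1)  # mean of order statistics
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def apply_qc(
    beta: pd.DataFrame,
    cfg: QCConfig,
    detp: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full probe-QC chain on a beta matrix.

    Order: detection filter (if a detection-P matrix is given) -> exclusion
    list -> beta-range filter -> optional quantile normalization. Returns the
    filtered (possibly normalized) beta matrix and a removal-count report.
    """
    n_input = beta.shape[0]
    kept = beta.index
    n_det = 0
    if detp is not None:
        if not detp.index.equals(beta.index) or list(detp.columns) != list(beta.columns):
            raise ValueError("detection-P matrix must align with the beta matrix")
        kept_det = detection_filter(detp, cfg)
        n_det = n_input - len(kept_det)
        kept = kept.intersection(kept_det, sort=False)
    excl = kept.intersection(pd.Index(sorted(cfg.exclusion_list)), sort=False)
    kept = kept.difference(excl, sort=False)
    sub = beta.loc[kept]
    kept_range = range_filter(sub, cfg)
    n_range = len(kept) - len(kept_range)
    out = beta.loc[kept_range]
    if cfg.apply_quantile_norm:
        out = quantile_normalize(out)
    report = QCReport(
        n_input=n_input,
        n_fail_detection=n_det,
        n_excluded=len(excl),
        n_fail_range=n_range,
        n_retained=out.shape[0],
    )
    return out, report


# ---------------------------------------------------------------------------
# Tabular I/O (TSV, probes as rows, header = sample ids)
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="probe_id")


def read_annotation(path) -> pd.DataFrame:
    """Probe annotation TSV: probe_id, chromosome, position (1-based), gene, region."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     dtype={"chromosome": str, "gene": str, "region": str})
    df.index = df.index.astype(str)
    if (df["position"] <= 0).any():
        raise ValueError("annotation positions must be positive 1-based bp")
    df["gene"] = df["gene"].fillna("")
    return df


def read_exclusion_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )
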