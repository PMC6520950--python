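"""Readers and writers for cBioPortal-style flat files, cohort alignment,
and the run configuration.

All tables are plain TSV.  Expression: first column gene symbol, header row
of sample ids.  Clinical: named columns with flexible status dialects
(``0/1``, ``LIVING/DECEASED``, ``0:LIVING/1:DECEASED``).  Copy number: a
gene x sample integer matrix restricted to the five GISTIC levels
{-2,-1,0,1,2}.  Mutations: long-format records (gene, sample, pathogenic).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

logger = logging.getLogger(__name__)

GISTIC_LEVELS = (-2, -1, 0, 1, 2)

_STATUS_TOKENS = {
    "0": 0, "1": 1,
    "LIVING": 0, "DECEASED": 1, "ALIVE": 0, "DEAD": 1,
    "0:LIVING": 0, "1:DECEASED": 1,
}


@dataclass
class GenomicEventsInput:
    """Somatic mutation records plus a discrete copy-number matrix."""

    mutations: pd.DataFrame  # columns: gene, sample, pathogenic
    cna: pd.DataFrame        # genes x samples, values in GISTIC_LEVELS

    def __post_init__(self) -> None:
        bad = set(np.unique(self.cna.to_numpy())) - set(GISTIC_LEVELS)
        if bad:
            raise FormatError(f"copy-number values outside GISTIC levels: {sorted(bad)}")


@dataclass
class RunConfig:
    """Pipeline settings; one object drives every stage.

    ``adjust`` is the residualization covariate set (subset of
    {age, stage, metagene}); ``corr_mode`` selects whether the significant-
    gene correlation matrix is built from continuous residuals or their
    median-binarized versions; ``loading_threshold`` is the minimum
    |loading| for a gene to be reported on the best binarized PC.
    """

    adjust: tuple[str, ...] = ("age", "stage", "metagene")
    alpha: float = 0.05
    B: int = 1000
    seed: int = 0
    corr_mode: str = "continuous"
    loading_threshold: float = 0.4
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.adjust) - {"age", "stage", "metagene"}
        if bad:
            raise ValueError(f"unknown adjustment covariates: {sorted(bad)}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.corr_mode not in ("continuous", "binarized"):
            raise ValueError("corr_mode must be 'continuous' or 'binarized'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "adjust" in raw and isinstance(raw["adjust"], (list, tuple)):
            raw["adjust"] = tuple(raw["adjust"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Duplicate gene rows are collapsed to the first occurrence (logged);
    missing cells remain NaN for downstream imputation.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed expression table: {exc}") from None
    if df.shape[1] == 0:
        raise FormatError(f"{path}: expression matrix has zero samples")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    df.index = df.index.astype(str).str.strip().str.upper()
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        logger.warning("duplicate gene rows collapsed to first occurrence: %s", dups)
        df = df[~df.index.duplicated(keep="first")]
    values = df.to_numpy(dtype=float)
    if np.isinf(values).any():
        raise FormatError(f"{path}: non-finite expression values")
    return df


def parse_os_status(token) -> int:
    key = str(token).strip().upper()
    if key in _STATUS_TOKENS:
        return _STATUS_TOKENS[key]
    raise FormatError(f"unrecognized overall-survival status token: {token!r}")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical table (sample, os_months, os_status, age, stage...).

    Rows with negative survival time are rejected with a log message.
    Unknown status tokens are a format error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    sample_c = pick("sample", "sample_id", "patient_id")
    time_c = pick("os_months", "os_time", "time")
    status_c = pick("os_status", "os_event", "status", "event")
    age_c = pick("age", "age_years", "age_at_diagnosis")
    stage_c = pick("stage", "ajcc_pathologic_tumor_stage", "pathologic_stage")
    cancer_c = pick("cancer_code", "cancer")
    if sample_c is None or time_c is None or status_c is None:
        raise FormatError(f"{path}: need sample, os_months and os_status columns")

    out = pd.DataFrame({
        "sample": df[sample_c].astype(str).str.strip(),
        "os_months": pd.to_numeric(df[time_c], errors="coerce"),
        "os_event": df[status_c].map(parse_os_status),
    })
    out["age_years"] = pd.to_numeric(df[age_c], errors="coerce") if age_c else np.nan
    out["stage"] = df[stage_c].str.strip() if stage_c else None
    if cancer_c:
        out["cancer_code"] = df[cancer_c].str.strip()
    if out["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in clinical table")

    bad = out["os_months"].isna() | (out["os_months"] < 0)
    if bad.any():
        logger.warning("rejected %d clinical records with missing/negative os_months",
                       int(bad.sum()))
        out = out[~bad]
    return out.reset_index(drop=True)


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read long-format mutation records with a pathogenicity flag."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise FormatError(f"{path}: missing one of columns {names}")

    out = pd.DataFrame({
        "gene": df[pick("gene", "hugo_symbol")].astype(str).str.strip().str.upper(),
        "sample": df[pick("sample", "sample_id", "tumor_sample_barcode")].astype(str).str.strip(),
        "pathogenic": pd.to_numeric(df[pick("pathogenic", "is_pathogenic")], errors="raise").astype(int),
    })
    if not out["pathogenic"].isin([0, 1]).all():
        raise FormatError(f"{path}: pathogenic flag must be 0/1")
    return out


def read_cna(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC-scored genes x samples copy-number matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str).str.strip().str.upper()
    values = df.to_numpy()
    bad = set(np.unique(values)) - set(GISTIC_LEVELS)
    if bad:
        raise FormatError(f"{path}: copy-number values outside GISTIC levels: {sorted(bad)}")
    return df.astype(int)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedCohort:
    """Expression and clinical restricted to a common, covariate-complete
    sample set (same order in both)."""

    expression: pd.DataFrame   # genes x samples
    clinical: pd.DataFrame     # one row per sample, same order as columns
    dropped: dict = field(default_factory=dict)


def align_cohort(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    required: Sequence[str] = (),
) -> AlignedCohort:
    """Intersect samples, drop those missing any required covariate.

    ``required`` names clinical columns ("age_years", "stage") that must be
    non-missing.  Raises on an empty intersection.
    """
    clin = clinical.set_index("sample", drop=False)
    common = [s for s in expression.columns if s in clin.index]
    dropped = {
        "expr_only": int(expression.shape[1] - len(common)),
        "clin_only": int(len(clin) - len(common)),
    }
    clin = clin.loc[common]
    for cov in required:
        if cov not in clin.columns:
            raise FormatError(f"required covariate {cov!r} absent from clinical table")
        miss = clin[cov].isna() | (clin[cov].astype(str).str.len() == 0)
        if miss.any():
            dropped[f"missing_{cov}"] = int(miss.sum())
            clin = clin[~miss]
    if len(clin) == 0:
        raise FormatError("no samples remain after aligning expression and clinical tables")
    keep = clin.index.tolist()
    if dropped:
        logger.info("cohort alignment dropped samples: %s", dropped)
    return AlignedCohort(
        expression=expression[keep],
        clinical=clin.reset_index(drop=True),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
                index: bool = True) -> None:
    """Write a result TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# repairsurv config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)
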