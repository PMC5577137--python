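"""Expression-matrix preprocessing for label-free shotgun proteomics.

The chain mirrors the standard label-free workflow for tumour cohorts:
quantifiability filtering (detection in >=75% of samples of at least one
group, >=2 unique peptides), log2 transform, downshifted-normal imputation
of missing-not-at-random low-abundance values, per-feature z-scoring, and a
location/scale batch correction.  An SRM transition-to-protein rule
(median light/heavy ratio over retained transitions) is included for
targeted verification data.

Matrices are pandas DataFrames with features in rows and samples in
columns; missing values are NaN (written as empty fields or ``NA`` in TSV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SrmTransitionSet",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "filter_quantifiable",
    "log2_transform",
    "impute_downshift",
    "zscore_rows",
    "correct_batch",
    "srm_protein_quant",
]


@dataclass
class ExpressionMatrix:
    """Feature x sample abundance table with per-feature metadata.

    Parameters
    ----------
    data
        DataFrame, rows = features, columns = samples; NaN marks missing.
    feature_kind
        Per-feature label, ``"protein"`` or ``"mirna"``.  Defaults to
        protein for every feature.
    unique_peptides
        Per-protein unique-peptide count used by the quantifiability
        filter; ignored for miRNAs.
    """

    data: pd.DataFrame
    feature_kind: pd.Series | None = None
    unique_peptides: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.feature_kind is None:
            self.feature_kind = pd.Series("protein", index=self.data.index)
        else:
            self.feature_kind = self.feature_kind.reindex(self.data.index)
        if self.unique_peptides is not None:
            self.unique_peptides = self.unique_peptides.reindex(self.data.index)

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            self.data.loc[ids],
            self.feature_kind.loc[ids],
            None if self.unique_peptides is None else self.unique_peptides.loc[ids],
        )


@dataclass
class SrmTransitionSet:
    """Light/heavy transition intensities for one peptide.

    Three transitions are monitored per endogenous (light) / internal
    standard (heavy) pair; transitions removed for interference may leave
    fewer, flagged by ``interference_removed``.
    """

    peptide_id: str
    protein_id: str
    light: np.ndarray = field(default_factory=lambda: np.empty(0))
    heavy: np.ndarray = field(default_factory=lambda: np.empty(0))
    interference_removed: bool = False

    def __post_init__(self) -> None:
        self.light = np.asarray(self.light, dtype=float)
        self.heavy = np.asarray(self.heavy, dtype=float)
        if self.light.shape != self.heavy.shape:
            raise ValueError("light/heavy transition counts differ")
        if np.any(self.light < 0) or np.any(self.heavy < 0):
            raise ValueError("negative transition intensity")
        if len(self.light) != 3 and not self.interference_removed:
            raise ValueError(
                "expected 3 transitions unless flagged interference_removed"
            )


# ---------------------------------------------------------------------------
# TSV I/O


def read_matrix_tsv(path: str | Path, meta_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column feature id, header = sample ids).

    ``meta_path`` may point to a TSV with columns ``feature_id``, ``kind``,
    ``unique_peptides``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    kind = peptides = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "kind" in meta:
            kind = meta["kind"]
        if "unique_peptides" in meta:
            peptides = meta["unique_peptides"]
    return ExpressionMatrix(df, kind, peptides)


def write_matrix_tsv(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Preprocessing chain


def _as_frame(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ExpressionMatrix) else matrix


def _rewrap(matrix, df: pd.DataFrame):
    if isinstance(matrix, ExpressionMatrix):
        peptides = matrix.unique_peptides
        if peptides is not None:
            peptides = peptides.reindex(df.index)
        return ExpressionMatrix(df, matrix.feature_kind.reindex(df.index), peptides)
    return df


def filter_quantifiable(
    matrix: ExpressionMatrix | pd.DataFrame,
    groups: Sequence,
    unique_peptides: pd.Series | None = None,
    min_frac: float = 0.75,
    min_peptides: int = 2,
):
    """Keep quantifiable features.

    A feature is quantifiable when it has ``unique_peptides >= min_peptides``
    and its non-missing fraction is ``>= min_frac`` within at least one
    group level (e.g. either the ER+ or the TNBC samples).
    """
    df = _as_frame(matrix)
    if df.empty:
        raise ValueError("empty matrix")
    groups = pd.Series(np.asarray(groups), index=df.columns)
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("groups must have at least 2 levels")

    detected = pd.DataFrame(index=df.index)
    for lev in levels:
        cols = groups.index[groups == lev]
        detected[lev] = df[cols].notna().mean(axis=1)
    keep = (detected >= min_frac).any(axis=1)

    if unique_peptides is None and isinstance(matrix, ExpressionMatrix):
        unique_peptides = matrix.unique_peptides
    if unique_peptides is not None:
        keep &= unique_peptides.reindex(df.index).fillna(0) >= min_peptides
    return _rewrap(matrix, df.loc[keep])


def log2_transform(matrix: ExpressionMatrix | pd.DataFrame):
    """Elementwise log2; missing entries stay missing."""
    df = _as_frame(matrix)
    if (df <= 0).any().any():
        raise ValueError("non-positive value present; cannot log2 transform")
    return _rewrap(matrix, np.log2(df))


def impute_downshift(
    matrix: ExpressionMatrix | pd.DataFrame,
    width_factor: float = 0.3,
    shift_factor: float = 1.8,
    seed: int | np.random.Generator | None = None,
):
    """Replace missing values with draws from a downshifted normal.

    For each sample column with observed mean ``mu`` and sd ``sigma``,
    missing entries are drawn from
    ``Normal(mu - shift_factor*sigma, (width_factor*sigma)^2)`` —
    the convention for left-censored label-free intensities, emulating
    abundances below the detection limit.  Observed values are untouched.
    """
    df = _as_frame(matrix).copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_obs = df.notna().sum(axis=0)
    if (n_obs < 2).any():
        bad = df.columns[n_obs < 2].tolist()
        raise ValueError(f"columns with <2 observed values: {bad}")
    for col in df.columns:
        vals = df[col]
        miss = vals.isna()
        if not miss.any():
            continue
        mu = vals.mean()
        sigma = vals.std(ddof=1)
        draws = rng.normal(mu - shift_factor * sigma, width_factor * sigma, miss.sum())
        df.loc[miss, col] = draws
    return _rewrap(matrix, df)


def zscore_rows(matrix: ExpressionMatrix | pd.DataFrame):
    """Per-feature standardisation to mean 0, sd 1 (population sd).

    Zero-variance features are set to all-zeros with a warning rather than
    producing NaNs.
    """
    df = _as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    arr = df.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance feature(s) set to 0")
        sd[sd == 0] = 1.0
    out = (arr - mean) / sd
    out[flat, :] = 0.0
    return _rewrap(matrix, pd.DataFrame(out, index=df.index, columns=df.columns))


def correct_batch(matrix: ExpressionMatrix | pd.DataFrame, batches: Sequence):
    """Location/scale batch adjustment toward the pooled feature distribution.

    Per feature, each batch's values are standardised with the batch mean
    and sd and re-expressed on the pooled (across all samples) mean/sd.
    This removes additive and multiplicative batch effects; it is a
    moment-matching correction, not an empirical-Bayes one, and a different
    implementation can be swapped in upstream of this step.
    """
    df = _as_frame(matrix)
    if df.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    batches = pd.Series(np.asarray(batches), index=df.columns)
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError(f"singleton batch(es): {counts.index[counts < 2].tolist()}")
    arr = df.to_numpy(dtype=float)
    pooled_mean = arr.mean(axis=1, keepdims=True)
    pooled_sd = arr.std(axis=1, ddof=0, keepdims=True)
    pooled_sd[pooled_sd == 0] = 1.0
    out = np.empty_like(arr)
    for b in counts.index:
        idx = np.flatnonzero(batches.to_numpy() == b)
        block = arr[:, idx]
        m = block.mean(axis=1, keepdims=True)
        s = block.std(axis=1, ddof=0, keepdims=True)
        s[s == 0] = 1.0
        out[:, idx] = (block - m) / s * pooled_sd + pooled_mean
    return _rewrap(matrix, pd.DataFrame(out, index=df.index, columns=df.columns))


def srm_protein_quant(transitions: SrmTransitionSet, min_intensity: float = 10.0) -> float:
    """Protein value from SRM transitions: median light/heavy ratio.

    Transitions with either channel at or below ``min_intensity`` are
    excluded; if none survive the value is missing (NaN).
    """
    keep = (transitions.light > min_intensity) & (transitions.heavy > min_intensity)
    if not keep.any():
        return float("nan")
    ratios = transitions.light[keep] / transitions.heavy[keep]
    return float(np.median(ratios))
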