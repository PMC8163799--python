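"""Dataset preprocessing, normalization and cross-dataset fusion.

gRNA efficiency datasets come in two flavours: loss-of-function screens
(efficiency inferred from depletion of gene function) and indel-based
screens (efficiency measured directly as indel frequency).  Before model
training both are cleaned with a shared set of filtering criteria, rank
normalized where the raw values are not indel frequencies, deduplicated
per 30mer, and — for two studies measuring on compatible scales — fused
by a linear rescaling fit on the 30mers present in both.

Expected frame columns (missing columns make the relevant criterion a
logged no-op, never a guess): ``mer30``, ``efficiency`` (percent), an
optional set of ``efficiency_*`` replicate columns, ``category``
("lof" or "indel"), ``target_gene``, ``cds_relative_position``,
``pam``, ``trna_expressed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOF = "lof"


class FusionError(ValueError):
    """Not enough usable overlap to fit the rescaling model."""


@dataclass(frozen=True)
class FusionModel:
    """Linear rescaling source -> reference efficiency scale."""

    slope: float
    intercept: float
    n_overlap: int
    residual_sd: float

    def __call__(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def variance_threshold(variances) -> float:
    """Outlier cut for between-setting variances: Q3 + 1.5 * IQR
    (quartiles by linear interpolation)."""
    v = np.asarray(variances, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def preprocess(records: pd.DataFrame,
               gene_table: dict[str, int] | None = None,
               genome_index: set[str] | None = None,
               gene_annotation: dict[str, set] | None = None,
               min_guides_per_gene: int = 10,
               max_cds_fraction: float = 0.9) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the seven filtering criteria; returns (kept, removed).

    Criteria — (2), (4) and (7) apply only to loss-of-function records:
      1. 30mer absent from the supplied genome index;
      2. no match between guide and target-gene annotation;
      3. between-setting efficiency variance above Q3 + 1.5*IQR of the
         variance distribution (columns ``efficiency_*``);
      4. target gene with fewer than ``min_guides_per_gene`` designed guides;
      5. PAM different from 5'-NGG-3';
      6. expressed from a tRNA system (``trna_expressed`` flag);
      7. guide targeting the last 10% of the merged coding sequence.

    ``removed`` carries a ``criterion`` label; criteria whose inputs are
    absent are skipped with a logged notice.  Each record is removed
    under the first criterion it matches.
    """
    df = records.copy()
    reason = pd.Series("", index=df.index, dtype=object)
    is_lof = df["category"].eq(LOF) if "category" in df else pd.Series(False, index=df.index)

    def mark(mask: pd.Series, label: str):
        mask = mask & reason.eq("")
        reason[mask] = label

    if genome_index is not None and "mer30" in df:
        mark(~df["mer30"].isin(genome_index), "1_not_in_genome")
    else:
        logger.info("criterion 1 skipped (no genome index)")
    if gene_annotation is not None and "target_gene" in df:
        ok = df.apply(lambda r: r["mer30"] in gene_annotation.get(r["target_gene"], set()), axis=1)
        mark(is_lof & ~ok, "2_gene_mismatch")
    else:
        logger.info("criterion 2 skipped (no gene annotation)")
    eff_cols = [c for c in df.columns if c.startswith("efficiency_")]
    if len(eff_cols) >= 2:
        variances = df[eff_cols].var(axis=1, ddof=1)
        mark(variances > variance_threshold(variances), "3_high_variance")
    else:
        logger.info("criterion 3 skipped (fewer than two setting columns)")
    if gene_table is not None and "target_gene" in df:
        few = df["target_gene"].map(lambda g: gene_table.get(g, 0) < min_guides_per_gene)
        mark(is_lof & few, "4_few_guides_per_gene")
    else:
        logger.info("criterion 4 skipped (no designed-guide table)")
    if "pam" in df:
        mark(df["pam"].str.upper().str.slice(1, 3) != "GG", "5_non_ngg_pam")
    else:
        logger.info("criterion 5 skipped (no pam column)")
    if "trna_expressed" in df:
        mark(df["trna_expressed"].fillna(False).astype(bool), "6_trna_expressed")
    if "cds_relative_position" in df:
        mark(is_lof & (df["cds_relative_position"] > max_cds_fraction), "7_cds_tail")
    else:
        logger.info("criterion 7 skipped (no cds position)")

    removed = df[reason != ""].copy()
    removed["criterion"] = reason[reason != ""]
    return df[reason == ""].copy(), removed


def rank_normalize(values) -> np.ndarray:
    """Average-rank normalization to (0, 1]: rank / n, order preserving."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    return stats.rankdata(v, method="average") / v.size


def average_duplicates(records: pd.DataFrame, key: str = "mer30",
                       value: str = "efficiency") -> tuple[pd.DataFrame, pd.DataFrame]:
    """One record per 30mer, efficiency averaged; reports per-group spread.

    Returns (deduplicated, spread_report) where the report lists, for
    each merged group, the max - min efficiency among its duplicates.
    """
    grouped = records.groupby(key, as_index=False, sort=False)
    agg = {value: "mean"}
    first_cols = [c for c in records.columns if c not in (key, value)]
    out = grouped.agg({**agg, **{c: "first" for c in first_cols}})
    spread = (records.groupby(key, sort=False)[value]
              .agg(n="size", spread=lambda v: v.max() - v.min())
              .reset_index())
    return out, spread[spread["n"] > 1]


def fit_fusion(source: pd.DataFrame, reference: pd.DataFrame,
               key: str = "mer30", value: str = "efficiency") -> FusionModel:
    """OLS of reference efficiency on source efficiency over shared 30mers."""
    pairs = source[[key, value]].merge(reference[[key, value]], on=key,
                                       suffixes=("_src", "_ref"))
    if len(pairs) < 2:
        raise FusionError(f"need >= 2 overlapping 30mers, found {len(pairs)}")
    x = pairs[f"{value}_src"].to_numpy(dtype=float)
    y = pairs[f"{value}_ref"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise FusionError("source efficiencies are constant on the overlap")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sd = float(np.std(resid, ddof=2)) if len(pairs) > 2 else 0.0
    return FusionModel(float(slope), float(intercept), len(pairs), sd)


def apply_fusion(model: FusionModel, source: pd.DataFrame, reference: pd.DataFrame,
                 key: str = "mer30", value: str = "efficiency") -> pd.DataFrame:
    """Rescale source to the reference scale and merge the two datasets.

    Rescaled values are clipped to [0, 100]; 30mers present in both get
    the mean of (rescaled source, reference); the result is the union.
    """
    src = source[[key, value]].copy()
    src[value] = np.clip(model(src[value]), 0.0, 100.0)
    ref = reference[[key, value]]
    merged = src.merge(ref, on=key, how="outer", suffixes=("_src", "_ref"))
    merged[value] = merged[[f"{value}_src", f"{value}_ref"]].mean(axis=1)
    merged["overlap"] = merged[f"{value}_src"].notna() & merged[f"{value}_ref"].notna()
    return merged[[key, value, "overlap"]]
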