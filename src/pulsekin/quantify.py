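"""Heavy fractional abundances, replicate CVs, reference-based batch
harmonization and PCA on peptide intensity tables."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def heavy_fraction(light, heavy):
    """H/(H+L): fraction of a peptide's signal carrying the heavy label.

    Accepts scalars or arrays. For multi-site peptides ``light`` is the
    fully light channel and ``heavy`` the summed intensity of every channel
    with at least one heavy residue. Undefined (NaN) when both are zero.
    """
    light = np.asarray(light, dtype=float)
    heavy = np.asarray(heavy, dtype=float)
    if np.any(light < 0) or np.any(heavy < 0):
        raise ValueError("intensities must be non-negative")
    total = light + heavy
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, heavy / total, np.nan)
    return float(frac) if frac.ndim == 0 else frac


def peptide_fractions(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-(peptide, sample) heavy fractional abundance.

    Channel 0 is light; all channels with >= 1 heavy site are summed into
    the heavy intensity. Records where both channels are zero (or the light
    channel is missing entirely) are skipped, with the skip count logged.
    """
    is_light = quant["n_heavy_sites"] == 0
    grouped = quant.assign(
        light=quant["intensity"].where(is_light, 0.0),
        heavy=quant["intensity"].where(~is_light, 0.0),
    ).groupby(["peptide_id", "sample_id"], sort=True, as_index=False)[["light", "heavy"]].sum()

    total = grouped["light"] + grouped["heavy"]
    skipped = int((total <= 0).sum())
    if skipped:
        logger.warning("skipped %d peptide-sample records with zero total intensity", skipped)
    out = grouped.loc[total > 0].copy()
    out["fraction"] = out["heavy"] / (out["light"] + out["heavy"])
    out["total_intensity"] = out["light"] + out["heavy"]
    return out[["peptide_id", "sample_id", "fraction", "total_intensity"]].reset_index(drop=True)


def incorporation_summary(
    fractions: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Mean/median/SE of heavy fractional abundance per sample and pooled.

    Reference samples are excluded: they measure a pooled mixture, not a
    labeling condition.
    """
    meta = metadata.set_index("sample_id")
    fr = fractions[~fractions["sample_id"].map(meta["is_reference"]).fillna(False)]

    def _summ(g: pd.Series) -> pd.Series:
        n = len(g)
        return pd.Series(
            {
                "n_peptides": n,
                "mean_fraction": g.mean(),
                "median_fraction": g.median(),
                "se_fraction": g.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            }
        )

    per_sample = fr.groupby("sample_id")["fraction"].apply(_summ).unstack().reset_index()
    per_sample["n_peptides"] = per_sample["n_peptides"].astype(int)
    for col in ("tissue", "time_hours", "replicate"):
        per_sample[col] = per_sample["sample_id"].map(meta[col])

    pooled = {
        "n": int(len(fr)),
        "mean_fraction": float(fr["fraction"].mean()),
        "median_fraction": float(fr["fraction"].median()),
        "se_fraction": float(fr["fraction"].std(ddof=1) / np.sqrt(len(fr)))
        if len(fr) > 1
        else 0.0,
    }
    return per_sample, pooled


def replicate_cv(
    quant: pd.DataFrame,
    metadata: pd.DataFrame,
    group_cols: tuple[str, ...] = ("tissue", "time_hours"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-peptide CV of intensities across replicates, split light vs heavy.

    The CV (sd/mean) is computed per peptide per channel class within each
    replicate group; peptides observed in fewer than two replicates of a
    group are skipped. Returns the per-peptide table and the median CV per
    channel class.
    """
    meta = metadata.set_index("sample_id")
    df = quant.copy()
    df["channel_class"] = np.where(df["n_heavy_sites"] == 0, "light", "heavy")
    for col in group_cols:
        df[col] = df["sample_id"].map(meta[col])
    df = df[~df["sample_id"].map(meta["is_reference"]).fillna(False)]

    # sum channels within a class first (heavy = all labeled channels)
    per_sample = df.groupby(
        ["peptide_id", "channel_class", *group_cols, "sample_id"], as_index=False
    )["intensity"].sum()

    stats = per_sample.groupby(["peptide_id", "channel_class", *group_cols])["intensity"].agg(
        ["count", "mean", "std"]
    )
    stats = stats[(stats["count"] >= 2) & (stats["mean"] > 0)]
    stats["cv"] = stats["std"] / stats["mean"]
    out = stats.reset_index()[["peptide_id", "channel_class", *group_cols, "cv"]]
    medians = out.groupby("channel_class")["cv"].median()
    return out, medians


def harmonize(
    quant: pd.DataFrame,
    metadata: pd.DataFrame,
    center: str = "median",
) -> pd.DataFrame:
    """Single-point calibration against pooled reference samples.

    Each batch runs one pooled reference sample. For every feature — a
    (peptide, isotopomer channel) pair, since light and heavy forms behave
    as distinct analytes — the batch offset is the feature's log2 reference
    intensity in that batch minus the mean of its log2 reference intensities
    across batches. Subtracting the offset makes the reference measurements
    identical across batches; per-sample median- (or mean-) centering is
    then applied. Features absent from a batch's reference are left
    uncorrected and flagged.

    Returns a long table: peptide_id, n_heavy_sites, sample_id, log2_corrected,
    corrected (flag).
    """
    meta = metadata.set_index("sample_id")
    batches = meta["batch"].dropna().unique()
    ref_samples = meta[meta["is_reference"]]
    missing_ref = set(batches) - set(ref_samples["batch"])
    if missing_ref:
        raise ValueError(f"batch(es) without a reference sample: {sorted(missing_ref)}")

    df = quant[quant["intensity"] > 0].copy()
    df["batch"] = df["sample_id"].map(meta["batch"])
    df["log2_intensity"] = np.log2(df["intensity"])
    df["_is_ref"] = df["sample_id"].map(meta["is_reference"])

    feature = ["peptide_id", "n_heavy_sites"]
    ref = df[df["_is_ref"]]
    # log2 reference value per feature per batch (mean if several refs/batch)
    ref_vals = ref.groupby([*feature, "batch"])["log2_intensity"].mean()
    ref_mean = ref_vals.groupby(feature).mean()
    offsets = (ref_vals - ref_mean).rename("offset")

    df = df.join(offsets, on=[*feature, "batch"])
    df["corrected"] = df["offset"].notna()
    n_uncorrected = int((~df["corrected"]).sum())
    if n_uncorrected:
        logger.warning(
            "%d records left uncorrected (feature absent from batch reference)",
            n_uncorrected,
        )
    df["log2_corrected"] = df["log2_intensity"] - df["offset"].fillna(0.0)

    if center == "median":
        centers = df.groupby("sample_id")["log2_corrected"].transform("median")
    elif center == "mean":
        centers = df.groupby("sample_id")["log2_corrected"].transform("mean")
    elif center in (None, "none"):
        centers = 0.0
    else:
        raise ValueError(f"unknown centering {center!r}")
    df["log2_corrected"] = df["log2_corrected"] - centers

    return df[
        ["peptide_id", "n_heavy_sites", "sample_id", "log2_corrected", "corrected"]
    ].reset_index(drop=True)


def recovered_batch_offsets(quant: pd.DataFrame, metadata: pd.DataFrame) -> pd.Series:
    """Median per-feature reference offset per batch (diagnostic).

    On data with a common reference mixture, this recovers each batch's
    injected log2 shift relative to the across-batch mean.
    """
    meta = metadata.set_index("sample_id")
    ref = quant[
        quant["sample_id"].map(meta["is_reference"]).fillna(False) & (quant["intensity"] > 0)
    ].copy()
    ref["batch"] = ref["sample_id"].map(meta["batch"])
    ref["log2_intensity"] = np.log2(ref["intensity"])
    feature = ["peptide_id", "n_heavy_sites"]
    vals = ref.groupby([*feature, "batch"])["log2_intensity"].mean()
    dev = vals - vals.groupby(feature).mean()
    return dev.groupby("batch").median()


def pca_scores(matrix: pd.DataFrame, n_components: int = 5) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores from a column-centered SVD of a samples x features matrix.

    Features with any missing value are dropped (complete-case). Returns
    (scores DataFrame indexed like the input rows, variance fractions).
    """
    mat = matrix.dropna(axis=1)
    if mat.shape[0] < 2:
        raise ValueError("PCA requires at least two samples")
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("degenerate matrix: no variance after centering")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    var_frac = (s**2 / (s**2).sum())[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=mat.index, columns=cols), var_frac


def fraction_matrix(values: pd.DataFrame, value_col: str = "log2_corrected") -> pd.DataFrame:
    """Pivot a long table to samples x features for PCA."""
    if "n_heavy_sites" in values.columns:
        return values.pivot_table(
            index="sample_id", columns=["peptide_id", "n_heavy_sites"], values=value_col
        )
    return values.pivot_table(index="sample_id", columns="peptide_id", values=value_col)
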