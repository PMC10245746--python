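"""Tissue- and compartment-level statistics on fitted turnover rates."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: combined sample size up to which the exact Mann-Whitney null is used
EXACT_MW_LIMIT = 12


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_rates(
    fits_a: pd.DataFrame, fits_b: pd.DataFrame, passing_only: bool = True
) -> tuple[float, float, int]:
    """Spearman rank correlation of turnover rates on shared peptides.

    Returns (rho, p, n_shared). Requires at least three shared peptides.
    """
    a, b = fits_a, fits_b
    if passing_only:
        a, b = a[a["passed_filter"]], b[b["passed_filter"]]
    merged = a.merge(b, on="peptide_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared peptides; >= 3 required")
    rho, p = stats.spearmanr(merged["k_a"], merged["k_b"])
    return float(rho), float(p), len(merged)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact null for small untied samples,
    tie-corrected normal approximation otherwise."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= EXACT_MW_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_per_protein(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    min_peptides: int = 3,
    passing_only: bool = True,
) -> pd.DataFrame:
    """Per-protein Mann-Whitney test of peptide turnover rates between tissues.

    Proteins with fewer than ``min_peptides`` passing peptide rates in either
    tissue are skipped (counted in the log). q-values are BH-adjusted across
    tested proteins. ``direction`` is the sign of median(a) − median(b).
    """
    a, b = fits_a, fits_b
    if passing_only:
        a, b = a[a["passed_filter"]], b[b["passed_filter"]]
    label_a = a["tissue"].iloc[0] if len(a) and a["tissue"].nunique() == 1 else "a"
    label_b = b["tissue"].iloc[0] if len(b) and b["tissue"].nunique() == 1 else "b"

    rows, n_skipped = [], 0
    shared = sorted(set(a["protein_accession"]) & set(b["protein_accession"]))
    for prot in shared:
        ka = a.loc[a["protein_accession"] == prot, "k"].to_numpy()
        kb = b.loc[b["protein_accession"] == prot, "k"].to_numpy()
        if len(ka) < min_peptides or len(kb) < min_peptides:
            n_skipped += 1
            continue
        u, p = _mannwhitney(ka, kb)
        rows.append(
            {
                "unit_id": prot,
                "group_a": label_a,
                "group_b": label_b,
                "statistic": u,
                "p_value": p,
                "n_a": len(ka),
                "n_b": len(kb),
                "direction": int(np.sign(np.median(ka) - np.median(kb))),
            }
        )
    if n_skipped:
        logger.info("%d proteins skipped (< %d peptides per tissue)", n_skipped, min_peptides)
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"])
    return out


def compartment_anova(
    fits: pd.DataFrame,
    annotation: pd.DataFrame,
    schemes: tuple[str, ...] = ("all", "cytosol", "mitochondria"),
    passing_only: bool = True,
) -> pd.DataFrame:
    """One-way ANOVA of log10 turnover rates per subcellular compartment.

    For each contrast scheme, every compartment is tested as a two-group
    ANOVA: against all other rates (scheme ``"all"``) or against a named
    reference compartment. q-values are BH-adjusted across compartments
    within a scheme. Proteins without annotation are omitted (counted).
    """
    f = fits[fits["passed_filter"]] if passing_only else fits
    merged = f.merge(annotation, on="protein_accession", how="left")
    n_missing = int(merged["compartment"].isna().sum())
    if n_missing:
        logger.info("%d rates omitted (protein lacks compartment annotation)", n_missing)
    merged = merged.dropna(subset=["compartment"])
    merged = merged[merged["k"] > 0].copy()
    merged["log10_k"] = np.log10(merged["k"])

    compartments = sorted(merged["compartment"].unique())
    rows = []
    for scheme in schemes:
        for comp in compartments:
            x = merged.loc[merged["compartment"] == comp, "log10_k"].to_numpy()
            if scheme == "all":
                y = merged.loc[merged["compartment"] != comp, "log10_k"].to_numpy()
                ref_label = "all_other"
            else:
                if comp == scheme:
                    continue
                y = merged.loc[merged["compartment"] == scheme, "log10_k"].to_numpy()
                ref_label = scheme
            if len(x) < 2 or len(y) < 2:
                continue
            separated = False
            if np.ptp(x) == 0 and np.ptp(y) == 0:
                if x[0] == y[0]:
                    fstat, p = 0.0, 1.0
                else:  # perfectly separated constant groups
                    fstat, p, separated = float("inf"), 0.0, True
            else:
                fstat, p = stats.f_oneway(x, y)
            rows.append(
                {
                    "scheme": scheme,
                    "unit_id": comp,
                    "group_a": comp,
                    "group_b": ref_label,
                    "statistic": float(fstat),
                    "p_value": float(p),
                    "n_a": len(x),
                    "n_b": len(y),
                    "direction": int(np.sign(np.median(x) - np.median(y))),
                    "separated": separated,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = out.groupby("scheme")["p_value"].transform(bh_adjust)
    return out
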