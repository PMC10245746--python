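"""Mass isotopomer distribution analysis (MIDA) of the precursor pool.

Peptides carrying exactly two labelable residues of the same kind (two
lysines or two arginines) exist in three isotopomer states: fully light
(LL), singly heavy (HL) and fully heavy (HH). If the free amino-acid pool
has heavy fraction p and the two residues are labeled independently, the
states occur as (1−p)², 2p(1−p), p², so

    p = (2·HH/HL) / (1 + 2·HH/HL).

Per-sample medians of p over qualifying peptides, fitted to an exponential
decay p(t) = p0·e^(−k_p·t) across labeling times, give the pool's initial
enrichment and half-life ln2/k_p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dataio import count_labelable_sites

logger = logging.getLogger(__name__)


def is_mida_sequence(sequence: str) -> bool:
    """True for peptides with exactly two labelable residues of one kind."""
    seq = str(sequence)
    n_k, n_r = seq.count("K"), seq.count("R")
    return (n_k == 2 and n_r == 0) or (n_r == 2 and n_k == 0)


def select_mida_peptides(quant: pd.DataFrame) -> pd.DataFrame:
    """Subset of the quant table usable for isotopomer-distribution analysis.

    Keeps (peptide, sample) groups whose sequence is KK- or RR-type (mixed
    K/R pairs are excluded because the two labels draw on different
    precursor pools) and where all three channels are present.
    """
    ok_seq = quant["sequence"].map(is_mida_sequence) & (
        quant["sequence"].map(count_labelable_sites) == 2
    )
    sub = quant[ok_seq]
    complete = sub.groupby(["peptide_id", "sample_id"])["n_heavy_sites"].transform(
        lambda s: set(s) == {0, 1, 2}
    )
    return sub[complete].reset_index(drop=True)


def precursor_fraction(hh: float, hl: float) -> float:
    """Pool heavy fraction from the HH/HL intensity ratio.

    Inverts the binomial channel split: with channels proportional to
    ((1−p)², 2p(1−p), p²), HH/HL = p/(2(1−p)), hence
    p = (2·HH/HL)/(1 + 2·HH/HL). Undefined (NaN) when HL is zero.
    """
    if hh < 0 or hl < 0:
        raise ValueError("intensities must be non-negative")
    if hl == 0:
        return float("nan")
    r = 2.0 * hh / hl
    return r / (1.0 + r)


def pool_timecourse(quant: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median precursor fraction joined to labeling time.

    Uses only qualifying two-site peptides with all three channels; samples
    with no qualifying peptide (or all NaN fractions) are dropped with a
    warning. Reference samples are excluded.
    """
    sub = select_mida_peptides(quant)
    meta = metadata.set_index("sample_id")
    sub = sub[~sub["sample_id"].map(meta["is_reference"]).fillna(False)]

    wide = sub.pivot_table(
        index=["peptide_id", "sample_id"], columns="n_heavy_sites", values="intensity"
    )
    fracs = [
        precursor_fraction(row.get(2, 0.0), row.get(1, 0.0)) for _, row in wide.iterrows()
    ]
    wide = wide.assign(fraction=fracs).reset_index()
    n_undef = int(wide["fraction"].isna().sum())
    if n_undef:
        logger.warning("%d MIDA peptide-sample records skipped (HL channel zero)", n_undef)
    wide = wide.dropna(subset=["fraction"])

    out = wide.groupby("sample_id", as_index=False)["fraction"].median()
    out["n_peptides"] = wide.groupby("sample_id")["fraction"].size().to_numpy()
    out["time_hours"] = out["sample_id"].map(meta["time_hours"])
    out["tissue"] = out["sample_id"].map(meta["tissue"])
    dropped = set(meta.index[~meta["is_reference"]]) - set(out["sample_id"])
    if dropped:
        logger.warning("%d samples had no qualifying MIDA peptides", len(dropped))
    return out[["sample_id", "tissue", "time_hours", "fraction", "n_peptides"]]


@dataclass
class PoolFit:
    """Exponential-decay fit of the precursor pool's heavy fraction."""

    tissue: str
    p0: float
    k_p: float  # hour^-1
    half_life_hours: float
    rss: float
    n_points: int
    converged: bool


def fit_pool_decay(
    times,
    fractions,
    tissue: str = "all",
    fix_p0: float | None = None,
) -> PoolFit:
    """Least-squares fit of p(t) = p0·e^(−k_p·t) to per-sample medians.

    Initialization is a log-linear regression of ln(fraction) on time. By
    default p0 is free (the bolus mixes with the endogenous pool, so initial
    enrichment is below 1); pass ``fix_p0`` to constrain it.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if len(t) < 3 or len(np.unique(t)) < 2:
        raise ValueError("pool fit needs >= 3 points with >= 2 distinct times")
    if np.any((y <= 0) | (y > 1)):
        raise ValueError("fractions must lie in (0, 1]")

    # log-linear initialization: ln y = ln p0 − k_p t
    slope, intercept = np.polyfit(t, np.log(y), 1)
    k0 = max(-slope, 1e-6)
    p0_init = min(math.exp(intercept), 1.0) if fix_p0 is None else fix_p0

    if fix_p0 is None:

        def resid(theta):
            p0, kp = theta
            return p0 * np.exp(-kp * t) - y

        res = least_squares(
            resid,
            x0=[p0_init, k0],
            bounds=([1e-12, 1e-12], [1.0, np.inf]),
            xtol=1e-12,
            max_nfev=200,
        )
        p0_hat, kp_hat = res.x
    else:

        def resid(theta):
            return fix_p0 * np.exp(-theta[0] * t) - y

        res = least_squares(
            resid, x0=[k0], bounds=([1e-12], [np.inf]), xtol=1e-12, max_nfev=200
        )
        p0_hat, kp_hat = fix_p0, res.x[0]

    # degenerate when the fitted decay over the sampled window is negligible
    span = float(t.max() - t.min())
    converged = bool(res.success) and kp_hat * span > 1e-4
    half_life = math.log(2.0) / kp_hat if converged else float("nan")
    return PoolFit(
        tissue=tissue,
        p0=float(p0_hat),
        k_p=float(kp_hat),
        half_life_hours=float(half_life),
        rss=float(np.sum(res.fun**2)),
        n_points=len(t),
        converged=converged,
    )


def fit_pool_by_tissue(timecourse: pd.DataFrame, fix_p0: float | None = None) -> pd.DataFrame:
    """Fit the pool decay per tissue, pooling all samples of a tissue."""
    rows = []
    for tissue, g in timecourse.groupby("tissue"):
        try:
            fit = fit_pool_decay(g["time_hours"], g["fraction"], tissue=tissue, fix_p0=fix_p0)
        except ValueError as e:
            logger.warning("pool fit skipped for tissue %s: %s", tissue, e)
            continue
        rows.append(vars(fit))
    return pd.DataFrame(rows)
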