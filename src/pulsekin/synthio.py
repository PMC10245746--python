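"""Synthetic pulse-labeling datasets with known ground truth.

The generator emulates the statistical structure of an in utero dynamic-SILAC
experiment: a bolus of heavy lysine/arginine is injected, tissues are
harvested at a handful of chase times, and each tryptic peptide is observed
as light and heavy isotopomer channels whose relative intensities encode the
protein's turnover rate and, for peptides with two labelable residues, the
heavy fraction of the free amino-acid precursor pool.

Key ingredients:

* per-peptide heavy fractional abundance follows the one-parameter
  pulse-chase model F(t) = k·t·e^(−k·t);
* the precursor pool decays exponentially, p(t) = p0·e^(−ln2·t/h);
* two-site (KK or RR) peptides split binomially across LL/HL/HH channels
  with success probability p(t);
* intensities are log-normal across peptides (spanning several orders of
  magnitude) with multiplicative log-normal measurement noise parameterized
  by channel-class CVs;
* each batch carries a multiplicative (log2-additive) offset and one pooled
  reference sample re-measuring a common mixture.

Everything is driven by a single integer seed: identical config + seed
yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import dataio

#: amino acids that never carry the label, used as sequence filler
_FILLER = list("ADEFGHILMNPQSTVWY")


def model_fraction(k: float, t):
    """Heavy fractional abundance of the pulse-chase model, F = k·t·e^(−k·t).

    ``k`` is the turnover rate constant in hour⁻¹ (must be positive), ``t``
    the chase time in hours (scalar or array). The curve rises from 0,
    peaks at F = e⁻¹ when t = 1/k, and relaxes back to 0 as the heavy
    precursor washes out.
    """
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    t = np.asarray(t, dtype=float)
    out = k * t * np.exp(-k * t)
    return float(out) if out.ndim == 0 else out


def simulate_pool(p0: float, halflife: float, t):
    """Precursor-pool heavy fraction p(t) = p0·e^(−ln2·t/halflife)."""
    if not 0 < p0 <= 1:
        raise ValueError(f"p0 must be in (0, 1], got {p0}")
    if halflife <= 0:
        raise ValueError(f"halflife must be positive, got {halflife}")
    t = np.asarray(t, dtype=float)
    out = p0 * np.exp(-math.log(2.0) * t / halflife)
    return float(out) if out.ndim == 0 else out


def simulate_isotopomers(p: float, total: float, n_sites: int = 2):
    """Expected LL/HL/HH channel intensities for a two-site peptide.

    With precursor heavy fraction ``p`` the two labelable residues are
    labeled independently, so the channels follow the binomial expansion
    ((1−p)², 2p(1−p), p²) scaled by ``total``.
    """
    if n_sites != 2:
        raise ValueError("only peptides with exactly two labelable sites are supported")
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if total < 0:
        raise ValueError(f"total must be non-negative, got {total}")
    return (total * (1 - p) ** 2, total * 2 * p * (1 - p), total * p**2)


class SimulationConfig(BaseModel):
    """Parameters of a synthetic pulse-labeling experiment.

    Defaults reproduce the study conditions the generator emulates: four
    chase times within a single gestational day, three pulse-injection
    replicates, turnover rates spanning roughly four orders of magnitude,
    precursor-pool half-life of a few hours, intensity CVs of ~14% (light)
    and ~22% (heavy), and one batch (with a pooled reference sample) per
    tissue.
    """

    n_proteins: int = Field(default=200, gt=0)
    peptides_per_protein: tuple[int, int] = (2, 4)
    tissues: list[str] = ["liver", "brain"]
    stage: str = "E14.5"
    timepoints_hours: list[float] = [1.0, 2.0, 4.0, 6.0]
    replicates_per_timepoint: int = Field(default=3, gt=0)
    #: (mu, sigma) of ln k; median e^mu ≈ 0.02 h⁻¹, spread covering
    #: ~3.8e-5 .. 0.42 h⁻¹ within ±3 sigma
    k_lognormal: tuple[float, float] = (-3.9, 1.4)
    pool_p0: float = Field(default=0.8, gt=0, le=1)
    pool_halflife_hours: float = Field(default=6.0, gt=0)
    #: (mu, sigma) of ln total intensity; sigma 2.3 ≈ 1 decade per sigma
    abundance_lognormal: tuple[float, float] = (13.8, 2.3)
    cv_light: float = Field(default=0.14, ge=0)
    cv_heavy: float = Field(default=0.22, ge=0)
    missing_rate: float = Field(default=0.05, ge=0, lt=1)
    #: tissue -> batch label; default assigns one batch per tissue
    batch_assignment: dict[str, str] | None = None
    batch_log2_offsets: dict[str, float] | None = None
    frac_double_residue: float = Field(default=0.1, ge=0, le=1)
    #: correlation knob between ln(abundance) and ln(k); negative values
    #: emulate the observed abundance/turnover anticorrelation. Default off.
    abundance_k_correlation: float = Field(default=0.0, ge=-1, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.peptides_per_protein
        if not (0 < lo <= hi):
            raise ValueError("peptides_per_protein must be a positive (lo, hi) range")
        if not self.tissues:
            raise ValueError("at least one tissue is required")
        if not self.timepoints_hours:
            raise ValueError("at least one timepoint is required")
        if any(t < 0 for t in self.timepoints_hours):
            raise ValueError("timepoints must be non-negative")
        if sorted(self.timepoints_hours) != list(self.timepoints_hours):
            raise ValueError("timepoints must be sorted non-decreasing")
        return self

    def resolved_batches(self) -> dict[str, str]:
        if self.batch_assignment is not None:
            return dict(self.batch_assignment)
        return {tissue: f"batch_{tissue}" for tissue in self.tissues}

    def resolved_offsets(self) -> dict[str, float]:
        batches = sorted(set(self.resolved_batches().values()))
        if self.batch_log2_offsets is not None:
            missing = [b for b in batches if b not in self.batch_log2_offsets]
            if missing:
                raise ValueError(f"no log2 offset for batch(es): {missing}")
            return {b: float(self.batch_log2_offsets[b]) for b in batches}
        return {b: 0.0 for b in batches}


@dataclass
class GroundTruth:
    """True parameters behind a simulated dataset."""

    peptides: pd.DataFrame  # peptide_id, protein_accession, k_true, abundance_true, n_labeled_sites
    batch_offsets: dict[str, float]
    pool_p0: float
    pool_halflife_hours: float
    config: SimulationConfig = field(repr=False, default=None)


def _make_sequence(rng: np.random.Generator, n_sites: int) -> str:
    """Random tryptic-looking sequence with the requested K/R site count."""
    body = "".join(rng.choice(_FILLER, size=7))
    if n_sites == 1:
        return body + rng.choice(["K", "R"])
    # missed-cleavage style: ...K...K or ...R...R (same residue type twice,
    # as required for isotopomer-distribution analysis)
    aa = rng.choice(["K", "R"])
    mid = "".join(rng.choice(_FILLER, size=4))
    return body + aa + mid + aa


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and relative SD ``cv``."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a full pulse-labeling dataset.

    Returns a validated long-format quantification table, a sample metadata
    table, and the generating ground truth. Single-site peptides' noise-free
    heavy fraction equals ``model_fraction(k_true, t)`` exactly; two-site
    peptides split across the three isotopomer channels according to the
    decaying precursor pool; one pooled reference sample per batch
    re-measures the across-sample mean mixture shifted by the batch offset.
    """
    rng = np.random.default_rng(config.seed)
    batches = config.resolved_batches()
    offsets = config.resolved_offsets()

    # --- peptides and their true parameters -------------------------------
    lo, hi = config.peptides_per_protein
    pep_rows = []
    mu_k, sd_k = config.k_lognormal
    mu_a, sd_a = config.abundance_lognormal
    rho = config.abundance_k_correlation
    for ip in range(config.n_proteins):
        acc = f"P{ip:05d}"
        n_pep = int(rng.integers(lo, hi + 1))
        z_k = rng.normal()
        k_true = math.exp(mu_k + sd_k * z_k)
        for jp in range(n_pep):
            double = rng.random() < config.frac_double_residue
            n_sites = 2 if double else 1
            z_a = rho * z_k + math.sqrt(1 - rho * rho) * rng.normal()
            abundance = math.exp(mu_a + sd_a * z_a)
            pep_rows.append(
                {
                    "peptide_id": f"{acc}_pep{jp}",
                    "sequence": _make_sequence(rng, n_sites),
                    "protein_accession": acc,
                    "protein_name": f"protein {ip}",
                    "n_labeled_sites": n_sites,
                    "k_true": k_true,
                    "abundance_true": abundance,
                }
            )
    peptides = pd.DataFrame(pep_rows)

    # --- sample table ------------------------------------------------------
    meta_rows = []
    for tissue in config.tissues:
        for t in config.timepoints_hours:
            for r in range(1, config.replicates_per_timepoint + 1):
                meta_rows.append(
                    {
                        "sample_id": f"{tissue}_t{t:g}_r{r}",
                        "tissue": tissue,
                        "stage": config.stage,
                        "time_hours": float(t),
                        "replicate": r,
                        "batch": batches[tissue],
                        "is_reference": False,
                    }
                )
    for b in sorted(set(batches.values())):
        meta_rows.append(
            {
                "sample_id": f"ref_{b}",
                "tissue": "pooled",
                "stage": config.stage,
                "time_hours": 0.0,
                "replicate": 0,
                "batch": b,
                "is_reference": True,
            }
        )
    metadata = pd.DataFrame(meta_rows)

    # --- expected (noise-free) channel intensities per sample --------------
    experimental = metadata[~metadata["is_reference"]]
    quant_parts = []
    # accumulate the pooled mixture as the mean expected intensity per channel
    pooled_sum: dict[tuple[str, int], float] = {}
    n_exp = len(experimental)

    k_arr = peptides["k_true"].to_numpy()
    a_arr = peptides["abundance_true"].to_numpy()
    sites = peptides["n_labeled_sites"].to_numpy()
    single = sites == 1
    double = ~single

    for _, s in experimental.iterrows():
        t = s["time_hours"]
        scale = 2.0 ** offsets[s["batch"]]
        # single-site peptides: channels 0 (light) and 1 (heavy)
        f = k_arr * t * np.exp(-k_arr * t)
        p = simulate_pool(config.pool_p0, config.pool_halflife_hours, t)
        exp_int = np.zeros((len(peptides), 3))
        exp_int[single, 0] = a_arr[single] * (1 - f[single])
        exp_int[single, 1] = a_arr[single] * f[single]
        exp_int[double, 0] = a_arr[double] * (1 - p) ** 2
        exp_int[double, 1] = a_arr[double] * 2 * p * (1 - p)
        exp_int[double, 2] = a_arr[double] * p * p
        exp_int *= scale

        for ch in (0, 1, 2):
            mask = np.ones(len(peptides), bool) if ch == 0 else (sites >= ch)
            if ch == 2:
                mask = double
            vals = exp_int[mask, ch]
            cv = config.cv_light if ch == 0 else config.cv_heavy
            noisy = vals * _lognormal_noise(rng, cv, vals.shape)
            part = pd.DataFrame(
                {
                    "peptide_id": peptides.loc[mask, "peptide_id"].to_numpy(),
                    "sequence": peptides.loc[mask, "sequence"].to_numpy(),
                    "protein_accession": peptides.loc[mask, "protein_accession"].to_numpy(),
                    "protein_name": peptides.loc[mask, "protein_name"].to_numpy(),
                    "n_labeled_sites": sites[mask],
                    "n_heavy_sites": ch,
                    "sample_id": s["sample_id"],
                    "intensity": noisy,
                }
            )
            quant_parts.append(part)
            for pid, v in zip(part["peptide_id"], exp_int[mask, ch] / scale):
                key = (pid, ch)
                pooled_sum[key] = pooled_sum.get(key, 0.0) + v / n_exp

    # --- pooled reference samples ------------------------------------------
    pep_lookup = peptides.set_index("peptide_id")
    for b in sorted(set(batches.values())):
        scale = 2.0 ** offsets[b]
        rows = []
        for (pid, ch), v in pooled_sum.items():
            cv = config.cv_light if ch == 0 else config.cv_heavy
            noise = _lognormal_noise(rng, cv, None)
            info = pep_lookup.loc[pid]
            rows.append(
                {
                    "peptide_id": pid,
                    "sequence": info["sequence"],
                    "protein_accession": info["protein_accession"],
                    "protein_name": info["protein_name"],
                    "n_labeled_sites": int(info["n_labeled_sites"]),
                    "n_heavy_sites": ch,
                    "sample_id": f"ref_{b}",
                    "intensity": v * scale * float(noise),
                }
            )
        quant_parts.append(pd.DataFrame(rows))

    quant = pd.concat(quant_parts, ignore_index=True)

    if config.missing_rate > 0:
        keep = rng.random(len(quant)) >= config.missing_rate
        quant = quant.loc[keep].reset_index(drop=True)

    quant = quant.sort_values(
        ["sample_id", "peptide_id", "n_heavy_sites"], kind="mergesort"
    ).reset_index(drop=True)
    quant = dataio.validate_quant(quant)
    metadata = dataio.validate_metadata(metadata)

    truth = GroundTruth(
        peptides=peptides[
            ["peptide_id", "protein_accession", "k_true", "abundance_true", "n_labeled_sites"]
        ].copy(),
        batch_offsets=offsets,
        pool_p0=config.pool_p0,
        pool_halflife_hours=config.pool_halflife_hours,
        config=config,
    )
    return quant, metadata, truth
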