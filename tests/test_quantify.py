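"""Heavy fractions, CVs, reference-based harmonization, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsekin import quantify
from pulsekin.quantify import (
    fraction_matrix,
    harmonize,
    heavy_fraction,
    incorporation_summary,
    pca_scores,
    peptide_fractions,
    recovered_batch_offsets,
    replicate_cv,
)


@pytest.mark.parametrize(
    "light, heavy, expected",
    [(9, 1, 0.1), (5, 0, 0.0), (3.5, 3.5, 0.5), (0, 2, 1.0)],
)
def test_heavy_fraction_values(light, heavy, expected):
    assert heavy_fraction(light, heavy) == pytest.approx(expected)


def test_heavy_fraction_undefined_when_both_zero():
    assert math.isnan(heavy_fraction(0.0, 0.0))


@settings(deadline=None, derandomize=True)
@given(
    light=st.floats(0, 1e9),
    heavy=st.floats(0, 1e9),
    scale=st.floats(1e-6, 1e6),
)
def test_heavy_fraction_scale_invariant(light, heavy, scale):
    """(aL, aH) gives the same fraction as (L, H) for any a > 0."""
    if light + heavy == 0 or (light + heavy) * scale == 0:
        return
    assert heavy_fraction(light * scale, heavy * scale) == pytest.approx(
        heavy_fraction(light, heavy), rel=1e-9, abs=1e-12
    )


def test_heavy_fraction_rejects_negative():
    with pytest.raises(ValueError):
        heavy_fraction(-1.0, 1.0)


def _mini_quant_meta():
    quant = pd.DataFrame(
        {
            "peptide_id": ["p1"] * 4,
            "n_heavy_sites": [0, 1, 0, 1],
            "sample_id": ["s1", "s1", "s2", "s2"],
            "intensity": [90.0, 10.0, 80.0, 20.0],
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "tissue": ["liver", "liver"],
            "stage": ["E14.5"] * 2,
            "time_hours": [2.0, 2.0],
            "replicate": [1, 2],
            "batch": ["b1", "b1"],
            "is_reference": [False, False],
        }
    )
    return quant, meta


def test_peptide_fractions_sums_heavy_channels():
    quant = pd.DataFrame(
        {
            "peptide_id": ["p1"] * 3,
            "n_heavy_sites": [0, 1, 2],
            "sample_id": ["s1"] * 3,
            "intensity": [640.0, 320.0, 40.0],
        }
    )
    fr = peptide_fractions(quant)
    assert fr["fraction"].iloc[0] == pytest.approx(0.36)
    assert fr["total_intensity"].iloc[0] == pytest.approx(1000.0)


def test_peptide_fractions_skips_zero_total():
    quant = pd.DataFrame(
        {
            "peptide_id": ["p1", "p2"],
            "n_heavy_sites": [0, 0],
            "sample_id": ["s1", "s1"],
            "intensity": [0.0, 5.0],
        }
    )
    fr = peptide_fractions(quant)
    assert fr["peptide_id"].tolist() == ["p2"]


def test_incorporation_summary_mean_median():
    quant, meta = _mini_quant_meta()
    fr = peptide_fractions(quant)
    per_sample, pooled = incorporation_summary(fr, meta)
    assert pooled["mean_fraction"] == pytest.approx(0.15)
    assert per_sample.set_index("sample_id").loc["s1", "median_fraction"] == pytest.approx(0.1)


def test_replicate_cv_hand_value():
    """CV of {1, 3} is sd/mean = sqrt(2)/2."""
    quant = pd.DataFrame(
        {
            "peptide_id": ["p1"] * 2,
            "n_heavy_sites": [0, 0],
            "sample_id": ["s1", "s2"],
            "intensity": [1.0, 3.0],
        }
    )
    _, meta = _mini_quant_meta()
    table, medians = replicate_cv(quant, meta)
    assert medians["light"] == pytest.approx(math.sqrt(2) / 2)
    assert len(table) == 1


def test_replicate_cv_constant_is_zero():
    quant = pd.DataFrame(
        {
            "peptide_id": ["p1"] * 2,
            "n_heavy_sites": [1, 1],
            "sample_id": ["s1", "s2"],
            "intensity": [10.0, 10.0],
        }
    )
    _, meta = _mini_quant_meta()
    _, medians = replicate_cv(quant, meta)
    assert medians["heavy"] == pytest.approx(0.0)


# ---------------------------------------------------------------- harmonize


def _batch_quant_meta():
    """Two batches sharing a reference mixture; batch B shifted by +1.5 log2."""
    rows = []
    ref_vals = {"p1": 1000.0, "p2": 50.0}
    for batch, shift, ref_sample, sample in [
        ("A", 0.0, "refA", "s1"),
        ("B", 1.5, "refB", "s2"),
    ]:
        for pid, v in ref_vals.items():
            rows.append((pid, 0, ref_sample, v * 2**shift))
            rows.append((pid, 0, sample, v * 1.7 * 2**shift))
    quant = pd.DataFrame(rows, columns=["peptide_id", "n_heavy_sites", "sample_id", "intensity"])
    meta = pd.DataFrame(
        {
            "sample_id": ["refA", "s1", "refB", "s2"],
            "tissue": ["pooled", "liver", "pooled", "liver"],
            "stage": ["E14.5"] * 4,
            "time_hours": [0.0, 2.0, 0.0, 2.0],
            "replicate": [0, 1, 0, 1],
            "batch": ["A", "A", "B", "B"],
            "is_reference": [True, False, True, False],
        }
    )
    return quant, meta


def test_harmonize_equalizes_references_across_batches():
    quant, meta = _batch_quant_meta()
    out = harmonize(quant, meta, center="none")
    ref = out[out["sample_id"].str.startswith("ref")]
    wide = ref.pivot(index="peptide_id", columns="sample_id", values="log2_corrected")
    np.testing.assert_allclose(wide["refA"], wide["refB"], atol=1e-12)
    # two-point symmetry: corrected reference is the across-batch mean
    assert wide.loc["p1", "refA"] == pytest.approx(math.log2(1000.0) + 0.75)


def test_harmonize_recovers_injected_offsets_exactly():
    quant, meta = _batch_quant_meta()
    rec = recovered_batch_offsets(quant, meta)
    assert rec["A"] == pytest.approx(-0.75, abs=1e-12)
    assert rec["B"] == pytest.approx(+0.75, abs=1e-12)
    assert rec["B"] - rec["A"] == pytest.approx(1.5, abs=1e-12)


def test_harmonize_single_batch_is_centering_only():
    quant, meta = _batch_quant_meta()
    sel = meta["batch"] == "A"
    out = harmonize(quant[quant["sample_id"].isin(meta[sel]["sample_id"])], meta[sel], center="none")
    np.testing.assert_allclose(
        out["log2_corrected"], np.log2(quant[quant["sample_id"].isin(meta[sel]["sample_id"])]["intensity"]), atol=1e-12
    )


def test_harmonize_is_idempotent():
    quant, meta = _batch_quant_meta()
    once = harmonize(quant, meta)
    again_input = once.assign(intensity=2.0 ** once["log2_corrected"])[
        ["peptide_id", "n_heavy_sites", "sample_id", "intensity"]
    ]
    twice = harmonize(again_input, meta)
    merged = once.merge(twice, on=["peptide_id", "n_heavy_sites", "sample_id"])
    np.testing.assert_allclose(merged["log2_corrected_x"], merged["log2_corrected_y"], atol=1e-10)


def test_harmonize_requires_reference_per_batch():
    quant, meta = _batch_quant_meta()
    meta2 = meta.copy()
    meta2.loc[meta2["sample_id"] == "refB", "is_reference"] = False
    with pytest.raises(ValueError, match="without a reference"):
        harmonize(quant, meta2)


def test_harmonize_on_simulation_recovers_truth(noisy_sim):
    """Median reference deviation per batch matches the injected log2 shifts."""
    _, quant, meta, truth = noisy_sim
    rec = recovered_batch_offsets(quant, meta)
    injected = pd.Series(truth.batch_offsets)
    centered = injected - injected.mean()
    # single noisy reference per batch: tolerance set by CV/sqrt(n_features)
    for b in centered.index:
        assert rec[b] == pytest.approx(centered[b], abs=0.1)


# ---------------------------------------------------------------------- PCA


def test_pca_separates_shifted_block():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(6, 40))
    base[3:, :15] += 5.0  # second block shifted in a feature subset
    mat = pd.DataFrame(base, index=[f"s{i}" for i in range(6)])
    scores, var_frac = pca_scores(mat)
    pc1 = scores["PC1"]
    assert (pc1[:3].max() < pc1[3:].min()) or (pc1[:3].min() > pc1[3:].max())
    assert var_frac[0] > 0.5


def test_pca_scores_orthogonal():
    rng = np.random.default_rng(2)
    mat = pd.DataFrame(rng.normal(size=(8, 30)))
    scores, _ = pca_scores(mat, n_components=4)
    gram = scores.to_numpy().T @ scores.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-8


def test_pca_identical_samples_coincide():
    rng = np.random.default_rng(3)
    mat = pd.DataFrame(rng.normal(size=(4, 20)))
    mat.iloc[3] = mat.iloc[2]
    scores, _ = pca_scores(mat)
    np.testing.assert_allclose(scores.iloc[2], scores.iloc[3], atol=1e-10)


def test_pca_constant_matrix_is_degenerate():
    mat = pd.DataFrame(np.ones((3, 10)))
    with pytest.raises(ValueError, match="degenerate"):
        pca_scores(mat)


def test_fraction_matrix_drops_incomplete_features_for_pca(noisy_sim):
    _, quant, meta, _ = noisy_sim
    corrected = quantify.harmonize(quant, meta)
    mat = fraction_matrix(corrected)
    scores, var_frac = pca_scores(mat)
    assert len(scores) == mat.shape[0]
    assert var_frac.sum() <= 1.0 + 1e-9
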