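"""Generators: calibration, determinism, conservation, truth recovery."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pyroaei.errors import AssayError, ValidationError
from pyroaei.io_formats import get_enzyme
from pyroaei.regulatory_analysis import cpg_stats
from pyroaei.rflp_genotyping import digest
from pyroaei.synthetic_data import (
    PRESETS,
    DirectionGroup,
    ImbalanceArchetype,
    MeasurementModel,
    PopulationSpec,
    SnpSpec,
    generate_promoter,
    generate_rflp_template,
    sample_true_folds,
    simulate_cdna_measurements,
    simulate_experiment,
    simulate_gdna_measurement,
    simulate_gdna_measurements,
    simulate_genotypes,
)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_heterozygote_count_within_binomial_bounds():
    spec = PopulationSpec(n_animals=40, snps=(SnpSpec("G1", "A", "G", 0.5),))
    gt = simulate_genotypes(spec, seed=1)
    n_het = int((gt["G1"] == "AB").sum())
    lo, hi = stats.binom.interval(0.99, 40, 0.5)  # expected 20 hets
    assert lo <= n_het <= hi


def test_extreme_frequency_gives_homozygotes():
    spec = PopulationSpec(n_animals=40, snps=(SnpSpec("G1", "A", "G", 1 - 1e-12),))
    gt = simulate_genotypes(spec, seed=2)
    assert (gt["G1"] == "AA").all()


def test_genotype_determinism():
    spec = PopulationSpec()
    pd.testing.assert_frame_equal(simulate_genotypes(spec, 7), simulate_genotypes(spec, 7))


def test_population_spec_validation():
    with pytest.raises(ValidationError):
        PopulationSpec(n_animals=1)
    with pytest.raises(ValidationError):
        SnpSpec("G", "A", "C", 0.0)


# ---------------------------------------------------------------------------
# gDNA measurement model
# ---------------------------------------------------------------------------

def test_zero_noise_model_is_exactly_balanced():
    assert simulate_gdna_measurement(MeasurementModel(0.0, 0.0, 0.0), 0) == (50.0, 50.0)


def test_gdna_bias_calibration():
    """Mean |deviation| matches the 3 % target within 3 Monte-Carlo SEs and
    never exceeds the 8 % hard maximum."""
    pct = simulate_gdna_measurements(MeasurementModel(), 10_000, 42)
    dev = np.abs(pct - 50.0)
    se = dev.std(ddof=1) / math.sqrt(len(dev))
    assert abs(dev.mean() - 3.0) < 3 * se
    assert dev.max() <= 8.0


def test_gdna_pair_sums_to_100():
    a, b = simulate_gdna_measurement(MeasurementModel(), 3)
    assert a + b == pytest.approx(100.0)


def test_infeasible_bias_model_rejected():
    # the truncated half-normal family cannot put its mean above half the cap
    with pytest.raises(ValidationError):
        MeasurementModel(gdna_bias_mean_pct=5.0, gdna_bias_max_pct=8.0)


# ---------------------------------------------------------------------------
# cDNA archetypes
# ---------------------------------------------------------------------------

def test_balanced_archetype_zero_noise_is_50_50():
    table, truth = simulate_cdna_measurements(
        PRESETS["null"].archetype, 5, MeasurementModel(0.0, 0.0, 0.0), 0
    )
    assert np.allclose(table.df["pct_a"], 50.0)
    assert (truth["true_status"] == "balanced").all()


def test_fold_four_zero_noise_measures_80_20():
    archetype = ImbalanceArchetype(
        "r4", groups=(DirectionGroup("A", 4.0, 0.0, 1.0),), fraction_imbalanced=1.0
    )
    table, truth = simulate_cdna_measurements(archetype, 3, MeasurementModel(0.0, 0.0, 0.0), 0)
    assert np.allclose(table.df["pct_a"], 80.0)
    assert np.allclose(table.df["pct_b"], 20.0)
    assert (truth["true_status"] == "imbalanced").all()


def test_measurement_rows_conserve_100():
    for name in PRESETS:
        table, _ = simulate_cdna_measurements(PRESETS[name].archetype, 20, MeasurementModel(), 1)
        total = table.df["pct_a"] + table.df["pct_b"]
        assert np.allclose(total, 100.0, atol=0)


def test_cdna_determinism():
    a1, t1 = simulate_cdna_measurements(PRESETS["lep-liver"].archetype, 8, MeasurementModel(), 9)
    a2, t2 = simulate_cdna_measurements(PRESETS["lep-liver"].archetype, 8, MeasurementModel(), 9)
    pd.testing.assert_frame_equal(a1.df, a2.df)
    pd.testing.assert_frame_equal(t1, t2)


def _group_calibration(archetype, group, n=1500, seed=5):
    single = ImbalanceArchetype(
        archetype.name, groups=(DirectionGroup(group.direction, group.fold_mean, group.fold_sd, 1.0),),
        fraction_imbalanced=1.0,
    )
    folds, dirs, _ = sample_true_folds(single, n, np.random.default_rng(seed))
    return folds


@pytest.mark.parametrize("preset_name", ["lep-liver", "igf2-pituitary", "igf2-kidney", "ccl2-pituitary"])
def test_archetype_calibration_three_se(preset_name):
    """Empirical mean/SD of true fold ratios match each preset group within
    3 Monte-Carlo standard errors over >= 1000 draws."""
    preset = PRESETS[preset_name]
    for group in preset.archetype.groups:
        folds = _group_calibration(preset.archetype, group)
        n = len(folds)
        se_mean = folds.std(ddof=1) / math.sqrt(n)
        assert abs(folds.mean() - group.fold_mean) < 3 * se_mean
        # SE of the sample SD from the empirical fourth moment
        m2 = folds.var(ddof=1)
        m4 = np.mean((folds - folds.mean()) ** 4)
        se_sd = math.sqrt(max(m4 - m2**2, 0.0) / (4 * m2 * n))
        assert abs(folds.std(ddof=1) - group.fold_sd) < 3 * se_sd


def test_igf2_pituitary_direction_counts():
    """7 of 9 samples toward the T allele (allele B of the G/T assay)."""
    _, truth = simulate_cdna_measurements(PRESETS["igf2-pituitary"].archetype, 9, MeasurementModel(), 3)
    assert (truth["true_direction"] == "B").sum() == 7
    assert (truth["true_direction"] == "A").sum() == 2


def test_experiment_couples_gdna_and_cdna_bias():
    table, _ = simulate_experiment("null", seed=8, model=MeasurementModel(3.0, 8.0, 0.0))
    gdna = table.gdna("NULL")
    cdna = table.cdna("NULL")
    # null archetype, zero noise: the only skew in cDNA is the shared assay bias
    bias = gdna["pct_a"].mean() - 50.0
    assert bias != 0.0
    assert np.allclose(cdna["pct_a"], 50.0 + bias, atol=1e-9)


# ---------------------------------------------------------------------------
# promoter fixtures
# ---------------------------------------------------------------------------

def test_planted_island_dimensions_and_stats():
    truth = generate_promoter(1400, planted_islands=[(400, 968, 0.65, 0.75)], seed=0)
    assert truth.islands == ((400, 968),)
    assert len(truth.sequence) == 1400
    st_ = cpg_stats(truth.sequence[400:968])
    assert st_.gc_fraction >= 0.5 and st_.obs_exp >= 0.6  # verifiably island-like
    background = truth.sequence[:400]
    bg = cpg_stats(background)
    assert bg.gc_fraction < 0.5 and bg.obs_exp < 0.6


def test_no_planted_features_empty_truth():
    truth = generate_promoter(500, seed=1)
    assert truth.islands == () and truth.motifs == () and truth.snps == ()
    assert truth.island_bed() == []


def test_planted_motif_retrievable_by_string_match():
    truth = generate_promoter(600, planted_motifs=[("GGGCGG", 250, "+"), ("TATAAT", 400, "-")], seed=2)
    assert truth.sequence[250:256] == "GGGCGG"
    from pyroaei._sequence import revcomp

    assert truth.sequence[400:406] == revcomp("TATAAT")


def test_planted_snp_written_and_overlap_rejected():
    truth = generate_promoter(300, planted_snps=[(150, "C", "G")], seed=3)
    assert truth.sequence[150] == "C"
    with pytest.raises(ValidationError, match="overlap"):
        generate_promoter(
            600, planted_islands=[(100, 320, 0.65, 0.75)], planted_motifs=[("GGGCGG", 310, "+")], seed=4
        )


def test_promoter_determinism():
    a = generate_promoter(800, planted_islands=[(200, 500, 0.6, 0.7)], seed=12)
    b = generate_promoter(800, planted_islands=[(200, 500, 0.6, 0.7)], seed=12)
    assert a.sequence == b.sequence


# ---------------------------------------------------------------------------
# RFLP fixtures
# ---------------------------------------------------------------------------

def test_natural_site_cuts_exactly_one_allele():
    syn = generate_rflp_template(("T", "C"), get_enzyme("MseI"), seed=0)
    # for MseI (TTAA) a T/C SNP inside the site: the T allele carries the site
    assert syn.cut_allele == "A"
    cut = digest(syn.templates["A"], syn.assay.enzyme)
    uncut = digest(syn.templates["B"], syn.assay.enzyme)
    assert len(cut.fragment_lengths) == 2
    assert len(uncut.fragment_lengths) == 1


def test_forced_site_comes_from_the_primer():
    """Forced-RFLP soundness: the unmodified templates are cut for neither
    allele; after primer incorporation exactly one amplicon is cut."""
    syn = generate_rflp_template(("G", "A"), get_enzyme("PvuII"), force_site=True, seed=1)
    for allele in ("A", "B"):
        assert len(digest(syn.templates[allele], syn.assay.enzyme).fragment_lengths) == 1
    patterns = {"A": syn.assay.expected_a, "B": syn.assay.expected_b}
    assert len(patterns[syn.cut_allele].fragment_lengths) == 2
    other = "B" if syn.cut_allele == "A" else "A"
    assert len(patterns[other].fragment_lengths) == 1
    assert syn.assay.primers.forward_forced  # one substitution, near the 3' end
    (offset, _base), = syn.assay.primers.forward_forced
    assert 0 <= offset <= 7


def test_flank_too_short_raises():
    with pytest.raises(AssayError, match="shorter"):
        generate_rflp_template(("T", "C"), get_enzyme("MseI"), flank_len=0)


def test_impossible_constraint_raises():
    # both alleles satisfy every position of an all-N site: nothing to discriminate
    from pyroaei.io_formats import EnzymeRecord

    loose = EnzymeRecord("FakeI", "NNNN", 2, 2)
    with pytest.raises(AssayError, match="discriminate"):
        generate_rflp_template(("T", "C"), loose, seed=0)


def test_rflp_determinism():
    a = generate_rflp_template(("T", "C"), get_enzyme("MseI"), seed=6)
    b = generate_rflp_template(("T", "C"), get_enzyme("MseI"), seed=6)
    assert a.templates == b.templates
    assert a.assay.primers == b.assay.primers
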