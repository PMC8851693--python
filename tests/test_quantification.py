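"""Mass quantification, LOQ formulas, censoring, and sample-level inversion."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ohpcb
from ohpcb.peak_tables import CalibrationReplicate, parse_analyte_id
from ohpcb.quantification import (
    QuantificationError,
    build_loq_table,
    censor,
    compute_recoveries,
    concentrations,
    loq_known,
    loq_unknown,
    quantify_mass,
    recovery_correct,
)
from ohpcb.response_model import compute_rrfs


def test_quantify_mass_identity_at_spiked_is_mass():
    assert quantify_mass(1e6, 1e6, 25.0, 1.0) == pytest.approx(25.0)


def test_quantify_mass_inverse_in_rrf():
    m1 = quantify_mass(5e5, 1e6, 25.0, 0.8)
    m2 = quantify_mass(5e5, 1e6, 25.0, 1.6)
    assert m1 == pytest.approx(2.0 * m2)


def test_quantify_mass_inverts_rrf_computation():
    """Algebraic round trip on random positive calibration rows."""
    rng = np.random.default_rng(4)
    for _ in range(50):
        mass, resp, is_resp, is_mass = rng.uniform(0.1, 100.0, size=4)
        rec = CalibrationReplicate(parse_analyte_id("PCB52"), mass, resp, 1)
        rrf = compute_rrfs([rec], is_resp, is_mass)[0].rrf
        assert quantify_mass(resp, is_resp, is_mass, rrf) == pytest.approx(mass)


def test_quantify_mass_rejects_nonpositive_inputs():
    with pytest.raises(QuantificationError):
        quantify_mass(1.0, 1.0, 1.0, 0.0)
    with pytest.raises(QuantificationError):
        quantify_mass(1.0, 0.0, 1.0, 1.0)


def test_recovery_correct_identity_and_halving():
    oh1 = parse_analyte_id("4-OH-PCB3")
    assert recovery_correct(10.0, oh1, {3: 1.0}) == pytest.approx(10.0)
    assert recovery_correct(10.0, oh1, {3: 0.5}) == pytest.approx(20.0)


def test_recovery_correct_uses_nearest_surrogate_tie_to_lower():
    mono = parse_analyte_id("4-OH-PCB1")  # 1 chlorine
    recs = {n: 1.0 for n in range(2, 8)}
    recs[2] = 0.5
    assert recovery_correct(10.0, mono, recs) == pytest.approx(20.0)  # nearest = 2
    tri = parse_analyte_id("4-OH-PCB18")  # 3 chlorines; tie between 2 and 4
    assert recovery_correct(10.0, tri, {2: 0.5, 4: 1.0}) == pytest.approx(20.0)


def test_recovery_correct_rejects_nonpositive_recovery():
    with pytest.raises(QuantificationError):
        recovery_correct(1.0, parse_analyte_id("4-OH-PCB3"), {3: 0.0})


def test_loq_known_degenerate_blanks():
    assert loq_known([1.0, 1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_loq_known_hand_value():
    # mean 1.0, s 0.5, one-sided t(0.95, df=2) = 2.9200
    t = stats.t.ppf(0.95, 2)
    assert loq_known([0.5, 1.0, 1.5]) == pytest.approx(1.0 + t * 0.5)
    assert loq_known([0.5, 1.0, 1.5]) == pytest.approx(2.4600, abs=1e-4)


def test_loq_known_scales_linearly():
    blanks = [0.2, 0.5, 0.9, 1.1]
    assert loq_known([7 * b for b in blanks]) == pytest.approx(7 * loq_known(blanks))


def test_loq_known_needs_two_blanks():
    with pytest.raises(QuantificationError, match="fallback"):
        loq_known([1.0])


def test_loq_unknown_equal_inputs_and_hand_value():
    assert loq_unknown([0.15, 0.15, 0.15]) == pytest.approx(0.15)
    # ln values {0, 2}: mean 1, sd sqrt(2), t(0.95, df=1) = 6.3138
    t = stats.t.ppf(0.95, 1)
    expected = np.exp(1.0 + t * np.sqrt(2.0))
    assert loq_unknown([np.e**0, np.e**2]) == pytest.approx(expected)


def test_loq_unknown_at_least_geometric_mean():
    rng = np.random.default_rng(0)
    for _ in range(20):
        vals = rng.lognormal(-2, 1, size=rng.integers(2, 8))
        assert loq_unknown(vals) >= np.exp(np.log(vals).mean()) - 1e-12


def test_loq_unknown_rejects_nonpositive():
    with pytest.raises(QuantificationError):
        loq_unknown([0.1, 0.0])


def test_censor_boundary_cases():
    assert censor(0.10, 0.15) == (0.0, True)
    assert censor(0.15, 0.15) == (0.15, False)  # value at the LOQ is retained
    assert censor(0.2, 0.0) == (0.2, False)
    assert censor(0.15, 0.15, boundary="at-or-below") == (0.0, True)
    with pytest.raises(QuantificationError):
        censor(-0.1, 0.15)


def _zero_noise_config(seed=3):
    cfg = ohpcb.ihsc_like_preset(seed=seed)
    cfg.rrf_sigma = 0.0
    cfg.replicate_sigma = 0.0
    cfg.recovery_gsd = 1.0
    cfg.blank_gm_ng = 1e-12
    cfg.blank_gsd = 1.0
    cfg.blank_cv = 0.0
    return cfg


def test_noiseless_sample_recovers_truth_exactly():
    study = ohpcb.generate_study(_zero_noise_config())
    _, table = ohpcb.analyze_study(study, B=200, seed=3)
    truth = study.truth.rename(columns={"concentration": "true_conc"})
    merged = table.frame.merge(truth, on=["sample_id", "analyte"], how="outer")
    merged = merged.fillna({"concentration": 0.0, "true_conc": 0.0})
    pos = merged[merged["true_conc"] > 0]
    np.testing.assert_allclose(pos["concentration"], pos["true_conc"], rtol=1e-9)
    assert (merged.loc[merged["true_conc"] == 0, "concentration"] == 0).all()


def test_true_zero_sample_yields_all_censored_zeros():
    """Responses far below the LOQ all censor to exact zeros."""
    study = ohpcb.generate_study(_zero_noise_config())
    model, _ = ohpcb.analyze_study(study, B=200, seed=3)
    sample = study.samples[0]
    tiny = dataclasses.replace(sample)
    tiny.peaks = [dataclasses.replace(p, response=p.response * 1e-9)
                  for p in sample.peaks]
    loq = build_loq_table(study.blanks["sediment"], "sediment")
    loq.known = {k: 1.0 for k in loq.known}
    loq.unknown_loq = 1.0
    table = ohpcb.concentrations(tiny, model, loq)
    assert table.frame["censored"].all()
    assert (table.frame["concentration"] == 0.0).all()


def test_uncensored_concentrations_scale_with_responses(small_study):
    model, _ = ohpcb.analyze_study(small_study, B=200, seed=5)
    loq = build_loq_table(small_study.blanks["sediment"], "sediment")
    sample = small_study.samples[0]
    k = 3.0
    scaled = dataclasses.replace(sample)
    scaled.peaks = [dataclasses.replace(p, response=k * p.response)
                    for p in sample.peaks]
    base = ohpcb.concentrations(sample, model, loq).frame.set_index("analyte")
    up = ohpcb.concentrations(scaled, model, loq).frame.set_index("analyte")
    both = (~base["censored"]) & (~up["censored"])
    np.testing.assert_allclose(
        up.loc[both, "concentration"], k * base.loc[both, "concentration"], rtol=1e-9
    )


def test_lowering_loq_never_censors_a_reported_value(small_study):
    model, _ = ohpcb.analyze_study(small_study, B=200, seed=5)
    loq_hi = build_loq_table(small_study.blanks["sediment"], "sediment")
    loq_lo = dataclasses.replace(
        loq_hi,
        known={k: v / 10 for k, v in loq_hi.known.items()},
        unknown_loq=loq_hi.unknown_loq / 10,
    )
    sample = small_study.samples[0]
    hi = ohpcb.concentrations(sample, model, loq_hi).frame.set_index("analyte")
    lo = ohpcb.concentrations(sample, model, loq_lo).frame.set_index("analyte")
    reported_hi = hi.index[~hi["censored"]]
    assert not lo.loc[reported_hi, "censored"].any()


def test_missing_internal_standard_names_sample(small_study):
    model, _ = ohpcb.analyze_study(small_study, B=200, seed=5)
    loq = build_loq_table(small_study.blanks["sediment"], "sediment")
    sample = dataclasses.replace(small_study.samples[0])
    sample.internal_standard_responses = {"PCB204": 1e6}
    with pytest.raises(QuantificationError, match=sample.sample_id):
        ohpcb.concentrations(sample, model, loq)


def test_recoveries_flagged_outside_range(small_study):
    sample = dataclasses.replace(small_study.samples[0])
    label = "SURR-OHPCB-Cl4"
    sample.surrogate_responses = dict(sample.surrogate_responses)
    sample.surrogate_responses[label] = sample.internal_standard_responses[
        "d5-PCB30"
    ] * 3.0  # recovery 300%
    table = compute_recoveries(sample)
    assert any(n_cl == 4 for (_, fam, n_cl, _r) in table.flagged if fam == "OHPCB")


def test_concentration_totals_reproducible(small_study):
    _, t1 = ohpcb.analyze_study(small_study, B=200, seed=5)
    _, t2 = ohpcb.analyze_study(small_study, B=200, seed=5)
    pd.testing.assert_frame_equal(t1.frame, t2.frame)
    assert (t1.totals("OHPCB") >= 0).all()
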