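"""Analyte-label grammar, canonical ordering, and CSV round trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ohpcb.peak_tables import (
    AnalyteParseError,
    CalibrationReplicate,
    PeakRecord,
    PeakTableError,
    SampleRun,
    canonical_order,
    format_analyte_id,
    parse_analyte_id,
    read_blank_table,
    read_calibration_table,
    read_peak_table,
    read_sample_table,
    write_blank_table,
    write_calibration_table,
    write_sample_table,
)


@pytest.mark.parametrize(
    "label, kind, n_cl, rrt",
    [
        ("2@1.232", "unknown-OHPCB", 2, 1.232),
        ("3@1.482", "unknown-OHPCB", 3, 1.482),
        ("4-OH-PCB52", "known-OHPCB", 4, None),
        ("4'-OH-PCB18", "known-OHPCB", 3, None),
        ("4′-OH-PCB18", "known-OHPCB", 3, None),  # typographic prime accepted
        ("PCB52", "known-PCB", 4, None),
        ("PCB209", "known-PCB", 10, None),
    ],
)
def test_parse_analyte_id(label, kind, n_cl, rrt):
    analyte = parse_analyte_id(label)
    assert analyte.kind == kind
    assert analyte.n_cl == n_cl
    assert analyte.rrt == rrt


def test_prime_emitted_as_ascii_apostrophe():
    assert parse_analyte_id("4′-OH-PCB18").label == "4'-OH-PCB18"


@pytest.mark.parametrize("shorthand", ["PCB20 + 28", "PCB20 + PCB28"])
def test_coeluting_congeners_form_one_analyte(shorthand):
    analyte = parse_analyte_id(shorthand)
    assert analyte.coeluters == ("PCB20", "PCB28")
    assert analyte.n_cl == 3  # shared homologue
    assert analyte.label == "PCB20 + PCB28"


@pytest.mark.parametrize(
    "bad",
    ["", "   ", "nonsense", "PCB210", "PCB0", "11@1.200", "0@1.100", "4-OH-PCB0",
     "PCB3 + PCB15"],  # last: coeluters span homologues 1 and 2
)
def test_malformed_labels_raise(bad):
    with pytest.raises(AnalyteParseError):
        parse_analyte_id(bad)


_known_pcb = st.integers(1, 209).map(lambda n: f"PCB{n}")
_known_oh = st.tuples(
    st.sampled_from(["2", "3", "4", "2'", "3'", "4'"]), st.integers(1, 209)
).map(lambda t: f"{t[0]}-OH-PCB{t[1]}")
_unknown_oh = st.tuples(
    st.integers(1, 10), st.floats(0.5, 3.0, allow_nan=False)
).map(lambda t: f"{t[0]}@{round(t[1], 3):.3f}")


@given(st.one_of(_known_pcb, _known_oh, _unknown_oh))
def test_parse_format_round_trip(label):
    parsed = parse_analyte_id(label)
    assert parse_analyte_id(format_analyte_id(parsed)) == parsed


def _oh(label, rrt=None):
    return parse_analyte_id(label).with_rrt(rrt)


def test_canonical_order_by_homologue_then_elution():
    analytes = [_oh("3@1.482"), _oh("2@1.232"), _oh("4-OH-PCB52", 1.524)]
    ordered = canonical_order(analytes, "OHPCB")
    assert [a.label for a in ordered] == ["2@1.232", "3@1.482", "4-OH-PCB52"]


def test_canonical_order_pcb_by_congener_number():
    analytes = [parse_analyte_id(lab) for lab in ["PCB52", "PCB8", "PCB209"]]
    assert [a.label for a in canonical_order(analytes, "PCB")] == [
        "PCB8",
        "PCB52",
        "PCB209",
    ]


@given(st.permutations(["2@1.232", "3@1.482", "2@0.901", "4-OH-PCB52", "5@1.600"]))
def test_canonical_order_permutation_invariant_and_idempotent(labels):
    analytes = [_oh(lab, rrt=1.524 if lab == "4-OH-PCB52" else None) for lab in labels]
    ordered = canonical_order(analytes, "OHPCB")
    assert ordered == canonical_order(ordered, "OHPCB")  # idempotent
    reference = canonical_order(sorted(analytes, key=lambda a: a.label), "OHPCB")
    assert ordered == reference


def test_canonical_order_rejects_mixed_families():
    with pytest.raises(PeakTableError):
        canonical_order([parse_analyte_id("PCB52"), _oh("2@1.232")], "OHPCB")


def test_calibration_csv_round_trip(tmp_path):
    records = [
        CalibrationReplicate(parse_analyte_id("PCB52"), 25.0, 1000.0 + r, r + 1)
        for r in range(6)
    ]
    path = tmp_path / "cal.csv"
    write_calibration_table(records, path)
    back = read_calibration_table(path)
    assert back == records


def test_calibration_reader_warns_on_missing_replicates(tmp_path):
    records = [CalibrationReplicate(parse_analyte_id("PCB52"), 25.0, 1.0, 1)]
    path = tmp_path / "cal.csv"
    write_calibration_table(records, path)
    with pytest.warns(UserWarning, match="sextuplicate"):
        read_calibration_table(path)


def test_sample_csv_round_trip(tmp_path):
    run = SampleRun(
        "S1",
        "NBH",
        "sediment",
        1.0,
        internal_standard_responses={"d5-PCB30": 1e6, "PCB204": 9e5},
        surrogate_responses={"SURR-OHPCB-Cl3": 8e5},
    )
    for inj in (1, 2):
        run.peaks.append(PeakRecord(_oh("2@1.232"), 123.0 * inj, "S1", inj))
        run.peaks.append(PeakRecord(_oh("4-OH-PCB52", 1.524), 77.0, "S1", inj))
    path = tmp_path / "samples.csv"
    write_sample_table([run], path)
    back = read_sample_table(path)
    assert len(back) == 1
    got = back[0]
    assert got.internal_standard_responses == run.internal_standard_responses
    assert got.surrogate_responses == run.surrogate_responses
    assert got.peaks == run.peaks
    got.validate()


def test_blank_csv_round_trip(tmp_path):
    import pandas as pd

    frame = pd.DataFrame(
        {
            "blank_id": ["b1", "b1", "b2", "b2"],
            "analyte": ["PCB52", "2@1.232", "PCB52", "2@1.232"],
            "mass_ng": [0.1, 0.02, 0.12, 0.03],
        }
    )
    path = tmp_path / "blanks.csv"
    write_blank_table(frame, path)
    back = read_blank_table(path)
    pd.testing.assert_frame_equal(back, frame)


@pytest.mark.parametrize(
    "content, match",
    [
        ("analyte,standard_mass_ng,response\nPCB52,25,1", "missing column"),
        (
            "analyte,standard_mass_ng,response,replicate\nPCB52,25,NA,1",
            "non-numeric",
        ),
        (
            "analyte,standard_mass_ng,response,replicate\n"
            "PCB52,25,1,1\nPCB52,25,2,1",
            "duplicate",
        ),
    ],
)
def test_calibration_reader_reports_first_failure(tmp_path, content, match):
    path = tmp_path / "cal.csv"
    path.write_text(content)
    with pytest.raises(PeakTableError, match=match):
        read_peak_table(path, "calibration")


def test_sample_reader_checks_n_cl_consistency(tmp_path):
    path = tmp_path / "samples.csv"
    path.write_text(
        "sample_id,site,matrix,sample_mass_g,analyte,n_cl,rrt,response,injection\n"
        "S1,NBH,sediment,1.0,2@1.232,3,1.232,10,1\n"
    )
    with pytest.raises(PeakTableError, match="disagrees"):
        read_sample_table(path)


def test_sample_run_requires_positive_mass():
    with pytest.raises(PeakTableError):
        SampleRun("S1", "NBH", "sediment", 0.0)


def test_validate_flags_missing_internal_standard():
    run = SampleRun("S1", "NBH", "sediment", 1.0,
                    internal_standard_responses={"d5-PCB30": 1e6})
    with pytest.raises(PeakTableError, match="PCB204"):
        run.validate()
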