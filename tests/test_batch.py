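"""Batch parameters parsing, missing-file accounting, batch runs, report."""

import numpy as np
import pandas as pd
import pytest

from editquant import (
    detect_edits,
    detect_edits_batch,
    missing_files,
    parse_parameters,
    percent_loss,
    save_batch_skeleton,
    write_abif,
)
from editquant.batch import PARAMETER_COLUMNS, ParameterError

from conftest import GZMA_GUIDE, synth_pair


def params_csv(tmp_path, rows, name="params.csv"):
    df = pd.DataFrame(rows, columns=PARAMETER_COLUMNS)
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


def base_row(**overrides):
    row = {
        "sample_name": "s1",
        "sample_file": "s1.ab1",
        "ctrl_file": "c1.ab1",
        "motif": GZMA_GUIDE,
        "motif_fwd": "TRUE",
        "wt": "A",
        "edit": "G",
        "phred_cutoff": "",
        "p_value": "",
    }
    row.update(overrides)
    return row


class TestParseParameters:
    def test_defaults_applied(self, tmp_path):
        table = parse_parameters(params_csv(tmp_path, [base_row()]))
        rec = table.data.iloc[0]
        assert rec["phred_cutoff"] == 0.001
        assert rec["p_value"] == 0.01
        assert rec["motif_fwd"] is np.True_ or rec["motif_fwd"] == True  # noqa: E712

    def test_duplicate_sample_name(self, tmp_path):
        path = params_csv(tmp_path, [base_row(), base_row(sample_file="x.ab1")])
        with pytest.raises(ParameterError, match="duplicate sample_name 's1'"):
            parse_parameters(path)

    def test_missing_column(self, tmp_path):
        df = pd.DataFrame([base_row()]).drop(columns=["motif"])
        path = tmp_path / "p.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ParameterError, match="motif"):
            parse_parameters(path)

    def test_bad_boolean_names_row(self, tmp_path):
        path = params_csv(tmp_path, [base_row(motif_fwd="maybe")])
        with pytest.raises(ParameterError, match="row 2"):
            parse_parameters(path)

    def test_boolean_any_case(self, tmp_path):
        rows = [
            base_row(sample_name="a", motif_fwd="True"),
            base_row(sample_name="b", motif_fwd="FALSE"),
        ]
        table = parse_parameters(params_csv(tmp_path, rows))
        assert list(table.data["motif_fwd"]) == [True, False]

    def test_unknown_column_warns(self, tmp_path):
        df = pd.DataFrame([base_row()])
        df["comment"] = "hello"
        path = tmp_path / "p.csv"
        df.to_csv(path, index=False)
        with pytest.warns(UserWarning, match="comment"):
            table = parse_parameters(path)
        assert list(table.data.columns) == PARAMETER_COLUMNS

    def test_xlsx_roundtrip(self, tmp_path):
        df = pd.DataFrame([base_row(phred_cutoff="0.01", p_value="0.05")])
        path = tmp_path / "p.xlsx"
        df.to_excel(path, index=False)
        table = parse_parameters(path)
        assert table.data.iloc[0]["phred_cutoff"] == 0.01
        assert table.data.iloc[0]["p_value"] == 0.05


class TestMissingFiles:
    def test_all_present(self, tmp_path):
        table = parse_parameters(params_csv(tmp_path, [base_row()]))
        assert missing_files(table, {"s1.ab1", "c1.ab1"}) == []

    def test_shared_control_deduplicated(self, tmp_path):
        rows = [base_row(sample_name=f"s{i}", sample_file=f"s{i}.ab1") for i in range(3)]
        table = parse_parameters(params_csv(tmp_path, rows))
        provided = {f"s{i}.ab1" for i in range(3)}
        assert missing_files(table, provided) == ["c1.ab1"]

    def test_sorted_output(self, tmp_path):
        rows = [
            base_row(sample_name="a", sample_file="zz.ab1"),
            base_row(sample_name="b", sample_file="aa.ab1", ctrl_file="c1.ab1"),
        ]
        table = parse_parameters(params_csv(tmp_path, rows))
        assert missing_files(table, set()) == ["aa.ab1", "c1.ab1", "zz.ab1"]


@pytest.fixture
def batch_dir(tmp_path):
    """Three synthetic samples sharing one control, written as .ab1."""
    files = tmp_path / "files"
    files.mkdir()
    sample0, ctrl = synth_pair(edits_at={5: ("G", 0.4)}, seed=21)
    write_abif(sample0, files / "s0.ab1")
    write_abif(ctrl.chromatogram, files / "ctrl.ab1")
    for i, f in [(1, 0.0), (2, 0.8)]:
        edits = {5: ("G", f)} if f else None
        s, _ = synth_pair(edits_at=edits, seed=21)  # same template as ctrl
        write_abif(s, files / f"s{i}.ab1")
    rows = [
        base_row(sample_name=f"s{i}", sample_file=f"s{i}.ab1", ctrl_file="ctrl.ab1")
        for i in range(3)
    ]
    return files, params_csv(tmp_path, rows)


class TestDetectEditsBatch:
    def test_three_ok_rows(self, batch_dir):
        files, params = batch_dir
        table = parse_parameters(params)
        result = detect_edits_batch(table, files)
        assert list(result.statuses.values()) == ["ok"] * 3
        # 5 wt positions per sample
        assert len(result.combined) == 15
        assert set(result.combined["sample_name"]) == {"s0", "s1", "s2"}

    def test_row_failure_isolated(self, batch_dir, tmp_path):
        files, _ = batch_dir
        rows = [
            base_row(sample_name="good", sample_file="s0.ab1", ctrl_file="ctrl.ab1"),
            base_row(
                sample_name="bad",
                sample_file="s1.ab1",
                ctrl_file="ctrl.ab1",
                motif="GGGGGGGGGGCCCCCCCCCC",
                wt="G",
                edit="A",
            ),
        ]
        table = parse_parameters(params_csv(tmp_path, rows, "p2.csv"))
        result = detect_edits_batch(table, files)
        assert result.statuses["good"] == "ok"
        assert result.statuses["bad"].startswith("error:")
        assert "not found" in result.statuses["bad"]
        assert set(result.combined["sample_name"]) == {"good"}

    def test_empty_table(self, tmp_path):
        save_batch_skeleton(tmp_path / "skel.csv")
        table = parse_parameters(tmp_path / "skel.csv")
        result = detect_edits_batch(table, tmp_path)
        assert len(result.combined) == 0
        assert result.statuses == {}

    def test_batch_of_one_equals_single(self, batch_dir):
        """Batch-of-one output is byte-identical to the direct call."""
        files, _ = batch_dir
        rows = [base_row(sample_name="only", sample_file="s0.ab1",
                         ctrl_file="ctrl.ab1")]
        df = pd.DataFrame(rows)
        path = files.parent / "one.csv"
        df.to_csv(path, index=False)
        table = parse_parameters(path)
        batch = detect_edits_batch(table, files)
        single = detect_edits(files / "s0.ab1", files / "ctrl.ab1",
                              GZMA_GUIDE, True, "A", "G")
        batch_tsv = (
            batch.combined.drop(columns=["sample_name"])
            .to_csv(sep="\t", index=False, float_format="%.6g")
        )
        assert batch_tsv == single.to_tsv()

    def test_deterministic_rerun(self, batch_dir):
        files, params = batch_dir
        table = parse_parameters(params)
        a = detect_edits_batch(table, files)
        b = detect_edits_batch(table, files)
        pd.testing.assert_frame_equal(a.combined, b.combined)


class TestSkeleton:
    def test_roundtrip_empty(self, tmp_path):
        for name in ("skel.xlsx", "skel.csv"):
            path = tmp_path / name
            save_batch_skeleton(path)
            table = parse_parameters(path)
            assert len(table) == 0
            assert list(table.data.columns) == PARAMETER_COLUMNS

    def test_overwrite(self, tmp_path):
        path = tmp_path / "skel.csv"
        save_batch_skeleton(path)
        first = path.read_bytes()
        save_batch_skeleton(path)
        assert path.read_bytes() == first


class TestPercentLoss:
    def test_equal_groups_zero(self):
        assert percent_loss([10, 10], [10, 10]) == pytest.approx(0.0)

    def test_total_loss(self):
        assert percent_loss([0, 0, 0], [5, 15]) == pytest.approx(100.0)

    def test_partial_loss(self):
        assert percent_loss([2], [10]) == pytest.approx(80.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="control mean"):
            percent_loss([1.0], [0.0])


class TestReport:
    def test_report_contents(self, batch_dir, tmp_path):
        from editquant.report import create_report

        files, params = batch_dir
        table = parse_parameters(params)
        result = detect_edits_batch(table, files)
        out = create_report(result, tmp_path / "report.html")
        html = out.read_text()
        assert "s0" in html and "s2" in html
        assert html.count("data:image/png;base64,") >= 6  # trace + barplot per sample
        assert "zero mass" in html

    def test_fasta_control_omits_control_plot(self, tmp_path):
        from editquant.report import create_report

        files = tmp_path / "f"
        files.mkdir()
        sample, ctrl = synth_pair(seed=30)
        write_abif(sample, files / "s.ab1")
        (files / "c.fa").write_text(f">c\n{ctrl.sequence}\n")
        rows = [base_row(sample_name="fasta_ctrl", sample_file="s.ab1",
                         ctrl_file="c.fa")]
        table = parse_parameters(params_csv(tmp_path, rows))
        result = detect_edits_batch(table, files)
        out = create_report(result, tmp_path / "r.html")
        assert "Control chromatogram not shown" in out.read_text()

    def test_empty_batch_valid_document(self, tmp_path):
        from editquant.batch import BatchResult
        from editquant.report import create_report

        empty = BatchResult(combined=pd.DataFrame(), statuses={}, models={})
        out = create_report(empty, tmp_path / "empty.html")
        assert "No samples" in out.read_text()
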