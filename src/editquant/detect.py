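"""Single-sample edit detection: files in, editing table plus null model out.

Pipeline: read the sample trace, build the per-base signal table, apply
the Phred filter, locate the (oriented) motif, align the control, fit
the background noise model from positions outside the motif (pooling
control-trace noise when available), then score every wild-type-base
position inside the motif: its edit-channel percent signal against the
zero-adjusted gamma null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import (
    UNALIGNED,
    AlignmentMap,
    MotifLocation,
    MotifSpec,
    align_sample_control,
    control_bases_at_motif,
    locate_motif,
)
from .noise import NoiseModel, collect_noise, edit_pvalue, fit_noise
from .signal import (
    DEFAULT_PHRED_CUTOFF,
    PERCENT_COLS,
    SignalTable,
    apply_quality_filter,
    build_signal_table,
)
from .trace_io import BASES, Chromatogram, ControlSequence, read_ab1, read_control

__all__ = [
    "RunParameters",
    "EditDetectionResult",
    "detect_edits",
    "detect_edits_from_traces",
    "expected_wt_edit",
    "RESULT_COLUMNS",
]

DEFAULT_P_THRESHOLD = 0.01

RESULT_COLUMNS = [
    "protospacer_position",
    "read_call_index",
    "wt_base",
    "edit_base",
    "control_base",
    "percent_A",
    "percent_C",
    "percent_G",
    "percent_T",
    "edit_percent",
    "edit_pvalue",
    "significant",
    "warnings",
]


@dataclass(frozen=True)
class RunParameters:
    """User-tunable knobs of a detection run.

    ``phred_cutoff`` is an error-probability threshold (0.001 = Q30);
    ``p_threshold`` is the raw p-value below which an edit is called
    significant (no multiple-testing correction).
    """

    phred_cutoff: float = DEFAULT_PHRED_CUTOFF
    p_threshold: float = DEFAULT_P_THRESHOLD

    def __post_init__(self) -> None:
        if not (0 < self.phred_cutoff <= 1):
            raise ValueError("phred_cutoff must be in (0, 1]")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")


@dataclass
class EditDetectionResult:
    """Output of :func:`detect_edits`.

    ``sample_data`` has one row per wild-type-base occurrence within the
    motif; ``statistical_parameters`` is the fitted background model.
    """

    sample_data: pd.DataFrame
    statistical_parameters: NoiseModel
    motif_location: MotifLocation
    alignment: AlignmentMap | None
    spec: MotifSpec
    params: RunParameters
    sample: Chromatogram
    control: ControlSequence | None
    signal_table: SignalTable
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path | None = None) -> str | None:
        """Serialize the editing table as TSV (returned when path is None)."""
        out = self.sample_data.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return out

    def summary(self) -> str:
        lines = [
            f"sample: {self.sample.source_name}",
            f"motif: {self.spec.motif} (motif_fwd={self.spec.motif_fwd}, "
            f"{self.spec.wt_base}->{self.spec.edit_base})",
            f"motif located at calls {self.motif_location.sample_interval} "
            f"with {self.motif_location.n_mismatches} mismatches",
            "noise model: nu={zero_mass:.4f} mu={mean:.4g} sigma={dispersion:.4g} "
            "(n={n_obs})".format(**self.statistical_parameters.summary()),
        ]
        sig = self.sample_data[self.sample_data["significant"] == True]  # noqa: E712
        lines.append(
            f"{len(self.sample_data)} candidate position(s), {len(sig)} significant "
            f"at p < {self.params.p_threshold}"
        )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def expected_wt_edit(editor_class: str, motif_fwd: bool) -> tuple[str, str]:
    """Read-strand (wt, edit) pair for an editor class and orientation.

    Adenine base editors convert A->G on the protospacer strand, read as
    T->C when the primer reads the opposite strand; cytosine base
    editors convert C->T, read as G->A.
    """
    editor = editor_class.upper()
    table = {
        ("ABE", True): ("A", "G"),
        ("ABE", False): ("T", "C"),
        ("CBE", True): ("C", "T"),
        ("CBE", False): ("G", "A"),
    }
    try:
        return table[(editor, bool(motif_fwd))]
    except KeyError:
        raise ValueError(
            f"unknown editor class {editor_class!r}; expected 'ABE' or 'CBE'"
        ) from None


def _control_noise(
    control: ControlSequence,
    alignment: AlignmentMap,
    location: MotifLocation,
    phred_cutoff: float,
) -> np.ndarray | None:
    """Background observations from a trace control, motif region excluded."""
    assert control.chromatogram is not None
    table = apply_quality_filter(
        build_signal_table(control.chromatogram), phred_cutoff
    )
    start, end = location.sample_interval
    mapped = [alignment.pairs[i] for i in range(start, end) if i in alignment.pairs]
    if mapped:
        if alignment.control_orientation == "reverse-complement":
            n = len(control.sequence)
            mapped = [n - 1 - i for i in mapped]
        lo, hi = min(mapped), max(mapped) + 1
        exclude = MotifLocation(sample_interval=(lo, hi), motif_fwd=True, n_mismatches=0)
    else:
        exclude = None
    try:
        return collect_noise(table, exclude)
    except ValueError:
        return None


def detect_edits_from_traces(
    sample: Chromatogram,
    control: ControlSequence | None,
    spec: MotifSpec,
    params: RunParameters = RunParameters(),
) -> EditDetectionResult:
    """Run the detection pipeline on in-memory objects.

    ``control`` may be None (control-free mode: candidate positions come
    from the motif string alone, noise from the sample only).
    """
    run_warnings: list[str] = []
    table = apply_quality_filter(build_signal_table(sample), params.phred_cutoff)
    location = locate_motif(sample.basecalls, spec)

    alignment = None
    control_bases: dict[int, str] = {}
    if control is not None:
        alignment = align_sample_control(sample.basecalls, control)
        control_bases = control_bases_at_motif(location, alignment, control)
        if all(b == UNALIGNED for b in control_bases.values()):
            run_warnings.append(
                "control does not cover the motif; falling back to control-free mode"
            )

    noise_obs = collect_noise(table, location)
    if control is not None and control.is_trace and alignment is not None:
        extra = _control_noise(control, alignment, location, params.phred_cutoff)
        if extra is not None:
            noise_obs = np.sort(np.concatenate([noise_obs, extra]))
    model = fit_noise(noise_obs)
    if model.zero_mass >= 1.0:
        run_warnings.append("degenerate noise model: all background signal is zero")

    start, end = location.sample_interval
    oriented = spec.oriented_motif
    data = table.data
    base_col = {b: f"percent_{b}" for b in BASES}
    rows = []
    for k in range(end - start):
        call_index = start + k
        pos = location.protospacer_of_offset[k]
        ctrl_base = control_bases.get(pos, UNALIGNED) if control is not None else UNALIGNED
        reference_base = ctrl_base if ctrl_base not in (UNALIGNED, "N") else oriented[k]
        if reference_base != spec.wt_base:
            continue
        row = data.iloc[call_index]
        row_warnings = []
        if not row["valid"]:
            row_warnings.append("no signal at peak")
        if not row["passes_quality"]:
            row_warnings.append("base quality below phred cutoff")
        if row["valid"]:
            edit_percent = float(row[base_col[spec.edit_base]])
            pval = edit_pvalue(edit_percent, model)
        else:
            edit_percent = float("nan")
            pval = float("nan")
        rows.append(
            {
                "protospacer_position": pos,
                "read_call_index": call_index,
                "wt_base": spec.wt_base,
                "edit_base": spec.edit_base,
                "control_base": ctrl_base,
                **{c: float(row[c]) for c in PERCENT_COLS},
                "edit_percent": edit_percent,
                "edit_pvalue": pval,
                "significant": bool(pval < params.p_threshold)
                if not np.isnan(pval)
                else False,
                "warnings": "; ".join(row_warnings),
            }
        )
        if row_warnings:
            run_warnings.append(
                f"protospacer position {pos}: " + "; ".join(row_warnings)
            )
    result_df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    result_df = result_df.sort_values("protospacer_position", ignore_index=True)

    return EditDetectionResult(
        sample_data=result_df,
        statistical_parameters=model,
        motif_location=location,
        alignment=alignment,
        spec=spec,
        params=params,
        sample=sample,
        control=control,
        signal_table=table,
        warnings=run_warnings,
    )


def detect_edits(
    sample_path: str | Path,
    control_path: str | Path | None,
    motif: str,
    motif_fwd: bool,
    wt: str,
    edit: str,
    params: RunParameters = RunParameters(),
) -> EditDetectionResult:
    """Detect base edits in one sample trace against its control.

    Parameters
    ----------
    sample_path
        ABIF (.ab1) chromatogram of the edited sample.
    control_path
        Unedited control, .ab1 or FASTA; None for control-free mode.
    motif
        gRNA protospacer sequence, 5'->3'.
    motif_fwd
        True when gRNA and sequencing primer read the same strand.
    wt, edit
        Wild-type base and its expected conversion, on the read strand.
    """
    sample = read_ab1(sample_path)
    control = read_control(control_path) if control_path is not None else None
    spec = MotifSpec(motif=motif, motif_fwd=motif_fwd, wt_base=wt, edit_base=edit)
    return detect_edits_from_traces(sample, control, spec, params)
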