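"""Result presentation: summary table, coverage profiles, structure figures.

Three user-facing products per run:

* a summary table of the predicted mature miRNAs — one row per arm — with
  their conservation status and per-library expression (RPM, 2 decimals);
* a per-position sRNA coverage profile along each pri-miRNA, drawn as a
  histogram with the mature-coding regions shaded yellow and the
  dot-bracket structure string as a track beneath the x axis;
* a secondary-structure drawing per pri-miRNA with the 5p arm marked green,
  the 3p arm red, and degradome-supported processing sites circled blue.

Every plotted series is also written to a machine-readable JSON sidecar, so
downstream checks (and this package's own tests) never parse images: the
figures are presentation only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import RNA

from .conservation import ConservationCall
from .degradome import ValidationResult
from .discovery import PriMiRNA, ReadMapping

__all__ = [
    "SummaryRow",
    "CoverageProfile",
    "AnnotationSpec",
    "mature_id",
    "build_summary_table",
    "build_coverage_profile",
    "build_annotation_spec",
    "render_outputs",
]

ARM_COLORS = {"5p": "green", "3p": "red"}
SITE_MARK = "blue circle"
MATURE_FILL = "yellow"


@dataclass
class SummaryRow:
    mature_id: str
    sequence: str
    conservation: str
    rpm_per_library: dict[str, float]


@dataclass
class CoverageProfile:
    pri_id: str
    per_position_rpm: dict[str, np.ndarray]  # library -> length-L array
    total: np.ndarray
    mature_regions: list[tuple[int, int]]
    dot_bracket: str

    @property
    def length(self) -> int:
        return len(self.total)


@dataclass
class AnnotationSpec:
    pri_id: str
    arm_marks: dict[str, tuple[int, int]] = field(default_factory=dict)  # arm -> interval
    supported_site_marks: list[int] = field(default_factory=list)
    mature_region_fill: str = MATURE_FILL


def mature_id(group: str, species_prefix: str, serial: int, arm: str) -> str:
    """Generated mature label, e.g. Leaf_tc_dof-miR1-5p."""
    return f"{group}_tc_{species_prefix}-miR{serial}-{arm}"


def build_summary_table(
    pris: list[PriMiRNA],
    calls: dict[str, ConservationCall],
    expression: pd.DataFrame,
    group: str,
    species_prefix: str = "xxx",
    serials: dict[str, int] | None = None,
) -> list[SummaryRow]:
    """Summary rows for the predicted matures: id, sequence, conservation, RPM.

    Two rows per two-armed pri (5p then 3p), one per single-armed pri.
    Serials follow discovery order unless an explicit mapping is given.
    ``calls`` is keyed by arm sequence; arms absent from it render as novel
    ("-"). Expression RPM is looked up per library in the merged expression
    table (``rpm_<lib>`` columns); arms absent from a library get 0.
    """
    lib_ids = [c[len("rpm_"):] for c in expression.columns if c.startswith("rpm_")]
    by_seq = expression.set_index("sequence") if len(expression) else None
    rows: list[SummaryRow] = []
    for i, pri in enumerate(pris, start=1):
        serial = serials[pri.pri_id] if serials else i
        for arm in ("5p", "3p"):
            seq = pri.candidate.arm_sequence(arm)
            if seq is None:
                continue
            call = calls.get(seq)
            rpm = {}
            for lib in lib_ids:
                if by_seq is not None and seq in by_seq.index:
                    rpm[lib] = float(by_seq.loc[seq, f"rpm_{lib}"])
                else:
                    rpm[lib] = 0.0
            rows.append(
                SummaryRow(
                    mature_id=mature_id(group, species_prefix, serial, arm),
                    sequence=seq,
                    conservation=call.render() if call else "-",
                    rpm_per_library=rpm,
                )
            )
    return rows


def summary_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    libs = sorted({lib for r in rows for lib in r.rpm_per_library}) if rows else []
    records = []
    for r in rows:
        rec = {"mature_id": r.mature_id, "sequence": r.sequence, "conservation": r.conservation}
        for lib in libs:
            rec[f"rpm_{lib}"] = round(r.rpm_per_library.get(lib, 0.0), 2)
        records.append(rec)
    cols = ["mature_id", "sequence", "conservation"] + [f"rpm_{l}" for l in libs]
    return pd.DataFrame(records, columns=cols)


def build_coverage_profile(pri: PriMiRNA, mappings: list[ReadMapping]) -> CoverageProfile:
    """Per-position sRNA accumulation (RPM) along a pri-miRNA.

    Each read contributes its RPM to every position it covers; values are
    kept per library and totalled. Only mappings inside the pri span and in
    the pri orientation contribute.
    """
    n = len(pri.sequence)
    span_start, span_end = pri.span
    libs = sorted({lib for m in mappings for lib, _ in m.rpm})
    per_lib = {lib: np.zeros(n) for lib in libs}
    total = np.zeros(n)
    for m in mappings:
        if m.transcript_id != pri.transcript_id or m.strand != pri.strand:
            continue
        if m.start < span_start or m.end > span_end:
            continue
        if pri.strand == "+":
            p_start = m.start - span_start + 1
        else:
            p_start = span_end - m.end + 1
        p_end = p_start + len(m.sequence) - 1
        sl = slice(p_start - 1, p_end)
        for lib, v in m.rpm:
            per_lib[lib][sl] += v
            total[sl] += v
    regions = [iv for iv in (pri.mature5p, pri.mature3p) if iv is not None]
    return CoverageProfile(
        pri_id=pri.pri_id,
        per_position_rpm=per_lib,
        total=total,
        mature_regions=regions,
        dot_bracket=pri.dot_bracket,
    )


def build_annotation_spec(pri: PriMiRNA, validation: ValidationResult | None = None) -> AnnotationSpec:
    """Colour/mark instructions for the structure drawing of one pri."""
    spec = AnnotationSpec(pri_id=pri.pri_id)
    if pri.mature5p is not None:
        spec.arm_marks["5p"] = pri.mature5p
    if pri.mature3p is not None:
        spec.arm_marks["3p"] = pri.mature3p
    if validation is not None:
        spec.supported_site_marks = sorted(s.site.position for s in validation.supported_sites)
    return spec


def _structure_coords(dot_bracket: str) -> tuple[np.ndarray, np.ndarray]:
    coords = RNA.simple_xy_coordinates(dot_bracket)
    xs = np.array([coords[i].X for i in range(len(dot_bracket))])
    ys = np.array([coords[i].Y for i in range(len(dot_bracket))])
    return xs, ys


def _plot_profile(profile: CoverageProfile, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(max(6, profile.length / 60), 3))
    x = np.arange(1, profile.length + 1)
    for s, e in profile.mature_regions:
        ax.axvspan(s - 0.5, e + 0.5, color=MATURE_FILL, alpha=0.6, lw=0)
    ax.bar(x, profile.total, width=1.0, color="steelblue")
    ax.set_xlabel("nucleotide position")
    ax.set_ylabel("sRNA accumulation (RPM)")
    ax.set_title(profile.pri_id, fontsize=9)
    ax.set_xlim(0.5, profile.length + 0.5)
    fig.text(0.02, 0.005, profile.dot_bracket, fontsize=3, family="monospace")
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def _plot_structure(profile: CoverageProfile, spec: AnnotationSpec, path: Path) -> None:
    xs, ys = _structure_coords(profile.dot_bracket)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot(xs, ys, color="0.6", lw=0.8, zorder=1)
    for arm, (s, e) in sorted(spec.arm_marks.items()):
        ax.plot(xs[s - 1 : e], ys[s - 1 : e], color=ARM_COLORS[arm], lw=2.5, zorder=2)
    for pos in spec.supported_site_marks:
        ax.scatter(
            [xs[pos - 1]], [ys[pos - 1]],
            facecolors="none", edgecolors="blue", s=80, zorder=3,
        )
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(spec.pri_id, fontsize=9)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def render_outputs(
    profiles: list[CoverageProfile],
    specs: list[AnnotationSpec],
    out_dir: str | Path,
) -> list[str]:
    """Write per-pri figures (SVG) and JSON sidecars, plus a manifest.

    Two images per pri (expression histogram, annotated structure) and one
    sidecar carrying every plotted series verbatim. Returns the manifest
    (list of relative file names), also written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matplotlib.rcParams["svg.hashsalt"] = "plantmir"
    spec_by_id = {s.pri_id: s for s in specs}
    manifest: list[str] = []
    for profile in profiles:
        spec = spec_by_id.get(profile.pri_id, AnnotationSpec(pri_id=profile.pri_id))
        safe = profile.pri_id.replace(":", "_").replace("/", "_")
        expr_svg = out / f"{safe}.expression.svg"
        struct_svg = out / f"{safe}.structure.svg"
        sidecar = out / f"{safe}.json"
        _plot_profile(profile, expr_svg)
        _plot_structure(profile, spec, struct_svg)
        payload = {
            "pri_id": profile.pri_id,
            "length": profile.length,
            "per_position_rpm": {
                lib: [round(float(v), 6) for v in arr]
                for lib, arr in sorted(profile.per_position_rpm.items())
            },
            "total_rpm": [round(float(v), 6) for v in profile.total],
            "mature_regions": [list(iv) for iv in profile.mature_regions],
            "dot_bracket": profile.dot_bracket,
            "arm_marks": {arm: [iv[0], iv[1]] for arm, iv in sorted(spec.arm_marks.items())},
            "arm_colors": {arm: ARM_COLORS[arm] for arm in sorted(spec.arm_marks)},
            "supported_site_marks": spec.supported_site_marks,
            "mature_region_fill": spec.mature_region_fill,
        }
        sidecar.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
        manifest.extend([expr_svg.name, struct_svg.name, sidecar.name])
    (out / "manifest.json").write_text(json.dumps(sorted(manifest), indent=1) + "\n")
    return sorted(manifest)
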