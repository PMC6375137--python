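"""Degradome-seq (PARE) validation of miRNA processing sites on pri-miRNAs.

Dicer-like maturation of a pri-miRNA leaves predictable 5' ends on its 3'
cleavage remnants, and those remnants are exactly what degradome-seq
captures on polyadenylated transcripts. Four processing sites are therefore
expected on a two-armed pri-miRNA: the 5' ends of the 5p and 3p matures,
and the positions 1 nt downstream of their 3' ends. A degradome tag whose
5' end coincides with such a site (exactly, by default) is a processing
signature supporting the candidate.

Tags are mapped to the sense strand of the pri-miRNA only: degradome reads
are fragments of the pri transcript itself, so antisense hits carry no
meaning here. The 3' extension carried by the pri-miRNA exists precisely so
that tags starting at the 3'-most site have transcript sequence to map onto.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .discovery import PriMiRNA

__all__ = [
    "ProcessingSite",
    "ProcessingSiteSet",
    "SignatureHit",
    "ValidationResult",
    "expected_processing_sites",
    "map_degradome_tags",
    "call_supported_sites",
    "validate_pri",
]

SITE_KINDS = ("start5p", "after_end5p", "start3p", "after_end3p")


@dataclass(frozen=True)
class ProcessingSite:
    position: int  # 1-based pri-miRNA coordinate
    site_kind: str


@dataclass(frozen=True)
class ProcessingSiteSet:
    pri_id: str
    sites: tuple[ProcessingSite, ...]

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)


@dataclass(frozen=True)
class SignatureHit:
    pri_id: str
    position: int  # 1-based 5'-end position of the mapped tag
    sequence: str
    count: int
    rpm: tuple[tuple[str, float], ...] = ()

    @property
    def total_rpm(self) -> float:
        return sum(v for _, v in self.rpm)


@dataclass
class SupportedSite:
    site: ProcessingSite
    tag_count: int
    rpm: dict[str, float]

    @property
    def total_rpm(self) -> float:
        return sum(self.rpm.values())


@dataclass
class ValidationResult:
    pri_id: str
    sites: ProcessingSiteSet
    supported_sites: list[SupportedSite] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites.sites)

    @property
    def n_supported(self) -> int:
        return len(self.supported_sites)


def expected_processing_sites(pri: PriMiRNA) -> ProcessingSiteSet:
    """The Dicer-like cleavage-derived 5'-end positions expected on a pri.

    Both arms annotated: {mature5p.start, mature5p.end + 1, mature3p.start,
    mature3p.end + 1}, in pri (read-orientation) coordinates. A single-arm
    candidate yields the two sites of that arm, labelled the same way.
    """
    sites: list[ProcessingSite] = []
    if pri.mature5p is not None:
        sites.append(ProcessingSite(pri.mature5p[0], "start5p"))
        sites.append(ProcessingSite(pri.mature5p[1] + 1, "after_end5p"))
    if pri.mature3p is not None:
        sites.append(ProcessingSite(pri.mature3p[0], "start3p"))
        sites.append(ProcessingSite(pri.mature3p[1] + 1, "after_end3p"))
    if not sites:
        raise ValueError(f"pri {pri.pri_id} has no annotated mature interval")
    sites.sort(key=lambda s: s.position)
    return ProcessingSiteSet(pri_id=pri.pri_id, sites=tuple(sites))


def map_degradome_tags(tags: pd.DataFrame, pri: PriMiRNA) -> list[SignatureHit]:
    """Exact, ungapped, sense-strand placement of degradome tags on a pri.

    ``tags`` is a collapsed tag table (columns sequence/count and optionally
    per-library rpm columns). One hit per (tag, position), ordered by
    position then sequence.
    """
    seq = pri.sequence
    hits: list[SignatureHit] = []
    for row in tags.to_dict("records"):
        tag = row["sequence"]
        rpm_cols = tuple(
            (name[len("rpm_"):], float(row[name])) for name in tags.columns if name.startswith("rpm_")
        )
        if not rpm_cols and "rpm" in tags.columns:
            rpm_cols = ((tags.attrs.get("library_id", "lib"), float(row["rpm"])),)
        if "count" in tags.columns:
            count = int(row["count"])
        else:
            count = sum(int(row[c]) for c in tags.columns if c.startswith("count_"))
        start = seq.find(tag)
        while start != -1:
            hits.append(
                SignatureHit(
                    pri_id=pri.pri_id,
                    position=start + 1,
                    sequence=tag,
                    count=count,
                    rpm=rpm_cols,
                )
            )
            start = seq.find(tag, start + 1)
    hits.sort(key=lambda h: (h.position, h.sequence))
    return hits


def call_supported_sites(
    hits: list[SignatureHit],
    sites: ProcessingSiteSet,
    tolerance: int = 0,
    min_rpm: float = 0.0,
) -> ValidationResult:
    """Call which expected processing sites have degradome support.

    A site is supported iff some hit lies within ``tolerance`` nt of it and
    the summed RPM over libraries at that site exceeds ``min_rpm``. Multiple
    distinct tags at one site are aggregated by summing counts and RPM.
    """
    result = ValidationResult(pri_id=sites.pri_id, sites=sites)
    for site in sites.sites:
        near = [h for h in hits if abs(h.position - site.position) <= tolerance]
        if not near:
            continue
        rpm: dict[str, float] = {}
        count = 0
        for h in near:
            count += h.count
            for lib, v in h.rpm:
                rpm[lib] = rpm.get(lib, 0.0) + v
        if sum(rpm.values()) > min_rpm or (not rpm and count > 0 and min_rpm <= 0):
            result.supported_sites.append(SupportedSite(site=site, tag_count=count, rpm=rpm))
    return result


def validate_pri(
    pri: PriMiRNA,
    tags: pd.DataFrame,
    tolerance: int = 0,
    min_rpm: float = 0.0,
) -> ValidationResult:
    """Convenience: derive sites, map tags, call support for one pri-miRNA."""
    sites = expected_processing_sites(pri)
    hits = map_degradome_tags(tags, pri)
    return call_supported_sites(hits, sites, tolerance=tolerance, min_rpm=min_rpm)


def validation_tables(results: list[ValidationResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site and per-pri summary DataFrames for TSV output."""
    site_rows = []
    summary_rows = []
    for res in results:
        supported = {s.site.position: s for s in res.supported_sites}
        for site in res.sites.sites:
            hit = supported.get(site.position)
            site_rows.append(
                {
                    "pri_id": res.pri_id,
                    "site_kind": site.site_kind,
                    "position": site.position,
                    "supported": int(hit is not None),
                    "tag_count": hit.tag_count if hit else 0,
                    "total_rpm": round(hit.total_rpm, 6) if hit else 0.0,
                }
            )
        summary_rows.append(
            {"pri_id": res.pri_id, "n_sites": res.n_sites, "n_supported": res.n_supported}
        )
    cols_site = ["pri_id", "site_kind", "position", "supported", "tag_count", "total_rpm"]
    cols_sum = ["pri_id", "n_sites", "n_supported"]
    return (
        pd.DataFrame(site_rows, columns=cols_site),
        pd.DataFrame(summary_rows, columns=cols_sum),
    )
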